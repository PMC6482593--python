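"""Reverse-complement homology between the introns flanking a circularized exon block.

Reverse-complementary segments in the 5' and 3' flanking introns let a
pre-mRNA fold back on itself, bringing the back-splice donor and acceptor
into proximity and favoring circRNA biogenesis.  Each intron pair is scored
by locally aligning the 5' intron against the reverse complement of the 3'
intron with affine gap penalties, then converting the raw score to a bit
score and E-value with Karlin–Altschul statistics:

    S' = (λ·S − ln K) / ln 2,      E = m·n·2^(−S')

with m, n the two intron lengths (a pairwise search space, not a database
model).  A pair is called significant when E < 1e−20.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from scipy import stats

__all__ = [
    "ScoringScheme",
    "HomologyResult",
    "DEFAULT_SCHEME",
    "EVALUE_CUTOFF",
    "reverse_complement",
    "align_rc",
    "score_all",
    "group_bitscore_tests",
]

logger = logging.getLogger(__name__)

#: Significance threshold on the pairwise E-value.
EVALUE_CUTOFF = 1e-20

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


@dataclass(frozen=True)
class ScoringScheme:
    """Nucleotide scoring: +match, −mismatch, affine gap cost open + k·extend.

    The Karlin–Altschul parameters default to the published ungapped values
    for +1/−2 scoring, used as an approximation for the gapped case.
    """

    match: int = 1
    mismatch: int = -2
    gap_open: int = 5
    gap_extend: int = 2
    lam: float = 1.28
    k: float = 0.46

    def __post_init__(self) -> None:
        if not (self.match > 0 > self.mismatch):
            raise ValueError("need match > 0 > mismatch")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be >= 0")
        if self.lam <= 0 or self.k <= 0:
            raise ValueError("Karlin-Altschul lambda and K must be > 0")

    def bitscore(self, raw_score: float) -> float:
        return (self.lam * raw_score - math.log(self.k)) / math.log(2)

    def evalue(self, bitscore: float, m: int, n: int) -> float:
        # m*n / 2**bitscore, in logs to survive bitscores of thousands
        log10_e = math.log10(m) + math.log10(n) - bitscore * math.log10(2)
        if log10_e < -320:
            return 0.0
        return 10.0**log10_e


DEFAULT_SCHEME = ScoringScheme()


@dataclass(frozen=True)
class HomologyResult:
    pident: float
    raw_score: float
    bitscore: float
    evalue: float
    aln_len: int
    significant: bool


def reverse_complement(seq: str) -> str:
    """Reverse complement over the ACGTN alphabet (case-insensitive; N<->N)."""
    bad = set(seq.upper()) - set("ACGTN")
    if bad:
        raise ValueError(f"non-ACGTN symbols in sequence: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def _aligner(scheme: ScoringScheme) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = scheme.match
    aligner.mismatch_score = scheme.mismatch
    # total cost of a length-k gap is gap_open + k*gap_extend
    aligner.open_gap_score = -(scheme.gap_open + scheme.gap_extend)
    aligner.extend_gap_score = -scheme.gap_extend
    return aligner


def align_rc(
    intron5: str, intron3: str, scheme: ScoringScheme = DEFAULT_SCHEME
) -> HomologyResult:
    """Best local alignment of the 5' intron against revcomp(3' intron).

    Ties between equal-scoring alignments are broken deterministically by
    the aligner's traceback order (first reported alignment).
    """
    if not intron5 or not intron3:
        raise ValueError("flanking intron sequences must be non-empty")
    target = intron5.upper()
    query = reverse_complement(intron3).upper()
    aligner = _aligner(scheme)
    score = float(aligner.score(target, query))
    if score <= 0:
        bitscore = scheme.bitscore(0.0)
        evalue = scheme.evalue(bitscore, len(intron5), len(intron3))
        return HomologyResult(0.0, 0.0, bitscore, evalue, 0, evalue < EVALUE_CUTOFF)
    alignment = next(iter(aligner.align(target, query)))
    counts = alignment.counts()
    aln_len = counts.identities + counts.mismatches + counts.gaps
    pident = 100.0 * counts.identities / aln_len if aln_len else 0.0
    bitscore = scheme.bitscore(score)
    evalue = scheme.evalue(bitscore, len(intron5), len(intron3))
    return HomologyResult(
        pident=pident,
        raw_score=score,
        bitscore=bitscore,
        evalue=evalue,
        aln_len=int(aln_len),
        significant=evalue < EVALUE_CUTOFF,
    )


def score_all(
    pairs: Mapping[str, tuple[str | None, str | None]],
    scheme: ScoringScheme = DEFAULT_SCHEME,
    groups: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Score every circRNA's flanking intron pair.

    ``pairs`` maps circ_key -> (intron5_seq, intron3_seq); a missing intron
    (None) scores 0 and is non-significant, keeping the design matrix
    complete.  Returns one row per circRNA, zero-filled bitscores included.
    """
    groups = groups or {}
    rows = []
    for key in pairs:
        i5, i3 = pairs[key]
        if not i5 or not i3:
            logger.warning("circRNA %s missing a flanking intron; bitscore set to 0", key)
            res = HomologyResult(0.0, 0.0, 0.0, math.inf, 0, False)
        else:
            res = align_rc(i5, i3, scheme)
            if not res.significant:
                # zero-fill convention: pairs without significant reverse
                # complementarity carry bitscore 0 in downstream group tests
                res = HomologyResult(
                    res.pident, res.raw_score, 0.0, res.evalue, res.aln_len, False
                )
        rows.append(
            {
                "circ_key": key,
                "group": groups.get(key),
                "pident": res.pident,
                "raw_score": res.raw_score,
                "bitscore": res.bitscore,
                "evalue": res.evalue,
                "aln_len": res.aln_len,
                "significant": res.significant,
            }
        )
    return pd.DataFrame(rows)


def group_bitscore_tests(
    bitscores_by_group: Mapping[str, Sequence[float]] | pd.DataFrame,
    drop_max: bool = False,
) -> tuple[float, float]:
    """One-way ANOVA and tie-corrected Kruskal–Wallis over zero-filled bitscores.

    ``drop_max`` removes the single global maximum observation (an outlier
    guard for a huge score in a tiny group) before testing.
    """
    if isinstance(bitscores_by_group, pd.DataFrame):
        grouped = {
            name: sub["bitscore"].to_list()
            for name, sub in bitscores_by_group.dropna(subset=["group"]).groupby("group")
        }
    else:
        grouped = {k: list(v) for k, v in bitscores_by_group.items()}
    groups = [np.asarray(v, dtype=float) for v in grouped.values() if len(v) > 0]
    if sum(1 for g in groups if len(g) >= 2) < 2:
        raise ValueError("need at least 2 groups with >= 2 observations")
    if drop_max:
        flat_max = max(g.max() for g in groups)
        removed = False
        out = []
        for g in groups:
            if not removed and g.max() == flat_max:
                idx = int(np.argmax(g))
                g = np.delete(g, idx)
                removed = True
            out.append(g)
        groups = [g for g in out if len(g) > 0]
    anova_p = float(stats.f_oneway(*groups).pvalue)
    kw_p = float(stats.kruskal(*groups).pvalue)
    return anova_p, kw_p
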