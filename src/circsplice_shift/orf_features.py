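"""Coding potential of circular transcripts.

A circular RNA has no 5' end: an open reading frame may start near the
back-splice junction and read straight through it, and in the extreme case
never meet an in-frame stop within a full pass of the circle (a
"rolling-circle" frame).  Scanning on the doubled sequence seq+seq with
starts restricted to the first copy handles both cases.  Translation
initiation context is assessed by exact circular matching of the Kozak
consensus GCCRCCATGG, and translatability by an externally supplied IRES
table (R-value and pseudoknot flag).  Candidate peptides are classified
against a reference protein set by local alignment under BLOSUM62 with
Karlin–Altschul E-values.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .io_formats import CircRecord

__all__ = [
    "CircOrf",
    "IresRecord",
    "PeptideMatch",
    "find_circular_orfs",
    "kozak_scan",
    "classify_peptide_match",
    "filter_ires",
    "match_by_length_and_locus",
    "IRES_R_CUTOFF",
    "PEPTIDE_EVALUE_NEAR_PERFECT",
    "PEPTIDE_EVALUE_PARTIAL",
]

IRES_R_CUTOFF = 1.54
PEPTIDE_EVALUE_NEAR_PERFECT = 1e-4
PEPTIDE_EVALUE_PARTIAL = 10.0

_KOZAK_RE = re.compile("GCC[AG]CCATGG")
_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class CircOrf:
    """An ORF on a circular sequence of length L.

    ``start`` is a circular coordinate in [0, L); ``length_nt`` includes the
    stop codon when one exists.  ``crosses_junction`` means the frame runs
    through the back-splice junction (start + length_nt > L);
    ``rolling_circle`` means no in-frame stop occurs within one full circle,
    in which case the frame is capped at one circle and flagged.
    """

    start: int
    length_nt: int
    peptide: str
    crosses_junction: bool
    rolling_circle: bool


@dataclass(frozen=True)
class IresRecord:
    circ_key: str
    r_value: float
    has_pseudoknot: bool


@dataclass(frozen=True)
class PeptideMatch:
    category: str  # near_perfect | partial | none
    pident: float
    evalue: float
    subject: str
    same_gene: bool


def _check_alphabet(seq: str) -> str:
    seq = seq.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"non-ACGTN symbols in sequence: {sorted(bad)}")
    return seq


def find_circular_orfs(seq: str, min_aa: int = 20) -> list[CircOrf]:
    """Scan a circular sequence for ORFs, including junction-crossing frames.

    ATG starts are sought at circular positions 0..L−1 on the doubled
    sequence; each start is translated until the first in-frame stop.  A
    frame with no stop within one full circle is reported once, capped at
    L − (L mod 3) nt, with ``rolling_circle=True``.  Only ORFs with at least
    ``min_aa`` translated residues are reported.
    """
    seq = _check_alphabet(seq)
    L = len(seq)
    if L < 3:
        raise ValueError("sequence must be at least 3 nt")
    doubled = seq + seq
    orfs: list[CircOrf] = []
    for start in range(L):
        if doubled[start : start + 3] != "ATG":
            continue
        stop_at = None
        pos = start
        while pos + 3 <= start + L:
            codon = doubled[pos : pos + 3]
            if len(codon) < 3:
                break
            if codon in _STOPS and pos > start:
                stop_at = pos
                break
            if codon in _STOPS and pos == start:
                break
            pos += 3
        if doubled[start : start + 3] in _STOPS:
            continue
        if stop_at is None:
            length_nt = L - (L % 3)
            coding = doubled[start : start + length_nt]
            peptide = str(Seq(coding).translate())
            rolling = True
        else:
            length_nt = stop_at + 3 - start
            coding = doubled[start : start + length_nt]
            peptide = str(Seq(coding[:-3]).translate())
            rolling = False
        if "*" in peptide:
            peptide = peptide.split("*")[0]
        if len(peptide) < min_aa:
            continue
        orfs.append(
            CircOrf(
                start=start,
                length_nt=length_nt,
                peptide=peptide,
                crosses_junction=start + length_nt > L,
                rolling_circle=rolling,
            )
        )
    return orfs


def kozak_scan(seq: str) -> list[int]:
    """Circular positions of exact Kozak consensus (GCCRCCATGG) matches.

    The scan runs on the doubled sequence so a motif split across the
    back-splice junction is found; positions are reported mod L, deduplicated
    and sorted.
    """
    seq = _check_alphabet(seq)
    L = len(seq)
    window = seq + seq[: min(9, L)]
    hits = set()
    for m in _KOZAK_RE.finditer(window):
        if m.start() < L:
            hits.add(m.start() % L)
    return sorted(hits)


def _protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    # length-k gap costs 11 + k
    aligner.open_gap_score = -12
    aligner.extend_gap_score = -1
    return aligner


def classify_peptide_match(
    pep: str,
    refdb: Mapping[str, tuple[str, str]],
    lam: float = 0.267,
    k: float = 0.041,
    query_gene: str | None = None,
) -> PeptideMatch:
    """Best local-alignment hit of a peptide against a reference protein set.

    ``refdb`` maps subject name -> (sequence, gene label).  The raw BLOSUM62
    affine-gap score of the best subject is converted to a bit score
    (λS − ln K)/ln 2 and E-value over a search space of query length × total
    database length.  Categories: near_perfect (E < 1e−4), partial
    (1e−4 ≤ E < 10), none.
    """
    if not refdb:
        raise ValueError("reference protein set is empty")
    aligner = _protein_aligner()
    db_len = sum(len(s) for s, _ in refdb.values())
    best_score = -math.inf
    best_name = ""
    best_aln = None
    for name in refdb:
        subject, _gene = refdb[name]
        score = aligner.score(pep, subject)
        if score > best_score:
            best_score = score
            best_name = name
            best_aln = None  # lazily recompute below
    subject_seq, subject_gene = refdb[best_name]
    alignments = aligner.align(pep, subject_seq)
    best_aln = next(iter(alignments))
    counts = best_aln.counts()
    aln_len = counts.identities + counts.mismatches + counts.gaps
    pident = 100.0 * counts.identities / aln_len if aln_len else 0.0
    bitscore = (lam * best_score - math.log(k)) / math.log(2)
    log10_e = math.log10(max(len(pep), 1)) + math.log10(max(db_len, 1)) - bitscore * math.log10(2)
    evalue = 0.0 if log10_e < -320 else 10.0**log10_e
    if evalue < PEPTIDE_EVALUE_NEAR_PERFECT:
        category = "near_perfect"
    elif evalue < PEPTIDE_EVALUE_PARTIAL:
        category = "partial"
    else:
        category = "none"
    return PeptideMatch(
        category=category,
        pident=pident,
        evalue=evalue,
        subject=best_name,
        same_gene=(query_gene is not None and subject_gene == query_gene),
    )


def filter_ires(
    records: Iterable[IresRecord],
    r_cutoff: float = IRES_R_CUTOFF,
    require_pseudoknot: bool = True,
) -> list[IresRecord]:
    """Keep IRES records with R-value strictly above the cutoff (and a pseudoknot)."""
    kept = []
    for rec in records:
        if rec.r_value <= r_cutoff:
            continue
        if require_pseudoknot and not rec.has_pseudoknot:
            continue
        kept.append(rec)
    return kept


def match_by_length_and_locus(circ: CircRecord, db: Sequence[dict]) -> list[dict]:
    """Database entries whose gene symbol and genomic length both match.

    ``db`` rows are dicts with at least ``gene`` and ``genomic_length``.
    An empty result corresponds to the record carrying no database ID.
    """
    length = circ.genomic_length
    return [
        row
        for row in db
        if row["gene"] == circ.gene_symbol and int(row["genomic_length"]) == length
    ]
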