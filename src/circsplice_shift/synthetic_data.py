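"""Seeded synthetic inputs with the statistical structure the analysis assumes.

The study's raw sequencing data and database downloads are not deposited, so
every pipeline stage is exercised on generated inputs instead: negative-
binomially distributed junction read counts with planted log2 effects,
housekeeping fold changes near 1, intron pairs with planted reverse-
complement segments, per-group signed interaction-distance mixtures with an
upstream/downstream bias, and circular sequences with planted
junction-crossing ORFs and Kozak motifs.  Every generator is a pure function
of :class:`SimConfig`; truth tables record each planted feature so that
downstream classifiers can be scored without re-reading the configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import CircRecord

__all__ = [
    "SimConfig",
    "HOUSEKEEPING_GENES",
    "generate_circ_tables",
    "generate_mrna_table",
    "generate_intron_pairs",
    "generate_interactions",
    "generate_circ_sequences",
]

#: The ten housekeeping genes whose fold changes calibrate the "unchanged" interval.
HOUSEKEEPING_GENES = (
    "C1orf43", "CHMP2A", "GAPDH", "EMC7", "GPI",
    "PSMB2", "PSMB4", "RAB7A", "SNRPD3", "VPS29",
)

_BASES = np.array(list("ACGT"))
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
# codons free of in-frame stops, used to extend planted ORFs safely
_SAFE_CODONS = ("GCT", "GGA", "CTG", "AAA", "GAA", "TCC", "CGT", "ACA")


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for all synthetic generators.

    Defaults emulate the observed data scale: ~1,000 circRNAs shared between
    conditions with low junction read counts (1–29), ~7% planted expression
    effects split 2:1 up:down, housekeeping fold changes with SD ≈ 0.02
    about 1, 68.8% of intron pairs carrying a reverse-complement segment,
    interaction distances on a 10^6 bp scale, and 74% of circular sequences
    carrying a junction-crossing ORF.
    """

    seed: int = 0
    n_shared: int = 1000
    n_condition_specific: int = 200
    nb_mean: float = 5.0
    nb_dispersion: float = 25.0
    frac_up: float = 0.047
    frac_down: float = 0.024
    effect_log2: float = 3.0
    hk_sd: float = 0.02
    frac_rc_introns: float = 0.688
    rc_len: int = 300
    rc_identity: float = 0.9
    intron_len: int = 2000
    n_intron_pairs: int = 77
    n_interactions_per_gene: int = 50
    upstream_bias: float = 0.5
    dist_scale: float = 1e6
    n_circ_sequences: int = 77
    circ_seq_len: int = 400
    orf_plant_rate: float = 0.74
    kozak_plant_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "frac_up", "frac_down", "frac_rc_introns", "rc_identity",
            "upstream_bias", "orf_plant_rate", "kozak_plant_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_shared", "n_condition_specific", "n_intron_pairs",
                     "n_interactions_per_gene", "n_circ_sequences"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.rc_len >= self.intron_len:
            raise ValueError("rc_len must be smaller than intron_len")
        if self.circ_seq_len < 300:
            raise ValueError("circ_seq_len must be >= 300")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic stream per generator."""
        return np.random.default_rng([self.seed, stream])


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, size_param: float) -> np.ndarray:
    """Negative binomial with given means and dispersion; zero-truncated to >= 1.

    Junction tables only contain detected circRNAs, so zero draws are lifted
    to 1 (a mild truncation at these means).
    """
    mean = np.asarray(mean, dtype=float)
    p = size_param / (size_param + mean)
    counts = rng.negative_binomial(size_param, p)
    return np.maximum(counts, 1)


def _mk_record(i: int, chrom: str, start: int, reads_c: int, reads_t: int) -> CircRecord:
    end = start + 500 + (i % 7) * 250
    return CircRecord(
        chrom=chrom,
        start=start,
        end=end,
        strand="+" if i % 2 == 0 else "-",
        gene_symbol=f"GENE{i:05d}",
        exon_indices=tuple(range(2, 2 + (i % 5) + 1)),
        reads_control=reads_c,
        reads_treated=reads_t,
        intron5_interval=(chrom, max(start - 2000, 0), start),
        intron3_interval=(chrom, end, end + 2000),
    )


def generate_circ_tables(
    cfg: SimConfig,
) -> tuple[list[CircRecord], list[CircRecord], pd.DataFrame]:
    """Per-condition junction-call tables plus a planted-class truth table.

    Shared circRNAs get control counts ~ NB(nb_mean) and treated counts
    ~ NB(nb_mean · 2^(±effect_log2)) for the planted up/down subsets
    (· 2^0 otherwise); each condition also gets condition-specific calls that
    must disappear in the two-condition merge.
    """
    rng = cfg.rng(1)
    n = cfg.n_shared
    n_up = int(round(cfg.frac_up * n))
    n_down = int(round(cfg.frac_down * n))
    classes = np.array(["null"] * n, dtype=object)
    order = rng.permutation(n)
    classes[order[:n_up]] = "up"
    classes[order[n_up : n_up + n_down]] = "down"

    chroms = np.array([f"chr{c}" for c in rng.integers(1, 23, size=n)])
    starts = rng.integers(10_000, 200_000_000, size=n)
    mean_c = np.full(n, cfg.nb_mean)
    mult = np.where(
        classes == "up", 2.0**cfg.effect_log2,
        np.where(classes == "down", 2.0**-cfg.effect_log2, 1.0),
    )
    reads_c = _nb_counts(rng, mean_c, cfg.nb_dispersion)
    reads_t = _nb_counts(rng, mean_c * mult, cfg.nb_dispersion)

    control, treated, truth_rows = [], [], []
    for i in range(n):
        rec = _mk_record(i, str(chroms[i]), int(starts[i]), int(reads_c[i]), int(reads_t[i]))
        control.append(replace(rec, reads_treated=0))
        treated.append(replace(rec, reads_control=0))
        truth_rows.append(
            {
                "circ_key": rec.circ_key,
                "gene_symbol": rec.gene_symbol,
                "planted_class": classes[i],
                "shared": True,
            }
        )
    # condition-specific calls, distinct coordinate block to guarantee no overlap
    for j in range(cfg.n_condition_specific):
        i = n + j
        chrom = f"chr{int(rng.integers(1, 23))}"
        start = int(rng.integers(250_000_000, 280_000_000))
        rc = int(_nb_counts(rng, np.array([cfg.nb_mean]), cfg.nb_dispersion)[0])
        control.append(_mk_record(i, chrom, start, rc, 0))
        truth_rows.append(
            {"circ_key": control[-1].circ_key, "gene_symbol": control[-1].gene_symbol,
             "planted_class": "control_only", "shared": False}
        )
    for j in range(cfg.n_condition_specific):
        i = n + cfg.n_condition_specific + j
        chrom = f"chr{int(rng.integers(1, 23))}"
        start = int(rng.integers(250_000_000, 280_000_000))
        rt = int(_nb_counts(rng, np.array([cfg.nb_mean]), cfg.nb_dispersion)[0])
        treated.append(_mk_record(i, chrom, start, 0, rt))
        truth_rows.append(
            {"circ_key": treated[-1].circ_key, "gene_symbol": treated[-1].gene_symbol,
             "planted_class": "treated_only", "shared": False}
        )
    return control, treated, pd.DataFrame(truth_rows)


def generate_mrna_table(
    cfg: SimConfig,
    genes: Sequence[str],
    effect: float = 0.3,
    frac_changed: float = 0.3,
) -> pd.DataFrame:
    """Fold-change table with housekeeping genes pinned near 1.

    Housekeeping fold changes are Normal(1, hk_sd) truncated positive; the
    remaining genes are a mixture of planted increased (1+effect), decreased
    (1−effect) and unchanged classes, recorded in the ``planted_class``
    column.
    """
    missing = set(HOUSEKEEPING_GENES) - set(genes)
    if missing:
        raise ValueError(f"gene list must include housekeeping genes, missing {sorted(missing)}")
    rng = cfg.rng(2)
    rows = []
    others = [g for g in genes if g not in HOUSEKEEPING_GENES]
    n_changed = int(round(frac_changed * len(others)))
    order = rng.permutation(len(others))
    planted = {}
    for rank, idx in enumerate(order):
        if rank < n_changed // 2:
            planted[others[idx]] = "increased"
        elif rank < n_changed:
            planted[others[idx]] = "decreased"
        else:
            planted[others[idx]] = "unchanged"
    for g in genes:
        if g in HOUSEKEEPING_GENES:
            fc = rng.normal(1.0, cfg.hk_sd) if cfg.hk_sd > 0 else 1.0
            while fc <= 0:
                fc = rng.normal(1.0, cfg.hk_sd)
            rows.append({"gene": g, "fold_change": fc, "planted_class": "housekeeping"})
        else:
            cls = planted[g]
            center = {"increased": 1 + effect, "decreased": 1 - effect, "unchanged": 1.0}[cls]
            fc = center * rng.normal(1.0, cfg.hk_sd) if cfg.hk_sd > 0 else center
            while fc <= 0:
                fc = center * rng.normal(1.0, cfg.hk_sd)
            rows.append({"gene": g, "fold_change": fc, "planted_class": cls})
    return pd.DataFrame(rows)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def generate_intron_pairs(
    cfg: SimConfig,
) -> tuple[dict[str, tuple[str, str]], pd.DataFrame]:
    """Flanking-intron sequence pairs, a planted fraction carrying homology.

    For a planted pair, a window of the 3' intron is the reverse complement
    of a 5' window with per-base identity ``rc_identity``; backgrounds are
    uniform A/C/G/T.  Returns ``{key: (intron5, intron3)}`` plus the truth
    table of planted pairs.
    """
    rng = cfg.rng(3)
    pairs: dict[str, tuple[str, str]] = {}
    rows = []
    n_planted = int(round(cfg.frac_rc_introns * cfg.n_intron_pairs))
    for i in range(cfg.n_intron_pairs):
        key = f"circ{i:04d}"
        i5 = _random_seq(rng, cfg.intron_len)
        i3 = _random_seq(rng, cfg.intron_len)
        planted = i < n_planted
        if planted:
            pos5 = int(rng.integers(0, cfg.intron_len - cfg.rc_len + 1))
            segment = i5[pos5 : pos5 + cfg.rc_len]
            rc = list(_revcomp(segment))
            n_mut = int(round((1.0 - cfg.rc_identity) * cfg.rc_len))
            for j in rng.choice(cfg.rc_len, size=n_mut, replace=False):
                current = rc[j]
                choices = [b for b in "ACGT" if b != current]
                rc[j] = choices[int(rng.integers(0, 3))]
            pos3 = int(rng.integers(0, cfg.intron_len - cfg.rc_len + 1))
            i3 = i3[:pos3] + "".join(rc) + i3[pos3 + cfg.rc_len :]
        pairs[key] = (i5, i3)
        rows.append({"circ_key": key, "planted_rc": planted})
    return pairs, pd.DataFrame(rows)


def generate_interactions(
    cfg: SimConfig,
    genes_with_groups: pd.DataFrame,
    group_bias: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """4DGenome-dialect interaction table with per-group upstream bias.

    ``genes_with_groups`` needs columns ``gene``, ``chrom``, ``start`` and
    ``group``.  Each anchor gene receives ``n_interactions_per_gene``
    partners; a partner lies upstream (anchor downstream ⇒ positive signed
    distance... the partner is *before* the anchor) with probability
    ``group_bias[group]`` (default ``cfg.upstream_bias``), and |distance| is
    LogNormal(ln dist_scale, 1).  Detection method is "Hi-C".
    """
    required = {"gene", "chrom", "start", "group"}
    if not required.issubset(genes_with_groups.columns):
        raise ValueError(f"genes_with_groups needs columns {sorted(required)}")
    rng = cfg.rng(4)
    group_bias = group_bias or {}
    rows = []
    for rec in genes_with_groups.itertuples(index=False):
        bias = group_bias.get(rec.group, cfg.upstream_bias)
        for _ in range(cfg.n_interactions_per_gene):
            mag = rng.lognormal(mean=np.log(cfg.dist_scale), sigma=1.0)
            mag = int(max(round(mag), 1))
            upstream = rng.random() < bias
            # upstream interaction: anchor lies upstream of its partner,
            # i.e. partner start beyond anchor start => negative signed distance
            partner_start = rec.start + mag if upstream else rec.start - mag
            partner_start = int(max(partner_start, 0))
            rows.append(
                {
                    "InteractorAChr": rec.chrom,
                    "InteractorAStart": int(rec.start),
                    "InteractorAEnd": int(rec.start) + 1000,
                    "InteractorBChr": rec.chrom,
                    "InteractorBStart": partner_start,
                    "InteractorBEnd": partner_start + 1000,
                    "Agene": rec.gene,
                    "Bgene": f"PARTNER_{rec.gene}",
                    "Cell/Tissue": "synthetic",
                    "Detection_Method": "Hi-C",
                    "Confidence_Score1": 1,
                    "Confidence_Score2": 1,
                    "Contact_Frequency": 1,
                    "Organism": "Homo sapiens",
                }
            )
    return pd.DataFrame(rows)


def generate_circ_sequences(
    cfg: SimConfig,
) -> tuple[dict[str, str], pd.DataFrame, pd.DataFrame]:
    """Circular transcript sequences with planted junction-crossing ORFs.

    A planted ORF starts in-frame shortly before the back-splice junction
    (position L−21) and runs through it on stop-free codons, terminating
    beyond the junction, so any circular ORF caller must read through the
    junction to find it.  Planted Kozak motifs are exact GCCRCCATGG copies.
    Returns sequences, an IRES annotation table (r_value, pseudoknot flag)
    and the truth table.
    """
    rng = cfg.rng(5)
    L = cfg.circ_seq_len
    seqs: dict[str, str] = {}
    ires_rows, truth_rows = [], []
    for i in range(cfg.n_circ_sequences):
        key = f"circ{i:04d}"
        seq = list(_random_seq(rng, L))
        plant_orf = rng.random() < cfg.orf_plant_rate
        plant_kozak = rng.random() < cfg.kozak_plant_rate
        if plant_orf:
            # ATG at L-21 (in-frame positions), ~40 safe codons crossing the
            # junction, then a stop: start + length > L guaranteed
            start = L - 21
            codons = ["ATG"]
            codons += [
                _SAFE_CODONS[int(rng.integers(0, len(_SAFE_CODONS)))]
                for _ in range(40)
            ]
            codons.append("TAA")
            insert = "".join(codons)
            for j, base in enumerate(insert):
                seq[(start + j) % L] = base
        if plant_kozak:
            r = "A" if rng.random() < 0.5 else "G"
            motif = f"GCC{r}CCATGG"
            # keep clear of a planted ORF region near the junction
            pos = int(rng.integers(0, L // 2))
            for j, base in enumerate(motif):
                seq[pos + j] = base
        seqs[key] = "".join(seq)
        r_value = float(rng.normal(1.54, 0.4))
        has_pk = bool(rng.random() < 0.6)
        ires_rows.append({"circ_key": key, "r_value": r_value, "has_pseudoknot": has_pk})
        truth_rows.append(
            {"circ_key": key, "planted_orf": plant_orf, "planted_kozak": plant_kozak}
        )
    return seqs, pd.DataFrame(ires_rows), pd.DataFrame(truth_rows)
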