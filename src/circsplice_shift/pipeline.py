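"""End-to-end orchestration: simulate or load inputs, run every stage, emit a report.

The pipeline chains the stages in analysis order — read/merge the
two-condition junction tables, fit or override the significance intervals
and assign the six groups, score flanking-intron reverse-complement
homology, run the interaction-distance battery, characterize circular ORFs
— and collects study-level counts and test statistics into a single
:class:`SummaryReport`, serialized as JSON and human-readable text.
Everything is deterministic given the seed in the configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import chromatin_interactions as ci
from . import diffexp, intron_homology, io_formats, orf_features
from .synthetic_data import HOUSEKEEPING_GENES, SimConfig, generate_circ_sequences
from .synthetic_data import generate_circ_tables, generate_interactions
from .synthetic_data import generate_intron_pairs, generate_mrna_table

__all__ = ["PipelineConfig", "SummaryReport", "run_pipeline", "spliceosome_overlap"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Inputs, thresholds and overrides for one pipeline run.

    Exactly one of ``sim`` (simulate mode) or the explicit input paths
    (``control_path``/``treated_path`` at minimum) must be set.
    """

    out_dir: str | Path = "pipeline_out"
    sim: SimConfig | None = None
    control_path: str | Path | None = None
    treated_path: str | Path | None = None
    control_dialect: str = "circexplorer2"  # or "ciri"
    treated_dialect: str = "circexplorer2"
    mrna_path: str | Path | None = None
    intron_pairs_path: str | Path | None = None
    interactions_path: str | Path | None = None
    genes_path: str | Path | None = None
    sequences_path: str | Path | None = None
    ires_path: str | Path | None = None
    circ_ci_override: diffexp.ExpressionCI | None = None
    mrna_ci_override: diffexp.ExpressionCI | None = None
    scheme: intron_homology.ScoringScheme = field(
        default_factory=intron_homology.ScoringScheme
    )
    method_filter: str = "Hi-C"
    homology_evalue: float = intron_homology.EVALUE_CUTOFF
    peptide_evalue: float = orf_features.PEPTIDE_EVALUE_NEAR_PERFECT
    ires_r_cutoff: float = orf_features.IRES_R_CUTOFF
    min_aa: int = 20

    def __post_init__(self) -> None:
        for name in ("homology_evalue", "peptide_evalue", "ires_r_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        have_real = self.control_path is not None and self.treated_path is not None
        if self.sim is not None and have_real:
            raise ValueError("choose either simulate mode or real input paths, not both")
        if self.sim is None and not have_real:
            raise ValueError("need a SimConfig or control/treated input paths")


@dataclass
class SummaryReport:
    """Study-level counts and statistics mirroring the analysis readout."""

    n_control: int = 0
    n_treated: int = 0
    n_merged: int = 0
    n_significant: int = 0
    n_up: int = 0
    n_down: int = 0
    group_sizes: dict = field(default_factory=dict)
    direction_bias: dict = field(default_factory=dict)
    exon_anova_p: float | None = None
    exon_kw_p: float | None = None
    homology_significant: int = 0
    homology_total: int = 0
    bitscore_anova_p: float | None = None
    bitscore_kw_p: float | None = None
    n_with_orf: int = 0
    n_sequences: int = 0
    ires_pass: int = 0
    kozak_hits: int = 0
    battery: dict = field(default_factory=dict)

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, pd.DataFrame):
                return o.to_dict()
            raise TypeError(f"not JSON serializable: {type(o)}")

        return json.dumps(dataclasses.asdict(self), indent=2, default=default)

    def _pct(self, count: int, total: int) -> str:
        if total == 0:
            return "n/a"
        # report percentages to 1 dp, round-half-even
        return f"{round(100.0 * count / total, 1)}%"

    def to_text(self) -> str:
        lines = [
            "circsplice-shift summary",
            "========================",
            f"junction calls: control {self.n_control}, treated {self.n_treated}, "
            f"merged {self.n_merged}",
            f"significant circRNAs: {self.n_significant} "
            f"({self._pct(self.n_significant, self.n_merged)} of merged)",
            f"  up {self.n_up} ({self._pct(self.n_up, self.n_significant)}), "
            f"down {self.n_down} ({self._pct(self.n_down, self.n_significant)})",
            f"group sizes: {self.group_sizes}",
        ]
        for name, d in self.direction_bias.items():
            lines.append(
                f"direction bias [{name}]: n={d['n']} of u={d['u']}, p={d['p']:.4f}"
            )
        if self.exon_anova_p is not None:
            lines.append(
                f"exon-count tests: ANOVA p={self.exon_anova_p:.4f}, "
                f"Kruskal-Wallis p={self.exon_kw_p:.5f}"
            )
        lines.append(
            f"flanking-intron homology: {self.homology_significant}/{self.homology_total} "
            f"significant ({self._pct(self.homology_significant, self.homology_total)})"
        )
        if self.bitscore_anova_p is not None:
            lines.append(
                f"bitscore group tests: ANOVA p={self.bitscore_anova_p:.5f}, "
                f"Kruskal-Wallis p={self.bitscore_kw_p:.5f}"
            )
        lines.append(
            f"circular ORFs: {self.n_with_orf}/{self.n_sequences} sequences "
            f"({self._pct(self.n_with_orf, self.n_sequences)}); "
            f"Kozak hits {self.kozak_hits}; IRES pass {self.ires_pass}"
        )
        for side, res in self.battery.items():
            if "comparisons" in res and res["comparisons"]:
                keys = ", ".join(
                    f"{k}: KS p={v['ks_p']:.3g}" for k, v in res["comparisons"].items()
                )
                lines.append(f"distance battery [{side}]: {keys}")
        return "\n".join(lines) + "\n"


def spliceosome_overlap(
    mrna_fc: pd.DataFrame, spliceosome_genes: list[str], mrna_ci: diffexp.ExpressionCI
) -> tuple[list[str], list[str]]:
    """Split spliceosome genes into significantly down- and up-regulated lists.

    ``down`` = genes with fold change strictly below the interval's lower
    bound; ``up`` = strictly above the upper bound (boundary values are
    unchanged, as everywhere else).
    """
    fc = dict(zip(mrna_fc["gene"], mrna_fc["fold_change"]))
    down = [g for g in spliceosome_genes if g in fc and fc[g] < mrna_ci.lower]
    up = [g for g in spliceosome_genes if g in fc and fc[g] > mrna_ci.upper]
    return down, up


def _stage(name: str):
    logger.info("stage: %s", name)
    return time.perf_counter()


def run_pipeline(cfg: PipelineConfig) -> SummaryReport:
    """Execute all stages in order, writing every stage's table under out_dir."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = SummaryReport()
    sim = cfg.sim

    # --- stage: read/merge -------------------------------------------------
    t0 = _stage("read/merge")
    if sim is not None:
        control, treated, circ_truth = generate_circ_tables(sim)
        io_formats.write_circexplorer2(control, out_dir / "control.circexplorer2.tsv", "control")
        io_formats.write_circexplorer2(treated, out_dir / "treated.circexplorer2.tsv", "treated")
        circ_truth.to_csv(out_dir / "circ_truth.tsv", sep="\t", index=False)
    else:
        readers = {"circexplorer2": io_formats.read_circexplorer2, "ciri": io_formats.read_ciri}
        control = readers[cfg.control_dialect](cfg.control_path, "control")
        treated = readers[cfg.treated_dialect](cfg.treated_path, "treated")
    merged = io_formats.merge_conditions(control, treated)
    io_formats.write_merged_table(merged, out_dir / "merged.tsv")
    report.n_control, report.n_treated = len(control), len(treated)
    report.n_merged = len(merged)
    logger.info("merged %d records (%.2fs)", len(merged), time.perf_counter() - t0)

    # --- stage: classify ---------------------------------------------------
    _stage("classify")
    if sim is not None:
        genes = [r.gene_symbol for r in merged] + list(HOUSEKEEPING_GENES)
        mrna = generate_mrna_table(sim, genes)
        mrna.to_csv(out_dir / "mrna_fc.tsv", sep="\t", index=False)
    elif cfg.mrna_path is not None:
        mrna = pd.read_csv(cfg.mrna_path, sep="\t")
    else:
        mrna = pd.DataFrame({"gene": [], "fold_change": []})
    log2_ratios = [
        diffexp.compute_ratio(r.reads_treated, r.reads_control)[1] for r in merged
    ]
    circ_ci = cfg.circ_ci_override or diffexp.fit_ci(log2_ratios)
    hk = mrna[mrna["gene"].isin(HOUSEKEEPING_GENES)] if len(mrna) else mrna
    if cfg.mrna_ci_override is not None:
        mrna_ci = cfg.mrna_ci_override
    elif len(hk) >= 2:
        mrna_ci = diffexp.fit_ci(hk["fold_change"].to_numpy())
    else:
        mrna_ci = diffexp.ExpressionCI(center=1.0, half_width=0.1, source="override")
    fc_map = dict(zip(mrna.get("gene", []), mrna.get("fold_change", [])))
    grouped = diffexp.assign_six_groups(merged, circ_ci, mrna_ci, fc_map)
    grouped.to_csv(out_dir / "grouped.tsv", sep="\t", index=False)
    sig = grouped[grouped["circ_class"] != "not_significant"]
    report.n_significant = len(sig)
    report.n_up = int((sig["circ_class"] == "up").sum())
    report.n_down = int((sig["circ_class"] == "down").sum())
    report.group_sizes = sig.dropna(subset=["group"]).groupby("group").size().to_dict()
    if report.n_significant:
        n_big = max(report.n_up, report.n_down)
        report.direction_bias["circ_up_vs_down"] = {
            "u": report.n_significant,
            "n": n_big,
            "p": diffexp.direction_bias_p((report.n_significant, n_big)),
        }
        up_sig = sig[sig["circ_class"] == "up"]
        n_minc = int((up_sig["mrna_class"] == "increased").sum())
        n_mdec = int((up_sig["mrna_class"] == "decreased").sum())
        if n_minc + n_mdec:
            report.direction_bias["mrna_within_up_circ"] = {
                "u": n_minc + n_mdec,
                "n": max(n_minc, n_mdec),
                "p": diffexp.direction_bias_p((n_minc + n_mdec, max(n_minc, n_mdec))),
            }
    by_group = sig.dropna(subset=["group"])
    if by_group["group"].nunique() >= 2 and len(by_group):
        try:
            report.exon_anova_p, report.exon_kw_p = diffexp.compare_exon_counts(by_group)
        except ValueError:
            logger.warning("exon-count tests skipped: degenerate groups")

    # --- stage: homology ---------------------------------------------------
    _stage("homology")
    if sim is not None:
        pairs, intron_truth = generate_intron_pairs(sim)
        intron_truth.to_csv(out_dir / "intron_truth.tsv", sep="\t", index=False)
        homology = intron_homology.score_all(pairs, cfg.scheme)
    elif cfg.intron_pairs_path is not None:
        pairs = _read_intron_fasta(cfg.intron_pairs_path)
        homology = intron_homology.score_all(pairs, cfg.scheme)
    else:
        homology = pd.DataFrame()
    if len(homology):
        homology.to_csv(out_dir / "homology.tsv", sep="\t", index=False)
        report.homology_total = len(homology)
        report.homology_significant = int(homology["significant"].sum())

    # --- stage: interactions ----------------------------------------------
    _stage("interactions")
    distances = pd.DataFrame()
    if sim is not None:
        gene_groups = sig.dropna(subset=["group"])[["gene_symbol", "group"]].copy()
        gene_groups = gene_groups.rename(columns={"gene_symbol": "gene"})
        rng = sim.rng(6)
        gene_groups["chrom"] = "chr1"
        gene_groups["start"] = rng.integers(10_000_000, 200_000_000, size=len(gene_groups))
        interactions = generate_interactions(sim, gene_groups)
        interactions.to_csv(out_dir / "interactions.4dgenome.tsv", sep="\t", index=False)
        distances = _distances_from_table(interactions, gene_groups, cfg.method_filter)
    elif cfg.interactions_path is not None and cfg.genes_path is not None:
        rows = io_formats.read_4dgenome(cfg.interactions_path)
        interactions = pd.DataFrame([dataclasses.asdict(r) for r in rows])
        interactions = interactions.rename(
            columns={
                "chrom_a": "InteractorAChr", "start_a": "InteractorAStart",
                "end_a": "InteractorAEnd", "chrom_b": "InteractorBChr",
                "start_b": "InteractorBStart", "end_b": "InteractorBEnd",
                "gene_a": "Agene", "gene_b": "Bgene", "method": "Detection_Method",
            }
        )
        gene_groups = pd.read_csv(cfg.genes_path, sep="\t")
        distances = _distances_from_table(interactions, gene_groups, cfg.method_filter)
    if len(distances):
        distances.to_csv(out_dir / "signed_distances.tsv", sep="\t", index=False)
        battery = ci.run_battery(distances)
        report.battery = _battery_digest(battery)
        _write_kde(battery, out_dir)

    # --- stage: orfs -------------------------------------------------------
    _stage("orfs")
    if sim is not None:
        seqs, ires, orf_truth = generate_circ_sequences(sim)
        orf_truth.to_csv(out_dir / "orf_truth.tsv", sep="\t", index=False)
        ires.to_csv(out_dir / "ires.tsv", sep="\t", index=False)
    elif cfg.sequences_path is not None:
        seqs = _read_fasta(cfg.sequences_path)
        ires = (
            pd.read_csv(cfg.ires_path, sep="\t")
            if cfg.ires_path is not None
            else pd.DataFrame()
        )
    else:
        seqs, ires = {}, pd.DataFrame()
    if seqs:
        orf_rows, kozak_total, n_with = [], 0, 0
        for key, seq in seqs.items():
            orfs = orf_features.find_circular_orfs(seq, cfg.min_aa)
            if orfs:
                n_with += 1
            hits = orf_features.kozak_scan(seq)
            kozak_total += len(hits)
            for o in orfs:
                orf_rows.append(
                    {
                        "circ_key": key, "start": o.start, "length_nt": o.length_nt,
                        "peptide": o.peptide, "crosses_junction": o.crosses_junction,
                        "rolling_circle": o.rolling_circle, "kozak_hits": len(hits),
                    }
                )
        pd.DataFrame(orf_rows).to_csv(out_dir / "orfs.tsv", sep="\t", index=False)
        report.n_sequences = len(seqs)
        report.n_with_orf = n_with
        report.kozak_hits = kozak_total
        if len(ires):
            records = [
                orf_features.IresRecord(r.circ_key, r.r_value, bool(r.has_pseudoknot))
                for r in ires.itertuples(index=False)
            ]
            report.ires_pass = len(
                orf_features.filter_ires(records, cfg.ires_r_cutoff)
            )

    # --- stage: report -----------------------------------------------------
    _stage("report")
    (out_dir / "report.json").write_text(report.to_json())
    (out_dir / "report.txt").write_text(report.to_text())
    return report


def _distances_from_table(
    interactions: pd.DataFrame, gene_groups: pd.DataFrame, method_filter: str
) -> pd.DataFrame:
    """Signed distances for anchor genes, Hi-C-filtered, trans pairs excluded."""
    info = {
        r.gene: (r.chrom, int(r.start), r.group)
        for r in gene_groups.itertuples(index=False)
    }
    rows = []
    keep = interactions[
        interactions["Detection_Method"].str.lower() == method_filter.lower()
    ]
    for rec in keep.itertuples(index=False):
        for anchor_gene, partner_chrom, partner_start in (
            (rec.Agene, rec.InteractorBChr, rec.InteractorBStart),
            (rec.Bgene, rec.InteractorAChr, rec.InteractorAStart),
        ):
            if anchor_gene not in info:
                continue
            chrom, start, group = info[anchor_gene]
            sd = ci.signed_distance(
                start, int(partner_start), chrom == partner_chrom,
                anchor_gene=anchor_gene, group=group,
            )
            if sd is not None and sd.distance != 0:
                rows.append(
                    {"anchor_gene": sd.anchor_gene, "group": sd.group,
                     "distance": sd.distance, "side": sd.side}
                )
    return pd.DataFrame(rows)


def _battery_digest(battery: dict) -> dict:
    digest = {}
    for side, res in battery.items():
        digest[side] = {
            "n": res.get("n", 0),
            "transform": res.get("transform"),
            "comparisons": res.get("comparisons", {}),
        }
        if "dscf" in res:
            digest[side]["dscf_min_p"] = float(res["dscf"].values.min())
    return digest


def _write_kde(battery: dict, out_dir: Path) -> None:
    rows = []
    for side, res in battery.items():
        for group, (grid, dens) in res.get("kde", {}).items():
            for g, d in zip(grid, dens):
                rows.append({"side": side, "group": group, "x": g, "density": d})
    if rows:
        pd.DataFrame(rows).to_csv(out_dir / "kde_curves.tsv", sep="\t", index=False)


def _read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def _read_intron_fasta(path: str | Path) -> dict[str, tuple[str | None, str | None]]:
    """FASTA with mate naming <key>/5 and <key>/3 -> {key: (intron5, intron3)}."""
    seqs = _read_fasta(path)
    pairs: dict[str, list[str | None]] = {}
    for name, seq in seqs.items():
        key, _, mate = name.rpartition("/")
        if mate not in ("5", "3") or not key:
            raise ValueError(f"intron FASTA record {name!r} lacks the /5 or /3 suffix")
        slot = pairs.setdefault(key, [None, None])
        slot[0 if mate == "5" else 1] = seq
    return {k: (v[0], v[1]) for k, v in pairs.items()}
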