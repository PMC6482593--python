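"""Significance filtering and six-group classification of circRNA/mRNA changes.

Expression change of a back-splice junction is the read-number ratio
treated/control; its base-2 logarithm is compared to a 95% interval
``mean ± 2·SD`` fitted to all merged junctions.  mRNA fold changes are
compared, unlogged, to an interval fitted to ten housekeeping genes.
Junctions significant on the circRNA axis are split into six groups by the
direction of the circRNA change crossed with increased / unchanged /
decreased mRNA expression.  Direction imbalance (e.g. 51 of 77 junctions up)
is scored with an exact binomial tail probability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CircRecord

__all__ = [
    "ExpressionCI",
    "GroupAssignment",
    "DirectionBiasInput",
    "SIX_GROUPS",
    "compute_ratio",
    "fit_ci",
    "classify_circ",
    "classify_mrna",
    "assign_six_groups",
    "direction_bias_p",
    "compare_exon_counts",
]

#: The six classes, circRNA direction crossed with mRNA class.
SIX_GROUPS = (
    "up_up", "down_up", "up_unchanged", "down_unchanged", "up_down", "down_down",
)


@dataclass(frozen=True)
class ExpressionCI:
    """An interval ``center ± half_width`` used for significance calls.

    ``half_width`` is 2× the sample SD when fitted; ``source`` records
    whether the interval was fitted from data or supplied as an override
    (e.g. a previously published interval).
    """

    center: float
    half_width: float
    source: str = "fitted"

    def __post_init__(self) -> None:
        if self.half_width < 0:
            raise ValueError("half_width must be >= 0")

    @property
    def lower(self) -> float:
        return self.center - self.half_width

    @property
    def upper(self) -> float:
        return self.center + self.half_width


@dataclass(frozen=True)
class GroupAssignment:
    circ_class: str  # up | down | not_significant
    mrna_class: str  # increased | unchanged | decreased | unknown
    group: str | None  # one of SIX_GROUPS, or None


@dataclass(frozen=True)
class DirectionBiasInput:
    """u = total genes considered, n = count in the larger direction."""

    u: int
    n: int

    def __post_init__(self) -> None:
        if self.u < 1:
            raise ValueError("u must be >= 1")
        if not 0 <= self.n <= self.u:
            raise ValueError(f"n must satisfy 0 <= n <= u, got n={self.n}, u={self.u}")


def compute_ratio(reads_treated: int, reads_control: int) -> tuple[float, float]:
    """Read-number ratio treated/control and its base-2 logarithm.

    Merged records have >= 1 read in each condition, so zero counts are a
    contract violation rather than something to pseudocount away.
    """
    if reads_treated < 1 or reads_control < 1:
        raise ValueError(
            "merged records cannot have zero reads "
            f"(got treated={reads_treated}, control={reads_control})"
        )
    ratio = reads_treated / reads_control
    return ratio, math.log2(ratio)


def fit_ci(values: Sequence[float]) -> ExpressionCI:
    """Fit ``mean ± 2·SD`` (sample SD, n−1 denominator) to a value vector."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 values to fit a confidence interval")
    return ExpressionCI(
        center=float(arr.mean()), half_width=float(2.0 * arr.std(ddof=1))
    )


def classify_circ(log2_ratio: float, ci: ExpressionCI) -> str:
    """up / down / not_significant against a closed interval (bounds inside)."""
    if log2_ratio > ci.upper:
        return "up"
    if log2_ratio < ci.lower:
        return "down"
    return "not_significant"


def classify_mrna(fc: float | None, ci: ExpressionCI) -> str:
    """increased / unchanged / decreased / unknown for an unlogged fold change."""
    if fc is None or (isinstance(fc, float) and math.isnan(fc)):
        return "unknown"
    if fc <= 0:
        raise ValueError(f"fold change must be positive, got {fc}")
    if fc > ci.upper:
        return "increased"
    if fc < ci.lower:
        return "decreased"
    return "unchanged"


_MRNA_SUFFIX = {"increased": "up", "unchanged": "unchanged", "decreased": "down"}


def assign_group(circ_class: str, mrna_class: str) -> GroupAssignment:
    group = None
    if circ_class != "not_significant" and mrna_class != "unknown":
        group = f"{circ_class}_{_MRNA_SUFFIX[mrna_class]}"
    return GroupAssignment(circ_class=circ_class, mrna_class=mrna_class, group=group)


def assign_six_groups(
    records: Sequence[CircRecord],
    circ_ci: ExpressionCI,
    mrna_ci: ExpressionCI,
    mrna_fc: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Classify every merged record on both axes and assign six-group labels.

    ``mrna_fc`` maps gene symbols to fold changes; genes absent from the map
    get mrna_class "unknown" and no group.  Returns one row per record with
    circ_key, gene, ratio, log2_ratio, fc, circ_class, mrna_class, group.
    """
    mrna_fc = mrna_fc or {}
    rows = []
    for rec in records:
        ratio, log2_ratio = compute_ratio(rec.reads_treated, rec.reads_control)
        circ_class = classify_circ(log2_ratio, circ_ci)
        fc = mrna_fc.get(rec.gene_symbol)
        mrna_class = classify_mrna(fc, mrna_ci)
        ga = assign_group(circ_class, mrna_class)
        rows.append(
            {
                "circ_key": rec.circ_key,
                "gene_symbol": rec.gene_symbol,
                "exon_count": rec.exon_count,
                "reads_control": rec.reads_control,
                "reads_treated": rec.reads_treated,
                "ratio": ratio,
                "log2_ratio": log2_ratio,
                "mrna_fc": fc if fc is not None else float("nan"),
                "circ_class": circ_class,
                "mrna_class": mrna_class,
                "group": ga.group,
            }
        )
    return pd.DataFrame(rows)


def direction_bias_p(inp: DirectionBiasInput | tuple[int, int]) -> float:
    """Exact upper-tail sign-test probability  Σ_{i=n..u} C(u,i) / 2^u.

    Computed with exact integer arithmetic and converted to float at the end,
    so u in the hundreds is handled without rounding error.
    """
    if isinstance(inp, tuple):
        inp = DirectionBiasInput(*inp)
    total = sum(math.comb(inp.u, i) for i in range(inp.n, inp.u + 1))
    return float(Fraction(total, 2**inp.u))


def compare_exon_counts(
    grouped: pd.DataFrame,
    value_col: str = "exon_count",
    group_col: str = "group",
) -> tuple[float, float]:
    """One-way ANOVA and tie-corrected Kruskal–Wallis p over exon counts by group."""
    groups = [
        sub[value_col].to_numpy(dtype=float)
        for _, sub in grouped.dropna(subset=[group_col]).groupby(group_col)
    ]
    groups = [g for g in groups if len(g) > 0]
    if len(groups) < 2:
        raise ValueError("need at least 2 non-empty groups")
    flat = np.concatenate(groups)
    if np.all(flat == flat[0]):
        raise ValueError("all observations equal across groups: F undefined")
    anova_p = float(stats.f_oneway(*groups).pvalue)
    kw_p = float(stats.kruskal(*groups).pvalue)
    return anova_p, kw_p
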