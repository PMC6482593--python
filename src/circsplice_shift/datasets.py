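"""Packaged reference tables for the 77 LPC-responsive circRNAs in HAECs.

Four small TSVs ship with the package: the six-group classification of the
77 significantly changed circRNAs with read counts, ratios, mRNA fold
changes and exon counts; the ten housekeeping fold changes calibrating the
"unchanged" mRNA interval; the flanking-intron alignment bit scores of the
53 circRNAs with significant reverse-complement homology; and the 17
spliceosome-component fold changes falling outside the housekeeping
interval.  These tables are the desk-scale inputs for reproducing the
study-level summary statistics.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .diffexp import SIX_GROUPS, ExpressionCI

__all__ = [
    "load_circ_six_groups",
    "load_housekeeping_fc",
    "load_intron_bitscores",
    "load_spliceosome_fc",
    "zero_filled_bitscores",
    "CIRC_LOG2_CI",
    "MRNA_FC_CI",
]

#: Published override intervals for the two significance filters
#: (log2 read-ratio interval fitted on 1,093 merged circRNAs; housekeeping
#: fold-change interval), used when the full merged table is unavailable.
CIRC_LOG2_CI = ExpressionCI(center=-0.3815, half_width=2.3395, source="override")
MRNA_FC_CI = ExpressionCI(center=1.01, half_width=0.1, source="override")


def _read(name: str) -> pd.DataFrame:
    with resources.files("circsplice_shift.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_circ_six_groups() -> pd.DataFrame:
    """The 77 significantly changed circRNAs with their six-group labels."""
    df = _read("circ_six_groups.tsv")
    assert set(df["group"]).issubset(SIX_GROUPS)
    return df


def load_housekeeping_fc() -> pd.DataFrame:
    """Fold changes of the ten housekeeping genes."""
    return _read("housekeeping_fc.tsv")


def load_intron_bitscores() -> pd.DataFrame:
    """Flanking-intron alignment results for the 53 circRNAs with significant homology."""
    return _read("flanking_intron_bitscores.tsv")


def load_spliceosome_fc() -> pd.DataFrame:
    """Spliceosome-component fold changes outside the housekeeping interval."""
    return _read("spliceosome_fc.tsv")


def zero_filled_bitscores() -> dict[str, list[float]]:
    """Bit scores by six-group label, zero-filled to all 77 circRNAs.

    circRNAs without significant flanking-intron reverse complementarity
    carry bit score 0, keeping the 77-row design matrix complete for the
    group tests.
    """
    groups = load_circ_six_groups()
    scores = load_intron_bitscores()
    out: dict[str, list[float]] = {g: [] for g in SIX_GROUPS}
    scored = dict(zip(scores["gene"], scores["bitscore"]))
    for rec in groups.itertuples(index=False):
        out[rec.group].append(float(scored.get(rec.gene, 0.0)))
    return out
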