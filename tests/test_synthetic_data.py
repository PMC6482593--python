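"""Determinism, truth bookkeeping and statistical structure of the generators."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from circsplice_shift import io_formats as io
from circsplice_shift.diffexp import classify_mrna, compute_ratio, fit_ci
from circsplice_shift.synthetic_data import (
    HOUSEKEEPING_GENES,
    SimConfig,
    generate_circ_sequences,
    generate_circ_tables,
    generate_interactions,
    generate_intron_pairs,
    generate_mrna_table,
)


class TestSimConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            SimConfig(frac_up=1.5)
        with pytest.raises(ValueError):
            SimConfig(nb_dispersion=0)
        with pytest.raises(ValueError):
            SimConfig(rc_len=3000, intron_len=2000)


class TestCircTables:
    def test_seed_determinism_byte_identical(self, small_sim, tmp_path):
        for name in ("a", "b"):
            control, treated, truth = generate_circ_tables(small_sim)
            io.write_circexplorer2(control, tmp_path / f"{name}_c.tsv", "control")
            io.write_circexplorer2(treated, tmp_path / f"{name}_t.tsv", "treated")
            truth.to_csv(tmp_path / f"{name}_truth.tsv", sep="\t", index=False)
        for suffix in ("c.tsv", "t.tsv", "truth.tsv"):
            assert (tmp_path / f"a_{suffix}").read_bytes() == (
                tmp_path / f"b_{suffix}"
            ).read_bytes()

    def test_merge_bookkeeping(self, small_sim):
        control, treated, truth = generate_circ_tables(small_sim)
        assert len(control) == small_sim.n_shared + small_sim.n_condition_specific
        assert len(treated) == small_sim.n_shared + small_sim.n_condition_specific
        merged = io.merge_conditions(control, treated)
        assert len(merged) == small_sim.n_shared
        shared_keys = set(truth.loc[truth["shared"], "circ_key"])
        assert {r.circ_key for r in merged} == shared_keys

    def test_no_planted_effects_when_fractions_zero(self, small_sim):
        from dataclasses import replace

        cfg = replace(small_sim, frac_up=0.0, frac_down=0.0)
        _, _, truth = generate_circ_tables(cfg)
        assert set(truth.loc[truth["shared"], "planted_class"]) == {"null"}

    def test_planted_up_separates_from_null(self):
        """Monte-Carlo: planted-up circRNAs mostly exceed the null 97.5th
        percentile of log2 ratios (aggregated over ten seeds)."""
        exceed = []
        for seed in range(1, 11):
            cfg = SimConfig(seed=seed, n_shared=1000, frac_up=0.05, effect_log2=3.0)
            control, treated, truth = generate_circ_tables(cfg)
            merged = io.merge_conditions(control, treated)
            tm = dict(zip(truth["circ_key"], truth["planted_class"]))
            lr = {
                r.circ_key: compute_ratio(r.reads_treated, r.reads_control)[1]
                for r in merged
            }
            null = [v for k, v in lr.items() if tm[k] == "null"]
            threshold = np.percentile(null, 97.5)
            exceed.extend(v > threshold for k, v in lr.items() if tm[k] == "up")
        assert np.mean(exceed) >= 0.8


class TestMrnaTable:
    def test_housekeeping_pinned_at_one_when_sd_zero(self, small_sim):
        from dataclasses import replace

        cfg = replace(small_sim, hk_sd=0.0)
        table = generate_mrna_table(cfg, list(HOUSEKEEPING_GENES) + ["X", "Y"])
        hk = table[table["gene"].isin(HOUSEKEEPING_GENES)]
        assert (hk["fold_change"] == 1.0).all()

    def test_missing_housekeeping_rejected(self, small_sim):
        with pytest.raises(ValueError, match="housekeeping"):
            generate_mrna_table(small_sim, ["A", "B"])

    def test_determinism(self, small_sim):
        genes = list(HOUSEKEEPING_GENES) + [f"G{i}" for i in range(30)]
        a = generate_mrna_table(small_sim, genes)
        b = generate_mrna_table(small_sim, genes)
        pd.testing.assert_frame_equal(a, b)

    def test_planted_class_recovery_with_generator_interval(self):
        """classify_mrna with the generator's nominal interval (1 ± 2·hk_sd)
        recovers ≥95% of planted classes at hk_sd=0.02, effect ±0.3."""
        from circsplice_shift.diffexp import ExpressionCI

        hits, total = 0, 0
        for seed in (1, 2, 3):
            cfg = SimConfig(seed=seed, hk_sd=0.02)
            genes = list(HOUSEKEEPING_GENES) + [f"G{i}" for i in range(200)]
            table = generate_mrna_table(cfg, genes, effect=0.3)
            ci = ExpressionCI(1.0, 2 * cfg.hk_sd)
            others = table[table["planted_class"] != "housekeeping"]
            for row in others.itertuples(index=False):
                total += 1
                hits += classify_mrna(row.fold_change, ci) == row.planted_class
        assert hits / total >= 0.95


class TestIntronPairs:
    def test_determinism(self, small_sim):
        a, ta = generate_intron_pairs(small_sim)
        b, tb = generate_intron_pairs(small_sim)
        assert a == b
        pd.testing.assert_frame_equal(ta, tb)

    def test_planted_count_matches_fraction(self, small_sim):
        pairs, truth = generate_intron_pairs(small_sim)
        expected = round(small_sim.frac_rc_introns * small_sim.n_intron_pairs)
        assert truth["planted_rc"].sum() == expected
        assert len(pairs) == small_sim.n_intron_pairs
        assert all(len(p[0]) == small_sim.intron_len for p in pairs.values())

    def test_no_planting_no_significance(self):
        """Background uniform pairs essentially never reach E < 1e-20."""
        from circsplice_shift.intron_homology import score_all

        for seed in (1, 2):
            cfg = SimConfig(seed=seed, n_intron_pairs=50, frac_rc_introns=0.0,
                            intron_len=500)
            pairs, _ = generate_intron_pairs(cfg)
            table = score_all(pairs)
            assert int(table["significant"].sum()) == 0


class TestInteractions:
    def _genes(self, n=8):
        return pd.DataFrame(
            {
                "gene": [f"G{i}" for i in range(n)],
                "chrom": ["chr1"] * n,
                "start": [50_000_000 + 10_000_000 * i for i in range(n)],
                "group": ["up_up", "down_down"] * (n // 2),
            }
        )

    def test_emits_4dgenome_dialect(self, small_sim):
        table = generate_interactions(small_sim, self._genes())
        assert list(table.columns) == io.FOURDGENOME_COLUMNS
        assert (table["Detection_Method"] == "Hi-C").all()

    def test_full_upstream_bias_gives_all_negative(self, small_sim):
        from dataclasses import replace

        cfg = replace(small_sim, upstream_bias=1.0)
        table = generate_interactions(cfg, self._genes())
        anchors = dict(zip(self._genes()["gene"], self._genes()["start"]))
        signed = table.apply(
            lambda r: anchors[r["Agene"]] - r["InteractorBStart"], axis=1
        )
        assert (signed < 0).all()

    def test_unbiased_generator_passes_binomial_test(self):
        cfg = SimConfig(seed=6, upstream_bias=0.5, n_interactions_per_gene=250)
        table = generate_interactions(cfg, self._genes())
        anchors = dict(zip(self._genes()["gene"], self._genes()["start"]))
        signed = table.apply(
            lambda r: anchors[r["Agene"]] - r["InteractorBStart"], axis=1
        )
        n_up = int((signed < 0).sum())
        p = stats.binomtest(n_up, len(signed), 0.5).pvalue
        assert p > 0.01

    def test_scale_parameter_separates_distributions(self):
        from circsplice_shift import chromatin_interactions as ci
        from dataclasses import replace

        cfg5 = SimConfig(seed=7, dist_scale=1e5, n_interactions_per_gene=125)
        cfg6 = replace(cfg5, dist_scale=1e6)
        genes = self._genes(4)
        mags = []
        for cfg in (cfg5, cfg6):
            t = generate_interactions(cfg, genes)
            anchors = dict(zip(genes["gene"], genes["start"]))
            d = t.apply(lambda r: anchors[r["Agene"]] - r["InteractorBStart"], axis=1)
            mags.append(np.abs(d.to_numpy(dtype=float)))
        _, p = ci.ks_2sample(mags[0], mags[1])
        assert p < 0.001


class TestCircSequences:
    def test_determinism(self, small_sim):
        a, ia, ta = generate_circ_sequences(small_sim)
        b, ib, tb = generate_circ_sequences(small_sim)
        assert a == b
        pd.testing.assert_frame_equal(ia, ib)
        pd.testing.assert_frame_equal(ta, tb)

    def test_truth_marks_planted_orfs(self, small_sim):
        seqs, ires, truth = generate_circ_sequences(small_sim)
        assert len(seqs) == small_sim.n_circ_sequences
        assert set(truth.columns) >= {"circ_key", "planted_orf", "planted_kozak"}
        assert len(ires) == len(seqs)
        assert np.isfinite(ires["r_value"]).all()

    def test_planted_kozak_found_exactly(self):
        from circsplice_shift.orf_features import kozak_scan

        cfg = SimConfig(seed=12, n_circ_sequences=20, kozak_plant_rate=1.0,
                        orf_plant_rate=0.0)
        seqs, _, truth = generate_circ_sequences(cfg)
        for key, seq in seqs.items():
            assert len(kozak_scan(seq)) >= 1
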