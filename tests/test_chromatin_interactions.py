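"""Signed distances, transformations, KDE, and the rank-test battery with oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from circsplice_shift import chromatin_interactions as ci


class TestSignedDistance:
    def test_sign_rule(self):
        d = ci.signed_distance(2_000_000, 1_500_000, True)
        assert d.distance == 500_000 and d.side == "downstream"
        d = ci.signed_distance(1_000_000, 1_800_000, True)
        assert d.distance == -800_000 and d.side == "upstream"

    def test_trans_chromosomal_excluded(self):
        assert ci.signed_distance(100, 200, False) is None

    def test_zero_distance_has_no_side(self):
        assert ci.signed_distance(5, 5, True).side is None


class TestTransforms:
    def test_examples(self):
        assert ci.transform([-8], "signed_cbrt")[0] == pytest.approx(-2.0)
        assert ci.transform([0], "signed_log10")[0] == 0.0
        assert ci.transform([3, -4], "identity").tolist() == [3.0, -4.0]

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            ci.transform([1.0], "sqrt")

    @pytest.mark.parametrize("method", ci.TRANSFORMS)
    def test_monotone_sign_preserving(self, method, rng):
        x = rng.normal(0, 1e6, size=200)
        t = ci.transform(x, method)
        order = np.argsort(x)
        assert (np.diff(t[order]) >= 0).all()  # same sort order
        assert (np.sign(t) == np.sign(x)).all()

    def test_select_transform_normal_data(self, rng):
        x = rng.normal(0, 1, size=5000)
        assert ci.select_transform(x) == "identity"

    def test_select_transform_cubed_normal(self, rng):
        x = rng.normal(0, 1, size=5000) ** 3
        assert ci.select_transform(x) == "signed_cbrt"

    def test_select_transform_constant_vector(self):
        assert ci.select_transform([1.0] * 25) == "identity"


class TestKDE:
    def test_integrates_to_one(self, rng):
        grid, dens = ci.kde(rng.normal(0, 1, size=500))
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-3)

    def test_standard_normal_peak_height(self, rng):
        grid, dens = ci.kde(rng.normal(0, 1, size=10_000))
        at_zero = dens[np.argmin(np.abs(grid))]
        assert 0.35 <= at_zero <= 0.45  # true density 1/sqrt(2π) ≈ 0.399

    def test_bimodal_mixture_has_two_modes(self, rng):
        x = np.concatenate([rng.normal(-5, 0.5, 400), rng.normal(5, 0.5, 400)])
        grid, dens = ci.kde(x)
        interior = (dens[1:-1] > dens[:-2]) & (dens[1:-1] > dens[2:])
        peaks = grid[1:-1][interior & (dens[1:-1] > dens.max() / 4)]
        assert (peaks < 0).any() and (peaks > 0).any()

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            ci.kde([3.0, 3.0, 3.0])


class TestKS:
    def test_identical_samples(self):
        x = [1.0, 2.0, 3.0, 4.0]
        d, p = ci.ks_2sample(x, x)
        assert d == 0.0 and p == pytest.approx(1.0)

    def test_small_sample_d_matches_ecdf_oracle(self, rng):
        """Brute-force D = max ECDF gap over the pooled support, n ≤ 8."""
        for _ in range(25):
            x = rng.integers(0, 6, size=int(rng.integers(2, 9))).astype(float)
            y = rng.integers(0, 6, size=int(rng.integers(2, 9))).astype(float)
            support = np.concatenate([x, y])
            oracle = max(
                abs((x <= t).mean() - (y <= t).mean()) for t in support
            )
            d, _ = ci.ks_2sample(x, y)
            assert d == pytest.approx(oracle)

    def test_scale_separation_detected(self):
        from circsplice_shift.synthetic_data import SimConfig

        rejections = 0
        for seed in range(1, 11):
            rng = np.random.default_rng(seed)
            x = rng.lognormal(math.log(1e5), 1.0, size=500)
            y = rng.lognormal(math.log(1e6), 1.0, size=500)
            _, p = ci.ks_2sample(x, y)
            rejections += p < 0.001
        assert rejections == 10


class TestHodgesLehmann:
    def test_pure_shift(self):
        y = np.array([1.0, 4.0, 9.0, 16.0])
        assert ci.hodges_lehmann(y + 7, y) == pytest.approx(7.0)

    def test_identical_pairs(self):
        assert ci.hodges_lehmann([1, 2], [1, 2]) == 0.0

    def test_matches_all_pairs_oracle(self, rng):
        for _ in range(20):
            x = rng.normal(0, 1, size=int(rng.integers(1, 12)))
            y = rng.normal(1, 2, size=int(rng.integers(1, 12)))
            oracle = float(np.median([a - b for a in x for b in y]))
            assert ci.hodges_lehmann(x, y) == pytest.approx(oracle)


class TestFlignerPolicello:
    def test_identical_multisets(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        z, p = ci.fligner_policello(x, x)
        assert z == 0.0 and p == pytest.approx(1.0)

    def test_sign_antisymmetry(self, rng):
        x = rng.normal(0, 1, 20)
        y = rng.normal(0.5, 2, 15)
        z_xy, p_xy = ci.fligner_policello(x, y)
        z_yx, p_yx = ci.fligner_policello(y, x)
        assert z_xy == pytest.approx(-z_yx)
        assert p_xy == pytest.approx(p_yx)

    def test_against_permutation_oracle(self):
        """Asymptotic p within ±0.02 of a 5,000-permutation reference on
        n = 15 vs 15 shifted normal samples."""
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 15)
        y = rng.normal(1.0, 1, 15)
        z_obs, p_asy = ci.fligner_policello(x, y)
        pool = np.concatenate([x, y])
        perm_rng = np.random.default_rng(11)
        count = 0
        for _ in range(5000):
            perm = perm_rng.permutation(pool)
            z, _ = ci.fligner_policello(perm[:15], perm[15:])
            count += abs(z) >= abs(z_obs) - 1e-12
        assert p_asy == pytest.approx(count / 5000, abs=0.02)

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            ci.fligner_policello([1.0, 2.0], [1.0, 2.0, 3.0])


class TestAnsariBradley:
    def test_statistic_matches_exhaustive_definition(self, rng):
        """AB statistic equals the sum over x of the mid-ranked
        min(rank, N+1−rank) scores, checked directly for n ≤ 6."""
        for _ in range(20):
            x = rng.normal(0, 1, size=int(rng.integers(2, 7)))
            y = rng.normal(0, 3, size=int(rng.integers(2, 7)))
            pooled = np.concatenate([x, y])
            n = len(pooled)
            ranks = stats.rankdata(pooled)
            scores_by_rank = np.minimum(ranks, n + 1 - ranks)
            oracle = scores_by_rank[: len(x)].sum()
            stat, _ = ci.ansari_bradley(x, y)
            assert stat == pytest.approx(oracle)

    def test_equal_scale_rarely_rejected(self):
        non_rejections = 0
        for seed in range(1, 11):
            rng = np.random.default_rng(seed)
            x = rng.normal(0, 1, 60)
            y = rng.normal(0, 1, 60)
            _, p = ci.ansari_bradley(x, y)
            non_rejections += p > 0.05
        assert non_rejections >= 9

    def test_five_fold_scale_detected(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 100)
        _, p = ci.ansari_bradley(x, 5 * x)
        assert p < 0.01


class TestDSCF:
    def test_identical_groups_near_one(self):
        g = list(np.linspace(0, 1, 20))
        table = ci.dscf_pairwise({"a": g, "b": g, "c": g})
        off_diag = table.values[~np.eye(3, dtype=bool)]
        assert (off_diag >= 0.9).all()

    def test_shifted_group_flagged(self):
        rng = np.random.default_rng(8)
        groups = {
            "a": rng.normal(0, 1, 30),
            "b": rng.normal(0, 1, 30),
            "c": rng.normal(3, 1, 30),
        }
        table = ci.dscf_pairwise(groups)
        assert table.loc["a", "c"] < 0.01 and table.loc["b", "c"] < 0.01
        assert table.loc["a", "b"] > 0.05

    def test_adjusted_p_dominates_unadjusted_wilcoxon(self, rng):
        groups = {f"g{i}": rng.normal(i * 0.3, 1, 25) for i in range(4)}
        table = ci.dscf_pairwise(groups)
        for a, b in itertools.combinations(groups, 2):
            _, p_raw = stats.ranksums(groups[a], groups[b])
            assert table.loc[a, b] >= p_raw - 1e-12

    def test_symmetry_and_group_minimum(self, rng):
        groups = {f"g{i}": rng.normal(0, 1, 10) for i in range(3)}
        table = ci.dscf_pairwise(groups)
        assert np.allclose(table.values, table.values.T)
        with pytest.raises(ValueError):
            ci.dscf_pairwise({"a": [1, 2], "b": [3, 4]})


def _distance_frame(rng, bias_by_group, n_per_group=400, scale=1e6):
    rows = []
    for group, bias in bias_by_group.items():
        mags = rng.lognormal(math.log(scale), 1.0, size=n_per_group)
        signs = np.where(rng.random(n_per_group) < bias, -1, 1)
        for d in (signs * mags).astype(int):
            if d != 0:
                rows.append({"anchor_gene": "g", "group": group, "distance": d})
    return pd.DataFrame(rows)


class TestRunBattery:
    def test_upstream_bias_shifts_counts_and_ks(self, rng):
        df = _distance_frame(
            rng,
            {"up_up": 0.7, "up_unchanged": 0.7, "up_down": 0.7,
             "down_up": 0.5, "down_unchanged": 0.5, "down_down": 0.5},
        )
        up = df[df["group"].str.startswith("up_")]
        down = df[df["group"].str.startswith("down_")]
        assert (up["distance"] < 0).mean() > (down["distance"] < 0).mean()
        battery = ci.run_battery(df)
        assert set(battery) == {"downstream", "upstream"}
        for side in battery.values():
            assert "overall_up_vs_down" in side["comparisons"]
            assert 0 <= side["comparisons"]["overall_up_vs_down"]["ks_p"] <= 1

    def test_sign_swap_exchanges_sides(self, rng):
        df = _distance_frame(rng, {"up_up": 0.6, "down_down": 0.4,
                                   "up_down": 0.5}, n_per_group=100)
        battery = ci.run_battery(df)
        flipped = df.copy()
        flipped["distance"] = -flipped["distance"]
        battery_f = ci.run_battery(flipped)
        assert battery["downstream"]["n"] == battery_f["upstream"]["n"]
        assert battery["upstream"]["n"] == battery_f["downstream"]["n"]

    def test_empty_upstream_side_no_crash(self):
        df = pd.DataFrame(
            {"anchor_gene": ["g"] * 10,
             "group": ["up_up"] * 5 + ["down_down"] * 5,
             "distance": list(range(1, 11))}
        )
        battery = ci.run_battery(df)
        assert battery["upstream"]["n"] == 0
        assert battery["downstream"]["n"] == 10

    def test_median_sign_recovers_bias_ordering(self):
        """Groups with upstream bias above/below 1/2 have negative/positive
        median signed distance at n ≥ 500."""
        rng = np.random.default_rng(21)
        df = _distance_frame(rng, {"up_up": 0.8, "down_down": 0.2}, n_per_group=500)
        med = df.groupby("group")["distance"].median()
        assert med["up_up"] < 0 < med["down_down"]
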