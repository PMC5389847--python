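"""Rank-sum tests, trend counting, regression and running averages."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gcorf import (
    AMINO_ACIDS,
    observed_vs_expected_aa,
    property_gc_regression,
    rank_sum,
    running_average,
    species_trend_table,
)
from gcorf.codon_model import expected_aa_vector_fast


def permutation_ranksum_p(a, b) -> float:
    """Independent oracle: exact two-sided Mann-Whitney p by enumerating
    every assignment of the pooled values to the two groups."""
    pooled = list(a) + list(b)
    n_a = len(a)
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:n_a].sum() - n_a * (n_a + 1) / 2
    mid = n_a * (len(pooled) - n_a) / 2
    dev_obs = abs(u_obs - mid)
    count = total = 0
    for idx in combinations(range(len(pooled)), n_a):
        u = ranks[list(idx)].sum() - n_a * (n_a + 1) / 2
        total += 1
        if abs(u - mid) >= dev_obs - 1e-9:
            count += 1
    return count / total


class TestRankSum:
    def test_separated_samples_exact_p(self):
        res = rank_sum([1, 2, 3], [4, 5, 6])
        assert res.p_two_sided == pytest.approx(0.1)
        assert res.direction == "higher_in_B"

    def test_identical_samples(self):
        res = rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.direction == "none"
        assert res.p_two_sided > 0.9

    def test_singletons(self):
        res = rank_sum([1], [2])
        assert res.p_two_sided == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rank_sum([], [1.0])

    @pytest.mark.parametrize("n_a,n_b", [(1, 1), (2, 3), (3, 3), (4, 5), (5, 5)])
    def test_exact_branch_matches_enumeration(self, n_a, n_b, rng):
        """For all small tie-free samples the p-value equals the full
        permutation enumeration."""
        for _ in range(5):
            pooled = rng.permutation(np.arange(1.0, n_a + n_b + 1))
            a, b = pooled[:n_a], pooled[n_a:]
            res = rank_sum(a, b)
            assert res.p_two_sided == pytest.approx(
                permutation_ranksum_p(a, b), abs=1e-12
            )


class TestSpeciesTrendTable:
    @staticmethod
    def _profiles(rng, n_species=12, n=30, shift=0.0):
        rows = []
        for s in range(n_species):
            for grp, delta in (("orphan", shift), ("ancient", 0.0)):
                for v in rng.normal(delta, 1.0, size=n):
                    rows.append(
                        {"species": f"sp{s}", "age_group": grp, "prop": v}
                    )
        return pd.DataFrame(rows)

    def test_planted_shift_counted_on_orphan_side(self, rng):
        profiles = self._profiles(rng, shift=1.0)
        table = species_trend_table(profiles, ["prop"])
        row = table.loc["prop"]
        assert row["n_higher_in_orphans"] > 0
        assert row["n_higher_in_ancients"] == 0
        assert row["n_species_tested"] == 12

    def test_planted_ancient_shift_counted_on_ancient_side(self, rng):
        # qualitative mirror of the length-increases-with-age pattern
        profiles = self._profiles(rng, shift=-1.0)
        table = species_trend_table(profiles, ["prop"])
        assert table.loc["prop", "n_higher_in_ancients"] > 0
        assert table.loc["prop", "n_higher_in_orphans"] == 0

    def test_species_missing_group_skipped(self, rng):
        profiles = self._profiles(rng, n_species=3)
        profiles = profiles[
            ~((profiles.species == "sp0") & (profiles.age_group == "orphan"))
        ]
        table = species_trend_table(profiles, ["prop"])
        assert table.loc["prop", "n_species_tested"] == 2


class TestRegression:
    def test_exact_line(self):
        gc = np.linspace(0.3, 0.6, 10)
        res = property_gc_regression(gc, 2 * gc)
        assert res.slope == pytest.approx(2.0)
        assert res.r == pytest.approx(1.0)

    def test_constant_y(self):
        gc = np.linspace(0.3, 0.6, 10)
        res = property_gc_regression(gc, np.ones(10))
        assert res.slope == pytest.approx(0.0)

    def test_constant_gc_rejected(self):
        with pytest.raises(ValueError):
            property_gc_regression([0.5] * 10, np.arange(10.0))

    def test_null_p_values_uniform(self, rng):
        """Under a true null the regression p-values are Uniform(0,1)."""
        pvals = []
        for _ in range(500):
            x = rng.uniform(0.3, 0.6, size=25)
            y = rng.normal(size=25)
            pvals.append(property_gc_regression(x, y).p_value)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.001


class TestRunningAverage:
    def test_constant_y_flat(self):
        x = np.repeat([0.31, 0.41, 0.51], 30)
        curve = running_average(x, np.full_like(x, 7.0), bin_width=0.1,
                                min_count=10)
        assert np.allclose(curve.bin_means, 7.0)
        assert len(curve.bin_centers) == 3

    def test_identity_limit(self, rng):
        x = rng.uniform(0, 1, size=20_000)
        curve = running_average(x, x, bin_width=0.005, min_count=5)
        assert np.abs(curve.bin_means - curve.bin_centers).max() < 0.005

    def test_sparse_bins_suppressed(self):
        x = np.array([0.305] * 25 + [0.415] * 3)
        curve = running_average(x, x, bin_width=0.01, min_count=20)
        assert len(curve.bin_centers) == 1

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            running_average([0.1, 0.2], [1.0], bin_width=0.01, min_count=1)


class TestObservedVsExpected:
    def test_random_proteins_track_expectation(self, rng):
        """Profiles drawn straight from the codon model coincide with the
        analytic curves within sampling error."""
        rows = []
        for _ in range(3000):
            g = rng.uniform(0.3, 0.6)
            comp = expected_aa_vector_fast(g)
            counts = rng.multinomial(300, comp)
            row = {"cds_gc": g, "age_group": "orphan"}
            row.update(
                {f"freq_{a}": c / 300 for a, c in zip(AMINO_ACIDS, counts)}
            )
            rows.append(row)
        profiles = pd.DataFrame(rows)
        curves = observed_vs_expected_aa(profiles, bin_width=0.05,
                                         min_count=50)
        for ab in ("P", "K"):
            obs = curves[(curves.amino_acid == ab)
                         & (curves.age_group == "orphan")]
            exp = curves[(curves.amino_acid == ab)
                         & (curves.age_group == "expected")]
            merged = obs.merge(exp, on="gc_bin_center",
                               suffixes=("_obs", "_exp"))
            assert len(merged) > 3
            resid = merged["mean_obs"] - merged["mean_exp"]
            se = np.sqrt(
                merged["mean_exp"] * (1 - merged["mean_exp"])
                / (300 * merged["count_obs"])
            )
            assert (np.abs(resid) < 5 * se).all()

    def test_expected_proline_below_5pct_at_40gc(self):
        profiles = pd.DataFrame(
            [{"cds_gc": 0.4, "age_group": "orphan",
              **{f"freq_{a}": 0.05 for a in AMINO_ACIDS}}] * 25
        )
        curves = observed_vs_expected_aa(profiles, bin_width=0.01,
                                         min_count=10)
        exp_p = curves[(curves.amino_acid == "P")
                       & (curves.age_group == "expected")]
        assert (exp_p["mean"] < 0.05).all()
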