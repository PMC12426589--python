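import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bruvkit import indices as idx
from bruvkit.indices import (ProxyResolution, accepted_lengths, biomass,
                             compute_indices, dispersion_index, dunn_test,
                             habitat_summary, resolve_length, richness,
                             shannon, validate_lw_registry)


class TestRichness:
    def test_counts_positive_taxa(self):
        assert richness(pd.Series({"A": 3, "B": 1, "C": 0})) == 2

    def test_all_zero(self):
        assert richness(pd.Series({"A": 0, "B": 0})) == 0

    def test_random_matrix_against_column_oracle(self):
        rng = np.random.default_rng(0)
        m = rng.integers(0, 2, size=(20, 10))
        for row in m:
            assert richness(row) == sum(1 for v in row if v >= 1)


class TestShannon:
    def test_equal_shares(self):
        assert shannon(pd.Series([5, 5, 5, 5])) == pytest.approx(np.log(4))

    def test_single_taxon_zero(self):
        assert shannon(pd.Series([7])) == pytest.approx(0.0)

    def test_hand_computed_value(self):
        # {A:2, B:1, C:1}: -(0.5 ln 0.5 + 2*0.25 ln 0.25) = 1.0397
        assert shannon(pd.Series([2, 1, 1])) == pytest.approx(1.0397, abs=1e-4)

    def test_all_zero_is_missing(self):
        assert np.isnan(shannon(pd.Series([0, 0])))

    def test_scale_invariance_and_max_at_equal_shares(self):
        rng = np.random.default_rng(1)
        v = rng.integers(1, 20, 8).astype(float)
        assert shannon(v) == pytest.approx(shannon(v * 17.0))
        assert shannon(v) <= np.log(len(v)) + 1e-12


class TestDispersionIndex:
    def test_printed_richness_pair(self):
        # mean 5.4, variance 4.9 -> 0.91 at 2 dp
        assert round(4.9 / 5.4, 2) == 0.91

    def test_constant_vector_zero(self):
        assert dispersion_index([3, 3, 3, 3]) == pytest.approx(0.0)

    def test_poisson_near_one(self):
        draws = np.random.default_rng(2).poisson(7, 100_000)
        assert dispersion_index(draws) == pytest.approx(1.0, abs=0.05)

    def test_negative_binomial_overdispersed(self):
        rng = np.random.default_rng(3)
        k, mu = 0.5, 10.0
        draws = rng.negative_binomial(k, k / (k + mu), 50_000)
        assert dispersion_index(draws) > 5.0

    def test_zero_mean_missing(self):
        assert np.isnan(dispersion_index([0, 0, 0]))


@pytest.fixture()
def registry():
    return validate_lw_registry(pd.DataFrame({
        "taxon": ["cod", "wrasse", "gadidae"],
        "a": [1e-5, 2e-5, 1e-5],
        "b": [3.0, 2.9, 3.0],
        "reference_length_mm": [250.0, np.nan, np.nan],
        "family": ["gadidae", "labridae", "gadidae"],
        "is_family_level": [False, False, True],
    }))


@pytest.fixture()
def length_table():
    return pd.DataFrame({
        "deployment_id": ["d1", "d1", "d2", "d3"],
        "taxon": ["wrasse", "wrasse", "wrasse", "wrasse"],
        "subhabitat": ["circalittoral rock"] * 3 + ["subtidal sediments"],
        "length_mm": [300.0, 340.0, 200.0, 150.0],
    })


class TestResolveLength:
    def test_measured_in_sample(self, registry, length_table):
        res = resolve_length("wrasse", "d1", length_table,
                             "circalittoral rock", registry)
        assert res.tier == "measured-in-sample"
        assert res.length_mm == pytest.approx(320.0)

    def test_subhabitat_mean_pooled(self, registry, length_table):
        # unmeasured here, measured elsewhere in same sub-habitat: pooled mean
        res = resolve_length("wrasse", "d9", length_table,
                             "circalittoral rock", registry)
        assert res.tier == "subhabitat-mean"
        assert res.length_mm == pytest.approx((300 + 340 + 200) / 3)

    def test_study_mean(self, registry, length_table):
        res = resolve_length("wrasse", "d9", length_table,
                             "subtidal seagrass", registry)
        assert res.tier == "study-mean"
        assert res.length_mm == pytest.approx((300 + 340 + 200 + 150) / 4)

    def test_reference_fallback(self, registry, length_table):
        res = resolve_length("cod", "d1", length_table,
                             "circalittoral rock", registry)
        assert res.tier == "reference"
        assert res.length_mm == 250.0

    def test_family_level_uses_family_mean(self, registry):
        lengths = pd.DataFrame({
            "deployment_id": ["d1", "d2"], "taxon": ["cod", "cod"],
            "subhabitat": ["subtidal sediments"] * 2,
            "length_mm": [400.0, 500.0]})
        res = resolve_length("gadidae", "d3", lengths, "subtidal sediments",
                             registry)
        assert res.tier == "family-mean"
        assert res.length_mm == pytest.approx(450.0)

    def test_mono_gear_skips_in_sample_tier(self, registry, length_table):
        res = resolve_length("wrasse", "d1", length_table,
                             "circalittoral rock", registry,
                             allow_in_sample=False)
        assert res.tier == "subhabitat-mean"

    def test_no_rule_applies_names_taxon(self, registry):
        empty = pd.DataFrame(columns=["deployment_id", "taxon", "subhabitat",
                                      "length_mm"])
        with pytest.raises(KeyError, match="wrasse"):
            resolve_length("wrasse", "d1", empty, "subtidal seagrass", registry)
        with pytest.raises(KeyError, match="unknown"):
            resolve_length("unknown", "d1", empty, "subtidal seagrass", registry)


class TestBiomass:
    def test_direct_arithmetic(self, registry):
        # L=100 mm, a=1e-5, b=3, MaxN=2 -> 2 * 1e-5 * 1e6 g = 20 g = 0.020 kg
        row = pd.Series({"cod": 2})
        res = {"cod": ProxyResolution("cod", "d1", 100.0, "reference")}
        assert biomass(row, res, registry) == pytest.approx(0.020)

    def test_empty_row_zero(self, registry):
        assert biomass(pd.Series({"cod": 0}), {}, registry) == 0.0

    def test_missing_entry_errors(self, registry):
        with pytest.raises(KeyError, match="eel"):
            biomass(pd.Series({"eel": 1}), {}, registry)

    def test_against_spreadsheet_oracle(self):
        rng = np.random.default_rng(5)
        taxa = [f"t{i}" for i in range(5)]
        reg = validate_lw_registry(pd.DataFrame({
            "taxon": taxa,
            "a": rng.uniform(1e-6, 1e-4, 5),
            "b": rng.uniform(2.5, 3.4, 5)}))
        counts = rng.integers(0, 6, 5)
        lengths = rng.uniform(80, 600, 5)
        res = {t: ProxyResolution(t, "d", L, "reference")
               for t, L in zip(taxa, lengths)}
        got = biomass(pd.Series(counts, index=taxa), res, reg)
        expected = sum(reg.loc[t, "a"] * L ** reg.loc[t, "b"] * c
                       for t, L, c in zip(taxa, lengths, counts)) / 1000.0
        assert got == pytest.approx(expected)

    def test_additive_and_linear_in_maxn(self, registry):
        res = {"cod": ProxyResolution("cod", "d", 200.0, "reference"),
               "wrasse": ProxyResolution("wrasse", "d", 300.0, "reference")}
        b1 = biomass(pd.Series({"cod": 1, "wrasse": 0}), res, registry)
        b2 = biomass(pd.Series({"cod": 0, "wrasse": 2}), res, registry)
        both = biomass(pd.Series({"cod": 1, "wrasse": 2}), res, registry)
        assert both == pytest.approx(b1 + b2)
        assert biomass(pd.Series({"cod": 3}), res, registry) == pytest.approx(3 * b1)


def test_registry_validation_errors():
    with pytest.raises(ValueError, match="positive"):
        validate_lw_registry(pd.DataFrame({"taxon": ["x"], "a": [0.0], "b": [3.0]}))
    with pytest.raises(ValueError, match="exponent"):
        validate_lw_registry(pd.DataFrame({"taxon": ["x"], "a": [1e-5], "b": [5.5]}))
    with pytest.raises(ValueError, match="missing column"):
        validate_lw_registry(pd.DataFrame({"taxon": ["x"], "a": [1e-5]}))


class TestProxyCascadeOnSynthetic:
    def test_full_detectability_means_all_in_sample(self):
        from bruvkit import synthetic
        from bruvkit.pipeline import synthetic_lw_registry
        rng = np.random.default_rng(8)
        n = 60
        dep = pd.DataFrame({
            "deployment_id": [f"d{i}" for i in range(n)],
            "x": rng.uniform(0, 1000, n), "y": rng.uniform(0, 1000, n),
            "depth_m": rng.uniform(5, 30, n),
            "subhabitat": "subtidal sediments", "habitat": "Sediments",
            "gear": "stereo"})
        pool = synthetic.default_species_pool(5, seed=1)
        for sp in pool:
            sp.detectability = 1.0
        ann, _ = synthetic.simulate_annotations(dep, pool, n_frames=10, seed=4)
        from bruvkit.ingest import compute_maxn
        maxn, _ = compute_maxn(ann, dep["deployment_id"])
        registry = validate_lw_registry(synthetic_lw_registry(pool))
        lengths = accepted_lengths(ann, dep)
        tab = compute_indices(maxn, dep, lengths=lengths, registry=registry)
        other_tiers = [c for c in tab.columns if c.startswith("tier_")
                       and c != "tier_measured_in_sample"]
        assert tab[other_tiers].to_numpy().sum() == 0
        assert tab["tier_measured_in_sample"].sum() == (maxn > 0).to_numpy().sum()


class TestHabitatSummary:
    @staticmethod
    def _make(values_a, values_b):
        n = len(values_a) + len(values_b)
        dep = pd.DataFrame({
            "deployment_id": [f"d{i}" for i in range(n)],
            "habitat": ["Reefs"] * len(values_a) + ["Sediments"] * len(values_b),
            "subhabitat": (["circalittoral rock"] * len(values_a)
                           + ["subtidal sediments"] * len(values_b)),
        })
        tab = pd.DataFrame({"deployment_id": dep["deployment_id"],
                            "richness": list(values_a) + list(values_b)})
        return tab, dep

    def test_identical_groups_p_one(self):
        tab, dep = self._make([1, 2, 3, 4], [1, 2, 3, 4])
        out = habitat_summary(tab, dep, index_cols=("richness",))
        assert out["tests"]["richness"]["mann_whitney"]["p"] == pytest.approx(1.0)

    def test_w_statistic_matches_exact_enumeration(self):
        """Oracle: U for {1,2,3} vs {4,5,6} by exhaustive pair counting."""
        a, b = [1, 2, 3], [4, 5, 6]
        u_oracle = sum(1 for x, y in itertools.product(a, b) if x > y) \
            + 0.5 * sum(1 for x, y in itertools.product(a, b) if x == y)
        tab, dep = self._make(a, b)
        out = habitat_summary(tab, dep, index_cols=("richness",))
        assert out["tests"]["richness"]["mann_whitney"]["W"] == pytest.approx(u_oracle)

    def test_group_means(self):
        tab, dep = self._make([2, 4], [6, 8])
        out = habitat_summary(tab, dep, index_cols=("richness",))
        assert out["habitat_means"].loc["Reefs", ("richness", "mean")] == 3.0
        assert out["habitat_means"].loc["Sediments", ("richness", "mean")] == 7.0

    def test_small_group_reported_missing(self):
        tab, dep = self._make([1], [2, 3, 4])
        out = habitat_summary(tab, dep, index_cols=("richness",))
        assert out["tests"]["richness"]["mann_whitney"] is None

    def test_rejection_rates_under_null_and_alternative(self):
        rng = np.random.default_rng(11)
        n_rep, n = 400, 30
        rej_h0 = rej_h1 = 0
        for _ in range(n_rep):
            a = rng.normal(0, 1, n)
            b0 = rng.normal(0, 1, n)
            b1 = rng.normal(1.0, 1, n)
            rej_h0 += stats.mannwhitneyu(a, b0).pvalue < 0.05
            rej_h1 += stats.mannwhitneyu(a, b1).pvalue < 0.05
        assert rej_h0 / n_rep == pytest.approx(0.05, abs=0.035)
        assert rej_h1 / n_rep > 0.5


class TestDunn:
    def test_symmetry_and_bonferroni_cap(self):
        rng = np.random.default_rng(12)
        groups = [rng.normal(i, 1, 25) for i in range(3)]
        out = dunn_test(groups, ["a", "b", "c"])
        assert len(out) == 3
        assert (out["p_adj"] <= 1.0).all()
        # extreme separation -> smallest p for the widest contrast
        assert out.loc[(out.group_a == "a") & (out.group_b == "c"),
                       "p_adj"].iloc[0] <= out["p_adj"].max()


def test_accepted_lengths_uses_maxn_frame(survey):
    lengths = accepted_lengths(survey["annotations"], survey["deployments"])
    assert set(lengths.columns) == {"deployment_id", "taxon", "subhabitat",
                                    "length_mm"}
    assert (lengths["length_mm"] > 0).all()
    # no lengths from mono deployments
    mono = survey["deployments"].loc[survey["deployments"]["gear"] == "mono",
                                     "deployment_id"]
    assert not lengths["deployment_id"].isin(set(mono)).any()
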