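import json

import numpy as np
import pandas as pd
import pytest

from geosurvey.model import (
    FixedTerm,
    MCMCConfig,
    ModelSpec,
    PosteriorSamples,
    SplineTerm,
)
from geosurvey.summarize import (
    CurveSummary,
    EffectSummary,
    SpatialClassification,
    classify_regions,
    curve_summary,
    export_choropleth,
    fixed_effect_por,
    harmonize_waves,
    stepwise_sensitivity,
    total_spatial_effect,
)
from helpers import tiny_dataset

from conftest import make_recovery_truth


def synthetic_samples(fixed=None, fixed_names=None, f_str=None, f_unstr=None,
                      labels=None, alpha=None, spline_meta=None):
    S = 100
    if fixed is None:
        fixed = np.zeros((S, 1))
        fixed_names = ["intercept"]
    return PosteriorSamples(
        fixed=fixed, fixed_names=fixed_names, alpha=alpha or {},
        spline_meta=spline_meta or {}, f_str=f_str, f_unstr=f_unstr,
        region_labels=labels, tau2={}, seed=0, config={}, spec_hash="x")


class TestFixedEffectPor:
    def test_zero_draws_give_unity(self):
        s = synthetic_samples(fixed=np.zeros((50, 2)),
                              fixed_names=["intercept", "urban=0"])
        out = fixed_effect_por(s)
        assert len(out) == 1
        assert out[0].por == pytest.approx(1.0)
        assert out[0].ci_low == pytest.approx(1.0)

    def test_constant_log2_gives_two(self):
        fixed = np.column_stack([np.zeros(50), np.full(50, np.log(2.0))])
        s = synthetic_samples(fixed=fixed, fixed_names=["intercept", "x=1"])
        out = fixed_effect_por(s)
        assert out[0].por == pytest.approx(2.0)

    def test_reference_rows_emitted(self):
        s = synthetic_samples(fixed=np.zeros((50, 2)),
                              fixed_names=["intercept", "x=1"])
        out = fixed_effect_por(s, references={"x": "0"})
        refs = [e for e in out if e.is_reference]
        assert len(refs) == 1 and refs[0].por == 1.0

    def test_bad_level_rejected(self):
        s = synthetic_samples()
        with pytest.raises(ValueError):
            fixed_effect_por(s, level=1.5)

    def test_planted_binary_effect_recovered(self, recovery_fits):
        # urban=0 planted at log 2 -> interval contains 2.0 in most replicates
        truth, fits = recovery_fits
        hits = 0
        for _, s in fits:
            es = [e for e in fixed_effect_por(s) if e.term == "urban=0"][0]
            hits += es.ci_low <= 2.0 <= es.ci_high
        assert hits >= 16


class TestTotalSpatialEffect:
    def test_sum_of_blocks(self):
        labels = ("A", "B")
        f_str = np.ones((50, 2))
        f_unstr = np.full((50, 2), 0.5)
        s = synthetic_samples(f_str=f_str, f_unstr=f_unstr, labels=labels)
        assert np.allclose(total_spatial_effect(s), 1.5)

    def test_unstructured_disabled_equals_structured(self):
        labels = ("A", "B")
        f_str = np.random.default_rng(0).normal(size=(50, 2))
        s = synthetic_samples(f_str=f_str, f_unstr=None, labels=labels)
        assert np.array_equal(total_spatial_effect(s), f_str)

    def test_no_spatial_block_rejected(self):
        s = synthetic_samples()
        with pytest.raises(ValueError, match="spatial"):
            total_spatial_effect(s)


class TestClassifyRegions:
    def test_all_positive_draws_black(self):
        draws = np.abs(np.random.default_rng(1).normal(size=(200, 1))) + 0.1
        out = classify_regions(draws, ["A"], nominal_level=0.9)
        assert out[0].category == "positive"

    def test_symmetric_draws_grey(self):
        rng = np.random.default_rng(2)
        draws = rng.normal(0, 1, size=(500, 1))
        out = classify_regions(draws, ["A"], nominal_level=0.95)
        assert out[0].category == "not_significant"

    def test_negative_draws_white(self):
        draws = -np.abs(np.random.default_rng(3).normal(size=(200, 1))) - 0.1
        out = classify_regions(draws, ["A"])
        assert out[0].category == "negative"

    def test_monotone_in_nominal_level(self):
        rng = np.random.default_rng(4)
        draws = rng.normal(0.3, 1.0, size=(400, 8)) * rng.uniform(0.2, 2, 8)
        c95 = {c.region: c.category for c in classify_regions(draws, list("ABCDEFGH"), 0.95)}
        c90 = {c.region: c.category for c in classify_regions(draws, list("ABCDEFGH"), 0.90)}
        for r in c95:
            if c95[r] != "not_significant":
                assert c90[r] == c95[r]

    def test_interval_contains_point(self):
        rng = np.random.default_rng(5)
        draws = rng.normal(size=(300, 4))
        for c in classify_regions(draws, list("ABCD")):
            assert c.ci_low <= c.total_effect_por <= c.ci_high

    def test_invariant_enforced_in_type(self):
        with pytest.raises(ValueError, match="inconsistent"):
            SpatialClassification(region="A", total_effect_por=2.0, ci_low=1.2,
                                  ci_high=3.0, category="negative",
                                  nominal_level=0.95)

    def test_planted_coldspot_classified_negative(self, large_age_fit):
        truth, _, _, samples = large_age_fit
        total = total_spatial_effect(samples)
        out = {c.region: c for c in classify_regions(
            total, samples.region_labels, nominal_level=0.95)}
        assert out["Diourbel"].category == "negative"
        assert out["Kolda"].category == "positive"


class TestCurveSummary:
    def _fit(self, amp, seed):
        rng = np.random.default_rng(seed)
        n = 1500
        age = rng.integers(15, 50, n)
        eta = -0.5 + amp * (30.0 - age) / 10.0
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        ds = tiny_dataset(y, age=age)
        spec = ModelSpec(nonlinear=[SplineTerm("age", 8, 3)], spatial_field=None,
                         include_structured=False, include_unstructured=False)
        from geosurvey.model import build_design, gibbs_fit

        blocks = build_design(ds, spec)
        return gibbs_fit(blocks, MCMCConfig(seed=seed, iterations=600,
                                            burn_in=200, thin=2), spec)

    def test_constant_curve_band_straddles_zero(self):
        s = self._fit(0.0, seed=30)
        cs = curve_summary(s, "age", np.arange(16, 49), level=0.8)
        assert (cs.band_low < 0).mean() > 0.8
        assert (cs.band_high > 0).mean() > 0.8

    def test_declining_curve_recovered(self):
        decr = 0
        for seed in range(31, 41):
            s = self._fit(0.9, seed=seed)
            cs = curve_summary(s, "age", np.arange(20, 46), level=0.8)
            decr += cs.direction_flag(20, 45) == "decreasing" or (
                cs.mean[0] > cs.mean[-1] and
                np.mean(np.diff(cs.mean) < 0) > 0.9)
        assert decr >= 8

    def test_band_nesting(self):
        s = self._fit(0.5, seed=42)
        g = np.arange(16, 49)
        c80 = curve_summary(s, "age", g, level=0.80)
        c95 = curve_summary(s, "age", g, level=0.95)
        assert (c95.band_low <= c80.band_low + 1e-12).all()
        assert (c80.band_high <= c95.band_high + 1e-12).all()

    def test_no_extrapolation(self):
        s = self._fit(0.5, seed=43)
        with pytest.raises(ValueError, match="range"):
            curve_summary(s, "age", np.array([10.0, 60.0]))

    def test_unknown_field_rejected(self):
        s = self._fit(0.5, seed=44)
        with pytest.raises(KeyError):
            curve_summary(s, "income", np.array([20.0]))


class TestHarmonizeWaves:
    def test_identity_map_plain_difference(self):
        out = harmonize_waves({"A": 10.0, "B": 20.0}, {"A": 12.0, "B": 15.0},
                              {"A": ["A"], "B": ["B"]})
        d = out.set_index("region")["difference"]
        assert d["A"] == pytest.approx(2.0)
        assert d["B"] == pytest.approx(-5.0)

    def test_two_subdivisions_unweighted_mean(self):
        out = harmonize_waves({"P": 0.0}, {"P1": 10.0, "P2": 20.0},
                              {"P": ["P1", "P2"]})
        assert out.loc[0, "wave2"] == pytest.approx(15.0)

    def test_unmapped_wave2_region_rejected(self):
        with pytest.raises(ValueError, match="not covered"):
            harmonize_waves({"A": 1.0}, {"A": 1.0, "Z": 2.0}, {"A": ["A"]})

    def test_mean_preservation_per_parent(self):
        rng = np.random.default_rng(7)
        w2 = {f"P{i}{j}": float(rng.normal()) for i in range(3) for j in range(2)}
        wmap = {f"P{i}": [f"P{i}0", f"P{i}1"] for i in range(3)}
        w1 = {f"P{i}": 0.0 for i in range(3)}
        out = harmonize_waves(w1, w2, wmap).set_index("region")
        for i in range(3):
            assert out.loc[f"P{i}", "wave2"] == pytest.approx(
                (w2[f"P{i}0"] + w2[f"P{i}1"]) / 2)

    def test_attenuated_parent_most_negative(self, graph11, wave_map, graph14):
        # plant wave-2 attenuation in one parent region; its harmonized
        # prevalence difference should be the most negative in >= 8/10 seeds
        from geosurvey.descriptive import prevalence_table
        from geosurvey.synthetic import SurveyDesign, simulate_survey
        from helpers import null_truth

        hits = 0
        for seed in range(10):
            t1 = null_truth(graph11, intercept=-1.0)
            t1.f_str["Kaolack"] = 1.0
            t2 = null_truth(graph11, intercept=-1.0)
            t2.f_str["Kaolack"] = -1.0
            d1 = SurveyDesign(clusters_per_region={l: 5 for l in graph11.labels})
            d2 = SurveyDesign(clusters_per_region={l: 4 for l in graph14.labels},
                              wave_region_map=wave_map, split_noise_sd=0.0)
            ds1 = simulate_survey(t1, d1, graph11, wave=1, seed=seed)
            ds2 = simulate_survey(t2, d2, graph14, wave=2, seed=seed + 50)
            p1 = prevalence_table(ds1, by=["region"]).set_index("region")["percent"]
            p2 = prevalence_table(ds2, by=["region"]).set_index("region")["percent"]
            out = harmonize_waves(p1, p2, wave_map).set_index("region")
            hits += out["difference"].idxmin() == "Kaolack"
        assert hits >= 8


@pytest.fixture(scope="module")
def confounded_dataset():
    # region B is high-risk AND young: region confounds the age effect
    rng = np.random.default_rng(9)
    n = 3000
    region = rng.choice(["A", "B"], n)
    age = np.where(region == "B",
                   rng.integers(15, 30, n), rng.integers(30, 50, n))
    family = rng.choice(["small", "large"], n)  # null factor
    eta = -1.0 + 1.5 * (region == "B")
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    return tiny_dataset(y, age=age, region=region, family_size=family,
                        cluster=np.char.add(region.astype(str), "-c1"))


@pytest.fixture(scope="module")
def two_region_graph():
    from geosurvey.region_graph import RegionGraph

    return RegionGraph(labels=("A", "B"), adjacency=frozenset({("A", "B")}))


class TestStepwiseSensitivity:
    def test_base_equals_full_single_noop_step(self, confounded_dataset):
        spec = ModelSpec(nonlinear=[SplineTerm("age", 6, 3)], spatial_field=None,
                         include_structured=False, include_unstructured=False)
        out = stepwise_sensitivity(confounded_dataset, spec, [],
                                   MCMCConfig(seed=70, iterations=300,
                                              burn_in=100, thin=2))
        assert len(out) == 1
        assert out.loc[0, "max_abs_change"] == 0.0

    def test_confounder_region_largest_change(self, confounded_dataset,
                                              two_region_graph):
        spec = ModelSpec(nonlinear=[SplineTerm("age", 6, 3)], spatial_field=None,
                         include_structured=False, include_unstructured=False)
        out = stepwise_sensitivity(
            confounded_dataset, spec,
            [FixedTerm("family_size", reference="large"), "region"],
            MCMCConfig(seed=71, iterations=400, burn_in=150, thin=2),
            graph=two_region_graph)
        changes = out.set_index("step")["max_abs_change"]
        assert changes["+region"] == changes.drop("base").max()

    def test_null_factor_change_below_noise_floor(self, confounded_dataset,
                                                  two_region_graph):
        spec = ModelSpec(nonlinear=[SplineTerm("age", 6, 3)], spatial_field=None,
                         include_structured=False, include_unstructured=False)
        # noise floor: replicate-to-replicate variation of the base curve
        from geosurvey.model import build_design, gibbs_fit

        grid = np.arange(16.0, 49.0)
        curves = []
        for seed in (80, 81):
            blocks = build_design(confounded_dataset, spec)
            s = gibbs_fit(blocks, MCMCConfig(seed=seed, iterations=400,
                                             burn_in=150, thin=2), spec)
            curves.append(curve_summary(s, "age", grid).mean)
        floor = np.max(np.abs(curves[0] - curves[1]))
        out = stepwise_sensitivity(
            confounded_dataset, spec,
            [FixedTerm("family_size", reference="large")],
            MCMCConfig(seed=80, iterations=400, burn_in=150, thin=2),
            grid=grid)
        assert out.set_index("step")["max_abs_change"]["+family_size"] < 2 * floor

    def test_unknown_candidate_rejected(self, confounded_dataset):
        spec = ModelSpec(nonlinear=[SplineTerm("age", 6, 3)], spatial_field=None,
                         include_structured=False, include_unstructured=False)
        with pytest.raises(KeyError):
            stepwise_sensitivity(confounded_dataset, spec,
                                 [FixedTerm("nope", reference="x")],
                                 MCMCConfig(seed=1, iterations=10, burn_in=0,
                                            thin=1))


class TestExportChoropleth:
    def _classification(self, categories):
        return [SpatialClassification(
            region=f"R{i}", total_effect_por=1.0 if c == "not_significant"
            else (2.0 if c == "positive" else 0.5),
            ci_low=1.2 if c == "positive" else (0.2 if c == "negative" else 0.8),
            ci_high=3.0 if c == "positive" else (0.8 if c == "negative" else 1.2),
            category=c, nominal_level=0.95)
            for i, c in enumerate(categories)]

    def test_missing_geometry_table_fallback(self, tmp_path):
        cls = self._classification(["not_significant", "positive"])
        with pytest.warns(UserWarning, match="fallback"):
            out = export_choropleth(cls, tmp_path / "map")
        df = pd.read_csv(out)
        assert set(df["region"]) == {"R0", "R1"}

    def test_geometry_render(self, tmp_path):
        cls = self._classification(["negative", "positive", "not_significant"])
        features = []
        for i in range(3):
            features.append({
                "type": "Feature", "properties": {"region": f"R{i}"},
                "geometry": {"type": "Polygon", "coordinates": [[
                    [i, 0], [i + 1, 0], [i + 1, 1], [i, 1], [i, 0]]]}})
        geo = tmp_path / "regions.geojson"
        geo.write_text(json.dumps({"type": "FeatureCollection",
                                   "features": features}))
        out = export_choropleth(cls, tmp_path / "map.png", geometry=geo)
        assert out.exists() and out.stat().st_size > 0

    def test_geometry_label_mismatch_rejected(self, tmp_path):
        cls = self._classification(["positive"])
        geo = tmp_path / "regions.geojson"
        geo.write_text(json.dumps({"type": "FeatureCollection", "features": []}))
        with pytest.raises(ValueError, match="missing regions"):
            export_choropleth(cls, tmp_path / "map.png", geometry=geo)


class TestEffectSummaryInvariants:
    def test_interval_must_contain_point(self):
        with pytest.raises(ValueError):
            EffectSummary(term="x", por=5.0, ci_low=1.0, ci_high=2.0)

    def test_curve_band_must_contain_mean(self):
        with pytest.raises(ValueError):
            CurveSummary(grid=np.array([1.0]), mean=np.array([2.0]),
                         band_low=np.array([0.0]), band_high=np.array([1.0]),
                         level=0.8)
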