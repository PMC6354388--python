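"""Shared fixtures: fixture graphs, planted recovery truths, and cached
model fits reused across recovery-style tests."""

from __future__ import annotations

import numpy as np
import pytest

from geosurvey.model import (
    FixedTerm,
    MCMCConfig,
    ModelSpec,
    SplineTerm,
    build_design,
    gibbs_fit,
)
from geosurvey.region_graph import (
    SENEGAL_SPLITS_2008,
    RegionGraph,
    senegal_graph_2005,
)
from geosurvey.synthetic import (
    AGE_MAX,
    AGE_MIN,
    GroundTruth,
    SurveyDesign,
    age_pmf,
    simulate_survey,
    split_region_map,
)


@pytest.fixture(scope="session")
def graph11() -> RegionGraph:
    return senegal_graph_2005()


@pytest.fixture(scope="session")
def graph14(graph11):
    g2, _ = split_region_map(graph11, SENEGAL_SPLITS_2008)
    return g2


@pytest.fixture(scope="session")
def wave_map(graph11):
    _, wmap = split_region_map(graph11, SENEGAL_SPLITS_2008)
    return wmap


def make_recovery_truth(graph: RegionGraph, *, curve_amp: float = 1.2,
                        intercept: float = -1.6) -> GroundTruth:
    """A fully known truth using only the covariates the recovery model
    fits (urban, wealth, smooth age, both spatial blocks), with a clear
    hotspot (Kolda) and cold spot (Diourbel)."""
    raw_str = {"Dakar": -0.5, "Diourbel": -1.0, "Fatick": -0.4, "Kaolack": -0.3,
               "Kolda": 1.1, "Louga": -0.6, "Matam": 0.6, "SaintLouis": 0.1,
               "Tambacounda": 0.8, "Thies": -0.5, "Ziguinchor": 0.2}
    vals = np.array([raw_str[l] for l in graph.labels])
    vals -= vals.mean()
    f_str = dict(zip(graph.labels, vals.tolist()))
    ustr = np.array([0.1 * (-1) ** i for i in range(graph.n_regions)], dtype=float)
    ustr -= ustr.mean()
    f_unstr = dict(zip(graph.labels, ustr.tolist()))
    ages, pmf = age_pmf()
    curve = curve_amp * np.exp(-(ages - AGE_MIN) / 12.0)
    curve -= float(np.average(curve, weights=pmf))
    beta = {
        "urban": {0: np.log(2.0)},
        "wealth": {"poorest": np.log(2.5), "poorer": np.log(2.0),
                   "middle": np.log(1.5), "richer": np.log(1.2)},
    }
    return GroundTruth(intercept=intercept, beta=beta,
                       age_grid=ages.astype(float), age_values=curve,
                       f_str=f_str, f_unstr=f_unstr,
                       tau2_str=0.5, tau2_unstr=0.05, tau2_age=0.1,
                       hotspots=("Kolda",))


RECOVERY_SPEC = ModelSpec(
    fixed=[FixedTerm("urban", reference=1),
           FixedTerm("wealth", reference="richest")],
    nonlinear=[SplineTerm("age", n_inner_knots=10, degree=3)],
    spatial_field="region",
)

# scaled-down chains: desk-budget replicates, documented in the README
RECOVERY_MCMC = dict(iterations=800, burn_in=250, thin=2)


def recovery_design(graph: RegionGraph, clusters: int = 9,
                    wave_region_map=None) -> SurveyDesign:
    return SurveyDesign(
        clusters_per_region={l: clusters for l in graph.labels},
        urban_fraction={l: 0.35 + 0.3 * (i % 3) / 2
                        for i, l in enumerate(graph.labels)},
        wave_region_map=wave_region_map,
    )


def fit_recovery_replicate(graph, truth, wave, seed, *, clusters=9,
                           wave_region_map=None, mcmc=None):
    design = recovery_design(graph, clusters, wave_region_map)
    ds = simulate_survey(truth, design, graph, wave=wave, seed=seed)
    blocks = build_design(ds, RECOVERY_SPEC, graph)
    cfg = MCMCConfig(seed=seed + 1000, **(mcmc or RECOVERY_MCMC))
    return ds, gibbs_fit(blocks, cfg, RECOVERY_SPEC)


@pytest.fixture(scope="session")
def recovery_fits(graph11, graph14, wave_map):
    """20 two-wave replicate fits (10 wave-1 on 11 regions, 10 wave-2 on
    14 regions) at n ~ 4,000 with scaled-down chains; shared by the
    coverage, hotspot and correlation tests."""
    truth = make_recovery_truth(graph11)
    fits = []
    for rep in range(10):
        _, s = fit_recovery_replicate(graph11, truth, 1, seed=100 + rep)
        fits.append(("wave1", s))
    for rep in range(10):
        _, s = fit_recovery_replicate(
            graph14, truth, 2, seed=200 + rep, clusters=7,
            wave_region_map=wave_map)
        fits.append(("wave2", s))
    return truth, fits


@pytest.fixture(scope="session")
def large_age_fit(graph11):
    """One n ~ 10,000 replicate for the age-curve recovery criterion."""
    truth = make_recovery_truth(graph11)
    design = recovery_design(graph11, clusters=23)
    ds = simulate_survey(truth, design, graph11, wave=1, seed=777)
    blocks = build_design(ds, RECOVERY_SPEC, graph11)
    cfg = MCMCConfig(seed=778, iterations=1000, burn_in=300, thin=2)
    samples = gibbs_fit(blocks, cfg, RECOVERY_SPEC)
    return truth, ds, blocks, samples
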