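"""Two-wave DHS-like survey simulation with known ground truth.

The generator plants a full geo-additive structure — fixed effects on the
log-odds scale, a smooth nonlinear age effect, and structured (intrinsic
CAR) plus unstructured region effects — then draws respondents through a
two-stage design: clusters within regions, a fixed number of households
per cluster, and all women aged 15-49 within each sampled household.
Everything is seed-mandatory and reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .region_graph import (
    GraphValidationError,
    RegionGraph,
    _canonical_pair,
    connected_components,
    icar_precision,
)

__all__ = [
    "AGE_MIN",
    "AGE_MAX",
    "GroundTruth",
    "SurveyDesign",
    "SurveyDataset",
    "DATASET_COLUMNS",
    "age_pmf",
    "default_truth",
    "default_design",
    "simulate_survey",
    "split_region_map",
    "write_dataset",
    "read_dataset",
    "write_truth",
    "read_truth",
]

AGE_MIN, AGE_MAX = 15, 49

EDUCATION_LEVELS = ("none", "primary", "secondary", "higher")
WEALTH_LEVELS = ("poorest", "poorer", "middle", "richer", "richest")
FAMILY_LEVELS = ("small", "middle", "large")
ETHNICITY_LEVELS = ("wolof", "poular", "serer", "mandingu", "diola", "soninke", "other")
RELIGION_LEVELS = ("muslim", "other")

DATASET_COLUMNS = (
    "outcome", "wave", "region", "cluster", "household", "age", "urban",
    "married", "education", "partner_education", "wealth", "family_size",
    "ethnicity", "religion", "partner_age",
)


def age_pmf() -> tuple[np.ndarray, np.ndarray]:
    """Sampling distribution of respondent age (declining pyramid).

    Returns the integer age grid 15..49 and its probability vector.
    """
    ages = np.arange(AGE_MIN, AGE_MAX + 1)
    w = (55.0 - ages).astype(float)
    return ages, w / w.sum()


def _center(values: np.ndarray, weights: np.ndarray | None = None) -> np.ndarray:
    if weights is None:
        return values - values.mean()
    return values - float(np.average(values, weights=weights))


@dataclass
class GroundTruth:
    """Planted generative parameters for one simulation run.

    ``beta`` maps a dataset column to a ``{level: log-odds coefficient}``
    dict; levels not listed (reference levels) contribute 0.  The age
    effect is stored as values on the integer age grid and interpolated
    linearly in between.
    """

    intercept: float
    beta: dict[str, dict[object, float]]
    age_grid: np.ndarray
    age_values: np.ndarray
    f_str: dict[str, float]
    f_unstr: dict[str, float]
    tau2_str: float
    tau2_unstr: float
    tau2_age: float
    hotspots: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for name, v in (("tau2_str", self.tau2_str),
                        ("tau2_unstr", self.tau2_unstr),
                        ("tau2_age", self.tau2_age)):
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        self.age_grid = np.asarray(self.age_grid, dtype=float)
        self.age_values = np.asarray(self.age_values, dtype=float)

    def f_age(self, age) -> np.ndarray:
        """Nonlinear age effect on the log-odds scale (linear interpolation)."""
        return np.interp(np.asarray(age, dtype=float), self.age_grid, self.age_values)

    def total_spatial(self) -> dict[str, float]:
        return {r: self.f_str[r] + self.f_unstr[r] for r in self.f_str}

    def regions(self) -> tuple[str, ...]:
        return tuple(self.f_str)

    def linear_predictor(self, row: pd.Series | dict) -> float:
        eta = self.intercept
        for fld, levels in self.beta.items():
            eta += levels.get(row[fld], 0.0)
        eta += float(self.f_age(row["age"]))
        eta += self.f_str[row["region"]] + self.f_unstr[row["region"]]
        return eta


@dataclass
class SurveyDesign:
    """Two-stage sampling design: clusters within regions, households within
    clusters, all women 15-49 within households."""

    clusters_per_region: dict[str, int]
    households_per_cluster: int = 21
    women_lambda: float = 2.0
    women_max: int = 4
    urban_fraction: dict[str, float] = field(default_factory=dict)
    wave_region_map: dict[str, list[str]] | None = None
    split_noise_sd: float = 0.2

    def __post_init__(self) -> None:
        if self.households_per_cluster < 1:
            raise ValueError("households_per_cluster must be >= 1")
        if self.wave_region_map is not None:
            children = [c for parts in self.wave_region_map.values() for c in parts]
            if len(children) != len(set(children)):
                raise ValueError("wave_region_map assigns a wave-2 region twice")


def default_design(graph: RegionGraph,
                   total_clusters: int = 377,
                   wave_region_map: dict[str, list[str]] | None = None) -> SurveyDesign:
    """A design roughly matching the survey scale: ~377 clusters split
    evenly across regions, 21 households per cluster."""
    per = max(1, round(total_clusters / graph.n_regions))
    rng_free = {lab: 0.35 + 0.3 * (i % 3) / 2 for i, lab in enumerate(graph.labels)}
    rng_free["Dakar"] = 0.93 if "Dakar" in graph.labels else rng_free.get("Dakar", 0.5)
    return SurveyDesign(
        clusters_per_region={lab: per for lab in graph.labels},
        urban_fraction=rng_free,
        wave_region_map=wave_region_map,
    )


@dataclass
class SurveyDataset:
    """Respondent-level records for one wave (thin wrapper over a DataFrame)."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in DATASET_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"dataset missing columns: {missing}")
        self.df = self.df.loc[:, list(DATASET_COLUMNS)].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def validate(self, graph: RegionGraph | None = None) -> None:
        df = self.df
        bad = sorted(set(df["outcome"].unique()) - {0, 1})
        if bad:
            raise ValueError(f"outcome must be 0/1; found {bad}")
        if ((df["age"] < AGE_MIN) | (df["age"] > AGE_MAX)).any():
            raise ValueError(f"age outside [{AGE_MIN},{AGE_MAX}]")
        if not df["wave"].isin([1, 2]).all():
            raise ValueError("wave must be 1 or 2")
        span = df.groupby("cluster")["region"].nunique()
        if (span > 1).any():
            raise ValueError(f"clusters spanning regions: {list(span[span > 1].index)}")
        if graph is not None:
            unknown = sorted(set(df["region"].unique()) - set(graph.labels))
            if unknown:
                raise ValueError(f"regions absent from graph: {unknown}")


# ---------------------------------------------------------------------------
# Ground-truth generation
# ---------------------------------------------------------------------------

def _sample_icar(graph: RegionGraph, tau2: float, rng: np.random.Generator) -> np.ndarray:
    """Draw from the intrinsic-CAR prior on its constrained subspace,
    centered per connected component."""
    n = graph.n_regions
    if tau2 == 0.0:
        return np.zeros(n)
    Q = icar_precision(graph).entries.astype(float)
    eigval, eigvec = np.linalg.eigh(Q)
    tol = 1e-9 * max(1.0, float(eigval.max()))
    keep = eigval > tol
    coefs = rng.normal(size=keep.sum()) * np.sqrt(tau2 / eigval[keep])
    f = eigvec[:, keep] @ coefs
    for comp in connected_components(graph):
        idx = [graph.index(l) for l in comp]
        f[idx] -= f[idx].mean()
    return f


def default_truth(graph: RegionGraph, seed: int, *,
                  tau2_str: float = 0.8,
                  tau2_unstr: float = 0.1,
                  tau2_age: float = 0.1,
                  intercept: float = -4.2) -> GroundTruth:
    """Plant a ground truth with magnitudes loosely echoing the fitted
    survey analysis: modest fixed effects, a declining age curve, and a
    spatially smooth region surface with recorded hotspots."""
    if seed is None:
        raise ValueError("seed is mandatory for ground-truth generation")
    rng = np.random.default_rng(seed)

    f_str_vec = _sample_icar(graph, tau2_str, rng)
    f_unstr_vec = rng.normal(scale=np.sqrt(tau2_unstr), size=graph.n_regions)
    for comp in connected_components(graph):
        idx = [graph.index(l) for l in comp]
        f_unstr_vec[idx] -= f_unstr_vec[idx].mean()
    if tau2_unstr == 0.0:
        f_unstr_vec[:] = 0.0

    ages, pmf = age_pmf()
    raw = 1.5 * np.exp(-(ages - AGE_MIN) / 14.0)
    age_values = _center(raw, pmf)

    beta = {
        "urban": {0: np.log(1.5)},              # rural excess risk
        "married": {1: np.log(1.4)},
        "education": {"none": np.log(2.2), "primary": np.log(1.8),
                      "secondary": np.log(1.4)},
        "wealth": {"poorest": np.log(3.5), "poorer": np.log(3.0),
                   "middle": np.log(2.0), "richer": np.log(1.5)},
        "ethnicity": {"poular": np.log(4.0), "mandingu": np.log(5.0),
                      "diola": np.log(3.0), "soninke": np.log(4.5),
                      "serer": np.log(0.3), "other": np.log(2.0)},
        "religion": {"muslim": np.log(2.5)},
    }

    total = f_str_vec + f_unstr_vec
    order = np.argsort(total)[::-1]
    hotspots = tuple(graph.labels[i] for i in order[:2] if total[i] > 0.5)

    return GroundTruth(
        intercept=intercept,
        beta=beta,
        age_grid=ages.astype(float),
        age_values=age_values,
        f_str=dict(zip(graph.labels, f_str_vec.tolist())),
        f_unstr=dict(zip(graph.labels, f_unstr_vec.tolist())),
        tau2_str=tau2_str,
        tau2_unstr=tau2_unstr,
        tau2_age=tau2_age,
        hotspots=hotspots,
    )


# ---------------------------------------------------------------------------
# Region splitting (wave-1 -> wave-2 harmonization support)
# ---------------------------------------------------------------------------

def split_region_map(graph_w1: RegionGraph,
                     splits: dict[str, list[str]],
                     ) -> tuple[RegionGraph, dict[str, list[str]]]:
    """Subdivide regions of the wave-1 graph into wave-2 regions.

    Each split region is replaced in place (in label order) by its parts;
    parts are mutually adjacent and inherit all of the parent's external
    adjacencies — a stylized rule, not surveyed geography.  Returns the
    wave-2 graph and the parent -> parts correspondence covering every
    wave-2 region exactly once.
    """
    labels1 = list(graph_w1.labels)
    for parent, parts in splits.items():
        if parent not in labels1:
            raise GraphValidationError(f"split parent {parent!r} not in graph")
        if len(parts) < 1:
            raise GraphValidationError(f"split for {parent!r} must be non-empty")
        for p in parts:
            collides = p in labels1 and p != parent
            if collides:
                raise GraphValidationError(
                    f"split label {p!r} collides with existing label")
        if len(set(parts)) != len(parts):
            raise GraphValidationError(f"duplicate labels in split for {parent!r}")

    labels2: list[str] = []
    for lab in labels1:
        labels2.extend(splits.get(lab, [lab]))
    if len(set(labels2)) != len(labels2):
        raise GraphValidationError("split labels collide across parents")

    def expand(lab: str) -> list[str]:
        return splits.get(lab, [lab])

    adjacency2: set[tuple[str, str]] = set()
    for a, b in graph_w1.adjacency:
        for pa in expand(a):
            for pb in expand(b):
                adjacency2.add(_canonical_pair(pa, pb))
    for parent, parts in splits.items():
        for i, pa in enumerate(parts):
            for pb in parts[i + 1:]:
                adjacency2.add(_canonical_pair(pa, pb))

    graph2 = RegionGraph(labels=tuple(labels2), adjacency=frozenset(adjacency2))
    wave_region_map = {lab: list(expand(lab)) for lab in labels1}
    return graph2, wave_region_map


def _child_effects(parent_effects: dict[str, float],
                   wave_region_map: dict[str, list[str]],
                   noise_sd: float,
                   rng: np.random.Generator) -> dict[str, float]:
    out: dict[str, float] = {}
    for parent, parts in wave_region_map.items():
        base = parent_effects[parent]
        for child in parts:
            out[child] = base + (rng.normal(scale=noise_sd) if noise_sd > 0 else 0.0)
    return out


# ---------------------------------------------------------------------------
# Survey simulation
# ---------------------------------------------------------------------------

def _trunc_poisson_pmf(lam: float, kmax: int) -> np.ndarray:
    from scipy.stats import poisson

    p = poisson.pmf(np.arange(kmax + 1), lam)
    return p / p.sum()


def _region_ethnicity_pmf(region_index: int) -> np.ndarray:
    # spatially clustered mixing: each region leans towards one group,
    # blended with the national base distribution
    base = np.array([0.40, 0.25, 0.15, 0.05, 0.05, 0.03, 0.07])
    lean = np.zeros(len(ETHNICITY_LEVELS))
    lean[region_index % len(ETHNICITY_LEVELS)] = 1.0
    mix = 0.55 * base + 0.45 * lean
    return mix / mix.sum()


def simulate_survey(truth: GroundTruth, design: SurveyDesign, graph: RegionGraph,
                    wave: int, seed: int, *, link: str = "logit") -> SurveyDataset:
    """Simulate one wave of respondent-level survey data.

    Stage 1 samples ``design.clusters_per_region[r]`` clusters per region;
    stage 2 samples ``design.households_per_cluster`` households per
    cluster; all women aged 15-49 in each household are interviewed.  The
    outcome is Bernoulli with linear predictor intercept + fixed effects +
    nonlinear age effect + structured and unstructured region effects.

    For wave 2 the truth's wave-1 region effects are inherited by their
    subdivisions through ``design.wave_region_map`` with independent
    Gaussian perturbation of SD ``design.split_noise_sd``.
    """
    if seed is None:
        raise ValueError("seed is mandatory for survey simulation")
    if wave not in (1, 2):
        raise ValueError("wave must be 1 or 2")
    if link not in ("logit", "probit"):
        raise ValueError(f"unknown link {link!r}")
    rng = np.random.default_rng(seed)

    if set(truth.regions()) == set(graph.labels):
        f_str = dict(truth.f_str)
        f_unstr = dict(truth.f_unstr)
    else:
        if wave != 2 or design.wave_region_map is None:
            raise ValueError(
                "wave=2 with subdivided regions requires design.wave_region_map")
        f_str = _child_effects(truth.f_str, design.wave_region_map,
                               design.split_noise_sd, rng)
        f_unstr = _child_effects(truth.f_unstr, design.wave_region_map,
                                 design.split_noise_sd, rng)
    missing = sorted(set(graph.labels) - set(f_str))
    if missing:
        raise ValueError(f"no planted effect for regions {missing}")
    missing_design = sorted(set(graph.labels) - set(design.clusters_per_region))
    if missing_design:
        raise ValueError(f"design does not cover regions {missing_design}")

    ages, a_pmf = age_pmf()
    w_pmf = _trunc_poisson_pmf(design.women_lambda, design.women_max)

    def _cat(levels, cdfs, size_or_idx):
        # vectorized categorical draw; cdfs may be one cdf or a per-row choice
        u = rng.random(size_or_idx if np.isscalar(size_or_idx) else len(size_or_idx))
        if isinstance(cdfs, tuple):  # (cdf_if_true, cdf_if_false, mask)
            cdf_t, cdf_f, mask = cdfs
            idx = np.where(mask, np.searchsorted(cdf_t, u), np.searchsorted(cdf_f, u))
        else:
            idx = np.searchsorted(cdfs, u)
        return np.asarray(levels, dtype=object)[idx]

    edu_cdf_urban = np.cumsum([0.45, 0.28, 0.23, 0.04])
    edu_cdf_rural = np.cumsum([0.66, 0.24, 0.09, 0.01])
    wl_cdf_urban = np.cumsum([0.05, 0.10, 0.20, 0.30, 0.35])
    wl_cdf_rural = np.cumsum([0.28, 0.25, 0.21, 0.16, 0.10])
    fam_cdf = np.cumsum([0.84, 0.14, 0.02])
    rel_cdf = np.cumsum([0.95, 0.05])
    pedu_cdf = np.cumsum([0.70, 0.13, 0.13, 0.04])
    age_cdf = np.cumsum(a_pmf)
    women_cdf = np.cumsum(w_pmf)

    frames: list[pd.DataFrame] = []
    H = design.households_per_cluster
    for r_idx, region in enumerate(graph.labels):
        eth_cdf = np.cumsum(_region_ethnicity_pmf(r_idx))
        urb_frac = design.urban_fraction.get(region, 0.5)
        n_cl = design.clusters_per_region[region]
        urban_cl = (rng.random(n_cl) < urb_frac).astype(np.int64)
        n_women_hh = np.searchsorted(women_cdf, rng.random(n_cl * H))
        hh_of_woman = np.repeat(np.arange(n_cl * H), n_women_hh)
        nw = len(hh_of_woman)
        if nw == 0:
            continue
        cl_of_woman = hh_of_woman // H
        urban = urban_cl[cl_of_woman]
        age = ages[np.searchsorted(age_cdf, rng.random(nw))]
        married = (rng.random(nw)
                   < np.clip(0.05 * (age - 14), 0.08, 0.95)).astype(np.int64)
        umask = urban.astype(bool)
        education = _cat(EDUCATION_LEVELS, (edu_cdf_urban, edu_cdf_rural, umask),
                         np.arange(nw))
        wealth = _cat(WEALTH_LEVELS, (wl_cdf_urban, wl_cdf_rural, umask),
                      np.arange(nw))
        family_size = _cat(FAMILY_LEVELS, fam_cdf, nw)
        ethnicity = _cat(ETHNICITY_LEVELS, eth_cdf, nw)
        religion = _cat(RELIGION_LEVELS, rel_cdf, nw)
        partner_age_raw = np.clip(np.round(age + rng.normal(15.0, 6.0, nw)), 18, 97)
        partner_education_raw = _cat(EDUCATION_LEVELS, pedu_cdf, nw)
        mmask = married.astype(bool)
        partner_age = pd.array(np.where(mmask, partner_age_raw, 0).astype(np.int64),
                               dtype="Int64")
        partner_age[~mmask] = pd.NA
        partner_education = np.where(mmask, partner_education_raw, None)

        eta = np.full(nw, truth.intercept + f_str[region] + f_unstr[region])
        eta += truth.f_age(age)
        cols = {"urban": urban, "married": married, "education": education,
                "wealth": wealth, "family_size": family_size,
                "ethnicity": ethnicity, "religion": religion,
                "partner_education": partner_education, "partner_age": partner_age}
        for fld, levels in truth.beta.items():
            if fld == "age":
                continue
            vals = cols.get(fld)
            if vals is None:
                raise KeyError(f"truth.beta refers to unknown field {fld!r}")
            coefs = pd.Series(vals).map(lambda v: levels.get(v, 0.0)).to_numpy(float)
            eta += coefs
        if link == "logit":
            p = 1.0 / (1.0 + np.exp(-eta))
        else:
            from scipy.special import ndtr

            p = ndtr(eta)
        outcome = (rng.random(nw) < p).astype(np.int64)

        frames.append(pd.DataFrame({
            "outcome": outcome, "wave": wave, "region": region,
            "cluster": np.array([f"{region}-c{c + 1:03d}" for c in range(n_cl)],
                                dtype=object)[cl_of_woman],
            "household": np.array(
                [f"{region}-c{h // H + 1:03d}-h{h % H + 1:02d}"
                 for h in range(n_cl * H)], dtype=object)[hh_of_woman],
            "age": age, "urban": urban, "married": married,
            "education": education, "partner_education": partner_education,
            "wealth": wealth, "family_size": family_size,
            "ethnicity": ethnicity, "religion": religion,
            "partner_age": partner_age,
        }))

    df = pd.concat(frames, ignore_index=True)[list(DATASET_COLUMNS)]
    df["partner_age"] = df["partner_age"].astype("Int64")
    ds = SurveyDataset(df)
    ds.validate(graph)
    return ds


# ---------------------------------------------------------------------------
# Dataset and truth I/O (plain text, round-trip exact)
# ---------------------------------------------------------------------------

def write_dataset(dataset: SurveyDataset, path: str | Path) -> None:
    """Write the documented CSV layout; missing partner fields become
    empty cells."""
    df = dataset.df.copy()
    df.to_csv(path, index=False, na_rep="")


def read_dataset(path: str | Path, graph: RegionGraph | None = None) -> SurveyDataset:
    """Read a survey CSV written by :func:`write_dataset` and validate it."""
    df = pd.read_csv(
        path,
        dtype={
            "outcome": np.int64, "wave": np.int64, "region": str, "cluster": str,
            "household": str, "age": np.int64, "urban": np.int64,
            "married": np.int64, "education": str, "partner_education": "object",
            "wealth": str, "family_size": str, "ethnicity": str, "religion": str,
            "partner_age": "Int64",
        },
        keep_default_na=True,
    )
    df["partner_education"] = df["partner_education"].where(
        df["partner_education"].notna(), None)
    ds = SurveyDataset(df)
    ds.validate(graph)
    return ds


def write_truth(truth: GroundTruth, path: str | Path) -> None:
    """Dump all planted parameters as JSON (for recovery tests)."""
    payload = {
        "intercept": truth.intercept,
        "beta": {f: {str(k): v for k, v in lv.items()}
                 for f, lv in truth.beta.items()},
        "beta_key_types": {f: {str(k): type(k).__name__ for k in lv}
                           for f, lv in truth.beta.items()},
        "age_grid": truth.age_grid.tolist(),
        "age_values": truth.age_values.tolist(),
        "f_str": truth.f_str,
        "f_unstr": truth.f_unstr,
        "tau2_str": truth.tau2_str,
        "tau2_unstr": truth.tau2_unstr,
        "tau2_age": truth.tau2_age,
        "hotspots": list(truth.hotspots),
    }
    Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


def read_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    beta: dict[str, dict[object, float]] = {}
    for f, lv in payload["beta"].items():
        kt = payload.get("beta_key_types", {}).get(f, {})
        conv = {}
        for k, v in lv.items():
            conv[int(k) if kt.get(k) == "int" else k] = v
        beta[f] = conv
    return GroundTruth(
        intercept=payload["intercept"],
        beta=beta,
        age_grid=np.asarray(payload["age_grid"]),
        age_values=np.asarray(payload["age_values"]),
        f_str=payload["f_str"],
        f_unstr=payload["f_unstr"],
        tau2_str=payload["tau2_str"],
        tau2_unstr=payload["tau2_unstr"],
        tau2_age=payload["tau2_age"],
        hotspots=tuple(payload["hotspots"]),
    )
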