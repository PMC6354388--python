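"""Model specification and design-block construction.

The linear predictor is

    eta = intercept + W gamma + sum_j B_j alpha_j + f_str[region] + f_unstr[region]

with dummy-coded fixed effects (declared reference dropped), penalized
B-spline bases for nonlinear terms (second-order random-walk penalty) and
one-hot region incidence for the spatial blocks.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

from ..region_graph import PrecisionMatrix, RegionGraph, icar_precision
from ..synthetic import SurveyDataset

__all__ = [
    "FixedTerm",
    "SplineTerm",
    "ModelSpec",
    "DesignBlocks",
    "bspline_design",
    "bspline_knots",
    "rw2_penalty",
    "build_design",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FixedTerm:
    """A categorical fixed effect with a declared reference level.

    ``levels`` may pin the admissible level set; data containing a level
    outside it is an error.  When omitted, levels are taken from the data
    (sorted, for reproducibility).
    """

    field: str
    reference: object
    levels: tuple | None = None


@dataclass(frozen=True)
class SplineTerm:
    field: str
    n_inner_knots: int = 20
    degree: int = 3


@dataclass
class ModelSpec:
    fixed: list[FixedTerm] = field(default_factory=list)
    nonlinear: list[SplineTerm] = field(default_factory=list)
    spatial_field: str | None = "region"
    include_structured: bool = True
    include_unstructured: bool = True
    hyper_a: float = 0.001
    hyper_b: float = 0.001
    fixed_prior_var: float = 1e6
    link: str = "logit"
    cluster_field: str | None = None  # optional i.i.d. cluster intercept

    def __post_init__(self) -> None:
        if self.hyper_a <= 0 or self.hyper_b <= 0:
            raise ValueError("inverse-gamma hyperparameters must be positive")
        if self.link not in ("logit", "probit"):
            raise ValueError(f"unknown link {self.link!r}")
        # the intercept is always present, so an otherwise empty spec is a
        # valid intercept-only model

    def to_dict(self) -> dict:
        return {
            "fixed": [{"field": t.field, "reference": t.reference,
                       "levels": list(t.levels) if t.levels else None}
                      for t in self.fixed],
            "nonlinear": [{"field": t.field, "n_inner_knots": t.n_inner_knots,
                           "degree": t.degree} for t in self.nonlinear],
            "spatial_field": self.spatial_field,
            "include_structured": self.include_structured,
            "include_unstructured": self.include_unstructured,
            "hyper_a": self.hyper_a,
            "hyper_b": self.hyper_b,
            "fixed_prior_var": self.fixed_prior_var,
            "link": self.link,
            "cluster_field": self.cluster_field,
        }

    def hash(self) -> str:
        js = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(js.encode()).hexdigest()[:16]


def bspline_knots(lo: float, hi: float, n_inner_knots: int, degree: int) -> np.ndarray:
    """Equidistant knots on [lo, hi] (``n_inner_knots`` including both
    endpoints) extended by ``degree`` extra knots on each side."""
    if n_inner_knots < 2:
        raise ValueError("need at least 2 inner knots (the range endpoints)")
    if degree < 1:
        raise ValueError("degree must be >= 1")
    if not hi > lo:
        raise ValueError("constant covariate: no spread to smooth over")
    h = (hi - lo) / (n_inner_knots - 1)
    return lo + h * np.arange(-degree, n_inner_knots + degree)


def bspline_design(x: np.ndarray, n_inner_knots: int, degree: int,
                   *, lo: float | None = None, hi: float | None = None) -> np.ndarray:
    """B-spline basis matrix on equidistant knots; rows sum to 1.

    The basis has ``n_inner_knots + degree - 1`` columns.  Values outside
    [lo, hi] raise (no extrapolation).
    """
    x = np.asarray(x, dtype=float)
    lo = float(np.min(x)) if lo is None else float(lo)
    hi = float(np.max(x)) if hi is None else float(hi)
    if np.any(x < lo) or np.any(x > hi):
        raise ValueError("x outside declared spline range")
    t = bspline_knots(lo, hi, n_inner_knots, degree)
    nb = len(t) - degree - 1
    B = BSpline(t, np.eye(nb), degree, extrapolate=True)(x)
    return np.asarray(B)


def rw2_penalty(m: int) -> np.ndarray:
    """Second-order random-walk penalty K = D'D with D the (m-2) x m
    second-difference matrix; symmetric PSD of rank m-2."""
    if m < 3:
        raise ValueError("rw2 penalty needs at least 3 coefficients")
    D = np.zeros((m - 2, m), dtype=np.int64)
    for i in range(m - 2):
        D[i, i], D[i, i + 1], D[i, i + 2] = 1, -2, 1
    return (D.T @ D).astype(float)


@dataclass
class DesignBlocks:
    """All matrices needed by the Gibbs sampler, dimension-consistent with
    the (possibly row-filtered) respondent data."""

    W: np.ndarray                      # fixed effects incl. leading intercept col
    W_names: list[str]
    B: dict[str, np.ndarray]           # spline bases per nonlinear field
    K: dict[str, np.ndarray]           # RW2 penalties
    spline_meta: dict[str, dict]       # lo/hi/n_inner_knots/degree per field
    region_index: np.ndarray | None    # per-row region position
    region_labels: tuple[str, ...] | None
    Q: PrecisionMatrix | None
    components: list[list[int]] | None  # connected components as index lists
    cluster_index: np.ndarray | None
    n_clusters: int
    y: np.ndarray
    n_dropped: int

    @property
    def n(self) -> int:
        return self.W.shape[0]


def build_design(dataset: SurveyDataset, spec: ModelSpec,
                 graph: RegionGraph | None = None) -> DesignBlocks:
    """Assemble design blocks from a dataset and a model spec.

    Rows with missing values in any referenced field are dropped with a
    logged count.  Regions present in the data but absent from the graph
    are an error.
    """
    df = dataset.df
    fields = [t.field for t in spec.fixed] + [t.field for t in spec.nonlinear]
    if spec.spatial_field:
        fields.append(spec.spatial_field)
    if spec.cluster_field:
        fields.append(spec.cluster_field)
    missing_cols = [f for f in fields if f not in df.columns]
    if missing_cols:
        raise KeyError(f"fields not in dataset: {missing_cols}")

    mask = np.ones(len(df), dtype=bool)
    for f in fields:
        mask &= df[f].notna().to_numpy()
    n_dropped = int((~mask).sum())
    if n_dropped:
        logger.info("dropped %d rows with missing values in model fields", n_dropped)
    sub = df.loc[mask]
    y = sub["outcome"].to_numpy(dtype=np.float64)

    cols = [np.ones(len(sub))]
    names = ["intercept"]
    for term in spec.fixed:
        vals = sub[term.field]
        levels = (list(term.levels) if term.levels is not None
                  else sorted(pd.unique(vals), key=str))
        observed = set(pd.unique(vals))
        unknown = sorted(observed - set(levels), key=str)
        if unknown:
            raise ValueError(
                f"field {term.field!r} has levels {unknown} outside the declared set")
        if term.reference not in levels:
            raise ValueError(
                f"reference {term.reference!r} not a level of {term.field!r}")
        for lev in levels:
            if lev == term.reference:
                continue
            cols.append((vals == lev).to_numpy(dtype=np.float64))
            names.append(f"{term.field}={lev}")
    W = np.column_stack(cols)

    B: dict[str, np.ndarray] = {}
    K: dict[str, np.ndarray] = {}
    meta: dict[str, dict] = {}
    for term in spec.nonlinear:
        x = sub[term.field].to_numpy(dtype=float)
        lo, hi = float(x.min()), float(x.max())
        Bm = bspline_design(x, term.n_inner_knots, term.degree, lo=lo, hi=hi)
        B[term.field] = Bm
        K[term.field] = rw2_penalty(Bm.shape[1])
        meta[term.field] = {"lo": lo, "hi": hi,
                            "n_inner_knots": term.n_inner_knots,
                            "degree": term.degree}

    region_index = None
    region_labels = None
    Q = None
    components = None
    if spec.spatial_field and (spec.include_structured or spec.include_unstructured):
        if graph is None:
            raise ValueError("spatial terms require a region graph")
        regions = sub[spec.spatial_field].astype(str)
        unknown = sorted(set(regions.unique()) - set(graph.labels))
        if unknown:
            raise ValueError(f"regions in data but absent from graph: {unknown}")
        pos = {lab: i for i, lab in enumerate(graph.labels)}
        region_index = regions.map(pos).to_numpy(dtype=np.int64)
        region_labels = graph.labels
        Q = icar_precision(graph)
        from ..region_graph import connected_components as _cc

        components = [[graph.index(l) for l in comp] for comp in _cc(graph)]

    cluster_index = None
    n_clusters = 0
    if spec.cluster_field:
        codes, uniques = pd.factorize(sub[spec.cluster_field])
        cluster_index = codes.astype(np.int64)
        n_clusters = len(uniques)

    return DesignBlocks(
        W=W, W_names=names, B=B, K=K, spline_meta=meta,
        region_index=region_index, region_labels=region_labels, Q=Q,
        components=components, cluster_index=cluster_index,
        n_clusters=n_clusters, y=y, n_dropped=n_dropped,
    )
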