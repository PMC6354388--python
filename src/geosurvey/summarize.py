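"""Posterior reporting layer.

Turns MCMC draws into odds-ratio tables, credible curve bands, total
residual spatial effects with white/grey/black significance categories,
between-wave comparisons on a harmonized region frame, and the stepwise
age-effect sensitivity sweep.

Point estimates for odds ratios are posterior medians of the
exponentiated draws (invariant to the log transform); all intervals are
equal-tailed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .model import MCMCConfig, ModelSpec, PosteriorSamples, build_design, gibbs_fit
from .region_graph import RegionGraph
from .synthetic import SurveyDataset

__all__ = [
    "EffectSummary",
    "SpatialClassification",
    "CurveSummary",
    "fixed_effect_por",
    "total_spatial_effect",
    "classify_regions",
    "curve_summary",
    "harmonize_waves",
    "stepwise_sensitivity",
    "export_choropleth",
]


@dataclass(frozen=True)
class EffectSummary:
    term: str
    por: float
    ci_low: float
    ci_high: float
    level: float = 0.95
    is_reference: bool = False

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.por <= self.ci_high):
            raise ValueError(f"interval must contain point estimate ({self.term})")


@dataclass(frozen=True)
class SpatialClassification:
    region: str
    total_effect_por: float
    ci_low: float
    ci_high: float
    category: str  # negative | not_significant | positive
    nominal_level: float

    def __post_init__(self) -> None:
        expected = ("positive" if self.ci_low > 1.0
                    else "negative" if self.ci_high < 1.0
                    else "not_significant")
        if self.category != expected:
            raise ValueError(f"category inconsistent with interval for {self.region}")


@dataclass(frozen=True)
class CurveSummary:
    grid: np.ndarray
    mean: np.ndarray
    band_low: np.ndarray
    band_high: np.ndarray
    level: float

    def __post_init__(self) -> None:
        if not (np.all(self.band_low <= self.mean + 1e-12)
                and np.all(self.mean <= self.band_high + 1e-12)):
            raise ValueError("band must contain the pointwise mean")

    def direction_flag(self, lo: float = 20.0, hi: float = 45.0) -> str:
        """Shape over [lo, hi]: 'decreasing', 'increasing', or 'mixed'."""
        sel = (self.grid >= lo) & (self.grid <= hi)
        d = np.diff(self.mean[sel])
        if np.all(d <= 1e-10):
            return "decreasing"
        if np.all(d >= -1e-10):
            return "increasing"
        return "mixed"


def _eqtail(draws: np.ndarray, level: float, axis: int = 0):
    a = (1.0 - level) / 2.0
    return (np.quantile(draws, a, axis=axis),
            np.quantile(draws, 1.0 - a, axis=axis))


def fixed_effect_por(samples: PosteriorSamples, level: float = 0.95,
                     references: dict[str, str] | None = None) -> list[EffectSummary]:
    """Posterior odds ratios for every dummy-coded fixed-effect term.

    Each non-intercept design column yields median and equal-tailed
    interval of exp(draws).  ``references`` optionally maps a covariate
    field to its reference label so reference rows (POR = 1, degenerate
    interval) appear in the output table.
    """
    if not 0 < level < 1:
        raise ValueError("level must lie in (0,1)")
    if samples.n_draws == 0:
        raise ValueError("no stored draws")
    out: list[EffectSummary] = []
    for i, name in enumerate(samples.fixed_names):
        if name == "intercept":
            continue
        ex = np.exp(samples.fixed[:, i])
        lo, hi = _eqtail(ex, level)
        out.append(EffectSummary(term=name, por=float(np.median(ex)),
                                 ci_low=float(lo), ci_high=float(hi), level=level))
    if references:
        for fld, ref in references.items():
            out.append(EffectSummary(term=f"{fld}={ref}", por=1.0, ci_low=1.0,
                                     ci_high=1.0, level=level, is_reference=True))
    return out


def total_spatial_effect(samples: PosteriorSamples) -> np.ndarray:
    """Per-draw, per-region total residual spatial effect: the sum of the
    structured and unstructured effects (whichever blocks were fitted)."""
    if samples.f_str is None and samples.f_unstr is None:
        raise ValueError("no spatial block was fitted")
    if samples.f_str is None:
        return samples.f_unstr
    if samples.f_unstr is None:
        return samples.f_str
    return samples.f_str + samples.f_unstr


def classify_regions(total_draws: np.ndarray, region_labels,
                     nominal_level: float = 0.95) -> list[SpatialClassification]:
    """White/grey/black significance classification of total effects.

    POR = median of exp(total); equal-tailed interval at ``nominal_level``;
    positive (black) iff the interval lies above 1, negative (white) iff
    below 1, otherwise not significant (grey).
    """
    if not 0 < nominal_level < 1:
        raise ValueError("nominal_level must lie in (0,1)")
    ex = np.exp(total_draws)
    lo, hi = _eqtail(ex, nominal_level)
    med = np.median(ex, axis=0)
    out = []
    for j, lab in enumerate(region_labels):
        cat = ("positive" if lo[j] > 1.0
               else "negative" if hi[j] < 1.0
               else "not_significant")
        out.append(SpatialClassification(
            region=lab, total_effect_por=float(med[j]), ci_low=float(lo[j]),
            ci_high=float(hi[j]), category=cat, nominal_level=nominal_level))
    return out


def curve_summary(samples: PosteriorSamples, field: str, grid,
                  level: float = 0.80) -> CurveSummary:
    """Pointwise posterior mean and equal-tailed band of a fitted
    nonlinear effect, evaluated on ``grid`` (no extrapolation)."""
    if not 0 < level < 1:
        raise ValueError("level must lie in (0,1)")
    grid = np.asarray(grid, dtype=float)
    draws = samples.curve_draws(field, grid)
    lo, hi = _eqtail(draws, level)
    return CurveSummary(grid=grid, mean=draws.mean(axis=0),
                        band_low=lo, band_high=hi, level=level)


def harmonize_waves(summary_w1: pd.Series | dict,
                    summary_w2: pd.Series | dict,
                    wave_region_map: dict[str, list[str]]) -> pd.DataFrame:
    """Merge wave-2 per-region statistics onto the wave-1 region frame.

    Subdivided wave-2 regions are combined by unweighted averaging; output
    rows are wave-1 regions with both waves' values and the difference
    (wave 2 minus wave 1).  Every wave-2 region must be covered by the map.
    """
    s1 = pd.Series(summary_w1, dtype=float)
    s2 = pd.Series(summary_w2, dtype=float)
    mapped_children = {c for parts in wave_region_map.values() for c in parts}
    unmapped = sorted(set(s2.index) - mapped_children)
    if unmapped:
        raise ValueError(f"wave-2 regions not covered by wave_region_map: {unmapped}")
    rows = []
    for parent in s1.index:
        parts = wave_region_map.get(parent, [parent])
        present = [p for p in parts if p in s2.index]
        if not present:
            raise ValueError(f"no wave-2 value for any subdivision of {parent!r}")
        merged = float(np.mean([s2[p] for p in present]))
        rows.append({"region": parent, "wave1": float(s1[parent]),
                     "wave2": merged, "difference": merged - float(s1[parent])})
    return pd.DataFrame(rows, columns=["region", "wave1", "wave2", "difference"])


def stepwise_sensitivity(dataset: SurveyDataset, base_spec: ModelSpec,
                         candidate_factors: list, config: MCMCConfig,
                         graph: RegionGraph | None = None,
                         curve_field: str = "age",
                         grid=None) -> pd.DataFrame:
    """Refit the model adding one candidate factor at a time and report
    how the posterior-mean nonlinear curve moves at each step.

    Each step's change is the maximum absolute difference of the
    posterior-mean curve from the previous step on the grid, plus the
    curve's direction flag.  Candidates are either fixed-effect terms
    (``FixedTerm``) or the string "region" to switch the spatial blocks on.
    """
    from .model import FixedTerm

    for cand in candidate_factors:
        fld = cand if isinstance(cand, str) else cand.field
        if fld not in dataset.df.columns and fld != "region":
            raise KeyError(f"candidate factor {fld!r} not in dataset")
    if grid is None:
        ages = dataset.df[curve_field].dropna()
        grid = np.arange(float(ages.min()), float(ages.max()) + 1)
    grid = np.asarray(grid, dtype=float)

    def fit_curve(spec: ModelSpec, step: str):
        try:
            blocks = build_design(dataset, spec, graph)
            samples = gibbs_fit(blocks, config, spec)
            cs = curve_summary(samples, curve_field, grid)
        except Exception as exc:  # annotate with the step, per contract
            raise RuntimeError(f"stepwise fit failed at step {step!r}: {exc}") from exc
        return cs

    spec = base_spec
    prev = fit_curve(spec, "base")
    rows = [{"step": "base", "added": None,
             "max_abs_change": 0.0, "direction": prev.direction_flag()}]
    for cand in candidate_factors:
        if isinstance(cand, str) and cand == "region":
            spec = replace(spec, spatial_field="region",
                           include_structured=True, include_unstructured=True)
            label = "region"
        elif isinstance(cand, FixedTerm):
            spec = replace(spec, fixed=list(spec.fixed) + [cand])
            label = cand.field
        else:
            raise TypeError(f"candidate must be FixedTerm or 'region', got {cand!r}")
        cur = fit_curve(spec, label)
        rows.append({
            "step": f"+{label}", "added": label,
            "max_abs_change": float(np.max(np.abs(cur.mean - prev.mean))),
            "direction": cur.direction_flag(),
        })
        prev = cur
    return pd.DataFrame(rows, columns=["step", "added", "max_abs_change", "direction"])


_CATEGORY_COLORS = {"negative": "#ffffff", "not_significant": "#9e9e9e",
                    "positive": "#000000"}


def export_choropleth(classification: list[SpatialClassification],
                      out_path: str | Path,
                      geometry: str | Path | None = None) -> Path:
    """Render the significance map, or fall back to a table.

    ``geometry`` is an optional GeoJSON file whose features carry a
    ``region`` property and polygon coordinates; its labels must cover
    every classified region.  Without geometry a CSV table is written and
    a warning issued (exit success).  Colors: white = negative effect,
    black = positive, grey = not significant.
    """
    out_path = Path(out_path)
    if geometry is None:
        warnings.warn("no geometry provided; writing tabular fallback",
                      stacklevel=2)
        table = pd.DataFrame([{
            "region": c.region, "por": c.total_effect_por, "ci_low": c.ci_low,
            "ci_high": c.ci_high, "category": c.category,
            "nominal_level": c.nominal_level} for c in classification])
        out_path = out_path.with_suffix(".csv")
        table.to_csv(out_path, index=False)
        return out_path

    import json as _json

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Polygon as MplPolygon

    geo = _json.loads(Path(geometry).read_text(encoding="utf-8"))
    shapes: dict[str, list] = {}
    for feat in geo.get("features", []):
        lab = feat.get("properties", {}).get("region")
        geom = feat.get("geometry", {})
        if geom.get("type") == "Polygon":
            polys = [geom["coordinates"]]
        elif geom.get("type") == "MultiPolygon":
            polys = geom["coordinates"]
        else:
            continue
        shapes[lab] = polys
    missing = sorted({c.region for c in classification} - set(shapes))
    if missing:
        raise ValueError(f"geometry missing regions: {missing}")

    fig, ax = plt.subplots(figsize=(7, 7))
    for c in classification:
        color = _CATEGORY_COLORS[c.category]
        for poly in shapes[c.region]:
            ax.add_patch(MplPolygon(np.asarray(poly[0]), closed=True,
                                    facecolor=color, edgecolor="#444444"))
    ax.autoscale_view()
    ax.set_aspect("equal")
    ax.set_axis_off()
    ax.set_title(f"Total residual spatial effect "
                 f"({classification[0].nominal_level:.0%} nominal level)")
    fig.savefig(out_path, bbox_inches="tight", dpi=150)
    plt.close(fig)
    return out_path
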