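"""Pipeline configuration: YAML schema, validation, normalized defaults.

``validate_config`` reports every schema deviation at once, each tagged
with a path-like key (e.g. ``mcmc.burn_in``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .model import FixedTerm, MCMCConfig, ModelSpec, SplineTerm
from .region_graph import (
    RegionGraph,
    read_gra,
    senegal_graph_2005,
)

__all__ = ["PipelineConfig", "ConfigError", "validate_config", "load_config"]


class ConfigError(ValueError):
    """Raised when a pipeline configuration is invalid; carries the full
    list of schema violations."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid configuration:\n  " + "\n  ".join(errors))


@dataclass
class PipelineConfig:
    seed: int
    output_dir: Path
    graph: RegionGraph
    splits: dict[str, list[str]] | None
    waves: list[int]
    data_paths: dict[int, Path]          # wave -> CSV (empty: simulate)
    clusters_per_region: int
    households_per_cluster: int
    model: ModelSpec
    mcmc: MCMCConfig
    nominal_level: float = 0.95
    curve_level: float = 0.80

    def graph_for_wave(self, wave: int):
        """Returns (graph, wave_region_map or None) for the given wave."""
        from .synthetic import split_region_map

        if wave == 1 or not self.splits:
            return self.graph, None
        g2, wmap = split_region_map(self.graph, self.splits)
        return g2, wmap


_DEFAULT_FIXED = [
    {"field": "urban", "reference": 1},
    {"field": "married", "reference": 0},
    {"field": "education", "reference": "higher"},
    {"field": "wealth", "reference": "richest"},
    {"field": "family_size", "reference": "large"},
    {"field": "ethnicity", "reference": "wolof"},
    {"field": "religion", "reference": "other"},
]


def validate_config(path: str | Path) -> PipelineConfig:
    """Parse and validate a YAML pipeline configuration.

    Fills defaults (21 households per cluster, 0.95/0.80 report levels,
    standard MCMC chain lengths) and raises :class:`ConfigError` listing
    every violation with its dotted key path.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        raise ConfigError([f"<file>: YAML parse error: {exc}"]) from exc
    if not isinstance(raw, dict):
        raise ConfigError(["<file>: top level must be a mapping"])

    errors: list[str] = []

    def req(key: str, typ, default=None, section=None):
        src = raw.get(section, {}) if section else raw
        full = f"{section}.{key}" if section else key
        if not isinstance(src, dict):
            errors.append(f"{section}: must be a mapping")
            return default
        val = src.get(key, default)
        if val is None:
            errors.append(f"{full}: missing required field")
            return default
        if typ is float and isinstance(val, int):
            val = float(val)
        if not isinstance(val, typ):
            errors.append(f"{full}: expected {getattr(typ, '__name__', typ)}, "
                          f"got {type(val).__name__}")
            return default
        return val

    seed = req("seed", int)
    output_dir = raw.get("output_dir", "output")
    graph_ref = raw.get("graph", "fixture11")

    graph = None
    splits = raw.get("splits")
    if graph_ref == "fixture11":
        graph = senegal_graph_2005()
        if splits is None:
            from .region_graph import SENEGAL_SPLITS_2008

            splits = SENEGAL_SPLITS_2008
    else:
        gp = Path(graph_ref)
        if not gp.exists():
            errors.append(f"graph: file {graph_ref!r} does not exist")
        else:
            graph = read_gra(gp)
    if splits is not None and not isinstance(splits, dict):
        errors.append("splits: expected a mapping of parent -> parts")
        splits = None

    waves = raw.get("waves", [1, 2])
    if not (isinstance(waves, list) and waves and all(w in (1, 2) for w in waves)):
        errors.append("waves: must be a non-empty list drawn from [1, 2]")
        waves = [1]

    data_paths: dict[int, Path] = {}
    for wave, key in ((1, "data_wave1"), (2, "data_wave2")):
        if key in raw:
            p = Path(raw[key])
            if not p.exists():
                errors.append(f"{key}: file {raw[key]!r} does not exist")
            else:
                data_paths[wave] = p

    design = raw.get("design", {}) or {}
    clusters = design.get("clusters_per_region", 34)
    households = design.get("households_per_cluster", 21)
    if not isinstance(clusters, int) or clusters < 1:
        errors.append("design.clusters_per_region: must be a positive integer")
        clusters = 1
    if not isinstance(households, int) or households < 1:
        errors.append("design.households_per_cluster: must be a positive integer")
        households = 21

    model_raw = raw.get("model", {}) or {}
    fixed_raw = model_raw.get("fixed", _DEFAULT_FIXED)
    fixed: list[FixedTerm] = []
    for i, t in enumerate(fixed_raw):
        if not isinstance(t, dict) or "field" not in t or "reference" not in t:
            errors.append(f"model.fixed[{i}]: needs 'field' and 'reference'")
            continue
        fixed.append(FixedTerm(field=t["field"], reference=t["reference"],
                               levels=tuple(t["levels"]) if t.get("levels") else None))
    nl_raw = model_raw.get("nonlinear",
                           [{"field": "age", "n_inner_knots": 20, "degree": 3}])
    nonlinear = []
    for i, t in enumerate(nl_raw):
        if not isinstance(t, dict) or "field" not in t:
            errors.append(f"model.nonlinear[{i}]: needs 'field'")
            continue
        nonlinear.append(SplineTerm(field=t["field"],
                                    n_inner_knots=int(t.get("n_inner_knots", 20)),
                                    degree=int(t.get("degree", 3))))
    try:
        model = ModelSpec(
            fixed=fixed, nonlinear=nonlinear,
            spatial_field=model_raw.get("spatial_field", "region"),
            include_structured=bool(model_raw.get("include_structured", True)),
            include_unstructured=bool(model_raw.get("include_unstructured", True)),
            hyper_a=float(model_raw.get("hyper_a", 0.001)),
            hyper_b=float(model_raw.get("hyper_b", 0.001)),
            link=model_raw.get("link", "logit"),
            cluster_field=model_raw.get("cluster_field"),
        )
    except ValueError as exc:
        errors.append(f"model: {exc}")
        model = None

    mcmc_raw = raw.get("mcmc", {}) or {}
    iterations = mcmc_raw.get("iterations", 12_000)
    burn_in = mcmc_raw.get("burn_in", 2_000)
    thin = mcmc_raw.get("thin", 10)
    mcmc = None
    if seed is not None:
        try:
            mcmc = MCMCConfig(seed=seed, iterations=int(iterations),
                              burn_in=int(burn_in), thin=int(thin),
                              init=mcmc_raw.get("init", "zeros"))
        except (ValueError, TypeError) as exc:
            errors.append(f"mcmc.burn_in: {exc}" if "burn_in" in str(exc)
                          else f"mcmc: {exc}")
    if isinstance(burn_in, int) and isinstance(iterations, int) and burn_in > iterations:
        if not any(e.startswith("mcmc") for e in errors):
            errors.append("mcmc.burn_in: burn_in must not exceed iterations")

    report = raw.get("report", {}) or {}
    nominal = float(report.get("nominal_level", 0.95))
    curve_level = float(report.get("curve_level", 0.80))
    for key, val in (("report.nominal_level", nominal),
                     ("report.curve_level", curve_level)):
        if not 0 < val < 1:
            errors.append(f"{key}: must lie in (0,1)")

    # unseen fixed-effect fields against the documented dataset schema
    from .synthetic import DATASET_COLUMNS

    for i, t in enumerate(fixed):
        if t.field not in DATASET_COLUMNS:
            errors.append(f"model.fixed[{i}].field: unknown covariate {t.field!r}")
    for i, t in enumerate(nonlinear):
        if t.field not in DATASET_COLUMNS:
            errors.append(f"model.nonlinear[{i}].field: unknown covariate {t.field!r}")

    if errors:
        raise ConfigError(sorted(set(errors)))
    return PipelineConfig(
        seed=seed, output_dir=Path(output_dir), graph=graph, splits=splits,
        waves=list(waves), data_paths=data_paths, clusters_per_region=clusters,
        households_per_cluster=households, model=model, mcmc=mcmc,
        nominal_level=nominal, curve_level=curve_level,
    )


load_config = validate_config
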