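"""End-to-end orchestration: simulate -> describe -> fit -> summarize ->
compare, with a JSON manifest of every artifact and its checksum."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .descriptive import prevalence_table
from .model import MCMCConfig, build_design, gibbs_fit
from .summarize import (
    classify_regions,
    curve_summary,
    fixed_effect_por,
    harmonize_waves,
    total_spatial_effect,
)
from .synthetic import (
    SurveyDesign,
    default_truth,
    read_dataset,
    simulate_survey,
    write_dataset,
    write_truth,
)

__all__ = ["run_pipeline"]

logger = logging.getLogger(__name__)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _StageError(RuntimeError):
    def __init__(self, stage: str, exc: Exception):
        super().__init__(f"stage {stage!r} failed: {exc}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline for every configured wave.

    Writes all artifacts under ``config.output_dir`` and returns the
    manifest (also written as ``manifest.json``).  Any stage failure
    aborts with a stage-tagged error; artifacts already written survive.
    """
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "spec_hash": config.model.hash(),
        "waves": config.waves,
        "stages": {},
    }

    region_prev: dict[int, pd.Series] = {}
    por_by_wave: dict[int, pd.Series] = {}
    wmap = None

    for wave in config.waves:
        tag = f"wave{wave}"
        graph, wmap_w = config.graph_for_wave(wave)
        if wave == 2:
            wmap = wmap_w

        # -- simulate or load ------------------------------------------
        t0 = time.time()
        try:
            if wave in config.data_paths:
                dataset = read_dataset(config.data_paths[wave], graph)
            else:
                truth = default_truth(config.graph, seed=config.seed)
                design = SurveyDesign(
                    clusters_per_region={l: config.clusters_per_region
                                         for l in graph.labels},
                    households_per_cluster=config.households_per_cluster,
                    urban_fraction={l: 0.35 + 0.3 * (i % 3) / 2
                                    for i, l in enumerate(graph.labels)},
                    wave_region_map=wmap_w,
                )
                dataset = simulate_survey(truth, design, graph, wave=wave,
                                          seed=config.seed + wave)
                data_path = out / f"{tag}_data.csv"
                write_dataset(dataset, data_path)
                write_truth(truth, out / f"{tag}_truth.json")
                artifacts += [data_path, out / f"{tag}_truth.json"]
        except Exception as exc:
            raise _StageError(f"{tag}.simulate", exc) from exc
        logger.info("%s simulate/load: %d records in %.1fs",
                    tag, len(dataset), time.time() - t0)

        # -- descriptive ----------------------------------------------
        t0 = time.time()
        try:
            prev = prevalence_table(dataset, by=["region"])
            prev_path = out / f"{tag}_prevalence_by_region.csv"
            prev.to_csv(prev_path, index=False)
            overall = prevalence_table(dataset)
            overall.to_csv(out / f"{tag}_prevalence_overall.csv", index=False)
            artifacts += [prev_path, out / f"{tag}_prevalence_overall.csv"]
            region_prev[wave] = prev.set_index("region")["percent"]
        except Exception as exc:
            raise _StageError(f"{tag}.descriptive", exc) from exc
        logger.info("%s descriptive in %.1fs", tag, time.time() - t0)

        # -- Bayesian fit ---------------------------------------------
        t0 = time.time()
        try:
            blocks = build_design(dataset, config.model, graph)
            if blocks.n_dropped:
                logger.info("%s fit: dropped %d rows with missing model fields",
                            tag, blocks.n_dropped)
            mcmc = MCMCConfig(seed=config.seed + 100 * wave,
                              iterations=config.mcmc.iterations,
                              burn_in=config.mcmc.burn_in,
                              thin=config.mcmc.thin, init=config.mcmc.init)
            samples = gibbs_fit(blocks, mcmc, config.model)
            sdir = out / f"{tag}_samples"
            samples.save(sdir)
            artifacts += [sdir / "draws.csv", sdir / "meta.json"]
        except Exception as exc:
            raise _StageError(f"{tag}.fit", exc) from exc
        logger.info("%s fit: %d draws in %.1fs", tag, samples.n_draws,
                    time.time() - t0)

        # -- summaries -------------------------------------------------
        t0 = time.time()
        try:
            refs = {t.field: str(t.reference) for t in config.model.fixed}
            por = fixed_effect_por(samples, level=config.nominal_level,
                                   references=refs)
            por_df = pd.DataFrame([{
                "term": e.term, "por": e.por, "ci_low": e.ci_low,
                "ci_high": e.ci_high, "level": e.level,
                "reference": e.is_reference} for e in por])
            por_path = out / f"{tag}_fixed_por.csv"
            por_df.to_csv(por_path, index=False)
            artifacts.append(por_path)

            if samples.f_str is not None or samples.f_unstr is not None:
                total = total_spatial_effect(samples)
                cls = classify_regions(total, samples.region_labels,
                                       nominal_level=config.nominal_level)
                cls_df = pd.DataFrame([{
                    "region": c.region, "por": c.total_effect_por,
                    "ci_low": c.ci_low, "ci_high": c.ci_high,
                    "category": c.category} for c in cls])
                cls_path = out / f"{tag}_spatial_classification.csv"
                cls_df.to_csv(cls_path, index=False)
                artifacts.append(cls_path)
                por_by_wave[wave] = cls_df.set_index("region")["por"]

            for term in config.model.nonlinear:
                meta = samples.spline_meta[term.field]
                grid = np.linspace(meta["lo"], meta["hi"], 50)
                cs = curve_summary(samples, term.field, grid,
                                   level=config.curve_level)
                curve_df = pd.DataFrame({
                    "grid": cs.grid, "mean": cs.mean,
                    "band_low": cs.band_low, "band_high": cs.band_high})
                cpath = out / f"{tag}_curve_{term.field}.csv"
                curve_df.to_csv(cpath, index=False)
                artifacts.append(cpath)
        except Exception as exc:
            raise _StageError(f"{tag}.summarize", exc) from exc
        logger.info("%s summarize in %.1fs", tag, time.time() - t0)
        manifest["stages"][tag] = {"n_records": len(dataset),
                                   "n_draws": samples.n_draws}

    # -- wave comparison ---------------------------------------------
    if set(config.waves) == {1, 2}:
        try:
            wmap_full = wmap or {l: [l] for l in config.graph.labels}
            comp = harmonize_waves(region_prev[1], region_prev[2], wmap_full)
            cpath = out / "wave_comparison_prevalence.csv"
            comp.to_csv(cpath, index=False)
            artifacts.append(cpath)
            if 1 in por_by_wave and 2 in por_by_wave:
                comp2 = harmonize_waves(por_by_wave[1], por_by_wave[2], wmap_full)
                p2 = out / "wave_comparison_spatial_por.csv"
                comp2.to_csv(p2, index=False)
                artifacts.append(p2)
        except Exception as exc:
            raise _StageError("compare", exc) from exc

    manifest["artifacts"] = {str(p.relative_to(out)): _sha256(p)
                             for p in artifacts}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1),
                                       encoding="utf-8")
    return manifest
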