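"""Container for MCMC draws, with plain-text persistence.

Draws are stored as a columnar CSV plus a JSON metadata sidecar (seed,
config, spec hash, spline ranges, region labels) so posterior summaries
can be recomputed without re-fitting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .design import bspline_design

__all__ = ["MCMCConfig", "PosteriorSamples"]


@dataclass(frozen=True)
class MCMCConfig:
    seed: int
    iterations: int = 12_000
    burn_in: int = 2_000
    thin: int = 10
    init: str = "zeros"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.burn_in > self.iterations:
            raise ValueError("burn_in must not exceed iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.init not in ("zeros", "mle-jitter"):
            raise ValueError(f"unknown init {self.init!r}")

    @property
    def n_stored(self) -> int:
        return (self.iterations - self.burn_in) // self.thin

    def to_dict(self) -> dict:
        return {"seed": self.seed, "iterations": self.iterations,
                "burn_in": self.burn_in, "thin": self.thin, "init": self.init}


@dataclass
class PosteriorSamples:
    """Stored MCMC draws for every model block.

    ``fixed`` has one column per fixed-effect design column (the leading
    column is the intercept); spline coefficients and spatial effects are
    centered draws satisfying their sum-to-zero constraints.
    """

    fixed: np.ndarray                      # (S, p)
    fixed_names: list[str]
    alpha: dict[str, np.ndarray]           # field -> (S, m)
    spline_meta: dict[str, dict]
    f_str: np.ndarray | None               # (S, R)
    f_unstr: np.ndarray | None
    region_labels: tuple[str, ...] | None
    tau2: dict[str, np.ndarray]
    seed: int = 0
    config: dict = field(default_factory=dict)
    spec_hash: str = ""
    link: str = "logit"

    @property
    def n_draws(self) -> int:
        return self.fixed.shape[0]

    @property
    def intercept(self) -> np.ndarray:
        return self.fixed[:, 0]

    def fixed_draws(self, name: str) -> np.ndarray:
        return self.fixed[:, self.fixed_names.index(name)]

    def curve_draws(self, field_name: str, grid: np.ndarray) -> np.ndarray:
        """Evaluate the centered spline effect on ``grid`` per draw -> (S, G).

        Raises if the grid leaves the fitted range (no extrapolation)."""
        if field_name not in self.alpha:
            raise KeyError(f"{field_name!r} was not fitted as a nonlinear term")
        meta = self.spline_meta[field_name]
        grid = np.asarray(grid, dtype=float)
        if grid.size and (grid.min() < meta["lo"] or grid.max() > meta["hi"]):
            raise ValueError(
                f"grid outside fitted range [{meta['lo']}, {meta['hi']}]")
        Bg = bspline_design(grid, meta["n_inner_knots"], meta["degree"],
                            lo=meta["lo"], hi=meta["hi"])
        return self.alpha[field_name] @ Bg.T

    # -- persistence -------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        cols: dict[str, np.ndarray] = {}
        for i, name in enumerate(self.fixed_names):
            cols[f"fixed:{name}"] = self.fixed[:, i]
        for f, arr in self.alpha.items():
            for j in range(arr.shape[1]):
                cols[f"alpha:{f}:{j}"] = arr[:, j]
        if self.f_str is not None:
            for j, lab in enumerate(self.region_labels):
                cols[f"fstr:{lab}"] = self.f_str[:, j]
        if self.f_unstr is not None:
            for j, lab in enumerate(self.region_labels):
                cols[f"funstr:{lab}"] = self.f_unstr[:, j]
        for name, arr in self.tau2.items():
            cols[f"tau2:{name}"] = arr
        pd.DataFrame(cols).to_csv(directory / "draws.csv", index=False)
        meta = {
            "fixed_names": self.fixed_names,
            "alpha_fields": {f: arr.shape[1] for f, arr in self.alpha.items()},
            "spline_meta": self.spline_meta,
            "region_labels": list(self.region_labels) if self.region_labels else None,
            "has_f_str": self.f_str is not None,
            "has_f_unstr": self.f_unstr is not None,
            "tau2_names": list(self.tau2),
            "seed": self.seed,
            "config": self.config,
            "spec_hash": self.spec_hash,
            "link": self.link,
        }
        (directory / "meta.json").write_text(json.dumps(meta, indent=1),
                                             encoding="utf-8")

    @classmethod
    def load(cls, directory: str | Path) -> "PosteriorSamples":
        directory = Path(directory)
        meta = json.loads((directory / "meta.json").read_text(encoding="utf-8"))
        df = pd.read_csv(directory / "draws.csv")
        fixed = np.column_stack(
            [df[f"fixed:{n}"].to_numpy() for n in meta["fixed_names"]]
        ) if len(df) else np.empty((0, len(meta["fixed_names"])))
        alpha = {}
        for f, m in meta["alpha_fields"].items():
            alpha[f] = (np.column_stack(
                [df[f"alpha:{f}:{j}"].to_numpy() for j in range(m)])
                if len(df) else np.empty((0, m)))
        labels = tuple(meta["region_labels"]) if meta["region_labels"] else None
        f_str = f_unstr = None
        if meta["has_f_str"]:
            f_str = (np.column_stack([df[f"fstr:{l}"].to_numpy() for l in labels])
                     if len(df) else np.empty((0, len(labels))))
        if meta["has_f_unstr"]:
            f_unstr = (np.column_stack([df[f"funstr:{l}"].to_numpy() for l in labels])
                       if len(df) else np.empty((0, len(labels))))
        tau2 = {n: df[f"tau2:{n}"].to_numpy() if len(df) else np.empty(0)
                for n in meta["tau2_names"]}
        return cls(fixed=fixed, fixed_names=meta["fixed_names"], alpha=alpha,
                   spline_meta=meta["spline_meta"], f_str=f_str, f_unstr=f_unstr,
                   region_labels=labels, tau2=tau2, seed=meta["seed"],
                   config=meta["config"], spec_hash=meta["spec_hash"],
                   link=meta.get("link", "logit"))
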