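"""Data-augmentation Gibbs sampler for the geo-additive binary model.

For the logit link each iteration draws Polya-Gamma latent precisions and
then conjugate Gaussian block updates for the fixed effects, each spline
coefficient vector, the structured (intrinsic-CAR) and unstructured
region effects, followed by inverse-gamma updates for every variance
component.  The probit link swaps the PG step for Albert-Chib truncated
normal latents.  After every iteration each penalized block is re-centered
to its sum-to-zero constraint, with the removed mean absorbed into the
intercept.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.special import ndtr, ndtri

from .design import DesignBlocks, ModelSpec
from .polya_gamma import polya_gamma
from .samples import MCMCConfig, PosteriorSamples

__all__ = ["gibbs_fit", "posterior_predictive_prevalence"]

_TAU2_DIVERGE = 1e8


def _draw_gaussian_block(prec: np.ndarray, rhs: np.ndarray,
                         rng: np.random.Generator) -> np.ndarray:
    """Sample from N(prec^-1 rhs, prec^-1) via a Cholesky factor."""
    try:
        c, lower = cho_factor(prec, lower=True)
    except np.linalg.LinAlgError:
        prec = prec + 1e-8 * np.eye(prec.shape[0])
        c, lower = cho_factor(prec, lower=True)
    mean = cho_solve((c, lower), rhs)
    z = rng.standard_normal(prec.shape[0])
    return mean + solve_triangular(c, z, lower=True, trans="T")


def _truncnorm_latent(eta: np.ndarray, y: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    """Albert-Chib latent draw: N(eta,1) truncated positive where y=1,
    negative where y=0 (inverse-cdf, clipped for stability)."""
    u = rng.random(eta.shape[0])
    lo_cdf = np.where(y == 1.0, ndtr(-eta), 0.0)
    hi_cdf = np.where(y == 1.0, 1.0, ndtr(-eta))
    p = np.clip(lo_cdf + u * (hi_cdf - lo_cdf), 1e-12, 1 - 1e-12)
    return eta + ndtri(p)


def _mle_jitter_init(W: np.ndarray, y: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
    """A few IRLS steps for the fixed block, plus small jitter."""
    beta = np.zeros(W.shape[1])
    for _ in range(8):
        eta = W @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(p * (1 - p), 1e-6, None)
        z = eta + (y - p) / w
        WtW = (W * w[:, None]).T @ W + 1e-8 * np.eye(W.shape[1])
        beta = np.linalg.solve(WtW, (W * w[:, None]).T @ z)
    return beta + 0.1 * rng.standard_normal(W.shape[1])


def gibbs_fit(blocks: DesignBlocks, config: MCMCConfig,
              spec: ModelSpec) -> PosteriorSamples:
    """Run the Gibbs sampler and return thinned post-burn-in draws.

    Reproducible from ``config.seed``; aborts with a diagnostic if any
    variance component diverges past 1e8.
    """
    y = np.asarray(blocks.y, dtype=np.float64)
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("outcome vector must be binary 0/1")
    n, p = blocks.W.shape
    rng = np.random.default_rng(config.seed)
    logit = spec.link == "logit"
    kappa = y - 0.5

    W = blocks.W
    P0 = np.eye(p) / spec.fixed_prior_var
    beta = (_mle_jitter_init(W, y, rng) if config.init == "mle-jitter"
            else np.zeros(p))

    spline_fields = list(blocks.B)
    alpha = {f: np.zeros(blocks.B[f].shape[1]) for f in spline_fields}
    tau2_spline = {f: 0.1 for f in spline_fields}

    has_str = blocks.Q is not None and spec.include_structured
    has_unstr = blocks.region_index is not None and spec.include_unstructured
    R = len(blocks.region_labels) if blocks.region_labels else 0
    ridx = blocks.region_index
    f_str = np.zeros(R)
    f_unstr = np.zeros(R)
    tau2_str, tau2_unstr = 0.1, 0.1
    Qmat = blocks.Q.entries.astype(float) if has_str else None
    Qrank = blocks.Q.rank if has_str else 0
    comps = blocks.components or []
    if ridx is not None:
        region_counts = np.bincount(ridx, minlength=R).astype(float)
    comp_obs_weight = None
    if comps and ridx is not None:
        comp_obs_weight = [region_counts[idx].sum() / max(1.0, n) for idx in comps]

    has_cluster = blocks.cluster_index is not None
    cidx = blocks.cluster_index
    C = blocks.n_clusters
    f_cluster = np.zeros(C)
    tau2_cluster = 0.1

    a0, b0 = spec.hyper_a, spec.hyper_b

    S = config.n_stored
    store_fixed = np.empty((S, p))
    store_alpha = {f: np.empty((S, blocks.B[f].shape[1])) for f in spline_fields}
    store_fstr = np.empty((S, R)) if has_str else None
    store_funstr = np.empty((S, R)) if has_unstr else None
    store_tau2: dict[str, np.ndarray] = {}
    if has_str:
        store_tau2["structured"] = np.empty(S)
    if has_unstr:
        store_tau2["unstructured"] = np.empty(S)
    for f in spline_fields:
        store_tau2[f"spline:{f}"] = np.empty(S)
    if has_cluster:
        store_tau2["cluster"] = np.empty(S)

    def eta_full() -> np.ndarray:
        eta = W @ beta
        for f in spline_fields:
            eta += blocks.B[f] @ alpha[f]
        if has_str:
            eta += f_str[ridx]
        if has_unstr:
            eta += f_unstr[ridx]
        if has_cluster:
            eta += f_cluster[cidx]
        return eta

    def inv_gamma(shape: float, rate: float) -> float:
        return rate / rng.gamma(shape)

    stored = 0
    for it in range(config.iterations):
        eta = eta_full()
        if logit:
            omega = polya_gamma(eta, int(rng.integers(1, 2**31 - 1)))
            zed = kappa
        else:
            omega = np.ones(n)
            zed = _truncnorm_latent(eta, y, rng)

        # fixed effects (incl. intercept)
        eta_rest = eta - W @ beta
        rhs = W.T @ (zed - omega * eta_rest)
        prec = (W * omega[:, None]).T @ W + P0
        beta = _draw_gaussian_block(prec, rhs, rng)
        eta = eta_rest + W @ beta

        # spline blocks
        for f in spline_fields:
            B = blocks.B[f]
            eta_rest = eta - B @ alpha[f]
            rhs = B.T @ (zed - omega * eta_rest)
            prec = (B * omega[:, None]).T @ B + blocks.K[f] / tau2_spline[f]
            alpha[f] = _draw_gaussian_block(prec, rhs, rng)
            eta = eta_rest + B @ alpha[f]

        # structured spatial block
        if has_str:
            eta_rest = eta - f_str[ridx]
            rhs = np.bincount(ridx, weights=zed - omega * eta_rest, minlength=R)
            prec = np.diag(np.bincount(ridx, weights=omega, minlength=R))
            prec += Qmat / tau2_str
            f_str = _draw_gaussian_block(prec, rhs, rng)
            eta = eta_rest + f_str[ridx]

        # unstructured spatial block
        if has_unstr:
            eta_rest = eta - f_unstr[ridx]
            rhs = np.bincount(ridx, weights=zed - omega * eta_rest, minlength=R)
            d = np.bincount(ridx, weights=omega, minlength=R) + 1.0 / tau2_unstr
            mean = rhs / d
            f_unstr = mean + rng.standard_normal(R) / np.sqrt(d)
            eta = eta_rest + f_unstr[ridx]

        # optional i.i.d. cluster intercepts
        if has_cluster:
            eta_rest = eta - f_cluster[cidx]
            rhs = np.bincount(cidx, weights=zed - omega * eta_rest, minlength=C)
            d = np.bincount(cidx, weights=omega, minlength=C) + 1.0 / tau2_cluster
            f_cluster = rhs / d + rng.standard_normal(C) / np.sqrt(d)

        # variance components
        if has_str:
            tau2_str = inv_gamma(a0 + 0.5 * Qrank, b0 + 0.5 * f_str @ Qmat @ f_str)
        if has_unstr:
            tau2_unstr = inv_gamma(a0 + 0.5 * R, b0 + 0.5 * f_unstr @ f_unstr)
        for f in spline_fields:
            K = blocks.K[f]
            m = K.shape[0]
            tau2_spline[f] = inv_gamma(a0 + 0.5 * (m - 2),
                                       b0 + 0.5 * alpha[f] @ K @ alpha[f])
        if has_cluster:
            tau2_cluster = inv_gamma(a0 + 0.5 * C, b0 + 0.5 * f_cluster @ f_cluster)
        all_tau2 = [tau2_str, tau2_unstr, tau2_cluster] + list(tau2_spline.values())
        if max(all_tau2) > _TAU2_DIVERGE:
            raise RuntimeError(
                f"variance component diverged (>{_TAU2_DIVERGE:g}) at iteration "
                f"{it}: str={tau2_str:.3g} unstr={tau2_unstr:.3g} "
                f"spline={ {f: round(v, 3) for f, v in tau2_spline.items()} }")

        # re-center penalized blocks; absorb removed means into intercept
        for f in spline_fields:
            m = float(np.mean(blocks.B[f] @ alpha[f]))
            alpha[f] = alpha[f] - m   # basis rows sum to 1
            beta[0] += m
        if has_str:
            shift = 0.0
            for ci, idx in enumerate(comps):
                mc = float(f_str[idx].mean())
                f_str[idx] -= mc
                shift += mc * comp_obs_weight[ci]
            beta[0] += shift
        if has_unstr:
            shift = 0.0
            for ci, idx in enumerate(comps) if comps else []:
                mc = float(f_unstr[idx].mean())
                f_unstr[idx] -= mc
                shift += mc * comp_obs_weight[ci]
            if not comps:
                mc = float(f_unstr.mean())
                f_unstr -= mc
                shift = mc
            beta[0] += shift
        if has_cluster:
            mc = float(f_cluster.mean())
            f_cluster -= mc
            beta[0] += mc

        # store
        if it >= config.burn_in and (it - config.burn_in) % config.thin == config.thin - 1:
            if stored < S:
                store_fixed[stored] = beta
                for f in spline_fields:
                    store_alpha[f][stored] = alpha[f]
                if has_str:
                    store_fstr[stored] = f_str
                    store_tau2["structured"][stored] = tau2_str
                if has_unstr:
                    store_funstr[stored] = f_unstr
                    store_tau2["unstructured"][stored] = tau2_unstr
                for f in spline_fields:
                    store_tau2[f"spline:{f}"][stored] = tau2_spline[f]
                if has_cluster:
                    store_tau2["cluster"][stored] = tau2_cluster
                stored += 1

    return PosteriorSamples(
        fixed=store_fixed[:stored],
        fixed_names=list(blocks.W_names),
        alpha={f: store_alpha[f][:stored] for f in spline_fields},
        spline_meta=dict(blocks.spline_meta),
        f_str=store_fstr[:stored] if has_str else None,
        f_unstr=store_funstr[:stored] if has_unstr else None,
        region_labels=blocks.region_labels,
        tau2={k: v[:stored] for k, v in store_tau2.items()},
        seed=config.seed,
        config=config.to_dict(),
        spec_hash=spec.hash(),
        link=spec.link,
    )


def posterior_predictive_prevalence(samples: PosteriorSamples,
                                    blocks: DesignBlocks) -> dict:
    """Per-region predicted prevalence draws: for every stored draw, the
    mean fitted probability among that region's respondents.

    Returns ``{"labels": ..., "draws": (S, R) array}``; with no spatial
    block the single key "overall" is used.
    """
    if samples.n_draws == 0:
        raise ValueError("no stored draws")
    S = samples.n_draws
    eta = np.tile(blocks.W @ samples.fixed.T, 1)           # (n, S)
    for f, arr in samples.alpha.items():
        eta += blocks.B[f] @ arr.T
    if samples.f_str is not None:
        eta += samples.f_str.T[blocks.region_index]
    if samples.f_unstr is not None:
        eta += samples.f_unstr.T[blocks.region_index]
    if samples.link == "logit":
        prob = 1.0 / (1.0 + np.exp(-eta))
    else:
        prob = ndtr(eta)
    if blocks.region_index is None:
        return {"labels": ("overall",), "draws": prob.mean(axis=0)[None, :].T}
    R = len(blocks.region_labels)
    draws = np.empty((S, R))
    for r in range(R):
        mask = blocks.region_index == r
        draws[:, r] = prob[mask].mean(axis=0) if mask.any() else np.nan
    return {"labels": blocks.region_labels, "draws": draws}
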