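"""Probe filtering, BMIQ type-II normalization and batch adjustment.

``filter_probes`` subsets the matrix to autosomal, non-blacklisted,
well-detected probes. ``bmiq_normalize`` removes the type II chemistry's
compressed dynamic range by fitting a three-state beta mixture to each
probe design separately and quantile-mapping the type II distribution
onto the type I one. ``combat_adjust`` removes batch location/scale
effects on the logit (M-value-like) scale with parametric empirical-
Bayes shrinkage across probes, protecting biological group covariates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import beta as beta_dist

from .containers import BetaMatrix, ProbeAnnotation, ValidationError

logger = logging.getLogger(__name__)

#: betas exactly 0 or 1 are clamped to [EPS, 1-EPS] before logit
EPS = 1e-3


def _logit(x: np.ndarray) -> np.ndarray:
    return logit(np.clip(x, EPS, 1 - EPS))


# ---------------------------------------------------------------------------
# Probe filtering
# ---------------------------------------------------------------------------

@dataclass
class FilterSpec:
    """Criteria applied by :func:`filter_probes`.

    The cross-reactive / SNP-overlapping blacklist is a user-supplied
    probe-id set, not a built-in.
    """

    drop_non_autosomal: bool = True
    blacklist: Set[str] = field(default_factory=set)
    max_missing_fraction: float = 1.0
    detection_mask_required: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.max_missing_fraction <= 1:
            raise ValidationError("max_missing_fraction must lie in [0, 1]")


def filter_probes(
    beta: BetaMatrix, ann: ProbeAnnotation, spec: FilterSpec
) -> BetaMatrix:
    """Return the row subset passing all criteria, order preserved."""
    missing_ann = beta.probe_ids.difference(ann.probe_ids)
    if len(missing_ann):
        raise ValidationError(
            f"probe(s) without annotation: {list(missing_ann[:5])}"
        )
    ann = ann.subset(beta.probe_ids)
    keep = pd.Series(True, index=beta.probe_ids)
    counts = {}
    if spec.drop_non_autosomal:
        autosomal = ann.table["chromosome"].isin([str(i) for i in range(1, 23)])
        counts["non_autosomal"] = int((~autosomal & keep).sum())
        keep &= autosomal
    if spec.blacklist:
        black = beta.probe_ids.isin(spec.blacklist)
        counts["blacklisted"] = int((pd.Series(black, index=keep.index) & keep).sum())
        keep &= ~black
    values = beta.values
    miss = values.isna()
    if spec.detection_mask_required and beta.mask is not None:
        miss = miss | ~beta.mask
    frac_missing = miss.mean(axis=1)
    too_missing = frac_missing > spec.max_missing_fraction
    counts["missing"] = int((too_missing & keep).sum())
    keep &= ~too_missing
    logger.info(
        "filter_probes: %d -> %d probes (removed: %s)",
        len(keep), int(keep.sum()),
        ", ".join(f"{k}={v}" for k, v in counts.items()) or "none",
    )
    kept = keep.index[keep]
    mask = beta.mask.loc[kept] if beta.mask is not None else None
    return BetaMatrix(values.loc[kept], mask)


# ---------------------------------------------------------------------------
# BMIQ: beta-mixture quantile dilation
# ---------------------------------------------------------------------------

class EMError(RuntimeError):
    """Raised when the beta-mixture EM fails to converge."""


def _beta_params_from_moments(m: np.ndarray, v: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    m = np.clip(m, 1e-4, 1 - 1e-4)
    v = np.minimum(v, m * (1 - m) * 0.999)
    v = np.maximum(v, 1e-6)
    common = m * (1 - m) / v - 1
    return m * common, (1 - m) * common


def fit_beta_mixture(
    x: np.ndarray,
    n_states: int = 3,
    tol: float = 1e-4,
    max_iter: int = 500,
) -> Dict[str, np.ndarray]:
    """Fit an ``n_states`` beta mixture by EM with moment-matching M-steps.

    Initialization is deterministic, from fixed quantiles of the data.
    Returns dict with keys a, b, w (each length ``n_states``, states
    ordered by increasing mean) and the final log-likelihood ``ll``.
    Raises :class:`EMError` on non-convergence.
    """
    from scipy.special import betaln

    x = np.asarray(x, dtype=float)
    x = np.clip(x[~np.isnan(x)], 1e-4, 1 - 1e-4)
    qs = np.linspace(0.5 / n_states, 1 - 0.5 / n_states, n_states)
    centers = np.quantile(x, qs)
    # initial hard assignment to the nearest center
    resp = np.zeros((len(x), n_states))
    resp[np.arange(len(x)), np.argmin(np.abs(x[:, None] - centers[None, :]), axis=1)] = 1.0

    log_x = np.log(x)[:, None]
    log_1mx = np.log1p(-x)[:, None]
    ll_old = -np.inf
    a = np.ones(n_states)
    b = np.ones(n_states)
    w = np.full(n_states, 1.0 / n_states)
    for it in range(max_iter):
        # M step: weighted moment matching per component
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-10)
        m = (resp * x[:, None]).sum(axis=0) / nk
        v = (resp * (x[:, None] - m[None, :]) ** 2).sum(axis=0) / nk
        a, b = _beta_params_from_moments(m, v)
        w = nk / nk.sum()
        # E step (beta log-density written out with precomputed log terms)
        logpdf = (
            (a[None, :] - 1) * log_x
            + (b[None, :] - 1) * log_1mx
            - betaln(a, b)[None, :]
            + np.log(w[None, :])
        )
        mx = logpdf.max(axis=1, keepdims=True)
        dens = np.exp(logpdf - mx)
        tot = dens.sum(axis=1, keepdims=True)
        resp = dens / tot
        ll = float((np.log(tot[:, 0]) + mx[:, 0]).sum())
        # tolerance applies per observation so it is size-independent
        if abs(ll - ll_old) < tol * len(x):
            order = np.argsort(a / (a + b))
            return {"a": a[order], "b": b[order], "w": w[order], "ll": ll, "iters": it + 1}
        ll_old = ll
    raise EMError(f"beta-mixture EM did not converge after {max_iter} iterations (ll={ll_old:.3f})")


def _classify(x: np.ndarray, fit: Dict[str, np.ndarray]) -> np.ndarray:
    """Hard state assignment (0=U, 1=H, 2=M) under a fitted mixture."""
    xc = np.clip(x, 1e-4, 1 - 1e-4)
    logpdf = beta_dist.logpdf(xc[:, None], fit["a"][None, :], fit["b"][None, :]) + np.log(
        fit["w"][None, :]
    )
    return np.argmax(logpdf, axis=1)


def _bmiq_sample(
    values: np.ndarray, is_type2: np.ndarray, tol: float, max_iter: int, sample_id: str
) -> np.ndarray:
    x1 = values[~is_type2]
    x2 = values[is_type2]
    try:
        fit1 = fit_beta_mixture(x1, tol=tol, max_iter=max_iter)
        fit2 = fit_beta_mixture(x2, tol=tol, max_iter=max_iter)
    except EMError as exc:
        raise EMError(f"sample {sample_id!r}: {exc}") from exc

    states2 = _classify(x2, fit2)
    out2 = np.clip(x2.copy(), 1e-4, 1 - 1e-4)

    # unmethylated state: quantile map type II U -> type I U
    u_mask = states2 == 0
    if u_mask.any():
        p = beta_dist.cdf(out2[u_mask], fit2["a"][0], fit2["b"][0])
        out2[u_mask] = beta_dist.ppf(np.clip(p, 1e-12, 1 - 1e-12), fit1["a"][0], fit1["b"][0])

    # methylated state: quantile map upper tails
    m_mask = states2 == 2
    if m_mask.any():
        p = beta_dist.sf(out2[m_mask], fit2["a"][2], fit2["b"][2])
        out2[m_mask] = beta_dist.isf(np.clip(p, 1e-12, 1 - 1e-12), fit1["a"][2], fit1["b"][2])

    # hemimethylated state: dilation between the transformed U max and M min
    h_mask = states2 == 1
    if h_mask.any():
        old = x2[h_mask]
        lo_old, hi_old = old.min(), old.max()
        lo_new = out2[u_mask].max() if u_mask.any() else lo_old
        hi_new = out2[m_mask].min() if m_mask.any() else hi_old
        if hi_old > lo_old and hi_new > lo_new:
            out2[h_mask] = lo_new + (old - lo_old) * (hi_new - lo_new) / (hi_old - lo_old)

    result = values.copy()
    result[is_type2] = np.clip(out2, 0.0, 1.0)
    return result


def bmiq_normalize(
    beta: BetaMatrix,
    ann: ProbeAnnotation,
    tol: float = 1e-4,
    max_iter: int = 500,
) -> BetaMatrix:
    """Map type II probe values onto the type I scale, per sample.

    Fits a three-state (unmethylated / hemimethylated / methylated) beta
    mixture by EM separately to the type I and type II probes of each
    sample; type II U- and M-state probes are carried through beta
    quantile functions onto the type I mixture and hemimethylated probes
    are rescaled by the dilation transform. Type I probes pass through
    unchanged. With no type II (or no type I) probes the matrix is
    returned unchanged.
    """
    ann = ann.subset(beta.probe_ids)
    is_type2 = (ann.table["design_type"] == "II").to_numpy()
    if not is_type2.any() or is_type2.all():
        return BetaMatrix(beta.values.copy(), beta.mask)
    out = beta.values.to_numpy().copy()
    for j, sid in enumerate(beta.sample_ids):
        out[:, j] = _bmiq_sample(out[:, j], is_type2, tol, max_iter, sid)
    return BetaMatrix(
        pd.DataFrame(out, index=beta.probe_ids, columns=beta.sample_ids), beta.mask
    )


# ---------------------------------------------------------------------------
# ComBat-style batch adjustment
# ---------------------------------------------------------------------------

@dataclass
class BatchModel:
    """Fitted per-batch location/scale adjustments (logit scale)."""

    batches: Sequence[str]
    gamma_star: pd.DataFrame  # probes x batches, location
    delta_star: pd.DataFrame  # probes x batches, scale (variance, > 0)
    prior: Dict[str, np.ndarray]


def _postmean(g_hat, g_bar, n, d_star, t2):
    return (t2 * n * g_hat + d_star * g_bar) / (t2 * n + d_star)


def _postvar(sum2, n, a, b):
    return (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)


def _it_sol(sdat, g_hat, d_hat, g_bar, t2, a, b, conv=1e-4, max_iter=500):
    """Iterative EB solution for one batch (location gamma, scale delta)."""
    n = (~np.isnan(sdat)).sum(axis=1).astype(float)
    g_old, d_old = g_hat.copy(), d_hat.copy()
    for _ in range(max_iter):
        g_new = _postmean(g_hat, g_bar, n, d_old, t2)
        sum2 = np.nansum((sdat - g_new[:, None]) ** 2, axis=1)
        d_new = _postvar(sum2, n, a, b)
        change = max(
            np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)),
            np.max(np.abs(d_new - d_old) / np.maximum(np.abs(d_old), 1e-12)),
        )
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    return g_old, d_old


def combat_adjust(
    beta: BetaMatrix,
    batches: Sequence[str],
    covariates: Optional[Sequence[str]] = None,
) -> BetaMatrix:
    """Remove batch location/scale effects with parametric EB shrinkage.

    Values are logit-transformed, per-probe batch effects are estimated
    within a standardization design that retains protected biological
    covariates, shrunk via parametric empirical-Bayes priors across
    probes, removed, and back-transformed. A single batch is a no-op.
    """
    batches = pd.Series(list(batches), index=beta.sample_ids, dtype=str)
    levels = batches.unique().tolist()
    if len(levels) == 1:
        return BetaMatrix(beta.values.copy(), beta.mask)
    sizes = batches.value_counts()
    if (sizes < 2).any():
        small = sizes.index[sizes < 2].tolist()
        raise ValidationError(f"batch(es) with a single sample: {small}")

    design_cols = [(batches == lv).to_numpy(float) for lv in levels]
    X_batch = np.column_stack(design_cols)
    X_cov = np.empty((len(batches), 0))
    if covariates is not None:
        cov = pd.Series(list(covariates), index=beta.sample_ids, dtype=str)
        cov_levels = cov.unique().tolist()
        for lv in cov_levels[1:]:  # drop first level (absorbed in batch means)
            X_cov = np.column_stack([X_cov, (cov == lv).to_numpy(float)])
        # confounding check: covariate must vary within the batch design
        X_full = np.column_stack([X_batch, X_cov])
        if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
            raise ValidationError(
                "batch is perfectly confounded with a protected covariate"
            )

    Y = _logit(beta.values.to_numpy())  # probes x samples
    X = np.column_stack([X_batch, X_cov])
    B_hat, *_ = np.linalg.lstsq(X, Y.T, rcond=None)  # params x probes

    n_batches = len(levels)
    n_array = sizes.reindex(levels).to_numpy(float)
    grand_mean = (n_array / n_array.sum()) @ B_hat[:n_batches]
    stand_mean = np.tile(grand_mean[:, None], (1, Y.shape[1]))
    if X_cov.shape[1]:
        stand_mean = stand_mean + (X_cov @ B_hat[n_batches:]).T

    resid = Y - (X @ B_hat).T
    var_pooled = (resid**2).mean(axis=1)
    var_pooled = np.maximum(var_pooled, 1e-12)
    sd = np.sqrt(var_pooled)[:, None]
    Z = (Y - stand_mean) / sd

    gamma_hat = np.column_stack(
        [Z[:, (batches == lv).to_numpy()].mean(axis=1) for lv in levels]
    )
    delta_hat = np.column_stack(
        [Z[:, (batches == lv).to_numpy()].var(axis=1, ddof=1) for lv in levels]
    )

    gamma_bar = gamma_hat.mean(axis=0)
    t2 = gamma_hat.var(axis=0, ddof=1)
    # inverse-gamma prior on delta^2, moments method
    d_mean = delta_hat.mean(axis=0)
    d_var = delta_hat.var(axis=0, ddof=1)
    a_prior = (2 * d_var + d_mean**2) / np.maximum(d_var, 1e-12)
    b_prior = (d_mean * d_var + d_mean**3) / np.maximum(d_var, 1e-12)

    gamma_star = np.empty_like(gamma_hat)
    delta_star = np.empty_like(delta_hat)
    Z_adj = Z.copy()
    for k, lv in enumerate(levels):
        sel = (batches == lv).to_numpy()
        g, d = _it_sol(
            Z[:, sel], gamma_hat[:, k], delta_hat[:, k],
            gamma_bar[k], t2[k], a_prior[k], b_prior[k],
        )
        gamma_star[:, k], delta_star[:, k] = g, np.maximum(d, 1e-12)
        Z_adj[:, sel] = (Z[:, sel] - g[:, None]) / np.sqrt(delta_star[:, k])[:, None]

    Y_adj = Z_adj * sd + stand_mean
    out = expit(Y_adj)
    return BetaMatrix(
        pd.DataFrame(out, index=beta.probe_ids, columns=beta.sample_ids), beta.mask
    )
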