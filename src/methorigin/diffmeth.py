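"""Per-CpG two-group differential methylation with moderated variance.

Each probe gets a two-sample comparison of beta values in which the
residual variance is replaced by its empirical-Bayes posterior: a scaled
inverse-chi-square prior is fitted across all probes by matching moments
of log sample variances, the per-probe variance is shrunk toward the
prior value, and the t statistic is referred to a t distribution with
prior-augmented degrees of freedom. This is the standard small-n
moderation that makes two-versus-two comparisons usable. Tests run on
beta values, so the effect-size gate (|delta beta|) and the test operate
on the same scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma
from scipy.stats import t as t_dist
from statsmodels.stats.multitest import multipletests

from .containers import BetaMatrix, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class DMParams:
    """Selection thresholds; inequalities are strict."""

    p_threshold: float = 0.001
    db_threshold: float = 0.2
    moderation: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.p_threshold < 1 or not 0 < self.db_threshold < 1:
            raise ValidationError("thresholds must lie in (0, 1)")


def _trigamma_inverse(x: np.ndarray) -> np.ndarray:
    """Solve trigamma(y) = x by Newton iteration."""
    x = np.asarray(x, dtype=float)
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = polygamma(1, y)
        dif = tri * (1.0 - tri / x) / polygamma(2, y)
        y = y + dif
        if np.max(-dif / y) < 1e-8:
            break
    return y


def fit_variance_prior(s2: np.ndarray, df: float) -> Tuple[float, float]:
    """Moments fit of the scaled inverse-chi-square variance prior.

    Returns (d0, s0_squared): prior degrees of freedom (may be inf) and
    prior variance, from the distribution of log sample variances.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(np.exp(np.mean(np.log(s2[ok])))) if ok.any() else 0.0
    z = np.log(s2[ok])
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    n = len(e)
    e_var = ((e - e_mean) ** 2).sum() / (n - 1)
    e_var = e_var - polygamma(1, df / 2.0)
    if e_var > 0:
        d0 = 2.0 * float(_trigamma_inverse(np.array([e_var]))[0])
        s0_sq = float(np.exp(e_mean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(np.exp(e_mean))
    return d0, s0_sq


def fit_probe_models(
    beta: BetaMatrix,
    groups: Sequence[str],
    moderation: bool = True,
) -> pd.DataFrame:
    """Moderated two-group t test per probe.

    ``groups`` assigns each sample to one of exactly two levels.
    Returns a DataFrame indexed by probe id with columns
    ``mean_<level>``, ``delta_beta`` (first level minus second in
    sorted level order, so relabelling samples negates it), ``t_stat``,
    ``p_value``, ``adj_p``. Probes with fewer than 2 non-missing values
    in either group are dropped with a logged count.
    """
    groups = pd.Series(list(groups), index=beta.sample_ids, dtype=str)
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValidationError(f"expected exactly two group levels, got {levels}")
    g1, g2 = levels
    Y = beta.values.to_numpy()
    m1 = (groups == g1).to_numpy()
    m2 = (groups == g2).to_numpy()
    if m1.sum() < 2 or m2.sum() < 2:
        raise ValidationError("each group needs at least 2 samples")

    n1 = (~np.isnan(Y[:, m1])).sum(axis=1)
    n2 = (~np.isnan(Y[:, m2])).sum(axis=1)
    usable = (n1 >= 2) & (n2 >= 2)
    n_drop = int((~usable).sum())
    if n_drop:
        logger.info("fit_probe_models: dropped %d probe(s) with <2 values per group", n_drop)
    probes = beta.probe_ids[usable]
    Y = Y[usable]
    n1, n2 = n1[usable].astype(float), n2[usable].astype(float)

    with np.errstate(invalid="ignore"):
        mean1 = np.nanmean(Y[:, m1], axis=1)
        mean2 = np.nanmean(Y[:, m2], axis=1)
        var1 = np.nanvar(Y[:, m1], axis=1, ddof=1)
        var2 = np.nanvar(Y[:, m2], axis=1, ddof=1)
    df_resid = n1 + n2 - 2
    s2 = ((n1 - 1) * var1 + (n2 - 1) * var2) / df_resid
    delta = mean1 - mean2

    if moderation and len(probes) > 1:
        d0, s0_sq = fit_variance_prior(s2, float(np.median(df_resid)))
        if np.isfinite(d0):
            s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
            df_total = df_resid + d0
        else:
            s2_post = np.full_like(s2, s0_sq)
            df_total = np.full_like(s2, np.inf)
    else:
        if moderation:
            logger.warning("single-probe input: moderation degenerates to ordinary t")
        s2_post = s2
        df_total = df_resid

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = delta / se
    with np.errstate(invalid="ignore"):
        t_stat = np.where(
            se == 0, np.where(delta == 0, 0.0, np.inf * np.sign(delta)), t_stat
        )
    finite_df = np.where(np.isfinite(df_total), df_total, 1e12)
    p = 2.0 * t_dist.sf(np.abs(t_stat), finite_df)
    p = np.clip(p, 0.0, 1.0)
    adj_p = benjamini_hochberg(p)

    return pd.DataFrame(
        {
            f"mean_{g1}": mean1,
            f"mean_{g2}": mean2,
            "delta_beta": delta,
            "t_stat": t_stat,
            "p_value": p,
            "adj_p": adj_p,
        },
        index=pd.Index(probes, name="probe_id"),
    )


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p values (step-up FDR)."""
    return multipletests(np.asarray(p, dtype=float), method="fdr_bh")[1]


def select_dm_sites(result: pd.DataFrame, params: DMParams = DMParams()) -> List[str]:
    """Probes with adj_p < p_threshold and |delta beta| > db_threshold.

    Both inequalities strict; output ordered by ascending adj_p, then
    descending |delta beta|, then probe id.
    """
    sel = result[
        (result["adj_p"] < params.p_threshold)
        & (result["delta_beta"].abs() > params.db_threshold)
    ]
    df = sel.reset_index()
    id_col = df.columns[0]
    df["_absdb"] = df["delta_beta"].abs()
    df = df.sort_values(
        by=["adj_p", "_absdb", id_col], ascending=[True, False, True], kind="mergesort"
    )
    return df[id_col].tolist()


def differential_methylation(
    beta: BetaMatrix,
    groups: Sequence[str],
    params: DMParams = DMParams(),
) -> Tuple[pd.DataFrame, List[str]]:
    """Fit probe models and apply the selection gate in one call."""
    result = fit_probe_models(beta, groups, moderation=params.moderation)
    selected = select_dm_sites(result, params)
    result["selected"] = result.index.isin(selected)
    return result, selected
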