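"""Negative-binomial two-group differential expression with BH FDR.

The workflow mirrors the classic count-based exact-test approach: TMM-derived
effective library sizes, library-size equalized pseudo-counts, a common
dispersion estimated by conditional maximum likelihood, and a two-sided exact
test conditioning on the pooled per-feature sum. At zero dispersion the exact
test reduces to the conditional binomial test.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from scipy.stats import ttest_ind
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, FormatError
from .expression_io import CountMatrix, cpm, tmm_factors

__all__ = [
    "estimate_common_dispersion",
    "nb_exact_test",
    "bh_fdr",
    "run_de_contrast",
    "select_de_features",
    "fpkm_de",
]

_DISP_MAX = 10.0


def _pseudo_counts(cm: CountMatrix, factors: pd.Series) -> np.ndarray:
    """Counts rescaled to a common (geometric-mean) effective library size."""
    eff = cm.lib_sizes.to_numpy(dtype=float) * factors.loc[cm.samples].to_numpy(dtype=float)
    target = np.exp(np.mean(np.log(eff)))
    return cm.counts.to_numpy(dtype=float) * (target / eff)


def _cond_loglik(phi: float, pseudo: np.ndarray, group_idx: Sequence[np.ndarray]) -> float:
    """Conditional NB log-likelihood (summed over features and groups)."""
    r = 1.0 / phi
    ll = 0.0
    for idx in group_idx:
        y = pseudo[:, idx]
        n = y.shape[1]
        z = y.sum(axis=1)
        ll += float(
            np.sum(gammaln(y + r)) + pseudo.shape[0] * gammaln(n * r)
            - np.sum(gammaln(z + n * r)) - pseudo.shape[0] * n * gammaln(r)
        )
    return ll


def estimate_common_dispersion(
    cm: CountMatrix,
    groups: pd.Series | None = None,
    factors: pd.Series | None = None,
) -> float:
    """Common NB dispersion by conditional maximum likelihood on pseudo-counts.

    Optimization runs on delta = phi/(1+phi); the estimate is clamped to
    [0, 10]. Groups with a single sample contribute nothing to the conditional
    likelihood but are tolerated as long as one group has >= 2 samples.
    """
    if cm.counts.shape[1] < 2:
        raise ConfigError("dispersion estimation needs at least two samples")
    if groups is None:
        groups = cm.groups
    groups = groups.loc[cm.samples]
    if factors is None:
        factors = tmm_factors(cm)
    pseudo = _pseudo_counts(cm, factors)
    keep = pseudo.sum(axis=1) > 0
    pseudo = pseudo[keep]
    labels = groups.to_numpy()
    group_idx = [np.flatnonzero(labels == g) for g in pd.unique(labels)]
    group_idx = [idx for idx in group_idx if idx.size >= 2]
    if not group_idx:
        raise ConfigError("no group with >= 2 samples; cannot estimate dispersion")

    delta_lo, delta_hi = 1e-6, _DISP_MAX / (1.0 + _DISP_MAX)

    def neg(delta: float) -> float:
        phi = delta / (1.0 - delta)
        return -_cond_loglik(phi, pseudo, group_idx)

    res = minimize_scalar(neg, bounds=(delta_lo, delta_hi), method="bounded",
                          options={"xatol": 1e-8})
    delta = float(res.x)
    if delta <= delta_lo * 5:
        # likelihood still increasing toward zero dispersion -> clamp
        if neg(delta_lo) <= neg(delta):
            return 0.0
    phi = delta / (1.0 - delta)
    return float(np.clip(phi, 0.0, _DISP_MAX))


def nb_exact_test(
    counts_a: Sequence[float],
    counts_b: Sequence[float],
    dispersion: float,
    lib_sizes: Sequence[float] | None = None,
) -> float:
    """Two-sided exact NB test conditioning on the pooled sum.

    ``counts_a``/``counts_b`` are (pseudo-)counts on a common library size; if
    ``lib_sizes`` is given, counts are first rescaled to the mean library size.
    The p-value sums the conditional probabilities of all outcomes no more
    likely than the observed split. ``dispersion == 0`` gives the conditional
    binomial test.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if (a < 0).any() or (b < 0).any():
        raise FormatError("negative counts")
    if dispersion < 0:
        raise FormatError("dispersion must be >= 0")
    if lib_sizes is not None:
        lib = np.asarray(lib_sizes, dtype=float)
        scale = lib.mean() / lib
        full = np.concatenate([a, b]) * scale
        a, b = full[: a.size], full[a.size:]
    na, nb = a.size, b.size
    sa = int(round(a.sum()))
    sb = int(round(b.sum()))
    s = sa + sb
    if s == 0:
        return 1.0
    x = np.arange(s + 1)
    if dispersion < 1e-12:
        # conditional binomial limit
        logp = (
            gammaln(s + 1) - gammaln(x + 1) - gammaln(s - x + 1)
            + x * np.log(na / (na + nb)) + (s - x) * np.log(nb / (na + nb))
        )
    else:
        ra = na / dispersion
        rb = nb / dispersion
        mu = s / (na + nb)
        mu_a, mu_b = na * mu, nb * mu
        # gammaln(x + r) - gammaln(r) via cumulative log sums: stable even for
        # the huge shape parameters arising at near-zero dispersion
        lg = np.log(np.arange(s, dtype=float)[None, :] + np.array([[ra], [rb]]))
        lg_a = np.concatenate([[0.0], np.cumsum(lg[0])])
        lg_b = np.concatenate([[0.0], np.cumsum(lg[1])])
        lfact = gammaln(x + 1.0)
        logp = (
            lg_a - lfact + x * (np.log(mu_a) - np.log(ra + mu_a))
            + ra * (np.log(ra) - np.log(ra + mu_a))
            + lg_b[::-1] - lfact[::-1] + (s - x) * (np.log(mu_b) - np.log(rb + mu_b))
            + rb * (np.log(rb) - np.log(rb + mu_b))
        )
    logp -= logp.max()
    p = np.exp(logp)
    p_obs = p[sa]
    # relative tie tolerance (binom.test convention); also absorbs the tiny
    # asymmetry of exactly-tied outcomes at near-zero dispersion
    pval = p[p <= p_obs * (1.0 + 1e-7)].sum() / p.sum()
    return float(min(pval, 1.0))


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotonicity enforced)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise FormatError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_de_contrast(
    cm: CountMatrix,
    contrast_group: str = "ATC",
    de_fdr: float = 0.01,
    prior_count: float = 2.0,
    dispersion: float | None = None,
) -> pd.DataFrame:
    """Full contrast of ``contrast_group`` vs all remaining samples.

    Returns a table indexed by feature with log2fc, avg_log2cpm, p_value, fdr
    and a direction label (UP/DN/NS at ``de_fdr``). log2 fold changes come from
    prior-augmented group mean CPM.
    """
    labels = cm.groups.to_numpy()
    in_a = labels == contrast_group
    if in_a.sum() == 0 or (~in_a).sum() == 0:
        raise ConfigError(f"contrast {contrast_group!r} vs rest has an empty group")
    factors = tmm_factors(cm)
    if dispersion is None:
        two_group = pd.Series(np.where(in_a, "A", "B"), index=cm.samples)
        dispersion = estimate_common_dispersion(cm, groups=two_group, factors=factors)
    pseudo = _pseudo_counts(cm, factors)

    pvals = np.ones(pseudo.shape[0])
    for i in range(pseudo.shape[0]):
        pvals[i] = nb_exact_test(pseudo[i, in_a], pseudo[i, ~in_a], dispersion)
    fdr = bh_fdr(pvals)

    eff = cm.lib_sizes.to_numpy(dtype=float) * factors.to_numpy(dtype=float)
    prior = prior_count * eff / eff.mean()
    cpm_adj = (cm.counts.to_numpy(dtype=float) + prior) / (eff + 2.0 * prior) * 1e6
    log2fc = np.log2(cpm_adj[:, in_a].mean(axis=1) / cpm_adj[:, ~in_a].mean(axis=1))
    avg_log2cpm = cpm(cm, factors, log=True, prior_count=prior_count).values.mean(axis=1)

    direction = np.where(fdr < de_fdr, np.where(log2fc > 0, "UP", "DN"), "NS")
    direction[log2fc == 0] = "NS"
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "avg_log2cpm": avg_log2cpm.to_numpy(),
            "p_value": pvals,
            "fdr": fdr,
            "direction": direction,
        },
        index=cm.features,
    )


def select_de_features(
    de: pd.DataFrame,
    cpm_values: pd.DataFrame,
    fdr_max: float = 0.01,
    min_avg_cpm: float = 100.0,
) -> pd.DataFrame:
    """DE feature selection: fdr < ``fdr_max`` and mean CPM > ``min_avg_cpm``.

    ``cpm_values`` is the pre-log CPM matrix over the same features. Returns the
    selected rows of ``de`` with a definite UP/DN label by log2fc sign.
    """
    missing = de.index.difference(cpm_values.index)
    if len(missing):
        raise ConfigError(f"features missing from CPM matrix: {list(missing)[:5]}")
    mean_cpm = cpm_values.loc[de.index].mean(axis=1)
    sel = (de["fdr"] < fdr_max) & (mean_cpm > min_avg_cpm)
    out = de.loc[sel].copy()
    out["direction"] = np.where(out["log2fc"] > 0, "UP", "DN")
    out["mean_cpm"] = mean_cpm.loc[out.index]
    return out


def fpkm_de(
    fpkm: pd.DataFrame,
    groups: pd.Series,
    contrast_group: str = "ATC",
    prior: float = 1.0,
) -> pd.DataFrame:
    """Two-group mRNA contrast on log2(FPKM + prior) via Welch's t-test + BH.

    Convenience producer of the mRNA DE table consumed by the scoring module
    (the pipeline takes FPKM, not mRNA read counts, as input).
    """
    labels = groups.loc[fpkm.columns].to_numpy()
    in_a = labels == contrast_group
    if in_a.sum() < 2 or (~in_a).sum() < 2:
        raise ConfigError("each group needs >= 2 samples for the t-test")
    logx = np.log2(fpkm.to_numpy(dtype=float) + prior)
    res = ttest_ind(logx[:, in_a], logx[:, ~in_a], axis=1, equal_var=False)
    pvals = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
    log2fc = logx[:, in_a].mean(axis=1) - logx[:, ~in_a].mean(axis=1)
    return pd.DataFrame(
        {"log2fc": log2fc, "p_value": pvals, "fdr": bh_fdr(pvals)}, index=fpkm.index
    )
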