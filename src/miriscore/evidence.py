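"""Gene-level external evidence: essentiality averaging and survival screening.

Survival evidence comes from a median split of log2 expression followed by a
Kaplan-Meier / log-rank comparison; the hazard ratio is the ratio of
observed/expected event ratios between the high and low groups. Both evidence
channels share a signed per-sign max-abs scaling into [-1, 1] with missing
values contributing 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .errors import ConfigError, FormatError

__all__ = [
    "average_essentiality",
    "signed_scale",
    "km_curve",
    "km_logrank",
    "gene_survival_screen",
    "read_essentiality",
    "read_clinical",
]


def read_essentiality(path) -> pd.DataFrame:
    """Gene x cell-line gene-effect CSV (first column gene ids)."""
    return pd.read_csv(path, index_col=0)


def read_clinical(path) -> pd.DataFrame:
    """Clinical TSV with sample_id, time, event columns."""
    df = pd.read_csv(path, sep="\t")
    for col in ("sample_id", "time", "event"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing clinical column {col!r}")
    if (df["time"] <= 0).any():
        raise FormatError(f"{path}: survival times must be positive")
    if not df["event"].isin([0, 1]).all():
        raise FormatError(f"{path}: event must be 0 or 1")
    return df.set_index("sample_id")


def average_essentiality(es_table: pd.DataFrame) -> pd.Series:
    """Per-gene arithmetic mean of gene-effect scores over non-missing cell lines."""
    if es_table.shape[1] < 1:
        raise ConfigError("essentiality table has no cell lines")
    return es_table.mean(axis=1, skipna=True).rename("es_mean")


def signed_scale(values, transform: str = "identity") -> np.ndarray:
    """Scale values into [-1, 1] separately per sign.

    After the transform (``log2`` for hazard ratios, so HR = 1 maps to 0),
    negatives are divided by max |negative| and positives by the max positive.
    Zeros and missing values map to 0.
    """
    v = np.asarray(values, dtype=float).copy()
    if transform == "log2":
        if np.any(v[~np.isnan(v)] <= 0):
            raise ValueError("log2 scaling requires strictly positive values")
        v = np.log2(v)
    elif transform != "identity":
        raise ValueError(f"unknown transform {transform!r}")
    out = np.zeros_like(v)
    neg = v < 0
    pos = v > 0
    if neg.any():
        out[neg] = v[neg] / np.abs(v[neg]).max()
    if pos.any():
        out[pos] = v[pos] / v[pos].max()
    return out


def km_curve(times, events) -> pd.DataFrame:
    """Product-limit survival estimate: one row per distinct event time."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    rows = []
    surv = 1.0
    for ti in np.unique(t[e == 1]):
        n_at_risk = int((t >= ti).sum())
        d = int(((t == ti) & (e == 1)).sum())
        surv *= 1.0 - d / n_at_risk
        rows.append({"time": ti, "n_at_risk": n_at_risk, "n_events": d, "survival": surv})
    return pd.DataFrame(rows, columns=["time", "n_at_risk", "n_events", "survival"])


@dataclass
class LogrankResult:
    observed: tuple[float, float]   # (group 1 = high, group 2 = low)
    expected: tuple[float, float]
    chisq: float
    p_value: float
    hr: float                       # (O1/E1) / (O2/E2); NaN when undefined
    curves: dict[str, pd.DataFrame]


def km_logrank(times, events, high) -> LogrankResult:
    """Log-rank comparison of the ``high`` group (True) vs the rest.

    Observed/expected counts are tabulated over distinct event times; the
    chi-square uses the hypergeometric variance. With zero events overall the
    p-value and HR are NaN.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(high, dtype=bool)
    if g.all() or (~g).all():
        raise ConfigError("both groups must be non-empty")
    o1 = o2 = e1 = e2 = var = 0.0
    for ti in np.unique(t[e == 1]):
        at = t >= ti
        n1 = float((at & g).sum())
        n2 = float((at & ~g).sum())
        n = n1 + n2
        d = float(((t == ti) & (e == 1)).sum())
        d1 = float(((t == ti) & (e == 1) & g).sum())
        o1 += d1
        o2 += d - d1
        e1 += d * n1 / n
        e2 += d * n2 / n
        if n > 1:
            var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    curves = {
        "high": km_curve(t[g], e[g]),
        "low": km_curve(t[~g], e[~g]),
    }
    if (o1 + o2) == 0 or var == 0:
        return LogrankResult((o1, o2), (e1, e2), 0.0, np.nan, np.nan, curves)
    chisq = (o1 - e1) ** 2 / var
    p = float(chi2.sf(chisq, df=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        hr = (o1 / e1) / (o2 / e2) if e1 > 0 and e2 > 0 and o2 > 0 else np.nan
    return LogrankResult((o1, o2), (e1, e2), float(chisq), p, float(hr), curves)


def gene_survival_screen(
    expr_fpkm: pd.DataFrame,
    clinical: pd.DataFrame,
    min_total_fpkm: float = 1.0,
    log_prior: float = 1.0,
) -> pd.DataFrame:
    """Per-gene hazard-ratio screen: median split of log2(FPKM + prior).

    Genes with total FPKM below ``min_total_fpkm`` are dropped. Samples at or
    below the median form the low group. Degenerate splits (an empty group)
    yield a missing HR.
    """
    common = expr_fpkm.columns.intersection(clinical.index)
    if len(common) == 0:
        raise ConfigError("no shared samples between expression and clinical tables")
    expr = expr_fpkm[common]
    clin = clinical.loc[common]
    times = clin["time"].to_numpy(dtype=float)
    events = clin["event"].to_numpy(dtype=int)
    rows = []
    for gene, vals in expr.iterrows():
        x = vals.to_numpy(dtype=float)
        if x.sum() < min_total_fpkm:
            continue
        logx = np.log2(x + log_prior)
        high = logx > np.median(logx)
        if high.all() or not high.any():
            rows.append({"gene": gene, "hr": np.nan, "p_value": np.nan,
                         "n_high": int(high.sum()), "n_low": int((~high).sum())})
            continue
        res = km_logrank(times, events, high)
        rows.append({"gene": gene, "hr": res.hr, "p_value": res.p_value,
                     "n_high": int(high.sum()), "n_low": int((~high).sum())})
    return pd.DataFrame(rows, columns=["gene", "hr", "p_value", "n_high", "n_low"]
                        ).set_index("gene")
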