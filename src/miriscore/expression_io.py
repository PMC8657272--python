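"""Count/expression matrix I/O, TMM normalization, CPM transformation, abundance filtering.

Counts are held features x samples. Normalization follows the trimmed mean of
M-values (TMM) scheme: a reference sample is chosen by upper-quartile CPM, and
each sample's scaling factor is a precision-weighted, doubly trimmed mean of
per-feature log-ratios against that reference, rescaled so factors have
geometric mean one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ConfigError, FormatError, NormalizationError, UnitError

__all__ = [
    "CountMatrix",
    "ExpressionMatrix",
    "read_count_matrix",
    "write_count_matrix",
    "tmm_factors",
    "cpm",
    "filter_by_abundance",
]


@dataclass
class CountMatrix:
    """Integer read counts (features x samples) with per-sample group labels.

    ``lib_sizes`` defaults to column sums; pass explicitly to override.
    """

    counts: pd.DataFrame
    groups: pd.Series
    lib_sizes: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise FormatError("negative counts are not allowed")
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise FormatError(f"duplicate feature id: {dup!r}")
        missing = [s for s in self.counts.columns if s not in self.groups.index]
        if missing:
            raise ConfigError(f"samples without group label: {missing}")
        self.groups = self.groups.loc[self.counts.columns]
        if self.lib_sizes is None:
            self.lib_sizes = self.counts.sum(axis=0).astype(np.int64)
        else:
            self.lib_sizes = self.lib_sizes.loc[self.counts.columns]
            if (self.lib_sizes <= 0).any():
                raise ConfigError("library sizes must be positive")

    @property
    def features(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def __eq__(self, other: object) -> bool:  # pragma: no cover - trivial
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (
            self.counts.equals(other.counts)
            and self.groups.equals(other.groups)
            and self.lib_sizes.equals(other.lib_sizes)
        )


@dataclass
class ExpressionMatrix:
    """Real-valued features x samples matrix tagged with its unit."""

    values: pd.DataFrame
    unit: str  # one of CPM, log2CPM, FPKM, log2FPKM

    _UNITS = ("CPM", "log2CPM", "FPKM", "log2FPKM")

    def __post_init__(self) -> None:
        if self.unit not in self._UNITS:
            raise UnitError(f"unknown unit {self.unit!r}; expected one of {self._UNITS}")


def read_count_matrix(path, group_map: Mapping[str, str]) -> CountMatrix:
    """Read a TSV count matrix (first column feature ids, one column per sample).

    Every sample must appear in ``group_map``. Non-integer counts or duplicated
    feature rows are rejected.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise FormatError(f"{path}: duplicated feature ids")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise FormatError(f"{path}: non-numeric values in count matrix")
    if not np.allclose(arr, np.round(arr)):
        raise FormatError(f"{path}: counts must be integers")
    counts = df.astype(np.int64)
    missing = [s for s in counts.columns if s not in group_map]
    if missing:
        raise ConfigError(f"{path}: samples missing from group map: {missing}")
    groups = pd.Series({s: group_map[s] for s in counts.columns}, name="group")
    return CountMatrix(counts=counts, groups=groups)


def write_count_matrix(cm: CountMatrix, path) -> None:
    cm.counts.to_csv(path, sep="\t", index_label="feature")


def _tmm_pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """Log2 TMM factor of one sample against the reference.

    Features with a zero count in either sample are skipped (log undefined).
    Trimming removes ``trim_m`` of features from each tail of M and ``trim_a``
    from each tail of A; the factor is the precision-weighted mean of the
    surviving M values (weights = inverse asymptotic variance).
    """
    keep = (obs > 0) & (ref > 0)
    o = obs[keep].astype(float)
    r = ref[keep].astype(float)
    if o.size == 0:
        return 0.0
    m = np.log2((o / n_obs) / (r / n_ref))
    a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
    v = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    if np.max(np.abs(m)) < 1e-6:
        return 0.0
    n = m.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = rankdata(m)
    rank_a = rankdata(a)
    sel = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not sel.any() or np.sum(1.0 / v[sel]) == 0:
        return 0.0
    f = np.sum(m[sel] / v[sel]) / np.sum(1.0 / v[sel])
    return float(f) if np.isfinite(f) else 0.0


def tmm_factors(cm: CountMatrix, trim_m: float = 0.30, trim_a: float = 0.05) -> pd.Series:
    """Per-sample TMM scaling factors with geometric mean one.

    The reference sample is the one whose upper-quartile CPM is closest to the
    mean upper quartile (lowest column index wins ties).
    """
    counts = cm.counts.to_numpy(dtype=float)
    if counts.shape[1] < 2:
        raise NormalizationError("TMM requires at least two samples")
    lib = cm.lib_sizes.to_numpy(dtype=float)
    if (counts.sum(axis=0) == 0).any():
        bad = cm.samples[counts.sum(axis=0) == 0].tolist()
        raise NormalizationError(f"all-zero sample(s): {bad}")
    uq = np.quantile(counts / lib, 0.75, axis=0)
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    log_f = np.zeros(counts.shape[1])
    for j in range(counts.shape[1]):
        if j == ref_idx:
            continue
        log_f[j] = _tmm_pair_factor(
            counts[:, j], counts[:, ref_idx], lib[j], lib[ref_idx], trim_m, trim_a
        )
    factors = 2.0 ** log_f
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=cm.samples, name="tmm_factor")


def cpm(
    cm: CountMatrix,
    factors: pd.Series | None = None,
    log: bool = False,
    prior_count: float = 2.0,
) -> ExpressionMatrix:
    """Counts per million over effective (factor-adjusted) library sizes.

    With ``log=True`` a library-size-scaled prior count is added to the counts
    and twice the prior to the library size, keeping all values finite.
    """
    if factors is None:
        factors = pd.Series(1.0, index=cm.samples)
    factors = factors.loc[cm.samples]
    if (factors <= 0).any():
        raise NormalizationError("normalization factors must be positive")
    eff = cm.lib_sizes.to_numpy(dtype=float) * factors.to_numpy(dtype=float)
    counts = cm.counts.to_numpy(dtype=float)
    if not log:
        vals = counts / eff * 1e6
        return ExpressionMatrix(
            pd.DataFrame(vals, index=cm.features, columns=cm.samples), unit="CPM"
        )
    prior = prior_count * eff / eff.mean()
    vals = np.log2((counts + prior) / (eff + 2.0 * prior) * 1e6)
    return ExpressionMatrix(
        pd.DataFrame(vals, index=cm.features, columns=cm.samples), unit="log2CPM"
    )


def filter_by_abundance(em: ExpressionMatrix, threshold: float = 100.0) -> pd.Index:
    """Features whose mean CPM across all samples is >= ``threshold``.

    Input must be in (pre-log) CPM units; order is preserved.
    """
    if em.unit != "CPM":
        raise UnitError(f"abundance filter needs CPM input, got {em.unit}")
    means = em.values.mean(axis=1)
    return em.values.index[means >= threshold]
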