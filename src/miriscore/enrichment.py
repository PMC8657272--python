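"""Unweighted pre-ranked gene-set enrichment.

The running-sum statistic increments by 1/|hits| at set members and decrements
by 1/(N - |hits|) elsewhere; the enrichment score (ES) is the signed maximum
deviation. Significance comes from a seeded gene-label permutation null: NES
normalizes ES by the mean |null ES| of matching sign, p-values are the
matching-sign null tail, and BH FDR is applied across sets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .diffexp import bh_fdr
from .errors import ConfigError

__all__ = [
    "unweighted_es",
    "preranked_gsea",
    "target_subset_rankings",
    "read_gmt",
    "write_gmt",
]


def _es_from_positions(hit_pos: np.ndarray, n: int) -> float:
    """ES given sorted 0-based hit positions within a ranking of length n."""
    k = int(hit_pos.size)
    # integer numerators over the common denominator k*(n-k): exact
    # arithmetic, so tie-breaking is deterministic
    i = np.arange(1, k + 1, dtype=np.int64)
    misses = hit_pos.astype(np.int64) - (i - 1)
    at_hit = i * (n - k) - misses * k          # just after the i-th hit
    before_hit = (i - 1) * (n - k) - misses * k  # just before it
    pos = max(int(at_hit.max()), 0)
    neg = min(int(before_hit.min()), 0)
    denom = k * (n - k)
    # equal-magnitude deviations break toward the positive extremum
    return pos / denom if pos >= -neg else neg / denom


def unweighted_es(ranking, gene_set) -> float:
    """Unweighted enrichment score of ``gene_set`` within an ordered ranking."""
    genes = list(ranking)
    n = len(genes)
    idx = {g: i for i, g in enumerate(genes)}
    hit_pos = np.sort([idx[g] for g in gene_set if g in idx])
    if hit_pos.size == 0:
        raise ConfigError("gene set does not overlap the ranking")
    if hit_pos.size == n:
        raise ConfigError("gene set covers the entire ranking (degenerate)")
    return _es_from_positions(hit_pos, n)


def preranked_gsea(
    ranking,
    gene_sets: dict[str, list[str]],
    min_size: int = 10,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation-based pre-ranked GSEA over a collection of gene sets.

    Sets overlapping the ranking in fewer than ``min_size`` genes are dropped.
    The null permutes gene labels (equivalently: random hit positions).
    p-values are lower-bounded by 1/(n_same_sign_nulls + 1).
    """
    genes = list(ranking)
    n = len(genes)
    if len(set(genes)) != n:
        raise ConfigError("ranking contains duplicate gene ids")
    rng = np.random.default_rng(seed)
    rows = []
    for name, members in gene_sets.items():
        idx = {g: i for i, g in enumerate(genes)}
        hit_pos = np.sort([idx[g] for g in members if g in idx])
        k = hit_pos.size
        if k < min_size or k == n:
            continue
        es = _es_from_positions(hit_pos, n)
        null = np.empty(n_perm)
        for b in range(n_perm):
            null[b] = _es_from_positions(np.sort(rng.choice(n, size=k, replace=False)), n)
        same = null[np.sign(null) == np.sign(es)] if es != 0 else null
        if same.size == 0:
            nes, p = np.nan, 1.0
        else:
            nes = es / np.mean(np.abs(same))
            p = (1.0 + np.sum(np.abs(same) >= abs(es))) / (1.0 + same.size)
        rows.append({"set_name": name, "es": es, "nes": nes, "p_value": p,
                     "set_size_used": int(k)})
    out = pd.DataFrame(rows, columns=["set_name", "es", "nes", "p_value", "set_size_used"])
    if len(out):
        out["fdr"] = bh_fdr(out["p_value"].to_numpy())
    else:
        out["fdr"] = pd.Series(dtype=float)
    return out.set_index("set_name")


def target_subset_rankings(
    scored: pd.DataFrame, mrna_de: pd.DataFrame
) -> dict[str, pd.Series]:
    """log2fc-ordered rankings of strictly-positive-IS target genes.

    Returns up to two rankings keyed by miRNA direction ('DN', 'UP'); each is a
    Series of log2fc indexed by gene, sorted descending. A gene targeted with
    positive scaled score by both an UP- and a DN-miRNA appears in both.
    """
    out: dict[str, pd.Series] = {}
    for d in ("DN", "UP"):
        sub = scored[(scored["direction"] == d) & (scored["is_scaled"] > 0)]
        genes = pd.unique(sub["gene"])
        if len(genes) == 0:
            out[d] = pd.Series(dtype=float)
            continue
        fc = mrna_de.loc[genes, "log2fc"].sort_values(ascending=False)
        out[d] = fc
    return out


def read_gmt(path) -> dict[str, list[str]]:
    """GMT: one set per line — name, description, then member genes."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(gene_sets: dict[str, list[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in gene_sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")
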