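"""Interaction scoring: component assembly, per-miRNA scaling, prime targets,
onco scoring and signature extraction.

Each candidate miRNA-gene interaction collects five components:

  c1  combined binding evidence in [0, 1]
  c2  per-sign scaled target mRNA log2 fold change in [-1, 1]
  c3  inverse-association bonus in {0, 1}
  c4  signed-scaled mean essentiality in [-1, 1]
  c5  signed-scaled log2 hazard ratio in [-1, 1]

Raw interaction scores combine them direction-specifically,

  UP-miRNA:  c1 - c2 + c3 + c4 - c5
  DN-miRNA:  c1 + c2 + c3 - c4 + c5

and are min-max scaled to [-1, 1] within each miRNA. Interactions reaching the
per-miRNA maximum (scaled score 1) are that miRNA's prime targets; prime genes
are ranked by the onco score c2 - c4 + c5, min-max scaled across the prime set.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ConfigError
from .evidence import signed_scale

__all__ = [
    "fc_component",
    "inverse_bonus",
    "interaction_score_raw",
    "scale_is_per_mirna",
    "score_interactions",
    "select_prime_targets",
    "onco_score",
    "extract_signature",
]

_TOL = 1e-9


def fc_component(log2fc, context) -> np.ndarray:
    """Per-sign scaled fold change: positives over the context max positive,
    negatives over |context min negative|; zero stays zero."""
    ctx = np.asarray(context, dtype=float)
    ctx = ctx[~np.isnan(ctx)]
    if ctx.size == 0:
        raise ConfigError("empty fold-change context")
    v = np.atleast_1d(np.asarray(log2fc, dtype=float)).copy()
    out = np.zeros_like(v)
    max_pos = ctx[ctx > 0].max() if (ctx > 0).any() else np.nan
    max_neg = np.abs(ctx[ctx < 0]).max() if (ctx < 0).any() else np.nan
    pos = v > 0
    neg = v < 0
    out[pos] = v[pos] / max_pos
    out[neg] = v[neg] / max_neg
    return out


def inverse_bonus(direction, target_log2fc, target_fdr, fdr_max: float = 0.05) -> np.ndarray:
    """1 iff the target fold change opposes the miRNA direction and the target
    mRNA change is significant (fdr < ``fdr_max``)."""
    d = np.atleast_1d(np.asarray(direction, dtype=object))
    if not np.isin(d, ["UP", "DN"]).all():
        raise ValueError("direction must be UP or DN")
    fc = np.atleast_1d(np.asarray(target_log2fc, dtype=float))
    fdr = np.atleast_1d(np.asarray(target_fdr, dtype=float))
    inverse = np.where(d == "UP", fc < 0, fc > 0)
    return (inverse & (fdr < fdr_max)).astype(int)


def interaction_score_raw(c1, c2, c3, c4, c5, direction) -> np.ndarray:
    """Direction-specific raw interaction score."""
    d = np.atleast_1d(np.asarray(direction, dtype=object))
    if not np.isin(d, ["UP", "DN"]).all():
        raise ValueError("direction must be UP or DN")
    c1, c2, c3, c4, c5 = (np.atleast_1d(np.asarray(c, dtype=float)) for c in (c1, c2, c3, c4, c5))
    up = c1 - c2 + c3 + c4 - c5
    dn = c1 + c2 + c3 - c4 + c5
    return np.where(d == "UP", up, dn)


def scale_is_per_mirna(raw) -> tuple[np.ndarray, bool]:
    """Min-max map of one miRNA's raw scores to [-1, 1].

    Returns (scaled, degenerate). If all raw values coincide the miRNA is
    degenerate: scores become 0 and it is excluded from prime-target selection.
    """
    v = np.asarray(raw, dtype=float)
    if v.size == 0:
        raise ConfigError("no interactions for miRNA")
    lo, hi = v.min(), v.max()
    if hi - lo < _TOL:
        return np.zeros_like(v), True
    return 2.0 * (v - lo) / (hi - lo) - 1.0, False


def score_interactions(
    de_mirnas: pd.DataFrame,
    mrna_de: pd.DataFrame,
    interactions: pd.DataFrame,
    es_mean: pd.Series | None = None,
    hr: pd.Series | None = None,
    inverse_fdr_max: float = 0.05,
    min_binding_probability: float = 0.95,
) -> pd.DataFrame:
    """Score all candidate interactions of the DE miRNAs.

    ``de_mirnas``: index = miRNA id, needs a ``direction`` column (UP/DN).
    ``mrna_de``: index = gene, needs ``log2fc`` and ``fdr``. Interactions of
    non-DE miRNAs, below-threshold binding probabilities, and genes absent from
    the mRNA table are dropped. Missing essentiality or hazard evidence
    contributes 0 to its component.
    """
    df = interactions[interactions["mirna"].isin(de_mirnas.index)]
    df = df[df["binding_probability"] >= min_binding_probability - 1e-12]
    df = df[df["gene"].isin(mrna_de.index)].copy()
    if df.empty:
        return pd.DataFrame(
            columns=["mirna", "direction", "gene", "c1", "c2", "c3", "c4", "c5",
                     "is_raw", "is_scaled", "degenerate"]
        )
    direction = de_mirnas.loc[df["mirna"], "direction"].to_numpy()
    gene_fc = mrna_de.loc[df["gene"], "log2fc"].to_numpy()
    gene_fdr = mrna_de.loc[df["gene"], "fdr"].to_numpy()

    c1 = (df["binding_probability"].to_numpy()
          + df["flag_targetscan"].to_numpy()
          + df["flag_mirdb"].to_numpy()) / 3.0
    # context for fold-change scaling: all distinct candidate target genes
    ctx = mrna_de.loc[pd.unique(df["gene"]), "log2fc"].to_numpy()
    c2 = fc_component(gene_fc, ctx)
    c3 = inverse_bonus(direction, gene_fc, gene_fdr, fdr_max=inverse_fdr_max)

    genes = pd.Index(pd.unique(df["gene"]))
    es_vals = (es_mean.reindex(genes).to_numpy() if es_mean is not None
               else np.full(len(genes), np.nan))
    hr_vals = (hr.reindex(genes).to_numpy() if hr is not None
               else np.full(len(genes), np.nan))
    es_scaled = pd.Series(signed_scale(es_vals, "identity"), index=genes)
    hr_for_scale = np.where(np.isnan(hr_vals) | (hr_vals <= 0), np.nan, hr_vals)
    hr_scaled = pd.Series(signed_scale(hr_for_scale, "log2"), index=genes)
    c4 = es_scaled.loc[df["gene"]].to_numpy()
    c5 = hr_scaled.loc[df["gene"]].to_numpy()

    is_raw = interaction_score_raw(c1, c2, c3, c4, c5, direction)
    out = pd.DataFrame(
        {"mirna": df["mirna"].to_numpy(), "direction": direction,
         "gene": df["gene"].to_numpy(), "c1": c1, "c2": c2, "c3": c3,
         "c4": c4, "c5": c5, "is_raw": is_raw}
    )
    out["is_scaled"] = 0.0
    out["degenerate"] = False
    for _mir, idx in out.groupby("mirna", sort=False).groups.items():
        scaled, degen = scale_is_per_mirna(out.loc[idx, "is_raw"].to_numpy())
        out.loc[idx, "is_scaled"] = scaled
        out.loc[idx, "degenerate"] = degen
    return out


def select_prime_targets(scored: pd.DataFrame) -> pd.DataFrame:
    """Per non-degenerate miRNA, the interactions with scaled score 1.

    Ties are kept and flagged (``tied``); a ``gene_prime_count`` column reports
    for how many miRNAs each gene is prime.
    """
    ok = scored[~scored["degenerate"]]
    prime = ok[np.abs(ok["is_scaled"] - 1.0) < _TOL].copy()
    per_mirna = prime.groupby("mirna")["gene"].transform("size")
    prime["tied"] = per_mirna > 1
    prime["gene_prime_count"] = prime.groupby("gene")["mirna"].transform("nunique")
    return prime.reset_index(drop=True)


def onco_score(prime: pd.DataFrame) -> pd.DataFrame:
    """Gene-level onco score over the prime set.

    os_raw = c2 - c4 + c5 per prime interaction; genes prime for several miRNAs
    keep their maximal-|os_raw| interaction. Scores are min-max scaled to
    [-1, 1] across the prime gene set.
    """
    if prime.empty:
        raise ConfigError("empty prime set")
    df = prime.copy()
    df["os_raw"] = df["c2"] - df["c4"] + df["c5"]
    idx = df.groupby("gene")["os_raw"].apply(lambda s: s.abs().idxmax())
    per_gene = df.loc[idx.to_numpy(), ["gene", "mirna", "c2", "c4", "c5", "os_raw"]]
    per_gene = per_gene.set_index("gene")
    lo, hi = per_gene["os_raw"].min(), per_gene["os_raw"].max()
    if hi - lo < _TOL:
        per_gene["os_scaled"] = 0.0
    else:
        per_gene["os_scaled"] = 2.0 * (per_gene["os_raw"] - lo) / (hi - lo) - 1.0
    return per_gene.sort_values("os_scaled", ascending=False)


def extract_signature(prime: pd.DataFrame, os_table: pd.DataFrame) -> pd.DataFrame:
    """Deduplicated prime gene list ordered by descending scaled onco score,
    with per-gene prime multiplicity."""
    mult = prime.groupby("gene")["mirna"].nunique().rename("multiplicity")
    sig = os_table.join(mult)
    return sig.sort_values("os_scaled", ascending=False)
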