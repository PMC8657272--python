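"""End-to-end orchestration of the analysis on a dataset directory or in-memory
dataset: DE selection, interaction scoring, enrichment and reporting products."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from . import diffexp, enrichment, evidence, interactions, reporting
from . import scoring as scoring_mod
from .expression_io import cpm, filter_by_abundance, tmm_factors
from .synthetic import SyntheticDataset, load_dataset

__all__ = ["run_pipeline", "make_truth_gene_sets"]


def make_truth_gene_sets(ds: SyntheticDataset, n_random: int = 8,
                         random_size: int = 25) -> dict[str, list[str]]:
    """Hallmark-style synthetic gene sets: the planted onco/suppressor target
    sets plus seeded random decoy sets."""
    import numpy as np

    rng = np.random.default_rng(ds.config.seed + 7919)
    sets = {}
    onco = ds.truth_genes.loc[ds.truth_genes["label"] == "oncogene", "gene"].tolist()
    supp = ds.truth_genes.loc[ds.truth_genes["label"] == "suppressor", "gene"].tolist()
    if onco:
        sets["PLANTED_ONCOGENE_TARGETS"] = onco
    if supp:
        sets["PLANTED_SUPPRESSOR_TARGETS"] = supp
    genes = list(ds.mrna_fpkm.index)
    for i in range(n_random):
        sets[f"RANDOM_SET_{i + 1:02d}"] = list(
            rng.choice(genes, size=min(random_size, len(genes)), replace=False)
        )
    return sets


def run_pipeline(
    dataset: SyntheticDataset | str | Path,
    out_dir: str | Path | None = None,
    gene_sets: dict[str, list[str]] | None = None,
    de_fdr: float = 0.01,
    min_avg_cpm: float = 100.0,
    n_perm: int = 500,
    gsea_seed: int = 0,
) -> dict:
    """Run the full analysis and (optionally) write TSV products.

    Returns a dict of all intermediate and final tables.
    """
    ds = dataset if isinstance(dataset, SyntheticDataset) else load_dataset(dataset)
    cm = ds.mirna_counts

    factors = tmm_factors(cm)
    cpm_mat = cpm(cm, factors).values
    de = diffexp.run_de_contrast(cm, "ATC", de_fdr=de_fdr)
    selected = diffexp.select_de_features(de, cpm_mat, fdr_max=de_fdr,
                                          min_avg_cpm=min_avg_cpm)
    mrna_de = diffexp.fpkm_de(ds.mrna_fpkm, cm.groups, "ATC")

    inter = interactions.collapse_interactions(ds.interactions)
    es_mean = evidence.average_essentiality(ds.essentiality)
    surv = evidence.gene_survival_screen(ds.surv_fpkm, ds.clinical)
    scored = scoring_mod.score_interactions(
        selected, mrna_de, inter, es_mean=es_mean, hr=surv["hr"]
    )
    prime = scoring_mod.select_prime_targets(scored)
    results: dict = {
        "tmm_factors": factors, "cpm": cpm_mat, "de": de, "selected": selected,
        "mrna_de": mrna_de, "es_mean": es_mean, "survival": surv, "scored": scored,
        "prime": prime,
    }
    if len(prime):
        os_table = scoring_mod.onco_score(prime)
        results["onco_score"] = os_table
        results["signature"] = scoring_mod.extract_signature(prime, os_table)

    rankings = enrichment.target_subset_rankings(scored, mrna_de)
    # global ranking of all expressed mRNAs by fold change, alongside the
    # direction-specific positive-IS target rankings
    rankings["ALL"] = mrna_de["log2fc"].sort_values(ascending=False)
    results["rankings"] = rankings
    if gene_sets:
        gsea = {}
        for d, ranking in rankings.items():
            if len(ranking) == 0:
                continue
            gsea[d] = enrichment.preranked_gsea(
                list(ranking.index), gene_sets, n_perm=n_perm, seed=gsea_seed
            )
        results["gsea"] = gsea

    abundant = filter_by_abundance(cpm(cm, factors), threshold=min_avg_cpm)
    log_cpm = cpm(cm, factors, log=True).values.loc[abundant]
    coords, var_frac = reporting.pca_project(log_cpm)
    results["pca_coords"], results["pca_var_frac"] = coords, var_frac
    de_log_cpm = log_cpm.loc[log_cpm.index.intersection(selected.index)]
    if de_log_cpm.shape[0] >= 2:
        results["clusters"] = reporting.hierarchical_cluster(de_log_cpm, k=2)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        de.to_csv(out / "de_mirna.tsv", sep="\t", index_label="feature")
        selected.to_csv(out / "de_selected.tsv", sep="\t", index_label="feature")
        mrna_de.to_csv(out / "de_mrna.tsv", sep="\t", index_label="gene")
        scored.to_csv(out / "scored_interactions.tsv", sep="\t", index=False)
        prime.to_csv(out / "prime_targets.tsv", sep="\t", index=False)
        if "signature" in results:
            results["signature"].to_csv(out / "signature.tsv", sep="\t",
                                        index_label="gene")
        surv.to_csv(out / "survival_screen.tsv", sep="\t")
        coords.to_csv(out / "pca_coordinates.tsv", sep="\t", index_label="sample")
        if "clusters" in results:
            results["clusters"].labels.rename("cluster").to_csv(
                out / "cluster_labels.tsv", sep="\t", index_label="sample"
            )
        if "gsea" in results:
            for d, table in results["gsea"].items():
                table.to_csv(out / f"gsea_{d.lower()}.tsv", sep="\t")
        for d, ranking in rankings.items():
            ranking.rename("log2fc").to_csv(
                out / f"ranking_{d.lower()}.tsv", sep="\t", index_label="gene"
            )
    return results
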