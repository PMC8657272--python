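"""Synthetic cohort generator: complete pipeline inputs with planted ground truth.

The generator emulates the study design end to end: a four-group cohort with
negative-binomially distributed miRNA counts and planted ATC effects, target
mRNAs with inverse fold changes, a transcript annotation with meta-3'UTR
structure, predicted interactions (true edges dominating every score
component, plus decoys), signed essentiality scores, and a survival cohort
whose hazard depends on a latent severity factor loaded onto the planted
onco/suppressor genes. Identical config + seed reproduce the dataset byte for
byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .expression_io import CountMatrix
from .interactions import INTERACTION_COLUMNS, UTR_REGION, Annotation

__all__ = ["SimConfig", "SyntheticDataset", "generate_cohort", "write_dataset", "load_dataset"]

_SITE_LEN = 7
_PRIME_ONCO_SHARE = 4  # DN-miRNAs sharing the prime oncogene target
_PRIME_SUPP_SHARE = 2  # UP-miRNAs sharing the prime suppressor target


@dataclass
class SimConfig:
    n_per_group: dict = field(
        default_factory=lambda: {"ATC": 10, "PTC": 6, "FTC": 6, "NT": 6}
    )
    n_mirna: int = 300
    n_planted_up: int = 23
    n_planted_dn: int = 62
    planted_log2fc: float = 2.0
    baseline_cpm_range: tuple = (50.0, 2000.0)
    nb_dispersion: float = 0.1
    n_genes: int = 400
    targets_per_planted_mirna: int = 2
    decoy_interactions: int = 600
    target_inverse_log2fc: float = 1.5
    ess_onco_mean: float = -1.0
    ess_ts_mean: float = 0.5
    surv_beta: float = 1.0
    censor_rate: float = 0.3
    seed: int = 0
    # cohort plumbing beyond the study-shape parameters
    n_survival: int = 200
    n_cell_lines: int = 9
    lib_size_range: tuple = (700_000.0, 1_400_000.0)

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.n_per_group.values()) or not self.n_per_group:
            raise ConfigError("group sizes must be positive")
        for name in ("n_mirna", "n_genes", "targets_per_planted_mirna",
                     "n_survival", "n_cell_lines"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.n_planted_up < 0 or self.n_planted_dn < 0 or self.decoy_interactions < 0:
            raise ConfigError("planted/decoy counts must be non-negative")
        if self.nb_dispersion < 0:
            raise ConfigError("dispersion must be >= 0")
        if not (0.0 <= self.censor_rate <= 1.0):
            raise ConfigError("censor_rate must lie in [0, 1]")
        if self.n_planted_up + self.n_planted_dn > self.n_mirna:
            raise ConfigError("more planted miRNAs than miRNAs")
        n_planted = self.n_planted_up + self.n_planted_dn
        needed = n_planted * self.targets_per_planted_mirna
        if needed > self.n_genes:
            raise ConfigError(
                f"planted targets ({needed}) exceed n_genes ({self.n_genes})"
            )


@dataclass
class SyntheticDataset:
    config: SimConfig
    mirna_counts: CountMatrix
    mrna_fpkm: pd.DataFrame
    interactions: pd.DataFrame
    gtf_lines: list
    essentiality: pd.DataFrame
    surv_fpkm: pd.DataFrame
    clinical: pd.DataFrame
    truth_mirnas: pd.DataFrame
    truth_edges: pd.DataFrame
    truth_genes: pd.DataFrame

    @property
    def annotation(self) -> Annotation:
        rows = []
        for line in self.gtf_lines:
            parts = line.split("\t")
            attrs = parts[8]
            gid = attrs.split('gene_id "')[1].split('"')[0] if 'gene_id "' in attrs else None
            tid = (attrs.split('transcript_id "')[1].split('"')[0]
                   if 'transcript_id "' in attrs else None)
            rows.append({"chrom": parts[0], "feature": parts[2],
                         "start": int(parts[3]) - 1, "end": int(parts[4]),
                         "strand": parts[6], "gene_id": gid, "transcript_id": tid})
        return Annotation(pd.DataFrame(rows))


def _gene_structures(cfg: SimConfig, rng: np.random.Generator):
    """Per-gene transcript/UTR layout plus the GTF lines describing it."""
    structures = {}
    gtf = []
    for i in range(cfg.n_genes):
        gene = f"GENE{i:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        anchor = 10_000 * (i + 1)
        utr_len = int(rng.integers(150, 401))
        split = rng.random() < 0.3
        tx_blocks = {}
        # transcript 1: optionally junction-split UTR
        if split:
            l1 = int(rng.integers(40, utr_len - 40))
            gap = int(rng.integers(50, 501))
            lens = [l1, utr_len - l1]
        else:
            gap = 0
            lens = [utr_len]
        blocks = []  # transcript order, 0-based half-open genomic
        if strand == "+":
            pos = anchor
            for j, ln in enumerate(lens):
                blocks.append((pos, pos + ln))
                pos += ln + gap
        else:
            pos = anchor + sum(lens) + gap * (len(lens) - 1)
            for ln in lens:
                blocks.append((pos - ln, pos))
                pos -= ln + gap
        tx_blocks[f"{gene}.t1"] = blocks
        # optional second transcript extending the terminal UTR block
        if rng.random() < 0.4:
            ext = int(rng.integers(30, 101))
            b2 = [list(b) for b in blocks]
            if strand == "+":
                b2[-1][1] += ext
            else:
                b2[-1][0] -= ext
            tx_blocks[f"{gene}.t2"] = [tuple(b) for b in b2]
        structures[gene] = {"strand": strand, "tx": tx_blocks}

        lo = min(s for bl in tx_blocks.values() for s, _e in bl)
        hi = max(e for bl in tx_blocks.values() for _s, e in bl)
        attr_g = f'gene_id "{gene}";'
        gtf.append(f"chr1\tsim\tgene\t{lo + 1}\t{hi}\t.\t{strand}\t.\t{attr_g}")
        for tid, bl in tx_blocks.items():
            t_lo = min(s for s, _e in bl)
            t_hi = max(e for _s, e in bl)
            attr_t = f'gene_id "{gene}"; transcript_id "{tid}";'
            gtf.append(f"chr1\tsim\ttranscript\t{t_lo + 1}\t{t_hi}\t.\t{strand}\t.\t{attr_t}")
            for s, e in sorted(bl):
                gtf.append(f"chr1\tsim\texon\t{s + 1}\t{e}\t.\t{strand}\t.\t{attr_t}")
                gtf.append(
                    f"chr1\tsim\tthree_prime_utr\t{s + 1}\t{e}\t.\t{strand}\t.\t{attr_t}"
                )
    return structures, gtf


def _utr_length(struct, tid) -> int:
    return sum(e - s for s, e in struct["tx"][tid])


def generate_cohort(config: SimConfig) -> SyntheticDataset:
    """Generate all pipeline inputs plus the planted-truth ledger."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    samples = [f"{g}{i + 1:02d}" for g, n in cfg.n_per_group.items() for i in range(n)]
    groups = pd.Series(
        [g for g, n in cfg.n_per_group.items() for _ in range(n)],
        index=samples, name="group",
    )
    is_atc = (groups == "ATC").to_numpy()

    mirnas = [f"mir-{i:04d}" for i in range(cfg.n_mirna)]
    up_ids = mirnas[: cfg.n_planted_up]
    dn_ids = mirnas[cfg.n_planted_up: cfg.n_planted_up + cfg.n_planted_dn]

    # --- miRNA counts -----------------------------------------------------
    lo, hi = cfg.baseline_cpm_range
    base_cpm = np.exp(rng.uniform(np.log(lo), np.log(hi), size=cfg.n_mirna))
    planted_lo = max(300.0, lo)
    n_planted = cfg.n_planted_up + cfg.n_planted_dn
    base_cpm[:n_planted] = np.exp(
        rng.uniform(np.log(planted_lo), np.log(max(hi, planted_lo * 2)), size=n_planted)
    )
    lib = np.exp(rng.uniform(np.log(cfg.lib_size_range[0]),
                             np.log(cfg.lib_size_range[1]), size=len(samples)))
    mean_cpm = np.tile(base_cpm[:, None], (1, len(samples)))
    mean_cpm[: cfg.n_planted_up, is_atc] *= 2.0 ** cfg.planted_log2fc
    mean_cpm[cfg.n_planted_up: n_planted, is_atc] *= 2.0 ** (-cfg.planted_log2fc)
    mu = mean_cpm * lib[None, :] / 1e6
    if cfg.nb_dispersion == 0:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / cfg.nb_dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
    mirna_counts = CountMatrix(
        counts=pd.DataFrame(counts.astype(np.int64),
                            index=pd.Index(mirnas, name="feature"), columns=samples),
        groups=groups.copy(),
    )

    # --- target assignment ------------------------------------------------
    genes = [f"GENE{i:04d}" for i in range(cfg.n_genes)]
    prime_onco = genes[0]
    prime_supp = genes[1]
    pool = iter(genes[2:])
    targets: dict[str, list[str]] = {}
    onco_genes, supp_genes = {prime_onco}, {prime_supp}
    for j, m in enumerate(dn_ids):
        t = [prime_onco] if j < _PRIME_ONCO_SHARE else [next(pool)]
        t += [next(pool) for _ in range(cfg.targets_per_planted_mirna - 1)]
        targets[m] = t
        onco_genes.update(t)
    for j, m in enumerate(up_ids):
        t = [prime_supp] if j < _PRIME_SUPP_SHARE else [next(pool)]
        t += [next(pool) for _ in range(cfg.targets_per_planted_mirna - 1)]
        targets[m] = t
        supp_genes.update(t)
    if cfg.n_planted_dn == 0:
        onco_genes = set()
    if cfg.n_planted_up == 0:
        supp_genes = set()

    # --- mRNA FPKM with inverse ATC shifts --------------------------------
    base_log2 = rng.uniform(2.0, 6.0, size=cfg.n_genes)
    shift = np.zeros(cfg.n_genes)
    gene_idx = {g: i for i, g in enumerate(genes)}
    for g in onco_genes:
        shift[gene_idx[g]] = cfg.target_inverse_log2fc
    for g in supp_genes:
        shift[gene_idx[g]] = -cfg.target_inverse_log2fc
    if prime_onco in onco_genes:
        shift[gene_idx[prime_onco]] = 1.5 * cfg.target_inverse_log2fc
    if prime_supp in supp_genes:
        shift[gene_idx[prime_supp]] = -1.5 * cfg.target_inverse_log2fc
    log2fpkm = (base_log2[:, None]
                + shift[:, None] * is_atc[None, :]
                + rng.normal(0.0, 0.35, size=(cfg.n_genes, len(samples))))
    mrna_fpkm = pd.DataFrame(2.0 ** log2fpkm,
                             index=pd.Index(genes, name="gene"), columns=samples)

    # --- annotation and interactions --------------------------------------
    structures, gtf_lines = _gene_structures(cfg, rng)

    def _random_site(gene: str):
        struct = structures[gene]
        tids = sorted(struct["tx"])
        tid = tids[int(rng.integers(len(tids)))]
        length = _utr_length(struct, tid)
        start = int(rng.integers(1, length - _SITE_LEN + 2))
        return tid, start, start + _SITE_LEN - 1

    edge_rows, truth_edge_rows = [], []
    edge_pairs = set()
    for m in up_ids + dn_ids:
        for g in targets[m]:
            tid, s, e = _random_site(g)
            edge_rows.append((m, g, tid, s, e, 1.0, 1, 1, UTR_REGION))
            truth_edge_rows.append((m, g, tid, s, e))
            edge_pairs.add((m, g))

    # decoys target non-planted genes only, so true edges dominate every
    # component; fall back to non-edge pairs if no free genes remain
    truth_gene_set = onco_genes | supp_genes
    decoy_genes = [g for g in genes if g not in truth_gene_set] or genes
    total_pairs = cfg.n_mirna * len(decoy_genes)
    n_draw = min(total_pairs, cfg.decoy_interactions + len(edge_pairs) + 64)
    flat = rng.choice(total_pairs, size=n_draw, replace=False)
    decoy_rows = []
    for f in flat:
        if len(decoy_rows) >= cfg.decoy_interactions:
            break
        m, g = mirnas[f // len(decoy_genes)], decoy_genes[f % len(decoy_genes)]
        if (m, g) in edge_pairs:
            continue
        tid, s, e = _random_site(g)
        prob = float(rng.uniform(0.95, 1.0))
        decoy_rows.append((m, g, tid, s, e, prob,
                           int(rng.random() < 0.5), int(rng.random() < 0.5), UTR_REGION))
    interactions = pd.DataFrame(edge_rows + decoy_rows, columns=INTERACTION_COLUMNS)

    # --- essentiality ------------------------------------------------------
    cell_lines = [f"CL{j + 1}" for j in range(cfg.n_cell_lines)]
    es_mean_by_gene = np.zeros(cfg.n_genes)
    for g in onco_genes:
        es_mean_by_gene[gene_idx[g]] = cfg.ess_onco_mean / 2.0
    for g in supp_genes:
        es_mean_by_gene[gene_idx[g]] = cfg.ess_ts_mean / 2.0
    if prime_onco in onco_genes:
        es_mean_by_gene[gene_idx[prime_onco]] = cfg.ess_onco_mean
    if prime_supp in supp_genes:
        es_mean_by_gene[gene_idx[prime_supp]] = cfg.ess_ts_mean
    es = es_mean_by_gene[:, None] + rng.normal(0.0, 0.2, size=(cfg.n_genes, cfg.n_cell_lines))
    es[rng.random(es.shape) < 0.01] = np.nan  # sporadic missing screens
    essentiality = pd.DataFrame(es, index=pd.Index(genes, name="gene"),
                                columns=cell_lines)

    # --- survival cohort ---------------------------------------------------
    surv_samples = [f"S{i + 1:03d}" for i in range(cfg.n_survival)]
    u = rng.normal(size=cfg.n_survival)  # latent severity
    loading = np.zeros(cfg.n_genes)
    sign = np.zeros(cfg.n_genes)
    for g in onco_genes:
        loading[gene_idx[g]], sign[gene_idx[g]] = 0.45, 1.0
    for g in supp_genes:
        loading[gene_idx[g]], sign[gene_idx[g]] = 0.45, -1.0
    if prime_onco in onco_genes:
        loading[gene_idx[prime_onco]] = 0.9
    if prime_supp in supp_genes:
        loading[gene_idx[prime_supp]] = 0.9
    eps = rng.normal(size=(cfg.n_genes, cfg.n_survival))
    z = (loading * sign)[:, None] * u[None, :] + np.sqrt(1.0 - loading ** 2)[:, None] * eps
    surv_fpkm = pd.DataFrame(2.0 ** (z + 3.0), index=pd.Index(genes, name="gene"),
                             columns=surv_samples)

    base_hazard = 0.1
    hazard = base_hazard * np.exp(cfg.surv_beta * u)
    t_event = rng.exponential(1.0 / hazard)
    if cfg.censor_rate <= 0:
        time, event = t_event, np.ones(cfg.n_survival, dtype=int)
    elif cfg.censor_rate >= 1:
        time = rng.exponential(1.0 / base_hazard, size=cfg.n_survival)
        event = np.zeros(cfg.n_survival, dtype=int)
    else:
        lam_c = base_hazard * cfg.censor_rate / (1.0 - cfg.censor_rate)
        t_cens = rng.exponential(1.0 / lam_c, size=cfg.n_survival)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
    clinical = pd.DataFrame(
        {"time": time, "event": event}, index=pd.Index(surv_samples, name="sample_id")
    )

    # --- truth ledger ------------------------------------------------------
    truth_mirnas = pd.DataFrame(
        {"mirna": up_ids + dn_ids,
         "direction": ["UP"] * len(up_ids) + ["DN"] * len(dn_ids)}
    )
    truth_edges = pd.DataFrame(
        truth_edge_rows, columns=["mirna", "gene", "transcript", "site_start", "site_end"]
    )
    gene_rows = [
        {"gene": g, "label": "oncogene", "prime": g == prime_onco}
        for g in sorted(onco_genes)
    ] + [
        {"gene": g, "label": "suppressor", "prime": g == prime_supp}
        for g in sorted(supp_genes)
    ]
    truth_genes = pd.DataFrame(gene_rows, columns=["gene", "label", "prime"])

    return SyntheticDataset(
        config=cfg, mirna_counts=mirna_counts, mrna_fpkm=mrna_fpkm,
        interactions=interactions, gtf_lines=gtf_lines, essentiality=essentiality,
        surv_fpkm=surv_fpkm, clinical=clinical, truth_mirnas=truth_mirnas,
        truth_edges=truth_edges, truth_genes=truth_genes,
    )


_FILES = {
    "mirna_counts": "mirna_counts.tsv",
    "groups": "groups.tsv",
    "mrna_fpkm": "mrna_fpkm.tsv",
    "interactions": "interactions.csv",
    "annotation": "annotation.gtf",
    "essentiality": "essentiality.csv",
    "surv_fpkm": "surv_fpkm.tsv",
    "clinical": "clinical.tsv",
    "truth_mirnas": "truth_mirnas.tsv",
    "truth_edges": "truth_edges.tsv",
    "truth_genes": "truth_genes.tsv",
}


def write_dataset(ds: SyntheticDataset, directory) -> dict:
    """Write every dataset table (TSV/CSV/GTF) and return a manifest.

    The manifest maps logical names to file names and row counts; a round trip
    through :func:`load_dataset` reproduces the dataset exactly.
    """
    out = Path(directory)
    out.mkdir(parents=True, exist_ok=True)
    ds.mirna_counts.counts.to_csv(out / _FILES["mirna_counts"], sep="\t",
                                  index_label="feature")
    ds.mirna_counts.groups.rename_axis("sample").to_csv(out / _FILES["groups"], sep="\t")
    ds.mrna_fpkm.to_csv(out / _FILES["mrna_fpkm"], sep="\t", index_label="gene")
    ds.interactions.to_csv(out / _FILES["interactions"], index=False)
    (out / _FILES["annotation"]).write_text("\n".join(ds.gtf_lines) + "\n")
    ds.essentiality.to_csv(out / _FILES["essentiality"], index_label="gene")
    ds.surv_fpkm.to_csv(out / _FILES["surv_fpkm"], sep="\t", index_label="gene")
    ds.clinical.to_csv(out / _FILES["clinical"], sep="\t")
    ds.truth_mirnas.to_csv(out / _FILES["truth_mirnas"], sep="\t", index=False)
    ds.truth_edges.to_csv(out / _FILES["truth_edges"], sep="\t", index=False)
    ds.truth_genes.to_csv(out / _FILES["truth_genes"], sep="\t", index=False)

    rows = {
        "mirna_counts": len(ds.mirna_counts.counts),
        "groups": len(ds.mirna_counts.groups),
        "mrna_fpkm": len(ds.mrna_fpkm),
        "interactions": len(ds.interactions),
        "annotation": len(ds.gtf_lines),
        "essentiality": len(ds.essentiality),
        "surv_fpkm": len(ds.surv_fpkm),
        "clinical": len(ds.clinical),
        "truth_mirnas": len(ds.truth_mirnas),
        "truth_edges": len(ds.truth_edges),
        "truth_genes": len(ds.truth_genes),
    }
    manifest = {
        "config": asdict(ds.config),
        "files": {k: {"file": v, "rows": rows[k]} for k, v in _FILES.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=list))
    return manifest


def load_dataset(directory) -> SyntheticDataset:
    """Read back a written dataset (inverse of :func:`write_dataset`)."""
    d = Path(directory)
    manifest = json.loads((d / "manifest.json").read_text())
    cfg_dict = dict(manifest["config"])
    for key in ("baseline_cpm_range", "lib_size_range"):
        cfg_dict[key] = tuple(cfg_dict[key])
    cfg = SimConfig(**cfg_dict)
    groups = pd.read_csv(d / _FILES["groups"], sep="\t", index_col=0)["group"]
    counts = pd.read_csv(d / _FILES["mirna_counts"], sep="\t", index_col=0).astype(np.int64)
    gtf_lines = (d / _FILES["annotation"]).read_text().rstrip("\n").split("\n")
    return SyntheticDataset(
        config=cfg,
        mirna_counts=CountMatrix(counts=counts, groups=groups),
        mrna_fpkm=pd.read_csv(d / _FILES["mrna_fpkm"], sep="\t", index_col=0),
        interactions=pd.read_csv(d / _FILES["interactions"]),
        gtf_lines=gtf_lines,
        essentiality=pd.read_csv(d / _FILES["essentiality"], index_col=0),
        surv_fpkm=pd.read_csv(d / _FILES["surv_fpkm"], sep="\t", index_col=0),
        clinical=pd.read_csv(d / _FILES["clinical"], sep="\t", index_col=0),
        truth_mirnas=pd.read_csv(d / _FILES["truth_mirnas"], sep="\t"),
        truth_edges=pd.read_csv(d / _FILES["truth_edges"], sep="\t"),
        truth_genes=pd.read_csv(d / _FILES["truth_genes"], sep="\t"),
    )
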