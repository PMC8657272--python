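"""Predicted miRNA-mRNA interaction tables, meta-3'UTRs and site coordinate mapping.

Interaction tables arrive as CSV with transcript-relative 3'UTR site positions
(1-based inclusive, position 1 = first UTR nucleotide). Annotation is GTF
(1-based inclusive); all internal genomic intervals are 0-based half-open.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import CoordinateError, FormatError, LookupError_

__all__ = [
    "INTERACTION_COLUMNS",
    "MetaUTR",
    "Annotation",
    "read_interaction_table",
    "write_interaction_table",
    "binding_component",
    "read_gtf",
    "build_meta_utr",
    "map_site_to_genome",
    "filter_binding_sites",
    "collapse_interactions",
    "sites_to_bed",
]

INTERACTION_COLUMNS = [
    "mirna",
    "gene",
    "transcript",
    "site_start",
    "site_end",
    "binding_probability",
    "flag_targetscan",
    "flag_mirdb",
    "region",
]

UTR_REGION = "3UTR"


@dataclass
class MetaUTR:
    """Merged genomic union of all 3'UTR intervals of a gene's transcripts."""

    gene: str
    chrom: str
    strand: str
    blocks: list[tuple[int, int]]  # sorted, merged, 0-based half-open
    transcripts: list[str]

    def intersects(self, start: int, end: int) -> bool:
        return any(s < end and start < e for s, e in self.blocks)


def read_interaction_table(path) -> pd.DataFrame:
    """Parse the interaction CSV dialect; keep only 3'UTR records.

    The number of dropped non-3'UTR rows is recorded in
    ``df.attrs['n_dropped_non_utr']``. Malformed rows raise with row numbers.
    """
    df = pd.read_csv(path)
    missing = [c for c in INTERACTION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    df = df[INTERACTION_COLUMNS]
    bad = df.index[
        df["site_start"].isna()
        | df["site_end"].isna()
        | (df["site_start"] > df["site_end"])
        | (df["binding_probability"] < 0)
        | (df["binding_probability"] > 1)
        | ~df["flag_targetscan"].isin([0, 1])
        | ~df["flag_mirdb"].isin([0, 1])
    ]
    if len(bad):
        raise FormatError(f"{path}: malformed rows (0-based data rows): {list(bad[:10])}")
    keep = df["region"] == UTR_REGION
    out = df.loc[keep].reset_index(drop=True)
    out = out.astype(
        {"site_start": np.int64, "site_end": np.int64,
         "flag_targetscan": np.int64, "flag_mirdb": np.int64}
    )
    out.attrs["n_dropped_non_utr"] = int((~keep).sum())
    return out


def write_interaction_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=INTERACTION_COLUMNS)


def binding_component(binding_probability: float, flag_ts: int, flag_mirdb: int) -> float:
    """Combined binding score: (probability + two predictor flags) / 3.

    Records below the 0.95 probability threshold must have been excluded
    upstream; passing one is a precondition violation.
    """
    if binding_probability < 0.95 - 1e-12:
        raise ValueError(
            f"binding probability {binding_probability} below the 0.95 threshold"
        )
    return (binding_probability + flag_ts + flag_mirdb) / 3.0


_ATTR_RE = {
    "gene_id": re.compile(r'gene_id "([^"]+)"'),
    "transcript_id": re.compile(r'transcript_id "([^"]+)"'),
}


def read_gtf(path) -> "Annotation":
    """Read a GTF file into an :class:`Annotation` (exon + three_prime_utr rows)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}: expected 9 GTF columns, got {len(parts)}")
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = parts
            gid = _ATTR_RE["gene_id"].search(attrs)
            tid = _ATTR_RE["transcript_id"].search(attrs)
            rows.append(
                {
                    "chrom": chrom,
                    "feature": feature,
                    "start": int(start) - 1,  # to 0-based half-open
                    "end": int(end),
                    "strand": strand,
                    "gene_id": gid.group(1) if gid else None,
                    "transcript_id": tid.group(1) if tid else None,
                }
            )
    return Annotation(pd.DataFrame(rows))


class Annotation:
    """Transcript structure lookup over a parsed GTF table."""

    def __init__(self, table: pd.DataFrame) -> None:
        self.table = table
        utr = table[table["feature"] == "three_prime_utr"]
        self._utr_by_tx = {tid: g for tid, g in utr.groupby("transcript_id")}
        self._tx_by_gene = {
            gid: sorted(g["transcript_id"].dropna().unique())
            for gid, g in utr.groupby("gene_id")
        }
        self._genes = set(table["gene_id"].dropna().unique())

    def transcripts_of(self, gene_id: str) -> list[str]:
        if gene_id not in self._genes:
            raise LookupError_(f"gene {gene_id!r} absent from annotation")
        return self._tx_by_gene.get(gene_id, [])

    def utr_blocks(self, transcript_id: str) -> tuple[str, str, list[tuple[int, int]]]:
        """UTR blocks of a transcript in transcript (5'->3') order.

        Returns (chrom, strand, blocks); each block is 0-based half-open. For
        minus-strand transcripts blocks are ordered by descending genomic
        coordinate (the UTR is read from high to low positions).
        """
        if transcript_id not in self._utr_by_tx:
            raise LookupError_(f"transcript {transcript_id!r} has no annotated 3'UTR")
        g = self._utr_by_tx[transcript_id]
        chrom = g["chrom"].iloc[0]
        strand = g["strand"].iloc[0]
        blocks = sorted(zip(g["start"], g["end"]), key=lambda b: b[0],
                        reverse=(strand == "-"))
        return chrom, strand, [(int(s), int(e)) for s, e in blocks]

    def gene_of(self, transcript_id: str) -> str:
        g = self._utr_by_tx.get(transcript_id)
        if g is None:
            raise LookupError_(f"unknown transcript {transcript_id!r}")
        return g["gene_id"].iloc[0]


def _merge_intervals(ivals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(ivals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def build_meta_utr(gene_id: str, annotation: Annotation) -> MetaUTR:
    """Union of all transcripts' 3'UTR genomic intervals, merged and sorted."""
    tx = annotation.transcripts_of(gene_id)
    if not tx:
        raise LookupError_(f"gene {gene_id!r} has no transcript with a 3'UTR")
    ivals: list[tuple[int, int]] = []
    chrom = strand = None
    for tid in tx:
        c, s, blocks = annotation.utr_blocks(tid)
        chrom, strand = c, s
        ivals.extend(blocks)
    return MetaUTR(
        gene=gene_id, chrom=chrom, strand=strand,
        blocks=_merge_intervals(ivals), transcripts=list(tx),
    )


def map_site_to_genome(
    transcript_id: str,
    site_start: int,
    site_end: int,
    annotation: Annotation,
) -> list[tuple[str, int, int]]:
    """Map 1-based inclusive UTR-relative positions to genomic intervals.

    Walks the transcript's UTR blocks in transcript order; sites spanning a
    block junction yield multiple intervals. Total mapped length equals
    ``site_end - site_start + 1``.
    """
    if site_start < 1 or site_end < site_start:
        raise CoordinateError(f"invalid site {site_start}..{site_end}")
    chrom, strand, blocks = annotation.utr_blocks(transcript_id)
    total = sum(e - s for s, e in blocks)
    if site_end > total:
        raise CoordinateError(
            f"site end {site_end} beyond UTR length {total} of {transcript_id}"
        )
    lo = site_start - 1  # 0-based half-open within the UTR
    hi = site_end
    out: list[tuple[str, int, int]] = []
    offset = 0
    for s, e in blocks:
        blen = e - s
        a = max(lo - offset, 0)
        b = min(hi - offset, blen)
        if a < b:
            if strand == "+":
                out.append((chrom, s + a, s + b))
            else:
                out.append((chrom, e - b, e - a))
        offset += blen
        if offset >= hi:
            break
    return out


def collapse_interactions(df: pd.DataFrame) -> pd.DataFrame:
    """One record per (miRNA, gene) pair, keeping the max binding probability.

    Ties resolve to the first occurrence in input order.
    """
    idx = df.groupby(["mirna", "gene"], sort=False)["binding_probability"].idxmax()
    return df.loc[idx.to_numpy()].reset_index(drop=True)


def filter_binding_sites(
    df: pd.DataFrame,
    cpm_values: pd.DataFrame,
    annotation: Annotation,
    prob_exact: float = 1.0,
    min_avg_cpm: float = 100.0,
) -> pd.DataFrame:
    """Stringent site filter for locus summaries.

    Keeps records with binding probability equal to ``prob_exact``, a targeting
    miRNA whose mean CPM exceeds ``min_avg_cpm``, and a mapped site that
    intersects the gene's meta-3'UTR. Mapped intervals are attached as a
    ``blocks`` column of (chrom, start, end) lists.
    """
    mean_cpm = cpm_values.mean(axis=1)
    keep_rows = []
    blocks_col = []
    meta_cache: dict[str, MetaUTR] = {}
    for row in df.itertuples():
        if abs(row.binding_probability - prob_exact) > 1e-12:
            continue
        if row.mirna not in mean_cpm.index or mean_cpm[row.mirna] <= min_avg_cpm:
            continue
        try:
            blocks = map_site_to_genome(
                row.transcript, row.site_start, row.site_end, annotation
            )
        except (CoordinateError, LookupError_):
            continue
        meta = meta_cache.get(row.gene)
        if meta is None:
            try:
                meta = build_meta_utr(row.gene, annotation)
            except LookupError_:
                continue
            meta_cache[row.gene] = meta
        if any(meta.intersects(s, e) for _c, s, e in blocks):
            keep_rows.append(row.Index)
            blocks_col.append(blocks)
    out = df.loc[keep_rows].copy()
    out["blocks"] = blocks_col
    return out


def sites_to_bed(filtered: pd.DataFrame, path) -> None:
    """Write mapped binding sites as BED6 (one line per genomic block)."""
    with open(path, "w") as fh:
        for row in filtered.itertuples():
            for chrom, s, e in row.blocks:
                name = f"{row.mirna}|{row.gene}|{row.transcript}"
                strand = "."
                fh.write(f"{chrom}\t{s}\t{e}\t{name}\t0\t{strand}\n")
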