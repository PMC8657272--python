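import numpy as np
import pandas as pd
import pytest

from oracles import enumerate_utr_nucleotides, intervals_from_positions

from miriscore.errors import CoordinateError, FormatError, LookupError_
from miriscore.interactions import (
    Annotation,
    binding_component,
    build_meta_utr,
    collapse_interactions,
    filter_binding_sites,
    map_site_to_genome,
    read_gtf,
    read_interaction_table,
    write_interaction_table,
)

HEADER = ("mirna,gene,transcript,site_start,site_end,"
          "binding_probability,flag_targetscan,flag_mirdb,region")


def _write_csv(tmp_path, rows):
    p = tmp_path / "inter.csv"
    p.write_text(HEADER + "\n" + "\n".join(rows) + "\n")
    return p


class TestReadInteractionTable:
    def test_three_rows(self, tmp_path):
        p = _write_csv(tmp_path, [
            "mirA,G1,G1.t1,5,11,0.97,1,0,3UTR",
            "mirA,G2,G2.t1,8,14,1.0,1,1,3UTR",
            "mirB,G1,G1.t1,20,26,0.95,0,1,3UTR",
        ])
        df = read_interaction_table(p)
        assert len(df) == 3
        assert df.attrs["n_dropped_non_utr"] == 0

    def test_cds_row_dropped_and_counted(self, tmp_path):
        p = _write_csv(tmp_path, [
            "mirA,G1,G1.t1,5,11,0.97,1,0,3UTR",
            "mirA,G3,G3.t1,2,8,0.99,1,1,CDS",
        ])
        df = read_interaction_table(p)
        assert len(df) == 1
        assert df.attrs["n_dropped_non_utr"] == 1

    def test_missing_column_raises(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("mirna,gene\nmirA,G1\n")
        with pytest.raises(FormatError):
            read_interaction_table(p)

    def test_malformed_row_raises_with_row_number(self, tmp_path):
        p = _write_csv(tmp_path, [
            "mirA,G1,G1.t1,5,11,0.97,1,0,3UTR",
            "mirA,G2,G2.t1,14,8,1.0,1,1,3UTR",  # start > end
        ])
        with pytest.raises(FormatError, match="1"):
            read_interaction_table(p)

    def test_round_trip(self, tmp_path, default_dataset):
        p = tmp_path / "rt.csv"
        write_interaction_table(default_dataset.interactions, p)
        back = read_interaction_table(p)
        pd.testing.assert_frame_equal(
            back, default_dataset.interactions, check_dtype=False
        )

    def test_empty_table_round_trip(self, tmp_path):
        p = tmp_path / "empty.csv"
        from miriscore.interactions import INTERACTION_COLUMNS

        write_interaction_table(pd.DataFrame(columns=INTERACTION_COLUMNS), p)
        assert len(read_interaction_table(p)) == 0


class TestBindingComponent:
    def test_stated_maximum(self):
        assert binding_component(1.0, 1, 1) == pytest.approx(1.0)

    def test_direct_arithmetic(self):
        assert binding_component(0.95, 1, 0) == pytest.approx(0.65)

    def test_below_threshold_rejected(self):
        with pytest.raises(ValueError):
            binding_component(0.94, 1, 1)


class TestBuildMetaUtr:
    def test_single_transcript(self, toy_gtf):
        ann = read_gtf(toy_gtf)
        meta = build_meta_utr("GPLUS", ann)
        assert meta.blocks == [(1000, 1200)]

    def test_overlapping_transcripts_merged(self, toy_gtf):
        ann = read_gtf(toy_gtf)
        meta = build_meta_utr("GMETA", ann)
        assert meta.blocks == [(1000, 1300)]

    def test_disjoint_utrs_two_sorted_blocks(self, toy_gtf):
        ann = read_gtf(toy_gtf)
        meta = build_meta_utr("GDISJ", ann)
        assert meta.blocks == [(5000, 5100), (6000, 6100)]

    def test_unknown_gene_raises(self, toy_gtf):
        with pytest.raises(LookupError_):
            build_meta_utr("NOPE", read_gtf(toy_gtf))

    def test_idempotent_and_order_invariant(self, toy_gtf):
        ann = read_gtf(toy_gtf)
        a = build_meta_utr("GMETA", ann)
        b = build_meta_utr("GMETA", ann)
        assert a.blocks == b.blocks


class TestMapSiteToGenome:
    def test_plus_strand_offset(self, toy_gtf):
        ann = read_gtf(toy_gtf)
        # UTR starts at genomic 1000 (0-based); site 11..17 1-based inclusive
        assert map_site_to_genome("GPLUS.t1", 11, 17, ann) == [("chr1", 1010, 1017)]

    def test_minus_strand_matches_enumeration_oracle(self, toy_gtf):
        ann = read_gtf(toy_gtf)
        chrom, strand, blocks = ann.utr_blocks("GMINUS.t1")
        nucs = enumerate_utr_nucleotides(blocks, strand)
        for start, end in [(1, 7), (5, 30), (140, 150)]:
            expected = intervals_from_positions(chrom, nucs[start - 1:end])
            assert map_site_to_genome("GMINUS.t1", start, end, ann) == expected

    def test_junction_straddling_site_two_blocks(self, toy_gtf):
        ann = read_gtf(toy_gtf)
        # GSPLIT UTR: [3000,3050) then [3100,3180); site 48..55 spans junction
        blocks = map_site_to_genome("GSPLIT.t1", 48, 55, ann)
        assert blocks == [("chr1", 3047, 3050), ("chr1", 3100, 3105)]
        assert sum(e - s for _c, s, e in blocks) == 55 - 48 + 1

    def test_site_beyond_utr_raises(self, toy_gtf):
        ann = read_gtf(toy_gtf)
        with pytest.raises(CoordinateError):
            map_site_to_genome("GPLUS.t1", 195, 205, ann)

    @pytest.mark.parametrize("seed", range(20))
    def test_length_conservation_random(self, seed, default_dataset):
        ann = default_dataset.annotation
        rng = np.random.default_rng(seed)
        edges = default_dataset.truth_edges
        row = edges.iloc[int(rng.integers(len(edges)))]
        blocks = map_site_to_genome(row.transcript, row.site_start, row.site_end, ann)
        assert sum(e - s for _c, s, e in blocks) == row.site_end - row.site_start + 1


class TestCollapseAndFilter:
    def test_collapse_keeps_max_probability(self):
        df = pd.DataFrame(
            {"mirna": ["m1", "m1", "m2"], "gene": ["g1", "g1", "g1"],
             "transcript": ["t1", "t2", "t1"], "site_start": [1, 5, 9],
             "site_end": [7, 11, 15], "binding_probability": [0.96, 0.99, 0.95],
             "flag_targetscan": [1, 0, 1], "flag_mirdb": [0, 1, 1],
             "region": ["3UTR"] * 3}
        )
        out = collapse_interactions(df)
        assert len(out) == 2
        m1 = out[out["mirna"] == "m1"].iloc[0]
        assert m1["binding_probability"] == 0.99
        assert m1["transcript"] == "t2"

    def test_probability_below_exact_excluded(self, default_dataset, pipeline_results):
        ann = default_dataset.annotation
        df = default_dataset.interactions
        filtered = filter_binding_sites(df, pipeline_results["cpm"], ann)
        assert (filtered["binding_probability"] == 1.0).all()

    def test_triple_filter_matches_brute_force(self, default_dataset, pipeline_results):
        ann = default_dataset.annotation
        df = default_dataset.interactions
        cpm_vals = pipeline_results["cpm"]
        filtered = filter_binding_sites(df, cpm_vals, ann)
        # independent recomputation of the three gates
        mean_cpm = {m: float(cpm_vals.loc[m].mean()) for m in cpm_vals.index}
        expected_idx = []
        for i, row in df.iterrows():
            if row["binding_probability"] != 1.0:
                continue
            if mean_cpm.get(row["mirna"], 0.0) <= 100.0:
                continue
            blocks = map_site_to_genome(row["transcript"], row["site_start"],
                                        row["site_end"], ann)
            meta = build_meta_utr(row["gene"], ann)
            hit = any(
                ms < e and s < me
                for _c, s, e in blocks for ms, me in meta.blocks
            )
            if hit:
                expected_idx.append(i)
        assert list(filtered.index) == expected_idx

    def test_retained_sites_intersect_meta_utr(self, default_dataset, pipeline_results):
        ann = default_dataset.annotation
        filtered = filter_binding_sites(
            default_dataset.interactions, pipeline_results["cpm"], ann
        )
        for row in filtered.itertuples():
            meta = build_meta_utr(row.gene, ann)
            assert any(meta.intersects(s, e) for _c, s, e in row.blocks)
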