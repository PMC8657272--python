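import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from miriscore.expression_io import CountMatrix
from miriscore.pipeline import make_truth_gene_sets, run_pipeline
from miriscore.synthetic import SimConfig, generate_cohort


def make_count_matrix(counts, groups=None, samples=None, features=None, lib_sizes=None):
    counts = np.asarray(counts)
    n_feat, n_samp = counts.shape
    samples = samples or [f"s{j}" for j in range(n_samp)]
    features = features or [f"f{i}" for i in range(n_feat)]
    groups = groups or ["A"] * (n_samp // 2) + ["B"] * (n_samp - n_samp // 2)
    ls = None
    if lib_sizes is not None:
        ls = pd.Series(lib_sizes, index=samples)
    return CountMatrix(
        counts=pd.DataFrame(counts, index=features, columns=samples),
        groups=pd.Series(groups, index=samples),
        lib_sizes=ls,
    )


@pytest.fixture(scope="session")
def default_dataset():
    return generate_cohort(SimConfig(seed=1))


@pytest.fixture(scope="session")
def pipeline_results(default_dataset):
    sets = make_truth_gene_sets(default_dataset)
    return run_pipeline(default_dataset, gene_sets=sets, n_perm=300, gsea_seed=1)


@pytest.fixture()
def toy_gtf(tmp_path):
    """Small plus/minus strand annotation incl. a junction-split UTR."""
    lines = [
        # GPLUS: single transcript, single-exon UTR at [1000, 1200)
        'chr1\tt\tgene\t1001\t1200\t.\t+\t.\tgene_id "GPLUS";',
        'chr1\tt\ttranscript\t1001\t1200\t.\t+\t.\tgene_id "GPLUS"; transcript_id "GPLUS.t1";',
        'chr1\tt\texon\t1001\t1200\t.\t+\t.\tgene_id "GPLUS"; transcript_id "GPLUS.t1";',
        'chr1\tt\tthree_prime_utr\t1001\t1200\t.\t+\t.\tgene_id "GPLUS"; transcript_id "GPLUS.t1";',
        # GMINUS: single transcript, single-exon UTR at [2000, 2150) on -
        'chr1\tt\tgene\t2001\t2150\t.\t-\t.\tgene_id "GMINUS";',
        'chr1\tt\ttranscript\t2001\t2150\t.\t-\t.\tgene_id "GMINUS"; transcript_id "GMINUS.t1";',
        'chr1\tt\texon\t2001\t2150\t.\t-\t.\tgene_id "GMINUS"; transcript_id "GMINUS.t1";',
        'chr1\tt\tthree_prime_utr\t2001\t2150\t.\t-\t.\tgene_id "GMINUS"; transcript_id "GMINUS.t1";',
        # GSPLIT: UTR split over two exons [3000,3050) + [3100,3180) on +
        'chr1\tt\tgene\t3001\t3180\t.\t+\t.\tgene_id "GSPLIT";',
        'chr1\tt\ttranscript\t3001\t3180\t.\t+\t.\tgene_id "GSPLIT"; transcript_id "GSPLIT.t1";',
        'chr1\tt\texon\t3001\t3050\t.\t+\t.\tgene_id "GSPLIT"; transcript_id "GSPLIT.t1";',
        'chr1\tt\texon\t3101\t3180\t.\t+\t.\tgene_id "GSPLIT"; transcript_id "GSPLIT.t1";',
        'chr1\tt\tthree_prime_utr\t3001\t3050\t.\t+\t.\tgene_id "GSPLIT"; transcript_id "GSPLIT.t1";',
        'chr1\tt\tthree_prime_utr\t3101\t3180\t.\t+\t.\tgene_id "GSPLIT"; transcript_id "GSPLIT.t1";',
        # GMETA: two transcripts with overlapping UTRs [1000,1200) and [1150,1300)
        'chr2\tt\tgene\t1001\t1300\t.\t+\t.\tgene_id "GMETA";',
        'chr2\tt\ttranscript\t1001\t1200\t.\t+\t.\tgene_id "GMETA"; transcript_id "GMETA.t1";',
        'chr2\tt\tthree_prime_utr\t1001\t1200\t.\t+\t.\tgene_id "GMETA"; transcript_id "GMETA.t1";',
        'chr2\tt\ttranscript\t1151\t1300\t.\t+\t.\tgene_id "GMETA"; transcript_id "GMETA.t2";',
        'chr2\tt\tthree_prime_utr\t1151\t1300\t.\t+\t.\tgene_id "GMETA"; transcript_id "GMETA.t2";',
        # GDISJ: two transcripts with disjoint UTRs
        'chr2\tt\tgene\t5001\t6100\t.\t+\t.\tgene_id "GDISJ";',
        'chr2\tt\ttranscript\t5001\t5100\t.\t+\t.\tgene_id "GDISJ"; transcript_id "GDISJ.t1";',
        'chr2\tt\tthree_prime_utr\t5001\t5100\t.\t+\t.\tgene_id "GDISJ"; transcript_id "GDISJ.t1";',
        'chr2\tt\ttranscript\t6001\t6100\t.\t+\t.\tgene_id "GDISJ"; transcript_id "GDISJ.t2";',
        'chr2\tt\tthree_prime_utr\t6001\t6100\t.\t+\t.\tgene_id "GDISJ"; transcript_id "GDISJ.t2";',
    ]
    path = tmp_path / "toy.gtf"
    path.write_text("\n".join(lines) + "\n")
    return path
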