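import numpy as np
import pandas as pd
import pytest

from restogen import CohortGL, SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def two_herd_cohort():
    """Two differentiated source herds, low-coverage GBS likelihoods."""
    cfg = SimConfig(n_sources=2, F=0.07, n_loci=800, sample_size=12,
                    mean_depth=6, seed=101)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def demo_ledger():
    return pd.DataFrame([
        {"source": "S1", "destination": "D1", "year": 1980, "count": 12},
        {"source": "S2", "destination": "D1", "year": 1982, "count": 12},
    ])


@pytest.fixture()
def tiny_cohort():
    """Hand-built 3-individual, 2-locus cohort with exact likelihoods."""
    gl = np.array([
        [[1.0, 1e-3, 1e-6], [1.0, 1.0, 1.0]],
        [[1e-3, 1.0, 1e-3], [1.0, 1e-2, 1e-4]],
        [[1e-6, 1e-3, 1.0], [1e-4, 1e-2, 1.0]],
    ])
    depth = np.array([[10, 0], [8, 6], [12, 9]])
    return CohortGL(
        individual_ids=["a", "b", "c"],
        locus_ids=["chr1:100", "chr2:50"],
        unit_of={"a": "U1", "b": "U1", "c": "U2"},
        gl=gl,
        depth=depth,
    )


def write_test_vcf(path, pl_rows, samples=("s1", "s2", "s3")):
    """Write a minimal VCF with PL and DP fields for the given records."""
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=PL,Number=G,Type=Integer,Description="Phred likelihoods">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    for (chrom, pos, alt), pls, dps in pl_rows:
        cells = [f"{p[0]},{p[1]},{p[2]}:{d}" for p, d in zip(pls, dps)]
        lines.append(f"{chrom}\t{pos}\t.\tA\t{alt}\t.\tPASS\t.\tPL:DP\t" + "\t".join(cells))
    path.write_text("\n".join(lines) + "\n")
    return path
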