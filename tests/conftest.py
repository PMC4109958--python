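import numpy as np
import pytest

from hstlkit import published
from hstlkit.karyotype import KaryotypeRecord
from hstlkit.simulate import CohortConfig, gen_expression


@pytest.fixture(scope="session")
def table1_records():
    """The nine cohort karyotype records (printed case table fixture)."""
    return [
        KaryotypeRecord.from_strings(cid, kt, flags)
        for cid, kt, flags in published.TABLE1_CASES
    ]


@pytest.fixture(scope="session")
def small_cohort():
    """A small planted cohort shared by expression-level tests."""
    config = CohortConfig(
        seed=11,
        n_genes=400,
        n_reference_samples=6,
        n_hstl_samples=6,
        n_cdr_genes=20,
        n_cgr_genes=20,
        n_chr8_genes=10,
    )
    return config, gen_expression(config)


def bp_coverage(segments, chromosome, states, grid_size):
    """Brute-force per-base sample-count oracle on a small coordinate grid."""
    cover = {}
    for seg in segments:
        if seg.chromosome != chromosome or seg.state not in states:
            continue
        for bp in range(seg.start_bp, min(seg.end_bp, grid_size) + 1):
            cover.setdefault(bp, set()).add(seg.sample_id)
    counts = np.zeros(grid_size + 1, dtype=int)
    for bp, samples in cover.items():
        counts[bp] = len(samples)
    return counts


def runs_at_least(counts, threshold):
    """Maximal [start, end] runs where the per-bp count >= threshold."""
    runs, start = [], None
    for bp in range(1, len(counts)):
        if counts[bp] >= threshold and start is None:
            start = bp
        elif counts[bp] < threshold and start is not None:
            runs.append((start, bp - 1))
            start = None
    if start is not None:
        runs.append((start, len(counts) - 1))
    return runs
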