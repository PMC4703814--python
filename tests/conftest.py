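"""Shared fixtures: small simulated datasets with known ground truth."""

import numpy as np
import pytest

from massdiv.readqc import demultiplex, filter_reads
from massdiv.seqsim import (CommunitySpec, ErrorModel, default_references,
                            generate_dataset)


@pytest.fixture(scope="session")
def clean_dataset():
    """Error-free 4-site, 15-OTU community (240 reads) plus truth."""
    spec = CommunitySpec(n_sites=4, n_otus=15, reads_per_site=60, seed=11)
    refs = default_references(15, seed=11)
    reads, truth = generate_dataset(spec, ErrorModel.none(), refs)
    return spec, refs, reads, truth


@pytest.fixture(scope="session")
def clean_demuxed(clean_dataset):
    """The clean dataset demultiplexed and QC-filtered."""
    spec, refs, reads, truth = clean_dataset
    barcode_map = {bc: s for s, bc in truth.attrs["barcodes"].items()}
    demuxed = demultiplex(reads, barcode_map)
    kept, report = filter_reads(demuxed)
    return spec, refs, kept, report, truth


@pytest.fixture(scope="session")
def random_otu_table():
    """A reproducible random 12-site x 60-OTU count table."""
    import pandas as pd
    rng = np.random.default_rng(99)
    counts = rng.integers(0, 8, size=(12, 60))
    counts[rng.random(counts.shape) < 0.5] = 0
    counts[:, 0] += 1  # no all-zero site
    return pd.DataFrame(counts, index=[f"S{i:02d}" for i in range(12)],
                        columns=[f"OTU#{j + 1}" for j in range(60)])
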