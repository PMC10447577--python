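"""Shared fixtures: synthetic bundles and their derived pipeline products.

Everything is generated in-process from seeded configs; no files ship with
the test suite. Session scope keeps the 8000-gene default bundle to a single
generation per run.
"""

from __future__ import annotations

import numpy as np
import pytest

from poised_omics import differential, integration, ruler, synthetic_data
from poised_omics.io_tables import filter_artifacts, filter_replicate_presence


@pytest.fixture(scope="session")
def default_ds() -> synthetic_data.SyntheticDataset:
    """Default study-condition bundle: 8000 genes, 4 subsets x 4 replicates."""
    return synthetic_data.generate_dataset(synthetic_data.SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def default_cn(default_ds) -> ruler.CopyNumberMatrix:
    prot = filter_artifacts(default_ds.protein_groups)
    cn = ruler.estimate_copy_numbers(prot, default_ds.ruler_config())
    return filter_replicate_presence(cn)


@pytest.fixture(scope="session")
def default_integrated(default_ds, default_cn) -> integration.IntegratedGeneTable:
    return integration.merge_omics(default_cn, default_ds.transcripts, default_ds.mapping)


@pytest.fixture(scope="session")
def default_norm(default_cn) -> differential.NormalizedMatrix:
    return differential.normalize_and_log(default_cn)


@pytest.fixture(scope="session")
def small_ds() -> synthetic_data.SyntheticDataset:
    """A fast 800-gene bundle for file round-trips and pipeline wiring."""
    return synthetic_data.generate_dataset(
        synthetic_data.SyntheticConfig(n_genes=800, gene_set_size=40, poised_set_size=15, seed=7)
    )


@pytest.fixture(scope="session")
def small_cn(small_ds) -> ruler.CopyNumberMatrix:
    prot = filter_artifacts(small_ds.protein_groups)
    return filter_replicate_presence(ruler.estimate_copy_numbers(prot, small_ds.ruler_config()))


def truth_rows(ds, cn) -> np.ndarray:
    """gene_id per copy-number row, via the generator's accession table."""
    by_acc = dict(zip(ds.truth.genes["accession"], ds.truth.genes.index))
    return np.array([by_acc.get(a) for a in cn.meta["lead_protein_id"]])
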