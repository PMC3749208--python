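import numpy as np
import pytest

import omzplume as oz


@pytest.fixture(scope="session")
def small_taxonomy():
    """2x2x2 taxonomy: 8 leaves, 15 nodes, rank-structured divergence."""
    spec = oz.TaxonomySpec(
        ranks=("phylum", "genus", "species"),
        children_per_rank=(2, 2, 2),
        divergence_per_rank=(0.10, 0.05, 0.01),
        seq_length=600,
        seed=7,
    )
    tree, refs = oz.make_reference_taxonomy(spec)
    return spec, tree, refs


@pytest.fixture(scope="session")
def deep_taxonomy():
    """Five-rank taxonomy used for lineage-mismatch and calibration checks."""
    spec = oz.TaxonomySpec(
        ranks=("class", "order", "family", "genus", "species"),
        children_per_rank=(2, 2, 2, 5, 5),
        divergence_per_rank=(0.10, 0.06, 0.04, 0.02, 0.01),
        seq_length=600,
        seed=42,
    )
    tree, refs = oz.make_reference_taxonomy(spec)
    return spec, tree, refs


def make_record(rid, bases, molecule="DNA", sample="S", depth=0.0):
    return oz.SequenceRecord(id=rid, sample_id=sample, depth=depth, molecule=molecule, bases=bases)


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
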