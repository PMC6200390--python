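import numpy as np
import pytest

from microbiability import OtuTable, Pedigree, SimConfig


@pytest.fixture
def toy_pedigree():
    """Two founders, two full sibs, and an offspring of the full-sib mating."""
    return Pedigree.from_records([
        ("A", None, None),
        ("B", None, None),
        ("C", "A", "B"),
        ("D", "A", "B"),
        ("E", "C", "D"),
    ])


@pytest.fixture
def small_config():
    """Scaled-down herd for fast end-to-end tests (~110 cows, 180 taxa)."""
    return SimConfig(
        n_founders=110, n_generations=2, offspring_per_mating=2, n_sires=8,
        n_bact_otus=150, n_arch_otus=30, mean_library_size=80_000,
        frac_low_depth_samples=0.1, seed=7)


@pytest.fixture
def tiny_table():
    """Hand-sized OTU table: 4 taxa x 4 samples, two platforms."""
    counts = np.array([
        [100, 200, 50, 400],
        [900, 700, 800, 500],
        [0, 90, 120, 80],
        [5, 10, 30, 20],
    ])
    return OtuTable(
        counts,
        taxon_ids=["t1", "t2", "t3", "t4"],
        sample_ids=["s1", "s2", "s3", "s4"],
        taxonomy=[
            "k__Bacteria; p__P1; f__FamX; g__GenA",
            "k__Bacteria; p__P1; f__FamX; g__GenA",
            "k__Bacteria; p__P2; f__FamY; g__",
            "k__Archaea; p__P3; f__FamZ; g__GenB",
        ],
        platform=np.array(["MiSeq", "MiSeq", "HiSeq", "HiSeq"], dtype=object),
        batch=np.array(["MiSeq_b0", "MiSeq_b0", "HiSeq_b1", "HiSeq_b1"],
                       dtype=object),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
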