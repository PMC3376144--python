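import numpy as np
import pytest

from methylpred import (
    EncoderConfig,
    build_bundle,
    make_fixture,
    read_property_table,
)
from methylpred.dataset import PeptideWindow


@pytest.fixture(scope="session")
def table():
    return read_property_table()


@pytest.fixture(scope="session")
def small_dataset():
    return make_fixture("small", seed=11)


@pytest.fixture(scope="session")
def small_bundle(small_dataset):
    ds = small_dataset
    return build_bundle(ds.proteins, ds.sites, "R", ratio=1, n_sets=5, seed=11)


@pytest.fixture(scope="session")
def signal_bundle():
    """Standard-scale dataset with full planted signal, ratio 1:1."""
    ds = make_fixture("standard", signal=True, seed=11)
    return build_bundle(ds.proteins, ds.sites, "R", ratio=1, n_sets=5, seed=11)


@pytest.fixture(scope="session")
def null_bundle():
    """Standard-scale dataset with every planted difference switched off."""
    ds = make_fixture("standard", signal=False, seed=11)
    return build_bundle(ds.proteins, ds.sites, "R", ratio=1, n_sets=5, seed=11)


@pytest.fixture(scope="session")
def signal_windows():
    """Deduplicated positive/negative windows of the signal dataset."""
    from methylpred.dataset import deduplicate, enumerate_candidates

    ds = make_fixture("standard", signal=True, seed=11)
    pos, neg = enumerate_candidates(ds.proteins, ds.sites, "R", L=7)
    reduced = deduplicate(pos + neg)
    return (
        [w for w in reduced if w.label == "positive"],
        [w for w in reduced if w.label == "negative"],
    )


@pytest.fixture(scope="session")
def default_config(table):
    return EncoderConfig(property_table=table)


def random_window(rng: np.random.Generator, L: int = 7, with_asa: bool = True):
    """A random peptide window: R/K center, optional terminal pads and ASA."""
    n = 2 * L + 1
    residues = list("ACDEFGHIKLMNPQRSTVWY")
    seq = [str(rng.choice(residues)) for _ in range(n)]
    seq[L] = str(rng.choice(["R", "K"]))
    left_pad = int(rng.integers(0, L + 1))
    right_pad = int(rng.integers(0, L + 1))
    for i in range(left_pad):
        seq[i] = "X"
    for i in range(right_pad):
        seq[n - 1 - i] = "X"
    asa = None
    if with_asa:
        asa = tuple(
            0.0 if c == "X" else float(rng.uniform(0, 100)) for c in seq
        )
    return PeptideWindow(
        sequence="".join(seq),
        label=str(rng.choice(["positive", "negative"])),
        protein_id="rand",
        position=L + 1,
        asa=asa,
    )
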