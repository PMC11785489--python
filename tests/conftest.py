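import warnings

import numpy as np
import pytest

import tcrfate as tf

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def gene_table():
    return tf.load_bundled_gene_table()


@pytest.fixture(scope="session")
def registry():
    return tf.build_registry()


@pytest.fixture(scope="session")
def small_sim():
    """A small multi-donor repertoire shared by read-only tests."""
    cfg = tf.SimConfig(n_donors=5, cells_per_donor=200, public_rate=0.02)
    return tf.simulate_repertoire(cfg, seed=11)


def make_pair(
    cell_id="cell1",
    donor="D1",
    va="TRAV12-2",
    ja="TRAJ45",
    vb="TRBV28",
    jb="TRBJ1-5",
    cdr3a="CAVKNAGNKLTF",
    cdr3b="CASRGTGLGNQPQHF",
):
    return tf.PairedTcr(
        cell_id=cell_id,
        donor_id=donor,
        alpha=tf.TcrChain(cell_id, "alpha", va, ja, cdr3a, True),
        beta=tf.TcrChain(cell_id, "beta", vb, jb, cdr3b, True),
    )


@pytest.fixture
def toy_pair():
    return make_pair()
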