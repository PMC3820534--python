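import numpy as np
import pytest

from isomil.containers import BagMap, ExpressionMatrix
from isomil.gold_standard import TermGoldStandard
from isomil.mil_core import MILConfig
from isomil.synthetic_data import SynthConfig, generate_term_dataset


@pytest.fixture(scope="session")
def small_synth():
    """A small but non-trivial planted-witness dataset shared across tests."""
    cfg = SynthConfig(
        n_pos_genes=12, n_neg_genes=120, n_experiments=40,
        signature_dim=12, seed=7,
    )
    return generate_term_dataset(cfg)


@pytest.fixture(scope="session")
def default_synth():
    """One dataset at the full default study conditions."""
    return generate_term_dataset(SynthConfig(seed=7))


@pytest.fixture
def tiny_problem():
    """Hand-sized separable problem: 2 positive genes x 2 isoforms, 6 negatives."""
    rng = np.random.default_rng(0)
    bags = BagMap({
        "gp1": ("gp1.a", "gp1.b"),
        "gp2": ("gp2.a", "gp2.b"),
        "gn1": ("gn1.a",), "gn2": ("gn2.a",), "gn3": ("gn3.a",),
        "gn4": ("gn4.a",), "gn5": ("gn5.a",), "gn6": ("gn6.a",),
    })
    n_exp = 6
    rows = {}
    for iso in bags.isoforms:
        rows[iso] = rng.normal(0, 1, n_exp)
    # witnesses: first isoform of each positive gene, shifted in first 3 columns
    rows["gp1.a"][:3] += 4
    rows["gp2.a"][:3] += 4
    matrix = ExpressionMatrix(
        isoform_ids=tuple(bags.isoforms),
        experiment_ids=tuple(f"e{j}" for j in range(n_exp)),
        values=np.vstack([rows[i] for i in bags.isoforms]),
        space="log2",
    )
    standard = TermGoldStandard(
        term_id="GO:TINY",
        positives=frozenset({"gp1", "gp2"}),
        negatives=frozenset({"gn1", "gn2", "gn3", "gn4", "gn5", "gn6"}),
    )
    return matrix, bags, standard


@pytest.fixture
def fast_config():
    return MILConfig(seed=0, max_iterations=20)
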