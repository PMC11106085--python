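"""Shared fixtures: small synthetic scenarios reused across the suite."""

from __future__ import annotations

import numpy as np
import pytest

import comodbn as cb
from comodbn.schema_io import Node
from comodbn.structure_learning import CPT, DBNModel


@pytest.fixture(scope="session")
def elsa_cat():
    return cb.elsa_catalog()


@pytest.fixture(scope="session")
def scenario_model():
    """Default synthetic scenario ground truth: 10 dynamic + 3 static variables."""
    return cb.make_ground_truth_dbn(10, 3, seed=0)


@pytest.fixture(scope="session")
def small_panel(scenario_model):
    """Complete sampled panel, 500 subjects, 6 waves (original wave numbers)."""
    return cb.sample_panel(scenario_model, 500, 6, seed=1)


@pytest.fixture(scope="session")
def small_aligned(small_panel):
    return cb.discretize(cb.align_waves(small_panel))


@pytest.fixture(scope="session")
def chain_model():
    """Hand-built 2-state self-loop chain with no deaths.

    Baseline distribution (0.7, 0.3); transition matrix
    [[0.9, 0.1], [0.2, 0.8]]; survival never fires, so trajectories are a
    plain 2-state Markov chain observed at every wave.
    """
    cat = cb.scenario_catalog(1, 0)
    x = "Biomarker 1"
    dag = cb.LayeredDAG(cat, [(Node(x, "t-1"), Node(x, "t"))])
    cpts = {
        Node(x, "t-1"): CPT(Node(x, "t-1"), (), (), np.array([[0.7, 0.3]])),
        Node(x, "t"): CPT(Node(x, "t"), (Node(x, "t-1"),), (2,),
                          np.array([[0.9, 0.1], [0.2, 0.8]])),
        Node("Survival", "survival"): CPT(Node("Survival", "survival"), (), (),
                                          np.array([[1.0, 0.0]])),
        Node("TSB", "time"): CPT(Node("TSB", "time"), (), (),
                                 np.array([[1 / 3, 1 / 3, 1 / 3]])),
    }
    return DBNModel(dag, cpts, cat)
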