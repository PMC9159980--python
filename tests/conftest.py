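import itertools
import math

import numpy as np
import pytest

from burrowstats import mk_simmap as mk
from burrowstats import treeio


@pytest.fixture
def three_taxon_tree():
    return treeio.parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def two_tip_tree():
    return treeio.parse_newick("(A:1,B:1);")


def enumerate_loglik(tree, tips, rm, prior):
    """Exhaustive-sum oracle for the Mk likelihood: sum over every assignment
    of states to internal nodes of prior x product of transition probs."""
    P = {v: rm.transition(float(tree.length[v]))
         for v in range(tree.n_nodes) if tree.parent[v] >= 0}
    internals = tree.internal_ids
    idx = {s: i for i, s in enumerate(rm.states)}
    tipstate = {i: idx[tips[tree.label[i]]] for i in tree.tip_ids}
    total = 0.0
    for assign in itertools.product(range(rm.k), repeat=len(internals)):
        st = dict(zip(internals, assign))
        st.update(tipstate)
        p = prior[st[tree.root]]
        for v in range(tree.n_nodes):
            if tree.parent[v] >= 0:
                p *= P[v][st[tree.parent[v]], st[v]]
        total += p
    return math.log(total) if total > 0 else float("-inf")


def enumerate_marginal(tree, tips, rm, prior, node):
    """Exhaustive-sum oracle for the marginal state posterior at one node."""
    P = {v: rm.transition(float(tree.length[v]))
         for v in range(tree.n_nodes) if tree.parent[v] >= 0}
    internals = tree.internal_ids
    idx = {s: i for i, s in enumerate(rm.states)}
    tipstate = {i: idx[tips[tree.label[i]]] for i in tree.tip_ids}
    w = np.zeros(rm.k)
    for assign in itertools.product(range(rm.k), repeat=len(internals)):
        st = dict(zip(internals, assign))
        st.update(tipstate)
        p = prior[st[tree.root]]
        for v in range(tree.n_nodes):
            if tree.parent[v] >= 0:
                p *= P[v][st[tree.parent[v]], st[v]]
        w[st[node]] += p
    return w / w.sum()
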