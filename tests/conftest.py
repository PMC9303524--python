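"""Shared fixtures and independent oracle implementations.

The oracles deliberately avoid the code paths they check: the exact-test
oracle enumerates outcomes with ``math.comb`` and explicit powers, and the
parsimony oracle exhaustively labels internal nodes.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from paralogon import datasets
from paralogon.model import ParalogTree


# ---------------------------------------------------------------------------
# Independent oracle: unconditional exact test by exhaustive enumeration
# ---------------------------------------------------------------------------


def oracle_wald(y1: int, n1: int, y2: int, n2: int) -> float:
    p1, p2 = y1 / n1, y2 / n2
    pooled = (y1 + y2) / (n1 + n2)
    var = pooled * (1 - pooled) * (1 / n1 + 1 / n2)
    return 0.0 if var <= 0 else (p1 - p2) / math.sqrt(var)


def oracle_exact_test(x1: int, n1: int, x2: int, n2: int, grid: int, sided: str = "one") -> float:
    """Brute-force maximised tail probability over a matched nuisance grid."""
    t_obs = oracle_wald(x1, n1, x2, n2)
    region = []
    for y1 in range(n1 + 1):
        for y2 in range(n2 + 1):
            t = oracle_wald(y1, n1, y2, n2)
            hit = t >= t_obs - 1e-10 if sided == "one" else abs(t) >= abs(t_obs) - 1e-10
            if hit:
                region.append((y1, y2))
    # explicit product-binomial formula, vectorised over the grid
    pis = np.linspace(0.0, 1.0, grid)
    coeff = np.array([math.comb(n1, y1) * math.comb(n2, y2) for y1, y2 in region], dtype=float)
    succ = np.array([y1 + y2 for y1, y2 in region], dtype=float)
    fail = np.array([(n1 - y1) + (n2 - y2) for y1, y2 in region], dtype=float)
    with np.errstate(invalid="ignore"):
        terms = coeff[None, :] * pis[:, None] ** succ[None, :] * (1 - pis)[:, None] ** fail[None, :]
    totals = np.nansum(terms, axis=1)
    return float(min(totals.max(), 1.0))


# ---------------------------------------------------------------------------
# Independent oracle: parsimony by exhaustive internal labeling
# ---------------------------------------------------------------------------


def oracle_parsimony(tree: ParalogTree, leaf_states: dict) -> tuple[int, dict]:
    """Minimal change count and per-node MPR sets by full enumeration.

    Unknown leaves are enumerated alongside internal nodes.
    """
    nodes = list(tree.tree.preorder_node_iter())
    free = [
        n
        for n in nodes
        if (not n.is_leaf()) or leaf_states[n.taxon.label] == "unknown"
    ]
    fixed = {
        id(n): (1 if leaf_states[n.taxon.label] == "present" else 0)
        for n in nodes
        if n.is_leaf() and leaf_states[n.taxon.label] != "unknown"
    }
    edges = [(n, c) for n in nodes for c in n.child_nodes()]
    best = math.inf
    optimal_labelings = []
    for assign in itertools.product((0, 1), repeat=len(free)):
        labels = dict(fixed)
        for node, state in zip(free, assign):
            labels[id(node)] = state
        cost = sum(1 for p, c in edges if labels[id(p)] != labels[id(c)])
        if cost < best:
            best = cost
            optimal_labelings = [labels]
        elif cost == best:
            optimal_labelings.append(labels)
    mpr: dict[str, set] = {}
    for node in nodes:
        name = node.taxon.label if node.is_leaf() else node.label
        mpr[name] = {lab[id(node)] for lab in optimal_labelings}
    return int(best), mpr


def random_tree(rng: np.random.Generator, n_leaves: int) -> ParalogTree:
    """Random rooted topology (with occasional polytomies) over t1..tn."""
    labels = [f"t{i + 1}" for i in range(n_leaves)]
    groups = [f"{lab}" for lab in labels]
    while len(groups) > 1:
        k = 2 if len(groups) == 2 or rng.random() > 0.25 else 3
        k = min(k, len(groups))
        idx = rng.choice(len(groups), size=k, replace=False)
        merged = "(" + ",".join(groups[i] for i in sorted(idx)) + ")"
        groups = [g for i, g in enumerate(groups) if i not in set(idx)] + [merged]
    return ParalogTree.from_newick(groups[0] + ";")


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def table2():
    return datasets.table2_tables()


@pytest.fixture(scope="session")
def table2_assignment():
    return datasets.table2_assignment()


@pytest.fixture(scope="session")
def hmg_block():
    return datasets.hmg_box_block()


@pytest.fixture(scope="session")
def paralog_tree():
    return datasets.tcf_paralog_tree()


@pytest.fixture(scope="session")
def gene_models():
    return datasets.tcf_gene_models()


@pytest.fixture(scope="session")
def feature_matrix():
    return datasets.tcf_feature_matrix()
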