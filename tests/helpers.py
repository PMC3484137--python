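"""Independent oracles and small random generators for the test suite.

The likelihood oracle sums explicitly over all internal-node state
assignments (tips are marginalised against their partial vectors), a
different algorithm from the pruning recursion it checks.
"""

from __future__ import annotations

import itertools

import numpy as np
import scipy.linalg

from traitcorr.phylo import Phylogeny


def random_tree(rng: np.random.Generator, n_leaves: int) -> Phylogeny:
    """Random rooted binary topology with uniform branch lengths."""
    parent = []
    lengths = []
    labels = []
    roots = []
    for i in range(n_leaves):
        parent.append(-1)
        lengths.append(float(rng.uniform(0.05, 2.0)))
        labels.append(f"L{i + 1}")
        roots.append(i)
    while len(roots) > 1:
        i = roots.pop(int(rng.integers(len(roots))))
        j = roots.pop(int(rng.integers(len(roots))))
        new = len(parent)
        parent.append(-1)
        lengths.append(float(rng.uniform(0.05, 2.0)))
        labels.append(None)
        parent[i] = new
        parent[j] = new
        roots.append(new)
    return Phylogeny(parent, lengths, labels)


def random_binary_q(rng: np.random.Generator) -> np.ndarray:
    a, b = rng.uniform(0.1, 3.0, 2)
    return np.array([[-a, a], [b, -b]])


def random_dependent_q(rng: np.random.Generator) -> np.ndarray:
    from traitcorr.ctmc import DependentRates, build_dependent_matrix
    vals = rng.uniform(0.1, 3.0, 8)
    return build_dependent_matrix(DependentRates.from_array(vals))


def random_tip_partials(rng: np.random.Generator, tree: Phylogeny, k: int
                        ) -> dict[str, np.ndarray]:
    """Observed, missing, or ambiguous tips with ~20% missingness."""
    out = {}
    for lab in tree.leaf_labels():
        u = rng.random()
        v = np.zeros(k)
        if u < 0.2:
            v[:] = 1.0
        elif u < 0.3 and k > 2:
            states = rng.choice(k, size=2, replace=False)
            v[states] = 1.0
        else:
            v[int(rng.integers(k))] = 1.0
        out[lab] = v
    return out


def enum_loglik(tree: Phylogeny, tip_partials: dict[str, np.ndarray],
                Q: np.ndarray, root_dist: np.ndarray,
                constraints: dict[int, set[int]] | None = None) -> float:
    """Likelihood by explicit summation over internal-node states."""
    k = Q.shape[0]
    P = {int(i): scipy.linalg.expm(Q * tree.lengths[i])
         for i in range(tree.n_nodes) if i != tree.root}
    internal = [i for i in range(tree.n_nodes) if not tree.is_leaf[i]]
    label_of = {i: tree.labels[i] for i in range(tree.n_nodes) if tree.is_leaf[i]}
    constraints = constraints or {}
    total = 0.0
    for assign in itertools.product(range(k), repeat=len(internal)):
        amap = dict(zip(internal, assign))
        ok = all(amap[n] in allowed for n, allowed in constraints.items()
                 if n in amap)
        if not ok:
            continue
        prob = root_dist[amap[tree.root]]
        for i in range(tree.n_nodes):
            if i == tree.root:
                continue
            ps = amap[int(tree.parent[i])]
            if tree.is_leaf[i]:
                tip = tip_partials[label_of[i]]
                if i in constraints:
                    tip = tip * np.isin(np.arange(k), list(constraints[i]))
                prob *= float(P[i][ps] @ tip)
            else:
                prob *= P[i][ps, amap[i]]
        total += prob
    return float(np.log(total)) if total > 0 else -np.inf


def enum_marginal(tree: Phylogeny, tip_partials, Q, root_dist, node: int
                  ) -> np.ndarray:
    """Marginal state probabilities at a node, by enumeration."""
    k = Q.shape[0]
    lls = np.array([enum_loglik(tree, tip_partials, Q, root_dist,
                                constraints={node: {s}}) for s in range(k)])
    w = np.exp(lls - lls.max())
    return w / w.sum()
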