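"""Continuous-time Markov machinery for one binary trait and for the
four-state joint (habitat, morphology) models.

Combined-state convention (indices 0..3 internally, 1..4 in rate names):

====  =========  ==========
index  habitat h  morphology m
====  =========  ==========
0      0 (soil/unexposed)   0 (plesiomorphic)
1      1 (epiphytic/exposed) 0
2      0          1 (derived)
3      1          1
====  =========  ==========

so ``q12`` is a habitat gain with ancestral morphology and ``q13`` a
morphology gain with ancestral habitat.  Simultaneous dual transitions
(0<->3, 1<->2) are structurally impossible (rate 0).

Likelihoods use Felsenstein pruning with per-node scaling; missing tip
observations contribute a partial likelihood of 1 in every compatible
state, and node constraints zero the partials outside the allowed set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import scipy.linalg

from .phylo import Phylogeny

try:  # pragma: no cover - exercised implicitly
    from numba import njit
    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn
        return wrap if not (args and callable(args[0])) else args[0]

__all__ = [
    "BinaryRates", "DependentRates", "RATE_NAMES", "INDEPENDENT_RATE_NAMES",
    "DEFAULT_RATE_BOUND", "INDEPENDENCE_PAIRS",
    "build_binary_matrix", "build_independent_matrix", "build_dependent_matrix",
    "build_restricted_matrix", "validate_rate_matrix", "stationary_distribution",
    "transition_probabilities", "branch_transition_matrices",
    "TreeLikelihood", "pruning_loglik", "marginal_ancestral_probs",
    "state_to_partial", "binary_tip_partials", "dual_tip_partials",
    "combined_state", "split_combined_state",
]

DEFAULT_RATE_BOUND = 100.0

RATE_NAMES = ("q12", "q13", "q21", "q24", "q31", "q34", "q42", "q43")
INDEPENDENT_RATE_NAMES = ("habitat_gain", "habitat_loss",
                          "morph_gain", "morph_loss")

#: Pairs of dependent rates that must coincide under independence:
#: habitat gain (q12,q34), habitat loss (q21,q43),
#: morphology gain (q13,q24), morphology loss (q31,q42).
INDEPENDENCE_PAIRS = (("q12", "q34"), ("q21", "q43"),
                      ("q13", "q24"), ("q31", "q42"))
INDEPENDENCE_PAIR_INDICES = tuple(
    (RATE_NAMES.index(a), RATE_NAMES.index(b)) for a, b in INDEPENDENCE_PAIRS)

# off-diagonal placement of the eight rates in the 4x4 generator
_RATE_POSITIONS = {
    "q12": (0, 1), "q13": (0, 2), "q21": (1, 0), "q24": (1, 3),
    "q31": (2, 0), "q34": (2, 3), "q42": (3, 1), "q43": (3, 2),
}


def combined_state(habitat: int, morphology: int) -> int:
    """Map (h, m) in {0,1}^2 to the combined state index 0..3."""
    return int(habitat) + 2 * int(morphology)


def split_combined_state(state: int) -> tuple[int, int]:
    return state & 1, state >> 1


@dataclass(frozen=True)
class BinaryRates:
    """Gain (0->1) and loss (1->0) rates for one binary character."""
    alpha: float
    beta: float

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("rates must be non-negative")


@dataclass(frozen=True)
class DependentRates:
    """The eight single-change rates of the dependent (correlated) model."""
    q12: float
    q13: float
    q21: float
    q24: float
    q31: float
    q34: float
    q42: float
    q43: float

    def __post_init__(self):
        for name in RATE_NAMES:
            if getattr(self, name) < 0:
                raise ValueError(f"rate {name} must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in RATE_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values) -> "DependentRates":
        return cls(**dict(zip(RATE_NAMES, map(float, values))))


def build_binary_matrix(rates: BinaryRates) -> np.ndarray:
    """2x2 generator for a single binary character."""
    a, b = rates.alpha, rates.beta
    return np.array([[-a, a], [b, -b]], dtype=float)


def build_dependent_matrix(rates: DependentRates) -> np.ndarray:
    """4x4 generator of the dependent model; dual-change entries are 0."""
    Q = np.zeros((4, 4))
    for name, (i, j) in _RATE_POSITIONS.items():
        Q[i, j] = getattr(rates, name)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def build_independent_matrix(habitat: BinaryRates, morphology: BinaryRates) -> np.ndarray:
    """4x4 generator where each trait evolves regardless of the other.

    Equivalent to the dependent generator with the four independence
    equalities enforced (q12=q34, q21=q43, q13=q24, q31=q42).
    """
    return build_dependent_matrix(DependentRates(
        q12=habitat.alpha, q34=habitat.alpha,
        q21=habitat.beta, q43=habitat.beta,
        q13=morphology.alpha, q24=morphology.alpha,
        q31=morphology.beta, q42=morphology.beta,
    ))


def build_restricted_matrix(rates: DependentRates) -> np.ndarray:
    """Dependent generator with the shared habitat/morphology gain rate
    q12 = q13 (seven free parameters)."""
    if rates.q12 != rates.q13:
        raise ValueError("restricted model requires q12 == q13")
    return build_dependent_matrix(rates)


def validate_rate_matrix(Q: np.ndarray, tol: float = 1e-10) -> None:
    Q = np.asarray(Q)
    if Q.ndim != 2 or Q.shape[0] != Q.shape[1]:
        raise ValueError("rate matrix must be square")
    off = Q - np.diag(np.diag(Q))
    if (off < -tol).any():
        raise ValueError("off-diagonal rates must be non-negative")
    if np.abs(Q.sum(axis=1)).max() > tol:
        raise ValueError("rate-matrix rows must sum to zero")


def stationary_distribution(Q: np.ndarray) -> np.ndarray:
    """Stationary distribution pi with pi Q = 0, sum(pi) = 1."""
    k = Q.shape[0]
    A = np.vstack([Q.T, np.ones(k)])
    b = np.zeros(k + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def branch_transition_matrices(Q: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """expm(Q*t) for a vector of branch lengths t, shape (B, k, k).

    Eigendecomposition when the generator is well-conditioned, otherwise
    a per-branch scaling-and-squaring fallback (defective generators can
    occur at symmetric rate settings).  Rows are clipped to [0, 1] and
    renormalised; the result is accurate to ~1e-12 for 2x2/4x4 inputs.
    """
    lengths = np.asarray(lengths, dtype=float)
    if (lengths < 0).any():
        raise ValueError("branch lengths must be non-negative")
    k = Q.shape[0]
    P = None
    try:
        w, V = np.linalg.eig(Q)
        Vi = np.linalg.inv(V)
        if np.abs(V @ Vi - np.eye(k)).max() < 1e-9:
            E = np.exp(np.multiply.outer(lengths, w))          # (B, k)
            P = np.einsum("ij,bj,jk->bik", V, E, Vi).real
    except np.linalg.LinAlgError:
        P = None
    if P is None or not np.isfinite(P).all():
        P = np.stack([scipy.linalg.expm(Q * t) for t in lengths])
    P = np.clip(P, 0.0, None)
    P /= P.sum(axis=2, keepdims=True)
    return P


def transition_probabilities(Q: np.ndarray, t: float) -> np.ndarray:
    """Stochastic matrix expm(Q*t) for a single branch length t >= 0."""
    validate_rate_matrix(Q)
    if t < 0:
        raise ValueError("branch length must be non-negative")
    return branch_transition_matrices(Q, np.array([t]))[0]


# ----------------------------------------------------------------------
# pruning

@njit(cache=True)
def _prune_kernel(post, parent, root, P, base, root_dist):  # pragma: no cover
    n, k = base.shape
    part = base.copy()
    logscale = 0.0
    for ii in range(post.shape[0]):
        i = post[ii]
        s = 0.0
        for a in range(k):
            s += part[i, a]
        if s <= 0.0:
            return -np.inf
        for a in range(k):
            part[i, a] /= s
        logscale += np.log(s)
        p = parent[i]
        for a in range(k):
            acc = 0.0
            for b in range(k):
                acc += P[i, a, b] * part[i, b]
            part[p, a] *= acc
    tot = 0.0
    for a in range(k):
        tot += root_dist[a] * part[root, a]
    if tot <= 0.0:
        return -np.inf
    return np.log(tot) + logscale


def _prune_py(post, parent, root, P, base, root_dist):
    part = base.copy()
    logscale = 0.0
    for i in post:
        s = part[i].sum()
        if s <= 0.0:
            return -np.inf
        part[i] /= s
        logscale += np.log(s)
        part[parent[i]] *= P[i] @ part[i]
    tot = float(root_dist @ part[root])
    if tot <= 0.0:
        return -np.inf
    return np.log(tot) + logscale


_prune = _prune_kernel if _HAVE_NUMBA else _prune_py


def state_to_partial(value, k: int) -> np.ndarray:
    """Convert an observed state (int), missing (None), an allowed-state
    set, or an explicit vector into a conditional-likelihood vector."""
    if value is None:
        return np.ones(k)
    if isinstance(value, (set, frozenset, list, tuple)):
        v = np.zeros(k)
        for s in value:
            v[int(s)] = 1.0
        return v
    if isinstance(value, np.ndarray):
        if value.shape != (k,):
            raise ValueError("tip partial vector has wrong length")
        return value.astype(float)
    s = int(value)
    if not 0 <= s < k:
        raise ValueError(f"state {s} outside model dimension {k}")
    v = np.zeros(k)
    v[s] = 1.0
    return v


def binary_tip_partials(states: Mapping[str, int | None]) -> dict[str, np.ndarray]:
    """Tip partials for a single binary character (missing -> (1,1))."""
    return {t: state_to_partial(s, 2) for t, s in states.items()}


def dual_tip_partials(habitat: Mapping[str, int | None],
                      morphology: Mapping[str, int | None]) -> dict[str, np.ndarray]:
    """Tip partials over the 4 combined states.

    A taxon missing one trait gets likelihood 1 in every combined state
    consistent with the trait that was observed.
    """
    if set(habitat) != set(morphology):
        raise ValueError("habitat and morphology must cover the same taxa")
    out = {}
    for t in habitat:
        v = np.zeros(4)
        for h in (0, 1):
            if habitat[t] is not None and habitat[t] != h:
                continue
            for m in (0, 1):
                if morphology[t] is not None and morphology[t] != m:
                    continue
                v[combined_state(h, m)] = 1.0
        out[t] = v
    return out


class TreeLikelihood:
    """Reusable pruning-likelihood evaluator for one tree and dataset.

    Precomputes the flat postorder arrays once so that repeated
    evaluations inside an MCMC only pay for the transition matrices and
    the pruning sweep.

    Parameters
    ----------
    root_dist : "uniform", "stationary", or explicit probability vector.
    constraints : mapping node index -> iterable of allowed states;
        partial likelihoods outside the allowed set are zeroed at that
        node (the "fossil" mechanism).
    """

    def __init__(self, tree: Phylogeny, tip_partials: Mapping[str, np.ndarray],
                 k: int, root_dist="uniform",
                 constraints: Mapping[int, Iterable[int]] | None = None):
        self.tree = tree
        self.k = k
        missing = tree.taxa - set(tip_partials)
        if missing:
            raise ValueError(f"no tip data for leaves: {sorted(missing)}")
        unknown = set(tip_partials) - tree.taxa
        if unknown:
            raise ValueError(f"unknown leaf labels in data: {sorted(unknown)}")
        base = np.ones((tree.n_nodes, k))
        for lab, i in tree.leaf_index.items():
            v = np.asarray(tip_partials[lab], dtype=float)
            if v.shape != (k,):
                raise ValueError(
                    f"tip partial for {lab!r} has dimension {v.shape}, expected ({k},)")
            base[i] = v
        if constraints:
            for node, allowed in constraints.items():
                node = int(node)
                if not 0 <= node < tree.n_nodes:
                    raise ValueError(f"node {node} not in tree")
                mask = np.zeros(k)
                for s in allowed:
                    mask[int(s)] = 1.0
                base[node] *= mask
        self._base = base
        self._post = tree.postorder[tree.postorder != tree.root]
        self._parent = tree.parent
        self._root_dist = root_dist

    def _resolve_root(self, Q) -> np.ndarray:
        rd = self._root_dist
        if isinstance(rd, str):
            if rd == "uniform":
                return np.full(self.k, 1.0 / self.k)
            if rd == "stationary":
                return stationary_distribution(Q)
            raise ValueError(f"unknown root distribution: {rd!r}")
        rd = np.asarray(rd, dtype=float)
        if rd.shape != (self.k,) or (rd < 0).any() or abs(rd.sum() - 1.0) > 1e-12:
            raise ValueError("root distribution must be a probability vector")
        return rd

    def loglik(self, Q: np.ndarray) -> float:
        if Q.shape != (self.k, self.k):
            raise ValueError(
                f"rate matrix dimension {Q.shape} does not match model ({self.k})")
        P = branch_transition_matrices(Q, self.tree.lengths)
        return float(_prune(self._post, self._parent, self.tree.root,
                            P, self._base, self._resolve_root(Q)))


def pruning_loglik(tree: Phylogeny, tip_states: Mapping[str, object],
                   Q: np.ndarray, root="uniform",
                   constraints: Mapping[int, Iterable[int]] | None = None) -> float:
    """Felsenstein-pruned log-likelihood of tip data under generator Q.

    ``tip_states`` maps each leaf label to an observed state, None
    (missing), an allowed-state set, or an explicit partial vector.
    """
    validate_rate_matrix(Q)
    k = Q.shape[0]
    partials = {t: state_to_partial(v, k) for t, v in tip_states.items()}
    return TreeLikelihood(tree, partials, k, root_dist=root,
                          constraints=constraints).loglik(Q)


def marginal_ancestral_probs(tree: Phylogeny, tip_states: Mapping[str, object],
                             Q: np.ndarray, root="uniform", node: int = None,
                             constraints: Mapping[int, Iterable[int]] | None = None
                             ) -> np.ndarray:
    """Marginal posterior probability of each state at an internal node.

    Computed by constraining the node to each state in turn: the
    constrained pruning likelihood is the joint P(data, node = s), so
    normalising over states yields the exact marginal.
    """
    if node is None or not 0 <= int(node) < tree.n_nodes:
        raise ValueError(f"node {node} not in tree")
    validate_rate_matrix(Q)
    k = Q.shape[0]
    partials = {t: state_to_partial(v, k) for t, v in tip_states.items()}
    lls = np.empty(k)
    for s in range(k):
        cons = dict(constraints or {})
        cons[int(node)] = {s}
        lls[s] = TreeLikelihood(tree, partials, k, root_dist=root,
                                constraints=cons).loglik(Q)
    m = lls.max()
    if not np.isfinite(m):
        raise ValueError("all constrained likelihoods are zero at this node")
    w = np.exp(lls - m)
    return w / w.sum()
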