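"""Metropolis-Hastings and reversible-jump samplers over trait-evolution
models on a fixed tree or a posterior tree sample.

Rates carry a uniform prior on ``rate_prior_bounds`` (default [0, 100]).
The rate proposal updates one randomly chosen parameter per iteration
by a symmetric sliding window with reflection at the prior bounds; the
window half-width is tuned toward ``target_acceptance`` during burn-in
only, then frozen so detailed balance holds for the retained samples.  When a TreeSample is supplied with
``tree_sampling="uniform"``, iterations additionally propose replacing
the current tree by one drawn uniformly from the sample.

The reversible-jump sampler walks over rate-class partitions with a
single-element reassignment kernel (move one rate into another class, a
fresh singleton class, or the optional zero class).  New class values
are drawn from the prior, which cancels against the prior ratio, so the
acceptance probability reduces to the likelihood ratio times the ratio
of target counts of the forward and reverse moves.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from . import ctmc
from .ctmc import (DependentRates, TreeLikelihood, build_binary_matrix,
                   build_dependent_matrix, build_independent_matrix,
                   BinaryRates, state_to_partial)
from .partitions import (ZERO, canonical_partition, is_independent_partition,
                         partition_string)
from .phylo import NodeQuery, Phylogeny, TreeSample, resolve_node

__all__ = ["McmcSettings", "PosteriorSample", "mcmc_run", "rj_mcmc_run",
           "MODEL_NAMES"]

MODEL_NAMES = ("binary", "independent", "dependent", "restricted")

_TREE_MOVE_PROB = 0.25
_TUNE_WINDOW = 50


@dataclass(frozen=True)
class McmcSettings:
    """Chain-length, prior, proposal and tree-sampling settings.

    ``burn_in=None`` resolves to 10% of ``iterations``.  ``thinning``
    retains every k-th post-burn-in iteration, so the retained sample
    count is ``floor((iterations - burn_in) / thinning)``.
    """

    iterations: int = 1_000_000
    burn_in: int | None = None
    thinning: int = 45
    seed: int = 0
    rate_prior_bounds: tuple[float, float] = (0.0, 100.0)
    initial_rate_deviation: float = 10.0
    target_acceptance: float = 0.20
    tree_sampling: str = "single"  # "single" | "uniform"
    root_dist: str = "uniform"
    partition_move_prob: float = 0.5  # RJ only
    zero_class: bool = False          # RJ only

    def __post_init__(self):
        lo, hi = self.rate_prior_bounds
        if not (0 <= lo < hi):
            raise ValueError("rate prior bounds must satisfy 0 <= lo < hi")
        if self.iterations <= 0 or self.thinning < 1:
            raise ValueError("iterations must be positive, thinning >= 1")
        if self.resolved_burn_in >= self.iterations:
            raise ValueError("burn_in must be smaller than iterations")
        if self.tree_sampling not in ("single", "uniform"):
            raise ValueError("tree_sampling must be 'single' or 'uniform'")

    @property
    def resolved_burn_in(self) -> int:
        return self.iterations // 10 if self.burn_in is None else self.burn_in

    @property
    def n_retained(self) -> int:
        return (self.iterations - self.resolved_burn_in) // self.thinning

    def with_seed(self, seed: int) -> "McmcSettings":
        return replace(self, seed=int(seed))


@dataclass
class PosteriorSample:
    """Retained MCMC samples plus run metadata."""

    model: str
    lnl: np.ndarray                      # (m,)
    rates: np.ndarray                    # (m, p); RJ: expanded 8-vector
    rate_names: tuple[str, ...]
    settings: McmcSettings
    seed: int
    acceptance_rate: float
    partitions: list[tuple[int, ...]] | None = None   # RJ only
    is_independent: np.ndarray | None = None          # RJ only
    tree_indices: np.ndarray | None = None
    proposal_width: float = field(default=np.nan)

    @property
    def n_samples(self) -> int:
        return int(self.lnl.shape[0])

    def rate(self, name: str) -> np.ndarray:
        return self.rates[:, self.rate_names.index(name)]

    @property
    def visits_independent(self) -> int:
        if self.is_independent is None:
            raise ValueError("visit counts only defined for RJ runs")
        return int(self.is_independent.sum())

    def to_tsv(self, dest) -> None:
        import pandas as pd
        cols = {"sample": np.arange(self.n_samples), "lnl": self.lnl}
        for j, nm in enumerate(self.rate_names):
            cols[nm] = self.rates[:, j]
        if self.partitions is not None:
            cols["partition"] = [partition_string(p) for p in self.partitions]
            cols["is_independent"] = self.is_independent.astype(int)
        pd.DataFrame(cols).to_csv(dest, sep="\t", index=False,
                                  float_format="%.6f")


# ----------------------------------------------------------------------
# model specifications

def _q_binary(theta):
    return build_binary_matrix(BinaryRates(theta[0], theta[1]))


def _q_independent(theta):
    return build_independent_matrix(BinaryRates(theta[0], theta[1]),
                                    BinaryRates(theta[2], theta[3]))


def _q_dependent(theta):
    return build_dependent_matrix(DependentRates.from_array(theta))


def _q_restricted(theta):
    return build_dependent_matrix(DependentRates(
        q12=theta[0], q13=theta[0], q21=theta[1], q24=theta[2],
        q31=theta[3], q34=theta[4], q42=theta[5], q43=theta[6]))


_MODELS = {
    "binary": (("alpha", "beta"), _q_binary, 2),
    "independent": (ctmc.INDEPENDENT_RATE_NAMES, _q_independent, 4),
    "dependent": (ctmc.RATE_NAMES, _q_dependent, 4),
    "restricted": (("q12_q13", "q21", "q24", "q31", "q34", "q42", "q43"),
                   _q_restricted, 4),
}


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    span = hi - lo
    y = np.mod(x - lo, 2.0 * span)
    y = np.where(y > span, 2.0 * span - y, y)
    return lo + y


def _build_evaluators(tree_input, data: Mapping[str, object], k: int,
                      root_dist: str,
                      constraints: Mapping | None) -> list[TreeLikelihood]:
    trees = list(tree_input) if isinstance(tree_input, TreeSample) else [tree_input]
    partials = {t: state_to_partial(v, k) for t, v in data.items()}
    if not partials:
        raise ValueError("empty data: no tip observations supplied")
    evals = []
    for tree in trees:
        cons = None
        if constraints:
            cons = {}
            for key, allowed in constraints.items():
                node = resolve_node(tree, key) if isinstance(key, NodeQuery) else int(key)
                cons[node] = allowed
        evals.append(TreeLikelihood(tree, partials, k, root_dist=root_dist,
                                    constraints=cons))
    return evals


class _ChainDriver:
    """Shared iteration bookkeeping for fixed-model and RJ chains.

    Proposal widths are kept per coordinate (one per free rate in the
    fixed-model samplers; a single shared one in the reversible-jump
    sampler, whose class identities change) and each is tuned toward
    the target acceptance during burn-in only.  Without per-coordinate
    tuning, rates the data cannot identify (which accept any proposal)
    would drag the shared width to the prior width and starve the
    identified rates of accepted moves.
    """

    def __init__(self, settings: McmcSettings, n_trees: int, n_widths: int = 1):
        self.s = settings
        self.rng = np.random.default_rng(settings.seed)
        self.widths = np.full(n_widths, float(settings.initial_rate_deviation))
        self.burn = settings.resolved_burn_in
        self.multi_tree = n_trees > 1 and settings.tree_sampling == "uniform"
        self._acc = 0
        self._tries = 0
        self._win_acc = np.zeros(n_widths, dtype=np.int64)
        self._win_tries = np.zeros(n_widths, dtype=np.int64)

    def record_rate_move(self, accepted: bool, iteration: int, c: int = 0):
        if iteration < self.burn:
            self._win_tries[c] += 1
            self._win_acc[c] += accepted
            if self._win_tries[c] >= _TUNE_WINDOW:
                frac = self._win_acc[c] / self._win_tries[c]
                lo, hi = self.s.rate_prior_bounds
                self.widths[c] *= float(np.exp(2.0 * (frac - self.s.target_acceptance)))
                self.widths[c] = float(np.clip(self.widths[c], 1e-3, hi - lo))
                self._win_acc[c] = self._win_tries[c] = 0
        else:
            self._tries += 1
            self._acc += accepted

    def retained(self, iteration: int) -> bool:
        if iteration < self.burn:
            return False
        return (iteration - self.burn) % self.s.thinning == self.s.thinning - 1

    @property
    def acceptance_rate(self) -> float:
        return self._acc / self._tries if self._tries else float("nan")


def mcmc_run(model: str, tree_input, data: Mapping[str, object],
             settings: McmcSettings,
             constraints: Mapping | None = None) -> PosteriorSample:
    """Fixed-model Metropolis-Hastings chain; fully reproducible from seed.

    ``model`` is one of "binary", "independent", "dependent",
    "restricted".  ``data`` maps leaf labels to observed states, missing
    (None), allowed-state sets, or partial vectors matching the model's
    state dimension (2 for "binary", 4 otherwise).
    """
    if model not in _MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {MODEL_NAMES}")
    names, build_q, k = _MODELS[model]
    p = len(names)
    evals = _build_evaluators(tree_input, data, k, settings.root_dist, constraints)
    drv = _ChainDriver(settings, len(evals), n_widths=p)
    rng = drv.rng
    lo, hi = settings.rate_prior_bounds

    theta = rng.uniform(lo, hi, p)
    ti = 0
    ll = evals[ti].loglik(build_q(theta))

    m = settings.n_retained
    out_lnl = np.empty(m)
    out_rates = np.empty((m, p))
    out_tree = np.empty(m, dtype=np.int64)
    j = 0
    for it in range(settings.iterations):
        if drv.multi_tree and rng.random() < _TREE_MOVE_PROB:
            tj = int(rng.integers(len(evals)))
            ll_new = evals[tj].loglik(build_q(theta))
            if np.log(rng.random()) < ll_new - ll:
                ti, ll = tj, ll_new
        else:
            prop = theta.copy()
            c = int(rng.integers(p))
            w = drv.widths[c]
            prop[c] = _reflect(prop[c] + rng.uniform(-w, w), lo, hi)
            ll_new = evals[ti].loglik(build_q(prop))
            ok = np.log(rng.random()) < ll_new - ll
            if ok:
                theta, ll = prop, ll_new
            drv.record_rate_move(ok, it, c)
        if drv.retained(it):
            out_lnl[j] = ll
            out_rates[j] = theta
            out_tree[j] = ti
            j += 1
    assert j == m
    return PosteriorSample(model=model, lnl=out_lnl, rates=out_rates,
                           rate_names=tuple(names), settings=settings,
                           seed=settings.seed,
                           acceptance_rate=drv.acceptance_rate,
                           tree_indices=out_tree,
                           proposal_width=float(np.mean(drv.widths)))


# ----------------------------------------------------------------------
# reversible jump

def _rj_targets(assign: np.ndarray, i: int, n_classes: int,
                zero_enabled: bool) -> list[tuple[str, int]]:
    c = int(assign[i])
    size_c = int(np.sum(assign == c))
    targets: list[tuple[str, int]] = [("class", e) for e in range(n_classes) if e != c]
    if c == ZERO or size_c > 1:
        targets.append(("new", -1))
    if zero_enabled and c != ZERO:
        targets.append(("zero", -1))
    return targets


def rj_mcmc_run(tree_input, data: Mapping[str, object],
                settings: McmcSettings,
                constraints: Mapping | None = None,
                model: str = "dependent") -> PosteriorSample:
    """Reversible-jump chain over (rate-class partition, class rates).

    With ``model="dependent"`` the chain partitions the eight
    dual-transition rates; with ``model="independent"`` it partitions
    the four rates of the independent model (each trait's gain and
    loss), so both model families are sampled with the same
    rate-class-averaging machinery, as in the published analyses.  The
    partition prior is uniform over the partition space (extended by
    the zero class when ``settings.zero_class``); class rates are iid
    uniform on the prior bounds.  Each retained sample of a dependent
    chain is flagged ``is_independent`` when its partition enforces the
    four independence equalities.
    """
    if model not in ("dependent", "independent"):
        raise ValueError("rj model must be 'dependent' or 'independent'")
    names, build_q, k = _MODELS[model]
    n_units = len(names)
    evals = _build_evaluators(tree_input, data, k, settings.root_dist, constraints)
    drv = _ChainDriver(settings, len(evals))
    rng = drv.rng
    lo, hi = settings.rate_prior_bounds
    zero_enabled = settings.zero_class

    # initial state: all singleton classes, prior-drawn values
    assign = np.arange(n_units, dtype=np.int64)
    rates = list(rng.uniform(lo, hi, n_units))

    def qvec(a, r):
        return np.array([0.0 if a[i] == ZERO else r[a[i]]
                         for i in range(n_units)])

    ti = 0
    ll = evals[ti].loglik(build_q(qvec(assign, rates)))

    m = settings.n_retained
    out_lnl = np.empty(m)
    out_rates = np.empty((m, n_units))
    out_tree = np.empty(m, dtype=np.int64)
    out_part: list[tuple[int, ...]] = []
    out_indep = np.empty(m, dtype=bool)
    j = 0
    for it in range(settings.iterations):
        u = rng.random()
        if drv.multi_tree and u < _TREE_MOVE_PROB:
            tj = int(rng.integers(len(evals)))
            ll_new = evals[tj].loglik(build_q(qvec(assign, rates)))
            if np.log(rng.random()) < ll_new - ll:
                ti, ll = tj, ll_new
        elif rng.random() < settings.partition_move_prob:
            i = int(rng.integers(n_units))
            fwd = _rj_targets(assign, i, len(rates), zero_enabled)
            kind, tgt = fwd[int(rng.integers(len(fwd)))]
            new_assign = assign.copy()
            new_rates = list(rates)
            c = int(assign[i])
            if kind == "class":
                new_assign[i] = tgt
            elif kind == "new":
                new_assign[i] = len(new_rates)
                new_rates.append(float(rng.uniform(lo, hi)))
            else:  # zero
                new_assign[i] = ZERO
            # remove the old class if it emptied
            if c != ZERO and int(np.sum(new_assign == c)) == 0:
                new_rates.pop(c)
                new_assign[new_assign > c] -= 1
            rev = _rj_targets(new_assign, i, len(new_rates), zero_enabled)
            log_h = np.log(len(fwd)) - np.log(len(rev))
            ll_new = evals[ti].loglik(build_q(qvec(new_assign, new_rates)))
            if np.log(rng.random()) < ll_new - ll + log_h:
                assign, rates, ll = new_assign, new_rates, ll_new
        else:
            if rates:
                prop = list(rates)
                c = int(rng.integers(len(rates)))
                w = drv.widths[0]
                prop[c] = float(_reflect(prop[c] + rng.uniform(-w, w), lo, hi))
                ll_new = evals[ti].loglik(build_q(qvec(assign, prop)))
                ok = np.log(rng.random()) < ll_new - ll
                if ok:
                    rates, ll = list(prop), ll_new
                drv.record_rate_move(ok, it)
        if drv.retained(it):
            out_lnl[j] = ll
            out_rates[j] = qvec(assign, rates)
            out_tree[j] = ti
            out_part.append(canonical_partition(assign))
            out_indep[j] = (True if model == "independent"
                            else is_independent_partition(assign))
            j += 1
    assert j == m
    return PosteriorSample(model=f"rj-{model}", lnl=out_lnl, rates=out_rates,
                           rate_names=tuple(names), settings=settings,
                           seed=settings.seed,
                           acceptance_rate=drv.acceptance_rate,
                           partitions=out_part, is_independent=out_indep,
                           tree_indices=out_tree,
                           proposal_width=float(drv.widths[0]))
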