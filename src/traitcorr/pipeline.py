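"""The three analyses as pipeline stages.

Stage 1 (ancestral): for each character and queried node, marginal
posterior state probabilities plus a Bayes factor comparing runs with
the node fossilised to state 1 versus state 0.

Stage 2 (correlation): for each morphological character against the
habitat character, the dependent (D) vs independent (I) model
comparison by (i) harmonic-mean Bayes factor from the best replicate
runs and (ii) independent-model visit odds from the best
reversible-jump run.

Stage 3 (ordering): for characters with strong correlation support,
whether the habitat changed first — the posterior of q12 (habitat gain
with ancestral morphology) is compared against q13 (morphology gain
with ancestral habitat) by a Mann-Whitney test, and the full dependent
model is compared against the restricted model with q12 = q13.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import scipy.stats
import yaml

from .bayesfactor import (best_of_replicates, bf_band, harmonic_mean_loglik,
                          log_bayes_factor, prior_odds_model_space,
                          visit_odds_bf)
from .ctmc import binary_tip_partials, dual_tip_partials, marginal_ancestral_probs
from .mcmc import McmcSettings, PosteriorSample, mcmc_run, rj_mcmc_run
from .phylo import (NodeQuery, Phylogeny, TreeSample, parse_newick,
                    parse_trees_block, resolve_node)
from .tables import write_table
from .traits import TraitMatrix, read_trait_table

__all__ = [
    "AnalysisConfig", "PipelineError", "CorrelationRow", "AncestralRow",
    "OrderingRow", "mann_whitney_u", "correlation_test",
    "ancestral_reconstruction", "ordering_test", "run_full_analysis",
    "load_config", "find_state_clades",
]

log = logging.getLogger("traitcorr")


class PipelineError(RuntimeError):
    """A stage failure, labelled with the stage that raised it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class AnalysisConfig:
    """Everything needed to reproduce a full analysis."""

    tree_file: str | None = None
    trait_file: str | None = None
    habitat: str = "habitat"
    characters: list[str] = field(default_factory=list)
    nodes: list[NodeQuery] = field(default_factory=list)
    mcmc: McmcSettings = field(default_factory=McmcSettings)
    replicates: int = 3
    ordering_bf_threshold: float = 5.0
    output_dir: str = "results"
    seed_base: int = 1
    marginal_max_samples: int = 200
    ess_thinning: int = 1   # optional extra thinning before the rank test

    def seeds(self, stage: str, n: int) -> list[int]:
        """Derived per-run seeds, deterministic in (seed_base, stage)."""
        salt = zlib.crc32(stage.encode())
        ss = np.random.SeedSequence([self.seed_base, salt])
        return [int(s) for s in ss.generate_state(n) % (2 ** 31)]


def load_config(path) -> AnalysisConfig:
    raw = yaml.safe_load(Path(path).read_text())
    nodes = [NodeQuery(frozenset(n["labels"]), n.get("name"))
             for n in raw.pop("nodes", [])]
    mcmc = McmcSettings(**raw.pop("mcmc", {}))
    return AnalysisConfig(nodes=nodes, mcmc=mcmc, **raw)


# ----------------------------------------------------------------------
# report rows

def _f(fmt):
    return field(default=None, metadata={"fmt": fmt})


@dataclass
class CorrelationRow:
    character: str
    d_mean_lnl: float = _f("%.2f")
    d_sd_lnl: float = _f("%.2f")
    d_max_lnl: float = _f("%.2f")
    i_mean_lnl: float = _f("%.2f")
    i_sd_lnl: float = _f("%.2f")
    i_max_lnl: float = _f("%.2f")
    bf: float = _f("%.2f")
    band: str = None
    visits_independent: tuple = None
    n_samples: int = None
    prior_odds: float = _f("%.2f")
    posterior_odds: float = _f("%.2f")
    odds_ratio: float = _f("%.2f")
    visit_bf: float = _f("%.2f")


@dataclass
class AncestralRow:
    node: str
    character: str
    p0: float = _f("%.4f")
    p1: float = _f("%.4f")
    lnl0: float = _f("%.2f")
    lnl1: float = _f("%.2f")
    bf1: float = _f("%.2f")
    band: str = None
    support: str = None   # categorical shading: <=0.90, >0.90, >0.95


@dataclass
class OrderingRow:
    character: str
    q12_mean: float = _f("%.2f")
    q12_sd: float = _f("%.2f")
    q13_mean: float = _f("%.2f")
    q13_sd: float = _f("%.2f")
    u_statistic: float = _f("%.1f")
    p_value: float = _f("%.4f")
    d_mean_lnl: float = _f("%.2f")
    d_max_lnl: float = _f("%.2f")
    r_mean_lnl: float = _f("%.2f")
    r_max_lnl: float = _f("%.2f")
    bf_r_vs_d: float = _f("%.2f")
    larger_rate: str = None


def find_state_clades(tree: Phylogeny, states: Mapping[str, int | None],
                      state: int = 1, min_size: int = 3) -> list[NodeQuery]:
    """Maximal clades whose observed tips all carry ``state``.

    Used to locate habitat-shift lineages for ancestral-state queries;
    missing tips are ignored.  Returns NodeQueries named ``shift 1``,
    ``shift 2``, ... in postorder.
    """
    tips_below: dict[int, set[str]] = {i: set() for i in range(tree.n_nodes)}
    pure = np.zeros(tree.n_nodes, dtype=bool)
    for i in tree.postorder:
        if tree.is_leaf[i]:
            lab = tree.labels[i]
            tips_below[i] = {lab}
            pure[i] = states.get(lab) in (state, None)
        else:
            for c in tree.children[i]:
                tips_below[i] |= tips_below[c]
            pure[i] = all(pure[c] for c in tree.children[i])
    queries = []
    for i in tree.postorder:
        if tree.is_leaf[i] or i == tree.root or not pure[i]:
            continue
        if pure[int(tree.parent[i])]:
            continue  # not maximal
        observed = [t for t in tips_below[i] if states.get(t) is not None]
        if len(tips_below[i]) >= min_size and observed:
            queries.append(NodeQuery(frozenset(tips_below[i]),
                                     f"shift {len(queries) + 1}"))
    return queries


# ----------------------------------------------------------------------
# statistics

def mann_whitney_u(x, y) -> tuple[float, float]:
    """Mann-Whitney U of the first sample with a two-sided p-value.

    Exact enumeration for samples of at most 20 without ties, otherwise
    the tie-corrected normal approximation with continuity correction.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    small = x.size <= 20 and y.size <= 20
    no_ties = np.unique(np.concatenate([x, y])).size == x.size + y.size
    method = "exact" if (small and no_ties) else "asymptotic"
    res = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    p = float(res.pvalue)
    if np.isnan(p):   # degenerate all-tied case
        p = 1.0
    return float(res.statistic), p


# ----------------------------------------------------------------------
# helpers

def _check_character(traits: TraitMatrix, name: str, stage: str) -> None:
    if name not in traits.characters:
        raise PipelineError(stage, f"character {name!r} not in trait table")
    if traits.n_observed(name) < 2:
        raise PipelineError(stage, f"character {name!r} has <2 observed taxa")


def _replicate_runs(model: str, tree_input, data, config: AnalysisConfig,
                    stage: str, constraints=None, rj: bool = False
                    ) -> list[PosteriorSample]:
    runs = []
    for seed in config.seeds(stage, config.replicates):
        settings = config.mcmc.with_seed(seed)
        if rj:
            runs.append(rj_mcmc_run(tree_input, data, settings, constraints,
                                    model=model))
        else:
            runs.append(mcmc_run(model, tree_input, data, settings, constraints))
    return runs


def _hm_stats(runs: Sequence[PosteriorSample]) -> tuple[float, float, float]:
    hms = np.array([harmonic_mean_loglik(r) for r in runs])
    return float(hms.mean()), float(hms.std(ddof=1) if len(hms) > 1 else 0.0), float(hms.max())


# ----------------------------------------------------------------------
# stages

def correlation_test(tree_input, traits: TraitMatrix, trait: str,
                     habitat: str, config: AnalysisConfig) -> CorrelationRow:
    """Dependent vs independent evolution of one character and habitat.

    Both model families are sampled with reversible-jump chains over
    their rate-class partitions (replicate chains each).  The
    harmonic-mean Bayes factor compares the best D run against the best
    I run; the visit-odds Bayes factor counts how often the best
    unrestricted (D) chain realised an independent-model partition,
    against the enumerated prior odds.
    """
    stage = f"correlation:{trait}"
    _check_character(traits, trait, stage)
    _check_character(traits, habitat, stage)
    data = dual_tip_partials(traits.states(habitat), traits.states(trait))

    d_runs = _replicate_runs("dependent", tree_input, data, config,
                             stage + ":D", rj=True)
    i_runs = _replicate_runs("independent", tree_input, data, config,
                             stage + ":I", rj=True)
    d_mean, d_sd, d_max = _hm_stats(d_runs)
    i_mean, i_sd, i_max = _hm_stats(i_runs)
    res = log_bayes_factor(d_max, i_max)

    prior_odds = prior_odds_model_space(config.mcmc.zero_class)
    best_rj = best_of_replicates(d_runs)
    summary = visit_odds_bf(best_rj, prior_odds)
    return CorrelationRow(
        character=trait, d_mean_lnl=d_mean, d_sd_lnl=d_sd, d_max_lnl=d_max,
        i_mean_lnl=i_mean, i_sd_lnl=i_sd, i_max_lnl=i_max,
        bf=res.bf, band=res.band,
        visits_independent=tuple(r.visits_independent for r in d_runs),
        n_samples=best_rj.n_samples, prior_odds=summary.prior_odds,
        posterior_odds=summary.posterior_odds, odds_ratio=summary.odds_ratio,
        visit_bf=summary.bf)


def _support_category(p: float) -> str:
    if p > 0.95:
        return ">0.95"
    if p > 0.90:
        return ">0.90"
    return "<=0.90"


def _posterior_mean_marginals(tree_input, states, run: PosteriorSample,
                              query: NodeQuery, config: AnalysisConfig,
                              root_dist) -> np.ndarray:
    from .mcmc import _MODELS
    trees = list(tree_input) if isinstance(tree_input, TreeSample) else [tree_input]
    nodes = [resolve_node(t, query) for t in trees]
    m = run.n_samples
    step = max(1, m // config.marginal_max_samples)
    idx = np.arange(0, m, step)
    build_q = _MODELS["binary"][1]
    acc = np.zeros(2)
    for i in idx:
        ti = int(run.tree_indices[i]) if run.tree_indices is not None else 0
        probs = marginal_ancestral_probs(trees[ti], states, build_q(run.rates[i]),
                                         root=root_dist, node=nodes[ti])
        acc += probs
    return acc / len(idx)


def ancestral_reconstruction(tree_input, traits: TraitMatrix, character: str,
                             nodes: Sequence[NodeQuery],
                             config: AnalysisConfig) -> list[AncestralRow]:
    """Marginal state probabilities and fossil-constrained BFs per node.

    Single-character (two-state) model: an unconstrained run yields the
    posterior-mean marginal probabilities at each queried node; two
    constrained runs (node fossilised to 0, then 1) yield harmonic
    means and BF(1) = 2 x (lnL(1) - lnL(0)).
    """
    stage = f"ancestral:{character}"
    _check_character(traits, character, stage)
    trees = list(tree_input) if isinstance(tree_input, TreeSample) else [tree_input]
    for q in nodes:
        unknown = q.labels - trees[0].taxa
        if unknown:
            raise PipelineError(stage, f"node {q.display}: unknown taxa {sorted(unknown)}")
    states = binary_tip_partials(traits.states(character))
    free_run = best_of_replicates(
        _replicate_runs("binary", tree_input, states, config, stage + ":free"))
    rows = []
    for q in nodes:
        probs = _posterior_mean_marginals(tree_input, states, free_run, q,
                                          config, config.mcmc.root_dist)
        hm = {}
        for s in (0, 1):
            runs = _replicate_runs("binary", tree_input, states, config,
                                   f"{stage}:fossil{s}:{q.display}",
                                   constraints={q: {s}})
            hm[s] = _hm_stats(runs)[2]
        res = log_bayes_factor(hm[1], hm[0])
        rows.append(AncestralRow(
            node=q.display, character=character, p0=float(probs[0]),
            p1=float(probs[1]), lnl0=hm[0], lnl1=hm[1], bf1=res.bf,
            band=bf_band(abs(res.bf)),
            support=_support_category(float(probs.max()))))
    return rows


def ordering_test(tree_input, traits: TraitMatrix, trait: str, habitat: str,
                  config: AnalysisConfig) -> OrderingRow:
    """Did the habitat or the morphology change first?

    Compares posterior samples of q12 and q13 from one dependent-model
    chain (Mann-Whitney, two-sided) and the harmonic-mean fit of the
    restricted model (q12 = q13) against the full dependent model.
    """
    stage = f"ordering:{trait}"
    _check_character(traits, trait, stage)
    _check_character(traits, habitat, stage)
    data = dual_tip_partials(traits.states(habitat), traits.states(trait))

    d_runs = _replicate_runs("dependent", tree_input, data, config, stage + ":D")
    r_runs = _replicate_runs("restricted", tree_input, data, config, stage + ":R")
    d_mean, _, d_max = _hm_stats(d_runs)
    r_mean, _, r_max = _hm_stats(r_runs)
    bf = log_bayes_factor(r_max, d_max).bf

    chain = best_of_replicates(d_runs)
    q12 = chain.rate("q12")[:: config.ess_thinning]
    q13 = chain.rate("q13")[:: config.ess_thinning]
    u, p = mann_whitney_u(q12, q13)
    return OrderingRow(
        character=trait,
        q12_mean=float(q12.mean()), q12_sd=float(q12.std(ddof=1)),
        q13_mean=float(q13.mean()), q13_sd=float(q13.std(ddof=1)),
        u_statistic=u, p_value=p,
        d_mean_lnl=d_mean, d_max_lnl=d_max,
        r_mean_lnl=r_mean, r_max_lnl=r_max, bf_r_vs_d=bf,
        larger_rate="q12" if q12.mean() > q13.mean() else "q13")


# ----------------------------------------------------------------------
# orchestration

def _load_tree_input(path: str):
    text = Path(path).read_text()
    if text.lstrip().upper().startswith("#NEXUS"):
        sample = parse_trees_block(text)
        return sample if len(sample) > 1 else sample[0]
    return parse_newick(text)


def run_full_analysis(config: AnalysisConfig,
                      tree_input=None, traits: TraitMatrix | None = None) -> dict:
    """Run all three stages and write the report tables and run log.

    Inputs may be passed in memory; otherwise ``config.tree_file`` and
    ``config.trait_file`` are loaded.  Returns a dict with the report
    rows and output paths.  Any stage failure raises
    :class:`PipelineError` naming the stage, after logging it.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    t0 = time.time()
    try:
        if tree_input is None:
            if not config.tree_file:
                raise PipelineError("setup", "no tree supplied")
            tree_input = _load_tree_input(config.tree_file)
        if traits is None:
            if not config.trait_file:
                raise PipelineError("setup", "no trait table supplied")
            traits = read_trait_table(config.trait_file)
        log.info("settings: %s", config.mcmc)
        log.info("seed base %d, replicates %d", config.seed_base, config.replicates)

        all_chars = [config.habitat] + list(config.characters)
        anc_rows = []
        if config.nodes:
            for ch in all_chars:
                try:
                    rows = ancestral_reconstruction(tree_input, traits, ch,
                                                    config.nodes, config)
                except PipelineError:
                    raise
                except Exception as exc:
                    raise PipelineError(f"ancestral:{ch}", str(exc)) from exc
                anc_rows.extend(rows)
                log.info("ancestral %s: %d nodes", ch, len(rows))
        write_table(anc_rows, out / "table_ancestral.tsv",
                    fieldnames=[f.name for f in dataclasses.fields(AncestralRow)])

        corr_rows = []
        for ch in config.characters:
            try:
                row = correlation_test(tree_input, traits, ch, config.habitat, config)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"correlation:{ch}", str(exc)) from exc
            corr_rows.append(row)
            log.info("correlation %s: BF=%.2f (%s)", ch, row.bf, row.band)
        write_table(corr_rows, out / "table_correlation.tsv",
                    fieldnames=[f.name for f in dataclasses.fields(CorrelationRow)])

        ord_rows = []
        for row in corr_rows:
            if row.bf > config.ordering_bf_threshold:
                try:
                    orow = ordering_test(tree_input, traits, row.character,
                                         config.habitat, config)
                except PipelineError:
                    raise
                except Exception as exc:
                    raise PipelineError(f"ordering:{row.character}", str(exc)) from exc
                ord_rows.append(orow)
                log.info("ordering %s: q12=%.2f q13=%.2f p=%.4f", row.character,
                         orow.q12_mean, orow.q13_mean, orow.p_value)
        write_table(ord_rows, out / "table_ordering.tsv",
                    fieldnames=[f.name for f in dataclasses.fields(OrderingRow)])
        log.info("done in %.1f s", time.time() - t0)
    except PipelineError as exc:
        log.error("aborted: %s", exc)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
    return {
        "ancestral": anc_rows, "correlation": corr_rows, "ordering": ord_rows,
        "paths": {name: out / f"table_{name}.tsv"
                  for name in ("ancestral", "correlation", "ordering")},
    }
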