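"""Synthetic trees and binary-trait data with the statistical structure
the analyses assume: a pure-birth tree, one habitat character with a
handful of clade-level shifts, and morphological characters that are
either linked to habitat (habitat-first regime: the derived morphology
is gained at an elevated rate once the lineage is in the exposed
habitat) or evolve independently.

Trait histories are simulated by exact event-driven CTMC simulation
(exponential waiting times, jump probabilities proportional to the
off-diagonal rates), so simultaneous dual transitions are impossible by
construction and full event logs are available.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .ctmc import (BinaryRates, DependentRates, build_binary_matrix,
                   build_dependent_matrix, split_combined_state)
from .phylo import Phylogeny
from .traits import TraitMatrix

__all__ = [
    "Scenario", "load_preset", "simulate_yule_tree", "simulate_markov_paths",
    "simulate_traits", "simulate_dual_pair", "simulate_conditional_binary",
    "inject_missing", "make_fixture",
]


def load_preset(name: str) -> dict:
    """Load a named scenario preset from the packaged presets file."""
    text = resources.files("traitcorr").joinpath("data/presets.yaml").read_text()
    presets = yaml.safe_load(text)
    if name not in presets:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(presets)}")
    return presets[name]


@dataclass
class Scenario:
    """A complete recipe for one synthetic dataset."""

    name: str = "moss_epiphyte"
    n_taxa: int = 44
    birth_rate: float = 1.0
    newick: str | None = None          # overrides the pure-birth tree
    tree_total_length: float = 2.0     # rescale target; None keeps raw lengths
    habitat_rates: BinaryRates = field(default_factory=lambda: BinaryRates(4.0, 1.5))
    linked_rates: dict = field(default_factory=lambda: {
        "gain_h0": 0.5, "gain_h1": 10.0, "loss_h0": 1.0, "loss_h1": 1.0})
    unlinked_rates: BinaryRates = field(default_factory=lambda: BinaryRates(1.0, 1.0))
    n_linked: int = 4
    n_unlinked: int = 4
    root_habitat: int = 0
    root_morphology: int = 0
    missing_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_taxa < 4:
            raise ValueError("need at least 4 taxa")
        if not 0 <= self.missing_fraction < 1:
            raise ValueError("missing fraction must be in [0, 1)")

    @classmethod
    def from_preset(cls, name: str, seed: int = 0, **overrides) -> "Scenario":
        p = dict(load_preset(name))
        hab = p.pop("habitat")
        unl = p.pop("unlinked")
        linked = p.pop("linked")
        p.update(overrides)
        return cls(name=name, seed=seed,
                   habitat_rates=BinaryRates(hab["gain"], hab["loss"]),
                   linked_rates=linked,
                   unlinked_rates=BinaryRates(unl["gain"], unl["loss"]),
                   **p)


def simulate_yule_tree(n: int, birth_rate: float, seed: int) -> Phylogeny:
    """Pure-birth tree grown to ``n`` contemporaneous tips (labelled t1..tn).

    Waiting times between successive splits are exponential with total
    rate (number of lineages) x birth_rate; after the last split the
    tips are extended by one further exponential interval.
    """
    if n < 2 or birth_rate <= 0:
        raise ValueError("need n >= 2 and birth_rate > 0")
    rng = np.random.default_rng(seed)
    parent = [-1, 0, 0]
    birth_time = [0.0, None, None]   # split time per internal node
    active = [1, 2]                  # currently unsplit lineages
    t = 0.0
    while len(active) < n:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        k = int(rng.integers(len(active)))
        node = active.pop(k)
        birth_time[node] = t
        for _ in range(2):
            parent.append(node)
            birth_time.append(None)
            active.append(len(parent) - 1)
    t += rng.exponential(1.0 / (birth_rate * n))
    lengths, labels = [], []
    tip_no = 0
    for i, p in enumerate(parent):
        end = birth_time[i] if birth_time[i] is not None else t
        start = 0.0 if p < 0 else birth_time[p]
        lengths.append(end - start)
        if birth_time[i] is None:
            tip_no += 1
            labels.append(f"t{tip_no}")
        else:
            labels.append(None)
    return Phylogeny(parent, lengths, labels)


def simulate_markov_paths(tree: Phylogeny, Q: np.ndarray, root_state,
                          rng: np.random.Generator):
    """Exact CTMC simulation of one character down every branch.

    ``root_state`` is an integer state or a probability vector to draw
    from.  Returns ``(node_states, branch_events)`` where
    ``branch_events[i]`` lists ``(time_from_branch_start, new_state)``
    for the branch above node ``i``.
    """
    k = Q.shape[0]
    if isinstance(root_state, (int, np.integer)):
        s0 = int(root_state)
    else:
        s0 = int(rng.choice(k, p=np.asarray(root_state, float)))
    node_states = np.empty(tree.n_nodes, dtype=np.int64)
    node_states[tree.root] = s0
    branch_events: dict[int, list[tuple[float, int]]] = {i: [] for i in range(tree.n_nodes)}
    for i in tree.postorder[::-1]:  # preorder
        if i == tree.root:
            continue
        s = int(node_states[tree.parent[i]])
        t, length = 0.0, float(tree.lengths[i])
        while True:
            total = -Q[s, s]
            if total <= 0:
                break
            t += rng.exponential(1.0 / total)
            if t >= length:
                break
            probs = np.clip(Q[s], 0.0, None)
            probs[s] = 0.0
            s = int(rng.choice(k, p=probs / probs.sum()))
            branch_events[i].append((t, s))
        node_states[i] = s
    return node_states, branch_events


def simulate_traits(tree: Phylogeny, Q: np.ndarray, root, seed: int
                    ) -> dict[str, int]:
    """Leaf states of one character simulated under generator ``Q``."""
    rng = np.random.default_rng(seed)
    node_states, _ = simulate_markov_paths(tree, Q, root, rng)
    return {lab: int(node_states[i]) for lab, i in tree.leaf_index.items()}


def simulate_dual_pair(tree: Phylogeny, rates: DependentRates, root, seed: int
                       ) -> tuple[dict[str, int], dict[str, int]]:
    """Joint (habitat, morphology) leaf states under the dependent model."""
    states = simulate_traits(tree, build_dependent_matrix(rates), root, seed)
    habitat = {t: split_combined_state(s)[0] for t, s in states.items()}
    morph = {t: split_combined_state(s)[1] for t, s in states.items()}
    return habitat, morph


def simulate_conditional_binary(tree: Phylogeny, habitat_states: np.ndarray,
                                habitat_events: Mapping[int, list],
                                gain: tuple[float, float], loss: tuple[float, float],
                                root_state: int, rng: np.random.Generator
                                ) -> dict[str, int]:
    """Simulate a binary character whose rates depend on the habitat path.

    ``gain[h]``/``loss[h]`` are the 0->1 and 1->0 rates while the
    lineage occupies habitat state ``h``.  Together with the habitat's
    own (morphology-independent) rates this realises exact joint
    simulation under a dependent-model generator of the habitat-first
    form, with the habitat path shared across characters.
    """
    node_m = np.empty(tree.n_nodes, dtype=np.int64)
    node_m[tree.root] = int(root_state)
    for i in tree.postorder[::-1]:
        if i == tree.root:
            continue
        m = int(node_m[tree.parent[i]])
        h = int(habitat_states[tree.parent[i]])
        length = float(tree.lengths[i])
        # habitat segments along this branch
        times = [t for t, _ in habitat_events[i]] + [length]
        hstates = [h] + [s for _, s in habitat_events[i]]
        t = 0.0
        for seg_end, seg_h in zip(times, hstates):
            while t < seg_end:
                rate = gain[seg_h] if m == 0 else loss[seg_h]
                if rate <= 0:
                    break
                dt = rng.exponential(1.0 / rate)
                if t + dt >= seg_end:
                    break
                t += dt
                m = 1 - m
            t = seg_end
        node_m[i] = m
    return {lab: int(node_m[i]) for lab, i in tree.leaf_index.items()}


def inject_missing(traits: TraitMatrix, fraction: float, seed: int) -> TraitMatrix:
    """Independently blank each cell with the given probability."""
    if not 0 <= fraction < 1:
        raise ValueError("missing fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    arr = traits.frame.to_numpy(dtype=float).copy()
    mask = rng.random(arr.shape) < fraction
    arr[mask] = np.nan
    frame = pd.DataFrame(arr, index=traits.frame.index,
                         columns=traits.frame.columns)
    return TraitMatrix(frame)


def generate_dataset(scenario: Scenario) -> tuple[Phylogeny, TraitMatrix, dict]:
    """Simulate the tree, trait table and ground truth for a scenario."""
    sc = scenario
    if sc.newick:
        from .phylo import parse_newick
        tree = parse_newick(sc.newick)
    else:
        tree = simulate_yule_tree(sc.n_taxa, sc.birth_rate, seed=sc.seed)
    if sc.tree_total_length:
        tree = tree.rescale(sc.tree_total_length)

    rng = np.random.default_rng(sc.seed + 1)
    Qh = build_binary_matrix(sc.habitat_rates)
    hab_states, hab_events = simulate_markov_paths(tree, Qh, sc.root_habitat, rng)
    columns = {"habitat": {lab: int(hab_states[i])
                           for lab, i in tree.leaf_index.items()}}
    truth: dict = {
        "scenario": sc.name, "seed": sc.seed,
        "habitat": {"gain": sc.habitat_rates.alpha, "loss": sc.habitat_rates.beta},
        "characters": {},
    }
    lr = sc.linked_rates
    for j in range(sc.n_linked):
        name = f"c{j + 1}"
        columns[name] = simulate_conditional_binary(
            tree, hab_states, hab_events,
            gain=(lr["gain_h0"], lr["gain_h1"]),
            loss=(lr["loss_h0"], lr["loss_h1"]),
            root_state=sc.root_morphology, rng=rng)
        truth["characters"][name] = {"model": "dependent", "rates": dict(lr)}
    Qu = build_binary_matrix(sc.unlinked_rates)
    for j in range(sc.n_unlinked):
        name = f"c{sc.n_linked + j + 1}"
        node_states, _ = simulate_markov_paths(tree, Qu, sc.root_morphology, rng)
        columns[name] = {lab: int(node_states[i])
                         for lab, i in tree.leaf_index.items()}
        truth["characters"][name] = {
            "model": "independent",
            "rates": {"gain": sc.unlinked_rates.alpha, "loss": sc.unlinked_rates.beta}}

    taxa = sorted(tree.taxa, key=lambda s: (len(s), s))
    frame = pd.DataFrame({c: [float(v[t]) for t in taxa] for c, v in columns.items()},
                         index=pd.Index(taxa, name="taxon"))
    traits = TraitMatrix(frame)
    if sc.missing_fraction > 0:
        traits = inject_missing(traits, sc.missing_fraction, seed=sc.seed + 2)
        # habitat coding is complete in the emulated study design
        traits.frame["habitat"] = frame["habitat"]
    return tree, traits, truth


def make_fixture(scenario: Scenario, output_dir) -> dict[str, Path]:
    """Write tree (Newick), trait table (TSV) and truth file (JSON)."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    tree, traits, truth = generate_dataset(scenario)
    paths = {"tree": out / "tree.nwk", "traits": out / "traits.tsv",
             "truth": out / "truth.json"}
    paths["tree"].write_text(tree.to_newick() + "\n")
    traits.to_tsv(paths["traits"])
    paths["truth"].write_text(json.dumps(truth, indent=2) + "\n")
    return paths
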