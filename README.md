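# traitcorr

Bayesian tests of correlated evolution between binary characters on a
phylogeny — built for the question of whether specialised (reduced)
sporophyte morphologies in mosses evolved *after* shifts into exposed
epiphytic/epilithic habitats (adaptation) or *before* them
(exaptation), but applicable to any habitat/morphology pair of binary
characters with a rooted tree.

## What it computes

For a rooted tree with branch lengths, one binary habitat character
(0 = soil/unexposed, 1 = epiphytic/exposed) and binary morphological
characters (0 = plesiomorphic, 1 = derived, `-` = missing):

1. **Correlation test.**  Compares a dependent model *D* — a 4-state
   CTMC over combined states (h, m) with up to eight single-change
   rates q12, q13, q21, q24, q31, q34, q42, q43 (dual changes
   impossible) — against the independent model *I* (each trait's rates
   unaffected by the other; 4 free rates).  Support is measured two
   ways: a Bayes factor `BF = 2 (lnL_D − lnL_I)` from harmonic-mean
   log marginal likelihoods of replicate MCMC runs (best run per
   model), and the frequency of visits to independent-model rate-class
   partitions in a reversible-jump chain, compared against the exactly
   enumerated prior odds (275 for the 4140-partition space).  BF > 2
   is positive, BF > 5 strong evidence.
2. **Ancestral states.**  Marginal posterior state probabilities at
   queried nodes (MRCA of a taxon set) and fossil-constrained Bayes
   factors: the node is fixed to state 0 and then 1, and
   `BF(1) = 2 (lnL₁ − lnL₀)` from the harmonic means of the two
   constrained runs.
3. **Ordering test.**  For correlated characters, did habitat change
   first?  The posterior of q12 (habitat gain while morphology is
   ancestral) is compared with q13 (morphology gain while habitat is
   ancestral) by a Mann-Whitney test, and the dependent model is
   compared against a restricted model with q12 = q13 (7 parameters).
   q12 ≫ q13 is the habitat-first (adaptation-compatible) signature.

Rates have uniform priors on [0, 100]; likelihoods use Felsenstein
pruning with missing data as total ambiguity.  A synthetic-data module
generates pure-birth trees and exact event-driven trait histories, so
the whole pipeline is testable without any external data.  See
`docs/methods.md` for the model details and caveats.

## Worked example

```bash
python analysis/01_simulate_dataset.py --seed 5
python analysis/03_correlation_tests.py --seed 5
python analysis/04_ordering_tests.py --seed 5
```

The first script writes a 44-taxon fixture under `results/fixture/`
and prints its shape:

```
44 taxa, 8 morphological characters (4 habitat-linked: c1, c2, c3, c4)
habitat: 31 exposed tips in 3 clade-level shifts
missing cells: 20
```

The second runs the correlation test per character (three
reversible-jump chains under each model family) and prints:

```
c1: BF = +4.02 (positive); I visits 4/2/7 of 2000, visit BF +1.19
c2: BF = -1.54 (none); I visits 25/27/34 of 2000, visit BF -2.49
c3: BF = +5.19 (strong); I visits 1/2/3 of 2000, visit BF +2.58
c4: BF = +6.09 (strong); I visits 1/1/3 of 2000, visit BF +1.77
c5: BF = -1.53 (none); I visits 22/16/22 of 2000, visit BF -2.24
c6: BF = +0.19 (none); I visits 22/25/30 of 2000, visit BF -2.49
c7: BF = -2.98 (none); I visits 40/28/33 of 2000, visit BF -3.45
c8: BF = +6.40 (strong); I visits 4/0/6 of 2000, visit BF +0.38
```

Three of the four truly habitat-linked characters (c1, c3, c4) earn
positive-to-strong harmonic-mean support for the dependent model, and
the best unrestricted chain visits independent partitions far less
often than the prior odds (275) predict.  Three of the unlinked
characters (c5–c7) are correctly flat or negative; c8 is a desk-scale
false positive and c2 a miss — at these chain lengths BFs carry noise
of a couple of units, which the replicate SDs in the written table
make visible.  The third script then asks, for each strongly
correlated character, which changed first:

```
c3: q12 = 11.13±13.65, q13 = 6.90±7.27, p = 4.64e-43, BF(R vs D) = +3.88 -> q12 larger
c4: q12 = 27.50±18.88, q13 = 3.64±4.44, p = 0, BF(R vs D) = -5.12 -> q12 larger
```

The habitat-gain rate q12 dominates the morphology-gain rate q13, as
the habitat-first generating regime dictates; the restricted model
(q12 = q13) is not decisively worse by harmonic means, mirroring how
this comparison typically behaves on data of this size.
`analysis/02_ancestral_states.py` produces the ancestral-state table
(marginal probabilities plus fossil-constrained BFs at the root and at
every habitat-shift clade) the same way; every stage is also a library
call (`traitcorr.correlation_test`, `ancestral_reconstruction`,
`ordering_test`, `run_full_analysis`) and a `traitcorr` CLI subcommand
(`simulate`, `correlate`, `ancestral`, `ordering`, `run-all`).

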