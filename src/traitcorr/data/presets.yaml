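# Scenario presets for the synthetic-data generator.
#
# moss_epiphyte emulates the study-shaped dataset: ~44 taxa, one fully
# scored habitat character with a handful of clade-level shifts, four
# morphological characters linked to habitat in the habitat-first
# regime (derived morphology gained at a much higher rate once the
# lineage is in the exposed habitat) and four evolving independently,
# with sporadic missing entries.  Trees are rescaled so each character
# sees roughly 2-6 state changes.
moss_epiphyte:
  n_taxa: 44
  birth_rate: 1.0
  tree_total_length: 2.0
  missing_fraction: 0.05
  n_linked: 4
  n_unlinked: 4
  habitat: {gain: 4.0, loss: 1.5}
  linked: {gain_h0: 0.5, gain_h1: 10.0, loss_h0: 1.0, loss_h1: 1.0}
  unlinked: {gain: 1.0, loss: 1.0}

# habitat_first: full eight-rate set for joint two-trait simulation.
# Habitat gain (q12) is 10x the morphology gain in the ancestral
# habitat (q13); the morphology gain after the habitat shift (q24) is
# 20x q13.  Used on 64-taxon trees rescaled to total length 4, which
# yields roughly ten changes per character -- enough realised dual
# transitions for the correlation signal to be identifiable.
habitat_first:
  rates: {q12: 5.0, q13: 0.5, q21: 1.0, q24: 10.0,
          q31: 1.0, q34: 5.0, q42: 1.0, q43: 1.0}
  n_taxa: 64
  tree_total_length: 4.0

# independent: matched-magnitude null with no habitat-morphology link.
independent_pair:
  habitat: {gain: 2.5, loss: 0.5}
  morphology: {gain: 1.5, loss: 1.0}
  n_taxa: 64
  tree_total_length: 4.0
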