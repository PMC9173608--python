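# Supplementary data drop-in

This directory is intentionally empty in the distributed repository.
Place the study's supplementary tables here (converted to CSV) to enable
the externally-anchored acceptance targets and the conditional acceptance
test:

- `species_table.csv` — columns `species,family` (one row per study species)
- `species_scores.csv` — columns `species,score` (species-level aesthetic values)
- `trees.nwk` — newick tree set (e.g., 100 resolved phylogenies) whose tip
  labels match the `species` column

`scripts/acceptance.py` computes family means, the species count, and the
mean maximum-likelihood phylogenetic-signal lambda from whichever of these
files are present, and omits those targets otherwise.
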