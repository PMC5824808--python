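# cryptclock

Clonal-evolution analysis of allele-specific copy-number profiles from
single crypts and whole-biopsy epithelium, at desk scale and fully
testable offline:

- **profiles_io** — segment tables (TSV), sample sheets (CSV), annotated
  Newick trees and posterior traces, with strict validation of the shared
  within-patient segment grid.
- **markers** — allele phasing across samples, allele-specific breakpoint
  markers, presence/absence character matrices (NEXUS export), clonality
  and crypt-vs-biopsy divergence statistics, 1 Mb window distances.
- **parsimony_phylo** — Fitch scoring, exhaustive and heuristic
  (stepwise addition + NNI) tree search rooted on an all-absent "normal"
  pseudo-tip, branch lengths as change counts, patristic distances and
  diversity.
- **clock_inference** — Bayesian copy-number clock: a per-allele
  birth-death CTMC on copy states 0..K, Felsenstein pruning on a
  time-calibrated tree with a constant-size coalescent prior, strict or
  random-local-clock branch rates, an irreversible genome-doubling overlay
  character, Metropolis-Hastings sampling, HPD/ESS summaries, posterior
  density overlap, and rate-change consensus trees.
- **ploidy_gd** — length-weighted ploidy, genome-doubling calls
  (strict > 3 by default, configurable), bimodality summary.
- **spatial_stats** — within/between-biopsy rank-sum tests, diversity
  correlations, physical-vs-evolutionary permutation tests with Holm (or
  Bonferroni) correction, the multivariate linear model of biopsy-pair
  distances, alteration-vs-GEJ correlations.
- **clonal_maps** — PCA → RGB sample colors and deterministic biopsy/crypt
  map layouts (JSON + SVG).
- **synthetic_data** — ground-truthed cohort simulator: serial coalescent
  crypt genealogies, Gillespie event placement, founder events, clade
  rate shifts, genome doublings, GEJ rate gradients, biopsy consensus
  profiles, and crypt measurement noise.

## CLI

```bash
cryptclock simulate --config sim.json --seed 3 --out cohort/
cryptclock validate cohort/segments.tsv cohort/samples.csv --grid cohort/truth.json
cryptclock markers  cohort/segments.tsv --out chars.nex
cryptclock tree     cohort/segments.tsv --out tree.nwk
cryptclock distances tree.nwk --sheet cohort/samples.csv --out pairs.tsv
cryptclock ploidy   cohort/segments.tsv --out ploidy.tsv
cryptclock clock    cohort/segments.tsv cohort/samples.csv \
    --grid cohort/truth.json --mode rlc --out-prefix clock
cryptclock stats    tree.nwk cohort/samples.csv --out-prefix stats
cryptclock map      cohort/segments.tsv cohort/samples.csv --out-prefix map
```

## Conventions

Coordinates are 0-based half-open; chromosome names carry no `chr`
prefix; autosomes only; the diploid normal state is `(cn1, cn2) = (1, 1)`.
All randomness flows through explicit integer seeds; simulator outputs
are bit-identical for a fixed seed.
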