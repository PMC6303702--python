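# phyloconv

Phylogenetic convergence analysis for continuous (morphometric) traits:

1. **shapes** — TPS landmark ingestion, Generalized Procrustes
   superimposition, covariance PCA, species-mean PC scores.
2. **treeio** — Newick parsing/writing, pruning, patristic distances,
   ultrametricity checks (stable post-order integer node ids).
3. **ancestral** — branch-length-weighted squared-change parsimony and
   phylomorphospace layouts.
4. **oumodels** — Brownian-motion and multi-regime Hansen
   (Ornstein–Uhlenbeck) fits with AICc, plus the stepwise
   forward-shift / backward-collapse regime search (SURFACE-style) and its
   bookkeeping (k, k′, Δk, c, convergent/non-convergent regime counts,
   four-model OUc/OUnc/OU1/BM comparison).
5. **convmetrics** — distance-based convergence measures C1–C4 and the
   frequency-based C5 (lineages entering the focal convex hull of a
   phylomorphospace), with Brownian-motion simulation nulls.
6. **wheatsheaf** — phylogenetically penalized strength-of-convergence
   index with permutation p-value and stratified-bootstrap CI.
7. **synthetic_data** — Yule trees, exact BM/OU trait simulators, landmark
   synthesis, and a planted-convergence scenario generator (a ~12-My
   radiation plus one ~77-My divergent lineage, three traits, six focal
   taxa sharing a convergent optimum) with a JSON truth record.
8. **pipeline / cli** — end-to-end orchestration with JSON/TSV reports.

## CLI

```bash
# synthetic scenario (tree.nwk, traits.csv, truth.json)
phyloconv simulate --seed 1 --out sim/

# GPA + PCA on landmarks -> species-mean PC scores
phyloconv shapes --tps landmarks.tps --out species_scores.csv

# regime search and four-model table
phyloconv surface --tree sim/tree.nwk --traits sim/traits.csv --out surface.json

# convergence metrics / Wheatsheaf for one focal set
phyloconv cmetrics  --tree sim/tree.nwk --traits sim/traits.csv \
    --focal outgroup,sp3,sp14 --seed 1 --out cmetrics.json
phyloconv wheatsheaf --tree sim/tree.nwk --traits sim/traits.csv \
    --focal outgroup,sp3,sp14 --seed 1 --out wheatsheaf.json

# full pipeline from a JSON config (see AnalysisConfig)
phyloconv run-all --config config.json --out results/
```

Exit codes: 0 success, 2 input error, 3 numerical failure. All stochastic
commands require `--seed` and are bitwise reproducible.

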