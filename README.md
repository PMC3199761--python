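# dclink — link-based differential coexpression analysis

`dclink` identifies **differentially coexpressed genes (DCGs)** and
**differentially coexpressed gene pairs / links (DCLs)** between two
conditions (e.g. disease vs. normal) from bulk expression data.  Most
differential coexpression measures compare a gene's *connectivity* —
how many neighbors it has in each condition's coexpression network —
which discards the quantitative correlation change of each pair and is
blind to **correlation reversal** (a pair strongly positively correlated
in one condition and strongly negatively in the other).  `dclink`
implements two link-based methods that work directly on the per-pair
correlation change, together with the connectivity-based comparators,
a ground-truth simulator and an evaluation protocol.

## Methods

Let `x_ij`, `y_ij` be the Pearson correlations of genes *i*, *j* under
conditions X and Y.  A **half-thresholding** filter keeps pair (i, j)
in *both* networks when at least one of the two correlations is
informative — by default, when `min(q_x, q_y) < 0.25` with per-condition
Benjamini–Hochberg q-values (an absolute-correlation cutoff ρ is also
supported).  The N surviving links form one shared link universe.

- **DCp** — for gene *i* with neighbors 1..n in the filtered set, the
  coexpression profiles `X = (x_i1..x_in)`, `Y = (y_i1..y_in)` give

      dC_i = sqrt( Σ_j (x_ij − y_ij)² / n )        ∈ [0, 2]

  Significance by condition-label permutation: shuffle samples between
  the two conditions, re-run the whole pipeline, pool all permutation
  dC values into one empirical null (default 1000 rounds).

- **DCe** — classifies each filtered link as *same-signed*,
  *diff-signed*, or *reversed* (opposite signs, both passing the
  cutoff; reversed links are DCLs outright).  The remaining classes are
  screened with the limit-fold-change model: bin links by the predictor
  (max absolute correlation for same-signed links, log absolute
  correlation ratio for diff-signed links — roles flipped), take the
  top fraction δ = 0.1 of each bin by response, fit `y = a + b/x` to
  the per-bin boundary outliers, and flag links above the curve.  With
  K DCLs among N links, gene *i* with `k_i` DCLs among its `n_i` links
  gets the upper-tail binomial p-value `P(X ≥ k_i)`, `X ~ Bin(n_i, K/N)`.

- **Baselines** — LRC (`|log10` ratio of hard-threshold connectivities`|`),
  ASC (mean count of condition-specific connections) and WGCNA-style
  differential weighted connectivity (signed `((1+r)/2)^β` or unsigned
  `|r|^β` adjacency, default β = 12).

- **Simulator** — builds a signed directed regulatory network, perturbs
  a fraction of edges by *regulation-elimination* or *regulation-switch*,
  and simulates paired expression matrices; perturbed links/genes
  (DRLs/DRGs) are the ground truth for ROC and enrichment evaluation.

## Worked example

```sh
dclink simulate --genes 200 --rate 0.1 --mode switch --samples 10 \
    --seed 3 --out sim/
dclink run --cond-x sim/cond_x.tsv --cond-y sim/cond_y.tsv \
    --n-perm 100 --seed 1 --out results/
dclink evaluate roc --scores results/dcp_dcg.tsv --truth sim/drgs.txt
```

The first command plants 20 regulation switches (10% of 200 edges) and
writes the two condition matrices plus truth files.  The `run` command
prints the pipeline bookkeeping and writes the link and gene tables:

```
INFO dclink.io: filtered link universe: N = 1065 of 19900 pairs
INFO dclink.dce: DCe: N = 1065 filtered links, K = 136 DCLs
INFO dclink.io: DCe: 136 DCLs, 199 genes scored
wrote 8 result tables to results/
```

i.e. 1065 of the 19 900 gene pairs carry an informative correlation in
at least one condition, and DCe flags 136 of them as differentially
coexpressed.  The final command scores the DCp ranking against the
planted truth:

```
{"auc": 0.8315151515151515, "n_genes": 200, "n_truth": 35}
```

an AUC of 0.83 for retrieving the 35 genes touched by a planted switch.
Top-ranked genes in `results/dcp_dcg.tsv` come with their dC scores and
permutation p-values.

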