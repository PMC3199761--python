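# Methods

## Problem setting

Given two genes × samples expression matrices over the same gene
universe — one per biological condition — the task is to find genes and
gene pairs whose *coexpression* (Pearson correlation, PCC) changes
between the conditions.  Differential coexpression complements
differential expression: a gene can keep its mean level while switching
the community it is coordinated with, and a pair can reverse the sign
of its correlation entirely.  Both matrices must be complete (missing
values are rejected rather than handled by pairwise-complete
correlation, which would silently vary the degrees of freedom from pair
to pair) and carry at least 4 samples, the minimum for a PCC p-value
with `df = n − 2 ≥ 2`.

## Shared pre-processing: correlations and the half-threshold filter

All `G(G−1)/2` unordered pairs are correlated in each condition.
Two-sided p-values use the standard t-transform
`t = r·sqrt((n−2)/(1−r²))` with `n − 2` degrees of freedom (`|r| = 1`
maps to `p = 0`); q-values are Benjamini–Hochberg adjusted *within each
condition*, treating each condition's all-pairs screen as its own
family of tests.  Genes with zero variance in either condition
(constant probes) are excluded from the link universe with a warning.

The half-thresholding filter keeps a pair in **both** condition
networks when either side is informative:

* q-mode (default): `min(q_x, q_y) < q_th`, default `q_th = 0.25`;
* ρ-mode: `max(|x|, |y|) ≥ ρ`.

Exactly one mode must be specified.  The result is one shared link
universe of size N: two networks with identical structure and different
link weights.  Raising `q_th` (or lowering ρ) only ever adds links.

## DCp

For gene *i* with *n* filtered-set neighbors, the two coexpression
profiles X and Y give the root-mean-square change
`dC_i = sqrt(Σ_j (x_ij − y_ij)² / n)`, bounded by 2 (every neighbor
correlation flipping from +1 to −1).  dC is symmetric in the two
conditions and invariant to neighbor order; genes with no kept links
have no score and are reported as undefined.

Significance: condition labels are permuted over the pooled samples,
preserving the two group sizes; each round re-runs the *entire*
pipeline — correlations, BH, filter, dC — so the link universe itself
is re-derived per permutation.  All permutation dC values, across genes
and rounds, are pooled into a single empirical null, and
`p = (1 + #{null ≥ observed}) / (1 + #null)` (add-one estimator, never
exactly zero; bit-reproducible under a fixed seed).  Pooling across
genes buys resolution — 1000 rounds would otherwise cap per-gene
p-values at 1/1001 — at the cost of assuming comparable null dC
distributions across genes.  Two residual effects are worth knowing:
low-degree genes have noisier dC than hubs, so their pooled-null
p-values are slightly conservative/anticonservative at the extremes;
and because every gene shares the same observed sample split, gene
p-values co-vary — on an unperturbed dataset they are approximately
U(0,1) marginally, while their joint fluctuations are wider than an
independent sample of the same size.  Default 1000 permutations; the
CLI accepts fewer for quick runs.

## DCe

Each filtered link is summarized by `max_corr = max(|x|, |y|)` and the
log absolute correlation ratio
`lfc = |log((|x| + ε)/(|y| + ε))|`, ε = 1e−4 (natural log; the guard
keeps zero correlations finite and affects nothing else at realistic
correlation scales).  Links partition three ways:

* **reversed** — `x·y < 0` with both sides passing the cutoff (ρ on
  absolute correlations, default 0.8, or q_th on q-values): DCLs
  immediately.  A zero correlation evidences no reversal, so `x·y = 0`
  counts as same-signed.
* **same-signed** (`x·y ≥ 0`) — screened by the limit-fold-change
  model with predictor `max_corr`, response `lfc`.
* **diff-signed** (opposite signs, not both strong) — screened with
  the roles flipped: a strong correlation that fails to reverse
  cleanly is suspicious in proportion to its magnitude.

LFC screen: equal-width bins over the predictor's observed range
(default 20 bins; the bin count is a smoothing parameter — more bins
track the boundary more tightly at the cost of noisier per-bin
quantiles); in each bin the `ceil(δ·size)` links with highest response
are outliers (δ = 0.1 default; ties broken by larger `max_corr`, then
lexicographic gene pair, making the selection deterministic).  The
boundary point of a bin is its lowest-response outlier; `y = a + b/x`
is fit to the boundary points by ordinary least squares on `1/x`, and
links strictly above the curve are DCLs.  A config switch
(`all-outliers`) fits to every per-bin outlier instead.  If the
boundary points are degenerate (fewer than two distinct points, or a
constant response), no curve is identifiable and exactly the per-bin
outliers are flagged, with a warning.

Gene stage: with K DCLs among N links, gene *i* with `k_i` DCLs among
`n_i` links gets the upper-tail binomial probability
`p_i = Σ_{j≥k_i} C(n_i, j)(K/N)^j(1−K/N)^{n_i−j}`.  Degenerate rates
behave naturally (K = 0 or K = N give p = 1).  BH across genes is
added for convenience; the ranking is by p.  The reported DCL set can
be narrowed post hoc to links touching a supplied gene list (typically
the significant DCGs); the enrichment always uses the full universe.

## Baselines

LRC and ASC operate on hard-thresholded networks (`|r| ≥ ρ` per
condition, default ρ = 0.8 shared by both measures):
`LRC = |log10((k_x+1)/(k_y+1))|` (pseudo-count 1 guards empty
neighborhoods; the base only rescales) and
`ASC = (specific_x + specific_y)/2`, counting links present in exactly
one network.  WGCNA-style soft thresholding keeps all pairs with
adjacency `|r|^β` (unsigned) or `((1+r)/2)^β` (signed), default β = 12,
and scores `dC = |wk_x − wk_y|` over the summed adjacencies; a
variant normalized by `max(wk_x, wk_y)` is available behind a flag.
The unsigned adjacency is invariant to a global sign flip of all
correlations — precisely why unsigned WGCNA, LRC and ASC cannot see
correlation reversals, and why the signed variant can.

## Simulator

The generator stands in for kinetic regulatory-network samplers: it is
a statistical emulator with the same perturbation semantics, not a
replica of any specific tool, and no external source networks are
required.

* **Network**: the first 15% of genes are regulatory inputs (roots)
  with no parents — a transcriptional network is driven by many
  independent signals, and a single global root would correlate
  essentially every gene pair.  Each remaining gene receives regulators
  drawn from earlier genes with probability proportional to out-degree
  plus one (preferential attachment → heavy-tailed out-degree, as in
  transcriptional networks).  A cumulative quota holds the edge count
  within rounding of `mean_degree·n/2` (default mean total degree 2).
  Edge signs are +1 (activation) with probability 0.7 — transcriptional
  networks are activator-rich, and the value is immaterial to the
  perturbation semantics — and weights are uniform on [0.5, 1].
* **Expression**: per sample, roots draw independent N(0, 1) levels;
  each regulated gene is `tanh(Σ_p sign_p·weight_p·level_p)` plus
  N(0, noise_sd) noise, evaluated in topological order (cyclic inputs
  would be resolved by a fixed number of sweeps; the internal generator
  is acyclic by construction).  The tanh squashing is bounded and
  sign-preserving, mimicking saturating regulation kinetics without
  kinetic constants.  noise_sd defaults to 0.25, placing the typical
  unperturbed regulator–target |PCC| in the 0.6–0.9 working range
  (asserted in the test suite at large sample count).
* **Perturbation**: exactly `round(rate·|edges|)` edges, uniform
  without replacement; *eliminate* removes the regulation, *switch*
  flips its sign, *mixed* does half each (elimination gets the odd
  extra).  A switched edge flips the sign of the regulator–target
  expression correlation between conditions while broadly preserving
  magnitude; an eliminated edge drives it toward zero.  DRGs are the
  endpoint set of the perturbed links (DRLs).
* **Scale**: defaults are 200 genes and 10 samples per condition with
  a 10% perturbation rate — a deliberate desk-scale rendition of the
  reference protocol (1000-gene networks, the same rate and sample
  range), chosen so the full five-replicate, five-method comparison
  runs in seconds while preserving every qualitative ordering of
  interest.  Headline orderings are therefore compared qualitatively,
  not numerically, against published full-scale values.

What the simulator does **not** emulate: measurement-scale artifacts
(counts, normalization), batch effects, feedback loops, combinatorial
regulation logic beyond additive signed inputs, and hence any claim
that passing benchmarks transfer quantitatively to real data — they
demonstrate correct mechanics and the expected relative behavior of
the methods under planted truth.

## Evaluation

Gene rankings are scored by ROC AUC against the DRG labels (midrank /
trapezoidal tie convention, equal to the Mann–Whitney statistic).
Genes with no defined score share one rank strictly below all scored
genes — dropping them would inflate sensitivity.  DCL sets are scored
by the fraction of truth links they contain versus the background
fraction in the link universe; *extended DRLs* add every universe link
sharing a gene with a DRL, capturing the one-step spread of
coexpression changes.  An empirical significance test compares the
observed fraction with uniformly resampled link sets of the same size
(add-one estimator).  Replicate AUCs are averaged arithmetically.

The paired signed-minus-unsigned WGCNA AUC contrast on switch data is
a small effect (≈ +0.01 at β = 12 in this simulator); the protocol
estimates it over 300 paired replicates rather than the headline five,
which a paired difference of that size requires for a stable sign.

## Numerical and design choices

* BH adjustment wraps the standard step-up implementation
  (statsmodels); the test suite checks it against an independent
  hand-rolled pass.
* Binomial tails come from `scipy.stats.binom.sf`, tested against
  brute-force pmf summation over a full small grid.
* AUC uses scikit-learn's ROC routines, tested against a brute-force
  pair count.
* All tables are plain TSV with `#` metadata headers recording
  version, parameters and seed; a rerun with identical configuration
  and seed is byte-identical.  Every source of randomness flows from
  one seeded generator per entry point.
* Pair canonicalization follows input row order; self-pairs excluded.

## Known limitations

* The pooled permutation null assumes cross-gene homogeneity of the
  dC null; strongly heterogeneous degree distributions bend gene-level
  calibration (see DCp section).
* The LFC boundary depends on the binning; very sparse link sets fall
  back to per-bin selection.
* No Spearman/partial-correlation options, no missing-data handling,
  no module-level (set-wise) differential coexpression, and no
  plotting — reports are data-only.
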