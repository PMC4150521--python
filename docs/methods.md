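# Methods

## Meta-analysis of carriage odds ratios

Each study contributes a 2×2 table (a, b = antigen carriers /
non-carriers among cases; c, d among controls). The per-study effect is
the log odds ratio `ln(ad/bc)` with Woolf's large-sample variance
`1/a + 1/b + 1/c + 1/d`. When any cell is zero, 0.5 is added to all
four cells of that study only (Haldane–Anscombe; the correction value
is configurable, and a correction of 0 on a zero-cell study is rejected
rather than silently producing an infinite estimate). Studies with no
cases or no controls are rejected at construction.

Fixed-effects pooling is inverse-variance: `θ̂ = Σwᵢθᵢ/Σwᵢ`,
`SE = (Σwᵢ)^(−1/2)`, `wᵢ = 1/vᵢ`. Heterogeneity is Cochran's
`Q = Σwᵢ(θᵢ − θ̂)²` with an upper-tail χ²(k−1) P-value; for k = 1 the
convention Q = 0, P = 1 applies. The between-study variance is the
DerSimonian–Laird moment estimate `τ²_raw = (Q − (k−1))/(Σw − Σw²/Σw)`,
clipped at zero for pooling but kept raw for model selection, because
the selection rule below is phrased in terms of a variance estimate
that can go negative.

**Model selection.** The fixed-effects result is reported when
`τ²_raw ≤ 0` **and** the Q-test shows no heterogeneity (P ≥ 0.10);
otherwise the random-effects result with weights `1/(vᵢ + τ²)`. Note a
statistical consequence of demanding both conditions: under a truly
homogeneous data-generating process, `τ²_raw > 0` exactly when
Q exceeds its degrees of freedom, which happens in roughly 45% of
replicates, so the random-effects model is chosen almost half the time
even when τ² = 0 is the truth. In those cases the fitted τ² is barely
above zero and the two models nearly coincide; CI coverage of the true
OR stays at its nominal level (checked by simulation in the test
suite). The generator calibration test asserts this behaviour rather
than a near-certain fixed-model choice.

All confidence intervals use the normal 1.96 multiplier on the log
scale. The sensitivity analysis refits the whole pipeline (including
model re-selection) on every leave-one-out subset. Subgroup analyses
(by population or typing technique) are row filters on the study table,
not separate code paths.

## Concept profiles and cohesion

Profiles are built from per-document binary occurrence indicators. The
weight of gene g in the profile of concept C is the symmetric
uncertainty `U(C,G) = 2·I(C;G)/(H(C)+H(G))` (base-free; 1 when the
indicators coincide, 0 when they are independent), defined as 0 when
the concept and gene never co-occur or when both indicators are
constant. Tiny negative mutual-information round-off is clamped to 0.
Zero weights are not stored but count toward the vocabulary size, and
two profiles can only be compared when built over vocabularies of equal
size.

The cohesion score is the plain inner product of two profiles (not
cosine): that choice makes the per-gene decomposition
`percent(g) = 100·w_a(g)·w_b(g)/CS` exact, and contribution
percentages are invariant under rescaling of either profile, which is
what the published percentages can actually verify (the absolute CS
scale cannot be checked from printed data). Contribution tables are
sorted by decreasing percentage with lexicographic tie-breaks, and a
threshold keeps genes with a share *strictly* above it.

The permutation P draws random groups of distinct profiles from a
caller-supplied pool (group score = pairwise CS for pairs, mean
pairwise CS for larger groups) and reports `(r+1)/(N+1)` where r counts
null scores ≥ the observation — the add-one correction avoids an exact
zero that N iterations cannot support. The pool is an explicit argument
because the appropriate null population (all concepts, gene concepts
only, ...) is a modelling choice the caller should see.

### Known inconsistency in the published contribution table

The shipped 21-gene table reproduces its printed percentages from the
printed weight products to within 10% relative error for 20 of 21 rows
and preserves their printed rank order — except the WT1 row, whose
printed weights (1.599E−6 × 1.000E−4) imply a 0.123% contribution, not
the printed 0.147%, and place WT1 below SELL. The acceptance test for
table consistency asserts the full property and therefore fails on
exactly that row; this is a documented defect of the published table
(most plausibly a typo in one WT1 weight), not of the decomposition.

## Subnetwork expansion and intermediate scoring

The background loader builds an undirected simple graph from
tab-separated or SIF edge lists, merging duplicate edges by unioning
their reference sets and dropping self-loops with a warning. The
reference filter marks a reference hub-like when it supports more than
`max_links_per_reference` edges (default 4) and keeps an edge iff it
has at least one non-hub reference and at least `min_references`
references (default 0). Edges with no reference annotation pass the hub
rule — nothing implicates them — but fail any positive
`min_references` requirement. The filter is idempotent because hub
status is decided on the input network each time and surviving edges
keep their full reference sets.

Expansion supports exactly the maximum path length of two: the
subnetwork is all seed–seed edges plus every non-seed node adjacent to
≥ 2 distinct seeds, with only its seed-incident edges
(intermediate–intermediate edges are dropped). This makes the
subnetwork's link count equal the seed–seed edge count plus the sum of
per-intermediate seed links, the identity the published table exhibits
(Σk = 29 with no seed–seed edges).

Each intermediate with background degree n and k seed links gets
`z = (k/n − p₀)/√(p₀(1−p₀)/n)`, `p₀ = L_sub/L_bg`, one-sided
significance at z ≥ 2.5, no multiple-testing correction and no
continuity correction — the plain formula reproduces all 13 published
z values within the ±0.02 truncation band, so nothing more elaborate is
warranted. "Links in background" is the filtered background's total
edge count (a global constant) and "links" a node's background degree;
this is the only reading under which every printed z reproduces.

The published background itself is not available, so
`datasets.reconstruct_intermediate_network` materialises one concrete
graph consistent with every published number: each intermediate wired
to its stated number of distinct seeds (round-robin over the 10 seed
proteins), padded with filler neighbours to its stated background
degree, plus a filler chain bringing the edge total to exactly 11429,
each edge carrying a unique reference. Any background with those
per-node (n, k) and global (29, 11429) constants yields identical
z-scores, so the arbitrary choices (which seeds, filler topology) are
provably immaterial to the scores.

## Synthetic data

* **Study tables** — per study, a true log OR is drawn from
  `Normal(ln OR, σ²_between)`; control carriers are binomial at the
  control carrier frequency and case carriers binomial at the
  odds-transformed case probability. Defaults are the study conditions
  of the carriage analysis: the 19 published case/control totals, a 40%
  control carrier frequency (typical of HLA-A2 in European-ancestry
  populations), true OR 1.1 and no between-study dispersion.
* **Corpora** — every concept occurs independently per document at the
  baseline rate (default 0.15, so a few hundred documents give stable
  entropy estimates); in documents containing a query concept, each
  planted gene's occurrence is *redrawn* at the planted rate, so
  setting the planted rate to the baseline plants exactly nothing. A
  document that draws no concept receives the neutral `BACKGROUND`
  marker so the document count is exact and concept sets stay
  non-empty. The generator emulates co-mention structure only — no
  language, no ambiguity, no citation dynamics — so passing tests show
  the scoring machinery is correct, not that real literature behaves
  this way.
* **Networks** — Erdős–Rényi at the requested mean degree (degree
  realism is irrelevant to the z-score identities under test; a
  degree-preserving rewiring utility is provided for null comparisons),
  with planted connectors wired to a fixed number of distinct seeds on
  top of their random wiring, and one unique reference per edge.

All generators are deterministic given their seed and write files with
a provenance comment (full parameter set and seed) that the readers
skip.

## Problem sizes and numerical choices

Simulation-backed tests use deliberately modest sizes — 50 random study
sets for oracle equivalence (agreement to 1e−6), 200 replicates for CI
coverage and selection calibration, 500 repeats × 200 iterations on a
120-document corpus for permutation uniformity (Kolmogorov–Smirnov
against uniform at P > 0.01), 100 rewirings for the connector null —
chosen so the whole suite runs in seconds while keeping each check's
Monte-Carlo error well inside its assertion margin. Determinism
contracts are enforced end-to-end (same config + seed ⇒ byte-identical
reports); report files embed their parameters and seeds and contain no
timestamps.
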