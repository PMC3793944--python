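# Methods

## The model

`icclust` finds, for a chosen *target* gene, the largest maximally
interconnected correlated gene cluster (ICGC) in an expression matrix
**X** (genes × samples):

1. **Target-conditioned correlation.** For every gene *i* ≠ target,
   compute the Pearson product-moment correlation
   r_i = corr(X[i], X[target]) across samples.
2. **Threshold selection.** Keep genes with |r_i| > τ (strict
   inequality), each tagged with sign(r_i). Positively and negatively
   correlated genes are retained alike: anticorrelated genes are as
   informative about co-regulation as correlated ones.
3. **Graph construction.** Among the selected genes, compute all
   pairwise correlations and connect two genes (edge indicator E = 1)
   whenever pairwise |r| > τ; the signed r is kept as the edge weight.
4. **Clique search.** Enumerate all maximal cliques of this graph with
   the Bron–Kerbosch algorithm and report the largest as the ICGC,
   with the target gene re-attached.

The target is *conditioned on*, not searched over: because every
selected gene is correlated with the target above τ, the target is
adjacent to all graph nodes, so it is held out of the pairwise search
and appended to the winning clique. This is equivalent to including it
and keeps the search smaller. Reported ICGC sizes therefore include
the target.

### Threshold calibration

Correlation coefficients are not normally distributed, so the threshold
is calibrated on the Fisher scale, z = ½·ln((1+r)/(1−r)) = artanh(r),
where the population of per-gene z-scores is approximately normal.
`z_diagnostics` summarizes that population: variance (n−1 denominator),
bias-adjusted skewness with its **exact** standard error
SES = √(6n(n−1)/((n−2)(n+1)(n+3))) — the large-sample √(6/n) shortcut
differs in the fifth decimal already at n ≈ 5000 — bias-adjusted excess
kurtosis, Shapiro–Wilk, and a two-sided one-sample Kolmogorov–Smirnov
test against a normal with the sample's own mean and SD (the reference
is estimated from the same data, so the KS p-value is approximate and
flagged as such). Two-tailed empirical critical values at level α are
the α/2 and 1−α/2 quantiles under the linear-interpolation ("type 7")
convention; a kernel-density alternative would depend on a bandwidth
choice, while quantiles are reproducible without one. Defaults:
α = 0.10, τ = 0.95, both overridable; the sensible working range for τ
is roughly 0.95–0.98, and the right value is a trade-off between
cluster size and stringency.

### Robustness across thresholds

Because τ is a judgment call, `threshold_sweep` runs the pipeline at
several values and reports the percent overlap in cluster composition
between every pair. Overlap denominators are configurable — Jaccard
(default), min-set, or reference-set — and always recorded in the run
configuration, since the three can differ substantially for clusters
of unequal size. A cluster whose core survives tightening of τ is
trustworthy; one that dissolves is not.

### Clique enumeration details

Bron–Kerbosch is implemented with pivoting (the pivot is the vertex of
P∪X with the most neighbours in P); for graphs above 200 nodes the
outer level follows a degeneracy ordering, which bounds recursion depth
on sparse graphs. Output is canonically ordered (size descending, then
lexicographic). Ties among equal-size maximum cliques are broken by
larger mean |r| over within-clique edges, then lexicographically, so
results are bit-for-bit reproducible. Dense graphs can contain
exponentially many maximal cliques; enumeration aborts with a clear
error beyond a configurable cap (default 10⁶). A brute-force
subset-enumeration oracle (≤ 20 nodes) ships in the package and backs
the equivalence tests.

### Direction annotation

Cluster members are labelled *up* (r > 0 versus the target) or *down*
(r < 0). This equates the sign of the correlation with the direction of
co-regulation at the end of the sampled course, which is correct when
the target itself rises late in the course. An alternative mode
computes sign(mean(last time point) − mean(first time point)) when
sample metadata carries time labels.

## Enrichment: the elim procedure

Ontology terms are tested for over-representation of the cluster with a
one-sided Fisher's exact (hypergeometric upper-tail) test, walking the
is_a DAG from the deepest terms (depth = longest path from a root;
lexicographic within a level) up to the root. When a term is
significant, its study genes are eliminated from all its ancestors
before those are tested, so signal is credited to the most specific
term that carries it. Configuration follows the pipeline's defaults:

- terms annotating < 20 universe genes (after true-path propagation)
  are dropped (`min_node_size`);
- the Bonferroni factor m is the number of terms surviving that filter;
- elimination triggers when the Bonferroni-adjusted p < 0.01
  (`node_cutoff`); a switch (`eliminate_on="raw"`) triggers on the raw
  p instead, matching the original elim formulation;
- terms with adjusted p < 0.05 are flagged significant
  (`report_alpha`).

One-sidedness is deliberate: enrichment semantics ask only about
over-representation. Universe genes without any annotation are
excluded from the universe total by default (configurable), since an
unannotatable gene can never contribute to any term's table. On a flat
hierarchy (every term a child of the root) nothing is ever eliminated
and elim reduces exactly to the classic per-term Fisher test — a
property the test suite checks.

`category_mean_p` scores a user-defined gene category by representing
each gene with its single best (minimum-p) tested term — under
true-path semantics the minimum ranges over every tested term
containing the gene — and averaging those minima.

## Differential expression

`identify_degs` runs one two-sided Welch (unequal-variance) t-test per
gene between two disjoint sample groups, with Welch–Satterthwaite
degrees of freedom, and thresholds the **raw** p-value at α = 0.05.
No multiple-testing correction drives the reported counts — this is
the procedure's deliberate, documented convention — but a
Benjamini–Hochberg column is emitted alongside for modern use. Both
groups constant and equal is treated as the defined limit t = 0, p = 1;
constant groups with unequal means leave the statistic undefined and
raise.

## Synthetic benchmark data

`generate_planted_dataset` emulates the shape of a small time-course
microarray experiment: a target gene, a planted block of `planted_size`
genes strongly correlated with it, and i.i.d. noise background. The
defaults are the study conditions the method is designed for — 2000
background genes, 12 samples, 10 planted genes at |r| ≈ 0.99 of which
30% anticorrelated.

The planted block is *equicorrelated with the target*: writing ρ for
`planted_rho`, each planted gene is

    g_i = s_i · (ρ·t + √(1−ρ²)·(√w·u + √(1−w)·e_i)),   w = ρ/(1+ρ),

with t the target profile, u a block-shared noise vector, e_i private
noise, and s_i = ±1. The weight w solves ρ² + (1−ρ²)·w = ρ, so the
population correlation of every planted gene with the target **and**
of every planted pair equals ρ in magnitude — the block is a genuine
planted clique at any threshold below ρ. With fully independent
per-gene noise the pairwise level would only be ρ² (≈ 0.980 at
ρ = 0.99), and at 12 samples enough of the 45 within-block sample
correlations dip under a 0.95 threshold that exact recovery drops to
roughly two-thirds of seeds; the equicorrelated construction recovers
the exact planted set in ≈ 95–97% of seeds. Given the constraints
(all mutual correlations ρ, Gaussian margins) this joint distribution
is unique, so no further sharpening is possible without changing the
stated conditions. Remaining failures are correlated, block-wide
sampling shifts — visible as one or two planted genes slipping just
under the threshold — which is exactly the finite-sample behaviour
the threshold-robustness check is meant to surface.

What the generator does **not** emulate: time-course autocorrelation,
batch or array effects, probe-level noise, heavy-tailed expression, or
correlation structure among background genes. Passing the recovery
tests therefore demonstrates correctness of the machinery under the
stated correlation model, not performance on real microarray data.

`generate_ontology_fixture` builds a random single-root is_a DAG
(depth-layered, occasional double parents), annotates genes to random
terms (Poisson-distributed multiplicity), and over-samples one deep,
well-annotated term's genes into the study set at a stated fraction;
setting that fraction to the background rate yields a null fixture.

Randomness everywhere flows from `numpy.random.default_rng` (PCG64)
with explicit seeds; identical seeds reproduce byte-identical matrices
across platforms.

## Numerical choices

- Sample SD uses the n−1 denominator throughout (z-scores,
  correlations, Welch tests).
- Correlations are clipped into [−1, 1] after computation to absorb
  floating-point overshoot; Fisher z of |r| = 1 is ±∞ and such genes
  are excluded from distribution diagnostics.
- Selection uses strict |r| > τ; a gene at exactly τ is excluded.
- Missing values in input matrices are a hard error by default; the
  only alternative is dropping the gene. No imputation is offered,
  because correlations on imputed profiles would silently distort
  cluster membership.
- Gene tables are written with `%.17g`, which round-trips doubles
  exactly.

## Problem sizes in the validation suite

The test suite and the acceptance script validate at desk scale: 2000
background genes × 12 samples for recovery (20 fixed seeds in the
suite; 100 seeds for the reported Monte Carlo rate), 200+ random graphs
of ≤ 14 nodes for the clique-oracle comparison, and 2000 genes × 10
seeds for the Welch type-I-error check. These sizes give binomial
standard errors comfortably inside the asserted tolerances while the
whole suite runs in seconds.

## Known limitations

- Pearson correlation only; no rank-based or robust variants.
- A single global threshold, not per-gene correlation p-values.
- The pipeline treats replicate arrays as independent samples (a
  replicate-averaging utility exists but is off by default).
- Maximal-clique enumeration is exponential in the worst case; the cap
  turns pathological inputs into a clear error rather than a hang.
- The elim implementation covers is_a edges only; part_of and other
  relations are ignored at parse time.
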