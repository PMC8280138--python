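# Methods

## The weighted-nodes network model

A master network G = (V, E) is an undirected simple connected graph over the
proteins shared by every sample. For one sample, each node v carries a
strictly positive weight w(v). The expanded network G' = (V', E') adds
a = w(v) − 1 copies of each v; {v, v.1, …, v.a} form a clique (edge set I),
and every clique member is wired to every master node u adjacent to v and to
u's copies (edge set C), so E' = E ∪ I ∪ C. With unit weights G' = G.

Counting edges incident to a master node v outside its own clique gives

    Degree(v) = Σ_{u ∈ N(v)} w(u),

which the package takes as *the* degree (`analytic_degree`). Its properties,
all enforced by tests against the explicit expansion:

- structural degree in G' = Degree(v) + (w(v) − 1) for masters; every copy of
  v has the same structural degree as v;
- |V'| = Σ w(v) and |E'| = Σ_{(u,v)∈E} w(u)w(v) + Σ_v C(w(v), 2);
- linearity: Degree scales with the weights, so real-valued weights are used
  directly and integerization is needed only to materialize a graph;
- self-independence: Degree(v) never depends on w(v).

Integerization (`integerize_weights`) maps w ↦ max(1, round(w·10^d)); the
floor keeps arbitrarily small positive weights as one node, and the rounding
error of the analytic degree after rescaling is bounded by m·0.5·10^(−d) for
a node with m neighbours. The default d = 4 resolves weights of magnitude
1e-4, the bottom of the normalized spectral-count range. The analytic route
is the default everywhere; materialization (quadratic in copy counts) is for
validation and export only.

## Input processing

Spectral counts are divided by the protein's molecular weight — no other
transformation — and any protein with a zero in at least one sample is
removed, so a single shared master network underlies all per-sample networks
and group differences are attributable to weighting alone (per-group
filtering would confound them with topology changes; it is deliberately not
implemented). Counts are accepted as any non-negative real, since upstream
tools sometimes emit averaged spectra. Edge tables are STRING-style exports;
self-pairs are dropped, symmetric duplicates merged keeping the maximum
score. The score threshold is inclusive (≥ 400 keeps an edge) to match
STRING's medium-confidence default; a flag makes it strict. The largest
connected component is the master network, with ties broken by the
lexicographically smallest node tuple for reproducibility.

## Statistics

- **t-test**: Welch (unequal variances), two-sided, the default of R's
  `t.test`; Student's variant is available via `equal_var=True`. Degenerate
  rows where both groups are constant get p = 1 for equal means and p = 0
  otherwise — the limit as variances shrink.
- **FDR**: Benjamini–Hochberg step-up within each comparison's protein family
  (one family per comparison, not pooled), α = 0.1 for both SSPs and SFCPs.
- **SFCP**: fold change = ratio of group means of the weights; the flag
  requires |log2 fc| strictly greater than 1 *and* adjusted p < 0.1.
- **High-degree sets**: each protein summarised by its mean degree over a
  group's samples; threshold = linear-interpolation quantile (q = 0.75) of
  those means; membership is strict (>). Computing the quantile over pooled
  per-sample degrees instead of per-protein means is a defensible alternative
  the interface does not currently expose.
- **Difference summary**: per-protein |mean treated − mean control| degree,
  averaged into one global difference per comparison; the Difference Ratio
  is the ratio of two comparisons' global differences.
- **Intersections**: exclusive (upset-style) membership patterns; the counts
  over all non-empty set combinations partition the union.
- **SSP subnetworks**: induced subgraph on SSPs plus first neighbours, each
  node labelled ssp / sfcp / both / contributor — contributors are neighbours
  in neither set whose weights nonetheless feed the SSPs' degrees.

## Synthetic data and the random null

`generate_master_graph` draws a uniformly random spanning tree and adds
uniform random extra edges: connected, simple, exact node/edge counts,
defaulting to the study scale of 79 nodes and 155 edges. Weights are
log-normal: per-protein baseline with log-mean −6 and log-sd 1.5 (median
≈ 2.5e-3, spanning roughly 1e-4–1e-1 like molecular-weight-normalized
spectral counts), times per-cell log-normal noise with log-sd 0.3 (~30%
coefficient of variation, typical of spectral-count replicates). The design
defaults to 4 groups of 6 samples with two treated/control comparisons.

A planted effect multiplies the **neighbours** of each target protein by the
effect size in the treated samples; the target itself is untouched but its
degree shifts by the full factor. Ground truth (`PlantedTruth`) distinguishes
three sets: the targets, the shifted proteins, and the *expected SSPs* —
every node adjacent to a shifted protein, whose degree distribution genuinely
differs between groups. Recovery metrics report the true-positive rate on
targets and count false positives only outside the expected-SSP set: a
flagged second-order node is a real consequence of the perturbation, not an
error. The generator emulates only the weight-matrix level of real data — no
peptide sampling, missingness mechanism, or count discreteness — so a green
recovery test establishes that the degree statistic propagates and detects
neighbourhood abundance shifts at realistic noise, not that the pipeline is
robust to mass-spectrometry artefacts.

The random-weight null (`run_random_null`) redraws every cell i.i.d. uniform
over the observed [min, max] weight range, rebuilds the degree matrix on the
same master network and reruns SSP detection, recording per-trial SSP counts
and adjusted-p summaries over (by default) 100 seeded trials.

## A calibration caveat

The reference analysis this package reproduces reports that *no* protein was
significant in any of 100 random trials. That outcome is not reproducible by
any valid test at FDR 0.1 under a per-cell random null: under the global
null, the probability that Benjamini–Hochberg rejects at least once equals
the FDR level — about 0.1 per comparison, hence ≈ 0.19 per trial with two
comparisons — for essentially any dependence among the degree statistics.
Empirically this implementation observes 11–20 trials (of 100) with at least
one SSP across seeds, with median adjusted p-values near 1, matching theory.
The unit suite therefore asserts the attainable property — the per-comparison
probability of any SSP under the null is ≈ α — while the literal zero-trials
reproduction is kept as a deliberately failing acceptance check documenting
the discrepancy. A random null with degenerate structure (e.g. weights
constant within a group) would yield zero detections trivially, but no such
structure is described for the reference analysis.

## Known limitations

- Degree is the only centrality; betweenness/stress/centroid on expanded
  graphs are out of scope.
- Edge weights, directed graphs and per-group master networks are not
  modelled.
- The deposited study dataset is not bundled; the headline dataset-specific
  counts (113 shared proteins, 32/2 SSPs, 1/19 SFCPs) can be reproduced by
  pointing the CLI at the deposited tables but are not asserted by the test
  suite.
- Upset-style intersection *plots* are not produced; the exclusive-count
  table carries the same information.
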