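# Methods

## Diversity profiles

Hill numbers are computed per sample from counts converted to relative
abundances with zero-count features dropped; richness therefore counts
only features observed in that sample. The natural logarithm is used
throughout, so $^1D$ is the exponential of Shannon entropy and the
"effective number of species" interpretation holds at every order. Orders
within $10^{-9}$ of 1 are routed to the limit formula
$\exp(-\sum p_i \ln p_i)$; all other orders use the power form. The
default grid is $q = 0,1,2,3,4$, the range over which heavy-tailed OTU
abundance distributions separate most clearly.

Group comparisons use the two-sided pooled-variance (equal-variance)
Student's t-test on per-sample $^qD$ values, one order at a time. Group
means average all member samples by default; `exclude_samples` lets the
caller drop, say, a longitudinal series' day-0 baseline explicitly —
baseline exclusion is never applied silently, because on 8-sample groups
a single dropped sample visibly moves every mean.

## Network inference

All three network flavours use plain Pearson correlation with the
two-sided p-value from $t = r\sqrt{(n-2)/(1-r^2)}$ on $n-2$ degrees of
freedom, and keep an edge when $p \le \alpha$ (default 0.05) and $r \ne 0$.
No multiple-testing correction is applied by default: the workflow this
package reproduces used a raw per-pair threshold, and reproducing its
networks requires honoring that. A Benjamini–Hochberg flag (`fdr=True`)
is available; it can only remove edges. Correlations are computed on
abundances as given (counts for OTU tables). Compositional effects are a
known caveat of Pearson-based co-occurrence inference; partial-correlation
or log-ratio approaches are deliberately out of scope.

Within-table mode (the species interaction network, SIN) tests all
unordered feature pairs after removing OTUs with fewer than `min_total`
(default 5) total reads in the group, and keeps all tested features as
nodes, isolated or not. Cross-table mode (diversity–metabolite, DMN, and
metabolite–OTU, MON) tests only cross pairs on the shared-sample
intersection (at least 3 samples required) and drops isolated nodes,
matching how such bipartite association graphs are conventionally drawn.
Constant features have undefined correlation and participate in no edge;
they are skipped with a logged notice rather than raising mid-build.

For the DMN, the per-sample Hill numbers at each grid order become
feature vectors named `q0`…`q4`, treated exactly like metabolite rows.
Which sample subset enters the DMN/MON is the caller's choice (an
explicit sample list in the CLI); nothing is inferred from group labels.

## Network summary panel

All metrics are computed on the unweighted, undirected simple graph:
average degree $2m/n$; density $2m/(n(n-1))$; average local clustering
with the 0-for-degree-<2 convention; diameter and average shortest path
length on the largest connected component (the only convention that
stays finite for the multi-component graphs these studies produce);
community count and modularity from greedy modularity maximization by
default — a deterministic choice — with seeded Louvain as an option. The
P/N ratio returns `inf` when there are positive but no negative links
and `nan` for an edgeless graph, never a division error. Hub and
most-abundant-OTU annotation flags the top-3 by degree and by total
abundance respectively, including all nodes tied at the boundary rank.

## Motifs and modules

The motif census counts connected *induced* subgraphs of sizes 3 and 4
per isomorphism class (two classes at size 3, six at size 4), ignoring
edge signs, via ESU enumeration; the test suite pins it to a brute-force
enumerate-all-subsets oracle classified by graph isomorphism.

Module detection follows the MCODE scheme: each vertex is weighted by
$k_{\max} \cdot \text{density}$ of the highest k-core of its closed
neighborhood (zero below the degree cutoff); complexes grow greedily
from the highest-weight unassigned seed, admitting neighbors whose
weight exceeds `seed_weight * (1 - node_score_cutoff)` within
`max_depth`; post-processing discards complexes without a 2-core and the
haircut trims each complex to its 2-core. Defaults are the published
ones (degree cutoff 2, node score cutoff 0.2, k-core 2, haircut on,
fluff off). Seeds and tie-breaks are ordered deterministically
(descending weight, then node id), so the cluster list is reproducible.

The reported **cluster score is internal edges divided by member nodes**,
not the density-times-size variant: edges/nodes is the convention that
matches the published module-strength values this package is validated
against, and it recomputes exactly from each cluster's member set.

## Synthetic data

The generator emulates the statistical shape of a small milk-microbiome
cohort, not its biology:

* **Abundance distribution.** OTU baselines follow a Zipf law with
  exponent `dominance`; larger values concentrate abundance in fewer
  OTUs and steepen the decline of $^qD$ with $q$. Counts are Poisson
  around the exponentiated log-scale latent mean, with no compositional
  closure — deliberately aligned with the downstream Pearson inference.
* **Planted edges.** Each planted pair occupies two dedicated
  high-abundance features sharing a standard-normal factor; loadings are
  calibrated numerically so the *count-scale* |r| hits the requested
  target, accounting for both the log-normal level transform and Poisson
  counting noise. Because the exponential link is convex, strongly
  negative level correlations are mathematically bounded
  (Fréchet-type limit $-e^{-s^2}$ at log-variance $s^2$); negative pairs
  therefore use a small idiosyncratic log-noise, and an infeasible
  negative target raises an error rather than silently undershooting.
* **Metabolites.** Coupled metabolites are linear in the standardized
  per-sample $^1D$ plus Gaussian noise, shifted positive (the shift
  leaves correlations untouched); the default panel has 4 positive and
  5 negative couplings with effect size 3 (implied $|r| \approx 0.95$),
  plus independent-noise background metabolites.
* **Preset.** `milk_study_preset` draws 8 + 8 + 9 samples over 70 OTUs
  at depth 1000 with per-group dominance (pre 1.6, post 1.5, healthy
  1.1), chosen so group-mean $^1D$, per-sample richness, and post-filter
  network node counts land in the ranges typical of the cohort design it
  emulates. One integer seed drives a single RNG stream through all
  tables; the same seed reproduces the scenario bit-for-bit. When
  composing generator calls manually, pass one `numpy.random.Generator`
  through them — reusing the same integer seed in two calls replays the
  same stream and manufactures spurious dependence.

What passing tests on this generator do **not** show: robustness to
compositional closure, sequencing-depth variation between samples,
taxon-specific overdispersion beyond log-normal–Poisson, or longitudinal
autocorrelation in the patient series. Conclusions about real data
inherit those caveats.

Recovery of planted structure is assessed on edges with target
$|r| \ge 0.7$ at $n = 200$ samples, where null pairs essentially never
reach that magnitude; precision and recall are averaged over 20 seeds.
Problem sizes throughout the suite (60–70 features, 8–200 samples, 20
seeds) are the scales at which these statistics stabilize while the
whole suite stays interactive.

## Numerical and design notes

* Missing table cells are hard errors, never imputed zeros — silent
  imputation corrupts correlation estimates at n = 8.
* Edge sign is strict ($r > 0$ positive, $r < 0$ negative); $r = 0$
  cannot pass $p \le 0.05$ at finite $n$, so no tie-break is needed.
* `graphml` and `edge-tsv` writers round-trip `r`/`p` at full precision
  (`repr` serialization); `sif` keeps only the sign token by design.
* Community count and modularity depend on the chosen algorithm and are
  reproducible only under the package's own defaults; they are reported
  but not validated against external values.
* The average-path-length of the 4-node path graph is 10/6 (mean over
  the 6 unordered pairs), the convention used by both networkx and
  igraph; the panel is cross-checked against igraph in the tests.

## Known limitations

Pearson-on-counts is sensitive to single extreme samples at n = 8–9;
uncorrected $\alpha = 0.05$ admits chance edges in proportion to the
number of pairs tested, so small-cohort networks (synthetic or real)
contain background edges of both signs; MCODE cluster *membership*
depends on implementation details (tie-breaking, haircut variant) even
when scores agree; and the generator's independence assumptions make it
an optimistic benchmark for real microbiome data.
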