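# milknet

Integrated diversity-profile and signed correlation-network analysis for
small-cohort microbiome/metabolome studies.

Co-occurrence studies of the human milk microbiome (and similar small
cohorts) routinely combine two views of the same OTU table: **Hill-number
diversity profiles**, which summarize each sample's species abundance
distribution, and **signed Pearson correlation networks**, which capture
pairwise associations that diversity indices cannot see. `milknet`
implements that workflow end to end — table IO, diversity profiles and
group t-tests, network inference (species–species, diversity–metabolite,
metabolite–OTU), network summary panels including the positive/negative
link ratio, motif censuses, MCODE-style dense-module detection, and a
synthetic-data generator with planted ground truth for validating the
whole pipeline.

## The statistics at the core

**Hill numbers.** For a sample with relative abundances
$p_1,\dots,p_S$, the diversity of order $q \ge 0$ is

$$ {}^qD = \Big(\sum_{i=1}^S p_i^{\,q}\Big)^{1/(1-q)}, \qquad
   {}^1D = \exp\Big(-\sum_i p_i \ln p_i\Big) \;(q \to 1), $$

in units of "species equivalents". $^0D$ is richness, $^1D$ the
exponential of Shannon entropy, $^2D$ the inverse Simpson concentration;
the profile over $q = 0\ldots4$ describes how diversity falls as rare
species are discounted.

**Signed networks.** An edge joins two features when their Pearson
correlation has a two-sided $p \le \alpha$ (default 0.05, uncorrected, as
in the study design this reproduces; a BH-FDR option exists). The sign of
$r$ colors the edge, and the **P/N ratio** — positive links over negative
links — is the headline network property. OTUs with fewer than 5 total
reads within a treatment group are removed before inference.

**Modules.** Dense regions are found with an MCODE-style seeded-growth
algorithm (k-core-weighted vertices, greedy expansion, haircut), and each
cluster is scored as internal edges divided by member nodes.

## Worked example

```python
from milknet import (milk_study_preset, profiles_from_table, group_mean_profile,
                     build_sin, summarize, mcode_clusters, compare_groups_t)

scenario = milk_study_preset(seed=42)          # 8 + 8 + 9 samples, 70 OTUs
otu, groups = scenario["otu_table"], scenario["groups"]

profiles = profiles_from_table(otu)            # samples x orders q = 0..4
print(group_mean_profile(profiles, groups).round(3))

healthy = otu.subset_samples(groups.samples_in("healthy"))
net = build_sin(healthy, alpha=0.05, min_total=5)
s = summarize(net)
print(f"healthy SIN: {s.n_nodes} nodes, {s.n_edges} edges, "
      f"P/N = {s.n_positive}/{s.n_negative} = {s.pn_ratio:.2f}")

top = mcode_clusters(net)[0]
print(f"top cluster: {top.n_nodes} nodes, {top.n_edges} edges, score = {top.score:.3f}")

ma, mb, t, p = compare_groups_t(profiles, groups, "healthy", "pre", q=1.0)
print(f"healthy vs pre at q=1: means {ma:.2f} vs {mb:.2f}, t = {t:.2f}, p = {p:.2e}")
```

prints

```
            0.0     1.0     2.0    3.0    4.0
group
pre      50.000   9.182   4.650  3.642  3.237
post     56.500  11.825   5.716  4.348  3.811
healthy  66.556  22.850  11.857  8.658  7.296
healthy SIN: 70 nodes, 137 edges, P/N = 94/43 = 2.19
top cluster: 6 nodes, 14 edges, score = 2.333
healthy vs pre at q=1: means 22.85 vs 9.18, t = 16.88, p = 3.63e-11
```

The group-mean table shows the simulated healthy cohort holding roughly
twice the patient groups' effective species number at every order
$q \ge 1$ (the planted condition), and the t-test confirms the gap is far
beyond sampling noise. The network line reads off the healthy group's
signed-edge balance, and the cluster line reports the strongest detected
module with its edges-per-node score.

The same workflow runs from the shell:

```sh
milknet simulate --seed 42 --out-dir sim/
milknet run --otu-table sim/otu.tsv --groups sim/groups.tsv \
            --metabolite-table sim/metabolites.tsv --out-dir results/
```

writing per-group SIN GraphML files, a Table-1-style summary TSV, motif
and cluster TSVs, diversity/t-test TSVs, diversity–metabolite and
metabolite–OTU networks, and a JSON run manifest.

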