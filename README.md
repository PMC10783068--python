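# hadal

Community assembly and co-occurrence network stability for multi-domain
marine microbiomes.

`hadal` is a tested, reusable implementation of the statistical pipeline
used to study how vertical environmental gradients shape bacterial,
archaeal and microeukaryotic communities in deep-ocean water columns —
from the upper bathypelagic down to the hadal zone (≥ 6,000 m).  It is
aimed at microbial ecologists working with ASV count tables, rooted
phylogenies and sample metadata, and at methodologists who want the null
models exercised against communities with *known* assembly processes.

## What it computes

* **Preprocessing** — ASV prevalence/count filtering, rarefaction to a
  common depth (multivariate hypergeometric), abundant/rare
  partitioning, UBW/HW zoning, log relative-abundance transform.
* **Alpha diversity & niche breadth** — richness, bias-corrected Chao1,
  Shannon *H* = −Σ*p* ln *p*, Simpson 1 − Σ*p*², Pielou *J* = *H*/ln *S*,
  and Levins niche breadth *B* = 1/Σ<sub>j</sub>*P*²<sub>ij</sub>, with
  two-way (depth × pore size) ANOVA, Tukey HSD and Spearman tests.
* **Beta diversity** — Jaccard, Bray-Curtis, unweighted and (normalized)
  weighted UniFrac; NMDS (Kruskal stress-1, isotonic regression) and
  ANOSIM with seeded permutation tests.
* **Phylogenetic null models** — MPD, MNTD and their standardized effect
  sizes under whole-tree tip shuffling:
  SES.MNTD = (MNTD<sub>obs</sub> − µ<sub>null</sub>)/σ<sub>null</sub>,
  and the between-sample βMNTD/βNTI with the conventional reading
  |βNTI| ≤ 2 → stochastic, βNTI > 2 → variable selection,
  βNTI < −2 → homogeneous selection.
* **Sloan neutral community model** — occurrence frequency
  *F*(p̄) = 1 − I<sub>d</sub>(*Nm*·p̄, *Nm*·(1 − p̄)) fitted by least
  squares over *Nm*, with *R*², Wilson 95 % prediction bands and the
  above/neutral/below taxon partition.
* **Multivariate regression trees** — De'ath-style recursive
  partitioning of the (Hellinger-transformed) community matrix on
  environmental thresholds, pruned by cross-validation, with
  per-predictor explained-variance percentages.
* **Co-occurrence networks** — Pearson correlations of log relative
  abundances thresholded either at a fixed |r| or by a random-matrix
  theory scan (GOE → Poisson transition of the eigenvalue spacing
  distribution); topology (degree, betweenness, clustering, modularity,
  negative-link ratio), hub/gatekeeper rankings, and stability:
  robustness to random or module-hub-targeted removal of 50 % of taxa,
  and the fragmentation series
  *f* = 1 − Σ*s*<sub>i</sub>(*s*<sub>i</sub> − 1)/(*N*′(*N*′ − 1)) under
  consecutive removal of the highest-betweenness nodes.
* **Synthetic communities** — a generator producing multi-domain ASV
  tables over the 2–8,727 m depth profile under neutral (zero-sum
  Moran dynamics with immigration *m*), niche (Brownian-motion optima on
  a Yule tree, Gaussian filter of width σ) or mixed assembly, with the
  exact generating process recorded as ground truth.

## A worked example

Simulate a neutral community at study scale and push it through the
pipeline:

```python
from hadal import (SimulationConfig, simulate_neutral, fit_ncm,
                   alpha_diversity, levins_breadth, ses_mntd,
                   build_network, topology, robustness)

cfg = SimulationConfig(n_taxa=400, m=0.1, local_size=10_000,
                       sequencing_depth=16_000, seed=42)
table, truth = simulate_neutral(cfg)

alpha = alpha_diversity(table)
nb = levins_breadth(table)
fit = fit_ncm(table, community_size=cfg.local_size)
ses = ses_mntd(table, truth.tree, n_rand=199, seed=1)
net = build_network(table, threshold=0.8, min_prevalence=6)
stats, _ = topology(net)
rob = robustness(net, fraction=0.5, mode="random", reps=50, seed=2)
```

which prints, with the formatting of the example script:

```
table: 400 taxa x 16 samples
mean richness: 209.0   mean Shannon: 4.50 nats
community niche breadth Bcom = 6.72
NCM: m = 0.087 (true 0.100), R^2 = 0.92
mean SES.MNTD = -0.34
network: 21 nodes, 11 edges, avg degree 1.0, modularity 0.89
robustness after 50% random removal: 0.27 +/- 0.09
```

Reading it: the fitted migration rate recovers the simulated *m* = 0.1
within 13 % with a tight neutral-model fit (*R*² = 0.92); SES.MNTD sits
near zero, as it should when no environmental filtering acted; and a
fixed 0.8 correlation cutoff keeps almost nothing on 16 neutral
samples — neutral data have no co-occurrence structure to find.

The same steps are available from the shell via the `hadal` entry point
(`hadal simulate`, `hadal prep`, `hadal diversity`, `hadal betadiv`,
`hadal nullmodel`, `hadal ncm`, `hadal mrt`, `hadal network`,
`hadal stability`); run `hadal --help` for the options.

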