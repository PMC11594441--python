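# herbwalk

Network-pharmacology prioritization of multi-compound herbs and their active
ingredients for a disease, by **biased random walks with restart** on a
**multiscale interactome** — a two-class graph whose nodes are proteins and
biological functions, connected by three edge layers (protein–protein,
protein–function annotation, function–function hierarchy).

Herbal preparations act through many compounds hitting many protein targets
at once, which makes single-target screening a poor fit. `herbwalk` instead
compares how an entity's influence *propagates* through the interactome with
how the disease's influence propagates, and ranks herbs and ingredients by
the similarity of those propagation patterns. It is aimed at computational
systems-biology and network-pharmacology researchers who have herb→
ingredient→target association tables, a disease protein set, and an
interactome, and want a reproducible prioritization pipeline.

## Model

For a seed distribution $s$ (an entity's associated proteins, uniformly
weighted), the walker satisfies

$$ r = (1-\alpha)\,T^{\top} r + \alpha\, s $$

where $\alpha$ is the restart probability and $T$ is the row-stochastic
transition operator. From node $u$, the probability of stepping to neighbor
$v$ through edge class $c$ is $w_c / Z(u)$ with $Z(u)$ the sum of class
weights over all of $u$'s (neighbor, class) pairs. The five class weights
($w_{pp}, w_{pf}, w_{fp}, w_{up}, w_{down}$) bias the walk; the defaults
favor moves toward biological functions. The stationary vector $r$ — the
**diffusion profile** — is found by power iteration (L1 stopping rule,
dangling mass redirected to $s$) and is deterministic for fixed inputs.

Entities are then scored against the disease by:

* **correlation score** — Pearson correlation of the two diffusion profiles
  over the aligned node universe;
* **overlap statistics** — $k$ of the entity's $n$ (top-)targets are disease
  proteins: exact hypergeometric upper-tail $P(X \ge k)$ for
  $X \sim \mathrm{Hypergeom}(N, K, n)$, and fold enrichment
  $(k/n)/(K/N)$;
* **prioritization** — overlap $p < 0.05$, enrichment $\ge 5$, and (herbs)
  $\ge 5$ ingredients individually significant against the disease proteins.

Downstream stages identify **core targets** (proteins hit by $\ge 3$ of the
top herbs), run over-representation analysis of a target list against GMT
gene-set libraries (BH-adjusted exact tests, random-set z-scores, combined
score $-\ln p \cdot z$), and extract **mechanism subnetworks**: the induced
graph on the top-$k$ (default 20) nodes of the ingredient and disease
profiles, linking an ingredient to the disease through proteins and
functions.

Because real interactomes and herb–target databases are license-restricted,
the package ships a seeded synthetic-data generator (`herbwalk.synthetic`)
that emulates their statistical structure — a scale-free PPI layer, a
function hierarchy, sparse annotations, and a catalog with *planted* herbs
whose targets concentrate near a disease module — so every stage is testable
against known ground truth.

## Worked example

```python
import herbwalk as hw

config = hw.SyntheticConfig(rng_seed=1)          # default study conditions
net, disease, catalog, truth = hw.generate_study(config)
print(net.summarize())
records, retained = hw.score_herbs(net, catalog, disease)
for r in records[:5]:
    print(r.entity, round(r.correlation_score, 4), r.overlap,
          f"{r.hypergeom_p:.2e}", round(r.enrichment, 2),
          r.entity in truth.planted_herbs)
```

prints

```
{'proteins': 800, 'functions': 300, 'ppi': 2391, 'annotation': 1600, 'hierarchy': 372}
HERB016 0.4563 5/27 7.12e-05 9.88 True
HERB014 0.4192 3/30 1.60e-02 5.33 True
HERB027 0.3999 2/27 8.79e-02 3.95 True
HERB008 0.3663 3/19 4.32e-03 8.42 True
HERB002 0.3294 1/21 3.31e-01 2.54 True
```

All five top-ranked herbs are planted ones: herbs constructed to target the
disease module's graph neighborhood out-rank the background herbs by
correlation score. `HERB016`'s row reads: its diffusion profile correlates
0.456 with the disease profile; 5 of its 27 top targets are disease
proteins, an overlap with hypergeometric $p = 7\times10^{-5}$ and a
9.9-fold enrichment over the background rate.

The same pipeline is scriptable from the shell:

```bash
herbwalk simulate --seed 1 --out study/        # write a synthetic study
herbwalk rank-herbs --config config.yaml       # ranking + core-target CSVs
herbwalk rank-ingredients --config config.yaml HERB016
herbwalk subnetwork --config config.yaml HERB016:ING00   # SIF + GraphML
herbwalk enrich --targets targets.txt --gmt library.gmt --out enrich.csv
```

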