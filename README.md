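# bioidkit

Post-identification analysis toolkit for **BioID proximity-labelling
interactome studies**, built for screens of the polycystin type: a handful of
baits (e.g. a membrane-tethered polycystin-1 C-terminal tail and polycystin-2)
run in biological replicates under cycling and ciliated (serum-deprived)
conditions against a panel of promiscuous-ligase negative controls, with a
companion microscopy readout of perinuclear lysosome positioning.

It is aimed at proteomics analysts who have spectral-count tables in the
SAINT interaction/bait/prey convention and want a scriptable, tested pipeline
from raw counts to high-confidence interactomes, condition comparisons,
gene-set analytics and figure-ready exports — plus the matching image
quantification for lysosome-positioning experiments.

## What it computes

**Interaction scoring.** Negative-control runs are compressed to *k* virtual
controls (per prey, the *k* = 4 highest control counts, zero-padded), and each
bait–prey pair is scored per replicate under a two-component count mixture:

- background: NB(μ₀, r) with μ₀ = max(mean of virtual controls, 0.1),
- true interaction: NB(μ₁, r) with μ₁ = max(mean test count, 2·μ₀),
- equal prior odds; shared NB size r = 10 (≈32 % replicate CV; r = ∞ is Poisson).

Per-replicate posterior probabilities are averaged into **AvgP**, and the
**BFDR** at rank *j* of the AvgP-sorted list is the cumulative mean of
1 − AvgP over the top *j* records (ties take the worst value of their block).
BFDR ≤ 0.01 defines high confidence.

**High-confidence filtering.** Per-bait plans add two manual filters in a
fixed order after the BFDR cut: *partner rescue* (a prey detected with the
bait that is high-confidence in a partner bait's dataset is kept) and
*control-bait exclusion* (a prey whose average count in a negative-control
bait dataset is ≥ 4× its average with the bait is dropped), with a complete
per-prey decision trail.

**Condition differential enrichment.** Per prey, FC = (mean ciliated + 0.5) /
(mean cycling + 0.5) and a two-sided Welch t test on log(count + 1);
volcano classes use FC ≥ 2 (or ≤ 0.5) and p < 0.05.

**Set analytics.** Exact overlap/Jaccard statistics, multi-database
membership tiers cross-tabulated by bait exclusivity, hypergeometric
over-representation with BH adjustment, and the dot-plot encoding
(control-subtracted counts capped at 50; relative abundance across baits as
size; BFDR bins black ≤ 0.01 / blue ≤ 0.05 / light blue > 0.05 as border).

**Lysosome imaging.** Per single-cell crop: histogram-mode background
subtraction, optional white top-hat, adaptive-threshold nuclear mask, a
30-pixel dilation ring around the nucleus, and the fraction of total
lysosomal-probe intensity inside the ring; plus per-cell integrated PLA
signal above a threshold.

**Synthetic ground truth.** `bioidkit.simulate` generates complete
experiments (negative-binomial background, planted interactors, condition
effects, nine controls split five cycling / four ciliated) and two-channel
cell images with an exactly known perinuclear intensity fraction, so every
stage of the pipeline can be validated against truth.

## Worked example

```python
from bioidkit import (SimulationDesign, simulate_experiment,
                      score_experiment, FilterPlan, build_high_confidence)

design = SimulationDesign(n_baits=2, n_preys=2000, n_true_per_bait=50,
                          background_mean=2.0, effect_multiplier=8.0, seed=1)
experiment, truth = simulate_experiment(design)

scored = score_experiment(experiment, k=4)
kept, reports = build_high_confidence(scored, FilterPlan(bfdr_threshold=0.01))

recovered = {(s.bait_id, s.prey_id) for s in scored if s.bfdr <= 0.01} & truth
print(f"planted pairs: {len(truth)}")
print(f"recovered at BFDR <= 0.01: {len(recovered)}")
for bait, report in sorted(reports.items()):
    print(f"{bait}: {report.final_n} high-confidence preys "
          f"(of {report.input_n} detected)")
```

prints

```
planted pairs: 100
recovered at BFDR <= 0.01: 89
bait01: 46 high-confidence preys (of 1999 detected)
bait02: 44 high-confidence preys (of 2000 detected)
```

i.e. 89 % of the planted 8×-enriched interactors are called high-confidence,
and each bait's final set is close to its 50 planted preys (a planted pair
can pass in either the cycling or the ciliated dataset, while each per-bait
set merges conditions at the best BFDR; background preys essentially never
pass).

The same pipeline is available from the shell:

```bash
bioidkit simulate --interactions i.tsv --baits b.tsv --truth truth.csv --seed 1
bioidkit score --interactions i.tsv --baits b.tsv --out scored.tsv
bioidkit filter --scored scored.tsv --out-prefix hc
bioidkit enrich --interactions i.tsv --baits b.tsv --bait bait01 --out volcano.csv
bioidkit simulate-images --out-dir cells --n-cells 10 --seed 1
bioidkit ringfrac cells/*.tif --out ring.csv
```

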