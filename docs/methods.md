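# Methods

This note documents the statistical models, numerical choices and known
limitations behind `bioidkit`. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Spectral-count scoring model

Spectral counts (MS/MS spectra per protein per run) are treated as the
abundance measure. For one bait dataset — one bait's replicate runs under one
cell-state condition — every detected prey (nonzero count in at least one
replicate) is scored against a background estimated from negative-control
runs.

**Virtual-control compression.** The control panel is first compressed to
*k* virtual controls: for each prey only its *k* largest control counts are
kept (descending, zero-padded when fewer than *k* control runs exist).
Default *k* = 4 over a nine-run control panel. Compression makes the
background estimate deliberately pessimistic — a prey seen at high counts in
even a few controls gets a high background mean — which is the standard
stringency device for sticky contaminants in affinity-purification scoring.
By default all control runs are pooled before compression; a
condition-matched mode (`by_condition=True`) restricts to controls collected
under the same cell state, at the cost of a smaller panel.

**Two-component mixture.** Per replicate count *x* the posterior probability
of a true interaction is

    P(true | x) = expit( log f1(x) − log f0(x) + prior_log_odds )

with

- background component f0 = NB(μ₀, r), μ₀ = max(mean of the prey's virtual
  controls, ε) with floor ε = 0.1 counts so the model is defined for preys
  never seen in controls;
- true component f1 = NB(μ₁, r), μ₁ = max(mean of the test counts, f·μ₀)
  with minimum fold f = 2, so the alternative is always an enrichment;
- equal prior odds (prior_log_odds = 0) by default.

Both components share a negative-binomial **size** r (variance μ + μ²/r):
Poisson sampling compounded with multiplicative between-replicate noise of
CV 1/√r. The default r = 10 corresponds to ≈32 % replicate CV, the
reproducibility regime of well-behaved spectral-count replicates (replicate
R² above ~0.9); `math.inf` recovers the Poisson limit. The probability is
monotone non-decreasing in the test count for fixed controls.

No claim of bit-compatibility with any external scorer is made. The contract
is the operating behaviour: control-like preys fail, strongly enriched preys
pass at BFDR ≤ 0.01, quantified below.

**AvgP and BFDR.** Replicate probabilities are averaged into AvgP
(averaging happens on probabilities, not counts). Within one bait dataset,
records are ranked by descending AvgP and the Bayesian FDR at rank *j* is the
cumulative mean of (1 − AvgP) over the top *j* records — the expected
proportion of false interactions if the list were cut at *j*. Records tied on
AvgP all receive the worst (largest) BFDR of their tie block, so thresholding
is independent of tie order. BFDR is non-decreasing down the ranked list by
construction. BFDR ≤ 0.01 defines high confidence.

**Operating characteristics** (computed by the acceptance script on the
synthetic generator at its defaults, one CPU, minutes): on pure-background
simulations (2000 preys, 2 replicates, 9 controls compressed to 4, 50 seeds)
the seed-averaged false-discovery proportion at BFDR ≤ 0.01 is ~0; with
8×-enriched planted interactors over background mean 2, ~92 % of planted
pairs are recovered at BFDR ≤ 0.01, and sensitivity is monotone in the
effect size.

### Why the NB size parametrization

An earlier draft fixed the variance-to-mean ratio of the counts at every
mean. A Neyman–Pearson computation (the best possible test of mean-16 vs
mean-2 NB counts over two replicates at the false-positive rate needed to
keep a 2000-prey null list clean) showed that a fixed variance-to-mean ratio
of 2 at mean 2 makes the calibration and recovery targets above jointly
unattainable by *any* scorer: the low-mean background tail is simply too
heavy relative to the planted signal. Overdispersion in spectral counts is
multiplicative — it grows with abundance and is mild at low means — which is
exactly the fixed-size NB (variance μ + μ²/r). The size parametrization is
therefore used throughout, in the generator and the scorer, with r = 10.

## High-confidence filtering

Every bait dataset gets the BFDR ≤ 0.01 cut (boundary inclusive; a prey
passes for a bait if any of its condition datasets passes, taking the best
BFDR). Baits named in a `FilterPlan` additionally get, in this fixed order:

1. **Partner rescue.** A prey detected with the bait (count > 0 in ≥ 1
   replicate) that is high-confidence in a designated partner bait's dataset
   is kept even if it missed the BFDR cut. Rescue never imports preys that
   were not observed with the bait — a proximity interactome cannot contain
   never-observed preys. Identifiers are compared case-insensitively at the
   gene-symbol level.
2. **Control-bait exclusion.** A prey whose average spectral count in a
   designated negative-control bait dataset is ≥ ratio× (default 4×) its
   average with the bait is dropped. The bait average is floored at 0.25
   (one count spread over four virtual-control slots) so the ratio is
   defined for preys with zero bait counts. Per-prey averages are the
   maximum replicate-mean across that bait's condition datasets, the
   conservative choice for an exclusion rule.

Exclusion runs last so control-sticky preys cannot re-enter via rescue; the
order sensitivity is real and covered by a dedicated test. A `FilterReport`
carries a per-prey ordered decision trail and reconciles exactly:
final = pass_bfdr + rescued − excluded.

## Condition differential enrichment

Per prey of one bait, FC = (mean ciliated + c) / (mean cycling + c) with
pseudocount c = 0.5, keeping FC finite and exactly antisymmetric under
condition swap (FC → 1/FC). Significance is a two-sided Welch t test on
log(count + 1); with fewer than two replicates in either condition, or zero
variance on both sides, the test returns p = 1 by contract (no evidence
either way). Welch on logs is the minimal defensible default for a
two-group comparison of overdispersed counts at small n; an exact
count-based test can be substituted via the module functions. Volcano
classes: increased iff FC ≥ 2 and p < 0.05; decreased iff FC ≤ 0.5 and
p < 0.05; else unchanged. The classification deliberately uses raw p-values
(the volcano convention); a Benjamini–Hochberg column is emitted alongside.
Power at these thresholds needs ≥ ~4 replicates per condition; the bundled
checks use 4 ("adequate replicates"), under which ~96–98 % of 4× planted
condition effects are recovered and the null non-unchanged fraction is
~3–4 %.

## Set analytics

Gene symbols are uppercased for comparison, preserved for reporting.
Overlap statistics are exact set arithmetic; Jaccard distance is
1 − |A∩B|/|A∪B|; percentages are rounded to the nearest whole percent
(reporting convention). Multi-database membership cross-tabulates tiers
("in ≥ 2 databases", "in all databases") against bait exclusivity
(both / a-only / b-only) for exactly two bait datasets.
Over-representation is the exact hypergeometric upper tail with the universe
defaulting to the union of all detected preys across baits — the natural
BioID background — and BH adjustment across multiple references. Small
*synthetic* stand-in gene lists ship under `bioidkit/data/genesets/` for
demonstrations; real curated lists (cellular-marker panels, lysosomal
catalogues, ciliary gold standards) drop in as one-symbol-per-line text.

Dot-plot records encode colour = max(0, AvgSpec − control average) capped at
50; size = the dataset's AvgSpec relative to the prey's maximum across
datasets (0 when never counted); border = black (BFDR ≤ 0.01), blue
(≤ 0.05), light blue (> 0.05). The encoding is total: every scored record
maps to exactly one in-range record.

## Lysosome-positioning image quantification

Inputs are single-cell crops (one dominant nucleus per crop) of two-channel
single-plane images; Z-stacks are assumed already projected (a max-projection
helper is provided; deconvolution is out of scope).

1. **Background**: the most populated bin of the intensity histogram (bin
   width 1 grey level for integer images, 256 bins over the observed range
   for floats), subtracted with clamping at zero.
2. **Top-hat** (optional): white top-hat with a disc footprint, radius
   larger than a punctum; removes smooth haze, preserves puncta.
3. **Nuclear mask**: local gaussian threshold with a window spanning half
   the shorter image side (suiting one dominant nucleus per crop; window and
   offset configurable and recorded in output metadata), largest connected
   component, holes filled. An empty foreground raises a segmentation error
   and the cell is skipped.
4. **Ring**: the mask dilated with a disc of radius ring_width (default 30
   pixels — disc rather than square to preserve isotropy) minus the mask.
   Ring and nuclear mask are disjoint by construction; a ring clipped by the
   frame edge flags the measurement as truncated.
5. **Readout**: fraction = integrated ring intensity / integrated whole-crop
   intensity of the background-corrected lysosome channel (one cell per
   crop, so the whole crop is the per-cell total). High values mean
   perinuclear clustering.

PLA quantification sums per-cell above-threshold intensity (Otsu default;
fixed thresholds supported); the readout is linear under exposure scaling.

## Synthetic-data generator

**Counts.** Negative binomial with fixed size (default r = 10) around
per-run means: background mean (default 2 counts) for every prey everywhere;
planted true interactors (default 50 per bait out of 2000 preys) inflated by
effect_multiplier (default 8) in their bait's test runs and additionally by
condition_effect in ciliated runs. Two baits × two conditions × two
replicates, nine controls split five cycling / four ciliated — the emulated
study design. An optional detection-dropout knob (default 0) zeroes counts
at random. Same seed, same bytes.

What it does *not* emulate: peptide-level identification and protein
inference, correlated contaminant structure across runs (each count is
independent), bait-abundance effects on total counts, and zero inflation by
default. Passing tests therefore demonstrate correct operating behaviour
under the stated count model, not performance on any particular real
dataset.

**Images.** One filled nuclear disc (default radius 40 px in a 256-px
frame), n Gaussian puncta (default 150, σ = 2 px, amplitude 2000) with a
controlled fraction centred inside the 30-px perinuclear band and the rest
beyond it (never inside the nucleus), constant background (default 100),
Gaussian read noise (default σ = 2), 16-bit output. Ground truth is the
exact fraction of pre-noise punctum intensity inside the analytic ring,
by pixel summation. Not emulated: PSF physics, cell-to-cell morphology
variation, non-circular nuclei, autofluorescence gradients (the top-hat
path is exercised with synthetic gradients in the tests instead). On a
100-cell sweep of truth fractions 0.1–0.9 the measured fraction tracks truth
within < 0.01 per cell with rank correlation ≈ 1, and two 35-cell arms at
0.4 vs 0.8 separate at p ≪ 0.01 by a two-sample t test (recomputed by the
acceptance script).

## Numerical and degenerate-input choices

- Counts are validated as non-negative integers; duplicate (run, prey) rows
  and runs missing from the bait manifest are errors, not warnings.
- All-zero test counts are valid scoring input (probability ≤ 0.5 always).
- BFDR of an empty record list is an error; a single record has
  BFDR = 1 − AvgP.
- Scored tables are written with shortest-round-trip float formatting, so
  read(write(x)) is bit-exact and thresholding at 0.01 is never affected by
  formatting.
- Fold change with empty replicate vectors is an error; p = 1 covers the
  untestable cases.
- Overlap of an empty gene set is an error (distance would be undefined);
  over-representation requires the universe to contain query ∪ reference.
- A blank PLA channel yields zero signal without attempting an Otsu split.

## Reported dataset-size benchmarks

The emulated study's published dataset sizes (507 / 379 / 257 / 266 / 172 /
143) derive from its deposited supplementary scored tables, which are
third-party data not redistributed here. The reproduction path is
implemented — drop the scored tables into `data/supplementary/` as
`pc1.tsv`, `pc2.tsv`, `fb_pc2.tsv`, `cd16.tsv` in this package's
scored-table format and the dedicated test applies BFDR ≤ 0.01 plus the two
manual filters and compares the resulting counts. Without those files the
test fails with an explanatory message rather than being skipped, so the gap
is visible. The shared-set figures 172 and 143 correspond to two different
intersection constructions (PC1 ∩ (PC2 ∪ FB-PC2) vs the three-way
intersection across all baits and conditions); both are computed and
reported, without asserting which construction matches which published
figure.

## Known limitations

- The scoring mixture is intentionally simple: no modelling of prey length
  (a normalization hook exists but is off by default), bait abundance, or
  run-level normalization; the dispersion is fixed rather than estimated.
- The BFDR is a Bayesian expected-FDR down a ranked list under the model; it
  is not a frequentist FDR guarantee under model misspecification.
- Whether ciliated and cycling runs should be scored against
  condition-matched or pooled controls is experiment-specific; both modes
  are provided, pooled is the default.
- The imaging pipeline assumes one dominant nucleus per crop; touching cells
  and mitotic figures must be cropped away upstream.
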