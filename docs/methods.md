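# Methods

`pollenoptics` re-implements, as a tested pipeline, the analysis chain of a
four-channel elastic light-scattering pollen counter: particle sizing from the
near-forward channel, size-based clustering of pollen taxa, speciation-index
optical signatures from the side/back channels, and per-size-cluster species
classification. Because no public measurement data exists for this instrument
class, a synthetic session generator with full ground truth stands in for the
laboratory sessions; this note records the model, the parameters that matter,
and the design choices made where the design was genuinely open.

## Instrument model

Single particles crossing a 650 nm laser are seen by four photodiodes at 15°,
60°, 125° and 160°. Every 10-s frame each channel reports counts over 19
intensity bins. The 15° channel is nearly insensitive to the refractive index
of irregular particles, so its intensity maps to an optical diameter through a
power law `F = a·d^b`; its bins double as size bins over 5–100 µm.

The true bin placement and calibration constants of any real unit are
proprietary, so the package uses a configurable stand-in:

* **bins** — geometrically spaced. Scattering intensities span decades, and
  geometric spacing makes a pure channel gain an integer-bin translation in
  log intensity, which in turn makes the speciation indices exactly
  gain-covariant on the grid (see below).
* **calibration** — `b = 2` by default (geometric-optics scaling of the
  scattering cross-section), `a = 1`; the channel-1 intensity range is the
  image of 5–100 µm by construction. Both are overridable in
  `InstrumentConfig`.
* **binning** — half-open `[e_i, e_{i+1})`, last bin closed; out-of-range
  intensities are tallied as under/overflow, never silently dropped.

## Synthetic sessions

A session releases one aerosol class and records 179–299 frames (the 30–50 min
protocol). Per frame:

* particle count ~ Poisson(`mean_rate`); per-species rates are the laboratory
  grains-per-frame figures (e.g. olive ≈ 5.4, sweet vernal grass ≈ 41);
* grain diameter ~ lognormal(`median_diameter`, `gsd`). Supplier (microscope)
  diameters parameterise the 12 pollen taxa, range midpoints where a range is
  given; `gsd = 1.08` since dry pollen is near-monodisperse;
* the **measured** channel-1 intensity multiplies the power-law image of the
  diameter by lognormal noise with `sizing_sigma = 0.20` (σ of log intensity,
  ≈ 10 % optical-diameter uncertainty at `b = 2`). Optical sizing of irregular
  grains is orientation- and shape-dependent; 10 % is the low end of the
  uncertainty range typical of optical particle counters. Without this term
  the per-species histograms are near-delta spikes, which no real unit
  produces;
* channels 2–4 see the measured channel-1 intensity times a fixed per-class
  gain triple `(g2, g3, g4)` times lognormal noise (`noise_sigma = 0.15` per
  channel). The triples encode the qualitative optics — droplets transparent
  (bright forward, very dim side/back), carbonaceous particles strongly
  absorbing (dim everywhere), minerals and semi-transparent pollen in between
  — and are frozen in the registry so tests are deterministic. Hazel and oak
  get deliberately close triples: the two are known to be optically
  confusable. Low gains and class diameters are jointly constrained so each
  class's speciation-channel modes stay inside the shared intensity range; an
  instrument whose channel cannot see its target particles would be
  mis-specified.

Contamination (defaults in parentheses): ambient background particles around
7 µm on 30 % of frames; aggregates — diameter × 1.6, matching the observed
25 → 40 µm olive artefact — with probability 0.08 per grain; storage debris
(random size and gains) at 0.02; and 10 % grossly contaminated outlier frames
drawn from a corrupted mixture (ambient always present, ≥ 50 % aggregates,
≥ 30 % debris). The levels are not measured quantities; they are chosen so the
generator reproduces the documented phenomenology (bimodal olive volume
distribution, outlier frames that an LOF filter can find) and are fixed in
`ContaminationModel`.

All randomness flows from one `numpy` generator per session; the pipeline
fans a single seed out to per-stage child seeds via `SeedSequence.spawn`, so
one integer reproduces a run byte-for-byte.

## Sizing stage

1. **Outlier filter.** Frames are 19-vectors of channel-1 counts. Classical
   LOF scores (Minkowski-p metric) mark a frame an outlier above a threshold
   of 1.5 — LOF ≈ 1 means locally homogeneous density, so the cut is a 50 %
   density deficit; the threshold is configurable because the choice is a
   convention, not a measurement. Neighbourhood size and p are tuned per
   session by a grid search (`n_neighbors ∈ {5, 10, 20, 35}`, `p ∈ {1, 2}`)
   scored by the silhouette of the inlier/outlier split averaged over five
   random 80 % subsamples; degenerate one-sided splits score −1. Duplicate
   frames (common in sparse count data) get capped reachability densities so
   scores stay finite.
2. **Oversampling.** Randomly drawn inlier frames (with replacement) are
   summed until every occupied size bin holds ≥ 20 particles — the count
   needed for stable mean scattering properties — with 30 cumulative
   distributions per species (12 × 30 = 360 rows). A bin counts as occupied
   when the session itself holds ≥ 20 counts there: a bin the session can
   never fill (one stray debris count) would otherwise drive every draw into
   the budget cap (10 × session length) and collapse all rows onto the scaled
   session mean. Budget-capped rows are flagged, not dropped silently.
3. **Normalization and tendency.** Rows are divided by their sums (zero rows
   flagged). The Hopkins statistic (uniform reference points in the bounding
   box, nearest-neighbour distances, 10 % sample) checks that the dataset is
   genuinely clusterable: ≈ 0.5 for spatial randomness, → 1 for strong
   structure. Synthetic study-layout datasets score ≈ 0.96–0.97.
4. **Cluster count.** Ten internal validity indices (silhouette,
   Calinski–Harabasz, Davies–Bouldin, Dunn, C-index, McClain–Rao, gap
   statistic with the one-standard-error rule, Ball–Hall largest-drop,
   Hartigan ≤ 10 rule, Xie–Beni) each vote for a k on the hierarchical
   partitions; majority wins, ties to the smaller k. The set and every
   decision rule are frozen for reproducibility. A caveat the acceptance
   suite documents honestly: on synthetic data the twelve species form twelve
   tight sub-clusters nested inside three size groups, and the extremum-rule
   indices resolve that fine structure, so the vote tends to k = 7–8 while
   laboratory data — with broader, overlapping per-species distributions —
   yields 3. The three-cluster *cut* reproduces the laboratory grouping
   (small / medium / large, monotone in diameter) on the synthetic data too.
5. **Clustering and projection.** Agglomerative clustering with Euclidean
   distances and complete linkage (scipy tree; deterministic given row
   order); a centered PCA projection with component signs fixed by making
   each loading's largest-magnitude entry positive.

## Speciation indices

For particles counted at intensity `F1` on channel 1, the index of channel c
solves `dN/dF1(F1) = dN/dFc(Fc)` for `Fc` and reports `S_c = F1/Fc`; the
optical signature is `(S2, S3, S4, S2/S3, S2/S4, S3/S4)`.

Numerical choices:

* **Matched quantity.** The inversion matches the number concentration per
  *logarithmic* intensity interval, `dN/dlnF = F·dN/dF`, interpolated
  log-log through the populated bins. Under a pure channel gain g the raw
  density transforms as `dN/dF(F) → dN/dF(F/g)/g` — a translation *plus* a
  vertical offset — whereas `dN/dlnF` translates rigidly, which makes
  `S_c = 1/g` exact for grid-aligned gains (and, with geometric bins,
  matching `dN/dlnF` is the same as matching counts per bin). Zero-count
  bins are bridged by the log-log line between their populated neighbours.
* **F1 policy.** `F1` is always the lower bound of a populated channel-1 bin.
  The default `flank` policy takes the first bin reaching half the modal
  count, putting the matched level on the rising flank at about half-maximum:
  any channel whose gain-shifted peak reaches half the channel-1 peak crosses
  it. Matching at the modal bin (`modal` policy, also available) puts the
  level at the channel-1 peak height, which sampling noise on the other
  channels' peaks routinely renders unreachable. A per-bin variant
  (`signatures_per_bin`) emits one signature per populated bin for feature
  enrichment.
* **Inversion.** The channel-c polyline is scanned from low intensity and the
  first crossing kept (deterministic; multiplicity is reported). Evaluation
  outside the node span extends end values as constants for at most one bin —
  extrapolating end-segment slopes would invent levels the curve never
  reached. A level the channel never attains is an error, not an
  extrapolation: an extrapolated index would fabricate optical contrast.
  Levels within 1e-9 of the curve's extremum count as boundary matches.

Signatures are computed per cumulative distribution (the same oversampled
frames that feed the clustering), not per raw frame: single frames of
low-rate species hold too few counts for a stable inversion.

## Classification

Within each size cluster, one binary logistic regression per unordered class
pair is fit on log-transformed, standardized signatures (the entries are
positive ratios spanning decades). Each pair's decision threshold is tuned on
pooled inner 3-fold held-out predictions to maximize the macro F1-score over
a 0.05–0.95 grid (step 0.05; ties to the threshold nearest 0.5). Prediction
aggregates thresholded pairwise votes by majority, ties broken by the larger
sum of winning-pair probabilities, then lexicographically. Rows with
non-finite or non-positive signature entries are `unclassified`, counted
separately. Evaluation uses repeated stratified 10-fold cross-validation
(5 repeats), thresholds tuned inside training folds only, reported as
per-class recall and confusion matrices.

Cluster rosters add the non-pollen classes (droplets, carbonaceous, two
mineral dusts) to every size cluster, except that carbonaceous particles are
left out of the largest-diameter cluster — they rarely occur that large in
ambient air. No class weighting is applied; the oversampling stage already
balances the classes at 30 rows each.

## Problem sizes

Default sessions are 180–300 frames, matching the 179–299-row laboratory
datasets; the study-layout dataset is 360 × 19. The test suite scales some
simulations down as its own choice of problem size: the 20-seed parameter-
recovery check uses 100–120-frame sessions with 12 draws per species, and the
pipeline round-trip tests use 4–6 species at 50–80 frames. The acceptance
script (`scripts/acceptance.py`) runs the full study layout.

## What passing tests do and do not show

The generator reproduces the statistical *structure* the analysis assumes —
lognormal near-monodisperse size modes at the supplier diameters, Poisson
counting, gain-separated channels, aggregate/ambient/debris contamination —
but not real scattering physics: no Mie or irregular-particle phase
functions, no hygroscopic growth or fresh-vs-dry pollen states, no
coincidence losses, no within-session concentration drift. Classification
recalls on synthetic data therefore validate the pipeline's correctness and
its qualitative behaviour (non-pollen classes with extreme gain triples
separate nearly perfectly; classes given similar triples confuse each other),
not field performance. Known limitations besides the physics: the cluster-
count vote caveat above, and LOF threshold/grid choices that are conventions
frozen in configuration rather than measured properties.
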