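# Methods

## Problem and approach

Given a labeled set of NIR absorbance spectra on a shared wavenumber axis,
the package searches for the combination of preprocessing pipeline and
similarity measure that best separates known classes, then applies that
scheme to formulation-replacement questions. The search is exhaustive:
32 pipelines × 11 measures = 352 schemes, each scored on all C(N,2)
unordered sample pairs.

## Preprocessing operators

Order is fixed as scatter → enhance → scale; "none" slots are identities.

* **SNV** (per spectrum): (x − mean)/sd with the sample (n−1) sd; a
  constant spectrum maps to zeros. Removes multiplicative gain and
  additive offset, so two spectra related by a·x + b (a > 0) become
  identical.
* **Savitzky–Golay** smoothing and 1st/2nd derivatives
  (`scipy.signal.savgol_filter`, `mode="interp"`): output length equals
  input length, boundary points come from the polynomial fitted on the
  first/last full window. Defaults: window 11 points, polynomial order 2
  for smoothing/d1 and 3 for d2 (so an exactly linear baseline is
  annihilated by d2); all configurable. Derivatives are per index step,
  not per cm⁻¹ — on a uniform grid this differs only by a global factor
  that subsequent scaling removes.
* **Scaling**: MC and AS act per wavenumber *across the dataset being
  processed* (the comparison batch), following standard chemometric
  convention; pairwise similarity after MC/AS therefore depends on the
  batch. MMS acts per spectrum, mapping it onto exactly [0, 1]
  (constant spectrum → zeros). AS uses the sample sd and maps
  zero-variance columns to 0.

## Similarity measures and normalization

The measure formulas are implemented literally (see the module docstring
of `nirsim.simmetrics`). Choices where the conventional definitions leave
room:

* **SAM** is the cosine itself, not the arccos angle.
* **SID** needs probability vectors; derivative spectra are negative, so
  each vector is shifted by its minimum plus ε = 1e-12 and
  sum-normalized. Taking absolute values instead is available via
  `conversion="abs"`. KL divergences use the natural logarithm.
* **Gsim** needs a per-wavenumber scale mᵢ with no standard definition;
  we use the per-wavenumber range (max − min) over the comparison batch,
  with fallback 1 where the range is 0. This keeps every term in [0, 1],
  is data-adaptive, and gives gsim(x, x) = 1.
* **Esim** uses uniform weights wᵢ = 1/n and the positive exponent of the
  normalized difference ratio (ratio defined as 0 when
  |xᵢ−yᵢ| + |xᵢ+yᵢ| = 0). Its value grows with difference, so it is
  treated as dissimilarity-oriented when normalized.

Normalization to [0, 1] is per (pipeline, metric) batch: Hsim, Close and
Gsim pass through (natively unit-interval); all other measures are
min–max scaled over the pooled within- **and** between-class pair values,
dissimilarities reversed (1 − scaled). Pooling is essential — the
within/between averages are only comparable on a shared frame. A
degenerate batch (all values equal) maps to 1.0. Pairs are unordered
(all 11 measures are symmetric, so ordered counting would only duplicate
every value).

## Scoring and selection

`within` and `between` are the means of the normalized similarities over
same-class and different-class pairs; the Evaluation Index
(within + 1 − between)/2 is strictly increasing in within and strictly
decreasing in between and lies in [0, 1]. Selection keeps schemes with
within ≥ 0.9 and between < 0.7 (defaults, configurable), sorted by index
descending with lexicographic tie-breaks (ties have no canonical order).
Schemes whose metric preconditions fail on the processed data (e.g.
Pearson on a spectrum that preprocessing flattened to a constant) are
recorded with `status="failed"` and a reason so the grid table is always
complete; failed cells are excluded from selection and from any
aggregate.

## Replacement analysis

Formula spectra are linear blends Σ pᵢ · materialᵢ with pᵢ > 0, Σ pᵢ = 1.
This is a model: real blended samples interact optically, and linear
mixing of absorbance is the standard first-order stand-in. The
substitute inherits exactly the replaced component's proportion. The
comparison batch is by default the four spectra {material a, material b,
formula a, formula b}; because batch min–max normalization pins the batch
extremes to 0 and 1, this default makes the formula pair (usually the
least-dissimilar pair) score exactly 1. Supplying a normalization
context (e.g. the materials dataset) widens the batch and yields graded
formula similarities; the trend tests use the materials dataset as
context for this reason.

## Synthetic data generator

Each class profile is a sum of Gaussian bands: a backbone of 7 broad
bands (σ 120–400 cm⁻¹, amplitude 0.2–1.0 AU) shared by all classes, plus
3 class-specific bands. With `separation="high"` the specific bands sit
anywhere on the axis at 15–35 % of the strongest backbone amplitude; with
`"low"` they are confined to the weak-difference windows 4900–5100 and
7200–8000 cm⁻¹ at ≤ 10 %. A measured sample is

    a · profile + b + (c₀ + c₁t + c₂t²) + ε,   t ∈ [−1, 1]

with a ~ 1 + N(0, 0.05), b ~ N(0, 0.02 AU), baseline coefficient sds
(0.02, 0.01, 0.005) AU and white noise sd 0.002 AU — a few percent
scatter, gentle drift and high instrument SNR, typical of a
well-controlled FT-NIR measurement of powdered samples; Gaussian (rather
than Lorentzian/Voigt) bands are the simplest shape that exercises every
operator and measure. The default design is 51 samples in 10 classes of
sizes (4, 3, 6, 5, 10, 3, 8, 4, 4, 4) on the 751-point
10,000→4,000 cm⁻¹ axis. Material fixtures come in "similar" pairs
(shared bands, ~2 % amplitude jitter) and "dissimilar" pairs
(independently drawn band sets).

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; output is bit-identical per seed (the CSV
writer renders 17 significant digits). The default seed is 20240601.

What the generator does **not** emulate: real chemical band assignments,
instrument response functions, temperature/humidity effects, nonlinear
scatter, or class structure beyond band composition. Tests passing on
synthetic data therefore demonstrate the machinery and its qualitative
behaviour (class recovery, replacement trends), not performance on any
real material.

## Problem sizes and numerical choices

The test suite and examples run the full 352-scheme grid on the
51 × 751 default dataset (1,275 pairs per scheme); pairwise metrics are
vectorized over pairs, so the full grid takes seconds. Equality
tolerances: oracle comparisons 1e-12, SG polynomial-reproduction checks
1e-9 (boundary fits accumulate more round-off), SNV/AS contract checks
1e-10. Degenerate-input conventions (constant spectra, zero-variance
columns, zero-range batches) are stated with each operator above and
asserted in tests.

## Known limitations

* MC/AS make similarity batch-dependent by construction; comparing values
  across differently composed batches is meaningful only qualitatively.
* Min–max normalization pins each batch's extremes at 0 and 1, so
  normalized similarities are relative within a batch, never absolute.
* The Esim exponent makes the measure grow with difference despite its
  "similarity" family name; it is handled as a dissimilarity throughout.
* No spectral resampling: datasets must share one axis exactly.
* Linear blend spectra ignore scatter interaction between materials.
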