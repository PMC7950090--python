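# Methods

This note documents the models and procedures implemented in
`shiftprofiler`, the parameters that matter, the numerical choices made
where the design was genuinely open, and what the synthetic fixtures do and
do not establish.

## Delta-mass histogram

All PSM delta masses are pooled across experiments with unit weight and
binned at `bin_width` (default 0.0002 Da).  Pooling with unit weights is
arithmetically identical — up to one global constant — to averaging
per-experiment histograms weighted by each experiment's share of total
PSMs, so one aggregate histogram serves multi-experiment analysis.  The
range is padded by `histogram_extension` (5 Da) on both sides so smoothing
cannot truncate extreme peaks.

**Tie-break jitter.** Uniform noise on ±`jitter_half_width` breaks ties
between mass values and bin boundaries.  The default is 0.0001 Da — half a
bin — rather than the historically used ±0.005 Da, which is 25× the bin
width and would smear sub-millidalton peak structure; the larger value
remains selectable.  One seeded generator (`rng_seed`, default 42) drives
it; the seed is part of the config and reports are byte-reproducible.

**Smoothing.** Each bin's weight is spread over `smoothing_bins` (5)
neighbors by a Gaussian kernel whose σ is fixed by requiring that the
central 5 bins hold `smoothing_mass_fraction` (95%) of the Gaussian mass:
σ = 2.5/Φ⁻¹(0.975) ≈ 1.2755 bins.  Kernel entries are per-bin integrals of
that Gaussian, renormalized.  Edge bins use source-side renormalized
truncated kernels, so total weight is conserved exactly (tested to 1e-9
relative); the price is that a constant vector is preserved only away from
the outermost `2·half` bins — irrelevant in practice because the ±5 Da
padding keeps signal off the edges.

## Peak detection

Prominence is computed on a flattened copy of the smoothed vector:
consecutive groups of bins (spanning `flatten_mass_span`, 0.0010 Da ⇒ 5
bins) are replaced by their group minimum, which suppresses sub-threshold
wiggles during the monotonic walk.  The group span is tied to the smoothing
span to keep the procedure scale-invariant under bin-width changes; the
flattened vector is used *only* for apex detection and prominence.

A candidate apex is (the weight-maximal bin of) a plateau of the flattened
vector strictly above both neighbors.  Walking left and right while values
are non-increasing yields two shoulders; prominence is
`(apex − max(shoulders))/apex`, in [0, 1].  The literal apex/shoulder
*ratio* is ≥ 1 and could not be compared with the 0.3 threshold, so the
normalized drop is used.  Peaks at the vector ends get prominence 0 and are
never called.

SNR is the mean smoothed bin height inside `snr_signal_window` (0.004 Da)
centered on the apex minus the mean over two `snr_background_flank`
(0.005 Da) flanks, truncated at histogram ends.  Candidates above the
prominence threshold are ranked by SNR and the top `top_n_peaks` (500)
retained.  Boundaries are where the monotonic descent from the apex ends or
apex ± `precursor_tol` (0.01 Da), whichever is closer; the tolerance is a
peak-width cap, not the search engine's precursor window.  Each PSM is
assigned to the covering peak with the nearest apex.  A peak's
`reported_mass` is the mean raw (unjittered) delta mass of its assigned
PSMs — a summary robust to bin quantization — while `apex_mass` keeps the
bin-center value.

## Annotation

The entry table holds a curated list of common Unimod shifts, single-residue
insertion/deletion masses for all 20 residues, isotopic-error entries at
±k·`isotope_spacing` (k = 1, 2; default 1.00235 Da, the averagine envelope
spacing — the constant is a package choice), user-defined shifts, and
negative counterparts of searched variable modifications (so "the search
engine attributed an oxidation that actually belongs to the composite
shift" is expressible).  Rare protocol labels (O18/N15 metabolic labeling)
are excluded by default because they alias common shifts.

Peaks are annotated in descending SNR order, staged per peak mass m:

1. best single entry with |m − Δ| ≤ `annotation_tol` (0.01 Da);
2. best pair (user shift, any entry);
3. best pair drawn from components already used in single annotations of
   this run plus masses of peaks left unannotated so far;
4. otherwise unannotated, and m joins the stage-3 pool.

Candidates rank by |residual|, then fewer components; with
`prioritize_user_mods`, any candidate containing a user entry outranks all
that do not.  Unimod site restrictions do not veto annotations (sites are
the localization stage's concern).

## Localization

For each assigned PSM with a resolvable spectrum, the peak's reported mass
is placed on each residue in turn; singly charged b/y ladders (fixed and
variable search modifications always applied) are matched greedily —
fragments in ascending m/z, each claiming the nearest unused spectrum peak
within `fragment_tol` (20 ppm default; absolute Da selectable) — and scored
with `log10(Nb!·Ny!·max(ΣIb,1)·max(ΣIy,1))`, factorials via log-gamma.
A PSM is localizable iff the best placement matches strictly more ions than
the unshifted baseline.  The unit weight is split uniformly over positions
tied at the best *score* (not ion count — an open choice, documented here);
the N-terminal flag records position 1 in the tie set.  Only singly charged
b/y ions are scored, for determinism and to match the default search
scoring ion set.

Per peak and experiment, residue weights are summed and divided by
background residue frequencies.  `background_scope` selects the background
population: all localizable PSMs in the dataset (default), their unique
peptides, or the peak's own localizable PSMs/peptides.  Enrichment is
(weight fraction)/(background fraction); residues absent from the
background are omitted rather than reported as infinite, and the
background-frequency-weighted mean enrichment is identically 1.  PSMs whose
spectra are missing are excluded from localization *and* from background
counts (they still count in the histogram and quantification).

## Modified–unmodified comparison

PSMs with |Δm| < `unmodified_threshold` (0.001 Da) are indexed by
(experiment, peptide, charge); keys with more than `unmodified_cap` (50)
spectra are subsampled with a per-key seed derived from `rng_seed` (CRC of
the key, kept below 2³¹).  Each shifted PSM is compared with all
counterparts of the same peptide and charge within the same experiment
(`same_run_only` restricts to the same run): cosine similarity of the two
spectra accumulated on a `similarity_grid_width` (0.05 Th) m/z grid —
binning rule and grid width are package choices; a square-root intensity
transform is available but off, and precursor peaks are not stripped — and
ΔRT = PSM RT − mean counterpart RT, in seconds.  Zero-shift PSMs compare
against their own bin (self included), which pins that peak's mean ΔRT to
exactly 0 per peptide and makes its similarity an upper reference.  Per-peak
profiles report mean similarity, mean ΔRT, n compared, and the fraction of
assigned PSMs with a counterpart ("% in unmodified").

## Reports

Five deterministic TSVs: `global.profile.tsv` (one row per peak, ordered by
pooled PSM count: mass, counts per experiment raw/normalized, annotation,
% in unmodified, similarity, ΔRT, N-term rate, top-2 residue enrichments),
`peaks.tsv`, `localization.tsv`, `similarity.tsv`, and
`experiment.matrix.tsv` (experiments × peaks, column-wise z-scores of
normalized spectral counts; sample n−1 standard deviation, constant columns
map to zeros).  Masses print at 4 decimals so printed values stay within
the annotation tolerance of their true values; rates/similarities at 2, ΔRT
at 1.  Identical inputs and seed give byte-identical files.

## Synthetic fixtures

`fixtures.FixtureSpec` states the world: by default 3 experiments × 2000
PSMs drawn from per-experiment pools of 250 tryptic-like peptides (length
7–16, C-terminal K/R; charge 2–3 fixed per peptide), with 8 implanted
shifts — oxidation (M), phospho (S), formyl (K), methyl (K), TMT (S),
deamidation (N), ammonia loss (Q), acetyl (K) — at 3–6% frequency each
(~70% unmodified), site fidelity 0.9, and RT offsets from −70 to +450 s.
Observed delta masses are true shift + N(0, 0.0005 Da) so peaks are sharp
relative to the 0.004 Da SNR window; RTs are a per-peptide base elution
U(600, 3000 s) + offset + N(0, 10 s).  Spectra are exact b/y ladders with
log-normal intensities plus 10 uniform noise peaks — the intensity model
exercises the score's intensity terms without claiming realism.

Not emulated: chromatographic peak shape, isotope envelopes, fragment
charge states > 1, neutral-loss ions, reporter ions, co-isolation.  A green
test on fixtures therefore establishes the bookkeeping, scoring and
aggregation are correct under the stated world, not instrument-level
performance.

## Known limitations

- Two-component annotation cannot express three-way composites (e.g. a
  missed cleavage + TMT + water loss); such peaks surface as unannotated
  with a pool entry.
- Greedy fragment matching is order-dependent by construction (b series
  before y); the brute-force test oracle implements the same stated rule.
- mzML support covers the subset this package writes (32/64-bit
  little-endian, optionally zlib-compressed arrays); exotic encodings need
  conversion to MGF.
- No RT alignment across runs; ΔRT comparisons are within-experiment.
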