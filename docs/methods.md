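# Methods

`teloprobe` implements three analyses of yeast telomerase RNA (TLC1)
biology — in-vivo chemical structure probing, single-molecule
localization, and 3′ end processing — together with seeded synthetic-data
generators so every stage can be exercised end to end against known
ground truth. This note records the models, the parameters that matter,
the numerical choices, and what the synthetic benchmarks do and do not
demonstrate about real data.

## DMS-MaPseq reactivity

Dimethyl sulfate methylates the Watson–Crick face of unpaired adenosines
and cytosines in vivo; a processive reverse transcriptase (e.g. TGIRT)
converts each adduct into a mutation, so deep sequencing yields
per-nucleotide mutation counts `X_k` and coverages `C_k` for a
DMS-treated (`+`) and an untreated (`−`) sample. The reactivity at
nucleotide *k* is the background-corrected rate

    r_k = max( ( X⁺_k/C⁺_k − X⁻_k/C⁻_k ) / ( 1 − X⁻_k/C⁻_k ), 0 )

clamped at zero when background exceeds signal. Guanines and uracils,
which DMS does not probe at the pairing face, are masked. Profiles are
scaled by 2–8% normalization: among the unmasked raw values sorted in
descending order, the top `ceil(0.02·n)` are excluded as outliers and
the normalizer is the mean of the next `ceil(0.08·n)` values (ties
broken by position order). The normalizer of a normalized profile is 1,
so the operation is idempotent and scale-invariant.

Parameters:

- `min_coverage` (default 1000 reads/nt in either channel): positions
  below it are flagged `low_coverage` and excluded. Real experiments of
  this kind reach hundreds of thousands of reads per A/C, so 1000 is a
  permissive floor; it is configurable because no canonical cutoff
  exists.
- Positions whose untreated mutation rate is 1 (degenerate denominator)
  are flagged `invalid` rather than evaluated.
- T and U are synonyms in all sequence input. No per-position standard
  error is computed; the SHAPE-style `.map` output carries a stderr
  placeholder of 0.

## Differential-structure screen

Given normalized profiles for ≥2 biological replicates of each of two
strains, the screen computes per-nucleotide dissimilarity scores:
`d_within,k` is the mean of |r_a,k − r_b,k| over all replicate pairs
drawn within a strain (pooled across both strains), `d_between,k` the
same mean over all cross-strain pairs, and `Δd_k = d_between,k −
d_within,k`. Candidate regions are maximal runs of consecutive unmasked
nucleotides with `Δd_k > 0`, split at masked gaps and position
discontinuities, keeping runs of ≥ `min_len` (default 5) nt. Each
candidate is tested with a one-sided Wilcoxon signed-rank test pairing
`d_between,k` with `d_within,k` (zero differences dropped; exact null
distribution up to 25 informative pairs, normal approximation with
continuity correction beyond). P-values are Benjamini–Hochberg adjusted
across the candidates of one pairwise strain comparison, and a region is
called significant when length ≥ 5 nt, p < 0.05, q < 0.1 and mean
Δd > 0.01. Output coordinates are 1-based inclusive in TSV and 0-based
half-open in BED.

Two statistical properties deserve emphasis:

- **The region test is conservative, not calibrated.** Under the null
  (identical strains), `Δd_k` has mean zero but a negative median:
  `d_within` averages 6 replicate pairs while `d_between` averages 9,
  both built from the same 6 replicate values, and the resulting
  difference of correlated, right-skewed means is asymmetric (direct
  Monte Carlo with iid normal replicates gives P(Δd_k > 0) ≈ 0.38).
  One-sided signed-rank p-values on a fixed region therefore
  concentrate toward 1 rather than being uniform — the acceptance suite
  measures this deliberately. Degree-balanced pair subsets and
  equal-cardinality homogeneous/heterogeneous subset constructions show
  the same asymmetry, so this is intrinsic to mean-absolute-difference
  dissimilarities, not a fixable detail. The practical consequence is
  loss of power, never inflation of false positives: on 100 null
  simulations (3v3 replicates, 300-nt transcript, coverage 10⁴) the
  fraction of simulations producing any significant call is ~0.04–0.10,
  within the intended ≤0.1 bound.
- **Candidate selection interacts with masking.** Because runs split at
  masked G/U positions, a differential region in a G/U-rich sequence
  fragments into sub-threshold runs. The power benchmark therefore
  plants its 20-nt region in an all-A/C transcript, where recovery is
  essentially complete (50/50 runs, median boundary error 0 nt); on
  sequences of typical composition, sensitivity is bounded by the
  lengths of unmasked A/C runs, not by the statistics.

This screen follows only the published description of the dStruct-style
procedure (dissimilarity contrast, thresholds, per-comparison FDR); it
does not reproduce the internals of any particular implementation and
makes no claim of numerical identity with one.

## smFISH quantification

Single RNA molecules appear as diffraction-limited spots in the Cy3
channel; a Cy5 probe against the rRNA spacer ITS1 marks the nucleolus
and DAPI marks the nucleus. Processing:

1. **Segmentation** — per-channel global threshold (Otsu by default, or
   a fixed value), 26-connected components in 3D, removal of objects
   smaller than `min_voxel_object` (default 10 voxels), labels inherited
   from the provided cell-boundary mask. Nucleolus voxels are
   constrained to lie within the nucleus mask.
2. **CLEAN spot extraction** — per cell, iteratively: take the brightest
   residual voxel, least-squares fit a 3D Gaussian (amplitude, subvoxel
   centroid, σ_xy, σ_z, local background) in a ±4σ window initialized at
   `psf_sigma` (σ_z initialized at 2σ_xy, the widefield axial
   elongation), subtract the fitted profile (background excluded), and
   stop when the residual maximum in the cell falls below
   `min_fluorophore_intensity` — the minimum acceptable intensity of a
   single fluorophore, a required input (calibrating it from
   photobleaching steps is out of scope). A non-convergent fit falls
   back to a fixed-σ peak-amplitude profile; an iteration cap (10,000
   per cell) guards against pathological inputs. Because subtracted
   profiles are nonnegative, the residual maximum is non-increasing. A
   refinement sweep then restores each spot into the residual and refits
   it with its neighbours removed, which unbiases fits whose window
   contained another spot's core; finally, components closer than
   2·`psf_sigma` (z compressed 2× to match the PSF anisotropy) are
   merged into their brighter neighbour, since sub-resolution CLEAN
   components describe a single source. A spot's integrated intensity
   is the flux actually subtracted from the image, which equals the
   analytic Gaussian volume A·(2π)^{3/2}σ_xy²σ_z away from stack
   boundaries.
3. **Classification** — by the compartment containing the spot's
   centroid voxel, with precedence nucleolus (NO) > nucleoplasm (NP) >
   cytoplasm (CYT); spots outside every cell are discarded and counted.
4. **Per-cell statistics and comparison** — totals, per-compartment
   counts and fractions (cells with zero spots are excluded from
   fraction averages, reported); strains are compared on per-cell totals
   and fractions with the two-sample Kolmogorov–Smirnov test.

## 3′ RACE classification

TLC1 exists as a minor long polyadenylated precursor and an abundant
~1157-nt mature form. After linker ligation, reverse transcription and
amplicon sequencing, each trimmed read is a templated stretch matching
the reference followed by zero or more non-templated adenosines. The
classifier strips the linker by exact suffix match, extends the
templated prefix greedily (a trailing A that matches the reference is
templated, the standard 3′ RACE convention; up to `max_mismatches`
scattered mismatches, default 0, with the stretch always ending on a
match), requires ≥ `min_anchor` (15) templated nt, and demands that all
remaining residues be A. End positions are binned 1154…1158, ≥1159
(pooled), "other" (<1154); tail lengths into 0 / 1 / 2–5 / 6–10 / >10
adenosines. The long:mature ratio counts reads with any tail or an end
beyond 1157 as precursor-like and untailed reads ending at ≤1157 as
mature; this sequencing-count definition is the package's own and is
config-overridable. Reads whose entire poly(A) tail happens to be
templated are called with a longer end and zero tail — an inherent
ambiguity of greedy templating that the simulation reference avoids by
keeping its 3′ window (positions 1150–1170) adenosine-free.

## Synthetic-data generators

All three generators are deterministic given `(config, seed)` and return
exact ground truth.

- **Mutational profiling** (`MapSimConfig`): per-nucleotide coverages
  are Poisson(`coverage_mean`, default 10⁴) truncated at ≥1; mutation
  counts are Binomial(C, rate) with treated rates `unpaired_rate` (0.05)
  at unpaired A/C, `paired_rate` (0.01) at paired A/C and
  `background_rate` (0.002) at G/U and everywhere in the untreated
  channel — rates representative of in-vivo DMS probing. Pairing states
  are Bernoulli(0.5) per position, shared between strains except inside
  `diff_regions`, where the state of every A/C flips in one strain.
  Biological replicate variability is a per-replicate log-normal
  multiplicative rate factor (σ = 0.05; real replicate dispersion for
  this assay is unpublished, so this is a free parameter chosen to make
  within-group dissimilarity non-degenerate). Counts are independent
  across positions; PCR bias, sequencing error and reverse-transcriptase
  drop-off are not modelled, so passing screens here demonstrates the
  statistics, not robustness to those artifacts.
- **smFISH stacks** (`FishSimConfig`): ellipsoidal cells on a grid, each
  with a nuclear ellipsoid and a nucleolar ellipsoid inside it; Cy3 =
  planted 3D Gaussian spots (σ_xy = `psf_sigma` = 1.3 voxels, σ_z =
  2σ_xy) + Poisson background (λ = 2); Cy5/DAPI = compartment fill +
  background. Planted spots keep a pairwise distance ≥ 4·`psf_sigma`
  (z-compressed), so each is an optically resolvable object with
  well-defined ground truth; blended sub-resolution molecules, optical
  aberrations and autofluorescence are not modelled.
- **RACE reads** (`RaceSimConfig`): reads are reference prefixes ending
  at positions sampled from `end_position_weights` plus poly(A) runs
  sampled from `tail_length_distribution`, optionally with a fixed 17-nt
  linker appended; constant Phred quality. Default mixture: ends mostly
  at the mature 1157 with minor 1156/1158/≥1159 species, 80% untailed.

## Benchmark problem sizes

The acceptance benchmarks use 100 null and 50 planted-region screen
simulations (300-nt transcripts, 3v3 replicates, coverage 10⁴), one
64×128×128 4-cell stack with 36 spots at amplitude 10× the detection
threshold plus a noise-free flux stack, and 1000 simulated RACE reads —
sizes at which every Monte-Carlo bound in the test suite is stable
across seeds while the whole suite runs in seconds.

## Known limitations

- The region test's conservativeness (above) means reported p-values
  for marginal regions overstate the evidence against significance;
  strong regions (the planted-region regime) are unaffected.
- CLEAN detection assumes a roughly Gaussian, spatially invariant PSF
  and spots separated by the resolution limit; it does not deconvolve
  blended molecules.
- The RACE classifier assumes error-free 3′ ends (≤1 configurable
  mismatch in the templated anchor) and exact linker match; it is a
  classifier for trimmed reads, not an aligner.
- Cell boundaries are an input (synthetic truth or a provided label
  mask); no DIC-based cell segmentation is included.
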