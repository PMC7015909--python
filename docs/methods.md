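# Methods

## Mass arithmetic

Peptide and fragment masses are monoisotopic throughout (PRM selects
monoisotopic precursors): a peptide's neutral mass is the sum of residue
monoisotopic masses (pyteomics reference table) plus water; y-ion m/z is
(C-terminal residue sum + water + z·proton)/z with proton mass 1.007276 Da.
SILAC heavy labels are fixed per-residue shifts, +8.014199 Da per lysine
([¹³C₆,¹⁵N₂]) and +6.020129 Da per arginine ([¹³C₆]); no other labels are
supported. Fixed chemical modifications are a per-residue table passed to
every mass function, defaulting to carbamidomethyl cysteine
(+57.0214637 Da), the usual consequence of iodoacetamide alkylation during
digestion; library construction protocols rarely state this explicitly, so
it is configuration, not hard-coded chemistry. The fragment-ion extraction
window is a symmetric ppm interval (20 ppm by convention).

## Spectral library model

One library entry is a tryptic peptide (canonical residues, C-terminal K/R,
at most one missed cleavage) with 4–6 unique y-ion transitions carrying
reference relative intensities; at most 4 peptides per kinase and no
duplicate (sequence, charge) pairs. The on-disk form is a flat TSV, one row
per transition with entry-level fields repeated — trivially diffable and
round-trips exactly. All invariants are enforced at load with file line
numbers in the error.

## Synthetic experiment generator

The generator emulates the structure of a SILAC-PRM kinome run, not any
particular instrument:

- **Elution.** Each peptide elutes once as a Gaussian of σ = 5 s shared by
  all transitions and both channels (co-elution is physical for a SILAC
  pair), sampled on a 2 s cycle over apex ± 8σ, so ≥ 10 points across the
  peak — enough for trapezoidal integration to ~1%.
- **Abundance.** Peak amplitudes are log-uniform over 4 orders of magnitude
  (10³–10⁷ a.u.), with the extremes pinned so the configured span is
  realized exactly in every draw.
- **Fold changes.** True protein log₂(metastatic/primary) ratios are
  N(0, 1); at that scale roughly half the proteins exceed a 1.5-fold
  change, a realistic fraction for a metastasis comparison. All peptides of
  a protein share its ratio. Forward labeling realizes heavy/light = r,
  reverse realizes 1/r, exactly reciprocal in the noiseless limit.
- **Transition intensities.** Per-peptide transition fractions are drawn
  from a Dirichlet(2) and double as the library's reference intensities, so
  a clean peptide scores dotp = 1 by construction and any drop measures
  distortion introduced by noise or interference.
- **Noise.** Two multiplicative log-normal terms: per sample point
  (σ = 0.10), and per peptide–channel–run amplitude factor (σ = 0.07)
  modeling the replicate-to-replicate variability that survives averaging
  over the ~9 effective points of an integrated peak. Point noise alone
  cannot produce realistic replicate scatter — it averages out in the
  integral — which is why the amplitude term exists. A flat baseline
  (2 a.u.) completes the model. Under these defaults peptide-ratio
  replicate RSDs come out near 11% and protein-level RSDs near 6%, the
  right order for a well-behaved SILAC-PRM assay, and forward/reverse sign
  consistency lands at 93–97%.
- **Interference.** A configurable fraction of peptides receives, in one
  channel on a random subset of at most half their transitions, an extra
  Gaussian centered 3–5σ from the apex with total amplitude 5× that
  channel's summed apex — a co-eluting contaminant from the complex matrix.
  This is the designed failure mode for the dotp/co-elution gates, and the
  generator records exactly which peptides were corrupted.
- **Determinism.** Every draw flows from one `numpy` Generator; equal
  configurations reproduce bit-identical experiments.

What the generator does **not** emulate: retention-time drift between
runs, chromatographic tailing, detector saturation, missing channels,
isotope envelopes, or scan-level spectra. Passing tests therefore
demonstrate the correctness of the arithmetic and the selectivity of the
gates under idealized peak shapes — not robustness to every pathology of
real LC-MS data.

## Quantification

Peak detection operates on the summed-across-transitions trace: apex at the
global maximum, boundaries where the trace first falls to 5% of apex height
or a local minimum (whichever comes first walking outward), capped at
apex ± 4 estimated σ (σ from the interpolated FWHM). Detection runs per
channel, but integration bounds are taken from the channel with the larger
summed apex and applied to both, so light and heavy areas always cover the
same window — the standard treatment for SILAC pairs. Transition areas are
trapezoidal with interpolated endpoints; no background subtraction or other
adjustment is applied to areas.

dotp is the cosine similarity of the observed transition-area vector
against the library reference intensities — scale-free in both arguments,
1 for proportional vectors — computed per channel and gated at ≥ 0.7 in
*both* channels (the stricter reading of a two-channel assay). Areas rather
than point-wise intensities are scored; with shared bounds the two choices
agree for clean peaks and areas are the quantity actually quantified.

Co-elution uses a per-transition apex estimate: the intensity-weighted
centroid within the shared bounds after subtracting the window minimum (so
a flat background cannot drag the centroid to the window center). The gate
passes when the largest pairwise centroid difference across all transitions
of both channels is within the tolerance, inclusive; the default tolerance
is one peak σ (5 s). Centroids were chosen over per-trace argmax because
the argmax of a noisy 2 s-sampled trace jitters by one or two cycles, which
at a 5 s tolerance would occasionally fail clean peptides; the centroid's
jitter is an order of magnitude smaller, while a genuine interfering peak
still displaces it by ≳ 2σ.

Failure precedence when several gates fail: missing_channel, then
low_dotp, then no_coelution. There is no multi-candidate peak search: the
global maximum of the summed trace *is* the quantified peak, so a dominant
interferent captures the window and is then rejected by the gates — the
intended behavior, since silently re-picking a lower peak that best matches
the library would amount to assuming the answer.

## Differential expression

Orientation maps each passing peptide's measured heavy/light ratio onto
log₂(metastatic/primary): +log₂ r under forward labeling, −log₂ r under
reverse. Roll-up is mean of peptide log₂ within a replicate, then mean
across replicates — log-scale averaging is symmetric under ratio inversion,
so forward and reverse replicates contribute on equal footing. RSD is
computed on linear-scale replicate protein ratios (sample SD, n−1), as a
percent of the mean; it is undefined (reported empty) for a single
replicate. Calls use the 1.5-fold cutoff on the protein mean log₂; no
p-values and no multiple-testing adjustment are attached, the cutoff being
the assay's significance device.

QC metrics: the consistency fraction is the share of peptides (averaged
per design first) whose oriented log₂ has the same sign in forward and
reverse experiments, an exact zero agreeing with either sign; R² is the
squared Pearson correlation of those per-peptide values; dynamic range is
log₁₀(max/min) of passing peptides' light+heavy summed areas. The
cross-pair matrix keeps only proteins quantified in every pair; class
counts are tabulated per pair before that intersection.

## Survival screen

Quartile groups take ⌈n/4⌉ samples per tail of the expression ranking,
with ties broken by sample id for determinism; constant-expression genes
are excluded with a reason. Kaplan-Meier estimation and the two-group
logrank test (χ², 1 df, two-sided) are delegated to lifelines; the test
suite cross-checks the statistic against a direct hypergeometric summation.
Direction is the sign of the difference in KM median survival (high −
low). Significance is unadjusted p < alpha (default 0.05) by design; on
1000 independent null genes with n = 200 the screen flags ~5%, which is
the expected behavior of an uncorrected screen, not a defect. The test
helper simulates exponential event times whose rate is multiplied by a
planted gene's hazard ratio in that gene's top expression quartile, with
uniform censoring.

## Demo and problem sizes

The packaged demo simulates an 80-kinase library (~190 peptides), three
cell pairs (4 + 2 + 2 runs) with 5% interference, and a 300-patient
survival screen with three planted prognostic kinases — sizes chosen so the
full workflow, and the acceptance recomputation, each complete in well
under a minute while leaving every estimate's sampling error small relative
to the margins being checked. Outputs are written with 6 significant
digits and are byte-identical across runs at a fixed seed.

## Known limitations

- The dotp here is a plain cosine on areas; vendor tools' dotp variants
  apply intensity transforms that are not publicly specified, so gate
  behavior near the 0.7 boundary need not match any particular tool.
- No retention-time alignment across runs and no imputation of proteins
  missing from a pair; a peptide absent in one channel is dropped, not
  rescued.
- The generator's noise is stationary and peak shapes are ideal Gaussians;
  conclusions about gate selectivity transfer to real data only insofar as
  real interference is at least as disruptive as the simulated kind.
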