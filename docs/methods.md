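# Methods

## Forward model of amide exchange

The simulator and analysis both assume the EX2 limit: each backbone amide
exchanges independently, first order, at k_obs = k_int / P, and a peptide's
isotope envelope shifts as a single population. The deuterated fraction of
one amide after labeling time t (seconds) is 1 − exp(−k_obs t). EX1
(bimodal) behaviour, side-chain exchange, and quench-phase kinetics are out
of scope.

Intrinsic rates k_int come from the standard poly-DL-alanine reference
parameterisation for D2O: acid-, base- and water-catalysed terms, each with
per-side-chain log10 corrections from the residue carrying the amide
("lambda") and its predecessor ("rho"), terminal-group corrections (the
protonated N-terminal amine on residue 2's amide; the carboxylate on the
last residue's amide), and Arrhenius temperature scaling (activation
energies 14/17/19 kcal·mol⁻¹ for the acid/base/water terms, reference
293 K). Ionisable side chains are used in their near-neutral-pD forms, and
the D2O ion product is held at pK = 15.05 independent of temperature; the
model is therefore intended for pD ≈ 6–9 near room temperature, which
covers the labeling condition used throughout (pD 8.0, 298 K, matching a
Tris pH 8.0 buffer at 25 °C). A uniform-k_int fallback decouples kinetics
from sequence where tests need that.

Exchangeable-amide convention: a peptide with n residues reports at most
n − 1 − (prolines beyond position 1) deuterons. Excluding exactly one
N-terminal residue (rather than two) is a deliberate choice, isolated in
`exchangeable_amides` so the alternative convention is a one-line change.

## Envelopes and centroids

Natural isotope envelopes are aggregated (unit-mass) stick spectra: the
elemental composition of the peptide (via pyteomics) is convolved over
per-element isotope-abundance vectors, and stick k sits at the monoisotopic
mass plus k × 1.0033548 Da. Fine isotope structure is irrelevant here
because the observable is the centroid, not peak shape. Deuteration
convolves an exact Poisson-binomial deuteron-count distribution (iterative
convolution over per-amide fractions) onto the envelope, shifting by
1.00628 Da (²H − ¹H) per deuteron; the centroid shift is then exactly
1.00628 × Σ fractions, which is what makes the round-trip identity testable
to 1e−9.

## What the simulator emulates, and what it does not

A simulated experiment is: a protein sequence; one log10-protection-factor
profile per state; peptides tiling the sequence (pepsin-like, default
10-mers with 5-residue overlap); 2 states × timepoints {15, 30, 45, 60,
120} s × 3 technical replicates, plus undeuterated controls; a uniform
multiplicative back-exchange loss (default 0.25) applied to all amides; and
Gaussian noise (default sd 0.02 Da) added to every measured centroid — the
instrument observable — so noise propagates into uptake through the same
centroid differencing the analysis uses. The first and last 10 residues
(configurable) are always fully disordered so the back-exchange estimator
has the disordered terminal peptides it requires. Random streams are split
per (peptide, state, exposure, replicate) from one seed, so enlarging the
peptide map never reshuffles existing draws; output tables are bit-identical
for a fixed seed.

The replicate noise level is a configuration knob, not a claimed
measurement: 0.02 Da is a plausible centroid repeatability for a
well-behaved TOF peptide, chosen once. The simulator does not model
retention time, charge states, ion mobility, spectral overlap, peptide
misassignment, or biological-replicate variance, so passing tests
demonstrate correctness of the analysis pipeline under its stated
statistical assumptions — not robustness to every pathology of real data.

The evidence-table simulator emits, per requested lysine, n covering
tryptic-like peptides (default 50) with round(occupancy × n) digly rows and
the rest acetyl; any other occupancy site a peptide covers is also assigned
digly/acetyl at that site's occupancy (stratified so assigned fractions
match to rounding), mirroring exhaustive acetylation where every covered
lysine carries exactly one of the two states. Areas are lognormal with
sigma 0.3 (~30% CV, typical of label-free peak areas); with zero noise the
recovered ratio equals the requested occupancy exactly by construction.

## Uptake pipeline choices

* The undeuterated reference for a peptide pools all of its control rows
  across states: the control carries no deuterium, so it is
  state-independent, and pooling makes control noise cancel exactly in
  state-versus-state differences (per-state references would inject a
  coherent offset that inflates the null false-positive rate).
* Back-exchange correction divides by (1 − factor) — restoring disordered
  termini to 100% of maximum — rather than multiplying the deficit; the
  convention is isolated in `correct_uptake`. The factor is global per
  experiment and estimated at the longest timepoint (120 s), where the
  disordered termini are saturated and kinetic bias is smallest; terminal
  window default 10 residues.
* Replicate-level corrected values are left unclipped: the correction is
  then a global scalar division, so every downstream test statistic is
  provably identical to the raw-uptake statistic (asserted by test).
  Clipping into [0, max_uptake] applies to curve means (with a logged
  warning) and to the scalar correction helper.
* Exponential fits D(t) = A(1 − e^(−kt)) are presentation-level summaries
  (single exponential, bounded 0 ≤ A ≤ max_uptake, k > 0, least squares on
  timepoint means); a flat-zero curve yields A = 0 with the rate flagged
  unidentifiable, and non-convergence is reported, never defaulted.
  Exports report time in minutes; all internal arithmetic is in seconds.

## Differential statistics

Identification filters (score ≥ 6.5, products per amino acid ≥ 0.2, MH+
error ≤ 5 ppm, retention-time sd ≤ 5%, observed in ≥ 2 of 3 runs) use
inclusive boundaries — the cutoffs are read as minimum/maximum acceptable
values.

The state comparison is a two-way ANOVA (state × exposure) on replicate
uptake plus one two-sample t-test per timepoint, with a peptide called
significant only when the ANOVA state effect and at least one t-test are
below alpha (default 0.05, no multiple-testing correction by default; a
per-peptide Benjamini–Hochberg option exists). "ANOVA and t-tests" admits
several composite rules, so both p-value families are reported in full and
the verdict rule can be audited or replaced. The default t-test is the
pooled-variance Student test: with three technical replicates per state
produced by one robotic protocol, equal variances are the natural
assumption and the test is exactly calibrated (measured null per-timepoint
rate 5.0% at alpha 0.05 on 500 simulated null peptides), whereas the Welch
variant's small-sample degrees-of-freedom approximation is conservative at
n = 3 (measured ~3.4%); Welch remains available via `t_variant="welch"`.
The AND-composite verdict is necessarily conservative (measured ~2–3%
at alpha 0.05), which is the intended trade for region calls.

Residue-level classification is a consensus over significant covering
peptides (majority; increased/decreased ties flagged ambiguous; covered but
never significant → not-significant; no coverage reported distinctly).
Spatial resolution is limited to one peptide overhang (9 residues at the
default tiling) at each edge of a true region.

## diGly occupancy

Occupancy of lysine p = Σ areas of score-filtered evidence rows with a
digly at p ÷ Σ areas of rows whose interval covers p (start ≤ p ≤ end,
including a C-terminal lysine covering itself). Areas, not spectral counts,
are summed; zero-area rows contribute nothing; rows placing a digly on a
non-lysine are rejected and logged. Missed-cleavage digly forms are
included in both numerator and denominator. A covered lysine with no digly
evidence reports occupancy 0; an uncovered lysine reports no-coverage
(NaN), a deliberately distinct outcome. The score filter is strict
(−10 log P > 15, so 15.0 itself is rejected). Chain linkages are classified
by the digly position on the canonical 76-residue human ubiquitin (shipped
as a FASTA resource): K6/K11/K27/K29/K33/K48/K63, plus M1 for the linear
linkage; fractions are area-weighted and sum to one over observed linkages.

## Numerical and engineering notes

* Envelope construction merges coincident sticks and renormalises, so
  envelopes always have strictly increasing masses and unit total
  intensity; centroids are plain intensity-weighted means.
* Element isotope patterns use exponentiation-by-squaring over polynomial
  convolution; patterns are truncated at cumulative abundance 1 − 1e−10 and
  cached per composition.
* The two-way ANOVA falls back to one-way on state when only one exposure
  level is present, and returns p = 1 for degenerate all-equal data; t-tests
  on two zero-variance groups return p = 1 (equal means) or 0.
* Peptide-map tiling anchors the final peptide at the C terminus so
  coverage is complete whenever the protein is at least one peptide long.
* Statistical test sizes: calibration tests use 500 simulated null peptides
  (2,500 t-tests); the acceptance script uses 1,000 (5,000 t-tests); power
  and fit-recovery tests use 200 Monte-Carlo draws; occupancy recovery uses
  50 evidence rows per site. These sizes give standard errors comfortably
  inside the asserted tolerances while keeping the whole suite fast.

## Known limitations

* Intrinsic-rate constants are a transcription of the published reference
  tables with fixed D2O ion product; absolute rates at extreme pD or
  temperature will drift, though every acceptance quantity here depends
  only on relative/saturating behaviour.
* No per-residue uptake deconvolution from overlapping peptides; residue
  calls are peptide-consensus paints, not deconvolved signals.
* No EX1/bimodal envelope handling; a transiently protected region is
  visible only through its per-timepoint t-tests (no dedicated transience
  statistic is defined).
* The linkage summary assumes evidence rows are already mapped to ubiquitin
  coordinates; branched/mixed-chain topology inference is out of scope.
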