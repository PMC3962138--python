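# Methods

## The quantification model

Each analyte is monitored as one SRM transition per isotopologue channel.
Quantification is ratio-based isotope dilution: in every injection the light
(¹²C, experimental) and heavy (¹³C extract or ¹⁸O spike, internal standard)
channels of a metabolite co-elute, so any multiplicative effect on peak area
that acts injection-wide or on the co-eluting pair — ionization suppression,
spray variability, injection-volume error — cancels in the area ratio. The
mol amount of the heavy standard aliquot is assigned once against a standard
series of known amounts, after which

    pmol(analyte) = A_light / A_heavy × pmol(heavy) / cf

with `cf = 1` for directly quantified metabolites and
`cf = R_target / R_surrogate` (a response-factor ratio measured in the same
standard solutions) for the two surrogate-quantified ones: IMP via the heavy
NMN peak (the extract's own IMP peak is too small) and NA via the heavy Nam
spike (NA carries no carbohydrate and no practical ¹⁸O form).

Assumptions this rests on, stated explicitly:

* detector response is linear in amount over the working range per channel;
* the co-eluting heavy isotopologue experiences the same suppression as its
  light analyte (exact for co-elution; only approximate for the surrogate
  pairs IMP/NMN at 9.65 vs 8.92 min and NA/Nam at 8.35 vs 9.82 min, where
  the factors can differ if suppression varies along the gradient);
* the heavy lot composition is identical in the assignment runs and all
  sample runs.

## Chromatographic processing

Traces are time/intensity tables per channel. Baseline noise is
1.4826 × MAD of the intensities outside ±window exclusion zones around
every expected analyte elution (a robust Gaussian-σ estimate; floor of 1
count for constant traces). Local maxima above 3 × noise (with matching
prominence, spanning ≥ 2 samples so single-sample spikes are never called)
become peaks. Peak boundaries extend from the apex to the nearer of a local
minimum and the first point below 2% of apex height. Boundaries are walked
on a 5-point moving-average copy of the trace, and a minimum only counts
once the smoothed trace has risen ≥ 3 smoothed-noise scales back above it:
on the raw trace, baseline noise both fakes minima and dips below the 2%
cutoff early, which truncates small peaks by a systematically larger
fraction than large ones and biases every downstream ratio. The area is the
trapezoidal integral of the *raw* trace between the bounds above a zero
baseline (zero-mean noise integrates to nothing), height is the raw apex,
and S/N = height / noise.

Analyte assignment is purely retention-time based: the peak whose apex is
nearest the expected RT within ±0.3 min (ties to the larger area). The
window is what makes the method immune to crosstalk, because both
interference mechanisms put signal at the *source* metabolite's retention
time: on-source fragmentation (NR and NMN shed nicotinamide in the source
and light up the Nam channel; NAR and NAMN likewise produce NA signal) and
isotopologue bleed (the ¹³C envelope of cytidine appearing one Dalton up in
the uridine channel, Nam's in the NA channel). The tightest pair on the
panel is cytidine (11.14 min) against uridine (11.50 min), 0.36 min apart,
which sets the ±0.3 min default. Capacity factors are k′ = (RT − t₀)/t₀
with a per-separation void time t₀ defaulting to 1.40 min, the value
implied by the published (RT, k′) pairs; the NADH row's printed k′ of 12 is
inconsistent with every other row's implied t₀ and is treated as a
typographical artifact.

## Calibration, LOQ, lot assignment

The standard series is 0, 0.1, 0.2, 0.6, 2, 6, 20, 60, 200 µM pre-mix;
mixed 1:1 with the internal-standard dilution and injected at 2.5 µl this
is 0.125–250 pmol on column (µM × µl = pmol). Curves are unweighted OLS of
area on pmol with free intercept over the nonzero levels (the zero standard
only informs noise). The linear range is the widest contiguous run of
levels whose back-calculated amounts deviate < 15% from nominal. LOQ is the
amount at S/N = 10, interpolated log-log between the bracketing levels
(exact for a linear detector, where S/N ∝ amount); a series entirely below
10 yields a right-censored bound at the top level.

The heavy lot is assigned from the same standards-mixed-1:1-with-lot
injections, treated as technical replicates. Within each replicate the
assignment is ratio-based — `heavy_area / light_area × light_pmol`, using
levels where the light peak reaches S/N ≥ 10 — rather than interpolating
the heavy area on the fitted curve. The two are equivalent on ideal data,
but curve interpolation inherits the fitted intercept's sensitivity to
per-injection intensity scale (an unweighted fit lets the 250 pmol level
swing the intercept by more than a small heavy peak's whole area), whereas
the within-injection ratio cancels that scale identically to the sample
calculation it feeds. Replicates without a usable light peak fall back to
curve interpolation. The ¹⁸O Nam and NR spikes are assigned the same way
against the light Nam/NR standards; their nominal 1.5 µM is ignored in
favor of the measured assignment. Correction factors average the per-level
response-factor ratio over standards where *both* analytes reach S/N ≥ 10;
below that the surrogate's area is noise-dominated and the ratio estimator
diverges.

## Sample bookkeeping and reporting

Resuspension volume is dry pellet mass / 3.6 mg × 100 µl. Extracts at
OD₂₆₀ ≥ 14 are diluted to 14 (scaling the final volume by OD/14); extracts
below 14 are left undiluted and flagged — the protocol defines only a
dilution step, so no concentration is ever applied. Intracellular volume is
cell count × per-cell volume (70 fl yeast, 2.5 pl HeLa). The analyzed
fraction is (2.5 µl injection × 0.5 mix fraction) / final volume, and the
effective intracellular volume on column is that fraction of the total;
concentration is pmol / effective volume (1 pmol per 26 nl ≈ 38.5 µM).

Reports round concentrations to two significant figures. An analyte whose
light peak misses S/N 10, or whose amount falls below the LOQ, is reported
as `<bound` with the LOQ converted through the same volume bookkeeping.
AMP is never reported: ATP and ADP fragment on-source to AMP and the three
are not resolved, so an AMP channel would mix biological and artifactual
signal. NADPH is monitored but never reported (not reliably preserved
through extraction and analysis); NADP carries a caveat that its peak may
include oxidized NADPH, and Nam a footnote that it is membrane-permeable
and easily lost to supernatants. NAD⁺:NADH (nearest integer) and NAD⁺:NADP
(one decimal) are appended as summary ratios. Replicate aggregation is left
to the caller; per-sample tables retain full precision.

## The synthetic-run generator

Peaks are Gaussians (σ = 0.05 min default) at the panel retention times on
a 0.01 min grid, area = pmol × response factor, plus zero-mean Gaussian
baseline noise (σ = 50 counts default; traces are baseline-subtracted
detector output, so small negative excursions are legitimate). Response
factors are placed so that each metabolite's LOQ under default noise lands
at its literature value — which also reproduces the qualitative sensitivity
ordering (NMN, ATP, NA and uridine least sensitive). Suppression is one
multiplicative factor per sample injection, drawn U(0.3, 1.0) and applied
to **every** channel of that injection — the sample-complexity model — with
per-metabolite overrides available; standards are clean solutions and are
simulated unsuppressed. Fragmentation crosstalk removes its fraction from
both isotopologue channels of the source (the chemistry does not
distinguish them) and deposits it in the matching target channel at the
source RT; bleed adds its fraction of the source's light signal to the
neighbor channel without depleting the source (it is the isotope envelope,
not the monoisotopic peak). Replicate structure: an independent
per-metabolite preparation factor (CV 5% default) per replicate, and a
shared per-injection intensity scale (CV 2% default). Ground truth (true
pmol on column and pre-noise area per channel) is written for every
injection. Identical seed and configuration reproduce identical bytes.

Default demo truth is a cultured mammalian line with a high-energy-charge
nucleotide profile (ATP ~1 mM down to NMN ~1.3 µM, vitamins and
biosynthetic intermediates at zero), prepared as 2×10⁷ cells of 2.5 pl at
3.6 mg dry pellet and OD₂₆₀ = 14 — an effective analyzed volume of 625 nl,
which places NMN (0.8 pmol) just below its 1 pmol LOQ and the absent
metabolites as `<bound` entries.

What the generator does **not** emulate — so what passing tests do not
show: peak tailing and shape distortion in complex matrices (peaks are
symmetric Gaussians), retention-time drift between runs, gradient-dependent
suppression that would differentiate the surrogate pairs, carryover,
detector saturation at the top of the range, and chemical instability
(NADH/NADPH oxidation during preparation). Recovery results on synthetic
data therefore validate the *bookkeeping and statistics* of the pipeline,
not the chromatography of any particular instrument.

## Numerical choices and problem sizes

Time is minutes everywhere, intensities arbitrary counts, amounts pmol,
concentrations µM. Tolerances: noise-free end-to-end identity is asserted
to 1e-9 relative with crosstalk disabled (with crosstalk enabled the
physical tail overlap of the cytidine bleed peak inside the uridine
integration window moves uridine by ~0.2%, within the ≤ 1% crosstalk-
immunity bound asserted separately). Parameter-recovery checks run 20 seeds
of the full pipeline (standards + triplicate-style sample, ~4 s total) and
assert ≤ 5% relative error for every metabolite at ≥ 10× LOQ. RSD-estimator
calibration runs 200 seeds on a three-metabolite subpanel (~12 s) and
compares the mean estimate against the designed CVs shrunk by the c₄
small-sample factor of the standard deviation (c₄ = 0.9515 at n = 6,
0.9213 at n = 4); the designed method CV combines preparation and injection
CVs in quadrature. These sizes keep the whole suite under half a minute on
one CPU while leaving the estimators' sampling error well inside the
asserted tolerances.

## Known limitations

* Surrogate correction factors are exact only while target and surrogate
  share the injection-wide suppression factor; gradient-localized
  suppression would bias IMP and NA specifically.
* Unweighted OLS calibration means the low end of the linear range is
  sensitive to top-level leverage; the lot assignment sidesteps this via
  ratios, but reported linear ranges for low-response metabolites
  (uridine, NA) start above the panel-wide 0.125 pmol.
* The ¹⁸O offsets (+2 Da per substitution) and heavy MS² fragment offsets
  are configured values, not derived from fragment structures.
* No cross-run RT alignment or co-elution deconvolution: two analytes
  closer than the RT window would need chromatographic, not computational,
  resolution.
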