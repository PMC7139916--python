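# Methods

This note records the models, conventions and numerical choices behind
maldiplex, and what its synthetic-data experiments do and do not show.

## Mass model

Peptide masses are singly protonated (MH+): MALDI produces predominantly
z = 1 ions, so higher charge states are out of scope by design.  The
residue constants live in `src/maldiplex/data/residue_masses.tsv`
(versioned, diffable): standard IUPAC monoisotopic values
(G 57.02146 … W 186.07931) and standard average values, with
water 18.010565 / 18.0153 Da and proton 1.007276 Da.  Modification
deltas (mono/avg): phospho 79.96633 / 79.9799, acetyl 42.01057 / 42.0367,
methyl 14.01565 / 14.0266, dimethyl and trimethyl as multiples
(trimethyl mono 42.04695), carbamidomethyl 57.02146 / 57.0513.

Average masses computed from any standard average table can differ from
third-party tables by a few mDa per residue (isotope-abundance
revisions); the test suite therefore validates average masses against an
independent elemental-composition oracle with a per-residue tolerance
rather than against any single published table.  Monoisotopic values are
validated to 0.001 Da.

**Labels.** Stable-isotope label schemes carry two delta sets.  The
`nominal` mode (default) uses integer shifts — K+8, R+10, V+6 — because
that is the convention in which calculated labelled masses are reported
in assay reference tables; `exact` mode uses the isotopologue deltas
(K 8.014199, R 10.008269, V 6.013809) for matching real acquisitions.
A heavy-channel variant whose sequence contains no labelable residue is
not emitted: it would be indistinguishable from the light channel.

**Fragments.** b/y ions are singly charged: bᵢ = Σ first i residues
(+ their modifications) + H⁺; yᵢ = Σ last i residues + H₂O + H⁺.  Each
series has n−1 members and bᵢ + yₙ₋ᵢ = MH+ + H⁺ exactly.

## Digestion

A protease rule is a deterministic cut-site predicate: cleavage residues,
side (C- or N-terminal) and Keil-style suppression before proline
(toggleable; the validated reference peptides are consistent with either
setting).  Chymotrypsin defaults to F/Y/W/L specificity (M optional as a
separate rule) because the published chymotryptic assay peptide requires
cleavage after leucine.  An optional flag suppresses cut sites within ±1
residue of a modified position, emulating the reduced cleavage
efficiency next to phosphosites that makes doubly phosphorylated
peptides appear mainly as missed-cleavage products; it is off by default
so digests depend only on sequence.

Missed cleavages are counted as internal cut sites of the product under
the active rule.  Published "XC" labels occasionally count differently
(nomenclature, not chemistry); epitope-covering selection makes the
difference immaterial because candidates are selected by coverage, not
by label.  The default missed-cleavage ceiling is 2 and per-assay
configurable (observed reference products span 0–4 internal sites for
the RPS6 tail).

Epitope-covering candidates are ranked (fewest missed cleavages,
shortest, lowest start): the shortest clean product is the likeliest
abundant species and the easiest to resolve.

## Assay variant spaces

A variant space is the cross product of required modifications (all-of,
or any-of for cross-reactive antibodies such as a pT37/pT46 reagent that
also binds singly phosphorylated forms), 0..max_extra variable
modifications on eligible residues (at most one modification per
position — acetyl and methyl compete for the same lysine amine),
point-mutation alleles kept alongside the wild type (heterozygosity),
and light/heavy label channels.  Duplicate masses collapse into one
record with multiplicity and the distinct compositions retained, which
is how ladder annotation can flag ambiguous assignments.  The space is
capped at 10,000 variants per assay with an explicit overflow error;
combinatorial histone-style assays should constrain eligible residues
rather than raise the cap.

Cross-assay mass collisions within the linear tolerance are reported at
panel compilation but are warnings, not errors: random-array decoding
degrades gracefully and the designer decides.

## Synthetic spectra

The generator emulates single-spot linear-mode acquisition over
750–7000 m/z on a uniform 0.05 Da grid (≥4 samples per FWHM at m/z 1500,
resolution 1000).  Each analyte is a Gaussian of FWHM = m/z ÷ resolution
at its **computed monoisotopic mass**; isotope envelopes, vendor
"interpolated monoisotopic" peak interpolation, detector saturation and
matrix cluster ions are deliberately not modelled — the matching
tolerances absorb the difference.  Background is an exponential decay
plus additive Gaussian noise (the noise floor S/N is measured against);
intensities are floored at zero as a detector would report them.  The
seed is mandatory and fully determines the spectrum.

Consequently, passing round-trip tests demonstrate that the decoding and
quantification logic is correct under the stated noise model; they do
not demonstrate robustness to isotope-envelope interference, calibration
drift or heteroscedastic detector noise in real acquisitions.

## Baseline, noise and peak picking

Baseline: morphological opening (rolling minimum then maximum, 20 Da
window) followed by a moving average, subtracted and floored at zero.
Opening avoids the ~−3σ bias a bare rolling minimum inherits from noise.

Noise: per-block robust scale with signal masking.  Points more than 5×
the global robust scale above the median are masked (with dilation) so
broad high-mass peaks do not inflate the estimate; blocks (25 Da) with
too few clean points inherit neighbouring estimates.  Because non-negative
spectra clip the lower half of the noise distribution at zero, the scale
estimator switches to the positive half-distribution (median of
positives ÷ 0.6745) when more than 20% of samples sit on the floor.

Peaks: local maxima whose **debiased height** reaches S/N ≥ 3 (default).
Height is the mean over ±FWHM/8 around the apex rather than the raw apex
sample; selecting maxima of noisy data otherwise biases heights upward
by roughly one noise unit, which corrupts weak-channel ratios.  The
window attenuates a Gaussian by <1%, identically for all peaks, so the
attenuation cancels in every ratio.  Centroids are intensity-weighted
means over ±FWHM/2 restricted to above-half-maximum samples.  Two
cleanup passes follow: split apexes within one FWHM merge to the taller,
and a weak maximum (<15% height) within two FWHM of a stronger peak is
discarded as a noise excursion on that peak's flank.

## Decoding and tolerance tiers

Linear-mode matching is two-tier: 0.25 Da strict (the quoted typical
accuracy of a calibrated instrument) plus a 0.5 Da tagged fallback,
because published observed linear masses themselves deviate up to
~0.3 Da from calculation.  Reflector mode uses 25 ppm.  Each peak goes
to the nearest reference within the window (ties: smaller |error|, then
lower assay id; error = observed − expected).  The spot is assigned to
the assay with the highest summed matched intensity — intensity-weighted
voting is this package's choice, for robustness against stray noise
peaks matching a rival assay.

## Quantification

Ratios use peak height; orientation (H:L vs L:H) is explicit metadata
because published tables mix both conventions.  A missing channel
propagates as a flagged undefined ratio, never as zero.  CV is the
sample CV (n−1 denominator).  Fold changes divide mean ratios; note that
fold changes computed from rounded ratios differ in the third digit from
those computed on unrounded intensities.  Reference-peak normalization
scales each spectrum so the reference height is 1, preserving
intra-spectrum ratios exactly.

## Calibration

Forward curves (constant heavy standard, serially diluted light spike in
background) estimate the endogenous level; reverse curves (constant
light, diluted heavy) estimate assay LOD/LOQ.  The default design is a
3-fold series from 10,000 fmol (11 levels reach ≈0.17 fmol; 12 reach
≈0.06 fmol) with an optional blank and 3 replicates.

"Identifiable" is operationalized as a matched peak within the active
tolerance at S/N ≥ 3.  LOD = lowest spiked level detected in more than
half of its replicates (≥2 of 3); LOQ additionally requires replicate
ratio CV < 30%.  LOQ ≥ LOD follows structurally because the LOQ rule
contains the LOD rule.

Curve fitting is least squares of log₁₀(mean ratio) on log₁₀(spike)
with uniform weights and a unit-slope expectation.  When the design has
a blank, its mean ratio is subtracted first (standard-addition
correction) so the endogenous plateau does not flatten the slope.
Levels with |residual| > 0.1 log₁₀ units are trimmed worst-first (≥3
levels always retained); the dynamic range is the log₁₀ span of retained
levels, and |slope − 1| > 0.2 flags the fit nonlinear.

Endogenous estimation uses the low-spike plateau: the blank (or lowest
level) seeds a first estimate E₀ = ratio × constant; levels with
spike ≤ E₀ form the plateau and each replicate contributes
ratio × constant − spike.  The top of the curve never enters, so the
estimate is invariant to high spike levels by construction.

The calibration simulator applies lognormal noise with the target CV to
the varied channel (so the injected CV *is* the measured ratio CV) and
detects a replicate when its signal exceeds 3× a configurable noise
floor (default 1 fmol-equivalent).  Experimental detection limits from
plasma digests depend on matrix effects this simulator does not model;
the package validates the *rules* (LOD/LOQ selection, plateau recovery,
slope), not any particular fmol value.

## Demo panel

The packaged demo FASTA carries the protein regions behind eight
published validated assays, with `region_start` offsets preserving
native protein numbering so sites keep their familiar names (S2448,
T37/T46, S235/S236 …).  Epitope ranges are not published; they were
chosen once so that each assay's epitope-covering peptide set equals its
published validated peptide set (e.g. the 4EBP1 C-terminal epitope
109–118 yields exactly the 0/1/2-missed-cleavage products; the RPS6
epitope extends to the C-terminus so only the two published tail
peptides qualify at ≤4 missed cleavages).  The demo simulation
experiments use published values as ground truth: Table-style H:L ratios
(1.22, 0.15, 1.73, 2.89, 0.25, 0.01, 0.33, 0.04) and a minimum channel
S/N of 20 for recovery experiments (50 for plain decoding spots), 3
replicates throughout.

Problem sizes in the standard experiments — 100 decoding spots, 8 assays
× 3 replicate quantification spots, 12-level × 3-replicate calibration
curves — were chosen as the smallest sizes at which the recovery
statistics are stable; each simulated spectrum spans the full 750–7000
m/z grid (125,001 samples).

## Known limitations

- No isotope envelopes: matching real reflector data of large peptides
  against monoisotopic references requires the envelope's monoisotopic
  peak to be resolved upstream.
- Charge states > 1, MS/MS (LIFT) simulation, and search-engine identity
  scoring are out of scope (a b/y calculator is provided instead).
- The noise model is additive and homoscedastic; dynamic-range effects
  such as detector saturation are not modelled.
- Digestion is fully specific; semi-tryptic products are not enumerated.
- Protein-level rollup across peptides and absolute copy-number
  quantification are out of scope.
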