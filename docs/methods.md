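# Methods

`kesct` simulates filter-based K-edge subtraction (KES) computed tomography at
a compact inverse-Compton X-ray source and analyses the resulting paired
scans.  This note records the models, the parameters that matter, the
numerical choices, and what the synthetic experiment does and does not show
about real data.

## Attenuation physics

All physics rests on packaged mass-attenuation tables µ/ρ(E) (cm²/g) on
15–60 keV, one TSV per material, at ≤0.25 keV spacing.  Values derive from
the standard Hubbell–Seltzer compilation: elemental anchor points are encoded
in `tools/make_attenuation_tables.py` and densified by log–log interpolation
(photoelectric cross sections are near power laws in E, so log–log segments
track the physics to well under a percent).  The iodine K edge at 33.1694 keV
is carried as a duplicated energy row — below-edge value first (6.553 cm²/g),
above-edge value second (35.82 cm²/g, a jump ratio of 5.5) — and queries
never interpolate across the pair: a query exactly at the edge returns the
below-edge branch.  Compound tables (water, air, PVP, whewellite CaC₂O₄·H₂O,
weddellite CaC₂O₄·2H₂O) are mass-fraction-weighted elemental sums evaluated
per grid point, so a hand-summed mixture reproduces them to interpolation
precision.  Two tables are approximate constructions rather than compilation
rows and are flagged as such in the generator: nitrogen (Z-scaled from
carbon; only a minor PVP constituent) and gadolinium (carried as a reference
entry only).  Soft tissue is modelled as water at ρ = 1.06 g/cm³.
Linear attenuation is µ = (µ/ρ)·ρ, reported in 1/mm.

Mixtures obey the mass-fraction rule µ/ρ(mix, E) = Σᵢ wᵢ (µ/ρ)ᵢ(E); mixture
density is always an explicit parameter, never derived.

## Source spectrum

The source emits a quasi-monochromatic beam, tunable 15–35 keV, with a quoted
bandwidth below 4.5% FWHM and flux up to 3.5×10¹⁰ ph/s (1.3×10¹⁰ ph/s during
the simulated experiment).  In the head-on approximation the backscattered
photon energy is E_X ≈ 4γ²E_L (exposed as `compton_peak_energy`; the machine
tuning is expressed directly as a peak energy since the electron and laser
energies of the experiment are not published).

The line shape is a Gaussian core at the peak energy mixed with an
exponential low-energy shoulder smoothed by the same Gaussian width (a
reversed exponentially-modified Gaussian).  Aperture-integrated
inverse-Compton spectra have exactly this character — a sharp cut-off at the
on-axis energy and a shoulder of down-shifted off-axis photons — and the
published spectrum plot shows mean < peak, ruling out a symmetric model.
Parameters:

| parameter | default | meaning |
|---|---|---|
| `peak_energy_kev` | 33.69 | spectral peak (just above the iodine K edge) |
| `fwhm_fraction` | 0.035 | Gaussian-core FWHM / peak |
| `tail_shape` | 0.55 keV | shoulder decay length |
| `mean_energy_target_kev` | 33.18 | solved constraint on the shoulder weight |
| `total_flux` | 1.3×10¹⁰ ph/s | integral of the fluence rate |

The shoulder *weight* is solved at model time (Brent's method on the
discrete-grid mean) so the spectral mean hits its target exactly.  The two
shape constants were calibrated once against the published spectral summaries
of this tuning and then frozen: with 0.035/0.55 the full model has a 4.39%
FWHM (inside the quoted <4.5% bound, which the nominal-4.5%-core variants
violate once the shoulder broadens them), and its transmission through the
nominal filter reproduces the published filtered mean energy within the
stated tolerances (see below).  The true lineshape is unpublished, so ±0.05
keV is the meaningful accuracy of any reproduction of the filtered mean.

The energy grid spans 15–60 keV at 0.025 keV — ≥20 bins across the FWHM and
fine enough to resolve the 0.59 keV mean-energy separation and the edge.

## Filtration and the above-edge survival discrepancy

The energy shift between the paired scans comes from an iodine filter with a
stated effective solid-iodine thickness of ~290 µm, modelled as pure iodine
at 4.93 g/cm³ (the real filter's PVP matrix attenuates smoothly and is
absorbed into the source calibration).  Each bin is multiplied by
exp(−µ_I(E)·t); filters therefore commute and compose multiplicatively, which
the tests assert to 1e-12.

Running the calibrated spectrum through this filter gives (computed by
`scripts/acceptance.py` and the acceptance tests): filtered mean 32.61 keV,
unfiltered–filtered separation 0.57 keV — against published values 32.59 keV
and 0.59 keV — and an above-edge intensity survival of 0.74%.  The published
survival figure of 3% is *irreconcilable* with a 290 µm solid-iodine layer
under standard attenuation data: 290 µm is 0.143 g/cm², the above-edge
optical depth is ≈5.1 (transmission 0.6%) right above the edge and nowhere
below ≈4.0 within the support of a quasi-monochromatic spectrum peaked at
33.69 keV.  A 3% average would require the above-edge spectrum to sit near
38 keV.  No single thickness reconciles all published numbers either (a
~210 µm layer reproduces 3% but not the kerma-rate ratio).  The likely origin
of the 3% figure is the finite energy resolution of the spectrometer used to
measure the plotted spectra, which smears below-edge transmitted intensity
(T ≈ 0.4) above the edge.  The package keeps the stated 290 µm and reports
the physically computed survival; the corresponding acceptance check is
expected to disagree with the published number and says so in its failure
message.

## Phantom

The synthetic object is a 2-D slice emulating the imaged preparation: a
plastic (PVP) beaker ring, a water bath, a soft-tissue kidney ellipse,
3–10 iodinated vessel discs inside the kidney and one calcium-oxalate stone
disc on the kidney surface.  Defaults: 512×512 voxels at 70 µm (matching the
effective pixel size), kidney semi-axes 11×7.5 mm, vessels 0.8–2 mm diameter,
stone 3 mm diameter — sizes of the real specimen are unpublished, so these
are config-exposed choices, not measured values.  Placement is seeded and
deterministic; primitives are hard-edged (no partial-volume blending), which
keeps the analytic projection oracles exact.

The two confusable inserts are calibrated, not nominal:

* vessel: iodine dissolved in water (volume-additive solution model), with
  the concentration solved so µ(33.18 keV) = 0.2184 1/mm — the measured
  contrast-agent attenuation; the solution lands at ≈52 mg I/ml, a plausible
  post-injection arterial concentration;
* stone: 90% whewellite / 10% weddellite, with the effective bulk density
  solved so µ(33.18 keV) = 0.2105 1/mm — the measured stone value; the
  density lands at ≈1.73 g/cm³, below the mineral value, as expected for a
  porous, organically bound concretion.

Their contrast at the unfiltered energy is 0.0079 1/mm by construction —
below the per-voxel noise of a default-dose scan — which is precisely the
clinical indistinguishability the subtraction method resolves.

## Forward model and acquisition

Rays are parallel: at 15.3 m source–sample and 16.4 m source–detector
distance the magnification varies by <0.2% over a cm-scale object, and the
detector maps onto the sample grid at the effective pixel size
74.8 µm × 15.3/16.4 = 69.78 µm ≈ 70 µm.  Line integrals use rotate-and-sum
projection on the voxel grid (scikit-image's Radon transform) scaled to
physical units; a circular field-of-view mask is applied.  The analytic disc
phantom bounds the discretization error (≲1% RMS on interior rays at the
default voxel size).

Polychromatic transmission per ray is

T = Σ_E w(E) Φ(E) exp(−∫µ(E) dl) / Σ_E w(E) Φ(E),

with detector weight w(E) ∝ E (energy-integrating scintillator; w = 1
selectable for photon counting).  The projector computes one Radon transform
per *material region* and reuses it across energy bins, making the spectral
sum exact; bins are grouped to ~0.1 keV (never across the K edge) before the
exponential, a second-order-accurate optimization over smooth µ segments
that is exact for single-bin spectra.

Noise: the expected incident photon count per pixel, N₀ = Φ·τ·A_pix/A_beam,
follows from the total flux and the stated elliptic beam extent
(62×74 mm² at the detector) — ≈888 photons/pixel per 44 ms projection at
1.3×10¹⁰ ph/s.  Detected counts are Poisson around N₀T and flat-field
normalized; repeated-draw variance matches T/N₀ within the tested 5%.

**Effective-energy default.** The default experiment acquires each scan
*monochromatically at that scan's spectral mean energy* (33.18 / 32.61 keV).
For every material whose attenuation is smooth across the band this
idealization is accurate to <0.1%; for the iodinated vessels, whose µ jumps
by a factor ≈5.5 inside the unfiltered band, the polychromatic effective µ
depends on the exact (unpublished) spectral weighting, whereas the measured
reconstruction values being calibrated against are themselves effective
values.  Anchoring the phantom at the scan mean energies therefore makes the
published µ values exact ground truth.  The full polychromatic projector
remains first-class and config-selectable (`acquisition_mode: poly`); its
distinctive physics — beam hardening along iodinated paths under the
edge-straddling spectrum, and higher filtered-beam transmission through
iodine — is property-tested.  Under the polychromatic mode the unfiltered
vessel signal drops to ≈0.14 1/mm (the band average of below- and above-edge
attenuation), which is the expected physical behaviour, not an error.

## Reconstruction

Filtered backprojection of −log T (transmissions floored at 1e-6 against
Poisson zeros) on the acquisition grid, in 1/mm.  The default filter is
Hann-apodized: the published ROI spreads (stone ±0.0151, iodine
±0.0100 1/mm) come from a regularized statistical iterative reconstruction,
and at the published dose an unapodized ramp gives ≈0.024 1/mm spreads
(noise-maximal) while Hann gives ≈0.018–0.023 — the closest standard FBP
analogue.  Plain ramp remains available and is used in the deterministic
oracle tests.  A SIRT least-squares solver (row/column-normalized
simultaneous updates, optional nonnegativity, divergence detection on the
residual norm) stands in for statistical iterative methods generally;
agreement with FBP is asserted at ROI level (3%), not voxel level.
Noiseless reconstructions recover the calibrated phantom parameters to
<0.1% at the published protocol; the 2% acceptance bound leaves room for
discretization at smaller test profiles.

## Subtraction analysis

KES iodine image: unfiltered − filtered, unscaled and signed, computed
slicewise on the intrinsically registered pair (a registration hook exists as
a no-op).  Inverse KES calcium image: c·filtered − unfiltered with
c = (Ē_unf/Ē_filt)³ ≈ 1.0553, the cubic compensating the ~E⁻³ energy
dependence of the photoelectric effect for edge-free materials.  The mean
energies enter from the scans' spectral metadata — a single source of truth —
and the ratio direction is a flag; the default (scale the filtered scan up)
is the one that produces the published qualitative behaviour: calcium
vanishes from the iodine image, iodine inverts and the stone rises above
tissue in the calcium image.

One subtlety the simulation makes explicit: plain KES does *not* cancel
calcium exactly.  With 0.59 keV between the scans, µ of the stone rises by
the smooth-material factor ≈1.05 in the filtered scan, leaving a systematic
≈−0.009 1/mm stone residual in the iodine image.  At the published dose this
sits well below the noise floor (0.65× the tissue-background standard
deviation with the default reconstruction), which is why the stone appears
eliminated — the separation claim is evaluated at that dose, noise on.  In a
noiseless ramp reconstruction the residual would be resolvable (≈3× the tiny
artifact-texture std); eliminating it exactly is what the inverse-KES cubic
correction is for.

ROI statistics are arithmetic mean and population standard deviation over
ground-truth region masks (optionally eroded to exclude partial-volume
rims).  Histogram-band segmentation selects voxels in [lo, hi] and keeps
connected components above a minimum size; on the unfiltered reconstruction
one band (default 0.19–0.23 1/mm) captures stone and vessels alike
(inseparability), on the KES volume a band over the iodine signal
(0.10–0.30 1/mm) returns vessels only.

## Dosimetry

Air kerma rate K̇ = Σ_E [Φ(E)/A]·E·(µ_en/ρ)_air(E) from a packaged mass
energy-absorption table for dry air, with the beam area from the stated
elliptic extent scaled by distance.  The model gives 0.22 mGy/s unfiltered
and 0.040 mGy/s filtered — the same order as the published 0.16/0.07 mGy/s,
whose exact beam-area and attenuation assumptions are unpublished; these
rates are documented context, not reproduction targets.  Effective dose
applies a kerma-to-effective-dose coefficient; the default 0.2587 Sv/Gy is
back-solved from the published 10.32 mGy → 2.67 mSv pair, since the
underlying kidney-tissue conversion tabulation is not reproduced here.  Note
the published rates and total are mutually inconsistent by rounding
(0.16 + 0.07 mGy/s over 44 s each is 10.12 mGy, not 10.32); the pipeline
reports unrounded values.

## Orchestration, determinism, profiles

`run_experiment` executes spectra → phantom → paired acquisition →
reconstruction → KES/inverse KES → ROI report, segmentation and dose report,
writing every artifact plus a JSON manifest with SHA-256 checksums; identical
config and seed give identical checksums (scan seeds derive as seed,
seed+1).  The default profile is the published protocol (1000 projections
over 360°, 44 ms each — 44 s per scan — 512² at 70 µm); the `desk-test`
profile (256² at 140 µm, 180 views) runs in about a second and is used where
tests only need qualitative behaviour.  Acceptance-level checks run at the
published protocol.

## What the generator does and does not emulate

Emulated: the spectral shift mechanism, calibrated attenuation levels of the
confusable materials, dose-limited Poisson noise, the published acquisition
geometry and protocol, detector energy weighting.  Not emulated: anatomical
kidney geometry, contrast-agent diffusion into tissue (only representable as
an optional low-µ halo), scatter, detector blur/MTF and ring artifacts,
sample motion, cone-beam effects, the specific statistical iterative
reconstruction, and 3-D volumes (the analysis is slicewise; a 2-D slice
carries all of the method's physics).  Passing tests therefore demonstrate
the correctness and internal consistency of the method's physics and
algebra under ideal imaging conditions — not performance on real organ data.

## Known limitations

* Attenuation anchors are encoded from the standard compilation rather than
  exported from a database at build time; nitrogen and gadolinium are
  physics-consistent approximations (both non-critical here).
* The above-edge survival of the real filter cannot be matched together with
  its stated effective thickness (see above); the package sides with the
  thickness and standard attenuation data.
* The effective-energy default trades polychromatic realism of the iodine
  channel for exact calibration anchors; polychromatic mode quantifies the
  difference.
* Air-kerma rates depend on beam-area assumptions the publication does not
  spell out; they are order-of-magnitude context.
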