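# Methods

`liverbrachy` compares two dose-calculation formalisms for interstitial
HDR ¹⁹²Ir liver brachytherapy: the clinical-standard water-kernel view
(every tissue treated as water, TG-43-style) and model-based dose
calculation on a segmented CT-like geometry (TG-186-style). The
comparison is carried by a collision-kerma Monte Carlo engine that can
score the same transport in three conventions:

* **Dw,w** — transport and scoring in water (the whole phantom replaced
  by water; the water-kernel surrogate and the comparison reference);
* **Dw,m** — transport in the segmented medium, scoring with the water
  mass energy-absorption coefficient (dose to water in medium);
* **Dm,m** — transport and scoring in the medium itself.

## Transport model

Each dwell position is an isotropic point source emitting a discrete
¹⁹²Ir line spectrum (γ lines plus Pt/Os K X-rays, 27 lines, intensity
sum ≈ 2.30 photons per decay, intensity-weighted mean 0.355 MeV; lines
below 10 keV dropped — they do not travel beyond a few mm of tissue).
Photons undergo Woodcock (delta) tracking against the energy-dependent
global majorant cross section; real collisions are photoelectric
absorption or Compton scattering on a free electron (Klein–Nishina,
sampled by rejection on the scattered-energy fraction). Rayleigh
scattering is omitted and, consistently, the bundled attenuation
coefficients are coherent-free totals, so transport and tables describe
the same physics. Secondary electrons are not transported: dose is
approximated as collision kerma under charged-particle equilibrium —
a good approximation for ¹⁹²Ir energies beyond ~1 mm from the source.
Photons below 10 keV deposit their remaining energy on the spot.

Scoring uses a track-length fluence estimator: every flight segment
(including flights that end in a virtual Woodcock collision) adds
`E · (μen/ρ)(E) · ℓ / V` to each voxel it crosses, evaluated with the
water coefficient and the voxel medium's coefficient simultaneously, so
one pass through the heterogeneous phantom yields both Dw,m and Dm,m.

**Normalisation.** The emitted-photon rate follows analytically from the
air-kerma strength: `photons/s = S_K / k̄_air`, where `k̄_air` is the air
kerma at 1 m per emitted photon summed over the spectrum. The analytic
TG-43 module is instead normalised through its dose-rate constant Λ.
Because the two normalisations share no code or constants, MC-vs-TG-43
agreement in water is a genuine two-sided physics check (observed:
within ~1% at 1–5 cm).

**Uncertainty.** Runs are split into batches (default 10) with sub-seeds
derived from the master seed by a counter scheme. The voxel-wise
standard error of the batch mean, relative to the mean, is reported per
voxel, and its maximum inside the 30%-isodose line (≥ 30% of
prescription) is the per-run summary — the same statistic used as a run
criterion in clinical-style studies (< 0.8% for Dw,w, < 1.3% for Dw,m at
production scale; the package demonstrates both thresholds on a coarse
scaled-down case, see below).

## Bundled physics data

No network access is assumed; all physics data are plain-text resources
regenerated by `scripts/build_physics_tables.py`:

* **Elemental μ/ρ and μen/ρ** (H, C, N, O, Na, Mg, P, S, Cl, Ar, K, Ca,
  Fe; 0.01–1.5 MeV, 19-point standard grid). These are an analytic
  reconstruction: incoherent scattering from the closed-form
  Klein–Nishina cross section, the Compton energy-transfer fraction from
  numerical integration, and photoelectric absorption anchored on a
  published oxygen μen/ρ table and scaled as Z^4.6/A. The build script
  verifies the reconstruction against independent published anchor
  values for hydrogen, water and dry air (≤ 0.6% above 60 keV, ≤ 2%
  above 30 keV). Accuracy degrades to ~5% for Fe and for argon below
  40 keV; neither matters dosimetrically here (Fe appears in no bundled
  tissue, and air μen only enters the source normalisation at emission
  energies). Mixture coefficients are mass-fraction-weighted sums;
  single-energy lookups are log–log interpolated with no extrapolation.
* **Tissues** (ICRU-44-style compositions): air 0.0012, lung 0.26, mean
  adipose 0.95, mean female soft 1.02, mean male soft 1.03, liver 1.06,
  cortical bone 1.92 g/cm³, plus water.
* **TG-43 fixture** for a generic ¹⁹²Ir HDR point source: Λ = 1.12
  cGy·h⁻¹·U⁻¹ (point-source consensus-style value), g(r) built from the
  classic Meisberger attenuation/buildup polynomial (0.25–10 cm), and a
  synthetic anisotropy table (`anisotropy_synthetic.csv`) whose only
  role is to exercise the 2-D code path; the point-source mode (F ≡ 1,
  G = 1/r²) is the default and the one used for MC cross-checks, which
  avoids capsule-anisotropy mismatch with the engine's bare point
  source.
* **Clinical tolerance limits**: liver V5Gy 67%, V10Gy 33%; OAR D1cc
  limits (Gy): bile duct 21, bowel 15, colon 20, duodenum 12, esophagus
  12, gall bladder 20, heart 22, stomach 12; kidney has none.

## Segmentation and geometry

HU thresholds map to tissues with half-open `[lower, upper)` bands:
air [−1024, −900), lung [−900, −199), adipose [−199, 0), soft tissue
[0, 201) (male or female variant by patient sex), cortical bone
[201, ∞). The printed clinical thresholds overlap at their endpoints;
the half-open convention resolves the ties deterministically. HU below
−1024 clamps to air and HU above 2000 is still called cortical bone,
each with a warning (the latter affects metal artefacts only).
Delineated structures override the HU segmentation: the liver mask
forces homogeneous reference liver regardless of HU, and
contrast-corrupted organ voxels can be reset to soft tissue through the
same mechanism (override masks are explicit inputs; the package does not
try to detect contrast).

In-plane CT resolution is adopted unchanged; only the slice axis is
linearly resampled to the 1 mm dose-grid spacing (first/last slice
positions preserved; binary masks threshold at 0.5). Contours rasterize
by voxel-centre inclusion with the even-odd rule, supporting holes.

## DVH conventions

"Volume receiving at least D" uses an inclusive threshold (≥). D_V is
computed by descending-dose accumulation and returns the dose of the
marginal voxel of the hottest-V subvolume, with fractional volume
bookkeeping but *no upward dose interpolation*: interpolating past the
marginal voxel's dose would break the exact inverse consistency
`v_at_dose(d_at_volume(V)) ≥ V`, which the suite asserts on scans. All
parameters are computed directly from voxel doses; binned cumulative
curves (default 0.05 Gy bins) are for reporting only. Deltas are
model-based minus water-reference values in each parameter's native
unit (% of structure volume, Gy for D1cc, % of prescription for
D95/D90); cohorts report per-parameter median/min/max. Doses are capped
at 200 Gy before analysis (clinical TPS convention).

## Synthetic cases

The generator emulates the study conditions without patient data:
prescriptions of 12/15/20/25 Gy in a single fraction; spherical CTVs
with radii 6–40 mm (≈ 0.9–270 cm³, matching the clinical spread of
<1 to ~280 cm³); straight z-axis catheters on a 20 mm lateral lattice
with dwells every 10 mm inside the CTV plus a 5 mm margin, giving <10
dwells for the smallest targets up to ~100–130 for the largest; 1–5
CTVs per case; an OAR mix led by the stomach; male:female ratio 15:3;
source strength 40 700 U (≈ 10 Ci). The HU phantom is a 96³ grid at
2 mm (resampled to 1 mm slices before transport): air background, an
elliptical soft-tissue body, a lung cap above the liver dome, the liver
ellipsoid (≈ 600 cm³), optional ribs, with per-tissue Gaussian HU noise
(lung ±50, soft ±15, liver ±10, rib ±150 HU) so segmentation is
exercised non-trivially; a noise-free mode supports exact-count tests.
Dwell times come from a non-negative least-squares fit of the analytic
point-source dose at CTV-surface sample points to the prescription,
rescaled so 90% of the surface is covered — a deliberately simple
stand-in for clinical inverse optimisation.

What the generator does **not** emulate: real CT texture and calibration
curves, contrast agent, curved catheters, respiratory motion, and
realistic OAR anatomy (OARs are spheres abutting the liver). Passing
tests therefore demonstrate the correctness of the dose-calculation
and analysis machinery under controlled conditions, not clinical
dosimetric equivalence on real patients.

## Problem sizes and numerical choices

Desk-scale runs use 10⁵–5×10⁶ histories; the bundled validation suite
sizes its experiments so each check resolves its effect well above MC
noise (e.g. the water-versus-liver medium effect is measured at 5 cm on
a full-scatter ±11 cm phantom, because scatter buildup almost fully
compensates the denser liver's attenuation at shorter range). The
MC–TG-43 cross-check compares shell averages over identical voxel sets
so discretisation bias cancels; the inverse-square oracle volume-averages
the analytic law with a per-voxel Gauss rule for the same reason.
Energy-dependent quantities are pre-resampled onto a 512-point
logarithmic grid inside the engine (interpolation error ≪ 0.1%).
Reproducibility is exact: identical phantom, plan, seed and history
count give bit-identical dose grids, and all randomness derives from
one master seed.

## Known limitations

* Point source without capsule or cable: near-field (< 5 mm) dose is
  not realistic; all comparisons are made beyond that range.
* Rayleigh scattering omitted (sub-percent effect at ¹⁹²Ir energies) and
  free-electron Compton (no binding/Doppler); both documented biases.
* Collision-kerma approximation: no electron transport, so interfaces
  sharper than the electron range (~mm) are smoothed.
* The photoelectric Z-scaling limits coefficient accuracy for Z > 20.
* The synthetic cohort's deviations are smaller than the largest
  clinical ones (its liver and dwell geometry are simpler and the
  homogeneous liver is the dominant heterogeneity), but their sign and
  volume trend reproduce the clinical finding.
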