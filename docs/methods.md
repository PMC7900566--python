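# Methods

`sodims` re-implements, as a testable pipeline, the native ion
mobility-mass spectrometry (IMS-MS) workflow used to follow the
acid/organic-induced unfolding of bovine Cu/Zn-superoxide dismutase
(SOD1): single-field collision-cross-section (CCS) calibration, charge- and
metalation-state assignment of nested drift-time x m/z spectra,
arrival-time-distribution (ATD) conformer analysis, CCS-vs-charge
unfolding profiling, and projection-approximation CCS from 3D structures.
Because the instrument data themselves are not redistributable, a forward
simulator generates frames with exact ground truth under the same drift
physics, and every stage is validated against that truth.

## Drift model and single-field calibration

A drift tube at fixed field relates an ion's arrival time to its CCS
through the Mason-Schamp equation, which at a single field collapses to a
line:

    t_A = (beta / z) * sqrt(m_i / (m_i + m_b)) * CCS + t_fix

with ion mass `m_i` (Da), drift-gas mass `m_b` (N2, 28.0134 Da average;
the monoisotopic alternative changes the reduced-mass factor by <0.02% for
these ions), charge `z`, mobility slope `beta` (ms per Å²·√(Da-ratio)/z)
and mobility-independent transit time `t_fix` (ms).  `fit_single_field`
performs unweighted ordinary least squares of measured tune-mix arrival
times on the abscissa `gamma(m)·CCS/z`, `gamma = sqrt(m/(m+m_b))`, and
reports R², residuals and per-ion back-calculated CCS errors; a fit with
R² below 0.999 (configurable) is flagged.  `drift_to_ccs` inverts the
line; an arrival time below `t_fix` implies negative mobility and returns
NaN with a warning rather than a silent negative CCS.

Calibrant identities and day-of CCS values for the original measurements
are not published, so the calibration *procedure* — not the original
line — is what is reproduced.  A packaged tune-mix reference table
(hexakis-fluoroalkoxy-phosphazene ions with standardized single-field N2
CCS values) provides a realistic calibrant set for the simulator; on real
data the calibrant table is a user-supplied CSV.

## Species hypotheses and assignment

A species hypothesis is an oligomer order n, an apo-monomer chain mass,
and a Cu/Zn stoichiometry (at most one Cu and one Zn per monomer).  Its
neutral average mass is

    M = n·M_apo + n_Cu·(63.546 − k·1.00728) + n_Zn·(65.38 − k·1.00728)

where k is the number of protons displaced per bound divalent metal.  The
displacement convention is not stated in the source measurements; the
default k = 2 (charge-neutral substitution) is the only choice under which
the observed holo masses and the printed m/z ladder are mutually
consistent, and it is configurable 0-2.  Average atomic masses are used
throughout because a ~16 kDa native protein's isotopic envelope is not
resolved; the single-isotope masses (⁶³Cu 62.9295975, ⁶⁴Zn 63.9291422 Da,
difference 0.999545 Da) enter only the metal-ambiguity check.

Peaks are matched to (species, z) hypotheses within ±1.0 Da at the
neutral-mass scale (±1.0/z in m/z).  Two flags qualify assignments:
`metal_identity_ambiguous` when another hypothesis of equal oligomer order
and metal count but different metalation lies within the mass-resolution
parameter (default 4 Da, representing broad native-TOF envelopes; Cu-only
vs Zn-only differ by 1.83 Da on average masses), and `mz_coincident` when
several hypotheses match one peak.  Charge windows are per-species
(defaults: dimer 9-13, monomers 6-16, the observed ranges).  This matters
because a dimer at charge 2z coincides *exactly* in m/z with its monomer
at z; unbounded windows would flag that coincidence at every even dimer
charge, whereas only the 12+ dimer / 6+ monomer overlap at 2,620 m/z falls
inside the observed envelopes.

Charge-ladder inference solves a strictly descending, consecutive-charge
peak list jointly for integer charges and neutral mass:
z₁ = round((p₂ − m_p)/(p₁ − p₂)) for the top adjacent pair, then
M = mean of z_i(p_i − m_p).  A per-peak mass spread above 5 Da raises an
inconsistency error with the spread reported.

m/z-coincident assignments are separated by mobility: the ATD in the
shared window is decomposed into conformer components, each component is
attributed to the hypothesis whose predicted arrival time (from its
compact-CCS prior through the calibration line) is nearest, and a
hypothesis survives only if it owns a component above 5% of the tallest.

## ATD conformer analysis

ATDs are extracted-ion mobilograms over ±1.2 x FWHM(m/z).  The trace is
smoothed with a 3-bin moving average, a constant baseline (5th percentile)
is subtracted, and local maxima with prominence ≥ 5% of the trace maximum
are conformer candidates.  The prominence default keeps the
three-conformer 11+ dimer ATD of the harshest condition intact while
rejecting noise spikes.  Apexes are refined by 3-point *log-parabolic*
(Gaussian) interpolation, which is exact for noiseless Gaussian peaks —
plain parabolic interpolation has an O(δ³/σ²) bias that would dominate
the parameter-recovery budget; a plain parabola is the fallback when a
flanking sample is non-positive.  Abundances are valley-to-valley areas
normalised to 1.  A valley whose baseline-subtracted minimum exceeds 10%
of the smaller flanking apex marks unresolved intermediate structures
("failed to return to baseline").

Peak-picking parameters of the original analysis are unpublished; the
defaults here are engineering choices validated against the simulator.

## Unfolding profile and elongation regions

Conformer tables from all conditions are assembled per species form
(holo-dimer, holo-monomer, single-metal monomer, apo-monomer).  The
compact reference of a form is the smallest CCS at its lowest observed
charge state; conformers more than 3% above it are "extended" (the 3% band
reflects that a ~1% growth of the 10+ dimer still counts as compact).
Elongation regions are found by one-dimensional single-linkage gap
clustering of the extended CCS values: sort and split where consecutive
values gap by more than 150 Å².  Gap clustering was chosen over k-means
because the bands are visually separated, and the procedure is
deterministic and parameter-light.  Condition harshness order is taken
from configuration, never inferred from the data.

Percent differences use the symmetric mean-denominator convention,
100·|a−b|/((a+b)/2), which reproduces the published platform/theory
comparison values (0.3 / 2.7 / 3.5 / 2.3 and 2.4) after 1-decimal
rounding; the denominator convention is configurable.  Two published
values are knowingly ambiguous at the printed precision: 1.0% (NMR
structure vs drift-tube dimer) recomputes to 1.05% and 0.7% (platform
comparison of the 7+ holo-monomer) to 0.63%; they are reported but not
used as checks.

The pathway summary ranks species forms by summed abundance per condition
and orders forms by first appearance (ties broken by abundance), yielding
holo-dimer → holo-monomer (+ single-metal) → apo-monomer over the three
conditions, with per-form monotone abundance trends flagged.

## Projection-approximation CCS

The projection approximation (PA) estimates CCS as the orientation-average
of the projected area of the union of atom spheres (atom radius + probe
radius).  For each uniformly random rotation (quaternion sampling; the
rotation stream and the sampling stream are spawned separately from the
seed, so the grid oracle at the same seed uses identical rotations) atom
centres are projected onto a plane and the union-of-disks area is
estimated by uniform Monte-Carlo sampling over the projected bounding box;
the reported `sd` is the standard error over orientations.  Defaults: PA
radii C 1.70, N 1.55, O 1.52, S 1.80, P 1.80, H 1.20, Cu/Zn 1.40 Å
(editable CSV), probe radius 1.0 Å, 32 orientations x 4,000 samples
(64 x 8,000 in the CLI).  A deterministic grid-rasterisation oracle with
the same geometric definition is used in tests only.

PA systematically underestimates trajectory-method (TJM) CCS for
proteins; `tjm_from_pa` applies a calibrated power law, default
`1.14 · PA^1.0`, the linear protein-regime inflation used by fast PA
tools.  This is a scaling, not an all-atom trajectory computation: no
Lennard-Jones or ion-quadrupole potentials are evaluated, and no
charge-state dependence is modelled.  Because the probe radius and radii
table dominate absolute accuracy, both are surfaced in configuration and
recorded in the provenance block of every estimate, and agreement with
published structure CCS values should be read with a ±5% allowance.
Multi-model NMR entries default to the first model with an option to
average per-model PA over the ensemble.

## The synthetic-data generator

The generator is first-class code, not a fixture: it forward-simulates
2D frames (0.1 ms x 1 Th grid) from an instrument truth
(beta = 0.15 ms/(Å²·√(Da-ratio)/z), t_fix = 0.5 ms chosen so arrival
times fall in ~17-53 ms, typical of the standardized single-field method;
these are configuration values, not physics claims).  Peaks are separable
Gaussians: m/z FWHM = m/500 (broad native-TOF envelopes subsume the
unresolved isotopic structure), drift FWHM = 3% of arrival time
(resolving power ~50).  Unresolved intermediates are emulated by a
valley-fill plateau applied as a pointwise maximum between adjacent
conformers of a charge state, which raises the valley without perturbing
the flanking peak shapes or creating spurious local maxima.  Additive
Gaussian noise is seeded and scaled per m/z column (sd = fraction x
column maximum), so "2% noise" means a per-bin noise amplitude of 2% of
each peak's apex; signal-free regions stay clean, and no Poisson option
exists in this version.

The three condition presets mirror the observed species content: native
(30 mM ammonium acetate) — holo-dimer 10+-12+ with a small 6+-8+
holo-monomer and the 2,620 m/z coincidence; intermediate (30% ACN +
100 µM FA) — extended 11+ dimer, holo-monomer to higher charges with
filled valleys, single-metal monomer; harsh (30% ACN + 25 mM FA) —
apo-monomer 7+-16+ dominant, three-conformer 11+ dimer.  All conformer
CCS values that were measured are configured verbatim (2,693.5; 2,716;
2,735/3,237/3,556; 2,743; 1,653; 1,656/2,105; 1,670; 1,697; 1,711;
1,767/2,267; 3,608 Å²).  Unreported values — the 12+ dimer and the
high-charge monomer ladder — were fixed once as smooth interpolations
consistent with the four observed monomer elongation bands, with
consecutive in-band values < 150 Å² apart and between-band gaps > 270 Å².
The apo-monomer chain mass (15,588.5 Da) was chosen so the k = 2 holo
masses reproduce the printed m/z ladder; it agrees with the bovine SOD1
chain mass to ~2 Da.

What the simulator does *not* emulate: isotopic fine structure, salt
adducts, Poisson counting statistics, drift-time peak-shape physics
(diffusion broadening is folded into the fixed relative FWHM), ESI
charging mechanisms, and detector saturation.  Passing tests therefore
demonstrate correctness of the analysis chain under the stated peak-shape
and noise model, not robustness to every artifact of real spectra.

## Numerical choices and problem sizes

- Apex interpolation: log-parabolic, exact on noiseless Gaussians; the
  clip of the sub-bin shift to ±0.5 bins guards against degenerate
  triples.
- Mass-spectrum peaks: marginal over drift, candidates by prominence
  (0.4% of maximum), apexes refined by Gaussian least squares on a
  ±2.5σ window truncated at the flanking valleys so close neighbours
  (e.g. holo vs single-metal monomer at 14+, 4.5 Th apart) cannot bias
  the fit.  The refinement is what holds the ±1 Da matching tolerance at
  dimer charges under noise, where the summed marginal's noise is ~25x a
  single bin's.
- Duplicate profile rows (same condition/form/charge, CCS within 0.1%)
  merge with abundance-weighted means and a warning.
- Default analysis sizes: frames of 601 x 2,401 bins; stochastic checks
  use 200 seeds (calibration-bias) and 50 seeds (noisy end-to-end), and
  the PA estimator uses up to 128 orientations x 20,000 samples in tests —
  sizes at which every stochastic tolerance has ≥3x headroom while a full
  test run stays in a few minutes.

## Known limitations

- The TJM scaling is a one-parameter calibration; absolute structure CCS
  accuracy inherits the radii/probe ambiguity (±5%).
- The ATD decomposition is peak-picking plus valley integration, not a
  multi-Gaussian global fit; strongly overlapped conformers (< ~1.5 FWHM
  apart) merge.
- Charge inference assumes protonation-only positive mode; metal charges
  are carried in the species mass, never as adducts.
- TIMS values are consumed as reported numbers only; no trapping physics
  is modelled.
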