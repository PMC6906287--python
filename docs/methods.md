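# Methods

This note documents the models implemented in `poretrace`, the defaults and
their rationale, what the synthetic generator does and does not emulate,
and the numerical choices that matter.

## Transport model

Dye efflux through a membrane-spanning channel is treated as quasi-static
hindered diffusion along a cylinder connecting the vesicle lumen (volume
`V = π d³/6`) to an infinite bath:

    k = H(λ) · π r_eff² · D / (L · V)          [1/s]

* `D = k_B T / (6π η R_h)` — Stokes–Einstein free diffusion of the cargo
  (defaults T = 298 K, η = 1 mPa·s; all lengths nm, times s).
* `r_eff = max(0, r − α_plug R_plug)` — the open lumen radius; a PEG-20k
  plug (R_h ≈ 4.9 nm) with flexibility α_plug = 0.5 narrows the default
  4.8 nm lumen to 2.35 nm.
* `λ = α R_h / r_eff` — relative cargo size.  Rigid small dyes carry
  α = 1; flexible dextran/PEG coils carry α = 0.5, because a polymer coil's
  hydrodynamic radius overstates the cross-section it needs to thread a
  channel.  With these defaults the gating table is: SRB passes the open
  and plugged pore; dFITC-40k (R_h 4.8 nm) is hindered by the open pore
  (λ = 0.5) and blocked by the plug (λ ≥ 1); dFITC-500k (R_h 15.9 nm) is
  always blocked.  The pass/hindered boundary is λ = 0.25 (config-exposed).
* `H(λ) = (1−λ)² (1 − 2.104λ + 2.09λ³ − 0.95λ⁵)` — the Renkin centerline
  hindrance polynomial, clamped to [0, 1], zero for λ ≥ 1.
* Geometry defaults: lumen radius 4.8 nm, channel length 32 nm.
* A `hagen_poiseuille` mode scales the open-pore conductance by
  `(r_eff/r)⁴` for pressure-driven comparisons only; efflux from an
  isotonic vesicle is diffusion-dominated, so the Fick form is the default.
* Access-resistance end corrections are omitted: sub-dominant for L ≫ r.

Efflux is first order, `N(t) = N₀ e^{−k(t−t_ins)}` after the insertion
time; influx relaxes toward the reservoir equilibrium with the same rate.

**Photophysics.**  Intensity per species is
`I = b·N / (1 + C/C₅₀)` (hyperbolic self-quenching in the lumen
concentration `C = N/V`; `C₅₀ = ∞` disables it).  A FRET donor is further
scaled by `1 − E₀·C_acc/(C_acc + C_half)`, so the donor de-quenches as its
acceptor effluxes — reproducing the two-dye sensing signature (acceptor
decay with simultaneous donor rise).  The assay reports de-quenching only
qualitatively, so `C₅₀`, `E₀` and `C_half` are free parameters with
order-of-magnitude defaults.

**Flow rate k_f.**  k_f is defined as the initial time derivative of the
*raw* (background-corrected) dye intensity, in counts/s.  Because the
encapsulated dye count scales with V while the rate constant scales with
1/V, `k_f = k·I₀` is independent of vesicle size for a rigid,
mechano-insensitive pore — which is why the flow-rate population of such a
pore shows no 70 nm size split while a mechanosensitive pore does.

## Synthetic generator

The generator emulates the study conditions of the single-vesicle assay:

* **Vesicles** — diameters i.i.d. log-normal (default median at the 200 nm
  extrusion size, σ = 0.35); ≈300 per 512×512 field; dye load proportional
  to volume at a fixed concentration (default 3×10⁻⁵ molecules/nm³,
  ≈50 µM; the narrow-pore-control experiment uses 6×10⁻⁴ ≈ 1 mM so that
  even 70 nm vesicles carry ≥100 molecules and count discreteness is
  negligible); positions uniform with a minimum separation.
* **Docking** — exponential lag per vesicle, right-censored at the end of
  acquisition, after an optional flow dead time.  The lipidated-pore
  scenarios use the fitted 1450 s mean; the NL+ scenario's rate is set so
  17% of vesicles dock within 8 h; NL− does not dock at all.
* **Insertion** — Bernoulli with logistic size preference
  `p(d) = p_max / (1 + e^{−(d−d₅₀)/s})` (d₅₀ = 120 nm, s = 30 nm: a mild
  preference for larger, flatter vesicles).  L+ vs L− differ only in
  `p_max` (0.55 vs 0.25), encoding the observed 2.2-fold contrast in
  insertion events.
* **Reorientation τ₂** — Gamma(shape 2, scale 300 s) with the scale
  stretched by `d/d_ref`, so high-curvature (small) vesicles reorient
  faster.  The gamma form is a modeling choice: positive support and a
  flexible, non-exponential shape for a multi-step process.
* **Transport rates** — from the pore model, times an *empirical hindrance*
  factor (default 8×10⁻⁴) that maps the ideal free-diffusion prediction
  onto the experimentally observed flux regime (cargo–wall and
  cargo–bilayer interactions slow transport by orders of magnitude; at the
  default it gives k ≈ 0.09 /s for the small dye in a 200 nm vesicle,
  matching the observed ~0.098 /s mean on unit-normalized traces), times a
  per-pore log-normal variability (CV 0.3, for stoichiometry and insertion
  geometry), times the mechano factor below.
* **Mechanosensitivity** — `k → k · max(0.1, 1 + β(d−d_ref)/d_ref)`.
  β = 0 for the rigid double-layer DNA pore.  The protein-pore control uses
  β ≈ 2.29, derived in closed form (truncated log-normal side means) so
  that the expected flow-rate ratio across a 70 nm split of its default
  population (log-normal median 70 nm, σ 0.35) equals the observed
  0.053/0.014 ≈ 3.8.  The 0.1 floor is ignored in that derivation, so the
  realized ratio on finite samples sits around 3–3.6.
* **Acquisition** — the sequential multi-field schedule: each cycle visits
  `n_fov` positions and exposes `n_channels` for `exposure` each, then
  moves for `change_time`; cycle period `n_fov(n_ch·t_exp + t_chg)`.  The
  canonical two-color setting (4 fields, 100 ms, 500 ms) gives 2.8 s.  For
  the three-color six-position setting the same arithmetic gives 4.8 s;
  the scheduler implements the arithmetic.
* **Traces and movies** — intensities from the transport + photophysics
  model on the frame clock; the pore channel is a step of 400 counts at
  dock time.  Movies render each particle as a pixel-integrated 2-D
  Gaussian (σ 1.2 px) of total flux equal to the trace value, offset by
  cumulative stage drift, over a constant background (100 counts) with
  Poisson shot noise and Gaussian read noise (σ 2) — an EMCCD-like but
  deliberately simple camera model.

Not emulated: evanescent-field depth profiles, polarization, aberrations,
multilamellar vesicles, photobleaching (off by default, available as an
exponential term), multi-pore vesicles.  Passing recovery tests therefore
demonstrates correctness of the inverse pipeline under this generative
model, not robustness to every optical artifact of real data.

## Inverse pipeline

* **Detection** — scale-normalized LoG response; threshold
  `median + k·1.4826·MAD` (k = 5) because the assay states no absolute
  threshold; minimum separation 2σ (brightest wins); subpixel refinement by
  intensity-weighted centroid in a (2⌈2σ⌉+1)² window.
* **Linking** — per-frame-pair LAP on squared displacement with
  birth/death cost `max_disp²` (solved exactly via the augmented-matrix
  assignment; the completion block is zero-cost), then a gap-closing
  assignment between track ends and starts within `max_gap` frames.
* **Drift** — mean displacement over all tracks present in consecutive
  frames; pairs spanned by no track inherit the previous value and are
  flagged.  Correction embeds each frame in a canvas 25 px larger per side
  (512 → 562) and applies the rounded negative cumulative drift; integer
  shifts preserve photometry exactly.  Sub-pixel interpolation is
  deliberately not the default.
* **Trace extraction** — aperture-disk sum minus annulus median × aperture
  area, per channel on the schedule's frame clock.  In movie analysis,
  anchors are localized on the raw first frame (cumulative drift is zero
  there by construction) because vesicles are tethered from the start and
  perforated ones go dark later; tracks shorter than one tenth of the
  movie are excluded from drift estimation as noise-born.
* **Docking τ₁** — first frame above `baseline mean + kσ·SD` (k = 5,
  baseline 10 frames) sustained for ≥3 frames.
* **Efflux onset** — exhaustive two-phase changepoint search after τ₁:
  constant plateau then decay, the decay fitted both as a line and as an
  exponential toward a baseline (default 0).  The exponential fit is a
  y²-weighted log-linear least squares — the weighting makes the log-space
  fit equivalent to least squares under additive intensity noise, so
  near-zero tail samples cannot drag the fit.  The changepoint minimizes
  the total RSS, ties to the earliest frame.  Events are rejected when the
  fractional drop is < 30% or (leaky-influx rule) when the decay constant
  exceeds 10× the median decay over accepted events; the median is a
  population quantity, so the rule is applied by the pipeline after all
  events are fitted.
* **Flow rate** — over the window from onset until the intensity first
  falls below 50% of the plateau, the better-fitting of the line and the
  exponential provides the *initial* derivative: |slope| for the line,
  `k̂·Î(onset)` for the exponential.  A raw least-squares line over a
  half-decay window of an exponential underestimates the initial derivative
  by ~28% (closed-form integral), which is why the model-based initial
  derivative is the default; `method="line"` gives the raw slope.
* **Diameter** — `d = d_ref (I/I_ref)^{1/3}` with the calibration anchored
  at the population median intensity mapped to the nominal extrusion size.
  How per-vesicle diameters were assigned in the original assay is not
  stated; the cube-root law is this package's convention for
  volume-encapsulated dye.

## Statistics

* **Docking lag** — censored-exponential MLE,
  mean = (Σ observed + Σ censored)/(# uncensored); CI by the normal
  approximation on the log-mean (SD 1/√d for d uncensored events).
* **Flow rate** — unbinned moments with a Student-t interval for the mean
  (equivalent to the Gaussian MLE on samples); no histogram fitting, so the
  result is bin-free and deterministic.
* **KS test** — exact ECDF supremum D; p from the asymptotic Kolmogorov
  distribution at `√n_e · D`, `n_e = n_a n_b/(n_a+n_b)`.  A brute-force
  ECDF maximization serves as the test oracle.  At the assay's per-side
  sample sizes (~100+) the asymptotic p is calibrated to the nominal level
  within Monte-Carlo error.
* **Insertion probability by size** — per-bin Wilson 95% intervals;
  zero-docked bins flagged rather than dropped.
* **Group comparison** — Welch (unequal-variance) two-sample t-test on
  per-replicate fractions, SEM error bars; identical zero-variance groups
  report t = 0, p = 1.

## Validation experiment sizes

The recovery experiments (in `poretrace.experiments`, shared by the test
suite and `scripts/acceptance.py`) use these problem sizes, chosen to make
Monte-Carlo error comfortably smaller than the asserted tolerances while
keeping each experiment in the seconds range: docking-lag recovery at 500
vesicles with ~20% censoring; flow-rate recovery over 200 traces with CI
coverage over 200 replicates; mechanosensitivity power at 400 vesicles
(≥60 events per side) and type-I calibration over 200 replicates of 300
vesicles; detection/drift on rendered 128 px fields (40 and 25 spots);
linking vs brute force on 40 random ≤4-particle fixtures; scenario
contrast at 4 replicates × 175 vesicles per arm; transport closed form vs
ODE on 100 random parameter draws.  End-to-end movie tests use a 128 px,
25–30-vesicle field with a compressed event clock (docking mean tens of
seconds) so whole movies stay small; the compression is an override of the
scenario parameters, not a change to their defaults.

## Known limitations

* The transport calibration (`empirical_hindrance`) is a single scalar; it
  does not model cargo-specific wall interactions beyond the Renkin term.
* Onset detection assumes one insertion per vesicle; multi-pore events
  bias k_f upward.
* Integer-shift drift correction leaves ≤0.5 px residual jitter, visible
  in per-frame photometry at high SNR.
* The movie analysis path assumes the pore and dye channels are
  co-registered; channel-to-channel mapping is not implemented.
* The mechano factor is linear in relative diameter with a hard floor;
  it is a phenomenological stand-in, not a tension model.
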