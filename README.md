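# poretrace

Single-particle TIRF analysis of nanopore-mediated dye transport on
surface-tethered liposomes — with a fully ground-truthed synthetic
experiment generator, so every stage of the analysis can be validated by
parameter recovery without any experimental data.

## The problem

In the single-vesicle efflux assay, small unilamellar vesicles (SUVs)
loaded with a self-quenching dye are tethered to a passivated coverslip and
imaged by TIRF microscopy while fluorescently labeled membrane-spanning
nanopores (DNA-origami channels or α-hemolysin) are flowed over them.  Each
vesicle reports three kinetic descriptors:

* **τ₁** — the docking lag, from the start of pore flow to stable
  pore–vesicle colocalization (exponential across the population, mean
  `⟨τ₁⟩`);
* **τ₂** — the reorientation time, from docking to membrane insertion
  (onset of dye efflux);
* **k_f** — the flow rate, the initial time derivative `|dI/dt|` of the
  vesicle's dye intensity after insertion.

Transport through the channel is modeled as hindered diffusion through a
cylinder of lumen radius *r* and length *L* out of a vesicle of volume *V*:

    k = H(λ) · π r_eff² · D / (L · V),    λ = α·R_h / r_eff

with `D = k_B T / (6π η R_h)` (Stokes–Einstein), `H(λ)` the Renkin
centerline hindrance polynomial, `r_eff` the lumen radius reduced by a
PEG plug when present, and `α ≤ 1` discounting the translocation
cross-section of flexible polymer cargo.  This single expression yields the
assay's size-selectivity table (small dyes pass, mid-size dextrans are
hindered or stopped by the plug, large dextrans never fit), efflux/influx
time courses `N(t) = N₀ e^{-k(t-t_ins)}`, and — through self-quenching and
FRET de-quenching photophysics — the two-dye sensing signatures.

Population inference follows the assay's reporting conventions: a
censored-exponential MLE for `⟨τ₁⟩` (mean = total observed time / number of
uncensored events), an unbinned Gaussian fit with a *t*-interval for the
mean flow rate, a two-sample Kolmogorov–Smirnov test on flow rates split at
a 70 nm diameter cutoff (mechanosensitivity), Wilson intervals for
P(insert | dock) versus vesicle size, and Welch *t*-tests on per-replicate
docked/perforated fractions across deployment scenarios.

The imaging inverse stack mirrors standard single-particle practice:
Laplacian-of-Gaussian spot detection with subpixel centroids, linear
assignment problem (LAP) frame linking with gap closing, stage-drift
estimation from the mean per-frame-pair displacement of all tracks,
integer-shift drift correction on an enlarged canvas (512 → 562 px), and
aperture-minus-annulus background-corrected trace extraction.

## Worked example

`examples/event_kinetics.py` synthesizes one noisy docking step and one
efflux trace on the 2.8 s two-color frame clock and recovers the
descriptors:

```
tau1  =   120.4 s   (true 120.0)
onset =   257.6 s   (true 260.0, model exponential)
tau2  =   137.2 s   (true 140.0)
k_f   =    23.6 counts/s (true k*I0 = 24.0)
d_m   =   200.1 nm  (calibration anchor 200 nm)
```

τ₁ is found as the first sustained 5σ excursion of the pore-channel trace,
the efflux onset by exhaustive two-phase changepoint fitting of the dye
trace, k_f as the fitted initial derivative over the window down to 50% of
the plateau, and the diameter from the cube-root intensity law
`d = d_ref (I/I_ref)^{1/3}` for volume-encapsulated dye.

The other examples cover the transport model (`transport_model.py`), the
generator (`simulate_experiment.py`), the imaging stack
(`track_and_extract.py`), population statistics
(`population_statistics.py`) and a full file-based run
(`end_to_end_run.py`).  The same pipeline is exposed as a CLI:

```bash
poretrace simulate   --config run.yaml --seed 1 --out out/sim
poretrace analyze    --config run.yaml --movie out/sim/movie.tif \
                     --schedule out/sim/schedule.json --out out/ana
poretrace report     --events out/ana/events.csv \
                     --summary out/ana/summary.json --out out/rep
poretrace end-to-end --config run.yaml --seed 1 --out out
```

Every run writes a manifest (config, seed, versions, output checksums);
reruns with the same config and seed are bit-identical.

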