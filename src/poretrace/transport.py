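"""Deterministic biophysics of dye transport through a membrane-spanning channel.

The model treats the nanopore as a cylindrical channel of lumen radius ``r``
and length ``L`` connecting the vesicle interior (volume ``V``) to an
effectively infinite external bath.  Efflux of an encapsulated dye is
diffusion-limited: the first-order rate constant is

    k = H(lambda) * pi * r_eff**2 * D / (L * V)

where ``D`` is the cargo's free diffusion coefficient (Stokes-Einstein),
``r_eff`` is the lumen radius reduced by any plug occupying the channel,
``lambda = alpha * R_h / r_eff`` is the cargo-to-pore size ratio (``alpha``
discounts the translocation cross-section of flexible polymers), and
``H(lambda)`` is the Renkin centerline hindrance polynomial.  A
``hagen_poiseuille`` mode is available for pressure-driven comparisons; it
scales the open-pore conductance by ``(r_eff / r)**4``.

All lengths are nm, times s, temperatures K, viscosities Pa*s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "BOLTZMANN_J_PER_K",
    "PoreGeometry",
    "CargoSpecies",
    "Vesicle",
    "stokes_einstein_diffusion",
    "hindrance_factor",
    "transport_rate_constant",
    "dye_count_timecourse",
    "fluorescence_from_counts",
    "classify_translocation",
    "DEFAULT_PORE",
    "DEFAULT_PLUGGED_PORE",
    "SRB",
    "DFITC_40K",
    "DFITC_500K",
]

BOLTZMANN_J_PER_K = 1.380649e-23

#: lambda above which translocation is labelled "hindered" (below it, "pass")
HINDERED_LAMBDA = 0.25


@dataclass(frozen=True)
class PoreGeometry:
    """Cylindrical channel geometry, optionally carrying a central plug.

    ``plug_radius`` is the hydrodynamic radius of the plug polymer (0 for an
    open channel); ``plug_flexibility`` discounts how much of that radius
    actually obstructs the lumen.  The effective open radius is
    ``max(0, lumen_radius - plug_flexibility * plug_radius)``.
    """

    lumen_radius: float
    channel_length: float
    plug_radius: float = 0.0
    plug_flexibility: float = 0.5

    def __post_init__(self) -> None:
        if self.lumen_radius <= 0:
            raise ValueError("lumen_radius must be positive")
        if self.channel_length <= 0:
            raise ValueError("channel_length must be positive")
        if self.plug_radius < 0:
            raise ValueError("plug_radius must be non-negative")
        if not 0 < self.plug_flexibility <= 1:
            raise ValueError("plug_flexibility must be in (0, 1]")

    @property
    def effective_radius(self) -> float:
        r_eff = self.lumen_radius - self.plug_flexibility * self.plug_radius
        return max(0.0, r_eff)

    def unplugged(self) -> "PoreGeometry":
        """The same channel with the plug removed."""
        return PoreGeometry(self.lumen_radius, self.channel_length, 0.0,
                            self.plug_flexibility)


@dataclass(frozen=True)
class CargoSpecies:
    """A diffusing cargo (dye or dye-polymer conjugate).

    ``flexibility`` is 1 for rigid small dyes and < 1 for flexible polymers
    (dextrans, PEG) whose coil radius overstates their translocation
    cross-section.  ``brightness`` is detector counts per molecule per 100 ms
    exposure.  ``self_quench_c50`` (molecules/nm^3) is the concentration at
    which self-quenching halves the per-molecule emission; ``inf`` disables
    it.  A species may be the FRET donor of another (``fret_donor_of``), its
    emission suppressed by depth ``fret_depth`` while the acceptor is
    concentrated, so the donor de-quenches as the acceptor effluxes.
    """

    name: str
    hydrodynamic_radius: float
    flexibility: float = 1.0
    free_diffusion: Optional[float] = None  # nm^2/s; derived if None
    brightness: float = 1.0
    self_quench_c50: float = math.inf
    fret_donor_of: Optional[str] = None
    fret_depth: float = 0.0

    def __post_init__(self) -> None:
        if self.hydrodynamic_radius <= 0:
            raise ValueError("hydrodynamic_radius must be positive")
        if not 0 < self.flexibility <= 1:
            raise ValueError("flexibility must be in (0, 1]")
        if self.free_diffusion is not None and self.free_diffusion <= 0:
            raise ValueError("free_diffusion must be positive when set")
        if not 0 <= self.fret_depth <= 1:
            raise ValueError("fret_depth must be in [0, 1]")

    def diffusion(self, temperature: float = 298.0,
                  viscosity: float = 1.0e-3) -> float:
        """Free diffusion coefficient in nm^2/s (given or Stokes-Einstein)."""
        if self.free_diffusion is not None:
            return self.free_diffusion
        return stokes_einstein_diffusion(self.hydrodynamic_radius,
                                         temperature, viscosity)


@dataclass
class Vesicle:
    """A surface-tethered unilamellar vesicle with encapsulated dye.

    ``content`` maps species name to the initial encapsulated molecule count.
    Volume is the sphere volume pi*d^3/6 of the membrane diameter ``diameter``.
    ``position`` is (x, y) in pixels on the rendered field of view.
    """

    id: int
    diameter: float
    content: dict = field(default_factory=dict)
    position: tuple = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("diameter must be positive")
        if any(n < 0 for n in self.content.values()):
            raise ValueError("initial molecule counts must be non-negative")

    @property
    def volume(self) -> float:
        """Enclosed volume in nm^3."""
        return math.pi * self.diameter ** 3 / 6.0


def stokes_einstein_diffusion(hydrodynamic_radius: float, temperature: float,
                              viscosity: float) -> float:
    """Stokes-Einstein diffusion coefficient ``D = kT / (6 pi eta R_h)``.

    Parameters are R_h in nm, T in K, eta in Pa*s; the result is in nm^2/s.
    """
    if hydrodynamic_radius <= 0 or temperature <= 0 or viscosity <= 0:
        raise ValueError("R_h, temperature and viscosity must all be positive")
    r_m = hydrodynamic_radius * 1e-9
    d_m2 = BOLTZMANN_J_PER_K * temperature / (6.0 * math.pi * viscosity * r_m)
    return d_m2 * 1e18


def hindrance_factor(lam: float) -> float:
    """Renkin centerline hindrance for a sphere of relative size ``lam``.

    ``H = (1 - lam)^2 (1 - 2.104 lam + 2.09 lam^3 - 0.95 lam^5)``, clamped to
    [0, 1]; H(0) = 1 and H = 0 for lam >= 1.
    """
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    if lam >= 1.0:
        return 0.0
    partition = (1.0 - lam) ** 2
    drag = 1.0 - 2.104 * lam + 2.09 * lam ** 3 - 0.95 * lam ** 5
    return float(min(1.0, max(0.0, partition * drag)))


def transport_rate_constant(pore: PoreGeometry, cargo: CargoSpecies,
                            vesicle: Vesicle,
                            mode: Literal["diffusive", "hagen_poiseuille"] = "diffusive",
                            temperature: float = 298.0,
                            viscosity: float = 1.0e-3) -> float:
    """First-order rate constant (1/s) for cargo passage through the pore.

    Diffusive mode: ``k = H(lambda) * pi * r_eff^2 * D / (L * V)``.
    Hagen-Poiseuille mode scales the open-pore conductance by
    ``(r_eff / r)^4`` for pressure-driven comparison only.
    Returns 0 when the cargo's effective radius fills the channel.
    """
    if mode not in ("diffusive", "hagen_poiseuille"):
        raise ValueError(f"unknown transport mode: {mode!r}")
    volume = vesicle.volume
    if volume <= 0:
        raise ValueError("vesicle volume must be positive")
    r_eff = pore.effective_radius
    if r_eff <= 0:
        return 0.0
    lam = cargo.flexibility * cargo.hydrodynamic_radius / r_eff
    if lam >= 1.0:
        return 0.0
    diffusion = cargo.diffusion(temperature, viscosity)
    conductance = hindrance_factor(lam) * math.pi * r_eff ** 2 * diffusion \
        / pore.channel_length
    if mode == "hagen_poiseuille":
        conductance *= (r_eff / pore.lumen_radius) ** 4
    return conductance / volume


def dye_count_timecourse(vesicle: Vesicle, k: float, insertion_time: float,
                         t_grid: Sequence[float],
                         direction: Literal["efflux", "influx"] = "efflux",
                         species: Optional[str] = None,
                         reservoir: Optional[float] = None) -> np.ndarray:
    """Encapsulated molecule count over time for first-order transport.

    Efflux: N(t) = N0 for t < t_ins, then N0 * exp(-k (t - t_ins)).
    Influx: N(t) rises as N_eq * (1 - exp(-k (t - t_ins))) toward the
    reservoir equilibrium count ``reservoir`` (required for influx).
    """
    if k < 0:
        raise ValueError("rate constant must be non-negative")
    t = np.asarray(t_grid, dtype=float)
    if t.size > 1 and np.any(np.diff(t) < 0):
        raise ValueError("t_grid must be non-decreasing")
    if direction == "efflux":
        if species is None:
            if len(vesicle.content) != 1:
                raise ValueError("species must be named for multi-dye vesicles")
            species = next(iter(vesicle.content))
        n0 = float(vesicle.content[species])
        out = np.full_like(t, n0)
        after = t >= insertion_time
        out[after] = n0 * np.exp(-k * (t[after] - insertion_time))
        return out
    if direction == "influx":
        if reservoir is None:
            raise ValueError("influx requires a reservoir equilibrium count")
        out = np.zeros_like(t)
        after = t >= insertion_time
        out[after] = reservoir * (1.0 - np.exp(-k * (t[after] - insertion_time)))
        return out
    raise ValueError(f"unknown direction: {direction!r}")


def fluorescence_from_counts(content: Mapping[str, float], vesicle: Vesicle,
                             species_table: Mapping[str, CargoSpecies],
                             fret_c_half: float = 1.0e-6) -> dict:
    """Per-species fluorescence intensity (counts) from molecule counts.

    Self-quenching is hyperbolic in concentration C = N/V:
    ``I = brightness * N / (1 + C / C50)``.  A FRET donor's intensity is
    further scaled by ``1 - E0 * C_acc / (C_acc + fret_c_half)`` so the donor
    brightens (de-quenches) as its acceptor leaves the vesicle.
    """
    volume = vesicle.volume
    intensities: dict = {}
    for name, count in content.items():
        if count < 0:
            raise ValueError("molecule counts must be non-negative")
        if name not in species_table:
            raise KeyError(f"species {name!r} missing from species table")
        spec = species_table[name]
        conc = count / volume
        intensity = spec.brightness * count
        if math.isfinite(spec.self_quench_c50):
            intensity /= 1.0 + conc / spec.self_quench_c50
        if spec.fret_donor_of is not None and spec.fret_depth > 0:
            acc_count = content.get(spec.fret_donor_of, 0.0)
            c_acc = acc_count / volume
            intensity *= 1.0 - spec.fret_depth * c_acc / (c_acc + fret_c_half)
        intensities[name] = max(0.0, intensity)
    return intensities


def classify_translocation(pore: PoreGeometry, cargo: CargoSpecies,
                           hindered_lambda: float = HINDERED_LAMBDA) -> str:
    """Label cargo passage through a pore: ``pass``, ``hindered`` or ``blocked``.

    ``blocked`` when the cargo's effective radius fills the channel
    (lambda >= 1); ``hindered`` when lambda is above ``hindered_lambda`` but
    below 1 (slower flux, as for mid-size dextrans); ``pass`` otherwise.
    """
    r_eff = pore.effective_radius
    if r_eff <= 0:
        return "blocked"
    lam = cargo.flexibility * cargo.hydrodynamic_radius / r_eff
    if lam >= 1.0:
        return "blocked"
    if lam >= hindered_lambda:
        return "hindered"
    return "pass"


# Canonical species and pore geometries used throughout the assays.  Lumen
# radius 4.8 nm (9.6 nm widest inner dimension), channel length 32 nm; the
# PEG-20k plug has R_h ~ 4.9 nm.  Dextran/PEG coils carry flexibility 0.5,
# rigid small dyes 1.0.
DEFAULT_PORE = PoreGeometry(lumen_radius=4.8, channel_length=32.0)
DEFAULT_PLUGGED_PORE = PoreGeometry(lumen_radius=4.8, channel_length=32.0,
                                    plug_radius=4.9, plug_flexibility=0.5)
SRB = CargoSpecies("SRB", hydrodynamic_radius=0.5, flexibility=1.0)
DFITC_40K = CargoSpecies("dFITC-40k", hydrodynamic_radius=4.8, flexibility=0.5)
DFITC_500K = CargoSpecies("dFITC-500k", hydrodynamic_radius=15.9,
                          flexibility=0.5)
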