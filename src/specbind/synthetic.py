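"""Synthetic instrument data with known ground truth.

Every downstream stage (quenching fits, ITC isotherm fit, amide-I
deconvolution, degradation kinetics, EEM peak extraction) can be exercised
against data generated here, where the true parameters are chosen rather
than estimated.  All generators take an explicit seed and are
bit-reproducible; noise is additive Gaussian with a user-set standard
deviation, the simplest defensible instrument-noise model.

Forward models:

* static quenching        F = F0 / (1 + K_SV [Q])
* sensitization           F = F0 * (1 + |K_SV| [Q])   (linear mirror form)
* n-site static binding   F = F0 / (1 + K_a [Q]^n)
* ITC                     single-site heats from :func:`specbind.itc.one_site_heats`,
                          rendered as Gaussian power pulses on a 1 s grid
* amide-I                 sum of Gaussian bands + linear baseline
* degradation             C(t) = C0 exp(-k t)
* EEM                     sum of 2-D Gaussians on the (ex, em) grid

The default ITC geometry mirrors a typical perfusion-cell protocol for a
small-molecule/protein titration: a 300 µL cell of 30 µmol/L protein
titrated with 20 x 2 µL injections of 600 µmol/L ligand at 200 s spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fluorescence import EEMSurface, TitrationSeries
from .ftir import AMIDE_I_WINDOW, FTIRSpectrum
from .itc import ITCThermogram, one_site_heats
from .stability import DegradationSeries

QUENCH_MODES = ("static", "sensitization", "binding")

#: Gaussian ITC pulse width (s); only pulse areas matter downstream.
ITC_PULSE_SIGMA = 10.0 / 2.355  # FWHM 10 s
ITC_SPACING_S = 200.0

UJ_TO_UCAL = 1.0 / 4.184


@dataclass(frozen=True)
class QuenchModel:
    """Ground truth for one fluorescence titration.

    ``mode`` selects the forward model; ``ksv`` (L/mol) drives static and
    sensitization series (negative values allowed for sensitization, the
    magnitude is used), while ``ka`` ((L/mol)^n) and ``n_sites`` drive the
    n-site binding form.  ``noise_sd`` is relative to ``f0``.
    """

    f0: float = 1000.0
    mode: str = "static"
    ksv: float = 1.0e4
    ka: float = 1.0e4
    n_sites: float = 1.0
    noise_sd: float = 0.0
    temperature: float = 298.0

    def __post_init__(self):
        if not self.f0 > 0:
            raise ValueError("f0 must be positive")
        if self.mode not in QUENCH_MODES:
            raise ValueError(f"mode must be one of {QUENCH_MODES}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.mode == "binding" and not self.n_sites > 0:
            raise ValueError("n_sites must be positive for binding mode")


@dataclass(frozen=True)
class ITCGroundTruth:
    """Ground truth for one ITC experiment (SI units; dh in kJ/mol,
    dilution_heat and noise_sd in µJ)."""

    n_sites: float = 1.0
    ka: float = 1.0e5
    dh: float = -20.0
    cell_volume: float = 300e-6
    cell_conc: float = 30e-6
    syringe_conc: float = 600e-6
    injection_volume: float = 2e-6
    n_injections: int = 20
    dilution_heat: float = 0.0
    noise_sd: float = 0.0
    temperature: float = 298.0

    def __post_init__(self):
        if min(self.cell_volume, self.cell_conc, self.syringe_conc, self.injection_volume) <= 0:
            raise ValueError("volumes and concentrations must be positive")
        if self.n_injections < 2:
            raise ValueError("need at least 2 injections")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class AmideBandSpec:
    """Ground truth for a synthetic amide-I band mixture.

    ``area_fractions`` are per-band fractions of the total band area; they
    must be non-negative and sum to 1.  The baseline is linear in
    wavenumber; ``noise_sd`` is in absorbance units.
    """

    centers: tuple = (1620.0, 1645.0, 1655.0, 1675.0)
    widths: tuple = (7.0, 5.0, 5.0, 8.0)
    area_fractions: tuple = (0.42, 0.14, 0.24, 0.20)
    baseline_slope: float = 0.0
    baseline_offset: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self):
        c = np.asarray(self.centers, float)
        w = np.asarray(self.widths, float)
        f = np.asarray(self.area_fractions, float)
        if not (c.size == w.size == f.size):
            raise ValueError("centers, widths and area_fractions must align")
        if np.any(f < 0) or abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("area_fractions must be non-negative and sum to 1")
        if np.any((c < AMIDE_I_WINDOW[0]) | (c > AMIDE_I_WINDOW[1])):
            raise ValueError("band centers must lie within 1600-1700 cm^-1")
        if np.any(w <= 0):
            raise ValueError("widths must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def quench_forward(model: QuenchModel, concentrations: np.ndarray) -> np.ndarray:
    """Noise-free fluorescence intensities for a concentration series."""
    q = np.asarray(concentrations, dtype=float)
    if model.mode == "static":
        return model.f0 / (1.0 + model.ksv * q)
    if model.mode == "sensitization":
        return model.f0 * (1.0 + abs(model.ksv) * q)
    return model.f0 / (1.0 + model.ka * q**model.n_sites)


def gen_quench_titration(model: QuenchModel, concentrations, seed: int = 0) -> TitrationSeries:
    """Simulate a fluorescence titration under ``model``.

    ``concentrations`` (mol/L) must be non-negative, strictly increasing
    and start at 0 so F0 is observed directly.
    """
    q = np.asarray(concentrations, dtype=float)
    if np.any(q < 0):
        raise ValueError("quencher concentrations must be non-negative")
    if q.size == 0 or q[0] != 0.0:
        raise ValueError("the first concentration must be 0 (the F0 reference)")
    if np.any(np.diff(q) <= 0):
        raise ValueError("concentrations must be strictly increasing")
    f = quench_forward(model, q)
    if model.noise_sd > 0:
        f = f + _rng(seed).normal(0.0, model.noise_sd * model.f0, size=f.shape)
    return TitrationSeries(quencher_conc=q, intensity=f, temperature=model.temperature)


def default_quench_concentrations(protein_conc: float = 1e-6, max_ratio: int = 18, step: int = 2):
    """Ligand series at molar ratios 0, 2, ..., 18 x the protein concentration."""
    return np.arange(0, max_ratio + 1, step, dtype=float) * protein_conc


def gen_itc_experiment(truth: ITCGroundTruth, seed: int = 0) -> ITCThermogram:
    """Render a single-site ITC experiment as a power-vs-time thermogram.

    Each injection is a Gaussian power pulse (FWHM 10 s) whose area equals
    the one-site model heat plus the dilution offset plus noise; pulses are
    spaced 200 s apart on a 1 s time grid.
    """
    vols = np.full(truth.n_injections, truth.injection_volume)
    heats = one_site_heats(
        truth.n_sites, truth.ka, truth.dh,
        truth.cell_volume, truth.cell_conc, truth.syringe_conc,
        vols, truth.dilution_heat,
    )
    if truth.noise_sd > 0:
        heats = heats + _rng(seed).normal(0.0, truth.noise_sd, size=heats.shape)

    inj_times = 100.0 + ITC_SPACING_S * np.arange(truth.n_injections)
    t_end = inj_times[-1] + ITC_SPACING_S
    t = np.arange(0.0, t_end + 1.0, 1.0)
    power = np.zeros_like(t)
    for ti, h in zip(inj_times, heats):
        center = ti + 4.0 * ITC_PULSE_SIGMA  # pulse fully inside [ti, ti+spacing)
        pulse = np.exp(-0.5 * ((t - center) / ITC_PULSE_SIGMA) ** 2)
        pulse /= np.trapezoid(pulse, t)
        power += h * UJ_TO_UCAL * pulse
    return ITCThermogram(
        time=t, power=power,
        injections=tuple((float(ti), truth.injection_volume) for ti in inj_times),
        cell_volume=truth.cell_volume, cell_conc=truth.cell_conc,
        syringe_conc=truth.syringe_conc, temperature=truth.temperature,
    )


def gen_amide_spectrum(
    spec: AmideBandSpec,
    wavenumbers=None,
    total_area: float = 10.0,
    seed: int = 0,
) -> FTIRSpectrum:
    """Synthesize an amide-I spectrum: Gaussian bands + linear baseline + noise.

    Band areas are ``area_fractions x total_area`` (absorbance · cm^-1).
    The default grid is 1600-1700 cm^-1 at 0.5 cm^-1 spacing.
    """
    if wavenumbers is None:
        wavenumbers = np.arange(AMIDE_I_WINDOW[0], AMIDE_I_WINDOW[1] + 0.5, 0.5)
    w = np.asarray(wavenumbers, dtype=float)
    if w[0] > AMIDE_I_WINDOW[0] or w[-1] < AMIDE_I_WINDOW[1] or np.max(np.diff(w)) > 1.0:
        raise ValueError("grid must cover 1600-1700 cm^-1 with spacing <= 1 cm^-1")
    a = spec.baseline_offset + spec.baseline_slope * (w - AMIDE_I_WINDOW[0])
    for c, s, frac in zip(spec.centers, spec.widths, spec.area_fractions):
        amp = frac * total_area / (s * np.sqrt(2.0 * np.pi))
        a = a + amp * np.exp(-0.5 * ((w - c) / s) ** 2)
    if spec.noise_sd > 0:
        a = a + _rng(seed).normal(0.0, spec.noise_sd, size=a.shape)
    return FTIRSpectrum(wavenumber=w, absorbance=a)


def gen_degradation_series(
    c0: float = 17.5,
    k: float = 0.01494,
    times=None,
    noise_sd: float = 0.0,
    seed: int = 0,
    condition: dict | None = None,
) -> DegradationSeries:
    """First-order degradation series C(t) = C0 exp(-k t) + noise.

    Defaults mirror a visible-light photostability time course: initial
    concentration 17.5 µg/mL sampled every 6 h for 36 h, with a rate that
    leaves 58.4% at the endpoint.  ``k`` must be non-negative (degradation
    only).
    """
    if times is None:
        times = np.arange(0.0, 37.0, 6.0)
    t = np.asarray(times, dtype=float)
    if not c0 > 0:
        raise ValueError("c0 must be positive")
    if k < 0:
        raise ValueError("k must be non-negative (degradation only)")
    if t[0] != 0.0 or np.any(t < 0):
        raise ValueError("times must be non-negative and include t=0 first")
    c = c0 * np.exp(-k * t)
    if noise_sd > 0:
        c = c + _rng(seed).normal(0.0, noise_sd, size=c.shape)
        c = np.maximum(c, 1e-9)  # keep the series physical under heavy noise
    return DegradationSeries(time=t, concentration=c, condition=condition or {})


@dataclass(frozen=True)
class EEMPeak:
    """One 2-D Gaussian EEM feature: center (nm), height, and widths (nm)."""

    excitation: float
    emission: float
    height: float
    sigma_ex: float = 8.0
    sigma_em: float = 12.0


def gen_eem_surface(
    peaks: list[EEMPeak] | tuple[EEMPeak, ...],
    excitation=None,
    emission=None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> EEMSurface:
    """Sum of 2-D Gaussian peaks on an excitation x emission grid plus noise.

    Default grids: excitation 200-400 nm at 5 nm steps and emission
    250-500 nm at 2 nm steps (typical protein EEM acquisition).
    """
    ex = np.arange(200.0, 401.0, 5.0) if excitation is None else np.asarray(excitation, float)
    em = np.arange(250.0, 501.0, 2.0) if emission is None else np.asarray(emission, float)
    z = np.zeros((ex.size, em.size))
    for p in peaks:
        if not (ex[0] <= p.excitation <= ex[-1] and em[0] <= p.emission <= em[-1]):
            raise ValueError("peak center outside the grid")
        z += p.height * np.outer(
            np.exp(-0.5 * ((ex - p.excitation) / p.sigma_ex) ** 2),
            np.exp(-0.5 * ((em - p.emission) / p.sigma_em) ** 2),
        )
    if noise_sd > 0:
        z = z + _rng(seed).normal(0.0, noise_sd, size=z.shape)
    return EEMSurface(excitation=ex, emission=em, intensity=z)
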