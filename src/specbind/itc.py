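"""Isothermal titration calorimetry: thermogram integration and one-site fitting.

An ITC experiment titrates ligand from a syringe into a stirred cell of
protein and records the compensating power needed to hold the cell
isothermal.  Each injection produces a heat pulse whose area is the heat of
that injection; plotted against the ligand/protein molar ratio these form
the binding isotherm.

The single-site (Wiseman) model expresses the cumulative heat after
injection i through the bound fraction Theta_i:

    Q_i = n * Theta_i * M_i * dH * V0,

where M_i is the protein concentration in the cell after i injections, V0
the cell volume, and Theta_i the physical root of the binding quadratic

    Theta^2 - Theta * (1 + X/(n M) + 1/(n K_a M)) + X/(n M) = 0

at the post-injection ligand concentration X_i.  Because the perfusion
cell overflows, injected volume displaces cell contents; the standard
overflow bookkeeping

    M_i = M0 (1 - dV_i/2V0) / (1 + dV_i/2V0),
    X_i = X_syr (dV_i/V0) / (1 + dV_i/2V0)

is used, and the per-injection model heat carries the matching
displaced-volume term:

    q_i = Q_i - Q_{i-1} + (v_i/V0) * (Q_i + Q_{i-1}) / 2 + q_dil.

Heats are handled internally in microjoules; molar enthalpies in kJ/mol.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from lmfit import Parameters, minimize

from .thermodynamics import GAS_CONSTANT

UCAL_TO_UJ = 4.184


@dataclass(frozen=True)
class ITCThermogram:
    """Raw power-vs-time trace with the injection schedule and cell geometry.

    ``time`` in s (strictly increasing), ``power`` in µcal/s,
    ``injections`` a list of (time s, volume L); volumes and concentrations
    in SI (L, mol/L).
    """

    time: np.ndarray
    power: np.ndarray
    injections: tuple
    cell_volume: float
    cell_conc: float
    syringe_conc: float
    temperature: float = 298.0

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        p = np.asarray(self.power, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "power", p)
        object.__setattr__(self, "injections", tuple((float(ti), float(vi)) for ti, vi in self.injections))
        if t.shape != p.shape or t.ndim != 1:
            raise ValueError("time and power must be 1-D and equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        for ti, vi in self.injections:
            if not (t[0] <= ti <= t[-1]):
                raise ValueError("injection times must lie within the trace")
            if not vi > 0:
                raise ValueError("injection volumes must be positive")
        if not (self.cell_volume > 0 and self.cell_conc > 0 and self.syringe_conc > 0):
            raise ValueError("cell volume and concentrations must be positive")


@dataclass(frozen=True)
class InjectionHeats:
    """Integrated per-injection heats on the molar-ratio axis.

    ``heats_uJ`` per injection; ``molar_ratio`` is cumulative injected
    ligand moles over initial cell protein moles (strictly increasing);
    ``enthalpy_kJ_per_mol_injectant`` normalizes each heat by the moles of
    ligand delivered in that injection.
    """

    heats_uJ: np.ndarray
    molar_ratio: np.ndarray
    enthalpy_kJ_per_mol_injectant: np.ndarray

    def __post_init__(self):
        h = np.asarray(self.heats_uJ, dtype=float)
        r = np.asarray(self.molar_ratio, dtype=float)
        e = np.asarray(self.enthalpy_kJ_per_mol_injectant, dtype=float)
        object.__setattr__(self, "heats_uJ", h)
        object.__setattr__(self, "molar_ratio", r)
        object.__setattr__(self, "enthalpy_kJ_per_mol_injectant", e)
        if not (h.shape == r.shape == e.shape) or h.ndim != 1:
            raise ValueError("heats, molar ratios and enthalpies must be 1-D and equal length")
        if np.any(np.diff(r) <= 0):
            raise ValueError("molar ratio must be strictly increasing")


@dataclass(frozen=True)
class ITCFitResult:
    """One-site fit: stoichiometry n, K_a (L/mol), dH (kJ/mol per mole of
    complex), a constant per-injection dilution heat (µJ), and the derived
    dG and dS at the experiment temperature."""

    n_sites: float
    ka: float
    dh: float
    dilution_heat: float
    dg: float
    ds: float
    residual_norm: float
    temperature: float
    converged: bool = True
    warnings: tuple = field(default_factory=tuple)

    def __post_init__(self):
        if not self.ka > 0:
            raise ValueError("ka must be positive")
        dg = -GAS_CONSTANT * self.temperature * np.log(self.ka) / 1000.0
        if not np.isclose(self.dg, dg, rtol=1e-9, atol=1e-12):
            raise ValueError("dg must equal -R T ln(ka)")
        ds = (self.dh - self.dg) * 1000.0 / self.temperature
        if not np.isclose(self.ds, ds, rtol=1e-9, atol=1e-9):
            raise ValueError("ds must equal (dh - dg)/T")


class ITCFitError(RuntimeError):
    """Raised when the one-site fit fails to converge."""


def one_site_heats(
    n_sites: float,
    ka: float,
    dh: float,
    cell_volume: float,
    cell_conc: float,
    syringe_conc: float,
    injection_volumes: np.ndarray,
    dilution_heat: float = 0.0,
) -> np.ndarray:
    """Per-injection heats (µJ) of the single-site model.

    ``dh`` in kJ/mol; volumes in L, concentrations in mol/L;
    ``dilution_heat`` is a constant offset per injection in µJ.
    """
    v = np.asarray(injection_volumes, dtype=float)
    dv = np.cumsum(v)
    v0 = cell_volume
    m = cell_conc * (1.0 - dv / (2.0 * v0)) / (1.0 + dv / (2.0 * v0))
    x = syringe_conc * (dv / v0) / (1.0 + dv / (2.0 * v0))

    nm = n_sites * m
    b = 1.0 + x / nm + 1.0 / (ka * nm)
    c = x / nm
    theta = (b - np.sqrt(b * b - 4.0 * c)) / 2.0

    # cumulative heat in J; dh kJ/mol -> J/mol
    q = n_sites * theta * m * v0 * dh * 1000.0
    q_prev = np.concatenate([[0.0], q[:-1]])
    dq = q - q_prev + (v / v0) * (q + q_prev) / 2.0
    return dq * 1e6 + dilution_heat


def integrate_injections(thermogram: ITCThermogram, baseline_window: float = 20.0) -> InjectionHeats:
    """Integrate each injection pulse above a local median baseline.

    For each injection the window runs from the injection time to the next
    injection (or trace end); the baseline is the median power over
    ``baseline_window`` seconds immediately before the injection.  Heats
    are converted from µcal to µJ (x 4.184).
    """
    times = np.array([ti for ti, _ in thermogram.injections])
    vols = np.array([vi for _, vi in thermogram.injections])
    if times.size < 1:
        raise ValueError("no injections in schedule")
    if np.any(np.diff(times) <= 0):
        raise ValueError("injection times must be strictly increasing")
    spacing = np.diff(times)
    if spacing.size and baseline_window > spacing.min():
        raise ValueError("baseline window overlaps the previous injection's integration window")

    t, p = thermogram.time, thermogram.power
    edges = np.concatenate([times, [t[-1]]])
    heats = np.empty(times.size)
    for i, ti in enumerate(times):
        lo, hi = edges[i], edges[i + 1]
        in_win = (t >= lo) & (t <= hi)
        if in_win.sum() < 2:
            raise ValueError(f"injection {i}: too few samples in integration window")
        base_mask = (t >= ti - baseline_window) & (t < ti)
        baseline = float(np.median(p[base_mask])) if base_mask.any() else 0.0
        heats[i] = np.trapezoid(p[in_win] - baseline, t[in_win]) * UCAL_TO_UJ

    protein_moles = thermogram.cell_conc * thermogram.cell_volume
    injected_moles = np.cumsum(vols) * thermogram.syringe_conc
    ratio = injected_moles / protein_moles
    per_inj_moles = vols * thermogram.syringe_conc
    enthalpy = heats * 1e-6 / per_inj_moles / 1000.0  # µJ -> J -> kJ/mol of injectant
    return InjectionHeats(heats_uJ=heats, molar_ratio=ratio, enthalpy_kJ_per_mol_injectant=enthalpy)


def subtract_control(sample: InjectionHeats, control: InjectionHeats) -> InjectionHeats:
    """Subtract a buffer-titration control, injection by injection.

    Molar ratios (and the per-injectant normalization denominator) are taken
    from the sample.
    """
    if sample.heats_uJ.size != control.heats_uJ.size:
        raise ValueError("sample and control must have the same number of injections")
    heats = sample.heats_uJ - control.heats_uJ
    scale = np.divide(
        sample.enthalpy_kJ_per_mol_injectant,
        sample.heats_uJ,
        out=np.zeros_like(heats),
        where=sample.heats_uJ != 0,
    )
    return InjectionHeats(
        heats_uJ=heats,
        molar_ratio=sample.molar_ratio,
        enthalpy_kJ_per_mol_injectant=heats * scale,
    )


def _model_params(heats: InjectionHeats, cell_volume, cell_conc, syringe_conc):
    ratio = heats.molar_ratio
    cum_moles = ratio * cell_conc * cell_volume
    vols = np.diff(np.concatenate([[0.0], cum_moles])) / syringe_conc
    return vols


def fit_one_site(
    heats: InjectionHeats,
    cell_volume: float,
    cell_conc: float,
    syringe_conc: float,
    temperature: float = 298.0,
    exclude_first: bool = False,
    fit_dilution: bool = True,
) -> ITCFitResult:
    """Fit the single-site isotherm to integrated injection heats.

    Nonlinear least squares over (n, log10 K_a, dH, dilution heat) with
    multistart initialization across a log K_a grid.  ``exclude_first``
    drops the first injection from the residuals (common practice for
    syringe-diffusion artifacts; off by default).  Saturated-from-start or
    null-signal data is fit anyway but flagged in ``warnings``.
    """
    y = heats.heats_uJ
    if y.size < 6:
        raise ValueError("one-site fit needs at least 6 injections")
    vols = _model_params(heats, cell_volume, cell_conc, syringe_conc)
    weight = np.ones_like(y)
    if exclude_first:
        weight[0] = 0.0

    flags = []
    span = np.ptp(y)
    scale = np.max(np.abs(y))
    if scale < 1e-12 or span < 0.02 * scale:
        flags.append(
            "injection heats are nearly constant: null signal or saturated-from-start "
            "design (c-value too high or too low); parameter confidence is poor"
        )

    dh_guess = y[0] * 1e-6 / (vols[0] * syringe_conc) / 1000.0  # kJ/mol if first inj ~fully bound
    if not np.isfinite(dh_guess) or dh_guess == 0:
        dh_guess = -1.0

    def residual(params):
        model = one_site_heats(
            params["n"].value,
            10.0 ** params["log10_ka"].value,
            params["dh"].value,
            cell_volume,
            cell_conc,
            syringe_conc,
            vols,
            params["q_dil"].value,
        )
        return (model - y) * weight

    best = None
    for log_ka0 in (3.0, 4.0, 5.0, 6.0, 7.0):
        for n0 in (0.5, 1.0, 2.0):
            params = Parameters()
            params.add("n", value=n0, min=0.05, max=10.0)
            params.add("log10_ka", value=log_ka0, min=0.0, max=12.0)
            params.add("dh", value=dh_guess)
            params.add("q_dil", value=0.0, vary=fit_dilution)
            try:
                res = minimize(residual, params, method="leastsq", nan_policy="raise")
            except Exception:
                continue
            if res.success and (best is None or res.chisqr < best.chisqr):
                best = res
    if best is None:
        raise ITCFitError("one-site fit failed to converge from any start")

    n = float(best.params["n"].value)
    ka = float(10.0 ** best.params["log10_ka"].value)
    dh = float(best.params["dh"].value)
    q_dil = float(best.params["q_dil"].value)
    if best.params["log10_ka"].value >= 11.9:
        flags.append("K_a at the upper fit bound: binding too tight to resolve from this design")
    dg = -GAS_CONSTANT * temperature * np.log(ka) / 1000.0
    ds = (dh - dg) * 1000.0 / temperature
    if flags:
        warnings.warn("; ".join(flags), stacklevel=2)
    return ITCFitResult(
        n_sites=n,
        ka=ka,
        dh=dh,
        dilution_heat=q_dil,
        dg=dg,
        ds=ds,
        residual_norm=float(np.sqrt(best.chisqr)),
        temperature=temperature,
        converged=True,
        warnings=tuple(flags),
    )
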