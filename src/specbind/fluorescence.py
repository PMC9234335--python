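"""Fluorescence titration analysis: Stern-Volmer, double-logarithm binding,
quenching-mechanism classification, and excitation-emission-matrix peaks.

The Stern-Volmer relation for a quenched fluorophore,

    F0 / F = 1 + K_SV [Q] = 1 + k_q * tau0 * [Q],

links the intensity ratio to the quencher concentration [Q] through the
Stern-Volmer constant K_SV (L/mol).  Dividing by the unquenched lifetime
tau0 gives the bimolecular quenching rate constant k_q; values above the
diffusion-collision ceiling (~2e10 L/mol/s) rule out purely dynamic
quenching and point to ground-state complex formation (static quenching).

For static quenching, the binding constant K_a and the number of binding
sites n per protein follow from the double-logarithm plot

    log10((F0 - F) / F) = log10 K_a + n log10 [Q].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

#: Default unquenched fluorophore lifetime (s), the textbook biopolymer value.
DEFAULT_TAU0 = 1e-8

#: Maximum diffusion-collision quenching rate constant (L/mol/s).
DIFFUSION_LIMIT_KQ = 2.0e10


@dataclass(frozen=True)
class TitrationSeries:
    """Fluorescence intensities vs quencher concentration at one temperature.

    ``quencher_conc`` is in mol/L, strictly increasing from 0; ``intensity``
    is in arbitrary instrument units and must be positive.  ``f0`` is the
    intensity at zero quencher (the first point).
    """

    quencher_conc: np.ndarray
    intensity: np.ndarray
    temperature: float

    def __post_init__(self):
        q = np.asarray(self.quencher_conc, dtype=float)
        f = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "quencher_conc", q)
        object.__setattr__(self, "intensity", f)
        if q.shape != f.shape or q.ndim != 1:
            raise ValueError("quencher_conc and intensity must be 1-D and equal length")
        if q.size < 3:
            raise ValueError("a titration needs at least 3 points")
        if q[0] != 0.0:
            raise ValueError("the first point must be the zero-quencher reference")
        if np.any(np.diff(q) <= 0):
            raise ValueError("quencher concentrations must be strictly increasing")
        if np.any(q < 0):
            raise ValueError("quencher concentrations must be non-negative")
        if np.any(f <= 0):
            raise ValueError("fluorescence intensities must be positive")
        if not self.temperature > 0:
            raise ValueError("temperature must be positive (kelvin)")

    @property
    def f0(self) -> float:
        """Intensity at zero quencher."""
        return float(self.intensity[0])


@dataclass(frozen=True)
class QuenchingResult:
    """Stern-Volmer fit at a single temperature.

    ``ksv`` is the fitted slope (L/mol, negative for sensitization),
    ``kq = ksv / tau0`` exactly, and ``intercept`` should be ~1 for
    well-behaved data.
    """

    ksv: float
    kq: float
    intercept: float
    r_squared: float
    temperature: float
    tau0: float = DEFAULT_TAU0

    def __post_init__(self):
        if not np.isclose(self.kq, self.ksv / self.tau0, rtol=1e-12, atol=0.0):
            raise ValueError("kq must equal ksv / tau0")


@dataclass(frozen=True)
class BindingResult:
    """Double-logarithm fit: binding constant and site number."""

    ka: float
    n_sites: float
    log10_ka: float
    r_squared: float

    def __post_init__(self):
        if not self.ka > 0:
            raise ValueError("ka must be positive")
        if not self.n_sites > 0:
            raise ValueError("n_sites must be positive")


@dataclass(frozen=True)
class MechanismCall:
    """Quenching-mechanism classification with the rules that produced it.

    ``label`` is one of ``static``, ``dynamic``, ``sensitization`` or
    ``ambiguous``; ``evidence`` records each rule's outcome so the label is
    auditable.
    """

    label: str
    evidence: tuple = field(default_factory=tuple)


@dataclass(frozen=True)
class EEMSurface:
    """Excitation-emission matrix: intensity over an (ex, em) wavelength grid."""

    excitation: np.ndarray  # nm, rows of `intensity`
    emission: np.ndarray  # nm, columns of `intensity`
    intensity: np.ndarray

    def __post_init__(self):
        ex = np.asarray(self.excitation, dtype=float)
        em = np.asarray(self.emission, dtype=float)
        z = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "excitation", ex)
        object.__setattr__(self, "emission", em)
        object.__setattr__(self, "intensity", z)
        if z.shape != (ex.size, em.size):
            raise ValueError("intensity matrix shape must match the grids")


def stern_volmer_fit(series: TitrationSeries, tau0: float = DEFAULT_TAU0) -> QuenchingResult:
    """Fit F0/F vs [Q] by ordinary least squares.

    The slope is K_SV (L/mol); the intercept is left free and reported (its
    ideal value is 1).  A negative slope indicates sensitization
    (fluorescence enhancement) and is permitted.
    """
    q = series.quencher_conc
    ratio = series.f0 / series.intensity
    fit = stats.linregress(q, ratio)
    ksv = float(fit.slope)
    r2 = float(fit.rvalue**2) if np.isfinite(fit.rvalue) else 1.0
    return QuenchingResult(
        ksv=ksv,
        kq=ksv / tau0,
        intercept=float(fit.intercept),
        r_squared=r2,
        temperature=series.temperature,
        tau0=tau0,
    )


def double_log_fit(series: TitrationSeries) -> BindingResult:
    """Fit log10((F0-F)/F) vs log10[Q] for the binding constant and site number.

    Only quenched points ([Q] > 0 and F < F0) carry signal; zero-quencher
    points are excluded.  Enhancement data (F >= F0) is refused because the
    double-logarithm relation models loss of fluorophore to a ground-state
    complex, not sensitization.
    """
    mask = series.quencher_conc > 0
    q = series.quencher_conc[mask]
    f = series.intensity[mask]
    if np.any(f >= series.f0):
        raise ValueError(
            "double-logarithm fit applies to quenching only: every point with "
            "[Q]>0 must satisfy F < F0 (got F >= F0; sensitization series "
            "cannot be analyzed with this model)"
        )
    if q.size < 3:
        raise ValueError("need at least 3 quenched points")
    x = np.log10(q)
    y = np.log10((series.f0 - f) / f)
    fit = stats.linregress(x, y)
    n = float(fit.slope)
    log10_ka = float(fit.intercept)
    r2 = float(fit.rvalue**2) if np.isfinite(fit.rvalue) else 1.0
    return BindingResult(ka=10.0**log10_ka, n_sites=n, log10_ka=log10_ka, r_squared=r2)


def classify_mechanism(
    results: list[QuenchingResult] | tuple[QuenchingResult, ...],
    kq_threshold: float = DIFFUSION_LIMIT_KQ,
) -> MechanismCall:
    """Classify the quenching mechanism from fits at one or more temperatures.

    Rule ladder:

    1. all Stern-Volmer slopes negative  -> sensitization;
    2. |k_q| above the diffusion-collision ceiling -> static;
    3. otherwise K_SV increasing with temperature -> dynamic,
       decreasing -> static.

    When the k_q rule and the temperature trend disagree (e.g. k_q above the
    ceiling but K_SV rising with temperature), the call is ``ambiguous``;
    every rule outcome is recorded in ``evidence``.  With a single
    temperature the trend rule is skipped and the k_q rule decides alone.
    """
    results = sorted(results, key=lambda r: r.temperature)
    if len(results) == 0:
        raise ValueError("at least one quenching result is required")
    temps = [r.temperature for r in results]
    if len(set(temps)) != len(temps):
        raise ValueError("temperatures must be distinct")

    evidence: list[tuple[str, str]] = []

    all_negative = all(r.ksv < 0 for r in results)
    evidence.append(("slope_sign", "all_negative" if all_negative else "not_all_negative"))
    if all_negative:
        return MechanismCall(label="sensitization", evidence=tuple(evidence))

    exceeds = all(abs(r.kq) > kq_threshold for r in results)
    evidence.append(("kq_vs_diffusion_limit", "above" if exceeds else "below"))

    if len(results) == 1:
        evidence.append(("temperature_trend", "skipped_single_temperature"))
        label = "static" if exceeds else "dynamic"
        return MechanismCall(label=label, evidence=tuple(evidence))

    ksvs = np.array([r.ksv for r in results])
    diffs = np.diff(ksvs)
    if np.all(diffs > 0):
        trend = "increasing"
    elif np.all(diffs < 0):
        trend = "decreasing"
    else:
        trend = "non_monotone"
    evidence.append(("temperature_trend", trend))

    if exceeds:
        # k_q rule says static; a rising K_SV(T) contradicts that.
        if trend == "increasing":
            return MechanismCall(label="ambiguous", evidence=tuple(evidence))
        return MechanismCall(label="static", evidence=tuple(evidence))
    if trend == "increasing":
        return MechanismCall(label="dynamic", evidence=tuple(evidence))
    if trend == "decreasing":
        return MechanismCall(label="static", evidence=tuple(evidence))
    return MechanismCall(label="ambiguous", evidence=tuple(evidence))


def eem_peak_extract(
    surface: EEMSurface,
    windows: dict[str, tuple[float, float, float, float]],
    reference: EEMSurface | None = None,
) -> dict[str, dict]:
    """Locate the peak in each (excitation, emission) window.

    ``windows`` maps a label (e.g. ``"peak_a"``) to a rectangle
    ``(ex_min, ex_max, em_min, em_max)`` in nm.  Returns per window the grid
    argmax location and intensity, plus the intensity ratio against
    ``reference`` (the same window on another surface) when given.
    """
    out: dict[str, dict] = {}
    for name, (ex_lo, ex_hi, em_lo, em_hi) in windows.items():
        ex_mask = (surface.excitation >= ex_lo) & (surface.excitation <= ex_hi)
        em_mask = (surface.emission >= em_lo) & (surface.emission <= em_hi)
        if not ex_mask.any() or not em_mask.any():
            raise ValueError(f"window {name!r} contains no grid points")
        sub = surface.intensity[np.ix_(ex_mask, em_mask)]
        i, j = np.unravel_index(int(np.argmax(sub)), sub.shape)
        ex_vals = surface.excitation[ex_mask]
        em_vals = surface.emission[em_mask]
        entry = {
            "excitation_nm": float(ex_vals[i]),
            "emission_nm": float(em_vals[j]),
            "intensity": float(sub[i, j]),
        }
        if reference is not None:
            ref = eem_peak_extract(reference, {name: (ex_lo, ex_hi, em_lo, em_hi)})[name]
            entry["intensity_ratio_vs_reference"] = (
                entry["intensity"] / ref["intensity"] if ref["intensity"] != 0 else float("nan")
            )
        out[name] = entry
    return out
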