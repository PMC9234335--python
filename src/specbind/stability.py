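"""Ligand photo- and thermostability: percent remaining, first-order rates,
and the protein-protection effect.

Phenolic ligands degrade under visible light and heat; embedding them in a
protein binding pocket slows the loss.  The model-free primary output is
percent remaining, 100*C(t)/C(0), interpolated linearly between sampled
time points.  A first-order rate constant (ln C vs t regression) makes
conditions comparable on a single scale; the protection effect compares a
with-protein series against its matched free-ligand series as an endpoint
percentage-point difference and a rate ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class DegradationSeries:
    """Ligand concentration (µg/mL) vs time (h) under a labeled condition.

    ``condition`` carries labels such as light/dark, temperature and the
    with-protein flag; series are comparable only when labels match.
    """

    time: np.ndarray
    concentration: np.ndarray
    condition: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        c = np.asarray(self.concentration, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "concentration", c)
        object.__setattr__(self, "condition", MappingProxyType(dict(self.condition)))
        if t.shape != c.shape or t.ndim != 1:
            raise ValueError("time and concentration must be 1-D and equal length")
        if t.size < 2:
            raise ValueError("a degradation series needs at least 2 points")
        if t[0] != 0.0:
            raise ValueError("the first point must be at t=0")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(c <= 0):
            raise ValueError("concentrations must be positive")

    @property
    def c0(self) -> float:
        return float(self.concentration[0])


def percent_remaining(series: DegradationSeries, at_time: float) -> float:
    """Percent of the initial concentration remaining at ``at_time`` hours.

    Linear interpolation between observed points; no extrapolation outside
    the observed range.
    """
    if not (series.time[0] <= at_time <= series.time[-1]):
        raise ValueError(
            f"t={at_time} h outside the observed range "
            f"[{series.time[0]}, {series.time[-1]}] h; extrapolation refused"
        )
    c = float(np.interp(at_time, series.time, series.concentration))
    return 100.0 * c / series.c0


def first_order_rate(series: DegradationSeries) -> tuple[float, float]:
    """First-order degradation rate constant k (h^-1) and fit R².

    Least squares of ln C vs t; k = -slope.  k ~ 0 for a stable series.
    """
    if series.time.size < 3:
        raise ValueError("rate fit needs at least 3 points")
    fit = stats.linregress(series.time, np.log(series.concentration))
    r2 = float(fit.rvalue**2) if np.isfinite(fit.rvalue) else 1.0
    return -float(fit.slope), r2


def protection_effect(
    with_protein: DegradationSeries, without_protein: DegradationSeries
) -> dict[str, float | bool]:
    """Protein protection: endpoint percent difference and rate ratio.

    The two series must share every condition label except the with-protein
    flag.  Returns the difference in percent remaining at the latest common
    time (with minus without; positive means protection), the rate ratio
    k_without / k_with, and a flag set when the protected series is so
    stable that the ratio is effectively infinite.
    """
    keys = set(with_protein.condition) | set(without_protein.condition)
    for key in keys - {"with_protein"}:
        a = with_protein.condition.get(key)
        b = without_protein.condition.get(key)
        if a != b:
            raise ValueError(f"condition mismatch on {key!r}: {a!r} vs {b!r}")

    t_end = min(with_protein.time[-1], without_protein.time[-1])
    if t_end <= max(with_protein.time[0], without_protein.time[0]):
        raise ValueError("series time ranges do not overlap")
    delta = percent_remaining(with_protein, t_end) - percent_remaining(without_protein, t_end)

    k_with, _ = first_order_rate(with_protein)
    k_without, _ = first_order_rate(without_protein)
    infinite = k_with <= np.finfo(float).eps
    ratio = float("inf") if infinite else k_without / k_with
    return {
        "endpoint_time_h": float(t_end),
        "delta_percent_remaining": float(delta),
        "rate_ratio": ratio,
        "rate_ratio_infinite": bool(infinite),
    }
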