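"""Van't Hoff analysis and binding-force classification.

With binding constants K_a measured at two or more temperatures, the linear
van't Hoff relation

    ln K_a = -dH/(R T) + dS/R

yields the enthalpy change dH (slope, assumed temperature-independent over
the narrow 288-308 K window) and entropy change dS (intercept).  The Gibbs
free energy follows as dG = dH - T dS.  The signs of dH and dS identify the
dominant intermolecular force (Ross-Subramanian rules): both positive ->
hydrophobic; both negative -> van der Waals forces and hydrogen bonds;
dH < 0 with dS > 0 -> electrostatic.
"""

from __future__ import annotations

from dataclasses import dataclass
from types import MappingProxyType
from typing import Mapping

import numpy as np
from scipy import stats

#: Gas constant, J/(mol K).
GAS_CONSTANT = 8.314

FORCE_CLASSES = ("hydrophobic", "vdw_hbond", "electrostatic", "unclassified")


def gibbs(dh: float, ds: float, temperature: float) -> float:
    """Gibbs free energy dG = dH - T dS, in kJ/mol.

    ``dh`` in kJ/mol, ``ds`` in J/(mol K), ``temperature`` in K.
    """
    if not temperature > 0:
        raise ValueError("temperature must be positive (kelvin)")
    return dh - temperature * ds / 1000.0


def classify_forces(dh: float, ds: float) -> str:
    """Dominant-force label from the signs of dH and dS.

    The sign rules are strict inequalities; exact zeros and the
    (dH>0, dS<0) quadrant fall outside the rule set and return
    ``"unclassified"``.
    """
    if dh > 0 and ds > 0:
        return "hydrophobic"
    if dh < 0 and ds < 0:
        return "vdw_hbond"
    if dh < 0 and ds > 0:
        return "electrostatic"
    return "unclassified"


@dataclass(frozen=True)
class ThermoParams:
    """Binding thermodynamics: dH (kJ/mol), dS (J/(mol K)), dG at each
    input temperature (kJ/mol), the van't Hoff fit quality, and the
    dominant-force label."""

    dh: float
    ds: float
    dg_at: Mapping[float, float]
    r_squared: float
    force_class: str

    def __post_init__(self):
        object.__setattr__(self, "dg_at", MappingProxyType(dict(self.dg_at)))
        for t, dg in self.dg_at.items():
            expected = gibbs(self.dh, self.ds, t)
            if not np.isclose(dg, expected, rtol=1e-12, atol=1e-12):
                raise ValueError(f"dg_at[{t}] inconsistent with dH - T dS")
        if self.force_class not in FORCE_CLASSES:
            raise ValueError(f"unknown force class {self.force_class!r}")


def vant_hoff_fit(
    ka_by_temperature: Mapping[float, float], gas_constant: float = GAS_CONSTANT
) -> ThermoParams:
    """Fit ln K_a vs 1/T and derive dH, dS, dG and the force class.

    ``ka_by_temperature`` maps temperature (K) to binding constant (L/mol);
    at least two distinct temperatures with positive K_a are required.
    dH is reported in kJ/mol, dS in J/(mol K); dG is evaluated at every
    input temperature.
    """
    temps = np.array(sorted(ka_by_temperature), dtype=float)
    kas = np.array([ka_by_temperature[t] for t in temps], dtype=float)
    if temps.size < 2:
        raise ValueError("van't Hoff fit needs at least two temperatures")
    if np.any(kas <= 0):
        raise ValueError("all binding constants must be positive")
    if np.any(temps <= 0):
        raise ValueError("temperatures must be positive (kelvin)")

    x = 1.0 / temps
    y = np.log(kas)
    fit = stats.linregress(x, y)
    dh = -float(fit.slope) * gas_constant / 1000.0  # kJ/mol
    ds = float(fit.intercept) * gas_constant  # J/(mol K)
    r2 = float(fit.rvalue**2) if np.isfinite(fit.rvalue) else 1.0
    dg_at = {float(t): gibbs(dh, ds, float(t)) for t in temps}
    return ThermoParams(
        dh=dh, ds=ds, dg_at=dg_at, r_squared=r2, force_class=classify_forces(dh, ds)
    )


def ka_from_thermo(
    dh: float, ds: float, temperature: float, gas_constant: float = GAS_CONSTANT
) -> float:
    """Invert the van't Hoff relation: K_a = exp(-dH/(R T) + dS/R).

    ``dh`` in kJ/mol, ``ds`` in J/(mol K).  Useful for forward-simulating
    K_a(T) from known thermodynamics.
    """
    if not temperature > 0:
        raise ValueError("temperature must be positive (kelvin)")
    return float(
        np.exp(-dh * 1000.0 / (gas_constant * temperature) + ds / gas_constant)
    )
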