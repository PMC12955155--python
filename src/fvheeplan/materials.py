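"""Water stopping-power tables and electron kinematics.

Collisional and radiative mass stopping powers for liquid water on a
0.5-300 MeV kinetic-energy grid, after the NIST ESTAR database (rounded).
Media are water-like, scaled by mass density only; no Z-dependent
correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ELECTRON_REST_MEV = 0.510998950
WATER_X0 = 36.08  # radiation length of water, g/cm^2
MEV_TO_JOULE = 1.602176634e-13
GY_PER_MEV_PER_G = 1.602176634e-10  # 1 MeV/g in Gy

# kinetic energy (MeV), collisional and radiative mass stopping power (MeV cm^2/g)
_E_GRID = np.array([0.5, 1.0, 2.0, 5.0, 10.0, 20.0, 50.0, 100.0, 150.0, 200.0, 250.0, 300.0])
_S_COL = np.array([2.034, 1.849, 1.824, 1.892, 1.968, 2.046, 2.131, 2.185, 2.217, 2.236, 2.255, 2.268])
_S_RAD = np.array([0.0070, 0.0128, 0.0259, 0.0774, 0.183, 0.409, 1.14, 2.45, 3.85, 5.29, 6.76, 8.25])

_N_DENSE = 4096


@dataclass
class MaterialTable:
    """Interpolated water stopping powers over 0.5-300 MeV.

    Interpolation is linear in log(E)-log(S), pre-sampled on a dense grid so
    per-step lookups reduce to a single ``np.interp``.  Queries are clamped
    to the tabulated energy range.
    """

    energies_mev: np.ndarray = field(default_factory=lambda: _E_GRID.copy())
    s_col: np.ndarray = field(default_factory=lambda: _S_COL.copy())
    s_rad: np.ndarray = field(default_factory=lambda: _S_RAD.copy())
    x0_g_cm2: float = WATER_X0

    def __post_init__(self) -> None:
        if np.any(self.s_col <= 0) or np.any(self.s_rad <= 0):
            raise ValueError("stopping powers must be positive")
        loge = np.log(self.energies_mev)
        self._dense_e = np.exp(np.linspace(loge[0], loge[-1], _N_DENSE))
        self._dense_col = np.exp(np.interp(np.log(self._dense_e), loge, np.log(self.s_col)))
        self._dense_rad = np.exp(np.interp(np.log(self._dense_e), loge, np.log(self.s_rad)))

    def stopping_power_col(self, energy_mev: np.ndarray) -> np.ndarray:
        return np.interp(energy_mev, self._dense_e, self._dense_col)

    def stopping_power_rad(self, energy_mev: np.ndarray) -> np.ndarray:
        return np.interp(energy_mev, self._dense_e, self._dense_rad)

    def stopping_power_total(self, energy_mev: np.ndarray) -> np.ndarray:
        return self.stopping_power_col(energy_mev) + self.stopping_power_rad(energy_mev)


def beta_pc_mev(kinetic_mev: np.ndarray) -> np.ndarray:
    """beta * p * c in MeV for electrons of the given kinetic energy."""
    e = np.asarray(kinetic_mev, dtype=float)
    return e * (e + 2.0 * ELECTRON_REST_MEV) / (e + ELECTRON_REST_MEV)


def highland_sigma(kinetic_mev: np.ndarray, t_radlen: np.ndarray) -> np.ndarray:
    """Highland multiple-scattering angle (rad) for a step of ``t_radlen``
    radiation lengths: theta0 = 13.6 MeV / (beta p c) * sqrt(t) * (1 + 0.038 ln t).

    Zero thickness gives zero; the logarithmic factor is clamped at zero.
    """
    t = np.asarray(t_radlen, dtype=float)
    out = np.zeros(np.broadcast_shapes(np.shape(kinetic_mev), t.shape))
    pos = t > 0
    if np.any(pos):
        tp = t[pos] if t.ndim else t
        bpc = np.broadcast_to(beta_pc_mev(kinetic_mev), out.shape)[pos]
        factor = np.maximum(1.0 + 0.038 * np.log(tp), 0.0)
        out[pos] = 13.6 / bpc * np.sqrt(tp) * factor
    return out
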