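"""Marcus hopping-rate evaluation and Arrhenius activation-energy analysis.

Energies cross the interface in eV; all arithmetic is done in joules with
CODATA constants from :mod:`scipy.constants`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.constants import Boltzmann as K_B
from scipy.constants import Planck as H_PLANCK
from scipy.constants import elementary_charge as E_CHARGE

from molsynapse.errors import DomainError

#: experimentally measured activation energies (eV): bare peptide vs. Ag+-bound
E_A_BARE_EV = 0.128
E_A_BOUND_EV = 0.036


@dataclass(frozen=True)
class HoppingParams:
    """Parameters of a thermally activated two-state hopping rate.

    ``V_coupling`` and ``lambda_reorg`` default to 1 eV unit placeholders
    (the per-pair electronic-structure values are not part of this artifact);
    the two shipped activation energies are the experimental ones.
    """

    V_coupling: float = 1.0  # eV, hopping integral
    lambda_reorg: float = 1.0  # eV, reorganization energy
    E_a: float = E_A_BARE_EV  # eV, activation energy
    T: float = 298.0  # K

    def __post_init__(self):
        if not (self.lambda_reorg > 0):
            raise DomainError(f"lambda_reorg must be > 0, got {self.lambda_reorg}")
        if not (self.T > 0):
            raise DomainError(f"T must be > 0, got {self.T}")
        if self.E_a < 0:
            raise DomainError(f"E_a must be >= 0, got {self.E_a}")
        if not (self.V_coupling > 0):
            raise DomainError(f"V_coupling must be > 0, got {self.V_coupling}")


def marcus_prefactor(p: HoppingParams, T: float | None = None) -> float:
    """Zero-barrier limit (2*pi/h) * V^2 / sqrt(4*pi*lambda*kB*T), in 1/s."""
    T = p.T if T is None else T
    v_j = p.V_coupling * E_CHARGE
    lam_j = p.lambda_reorg * E_CHARGE
    return (2.0 * math.pi / H_PLANCK) * v_j**2 / math.sqrt(4.0 * math.pi * lam_j * K_B * T)


def marcus_rate(p: HoppingParams, T: float | None = None) -> float:
    """Hopping rate k_et = (2*pi/h) V^2 / sqrt(4*pi*lambda*kB*T) * exp(-E_a/kB*T)."""
    T = p.T if T is None else T
    if not (T > 0):
        raise DomainError(f"T must be > 0, got {T}")
    return marcus_prefactor(p, T) * math.exp(-p.E_a * E_CHARGE / (K_B * T))


def inverse_rate_curve(
    p: HoppingParams, T_grid, reduced: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Per-temperature inverse hopping rate ``(T, 1/k_et)``.

    With ``reduced=True`` the temperature-dependent prefactor is divided out
    so that ``log(reduced 1/k)`` is exactly affine in ``1/T`` (the Arrhenius
    straight line); the un-reduced curve keeps the ``1/sqrt(T)`` factor.
    """
    T_grid = np.asarray(T_grid, dtype=float)
    if T_grid.ndim != 1 or T_grid.size == 0:
        raise DomainError("T_grid must be a non-empty 1-D sequence")
    if np.any(T_grid <= 0):
        raise DomainError("all temperatures must be positive")
    if T_grid.size >= 2 and not np.all(np.diff(T_grid) > 0):
        raise DomainError("T_grid must be sorted increasing")
    k = np.array([marcus_rate(p, T=t) for t in T_grid])
    if reduced:
        pref = np.array([marcus_prefactor(p, T=t) for t in T_grid])
        k = k / pref  # = exp(-E_a / kB T)
    return T_grid, 1.0 / k


def arrhenius_series(
    E_a_ev: float,
    k0: float,
    T_grid,
    noise_sigma: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Synthetic Arrhenius rates k(T) = k0 exp(-E_a/kB T), optionally with
    multiplicative Gaussian noise (the Monte-Carlo generator for the fitter)."""
    T_grid = np.asarray(T_grid, dtype=float)
    k = k0 * np.exp(-E_a_ev * E_CHARGE / (K_B * T_grid))
    if noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng()
        k = k * (1.0 + noise_sigma * rng.standard_normal(k.shape))
    return k


def arrhenius_fit(T, k) -> tuple[float, float]:
    """Least-squares line on (1/T, ln k); returns ``(E_a [eV], prefactor)``.

    E_a = -slope * kB.  Exact on noiseless Arrhenius input.
    """
    T = np.asarray(T, dtype=float)
    k = np.asarray(k, dtype=float)
    if T.size < 3:
        raise DomainError(f"arrhenius_fit needs >= 3 points, got {T.size}")
    if np.any(k <= 0):
        raise DomainError("all rates must be positive")
    if np.any(T <= 0):
        raise DomainError("all temperatures must be positive")
    slope, intercept = np.polyfit(1.0 / T, np.log(k), 1)
    e_a_ev = -slope * K_B / E_CHARGE
    return float(e_a_ev), float(np.exp(intercept))
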