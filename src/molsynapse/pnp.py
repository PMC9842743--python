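"""1-D coupled Poisson--Nernst--Planck transport through a molecular film.

Two charged species -- cations (index ``n``) and electrons (index ``e``) --
drift and diffuse on a uniform node-centred grid over ``[0, L]``:

    dC/dt = d/dx ( D dC/dx + z e D beta C dphi/dx ),
    -d2phi/dx2 = e/(eps0 epsr) (z_e C_e + z_n C_n).

Discretization: finite volumes with Scharfetter--Gummel edge fluxes and
backward-Euler time stepping; a per-step Gummel loop couples the Poisson and
transport solves.  The electron diffusion coefficient follows a piecewise
exponential schedule in time that models the cation-enhanced hopping during
potentiation and its loss during depression.

Boundary conditions (x = 0 is the grounded cation-source electrode, x = L is
the biased liquid contact):

* potential: Dirichlet, phi(0) = 0, phi(L) = V_applied;
* electrons: fixed contact concentrations at both ends (ohmic metallic
  reservoirs);
* cations: zero flux at x = L always; at x = 0 a Dirichlet reservoir C0 when
  injecting (V_applied < -V_on), an absorbing Dirichlet 0 otherwise, or
  zero-flux in the ``sealed`` test mode.

The voltage dependence of the hopping schedule is a documented model
extension (the base schedule has no voltage argument): the potentiation
growth rate scales linearly with the over-threshold voltage and the fast
depression rate scales inversely with it, recovering the printed constants
at the -1.3 V reference bias.  Every simulated trace carries these flags in
its metadata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.constants import Boltzmann as K_B
from scipy.constants import elementary_charge as E_CHARGE
from scipy.constants import epsilon_0 as EPS_0
from scipy.linalg import solve_banded

from molsynapse.errors import ConfigurationError, DomainError, SolverError
from molsynapse.signals import CurrentTrace

#: reference bias (V) at which the printed schedule constants apply
V_REF = 1.3


@dataclass(frozen=True)
class PNPConfig:
    """Geometry, material and solver parameters of the 1-D PNP model."""

    L: float = 4e-9  # m, film thickness
    n_grid: int = 128
    dt: float = 1e-3  # s
    T: float = 298.0  # K
    eps_r: float = 4.0
    D_n: float = 1e-18  # m^2/s, cation diffusion coefficient
    z_n: int = 1
    z_e: int = -1
    junction_area: float = math.pi * (10e-6) ** 2  # m^2
    C0: float = 1e25  # 1/m^3, cation reservoir concentration while injecting
    V_on: float = 0.3  # V, |bias| threshold for cation injection
    C_e0: float = 1e25  # 1/m^3, electron contact concentration
    coupling_scale: float = 1.0  # factor on the Poisson source term
    injection_enabled: bool = True
    ion_bc: str = "auto"  # "auto" (injection/outflow by bias) or "sealed"
    gummel_tol: float = 1e-8
    gummel_maxiter: int = 50

    def __post_init__(self):
        if not (self.L > 0):
            raise ConfigurationError(f"L must be > 0, got {self.L}")
        if self.n_grid < 16:
            raise ConfigurationError(
                f"n_grid must be >= 16 (degenerate grids rejected), got {self.n_grid}"
            )
        if not (self.dt > 0):
            raise ConfigurationError(f"dt must be > 0, got {self.dt}")
        if self.eps_r < 1:
            raise ConfigurationError(f"eps_r must be >= 1, got {self.eps_r}")
        if self.ion_bc not in ("auto", "sealed"):
            raise ConfigurationError(f"ion_bc must be 'auto' or 'sealed', got {self.ion_bc}")

    @property
    def h(self) -> float:
        return self.L / (self.n_grid - 1)

    @property
    def beta(self) -> float:
        return 1.0 / (K_B * self.T)

    @property
    def x(self) -> np.ndarray:
        return np.linspace(0.0, self.L, self.n_grid)


@dataclass(frozen=True)
class DiffusionSchedule:
    """Piecewise-exponential electron diffusion coefficient D_e(t).

    ``t_p`` is the potentiation duration and ``t_d`` the depression duration
    (the simulated window is ``[0, t_p + t_d]``).  On ``[0, t_p)`` the
    coefficient grows as ``A exp(a t)``; on ``[t_p, t_p + 0.1 t_d)`` it
    decays fast as ``B exp(b (t - t_p))``; afterwards it decays slowly as
    ``B exp(0.1 b t_d) exp(c (t - t_p - 0.1 t_d))``, which joins the second
    branch continuously.
    """

    A: float = 1e-17  # m^2/s
    B: float = 3e-16  # m^2/s
    a: float = 6.8  # 1/s
    b: float = -7.4  # 1/s
    c: float = -3.4  # 1/s
    t_p: float = 0.5  # s, potentiation duration
    t_d: float = 1.0  # s, depression duration

    def __post_init__(self):
        if not (self.A > 0 and self.B > 0):
            raise ConfigurationError("schedule prefactors A, B must be > 0")
        if self.t_p < 0 or not (self.t_d > 0):
            raise ConfigurationError("need t_p >= 0 and t_d > 0")

    @property
    def t_end(self) -> float:
        return self.t_p + self.t_d

    def for_voltage(self, V_pot: float, V_on: float = 0.3, V_ref: float = V_REF) -> "DiffusionSchedule":
        """Schedule scaled to potentiation bias ``V_pot`` (model extension).

        The growth exponent scales as ``a * s`` and the fast depression rate
        as ``b / s`` with ``s = (|V_pot| - V_on)/(V_ref - V_on)`` (stronger
        injection -> faster build-up, slower fast unbinding); ``B`` is reset
        to ``A exp(a s t_p)`` so the two branches stay continuous.  At the
        reference bias the printed constants are recovered.
        """
        s = (abs(V_pot) - V_on) / (V_ref - V_on)
        if s <= 0:
            raise DomainError(
                f"|V_pot| = {abs(V_pot)} below the injection threshold {V_on}"
            )
        a_s = self.a * s
        return replace(self, a=a_s, b=self.b / s, B=self.A * math.exp(a_s * self.t_p))


def diffusion_coefficient(t, sched: DiffusionSchedule):
    """Evaluate the schedule at time(s) ``t`` in ``[0, t_p + t_d]``."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0) or np.any(t_arr > sched.t_end + 1e-12):
        raise DomainError(
            f"t outside schedule domain [0, {sched.t_end}]: {t!r}"
        )
    t_b = sched.t_p + 0.1 * sched.t_d
    out = np.where(
        t_arr < sched.t_p,
        sched.A * np.exp(sched.a * t_arr),
        np.where(
            t_arr < t_b,
            sched.B * np.exp(sched.b * (t_arr - sched.t_p)),
            sched.B * np.exp(sched.b * 0.1 * sched.t_d) * np.exp(sched.c * (t_arr - t_b)),
        ),
    )
    return float(out) if np.isscalar(t) else out


@dataclass
class PNPFields:
    """Spatial profiles on the grid plus the electron D used at the last step."""

    x: np.ndarray
    C_n: np.ndarray
    C_e: np.ndarray
    phi: np.ndarray
    D_e: float = 1e-17

    def copy(self) -> "PNPFields":
        return PNPFields(self.x.copy(), self.C_n.copy(), self.C_e.copy(), self.phi.copy(), self.D_e)


def initial_fields(config: PNPConfig) -> PNPFields:
    """Cation-free film with uniform electron contact concentration."""
    n = config.n_grid
    return PNPFields(
        x=config.x,
        C_n=np.zeros(n),
        C_e=np.full(n, config.C_e0),
        phi=np.zeros(n),
        D_e=1e-17,
    )


# ---------------------------------------------------------------------------
# Poisson
# ---------------------------------------------------------------------------


def solve_poisson(C_n, C_e, boundary_potentials, config: PNPConfig) -> np.ndarray:
    """Solve -phi'' = e/(eps0 epsr) (z_e C_e + z_n C_n) with Dirichlet ends."""
    C_n = np.asarray(C_n, dtype=float)
    C_e = np.asarray(C_e, dtype=float)
    n = C_n.size
    if n < 3:
        raise ConfigurationError(f"Poisson solve needs >= 3 nodes, got {n}")
    phi0, phiL = boundary_potentials
    if not (np.isfinite(phi0) and np.isfinite(phiL)):
        raise DomainError("boundary potentials must be finite")
    h = config.L / (n - 1)
    rho = (
        config.coupling_scale
        * E_CHARGE
        / (EPS_0 * config.eps_r)
        * (config.z_e * C_e + config.z_n * C_n)
    )
    # interior nodes: (phi[i-1] - 2 phi[i] + phi[i+1])/h^2 = -rho[i]
    m = n - 2
    ab = np.zeros((3, m))
    ab[0, 1:] = 1.0
    ab[1, :] = -2.0
    ab[2, :-1] = 1.0
    rhs = -rho[1:-1] * h * h
    rhs[0] -= phi0
    rhs[-1] -= phiL
    phi = np.empty(n)
    phi[0], phi[-1] = phi0, phiL
    phi[1:-1] = solve_banded((1, 1), ab, rhs)
    return phi


# ---------------------------------------------------------------------------
# Scharfetter--Gummel transport
# ---------------------------------------------------------------------------


def _bernoulli(x: np.ndarray) -> np.ndarray:
    """B(x) = x / (exp(x) - 1), stable near 0."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = np.abs(x) < 1e-10
    out[small] = 1.0 - x[small] / 2.0
    xs = x[~small]
    out[~small] = xs / np.expm1(xs)
    return out


def _sg_flux(C: np.ndarray, psi: np.ndarray, D: float, z: int, h: float) -> np.ndarray:
    """Edge fluxes J_{i+1/2} = (D/h) [C_i B(z dpsi) - C_{i+1} B(-z dpsi)]."""
    dpsi = z * np.diff(psi)
    return (D / h) * (C[:-1] * _bernoulli(dpsi) - C[1:] * _bernoulli(-dpsi))


def _implicit_species_step(
    C_old: np.ndarray,
    psi: np.ndarray,
    D: float,
    z: int,
    dt: float,
    h: float,
    bc_left: tuple[str, float],
    bc_right: tuple[str, float],
) -> np.ndarray:
    """One backward-Euler step for one species at frozen potential.

    ``bc_*`` is ``("dirichlet", value)`` or ``("noflux", 0)``.  Finite-volume
    assembly (half cells at the boundaries) keeps mass exactly conserved
    under no-flux boundaries.
    """
    n = C_old.size
    dpsi = z * np.diff(psi)
    bp = _bernoulli(dpsi)  # weight on C_i      in J_{i+1/2}
    bm = _bernoulli(-dpsi)  # weight on C_{i+1}  in J_{i+1/2}
    r = D * dt / (h * h)

    lower = np.zeros(n)
    diag = np.zeros(n)
    upper = np.zeros(n)
    rhs = C_old.copy()

    # interior: C_i + (dt/h)(J_{i+1/2} - J_{i-1/2}) = C_i^old
    diag[1:-1] = 1.0 + r * (bp[1:] + bm[:-1])
    upper[2:] = -r * bm[1:]
    lower[:-2] = -r * bp[:-1]

    kind_l, val_l = bc_left
    if kind_l == "dirichlet":
        diag[0] = 1.0
        upper[1] = 0.0
        rhs[0] = val_l
    elif kind_l == "noflux":
        # half cell: C_0 + (2 dt/h) J_{1/2} = C_0^old
        diag[0] = 1.0 + 2.0 * r * bp[0]
        upper[1] = -2.0 * r * bm[0]
    else:  # pragma: no cover
        raise ConfigurationError(f"unknown boundary kind {kind_l!r}")

    kind_r, val_r = bc_right
    if kind_r == "dirichlet":
        diag[-1] = 1.0
        lower[-2] = 0.0
        rhs[-1] = val_r
    elif kind_r == "noflux":
        diag[-1] = 1.0 + 2.0 * r * bm[-1]
        lower[-2] = -2.0 * r * bp[-1]
    else:  # pragma: no cover
        raise ConfigurationError(f"unknown boundary kind {kind_r!r}")

    ab = np.zeros((3, n))
    ab[0, 1:] = upper[1:]
    ab[1, :] = diag
    ab[2, :-1] = lower[:-1]
    C_new = solve_banded((1, 1), ab, rhs)
    return np.maximum(C_new, 0.0)


def _ion_boundaries(config: PNPConfig, V_applied: float):
    if config.ion_bc == "sealed":
        return ("noflux", 0.0), ("noflux", 0.0)
    if config.injection_enabled and V_applied < -config.V_on:
        left = ("dirichlet", config.C0)
    else:
        left = ("dirichlet", 0.0)
    return left, ("noflux", 0.0)


def step_transport(
    fields: PNPFields,
    V_applied: float,
    t: float,
    dt: float,
    sched: DiffusionSchedule | None,
    config: PNPConfig,
    D_e: float | None = None,
) -> PNPFields:
    """Advance the coupled system by one backward-Euler step.

    The Gummel loop alternates a Poisson solve (from the current iterate of
    the concentrations) with implicit transport solves for both species until
    the relative change of all fields drops below ``gummel_tol``.
    """
    if D_e is None:
        if sched is None:
            raise ConfigurationError("either sched or D_e must be given")
        D_e = diffusion_coefficient(t, sched)
    bc_ion = _ion_boundaries(config, V_applied)
    bc_e = (("dirichlet", config.C_e0), ("dirichlet", config.C_e0))
    beta_e = config.beta * E_CHARGE
    h = config.h

    C_n, C_e = fields.C_n, fields.C_e
    C_n_it, C_e_it = C_n.copy(), C_e.copy()
    phi_it = fields.phi.copy()
    history = []
    scale_n = max(float(np.max(np.abs(C_n_it))), config.C0, 1.0)
    scale_e = max(float(np.max(np.abs(C_e_it))), config.C_e0, 1.0)
    omega = 1.0  # adaptive under-relaxation for stiff Poisson coupling
    for _ in range(config.gummel_maxiter):
        phi_new = solve_poisson(C_n_it, C_e_it, (0.0, V_applied), config)
        psi = beta_e * phi_new
        C_n_new = _implicit_species_step(C_n, psi, config.D_n, config.z_n, dt, h, *bc_ion)
        C_e_new = _implicit_species_step(C_e, psi, D_e, config.z_e, dt, h, *bc_e)
        res = max(
            float(np.max(np.abs(C_n_new - C_n_it))) / scale_n,
            float(np.max(np.abs(C_e_new - C_e_it))) / scale_e,
            float(np.max(np.abs(phi_new - phi_it))) / max(abs(V_applied), 0.0257),
        )
        if history and res > 0.7 * history[-1]:
            omega = max(omega * 0.5, 0.05)
        elif history and res < 0.2 * history[-1]:
            omega = min(omega * 1.5, 1.0)
        history.append(res)
        C_n_it = (1.0 - omega) * C_n_it + omega * C_n_new
        C_e_it = (1.0 - omega) * C_e_it + omega * C_e_new
        phi_it = (1.0 - omega) * phi_it + omega * phi_new
        if res < config.gummel_tol:
            C_n_it, C_e_it, phi_it = C_n_new, C_e_new, phi_new
            break
    else:
        raise SolverError(
            f"Gummel iteration did not converge in {config.gummel_maxiter} "
            f"iterations (last residual {history[-1]:.3e})",
            residual_history=history,
        )
    return PNPFields(fields.x, C_n_it, C_e_it, phi_it, D_e)


def junction_current(
    fields: PNPFields,
    V_applied: float,
    config: PNPConfig,
    D_e: float | None = None,
) -> float:
    """Terminal current from the discrete electron flux at x = L.

    Uses the same Scharfetter--Gummel edge flux as the transport step on the
    last edge; the sign convention makes the potentiation (negative-bias)
    current positive.
    """
    D_e = fields.D_e if D_e is None else D_e
    psi = config.beta * E_CHARGE * fields.phi
    flux = _sg_flux(fields.C_e, psi, D_e, config.z_e, config.h)
    # current density j = z_e * e * J_e; at z_e = -1 a leftward electron flux
    # (negative bias at x = L) gives a positive terminal current
    return float(config.z_e * E_CHARGE * flux[-1] * config.junction_area)


def total_ion_content(fields: PNPFields, config: PNPConfig) -> float:
    """Trapezoidal integral of C_n over the film (finite-volume mass)."""
    h = config.h
    w = np.full(fields.C_n.size, h)
    w[0] = w[-1] = h / 2.0
    return float(np.sum(w * fields.C_n))


def simulate_potentiation_depression(
    config: PNPConfig,
    sched: DiffusionSchedule,
    V_pot: float = -1.3,
    t_pot: float = 0.5,
    V_dep: float = 0.1,
    t_dep: float = 1.0,
    scale_schedule_with_voltage: bool = True,
) -> tuple[CurrentTrace, CurrentTrace]:
    """Simulate a potentiation pulse followed by a depression pulse.

    Returns ``(potentiation_trace, depression_trace)``; the depression trace
    records |I| (the depression-bias current magnitude) on absolute time.
    With ``injection_enabled=False`` the electron schedule is frozen at its
    baseline value ``A`` (no cations -> no hopping enhancement) and both
    traces are flat after the initial contact transient.
    """
    if t_pot > 0 and not (V_pot < 0 < V_dep):
        raise DomainError("polarity convention requires V_pot < 0 < V_dep")
    sched = replace(sched, t_p=t_pot, t_d=t_dep)
    scaled = False
    if config.injection_enabled and scale_schedule_with_voltage and t_pot > 0:
        sched = sched.for_voltage(V_pot, V_on=config.V_on)
        scaled = True
    fields = initial_fields(config)
    dt = config.dt
    meta = {
        "model": "pnp-1d",
        "schedule": {k: getattr(sched, k) for k in ("A", "B", "a", "b", "c", "t_p", "t_d")},
        "voltage_scaled_schedule": scaled,
        "injection_enabled": config.injection_enabled,
        "V_pot": V_pot,
        "V_dep": V_dep,
    }

    # the schedule models cation-enhanced hopping: without injection, or
    # without any potentiation phase, the electron coefficient stays at A
    use_schedule = config.injection_enabled and t_pot > 0

    def run_phase(V, t0, t1):
        times, currents = [], []
        nonlocal fields
        t = t0
        while t < t1 - 1e-12:
            t_new = min(t + dt, t1)
            if use_schedule:
                d_e = diffusion_coefficient(min(t_new, sched.t_end), sched)
            else:
                d_e = sched.A
            fields = step_transport(fields, V, t_new, t_new - t, None, config, D_e=d_e)
            times.append(t_new)
            currents.append(junction_current(fields, V, config))
            t = t_new
        return np.array(times), np.array(currents)

    if t_pot > 0:
        t_a, i_a = run_phase(V_pot, 0.0, t_pot)
        pot = CurrentTrace(t_a, i_a, {**meta, "phase": "potentiation"})
    else:
        pot = CurrentTrace(np.array([0.0]), np.array([0.0]), {**meta, "phase": "potentiation"})
    t_b, i_b = run_phase(V_dep, t_pot, t_pot + t_dep)
    dep = CurrentTrace(t_b, np.abs(i_b), {**meta, "phase": "depression"})
    return pot, dep


def voltage_sweep_relaxation(
    config: PNPConfig,
    base_sched: DiffusionSchedule,
    V_list,
    t_pot: float = 0.5,
    V_dep: float = 0.1,
    t_dep: float = 1.0,
) -> pd.DataFrame:
    """Per-voltage depression traces fitted by the double exponential.

    Returns a table with columns ``V, tau1, tau2, fit_ok, message``; fit
    failures are flagged per row and the sweep continues.
    """
    from molsynapse.plasticity import fit_double_exponential

    V_list = list(V_list)
    if any(v >= 0 for v in V_list):
        raise DomainError("all sweep voltages must be negative (potentiation bias)")
    rows = []
    for V in V_list:
        try:
            _, dep = simulate_potentiation_depression(
                config, base_sched, V_pot=V, t_pot=t_pot, V_dep=V_dep, t_dep=t_dep
            )
            fit = fit_double_exponential(dep)
            rows.append(
                {
                    "V": V,
                    "tau1": fit.tau1,
                    "tau2": fit.tau2,
                    "residual_rms": fit.residual_rms,
                    "fit_ok": not fit.degenerate,
                    "message": "degenerate fit" if fit.degenerate else "",
                }
            )
        except (SolverError, DomainError, Exception) as exc:  # noqa: BLE001 - row-level isolation
            if isinstance(exc, KeyboardInterrupt):
                raise
            rows.append(
                {
                    "V": V,
                    "tau1": np.nan,
                    "tau2": np.nan,
                    "residual_rms": np.nan,
                    "fit_ok": False,
                    "message": f"{type(exc).__name__}: {exc}",
                }
            )
    return pd.DataFrame(rows)
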