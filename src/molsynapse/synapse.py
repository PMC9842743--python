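"""Phenomenological two-timescale synapse surrogate.

A lumped stand-in for the physical junction: a fast weight (chemical gating
by free cations, ~150 ms) and a slow weight (cation coordination, ~80 s)
relax exponentially and are pumped by supra-threshold bias.  Negative bias
beyond the threshold potentiates; positive bias beyond it depresses.  This
surrogate feeds the plasticity fitters with synthetic data and serves as the
physical node of the reservoir-computing pipeline.  It makes no claim of
microscopic fidelity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from molsynapse.errors import DomainError
from molsynapse.signals import CurrentTrace, VoltageProtocol

# Gains calibrated (bisection, once) so that a single (-1 V, 1 s) write pulse
# from rest yields a total weight change of ~0.4, split 3:1 fast:slow:
#   alpha_fast * 0.7 * tau_f * (1 - e^(-1/tau_f)) = 0.30
#   alpha_slow * 0.7 * tau_s * (1 - e^(-1/tau_s)) = 0.10
ALPHA_FAST_DEFAULT = 2.8607
ALPHA_SLOW_DEFAULT = 0.14377


@dataclass(frozen=True)
class SynapseParams:
    g0: float = 2e-9  # S, baseline conductance
    tau_fast: float = 0.15  # s
    tau_slow: float = 80.0  # s
    V_th: float = 0.3  # V, |bias| threshold for weight updates
    alpha_fast: float = ALPHA_FAST_DEFAULT  # weight gain per (V s) above threshold
    alpha_slow: float = ALPHA_SLOW_DEFAULT
    w_max: float = 5.0
    noise_sigma: float = 0.0  # relative multiplicative current noise
    seed: int = 0

    def __post_init__(self):
        if not (self.tau_fast < self.tau_slow):
            raise DomainError("tau_fast must be < tau_slow")
        if not (self.V_th > 0):
            raise DomainError("V_th must be > 0")
        if self.alpha_fast < 0 or self.alpha_slow < 0:
            raise DomainError("gains must be >= 0")
        if not (0 <= self.noise_sigma < 1):
            raise DomainError("noise_sigma must be in [0, 1)")
        if not (self.w_max > 0):
            raise DomainError("w_max must be > 0")


def device_default_params(**overrides) -> SynapseParams:
    """The shipped preset: defaults anchored to the measured device scales."""
    return replace(SynapseParams(noise_sigma=0.01), **overrides)


@dataclass
class SynapseState:
    w_fast: float = 0.0
    w_slow: float = 0.0
    t_now: float = 0.0


def _weight_update(w_fast, w_slow, V, dt, p):
    """Shared scalar/vector weight update; returns new (w_fast, w_slow)."""
    w_fast = w_fast * math.exp(-dt / p.tau_fast) if np.isscalar(w_fast) else w_fast * np.exp(-dt / p.tau_fast)
    w_slow = w_slow * math.exp(-dt / p.tau_slow) if np.isscalar(w_slow) else w_slow * np.exp(-dt / p.tau_slow)
    drive_pot = np.maximum(-V - p.V_th, 0.0) * (np.asarray(V) < -p.V_th)
    drive_dep = np.maximum(V - p.V_th, 0.0) * (np.asarray(V) > p.V_th)
    w_fast = np.maximum(w_fast + p.alpha_fast * dt * (drive_pot - drive_dep), 0.0)
    w_slow = np.maximum(w_slow + p.alpha_slow * dt * (drive_pot - drive_dep), 0.0)
    total = w_fast + w_slow
    over = total > p.w_max
    if np.any(over):
        scale = np.where(over, p.w_max / np.maximum(total, 1e-300), 1.0)
        w_fast = w_fast * scale
        w_slow = w_slow * scale
    return w_fast, w_slow


def step(
    state: SynapseState,
    V: float,
    dt: float,
    params: SynapseParams,
    rng: np.random.Generator | None = None,
) -> tuple[SynapseState, float]:
    """Advance the synapse by ``dt`` under constant bias ``V``.

    Both weights decay exponentially; supra-threshold bias adds (negative V)
    or removes (positive V, floored at 0) weight in proportion to
    ``(|V| - V_th) * dt``.  Returns the new state and the instantaneous
    current ``g0 * (1 + w_fast + w_slow) * V * (1 + noise)``.
    """
    if not (dt > 0):
        raise DomainError(f"dt must be > 0, got {dt}")
    w_fast, w_slow = _weight_update(state.w_fast, state.w_slow, V, dt, params)
    noise = 0.0
    if params.noise_sigma > 0:
        if rng is None:
            raise DomainError("noise_sigma > 0 requires an rng")
        noise = params.noise_sigma * rng.standard_normal()
    current = params.g0 * (1.0 + w_fast + w_slow) * V * (1.0 + noise)
    new_state = SynapseState(float(w_fast), float(w_slow), state.t_now + dt)
    return new_state, float(current)


def step_many(
    w_fast: np.ndarray,
    w_slow: np.ndarray,
    V: np.ndarray,
    dt: float,
    params: SynapseParams,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized :func:`step` over many independent devices (reservoir nodes)."""
    w_fast, w_slow = _weight_update(np.asarray(w_fast, float), np.asarray(w_slow, float), np.asarray(V, float), dt, params)
    noise = 0.0
    if params.noise_sigma > 0:
        if rng is None:
            raise DomainError("noise_sigma > 0 requires an rng")
        noise = params.noise_sigma * rng.standard_normal(np.shape(w_fast))
    current = params.g0 * (1.0 + w_fast + w_slow) * np.asarray(V, float) * (1.0 + noise)
    return w_fast, w_slow, current


def run_protocol(
    protocol: VoltageProtocol,
    params: SynapseParams,
    initial_state: SynapseState | None = None,
) -> CurrentTrace:
    """Drive the surrogate through a sampled protocol; seeded and reproducible."""
    t, v = protocol.sample()
    dt = 1.0 / protocol.sample_rate
    rng = np.random.default_rng(params.seed)
    state = initial_state or SynapseState()
    current = np.empty_like(v)
    wf, ws = state.w_fast, state.w_slow
    decay_f = math.exp(-dt / params.tau_fast)
    decay_s = math.exp(-dt / params.tau_slow)
    noise_draws = (
        params.noise_sigma * rng.standard_normal(v.size) if params.noise_sigma > 0 else None
    )
    for k in range(v.size):
        vk = v[k]
        wf *= decay_f
        ws *= decay_s
        if vk < -params.V_th:
            drive = (-vk - params.V_th) * dt
            wf += params.alpha_fast * drive
            ws += params.alpha_slow * drive
        elif vk > params.V_th:
            drive = (vk - params.V_th) * dt
            wf = max(wf - params.alpha_fast * drive, 0.0)
            ws = max(ws - params.alpha_slow * drive, 0.0)
        total = wf + ws
        if total > params.w_max:
            scale = params.w_max / total
            wf *= scale
            ws *= scale
        noise = noise_draws[k] if noise_draws is not None else 0.0
        current[k] = params.g0 * (1.0 + wf + ws) * vk * (1.0 + noise)
    meta = {
        "model": "two-timescale synapse surrogate",
        "seed": params.seed,
        "noise_sigma": params.noise_sigma,
        "rng": "numpy default_rng",
    }
    return CurrentTrace(t, current, meta)


# ---------------------------------------------------------------------------
# spike-timing-dependent plasticity
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StdpSpike:
    """Shape of one pre/post spike as seen between the two terminals.

    Each spike is a head pulse at exactly the threshold amplitude followed by
    a sub-threshold exponential tail of opposite sign.  Neither feature alone
    crosses the update threshold; only the superposition of one spike's head
    with the other spike's decaying tail does, which yields an exponential
    timing dependence with time constant ``tail_tau``.
    """

    head_amp: float = 0.3  # V (== default V_th: alone it never crosses)
    head_width: float = 0.05  # s
    tail_amp: float = 0.25  # V, must stay below V_th on its own
    tail_tau: float = 0.4  # s
    tail_span: float = 2.0  # s of simulated tail

    def waveform(self, t: np.ndarray, t0: float) -> np.ndarray:
        """Spike contribution at times ``t`` for a spike fired at ``t0``."""
        rel = t - t0
        head = (rel >= 0) & (rel < self.head_width)
        tail = (rel >= self.head_width) & (rel < self.head_width + self.tail_span)
        out = np.zeros_like(t)
        out[head] = self.head_amp
        out[tail] = -self.tail_amp * np.exp(-(rel[tail] - self.head_width) / self.tail_tau)
        return out


def stdp_response(
    delta_t: float,
    params: SynapseParams,
    spike: StdpSpike | None = None,
    read_voltage: float = 0.15,
    read_offset: float = 10.0,
    read_window: float = 0.5,
    dt: float = 0.005,
    w_slow_init: float = 1.0,
) -> float:
    """Net weight change for a pre/post spike pair separated by ``delta_t``.

    ``delta_t = t_pre - t_post``: negative values (pre fires first) potentiate,
    positive values depress, with |dwt| decaying exponentially in |delta_t|.
    The device voltage is the terminal difference ``spike(pre) - spike(post)``,
    read at ``read_voltage`` ``read_offset`` s before and after the pair.  The
    intrinsic relaxation of the pre-conditioned slow weight is removed by
    subtracting an identical spike-free reference run.
    """
    if delta_t == 0:
        raise DomainError("delta_t = 0: spike order undefined")
    spike = spike or StdpSpike()
    if spike.tail_amp >= params.V_th:
        raise DomainError("spike tail_amp must stay below V_th on its own")
    t_c = read_offset + read_window + 1.0  # spike-pair centre
    t_pre = t_c + delta_t / 2.0
    t_post = t_c - delta_t / 2.0
    t_end = t_c + read_offset + read_window + 0.5
    t = np.arange(0.0, t_end, dt)

    def run(with_spikes: bool) -> CurrentTrace:
        v = np.full_like(t, read_voltage)
        if with_spikes:
            net = spike.waveform(t, t_pre) - spike.waveform(t, t_post)
            active = net != 0.0
            v[active] = net[active]
        state = SynapseState(w_fast=0.0, w_slow=w_slow_init)
        current = np.empty_like(v)
        wf, ws = state.w_fast, state.w_slow
        for k in range(v.size):
            wf, ws = _weight_update(wf, ws, float(v[k]), dt, params)
            current[k] = params.g0 * (1.0 + wf + ws) * read_voltage  # read-bias current
        return CurrentTrace(t, current)

    from molsynapse.plasticity import stdp_weight_change

    dwt = stdp_weight_change(run(True), t_c, read_offset, read_window)
    dwt_null = stdp_weight_change(run(False), t_c, read_offset, read_window)
    return dwt - dwt_null
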