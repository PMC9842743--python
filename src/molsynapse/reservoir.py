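"""Mask-encoded physical reservoir computing with synapse-surrogate nodes.

Sine/square waveform classification in four steps: sample each waveform,
expand every sample into ``ML`` voltage pulses through a fixed random +-1
mask (one mask per node), drive the node dynamics and collect the per-pulse
currents, and train an ordinary least-squares readout on the concatenated
current vector of each waveform.  The reservoir size ``M x N`` (mask length
times node count) is held fixed when sweeping the mask length.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from molsynapse.errors import ConfigurationError, DomainError
from molsynapse.synapse import SynapseParams, step_many


@dataclass
class WaveformDataset:
    """Random sine/square sequences; labels 1 = sine, 0 = square."""

    samples_train: np.ndarray  # (n_train, S)
    labels_train: np.ndarray
    samples_test: np.ndarray  # (n_test, S)
    labels_test: np.ndarray
    seed: int


def sine_waveform(samples_per_waveform: int = 8) -> np.ndarray:
    k = np.arange(samples_per_waveform)
    return np.sin(2.0 * np.pi * k / samples_per_waveform)


def square_waveform(samples_per_waveform: int = 8) -> np.ndarray:
    k = np.arange(samples_per_waveform)
    return np.sign(np.sin(2.0 * np.pi * (k + 0.5) / samples_per_waveform))


def generate_dataset(
    n_train: int,
    n_test: int,
    samples_per_waveform: int = 8,
    seed: int = 0,
) -> WaveformDataset:
    """Seeded random mixtures of single-period sine and square waveforms."""
    if n_train < 1 or n_test < 1:
        raise DomainError("dataset sizes must be >= 1")
    rng = np.random.default_rng(seed)
    sine = sine_waveform(samples_per_waveform)
    square = square_waveform(samples_per_waveform)

    def make(n):
        labels = rng.integers(0, 2, size=n)
        samples = np.where(labels[:, None] == 1, sine[None, :], square[None, :])
        return samples.astype(float), labels.astype(int)

    s_tr, l_tr = make(n_train)
    s_te, l_te = make(n_test)
    return WaveformDataset(s_tr, l_tr, s_te, l_te, seed)


@dataclass(frozen=True)
class Mask:
    """A fixed random +-1 vector expanding one sample into ML pulses."""

    entries: tuple

    def __post_init__(self):
        if len(self.entries) < 1:
            raise DomainError("mask length must be >= 1")
        if any(e not in (1, -1) for e in self.entries):
            raise DomainError("mask entries must be +1 or -1")

    def __len__(self):
        return len(self.entries)

    def as_array(self) -> np.ndarray:
        return np.array(self.entries, dtype=float)


def make_mask(ML: int, seed=0) -> Mask:
    """Uniform random +-1 vector of length ``ML`` (fixed per RC unit)."""
    if ML < 1:
        raise DomainError(f"mask length must be >= 1, got {ML}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return Mask(tuple(int(v) for v in rng.choice([1, -1], size=ML)))


def default_bias_map(u: np.ndarray) -> np.ndarray:
    """Masked value u in [-1, 1] -> pulse amplitude -(0.5 + 0.5 u) volts."""
    return -(0.5 + 0.5 * np.asarray(u, dtype=float))


def encode_to_voltages(samples: np.ndarray, mask: Mask, bias_map=default_bias_map,
                       safe_range: tuple[float, float] = (-1.5, 1.5)) -> np.ndarray:
    """Expand each sample into ``len(mask)`` pulse amplitudes via the mask."""
    samples = np.asarray(samples, dtype=float).ravel()
    masked = (samples[:, None] * mask.as_array()[None, :]).ravel()
    volts = np.asarray(bias_map(masked), dtype=float)
    lo, hi = safe_range
    if np.any(volts < lo) or np.any(volts > hi):
        raise DomainError(
            f"bias_map produced amplitudes outside the device-safe range {safe_range}"
        )
    return volts


@dataclass(frozen=True)
class ReservoirConfig:
    mask_length: int = 2  # M
    n_nodes: int = 20  # N
    fixed_size: int = 40  # M*N held fixed during sweeps
    node_params: SynapseParams = field(default_factory=lambda: SynapseParams(noise_sigma=0.01))
    pulse_width: float = 0.01  # s
    samples_per_waveform: int = 8
    n_train: int = 250
    n_test: int = 250
    ridge: float = 0.0  # optional Tikhonov strength for the readout
    # relative singular-value cutoff of the least-squares solve; +-1 masks
    # repeat across nodes, so the noiseless design is exactly rank-deficient
    # and the cutoff keeps read noise out of the null directions
    rcond: float | None = 1e-2
    seed: int = 0

    def __post_init__(self):
        if self.mask_length < 1 or self.n_nodes < 1:
            raise ConfigurationError("mask_length and n_nodes must be >= 1")
        if not (self.pulse_width > 0):
            raise ConfigurationError("pulse_width must be > 0")


@dataclass
class RCResult:
    readout_weights: np.ndarray  # includes trailing intercept
    train_output: np.ndarray
    test_output: np.ndarray
    train_labels: np.ndarray
    test_labels: np.ndarray
    nrmse: float
    accuracy: float  # percent, on the test set
    rank_deficient: bool
    meta: dict = field(default_factory=dict)


def collect_states(
    samples: np.ndarray,
    masks: np.ndarray,
    config: ReservoirConfig,
    rng: np.random.Generator,
    bias_map=default_bias_map,
) -> np.ndarray:
    """Drive all nodes through a waveform sequence; per-waveform features.

    ``samples`` is ``(n_waveforms, S)``; ``masks`` is ``(N, ML)``.  Device
    state is carried across consecutive waveforms (fading memory), not reset
    per waveform.  Returns ``(n_waveforms, N * S * ML)`` pulse currents.
    """
    n_wave, S = samples.shape
    N, ML = masks.shape
    p = config.node_params
    dt = config.pulse_width
    w_fast = np.zeros(N)
    w_slow = np.zeros(N)
    feats = np.empty((n_wave, S * ML, N))
    for i in range(n_wave):
        for k in range(S):
            s = samples[i, k]
            for j in range(ML):
                volts = bias_map(s * masks[:, j])
                w_fast, w_slow, current = step_many(w_fast, w_slow, volts, dt, p, rng)
                feats[i, k * ML + j, :] = current
    return feats.reshape(n_wave, S * ML * N)


def train_readout(
    states: np.ndarray,
    labels: np.ndarray,
    ridge: float = 0.0,
    rcond: float | None = None,
):
    """OLS (minimum-norm on rank deficiency) readout with intercept.

    Features are centred and scaled internally (the current vector lives on
    the ampere scale) and the affine transform is folded back into the
    returned weights, so ``readout_apply`` uses raw states.  ``rcond``
    truncates relative singular values below the cutoff (noise-robust
    minimum-norm solution); ``ridge`` switches to Tikhonov regression with a
    strength relative to the mean feature power.

    Returns ``(weights, rank_deficient)``; ``weights[-1]`` is the intercept.
    """
    labels = np.asarray(labels, dtype=float)
    if np.unique(labels).size < 2:
        w = np.zeros(states.shape[1] + 1)
        w[-1] = labels[0] if labels.size else 0.0
        return w, True
    mean = states.mean(axis=0)
    centred = states - mean
    scale = float(np.sqrt(np.mean(centred**2)))
    if scale == 0:
        scale = 1.0
    Z = centred / scale
    if ridge > 0:
        ztz = Z.T @ Z
        reg = ridge * max(np.trace(ztz) / Z.shape[1], 1e-300) * np.eye(Z.shape[1])
        wz = np.linalg.solve(ztz + reg, Z.T @ (labels - labels.mean()))
        rank_deficient = False
    else:
        wz, _, rank, _ = np.linalg.lstsq(Z, labels - labels.mean(), rcond=rcond)
        rank_deficient = bool(rank < Z.shape[1])
    w = np.empty(states.shape[1] + 1)
    w[:-1] = wz / scale
    w[-1] = labels.mean() - mean @ w[:-1]
    return w, rank_deficient


def readout_apply(states: np.ndarray, weights: np.ndarray) -> np.ndarray:
    return states @ weights[:-1] + weights[-1]


def evaluate(y: np.ndarray, y_target: np.ndarray) -> tuple[float, float]:
    """(NRMSE, accuracy %) with target-variance normalization and 0.5 threshold."""
    y = np.asarray(y, dtype=float)
    y_target = np.asarray(y_target, dtype=float)
    var = float(np.var(y_target))
    if var == 0:
        raise DomainError("zero-variance target: NRMSE undefined")
    nrmse = float(np.sqrt(np.mean((y - y_target) ** 2) / var))
    accuracy = float(np.mean((y >= 0.5).astype(int) == y_target.astype(int)) * 100.0)
    return nrmse, accuracy


def run_rc(config: ReservoirConfig, dataset: WaveformDataset | None = None) -> RCResult:
    """Full pipeline: dataset -> masks -> states -> readout -> evaluation."""
    rng = np.random.default_rng(config.seed)
    if dataset is None:
        dataset = generate_dataset(
            config.n_train, config.n_test, config.samples_per_waveform,
            seed=int(rng.integers(2**31)),
        )
    masks = np.stack(
        [make_mask(config.mask_length, rng).as_array() for _ in range(config.n_nodes)]
    )
    noise_rng_train = np.random.default_rng(config.seed + 1)
    noise_rng_test = np.random.default_rng(config.seed + 2)
    states_train = collect_states(dataset.samples_train, masks, config, noise_rng_train)
    states_test = collect_states(dataset.samples_test, masks, config, noise_rng_test)
    weights, rank_deficient = train_readout(
        states_train, dataset.labels_train, config.ridge, config.rcond
    )
    y_train = readout_apply(states_train, weights)
    y_test = readout_apply(states_test, weights)
    nrmse, accuracy = evaluate(y_test, dataset.labels_test)
    meta = {
        "mask_length": config.mask_length,
        "n_nodes": config.n_nodes,
        "state_carry": "across waveforms within a sequence (no per-waveform reset)",
        "seed": config.seed,
    }
    return RCResult(
        readout_weights=weights,
        train_output=y_train,
        test_output=y_test,
        train_labels=dataset.labels_train,
        test_labels=dataset.labels_test,
        nrmse=nrmse,
        accuracy=accuracy,
        rank_deficient=rank_deficient,
        meta=meta,
    )


def sweep_mask_length(
    config: ReservoirConfig,
    ML_list,
    n_seeds: int = 10,
) -> pd.DataFrame:
    """Fixed-size (M*N) sweep over mask lengths with replicate seeds.

    Every ``ML`` must divide ``config.fixed_size``; ``N = fixed_size / ML``.
    Returns one row per (ML, seed) with columns ``ML, N, seed, nrmse,
    accuracy``.
    """
    ML_list = list(ML_list)
    for ml in ML_list:
        if ml < 1 or config.fixed_size % ml != 0:
            raise ConfigurationError(
                f"mask length {ml} does not divide fixed reservoir size "
                f"{config.fixed_size}"
            )
    rows = []
    for ml in ML_list:
        n_nodes = config.fixed_size // ml
        for s in range(n_seeds):
            cfg = replace(config, mask_length=ml, n_nodes=n_nodes, seed=config.seed + 7919 * s)
            res = run_rc(cfg)
            rows.append(
                {"ML": ml, "N": n_nodes, "seed": cfg.seed, "nrmse": res.nrmse,
                 "accuracy": res.accuracy}
            )
    return pd.DataFrame(rows)
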