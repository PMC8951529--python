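"""Synthetic neck-collar accelerometer traces with ground-truth behaviour labels.

The simulator stands in for the collar + halter recordings: 18 steers across
3 farm trials, a 10 Hz y-axis (vertical) acceleration channel and a paired
10 Hz behaviour-label stream. Each behaviour has a distinct signature:

* **rumination** — a narrowband oscillation near 3 Hz (rhythmic jaw motion);
  the bout frequency wanders within ``rumination_freq +- rumination_bandwidth``
  so band amplitude, not a fixed-lag autocorrelation, is the stable marker;
* **eating** — broadband noise with a slow burst envelope (tearing/chewing),
  i.e. a comparatively flat spectrum;
* **other** — a low-power noise baseline.

Collar placement varies between animals: each steer gets a multiplicative
lognormal gain and an additive offset. Traces are clipped to the sensor range
(default +-2 g) and can optionally be quantised to 12 bits.

All randomness is derived from ``SimConfig.seed`` through per-steer,
per-purpose ``numpy.random.SeedSequence`` streams, so outputs are
byte-identical for identical configurations.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .states import LABELS, STATES

logger = logging.getLogger(__name__)

_STATE_NAMES = list(LABELS)


def _default_transition_weights() -> np.ndarray:
    # zero diagonal, uniform switching between the other two states
    return np.ones((3, 3)) - np.eye(3)


@dataclass
class SimConfig:
    """Study conditions for the synthetic herd.

    Durations are seconds, accelerations g, frequencies Hz. Defaults emulate
    the study layout (18 steers in 3 trials, 10 Hz sampling, +-2 g range) at a
    desk-scale duration of 2 h per steer; behaviour bouts last minutes
    (exponential dwell, mean ``dwell_mean``, floor ``dwell_min``).
    """

    n_steers: int = 18
    n_trials: int = 3
    sampling_rate: float = 10.0
    duration: float = 7200.0
    dwell_mean: float = 300.0
    dwell_min: float = 30.0
    rumination_freq: float = 3.0
    rumination_bandwidth: float = 0.4
    rumination_amplitude: float = 0.3
    rumination_noise_power: float = 0.0025
    eating_noise_power: float = 0.09
    other_noise_power: float = 0.0025
    steer_gain_sd: float = 0.15
    steer_offset_sd: float = 0.05
    clip_g: float = 2.0
    quantize_12bit: bool = False
    transition_weights: np.ndarray = field(default_factory=_default_transition_weights)
    seed: int = 0

    def __post_init__(self) -> None:
        self.transition_weights = np.asarray(self.transition_weights, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.duration < 90.0:
            raise ValueError("duration must cover at least one 90 s block")
        if self.dwell_mean <= 0:
            raise ValueError("dwell_mean must be positive")
        if not (0 < self.dwell_min <= self.dwell_mean):
            raise ValueError("dwell_min must lie in (0, dwell_mean]")
        if self.n_steers < 1 or self.n_trials < 1 or self.n_steers < self.n_trials:
            raise ValueError("need at least one steer per trial")
        w = self.transition_weights
        if w.shape != (3, 3) or (w < 0).any() or np.diag(w).any():
            raise ValueError(
                "transition_weights must be 3x3 nonnegative with zero diagonal"
            )

    def steers(self) -> list[tuple[str, str]]:
        """Registered (steer_id, trial_id) pairs; trials assigned round-robin."""
        return [
            (f"steer{i + 1:02d}", f"trial{i % self.n_trials + 1}")
            for i in range(self.n_steers)
        ]

    def steer_index(self, steer_id: str) -> int:
        for i, (sid, _) in enumerate(self.steers()):
            if sid == steer_id:
                return i
        raise KeyError(f"steer {steer_id!r} is not registered in this config")

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        d["transition_weights"] = self.transition_weights.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        return cls(**d)


@dataclass
class LabelStream:
    """Per-sample behaviour labels on the same grid as the paired trace."""

    steer_id: str
    t: np.ndarray
    state: np.ndarray  # array of label strings

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.state = np.asarray(self.state, dtype=object)
        if len(self.t) != len(self.state):
            raise ValueError("t and state must have equal length")


@dataclass
class AccelTrace:
    """One steer's y-axis acceleration series on a uniform grid."""

    steer_id: str
    trial_id: str
    t: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if len(self.t) != len(self.y):
            raise ValueError("t and y must have equal length")

    @property
    def sampling_rate(self) -> float:
        return 1.0 / (self.t[1] - self.t[0])


def _rng(config: SimConfig, steer_index: int, purpose: int) -> np.random.Generator:
    """Independent stream keyed by (seed, steer, purpose); reproducible."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=(int(config.seed), steer_index, purpose))
    )


def simulate_state_sequence(config: SimConfig, steer: str) -> LabelStream:
    """Draw a semi-Markov behaviour sequence for one steer.

    Bout dwell times are ``dwell_min + Exponential(dwell_mean - dwell_min)``
    so the mean dwell is exactly ``dwell_mean``. The next state is drawn from
    the row of ``transition_weights`` for the current state (rows normalised;
    zero-weight states never occur). The initial state is drawn proportionally
    to column weight mass, so forbidden states are never initial either.
    """
    idx = config.steer_index(steer)
    rng = _rng(config, idx, 0)
    fs = config.sampling_rate
    n = int(round(config.duration * fs))
    if config.duration < config.dwell_min:
        raise ValueError("duration is shorter than one minimum bout")

    w = config.transition_weights
    row_sums = w.sum(axis=1)
    col_mass = w.sum(axis=0)
    if col_mass.sum() <= 0:
        raise ValueError("transition_weights admit no reachable state")
    init_p = col_mass / col_mass.sum()

    state_codes = np.empty(n, dtype=np.int8)
    pos = 0
    current = int(rng.choice(3, p=init_p))
    while pos < n:
        dwell = config.dwell_min + rng.exponential(config.dwell_mean - config.dwell_min)
        length = max(1, int(round(dwell * fs)))
        state_codes[pos : pos + length] = current
        pos += length
        if row_sums[current] <= 0:
            # absorbing state: remain until the end of the recording
            state_codes[pos:] = current
            break
        current = int(rng.choice(3, p=w[current] / row_sums[current]))

    t = np.arange(n) / fs
    labels = np.array([_STATE_NAMES[c] for c in state_codes], dtype=object)
    return LabelStream(steer_id=steer, t=t, state=labels)


def _contiguous_runs(codes: np.ndarray):
    """Yield (start, stop, code) for each maximal constant run."""
    change = np.flatnonzero(np.diff(codes)) + 1
    bounds = np.concatenate(([0], change, [len(codes)]))
    for a, b in zip(bounds[:-1], bounds[1:]):
        yield int(a), int(b), int(codes[a])


def synth_trace(labels: LabelStream, config: SimConfig) -> AccelTrace:
    """Render the y-axis acceleration implied by a label stream.

    Segment signatures are drawn per bout; the per-steer collar gain/offset is
    applied afterwards and the result clipped to the sensor range.
    """
    idx = config.steer_index(labels.steer_id)
    rng = _rng(config, idx, 1)
    steer_rng = _rng(config, idx, 2)
    t = labels.t
    codes = np.array([_STATE_NAMES.index(s) for s in labels.state], dtype=np.int8)
    y = np.zeros_like(t)

    for a, b, code in _contiguous_runs(codes):
        seg_t = t[a:b]
        n = b - a
        name = _STATE_NAMES[code]
        if name == "rumination":
            f = rng.uniform(
                config.rumination_freq - config.rumination_bandwidth,
                config.rumination_freq + config.rumination_bandwidth,
            )
            phase = rng.uniform(0.0, 2.0 * np.pi)
            seg = config.rumination_amplitude * np.sin(2.0 * np.pi * f * seg_t + phase)
            if config.rumination_noise_power > 0:
                seg = seg + rng.normal(0.0, np.sqrt(config.rumination_noise_power), n)
        elif name == "eating":
            if config.eating_noise_power > 0:
                f_env = rng.uniform(0.3, 0.7)
                phase = rng.uniform(0.0, 2.0 * np.pi)
                env = 0.6 + 0.4 * np.abs(np.sin(2.0 * np.pi * f_env * seg_t + phase))
                seg = env * rng.normal(0.0, np.sqrt(config.eating_noise_power), n)
            else:
                seg = np.zeros(n)
        else:  # other: low-activity baseline
            if config.other_noise_power > 0:
                seg = rng.normal(0.0, np.sqrt(config.other_noise_power), n)
            else:
                seg = np.zeros(n)
        y[a:b] = seg

    gain = float(np.exp(steer_rng.normal(0.0, config.steer_gain_sd)))
    offset = float(steer_rng.normal(0.0, config.steer_offset_sd))
    y = np.clip(gain * y + offset, -config.clip_g, config.clip_g)
    if config.quantize_12bit:
        step = 2.0 * config.clip_g / 4095.0
        y = np.round(y / step) * step

    _, trial_id = config.steers()[idx]
    return AccelTrace(steer_id=labels.steer_id, trial_id=trial_id, t=t, y=y)


def generate_dataset(config: SimConfig) -> tuple[list[AccelTrace], list[LabelStream]]:
    """Simulate label streams and traces for every registered steer."""
    traces, labels = [], []
    for steer_id, _trial in config.steers():
        ls = simulate_state_sequence(config, steer_id)
        traces.append(synth_trace(ls, config))
        labels.append(ls)
    return traces, labels


# ---------------------------------------------------------------------------
# CSV dataset round-trip

_TRACE_COLUMNS = ["steer_id", "trial_id", "t_s", "acc_x_g", "acc_y_g", "acc_z_g"]
_LABEL_COLUMNS = ["steer_id", "t_s", "state"]
_XZ_NOISE_SD = 0.02  # x/z columns are format filler only; y carries the signal


def write_dataset(
    traces: list[AccelTrace],
    labels: list[LabelStream],
    path: str | Path,
    config: SimConfig | None = None,
) -> dict:
    """Write per-steer trace/label CSVs plus a manifest JSON; returns manifest."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    if len(traces) != len(labels):
        raise ValueError("traces and labels must be paired")
    manifest: dict = {"steers": {}, "files": {}}
    if config is not None:
        manifest["seed"] = int(config.seed)
        manifest["config"] = config.to_jsonable()
    for k, (trace, label) in enumerate(zip(traces, labels)):
        if trace.steer_id != label.steer_id or len(trace.t) != len(label.t):
            raise ValueError(f"trace/label mismatch for steer {trace.steer_id!r}")
        xz_rng = np.random.default_rng(
            np.random.SeedSequence(
                entropy=(0 if config is None else int(config.seed), k, 3)
            )
        )
        n = len(trace.t)
        df = pd.DataFrame(
            {
                "steer_id": trace.steer_id,
                "trial_id": trace.trial_id,
                "t_s": trace.t,
                "acc_x_g": xz_rng.normal(0.0, _XZ_NOISE_SD, n),
                "acc_y_g": trace.y,
                "acc_z_g": xz_rng.normal(0.0, _XZ_NOISE_SD, n),
            }
        )
        trace_file = f"trace_{trace.steer_id}.csv"
        label_file = f"labels_{trace.steer_id}.csv"
        df.to_csv(path / trace_file, index=False, float_format="%.6f")
        pd.DataFrame(
            {"steer_id": label.steer_id, "t_s": label.t, "state": label.state}
        ).to_csv(path / label_file, index=False, float_format="%.6f")
        manifest["steers"][trace.steer_id] = trace.trial_id
        manifest["files"][trace.steer_id] = {"trace": trace_file, "labels": label_file}
    with open(path / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def read_dataset(path: str | Path) -> tuple[list[AccelTrace], list[LabelStream]]:
    """Read a dataset directory written by :func:`write_dataset`."""
    path = Path(path)
    with open(path / "manifest.json") as fh:
        manifest = json.load(fh)
    traces, labels = [], []
    for steer_id in sorted(manifest["files"]):
        entry = manifest["files"][steer_id]
        tdf = pd.read_csv(path / entry["trace"])
        ldf = pd.read_csv(path / entry["labels"])
        traces.append(
            AccelTrace(
                steer_id=steer_id,
                trial_id=str(tdf["trial_id"].iloc[0]),
                t=tdf["t_s"].to_numpy(),
                y=tdf["acc_y_g"].to_numpy(),
            )
        )
        labels.append(
            LabelStream(
                steer_id=steer_id,
                t=ldf["t_s"].to_numpy(),
                state=ldf["state"].to_numpy(dtype=object),
            )
        )
    return traces, labels
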