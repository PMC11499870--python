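"""Seeded synthetic two-photon imaging experiments with known ground truth.

This module fabricates trial-structured fluorescence data with the same
shape as a chronic drifting-grating experiment in mouse V1: a set of
neurons imaged over several sessions (days apart), each session presenting
``n_directions`` grating directions ``n_reps`` times, with a 1 s
pre-stimulus window and a multi-second stimulus window per trial.  Every
neuron carries a ground-truth preferred orientation (PO) that can stay
fixed, diffuse as a random walk, or walk with a bias toward a target
orientation — emulating orientation deprivation.

The generative model, deliberately simple and fully controlled:

* orientation tuning is a circular Gaussian (period 180°) of amplitude
  ``response_amplitude`` and per-neuron width drawn log-normally;
* single-trial responses are scaled by a behavior-driven gain (running /
  arousal), which preserves the PO by construction;
* the recorded trace is ``F0·(1 + signal + frame noise)`` plus a shared
  neuropil trace mixed in with a fixed contamination coefficient, chosen
  equal to the analysis-side correction so the noiseless round trip
  through the analysis is exact.

Everything is driven by one seed; per-neuron randomness uses spawned
substreams indexed by neuron counter, so outputs are bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import h5py
import numpy as np
import pandas as pd

from .angles import orientation_distance, signed_orientation_diff, wrap_orientation
from .errors import ParameterError

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "TrialTensor",
    "generate_experiment",
    "biased_walk_step",
    "save_experiment",
    "load_experiment",
]

#: Neuropil contamination coefficient; equals the analysis-side correction
#: factor so that generation followed by correction is an exact inverse.
NEUROPIL_R = 0.7

#: Baseline fluorescence of every ROI, arbitrary units.
F0 = 100.0

#: Mean level of the shared neuropil trace, arbitrary units.
NEUROPIL_BASE = 20.0

_DRIFT_MODELS = ("none", "random_walk", "biased_walk")


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of a synthetic chronic-imaging experiment.

    Durations are seconds, rates Hz, angles degrees, fluorescence-change
    quantities ΔF/F units.  ``session_days`` are absolute day indices and
    must be strictly increasing; drift acts once per elapsed day.
    """

    n_neurons: int = 200
    session_days: tuple = (0, 7)
    n_directions: int = 12
    n_reps: int = 32
    frame_rate: float = 5.0
    stim_duration: float = 5.0
    isi_duration: float = 6.0
    pre_duration: float = 1.0
    tuning_width_log_mean: float = float(np.log(25.0))
    tuning_width_log_sd: float = 0.25
    response_amplitude: float = 1.0
    noise_sd: float = 0.2
    neuropil_contamination: float = NEUROPIL_R
    drift_model: str = "none"
    drift_step_sd: float = 2.0
    drift_target: float = -30.0
    drift_bias: float = 0.01
    fraction_untuned: float = 0.15
    behavior_gain: float = 0.1
    seed: int = 0

    @property
    def n_sessions(self) -> int:
        return len(self.session_days)

    @property
    def n_trials(self) -> int:
        return self.n_directions * self.n_reps

    def __post_init__(self):
        problems = []
        if not (isinstance(self.n_neurons, (int, np.integer)) and self.n_neurons >= 1):
            problems.append("n_neurons must be a positive integer")
        days = np.asarray(self.session_days)
        if days.ndim != 1 or len(days) < 1 or np.any(np.diff(days) <= 0):
            problems.append("session_days must be a strictly increasing sequence")
        if self.n_directions < 4 or self.n_directions % 2:
            problems.append("n_directions must be even and >= 4")
        if self.n_reps < 1:
            problems.append("n_reps must be >= 1")
        for name in ("frame_rate", "stim_duration", "isi_duration", "pre_duration"):
            if getattr(self, name) <= 0:
                problems.append(f"{name} must be strictly positive")
        for name in ("tuning_width_log_sd", "noise_sd", "drift_step_sd",
                     "response_amplitude", "drift_bias", "behavior_gain"):
            if getattr(self, name) < 0:
                problems.append(f"{name} must be non-negative")
        for name in ("neuropil_contamination", "fraction_untuned"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                problems.append(f"{name} must lie in [0, 1]")
        if self.drift_model not in _DRIFT_MODELS:
            problems.append(f"drift_model must be one of {_DRIFT_MODELS}")
        if round(self.frame_rate * self.pre_duration) < 1:
            problems.append("pre_duration too short for frame_rate (empty pre window)")
        if round(self.frame_rate * self.stim_duration) < 1:
            problems.append("stim_duration too short for frame_rate (empty stim window)")
        if problems:
            raise ParameterError("; ".join(problems))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["session_days"] = list(self.session_days)
        return d


@dataclass
class GroundTruth:
    """Ground truth attached to a synthetic experiment.

    ``true_po`` has shape (n_sessions, n_neurons), wrapped to [-90, 90);
    for ``drift_model='none'`` it is constant across sessions.  Behavior
    covariates are per trial per session.
    """

    true_po: np.ndarray
    true_width: np.ndarray
    tuned_mask: np.ndarray
    running_speed: np.ndarray
    pupil_diameter: np.ndarray
    response_gain: np.ndarray
    session_days: np.ndarray


@dataclass
class TrialTensor:
    """One session of trial-cut fluorescence.

    ``raw_f`` and ``neuropil_f`` have shape (n_neurons, n_trials,
    n_frames); ``stim_label`` is the grating drift direction in [0, 360)
    degrees per trial; ``pre_window`` / ``stim_window`` are (start, stop)
    frame ranges per trial (stop exclusive, non-overlapping).
    """

    raw_f: np.ndarray
    neuropil_f: np.ndarray
    stim_label: np.ndarray
    pre_window: np.ndarray
    stim_window: np.ndarray
    day: int
    frame_rate: float

    @property
    def n_neurons(self) -> int:
        return self.raw_f.shape[0]

    @property
    def n_trials(self) -> int:
        return self.raw_f.shape[1]


def biased_walk_step(po, target, step_sd, bias_strength, rng):
    """One day of biased orientation drift.

    The step is Gaussian with standard deviation ``step_sd`` and mean
    ``bias_strength`` times the signed circular distance from ``po``
    toward ``target`` — i.e. an Ornstein–Uhlenbeck-like pull on the
    orientation circle.  ``bias_strength=0`` reduces to a pure random
    walk; ``po == target`` is a fixed point in expectation.
    """
    if bias_strength < 0:
        raise ParameterError("bias_strength must be non-negative")
    po = np.asarray(po, dtype=float)
    pull = bias_strength * signed_orientation_diff(target, po)
    step = pull + rng.normal(0.0, step_sd, size=po.shape)
    return wrap_orientation(po + step)


def _evolve_po(po0, config: SyntheticConfig, rng) -> np.ndarray:
    """Per-session ground-truth POs, stepping the drift model once per day."""
    days = np.asarray(config.session_days)
    pos = [np.asarray(po0, dtype=float)]
    po = pos[0]
    for gap in np.diff(days):
        for _ in range(int(gap)):
            if config.drift_model == "random_walk":
                po = wrap_orientation(po + rng.normal(0.0, config.drift_step_sd, size=po.shape))
            elif config.drift_model == "biased_walk":
                po = biased_walk_step(po, config.drift_target, config.drift_step_sd,
                                      config.drift_bias, rng)
        pos.append(po)
    return np.stack(pos, axis=0)


def _behavior(config: SyntheticConfig, rng):
    """Per-trial behavior covariates and the response gain they drive.

    A single AR(1) arousal latent generates correlated running speed and
    pupil diameter; the gain is an affine function of the latent only, so
    behavior modulates response amplitude but never the PO.
    """
    n = config.n_trials
    phi = 0.8
    a = np.empty(n)
    a[0] = rng.normal()
    innov = rng.normal(0.0, np.sqrt(1 - phi**2), size=n)
    for t in range(1, n):
        a[t] = phi * a[t - 1] + innov[t]
    speed = np.maximum(0.0, 4.0 + 3.0 * a + rng.normal(0.0, 0.5, size=n))
    pupil = 3.0 + 0.4 * a + rng.normal(0.0, 0.1, size=n)
    gain = np.maximum(0.05, 1.0 + config.behavior_gain * a)
    return speed, pupil, gain


def generate_experiment(config: SyntheticConfig):
    """Generate one seeded experiment.

    Returns
    -------
    trials : list of TrialTensor
        One per session, identical neuron ordering throughout.
    truth : GroundTruth

    Notes
    -----
    Same config (incl. seed) gives bit-identical arrays.  The per-trial
    direction order is reshuffled each session, as in the experiment.
    """
    cfg = config
    root = np.random.SeedSequence(cfg.seed)
    # fixed stream layout: [population, schedule, neuropil, behavior, drift, neurons...]
    children = root.spawn(5 + cfg.n_neurons)
    pop_rng = np.random.default_rng(children[0])
    sched_rng = np.random.default_rng(children[1])
    npil_rng = np.random.default_rng(children[2])
    behav_rng = np.random.default_rng(children[3])
    drift_rng = np.random.default_rng(children[4])
    neuron_ss = children[5:]

    n, s_count, t_count = cfg.n_neurons, cfg.n_sessions, cfg.n_trials
    f_pre = int(round(cfg.frame_rate * cfg.pre_duration))
    f_stim = int(round(cfg.frame_rate * cfg.stim_duration))
    n_frames = f_pre + f_stim

    po0 = pop_rng.uniform(-90.0, 90.0, size=n)
    width = np.exp(pop_rng.normal(cfg.tuning_width_log_mean, cfg.tuning_width_log_sd, size=n))
    tuned = pop_rng.uniform(size=n) >= cfg.fraction_untuned
    amp = np.where(tuned, cfg.response_amplitude, 0.0)
    true_po = _evolve_po(po0, cfg, drift_rng)

    directions = np.arange(cfg.n_directions) * (360.0 / cfg.n_directions)
    pre_win = np.tile([0, f_pre], (t_count, 1)).astype(np.int64)
    stim_win = np.tile([f_pre, n_frames], (t_count, 1)).astype(np.int64)

    sessions = []
    speed_all, pupil_all, gain_all = [], [], []
    for s in range(s_count):
        labels = np.repeat(directions, cfg.n_reps)
        sched_rng.shuffle(labels)
        speed, pupil, gain = _behavior(cfg, behav_rng)
        speed_all.append(speed)
        pupil_all.append(pupil)
        gain_all.append(gain)

        # shared neuropil: slow oscillation across the session plus frame noise
        tt = np.arange(t_count * n_frames, dtype=float).reshape(t_count, n_frames)
        npil = (NEUROPIL_BASE
                + 2.0 * np.sin(2.0 * np.pi * tt / (t_count * n_frames / 3.0))
                + 0.5 * npil_rng.standard_normal((t_count, n_frames)))

        dist = orientation_distance(labels[None, :] % 180.0, true_po[s][:, None])
        resp = amp[:, None] * np.exp(-0.5 * (dist / width[:, None]) ** 2)  # (n, trials)
        signal = np.zeros((n, t_count, n_frames))
        signal[:, :, f_pre:] = (resp * gain[None, :])[:, :, None]

        raw = F0 * (1.0 + signal)
        if cfg.noise_sd > 0:
            for i in range(n):
                nrng = np.random.default_rng(np.random.SeedSequence(
                    entropy=neuron_ss[i].entropy, spawn_key=neuron_ss[i].spawn_key + (s,)))
                raw[i] += F0 * cfg.noise_sd * nrng.standard_normal((t_count, n_frames))
        raw += cfg.neuropil_contamination * (npil - np.median(npil))
        np.maximum(raw, 1e-3, out=raw)  # positivity guard; vanishing probability of acting

        sessions.append(TrialTensor(
            raw_f=raw,
            neuropil_f=np.broadcast_to(npil, (n, t_count, n_frames)),
            stim_label=labels,
            pre_window=pre_win.copy(),
            stim_window=stim_win.copy(),
            day=int(cfg.session_days[s]),
            frame_rate=cfg.frame_rate,
        ))

    truth = GroundTruth(
        true_po=true_po,
        true_width=width,
        tuned_mask=tuned,
        running_speed=np.stack(speed_all),
        pupil_diameter=np.stack(pupil_all),
        response_gain=np.stack(gain_all),
        session_days=np.asarray(cfg.session_days, dtype=np.int64),
    )
    return sessions, truth


# ---------------------------------------------------------------------------
# persistence


def save_experiment(path, sessions, truth: GroundTruth, config: SyntheticConfig | None = None):
    """Write trial bundles to HDF5 (one group per session) plus ground truth.

    The ground truth is duplicated as ``<path>.truth.csv`` (per-neuron
    table) and ``<path>.truth.json`` (arrays + session days) next to the
    HDF5 file for quick inspection.
    """
    path = str(path)
    with h5py.File(path, "w") as f:
        if config is not None:
            f.attrs["config"] = json.dumps(config.to_dict())
        for i, tt in enumerate(sessions):
            g = f.create_group(f"session_{i:03d}")
            g.attrs["day"] = tt.day
            g.attrs["frame_rate"] = tt.frame_rate
            g.create_dataset("raw_f", data=np.asarray(tt.raw_f))
            g.create_dataset("neuropil_f", data=np.asarray(tt.neuropil_f))
            g.create_dataset("stim_label", data=tt.stim_label)
            g.create_dataset("pre_window", data=tt.pre_window)
            g.create_dataset("stim_window", data=tt.stim_window)
        g = f.create_group("ground_truth")
        for name in ("true_po", "true_width", "tuned_mask", "running_speed",
                     "pupil_diameter", "response_gain", "session_days"):
            g.create_dataset(name, data=getattr(truth, name))

    per_neuron = pd.DataFrame({"neuron": np.arange(len(truth.true_width)),
                               "true_width_deg": truth.true_width,
                               "tuned": truth.tuned_mask})
    for s, day in enumerate(truth.session_days):
        per_neuron[f"true_po_day{int(day)}"] = truth.true_po[s]
    per_neuron.to_csv(path + ".truth.csv", index=False)
    with open(path + ".truth.json", "w") as fh:
        json.dump({"session_days": truth.session_days.tolist(),
                   "true_po": truth.true_po.tolist()}, fh)


def load_experiment(path):
    """Inverse of :func:`save_experiment`; returns (sessions, truth)."""
    sessions, kw = [], {}
    with h5py.File(str(path), "r") as f:
        for key in sorted(k for k in f.keys() if k.startswith("session_")):
            g = f[key]
            sessions.append(TrialTensor(
                raw_f=g["raw_f"][()],
                neuropil_f=g["neuropil_f"][()],
                stim_label=g["stim_label"][()],
                pre_window=g["pre_window"][()],
                stim_window=g["stim_window"][()],
                day=int(g.attrs["day"]),
                frame_rate=float(g.attrs["frame_rate"]),
            ))
        gt = f["ground_truth"]
        for name in ("true_po", "true_width", "tuned_mask", "running_speed",
                     "pupil_diameter", "response_gain", "session_days"):
            kw[name] = gt[name][()]
    return sessions, GroundTruth(**kw)
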