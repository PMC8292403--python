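"""Ground-truth modular EMG generator.

Builds synthetic cycle matrices, condition tensors and raw trials with the
structure the downstream analysis assumes: a small set of nonnegative
spatial modules with disjoint-dominant muscle groups, unimodal phase-locked
temporal bursts, condition-dependent nonnegative gains, inter-participant
variability, and nonnegative noise. Every output is deterministic given the
arguments and seeds, which makes parameter-recovery testing of each stage
possible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .errors import InvalidArgumentError
from .preprocessing import CycleMatrix

logger = logging.getLogger(__name__)

PROFILE_KINDS = ("constant", "linear_decreasing", "threshold_decreasing", "u_shaped")

#: default burst centres as fractions of the gait cycle: initial contact,
#: propulsion, early swing, late swing
DEFAULT_BURST_CENTERS = (0.05, 0.40, 0.60, 0.95)

BURST_SIGMA_FRACTION = 0.05


@dataclass
class GroundTruth:
    """Generative parameters for one synthetic cohort."""

    n_muscles: int
    n_bins: int
    n_modules: int
    W_true: np.ndarray  # muscles x modules, unit-norm columns
    C_true: np.ndarray  # modules x bins, unit-norm rows
    condition_labels: tuple[str, ...]  # gravity-ordered, highest first
    gain_profiles: list[dict[str, float]]  # per module: label -> gain
    profile_kinds: tuple[str, ...]
    participant_scales: np.ndarray  # participants x modules gain multipliers
    participant_sigma: float
    noise_sd: float
    seed: int

    @property
    def n_participants(self) -> int:
        return self.participant_scales.shape[0]

    def gains(self, participant: int, condition: str) -> np.ndarray:
        """Per-module gains for one participant/condition."""
        if condition not in self.condition_labels:
            raise InvalidArgumentError(f"unknown condition label {condition!r}")
        base = np.array([p[condition] for p in self.gain_profiles])
        return base * self.participant_scales[participant]

    def participant_weights(self, participant: int) -> np.ndarray:
        """Spatial modules for one participant: element-wise lognormal jitter
        on the true weights, columns renormalized to unit norm."""
        if self.participant_sigma == 0:
            return self.W_true.copy()
        rng = np.random.default_rng((self.seed, 7001, participant))
        jitter = rng.lognormal(0.0, self.participant_sigma, self.W_true.shape)
        W = self.W_true * jitter
        return W / np.linalg.norm(W, axis=0, keepdims=True)

    def to_json(self, path) -> None:
        payload = {
            "n_muscles": self.n_muscles,
            "n_bins": self.n_bins,
            "n_modules": self.n_modules,
            "W_true": self.W_true.tolist(),
            "C_true": self.C_true.tolist(),
            "condition_labels": list(self.condition_labels),
            "gain_profiles": self.gain_profiles,
            "profile_kinds": list(self.profile_kinds),
            "participant_scales": self.participant_scales.tolist(),
            "participant_sigma": self.participant_sigma,
            "noise_sd": self.noise_sd,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


@dataclass
class SyntheticRawTrial:
    """A raw synthetic recording with known contact times and envelopes."""

    emg: np.ndarray  # channels x samples, signed broadband
    limb_angle: np.ndarray  # samples, degrees
    fs: float
    cycle_duration: float
    n_cycles: int
    contact_samples_true: np.ndarray
    envelope_true: np.ndarray = field(repr=False, default=None)  # channels x samples

    def to_csv(self, path, muscle_labels: tuple[str, ...] | None = None) -> None:
        n_ch = self.emg.shape[0]
        labels = muscle_labels or tuple(f"ch{i}" for i in range(n_ch))
        t = np.arange(self.emg.shape[1]) / self.fs
        df = pd.DataFrame({"time": t})
        for i, lab in enumerate(labels):
            df[lab] = self.emg[i]
        df["limb_angle"] = self.limb_angle
        with open(path, "w") as fh:
            fh.write(f"# fs={self.fs}\n")
            df.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# Gain profiles
# ---------------------------------------------------------------------------

def _profile(kind: str, n_labels: int) -> np.ndarray:
    """Gain over gravity-ordered labels (index 0 = highest gravity)."""
    if kind == "constant":
        return np.ones(n_labels)
    if kind == "linear_decreasing":
        return np.linspace(1.0, 0.2, n_labels)
    if kind == "threshold_decreasing":
        # flat at the top gravity levels, then a linear fall-off
        n_flat = max(1, int(np.ceil(n_labels * 0.4)))
        tail = np.linspace(1.0, 0.2, n_labels - n_flat + 1)[1:]
        return np.concatenate([np.ones(n_flat), tail])
    if kind == "u_shaped":
        mid = (n_labels - 1) / 2.0
        idx = np.arange(n_labels)
        return 0.4 + 0.6 * ((idx - mid) / mid) ** 2
    raise InvalidArgumentError(f"unknown profile kind {kind!r}")


def make_ground_truth(
    n_modules: int,
    condition_labels: list[str],
    profile_kinds: list[str],
    seed: int,
    n_muscles: int = 12,
    n_bins: int = 200,
    n_participants: int = 9,
    participant_sigma: float = 0.1,
    noise_sd: float = 0.02,
    burst_centers: list[float] | None = None,
) -> GroundTruth:
    """Build a ground-truth generative model.

    Temporal modules are truncated Gaussian bursts (sigma = 5% of the cycle)
    centred at distinct phases; spatial modules have disjoint-dominant muscle
    groups; gains follow the requested kind over gravity-ordered labels.
    """
    if n_modules < 1:
        raise InvalidArgumentError("n_modules must be >= 1")
    if n_modules > n_muscles:
        raise InvalidArgumentError("n_modules cannot exceed n_muscles")
    if len(condition_labels) < 2:
        raise InvalidArgumentError("need at least 2 condition labels")
    if len(profile_kinds) != n_modules:
        raise InvalidArgumentError("one profile kind required per module")
    for kind in profile_kinds:
        if kind not in PROFILE_KINDS:
            raise InvalidArgumentError(f"unknown profile kind {kind!r}")

    rng = np.random.default_rng(seed)

    if burst_centers is None:
        if n_modules <= len(DEFAULT_BURST_CENTERS):
            burst_centers = list(DEFAULT_BURST_CENTERS[:n_modules])
        else:
            burst_centers = list(np.linspace(0.05, 0.95, n_modules))
    if len(burst_centers) != n_modules:
        raise InvalidArgumentError("one burst centre required per module")

    # temporal modules: truncated Gaussians, unit-norm rows
    x = np.arange(n_bins, dtype=float)
    sigma = BURST_SIGMA_FRACTION * n_bins
    C = np.empty((n_modules, n_bins))
    for n, c in enumerate(burst_centers):
        C[n] = np.exp(-((x - c * n_bins) ** 2) / (2.0 * sigma**2))
    C /= np.linalg.norm(C, axis=1, keepdims=True)

    # spatial modules: round-robin partition into dominant groups
    groups = [np.arange(n_muscles)[g::n_modules] for g in range(n_modules)]
    W = rng.uniform(0.0, 0.1, (n_muscles, n_modules))
    for n, g in enumerate(groups):
        W[g, n] = rng.uniform(0.6, 1.0, g.size)
    W /= np.linalg.norm(W, axis=0, keepdims=True)

    profiles = [
        dict(zip(condition_labels, _profile(kind, len(condition_labels))))
        for kind in profile_kinds
    ]
    scales = (
        rng.lognormal(0.0, participant_sigma, (n_participants, n_modules))
        if participant_sigma > 0
        else np.ones((n_participants, n_modules))
    )

    return GroundTruth(
        n_muscles=n_muscles,
        n_bins=n_bins,
        n_modules=n_modules,
        W_true=W,
        C_true=C,
        condition_labels=tuple(condition_labels),
        gain_profiles=profiles,
        profile_kinds=tuple(profile_kinds),
        participant_scales=scales,
        participant_sigma=participant_sigma,
        noise_sd=noise_sd,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Cycle matrices and tensors
# ---------------------------------------------------------------------------

def noiseless_cycle_values(gt: GroundTruth, participant: int, condition: str) -> np.ndarray:
    """W_p . diag(gains) . C without noise."""
    g = gt.gains(participant, condition)
    return gt.participant_weights(participant) @ np.diag(g) @ gt.C_true


def generate_cycle_matrix(
    gt: GroundTruth, participant: int, condition: str, seed: int
) -> CycleMatrix:
    """max(0, W_p . diag(gains) . C + Gaussian noise), deterministic per
    (gt, participant, condition, seed)."""
    clean = noiseless_cycle_values(gt, participant, condition)
    cond_idx = gt.condition_labels.index(condition)
    rng = np.random.default_rng((gt.seed, 1301, participant, cond_idx, seed))
    noisy = clean + rng.normal(0.0, gt.noise_sd, clean.shape) if gt.noise_sd > 0 else clean
    values = np.clip(noisy, 0.0, None)
    if gt.noise_sd > 0:
        clipped = np.mean(noisy < 0)
        logger.debug("generate_cycle_matrix clipped %.1f%% of entries", 100 * clipped)
    return CycleMatrix(
        values=values,
        muscle_labels=tuple(f"m{i:02d}" for i in range(gt.n_muscles)),
        participant=f"P{participant:02d}",
        condition=condition,
    )


def generate_condition_set(
    gt: GroundTruth, seed: int, conditions: list[str] | None = None
) -> dict[tuple[int, str], CycleMatrix]:
    """Cycle matrices for every (participant, condition) pair."""
    conditions = list(conditions or gt.condition_labels)
    return {
        (p, c): generate_cycle_matrix(gt, p, c, seed)
        for p in range(gt.n_participants)
        for c in conditions
    }


# ---------------------------------------------------------------------------
# Raw trials
# ---------------------------------------------------------------------------

def generate_raw_trial(
    gt: GroundTruth,
    participant: int,
    condition: str,
    fs: float = 1000.0,
    cycle_duration: float = 1.0,
    n_cycles: int = 12,
    seed: int = 0,
) -> SyntheticRawTrial:
    """Simulate a raw recording: per channel, a broadband carrier
    (100-400 Hz noise, rectified mean scaled to 1) amplitude-modulated by
    the module-mixture envelope; a smooth periodic limb-elevation angle whose
    local maxima sit exactly at the true contact samples."""
    if fs < 500:
        raise InvalidArgumentError("fs must be >= 500 Hz")
    if n_cycles < 12:
        raise InvalidArgumentError("n_cycles must be >= 12")
    if condition not in gt.condition_labels:
        raise InvalidArgumentError(f"unknown condition label {condition!r}")

    spc = int(round(fs * cycle_duration))  # samples per cycle
    n_samples = n_cycles * spc
    cond_idx = gt.condition_labels.index(condition)
    rng = np.random.default_rng((gt.seed, 2903, participant, cond_idx, seed))

    # contacts at mid-cosine peaks: (k + 1/2) * spc, k = 0..n_cycles-1
    contacts = ((np.arange(n_cycles) + 0.5) * spc).astype(int)
    i = np.arange(n_samples)
    limb_angle = 20.0 * np.cos(2.0 * np.pi * (i - 0.5 * spc) / spc)

    # envelope: periodic linear interpolation of the noiseless cycle matrix
    clean = noiseless_cycle_values(gt, participant, condition)  # muscles x bins
    phase = ((i - contacts[0]) % spc) / spc * gt.n_bins
    bins_ext = np.arange(gt.n_bins + 1, dtype=float)
    envelope = np.stack(
        [np.interp(phase, bins_ext, np.append(row, row[0])) for row in clean]
    )

    sos = signal.butter(4, [100.0, min(400.0, 0.45 * fs)], btype="bandpass", fs=fs, output="sos")

    def carrier() -> np.ndarray:
        w = signal.sosfiltfilt(sos, rng.standard_normal((gt.n_muscles, n_samples)), axis=1)
        m = np.mean(np.abs(w), axis=1, keepdims=True)
        return w / np.where(m > 0, m, 1.0)  # rectified mean == 1 per channel

    emg = envelope * carrier()
    if gt.noise_sd > 0:
        emg = emg + gt.noise_sd * carrier()

    return SyntheticRawTrial(
        emg=emg,
        limb_angle=limb_angle,
        fs=fs,
        cycle_duration=cycle_duration,
        n_cycles=n_cycles,
        contact_samples_true=contacts,
        envelope_true=envelope,
    )
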