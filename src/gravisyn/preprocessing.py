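"""EMG conditioning, gait-cycle normalization, and walking-protocol utilities.

Turns raw multi-channel EMG plus two-landmark leg kinematics into nonnegative
``muscles x n_bins`` cycle matrices: zero-phase Butterworth conditioning,
foot-contact detection from the limb-axis elevation angle, per-cycle time
normalization onto a fixed number of phase bins, amplitude normalization
across conditions, and per-muscle unit-variance scaling. Also provides the
Froude-number speed protocol and the pendular net-load proxy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import signal

from .errors import (
    DegenerateChannelError,
    InsufficientDataError,
    InvalidArgumentError,
)

logger = logging.getLogger(__name__)

DEFAULT_MUSCLES = (
    "MG", "LG", "SOL", "TA", "VL", "RF",
    "BFL", "BFS", "AL", "TFL", "GMed", "GMax",
)

HIGHPASS_HZ = 100.0
LOWPASS_HZ = 10.0
FILTER_ORDER = 4  # per pass; filtfilt doubles the effective order


@dataclass
class RawRecording:
    """Raw multi-channel EMG, signed, arbitrary units."""

    emg: np.ndarray  # channels x samples
    fs: float
    muscle_labels: tuple[str, ...]

    def __post_init__(self):
        self.emg = np.asarray(self.emg, dtype=float)
        if self.emg.ndim != 2:
            raise InvalidArgumentError("emg must be a 2-D channels x samples array")
        if self.fs <= 0:
            raise InvalidArgumentError("fs must be positive")
        if len(self.muscle_labels) != self.emg.shape[0]:
            raise InvalidArgumentError("label count must equal channel count")
        if len(set(self.muscle_labels)) != len(self.muscle_labels):
            raise InvalidArgumentError("muscle labels must be unique")


@dataclass
class LimbAxisTrack:
    """Sagittal-plane trajectories of the proximal (gt) and distal (lm)
    leg landmarks, columns (x anterior, y vertical), metres."""

    gt_xy: np.ndarray  # samples x 2
    lm_xy: np.ndarray  # samples x 2
    fs: float

    def __post_init__(self):
        self.gt_xy = np.asarray(self.gt_xy, dtype=float)
        self.lm_xy = np.asarray(self.lm_xy, dtype=float)
        if self.gt_xy.shape != self.lm_xy.shape or self.gt_xy.ndim != 2:
            raise InvalidArgumentError("gt_xy and lm_xy must have identical samples x 2 shapes")
        if self.fs <= 0:
            raise InvalidArgumentError("fs must be positive")


@dataclass
class GaitEvents:
    """Foot-contact sample indices, strictly increasing."""

    contact_samples: np.ndarray

    def __post_init__(self):
        self.contact_samples = np.asarray(self.contact_samples, dtype=int)
        if self.contact_samples.size < 2:
            raise InsufficientDataError("need at least 2 contacts to define a cycle")
        if np.any(np.diff(self.contact_samples) <= 0):
            raise InvalidArgumentError("contact samples must be strictly increasing")

    @property
    def n_cycles(self) -> int:
        return self.contact_samples.size - 1


@dataclass
class CycleMatrix:
    """Nonnegative muscles x n_bins activity matrix for one
    participant / condition."""

    values: np.ndarray  # muscles x n_bins
    muscle_labels: tuple[str, ...]
    participant: str = ""
    condition: str = ""
    scale_info: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InvalidArgumentError("values must be 2-D")
        if np.any(self.values < 0):
            raise InvalidArgumentError("cycle matrix must be nonnegative")
        if len(self.muscle_labels) != self.values.shape[0]:
            raise InvalidArgumentError("label count must equal row count")

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            self.values,
            index=list(self.muscle_labels),
            columns=[str(j) for j in range(self.values.shape[1])],
        )
        df.to_csv(path, index_label="muscle")

    @classmethod
    def from_csv(cls, path, participant: str = "", condition: str = "") -> "CycleMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(
            values=df.to_numpy(dtype=float),
            muscle_labels=tuple(df.index.astype(str)),
            participant=participant,
            condition=condition,
        )


@dataclass
class ProtocolParams:
    """Walking-protocol parameters for one trial."""

    m: float  # body mass, kg
    L: float  # leg length, m
    g_eff: float  # effective gravity, m s^-2
    v: float  # walking speed, m s^-1

    def __post_init__(self):
        for name in ("m", "L", "g_eff", "v"):
            if getattr(self, name) <= 0:
                raise InvalidArgumentError(f"{name} must be positive")

    @property
    def Fr(self) -> float:
        return self.v**2 / (self.g_eff * self.L)


# ---------------------------------------------------------------------------
# EMG conditioning
# ---------------------------------------------------------------------------

def condition_emg(
    rec: RawRecording,
    highpass_hz: float = HIGHPASS_HZ,
    lowpass_hz: float = LOWPASS_HZ,
    order: int = FILTER_ORDER,
) -> np.ndarray:
    """Condition raw EMG into nonnegative linear envelopes.

    High-pass filter, demean, full-wave rectify, then low-pass filter.
    Both filters are Butterworth designs of the given per-pass order applied
    forward-backward (zero phase). Returns a channels x samples array,
    clipped at zero.
    """
    if rec.fs <= 2.2 * highpass_hz:
        raise InvalidArgumentError(
            f"fs={rec.fs} too low for a {highpass_hz} Hz high-pass corner"
        )
    if not np.all(np.isfinite(rec.emg)):
        raise InvalidArgumentError("emg contains non-finite samples")

    sos_hp = signal.butter(order, highpass_hz, btype="highpass", fs=rec.fs, output="sos")
    sos_lp = signal.butter(order, lowpass_hz, btype="lowpass", fs=rec.fs, output="sos")

    x = signal.sosfiltfilt(sos_hp, rec.emg, axis=1)
    x = x - x.mean(axis=1, keepdims=True)
    x = np.abs(x)
    env = signal.sosfiltfilt(sos_lp, x, axis=1)
    # zero-phase low-pass of a rectified signal can undershoot slightly
    return np.clip(env, 0.0, None)


# ---------------------------------------------------------------------------
# Foot-contact detection
# ---------------------------------------------------------------------------

def elevation_angle(track: LimbAxisTrack) -> np.ndarray:
    """Sagittal elevation angle of the limb axis, degrees.

    Angle between the proximal-to-distal landmark vector and the downward
    vertical; positive when the distal landmark is anterior to the proximal
    one, so the per-cycle maximum marks foot contact.
    """
    d = track.lm_xy - track.gt_xy
    return np.degrees(np.arctan2(d[:, 0], -d[:, 1]))


def detect_contacts_from_angle(
    angle: np.ndarray, fs: float, min_period_s: float = 0.4
) -> GaitEvents:
    """Local maxima of an elevation-angle trace, separated by at least
    ``min_period_s``."""
    angle = np.asarray(angle, dtype=float)
    distance = max(1, int(round(min_period_s * fs)))
    peaks, _ = signal.find_peaks(angle, distance=distance)
    if peaks.size < 2:
        raise InsufficientDataError(
            f"found {peaks.size} contact(s); need at least 2 for one gait cycle"
        )
    return GaitEvents(contact_samples=peaks)


def detect_foot_contacts(track: LimbAxisTrack, min_period_s: float = 0.4) -> GaitEvents:
    """Foot contacts at the maximum elevation of the limb axis."""
    return detect_contacts_from_angle(elevation_angle(track), track.fs, min_period_s)


# ---------------------------------------------------------------------------
# Cycle segmentation and normalization
# ---------------------------------------------------------------------------

def segment_and_normalize(
    envelope: np.ndarray,
    events: GaitEvents,
    n_bins: int = 200,
    n_cycles: int = 10,
    discard_first: bool = True,
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Interpolate each gait cycle onto ``n_bins`` phase bins and average.

    Each cycle spans the half-open interval ``[contact_k, contact_{k+1})``;
    bin j sits at phase ``j / n_bins`` of the cycle, interpolated linearly.
    The first cycle is discarded (transient), then the middle-most
    ``n_cycles`` of the remaining complete cycles are averaged.

    Returns ``(stack, mean, used_cycle_indices)`` with
    ``stack`` of shape ``n_cycles x channels x n_bins``.
    """
    envelope = np.atleast_2d(np.asarray(envelope, dtype=float))
    contacts = events.contact_samples
    first = 1 if discard_first else 0
    available = events.n_cycles - first
    if available < n_cycles:
        raise InsufficientDataError(
            f"only {available} analysable cycles available, need {n_cycles}"
        )
    # middle-most n_cycles of the analysable cycles
    start = first + (available - n_cycles) // 2
    used = list(range(start, start + n_cycles))

    n_ch = envelope.shape[0]
    t = np.arange(envelope.shape[1], dtype=float)
    stack = np.empty((n_cycles, n_ch, n_bins))
    phases = np.arange(n_bins, dtype=float) / n_bins
    for out_i, k in enumerate(used):
        c0, c1 = contacts[k], contacts[k + 1]
        sample_pos = c0 + phases * (c1 - c0)
        for ch in range(n_ch):
            stack[out_i, ch] = np.interp(sample_pos, t, envelope[ch])
    logger.debug("segment_and_normalize used cycles %s", used)
    return stack, stack.mean(axis=0), used


# ---------------------------------------------------------------------------
# Amplitude / variance normalization
# ---------------------------------------------------------------------------

def normalize_amplitude(matrices: dict[str, CycleMatrix]) -> dict[str, CycleMatrix]:
    """Normalize one participant's cycle matrices across all conditions.

    Per muscle trace: subtract its own cycle minimum, then divide by that
    muscle's maximum over all the participant's conditions (computed after
    min subtraction). After normalization every muscle attains max 1 in at
    least one condition. Idempotent.
    """
    if not matrices:
        raise InvalidArgumentError("need at least one condition")
    conds = list(matrices)
    labels = matrices[conds[0]].muscle_labels
    for c in conds:
        if matrices[c].muscle_labels != labels:
            raise InvalidArgumentError(f"muscle ordering differs in condition {c!r}")

    shifted = {c: matrices[c].values - matrices[c].values.min(axis=1, keepdims=True)
               for c in conds}
    max_across = np.max(np.stack([shifted[c].max(axis=1) for c in conds]), axis=0)
    for i, label in enumerate(labels):
        if max_across[i] <= 0:
            raise DegenerateChannelError(
                label, f"muscle {label!r} is constant in every condition"
            )

    out = {}
    for c in conds:
        src = matrices[c]
        out[c] = CycleMatrix(
            values=shifted[c] / max_across[:, None],
            muscle_labels=labels,
            participant=src.participant,
            condition=src.condition,
            scale_info={
                "min_subtracted": src.values.min(axis=1).tolist(),
                "max_divisor": max_across.tolist(),
            },
        )
    return out


def scale_unit_variance(matrix: CycleMatrix) -> tuple[CycleMatrix, np.ndarray]:
    """Divide each muscle row by its (population) standard deviation.

    Returns the scaled matrix and the per-muscle scale factors; multiplying
    rows (or extracted spatial weightings) by the factors inverts the
    scaling exactly.
    """
    sd = matrix.values.std(axis=1, ddof=0)
    for i, label in enumerate(matrix.muscle_labels):
        if sd[i] <= 0:
            raise DegenerateChannelError(label, f"muscle {label!r} has zero variance")
    scaled = CycleMatrix(
        values=matrix.values / sd[:, None],
        muscle_labels=matrix.muscle_labels,
        participant=matrix.participant,
        condition=matrix.condition,
        scale_info=dict(matrix.scale_info, unit_variance_sd=sd.tolist()),
    )
    return scaled, sd


def unscale_unit_variance(matrix: CycleMatrix, sd: np.ndarray) -> CycleMatrix:
    """Invert :func:`scale_unit_variance`."""
    return CycleMatrix(
        values=matrix.values * np.asarray(sd)[:, None],
        muscle_labels=matrix.muscle_labels,
        participant=matrix.participant,
        condition=matrix.condition,
        scale_info=matrix.scale_info,
    )


# ---------------------------------------------------------------------------
# Froude-number protocol
# ---------------------------------------------------------------------------

def froude_speed(L: float, g_eff: float, Fr: float = 0.25) -> float:
    """Walking speed (m/s) at a given Froude number: v = sqrt(Fr * g * L)."""
    if L <= 0 or g_eff <= 0 or Fr <= 0:
        raise InvalidArgumentError("L, g_eff and Fr must all be positive")
    return float(np.sqrt(Fr * g_eff * L))


def fr_number(v: float, g_eff: float, L: float) -> float:
    """Froude number v^2 / (g L)."""
    if v <= 0 or g_eff <= 0 or L <= 0:
        raise InvalidArgumentError("v, g_eff and L must all be positive")
    return float(v**2 / (g_eff * L))


def speed_at_gravity_ratio(v_ref: float, ratio: float) -> float:
    """Scale a matched-Froude speed to another gravity: v(r*g) = v(g) * sqrt(r)."""
    if v_ref <= 0 or ratio <= 0:
        raise InvalidArgumentError("v_ref and ratio must be positive")
    return float(v_ref * np.sqrt(ratio))


def round_kmh(v: float, ndigits: int = 2) -> float:
    """Half-up rounding used when comparing km/h speeds."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(v)).quantize(q, rounding=ROUND_HALF_UP))


def net_load_proxy(p: ProtocolParams) -> float:
    """Pendular net-load proxy m * (g - v^2 / L), newtons.

    Negative when v^2 / (g L) > 1 (the dynamically-broken regime); returned
    as-is.
    """
    return float(p.m * (p.g_eff - p.v**2 / p.L))


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _read_fs_comment(path) -> float | None:
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#") and "fs=" in first:
        return float(first.split("fs=")[1].strip())
    return None


def read_emg_csv(path, fs: float | None = None) -> RawRecording:
    """Read an EMG CSV (channel headers = muscle labels, optional leading
    ``time`` column, optional ``# fs=...`` header comment)."""
    if fs is None:
        fs = _read_fs_comment(path)
    if fs is None:
        raise InvalidArgumentError("sampling rate not given and no '# fs=' header found")
    df = pd.read_csv(path, comment="#")
    cols = [c for c in df.columns if c.lower() != "time"]
    return RawRecording(
        emg=df[cols].to_numpy(dtype=float).T,
        fs=fs,
        muscle_labels=tuple(cols),
    )


def read_markers_csv(path, fs: float | None = None) -> LimbAxisTrack:
    """Read a marker CSV with columns gt_x, gt_y, lm_x, lm_y."""
    if fs is None:
        fs = _read_fs_comment(path)
    if fs is None:
        raise InvalidArgumentError("sampling rate not given and no '# fs=' header found")
    df = pd.read_csv(path, comment="#")
    return LimbAxisTrack(
        gt_xy=df[["gt_x", "gt_y"]].to_numpy(dtype=float),
        lm_xy=df[["lm_x", "lm_y"]].to_numpy(dtype=float),
        fs=fs,
    )
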