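"""Core domain types shared across the package.

Conventions used throughout:

* sampling rate is fixed at 1000 Hz, so one sample equals one millisecond;
* sample indices are 0-based and windows are half-open ``[start, stop)``;
* the one-step target is ``dy(t) = y(t+1) - y(t)`` and lag vectors start at
  ``t - 1`` (dense) or ``t - tau`` (sparse).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

FS_HZ = 1000
"""Sampling rate (samples per second). One sample == one millisecond."""

STIM_DURATION_MS = 500
"""Fixed pulse-train duration."""

ALLOWED_FREQS = (10.0, 25.0, 50.0, 100.0, 200.0)
"""Pulse-train frequencies (Hz). A single pulse is encoded as ``freq_hz == -1``."""

SINGLE_PULSE = -1.0

GATING_MODES = ("none", "switched", "amplitude", "bilinear")

WINDOW_MS = 1500
FOLD_MS = 300
N_FOLDS = 5
PRE_MS = 500
SINGLE_PRE_MS = 750


class StimarxError(Exception):
    """Base class for package errors."""


class InvalidArgumentError(StimarxError, ValueError):
    pass


class InstabilityError(StimarxError):
    """Raised when a ground-truth system cannot be stabilized."""


class ScheduleError(StimarxError):
    pass


class DataError(StimarxError):
    """Raised when data does not support the requested operation."""


# ---------------------------------------------------------------------------
# geometry / stimulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ElectrodeGeometry:
    """Per-channel 3-D electrode positions (mm) plus the stimulation site."""

    coords: np.ndarray  # (C, 3) float64, mm
    anode_index: int = 0

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 1:
            raise InvalidArgumentError("coords must be a (C, 3) array with C >= 1")
        if not 0 <= self.anode_index < coords.shape[0]:
            raise InvalidArgumentError("anode_index out of range")
        object.__setattr__(self, "coords", coords)

    @property
    def n_channels(self) -> int:
        return self.coords.shape[0]

    @property
    def pairwise_dist(self) -> np.ndarray:
        diff = self.coords[:, None, :] - self.coords[None, :, :]
        return np.sqrt((diff**2).sum(axis=-1))

    @property
    def dist_to_anode(self) -> np.ndarray:
        return self.pairwise_dist[self.anode_index]


@dataclass(frozen=True)
class StimEvent:
    """A single stimulation delivery."""

    onset: int  # sample index of delivery start
    duration_ms: int = STIM_DURATION_MS
    freq_hz: float = SINGLE_PULSE  # -1 encodes a single pulse
    amp_ma: float = 1.0

    @property
    def is_single_pulse(self) -> bool:
        return self.freq_hz < 0


@dataclass(frozen=True)
class StimSchedule:
    """Ordered, non-overlapping stimulation events for one session."""

    events: tuple[StimEvent, ...]
    a_safe: float
    gap_ms: int

    def __post_init__(self) -> None:
        events = tuple(self.events)
        for prev, nxt in zip(events, events[1:]):
            if nxt.onset < prev.onset + prev.duration_ms:
                raise ScheduleError(
                    f"overlapping events at onsets {prev.onset} and {nxt.onset}"
                )
        object.__setattr__(self, "events", events)

    def __len__(self) -> int:
        return len(self.events)

    @property
    def end_sample(self) -> int:
        if not self.events:
            return 0
        last = self.events[-1]
        return last.onset + last.duration_ms


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------


@dataclass
class GroundTruthSystem:
    """Per-channel parameter blocks of a switched-linear/bilinear network system.

    ``a`` is (C, L); ``b`` is (C, M); ``c`` is (C, L); ``d`` is (C, C, P) with
    ``d[k, i]`` the weights from source channel ``i`` to target ``k``
    (``d[k, k] == 0``).  Blocks excluded by the family are all-zero arrays.
    """

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    d: np.ndarray
    gating: str
    noise_sd: float
    margin: float = 0.95
    seed: int | None = None

    def __post_init__(self) -> None:
        self.a = np.atleast_2d(np.asarray(self.a, dtype=float))
        self.b = np.atleast_2d(np.asarray(self.b, dtype=float))
        self.c = np.atleast_2d(np.asarray(self.c, dtype=float))
        self.d = np.asarray(self.d, dtype=float)
        if self.gating not in GATING_MODES:
            raise InvalidArgumentError(f"unknown gating mode {self.gating!r}")
        C = self.a.shape[0]
        if self.d.size == 0:
            self.d = np.zeros((C, C, 0))
        if self.c.size == 0:
            self.c = np.zeros((C, self.L))

    @property
    def n_channels(self) -> int:
        return self.a.shape[0]

    @property
    def L(self) -> int:
        return self.a.shape[1]

    @property
    def M(self) -> int:
        return self.b.shape[1]

    @property
    def P(self) -> int:
        return self.d.shape[2]

    @property
    def max_lag(self) -> int:
        return max(self.L, self.M, self.P, 1)

    def theta(self, k: int, spec: "ModelSpec") -> np.ndarray:
        """True parameter vector for channel ``k`` laid out as ``spec``'s features."""
        parts = [self.a[k, : spec.L]]
        if spec.gated:
            parts.append(self.c[k, : spec.L])
        parts.append(self.b[k, : spec.M])
        for i in spec.sources:
            parts.append(self.d[k, i, : spec.P])
        return np.concatenate(parts) if parts else np.zeros(0)


# ---------------------------------------------------------------------------
# recordings and windows
# ---------------------------------------------------------------------------


@dataclass
class Recording:
    """A C x T multichannel signal with its geometry and stimulation events."""

    signal: np.ndarray  # (C, T)
    geometry: ElectrodeGeometry
    schedule: StimSchedule
    fs: int = FS_HZ
    session_id: str = "session-0"

    def __post_init__(self) -> None:
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=float))

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]


@dataclass(frozen=True)
class Window:
    """One 1500 ms analysis window around a stimulation event."""

    start: int
    stop: int
    event_index: int
    onset: int  # (corrected) stimulation onset sample
    freq_hz: float
    amp_ma: float
    test_fold: int
    fold_len: int = FOLD_MS

    @property
    def is_single_pulse(self) -> bool:
        return self.freq_hz < 0

    @property
    def stim_span(self) -> tuple[int, int]:
        """Half-open span of samples counted as STIM ON (empty for 0 Hz
        STIM OFF pseudo-windows)."""
        if self.freq_hz == 0:
            return (self.onset, self.onset)
        if self.is_single_pulse:
            return (self.onset, self.onset + 1)
        return (self.onset, self.onset + STIM_DURATION_MS + 1)

    def fold_of(self, t: int | np.ndarray) -> np.ndarray:
        return np.minimum((np.asarray(t) - self.start) // self.fold_len, N_FOLDS - 1)


@dataclass
class WindowSet:
    windows: list[Window]
    seed: int | None = None
    n_skipped: int = 0

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)

    def __getitem__(self, i: int) -> Window:
        return self.windows[i]


# ---------------------------------------------------------------------------
# model specification / fit results
# ---------------------------------------------------------------------------

_FAMILY_BLOCKS: Mapping[str, frozenset[str]] = {
    "ar": frozenset({"a"}),
    "arx": frozenset({"a", "b"}),
    "var": frozenset({"a", "d"}),
    "varx": frozenset({"a", "b", "d"}),
    "sl-ar": frozenset({"a", "c"}),
    "sl-arx": frozenset({"a", "b", "c"}),
    "sl-var": frozenset({"a", "c", "d"}),
    "sl-varx": frozenset({"a", "b", "c", "d"}),
}


@dataclass(frozen=True)
class ModelSpec:
    """Structural choices for one channel model.

    ``gating`` selects how the interaction term is driven: ``"none"`` (linear),
    ``"switched"`` (0/1), ``"amplitude"`` (amplitude-weighted switched) or
    ``"bilinear"`` (gate equals the input series).  ``sources`` lists the other
    channels whose ``P`` past samples enter as network features.  ``sparse``
    switches the autoregressive block to delay-embedded lags
    ``t - tau, t - 2 tau, ..., t - L tau``.
    """

    target: int
    L: int
    M: int = 0
    P: int = 0
    gating: str = "none"
    sources: tuple[int, ...] = ()
    sparse: bool = False
    tau: int = 1

    def __post_init__(self) -> None:
        if self.L < 0 or self.M < 0 or self.P < 0:
            raise InvalidArgumentError("lags must be nonnegative")
        if self.tau < 1:
            raise InvalidArgumentError("tau must be >= 1")
        if self.gating not in GATING_MODES:
            raise InvalidArgumentError(f"unknown gating mode {self.gating!r}")
        if self.sparse and (self.gating != "none" or self.P > 0):
            raise InvalidArgumentError(
                "sparse delay embedding is defined for the plain ARX family only"
            )
        object.__setattr__(self, "sources", tuple(sorted(self.sources)))
        if self.target in self.sources:
            raise InvalidArgumentError("target channel cannot be its own source")
        if self.P > 0 and not self.sources:
            raise InvalidArgumentError("P > 0 requires a nonempty source set")

    @property
    def gated(self) -> bool:
        return self.gating != "none"

    @property
    def family(self) -> str:
        blocks = {"a"}
        if self.gated:
            blocks.add("c")
        if self.M > 0:
            blocks.add("b")
        if self.P > 0 and self.sources:
            blocks.add("d")
        for name, members in _FAMILY_BLOCKS.items():
            if members == frozenset(blocks):
                return name
        raise AssertionError("unreachable")

    @property
    def max_lag(self) -> int:
        ar_span = self.L * self.tau if self.sparse else self.L
        return max(ar_span, self.M, self.P if self.sources else 0)

    @property
    def n_params(self) -> int:
        n = self.L + (self.L if self.gated else 0) + self.M
        n += self.P * len(self.sources)
        return n

    def block_slices(self) -> dict[str, slice]:
        """Column layout of the feature matrix: a, (c), b, then one d block per source."""
        out: dict[str, slice] = {}
        pos = 0
        out["a"] = slice(pos, pos + self.L)
        pos += self.L
        if self.gated:
            out["c"] = slice(pos, pos + self.L)
            pos += self.L
        out["b"] = slice(pos, pos + self.M)
        pos += self.M
        for i in self.sources:
            out[f"d:{i}"] = slice(pos, pos + self.P)
            pos += self.P
        return out

    def with_sources(self, sources: Sequence[int], P: int | None = None) -> "ModelSpec":
        P = self.P if P is None else P
        if not sources:
            P = 0
        return replace(self, sources=tuple(sources), P=P)


@dataclass
class RegressionDataset:
    """Feature matrix / target pairs extracted under one :class:`ModelSpec`.

    Row bookkeeping keeps, for every sample ``t``: the current value ``y(t)``
    (so predictions ``y(t+1) = y(t) + dy`` can be reconstructed), the window it
    came from, its fold, and whether the fold was assigned to training.
    """

    X: np.ndarray  # (N, p)
    dy: np.ndarray  # (N,)
    y_t: np.ndarray  # (N,)
    t_index: np.ndarray  # (N,) sample index t of each row
    window_index: np.ndarray  # (N,)
    fold: np.ndarray  # (N,) in 0..4
    is_train: np.ndarray  # (N,) bool
    spec: ModelSpec

    @property
    def N(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def rows(self, which: str = "all") -> np.ndarray:
        if which == "all":
            return np.ones(self.N, dtype=bool)
        if which == "train":
            return self.is_train.copy()
        if which == "test":
            return ~self.is_train
        raise InvalidArgumentError("rows must be 'all', 'train' or 'test'")


@dataclass
class FittedModel:
    """A ridge-estimated parameter vector together with the spec it realizes."""

    spec: ModelSpec
    theta: np.ndarray
    lam: float
    n_train: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float).ravel()
        if self.theta.size != self.spec.n_params:
            raise InvalidArgumentError(
                f"theta length {self.theta.size} != free-parameter count "
                f"{self.spec.n_params}"
            )

    def block(self, name: str) -> np.ndarray:
        return self.theta[self.spec.block_slices()[name]]

    def predict_dy(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.theta.size:
            raise InvalidArgumentError(
                f"feature dimension {X.shape[1]} != theta length {self.theta.size}"
            )
        return X @ self.theta


@dataclass
class CausalTestResult:
    """Outcome of a shuffle-based causal-effect test."""

    observed_mse: float
    null_mse: np.ndarray
    p_value: float
    n_boot: int
    alpha: float
    reject: bool
    seed: int | None = None
    degenerate: bool = False
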