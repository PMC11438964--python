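"""Signal conditioning, stimulation encoding, onset correction and windowing.

The preprocessing chain per channel is: zero-phase Butterworth notch filters
at the power-line harmonics (60/120/180 Hz), first-order polynomial detrend,
then z-scoring over the whole session.  Analysis windows of 1500 ms are cut
around every stimulation event (500 pre / 500 stim / 500 post for pulse
trains; 750 pre / 750 post for single pulses) and tiled by five contiguous
300 ms folds, four of which are assigned to training per window.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import replace

import numpy as np
from scipy import signal as sps

from .types import (
    ALLOWED_FREQS,
    FOLD_MS,
    FS_HZ,
    N_FOLDS,
    PRE_MS,
    SINGLE_PRE_MS,
    STIM_DURATION_MS,
    DataError,
    InvalidArgumentError,
    Recording,
    StimEvent,
    StimSchedule,
    Window,
    WindowSet,
)

logger = logging.getLogger(__name__)

NOTCH_FREQS_HZ = (60.0, 120.0, 180.0)
NOTCH_HALF_BANDWIDTH_HZ = 2.0


def _notch_sos(freq: float, fs: float) -> np.ndarray:
    lo = freq - NOTCH_HALF_BANDWIDTH_HZ
    hi = freq + NOTCH_HALF_BANDWIDTH_HZ
    # order 2 band-stop -> 4 poles, i.e. a 4th-order notch
    return sps.butter(2, [lo, hi], btype="bandstop", fs=fs, output="sos")


def preprocess_signal(recording: Recording) -> Recording:
    """Notch-filter, detrend and z-score every channel of a recording.

    Constant (zero-variance) channels are left un-z-scored and reported via a
    ``RuntimeWarning``.
    """
    if recording.fs != FS_HZ:
        raise InvalidArgumentError(f"expected fs={FS_HZ} Hz, got {recording.fs}")
    y = np.array(recording.signal, dtype=float)
    sos = [_notch_sos(f, recording.fs) for f in NOTCH_FREQS_HZ]
    for k in range(y.shape[0]):
        ch = y[k]
        for s in sos:
            ch = sps.sosfiltfilt(s, ch)
        ch = sps.detrend(ch, type="linear")
        sd = ch.std()
        if sd == 0:
            warnings.warn(
                f"channel {k} has zero variance; z-score skipped", RuntimeWarning
            )
            y[k] = ch
            continue
        y[k] = (ch - ch.mean()) / sd
    return replace(recording, signal=y)


def encode_input(
    events: StimSchedule | list[StimEvent], T: int
) -> np.ndarray:
    """Build the input series ``u`` from the stimulation events.

    A pulse train ``(f, a)`` starting at sample ``t_k`` sets ``u(t_k + dt) = a``
    for every ``dt`` in ``[0, 500]`` that is an integer multiple of ``1000/f``;
    a single pulse sets only ``u(t_k) = a``.
    """
    evts = events.events if isinstance(events, StimSchedule) else events
    u = np.zeros(T)
    for ev in evts:
        if not 0 <= ev.onset < T:
            raise InvalidArgumentError(f"event onset {ev.onset} outside [0, {T})")
        if ev.is_single_pulse:
            u[ev.onset] = ev.amp_ma
            continue
        if ev.freq_hz not in ALLOWED_FREQS:
            raise InvalidArgumentError(
                f"frequency {ev.freq_hz} Hz not in allowed set {ALLOWED_FREQS}"
            )
        period = 1000.0 / ev.freq_hz
        n_pulses = int(np.floor(STIM_DURATION_MS / period)) + 1
        offsets = np.rint(np.arange(n_pulses) * period).astype(int)
        idx = ev.onset + offsets
        u[idx[idx < T]] = ev.amp_ma
    return u


def gating_signal(
    u: np.ndarray,
    events: StimSchedule | list[StimEvent],
    mode: str,
) -> np.ndarray:
    """Build the gating series for a declared mode.

    ``switched`` is 1 on ``[t_k, t_k + 500]`` (inclusive of both ends) and 0
    elsewhere; ``amplitude`` uses the event amplitude on the same span;
    ``bilinear`` equals ``u`` elementwise; ``none`` is identically zero.
    """
    u = np.asarray(u, dtype=float)
    T = u.shape[0]
    if mode == "bilinear":
        return u.copy()
    U = np.zeros(T)
    if mode == "none":
        return U
    if mode not in ("switched", "amplitude"):
        raise InvalidArgumentError(f"unknown gating mode {mode!r}")
    evts = events.events if isinstance(events, StimSchedule) else events
    for ev in evts:
        if ev.is_single_pulse:
            span = slice(ev.onset, min(ev.onset + 1, T))
        else:
            span = slice(ev.onset, min(ev.onset + STIM_DURATION_MS + 1, T))
        U[span] = 1.0 if mode == "switched" else ev.amp_ma
    return U


def correct_onsets(
    recording: Recording,
    events: StimSchedule | None = None,
    search_halfwidth_ms: int = 50,
    threshold_multiple: float = 5.0,
    baseline_ms: int = 300,
) -> tuple[StimSchedule, list[dict]]:
    """Re-align reported onsets to the observed response in the anode channel.

    For each event, the onset moves to the first sample within the search
    half-width of the reported onset where ``|dy|`` of the anode channel
    exceeds ``threshold_multiple`` times the pre-event SD of ``dy``.  Events
    with no threshold crossing keep their reported onset and are flagged.
    """
    schedule = events if events is not None else recording.schedule
    anode = recording.geometry.anode_index
    if anode >= recording.n_channels:
        raise InvalidArgumentError("anode channel missing from recording")
    dy = np.diff(recording.signal[anode], prepend=recording.signal[anode, :1])
    hw = int(search_halfwidth_ms)
    corrected = []
    report = []
    for ev in schedule.events:
        t0 = ev.onset
        base = dy[max(0, t0 - hw - baseline_ms) : max(0, t0 - hw)]
        sd = base.std() if base.size else 0.0
        lo, hi = max(1, t0 - hw), min(len(dy) - 1, t0 + hw)
        hit = None
        if sd > 0:
            seg = np.abs(dy[lo : hi + 1])
            above = np.nonzero(seg > threshold_multiple * sd)[0]
            if above.size:
                hit = lo + int(above[0])
        new_onset = hit if hit is not None else t0
        corrected.append(replace(ev, onset=new_onset))
        report.append(
            {
                "event_onset": t0,
                "corrected_onset": new_onset,
                "delay": new_onset - t0,
                "adjusted": hit is not None,
            }
        )
    n_flagged = sum(not r["adjusted"] for r in report)
    if n_flagged:
        logger.info("onset correction: %d/%d events unadjusted", n_flagged, len(report))
    return StimSchedule(tuple(corrected), schedule.a_safe, schedule.gap_ms), report


def extract_windows_and_folds(
    recording: Recording,
    events: StimSchedule | None = None,
    seed: int | None = 0,
) -> WindowSet:
    """Cut one 1500 ms window per event and assign a random test fold to each.

    Pulse-train windows span ``[onset - 500, onset + 1000)``; single-pulse
    windows span ``[onset - 750, onset + 750)``.  Each window is tiled by five
    contiguous 300 ms folds and one fold, drawn per window from ``seed``, is
    held out for testing.  Windows that would cross the recording edges are
    skipped.
    """
    schedule = events if events is not None else recording.schedule
    rng = np.random.default_rng(seed)
    T = recording.n_samples
    windows: list[Window] = []
    n_skipped = 0
    for j, ev in enumerate(schedule.events):
        pre = SINGLE_PRE_MS if ev.is_single_pulse else PRE_MS
        start = ev.onset - pre
        stop = start + N_FOLDS * FOLD_MS
        test_fold = int(rng.integers(N_FOLDS))
        if start < 0 or stop > T:
            n_skipped += 1
            continue
        windows.append(
            Window(
                start=start,
                stop=stop,
                event_index=j,
                onset=ev.onset,
                freq_hz=ev.freq_hz,
                amp_ma=ev.amp_ma,
                test_fold=test_fold,
            )
        )
    if n_skipped:
        logger.info("skipped %d windows too close to recording edges", n_skipped)
    if not windows:
        raise DataError("no extractable windows")
    return WindowSet(windows=windows, seed=seed, n_skipped=n_skipped)


def full_series_window(T: int, seed: int | None = None) -> WindowSet:
    """A single pseudo-window covering the whole recording.

    Used when models are fit on a continuous stretch rather than on
    stimulation-locked excerpts (e.g. parameter-recovery experiments).  The
    window still carries five contiguous folds (of ``T/5`` samples each here)
    with one held out.
    """
    rng = np.random.default_rng(seed)
    test_fold = int(rng.integers(N_FOLDS)) if seed is not None else N_FOLDS - 1
    w = Window(
        start=0, stop=T, event_index=-1, onset=0, freq_hz=0.0, amp_ma=0.0,
        test_fold=test_fold, fold_len=-(-T // N_FOLDS),
    )
    return WindowSet(windows=[w], seed=seed)


def prepare_inputs(
    schedule: StimSchedule, T: int, mode: str
) -> tuple[np.ndarray, np.ndarray]:
    """Convenience: ``(u, U)`` for a schedule and gating mode."""
    u = encode_input(schedule, T)
    return u, gating_signal(u, schedule, mode)
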