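"""Ground-truth system sampling, stimulation schedules and forward simulation.

Systems are sampled directly in terms of stable dynamics: the map
``y(t+1) = y(t) + a' [y(t-1)..y(t-L)]`` has characteristic polynomial
``z^(L+1) - z^L - a_1 z^(L-1) - ... - a_L``, so we draw ``L + 1`` roots inside
the stability margin whose sum equals 1 (the fixed ``z^L`` coefficient) and
read the coefficients off the polynomial.  The STIM ON regime ``a + c`` is
sampled the same way, which defines ``c``.  Network couplings are drawn
uniform with random sign and globally rescaled until the joint
companion-form system is stable in both regimes.
"""

from __future__ import annotations

import logging

import numpy as np

from .io import read_ground_truth, write_ground_truth  # noqa: F401 (re-export)
from .preprocess import prepare_inputs
from .types import (
    ALLOWED_FREQS,
    SINGLE_PRE_MS,
    SINGLE_PULSE,
    STIM_DURATION_MS,
    ElectrodeGeometry,
    GroundTruthSystem,
    InstabilityError,
    InvalidArgumentError,
    Recording,
    ScheduleError,
    StimEvent,
    StimSchedule,
)

logger = logging.getLogger(__name__)

FAMILIES = ("ar", "arx", "var", "varx", "sl-ar", "sl-arx", "sl-var", "sl-varx")


def make_electrode_geometry(
    n_channels: int,
    extent_mm: float = 150.0,
    seed: int | None = 0,
    coords: np.ndarray | None = None,
) -> ElectrodeGeometry:
    """Random electrode positions with the anode (channel 0) at the origin.

    Channels 1.. are uniform in the cube ``[-extent/2, extent/2]^3``.  Pass
    ``coords`` to pin positions explicitly.
    """
    if n_channels < 1:
        raise InvalidArgumentError("n_channels must be >= 1")
    if coords is not None:
        return ElectrodeGeometry(coords=np.asarray(coords, dtype=float), anode_index=0)
    if extent_mm <= 0:
        raise InvalidArgumentError("extent must be positive")
    rng = np.random.default_rng(seed)
    pts = np.zeros((n_channels, 3))
    if n_channels > 1:
        pts[1:] = rng.uniform(-extent_mm / 2, extent_mm / 2, size=(n_channels - 1, 3))
    return ElectrodeGeometry(coords=pts, anode_index=0)


# ---------------------------------------------------------------------------
# stable coefficient sampling
# ---------------------------------------------------------------------------


def companion_radius(a: np.ndarray) -> float:
    """Spectral radius of the map ``y(t+1) = y(t) + a' [y(t-1)..y(t-L)]``."""
    a = np.asarray(a, dtype=float).ravel()
    L = a.size
    C = np.zeros((L + 1, L + 1))
    C[0, 0] = 1.0
    C[0, 1:] = a
    C[1:, :-1] = np.eye(L)
    return float(np.max(np.abs(np.linalg.eigvals(C))))


def sample_stable_ar(
    L: int,
    rng: np.random.Generator,
    margin: float = 0.95,
    root_radius: float = 0.6,
    root_center: float = 0.15,
    max_retries: int = 200,
) -> np.ndarray:
    """Draw ``a`` (length L) with companion spectral radius <= margin.

    Roots are sampled conjugate-symmetric in a disk, then shifted by a common
    real offset so they sum to 1 as the characteristic polynomial requires.
    """
    if L == 0:
        return np.zeros(0)
    n = L + 1
    for _ in range(max_retries):
        m = n // 2
        z = (root_center + root_radius * rng.uniform(-1, 1, m)
             + 1j * root_radius * rng.uniform(0, 1, m))
        roots = np.concatenate([z, np.conj(z)])
        if n % 2:
            roots = np.append(roots, root_center + root_radius * rng.uniform(-1, 1))
        roots = roots + (1 - roots.sum().real) / n
        if np.max(np.abs(roots)) > margin:
            continue
        poly = np.real(np.poly(roots))
        a = -poly[2:]
        if companion_radius(a) <= margin + 1e-9:
            return a
    raise InstabilityError(f"could not sample a stable AR({L}) block")


def _joint_companion(a_eff: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Companion matrix of the coupled network map for one regime."""
    C, L = a_eff.shape
    P = d.shape[2]
    Q = max(L, P) + 1
    A = np.zeros((C * Q, C * Q))
    for k in range(C):
        row = k * Q
        A[row, row] = 1.0
        A[row, row + 1 : row + 1 + L] += a_eff[k]
        for i in range(C):
            if i == k:
                continue
            col = i * Q
            A[row, col + 1 : col + 1 + P] += d[k, i]
        A[row + 1 : row + Q, row : row + Q - 1] += np.eye(Q - 1)
    return A


def network_radius(system: GroundTruthSystem) -> float:
    """Largest spectral radius over the two regimes of the full coupled system."""
    r_off = np.max(np.abs(np.linalg.eigvals(
        _joint_companion(system.a, system.d))))
    r_on = np.max(np.abs(np.linalg.eigvals(
        _joint_companion(system.a + system.c, system.d))))
    return float(max(r_off, r_on))


def sample_ground_truth_system(
    geometry: ElectrodeGeometry,
    family: str = "sl-arx",
    L: int = 5,
    M: int = 3,
    P: int = 1,
    gating: str | None = None,
    noise_sd: float = 0.1,
    margin: float = 0.95,
    coupling_band: tuple[float, float] | None = None,
    coupling_sources: str = "all",
    b_range: tuple[float, float] = (0.1, 0.5),
    d_range: tuple[float, float] = (0.05, 0.25),
    min_regime_gap: float = 0.0,
    seed: int | None = 0,
    max_retries: int = 50,
) -> GroundTruthSystem:
    """Sample a stable ground-truth system of the requested family.

    Blocks outside the family are exactly zero.  ``coupling_band`` restricts
    nonzero ``d[k, i]`` to source-target distances inside the given open
    interval (mm); ``coupling_sources="anode"`` additionally restricts sources
    to the stimulation channel.  Couplings are rescaled (factor 0.7 per retry)
    until the joint two-regime system is stable; failure after bounded retries
    raises :class:`InstabilityError`.
    """
    if family not in FAMILIES:
        raise InvalidArgumentError(f"unknown family {family!r}")
    if L < 0 or M < 0 or P < 0:
        raise InvalidArgumentError("lags must be nonnegative")
    has_b = "x" in family
    has_c = family.startswith("sl-")
    has_d = "v" in family
    if gating is None:
        gating = "switched" if has_c else "none"
    if has_c and gating == "none":
        raise InvalidArgumentError(f"family {family!r} requires a gating mode")
    if not has_c:
        gating = "none"
    rng = np.random.default_rng(seed)
    C = geometry.n_channels

    a = np.vstack([sample_stable_ar(L, rng, margin=margin) for _ in range(C)]) \
        if L else np.zeros((C, 0))
    c = np.zeros((C, L))
    if has_c and L:
        # ``min_regime_gap`` (l1 distance between the two regimes) guards
        # against draws whose ON regime lands so close to the OFF regime
        # that the switching is undetectable
        on = np.empty_like(a)
        for k in range(C):
            for _ in range(max_retries):
                on[k] = sample_stable_ar(L, rng, margin=margin)
                if np.abs(on[k] - a[k]).sum() >= min_regime_gap:
                    break
            else:
                raise InstabilityError(
                    "could not sample a sufficiently distinct ON regime")
        c = on - a
    b = np.zeros((C, M))
    if has_b and M:
        mag = rng.uniform(*b_range, size=(C, M))
        b = mag * rng.choice([-1.0, 1.0], size=(C, M))

    d = np.zeros((C, C, max(P, 0)))
    if has_d and P and C > 1:
        dist = geometry.pairwise_dist
        mask = ~np.eye(C, dtype=bool)
        if coupling_sources == "anode":
            m2 = np.zeros_like(mask)
            m2[:, geometry.anode_index] = True
            mask &= m2
        elif coupling_sources != "all":
            raise InvalidArgumentError("coupling_sources must be 'all' or 'anode'")
        if coupling_band is not None:
            lo, hi = coupling_band
            mask &= (dist > lo) & (dist < hi)
        mag = rng.uniform(*d_range, size=(C, C, P))
        sgn = rng.choice([-1.0, 1.0], size=(C, C, P))
        d = np.where(mask[:, :, None], mag * sgn, 0.0)

    system = GroundTruthSystem(
        a=a, b=b, c=c, d=d, gating=gating, noise_sd=noise_sd,
        margin=margin, seed=seed,
    )
    if has_d and np.any(d != 0):
        for attempt in range(max_retries):
            if network_radius(system) <= margin + 1e-9:
                break
            system.d *= 0.7
        else:
            raise InstabilityError(
                f"network system not stabilizable after {max_retries} rescalings"
            )
    return system


# ---------------------------------------------------------------------------
# schedules
# ---------------------------------------------------------------------------


def make_schedule(
    frequencies=ALLOWED_FREQS + (SINGLE_PULSE,),
    amplitudes: tuple[float, ...] | None = None,
    reps: int = 20,
    gap_ms: int = 1500,
    a_safe: float = 2.0,
    seed: int | None = 0,
    start_ms: int | None = None,
) -> StimSchedule:
    """A randomized factorial schedule: every (frequency, amplitude) cell
    appears exactly ``reps`` times, order shuffled by ``seed``.

    Amplitudes default to the three levels ``{a_safe, a_safe - 0.25,
    a_safe - 0.5}`` mA.  Consecutive onsets are ``500 + gap_ms`` apart;
    ``gap_ms`` must be at least 1000 so 1500 ms windows never overlap.
    """
    if reps < 1:
        raise InvalidArgumentError("reps must be >= 1")
    if gap_ms < 1000:
        raise ScheduleError("gap must be >= 1000 ms so windows cannot overlap")
    for f in frequencies:
        if f != SINGLE_PULSE and f not in ALLOWED_FREQS:
            raise InvalidArgumentError(f"frequency {f} not in allowed set")
    if amplitudes is None:
        amplitudes = (a_safe, a_safe - 0.25, a_safe - 0.5)
    rng = np.random.default_rng(seed)
    cells = [(f, amp) for f in frequencies for amp in amplitudes for _ in range(reps)]
    rng.shuffle(cells)
    start = start_ms if start_ms is not None else max(SINGLE_PRE_MS, gap_ms)
    events = []
    for j, (f, amp) in enumerate(cells):
        onset = start + j * (STIM_DURATION_MS + gap_ms)
        events.append(
            StimEvent(onset=onset, duration_ms=STIM_DURATION_MS,
                      freq_hz=float(f), amp_ma=float(amp))
        )
    return StimSchedule(events=tuple(events), a_safe=a_safe, gap_ms=gap_ms)


# ---------------------------------------------------------------------------
# forward simulation
# ---------------------------------------------------------------------------


def simulate_recording(
    system: GroundTruthSystem,
    schedule: StimSchedule,
    geometry: ElectrodeGeometry | None = None,
    duration: int | None = None,
    init: np.ndarray | None = None,
    seed: int | None = 0,
    session_id: str = "session-0",
) -> Recording:
    """Run the system forward over a stimulation schedule.

    ``y(t+1) = y(t) + dy(t) + noise`` with ``dy`` from the one-step model
    under the system's gating mode; pre-history (t < 0) is zero unless
    ``init`` provides the first samples.  Refuses visibly unstable systems.
    """
    C = system.n_channels
    if geometry is None:
        geometry = make_electrode_geometry(C, seed=0)
    if geometry.n_channels != C:
        raise InvalidArgumentError("geometry channel count mismatch")
    T = duration if duration is not None else schedule.end_sample + 1000
    if schedule.events and T < schedule.end_sample:
        raise InvalidArgumentError("duration does not cover the schedule")
    for k in range(C):
        if companion_radius(system.a[k]) > system.margin + 1e-6:
            raise InstabilityError(f"channel {k} STIM OFF regime unstable")
        if system.c.size and companion_radius(system.a[k] + system.c[k]) \
                > system.margin + 1e-6:
            raise InstabilityError(f"channel {k} STIM ON regime unstable")

    u, U = prepare_inputs(schedule, T, system.gating)
    L, M, P = system.L, system.M, system.P
    mp = max(system.max_lag, 1)
    yp = np.zeros((C, mp + T))
    if init is not None:
        init = np.atleast_2d(np.asarray(init, dtype=float))
        yp[:, mp : mp + init.shape[1]] = init
    up = np.concatenate([np.zeros(mp), u])
    a_rev = system.a[:, ::-1].copy() if L else None
    c_rev = system.c[:, ::-1].copy() if (L and system.c.size) else None
    b_rev = system.b[:, ::-1].copy() if M else None
    d_rev = system.d[:, :, ::-1].copy() if P else None
    has_gate = system.gating != "none" and c_rev is not None
    has_net = d_rev is not None and np.any(d_rev != 0)

    rng = np.random.default_rng(seed)
    noise = (rng.normal(0.0, system.noise_sd, size=(C, T))
             if system.noise_sd > 0 else None)
    start = init.shape[1] if init is not None else 1
    for t in range(max(start, 1) - 1, T - 1):
        i = mp + t
        dy = np.zeros(C)
        if L:
            yl = yp[:, i - L : i]
            dy += (a_rev * yl).sum(axis=1)
            if has_gate and U[t] != 0:
                dy += U[t] * (c_rev * yl).sum(axis=1)
        if M:
            dy += b_rev @ up[i - M : i]
        if has_net:
            dy += np.einsum("kip,ip->k", d_rev, yp[:, i - P : i])
        nxt = yp[:, i] + dy
        if noise is not None:
            nxt = nxt + noise[:, t + 1]
        yp[:, i + 1] = nxt
    return Recording(
        signal=yp[:, mp:], geometry=geometry, schedule=schedule,
        session_id=session_id,
    )
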