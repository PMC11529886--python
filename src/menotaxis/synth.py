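"""Synthetic tethered-fly cohorts: paradigm schedules and heading traces.

The generator stands in for raw arena recordings. Each synthetic fly
holds a von-Mises-concentrated heading around a preferred direction
defined by an explicit behavior policy:

``maintain_relative``
    locks to the (weight-dominant) stimulus azimuth and tracks it — sun
    orientation.
``reset_on_move``
    menotaxis to the stimulus, but redraws a fresh uniform offset
    whenever the stimulus jumps by at least ``reset_threshold_deg`` —
    the observed response to large single-LED moves.
``real_world_keeper``
    holds a fixed arena (real-world) direction regardless of the
    stimulus.
``time_compensated``
    shifts its stimulus-relative heading at ``compensation_rate_deg_per_h``
    (negative drift for clockwise stimulus rotation, positive for
    counterclockwise), the signature a time-compensated sun compass
    would leave in the stimulus frame.
``uniform_random``
    redraws a fresh uniform offset every flight epoch (no heading
    memory).

Per-frame noise is an AR(1) process on the heading deviation built
through a Gaussian copula, so the stationary marginal is exactly von
Mises with concentration ``kappa`` while consecutive frames remain
correlated. Dark epochs emit rapid rotation; stop episodes arrive as a
Poisson process and are emitted as flagged stopped runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .arena import (
    DEFAULT_FRAME_RATE_HZ,
    HeadingTrace,
    Stimulus,
    StimulusEpoch,
    StimulusSchedule,
    write_schedule,
    write_trace,
)
from .circkit import wrap_deg, vm_mean_resultant

__all__ = [
    "BehaviorPolicy",
    "NoiseModel",
    "CohortTruth",
    "PARADIGMS",
    "build_schedule",
    "simulate_fly",
    "simulate_cohort",
]

POLICY_KINDS = (
    "maintain_relative",
    "reset_on_move",
    "real_world_keeper",
    "time_compensated",
    "uniform_random",
)

#: the four 90-deg-spaced starting azimuths used for single-LED trials
START_POSITIONS = (0.0, 90.0, 180.0, -90.0)

DARK_CHECK_S = 30.0
FLIGHT_S = 300.0


@dataclass(frozen=True)
class BehaviorPolicy:
    """How a synthetic fly chooses its reference direction."""

    kind: str = "maintain_relative"
    cue_weights: Dict[str, float] = field(
        default_factory=lambda: {"uv": 2.0, "green": 1.0}
    )
    reset_threshold_deg: float = 30.0
    compensation_rate_deg_per_h: float = 15.0

    def __post_init__(self):
        if self.kind not in POLICY_KINDS:
            raise ValueError(f"unknown policy kind {self.kind!r}")
        if self.reset_threshold_deg <= 0:
            raise ValueError("reset_threshold_deg must be positive")
        if any(w < 0 for w in self.cue_weights.values()):
            raise ValueError("cue weights must be non-negative")

    def dominant_channel(self, stimuli: Sequence[Stimulus]) -> Stimulus:
        """Weight-argmax stimulus; green wins exact ties (documented
        arbitrary rule, moot with the default UV-dominant weights)."""
        if not stimuli:
            raise ValueError("no stimuli present")
        weights = [self.cue_weights.get(s.channel, 0.0) for s in stimuli]
        if all(w == 0 for w in weights):
            raise ValueError("all cue weights zero with stimuli present")
        best = max(weights)
        tied = [s for s, w in zip(stimuli, weights) if w == best]
        for s in tied:
            if s.channel == "green":
                return s
        return tied[0]


@dataclass(frozen=True)
class NoiseModel:
    """Per-frame heading noise and non-flight behavior.

    ``kappa`` is the von Mises concentration of the stationary per-frame
    deviation (kappa ~ 2.9 gives vector strength ~0.8); ``ar_coefficient``
    sets frame-to-frame persistence (0.8 at 25 Hz is a ~0.2 s relaxation
    time). Dark periods rotate at ``dark_rotation_deg_s``; stops arrive
    at ``stop_rate_per_min`` and last ``stop_duration_s``.
    """

    kappa: float = 2.9
    ar_coefficient: float = 0.8
    dark_rotation_deg_s: float = 120.0
    stop_rate_per_min: float = 0.05
    stop_duration_s: float = 5.0

    def __post_init__(self):
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if not 0.0 <= self.ar_coefficient < 1.0:
            raise ValueError("ar_coefficient must lie in [0, 1)")
        if self.stop_rate_per_min < 0 or self.stop_duration_s <= 0:
            raise ValueError("invalid stop process parameters")


@dataclass(frozen=True)
class CohortTruth:
    """Generator-side ground truth for one synthetic fly."""

    fly_id: str
    policy: str
    preferred_offset_deg: float
    kappa: float
    seed: int


# ---------------------------------------------------------------------------
# paradigm schedules
# ---------------------------------------------------------------------------

def _start_azimuth(rng: np.random.Generator) -> float:
    return float(rng.choice(START_POSITIONS))


def _dir_sign(rotation_dir: str) -> int:
    return -1 if rotation_dir == "cw" else 1


def _green(az: float) -> Tuple[Stimulus, ...]:
    return (Stimulus(az, "green"),)


def _uv(az: float) -> Tuple[Stimulus, ...]:
    return (Stimulus(az, "uv"),)


def _paired(green_az: float) -> Tuple[Stimulus, ...]:
    return (Stimulus(green_az, "green"), Stimulus(green_az + 180.0, "uv"))


def build_schedule(paradigm: str, seed: Optional[int] = None,
                   rotation_dir: Optional[str] = None,
                   step_deg: Optional[float] = None,
                   rest_h: float = 2.0,
                   intertrial_visual: str = "dark",
                   intertrial_motor: str = "rest",
                   move_deg: float = 90.0,
                   second_channel: str = "uv") -> StimulusSchedule:
    """Build the stimulus schedule for one of the experimental paradigms.

    Paradigms
    ---------
    long_constant
        30 s dark, then a 20 min flight with one static green LED.
    long_moves
        30 s dark, then four 5 min flights; the LED jumps by
        ``step_deg`` (90 or 180) between flights.
    varied_stimuli
        30 s dark, 5 min flight, 5 min intertrial (dark/LED x
        rest/flight), 5 min second flight with the LED moved by
        ``move_deg`` (0, 90 or 180).
    time_gap
        5 min flight, a ``rest_h``-hour rest out of the arena, 5 min
        second flight with the LED unmoved.
    small_shift
        three 5 min flights; the LED shifts 15 deg cw/ccw between each.
    gradual_shift
        twelve 100 s presentations shifting 5 deg each, 60 deg total.
    tcsc_single / tcsc_paired
        5 min flights at 0, 1, 2 and 6 h; the stimulus moves at
        15 deg/h (offsets 15, 30, 90 deg), single green or paired
        green+UV.
    paired_uv_green
        5 min with paired green+UV 180 deg apart, then 5 min with only
        ``second_channel`` lit.
    uv_only_moves
        three 5 min UV-only flights with ``step_deg`` jumps between.
    paired_move_90
        5 min paired, then 5 min with both LEDs moved 90 deg cw/ccw.
    """
    rng = np.random.default_rng(seed)
    if rotation_dir is None:
        rotation_dir = "cw" if rng.random() < 0.5 else "ccw"
    sgn = _dir_sign(rotation_dir)
    az0 = _start_azimuth(rng)
    eps: List[StimulusEpoch] = []
    t = 0.0

    def add(duration, label, stimuli=()):
        nonlocal t
        eps.append(StimulusEpoch(t, t + duration, label, stimuli))
        t += duration

    if paradigm == "long_constant":
        add(DARK_CHECK_S, "dark")
        add(1200.0, "flight1", _green(az0))
        rotation_dir = "none"
    elif paradigm == "long_moves":
        step = step_deg if step_deg is not None else float(rng.choice([90.0, 180.0]))
        add(DARK_CHECK_S, "dark")
        for k in range(4):
            add(FLIGHT_S, f"flight{k + 1}", _green(az0 + sgn * step * k))
    elif paradigm == "varied_stimuli":
        if intertrial_visual not in ("dark", "led"):
            raise ValueError("intertrial_visual must be 'dark' or 'led'")
        if intertrial_motor not in ("rest", "flight"):
            raise ValueError("intertrial_motor must be 'rest' or 'flight'")
        add(DARK_CHECK_S, "dark")
        add(FLIGHT_S, "flight1", _green(az0))
        inter_stim = _green(az0) if intertrial_visual == "led" else ()
        add(FLIGHT_S, f"intertrial_{intertrial_visual}_{intertrial_motor}",
            inter_stim)
        add(FLIGHT_S, "flight2", _green(az0 + sgn * move_deg))
        rotation_dir = rotation_dir if move_deg else "none"
    elif paradigm == "time_gap":
        add(DARK_CHECK_S, "dark")
        add(FLIGHT_S, "flight1", _green(az0))
        add(rest_h * 3600.0, "rest")
        add(FLIGHT_S, "flight2", _green(az0))
        rotation_dir = "none"
    elif paradigm == "small_shift":
        add(DARK_CHECK_S, "dark")
        for k in range(3):
            add(FLIGHT_S, f"flight{k + 1}", _green(az0 + sgn * 15.0 * k))
    elif paradigm == "gradual_shift":
        # 12 presentations, each shifted 5 deg from the one before (the
        # first already shifted from the starting position): 60 deg total
        add(DARK_CHECK_S, "dark")
        for k in range(12):
            add(100.0, f"flight{k + 1}", _green(az0 + sgn * 5.0 * (k + 1)))
    elif paradigm in ("tcsc_single", "tcsc_paired"):
        mk = _green if paradigm == "tcsc_single" else _paired
        hours = (0.0, 1.0, 2.0, 6.0)
        for i, h in enumerate(hours):
            start = h * 3600.0
            if t < start:
                add(start - t, f"rest{i}")
            add(DARK_CHECK_S, f"dark{i + 1}" if i else "dark")
            add(FLIGHT_S, f"flight{i + 1}", mk(az0 + sgn * 15.0 * h))
    elif paradigm == "paired_uv_green":
        add(DARK_CHECK_S, "dark")
        add(FLIGHT_S, "flight1", _paired(az0))
        if second_channel == "green":
            add(FLIGHT_S, "flight2", _green(az0))
        elif second_channel == "uv":
            add(FLIGHT_S, "flight2", _uv(az0 + 180.0))
        else:
            raise ValueError("second_channel must be 'green' or 'uv'")
        rotation_dir = "none"
    elif paradigm == "uv_only_moves":
        step = step_deg if step_deg is not None else float(rng.choice([90.0, 180.0]))
        add(DARK_CHECK_S, "dark")
        for k in range(3):
            add(FLIGHT_S, f"flight{k + 1}", _uv(az0 + sgn * step * k))
    elif paradigm == "paired_move_90":
        add(DARK_CHECK_S, "dark")
        add(FLIGHT_S, "flight1", _paired(az0))
        add(FLIGHT_S, "flight2", _paired(az0 + sgn * 90.0))
    else:
        raise ValueError(f"unknown paradigm {paradigm!r}")

    return StimulusSchedule(tuple(eps), paradigm=paradigm,
                            rotation_dir=rotation_dir)


PARADIGMS = (
    "long_constant", "long_moves", "varied_stimuli", "time_gap",
    "small_shift", "gradual_shift", "tcsc_single", "paired_uv_green",
    "uv_only_moves", "paired_move_90", "tcsc_paired",
)


# ---------------------------------------------------------------------------
# noise: AR(1) with exact von Mises stationary marginal
# ---------------------------------------------------------------------------

_VM_GRID = np.linspace(-math.pi, math.pi, 4097)
_VM_CDF_CACHE: Dict[float, np.ndarray] = {}


def _vm_cdf_table(kappa: float) -> np.ndarray:
    """Numeric CDF of a zero-mean von Mises on (-pi, pi] (cached)."""
    from scipy import stats as sstats

    tab = _VM_CDF_CACHE.get(kappa)
    if tab is None:
        tab = sstats.vonmises.cdf(_VM_GRID, kappa)
        tab[0], tab[-1] = 0.0, 1.0
        if len(_VM_CDF_CACHE) > 64:
            _VM_CDF_CACHE.clear()
        _VM_CDF_CACHE[kappa] = tab
    return tab


def _ar1_vonmises(n: int, kappa: float, phi: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Correlated deviations (radians) with exact VM(0, kappa) marginal.

    A latent standard-normal AR(1) series is pushed through the Gaussian
    copula: z -> Phi(z) -> VM quantile. Temporal persistence comes from
    the latent process; the marginal is exact at every frame.
    """
    from scipy import signal, special as sspecial

    innov = rng.standard_normal(n)
    if phi > 0:
        x = innov * math.sqrt(1.0 - phi * phi)
        x[0] = innov[0]  # stationary start
        z = signal.lfilter([1.0], [1.0, -phi], x)
    else:
        z = innov
    u = sspecial.ndtr(z)
    return np.interp(u, _vm_cdf_table(kappa), _VM_GRID)


# ---------------------------------------------------------------------------
# fly simulation
# ---------------------------------------------------------------------------

def _epoch_frames(epoch: StimulusEpoch, dt: float) -> np.ndarray:
    n = int(round(epoch.duration_s / dt))
    return epoch.t_start_s + dt * np.arange(n)


def simulate_fly(policy: BehaviorPolicy, noise: NoiseModel,
                 schedule: StimulusSchedule, seed: int,
                 fly_id: Optional[str] = None,
                 frame_rate_hz: float = DEFAULT_FRAME_RATE_HZ):
    """Simulate one fly's heading trace under a behavior policy.

    Returns ``(HeadingTrace, CohortTruth)``. Frames are emitted for
    every in-arena epoch (dark checks, flights, intertrials); rest
    epochs (label starting with 'rest') produce no frames, like a fly
    removed from the arena. Identical seed => identical trace.
    """
    rng = np.random.default_rng(seed)
    dt = 1.0 / frame_rate_hz
    fly_id = fly_id or f"fly{seed}"
    preferred = float(rng.uniform(-180.0, 180.0))

    sgn = _dir_sign(schedule.rotation_dir) if schedule.rotation_dir != "none" else 0

    times: List[np.ndarray] = []
    headings: List[np.ndarray] = []
    flying: List[np.ndarray] = []

    offset = preferred          # current offset from the reference direction
    last_azimuth: Optional[float] = None
    arena_dir = preferred       # for real_world_keeper / time_compensated
    last_heading = preferred

    for epoch in schedule.epochs:
        if epoch.label.lower().startswith("rest"):
            continue  # out of the arena: no frames recorded
        t = _epoch_frames(epoch, dt)
        n = t.size
        if n == 0:
            continue

        if epoch.is_dark:
            resting = "rest" in epoch.label.lower()
            if resting:
                # landed in the dark: body angle frozen where it stopped
                ang = np.full(n, last_heading)
                fl = np.zeros(n, dtype=bool)
            else:
                # rapid body rotations; direction fixed per dark epoch
                sign = 1.0 if rng.random() < 0.5 else -1.0
                ang = last_heading + sign * noise.dark_rotation_deg_s * dt * np.arange(1, n + 1)
                fl = np.ones(n, dtype=bool)
            times.append(t)
            headings.append(wrap_deg(ang))
            flying.append(fl)
            last_heading = float(ang[-1])
            continue

        # stimulus visible: update policy state
        dom = policy.dominant_channel(epoch.stimuli)
        az = dom.azimuth_deg
        if policy.kind == "reset_on_move" and last_azimuth is not None:
            disp = abs(wrap_deg(az - last_azimuth))
            if disp >= policy.reset_threshold_deg:
                offset = float(rng.uniform(-180.0, 180.0))
        if policy.kind == "uniform_random" and epoch.is_analysis:
            offset = float(rng.uniform(-180.0, 180.0))
        last_azimuth = az

        if policy.kind in ("maintain_relative", "reset_on_move",
                           "uniform_random"):
            ref = np.full(n, az)
            base = ref + offset
        elif policy.kind == "real_world_keeper":
            base = np.full(n, arena_dir)
        elif policy.kind == "time_compensated":
            drift = sgn * policy.compensation_rate_deg_per_h * (t / 3600.0)
            base = az + offset + drift
        else:  # pragma: no cover
            raise AssertionError(policy.kind)

        dev = np.degrees(_ar1_vonmises(n, noise.kappa,
                                       noise.ar_coefficient, rng))
        ang = wrap_deg(base + dev)

        # motor state: resting intertrial epochs are stopped throughout;
        # flights get Poisson stop episodes
        fl = np.ones(n, dtype=bool)
        if "rest" in epoch.label.lower():
            fl[:] = False
        elif noise.stop_rate_per_min > 0:
            n_stops = rng.poisson(noise.stop_rate_per_min * epoch.duration_s / 60.0)
            stop_len = max(1, int(round(noise.stop_duration_s * frame_rate_hz)))
            for start in sorted(rng.integers(0, n, size=n_stops)):
                fl[start:start + stop_len] = False

        times.append(t)
        headings.append(ang)
        flying.append(fl)
        last_heading = float(ang[-1])

    trace = HeadingTrace(
        fly_id=fly_id,
        time_s=np.concatenate(times),
        heading_deg=np.concatenate(headings),
        flying=np.concatenate(flying),
        frame_rate_hz=frame_rate_hz,
    )
    truth = CohortTruth(fly_id=fly_id, policy=policy.kind,
                        preferred_offset_deg=wrap_deg(preferred),
                        kappa=noise.kappa, seed=seed)
    return trace, truth


def simulate_cohort(n_flies: int, policy, noise: NoiseModel,
                    paradigm: str, master_seed: int,
                    out_dir: Optional[Path] = None,
                    schedule: Optional[StimulusSchedule] = None,
                    **schedule_kwargs):
    """Simulate a cohort sharing one schedule; optionally write to disk.

    ``policy`` may be a single :class:`BehaviorPolicy` or a list of
    ``(BehaviorPolicy, fraction)`` pairs. Child seeds derive
    deterministically from ``master_seed``. When ``out_dir`` is given,
    writes one trace CSV per fly, the schedule YAML and a truth table
    CSV (``fly_id,policy,preferred_offset_deg,kappa,seed``).

    Returns ``(traces, truths, schedule)``.
    """
    if n_flies < 1:
        raise ValueError("n_flies must be >= 1")
    rng = np.random.default_rng(master_seed)
    if schedule is None:
        schedule = build_schedule(
            paradigm, seed=int(rng.integers(2**31)), **schedule_kwargs)

    if isinstance(policy, BehaviorPolicy):
        policies = [policy] * n_flies
    else:
        kinds, fracs = zip(*policy)
        counts = np.floor(np.asarray(fracs) / sum(fracs) * n_flies).astype(int)
        while counts.sum() < n_flies:
            counts[int(np.argmax(fracs))] += 1
        policies = [k for k, c in zip(kinds, counts) for _ in range(c)]

    child_seeds = rng.integers(0, 2**31, size=n_flies)
    traces, truths = [], []
    for i in range(n_flies):
        tr, tu = simulate_fly(policies[i], noise, schedule,
                              seed=int(child_seeds[i]),
                              fly_id=f"fly{i:03d}")
        traces.append(tr)
        truths.append(tu)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_schedule(schedule, out / "schedule.yaml")
        for tr in traces:
            write_trace(tr, out / f"{tr.fly_id}.csv")
        pd.DataFrame([{
            "fly_id": tu.fly_id, "policy": tu.policy,
            "preferred_offset_deg": tu.preferred_offset_deg,
            "kappa": tu.kappa, "seed": tu.seed,
        } for tu in truths]).to_csv(out / "truth.csv", index=False)

    return traces, truths, schedule
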