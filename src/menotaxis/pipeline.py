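"""Per-experiment heading analyses.

Takes segmented heading traces and produces: per-segment circular
summaries with the standard exclusion rules (vector strength < 0.2, or
more than 2 stop episodes per flight period); per-fly heading
differences in the stimulus-relative and arena (real-world) frames; the
10,000-iteration reshuffling null for heading maintenance; the
short-term drift metric; cue-preference comparisons for paired
green/UV presentations; and the three-hypothesis evaluation used to
test for a time-compensated sun compass (maintain a stimulus-relative
heading, compensate at the stimulus rotation rate, or pick a new
heading).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .arena import FlightSegment, HeadingTrace, StimulusSchedule, segment_trace, to_reference_frame
from .circkit import (
    CircSummary,
    CircTestResult,
    CircularSample,
    bh_adjust,
    circ_mean_R,
    circ_mean_ci95,
    fisher_lee_regression,
    rayleigh_test,
    watson_u2,
    watson_williams,
    wrap_deg,
)

__all__ = [
    "SegmentSummary",
    "HeadingDifferenceRow",
    "ReshuffleResult",
    "HypothesisScores",
    "ExperimentTable",
    "summarize_segments",
    "heading_differences",
    "reshuffle_test",
    "drift_metric",
    "cue_preference_analysis",
    "tcsc_predictions",
    "evaluate_tcsc",
    "run_experiment",
]

R_CUTOFF = 0.2          # vector strength below which a mean heading is not meaningful
MAX_STOPS = 2           # flight periods with more stops are discarded
N_RESHUFFLE = 10_000
ALPHA = 0.05

HYPOTHESES = ("maintain_relative", "time_compensated", "new_heading")


# ---------------------------------------------------------------------------
# per-segment summaries and exclusions
# ---------------------------------------------------------------------------

@dataclass
class SegmentSummary:
    """Circular summary of one fly's flight period with exclusion status.

    The summary is computed in the arena frame; ``reference_azimuth_deg``
    (the designated stimulus azimuth, if any) converts the mean to the
    stimulus-relative frame by subtraction, which leaves R, variance and
    the CI unchanged.
    """

    fly_id: str
    label: str
    summary: CircSummary
    reference_azimuth_deg: Optional[float] = None
    stop_count: int = 0
    excluded: bool = False
    exclusion_reason: str = "none"

    def mean_in_frame(self, frame: str) -> Optional[float]:
        if self.summary.mean_deg is None:
            return None
        if frame == "arena":
            return self.summary.mean_deg
        if frame == "stimulus_relative":
            if self.reference_azimuth_deg is None:
                return None
            return wrap_deg(self.summary.mean_deg - self.reference_azimuth_deg)
        raise ValueError(f"unknown frame {frame!r}")


def summarize_segments(segments: Sequence[FlightSegment],
                       r_cutoff: float = R_CUTOFF,
                       max_stops: int = MAX_STOPS,
                       reference_channel: str = "green",
                       include_stopped: bool = False) -> List[SegmentSummary]:
    """Summarize flight segments and apply the exclusion rules.

    A segment is excluded when its stop-episode count exceeds
    ``max_stops`` (strictly more than 2 by default) or its vector
    strength is strictly below ``r_cutoff`` (0.2 by default; R exactly
    at the cutoff is retained). An empty angle sample is excluded as
    low_R with n = 0.
    """
    if not segments:
        raise ValueError("no segments to summarize")
    out: List[SegmentSummary] = []
    for seg in segments:
        ref = None
        for channel in (reference_channel, "uv", "green"):
            try:
                ref = seg.reference_azimuth(channel)
                break
            except KeyError:
                continue
        angles = seg.heading_deg if include_stopped else seg.angles_flying
        if angles.size == 0:
            out.append(SegmentSummary(
                fly_id=seg.fly_id, label=seg.label,
                summary=CircSummary(None, 0.0, 1.0, 0),
                reference_azimuth_deg=ref, stop_count=seg.stop_count,
                excluded=True, exclusion_reason="low_R"))
            continue
        sample = CircularSample(angles)
        summ = circ_mean_R(sample)
        ci = circ_mean_ci95(sample) if len(sample) >= 2 else None
        summ = CircSummary(summ.mean_deg, summ.R, summ.variance, summ.n,
                           ci95_halfwidth_deg=ci)
        excluded, reason = False, "none"
        if seg.stop_count > max_stops:
            excluded, reason = True, "too_many_stops"
        elif summ.R < r_cutoff:
            excluded, reason = True, "low_R"
        out.append(SegmentSummary(
            fly_id=seg.fly_id, label=seg.label, summary=summ,
            reference_azimuth_deg=ref, stop_count=seg.stop_count,
            excluded=excluded, exclusion_reason=reason))
    return out


# ---------------------------------------------------------------------------
# heading differences
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HeadingDifferenceRow:
    """Signed circular difference between two flight-period means."""

    fly_id: str
    pair: str
    frame: str
    diff_deg: float


def heading_differences(summaries: Sequence[SegmentSummary],
                        pairs: Sequence[Tuple[str, str]],
                        frame: str = "stimulus_relative",
                        dropped: Optional[list] = None) -> List[HeadingDifferenceRow]:
    """Per-fly signed heading differences ``wrap(mean_second - mean_first)``.

    Pairs whose first or second member is excluded (or has an undefined
    mean) are dropped; when a ``dropped`` list is supplied the
    ``(fly_id, pair, why)`` records are appended to it, never silently
    zeroed.
    """
    by_fly: Dict[str, Dict[str, SegmentSummary]] = {}
    for s in summaries:
        by_fly.setdefault(s.fly_id, {})[s.label] = s
    rows: List[HeadingDifferenceRow] = []
    for fly_id, labeled in by_fly.items():
        for first, second in pairs:
            pair_name = f"{second}-{first}"
            a, b = labeled.get(first), labeled.get(second)
            if a is None or b is None:
                continue
            why = None
            if a.excluded or b.excluded:
                why = "excluded member"
            else:
                m1, m2 = a.mean_in_frame(frame), b.mean_in_frame(frame)
                if m1 is None or m2 is None:
                    why = "undefined mean"
            if why is not None:
                if dropped is not None:
                    dropped.append((fly_id, pair_name, why))
                continue
            rows.append(HeadingDifferenceRow(
                fly_id=fly_id, pair=pair_name, frame=frame,
                diff_deg=wrap_deg(m2 - m1)))
    return rows


# ---------------------------------------------------------------------------
# the reshuffling null
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReshuffleResult:
    """Permutation null for heading maintenance.

    The observed statistic is the mean over flies of the absolute
    circular difference between second- and first-period means; the null
    re-pairs the second-period means at random (without replacement).
    ``p_value`` is the raw proportion of shuffled statistics strictly
    smaller than the observed one — it may be exactly 0.
    """

    observed_mean_abs_diff_deg: float
    p_value: float
    n_iter: int
    seed: Optional[int]
    null_quantiles: Dict[str, float]


def _mean_abs_circ_diff(first: np.ndarray, second: np.ndarray) -> float:
    return float(np.mean(np.abs(wrap_deg(second - first))))


def reshuffle_test(first_means, second_means, n_iter: int = N_RESHUFFLE,
                   seed: Optional[int] = None) -> ReshuffleResult:
    """Reshuffling test for heading maintenance between two flight periods."""
    a = np.asarray(first_means, dtype=float)
    b = np.asarray(second_means, dtype=float)
    if a.shape != b.shape:
        raise ValueError("first and second mean lists must have equal length")
    if a.size < 3:
        raise ValueError("need at least 3 flies")
    observed = _mean_abs_circ_diff(a, b)
    rng = np.random.default_rng(seed)
    # all n_iter permutations at once: rows of shuffled second means
    idx = np.argsort(rng.random((n_iter, b.size)), axis=1)
    shuffled = b[idx]
    null = np.abs(wrap_deg(shuffled - a)).mean(axis=1)
    p = float(np.count_nonzero(null < observed) / n_iter)
    qs = np.quantile(null, [0.05, 0.25, 0.5, 0.75, 0.95])
    return ReshuffleResult(
        observed_mean_abs_diff_deg=observed, p_value=p, n_iter=n_iter,
        seed=seed,
        null_quantiles={f"q{int(q * 100):02d}": float(v)
                        for q, v in zip([0.05, 0.25, 0.5, 0.75, 0.95], qs)})


# ---------------------------------------------------------------------------
# drift
# ---------------------------------------------------------------------------

def drift_metric(trace: HeadingTrace, schedule: StimulusSchedule,
                 frame: str = "arena",
                 r_cutoff: float = R_CUTOFF,
                 max_stops: int = MAX_STOPS):
    """Short-term drift: mean heading of minutes 10-15 minus minutes 0-5
    of stimulus time, wrapped. Returns ``(drift_deg, reason)``; the
    angle is None (with the reason) when either 5 min window is
    excluded. Arena frame by default (appropriate for a static
    stimulus).
    """
    segments = segment_trace(trace, schedule, bin_s=300.0)
    summaries = summarize_segments(segments, r_cutoff=r_cutoff,
                                   max_stops=max_stops)
    t0 = schedule.analysis_epochs()[0].t_start_s
    window = {}
    for seg, summ in zip(segments, summaries):
        rel = seg.time_s[0] - t0
        if abs(rel) < 1.0:
            window["first"] = summ
        elif abs(rel - 600.0) < 1.0:
            window["late"] = summ
    if "first" not in window or "late" not in window:
        return None, "trial does not cover 15 min of stimulus time"
    for key in ("first", "late"):
        if window[key].excluded:
            return None, f"{key} window excluded ({window[key].exclusion_reason})"
    m1 = window["first"].mean_in_frame(frame)
    m2 = window["late"].mean_in_frame(frame)
    if m1 is None or m2 is None:
        return None, "undefined mean"
    return wrap_deg(m2 - m1), "ok"


# ---------------------------------------------------------------------------
# cue preference (paired green/UV presentations)
# ---------------------------------------------------------------------------

def cue_preference_analysis(paired_summaries: Sequence[SegmentSummary],
                            single_summaries: Sequence[SegmentSummary],
                            surviving_channel_azimuth: Dict[str, float],
                            surviving_channel: str,
                            n_iter: int = N_RESHUFFLE,
                            seed: Optional[int] = None) -> dict:
    """Heading maintenance across a paired-cue to single-cue transition.

    Heading differences are computed relative to the surviving channel's
    azimuth (constant across both epochs in the cue-preference design,
    so the stimulus-relative and arena differences agree). Also reports
    the group's vector-strength distribution as mean R and
    CV = sd(R) / mean(R).

    Returns a dict with per-fly ``diffs_deg``, a :class:`ReshuffleResult`,
    and ``vector_strength`` statistics for both epochs.
    """
    az = surviving_channel_azimuth[surviving_channel]
    by_fly_first = {s.fly_id: s for s in paired_summaries if not s.excluded}
    by_fly_second = {s.fly_id: s for s in single_summaries if not s.excluded}
    fly_ids = sorted(set(by_fly_first) & set(by_fly_second))
    first, second = [], []
    for f in fly_ids:
        m1, m2 = by_fly_first[f].summary.mean_deg, by_fly_second[f].summary.mean_deg
        if m1 is None or m2 is None:
            continue
        first.append(wrap_deg(m1 - az))
        second.append(wrap_deg(m2 - az))
    first, second = np.asarray(first), np.asarray(second)
    diffs = wrap_deg(second - first) if first.size else np.empty(0)
    resh = (reshuffle_test(first, second, n_iter=n_iter, seed=seed)
            if first.size >= 3 else None)

    def r_stats(summaries):
        rs = np.asarray([s.summary.R for s in summaries if not s.excluded])
        if rs.size == 0:
            return {"mean_R": math.nan, "cv": math.nan, "n": 0}
        mean = float(rs.mean())
        cv = float(rs.std(ddof=1) / mean) if rs.size > 1 and mean > 0 else 0.0
        return {"mean_R": mean, "cv": cv, "n": int(rs.size)}

    return {
        "channel": surviving_channel,
        "fly_ids": fly_ids,
        "diffs_deg": diffs,
        "reshuffle": resh,
        "vector_strength": {"paired": r_stats(paired_summaries),
                            "single": r_stats(single_summaries)},
    }


# ---------------------------------------------------------------------------
# time-compensated sun compass hypotheses
# ---------------------------------------------------------------------------

def tcsc_predictions(rotation_dir: str, total_rotation_deg: float) -> dict:
    """Predicted stimulus-relative heading change under each hypothesis.

    * ``maintain_relative`` — the fly tracks the stimulus: change 0 deg.
    * ``time_compensated`` — the fly compensates at the stimulus rate:
      change ``-total_rotation_deg`` for clockwise stimulus movement,
      ``+total_rotation_deg`` for counterclockwise.
    * ``new_heading`` — no point target; changes uniformly distributed.
    """
    if total_rotation_deg <= 0:
        raise ValueError("total_rotation_deg must be positive")
    if rotation_dir not in ("cw", "ccw"):
        raise ValueError("rotation_dir must be 'cw' or 'ccw'")
    sign = -1.0 if rotation_dir == "cw" else 1.0
    return {
        "maintain_relative": 0.0,
        "time_compensated": sign * total_rotation_deg,
        "new_heading": None,
    }


@dataclass(frozen=True)
class HypothesisScores:
    """Evidence for each heading-change hypothesis.

    ``scores`` holds, for each point hypothesis, the mean cosine of the
    deviations of the observed changes from the hypothesized target (a
    V-style concentration score in [-1, 1]); ``distance_deg`` the
    circular distance from the sample mean change to the target;
    ``rayleigh_p`` the uniformity test backing the new-heading
    hypothesis; ``label`` the best-supported hypothesis or 'abstain'.
    """

    predictions: Dict[str, Optional[float]]
    scores: Dict[str, float]
    distance_deg: Dict[str, Optional[float]]
    rayleigh_p: float
    label: str
    n: int


def evaluate_tcsc(diffs, rotation_dir: str, total_rotation_deg: float,
                  alpha: float = ALPHA, margin: float = 0.1,
                  min_n: int = 8) -> HypothesisScores:
    """Score the three heading-change hypotheses on observed
    stimulus-relative changes.

    Labeling rule: a point hypothesis (maintain or time-compensated)
    wins when its concentration score exceeds the other's by at least
    ``margin`` AND the Rayleigh test rejects uniformity at ``alpha``;
    if the Rayleigh test does not reject, the label is ``new_heading``;
    a rejection without a clear score winner abstains. Fewer than
    ``min_n`` observations refuse a label (scores still reported).
    """
    d = np.asarray(diffs, dtype=float)
    preds = tcsc_predictions(rotation_dir, total_rotation_deg)
    sample = CircularSample(d)
    summ = circ_mean_R(sample)
    rp = rayleigh_test(sample).p_value if len(sample) >= 4 else math.nan
    scores, dist = {}, {}
    for hyp, target in preds.items():
        if target is None:
            continue
        scores[hyp] = float(np.mean(np.cos(np.deg2rad(d - target))))
        dist[hyp] = (abs(wrap_deg(summ.mean_deg - target))
                     if summ.mean_deg is not None else None)
    dist["new_heading"] = None

    if d.size < min_n or math.isnan(rp):
        label = "too_few"
    elif rp >= alpha:
        label = "new_heading"
    else:
        s_m, s_t = scores["maintain_relative"], scores["time_compensated"]
        if s_m >= s_t + margin:
            label = "maintain_relative"
        elif s_t >= s_m + margin:
            label = "time_compensated"
        else:
            label = "abstain"
    return HypothesisScores(predictions=preds, scores=scores,
                            distance_deg=dist, rayleigh_p=rp, label=label,
                            n=int(d.size))


# ---------------------------------------------------------------------------
# experiment orchestration
# ---------------------------------------------------------------------------

@dataclass
class ExperimentTable:
    """Tidy per-fly results plus population statistics for one experiment."""

    paradigm: str
    summaries: pd.DataFrame
    differences: pd.DataFrame
    reshuffle: Dict[str, ReshuffleResult]
    tests: Dict[str, object]
    population: Dict[str, dict]
    hypothesis: Optional[HypothesisScores]
    dropped: List[tuple]
    seed: Optional[int]

    def to_json_dict(self) -> dict:
        def conv(o):
            if isinstance(o, ReshuffleResult):
                return {
                    "observed_mean_abs_diff_deg": o.observed_mean_abs_diff_deg,
                    "p_value": o.p_value, "n_iter": o.n_iter,
                    "seed": o.seed, "null_quantiles": o.null_quantiles,
                }
            if isinstance(o, CircTestResult):
                return {"test": o.test_name, "statistic": o.statistic,
                        "p_value": o.p_value, "df": list(o.df),
                        "method": o.method}
            if isinstance(o, HypothesisScores):
                return {"predictions": o.predictions, "scores": o.scores,
                        "distance_deg": o.distance_deg,
                        "rayleigh_p": o.rayleigh_p, "label": o.label,
                        "n": o.n}
            if isinstance(o, dict):
                return {k: conv(v) for k, v in o.items()}
            if isinstance(o, (list, tuple)):
                return [conv(v) for v in o]
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            return o

        return {
            "paradigm": self.paradigm,
            "seed": self.seed,
            "reshuffle": conv(self.reshuffle),
            "tests": conv(self.tests),
            "population": conv(self.population),
            "hypothesis": conv(self.hypothesis),
            "n_dropped_pairs": len(self.dropped),
        }


def _population_stats(values: np.ndarray) -> dict:
    """Population mean / variance / CI-or-undefined of a set of angles."""
    if values.size == 0:
        return {"n": 0, "mean_deg": None, "variance": None,
                "ci95_halfwidth_deg": None}
    sample = CircularSample(values)
    summ = circ_mean_R(sample)
    ci = circ_mean_ci95(sample) if values.size >= 2 else None
    return {"n": int(values.size), "mean_deg": summ.mean_deg,
            "variance": summ.variance, "ci95_halfwidth_deg": ci}


def _sequential_lrt_orders(responses, X: np.ndarray,
                           names: Sequence[str]) -> dict:
    """Sequential (type-I) likelihood-ratio p-values for every ordering
    of the covariates — the all-orders robustness sweep. Returns
    per-factor min/max p across orders plus the simultaneous
    (order-free, drop-one) p-values."""
    from .circkit import _fit_vm_link  # shared fitting core
    from scipy import stats as sstats

    theta = np.deg2rad(np.asarray(responses, dtype=float))
    k = X.shape[1]
    ll_cache: Dict[frozenset, float] = {}

    def ll(cols: frozenset) -> float:
        if cols not in ll_cache:
            Xs = X[:, sorted(cols)] if cols else None
            _, l, _, _ = _fit_vm_link(theta, Xs)
            ll_cache[cols] = l
        return ll_cache[cols]

    sweep: Dict[str, List[float]] = {nm: [] for nm in names}
    for order in itertools.permutations(range(k)):
        included: frozenset = frozenset()
        for j in order:
            lr = max(0.0, 2.0 * (ll(included | {j}) - ll(included)))
            sweep[names[j]].append(float(sstats.chi2.sf(lr, 1)))
            included = included | {j}
    return {nm: {"min_p": min(ps), "max_p": max(ps)}
            for nm, ps in sweep.items()}


def run_experiment(traces: Sequence[HeadingTrace],
                   schedule: StimulusSchedule,
                   design: Optional[dict] = None,
                   seed: Optional[int] = None) -> ExperimentTable:
    """Run the full per-experiment analysis on a cohort of traces.

    ``design`` may override: ``r_cutoff``, ``max_stops``, ``n_reshuffle``,
    ``alpha``, ``frame`` ('stimulus_relative' or 'arena', for the
    reshuffle statistic), ``bin_s`` (sub-bin width for single long
    flights), ``reference_channel`` and ``glm_covariates`` (a DataFrame
    of per-fly factors keyed by fly_id for the circular GLM).
    Deterministic for a fixed seed.
    """
    design = dict(design or {})
    r_cutoff = design.get("r_cutoff", R_CUTOFF)
    max_stops = design.get("max_stops", MAX_STOPS)
    n_iter = design.get("n_reshuffle", N_RESHUFFLE)
    alpha = design.get("alpha", ALPHA)
    frame = design.get("frame", "stimulus_relative")
    ref_channel = design.get("reference_channel", "green")
    if design.get("paradigm") and design["paradigm"] != schedule.paradigm:
        raise ValueError(
            f"design paradigm {design['paradigm']!r} does not match "
            f"schedule paradigm {schedule.paradigm!r}")
    rng = np.random.default_rng(seed)

    # segment every trace; a single long flight epoch is binned at 5 min
    n_analysis = len(schedule.analysis_epochs())
    bin_s = design.get("bin_s", 300.0 if n_analysis == 1 else None)
    summaries: List[SegmentSummary] = []
    errors: List[tuple] = []
    for tr in traces:
        try:
            segs = segment_trace(tr, schedule, bin_s=bin_s)
            summaries.extend(summarize_segments(
                segs, r_cutoff=r_cutoff, max_stops=max_stops,
                reference_channel=ref_channel))
        except ValueError as exc:  # carry fly id and stage
            errors.append((tr.fly_id, "segmentation", str(exc)))
    if not summaries:
        raise ValueError(f"no usable traces; first error: {errors[:1]}")

    labels = sorted({s.label for s in summaries},
                    key=lambda L: [s.label for s in summaries].index(L))
    pairs = list(zip(labels[:-1], labels[1:]))
    if len(labels) > 2:
        pairs.append((labels[0], labels[-1]))

    dropped: List[tuple] = []
    diff_rows: List[HeadingDifferenceRow] = []
    for fr in ("stimulus_relative", "arena"):
        diff_rows.extend(heading_differences(summaries, pairs, frame=fr,
                                             dropped=dropped))

    sum_df = pd.DataFrame([{
        "fly_id": s.fly_id, "label": s.label,
        "mean_deg": s.summary.mean_deg, "R": s.summary.R,
        "variance": s.summary.variance,
        "ci95_halfwidth_deg": s.summary.ci95_halfwidth_deg,
        "n_frames": s.summary.n, "stop_count": s.stop_count,
        "reference_azimuth_deg": s.reference_azimuth_deg,
        "excluded": s.excluded, "exclusion_reason": s.exclusion_reason,
    } for s in summaries])
    diff_df = pd.DataFrame([{
        "fly_id": r.fly_id, "pair": r.pair, "frame": r.frame,
        "diff_deg": r.diff_deg,
    } for r in diff_rows])

    # reshuffle test per consecutive pair, in the requested frame
    reshuffles: Dict[str, ReshuffleResult] = {}
    by_fly: Dict[str, Dict[str, SegmentSummary]] = {}
    for s in summaries:
        by_fly.setdefault(s.fly_id, {})[s.label] = s
    for first, second in pairs:
        a, b = [], []
        for fly, labeled in by_fly.items():
            s1, s2 = labeled.get(first), labeled.get(second)
            if (s1 is None or s2 is None or s1.excluded or s2.excluded):
                continue
            m1, m2 = s1.mean_in_frame(frame), s2.mean_in_frame(frame)
            if m1 is None or m2 is None:
                continue
            a.append(m1)
            b.append(m2)
        if len(a) >= 3:
            reshuffles[f"{second}-{first}"] = reshuffle_test(
                a, b, n_iter=n_iter, seed=int(rng.integers(2**31)))

    # population statistics and tests on the heading differences
    population: Dict[str, dict] = {}
    tests: Dict[str, object] = {}
    if not diff_df.empty:
        for (pair, fr), grp in diff_df.groupby(["pair", "frame"], sort=True):
            vals = grp["diff_deg"].to_numpy()
            population[f"{pair}[{fr}]"] = _population_stats(vals)
            if vals.size >= 4:
                tests[f"rayleigh:{pair}[{fr}]"] = rayleigh_test(vals)
        # Watson-Williams across consecutive difference families + BH
        fam = [(p, g["diff_deg"].to_numpy())
               for (p, fr), g in diff_df.groupby(["pair", "frame"], sort=True)
               if fr == frame and g.shape[0] >= 5]
        ww_keys, ww_ps = [], []
        for (p1, v1), (p2, v2) in zip(fam[:-1], fam[1:]):
            try:
                res = watson_williams(v1, v2)
            except ValueError:
                continue
            tests[f"watson_williams:{p2} vs {p1}"] = res
            ww_keys.append(f"watson_williams:{p2} vs {p1}")
            ww_ps.append(res.p_value)
        if ww_ps:
            for key, adj in zip(ww_keys, bh_adjust(ww_ps)):
                tests[key + ":bh_adjusted_p"] = float(adj)
        # Watson U2: stimulus-relative vs arena differences per pair
        for pair in diff_df["pair"].unique():
            rel = diff_df.query("pair == @pair and frame == 'stimulus_relative'")
            ab = diff_df.query("pair == @pair and frame == 'arena'")
            if rel.shape[0] >= 8 and ab.shape[0] >= 8:
                tests[f"watson_u2:{pair} rel-vs-arena"] = watson_u2(
                    rel["diff_deg"].to_numpy(), ab["diff_deg"].to_numpy(),
                    n_perm=min(n_iter, 2000),
                    seed=int(rng.integers(2**31)))

    # circular GLM with the all-orders robustness sweep. The response is
    # the signed heading difference by default; 'absolute' regresses the
    # magnitude |diff| instead, which is the sensitive coding when a
    # factor disrupts heading maintenance without shifting its direction
    # (e.g. flies redrawing arbitrary new headings after an LED move).
    glm_cov = design.get("glm_covariates")
    glm_response = design.get("glm_response", "signed")
    if glm_cov is not None and not diff_df.empty:
        resp_rows = diff_df[(diff_df["frame"] == frame)
                            & (diff_df["pair"] == diff_df["pair"].iloc[0])]
        merged = resp_rows.merge(glm_cov, on="fly_id", how="inner")
        names = [c for c in glm_cov.columns if c != "fly_id"]
        if merged.shape[0] > len(names) + 2:
            X = merged[names].to_numpy(float)
            resp = merged["diff_deg"].to_numpy()
            if glm_response == "absolute":
                resp = np.abs(resp)
            elif glm_response != "signed":
                raise ValueError("glm_response must be 'signed' or 'absolute'")
            fit = fisher_lee_regression(resp, X, covariate_names=names)
            tests["glm"] = {
                "intercept_deg": fit.intercept_deg,
                "kappa_hat": fit.kappa_hat,
                "p_values": dict(zip(names, fit.p_values.tolist())),
                "converged": fit.converged,
                "order_sweep": _sequential_lrt_orders(
                    merged["diff_deg"].to_numpy(), X, names),
            }

    # time-compensation scoring for tcsc paradigms
    hypothesis = None
    if schedule.paradigm.startswith("tcsc") and schedule.rotation_dir in ("cw", "ccw"):
        total = 0.0
        eps = schedule.analysis_epochs()
        for e1, e2 in zip(eps[:-1], eps[1:]):
            az1 = e1.stimuli[0].azimuth_deg
            az2 = e2.stimuli[0].azimuth_deg
            total += abs(wrap_deg(az2 - az1))
        key = f"{labels[-1]}-{labels[0]}"
        vals = diff_df.query("pair == @key and frame == 'stimulus_relative'")
        if total > 0 and not vals.empty:
            hypothesis = evaluate_tcsc(vals["diff_deg"].to_numpy(),
                                       schedule.rotation_dir, total,
                                       alpha=alpha)

    return ExperimentTable(
        paradigm=schedule.paradigm, summaries=sum_df, differences=diff_df,
        reshuffle=reshuffles, tests=tests, population=population,
        hypothesis=hypothesis, dropped=dropped + errors, seed=seed)
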