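"""Residence-time survival analysis across continuous and time-lapse imaging.

Continuous imaging resolves short nonspecific binding events but
photobleaching hides long ones; time-lapse imaging (short exposures
separated by dark gaps) extends the observation window.  The full survival
probability (SP, the complementary cumulative distribution of bound-event
durations) is assembled by renormalizing each time-lapse SP to the
continuous-imaging SP at an anchor time (1 s), fitting the power-law
regime, and numerically integrating SP to the mean nonspecific bound time
tau_1D.  The mobile fraction then partitions the cycle into tau_1D and
tau_3D, whose sum sets the rate at which nonspecific sites are visited.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .mobility import BindingEvent
from .simulate import Trajectory

__all__ = [
    "SurvivalCurve",
    "NonspecificKinetics",
    "ResidenceModel",
    "ResidenceResults",
    "detect_immobile_timelapse",
    "survival_probability",
    "merge_survival_curves",
    "fit_powerlaw",
    "mean_binding_time",
    "partition_times",
]


@dataclass(frozen=True)
class SurvivalCurve:
    """SP(t): probability that a bound event lasts longer than t."""

    times_s: np.ndarray
    sp: np.ndarray
    protocol: str = ""
    scale: float = 1.0

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        s = np.asarray(self.sp, dtype=float)
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "sp", s)
        if len(t) != len(s):
            raise ValueError("times_s and sp must have equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times_s must be strictly increasing")

    def at(self, t: float) -> float:
        """Empirical (step-function) SP: the value at the largest grid time
        not exceeding t; 1 below the first grid point."""
        times, sp = self.times_s, self.sp
        if t < times[0]:
            return 1.0
        idx = int(np.searchsorted(times, t, side="right")) - 1
        return float(sp[idx])

    def interp_at(self, t: float) -> float:
        """SP interpolated log-linearly in (log t, log SP) between grid
        points (used when evaluating a curve at an anchor between points);
        falls back to linear interpolation where a zero or t=0 forbids
        logs."""
        times, sp = self.times_s, self.sp
        if t < times[0]:
            return 1.0
        if t >= times[-1]:
            return float(sp[-1]) if t == times[-1] else 0.0
        i = int(np.searchsorted(times, t, side="right")) - 1
        t0, t1, s0, s1 = times[i], times[i + 1], sp[i], sp[i + 1]
        if t == t0:
            return float(s0)
        if s0 > 0 and s1 > 0 and t0 > 0:
            return float(
                math.exp(
                    np.interp(math.log(t), [math.log(t0), math.log(t1)], [math.log(s0), math.log(s1)])
                )
            )
        return float(np.interp(t, [t0, t1], [s0, s1]))


def _durations(events) -> tuple[np.ndarray, np.ndarray]:
    """(durations, censored flags) from events or a plain duration array."""
    events = list(events) if not isinstance(events, np.ndarray) else events
    if len(events) and isinstance(events[0], BindingEvent):
        return (
            np.array([e.duration_s for e in events]),
            np.array([e.censored for e in events], dtype=bool),
        )
    arr = np.asarray(events, dtype=float)
    return arr, np.zeros(len(arr), dtype=bool)


def detect_immobile_timelapse(
    traj: Trajectory, pixel_um: float = 0.160, min_frames: int = 2
) -> list[BindingEvent]:
    """Bound events in a time-lapse trajectory by the 1-pixel rule.

    A molecule is considered bound while it moves by at most ``pixel_um``
    between consecutive frames; maximal such runs covering at least
    ``min_frames`` frames become events of duration
    (n_frames - 1) * interval.  Runs touching either track end are
    censored: the observed duration is a lower bound there (event cut by
    bleaching/track loss at the end; residual of an in-progress,
    size-biased event at the start).
    """
    n = len(traj)
    if n < 2:
        return []
    dt = traj.interval_s
    label = traj.protocol.label if traj.protocol is not None else ""
    step_ok = np.hypot(np.diff(traj.x_um), np.diff(traj.y_um)) <= pixel_um
    padded = np.concatenate([[False], step_ok, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    events = []
    for s, e in zip(edges[::2], edges[1::2]):  # steps [s, e) ok -> frames s..e
        n_frames = e - s + 1
        if n_frames < min_frames:
            continue
        events.append(
            BindingEvent(
                track_id=traj.track_id,
                start_s=float(traj.t_s[s]),
                duration_s=(n_frames - 1) * dt,
                censored=bool(e == n - 1 or s == 0),
                protocol=label,
            )
        )
    return events


def survival_probability(events, censor_policy: str = "drop", protocol: str = "") -> SurvivalCurve:
    """Empirical SP on the sorted unique durations, with SP(0) = 1.

    ``censor_policy='drop'`` excludes censored events; ``'include'`` keeps
    them as if complete (biased low for long events); ``'km'`` retains
    censored events through the Kaplan-Meier product-limit estimator,
    which is unbiased when censoring (photobleaching, track loss) is
    independent of dissociation.
    """
    durations, censored = _durations(events)
    if not np.any(~censored):
        raise ValueError("no uncensored events; cannot build a survival curve")
    if censor_policy == "km":
        order = np.argsort(durations, kind="stable")
        d, c = durations[order], censored[order]
        uniq = np.unique(d[~c])
        sp = np.empty(len(uniq))
        s = 1.0
        for i, u in enumerate(uniq):
            n_at_risk = (d >= u).sum()
            n_events = ((d == u) & ~c).sum()
            s *= 1.0 - n_events / n_at_risk
            sp[i] = s
    elif censor_policy in ("drop", "include"):
        if censor_policy == "drop":
            durations = durations[~censored]
        uniq = np.unique(durations)
        n = len(durations)
        sp = np.array([(durations > u).sum() / n for u in uniq])
    else:
        raise ValueError(f"unknown censor_policy {censor_policy!r}")
    return SurvivalCurve(
        times_s=np.concatenate([[0.0], uniq]),
        sp=np.concatenate([[1.0], sp]),
        protocol=protocol,
    )


def renormalize_to(curve: SurvivalCurve, reference: SurvivalCurve, anchor_s: float) -> SurvivalCurve:
    """Scale ``curve`` so it agrees with ``reference`` at the anchor time."""
    sp_ref = reference.interp_at(anchor_s)
    sp_cur = curve.interp_at(anchor_s)
    if sp_cur <= 0:
        raise ValueError(f"SP of protocol {curve.protocol!r} is 0 at anchor {anchor_s} s; cannot renormalize")
    scale = sp_ref / sp_cur
    return SurvivalCurve(curve.times_s, curve.sp * scale, protocol=curve.protocol, scale=scale)


def merge_survival_curves(
    continuous: SurvivalCurve,
    timelapse: Sequence[SurvivalCurve],
    anchor_s: float = 1.0,
) -> SurvivalCurve:
    """Full SP: continuous imaging below the anchor, renormalized
    time-lapse curves above it.

    Each time-lapse SP is multiplied by SP_cont(anchor)/SP_TL(anchor)
    (log-linear interpolation at the anchor); points are concatenated in
    time order and coincident times averaged in log SP.
    """
    pieces: list[tuple[np.ndarray, np.ndarray]] = []
    mask = continuous.times_s <= anchor_s
    pieces.append((continuous.times_s[mask], continuous.sp[mask]))
    for tl in timelapse:
        scaled = renormalize_to(tl, continuous, anchor_s)
        m = scaled.times_s > anchor_s
        pieces.append((scaled.times_s[m], scaled.sp[m]))
    t_all = np.concatenate([p[0] for p in pieces])
    s_all = np.concatenate([p[1] for p in pieces])
    order = np.argsort(t_all)
    t_all, s_all = t_all[order], s_all[order]
    # average duplicate times in log SP (geometric mean); zeros averaged arithmetically
    uniq, inv = np.unique(t_all, return_inverse=True)
    sp_out = np.empty(len(uniq))
    for i in range(len(uniq)):
        vals = s_all[inv == i]
        sp_out[i] = np.exp(np.mean(np.log(vals))) if np.all(vals > 0) else vals.mean()
    return SurvivalCurve(uniq, sp_out, protocol="merged")


def fit_powerlaw(
    sp: SurvivalCurve,
    range_s: tuple[float, float] = (0.1, 100.0),
    log_resample: Optional[int] = None,
) -> float:
    """Least-squares power-law exponent of SP over ``range_s``.

    Slope of log10 SP vs log10 t restricted to the range (points with
    SP > 0 only); requires at least 5 usable points.  With
    ``log_resample`` the curve is first interpolated onto that many
    points per decade, uniform in log t, so that each decade carries the
    same weight regardless of how densely events populate it (empirical
    grids are linear in duration and would otherwise dominate the fit
    with their long-time points).
    """
    mask = (sp.times_s >= range_s[0]) & (sp.times_s <= range_s[1]) & (sp.sp > 0) & (sp.times_s > 0)
    if mask.sum() < 5:
        raise ValueError(f"need >= 5 points with SP > 0 in range {range_s}, got {int(mask.sum())}")
    if log_resample is None:
        tt, ss = sp.times_s[mask], sp.sp[mask]
    else:
        lo = max(range_s[0], sp.times_s[mask][0])
        hi = min(range_s[1], sp.times_s[mask][-1])
        n = max(5, int(round(log_resample * math.log10(hi / lo))))
        tt = np.logspace(math.log10(lo), math.log10(hi), n)
        ss = np.array([sp.at(t) for t in tt])
        keep = ss > 0
        tt, ss = tt[keep], ss[keep]
    return float(np.polyfit(np.log10(tt), np.log10(ss), 1)[0])


def _isotonic_decreasing(y: np.ndarray) -> np.ndarray:
    from sklearn.isotonic import IsotonicRegression

    return IsotonicRegression(increasing=False).fit_transform(np.arange(len(y)), y)


def mean_binding_time(sp: SurvivalCurve, tail_policy="power_law_to:100") -> float:
    """Mean bound time tau_1D = integral of SP over time.

    Trapezoidal integration over the observed grid (SP(0)=1 prepended if
    missing).  ``tail_policy`` controls extrapolation beyond the last
    point: ``'truncate'`` stops there; ``'power_law_to:T'`` (or the tuple
    ``('power_law_to', T)``) continues as SP_last * (t/t_last)^gamma up to
    T and zero beyond, with gamma fitted from the curve itself.
    Non-monotone curves (merge noise) are projected onto the decreasing
    cone first, with a warning.
    """
    times, vals = sp.times_s, sp.sp
    if times[0] > 0:
        times = np.concatenate([[0.0], times])
        vals = np.concatenate([[1.0], vals])
    if np.any(np.diff(vals) > 0):
        warnings.warn("survival curve is not monotone; applying isotonic-decreasing projection")
        vals = _isotonic_decreasing(vals)
    total = float(np.trapezoid(vals, times))

    if isinstance(tail_policy, str):
        if tail_policy == "truncate":
            return total
        if tail_policy.startswith("power_law_to:"):
            t_stop = float(tail_policy.split(":", 1)[1])
        else:
            raise ValueError(f"unknown tail_policy {tail_policy!r}")
    else:
        kind, t_stop = tail_policy
        if kind != "power_law_to":
            raise ValueError(f"unknown tail_policy {tail_policy!r}")

    t_last, sp_last = float(times[-1]), float(vals[-1])
    if t_stop <= t_last or sp_last <= 0:
        return total
    gamma = fit_powerlaw(SurvivalCurve(times[times > 0], vals[times > 0]), range_s=(0.1, t_last))
    if gamma == -1.0:
        tail = sp_last * t_last * math.log(t_stop / t_last)
    else:
        tail = sp_last * t_last / (gamma + 1.0) * ((t_stop / t_last) ** (gamma + 1.0) - 1.0)
    return total + max(tail, 0.0)


def partition_times(tau_1D: float, f_mobile: float) -> tuple[float, float]:
    """Split the binding/diffusion cycle given the mobile time fraction.

    The long-run mobile fraction equals tau_3D/(tau_1D + tau_3D), so
    tau_3D = tau_1D * f_mobile/(1 - f_mobile); the visit rate of
    nonspecific sites is 1/(tau_1D + tau_3D).
    """
    if not 0 < f_mobile < 1:
        raise ValueError("f_mobile must be strictly between 0 and 1")
    if not tau_1D > 0:
        raise ValueError("tau_1D must be > 0")
    tau_3D = tau_1D * f_mobile / (1.0 - f_mobile)
    return tau_3D, 1.0 / (tau_1D + tau_3D)


@dataclass(frozen=True)
class NonspecificKinetics:
    """Summary of nonspecific interaction kinetics."""

    tau_RS: float
    gamma: float
    tau_1D: float
    tau_3D: float
    visit_rate: float
    tau_SPE: float = 60.0

    def __post_init__(self) -> None:
        if min(self.tau_RS, self.tau_1D, self.tau_3D, self.tau_SPE) <= 0:
            raise ValueError("all times must be > 0")
        if abs(self.visit_rate * (self.tau_1D + self.tau_3D) - 1.0) > 1e-12:
            raise ValueError("visit_rate must equal 1/(tau_1D + tau_3D)")


class ResidenceModel:
    """Full residence-time analysis from continuous plus time-lapse events.

    Parameters
    ----------
    continuous_events : events (or durations) from continuous imaging.
    timelapse_events : mapping from protocol label to events from that
        time-lapse protocol.
    f_mobile : long-run mobile time fraction used to partition the cycle.
    tau_RS : residence time on random sequences (s); when None it is not
        reported in the summary.
    bleach_rates : optional mapping from protocol label ("continuous" plus
        the time-lapse labels) to the effective bleach rate experienced by
        an event of that protocol, in 1/s of event duration (per-frame
        bleach probability divided by the frame interval).  Dissociation
        and bleaching compete, so the observed SP of each protocol is
        depressed by exp(-rate * t); the correction multiplies it back
        before merging.
    """

    def __init__(
        self,
        continuous_events,
        timelapse_events: Mapping[str, Sequence],
        f_mobile: float = 0.75,
        tau_RS: Optional[float] = None,
        bleach_rates: Optional[Mapping[str, float]] = None,
        censor_policy: str = "km",
    ):
        self.sp_continuous = survival_probability(
            continuous_events, censor_policy=censor_policy, protocol="continuous"
        )
        self.sp_timelapse = [
            survival_probability(ev, censor_policy=censor_policy, protocol=label)
            for label, ev in timelapse_events.items()
        ]
        self.f_mobile = f_mobile
        self.tau_RS = tau_RS
        self.bleach_rates = dict(bleach_rates) if bleach_rates else {}

    def _corrected(self, curve: SurvivalCurve) -> SurvivalCurve:
        rate = self.bleach_rates.get(curve.protocol, 0.0)
        if rate == 0.0:
            return curve
        sp = np.minimum(curve.sp * np.exp(rate * curve.times_s), 1.0)
        return SurvivalCurve(curve.times_s, sp, protocol=curve.protocol, scale=curve.scale)

    @staticmethod
    def _trim_span(curve: SurvivalCurve, max_span_frames: int) -> SurvivalCurve:
        """Drop points beyond ``max_span_frames`` frame intervals.

        An event spanning many frames has accumulated a large bleaching
        probability, so the product-limit tail there rests on a handful of
        events and is unreliable; each time-lapse protocol contributes the
        decade it was designed for.  The frame interval is inferred from
        the shortest positive duration on the grid (events start at
        min_frames = 2, i.e. one interval).
        """
        pos = curve.times_s[curve.times_s > 0]
        if len(pos) == 0:
            return curve
        t_max = pos[0] * max_span_frames
        keep = curve.times_s <= t_max
        return SurvivalCurve(curve.times_s[keep], curve.sp[keep], curve.protocol, curve.scale)

    @staticmethod
    def _half_interval_shift(curve: SurvivalCurve) -> SurvivalCurve:
        """Shift grid times by half a frame interval.

        An event observed on n frames reports duration (n-1) intervals,
        while the underlying dwell covered between (n-1) and (n+1)
        intervals; the survival value at the reported duration is an
        unbiased estimate of SP half an interval later.  The interval is
        inferred from the shortest positive duration (one interval at
        min_frames = 2).
        """
        pos = curve.times_s[curve.times_s > 0]
        if len(pos) == 0:
            return curve
        shift = pos[0] / 2.0
        times = np.where(curve.times_s > 0, curve.times_s + shift, curve.times_s)
        return SurvivalCurve(times, curve.sp, curve.protocol, curve.scale)

    def fit(
        self,
        anchor_s: float = 1.0,
        powerlaw_range_s: tuple[float, float] = (0.1, 100.0),
        tail_policy="power_law_to:100",
        max_span_frames: int = 100,
        log_resample: Optional[int] = 20,
        half_interval_shift: bool = True,
    ) -> "ResidenceResults":
        timelapse = [self._corrected(c) for c in self.sp_timelapse]
        if max_span_frames is not None:
            timelapse = [self._trim_span(c, max_span_frames) for c in timelapse]
        if half_interval_shift:
            timelapse = [self._half_interval_shift(c) for c in timelapse]
        merged = merge_survival_curves(
            self._corrected(self.sp_continuous), timelapse, anchor_s=anchor_s
        )
        gamma = fit_powerlaw(merged, range_s=powerlaw_range_s, log_resample=log_resample)
        tau_1d = mean_binding_time(merged, tail_policy=tail_policy)
        tau_3d, visit_rate = partition_times(tau_1d, self.f_mobile)
        return ResidenceResults(
            merged=merged,
            gamma=gamma,
            tau_1D=tau_1d,
            tau_3D=tau_3d,
            visit_rate=visit_rate,
            f_mobile=self.f_mobile,
            tau_RS=self.tau_RS,
        )


@dataclass(frozen=True)
class ResidenceResults:
    merged: SurvivalCurve
    gamma: float
    tau_1D: float
    tau_3D: float
    visit_rate: float
    f_mobile: float
    tau_RS: Optional[float] = None

    def summary(self) -> str:
        lines = [
            "Nonspecific residence-time analysis",
            f"  power-law exponent gamma : {self.gamma:8.3f}",
            f"  tau_1D (mean bound time) : {self.tau_1D:8.3f} s",
            f"  mobile fraction          : {self.f_mobile:8.3f}",
            f"  tau_3D (mean free time)  : {self.tau_3D:8.3f} s",
            f"  visit rate               : {self.visit_rate:8.4f} 1/s",
        ]
        if self.tau_RS is not None:
            lines.insert(2, f"  tau_RS (random sequences): {self.tau_RS * 1e3:8.1f} ms")
        return "\n".join(lines)
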