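"""Two-state diffusion–binding trajectory simulator and locus time courses.

The generative picture: a DNA-binding protein alternates between 3D
diffusion in the nucleoplasm (phase mean ``mean_unbound_s``, exponential)
and nonspecific binding to chromatin (phase durations from a dwell model).
While mobile, motion is Brownian in the imaging plane with a diffusion
coefficient drawn once per phase from a finite mixture (producing the
multi-population structure of instantaneous-diffusion histograms); while
bound, the molecule moves with the slow chromatin-like coefficient
``D_bound``.  Observation adds localization noise at frame times and
truncates tracks by per-frame photobleaching.

Brownian increments between arbitrary times are exact: with piecewise
constant D, the displacement over [t0, t1] is Gaussian with per-axis
variance ``2 * ∫ D dt``, so no fine time discretization is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .dwell import DwellModel, ExponentialDwell, sample_bound_dwell  # noqa: F401
from .protocols import ImagingProtocol

__all__ = [
    "KineticsConfig",
    "Trajectory",
    "simulate_trajectory",
    "simulate_trajectories",
    "apply_imaging_protocol",
    "simulate_locus_timecourse",
]


@dataclass(frozen=True)
class KineticsConfig:
    """Kinetic parameters of the two-state (diffusing/bound) model.

    ``diffusion_states`` lists (D in μm²/s, weight) for the mobile mixture;
    the default 8 and 1 μm²/s states in 33:43 proportion, with
    ``D_bound = 0.1`` μm²/s, reproduce the three observed mobility
    populations at the 33/43/24% partition when the phase means are
    (6 s unbound, 2 s bound).
    """

    diffusion_states: tuple = ((8.0, 33.0 / 76.0), (1.0, 43.0 / 76.0))
    D_bound: float = 0.1
    mean_unbound_s: float = 6.0
    dwell_model: DwellModel = field(default_factory=lambda: ExponentialDwell(rate=0.5))
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        w = np.array([wt for _, wt in self.diffusion_states], dtype=float)
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("diffusion-state weights must be nonnegative and sum to 1")
        if not self.mean_unbound_s > 0:
            raise ValueError("mean_unbound_s must be > 0")
        if self.D_bound < 0:
            raise ValueError("D_bound must be >= 0")


@dataclass
class Trajectory:
    """One tracked molecule: time-ordered 2D localizations plus metadata.

    ``bound_truth`` carries per-frame ground-truth binding labels (True =
    bound) when the trajectory was simulated; it is ``None`` for real data.
    """

    track_id: int | str
    frame_index: np.ndarray
    t_s: np.ndarray
    x_um: np.ndarray
    y_um: np.ndarray
    protocol: Optional[ImagingProtocol] = None
    bound_truth: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.frame_index = np.asarray(self.frame_index, dtype=int)
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.x_um = np.asarray(self.x_um, dtype=float)
        self.y_um = np.asarray(self.y_um, dtype=float)
        n = len(self.frame_index)
        if not (len(self.t_s) == len(self.x_um) == len(self.y_um) == n):
            raise ValueError("frame_index, t_s, x_um, y_um must have equal length")
        if n > 1 and np.any(np.diff(self.frame_index) <= 0):
            raise ValueError("frame indices must be strictly increasing")
        if n and (np.any(self.t_s < 0) or not np.all(np.isfinite(self.x_um)) or not np.all(np.isfinite(self.y_um))):
            raise ValueError("times must be nonnegative and coordinates finite")
        if self.bound_truth is not None:
            self.bound_truth = np.asarray(self.bound_truth, dtype=bool)
            if len(self.bound_truth) != n:
                raise ValueError("bound_truth length mismatch")

    def __len__(self) -> int:
        return len(self.frame_index)

    @property
    def duration_s(self) -> float:
        return float(self.t_s[-1] - self.t_s[0]) if len(self) > 1 else 0.0

    @property
    def interval_s(self) -> float:
        if self.protocol is not None:
            return self.protocol.interval_s
        if len(self) < 2:
            raise ValueError("cannot infer frame interval from <2 frames")
        return float(np.median(np.diff(self.t_s) / np.diff(self.frame_index)))

    def to_dataframe(self):
        import pandas as pd

        d = {
            "track_id": np.repeat(self.track_id, len(self)),
            "frame": self.frame_index,
            "t_s": self.t_s,
            "x_um": self.x_um,
            "y_um": self.y_um,
        }
        if self.bound_truth is not None:
            d["bound_truth"] = self.bound_truth.astype(int)
        return pd.DataFrame(d)


def _phase_schedule(
    kin: KineticsConfig, duration_s: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Alternating phase boundaries, per-phase D, and per-phase bound flags."""
    tau_1d = kin.dwell_model.mean()
    if np.isfinite(tau_1d):
        p_bound = tau_1d / (tau_1d + kin.mean_unbound_s)
    else:
        p_bound = 0.0  # heavy-tailed dwell: start mobile
    bound = rng.uniform() < p_bound

    d_vals = np.array([d for d, _ in kin.diffusion_states])
    d_wts = np.array([w for _, w in kin.diffusion_states])

    starts, coeffs, flags = [0.0], [], []
    t = 0.0
    while t < duration_s:
        if bound:
            dur = float(kin.dwell_model.sample(1, rng)[0])
            coeffs.append(kin.D_bound)
        else:
            dur = float(rng.exponential(kin.mean_unbound_s))
            coeffs.append(float(rng.choice(d_vals, p=d_wts)))
        flags.append(bound)
        t += dur
        starts.append(t)
        bound = not bound
    return np.array(starts), np.array(coeffs), np.array(flags, dtype=bool)


def simulate_trajectory(
    kin: KineticsConfig,
    protocol: ImagingProtocol,
    duration_s: float,
    seed: int,
    track_id: int | str = 0,
    bleaching: bool = True,
) -> Trajectory:
    """Simulate one two-state trajectory observed through ``protocol``.

    Positions are sampled exactly at frame times (Gaussian increments with
    variance 2·∫D dt per axis), localization noise of s.d.
    ``protocol.loc_sigma_um`` is added per axis, and per-frame ground-truth
    labels record the kinetic state at each frame time.  With
    ``bleaching=True`` the track is truncated at a geometric per-frame
    bleach event (see :meth:`ImagingProtocol.frame_bleach_probability`).
    """
    if not duration_s > 0:
        raise ValueError("duration_s must be > 0")
    rng = np.random.default_rng(seed)
    boundaries, coeffs, flags = _phase_schedule(kin, duration_s, rng)

    t_f = np.arange(0.0, duration_s + 0.5 * protocol.interval_s, protocol.interval_s)
    t_f = t_f[t_f <= duration_s + 1e-12]

    # cumulative "diffusion time" integral at phase knots, interpolated at frames
    seg = np.diff(boundaries)
    cum = np.concatenate([[0.0], np.cumsum(coeffs * seg)])
    cum_f = np.interp(t_f, boundaries, cum)
    var = 2.0 * np.diff(cum_f)
    steps = rng.standard_normal((2, len(var))) * np.sqrt(var)
    xy = np.concatenate([np.zeros((2, 1)), np.cumsum(steps, axis=1)], axis=1)
    if protocol.loc_sigma_um > 0:
        xy = xy + rng.standard_normal(xy.shape) * protocol.loc_sigma_um

    phase_of_frame = np.clip(np.searchsorted(boundaries, t_f, side="right") - 1, 0, len(flags) - 1)
    truth = flags[phase_of_frame]

    n = len(t_f)
    if bleaching and protocol.bleach_rate_continuous > 0:
        p_b = protocol.frame_bleach_probability()
        n = min(n, int(rng.geometric(p_b)))
    return Trajectory(
        track_id=track_id,
        frame_index=np.arange(n),
        t_s=t_f[:n],
        x_um=xy[0, :n],
        y_um=xy[1, :n],
        protocol=protocol,
        bound_truth=truth[:n],
    )


def simulate_trajectories(
    kin: KineticsConfig,
    protocol: ImagingProtocol,
    duration_s: float,
    n_tracks: int,
    seed: int,
    bleaching: bool = True,
) -> list[Trajectory]:
    """Simulate an ensemble of independent trajectories (seeded per track)."""
    ss = np.random.SeedSequence(seed).spawn(n_tracks)
    return [
        simulate_trajectory(
            kin,
            protocol,
            duration_s,
            seed=int(s.generate_state(1)[0] % (2**31)),
            track_id=i,
            bleaching=bleaching,
        )
        for i, s in enumerate(ss)
    ]


def apply_imaging_protocol(
    t_dense: np.ndarray,
    xy_dense: np.ndarray,
    protocol: ImagingProtocol,
    seed: int,
    bound_dense: Optional[np.ndarray] = None,
    track_id: int | str = 0,
) -> Trajectory:
    """Observe a dense true path through an imaging protocol.

    ``t_dense`` must sample the path at least 10x finer than the frame
    interval.  Positions are linearly interpolated at frame times,
    localization noise added, and the track truncated at a per-frame
    Bernoulli bleach event whose probability is protocol independent
    (bleaching occurs during exposures only, never in dark gaps).
    """
    t_dense = np.asarray(t_dense, dtype=float)
    xy_dense = np.asarray(xy_dense, dtype=float)
    if t_dense.size < 2 or (t_dense[-1] - t_dense[0]) < protocol.interval_s:
        return Trajectory(track_id, np.empty(0, int), np.empty(0), np.empty(0), np.empty(0), protocol)
    if np.median(np.diff(t_dense)) > protocol.interval_s / 10.0:
        raise ValueError("dense path must be sampled >= 10x finer than the frame interval")

    rng = np.random.default_rng(seed)
    t_f = np.arange(t_dense[0], t_dense[-1] + 1e-12, protocol.interval_s)
    x = np.interp(t_f, t_dense, xy_dense[0])
    y = np.interp(t_f, t_dense, xy_dense[1])
    if protocol.loc_sigma_um > 0:
        x = x + rng.standard_normal(len(t_f)) * protocol.loc_sigma_um
        y = y + rng.standard_normal(len(t_f)) * protocol.loc_sigma_um
    truth = None
    if bound_dense is not None:
        idx = np.clip(np.searchsorted(t_dense, t_f, side="right") - 1, 0, len(t_dense) - 1)
        truth = np.asarray(bound_dense, dtype=bool)[idx]

    n = len(t_f)
    p_b = protocol.frame_bleach_probability()
    if p_b > 0:
        n = min(n, int(rng.geometric(p_b)))
    return Trajectory(
        track_id=track_id,
        frame_index=np.arange(n),
        t_s=t_f[:n] - t_f[0],
        x_um=x[:n],
        y_um=y[:n],
        protocol=protocol,
        bound_truth=None if truth is None else truth[:n],
    )


def simulate_locus_timecourse(
    k_a: float,
    k_off: float,
    c: float,
    plateau: float,
    noise_sd: float,
    t_grid: np.ndarray,
    seed: int,
    cell_id: str = "cell0",
    cell_line: str = "2-6-3",
):
    """Simulate a locus-intensity association time course for one cell.

    I(t) = plateau * (1 - exp(-(k_a*c + k_off) * t)) + Gaussian noise, the
    monoexponential filling of the target array at observed rate
    k_obs = k_a*c + k_off.  Returns a
    :class:`~searchkin.association.CellAssociationRecord` carrying the true
    concentration.
    """
    from .association import CellAssociationRecord

    if c < 0:
        raise ValueError("concentration must be >= 0")
    if plateau < 0 or noise_sd < 0:
        raise ValueError("plateau and noise_sd must be >= 0")
    t_grid = np.asarray(t_grid, dtype=float)
    if np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    rng = np.random.default_rng(seed)
    rate = k_a * c + k_off
    intensity = plateau * (1.0 - np.exp(-rate * t_grid))
    if noise_sd > 0:
        intensity = intensity + rng.standard_normal(len(t_grid)) * noise_sd
    return CellAssociationRecord(
        cell_id=cell_id,
        c_M=c,
        t_s=t_grid,
        intensity=intensity,
        cell_line=cell_line,
        true_rate=rate,
    )
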