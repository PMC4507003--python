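"""Association kinetics at the target locus.

After switching the searcher's DNA-binding affinity on, the locus
fluorescence fills as I(t) = B + A(1 - exp(-k_obs t)) with observed rate
k_obs = k_a c + k_off.  Per-cell concentrations come from the FCS
autocorrelation amplitude (<N> = 1/G0 molecules in the effective volume).
Regressing k_obs on c across cells yields the association rate constant
k_a (slope) and the dissociation rate k_off (intercept).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.constants import Avogadro
from scipy.optimize import curve_fit

__all__ = [
    "CellAssociationRecord",
    "AssociationFit",
    "AssociationModel",
    "AssociationResults",
    "fit_monoexponential_rise",
    "fit_monoexponential_decay",
    "concentration_from_fcs",
    "fit_association_constant",
    "occupancy_ratio",
    "site_scaling_report",
    "SiteScalingReport",
]


@dataclass
class CellAssociationRecord:
    """One cell: nuclear concentration and locus-intensity time course."""

    cell_id: str
    c_M: float
    t_s: Optional[np.ndarray] = None
    intensity: Optional[np.ndarray] = None
    c_sd_M: float = 0.0
    k_obs: Optional[float] = None
    cell_line: str = "2-6-3"
    true_rate: Optional[float] = None  # generative truth, simulation only

    def __post_init__(self) -> None:
        if self.c_M < 0:
            raise ValueError("c_M must be >= 0")
        if self.intensity is not None:
            self.intensity = np.asarray(self.intensity, dtype=float)
            self.t_s = np.asarray(self.t_s, dtype=float)
            if len(self.intensity) < 5:
                raise ValueError("intensity series must have >= 5 points")

    def fit_kobs(self) -> float:
        """Fit the monoexponential rise and store/return k_obs."""
        k, _, _ = fit_monoexponential_rise(self.t_s, self.intensity)
        self.k_obs = k
        return k


def fit_monoexponential_rise(t: np.ndarray, intensity: np.ndarray) -> tuple[float, float, float]:
    """Fit I(t) = B + A(1 - exp(-k t)); returns (k_obs, plateau A, baseline B)."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(intensity, dtype=float)
    if len(t) < 5 or not np.all(np.isfinite(y)):
        raise ValueError("need >= 5 finite intensity points")
    span = max(t[-1] - t[0], 1e-12)
    amp0 = y[-1] - y[0]
    if np.ptp(y) <= 1e-12 * max(abs(y).max(), 1.0):
        warnings.warn("intensity series is flat; k_obs indistinguishable from 0")
        return 0.0, 0.0, float(y.mean())
    if amp0 == 0.0:
        amp0 = np.ptp(y)
    try:
        popt, _ = curve_fit(
            lambda tt, b, a, k: b + a * (1.0 - np.exp(-k * tt)),
            t,
            y,
            p0=(y[0], amp0, 3.0 / span),
            maxfev=20000,
        )
    except RuntimeError as err:
        resid = np.ptp(y)
        raise RuntimeError(f"monoexponential rise fit did not converge (data range {resid:g})") from err
    b, a, k = popt
    return float(k), float(a), float(b)


def fit_monoexponential_decay(t: np.ndarray, intensity: np.ndarray) -> tuple[float, float, float]:
    """Fit I(t) = B + A exp(-t/tau); returns (tau, amplitude A, baseline B)."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(intensity, dtype=float)
    span = max(t[-1] - t[0], 1e-12)
    popt, _ = curve_fit(
        lambda tt, b, a, tau: b + a * np.exp(-tt / tau),
        t,
        y,
        p0=(y[-1], y[0] - y[-1], span / 3.0),
        maxfev=20000,
    )
    b, a, tau = popt
    return float(tau), float(a), float(b)


def concentration_from_fcs(g0: float, v_eff_L: float = 0.5e-15) -> float:
    """Molar concentration from the FCS amplitude.

    The mean molecule number in the effective volume is <N> = 1/G0, so
    c = (1/G0) / (N_A * V_eff).  Default V_eff is 0.5 fl.
    """
    if not g0 > 0 or not v_eff_L > 0:
        raise ValueError("g0 and v_eff_L must be > 0")
    return (1.0 / g0) / (Avogadro * v_eff_L)


@dataclass(frozen=True)
class AssociationFit:
    """k_obs-vs-c regression result: k_a (M^-1 s^-1) and k_off (s^-1)."""

    k_a: float
    k_a_se: float
    k_off: float
    k_off_se: float
    n_cells: int


class AssociationModel:
    """Linear model k_obs = k_a * c + k_off across cells.

    Built from fitted :class:`CellAssociationRecord` objects (records
    without a stored ``k_obs`` are fitted on the fly) or directly from
    concentration/rate arrays.  The default fit is ordinary least squares,
    unweighted and ignoring concentration uncertainties; ``weights``
    enables a WLS variant.
    """

    def __init__(self, c_M: np.ndarray, k_obs: np.ndarray, weights: Optional[np.ndarray] = None):
        self.c_M = np.asarray(c_M, dtype=float)
        self.k_obs = np.asarray(k_obs, dtype=float)
        self.weights = None if weights is None else np.asarray(weights, dtype=float)
        if len(self.c_M) != len(self.k_obs) or len(self.c_M) < 2:
            raise ValueError("need >= 2 (c, k_obs) pairs of equal length")
        if np.ptp(self.c_M) == 0:
            raise ValueError("degenerate design: all concentrations identical")
        span = self.c_M.max() / self.c_M.min()
        if len(self.c_M) < 3 or span < 5:
            warnings.warn(
                f"weak design for the association fit (n={len(self.c_M)}, c span x{span:.2g}); "
                "recommend >= 3 cells spanning >= 5-fold in concentration"
            )

    @classmethod
    def from_records(cls, records: Sequence[CellAssociationRecord], **kw) -> "AssociationModel":
        c, k = [], []
        for r in records:
            if r.k_obs is None:
                r.fit_kobs()
            c.append(r.c_M)
            k.append(r.k_obs)
        return cls(np.array(c), np.array(k), **kw)

    def fit(self) -> "AssociationResults":
        import statsmodels.api as sm

        X = sm.add_constant(self.c_M)
        if self.weights is None:
            res = sm.OLS(self.k_obs, X).fit()
        else:
            res = sm.WLS(self.k_obs, X, weights=self.weights).fit()
        k_off, k_a = res.params
        se_off, se_a = res.bse
        return AssociationResults(
            k_a=float(k_a),
            k_a_se=float(se_a),
            k_off=float(k_off),
            k_off_se=float(se_off),
            n_cells=len(self.c_M),
            _sm_results=res,
        )


@dataclass(frozen=True)
class AssociationResults:
    k_a: float
    k_a_se: float
    k_off: float
    k_off_se: float
    n_cells: int
    _sm_results: object = field(default=None, repr=False, compare=False)

    def as_fit(self) -> AssociationFit:
        return AssociationFit(self.k_a, self.k_a_se, self.k_off, self.k_off_se, self.n_cells)

    def summary(self) -> str:
        return "\n".join(
            [
                "Association kinetics (OLS of k_obs on c)",
                f"  n cells : {self.n_cells}",
                f"  k_a     : {self.k_a:.4g} +/- {self.k_a_se:.2g} M^-1 s^-1",
                f"  k_off   : {self.k_off:.4g} +/- {self.k_off_se:.2g} s^-1",
            ]
        )


def fit_association_constant(records: Sequence[CellAssociationRecord]) -> AssociationFit:
    """OLS of k_obs on c over a cell ensemble: slope k_a, intercept k_off."""
    return AssociationModel.from_records(records).fit().as_fit()


def occupancy_ratio(i_eq_a: float, i_eq_b: float) -> float:
    """Ratio of equilibrium locus occupancies (intensities)."""
    if not (i_eq_a > 0 and i_eq_b > 0):
        raise ValueError("intensities must be positive")
    return i_eq_a / i_eq_b


@dataclass(frozen=True)
class SiteScalingReport:
    """Which quantity the measured k_a ratio tracks: inserts or total sites."""

    ratio_ka: float
    ratio_sites: float
    ratio_inserts: float
    log_distance_sites: float
    log_distance_inserts: float
    closer_to: str


def site_scaling_report(
    ratio_ka: float, ratio_sites: float, ratio_inserts: float
) -> SiteScalingReport:
    """Compare the k_a ratio between cell lines with the site and insert
    ratios, in log space.

    If the search were reaction-limited by per-site binding efficiency the
    rate would scale with the total site count; scaling with the insert
    count instead indicates sliding merges each insert into one target.
    """
    d_sites = abs(math.log(ratio_ka) - math.log(ratio_sites))
    d_inserts = abs(math.log(ratio_ka) - math.log(ratio_inserts))
    return SiteScalingReport(
        ratio_ka=ratio_ka,
        ratio_sites=ratio_sites,
        ratio_inserts=ratio_inserts,
        log_distance_sites=d_sites,
        log_distance_inserts=d_inserts,
        closer_to="inserts" if d_inserts <= d_sites else "sites",
    )
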