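"""Closed-form target-search rate models in consistent molar units.

Three nested descriptions of the association rate constant k_a to a
clustered target (N specific sites inside a spherical locus of radius r_t):

* the diffusion-limited ("absorbing sphere") ceiling k_a = 4 pi D r_t;
* the uniformly reactive sphere k_a = 4 pi D r_t (1 - tanh(x)/x) with
  x = r_t sqrt(kappa/D), where kappa is the per-unit-time binding rate
  inside the locus, itself built from the per-site binding efficiency
  lambda (probability per unit time of binding within the capture radius
  a of one site);
* the reaction-limited limit k_a = (4 pi / 3) lambda N a^3, independent of
  transport.

A facilitated-diffusion variant accounts for 1D sliding: a nonspecific
binding event scans ell_SL = sqrt(4 D_SL tau_RS) base pairs, so inserts
(clusters of sites closer than ell_SL) act as single targets and
k_a = p N_i ell_SL / (c_DNA (tau_1D + tau_3D)).

Internal units: lengths in μm, volumes in μm³, times in s, concentrations
in M; rates cross between μm³/s and M⁻¹ s⁻¹ via Avogadro's number.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

from scipy.constants import Avogadro

__all__ = [
    "SearchModelParams",
    "effective_diffusion",
    "rate_to_molar",
    "molar_to_rate",
    "absorbing_sphere_rate",
    "site_rate_kappa",
    "locus_binding_rate",
    "extract_lambda",
    "sliding_length",
    "fd_association_rate",
    "solve_p",
    "search_time_single",
    "nonspecific_visits",
    "diffusion_limited_ns_time",
    "model_report",
]

_UM3_PER_L = 1e15  # μm³ per litre


@dataclass(frozen=True)
class SearchModelParams:
    """All symbols of the clustered-target / facilitated-diffusion models.

    Defaults are the measured values for the TetR searcher in U2OS 2-6-3
    cells: D1 = 8 μm²/s slowed to D = 6 μm²/s by intermittent binding,
    a 350-nm locus carrying N = 200 x 96 = 19,200 sites in 200 inserts,
    1-nm capture radius, genomic base-pair concentration 10⁻² M, sliding
    coefficient 10⁵ bp²/s, and the (2 s, 6 s) bound/free cycle.
    """

    D: float = 6.0            # effective 3D diffusion coefficient (μm²/s)
    r_t: float = 0.35         # locus radius (μm)
    N: int = 19200            # specific sites in the locus
    N_i: int = 200            # inserts
    a: float = 1e-3           # capture radius (μm)
    lambda_: Optional[float] = None  # per-site binding efficiency (1/s)
    kappa: Optional[float] = None    # in-locus binding rate (1/s)
    c_DNA: float = 1e-2       # genomic bp concentration (M)
    D_SL: float = 1e5         # 1D sliding coefficient (bp²/s)
    ell_SL: Optional[float] = None   # sliding length (bp)
    p: float = 1.0            # specific-binding probability per overlap
    tau_RS: float = 0.158     # residence time on random sequences (s)
    tau_1D: float = 2.0       # mean bound phase (s)
    tau_3D: float = 6.0       # mean free phase (s)
    V_nuc: float = 500.0      # nuclear volume (μm³)

    def __post_init__(self) -> None:
        for name in ("D", "r_t", "N", "N_i", "a", "c_DNA", "D_SL", "tau_RS", "tau_1D", "tau_3D", "V_nuc"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 <= self.p <= 1:
            raise ValueError("p must be in [0, 1]")

    @property
    def v(self) -> float:
        """Elementary volume per site within the locus (μm³)."""
        return (4.0 * math.pi / 3.0) * self.r_t**3 / self.N


def effective_diffusion(D1: float, tau_1D: float, tau_3D: float) -> float:
    """Free-diffusion coefficient slowed by intermittent nonspecific binding:
    D = D1 * tau_3D / (tau_1D + tau_3D)."""
    return D1 * tau_3D / (tau_1D + tau_3D)


def rate_to_molar(k_vol: float) -> float:
    """Convert a rate constant from μm³/s to M⁻¹ s⁻¹."""
    if k_vol < 0:
        raise ValueError("rate must be >= 0")
    return k_vol * Avogadro / _UM3_PER_L


def molar_to_rate(k_molar: float) -> float:
    """Convert a rate constant from M⁻¹ s⁻¹ to μm³/s."""
    if k_molar < 0:
        raise ValueError("rate must be >= 0")
    return k_molar * _UM3_PER_L / Avogadro


def absorbing_sphere_rate(D: float, r_t: float) -> float:
    """Diffusion-limited (Smoluchowski) rate to an absorbing sphere,
    k_a = 4 pi D r_t, in M⁻¹ s⁻¹."""
    return rate_to_molar(4.0 * math.pi * D * r_t)


def site_rate_kappa(D: float, a: float, v: float, lambda_: float) -> float:
    """Per-unit-time binding rate inside the locus (1/s).

    Harmonic interpolation between the perfect-association limit
    kappa = 4 pi D a / v (lambda >> D/a²) and the low-efficiency limit
    kappa = lambda (4 pi/3) a³ / v (lambda << D/a²); exact in both limits.
    """
    if min(D, a, v, lambda_) <= 0:
        raise ValueError("all inputs must be > 0")
    k_fast = 4.0 * math.pi * D * a / v
    k_slow = lambda_ * (4.0 * math.pi / 3.0) * a**3 / v
    return 1.0 / (1.0 / k_fast + 1.0 / k_slow)


def locus_binding_rate(D: float, r_t: float, kappa: float) -> float:
    """Association rate constant (M⁻¹ s⁻¹) to a uniformly reactive sphere.

    k_a = 4 pi D r_t (1 - tanh(x)/x), x = r_t sqrt(kappa/D).  For
    kappa -> inf this is the absorbing sphere; for small kappa it reduces
    to the volume-reaction limit (4 pi/3) r_t³ kappa.
    """
    x = r_t * math.sqrt(kappa / D)
    if x < 1e-4:
        factor = x**2 / 3.0 - 2.0 * x**4 / 15.0  # series of 1 - tanh(x)/x
    else:
        factor = 1.0 - math.tanh(x) / x
    return rate_to_molar(4.0 * math.pi * D * r_t * factor)


def extract_lambda(k_a_meas: float, N: int, a: float, D: Optional[float] = None) -> float:
    """Per-site binding efficiency from a measured reaction-limited k_a.

    Inverts k_a = (4 pi/3) lambda N a³.  When ``D`` is supplied, the
    reaction-limited regime condition lambda << D/a² is checked and a
    warning issued if violated (the value is still returned).
    """
    k_vol = molar_to_rate(k_a_meas)
    lam = k_vol / ((4.0 * math.pi / 3.0) * N * a**3)
    if D is not None and lam >= 0.1 * D / a**2:
        warnings.warn(
            f"lambda = {lam:.3g} 1/s is not << D/a^2 = {D / a**2:.3g} 1/s; "
            "reaction-limited inversion may be invalid"
        )
    return lam


def sliding_length(D_SL: float, tau_RS: float) -> float:
    """1D sliding span (bp) during one nonspecific event:
    ell_SL = sqrt(4 D_SL tau_RS)."""
    if D_SL < 0 or tau_RS < 0:
        raise ValueError("inputs must be >= 0")
    return math.sqrt(4.0 * D_SL * tau_RS)


def fd_association_rate(
    p: float, N_i: int, ell_SL: float, c_DNA: float, tau_1D: float, tau_3D: float
) -> float:
    """Facilitated-diffusion association rate constant (M⁻¹ s⁻¹).

    k_a = p N_i ell_SL / (c_DNA (tau_1D + tau_3D)): per search cycle of
    duration tau_1D + tau_3D the protein scans ell_SL of the c_DNA molar
    base pairs, hits one of the N_i insert-sized targets with the
    corresponding probability, and converts with probability p.
    """
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0, 1]")
    return p * N_i * ell_SL / (c_DNA * (tau_1D + tau_3D))


def solve_p(
    k_a_meas: float, N_i: int, ell_SL: float, c_DNA: float, tau_1D: float, tau_3D: float
) -> tuple[float, bool]:
    """Invert the facilitated-diffusion rate for the specific-binding
    probability p.

    Returns (p clipped to [0, 1], in_range flag); out-of-range p means the
    parameter combination cannot reproduce the measured rate.
    """
    p = k_a_meas * c_DNA * (tau_1D + tau_3D) / (N_i * ell_SL)
    return min(max(p, 0.0), 1.0), bool(0.0 <= p <= 1.0)


def search_time_single(k_a: float, V_nuc: float = 500.0) -> float:
    """Mean time (s) for a single protein to find the locus in a nucleus of
    ``V_nuc`` μm³: T = 1/(k_a c1) with c1 the one-molecule concentration."""
    c1 = 1.0 / (Avogadro * V_nuc / _UM3_PER_L)
    return 1.0 / (k_a * c1)


def nonspecific_visits(T_search: float, visit_rate: float) -> float:
    """Number of nonspecific sites visited during one search."""
    return T_search * visit_rate


def diffusion_limited_ns_time(D: float, a: float, c_DNA: float) -> float:
    """Diffusion-limited nonspecific association time 1/(D a c_DNA) (s),
    with c_DNA converted from M to molecules/μm³."""
    if min(D, a, c_DNA) <= 0:
        raise ValueError("all inputs must be > 0")
    c_num = c_DNA * Avogadro / _UM3_PER_L
    return 1.0 / (D * a * c_num)


def model_report(params: SearchModelParams, k_a_meas: Optional[float] = None) -> dict:
    """Every derived quantity of the search-rate models, as a flat dict.

    When a measured k_a is supplied, the per-site efficiency lambda, the
    facilitated-diffusion probability p, the single-molecule search time
    and the visit count during one search are derived from it.
    """
    out: dict[str, float | bool | str] = {
        "D_eff_um2_s": params.D,
        "v_um3": params.v,
        "ka_absorbing_sphere_M_s": absorbing_sphere_rate(params.D, params.r_t),
        "ell_SL_bp": params.ell_SL if params.ell_SL is not None else sliding_length(params.D_SL, params.tau_RS),
        "diffusion_limited_ns_time_s": diffusion_limited_ns_time(params.D, params.a, params.c_DNA),
        "visit_rate_s": 1.0 / (params.tau_1D + params.tau_3D),
    }
    lam = params.lambda_
    if lam is None and k_a_meas is not None:
        lam = extract_lambda(k_a_meas, params.N, params.a, D=params.D)
    if lam is not None:
        kappa = params.kappa if params.kappa is not None else site_rate_kappa(params.D, params.a, params.v, lam)
        out["lambda_s"] = lam
        out["kappa_s"] = kappa
        out["ka_reactive_sphere_M_s"] = locus_binding_rate(params.D, params.r_t, kappa)
        out["ka_reaction_limited_M_s"] = rate_to_molar(
            lam * (4.0 * math.pi / 3.0) * params.N * params.a**3
        )
        out["reaction_limited_regime"] = bool(lam < 0.1 * params.D / params.a**2)
    if k_a_meas is not None:
        ell = out["ell_SL_bp"]
        p, in_range = solve_p(k_a_meas, params.N_i, ell, params.c_DNA, params.tau_1D, params.tau_3D)
        t_search = search_time_single(k_a_meas, params.V_nuc)
        out.update(
            {
                "ka_measured_M_s": k_a_meas,
                "p_fd": p,
                "p_fd_in_range": in_range,
                "T_search_s": t_search,
                "T_search_days": t_search / 86400.0,
                "nonspecific_visits": nonspecific_visits(t_search, out["visit_rate_s"]),
            }
        )
    return out
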