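"""Forward kinetic model of the Gα nucleotide cycle.

A Gα subunit cycles between a GDP-bound (inactive) and a GTP-bound (active)
state.  The steady-state balance is set by two first-order rates: the apparent
nucleotide-exchange rate ``k_exchange`` (GDP release followed by fast GTP
binding, the observable in GTPγS-binding assays) and the intrinsic
single-turnover hydrolysis rate ``k_cat``.  Plant Gα proteins are unusual in
that exchange is faster than hydrolysis, so the protein accumulates in the
active state with no exchange factor — it is "self-activating" — and the
physiological control point is hydrolysis, accelerated by an RGS GAP.

This module provides closed-form curves for each in-vitro assay
(GTPγS association, single-turnover hydrolysis, SPR sensorgrams), the derived
steady-state statistics, a hyperbolic GAP dose–response, and an ODE for
multi-turnover kinetics under a finite GTP pool (the fluorescence experiment,
where free GDP released by exchange competes with remaining GTP).

Units: rates in min⁻¹ and concentrations in nM for enzymology; SPR uses
seconds, M and response units (RU).  Conversions are explicit at call sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

from .errors import IntegrationError, ValidationError

__all__ = [
    "RateConstants",
    "CyclePools",
    "CycleTrajectory",
    "TimeCourse",
    "Sensorgram",
    "BindingKinetics",
    "gtpgs_binding_curve",
    "single_turnover_curve",
    "steady_state_turnover",
    "fraction_gtp_bound",
    "percent_gtp_bound",
    "turnover_ode",
    "gap_hydrolysis_rate",
    "spr_sensorgram",
    "round_half_up",
]

ASSAY_KINDS = ("gtpgs_binding", "single_turnover", "steady_state", "fluorescence", "spr")


def round_half_up(x: float) -> int:
    """Round to the nearest integer with ties going up (94.65 → 95)."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class RateConstants:
    """Intrinsic nucleotide-cycle parameters of one Gα subunit.

    Parameters
    ----------
    k_exchange : float
        Apparent nucleotide exchange rate (GDP release / GTPγS binding,
        pseudo-first-order), min⁻¹.
    k_cat : float
        Intrinsic single-turnover GTP hydrolysis rate, min⁻¹.
    k_gap_max : float, optional
        Maximal GAP-added hydrolysis rate at saturating RGS, min⁻¹.
    k_half_gap : float, optional
        RGS concentration giving half-maximal GAP acceleration, nM.
    """

    k_exchange: float
    k_cat: float
    k_gap_max: float | None = None
    k_half_gap: float | None = None

    def __post_init__(self) -> None:
        for name in ("k_exchange", "k_cat", "k_gap_max", "k_half_gap"):
            v = getattr(self, name)
            if v is None:
                continue
            if not math.isfinite(v) or v < 0:
                raise ValidationError(f"{name} must be finite and >= 0, got {v!r}")

    @property
    def has_gap_terms(self) -> bool:
        return self.k_gap_max is not None and self.k_half_gap is not None

    def with_gap(self, k_gap_max: float, k_half_gap: float) -> "RateConstants":
        return replace(self, k_gap_max=k_gap_max, k_half_gap=k_half_gap)


@dataclass(frozen=True)
class CyclePools:
    """Instantaneous species concentrations in the turnover ODE, nM."""

    g_total: float
    g_gtp: float
    free_gtp: float
    free_gdp: float

    def __post_init__(self) -> None:
        if self.g_total <= 0:
            raise ValidationError(f"g_total must be > 0, got {self.g_total}")
        if not (0 <= self.g_gtp <= self.g_total * (1 + 1e-9)):
            raise ValidationError(
                f"g_gtp must lie in [0, g_total]; got {self.g_gtp} with g_total {self.g_total}"
            )
        if self.free_gtp < 0 or self.free_gdp < 0:
            raise ValidationError("free nucleotide pools must be >= 0")


@dataclass
class CycleTrajectory:
    """Solution of :func:`turnover_ode` at the requested output times."""

    times: np.ndarray
    g_gtp: np.ndarray
    free_gtp: np.ndarray
    free_gdp: np.ndarray
    pi: np.ndarray  # cumulative inorganic phosphate released, nM
    g_total: float

    def pools_at(self, i: int) -> CyclePools:
        return CyclePools(
            g_total=self.g_total,
            g_gtp=float(min(max(self.g_gtp[i], 0.0), self.g_total)),
            free_gtp=float(max(self.free_gtp[i], 0.0)),
            free_gdp=float(max(self.free_gdp[i], 0.0)),
        )


@dataclass
class TimeCourse:
    """One assay trace: strictly increasing times and one signal per time."""

    times: np.ndarray
    values: np.ndarray
    assay_kind: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.assay_kind not in ASSAY_KINDS:
            raise ValidationError(
                f"unknown assay_kind {self.assay_kind!r}; expected one of {ASSAY_KINDS}"
            )
        _validate_times(self.times)
        if self.times.shape != self.values.shape:
            raise ValidationError(
                f"times and values must have equal length "
                f"({len(self.times)} != {len(self.values)})"
            )


@dataclass
class Sensorgram:
    """SPR trace at one analyte concentration.

    Times in seconds, response in RU; points with ``t <= t_assoc`` belong to
    the association phase, later points to dissociation.
    """

    times: np.ndarray
    response: np.ndarray
    conc: float  # analyte concentration, M
    t_assoc: float  # end of injection, s

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        _validate_times(self.times)
        if self.times.shape != self.response.shape:
            raise ValidationError("times and response must have equal length")
        if self.conc < 0:
            raise ValidationError(f"analyte concentration must be >= 0, got {self.conc}")

    @property
    def phase(self) -> np.ndarray:
        return np.where(self.times <= self.t_assoc, "assoc", "dissoc")


@dataclass(frozen=True)
class BindingKinetics:
    """1:1 Langmuir binding constants from SPR: k_a (M⁻¹s⁻¹), k_d (s⁻¹), R_max (RU)."""

    k_a: float
    k_d: float
    r_max: float | None = None

    def __post_init__(self) -> None:
        if self.k_a <= 0 or self.k_d <= 0:
            raise ValidationError(
                f"k_a and k_d must be > 0, got k_a={self.k_a}, k_d={self.k_d}"
            )
        if self.r_max is not None and self.r_max <= 0:
            raise ValidationError(f"r_max must be > 0, got {self.r_max}")

    @property
    def k_D(self) -> float:
        """Equilibrium dissociation constant K_D = k_d / k_a, in M."""
        return self.k_d / self.k_a


def _validate_times(times: np.ndarray) -> None:
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or len(times) == 0:
        raise ValidationError("times must be a non-empty 1-D sequence")
    neg = np.nonzero(times < 0)[0]
    if len(neg):
        raise ValidationError(f"negative time at index {int(neg[0])}: {times[neg[0]]}")
    if np.any(np.diff(times) <= 0):
        i = int(np.nonzero(np.diff(times) <= 0)[0][0])
        raise ValidationError(f"times must be strictly increasing (violation after index {i})")


def gtpgs_binding_curve(rc: RateConstants, b_max: float, times) -> TimeCourse:
    """Pseudo-first-order GTPγS association: B(t) = b_max·(1 − e^(−k_exchange·t)).

    The plateau ``b_max`` is set experimentally by the amount of active
    protein (concentration × specific activity).
    """
    if b_max < 0:
        raise ValidationError(f"b_max must be >= 0, got {b_max}")
    if rc.k_exchange <= 0:
        raise ValidationError("k_exchange must be > 0 to simulate binding")
    times = np.asarray(times, dtype=float)
    _validate_times(times)
    values = b_max * (1.0 - np.exp(-rc.k_exchange * times))
    return TimeCourse(times, values, "gtpgs_binding", {"k_exchange": rc.k_exchange, "b_max": b_max})


def single_turnover_curve(rc: RateConstants, p0: float, times) -> TimeCourse:
    """Single-turnover Pi release: Pi(t) = p0·(1 − e^(−k_cat·t)).

    Gα is preloaded with labelled GTP, so each protein hydrolyzes once and
    Pi release is first order in the remaining loaded protein.
    """
    if p0 < 0:
        raise ValidationError(f"p0 must be >= 0, got {p0}")
    times = np.asarray(times, dtype=float)
    _validate_times(times)
    values = p0 * (1.0 - np.exp(-rc.k_cat * times))
    return TimeCourse(times, values, "single_turnover", {"k_cat": rc.k_cat, "p0": p0})


def steady_state_turnover(rc: RateConstants) -> float:
    """Multi-turnover rate per Gα for two first-order steps in series.

    v = (1/k_exchange + 1/k_cat)⁻¹ — bounded by the slower step and symmetric
    in the two rates.
    """
    if rc.k_exchange <= 0 or rc.k_cat <= 0:
        raise ValidationError(
            "steady-state turnover undefined: both k_exchange and k_cat must be > 0"
        )
    return 1.0 / (1.0 / rc.k_exchange + 1.0 / rc.k_cat)


def fraction_gtp_bound(rc: RateConstants) -> float:
    """Steady-state active fraction: k_exchange / (k_exchange + k_cat)."""
    total = rc.k_exchange + rc.k_cat
    if total <= 0:
        raise ValidationError("fraction undefined: k_exchange + k_cat must be > 0")
    return rc.k_exchange / total


def percent_gtp_bound(rc: RateConstants) -> int:
    """Active fraction as an integer percent, ties rounded up."""
    return round_half_up(100.0 * fraction_gtp_bound(rc))


def gap_hydrolysis_rate(rc: RateConstants, rgs_conc: float) -> float:
    """Observed hydrolysis rate with GAP: k_cat + k_gap_max·[RGS]/(k_half_gap + [RGS])."""
    if rgs_conc < 0:
        raise ValidationError(f"rgs_conc must be >= 0, got {rgs_conc}")
    if rgs_conc == 0:
        return rc.k_cat
    if not rc.has_gap_terms:
        raise ValidationError(
            "GAP parameters (k_gap_max, k_half_gap) are unset but rgs_conc > 0"
        )
    return rc.k_cat + rc.k_gap_max * rgs_conc / (rc.k_half_gap + rgs_conc)


def turnover_ode(
    rc: RateConstants,
    pools0: CyclePools,
    times,
    hydrolysable: bool = True,
    unlimited_gtp: bool = False,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> CycleTrajectory:
    """Integrate the nucleotide cycle under a finite (or unlimited) GTP pool.

    Model: d(g_gtp)/dt = k_exchange·(g_total − g_gtp)·φ − k_cat·g_gtp with
    φ = free_gtp/(free_gtp + free_gdp), the mass-action probability that an
    exchange event loads GTP rather than rebinding GDP.  Each productive
    exchange consumes one free GTP and releases one free GDP, so the free
    nucleotide total is conserved.  Hydrolysis converts bound GTP to bound
    GDP in place (Pi leaves; no free-pool change) and is tracked as
    cumulative Pi.  ``hydrolysable=False`` models GTPγS (k_cat term off);
    ``unlimited_gtp=True`` pins φ at 1 and freezes the free pools (excess
    substrate limit).
    """
    times = np.asarray(times, dtype=float)
    _validate_times(times)
    k_cat = rc.k_cat if hydrolysable else 0.0
    k_ex = rc.k_exchange
    g_total = pools0.g_total

    def rhs(_t, y):
        g_gtp, f_gtp, f_gdp, _pi = y
        if unlimited_gtp:
            phi = 1.0
        else:
            denom = f_gtp + f_gdp
            phi = f_gtp / denom if denom > 0 else 0.0
        flux_ex = k_ex * max(g_total - g_gtp, 0.0) * phi
        flux_hyd = k_cat * max(g_gtp, 0.0)
        d_free = 0.0 if unlimited_gtp else flux_ex
        return (flux_ex - flux_hyd, -d_free, d_free, flux_hyd)

    y0 = (pools0.g_gtp, pools0.free_gtp, pools0.free_gdp, 0.0)
    t0 = min(0.0, times[0])
    sol = solve_ivp(
        rhs,
        (t0, times[-1]),
        y0,
        method="LSODA",
        t_eval=times,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(f"turnover ODE integration failed: {sol.message}")
    g_gtp = np.clip(sol.y[0], 0.0, g_total)
    return CycleTrajectory(
        times=times,
        g_gtp=g_gtp,
        free_gtp=np.clip(sol.y[1], 0.0, None),
        free_gdp=np.clip(sol.y[2], 0.0, None),
        pi=np.clip(sol.y[3], 0.0, None),
        g_total=g_total,
    )


def spr_sensorgram(
    kin: BindingKinetics,
    analyte_conc: float,
    t_assoc: float,
    t_dissoc: float,
    dt: float,
    bulk_shift: float = 0.0,
) -> Sensorgram:
    """Noise-free 1:1 Langmuir sensorgram.

    Association: R(t) = R_eq·(1 − e^(−(k_a·C + k_d)·t)) with
    R_eq = k_a·C·R_max/(k_a·C + k_d).  Dissociation decays exponentially at
    k_d from the response reached at the end of injection.  ``bulk_shift``
    is an optional additive refractive-index offset applied during
    association only.
    """
    if analyte_conc <= 0:
        raise ValidationError(f"analyte_conc must be > 0, got {analyte_conc}")
    if t_assoc <= 0 or t_dissoc <= 0:
        raise ValidationError("t_assoc and t_dissoc must be > 0")
    if dt <= 0:
        raise ValidationError(f"dt must be > 0, got {dt}")
    if kin.r_max is None:
        raise ValidationError("BindingKinetics.r_max is required to simulate a sensorgram")
    times = np.arange(0.0, t_assoc + t_dissoc + dt / 2, dt)
    k_obs = kin.k_a * analyte_conc + kin.k_d
    r_eq = kin.k_a * analyte_conc * kin.r_max / k_obs
    assoc = times <= t_assoc
    resp = np.empty_like(times)
    resp[assoc] = r_eq * (1.0 - np.exp(-k_obs * times[assoc])) + bulk_shift
    r_end = r_eq * (1.0 - math.exp(-k_obs * t_assoc))
    resp[~assoc] = r_end * np.exp(-kin.k_d * (times[~assoc] - t_assoc))
    return Sensorgram(times=times, response=resp, conc=analyte_conc, t_assoc=t_assoc)
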