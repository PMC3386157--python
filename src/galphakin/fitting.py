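"""Rate-constant estimation from assay time courses.

Exponential association (GTPγS binding / Trp fluorescence), single-turnover
hydrolysis, steady-state initial-slope fitting, global 1:1 Langmuir SPR
fitting across an analyte dilution series, and the hyperbolic GAP
dose–response.  All nonlinear fits use damped least squares (lmfit) on the
analytic model functions with a small multi-start over log-spaced initial
rates; replicates are pooled into one residual vector rather than averaged.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import lmfit
import numpy as np

from .cycle import BindingKinetics, Sensorgram, TimeCourse
from .errors import FitError, ValidationError

__all__ = [
    "FitResult",
    "BindingKinetics",
    "SPRFitResult",
    "fit_exponential_association",
    "fit_single_turnover",
    "fit_steady_state_rate",
    "fit_spr_global",
    "fit_gap_dose_response",
    "kd_from_rates",
]


@dataclass
class FitResult:
    """Parameter estimates with standard errors from one least-squares fit."""

    params: dict[str, float]
    stderr: dict[str, float]
    residual_ss: float
    n_points: int
    converged: bool
    covariance: np.ndarray | None = None
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "params": dict(self.params),
            "se": dict(self.stderr),
            "n": self.n_points,
            "converged": self.converged,
            "residual_ss": self.residual_ss,
            "flags": list(self.flags),
        }


@dataclass
class SPRFitResult:
    """Global SPR fit outcome: shared kinetics, or a flagged non-binder."""

    kinetics: BindingKinetics | None
    non_binder: bool
    converged: bool
    residual_ss: float
    n_points: int
    stderr: dict[str, float] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)


def _pool(tcs: TimeCourse | Sequence[TimeCourse]) -> tuple[np.ndarray, np.ndarray, int]:
    """Pool one trace or a replicate list into sorted (t, y) residual inputs."""
    if isinstance(tcs, TimeCourse):
        tcs = [tcs]
    if not tcs:
        raise ValidationError("no time courses supplied")
    t = np.concatenate([tc.times for tc in tcs])
    y = np.concatenate([tc.values for tc in tcs])
    order = np.argsort(t, kind="stable")
    return t[order], y[order], len(tcs)


def _exp_assoc(t, plateau, rate):
    return plateau * (1.0 - np.exp(-rate * t))


def _initial_rate_guess(t: np.ndarray, y: np.ndarray) -> float:
    """k0 = ln 2 / (time of half-max signal); crude but robust."""
    ymax = float(np.max(y))
    above = np.nonzero(y >= 0.5 * ymax)[0]
    if len(above) and t[above[0]] > 0:
        return math.log(2.0) / float(t[above[0]])
    positive = t[t > 0]
    return 1.0 / float(positive[0]) if len(positive) else 1.0


def _fit_exponential(tcs, rate_name: str) -> FitResult:
    t, y, _ = _pool(tcs)
    if len(t) < 4:
        raise ValidationError(f"exponential fit needs >= 4 points, got {len(t)}")
    if np.allclose(y, y[0]):
        raise FitError("all signal values are equal; rate is unidentifiable")
    if np.max(np.abs(y)) == 0:
        raise FitError("all-zero signal; nothing to fit")

    model = lmfit.Model(_exp_assoc)
    k0 = _initial_rate_guess(t, y)
    ymax = float(np.max(y))
    best = None
    for k_start in (k0 / 5.0, k0, 5.0 * k0):
        params = model.make_params(plateau=ymax, rate=k_start)
        params["rate"].set(min=1e-12)
        params["plateau"].set(min=1e-12 * max(ymax, 1.0))
        try:
            res = model.fit(y, params, t=t)
        except Exception:  # singular steps on bad starts; try next start
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None:
        raise FitError("exponential fit failed from every initial guess")

    rate = float(best.params["rate"].value)
    plateau = float(best.params["plateau"].value)
    flags: list[str] = []
    converged = bool(best.success) and rate > 1e-10
    if not (0.5 * ymax <= plateau <= 2.0 * ymax):
        flags.append("plateau_outside_observed_range")
    stderr = {
        rate_name: float(best.params["rate"].stderr or np.nan),
        "plateau": float(best.params["plateau"].stderr or np.nan),
    }
    return FitResult(
        params={rate_name: rate, "plateau": plateau},
        stderr=stderr,
        residual_ss=float(best.chisqr),
        n_points=len(t),
        converged=converged,
        covariance=best.covar,
        flags=flags,
    )


def fit_exponential_association(tc: TimeCourse | Sequence[TimeCourse]) -> FitResult:
    """Fit B(t) = plateau·(1 − e^(−K_obs·t)) to a GTPγS binding or fluorescence trace."""
    return _fit_exponential(tc, "k_obs")


def fit_single_turnover(tc: TimeCourse | Sequence[TimeCourse]) -> FitResult:
    """Fit Pi(t) = p0·(1 − e^(−K_cat·t)) to a single-turnover hydrolysis trace."""
    return _fit_exponential(tc, "k_cat")


def fit_steady_state_rate(
    tc: TimeCourse | Sequence[TimeCourse],
    g_conc: float,
    substrate_fraction: float = 0.20,
) -> FitResult:
    """Per-Gα multi-turnover rate from the initial linear window of Pi accumulation.

    The window keeps points with cumulative Pi at most ``substrate_fraction``
    of the initial GTP pool (taken from ``meta['gtp0']`` when present, else
    all points are used).  An ordinary linear regression with intercept
    absorbs the brief pre-steady-state lag; the slope divided by ``g_conc``
    is the turnover in min⁻¹ per Gα.
    """
    if g_conc <= 0:
        raise ValidationError(f"g_conc must be > 0, got {g_conc}")
    traces = [tc] if isinstance(tc, TimeCourse) else list(tc)
    t, y, _ = _pool(traces)
    if y[-1] < y[0]:
        raise ValidationError("Pi values decrease over the trace; non-physical input")
    gtp0 = traces[0].meta.get("gtp0")
    if gtp0 is not None:
        mask = y <= substrate_fraction * float(gtp0)
    else:
        mask = np.ones_like(y, dtype=bool)
    if mask.sum() < 3:
        raise ValidationError(
            f"fewer than 3 points within the linear window (Pi <= "
            f"{substrate_fraction:.0%} of initial GTP)"
        )
    tw, yw = t[mask], y[mask]
    (slope, intercept), cov = np.polyfit(tw, yw, 1, cov=True)
    if slope <= 0:
        raise ValidationError("fitted Pi slope is non-positive; non-physical input")
    resid = yw - (slope * tw + intercept)
    return FitResult(
        params={"turnover": float(slope / g_conc), "slope": float(slope),
                "intercept": float(intercept)},
        stderr={"turnover": float(np.sqrt(cov[0, 0]) / g_conc),
                "slope": float(np.sqrt(cov[0, 0]))},
        residual_ss=float(np.sum(resid**2)),
        n_points=int(mask.sum()),
        converged=True,
        covariance=cov,
    )


def _langmuir_response(t, t_assoc, conc, k_a, k_d, r_max):
    k_obs = k_a * conc + k_d
    r_eq = k_a * conc * r_max / k_obs
    assoc = t <= t_assoc
    out = np.empty_like(t)
    out[assoc] = r_eq * (1.0 - np.exp(-k_obs * t[assoc]))
    r_end = r_eq * (1.0 - math.exp(-k_obs * t_assoc))
    out[~assoc] = r_end * np.exp(-k_d * (t[~assoc] - t_assoc))
    return out


def _estimate_noise_sd(series: Sequence[Sensorgram]) -> float:
    """High-frequency noise estimate from successive differences (MAD-based)."""
    diffs = np.concatenate([np.diff(s.response) for s in series if len(s.response) > 1])
    if len(diffs) == 0:
        return 0.0
    return float(np.median(np.abs(diffs - np.median(diffs))) / 0.6745 / math.sqrt(2.0))


def fit_spr_global(
    series: Sequence[Sensorgram],
    share_rmax: bool = True,
    noise_floor: float | None = None,
) -> SPRFitResult:
    """Globally fit a 1:1 Langmuir model across an SPR dilution series.

    One shared (k_a, k_d) pair — and by default one shared R_max — minimizes
    the pooled residuals over all sensorgrams.  A series whose maximal
    response stays below three times the noise SD is reported as a
    non-binder rather than fitted (the behaviour of a negative control
    analyte).  A single-concentration series is fitted but flagged, since
    k_a and k_d are then poorly separable.
    """
    series = list(series)
    if not series:
        raise ValidationError("empty sensorgram series")
    n_points = int(sum(len(s.times) for s in series))
    max_resp = max(float(np.max(np.abs(s.response))) for s in series)
    noise_sd = noise_floor if noise_floor is not None else _estimate_noise_sd(series)
    threshold = max(3.0 * noise_sd, 1e-6)
    if max_resp < threshold:
        return SPRFitResult(
            kinetics=None, non_binder=True, converged=True,
            residual_ss=float(sum(np.sum(s.response**2) for s in series)),
            n_points=n_points, flags=["below_noise_floor"],
        )

    flags: list[str] = []
    n_conc = len({s.conc for s in series})
    if n_conc < 2:
        warnings.warn("single analyte concentration: k_a/k_d are degenerate", stacklevel=2)
        flags.append("ka_kd_degenerate")

    kd0 = _initial_kd_guess(series)

    def residuals(p):
        out = []
        for i, s in enumerate(series):
            rmax = p["rmax"] if share_rmax else p[f"rmax_{i}"]
            model = _langmuir_response(
                s.times, s.t_assoc, s.conc, 10.0 ** p["log_ka"], 10.0 ** p["log_kd"], rmax
            )
            out.append(s.response - model)
        return np.concatenate(out)

    best = None
    for ka0 in (1e4, 1e5, 1e6):
        params = lmfit.Parameters()
        params.add("log_ka", value=math.log10(ka0), min=0.0, max=10.0)
        params.add("log_kd", value=math.log10(kd0), min=-8.0, max=2.0)
        if share_rmax:
            params.add("rmax", value=max_resp / 0.9, min=1e-6)
        else:
            for i in range(len(series)):
                params.add(f"rmax_{i}", value=max_resp / 0.9, min=1e-6)
        try:
            res = lmfit.minimize(residuals, params, method="leastsq")
        except Exception:
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None:
        raise FitError("SPR global fit failed from every initial guess")

    k_a = 10.0 ** float(best.params["log_ka"].value)
    k_d = 10.0 ** float(best.params["log_kd"].value)
    if share_rmax:
        r_max = float(best.params["rmax"].value)
    else:
        r_max = float(np.mean([best.params[f"rmax_{i}"].value for i in range(len(series))]))
        flags.append("per_curve_rmax")
    ln10 = math.log(10.0)
    stderr = {
        "k_a": k_a * ln10 * float(best.params["log_ka"].stderr or np.nan),
        "k_d": k_d * ln10 * float(best.params["log_kd"].stderr or np.nan),
    }
    return SPRFitResult(
        kinetics=BindingKinetics(k_a=k_a, k_d=k_d, r_max=r_max),
        non_binder=False,
        converged=bool(best.success),
        residual_ss=float(best.chisqr),
        n_points=n_points,
        stderr=stderr,
        flags=flags,
    )


def _initial_kd_guess(series: Sequence[Sensorgram]) -> float:
    """k_d from a log-linear fit to the dissociation tail of the strongest curve."""
    s = max(series, key=lambda s: float(np.max(np.abs(s.response))))
    mask = (s.times > s.t_assoc) & (s.response > 1e-9)
    if mask.sum() >= 3:
        slope = np.polyfit(s.times[mask], np.log(s.response[mask]), 1)[0]
        if slope < 0:
            return float(np.clip(-slope, 1e-7, 10.0))
    return 1e-2


def _gap_hyperbola(x, k_cat, k_gap_max, k_half_gap):
    return k_cat + k_gap_max * x / (k_half_gap + x)


def fit_gap_dose_response(
    rates: Iterable[tuple[float, float]],
    insensitive_fraction: float = 0.10,
) -> FitResult:
    """Fit k_obs([RGS]) = k_cat + k_gap_max·[RGS]/(k_half_gap + [RGS]).

    Requires at least four dose points including a zero dose (which anchors
    k_cat).  A fitted k_gap_max below ``insensitive_fraction`` of k_cat
    flags the protein as RGS-insensitive (GAP addition does not accelerate
    hydrolysis, the behaviour of a Gα whose intrinsic hydrolysis is already
    fast).
    """
    pts = sorted((float(c), float(k)) for c, k in rates)
    if len(pts) < 4:
        raise ValidationError(f"GAP dose-response fit needs >= 4 points, got {len(pts)}")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if x.min() < 0:
        raise ValidationError("RGS concentrations must be >= 0")
    if not np.any(x == 0):
        raise ValidationError("a zero-dose point is required (k_cat unidentifiable without it)")

    k_cat0 = float(np.mean(y[x == 0]))
    span = max(float(y.max() - k_cat0), 1e-9)
    pos = x[x > 0]
    model = lmfit.Model(_gap_hyperbola)
    best = None
    for khalf0 in (float(pos.min()), float(np.median(pos)), float(pos.max())):
        params = model.make_params(k_cat=max(k_cat0, 1e-9), k_gap_max=span, k_half_gap=khalf0)
        params["k_cat"].set(min=0.0)
        params["k_gap_max"].set(min=0.0)
        params["k_half_gap"].set(min=1e-9)
        try:
            res = model.fit(y, params, x=x)
        except Exception:
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None:
        raise FitError("GAP dose-response fit failed from every initial guess")

    k_cat = float(best.params["k_cat"].value)
    k_gap_max = float(best.params["k_gap_max"].value)
    flags = []
    if k_gap_max < max(insensitive_fraction * k_cat, 1e-9):
        flags.append("rgs_insensitive")
    return FitResult(
        params={
            "k_cat": k_cat,
            "k_gap_max": k_gap_max,
            "k_half_gap": float(best.params["k_half_gap"].value),
        },
        stderr={
            name: float(best.params[key].stderr or np.nan)
            for name, key in (("k_cat", "k_cat"), ("k_gap_max", "k_gap_max"),
                              ("k_half_gap", "k_half_gap"))
        },
        residual_ss=float(best.chisqr),
        n_points=len(pts),
        converged=bool(best.success),
        covariance=best.covar,
        flags=flags,
    )


def kd_from_rates(k_a: float, k_d: float) -> float:
    """Equilibrium dissociation constant K_D = k_d / k_a (M)."""
    if k_a <= 0:
        raise ValidationError(f"k_a must be > 0, got {k_a}")
    return k_d / k_a
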