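"""Derived statistics and per-protein regulatory profiles.

From fitted rate constants this module computes the quantities that
summarize how a Gα subunit is regulated: the steady-state percent of
GTP-occupied protein, the rate-limiting step of the cycle, whether the
protein is self-activating (exchange faster than hydrolysis, so it needs no
GEF) or GEF-dependent (the animal paradigm), how strongly a GAP accelerates
its steady-state turnover, and fold-changes in RGS affinity between
wild-type and switch-I variants.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

from .cycle import RateConstants, fraction_gtp_bound, percent_gtp_bound, round_half_up
from .errors import ValidationError

__all__ = [
    "GAlphaProfile",
    "FoldChange",
    "rate_limiting_step",
    "classify_activation",
    "gap_fold_acceleration",
    "affinity_fold_change",
    "build_profile",
]

#: rates within this relative band of each other are called "balanced"
BALANCED_BAND = 0.05

#: k_cat at or above this (min⁻¹) marks a Gα that inactivates itself quickly
SELF_INACTIVATING_KCAT = 0.5

#: fold-acceleration at or above this counts as GAP (RGS) stimulation
RGS_STIMULATED_FOLD = 1.5


@dataclass
class FoldChange:
    """Affinity or rate fold-change, exact and integer-rounded as reported."""

    ratio: float  # kd_variant / kd_ref; >1 means weakened affinity
    fold: int  # integer-rounded magnitude (of the ratio or its inverse)
    direction: str  # "weakened" | "strengthened" | "unchanged"

    @property
    def label(self) -> str:
        if self.direction == "unchanged":
            return "unchanged"
        verb = "decrease" if self.direction == "weakened" else "increase"
        return f"{self.fold}-fold {verb} in affinity"


@dataclass
class GAlphaProfile:
    """Assembled kinetic/regulatory record for one Gα protein."""

    name: str
    k_obs_binding: float  # min⁻¹
    k_cat: float  # min⁻¹
    k_obs_fluorescence: float | None = None
    kd_rgs: float | None = None  # M
    pct_gtp_bound: int = 0
    rate_limiting: str = ""
    activation_class: str = ""
    self_inactivating: bool = False
    gap_fold: float | None = None
    rgs_stimulated: bool | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def rate_limiting_step(k_exchange: float, k_cat: float) -> str:
    """Name the slower step of the cycle: "exchange", "hydrolysis" or "balanced".

    Rates within ``BALANCED_BAND`` (5%) of each other are balanced; outside
    the band the slower rate names the limiting step.
    """
    if k_exchange <= 0 or k_cat <= 0:
        raise ValidationError("both rates must be > 0 to determine the rate-limiting step")
    if min(k_exchange, k_cat) / max(k_exchange, k_cat) >= 1.0 - BALANCED_BAND:
        return "balanced"
    return "hydrolysis" if k_cat < k_exchange else "exchange"


def classify_activation(profile: GAlphaProfile) -> tuple[str, bool]:
    """Activation class plus self-inactivating flag.

    Self-activating iff hydrolysis is rate limiting (exchange outpaces
    hydrolysis, so active protein accumulates without a GEF); otherwise
    GEF-dependent, the animal regime.  The self-inactivating flag marks a
    hydrolysis rate fast enough (>= 0.5 min⁻¹) to reset the protein quickly
    without a GAP.
    """
    if profile.k_obs_binding is None or profile.k_cat is None:
        raise ValidationError("profile must carry both k_obs_binding and k_cat")
    limiting = rate_limiting_step(profile.k_obs_binding, profile.k_cat)
    activation = "self_activating" if limiting == "hydrolysis" else "gef_dependent"
    return activation, profile.k_cat >= SELF_INACTIVATING_KCAT


def gap_fold_acceleration(v_minus: float, v_plus: float) -> tuple[float, bool]:
    """Steady-state fold-acceleration by GAP and whether it counts as stimulation."""
    if v_minus <= 0:
        raise ValidationError(f"v_minus must be > 0, got {v_minus}")
    ratio = v_plus / v_minus
    return ratio, ratio >= RGS_STIMULATED_FOLD


def affinity_fold_change(kd_ref: float, kd_variant: float) -> FoldChange:
    """K_D fold-change of a variant versus reference (ratio > 1 = weakened)."""
    if kd_ref <= 0 or kd_variant <= 0:
        raise ValidationError("K_D values must be > 0")
    ratio = kd_variant / kd_ref
    if ratio == 1.0:
        return FoldChange(ratio=1.0, fold=1, direction="unchanged")
    magnitude = ratio if ratio > 1 else 1.0 / ratio
    return FoldChange(
        ratio=ratio,
        fold=round_half_up(magnitude),
        direction="weakened" if ratio > 1 else "strengthened",
    )


def build_profile(
    name: str,
    k_obs_binding: float | None = None,
    k_cat: float | None = None,
    k_obs_fluorescence: float | None = None,
    kd_rgs: float | None = None,
    v_minus: float | None = None,
    v_plus: float | None = None,
) -> GAlphaProfile:
    """Assemble a full profile from fitted constants, deriving every
    computable field.  Both k_obs_binding and k_cat are mandatory."""
    missing = [n for n, v in (("k_obs_binding", k_obs_binding), ("k_cat", k_cat)) if v is None]
    if missing:
        raise ValidationError(f"cannot build profile for {name!r}: missing {', '.join(missing)}")
    rc = RateConstants(k_exchange=k_obs_binding, k_cat=k_cat)
    profile = GAlphaProfile(
        name=name,
        k_obs_binding=k_obs_binding,
        k_cat=k_cat,
        k_obs_fluorescence=k_obs_fluorescence,
        kd_rgs=kd_rgs,
        pct_gtp_bound=percent_gtp_bound(rc),
        rate_limiting=rate_limiting_step(k_obs_binding, k_cat),
    )
    profile.activation_class, profile.self_inactivating = classify_activation(profile)
    if v_minus is not None and v_plus is not None:
        profile.gap_fold, profile.rgs_stimulated = gap_fold_acceleration(v_minus, v_plus)
    # exact fraction kept alongside the rounded percent for downstream use
    profile_fraction = fraction_gtp_bound(rc)
    assert 0.0 <= profile_fraction <= 1.0
    return profile
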