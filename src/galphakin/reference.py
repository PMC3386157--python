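"""Published in-vitro constants for representative plant Gα proteins.

These are literature-reported measurements at 20°C for an informative set of
plant Gα subunits spanning the plant kingdom — a eudicot (Arabidopsis
AtGPA1), a grass (rice OsRGA1), a gymnosperm (pine PtGα1) and a liverwort
(Marchantia MpGα1) — plus the reciprocal switch-I point mutants
AtGPA1-T194N and OsRGA1-N195T.  They serve as inputs for simulations,
round-trip fitting checks and profile assembly; every derived quantity
(percent GTP-bound, rate-limiting step, fold-changes) is computed by the
package, never stored here.
"""

from __future__ import annotations

from .cycle import BindingKinetics, RateConstants

__all__ = [
    "NUCLEOTIDE_CYCLE_RATES",
    "FLUORESCENCE_EXCHANGE_RATES",
    "EXCHANGE_ONLY_RATES",
    "RGS1_BINDING_KINETICS",
    "STEADY_STATE_RATES",
    "SPECIFIC_ACTIVITIES",
    "SPR_CONCENTRATIONS_NM",
    "SPR_T_ASSOC_S",
    "SPR_T_DISSOC_S",
]

#: apparent GTPγS-binding (exchange) and single-turnover hydrolysis rates, min⁻¹
NUCLEOTIDE_CYCLE_RATES: dict[str, RateConstants] = {
    "AtGPA1": RateConstants(k_exchange=5.80, k_cat=0.047),
    "AtGPA1-T194N": RateConstants(k_exchange=6.97, k_cat=0.059),
    "OsRGA1": RateConstants(k_exchange=0.92, k_cat=0.052),
    "OsRGA1-N195T": RateConstants(k_exchange=0.70, k_cat=0.051),
    "MpGa1": RateConstants(k_exchange=1.84, k_cat=0.87),
}

#: exchange rates measured independently via intrinsic Trp fluorescence, min⁻¹
FLUORESCENCE_EXCHANGE_RATES: dict[str, float] = {
    "AtGPA1": 3.63,
    "OsRGA1": 2.38,
    "MpGa1": 4.09,
}

#: proteins with only the exchange rate measured (hydrolysis not determined)
EXCHANGE_ONLY_RATES: dict[str, float] = {"PtGa1": 6.85}

#: SPR 1:1 Langmuir constants against the immobilized AtRGS1 RGS domain.
#: R_max is surface-specific and not part of the published constants; a
#: nominal 100 RU capacity is used when simulating sensorgrams.
RGS1_BINDING_KINETICS: dict[str, BindingKinetics] = {
    "AtGPA1": BindingKinetics(k_a=3.53e5, k_d=6.16e-3, r_max=100.0),
    "AtGPA1-T194N": BindingKinetics(k_a=1.17e5, k_d=1.34e-2, r_max=100.0),
    "OsRGA1": BindingKinetics(k_a=3.83e5, k_d=2.17e-2, r_max=100.0),
    "OsRGA1-N195T": BindingKinetics(k_a=1.21e6, k_d=5.84e-3, r_max=100.0),
}

#: steady-state GTP hydrolysis per Gα, min⁻¹, without / with 750 nM AtRGS1
STEADY_STATE_RATES: dict[str, tuple[float, float]] = {
    "AtGPA1": (0.025, 0.503),
    "AtGPA1-T194N": (0.031, 0.158),
    "OsRGA1": (0.019, 0.127),
    "OsRGA1-N195T": (0.031, 0.288),
    "MpGa1": (1.06, 1.13),
}

#: active fraction of the purified preparations (mol GTPγS bound / mol protein)
SPECIFIC_ACTIVITIES: dict[str, float] = {
    "AtGPA1": 0.46,
    "OsRGA1": 0.55,
    "MpGa1": 0.69,
}

#: analyte dilution series and phase durations used in the SPR experiments
SPR_CONCENTRATIONS_NM: tuple[float, ...] = (6.25, 12.5, 25.0, 50.0, 100.0, 200.0, 400.0)
SPR_T_ASSOC_S: float = 180.0
SPR_T_DISSOC_S: float = 300.0
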