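"""Seeded synthetic datasets for every assay and sequence analysis.

Every generator is deterministic under a fixed seed and reduces to the
corresponding closed-form model in the noiseless limit, so that each
simulator/fitter pair round-trips exactly.  Default noise magnitudes mirror
the scatter typical of the underlying instruments: 3% multiplicative
Gaussian for scintillation-counted binding/hydrolysis traces and 0.5 RU
additive Gaussian for SPR.

The bundled Gα reference sequences are deterministic synthetic stand-ins
(no real accession is reproduced here): they place the switch-I coupling
determinant at reference position 194 (Thr) and, in the rice-like variant,
at query position 195 (Asn), matching the positional geometry of the
Arabidopsis/rice pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from Bio.Data import CodonTable

from .cycle import (
    BindingKinetics,
    CyclePools,
    RateConstants,
    Sensorgram,
    TimeCourse,
    gap_hydrolysis_rate,
    gtpgs_binding_curve,
    single_turnover_curve,
    spr_sensorgram,
    turnover_ode,
)
from .errors import ValidationError
from .seqdet import ProteinRecord
from .reference import SPR_CONCENTRATIONS_NM, SPR_T_ASSOC_S, SPR_T_DISSOC_S

__all__ = [
    "NoiseModel",
    "GalphaFamily",
    "gen_gtpgs_binding",
    "gen_single_turnover",
    "gen_steady_state",
    "gen_spr_series",
    "gen_galpha_family",
    "synthetic_reference_galpha",
    "synthetic_grass_galpha",
    "default_times",
    "DETERMINANT_POSITION",
]

#: 1-based switch-I determinant position on the bundled reference
DETERMINANT_POSITION = 194

_REFERENCE_LENGTH = 380


@dataclass(frozen=True)
class NoiseModel:
    """Seeded Gaussian noise: multiplicative (sd as fraction) or additive (sd in signal units)."""

    kind: str = "multiplicative_gaussian"
    sd: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("multiplicative_gaussian", "additive_gaussian"):
            raise ValidationError(f"unknown noise kind {self.kind!r}")
        if self.sd < 0:
            raise ValidationError(f"noise sd must be >= 0, got {self.sd}")

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.sd == 0:
            return values.copy()
        eps = rng.normal(0.0, self.sd, size=values.shape)
        if self.kind == "multiplicative_gaussian":
            return values * (1.0 + eps)
        return values + eps


def default_times(rate: float, n_points: int | None = None) -> np.ndarray:
    """Sampling grid adapted to the dynamic range of a first-order process.

    The grid covers ~5 half-lives (capped at 60 min, the practical length of
    these assays): fast processes (>= 1 min⁻¹) get 10 log-spaced points,
    slower ones 12 linear points, so the rising phase is always resolved.
    """
    if rate <= 0:
        raise ValidationError(f"rate must be > 0, got {rate}")
    t_end = min(5.0 * math.log(2.0) / rate, 60.0)
    if rate >= 1.0:
        n = n_points or 10
        return np.logspace(math.log10(t_end / 50.0), math.log10(t_end), n)
    n = n_points or 12
    return np.linspace(t_end / n, t_end, n)


def _noisy_replicates(
    base: TimeCourse, noise: NoiseModel | None, replicates: int
) -> list[TimeCourse]:
    if replicates < 1:
        raise ValidationError(f"replicates must be >= 1, got {replicates}")
    if noise is None:
        noise = NoiseModel(sd=0.0)
    rng = np.random.default_rng(noise.seed)
    out = []
    for rep in range(replicates):
        values = noise.apply(base.values, rng)
        meta = dict(base.meta, replicate=rep, noise_sd=noise.sd, noise_kind=noise.kind,
                    seed=noise.seed)
        out.append(TimeCourse(base.times.copy(), values, base.assay_kind, meta))
    return out


def gen_gtpgs_binding(
    rc: RateConstants,
    g_conc: float,
    specific_activity: float,
    times,
    noise: NoiseModel | None = None,
    replicates: int = 1,
) -> list[TimeCourse]:
    """Synthetic GTPγS association traces; plateau = g_conc × specific_activity (nM)."""
    if specific_activity < 0:
        raise ValidationError(f"specific_activity must be >= 0, got {specific_activity}")
    base = gtpgs_binding_curve(rc, g_conc * specific_activity, times)
    base.meta.update(g_conc=g_conc, specific_activity=specific_activity)
    return _noisy_replicates(base, noise, replicates)


def gen_single_turnover(
    rc: RateConstants,
    g_conc: float,
    times,
    noise: NoiseModel | None = None,
    replicates: int = 1,
    specific_activity: float = 1.0,
) -> list[TimeCourse]:
    """Synthetic single-turnover Pi-release traces from GTP-preloaded Gα."""
    if specific_activity < 0:
        raise ValidationError(f"specific_activity must be >= 0, got {specific_activity}")
    base = single_turnover_curve(rc, g_conc * specific_activity, times)
    base.meta.update(g_conc=g_conc, specific_activity=specific_activity)
    return _noisy_replicates(base, noise, replicates)


def gen_steady_state(
    rc: RateConstants,
    g_conc: float,
    gtp0: float,
    times,
    rgs_conc: float = 0.0,
    noise: NoiseModel | None = None,
) -> TimeCourse:
    """Multi-turnover Pi accumulation (nM) under a finite GTP pool.

    The observed hydrolysis rate includes GAP acceleration when
    ``rgs_conc > 0`` (requires GAP parameters on ``rc``).  Before
    appreciable substrate depletion the Pi slope equals the two-step series
    turnover times the Gα concentration.
    """
    if gtp0 <= g_conc:
        raise ValidationError(
            f"multi-turnover needs excess GTP: gtp0 ({gtp0}) must exceed g_conc ({g_conc})"
        )
    k_cat_eff = gap_hydrolysis_rate(rc, rgs_conc)
    rc_eff = RateConstants(k_exchange=rc.k_exchange, k_cat=k_cat_eff)
    pools0 = CyclePools(g_total=g_conc, g_gtp=0.0, free_gtp=gtp0, free_gdp=0.0)
    traj = turnover_ode(rc_eff, pools0, np.asarray(times, dtype=float))
    base = TimeCourse(
        traj.times,
        traj.pi,
        "steady_state",
        {
            "g_conc": g_conc,
            "gtp0": gtp0,
            "rgs_conc": rgs_conc,
            "k_cat_effective": k_cat_eff,
            "k_exchange": rc.k_exchange,
        },
    )
    return _noisy_replicates(base, noise, 1)[0]


def gen_spr_series(
    kin: BindingKinetics,
    concs_nm=SPR_CONCENTRATIONS_NM,
    t_assoc: float = SPR_T_ASSOC_S,
    t_dissoc: float = SPR_T_DISSOC_S,
    dt: float = 1.0,
    noise: NoiseModel | None = None,
) -> list[Sensorgram]:
    """Synthetic sensorgram dilution series (concentrations in nM).

    SPR noise is additive in RU; the default series covers 6.25–400 nM with
    3 min association and 5 min dissociation.
    """
    if noise is None:
        noise = NoiseModel(kind="additive_gaussian", sd=0.0)
    rng = np.random.default_rng(noise.seed)
    out = []
    for c_nm in concs_nm:
        s = spr_sensorgram(kin, c_nm * 1e-9, t_assoc, t_dissoc, dt)
        out.append(
            Sensorgram(s.times, noise.apply(s.response, rng), s.conc, s.t_assoc)
        )
    return out


# ---------------------------------------------------------------------------
# Synthetic Gα sequence family
# ---------------------------------------------------------------------------

_AA = "ACDEFGHIKLMNPQRSTVWY"
_BACK_TABLE: dict[str, list[str]] = {}
for _codon, _aa in CodonTable.unambiguous_dna_by_id[1].forward_table.items():
    _BACK_TABLE.setdefault(_aa, []).append(_codon)


def synthetic_reference_galpha() -> ProteinRecord:
    """Deterministic synthetic stand-in for a eudicot-type Gα reference.

    380 residues drawn reproducibly from a fixed-seed generator, with the
    canonical P-loop motif embedded near the N terminus and Thr placed at
    the switch-I determinant (position 194).  This is a constructed
    sequence, not a database record.
    """
    rng = np.random.default_rng(20120628)
    seq = list(rng.choice(list(_AA), size=_REFERENCE_LENGTH))
    ploop = "GAGESGKST"
    seq[35 : 35 + len(ploop)] = list(ploop)
    seq[DETERMINANT_POSITION - 1] = "T"
    return ProteinRecord(id="synthetic_AtGPA1_like", sequence="".join(seq))


def synthetic_grass_galpha() -> ProteinRecord:
    """Deterministic synthetic stand-in for a grass-type Gα.

    Derived from :func:`synthetic_reference_galpha` by a handful of seeded
    substitutions plus a single-residue insertion upstream of switch I, so
    the determinant site maps to position 195 and carries Asn — the
    positional geometry of the rice/Arabidopsis pair.
    """
    ref = list(synthetic_reference_galpha().sequence)
    rng = np.random.default_rng(20120629)
    for i in rng.choice(_REFERENCE_LENGTH, size=12, replace=False):
        if abs(int(i) - (DETERMINANT_POSITION - 1)) <= 5 or 30 <= int(i) <= 45:
            continue
        ref[int(i)] = _AA[int(rng.integers(len(_AA)))]
    ref.insert(99, "A")  # shifts the determinant from 194 to 195
    ref[DETERMINANT_POSITION] = "N"  # index 194 == 1-based 195 after insertion
    return ProteinRecord(id="synthetic_OsRGA1_like", sequence="".join(ref))


def back_translate(protein: str, rng: np.random.Generator) -> str:
    """Coding sequence with synonymous codons drawn uniformly under the seed."""
    codons = []
    for aa in protein:
        options = _BACK_TABLE.get(aa.upper())
        if options is None:
            raise ValidationError(f"cannot back-translate residue {aa!r}")
        codons.append(options[int(rng.integers(len(options)))])
    return "".join(codons)


@dataclass
class GalphaFamily:
    """Synthetic Gα family with per-member ground truth for the determinant."""

    proteins: list[ProteinRecord]
    cds: dict[str, str]
    grass_ids: set[str]


def gen_galpha_family(
    n: int, grass_fraction: float, mutation_rate: float, seed: int
) -> GalphaFamily:
    """Generate ``n`` variants of the bundled reference with exactly
    ``round(n·grass_fraction)`` members carrying Asn at the determinant site
    (the rest keep Thr), random substitutions elsewhere at ``mutation_rate``
    per site, and seeded back-translated coding sequences."""
    if not 0.0 <= grass_fraction <= 1.0:
        raise ValidationError(f"grass_fraction must be in [0, 1], got {grass_fraction}")
    if not 0.0 <= mutation_rate <= 0.2:
        raise ValidationError(
            f"mutation_rate must be in [0, 0.2] for reliable alignment, got {mutation_rate}"
        )
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    ref = synthetic_reference_galpha().sequence
    rng = np.random.default_rng(seed)
    n_grass = round(n * grass_fraction)
    proteins: list[ProteinRecord] = []
    cds: dict[str, str] = {}
    grass_ids: set[str] = set()
    for i in range(n):
        is_grass = i < n_grass
        seq = list(ref)
        for pos in range(len(seq)):
            if pos == DETERMINANT_POSITION - 1:
                continue
            if rng.random() < mutation_rate:
                seq[pos] = _AA[int(rng.integers(len(_AA)))]
        seq[DETERMINANT_POSITION - 1] = "N" if is_grass else "T"
        label = "grass" if is_grass else "nongrass"
        rec = ProteinRecord(id=f"synth_galpha_{i:03d}_{label}", sequence="".join(seq))
        proteins.append(rec)
        cds[rec.id] = back_translate(rec.sequence, rng)
        if is_grass:
            grass_ids.add(rec.id)
    return GalphaFamily(proteins=proteins, cds=cds, grass_ids=grass_ids)
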