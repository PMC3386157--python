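"""Switch-I RGS-coupling determinant scanning and domain-wise dN/dS.

The switch-I threonine of eudicot-type Gα proteins (position 194 in the
Arabidopsis AtGPA1 numbering) sits at the centre of the Gα–RGS interface.
Grass Gα subunits carry asparagine at the homologous site (position 195 in
rice OsRGA1), which weakens RGS coupling; animal Gα12/13 carry lysine there
and use dedicated RH-domain effectors instead of classical RGS GAPs.  This
module maps that determinant from a reference onto query sequences through a
global protein alignment and classifies the aligned residue.

It also provides a pathway-counting dN/dS (Nei–Gojobori 1986 with
Jukes–Cantor correction) over named codon regions of a pairwise coding
alignment, used to compare selective constraint between protein domains
(e.g. a 7TM region versus an RGS domain).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable

from .errors import ValidationError

__all__ = [
    "ProteinRecord",
    "AlignmentResult",
    "SwitchICall",
    "CodonAlignment",
    "DnDsResult",
    "global_align",
    "switch1_residue",
    "nei_gojobori_dnds",
    "classify_determinant",
]

logger = logging.getLogger(__name__)

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")

#: switch-I residue classes keyed by amino acid at the mapped determinant site
DETERMINANT_CLASSES = {
    "T": "rgs_couplable",
    "S": "rgs_couplable",  # conservative substitution at the H-bonding site
    "N": "grass_uncoupled",
    "K": "g12_like",
}

GAP_OPEN = -10.0
GAP_EXTEND = -0.5

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence in IUPAC one-letter code (20 amino acids + X)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"sequence {self.id!r} is empty")
        for i, aa in enumerate(self.sequence):
            if aa.upper() not in AA_ALPHABET:
                raise ValidationError(
                    f"illegal character {aa!r} at position {i + 1} in sequence {self.id!r}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class AlignmentResult:
    """Global alignment of query against reference with position mapping."""

    reference_id: str
    query_id: str
    score: float
    aligned_reference: str
    aligned_query: str
    # list of ((ref_start, ref_end), (query_start, query_end)) 0-based blocks
    blocks: list[tuple[tuple[int, int], tuple[int, int]]]

    def map_ref_to_query(self, ref_position: int) -> int | None:
        """Map a 1-based reference position to the 1-based query position
        aligned to it, or None if the site falls in a gap."""
        p = ref_position - 1
        for (rs, re), (qs, _qe) in self.blocks:
            if rs <= p < re:
                return qs + (p - rs) + 1
        return None

    def map_query_to_ref(self, query_position: int) -> int | None:
        p = query_position - 1
        for (rs, _re), (qs, qe) in self.blocks:
            if qs <= p < qe:
                return rs + (p - qs) + 1
        return None


@dataclass
class SwitchICall:
    """Determinant call for one query sequence at a reference switch-I site."""

    query_id: str
    ref_position: int
    query_position: int | None
    residue: str  # one-letter amino acid, or "-" when unaligned
    coupling_class: str

    def to_dict(self) -> dict:
        return {
            "query_id": self.query_id,
            "ref_position": self.ref_position,
            "query_position": self.query_position,
            "residue": self.residue,
            "coupling_class": self.coupling_class,
        }


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


def global_align(query: ProteinRecord, reference: ProteinRecord) -> AlignmentResult:
    """Needleman–Wunsch optimal global alignment under BLOSUM62 with affine
    gaps (open 10, extend 0.5).  The first optimal alignment in Biopython's
    deterministic traversal order is returned, so repeated calls are
    reproducible."""
    aligner = _make_aligner()
    alignments = aligner.align(reference.sequence.upper(), query.sequence.upper())
    aln = alignments[0]
    ref_blocks, query_blocks = aln.aligned
    blocks = [
        ((int(rs), int(re)), (int(qs), int(qe)))
        for (rs, re), (qs, qe) in zip(ref_blocks, query_blocks)
    ]
    gapped_ref, gapped_query = str(aln[0]), str(aln[1])
    return AlignmentResult(
        reference_id=reference.id,
        query_id=query.id,
        score=float(aln.score),
        aligned_reference=gapped_ref,
        aligned_query=gapped_query,
        blocks=blocks,
    )


def classify_determinant(residue: str | None) -> str:
    """Class for the residue found at the mapped switch-I site."""
    if residue is None or residue == "-":
        return "unaligned"
    return DETERMINANT_CLASSES.get(residue.upper(), "other")


def switch1_residue(
    query: ProteinRecord, reference: ProteinRecord, ref_position: int = 194
) -> SwitchICall:
    """Map ``ref_position`` (1-based on the reference) through a global
    alignment and classify the aligned query residue."""
    if not 1 <= ref_position <= len(reference):
        raise ValidationError(
            f"ref_position {ref_position} is outside reference {reference.id!r} "
            f"(length {len(reference)})"
        )
    aln = global_align(query, reference)
    qpos = aln.map_ref_to_query(ref_position)
    residue = query.sequence[qpos - 1].upper() if qpos is not None else "-"
    return SwitchICall(
        query_id=query.id,
        ref_position=ref_position,
        query_position=qpos,
        residue=residue,
        coupling_class=classify_determinant(residue if qpos is not None else None),
    )


# ---------------------------------------------------------------------------
# Nei–Gojobori dN/dS
# ---------------------------------------------------------------------------

_BASES = "TCAG"


def _translate(codon: str) -> str | None:
    """Amino acid for a codon, or None for a stop codon."""
    if codon in _STANDARD_TABLE.stop_codons:
        return None
    return _STANDARD_TABLE.forward_table[codon]


def _codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts for one codon.

    Each position contributes the fraction of its three possible base
    changes that preserve the encoded amino acid; changes creating a stop
    codon count as nonsynonymous so that S + N = 3 exactly.
    """
    aa = _translate(codon)
    s = 0.0
    for pos in range(3):
        syn = 0
        for base in _BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if _translate(alt) == aa and aa is not None:
                syn += 1
        s += syn / 3.0
    return s, 3.0 - s


def _codon_differences(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) difference counts for one codon pair,
    averaged with equal weight over all minimal substitution pathways.

    Pathways passing through a stop codon are excluded; if every pathway is
    blocked the average falls back to all pathways with stop-codon steps
    counted as nonsynonymous.
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0

    def walk(order) -> tuple[float, float, bool]:
        syn = non = 0.0
        current = c1
        through_stop = False
        for pos in order:
            nxt = current[:pos] + c2[pos] + current[pos + 1 :]
            aa_from, aa_to = _translate(current), _translate(nxt)
            if aa_to is None or aa_from is None:
                through_stop = True
                non += 1.0
            elif aa_from == aa_to:
                syn += 1.0
            else:
                non += 1.0
            current = nxt
        return syn, non, through_stop

    paths = [walk(order) for order in itertools.permutations(diff_pos)]
    clean = [(s, n) for s, n, stop in paths if not stop]
    pool = clean if clean else [(s, n) for s, n, _ in paths]
    syn = sum(p[0] for p in pool) / len(pool)
    non = sum(p[1] for p in pool) / len(pool)
    return syn, non


def _jukes_cantor(p: float) -> float | None:
    """d = −3/4·ln(1 − 4p/3); None when p >= 3/4 (correction undefined)."""
    if p >= 0.75:
        return None
    d = -0.75 * math.log(1.0 - 4.0 * p / 3.0)
    return 0.0 if d == 0.0 else d


@dataclass
class CodonAlignment:
    """Pair of aligned coding sequences (gaps in multiples of 3, aligned
    codon-wise) with optional named 1-based codon domain ranges."""

    seq1: str
    seq2: str
    domain_ranges: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.seq1 = self.seq1.upper().replace("U", "T")
        self.seq2 = self.seq2.upper().replace("U", "T")
        if len(self.seq1) != len(self.seq2):
            raise ValidationError("aligned coding sequences must have equal length")
        if len(self.seq1) % 3:
            raise ValidationError("aligned length must be divisible by 3")
        for name, seq in (("seq1", self.seq1), ("seq2", self.seq2)):
            ungapped = seq.replace("-", "")
            codons = [ungapped[i : i + 3] for i in range(0, len(ungapped) - 2, 3)]
            internal = codons[:-1]
            stops = [c for c in internal if c in _STANDARD_TABLE.stop_codons]
            if stops:
                raise ValidationError(f"internal stop codon {stops[0]} in {name}")
        for name, (start, end) in self.domain_ranges.items():
            if not (1 <= start <= end <= self.n_codons):
                raise ValidationError(
                    f"domain {name!r} range ({start}, {end}) outside alignment "
                    f"of {self.n_codons} codons"
                )

    @property
    def n_codons(self) -> int:
        return len(self.seq1) // 3

    def codon_pairs(self, region: str | None = None):
        if region is not None:
            if region not in self.domain_ranges:
                raise ValidationError(
                    f"region {region!r} not defined; known: {sorted(self.domain_ranges)}"
                )
            start, end = self.domain_ranges[region]
        else:
            start, end = 1, self.n_codons
        for i in range(start - 1, end):
            yield self.seq1[3 * i : 3 * i + 3], self.seq2[3 * i : 3 * i + 3]


@dataclass
class DnDsResult:
    """Nei–Gojobori estimates for one region of a codon alignment."""

    dN: float | None
    dS: float | None
    ratio: float | None  # dN/dS; inf when dS == 0 and dN > 0; None when undefined
    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float
    codons_used: int
    codons_skipped: int
    flags: list[str] = field(default_factory=list)


def nei_gojobori_dnds(aln: CodonAlignment, region: str | None = None) -> DnDsResult:
    """Pathway-counting dN/dS with Jukes–Cantor correction over one region.

    Codon columns containing gaps, stop codons or ambiguous bases are
    skipped (skips are counted and logged).  Per-codon site counts are
    averaged between the two sequences; differences are averaged with equal
    weight over all minimal substitution pathways.
    """
    S = N = Sd = Nd = 0.0
    used = skipped = 0
    for c1, c2 in aln.codon_pairs(region):
        if "-" in c1 or "-" in c2 or not set(c1 + c2) <= set(_BASES):
            skipped += 1
            continue
        if c1 in _STANDARD_TABLE.stop_codons or c2 in _STANDARD_TABLE.stop_codons:
            skipped += 1
            continue
        s1, n1 = _codon_sites(c1)
        s2, n2 = _codon_sites(c2)
        S += (s1 + s2) / 2.0
        N += (n1 + n2) / 2.0
        sd, nd = _codon_differences(c1, c2)
        Sd += sd
        Nd += nd
        used += 1
    if skipped:
        logger.info("nei_gojobori_dnds: skipped %d gapped/ambiguous codon columns", skipped)
    flags: list[str] = []
    if used == 0 or S == 0 or N == 0:
        return DnDsResult(None, None, None, S, N, Sd, Nd, used, skipped, ["no_usable_codons"])

    pS, pN = Sd / S, Nd / N
    dS, dN = _jukes_cantor(pS), _jukes_cantor(pN)
    if dS is None:
        flags.append("dS_correction_undefined")
    if dN is None:
        flags.append("dN_correction_undefined")
    ratio: float | None
    if dS is None or dN is None:
        ratio = None
    elif dS == 0.0 and dN == 0.0:
        ratio = None
        flags.append("ratio_undefined_no_substitutions")
    elif dS == 0.0:
        ratio = math.inf
        flags.append("ratio_infinite_dS_zero")
    else:
        ratio = dN / dS
    return DnDsResult(dN, dS, ratio, S, N, Sd, Nd, used, skipped, flags)
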