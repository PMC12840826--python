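"""Gene model: genomic/CDS/protein coordinate systems for a single coding gene.

A :class:`GeneModel` is a plus-strand genomic sequence together with an ordered
set of exon intervals (1-based, inclusive).  Concatenating the exon substrings
yields the coding sequence (CDS); translating the CDS with the standard nuclear
genetic code yields the protein, whose terminal stop codon is rendered ``*``
and counted as a residue position.  All user-facing coordinates are 1-based.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Sequence

from .errors import CoordinateError, FrameError, GeneModelError

__all__ = [
    "GENETIC_CODE",
    "STOP_CODONS",
    "GeneModel",
    "CodingSequence",
    "ProteinSequence",
    "CdsCoordinate",
    "IntronicPosition",
    "assemble_cds",
    "translate",
    "translate_codon",
    "genomic_to_cds",
    "cds_to_genomic",
]

#: Standard nuclear genetic code, DNA alphabet, stop rendered '*'.
GENETIC_CODE: dict[str, str] = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

STOP_CODONS: frozenset[str] = frozenset(c for c, a in GENETIC_CODE.items() if a == "*")
SENSE_CODONS: tuple[str, ...] = tuple(sorted(set(GENETIC_CODE) - STOP_CODONS))

_VALID_BASES = frozenset("ACGTN")


def translate_codon(codon: str) -> str:
    """Translate one codon; unknown/ambiguous codons give 'X'."""
    return GENETIC_CODE.get(codon.upper(), "X")


@dataclass(frozen=True)
class CdsCoordinate:
    """Position of a nucleotide within the CDS and within its codon."""

    cds_position: int   # 1-based index into the CDS
    codon_index: int    # 1-based protein position
    codon_offset: int   # 0..2 within the codon

    @classmethod
    def from_cds_position(cls, cds_position: int) -> "CdsCoordinate":
        if cds_position < 1:
            raise CoordinateError(f"CDS position must be >= 1, got {cds_position}")
        return cls(
            cds_position=cds_position,
            codon_index=(cds_position + 2) // 3,
            codon_offset=(cds_position - 1) % 3,
        )


@dataclass(frozen=True)
class IntronicPosition:
    """Marker for a genomic position that falls between exons.

    ``distance_to_exon`` is the number of bases to the nearest exon boundary
    (1 = immediately adjacent to an exon edge).
    """

    genomic_position: int
    distance_to_exon: int


@dataclass(frozen=True)
class CodingSequence:
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) % 3 != 0:
            raise FrameError(
                f"CDS length {len(self.sequence)} is not a multiple of 3"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def codon(self, codon_index: int) -> str:
        """Return the 1-based codon at ``codon_index``."""
        n_codons = len(self.sequence) // 3
        if not 1 <= codon_index <= n_codons:
            raise CoordinateError(
                f"codon index {codon_index} outside 1..{n_codons}"
            )
        return self.sequence[(codon_index - 1) * 3 : codon_index * 3]


@dataclass(frozen=True)
class ProteinSequence:
    """Translated protein; the terminal stop is '*' and counts as a position."""

    residues: str
    internal_stops: tuple[int, ...] = ()      # 1-based positions of premature stops
    ambiguous_positions: tuple[int, ...] = () # positions translated as 'X'

    def __len__(self) -> int:
        return len(self.residues)

    def residue(self, position: int) -> str:
        if not 1 <= position <= len(self.residues):
            raise CoordinateError(
                f"protein position {position} outside 1..{len(self.residues)}"
            )
        return self.residues[position - 1]


@dataclass(frozen=True)
class GeneModel:
    """A plus-strand gene: genomic sequence plus ordered exon intervals."""

    gene_id: str
    genomic_sequence: str
    exons: tuple[tuple[int, int], ...]
    _exon_cumlen: tuple[int, ...] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "genomic_sequence", self.genomic_sequence.upper())
        object.__setattr__(self, "exons", tuple((int(s), int(e)) for s, e in self.exons))
        self.validate()
        cum = [0]
        for s, e in self.exons:
            cum.append(cum[-1] + (e - s + 1))
        object.__setattr__(self, "_exon_cumlen", tuple(cum))

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        n = len(self.genomic_sequence)
        if n == 0:
            raise GeneModelError("empty genomic sequence")
        bad = set(self.genomic_sequence) - _VALID_BASES
        if bad:
            raise GeneModelError(f"invalid bases in genomic sequence: {sorted(bad)}")
        if not self.exons:
            raise GeneModelError("gene model has no exons")
        prev_end = 0
        for s, e in self.exons:
            if s < 1 or e > n:
                raise CoordinateError(
                    f"exon [{s}, {e}] outside genomic bounds [1, {n}]"
                )
            if s > e:
                raise GeneModelError(f"exon start {s} > end {e}")
            if s <= prev_end:
                raise GeneModelError(
                    f"exons overlap or are out of order at [{s}, {e}]"
                )
            prev_end = e
        if self.cds_length % 3 != 0:
            raise FrameError(
                f"total exon length {self.cds_length} is not a multiple of 3"
            )

    # -- derived lengths ----------------------------------------------------
    @property
    def genomic_length(self) -> int:
        return len(self.genomic_sequence)

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def intron_length(self) -> int:
        """Everything non-exonic, including flanks: genomic − CDS."""
        return self.genomic_length - self.cds_length

    def is_exonic(self, genomic_pos: int) -> bool:
        coord = genomic_to_cds(self, genomic_pos)
        return isinstance(coord, CdsCoordinate)


def assemble_cds(model: GeneModel) -> CodingSequence:
    """Concatenate exon substrings in genomic order into the CDS."""
    seq = model.genomic_sequence
    parts = [seq[s - 1 : e] for s, e in model.exons]
    return CodingSequence("".join(parts))


def translate(cds: CodingSequence | str) -> ProteinSequence:
    """Translate a CDS with the standard nuclear code.

    Internal stop codons are recorded, not silently truncated; codons with
    non-ACGT bases translate to 'X' and are recorded as ambiguous.
    """
    seq = cds.sequence if isinstance(cds, CodingSequence) else cds
    if len(seq) % 3 != 0:
        raise FrameError(f"CDS length {len(seq)} is not a multiple of 3")
    residues: list[str] = []
    internal_stops: list[int] = []
    ambiguous: list[int] = []
    n_codons = len(seq) // 3
    for i in range(n_codons):
        aa = translate_codon(seq[i * 3 : i * 3 + 3])
        residues.append(aa)
        if aa == "X":
            ambiguous.append(i + 1)
        elif aa == "*" and i + 1 < n_codons:
            internal_stops.append(i + 1)
    return ProteinSequence(
        residues="".join(residues),
        internal_stops=tuple(internal_stops),
        ambiguous_positions=tuple(ambiguous),
    )


def genomic_to_cds(
    model: GeneModel, genomic_pos: int
) -> CdsCoordinate | IntronicPosition:
    """Map a 1-based genomic position to its CDS coordinate.

    Exonic positions map bijectively, order-preserving, to 1..CDS length.
    Intronic/flanking positions return an :class:`IntronicPosition` carrying
    the distance to the nearest exon boundary.
    """
    if not 1 <= genomic_pos <= model.genomic_length:
        raise CoordinateError(
            f"genomic position {genomic_pos} outside gene bounds "
            f"[1, {model.genomic_length}]"
        )
    starts = [s for s, _ in model.exons]
    i = bisect_right(starts, genomic_pos) - 1
    if i >= 0:
        s, e = model.exons[i]
        if genomic_pos <= e:
            cds_pos = model._exon_cumlen[i] + (genomic_pos - s + 1)
            return CdsCoordinate.from_cds_position(cds_pos)
    # intronic or flanking: distance to nearest exon edge
    dists = []
    if i >= 0:
        dists.append(genomic_pos - model.exons[i][1])
    if i + 1 < len(model.exons):
        dists.append(model.exons[i + 1][0] - genomic_pos)
    return IntronicPosition(genomic_position=genomic_pos, distance_to_exon=min(dists))


def cds_to_genomic(model: GeneModel, cds_position: int) -> int:
    """Inverse of :func:`genomic_to_cds` on exonic positions."""
    if not 1 <= cds_position <= model.cds_length:
        raise CoordinateError(
            f"CDS position {cds_position} outside [1, {model.cds_length}]"
        )
    i = bisect_right(model._exon_cumlen, cds_position - 1) - 1
    s, _ = model.exons[i]
    return s + (cds_position - 1 - model._exon_cumlen[i])
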