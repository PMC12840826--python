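"""Codon-aware SNP consequence classification against a gene model.

Each variant is a single-nucleotide substitution observed in one or more
populations, with per-population counts of observations without (``f``) and
with (``g``) the change.  Classification substitutes the alternate base into
the reference codon and compares translated amino acids: synonymous (sSNP),
nonsynonymous (nsSNP), stop-gained, stop-lost, or intronic.

Rarely a published codon alteration involves two linked substitutions in the
same codon reported as one event; ``VariantObservation.alt_codon`` carries
such a codon-level override while the record itself stays anchored to one
primary SNP.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

from .errors import (
    CoordinateError,
    DegenerateVariantError,
    ReferenceMismatchError,
)
from .gene_model import (
    CdsCoordinate,
    GeneModel,
    IntronicPosition,
    assemble_cds,
    genomic_to_cds,
    translate_codon,
)

__all__ = [
    "EffectClass",
    "VariantObservation",
    "SiteMatch",
    "VariantEffect",
    "annotate",
    "annotate_all",
    "partition_effects",
]

_BASES = frozenset("ACGT")

#: SNPs within this many bases of an exon edge get the boundary flag.
EXON_BOUNDARY_WINDOW = 2


class EffectClass(str, enum.Enum):
    INTRONIC = "intronic"
    SYNONYMOUS = "synonymous"
    NONSYNONYMOUS = "nonsynonymous"
    STOP_GAINED = "stop_gained"
    STOP_LOST = "stop_lost"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class VariantObservation:
    """One genomic SNP with per-population (f, g) observation counts.

    ``counts`` maps population name -> (f, g) where ``f`` counts observations
    without the nucleotide change and ``g`` observations with it.  A
    population absent from the map means "not detected", which is distinct
    from g = 0.  ``alt_codon`` optionally overrides the alternate codon when
    the reported alteration includes a second linked change in the same codon;
    the override must still contain ``alt_base`` at this SNP's codon offset.
    """

    genomic_position: int
    ref_base: str
    alt_base: str
    counts: Mapping[str, tuple[int, int]] = field(default_factory=dict)
    alt_codon: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "ref_base", self.ref_base.upper())
        object.__setattr__(self, "alt_base", self.alt_base.upper())
        if self.ref_base not in _BASES or self.alt_base not in _BASES:
            raise DegenerateVariantError(
                f"ref/alt must be single A/C/G/T bases, got "
                f"{self.ref_base!r}>{self.alt_base!r}"
            )
        if self.alt_base == self.ref_base:
            raise DegenerateVariantError(
                f"alternate equals reference ({self.ref_base}) at position "
                f"{self.genomic_position}"
            )
        for pop, (f, g) in self.counts.items():
            if f < 0 or g < 0:
                raise ValueError(f"negative counts for population {pop!r}")
        if self.alt_codon is not None:
            object.__setattr__(self, "alt_codon", self.alt_codon.upper())
            if len(self.alt_codon) != 3 or set(self.alt_codon) - _BASES:
                raise DegenerateVariantError(
                    f"alt_codon override {self.alt_codon!r} is not a DNA codon"
                )


@dataclass(frozen=True)
class SiteMatch:
    """A hit against the known-resistance-site catalog (see topology module)."""

    catalog_label: str        # e.g. "M918T"
    binding_site: str         # PyR1 / PyR2 / D IVS6 / other
    compound_class: str       # pyrethroid / indoxacarb / ...
    match_type: str           # "full" (position + ref/alt aa) or "position"
    numbering: str            # "canonical" or "native"
    literature_only: bool = False


@dataclass(frozen=True)
class VariantEffect:
    """Codon-resolved consequence of one variant."""

    genomic_position: int
    effect_class: EffectClass
    codon_index: int | None = None
    codon_offset: int | None = None
    ref_codon: str | None = None
    alt_codon: str | None = None
    ref_aa: str | None = None
    alt_aa: str | None = None
    label: str | None = None                 # e.g. "M922T", "L145L"
    nucleotide_alteration: str | None = None # "ATG > ACG"
    region_label: str = "unassigned"
    canonical_position: int | None = None
    known_site_matches: tuple[SiteMatch, ...] = ()
    exon_boundary: bool = False
    intron_distance: int | None = None
    counts: Mapping[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def label_short(self) -> str | None:
        """Synonymous labels without the repeated amino acid ("L145")."""
        if self.label is None:
            return None
        if self.effect_class is EffectClass.SYNONYMOUS:
            return f"{self.ref_aa}{self.codon_index}"
        return self.label

    def with_topology(
        self,
        region_label: str,
        canonical_position: int | None,
        matches: Sequence[SiteMatch],
    ) -> "VariantEffect":
        return replace(
            self,
            region_label=region_label,
            canonical_position=canonical_position,
            known_site_matches=tuple(matches),
        )


def _classify(ref_aa: str, alt_aa: str) -> EffectClass:
    if ref_aa == "*" and alt_aa != "*":
        return EffectClass.STOP_LOST
    if alt_aa == "*" and ref_aa != "*":
        return EffectClass.STOP_GAINED
    if ref_aa == alt_aa:
        return EffectClass.SYNONYMOUS
    return EffectClass.NONSYNONYMOUS


def annotate(model: GeneModel, variant: VariantObservation) -> VariantEffect:
    """Classify one SNP against the gene model.

    Intronic positions yield an intronic effect carrying the distance to the
    nearest exon.  Exonic positions get the codon substitution at the SNP's
    codon offset (other codon positions carry the reference base unless an
    ``alt_codon`` override is supplied), classified by the standard code.
    """
    pos = variant.genomic_position
    model_base = model.genomic_sequence[pos - 1] if 1 <= pos <= model.genomic_length else None
    if model_base is None:
        raise CoordinateError(
            f"variant position {pos} outside gene bounds [1, {model.genomic_length}]"
        )
    if model_base != variant.ref_base:
        raise ReferenceMismatchError(
            f"reference mismatch at genomic position {pos}: variant says "
            f"{variant.ref_base}, gene model has {model_base}"
        )
    coord = genomic_to_cds(model, pos)
    if isinstance(coord, IntronicPosition):
        return VariantEffect(
            genomic_position=pos,
            effect_class=EffectClass.INTRONIC,
            intron_distance=coord.distance_to_exon,
            counts=dict(variant.counts),
        )
    assert isinstance(coord, CdsCoordinate)
    cds = assemble_cds(model)
    ref_codon = cds.codon(coord.codon_index)
    if variant.alt_codon is not None:
        alt_codon = variant.alt_codon
        if alt_codon == ref_codon:
            raise DegenerateVariantError(
                f"alt_codon override equals reference codon {ref_codon}"
            )
        if alt_codon[coord.codon_offset] != variant.alt_base:
            raise DegenerateVariantError(
                f"alt_codon override {alt_codon} does not carry alt base "
                f"{variant.alt_base} at codon offset {coord.codon_offset}"
            )
    else:
        alt_codon = (
            ref_codon[: coord.codon_offset]
            + variant.alt_base
            + ref_codon[coord.codon_offset + 1 :]
        )
    ref_aa = translate_codon(ref_codon)
    alt_aa = translate_codon(alt_codon)
    effect_class = _classify(ref_aa, alt_aa)
    if effect_class is EffectClass.SYNONYMOUS:
        label = f"{ref_aa}{coord.codon_index}{ref_aa}"
    else:
        label = f"{ref_aa}{coord.codon_index}{alt_aa}"
    # flag SNPs at exon edges: splice effects are out of scope but worth noting
    boundary = False
    for s, e in model.exons:
        if s <= pos <= e:
            boundary = (pos - s < EXON_BOUNDARY_WINDOW) or (e - pos < EXON_BOUNDARY_WINDOW)
            break
    return VariantEffect(
        genomic_position=pos,
        effect_class=effect_class,
        codon_index=coord.codon_index,
        codon_offset=coord.codon_offset,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        label=label,
        nucleotide_alteration=f"{ref_codon} > {alt_codon}",
        exon_boundary=boundary,
        counts=dict(variant.counts),
    )


def annotate_all(
    model: GeneModel, variants: Sequence[VariantObservation]
) -> list[VariantEffect]:
    """Annotate a collection of variants, ordered by genomic position."""
    return [
        annotate(model, v)
        for v in sorted(variants, key=lambda v: v.genomic_position)
    ]


def partition_effects(
    effects: Sequence[VariantEffect],
) -> tuple[list[VariantEffect], list[VariantEffect], list[VariantEffect]]:
    """Split effects into (nonsynonymous, synonymous, other).

    Stop-gained/lost and intronic effects land in "other" and are never
    counted in the dN/dS numerator or denominator.
    """
    ns: list[VariantEffect] = []
    s: list[VariantEffect] = []
    other: list[VariantEffect] = []
    for eff in effects:
        if eff.effect_class is EffectClass.NONSYNONYMOUS:
            ns.append(eff)
        elif eff.effect_class is EffectClass.SYNONYMOUS:
            s.append(eff)
        else:
            other.append(eff)
    return ns, s, other
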