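"""Channel topology regions, canonical numbering, and known resistance sites.

Insect voltage-gated sodium channels (VGSC) comprise four homologous domains
(I-IV) of six transmembrane helices (S1-S6) joined by intra- and inter-domain
linkers.  Resistance literature reports mutations in a canonical numbering
transferred from a reference species (the classic house-fly kdr numbering),
so a species' native residue numbers must be offset-mapped before comparing
against known knockdown-resistance (kdr) and sodium-channel-blocker sites.

Region labels follow the field's shorthand: ``D II-S5`` (helix 5 of domain
II), ``D II-S45-L`` (intra-domain linker between S4 and S5), ``D II-III-L``
(inter-domain linker), ``D IV < L`` (region C-terminal of domain IV).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

from .errors import ConfigError, CoordinateError
from .variants import SiteMatch, VariantEffect

__all__ = [
    "Region",
    "TopologyMap",
    "CanonicalMap",
    "KnownSite",
    "KnownSiteCatalog",
    "region_label",
    "to_canonical",
    "match_known_sites",
    "annotate_topology",
]

UNASSIGNED = "unassigned"

_SITE_LABEL_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


@dataclass(frozen=True)
class Region:
    label: str
    aa_start: int
    aa_end: int


@dataclass(frozen=True)
class TopologyMap:
    """Ordered, non-overlapping protein intervals with region labels.

    The union need not cover every residue; uncovered positions label as
    ``unassigned``.
    """

    regions: tuple[Region, ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "regions", tuple(Region(r.label, r.aa_start, r.aa_end)
                                   if isinstance(r, Region) else Region(*r)
                                   for r in self.regions)
        )
        prev_end = 0
        for r in self.regions:
            if r.aa_start < 1 or r.aa_start > r.aa_end:
                raise ConfigError(f"bad region interval {r}")
            if r.aa_start <= prev_end:
                raise ConfigError(f"regions overlap or out of order at {r}")
            prev_end = r.aa_end

    def label_for(self, protein_pos: int) -> str:
        return region_label(self, protein_pos)


def region_label(topology: TopologyMap, protein_pos: int) -> str:
    """Label of the unique region covering ``protein_pos``, else 'unassigned'."""
    if protein_pos < 1:
        raise CoordinateError(f"protein position must be >= 1, got {protein_pos}")
    for r in topology.regions:
        if r.aa_start <= protein_pos <= r.aa_end:
            return r.label
    return UNASSIGNED


@dataclass(frozen=True)
class CanonicalMap:
    """Piecewise-offset map from native to canonical residue numbering.

    Each interval ``(native_start, native_end, offset)`` maps native position
    p to p + offset.  Positions outside every interval are unmapped.
    """

    intervals: tuple[tuple[int, int, int], ...]

    def __post_init__(self) -> None:
        ivs = tuple((int(a), int(b), int(o)) for a, b, o in self.intervals)
        object.__setattr__(self, "intervals", ivs)
        prev_end = 0
        for a, b, _ in ivs:
            if a < 1 or a > b:
                raise ConfigError(f"bad canonical-map interval ({a}, {b})")
            if a <= prev_end:
                raise ConfigError("canonical-map intervals overlap or out of order")
            prev_end = b

    def __call__(self, native_pos: int) -> int | None:
        return to_canonical(self, native_pos)

    @classmethod
    def identity(cls, upto: int = 10**6) -> "CanonicalMap":
        return cls(((1, upto, 0),))


def to_canonical(cmap: CanonicalMap, native_pos: int) -> int | None:
    """Canonical residue number for ``native_pos``, or None when unmapped."""
    for a, b, offset in cmap.intervals:
        if a <= native_pos <= b:
            return native_pos + offset
    return None


@dataclass(frozen=True)
class KnownSite:
    """One catalogued resistance substitution in canonical numbering."""

    label: str                 # "M918T"
    binding_site: str          # PyR1 / PyR2 / D IVS6 / other
    compound_class: str        # pyrethroid / indoxacarb / ...
    note: str = ""
    literature_only: bool = False

    def __post_init__(self) -> None:
        if not _SITE_LABEL_RE.match(self.label):
            raise ConfigError(f"catalog label {self.label!r} is not refAA+pos+altAA")

    @property
    def ref_aa(self) -> str:
        return self.label[0]

    @property
    def position(self) -> int:
        return int(_SITE_LABEL_RE.match(self.label).group(2))

    @property
    def alt_aa(self) -> str:
        return self.label[-1]


@dataclass(frozen=True)
class KnownSiteCatalog:
    entries: tuple[KnownSite, ...]

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


def match_known_sites(
    effect: VariantEffect,
    cmap: CanonicalMap,
    catalog: KnownSiteCatalog,
) -> list[SiteMatch]:
    """Match a nonsynonymous effect against the known-site catalog.

    A catalog position is compared against the variant's canonical position
    and, because some sites are catalogued in the species' own numbering when
    the two schemes coincide in the source literature, against its native
    position as well.  A *full* match additionally requires ref and alt
    amino-acid identity; position-only hits are reported as partial matches.
    Full matches sort first.
    """
    if effect.codon_index is None:
        return []
    native = effect.codon_index
    canonical = to_canonical(cmap, native)
    matches: list[SiteMatch] = []
    seen: set[tuple[str, str]] = set()
    for numbering, pos in (("canonical", canonical), ("native", native)):
        if pos is None:
            continue
        for site in catalog:
            if site.position != pos:
                continue
            full = site.ref_aa == effect.ref_aa and site.alt_aa == effect.alt_aa
            match_type = "full" if full else "position"
            key = (site.label, match_type)
            if key in seen:
                continue
            seen.add(key)
            matches.append(
                SiteMatch(
                    catalog_label=site.label,
                    binding_site=site.binding_site,
                    compound_class=site.compound_class,
                    match_type=match_type,
                    numbering=numbering,
                    literature_only=site.literature_only,
                )
            )
    matches.sort(key=lambda m: (m.match_type != "full", m.catalog_label))
    return matches


def annotate_topology(
    effects: Sequence[VariantEffect],
    topology: TopologyMap,
    cmap: CanonicalMap,
    catalog: KnownSiteCatalog,
) -> list[VariantEffect]:
    """Fill region labels, canonical positions and known-site matches."""
    out: list[VariantEffect] = []
    for eff in effects:
        if eff.codon_index is None:
            out.append(eff)
            continue
        region = region_label(topology, eff.codon_index)
        canonical = to_canonical(cmap, eff.codon_index)
        from .variants import EffectClass

        matches: list[SiteMatch] = []
        if eff.effect_class is EffectClass.NONSYNONYMOUS:
            matches = match_known_sites(eff, cmap, catalog)
        out.append(eff.with_topology(region, canonical, matches))
    return out
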