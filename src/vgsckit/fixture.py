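"""Packaged study fixture: the 37 published VGSC variants of *Liriomyza trifolii*.

The study's raw resequencing data are not public, but its per-variant,
per-population observation counts, codon alterations, channel-region labels
and canonical-numbering offsets are published in full.  This module embeds
that table verbatim and reconstructs around it a *synthetic* gene model whose
printed totals it is constrained to reproduce: genomic 36,774 nt, intron
30,360 nt, CDS 6414 nt, protein 2138 positions including the stop, with the
published reference codon pinned at each of the 37 variant positions.  Exon
boundaries and all non-variant codons are synthetic (deterministic, seeded):
only length totals, not exon coordinates, are on public record.

The five sampled populations are listed north to south by latitude:
MY, TS, DA, TY, JY.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .gene_model import (
    GeneModel,
    SENSE_CODONS,
    STOP_CODONS,
    cds_to_genomic,
    translate_codon,
)
from .popstats import PopulationInfo
from .topology import CanonicalMap, KnownSite, KnownSiteCatalog, Region, TopologyMap
from .variants import VariantObservation

__all__ = [
    "FIXTURE_GENE_ID",
    "FixtureBundle",
    "PrintedCell",
    "fixture_populations",
    "fixture_topology",
    "fixture_canonical_map",
    "fixture_catalog",
    "fixture_gene_model",
    "fixture_observations",
    "fixture_printed_cells",
    "paper_fixture",
]

FIXTURE_GENE_ID = "LtVGSC"

#: deterministic stream for the synthetic parts of the fixture gene
_FIXTURE_SEED = 732

#: populations in decreasing-latitude (north-to-south) order
_POPULATIONS = (
    PopulationInfo("MY", 18.94, 109.51),
    PopulationInfo("TS", 18.79, 109.52),
    PopulationInfo("DA", 18.47, 108.90),
    PopulationInfo("TY", 18.31, 109.48),
    PopulationInfo("JY", 18.29, 109.54),
)

# Published variant table (synonymous then nonsynonymous rows).  Columns:
# region | label | refcodon>altcodon | MY | TS | DA | TY | JY
# with each populated cell as "percent (f, g)" and "-" for not detected.
_VARIANT_TABLE = """
D I-S1|L145|TTA>TTG|21.33 (59, 16)|11.36 (78, 10)|13.11 (53, 8)|16.22 (62, 12)|13.11 (53, 8)
D I-S56-L|I290|ATT>ATC|27.05 (89, 33)|18.03 (100, 22)|23.08 (60, 18)|15.65 (97, 18)|12.07 (102, 14)
D I-S56-L|S319|TCT>TCA|24.77 (82, 27)|25.00 (72, 24)|26.47 (50, 18)|12.90 (81, 12)|14.00 (86, 14)
D I-S56-L|Y354|TAT>TAC|-|9.89 (82, 9)|11.96 (81, 11)|-|-
D I-II-L|A470|GCG>GCT|-|8.57 (64, 6)|-|-|-
D I-II-L|L474|TTA>TTG|-|19.70 (53, 13)|28.24 (61, 24)|-|14.55 (94, 16)
D I-II-L|E496|GAG>GAA|27.27 (48, 18)|23.91 (35, 11)|32.94 (57, 28)|17.72 (65, 14)|14.46 (71, 12)
D I-II-L|E505|GAA>GAG|22.95 (47, 14)|18.75 (39, 9)|28.57 (55, 22)|13.33 (52, 8)|14.08 (61, 10)
D I-II-L|E661|GAG>GAA|39.18 (59, 38)|19.18 (59, 14)|10.00 (81, 9)|18.95 (77, 18)|-
D I-II-L|A685|GCC>GCA|44.33 (54, 43)|25.00 (51, 17)|11.24 (79, 10)|20.93 (68, 18)|-
D I-II-L|L733|TTG>TTA|54.22 (38, 45)|21.95 (64, 18)|11.59 (61, 8)|22.69 (92, 27)|10.24 (114, 13)
D I-II-L|L778|CTC>CTT|45.53 (67, 56)|18.63 (83, 19)|13.49 (109, 17)|28.91 (91, 37)|-
D II-S1|T814|ACA>ACG|45.28 (58, 48)|20.00 (80, 20)|19.82 (89, 22)|29.91 (75, 32)|-
D II-S23-L|Y866|TAC>TAT|38.46 (56, 35)|18.68 (74, 17)|-|22.23 (70, 20)|-
D II-S5|N931|AAC>AAT|48.00 (39, 36)|24.64 (52, 17)|21.43 (66, 18)|16.16 (83, 16)|7.08 (105, 8)
D II-S56-L|S978|TCT>TCG|52.87 (41, 46)|25.00 (54, 18)|17.71 (79, 17)|18.00 (82, 18)|9.16 (119, 12)
D II-III-L|A1112|GCT>GCA|44.87 (43, 35)|21.88 (50, 14)|23.38 (59, 18)|24.44 (68, 22)|9.76 (74, 8)
D II-III-L|L1231|CTA>CTT|-|-|11.76 (90, 12)|-|-
D II-III-L|D1232|GAT>GAC|-|-|12.24 (86, 12)|-|-
D II-III-L|P1282|CCT>CCG|35.71 (72, 40)|20.72 (88, 23)|28.70 (77, 31)|27.17 (67, 25)|11.72 (113, 15)
D III-S3|F1372|TTT>TTC|16.67 (30, 6)|7.50 (37, 3)|-|-|-
D III-S56-L|I1471|ATC>ATT|-|10.10 (89, 10)|-|-|-
D III-S56-L|Y1483|TAT>TAC|-|16.19 (88, 17)|-|-|-
D IV < L|H1996|CAC>CAT|32.43 (75, 36)|18.52 (66, 15)|13.21 (92, 14)|23.15 (83, 25)|-
D IV < L|Q2006|CAA>CAG|72.32 (31, 81)|80.28 (14, 57)|85.15 (15, 86)|76.77 (23, 76)|94.31 (7, 116)
D IV < L|R2011|CGA>CGT|72.22 (30, 78)|82.54 (11, 52)|85.29 (15, 87)|76.84 (22, 73)|93.97 (7, 109)
D IV < L|G2022|GGT>GGC|-|10.00 (54, 6)|6.06 (93, 6)|-|-
D IV < L|G2033|GGG>GGT|73.63 (24, 67)|91.94 (5, 57)|91.86 (7, 79)|81.94 (13, 59)|94.44 (6, 102)
D IV < L|A2038|GCG>GCT|-|7.04 (66, 5)|-|-|-
D IV < L|G2040|GGA>GGT|-|8.33 (66, 6)|-|-|-
D IV < L|A2050|GCC>GCT|64.41 (21, 38)|94.29 (4, 66)|88.57 (8, 62)|81.36 (11, 48)|93.40 (7, 99)
D II-S45-L|M922T|ATG>ACG|58.46 (27, 38)|62.07 (22, 36)|72.09 (24, 62)|80.58 (20, 83)|90.91 (11, 110)
D II-S5|T933I|ACA>ATA|-|8.57 (64, 6)|-|-|-
D II-S6|L1018F|CTT>TTT|100.00 (0, 64)|100.00 (0, 71)|100.00 (0, 90)|100.00 (0, 102)|100.00 (0, 126)
D II-III-L|Q1285H|CAA>CAC|-|-|80.00 (18, 72)|-|96.52 (4, 111)
D IV-S6|V1845I|GTT>ATA|36.54 (99, 57)|86.27 (14, 88)|80.00 (18, 72)|79.55 (18, 70)|96.52 (4, 111)
D IV < L|D2036E|GAC>GAA|-|6.94 (67, 5)|-|-|-
""".strip()

# Channel-region intervals placing every published variant in its published
# region while respecting the domain partition (I: 1-415, II: 416-1029,
# III: 1030-1560, IV: 1561-2138, 415/614/531/578 residues).  Segment-level
# boundaries inside those constraints are synthetic: the study publishes
# region membership, not numeric boundaries.
_REGIONS = (
    ("D I-S1", 120, 150),
    ("D I-S56-L", 280, 370),
    ("D I-II-L", 416, 800),
    ("D II-S1", 801, 835),
    ("D II-S23-L", 850, 890),
    ("D II-S45-L", 915, 925),
    ("D II-S5", 926, 955),
    ("D II-S56-L", 956, 1005),
    ("D II-S6", 1006, 1029),
    ("D II-III-L", 1030, 1320),
    ("D III-S3", 1360, 1385),
    ("D III-S56-L", 1450, 1500),
    ("D IV-S6", 1820, 1855),
    ("D IV < L", 1856, 2138),
)

# Native -> canonical (house-fly kdr numbering) piecewise offsets, encoding
# the published parentheticals verbatim: 922->918, 1018->1014, 1845->1851;
# positions without a published parenthetical map identically.
_CANONICAL_INTERVALS = (
    (1, 910, 0),
    (911, 929, -4),
    (930, 1010, 0),
    (1011, 1100, -4),
    (1101, 1840, 0),
    (1841, 1900, 6),
    (1901, 2138, 0),
)

# Resistance-site catalog: the four study-confirmed sites plus
# literature-only variants at the same hot spots.
_CONFIRMED_SITES = (
    ("M918T", "PyR1", "pyrethroid", "classic super-kdr site"),
    ("L1014F", "PyR1", "pyrethroid", "classic kdr site, first confirmed in house fly"),
    ("T933I", "PyR2", "pyrethroid", "PyR2 site, species-native numbering"),
    ("V1845I", "D IVS6", "indoxacarb", "sodium-channel-blocker (SCBI) site"),
)
_LITERATURE_SITES = (
    ("M918L", "PyR1", "pyrethroid"),
    ("M918V", "PyR1", "pyrethroid"),
    ("L1014S", "PyR1", "pyrethroid"),
    ("L1014H", "PyR1", "pyrethroid"),
    ("L1014C", "PyR1", "pyrethroid"),
    ("L1014W", "PyR1", "pyrethroid"),
    ("T929C", "PyR2", "pyrethroid"),
    ("T933C", "PyR2", "pyrethroid"),
    ("T933V", "PyR2", "pyrethroid"),
)

# Exon lengths mirror the 13 cloning fragments' per-fragment exon content,
# last adjusted so the total is exactly the published CDS length 6414; the
# 12 introns are equal-length so everything non-exonic sums to 30,360.
_EXON_LENGTHS = (215, 188, 236, 713, 565, 610, 697, 796, 225, 301, 584, 327, 957)
_INTRON_LENGTH = 2530

_CELL_RE = re.compile(r"^([\d.]+) \((\d+), (\d+)\)$")
_LABEL_RE = re.compile(r"^([A-Z])(\d+)([A-Z]?)$")


class PrintedCell(NamedTuple):
    """One populated table cell as printed: label, population, percent, f, g."""

    variant_label: str
    population: str
    printed_percent: str
    f: int
    g: int


@dataclass(frozen=True)
class _FixtureRow:
    region: str
    label: str
    codon_index: int
    ref_codon: str
    alt_codon: str
    counts: dict[str, tuple[int, int]]
    printed: dict[str, str]


def _parse_table() -> list[_FixtureRow]:
    rows = []
    pop_names = [p.name for p in _POPULATIONS]
    for line in _VARIANT_TABLE.splitlines():
        region, label, alteration, *cells = [c.strip() for c in line.split("|")]
        ref_codon, alt_codon = alteration.split(">")
        m = _LABEL_RE.match(label)
        codon_index = int(m.group(2))
        counts, printed = {}, {}
        for pop, cell in zip(pop_names, cells):
            if cell == "-":
                continue
            cm = _CELL_RE.match(cell)
            counts[pop] = (int(cm.group(2)), int(cm.group(3)))
            printed[pop] = cm.group(1)
        assert translate_codon(ref_codon) == m.group(1), label
        rows.append(
            _FixtureRow(region, label, codon_index, ref_codon, alt_codon,
                        counts, printed)
        )
    return rows


_ROWS = _parse_table()


def fixture_populations() -> list[PopulationInfo]:
    return list(_POPULATIONS)


def fixture_topology() -> TopologyMap:
    return TopologyMap(tuple(Region(*r) for r in _REGIONS))


def fixture_canonical_map() -> CanonicalMap:
    return CanonicalMap(_CANONICAL_INTERVALS)


def fixture_catalog() -> KnownSiteCatalog:
    entries = [KnownSite(lbl, site, cmpd, note) for lbl, site, cmpd, note in _CONFIRMED_SITES]
    entries += [
        KnownSite(lbl, site, cmpd, "reported in other species", literature_only=True)
        for lbl, site, cmpd in _LITERATURE_SITES
    ]
    return KnownSiteCatalog(tuple(entries))


def fixture_gene_model() -> GeneModel:
    """Synthetic gene reproducing the published totals and variant codons."""
    n_codons = 2138
    rng = np.random.default_rng(_FIXTURE_SEED)
    codons = list(rng.choice(SENSE_CODONS, size=n_codons))
    codons[0] = "ATG"
    codons[-1] = "TAA"
    for row in _ROWS:
        codons[row.codon_index - 1] = row.ref_codon
    cds = "".join(codons)
    assert len(cds) == sum(_EXON_LENGTHS) == 6414

    bases = np.array(list("ACGT"))
    pieces: list[str] = []
    exons: list[tuple[int, int]] = []
    cds_cursor = 0
    genomic_cursor = 0
    for i, elen in enumerate(_EXON_LENGTHS):
        if i > 0:
            intron = "".join(rng.choice(bases, size=_INTRON_LENGTH))
            # canonical GT..AG splice dinucleotides, for realism only
            intron = "GT" + intron[2:-2] + "AG"
            pieces.append(intron)
            genomic_cursor += _INTRON_LENGTH
        pieces.append(cds[cds_cursor : cds_cursor + elen])
        exons.append((genomic_cursor + 1, genomic_cursor + elen))
        cds_cursor += elen
        genomic_cursor += elen
    return GeneModel(FIXTURE_GENE_ID, "".join(pieces), tuple(exons))


def fixture_observations(model: GeneModel | None = None) -> list[VariantObservation]:
    """The 37 published variants as SNP observations on the fixture gene.

    Each variant's SNP sits at the first codon offset where reference and
    alternate codons differ; the one published two-base codon alteration
    (V1845I, GTT > ATA) keeps its full published alternate codon as an
    ``alt_codon`` override on its primary SNP.
    """
    model = model or fixture_gene_model()
    obs = []
    for row in _ROWS:
        diffs = [k for k in range(3) if row.ref_codon[k] != row.alt_codon[k]]
        offset = diffs[0]
        cds_pos = (row.codon_index - 1) * 3 + offset + 1
        gpos = cds_to_genomic(model, cds_pos)
        obs.append(
            VariantObservation(
                genomic_position=gpos,
                ref_base=row.ref_codon[offset],
                alt_base=row.alt_codon[offset],
                counts=dict(row.counts),
                alt_codon=row.alt_codon if len(diffs) > 1 else None,
            )
        )
    return obs


def fixture_printed_cells() -> list[PrintedCell]:
    """Every populated cell as printed, for checksum-style verification."""
    cells = []
    for row in _ROWS:
        for pop in (p.name for p in _POPULATIONS):
            if pop in row.counts:
                f, g = row.counts[pop]
                cells.append(PrintedCell(row.label, pop, row.printed[pop], f, g))
    return cells


def fixture_expected_labels() -> dict[str, tuple[str, str]]:
    """label -> (region, 'REF > ALT') as published, keyed by table label."""
    return {r.label: (r.region, f"{r.ref_codon} > {r.alt_codon}") for r in _ROWS}


class FixtureBundle(NamedTuple):
    gene_model: GeneModel
    topology: TopologyMap
    canonical_map: CanonicalMap
    catalog: KnownSiteCatalog
    observations: list[VariantObservation]
    populations: list[PopulationInfo]


def paper_fixture() -> FixtureBundle:
    """Everything needed to re-run the analysis on the published counts."""
    model = fixture_gene_model()
    return FixtureBundle(
        gene_model=model,
        topology=fixture_topology(),
        canonical_map=fixture_canonical_map(),
        catalog=fixture_catalog(),
        observations=fixture_observations(model),
        populations=fixture_populations(),
    )
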