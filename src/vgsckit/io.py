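"""Readers and writers for the pipeline's interchange formats.

Formats: FASTA (single-record genomic sequence, via Biopython), BED /
two-column TSV exon intervals, a variants TSV (the reference format) or a
minimal VCFv4.2 subset (via pysam), a YAML channel config (topology +
canonical map + known-site catalog), a population metadata TSV, and the
annotated/summary TSV outputs.

Coordinate conventions: everything user-facing is 1-based inclusive; BED's
0-based half-open intervals are converted at this boundary.
"""

from __future__ import annotations

import json
import sys
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .errors import ConfigError
from .gene_model import GeneModel
from .popstats import PopulationInfo, frequency_display
from .topology import (
    CanonicalMap,
    KnownSite,
    KnownSiteCatalog,
    Region,
    TopologyMap,
)
from .variants import EffectClass, VariantEffect, VariantObservation

__all__ = [
    "read_gene_model",
    "write_gene_model",
    "read_variants_tsv",
    "write_variants_tsv",
    "read_variants_vcf",
    "write_variants_vcf",
    "read_variants",
    "read_channel_config",
    "write_channel_config",
    "read_populations",
    "write_populations",
    "effects_to_frame",
    "write_annotated",
    "write_manifest",
]

MISSING = "-"


# ---------------------------------------------------------------------------
# gene model: FASTA + BED/TSV
# ---------------------------------------------------------------------------

def read_gene_model(fasta_path: str | Path, exons_path: str | Path) -> GeneModel:
    """Single-record FASTA plus exon intervals (BED 0-based or TSV 1-based)."""
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise ConfigError(
            f"{fasta_path}: expected exactly one FASTA record, found {len(records)}"
        )
    rec = records[0]
    exons = _read_exons(Path(exons_path))
    return GeneModel(rec.id, str(rec.seq), tuple(exons))


def _read_exons(path: Path) -> list[tuple[int, int]]:
    is_bed = path.suffix.lower() == ".bed"
    exons: list[tuple[int, int]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        try:
            if is_bed:
                start, end = int(fields[1]), int(fields[2])  # 0-based half-open
                exons.append((start + 1, end))
            else:
                start, end = int(fields[0]), int(fields[1])  # 1-based inclusive
                exons.append((start, end))
        except (IndexError, ValueError) as exc:
            raise ConfigError(f"{path}:{lineno}: cannot parse exon interval") from exc
    if not exons:
        raise ConfigError(f"{path}: no exon intervals found")
    return exons


def write_gene_model(
    model: GeneModel, fasta_path: str | Path, bed_path: str | Path
) -> None:
    rec = SeqRecord(Seq(model.genomic_sequence), id=model.gene_id, description="")
    SeqIO.write([rec], str(fasta_path), "fasta")
    with open(bed_path, "w") as fh:
        for s, e in model.exons:
            fh.write(f"{model.gene_id}\t{s - 1}\t{e}\n")  # back to BED convention


# ---------------------------------------------------------------------------
# variants: TSV (reference format) and VCF subset
# ---------------------------------------------------------------------------

def write_variants_tsv(
    variants: Sequence[VariantObservation],
    path: str | Path,
    populations: Sequence[str] | Sequence[PopulationInfo],
) -> None:
    """Columns: position, ref, alt, alt_codon, then f_<POP> g_<POP> pairs."""
    pop_names = [p.name if isinstance(p, PopulationInfo) else p for p in populations]
    cols = ["position", "ref", "alt", "alt_codon"]
    for p in pop_names:
        cols += [f"f_{p}", f"g_{p}"]
    rows = []
    for v in variants:
        row: dict[str, object] = {
            "position": v.genomic_position,
            "ref": v.ref_base,
            "alt": v.alt_base,
            "alt_codon": v.alt_codon or MISSING,
        }
        for p in pop_names:
            if p in v.counts:
                row[f"f_{p}"], row[f"g_{p}"] = v.counts[p]
            else:
                row[f"f_{p}"] = row[f"g_{p}"] = MISSING
        rows.append(row)
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_variants_tsv(path: str | Path) -> tuple[list[VariantObservation], list[str]]:
    """Returns (variants, population names found in the header)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"position", "ref", "alt"}
    if not required.issubset(df.columns):
        raise ConfigError(f"{path}: missing required columns {sorted(required - set(df.columns))}")
    pops = [c[2:] for c in df.columns if c.startswith("f_")]
    variants = []
    for idx, row in df.iterrows():
        counts = {}
        for p in pops:
            f, g = row.get(f"f_{p}", MISSING), row.get(f"g_{p}", MISSING)
            if pd.isna(f) or pd.isna(g) or f == MISSING or g == MISSING:
                continue
            counts[p] = (int(f), int(g))
        alt_codon = row.get("alt_codon")
        if pd.isna(alt_codon) or alt_codon == MISSING:
            alt_codon = None
        try:
            variants.append(
                VariantObservation(
                    genomic_position=int(row["position"]),
                    ref_base=row["ref"],
                    alt_base=row["alt"],
                    counts=counts,
                    alt_codon=alt_codon,
                )
            )
        except Exception as exc:
            raise ConfigError(f"{path}: line {idx + 2}: {exc}") from exc
    return variants, pops


_VCF_HEADER_NOTE = "per-population pooled observation counts without/with the change"


def write_variants_vcf(
    variants: Sequence[VariantObservation],
    path: str | Path,
    populations: Sequence[str] | Sequence[PopulationInfo],
    contig: str = "gene",
    contig_length: int | None = None,
) -> None:
    """Minimal VCFv4.2: SNPs only, counts as per-population INFO pairs."""
    pop_names = [p.name if isinstance(p, PopulationInfo) else p for p in populations]
    header = pysam.VariantHeader()
    if contig_length is not None:
        header.contigs.add(contig, length=contig_length)
    else:
        header.contigs.add(contig)
    for p in pop_names:
        header.info.add(f"FG_{p}", 2, "Integer", f"{_VCF_HEADER_NOTE} ({p})")
    header.info.add("ALTCODON", 1, "String", "full alternate codon for linked changes")
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in sorted(variants, key=lambda v: v.genomic_position):
            rec = out.new_record(
                contig=contig,
                start=v.genomic_position - 1,
                stop=v.genomic_position,
                alleles=(v.ref_base, v.alt_base),
            )
            for p in pop_names:
                if p in v.counts:
                    rec.info[f"FG_{p}"] = v.counts[p]
            if v.alt_codon:
                rec.info["ALTCODON"] = v.alt_codon
            out.write(rec)


def read_variants_vcf(path: str | Path) -> tuple[list[VariantObservation], list[str]]:
    variants = []
    with pysam.VariantFile(str(path)) as vcf:
        pops = [k[3:] for k in vcf.header.info.keys() if k.startswith("FG_")]
        for rec in vcf:
            if len(rec.alleles) != 2 or any(len(a) != 1 for a in rec.alleles):
                raise ConfigError(
                    f"{path}: only biallelic SNPs supported (pos {rec.pos})"
                )
            counts = {}
            for p in pops:
                key = f"FG_{p}"
                if key in rec.info:
                    f, g = rec.info[key]
                    counts[p] = (int(f), int(g))
            alt_codon = rec.info.get("ALTCODON")
            variants.append(
                VariantObservation(
                    genomic_position=rec.pos,
                    ref_base=rec.ref,
                    alt_base=rec.alts[0],
                    counts=counts,
                    alt_codon=alt_codon,
                )
            )
    return variants, pops


def read_variants(path: str | Path) -> tuple[list[VariantObservation], list[str]]:
    """Dispatch on extension: .vcf[.gz] or the TSV reference format."""
    p = Path(path)
    if p.name.endswith((".vcf", ".vcf.gz")):
        return read_variants_vcf(p)
    return read_variants_tsv(p)


# ---------------------------------------------------------------------------
# channel config: topology + canonical map + catalog (YAML)
# ---------------------------------------------------------------------------

def write_channel_config(
    path: str | Path,
    topology: TopologyMap,
    cmap: CanonicalMap,
    catalog: KnownSiteCatalog,
) -> None:
    doc = {
        "regions": [
            {"label": r.label, "start": r.aa_start, "end": r.aa_end}
            for r in topology.regions
        ],
        "canonical_map": [
            {"start": a, "end": b, "offset": o} for a, b, o in cmap.intervals
        ],
        "known_sites": [
            {
                "label": s.label,
                "binding_site": s.binding_site,
                "compound_class": s.compound_class,
                "note": s.note,
                "literature_only": s.literature_only,
            }
            for s in catalog
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_channel_config(
    path: str | Path,
) -> tuple[TopologyMap, CanonicalMap, KnownSiteCatalog]:
    try:
        doc = yaml.safe_load(Path(path).read_text())
        topology = TopologyMap(
            tuple(Region(r["label"], int(r["start"]), int(r["end"]))
                  for r in doc["regions"])
        )
        cmap = CanonicalMap(
            tuple((int(i["start"]), int(i["end"]), int(i["offset"]))
                  for i in doc.get("canonical_map", []))
        )
        catalog = KnownSiteCatalog(
            tuple(
                KnownSite(
                    s["label"],
                    s.get("binding_site", "other"),
                    s.get("compound_class", ""),
                    s.get("note", ""),
                    bool(s.get("literature_only", False)),
                )
                for s in doc.get("known_sites", [])
            )
        )
        return topology, cmap, catalog
    except (KeyError, TypeError, yaml.YAMLError) as exc:
        raise ConfigError(f"{path}: invalid channel config: {exc}") from exc


# ---------------------------------------------------------------------------
# populations
# ---------------------------------------------------------------------------

def write_populations(pops: Sequence[PopulationInfo], path: str | Path) -> None:
    pd.DataFrame(
        [{"name": p.name, "latitude": p.latitude, "longitude": p.longitude}
         for p in pops]
    ).to_csv(path, sep="\t", index=False)


def read_populations(path: str | Path) -> list[PopulationInfo]:
    df = pd.read_csv(path, sep="\t")
    for col in ("name", "latitude", "longitude"):
        if col not in df.columns:
            raise ConfigError(f"{path}: missing column {col!r}")
    pops = [
        PopulationInfo(str(r["name"]), float(r["latitude"]), float(r["longitude"]))
        for _, r in df.iterrows()
    ]
    if len({p.name for p in pops}) != len(pops):
        raise ConfigError(f"{path}: duplicate population names")
    return pops


# ---------------------------------------------------------------------------
# annotated output
# ---------------------------------------------------------------------------

def effects_to_frame(
    effects: Sequence[VariantEffect],
    populations: Sequence[str] | Sequence[PopulationInfo],
    short_synonymous_labels: bool = True,
) -> pd.DataFrame:
    """One row per variant, mirroring the published table layout.

    Per-population cells render "percent (f, g)" with exact 2-dp display
    rounding and "-" for undetected, exactly as the source tables do.
    """
    pop_names = [p.name if isinstance(p, PopulationInfo) else p for p in populations]
    rows = []
    for eff in sorted(effects, key=lambda e: e.genomic_position):
        matches = "; ".join(
            f"{m.catalog_label}[{m.binding_site},{m.match_type}]"
            for m in eff.known_site_matches
        )
        row: dict[str, object] = {
            "genomic_position": eff.genomic_position,
            "class": eff.effect_class.value,
            "region": eff.region_label,
            "label": (eff.label_short if short_synonymous_labels else eff.label)
                     or MISSING,
            "nucleotide_alteration": eff.nucleotide_alteration or MISSING,
            "codon_index": eff.codon_index if eff.codon_index else MISSING,
            "canonical_position": eff.canonical_position
                                  if eff.canonical_position else MISSING,
            "known_site_matches": matches or MISSING,
        }
        for p in pop_names:
            if p in eff.counts:
                f, g = eff.counts[p]
                row[p] = f"{frequency_display(f, g)} ({f}, {g})"
            else:
                row[p] = MISSING
        rows.append(row)
    cols = [
        "genomic_position", "class", "region", "label", "nucleotide_alteration",
        "codon_index", "canonical_position", "known_site_matches", *pop_names,
    ]
    return pd.DataFrame(rows, columns=cols)


def write_annotated(
    effects: Sequence[VariantEffect],
    path: str | Path,
    populations: Sequence[str] | Sequence[PopulationInfo],
) -> None:
    effects_to_frame(effects, populations).to_csv(path, sep="\t", index=False)


def write_manifest(out_dir: str | Path, inputs: dict, seed: int | None = None) -> None:
    """Machine-readable record of what produced an output directory."""
    manifest = {
        "tool": "vgsckit",
        "version": __version__,
        "inputs": {k: str(v) for k, v in inputs.items()},
        "seed": seed,
        "python": sys.version.split()[0],
    }
    Path(out_dir, "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
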