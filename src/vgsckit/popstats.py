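"""Population-level summaries: frequencies, presence, count dN/dS, latitude trend.

The per-cell frequency statistic is e = g/(f+g): the proportion of pooled
observations carrying the nucleotide change, reported as a percentage.
Display rounding (2 decimal places, half away from zero) is separated from
the full-precision values statistics are computed on.

dN/dS here is the raw nsSNP/sSNP count ratio — a segregating-site tally, not
a codon-model (NG86/GY94) estimator — and its interpretation from
population-level SNP data carries the usual caveat.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UndefinedFrequencyError, UndefinedRatioError
from .variants import EffectClass, VariantEffect, partition_effects

__all__ = [
    "PopulationInfo",
    "frequency",
    "frequency_display",
    "round_half_away",
    "build_frequency_table",
    "build_presence_matrix",
    "PresenceSummary",
    "presence_summary",
    "DnDsResult",
    "dnds_count_ratio",
    "TrendResult",
    "latitude_trend",
    "SummaryStats",
    "summarize",
]

DNDS_CAVEAT = (
    "Count-based dN/dS from population-level SNPs; interpretation as a "
    "selection statistic requires caution."
)

#: half-width of the band around 1 treated as "approximately neutral"
_NEUTRAL_BAND = 0.05


@dataclass(frozen=True)
class PopulationInfo:
    """A sampled population with its collection coordinates."""

    name: str
    latitude: float   # decimal degrees N
    longitude: float  # decimal degrees E

    def __post_init__(self) -> None:
        if not math.isfinite(self.latitude):
            raise ValueError(f"latitude of {self.name!r} is not finite")


# ---------------------------------------------------------------------------
# per-cell frequency
# ---------------------------------------------------------------------------

def frequency(f: int, g: int) -> float:
    """Percentage of observations with the change: 100*g/(f+g), full precision."""
    if f < 0 or g < 0:
        raise ValueError("counts must be non-negative")
    if f + g == 0:
        raise UndefinedFrequencyError("frequency undefined for f + g = 0")
    return 100.0 * g / (f + g)


def round_half_away(value: float, ndigits: int = 2) -> float:
    """Round half away from zero (ties like 0.125 -> 0.13, not banker's)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def frequency_display(f: int, g: int, ndigits: int = 2) -> str:
    """Exact display rounding of 100*g/(f+g), computed in decimal arithmetic."""
    if f + g == 0:
        raise UndefinedFrequencyError("frequency undefined for f + g = 0")
    q = Decimal(1).scaleb(-ndigits)
    return str((Decimal(100 * g) / Decimal(f + g)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def _effect_row_label(eff: VariantEffect) -> str:
    if eff.label is None:
        return f"g.{eff.genomic_position}"
    return eff.label


def build_frequency_table(
    effects: Sequence[VariantEffect],
    populations: Sequence[str] | Sequence[PopulationInfo],
) -> pd.DataFrame:
    """Variant x population percentage table; NaN marks undetected cells."""
    pop_names = [p.name if isinstance(p, PopulationInfo) else p for p in populations]
    data = {}
    for eff in effects:
        row = {}
        for pop in pop_names:
            if pop in eff.counts:
                f, g = eff.counts[pop]
                row[pop] = frequency(f, g) if f + g > 0 else np.nan
            else:
                row[pop] = np.nan
        data[_effect_row_label(eff)] = row
    table = pd.DataFrame.from_dict(data, orient="index", columns=pop_names)
    table.index.name = "variant"
    return table


def build_presence_matrix(
    effects: Sequence[VariantEffect],
    populations: Sequence[str] | Sequence[PopulationInfo],
) -> pd.DataFrame:
    """Boolean variant x population matrix: counts reported for the cell.

    Presence means the cell was reported at all; a reported cell with g = 0
    would still count as present (present-but-unchanged) — such cells are
    surfaced by :func:`presence_summary` as ``zero_change_cells``.
    """
    pop_names = [p.name if isinstance(p, PopulationInfo) else p for p in populations]
    data = {}
    for eff in effects:
        data[_effect_row_label(eff)] = {p: p in eff.counts for p in pop_names}
    mat = pd.DataFrame.from_dict(data, orient="index", columns=pop_names)
    mat.index.name = "variant"
    return mat


@dataclass(frozen=True)
class PresenceSummary:
    shared_in_all: int
    unique_to_one: int
    max_population: dict[str, str]   # variant -> population with highest freq
    min_population: dict[str, str]
    zero_change_cells: tuple[tuple[str, str], ...] = ()


def presence_summary(
    effects: Sequence[VariantEffect],
    populations: Sequence[str] | Sequence[PopulationInfo],
) -> PresenceSummary:
    """Shared/unique counts and per-variant extreme populations."""
    pop_names = [p.name if isinstance(p, PopulationInfo) else p for p in populations]
    if not pop_names:
        raise ValueError("at least one population required")
    presence = build_presence_matrix(effects, pop_names)
    freqs = build_frequency_table(effects, pop_names)
    shared = int((presence.sum(axis=1) == len(pop_names)).sum())
    unique = int((presence.sum(axis=1) == 1).sum())
    max_pop = {v: row.idxmax() for v, row in freqs.iterrows() if row.notna().any()}
    min_pop = {v: row.idxmin() for v, row in freqs.iterrows() if row.notna().any()}
    zero_cells = []
    for eff in effects:
        for pop, (f, g) in eff.counts.items():
            if g == 0 and f > 0:
                zero_cells.append((_effect_row_label(eff), pop))
    return PresenceSummary(
        shared_in_all=shared,
        unique_to_one=unique,
        max_population=max_pop,
        min_population=min_pop,
        zero_change_cells=tuple(zero_cells),
    )


# ---------------------------------------------------------------------------
# dN/dS
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DnDsResult:
    ratio: float
    n_ns: int
    n_s: int
    regime: str          # purifying-consistent / neutral-consistent / positive-consistent
    caveat: str = DNDS_CAVEAT


def dnds_count_ratio(n_ns: int, n_s: int) -> DnDsResult:
    """Raw nonsynonymous/synonymous segregating-site count ratio."""
    if n_ns < 0 or n_s < 0:
        raise ValueError("counts must be non-negative")
    if n_s == 0:
        raise UndefinedRatioError(
            "dN/dS undefined with zero synonymous changes (n_s = 0)"
        )
    ratio = n_ns / n_s
    if ratio < 1 - _NEUTRAL_BAND:
        regime = "purifying-consistent"
    elif ratio > 1 + _NEUTRAL_BAND:
        regime = "positive-consistent"
    else:
        regime = "neutral-consistent"
    return DnDsResult(ratio=ratio, n_ns=n_ns, n_s=n_s, regime=regime)


# ---------------------------------------------------------------------------
# latitude trend
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrendResult:
    rho: float | None
    n: int
    status: str  # "ok" | "degenerate" | "insufficient"


def latitude_trend(
    populations: Sequence[PopulationInfo],
    freqs: Mapping[str, float],
) -> TrendResult:
    """Spearman rank correlation between latitude and per-population frequency.

    Populations missing from ``freqs`` (or with NaN) are excluded pairwise;
    ties are mid-ranked.  A negative rho means the frequency increases as
    latitude decreases (toward the south).  This is an artifact-defined
    formalization of a verbal "increases with decreasing latitude" trend,
    reported without a significance claim.
    """
    lats, values = [], []
    for pop in populations:
        v = freqs.get(pop.name)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            continue
        lats.append(pop.latitude)
        values.append(float(v))
    n = len(values)
    if n < 3:
        return TrendResult(rho=None, n=n, status="insufficient")
    if len(set(values)) == 1 or len(set(lats)) == 1:
        return TrendResult(rho=0.0, n=n, status="degenerate")
    rho = float(stats.spearmanr(lats, values).statistic)
    return TrendResult(rho=rho, n=n, status="ok")


# ---------------------------------------------------------------------------
# bundle
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SummaryStats:
    frequency_table: pd.DataFrame
    presence_matrix: pd.DataFrame
    n_ns: int
    n_s: int
    dnds: DnDsResult | None
    ns_presence: PresenceSummary
    s_presence: PresenceSummary
    trend: dict[str, TrendResult] = field(default_factory=dict)


def summarize(
    effects: Sequence[VariantEffect],
    populations: Sequence[PopulationInfo],
) -> SummaryStats:
    """Full summary over annotated effects: tables, dN/dS, presence, trends."""
    ns, s, _other = partition_effects(effects)
    coding = [e for e in effects if e.effect_class in
              (EffectClass.SYNONYMOUS, EffectClass.NONSYNONYMOUS)]
    freq_table = build_frequency_table(coding, populations)
    presence = build_presence_matrix(coding, populations)
    dnds = dnds_count_ratio(len(ns), len(s)) if s else None
    trends: dict[str, TrendResult] = {}
    for eff in ns:
        label = _effect_row_label(eff)
        trends[label] = latitude_trend(
            populations, freq_table.loc[label].to_dict()
        )
    return SummaryStats(
        frequency_table=freq_table,
        presence_matrix=presence,
        n_ns=len(ns),
        n_s=len(s),
        dnds=dnds,
        ns_presence=presence_summary(ns, populations) if ns else
            PresenceSummary(0, 0, {}, {}),
        s_presence=presence_summary(s, populations) if s else
            PresenceSummary(0, 0, {}, {}),
        trend=trends,
    )
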