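"""Frequencies, presence summaries, dN/dS, latitude trend."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vgsckit.errors import UndefinedFrequencyError, UndefinedRatioError
from vgsckit.fixture import fixture_printed_cells
from vgsckit.popstats import (
    PopulationInfo,
    dnds_count_ratio,
    frequency,
    frequency_display,
    latitude_trend,
    presence_summary,
    round_half_away,
    summarize,
)
from vgsckit.variants import partition_effects


def rank_correlation_oracle(xs, ys):
    """Brute-force Spearman: mid-ranks plus Pearson on the ranks."""
    def midranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            r = (i + j) / 2 + 1
            for k in range(i, j + 1):
                ranks[order[k]] = r
            i = j + 1
        return ranks

    rx, ry = midranks(xs), midranks(ys)
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den


class TestFrequency:
    @pytest.mark.parametrize(
        "f,g,expected",
        [(11, 110, "90.91"), (0, 64, "100.00"), (5, 0, "0.00"),
         (105, 8, "7.08"), (6, 102, "94.44"), (7, 116, "94.31")],
    )
    def test_published_cells(self, f, g, expected):
        assert frequency_display(f, g) == expected

    def test_undefined(self):
        with pytest.raises(UndefinedFrequencyError):
            frequency(0, 0)

    def test_half_away_from_zero(self):
        # 1/16 = 6.25 exactly; its half-case rounds up, not to even
        assert frequency_display(15, 1, ndigits=1) == "6.3"
        assert round_half_away(0.125, 2) == 0.13

    @settings(max_examples=200, derandomize=True)
    @given(st.integers(0, 500), st.integers(0, 500), st.integers(1, 20))
    def test_scale_invariance(self, f, g, k):
        if f + g == 0:
            return
        assert frequency(k * f, k * g) == pytest.approx(frequency(f, g))

    def test_all_printed_cells_reproduce_from_counts(self):
        """Checksum over every populated table cell: recomputing e = g/(f+g)
        at 2 dp matches the printed percentage everywhere except the single
        cell whose printed value is inconsistent with its own printed counts
        (Y866/TY: 20/90 = 22.22, printed 22.23)."""
        cells = fixture_printed_cells()
        assert len(cells) == 128
        mismatches = [
            (c.variant_label, c.population)
            for c in cells
            if frequency_display(c.f, c.g) != c.printed_percent
        ]
        assert mismatches == [("Y866", "TY")]
        typo = next(c for c in cells if (c.variant_label, c.population) == ("Y866", "TY"))
        assert frequency_display(typo.f, typo.g) == "22.22"


class TestDnDs:
    def test_fixture_ratio(self):
        res = dnds_count_ratio(6, 31)
        assert round_half_away(res.ratio) == 0.19
        assert res.regime == "purifying-consistent"
        assert "caution" in res.caveat

    def test_equal_counts_neutral(self):
        res = dnds_count_ratio(3, 3)
        assert res.ratio == 1.0
        assert res.regime == "neutral-consistent"

    def test_positive(self):
        assert dnds_count_ratio(9, 3).regime == "positive-consistent"

    def test_zero_denominator_never_silently_infinite(self):
        with pytest.raises(UndefinedRatioError):
            dnds_count_ratio(5, 0)


class TestPresence:
    def test_fixture_ssnp_summary(self, annotated, bundle):
        _ns, s, _ = partition_effects(annotated)
        summary = presence_summary(s, bundle.populations)
        assert summary.shared_in_all == 14
        assert summary.unique_to_one == 7
        assert summary.zero_change_cells == ()

    def test_fixture_nssnp_summary(self, annotated, bundle):
        ns, _s, _ = partition_effects(annotated)
        summary = presence_summary(ns, bundle.populations)
        assert summary.shared_in_all == 3
        assert summary.unique_to_one == 2  # T933I and D2036E, both TS-only
        assert summary.max_population["M922T"] == "JY"
        assert summary.min_population["M922T"] == "MY"

    def test_single_population_degenerate(self, annotated):
        _ns, s, _ = partition_effects(annotated)
        detected_in_ts = [e for e in s if "TS" in e.counts]
        summary = presence_summary(detected_in_ts, ["TS"])
        assert summary.shared_in_all == summary.unique_to_one == len(detected_in_ts)


class TestLatitudeTrend:
    POPS = (
        PopulationInfo("MY", 18.94, 109.51),
        PopulationInfo("TS", 18.79, 109.52),
        PopulationInfo("DA", 18.47, 108.90),
        PopulationInfo("TY", 18.31, 109.48),
        PopulationInfo("JY", 18.29, 109.54),
    )

    def test_perfectly_monotone_south_increase(self):
        freqs = {"MY": 58.46, "TS": 62.07, "DA": 72.09, "TY": 80.58, "JY": 90.91}
        res = latitude_trend(self.POPS, freqs)
        assert res.status == "ok"
        assert res.rho == pytest.approx(-1.0)

    def test_non_monotone_against_rank_oracle(self):
        freqs = {"MY": 36.54, "TS": 86.27, "DA": 80.00, "TY": 79.55, "JY": 96.52}
        res = latitude_trend(self.POPS, freqs)
        expected = rank_correlation_oracle(
            [p.latitude for p in self.POPS], [freqs[p.name] for p in self.POPS]
        )
        assert res.rho == pytest.approx(expected)
        assert res.rho == pytest.approx(-0.6)

    def test_constant_frequencies_degenerate(self):
        res = latitude_trend(self.POPS, {p.name: 100.0 for p in self.POPS})
        assert res.status == "degenerate"
        assert res.rho == 0.0

    def test_missing_populations_excluded_pairwise(self):
        res = latitude_trend(self.POPS, {"TS": 10.0, "DA": 20.0, "JY": 30.0,
                                         "MY": float("nan")})
        assert res.n == 3 and res.status == "ok"

    def test_insufficient_data(self):
        res = latitude_trend(self.POPS, {"TS": 8.57})
        assert res.status == "insufficient" and res.rho is None

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_antisymmetric_under_latitude_negation(self, seed):
        rng = np.random.default_rng(seed)
        lats = rng.uniform(-30, 30, size=5)
        freqs = rng.uniform(0, 100, size=5)
        pops = [PopulationInfo(f"P{i}", float(l), 0.0) for i, l in enumerate(lats)]
        flipped = [PopulationInfo(p.name, -p.latitude, 0.0) for p in pops]
        fmap = {p.name: float(f) for p, f in zip(pops, freqs)}
        a, b = latitude_trend(pops, fmap), latitude_trend(flipped, fmap)
        if a.status == "ok":
            assert a.rho == pytest.approx(-b.rho)


class TestSummarize:
    def test_fixture_summary_bundle(self, annotated, bundle):
        stats = summarize(annotated, bundle.populations)
        assert (stats.n_ns, stats.n_s) == (6, 31)
        assert stats.dnds.ratio == pytest.approx(6 / 31)
        assert stats.frequency_table.shape == (37, 5)
        # global sSNP maximum: G2033 in JY at 94.44%
        s_rows = stats.frequency_table.loc[
            [e.label for e in annotated if e.label and e.label[0] == e.label[-1]]
        ]
        idx = s_rows.stack().idxmax()
        assert idx == ("G2033G", "JY")
        assert round_half_away(s_rows.stack().max()) == 94.44
        assert stats.trend["M922T"].rho == pytest.approx(-1.0)
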