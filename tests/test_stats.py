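"""Transformed medians, shifts, IdU reporting rule, bootstrap, star bins."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cytosynth import population_stats as ps
from cytosynth.io_core import ChannelDef, EventTable


class TestTransformedMedian:
    def test_zeros(self):
        assert ps.transformed_median(np.zeros(3)) == 0.0

    def test_singleton_inverse_construction(self):
        assert ps.transformed_median([5 * np.sinh(1.0)]) == pytest.approx(1.0)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            ps.transformed_median([])


class TestMedianShift:
    def test_identical_populations_shift_zero(self):
        x = np.array([1.0, 5.0, 9.0])
        assert ps.median_shift(x, x) == 0.0

    def test_closed_form(self):
        pop = np.full(11, 20.0)
        control = np.full(11, 10.0)
        expected = np.arcsinh(4.0) - np.arcsinh(2.0)
        assert ps.median_shift(pop, control) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.651077, abs=1e-6)

    @settings(max_examples=30, deadline=None)
    @given(
        a=st.lists(st.floats(0, 1e4), min_size=1, max_size=30),
        b=st.lists(st.floats(0, 1e4), min_size=1, max_size=30),
    )
    def test_antisymmetric(self, a, b):
        assert ps.median_shift(a, b) == pytest.approx(-ps.median_shift(b, a), abs=1e-9)


def _idu_table(n_pos, n_neg):
    values = np.concatenate([np.full(n_pos, 50.0), np.zeros(n_neg)])[:, None]
    return EventTable(values=values, channels=[ChannelDef("IdU", kind="biosynthesis")])


class TestIdUFractionReport:
    def test_below_four_percent_no_split(self):
        fraction, split = ps.idu_fraction_report(_idu_table(3, 97))
        assert fraction == pytest.approx(0.03)
        assert split is None

    def test_exactly_at_boundary_no_split(self):
        fraction, split = ps.idu_fraction_report(_idu_table(4, 96))
        assert fraction == pytest.approx(0.04)
        assert split is None  # rule requires strictly greater than 4%

    def test_above_four_percent_split_partitions_parent(self):
        fraction, split = ps.idu_fraction_report(_idu_table(5, 95))
        assert fraction == pytest.approx(0.05)
        pos, neg = split
        assert pos.n_events + neg.n_events == 100
        assert pos.n_events == 5


class TestBootstrapMedian:
    def test_constant_vector_point_ci(self):
        s = ps.bootstrap_median(np.full(50, 7.0), seed=0)
        assert (s.ci_low, s.boot_median, s.ci_high) == (7.0, 7.0, 7.0)
        assert s.R == 1000

    def test_same_seed_same_interval(self):
        x = np.random.default_rng(1).normal(size=200)
        a = ps.bootstrap_median(x, seed=5)
        b = ps.bootstrap_median(x, seed=5)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            ps.bootstrap_median(np.array([]))

    def test_ci_width_shrinks_like_root_n(self):
        rng = np.random.default_rng(7)
        params = ps.StatParams(bootstrap_R=400)
        widths = {n: [] for n in (100, 200)}
        for rep in range(60):
            for n in widths:
                x = rng.normal(size=n)
                s = ps.bootstrap_median(x, params, seed=rep)
                widths[n].append(s.ci_high - s.ci_low)
        factor = np.mean(widths[200]) / np.mean(widths[100])
        assert 0.6 <= factor <= 0.8


class TestShiftTable:
    def _groups(self):
        rng = np.random.default_rng(0)
        groups = {}
        for pop in ("B", "T"):
            for cond, scale in (("0h", 1.0), ("1h", 3.0)):
                groups[(pop, cond)] = rng.poisson(100 * scale, size=(500, 2)).astype(float)
        return groups

    def test_control_column_identically_zero(self):
        table = ps.shift_table(self._groups(), ["BRU", "Puromycin"], "0h")
        ctrl = table.xs("0h", level="condition")
        assert (ctrl == 0).all().all()

    def test_upshifted_condition_positive(self):
        table = ps.shift_table(self._groups(), ["BRU", "Puromycin"], "0h")
        assert (table.xs("1h", level="condition") > 0.5).all().all()

    def test_missing_population_is_nan_not_zero(self):
        groups = self._groups()
        del groups[("T", "1h")]
        table = ps.shift_table(groups, ["BRU", "Puromycin"], "0h")
        assert table.loc[("T", "1h")].isna().all()

    def test_unknown_control_errors(self):
        with pytest.raises(ValueError, match="control"):
            ps.shift_table(self._groups(), ["BRU"], "nope")


class TestStarBins:
    @pytest.mark.parametrize(
        "p,stars",
        [
            (0.5, ""),
            (1e-7, ""),  # boundary values fall in the weaker bin
            (1e-10, "*"),
            (1e-14, "*"),
            (1e-20, "**"),
            (1e-21, "**"),
            (1e-27, "***"),
            (1e-28, "***"),
            (1e-30, "****"),
            (0.0, "****"),
        ],
    )
    def test_bins(self, p, stars):
        assert ps.star_bins(p) == stars

    def test_invalid_probability(self):
        with pytest.raises(ValueError):
            ps.star_bins(1.5)
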