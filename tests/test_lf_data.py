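"""Length-frequency construction and catch-length indicators."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lbb import (
    LengthFrequency,
    LengthRecord,
    assign_class_interval,
    build_length_frequency,
    compute_length_indicators,
)
from lbb.lf_data import read_lf_csv, write_lf_csv


@pytest.mark.parametrize(
    "l_max, expected",
    [
        (51.0, 2.0),  # largest species
        (10.2, 0.3),  # small species
        (12.0, 0.3),  # boundary: rule is l_max <= 12
        (12.1, 0.5),
        (20.0, 0.5),
        (20.5, 1.0),
        (35.0, 1.0),
        (35.1, 2.0),
    ],
)
def test_class_interval_step_rule(l_max, expected):
    assert assign_class_interval(l_max) == expected


@pytest.mark.parametrize("bad", [0.0, -3.0, float("nan"), float("inf")])
def test_class_interval_rejects_invalid_lengths(bad):
    with pytest.raises(ValueError):
        assign_class_interval(bad)


def test_class_interval_reproduces_survey_table(survey_priors):
    """The step rule reproduces every published class interval from L_max."""
    got = survey_priors["max_cm"].map(assign_class_interval)
    assert (got == survey_priors["class_interval_cm"]).all()


def _records(lengths, species="sp", year=2024):
    return [LengthRecord(species, year, l) for l in lengths]


class TestBuildLengthFrequency:
    def test_small_sample_binning(self):
        lf = build_length_frequency(_records([5.0, 5.1, 11.9]), "sp", 2024)
        assert lf.class_interval_cm == 0.3
        assert lf.n_total == 3
        assert lf.bin_midpoints[0] - lf.class_interval_cm / 2 <= 5.0
        assert lf.bin_midpoints[-1] + lf.class_interval_cm / 2 >= 11.9

    def test_interval_follows_max_length(self):
        rng = np.random.default_rng(0)
        lengths = np.clip(rng.normal(12, 3, 396), 5.5, 18.5)
        lengths[0], lengths[1] = 5.5, 18.5
        lf = build_length_frequency(_records(lengths, year=2019), "sp", 2019)
        assert lf.class_interval_cm == 0.5
        assert lf.n_total == 396

    def test_top_edge_record_is_kept(self):
        # a fish exactly on the upper edge of the last bin is included
        lf = build_length_frequency(_records([9.7, 10.0, 10.2, 10.5]), "sp", 2024)
        assert lf.n_total == 4

    def test_empty_input_raises(self):
        with pytest.raises(ValueError, match="no records"):
            build_length_frequency([], "sp", 2024)

    def test_single_class_raises(self):
        with pytest.raises(ValueError, match="non-empty bins"):
            build_length_frequency(_records([10.0, 10.01]), "sp", 2024)

    @given(st.lists(st.floats(min_value=0.5, max_value=60.0), min_size=2, max_size=300))
    def test_count_conservation(self, lengths):
        try:
            lf = build_length_frequency(_records(lengths), "sp", 2024)
        except ValueError:
            return  # all lengths in one class: rejected by construction
        assert lf.n_total == len(lengths)


class TestLengthIndicators:
    def test_degenerate_single_bin(self):
        lf = LengthFrequency("sp", 2024, 1.0, np.array([10.0]), np.array([100]))
        ind = compute_length_indicators(lf, l_c=0.0)
        assert ind.l_mean_cm == pytest.approx(10.0)
        assert ind.l_95th_cm == pytest.approx(10.45)  # within the only bin
        assert not ind.degenerate

    def test_single_contributing_bin(self):
        lf = LengthFrequency("sp", 2024, 1.0, np.array([10.0, 11.0, 12.0]),
                             np.array([0, 0, 50]))
        ind = compute_length_indicators(lf, l_c=11.5)
        assert ind.l_mean_cm == pytest.approx(12.0)

    def test_no_catch_above_lc_is_flagged(self):
        lf = LengthFrequency("sp", 2024, 1.0, np.array([10.0, 11.0]), np.array([5, 5]))
        ind = compute_length_indicators(lf, l_c=50.0)
        assert ind.degenerate
        assert np.isnan(ind.l_mean_cm)

    def test_95th_percentile_against_expanded_oracle(self):
        """Weighted within-bin-interpolated percentile agrees with a brute
        force percentile over the expanded per-individual list (individuals
        placed at uniform quantile offsets inside their bin)."""
        mids = np.arange(10.0, 21.0)
        counts = np.full(11, 40)
        lf = LengthFrequency("sp", 2024, 1.0, mids, counts)
        ind = compute_length_indicators(lf, l_c=0.0)
        expanded = np.concatenate([
            mid - 0.5 + (np.arange(c) + 0.5) / c for mid, c in zip(mids, counts)
        ])
        oracle = np.quantile(expanded, 0.95)
        assert ind.l_mean_cm == pytest.approx(15.0)
        assert ind.l_95th_cm == pytest.approx(oracle, abs=0.05)

    def test_l_mean_monotone_in_lc(self):
        rng = np.random.default_rng(3)
        lf = build_length_frequency(
            _records(np.round(rng.gamma(8, 1.5, 500) + 4, 1)), "sp", 2024)
        lcs = np.linspace(0, 15, 16)
        means = [compute_length_indicators(lf, lc).l_mean_cm for lc in lcs]
        assert all(a <= b + 1e-12 for a, b in zip(means, means[1:]))

    def test_ordering_invariant(self, fished_lf):
        ind = compute_length_indicators(fished_lf, l_c=0.0)
        assert ind.l_mean_cm <= ind.l_95th_cm <= ind.l_max_cm


def test_lf_csv_round_trip(tmp_path, fished_lf):
    path = tmp_path / "lf.csv"
    write_lf_csv(fished_lf, path)
    back = read_lf_csv(path)[0]
    assert back.species_id == fished_lf.species_id
    np.testing.assert_allclose(back.bin_midpoints, fished_lf.bin_midpoints)
    np.testing.assert_array_equal(back.counts, fished_lf.counts)


def test_invalid_length_frequency_rejected():
    with pytest.raises(ValueError):
        LengthFrequency("sp", 2024, 1.0, np.array([10.0, 12.5]), np.array([3, 4]))
    with pytest.raises(ValueError):
        LengthFrequency("sp", 2024, 1.0, np.array([10.0, 11.0]), np.array([3, -1]))


def test_length_record_validation():
    with pytest.raises(ValueError):
        LengthRecord("sp", 2024, -1.0)
    with pytest.raises(ValueError):
        LengthRecord("sp", 2024, 10.0, weight_g=0.0)
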