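"""Frameshift assay arithmetic: normalization, ratios, activity, summaries."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from riboframe import fsquant
from riboframe.fsquant import (LaneQuant, activity, count_internal_met,
                               frameshift_stats, normalized_amounts,
                               ratio_from_percent, summarize)


def test_methionine_normalization():
    lane = LaneQuant("x", 90.0, 30.0, 9, 6)
    assert normalized_amounts(lane) == (10.0, 5.0)


def test_zero_frameshift_band():
    lane = LaneQuant("x", 50.0, 0.0, 5, 3)
    full, fs = normalized_amounts(lane)
    p, r = frameshift_stats(full, fs)
    assert (p, r) == (0.0, 0.0)


def test_invalid_met_count_rejected():
    with pytest.raises(ValueError):
        LaneQuant("x", 1.0, 1.0, 0, 3)


@pytest.mark.parametrize("percent,expected_ratio", [
    (33.8, 0.51),   # wild-type tight-couple level
    (55.4, 1.24),   # abasic-1503 level
])
def test_percent_to_ratio_identity_at_reported_levels(percent, expected_ratio):
    """Percent frameshift and the -1/0-frame ratio are two views of the
    same quantity: ratio = p / (100 - p), rounded to 2 decimals."""
    assert round(ratio_from_percent(percent), 2) == expected_ratio
    # and frameshift_stats reproduces the same pair from raw amounts
    fs = percent
    full = 100.0 - percent
    p, r = frameshift_stats(full, fs)
    assert p == pytest.approx(percent, abs=1e-9)
    assert round(r, 2) == expected_ratio


def test_both_bands_zero_is_undefined():
    with pytest.raises(ValueError):
        frameshift_stats(0.0, 0.0)


def test_zero_full_length_flagged_infinite():
    _, r = frameshift_stats(0.0, 5.0)
    assert math.isinf(r)


class TestActivity:
    def test_equal_totals_give_unity(self):
        lane = LaneQuant("x", 40.0, 20.0, 4, 2)      # amounts 10 + 10
        ctrl = LaneQuant("c", 50.0, 100.0, 5, 10)    # amounts 10 + 10
        assert activity(lane, ctrl) == pytest.approx(1.0)

    def test_constructed_fraction(self):
        ctrl = LaneQuant("c", 100.0, 0.0, 1, 1)
        lane = LaneQuant("x", 71.0, 0.0, 1, 1)
        assert activity(lane, ctrl) == pytest.approx(0.71)

    def test_zero_control_rejected(self):
        with pytest.raises(ValueError):
            activity(LaneQuant("x", 1.0, 1.0, 1, 1), LaneQuant("c", 0.0, 0.0, 1, 1))


class TestInternalMet:
    @pytest.mark.parametrize("seq,expected", [
        ("MAMKM", 2),
        ("MAAA", 0),
        ("AMMM", 3),  # no initiator Met: all are internal
    ])
    def test_examples(self, seq, expected):
        assert count_internal_met(seq) == expected

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValueError):
            count_internal_met("MABZ")

    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=80))
    @settings(max_examples=200, derandomize=True)
    def test_matches_brute_force_scan(self, seq):
        assert count_internal_met(seq) == sum(1 for c in seq[1:] if c == "M")

    def test_translation_products_of_slippery_mrna(self):
        """0-frame vs -1-frame products of a toy message with a GAAAAAAG
        slippery site, translated independently with biopython."""
        from Bio.Seq import Seq

        mrna = "ATGGCTATGGAAAAAAGCATGAAAATGTAAGGG"
        zero = str(Seq(mrna).translate(to_stop=True))
        # -1 slip at the slippery site: re-read from one base upstream
        slip_at = mrna.index("GAAAAAAG") + len("GAAAAAAG")
        shifted = mrna[:slip_at] + mrna[slip_at - 1:]
        minus1 = str(Seq(shifted).translate(to_stop=True))
        assert count_internal_met(zero) == zero[1:].count("M")
        assert count_internal_met(minus1) == minus1[1:].count("M")


class TestSummarize:
    def test_constant_replicates(self):
        assert summarize([0.5, 0.5, 0.5]) == (0.5, 0.0)

    def test_two_replicates(self):
        mean, sem = summarize([0.4, 0.6])
        assert mean == pytest.approx(0.5)
        assert sem == pytest.approx(0.1)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(12)
        vals = rng.uniform(0.2, 1.5, 8)
        mean, sem = summarize(vals)
        assert mean == pytest.approx(vals.sum() / 8)
        sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / 7)
        assert sem == pytest.approx(sd / math.sqrt(8))

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            summarize([0.5])


def test_mean_of_ratios_differs_from_ratio_of_means():
    """Replicate ratios are averaged per replicate; recomputing the ratio
    from the mean percent gives a different (wrong) number when replicates
    vary."""
    percents = [30.0, 55.0]
    mean_ratio = np.mean([ratio_from_percent(p) for p in percents])
    ratio_of_mean = ratio_from_percent(float(np.mean(percents)))
    assert mean_ratio != pytest.approx(ratio_of_mean, rel=1e-3)


@given(st.floats(min_value=0.1, max_value=1000.0))
@settings(max_examples=50, derandomize=True)
def test_scale_invariance_of_all_outputs(scale):
    base = LaneQuant("x", 60.0, 30.0, 6, 3)
    ctrl = LaneQuant("c", 80.0, 10.0, 8, 2)
    scaled = LaneQuant("x", 60.0 * scale, 30.0 * scale, 6, 3)
    ctrl_s = LaneQuant("c", 80.0 * scale, 10.0 * scale, 8, 2)
    p0, r0 = frameshift_stats(*normalized_amounts(base))
    p1, r1 = frameshift_stats(*normalized_amounts(scaled))
    assert p1 == pytest.approx(p0, rel=1e-9)
    assert r1 == pytest.approx(r0, rel=1e-9)
    assert activity(scaled, ctrl_s) == pytest.approx(activity(base, ctrl), rel=1e-9)


def test_quantify_constructs_table_shape():
    rng = np.random.default_rng(3)
    rows = []
    for construct, p_true in (("wt", 33.8), ("abasic", 55.4)):
        for rep in range(4):
            fs = p_true + rng.normal(0, 1.0)
            rows.append({"construct": construct, "replicate": rep,
                         "intensity_full": (100 - fs) * 9, "intensity_fs": fs * 6})
    lanes = pd.DataFrame(rows)
    table = fsquant.quantify_constructs(lanes, {"wt": (9, 6), "abasic": (9, 6)},
                                        control="wt")
    assert list(table.index) == ["wt", "abasic"]
    assert table.loc["wt", "percent_fs"] == pytest.approx(33.8, abs=1.5)
    assert table.loc["abasic", "percent_fs"] == pytest.approx(55.4, abs=1.5)
    assert table.loc["wt", "activity"] == pytest.approx(1.0, abs=0.05)
    for construct in table.index:
        p = table.loc[construct, "percent_fs"]
        assert table.loc[construct, "ratio_fs"] == pytest.approx(
            p / (100 - p), abs=0.05)
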