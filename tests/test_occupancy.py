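"""Occupancy scanning: point data, window tests, dual FDR, regions, scoring."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from chipbs.errors import ParameterError
from chipbs.io import AnnotatedElement
from chipbs.methylation import ReadAlignmentRecord
from chipbs.occupancy import (
    PointData,
    attach_fdr,
    binomial_tail_p,
    intersect_annotation,
    make_regions,
    scan_windows,
    score_elements,
    to_point_data,
)

CONTIGS = {"c": 10_000}


def _rec(start, strand="+", weight=1.0, length=50):
    return ReadAlignmentRecord(
        read_id=f"r{start}{strand}",
        contig="c",
        start=start,
        strand=strand,
        bisulfite_strand="OT" if strand == "+" else "OB",
        sequence="A" * length,
        n_alignments=1,
        weight=weight,
    )


def _points(positions, weights=None, contig="c"):
    positions = np.asarray(positions, dtype=np.int64)
    order = np.argsort(positions)
    w = np.ones(len(positions)) if weights is None else np.asarray(weights, float)
    return PointData(
        positions={contig: positions[order]},
        weights={contig: w[order]},
        library_size=float(w.sum()),
    )


class TestPointData:
    def test_plus_strand_shift(self):
        pd_ = to_point_data([_rec(1000)], 116, CONTIGS)
        assert pd_.positions["c"][0] == 1058

    def test_minus_strand_shift(self):
        pd_ = to_point_data([_rec(1000, strand="-", length=50)], 116, CONTIGS)
        assert pd_.positions["c"][0] == 1050 - 58

    def test_zero_shift_identity(self):
        pd_ = to_point_data([_rec(1000), _rec(2000, strand="-", length=50)], 0, CONTIGS)
        assert list(pd_.positions["c"]) == [1000, 2050]

    def test_weight_conservation(self):
        records = [_rec(100 * i, weight=1.0 / 3) for i in range(30)]
        pd_ = to_point_data(records, 116, CONTIGS)
        assert pd_.library_size == pytest.approx(sum(r.weight for r in records))

    def test_clipping_to_bounds(self):
        pd_ = to_point_data([_rec(9990)], 116, CONTIGS)
        assert pd_.positions["c"][0] == CONTIGS["c"] - 1


class TestScanWindows:
    def test_symmetric_counts_zero_log2(self):
        chip = _points([100] * 20)
        inp = _points([100] * 20)
        win = scan_windows(chip, inp, {"c": 1000}, 300, 150)
        row = win[win["start"] == 0].iloc[0]
        assert row["log2_ratio"] == pytest.approx(0.0)

    def test_log2_closed_form(self):
        chip = _points([100] * 20 + [5000] * 5)
        inp = _points([100] * 5 + [5000] * 20)
        win = scan_windows(chip, inp, {"c": 6000}, 300, 300)
        row = win[win["start"] == 0].iloc[0]
        assert row["log2_ratio"] == pytest.approx(np.log2(20.5 / 5.5))

    def test_binomial_tail_exact(self):
        p = binomial_tail_p(np.array([20]), np.array([25]), 0.5)[0]
        oracle = float(sum(Fraction(comb(25, k), 2**25) for k in range(20, 26)))
        assert p == pytest.approx(oracle, abs=1e-12)

    def test_binomial_oracle_batch(self):
        """Exact tail-sum enumeration agreement to 1e-10 for counts <= 200."""
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(1, 201))
            k = int(rng.integers(0, n + 1))
            p0 = float(rng.uniform(0.1, 0.9))
            p = binomial_tail_p(np.array([k]), np.array([n]), p0)[0]
            oracle = sum(
                comb(n, j) * (p0**j) * ((1 - p0) ** (n - j)) for j in range(k, n + 1)
            )
            assert abs(p - min(oracle, 1.0)) < 1e-10

    def test_empty_window_omitted(self):
        win = scan_windows(_points([100]), _points([150]), {"c": 2000}, 300, 300)
        assert set(win["start"]) == {0}

    def test_invalid_window_size(self):
        with pytest.raises(ParameterError):
            scan_windows(_points([1]), _points([1]), {"c": 100}, 0)

    def test_swap_antisymmetry(self):
        rng = np.random.default_rng(1)
        chip = _points(rng.integers(0, 5000, size=300))
        inp = _points(rng.integers(0, 5000, size=500))
        fwd = scan_windows(chip, inp, {"c": 5000}, 300, 150)
        rev = scan_windows(inp, chip, {"c": 5000}, 300, 150)
        merged = fwd.merge(rev, on=["contig", "start"], suffixes=("_f", "_r"))
        assert len(merged) == len(fwd)
        np.testing.assert_allclose(
            merged["log2_ratio_f"], -merged["log2_ratio_r"], atol=1e-12
        )


class TestFdr:
    def test_single_window_bh_identity(self):
        win = pd.DataFrame(
            {"contig": ["c"], "start": [0], "end": [300], "chip_sum": [5.0],
             "input_sum": [0.0], "log2_ratio": [2.0], "p_value": [0.01]}
        )
        out = attach_fdr(win, win.iloc[0:0])
        assert out["q_phred"].iloc[0] == pytest.approx(20.0)

    def test_bh_step_up_oracle(self):
        win = pd.DataFrame(
            {"contig": "c", "start": [0, 150, 300], "end": [300, 450, 600],
             "chip_sum": 1.0, "input_sum": 1.0, "log2_ratio": 0.0,
             "p_value": [0.01, 0.02, 0.04]}
        )
        out = attach_fdr(win, win.iloc[0:0])
        np.testing.assert_allclose(
            10 ** (-out["q_phred"].to_numpy() / 10), [0.03, 0.03, 0.04], atol=1e-12
        )

    def test_empirical_fdr_ratio_oracle(self):
        real = pd.DataFrame(
            {"contig": "c", "start": np.arange(20) * 300, "end": np.arange(20) * 300 + 300,
             "chip_sum": 1.0, "input_sum": 1.0, "log2_ratio": 0.0, "p_value": 0.001}
        )
        swapped = real.iloc[:2].copy()
        out = attach_fdr(real, swapped)
        # 2 swapped vs 20 real passing -> eFDR 0.1 -> 10 phred
        np.testing.assert_allclose(out["efdr_phred"], 10.0, atol=1e-9)

    def test_efdr_numerator_floor(self):
        real = pd.DataFrame(
            {"contig": "c", "start": [0], "end": [300], "chip_sum": 1.0,
             "input_sum": 0.0, "log2_ratio": 1.0, "p_value": [1e-30]}
        )
        out = attach_fdr(real, real.assign(p_value=0.9))
        assert out["efdr_phred"].iloc[0] == pytest.approx(0.0)  # max(1,0)/1 = 1


class TestRegions:
    @staticmethod
    def _window_frame(rows):
        return pd.DataFrame(
            rows, columns=["contig", "start", "end", "p_value", "log2_ratio", "q_phred", "efdr_phred"]
        )

    def test_no_passing_windows(self):
        win = self._window_frame([("c", 0, 300, 0.5, 0.1, 3.0, 0.0)])
        assert make_regions(win).empty

    def test_overlapping_windows_merge(self):
        win = self._window_frame(
            [
                ("c", 0, 300, 1e-9, 2.0, 90.0, 50.0),
                ("c", 150, 450, 1e-8, 2.0, 80.0, 50.0),
            ]
        )
        regions = make_regions(win)
        assert len(regions) == 1
        assert (regions.iloc[0]["start"], regions.iloc[0]["end"]) == (0, 450)
        assert regions.iloc[0]["n_windows"] == 2
        assert regions.iloc[0]["best_p"] == 1e-9

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(2)
        rows = [
            ("c", 150 * i, 150 * i + 300, rng.uniform(), rng.uniform(-2, 4),
             rng.uniform(0, 100), rng.uniform(0, 100))
            for i in range(200)
        ]
        win = self._window_frame(rows)
        base = len(make_regions(win, 20, 13, 1))
        for q, e, l2 in [(30, 13, 1), (20, 20, 1), (20, 13, 2), (70, 40, 3)]:
            assert len(make_regions(win, q, e, l2)) <= base


def _elements(spans, contig="c"):
    return [
        AnnotatedElement(contig, s, e, "+", f"el{i}", "famA", "SINE")
        for i, (s, e) in enumerate(spans)
    ]


class TestAnnotation:
    def test_region_spanning_element_flags_it(self):
        regions = pd.DataFrame({"contig": ["c"], "start": [100], "end": [400]})
        tallies, flagged = intersect_annotation(regions, _elements([(100, 400)]))
        assert tallies["SINE"] == 1 and len(flagged) == 1

    def test_region_over_two_adjacent_elements(self):
        regions = pd.DataFrame({"contig": ["c"], "start": [250], "end": [550]})
        _, flagged = intersect_annotation(regions, _elements([(100, 300), (300, 600)]))
        assert set(flagged["element_id"]) == {"el0", "el1"}

    def test_touching_region_does_not_flag(self):
        regions = pd.DataFrame({"contig": ["c"], "start": [300], "end": [600]})
        _, flagged = intersect_annotation(regions, _elements([(100, 300)]))
        assert flagged.empty

    def test_empty_regions_zero_tallies(self):
        tallies, flagged = intersect_annotation(
            pd.DataFrame(columns=["contig", "start", "end"]), _elements([(0, 100)])
        )
        assert tallies.sum() == 0 and flagged.empty


class TestElementScores:
    def test_element_equals_window_when_spans_match(self):
        rng = np.random.default_rng(3)
        chip = _points(rng.integers(0, 600, size=200))
        inp = _points(rng.integers(0, 600, size=200))
        win = scan_windows(chip, inp, {"c": 600}, 300, 300)
        scores = score_elements(_elements([(0, 300)]), chip, inp)
        wrow = win[win["start"] == 0].iloc[0]
        srow = scores.iloc[0]
        assert srow["chip_sum"] == wrow["chip_sum"]
        assert srow["input_sum"] == wrow["input_sum"]
        assert srow["occupancy_score"] == pytest.approx(wrow["log2_ratio"])
        assert srow["p_value"] == pytest.approx(wrow["p_value"])

    def test_zero_coverage_flagged(self):
        scores = score_elements(_elements([(0, 300)]), _points([500]), _points([500]))
        assert not scores.iloc[0]["has_coverage"]
        assert not scores.iloc[0]["high_confidence"]
        assert np.isfinite(scores.iloc[0]["occupancy_score"])

    def test_occupied_score_higher_on_simulation(self, occupancy_sim):
        cfg = occupancy_sim.config
        lens = {k: len(v) for k, v in occupancy_sim.genome.items()}
        chip = to_point_data(occupancy_sim.records["chip"], cfg.fragment_len_mean // 1, lens)
        inp = to_point_data(occupancy_sim.records["input"], cfg.fragment_len_mean // 1, lens)
        scores = score_elements(occupancy_sim.annotation, chip, inp)
        occupied = set(occupancy_sim.truth.occupied_loci["element_id"])
        occ = scores[scores["element_id"].isin(occupied)]["occupancy_score"]
        rest = scores[~scores["element_id"].isin(occupied)]["occupancy_score"]
        assert occ.mean() > rest.mean() + 1.0


def test_null_calibration(null_sim):
    """With occupancy fold 1 the windows at Q-phred >= 20 are <= 1% + noise."""
    cfg = null_sim.config
    lens = {k: len(v) for k, v in null_sim.genome.items()}
    chip = to_point_data(null_sim.records["chip"], 116, lens)
    inp = to_point_data(null_sim.records["input"], 116, lens)
    win = scan_windows(chip, inp, lens, 300, 150, exclude_contigs=(cfg.spike_in_name,))
    swapped = scan_windows(inp, chip, lens, 300, 150, exclude_contigs=(cfg.spike_in_name,))
    win = attach_fdr(win, swapped)
    frac = (win["q_phred"] >= 20).mean()
    assert frac <= 0.01 + 3 * np.sqrt(0.01 * 0.99 / len(win))
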