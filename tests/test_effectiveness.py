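"""Tool-specific transmissibility values, percent reductions and match classification."""

import math

import numpy as np
import pandas as pd
import pytest

from vibroglove import (
    classify_matches,
    full_finger_result,
    make_band_grid,
    percent_reduction,
    render_report,
    tool_specific_values,
    wh_weights,
)
from vibroglove.effectiveness import EffectivenessResult, round_half_away
from vibroglove.fixtures import load_fixture

from .conftest import make_spectrum, make_tool, random_spectrum, random_tool


def naive_tool_values(ty, txz, tool, wh):
    """Independent per-band loop evaluation of the energy-weighted T values."""
    ny = dy = nxz = dxz = nt = dt = 0.0
    for i in range(len(wh)):
        w2 = wh[i] ** 2
        ey = tool.ay[i] ** 2 * w2
        exz = (tool.ax[i] ** 2 + tool.az[i] ** 2) * w2
        ny += ty[i] ** 2 * ey
        dy += ey
        nxz += txz[i] ** 2 * exz
        dxz += exz
        nt += ty[i] ** 2 * ey + txz[i] ** 2 * exz
        dt += ey + exz
    return (
        math.sqrt(ny / dy) if dy > 0 else math.nan,
        math.sqrt(nxz / dxz) if dxz > 0 else math.nan,
        math.sqrt(nt / dt),
    )


def glove_pair(rng, grid, lo=0.3, hi=1.8, glove="g1", location="fingertip"):
    ty = random_spectrum(rng, grid, lo, hi, glove=glove, location=location, direction="y")
    txz = random_spectrum(rng, grid, lo, hi, glove=glove, location=location, direction="xz")
    return ty, txz


class TestToolSpecificValues:
    def test_single_band_energy_cancels(self, assess_grid):
        rng = np.random.default_rng(0)
        ty, txz = glove_pair(rng, assess_grid)
        n = len(assess_grid)
        k = assess_grid.index_of(100.0)
        ax = np.zeros(n); ax[k] = 3.0
        ay = np.zeros(n); ay[k] = 5.0
        az = np.zeros(n); az[k] = 4.0
        tool = make_tool(assess_grid, ax, ay, az)
        for mode in ("unity", "iso_wh"):
            res = tool_specific_values(ty, txz, tool, wh_weights(assess_grid, mode))
            assert res.t_y == pytest.approx(ty.values[k], rel=1e-12)
            assert res.t_xz == pytest.approx(txz.values[k], rel=1e-12)
            expected_total = math.sqrt(
                (txz.values[k] ** 2 * 25.0 + ty.values[k] ** 2 * 25.0) / 50.0
            )
            assert res.t_xzy == pytest.approx(expected_total, rel=1e-12)

    def test_unity_spectra_preserved_for_any_tool(self, assess_grid):
        ones = np.ones(len(assess_grid))
        ty = make_spectrum(assess_grid, ones, direction="y")
        txz = make_spectrum(assess_grid, ones, direction="xz")
        tool = random_tool(np.random.default_rng(1), assess_grid)
        for mode in ("unity", "iso_wh", "table"):
            res = tool_specific_values(ty, txz, tool, wh_weights(assess_grid, mode))
            assert res.t_y == pytest.approx(1.0, rel=1e-12)
            assert res.t_xz == pytest.approx(1.0, rel=1e-12)
            assert res.t_xzy == pytest.approx(1.0, rel=1e-12)
            assert res.r_percent == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize("mode", ["unity", "iso_wh"])
    def test_brute_force_oracle_equivalence(self, assess_grid, mode):
        rng = np.random.default_rng(2)
        weights = wh_weights(assess_grid, mode)
        for _ in range(100):
            ty, txz = glove_pair(rng, assess_grid)
            tool = random_tool(rng, assess_grid)
            res = tool_specific_values(ty, txz, tool, weights)
            oy, oxz, ot = naive_tool_values(ty.values, txz.values, tool, weights.wh)
            assert res.t_y == pytest.approx(oy, rel=1e-12)
            assert res.t_xz == pytest.approx(oxz, rel=1e-12)
            assert res.t_xzy == pytest.approx(ot, rel=1e-12)

    def test_scale_invariance_in_tool(self, assess_grid):
        rng = np.random.default_rng(3)
        ty, txz = glove_pair(rng, assess_grid)
        tool = random_tool(rng, assess_grid)
        big = make_tool(assess_grid, 7.0 * tool.ax, 7.0 * tool.ay, 7.0 * tool.az)
        w = wh_weights(assess_grid, "iso_wh")
        r1 = tool_specific_values(ty, txz, tool, w)
        r2 = tool_specific_values(ty, txz, big, w)
        assert r1.t_xzy == pytest.approx(r2.t_xzy, rel=1e-12)

    def test_total_between_directional_values(self, assess_grid):
        rng = np.random.default_rng(4)
        for _ in range(20):
            ty, txz = glove_pair(rng, assess_grid)
            tool = random_tool(rng, assess_grid)
            res = tool_specific_values(ty, txz, tool, wh_weights(assess_grid, "unity"))
            assert min(res.t_y, res.t_xz) - 1e-12 <= res.t_xzy <= max(res.t_y, res.t_xz) + 1e-12

    def test_attenuating_spectra_give_nonnegative_reduction(self, assess_grid):
        """T <= 1 on every band implies T values <= 1 and R >= 0 (convexity)."""
        rng = np.random.default_rng(5)
        for mode in ("unity", "iso_wh"):
            w = wh_weights(assess_grid, mode)
            for _ in range(20):
                ty, txz = glove_pair(rng, assess_grid, lo=0.2, hi=1.0)
                tool = random_tool(rng, assess_grid)
                res = tool_specific_values(ty, txz, tool, w)
                assert res.t_y <= 1.0 + 1e-12
                assert res.t_xz <= 1.0 + 1e-12
                assert res.t_xzy <= 1.0 + 1e-12
                assert res.r_percent >= -1e-10

    def test_zero_shear_energy_gives_nan_directional_value(self, assess_grid):
        rng = np.random.default_rng(6)
        ty, txz = glove_pair(rng, assess_grid)
        n = len(assess_grid)
        tool = make_tool(assess_grid, np.ones(n), np.zeros(n), np.ones(n))
        res = tool_specific_values(ty, txz, tool, wh_weights(assess_grid, "unity"))
        assert math.isnan(res.t_y)
        assert res.t_xzy == pytest.approx(res.t_xz, rel=1e-12)

    def test_unweighted_equals_unity_weighted(self, assess_grid):
        rng = np.random.default_rng(7)
        ty, txz = glove_pair(rng, assess_grid)
        tool = random_tool(rng, assess_grid)
        res = tool_specific_values(ty, txz, tool, wh_weights(assess_grid, "unity"))
        assert res.mode == "unweighted"

    def test_reconstruction_identity_from_published_values(self):
        """Recombining printed directional values reproduces the printed total."""
        acc = load_fixture("tool_accel_summaries").set_index(["tool", "mode"])
        tdf = load_fixture("glove_tool_transmissibilities").set_index(
            ["tool", "mode", "location", "glove"]
        )
        cases = [
            ("Impact wrench", "unweighted", "fingertip", "neoprene", 0.65),
            ("Sander", "unweighted", "fingertip", "bladder", 1.06),
            ("Vibrating fork", "unweighted", "fingertip", "gel", 1.03),
        ]
        for tool, mode, loc, glove, expected in cases:
            a = acc.loc[(tool, mode)]
            t = tdf.loc[(tool, mode, loc, glove)]
            recon = math.sqrt(
                (t.t_y**2 * a.ay_ms2**2 + t.t_xz**2 * a.axz_ms2**2)
                / (a.ay_ms2**2 + a.axz_ms2**2)
            )
            assert recon == pytest.approx(expected, abs=0.01)


class TestPercentReduction:
    @pytest.mark.parametrize("t,expected", [(1.0, 0.0), (0.9, 10.0), (1.25, -25.0)])
    def test_linear_map(self, t, expected):
        res = EffectivenessResult(
            glove_id="g", tool_id="t", location="full", mode="unweighted",
            t_y=t, t_xz=t, t_xzy=t,
        )
        assert percent_reduction(res) == pytest.approx(expected)


class TestFullFinger:
    def test_identical_inputs_agree_across_strategies(self, assess_grid):
        rng = np.random.default_rng(8)
        ty, txz = glove_pair(rng, assess_grid, location="fingertip")
        prox_y = make_spectrum(assess_grid, ty.values, location="proximal", direction="y")
        prox_xz = make_spectrum(assess_grid, txz.values, location="proximal", direction="xz")
        tool = random_tool(rng, assess_grid)
        w = wh_weights(assess_grid, "unity")
        a = full_finger_result((ty, txz), (prox_y, prox_xz), tool, w, "spectrum_mean")
        b = full_finger_result((ty, txz), (prox_y, prox_xz), tool, w, "value_mean")
        assert a.t_xzy == pytest.approx(b.t_xzy, rel=1e-12)
        assert a.location == b.location == "full"

    def test_constant_spectra_average_like_constants(self, assess_grid):
        n = len(assess_grid)
        tip_y = make_spectrum(assess_grid, np.full(n, 0.8), location="fingertip", direction="y")
        tip_xz = make_spectrum(assess_grid, np.full(n, 0.8), location="fingertip", direction="xz")
        prox_y = make_spectrum(assess_grid, np.full(n, 1.2), location="proximal", direction="y")
        prox_xz = make_spectrum(assess_grid, np.full(n, 1.2), location="proximal", direction="xz")
        tool = random_tool(np.random.default_rng(9), assess_grid)
        res = full_finger_result(
            (tip_y, tip_xz), (prox_y, prox_xz), tool, wh_weights(assess_grid, "unity")
        )
        assert res.t_xzy == pytest.approx(1.0, rel=1e-12)

    def test_strategies_differ_but_both_bracketed(self, assess_grid):
        rng = np.random.default_rng(10)
        w = wh_weights(assess_grid, "unity")
        tool = random_tool(rng, assess_grid)
        tip = glove_pair(rng, assess_grid, location="fingertip")
        prox = glove_pair(rng, assess_grid, location="proximal")
        a = full_finger_result(tip, prox, tool, w, "spectrum_mean")
        b = full_finger_result(tip, prox, tool, w, "value_mean")
        assert a.t_xzy != pytest.approx(b.t_xzy, rel=1e-9)
        r_tip = tool_specific_values(*tip, tool, w).t_xzy
        r_prox = tool_specific_values(*prox, tool, w).t_xzy
        lo, hi = sorted((r_tip, r_prox))
        # spectrum averaging of magnitudes can shift slightly outside the
        # scalar bracket, value averaging cannot
        assert lo <= b.t_xzy <= hi
        assert lo - 0.1 <= a.t_xzy <= hi + 0.1

    def test_unknown_strategy_rejected(self, assess_grid):
        rng = np.random.default_rng(11)
        tip = glove_pair(rng, assess_grid, location="fingertip")
        prox = glove_pair(rng, assess_grid, location="proximal")
        tool = random_tool(rng, assess_grid)
        with pytest.raises(ValueError, match="strategy"):
            full_finger_result(tip, prox, tool, wh_weights(assess_grid, "unity"), "median")


class TestClassification:
    def _table4_long(self, mode_prefix):
        t4 = load_fixture("table4")
        gloves = ["gel", "bladder", "bubble", "neoprene"]
        rows = []
        for g in gloves:
            col = f"{mode_prefix}_{g}"
            rows.append(pd.DataFrame({"tool": t4.tool, "glove": g, "r_percent": t4[col]}))
        return pd.concat(rows, ignore_index=True)

    def test_neoprene_unweighted_reduces_27_of_79(self):
        rep = classify_matches(self._table4_long("u"), threshold=10.0, inclusive=True)
        assert rep.counts.loc["neoprene", "reduced"] == 27
        assert rep.counts.sum(axis=1).eq(79).all()

    def test_neoprene_weighted_strict_reduces_3(self):
        rep = classify_matches(self._table4_long("w"), threshold=10.0, inclusive=False)
        assert rep.counts.loc["neoprene", "reduced"] == 3
        assert rep.counts.loc["neoprene", "amplified"] == 9

    def test_all_zero_reductions_are_neutral(self):
        df = pd.DataFrame({"tool": ["a", "b"], "glove": "g", "r_percent": [0.0, 0.0]})
        rep = classify_matches(df, threshold=10.0)
        assert rep.counts.loc["g", "neutral"] == 2

    def test_rounding_half_away_from_zero(self):
        np.testing.assert_array_equal(
            round_half_away([9.5, -9.5, 10.4, -10.5]), [10.0, -10.0, 10.0, -11.0]
        )

    def test_negative_threshold_rejected(self):
        df = pd.DataFrame({"tool": ["a"], "glove": "g", "r_percent": [0.0]})
        with pytest.raises(ValueError):
            classify_matches(df, threshold=-1.0)


class TestReport:
    def test_single_pair_report_shape(self, assess_grid):
        df = pd.DataFrame(
            [("drill", "gel", "full", "unweighted", 1.05, 0.98, 1.0, 0.0)],
            columns=["tool", "glove", "location", "mode", "t_y", "t_xz", "t_xzy", "r_percent"],
        )
        rep = classify_matches(df)
        text = render_report(rep, df, fmt="text")
        assert "drill" in text and "mean_r_percent" in text

    def test_mean_reduction_matches_published_row(self):
        printed_mean = {"gel": -6, "bladder": -5, "bubble": -3, "neoprene": 6}
        long = TestClassification()._table4_long("u")
        rep = classify_matches(long)
        for glove, expected in printed_mean.items():
            assert rep.mean_r[glove] == pytest.approx(expected, abs=0.5)

    def test_empty_results_rejected(self):
        df = pd.DataFrame(columns=["tool", "glove", "r_percent"])
        with pytest.raises(ValueError):
            render_report(classify_matches(df), df)
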