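"""Layer table I/O, chronology validation, lens geometry, replicate QC."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from isolens.lens_data import (
    FormatError,
    GeometryFit,
    LayerRecord,
    ValidationError,
    filter_regression_layers,
    fit_geometry_regression,
    interpolate_missing_diameter,
    predict_ld,
    qc_replicate_precision,
    read_layer_table,
    write_layer_table,
)


def _layer(fish="F1", idx=1, diam=3.0, role="hard", kind="primary", eye="right",
           d13C=-28.0, d15N=9.0):
    return LayerRecord(
        fish_id=fish, lake="Floods", species="Arctic Charr", eye=eye,
        layer_index=idx, diameter_mm=diam, d13C=d13C, d15N=d15N,
        role=role, sample_kind=kind,
    )


def _chronology(n, fish="F1"):
    """n layers outward-in: outermost, hard..., core."""
    recs = []
    for j in range(n):
        role = "outermost" if j == 0 else ("core" if j == n - 1 else "hard")
        recs.append(_layer(fish=fish, idx=j + 1, diam=5.0 - 0.4 * j, role=role))
    return recs


class TestLayerTableIO:
    def test_round_trip_identity(self, tiny_layer_csv, tmp_path):
        records = read_layer_table(tiny_layer_csv)
        assert len(records) == 4
        out = tmp_path / "copy.csv"
        write_layer_table(records, out)
        again = read_layer_table(out)
        for a, b in zip(records, again):
            assert (a.fish_id, a.lake, a.eye, a.role, a.sample_kind) == (
                b.fish_id, b.lake, b.eye, b.role, b.sample_kind
            )
            assert a.layer_index == b.layer_index
            assert abs(a.diameter_mm - b.diameter_mm) < 1e-9
            assert abs(a.d15N - b.d15N) < 1e-9
            assert abs(a.d13C - b.d13C) < 1e-9

    def test_row_order_does_not_defeat_monotonicity_check(self, tmp_path):
        # index 1 has the larger diameter even though rows arrive inner-first
        p = tmp_path / "t.csv"
        p.write_text(
            "fish_id,lake,species,eye,layer_index,diameter_mm,d13C,d15N,role,measured,sample_kind\n"
            "F1,L,S,right,2,2.0,-28,9,core,True,primary\n"
            "F1,L,S,right,1,2.5,-28,9,hard,True,primary\n"
        )
        recs = read_layer_table(p)
        assert len(recs) == 2

    def test_equal_diameters_rejected(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text(
            "fish_id,lake,species,eye,layer_index,diameter_mm,d13C,d15N,role,measured,sample_kind\n"
            "F1,L,S,right,1,2.0,-28,9,hard,True,primary\n"
            "F1,L,S,right,2,2.0,-28,9,core,True,primary\n"
        )
        with pytest.raises(ValidationError, match="F1"):
            read_layer_table(p)

    def test_missing_column_is_format_error(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("fish_id,lake,species\nF1,L,S\n")
        with pytest.raises(FormatError, match="missing required columns"):
            read_layer_table(p)

    def test_unknown_columns_preserved_as_annotations(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text(
            "fish_id,lake,species,eye,layer_index,diameter_mm,d13C,d15N,role,measured,sample_kind,note\n"
            "F1,L,S,right,1,2.0,-28,9,core,True,primary,damaged\n"
        )
        recs = read_layer_table(p)
        assert recs[0].annotations == {"note": "damaged"}


class TestInterpolation:
    @pytest.mark.parametrize(
        "prev,nxt,expected", [(2.0, 3.0, 2.5), (0.80, 1.40, 1.10)]
    )
    def test_midpoint(self, prev, nxt, expected):
        assert interpolate_missing_diameter(prev, nxt) == pytest.approx(expected)

    def test_equal_neighbours_rejected(self):
        with pytest.raises(ValidationError, match="monotonicity"):
            interpolate_missing_diameter(1.10, 1.10)

    @given(
        outer=st.floats(0.5, 6.0),
        gap=st.floats(0.01, 2.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_midpoint_preserves_strict_ordering(self, outer, gap):
        inner = outer - gap
        if inner <= 0:
            return
        mid = interpolate_missing_diameter(outer, inner)
        assert inner < mid < outer


class TestGeometryRegression:
    def test_noiseless_line_recovered_exactly(self):
        hd = np.array([2.0, 2.3, 2.6, 3.0, 3.4])
        pairs = [(h, 1.95 + 1.20 * h) for h in hd]
        fit = fit_geometry_regression(pairs)
        assert fit.slope == pytest.approx(1.20, abs=1e-12)
        assert fit.intercept == pytest.approx(1.95, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        hd = rng.uniform(2.0, 3.5, size=6)
        ld = 1.95 + 1.20 * hd + rng.normal(0, 0.4, size=6)
        ld = np.maximum(ld, hd + 0.1)
        fit = fit_geometry_regression(list(zip(hd, ld)))
        # independent normal-equations solution
        X = np.column_stack([np.ones_like(hd), hd])
        coef = np.linalg.solve(X.T @ X, X.T @ ld)
        resid = ld - X @ coef
        s2 = resid @ resid / (len(hd) - 2)
        cov = s2 * np.linalg.inv(X.T @ X)
        ss_tot = np.sum((ld - ld.mean()) ** 2)
        r2 = 1 - resid @ resid / ss_tot
        assert fit.intercept == pytest.approx(coef[0], abs=1e-10)
        assert fit.slope == pytest.approx(coef[1], abs=1e-10)
        assert fit.se_intercept == pytest.approx(math.sqrt(cov[0, 0]), abs=1e-10)
        assert fit.se_slope == pytest.approx(math.sqrt(cov[1, 1]), abs=1e-10)
        assert fit.r_squared == pytest.approx(r2, abs=1e-10)

    def test_too_few_pairs(self):
        with pytest.raises(Exception, match="at least 3"):
            fit_geometry_regression([(2.0, 4.0), (2.5, 4.5)])

    def test_zero_hd_variance_is_singular(self):
        with pytest.raises(Exception, match="singular"):
            fit_geometry_regression([(2.0, 4.0), (2.0, 4.2), (2.0, 4.4)])

    def test_ratio_statistics(self):
        pairs = [(2.0, 4.0), (2.6, 5.2), (3.0, 6.0)]
        fit = fit_geometry_regression(pairs)
        assert fit.ratio_mean == pytest.approx(0.5)
        assert fit.ratio_sd == pytest.approx(0.0, abs=1e-12)


class TestPredictLD:
    FIT = GeometryFit(
        slope=1.20, intercept=1.95, se_slope=0.189, se_intercept=0.52,
        r_squared=0.705, ratio_mean=0.52, ratio_sd=0.04, n=18,
    )

    def test_field_coefficients(self):
        assert predict_ld(2.5, self.FIT) == pytest.approx(4.95)

    def test_zero_hd_returns_intercept(self):
        assert predict_ld(0.0, self.FIT) == pytest.approx(1.95)

    def test_zero_slope_is_constant(self):
        flat = GeometryFit(0.0, 3.0, 0.1, 0.1, 0.0, 0.5, 0.02, 5)
        assert predict_ld(1.0, flat) == predict_ld(9.0, flat) == 3.0

    def test_negative_prediction_rejected(self):
        bad = GeometryFit(-3.0, 1.0, 0.1, 0.1, 0.9, 0.5, 0.02, 5)
        with pytest.raises(Exception, match="negative"):
            predict_ld(2.0, bad)


class TestFilterRegressionLayers:
    @pytest.mark.parametrize("n,expected", [(10, 8), (4, 2)])
    def test_removes_core_and_outermost(self, n, expected):
        chron = _chronology(n)
        kept = filter_regression_layers(chron)
        assert len(kept) == expected
        assert all(r.role == "hard" for r in kept)
        # order preserved
        assert [r.layer_index for r in kept] == sorted(r.layer_index for r in kept)

    def test_short_chronology_warns_but_passes(self):
        with pytest.warns(UserWarning, match="few regression points"):
            kept = filter_regression_layers(_chronology(3))
        assert len(kept) == 1

    def test_removes_exactly_two_when_both_roles_present(self, floods_sim):
        _, layers, _, _ = floods_sim
        by_fish = {}
        for r in layers:
            by_fish.setdefault(r.fish_id, []).append(r)
        for chron in by_fish.values():
            assert len(filter_regression_layers(chron)) == len(chron) - 2


class TestReplicatePrecision:
    def test_identical_duplicate_pair_has_zero_sd(self):
        recs = [
            _layer(idx=1, diam=3.0, role="outermost", d15N=10.0),
            _layer(idx=2, diam=2.0, role="core", d15N=9.0),
            _layer(idx=1, diam=3.0, role="outermost", kind="true_duplicate", d15N=10.0),
        ]
        out = qc_replicate_precision(recs)
        assert out["true_duplicate"]["d15N"]["max_sd"] == 0.0
        assert out["true_duplicate"]["d15N"]["n_pairs"] == 1

    def test_two_point_sd(self):
        recs = [
            _layer(idx=1, diam=3.0, role="outermost", d15N=10.0),
            _layer(idx=2, diam=2.0, role="core", d15N=9.0),
            _layer(idx=1, diam=3.0, role="outermost", kind="true_duplicate", d15N=10.2),
        ]
        out = qc_replicate_precision(recs)
        assert out["true_duplicate"]["d15N"]["mean_sd"] == pytest.approx(
            0.2 / math.sqrt(2), abs=1e-12
        )

    def test_left_eye_replicate_pairs_by_index_then_diameter(self):
        right = [
            _layer(idx=1, diam=3.0, role="outermost", d15N=10.0),
            _layer(idx=2, diam=2.0, role="hard", d15N=9.0),
            _layer(idx=3, diam=1.0, role="core", d15N=8.0),
        ]
        # same index but diameter off by 1.5 mm -> falls back to nearest diameter
        rep = _layer(idx=1, diam=1.05, role="hard", kind="left_eye_replicate",
                     eye="left", d15N=8.2)
        out = qc_replicate_precision(right + [rep])
        # paired with the diam=1.0 core (d15N=8.0), not the outermost
        assert out["left_eye_replicate"]["d15N"]["mean_sd"] == pytest.approx(
            0.2 / math.sqrt(2), abs=1e-9
        )

    def test_unpaired_replicate_warns(self):
        rep = _layer(fish="GHOST", idx=1, diam=2.0, role="hard",
                     kind="left_eye_replicate", eye="left")
        with pytest.warns(UserWarning, match="unpaired"):
            out = qc_replicate_precision([rep])
        assert out["left_eye_replicate"]["d15N"]["n_pairs"] == 0
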