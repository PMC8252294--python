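"""Annotation: acylsugar stoichiometry, adduct masses, Kovats indices, tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trichoselect.annotation import (
    AcylsugarLabel,
    AnnotationError,
    CalibrationSeries,
    FeatureTable,
    MolecularFormula,
    adduct_mz,
    assign_isomer_suffixes,
    build_feature_table,
    formula_to_label,
    kovats_index,
    label_to_formula,
    normalize_abundance,
)

GRID = [
    AcylsugarLabel(b, k, N)
    for b in ("S", "G")
    for k in range(0, 7)
    for N in ([0] if k == 0 else range(2 * k, 41))
]


class TestStoichiometry:
    @pytest.mark.parametrize(
        "label,formula",
        [("S3:15", "C27H46O14"), ("G0:0", "C6H12O6"), ("G2:10", "C16H28O8"),
         ("S0:0", "C12H22O11")],
    )
    def test_label_to_formula_known_cases(self, label, formula):
        assert str(label_to_formula(label)) == formula

    @pytest.mark.parametrize(
        "label,dbe", [("S3:15", 5), ("G2:10", 3), ("S0:0", 2), ("G0:0", 1)]
    )
    def test_dbe_counts_rings_plus_ester_carbonyls(self, label, dbe):
        assert label_to_formula(label).dbe == dbe

    @pytest.mark.parametrize("formula,label", [("C27H46O14", "S3:15"), ("C6H12O6", "G0:0")])
    def test_formula_to_label_known_cases(self, formula, label):
        assert str(formula_to_label(formula)) == label

    def test_monoterpene_rejected_as_acylsugar(self):
        with pytest.raises(AnnotationError, match="not a saturated acylsugar"):
            formula_to_label(MolecularFormula(10, 16, 0))

    def test_round_trip_over_full_grid(self):
        failures = [L for L in GRID if formula_to_label(label_to_formula(L)) != L]
        assert failures == []

    def test_no_formula_matches_both_backbones(self):
        seen = {}
        for L in GRID:
            f = label_to_formula(L)
            assert f not in seen, f"{f} maps to both {seen[f]} and {L}"
            seen[f] = L

    def test_chain_shorter_than_acetyl_rejected(self):
        with pytest.raises(AnnotationError):
            AcylsugarLabel("S", 3, 5)

    def test_label_parsing_with_isomer_suffix(self):
        lab = AcylsugarLabel.parse("S3:21-2")
        assert (lab.backbone, lab.k, lab.N, lab.isomer_index) == ("S", 3, 21, 2)
        assert str(lab) == "S3:21-2"


class TestAdductMasses:
    def test_triacylsucrose_sodium_adduct_nominal_mass(self):
        mz = adduct_mz(label_to_formula("S3:15"), "[M+Na]+")
        assert mz == pytest.approx(617.2785, abs=0.001)
        assert round(mz) == 617

    def test_sesquiterpene_neutral_mass(self):
        assert adduct_mz(MolecularFormula(15, 24, 0), None) == pytest.approx(
            204.2, abs=0.05
        )

    def test_sodium_minus_proton_shift_is_constant(self):
        shifts = {
            adduct_mz(f, "[M+Na]+") - adduct_mz(f, "[M+H]+")
            for f in (MolecularFormula(6, 12, 6), MolecularFormula(27, 46, 14),
                      MolecularFormula(10, 16, 0))
        }
        assert len(shifts) == 1
        assert shifts.pop() == pytest.approx(21.98194, abs=1e-4)

    def test_unknown_adduct_rejected(self):
        with pytest.raises(AnnotationError, match="unknown adduct"):
            adduct_mz(MolecularFormula(6, 12, 6), "[M+NH4]+")


class TestKovats:
    def test_alkanes_land_on_their_own_index(self, alkane_calibration):
        for n, t in zip(alkane_calibration.carbon_numbers,
                        alkane_calibration.retention_times):
            assert kovats_index(t, alkane_calibration) == pytest.approx(100 * n)

    def test_midpoint_between_alkanes(self):
        cal = CalibrationSeries.from_pairs([(10, 10.0), (11, 12.0)])
        assert kovats_index(11.0, cal) == pytest.approx(1050)

    def test_linear_interpolation_worked_example(self):
        cal = CalibrationSeries.from_pairs([(14, 20.0), (15, 22.0)])
        assert kovats_index(21.4, cal) == pytest.approx(1470)

    def test_out_of_range_requires_explicit_extrapolation(self, alkane_calibration):
        t_last = alkane_calibration.retention_times[-1]
        with pytest.raises(AnnotationError, match="extrapolate"):
            kovats_index(t_last + 1.0, alkane_calibration)
        assert kovats_index(t_last + 1.0, alkane_calibration, extrapolate=True) > 2000

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.floats(min_value=0.0, max_value=1.0), st.floats(min_value=1e-3, max_value=1.0))
    def test_strictly_increasing_in_rt(self, frac, gap):
        cal = CalibrationSeries.from_pairs(
            (n, 2.0 + 1.7 * (n - 8) + 0.01 * (n - 8) ** 2) for n in range(8, 21)
        )
        lo, hi = cal.retention_times[0], cal.retention_times[-1]
        rt1 = lo + frac * (hi - lo - gap)
        rt2 = rt1 + gap
        assert kovats_index(rt1, cal) < kovats_index(rt2, cal)

    def test_non_monotone_calibration_rejected(self):
        with pytest.raises(AnnotationError):
            CalibrationSeries((8, 9), (5.0, 4.0))


class TestNormalisation:
    @pytest.mark.parametrize(
        "raw,is_area,dil,weight,expected",
        [(500.0, 500.0, 1.0, 1.0, 1.0),
         (0.0, 500.0, 1.0, 1.0, 0.0),
         (2000.0, 500.0, 2.0, 0.1, 80.0)],
    )
    def test_arithmetic(self, raw, is_area, dil, weight, expected):
        assert normalize_abundance(raw, is_area, dil, weight) == pytest.approx(expected)

    def test_dilution_convention_flag(self):
        assert normalize_abundance(100, 50, 2.0, 1.0, dilution_divides=True) == 1.0

    @pytest.mark.parametrize("kwargs", [dict(internal_standard_area=0.0),
                                        dict(fresh_weight=-1.0),
                                        dict(dilution_factor=0.0)])
    def test_invalid_inputs_rejected(self, kwargs):
        base = dict(raw_area=1.0, internal_standard_area=1.0,
                    dilution_factor=1.0, fresh_weight=1.0)
        base.update(kwargs)
        with pytest.raises(AnnotationError):
            normalize_abundance(**base)


def long_df(rows):
    return pd.DataFrame(rows, columns=["accession", "replicate", "feature_id", "abundance"])


class TestFeatureTableBuild:
    def test_coeluting_features_merge_by_summation(self):
        df = long_df([("A", 1, "limonene", 3.0), ("A", 1, "b-phellandrene", 4.0)])
        table = build_feature_table(
            df, merge_rules={"b-phellandrene/limonene": ["limonene", "b-phellandrene"]}
        )
        wide = table.replicate_matrix()
        assert list(wide.columns) == ["b-phellandrene/limonene"]
        assert wide.iloc[0, 0] == 7.0

    def test_absent_feature_zero_filled(self):
        df = long_df([("A", 1, "f1", 5.0), ("B", 1, "f2", 2.0)])
        wide = build_feature_table(df).replicate_matrix()
        assert wide.loc[("A", 1), "f2"] == 0.0
        assert wide.loc[("B", 1), "f1"] == 0.0

    def test_accession_mean_over_replicates(self):
        df = long_df([("A", r, "f1", float(r)) for r in range(1, 7)])
        means = build_feature_table(df).accession_means()
        assert means.loc["A", "f1"] == pytest.approx(3.5)

    def test_duplicate_rows_rejected(self):
        df = long_df([("A", 1, "f1", 1.0), ("A", 1, "f1", 2.0)])
        with pytest.raises(AnnotationError, match="duplicate"):
            build_feature_table(df)

    def test_negative_abundance_rejected(self):
        with pytest.raises(AnnotationError, match="negative"):
            FeatureTable(long_df([("A", 1, "f1", -1.0)]))

    def test_isomer_suffixes_follow_retention_order(self):
        feats = pd.DataFrame(
            {"label": ["S3:21", "S3:15", "S3:21"], "rt": [8.4, 3.0, 6.1]}
        )
        out = assign_isomer_suffixes(feats)
        assert list(out) == ["S3:21-2", "S3:15", "S3:21-1"]
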