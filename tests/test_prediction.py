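"""Prediction engine: equation evaluation, model cascade, flags."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import allomass as am
from allomass.errors import UsageError, ValidationError

finite_pos = st.floats(min_value=0.01, max_value=100.0, allow_nan=False)


class TestPredictLog10Mass:
    def test_unit_length_returns_intercept(self, db):
        # log10(1) = 0, so the prediction collapses to the intercept
        assert am.predict_log10_mass(db.lookup("L"), 1.0) == pytest.approx(-0.792)
        assert am.predict_log10_mass(db.lookup("LW"), 1.0, 1.0) == pytest.approx(-0.340)

    def test_ten_mm_length_only(self, db):
        y = am.predict_log10_mass(db.lookup("L"), 10.0)
        assert y == pytest.approx(-0.792 + 2.181, abs=1e-12)
        assert 10.0 ** y == pytest.approx(24.49, abs=0.01)

    def test_measurement_domain_errors(self, db):
        with pytest.raises(ValidationError):
            am.predict_log10_mass(db.lookup("L"), 0.0)
        with pytest.raises(ValidationError):
            am.predict_log10_mass(db.lookup("L"), -3.0)

    def test_width_usage_errors(self, db):
        with pytest.raises(UsageError):
            am.predict_log10_mass(db.lookup("L"), 5.0, width=2.0)
        with pytest.raises(UsageError):
            am.predict_log10_mass(db.lookup("LW"), 5.0)

    @settings(max_examples=50, deadline=None)
    @given(length=finite_pos, width=finite_pos, k=st.floats(min_value=0.1, max_value=10))
    def test_scale_coherence_and_monotonicity(self, length, width, k):
        p = am.ParameterSet("LW", -0.34, 1.07, 1.634)
        base = am.predict_log10_mass(p, length, width)
        scaled = am.predict_log10_mass(p, k * length, width)
        assert scaled == pytest.approx(base + p.slope_length * math.log10(k), abs=1e-9)
        if k > 1:  # positive slopes: strictly increasing in each measurement
            assert scaled > base
            assert am.predict_log10_mass(p, length, k * width) > base


class TestSelectModel:
    @pytest.mark.parametrize(
        "has_width, taxon, region, entry, expected",
        [
            (True, True, True, True, "LWTR"),
            (True, True, True, False, "LWR"),
            (True, False, True, True, "LWR"),
            (True, True, False, True, "LWT"),
            (True, False, False, True, "LW"),
            (False, True, True, True, "LTR"),
            (False, True, False, True, "LT"),
            (False, False, True, True, "LR"),
            (False, False, False, True, "L"),
            (False, True, True, False, "LR"),
        ],
    )
    def test_preference_cascade(self, has_width, taxon, region, entry, expected):
        assert am.select_model(has_width, taxon, region, entry) == expected


class TestPredictMass:
    def test_full_record_uses_top_ranked_family(self, db):
        rec = am.MorphometricRecord("a1", 5.0, taxon="Araneae", region="temperate",
                                    body_width=2.0)
        res = am.predict_mass(rec, db)
        assert res.model_used == "LWTR"
        assert res.parameter_key == ("Araneae", "temperate")
        assert "fallback_model" not in res.flags
        assert math.log10(res.mass_pred) == pytest.approx(res.log10_mass_pred, abs=1e-12)

    def test_length_only_record_falls_to_plain_model(self, db):
        rec = am.MorphometricRecord("a2", 10.0)
        res = am.predict_mass(rec, db)
        assert res.model_used == "L"
        assert res.mass_pred == pytest.approx(10 ** (-0.792 + 2.181), rel=1e-12)

    def test_missing_database_entry_sets_fallback_flag(self, db):
        # Dictyoptera was never sampled in the temperate region: LWTR is
        # skipped purely for lack of an entry, and LWT (taxon-only) is used.
        rec = am.MorphometricRecord("d1", 12.0, taxon="Dictyoptera",
                                    region="temperate", body_width=4.0)
        res = am.predict_mass(rec, db)
        assert res.model_used == "LWT"
        assert "fallback_model" in res.flags

    def test_unknown_taxon_cascades_without_fallback_flag(self, db):
        rec = am.MorphometricRecord("x1", 8.0, region="tropical", body_width=3.0)
        res = am.predict_mass(rec, db)
        assert res.model_used == "LWR"
        assert "fallback_model" not in res.flags

    def test_nonsignificant_coefficient_flagged(self, db):
        # temperate Neuroptera's length slope carries no significance star
        rec = am.MorphometricRecord("n1", 5.0, taxon="Neuroptera",
                                    region="temperate", body_width=1.5)
        res = am.predict_mass(rec, db)
        assert res.model_used == "LWTR"
        assert "nonsignificant_coefficient" in res.flags

    def test_model_override_enforces_required_fields(self, db):
        rec = am.MorphometricRecord("o1", 5.0)
        with pytest.raises(UsageError):
            am.predict_mass(rec, db, model_override="LW")

    def test_smearing_correction_scales_back_transform(self, db):
        rec = am.MorphometricRecord("s1", 10.0)
        naive = am.predict_mass(rec, db)
        corrected = am.predict_mass(rec, db, bias_correction="smearing",
                                    smearing_factor=1.05)
        assert corrected.mass_pred == pytest.approx(1.05 * naive.mass_pred, rel=1e-12)
        assert corrected.log10_mass_pred == naive.log10_mass_pred

    def test_cascade_total_over_builtin_records(self, db):
        """Every positive-length record gets a prediction, whatever is missing."""
        records = [
            am.MorphometricRecord("t1", 3.0),
            am.MorphometricRecord("t2", 3.0, taxon="NovelOrder", region="temperate",
                                  body_width=1.0),
            am.MorphometricRecord("t3", 3.0, taxon="Odonata", region="temperate"),
            am.MorphometricRecord("t4", 3.0, region="tropical"),
        ]
        for rec in records:
            res = am.predict_mass(rec, db)
            assert res.mass_pred > 0


class TestExtrapolationFlags:
    @pytest.mark.parametrize(
        "taxon, region, length, expected",
        [
            ("Araneae", "temperate", 15.0, {"extrapolated_length"}),
            ("Araneae", "temperate", 5.0, set()),
            ("Orthoptera", "tropical", 68.12, set()),  # boundary is inclusive
            ("Araneae", "temperate", 1.01, set()),
        ],
    )
    def test_length_range_checks(self, db, taxon, region, length, expected):
        rec = am.MorphometricRecord("e", length, taxon=taxon, region=region)
        meta = db.validity_range(taxon, region)
        assert am.flag_extrapolation(rec, meta) == expected

    def test_flags_attached_by_predict_mass(self, db):
        rec = am.MorphometricRecord("e2", 15.0, taxon="Araneae", region="temperate",
                                    body_width=5.0)
        assert "extrapolated_length" in am.predict_mass(rec, db).flags
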