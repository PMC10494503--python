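import dataclasses
import math

import numpy as np
import pytest

from freevitd import (
    Analyte,
    BindingConstants,
    EQ1,
    EQ2,
    EQ3,
    EquationSpec,
    ParticipantRecord,
    estimate_bikle,
    estimate_eq1,
    estimate_eq2,
    estimate_eq3,
    evaluate,
    free_fraction,
    from_molar,
    to_molar,
    vmr,
)
from freevitd.errors import DomainError, MissingInputError, SchemaError
from tests.conftest import MEDIANS


class TestEstimatingEquations:
    def test_eq1_at_cohort_medians(self, median_record):
        # independent hand evaluation of the printed formula, natural logs
        assert estimate_eq1(median_record) == pytest.approx(5.0539, abs=1e-3)

    def test_eq3_at_cohort_medians(self, median_record):
        assert estimate_eq3(median_record) == pytest.approx(5.3584, abs=1e-3)

    def test_intercept_recovered_when_all_logs_vanish(self):
        # albumin 0 and every log-transformed input at 1 leaves the intercept
        rec = ParticipantRecord(
            albumin=0.0, d25_3=1.0, d25_2=1.0, vdbp=1.0, d1_25_3=1.0, d24_25_3=1.0
        )
        assert evaluate(EQ1, rec) == pytest.approx(12.202, abs=1e-12)

    @pytest.mark.parametrize(
        "phenotype, offset",
        [
            ("Gc1f/Gc1f", 0.0),
            ("Gc1f/Gc1s", 0.019716),
            ("Gc1s/Gc1s", 0.002741),
            ("Gc2/Gc1f", -0.394562),
            ("Gc2/Gc1s", -0.1283514),
            ("Gc2/Gc2", -0.1381116),
        ],
    )
    def test_eq2_phenotype_offsets_are_exact(self, phenotype, offset):
        ref = ParticipantRecord(phenotype="Gc1f/Gc1f", **MEDIANS)
        other = ParticipantRecord(phenotype=phenotype, **MEDIANS)
        assert estimate_eq2(other) - estimate_eq2(ref) == pytest.approx(
            offset, abs=1e-12
        )

    def test_eq2_offset_difference_between_heterozygotes(self):
        a = ParticipantRecord(phenotype="Gc1f/Gc1s", **MEDIANS)
        b = ParticipantRecord(phenotype="Gc1s/Gc1s", **MEDIANS)
        assert estimate_eq2(a) - estimate_eq2(b) == pytest.approx(
            0.019716 - 0.002741, abs=1e-12
        )

    def test_missing_variable_error_names_the_variable(self):
        rec = ParticipantRecord(albumin=4.3, d25_3=20.3, d25_2=0.33)
        with pytest.raises(MissingInputError, match="vdbp"):
            estimate_eq1(rec)

    def test_phenotype_required_by_eq2(self, median_record):
        rec = dataclasses.replace(median_record, phenotype=None)
        with pytest.raises(MissingInputError, match="phenotype"):
            estimate_eq2(rec)

    def test_nonpositive_log_input_is_domain_error(self):
        rec = ParticipantRecord(
            albumin=4.3, d25_3=20.3, d25_2=0.0, vdbp=253.3, d1_25_3=40.2, d24_25_3=1.7
        )
        with pytest.raises(DomainError, match="d25_2"):
            estimate_eq1(rec)

    def test_evaluate_is_linear_in_each_coefficient(self, median_record):
        base = evaluate(EQ1, median_record)
        delta = 0.37
        terms = list(EQ1.terms)
        var, transform, coef = terms[1]  # log 25(OH)D3 term
        terms[1] = (var, transform, coef + delta)
        perturbed = EquationSpec(
            name="p",
            intercept=EQ1.intercept,
            terms=tuple(terms),
            interactions=EQ1.interactions,
        )
        expected = base + delta * math.log(MEDIANS["d25_3"])
        assert evaluate(perturbed, median_record) == pytest.approx(expected, rel=1e-12)

    def test_eq2_shares_eq1_term_structure_plus_offsets(self):
        assert {(v, t) for v, t, _ in EQ1.terms} == {(v, t) for v, t, _ in EQ2.terms}
        assert [(a, b) for a, b, _ in EQ1.interactions] == [
            (a, b) for a, b, _ in EQ2.interactions
        ]
        assert not EQ1.phenotype_offsets and len(EQ2.phenotype_offsets) == 6

    def test_offsets_must_cover_all_diplotypes_with_zero_reference(self):
        with pytest.raises(SchemaError):
            EquationSpec(
                name="bad",
                intercept=0.0,
                terms=(),
                phenotype_offsets={"Gc1f/Gc1f": 0.0, "Gc2/Gc2": -0.1},
            )
        with pytest.raises(SchemaError):
            EquationSpec(
                name="bad",
                intercept=0.0,
                terms=(),
                phenotype_offsets={p: 0.1 for p in EQ2.phenotype_offsets},
            )


class TestBikleEquation:
    def test_at_cohort_medians(self, median_record):
        # hand oracle: denominator 1 + 8e8·[VDBP] + 6e5·[albumin] ≈ 3883
        est = estimate_bikle(median_record)
        assert est == pytest.approx(5.3127, abs=5e-3)
        denom = 1.0 / free_fraction(MEDIANS["vdbp"], MEDIANS["albumin"])
        assert denom == pytest.approx(3883.2, abs=0.5)

    def test_free_equals_total_without_carriers(self):
        rec = ParticipantRecord(albumin=0.0, d25_3=20.0, d25_2=0.0, vdbp=0.0)
        assert estimate_bikle(rec) == pytest.approx(20_000.0, rel=1e-12)

    def test_agrees_with_molar_route_oracle(self, median_record):
        # independent evaluation doing the conversions in a different order:
        # convert total 25(OH)D to mol/L, solve in molar space, convert back
        constants = BindingConstants()
        total_ng_ml = MEDIANS["d25_3"] + MEDIANS["d25_2"]
        total_m = to_molar(total_ng_ml, Analyte.D25_TOTAL, constants)
        vdbp_m = to_molar(MEDIANS["vdbp"], Analyte.VDBP, constants)
        alb_m = to_molar(MEDIANS["albumin"], Analyte.ALBUMIN, constants)
        free_m = total_m / (1 + constants.ka_dbp * vdbp_m + constants.ka_alb * alb_m)
        oracle_pg_ml = from_molar(free_m, Analyte.D25_TOTAL, constants) * 1000.0
        assert estimate_bikle(median_record, constants) == pytest.approx(
            oracle_pg_ml, rel=1e-9
        )

    def test_strictly_decreasing_in_vdbp_and_albumin(self):
        base = dict(d25_3=20.3, d25_2=0.33)
        vdbp_grid = [0.0, 10.0, 100.0, 253.3, 500.0]
        estimates = [
            estimate_bikle(ParticipantRecord(albumin=4.3, vdbp=v, **base))
            for v in vdbp_grid
        ]
        assert all(a > b for a, b in zip(estimates, estimates[1:]))
        alb_grid = [0.0, 2.0, 4.3, 6.0]
        estimates = [
            estimate_bikle(ParticipantRecord(albumin=a, vdbp=253.3, **base))
            for a in alb_grid
        ]
        assert all(a > b for a, b in zip(estimates, estimates[1:]))

    def test_free_fraction_bounded(self):
        for vdbp, alb in [(0.0, 0.0), (253.3, 4.3), (1000.0, 10.0)]:
            f = free_fraction(vdbp, alb)
            assert 0 < f <= 1


class TestVmr:
    @pytest.mark.parametrize(
        "d24, d3, expected",
        [(0.0, 20.3, 0.0), (1.7, 20.3, 8.374), (2.0, 20.0, 10.0), (4.0, 40.0, 10.0)],
    )
    def test_values(self, d24, d3, expected):
        assert vmr(d24, d3) == pytest.approx(expected, abs=1e-3)

    def test_scale_invariance(self):
        assert vmr(1.7, 20.3) == pytest.approx(vmr(17.0, 203.0), rel=1e-12)

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            vmr(1.7, 0.0)
        with pytest.raises(DomainError):
            vmr(-0.1, 20.3)
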