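"""Virtual individuals, growth tables, GFR maturation and population sampling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pedpk.errors import ConfigError, DomainError
from pedpk.physiology import (
    PEDIATRIC_GROUPS,
    PopulationSpec,
    anthropometry,
    bsa,
    build_individual,
    gfr_fraction,
    group_spec,
    population_frame,
    sample_population,
)


class TestAnthropometry:
    @pytest.mark.parametrize(
        "age,sex,weight",
        [(1, "male", 10.0), (5, "male", 17.0), (12, "male", 40.0), (29, "male", 70.0)],
    )
    def test_growth_anchors(self, age, sex, weight):
        wt, _ = anthropometry(age, sex)
        assert wt == pytest.approx(weight, rel=1e-3)

    def test_adult_male_plateau(self):
        wt, ht = anthropometry(29, "male")
        assert wt == pytest.approx(70.0, rel=1e-3)
        assert ht == pytest.approx(170.0, rel=1e-3)

    def test_sex_offset_beyond_age_12(self):
        wt_m, ht_m = anthropometry(16, "male")
        wt_f, ht_f = anthropometry(16, "female")
        assert wt_m > wt_f and ht_m > ht_f
        assert anthropometry(8, "male") == anthropometry(8, "female")

    @pytest.mark.parametrize("bad_age", [0.0, -1.0, 95.0])
    def test_age_domain(self, bad_age):
        with pytest.raises(DomainError):
            anthropometry(bad_age, "male")


class TestBsa:
    @pytest.mark.parametrize(
        "h,w,expected", [(170, 70, 1.8181), (110, 17, 0.7207)]
    )
    def test_mosteller(self, h, w, expected):
        assert bsa(h, w) == pytest.approx(expected, abs=1e-3)

    def test_nonpositive_rejected(self):
        with pytest.raises(DomainError):
            bsa(170, 0)


class TestGfrMaturation:
    def test_above_90_percent_by_first_birthday(self):
        assert gfr_fraction(1.0) >= 0.90
        assert gfr_fraction(1.0) == pytest.approx(0.9037, abs=2e-3)

    def test_term_newborn(self):
        assert gfr_fraction(0.0) == pytest.approx(0.3547, abs=2e-3)

    def test_saturates_at_adult_level(self):
        assert gfr_fraction(1e6) == pytest.approx(1.0, abs=1e-6)
        assert gfr_fraction(40.0) < 1.0

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(min_value=0.0, max_value=90.0), st.floats(min_value=0.0, max_value=90.0))
    def test_monotone_nondecreasing(self, a, b):
        lo, hi = sorted((a, b))
        assert gfr_fraction(lo) <= gfr_fraction(hi) + 1e-12

    def test_negative_age_rejected(self):
        with pytest.raises(DomainError):
            gfr_fraction(-0.1)


class TestBuildIndividual:
    def test_flows_sum_to_cardiac_output(self, adult):
        assert sum(adult.blood_flows.values()) == pytest.approx(
            adult.cardiac_output_l_h, rel=1e-9
        )

    def test_volumes_close_to_body_weight(self, adult):
        total = sum(adult.organ_volumes.values())
        assert abs(total - adult.weight_kg) / adult.weight_kg < 0.15

    def test_child_organs_uniformly_smaller(self, adult):
        child = build_individual(1.0, "male")
        for organ, v in child.organ_volumes.items():
            assert v < adult.organ_volumes[organ]
        for seg, g in child.gut_geometry.items():
            assert g["length_cm"] < adult.gut_geometry[seg]["length_cm"]
            assert g["radius_cm"] < adult.gut_geometry[seg]["radius_cm"]

    def test_weight_override(self):
        ind = build_individual(29, "male", overrides={"weight_kg": 73})
        assert ind.weight_kg == 73

    def test_unknown_override_key_rejected(self):
        with pytest.raises(ConfigError):
            build_individual(29, "male", overrides={"wieght_kg": 73})


class TestSamplePopulation:
    def test_female_count_is_deterministic_split(self):
        pop = sample_population(PopulationSpec(n=100, prop_female=0.5, seed=3))
        assert sum(1 for p in pop if p.sex == "female") == 50
        # round-half-up on odd counts
        pop = sample_population(PopulationSpec(n=5, prop_female=0.5, seed=3))
        assert sum(1 for p in pop if p.sex == "female") == 3

    def test_seeded_determinism(self):
        spec = PopulationSpec(n=20, prop_female=0.4, age_min_years=2, age_max_years=5, seed=7)
        a = population_frame(sample_population(spec))
        b = population_frame(sample_population(spec))
        assert a.equals(b)

    def test_age_bounds_honoured(self):
        pop = sample_population(
            PopulationSpec(n=50, age_min_years=2, age_max_years=5, seed=0)
        )
        ages = [p.age_years for p in pop]
        assert min(ages) >= 2 and max(ages) <= 5

    def test_height_variability_matches_cv(self):
        spec = PopulationSpec(n=400, age_min_years=29, age_max_years=29, seed=11,
                              prop_female=0.0, height_sd_fraction=0.10)
        pop = sample_population(spec)
        heights = np.array([p.height_cm for p in pop])
        cv = np.std(np.log(heights))
        assert cv == pytest.approx(np.sqrt(np.log(1.01)), rel=0.15)

    def test_pediatric_groups_cover_birth_to_16(self):
        assert set(PEDIATRIC_GROUPS) == {
            "neonates_to_infants", "infants_to_toddler", "preschool", "school", "adolescent",
        }
        spec = group_spec("preschool", n=10, seed=0)
        assert (spec.age_min_years, spec.age_max_years) == (2.0, 5.0)
        with pytest.raises(DomainError):
            group_spec("toddlers")
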