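"""Profile aggregation, syndrome scoring, rankings, and category summaries."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from perveg.fixtures import (
    INDUSTRIAL_MULTINUTRIENT,
    TRADITIONAL_MULTINUTRIENT,
)
from perveg.inventory import Form, Part, SpeciesRecord
from perveg.nutrient_classes import ClassBounds, ConcentrationClass, Nutrient
from perveg.nutrient_scoring import (
    CLASS_POINTS,
    QUALIFYING_SCORE,
    SYNDROME_NUTRIENTS,
    NutrientMeasurement,
    NutrientProfile,
    Syndrome,
    aggregate_profile,
    combine_parts,
    dry_to_fresh,
    score_syndrome,
    superabundance_by_category,
    top_n,
)


def brute_force_points(classes: dict[Nutrient, ConcentrationClass], syndrome: Syndrome) -> int:
    """Independent oracle: literal sum of the 3/2/1 point rule."""
    total = 0
    for nutrient in SYNDROME_NUTRIENTS[syndrome]:
        cls = classes.get(nutrient)
        if cls is ConcentrationClass.extremely_high:
            total += 3
        elif cls is ConcentrationClass.very_high:
            total += 2
        elif cls is ConcentrationClass.high:
            total += 1
    return total


class TestDryToFresh:
    @pytest.mark.parametrize(
        "dry, moisture, expected", [(10, 0.9, 1.0), (5, 0.0, 5.0), (8, 0.75, 2.0)]
    )
    def test_conversion(self, dry, moisture, expected):
        assert dry_to_fresh(dry, moisture) == pytest.approx(expected)

    def test_never_exceeds_dry_value(self):
        assert dry_to_fresh(3.0, 0.4) <= 3.0

    @pytest.mark.parametrize("moisture", [1.0, 1.5, -0.1])
    def test_invalid_moisture(self, moisture):
        with pytest.raises(ValueError):
            dry_to_fresh(1.0, moisture)


class TestAggregateProfile:
    def test_mixed_basis_mean(self):
        ms = [
            NutrientMeasurement(species_name="X y", nutrient=Nutrient.Fe, value=2.0),
            NutrientMeasurement(
                species_name="X y", nutrient=Nutrient.Fe, value=6.0,
                basis="dry", moisture_fraction=0.5,
            ),
        ]
        profile = aggregate_profile(ms)
        assert profile.means[Nutrient.Fe] == pytest.approx(2.5)
        assert profile.n_sources[Nutrient.Fe] == 2

    def test_single_measurement_identity(self):
        ms = [NutrientMeasurement(species_name="X y", nutrient=Nutrient.Ca, value=40.0)]
        assert aggregate_profile(ms).means == {Nutrient.Ca: 40.0}

    def test_absent_nutrient_absent_from_means(self):
        ms = [NutrientMeasurement(species_name="X y", nutrient=Nutrient.Ca, value=40.0)]
        assert Nutrient.Fe not in aggregate_profile(ms).means

    def test_mixed_species_rejected(self):
        ms = [
            NutrientMeasurement(species_name="A b", nutrient=Nutrient.Fe, value=1.0),
            NutrientMeasurement(species_name="C d", nutrient=Nutrient.Fe, value=2.0),
        ]
        with pytest.raises(ValueError, match="mixed species"):
            aggregate_profile(ms)

    @given(
        values=st.lists(st.floats(0.0, 1e3), min_size=1, max_size=8),
        scale=st.floats(0.1, 10.0),
    )
    @settings(max_examples=100, derandomize=True)
    def test_permutation_invariant_and_scale_consistent(self, values, scale):
        def profile_of(vals):
            return aggregate_profile(
                [
                    NutrientMeasurement(species_name="X y", nutrient=Nutrient.Mg, value=v)
                    for v in vals
                ]
            ).means[Nutrient.Mg]

        mean = profile_of(values)
        assert profile_of(list(reversed(values))) == pytest.approx(mean)
        assert profile_of([v * scale for v in values]) == pytest.approx(
            mean * scale, rel=1e-9, abs=1e-9
        )

    def test_combine_parts_takes_per_nutrient_maximum(self):
        leaf = NutrientProfile("X y", {Nutrient.Fe: 5.0, Nutrient.Ca: 10.0}, {Nutrient.Fe: 1, Nutrient.Ca: 1}, "leaf")
        fruit = NutrientProfile("X y", {Nutrient.Fe: 2.0, Nutrient.Zn: 1.0}, {Nutrient.Fe: 1, Nutrient.Zn: 1}, "fruit")
        combined = combine_parts([leaf, fruit])
        assert combined.means == {Nutrient.Fe: 5.0, Nutrient.Ca: 10.0, Nutrient.Zn: 1.0}


class TestScoreSyndrome:
    def test_moringa_traditional(self):
        classes = {
            Nutrient.Fe: ConcentrationClass.extremely_high,
            Nutrient.Zn: ConcentrationClass.very_high,
            Nutrient.vitA: ConcentrationClass.very_high,
        }
        score = score_syndrome(classes, Syndrome.traditional, species_name="Moringa oleifera")
        assert score.points == 7
        assert score.qualifies

    def test_toona_industrial(self):
        classes = {
            Nutrient.Ca: ConcentrationClass.very_high,
            Nutrient.vitA: ConcentrationClass.extremely_high,
            Nutrient.vitC: ConcentrationClass.very_high,
            Nutrient.vitE: ConcentrationClass.extremely_high,
        }
        score = score_syndrome(classes, Syndrome.industrial)
        assert score.points == 10
        assert score.qualifies

    def test_all_medium_scores_zero(self):
        classes = {n: ConcentrationClass.medium for n in Nutrient}
        score = score_syndrome(classes, Syndrome.traditional)
        assert score.points == 0
        assert not score.qualifies

    def test_missing_nutrients_contribute_zero_and_are_flagged(self):
        score = score_syndrome({Nutrient.Fe: ConcentrationClass.extremely_high},
                               Syndrome.traditional)
        assert score.points == 3
        assert score.contributing[Nutrient.Zn] is None

    @pytest.mark.parametrize(
        "fixture, syndrome",
        [
            (TRADITIONAL_MULTINUTRIENT, Syndrome.traditional),
            (INDUSTRIAL_MULTINUTRIENT, Syndrome.industrial),
        ],
    )
    def test_all_published_multinutrient_species_qualify(self, fixture, syndrome):
        for row in fixture:
            score = score_syndrome(row.classes, syndrome, species_name=row.species_name)
            assert score.qualifies, (row.species_name, score.points)
            assert score.points == brute_force_points(row.classes, syndrome)

    def test_exhaustive_enumeration_oracle_traditional(self):
        """Implementation matches the brute-force oracle over all 6^4 class
        combinations of the four traditional-syndrome nutrients."""
        nutrients = SYNDROME_NUTRIENTS[Syndrome.traditional]
        for combo in itertools.product(ConcentrationClass, repeat=len(nutrients)):
            classes = dict(zip(nutrients, combo))
            score = score_syndrome(classes, Syndrome.traditional)
            assert score.points == brute_force_points(classes, Syndrome.traditional)
            assert score.qualifies == (score.points >= QUALIFYING_SCORE)

    def test_score_bounds(self):
        best = {n: ConcentrationClass.extremely_high for n in Nutrient}
        assert score_syndrome(best, Syndrome.traditional).points == 12
        assert score_syndrome(best, Syndrome.industrial).points == 18

    @given(
        combo=st.tuples(*[st.sampled_from(list(ConcentrationClass))] * 4),
        idx=st.integers(0, 3),
    )
    @settings(max_examples=200, derandomize=True)
    def test_upgrading_one_class_never_decreases_points(self, combo, idx):
        nutrients = SYNDROME_NUTRIENTS[Syndrome.traditional]
        classes = dict(zip(nutrients, combo))
        base = score_syndrome(classes, Syndrome.traditional).points
        cls = classes[nutrients[idx]]
        if cls is ConcentrationClass.extremely_high:
            return
        classes[nutrients[idx]] = ConcentrationClass(cls + 1)
        assert score_syndrome(classes, Syndrome.traditional).points >= base


class TestTopN:
    def _profiles(self, values: dict[str, float]) -> list[NutrientProfile]:
        return [
            NutrientProfile(name, {Nutrient.Ca: v}, {Nutrient.Ca: 1})
            for name, v in values.items()
        ]

    def test_descending_order(self):
        ranked = top_n(self._profiles({"A a": 100, "B b": 300, "C c": 200}), Nutrient.Ca, 2)
        assert ranked == [("B b", 300), ("C c", 200)]

    def test_alphabetical_tie_break(self):
        ranked = top_n(self._profiles({"B b": 100, "A a": 100}), Nutrient.Ca, 2)
        assert [name for name, _ in ranked] == ["A a", "B b"]

    def test_n_larger_than_list(self):
        ranked = top_n(self._profiles({"A a": 1}), Nutrient.Ca, 10)
        assert len(ranked) == 1

    def test_species_without_nutrient_excluded(self):
        profiles = self._profiles({"A a": 1}) + [
            NutrientProfile("B b", {Nutrient.Fe: 9}, {Nutrient.Fe: 1})
        ]
        assert top_n(profiles, Nutrient.Ca, 10) == [("A a", 1)]


def _record(name: str, form: Form, parts: set[Part]) -> SpeciesRecord:
    return SpeciesRecord(
        species_name=name, family="F", form=form, parts=frozenset(parts),
        thermal_climates=frozenset({"subtropical"}), moisture=frozenset({"humid"}),
        shade="sun_only", domestication="regional", lifecycle="perennial",
    )


class TestSuperabundanceByCategory:
    def test_all_superabundant_cohort(self, bounds_set):
        ca_max = bounds_set[Nutrient.Ca].ref_max
        profiles = [
            NutrientProfile(f"S sp{i}", {Nutrient.Ca: ca_max * 3}, {Nutrient.Ca: 1})
            for i in range(4)
        ]
        records = [
            _record("S sp0", Form.woody, {Part.leaf}),
            _record("S sp1", Form.woody, {Part.shoot}),
            _record("S sp2", Form.herb, {Part.leaf}),
            _record("S sp3", Form.vine, {Part.ripe_fruit}),
        ]
        summary = superabundance_by_category(profiles, records, bounds_set)
        assert all(s.prop_one_or_more == 1.0 for s in summary.values())

    def test_only_constructed_cell_positive(self, bounds_set):
        ca = bounds_set[Nutrient.Ca]
        profiles = [
            NutrientProfile("W leaf", {Nutrient.Ca: ca.ref_max * 3}, {Nutrient.Ca: 1}),
            NutrientProfile("H leaf", {Nutrient.Ca: ca.ref_min}, {Nutrient.Ca: 1}),
        ]
        records = [
            _record("W leaf", Form.woody, {Part.leaf}),
            _record("H leaf", Form.herb, {Part.leaf}),
        ]
        summary = superabundance_by_category(profiles, records, bounds_set)
        assert summary[(Form.woody, Part.leaf)].prop_one_or_more == 1.0
        assert summary[(Form.herb, Part.leaf)].prop_one_or_more == 0.0

    def test_unmatched_profile_logged_and_excluded(self, bounds_set, caplog):
        profiles = [NutrientProfile("Ghost sp", {Nutrient.Ca: 1.0}, {Nutrient.Ca: 1})]
        with caplog.at_level("WARNING"):
            summary = superabundance_by_category(profiles, [], bounds_set)
        assert summary == {}
        assert "Ghost sp" in caplog.text
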