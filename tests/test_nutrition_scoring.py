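"""Unit and property tests of the calorie-scoring stage."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import foodsec as fs
from foodsec.nutrition_scoring import CompositionEntry
from foodsec.records import ConsumptionRecord, PersonSpec

AE = fs.AdultEquivalentTable.default()


@pytest.mark.parametrize("sex,age,expected", [
    ("male", 45, 1.00),
    ("female", 45, 0.82),
    ("male", 0.5, 0.33),
    ("female", 62, 0.74),
    ("male", 17, 1.14),
    ("female", 25, 0.80),
    # shared printed endpoints resolve half-open: 5 falls in [5, 7)
    ("male", 5, 0.74),
    ("female", 7, 0.72),
    ("male", 60, 0.84),
])
def test_adult_equivalent_band_lookup(sex, age, expected):
    assert fs.adult_equivalent(PersonSpec(age, sex), AE) == pytest.approx(expected)


def test_adult_equivalent_rejects_negative_age():
    with pytest.raises(ValueError):
        PersonSpec(-1.0, "male")
    with pytest.raises(ValueError):
        AE.factors([-0.5], ["male"])


def test_household_adult_equivalents_sums_member_factors():
    roster = [PersonSpec(35, "male"), PersonSpec(32, "female"),
              PersonSpec(8, "male"), PersonSpec(4, "female")]
    assert fs.household_adult_equivalents(roster, AE) == pytest.approx(3.28)
    assert fs.household_adult_equivalents([PersonSpec(45, "male")], AE) == 1.0
    with pytest.raises(ValueError):
        fs.household_adult_equivalents([], AE)


@given(st.lists(st.tuples(st.floats(0, 99), st.sampled_from(["male", "female"])),
                min_size=1, max_size=10))
@settings(deadline=None, max_examples=50, derandomize=True)
def test_household_ae_bounded_by_max_factor(roster):
    total = fs.household_adult_equivalents(
        [PersonSpec(a, s) for a, s in roster], AE)
    assert 0 < total <= 1.14 * len(roster) + 1e-12
    assert total >= 0.33 * len(roster) - 1e-12


def test_edible_grams_removes_waste():
    entry = CompositionEntry(1, kcal_per_100g=100, waste_fraction=0.10,
                             grams_per_unit=500)
    assert fs.edible_grams(ConsumptionRecord(0, 1, 2.0), entry) == pytest.approx(900.0)
    no_waste = CompositionEntry(1, 100, 0.0, 500)
    assert fs.edible_grams(ConsumptionRecord(0, 1, 2.0), no_waste) == pytest.approx(1000.0)
    assert fs.edible_grams(ConsumptionRecord(0, 1, 0.0), entry) == 0.0


def test_household_intake_hand_arithmetic():
    # one reference adult eating 365,000 g edible of a 220 kcal/100 g item
    # over the year: 803,000 kcal/yr = 2,200 kcal/day per AE -> insecure
    comp = {1: CompositionEntry(1, 220.0, 0.0, 1.0)}
    res = fs.household_intake([ConsumptionRecord(0, 1, 365_000.0)], comp,
                              [PersonSpec(45, "male")], AE)
    assert res.annual_kcal == pytest.approx(803_000.0)
    assert res.daily_kcal == pytest.approx(2200.0)
    assert res.adult_equivalents == 1.0
    assert res.y_star == pytest.approx(0.0, abs=1e-9)
    assert not res.food_secure  # y* <= 0 is insecure, boundary included


def test_threshold_is_strict():
    comp = {1: CompositionEntry(1, 220.0, 0.0, 1.0)}
    just_above = fs.household_intake(
        [ConsumptionRecord(0, 1, 365.0 * 2201 / 2.2)], comp,
        [PersonSpec(45, "male")], AE)
    assert just_above.daily_kcal_per_ae == pytest.approx(2201.0)
    assert just_above.food_secure


def test_unknown_item_is_reported_by_id():
    comp = {1: CompositionEntry(1, 220.0, 0.0, 1.0)}
    with pytest.raises(KeyError, match="99"):
        fs.household_intake([ConsumptionRecord(0, 99, 1.0)], comp,
                            [PersonSpec(45, "male")], AE)


def test_hdds_percentage_of_catalog():
    recs = [ConsumptionRecord(0, i, 1.0) for i in range(1, 54)]
    score = fs.hdds(recs)
    assert score.items_consumed == 53
    assert score.hdds == pytest.approx(19.85, abs=0.01)

    full = [ConsumptionRecord(0, i, 1.0) for i in range(1, 268)]
    assert fs.hdds(full).hdds == 100.0
    assert fs.hdds([]).hdds == 0.0
    # zero-quantity and duplicate records do not count
    dup = [ConsumptionRecord(0, 1, 1.0), ConsumptionRecord(0, 1, 2.0),
           ConsumptionRecord(0, 2, 0.0)]
    assert fs.hdds(dup).items_consumed == 1
    with pytest.raises(ValueError):
        fs.hdds([], catalog_size=0)


def _random_fixture(rng, n_households=5, n_items=12):
    comp = fs.generate_composition_table(n_items, int(rng.integers(2**31)))
    rows = []
    for h in range(1, n_households + 1):
        for item in rng.choice(n_items, size=rng.integers(1, n_items), replace=False):
            rows.append({"household_id": h, "item_id": int(item) + 1,
                         "quantity": float(rng.uniform(0, 500))})
    cons = pd.DataFrame(rows)
    members = pd.DataFrame({
        "household_id": np.repeat(np.arange(1, n_households + 1), 2),
        "age": rng.uniform(1, 70, 2 * n_households),
        "sex": rng.choice(["male", "female"], 2 * n_households),
    })
    return cons, comp, members


def _brute_force_scores(cons, comp, members, mcr=2200.0):
    """Independent straight-loop recomputation (shares no code with
    score_households)."""
    comp_by_id = {int(r.item_id): r for r in comp.itertuples()}
    out = {}
    for h in sorted(members["household_id"].unique()):
        kcal = 0.0
        for r in cons.itertuples():
            if r.household_id != h:
                continue
            e = comp_by_id[int(r.item_id)]
            grams = r.quantity * e.grams_per_unit * (1 - e.waste_fraction)
            kcal += grams * e.kcal_per_100g / 100.0
        ae = 0.0
        for m in members.itertuples():
            if m.household_id != h:
                continue
            ae += fs.adult_equivalent(PersonSpec(m.age, m.sex), AE)
        per_ae = kcal / 365.0 / ae
        out[h] = (kcal, ae, per_ae, per_ae - mcr > 0)
    return out


def test_scoring_matches_bruteforce_loop(rng):
    cons, comp, members = _random_fixture(rng)
    got = fs.score_households(cons, comp, members, AE)
    expected = _brute_force_scores(cons, comp, members)
    for row in got.itertuples():
        kcal, ae, per_ae, secure = expected[row.household_id]
        assert row.annual_kcal == pytest.approx(kcal, rel=1e-9)
        assert row.adult_equivalents == pytest.approx(ae, rel=1e-9)
        assert row.daily_kcal_per_ae == pytest.approx(per_ae, rel=1e-9)
        assert row.food_secure == secure


def test_order_invariance_and_monotonicity(rng):
    cons, comp, members = _random_fixture(rng)
    base = fs.score_households(cons, comp, members, AE)
    shuffled = cons.sample(frac=1.0, random_state=1).reset_index(drop=True)
    again = fs.score_households(shuffled, comp, members, AE)
    merged = base.merge(again, on="household_id", suffixes=("_a", "_b"))
    assert np.allclose(merged["annual_kcal_a"], merged["annual_kcal_b"])
    assert (merged["food_secure_a"] == merged["food_secure_b"]).all()

    # increasing any quantity never lowers kcal nor flips secure -> insecure
    bumped = cons.copy()
    i = int(rng.integers(len(bumped)))
    bumped.loc[i, "quantity"] += 100.0
    after = fs.score_households(bumped, comp, members, AE)
    m = base.merge(after, on="household_id", suffixes=("_a", "_b"))
    assert (m["annual_kcal_b"] >= m["annual_kcal_a"] - 1e-9).all()
    assert not ((m["food_secure_a"]) & (~m["food_secure_b"])).any()


def test_doubling_roster_halves_per_ae_intake(rng):
    cons, comp, members = _random_fixture(rng)
    doubled = pd.concat([members, members], ignore_index=True)
    a = fs.score_households(cons, comp, members, AE)
    b = fs.score_households(cons, comp, doubled, AE)
    m = a.merge(b, on="household_id", suffixes=("_1", "_2"))
    assert np.allclose(m["daily_kcal_per_ae_2"], m["daily_kcal_per_ae_1"] / 2.0)
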