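"""Model-matrix construction: quintiles, recodes, shares."""

import numpy as np
import pandas as pd
import pytest

import foodsec as fs
from foodsec.covariates import CovariateConfig


def _households(incomes, year=2014, region=1):
    n = len(incomes)
    return pd.DataFrame({"household_id": np.arange(1, n + 1),
                         "region_id": region, "year": year,
                         "monthly_income": incomes})


def test_quintiles_match_percentile_oracle():
    hh = _households(list(range(1, 11)))
    q = fs.assign_income_quintiles(hh)
    expected = {1: 1, 2: 1, 3: 2, 4: 2, 5: 3, 6: 3, 7: 4, 8: 4, 9: 5, 10: 5}
    assert dict(zip(hh["monthly_income"], q)) == expected


def test_quintiles_equal_incomes_collapse_with_warning():
    hh = _households([7.0] * 20)
    with pytest.warns(UserWarning, match="degenerate"):
        q = fs.assign_income_quintiles(hh)
    assert set(q) == {1}


def test_quintiles_order_invariant_and_balanced(rng):
    incomes = rng.lognormal(10, 0.5, 103)
    hh = _households(incomes)
    q1 = fs.assign_income_quintiles(hh)
    perm = rng.permutation(len(hh))
    hh2 = hh.iloc[perm].reset_index(drop=True)
    q2 = fs.assign_income_quintiles(hh2)
    by_id1 = dict(zip(hh["household_id"], q1))
    by_id2 = dict(zip(hh2["household_id"], q2))
    assert by_id1 == by_id2
    sizes = pd.Series(list(by_id1.values())).value_counts()
    assert sizes.max() - sizes.min() <= 1  # distinct incomes: near-equal cells
    # labels are monotone in income
    s = hh.sort_values("monthly_income")
    assert (np.diff([by_id1[h] for h in s["household_id"]]) >= 0).all()


def test_quintiles_small_cell_raises_naming_cell():
    hh = _households([1, 2, 3], year=2017)
    with pytest.raises(ValueError, match="2017"):
        fs.assign_income_quintiles(hh)


def _tiny_survey():
    """Two hand-built households hitting both sides of every recode."""
    households = pd.DataFrame({
        "household_id": [1, 2], "region_id": [1, 1], "year": [2014, 2014],
        "head_index": [0, 0],
        "monthly_income": [100.0, 200.0],
        "total_expenditure": [80.0, 120.0],
        "food_expenditure": [40.0, 120.0],
        "agricultural_income": [240.0, 0.0],
        "home_owned": [True, False],
        "home_size": [90.0, 60.0],
        "head_employed": [True, False],
        "head_under_education": [False, True],
        "head_married": [True, False],
        "n_students": [2, 1],
    })
    members = pd.DataFrame({
        "household_id": [1, 1, 1, 2, 2],
        "member_index": [0, 1, 2, 0, 1],
        "age": [41.0, 38.0, 9.0, 39.0, 10.0],
        "sex": ["male", "female", "male", "female", "female"],
    })
    intake = pd.DataFrame({"household_id": [1, 2], "food_secure": [True, False]})
    hdds = pd.DataFrame({"household_id": [1, 2], "hdds": [20.0, 10.0]})
    return households, members, intake, hdds


def _padded_survey():
    """_tiny_survey plus filler rows so the quintile cell is big enough."""
    households, members, intake, hdds = _tiny_survey()
    filler_ids = np.arange(3, 11)
    filler = pd.DataFrame({
        "household_id": filler_ids, "region_id": 1, "year": 2014,
        "head_index": 0, "monthly_income": np.linspace(300, 1000, 8),
        "total_expenditure": 100.0, "food_expenditure": 50.0,
        "agricultural_income": 0.0, "home_owned": False, "home_size": 70.0,
        "head_employed": True, "head_under_education": False,
        "head_married": True, "n_students": 0})
    fm = pd.DataFrame({"household_id": filler_ids, "member_index": 0,
                       "age": 50.0, "sex": "male"})
    households = pd.concat([households, filler], ignore_index=True)
    members = pd.concat([members, fm], ignore_index=True)
    intake = pd.concat([intake, pd.DataFrame(
        {"household_id": filler_ids, "food_secure": True})], ignore_index=True)
    hdds = pd.concat([hdds, pd.DataFrame(
        {"household_id": filler_ids, "hdds": 15.0})], ignore_index=True)
    return households, members, intake, hdds


def test_threshold_recodes_both_sides():
    mm = fs.build_model_matrix(*_padded_survey())
    r1 = mm.set_index("household_id").loc[1]
    # 3 members, 2 students, male head aged 41, owned 90 m2 home
    assert (r1[["size_ge3", "students_ge2", "head_male", "head_age",
                "home_owned", "home_size"]] == 1).all()
    assert r1["food_share"] == pytest.approx(50.0)
    assert r1["agri_share"] == pytest.approx(100.0 * 240.0 / 1200.0)
    r2 = mm.set_index("household_id").loc[2]
    # 2 members, 1 student, female head aged 39, rented 60 m2 home
    assert (r2[["size_ge3", "students_ge2", "head_male", "head_age",
                "home_owned", "home_size"]] == 0).all()
    assert r2["food_share"] == pytest.approx(100.0)  # food == total spend
    assert r2["fs"] == 0 and r1["fs"] == 1


def test_continuous_encodings_keep_raw_values():
    cfg = CovariateConfig(age_encoding="continuous",
                          homesize_encoding="continuous")
    mm = fs.build_model_matrix(*_padded_survey(), config=cfg)
    row = mm.set_index("household_id").loc[1]
    assert row["head_age"] == pytest.approx(41.0)
    assert row["home_size"] == pytest.approx(90.0)


def test_zero_expenditure_row_excluded_with_warning():
    households, members, intake, hdds = _padded_survey()
    households.loc[households["household_id"] == 3, "total_expenditure"] = 0.0
    with pytest.warns(UserWarning, match="excluded 1"):
        mm = fs.build_model_matrix(households, members, intake, hdds)
    assert 3 not in set(mm["household_id"])


def test_dummy_partition_shares_and_idempotence(small_survey, scored,
                                                hdds_frame, model_matrix):
    dummies = model_matrix[["ig2", "ig3", "ig4", "ig5"]].sum(axis=1)
    assert dummies.isin([0, 1]).all()
    # rows with all four zero are exactly the first-quintile households
    q = fs.assign_income_quintiles(small_survey.households)
    q1_ids = set(small_survey.households.loc[q == 1, "household_id"])
    assert set(model_matrix.loc[dummies == 0, "household_id"]) == q1_ids
    for col in ("food_share", "hdds", "agri_share"):
        assert model_matrix[col].between(0, 100).all()
    rebuilt = fs.build_model_matrix(small_survey.households,
                                    small_survey.members, scored, hdds_frame)
    pd.testing.assert_frame_equal(model_matrix, rebuilt)


def test_builder_reproduces_generator_truth(small_survey, model_matrix):
    truth = fs.ground_truth(small_survey).covariates
    pd.testing.assert_frame_equal(model_matrix.reset_index(drop=True),
                                  truth.reset_index(drop=True))
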