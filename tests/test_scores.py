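import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from dietfrail import (
    ConfigurationError,
    assign_tertiles,
    score_ahei,
    score_dash,
    score_dii,
    score_med,
    score_pdi_family,
)
from dietfrail.scores import DIIScorer, MEDScorer, intake_frame
from dietfrail.simulate import ITEM_MODELS, TruthParams, generate_cohort

from conftest import brute_force_quantile

ALL_ITEMS = list(ITEM_MODELS) + ["energy_kcal"]


def _intakes(rows, sex="male"):
    """Build an intake frame from partial dicts (unspecified items zero)."""
    data = []
    for row in rows:
        full = {item: 0.0 for item in ALL_ITEMS}
        full.update(row)
        full["sex"] = row.get("sex", sex)
        data.append(full)
    return pd.DataFrame(data)


# ----------------------------------------------------------------------- AHEI

def test_ahei_maximal_intake_scores_110_and_100_without_alcohol(taxonomy):
    best = _intakes([{
        "vegetables": 6.0, "fruit": 5.0, "whole_grains": 95.0, "ssb": 0.0,
        "fruit_juice": 0.0, "nuts": 1.2, "legumes": 0.0, "red_meat": 0.0,
        "processed_meat": 0.0, "trans_fat_pct": 0.4, "n3_g": 0.3,
        "pufa_pct": 11.0, "sodium_mg": 1000.0, "alcohol_g": 14.0,  # 1 drink
    }])
    assert score_ahei(best, taxonomy)[0] == pytest.approx(110.0)
    assert score_ahei(best, taxonomy, alcohol_item_removed=True)[0] == pytest.approx(100.0)


def test_ahei_all_zero_intake_hits_component_floors(taxonomy):
    zero = _intakes([{}])
    # vegetables..n3 floor at 0; ssb/meat at best (no intake of adverse items)
    # scores 10 each; trans at 0% beats the 0.5% cutoff (10); pufa 0% floors
    # (0); sodium 0 beats the healthy cutoff (10); abstainer alcohol 2.5.
    expected = 0 + 0 + 0 + 10 + 0 + 10 + 10 + 0 + 0 + 10 + 2.5
    assert score_ahei(zero, taxonomy)[0] == pytest.approx(expected)


def test_ahei_hand_scored_participant(taxonomy, intake_row):
    # Component-wise hand score for the fixture row (male):
    # vegetables 2.5/5*10=5; fruit 2/4*10=5; whole grains 45/90*10=5;
    # ssb+juice 0.5/d -> (1-0.5)*10=5; nuts+legumes 0.75 -> 7.5;
    # red+processed 0.75 -> (1.5-0.75)/1.5*10=5; trans 2.25% -> 5;
    # n3 125mg -> 5; pufa 6% -> 5; sodium 2224.5 -> 5; alcohol 1 drink -> 10.
    expected = 5 * 10 + 10
    assert score_ahei(intake_row, taxonomy)[0] == pytest.approx(expected)


def test_ahei_alcohol_removed_equals_full_when_alcohol_scores_zero(taxonomy):
    heavy = _intakes([{"vegetables": 3.0, "alcohol_g": 14.0 * 5}])  # 5 drinks
    full = score_ahei(heavy, taxonomy)[0]
    removed = score_ahei(heavy, taxonomy, alcohol_item_removed=True)[0]
    assert full == pytest.approx(removed)


# ----------------------------------------------------------------------- DASH

def test_dash_extreme_participant_scores_40(taxonomy):
    rows = [{"fruit": f, "vegetables": f, "nuts": f, "whole_grains": 10 * f,
             "dairy_low_fat": f, "sodium_mg": 3000 - 100 * f,
             "red_meat": 3 - 0.2 * f, "ssb": 3 - 0.2 * f}
            for f in range(1, 11)]
    scores = score_dash(_intakes(rows), taxonomy)
    assert scores[-1] == 40.0  # top of every healthy, bottom of every adverse
    assert scores[0] == 8.0


def test_dash_identical_diets_all_share_one_score(taxonomy):
    rows = [{"fruit": 2.0, "sodium_mg": 2000.0}] * 6
    scores = score_dash(_intakes(rows), taxonomy)
    assert len(set(scores)) == 1


def test_dash_toy_cohort_matches_brute_force_quintiles(taxonomy):
    rng = np.random.default_rng(4)
    rows = [{item: float(rng.gamma(2.0, 1.0)) for item in
             ("fruit", "vegetables", "nuts", "legumes", "whole_grains",
              "dairy_low_fat", "sodium_mg", "red_meat", "processed_meat", "ssb")}
            for _ in range(10)]
    intakes = _intakes(rows)
    got = score_dash(intakes, taxonomy)
    expected = np.zeros(10)
    for name, comp in taxonomy.dash["components"].items():
        total = sum(intakes[c].to_numpy() * w for c, w in comp["items"].items())
        q = brute_force_quantile(total, total, 5)
        expected += q if comp["direction"] == "healthy" else 6 - q
    np.testing.assert_array_equal(got, expected)


# ------------------------------------------------------------------------ MED

def test_med_all_favourable_scores_9(taxonomy):
    favourable = {"vegetables": 5.0, "legumes": 2.0, "fruit": 4.0, "nuts": 1.0,
                  "whole_grains": 90.0, "fish": 1.5, "mufa_g": 40.0, "sfa_g": 10.0,
                  "red_meat": 0.01, "dairy_low_fat": 0.01, "alcohol_g": 20.0}
    background = {"vegetables": 1.0, "legumes": 0.2, "fruit": 1.0, "nuts": 0.1,
                  "whole_grains": 20.0, "fish": 0.2, "mufa_g": 20.0, "sfa_g": 30.0,
                  "red_meat": 1.5, "dairy_low_fat": 2.0, "alcohol_g": 0.0}
    intakes = _intakes([favourable] + [background] * 6)
    assert score_med(intakes, taxonomy)[0] == 9.0


def test_med_exact_median_boundary_beneficial_1_detrimental_0(taxonomy):
    row = {"vegetables": 2.0, "legumes": 1.0, "fruit": 1.0, "whole_grains": 30.0,
           "fish": 0.5, "mufa_g": 20.0, "sfa_g": 20.0, "red_meat": 1.0,
           "dairy_low_fat": 1.0}
    intakes = _intakes([row] * 5)  # every intake equals the cohort median
    # 6 beneficial components score 1 (>= median); meat and dairy score 0
    # (not < median); alcohol 0 is outside the moderate range.
    assert score_med(intakes, taxonomy)[0] == 6.0


def test_med_toy_cohort_matches_enumeration(taxonomy):
    rng = np.random.default_rng(12)
    items = ("vegetables", "legumes", "fruit", "nuts", "whole_grains",
             "refined_grains", "fish", "mufa_g", "sfa_g", "red_meat",
             "processed_meat", "dairy_low_fat", "dairy_high_fat", "alcohol_g")
    rows = [{item: float(rng.gamma(2.0, 1.5)) + 0.1 for item in items}
            for _ in range(7)]
    intakes = _intakes(rows, sex="female")
    got = score_med(intakes, taxonomy)

    expected = np.zeros(7)
    comps = taxonomy.med["components"]
    for name, comp in comps.items():
        if comp.get("kind") == "ratio":
            total = intakes["mufa_g"].to_numpy() / intakes["sfa_g"].to_numpy()
        else:
            total = sum(intakes[c].to_numpy() * w for c, w in comp["items"].items())
        med = np.median(total)
        if comp["direction"] == "beneficial":
            expected += total >= med
        else:
            expected += total < med
    lo, hi = taxonomy.med["alcohol"]["moderate"]["female"]
    grams = intakes["alcohol_g"].to_numpy()
    expected += (grams >= lo) & (grams <= hi)
    np.testing.assert_array_equal(got, expected)


def test_med_missing_fat_column_errors(taxonomy):
    intakes = _intakes([{"vegetables": 1.0}] * 3).drop(columns=["mufa_g"])
    with pytest.raises(ConfigurationError, match="mufa"):
        score_med(intakes, taxonomy)


# ------------------------------------------------------------------------ DII

def test_dii_zero_at_reference_means(taxonomy):
    row = {}
    for name, param in taxonomy.dii["parameters"].items():
        (col, weight), = param["items"].items()
        row[col] = param["ref_mean"] / weight
    assert score_dii(_intakes([row]), taxonomy)[0] == pytest.approx(0.0, abs=1e-12)


def test_dii_saturates_at_signed_effect_sum(taxonomy):
    huge = {"energy_kcal": 1e9, "fiber_g": 1e9, "vitamin_c_mg": 1e9,
            "alcohol_g": 1e9, "sfa_g": 1e9, "mufa_g": 1e9, "pufa_g": 1e9,
            "n3_g": 1e9}
    limit = sum(p["effect"] for p in taxonomy.dii["parameters"].values())
    assert score_dii(_intakes([huge]), taxonomy)[0] == pytest.approx(limit, abs=1e-9)


def test_dii_three_parameter_worked_example(taxonomy):
    # Hand computation over fiber, vitamin C and saturated fat only.
    sub = dataclasses.replace(
        taxonomy,
        dii={"parameters": {k: taxonomy.dii["parameters"][k]
                            for k in ("fiber", "vitamin_c", "saturated_fat")},
             "alcohol_energy_parameters": []},
    )
    row = {"fiber_g": 25.0, "vitamin_c_mg": 80.0, "sfa_g": 35.0}
    got = score_dii(_intakes([row]), sub)[0]
    expected = 0.0
    for col, mean, sd, eff in [("fiber_g", 18.8, 4.9, -0.663),
                               ("vitamin_c_mg", 118.2, 43.46, -0.424),
                               ("sfa_g", 28.6, 8.0, 0.373)]:
        z = (row[col] - mean) / sd
        expected += (2.0 * norm.cdf(z) - 1.0) * eff
    assert got == pytest.approx(expected, abs=1e-12)


def test_dii_drop_alcohol_energy_removes_those_parameters(taxonomy):
    scorer = DIIScorer(taxonomy, drop_alcohol_energy=True).fit(_intakes([{}]))
    assert set(scorer.parameters_).isdisjoint({"alcohol", "energy"})


# ----------------------------------------------------------------- PDI family

def test_pdi_plant_extreme_scores_90(taxonomy):
    plant_groups = ["whole_grains", "fruit", "vegetables", "nuts", "legumes",
                    "vegetable_oils", "tea_coffee", "fruit_juice", "refined_grains",
                    "potatoes", "ssb", "sweets"]
    animal_items = ["animal_fat", "dairy_low_fat", "dairy_high_fat", "eggs",
                    "fish", "red_meat", "processed_meat", "misc_animal"]
    rows = [{**{g: float(f) for g in plant_groups},
             **{g: 10.0 - f for g in animal_items}}
            for f in range(1, 11)]
    scores = score_pdi_family(_intakes(rows), taxonomy)
    assert scores.loc[9, "pdi"] == 90.0
    assert scores.loc[0, "pdi"] == 18.0


def test_pdi_family_matches_brute_force_enumeration(taxonomy):
    rng = np.random.default_rng(77)
    items = ["whole_grains", "fruit", "vegetables", "nuts", "legumes",
             "vegetable_oils", "tea_coffee", "fruit_juice", "refined_grains",
             "potatoes", "ssb", "sweets", "animal_fat", "dairy_low_fat",
             "dairy_high_fat", "eggs", "fish", "red_meat", "processed_meat",
             "misc_animal"]
    rows = [{item: float(rng.gamma(2.0, 1.0)) for item in items} for _ in range(10)]
    intakes = _intakes(rows)
    got = score_pdi_family(intakes, taxonomy)

    positive = {"pdi": ("healthy_plant", "less_healthy_plant"),
                "hpdi": ("healthy_plant",), "updi": ("less_healthy_plant",)}
    expected = {k: np.zeros(10) for k in positive}
    for name, spec in taxonomy.pdi["groups"].items():
        total = sum(intakes[c].to_numpy() * w for c, w in spec["items"].items())
        q = brute_force_quantile(total, total, 5)
        for index, classes in positive.items():
            expected[index] += q if spec["class"] in classes else 6 - q
        # reversal symmetry: scores of opposite-direction indices sum to 6/group
        if spec["class"] == "less_healthy_plant":
            np.testing.assert_array_equal(q + (6 - q), np.full(10, 6))
    for index in positive:
        np.testing.assert_array_equal(got[index].to_numpy(), expected[index])


def test_pdi_requires_18_group_partition(taxonomy):
    groups = dict(taxonomy.pdi["groups"])
    groups.pop("eggs")
    broken = dataclasses.replace(taxonomy, pdi={"groups": groups})
    with pytest.raises(ConfigurationError, match="18"):
        score_pdi_family(_intakes([{}] * 3), broken)


# -------------------------------------------------------------------- tertiles

def test_tertiles_of_1_to_9_split_into_exact_thirds():
    scores = np.arange(1.0, 10.0)
    healthy = assign_tertiles(scores, "healthy")
    assert list(healthy[:3]) == ["unhealthier"] * 3
    assert list(healthy[3:6]) == ["medium"] * 3
    assert list(healthy[6:]) == ["healthier"] * 3
    flipped = assign_tertiles(scores, "unhealthy")
    assert list(flipped[:3]) == ["healthier"] * 3
    assert list(flipped[6:]) == ["unhealthier"] * 3


def test_tertiles_with_heavy_ties_match_brute_force():
    rng = np.random.default_rng(3)
    scores = rng.integers(0, 4, size=200).astype(float)
    got = assign_tertiles(scores, "healthy")
    ranks = brute_force_quantile(scores, scores, 3)
    labels = np.array(["unhealthier", "medium", "healthier"])[ranks - 1]
    np.testing.assert_array_equal(got, labels)


def test_tertile_sizes_balanced_without_ties():
    rng = np.random.default_rng(9)
    scores = rng.standard_normal(301)
    labels = assign_tertiles(scores, "healthy")
    counts = pd.Series(labels).value_counts()
    assert counts.max() - counts.min() <= 1


# ----------------------------------------------------------- range/monotonicity

def test_score_ranges_on_random_diets(taxonomy):
    cohort = generate_cohort(TruthParams(n=10_000, seed=55))
    intakes = intake_frame(cohort)
    assert np.all((score_ahei(intakes, taxonomy) >= 0)
                  & (score_ahei(intakes, taxonomy) <= 110))
    dash = score_dash(intakes, taxonomy)
    assert dash.min() >= 8 and dash.max() <= 40
    med = score_med(intakes, taxonomy)
    assert med.min() >= 0 and med.max() <= 9
    pdi = score_pdi_family(intakes, taxonomy)
    assert (pdi.to_numpy() >= 18).all() and (pdi.to_numpy() <= 90).all()
    n_params = len(taxonomy.dii["parameters"])
    dii = score_dii(intakes, taxonomy)
    bound = sum(abs(p["effect"]) for p in taxonomy.dii["parameters"].values())
    assert np.all(np.abs(dii) <= bound)


def test_more_vegetables_never_hurts_any_healthy_score(taxonomy):
    cohort = generate_cohort(TruthParams(n=400, seed=66))
    intakes = intake_frame(cohort)
    boosted = intakes.copy()
    boosted["vegetables"] = boosted["vegetables"] + 1.0

    assert np.all(score_ahei(boosted, taxonomy) >= score_ahei(intakes, taxonomy))
    # rank-based scores: compare with quantiles learned on the original cohort
    from dietfrail.scores import DASHScorer, PlantIndexScorer

    dash = DASHScorer(taxonomy).fit(intakes)
    assert np.all(dash.transform(boosted) >= dash.transform(intakes))
    med = MEDScorer(taxonomy).fit(intakes)
    assert np.all(med.transform(boosted) >= med.transform(intakes))
    plant = PlantIndexScorer(taxonomy).fit(intakes)
    before = plant.transform(intakes)
    after = plant.transform(boosted)
    assert np.all(after[:, 0] >= before[:, 0])   # overall index rises
    assert np.all(after[:, 1] >= before[:, 1])   # healthful index rises
    assert np.all(after[:, 2] <= before[:, 2])   # unhealthful index falls
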