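"""Breeding-scheme engine: selection, mating, stage structure, conservation.

Structural checks run on a proportionally scaled scheme (fast); consistency
with the coancestry oracle is verified on a scaled full run.
"""

import numpy as np
import pytest

from cryosim.experiment import build_scenario
from cryosim.pedigree import FEMALE, MALE, kinship_pair
from cryosim.scheme import (
    SchemeConfig,
    equalize_male_lines,
    mate_cohort,
    run_stage1,
    run_stage2,
    select_from_lines,
    select_parents,
)

SCALED = SchemeConfig().scaled(0.2)


def test_config_validation():
    with pytest.raises(ValueError):
        SchemeConfig(rho=-2.0)
    with pytest.raises(ValueError):
        SchemeConfig(cd_male=0.0)
    with pytest.raises(ValueError):
        SchemeConfig(n_sires_of_males=200)
    sc = SchemeConfig().scaled(0.1)
    assert sc.n_males_per_gen == 10 and sc.n_females_per_gen == 1000
    assert sc.n_sires_of_males == 2  # floor of 2 per selected list


@pytest.fixture(scope="module")
def scaled_stage1():
    return run_stage1(SCALED, np.random.default_rng(99), "all_young_bulls")


def test_selection_is_truncation_with_id_tiebreak(scaled_stage1):
    ped = scaled_stage1.ped
    males = ped.males(0)
    females = ped.females(0)
    parents = select_parents(ped, males, females, "EBVA", SCALED)
    assert len(parents.sires_of_males) == SCALED.n_sires_of_males
    assert len(parents.sires_of_females) == SCALED.n_sires_of_females
    assert len(parents.dams_of_males) == SCALED.n_dams_of_males
    assert len(parents.dams_of_females) == SCALED.n_females_per_gen
    # truncation: every selected sire beats every unselected male
    thresh = ped.ebva[parents.sires_of_females].min()
    unselected = np.setdiff1d(males, parents.sires_of_females)
    assert np.all(ped.ebva[unselected] <= thresh)
    # TMI with w_A = 1 degenerates to EBVA selection
    tmi_parents = select_parents(ped, males, females, "TMI", SCALED, w_b=0.0)
    assert np.array_equal(tmi_parents.sires_of_males, parents.sires_of_males)
    assert np.array_equal(tmi_parents.dams_of_males, parents.dams_of_males)


def test_mate_cohort_single_parent_pair(scaled_stage1):
    ped = scaled_stage1.ped.copy()
    kin = scaled_stage1.state.kinship
    males = scaled_stage1.state.male_ids
    females = scaled_stage1.state.female_ids
    ids, sires, dams = mate_cohort(
        males[:1], females[:1], 5, MALE, ped, kin, SCALED,
        generation=9, rng=np.random.default_rng(0),
    )
    assert np.all(sires == males[0]) and np.all(dams == females[0])
    assert len(ids) == 5


def test_mate_cohort_empty_parent_list(scaled_stage1):
    ped = scaled_stage1.ped.copy()
    with pytest.raises(ValueError):
        mate_cohort(np.array([], dtype=np.int64), np.array([0]), 3, MALE, ped,
                    scaled_stage1.state.kinship, SCALED, 9,
                    np.random.default_rng(0))


def test_progeny_count_dispersion_matches_binomial():
    """Random assignment of calves to sires: across-sire s.d. ~ sqrt(n*p*q)."""
    rng = np.random.default_rng(5)
    sds_m, sds_f = [], []
    for _ in range(300):
        counts = np.bincount(rng.integers(0, 10, 100), minlength=10)
        sds_m.append(counts.std(ddof=0))
        counts = np.bincount(rng.integers(0, 20, 10000), minlength=20)
        sds_f.append(counts.std(ddof=0))
    assert np.mean(sds_m) == pytest.approx(np.sqrt(100 * 0.1 * 0.9), rel=0.05)
    assert np.mean(sds_f) == pytest.approx(np.sqrt(10000 * 0.05 * 0.95), rel=0.03)


def test_stage1_structure(scaled_stage1):
    ped = scaled_stage1.ped
    for g in range(SCALED.stage2_start):
        assert len(ped.males(g)) == SCALED.n_males_per_gen
        assert len(ped.females(g)) == SCALED.n_females_per_gen
    # store-all mode banks every bull of generations 0..7
    assert len(scaled_stage1.bank) == 8 * SCALED.n_males_per_gen
    assert len(scaled_stage1.summaries) == 2 * SCALED.stage2_start


def test_inbreeding_equals_parental_coancestry_oracle(scaled_stage1):
    """F from the cohort matrix equals the pair-recursion on the pedigree."""
    ped = scaled_stage1.ped
    rng = np.random.default_rng(0)
    memo: dict = {}
    ids = rng.choice(ped.cohort(4), size=5, replace=False)
    for i in ids:
        s, d = int(ped.sire[i]), int(ped.dam[i])
        assert ped.f[i] == pytest.approx(kinship_pair(ped, s, d, memo), abs=1e-6)


def test_stage1_determinism():
    cfg = SchemeConfig().scaled(0.1)
    a = run_stage1(cfg, np.random.default_rng(7), "all_young_bulls")
    b = run_stage1(cfg, np.random.default_rng(7), "all_young_bulls")
    assert np.array_equal(a.ped.a, b.ped.a)
    assert np.array_equal(a.ped.sire, b.ped.sire)
    assert a.summaries == b.summaries


def test_equalize_male_lines_plan():
    plan = equalize_male_lines(np.array([3, 1, 2]), 9)
    counts = {s: np.sum(plan == s) for s in (1, 2, 3)}
    assert set(counts.values()) == {3}
    with pytest.raises(ValueError):
        equalize_male_lines(np.array([1, 2]), 9)


def test_select_from_lines_keeps_one_sire_per_line(scaled_stage1):
    ped = scaled_stage1.ped.copy()
    males = scaled_stage1.state.male_ids
    n = len(males)
    sires = np.repeat(np.array([101, 202]), n // 2)
    som, sof = select_from_lines(ped, males, sires, 2, 4)
    # one sire-of-sires per paternal line, the best EBVA of its sib group
    for line in (101, 202):
        in_line = males[sires == line]
        best = in_line[np.argmax(ped.ebva[in_line])]
        assert best in som
        assert best in sof  # the best son serves on both paths


def test_conservation_gives_equal_lines_and_survival():
    cfg = SCALED
    s1 = run_stage1(cfg, np.random.default_rng(11), "all_young_bulls")
    run = run_stage2(s1, build_scenario("d3", bank_mode="all_young_bulls"),
                     cfg, np.random.default_rng(1))
    ped = run.ped
    n_lines = cfg.n_sires_of_males
    for g in range(cfg.stage2_start, cfg.n_generations):
        males = ped.males(g)
        sires, counts = np.unique(ped.sire[males], return_counts=True)
        assert len(sires) == n_lines
        assert np.all(counts == cfg.n_males_per_gen // n_lines)  # s.d. = 0
    # cryobank lines persist: contribution stays positive through generation 12
    assert run.contributions[cfg.n_generations - 1] > 0


def test_fraction_zero_keeps_regular_sires(scaled_stage1):
    run = run_stage2(scaled_stage1,
                     build_scenario("b2", bank_mode="all_young_bulls"),
                     SCALED, np.random.default_rng(3))
    g9_males = run.ped.males(SCALED.stage2_start)
    sires = np.unique(run.ped.sire[g9_males])
    assert len(run.used_bull_ids) == 0
    assert run.contributions == {10: 0.0, 12: 0.0}
    # all sires of generation-9 bulls were generation-8 bulls
    assert np.all(np.isin(sires, scaled_stage1.state.male_ids))


def test_cryobank_fraction_realized(scaled_stage1):
    run = run_stage2(scaled_stage1,
                     build_scenario("b3", bank_mode="all_young_bulls"),
                     SCALED, np.random.default_rng(3))
    nm = SCALED.n_males_per_gen
    n_cryo = int(round(0.4 * nm))
    assert len(run.source_links) == n_cryo
    g9 = run.ped.males(SCALED.stage2_start)
    cryo_sired = np.isin(g9, [o for _, o in run.source_links])
    assert cryo_sired.sum() == n_cryo
    # cryobank sires were born before generation 8
    assert np.all(run.used_bull_birth_generations < SCALED.stage2_start - 1)


def test_empty_bank_is_an_error():
    cfg = SchemeConfig().scaled(0.1)
    s1 = run_stage1(cfg, np.random.default_rng(2), "french_rules")
    s1.bank.entries.clear()
    with pytest.raises(ValueError):
        run_stage2(s1, build_scenario("b3"), cfg, np.random.default_rng(0))


def test_neutral_small_population_kinship_never_decreases():
    """Closed random-mating population: expected average kinship rises."""
    cfg = SchemeConfig(
        n_males_per_gen=6, n_females_per_gen=12, n_sires_of_males=3,
        n_dams_of_males=6, n_sires_of_females=3, n_generations=6,
        stage2_start=5,
    )
    diffs = []
    for rep in range(30):
        s1 = run_stage1(cfg, np.random.default_rng(1000 + rep),
                        "all_young_bulls")
        phi = [r["mean_phi"] for r in s1.summaries if r["group"] == "all"]
        diffs.extend(np.diff(phi))
    assert np.mean(diffs) > 0
    # per-step expectation is non-negative as well
    assert np.mean(np.array(diffs) < -1e-9) < 0.2
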