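"""Coancestry recursions, cohort-matrix propagation and gene contributions.

The memoised pair recursion is the oracle; the vectorised cohort propagation
and the gene-dropping estimator are checked against it (and against exact
expectations) on small random pedigrees.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cryosim.pedigree import (
    FEMALE,
    MALE,
    CohortKinship,
    Pedigree,
    average_kinship,
    expected_contribution,
    founder_kinship,
    gene_drop,
    inbreeding_from_parents,
    kinship_pair,
    mean_kinship_to_population,
    pair_coancestry,
    propagate_kinship,
    read_pedigree,
    write_pedigree,
    _offspring_block_numpy,
)
from conftest import make_random_pedigree


def _ped_from_rows(rows):
    """rows: (sex, sire, dam) with -1 for founders, in topological order."""
    ped = Pedigree()
    for sex, s, d in rows:
        g = 0 if s < 0 else int(max(ped.generation[s], ped.generation[d])) + 1
        z = np.zeros(1)
        ped.add_cohort(g, sex, np.array([s]), np.array([d]), z, z, z, z, z, 0.5)
    return ped


def test_distinct_founders_are_unrelated():
    ped = _ped_from_rows([(MALE, -1, -1), (FEMALE, -1, -1)])
    assert kinship_pair(ped, 0, 1) == 0.0
    assert kinship_pair(ped, 0, 0) == 0.5  # non-inbred self-kinship


def test_parent_offspring_coancestry():
    ped = _ped_from_rows([(MALE, -1, -1), (FEMALE, -1, -1), (MALE, 0, 1)])
    assert kinship_pair(ped, 0, 2) == pytest.approx(0.25)


def test_half_sib_offspring_inbreeding():
    # shared sire 0; dams 1 and 2 unrelated; offspring of the two half sibs
    ped = Pedigree()
    z1 = np.zeros(1)
    ped.add_cohort(0, MALE, np.array([-1]), np.array([-1]), z1, z1, z1, z1, z1, 0.5)
    z2 = np.zeros(2)
    ped.add_cohort(0, FEMALE, np.full(2, -1), np.full(2, -1), z2, z2, z2, z2, z2, 0.5)
    ped.add_cohort(1, MALE, np.array([0]), np.array([1]), z1, z1, z1, z1, z1, 0.5)
    ped.add_cohort(1, FEMALE, np.array([0]), np.array([2]), z1, z1, z1, z1, z1, 0.5)
    ped.add_cohort(2, MALE, np.array([3]), np.array([4]), z1, z1, z1, z1, z1, 0.5)
    phi_parents = kinship_pair(ped, 3, 4)
    assert phi_parents == pytest.approx(0.125)
    assert inbreeding_from_parents(phi_parents) == pytest.approx(0.125)


def test_full_sib_and_parent_offspring_matings():
    ped = _ped_from_rows([(MALE, -1, -1), (FEMALE, -1, -1)])
    z = np.zeros(2)
    ped.add_cohort(1, MALE, np.array([0, 0]), np.array([1, 1]), z[:2], z[:2],
                   z[:2], z[:2], z[:2], 0.5)
    # full sibs 2,3 -> offspring F = 0.25
    assert kinship_pair(ped, 2, 3) == pytest.approx(0.25)
    # parent-offspring mating: sire 0 x daughter 2... use dam 1 x son 2
    z1 = np.zeros(1)
    ped.add_cohort(2, MALE, np.array([2]), np.array([1]), z1, z1, z1, z1, z1, 0.5)
    assert ped.record(4).sire_id == 2
    assert kinship_pair(ped, 2, 1) == pytest.approx(0.25)


@settings(derandomize=True, max_examples=15, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_cohort_propagation_matches_pair_recursion(seed):
    """Vectorised per-generation update == memoised recursion, entrywise."""
    rng = np.random.default_rng(seed)
    ped = make_random_pedigree(rng, n_founders=6, n_generations=4,
                               per_generation=10)
    kin = founder_kinship(ped.cohort(0))
    memo: dict = {}
    # carry one founder as a tracked cross-row through every update
    tracked = [int(rng.integers(0, len(ped.cohort(0))))]
    for g in range(1, ped.n_generations):
        ids = ped.cohort(g)
        kin = propagate_kinship(kin, ids, ped.sire[ids], ped.dam[ids],
                                tracked_ids=tracked)
        for a in range(len(kin.ids)):
            for b in range(a, len(kin.ids)):
                expected = kinship_pair(ped, int(kin.ids[a]), int(kin.ids[b]), memo)
                assert kin.phi[a, b] == pytest.approx(expected, abs=1e-12)
        assert np.allclose(kin.phi, kin.phi.T, atol=1e-12)
        assert kin.phi.min() >= 0.0 and kin.phi.max() <= 1.0


def test_numpy_fallback_block_matches_default():
    rng = np.random.default_rng(5)
    ped = make_random_pedigree(rng, n_founders=6, n_generations=3,
                               per_generation=12)
    kin = founder_kinship(ped.cohort(0))
    ids = ped.cohort(1)
    via_default = propagate_kinship(kin, ids, ped.sire[ids], ped.dam[ids])
    s = kin.positions(ped.sire[ids])
    d = kin.positions(ped.dam[ids])
    via_numpy = _offspring_block_numpy(kin.phi, s, d)
    assert np.allclose(via_default.phi, via_numpy, atol=1e-12)


def test_propagation_diagonal_is_inbreeding():
    ped = _ped_from_rows([(MALE, -1, -1), (FEMALE, -1, -1)])
    z = np.zeros(2)
    ped.add_cohort(1, MALE, np.array([0, 0]), np.array([1, 1]), z, z, z, z, z, 0.5)
    kin0 = founder_kinship(ped.cohort(0))
    kin1 = propagate_kinship(kin0, ped.cohort(1), ped.sire[ped.cohort(1)],
                             ped.dam[ped.cohort(1)])
    # non-inbred full sibs: diag 0.5, off-diag 0.25
    assert np.allclose(np.diagonal(kin1.phi), 0.5)
    assert kin1.phi[0, 1] == pytest.approx(0.25)
    assert np.allclose(kin1.inbreeding(), 0.0)


def test_propagation_missing_parent_errors():
    kin = founder_kinship(np.array([0, 1]))
    with pytest.raises(KeyError):
        propagate_kinship(kin, np.array([2]), np.array([0]), np.array([7]))


def test_average_kinship_matches_bruteforce():
    rng = np.random.default_rng(11)
    ped = make_random_pedigree(rng, n_founders=6, n_generations=3,
                               per_generation=10)
    kin = founder_kinship(ped.cohort(0))
    for g in range(1, ped.n_generations):
        ids = ped.cohort(g)
        kin = propagate_kinship(kin, ids, ped.sire[ids], ped.dam[ids])
    group = kin.cohort_ids
    memo: dict = {}
    pairs = [
        kinship_pair(ped, int(i), int(j), memo)
        for a, i in enumerate(group) for j in group[a + 1:]
    ]
    assert average_kinship(kin, group) == pytest.approx(np.mean(pairs), abs=1e-12)
    # full sibs example: 3 sibs of unrelated non-inbred parents -> 0.25
    sibs = _ped_from_rows([(MALE, -1, -1), (FEMALE, -1, -1)])
    z = np.zeros(3)
    sib_ids = sibs.add_cohort(1, MALE, np.full(3, 0), np.full(3, 1), z, z, z, z, z, 0.5)
    k = propagate_kinship(founder_kinship(sibs.cohort(0)), sib_ids,
                          sibs.sire[sib_ids], sibs.dam[sib_ids])
    assert average_kinship(k, sib_ids) == pytest.approx(0.25)
    with pytest.raises(ValueError):
        average_kinship(k, sib_ids[:1])


def test_mean_kinship_to_population():
    # candidate sires every population member, all else unrelated -> 0.25
    ped = _ped_from_rows([(MALE, -1, -1)])
    nf = 4
    z = np.zeros(nf)
    ped.add_cohort(0, FEMALE, np.full(nf, -1), np.full(nf, -1), z, z, z, z, z, 0.4)
    kids = ped.add_cohort(1, FEMALE, np.full(nf, 0), np.arange(1, nf + 1), z, z,
                          z, z, z, 0.4)
    kin = founder_kinship(ped.cohort(0))
    kin = propagate_kinship(kin, kids, ped.sire[kids], ped.dam[kids],
                            tracked_ids=[0])
    assert mean_kinship_to_population(kin, 0, kids) == pytest.approx(0.25)
    memo: dict = {}
    brute = np.mean([kinship_pair(ped, 0, int(i), memo) for i in kids])
    assert mean_kinship_to_population(kin, 0, kids) == pytest.approx(brute)


def test_pair_coancestry_lookup():
    kin = founder_kinship(np.array([0, 1, 2]))
    out = pair_coancestry(kin, np.array([0, 1]), np.array([0, 2]))
    assert out == pytest.approx([0.5, 0.0])


# ---------------------------------------------------------------------------
# gene contributions
# ---------------------------------------------------------------------------

def _toy_pedigree_with_links():
    rng = np.random.default_rng(7)
    ped = make_random_pedigree(rng, n_founders=6, n_generations=4,
                               per_generation=8)
    g1 = ped.cohort(1)
    # label all matings where the sire is male founder 0
    links = {(0, int(i)) for i in g1 if ped.sire[i] == 0}
    if not links:  # ensure at least one link
        links = {(int(ped.sire[g1[0]]), int(g1[0]))}
    return ped, links


def test_expected_contribution_direct_offspring():
    ped = _ped_from_rows([(MALE, -1, -1), (FEMALE, -1, -1), (MALE, 0, 1)])
    p = expected_contribution(ped, {(0, 2)})
    assert p[2] == pytest.approx(0.5)
    # grandchild through one linked parent
    z = np.zeros(1)
    ped.add_cohort(2, FEMALE, np.array([2]), np.array([1]), z, z, z, z, z, 0.4)
    p = expected_contribution(ped, {(0, 2)})
    assert p[3] == pytest.approx(0.25)
    assert p[0] == 0.0 and p[1] == 0.0


def test_gene_drop_degenerate_cases():
    ped = _ped_from_rows([(MALE, -1, -1), (FEMALE, -1, -1), (MALE, 0, 1)])
    rng = np.random.default_rng(0)
    both = gene_drop(ped, {(0, 2), (1, 2)}, 50, rng)
    assert np.all(both[2] == 1.0)  # both parental alleles labelled
    none = gene_drop(ped, {(0, 2)}, 50, rng)
    assert none[1] == 0.0  # no linked ancestor


def test_gene_drop_converges_to_exact_recursion():
    ped, links = _toy_pedigree_with_links()
    exact = expected_contribution(ped, links)
    runs = 100_000
    est = gene_drop(ped, links, runs, np.random.default_rng(123))
    # three Monte-Carlo standard errors per individual (binomial on 2*runs)
    se = np.sqrt(np.maximum(exact * (1 - exact), 1e-12) / (2 * runs))
    assert np.all(np.abs(est - exact) <= np.maximum(3 * se, 1e-9) + 1e-3)


def test_contribution_invalid_link():
    ped = _ped_from_rows([(MALE, -1, -1), (FEMALE, -1, -1), (MALE, 0, 1)])
    with pytest.raises(KeyError):
        expected_contribution(ped, {(1, 0)})


def test_pedigree_text_round_trip(tmp_path):
    rng = np.random.default_rng(3)
    ped = make_random_pedigree(rng, n_founders=6, n_generations=3,
                               per_generation=9)
    path = tmp_path / "ped.tsv"
    write_pedigree(ped, path)
    back = read_pedigree(path)
    assert np.array_equal(back.sire, ped.sire)
    assert np.array_equal(back.dam, ped.dam)
    assert np.array_equal(back.sex, ped.sex)
    assert np.array_equal(back.generation, ped.generation)


def test_record_view_and_roles():
    ped = _ped_from_rows([(MALE, -1, -1), (FEMALE, -1, -1), (MALE, 0, 1)])
    ped.add_role([2], "young_bull")
    rec = ped.record(2)
    assert rec.sire_id == 0 and rec.dam_id == 1
    assert rec.sex == "M"
    assert rec.roles == frozenset({"young_bull"})
    founder = ped.record(0)
    assert founder.sire_id is None and founder.F == 0.0
    with pytest.raises(KeyError):
        ped.record(99)
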