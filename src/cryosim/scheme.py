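"""The breeding-scheme engine.

A simplified dairy-cattle breed is simulated over 13 discrete generations
(0-12), each with 100 young bulls and 10,000 cows.  Four parent paths are
selected by truncation on an EBV criterion: 10 sires and 50 dams of the male
progeny, 20 sires of the female progeny, and all cows as dams of the female
progeny (no selection on the dam-to-dam path).  Mating is random within the
selected lists, so progeny sizes vary multinomially among parents.

Stage 1 (production of generations 1-8) selects on EBVA only and applies the
cryobank sampling rules (see :mod:`cryosim.cryobank`).  Stage 2 (production
of generations 9-12) follows a scenario: four stored bulls may sire a
fraction of the generation-9 bull calves, the selection criterion may switch
to a total merit index, and male lines may be conserved by equalising
progeny sizes on the sire-to-sire path.

Coancestry is propagated cohort by cohort (plus tracked rows for banked
bulls) so that inbreeding, average kinship and the minimum-kinship choice of
cryobank bulls are exact pedigree quantities, not estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import cryobank as cb
from .pedigree import (
    FEMALE,
    MALE,
    CohortKinship,
    Pedigree,
    average_kinship,
    expected_contribution,
    founder_kinship,
    pair_coancestry,
    propagate_kinship,
)
from .quantgen import (
    draw_founder_pairs,
    offspring_genetic_values_array,
    simulate_ebv_array,
    total_merit_index_array,
)

__all__ = [
    "SchemeConfig",
    "ParentLists",
    "GenerationState",
    "Stage1Result",
    "ScenarioRun",
    "select_parents",
    "mate_cohort",
    "equalize_male_lines",
    "select_from_lines",
    "run_stage1",
    "run_stage2",
]

CRITERION_EBVA = "EBVA"
CRITERION_TMI = "TMI"

BANK_FRENCH = "french_rules"
BANK_ALL = "all_young_bulls"


@dataclass(frozen=True)
class SchemeConfig:
    """Parameters of the base breeding scheme.

    Defaults are the reference scheme: 100 bulls / 10,000 cows per
    generation; 10 sires and 50 dams of the male progeny; 20 sires of the
    female progeny; genetic correlation -0.3 between the production trait A
    and the functional trait B; EBV accuracy 0.6 for bulls and 0.4 for cows;
    cryobank thresholds of 3 (EBVA, both tails) and 2 (EBVB, upper tail)
    within-cohort standard deviations; 13 generations with stage 2 starting
    at the production of generation 9.
    """

    n_males_per_gen: int = 100
    n_females_per_gen: int = 10000
    n_sires_of_males: int = 10
    n_dams_of_males: int = 50
    n_sires_of_females: int = 20
    rho: float = -0.3
    cd_male: float = 0.6
    cd_female: float = 0.4
    n_generations: int = 13
    stage2_start: int = 9
    cryo_thresh_a: float = 3.0
    cryo_thresh_b: float = 2.0
    n_cryobank_bulls_used: int = 4
    kinship_dtype: str = "float32"

    def __post_init__(self) -> None:
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError(f"rho must lie in [-1, 1], got {self.rho}")
        for name in ("cd_male", "cd_female"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if self.n_sires_of_males > self.n_males_per_gen:
            raise ValueError("more sires of males than bulls per generation")
        if self.n_sires_of_females > self.n_males_per_gen:
            raise ValueError("more sires of females than bulls per generation")
        if self.n_dams_of_males > self.n_females_per_gen:
            raise ValueError("more dams of males than cows per generation")
        if not 1 <= self.stage2_start < self.n_generations:
            raise ValueError("stage2_start must fall inside the simulated range")

    @property
    def stage1_last_generation(self) -> int:
        return self.stage2_start - 1

    def scaled(self, factor: float) -> "SchemeConfig":
        """Proportionally shrunk scheme for fast tests.

        Cohorts and selected lists scale with ``factor`` (minimum 2 per
        list).  Selection intensities change with scale, so a scaled scheme
        does not reproduce the full-size trajectories.
        """
        if factor <= 0:
            raise ValueError("scale factor must be positive")

        def sc(n: int) -> int:
            return max(2, int(round(n * factor)))

        return replace(
            self,
            n_males_per_gen=sc(self.n_males_per_gen),
            n_females_per_gen=sc(self.n_females_per_gen),
            n_sires_of_males=sc(self.n_sires_of_males),
            n_dams_of_males=min(sc(self.n_dams_of_males), sc(self.n_females_per_gen)),
            n_sires_of_females=min(sc(self.n_sires_of_females), sc(self.n_males_per_gen)),
        )


@dataclass
class ParentLists:
    """Selected ids for the four parent paths of one selection round."""

    sires_of_males: np.ndarray
    dams_of_males: np.ndarray
    sires_of_females: np.ndarray
    dams_of_females: np.ndarray


@dataclass
class GenerationState:
    """Current-generation cohort plus its (tracked) coancestry matrix."""

    generation: int
    male_ids: np.ndarray
    female_ids: np.ndarray
    kinship: CohortKinship
    male_sire_assignment: np.ndarray | None = None  # sire id of each young bull


@dataclass
class Stage1Result:
    ped: Pedigree
    state: GenerationState
    bank: cb.Cryobank
    summaries: list[dict]
    progeny_sd: list[dict]


@dataclass
class ScenarioRun:
    """One scenario branch grown from a stage-1 run to generation 12."""

    ped: Pedigree
    bank: cb.Cryobank
    summaries: list[dict]
    progeny_sd: list[dict]
    used_bull_ids: np.ndarray
    used_bull_birth_generations: np.ndarray
    used_bull_reasons: list[frozenset[str]]
    source_links: set[tuple[int, int]]
    contributions: dict[int, float]  # generation -> whole-population fraction


# ---------------------------------------------------------------------------
# selection and mating primitives
# ---------------------------------------------------------------------------

def _criterion_values(
    ped: Pedigree, ids: np.ndarray, criterion: str, w_b: float
) -> np.ndarray:
    if criterion == CRITERION_EBVA:
        return ped.ebva[ids]
    if criterion == CRITERION_TMI:
        return total_merit_index_array(ped.ebva[ids], ped.ebvb[ids], 1.0 - w_b)
    raise ValueError(f"unknown selection criterion {criterion!r}")


def _top_k(ids: np.ndarray, values: np.ndarray, k: int) -> np.ndarray:
    """Ids of the k largest values; ties broken by ascending id."""
    if k > len(ids):
        raise ValueError(f"cannot select {k} parents from {len(ids)} candidates")
    order = np.argsort(-values, kind="stable")  # ids ascending within cohort
    return ids[order[:k]]


def select_parents(
    ped: Pedigree,
    male_ids: np.ndarray,
    female_ids: np.ndarray,
    criterion: str,
    cfg: SchemeConfig,
    w_b: float = 0.5,
) -> ParentLists:
    """Truncation selection on the four parent paths.

    Sire lists are drawn independently from the same bull cohort, so the
    sires of males may (and, under a shared criterion, do) also appear among
    the sires of females.  All cows serve as dams of the female progeny.
    """
    male_crit = _criterion_values(ped, male_ids, criterion, w_b)
    female_crit = _criterion_values(ped, female_ids, criterion, w_b)
    return ParentLists(
        sires_of_males=_top_k(male_ids, male_crit, cfg.n_sires_of_males),
        dams_of_males=_top_k(female_ids, female_crit, cfg.n_dams_of_males),
        sires_of_females=_top_k(male_ids, male_crit, cfg.n_sires_of_females),
        dams_of_females=female_ids,
    )


def mate_cohort(
    sires: np.ndarray,
    dams: np.ndarray,
    n_offspring: int,
    sex: int,
    ped: Pedigree,
    parent_kinship: CohortKinship,
    cfg: SchemeConfig,
    generation: int,
    rng: np.random.Generator,
    sire_assignment: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Create one same-sex cohort by random mating.

    For each newborn the sire and dam are drawn independently and uniformly
    from their lists (unless an explicit ``sire_assignment`` imposes the
    sire, as under male-line conservation or cryobank siring).  Inbreeding is
    the parental coancestry from ``parent_kinship``; genetic values follow
    the infinitesimal model; EBVs are simulated at the sex's accuracy.

    Returns (offspring ids, sire id per offspring, dam id per offspring).
    """
    sires = np.asarray(sires, dtype=np.int64)
    dams = np.asarray(dams, dtype=np.int64)
    if len(sires) == 0 or len(dams) == 0:
        raise ValueError("empty parent list")
    if sire_assignment is None:
        sire_per_off = sires[rng.integers(0, len(sires), n_offspring)]
    else:
        sire_per_off = np.asarray(sire_assignment, dtype=np.int64)
        if len(sire_per_off) != n_offspring:
            raise ValueError("sire assignment length does not match cohort size")
    dam_per_off = dams[rng.integers(0, len(dams), n_offspring)]
    f_off = pair_coancestry(parent_kinship, sire_per_off, dam_per_off)
    a, b = offspring_genetic_values_array(
        ped.a[sire_per_off],
        ped.b[sire_per_off],
        ped.a[dam_per_off],
        ped.b[dam_per_off],
        ped.f[sire_per_off],
        ped.f[dam_per_off],
        cfg.rho,
        rng,
    )
    cd = cfg.cd_male if sex == MALE else cfg.cd_female
    ebva, ebvb = simulate_ebv_array(a, b, cd, rng)
    ids = ped.add_cohort(
        generation, sex, sire_per_off, dam_per_off, a, b, f_off, ebva, ebvb, cd
    )
    return ids, sire_per_off, dam_per_off


def equalize_male_lines(
    sires_of_males: np.ndarray, n_offspring: int
) -> np.ndarray:
    """Equal-progeny plan on the sire-to-sire path.

    Returns a sire assignment giving every sire of sires exactly
    ``n_offspring / len(sires)`` sons (male-line conservation); the
    across-sire progeny-count standard deviation is zero by construction.
    """
    sires_of_males = np.asarray(sires_of_males, dtype=np.int64)
    n_sires = len(sires_of_males)
    if n_offspring % n_sires != 0:
        raise ValueError(
            f"{n_offspring} sons cannot be split equally among {n_sires} sires"
        )
    return np.repeat(sires_of_males, n_offspring // n_sires)


def select_from_lines(
    ped: Pedigree,
    male_ids: np.ndarray,
    sire_assignment: np.ndarray,
    n_som: int,
    n_sof: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Within-line male selection under line conservation.

    Within each paternal sib group, the son with the best EBVA becomes a
    sire-of-sires candidate and the two best become sire-of-dams candidates
    (the best son serves on both paths).  With ten lines this yields exactly
    the 10 + 20 bulls of the scheme; if extra lines exist (cryobank lines at
    generation 9), candidates are truncated on EBVA to the required counts.
    """
    male_ids = np.asarray(male_ids, dtype=np.int64)
    som_cand: list[int] = []
    sof_cand: list[int] = []
    for sire in np.unique(sire_assignment):
        in_line = male_ids[sire_assignment == sire]
        order = np.argsort(-ped.ebva[in_line], kind="stable")
        som_cand.append(int(in_line[order[0]]))
        sof_cand.extend(int(i) for i in in_line[order[: min(2, len(in_line))]])
    som_cand_arr = np.array(sorted(som_cand), dtype=np.int64)
    sof_cand_arr = np.array(sorted(sof_cand), dtype=np.int64)
    som = _top_k(som_cand_arr, ped.ebva[som_cand_arr], min(n_som, len(som_cand_arr)))
    sof = _top_k(sof_cand_arr, ped.ebva[sof_cand_arr], min(n_sof, len(sof_cand_arr)))
    if len(som) < n_som or len(sof) < n_sof:
        raise ValueError("not enough paternal lines to fill the sire lists")
    return np.sort(som), np.sort(sof)


# ---------------------------------------------------------------------------
# per-generation bookkeeping
# ---------------------------------------------------------------------------

def _summaries_for_generation(
    ped: Pedigree,
    kin: CohortKinship,
    generation: int,
    male_ids: np.ndarray,
    female_ids: np.ndarray,
) -> list[dict]:
    all_ids = np.concatenate([male_ids, female_ids])
    rows = []
    for group, ids in (("young_bulls", male_ids), ("all", all_ids)):
        rows.append(
            {
                "generation": generation,
                "group": group,
                "mean_a": float(ped.a[ids].mean()),
                "mean_b": float(ped.b[ids].mean()),
                "mean_f": float(ped.f[ids].mean()),
                "mean_phi": average_kinship(kin, ids),
            }
        )
    return rows


def _progeny_sd_row(
    generation: int,
    sire_per_male: np.ndarray,
    sires_of_males: np.ndarray,
    sire_per_female: np.ndarray,
    sires_of_females: np.ndarray,
) -> dict:
    def sd(assign: np.ndarray, sires: np.ndarray) -> float:
        # across-sire dispersion of progeny counts (population s.d.; the
        # count mean is fixed by the cohort size)
        counts = np.array([(assign == s).sum() for s in sires], dtype=float)
        return float(counts.std(ddof=0))

    return {
        "generation": generation,
        "male_path_sd": sd(sire_per_male, sires_of_males),
        "female_path_sd": sd(sire_per_female, sires_of_females),
    }


# ---------------------------------------------------------------------------
# stage 1
# ---------------------------------------------------------------------------

def run_stage1(
    cfg: SchemeConfig,
    rng: np.random.Generator,
    bank_mode: str = BANK_FRENCH,
) -> Stage1Result:
    """Found the breed and run EBVA selection up to generation ``stage2_start - 1``.

    Cryobank sampling: rules i-ii on each young-bull cohort up to the
    second-to-last stage-1 generation, rule iii on sires of sires with a
    one-generation lag (or every young bull under the store-everything
    variant).  Banked bulls keep tracked coancestry rows against every later
    cohort.
    """
    if bank_mode not in (BANK_FRENCH, BANK_ALL):
        raise ValueError(f"unknown bank mode {bank_mode!r}")
    ped = Pedigree()
    bank = cb.Cryobank()
    last_gen = cfg.stage1_last_generation
    # Rules i-ii apply to cohorts whose sampling can still matter within
    # stage 1; with the one-generation lag of rule iii this is generations
    # 0 .. last_gen - 1 for rules i-ii and sires of sires born up to
    # last_gen - 2 for rule iii.
    rules_last_cohort = last_gen - 1

    nm, nf = cfg.n_males_per_gen, cfg.n_females_per_gen
    a0, b0 = draw_founder_pairs(nm + nf, cfg.rho, rng)
    ebva_m, ebvb_m = simulate_ebv_array(a0[:nm], b0[:nm], cfg.cd_male, rng)
    ebva_f, ebvb_f = simulate_ebv_array(a0[nm:], b0[nm:], cfg.cd_female, rng)
    none = np.full(nm, -1, dtype=np.int64)
    male_ids = ped.add_cohort(
        0, MALE, none, none, a0[:nm], b0[:nm], np.zeros(nm), ebva_m, ebvb_m,
        cfg.cd_male,
    )
    none_f = np.full(nf, -1, dtype=np.int64)
    female_ids = ped.add_cohort(
        0, FEMALE, none_f, none_f, a0[nm:], b0[nm:], np.zeros(nf), ebva_f,
        ebvb_f, cfg.cd_female,
    )
    dtype = np.dtype(cfg.kinship_dtype)
    kin = founder_kinship(np.concatenate([male_ids, female_ids]), dtype=dtype)
    ped.add_role(male_ids, "young_bull")

    summaries = _summaries_for_generation(ped, kin, 0, male_ids, female_ids)
    progeny_sd: list[dict] = []

    def bank_cohort(mids: np.ndarray, generation: int) -> None:
        if bank_mode == BANK_ALL:
            entries = cb.sample_all_young_bulls(
                mids, ped.ebva[mids], ped.ebvb[mids], generation
            )
        else:
            entries = cb.sample_rules_i_ii(
                mids,
                ped.ebva[mids],
                ped.ebvb[mids],
                generation,
                thresh_a=cfg.cryo_thresh_a,
                thresh_b=cfg.cryo_thresh_b,
            )
        for e in entries:
            bank.add(e)
            ped.add_role([e.bull_id], "cryobank_sampled")

    bank_cohort(male_ids, 0)

    prev_som: np.ndarray | None = None  # sires of males of the previous round
    for g in range(1, last_gen + 1):
        parents = select_parents(ped, male_ids, female_ids, CRITERION_EBVA, cfg)
        ped.add_role(parents.sires_of_males, "sire_of_sires")
        ped.add_role(parents.sires_of_females, "sire_of_dams")
        ped.add_role(parents.dams_of_males, "dam_of_bulls")

        if prev_som is not None and bank_mode == BANK_FRENCH:
            selected = np.unique(
                np.concatenate([parents.sires_of_males, parents.sires_of_females])
            )
            entries = cb.sample_rule_iii(
                prev_som,
                selected,
                ped.sire[selected],
                birth_generation=g - 2,
                ebva=ped.ebva[prev_som],
                ebvb=ped.ebvb[prev_som],
            )
            for e in entries:
                bank.add(e)
                ped.add_role([e.bull_id], "cryobank_sampled")

        new_males, m_sire, _ = mate_cohort(
            parents.sires_of_males, parents.dams_of_males, nm, MALE, ped, kin,
            cfg, g, rng,
        )
        new_females, f_sire, _ = mate_cohort(
            parents.sires_of_females, parents.dams_of_females, nf, FEMALE, ped,
            kin, cfg, g, rng,
        )
        ped.add_role(new_males, "young_bull")
        progeny_sd.append(
            _progeny_sd_row(g, m_sire, parents.sires_of_males, f_sire,
                            parents.sires_of_females)
        )

        tracked = set(int(i) for i in bank.bull_ids())
        if g <= last_gen - 1 and bank_mode == BANK_FRENCH:
            # future rule-iii candidates need rows against the next cohort
            tracked |= set(int(i) for i in parents.sires_of_males)
        offspring = np.concatenate([new_males, new_females])
        kin = propagate_kinship(
            kin,
            offspring,
            np.concatenate([m_sire, f_sire]),
            np.concatenate([ped.dam[new_males], ped.dam[new_females]]),
            tracked_ids=sorted(tracked),
        )
        male_ids, female_ids = new_males, new_females
        if g <= rules_last_cohort:
            bank_cohort(male_ids, g)
        summaries.extend(_summaries_for_generation(ped, kin, g, male_ids, female_ids))
        prev_som = parents.sires_of_males

    state = GenerationState(
        generation=last_gen,
        male_ids=male_ids,
        female_ids=female_ids,
        kinship=kin,
        male_sire_assignment=None,
    )
    return Stage1Result(ped=ped, state=state, bank=bank, summaries=summaries,
                        progeny_sd=progeny_sd)


# ---------------------------------------------------------------------------
# stage 2
# ---------------------------------------------------------------------------

def run_stage2(
    stage1: Stage1Result,
    scenario,
    cfg: SchemeConfig,
    rng: np.random.Generator,
) -> ScenarioRun:
    """Extend a stage-1 run to generation ``n_generations - 1`` under a scenario.

    ``scenario`` is an :class:`cryosim.experiment.ScenarioConfig`.  The
    stage-1 structures are not mutated, so several scenarios can branch from
    the same stage-1 run with independent random streams.
    """
    ped = stage1.ped.copy()
    bank = stage1.bank
    kin = stage1.state.kinship
    male_ids = stage1.state.male_ids
    female_ids = stage1.state.female_ids
    summaries = [dict(r) for r in stage1.summaries]
    progeny_sd = [dict(r) for r in stage1.progeny_sd]

    nm, nf = cfg.n_males_per_gen, cfg.n_females_per_gen
    n_cryo_sons = int(round(scenario.fraction_cryobank_sons * nm))
    source_links: set[tuple[int, int]] = set()
    used_ids = np.empty(0, dtype=np.int64)
    used_birth = np.empty(0, dtype=np.int64)
    used_reasons: list[frozenset[str]] = []
    line_assignment: np.ndarray | None = None  # sire of each current young bull

    for g in range(cfg.stage2_start, cfg.n_generations):
        criterion = scenario.stage2_criterion
        if scenario.male_line_conservation and line_assignment is not None:
            som, sof = select_from_lines(
                ped, male_ids, line_assignment, cfg.n_sires_of_males,
                cfg.n_sires_of_females,
            )
            female_crit = _criterion_values(ped, female_ids, criterion, scenario.w_b)
            dom = _top_k(female_ids, female_crit, cfg.n_dams_of_males)
            parents = ParentLists(som, dom, sof, female_ids)
        else:
            parents = select_parents(
                ped, male_ids, female_ids, criterion, cfg, w_b=scenario.w_b
            )
        ped.add_role(parents.sires_of_males, "sire_of_sires")
        ped.add_role(parents.sires_of_females, "sire_of_dams")
        ped.add_role(parents.dams_of_males, "dam_of_bulls")

        # --- sire assignment for the bull-calf cohort
        sire_assignment = None
        cryo_ids: np.ndarray | None = None
        if g == cfg.stage2_start and n_cryo_sons > 0:
            cryo_ids = cb.choose_cryobank_bulls(
                bank,
                scenario.cryobank_choice,
                cfg.n_cryobank_bulls_used,
                population_kinship=kin,
                population=np.concatenate([male_ids, female_ids]),
                w_b=scenario.w_b,
            )
            if scenario.male_line_conservation:
                # the cryobank bulls head their share of the conserved lines,
                # displacing the lowest-ranked regular sires of sires; every
                # line keeps the same number of sons
                n_lines = cfg.n_sires_of_males
                n_cryo_lines = int(round(scenario.fraction_cryobank_sons * n_lines))
                heads = np.concatenate(
                    [
                        np.resize(cryo_ids, n_cryo_lines),
                        parents.sires_of_males[: n_lines - n_cryo_lines],
                    ]
                )
                sire_assignment = equalize_male_lines(heads, nm)
            else:
                n_regular = nm - n_cryo_sons
                cryo_part = cryo_ids[rng.integers(0, len(cryo_ids), n_cryo_sons)]
                reg_part = parents.sires_of_males[
                    rng.integers(0, len(parents.sires_of_males), n_regular)
                ]
                sire_assignment = np.concatenate([cryo_part, reg_part])
            used_ids = np.unique(sire_assignment[np.isin(sire_assignment, cryo_ids)])
            ped.add_role(used_ids, "cryobank_used")
            used_birth = ped.generation[used_ids].astype(np.int64)
            used_reasons = [
                frozenset(bank.entries[int(i)].reasons) for i in used_ids
            ]
        elif scenario.male_line_conservation:
            sire_assignment = equalize_male_lines(parents.sires_of_males, nm)

        new_males, m_sire, _ = mate_cohort(
            parents.sires_of_males if sire_assignment is None else np.unique(sire_assignment),
            parents.dams_of_males, nm, MALE, ped, kin, cfg, g, rng,
            sire_assignment=sire_assignment,
        )
        new_females, f_sire, _ = mate_cohort(
            parents.sires_of_females, parents.dams_of_females, nf, FEMALE, ped,
            kin, cfg, g, rng,
        )
        ped.add_role(new_males, "young_bull")
        if cryo_ids is not None:
            in_cryo = np.isin(m_sire, cryo_ids)
            source_links |= {
                (int(s), int(o)) for s, o in zip(m_sire[in_cryo], new_males[in_cryo])
            }
        progeny_sd.append(
            _progeny_sd_row(g, m_sire, parents.sires_of_males, f_sire,
                            parents.sires_of_females)
        )
        kin = propagate_kinship(
            kin,
            np.concatenate([new_males, new_females]),
            np.concatenate([m_sire, f_sire]),
            np.concatenate([ped.dam[new_males], ped.dam[new_females]]),
        )
        male_ids, female_ids = new_males, new_females
        line_assignment = m_sire if scenario.male_line_conservation else None
        summaries.extend(_summaries_for_generation(ped, kin, g, male_ids, female_ids))

    contributions: dict[int, float] = {}
    if source_links:
        p = expected_contribution(ped, source_links)
    else:
        p = np.zeros(len(ped))
    for g in (cfg.stage2_start + 1, cfg.n_generations - 1):
        contributions[g] = float(p[ped.cohort(g)].mean())

    return ScenarioRun(
        ped=ped,
        bank=bank,
        summaries=summaries,
        progeny_sd=progeny_sd,
        used_bull_ids=used_ids,
        used_bull_birth_generations=used_birth,
        used_bull_reasons=used_reasons,
        source_links=source_links,
        contributions=contributions,
    )
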