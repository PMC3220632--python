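"""Cryobank sampling rules and the choice of stored bulls for reuse.

During stage 1 of the breeding scheme, semen of selected young bulls enters
the bank according to the French National Cryobank rules for "original"
bulls of non-endangered breeds:

  (i)  EBVA more than three within-cohort standard deviations above *or*
       below the cohort mean (reasons ``high_EBVA`` / ``low_EBVA``);
  (ii) EBVB more than two standard deviations above the cohort mean
       (reason ``high_EBVB``; trait B is functional, only the upper tail
       is of interest);
  (iii) a sire of sires none of whose sons was selected as a sire in the
       next round (reason ``unused_sire_of_sires``; applied with a
       one-generation lag).

A simpler variant stores every young bull (``sample_all_young_bulls``,
reason ``all``), mimicking store-everything national collections.

At generation 9 four stored bulls are picked, either by highest total merit
index among banked bulls or by lowest average kinship with the current
population (males and females together).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pedigree import CohortKinship, mean_kinship_to_population
from .quantgen import total_merit_index_array

__all__ = [
    "CryobankEntry",
    "Cryobank",
    "sample_rules_i_ii",
    "sample_rule_iii",
    "sample_all_young_bulls",
    "choose_cryobank_bulls",
]

REASON_HIGH_EBVA = "high_EBVA"
REASON_LOW_EBVA = "low_EBVA"
REASON_HIGH_EBVB = "high_EBVB"
REASON_UNUSED_SIRE = "unused_sire_of_sires"
REASON_ALL = "all"

RULE_REASONS = (REASON_HIGH_EBVA, REASON_LOW_EBVA, REASON_HIGH_EBVB,
                REASON_UNUSED_SIRE)


@dataclass
class CryobankEntry:
    """One stored bull (reasons merged if several rules fired)."""

    bull_id: int
    birth_generation: int
    reasons: set[str]
    sampling_generation: int
    ebva: float
    ebvb: float


@dataclass
class Cryobank:
    """Collection of stored bulls, at most one entry per bull."""

    entries: dict[int, CryobankEntry] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def bull_ids(self) -> np.ndarray:
        return np.array(sorted(self.entries), dtype=np.int64)

    def add(self, entry: CryobankEntry) -> None:
        """Add an entry, merging reasons with any existing entry."""
        if not entry.reasons:
            raise ValueError("a cryobank entry needs at least one reason")
        existing = self.entries.get(entry.bull_id)
        if existing is None:
            self.entries[entry.bull_id] = entry
        else:
            existing.reasons |= entry.reasons

    def reason_counts(self) -> dict[str, int]:
        """Per-rule bull counts; a bull satisfying several rules is credited
        to each of them, so counts may sum to more than ``len(self)``."""
        counts = {r: 0 for r in RULE_REASONS}
        counts[REASON_ALL] = 0
        for e in self.entries.values():
            for r in e.reasons:
                counts[r] += 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "bull_id": e.bull_id,
                "birth_generation": e.birth_generation,
                "reasons": "|".join(sorted(e.reasons)),
                "sampling_generation": e.sampling_generation,
                "EBVA": e.ebva,
                "EBVB": e.ebvb,
            }
            for e in sorted(self.entries.values(), key=lambda e: e.bull_id)
        ]
        return pd.DataFrame(
            rows,
            columns=["bull_id", "birth_generation", "reasons",
                     "sampling_generation", "EBVA", "EBVB"],
        )


def sample_rules_i_ii(
    male_ids: np.ndarray,
    ebva: np.ndarray,
    ebvb: np.ndarray,
    generation: int,
    thresh_a: float = 3.0,
    thresh_b: float = 2.0,
) -> list[CryobankEntry]:
    """Apply rules (i) and (ii) to one cohort of young bulls.

    Thresholds use the empirical mean and standard deviation of the cohort's
    own EBVs; inequalities are strict, so a zero-variance cohort samples
    nobody.
    """
    if len(male_ids) < 2:
        raise ValueError("rules i-ii need a cohort of at least two bulls")
    ebva = np.asarray(ebva, float)
    ebvb = np.asarray(ebvb, float)
    mean_a, sd_a = ebva.mean(), ebva.std(ddof=1)
    mean_b, sd_b = ebvb.mean(), ebvb.std(ddof=1)
    entries: list[CryobankEntry] = []
    for k, bull in enumerate(np.asarray(male_ids, np.int64)):
        reasons = set()
        if ebva[k] > mean_a + thresh_a * sd_a:
            reasons.add(REASON_HIGH_EBVA)
        if ebva[k] < mean_a - thresh_a * sd_a:
            reasons.add(REASON_LOW_EBVA)
        if ebvb[k] > mean_b + thresh_b * sd_b:
            reasons.add(REASON_HIGH_EBVB)
        if reasons:
            entries.append(
                CryobankEntry(
                    bull_id=int(bull),
                    birth_generation=generation,
                    reasons=reasons,
                    sampling_generation=generation,
                    ebva=float(ebva[k]),
                    ebvb=float(ebvb[k]),
                )
            )
    return entries


def sample_rule_iii(
    sires_of_males: np.ndarray,
    selected_next_sires: np.ndarray,
    sire_of_selected: np.ndarray,
    birth_generation: int,
    ebva: np.ndarray,
    ebvb: np.ndarray,
) -> list[CryobankEntry]:
    """Apply rule (iii): sires of sires with no selected son.

    Parameters
    ----------
    sires_of_males : ids of the sires of sires used ``birth_generation``'s
        selection round (the bulls themselves born in ``birth_generation``).
    selected_next_sires : ids of all bulls selected as sires (of males or of
        females) in the following round.
    sire_of_selected : sire id of each animal in ``selected_next_sires``.
    ebva, ebvb : EBVs of ``sires_of_males`` (aligned).
    """
    represented = set(np.asarray(sire_of_selected, np.int64)[
        np.isin(np.asarray(sire_of_selected, np.int64),
                np.asarray(sires_of_males, np.int64))
    ].tolist())
    entries = []
    for k, bull in enumerate(np.asarray(sires_of_males, np.int64)):
        if int(bull) not in represented:
            entries.append(
                CryobankEntry(
                    bull_id=int(bull),
                    birth_generation=birth_generation,
                    reasons={REASON_UNUSED_SIRE},
                    sampling_generation=birth_generation + 1,
                    ebva=float(ebva[k]),
                    ebvb=float(ebvb[k]),
                )
            )
    return entries


def sample_all_young_bulls(
    male_ids: np.ndarray,
    ebva: np.ndarray,
    ebvb: np.ndarray,
    generation: int,
) -> list[CryobankEntry]:
    """Store-everything variant: every young bull of the cohort enters."""
    return [
        CryobankEntry(
            bull_id=int(bull),
            birth_generation=generation,
            reasons={REASON_ALL},
            sampling_generation=generation,
            ebva=float(ebva[k]),
            ebvb=float(ebvb[k]),
        )
        for k, bull in enumerate(np.asarray(male_ids, np.int64))
    ]


def choose_cryobank_bulls(
    bank: Cryobank,
    method: str,
    k: int,
    population_kinship: CohortKinship | None = None,
    population: np.ndarray | None = None,
    w_b: float = 0.5,
) -> np.ndarray:
    """Pick the ``k`` bulls to reuse.

    ``method`` is ``"best_TMI"`` (highest w_A*EBVA + w_B*EBVB among banked
    bulls, using their original EBVs) or ``"min_mean_kinship"`` (lowest mean
    coancestry with the given population, males and females together).  Ties
    break by ascending bull id.
    """
    if len(bank) < k:
        raise ValueError(f"cryobank holds {len(bank)} bulls, need {k}")
    ids = bank.bull_ids()
    if method == "best_TMI":
        ebva = np.array([bank.entries[int(i)].ebva for i in ids])
        ebvb = np.array([bank.entries[int(i)].ebvb for i in ids])
        score = -total_merit_index_array(ebva, ebvb, 1.0 - w_b)
    elif method == "min_mean_kinship":
        if population_kinship is None or population is None:
            raise ValueError("min_mean_kinship needs a population kinship")
        score = np.array(
            [
                mean_kinship_to_population(population_kinship, int(i), population)
                for i in ids
            ]
        )
    else:
        raise ValueError(f"unknown cryobank choice method {method!r}")
    # ids are ascending, stable sort keeps that order on ties
    order = np.argsort(score, kind="stable")
    return ids[order[:k]]
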