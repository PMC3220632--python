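"""Pedigree storage, inbreeding/coancestry recursions, and gene contributions.

The pedigree is stored in columnar form (one numpy array per field, one row
per animal) with dense 0-based ids equal to row position; parents always
precede offspring, so the row order is a topological order.  Scalar access is
available through :class:`IndividualRecord` views.

Two coancestry paths are provided:

* :func:`kinship_pair` - the classic memoised recursion on a pair of ids.
  It is the small-instance oracle.
* :func:`propagate_kinship` - a vectorised one-generation update of a full
  cohort coancestry matrix, used by the breeding-scheme engine where whole
  10,100-animal generations must be averaged.  Extra rows ("tracked" animals,
  e.g. cryobank bulls) are carried along so that stored bulls keep a kinship
  row against every later cohort.

Genetic contributions of a designated set of matings (e.g. the cryobank
matings at generation 9) are computed either exactly
(:func:`expected_contribution`) or by Monte-Carlo gene dropping
(:func:`gene_drop`); the former is the infinite-run limit of the latter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .quantgen import EbvRecord, TraitPair
from . import _kernels

__all__ = [
    "MALE",
    "FEMALE",
    "IndividualRecord",
    "Pedigree",
    "CohortKinship",
    "kinship_pair",
    "inbreeding_from_parents",
    "founder_kinship",
    "propagate_kinship",
    "pair_coancestry",
    "average_kinship",
    "mean_kinship_to_population",
    "expected_contribution",
    "gene_drop",
    "write_pedigree",
    "read_pedigree",
]

MALE = 0
FEMALE = 1

_SEX_CHAR = {MALE: "M", FEMALE: "F"}
_CHAR_SEX = {"M": MALE, "F": FEMALE}


@dataclass(frozen=True)
class IndividualRecord:
    """Read-only view of one animal."""

    id: int
    generation: int
    sex: str  # "M" or "F"
    sire_id: int | None
    dam_id: int | None
    traits: TraitPair
    F: float
    ebv: EbvRecord
    roles: frozenset[str]


class Pedigree:
    """Topologically ordered columnar pedigree.

    Ids are dense integers equal to row position; founders have sire/dam -1.
    Cohorts are appended generation by generation via :meth:`add_cohort`.
    """

    def __init__(self) -> None:
        self.sire = np.empty(0, dtype=np.int64)
        self.dam = np.empty(0, dtype=np.int64)
        self.sex = np.empty(0, dtype=np.int8)
        self.generation = np.empty(0, dtype=np.int16)
        self.a = np.empty(0, dtype=np.float64)
        self.b = np.empty(0, dtype=np.float64)
        self.f = np.empty(0, dtype=np.float64)
        self.ebva = np.empty(0, dtype=np.float64)
        self.ebvb = np.empty(0, dtype=np.float64)
        self.cd = np.empty(0, dtype=np.float64)
        self.roles: dict[int, set[str]] = {}

    def __len__(self) -> int:
        return len(self.sire)

    def add_cohort(
        self,
        generation: int,
        sex: int,
        sire: np.ndarray,
        dam: np.ndarray,
        a: np.ndarray,
        b: np.ndarray,
        f: np.ndarray,
        ebva: np.ndarray,
        ebvb: np.ndarray,
        cd: float,
    ) -> np.ndarray:
        """Append one same-sex cohort; returns the new ids."""
        n = len(a)
        sire = np.asarray(sire, dtype=np.int64)
        dam = np.asarray(dam, dtype=np.int64)
        if n and (sire.max(initial=-1) >= len(self) or dam.max(initial=-1) >= len(self)):
            raise ValueError("parents must reference existing animals")
        ids = np.arange(len(self), len(self) + n, dtype=np.int64)
        self.sire = np.concatenate([self.sire, sire])
        self.dam = np.concatenate([self.dam, dam])
        self.sex = np.concatenate([self.sex, np.full(n, sex, dtype=np.int8)])
        self.generation = np.concatenate(
            [self.generation, np.full(n, generation, dtype=np.int16)]
        )
        self.a = np.concatenate([self.a, np.asarray(a, dtype=np.float64)])
        self.b = np.concatenate([self.b, np.asarray(b, dtype=np.float64)])
        self.f = np.concatenate([self.f, np.asarray(f, dtype=np.float64)])
        self.ebva = np.concatenate([self.ebva, np.asarray(ebva, dtype=np.float64)])
        self.ebvb = np.concatenate([self.ebvb, np.asarray(ebvb, dtype=np.float64)])
        self.cd = np.concatenate([self.cd, np.full(n, cd, dtype=np.float64)])
        return ids

    def add_role(self, ids: np.ndarray | list[int], role: str) -> None:
        for i in np.atleast_1d(np.asarray(ids, dtype=np.int64)):
            self.roles.setdefault(int(i), set()).add(role)

    def cohort(self, generation: int) -> np.ndarray:
        return np.flatnonzero(self.generation == generation).astype(np.int64)

    def males(self, generation: int) -> np.ndarray:
        return np.flatnonzero(
            (self.generation == generation) & (self.sex == MALE)
        ).astype(np.int64)

    def females(self, generation: int) -> np.ndarray:
        return np.flatnonzero(
            (self.generation == generation) & (self.sex == FEMALE)
        ).astype(np.int64)

    @property
    def n_generations(self) -> int:
        return int(self.generation.max()) + 1 if len(self) else 0

    def record(self, i: int) -> IndividualRecord:
        if not 0 <= i < len(self):
            raise KeyError(f"unknown id {i}")
        sire = int(self.sire[i])
        dam = int(self.dam[i])
        return IndividualRecord(
            id=int(i),
            generation=int(self.generation[i]),
            sex=_SEX_CHAR[int(self.sex[i])],
            sire_id=sire if sire >= 0 else None,
            dam_id=dam if dam >= 0 else None,
            traits=TraitPair(A=float(self.a[i]), B=float(self.b[i])),
            F=float(self.f[i]),
            ebv=EbvRecord(
                EBVA=float(self.ebva[i]), EBVB=float(self.ebvb[i]), CD=float(self.cd[i])
            ),
            roles=frozenset(self.roles.get(int(i), set())),
        )

    def copy(self) -> "Pedigree":
        new = Pedigree()
        for name in ("sire", "dam", "sex", "generation", "a", "b", "f",
                     "ebva", "ebvb", "cd"):
            setattr(new, name, getattr(self, name).copy())
        new.roles = {k: set(v) for k, v in self.roles.items()}
        return new


# ---------------------------------------------------------------------------
# pairwise coancestry recursion (oracle path)
# ---------------------------------------------------------------------------

def kinship_pair(ped: Pedigree, i: int, j: int, memo: dict | None = None) -> float:
    """Coancestry Phi(i, j) by the memoised tabular recursion.

    Phi(i, i) = (1 + F_i)/2; for distinct animals the younger one (larger id,
    by topological order) is decomposed into its parents:
    Phi(i, j) = [Phi(sire_j, i) + Phi(dam_j, i)] / 2, with distinct founders
    unrelated.  A shared ``memo`` dict may be passed to amortise repeated
    queries on the same pedigree.
    """
    n = len(ped)
    if not (0 <= i < n and 0 <= j < n):
        raise KeyError(f"unknown id in pair ({i}, {j})")
    if memo is None:
        memo = {}

    def phi(x: int, y: int) -> float:
        if x > y:
            x, y = y, x
        key = (x, y)
        if key in memo:
            return memo[key]
        sy, dy = int(ped.sire[y]), int(ped.dam[y])
        if x == y:
            val = 0.5 * (1.0 + (phi(sy, dy) if sy >= 0 else 0.0))
        elif sy < 0:  # y is a founder and distinct from x
            val = 0.0
        else:
            val = 0.5 * (phi(sy, x) + phi(dy, x))
        memo[key] = val
        return val

    return phi(int(i), int(j))


def inbreeding_from_parents(phi_parents: float) -> float:
    """F of an offspring equals the coancestry of its parents."""
    if not 0.0 <= phi_parents <= 1.0:
        raise ValueError(f"coancestry must lie in [0, 1], got {phi_parents}")
    return float(phi_parents)


# ---------------------------------------------------------------------------
# cohort-matrix path
# ---------------------------------------------------------------------------

@dataclass
class CohortKinship:
    """Symmetric coancestry matrix over one generation plus tracked rows.

    ``ids[:n_cohort]`` are the cohort animals; the remainder are tracked
    extras (cryobank bulls) whose rows are propagated along with each new
    generation.  Diagonal entries are (1 + F)/2.
    """

    ids: np.ndarray
    phi: np.ndarray
    n_cohort: int
    _pos: dict[int, int] = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=np.int64)
        if self.phi.shape != (len(self.ids), len(self.ids)):
            raise ValueError("phi shape does not match ids")
        self._pos = {int(v): k for k, v in enumerate(self.ids)}

    @property
    def cohort_ids(self) -> np.ndarray:
        return self.ids[: self.n_cohort]

    @property
    def tracked_ids(self) -> np.ndarray:
        return self.ids[self.n_cohort:]

    def positions(self, query: np.ndarray | list[int]) -> np.ndarray:
        query = np.atleast_1d(np.asarray(query, dtype=np.int64))
        try:
            return np.fromiter(
                (self._pos[int(q)] for q in query), dtype=np.int64, count=len(query)
            )
        except KeyError as exc:  # pragma: no cover - message only
            raise KeyError(f"id {exc.args[0]} not covered by this kinship") from None

    def inbreeding(self) -> np.ndarray:
        """F of the cohort animals, from the diagonal."""
        return 2.0 * np.diagonal(self.phi)[: self.n_cohort].astype(np.float64) - 1.0


def founder_kinship(
    founder_ids: np.ndarray, dtype=np.float64
) -> CohortKinship:
    """Base-population matrix: unrelated, non-inbred founders (diag 1/2)."""
    n = len(founder_ids)
    phi = np.zeros((n, n), dtype=dtype)
    np.fill_diagonal(phi, 0.5)
    return CohortKinship(ids=np.asarray(founder_ids), phi=phi, n_cohort=n)


def _offspring_block_numpy(
    P: np.ndarray, s: np.ndarray, d: np.ndarray
) -> np.ndarray:
    block = 0.25 * (
        P[np.ix_(s, s)] + P[np.ix_(s, d)] + P[np.ix_(d, s)] + P[np.ix_(d, d)]
    )
    np.fill_diagonal(block, 0.5 * (1.0 + P[s, d]))
    return block.astype(P.dtype, copy=False)


def propagate_kinship(
    parent_kinship: CohortKinship,
    offspring_ids: np.ndarray,
    sire_ids: np.ndarray,
    dam_ids: np.ndarray,
    tracked_ids: np.ndarray | list[int] = (),
) -> CohortKinship:
    """One-generation coancestry update.

    Every sire/dam must have a row in ``parent_kinship`` (cohort or tracked).
    Off-diagonal offspring entries are the mean of the four parental
    coancestries; the diagonal is (1 + Phi(sire, dam))/2; tracked rows
    propagate as Phi(t, o) = [Phi(t, sire_o) + Phi(t, dam_o)]/2.
    """
    P = parent_kinship.phi
    s = parent_kinship.positions(sire_ids)
    d = parent_kinship.positions(dam_ids)
    if _kernels.propagate_offspring_block is not None:
        block = _kernels.propagate_offspring_block(P, s, d)
    else:
        block = _offspring_block_numpy(P, s, d)

    tracked_ids = np.asarray(tracked_ids, dtype=np.int64)
    n_off = len(offspring_ids)
    if len(tracked_ids):
        t = parent_kinship.positions(tracked_ids)
        cross = 0.5 * (P[np.ix_(t, s)] + P[np.ix_(t, d)])
        tt = P[np.ix_(t, t)]
        n = n_off + len(t)
        phi = np.empty((n, n), dtype=P.dtype)
        phi[:n_off, :n_off] = block
        phi[n_off:, :n_off] = cross
        phi[:n_off, n_off:] = cross.T
        phi[n_off:, n_off:] = tt
        ids = np.concatenate([np.asarray(offspring_ids, np.int64), tracked_ids])
    else:
        phi = block
        ids = np.asarray(offspring_ids, dtype=np.int64)
    return CohortKinship(ids=ids, phi=phi, n_cohort=n_off)


def pair_coancestry(
    k: CohortKinship, ids_i: np.ndarray, ids_j: np.ndarray
) -> np.ndarray:
    """Elementwise Phi between two equal-length id vectors (float64)."""
    i = k.positions(ids_i)
    j = k.positions(ids_j)
    return k.phi[i, j].astype(np.float64)


def average_kinship(k: CohortKinship, group: np.ndarray | list[int]) -> float:
    """Mean coancestry over all unordered distinct pairs of ``group``."""
    pos = k.positions(group)
    m = len(pos)
    if m < 2:
        raise ValueError("average_kinship needs at least two animals")
    # contiguous groups (e.g. a whole cohort) avoid the fancy-index copy
    if pos[0] + m - 1 == pos[-1] and np.all(np.diff(pos) == 1):
        sub = k.phi[pos[0]: pos[0] + m, pos[0]: pos[0] + m]
    else:
        sub = k.phi[np.ix_(pos, pos)]
    total = float(np.sum(sub, dtype=np.float64))
    diag = float(np.sum(np.diagonal(sub), dtype=np.float64))
    return (total - diag) / (m * (m - 1))


def mean_kinship_to_population(
    k: CohortKinship, candidate: int, population: np.ndarray | list[int]
) -> float:
    """Mean Phi(candidate, p) over the population (candidate excluded)."""
    c = int(k.positions([candidate])[0])
    pos = k.positions(population)
    pos = pos[pos != c]
    if len(pos) == 0:
        raise ValueError("population contains no animal other than the candidate")
    return float(np.mean(k.phi[c, pos], dtype=np.float64))


# ---------------------------------------------------------------------------
# gene contributions
# ---------------------------------------------------------------------------

def _link_masks(
    ped: Pedigree, source_links: set[tuple[int, int]]
) -> tuple[np.ndarray, np.ndarray]:
    linked_sire = np.zeros(len(ped), dtype=bool)
    linked_dam = np.zeros(len(ped), dtype=bool)
    for parent, off in source_links:
        hit = False
        if 0 <= off < len(ped):
            if ped.sire[off] == parent:
                linked_sire[off] = True
                hit = True
            if ped.dam[off] == parent:
                linked_dam[off] = True
                hit = True
        if not hit:
            raise KeyError(f"link ({parent}, {off}) is not a mating in the pedigree")
    return linked_sire, linked_dam


def expected_contribution(
    ped: Pedigree, source_links: set[tuple[int, int]]
) -> np.ndarray:
    """Exact expected fraction of genes flowing through the source links.

    p(i) = [sigma_sire + sigma_dam]/2 where sigma_parent is 1 if the
    (parent, i) mating is a source link and p(parent) otherwise; founders
    carry 0.  This is the infinite-run limit of :func:`gene_drop`.
    """
    linked_sire, linked_dam = _link_masks(ped, source_links)
    p = np.zeros(len(ped), dtype=np.float64)
    for g in range(ped.n_generations):
        idx = ped.cohort(g)
        rows = idx[ped.sire[idx] >= 0]
        if len(rows) == 0:
            continue  # founder cohort keeps 0
        sig_s = np.where(linked_sire[rows], 1.0, p[ped.sire[rows]])
        sig_d = np.where(linked_dam[rows], 1.0, p[ped.dam[rows]])
        p[rows] = 0.5 * (sig_s + sig_d)
    return p


def gene_drop(
    ped: Pedigree,
    source_links: set[tuple[int, int]],
    runs: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Monte-Carlo gene dropping of one biallelic locus per run.

    Each offspring inherits one uniformly chosen allele from each parent;
    alleles transmitted across a source link are labelled.  Returns the
    per-individual labelled-allele fraction averaged over runs - an unbiased
    estimator of :func:`expected_contribution`.
    """
    if runs < 1:
        raise ValueError("runs must be >= 1")
    linked_sire, linked_dam = _link_masks(ped, source_links)
    n = len(ped)
    run_idx = np.arange(runs)
    # labels[i, r, a]: whether allele a of animal i in run r descends from a link
    labels = np.zeros((n, runs, 2), dtype=bool)
    for i in range(n):
        s, d = int(ped.sire[i]), int(ped.dam[i])
        if s < 0:
            continue
        if linked_sire[i]:
            labels[i, :, 0] = True
        else:
            labels[i, :, 0] = labels[s, run_idx, rng.integers(0, 2, runs)]
        if linked_dam[i]:
            labels[i, :, 1] = True
        else:
            labels[i, :, 1] = labels[d, run_idx, rng.integers(0, 2, runs)]
    return labels.mean(axis=(1, 2))


# ---------------------------------------------------------------------------
# text interchange
# ---------------------------------------------------------------------------

def write_pedigree(ped: Pedigree, path) -> None:
    """Write id/sire/dam/sex/generation as tab-delimited text (1-based ids,
    0 for unknown parent).  Trait and EBV columns are not part of the
    interchange format."""
    df = pd.DataFrame(
        {
            "id": np.arange(1, len(ped) + 1),
            "sire": ped.sire + 1,
            "dam": ped.dam + 1,
            "sex": [_SEX_CHAR[int(s)] for s in ped.sex],
            "generation": ped.generation,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_pedigree(path) -> Pedigree:
    """Inverse of :func:`write_pedigree`; trait fields are filled with NaN."""
    df = pd.read_csv(path, sep="\t")
    ped = Pedigree()
    n = len(df)
    ped.sire = df["sire"].to_numpy(np.int64) - 1
    ped.dam = df["dam"].to_numpy(np.int64) - 1
    ped.sex = np.array([_CHAR_SEX[s] for s in df["sex"]], dtype=np.int8)
    ped.generation = df["generation"].to_numpy(np.int16)
    for name in ("a", "b", "f", "ebva", "ebvb", "cd"):
        setattr(ped, name, np.full(n, np.nan))
    if not np.all(df["id"].to_numpy() == np.arange(1, n + 1)):
        raise ValueError("pedigree ids must be dense and 1-based in file order")
    if np.any((ped.sire >= np.arange(n)) & (ped.sire >= 0)) or np.any(
        (ped.dam >= np.arange(n)) & (ped.dam >= 0)
    ):
        raise ValueError("parents must precede offspring")
    return ped
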