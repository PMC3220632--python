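"""Bivariate additive polygenic model, simulated EBVs and the total merit index.

Two traits are modelled: a production trait A under direct selection and a
functional trait B genetically correlated with A (correlation ``rho``, -0.3 by
default in the breeding scheme).  Both traits have unit genetic variance in the
founder population, so every genetic value is expressed in initial-genetic-
standard-deviation units.

The model is purely infinitesimal: an offspring's genetic value is the
mid-parent mean plus a Mendelian sampling deviation whose variance shrinks
with parental inbreeding,

    A_o = (A_s + A_d)/2 + gamma * sqrt(1/2 * (1 - (F_s + F_d)/2)),

with the analogous expression for trait B and (gamma, delta) a standard
bivariate normal pair of correlation ``rho``.

EBVs are not estimated from data; an evaluation of fixed accuracy CD (the
squared correlation between EBV and true value; 0.6 for bulls, 0.4 for cows)
is imposed directly:

    EBV = CD * g + eps * sqrt(CD * (1 - CD)),   eps ~ N(0, 1),

which gives corr(EBV, g)^2 = CD and var(EBV) = CD^2 + CD(1 - CD).  The total
merit index is the weighted sum TMI = w_A * EBVA + w_B * EBVB with
w_B = 1 - w_A.

All functions exist in a scalar form (returning :class:`TraitPair` /
:class:`EbvRecord`) and a vectorised form operating on numpy arrays; the
breeding-scheme engine uses the vectorised forms.  Randomness always enters
through an explicit ``numpy.random.Generator``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TraitPair",
    "EbvRecord",
    "draw_founder_pair",
    "draw_founder_pairs",
    "offspring_genetic_values",
    "offspring_genetic_values_array",
    "simulate_ebv",
    "simulate_ebv_array",
    "total_merit_index",
    "total_merit_index_array",
]

#: Default genetic correlation between traits A and B.
DEFAULT_RHO = -0.3


@dataclass(frozen=True)
class TraitPair:
    """True genetic values of one animal for traits A and B."""

    A: float
    B: float


@dataclass
class EbvRecord:
    """Simulated estimated breeding values of one animal.

    Attributes
    ----------
    EBVA, EBVB : float
        EBVs for traits A and B.
    CD : float
        Accuracy (squared correlation between EBV and true value) used when
        the EBVs were simulated.
    TMI : float or None
        Total merit index, set once a weight is chosen.
    """

    EBVA: float
    EBVB: float
    CD: float
    TMI: float | None = None


def _check_rho(rho: float) -> None:
    if not -1.0 <= rho <= 1.0:
        raise ValueError(f"rho must lie in [-1, 1], got {rho}")


def _check_cd(cd: float) -> None:
    if not 0.0 < cd <= 1.0:
        raise ValueError(f"accuracy CD must lie in (0, 1], got {cd}")


def draw_founder_pairs(
    n: int, rho: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` founder genetic-value pairs.

    A is standard normal; B = rho*A + sqrt(1-rho^2)*beta with beta an
    independent standard normal, so B is also marginally N(0, 1) and
    corr(A, B) = rho.
    """
    _check_rho(rho)
    a = rng.standard_normal(n)
    beta = rng.standard_normal(n)
    b = rho * a + np.sqrt(1.0 - rho * rho) * beta
    return a, b


def draw_founder_pair(rho: float, rng: np.random.Generator) -> TraitPair:
    """Draw one founder animal's (A, B) pair; see :func:`draw_founder_pairs`."""
    a, b = draw_founder_pairs(1, rho, rng)
    return TraitPair(A=float(a[0]), B=float(b[0]))


def correlated_mendelian_draws(
    n: int, rho: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` (gamma, delta) standard-normal pairs with correlation rho.

    Cholesky construction: delta = rho*gamma + sqrt(1-rho^2)*z.
    """
    _check_rho(rho)
    gamma = rng.standard_normal(n)
    z = rng.standard_normal(n)
    delta = rho * gamma + np.sqrt(1.0 - rho * rho) * z
    return gamma, delta


def offspring_genetic_values_array(
    sire_a: np.ndarray,
    sire_b: np.ndarray,
    dam_a: np.ndarray,
    dam_b: np.ndarray,
    f_sire: np.ndarray,
    f_dam: np.ndarray,
    rho: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Genetic values of offspring given parental values and inbreeding.

    The Mendelian sampling standard deviation is
    sqrt(1/2 * (1 - (F_s + F_d)/2)); it vanishes when both parents are fully
    inbred and equals sqrt(1/2) for non-inbred parents.
    """
    f_sire = np.asarray(f_sire, dtype=float)
    f_dam = np.asarray(f_dam, dtype=float)
    for f in (f_sire, f_dam):
        if np.any((f < 0.0) | (f > 1.0)):
            raise ValueError("inbreeding coefficients must lie in [0, 1]")
    n = np.broadcast(sire_a, dam_a, f_sire, f_dam).size
    gamma, delta = correlated_mendelian_draws(n, rho, rng)
    sd = np.sqrt(0.5 * (1.0 - 0.5 * (f_sire + f_dam)))
    a = 0.5 * (np.asarray(sire_a, float) + np.asarray(dam_a, float)) + gamma * sd
    b = 0.5 * (np.asarray(sire_b, float) + np.asarray(dam_b, float)) + delta * sd
    return a, b


def offspring_genetic_values(
    sire: TraitPair,
    dam: TraitPair,
    f_sire: float,
    f_dam: float,
    rho: float,
    rng: np.random.Generator,
) -> TraitPair:
    """Scalar form of :func:`offspring_genetic_values_array`."""
    a, b = offspring_genetic_values_array(
        np.array([sire.A]),
        np.array([sire.B]),
        np.array([dam.A]),
        np.array([dam.B]),
        np.array([f_sire]),
        np.array([f_dam]),
        rho,
        rng,
    )
    return TraitPair(A=float(a[0]), B=float(b[0]))


def simulate_ebv_array(
    a: np.ndarray, b: np.ndarray, cd: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate EBVs for both traits at accuracy ``cd``.

    EBV = cd*g + eps*sqrt(cd*(1-cd)) with eps independent standard normals
    per trait, so the squared correlation between EBV and g equals cd.
    """
    _check_cd(cd)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    noise_sd = np.sqrt(cd * (1.0 - cd))
    eps = rng.standard_normal(a.shape)
    phi = rng.standard_normal(b.shape)
    return cd * a + eps * noise_sd, cd * b + phi * noise_sd


def simulate_ebv(traits: TraitPair, cd: float, rng: np.random.Generator) -> EbvRecord:
    """Scalar form of :func:`simulate_ebv_array` (TMI left unset)."""
    ebva, ebvb = simulate_ebv_array(
        np.array([traits.A]), np.array([traits.B]), cd, rng
    )
    return EbvRecord(EBVA=float(ebva[0]), EBVB=float(ebvb[0]), CD=cd)


def total_merit_index_array(
    ebva: np.ndarray, ebvb: np.ndarray, w_a: float
) -> np.ndarray:
    """TMI = w_A*EBVA + (1-w_A)*EBVB for arrays of EBVs."""
    if not 0.0 <= w_a <= 1.0:
        raise ValueError(f"w_A must lie in [0, 1], got {w_a}")
    return w_a * np.asarray(ebva, float) + (1.0 - w_a) * np.asarray(ebvb, float)


def total_merit_index(ebv: EbvRecord, w_a: float) -> float:
    """Scalar TMI; also stores the result on the record."""
    tmi = float(total_merit_index_array(np.array(ebv.EBVA), np.array(ebv.EBVB), w_a))
    ebv.TMI = tmi
    return tmi
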