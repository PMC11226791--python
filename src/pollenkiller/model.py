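"""Deterministic two-locus toxin–antidote pollen-killer model.

The model tracks a hermaphroditic plant population with perfect flowers.
Two linked loci (alleles A/a and B/b, recombination rate ``r``) define four
haplotypes in the fixed order

    0 AB  "neutral"    cannot kill, cannot be killed
    1 Ab  "killer"     kills a-bearing pollen, cannot be killed
    2 aB  "sensitive"  killed by b-carriers, does not kill
    3 ab  "suicide"    kills and is killed

Pollen (male gametes) bearing allele "a" is destroyed with probability ``k``
whenever the diploid producing it carries at least one "b" allele.  Female
gametes are unaffected.  Each flower is fertilized either by its own pollen
(selfing, pollen mass ``M_self``) or by a shared outcross pollen pool
(``M_pool``); the selfing rate is ``s = M_self / (M_self + M_pool)``.
Fertility of a flower saturates at 1 once available pollen exceeds a
``1/R`` fraction of the normal supply, where ``R >= 1`` is the pollen
redundancy level.

The population state is a length-10 probability vector over ordered
diploid genotypes

    H = (AB|AB, AB|Ab, AB|aB, AB|ab, Ab|Ab, Ab|aB, Ab|ab, aB|aB, aB|ab, ab|ab)

where the two double heterozygotes AB|ab (index 3) and Ab|aB (index 5)
are kept distinct because they produce different recombinant pollen.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "HAPLOTYPES",
    "HAPLOTYPE_LABELS",
    "GENOTYPES",
    "GENOTYPE_NAMES",
    "N_HAPLOTYPES",
    "N_GENOTYPES",
    "ModelParams",
    "GameteMatrices",
    "StopRule",
    "EquilibriumReport",
    "build_gamete_matrices",
    "pollen_pool_frequencies",
    "pollen_availability",
    "fertility",
    "offspring_distribution",
    "transition_update",
    "step",
    "haplotype_frequencies",
    "genotype_frequencies_from_haplotype_homozygotes",
    "iterate",
    "classify_equilibrium",
]

HAPLOTYPES: tuple[str, ...] = ("AB", "Ab", "aB", "ab")
HAPLOTYPE_LABELS: tuple[str, ...] = ("neutral", "killer", "sensitive", "suicide")
N_HAPLOTYPES = 4

#: Index of each haplotype by its conventional name.
NEUTRAL, KILLER, SENSITIVE, SUICIDE = 0, 1, 2, 3

#: Ordered genotype list: pairs (h1, h2) of haplotype indices.
GENOTYPES: tuple[tuple[int, int], ...] = (
    (0, 0), (0, 1), (0, 2), (0, 3), (1, 1),
    (1, 2), (1, 3), (2, 2), (2, 3), (3, 3),
)
GENOTYPE_NAMES: tuple[str, ...] = tuple(
    f"{HAPLOTYPES[a]}|{HAPLOTYPES[b]}" for a, b in GENOTYPES
)
N_GENOTYPES = 10

# allele composition per haplotype: (locus-1 allele is "a", locus-2 allele is "b")
_HAS_A = np.array([False, False, True, True])  # AB, Ab, aB, ab
_HAS_B = np.array([False, True, False, True])

_SUM_TOL = 1e-9
_NEG_TOL = 1e-12


class ParameterError(ValueError):
    """A model parameter is outside its admissible range."""


class DegeneratePopulationError(RuntimeError):
    """The population produces no pollen or no offspring at all."""


@dataclass(frozen=True)
class ModelParams:
    """Scalar parameters of the pollen-killer model.

    Parameters
    ----------
    r
        Recombination probability between the two loci, in [0, 0.5].
    s
        Selfing rate, in [0, 1]; the probability a flower is fertilized by
        pollen from its own plant.
    k
        Killing efficiency, in [0, 1]; probability an a-bearing pollen grain
        dies in a b-carrying plant.
    R
        Pollen redundancy level, >= 1; pollen delivered per flower divided by
        the pollen needed to fertilize all of its ovules.
    M_total
        Pollen-supply scale M_self + M_pool.  Only the ratio, fixed by ``s``,
        matters; the default of 1 gives M_self = s and M_pool = 1 - s.
    """

    r: float
    s: float
    k: float = 1.0
    R: float = 10.0
    M_total: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.r <= 0.5:
            raise ParameterError(f"recombination rate r={self.r} not in [0, 0.5]")
        if not 0.0 <= self.s <= 1.0:
            raise ParameterError(f"selfing rate s={self.s} not in [0, 1]")
        if not 0.0 <= self.k <= 1.0:
            raise ParameterError(f"killing efficiency k={self.k} not in [0, 1]")
        if self.R < 1.0:
            raise ParameterError(f"pollen redundancy R={self.R} must be >= 1")
        if not self.M_total > 0.0:
            raise ParameterError(f"pollen supply M_total={self.M_total} must be > 0")

    @property
    def M_self(self) -> float:
        return self.s * self.M_total

    @property
    def M_pool(self) -> float:
        return (1.0 - self.s) * self.M_total


@dataclass(frozen=True)
class GameteMatrices:
    """Male (``Gm``) and female (``Gf``) 10x4 gamete-generating matrices.

    Row i gives, for a plant of genotype ``GENOTYPES[i]``, the probability
    that a gamete carries each haplotype *and survives*.  Female rows always
    sum to 1; male rows fall below 1 when pollen killing removes mass.
    """

    Gm: np.ndarray
    Gf: np.ndarray


def _recombinants(h1: int, h2: int) -> tuple[int, int]:
    """Haplotypes produced by a crossover between h1 and h2."""
    # haplotype index = 2*has_a + has_b with ordering AB=0, Ab=1, aB=2, ab=3
    a1, b1 = _HAS_A[h1], _HAS_B[h1]
    a2, b2 = _HAS_A[h2], _HAS_B[h2]
    rec1 = 2 * int(a1) + int(b2)
    rec2 = 2 * int(a2) + int(b1)
    return rec1, rec2


def build_gamete_matrices(params: ModelParams) -> GameteMatrices:
    """Construct the gamete-generating matrices for the given parameters.

    Pre-killing, a genotype h1|h2 puts mass (1-r)/2 on each parental
    haplotype and r/2 on each recombinant (masses accumulate on identical
    haplotypes, so homozygote rows are a point mass).  The female matrix is
    exactly this distribution.  The male matrix additionally multiplies the
    mass of every a-carrying haplotype (aB, ab) by (1-k) iff the diploid
    carries at least one "b" allele.
    """
    r, k = params.r, params.k
    Gf = np.zeros((N_GENOTYPES, N_HAPLOTYPES))
    for i, (h1, h2) in enumerate(GENOTYPES):
        Gf[i, h1] += 0.5 * (1.0 - r)
        Gf[i, h2] += 0.5 * (1.0 - r)
        rec1, rec2 = _recombinants(h1, h2)
        Gf[i, rec1] += 0.5 * r
        Gf[i, rec2] += 0.5 * r
    Gm = Gf.copy()
    carries_b = np.array([_HAS_B[h1] or _HAS_B[h2] for h1, h2 in GENOTYPES])
    Gm[np.ix_(carries_b, _HAS_A)] *= 1.0 - k
    return GameteMatrices(Gm=Gm, Gf=Gf)


def _check_theta(theta: np.ndarray) -> np.ndarray:
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (N_GENOTYPES,):
        raise ValueError(f"theta must have shape ({N_GENOTYPES},), got {theta.shape}")
    if np.any(theta < -_NEG_TOL):
        raise ValueError("genotype frequencies must be nonnegative")
    theta = np.clip(theta, 0.0, None)
    if abs(theta.sum() - 1.0) > _SUM_TOL:
        raise ValueError(f"genotype frequencies sum to {theta.sum()!r}, expected 1")
    return theta


def pollen_pool_frequencies(G: GameteMatrices, theta: np.ndarray) -> np.ndarray:
    """Haplotype frequencies of the outcross pollen pool.

    The pool receives each genotype's surviving pollen in proportion to its
    population frequency; the result is ``Gm.T @ theta`` normalized to sum 1.
    """
    theta = _check_theta(theta)
    mass = G.Gm.T @ theta
    total = mass.sum()
    if total <= 0.0:
        raise DegeneratePopulationError("population produces no pollen")
    return mass / total


def pollen_availability(G: GameteMatrices, params: ModelParams) -> np.ndarray:
    """Pollen available to a flower of each genotype: pool plus own surviving pollen."""
    return params.M_pool + params.M_self * G.Gm.sum(axis=1)


def fertility(N: np.ndarray, params: ModelParams) -> np.ndarray:
    """Probability each genotype's flower forms an embryo.

    Linear in available pollen up to the saturation point M_total / R,
    and 1 beyond it; a flower with no pollen at all has fertility 0.
    """
    N = np.asarray(N, dtype=float)
    phi = np.minimum(1.0, N * params.R / params.M_total)
    return np.clip(phi, 0.0, 1.0)


def offspring_distribution(
    i: int,
    G: GameteMatrices,
    f: np.ndarray,
    N: np.ndarray,
    params: ModelParams,
) -> np.ndarray:
    """Genotype distribution of offspring from a fertilized flower of genotype i.

    The female gamete comes from the flower's own Gf row; the fertilizing
    pollen haplotype is drawn from the mixture of self pollen (mass
    ``M_self * Gm[i]``) and pool pollen (mass ``M_pool * f``), normalized by
    the flower's available pollen ``N[i]``.  The two phase-distinct double
    heterozygotes receive their separate masses.  Returns the all-zero
    vector for a flower with no pollen at all (it contributes nothing).
    """
    if N[i] <= 0.0:
        return np.zeros(N_GENOTYPES)
    pollen = (params.M_self * G.Gm[i] + params.M_pool * f) / N[i]
    female = G.Gf[i]
    p = np.zeros(N_GENOTYPES)
    for j, (h1, h2) in enumerate(GENOTYPES):
        p[j] = female[h1] * pollen[h2]
        if h1 != h2:
            p[j] += female[h2] * pollen[h1]
    return p


def transition_update(theta: np.ndarray, params: ModelParams,
                      G: GameteMatrices | None = None) -> np.ndarray:
    """One-generation update (un-normalized masses are fertility-weighted).

    Implements theta'_j ∝ sum_i theta_i * phi_i * p_ij, renormalized so the
    next generation is again a probability vector.
    """
    theta = _check_theta(theta)
    if G is None:
        G = build_gamete_matrices(params)
    f = pollen_pool_frequencies(G, theta)
    N = pollen_availability(G, params)
    phi = fertility(N, params)
    # P[i, j] = offspring distribution of flower genotype i
    pollen = params.M_self * G.Gm + params.M_pool * f[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        pollen = np.where(N[:, None] > 0.0, pollen / N[:, None], 0.0)
    P = np.zeros((N_GENOTYPES, N_GENOTYPES))
    for j, (h1, h2) in enumerate(GENOTYPES):
        P[:, j] = G.Gf[:, h1] * pollen[:, h2]
        if h1 != h2:
            P[:, j] += G.Gf[:, h2] * pollen[:, h1]
    mass = (theta * phi) @ P
    total = mass.sum()
    if total <= 0.0:
        raise DegeneratePopulationError("population produced no offspring")
    out = np.clip(mass / total, 0.0, None)
    return out / out.sum()


def step(theta: np.ndarray, params: ModelParams) -> np.ndarray:
    """One deterministic generation of the recursion."""
    return transition_update(theta, params)


def haplotype_frequencies(theta: np.ndarray) -> np.ndarray:
    """Length-4 haplotype frequencies; each genotype contributes 0.5 per copy."""
    theta = _check_theta(theta)
    h = np.zeros(N_HAPLOTYPES)
    for freq, (h1, h2) in zip(theta, GENOTYPES):
        h[h1] += 0.5 * freq
        h[h2] += 0.5 * freq
    return h


def genotype_frequencies_from_haplotype_homozygotes(
    freqs: Sequence[float] | dict[str, float],
) -> np.ndarray:
    """Initial genotype vector from homozygote frequencies per haplotype.

    ``freqs`` maps haplotype (name or index order AB, Ab, aB, ab) to the
    frequency of its homozygote; used to set up invasion scenarios where the
    population starts as a mixture of pure lines.
    """
    vec = np.zeros(N_HAPLOTYPES)
    if isinstance(freqs, dict):
        for name, val in freqs.items():
            vec[HAPLOTYPES.index(name)] = val
    else:
        vec[:] = np.asarray(freqs, dtype=float)
    if abs(vec.sum() - 1.0) > _SUM_TOL:
        raise ValueError("homozygote frequencies must sum to 1")
    theta = np.zeros(N_GENOTYPES)
    for h, val in enumerate(vec):
        theta[GENOTYPES.index((h, h))] = val
    return theta


@dataclass(frozen=True)
class StopRule:
    """Termination rule for long-run iteration.

    mode
        "absolute": stop once the killer (Ab) or sensitive (aB) haplotype
        frequency drops below ``threshold`` (default 0.001).
        "relative_1pct": stop once either drops below 1% of its own initial
        frequency (haplotypes starting at 0 are ignored).
    max_generations
        Hard cap on the number of iterations (default 10,000).
    """

    mode: Literal["absolute", "relative_1pct"] = "absolute"
    threshold: float = 1e-3
    max_generations: int = 10_000

    def limits(self, theta0: np.ndarray) -> tuple[float, float]:
        """(killer, sensitive) stop thresholds for a given initial state."""
        if self.mode == "absolute":
            return self.threshold, self.threshold
        if self.mode == "relative_1pct":
            h0 = haplotype_frequencies(theta0)
            lo_k = 0.01 * h0[KILLER] if h0[KILLER] > 0 else -np.inf
            lo_s = 0.01 * h0[SENSITIVE] if h0[SENSITIVE] > 0 else -np.inf
            return lo_k, lo_s
        raise ValueError(f"unknown stop mode {self.mode!r}")


@dataclass(frozen=True)
class EquilibriumReport:
    """Result of iterating the recursion to (pseudo-)equilibrium."""

    terminal_theta: np.ndarray
    generations_run: int
    stop_reason: Literal["threshold", "max_generations"]
    state: str
    trajectory: np.ndarray | None = field(default=None, repr=False)

    @property
    def terminal_haplotype_frequencies(self) -> np.ndarray:
        return haplotype_frequencies(self.terminal_theta)


#: The five enumerated equilibrium states, keyed by the set of present haplotypes.
_STATES: dict[frozenset[int], str] = {
    frozenset({KILLER}): "killer_fixed",
    frozenset({SENSITIVE}): "sensitive_fixed",
    frozenset({NEUTRAL}): "neutral_fixed",
    frozenset({NEUTRAL, SENSITIVE}): "neutral_sensitive_coexist",
    frozenset({NEUTRAL, KILLER}): "neutral_killer_coexist",
}


def classify_equilibrium(theta: np.ndarray, presence_threshold: float = 1e-3) -> str:
    """Map a genotype state to one of the five equilibrium classes.

    A haplotype counts as present when its frequency exceeds
    ``presence_threshold``.  Any presence set outside the five enumerated
    states (e.g. suicide still segregating, or killer and sensitive both
    present before convergence) is reported as "unresolved".
    """
    h = haplotype_frequencies(theta)
    present = frozenset(int(i) for i in np.flatnonzero(h > presence_threshold))
    return _STATES.get(present, "unresolved")


def iterate(
    theta0: np.ndarray,
    params: ModelParams,
    stop: StopRule | None = None,
    record_trajectory: bool = False,
) -> EquilibriumReport:
    """Iterate the recursion until a stop rule fires.

    Runs :func:`step` until the killer or sensitive haplotype frequency
    crosses the stop rule's loss threshold, or ``max_generations`` elapse.
    When ``record_trajectory`` is set the report carries a
    ``(generations_run + 1) x 10`` array of genotype frequencies including
    the initial state.
    """
    if stop is None:
        stop = StopRule()
    theta = _check_theta(theta0)
    lo_k, lo_s = stop.limits(theta)
    G = build_gamete_matrices(params)
    traj = [theta.copy()] if record_trajectory else None
    gens = 0
    reason: Literal["threshold", "max_generations"] = "max_generations"
    for _ in range(stop.max_generations):
        h = haplotype_frequencies(theta)
        if h[KILLER] < lo_k or h[SENSITIVE] < lo_s:
            reason = "threshold"
            break
        theta = transition_update(theta, params, G)
        gens += 1
        if traj is not None:
            traj.append(theta.copy())
    else:
        # loop exhausted without breaking; credit the threshold if it was
        # reached exactly at the final generation (not for a zero-length run)
        if stop.max_generations > 0:
            h = haplotype_frequencies(theta)
            if h[KILLER] < lo_k or h[SENSITIVE] < lo_s:
                reason = "threshold"
    return EquilibriumReport(
        terminal_theta=theta,
        generations_run=gens,
        stop_reason=reason,
        state=classify_equilibrium(theta),
        trajectory=np.array(traj) if traj is not None else None,
    )
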