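"""Exact two-locus dynamics under partial selfing and Gaussian stabilising selection.

Two biallelic loci (alleles a/A and b/B) contribute additively to a trait under
Gaussian stabilising selection with variance ``Vs``.  Effects and the distance
to the optimum are scaled by ``sqrt(Vs)`` so that ``gamma = alpha/sqrt(Vs)`` and
``d = z/sqrt(Vs)`` are dimensionless.  The population reproduces by partial
self-fertilisation: with probability ``sigma`` an offspring is produced by two
independent meioses of a single (fitness-sampled) parent, otherwise by the
union of gametes from two independent fitness-sampled parents.

The module provides

* an exact, deterministic (infinite-population) genotype recursion
  (:class:`TwoLocusRecursion`, :func:`exact_generation_step`) which models
  selfing explicitly, including recombination during self-fertilisation — this
  is the brute-force oracle against which the closed forms are checked;
* the closed-form weak-selection approximations for the change in linkage
  disequilibrium at the optimum, its quasi-linkage-equilibrium value, and the
  directional-phase allele-frequency and LD dynamics after an optimum shift.

Haplotypes are indexed 0..3 for ab, Ab, aB, AB.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "HAPLOTYPE_LABELS",
    "TwoLocusParams",
    "TwoLocusState",
    "GenotypeTable",
    "DirectionalCoefficients",
    "genotypes_from_haplotypes",
    "TwoLocusRecursion",
    "exact_generation_step",
    "delta_ld_at_optimum",
    "gamma_threshold",
    "qle_ld",
    "allele_change_directional",
    "ld_change_directional",
    "directional_coefficients",
]

HAPLOTYPE_LABELS = ("ab", "Ab", "aB", "AB")

# allele content of each haplotype: (carries A, carries B)
_A_ALLELE = np.array([0, 1, 0, 1], dtype=float)
_B_ALLELE = np.array([0, 0, 1, 1], dtype=float)


def _neutral_F(sigma: float) -> float:
    """Equilibrium inbreeding coefficient under partial selfing, sigma/(2-sigma)."""
    return sigma / (2.0 - sigma)


@dataclass(frozen=True)
class TwoLocusParams:
    """Parameters of the scaled two-locus model.

    Parameters
    ----------
    gammaA, gammaB : float
        Scaled allelic effects, ``gamma = alpha / sqrt(Vs)``.
    r : float
        Recombination fraction between the loci, in [0, 1/2].
    sigma : float
        Selfing fraction in [0, 1].
    F : float, optional
        Inbreeding coefficient.  Defaults to the neutral equilibrium value
        ``sigma / (2 - sigma)``.
    d0 : float
        Scaled distance of the optimum from the ancestral mean, ``z0/sqrt(Vs)``.
    """

    gammaA: float
    gammaB: float
    r: float
    sigma: float = 0.0
    F: float | None = None
    d0: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.r <= 0.5:
            raise ValueError(f"recombination fraction must be in [0, 1/2], got {self.r}")
        if not 0.0 <= self.sigma <= 1.0:
            raise ValueError(f"selfing fraction must be in [0, 1], got {self.sigma}")
        if self.F is None:
            object.__setattr__(self, "F", _neutral_F(self.sigma))
        if not 0.0 <= self.F <= 1.0:
            raise ValueError(f"inbreeding coefficient must be in [0, 1], got {self.F}")


@dataclass(frozen=True)
class TwoLocusState:
    """Haplotype frequencies (ab, Ab, aB, AB) with derived quantities."""

    x: tuple[float, float, float, float]

    def __post_init__(self):
        arr = np.asarray(self.x, dtype=float)
        if arr.shape != (4,):
            raise ValueError("expected four haplotype frequencies")
        if np.any(arr < -1e-12) or np.any(arr > 1 + 1e-12):
            raise ValueError(f"haplotype frequencies outside [0, 1]: {arr}")
        if abs(arr.sum() - 1.0) > 1e-9:
            raise ValueError(f"haplotype frequencies must sum to 1, got {arr.sum()}")
        object.__setattr__(self, "x", tuple(float(v) for v in arr))

    @classmethod
    def from_frequencies(cls, pA: float, pB: float, delta: float = 0.0) -> "TwoLocusState":
        """Build a state from allele frequencies and linkage disequilibrium."""
        x = (
            (1 - pA) * (1 - pB) + delta,
            pA * (1 - pB) - delta,
            (1 - pA) * pB - delta,
            pA * pB + delta,
        )
        return cls(x)

    @property
    def pA(self) -> float:
        return self.x[1] + self.x[3]

    @property
    def pB(self) -> float:
        return self.x[2] + self.x[3]

    @property
    def delta(self) -> float:
        """Linkage disequilibrium, delta = x_AB - pA*pB."""
        return self.x[3] - self.pA * self.pB


@dataclass(frozen=True)
class GenotypeTable:
    """Ordered 4x4 genotype-frequency matrix; g[i, j] is the frequency of the
    ordered haplotype pair (i, j).  Symmetric; sums to one."""

    g: np.ndarray

    def __post_init__(self):
        g = np.asarray(self.g, dtype=float)
        if g.shape != (4, 4):
            raise ValueError("genotype table must be 4x4")
        if np.any(g < -1e-12):
            raise ValueError("negative genotype frequency")
        if abs(g.sum() - 1.0) > 1e-9:
            raise ValueError(f"genotype frequencies must sum to 1, got {g.sum()}")
        object.__setattr__(self, "g", g)

    def unordered(self, i: int, j: int) -> float:
        """Frequency of the unordered genotype {i, j}."""
        if i == j:
            return float(self.g[i, i])
        return float(self.g[i, j] + self.g[j, i])

    def haplotype_frequencies(self) -> np.ndarray:
        return self.g.sum(axis=1)

    def state(self) -> TwoLocusState:
        return TwoLocusState(tuple(self.haplotype_frequencies()))


@dataclass(frozen=True)
class DirectionalCoefficients:
    """Composite coefficients of the directional-phase dynamics."""

    kappa: float
    Gamma: float


def genotypes_from_haplotypes(state: TwoLocusState, F: float) -> GenotypeTable:
    """Genotype frequencies from haplotype frequencies under inbreeding.

    Inbreeding is approximated as raising the probability of identity by
    descent of an individual's two haplotypes by ``F``:
    ``g_ii = x_i^2 + F x_i (1 - x_i)`` and ``g_ij = 2 x_i x_j (1 - F)`` for
    distinct haplotypes (the latter split evenly across the two orderings).
    The approximation ignores recombination during self-fertilisation, which
    only matters when both selfing and recombination are high.
    """
    if not 0.0 <= F <= 1.0:
        raise ValueError(f"inbreeding coefficient must be in [0, 1], got {F}")
    x = np.asarray(state.x)
    g = (1.0 - F) * np.outer(x, x)
    g[np.diag_indices(4)] += F * x
    return GenotypeTable(g)


def _gamete_tensor(r: float) -> np.ndarray:
    """T[i, j, k]: probability that a parent with haplotypes (i, j) transmits
    gamete haplotype k, given recombination fraction r."""
    T = np.zeros((4, 4, 4))
    for i in range(4):
        for j in range(4):
            # non-recombinant gametes
            T[i, j, i] += (1.0 - r) / 2.0
            T[i, j, j] += (1.0 - r) / 2.0
            # recombinants: A-locus allele from one haplotype, B-locus from the other
            rec1 = int(_A_ALLELE[i] + 2 * _B_ALLELE[j])
            rec2 = int(_A_ALLELE[j] + 2 * _B_ALLELE[i])
            T[i, j, rec1] += r / 2.0
            T[i, j, rec2] += r / 2.0
    return T


def _fitness_matrix(params: TwoLocusParams) -> np.ndarray:
    """Gaussian fitness of each ordered genotype (scaled phenotype minus d0)."""
    nA = _A_ALLELE[:, None] + _A_ALLELE[None, :]
    nB = _B_ALLELE[:, None] + _B_ALLELE[None, :]
    d = params.gammaA * nA + params.gammaB * nB - params.d0
    return np.exp(-0.5 * d**2)


class TwoLocusRecursion:
    """Exact deterministic recursion on the full 4x4 genotype distribution.

    One generation consists of (i) viability selection — genotype frequencies
    weighted by Gaussian fitness; (ii) reproduction — with probability
    ``sigma`` an offspring is formed from two independent gametes of a single
    selected parent (selfing, with recombination acting in each meiosis),
    otherwise from one gamete each of two independently selected parents.

    The genotype distribution, not just haplotype frequencies, is the state:
    partial selfing drives it away from Hardy–Weinberg proportions.
    """

    def __init__(self, params: TwoLocusParams, genotypes: GenotypeTable):
        self.params = params
        self.g = np.array(genotypes.g, dtype=float)
        self._T = _gamete_tensor(params.r)
        self._W = _fitness_matrix(params)

    @classmethod
    def from_state(cls, params: TwoLocusParams, state: TwoLocusState,
                   F: float | None = None) -> "TwoLocusRecursion":
        """Initialise the genotype distribution from haplotype frequencies via
        the F-structure transform (F defaults to the params value)."""
        F = params.F if F is None else F
        return cls(params, genotypes_from_haplotypes(state, F))

    def step(self, n: int = 1) -> TwoLocusState:
        sigma = self.params.sigma
        for _ in range(n):
            sel = self.g * self._W
            sel /= sel.sum()
            # selfing: offspring genotype from two iid gametes of one parent
            g_self = np.einsum("ij,ijk,ijl->kl", sel, self._T, self._T)
            # outcrossing: population gamete pool
            pool = np.einsum("ij,ijk->k", sel, self._T)
            g_out = np.outer(pool, pool)
            self.g = sigma * g_self + (1.0 - sigma) * g_out
        return self.state()

    def state(self) -> TwoLocusState:
        return TwoLocusState(tuple(self.g.sum(axis=1)))

    def genotypes(self) -> GenotypeTable:
        return GenotypeTable(self.g.copy())

    def mean_fitness(self) -> float:
        return float((self.g * self._W).sum())

    def observed_heterozygosity(self, locus: str = "A") -> float:
        """Frequency of heterozygotes at one locus."""
        allele = _A_ALLELE if locus == "A" else _B_ALLELE
        het = allele[:, None] != allele[None, :]
        return float(self.g[het].sum())

    def inbreeding_coefficient(self, locus: str = "A") -> float:
        """F-hat = 1 - H_obs/H_exp at one locus (NaN if the locus is fixed)."""
        st = self.state()
        p = st.pA if locus == "A" else st.pB
        h_exp = 2.0 * p * (1.0 - p)
        if h_exp == 0.0:
            return float("nan")
        return 1.0 - self.observed_heterozygosity(locus) / h_exp


def exact_generation_step(state: TwoLocusState, params: TwoLocusParams) -> TwoLocusState:
    """One exact generation from haplotype frequencies.

    The genotype distribution is first reconstructed with the F-structure
    transform (using ``params.F``), then one full
    selection-plus-reproduction generation is applied.  For iterated dynamics
    prefer :class:`TwoLocusRecursion`, which carries the genotype distribution
    forward without re-imposing the F-structure each generation.
    """
    rec = TwoLocusRecursion.from_state(params, state)
    return rec.step()


def directional_coefficients(state: TwoLocusState, params: TwoLocusParams) -> DirectionalCoefficients:
    """kappa and Gamma for the directional-phase and at-optimum LD dynamics."""
    gA, gB, F, r = params.gammaA, params.gammaB, params.F, params.r
    pA, pB = state.pA, state.pB
    kappa = params.d0 * (gA * ((1 - pA) - pA) + gB * ((1 - pB) - pB))
    s = gA + gB
    Gamma = (1 + 3 * F) * s**2 + (1 - F) * r * (2 - s**2)
    return DirectionalCoefficients(kappa=kappa, Gamma=Gamma)


def delta_ld_at_optimum(state: TwoLocusState, params: TwoLocusParams) -> float:
    """Per-generation change in LD at the optimum (d0 = 0), to O(zeta^3):

        Delta delta = -(1+3F) pA pB gammaA gammaB - (delta/2) Gamma

    Stabilising selection generates negative LD between alleles whose effects
    point the same way (gammaA*gammaB > 0) and positive LD otherwise; existing
    LD decays through both selection and recombination (Gamma).
    """
    gA, gB, F = params.gammaA, params.gammaB, params.F
    Gamma = directional_coefficients(state, params).Gamma
    return -(1 + 3 * F) * state.pA * state.pB * gA * gB - 0.5 * state.delta * Gamma


def gamma_threshold(gammaA: float, gammaB: float) -> float:
    """Critical recombination fraction below which selfing amplifies negative LD.

    d(Gamma)/dF = 3 s^2 - r (2 - s^2) for s = gammaA + gammaB is positive iff
    r < 3 s^2 / (2 - s^2); returns that threshold.
    """
    s2 = (gammaA + gammaB) ** 2
    if s2 >= 2.0:
        raise ValueError("effect sum too large: requires (gammaA+gammaB)^2 < 2")
    return 3.0 * s2 / (2.0 - s2)


def qle_ld(state: TwoLocusState, params: TwoLocusParams) -> float:
    """Quasi-linkage-equilibrium LD at the optimum:

        delta_QLE = -[(1+3F) gammaA gammaB / ((1-F) r)] pA pB

    Valid when selection is slow relative to effective recombination,
    gammaA, gammaB << r (1-F).
    """
    if params.F >= 1.0 or params.r == 0.0:
        raise ValueError("QLE undefined for F = 1 or r = 0 (no effective recombination)")
    gA, gB, F, r = params.gammaA, params.gammaB, params.F, params.r
    return -((1 + 3 * F) * gA * gB / ((1 - F) * r)) * state.pA * state.pB


def allele_change_directional(state: TwoLocusState, params: TwoLocusParams,
                              locus: str = "A") -> float:
    """Directional-phase change in allele frequency (gamma << d0):

        Delta pA = d0 (1+F) (gammaA pA (1-pA) + delta gammaB)

    Negative LD with a like-directed partner slows the initial spread.
    """
    F, d0 = params.F, params.d0
    if locus == "A":
        g_own, g_other, p = params.gammaA, params.gammaB, state.pA
    elif locus == "B":
        g_own, g_other, p = params.gammaB, params.gammaA, state.pB
    else:
        raise ValueError("locus must be 'A' or 'B'")
    return d0 * (1 + F) * (g_own * p * (1 - p) + state.delta * g_other)


def ld_change_directional(state: TwoLocusState, params: TwoLocusParams) -> float:
    """Directional-phase change in LD:  Delta delta = delta (kappa (1+F) - (1-F) r)."""
    co = directional_coefficients(state, params)
    return state.delta * (co.kappa * (1 + params.F) - (1 - params.F) * params.r)
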