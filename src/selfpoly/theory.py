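"""Closed-form multi-locus predictions with background-association coefficients.

A quantitative trait is affected by ``n`` biallelic loci with additive effects
``alpha_i``; the mean phenotype is ``z = sum_i 2 alpha_i x_i``.  Under partial
selfing and stabilising selection, each allele is statistically associated with
the genetic background at the other loci.  The association is summarised by a
single coefficient per locus, ``beta_i``: allele ``A_i`` carries the background
deviation ``beta_i (1 - x_i)`` and ``a_i`` the deviation ``-beta_i x_i`` (so the
frequency-weighted mean deviation is zero).  Stabilising selection makes
``beta_i`` typically opposite in sign to ``alpha_i`` (negative LD / Bulmer
effect).  The ``beta_i`` are *variables* of the full dynamics, not parameters;
here they are exogenous inputs, and :func:`estimate_background_coefficients`
measures them from simulated haplotypes.

The module implements the per-locus allele dynamics, the recursion for the
distance of the mean phenotype from the optimum, the mutation–selection-balance
equilibrium frequency, and the equilibrium decomposition of the genetic
variance into genic variance ``V_g``, inbreeding covariance ``V_I`` and linkage
covariance ``C_LD`` (``V_G = V_g + V_I + C_LD``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TraitArchitecture",
    "DistanceState",
    "VarianceComponents",
    "allele_change",
    "distance_change",
    "equilibrium_frequency",
    "equilibrium_variance_components",
    "moments_from_frequencies",
    "mean_distance_change_from_frequencies",
    "estimate_background_coefficients",
]


@dataclass(frozen=True)
class TraitArchitecture:
    """Genetic architecture of one trait.

    Parameters
    ----------
    alpha : array of allelic effects of the derived alleles (trait units).
    beta : array of background-association coefficients (trait units);
        zero means associations are neglected.
    u : per-locus mutation rates; a scalar is broadcast to all loci.
    Vs : stabilising-selection variance (> 0); larger is weaker selection.
    F : inbreeding coefficient in [0, 1].
    """

    alpha: np.ndarray
    beta: np.ndarray | None = None
    u: np.ndarray | float = 1e-5
    Vs: float = 1.0
    F: float = 0.0

    def __post_init__(self):
        a = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        b = (np.zeros_like(a) if self.beta is None
             else np.broadcast_to(np.asarray(self.beta, dtype=float), a.shape).copy())
        u = np.broadcast_to(np.asarray(self.u, dtype=float), a.shape).copy()
        if self.Vs <= 0:
            raise ValueError("Vs must be positive")
        if not 0.0 <= self.F <= 1.0:
            raise ValueError(f"inbreeding coefficient must be in [0, 1], got {self.F}")
        object.__setattr__(self, "alpha", a)
        object.__setattr__(self, "beta", b)
        object.__setattr__(self, "u", u)

    @property
    def n(self) -> int:
        return self.alpha.size

    @property
    def U(self) -> float:
        """Total mutation rate, sum of per-locus rates."""
        return float(self.u.sum())


@dataclass(frozen=True)
class DistanceState:
    """State of the mean-phenotype dynamics at one generation.

    ``D`` is the distance of the mean phenotype from the optimum (trait units,
    positive when the optimum exceeds the mean), ``Vg`` the genic variance,
    ``CLD`` the linkage covariance, and ``mu3``, ``nu21``, ``nu12`` third-order
    central moments mixing powers of direct effects and background deviations.
    """

    D: float
    Vg: float
    CLD: float = 0.0
    mu3: float = 0.0
    nu21: float = 0.0
    nu12: float = 0.0


@dataclass(frozen=True)
class VarianceComponents:
    """Equilibrium decomposition of the genetic variance."""

    VG: float
    Vg: float
    VI: float
    CLD: float


def allele_change(x, arch: TraitArchitecture, D: float) -> np.ndarray:
    """Per-generation change of derived-allele frequencies at distance D.

    Two terms: directional selection toward the optimum, proportional to
    ``(1+F)(alpha_i+beta_i) D x (1-x)``, and stabilising selection pushing
    frequencies away from 1/2, proportional to
    ``(1+3F)(alpha_i+beta_i)^2 (1 - D^2/(2 Vs)) x (1-x)(1/2 - x)``.
    """
    x = np.asarray(x, dtype=float)
    ab = arch.alpha + arch.beta
    Vs, F = arch.Vs, arch.F
    directional = (1 + F) * ab * D * x * (1 - x) / Vs
    stabilising = (1 + 3 * F) * ab**2 * (1 - D**2 / (2 * Vs)) * x * (1 - x) * (0.5 - x) / Vs
    return directional - stabilising


def distance_change(state: DistanceState, arch: TraitArchitecture) -> float:
    """Per-generation change in the distance of the mean phenotype from the optimum.

    ``Delta D = -[(1+F) Vg + CLD] D / Vs
      + (1+3F)(1 - D^2/(2 Vs)) (mu3 + 2 nu21 + nu12) / Vs``

    The first term is the Lande-type response through expressed variance; the
    second is the contribution of third-order moments (skew of allelic effects
    around intermediate frequencies).
    """
    Vs, F = arch.Vs, arch.F
    third = state.mu3 + 2.0 * state.nu21 + state.nu12
    return (-( (1 + F) * state.Vg + state.CLD) * state.D / Vs
            + (1 + 3 * F) * (1 - state.D**2 / (2 * Vs)) * third / Vs)


def equilibrium_frequency(u, Vs: float, F: float, alpha, beta=0.0) -> np.ndarray:
    """Mutation–selection-balance frequency at the optimum (rare-allele regime):

        x_i(0) = u Vs / [(1+3F)(alpha_i + beta_i)^2]

    At ``beta=0, F=0`` this is the house-of-cards frequency ``u Vs / alpha^2``.
    Negative ``beta`` (opposing background) weakens the effective selection on
    the allele, so associations reduce the purging effect of selfing.
    """
    alpha = np.asarray(alpha, dtype=float)
    ab = alpha + np.asarray(beta, dtype=float)
    if np.any(ab == 0.0):
        raise ValueError("alpha + beta = 0: allele is effectively neutral, "
                         "no mutation-selection balance")
    return np.asarray(u, dtype=float) * Vs / ((1 + 3 * F) * ab**2)


def equilibrium_variance_components(arch: TraitArchitecture) -> VarianceComponents:
    """Equilibrium genetic variance and its decomposition at the optimum.

    With mean taken over loci (``<.> = (1/n) sum_i``):

    * ``VG  = 4 U Vs (1+F)/(1+3F) <alpha/(alpha+beta)>``
    * ``Vg  = 4 U Vs /(1+3F) <alpha^2/(alpha+beta)^2>``
    * ``VI  = F * Vg``
    * ``CLD = 4 U Vs (1+F)/(1+3F) <alpha beta/(alpha+beta)^2>``

    and ``VG = Vg + VI + CLD`` holds algebraically.  At ``beta=0, F=0`` this is
    the house-of-cards variance ``VG = Vg = 4 U Vs``.
    """
    ab = arch.alpha + arch.beta
    if np.any(ab == 0.0):
        raise ValueError("alpha + beta = 0 at some locus: degenerate architecture")
    U, Vs, F = arch.U, arch.Vs, arch.F
    base = 4.0 * U * Vs / (1 + 3 * F)
    Vg = base * float(np.mean(arch.alpha**2 / ab**2))
    VI = F * Vg
    CLD = base * (1 + F) * float(np.mean(arch.alpha * arch.beta / ab**2))
    VG = base * (1 + F) * float(np.mean(arch.alpha / ab))
    return VarianceComponents(VG=VG, Vg=Vg, VI=VI, CLD=CLD)


def moments_from_frequencies(x, arch: TraitArchitecture) -> DistanceState:
    """Per-locus (linkage-equilibrium) estimators of the variance and third
    moments entering the distance recursion, at frequencies ``x``.

    With ``q = 1 - x``:

    * ``Vg   = sum 2 alpha^2 x q``
    * ``CLD  = (1+F) sum 2 alpha beta x q``
    * ``mu3  = sum alpha^3 x q (q - x)``
    * ``nu21 = sum alpha^2 beta x q (q - x)``
    * ``nu12 = sum alpha beta^2 x q (q - x)``

    These groupings are fixed by requiring the distance recursion to be exactly
    consistent with the per-locus allele recursion
    (``Delta D = -sum_i 2 alpha_i Delta x_i`` for a fixed optimum).
    The returned state has ``D = 0``; callers set the distance.
    """
    x = np.asarray(x, dtype=float)
    a, b, F = arch.alpha, arch.beta, arch.F
    q = 1.0 - x
    w = x * q * (q - x)
    return DistanceState(
        D=0.0,
        Vg=float(np.sum(2.0 * a**2 * x * q)),
        CLD=float((1 + F) * np.sum(2.0 * a * b * x * q)),
        mu3=float(np.sum(a**3 * w)),
        nu21=float(np.sum(a**2 * b * w)),
        nu12=float(np.sum(a * b**2 * w)),
    )


def mean_distance_change_from_frequencies(x, arch: TraitArchitecture, D: float) -> float:
    """Distance change implied by the per-locus allele recursion,
    ``-sum_i 2 alpha_i Delta x_i`` (the optimum held fixed)."""
    return float(-np.sum(2.0 * arch.alpha * allele_change(x, arch, D)))


def estimate_background_coefficients(haplotype_effects: np.ndarray,
                                     carrier_matrix: np.ndarray,
                                     locus_effects: np.ndarray) -> np.ndarray:
    """Empirical background-association coefficients from a haplotype sample.

    The background of haplotype *h* at focal locus *i* is its total trait
    effect minus the locus-*i* contribution, ``z_h - alpha_i C[h, i]``.  The
    coefficient ``beta_i`` satisfies ``E[bg | carrier] - E[bg] =
    beta_i (1 - x_i)``.

    Parameters
    ----------
    haplotype_effects : (n_haplotypes,) total trait effect of each haplotype.
    carrier_matrix : (n_haplotypes, n_loci) 0/1 carrier indicators.
    locus_effects : (n_loci,) allelic effects ``alpha_i`` (from annotations).

    Returns
    -------
    beta : (n_loci,) array; NaN where a locus is monomorphic in the sample.
    """
    C = np.asarray(carrier_matrix, dtype=float)
    z = np.asarray(haplotype_effects, dtype=float)
    a = np.asarray(locus_effects, dtype=float)
    x = C.mean(axis=0)
    beta = np.full(C.shape[1], np.nan)
    for i in range(C.shape[1]):
        if x[i] <= 0.0 or x[i] >= 1.0:
            continue
        bg = z - a[i] * C[:, i]
        beta[i] = (bg[C[:, i] > 0.5].mean() - bg.mean()) / (1.0 - x[i])
    return beta
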