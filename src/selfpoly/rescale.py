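"""Effective-parameter rescaling for the outcrossing comparison.

Self-fertilisation reduces both the net input of new mutations (through the
reduction of effective population size by 1 + F) and the efficacy of
recombination (through homozygosity).  To ask whether high-selfing results are
explained by those rate changes alone, an outcrossing population is simulated
with the rescaled rates: ``mu_eff = mu / (1 + F)`` and
``rec_eff = rec (1 - 2F + Phi)``, where ``F = sigma/(2 - sigma)`` is the
equilibrium inbreeding coefficient and ``Phi`` the probability of joint
identity-by-descent at two loci, evaluated at recombination fraction 1/2
(appropriate when the per-genome crossover expectation ``rec (L-1)`` is what
is being rescaled):

    Phi = sigma (2 + sigma) / [(4 - sigma)(2 - sigma)]
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["RescaleResult", "inbreeding_F", "joint_ibd_Phi", "effective_rates"]


@dataclass(frozen=True)
class RescaleResult:
    F: float
    Phi: float
    mu_eff: float
    rec_eff: float


def _check_sigma(sigma: float):
    if not 0.0 <= sigma <= 1.0:
        raise ValueError(f"selfing fraction must be in [0, 1], got {sigma}")


def inbreeding_F(sigma: float) -> float:
    """Equilibrium inbreeding coefficient under partial selfing, sigma/(2 - sigma)."""
    _check_sigma(sigma)
    return sigma / (2.0 - sigma)


def joint_ibd_Phi(sigma: float) -> float:
    """Joint two-locus identity-by-descent probability at r = 1/2,
    sigma (2 + sigma) / [(4 - sigma)(2 - sigma)]."""
    _check_sigma(sigma)
    return sigma * (2.0 + sigma) / ((4.0 - sigma) * (2.0 - sigma))


def effective_rates(mu: float, rec: float, sigma: float) -> RescaleResult:
    """Mutation and recombination rates rescaled to their effective values
    under partial selfing: ``mu/(1+F)`` and ``rec (1 - 2F + Phi)``."""
    F = inbreeding_F(sigma)
    Phi = joint_ibd_Phi(sigma)
    return RescaleResult(F=F, Phi=Phi,
                         mu_eff=mu / (1.0 + F),
                         rec_eff=rec * (1.0 - 2.0 * F + Phi))
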