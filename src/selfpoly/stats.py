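"""Downstream measurements on simulated populations.

Implements the study's observables: the decomposition of genetic variance into
genic variance, inbreeding covariance and linkage-disequilibrium covariance;
the selfed-versus-outcrossed inbreeding-depression assay; pairwise linkage
disequilibrium (r^2, |D'|) with the thinning / minor-allele-frequency /
binning pipeline; haplotype sampling for visualisation; and allele-frequency
trajectories across the designated timepoints.

Variance decomposition (per trait, over the derived-allele sites j with
genotype frequencies f0, f1, f2, allele frequency p and effect a):

* genic variance      ``V_g = sum_j 2 p q a^2``   (Hardy–Weinberg, no linkage)
* inbreeding covariance ``V_I = sum_j (2 f2 f0 - f1^2/2) a^2``
  (zero at Hardy–Weinberg proportions; equals ``2 F p q a^2`` under the
  single-locus inbreeding model)
* total genetic variance ``V_G`` = variance of individual trait values
  (captures cross-locus covariance)
* LD covariance       ``C_LD = V_G - V_g - V_I``  (by construction)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import (DELETERIOUS, NEUTRAL, TRAIT, Haplotype, Population,
                       individual_fitness, make_gamete)

__all__ = [
    "VarianceReport",
    "LDTable",
    "HaplotypeSample",
    "variance_decomposition",
    "inbreeding_depression",
    "pairwise_ld",
    "ld_matrix",
    "ld_matrix_from_population",
    "ld_decay",
    "haplotype_sample",
    "allele_trajectories",
    "bootstrap_ci",
]


# ---------------------------------------------------------------------------
# variance decomposition


@dataclass
class VarianceReport:
    """Per-trait variance decomposition at one timepoint.

    The scalar accessors average over traits, which is how the study reports
    multi-trait runs.  ``VG = Vg + VI + CLD`` holds per trait by construction.
    """

    generation: int
    VG_i: np.ndarray
    Vg_i: np.ndarray
    VI_i: np.ndarray
    CLD_i: np.ndarray
    mean_trait_i: np.ndarray
    VG_per_locus_i: np.ndarray   # diagnostic: per-locus variances summed (= Vg+VI under LE)
    n_trait_sites: int

    def _mean(self, arr) -> float:
        return float(np.mean(arr))

    @property
    def VG(self) -> float:
        return self._mean(self.VG_i)

    @property
    def Vg(self) -> float:
        return self._mean(self.Vg_i)

    @property
    def VI(self) -> float:
        return self._mean(self.VI_i)

    @property
    def CLD(self) -> float:
        return self._mean(self.CLD_i)

    @property
    def mean_trait(self) -> float:
        return self._mean(self.mean_trait_i)


def _trait_dosage_matrix(pop: Population, individuals: np.ndarray | None = None
                         ) -> tuple[np.ndarray, np.ndarray]:
    """(dosage, trait_ids): per-individual copy counts of each segregating
    trait mutation, restricted to ``individuals`` when given."""
    idx = np.arange(pop.N) if individuals is None else np.asarray(individuals)
    hap_ids = []
    for i in idx:
        hap_ids.append(pop.haplotypes[2 * i].ids)
        hap_ids.append(pop.haplotypes[2 * i + 1].ids)
    if hap_ids:
        allids = np.concatenate(hap_ids)
    else:
        raise ValueError("empty sample")
    if len(allids) == 0:
        return np.zeros((len(idx), 0), dtype=np.int8), np.empty(0, dtype=np.int64)
    seg = np.unique(allids)
    tids = seg[pop.table.mclass[seg] == TRAIT]
    col = {int(m): k for k, m in enumerate(tids)}
    dosage = np.zeros((len(idx), len(tids)), dtype=np.int8)
    for row, i in enumerate(idx):
        for h in (pop.haplotypes[2 * i], pop.haplotypes[2 * i + 1]):
            ids = h.ids
            sub = ids[pop.table.mclass[ids] == TRAIT]
            for m in sub:
                dosage[row, col[int(m)]] += 1
    return dosage, tids


def variance_decomposition(pop: Population,
                           individuals: np.ndarray | None = None) -> VarianceReport:
    """Decompose the genetic variance of each trait for a population (or a
    subset of its individuals)."""
    cfg = pop.config
    dosage, tids = _trait_dosage_matrix(pop, individuals)
    n_ind = dosage.shape[0]
    if n_ind == 0:
        raise ValueError("empty sample")
    effects = pop.table.effects[tids] if len(tids) else \
        np.zeros((0, cfg.n_traits))  # (n_sites, n_traits)

    f0 = (dosage == 0).mean(axis=0)
    f1 = (dosage == 1).mean(axis=0)
    f2 = (dosage == 2).mean(axis=0)
    p = (f1 + 2.0 * f2) / 2.0
    a2 = effects**2  # (n_sites, n_traits)

    Vg_i = (2.0 * p * (1.0 - p)) @ a2 if len(tids) else np.zeros(cfg.n_traits)
    VI_i = (2.0 * f2 * f0 - 0.5 * f1**2) @ a2 if len(tids) else np.zeros(cfg.n_traits)
    per_locus = ((f1 + 4.0 * f2)[:, None] * a2
                 - ((f1 + 2.0 * f2)[:, None] * effects) ** 2).sum(axis=0) \
        if len(tids) else np.zeros(cfg.n_traits)

    # total genetic variance from individual trait values (includes cross-locus
    # covariance); the substitution offset is a constant and drops out
    z = (dosage @ effects) if len(tids) else np.zeros((n_ind, cfg.n_traits))
    z = z + 2.0 * pop.sub_trait
    VG_i = z.var(axis=0)
    CLD_i = VG_i - Vg_i - VI_i
    return VarianceReport(
        generation=pop.generation,
        VG_i=VG_i, Vg_i=Vg_i, VI_i=VI_i, CLD_i=CLD_i,
        mean_trait_i=z.mean(axis=0),
        VG_per_locus_i=per_locus,
        n_trait_sites=int(len(tids)),
    )


# ---------------------------------------------------------------------------
# inbreeding depression


def inbreeding_depression(pop: Population, rng: np.random.Generator,
                          n_offspring: int = 500) -> float:
    """1 - mean(w_selfed)/mean(w_outcrossed) over two transient cohorts.

    Each cohort holds ``n_offspring`` offspring of fitness-sampled parents of
    the source population — one produced by obligate selfing, one by obligate
    outcrossing (two distinct parents) — with mutation disabled, so cohort
    fitness reflects only variation already present.  Cohorts are discarded.
    """
    w = pop.fitnesses()
    total = w.sum()
    if total <= 0:
        raise ValueError("all parental fitnesses are zero")
    cum = np.cumsum(w)
    z0 = pop.optimum()

    def offspring_fitness(p1: int, p2: int) -> float:
        g1 = make_gamete(*pop.individual(p1), pop, rng, mutate=False)
        g2 = make_gamete(*pop.individual(p2), pop, rng, mutate=False)
        return individual_fitness(g1, g2, z0, pop.config,
                                  sub_trait=pop.sub_trait,
                                  n_fixed_del=pop.n_fixed_del)

    w_self = np.empty(n_offspring)
    w_out = np.empty(n_offspring)
    for k in range(n_offspring):
        p = int(np.searchsorted(cum, rng.random() * total))
        w_self[k] = offspring_fitness(p, p)
        p1 = int(np.searchsorted(cum, rng.random() * total))
        p2 = p1
        while p2 == p1 and pop.N > 1:
            p2 = int(np.searchsorted(cum, rng.random() * total))
        w_out[k] = offspring_fitness(p1, p2)
    if w_out.mean() == 0:
        raise ValueError("outcrossed cohort has zero mean fitness")
    return float(1.0 - w_self.mean() / w_out.mean())


# ---------------------------------------------------------------------------
# linkage disequilibrium


@dataclass
class LDTable:
    """Pairwise LD among retained SNPs plus the filters' provenance."""

    pairs: pd.DataFrame          # pos_i, pos_j, dist, r2, dprime
    positions: np.ndarray        # retained SNP positions
    genome_length: int

    def __len__(self):
        return len(self.pairs)


def pairwise_ld(h_i: np.ndarray, h_j: np.ndarray) -> tuple[float, float]:
    """(r^2, |D'|) of two 0/1 haplotype columns."""
    pA, pB = h_i.mean(), h_j.mean()
    pAB = (h_i * h_j).mean()
    D = pAB - pA * pB
    denom = pA * (1 - pA) * pB * (1 - pB)
    r2 = D**2 / denom if denom > 0 else np.nan
    if D >= 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    dprime = abs(D) / dmax if dmax > 0 else np.nan
    return float(r2), float(dprime)


def _thin_positions(positions: np.ndarray, min_spacing: float) -> np.ndarray:
    """Greedy left-to-right thinning: keep the first SNP, then every next SNP
    at least ``min_spacing`` beyond the last retained one."""
    keep = []
    last = -np.inf
    for k, p in enumerate(positions):
        if p - last >= min_spacing:
            keep.append(k)
            last = p
    return np.asarray(keep, dtype=np.int64)


def ld_matrix(hap_matrix: np.ndarray, positions: np.ndarray, genome_length: int,
              min_spacing: float | None = None, maf: float = 0.1) -> LDTable:
    """Pairwise r^2 and |D'| after MAF and spacing filters.

    ``min_spacing`` defaults to 2% of the genome length (0.5 Mb on the
    full-scale 25 Mb genome), so desk-scale runs retain the same genome
    fraction between SNPs.
    """
    if min_spacing is None:
        min_spacing = 0.02 * genome_length
    H = np.asarray(hap_matrix)
    positions = np.asarray(positions)
    order = np.argsort(positions, kind="stable")
    positions, H = positions[order], H[:, order]
    freq = H.mean(axis=0)
    minor = np.minimum(freq, 1 - freq)
    ok = minor >= maf
    positions, H = positions[ok], H[:, ok]
    keep = _thin_positions(positions, min_spacing)
    positions, H = positions[keep], H[:, keep]
    rows = []
    m = len(positions)
    if m < 2:
        warnings.warn("fewer than two SNPs retained after filtering")
    for i in range(m):
        for j in range(i + 1, m):
            r2, dp = pairwise_ld(H[:, i], H[:, j])
            rows.append((positions[i], positions[j],
                         positions[j] - positions[i], r2, dp))
    pairs = pd.DataFrame(rows, columns=["pos_i", "pos_j", "dist", "r2", "dprime"])
    return LDTable(pairs=pairs, positions=positions, genome_length=genome_length)


def ld_matrix_from_population(pop: Population, rng: np.random.Generator,
                              n_individuals: int = 50, **kwargs) -> LDTable:
    """LD table from a random sample of individuals' phased haplotypes."""
    sample = haplotype_sample(pop, rng, n_individuals=n_individuals,
                              max_mutations=None)
    return ld_matrix(sample.matrix, sample.positions, pop.config.L, **kwargs)


def ld_decay(tables: list[LDTable], rng: np.random.Generator,
             bin_frac: float = 0.02, max_frac: float = 0.5,
             min_bin_count: int = 10) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Binned LD-decay curves across replicates.

    Per replicate, pair distances are binned into windows of ``bin_frac`` of
    the genome (0.5 Mb at full scale) up to ``max_frac`` (half the genome);
    each occupied bin is randomly down-sampled to the size of the sparsest
    occupied bin, and the replicate is dropped entirely when that minimum is
    below ``min_bin_count``.

    Returns ``(per_replicate, mean_curve)`` data frames; both empty (with a
    warning) when every replicate is dropped.
    """
    rows = []
    for rep, tab in enumerate(tables):
        L = tab.genome_length
        width = bin_frac * L
        pairs = tab.pairs[tab.pairs["dist"] < max_frac * L]
        if len(pairs) == 0:
            continue
        bin_idx = np.floor(pairs["dist"].to_numpy() / width).astype(int)
        counts = pd.Series(bin_idx).value_counts()
        if counts.min() < min_bin_count:
            continue  # replicate omitted: too few entries in its sparsest bin
        m = int(counts.min())
        for b in counts.index:
            members = np.nonzero(bin_idx == b)[0]
            chosen = rng.choice(members, size=m, replace=False)
            sub = pairs.iloc[chosen]
            rows.append({
                "replicate": rep,
                "bin_mid": (b + 0.5) * width,
                "mean_r2": float(sub["r2"].mean()),
                "mean_dprime": float(sub["dprime"].mean()),
                "n": m,
            })
    per_rep = pd.DataFrame(rows, columns=["replicate", "bin_mid", "mean_r2",
                                          "mean_dprime", "n"])
    if per_rep.empty:
        warnings.warn("all replicates dropped by the LD-decay filters")
        return per_rep, per_rep.drop(columns=["replicate"])
    mean_curve = (per_rep.groupby("bin_mid", as_index=False)
                  [["mean_r2", "mean_dprime"]].mean())
    return per_rep, mean_curve


# ---------------------------------------------------------------------------
# haplotype samples and trajectories


@dataclass
class HaplotypeSample:
    """Phased 0/1 matrix of sampled haplotypes with mutation annotations."""

    matrix: np.ndarray           # (2 * n_individuals, n_sites)
    positions: np.ndarray
    annotations: pd.DataFrame    # id, position, class, mean_effect, sample_freq
    individuals: np.ndarray      # sampled individual indices
    generation: int


def haplotype_sample(pop: Population, rng: np.random.Generator,
                     n_individuals: int = 50,
                     max_mutations: int | None = 100) -> HaplotypeSample:
    """Sample individuals and build their phased haplotype matrix.

    Trait mutations fixed within the sample are excluded.  When
    ``max_mutations`` is set, retained sites are thinned to that many,
    prioritising segregating trait variants and filling with background
    (neutral and deleterious) mutations if space allows.
    """
    n = n_individuals
    if pop.N < n:
        warnings.warn(f"population has only {pop.N} individuals; sampling all")
        idx = np.arange(pop.N)
    else:
        idx = np.sort(rng.choice(pop.N, size=n, replace=False))
    haps = []
    for i in idx:
        haps.append(pop.haplotypes[2 * i])
        haps.append(pop.haplotypes[2 * i + 1])
    nh = len(haps)
    present = [h.ids for h in haps if len(h.ids)]
    if present:
        counts = pd.Series(np.concatenate(present)).value_counts()
        ids = counts.index.to_numpy()
        freq = counts.to_numpy() / nh
    else:
        ids = np.empty(0, dtype=np.int64)
        freq = np.empty(0)
    cls = pop.table.mclass[ids] if len(ids) else np.empty(0, dtype=np.int8)
    segregating = freq < 1.0
    is_trait = cls == TRAIT
    # trait mutations fixed in the sample are dropped outright
    keep_mask = segregating | ~is_trait
    ids, freq, cls = ids[keep_mask], freq[keep_mask], cls[keep_mask]
    is_trait = cls == TRAIT

    if max_mutations is not None and len(ids) > max_mutations:
        trait_ids = ids[is_trait]
        bg_ids = ids[~is_trait]
        if len(trait_ids) >= max_mutations:
            chosen = rng.choice(trait_ids, size=max_mutations, replace=False)
        else:
            fill = rng.choice(bg_ids, size=max_mutations - len(trait_ids),
                              replace=False)
            chosen = np.concatenate([trait_ids, fill])
        sel = np.isin(ids, chosen)
        ids, freq, cls = ids[sel], freq[sel], cls[sel]

    order = np.argsort(pop.table.position[ids], kind="stable") if len(ids) \
        else np.empty(0, dtype=np.int64)
    ids, freq, cls = ids[order], freq[order], cls[order]
    positions = pop.table.position[ids]
    col = {int(m): k for k, m in enumerate(ids)}
    M = np.zeros((nh, len(ids)), dtype=np.int8)
    for r, h in enumerate(haps):
        for m in h.ids:
            k = col.get(int(m))
            if k is not None:
                M[r, k] = 1
    ann = pd.DataFrame({
        "id": ids,
        "position": positions,
        "class": [  # noqa: C416
            {NEUTRAL: "neutral", TRAIT: "trait", DELETERIOUS: "deleterious"}[c]
            for c in cls],
        "mean_effect": pop.table.effects[ids].mean(axis=1) if len(ids)
        else np.empty(0),
        "sample_freq": M.mean(axis=0) if len(ids) else np.empty(0),
    })
    return HaplotypeSample(matrix=M, positions=positions, annotations=ann,
                           individuals=idx, generation=pop.generation)


def allele_trajectories(snapshots: dict[str, Population],
                        pre_label: str = "pre_shift") -> pd.DataFrame:
    """Frequency trajectories of trait mutations segregating just before the
    optimum shift, across all snapshots (whole population, not a sample).

    Mutations arising after the shift are excluded; a mutation absent from a
    later snapshot's haplotypes but present in its substitutions ledger has
    fixed and is reported at frequency 1.
    """
    if pre_label not in snapshots:
        raise KeyError(f"missing pre-shift snapshot {pre_label!r}")
    pre = snapshots[pre_label]
    counts = pre.mutation_counts()
    seg = np.nonzero(counts)[0]
    tids = seg[pre.table.mclass[seg] == TRAIT]
    out = {"id": tids, "position": pre.table.position[tids],
           "mean_effect": pre.table.effects[tids].mean(axis=1)}
    labels = [pre_label] + [k for k in snapshots if k != pre_label]
    for label in labels:
        snap = snapshots[label]
        c = snap.mutation_counts()
        freq = np.zeros(len(tids))
        for k, m in enumerate(tids):
            if m < len(c) and c[m] > 0:
                freq[k] = c[m] / (2.0 * snap.N)
            elif int(m) in set(snap.sub_ids):
                freq[k] = 1.0
        out[f"freq_{label}"] = freq
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# bootstrap


def bootstrap_ci(values, stat=np.mean, n_boot: int = 1000, alpha: float = 0.05,
                 rng: np.random.Generator | None = None) -> tuple[float, float, float]:
    """Percentile bootstrap confidence interval; returns (point, lo, hi)."""
    rng = rng or np.random.default_rng(0)
    values = np.asarray(values)
    point = float(stat(values))
    reps = np.empty(n_boot)
    n = len(values)
    for b in range(n_boot):
        reps[b] = stat(values[rng.integers(0, n, size=n)])
    lo, hi = np.quantile(reps, [alpha / 2, 1 - alpha / 2])
    return point, float(lo), float(hi)
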