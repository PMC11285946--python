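"""Wright–Fisher forward simulator with partial selfing and stabilising selection.

The simulated organism is diploid and hermaphroditic.  Its genome is a single
chromosome of alternating neutral buffer regions and genes; gene mutations are
neutral, unconditionally deleterious (partially recessive), or affect ``n``
pleiotropic quantitative traits under multivariate Gaussian stabilising
selection.  Reproduction is by partial self-fertilisation: each offspring
derives from a single fitness-sampled parent (two independent meioses) with
probability ``sigma``, otherwise from two independent fitness-sampled parents.
Population size is fixed (soft selection).

Default parameters are the study conditions: N = 5,000 diploids, a 25 Mb
genome of 4,000 bp buffers and 1,000 bp genes, per-nucleotide mutation rate
4e-8 and recombination rate 1.98e-7, gene mutations split 25% neutral /
65% deleterious / 10% trait, trait effects drawn with total standard
deviation 0.25 spread over the traits, Vs = 1, deleterious mutations with
|s| = 0.02 and h = 0.2, burn-in of 10N generations at optimum zero followed by
a shift to 1/sqrt(n) on every trait.  :meth:`SimulationConfig.desk_scale`
builds a proportionally reduced configuration preserving the trait mutation
input, for runs that complete on a single workstation core.

Haplotypes are sparse, immutable lists of mutation ids; fixed mutations are
swept into a substitutions ledger.  All randomness flows through one
``numpy.random.Generator``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "NEUTRAL",
    "TRAIT",
    "DELETERIOUS",
    "CLASS_NAMES",
    "SimulationConfig",
    "MutationTable",
    "Haplotype",
    "Population",
    "SimResult",
    "individual_fitness",
    "make_gamete",
    "next_generation",
    "optimum_at",
    "run",
]

NEUTRAL, TRAIT, DELETERIOUS = 0, 1, 2
CLASS_NAMES = {NEUTRAL: "neutral", TRAIT: "trait", DELETERIOUS: "deleterious"}

_EMPTY_I8 = np.empty(0, dtype=np.int64)
_MAX_I8 = np.iinfo(np.int64).max


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one forward simulation."""

    N: int = 5000
    L: int = 25_000_000
    buffer_len: int = 4000
    gene_len: int = 1000
    mu: float = 4e-8
    rec: float = 1.98e-7
    frac_neutral: float = 0.25
    frac_deleterious: float = 0.65
    frac_trait: float = 0.10
    selfing: float = 0.0
    n_traits: int = 1
    effect_sd: float = 0.25
    Vs: float = 1.0
    s_del: float = 0.02          # magnitude of the deleterious selection coefficient
    h_del: float = 0.2
    z0_schedule: str = "instant"  # "instant" | "gradual"
    gradual_gens: int = 100
    burn_in: int | None = None    # defaults to 10 N
    post_gens: int = 1001
    stats_interval_pre: int = 500
    stats_interval_post: int = 10
    sample_offsets: tuple[int, ...] = (40, 300, 1000)
    sweep_interval: int = 25      # generations between fixation sweeps
    resource_budget: float = 2e11  # guard on N * L

    def __post_init__(self):
        fr = self.frac_neutral + self.frac_deleterious + self.frac_trait
        if abs(fr - 1.0) > 1e-9:
            raise ValueError(f"gene mutation-class fractions must sum to 1, got {fr}")
        if not 0.0 <= self.selfing <= 1.0:
            raise ValueError(f"selfing fraction must be in [0, 1], got {self.selfing}")
        if self.z0_schedule not in ("instant", "gradual"):
            raise ValueError(f"unknown optimum schedule {self.z0_schedule!r}")
        if self.burn_in is None:
            object.__setattr__(self, "burn_in", 10 * self.N)
        if self.N * self.L > self.resource_budget:
            raise ValueError(
                f"N*L = {self.N * self.L:.3g} exceeds the resource budget "
                f"{self.resource_budget:.3g}; raise resource_budget explicitly "
                "for cluster-scale runs")

    @property
    def period(self) -> int:
        return self.buffer_len + self.gene_len

    @property
    def gene_fraction(self) -> float:
        return self.gene_len / self.period

    @property
    def U_trait(self) -> float:
        """Trait mutation rate per gamete (haploid genome)."""
        return self.L * self.gene_fraction * self.mu * self.frac_trait

    @property
    def U_total(self) -> float:
        """Total mutation rate per gamete."""
        return self.L * self.mu

    @property
    def shift_magnitude(self) -> float:
        """Post-shift optimum per trait, 1/sqrt(n); equalises the initial
        fitness drop across pleiotropy levels."""
        return 1.0 / np.sqrt(self.n_traits)

    @property
    def deleterious_active(self) -> bool:
        return self.s_del != 0.0 and self.frac_deleterious > 0.0

    def trait_mutation_input(self) -> dict[str, float]:
        """Expected new trait mutations per generation, reported under both
        the per-gamete (2N U_t) and per-diploid (N U_t) counting conventions."""
        return {"per_gamete_pool": 2 * self.N * self.U_trait,
                "per_diploid_pool": self.N * self.U_trait}

    @classmethod
    def desk_scale(cls, N: int = 200, L: int = 200_000, rate_scale: float = 1.0,
                   U_trait: float = 0.02, **overrides) -> "SimulationConfig":
        """Workstation-scale configuration preserving the study's mutation input.

        The genome keeps the 4 kb buffer / 1 kb gene layout; ``mu`` is chosen
        so the per-gamete trait mutation rate equals ``U_trait * rate_scale``
        and ``rec`` preserves the full-scale genome-wide map length, also
        multiplied by ``rate_scale`` (use ``rate_scale=0.1`` for the 10-fold
        reduced-rate validation runs).
        """
        base = cls()  # full-scale defaults for the reference map length
        frac_trait = overrides.get("frac_trait", base.frac_trait)
        if frac_trait <= 0:
            raise ValueError("desk_scale anchors mu on the trait mutation rate; "
                             "with frac_trait=0 set mu explicitly instead")
        gene_fraction = base.gene_fraction
        mu = U_trait * rate_scale / (L * gene_fraction * frac_trait)
        map_length = base.rec * base.L
        rec = map_length * rate_scale / L
        kwargs = dict(N=N, L=L, mu=mu, rec=rec)
        kwargs.update(overrides)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sample_offsets"] = list(self.sample_offsets)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "sample_offsets" in d:
            d["sample_offsets"] = tuple(d["sample_offsets"])
        return cls(**d)


class MutationTable:
    """Append-only store of every mutation that ever arose.

    Rows are never modified; haplotypes refer to rows by integer id, so
    snapshots taken at different generations can safely share one table.
    """

    def __init__(self, n_traits: int, capacity: int = 1024):
        self.n = 0
        self.position = np.zeros(capacity, dtype=np.int64)
        self.mclass = np.zeros(capacity, dtype=np.int8)
        self.origin = np.zeros(capacity, dtype=np.int64)
        self.effects = np.zeros((capacity, n_traits), dtype=np.float64)

    def _grow(self, need: int):
        cap = len(self.position)
        if self.n + need <= cap:
            return
        new_cap = max(2 * cap, self.n + need)
        self.position = np.resize(self.position, new_cap)
        self.mclass = np.resize(self.mclass, new_cap)
        self.origin = np.resize(self.origin, new_cap)
        eff = np.zeros((new_cap, self.effects.shape[1]))
        eff[: self.n] = self.effects[: self.n]
        self.effects = eff

    def append(self, position: int, mclass: int, effects: np.ndarray | None,
               origin: int) -> int:
        self._grow(1)
        i = self.n
        self.position[i] = position
        self.mclass[i] = mclass
        self.origin[i] = origin
        if effects is not None:
            self.effects[i] = effects
        self.n += 1
        return i


class Haplotype:
    """Immutable sparse haplotype: mutation ids sorted by genomic position."""

    __slots__ = ("ids", "pos", "trait", "del_ids")

    def __init__(self, ids: np.ndarray, pos: np.ndarray, trait: np.ndarray,
                 del_ids: np.ndarray | None):
        self.ids = ids
        self.pos = pos
        self.trait = trait
        self.del_ids = del_ids  # sorted mutation ids of deleterious sites, or None

    @classmethod
    def empty(cls, n_traits: int, track_del: bool) -> "Haplotype":
        return cls(_EMPTY_I8, _EMPTY_I8, np.zeros(n_traits),
                   _EMPTY_I8 if track_del else None)

    @classmethod
    def from_ids(cls, ids: np.ndarray, table: MutationTable,
                 track_del: bool, presorted_pos: np.ndarray | None = None
                 ) -> "Haplotype":
        """Build from mutation ids; ``presorted_pos`` skips the position sort
        when the caller already holds the ids in genomic order."""
        if presorted_pos is None:
            pos = table.position[ids]
            order = np.argsort(pos, kind="stable")
            ids, pos = ids[order], pos[order]
        else:
            pos = presorted_pos
        trait = table.effects[ids].sum(axis=0) if len(ids) else \
            np.zeros(table.effects.shape[1])
        del_ids = None
        if track_del:
            del_ids = np.sort(ids[table.mclass[ids] == DELETERIOUS])
        return cls(ids, pos, trait, del_ids)

    def __len__(self):
        return len(self.ids)


class Population:
    """N diploid individuals as 2N paired haplotypes plus a substitutions ledger.

    Individual ``i`` owns haplotypes ``2i`` and ``2i+1``.  Trait values include
    twice the summed effects of fixed substitutions.
    """

    def __init__(self, config: SimulationConfig, table: MutationTable | None = None):
        self.config = config
        self.table = table or MutationTable(config.n_traits)
        track = config.deleterious_active
        self.haplotypes: list[Haplotype] = [
            Haplotype.empty(config.n_traits, track) for _ in range(2 * config.N)]
        self.generation = 0
        self.sub_ids: list[int] = []
        self.sub_gens: list[int] = []
        self.sub_trait = np.zeros(config.n_traits)
        self.n_fixed_del = 0
        self.positions_in_use: set[int] = set()

    @property
    def N(self) -> int:
        return self.config.N

    def optimum(self) -> np.ndarray:
        return optimum_at(self.generation, self.config)

    def individual(self, i: int) -> tuple[Haplotype, Haplotype]:
        return self.haplotypes[2 * i], self.haplotypes[2 * i + 1]

    def trait_values(self) -> np.ndarray:
        """(N, n_traits) matrix of individual trait values."""
        z = np.empty((self.N, self.config.n_traits))
        base = 2.0 * self.sub_trait
        for i in range(self.N):
            z[i] = self.haplotypes[2 * i].trait + self.haplotypes[2 * i + 1].trait
        return z + base

    def fitnesses(self) -> np.ndarray:
        cfg = self.config
        z = self.trait_values()
        z0 = self.optimum()
        w = np.exp(-0.5 * ((z - z0) ** 2).sum(axis=1) / cfg.Vs)
        if cfg.deleterious_active:
            s, h = abs(cfg.s_del), cfg.h_del
            for i in range(self.N):
                h1, h2 = self.individual(i)
                nhom = _n_shared(h1.del_ids, h2.del_ids)
                nhet = len(h1.del_ids) + len(h2.del_ids) - 2 * nhom
                w[i] *= (1.0 - h * s) ** nhet * (1.0 - s) ** nhom
            w *= (1.0 - s) ** self.n_fixed_del
        return w

    def mutation_counts(self) -> np.ndarray:
        """Copy count of every table row across the 2N haplotypes."""
        counts = np.zeros(self.table.n, dtype=np.int64)
        for h in self.haplotypes:
            if len(h.ids):
                np.add.at(counts, h.ids, 1)
        return counts

    def segregating_ids(self) -> np.ndarray:
        counts = self.mutation_counts()
        return np.nonzero(counts)[0]

    def allele_frequencies(self, ids: np.ndarray | None = None) -> np.ndarray:
        counts = self.mutation_counts()
        if ids is None:
            ids = np.nonzero(counts)[0]
        return counts[ids] / (2.0 * self.N)

    def sweep_fixed(self):
        """Move mutations present on all 2N haplotypes to the substitutions
        ledger and refresh the set of occupied positions."""
        counts = self.mutation_counts()
        full = 2 * self.N
        fixed = np.nonzero(counts == full)[0]
        if len(fixed):
            for mid in fixed:
                self.sub_ids.append(int(mid))
                self.sub_gens.append(self.generation)
                self.sub_trait += self.table.effects[mid]
                if self.table.mclass[mid] == DELETERIOUS:
                    self.n_fixed_del += 1
            # every haplotype carries every fixed mutation exactly once
            fixed_delta = self.table.effects[fixed].sum(axis=0)
            for k, h in enumerate(self.haplotypes):
                keep = ~np.isin(h.ids, fixed)
                self.haplotypes[k] = Haplotype(
                    h.ids[keep], h.pos[keep], h.trait - fixed_delta,
                    None if h.del_ids is None
                    else h.del_ids[~np.isin(h.del_ids, fixed)])
        segregating = np.nonzero(counts)[0]
        self.positions_in_use = set(
            int(p) for p in self.table.position[segregating])
        self.positions_in_use.update(
            int(self.table.position[m]) for m in self.sub_ids)

    def copy(self) -> "Population":
        """Snapshot sharing the (append-only) mutation table."""
        new = Population.__new__(Population)
        new.config = self.config
        new.table = self.table
        new.haplotypes = list(self.haplotypes)
        new.generation = self.generation
        new.sub_ids = list(self.sub_ids)
        new.sub_gens = list(self.sub_gens)
        new.sub_trait = self.sub_trait.copy()
        new.n_fixed_del = self.n_fixed_del
        new.positions_in_use = set(self.positions_in_use)
        return new


def _n_shared(a: np.ndarray | None, b: np.ndarray | None) -> int:
    if a is None or b is None or len(a) == 0 or len(b) == 0:
        return 0
    return len(np.intersect1d(a, b, assume_unique=True))


def individual_fitness(hap1: Haplotype, hap2: Haplotype, optimum: np.ndarray,
                       config: SimulationConfig,
                       sub_trait: np.ndarray | None = None,
                       n_fixed_del: int = 0) -> float:
    """Fitness of one diploid: Gaussian trait component times the deleterious
    component ``(1-h|s|)^nhet (1-|s|)^nhom``."""
    z = hap1.trait + hap2.trait
    if sub_trait is not None:
        z = z + 2.0 * sub_trait
    w = float(np.exp(-0.5 * ((z - optimum) ** 2).sum() / config.Vs))
    if config.deleterious_active:
        s, h = abs(config.s_del), config.h_del
        nhom = _n_shared(hap1.del_ids, hap2.del_ids) + n_fixed_del
        nhet = ((0 if hap1.del_ids is None else len(hap1.del_ids))
                + (0 if hap2.del_ids is None else len(hap2.del_ids))
                - 2 * (nhom - n_fixed_del))
        w *= (1.0 - h * s) ** nhet * (1.0 - s) ** nhom
    return w


def _classify_position(pos: int, config: SimulationConfig) -> int:
    """Region lookup: buffers are neutral; gene mutations fall in a class."""
    return NEUTRAL if (pos % config.period) < config.buffer_len else -1


def _recombine(h1: Haplotype, h2: Haplotype, breakpoints: np.ndarray,
               start_first: bool) -> tuple[np.ndarray, np.ndarray]:
    """Merge two parental haplotypes along sorted breakpoints; returns the
    (ids, pos) arrays of the recombinant, sorted by position."""
    haps = (h1, h2)
    # cut indices of every breakpoint in both parents' position arrays
    cuts = (h1.pos.searchsorted(breakpoints), h2.pos.searchsorted(breakpoints))
    nb = len(breakpoints)
    ids_parts, pos_parts = [], []
    lo0, lo1 = 0, 0
    idx = 0 if start_first else 1
    for k in range(nb + 1):
        src = haps[idx]
        a = lo0 if idx == 0 else lo1
        b = cuts[idx][k] if k < nb else len(src.pos)
        if b > a:
            ids_parts.append(src.ids[a:b])
            pos_parts.append(src.pos[a:b])
        if k < nb:
            lo0, lo1 = cuts[0][k], cuts[1][k]
        idx = 1 - idx
    if not ids_parts:
        return _EMPTY_I8, _EMPTY_I8
    if len(ids_parts) == 1:
        return ids_parts[0], pos_parts[0]
    return np.concatenate(ids_parts), np.concatenate(pos_parts)


def make_gamete(h1: Haplotype, h2: Haplotype, pop: Population,
                rng: np.random.Generator, mutate: bool = True,
                n_x: int | None = None, n_mut: int | None = None) -> Haplotype:
    """One meiotic product of the parent (h1, h2), plus de novo mutation.

    Crossover count is Poisson with mean ``rec * (L - 1)``; breakpoints are
    uniform.  New mutations are Poisson with mean ``mu * L`` at uniform
    positions; a mutation landing on an already-mutated site is discarded
    (first-arrival stacking policy).  ``n_x`` / ``n_mut`` allow the caller to
    supply pre-drawn counts (batched per generation).
    """
    cfg = pop.config
    table = pop.table
    if n_x is None:
        n_x = rng.poisson(cfg.rec * (cfg.L - 1))
    if n_mut is None:
        n_mut = rng.poisson(cfg.mu * cfg.L) if mutate else 0
    elif not mutate:
        n_mut = 0

    base = None
    if n_x == 0:
        base = h1 if rng.random() < 0.5 else h2
        if n_mut == 0:
            return base  # immutable: safe to share
        ids, pos = base.ids, base.pos
    else:
        bps = np.sort(rng.integers(1, cfg.L, size=n_x))
        ids, pos = _recombine(h1, h2, bps, rng.random() < 0.5)
        if n_mut == 0:
            return Haplotype.from_ids(ids, table, cfg.deleterious_active,
                                      presorted_pos=pos)

    new_ids = []
    for _ in range(n_mut):
        p = int(rng.integers(0, cfg.L))
        if p in pop.positions_in_use:
            continue  # stacking: first-appearing mutation at a site wins
        if (p % cfg.period) < cfg.buffer_len:
            mclass = NEUTRAL
        else:
            mclass = int(rng.choice(
                3, p=[cfg.frac_neutral, cfg.frac_trait, cfg.frac_deleterious]))
            mclass = (NEUTRAL, TRAIT, DELETERIOUS)[mclass]
        effects = None
        if mclass == TRAIT:
            effects = rng.normal(
                0.0, cfg.effect_sd / np.sqrt(cfg.n_traits), cfg.n_traits)
        mid = table.append(p, mclass, effects, pop.generation)
        pop.positions_in_use.add(p)
        new_ids.append(mid)

    if not new_ids:
        if base is not None:
            return base  # all de novo mutations discarded by stacking
        return Haplotype.from_ids(ids, table, cfg.deleterious_active)
    all_ids = np.concatenate([ids, np.asarray(new_ids, dtype=np.int64)])
    return Haplotype.from_ids(all_ids, table, cfg.deleterious_active)


def next_generation(pop: Population, rng: np.random.Generator,
                    mutate: bool = True) -> None:
    """Advance the population by one generation in place.

    Parents are sampled proportionally to fitness (viability selection, soft
    selection).  With probability ``sigma`` both gametes come from one parent.
    """
    cfg = pop.config
    w = pop.fitnesses()
    total = w.sum()
    if total <= 0.0:
        raise RuntimeError("all fitnesses are zero: degenerate population")
    cum = np.cumsum(w)
    N = pop.N
    p1 = np.searchsorted(cum, rng.random(N) * total)
    p2 = np.searchsorted(cum, rng.random(N) * total)
    selfed = rng.random(N) < cfg.selfing
    p2[selfed] = p1[selfed]

    n_x = rng.poisson(cfg.rec * (cfg.L - 1), size=2 * N)
    n_mut = rng.poisson(cfg.mu * cfg.L, size=2 * N) if mutate else np.zeros(2 * N, int)
    new_haps: list[Haplotype] = []
    for i in range(N):
        a1, a2 = pop.individual(int(p1[i]))
        b1, b2 = pop.individual(int(p2[i]))
        new_haps.append(make_gamete(a1, a2, pop, rng, mutate,
                                    int(n_x[2 * i]), int(n_mut[2 * i])))
        new_haps.append(make_gamete(b1, b2, pop, rng, mutate,
                                    int(n_x[2 * i + 1]), int(n_mut[2 * i + 1])))
    pop.haplotypes = new_haps
    pop.generation += 1
    if pop.generation % cfg.sweep_interval == 0:
        pop.sweep_fixed()


def optimum_at(generation: int, config: SimulationConfig) -> np.ndarray:
    """Optimum vector at a generation: zero through the burn-in, then a shift
    to 1/sqrt(n) per trait, instantaneous or ramped linearly over
    ``gradual_gens`` equal increments."""
    n = config.n_traits
    target = config.shift_magnitude
    t = generation - config.burn_in
    if t <= 0:
        return np.zeros(n)
    if config.z0_schedule == "instant":
        return np.full(n, target)
    ramp = min(t, config.gradual_gens) / config.gradual_gens
    return np.full(n, target * ramp)


@dataclass
class SimResult:
    """Output of :func:`run`: the statistics stream, snapshot populations at
    the designated timepoints, and the final population."""

    config: SimulationConfig
    stats: pd.DataFrame
    snapshots: dict[str, Population]
    population: Population
    seed: int | None = None


def run(config: SimulationConfig, seed: int | np.random.Generator = 0,
        progress: bool = False, measure_id: bool = True) -> SimResult:
    """Execute burn-in plus post-shift phase, emitting statistics on the way.

    Statistics are recorded every ``stats_interval_pre`` generations before
    the optimum shift and every ``stats_interval_post`` after it; haplotype
    snapshots are stored just before the shift and at the configured offsets
    after it.
    """
    from . import stats as stats_mod  # local import; stats depends on this module

    rng = seed if isinstance(seed, np.random.Generator) else \
        np.random.default_rng(seed)
    pop = Population(config)
    total_gens = config.burn_in + config.post_gens
    snapshots: dict[str, Population] = {}
    rows = []

    def record(label=None):
        z0 = pop.optimum()
        report = stats_mod.variance_decomposition(pop)
        w = pop.fitnesses()
        row = {
            "generation": pop.generation,
            "phase": "pre" if pop.generation < config.burn_in else "post",
            "optimum": float(z0.mean()),
            "mean_trait": report.mean_trait,
            "mean_fitness": float(w.mean()),
            "var_fitness": float(w.var()),
            "VG": report.VG, "Vg": report.Vg, "VI": report.VI,
            "CLD": report.CLD,
            "n_segregating_trait": report.n_trait_sites,
        }
        if measure_id:
            row["inbreeding_depression"] = stats_mod.inbreeding_depression(
                pop, rng)
        rows.append(row)

    record()
    for gen in range(1, total_gens + 1):
        next_generation(pop, rng)
        t_post = pop.generation - config.burn_in
        if t_post == 0:
            snapshots["pre_shift"] = pop.copy()
        elif t_post in config.sample_offsets:
            snapshots[f"post_{t_post}"] = pop.copy()
        interval = (config.stats_interval_pre if t_post < 0
                    else config.stats_interval_post)
        if pop.generation % interval == 0 or gen == total_gens:
            record()
        if progress and gen % 500 == 0:
            print(f"generation {gen}/{total_gens}", flush=True)
    # ensure the pre-shift snapshot exists even if post_gens == 0
    if "pre_shift" not in snapshots and config.post_gens == 0:
        snapshots["pre_shift"] = pop.copy()
    return SimResult(config=config, stats=pd.DataFrame(rows),
                     snapshots=snapshots, population=pop,
                     seed=None if isinstance(seed, np.random.Generator) else seed)
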