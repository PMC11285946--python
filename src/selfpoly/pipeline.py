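"""Experiment orchestration: grids over study conditions, seeding, output layout.

An :class:`ExperimentGrid` expands a base configuration over factor axes
(selfing fraction, pleiotropy, deleterious background, optimum schedule) into
seeded replicate jobs; :func:`run_experiment` executes the jobs, writes
per-replicate statistics streams, snapshot VCFs and LD tables as TSV/VCF under
an output directory, and records a manifest.  Every replicate's seed derives
deterministically from the grid's top-level seed.

:func:`make_fixture` builds tiny deterministic populations with analytically
known variance decompositions, used throughout the test-suite.
"""

from __future__ import annotations

import dataclasses
import json
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import stats as stats_mod
from .simulate import (TRAIT, Haplotype, MutationTable, Population,
                       SimulationConfig, run)
from .vcfio import write_vcf

__all__ = ["ExperimentGrid", "run_experiment", "make_fixture", "spawn_seeds",
           "genic_variance_validation", "selfing_contrast_experiment"]


def spawn_seeds(top_seed: int, n: int) -> list[int]:
    """Derive n distinct child seeds (< 2**31) from one top-level seed."""
    ss = np.random.SeedSequence(top_seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


@dataclass
class ExperimentGrid:
    """Cartesian grid of configuration variants with seeded replicates."""

    base: SimulationConfig
    axes: dict[str, list] = field(default_factory=dict)
    replicates: int = 1
    seed: int = 0

    def jobs(self) -> list[tuple[str, SimulationConfig, int, int]]:
        """(name, config, replicate, seed) for every grid cell x replicate."""
        keys = sorted(self.axes)
        combos = [{}]
        for k in keys:
            combos = [dict(c, **{k: v}) for c in combos for v in self.axes[k]]
        jobs = []
        seeds = spawn_seeds(self.seed, len(combos) * self.replicates)
        i = 0
        for combo in combos:
            cfg = dataclasses.replace(self.base, **combo)
            name = "_".join(f"{k}={combo[k]}" for k in keys) or "base"
            for rep in range(self.replicates):
                jobs.append((name, cfg, rep, seeds[i]))
                i += 1
        return jobs


def run_experiment(grid: ExperimentGrid, outdir: str | Path,
                   write_snapshots: bool = True,
                   progress: bool = False) -> pd.DataFrame:
    """Run every job in the grid, writing outputs and a manifest.

    Per replicate: the statistics stream as TSV, snapshot haplotype samples as
    VCF, an LD table per snapshot as TSV, and the substitutions ledger.
    Failures of individual jobs are recorded in the manifest and the run
    continues.  Returns the manifest as a data frame (also written as JSON).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for name, cfg, rep, seed in grid.jobs():
        job_dir = outdir / name / f"rep{rep}"
        entry = {"name": name, "replicate": rep, "seed": seed,
                 "config": cfg.to_dict(), "status": "ok", "outputs": []}
        try:
            job_dir.mkdir(parents=True, exist_ok=True)
            result = run(cfg, seed=seed, progress=progress)
            stats_path = job_dir / "stats.tsv"
            result.stats.to_csv(stats_path, sep="\t", index=False)
            entry["outputs"].append(str(stats_path))
            rng = np.random.default_rng(seed + 1)
            if write_snapshots:
                for label, snap in result.snapshots.items():
                    sample = stats_mod.haplotype_sample(snap, rng)
                    vcf_path = write_vcf(sample, snap,
                                         job_dir / f"sample_{label}.vcf")
                    entry["outputs"].append(str(vcf_path))
                    tab = stats_mod.ld_matrix_from_population(snap, rng)
                    ld_path = job_dir / f"ld_{label}.tsv"
                    tab.pairs.to_csv(ld_path, sep="\t", index=False)
                    entry["outputs"].append(str(ld_path))
            pop = result.population
            subs = pd.DataFrame({
                "id": pop.sub_ids,
                "fixed_generation": pop.sub_gens,
                "position": [int(pop.table.position[m]) for m in pop.sub_ids],
                "class": [int(pop.table.mclass[m]) for m in pop.sub_ids],
                "mean_effect": [float(pop.table.effects[m].mean())
                                for m in pop.sub_ids],
            })
            subs_path = job_dir / "substitutions.tsv"
            subs.to_csv(subs_path, sep="\t", index=False)
            entry["outputs"].append(str(subs_path))
        except Exception:
            entry["status"] = "failed"
            entry["error"] = traceback.format_exc(limit=5)
        manifest.append(entry)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return pd.DataFrame([{k: e[k] for k in ("name", "replicate", "seed", "status")}
                         for e in manifest])


# ---------------------------------------------------------------------------
# deterministic fixtures with known variance decompositions


def _population_from_haplotype_ids(config: SimulationConfig,
                                   table: MutationTable,
                                   hap_ids: list[list[int]]) -> Population:
    pop = Population(config, table)
    track = config.deleterious_active
    pop.haplotypes = [
        Haplotype.from_ids(np.asarray(ids, dtype=np.int64), table, track)
        for ids in hap_ids]
    pop.positions_in_use = set(int(p) for p in table.position[: table.n])
    return pop


def make_fixture(kind: str, rng: np.random.Generator | None = None) -> Population:
    """Small deterministic populations for statistics tests.

    kinds
    -----
    ``hwe_single_locus``     one site, a=0.5, Hardy–Weinberg at p=1/2:
                             Vg=0.125, VI=0, CLD=0.
    ``inbred_single_locus``  one site, a=0.5, only homozygotes at p=1/2:
                             Vg=0.125, VI=0.125 (F=1), CLD=0.
    ``negative_ld_pair``     two sites with opposing effects a=+0.5/-0.5 in
                             complete coupling (haplotypes AB, ab only) at
                             Hardy-Weinberg pairings — the Bulmer
                             cancellation: VG=0, Vg=0.25, VI=0, CLD=-0.25.
    ``random_small``         8 individuals, 3 trait sites, random genotypes
                             from the supplied rng (golden-file checks).
    """
    cfg = SimulationConfig(N=4, L=50_000, mu=0.0, rec=0.0, burn_in=0,
                           post_gens=0, s_del=0.0)
    table = MutationTable(cfg.n_traits)

    if kind == "hwe_single_locus":
        m = table.append(4500, TRAIT, np.array([0.5]), 0)
        hap_ids = [[m], [m], [m], [], [], [m], [], []]  # AA, Aa, Aa, aa
        return _population_from_haplotype_ids(cfg, table, hap_ids)
    if kind == "inbred_single_locus":
        m = table.append(4500, TRAIT, np.array([0.5]), 0)
        hap_ids = [[m], [m], [m], [m], [], [], [], []]  # AA, AA, aa, aa
        return _population_from_haplotype_ids(cfg, table, hap_ids)
    if kind == "negative_ld_pair":
        mA = table.append(4200, TRAIT, np.array([0.5]), 0)
        mB = table.append(9200, TRAIT, np.array([-0.5]), 0)
        # opposing effects in complete coupling (only AB and ab haplotypes,
        # each haplotype value zero), individuals at Hardy-Weinberg pairings:
        # AB/AB, AB/ab, AB/ab, ab/ab -> VG = 0 while Vg = 0.25
        hap_ids = [[mA, mB], [mA, mB],
                   [mA, mB], [],
                   [mA, mB], [],
                   [], []]
        return _population_from_haplotype_ids(cfg, table, hap_ids)
    if kind == "random_small":
        rng = rng or np.random.default_rng(12345)
        cfg8 = SimulationConfig(N=8, L=50_000, mu=0.0, rec=0.0, burn_in=0,
                                post_gens=0, s_del=0.0)
        t8 = MutationTable(cfg8.n_traits)
        mids = [t8.append(4200 + 5000 * k, TRAIT,
                          np.array([rng.normal(0, 0.25)]), 0) for k in range(3)]
        hap_ids = [[m for m in mids if rng.random() < 0.4] for _ in range(16)]
        return _population_from_haplotype_ids(cfg8, t8, hap_ids)
    raise ValueError(f"unknown fixture kind {kind!r}")


# ---------------------------------------------------------------------------
# study-condition experiments (workstation scale)


def genic_variance_validation(seed: int = 1, n_replicates: int = 10,
                              N: int = 400, L: int = 200_000,
                              window: int = 1500) -> dict:
    """Equilibrium genic variance under 10-fold reduced rates vs 4 U_t V_s.

    Re-runs the simulator's sanity check: an outcrossing population with a
    single trait and no deleterious selection, mutation and recombination
    rates reduced 10-fold (trait mutation rate U_t = 0.002), burn-in of 10N
    generations with the optimum fixed at zero.  The genic variance is
    time-averaged over the last ``window`` generations of the burn-in and
    averaged over replicates; at mutation-selection balance in the
    house-of-cards regime the expectation is 4 U_t V_s = 0.008.
    """
    vals = []
    cfg = None
    for child in spawn_seeds(seed, n_replicates):
        cfg = SimulationConfig.desk_scale(
            N=N, L=L, rate_scale=0.1, selfing=0.0, s_del=0.0, n_traits=1,
            burn_in=10 * N, post_gens=0, stats_interval_pre=50)
        res = run(cfg, seed=child, measure_id=False)
        tail = res.stats[res.stats.generation >= cfg.burn_in - window]
        vals.append(float(tail["Vg"].mean()))
    expected = 4.0 * cfg.U_trait * cfg.Vs
    return {"replicate_vg": vals, "mean_vg": float(np.mean(vals)),
            "expected": expected, "U_trait": cfg.U_trait,
            "n_replicates": n_replicates, "N": N, "L": L}


def selfing_contrast_experiment(seed: int = 1, deleterious: bool = False,
                                selfing=(0.0, 0.999), n_replicates: int = 3,
                                N: int = 100, L: int = 100_000,
                                post_gens: int = 400,
                                equilibrated_after: int = 200) -> pd.DataFrame:
    """Post-shift contrasts between selfing fractions at workstation scale.

    For each selfing fraction, runs replicates of the optimum-shift
    experiment (single trait, full-strength trait mutation input U_t = 0.02)
    and summarises post-shift equilibrium behaviour — mean fitness,
    inbreeding depression and the LD covariance — time-averaged over the
    post-shift rows at least ``equilibrated_after`` generations past the
    shift.  ``deleterious`` switches the recessive deleterious background
    (|s| = 0.02, h = 0.2) on or off.
    """
    rows = []
    seeds = spawn_seeds(seed, len(selfing) * n_replicates)
    i = 0
    for sigma in selfing:
        for rep in range(n_replicates):
            cfg = SimulationConfig.desk_scale(
                N=N, L=L, selfing=sigma,
                s_del=0.02 if deleterious else 0.0, n_traits=1,
                burn_in=10 * N, post_gens=post_gens,
                stats_interval_pre=500, stats_interval_post=25)
            res = run(cfg, seed=seeds[i], measure_id=True)
            i += 1
            st = res.stats
            eq = st[st.generation >= cfg.burn_in + equilibrated_after]
            rows.append({
                "selfing": sigma, "replicate": rep,
                "deleterious": deleterious,
                "mean_fitness": float(eq["mean_fitness"].mean()),
                "inbreeding_depression":
                    float(eq["inbreeding_depression"].mean()),
                "CLD": float(eq["CLD"].mean()),
                "VG": float(eq["VG"].mean()),
                "Vg": float(eq["Vg"].mean()),
                "VI": float(eq["VI"].mean()),
            })
    return pd.DataFrame(rows)
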