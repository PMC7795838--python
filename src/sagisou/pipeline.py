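"""End-to-end synthetic-study orchestration.

Runs the full chain — simulate lips and genotypes, morphometric radar
profiles, per-population heterozygosity table, Nei-distance NJ tree with
bootstrap, admixture K-scan with Evanno's ΔK — writing every artifact plus
a machine-readable run manifest.  All randomness flows from one explicit
root seed; rerunning with the same configuration gives byte-identical data
files (the manifest also records wall-clock timings, which of course vary).
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .admixture import MCMCConfig, align_runs, evanno_delta_k, membership_table, run_k_scan
from .datasets import GenotypeDataset
from .disttree import BootstrapConfig, bootstrap_tree, nei_standard_distance, write_newick
from .formats import write_contours, write_genepop, write_landmarks, write_structure
from .morphometrics import measure_lip, normalize_profile, summarize_population
from .popgen import population_table
from .synthetic import (LipShapeParams, PopSimParams, generate_lip_contour,
                        simulate_genotypes)

log = logging.getLogger("sagisou")


@dataclass
class PipelineConfig:
    """Stage switches, seeds and thresholds for a full synthetic run."""

    outdir: str = "sagisou_run"
    seed: int = 0
    # morphometrics
    run_morphometrics: bool = True
    flowers_per_pop: int = 6
    prominence_threshold: float = 0.2
    # genotypes / popgen
    run_popgen: bool = True
    sim: PopSimParams = field(default_factory=PopSimParams)
    hwe_alpha: float = 0.05
    f_test_reps: int = 1999
    # tree
    run_tree: bool = True
    bootstrap_replicates: int = 100
    tree_unit: str = "individual"
    nei_cap: float | None = 10.0  # finite stand-in when units share no alleles
    # admixture
    run_admixture: bool = True
    k_min: int = 1
    k_max: int = 3
    runs_per_k: int = 2
    burn_in: int = 500
    mcmc_reps: int = 2000


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _simulate_lips(config: PipelineConfig, rng_seeds, populations) -> dict:
    annotations = {}
    seeds = iter(rng_seeds)
    for pop in populations:
        base = np.random.default_rng(next(seeds))
        for i in range(config.flowers_per_pop):
            params = LipShapeParams(
                body_length=float(base.uniform(8, 20)),
                body_width=float(base.uniform(2.5, 6)),
                wing_radius=float(base.uniform(10, 22)),
                wing_angular_extent=float(base.uniform(70, 130)),
                body_wing_angle=float(base.uniform(50, 110)),
                serration_count=int(base.integers(5, 45)),
                serration_amplitude=float(base.uniform(0.45, 0.9)),
                jitter_sd=0.02,
                seed=int(base.integers(0, 2**31 - 1)),
            )
            annotations[f"{pop}_flower{i + 1:02d}"] = generate_lip_contour(params)[0]
    return annotations


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the configured stages; returns the output directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(stream=sys.stderr, level=logging.INFO,
                        format="%(levelname)s %(name)s: %(message)s")

    root = np.random.SeedSequence(config.seed)
    seed_lips, seed_sim, seed_pt, seed_boot, seed_mcmc = root.spawn(5)
    manifest: dict = {
        "package": "sagisou",
        "version": __version__,
        "seed": config.seed,
        "config": {k: (asdict(v) if hasattr(v, "__dataclass_fields__") else v)
                   for k, v in asdict(config).items()},
        "stages": {},
        "outputs": {},
    }
    timings = manifest["stages"]

    sim_params = config.sim
    sim_params = PopSimParams(**{**asdict(sim_params),
                                 "seed": int(seed_sim.generate_state(1)[0] % 2**31)})
    dataset, truth = simulate_genotypes(sim_params)

    if config.run_morphometrics:
        t0 = time.perf_counter()
        annotations = _simulate_lips(
            config, seed_lips.spawn(len(dataset.populations)), dataset.populations)
        write_contours(annotations, outdir / "contours.csv")
        write_landmarks(annotations, outdir / "landmarks.csv")
        rows = []
        profiles_by_pop: dict[str, list] = {}
        for shape_id, ann in annotations.items():
            m = measure_lip(ann, config.prominence_threshold)
            prof = normalize_profile(m)
            pop = shape_id.rsplit("_flower", 1)[0]
            profiles_by_pop.setdefault(pop, []).append(prof)
            rows.append({"shape_id": shape_id, "population": pop,
                         **{k: getattr(m, k) for k in (
                             "area", "perimeter", "dissection_index",
                             "body_length", "body_width", "wing_length",
                             "angle", "serration_number")},
                         **{f"radar_{k}": v for k, v in prof.as_dict().items()}})
        pd.DataFrame(rows).to_csv(outdir / "measurements.csv", index=False)
        radar = pd.concat(
            {pop: summarize_population(p) for pop, p in profiles_by_pop.items()},
            names=["population"])
        radar.to_csv(outdir / "radar_summary.csv")
        timings["morphometrics"] = {"seconds": time.perf_counter() - t0,
                                    "flowers": len(annotations)}
        log.info("morphometrics: %d flowers", len(annotations))

    if config.run_popgen or config.run_tree or config.run_admixture:
        write_genepop(dataset, outdir / "genotypes.gen")
        write_structure(dataset, outdir / "genotypes.str")
        manifest["outputs"]["genotypes.gen"] = _sha256(outdir / "genotypes.gen")
        manifest["outputs"]["genotypes.str"] = _sha256(outdir / "genotypes.str")

    if config.run_popgen:
        t0 = time.perf_counter()
        table = population_table(dataset, reps=config.f_test_reps,
                                 seed=seed_pt, alpha=config.hwe_alpha)
        table.to_csv(outdir / "population_table.csv", index=False)
        timings["popgen"] = {"seconds": time.perf_counter() - t0,
                             "populations": len(table)}
        log.info("popgen: %d populations", len(table))

    if config.run_tree:
        t0 = time.perf_counter()
        dm = nei_standard_distance(dataset, unit=config.tree_unit, cap=config.nei_cap)
        dm.to_frame().to_csv(outdir / "nei_distances.csv")
        boot = BootstrapConfig(replicates=config.bootstrap_replicates,
                               seed=int(seed_boot.generate_state(1)[0] % 2**31))
        tree = bootstrap_tree(dataset, unit=config.tree_unit, config=boot,
                              cap=config.nei_cap)
        write_newick(tree, outdir / "nj_tree.nwk")
        timings["tree"] = {"seconds": time.perf_counter() - t0,
                           "units": len(dm.labels),
                           "replicates": config.bootstrap_replicates}
        log.info("tree: %d units, %d bootstrap replicates",
                 len(dm.labels), config.bootstrap_replicates)

    if config.run_admixture:
        t0 = time.perf_counter()
        mcmc = MCMCConfig(burn_in=config.burn_in, reps=config.mcmc_reps,
                          runs_per_k=config.runs_per_k,
                          seed=int(seed_mcmc.generate_state(1)[0] % 2**31))
        scan = run_k_scan(dataset, range(config.k_min, config.k_max + 1), mcmc)
        lnp = {k: [r.ln_prob_data for r in runs] for k, runs in scan.items()}
        if len(lnp) >= 3:
            ev = evanno_delta_k(lnp)
            ev.table.to_csv(outdir / "evanno.csv", index=False)
            best_k = ev.optimal_k or max(lnp, key=lambda k: np.mean(lnp[k]))
        else:
            best_k = max(lnp, key=lambda k: np.mean(lnp[k]))
        _, mean_q, _ = align_runs(scan[best_k])
        pd.DataFrame(mean_q, index=dataset.individuals,
                     columns=[f"cluster_{c + 1}" for c in range(best_k)]
                     ).to_csv(outdir / "q_matrix.csv")
        pop_of = {ind: dataset.populations[dataset.pop_index[i]]
                  for i, ind in enumerate(dataset.individuals)}
        membership_table(mean_q, dataset.individuals, pop_of,
                         list(dataset.populations)
                         ).to_csv(outdir / "membership.csv", index=False)
        timings["admixture"] = {"seconds": time.perf_counter() - t0,
                                "k_range": [config.k_min, config.k_max],
                                "optimal_k": int(best_k)}
        log.info("admixture: optimal K = %d", best_k)

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return outdir
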