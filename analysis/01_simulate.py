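"""Simulate the three-pair kinome study: library, truth, and 8 PRM runs.

Generates a shared transition library for 80 synthetic kinases, then for
each of three primary/metastatic cell-line pairs draws its own true fold
changes and simulates the labeling replicates (2 forward + 2 reverse for
pair A, 1 + 1 for pairs B and C) with default noise and 5% interference.
Chromatograms are large and go to the scratch data directory; the library
and ground-truth tables are written alongside them.

Run from the repository root:  python analysis/01_simulate.py
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

import silacprm as sp
from silacprm.pipeline import PAIR_DESIGNS

DEFAULT_DATA_DIR = Path("scratch/analysis/data")


def main(data_dir: Path = DEFAULT_DATA_DIR, seed: int = 1) -> None:
    data_dir.mkdir(parents=True, exist_ok=True)
    cfg = sp.SimulationConfig(n_proteins=80, seed=seed, interference_fraction=0.05)
    seeds = np.random.SeedSequence(seed).spawn(2)
    rng_lib, rng_pairs = (np.random.default_rng(s) for s in seeds)

    library = sp.generate_library(cfg, rng_lib)
    sp.write_library(library, data_dir / "library.tsv")
    print(f"library: {len(library)} peptides across {len(library.proteins)} kinases")

    manifest = []
    for pair_id, runs in PAIR_DESIGNS.items():
        truth = sp.generate_ground_truth(library, cfg, rng_pairs)
        truth.protein_frame().to_csv(
            data_dir / f"truth_{pair_id}_proteins.csv", index=False, float_format="%.6g"
        )
        truth.peptide_frame().to_csv(
            data_dir / f"truth_{pair_id}_peptides.csv", index=False, float_format="%.6g"
        )
        for design, rep in runs:
            run_id = f"{pair_id}_{design}{rep}"
            chroms = sp.simulate_experiment(
                library, truth, sp.ExperimentDesign(design), cfg, rng_pairs
            )
            sp.inject_interference(chroms, truth, cfg, rng_pairs)
            sp.write_chromatograms(chroms, data_dir / f"{run_id}_chromatograms.csv")
            manifest.append(
                {
                    "run_id": run_id,
                    "pair_id": pair_id,
                    "design": design,
                    "replicate_id": rep,
                    "quant_csv": f"{run_id}_quant.csv",
                }
            )
            print(f"  simulated {run_id}")
        print(
            f"pair {pair_id}: {len(runs)} runs, "
            f"{len(truth.corrupted)} peptides carry interference in at least one run"
        )
    pd.DataFrame(manifest).to_csv(data_dir / "manifest.csv", index=False)
    print(f"wrote chromatograms + manifest to {data_dir}")


if __name__ == "__main__":
    p = argparse.ArgumentParser()
    p.add_argument("--data-dir", type=Path, default=DEFAULT_DATA_DIR)
    p.add_argument("--seed", type=int, default=1)
    a = p.parse_args()
    main(a.data_dir, a.seed)
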