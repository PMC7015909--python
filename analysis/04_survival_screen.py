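"""Quartile logrank survival screen over the commonly quantified kinases.

Simulates patient expression and overall survival for the kinases in the
cross-pair matrix, planting a prognostic effect (hazard rate ratio 3 in the
top expression quartile) on the three kinases with the largest true fold
change in pair A, then screens every gene with the top-vs-bottom-quartile
logrank test at unadjusted p < 0.05.

Run from the repository root:  python analysis/04_survival_screen.py
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

import silacprm as sp

DEFAULT_DATA_DIR = Path("scratch/analysis/data")
DEFAULT_RESULTS = Path("results")


def main(
    data_dir: Path = DEFAULT_DATA_DIR, results: Path = DEFAULT_RESULTS, seed: int = 1
) -> None:
    results.mkdir(parents=True, exist_ok=True)
    matrix = pd.read_csv(results / "kinome_matrix.csv", index_col=0)
    truth = pd.read_csv(data_dir / "truth_pairA_proteins.csv").set_index("protein_id")
    genes = list(matrix.index)
    planted_genes = (
        truth.loc[genes, "true_log2_ratio"].abs().sort_values(ascending=False).index[:3]
    )
    planted = {g: 3.0 for g in planted_genes}
    rng = np.random.default_rng(seed + 1000)
    expr, surv = sp.simulate_survival_dataset(genes, 300, rng, planted=planted)
    expr.to_csv(data_dir / "expression.csv", float_format="%.6g")
    surv.to_csv(data_dir / "survival.csv", index=False, float_format="%.6g")
    screen = sp.screen_genes(expr, surv, alpha=0.05)
    screen.to_csv(results / "screen.csv", index=False, float_format="%.6g")
    sig = screen[screen.significant]
    print(f"screened {len(screen)} kinases in {expr.shape[1]} simulated patients")
    print(f"{len(sig)} significant at unadjusted logrank p < 0.05: {list(sig.gene)}")
    hits = set(planted) & set(sig.gene)
    print(f"planted prognostic kinases recovered: {len(hits)}/{len(planted)} {sorted(hits)}")


if __name__ == "__main__":
    p = argparse.ArgumentParser()
    p.add_argument("--data-dir", type=Path, default=DEFAULT_DATA_DIR)
    p.add_argument("--results", type=Path, default=DEFAULT_RESULTS)
    p.add_argument("--seed", type=int, default=1)
    a = p.parse_args()
    main(a.data_dir, a.results, a.seed)
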