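"""Label-swap reconciliation and protein-level fold changes per cell pair.

Orients the per-run heavy/light ratios onto log2(metastatic/primary), rolls
them up to proteins with RSDs and 1.5-fold calls, computes the QC metrics
(forward/reverse consistency, R^2, dynamic range), and assembles the
common-kinase matrix with per-class counts.  Also regresses the estimates on
the simulation's known truth to report recovery quality.

Run from the repository root:  python analysis/03_differential_expression.py
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

import silacprm as sp
from silacprm.pipeline import _jsonable, pair_qc

DEFAULT_DATA_DIR = Path("scratch/analysis/data")
DEFAULT_RESULTS = Path("results")


def main(data_dir: Path = DEFAULT_DATA_DIR, results: Path = DEFAULT_RESULTS) -> None:
    results.mkdir(parents=True, exist_ok=True)
    library = sp.read_library(data_dir / "library.tsv")
    class_map = {e.protein_id: e.kinase_class for e in library.entries}
    manifest = pd.read_csv(data_dir / "manifest.csv")
    qc, pair_tables = {"pairs": {}}, {}
    for pair_id, grp in manifest.groupby("pair_id", sort=True):
        records, tables = [], []
        for _, row in grp.iterrows():
            table = pd.read_csv(data_dir / row.quant_csv)
            tables.append(table)
            records.append(sp.orient_ratios(table, row.design, row.replicate_id))
        records = pd.concat(records, ignore_index=True)
        proteins = sp.aggregate_protein(records, cutoff=1.5, kinase_classes=class_map)
        proteins.to_csv(results / f"{pair_id}_proteins.csv", index=False, float_format="%.6g")
        pair_tables[pair_id] = proteins
        qc["pairs"][pair_id] = pair_qc(records, tables, proteins)

        truth = pd.read_csv(data_dir / f"truth_{pair_id}_proteins.csv").set_index("protein_id")
        merged = proteins.set_index("protein_id").join(truth)
        slope, _ = np.polyfit(merged.true_log2_ratio, merged.mean_log2, 1)
        r2 = np.corrcoef(merged.true_log2_ratio, merged.mean_log2)[0, 1] ** 2
        m = qc["pairs"][pair_id]
        print(
            f"{pair_id}: consistency {100 * m['consistency_fraction']:.1f}%, "
            f"fwd/rev R2 {m['forward_reverse_r2']:.3f}, "
            f"dynamic range {m['dynamic_range_orders']:.2f} orders, "
            f"truth recovery slope {slope:.3f} (R2 {r2:.3f})"
        )
    (results / "qc.json").write_text(json.dumps(_jsonable(qc), indent=2, sort_keys=True) + "\n")
    matrix, class_counts = sp.build_kinome_matrix(pair_tables)
    matrix.to_csv(results / "kinome_matrix.csv", float_format="%.6g")
    class_counts.to_csv(results / "class_counts.csv", index=False)
    up = {p: int((t["call"] == "up").sum()) for p, t in pair_tables.items()}
    down = {p: int((t["call"] == "down").sum()) for p, t in pair_tables.items()}
    print(f"kinases quantified in all pairs: {len(matrix.index)}")
    print(f"up-regulated calls per pair: {up}")
    print(f"down-regulated calls per pair: {down}")


if __name__ == "__main__":
    p = argparse.ArgumentParser()
    p.add_argument("--data-dir", type=Path, default=DEFAULT_DATA_DIR)
    p.add_argument("--results", type=Path, default=DEFAULT_RESULTS)
    a = p.parse_args()
    main(a.data_dir, a.results)
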