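"""Quantify every simulated run against the spectral library.

Reads the chromatograms written by 01_simulate.py, applies peak detection,
shared-bounds integration, the 0.7 dotp gate in both channels and the
co-elution check, and writes one peptide table per run next to the data plus
a small per-run summary under results/.

Run from the repository root:  python analysis/02_quantify.py
"""

import argparse
from pathlib import Path

import pandas as pd

import silacprm as sp

DEFAULT_DATA_DIR = Path("scratch/analysis/data")
DEFAULT_RESULTS = Path("results")


def main(data_dir: Path = DEFAULT_DATA_DIR, results: Path = DEFAULT_RESULTS) -> None:
    results.mkdir(parents=True, exist_ok=True)
    library = sp.read_library(data_dir / "library.tsv")
    manifest = pd.read_csv(data_dir / "manifest.csv")
    params = sp.QuantParams()  # dotp >= 0.7 both channels, 5 s co-elution tolerance
    summary = []
    for _, row in manifest.iterrows():
        chroms = sp.read_chromatograms(data_dir / f"{row.run_id}_chromatograms.csv")
        table = sp.quantify_run(chroms, library, params)
        table.to_csv(data_dir / row.quant_csv, index=False, float_format="%.6g")
        failed = table.loc[~table.passed_filters, "failure_reason"].value_counts().to_dict()
        summary.append(
            {
                "run_id": row.run_id,
                "n_peptides": len(table),
                "n_passed": int(table.passed_filters.sum()),
                "n_low_dotp": failed.get("low_dotp", 0),
                "n_no_coelution": failed.get("no_coelution", 0),
                "n_missing_channel": failed.get("missing_channel", 0),
            }
        )
        print(f"{row.run_id}: {summary[-1]['n_passed']}/{len(table)} peptides pass the gates")
    out = pd.DataFrame(summary)
    out.to_csv(results / "quant_summary.csv", index=False)
    frac = out.n_passed.sum() / out.n_peptides.sum()
    print(f"overall: {100 * frac:.1f}% of peptide measurements pass; see {results}/quant_summary.csv")


if __name__ == "__main__":
    p = argparse.ArgumentParser()
    p.add_argument("--data-dir", type=Path, default=DEFAULT_DATA_DIR)
    p.add_argument("--results", type=Path, default=DEFAULT_RESULTS)
    a = p.parse_args()
    main(a.data_dir, a.results)
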