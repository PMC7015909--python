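"""Label-swap reconciliation and protein-level differential expression.

Peptide heavy/light ratios from forward and reverse SILAC replicates are
oriented onto a common log2(metastatic/primary) scale, rolled up to protein
fold changes (mean of peptide log2 within a replicate, then mean across
replicates), scored for replicate precision (RSD of linear-scale replicate
ratios), and called up/down against a 1.5-fold cutoff.  QC statistics cover
forward/reverse trend consistency, forward/reverse R^2 and the measured
dynamic range; multi-pair results are assembled into a common-kinase matrix
with per-class counts.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

__all__ = [
    "orient_ratios",
    "consistency_fraction",
    "forward_reverse_r2",
    "aggregate_protein",
    "dynamic_range",
    "build_kinome_matrix",
    "PROTEIN_COLUMNS",
]

PROTEIN_COLUMNS = [
    "protein_id",
    "kinase_class",
    "mean_log2",
    "rsd_percent",
    "n_peptides",
    "n_replicates",
    "call",
]

RECORD_COLUMNS = [
    "peptide_sequence",
    "protein_id",
    "design",
    "replicate_id",
    "measured_ratio",
    "oriented_log2",
]


def orient_ratios(quant_table: pd.DataFrame, design: str, replicate_id) -> pd.DataFrame:
    """Convert one run's peptide table into oriented replicate ratio records.

    Only peptides that passed the quantification gates are kept.  The
    measured heavy/light ratio is mapped onto log2(metastatic/primary):
    ``log2(ratio)`` under forward labeling (heavy = metastatic) and
    ``-log2(ratio)`` under reverse labeling.
    """
    if design not in ("forward", "reverse"):
        raise ValueError(f"unknown design label {design!r}")
    passed = quant_table[quant_table["passed_filters"].astype(bool)].copy()
    passed = passed[np.isfinite(passed["ratio"]) & (passed["ratio"] > 0)]
    sign = 1.0 if design == "forward" else -1.0
    out = pd.DataFrame(
        {
            "peptide_sequence": passed["peptide_sequence"].to_numpy(),
            "protein_id": passed["protein_id"].to_numpy(),
            "design": design,
            "replicate_id": replicate_id,
            "measured_ratio": passed["ratio"].to_numpy(dtype=float),
            "oriented_log2": sign * np.log2(passed["ratio"].to_numpy(dtype=float)),
        }
    )
    return out[RECORD_COLUMNS]


def _peptide_means(records: pd.DataFrame) -> pd.Series:
    return records.groupby("peptide_sequence")["oriented_log2"].mean()


def consistency_fraction(forward_records: pd.DataFrame, reverse_records: pd.DataFrame) -> float:
    """Fraction of shared peptides with the same oriented-log2 sign in the
    forward and reverse experiments.

    Replicates within a design are averaged per peptide first.  An exact
    zero agrees with either sign.  Returns NaN when the designs share no
    peptide (undefined).
    """
    fwd = _peptide_means(forward_records)
    rev = _peptide_means(reverse_records)
    shared = fwd.index.intersection(rev.index)
    if len(shared) == 0:
        return math.nan
    sf = np.sign(fwd.loc[shared].to_numpy())
    sr = np.sign(rev.loc[shared].to_numpy())
    consistent = (sf == sr) | (sf == 0) | (sr == 0)
    return float(consistent.mean())


def forward_reverse_r2(forward_records: pd.DataFrame, reverse_records: pd.DataFrame) -> float:
    """Squared Pearson correlation of per-peptide oriented log2 ratios
    between the forward and reverse experiments (replicate-averaged).

    Returns NaN when fewer than 3 peptides are shared or either vector has
    zero variance.
    """
    fwd = _peptide_means(forward_records)
    rev = _peptide_means(reverse_records)
    shared = fwd.index.intersection(rev.index)
    if len(shared) < 3:
        return math.nan
    x = fwd.loc[shared].to_numpy()
    y = rev.loc[shared].to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        return math.nan
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def aggregate_protein(
    records: pd.DataFrame,
    cutoff: float = 1.5,
    kinase_classes: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Roll peptide records up to protein-level fold changes and calls.

    Within each replicate (design x replicate_id) the protein log2 ratio is
    the mean over its peptides; ``mean_log2`` averages those replicate
    values.  ``rsd_percent`` is the relative standard deviation (sample SD /
    mean x 100) of the linear-scale replicate protein ratios; it is NaN for
    a single replicate.  Calls: up when ``mean_log2 >= log2(cutoff)``, down
    when ``<= -log2(cutoff)``, otherwise unchanged.
    """
    if cutoff <= 1:
        raise ValueError(f"fold-change cutoff must exceed 1, got {cutoff}")
    log_cut = math.log2(cutoff)
    rows = []
    for protein_id, grp in records.groupby("protein_id", sort=True):
        rep_log2 = grp.groupby(["design", "replicate_id"])["oriented_log2"].mean()
        mean_log2 = float(rep_log2.mean())
        rep_linear = np.exp2(rep_log2.to_numpy())
        if len(rep_linear) > 1:
            rsd = float(100.0 * np.std(rep_linear, ddof=1) / np.mean(rep_linear))
        else:
            rsd = math.nan
        call = "up" if mean_log2 >= log_cut else ("down" if mean_log2 <= -log_cut else "unchanged")
        rows.append(
            {
                "protein_id": protein_id,
                "kinase_class": (kinase_classes or {}).get(protein_id, ""),
                "mean_log2": mean_log2,
                "rsd_percent": rsd,
                "n_peptides": grp["peptide_sequence"].nunique(),
                "n_replicates": len(rep_log2),
                "call": call,
            }
        )
    return pd.DataFrame(rows, columns=PROTEIN_COLUMNS)


def dynamic_range(summed_areas) -> float:
    """Span of peptide signals in orders of magnitude: log10(max/min)."""
    areas = np.asarray(summed_areas, dtype=float)
    if len(areas) == 0:
        raise ValueError("no areas provided")
    if np.any(~np.isfinite(areas)) or np.any(areas <= 0):
        raise ValueError("all areas must be positive and finite")
    return float(np.log10(areas.max() / areas.min()))


def build_kinome_matrix(
    pair_tables: dict[str, pd.DataFrame],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble the cross-pair fold-change matrix and per-class counts.

    The matrix holds ``mean_log2`` for the kinases quantified in *every*
    cell-line pair (rows = proteins, columns = pairs; no missing cells).
    ``class_counts`` tabulates, per pair, how many kinases of each class
    were quantified at all (before the intersection).
    """
    if not pair_tables:
        raise ValueError("at least one pair table is required")
    common = None
    for table in pair_tables.values():
        ids = set(table["protein_id"])
        common = ids if common is None else (common & ids)
    common = sorted(common)
    matrix = pd.DataFrame(index=pd.Index(common, name="protein_id"))
    counts = []
    for pair_id, table in pair_tables.items():
        indexed = table.set_index("protein_id")
        matrix[pair_id] = indexed.loc[common, "mean_log2"]
        by_class = table.groupby("kinase_class")["protein_id"].nunique()
        for kclass, n in by_class.items():
            counts.append({"pair_id": pair_id, "kinase_class": kclass, "n_quantified": int(n)})
    class_counts = pd.DataFrame(counts, columns=["pair_id", "kinase_class", "n_quantified"])
    return matrix, class_counts
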