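"""Quartile-stratified Kaplan-Meier / logrank survival screen.

For each gene, samples in the top and bottom quartiles of expression form
the high and low groups (the middle half is excluded), survival in the two
groups is compared with the standard two-group logrank test (chi-square, 1
df), and genes with unadjusted p < alpha are flagged — deliberately without
multiple-testing correction, mirroring how single-gene prognosis screens
such as OncoLnc report TCGA associations.

Kaplan-Meier estimation and the logrank test are delegated to lifelines.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

__all__ = [
    "quartile_groups",
    "km_curve",
    "km_median",
    "logrank_test",
    "screen_genes",
    "SCREEN_COLUMNS",
]

SCREEN_COLUMNS = [
    "gene",
    "n_high",
    "n_low",
    "logrank_statistic",
    "p_value",
    "direction",
    "significant",
    "note",
]


def quartile_groups(expression: pd.Series) -> tuple[list[str], list[str]]:
    """Split samples into top-quartile (high) and bottom-quartile (low) sets.

    ``ceil(n/4)`` samples per tail; ties are broken by sample id so the
    grouping is invariant under input permutation.  Raises when expression
    is constant (groups undefined) or fewer than 8 samples are provided.
    """
    if len(expression) < 8:
        raise ValueError(f"need >=8 samples for quartile groups, got {len(expression)}")
    values = expression.to_numpy(dtype=float)
    if np.all(values == values[0]):
        raise ValueError("expression is constant; quartile groups undefined")
    order = sorted(expression.index, key=lambda s: (expression[s], str(s)))
    k = math.ceil(len(order) / 4)
    return list(order[-k:]), list(order[:k])


def km_curve(times, events) -> pd.DataFrame:
    """Product-limit (Kaplan-Meier) survival estimate.

    Returns a step function as a frame with columns ``time`` and
    ``survival``, starting at S(0) = 1; the estimate drops only at event
    times and is flat across censoring times.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise ValueError("need at least one record")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(dtype=float), "survival": sf.iloc[:, 0].to_numpy()})


def km_median(times, events) -> float:
    """Median survival time (inf when the curve never reaches 0.5)."""
    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(times, dtype=float), np.asarray(events, dtype=int))
    return float(kmf.median_survival_time_)


def logrank_test(high: pd.DataFrame, low: pd.DataFrame) -> tuple[float, float, bool]:
    """Two-group logrank test on survival frames with ``time``/``event``.

    Returns ``(statistic, p_value, degenerate)``.  The statistic is the
    usual (sum O-E)^2 / sum V chi-square with 1 df.  When the hypergeometric
    variance is zero everywhere (no informative event time) the test is
    degenerate and reported as statistic 0, p = 1 with the flag set.
    """
    if len(high) == 0 or len(low) == 0:
        raise ValueError("both groups must be non-empty")
    if int(high["event"].sum() + low["event"].sum()) < 1:
        raise ValueError("need at least one observed event")
    res = _ll_logrank(
        high["time"].to_numpy(dtype=float),
        low["time"].to_numpy(dtype=float),
        event_observed_A=high["event"].to_numpy(dtype=int),
        event_observed_B=low["event"].to_numpy(dtype=int),
    )
    stat = float(res.test_statistic)
    p = float(res.p_value)
    if not (math.isfinite(stat) and math.isfinite(p)):
        return 0.0, 1.0, True
    return stat, min(max(p, np.nextafter(0.0, 1.0)), 1.0), False


def _direction(high: pd.DataFrame, low: pd.DataFrame) -> int:
    """Sign of (median survival high - median survival low); 0 on a tie or
    when both medians are unreached."""
    mh = km_median(high["time"], high["event"])
    ml = km_median(low["time"], low["event"])
    if math.isinf(mh) and math.isinf(ml):
        return 0
    if math.isinf(mh):
        return 1
    if math.isinf(ml):
        return -1
    return int(np.sign(mh - ml))


def screen_genes(
    expression: pd.DataFrame,
    survival: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Run the quartile logrank screen over every gene.

    ``expression`` is genes x samples; ``survival`` has columns
    ``sample_id``, ``time`` (days, > 0) and ``event`` (1 = death observed).
    Sample ids must align.  Genes whose quartile groups are undefined
    (constant expression) are reported with empty statistics and excluded
    from the significant set.  Results are sorted by p-value.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    surv = survival.set_index("sample_id")
    if bad := set(expression.columns) - set(surv.index):
        raise ValueError(f"samples missing from the survival table: {sorted(bad)[:5]}")
    if (surv["time"] <= 0).any():
        raise ValueError("survival times must be positive")
    if not surv["event"].isin((0, 1)).all():
        raise ValueError("event indicators must be 0 or 1")
    rows = []
    for gene in expression.index:
        try:
            high_ids, low_ids = quartile_groups(expression.loc[gene])
        except ValueError as exc:
            rows.append(
                {
                    "gene": gene,
                    "n_high": 0,
                    "n_low": 0,
                    "logrank_statistic": math.nan,
                    "p_value": math.nan,
                    "direction": 0,
                    "significant": False,
                    "note": str(exc),
                }
            )
            continue
        high = surv.loc[high_ids, ["time", "event"]]
        low = surv.loc[low_ids, ["time", "event"]]
        stat, p, degenerate = logrank_test(high, low)
        rows.append(
            {
                "gene": gene,
                "n_high": len(high_ids),
                "n_low": len(low_ids),
                "logrank_statistic": stat,
                "p_value": p,
                "direction": _direction(high, low),
                "significant": bool(p < alpha) and not degenerate,
                "note": "degenerate" if degenerate else "",
            }
        )
    out = pd.DataFrame(rows, columns=SCREEN_COLUMNS)
    return out.sort_values("p_value", na_position="last", kind="stable").reset_index(drop=True)
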