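"""PRM quantification core: peak detection, XIC integration, dotp, ratios.

This module replaces the interactive chromatogram review of a targeted
proteomics workflow with automated gates: each peptide's light and heavy
transition traces are integrated over a shared peak window, the observed
per-transition area distribution is scored against the spectral-library
reference intensities (dotp, a cosine similarity, gated at 0.7), transition
apexes must co-elute within a retention-time tolerance, and the heavy/light
ratio is the quotient of summed transition areas — no other adjustments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chromatograms import ChromatogramSet
from .spectral_library import LibraryEntry, SpectralLibrary

__all__ = [
    "PeakBounds",
    "PeptideQuant",
    "QuantParams",
    "MissingChannelError",
    "detect_peak",
    "integrate_transition",
    "compute_dotp",
    "check_coelution",
    "quantify_peptide",
    "quantify_run",
    "QUANT_COLUMNS",
]

QUANT_COLUMNS = [
    "peptide_sequence",
    "protein_id",
    "area_light",
    "area_heavy",
    "dotp_light",
    "dotp_heavy",
    "apex_rt",
    "ratio",
    "passed_filters",
    "failure_reason",
]

GAUSSIAN_FWHM_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


class MissingChannelError(ValueError):
    """A channel carries no signal, so no peak can be detected."""


@dataclass(frozen=True)
class PeakBounds:
    apex_rt: float
    left_rt: float
    right_rt: float

    def __post_init__(self) -> None:
        if not self.left_rt < self.apex_rt < self.right_rt:
            raise ValueError(
                f"peak bounds must satisfy left < apex < right, got "
                f"({self.left_rt}, {self.apex_rt}, {self.right_rt})"
            )


@dataclass(frozen=True)
class QuantParams:
    """Gate settings for peptide quantification."""

    dotp_min: float = 0.7
    rt_tolerance: float = 5.0  # seconds; one peak sigma under default simulation
    rel_height: float = 0.05  # peak boundary at this fraction of apex height
    sigma_cap: float = 4.0  # cap boundaries at apex +/- this many estimated sigmas

    def __post_init__(self) -> None:
        if not 0.0 <= self.dotp_min <= 1.0:
            raise ValueError(f"dotp_min must be in [0, 1], got {self.dotp_min}")
        if self.rt_tolerance < 0:
            raise ValueError("rt_tolerance must be >=0")
        if not 0.0 < self.rel_height < 1.0:
            raise ValueError("rel_height must be in (0, 1)")
        if self.sigma_cap <= 0:
            raise ValueError("sigma_cap must be positive")


@dataclass
class PeptideQuant:
    """Quantification result for one peptide in one run."""

    peptide_sequence: str
    protein_id: str
    areas: dict[str, dict[str, float]] = field(default_factory=dict)  # channel -> frag -> area
    summed_area: dict[str, float] = field(default_factory=dict)
    dotp: dict[str, float] = field(default_factory=dict)
    apex_rt: float = math.nan
    transition_apex_rt: dict[str, dict[str, float]] = field(default_factory=dict)
    ratio: float = math.nan  # heavy / light
    passed_filters: bool = False
    failure_reason: str = "none"

    def as_row(self) -> dict:
        return {
            "peptide_sequence": self.peptide_sequence,
            "protein_id": self.protein_id,
            "area_light": self.summed_area.get("light", math.nan),
            "area_heavy": self.summed_area.get("heavy", math.nan),
            "dotp_light": self.dotp.get("light", math.nan),
            "dotp_heavy": self.dotp.get("heavy", math.nan),
            "apex_rt": self.apex_rt,
            "ratio": self.ratio,
            "passed_filters": self.passed_filters,
            "failure_reason": self.failure_reason,
        }


def _estimate_sigma(times: np.ndarray, y: np.ndarray, apex_idx: int) -> float:
    """Peak width from interpolated half-maximum crossings (sigma = FWHM/2.355)."""
    half = 0.5 * y[apex_idx]
    left_t = times[0]
    for i in range(apex_idx - 1, -1, -1):
        if y[i] <= half:
            frac = (half - y[i]) / (y[i + 1] - y[i])
            left_t = times[i] + frac * (times[i + 1] - times[i])
            break
    right_t = times[-1]
    for i in range(apex_idx + 1, len(y)):
        if y[i] <= half:
            frac = (y[i - 1] - half) / (y[i - 1] - y[i])
            right_t = times[i - 1] + frac * (times[i] - times[i - 1])
            break
    fwhm = right_t - left_t
    if fwhm <= 0:
        fwhm = float(np.median(np.diff(times)))
    return fwhm / GAUSSIAN_FWHM_SIGMA


def detect_peak(
    times: np.ndarray,
    summed_intensity: np.ndarray,
    rel_height: float = 0.05,
    sigma_cap: float = 4.0,
) -> PeakBounds:
    """Locate the dominant peak of a summed-across-transitions trace.

    The apex is the global maximum.  Walking outward from the apex, each
    boundary is the first sample that falls to ``rel_height`` of the apex
    height or a local minimum, whichever comes first, and is capped at
    ``sigma_cap`` estimated peak widths from the apex.
    """
    times = np.asarray(times, dtype=float)
    y = np.asarray(summed_intensity, dtype=float)
    if len(times) < 5:
        raise ValueError("need at least 5 time points for peak detection")
    apex_idx = int(np.argmax(y))
    apex_height = y[apex_idx]
    if apex_height <= 0:
        raise MissingChannelError("trace carries no signal")
    threshold = rel_height * apex_height
    dt = float(np.median(np.diff(times)))

    left_idx = 0
    for i in range(apex_idx - 1, -1, -1):
        if y[i] <= threshold or (i > 0 and y[i - 1] > y[i]):
            left_idx = i
            break
    right_idx = len(y) - 1
    for i in range(apex_idx + 1, len(y)):
        if y[i] <= threshold or (i < len(y) - 1 and y[i + 1] > y[i]):
            right_idx = i
            break

    apex_rt = float(times[apex_idx])
    sigma = _estimate_sigma(times, y, apex_idx)
    cap = sigma_cap * sigma
    left_rt = max(float(times[left_idx]), apex_rt - cap)
    right_rt = min(float(times[right_idx]), apex_rt + cap)
    # degenerate edges: keep at least one sampling interval on each side
    if left_rt >= apex_rt:
        left_rt = apex_rt - dt
    if right_rt <= apex_rt:
        right_rt = apex_rt + dt
    return PeakBounds(apex_rt=apex_rt, left_rt=left_rt, right_rt=right_rt)


def integrate_transition(times: np.ndarray, intensity: np.ndarray, bounds: PeakBounds) -> float:
    """Trapezoidal area of one trace between the peak bounds (intensity x s).

    Boundary intensities are linearly interpolated so the integral covers
    exactly ``[left_rt, right_rt]``; an empty window integrates to zero.
    """
    times = np.asarray(times, dtype=float)
    y = np.asarray(intensity, dtype=float)
    lo = max(bounds.left_rt, float(times[0]))
    hi = min(bounds.right_rt, float(times[-1]))
    if hi <= lo:
        return 0.0
    inner = (times > lo) & (times < hi)
    t_win = np.concatenate(([lo], times[inner], [hi]))
    y_win = np.concatenate(([np.interp(lo, times, y)], y[inner], [np.interp(hi, times, y)]))
    return float(max(np.trapezoid(y_win, t_win), 0.0))


def compute_dotp(observed: np.ndarray, library_intensities: np.ndarray) -> float:
    """Cosine similarity between observed transition areas and the library
    reference intensities (both unit-normalized); 1 for proportional vectors,
    0 when the observed vector is all zero."""
    a = np.asarray(observed, dtype=float)
    b = np.asarray(library_intensities, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("observed and library vectors must be 1-D, equal length >= 2")
    nb = np.linalg.norm(b)
    if nb == 0:
        raise ValueError("library intensity vector is all zero")
    na = np.linalg.norm(a)
    if na == 0:
        return 0.0
    return float(np.clip(np.dot(a, b) / (na * nb), 0.0, 1.0))


def check_coelution(apex_rts: list[float] | np.ndarray, tolerance: float) -> bool:
    """True when the largest pairwise apex RT difference is within tolerance
    (inclusive at the boundary)."""
    rts = np.asarray(apex_rts, dtype=float)
    if len(rts) < 2:
        raise ValueError("co-elution needs at least 2 transition apexes")
    return bool(rts.max() - rts.min() <= tolerance)


def _window_centroid(times: np.ndarray, y: np.ndarray, bounds: PeakBounds) -> float:
    """Intensity-weighted apex estimate of one transition inside the shared
    window; the window minimum is subtracted so a flat background does not
    pull the centroid toward the window center."""
    mask = (times >= bounds.left_rt) & (times <= bounds.right_rt)
    if not np.any(mask):
        return bounds.apex_rt
    t = times[mask]
    w = y[mask] - y[mask].min()
    total = w.sum()
    if total <= 0:
        return bounds.apex_rt
    return float(np.sum(t * w) / total)


def quantify_peptide(
    chromatogram: ChromatogramSet,
    entry: LibraryEntry,
    params: QuantParams = QuantParams(),
) -> PeptideQuant:
    """Quantify one peptide from its light/heavy transition chromatograms.

    Integration bounds come from the channel with the larger summed apex and
    are applied to both channels, so light and heavy areas always cover the
    same RT window.  Gates: dotp >= ``dotp_min`` in both channels, and all
    per-transition apexes (both channels) co-eluting within
    ``rt_tolerance``.  The ratio is heavy/light summed area.
    """
    result = PeptideQuant(
        peptide_sequence=entry.peptide_sequence, protein_id=entry.protein_id
    )
    frags = entry.transition_labels()
    lib_vec = np.array([t.library_relative_intensity for t in entry.transitions])
    times = chromatogram.times

    for channel in ("light", "heavy"):
        if channel not in chromatogram.traces or any(
            f not in chromatogram.traces[channel] for f in frags
        ):
            result.failure_reason = "missing_channel"
            return result

    summed = {ch: chromatogram.summed(ch) for ch in ("light", "heavy")}
    try:
        peaks = {
            ch: detect_peak(times, summed[ch], params.rel_height, params.sigma_cap)
            for ch in ("light", "heavy")
        }
    except MissingChannelError:
        result.failure_reason = "missing_channel"
        return result

    anchor = max(("light", "heavy"), key=lambda ch: summed[ch].max())
    bounds = peaks[anchor]
    result.apex_rt = bounds.apex_rt

    apexes: list[float] = []
    for channel in ("light", "heavy"):
        areas = {
            f: integrate_transition(times, chromatogram.traces[channel][f], bounds) for f in frags
        }
        result.areas[channel] = areas
        result.summed_area[channel] = sum(areas.values())
        result.dotp[channel] = compute_dotp(np.array([areas[f] for f in frags]), lib_vec)
        result.transition_apex_rt[channel] = {
            f: _window_centroid(times, chromatogram.traces[channel][f], bounds) for f in frags
        }
        apexes.extend(result.transition_apex_rt[channel].values())

    if result.summed_area["light"] <= 0 or result.summed_area["heavy"] <= 0:
        result.failure_reason = "missing_channel"
        return result
    result.ratio = result.summed_area["heavy"] / result.summed_area["light"]

    dotp_ok = all(result.dotp[ch] >= params.dotp_min for ch in ("light", "heavy"))
    coelute = check_coelution(apexes, params.rt_tolerance)
    if not dotp_ok:
        result.failure_reason = "low_dotp"
    elif not coelute:
        result.failure_reason = "no_coelution"
    else:
        result.passed_filters = True
        result.failure_reason = "none"
    return result


def quantify_run(
    chromatograms: dict[str, ChromatogramSet],
    library: SpectralLibrary,
    params: QuantParams = QuantParams(),
) -> pd.DataFrame:
    """Quantify every library peptide present in a run.

    Returns the per-run peptide table (one row per peptide) with areas, dotp
    scores, heavy/light ratio and filter outcome.
    """
    rows = []
    for entry in library.entries:
        cs = chromatograms.get(entry.peptide_sequence)
        if cs is None:
            continue
        rows.append(quantify_peptide(cs, entry, params).as_row())
    return pd.DataFrame(rows, columns=QUANT_COLUMNS)
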