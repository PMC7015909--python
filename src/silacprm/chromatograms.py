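"""Transition chromatograms: in-memory container and long-form CSV I/O.

A :class:`ChromatogramSet` holds, for one peptide, the extracted-ion
chromatogram of every transition in both SILAC channels on a shared
retention-time grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ChromatogramSet", "write_chromatograms", "read_chromatograms", "CHROMATOGRAM_COLUMNS"]

CHROMATOGRAM_COLUMNS = ["peptide_sequence", "channel", "fragment", "rt_sec", "intensity"]


@dataclass
class ChromatogramSet:
    """Per-channel, per-transition intensity traces for one peptide.

    ``traces[channel][fragment_label]`` is an intensity array aligned with
    ``times``; both channels share the grid (co-acquired in one PRM run).
    """

    peptide_sequence: str
    times: np.ndarray
    traces: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1 or len(self.times) < 2:
            raise ValueError(f"{self.peptide_sequence}: need a 1-D time grid with >=2 points")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError(f"{self.peptide_sequence}: retention times must be strictly increasing")
        for channel, by_frag in self.traces.items():
            for frag, y in by_frag.items():
                y = np.asarray(y, dtype=float)
                if y.shape != self.times.shape:
                    raise ValueError(
                        f"{self.peptide_sequence} {channel} {frag}: trace length "
                        f"{y.shape} does not match time grid {self.times.shape}"
                    )
                if np.any(y < 0):
                    raise ValueError(f"{self.peptide_sequence} {channel} {frag}: negative intensity")
                by_frag[frag] = y

    @property
    def channels(self) -> list[str]:
        return list(self.traces)

    def fragments(self, channel: str) -> list[str]:
        return list(self.traces[channel])

    def summed(self, channel: str) -> np.ndarray:
        """Across-transition summed trace for one channel."""
        by_frag = self.traces[channel]
        return np.sum([by_frag[f] for f in by_frag], axis=0)


def write_chromatograms(chromatograms: dict[str, ChromatogramSet], path) -> None:
    """Write a collection of chromatogram sets as long-form CSV."""
    frames = []
    for seq in chromatograms:
        cs = chromatograms[seq]
        for channel in cs.channels:
            for frag in cs.fragments(channel):
                frames.append(
                    pd.DataFrame(
                        {
                            "peptide_sequence": seq,
                            "channel": channel,
                            "fragment": frag,
                            "rt_sec": cs.times,
                            "intensity": cs.traces[channel][frag],
                        }
                    )
                )
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=CHROMATOGRAM_COLUMNS)
    out.to_csv(path, index=False, float_format="%.6g")


def read_chromatograms(path) -> dict[str, ChromatogramSet]:
    """Read long-form chromatogram CSV into per-peptide ChromatogramSets."""
    df = pd.read_csv(path, dtype={"peptide_sequence": str, "channel": str, "fragment": str})
    missing = [c for c in CHROMATOGRAM_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    out: dict[str, ChromatogramSet] = {}
    for seq, pep_grp in df.groupby("peptide_sequence", sort=False):
        times = None
        traces: dict[str, dict[str, np.ndarray]] = {}
        for (channel, frag), grp in pep_grp.groupby(["channel", "fragment"], sort=False):
            grp = grp.sort_values("rt_sec")
            t = grp["rt_sec"].to_numpy(dtype=float)
            if times is None:
                times = t
            elif len(t) != len(times) or not np.allclose(t, times):
                raise ValueError(f"{path}: {seq} {channel} {frag}: trace not on the shared time grid")
            traces.setdefault(channel, {})[frag] = grp["intensity"].to_numpy(dtype=float)
        out[str(seq)] = ChromatogramSet(peptide_sequence=str(seq), times=times, traces=traces)
    return out
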