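"""Synthetic SILAC-PRM experiment generator with known ground truth.

Emulates the structure of a targeted kinome run: a transition library of
tryptic peptides, and per-run transition chromatograms in which light and
heavy channels co-elute as Gaussian peaks whose amplitude ratio realizes a
known metastatic/primary fold change under a forward or reverse labeling
scheme.  Peptide abundances span a configurable number of orders of
magnitude (4 by default).  Optional interference adds large retention-shifted
peaks on a subset of transitions, the failure mode the dotp and co-elution
gates exist to reject.

Every random draw flows from a single :class:`numpy.random.Generator`, so a
fixed seed reproduces an experiment bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .chromatograms import ChromatogramSet
from .spectral_library import (
    KINASE_CLASSES,
    LibraryEntry,
    SpectralLibrary,
    Transition,
)

__all__ = [
    "SimulationConfig",
    "ExperimentDesign",
    "FORWARD",
    "REVERSE",
    "PeptideTruth",
    "GroundTruth",
    "generate_library",
    "generate_ground_truth",
    "simulate_experiment",
    "inject_interference",
    "simulate_survival_dataset",
]

# Sampling weights over kinase classes, shaped after a typical kinome panel
# (protein kinases dominate; lipid/nucleotide/carbohydrate/other are minor).
_CLASS_WEIGHTS = (0.79, 0.045, 0.09, 0.05, 0.025)

_BODY_RESIDUES = np.array(list("ACDEFGHILMNPQSTVWY"))  # K/R reserved for cleavage sites


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic kinome experiment.

    Defaults describe a clean, well-behaved PRM run: 5 s Gaussian peaks
    sampled every 2 s (>10 points per peak), peptide abundances log-uniform
    over 4 orders of magnitude, true protein log2 fold changes ~ N(0, 1) so
    roughly half the proteins exceed a 1.5-fold change, and two noise terms —
    a per-point multiplicative log-normal and a per-channel log-normal
    amplitude factor that models run-to-run quantification variability.
    """

    n_proteins: int = 80
    peptides_per_protein: tuple[int, int] = (1, 4)
    transitions_per_peptide: tuple[int, int] = (4, 6)
    rt_range: tuple[float, float] = (300.0, 2700.0)  # seconds
    peak_sigma: float = 5.0  # seconds
    cycle_time: float = 2.0  # seconds between PRM cycles
    abundance_log10_range: float = 4.0
    abundance_log10_min: float = 3.0
    true_log2_ratio_loc: float = 0.0
    true_log2_ratio_scale: float = 1.0
    noise_relative_sd: float = 0.10  # per-sample multiplicative noise
    channel_noise_sd: float = 0.07  # per peptide-channel-run amplitude noise (ln scale)
    baseline_level: float = 2.0  # flat background intensity
    interference_fraction: float = 0.0
    interference_amplitude_factor: float = 5.0  # x the channel's summed apex
    interference_offset_sigmas: tuple[float, float] = (3.0, 5.0)
    window_sigmas: float = 8.0  # half-width of the simulated RT window
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >=1")
        lo, hi = self.peptides_per_protein
        if not 1 <= lo <= hi <= 4:
            raise ValueError("peptides_per_protein must be within 1-4")
        lo, hi = self.transitions_per_peptide
        if not 4 <= lo <= hi <= 6:
            raise ValueError("transitions_per_peptide must be within 4-6")
        if self.rt_range[0] >= self.rt_range[1] or self.rt_range[0] < 0:
            raise ValueError("rt_range must be an increasing pair of non-negative seconds")
        for name in ("peak_sigma", "cycle_time", "abundance_log10_range"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.interference_fraction <= 1.0:
            raise ValueError("interference_fraction must be in [0, 1]")
        for name in ("noise_relative_sd", "channel_noise_sd", "baseline_level"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >=0")
        if self.interference_offset_sigmas[0] < 3.0:
            raise ValueError("interference offset must be at least 3 peak sigmas")

    def noiseless(self) -> "SimulationConfig":
        """Copy with every stochastic perturbation switched off."""
        return replace(self, noise_relative_sd=0.0, channel_noise_sd=0.0, baseline_level=0.0)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class ExperimentDesign:
    """Which cell state carries the heavy label.

    Forward labeling puts the heavy isotopologues on the metastatic line,
    reverse labeling on the primary line; the realized heavy/light ratios of
    the two schemes are reciprocal for the same underlying fold change.
    """

    label_scheme: str  # "forward" | "reverse"

    def __post_init__(self) -> None:
        if self.label_scheme not in ("forward", "reverse"):
            raise ValueError(f"unknown label scheme {self.label_scheme!r}")

    @property
    def channel_state(self) -> dict[str, str]:
        if self.label_scheme == "forward":
            return {"heavy": "metastatic", "light": "primary"}
        return {"heavy": "primary", "light": "metastatic"}


FORWARD = ExperimentDesign("forward")
REVERSE = ExperimentDesign("reverse")


@dataclass
class PeptideTruth:
    peptide_sequence: str
    protein_id: str
    abundance: float  # peak amplitude of the unit-ratio channel, a.u.
    apex_rt: float  # seconds
    fractions: dict[str, float]  # fragment label -> true fractional intensity


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline is asked to recover."""

    protein_log2: dict[str, float]
    peptides: dict[str, PeptideTruth]
    corrupted: set[str] = field(default_factory=set)

    def protein_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"protein_id": list(self.protein_log2), "true_log2_ratio": list(self.protein_log2.values())}
        )

    def peptide_frame(self) -> pd.DataFrame:
        rows = [
            (p.peptide_sequence, p.protein_id, p.abundance, p.apex_rt, seq in self.corrupted)
            for seq, p in self.peptides.items()
        ]
        return pd.DataFrame(
            rows, columns=["peptide_sequence", "protein_id", "abundance", "apex_rt", "corrupted"]
        )


# ---------------------------------------------------------------------------
# Library generation
# ---------------------------------------------------------------------------

def _random_tryptic_sequence(rng: np.random.Generator) -> tuple[str, int]:
    """A random tryptic peptide (8-15 residues) with 0 or 1 missed cleavage."""
    n_body = int(rng.integers(7, 15))
    body = rng.choice(_BODY_RESIDUES, size=n_body)
    missed = int(rng.random() < 0.3)
    if missed:
        pos = int(rng.integers(1, n_body - 1))  # internal, away from the C terminus
        body[pos] = "K" if rng.random() < 0.5 else "R"
    terminal = "K" if rng.random() < 0.5 else "R"
    return "".join(body) + terminal, missed


def generate_library(config: SimulationConfig, rng: np.random.Generator | None = None) -> SpectralLibrary:
    """Generate a synthetic kinome transition library.

    Each of ``n_proteins`` kinases gets 1-4 unique tryptic peptides; each
    peptide 4-6 y-ion transitions with reference relative intensities drawn
    from a flat Dirichlet (they sum to 1 within a peptide).
    """
    rng = config.rng() if rng is None else rng
    width = max(4, len(str(config.n_proteins)))
    entries: list[LibraryEntry] = []
    seen: set[str] = set()
    for i in range(config.n_proteins):
        protein_id = f"KIN{i + 1:0{width}d}"
        kinase_class = KINASE_CLASSES[int(rng.choice(len(KINASE_CLASSES), p=_CLASS_WEIGHTS))]
        n_pep = int(rng.integers(config.peptides_per_protein[0], config.peptides_per_protein[1] + 1))
        for _ in range(n_pep):
            while True:
                seq, missed = _random_tryptic_sequence(rng)
                if seq not in seen:
                    seen.add(seq)
                    break
            n_trans = int(
                rng.integers(config.transitions_per_peptide[0], config.transitions_per_peptide[1] + 1)
            )
            ordinals = rng.choice(np.arange(2, len(seq)), size=n_trans, replace=False)
            fractions = rng.dirichlet(np.full(n_trans, 2.0))
            transitions = [
                Transition("y", int(o), 1, float(f))
                for o, f in sorted(zip(ordinals, fractions), key=lambda p: p[0])
            ]
            entries.append(
                LibraryEntry(
                    peptide_sequence=seq,
                    protein_id=protein_id,
                    kinase_class=kinase_class,
                    precursor_charge=int(rng.integers(2, 4)),
                    missed_cleavages=missed,
                    transitions=transitions,
                )
            )
    return SpectralLibrary(entries=entries)


def generate_ground_truth(
    library: SpectralLibrary, config: SimulationConfig, rng: np.random.Generator | None = None
) -> GroundTruth:
    """Draw true fold changes, abundances and elution apexes for a library.

    Protein log2(metastatic/primary) ratios are normal; peptide abundances
    are log-uniform over ``abundance_log10_range`` orders with the extremes
    pinned so the configured span is realized exactly; per-transition true
    fractional intensities equal the library reference intensities, so a
    clean peptide scores dotp = 1 against its own library entry.
    """
    rng = config.rng() if rng is None else rng
    protein_log2 = {
        pid: float(rng.normal(config.true_log2_ratio_loc, config.true_log2_ratio_scale))
        for pid in library.proteins
    }
    n_pep = len(library.entries)
    lo = config.abundance_log10_min
    log10_ab = rng.uniform(lo, lo + config.abundance_log10_range, size=n_pep)
    if n_pep >= 2:  # pin the span
        ends = rng.choice(n_pep, size=2, replace=False)
        log10_ab[ends[0]] = lo
        log10_ab[ends[1]] = lo + config.abundance_log10_range
    peptides: dict[str, PeptideTruth] = {}
    for entry, la in zip(library.entries, log10_ab):
        total = sum(t.library_relative_intensity for t in entry.transitions)
        peptides[entry.peptide_sequence] = PeptideTruth(
            peptide_sequence=entry.peptide_sequence,
            protein_id=entry.protein_id,
            abundance=float(10.0**la),
            apex_rt=float(rng.uniform(*config.rt_range)),
            fractions={t.label: t.library_relative_intensity / total for t in entry.transitions},
        )
    return GroundTruth(protein_log2=protein_log2, peptides=peptides)


# ---------------------------------------------------------------------------
# Chromatogram simulation
# ---------------------------------------------------------------------------

def _time_grid(apex: float, config: SimulationConfig) -> np.ndarray:
    half = config.window_sigmas * config.peak_sigma
    start = math.floor((apex - half) / config.cycle_time) * config.cycle_time
    n = int(round(2 * half / config.cycle_time)) + 1
    return start + config.cycle_time * np.arange(n)


def simulate_experiment(
    library: SpectralLibrary,
    truth: GroundTruth,
    design: ExperimentDesign,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> dict[str, ChromatogramSet]:
    """Simulate one PRM run (one labeling replicate) for every library peptide.

    Each transition trace is a Gaussian sharing the peptide's apex RT and
    sigma across transitions and channels, with amplitude
    ``abundance x state factor x transition fraction``; the heavy/light
    amplitude ratio realizes the true fold change under the design's channel
    map.  Noise: per-channel log-normal amplitude factor (replicate-level
    variability) and per-point multiplicative log-normal, plus a flat
    baseline.  In the noiseless configuration traces are exact Gaussians.
    """
    rng = config.rng() if rng is None else rng
    out: dict[str, ChromatogramSet] = {}
    for entry in library.entries:
        seq = entry.peptide_sequence
        if seq not in truth.peptides:
            raise KeyError(f"ground truth missing for peptide {seq}")
        pep = truth.peptides[seq]
        ratio = 2.0 ** truth.protein_log2[pep.protein_id]  # metastatic / primary
        state_factor = {"primary": 1.0, "metastatic": ratio}
        times = _time_grid(pep.apex_rt, config)
        shape = np.exp(-0.5 * ((times - pep.apex_rt) / config.peak_sigma) ** 2)
        traces: dict[str, dict[str, np.ndarray]] = {}
        for channel in ("light", "heavy"):
            amp = pep.abundance * state_factor[design.channel_state[channel]]
            if config.channel_noise_sd > 0:
                amp *= float(np.exp(rng.normal(0.0, config.channel_noise_sd)))
            by_frag: dict[str, np.ndarray] = {}
            for t in entry.transitions:
                y = amp * pep.fractions[t.label] * shape
                if config.noise_relative_sd > 0:
                    y = y * np.exp(rng.normal(0.0, config.noise_relative_sd, size=y.shape))
                by_frag[t.label] = y + config.baseline_level
            traces[channel] = by_frag
        out[seq] = ChromatogramSet(peptide_sequence=seq, times=times, traces=traces)
    return out


def inject_interference(
    chromatograms: dict[str, ChromatogramSet],
    truth: GroundTruth,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> dict[str, ChromatogramSet]:
    """Corrupt a fraction of peptides with a large retention-shifted peak.

    For each selected peptide one channel gains, on a random subset of at
    most half its transitions, an extra Gaussian centered >=3 peak sigmas
    away from the apex, with total amplitude a multiple of that channel's
    summed apex intensity.  This distorts both the relative transition
    intensities (dotp) and the per-transition apex agreement (co-elution).
    Corrupted peptides are recorded in ``truth.corrupted``.  Traces are
    modified in place; the collection is returned for chaining.
    """
    if config.interference_fraction == 0:
        return chromatograms
    rng = config.rng() if rng is None else rng
    sequences = list(chromatograms)
    n_corrupt = int(round(config.interference_fraction * len(sequences)))
    chosen = rng.choice(len(sequences), size=n_corrupt, replace=False)
    lo, hi = config.interference_offset_sigmas
    for idx in chosen:
        seq = sequences[int(idx)]
        cs = chromatograms[seq]
        channel = "light" if rng.random() < 0.5 else "heavy"
        frags = cs.fragments(channel)
        n_hit = int(rng.integers(1, max(1, len(frags) // 2) + 1))
        hit = [frags[int(i)] for i in rng.choice(len(frags), size=n_hit, replace=False)]
        summed = cs.summed(channel)
        apex_rt = cs.times[int(np.argmax(summed))]
        offset = float(rng.uniform(lo, hi)) * config.peak_sigma * (1 if rng.random() < 0.5 else -1)
        # keep the interfering apex inside the simulated window
        if not cs.times[0] <= apex_rt + offset <= cs.times[-1]:
            offset = -offset
        total_amp = config.interference_amplitude_factor * float(summed.max())
        bump = np.exp(-0.5 * ((cs.times - (apex_rt + offset)) / config.peak_sigma) ** 2)
        for frag in hit:
            cs.traces[channel][frag] = cs.traces[channel][frag] + (total_amp / n_hit) * bump
        truth.corrupted.add(seq)
    return chromatograms


# ---------------------------------------------------------------------------
# Survival simulation (for the screen)
# ---------------------------------------------------------------------------

def simulate_survival_dataset(
    gene_names: list[str],
    n_samples: int,
    rng: np.random.Generator,
    planted: dict[str, float] | None = None,
    base_rate: float = 1.0 / 500.0,
    censor_horizon: float = 2000.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate an expression matrix plus a survival table.

    Expression is standard normal per gene and sample.  Event times are
    exponential with a group-dependent rate: samples in the top expression
    quartile of a planted gene have their hazard multiplied by that gene's
    rate ratio; all other genes are independent of survival.  Censoring is
    uniform on (0, ``censor_horizon``) days.

    Returns ``(expression genes x samples, survival table)``.
    """
    planted = planted or {}
    sample_ids = [f"S{i + 1:04d}" for i in range(n_samples)]
    expr = pd.DataFrame(
        rng.standard_normal((len(gene_names), n_samples)), index=gene_names, columns=sample_ids
    )
    rates = np.full(n_samples, base_rate)
    for gene, ratio in planted.items():
        values = expr.loc[gene].to_numpy()
        k = math.ceil(n_samples / 4)
        top = np.argsort(values, kind="stable")[-k:]
        rates[top] *= ratio
    event_times = rng.exponential(1.0 / rates)
    censor_times = rng.uniform(0.0, censor_horizon, size=n_samples)
    observed = np.minimum(event_times, censor_times)
    surv = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "time": np.maximum(observed, 1e-9),
            "event": (event_times <= censor_times).astype(int),
        }
    )
    return expr, surv
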