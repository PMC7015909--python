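import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import silacprm as sp

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


# Independent monoisotopic residue-mass table (standard reference values),
# used as the brute-force oracle for the package's mass arithmetic.
ORACLE_RESIDUE_MASS = {
    "G": 57.0214637, "A": 71.0371138, "S": 87.0320284, "P": 97.0527639,
    "V": 99.0684139, "T": 101.0476785, "C": 103.0091845, "L": 113.0840640,
    "I": 113.0840640, "N": 114.0429274, "D": 115.0269430, "Q": 128.0585775,
    "K": 128.0949630, "E": 129.0425931, "M": 131.0404846, "H": 137.0589119,
    "F": 147.0684139, "R": 156.1011110, "Y": 163.0633285, "W": 186.0793130,
}
ORACLE_WATER = 18.0105646
ORACLE_PROTON = 1.0072765
ORACLE_CAM_C = 57.0214637  # carbamidomethyl fixed mod on C
ORACLE_HEAVY_K = 8.014199
ORACLE_HEAVY_R = 6.020129


def oracle_peptide_mass(seq: str, heavy: bool = False) -> float:
    m = ORACLE_WATER
    for aa in seq:
        m += ORACLE_RESIDUE_MASS[aa]
        if aa == "C":
            m += ORACLE_CAM_C
        if heavy and aa == "K":
            m += ORACLE_HEAVY_K
        if heavy and aa == "R":
            m += ORACLE_HEAVY_R
    return m


def oracle_y_mz(seq: str, ordinal: int, charge: int, heavy: bool = False) -> float:
    return (oracle_peptide_mass(seq[-ordinal:], heavy) + charge * ORACLE_PROTON) / charge


@pytest.fixture(scope="session")
def noiseless_experiment():
    """50-protein noiseless forward run with ground truth."""
    cfg = sp.SimulationConfig(n_proteins=50, seed=11).noiseless()
    rng = cfg.rng()
    lib = sp.generate_library(cfg, rng)
    truth = sp.generate_ground_truth(lib, cfg, rng)
    chroms = sp.simulate_experiment(lib, truth, sp.FORWARD, cfg, rng)
    return cfg, lib, truth, chroms


@pytest.fixture(scope="session")
def small_library():
    cfg = sp.SimulationConfig(n_proteins=12, seed=7)
    return sp.generate_library(cfg)


def make_gaussian_chromatogram(
    seq="PEPTIDEK",
    amp_light=1000.0,
    ratio=2.0,
    fractions=(0.4, 0.3, 0.2, 0.1),
    apex=300.0,
    sigma=5.0,
    dt=2.0,
    half_width=40.0,
):
    """Hand-built clean light/heavy Gaussian chromatogram pair."""
    times = np.arange(apex - half_width, apex + half_width + dt / 2, dt)
    shape = np.exp(-0.5 * ((times - apex) / sigma) ** 2)
    frags = [f"y{i + 3}" for i in range(len(fractions))]
    traces = {
        "light": {f: amp_light * fr * shape for f, fr in zip(frags, fractions)},
        "heavy": {f: amp_light * ratio * fr * shape for f, fr in zip(frags, fractions)},
    }
    cs = sp.ChromatogramSet(peptide_sequence=seq, times=times, traces=traces)
    entry = sp.LibraryEntry(
        peptide_sequence=seq,
        protein_id="KIN_TEST",
        kinase_class="protein",
        precursor_charge=2,
        missed_cleavages=0,
        transitions=[sp.Transition("y", i + 3, 1, fr) for i, fr in enumerate(fractions)],
    )
    return cs, entry
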