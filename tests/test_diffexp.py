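"""Label-swap reconciliation, protein roll-up, QC metrics."""

import math

import numpy as np
import pandas as pd
import pytest

import silacprm as sp


def quant_row(seq, protein, ratio, passed=True):
    return {
        "peptide_sequence": seq,
        "protein_id": protein,
        "area_light": 1.0,
        "area_heavy": ratio,
        "dotp_light": 1.0,
        "dotp_heavy": 1.0,
        "apex_rt": 100.0,
        "ratio": ratio,
        "passed_filters": passed,
        "failure_reason": "none" if passed else "low_dotp",
    }


def quant_table(rows):
    return pd.DataFrame(rows)


class TestOrientRatios:
    @pytest.mark.parametrize(
        "design,ratio,expected",
        [("forward", 2.0, 1.0), ("reverse", 2.0, -1.0), ("reverse", 0.5, 1.0)],
    )
    def test_orientation(self, design, ratio, expected):
        rec = sp.orient_ratios(quant_table([quant_row("PEPK", "P1", ratio)]), design, 1)
        assert rec["oriented_log2"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_failed_peptides_excluded(self):
        table = quant_table(
            [quant_row("AK", "P1", 2.0), quant_row("BK", "P1", 2.0, passed=False)]
        )
        assert list(sp.orient_ratios(table, "forward", 1)["peptide_sequence"]) == ["AK"]

    def test_unknown_design_rejected(self):
        with pytest.raises(ValueError):
            sp.orient_ratios(quant_table([quant_row("AK", "P1", 2.0)]), "sideways", 1)

    def test_orientation_involution(self):
        """Orienting a ratio as forward then as reverse negates the log2 value."""
        table = quant_table([quant_row("AK", "P1", 3.7)])
        f = sp.orient_ratios(table, "forward", 1)["oriented_log2"].iloc[0]
        r = sp.orient_ratios(table, "reverse", 1)["oriented_log2"].iloc[0]
        assert f == pytest.approx(-r, abs=1e-12)


def records(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "peptide_sequence",
            "protein_id",
            "design",
            "replicate_id",
            "measured_ratio",
            "oriented_log2",
        ],
    )


class TestConsistencyAndR2:
    def _pair(self, fwd_vals, rev_vals):
        fwd = records(
            [(f"P{i}K", "X", "forward", 1, 2.0**v, v) for i, v in enumerate(fwd_vals)]
        )
        rev = records(
            [(f"P{i}K", "X", "reverse", 1, 2.0**-v, v) for i, v in enumerate(rev_vals)]
        )
        return fwd, rev

    def test_all_concordant(self):
        fwd, rev = self._pair([1.0, -0.5, 2.0, 0.1], [0.8, -0.4, 1.5, 0.2])
        assert sp.consistency_fraction(fwd, rev) == 1.0

    def test_one_of_four_discordant(self):
        fwd, rev = self._pair([1.0, -0.5, 2.0, 0.1], [0.8, -0.4, 1.5, -0.2])
        assert sp.consistency_fraction(fwd, rev) == 0.75

    def test_zero_counts_as_consistent(self):
        fwd, rev = self._pair([0.0, 1.0], [1.0, 1.0])
        assert sp.consistency_fraction(fwd, rev) == 1.0

    def test_empty_intersection_undefined(self):
        fwd, _ = self._pair([1.0], [1.0])
        rev = records([("OTHERK", "X", "reverse", 1, 2.0, 1.0)])
        assert math.isnan(sp.consistency_fraction(fwd, rev))

    def test_r2_identical_vectors(self):
        fwd, rev = self._pair([1.0, -0.5, 2.0], [1.0, -0.5, 2.0])
        assert sp.forward_reverse_r2(fwd, rev) == pytest.approx(1.0, abs=1e-12)

    def test_r2_needs_three_shared_and_variance(self):
        fwd, rev = self._pair([1.0, 2.0], [1.0, 2.0])
        assert math.isnan(sp.forward_reverse_r2(fwd, rev))
        fwd, rev = self._pair([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert math.isnan(sp.forward_reverse_r2(fwd, rev))

    def test_noiseless_label_swap_is_perfect(self, noiseless_experiment):
        cfg, lib, truth, chroms_fwd = noiseless_experiment
        chroms_rev = sp.simulate_experiment(lib, truth, sp.REVERSE, cfg)
        fwd = sp.orient_ratios(sp.quantify_run(chroms_fwd, lib), "forward", 1)
        rev = sp.orient_ratios(sp.quantify_run(chroms_rev, lib), "reverse", 1)
        assert sp.consistency_fraction(fwd, rev) == 1.0
        assert sp.forward_reverse_r2(fwd, rev) == pytest.approx(1.0, abs=1e-6)


class TestAggregateProtein:
    def test_rsd_against_direct_formula(self):
        # replicate linear ratios 8, 10, 12 -> SD 2, mean 10 -> RSD 20%
        recs = records(
            [("AK", "P1", "forward", r, v, math.log2(v)) for r, v in enumerate((8.0, 10.0, 12.0))]
        )
        out = sp.aggregate_protein(recs)
        assert out["rsd_percent"].iloc[0] == pytest.approx(20.0, rel=1e-10)
        assert out["n_replicates"].iloc[0] == 3

    @pytest.mark.parametrize(
        "mean_log2,call", [(0.7, "up"), (0.0, "unchanged"), (-0.7, "down"), (0.5, "unchanged")]
    )
    def test_call_cutoff(self, mean_log2, call):
        recs = records([("AK", "P1", "forward", 1, 2.0**mean_log2, mean_log2)])
        out = sp.aggregate_protein(recs, cutoff=1.5)
        assert out["call"].iloc[0] == call

    def test_single_replicate_rsd_undefined_but_called(self):
        recs = records([("AK", "P1", "forward", 1, 4.0, 2.0)])
        out = sp.aggregate_protein(recs)
        assert math.isnan(out["rsd_percent"].iloc[0])
        assert out["call"].iloc[0] == "up"

    def test_rollup_is_mean_within_then_across_replicates(self):
        recs = records(
            [
                ("AK", "P1", "forward", 1, 2.0, 1.0),
                ("BK", "P1", "forward", 1, 8.0, 3.0),
                ("AK", "P1", "reverse", 1, 0.5, 1.0),
            ]
        )
        out = sp.aggregate_protein(recs)
        # replicate means: forward (1+3)/2 = 2, reverse 1 -> protein mean 1.5
        assert out["mean_log2"].iloc[0] == pytest.approx(1.5, abs=1e-12)
        assert out["n_peptides"].iloc[0] == 2


class TestDynamicRange:
    def test_log_quotient(self):
        assert sp.dynamic_range([1e3, 5e4, 1e7]) == pytest.approx(4.0, abs=1e-12)

    def test_equal_areas(self):
        assert sp.dynamic_range([7.0, 7.0]) == 0.0

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            sp.dynamic_range([1.0, 0.0])


class TestKinomeMatrix:
    def _table(self, proteins, kclass="protein"):
        return pd.DataFrame(
            {
                "protein_id": proteins,
                "kinase_class": kclass,
                "mean_log2": np.linspace(-1, 1, len(proteins)),
                "rsd_percent": 10.0,
                "n_peptides": 2,
                "n_replicates": 2,
                "call": "unchanged",
            }
        )

    def test_intersection_of_pairs(self):
        matrix, counts = sp.build_kinome_matrix(
            {"p1": self._table(["A", "B", "C"]), "p2": self._table(["B", "C", "D"])}
        )
        assert list(matrix.index) == ["B", "C"]
        assert matrix.notna().all().all()
        assert counts.groupby("pair_id")["n_quantified"].sum().tolist() == [3, 3]

    def test_single_pair_passthrough(self):
        t = self._table(["A", "B"])
        matrix, _ = sp.build_kinome_matrix({"only": t})
        assert list(matrix.index) == ["A", "B"]
        assert matrix["only"].tolist() == t.set_index("protein_id").loc[["A", "B"], "mean_log2"].tolist()

    def test_class_counts_match_counting_oracle(self):
        cfg = sp.SimulationConfig(n_proteins=25, seed=8)
        lib = sp.generate_library(cfg)
        class_map = {e.protein_id: e.kinase_class for e in lib.entries}
        table = self._table(sorted(set(class_map)))
        table["kinase_class"] = table["protein_id"].map(class_map)
        _, counts = sp.build_kinome_matrix({"p": table})
        expected = pd.Series(class_map).value_counts()
        for _, row in counts.iterrows():
            assert row["n_quantified"] == expected[row["kinase_class"]]
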