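"""Cell assignment, LogNormalize, hurdle DE and cis-window reporting."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pairdel import sc, simulate
from pairdel.models import TargetRegion


def capture_frame(cells: dict[str, dict[str, int]], pairs=("pA", "pB")):
    features = [f"{p}_{s}" for p in pairs for s in ("u6", "h1")]
    df = pd.DataFrame(0, index=features, columns=sorted(cells))
    for cell, umis in cells.items():
        for feat, n in umis.items():
            df.loc[feat, cell] = n
    return df


def expression_for(cells, n_genes=5, fill=3):
    rng = np.random.default_rng(1)
    return pd.DataFrame(rng.poisson(fill, size=(n_genes, len(cells))),
                        index=[f"g{i}" for i in range(n_genes)],
                        columns=sorted(cells))


class TestAssignPerturbations:
    def pair_map(self, pairs=("pA", "pB")):
        return {f"{p}_{s}": p for p in pairs for s in ("u6", "h1")}

    def test_single_dominant_pair_assigned(self):
        cap = capture_frame({"c1": {"pA_u6": 6, "pA_h1": 4}})
        out = sc.assign_perturbations(cap, self.pair_map(),
                                      expression_for(["c1"]))
        assert out.loc["c1", "label"] == "pA"

    def test_two_strong_pairs_without_dominance_is_multiplet(self):
        cap = capture_frame({"c1": {"pA_u6": 10, "pB_u6": 9}})
        out = sc.assign_perturbations(cap, self.pair_map(),
                                      expression_for(["c1"]))
        assert out.loc["c1", "label"] == "multiplet"  # 10/19 < 0.8

    def test_all_zero_capture_is_unassigned(self):
        cap = capture_frame({"c1": {}})
        out = sc.assign_perturbations(cap, self.pair_map(),
                                      expression_for(["c1"]))
        assert out.loc["c1", "label"] == "unassigned"

    def test_barcode_mismatch_raises(self):
        cap = capture_frame({"c1": {"pA_u6": 5}})
        expr = expression_for(["c2"])
        with pytest.raises(ValueError, match="c1"):
            sc.assign_perturbations(cap, self.pair_map(), expr)

    def test_assignment_conservation(self):
        simd = simulate.simulate_single_cell(
            ["pairA", "pairB"], cells_per_target=40, n_control_cells=120,
            n_genes=20, multiplet_rate=0.1, seed=2)
        out = sc.assign_perturbations(simd["capture"], simd["pair_of_guide"],
                                      simd["expression"])
        labels = out["label"]
        n_assigned = (~labels.isin(["multiplet", "unassigned"])).sum()
        assert n_assigned + (labels == "multiplet").sum() \
            + (labels == "unassigned").sum() == len(out)

    def test_multiplet_fraction_matches_generator(self):
        rate, n = 0.05, 2000
        simd = simulate.simulate_single_cell(
            ["pairA"], cells_per_target=500, n_control_cells=n - 500,
            n_genes=20, multiplet_rate=rate, seed=3)
        out = sc.assign_perturbations(simd["capture"], simd["pair_of_guide"],
                                      simd["expression"])
        observed = (out["label"] == "multiplet").mean()
        se = math.sqrt(rate * (1 - rate) / n)
        assert abs(observed - rate) <= 2 * se


class TestLogNormalize:
    def test_zero_count_maps_to_zero(self):
        counts = pd.DataFrame({"c1": [0, 10]}, index=["g0", "g1"])
        norm = sc.lognormalize_cells(counts)
        assert norm.loc["g0", "c1"] == 0.0

    def test_full_cell_total_closed_form(self):
        counts = pd.DataFrame({"c1": [7, 0]}, index=["g0", "g1"])
        norm = sc.lognormalize_cells(counts)
        assert norm.loc["g0", "c1"] == pytest.approx(math.log(1 + 10000))

    def test_depth_rescaling_invariance(self):
        rng = np.random.default_rng(4)
        counts = pd.DataFrame(rng.poisson(5, size=(20, 3)),
                              columns=["c1", "c2", "c3"])
        doubled = counts.copy()
        doubled["c2"] = counts["c2"] * 2
        a = sc.lognormalize_cells(counts)
        b = sc.lognormalize_cells(doubled)
        assert np.allclose(a["c2"], b["c2"])

    def test_zero_total_cells_dropped(self):
        counts = pd.DataFrame({"ok": [1, 2], "empty": [0, 0]})
        norm = sc.lognormalize_cells(counts)
        assert list(norm.columns) == ["ok"]

    def test_monotone_within_cell(self):
        counts = pd.DataFrame({"c1": [1, 5, 20]})
        norm = sc.lognormalize_cells(counts)
        assert norm["c1"].is_monotonic_increasing


class TestHurdleDE:
    def test_low_expression_gene_skipped(self):
        simd = simulate.simulate_single_cell(["pairA"], cells_per_target=50,
                                             n_control_cells=200, n_genes=20,
                                             seed=5)
        assign = sc.assign_perturbations(simd["capture"], simd["pair_of_guide"],
                                         simd["expression"])
        norm = sc.lognormalize_cells(simd["expression"])
        # force one gene to near-absence: detected once, tiny normalized mean
        norm.iloc[0, :] = 0.0
        norm.iloc[0, 0] = 0.005
        res = sc.hurdle_de(norm, assign, "pairA", "ctrl_pair")
        assert norm.index[0] not in res.index

    def test_planted_knockdown_detected_and_signed(self):
        simd = simulate.simulate_single_cell(
            ["pairA"], cells_per_target=150, n_control_cells=1000, n_genes=25,
            cis_effects={"pairA": {"gene0003": 0.5}}, seed=6)
        assign = sc.assign_perturbations(simd["capture"], simd["pair_of_guide"],
                                         simd["expression"])
        norm = sc.lognormalize_cells(simd["expression"])
        res = sc.hurdle_de(norm, assign, "pairA", "ctrl_pair")
        assert res.loc["gene0003", "p_adj"] < 0.05
        assert res.loc["gene0003", "lfc"] < 0

    def test_type_i_error_calibrated_on_permuted_labels(self):
        simd = simulate.simulate_single_cell(
            ["pairA"], cells_per_target=150, n_control_cells=450, n_genes=300,
            mean_depth=1500.0, seed=7)
        assign = sc.assign_perturbations(simd["capture"], simd["pair_of_guide"],
                                         simd["expression"])
        rng = np.random.default_rng(8)
        assign["label"] = rng.permutation(assign["label"].to_numpy())
        norm = sc.lognormalize_cells(simd["expression"])
        res = sc.hurdle_de(norm, assign, "pairA", "ctrl_pair")
        rate = (res["p"] < 0.05).mean()
        se = math.sqrt(0.05 * 0.95 / len(res))
        assert abs(rate - 0.05) <= 2 * se

    def test_null_lrt_close_to_chi2_two_df(self):
        simd = simulate.simulate_single_cell(
            ["pairA"], cells_per_target=150, n_control_cells=450, n_genes=300,
            mean_depth=1500.0, seed=9)
        assign = sc.assign_perturbations(simd["capture"], simd["pair_of_guide"],
                                         simd["expression"])
        rng = np.random.default_rng(10)
        assign["label"] = rng.permutation(assign["label"].to_numpy())
        norm = sc.lognormalize_cells(simd["expression"])
        res = sc.hurdle_de(norm, assign, "pairA", "ctrl_pair")
        two = res[res["df"] == 2]
        q = stats.chi2.ppf((np.arange(1, len(two) + 1) - 0.5) / len(two), 2)
        slope = np.polyfit(q, np.sort(two["lrt"]), 1)[0]
        assert abs(slope - 1.0) <= 0.1

    def test_knockdown_lfc_ordering_monotone(self):
        for rep in range(3):
            simd = simulate.simulate_single_cell(
                ["p25", "p50", "p75"], cells_per_target=150,
                n_control_cells=1000, n_genes=25,
                cis_effects={"p25": {"gene0002": 0.25},
                             "p50": {"gene0002": 0.50},
                             "p75": {"gene0002": 0.75}}, seed=20 + rep)
            assign = sc.assign_perturbations(simd["capture"],
                                             simd["pair_of_guide"],
                                             simd["expression"])
            norm = sc.lognormalize_cells(simd["expression"])
            lfcs = [sc.hurdle_de(norm, assign, t, "ctrl_pair").loc["gene0002", "lfc"]
                    for t in ("p25", "p50", "p75")]
            assert lfcs[0] > lfcs[1] > lfcs[2]

    def test_too_few_cells_raises(self):
        simd = simulate.simulate_single_cell(["pairA"], cells_per_target=5,
                                             n_control_cells=50, n_genes=10,
                                             seed=11)
        assign = sc.assign_perturbations(simd["capture"], simd["pair_of_guide"],
                                         simd["expression"])
        norm = sc.lognormalize_cells(simd["expression"])
        with pytest.raises(ValueError, match="two cells"):
            sc.hurdle_de(norm, assign, "absent_pair", "ctrl_pair")


class TestCisWindowReport:
    def annotations(self):
        return pd.DataFrame({
            "gene": ["near", "far", "adjacent_tad"],
            "chrom": ["chr1", "chr1", "chr1"],
            "start": [1_500_000, 2_600_000, 1_900_000],
            "end": [1_520_000, 2_620_000, 1_920_000]})

    def region(self):
        return TargetRegion(region_id="r", chrom="chr1",
                            start=1_000_000, end=1_001_000)

    def results(self):
        return pd.DataFrame({"lfc": [-1.0, 0.2, 0.4], "p": [0.001, 0.5, 0.6],
                             "p_adj": [0.01, 0.8, 0.9]},
                            index=["near", "far", "adjacent_tad"])

    def test_window_mode_includes_half_megabase_gene(self):
        out = sc.cis_window_report(self.results(), self.region(),
                                   self.annotations())
        assert "near" in out.index and "far" not in out.index

    def test_tad_mode_excludes_adjacent_tad_gene(self):
        tads = [("chr1", 900_000, 1_800_000), ("chr1", 1_800_000, 2_500_000)]
        with_tad = sc.cis_window_report(self.results(), self.region(),
                                        self.annotations(), tads=tads)
        window = sc.cis_window_report(self.results(), self.region(),
                                      self.annotations())
        assert "adjacent_tad" not in with_tad.index
        assert "adjacent_tad" in window.index

    def test_region_outside_tads_falls_back_to_window(self):
        tads = [("chr2", 0, 1_000_000)]
        out = sc.cis_window_report(self.results(), self.region(),
                                   self.annotations(), tads=tads)
        assert "near" in out.index

    def test_results_attached_and_ordered(self):
        out = sc.cis_window_report(self.results(), self.region(),
                                   self.annotations())
        assert out.loc["near", "lfc"] == -1.0
        assert list(out["start"]) == sorted(out["start"])
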