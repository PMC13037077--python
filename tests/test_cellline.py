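import numpy as np
import pandas as pd
import pytest

import pathprog as pp
from pathprog.cellline import AMBIGUOUS, PanelAssignment
from pathprog.cof import LONG, SHORT


@pytest.fixture(scope="module")
def patient_groups():
    """Patients in two well-separated clusters over 4 COF columns."""
    rng = np.random.default_rng(0)
    cols = ["P1-P2", "P3-P4", "P5", "P2-P6"]
    n = 60
    rows, labels = [], []
    for i in range(n):
        short = i < n // 2
        mu = np.array([6.0, 5.0, 1.0, 4.0]) if short else np.array([1.0, 0.5, 3.0, 0.2])
        rows.append(mu + rng.normal(0, 0.4, size=4))
        labels.append(SHORT if short else LONG)
    matrix = pd.DataFrame(rows, index=[f"s{i}" for i in range(n)], columns=cols)
    return matrix, pd.Series(labels, index=matrix.index)


def assignment_for(lines, groups):
    return PanelAssignment(
        groups=pd.Series(groups, index=lines),
        coordinates=pd.DataFrame(),
        centroids={},
    )


class TestProjectAndAssign:
    def test_planted_clusters_fully_recovered(self, patient_groups):
        matrix, grouping = patient_groups
        panel = pp.generate_cellline_panel(
            matrix, grouping, list(matrix.columns),
            n_lines_per_group=6, noise_sd=0.3, rng_seed=1,
        )
        out = pp.project_and_assign(matrix, panel["cof_matrix"], grouping)
        assert (out.groups == panel["true_groups"]).all()

    def test_line_at_centroid(self, patient_groups):
        matrix, grouping = patient_groups
        short_mean = matrix[(grouping == SHORT).to_numpy()].mean(axis=0)
        cl = pd.DataFrame([short_mean], index=["atC"], columns=matrix.columns)
        out = pp.project_and_assign(matrix, cl, grouping)
        assert out.groups["atC"] == SHORT

    def test_equidistant_is_ambiguous(self, patient_groups):
        matrix, grouping = patient_groups
        mid = (matrix[(grouping == SHORT).to_numpy()].mean(axis=0)
               + matrix[(grouping == LONG).to_numpy()].mean(axis=0)) / 2
        cl = pd.DataFrame([mid], index=["mid"], columns=matrix.columns)
        out = pp.project_and_assign(matrix, cl, grouping)
        assert out.groups["mid"] == AMBIGUOUS

    def test_rotation_equivariance(self, patient_groups):
        """A rigid rotation applied jointly to patients and lines does not
        change any assignment."""
        matrix, grouping = patient_groups
        panel = pp.generate_cellline_panel(
            matrix, grouping, list(matrix.columns), n_lines_per_group=5, rng_seed=3,
        )
        cl = panel["cof_matrix"]
        before = pp.project_and_assign(matrix, cl, grouping).groups
        rng = np.random.default_rng(4)
        a = rng.normal(size=(4, 4))
        q, _ = np.linalg.qr(a)
        rot_p = pd.DataFrame(matrix.to_numpy() @ q, index=matrix.index,
                             columns=matrix.columns)
        rot_c = pd.DataFrame(cl.to_numpy() @ q, index=cl.index, columns=cl.columns)
        after = pp.project_and_assign(rot_p, rot_c, grouping).groups
        assert (before == after).all()

    def test_too_few_columns_rejected(self, patient_groups):
        matrix, grouping = patient_groups
        with pytest.raises(ValueError, match="2 shared COF columns"):
            pp.project_and_assign(matrix[["P5"]], matrix[["P5"]], grouping)


class TestDifferentialDependency:
    def _panel(self, rng, n_genes=50, planted=0):
        lines = [f"cl{i}" for i in range(12)]
        dep = rng.normal(0, 0.3, size=(n_genes, 12))
        for g in range(planted):
            dep[g, :6] = rng.normal(-0.8, 0.1, size=6)
            dep[g, 6:] = rng.normal(0.1, 0.1, size=6)
        frame = pd.DataFrame(dep, index=[f"D{i}" for i in range(n_genes)],
                             columns=lines)
        pa = assignment_for(lines, [SHORT] * 6 + [LONG] * 6)
        return frame, pa

    def test_planted_gene_selected_short_only(self):
        dep, pa = self._panel(np.random.default_rng(0), planted=1)
        out = pp.differential_dependency(dep, pa)
        assert bool(out.loc["D0", "selected"])
        assert out.loc["D0", "category"] == "Short only"

    def test_identical_distributions_select_nothing(self):
        rng = np.random.default_rng(1)
        lines = [f"cl{i}" for i in range(20)]
        dep = pd.DataFrame(np.tile(rng.normal(0, 1, size=(30, 1)), (1, 20)),
                           index=[f"D{i}" for i in range(30)], columns=lines)
        pa = assignment_for(lines, [SHORT] * 10 + [LONG] * 10)
        out = pp.differential_dependency(dep, pa)
        assert not out["selected"].any()

    def test_null_calibration(self):
        """With labels carrying no information, about 3% of genes clear the
        0.03 threshold."""
        rng = np.random.default_rng(2)
        lines = [f"cl{i}" for i in range(30)]
        dep = pd.DataFrame(rng.normal(0, 1, size=(1000, 30)),
                           index=[f"D{i}" for i in range(1000)], columns=lines)
        pa = assignment_for(lines, [SHORT] * 15 + [LONG] * 15)
        rate = pp.differential_dependency(dep, pa)["selected"].mean()
        assert 0.01 <= rate <= 0.05

    def test_categories_mutually_exclusive_exhaustive(self):
        dep, pa = self._panel(np.random.default_rng(3), planted=3)
        out = pp.differential_dependency(dep, pa)
        assert set(out["category"]) <= {"Short & Long", "Short only",
                                        "Long only", "neither"}
        assert out["category"].notna().all()

    def test_requires_three_lines_per_group(self):
        lines = ["a", "b", "c", "d"]
        dep = pd.DataFrame(np.zeros((3, 4)), index=["D0", "D1", "D2"],
                           columns=lines)
        pa = assignment_for(lines, [SHORT, SHORT, LONG, LONG])
        with pytest.raises(ValueError, match="3 cell lines"):
            pp.differential_dependency(dep, pa)


class TestDrugResponse:
    def _panel(self, rng, planted=False):
        lines = [f"cl{i}" for i in range(14)]
        z = rng.normal(0, 1, size=(20, 14))
        if planted:
            z[0, :7] -= 2.5
        frame = pd.DataFrame(z, index=[f"C{i}" for i in range(20)], columns=lines)
        return frame, assignment_for(lines, [SHORT] * 7 + [LONG] * 7)

    def test_planted_compound_short_effective(self):
        z, pa = self._panel(np.random.default_rng(0), planted=True)
        out = pp.drug_response_diff(z, pa)
        assert bool(out.loc["C0", "significant"])
        assert out.loc["C0", "effective_against"] == SHORT
        assert out.loc["C0", "mean_short"] < out.loc["C0", "mean_long"]

    def test_identical_distributions_nothing_significant(self):
        rng = np.random.default_rng(5)
        lines = [f"cl{i}" for i in range(16)]
        z = pd.DataFrame(np.tile(rng.normal(size=(10, 1)), (1, 16)),
                         index=[f"C{i}" for i in range(10)], columns=lines)
        pa = assignment_for(lines, [SHORT] * 8 + [LONG] * 8)
        out = pp.drug_response_diff(z, pa)
        assert not out["significant"].any()

    def test_sparse_compound_skipped(self):
        z, pa = self._panel(np.random.default_rng(1))
        z.iloc[0, :5] = np.nan  # only 2 short lines left for C0
        out = pp.drug_response_diff(z, pa)
        assert "C0" not in out.index
        assert len(out) == 19


class TestRepurposing:
    def _results(self, p=0.001):
        return pd.DataFrame(
            {
                "mean_short": [-1.0], "mean_long": [0.0], "t": [-5.0],
                "p": [p], "significant": [p < 0.05],
                "effective_against": [SHORT if p < 0.05 else "none"],
            },
            index=pd.Index(["drugX"], name="compound"),
        )

    def test_same_cancer_approval_excluded(self):
        out = pp.repurposing_screen(
            {"CANCER_A": self._results()},
            {"CANCER_A": {"drugX"}, "CANCER_B": {"drugX"}},
        )
        assert out.empty

    def test_cross_cancer_hit_included_with_origin(self):
        out = pp.repurposing_screen(
            {"CANCER_A": self._results()},
            {"CANCER_A": set(), "CANCER_B": {"drugX"}},
        )
        assert len(out) == 1
        assert out.iloc[0]["compound"] == "drugX"
        assert out.iloc[0]["origin_cancer_types"] == "CANCER_B"

    def test_toy_three_cancer_fixture(self):
        """One planted cross-type hit among three cancers is the only
        candidate returned."""
        results = {
            "A": self._results(p=0.001),          # drugX short-effective in A
            "B": self._results(p=0.5),            # not significant in B
            "C": pd.DataFrame(columns=["mean_short", "mean_long", "t", "p",
                                       "significant", "effective_against"]),
        }
        approved = {"A": {"drugA"}, "B": {"drugX"}, "C": {"drugC"}}
        out = pp.repurposing_screen(results, approved)
        assert list(out["cancer_type"]) == ["A"]
        assert list(out["compound"]) == ["drugX"]


class TestHitCrosstalkEnrichment:
    def test_planted_link_is_top_hit(self, toy_pathways):
        cat = pp.enumerate_features(toy_pathways)
        background = {"a", "b", "c", "d", "e", "f", "g", "h", "i", "j"}
        hits = {"b", "c"}  # exactly the P1-P2 intersection
        out = pp.hit_crosstalk_enrichment(hits, cat, background,
                                          cof_ids={"P1-P2"})
        assert not out.empty
        assert out.iloc[0]["feature_id"] == "P1-P2"
        assert bool(out.iloc[0]["is_cof"])

    def test_disjoint_hits_empty_table(self, toy_pathways):
        cat = pp.enumerate_features(toy_pathways)
        background = {"a", "b", "c", "d", "f", "g", "x", "y", "z"}
        out = pp.hit_crosstalk_enrichment({"x", "y", "z"}, cat, background)
        assert out.empty

    def test_empty_hits_empty_table(self, toy_pathways):
        cat = pp.enumerate_features(toy_pathways)
        out = pp.hit_crosstalk_enrichment(set(), cat, {"a", "b"})
        assert out.empty
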