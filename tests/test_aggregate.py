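"""Sigma-summation hierarchy, cohort comparison, flow export."""

import json
from importlib import resources

import numpy as np
import pandas as pd
import pytest

from immunodyn.aggregate import (CohortComparison, average_cohort,
                                 diff_cohorts, export_flow, sum_doublets,
                                 sum_singlets, sum_triplets, top_doublets)
from immunodyn.knowledge import NA


@pytest.fixture(scope="module")
def published():
    """Transcribed published occurrence-count excerpt (one cancer
    participant, one healthy volunteer; 48-point grid)."""
    with resources.files("immunodyn.data").joinpath(
            "published_quads.csv").open() as fh:
        return pd.read_csv(fh)


def _to_raw(values, max_count=48):
    return (np.asarray(values) * max_count / 100).round().astype(int)


def quad_table(rows):
    return pd.DataFrame(rows, columns=["modulator", "source", "target",
                                       "lsv", "raw_count", "normalized"])


@pytest.fixture
def small_quads():
    rows = [
        ("M1", "S1", "T1", "L1", 24, 50.0),
        ("M1", "S1", "T1", "L2", 12, 25.0),
        ("M1", "S2", "T2", "L1", 6, 12.5),
        ("M2", "S1", "T2", "L3", 3, 6.25),
        (NA, "S2", "T1", "T1", 9, 18.75),
    ]
    return quad_table(rows)


class TestTriplets:
    def test_published_cancer_triplet_sum(self, published):
        """Summing the printed (IP-10, CD3+, IL-8) quads through raw counts
        reproduces the printed triplet total 502.08."""
        sub = published[(published.target == "IL-8")
                        & (published.section == "bilinear")].copy()
        sub["raw_count"] = _to_raw(sub.occ_cancer_12A)
        trip = sum_triplets(sub, max_count=48)
        assert round(trip.value.iloc[0], 2) == 502.08

    def test_published_healthy_triplet_sum_needs_raw_path(self, published):
        """The healthy triplet prints 183.33; naive summation of the
        rounded 2-dp values gives 183.32, so the raw-count path matters."""
        sub = published[(published.target == "IL-8")
                        & (published.section == "bilinear")].copy()
        naive = round(sub.occ_healthy_10.sum(), 2)
        assert naive == 183.32
        sub["raw_count"] = _to_raw(sub.occ_healthy_10)
        trip = sum_triplets(sub, max_count=48)
        assert round(trip.value.iloc[0], 2) == 183.33

    def test_single_quad_triplet(self, small_quads):
        one = small_quads.iloc[[3]]
        trip = sum_triplets(one)
        assert trip.value.iloc[0] == 6.25


class TestDoubletsSinglets:
    def test_hand_doublet_sums_all_views(self, small_quads):
        ms = sum_doublets(small_quads, "modulator_source")
        assert dict(zip(zip(ms.modulator, ms.source), ms.value)) == {
            ("M1", "S1"): 75.0, ("M1", "S2"): 12.5, ("M2", "S1"): 6.25,
            (NA, "S2"): 18.75}
        st = sum_doublets(small_quads, "source_target")
        assert dict(zip(zip(st.source, st.target), st.value)) == {
            ("S1", "T1"): 75.0, ("S2", "T2"): 12.5, ("S1", "T2"): 6.25,
            ("S2", "T1"): 18.75}
        tm = sum_doublets(small_quads, "target_modulator")
        assert dict(zip(zip(tm.target, tm.modulator), tm.value)) == {
            ("T1", "M1"): 75.0, ("T2", "M1"): 12.5, ("T2", "M2"): 6.25,
            ("T1", NA): 18.75}

    def test_shared_doublet_collapses_to_grand_total(self):
        qt = quad_table([("M", "S", f"T{i}", f"L{i}", 1, 10.0)
                         for i in range(5)])
        d = sum_doublets(qt, "modulator_source")
        assert len(d) == 1
        assert d.value.iloc[0] == pytest.approx(50.0)

    def test_conservation_across_hierarchy(self, small_quads):
        total = small_quads.normalized.sum()
        assert sum_triplets(small_quads).value.sum() == pytest.approx(total)
        for view in ("modulator_source", "source_target",
                     "target_modulator"):
            assert sum_doublets(small_quads, view).value.sum() == \
                pytest.approx(total, abs=1e-9)
        for role in ("modulator", "source", "target", "lsv"):
            assert sum_singlets(small_quads, role).value.sum() == \
                pytest.approx(total, abs=1e-9)

    def test_quad_triplet_doublet_composition(self, small_quads):
        via_triplet = sum_doublets(
            sum_triplets(small_quads).rename(columns={"value": "normalized"})
            .assign(lsv="x"), "modulator_source")
        direct = sum_doublets(small_quads, "modulator_source")
        pd.testing.assert_frame_equal(via_triplet, direct)

    def test_unknown_view_role(self, small_quads):
        with pytest.raises(ValueError):
            sum_doublets(small_quads, "lsv_target")
        with pytest.raises(ValueError):
            sum_singlets(small_quads, "time")


class TestCohorts:
    def test_average_idempotent(self, small_quads):
        avg = average_cohort([small_quads, small_quads.copy()])
        merged = avg.merge(small_quads, on=["modulator", "source",
                                            "target", "lsv"])
        np.testing.assert_allclose(merged.normalized_x, merged.normalized_y)

    def test_absent_quad_counts_as_zero(self, small_quads):
        other = small_quads.iloc[[0]]
        avg = average_cohort([small_quads, other])
        row = avg[(avg.modulator == "M2")]
        assert row.normalized.iloc[0] == pytest.approx(6.25 / 2)
        assert avg.attrs["n_participants"] == 2

    def test_average_permutation_invariant(self, small_quads):
        a = average_cohort([small_quads, small_quads.iloc[[0, 2]]])
        b = average_cohort([small_quads.iloc[[0, 2]], small_quads])
        pd.testing.assert_frame_equal(a, b)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            average_cohort([])

    def test_self_diff_is_zero(self, small_quads):
        cmp = diff_cohorts(small_quads, small_quads)
        assert (cmp.diff.normalized == 0).all()
        assert cmp.positive.empty and cmp.negative.empty

    def test_hand_diff_and_sign_partition(self, small_quads):
        other = small_quads.copy()
        other.loc[0, "normalized"] = 10.0       # 50 -> 10
        cmp = diff_cohorts(small_quads, other)
        row = cmp.diff[(cmp.diff.modulator == "M1")
                       & (cmp.diff.lsv == "L1")
                       & (cmp.diff.source == "S1")]
        assert row.normalized.iloc[0] == pytest.approx(40.0)
        recon = pd.concat([cmp.positive, cmp.negative])
        assert recon.normalized.sum() == pytest.approx(
            cmp.diff.normalized.sum())

    def test_diff_antisymmetry(self, small_quads):
        other = small_quads.copy()
        other["normalized"] = other["normalized"].iloc[::-1].values
        ab = diff_cohorts(small_quads, other).diff
        ba = diff_cohorts(other, small_quads).diff
        merged = ab.merge(ba, on=["modulator", "source", "target", "lsv"])
        np.testing.assert_allclose(merged.normalized_x,
                                   -merged.normalized_y)

    def test_top_doublets_ranking(self):
        rows = [(f"M{i}", f"S{j}", "T", "L", 1, float(10 * i + j))
                for i in range(4) for j in range(3)]
        qt = quad_table(rows)
        top = top_doublets(qt, n=10)
        assert len(top) == 10
        assert (np.diff(top.value.values) <= 0).all()
        assert top.value.iloc[0] == 32.0


class TestFlowExport:
    def test_export_matches_sums(self, tmp_path):
        qt = quad_table([
            ("M1", "S1", "T", "L", 10, 20.0),
            ("M2", "S1", "T", "L", 5, 10.0),
            ("M1", "S1", "T2", "L2", 5, 10.0),
        ])
        out = tmp_path / "flow.dot"
        g = export_flow(qt, out)
        assert g.number_of_nodes() == 3            # 2 modulators + 1 source
        assert g.number_of_edges() == 2
        assert g.nodes["M::M1"]["size"] == pytest.approx(30.0)
        assert g.nodes["S::S1"]["size"] == pytest.approx(40.0)
        assert g.edges["M::M1", "S::S1"]["width"] == pytest.approx(30.0)
        text = out.read_text()
        assert "octagon" in text and "circle" in text
        twin = json.loads(out.with_suffix(".json").read_text())
        assert len(twin["nodes"]) == 3 and len(twin["edges"]) == 2

    def test_empty_table_valid_file(self, tmp_path):
        qt = quad_table([])
        out = tmp_path / "empty.dot"
        g = export_flow(qt, out)
        assert g.number_of_edges() == 0
        assert out.read_text().startswith("digraph")

    def test_zero_diffs_not_colored(self, tmp_path, small_quads):
        cmp = diff_cohorts(small_quads, small_quads)
        g = export_flow(cmp, tmp_path / "zero.dot")
        assert all(d["color"] in ("black", "gray")
                   for _, _, d in g.edges(data=True))

    def test_signed_diff_colors(self, tmp_path, small_quads):
        other = small_quads.copy()
        other.loc[0, "normalized"] = 100.0
        cmp = diff_cohorts(small_quads, other)
        g = export_flow(cmp, tmp_path / "signed.dot")
        colors = {d["color"] for _, _, d in g.edges(data=True)}
        assert "red" in colors or "green" in colors

    def test_rerun_byte_identical(self, tmp_path, small_quads):
        a = tmp_path / "a.dot"
        b = tmp_path / "b.dot"
        export_flow(small_quads, a)
        export_flow(small_quads.copy(), b)
        assert a.read_bytes() == b.read_bytes()
        assert a.with_suffix(".json").read_bytes() == \
            b.with_suffix(".json").read_bytes()
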