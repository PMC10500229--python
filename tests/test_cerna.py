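"""FRG intersection, database merging, axis assembly, direction rule."""

import itertools

import numpy as np
import pandas as pd
import pytest

from fercerna import (
    assemble_axes,
    build_network,
    combine_target_dbs,
    filter_directions,
    intersect_frgs,
)
from fercerna.cerna import TRIAD_COLUMNS


def de_table(records):
    """records: (gene, log2fc, passes) -> minimal DE frame."""
    return pd.DataFrame(
        [
            {
                "gene": g, "rna_class": "mRNA", "log2fc": fc, "p_value": 0.01,
                "fdr": 0.01, "direction": "up" if fc > 0 else "down", "passes": ok,
            }
            for g, fc, ok in records
        ]
    )


def pairs(*pp):
    return pd.DataFrame(list(pp), columns=["source", "target"])


class TestIntersectFrgs:
    def test_disjoint_sets_give_empty_result(self):
        de = de_table([("A", 2.0, True)])
        frgs = pd.DataFrame({"gene": ["B"], "role": ["Driver"]})
        assert len(intersect_frgs(de, frgs)) == 0

    def test_simple_intersection_keeps_directions_and_roles(self):
        de = de_table([("A", 2.0, True), ("B", -2.0, True), ("C", 1.5, True)])
        frgs = pd.DataFrame({"gene": ["B", "C"], "role": ["Driver", "Marker"]})
        out = intersect_frgs(de, frgs).set_index("gene")
        assert set(out.index) == {"B", "C"}
        assert out.loc["B", "direction"] == "down" and out.loc["B", "role"] == "Driver"

    def test_matching_is_case_insensitive_but_ids_kept_verbatim(self):
        de = de_table([("Hmox1 ", 2.0, True)])
        frgs = pd.DataFrame({"gene": ["HMOX1"], "role": ["Driver"]})
        out = intersect_frgs(de, frgs)
        assert list(out["gene"]) == ["Hmox1 "]

    def test_empty_frg_list_warns(self):
        de = de_table([("A", 2.0, True)])
        with pytest.warns(UserWarning):
            out = intersect_frgs(de, de.iloc[0:0][["gene"]].assign(role=None))
        assert len(out) == 0

    def test_non_passing_records_are_ignored(self):
        de = de_table([("A", 2.0, False)])
        frgs = pd.DataFrame({"gene": ["A"], "role": ["Driver"]})
        assert len(intersect_frgs(de, frgs)) == 0


class TestCombineTargetDbs:
    def test_identical_dbs_agree_in_both_modes(self):
        db = pairs(("m1", "g1"), ("m2", "g2"))
        for mode in ("intersection", "union"):
            out = combine_target_dbs(db, db, mode=mode)
            assert set(map(tuple, out[["source", "target"]].itertuples(index=False))) == {
                ("m1", "g1"), ("m2", "g2")
            }
            assert set(out["provenance"]) == {"db1,db2"}

    def test_disjoint_dbs_empty_intersection_full_union(self):
        db1, db2 = pairs(("m1", "g1")), pairs(("m2", "g2"))
        assert len(combine_target_dbs(db1, db2, mode="intersection")) == 0
        out = combine_target_dbs(db1, db2, mode="union")
        assert len(out) == 2 and set(out["provenance"]) == {"db1", "db2"}

    def test_self_pairs_and_bad_mode_rejected(self):
        with pytest.raises(ValueError):
            combine_target_dbs(pairs(("m1", "m1")), pairs(("m2", "g2")))
        with pytest.raises(ValueError):
            combine_target_dbs(pairs(("m1", "g1")), pairs(("m2", "g2")), mode="both")


class TestAssembleAxes:
    def test_single_join(self):
        axes = assemble_axes(
            pairs(("L1", "M1")), pairs(("M1", "G1")), de_table([("M1", 1.0, True)])
        )
        assert axes.values.tolist() == [["L1", "M1", "G1"]]

    def test_non_de_mirna_is_dropped(self):
        axes = assemble_axes(
            pairs(("L1", "M1")), pairs(("M1", "G1")), de_table([("M1", 1.0, False)])
        )
        assert len(axes) == 0

    def test_matches_bruteforce_triple_loop_on_random_instances(self):
        rng = np.random.default_rng(1)
        lncs = [f"L{i}" for i in range(8)]
        mis = [f"M{i}" for i in range(8)]
        genes = [f"G{i}" for i in range(8)]
        for _ in range(30):
            lm = {(l, m) for l in lncs for m in mis if rng.random() < 0.2}
            mg = {(m, g) for m in mis for g in genes if rng.random() < 0.2}
            de_mi = {m for m in mis if rng.random() < 0.6}
            expected = {
                (l, m, g)
                for l, m, g in itertools.product(lncs, mis, genes)
                if (l, m) in lm and (m, g) in mg and m in de_mi
            }
            axes = assemble_axes(
                pairs(*lm) if lm else pairs(),
                pairs(*mg) if mg else pairs(),
                de_table([(m, 1.0, m in de_mi) for m in mis]),
            )
            got = set(map(tuple, axes.itertuples(index=False)))
            assert got == expected


class TestFilterDirections:
    de_all = de_table(
        [("L1", 1.0, True), ("M1", -1.0, True), ("G1", 2.0, True),
         ("M2", 1.0, True), ("G2", -2.0, True), ("Z", 0.0, True)]
    )

    def axes(self, *rows):
        return pd.DataFrame(list(rows), columns=["lncrna", "mirna", "mrna"])

    def test_consistent_axis_kept_with_directions(self):
        out = filter_directions(self.axes(("L1", "M1", "G1")), self.de_all)
        assert out.values.tolist() == [["L1", "M1", "G1", "up", "down", "up"]]

    def test_inconsistent_axes_dropped(self):
        out = filter_directions(
            self.axes(("L1", "M2", "G2"), ("L1", "M1", "G2"), ("L1", "M2", "G1")),
            self.de_all,
        )
        assert len(out) == 0

    def test_zero_fold_change_member_drops_the_axis(self):
        assert len(filter_directions(self.axes(("L1", "M1", "Z")), self.de_all)) == 0

    def test_missing_de_record_names_the_member(self):
        with pytest.raises(KeyError, match="MISSING"):
            filter_directions(self.axes(("L1", "MISSING", "G1")), self.de_all)

    def test_idempotent(self):
        once = filter_directions(self.axes(("L1", "M1", "G1")), self.de_all)
        twice = filter_directions(once[["lncrna", "mirna", "mrna"]], self.de_all)
        pd.testing.assert_frame_equal(once, twice)


class TestBuildNetwork:
    def triads(self, *rows):
        return pd.DataFrame(list(rows), columns=TRIAD_COLUMNS)

    def test_single_triad_three_nodes_two_edges(self):
        net = build_network(self.triads(("L1", "M1", "G1", "up", "down", "up")))
        assert net.graph.number_of_nodes() == 3
        assert net.graph.number_of_edges() == 2
        assert net.class_counts == {"lncRNA": 1, "miRNA": 1, "mRNA": 1}

    def test_two_triads_sharing_a_mirna(self):
        net = build_network(
            self.triads(
                ("L1", "M1", "G1", "up", "down", "up"),
                ("L2", "M1", "G2", "up", "down", "up"),
            )
        )
        assert net.graph.number_of_nodes() == 5
        assert net.graph.number_of_edges() == 4

    def test_network_is_tripartite_with_every_edge_in_a_triad(self, default_analysis):
        net = default_analysis.network
        classes = {n: d["node_class"] for n, d in net.graph.nodes(data=True)}
        triad_edges = set()
        for l, m, g, *_ in net.triads.itertuples(index=False):
            triad_edges |= {frozenset((l, m)), frozenset((m, g))}
        for u, v, d in net.graph.edges(data=True):
            assert {classes[u], classes[v]} in (
                {"lncRNA", "miRNA"}, {"miRNA", "mRNA"}
            )
            assert frozenset((u, v)) in triad_edges
        assert net.graph.number_of_nodes() == len(
            set(net.triads[["lncrna", "mirna", "mrna"]].values.ravel())
        )
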