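"""Tree IO, Dollo/Sankoff reconstruction, loss counting and dating."""

import pytest

import dollotrace as dt
from dollotrace.trees import ROOT

from conftest import (
    all_rooted_topologies,
    brute_force_min_dollo_losses,
    topology_to_newick,
)


class TestTreeIO:
    def test_three_leaf_newick(self):
        t = dt.SpeciesTree.from_newick("((A:1,B:1):1,C:2);")
        assert sorted(t.leaves()) == ["A", "B", "C"]
        assert len(t.children(t.root)) == 2

    def test_newick_without_lengths_disables_dating(self):
        t = dt.SpeciesTree.from_newick("((A,B),C);")
        assert not t.has_branch_lengths()
        with pytest.raises(ValueError, match="dating"):
            t.node_age("A")

    def test_duplicate_leaf_labels_are_hard_error(self):
        with pytest.raises(ValueError):
            dt.SpeciesTree.from_newick("((A:1,A:1):1,C:2);")

    def test_write_read_round_trip(self, mammal_tree, tmp_path):
        ev = dt.EventSet(
            gene="KRT24", gain_branch=ROOT,
            loss_branches=frozenset({"Cetacea", "Otaroidea", "Camelus"}),
        )
        path = dt.write_annotated_newick(mammal_tree, [ev], tmp_path / "out.nwk")
        text = path.read_text()
        assert "&loss=KRT24" in text
        back = dt.read_newick(path)
        assert sorted(back.leaves()) == sorted(mammal_tree.leaves())
        assert back.preorder() == mammal_tree.preorder()
        for node in back.preorder():
            if node != back.root:
                assert back.edge_length(node) == mammal_tree.edge_length(node)


class TestDolloReconstruct:
    def test_all_present_gains_at_mrca_no_losses(self, mammal_tree):
        column = {sp: 1 for sp in mammal_tree.leaves()}
        ev = dt.dollo_reconstruct(column, mammal_tree)
        assert ev.gain_branch == ROOT and ev.loss_branches == frozenset()

    def test_no_present_leaf_means_no_gain(self, mammal_tree):
        ev = dt.dollo_reconstruct({"human": 0}, mammal_tree)
        assert ev.gain_branch is None and ev.loss_branches == frozenset()

    def test_krt24_fixture_gives_three_stem_losses(self, mammal_tree, krt24_states):
        ev = dt.dollo_reconstruct(
            krt24_states.column("KRT24"), mammal_tree,
            gene="KRT24", ancestral_at_root=True,
        )
        assert ev.loss_branches == frozenset({"Cetacea", "Otaroidea", "Camelus"})

    def test_unknown_leaf_species_is_hard_error(self, mammal_tree):
        with pytest.raises(KeyError):
            dt.dollo_reconstruct({"yeti": 1}, mammal_tree)

    def test_losses_are_never_nested(self, mammal_tree):
        import numpy as np

        rng = np.random.default_rng(42)
        leaves = mammal_tree.leaves()
        for _ in range(200):
            column = {
                sp: rng.choice([0, 1, "?"], p=[0.4, 0.4, 0.2]) for sp in leaves
            }
            column = {k: (int(v) if v != "?" else "?") for k, v in column.items()}
            ev = dt.dollo_reconstruct(column, mammal_tree)
            ev.validate(mammal_tree)  # raises on nesting

    def test_unknown_monotonicity(self, mammal_tree):
        import numpy as np

        rng = np.random.default_rng(7)
        leaves = mammal_tree.leaves()
        for _ in range(50):
            column = {sp: int(rng.integers(2)) for sp in leaves}
            if not any(v == 1 for v in column.values()):
                column[leaves[0]] = 1
            base = len(dt.dollo_reconstruct(column, mammal_tree).loss_branches)
            zeros = [sp for sp, v in column.items() if v == 0]
            if not zeros:
                continue
            relaxed = dict(column)
            relaxed[zeros[rng.integers(len(zeros))]] = "?"
            after = len(dt.dollo_reconstruct(relaxed, mammal_tree).loss_branches)
            assert after <= base

    @pytest.mark.parametrize("n_leaves", [2, 3, 4])
    def test_exhaustive_small_trees_match_brute_force(self, n_leaves):
        """Loss count equals the enumeration minimum on every topology and
        every {0,1,?} column (small sizes; larger sweep in acceptance)."""
        import itertools

        leaves = [f"L{i}" for i in range(n_leaves)]
        for top in all_rooted_topologies(leaves):
            tree = dt.SpeciesTree.from_newick(topology_to_newick(top) + ";")
            for states in itertools.product((0, 1, "?"), repeat=n_leaves):
                column = dict(zip(leaves, states))
                expected = brute_force_min_dollo_losses(top, column)
                ev = dt.dollo_reconstruct(column, tree)
                if not any(s == 1 for s in states):
                    assert ev.gain_branch is None
                    continue
                assert len(ev.loss_branches) == expected


class TestSankoff:
    def test_cherry_single_change(self):
        tree = dt.SpeciesTree.from_newick("(A:1,B:1);")
        cost, _, _ = dt.sankoff_reconstruct({"A": 1, "B": 0}, tree, 1.0, 1.0)
        assert cost == 1.0

    def test_all_unknown_costs_nothing(self, mammal_tree):
        cost, _, ev = dt.sankoff_reconstruct({}, mammal_tree, 2.0, 1.0)
        assert cost == 0.0 and ev.gain_branch is None

    def test_prohibitive_regain_matches_dollo_fuzz(self, mammal_tree):
        import numpy as np

        rng = np.random.default_rng(11)
        leaves = mammal_tree.leaves()
        cost_loss = 1.0
        cost_gain = (1 + len(leaves)) * cost_loss
        for _ in range(300):
            column = {
                sp: v if v != 2 else "?"
                for sp, v in zip(leaves, rng.integers(0, 3, size=len(leaves)))
            }
            column = {k: int(v) if v != "?" else "?" for k, v in column.items()}
            dollo = dt.dollo_reconstruct(column, mammal_tree)
            _, _, sank = dt.sankoff_reconstruct(column, mammal_tree, cost_gain, cost_loss)
            assert sank.gain_branch == dollo.gain_branch
            assert sank.loss_branches == dollo.loss_branches

    def test_invalid_costs_rejected(self, mammal_tree):
        with pytest.raises(ValueError):
            dt.sankoff_reconstruct({"human": 1}, mammal_tree, 0.0, 1.0)


class TestCountIndependentLosses:
    def test_krt24_fixture_counts_three(self, mammal_tree, krt24_states):
        ev = dt.dollo_reconstruct(
            krt24_states.column("KRT24"), mammal_tree, ancestral_at_root=True
        )
        assert dt.count_independent_losses(ev, mammal_tree) == 3

    def test_empty_event_set_counts_zero(self):
        assert dt.count_independent_losses(dt.EventSet("g", None)) == 0

    def test_shared_lesion_merges_sister_losses(self, mammal_tree):
        # fur seal and sea lion lost independently per topology, but a
        # lesion at one conserved position collapses them onto their stem
        ev = dt.EventSet(
            gene="g", gain_branch=ROOT,
            loss_branches=frozenset({"fur_seal", "sea_lion"}),
        )
        merged = dt.count_independent_losses(
            ev, mammal_tree, shared_groups=[{"fur_seal", "sea_lion"}]
        )
        assert merged == 1


class TestDating:
    def test_terminal_edge_interval(self, mammal_tree):
        assert dt.date_event("dolphin", mammal_tree) == (32.0, 0.0)

    def test_internal_edge_interval_from_summed_lengths(self, mammal_tree):
        assert dt.date_event("Cetacea", mammal_tree) == (54.0, 32.0)
        assert dt.date_event("Otaroidea", mammal_tree) == (24.0, 19.0)
        assert dt.date_event("Camelus", mammal_tree) == (25.0, 5.0)

    def test_zero_length_edge_degenerate_interval(self):
        t = dt.SpeciesTree.from_newick("((A:1,B:1)X:0,C:1)R;")
        assert dt.date_event("X", t) == (1.0, 1.0)

    def test_bounds_are_sane_for_all_fixture_events(self, mammal_tree, krt24_states):
        ev = dt.dollo_reconstruct(
            krt24_states.column("KRT24"), mammal_tree, ancestral_at_root=True
        )
        root_age = mammal_tree.root_age()
        for edge in ev.loss_branches:
            older, younger = dt.date_event(edge, mammal_tree)
            assert older >= younger >= 0.0
            assert older <= root_age

    def test_missing_lengths_signal(self):
        t = dt.SpeciesTree.from_newick("((A,B),C);")
        with pytest.raises(ValueError, match="dating"):
            dt.date_event("A", t)


class TestEventsReport:
    def test_human_lineage_lost_two_genes(self, mammal_tree, fig4_states):
        table, events = dt.events_report(
            fig4_states, mammal_tree, ancestral_at_root=["KRT224"]
        )
        human_path = set(mammal_tree.path_to_root("human"))
        lost = {g for g, ev in events.items() if ev.loss_branches & human_path}
        assert {"KRT223", "KRT224"} <= lost

    def test_all_present_gene_single_gain_row(self, mammal_tree):
        import pandas as pd

        states = pd.DataFrame(
            {"G": ["INTACT"] * len(mammal_tree.leaves())},
            index=mammal_tree.leaves(),
        )
        table, events = dt.events_report(dt.PresenceMatrix(states), mammal_tree)
        assert len(table) == 1
        assert table.iloc[0].event == "gain"
        assert events["G"].loss_branches == frozenset()

    def test_row_order_is_deterministic(self, mammal_tree, fig4_states):
        t1, _ = dt.events_report(fig4_states, mammal_tree)
        t2, _ = dt.events_report(fig4_states, mammal_tree)
        assert t1.equals(t2)
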