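"""Token scoring, pairwise/profile Needleman–Wunsch and progressive alignment."""

from __future__ import annotations

import random

import pytest

from oracles import brute_force_nw_score, random_token_string
from synfam.io_formats import GeneLocus, GeneOrders, OrthogroupTable, read_newick
from synfam.synteny_align import (
    GAP,
    NeighborhoodString,
    ProfileRow,
    ScoringScheme,
    SyntenyProfile,
    SyntenyToken,
    align_profiles,
    extract_neighborhood,
    pairwise_nw,
    profile_column_score,
    progressive_align,
    token_score,
)

SCHEME = ScoringScheme()


def tok(gene, og=None, sub=None):
    return SyntenyToken(gene, og, sub)


def string_of(tokens, focal_index=0, sample="S", k=None):
    k = k if k is not None else len(tokens)
    return NeighborhoodString(
        focal_gene=tokens[focal_index].gene_id,
        sample_id=sample,
        k=k,
        tokens=tuple(tokens),
        focal_index=focal_index,
    )


def table_abc():
    return OrthogroupTable(
        groups={
            "OGA": {"S": ["x1"]},
            "OGB": {"S": ["x2"]},
            "OGC": {"S": ["x3"]},
        }
    )


class TestNeighborhoodExtraction:
    LOCI = [
        GeneLocus("x1", "S", "c1", 100, 190, "+", 0),
        GeneLocus("x2", "S", "c1", 300, 390, "-", 1),
        GeneLocus("x3", "S", "c1", 500, 590, "+", 2),
    ]

    def test_zero_radius_is_the_focal_gene_alone(self):
        nb = extract_neighborhood("x2", GeneOrders(self.LOCI), table_abc(), {}, 0)
        assert [t.gene_id for t in nb.tokens] == ["x2"]
        assert nb.focal_index == 0

    def test_contig_end_truncates_window(self):
        nb = extract_neighborhood(
            "x2", GeneOrders(self.LOCI), table_abc(), {}, 5, normalize_strand=False
        )
        assert [t.gene_id for t in nb.tokens] == ["x1", "x2", "x3"]
        assert nb.focal_index == 1

    def test_minus_strand_focal_reverses_tokens(self):
        nb = extract_neighborhood("x2", GeneOrders(self.LOCI), table_abc(), {}, 5)
        assert [t.gene_id for t in nb.tokens] == ["x3", "x2", "x1"]
        assert nb.focal_index == 1

    def test_tokens_carry_orthogroup_and_subcluster_labels(self):
        nb = extract_neighborhood(
            "x2", GeneOrders(self.LOCI), table_abc(), {"x1": "OGA.0"}, 5
        )
        by_gene = {t.gene_id: t for t in nb.tokens}
        assert by_gene["x1"].orthogroup_id == "OGA"
        assert by_gene["x1"].subcluster_id == "OGA.0"
        assert by_gene["x2"].subcluster_id is None

    def test_unassigned_gene_gets_null_orthogroup(self):
        loci = self.LOCI + [GeneLocus("orphan", "S", "c1", 700, 790, "+", 3)]
        nb = extract_neighborhood("x3", GeneOrders(loci), table_abc(), {}, 1)
        orphan = [t for t in nb.tokens if t.gene_id == "orphan"][0]
        assert orphan.orthogroup_id is None

    def test_missing_locus_is_an_error(self):
        with pytest.raises(KeyError, match="no locus"):
            extract_neighborhood("nope", GeneOrders(self.LOCI), table_abc(), {}, 2)


class TestTokenScore:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (tok("g1", "OG7", "OG7.2"), tok("g2", "OG7", "OG7.2"), 2.0),
            (tok("g1", "OG7", "OG7.1"), tok("g2", "OG7", "OG7.2"), 1.0),
            (tok("g1", "OG7"), tok("g2", "OG7"), 1.0),
            (tok("g1"), tok("g2", "OG7", "OG7.1"), -1.0),
            (tok("g1"), tok("g2"), -1.0),
            (tok("g1", "OG7"), GAP, -1.0),
            (GAP, GAP, 0.0),
        ],
    )
    def test_match_categories(self, a, b, expected):
        assert token_score(a, b, SCHEME) == expected

    def test_scheme_ordering_enforced(self):
        with pytest.raises(ValueError):
            ScoringScheme(s_match=-2.0)
        with pytest.raises(ValueError):
            ScoringScheme(s_gap=0.5)
        with pytest.raises(ValueError):
            ScoringScheme(s_gapgap=1.0)

    def test_subcluster_must_extend_orthogroup(self):
        with pytest.raises(ValueError):
            SyntenyToken("g", "OG1", "OG2.0")


class TestPairwiseNW:
    def test_self_alignment_is_gap_free_and_perfect(self):
        tokens = [tok(f"g{i}", "OG1", "OG1.0") for i in range(4)]
        prof = pairwise_nw(string_of(tokens), string_of(tokens), SCHEME)
        assert prof.score == 4 * SCHEME.s_perfect
        assert all(c is not GAP for row in prof.cells for c in row)

    def test_single_deletion_scores_two_matches_and_one_gap(self):
        abc = [tok("a", "OGA", "OGA.0"), tok("b", "OGB", "OGB.0"), tok("c", "OGC", "OGC.0")]
        ac = [tok("a2", "OGA", "OGA.0"), tok("c2", "OGC", "OGC.0")]
        prof = pairwise_nw(string_of(abc), string_of(ac), SCHEME)
        assert prof.score == 3.0
        assert prof.score == brute_force_nw_score(abc, ac, SCHEME)
        assert prof.cells[1][1] is GAP  # the gap sits at the missing middle token

    def test_score_is_symmetric(self):
        rng = random.Random(0)
        for _ in range(50):
            s1 = string_of(random_token_string(rng, rng.randint(1, 6)))
            s2 = string_of(random_token_string(rng, rng.randint(1, 6)))
            assert pairwise_nw(s1, s2, SCHEME).score == pairwise_nw(s2, s1, SCHEME).score

    def test_optimal_against_bruteforce(self):
        rng = random.Random(1)
        for _ in range(60):
            t1 = random_token_string(rng, rng.randint(1, 6))
            t2 = random_token_string(rng, rng.randint(1, 6))
            got = pairwise_nw(string_of(t1), string_of(t2), SCHEME).score
            assert got == pytest.approx(brute_force_nw_score(t1, t2, SCHEME))

    def test_empty_profile_rejected(self):
        good = pairwise_nw(string_of([tok("a", "OGA")]), string_of([tok("b", "OGB")]))
        with pytest.raises(ValueError):
            align_profiles(good, SyntenyProfile(rows=[], cells=[]))


class TestProfileColumnScore:
    def test_one_by_one_reduces_to_token_score(self):
        a, b = tok("g1", "OG1", "OG1.0"), tok("g2", "OG1", "OG1.1")
        assert profile_column_score([a], [b], SCHEME) == token_score(a, b, SCHEME)

    def test_token_plus_gap_column(self):
        col1 = [tok("g1", "OG1", "OG1.0"), GAP]
        col2 = [tok("g2", "OG1", "OG1.0")]
        assert profile_column_score(col1, col2, SCHEME) == SCHEME.s_perfect + SCHEME.s_gap

    def test_all_gap_column_costs_gap_per_token(self):
        col2 = [tok("a", "OG1"), tok("b", "OG2"), tok("c", None)]
        assert profile_column_score([GAP, GAP], col2, SCHEME) == 2 * 3 * SCHEME.s_gap


class TestAlignProfiles:
    def test_identical_single_row_profiles_gain_no_gaps(self):
        tokens = [tok(f"g{i}", "OG1", "OG1.0") for i in range(3)]
        p1 = pairwise_nw(string_of(tokens), string_of(tokens), SCHEME)
        merged = align_profiles(p1, pairwise_nw(string_of(tokens), string_of(tokens)), SCHEME)
        assert merged.n_columns == 3
        assert all(c is not GAP for row in merged.cells for c in row)

    def test_row_order_is_p1_then_p2(self):
        t1 = [tok("a", "OGA")]
        t2 = [tok("b", "OGB")]
        p = align_profiles(
            pairwise_nw(string_of(t1, sample="X"), string_of(t1, sample="Y")),
            pairwise_nw(string_of(t2, sample="Z"), string_of(t2, sample="W")),
        )
        assert [r.sample_id for r in p.rows] == ["X", "Y", "Z", "W"]

    def test_third_row_joins_existing_gap_column(self):
        abc = [tok("a", "OGA", "OGA.0"), tok("b", "OGB", "OGB.0"), tok("c", "OGC", "OGC.0")]
        ac = [tok("a2", "OGA", "OGA.0"), tok("c2", "OGC", "OGC.0")]
        abc2 = [tok("a3", "OGA", "OGA.0"), tok("b3", "OGB", "OGB.0"), tok("c3", "OGC", "OGC.0")]
        two = pairwise_nw(string_of(abc), string_of(ac), SCHEME)
        fresh = SyntenyProfile(rows=[ProfileRow("a3", "S", 0)], cells=[list(abc2)])
        three = align_profiles(two, fresh, SCHEME)
        assert three.n_columns == 3  # B column absorbs the new B token
        assert three.cells[2][1].gene_id == "b3"
        assert three.cells[1][1] is GAP

    def test_projection_recovers_each_input_row(self):
        rng = random.Random(2)
        for _ in range(30):
            strings = [
                string_of(random_token_string(rng, rng.randint(1, 6)))
                for _ in range(3)
            ]
            p = align_profiles(
                pairwise_nw(strings[0], strings[1], SCHEME),
                SyntenyProfile(
                    rows=[ProfileRow(strings[2].focal_gene, "S", 0)],
                    cells=[list(strings[2].tokens)],
                ),
                SCHEME,
            )
            for i, s in enumerate(strings):
                assert p.row_tokens(i) == list(s.tokens)


def make_progressive_case(orders_rows, tree_newick, table, k=5):
    orders = GeneOrders(orders_rows)
    tree = read_newick(tree_newick)
    nbs = {
        l.taxon.label: extract_neighborhood(l.taxon.label, orders, table, {}, k)
        for l in tree.leaf_node_iter()
        if l.taxon.label in orders
    }
    return tree, nbs


class TestProgressiveAlign:
    def test_single_leaf_tree_is_the_neighborhood_itself(self):
        tokens = [tok("a", "OGA"), tok("b", "OGB")]
        s = string_of(tokens, focal_index=0)
        tree = read_newick("(a:0.1);")
        prof = progressive_align(tree, {"a": s}, SCHEME)
        assert prof.cells == [list(tokens)]
        assert prof.total_score == 0.0

    def test_two_leaf_tree_reduces_to_pairwise(self):
        rng = random.Random(4)
        s1 = string_of(random_token_string(rng, 5), sample="A")
        s2 = string_of(random_token_string(rng, 4), sample="B")
        tree = read_newick("(x:0.1,y:0.1);")
        prof = progressive_align(tree, {"x": s1, "y": s2}, SCHEME)
        pw = pairwise_nw(s1, s2, SCHEME)
        assert prof.cells == pw.cells and prof.score == pw.score

    def test_row_order_follows_tree_leaf_order(self, planted_events):
        from synfam.cli import load_inputs
        from synfam.tree_ops import assign_subclusters

        result, info = planted_events
        table, trees, _, _, orders = load_inputs(result.out_dir)
        tree = trees[info["focal_og"]]
        labels = assign_subclusters(tree, 0.5, info["focal_og"]).labels
        nbs = {
            l.taxon.label: extract_neighborhood(l.taxon.label, orders, table, labels, 5)
            for l in tree.leaf_node_iter()
        }
        prof = progressive_align(tree, nbs, SCHEME)
        assert [r.focal_gene for r in prof.rows] == [
            l.taxon.label for l in tree.leaf_node_iter()
        ]

    def test_leaves_without_neighborhood_are_dropped_with_warning(self, caplog):
        tokens = [tok("a", "OGA")]
        tree = read_newick("(x:0.1,y:0.1);")
        with caplog.at_level("WARNING"):
            prof = progressive_align(tree, {"x": string_of(tokens)}, SCHEME)
        assert len(prof.rows) == 1
        assert any("dropping" in r.message for r in caplog.records)

    def test_no_neighborhood_at_all_is_an_error(self):
        with pytest.raises(ValueError):
            progressive_align(read_newick("(x:1,y:1);"), {}, SCHEME)

    def test_total_score_equals_sum_of_pairs_of_final_matrix(self, sim_inputs):
        from synfam.tree_ops import assign_subclusters

        table, trees, _, _, orders = sim_inputs
        subs = {}
        for og, t in trees.items():
            subs.update(assign_subclusters(t, 0.5, og).labels)
        checked = 0
        for og in list(trees)[:6]:
            tree = trees[og]
            nbs = {
                l.taxon.label: extract_neighborhood(
                    l.taxon.label, orders, table, subs, 4
                )
                for l in tree.leaf_node_iter()
                if l.taxon.label in orders
            }
            if not nbs:
                continue
            prof = progressive_align(tree, nbs, SCHEME)
            n = len(prof.rows)
            sp = sum(
                token_score(prof.cells[i][j], prof.cells[k][j], SCHEME)
                for j in range(prof.n_columns)
                for i in range(n)
                for k in range(i + 1, n)
            )
            assert prof.total_score == pytest.approx(sp, abs=1e-9)
            checked += 1
        assert checked >= 3

    def test_tandem_duplication_creates_private_adjacent_column(self, planted_events):
        from synfam.cli import load_inputs
        from synfam.tree_ops import assign_subclusters

        result, info = planted_events
        table, trees, _, _, orders = load_inputs(result.out_dir)
        subs = {}
        for og, t in trees.items():
            subs.update(assign_subclusters(t, 0.5, og).labels)
        tree = trees[info["focal_og"]]
        nbs = {
            l.taxon.label: extract_neighborhood(l.taxon.label, orders, table, subs, 5)
            for l in tree.leaf_node_iter()
        }
        prof = progressive_align(tree, nbs, SCHEME)
        dup_row = [
            i for i, r in enumerate(prof.rows) if r.sample_id == info["dup_sample"]
        ][0]
        private = [
            j
            for j in range(prof.n_columns)
            if prof.cells[dup_row][j] is not GAP
            and all(
                prof.cells[i][j] is GAP
                for i in range(len(prof.rows))
                if i != dup_row
            )
        ]
        assert len(private) == 1
        assert abs(private[0] - prof.focal_column) == 1
        # the two tandem copies sit in adjacent columns of the duplicated row
        cols = [
            j
            for j in range(prof.n_columns)
            if prof.cells[dup_row][j] is not GAP
            and prof.cells[dup_row][j].orthogroup_id == info["dup_og"]
        ]
        assert len(cols) == 2 and cols[1] - cols[0] == 1

    def test_identical_inputs_give_identical_profiles(self, sim_inputs):
        from synfam.tree_ops import assign_subclusters

        table, trees, _, _, orders = sim_inputs
        og = list(trees)[0]
        subs = assign_subclusters(trees[og], 0.5, og).labels

        def run():
            nbs = {
                l.taxon.label: extract_neighborhood(
                    l.taxon.label, orders, table, subs, 5
                )
                for l in trees[og].leaf_node_iter()
                if l.taxon.label in orders
            }
            return progressive_align(trees[og], nbs, SCHEME).to_tsv()

        assert run() == run()
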