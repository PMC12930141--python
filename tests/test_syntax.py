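"""Delexicalization, Subset Tree Kernel, core dependencies, POS-LCS."""

import itertools
from collections import Counter

import numpy as np
import pytest

from gazelang.data_io import DepNode, DepTree
from gazelang.syntax import (
    KernelConfig,
    StructNode,
    core_dep_sequence,
    delexicalize,
    normalized_sst,
    pairwise_normalized_sst,
    parse_bracket,
    pos_lcs_similarity,
    pos_sequence,
    sst_kernel,
    tabulate_word_orders,
    to_bracket,
)

# ---------------------------------------------------------------------------
# Independent oracle: exhaustive fragment enumeration
# ---------------------------------------------------------------------------


def frag_sigs(node):
    """All SST fragments rooted at this node (the root is expanded; each
    child is independently cut at its label or expanded further)."""
    if not node.children:
        return [(node.label, ())]
    child_opts = [
        [(c.label, None)] + frag_sigs(c) for c in node.children
    ]
    return [(node.label, tuple(combo)) for combo in itertools.product(*child_opts)]


def expanded_count(sig):
    label, kids = sig
    if kids is None:
        return 0
    return 1 + sum(expanded_count(k) for k in kids)


def sst_oracle(t1, t2, lam):
    c1, c2 = Counter(), Counter()
    for n in t1.iter_nodes():
        c1.update(frag_sigs(n))
    for n in t2.iter_nodes():
        c2.update(frag_sigs(n))
    return float(sum(c1[s] * c2[s] * lam ** expanded_count(s) for s in c1 if s in c2))


def random_tree(rng, max_nodes=6, labels="xyz"):
    """Random ordered tree over a tiny label alphabet (so matches occur)."""
    n = int(rng.integers(1, max_nodes + 1))
    budget = [n - 1]

    def grow():
        label = labels[int(rng.integers(len(labels)))]
        kids = []
        while budget[0] > 0 and rng.random() < 0.6:
            budget[0] -= 1
            kids.append(grow())
        return StructNode(label, tuple(kids))

    return grow()


# ---------------------------------------------------------------------------


class TestDelexicalize:
    def test_svo_with_head_marker(self, worked):
        assert to_bracket(delexicalize(worked.svo_tree)) == "(ROOT (nsubj) (HEAD) (dobj))"

    def test_sov_head_marker_final(self, worked):
        assert to_bracket(delexicalize(worked.sov_tree)) == "(ROOT (nsubj) (dobj) (HEAD))"

    def test_single_word_utterance(self):
        tree = DepTree([DepNode(1, 0, "root", word="dog", upos="NOUN")])
        assert to_bracket(delexicalize(tree)) == "(ROOT)"

    def test_order_differs_between_templates(self, worked):
        assert delexicalize(worked.svo_tree) != delexicalize(worked.sov_tree)

    def test_nested_children_ordered_by_token_index(self):
        # "the dog sees max": det attaches under nsubj
        tree = DepTree([
            DepNode(1, 2, "det"), DepNode(2, 3, "nsubj"),
            DepNode(3, 0, "root"), DepNode(4, 3, "obj"),
        ])
        assert to_bracket(delexicalize(tree)) == "(ROOT (nsubj (det) (HEAD)) (HEAD) (dobj))"


class TestBracket:
    def test_roundtrip(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            t = random_tree(rng)
            assert parse_bracket(to_bracket(t)) == t


class TestSstKernel:
    def test_identical_single_production_lambda_one(self):
        t = parse_bracket("(ROOT (nsubj) (dobj))")
        cfg = KernelConfig(decay=1.0)
        # root fragments: 1*(1+1)(1+1)=4; leaf matches contribute 1 each
        assert sst_kernel(t, t, cfg) == pytest.approx(6.0)
        assert sst_oracle(t, t, 1.0) == pytest.approx(6.0)

    def test_order_swap_loses_root_fragments(self):
        t1 = parse_bracket("(ROOT (nsubj) (dobj))")
        t2 = parse_bracket("(ROOT (dobj) (nsubj))")
        cfg = KernelConfig(decay=1.0)
        assert sst_kernel(t1, t2, cfg) == pytest.approx(2.0)  # only the two leaves

    def test_disjoint_labels_zero(self):
        t1 = parse_bracket("(a (b) (c))")
        t2 = parse_bracket("(x (y) (z))")
        assert sst_kernel(t1, t2, KernelConfig()) == 0.0

    def test_matches_fragment_enumeration_oracle(self):
        rng = np.random.default_rng(11)
        cfg = KernelConfig(decay=0.4)
        for _ in range(200):
            t1, t2 = random_tree(rng), random_tree(rng)
            assert sst_kernel(t1, t2, cfg) == pytest.approx(
                sst_oracle(t1, t2, 0.4), rel=1e-9
            )

    def test_symmetry(self):
        rng = np.random.default_rng(4)
        cfg = KernelConfig()
        for _ in range(30):
            t1, t2 = random_tree(rng), random_tree(rng)
            assert sst_kernel(t1, t2, cfg) == pytest.approx(sst_kernel(t2, t1, cfg))

    def test_decay_monotonicity(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            t1, t2 = random_tree(rng), random_tree(rng)
            vals = [
                sst_kernel(t1, t2, KernelConfig(decay=lam))
                for lam in (0.1, 0.4, 0.7, 1.0)
            ]
            assert all(a <= b + 1e-12 for a, b in zip(vals, vals[1:]))


class TestNormalizedSst:
    def test_identical_trees_score_one(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            t = random_tree(rng)
            assert normalized_sst(t, t) == pytest.approx(1.0)

    def test_disjoint_label_trees_score_zero(self):
        t1 = parse_bracket("(a (b))")
        t2 = parse_bracket("(x (y))")
        assert normalized_sst(t1, t2) == 0.0

    def test_values_in_unit_interval_and_match_oracle(self):
        rng = np.random.default_rng(21)
        cfg = KernelConfig(decay=0.4)
        for _ in range(60):
            t1, t2 = random_tree(rng), random_tree(rng)
            got = normalized_sst(t1, t2, cfg)
            expect = sst_oracle(t1, t2, 0.4) / np.sqrt(
                sst_oracle(t1, t1, 0.4) * sst_oracle(t2, t2, 0.4)
            )
            assert got == pytest.approx(expect, rel=1e-9)
            assert -1e-12 <= got <= 1 + 1e-12

    def test_order_swap_scores_below_identical(self):
        t1 = parse_bracket("(ROOT (nsubj) (HEAD) (dobj))")
        t2 = parse_bracket("(ROOT (nsubj) (dobj) (HEAD))")
        s_swap = normalized_sst(t1, t2)
        assert s_swap < 1.0
        assert s_swap < normalized_sst(t1, t1)

    def test_gram_matrix_positive_semidefinite(self):
        rng = np.random.default_rng(13)
        trees = [random_tree(rng) for _ in range(10)]
        gram = pairwise_normalized_sst(trees)
        eigvals = np.linalg.eigvalsh(gram)
        assert eigvals.min() >= -1e-9

    def test_pairwise_matrix_matches_scalar_path(self):
        rng = np.random.default_rng(17)
        trees = [random_tree(rng) for _ in range(6)]
        mat = pairwise_normalized_sst(trees)
        for i in range(6):
            for j in range(6):
                assert mat[i, j] == pytest.approx(normalized_sst(trees[i], trees[j]))


class TestCoreDependencies:
    def test_worked_examples(self, worked):
        assert core_dep_sequence(worked.svo_tree) == ["nsubj", "ROOT", "dobj"]
        assert core_dep_sequence(worked.sov_tree) == ["nsubj", "dobj", "ROOT"]

    def test_modifier_only_tree(self):
        tree = DepTree([
            DepNode(1, 2, "det"), DepNode(2, 0, "root"), DepNode(3, 2, "amod"),
        ])
        assert core_dep_sequence(tree) == ["ROOT"]

    def test_exactly_one_root_per_tree(self, small_bundle):
        for tree in small_bundle.trees.values():
            assert core_dep_sequence(tree).count("ROOT") == 1

    def test_alias_obj_counts_as_core(self):
        tree = DepTree([
            DepNode(1, 2, "nsubj"), DepNode(2, 0, "root"), DepNode(3, 2, "obj"),
        ])
        assert core_dep_sequence(tree) == ["nsubj", "ROOT", "dobj"]


class TestWordOrderTabulation:
    def test_identical_trees_collapse_to_one_row(self, worked):
        table = tabulate_word_orders({"en": [worked.svo_tree] * 3})
        assert len(table) == 1
        assert table.iloc[0]["sequence"] == "nsubj ROOT dobj"
        assert table.iloc[0]["count"] == 3

    def test_empty_language_group_yields_no_rows(self, worked):
        table = tabulate_word_orders({"en": [worked.svo_tree], "xx": []})
        assert set(table["language"]) == {"en"}

    def test_head_final_language_always_ends_in_root(self, small_bundle):
        ja = [
            tree for tid, tree in small_bundle.trees.items() if tid.startswith("ja")
        ]
        assert len(ja) > 0
        table = tabulate_word_orders({"ja": ja})
        assert all(seq.split()[-1] == "ROOT" for seq in table["sequence"])

    def test_top_k_truncation(self, small_bundle):
        langs = {"en": [t for i, t in small_bundle.trees.items() if i.startswith("en")]}
        table = tabulate_word_orders(langs, top_k=2)
        assert len(table) <= 2


class TestPosLcs:
    def test_identical_sequences(self):
        assert pos_lcs_similarity(["NOUN", "VERB"], ["NOUN", "VERB"]) == 1.0

    def test_hand_dynamic_program(self):
        got = pos_lcs_similarity(["NOUN", "VERB", "NOUN"], ["NOUN", "NOUN", "VERB"])
        assert got == pytest.approx(2 / 3)

    def test_empty_undefined(self):
        from gazelang.errors import SimilarityUndefinedError

        with pytest.raises(SimilarityUndefinedError):
            pos_lcs_similarity([], ["NOUN"])

    def test_pos_sequence_extraction(self, worked):
        assert pos_sequence(worked.svo_tree) == ["NOUN", "VERB", "NOUN"]
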