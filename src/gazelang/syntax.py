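"""Syntactic similarity via order-dependent Subset Tree Kernels.

Dependency parses are first *delexicalized*: words and POS tags are
discarded and each node is labeled only with its dependency relation (the
root token becomes "ROOT"). Children are ordered by the linear position of
the dependent tokens, and the head's own position within its dependents is
encoded by a reserved "HEAD" marker child inserted at the head token's
slot. A verb-medial clause therefore yields (ROOT (nsubj) (HEAD) (dobj))
while its verb-final counterpart yields (ROOT (nsubj) (dobj) (HEAD)), so
the kernel distinguishes SVO from SOV even with identical relation sets.

The Subset Tree Kernel (SST) counts tree fragments shared by two trees,
where a fragment keeps either all of a node's children or none of them.
Matching is all-or-none over the full ordered child-label list, which makes
the similarity order-dependent. A decay factor lambda in (0, 1] discounts
large fragments; the kernel is normalized to [0, 1] by
K(t1,t2)/sqrt(K(t1,t1) K(t2,t2)).

The module also extracts core-dependency label sequences ("nsubj ROOT
dobj") used to tabulate word-order profiles per language, and a coarser
POS-sequence similarity that applies the LCS machinery to part-of-speech
token sequences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_io import DepTree, normalize_deprel
from .errors import ConfigError, SimilarityUndefinedError
from .scanpath import lcs_similarity

HEAD_MARKER = "HEAD"
ROOT_LABEL = "ROOT"

#: Obligatory grammatical relations retained by core-dependency extraction
#: (modifiers excluded); the older UD inventory, reached via the alias map.
CORE_DEPENDENCIES = frozenset(
    {"nsubj", "nsubjpass", "dobj", "iobj", "csubj", "csubjpass", "ccomp", "xcomp"}
)


@dataclass(frozen=True)
class StructNode:
    """Node of a delexicalized tree: relation label + ordered children."""

    label: str
    children: tuple["StructNode", ...] = ()

    def production(self) -> tuple[str, tuple[str, ...]]:
        return (self.label, tuple(c.label for c in self.children))

    def iter_nodes(self):
        yield self
        for c in self.children:
            yield from c.iter_nodes()

    def size(self) -> int:
        return 1 + sum(c.size() for c in self.children)


@dataclass(frozen=True)
class KernelConfig:
    """SST parameters: decay lambda in (0, 1] and output normalization."""

    decay: float = 0.4
    normalize: bool = True

    def __post_init__(self):
        if not (0 < self.decay <= 1):
            raise ConfigError(f"kernel decay must be in (0, 1], got {self.decay}")


# ---------------------------------------------------------------------------
# Delexicalization
# ---------------------------------------------------------------------------


def delexicalize(
    tree: DepTree,
    label_aliases: Mapping[str, str] | None = None,
) -> StructNode:
    """Strip words/POS from a dependency tree, keeping ordered relation labels.

    Every node with dependents receives a "HEAD" marker child at the head
    token's own linear slot, so head-medial and head-final constructions
    with identical dependents delexicalize to different ordered trees.
    """

    def build(index: int, label: str) -> StructNode:
        deps = tree.children(index)
        if not deps:
            return StructNode(label)
        slots: list[tuple[int, StructNode]] = [(index, StructNode(HEAD_MARKER))]
        for dep in deps:
            slots.append(
                (dep.index, build(dep.index, normalize_deprel(dep.deprel, label_aliases)))
            )
        slots.sort(key=lambda t: t[0])
        return StructNode(label, tuple(node for _, node in slots))

    return build(tree.root.index, ROOT_LABEL)


def to_bracket(node: StructNode) -> str:
    """Serialize as a bracketed string, e.g. ``(ROOT (nsubj) (HEAD) (dobj))``."""
    if not node.children:
        return f"({node.label})"
    inner = " ".join(to_bracket(c) for c in node.children)
    return f"({node.label} {inner})"


def parse_bracket(text: str) -> StructNode:
    """Inverse of `to_bracket`."""
    tokens = text.replace("(", " ( ").replace(")", " ) ").split()
    pos = 0

    def parse() -> StructNode:
        nonlocal pos
        if tokens[pos] != "(":
            raise ValueError(f"expected '(' at token {pos} of {text!r}")
        pos += 1
        label = tokens[pos]
        pos += 1
        children = []
        while tokens[pos] == "(":
            children.append(parse())
        if tokens[pos] != ")":
            raise ValueError(f"expected ')' at token {pos} of {text!r}")
        pos += 1
        return StructNode(label, tuple(children))

    node = parse()
    if pos != len(tokens):
        raise ValueError(f"trailing content in {text!r}")
    return node


# ---------------------------------------------------------------------------
# Subset Tree Kernel
# ---------------------------------------------------------------------------


def _delta(n1: StructNode, n2: StructNode, decay: float, memo: dict) -> float:
    key = (id(n1), id(n2))
    hit = memo.get(key)
    if hit is not None:
        return hit
    if n1.production() != n2.production():
        val = 0.0
    elif not n1.children:
        val = decay
    else:
        val = decay
        for c1, c2 in zip(n1.children, n2.children):
            val *= 1.0 + _delta(c1, c2, decay, memo)
    memo[key] = val
    return val


def sst_kernel(t1: StructNode, t2: StructNode, cfg: KernelConfig | None = None) -> float:
    """Raw SST kernel: sum of Delta over all node pairs.

    Delta(n1, n2) is 0 unless the two nodes share the same production
    (label plus full ordered child-label list); it is lambda for matching
    leaf productions and lambda * prod_i (1 + Delta(c1_i, c2_i)) for
    matching internal productions.
    """
    if cfg is None:
        cfg = KernelConfig()
    memo: dict = {}
    total = 0.0
    nodes2 = list(t2.iter_nodes())
    for n1 in t1.iter_nodes():
        p1 = n1.production()
        for n2 in nodes2:
            if p1 == n2.production():
                total += _delta(n1, n2, cfg.decay, memo)
    return total


def normalized_sst(
    t1: StructNode, t2: StructNode, cfg: KernelConfig | None = None
) -> float:
    """Kernel normalized to [0, 1]: K(t1,t2)/sqrt(K(t1,t1) K(t2,t2))."""
    if cfg is None:
        cfg = KernelConfig()
    k11 = sst_kernel(t1, t1, cfg)
    k22 = sst_kernel(t2, t2, cfg)
    if k11 <= 0 or k22 <= 0:
        raise SimilarityUndefinedError("self-kernel is zero; similarity undefined")
    return sst_kernel(t1, t2, cfg) / float(np.sqrt(k11 * k22))


def pairwise_normalized_sst(
    trees: Sequence[StructNode], cfg: KernelConfig | None = None
) -> np.ndarray:
    """Symmetric matrix of normalized SST similarities over all tree pairs.

    Generated studies repeat a modest set of structures, so results are
    cached by the trees' bracketed signatures.
    """
    if cfg is None:
        cfg = KernelConfig()
    sigs = [to_bracket(t) for t in trees]
    uniq: dict[str, StructNode] = {}
    for s, t in zip(sigs, trees):
        uniq.setdefault(s, t)
    self_k = {s: sst_kernel(t, t, cfg) for s, t in uniq.items()}
    cache: dict[tuple[str, str], float] = {}
    k = len(trees)
    out = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            key = (sigs[i], sigs[j]) if sigs[i] <= sigs[j] else (sigs[j], sigs[i])
            val = cache.get(key)
            if val is None:
                if sigs[i] == sigs[j]:
                    val = 1.0
                else:
                    val = sst_kernel(uniq[sigs[i]], uniq[sigs[j]], cfg) / float(
                        np.sqrt(self_k[sigs[i]] * self_k[sigs[j]])
                    )
                cache[key] = val
            out[i, j] = out[j, i] = val
    return out


# ---------------------------------------------------------------------------
# Core-dependency sequences and word-order tabulation
# ---------------------------------------------------------------------------


def core_dep_sequence(
    tree: DepTree,
    label_aliases: Mapping[str, str] | None = None,
) -> list[str]:
    """Core-dependency labels in surface (token) order, with ROOT for the root.

    Walks tokens left to right and keeps only the obligatory grammatical
    relations (CORE_DEPENDENCIES) plus the root token, so the sequence
    reflects the word order of the dependents, e.g. "nsubj ROOT dobj" for a
    transitive verb-medial clause and "nsubj dobj ROOT" for its head-final
    counterpart.
    """
    out = []
    for nd in tree.nodes:
        if nd.head == 0:
            out.append(ROOT_LABEL)
        else:
            label = normalize_deprel(nd.deprel, label_aliases)
            if label in CORE_DEPENDENCIES:
                out.append(label)
    return out


def tabulate_word_orders(
    trees_by_language: Mapping[str, Sequence[DepTree]],
    top_k: int | None = None,
    label_aliases: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Frequency table of core-dependency sequences per language.

    Returns columns (language, sequence, count) sorted by descending count
    within language; ``top_k`` truncates each language's list.
    """
    rows = []
    for lang, trees in trees_by_language.items():
        counts: dict[str, int] = {}
        for tree in trees:
            seq = " ".join(core_dep_sequence(tree, label_aliases))
            counts[seq] = counts.get(seq, 0) + 1
        ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        if top_k is not None:
            ordered = ordered[:top_k]
        rows.extend({"language": lang, "sequence": s, "count": c} for s, c in ordered)
    return pd.DataFrame(rows, columns=["language", "sequence", "count"])


def pos_sequence(tree: DepTree) -> list[str]:
    """UPOS tags in token order."""
    return [nd.upos for nd in tree.nodes]


def pos_lcs_similarity(pos_seq1: Sequence[str], pos_seq2: Sequence[str]) -> float:
    """Normalized LCS similarity over part-of-speech sequences."""
    if len(pos_seq1) == 0 or len(pos_seq2) == 0:
        raise SimilarityUndefinedError("POS-LCS undefined for empty sequences")
    return lcs_similarity(list(pos_seq1), list(pos_seq2))
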