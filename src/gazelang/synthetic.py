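"""Synthetic multilingual scene-description studies with planted structure.

The generator emulates a production study in which participants from
several language groups describe the same scenes while their gaze is
tracked. Its central assumption mirrors the analysis it exists to test:
each trial has a latent *message* — a sparse weighting over the scene's
objects plus a relation type — that lives in a language-independent space
and jointly drives three observable channels:

1. **Gaze**: a stochastic fixation walk over grid cells whose target
   distribution mixes the message objects' anchor cells (strength
   ``g_sem``) with uniform exploration noise. During the planning phase an
   additional ordering component (strength ``g_syn_before``) visits the
   message objects in the order the language template linearizes them.
2. **Embedding**: a shared cross-language linear map of the message into
   R^d plus Gaussian noise, so the same message expressed in different
   languages yields nearby embedding vectors.
3. **Utterance**: a dependency tree instantiated from the language's
   word-order template (strictly head-final for SOV, so the root token is
   always last), with per-trial complexity (modifiers, embedded clauses);
   the transcript is pseudo-words read off the tree.

Objects are drawn from a global pool with fixed anchor cells and fixed
semantic vectors, so scenes overlap in content and the semantic-gaze
coupling is recoverable both within and between scenes.

Setting ``g_sem = 0`` and ``g_syn_before = 0`` severs gaze from language
entirely, which is the null condition for the recovery tests.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .data_io import (
    DepNode,
    DepTree,
    EmbeddingVector,
    Fixation,
    Region,
    Trial,
    write_conllu,
    write_embeddings,
    write_fixation_table,
    write_region_map,
    write_utterance_table,
)
from .errors import ConfigError

SVO = "SVO"
SOV = "SOV"
V_INITIAL_MIX = "VIN"


@dataclass(frozen=True)
class LanguageSpec:
    """One language group: code, word-order template, mean utterance length."""

    code: str
    template: str
    during_mean_s: float
    spaces: bool = True  # whitespace-delimited orthography


#: Default 3-language design: a rigid SVO language, a strictly head-final
#: SOV language, and a verb-initial-leaning mix; mean utterance durations
#: (s) differ per language as they do in real production data.
DEFAULT_LANGUAGES: tuple[LanguageSpec, ...] = (
    LanguageSpec("en", SVO, 3.4, spaces=True),
    LanguageSpec("pt", V_INITIAL_MIX, 8.1, spaces=True),
    LanguageSpec("ja", SOV, 5.1, spaces=False),
)


@dataclass(frozen=True)
class SynthConfig:
    """Generator parameters; the defaults define the study conditions."""

    languages: tuple[LanguageSpec, ...] = DEFAULT_LANGUAGES
    n_participants_per_language: int = 8
    n_scenes: int = 12
    objects_per_scene: int = 4
    object_pool_size: int = 16
    n_cues: int = 8
    embedding_dim: int = 32
    g_sem: float = 0.8
    g_syn_before: float = 0.0
    noise_sd: float = 0.2
    before_mean_s: float = 3.0
    bin_ms: float = 25.0
    image_width: float = 1024.0
    image_height: float = 768.0
    n_cols: int = 6
    n_rows: int = 4
    fix_dur_shape: float = 4.0
    fix_dur_scale_ms: float = 62.5
    fix_dur_min_ms: float = 80.0
    saccade_ms: float = 30.0
    p_transitive: float = 0.5
    p_embedded: float = 0.15
    p_alternation: float = 0.25  # passive voice / object scrambling rate
    seed: int = 0

    def __post_init__(self):
        for name in ("n_participants_per_language", "n_scenes", "objects_per_scene",
                     "object_pool_size", "n_cues", "embedding_dim"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        for name in ("g_sem", "g_syn_before"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.objects_per_scene > self.n_cols * self.n_rows:
            raise ConfigError(
                f"objects_per_scene={self.objects_per_scene} exceeds the "
                f"{self.n_cols}x{self.n_rows} grid"
            )
        if self.object_pool_size < self.objects_per_scene:
            raise ConfigError("object pool smaller than objects_per_scene")


@dataclass
class StudyBundle:
    """Everything a study run consumes, in memory.

    ``messages`` records each trial's latent message (generator-internal
    ground truth, useful for diagnostics and recovery tests; it is not
    written to disk and is never visible to the analysis).
    """

    config: SynthConfig
    trials: list[Trial]
    embeddings: dict[str, EmbeddingVector]
    trees: dict[str, DepTree]
    region_map: dict[str, list[Region]]
    messages: dict[str, tuple] = None


# ---------------------------------------------------------------------------
# Dependency-tree templates
# ---------------------------------------------------------------------------


class _TNode:
    """Template-tree node with explicit pre-/post-head dependent lists."""

    __slots__ = ("deprel", "upos", "pre", "post")

    def __init__(self, deprel: str, upos: str):
        self.deprel = deprel
        self.upos = upos
        self.pre: list[_TNode] = []
        self.post: list[_TNode] = []


def _flatten(root: _TNode) -> list[tuple[_TNode, _TNode | None]]:
    out: list[tuple[_TNode, _TNode | None]] = []

    def walk(node: _TNode, parent: _TNode | None):
        for c in node.pre:
            walk(c, node)
        out.append((node, parent))
        for c in node.post:
            walk(c, node)

    walk(root, None)
    return out


_CONS = "bdgkmnprstz"
_VOWS = "aeiou"


def _pseudo_word(rng: np.random.Generator) -> str:
    n_syll = int(rng.integers(2, 4))
    return "".join(
        _CONS[int(rng.integers(len(_CONS)))] + _VOWS[int(rng.integers(len(_VOWS)))]
        for _ in range(n_syll)
    )


def _noun_phrase(rng: np.random.Generator, deprel: str, lang: LanguageSpec) -> _TNode:
    np_ = _TNode(deprel, "NOUN")
    if lang.spaces and rng.random() < 0.85:
        np_.pre.append(_TNode("det", "DET"))
    for _ in range(rng.poisson(0.5)):
        np_.pre.append(_TNode("amod", "ADJ"))
    if not lang.spaces:
        # postposed case particle (non-core, follows its noun)
        np_.post.append(_TNode("case", "ADP"))
    return np_


def _oblique_phrase(rng: np.random.Generator, lang: LanguageSpec) -> _TNode:
    """A locative/instrumental adjunct ("on the table"); non-core by design."""
    np_ = _noun_phrase(rng, "obl", lang)
    adp = _TNode("case", "ADP")
    if lang.spaces:
        np_.pre.insert(0, adp)  # preposition
    else:
        np_.post.append(adp)  # postposition
    return np_


def _clause(
    rng: np.random.Generator,
    lang: LanguageSpec,
    transitive: bool,
    deprel: str,
    allow_embedding: bool,
    p_embedded: float,
    variant: str = "active",
) -> _TNode:
    """One clause in the language's template order; SOV is strictly verb-final.

    ``variant`` selects within-language word-order alternations for
    transitive clauses: "passive" promotes the patient to subject
    (nsubjpass, short passive without an agent phrase), "scrambled" fronts
    the object in the head-final template.
    """
    verb = _TNode(deprel, "VERB")
    passive = transitive and variant == "passive"
    subj = _noun_phrase(rng, "nsubjpass" if passive else "nsubj", lang)
    obj = _noun_phrase(rng, "dobj", lang) if transitive and not passive else None
    if passive and lang.spaces:
        verb.pre.append(_TNode("auxpass", "AUX"))
    adv = _TNode("advmod", "ADV") if rng.random() < 0.4 else None
    obl = _oblique_phrase(rng, lang) if rng.random() < 0.6 else None
    embedded = None
    if allow_embedding and rng.random() < p_embedded:
        embedded = _clause(rng, lang, bool(rng.random() < 0.5), "ccomp",
                           allow_embedding=False, p_embedded=0.0)

    if lang.template == SOV:
        # all dependents precede the verb; nothing may follow it
        core = [subj] if obj is None else (
            [obj, subj] if variant == "scrambled" else [subj, obj]
        )
        verb.pre = core + verb.pre
        if adv is not None:
            verb.pre.append(adv)
        if obl is not None:
            verb.pre.insert(0, obl)
        if embedded is not None:
            verb.pre.insert(0, embedded)
        return verb

    predicative = lang.template == V_INITIAL_MIX and rng.random() < 0.5
    if predicative:
        # verb-initial: complements follow the root
        verb.post.append(subj)
        if obj is not None:
            verb.post.append(obj)
    else:
        verb.pre.insert(0, subj)
        if obj is not None:
            verb.post.append(obj)
    if adv is not None:
        verb.post.append(adv)
    if obl is not None:
        verb.post.append(obl)
    if embedded is not None:
        verb.post.append(embedded)
    return verb


def generate_tree(
    rng: np.random.Generator,
    lang: LanguageSpec,
    transitive: bool,
    trial_id: str,
    p_embedded: float = 0.15,
    variant: str = "active",
) -> DepTree:
    """Instantiate a dependency tree from the language's word-order template."""
    root = _clause(rng, lang, transitive, "root", True, p_embedded, variant)
    flat = _flatten(root)
    index_of = {id(node): i + 1 for i, (node, _) in enumerate(flat)}
    nodes = [
        DepNode(
            index=i + 1,
            head=0 if parent is None else index_of[id(parent)],
            deprel=node.deprel if parent is not None else "root",
            word=_pseudo_word(rng),
            upos=node.upos,
        )
        for i, (node, parent) in enumerate(flat)
    ]
    return DepTree(nodes=nodes, trial_id=trial_id)


# ---------------------------------------------------------------------------
# Study generation
# ---------------------------------------------------------------------------


def _cell_center(cfg: SynthConfig, cell: int) -> tuple[float, float]:
    col, row = cell % cfg.n_cols, cell // cfg.n_cols
    w, h = cfg.image_width / cfg.n_cols, cfg.image_height / cfg.n_rows
    return (col + 0.5) * w, (row + 0.5) * h


def _center_cell(cfg: SynthConfig) -> int:
    """The image-center cell: the stylized "action region" where the depicted
    interaction unfolds, shared by all scenes."""
    col = min(cfg.n_cols // 2, cfg.n_cols - 1)
    row = min(cfg.n_rows // 2, cfg.n_rows - 1)
    return row * cfg.n_cols + col


def _setting_cell(cfg: SynthConfig) -> int:
    """Top-left corner cell: the stylized scene-setting/background region."""
    return 0


def _plan_cells(tree: DepTree, region_of: dict[str, int], default_cell: int) -> list[int]:
    """Per-token dwell targets for the planning routine, in surface order.

    Each token inherits the region of its nearest ancestor (or itself)
    whose relation has a referent region; tokens outside any such
    constituent default to the action region.
    """
    cells = []
    for nd in tree.nodes:
        cur = nd
        cell = default_cell
        while True:
            key = "root" if cur.head == 0 else cur.deprel
            if key in region_of:
                cell = region_of[key]
                break
            if cur.head == 0:
                break
            cur = tree.nodes[cur.head - 1]
        cells.append(cell)
    return cells or [default_cell]


def _cell_rect(cfg: SynthConfig, cell: int) -> tuple[float, float, float, float]:
    col, row = cell % cfg.n_cols, cell // cfg.n_cols
    w, h = cfg.image_width / cfg.n_cols, cfg.image_height / cfg.n_rows
    return col * w, row * h, (col + 1) * w, (row + 1) * h


def generate_study(cfg: SynthConfig | None = None) -> StudyBundle:
    """Generate a complete study bundle (trials, embeddings, parses, regions)."""
    if cfg is None:
        cfg = SynthConfig()
    rng = np.random.default_rng(cfg.seed)
    d = cfg.embedding_dim
    n_cells = cfg.n_cols * cfg.n_rows

    # global object pool: fixed anchor cell + fixed unit semantic vector
    pool = cfg.object_pool_size
    anchor_cells = rng.choice(n_cells, size=pool, replace=pool > n_cells)
    obj_vecs = rng.normal(size=(pool, d))
    obj_vecs /= np.linalg.norm(obj_vecs, axis=1, keepdims=True)
    rel_vecs = rng.normal(size=(4, d))
    rel_vecs /= np.linalg.norm(rel_vecs, axis=1, keepdims=True)

    # scenes shared by all language groups; cues drawn from a smaller pool
    scene_objects = [
        rng.choice(pool, size=cfg.objects_per_scene, replace=False)
        for _ in range(cfg.n_scenes)
    ]
    cue_words = [f"cue{k:02d}" for k in range(cfg.n_cues)]
    region_map: dict[str, list[Region]] = {}
    for s in range(cfg.n_scenes):
        scene_id = f"s{s:02d}"
        regions = []
        for pri, obj in enumerate(scene_objects[s]):
            x0, y0, x1, y1 = _cell_rect(cfg, int(anchor_cells[obj]))
            regions.append(Region(f"obj{obj:02d}", x0, y0, x1, y1, priority=pri))
        region_map[scene_id] = regions

    cell_w = cfg.image_width / cfg.n_cols
    cell_h = cfg.image_height / cfg.n_rows

    trials: list[Trial] = []
    embeddings: dict[str, EmbeddingVector] = {}
    trees: dict[str, DepTree] = {}
    messages: dict[str, tuple] = {}

    for lang in cfg.languages:
        for p in range(cfg.n_participants_per_language):
            participant = f"{lang.code}_p{p:02d}"
            for s in range(cfg.n_scenes):
                scene_id = f"s{s:02d}"
                objs = scene_objects[s]

                # --- latent message ---
                transitive = bool(rng.random() < cfg.p_transitive)
                relation = int(rng.integers(2)) + (2 if transitive else 0)
                picks = rng.choice(len(objs), size=2, replace=False)
                agent = int(objs[picks[0]])
                patient = int(objs[picks[1]]) if transitive else None
                if transitive:
                    msg_objs = [agent, patient]
                    weights = np.array([0.65, 0.35])
                else:
                    msg_objs = [agent]
                    weights = np.array([1.0])

                # --- timings ---
                before_ms = max(1000.0, rng.normal(cfg.before_mean_s, 0.3 * cfg.before_mean_s) * 1000)
                during_ms = max(1500.0, rng.normal(lang.during_mean_s, 0.3 * lang.during_mean_s) * 1000)
                utt_onset = float(round(before_ms))
                utt_offset = float(round(before_ms + during_ms))

                # --- utterance: tree + transcript (built first; the planning-
                # phase gaze routine follows the planned structure) ---
                trial_id = f"{participant}:{scene_id}"
                variant = "active"
                if transitive:
                    u_var = rng.random()
                    if u_var < cfg.p_alternation:
                        variant = "scrambled" if lang.template == SOV else "passive"
                tree = generate_tree(
                    rng, lang, transitive, trial_id, cfg.p_embedded, variant
                )
                trees[trial_id] = tree

                # planning-phase scan routine: dwell over the planned
                # utterance token by token in surface order, each token at
                # its governing constituent's referent region (subjects at
                # the agent's region, objects/passive subjects at the
                # patient's, verbs and their adverbs at the action region,
                # obliques at the setting region), so phrase elaboration and
                # word order both shape the planning gaze profile
                agent_cell = int(anchor_cells[agent])
                patient_cell = int(anchor_cells[patient]) if transitive else agent_cell
                region_of = {
                    "nsubj": agent_cell,
                    "nsubjpass": patient_cell,
                    "dobj": patient_cell,
                    "root": _center_cell(cfg),
                    "ccomp": _center_cell(cfg),
                    "xcomp": _center_cell(cfg),
                    "obl": _setting_cell(cfg),
                }
                plan_cells = _plan_cells(tree, region_of, _center_cell(cfg))

                # --- gaze walk ---
                fixations: list[Fixation] = []
                t = 0.0
                while t < utt_offset:
                    u = rng.random()
                    in_before = t < utt_onset
                    if in_before and u < cfg.g_syn_before:
                        frac = t / utt_onset
                        idx = min(int(frac * len(plan_cells)), len(plan_cells) - 1)
                        cell = plan_cells[idx]
                    elif u < cfg.g_syn_before * in_before + (1 - cfg.g_syn_before * in_before) * cfg.g_sem:
                        obj = msg_objs[int(rng.choice(len(msg_objs), p=weights))]
                        cell = int(anchor_cells[obj])
                    else:
                        cell = int(rng.integers(n_cells))
                    cx, cy = _cell_center(cfg, cell)
                    x = float(np.clip(cx + rng.normal(0, cell_w / 6), 0, cfg.image_width))
                    y = float(np.clip(cy + rng.normal(0, cell_h / 6), 0, cfg.image_height))
                    dur = cfg.fix_dur_min_ms + rng.gamma(cfg.fix_dur_shape, cfg.fix_dur_scale_ms)
                    fixations.append(Fixation(x=x, y=y, t_start=t, t_end=t + dur))
                    t += dur + cfg.saccade_ms

                sep = " " if lang.spaces else ""
                trial = Trial(
                    participant_id=participant,
                    scene_id=scene_id,
                    language_code=lang.code,
                    cue_word=cue_words[s % cfg.n_cues],
                    utt_onset=utt_onset,
                    utt_offset=utt_offset,
                    transcript=sep.join(nd.word for nd in tree.nodes),
                    fixations=fixations,
                    image_width=cfg.image_width,
                    image_height=cfg.image_height,
                )
                trials.append(trial)

                # --- embedding: shared cross-language map of the message ---
                e = weights @ obj_vecs[msg_objs] + 0.4 * rel_vecs[relation]
                e = e + rng.normal(0, cfg.noise_sd / np.sqrt(d), size=d)
                embeddings[trial_id] = EmbeddingVector(trial_id=trial_id, values=e)
                messages[trial_id] = (scene_id, relation, agent, patient)

    return StudyBundle(
        config=cfg,
        trials=trials,
        embeddings=embeddings,
        trees=trees,
        region_map=region_map,
        messages=messages,
    )


def write_study(bundle: StudyBundle, out_dir) -> dict[str, str]:
    """Write a bundle to disk in every external format, plus a manifest.

    Returns the path map written into the manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fixations": str(out / "fixations.tsv"),
        "utterances": str(out / "utterances.tsv"),
        "embeddings": str(out / "embeddings.tsv"),
        "parses": str(out / "parses.conllu"),
        "regions": str(out / "regions.tsv"),
    }
    write_fixation_table(bundle.trials, paths["fixations"])
    write_utterance_table(bundle.trials, paths["utterances"])
    order = [t.trial_id for t in bundle.trials]
    write_embeddings([bundle.embeddings[tid] for tid in order], paths["embeddings"])
    write_conllu([bundle.trees[tid] for tid in order], paths["parses"])
    write_region_map(bundle.region_map, paths["regions"])
    manifest = {
        "config": dataclasses.asdict(bundle.config),
        "paths": paths,
        "n_trials": len(bundle.trials),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return paths


# ---------------------------------------------------------------------------
# Worked micro-fixtures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WorkedFixture:
    """Tiny printable examples exercised by the worked-example tests."""

    lcs_pair: tuple[str, str]
    svo_tree: DepTree
    sov_tree: DepTree


def generate_worked_fixture() -> WorkedFixture:
    """The canonical micro-examples: an LCS string pair whose LCS is "BCAB",
    a transitive verb-medial parse whose core-dependency sequence is
    "nsubj ROOT dobj", and its verb-final counterpart, "nsubj dobj ROOT".
    """
    svo = DepTree(
        nodes=[
            DepNode(1, 2, "nsubj", word="sam", upos="NOUN"),
            DepNode(2, 0, "root", word="sees", upos="VERB"),
            DepNode(3, 2, "dobj", word="max", upos="NOUN"),
        ],
        trial_id="worked_svo",
    )
    sov = DepTree(
        nodes=[
            DepNode(1, 3, "nsubj", word="sam", upos="NOUN"),
            DepNode(2, 3, "dobj", word="max", upos="NOUN"),
            DepNode(3, 0, "root", word="miru", upos="VERB"),
        ],
        trial_id="worked_sov",
    )
    return WorkedFixture(lcs_pair=("ABCBDAB", "BDCABC"), svo_tree=svo, sov_tree=sov)
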