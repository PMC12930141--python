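"""End-to-end orchestration: load -> encode -> filter -> pair -> fit -> report.

A single `StudyConfig` names every input file and parameter; `run_all`
executes the whole analysis deterministically given the config and its
seed, returning the long pair table, the fitted association model, the
descriptive summaries, and a log of exclusions and clamped fixations.
Intermediate stages are exposed individually so the CLI subcommands can be
composed by hand with identical results.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import data_io, pairing, scanpath, semantics, syntax
from .data_io import DepTree, EmbeddingVector, Trial
from .errors import ConfigError, DataError
from .inference import (
    ModelFit,
    binned_summary,
    fit_association_model,
    phase_association,
    similarity_correlation,
)
from .scanpath import BEFORE, DURING, GridSpec
from .synthetic import StudyBundle

logger = logging.getLogger(__name__)


@dataclass
class StudyConfig:
    """All file paths and parameters of one analysis run."""

    fixations: str = ""
    utterances: str = ""
    embeddings: str = ""
    parses: str = ""
    regions: str = ""          # optional; required for roi encoding
    encoding: str = "grid"     # "grid" | "roi"
    n_cols: int = 6
    n_rows: int = 4
    bin_ms: float = 25.0
    kernel_decay: float = 0.4
    min_words: int = 4
    max_words: int = 77
    length_mode: str = "absolute"
    min_fixations: int = 2
    similarity: str = "dot"    # "dot" | "cosine"
    shuffle: bool = False
    seed: int = 1
    out_dir: str = ""

    @classmethod
    def from_file(cls, path) -> "StudyConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        with open(path) as fh:
            raw = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**raw)
        # input paths are resolved relative to the config file
        base = path.parent
        for name in ("fixations", "utterances", "embeddings", "parses", "regions"):
            val = getattr(cfg, name)
            if val and not Path(val).is_absolute():
                setattr(cfg, name, str(base / val))
        return cfg

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


@dataclass
class RunResult:
    """Outputs of one full pipeline run."""

    pair_table: pd.DataFrame
    fit: ModelFit | None
    binned_sem: pd.DataFrame
    binned_syn: pd.DataFrame
    correlations: dict
    syntax_phase_association: dict
    word_orders: pd.DataFrame
    exclusions: pd.DataFrame
    log: dict = field(default_factory=dict)


def load_study(cfg: StudyConfig) -> tuple[list[Trial], dict[str, EmbeddingVector], dict[str, DepTree], dict | None]:
    """Read and cross-validate all study inputs named by the config."""
    for name in ("fixations", "utterances", "embeddings", "parses"):
        p = getattr(cfg, name)
        if not p:
            raise ConfigError(f"config is missing the {name!r} path")
        if not Path(p).exists():
            raise ConfigError(f"{name} path does not exist: {p}")
    trials = data_io.read_fixation_table(cfg.fixations)
    utts = data_io.read_utterance_table(cfg.utterances)
    trials = data_io.attach_utterances(trials, utts)
    vectors = data_io.read_embeddings(cfg.embeddings)
    embeddings = {v.trial_id: v for v in vectors}
    trees = {t.trial_id: t for t in data_io.read_conllu(cfg.parses)}
    regions = None
    if cfg.regions:
        if not Path(cfg.regions).exists():
            raise ConfigError(f"regions path does not exist: {cfg.regions}")
        regions = data_io.read_region_map(cfg.regions)
    missing_e = [t.trial_id for t in trials if t.trial_id not in embeddings]
    missing_t = [t.trial_id for t in trials if t.trial_id not in trees]
    if missing_e or missing_t:
        raise DataError(
            f"trials without embedding: {missing_e[:5]}; without parse: {missing_t[:5]}"
        )
    return trials, embeddings, trees, regions


def encode_stage(
    trials: list[Trial],
    cfg: StudyConfig,
    regions: dict | None = None,
) -> tuple[dict[str, dict[str, scanpath.ScanSequence]], int]:
    """Encode every trial into phase-tagged scan sequences.

    Returns the sequences keyed by trial and phase, plus the count of
    fixations clamped into the image.
    """
    sequences: dict[str, dict[str, scanpath.ScanSequence]] = {}
    clamped = 0
    for t in trials:
        if cfg.encoding == "roi":
            if regions is None:
                raise ConfigError("roi encoding requires a regions path")
            before, during = scanpath.encode_trial_roi(t, regions, cfg.bin_ms)
        else:
            grid = GridSpec(t.image_width, t.image_height, cfg.n_cols, cfg.n_rows)
            before, during = scanpath.encode_trial(t, grid, cfg.bin_ms)
            clamped += scanpath.count_clamped(t, grid)
        sequences[t.trial_id] = {BEFORE: before, DURING: during}
    return sequences, clamped


def similarity_stage(
    trials: list[Trial],
    embeddings: dict[str, EmbeddingVector],
    trees: dict[str, DepTree],
    sequences: dict[str, dict[str, scanpath.ScanSequence]],
    cfg: StudyConfig,
) -> tuple[np.ndarray, np.ndarray, dict[str, np.ndarray]]:
    """Pairwise semantic, syntactic and per-phase scan similarity matrices."""
    order = [t.trial_id for t in trials]
    sem = semantics.pairwise_similarity([embeddings[tid] for tid in order], cfg.similarity)
    kcfg = syntax.KernelConfig(decay=cfg.kernel_decay)
    structs = [syntax.delexicalize(trees[tid]) for tid in order]
    syn = syntax.pairwise_normalized_sst(structs, kcfg)
    scans = {}
    for phase in (BEFORE, DURING):
        toks = [
            sequences.get(tid, {}).get(phase).tokens
            if phase in sequences.get(tid, {})
            else []
            for tid in order
        ]
        scans[phase] = scanpath.pairwise_lcs_similarity(toks)
    return sem, syn, scans


def run_all(
    cfg: StudyConfig,
    bundle: StudyBundle | None = None,
    fit_model: bool = True,
) -> RunResult:
    """Execute the full analysis; deterministic given config + seed.

    ``bundle`` bypasses file loading for in-memory synthetic studies.
    """
    if bundle is not None:
        trials = list(bundle.trials)
        embeddings = dict(bundle.embeddings)
        trees = dict(bundle.trees)
        regions = bundle.region_map
    else:
        trials, embeddings, trees, regions = load_study(cfg)
    n_input = len(trials)

    trials, sent_log = pairing.filter_sentences(
        trials, trees,
        min_words=cfg.min_words, max_words=cfg.max_words, mode=cfg.length_mode,
    )

    if cfg.shuffle:
        trials, embeddings, trees = pairing.shuffle_pairing(
            trials, embeddings, trees, cfg.seed
        )

    sequences, clamped = encode_stage(trials, cfg, regions)
    sequences, scan_log = pairing.filter_scanpatterns(sequences, cfg.min_fixations)

    sem, syn, scans = similarity_stage(trials, embeddings, trees, sequences, cfg)
    pair_table = pairing.assemble_pair_table(trials, sequences, sem, syn, scans)

    fit = fit_association_model(pair_table) if fit_model else None

    word_orders = syntax.tabulate_word_orders(
        _trees_by_language(trials, trees), top_k=10
    )
    exclusions = pd.concat([sent_log, scan_log], ignore_index=True)
    result = RunResult(
        pair_table=pair_table,
        fit=fit,
        binned_sem=binned_summary(pair_table, "sem_sim"),
        binned_syn=binned_summary(pair_table, "syn_sim"),
        correlations=similarity_correlation(pair_table),
        syntax_phase_association=phase_association(pair_table, "syn_sim"),
        word_orders=word_orders,
        exclusions=exclusions,
        log={
            "n_trials_input": n_input,
            "n_trials_after_sentence_filter": len(trials),
            "n_sentence_exclusions": len(sent_log),
            "n_scanpattern_exclusions": len(scan_log),
            "n_clamped_fixations": clamped,
            "n_pair_records": len(pair_table),
            "shuffled": cfg.shuffle,
            "seed": cfg.seed,
        },
    )
    if cfg.out_dir:
        write_outputs(result, cfg)
    return result


def _trees_by_language(trials, trees):
    by_lang: dict[str, list] = {}
    for t in trials:
        if t.trial_id in trees:
            by_lang.setdefault(t.language_code, []).append(trees[t.trial_id])
    return by_lang


def write_outputs(result: RunResult, cfg: StudyConfig) -> dict[str, str]:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    def save(df: pd.DataFrame, name: str):
        p = out / name
        df.to_csv(p, sep="\t", index=False, float_format="%.17g")
        paths[name] = str(p)

    data_io.write_pair_table(result.pair_table, out / "pair_table.tsv")
    paths["pair_table.tsv"] = str(out / "pair_table.tsv")
    if result.fit is not None:
        save(result.fit.summary(), "coefficients.tsv")
    save(result.binned_sem, "binned_semantics.tsv")
    save(result.binned_syn, "binned_syntax.tsv")
    save(result.word_orders, "word_orders.tsv")
    save(result.exclusions, "exclusions.tsv")
    manifest = {
        "config": dataclasses.asdict(cfg),
        "log": result.log,
        "correlations": result.correlations,
        "syntax_phase_association": result.syntax_phase_association,
    }
    if result.fit is not None:
        manifest["model"] = {
            "converged": result.fit.converged,
            "boundary": result.fit.boundary,
            "loglik": result.fit.loglik,
            "n": result.fit.n,
            "variance_components": result.fit.variance_components,
            "residual_variance": result.fit.residual_variance,
            "dropped_terms": result.fit.dropped_terms,
        }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    paths["manifest.json"] = str(out / "manifest.json")
    return paths
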