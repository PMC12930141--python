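"""Exclusion filters, exhaustive pair assembly, and the shuffle control.

Every surviving trial is compared with every other trial, independently for
the two production phases (BEFORE/DURING); each unordered trial pair yields
at most one record per phase. Records carry the condition labels consumed
by the association model — same vs different scene (reference: different),
same vs different language (reference: different) — and the unordered
grouping keys (participant pair, item pair, cue pair) used as random
intercepts. Self-pairs of the grouping keys ({p, p}) arise naturally when
two trials of the same participant are compared and are retained.

The shuffle control destroys the gaze-language correspondence by randomly
reassigning each trial's linguistic bundle (transcript, embedding,
dependency tree) to another trial's scan sequences; pair assembly then runs
unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_io import DepTree, EmbeddingVector, Trial
from .scanpath import BEFORE, DURING, ScanSequence

PHASES = (BEFORE, DURING)


@dataclass(frozen=True)
class PairRecord:
    """One row of the analysis table: one unordered trial pair in one phase."""

    trial_id_1: str
    trial_id_2: str
    phase: str
    scan_sim: float
    sem_sim: float
    syn_sim: float
    same_scene: bool
    same_language: bool
    participant_pair: str
    item_pair: str
    cue_pair: str


# ---------------------------------------------------------------------------
# Exclusion filters
# ---------------------------------------------------------------------------


def word_count(transcript: str, tree: DepTree | None = None) -> int:
    """Sentence length in words.

    Whitespace tokens for space-delimited transcripts; for scripts written
    without spaces the number of syntactic tokens in the parse is used.
    """
    tokens = transcript.split()
    if len(tokens) > 1 or tree is None:
        return len(tokens)
    return len(tree.nodes)


def filter_sentences(
    trials: Sequence[Trial],
    trees: Mapping[str, DepTree] | None = None,
    min_words: int = 4,
    max_words: int = 77,
    mode: str = "absolute",
    percentiles: tuple[float, float] = (2.0, 99.0),
) -> tuple[list[Trial], pd.DataFrame]:
    """Drop trials whose descriptions are too short or too long.

    ``mode='absolute'`` keeps word counts in the inclusive
    [min_words, max_words] band; ``mode='percentile'`` recomputes the band
    from the study's own length distribution at the given percentiles.
    Returns the kept trials and an exclusion log (trial_id, reason).
    """
    counts = np.array(
        [word_count(t.transcript, (trees or {}).get(t.trial_id)) for t in trials],
        dtype=float,
    )
    if mode == "percentile":
        if len(counts) == 0:
            lo, hi = min_words, max_words
        else:
            lo = float(np.percentile(counts, percentiles[0]))
            hi = float(np.percentile(counts, percentiles[1]))
    elif mode == "absolute":
        lo, hi = float(min_words), float(max_words)
    else:
        raise ValueError(f"unknown filter mode {mode!r}")
    kept, log = [], []
    for t, c in zip(trials, counts):
        if c < lo:
            log.append({"trial_id": t.trial_id, "phase": "", "reason": f"too_short:{int(c)}"})
        elif c > hi:
            log.append({"trial_id": t.trial_id, "phase": "", "reason": f"too_long:{int(c)}"})
        else:
            kept.append(t)
    return kept, pd.DataFrame(log, columns=["trial_id", "phase", "reason"])


def filter_scanpatterns(
    sequences: Mapping[str, Mapping[str, ScanSequence]],
    min_fixations: int = 2,
) -> tuple[dict[str, dict[str, ScanSequence]], pd.DataFrame]:
    """Drop phase-sequences built from fewer than ``min_fixations`` fixations.

    Removal is per phase: a trial's BEFORE sequence can be excluded while
    its DURING sequence survives. Returns kept sequences and the log.
    """
    kept: dict[str, dict[str, ScanSequence]] = {}
    log = []
    for trial_id, phases in sequences.items():
        for phase, seq in phases.items():
            if seq.n_fixations < min_fixations:
                log.append(
                    {
                        "trial_id": trial_id,
                        "phase": phase,
                        "reason": f"few_fixations:{seq.n_fixations}",
                    }
                )
            else:
                kept.setdefault(trial_id, {})[phase] = seq
    return kept, pd.DataFrame(log, columns=["trial_id", "phase", "reason"])


# ---------------------------------------------------------------------------
# Pair assembly
# ---------------------------------------------------------------------------


def _pair_key(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    lo = np.where(a <= b, a, b)
    hi = np.where(a <= b, b, a)
    return np.char.add(np.char.add(lo.astype(str), "|"), hi.astype(str))


def trial_metadata(trials: Sequence[Trial]) -> pd.DataFrame:
    """Per-trial label frame (trial_id, participant, scene, language, cue)."""
    return pd.DataFrame(
        {
            "trial_id": [t.trial_id for t in trials],
            "participant": [t.participant_id for t in trials],
            "scene": [t.scene_id for t in trials],
            "language": [t.language_code for t in trials],
            "cue": [t.cue_word for t in trials],
        }
    )


def build_pairs(
    meta: pd.DataFrame,
    phase: str,
    scan_sim: np.ndarray | None = None,
    sem_sim: np.ndarray | None = None,
    syn_sim: np.ndarray | None = None,
    valid: np.ndarray | None = None,
) -> pd.DataFrame:
    """All unordered trial pairs for one phase, with labels and grouping keys.

    ``meta`` is a `trial_metadata` frame; the optional similarity arguments
    are symmetric matrices aligned with its rows. ``valid`` masks trials
    whose scan sequence survives this phase's filters; invalid trials form
    no pairs. Returns a DataFrame in the pair-table schema (one row per
    unordered pair; C(k, 2) rows for k valid trials).
    """
    if valid is None:
        keep = np.arange(len(meta))
    else:
        keep = np.flatnonzero(np.asarray(valid))
    sub = meta.iloc[keep].reset_index(drop=True)
    k = len(sub)
    i, j = np.triu_indices(k, k=1)
    tid = sub["trial_id"].to_numpy(dtype=str)
    part = sub["participant"].to_numpy(dtype=str)
    scene = sub["scene"].to_numpy(dtype=str)
    lang = sub["language"].to_numpy(dtype=str)
    cue = sub["cue"].to_numpy(dtype=str)

    def pick(mat):
        if mat is None:
            return np.full(len(i), np.nan)
        return np.asarray(mat)[np.ix_(keep, keep)][i, j]

    return pd.DataFrame(
        {
            "trial_id_1": tid[i],
            "trial_id_2": tid[j],
            "phase": phase,
            "scan_sim": pick(scan_sim),
            "sem_sim": pick(sem_sim),
            "syn_sim": pick(syn_sim),
            "same_scene": scene[i] == scene[j],
            "same_language": lang[i] == lang[j],
            "participant_pair": _pair_key(part[i], part[j]),
            "item_pair": _pair_key(scene[i], scene[j]),
            "cue_pair": _pair_key(cue[i], cue[j]),
        }
    )


def assemble_pair_table(
    trials: Sequence[Trial],
    sequences: Mapping[str, Mapping[str, ScanSequence]],
    sem_matrix: np.ndarray,
    syn_matrix: np.ndarray,
    scan_matrices: Mapping[str, np.ndarray],
    drop_undefined: bool = True,
) -> pd.DataFrame:
    """Stack both phases' pair tables into one long analysis frame.

    ``scan_matrices`` maps phase name to the pairwise scan-similarity
    matrix over all trials (NaN where a member's sequence was excluded).
    Semantic and syntactic similarities are phase-independent, so the two
    phase records of one trial pair share sem_sim/syn_sim but not scan_sim.
    """
    meta = trial_metadata(trials)
    frames = []
    for phase in PHASES:
        valid = np.array([phase in sequences.get(t.trial_id, {}) for t in trials])
        df = build_pairs(
            meta,
            phase,
            scan_sim=scan_matrices[phase],
            sem_sim=sem_matrix,
            syn_sim=syn_matrix,
            valid=valid,
        )
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    if drop_undefined:
        out = out.dropna(subset=["scan_sim", "sem_sim", "syn_sim"]).reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# Shuffle control
# ---------------------------------------------------------------------------


def shuffle_pairing(
    trials: Sequence[Trial],
    embeddings: Mapping[str, EmbeddingVector],
    trees: Mapping[str, DepTree],
    seed: int | np.random.Generator,
) -> tuple[list[Trial], dict[str, EmbeddingVector], dict[str, DepTree]]:
    """Randomly reassign linguistic bundles to scan sequences.

    A uniform seeded permutation moves each trial's sentence (transcript,
    embedding, dependency tree) onto another trial's scan data; participant,
    scene, language, cue and utterance timings stay with the scan side so
    pair assembly and condition labels are computed exactly as before.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(trials)
    perm = rng.permutation(n) if n > 1 else np.arange(n)
    new_trials: list[Trial] = []
    new_emb: dict[str, EmbeddingVector] = {}
    new_trees: dict[str, DepTree] = {}
    for i, trial in enumerate(trials):
        donor = trials[int(perm[i])]
        new_trials.append(replace(trial, transcript=donor.transcript))
        if donor.trial_id in embeddings:
            new_emb[trial.trial_id] = EmbeddingVector(
                trial_id=trial.trial_id, values=embeddings[donor.trial_id].values
            )
        if donor.trial_id in trees:
            src = trees[donor.trial_id]
            new_trees[trial.trial_id] = DepTree(
                nodes=list(src.nodes), trial_id=trial.trial_id
            )
    return new_trials, new_emb, new_trees
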