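"""Domain types and readers/writers for the study's external formats.

Tabular inputs (fixations, utterance metadata, embeddings, pair tables,
region maps) are delimited text with a header row; syntactic parses arrive
as CoNLL-U. This module does validated I/O only — no similarity math.

Conventions
-----------
* Pixel coordinates have their origin at the top-left of the image with y
  increasing downward, the standard eye-tracker report convention.
* A trial is identified by the (participant_id, scene_id) pair — one
  description per scene per participant — so duplicate pairs are an error.
* Dependency labels carrying language-specific subtypes ("obj:dobj") are
  truncated at ":"; the older "dobj"/"nsubjpass" inventory and the modern
  "obj"/"nsubj:pass" labels are reconciled through a configurable alias map.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np
import pandas as pd

from .errors import (
    DataError,
    DimensionError,
    RowParseError,
    SchemaError,
    StructuralError,
)

# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Fixation:
    """One fixation event: position in pixels, onset/offset in ms from scene onset."""

    x: float
    y: float
    t_start: float
    t_end: float

    def __post_init__(self):
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise DataError(f"non-finite fixation coordinates ({self.x}, {self.y})")
        if not (self.t_end > self.t_start >= 0):
            raise DataError(
                f"fixation times must satisfy t_end > t_start >= 0, "
                f"got [{self.t_start}, {self.t_end})"
            )

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class Trial:
    """One participant x scene recording.

    ``utt_onset``/``utt_offset`` are in ms from scene onset and delimit the
    spoken description; fixations are kept sorted by onset.
    """

    participant_id: str
    scene_id: str
    language_code: str = ""
    cue_word: str = ""
    utt_onset: float | None = None
    utt_offset: float | None = None
    transcript: str = ""
    fixations: list[Fixation] = field(default_factory=list)
    image_width: float = 0.0
    image_height: float = 0.0

    def __post_init__(self):
        if self.utt_onset is not None and self.utt_offset is not None:
            if not (self.utt_offset > self.utt_onset > 0):
                raise DataError(
                    f"trial {self.trial_id}: need utt_offset > utt_onset > 0, "
                    f"got ({self.utt_onset}, {self.utt_offset})"
                )
        self.fixations = sorted(self.fixations, key=lambda f: f.t_start)

    @property
    def trial_id(self) -> str:
        return f"{self.participant_id}:{self.scene_id}"


@dataclass(frozen=True)
class DepNode:
    """One token of a dependency parse (1-based index; head 0 = root)."""

    index: int
    head: int
    deprel: str
    word: str = ""
    upos: str = ""


@dataclass
class DepTree:
    """An ordered dependency tree over the tokens of one utterance."""

    nodes: list[DepNode]
    trial_id: str = ""

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        n = len(self.nodes)
        if n == 0:
            raise StructuralError(f"tree {self.trial_id!r}: empty")
        for expect, node in enumerate(self.nodes, start=1):
            if node.index != expect:
                raise StructuralError(
                    f"tree {self.trial_id!r}: node indices must be 1..n contiguous"
                )
            if not (0 <= node.head <= n):
                raise StructuralError(
                    f"tree {self.trial_id!r}: head {node.head} out of range"
                )
        roots = [nd.index for nd in self.nodes if nd.head == 0]
        if len(roots) != 1:
            raise StructuralError(
                f"tree {self.trial_id!r}: expected exactly one root, found {len(roots)}"
            )
        # cycle check: follow heads from every node; must reach 0
        for nd in self.nodes:
            seen = set()
            cur = nd.index
            while cur != 0:
                if cur in seen:
                    raise StructuralError(
                        f"tree {self.trial_id!r}: cycle through token {cur}"
                    )
                seen.add(cur)
                cur = self.nodes[cur - 1].head

    @property
    def root(self) -> DepNode:
        return next(nd for nd in self.nodes if nd.head == 0)

    def children(self, index: int) -> list[DepNode]:
        """Dependents of the given token, in linear (index) order."""
        return [nd for nd in self.nodes if nd.head == index]


@dataclass(frozen=True)
class EmbeddingVector:
    """Fixed-length sentence-embedding vector for one trial."""

    trial_id: str
    values: np.ndarray

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1:
            raise DimensionError(f"{self.trial_id}: embedding must be 1-D")
        if not np.all(np.isfinite(vals)):
            raise DataError(f"{self.trial_id}: non-finite embedding values")
        object.__setattr__(self, "values", vals)

    @property
    def dim(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class Region:
    """A labeled rectangle on a scene image; lower priority number wins overlaps."""

    label: str
    x0: float
    y0: float
    x1: float
    y1: float
    priority: int = 0

    def contains(self, x: float, y: float) -> bool:
        return self.x0 <= x <= self.x1 and self.y0 <= y <= self.y1


# Label normalization: language-specific subtypes are cut at ":", then the
# modern UD labels are folded onto the older inventory the core-dependency
# table uses. Full-label aliases (checked before truncation) let callers map
# e.g. "nsubj:pass" -> "nsubjpass" without losing the subtype.
DEFAULT_LABEL_ALIASES: dict[str, str] = {
    "obj": "dobj",
    "nsubj:pass": "nsubjpass",
    "csubj:pass": "csubjpass",
}


def normalize_deprel(label: str, aliases: Mapping[str, str] | None = None) -> str:
    """Truncate subtype suffixes and apply the alias map (full label first)."""
    if aliases is None:
        aliases = DEFAULT_LABEL_ALIASES
    if label in aliases:
        return aliases[label]
    base = label.split(":", 1)[0]
    return aliases.get(base, base)


# ---------------------------------------------------------------------------
# Fixation / utterance tables
# ---------------------------------------------------------------------------

DEFAULT_FIXATION_SCHEMA: dict[str, str] = {
    "participant": "participant",
    "scene": "scene",
    "x": "x",
    "y": "y",
    "t_start": "t_start",
    "t_end": "t_end",
    "image_width": "image_width",
    "image_height": "image_height",
}

DEFAULT_UTTERANCE_SCHEMA: dict[str, str] = {
    "participant": "participant",
    "scene": "scene",
    "language": "language",
    "cue_word": "cue_word",
    "utt_onset": "utt_onset",
    "utt_offset": "utt_offset",
    "transcript": "transcript",
}


def _as_text_stream(stream) -> TextIO:
    if isinstance(stream, (str,)) or hasattr(stream, "__fspath__"):
        return open(stream, "r", newline="")
    return stream


def _sniff_delim(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def read_fixation_table(
    stream,
    schema_config: Mapping[str, str] | None = None,
) -> list[Trial]:
    """Read a long-format fixation table into per-trial bundles.

    One row per fixation; required columns (after schema mapping):
    participant, scene, x, y, t_start, t_end, image_width, image_height.
    Rows are grouped by (participant, scene) and fixations sorted by onset.
    Utterance metadata is attached separately (`attach_utterances`).
    """
    schema = dict(DEFAULT_FIXATION_SCHEMA)
    if schema_config:
        schema.update(schema_config)
    fh = _as_text_stream(stream)
    header_line = fh.readline()
    if not header_line:
        raise SchemaError("empty fixation table")
    delim = _sniff_delim(header_line)
    columns = [c.strip() for c in header_line.rstrip("\n").split(delim)]
    col_ix: dict[str, int] = {}
    for fieldname, colname in schema.items():
        if colname not in columns:
            raise SchemaError(f"fixation table missing required column {colname!r}")
        col_ix[fieldname] = columns.index(colname)

    trials: dict[tuple[str, str], Trial] = {}
    for lineno, line in enumerate(fh, start=2):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split(delim)
        try:
            x = float(parts[col_ix["x"]])
            y = float(parts[col_ix["y"]])
            t0 = float(parts[col_ix["t_start"]])
            t1 = float(parts[col_ix["t_end"]])
            iw = float(parts[col_ix["image_width"]])
            ih = float(parts[col_ix["image_height"]])
        except (ValueError, IndexError) as exc:
            raise RowParseError(f"cannot parse fixation row: {exc}", line=lineno)
        try:
            fix = Fixation(x=x, y=y, t_start=t0, t_end=t1)
        except DataError as exc:
            raise RowParseError(str(exc), line=lineno)
        key = (parts[col_ix["participant"]], parts[col_ix["scene"]])
        trial = trials.get(key)
        if trial is None:
            trial = Trial(
                participant_id=key[0],
                scene_id=key[1],
                image_width=iw,
                image_height=ih,
            )
            trials[key] = trial
        else:
            if (trial.image_width, trial.image_height) != (iw, ih):
                raise RowParseError(
                    f"inconsistent image geometry for trial {key}", line=lineno
                )
        trial.fixations.append(fix)
    out = list(trials.values())
    for t in out:
        t.fixations.sort(key=lambda f: f.t_start)
    return out


def read_utterance_table(
    stream,
    schema_config: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read per-trial utterance metadata; one row per (participant, scene)."""
    schema = dict(DEFAULT_UTTERANCE_SCHEMA)
    if schema_config:
        schema.update(schema_config)
    fh = _as_text_stream(stream)
    first = fh.readline()
    if not first:
        raise SchemaError("empty utterance table")
    delim = _sniff_delim(first)
    df = pd.read_csv(io.StringIO(first + fh.read()), sep=delim, dtype=str)
    missing = [c for c in schema.values() if c not in df.columns]
    if missing:
        raise SchemaError(f"utterance table missing required column(s) {missing}")
    inv = {v: k for k, v in schema.items()}
    df = df.rename(columns=inv)
    df["utt_onset"] = df["utt_onset"].astype(float)
    df["utt_offset"] = df["utt_offset"].astype(float)
    df["transcript"] = df["transcript"].fillna("")
    dup = df.duplicated(subset=["participant", "scene"])
    if dup.any():
        key = df.loc[dup, ["participant", "scene"]].iloc[0].tolist()
        raise DataError(f"duplicate trial {tuple(key)} in utterance table")
    return df


def attach_utterances(trials: Sequence[Trial], utterances: pd.DataFrame) -> list[Trial]:
    """Merge utterance metadata onto fixation trials by (participant, scene)."""
    meta = {
        (row.participant, row.scene): row
        for row in utterances.itertuples(index=False)
    }
    out = []
    for t in trials:
        key = (t.participant_id, t.scene_id)
        if key not in meta:
            raise DataError(f"trial {t.trial_id}: no utterance metadata")
        row = meta[key]
        out.append(
            replace(
                t,
                language_code=str(row.language),
                cue_word=str(row.cue_word),
                utt_onset=float(row.utt_onset),
                utt_offset=float(row.utt_offset),
                transcript=str(row.transcript),
            )
        )
    return out


def write_fixation_table(trials: Iterable[Trial], stream) -> int:
    """Write trials back to the long fixation format; returns rows written."""
    fh = stream if hasattr(stream, "write") else open(stream, "w", newline="")
    cols = ["participant", "scene", "x", "y", "t_start", "t_end",
            "image_width", "image_height"]
    fh.write("\t".join(cols) + "\n")
    n = 0
    for t in trials:
        for f in t.fixations:
            fh.write(
                f"{t.participant_id}\t{t.scene_id}\t{f.x!r}\t{f.y!r}"
                f"\t{f.t_start!r}\t{f.t_end!r}\t{t.image_width!r}\t{t.image_height!r}\n"
            )
            n += 1
    return n


def write_utterance_table(trials: Iterable[Trial], stream) -> int:
    fh = stream if hasattr(stream, "write") else open(stream, "w", newline="")
    cols = ["participant", "scene", "language", "cue_word",
            "utt_onset", "utt_offset", "transcript"]
    fh.write("\t".join(cols) + "\n")
    n = 0
    for t in trials:
        fh.write(
            f"{t.participant_id}\t{t.scene_id}\t{t.language_code}\t{t.cue_word}"
            f"\t{t.utt_onset!r}\t{t.utt_offset!r}\t{t.transcript}\n"
        )
        n += 1
    return n


# ---------------------------------------------------------------------------
# CoNLL-U
# ---------------------------------------------------------------------------


def read_conllu(
    stream,
    label_aliases: Mapping[str, str] | None = None,
) -> list[DepTree]:
    """Parse CoNLL-U sentences into dependency trees.

    Multiword-token ranges ("1-2") and empty nodes ("1.1") are skipped.
    A comment line ``# trial_id = X`` attaches the trial identifier; the
    standard ``# sent_id`` is used as a fallback. DEPREL labels are
    normalized (subtype truncation + alias map) on read.
    """
    fh = _as_text_stream(stream)
    trees: list[DepTree] = []
    nodes: list[DepNode] = []
    trial_id = ""

    def flush():
        nonlocal nodes, trial_id
        if nodes:
            trees.append(DepTree(nodes=nodes, trial_id=trial_id))
        nodes = []
        trial_id = ""

    for lineno, raw in enumerate(fh, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            flush()
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if "=" in body:
                key, _, val = body.partition("=")
                key = key.strip()
                if key == "trial_id" or (key == "sent_id" and not trial_id):
                    trial_id = val.strip()
            continue
        fields = line.split("\t")
        if len(fields) < 8:
            raise RowParseError(
                f"CoNLL-U line has {len(fields)} fields, expected >= 8", line=lineno
            )
        tid = fields[0]
        if "-" in tid or "." in tid:
            continue  # multiword token range / empty node
        try:
            index = int(tid)
            head = int(fields[6])
        except ValueError as exc:
            raise RowParseError(f"bad CoNLL-U index/head: {exc}", line=lineno)
        nodes.append(
            DepNode(
                index=index,
                head=head,
                deprel=normalize_deprel(fields[7], label_aliases),
                word=fields[1],
                upos=fields[3],
            )
        )
    flush()
    return trees


def write_conllu(trees: Iterable[DepTree], stream) -> int:
    """Write trees as CoNLL-U with trial_id comments; returns sentence count."""
    fh = stream if hasattr(stream, "write") else open(stream, "w", newline="")
    n = 0
    for tree in trees:
        if tree.trial_id:
            fh.write(f"# trial_id = {tree.trial_id}\n")
        for nd in tree.nodes:
            fh.write(
                f"{nd.index}\t{nd.word or '_'}\t_\t{nd.upos or '_'}\t_\t_"
                f"\t{nd.head}\t{nd.deprel}\t_\t_\n"
            )
        fh.write("\n")
        n += 1
    return n


# ---------------------------------------------------------------------------
# Embedding tables
# ---------------------------------------------------------------------------


def read_embeddings(stream) -> list[EmbeddingVector]:
    """Read a delimited table: trial_id column + d numeric columns.

    Every row must have the same number of numeric columns; ragged rows
    raise DimensionError.
    """
    fh = _as_text_stream(stream)
    first = fh.readline()
    if not first:
        raise SchemaError("empty embedding table")
    delim = _sniff_delim(first)
    reader = csv.reader(io.StringIO(fh.read()), delimiter=delim)
    header = [c.strip() for c in first.rstrip("\n").split(delim)]
    if header[0] != "trial_id":
        raise SchemaError("embedding table must start with a 'trial_id' column")
    d = len(header) - 1
    out: list[EmbeddingVector] = []
    for lineno, row in enumerate(reader, start=2):
        if not row:
            continue
        if len(row) - 1 != d:
            raise DimensionError(
                f"line {lineno}: embedding row has {len(row) - 1} values, expected {d}"
            )
        try:
            vals = np.array([float(v) for v in row[1:]], dtype=float)
        except ValueError as exc:
            raise RowParseError(f"non-numeric embedding value: {exc}", line=lineno)
        out.append(EmbeddingVector(trial_id=row[0], values=vals))
    return out


def write_embeddings(vectors: Iterable[EmbeddingVector], stream) -> int:
    vectors = list(vectors)
    fh = stream if hasattr(stream, "write") else open(stream, "w", newline="")
    d = vectors[0].dim if vectors else 0
    fh.write("trial_id\t" + "\t".join(f"e{i}" for i in range(d)) + "\n")
    for v in vectors:
        fh.write(v.trial_id + "\t" + "\t".join(repr(float(x)) for x in v.values) + "\n")
    return len(vectors)


# ---------------------------------------------------------------------------
# Pair table
# ---------------------------------------------------------------------------

PAIR_TABLE_COLUMNS = [
    "trial_id_1", "trial_id_2", "phase",
    "scan_sim", "sem_sim", "syn_sim",
    "same_scene", "same_language",
    "participant_pair", "item_pair", "cue_pair",
]


def write_pair_table(records, stream) -> int:
    """Write the long-format pair table (TSV); returns data rows written.

    ``records`` is a pandas DataFrame with the PAIR_TABLE_COLUMNS schema
    (extra columns are preserved after the canonical ones).
    """
    df = pd.DataFrame(records)
    for col in PAIR_TABLE_COLUMNS:
        if col not in df.columns:
            if len(df) == 0:
                df[col] = pd.Series(dtype=object)
            else:
                raise SchemaError(f"pair records missing column {col!r}")
    extra = [c for c in df.columns if c not in PAIR_TABLE_COLUMNS]
    df = df[PAIR_TABLE_COLUMNS + extra]
    df.to_csv(stream, sep="\t", index=False, float_format="%.17g")
    return len(df)


def read_pair_table(stream) -> pd.DataFrame:
    df = pd.read_csv(stream, sep="\t", float_precision="round_trip")
    missing = [c for c in PAIR_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"pair table missing column(s) {missing}")
    for col in ("same_scene", "same_language"):
        if df[col].dtype == object:
            df[col] = df[col].map({"True": True, "False": False})
        df[col] = df[col].astype(bool)
    return df


# ---------------------------------------------------------------------------
# Region maps
# ---------------------------------------------------------------------------


def read_region_map(stream) -> dict[str, list[Region]]:
    """Read a region-map TSV: scene_id, label, x0, y0, x1, y1, priority."""
    df = pd.read_csv(stream, sep="\t", dtype={"scene_id": str, "label": str})
    required = ["scene_id", "label", "x0", "y0", "x1", "y1", "priority"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"region map missing column(s) {missing}")
    out: dict[str, list[Region]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.scene_id), []).append(
            Region(
                label=str(row.label),
                x0=float(row.x0), y0=float(row.y0),
                x1=float(row.x1), y1=float(row.y1),
                priority=int(row.priority),
            )
        )
    for regions in out.values():
        regions.sort(key=lambda r: r.priority)
    return out


def write_region_map(region_map: Mapping[str, Sequence[Region]], stream) -> int:
    fh = stream if hasattr(stream, "write") else open(stream, "w", newline="")
    fh.write("scene_id\tlabel\tx0\ty0\tx1\ty1\tpriority\n")
    n = 0
    for scene_id in region_map:
        for r in region_map[scene_id]:
            fh.write(
                f"{scene_id}\t{r.label}\t{r.x0!r}\t{r.y0!r}\t{r.x1!r}\t{r.y1!r}"
                f"\t{r.priority}\n"
            )
            n += 1
    return n
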