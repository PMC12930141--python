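"""Scan-pattern encoding and normalized longest-common-subsequence similarity.

A trial's fixation stream is mapped onto a categorical token sequence: the
image is tiled by a grid (6 columns x 4 rows by default), time is cut into
consecutive 25 ms bins starting at scene onset, and each bin whose start
instant falls inside a fixation receives that fixation's cell label. Bins
covered by no fixation (saccades, blinks) are dropped. Bins are split into
two production phases: BEFORE speaking (scene onset to utterance onset) and
DURING speaking (utterance onset to offset); bins at or after the utterance
offset are discarded.

Similarity between two token sequences is the length of their longest
common subsequence divided by the geometric mean of the two lengths, giving
a value in [0, 1] that is 1 exactly when the sequences are identical.

The LCS length is computed two ways: a classic dynamic program over the
(m+1) x (n+1) matrix (`lcs_length`, with an optional witness via
`lcs_witness`), and a bit-parallel row-update used for all-pairs sweeps
(`PackedSequence` / `lcs_length_packed`), which computes the same quantity
roughly 50x faster. The two are cross-checked by property tests.
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .data_io import Fixation, Region, Trial
from .errors import ConfigError, RegionMapError, SimilarityUndefinedError

logger = logging.getLogger(__name__)

BEFORE = "before"
DURING = "during"

# ---------------------------------------------------------------------------
# Grid encoding
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GridSpec:
    """Equal-size cell grid over one trial's image extent.

    The grid is defined over each trial's own image dimensions, so cell
    labels are comparable across recording setups with different screen
    resolutions.
    """

    image_width: float
    image_height: float
    n_cols: int = 6
    n_rows: int = 4

    def __post_init__(self):
        if self.n_cols < 1 or self.n_rows < 1:
            raise ConfigError("grid needs at least one row and one column")
        if self.image_width <= 0 or self.image_height <= 0:
            raise ConfigError("image dimensions must be positive")

    def cell_label(self, row: int, col: int) -> str:
        """Row letter (a.. top to bottom) followed by column letter (a.. left to right)."""
        return string.ascii_lowercase[row] + string.ascii_lowercase[col]


def assign_cell(fixation: Fixation, grid: GridSpec) -> str:
    """Map a fixation to its grid-cell label.

    Cells are half-open intervals; the right/bottom image edge closes into
    the final column/row. Fixations outside the image are clamped to the
    nearest edge cell (trackers report small overshoots).
    """
    x = min(max(fixation.x, 0.0), grid.image_width)
    y = min(max(fixation.y, 0.0), grid.image_height)
    if (x, y) != (fixation.x, fixation.y):
        logger.debug("clamped fixation (%s, %s) into image", fixation.x, fixation.y)
    col = min(int(x / (grid.image_width / grid.n_cols)), grid.n_cols - 1)
    row = min(int(y / (grid.image_height / grid.n_rows)), grid.n_rows - 1)
    return grid.cell_label(row, col)


def count_clamped(trial: Trial, grid: GridSpec) -> int:
    return sum(
        1
        for f in trial.fixations
        if not (0 <= f.x <= grid.image_width and 0 <= f.y <= grid.image_height)
    )


@dataclass
class ScanSequence:
    """Phase-tagged categorical token sequence (one token per retained bin)."""

    trial_id: str
    phase: str
    tokens: list[str]
    bin_ms: float = 25.0
    n_fixations: int = 0  # fixations contributing >= 1 retained bin

    def __len__(self) -> int:
        return len(self.tokens)


def _encode_with_labels(
    trial: Trial,
    labels: Sequence[str],
    bin_ms: float,
) -> tuple[ScanSequence, ScanSequence]:
    """Shared bin/phase machinery for grid and ROI encodings."""
    if trial.utt_onset is None or trial.utt_offset is None:
        raise ConfigError(f"trial {trial.trial_id}: missing utterance timings")
    tokens = {BEFORE: [], DURING: []}
    used = {BEFORE: set(), DURING: set()}
    if trial.fixations:
        starts = np.array([f.t_start for f in trial.fixations])
        ends = np.array([f.t_end for f in trial.fixations])
        n_bins = int(np.ceil(trial.utt_offset / bin_ms))
        bin_starts = np.arange(n_bins) * bin_ms
        bin_starts = bin_starts[bin_starts < trial.utt_offset]
        # bin start inside [t_start, t_end) of the (unique, non-overlapping)
        # covering fixation; searchsorted over sorted onsets
        ix = np.searchsorted(starts, bin_starts, side="right") - 1
        covered = (ix >= 0) & (bin_starts < ends[np.maximum(ix, 0)])
        for t, i, ok in zip(bin_starts, ix, covered):
            if not ok:
                continue
            phase = BEFORE if t < trial.utt_onset else DURING
            tokens[phase].append(labels[i])
            used[phase].add(int(i))
    else:
        logger.warning("trial %s has no fixations; empty scan sequences", trial.trial_id)
    return (
        ScanSequence(trial.trial_id, BEFORE, tokens[BEFORE], bin_ms, len(used[BEFORE])),
        ScanSequence(trial.trial_id, DURING, tokens[DURING], bin_ms, len(used[DURING])),
    )


def encode_trial(
    trial: Trial,
    grid: GridSpec | None = None,
    bin_ms: float = 25.0,
) -> tuple[ScanSequence, ScanSequence]:
    """Encode a trial against the cell grid; returns (BEFORE, DURING) sequences."""
    if grid is None:
        grid = GridSpec(image_width=trial.image_width, image_height=trial.image_height)
    labels = [assign_cell(f, grid) for f in trial.fixations]
    return _encode_with_labels(trial, labels, bin_ms)


def encode_trial_roi(
    trial: Trial,
    region_map: Mapping[str, Sequence[Region]],
    bin_ms: float = 25.0,
    background_label: str = "background",
) -> tuple[ScanSequence, ScanSequence]:
    """Encode a trial against labeled object regions instead of grid cells.

    Overlaps resolve to the region with the smallest priority number;
    fixations inside no region are labeled ``background``.
    """
    if trial.scene_id not in region_map:
        raise RegionMapError(f"scene {trial.scene_id!r} missing from region map")
    regions = sorted(region_map[trial.scene_id], key=lambda r: r.priority)
    labels = []
    for f in trial.fixations:
        hit = next((r.label for r in regions if r.contains(f.x, f.y)), background_label)
        labels.append(hit)
    return _encode_with_labels(trial, labels, bin_ms)


# ---------------------------------------------------------------------------
# Longest common subsequence
# ---------------------------------------------------------------------------


def lcs_length(a: Sequence, b: Sequence) -> int:
    """LCS length by the standard dynamic program.

    C[i][j] = C[i-1][j-1] + 1 on a match, else max(C[i-1][j], C[i][j-1]),
    over the (m+1) x (n+1) matrix.
    """
    m, n = len(a), len(b)
    if m == 0 or n == 0:
        return 0
    prev = [0] * (n + 1)
    for i in range(1, m + 1):
        cur = [0] * (n + 1)
        ai = a[i - 1]
        for j in range(1, n + 1):
            if ai == b[j - 1]:
                cur[j] = prev[j - 1] + 1
            else:
                cur[j] = prev[j] if prev[j] >= cur[j - 1] else cur[j - 1]
        prev = cur
    return prev[n]


def lcs_witness(a: Sequence, b: Sequence) -> list:
    """One longest common subsequence, recovered by traceback of the DP matrix."""
    m, n = len(a), len(b)
    C = np.zeros((m + 1, n + 1), dtype=np.int32)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            if a[i - 1] == b[j - 1]:
                C[i, j] = C[i - 1, j - 1] + 1
            else:
                C[i, j] = max(C[i - 1, j], C[i, j - 1])
    out = []
    i, j = m, n
    while i > 0 and j > 0:
        if a[i - 1] == b[j - 1]:
            out.append(a[i - 1])
            i -= 1
            j -= 1
        elif C[i - 1, j] >= C[i, j - 1]:
            i -= 1
        else:
            j -= 1
    return out[::-1]


@dataclass
class PackedSequence:
    """Token sequence with per-symbol bit masks for the bit-parallel LCS.

    Precomputing the masks once per trial makes all-pairs sweeps cheap: a
    pair costs O(len(other)) big-integer operations.
    """

    tokens: list[str]
    masks: dict[str, int] = field(init=False)
    full: int = field(init=False)

    def __post_init__(self):
        masks: dict[str, int] = {}
        for j, tok in enumerate(self.tokens):
            masks[tok] = masks.get(tok, 0) | (1 << j)
        self.masks = masks
        self.full = (1 << len(self.tokens)) - 1

    def __len__(self) -> int:
        return len(self.tokens)


def lcs_length_packed(a: Sequence, b: PackedSequence) -> int:
    """Bit-parallel LCS length: identical result to `lcs_length`."""
    n = len(b)
    if n == 0 or len(a) == 0:
        return 0
    full = b.full
    masks = b.masks
    V = full
    for tok in a:
        U = V & masks.get(tok, 0)
        if U:
            V = ((V + U) | (V - U)) & full
    return n - V.bit_count()


def lcs_similarity(a: Sequence, b: Sequence) -> float:
    """LCS length over the geometric mean of the two sequence lengths."""
    m, n = len(a), len(b)
    if m == 0 or n == 0:
        raise SimilarityUndefinedError(
            "LCS similarity undefined for empty sequences"
        )
    return lcs_length(a, b) / float(np.sqrt(m * n))


def pairwise_lcs_similarity(sequences: Sequence[Sequence[str]]) -> np.ndarray:
    """Symmetric matrix of normalized LCS similarities over all sequence pairs.

    Empty sequences yield NaN rows/columns (their pairs are excluded
    upstream by the fixation-count filter).
    """
    k = len(sequences)
    packed = [PackedSequence(list(s)) for s in sequences]
    lengths = np.array([len(s) for s in sequences], dtype=float)
    out = np.full((k, k), np.nan)
    np.fill_diagonal(out, np.where(lengths > 0, 1.0, np.nan))
    for i in range(k):
        si = sequences[i]
        if lengths[i] == 0:
            continue
        for j in range(i + 1, k):
            if lengths[j] == 0:
                continue
            lcs = lcs_length_packed(si, packed[j])
            out[i, j] = out[j, i] = lcs / np.sqrt(lengths[i] * lengths[j])
    return out
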