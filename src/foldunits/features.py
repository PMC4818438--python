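"""Per-residue feature tracks.

The target score combines five per-residue signals — order (the complement
of intrinsic-disorder propensity), secondary-structure propensity, sequence
conservation, antigenicity and hydrophobicity — each normalized to [0, 1]
per protein so the signals are commensurate before weighting.

Four of the five have built-in sequence-only providers based on published
residue propensity scales smoothed with a sliding window; conservation
requires a multiple alignment of close homologs.  Users running real
predictors (disorder ensembles, secondary-structure servers, rate
estimators) can import their per-residue output through the long-format
track TSV instead; imported values are min-max normalized per protein per
feature the same way.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .core import ProteinRecord, sanitize_sequence

logger = logging.getLogger("foldunits")

FEATURE_NAMES = (
    "order",
    "secondary_structure",
    "conservation",
    "antigenicity",
    "hydrophobicity",
)

# Default smoothing windows per built-in provider (odd residue counts).
DEFAULT_WINDOWS = {
    "order": 21,
    "secondary_structure": 9,
    "antigenicity": 7,
    "hydrophobicity": 9,
}

# TOP-IDP disorder propensity (Campen et al. 2008): positive = disorder
# promoting, negative = order promoting.  The order track is 1 minus the
# normalized windowed value of this scale.
TOP_IDP_DISORDER = {
    "A": 0.060, "R": 0.180, "N": 0.007, "D": 0.192, "C": 0.020,
    "Q": 0.318, "E": 0.736, "G": 0.166, "H": 0.303, "I": -0.486,
    "L": -0.326, "K": 0.586, "M": -0.397, "F": -0.697, "P": 0.987,
    "S": 0.341, "T": 0.059, "W": -0.884, "Y": -0.510, "V": -0.121,
}

# Chou-Fasman conformational propensities; the secondary-structure signal
# takes max(helix, strand) per residue before windowing.
CHOU_FASMAN_HELIX = {
    "A": 1.42, "R": 0.98, "N": 0.67, "D": 1.01, "C": 0.70,
    "Q": 1.11, "E": 1.51, "G": 0.57, "H": 1.00, "I": 1.08,
    "L": 1.21, "K": 1.16, "M": 1.45, "F": 1.13, "P": 0.57,
    "S": 0.77, "T": 0.83, "W": 1.08, "Y": 0.69, "V": 1.06,
}
CHOU_FASMAN_STRAND = {
    "A": 0.83, "R": 0.93, "N": 0.89, "D": 0.54, "C": 1.19,
    "Q": 1.10, "E": 0.37, "G": 0.75, "H": 0.87, "I": 1.60,
    "L": 1.30, "K": 0.74, "M": 1.05, "F": 1.38, "P": 0.55,
    "S": 0.75, "T": 1.19, "W": 1.37, "Y": 1.47, "V": 1.70,
}

# Kolaskar-Tongaonkar antigenic propensity.
KOLASKAR_ANTIGENICITY = {
    "A": 1.064, "R": 0.873, "N": 0.776, "D": 1.056, "C": 1.412,
    "Q": 1.015, "E": 0.958, "G": 1.015, "H": 1.105, "I": 1.152,
    "L": 1.250, "K": 0.930, "M": 1.341, "F": 1.091, "P": 1.064,
    "S": 1.012, "T": 0.909, "W": 0.893, "Y": 1.161, "V": 1.322,
}

# Kyte-Doolittle hydropathy.
KYTE_DOOLITTLE_HYDROPATHY = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

_SS_PROPENSITY = {
    aa: max(CHOU_FASMAN_HELIX[aa], CHOU_FASMAN_STRAND[aa])
    for aa in CHOU_FASMAN_HELIX
}


@dataclass(frozen=True)
class FeatureTrack:
    """One named per-residue signal, normalized to [0, 1]."""

    feature_name: str
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.feature_name not in FEATURE_NAMES:
            raise ValueError(f"unknown feature {self.feature_name!r}")
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 1 or vals.size == 0:
            raise ValueError("track values must be a non-empty 1-D vector")
        if np.any(vals < 0) or np.any(vals > 1):
            raise ValueError(f"track {self.feature_name}: values outside [0, 1]")

    def __len__(self) -> int:
        return self.values.size


def sliding_window_scale(
    sequence: str, scale: dict[str, float], window: int
) -> np.ndarray:
    """Windowed mean of a residue scale along a sequence.

    The window is centred at each position and truncated at the termini
    (no phantom residues), so positions near the ends average over fewer
    residues.  Letters absent from the scale (notably X) contribute 0.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 1")
    n = len(sequence)
    if window > n:
        raise ValueError(f"window {window} exceeds sequence length {n}")
    raw = np.array([scale.get(ch, 0.0) for ch in sequence], dtype=float)
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(raw)])
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half, n - 1)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def minmax_normalize(values: np.ndarray) -> np.ndarray:
    """Map a vector linearly onto [0, 1]; a constant vector maps to 0.5."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot normalize an empty vector")
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.full_like(values, 0.5)
    return (values - lo) / (hi - lo)


def builtin_track(
    protein: ProteinRecord, feature_name: str, window: int | None = None
) -> FeatureTrack:
    """Compute one of the four sequence-only tracks for a protein.

    order
        1 minus the normalized windowed TOP-IDP disorder propensity, so the
        value rises in ordered regions.
    secondary_structure
        normalized windowed max(helix, strand) Chou-Fasman propensity.
    antigenicity
        normalized windowed Kolaskar-Tongaonkar propensity.
    hydrophobicity
        normalized windowed Kyte-Doolittle hydropathy.

    Conservation cannot be derived from a single sequence; request it via
    :func:`conservation_track` with an alignment.
    """
    if feature_name == "conservation":
        raise ValueError(
            "conservation needs a homolog alignment; use conservation_track"
        )
    scales = {
        "order": TOP_IDP_DISORDER,
        "secondary_structure": _SS_PROPENSITY,
        "antigenicity": KOLASKAR_ANTIGENICITY,
        "hydrophobicity": KYTE_DOOLITTLE_HYDROPATHY,
    }
    if feature_name not in scales:
        raise ValueError(f"unknown feature {feature_name!r}")
    seq = sanitize_sequence(protein.sequence)
    win = window if window is not None else DEFAULT_WINDOWS[feature_name]
    win = min(win, len(seq) if len(seq) % 2 == 1 else len(seq) - 1)
    win = max(win, 1)
    smoothed = sliding_window_scale(seq, scales[feature_name], win)
    norm = minmax_normalize(smoothed)
    if feature_name == "order":
        norm = 1.0 - norm
    return FeatureTrack(feature_name, norm)


def alignment_conservation(columns: np.ndarray) -> np.ndarray:
    """Raw per-column conservation of an alignment, 1 - H/log2(20).

    ``columns`` is a character matrix (rows = sequences).  Gaps (``-`` or
    ``.``) are excluded from the counts; a column with fewer than two
    non-gap symbols is uninformative and scores 0.5.
    """
    n_cols = columns.shape[1]
    out = np.empty(n_cols)
    for j in range(n_cols):
        col = [c for c in columns[:, j] if c not in ("-", ".")]
        if len(col) < 2:
            out[j] = 0.5
            continue
        _, freq = np.unique(col, return_counts=True)
        p = freq / freq.sum()
        entropy = -np.sum(p * np.log2(p))
        out[j] = 1.0 - entropy / math.log2(20)
    return out


def conservation_track(
    protein: ProteinRecord, alignment: list[str]
) -> FeatureTrack:
    """Conservation signal from a gapped alignment containing the query.

    The query row is located by stripping gaps and matching the protein
    sequence; its non-gap columns define the coordinate mapping.  Column
    conservation is ``1 - H/log2(20)`` (Shannon entropy over non-gap
    residues), then min-max normalized per protein.
    """
    if not alignment:
        raise ValueError("empty alignment")
    lengths = {len(row) for row in alignment}
    if len(lengths) != 1:
        raise ValueError("alignment rows must have equal length")
    target = protein.sequence.upper()
    query_row = None
    for row in alignment:
        if row.upper().replace("-", "").replace(".", "") == target:
            query_row = row.upper()
            break
    if query_row is None:
        raise ValueError(
            f"no alignment row matches the query sequence of {protein.id}"
        )
    matrix = np.array([list(row.upper()) for row in alignment])
    raw = alignment_conservation(matrix)
    query_cols = [j for j, c in enumerate(query_row) if c not in ("-", ".")]
    per_residue = raw[query_cols]
    return FeatureTrack("conservation", minmax_normalize(per_residue))


def import_tracks(
    table, proteins: dict[str, ProteinRecord]
) -> dict[str, dict[str, FeatureTrack]]:
    """Build feature tracks from a long-format table of predictor output.

    ``table`` is a pandas DataFrame with columns ``protein_id``,
    ``position`` (1-based), ``feature_name``, ``value``.  Per protein and
    feature, missing positions are filled with 0 and the vector is min-max
    normalized (an identity when the raw values already span [0, 1]); raw
    values outside [0, 1] trigger a logged notice.  Rows with positions
    outside the protein or unknown proteins are rejected with a warning;
    an unknown feature name is an error.
    """
    bad_features = set(table["feature_name"]) - set(FEATURE_NAMES)
    if bad_features:
        raise ValueError(f"unknown feature name(s): {sorted(bad_features)}")

    out: dict[str, dict[str, FeatureTrack]] = {}
    for (pid, feat), sub in table.groupby(["protein_id", "feature_name"], sort=True):
        if pid not in proteins:
            logger.warning("track rows for unknown protein %s dropped", pid)
            continue
        n = len(proteins[pid])
        values = np.zeros(n)
        positions = sub["position"].to_numpy(dtype=int)
        vals = sub["value"].to_numpy(dtype=float)
        in_range = (positions >= 1) & (positions <= n)
        if not in_range.all():
            logger.warning(
                "protein %s feature %s: %d rows out of range [1, %d] dropped",
                pid, feat, int((~in_range).sum()), n,
            )
        values[positions[in_range] - 1] = vals[in_range]
        if values.min() < 0 or values.max() > 1:
            logger.info(
                "protein %s feature %s: raw values outside [0, 1]; "
                "min-max normalizing", pid, feat,
            )
        out.setdefault(pid, {})[feat] = FeatureTrack(feat, minmax_normalize(values))
    return out


def builtin_tracks(
    protein: ProteinRecord,
    windows: dict[str, int] | None = None,
    alignment: list[str] | None = None,
) -> dict[str, FeatureTrack]:
    """All available built-in tracks for one protein.

    Without an alignment the conservation track defaults to an
    uninformative constant 0.5 (weight it to zero or import real rate
    output for meaningful conservation).
    """
    windows = windows or {}
    tracks = {
        name: builtin_track(protein, name, windows.get(name))
        for name in DEFAULT_WINDOWS
    }
    if alignment is not None:
        tracks["conservation"] = conservation_track(protein, alignment)
    else:
        tracks["conservation"] = FeatureTrack(
            "conservation", np.full(len(protein), 0.5)
        )
    return tracks
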