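"""Three-part WBC classification from PPED features and cell size.

Each cell's descriptor is compared by Euclidean distance to one
standard (reference) PPED vector per class — neutrophil, monocyte,
lymphocyte. Distances are normalized by their maximum and flipped into
pseudo-probabilities, P_m = 1 − D/max(D), so the nearest class scores
highest. Because low-resolution shadows blur morphological detail, a
second, independent cue is fused in: the cell's equivalent diameter is
binned into the classic size ranges (lymphocyte 5–10 µm, neutrophil
10–14 µm, monocyte 14–25 µm) and the matching class receives an
indicator probability P_s. The decision score is the fixed-weight blend
T = 0.9·P_m + 0.1·P_s and the cell is assigned to the arg max.

Class order everywhere is (Neu, Mon, Lym).
"""

from __future__ import annotations

import json
import os
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

CLASSES = ("Neu", "Mon", "Lym")

#: Size-prior bins in µm, lower-inclusive; the top of the monocyte bin
#: is closed because nothing wider counts as a single leukocyte.
SIZE_BINS_UM = {"Lym": (5.0, 10.0), "Neu": (10.0, 14.0), "Mon": (14.0, 25.0)}

DEFAULT_FEATURE_WEIGHT = 0.9
DEFAULT_SIZE_WEIGHT = 0.1


def euclidean_distance(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    return float(np.linalg.norm(x - y))


@dataclass
class StandardVectors:
    """Per-class reference PPED vectors the classifier measures against."""

    vectors: dict[str, np.ndarray]
    provenance: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in CLASSES if c not in self.vectors]
        if missing:
            raise ValueError(f"standard vectors missing classes {missing}")
        clean = {}
        for c in CLASSES:
            v = np.asarray(self.vectors[c], dtype=np.float64)
            if v.shape != (64,):
                raise ValueError(f"standard vector for {c} must have length 64, got {v.shape}")
            if (v < 0).any():
                raise ValueError(f"standard vector for {c} has negative components")
            clean[c] = v
        self.vectors = clean

    def as_matrix(self) -> np.ndarray:
        return np.stack([self.vectors[c] for c in CLASSES])

    def to_json(self, path: str | os.PathLike) -> None:
        payload = {"provenance": self.provenance,
                   "vectors": {c: self.vectors[c].tolist() for c in CLASSES}}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "StandardVectors":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(vectors={c: np.asarray(v) for c, v in payload["vectors"].items()},
                   provenance=payload.get("provenance", ""))


def train_standards(vectors: Sequence[np.ndarray], labels: Sequence[str],
                    aggregate: str = "mean", provenance: str = "") -> StandardVectors:
    """Build standard vectors as the per-class mean (or median) descriptor.

    Raises a training error naming any class with no exemplar.
    """
    if len(vectors) != len(labels):
        raise ValueError("vectors and labels must have equal length")
    if aggregate not in ("mean", "median"):
        raise ValueError(f"unknown aggregate {aggregate!r}")
    agg = np.mean if aggregate == "mean" else np.median
    out: dict[str, np.ndarray] = {}
    for c in CLASSES:
        group = [np.asarray(v, dtype=np.float64) for v, l in zip(vectors, labels) if l == c]
        if not group:
            raise ValueError(f"no training exemplars for class {c!r}")
        out[c] = agg(np.stack(group), axis=0)
    return StandardVectors(out, provenance=provenance)


def feature_probabilities(v: np.ndarray, standards: StandardVectors
                          ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Distances to the three standards and their probability transform.

    Returns ``(D_p, D_m, P_m)`` in class order: raw Euclidean distances,
    distances normalized by their maximum, and P_m = 1 − D_m. If all
    three distances are zero (degenerate input) the normalized distances
    are taken as 0 and every class gets probability 1.
    """
    d_p = np.array([euclidean_distance(v, standards.vectors[c]) for c in CLASSES])
    d_max = d_p.max()
    if d_max == 0.0:
        d_m = np.zeros(3)
    else:
        d_m = d_p / d_max
    return d_p, d_m, 1.0 - d_m


def size_class(d: float) -> str | None:
    """Size-prior bin of an equivalent diameter in µm, or None outside 5–25."""
    if d <= 0:
        raise ValueError(f"diameter must be positive, got {d}")
    for c, (lo, hi) in SIZE_BINS_UM.items():
        if lo <= d < hi:
            return c
    if d == SIZE_BINS_UM["Mon"][1]:
        return "Mon"
    return None


def size_probabilities(t: str | None) -> np.ndarray:
    """Indicator vector of the size bin in class order; zeros when t is None."""
    if t is None:
        return np.zeros(3)
    if t not in CLASSES:
        raise ValueError(f"unknown class {t!r}")
    return np.array([1.0 if c == t else 0.0 for c in CLASSES])


@dataclass
class ClassScores:
    """All intermediate and final scores for one classified cell."""

    d_p: np.ndarray
    d_m: np.ndarray
    p_m: np.ndarray
    p_s: np.ndarray
    t_m: np.ndarray
    label: str
    diameter_um: float


def classify(v: np.ndarray, diameter_um: float, standards: StandardVectors,
             w_feature: float = DEFAULT_FEATURE_WEIGHT,
             w_size: float = DEFAULT_SIZE_WEIGHT) -> ClassScores:
    """Fuse feature and size probabilities and decide the class.

    ``T(i) = w_feature·P_m(i) + w_size·P_s(i)``; the label is the class
    with the largest T. Exact ties go first to the class with the
    smaller raw distance, then to the fixed order Neu, Mon, Lym.
    """
    if w_feature < 0 or w_size < 0 or abs(w_feature + w_size - 1.0) > 1e-9:
        raise ValueError(f"weights must be non-negative and sum to 1, got "
                         f"({w_feature}, {w_size})")
    d_p, d_m, p_m = feature_probabilities(v, standards)
    p_s = size_probabilities(size_class(diameter_um))
    t_m = w_feature * p_m + w_size * p_s
    # Lexicographic tie-break: max T, then min D_p, then class order.
    order = sorted(range(3), key=lambda i: (-t_m[i], d_p[i], i))
    return ClassScores(d_p=d_p, d_m=d_m, p_m=p_m, p_s=p_s, t_m=t_m,
                       label=CLASSES[order[0]], diameter_um=float(diameter_um))


def differential_count(labels: Iterable[str]) -> dict[str, float]:
    """Percentage of each class among the given labels (sums to 100)."""
    labels = list(labels)
    if not labels:
        raise ValueError("cannot compute a differential of zero cells")
    unknown = set(labels) - set(CLASSES)
    if unknown:
        raise ValueError(f"unknown class labels {sorted(unknown)}")
    counts = Counter(labels)
    return {c: 100.0 * counts.get(c, 0) / len(labels) for c in CLASSES}
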