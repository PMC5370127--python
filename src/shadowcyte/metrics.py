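"""Agreement metrics between two three-part differential counts.

The instrument's output for a sample is a (Neu, Mon, Lym) percentage
triple; the reference is the same triple from a hematology analyzer.
Agreement is summarized the way the field reports it for this kind of
method comparison: a per-sample Pearson correlation across the three
class percentages, the mean of those correlations over samples, and a
per-class mean absolute error in percentage points.

A Pearson coefficient over only three points is statistically fragile —
it can be driven to ±1 by a single dominant class — so treat the
correlations as a coarse concordance index, not an inferential
statistic. The package ships a six-sample comparison table between a
lens-free shadow-imaging prototype and a Mindray BC-5180 analyzer as a
worked fixture (:func:`reference_differentials`).
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classifier import CLASSES


@dataclass
class DifferentialPair:
    """One sample's (Neu, Mon, Lym) percentages from test and reference."""

    sample_id: str
    test: tuple[float, float, float]
    reference: tuple[float, float, float]

    def __post_init__(self) -> None:
        for name, triple in (("test", self.test), ("reference", self.reference)):
            if len(triple) != 3:
                raise ValueError(f"{name} must have three percentages")
            if any(not 0 <= v <= 100 for v in triple):
                raise ValueError(f"{name} percentages must lie in [0, 100]: {triple}")


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation; rejects constant inputs."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size < 2 or y.size < 2:
        raise ValueError("correlation needs at least two points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant input")
    return float(stats.pearsonr(x, y)[0])


def mean_correlation(pairs: Iterable[DifferentialPair]) -> float:
    pairs = list(pairs)
    if not pairs:
        raise ValueError("no differential pairs given")
    return float(np.mean([pearson_correlation(p.test, p.reference) for p in pairs]))


def mean_abs_error(pairs: Iterable[DifferentialPair], wbc_class: str) -> float:
    """Mean |test − reference| for one class, in percentage points."""
    pairs = list(pairs)
    if not pairs:
        raise ValueError("no differential pairs given")
    if wbc_class not in CLASSES:
        raise ValueError(f"unknown class {wbc_class!r}")
    k = CLASSES.index(wbc_class)
    return float(np.mean([abs(p.test[k] - p.reference[k]) for p in pairs]))


def evaluate(pairs: Iterable[DifferentialPair]) -> pd.DataFrame:
    """Per-sample correlations plus a summary row of mean r and MAEs."""
    pairs = list(pairs)
    rows = [{"sample_id": p.sample_id,
             "correlation": pearson_correlation(p.test, p.reference)}
            for p in pairs]
    df = pd.DataFrame(rows)
    summary = {"mean_correlation": mean_correlation(pairs)}
    for c in CLASSES:
        summary[f"mae_{c}"] = mean_abs_error(pairs, c)
    return df.assign(**{k: v for k, v in summary.items()})


def load_differential_pairs(path: str | os.PathLike | "os.PathLike[str]") -> list[DifferentialPair]:
    """Read pairs from a CSV with columns sample_id, test_neu, test_mon,
    test_lym, ref_neu, ref_mon, ref_lym."""
    df = pd.read_csv(path)
    needed = ["sample_id", "test_neu", "test_mon", "test_lym",
              "ref_neu", "ref_mon", "ref_lym"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"differential CSV missing columns {missing}")
    return [
        DifferentialPair(
            sample_id=str(r.sample_id),
            test=(r.test_neu, r.test_mon, r.test_lym),
            reference=(r.ref_neu, r.ref_mon, r.ref_lym),
        )
        for r in df.itertuples()
    ]


def reference_differentials() -> list[DifferentialPair]:
    """The bundled six-patient prototype-vs-analyzer comparison table."""
    src = resources.files("shadowcyte.data") / "patient_differentials.csv"
    with resources.as_file(src) as path:
        return load_differential_pairs(path)
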