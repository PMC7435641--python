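"""Counts to yield mass, and counting-accuracy evaluation.

Yield is estimated as total fruit count x a representative per-fruit weight
(default 97.95 g, the mean of a 20-fruit field sample in the deployment this
package models).  Counting accuracy is the average percentage error (APE):
the mean over evaluation images of |EC - AC| / AC x 100, where EC is the
estimated and AC the actual count.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

DEFAULT_REPRESENTATIVE_WEIGHT_G = 97.95


def estimate_yield(total_count: int,
                   representative_weight: float = DEFAULT_REPRESENTATIVE_WEIGHT_G
                   ) -> float:
    """Estimated yield in kilograms: count x representative weight (g) / 1000."""
    if total_count < 0:
        raise ValueError("total_count must be >= 0")
    if representative_weight <= 0:
        raise ValueError("representative_weight must be > 0 grams")
    return total_count * representative_weight / 1000.0


def representative_weight(sample_weights) -> float:
    """Mean of a field sample of individual fruit weights (grams)."""
    w = np.asarray(sample_weights, dtype=float)
    if w.size == 0:
        raise ValueError("need at least one sampled fruit weight")
    if np.any(w <= 0):
        raise ValueError("fruit weights must be positive")
    return float(w.mean())


def ape(pairs) -> float:
    """Average percentage error over (estimated, actual) count pairs.

    APE = (100 / N) * sum_i |EC_i - AC_i| / AC_i.  Undefined when any actual
    count is zero.
    """
    pairs = list(pairs)
    if len(pairs) == 0:
        raise ValueError("APE needs at least one (EC, AC) pair")
    total = 0.0
    for ec, ac in pairs:
        if ac <= 0:
            raise ValueError("actual count must be > 0 (relative error undefined)")
        total += abs(ec - ac) / ac
    return 100.0 * total / len(pairs)


@dataclass
class YieldReport:
    """Per-panorama counts and the derived yield estimate.

    ``estimated_yield`` (kg) is always ``total_count x representative_weight
    / 1000``; the metadata dict may carry an orchard id, a timestamp and the
    configuration hash and is persisted as commented CSV header lines.
    """

    per_panorama_counts: list[int]
    representative_weight: float = DEFAULT_REPRESENTATIVE_WEIGHT_G
    metadata: dict = field(default_factory=dict)

    @property
    def total_count(self) -> int:
        return int(sum(self.per_panorama_counts))

    @property
    def estimated_yield(self) -> float:
        return estimate_yield(self.total_count, self.representative_weight)

    def to_csv(self, path: str | Path | None = None) -> str:
        lines = [f"# representative_weight_g={self.representative_weight!r}"]
        for key in sorted(self.metadata):
            lines.append(f"# {key}={self.metadata[key]}")
        df = pd.DataFrame({
            "panorama_id": list(range(len(self.per_panorama_counts))),
            "count": self.per_panorama_counts,
        })
        df["estimated_kg"] = [
            estimate_yield(c, self.representative_weight) for c in df["count"]
        ]
        total = pd.DataFrame({
            "panorama_id": ["total"],
            "count": [self.total_count],
            "estimated_kg": [self.estimated_yield],
        })
        body = pd.concat([df, total], ignore_index=True).to_csv(index=False)
        text = "\n".join(lines) + "\n" + body
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_csv(cls, source: str | Path) -> "YieldReport":
        if isinstance(source, Path) or (isinstance(source, str)
                                        and "\n" not in source):
            text = Path(source).read_text()
        else:
            text = source
        metadata = {}
        weight = DEFAULT_REPRESENTATIVE_WEIGHT_G
        for line in text.splitlines():
            if line.startswith("# "):
                key, _, value = line[2:].partition("=")
                if key == "representative_weight_g":
                    weight = float(value)
                else:
                    metadata[key] = value
        df = pd.read_csv(io.StringIO(text), comment="#")
        rows = df[df["panorama_id"] != "total"]
        return cls(per_panorama_counts=[int(c) for c in rows["count"]],
                   representative_weight=weight, metadata=metadata)


@dataclass
class EvalRecord:
    """Per-image (estimated, actual) counts and the resulting APE."""

    pairs: list[tuple[int, int]]
    image_ids: list[str] | None = None

    @property
    def n(self) -> int:
        return len(self.pairs)

    @property
    def ape(self) -> float:
        return ape(self.pairs)

    def to_csv(self, path: str | Path | None = None) -> str:
        ids = self.image_ids or [str(i) for i in range(self.n)]
        df = pd.DataFrame({
            "image_id": ids,
            "EC": [p[0] for p in self.pairs],
            "AC": [p[1] for p in self.pairs],
        })
        df["ape_percent"] = 100.0 * (df["EC"] - df["AC"]).abs() / df["AC"]
        summary = pd.DataFrame({
            "image_id": ["summary"],
            "EC": [df["EC"].sum()],
            "AC": [df["AC"].sum()],
            "ape_percent": [self.ape],
        })
        text = pd.concat([df, summary], ignore_index=True).to_csv(index=False)
        if path is not None:
            Path(path).write_text(text)
        return text


def run_ablation(
    cascade_numbers=(2, 4, 6),
    rejection_rates=(10.0, 20.0, 30.0, 40.0, 50.0),
    preprocessing=(True, False),
    scene_spec=None,
    n_eval_scenes: int = 6,
    seed: int = 0,
    config=None,
) -> pd.DataFrame:
    """Train and evaluate the detector over the two standard ablation grids.

    Grid A varies the number of cascade stages with preprocessing switched
    on or off (rejection rate fixed at the config default); grid B sweeps
    the rejection rate at the config's default stage count, with
    preprocessing on.  Returns a tidy table with columns
    ``experiment, n_stages, rejection_rate, preprocessing, ape_percent``;
    cascades are trained once per (n_stages, rejection_rate) cell and shared
    between preprocessing settings (training never sees the mask switch).
    """
    from kiwicount.config import PipelineConfig
    from kiwicount.pipeline import (evaluate_counting, make_training_windows,
                                    train_default_cascade)

    config = config or PipelineConfig()
    windows = make_training_windows(config, seed=seed, scene_spec=scene_spec)
    cache: dict[tuple[int, float], object] = {}

    def cascade_for(n_stages: int, rejection: float):
        key = (n_stages, rejection)
        if key not in cache:
            cache[key] = train_default_cascade(
                config, seed=seed, n_stages=n_stages,
                rejection_rate=rejection, windows=windows,
                scene_spec=scene_spec)
        return cache[key]

    rows = []
    for n_stages in cascade_numbers:
        cas = cascade_for(int(n_stages), config.rejection_rate)
        for pre in preprocessing:
            record = evaluate_counting(
                cas, config, n_scenes=n_eval_scenes, seed=seed,
                preprocessing=bool(pre), scene_spec=scene_spec)
            rows.append(("cascade_number", int(n_stages),
                         config.rejection_rate, bool(pre), record.ape))
    for rejection in rejection_rates:
        cas = cascade_for(config.n_stages, float(rejection))
        record = evaluate_counting(
            cas, config, n_scenes=n_eval_scenes, seed=seed,
            preprocessing=True, scene_spec=scene_spec)
        rows.append(("rejection_rate", config.n_stages, float(rejection),
                     True, record.ape))
    return pd.DataFrame(
        rows, columns=["experiment", "n_stages", "rejection_rate",
                       "preprocessing", "ape_percent"])
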