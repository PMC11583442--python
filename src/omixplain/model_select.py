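"""Best-model recommendation from the train/test performance plane.

Each tuned model is a point (t, v) = (train score, test score) of the
configured metric.  The ideal point is (1, 1) for score-type metrics
(values bounded above by 1) and the origin (0, 0) for error-type metrics.
The recommended model minimizes

    D = sqrt((t − i)² + (v − i)²) + |t − v| / √2,

the Euclidean distance to the ideal point plus the perpendicular distance
to the diagonal t = v.  The diagonal term penalizes overfitting: a model
whose train performance far outruns its test performance is pushed away
even when its test value alone looks attractive.  Ties within 1e-12 go to
the first model in registry order and are recorded in a tie note.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

TIE_TOL = 1e-12


@dataclass(frozen=True)
class PerformancePoint:
    name: str
    train: float
    test: float
    orientation: str  # "score" (ideal 1) | "error" (ideal 0)

    def __post_init__(self):
        if self.orientation not in ("score", "error"):
            raise ValueError(f"unknown orientation {self.orientation!r}")
        if self.orientation == "error" and (self.train < 0 or self.test < 0):
            raise ValueError("error-type values must be nonnegative")


def distance_to_ideal(point: PerformancePoint) -> float:
    """The combined closeness criterion D (smaller is better)."""
    ideal = 1.0 if point.orientation == "score" else 0.0
    euclid = math.hypot(point.train - ideal, point.test - ideal)
    diagonal = abs(point.train - point.test) / math.sqrt(2.0)
    return euclid + diagonal


def select_best(
    points: list[PerformancePoint],
) -> tuple[PerformancePoint, str | None]:
    """The point minimizing D; a tie note when >1 model is within 1e-12."""
    if not points:
        raise ValueError("no performance points to select from")
    orientations = {p.orientation for p in points}
    if len(orientations) > 1:
        raise ValueError("mixed metric orientations in one selection")
    distances = [distance_to_ideal(p) for p in points]
    d_min = min(distances)
    tied = [p for p, d in zip(points, distances) if d - d_min <= TIE_TOL]
    winner = tied[0]
    note = None
    if len(tied) > 1:
        others = ", ".join(p.name for p in tied[1:])
        note = (
            f"Best-model selection tie: {winner.name} chosen (first in "
            f"registry order); equally distant candidates: {others}. "
            f"D = {d_min:.12g}."
        )
    return winner, note
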