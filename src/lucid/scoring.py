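"""Rank fusion of the three per-frame scores into the informative score S_I.

Each frame carries three raw scores — eardrum view S_edv, eardrum coverage
S_edc and final blur S_blf — all better-when-larger.  Each score is ranked
across the video's frames (rank 1 = best, ties get the average of the tied
positions) and the ranks are fused:

    S_I = 0.4 * Rank(S_edv) + 0.2 * Rank(S_edc) + 0.4 * Rank(S_blf)

A *smaller* S_I marks a more informative frame; the top-k frames are those
with the smallest S_I, ties broken by larger S_edv then smaller frame index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "DEFAULT_WEIGHTS",
    "FusionWeights",
    "rank_scores",
    "informative_score",
    "select_top_k",
]


@dataclass(frozen=True)
class FusionWeights:
    w_edv: float = 0.4
    w_edc: float = 0.2
    w_blf: float = 0.4

    def __post_init__(self) -> None:
        ws = (self.w_edv, self.w_edc, self.w_blf)
        if any(w < 0 for w in ws):
            raise ValueError(f"fusion weights must be non-negative: {ws}")
        if abs(sum(ws) - 1.0) > 1e-9:
            raise ValueError(f"fusion weights must sum to 1: {ws}")


DEFAULT_WEIGHTS = FusionWeights()


def rank_scores(values: np.ndarray | list[float]) -> np.ndarray:
    """Rank with 1 = largest raw score; ties receive average ranks."""
    values = np.asarray(values, dtype=np.float64)
    if values.size < 1:
        raise ValueError("need at least one value")
    if not np.isfinite(values).all():
        raise ValueError("scores must be finite")
    return rankdata(-values, method="average")


def informative_score(
    rows: pd.DataFrame, weights: FusionWeights = DEFAULT_WEIGHTS
) -> pd.DataFrame:
    """Add rank columns and S_I to a frame-score table.

    ``rows`` must have columns ``frame_index``, ``s_edv``, ``s_edc``,
    ``s_blf``.  Returns a copy with ``rank_edv``, ``rank_edc``, ``rank_blf``
    and ``s_i`` added.
    """
    required = {"frame_index", "s_edv", "s_edc", "s_blf"}
    missing = required - set(rows.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    out = rows.copy()
    out["rank_edv"] = rank_scores(out["s_edv"].to_numpy())
    out["rank_edc"] = rank_scores(out["s_edc"].to_numpy())
    out["rank_blf"] = rank_scores(out["s_blf"].to_numpy())
    out["s_i"] = (
        weights.w_edv * out["rank_edv"]
        + weights.w_edc * out["rank_edc"]
        + weights.w_blf * out["rank_blf"]
    )
    return out


def select_top_k(rows: pd.DataFrame, k: int) -> list[int]:
    """Frame indices of the k most informative frames, most informative first.

    Ordering: ascending S_I, then descending S_edv, then ascending frame
    index — a deterministic total order.
    """
    if "s_i" not in rows.columns:
        raise ValueError("rows must contain s_i (run informative_score first)")
    n = len(rows)
    if not (1 <= k <= n):
        raise ValueError(f"k must lie in [1, {n}], got {k}")
    ordered = rows.sort_values(
        ["s_i", "s_edv", "frame_index"], ascending=[True, False, True]
    )
    return [int(i) for i in ordered["frame_index"].head(k)]
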