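"""Dot-product dictionary matching — the conventional MRF reconstruction.

Each measured trajectory is 2-norm normalized and compared against every
normalized dictionary entry by inner product; the entry with the highest
score wins (ties broken by lowest dictionary index). Evaluation is chunked
over dictionary rows to bound memory; results are chunk-size invariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dictionary import Dictionary, l2_normalize
from .io import ImageStack, QuantMaps

__all__ = ["MatchResult", "dot_product_match", "match_stack"]


@dataclass
class MatchResult:
    """Best dictionary entry per query trajectory."""

    indices: np.ndarray  # (n_queries,) best-entry flat grid index
    params: np.ndarray  # (n_queries, n_axes) matched parameter tuples
    scores: np.ndarray  # (n_queries,) inner product of the winning entry
    axis_names: tuple[str, ...]


def dot_product_match(
    dictionary: Dictionary,
    trajectories: np.ndarray,
    chunk_size: int = 65536,
) -> MatchResult:
    """Exhaustive inner-product argmax of queries against the dictionary."""
    if not dictionary.normalized:
        raise ValueError("dictionary must be 2-norm normalized before matching")
    queries = np.atleast_2d(np.asarray(trajectories, dtype=float))
    if queries.shape[0] == 0:
        raise ValueError("no query trajectories (empty mask?)")
    n = dictionary.signals.shape[1]
    if queries.shape[1] != n:
        raise ValueError(
            f"trajectory length {queries.shape[1]} != dictionary length {n}"
        )
    queries = l2_normalize(queries)

    best_idx = np.zeros(len(queries), dtype=np.int64)
    best_score = np.full(len(queries), -np.inf)
    for start in range(0, len(dictionary.signals), chunk_size):
        block = dictionary.signals[start : start + chunk_size]
        scores = queries @ block.T  # (n_queries, block)
        idx = np.argmax(scores, axis=1)
        val = scores[np.arange(len(queries)), idx]
        better = val > best_score  # strict: keeps the lowest index on ties
        best_idx[better] = idx[better] + start
        best_score[better] = val[better]

    values = dictionary.grid.value_matrix()[best_idx]
    return MatchResult(
        indices=best_idx,
        params=values,
        scores=best_score,
        axis_names=dictionary.grid.axis_names,
    )


def match_stack(
    dictionary: Dictionary,
    stack: ImageStack,
    mask: np.ndarray | None = None,
    chunk_size: int = 65536,
) -> QuantMaps:
    """Match every masked pixel of a stack; return parameter maps (NaN
    outside the mask) plus a ``match_score`` map."""
    if mask is None:
        mask = np.ones(stack.spatial_shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != stack.spatial_shape:
        raise ValueError("mask shape does not match stack geometry")
    if not mask.any():
        raise ValueError("empty mask")
    result = dot_product_match(dictionary, stack.trajectories(mask), chunk_size)
    maps = {}
    for j, name in enumerate(result.axis_names):
        vol = np.full(stack.spatial_shape, np.nan)
        vol[mask] = result.params[:, j]
        maps[name] = vol
    score = np.full(stack.spatial_shape, np.nan)
    score[mask] = result.scores
    maps["match_score"] = score
    return QuantMaps(
        maps=maps, affine=stack.affine, mask=mask,
        provenance={"dictionary_schedule": dictionary.schedule_id},
    )
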