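"""Negative-sample (decoy) selection by minimal summed Tanimoto similarity.

Balanced training sets are built by pairing each positive set with decoys
drawn from a large pool.  For every decoy g_i the sum over all positives c_j
of tanimoto(g_i, c_j) is computed; the decoys with the smallest sums — i.e.
least similar to the active chemistry — are kept, at a configurable
negative:positive ratio (default 2, so m positives yield the 2m least similar
decoys).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .chem import Compound, Fingerprint, tanimoto_matrix

__all__ = ["DecoyRanking", "score_decoys", "select_negatives"]


@dataclass(frozen=True)
class DecoyRanking:
    """A decoy's summed similarity to the positive set and its rank (1-based)."""

    decoy_id: str
    sum_similarity: float
    rank: int


def _fps(items: Sequence) -> list[Fingerprint]:
    out = []
    for it in items:
        out.append(it if isinstance(it, Fingerprint) else it.featurize())
    return out


def _ids(items: Sequence) -> list[str]:
    return [it.id if isinstance(it, Compound) else f"decoy{i}" for i, it in enumerate(items)]


def score_decoys(positives: Sequence, decoys: Sequence) -> list[DecoyRanking]:
    """Rank decoys by summed Tanimoto similarity to the positive set, ascending.

    Accepts :class:`Fingerprint` or :class:`Compound` sequences.  Ties keep
    input order (stable sort), so the ranking is fully deterministic.
    """
    if len(positives) == 0:
        raise ValueError("empty positive set")
    if len(decoys) == 0:
        raise ValueError("empty decoy pool")
    sums = tanimoto_matrix(_fps(decoys), _fps(positives)).sum(axis=1)
    order = np.argsort(sums, kind="stable")
    ids = _ids(decoys)
    return [
        DecoyRanking(decoy_id=ids[j], sum_similarity=float(sums[j]), rank=r + 1)
        for r, j in enumerate(order)
    ]


def select_negatives(positives: Sequence, decoys: Sequence, ratio: int = 2) -> list:
    """Select the ``ratio * len(positives)`` decoys least similar to the positives.

    Returns the selected decoy objects (Compounds or Fingerprints, matching the
    input) in ascending order of summed similarity.  Raises if the pool is too
    small, stating required vs available counts.
    """
    if ratio < 1:
        raise ValueError("ratio must be a positive integer")
    m = len(positives)
    need = ratio * m
    if len(decoys) < need:
        raise ValueError(
            f"insufficient decoys: need ratio*m = {ratio}*{m} = {need}, "
            f"pool has {len(decoys)}"
        )
    ranking = score_decoys(positives, decoys)
    ids = _ids(decoys)
    index_of = {cid: i for i, cid in enumerate(ids)}
    return [decoys[index_of[r.decoy_id]] for r in ranking[:need]]
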