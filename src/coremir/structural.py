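"""Structural information score from database consistency.

An interaction supported by several target databases that are
themselves mutually consistent carries more prior biological weight
than one appearing in a single source. This module quantifies that
intuition: pairwise chance-corrected consistency indices between the
four engines are normalised so the six unordered engine pairs sum to 1,
and each interaction's structural information score (SI) is the sum of
the normalised indices of the engine pairs that both contain it.

Consequences of the normalisation: presence in all four engines gives
SI = 1 exactly; presence in at most one engine gives SI = 0.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .engines_io import ENGINE_NAMES, CandidatePool, EngineTable


class DegenerateUniverseError(ValueError):
    """Universe too small for the chance-corrected index to be defined."""


@dataclass(frozen=True)
class ConsistencyMatrix:
    """Pairwise engine consistency indices, raw and normalised.

    ``raw`` and ``normalized`` are symmetric 4x4 arrays in the canonical
    engine order with zero diagonal; the normalised off-diagonal values,
    counted once per unordered pair, sum to 1 unless every raw index is
    zero.
    """

    raw: np.ndarray
    normalized: np.ndarray
    universe_size: int

    def pair_value(self, k: int, l: int) -> float:
        return float(self.normalized[k, l])


def consistency_index(
    set_a: frozenset | set,
    set_b: frozenset | set,
    universe_size: int,
) -> float:
    """Chance-corrected similarity of two interaction sets.

    Kuncheva's consistency index, generalised to unequal set sizes:

        I(A, B) = (r*n - |A|*|B|) / (min(|A|, |B|)*n - |A|*|B|)

    with r = |A & B| and n the number of possible interactions. The
    index is 1 when A = B, 0 at chance-level overlap r = |A||B|/n, and
    negative below chance; negatives are clipped to 0 so downstream
    scores stay in [0, 1].
    """
    a, b = len(set_a), len(set_b)
    if min(a, b) < 1:
        raise ValueError("consistency_index requires non-empty sets")
    if universe_size <= max(a, b):
        raise DegenerateUniverseError(
            f"universe_size {universe_size} must exceed both set sizes ({a}, {b})"
        )
    r = len(set(set_a) & set(set_b))
    num = r * universe_size - a * b
    den = min(a, b) * universe_size - a * b
    return float(np.clip(num / den, 0.0, 1.0))


def engine_universe_size(panel: Sequence[EngineTable]) -> int:
    """Number of distinct pairs in the union of the engine tables."""
    union: set = set()
    for table in panel:
        union |= table.interactions
    return len(union)


def build_consistency_matrix(
    panel: Sequence[EngineTable],
    universe_size: int | None = None,
) -> ConsistencyMatrix:
    """Compute and normalise all pairwise engine consistency indices.

    ``universe_size`` defaults to the size of the union of the four
    engine tables — the smallest universe in which every observed
    interaction is possible. Each unordered-pair index is divided by
    the sum over the six unordered pairs; if that sum is zero the
    normalised matrix is all-zero and a warning is raised.
    """
    by_name = {t.name: t for t in panel}
    tables = [by_name[name] for name in ENGINE_NAMES]
    if universe_size is None:
        universe_size = engine_universe_size(tables)
    raw = np.zeros((4, 4))
    for k, l in itertools.combinations(range(4), 2):
        raw[k, l] = raw[l, k] = consistency_index(
            tables[k].interactions, tables[l].interactions, universe_size
        )
    total = sum(raw[k, l] for k, l in itertools.combinations(range(4), 2))
    if total == 0.0:
        warnings.warn(
            "all pairwise consistency indices are zero; structural scores will be 0",
            stacklevel=2,
        )
        normalized = np.zeros((4, 4))
    else:
        normalized = raw / total
    return ConsistencyMatrix(raw=raw, normalized=normalized, universe_size=universe_size)


def structural_scores(pool: CandidatePool, cmatrix: ConsistencyMatrix) -> np.ndarray:
    """Per-interaction structural information score.

    SI of an interaction is the sum, over unordered engine pairs {k, l},
    of the normalised consistency index of that pair when the
    interaction is present in both engines. Values lie in [0, 1]; an
    interaction in fewer than two engines scores 0, one in all four
    scores 1 (when normalisation is well defined).
    """
    presence = pool.presence
    # sum raw indices of supported pairs and divide by the raw total once:
    # with identical summation order the all-engines numerator equals the
    # denominator bit-for-bit, so full support scores exactly 1.0
    pairs = list(itertools.combinations(range(4), 2))
    total = sum(cmatrix.raw[k, l] for k, l in pairs)
    if total == 0.0:
        return np.zeros(len(pool))
    si = np.zeros(len(pool))
    for i in range(len(pool)):
        si[i] = sum(
            cmatrix.raw[k, l] for k, l in pairs
            if presence[i, k] and presence[i, l]
        ) / total
    return np.clip(si, 0.0, 1.0)
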