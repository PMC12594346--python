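"""Merging structural and functional rankings into one hierarchy.

Candidate interactions are ranked twice — once by structural support
(SI) and once by phenotype association (FI) — and the two orders are
merged into the single hierarchy that defines network topology for any
network size k. Two merge modes are supported:

``alternative`` (default)
    Take the next not-yet-selected interaction alternately from the
    functional and the structural ranking, functional first.
``weighted``
    Sort by the convex combination of the two rank positions,
    ``weight * struct_pos + (1 - weight) * func_pos``, ascending.

Ties are broken by the ``isolated`` policy by default: tied
interactions are preferred when their molecules participate in fewer
pool interactions overall, favouring isolated, potentially novel
regulatory paths. The (mirna, gene) lexicographic order is the final
fallback everywhere, making every ranking bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engines_io import CandidatePool

MODES = ("alternative", "weighted")
TIE_POLICIES = ("isolated", "lexicographic")


@dataclass
class ScoredInteraction:
    mirna: str
    gene: str
    si: float
    fi: float
    presence_mask: str
    struct_rank: int = 0
    func_rank: int = 0
    final_rank: int = 0


@dataclass
class InteractionRanking:
    """The merged interaction hierarchy.

    ``interactions`` is ordered by final rank (rank 1 first). Only
    interactions with SI > 0 and a computed FI are eligible.
    """

    interactions: list[ScoredInteraction]
    mode: str
    ties: str
    weight: float | None = None
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.interactions)

    def top(self, k: int) -> list[tuple[str, str]]:
        return [(si.mirna, si.gene) for si in self.interactions[:k]]

    def to_frame(self) -> pd.DataFrame:
        """connections_-style table: one row per interaction, rank order."""
        return pd.DataFrame(
            {
                "mirna": [i.mirna for i in self.interactions],
                "gene": [i.gene for i in self.interactions],
                "SI": [i.si for i in self.interactions],
                "FI": [i.fi for i in self.interactions],
                "presence_mask": [i.presence_mask for i in self.interactions],
                "struct_rank": [i.struct_rank for i in self.interactions],
                "func_rank": [i.func_rank for i in self.interactions],
                "final_rank": [i.final_rank for i in self.interactions],
            }
        )


def _tie_key(pair: tuple[str, str], ties: str, pool: CandidatePool):
    if ties == "isolated":
        occ = pool.occurrence_counts
        return (occ[pair[0]] + occ[pair[1]], pair)
    return pair


def rank_single(
    scores: dict[tuple[str, str], float],
    ties: str,
    pool: CandidatePool,
) -> list[tuple[str, str]]:
    """Order interactions by descending score with deterministic ties.

    The ``isolated`` policy ranks tied interactions by ascending sum of
    endpoint occurrence counts in the pool (rarer molecules first),
    then lexicographically; ``lexicographic`` goes straight to the
    (mirna, gene) order.
    """
    if ties not in TIE_POLICIES:
        raise ValueError(f"unknown tie policy {ties!r}")
    for pair, s in scores.items():
        if not np.isfinite(s):
            raise ValueError(f"non-finite score for {pair}")
    return sorted(scores, key=lambda p: (-scores[p], _tie_key(p, ties, pool)))


def merge_alternative(func_rank: list, struct_rank: list) -> list:
    """Alternate picks from the two rankings, functional first.

    At each step the next not-yet-selected element of the current
    ranking is appended; already-selected elements are skipped. The
    result is a permutation of the input set.
    """
    if set(func_rank) != set(struct_rank):
        raise ValueError("rankings must cover the same interaction set")
    seen = set()
    merged = []
    iters = [iter(func_rank), iter(struct_rank)]
    turn = 0
    while len(merged) < len(func_rank):
        for item in iters[turn]:
            if item not in seen:
                seen.add(item)
                merged.append(item)
                break
        turn = 1 - turn
    return merged


def merge_weighted(
    func_rank: list,
    struct_rank: list,
    weight: float,
    ties: str = "lexicographic",
    pool: CandidatePool | None = None,
) -> list:
    """Sort by convex combination of 1-based rank positions.

    ``weight`` is the weight of the structural ranking; 0 reproduces
    the functional ranking exactly and 1 the structural one.
    """
    if not 0 <= weight <= 1:
        raise ValueError("weight must be in [0, 1]")
    if set(func_rank) != set(struct_rank):
        raise ValueError("rankings must cover the same interaction set")
    f_pos = {p: i + 1 for i, p in enumerate(func_rank)}
    s_pos = {p: i + 1 for i, p in enumerate(struct_rank)}
    if ties == "isolated" and pool is not None:
        tie = lambda p: _tie_key(p, "isolated", pool)  # noqa: E731
    else:
        tie = lambda p: p  # noqa: E731
    return sorted(
        func_rank,
        key=lambda p: (weight * s_pos[p] + (1 - weight) * f_pos[p], tie(p)),
    )


def build_hierarchy(
    pool: CandidatePool,
    si: np.ndarray,
    fi: np.ndarray,
    mode: str = "alternative",
    weight: float = 0.5,
    ties: str = "isolated",
) -> InteractionRanking:
    """Build the final interaction hierarchy.

    Interactions with SI = 0 (or no FI) are excluded; the rest are
    ranked separately by SI and FI, merged per ``mode``, and numbered
    from 1. Reproducible bit-for-bit for identical inputs regardless of
    pool construction order.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    eligible = [
        i for i in range(len(pool))
        if si[i] > 0 and np.isfinite(fi[i])
    ]
    if not eligible:
        raise ValueError("no eligible interactions: every candidate has SI = 0")
    pairs = [pool.interactions[i] for i in eligible]
    si_map = {pool.interactions[i]: float(si[i]) for i in eligible}
    fi_map = {pool.interactions[i]: float(fi[i]) for i in eligible}
    struct_order = rank_single(si_map, ties, pool)
    func_order = rank_single(fi_map, ties, pool)
    if mode == "alternative":
        merged = merge_alternative(func_order, struct_order)
    else:
        merged = merge_weighted(func_order, struct_order, weight, ties, pool)
    s_pos = {p: i + 1 for i, p in enumerate(struct_order)}
    f_pos = {p: i + 1 for i, p in enumerate(func_order)}
    mask = {
        pool.interactions[i]: pool.presence_mask(i) for i in eligible
    }
    ranked = [
        ScoredInteraction(
            mirna=p[0],
            gene=p[1],
            si=si_map[p],
            fi=fi_map[p],
            presence_mask=mask[p],
            struct_rank=s_pos[p],
            func_rank=f_pos[p],
            final_rank=r + 1,
        )
        for r, p in enumerate(merged)
    ]
    assert len(ranked) == len(pairs)
    return InteractionRanking(
        interactions=ranked,
        mode=mode,
        ties=ties,
        weight=weight if mode == "weighted" else None,
    )
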