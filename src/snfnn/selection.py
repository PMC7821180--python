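"""Heuristic similarity-view selection: keep informative, non-redundant views.

Fusing many heterogeneous similarity matrices helps only if each contributes
signal; near-uniform ("noisy") views dilute the fusion and near-duplicate
views double-count one signal.  Selection therefore runs in four steps,
independently for drug views and disease views:

1. score every view by its mean row entropy (off-diagonal entries of each
   row normalized to a probability vector; ``0 log 0 := 0``; entropy in bits,
   bounded by ``log2(p - 1)``);
2. drop views whose mean entropy exceeds ``entropy_cutoff_fraction`` of that
   bound — rows close to uniform carry no ranking information;
3. among survivors, score every pair by the Spearman correlation of their
   vectorized upper-triangle off-diagonal entries (redundancy);
4. scan pairs in decreasing redundancy and, for each pair above
   ``redundancy_threshold`` whose members both survive, drop the
   higher-entropy (less structured) member.

If step 2 would drop everything, the single lowest-entropy view is kept.
Ties are broken by lexicographic view name so the result is deterministic
and independent of input order.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dataio import SimilarityMatrix

logger = logging.getLogger(__name__)

__all__ = ["SelectionConfig", "SelectionReport", "view_entropy", "select_views"]


@dataclass
class SelectionConfig:
    """Thresholds for the noisy-view and redundant-view filters.

    ``entropy_cutoff_fraction`` — a view is discarded as noisy when its mean
    row entropy exceeds this fraction of the maximum attainable entropy
    ``log2(p - 1)``.  Row entropies of dense similarity matrices concentrate
    near the maximum (a row spread over ~p entries is high-entropy even when
    clearly structured — informative kernel views routinely sit above 0.95
    of the bound), so the default is close to 1: only views statistically
    indistinguishable from uniform are treated as noise.  Structured-but-
    diffuse views are left to the redundancy step.

    ``redundancy_threshold`` — two views are redundant when the Spearman
    correlation of their off-diagonal entries exceeds this value.
    """

    entropy_cutoff_fraction: float = 0.99
    redundancy_threshold: float = 0.6

    def __post_init__(self) -> None:
        if not 0 < self.entropy_cutoff_fraction <= 1:
            raise ValueError("entropy_cutoff_fraction must be in (0, 1]")
        if not 0 <= self.redundancy_threshold <= 1:
            raise ValueError("redundancy_threshold must be in [0, 1]")


@dataclass
class SelectionReport:
    """Audit trail of one selection run."""

    entropies: dict[str, float]
    redundancies: dict[tuple[str, str], float]
    kept: list[str]
    dropped: dict[str, str]  # view name -> reason ("noisy" | "redundant")
    max_entropy: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "entropies": self.entropies,
                "max_entropy": self.max_entropy,
                "redundancies": {f"{a}|{b}": r for (a, b), r in self.redundancies.items()},
                "kept": self.kept,
                "dropped": self.dropped,
            },
            indent=2,
        )

    def __str__(self) -> str:
        lines = ["view\tentropy\tstatus"]
        for name in sorted(self.entropies):
            status = "kept" if name in self.kept else f"dropped ({self.dropped[name]})"
            lines.append(f"{name}\t{self.entropies[name]:.4f}\t{status}")
        return "\n".join(lines)


def view_entropy(sim: SimilarityMatrix) -> float:
    """Mean Shannon entropy (bits) of the row-normalized off-diagonal entries.

    Each row's off-diagonal entries are normalized to a probability vector;
    a row whose off-diagonal entries are all zero contributes entropy 0.
    The result lies in ``[0, log2(p - 1)]``.
    """
    p = sim.n_entities
    if p < 2:
        raise ValueError("entropy needs at least 2 entities")
    values = sim.values.copy()
    np.fill_diagonal(values, 0.0)
    row_sums = values.sum(axis=1)
    degenerate = row_sums <= 0
    if degenerate.any():
        logger.info(
            "view %r: %d all-zero off-diagonal rows contribute entropy 0",
            sim.view_name,
            int(degenerate.sum()),
        )
    row_sums[degenerate] = 1.0
    q = values / row_sums[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(q > 0, q * np.log2(q), 0.0)
    row_entropy = -terms.sum(axis=1)
    row_entropy[degenerate] = 0.0
    return float(row_entropy.mean())


def _offdiag_vector(sim: SimilarityMatrix) -> np.ndarray:
    iu = np.triu_indices(sim.n_entities, k=1)
    return sim.values[iu]


def redundancy(a: SimilarityMatrix, b: SimilarityMatrix) -> float:
    """Spearman correlation of two views' off-diagonal entries (constant → 0)."""
    va, vb = _offdiag_vector(a), _offdiag_vector(b)
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        return 0.0
    rho = stats.spearmanr(va, vb).statistic
    return float(rho) if math.isfinite(rho) else 0.0


def select_views(
    views: list[SimilarityMatrix], config: SelectionConfig | None = None
) -> tuple[list[SimilarityMatrix], SelectionReport]:
    """Run the four-step filter; returns the kept views plus an audit report."""
    if not views:
        raise ValueError("select_views needs at least one view")
    config = config or SelectionConfig()
    names = [v.view_name for v in views]
    if len(set(names)) != len(names):
        raise ValueError("view names must be unique for selection reporting")
    axis = views[0].entity_ids
    for v in views:
        if v.entity_ids != axis:
            raise ValueError(f"view {v.view_name!r} is on a different entity axis")

    by_name = {v.view_name: v for v in views}
    entropies = {v.view_name: view_entropy(v) for v in views}
    p = views[0].n_entities
    max_entropy = math.log2(p - 1) if p > 1 else 0.0
    cutoff = config.entropy_cutoff_fraction * max_entropy

    dropped: dict[str, str] = {}
    survivors = sorted(n for n in names if entropies[n] <= cutoff)
    for name in names:
        if name not in survivors:
            dropped[name] = "noisy"
    if not survivors:
        # Everything looked noisy: keep the least-noisy view rather than none.
        keep = min(sorted(names), key=lambda n: entropies[n])
        logger.warning("all views exceeded the entropy cutoff; keeping %r", keep)
        survivors = [keep]
        dropped.pop(keep)

    redundancies: dict[tuple[str, str], float] = {}
    for i, a in enumerate(survivors):
        for b in survivors[i + 1 :]:
            redundancies[(a, b)] = redundancy(by_name[a], by_name[b])

    # Decreasing redundancy; lexicographic pair order breaks exact ties.
    kept = set(survivors)
    for (a, b), rho in sorted(redundancies.items(), key=lambda kv: (-kv[1], kv[0])):
        if rho <= config.redundancy_threshold:
            break
        if a in kept and b in kept:
            # Drop the higher-entropy (less structured) member; on an exact
            # entropy tie drop the lexicographically later name.
            loser = b if (entropies[b], b) > (entropies[a], a) else a
            kept.discard(loser)
            dropped[loser] = "redundant"

    kept_names = [n for n in names if n in kept]
    report = SelectionReport(
        entropies=entropies,
        redundancies=redundancies,
        kept=sorted(kept_names),
        dropped=dropped,
        max_entropy=max_entropy,
    )
    return [by_name[n] for n in kept_names], report
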