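"""Labeled drug-disease pair examples with fused-similarity feature vectors.

Each candidate pair (drug r_i, disease d_j) is described by concatenating
row i of the fused drug network with row j of the fused disease network —
an (m + n)-length vector placing the pair inside both similarity landscapes.
Training sets are balanced: all known interactions (positives) plus an
equally sized seeded uniform sample of unknown cells (negatives).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .dataio import InteractionMatrix
from .fusion import FusedNetwork

logger = logging.getLogger(__name__)

__all__ = ["PairFeatureTable", "build_features", "sample_balanced_pairs"]


@dataclass
class PairFeatureTable:
    """Drug-disease pairs, optional 0/1 labels, and their feature matrix."""

    drug_ids: list[str]
    disease_ids: list[str]
    labels: np.ndarray  # int8; -1 encodes "unknown" (unlabeled candidates)
    features: np.ndarray  # shape (n_pairs, m + n)

    def __post_init__(self) -> None:
        n = len(self.drug_ids)
        if not (len(self.disease_ids) == len(self.labels) == self.features.shape[0] == n):
            raise ValueError("pair columns, labels and feature rows disagree in length")
        pairs = list(zip(self.drug_ids, self.disease_ids))
        if len(set(pairs)) != n:
            raise ValueError("duplicate (drug, disease) pair")
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if not np.isin(self.labels, (-1, 0, 1)).all():
            raise ValueError("labels must be 0, 1 or -1 (unknown)")

    def __len__(self) -> int:
        return len(self.drug_ids)

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def subset(self, idx: np.ndarray) -> "PairFeatureTable":
        idx = np.asarray(idx)
        return PairFeatureTable(
            drug_ids=[self.drug_ids[i] for i in idx],
            disease_ids=[self.disease_ids[i] for i in idx],
            labels=self.labels[idx],
            features=self.features[idx],
        )

    def write(self, path: str | Path) -> None:
        """TSV of pairs + labels; features go to a sidecar .npy next to it."""
        path = Path(path)
        pd.DataFrame(
            {"drug": self.drug_ids, "disease": self.disease_ids, "label": self.labels}
        ).to_csv(path, sep="\t", index=False)
        np.save(path.with_suffix(path.suffix + ".features.npy"), self.features)


def build_features(
    fused_drug: FusedNetwork,
    fused_disease: FusedNetwork,
    pairs: list[tuple],
) -> PairFeatureTable:
    """Look up the concatenated feature vector for each (drug, disease[, label]).

    ``pairs`` items are ``(drug_id, disease_id)`` or ``(drug_id, disease_id,
    label)`` with label in {0, 1} or None for unlabeled candidates.  Feature
    construction is a pure lookup: rebuilding the same pair list is
    bit-identical.
    """
    drug_index = {d: i for i, d in enumerate(fused_drug.entity_ids)}
    disease_index = {d: i for i, d in enumerate(fused_disease.entity_ids)}
    drugs, diseases, labels = [], [], []
    rows_d, rows_s = [], []
    for pair in pairs:
        drug, disease = pair[0], pair[1]
        label = pair[2] if len(pair) > 2 else None
        if drug not in drug_index:
            raise KeyError(f"unknown drug identifier {drug!r}")
        if disease not in disease_index:
            raise KeyError(f"unknown disease identifier {disease!r}")
        drugs.append(drug)
        diseases.append(disease)
        labels.append(-1 if label is None else int(label))
        rows_d.append(drug_index[drug])
        rows_s.append(disease_index[disease])
    features = np.hstack(
        [fused_drug.values[rows_d], fused_disease.values[rows_s]]
    ) if pairs else np.zeros((0, len(drug_index) + len(disease_index)))
    return PairFeatureTable(
        drug_ids=drugs,
        disease_ids=diseases,
        labels=np.asarray(labels, dtype=np.int8),
        features=features,
    )


def sample_balanced_pairs(
    y: InteractionMatrix, seed: int
) -> list[tuple[str, str, int]]:
    """All positive pairs plus an equal-sized seeded sample of unknown cells.

    Negatives are drawn uniformly without replacement from the zero cells of
    Y, so positives and negatives are disjoint and the class balance is
    exactly 1:1.
    """
    pos_r, pos_c = np.nonzero(y.values)
    n_pos = len(pos_r)
    if n_pos == 0:
        raise ValueError("Y has no positive entries")
    zero_r, zero_c = np.nonzero(y.values == 0)
    if len(zero_r) < n_pos:
        raise ValueError(
            f"only {len(zero_r)} unknown cells available for {n_pos} positives"
        )
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(zero_r), size=n_pos, replace=False)
    logger.info("sampled %d negatives for %d positives (seed=%d)", n_pos, n_pos, seed)
    pairs = [
        (y.drug_ids[r], y.disease_ids[c], 1) for r, c in zip(pos_r, pos_c)
    ]
    pairs += [
        (y.drug_ids[zero_r[i]], y.disease_ids[zero_c[i]], 0) for i in pick
    ]
    return pairs
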