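"""Gaussian Interaction Profile (GIP) kernel similarities.

Each drug is represented by its binary interaction profile f(r) — the row of
Y recording which diseases it is known to treat — and each disease by its
profile g(d), the column of Y.  The working assumption is that drugs with
similar interaction profiles behave similarly on new diseases (and
symmetrically for diseases).  Similarity between two profiles is a Gaussian
kernel of their squared Euclidean distance, with the bandwidth normalized by
the mean number of interactions per entity:

    sr(r_a, r_b) = exp( -tau * m * ||f(r_a) - f(r_b)||^2 / sum_i ||f(r_i)||^2 )

For binary profiles ``||f(r_i)||^2`` equals drug r_i's interaction count, so
the denominator divided by m is the average interaction count — i.e. the
exponent is ``-tau * d^2 / mean-interactions``.  The disease kernel is the
mirror image on columns.  ``tau`` controls the bandwidth and defaults to 1.

Because the profiles are the gold-standard labels themselves, a GIP matrix
computed on the full Y encodes held-out test labels when used inside
cross-validation.  The pipeline computes GIP once on the full matrix by
default (see :mod:`snfnn.evaluation` for the strict no-leakage mode).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataio import InteractionMatrix, SimilarityMatrix

__all__ = ["GipConfig", "DegenerateKernelError", "gip_drug_similarity", "gip_disease_similarity"]


class DegenerateKernelError(ValueError):
    """Raised when Y has no interactions at all (zero normalizer)."""


@dataclass
class GipConfig:
    """Bandwidth control for the interaction-profile kernel."""

    tau: float = 1.0

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ValueError(f"tau must be positive, got {self.tau}")


def _gip_kernel(profiles: np.ndarray, tau: float) -> np.ndarray:
    """Kernel matrix over the rows of a binary profile matrix."""
    profiles = np.asarray(profiles, dtype=float)
    p = profiles.shape[0]
    normalizer = float((profiles**2).sum())  # = total interaction count for 0/1 data
    if normalizer == 0.0:
        raise DegenerateKernelError(
            "interaction matrix has no interactions; GIP bandwidth is undefined"
        )
    sq_norms = (profiles**2).sum(axis=1)
    d2 = sq_norms[:, None] + sq_norms[None, :] - 2.0 * (profiles @ profiles.T)
    np.clip(d2, 0.0, None, out=d2)
    kernel = np.exp(-tau * p * d2 / normalizer)
    kernel = (kernel + kernel.T) / 2.0
    np.fill_diagonal(kernel, 1.0)
    return kernel


def gip_drug_similarity(
    y: InteractionMatrix, config: GipConfig | None = None
) -> SimilarityMatrix:
    """m x m GIP similarity over drugs from their disease-interaction rows."""
    config = config or GipConfig()
    return SimilarityMatrix(
        entity_ids=list(y.drug_ids),
        values=_gip_kernel(y.values, config.tau),
        view_name="gip_drug",
    )


def gip_disease_similarity(
    y: InteractionMatrix, config: GipConfig | None = None
) -> SimilarityMatrix:
    """n x n GIP similarity over diseases from their drug-interaction columns."""
    config = config or GipConfig()
    return SimilarityMatrix(
        entity_ids=list(y.disease_ids),
        values=_gip_kernel(y.values.T, config.tau),
        view_name="gip_disease",
    )
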