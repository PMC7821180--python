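"""Core domain types and labeled-matrix file I/O.

The pipeline operates on three kinds of matrices, all exchanged as labeled
TSV/CSV files: a binary drug-disease interaction matrix ``Y`` (the gold
standard, where 1 marks a clinically validated indication and 0 an *unknown*
pair), square symmetric similarity matrices in ``[0, 1]`` over drugs or over
diseases (one per data view, e.g. chemical structure or phenotype
similarity), and the fused networks produced downstream.

File dialect: first header cell empty, row and column labels are opaque
identifiers, tab-separated by default with comma accepted for ``.csv``.
Identifiers are compared as exact case-sensitive strings; synonym mapping
(DrugBank accession numbers, UMLS CUIs) is assumed to have happened upstream.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ValidationError",
    "FormatError",
    "AlignmentError",
    "InteractionMatrix",
    "SimilarityMatrix",
    "HeterogeneousDataset",
    "DatasetSummary",
    "read_similarity_matrix",
    "write_similarity_matrix",
    "read_interaction_matrix",
    "write_interaction_matrix",
    "align_dataset",
    "summarize_dataset",
]

_SYMMETRY_TOL = 1e-6
_RANGE_TOL = 1e-9
_DIAG_TOL = 1e-6


class ValidationError(ValueError):
    """A matrix violates a domain invariant (range, symmetry, binarity...)."""


class FormatError(ValueError):
    """A file cannot be parsed as a labeled matrix of the expected shape."""


class AlignmentError(ValueError):
    """Identifier sets of the views and the interaction matrix are disjoint."""


def _check_unique(ids: list[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))
        raise ValidationError(f"duplicate {what} identifier: {dup!r}")


@dataclass
class InteractionMatrix:
    """Binary gold-standard matrix Y (m drugs x n diseases).

    ``values[i, j] == 1`` iff drug ``drug_ids[i]`` is known to treat disease
    ``disease_ids[j]``; 0 means unknown, not confirmed-negative.
    """

    drug_ids: list[str]
    disease_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.drug_ids = [str(i) for i in self.drug_ids]
        self.disease_ids = [str(i) for i in self.disease_ids]
        v = np.asarray(self.values)
        if v.ndim != 2 or v.shape != (len(self.drug_ids), len(self.disease_ids)):
            raise ValidationError(
                f"interaction matrix shape {v.shape} does not match "
                f"{len(self.drug_ids)} drugs x {len(self.disease_ids)} diseases"
            )
        if v.shape[0] < 2 or v.shape[1] < 2:
            raise ValidationError("need at least 2 drugs and 2 diseases")
        if not np.isin(v, (0, 1)).all():
            bad = v[~np.isin(v, (0, 1))].flat[0]
            raise ValidationError(f"non-binary interaction entry: {bad!r}")
        _check_unique(self.drug_ids, "drug")
        _check_unique(self.disease_ids, "disease")
        self.values = v.astype(np.int8)

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_diseases(self) -> int:
        return len(self.disease_ids)

    @property
    def n_interactions(self) -> int:
        return int(self.values.sum())


@dataclass
class SimilarityMatrix:
    """One square symmetric similarity view over a single entity set.

    Entries lie in ``[0, 1]`` (1 = perfect similarity), the diagonal is 1
    (self-similarity is perfect) and the matrix is symmetric to 1e-9.
    """

    entity_ids: list[str]
    values: np.ndarray
    view_name: str = "similarity"

    def __post_init__(self) -> None:
        self.entity_ids = [str(i) for i in self.entity_ids]
        v = np.asarray(self.values, dtype=float)
        p = len(self.entity_ids)
        if v.shape != (p, p):
            raise ValidationError(
                f"view {self.view_name!r}: shape {v.shape} does not match {p} ids"
            )
        _check_unique(self.entity_ids, "entity")
        if not np.isfinite(v).all():
            raise ValidationError(f"view {self.view_name!r}: non-finite entry")
        if v.min() < -_RANGE_TOL or v.max() > 1 + _RANGE_TOL:
            raise ValidationError(
                f"view {self.view_name!r}: entry outside [0, 1]: "
                f"min={v.min():.6g}, max={v.max():.6g}"
            )
        if np.abs(v - v.T).max() > 1e-9:
            raise ValidationError(f"view {self.view_name!r}: asymmetric values")
        np.clip(v, 0.0, 1.0, out=v)
        self.values = v

    @property
    def n_entities(self) -> int:
        return len(self.entity_ids)


@dataclass
class HeterogeneousDataset:
    """Interaction matrix plus aligned drug and disease similarity views."""

    interactions: InteractionMatrix
    drug_views: list[SimilarityMatrix] = field(default_factory=list)
    disease_views: list[SimilarityMatrix] = field(default_factory=list)

    def __post_init__(self) -> None:
        for view in self.drug_views:
            if view.entity_ids != self.interactions.drug_ids:
                raise ValidationError(
                    f"drug view {view.view_name!r} is not aligned to the "
                    "interaction drug axis"
                )
        for view in self.disease_views:
            if view.entity_ids != self.interactions.disease_ids:
                raise ValidationError(
                    f"disease view {view.view_name!r} is not aligned to the "
                    "interaction disease axis"
                )


@dataclass
class DatasetSummary:
    """Headline counts of a heterogeneous dataset (benchmark-table style)."""

    n_drugs: int
    n_diseases: int
    n_interactions: int
    sparsity_percent: float
    n_drug_views: int
    n_disease_views: int

    def to_dict(self) -> dict:
        return {
            "n_drugs": self.n_drugs,
            "n_diseases": self.n_diseases,
            "n_interactions": self.n_interactions,
            "sparsity_percent": self.sparsity_percent,
            "n_drug_views": self.n_drug_views,
            "n_disease_views": self.n_disease_views,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def __str__(self) -> str:
        return "\n".join(f"{k}\t{v}" for k, v in self.to_dict().items())


def _read_labeled_frame(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    try:
        frame = pd.read_csv(path, sep=sep, index_col=0, header=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: cannot parse labeled matrix: {exc}") from exc
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    # pandas de-duplicates repeated column labels ("x", "x.1"); check the raw header
    with open(path, encoding="utf-8") as handle:
        header = handle.readline().rstrip("\n").split(sep)[1:]
    if len(set(header)) != len(header):
        raise ValidationError(f"{path}: duplicate column identifier in header")
    if frame.index.has_duplicates:
        raise ValidationError(f"{path}: duplicate row identifier")
    return frame


def _to_float(frame: pd.DataFrame, path: Path) -> np.ndarray:
    try:
        return frame.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValidationError(f"{path}: unparseable cell ({exc})") from exc


def read_similarity_matrix(
    path: str | Path, view_name: str | None = None, symmetrize: bool = False
) -> SimilarityMatrix:
    """Read a labeled square similarity matrix from a TSV/CSV file.

    Row and column identifiers must match in the same order.  Entries must be
    in [0, 1]; asymmetry beyond 1e-6 is an error unless ``symmetrize`` is set,
    in which case ``(S + S.T) / 2`` is stored.  Diagonals are forced to 1.0
    (with a logged warning if any differed by more than 1e-6).
    """
    path = Path(path)
    frame = _read_labeled_frame(path)
    if frame.shape[0] != frame.shape[1]:
        raise FormatError(f"{path}: matrix is {frame.shape[0]}x{frame.shape[1]}, not square")
    if list(frame.index) != list(frame.columns):
        raise FormatError(f"{path}: row and column identifiers differ (order matters)")
    values = _to_float(frame, path)
    if not np.isfinite(values).all():
        raise ValidationError(f"{path}: missing or non-finite cell")
    asym = np.abs(values - values.T).max() if values.size else 0.0
    if asym > _SYMMETRY_TOL:
        if symmetrize:
            logger.warning("%s: symmetrized (max asymmetry %.3g)", path, asym)
        else:
            raise ValidationError(
                f"{path}: asymmetry {asym:.3g} exceeds {_SYMMETRY_TOL:g} "
                "(pass symmetrize=True to average)"
            )
    values = (values + values.T) / 2.0
    if values.size and np.abs(np.diag(values) - 1.0).max() > _DIAG_TOL:
        logger.warning("%s: diagonal entries differ from 1; overwritten to 1.0", path)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(
        entity_ids=list(frame.index),
        values=values,
        view_name=view_name or path.stem,
    )


def write_similarity_matrix(sim: SimilarityMatrix, path: str | Path) -> None:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    frame = pd.DataFrame(sim.values, index=sim.entity_ids, columns=sim.entity_ids)
    frame.to_csv(path, sep=sep, float_format="%.17g")


def read_interaction_matrix(path: str | Path) -> InteractionMatrix:
    """Read a labeled rectangular 0/1 matrix (drugs in rows, diseases in columns)."""
    path = Path(path)
    frame = _read_labeled_frame(path)
    values = _to_float(frame, path)
    if not np.isfinite(values).all():
        raise ValidationError(f"{path}: missing or non-finite cell")
    if not np.isin(values, (0.0, 1.0)).all():
        bad = values[~np.isin(values, (0.0, 1.0))].flat[0]
        raise ValidationError(f"{path}: non-binary entry {bad!r}")
    return InteractionMatrix(
        drug_ids=list(frame.index),
        disease_ids=list(frame.columns),
        values=values.astype(np.int8),
    )


def write_interaction_matrix(y: InteractionMatrix, path: str | Path) -> None:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    frame = pd.DataFrame(y.values, index=y.drug_ids, columns=y.disease_ids)
    frame.to_csv(path, sep=sep)


def _restrict_view(view: SimilarityMatrix, ids: list[str]) -> SimilarityMatrix:
    index = {e: i for i, e in enumerate(view.entity_ids)}
    order = np.array([index[e] for e in ids], dtype=int)
    return SimilarityMatrix(
        entity_ids=list(ids),
        values=view.values[np.ix_(order, order)],
        view_name=view.view_name,
    )


def align_dataset(
    interactions: InteractionMatrix,
    drug_views: list[SimilarityMatrix],
    disease_views: list[SimilarityMatrix],
) -> HeterogeneousDataset:
    """Restrict everything to the shared identifiers, in interaction-axis order.

    Views may cover a superset or subset of the interaction identifiers; the
    dataset is cut down to the intersection (rows/columns of Y whose drug or
    disease is missing from some view are removed, and vice versa).  Dropped
    identifiers are reported in the log.  Idempotent on aligned datasets.
    """
    drug_ids = list(interactions.drug_ids)
    for view in drug_views:
        keep = set(view.entity_ids)
        drug_ids = [d for d in drug_ids if d in keep]
    disease_ids = list(interactions.disease_ids)
    for view in disease_views:
        keep = set(view.entity_ids)
        disease_ids = [d for d in disease_ids if d in keep]
    if not drug_ids or not disease_ids:
        raise AlignmentError("identifier intersection across views is empty")

    dropped_drugs = sorted(set(interactions.drug_ids) - set(drug_ids))
    dropped_dis = sorted(set(interactions.disease_ids) - set(disease_ids))
    for view in drug_views:
        extra = sorted(set(view.entity_ids) - set(drug_ids))
        if extra:
            logger.info("view %r: dropping %d extra drugs", view.view_name, len(extra))
    if dropped_drugs:
        logger.info("alignment dropped %d drugs: %s", len(dropped_drugs), dropped_drugs)
    if dropped_dis:
        logger.info("alignment dropped %d diseases: %s", len(dropped_dis), dropped_dis)

    row_idx = [interactions.drug_ids.index(d) for d in drug_ids]
    col_idx = [interactions.disease_ids.index(d) for d in disease_ids]
    y = InteractionMatrix(
        drug_ids=drug_ids,
        disease_ids=disease_ids,
        values=interactions.values[np.ix_(row_idx, col_idx)],
    )
    return HeterogeneousDataset(
        interactions=y,
        drug_views=[_restrict_view(v, drug_ids) for v in drug_views],
        disease_views=[_restrict_view(v, disease_ids) for v in disease_views],
    )


def summarize_dataset(dataset: HeterogeneousDataset) -> DatasetSummary:
    """Counts and interaction sparsity, benchmark-table style.

    Sparsity is the percentage of drug-disease cells that are *not* known
    interactions, ``100 * (1 - ones / (m * n))``, rounded to 2 decimals.
    """
    y = dataset.interactions
    m, n = y.n_drugs, y.n_diseases
    ones = y.n_interactions
    sparsity = round(100.0 * (1.0 - ones / (m * n)), 2)
    return DatasetSummary(
        n_drugs=m,
        n_diseases=n,
        n_interactions=ones,
        sparsity_percent=sparsity,
        n_drug_views=len(dataset.drug_views),
        n_disease_views=len(dataset.disease_views),
    )
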