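"""Signature scoring: per-sample up-minus-down mean expression.

The score of a sample is the mean log expression of the signature's
up-regulated genes minus the mean over its down-regulated genes. Applied to
the 17-gene EMT signature this is the EMT score; applied to a claudin-low
signature it is the CL score. Scores are invariant to adding a constant to
the whole matrix and scale linearly with the matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sigio import ExpressionMatrix, GeneSignature

logger = logging.getLogger(__name__)

#: Coverage fraction below which a warning is emitted (runs still proceed
#: with >= 1 matched gene per side).
COVERAGE_WARN = 0.80


@dataclass(frozen=True)
class MatchedSignature:
    """A signature resolved against a concrete matrix's gene rows."""

    signature: GeneSignature
    up_rows: tuple[int, ...]
    down_rows: tuple[int, ...]

    @property
    def coverage_up(self) -> float:
        return len(self.up_rows) / len(self.signature.up_genes)

    @property
    def coverage_down(self) -> float:
        return len(self.down_rows) / len(self.signature.down_genes)


@dataclass(frozen=True)
class ScoreVector:
    """One score per sample for a named signature."""

    signature_name: str
    scores: pd.Series  # index = sample ids, values = float

    def __post_init__(self) -> None:
        if self.scores.index.has_duplicates:
            raise ValueError("duplicate sample ids in score vector")
        if not np.isfinite(self.scores.to_numpy()).all():
            raise ValueError("non-finite scores")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.index)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.scores.index,
                "signature_name": self.signature_name,
                "score": self.scores.to_numpy(),
            }
        )


def match_signature(sig: GeneSignature, matrix: ExpressionMatrix) -> MatchedSignature:
    """Resolve signature genes to matrix row indices.

    Unmatched genes are logged; matching fails if either side matches
    nothing, and warns below 80% coverage on either side.
    """
    row_of = {g: i for i, g in enumerate(matrix.gene_ids)}
    up_rows = tuple(row_of[g] for g in sig.up_genes if g in row_of)
    down_rows = tuple(row_of[g] for g in sig.down_genes if g in row_of)
    for g in sig.genes:
        if g not in row_of:
            logger.info("signature %s: gene %s not in matrix", sig.name, g)
    if not up_rows or not down_rows:
        raise ValueError(
            f"signature {sig.name!r}: no matched "
            f"{'up' if not up_rows else 'down'}-genes in matrix"
        )
    matched = MatchedSignature(sig, up_rows, down_rows)
    for side, cov in (("up", matched.coverage_up), ("down", matched.coverage_down)):
        if cov < COVERAGE_WARN:
            logger.warning(
                "signature %s: %s-gene coverage %.0f%% below %.0f%%",
                sig.name, side, 100 * cov, 100 * COVERAGE_WARN,
            )
    return matched


def score_samples(
    matched: MatchedSignature,
    matrix: ExpressionMatrix,
    standardize: bool = False,
) -> ScoreVector:
    """Compute per-sample scores: mean(up rows) - mean(down rows).

    With ``standardize`` on, every gene row is z-scored across samples
    before averaging (an extension for cross-platform use; the default is
    the plain average).
    """
    values = matrix.values.astype(float)
    if max(matched.up_rows + matched.down_rows, default=0) >= values.shape[0]:
        raise ValueError("matched rows do not fit this matrix")
    if standardize:
        mu = values.mean(axis=1, keepdims=True)
        sd = values.std(axis=1, ddof=0, keepdims=True)
        sd[sd == 0] = 1.0
        values = (values - mu) / sd
    up_mean = values[list(matched.up_rows)].mean(axis=0)
    down_mean = values[list(matched.down_rows)].mean(axis=0)
    return ScoreVector(
        matched.signature.name,
        pd.Series(up_mean - down_mean, index=matrix.sample_ids, name="score"),
    )


def claudin_low_score(
    sig: GeneSignature, matrix: ExpressionMatrix, standardize: bool = False
) -> ScoreVector:
    """Claudin-low score: same up-minus-down computation under the CL label.

    A named entry point so CL runs are separately matched and logged; the
    formula is identical to :func:`score_samples`.
    """
    logger.info("computing claudin-low score with signature %s", sig.name)
    return score_samples(match_signature(sig, matrix), matrix, standardize=standardize)


def order_samples_by_score(scores: ScoreVector, direction: str = "ascending") -> list[str]:
    """Sample ids sorted by score; ties broken lexicographically by id."""
    if direction not in ("ascending", "descending"):
        raise ValueError(f"unknown direction {direction!r}")
    items = sorted(
        scores.scores.items(),
        key=lambda kv: (kv[1], kv[0]) if direction == "ascending" else (-kv[1], kv[0]),
    )
    return [k for k, _ in items]


def select_top_signature_genes(sig: GeneSignature, k: int) -> GeneSignature:
    """Subset a signature to its k "top" genes, for report/heatmap export.

    With weights present, the k genes of largest absolute weight; otherwise
    a deterministic order (up-set alphabetical, then down-set alphabetical).
    Presentation only — scores never depend on this selection.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(sig):
        raise ValueError(f"k={k} exceeds signature size {len(sig)}")
    if sig.weights is not None:
        ranked = sorted(sig.genes, key=lambda g: (-abs(sig.weights[g]), g))
        keep = set(ranked[:k])
    else:
        ordered = sorted(sig.up_genes) + sorted(sig.down_genes)
        keep = set(ordered[:k])
    up = tuple(g for g in sig.up_genes if g in keep)
    down = tuple(g for g in sig.down_genes if g in keep)
    weights = (
        {g: sig.weights[g] for g in keep} if sig.weights is not None else None
    )
    return GeneSignature(f"{sig.name}_top{k}", up, down, weights)


def export_ordered_matrix(
    matrix: ExpressionMatrix,
    ordered_sample_ids: list[str],
    genes: list[str],
    path,
) -> None:
    """Write a heatmap-ready sub-matrix with columns in score order.

    Bit-identical across runs for identical inputs.
    """
    unknown_samples = set(ordered_sample_ids) - set(matrix.sample_ids)
    unknown_genes = set(genes) - set(matrix.gene_ids)
    if unknown_samples:
        raise KeyError(f"unknown sample ids: {sorted(unknown_samples)}")
    if unknown_genes:
        raise KeyError(f"unknown genes: {sorted(unknown_genes)}")
    sub = matrix.data.loc[genes, ordered_sample_ids]
    sub.to_csv(path, sep="\t", index_label="gene", float_format="%.6g")
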