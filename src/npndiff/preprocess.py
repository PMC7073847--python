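"""Expression-matrix ingestion and median/variance-matching batch correction.

The batch correction recenters each gene within each batch to the gene's
overall median and rescales to the gene's overall standard deviation:

    g*_ijk = M_i + (g_ijk - M_ij) * sd_i / sd_ij,

where M_i / sd_i are the median / SD of gene i over all samples and
M_ij / sd_ij over batch j only.  The same operation applied with age-group
labels removes age-group effects.  Exact idempotence does not hold in
general (medians are not means, and the pooled SD of per-batch standardized
values is not exactly 1), but per-batch medians are exactly matched after
one pass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .npn import ObservedMatrix

__all__ = [
    "BatchedMatrix",
    "batch_correct",
    "read_expression_matrix",
    "write_expression_matrix",
]

logger = logging.getLogger(__name__)


@dataclass
class BatchedMatrix:
    """Genes x samples matrix with a batch label per sample."""

    values: pd.DataFrame  # index: gene ids, columns: sample ids
    batch_of: dict[str, str]

    def __post_init__(self) -> None:
        missing = [s for s in self.values.columns if s not in self.batch_of]
        if missing:
            raise ValueError(f"samples without batch label: {missing[:5]}")

    @property
    def batches(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.values.columns:
            seen.setdefault(self.batch_of[s], None)
        return list(seen)


def batch_correct(data: BatchedMatrix, ddof: int = 1) -> pd.DataFrame:
    """Median-matching / variance-matching removal of batch effects.

    With a single batch the input is returned unchanged.  A batch in which
    some gene has zero spread cannot be rescaled and raises an error naming
    the gene and batch.
    """
    batches = data.batches
    if len(batches) <= 1:
        return data.values.copy()
    values = data.values
    arr = values.to_numpy(dtype=float)
    overall_median = np.median(arr, axis=1)
    overall_sd = arr.std(axis=1, ddof=ddof)
    out = np.empty_like(arr)
    cols = list(values.columns)
    for batch in batches:
        mask = np.array([data.batch_of[s] == batch for s in cols])
        if mask.sum() < 2:
            raise ValueError(f"batch {batch!r} has fewer than 2 samples")
        block = arr[:, mask]
        med = np.median(block, axis=1)
        sd = block.std(axis=1, ddof=ddof)
        if np.any(sd == 0):
            gene = values.index[int(np.argmin(sd))]
            raise ValueError(f"gene {gene!r} has zero SD in batch {batch!r}")
        out[:, mask] = (
            overall_median[:, None]
            + (block - med[:, None]) * (overall_sd / sd)[:, None]
        )
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def read_expression_matrix(
    path: str | Path,
    orientation: str = "samples_in_rows",
    class_of: dict[str, str] | None = None,
    missing_fraction: float = 0.01,
    sep: str = "\t",
) -> dict[str, ObservedMatrix]:
    """Read a delimited expression matrix into one ObservedMatrix per class.

    ``orientation`` is "samples_in_rows" (header = variable ids) or
    "genes_in_rows" (header = sample ids; the matrix is transposed on read).
    Samples whose fraction of missing values exceeds ``missing_fraction``
    are dropped and logged; remaining samples with any missing value are
    dropped too (no imputation of missing cells).  Without ``class_of`` all
    samples form a single class "all".
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"cannot parse {path}: {exc}") from exc
    if orientation == "genes_in_rows":
        df = df.T
    elif orientation != "samples_in_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    non_numeric = df.columns[
        [not np.issubdtype(dt, np.number) for dt in df.dtypes]
    ]
    if len(non_numeric):
        # re-parse offending columns so a stray string raises with context
        for col in non_numeric:
            try:
                df[col] = pd.to_numeric(df[col])
            except Exception as exc:
                raise ValueError(f"non-numeric cell in column {col!r} of {path}") from exc

    incomplete = df.index[df.isna().mean(axis=1) > 0].tolist()
    if incomplete:
        logger.info("dropping %d samples with missing values", len(incomplete))
        df = df.drop(index=incomplete)

    if class_of is None:
        groups = {"all": df}
    else:
        unknown = [s for s in df.index if s not in class_of]
        if unknown:
            raise ValueError(f"samples without class label: {unknown[:5]}")
        groups = {
            label: df.loc[[s for s in df.index if class_of[s] == label]]
            for label in dict.fromkeys(class_of[s] for s in df.index)
        }
    out = {}
    for label, sub in groups.items():
        out[label] = ObservedMatrix(
            values=sub.to_numpy(dtype=float),
            sample_ids=[str(s) for s in sub.index],
            variable_ids=[str(v) for v in sub.columns],
            class_label=label,
        )
    return out


def write_expression_matrix(
    data: ObservedMatrix, path: str | Path, sep: str = "\t"
) -> None:
    """Write an observed/imputed matrix as delimited text (samples in rows)."""
    df = pd.DataFrame(data.values, index=data.sample_ids, columns=data.variable_ids)
    # %.17g round-trips IEEE doubles exactly
    df.to_csv(Path(path), sep=sep, float_format="%.17g")
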