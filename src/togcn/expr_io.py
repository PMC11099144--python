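"""Reading, validation, filtering and normalization of expression matrices.

All text formats are tab-separated UTF-8 with ``.`` as the decimal mark.
Expression matrices are genes x samples, first column gene IDs, header row
of sample IDs (the first header cell is ignored). Sample sheets carry the
columns ``sample_id``, ``condition``, ``order``, ``replicate``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SampleSheet",
    "ValidationError",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_gene_list",
    "write_gene_list",
    "filter_expressed",
    "upper_quartile_normalize",
    "condition_means",
]


class ValidationError(ValueError):
    """Input data violates a documented invariant."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValidationError(f"duplicate {what} ID: {x!r}")
        seen.add(x)


@dataclass(frozen=True)
class ExpressionMatrix:
    """A genes x samples matrix of non-negative expression values (TPM).

    Parameters
    ----------
    data
        DataFrame with gene IDs as index and sample IDs as columns.
        Validated on construction: unique IDs, finite non-negative values.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(list(self.data.index), "gene")
        _check_unique(list(self.data.columns), "sample")
        values = self.data.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise ValidationError("expression matrix contains non-numeric values")
        if values.size and not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                f"non-finite value at gene {self.data.index[bad[0]]!r}, "
                f"sample {self.data.columns[bad[1]]!r}"
            )
        if values.size and (values < 0).any():
            bad = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative value at gene {self.data.index[bad[0]]!r}, "
                f"sample {self.data.columns[bad[1]]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = list(genes)
        missing = [g for g in genes if g not in self.data.index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        return ExpressionMatrix(self.data.loc[genes])


@dataclass(frozen=True)
class SampleSheet:
    """Maps samples to ordered conditions and replicate labels."""

    table: pd.DataFrame = field(repr=False)

    REQUIRED = ("sample_id", "condition", "order", "replicate")

    def __post_init__(self) -> None:
        t = self.table
        for col in self.REQUIRED:
            if col not in t.columns:
                raise ValidationError(f"sample sheet missing column {col!r}")
        if len(t) == 0:
            raise ValidationError("no samples in sample sheet")
        _check_unique(list(t["sample_id"]), "sample")
        orders = t.groupby("condition")["order"].unique()
        for cond, vals in orders.items():
            if len(vals) != 1:
                raise ValidationError(
                    f"condition {cond!r} has multiple order values: {sorted(vals)}"
                )
        by_order = t.drop_duplicates("condition")
        dup = by_order["order"].duplicated()
        if dup.any():
            shared = by_order.loc[dup, "order"].iloc[0]
            conds = sorted(by_order.loc[by_order["order"] == shared, "condition"])
            raise ValidationError(f"conditions {conds} share order {shared}")
        if (t["order"] <= 0).any():
            raise ValidationError("order values must be positive integers")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def ordered_conditions(self) -> list[str]:
        t = self.table.drop_duplicates("condition").sort_values("order")
        return list(t["condition"])

    def samples_for(self, condition: str) -> list[str]:
        sel = self.table[self.table["condition"] == condition]
        return list(sel["sample_id"])

    def condition_of(self, sample_id: str) -> str:
        sel = self.table[self.table["sample_id"] == sample_id]
        if len(sel) == 0:
            raise KeyError(f"sample {sample_id!r} not in sample sheet")
        return sel["condition"].iloc[0]


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a genes x samples TSV into a validated :class:`ExpressionMatrix`.

    Raises
    ------
    ValidationError
        On duplicate gene/sample IDs or negative values, naming the offender.
    ValueError
        On a non-numeric cell, naming its row and column.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, header=0)
    raw.index = raw.index.astype(str)
    raw.columns = raw.columns.astype(str)
    numeric = raw.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric value {raw.iat[i, j]!r} at gene "
            f"{raw.index[i]!r}, sample {raw.columns[j]!r}"
        )
    if numeric.isna().to_numpy().any():
        i, j = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(
            f"{path}: missing value at gene {raw.index[i]!r}, "
            f"sample {raw.columns[j]!r}"
        )
    return ExpressionMatrix(numeric.astype(float))


def write_expression_matrix(m: ExpressionMatrix, path: str | Path) -> None:
    m.data.to_csv(path, sep="\t", index_label="gene_id")


def read_sample_sheet(path: str | Path) -> SampleSheet:
    path = Path(path)
    t = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "condition": str, "replicate": str})
    if len(t) == 0:
        raise ValidationError(f"{path}: no samples")
    t["order"] = pd.to_numeric(t["order"], errors="raise").astype(int)
    return SampleSheet(t)


def write_sample_sheet(s: SampleSheet, path: str | Path) -> None:
    s.table.to_csv(path, sep="\t", index=False)


def read_gene_list(path: str | Path) -> list[str]:
    """Plain-text gene list, one ID per line; ``#`` starts a comment."""
    out: list[str] = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            out.append(line)
    _check_unique(out, "gene")
    return out


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def filter_expressed(m: ExpressionMatrix, tpm_min: float = 1.0) -> ExpressionMatrix:
    """Keep genes whose maximum over samples is >= ``tpm_min``.

    A gene counts as expressed if it reaches the threshold in at least one
    sample. Row order is preserved; the operation is idempotent.
    """
    keep = m.data.max(axis=1) >= tpm_min
    if not keep.any():
        warnings.warn("filter_expressed removed every gene", stacklevel=2)
    return ExpressionMatrix(m.data.loc[keep])


def upper_quartile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each sample so upper quartiles of expressed values agree.

    The upper quartile (UQ) of a sample is the 75th percentile of its
    strictly positive values (linear interpolation between order
    statistics); zeros are excluded so that sparsely expressed matrices do
    not collapse the quartile. Each column is multiplied by
    ``target / UQ_sample`` where ``target`` is the geometric mean of all
    per-sample UQs, keeping the overall scale near the input data.
    """
    uqs = {}
    for sample in m.sample_ids:
        col = m.data[sample].to_numpy()
        pos = col[col > 0]
        if pos.size == 0:
            raise ValidationError(f"sample {sample!r} has no positive values")
        uqs[sample] = float(np.percentile(pos, 75))
    target = float(np.exp(np.mean(np.log(list(uqs.values())))))
    scaled = m.data * pd.Series({s: target / u for s, u in uqs.items()})
    return ExpressionMatrix(scaled)


def condition_means(m: ExpressionMatrix, s: SampleSheet) -> ExpressionMatrix:
    """Collapse replicate columns to per-condition arithmetic means.

    Output columns are the conditions, ordered by their ``order`` field.
    Every sample in the matrix must appear in the sheet.
    """
    missing = [x for x in m.sample_ids if x not in set(s.sample_ids)]
    if missing:
        raise ValidationError(f"matrix samples absent from sample sheet: {missing[:5]}")
    cols = {}
    for cond in s.ordered_conditions():
        members = [x for x in s.samples_for(cond) if x in m.data.columns]
        if members:
            cols[cond] = m.data[members].mean(axis=1)
    return ExpressionMatrix(pd.DataFrame(cols, index=m.data.index))
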