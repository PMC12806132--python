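"""Omic feature matrices and reference-gene anchored min-max normalization."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "normalize_reference_minmax",
    "log_transform",
    "DEFAULT_REFERENCE_GENE",
]

#: Conventional reference-gene token; synthetic cohorts plant a constitutive
#: high expressor under this name.
DEFAULT_REFERENCE_GENE = "PKM"

LAYERS = ("TX", "GX", "PX", "JX", "reaction_expression")


class DegenerateSampleError(ValueError):
    """Reference expression does not exceed the per-sample minimum."""


@dataclass
class ExpressionMatrix:
    """Features x samples continuous matrix with an omic-layer tag.

    Thin wrapper around a :class:`pandas.DataFrame` whose index holds the
    feature (gene/reaction) ids and whose columns hold the sample ids.
    """

    values: pd.DataFrame
    layer: str = "TX"

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate feature ids: {sorted(set(dupes))}")
        if self.values.columns.has_duplicates:
            dupes = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {sorted(set(dupes))}")
        arr = self.values.to_numpy(dtype=float)
        if arr.size and not np.all(np.isfinite(arr)):
            bad = int(np.sum(~np.isfinite(arr)))
            raise ValueError(f"{bad} non-finite values in {self.layer} matrix")

    @property
    def gene_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def sample(self, sample_id: str) -> dict[str, float]:
        """Expression of every feature in one sample, as a plain dict."""
        return self.values[sample_id].to_dict()

    def with_values(self, values: pd.DataFrame) -> "ExpressionMatrix":
        return ExpressionMatrix(values=values, layer=self.layer)

    # -- I/O --------------------------------------------------------------
    @classmethod
    def from_tsv(
        cls, path: Union[str, Path], layer: str = "TX", sep: str = "\t"
    ) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep=sep, index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        return cls(values=df.astype(float), layer=layer)

    def to_tsv(self, path: Union[str, Path], sep: str = "\t") -> None:
        df = self.values.copy()
        df.index.name = "feature_id"
        df.to_csv(path, sep=sep, lineterminator="\n")


def normalize_reference_minmax(
    expr: ExpressionMatrix, reference_gene: str = DEFAULT_REFERENCE_GENE
) -> ExpressionMatrix:
    """Per-sample min-max normalization anchored at a reference gene.

    For sample ``s``::

        e'(g, s) = (e(g, s) - min_g e(g, s)) / (e(ref, s) - min_g e(g, s))

    clipped above at 1, so the output lies in [0, 1] with the reference gene
    mapped to exactly 1 in every sample.  The result feeds fractional
    expression-based flux bounds, which require a [0, 1] scale.
    """
    if reference_gene not in expr.values.index:
        raise KeyError(
            f"reference gene {reference_gene!r} not present in the "
            f"{expr.layer} matrix"
        )
    mat = expr.values.to_numpy(dtype=float)
    mins = mat.min(axis=0)
    ref = expr.values.loc[reference_gene].to_numpy(dtype=float)
    span = ref - mins
    bad = np.flatnonzero(span <= 0)
    if bad.size:
        names = [expr.sample_ids[i] for i in bad[:5]]
        raise DegenerateSampleError(
            f"reference gene {reference_gene!r} does not exceed the sample "
            f"minimum in sample(s) {names}"
        )
    out = (mat - mins) / span
    np.clip(out, 0.0, 1.0, out=out)
    return ExpressionMatrix(
        values=pd.DataFrame(out, index=expr.values.index, columns=expr.values.columns),
        layer=expr.layer,
    )


def log_transform(expr: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Elementwise ``log2(value + pseudocount)``."""
    if pseudocount < 0:
        raise ValueError(f"pseudocount must be >= 0, got {pseudocount}")
    mat = expr.values.to_numpy(dtype=float)
    if mat.size and mat.min() < 0:
        raise ValueError("log_transform requires nonnegative values")
    return expr.with_values(
        pd.DataFrame(
            np.log2(mat + pseudocount),
            index=expr.values.index,
            columns=expr.values.columns,
        )
    )
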