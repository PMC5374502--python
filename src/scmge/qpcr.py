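"""Single-cell multiplexed qPCR analysis.

Missing Ct values are set to 40 (no amplification within the run), expression
is normalized per cell as ΔCt relative to the reference gene Actb, and each
gene is z-scored across cells (population standard deviation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_model import ExpressionMatrix, ValidationError

__all__ = ["CtMatrix", "impute_missing", "delta_ct", "zscore_genes"]


@dataclass
class CtMatrix:
    """Gene x cell Ct cycle values; NaN marks a missing (failed) reaction."""

    values: pd.DataFrame
    reference_gene: str = "Actb"
    missing_fill: float = 40.0

    def __post_init__(self) -> None:
        if self.reference_gene not in self.values.index:
            raise ValidationError(f"reference gene {self.reference_gene!r} missing")
        arr = self.values.to_numpy()
        observed = arr[~np.isnan(arr)]
        if ((observed <= 0) | (observed > self.missing_fill)).any():
            raise ValidationError(f"Ct values must lie in (0, {self.missing_fill}]")


def impute_missing(ct: CtMatrix) -> CtMatrix:
    """Replace every missing Ct with the fill value (default 40); nothing else changes."""
    return CtMatrix(ct.values.fillna(ct.missing_fill), ct.reference_gene, ct.missing_fill)


def delta_ct(ct: CtMatrix) -> ExpressionMatrix:
    """ΔCt per gene relative to the reference gene within each cell.

    The reference gene's own row is identically zero, and any per-cell
    assay-wide Ct offset cancels.
    """
    filled = ct.values
    if filled.isna().any().any():
        filled = filled.fillna(ct.missing_fill)
    ref = filled.loc[ct.reference_gene]
    vals = filled - ref
    return ExpressionMatrix(vals, transform="delta_ct",
                            meta={"reference_gene": ct.reference_gene})


def zscore_genes(x: ExpressionMatrix) -> ExpressionMatrix:
    """Per-gene z-score across cells with population (n-denominator) sd.

    Zero-variance rows become all zeros, with a warning.
    """
    arr = x.values.to_numpy().astype(float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=0, keepdims=True)
    constant = (sd == 0).ravel()
    if constant.any():
        warnings.warn(f"{int(constant.sum())} zero-variance gene(s) z-scored to 0",
                      stacklevel=2)
    vals = np.where(sd > 0, (arr - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return ExpressionMatrix(
        pd.DataFrame(vals, index=x.values.index, columns=x.values.columns),
        transform="zscore",
        meta={"sd_convention": "population", "source_transform": x.transform},
    )
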