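"""Shared in-memory containers.

Count data travel as pandas DataFrames with features as rows and samples
as columns. :class:`CountMatrix` tags such a frame with the RNA class it
quantifies (gene-level reads, back-splice junction reads or
forward-splice junction reads), which downstream stages use to route
normalization and reporting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

RNA_CLASSES = ("gene", "BSJ", "FSJ")


@dataclass
class CountMatrix:
    """Features x samples non-negative integer read counts.

    Parameters
    ----------
    data
        DataFrame with feature identifiers as index and sample
        identifiers as columns.
    rna_class
        One of ``"gene"``, ``"BSJ"`` or ``"FSJ"``.
    """

    data: pd.DataFrame
    rna_class: str

    def __post_init__(self) -> None:
        if self.rna_class not in RNA_CLASSES:
            raise ValueError(
                f"rna_class must be one of {RNA_CLASSES}, got {self.rna_class!r}"
            )
        values = self.data.to_numpy()
        if values.size and (values < 0).any():
            raise ValueError("count matrices must be non-negative")

    @property
    def samples(self) -> pd.Index:
        return self.data.columns

    @property
    def features(self) -> pd.Index:
        return self.data.index


def as_frame(counts: "CountMatrix | pd.DataFrame") -> pd.DataFrame:
    """Accept either a tagged CountMatrix or a bare DataFrame."""
    if isinstance(counts, CountMatrix):
        return counts.data
    return counts


def check_integer_counts(frame: pd.DataFrame) -> None:
    values = frame.to_numpy()
    if not np.allclose(values, np.round(values)):
        raise ValueError("expected integer read counts")
    if values.size and (values < 0).any():
        raise ValueError("expected non-negative read counts")
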