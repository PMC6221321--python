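"""Expression-matrix container and plain-text I/O.

The pipeline operates on normalized log2 intensities indexed by gene and by
(drug, time in hours, replicate).  Columns follow the ``drug|t<h>|r<i>``
naming convention so a matrix round-trips through a single TSV plus a sample
sheet CSV.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ExpressionDataset", "read_expression", "write_expression"]


def sample_name(drug: str, time_hours: float, replicate: int) -> str:
    t = int(time_hours) if float(time_hours).is_integer() else time_hours
    return f"{drug}|t{t}|r{replicate}"


@dataclass
class ExpressionDataset:
    """Gene x sample log2 expression with sample annotations.

    Parameters
    ----------
    values
        DataFrame, genes (index, symbols) x samples (columns).
    samples
        DataFrame indexed by sample name with columns ``drug``,
        ``time_hours`` and ``replicate``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in self.values.columns if c not in self.samples.index]
        if missing:
            raise ValueError(f"samples sheet missing entries for columns: {missing[:5]}")
        self.samples = self.samples.loc[list(self.values.columns)]
        for drug in self.drugs:
            times = self.times_for(drug)
            if 0.0 not in times:
                raise ValueError(f"drug {drug!r} has no time-0 control samples")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def drugs(self) -> list[str]:
        seen: dict[str, None] = {}
        for d in self.samples["drug"]:
            seen.setdefault(d, None)
        return list(seen)

    def times_for(self, drug: str) -> np.ndarray:
        mask = self.samples["drug"] == drug
        return np.unique(self.samples.loc[mask, "time_hours"].to_numpy(float))

    def matrix_for(self, drug: str) -> tuple[np.ndarray, np.ndarray]:
        """Observation times (replicate-level, sorted) and the gene x obs matrix."""
        mask = (self.samples["drug"] == drug).to_numpy()
        sub = self.samples.loc[mask].sort_values(["time_hours", "replicate"])
        times = sub["time_hours"].to_numpy(float)
        mat = self.values.loc[:, sub.index].to_numpy(float)
        return times, mat


def write_expression(ds: ExpressionDataset, matrix_tsv: str | Path, samples_csv: str | Path) -> None:
    ds.values.to_csv(matrix_tsv, sep="\t", index_label="gene", float_format="%.6f")
    ds.samples.to_csv(samples_csv, index_label="sample")


def read_expression(matrix_tsv: str | Path, samples_csv: str | Path) -> ExpressionDataset:
    values = pd.read_csv(matrix_tsv, sep="\t", index_col="gene", comment="#")
    values.index = values.index.astype(str).str.upper()
    samples = pd.read_csv(samples_csv, index_col="sample", comment="#")
    required = {"drug", "time_hours", "replicate"}
    if not required <= set(samples.columns):
        raise ValueError(f"sample sheet must have columns {sorted(required)}")
    return ExpressionDataset(values, samples)
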