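"""qPCR-style relative quantification.

Relative quantities (already efficiency-corrected; Ct conversion is out of
scope) are normalized per sample to the geometric mean of one or more
reference targets, then expressed as fold change relative to the mean of the
control samples, so controls average exactly 1.  The splicing index compares
a variant-containing isoform with the fully skipped isoform:
SI = 100 * variant / (variant + skipped).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass
class RelQuantTable:
    """targets x samples positive relative quantities with a declared set of
    reference targets and control samples."""

    quantities: pd.DataFrame
    reference_targets: list[str]
    control_samples: list[str]

    def __post_init__(self) -> None:
        missing_t = set(self.reference_targets) - set(self.quantities.index)
        if missing_t:
            raise ValueError(f"reference targets not measured: {sorted(missing_t)}")
        missing_s = set(self.control_samples) - set(self.quantities.columns)
        if missing_s:
            raise ValueError(f"control samples not present: {sorted(missing_s)}")
        refs = self.quantities.loc[self.reference_targets]
        if (refs.values <= 0).any():
            raise ValueError("reference quantities must be strictly positive")


def read_relquant_table(
    path: str | Path, reference_targets: Sequence[str], control_samples: Sequence[str]
) -> RelQuantTable:
    """Long TSV with columns target, sample, quantity."""
    df = pd.read_csv(path, sep="\t")
    wide = df.pivot(index="target", columns="sample", values="quantity")
    return RelQuantTable(
        quantities=wide,
        reference_targets=list(reference_targets),
        control_samples=list(control_samples),
    )


def normalize_to_references(table: RelQuantTable) -> pd.DataFrame:
    """Two-step normalization: divide each target by the per-sample geometric
    mean of the reference targets, then by the control-sample mean of the
    target so that controls average 1."""
    refs = table.quantities.loc[table.reference_targets]
    geo = np.exp(np.log(refs).mean(axis=0))  # per-sample geometric mean
    ref_norm = table.quantities.div(geo, axis=1)
    control_mean = ref_norm[table.control_samples].mean(axis=1)
    if (control_mean == 0).any():
        raise ValueError("control mean is zero for some target")
    return ref_norm.div(control_mean, axis=0)


def splicing_index(variant: float, skipped: float) -> float:
    """SI = 100 * variant / (variant + skipped); NaN when both are zero."""
    if variant < 0 or skipped < 0:
        raise ValueError("quantities must be non-negative")
    total = variant + skipped
    if total == 0:
        return float("nan")
    return 100.0 * variant / total


def write_normalized_table(normalized: pd.DataFrame, path: str | Path) -> None:
    normalized.to_csv(path, sep="\t", float_format="%.6g")
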