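"""Library-size normalization, sample QC, expression-range selection and
the paired differential-expression criterion.

Counts live in a plain pandas DataFrame (genes x samples); sample metadata
(group, pairing key, mapping QC percentages) in a second DataFrame indexed
by sample.  Differential expression follows the conjunction rule
|log2FC| > 1 AND paired-t p < 0.05 on log2(CPM + 1) values; the full
count-model machinery of dedicated DE packages is deliberately out of scope
here — the criterion itself is the product.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .gene_model import ExonRole, GeneModel
from .junction_quant import JunctionClass, JunctionRecord, classify_junction

logger = logging.getLogger(__name__)

QC_MIN_UNIQUELY_MAPPED = 60.0  # percent
QC_MIN_ASSIGNED = 10.0  # percent


@dataclass
class CountMatrix:
    """Gene-level counts plus per-sample metadata.

    counts : DataFrame, genes x samples, non-negative integers.
    meta   : DataFrame indexed by sample; recognised columns are ``group``,
             ``pairing`` (study/extract-type key for matched designs),
             ``pct_uniquely_mapped`` and ``pct_assigned``.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("count matrix contains negative entries")
        missing = set(self.counts.columns) - set(self.meta.index)
        if missing:
            raise ValueError(f"samples missing from metadata: {sorted(missing)}")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def collapse_samples(self, collapse_map: Mapping[str, str]) -> "CountMatrix":
        """Average groups of technical replicates into single samples
        (e.g. study duplicates treated as one sample).  ``collapse_map``
        maps each original sample to its collapsed name; unmapped samples
        keep their own name."""
        groups = {s: collapse_map.get(s, s) for s in self.samples}
        counts = self.counts.T.groupby(pd.Series(groups)).mean().T
        meta = self.meta.groupby(pd.Series(groups)).first()
        return CountMatrix(counts=counts, meta=meta.loc[counts.columns])


def read_count_matrix(counts_path: str | Path, meta_path: str | Path) -> CountMatrix:
    """TSV readers: counts with genes in rows (first column = gene id,
    header = sample ids); metadata indexed by its first column (sample id)."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    return CountMatrix(counts=counts, meta=meta)


# ---------------------------------------------------------------------------
# normalization

def cpm_normalize(counts: pd.DataFrame | CountMatrix) -> pd.DataFrame:
    """Counts-per-million: each sample column scaled to sum to 1e6 over the
    genes present in the matrix."""
    if isinstance(counts, CountMatrix):
        counts = counts.counts
    libsize = counts.sum(axis=0)
    if (libsize <= 0).any():
        bad = list(libsize.index[libsize <= 0])
        raise ValueError(f"zero-library samples: {bad}")
    return counts.div(libsize, axis=1) * 1e6


# ---------------------------------------------------------------------------
# QC

@dataclass
class QCResult:
    kept: list[str]
    excluded: pd.DataFrame  # index sample, column "reasons" (semicolon-joined)
    unevaluable: list[str]

    @property
    def n_total(self) -> int:
        return len(self.kept) + len(self.excluded) + len(self.unevaluable)


def qc_filter(
    meta: pd.DataFrame | CountMatrix,
    min_uniquely_mapped: float = QC_MIN_UNIQUELY_MAPPED,
    min_assigned: float = QC_MIN_ASSIGNED,
) -> QCResult:
    """Exclude low-quality libraries.

    A sample is excluded iff pct_uniquely_mapped < min_uniquely_mapped OR
    pct_assigned < min_assigned (strict inequalities: a sample at exactly
    the threshold is kept).  Samples with a missing metric are flagged
    unevaluable, never silently kept.
    """
    if isinstance(meta, CountMatrix):
        meta = meta.meta
    for col in ("pct_uniquely_mapped", "pct_assigned"):
        if col not in meta.columns:
            raise ValueError(f"QC metric column {col!r} missing from metadata")
    kept: list[str] = []
    unevaluable: list[str] = []
    excluded_rows: dict[str, str] = {}
    for sample, row in meta.iterrows():
        um, asg = row["pct_uniquely_mapped"], row["pct_assigned"]
        if pd.isna(um) or pd.isna(asg):
            unevaluable.append(sample)
            continue
        reasons = []
        if um < min_uniquely_mapped:
            reasons.append(f"pct_uniquely_mapped {um:g} < {min_uniquely_mapped:g}")
        if asg < min_assigned:
            reasons.append(f"pct_assigned {asg:g} < {min_assigned:g}")
        if reasons:
            excluded_rows[sample] = "; ".join(reasons)
        else:
            kept.append(sample)
    excluded = pd.DataFrame({"reasons": pd.Series(excluded_rows, dtype=object)})
    excluded.index.name = "sample"
    return QCResult(kept=kept, excluded=excluded, unevaluable=unevaluable)


# ---------------------------------------------------------------------------
# sample selection by expression range

def select_in_reference_range(
    values: pd.Series, reference_samples: Sequence[str]
) -> list[str]:
    """Keep samples whose value lies within [min, max] of the reference
    samples (inclusive bounds).  Used to restrict analysis to test samples
    whose expression of a gene matches the control range."""
    reference_samples = list(reference_samples)
    if not reference_samples:
        raise ValueError("reference subset is empty")
    ref = values.loc[reference_samples]
    lo, hi = ref.min(), ref.max()
    return [s for s, v in values.items() if lo <= v <= hi]


# ---------------------------------------------------------------------------
# paired differential expression

def paired_de(
    cm: CountMatrix,
    pairs: Sequence[tuple[str, str]],
    lfc_threshold: float = 1.0,
    p_threshold: float = 0.05,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Paired differential expression on log2(CPM + pseudocount).

    ``pairs`` lists (condition-A sample, condition-B sample) matched e.g. by
    study and extract type.  Per gene: log2FC = mean over pairs of the paired
    log2-CPM difference (A minus B); two-tailed paired t-test; call "up" or
    "down" iff |log2FC| > lfc_threshold AND p < p_threshold.  Genes with zero
    counts everywhere are called unchanged with a missing p-value.
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 matched pairs")
    log_cpm = np.log2(cpm_normalize(cm.counts) + pseudocount)
    a_cols = [p[0] for p in pairs]
    b_cols = [p[1] for p in pairs]
    diffs = log_cpm[a_cols].values - log_cpm[b_cols].values  # genes x pairs
    log2fc = diffs.mean(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        tstat, pval = stats.ttest_rel(
            log_cpm[a_cols].values, log_cpm[b_cols].values, axis=1
        )
    all_zero = (cm.counts[a_cols + b_cols].sum(axis=1) == 0).values
    log2fc = np.where(all_zero, 0.0, log2fc)
    pval = np.where(all_zero, np.nan, pval)
    call = np.full(len(log2fc), "unchanged", dtype=object)
    sig = (~np.isnan(pval)) & (np.abs(log2fc) > lfc_threshold) & (pval < p_threshold)
    call[sig & (log2fc > 0)] = "up"
    call[sig & (log2fc < 0)] = "down"
    return pd.DataFrame(
        {"log2fc": log2fc, "p": pval, "call": call}, index=cm.counts.index
    )


def write_de_table(de: pd.DataFrame, path: str | Path) -> None:
    de.to_csv(path, sep="\t", float_format="%.6g")


# ---------------------------------------------------------------------------
# constitutive (gene-level) expression from junctions

def constitutive_expression(
    junctions: Sequence[JunctionRecord],
    model: GeneModel,
    library_sizes: Optional[pd.Series] = None,
) -> pd.Series:
    """Per-sample gene expression proxy: CPM-normalized reads summed over
    junctions joining two *constant* exons (e.g. C2-C3, C3-C5 and the
    C5-C16 skipping junction all qualify).  ``library_sizes`` defaults to
    each sample's total junction reads in the input.
    """
    if len(model.constant_exons) < 2:
        raise ValueError("model needs at least 2 constant exons")
    from .junction_quant import _abutting_exons

    samples: dict[str, float] = {}
    all_samples: set[str] = set()
    for j in junctions:
        all_samples.update(j.counts)
    if library_sizes is None:
        library_sizes = pd.Series(
            {s: float(sum(j.counts.get(s, 0) for j in junctions)) for s in all_samples}
        )
    total = pd.Series(0.0, index=sorted(all_samples))
    n_const = 0
    for j in junctions:
        left, right = _abutting_exons(j, model)
        if (
            left is not None
            and right is not None
            and left.role is ExonRole.CONSTANT
            and right.role is ExonRole.CONSTANT
        ):
            n_const += 1
            for s, c in j.counts.items():
                total[s] += 1e6 * c / library_sizes[s]
    if n_const == 0:
        logger.warning("no constitutive exon-exon junctions detected")
    return total
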