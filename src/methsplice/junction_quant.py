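"""Anchor-exon junction quantification of variant-exon inclusion.

Given splice-junction read counts (e.g. from a spliced aligner's junction
table) and a :class:`~methsplice.gene_model.GeneModel`, junctions touching a
chosen constant *anchor* exon (C5 or C16 in the CD44 nomenclature) are
classified as *inclusion* (anchor joined to a variant exon), *skipping*
(anchor joined to the constant exon on the far side of the variant block,
i.e. the C5-C16 junction of the fully skipped isoform) or *other*.  Per
sample, the inclusion percentage is

    inclusion_pct = 100 * sum(reads over inclusion junctions)
                        / sum(reads over inclusion + skipping junctions)

so that inclusion_pct + skipping_pct = 100 whenever the denominator is
positive; samples with no detected anchor junctions are reported missing
rather than zero.  Junctions classified "other" never enter the denominator.

Group comparisons use a paired/unpaired Student t-test or the Wilcoxon
signed-rank test; for small pair counts the signed-rank p-value comes from
the exact enumeration of the null distribution.
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .gene_model import ExonRecord, ExonRole, GeneModel

logger = logging.getLogger(__name__)

EXACT_WILCOXON_MAX_N = 25  # exact signed-rank null up to here, normal approx beyond


class JunctionClass(str, enum.Enum):
    INCLUSION = "inclusion"
    SKIPPING = "skipping"
    OTHER = "other"


@dataclass
class JunctionRecord:
    """One splice junction: the 0-based half-open *intron* interval, its
    strand ('+', '-' or '?' when unknown) and per-sample unique-read counts."""

    chrom: str
    intron_start: int
    intron_end: int
    strand: str = "?"
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.intron_start >= self.intron_end:
            raise ValueError(
                f"intron_start must be < intron_end "
                f"({self.intron_start} >= {self.intron_end})"
            )
        for s, c in self.counts.items():
            if c < 0:
                raise ValueError(f"negative read count for sample {s!r}")

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.chrom, self.intron_start, self.intron_end)


@dataclass
class AnchorJunctionSet:
    """Junctions touching the anchor exon, each with its class label."""

    anchor: ExonRecord
    junctions: list[tuple[JunctionRecord, JunctionClass]]
    min_reads: int = 2

    @property
    def samples(self) -> list[str]:
        seen: dict[str, None] = {}
        for j, _ in self.junctions:
            for s in j.counts:
                seen.setdefault(s)
        return list(seen)


@dataclass
class AnchorInclusionResult:
    """Per-sample inclusion/skipping percentages for one anchor exon.

    ``table`` has one row per sample with columns ``inclusion_pct``,
    ``skipping_pct`` and ``total_reads``; samples whose filtered
    anchor-junction denominator is zero carry NaN percentages.
    """

    anchor_id: str
    table: pd.DataFrame

    def inclusion_pct(self) -> pd.Series:
        return self.table["inclusion_pct"]


# ---------------------------------------------------------------------------
# input

_SJ_STRAND = {0: "?", 1: "+", 2: "-"}


def read_junction_table(
    path: str | Path,
    dialect: str = "sj_tab",
    sample: Optional[str] = None,
) -> list[JunctionRecord]:
    """Read one sample's junction table.

    ``sj_tab`` is the spliced-aligner junction dialect: 1-based inclusive
    first/last intron bases, a strand code (0 unknown / 1 '+' / 2 '-'),
    unique-read counts in column 7 (multi-mapper counts in column 8 are
    ignored).  ``bed`` stores the 0-based half-open intron interval directly
    with the read count in the score column.  The sample name defaults to
    the file stem.
    """
    path = Path(path)
    if sample is None:
        sample = path.stem
        # common junction-file naming: <sample>.SJ.tab / <sample>SJ.out.tab
        for suffix in (".SJ", "SJ.out", ".SJ.out"):
            if sample.endswith(suffix):
                sample = sample[: -len(suffix)].rstrip("._")
                break
    records: list[JunctionRecord] = []
    lines = path.read_text().splitlines()
    if not lines:
        logger.warning("junction table %s is empty", path)
        return records
    for lineno, line in enumerate(lines, 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        try:
            if dialect == "sj_tab":
                chrom = f[0]
                first, last = int(f[1]), int(f[2])
                strand = _SJ_STRAND.get(int(f[3]), "?")
                count = int(f[6])
                intron_start, intron_end = first - 1, last
            elif dialect == "bed":
                chrom = f[0]
                intron_start, intron_end = int(f[1]), int(f[2])
                count = int(f[4]) if len(f) > 4 else 0
                strand = f[5] if len(f) > 5 else "?"
            else:
                raise ValueError(f"unknown junction dialect {dialect!r}")
        except (IndexError, ValueError) as exc:
            if isinstance(exc, ValueError) and "dialect" in str(exc):
                raise
            raise ValueError(f"{path}:{lineno}: malformed {dialect} line") from exc
        if count < 0:
            raise ValueError(f"{path}:{lineno}: negative read count")
        records.append(
            JunctionRecord(chrom, intron_start, intron_end, strand, {sample: count})
        )
    return records


def merge_junctions(per_sample: Iterable[Sequence[JunctionRecord]]) -> list[JunctionRecord]:
    """Merge per-sample junction lists into records with combined count dicts."""
    merged: dict[tuple[str, int, int], JunctionRecord] = {}
    for records in per_sample:
        for j in records:
            if j.key not in merged:
                merged[j.key] = JunctionRecord(
                    j.chrom, j.intron_start, j.intron_end, j.strand, {}
                )
            tgt = merged[j.key]
            if tgt.strand == "?" and j.strand != "?":
                tgt.strand = j.strand
            for s, c in j.counts.items():
                tgt.counts[s] = tgt.counts.get(s, 0) + c
    return list(merged.values())


# ---------------------------------------------------------------------------
# classification

def _abutting_exons(
    j: JunctionRecord, model: GeneModel
) -> tuple[Optional[ExonRecord], Optional[ExonRecord]]:
    """Exons abutting the junction on its genomic-left (donor on '+') and
    genomic-right side: left iff exon.end == intron_start, right iff
    exon.start == intron_end."""
    left = right = None
    for e in model.exons:
        if e.chrom != j.chrom:
            continue
        if e.end == j.intron_start:
            left = e
        if e.start == j.intron_end:
            right = e
    return left, right


def classify_junction(
    j: JunctionRecord, model: GeneModel, anchor: ExonRecord
) -> JunctionClass:
    """Classify a junction relative to a constant anchor exon.

    inclusion: anchor joined to a variant exon; skipping: anchor joined to a
    constant exon on the far side of the variant block; everything else
    (anchor not involved, intronic far boundary, same-side constant exon)
    is "other".  Junctions with a known strand that contradicts the gene
    model's strand are "other"; unknown-strand junctions are matched on
    coordinates alone.
    """
    if j.strand in ("+", "-") and j.strand != model.strand:
        return JunctionClass.OTHER
    left, right = _abutting_exons(j, model)
    if left is anchor:
        partner = right
    elif right is anchor:
        partner = left
    else:
        return JunctionClass.OTHER
    if partner is None:
        return JunctionClass.OTHER
    if partner.role is ExonRole.VARIANT:
        return JunctionClass.INCLUSION
    # constant partner: skipping iff anchor and partner bracket the variant block
    vb = model.variant_block
    if not vb:
        return JunctionClass.OTHER
    lo = min(e.ordinal for e in vb)
    hi = max(e.ordinal for e in vb)
    a, p = anchor.ordinal, partner.ordinal
    if (a < lo and p > hi) or (a > hi and p < lo):
        return JunctionClass.SKIPPING
    return JunctionClass.OTHER


def enumerate_anchor_junctions(
    junctions: Iterable[JunctionRecord],
    model: GeneModel,
    anchor: ExonRecord | str,
    min_reads: int = 2,
) -> AnchorJunctionSet:
    """Collect inclusion/skipping junctions for the anchor exon.

    ``min_reads`` is the per-sample detection threshold: a junction's reads
    in a given sample enter downstream percentages only when that sample has
    at least ``min_reads`` reads on it (default 2).
    """
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    if isinstance(anchor, str):
        anchor = model.exon(anchor)
    elif anchor not in model.exons:
        raise KeyError(f"anchor {anchor.exon_id!r} not in model {model.gene_id!r}")
    kept = []
    for j in junctions:
        cls = classify_junction(j, model, anchor)
        if cls in (JunctionClass.INCLUSION, JunctionClass.SKIPPING):
            kept.append((j, cls))
    return AnchorJunctionSet(anchor=anchor, junctions=kept, min_reads=min_reads)


def inclusion_percentage(
    ajs: AnchorJunctionSet, weight: str = "reads"
) -> AnchorInclusionResult:
    """Per-sample inclusion/skipping percentages for the anchor.

    ``weight="reads"`` (default) weights by junction read counts;
    ``weight="junctions"`` counts each detected junction once.
    """
    if weight not in ("reads", "junctions"):
        raise ValueError("weight must be 'reads' or 'junctions'")
    samples = ajs.samples
    rows = {}
    for s in samples:
        inc = skp = 0
        total = 0
        for j, cls in ajs.junctions:
            c = j.counts.get(s, 0)
            if c < ajs.min_reads:
                continue  # per-sample detection filter
            total += c
            w = c if weight == "reads" else 1
            if cls is JunctionClass.INCLUSION:
                inc += w
            else:
                skp += w
        denom = inc + skp
        if denom > 0:
            rows[s] = (100.0 * inc / denom, 100.0 * skp / denom, total)
        else:
            rows[s] = (np.nan, np.nan, total)
    table = pd.DataFrame.from_dict(
        rows, orient="index", columns=["inclusion_pct", "skipping_pct", "total_reads"]
    )
    table.index.name = "sample"
    return AnchorInclusionResult(anchor_id=ajs.anchor.exon_id, table=table)


def write_inclusion_table(result: AnchorInclusionResult, path: str | Path) -> None:
    result.table.to_csv(path, sep="\t", float_format="%.6g")


def write_classified_junctions(
    ajs: AnchorJunctionSet, path: str | Path
) -> None:
    rows = []
    for j, cls in ajs.junctions:
        row = {
            "chrom": j.chrom,
            "intron_start": j.intron_start,
            "intron_end": j.intron_end,
            "strand": j.strand,
            "class": cls.value,
        }
        row.update(j.counts)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# group comparison

@dataclass
class ComparisonResult:
    statistic: float
    pvalue: float
    test: str
    design: str
    tails: str
    n: int
    degenerate: bool = False


def compare_inclusion(
    group_a: Sequence[float] | pd.Series,
    group_b: Sequence[float] | pd.Series,
    design: str = "paired",
    test: str = "wilcoxon_signed_rank",
    tails: str = "two",
    alternative: str = "greater",
) -> ComparisonResult:
    """Compare per-sample inclusion percentages between two groups.

    ``test`` is ``"t"`` or ``"wilcoxon_signed_rank"`` (the latter requires a
    paired design).  ``tails="one"`` uses ``alternative`` ("greater" means
    group A exceeds group B).  Zero paired differences are dropped before
    the signed-rank test; with all differences zero the comparison carries
    no signal and p = 1 is returned with a warning.  The exact signed-rank
    null is used up to n = 25 informative pairs.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if design == "paired":
        if len(a) != len(b):
            raise ValueError("paired design requires equal-length matched vectors")
        keep = ~(np.isnan(a) | np.isnan(b))
        a, b = a[keep], b[keep]
    else:
        a = a[~np.isnan(a)]
        b = b[~np.isnan(b)]
    if min(len(a), len(b)) < 2:
        raise ValueError("need at least 2 observations per group")
    alt = "two-sided" if tails == "two" else alternative
    if test == "wilcoxon_signed_rank":
        if design != "paired":
            raise ValueError("wilcoxon signed-rank requires a paired design")
        d = a - b
        if np.all(d == 0):
            warnings.warn("all paired differences are zero; p = 1")
            return ComparisonResult(0.0, 1.0, test, design, tails, len(a), True)
        n_inf = int(np.sum(d != 0))
        method = "exact" if n_inf <= EXACT_WILCOXON_MAX_N else "approx"
        res = stats.wilcoxon(
            a, b, zero_method="wilcox", correction=(method == "approx"),
            alternative=alt, method=method,
        )
        return ComparisonResult(float(res.statistic), float(res.pvalue),
                                test, design, tails, len(a))
    if test == "t":
        if design == "paired":
            d = a - b
            if np.all(d == 0):
                warnings.warn("all paired differences are zero; p = 1")
                return ComparisonResult(0.0, 1.0, test, design, tails, len(a), True)
            if np.std(d, ddof=1) == 0:
                warnings.warn(
                    "paired differences have zero variance; t statistic undefined"
                )
                return ComparisonResult(np.nan, np.nan, test, design, tails,
                                        len(a), True)
            res = stats.ttest_rel(a, b, alternative=alt)
        else:
            res = stats.ttest_ind(a, b, alternative=alt)
        return ComparisonResult(float(res.statistic), float(res.pvalue),
                                test, design, tails, len(a))
    raise ValueError(f"unknown test {test!r}")
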