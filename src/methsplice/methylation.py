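"""Methylation quantification and differential methylated region (DMR) calling.

Two quantification modes are covered: targeted MeDIP-qPCR expressed as a
percentage of input DNA, and genome-binned enrichment counts (MIRA-like
tracks) compared between two sample groups.  Group comparison normalizes ROI
counts with trimmed-mean-of-M-values (TMM) scale factors, converts to
log2-CPM, applies a two-sample t-test per ROI and a Bonferroni correction
over the number of tested ROIs.  A DMR is *hypo* when the test group
(group A, the disease/demethylated condition) has a negative log2 fold
change relative to the control group B.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

TMM_TRIM_M = 0.30  # two-sided trim fraction on M-values (log ratios)
TMM_TRIM_A = 0.05  # two-sided trim fraction on A-values (log abundances)


# ---------------------------------------------------------------------------
# containers

@dataclass
class MethylProfile:
    """Binned/locus methylation signal for a two-group comparison.

    bins   : DataFrame with columns chrom, start, end and optional label
             (0-based half-open, non-overlapping within a track).
    counts : DataFrame, bins x samples (row order matches ``bins``).
    groups : Series mapping sample -> group label.
    """

    bins: pd.DataFrame
    counts: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if len(self.bins) != len(self.counts):
            raise ValueError("bins and counts row counts differ")
        if (self.counts.values < 0).any():
            raise ValueError("negative methylation counts")
        missing = set(self.counts.columns) - set(self.groups.index)
        if missing:
            raise ValueError(f"samples missing a group label: {sorted(missing)}")

    def group_samples(self, group: str) -> list[str]:
        return [s for s in self.counts.columns if self.groups[s] == group]


def read_binned_coverage(
    counts_path: str | Path, groups_path: str | Path
) -> MethylProfile:
    """Read a TSV with columns chrom, start, end[, label] then one column per
    sample, plus a two-column sample/group TSV."""
    df = pd.read_csv(counts_path, sep="\t")
    bin_cols = [c for c in ("chrom", "start", "end", "label") if c in df.columns]
    bins = df[bin_cols].copy()
    counts = df.drop(columns=bin_cols)
    g = pd.read_csv(groups_path, sep="\t", index_col=0).iloc[:, 0]
    return MethylProfile(bins=bins, counts=counts, groups=g)


@dataclass
class DMR:
    chrom: str
    start: int
    end: int
    log2fc: float
    p_raw: float
    p_adj: float
    direction: str  # "hypo" | "hyper"
    significant: bool
    label: str = ""


def write_dmr_table(dmrs: Sequence[DMR], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "chrom": d.chrom, "start": d.start, "end": d.end,
                "log2fc": d.log2fc, "p_raw": d.p_raw, "p_adj": d.p_adj,
                "direction": d.direction, "significant": d.significant,
                "label": d.label,
            }
            for d in dmrs
        ]
    ).to_csv(path, sep="\t", index=False)


def read_dmr_table(path: str | Path) -> list[DMR]:
    df = pd.read_csv(path, sep="\t")
    return [
        DMR(
            chrom=str(r.chrom), start=int(r.start), end=int(r.end),
            log2fc=float(r.log2fc), p_raw=float(r.p_raw), p_adj=float(r.p_adj),
            direction=str(r.direction), significant=bool(r.significant),
            label=str(getattr(r, "label", "")),
        )
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# MeDIP percent input

def medip_percent_input(
    ip: pd.Series | Sequence[float], input_dna: pd.Series | Sequence[float]
) -> pd.Series:
    """5mC level per locus as a percentage of input DNA: 100 * IP / input.
    Loci with zero input are reported missing (NaN)."""
    ip = pd.Series(np.asarray(ip, dtype=float)) if not isinstance(ip, pd.Series) else ip.astype(float)
    inp = (
        pd.Series(np.asarray(input_dna, dtype=float), index=ip.index)
        if not isinstance(input_dna, pd.Series)
        else input_dna.astype(float)
    )
    if (ip < 0).any() or (inp < 0).any():
        raise ValueError("negative IP or input quantities")
    out = 100.0 * ip / inp.where(inp > 0)
    if (inp == 0).any():
        logger.warning("loci with zero input flagged missing")
    return out


# ---------------------------------------------------------------------------
# TMM scale factors

def _tmm_pair(
    obs: np.ndarray, ref: np.ndarray, trim_m: float, trim_a: float
) -> float:
    """Weighted trimmed mean of M-values of one sample against the reference;
    returns the scale factor 2**TMM."""
    n_obs, n_ref = obs.sum(), ref.sum()
    keep = (obs > 0) & (ref > 0)
    obs, ref = obs[keep].astype(float), ref[keep].astype(float)
    if obs.size == 0:
        return 1.0
    p_obs, p_ref = obs / n_obs, ref / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    # delta-method weights: inverse asymptotic variance of M
    w = 1.0 / ((n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref))
    if np.allclose(m, m[0], atol=1e-10):
        return float(2 ** m[0])
    # double trimming: drop the extreme trim_m of M and trim_a of A
    n = m.size
    lo_m, hi_m = np.floor(n * trim_m) + 1, n + 1 - (np.floor(n * trim_m) + 1)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n + 1 - (np.floor(n * trim_a) + 1)
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep2.any():
        return 1.0
    tmm = np.sum(w[keep2] * m[keep2]) / np.sum(w[keep2])
    return float(2 ** tmm)


def tmm_factors(
    counts: pd.DataFrame,
    trim_m: float = TMM_TRIM_M,
    trim_a: float = TMM_TRIM_A,
    reference: Optional[str] = None,
) -> pd.Series:
    """Trimmed-mean-of-M-values scale factors, one per sample column.

    The reference sample, unless given, is the one whose upper-quartile
    count fraction is closest to the mean upper-quartile across samples.
    Factors are renormalized to geometric mean 1.  A sample's effective
    library size is its raw library size times its factor.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    libsize = counts.sum(axis=0)
    if (libsize <= 0).any():
        bad = list(libsize.index[libsize <= 0])
        raise ValueError(f"all-zero samples: {bad}")
    uq = counts.div(libsize, axis=1).quantile(0.75, axis=0)
    if reference is None:
        reference = (uq - uq.mean()).abs().idxmin()
    ref = counts[reference].values
    factors = pd.Series(
        {
            s: _tmm_pair(counts[s].values, ref, trim_m, trim_a)
            for s in counts.columns
        }
    )
    factors /= np.exp(np.mean(np.log(factors)))  # geometric mean 1
    return factors


def effective_library_sizes(counts: pd.DataFrame, factors: pd.Series) -> pd.Series:
    return counts.sum(axis=0) * factors


def tmm_log2_cpm(counts: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(CPM + pseudocount) with CPM computed on TMM-effective library sizes."""
    factors = tmm_factors(counts)
    eff = effective_library_sizes(counts, factors)
    cpm = counts.div(eff, axis=1) * 1e6
    return np.log2(cpm + pseudocount)


# ---------------------------------------------------------------------------
# ROI aggregation and DMR calling

def aggregate_rois(
    profile: MethylProfile, rois: pd.DataFrame
) -> pd.DataFrame:
    """Sum bin counts into ROI rows (a bin contributes to every ROI its
    interval overlaps).  ``rois`` needs columns chrom, start, end and an
    optional label."""
    out = np.zeros((len(rois), profile.counts.shape[1]))
    bins = profile.bins
    for i, roi in enumerate(rois.itertuples()):
        mask = (
            (bins["chrom"] == roi.chrom)
            & (bins["end"] > roi.start)
            & (bins["start"] < roi.end)
        ).values
        out[i] = profile.counts.values[mask].sum(axis=0)
    return pd.DataFrame(out, columns=profile.counts.columns)


def read_roi_bed(path: str | Path) -> pd.DataFrame:
    rows = []
    for ln in Path(path).read_text().splitlines():
        if not ln.strip() or ln.startswith(("track", "browser", "#")):
            continue
        f = ln.split("\t")
        rows.append(
            {
                "chrom": f[0], "start": int(f[1]), "end": int(f[2]),
                "label": f[3] if len(f) > 3 else f"{f[0]}:{f[1]}-{f[2]}",
            }
        )
    return pd.DataFrame(rows)


def tiling_rois(
    chrom: str, start: int, end: int, width: int = 500
) -> pd.DataFrame:
    """Fallback ROI generator: fixed-width tiling bins over an interval,
    for synthetic runs where no peak-based ROI set exists."""
    starts = np.arange(start, end, width)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": np.minimum(starts + width, end),
            "label": [f"bin{i}" for i in range(len(starts))],
        }
    )


def call_dmrs(
    profile: MethylProfile,
    rois: pd.DataFrame,
    group_a: str,
    group_b: str,
    alpha: float = 0.05,
    pseudocount: float = 1.0,
) -> list[DMR]:
    """Call differentially methylated regions between group A (test:
    disease/demethylated) and group B (control).

    Per ROI the bin counts are summed, TMM+library-size normalized to
    log2-CPM, compared with a two-sample two-tailed t-test, and the raw
    p-values Bonferroni-corrected over the number of ROIs.  log2fc is
    mean(A) - mean(B) on the log2 scale; a region is significant iff
    p_adj < alpha (strict) and hypo iff log2fc < 0.
    """
    if len(rois) == 0:
        raise ValueError("empty ROI list")
    a_samples = profile.group_samples(group_a)
    b_samples = profile.group_samples(group_b)
    if len(a_samples) < 2 or len(b_samples) < 2:
        raise ValueError("each group needs at least 2 samples")
    roi_counts = aggregate_rois(profile, rois)
    log_cpm = tmm_log2_cpm(roi_counts, pseudocount=pseudocount)
    a = log_cpm[a_samples].values
    b = log_cpm[b_samples].values
    with np.errstate(invalid="ignore"):
        _, p_raw = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p_raw = np.where(np.isnan(p_raw), 1.0, p_raw)
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    _, p_adj, _, _ = multipletests(p_raw, method="bonferroni")
    out = []
    labels = rois["label"] if "label" in rois.columns else pd.Series([""] * len(rois))
    for i, roi in enumerate(rois.itertuples()):
        out.append(
            DMR(
                chrom=str(roi.chrom), start=int(roi.start), end=int(roi.end),
                log2fc=float(log2fc[i]), p_raw=float(p_raw[i]),
                p_adj=float(p_adj[i]),
                direction="hypo" if log2fc[i] < 0 else "hyper",
                significant=bool(p_adj[i] < alpha),
                label=str(labels.iloc[i]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# locus-group comparisons (targeted %input panels)

def default_locus_groups(locus_ids: Sequence[str]) -> dict[str, list[str]]:
    """Locus groupings for a targeted CD44-like %input panel, keyed the way
    the panel rows are usually reported: all loci; constant exons; the
    variant region including its assayed introns; variant exons only;
    introns only.  Locus ids follow the exon nomenclature (C*, v*, i*)."""
    ids = list(locus_ids)
    const = [l for l in ids if l.startswith("C")]
    var = [l for l in ids if l.startswith("v")]
    introns = [l for l in ids if l.startswith("i")]
    return {
        "all_loci": ids,
        "constant_exons": const,
        "variant_region_incl_introns": var + introns,
        "variant_exons_only": var,
        "introns_only": introns,
    }


def compare_locus_groups(
    values_by_cellline: pd.DataFrame,
    group_def: Mapping[str, Sequence[str]],
    baseline: str,
) -> pd.DataFrame:
    """Paired two-tailed t-tests of %input per locus group, each cell line
    against the baseline line; pairing is locus identity.  Degenerate cases
    (identical values at every locus) are reported p = 1.
    """
    rows = {}
    for gname, loci in group_def.items():
        loci = list(loci)
        if len(loci) < 2:
            raise ValueError(f"group {gname!r} has fewer than 2 loci")
        base = values_by_cellline.loc[loci, baseline].values
        pvals = {}
        for cl in values_by_cellline.columns:
            if cl == baseline:
                continue
            v = values_by_cellline.loc[loci, cl].values
            d = v - base
            if np.all(d == 0):
                pvals[cl] = 1.0
            elif np.std(d, ddof=1) == 0:
                pvals[cl] = np.nan  # constant nonzero shift: t undefined
            else:
                pvals[cl] = float(stats.ttest_rel(v, base).pvalue)
        rows[gname] = pvals
    return pd.DataFrame(rows).T
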