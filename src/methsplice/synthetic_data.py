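"""Synthetic data with the statistical structure the pipeline assumes.

The generator emulates a CD44-like cassette gene: a contiguous block of
variant exons flanked by constant exons, per-sample junction read counts in
which each variant exon's inclusion probability is coupled to the regional
methylation level through a logistic link,

    pi_e,g = logistic(baseline_logit_e + beta * meth_e,g),

negative-binomial binned methylation coverage for two groups, per-sample
mapping-QC metrics, and event/DMR tables with a known concordance
composition.  The logistic link is the simulator's own minimal monotone
model of the methylation-to-inclusion coupling; beta > 0 means more
methylation promotes inclusion.  Group "A" plays the perturbed/demethylated
condition (DKO- or tumor-like), group "B" the control.

Read allocation: each anchor-junction read first picks a variant exon
uniformly, then is an inclusion read for that exon with probability pi_e
(otherwise a skipping read), so the expected read-weighted inclusion
percentage is exactly 100 * mean_e(pi_e).

All generators are deterministic given (seed, config).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .concordance import EventKind, SplicingEvent
from .gene_model import ExonRecord, ExonRole, GeneModel, cd44_like_model
from .junction_quant import JunctionRecord
from .methylation import DMR, MethylProfile


@dataclass
class SimConfig:
    """Study conditions for the coupled methylation-splicing simulation.

    Defaults mirror the scale of the emulated comparisons: 6 samples per
    group, ~1e4 anchor-junction reads per sample (large enough that
    percentage estimates are stable to about +/-1 point), negative-binomial
    dispersion 0.1, a 4-fold methylation depletion in the perturbed group
    over the variant region, and a coupling of 4 log-odds per unit
    methylation so the planted splicing shift is well clear of sampling
    noise.
    """

    seed: int = 0
    n_samples: int = 6            # per group
    depth: float = 1e4            # mean anchor-junction reads per sample
    beta: float = 4.0             # log-odds of inclusion per unit methylation
    baseline_logit: float = -2.0  # inclusion log-odds at methylation 0
    meth_a: float = 0.2           # variant-region methylation, group A (perturbed)
    meth_b: float = 0.8           # variant-region methylation, group B (control)
    meth_constant: float = 0.5    # methylation outside the variant region, both groups
    nb_dispersion: float = 0.1    # var = mu + disp * mu^2
    bin_width: int = 100          # methylation coverage bin width (bp)
    flank_margin: int = 8000      # unchanged background flanking the gene (bp);
                                  # keeps shifted bins a small minority, as TMM
                                  # (and real enrichment data) assume
    meth_depth: float = 250.0     # mean bin counts at methylation level 1;
                                  # keeps the depleted group at >= ~50 mean counts
    dmr_truth_fold: float = 2.0   # group fold difference that defines a true DMR
    n_variant: int = 9
    n_constant_5p: int = 5
    n_constant_3p: int = 2
    n_events: int = 50            # genes in the event-table simulation

    def __post_init__(self) -> None:
        if self.depth <= 0 or self.nb_dispersion <= 0:
            raise ValueError("depth and nb_dispersion must be positive")
        for v in (self.meth_a, self.meth_b, self.meth_constant):
            if not 0 <= v <= 1:
                raise ValueError("methylation levels must lie in [0, 1]")


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def _nb(rng: np.random.Generator, mu, dispersion: float, size=None) -> np.ndarray:
    """Negative binomial with mean mu and variance mu + dispersion * mu^2."""
    mu = np.asarray(mu, dtype=float)
    n = 1.0 / dispersion
    out = np.zeros(np.broadcast_shapes(mu.shape if mu.shape else (1,),
                                       () if size is None else (size,)), dtype=int)
    mu_b = np.broadcast_to(mu, out.shape)
    pos = mu_b > 0
    p = n / (n + mu_b[pos])
    out[pos] = rng.negative_binomial(n, p)
    return out if size is not None or mu.shape else int(out[0])


# ---------------------------------------------------------------------------
# gene

def simulate_gene(config: SimConfig | None = None) -> GeneModel:
    """Deterministic CD44-like gene model: ``n_constant_5p`` constant exons,
    a contiguous block of ``n_variant`` variant exons, ``n_constant_3p``
    constant exons (defaults C1-C5, v2-v10, C16-C17)."""
    config = config or SimConfig()
    if config.n_variant < 1:
        raise ValueError("need at least one variant exon")
    if config.n_constant_5p < 1 or config.n_constant_3p < 1:
        raise ValueError("variant block must be flanked by constant exons")
    if (
        config.n_constant_5p == 5
        and config.n_variant == 9
        and config.n_constant_3p == 2
    ):
        return cd44_like_model()
    ids = (
        [f"C{i}" for i in range(1, config.n_constant_5p + 1)]
        + [f"v{i}" for i in range(2, config.n_variant + 2)]
        + [
            f"C{config.n_constant_5p + config.n_variant + 1 + i}"
            for i in range(1, config.n_constant_3p + 1)
        ]
    )
    exons, pos = [], 1000
    for ordinal, eid in enumerate(ids, 1):
        role = ExonRole.VARIANT if eid.startswith("v") else ExonRole.CONSTANT
        exons.append(ExonRecord(eid, "chrSim", pos, pos + 100, role, ordinal))
        pos += 400
    return GeneModel(gene_id="simGene", strand="+", exons=exons)


# ---------------------------------------------------------------------------
# junction counts

def inclusion_probabilities(config: SimConfig, group: str) -> np.ndarray:
    """pi_e for every variant exon in one group (logistic link)."""
    meth = config.meth_a if group == "A" else config.meth_b
    logit = config.baseline_logit + config.beta * meth
    pi = 1.0 / (1.0 + np.exp(-logit))
    return np.full(config.n_variant, pi)


def expected_inclusion_pct(config: SimConfig, group: str) -> float:
    """Closed-form expectation of the read-weighted anchor inclusion
    percentage under the uniform-exon-choice allocation: 100 * mean(pi_e)."""
    return 100.0 * float(inclusion_probabilities(config, group).mean())


def simulate_junction_counts(
    model: GeneModel,
    config: SimConfig,
    groups: Optional[Mapping[str, Sequence[str]]] = None,
) -> tuple[list[JunctionRecord], pd.Series]:
    """Per-sample junction read counts for the anchor statistic.

    Returns merged junction records (counts keyed by sample) and a sample ->
    group Series.  Junctions generated: anchor -> each variant exon
    (inclusion), anchor -> far-flank constant exon (skipping; the fully
    skipped isoform), plus variant -> next-variant junctions at one tenth of
    the anchor depth (classified "other"/non-anchor downstream and excluded
    from the statistic by construction).
    """
    rng = _rng(config.seed)
    if groups is None:
        groups = {
            "A": [f"A{i+1}" for i in range(config.n_samples)],
            "B": [f"B{i+1}" for i in range(config.n_samples)],
        }
    anchor, far = model.flanking_constants()
    variants = model.variant_block
    if len(variants) != config.n_variant:
        raise ValueError("config.n_variant does not match the gene model")
    # junction skeletons
    inc_juncs = [
        JunctionRecord(model.chrom, anchor.end, v.start, model.strand, {})
        for v in variants
    ]
    skip_junc = JunctionRecord(model.chrom, anchor.end, far.start, model.strand, {})
    vv_juncs = [
        JunctionRecord(model.chrom, a.end, b.start, model.strand, {})
        for a, b in zip(variants, variants[1:])
    ]
    group_of: dict[str, str] = {}
    for g, samples in groups.items():
        pi = inclusion_probabilities(config, g)
        k = len(pi)
        probs = np.concatenate([pi / k, [1.0 - pi.sum() / k]])
        for s in samples:
            group_of[s] = g
            total = int(_nb(rng, config.depth, config.nb_dispersion))
            alloc = rng.multinomial(total, probs)
            for j, c in zip(inc_juncs, alloc[:-1]):
                j.counts[s] = int(c)
            skip_junc.counts[s] = int(alloc[-1])
            vv_total = int(_nb(rng, config.depth / 10.0, config.nb_dispersion))
            vv_alloc = (
                rng.multinomial(vv_total, np.full(len(vv_juncs), 1.0 / len(vv_juncs)))
                if vv_juncs
                else []
            )
            for j, c in zip(vv_juncs, vv_alloc):
                j.counts[s] = int(c)
    records = inc_juncs + [skip_junc] + vv_juncs
    return records, pd.Series(group_of, name="group")


_SJ_STRAND_CODE = {"?": 0, "+": 1, "-": 2}


def write_sj_tab(
    records: Sequence[JunctionRecord], sample: str, path: str | Path
) -> None:
    """Write one sample's counts in the spliced-aligner junction-table
    dialect (1-based inclusive intron bounds, unique reads in column 7)."""
    with open(path, "w") as fh:
        for j in sorted(records, key=lambda j: (j.chrom, j.intron_start)):
            c = j.counts.get(sample, 0)
            fh.write(
                f"{j.chrom}\t{j.intron_start + 1}\t{j.intron_end}\t"
                f"{_SJ_STRAND_CODE.get(j.strand, 0)}\t0\t1\t{c}\t0\t20\n"
            )


# ---------------------------------------------------------------------------
# methylation coverage

def _bin_meth_level(
    model: GeneModel, start: int, end: int, config: SimConfig, group: str
) -> float:
    """Methylation level of a bin: the variant-region level of the bin's
    group if the bin overlaps the variant block span (introns included),
    otherwise the constant background level."""
    vb = model.variant_block
    v_lo = min(e.start for e in vb)
    v_hi = max(e.end for e in vb)
    in_variant = end > v_lo and start < v_hi
    if in_variant:
        return config.meth_a if group == "A" else config.meth_b
    return config.meth_constant


def simulate_methylation(
    model: GeneModel,
    config: SimConfig,
    groups: Optional[Mapping[str, Sequence[str]]] = None,
) -> tuple[MethylProfile, pd.DataFrame]:
    """Binned NB coverage for two groups over the gene span, plus the
    true-DMR table (bins whose group methylation levels differ by at least
    ``dmr_truth_fold``; direction hypo when group A is lower)."""
    rng = _rng(config.seed + 1)
    if groups is None:
        groups = {
            "A": [f"A{i+1}" for i in range(config.n_samples)],
            "B": [f"B{i+1}" for i in range(config.n_samples)],
        }
    span_lo = max(0, min(e.start for e in model.exons) - config.flank_margin)
    span_hi = max(e.end for e in model.exons) + config.flank_margin
    starts = np.arange(span_lo, span_hi, config.bin_width)
    bins = pd.DataFrame(
        {
            "chrom": model.chrom,
            "start": starts,
            "end": np.minimum(starts + config.bin_width, span_hi),
            "label": [f"bin{i}" for i in range(len(starts))],
        }
    )
    counts = {}
    group_of = {}
    levels = {
        g: np.array(
            [
                _bin_meth_level(model, s, e, config, g)
                for s, e in zip(bins["start"], bins["end"])
            ]
        )
        for g in groups
    }
    for g, samples in groups.items():
        mu = levels[g] * config.meth_depth
        for s in samples:
            group_of[s] = g
            counts[s] = _nb(rng, mu, config.nb_dispersion, size=None)
    profile = MethylProfile(
        bins=bins, counts=pd.DataFrame(counts), groups=pd.Series(group_of)
    )
    if set(levels) != {"A", "B"}:
        raise ValueError("methylation truth requires exactly groups 'A' and 'B'")
    eps = 1e-12
    la, lb = levels["A"], levels["B"]
    fold = np.maximum(la, lb) / np.maximum(np.minimum(la, lb), eps)
    is_dmr = fold >= config.dmr_truth_fold
    truth = bins[is_dmr].copy()
    truth["direction"] = np.where(la[is_dmr] < lb[is_dmr], "hypo", "hyper")
    return profile, truth.reset_index(drop=True)


def merge_truth_regions(truth: pd.DataFrame) -> pd.DataFrame:
    """Merge contiguous true-DMR bins of the same direction into regions —
    the ROI-level truth (a differentially methylated *region*, like an
    enrichment peak, spans many adjacent bins)."""
    rows = []
    cur = None
    for r in truth.sort_values(["chrom", "start"]).itertuples():
        if (
            cur is not None
            and r.chrom == cur["chrom"]
            and r.direction == cur["direction"]
            and r.start <= cur["end"]
        ):
            cur["end"] = max(cur["end"], r.end)
        else:
            if cur is not None:
                rows.append(cur)
            cur = {"chrom": r.chrom, "start": r.start, "end": r.end,
                   "direction": r.direction}
    if cur is not None:
        rows.append(cur)
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "direction"])
    out["label"] = [f"region{i}" for i in range(len(out))]
    return out


def write_true_dmr_bed(truth: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in truth.itertuples():
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.direction}\n")


# ---------------------------------------------------------------------------
# QC metrics

def simulate_qc(n: int, fraction_bad: float, seed: int = 0) -> pd.DataFrame:
    """Per-sample mapping QC metrics with planted failures.

    "Bad" samples are drawn strictly below the exclusion thresholds on at
    least one metric (uniquely-mapped < 60% or assigned < 10%); good samples
    strictly above both.  The planted truth is recorded in ``planted_bad``.
    """
    if not 0 <= fraction_bad <= 1:
        raise ValueError("fraction_bad must be in [0, 1]")
    rng = _rng(seed)
    n_bad = int(round(n * fraction_bad))
    bad = np.zeros(n, dtype=bool)
    bad[rng.choice(n, size=n_bad, replace=False)] = True
    um = rng.uniform(70, 95, size=n)
    asg = rng.uniform(20, 80, size=n)
    for i in np.where(bad)[0]:
        mode = rng.integers(3)
        if mode in (0, 2):
            um[i] = rng.uniform(30, 58)
        if mode in (1, 2):
            asg[i] = rng.uniform(1, 8)
    df = pd.DataFrame(
        {
            "pct_uniquely_mapped": um,
            "pct_assigned": asg,
            "planted_bad": bad,
        },
        index=[f"S{i+1}" for i in range(n)],
    )
    df.index.name = "sample"
    return df


# ---------------------------------------------------------------------------
# event / DMR tables with known concordance composition

DEFAULT_COMPOSITION: dict[str, int] = {
    # Fig-8A-style bookkeeping composition: 49 same-local events of which
    # 8 lack any nearby DMR, 9 alternative promoters, 5 different events.
    "concordant": 24,
    "opposite": 12,
    "uncertain": 5,
    "meDNA_absent": 8,
    "alt_promoter": 9,
    "different_event": 5,
}


def simulate_event_tables(
    composition: Optional[Mapping[str, int]] = None,
    seed: int = 0,
) -> tuple[list[SplicingEvent], list[SplicingEvent], list[DMR], list[DMR], pd.DataFrame]:
    """Two systems' event tables plus matching DMR tables whose rule-based
    classification reproduces a known category composition.

    Returns (events1, events2, dmrs1, dmrs2, truth) where truth maps each
    gene to its planted category.
    """
    comp = dict(DEFAULT_COMPOSITION if composition is None else composition)
    rng = _rng(seed)
    events1: list[SplicingEvent] = []
    events2: list[SplicingEvent] = []
    dmrs1: list[DMR] = []
    dmrs2: list[DMR] = []
    truth_rows = []
    gi = 0
    for category, count in comp.items():
        for _ in range(count):
            gi += 1
            gene = f"G{gi:03d}"
            chrom = "chr1"
            base = 1_000_000 * gi  # genes isolated in coordinate space
            src = base + int(rng.integers(0, 1000))
            tgt = src + 300 + int(rng.integers(0, 200))
            sign = -1 if rng.random() < 0.5 else 1
            dpsi = sign * rng.uniform(0.25, 0.6)
            kind = EventKind.CASSETTE
            e1 = SplicingEvent(gene, chrom, src, tgt, kind, float(dpsi), 0.99)
            if category == "alt_promoter":
                e2 = SplicingEvent(
                    gene, chrom, src, tgt + 2000, EventKind.ALT_PROMOTER,
                    float(dpsi), 0.99,
                )
            elif category == "different_event":
                e2 = SplicingEvent(
                    gene, chrom, src, tgt + 5000, kind, float(dpsi), 0.99
                )
            else:
                e2 = SplicingEvent(
                    gene, chrom, src, tgt, kind,
                    float(dpsi * rng.uniform(0.8, 1.2)), 0.99,
                )
            events1.append(e1)
            events2.append(e2)
            truth_rows.append({"gene": gene, "category": category})

            def _dmr(sign_fc: int, significant: bool) -> DMR:
                s = src + int(rng.integers(-2000, 2000))
                fc = sign_fc * rng.uniform(0.8, 2.5)
                return DMR(
                    chrom=chrom, start=s, end=s + 400, log2fc=float(fc),
                    p_raw=0.001 if significant else 0.5,
                    p_adj=0.01 if significant else 1.0,
                    direction="hypo" if fc < 0 else "hyper",
                    significant=significant, label=gene,
                )

            if category == "concordant":
                dmrs1.append(_dmr(sign, True))
                dmrs2.append(_dmr(sign, True))
            elif category == "opposite":
                dmrs1.append(_dmr(-sign, True))
                dmrs2.append(_dmr(-sign, True))
            elif category == "uncertain":
                dmrs1.append(_dmr(sign, False))
                dmrs2.append(_dmr(sign, False))
            # meDNA_absent / alt_promoter / different_event: no nearby DMRs
    return events1, events2, dmrs1, dmrs2, pd.DataFrame(truth_rows)
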