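"""Cross-system splicing-methylation direction concordance.

Differential-splicing events detected independently in two systems (e.g. a
demethylated cell-line model and a patient cohort, each versus its control)
are matched by shared splice-site coordinates, sub-classified (same local
event / alternative promoter / different event despite a shared site), and
the same-local events are scored against differentially methylated regions
(DMRs) found near the event in each system:

* ``concordant``  — the sign of the splicing change (dPSI) equals the sign of
  the nearest significant DMR's log2 fold change in *both* systems (less
  methylation with less inclusion, or more with more);
* ``opposite``    — the signs disagree in both systems;
* ``uncertain``   — mixed signs between systems, conflicting significant DMRs
  within a system, or matched DMRs none of which is significant;
* ``meDNA_absent``— no DMR within the window in either system.

Sign convention, fixed project-wide: condition A is the perturbed/tumor
state; positive dPSI means more inclusion in A; positive DMR log2fc means
more methylation in A.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .methylation import DMR

DEFAULT_DMR_WINDOW = 5000  # bp around the event's splice-site span


class EventKind(str, enum.Enum):
    CASSETTE = "cassette"
    ALT_PROMOTER = "alt_promoter"
    OTHER = "other"


class Category(str, enum.Enum):
    CONCORDANT = "concordant"
    OPPOSITE = "opposite"
    MEDNA_ABSENT = "meDNA_absent"
    UNCERTAIN = "uncertain"
    ALT_PROMOTER = "alt_promoter"
    DIFFERENT_EVENT = "different_event"


@dataclass(frozen=True)
class SplicingEvent:
    """One differential-splicing event as reported by an upstream tool.

    dpsi is the differential percent-spliced-in in [-1, 1] (positive = more
    inclusion in condition A); confidence is the posterior probability that
    |dPSI| exceeds the tool's threshold.  Events are assumed pre-filtered at
    high confidence (e.g. P(|dPSI| > 0.2) > 0.95); the classifier does not
    re-filter.
    """

    gene: str
    chrom: str
    source_site: int
    target_site: int
    event_kind: EventKind
    dpsi: float
    confidence: float

    def __post_init__(self) -> None:
        if abs(self.dpsi) > 1 + 1e-12:
            raise ValueError(f"|dpsi| must be <= 1, got {self.dpsi}")
        if not 0 <= self.confidence <= 1:
            raise ValueError("confidence must be in [0, 1]")

    @property
    def sites(self) -> tuple[int, int]:
        return (self.source_site, self.target_site)

    @property
    def span(self) -> int:
        return abs(self.target_site - self.source_site)


@dataclass
class EventPair:
    event1: SplicingEvent
    event2: SplicingEvent
    shared_sites: int


@dataclass
class ConcordanceRecord:
    gene: str
    pair: EventPair
    category: Category
    dmrs1: list[DMR] = field(default_factory=list)
    dmrs2: list[DMR] = field(default_factory=list)


# ---------------------------------------------------------------------------
# IO

def read_event_table(path: str | Path) -> list[SplicingEvent]:
    """TSV with columns gene, chrom, source_site, target_site, event_kind,
    dpsi, confidence."""
    df = pd.read_csv(path, sep="\t")
    return [
        SplicingEvent(
            gene=str(r.gene), chrom=str(r.chrom),
            source_site=int(r.source_site), target_site=int(r.target_site),
            event_kind=EventKind(str(r.event_kind)),
            dpsi=float(r.dpsi), confidence=float(r.confidence),
        )
        for r in df.itertuples()
    ]


def write_event_table(events: Sequence[SplicingEvent], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "gene": e.gene, "chrom": e.chrom,
                "source_site": e.source_site, "target_site": e.target_site,
                "event_kind": e.event_kind.value,
                "dpsi": e.dpsi, "confidence": e.confidence,
            }
            for e in events
        ]
    ).to_csv(path, sep="\t", index=False)


def write_concordance_table(records: Sequence[ConcordanceRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "gene": r.gene,
                "category": r.category.value,
                "dpsi1": r.pair.event1.dpsi,
                "dpsi2": r.pair.event2.dpsi,
                "n_dmrs1": len(r.dmrs1),
                "n_dmrs2": len(r.dmrs2),
            }
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# matching and classification

def _sites_match(a: int, b: int, tol: int) -> bool:
    return abs(a - b) <= tol


def _shared_site_count(e1: SplicingEvent, e2: SplicingEvent, tol: int) -> int:
    used: set[int] = set()
    shared = 0
    for s1 in e1.sites:
        for k, s2 in enumerate(e2.sites):
            if k not in used and _sites_match(s1, s2, tol):
                used.add(k)
                shared += 1
                break
    return shared


def match_events(
    events1: Sequence[SplicingEvent],
    events2: Sequence[SplicingEvent],
    site_tolerance: int = 0,
) -> tuple[list[EventPair], list[SplicingEvent], list[SplicingEvent]]:
    """Pair events across the two systems by shared splice-site coordinates.

    A pair needs at least one shared site (within ``site_tolerance`` bp).
    Each gene contributes at most one pair: the one sharing the most sites,
    ties broken by the smallest combined genomic span.  Returns
    (pairs, unmatched-from-1, unmatched-from-2).
    """
    by_gene1: dict[str, list[SplicingEvent]] = {}
    by_gene2: dict[str, list[SplicingEvent]] = {}
    for e in events1:
        by_gene1.setdefault(e.gene, []).append(e)
    for e in events2:
        by_gene2.setdefault(e.gene, []).append(e)
    pairs: list[EventPair] = []
    matched1: set[int] = set()
    matched2: set[int] = set()
    for gene, g1 in by_gene1.items():
        g2 = by_gene2.get(gene, [])
        best: Optional[tuple[int, int, SplicingEvent, SplicingEvent]] = None
        for e1 in g1:
            for e2 in g2:
                if e1.chrom != e2.chrom:
                    continue
                shared = _shared_site_count(e1, e2, site_tolerance)
                if shared == 0:
                    continue
                key = (shared, -(e1.span + e2.span))
                if best is None or key > (best[0], best[1]):
                    best = (shared, -(e1.span + e2.span), e1, e2)
        if best is not None:
            pairs.append(EventPair(event1=best[2], event2=best[3], shared_sites=best[0]))
            matched1.add(id(best[2]))
            matched2.add(id(best[3]))
    unmatched1 = [e for e in events1 if id(e) not in matched1]
    unmatched2 = [e for e in events2 if id(e) not in matched2]
    return pairs, unmatched1, unmatched2


def classify_event_pair(pair: EventPair, site_tolerance: int = 0) -> str:
    """Sub-classify a matched pair: ``same_local`` iff both sites match and
    neither event is an alternative promoter; ``alt_promoter`` if either
    event is; ``different_event`` when only one site is shared."""
    if (
        pair.event1.event_kind is EventKind.ALT_PROMOTER
        or pair.event2.event_kind is EventKind.ALT_PROMOTER
    ):
        return "alt_promoter"
    if _shared_site_count(pair.event1, pair.event2, site_tolerance) >= 2:
        return "same_local"
    return "different_event"


def dmr_proximity(
    event: SplicingEvent, dmrs: Sequence[DMR], window: int = DEFAULT_DMR_WINDOW
) -> list[DMR]:
    """DMRs whose interval overlaps the event's splice-site span extended by
    ``window`` bp on each side."""
    if window < 0:
        raise ValueError("window must be >= 0")
    lo = min(event.sites) - window
    hi = max(event.sites) + window
    return [d for d in dmrs if d.chrom == event.chrom and d.end > lo and d.start < hi]


def _event_center(event: SplicingEvent) -> float:
    return 0.5 * (event.source_site + event.target_site)


def _system_meth_sign(event: SplicingEvent, matched: Sequence[DMR]) -> Optional[int]:
    """Sign of the methylation change for one system, from the nearest
    significant matched DMR.  Conflicting significant signs within the
    system, or no significant DMR among the matches, give None
    (-> uncertain)."""
    sig = [d for d in matched if d.significant and d.log2fc != 0]
    if not sig:
        return None
    signs = {1 if d.log2fc > 0 else -1 for d in sig}
    if len(signs) > 1:
        return None
    center = _event_center(event)
    nearest = min(sig, key=lambda d: abs(0.5 * (d.start + d.end) - center))
    return 1 if nearest.log2fc > 0 else -1


def concordance_category(
    pair: EventPair,
    dmrs1: Sequence[DMR],
    dmrs2: Sequence[DMR],
    window: int = DEFAULT_DMR_WINDOW,
    require_both: bool = True,
) -> Category:
    """Direction-concordance category for a same-local event pair.

    With ``require_both`` (default) concordance demands sign(dPSI) equal to
    the methylation sign in both systems; ``require_both=False`` accepts
    agreement in either system provided the other is not discordant.
    """
    m1 = dmr_proximity(pair.event1, dmrs1, window)
    m2 = dmr_proximity(pair.event2, dmrs2, window)
    if not m1 and not m2:
        return Category.MEDNA_ABSENT
    s1 = 0 if pair.event1.dpsi == 0 else (1 if pair.event1.dpsi > 0 else -1)
    s2 = 0 if pair.event2.dpsi == 0 else (1 if pair.event2.dpsi > 0 else -1)
    g1 = _system_meth_sign(pair.event1, m1) if m1 else None
    g2 = _system_meth_sign(pair.event2, m2) if m2 else None
    verdicts = []
    for s, g in ((s1, g1), (s2, g2)):
        if g is None or s == 0:
            verdicts.append(None)
        elif s == g:
            verdicts.append(True)
        else:
            verdicts.append(False)
    if require_both:
        if verdicts == [True, True]:
            return Category.CONCORDANT
        if verdicts == [False, False]:
            return Category.OPPOSITE
        return Category.UNCERTAIN
    decided = [v for v in verdicts if v is not None]
    if decided and all(decided):
        return Category.CONCORDANT
    if decided and not any(decided):
        return Category.OPPOSITE
    return Category.UNCERTAIN


def classify_shared_events(
    events1: Sequence[SplicingEvent],
    events2: Sequence[SplicingEvent],
    dmrs1: Sequence[DMR],
    dmrs2: Sequence[DMR],
    window: int = DEFAULT_DMR_WINDOW,
    site_tolerance: int = 0,
    require_both: bool = True,
) -> list[ConcordanceRecord]:
    """End-to-end classification: match events, split off alternative-promoter
    and different-event pairs, and score the same-local pairs against DMRs."""
    pairs, _, _ = match_events(events1, events2, site_tolerance)
    records = []
    for pair in pairs:
        sub = classify_event_pair(pair, site_tolerance)
        if sub == "alt_promoter":
            cat = Category.ALT_PROMOTER
        elif sub == "different_event":
            cat = Category.DIFFERENT_EVENT
        else:
            cat = concordance_category(pair, dmrs1, dmrs2, window, require_both)
        records.append(
            ConcordanceRecord(
                gene=pair.event1.gene, pair=pair, category=cat,
                dmrs1=dmr_proximity(pair.event1, dmrs1, window),
                dmrs2=dmr_proximity(pair.event2, dmrs2, window),
            )
        )
    return records


# ---------------------------------------------------------------------------
# tallies

def tally_categories(records: Sequence[ConcordanceRecord]) -> dict:
    """Category counts plus the derived summary fractions.

    same_local = concordant + opposite + uncertain + meDNA_absent;
    dmr_proximal = same_local - meDNA_absent.  Percentages are reported both
    exactly and rounded to the nearest integer; with an empty denominator
    they are None.
    """
    counts = {c.value: 0 for c in Category}
    for r in records:
        counts[r.category.value] += 1
    same_local = (
        counts["concordant"] + counts["opposite"]
        + counts["uncertain"] + counts["meDNA_absent"]
    )
    proximal = same_local - counts["meDNA_absent"]
    total = len(records)

    def pct(num: int, den: int):
        return None if den == 0 else 100.0 * num / den

    out = {
        "counts": counts,
        "total": total,
        "same_local": same_local,
        "dmr_proximal": proximal,
        "pct_dmr_proximal_of_same_local": pct(proximal, same_local),
        "pct_concordant_of_proximal": pct(counts["concordant"], proximal),
        "pct_uncorrelated_of_proximal": pct(counts["opposite"], proximal),
    }
    for k in list(out):
        if k.startswith("pct_"):
            out[k.replace("pct_", "pct_rounded_")] = (
                None if out[k] is None else round(out[k])
            )
    return out


def write_category_summary(tally: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(tally, indent=2, sort_keys=True) + "\n")
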