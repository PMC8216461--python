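"""Exon architecture of a single gene with constant/variant cassette roles.

The central object is :class:`GeneModel`: an ordered catalogue of exons in
transcription order, each labelled ``constant`` (always included, e.g. the
CD44 C1-C5 and C16-C17 exons) or ``variant`` (alternatively included cassette
exons, e.g. CD44 v2-v10).  All coordinates are 0-based half-open internally,
whatever the source file convention; GFF3 (1-based inclusive) is converted on
load.  Exon ordinals follow the direction of transcription, so on the '-'
strand the first ordinal is the exon with the highest genomic coordinate.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import yaml


class ExonRole(str, enum.Enum):
    CONSTANT = "constant"
    VARIANT = "variant"


@dataclass(frozen=True)
class ExonRecord:
    """One exon: half-open genomic interval plus its cassette role.

    Parameters
    ----------
    exon_id : str
        Label such as ``"C5"`` or ``"v6"``; unique within a gene.
    chrom : str
    start, end : int
        0-based half-open genomic interval.
    role : ExonRole
    ordinal : int
        1-based transcription-order index.
    """

    exon_id: str
    chrom: str
    start: int
    end: int
    role: ExonRole
    ordinal: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"exon {self.exon_id}: start must be < end ({self.start} >= {self.end})"
            )
        if self.ordinal < 1:
            raise ValueError(f"exon {self.exon_id}: ordinal must be >= 1")

    def contains(self, position: int) -> bool:
        return self.start <= position < self.end

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GeneModel:
    """Ordered exon catalogue of one gene.

    ``exons`` must be supplied in transcription order (strictly increasing
    ordinals).  Variant exons must form a single contiguous block flanked on
    both sides by at least one constant exon, because the skipping junction is
    defined as joining the two constant exons bracketing the block.
    """

    gene_id: str
    strand: str
    exons: list[ExonRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError("GeneModel requires at least one exon")
        ids = [e.exon_id for e in self.exons]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate exon ids in gene {self.gene_id}")
        ordinals = [e.ordinal for e in self.exons]
        if any(b <= a for a, b in zip(ordinals, ordinals[1:])):
            raise ValueError("exon ordinals must be strictly increasing")
        by_pos = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(by_pos, by_pos[1:]):
            if a.chrom == b.chrom and b.start < a.end:
                raise ValueError(
                    f"overlapping exons {a.exon_id} and {b.exon_id} in {self.gene_id}"
                )
        # variant block contiguity + constant flanks
        variant_idx = [i for i, e in enumerate(self.exons) if e.role is ExonRole.VARIANT]
        if variant_idx:
            lo, hi = variant_idx[0], variant_idx[-1]
            if variant_idx != list(range(lo, hi + 1)):
                raise ValueError("variant exons must form one contiguous block")
            if lo == 0 or hi == len(self.exons) - 1:
                raise ValueError(
                    "variant block must be flanked by a constant exon on each side"
                )

    # -- accessors -------------------------------------------------------

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def variant_block(self) -> list[ExonRecord]:
        """The maximal run of consecutive variant exons (may be empty)."""
        return [e for e in self.exons if e.role is ExonRole.VARIANT]

    @property
    def constant_exons(self) -> list[ExonRecord]:
        return [e for e in self.exons if e.role is ExonRole.CONSTANT]

    def exon(self, exon_id: str) -> ExonRecord:
        for e in self.exons:
            if e.exon_id == exon_id:
                return e
        raise KeyError(f"no exon {exon_id!r} in gene {self.gene_id}")

    def flanking_constants(self) -> tuple[ExonRecord, ExonRecord]:
        """Constant exons immediately up- and downstream of the variant block
        (transcription order), e.g. (C5, C16) for the CD44-like model."""
        vb = self.variant_block
        if not vb:
            raise ValueError("gene model has no variant block")
        idx = [i for i, e in enumerate(self.exons) if e.role is ExonRole.VARIANT]
        return self.exons[idx[0] - 1], self.exons[idx[-1] + 1]


def exon_at(model: GeneModel, chrom: str, position: int) -> Optional[ExonRecord]:
    """Exon whose half-open interval contains ``position``, else None."""
    for e in model.exons:
        if e.chrom == chrom and e.contains(position):
            return e
    return None


# ---------------------------------------------------------------------------
# role maps

def load_role_map(path: str | Path) -> dict[str, ExonRole]:
    """Read an exon_id -> role mapping from two-column TSV or YAML."""
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        raw = yaml.safe_load(path.read_text())
        return {str(k): ExonRole(str(v)) for k, v in raw.items()}
    out: dict[str, ExonRole] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: expected two tab-separated columns")
        out[parts[0].strip()] = ExonRole(parts[1].strip())
    return out


# ---------------------------------------------------------------------------
# readers / writers

def _order_by_transcription(records: list[tuple[str, str, int, int]], strand: str):
    reverse = strand == "-"
    return sorted(records, key=lambda r: r[2], reverse=reverse)


def _build_model(
    gene_id: str,
    strand: str,
    records: list[tuple[str, str, int, int]],
    role_map: Mapping[str, ExonRole | str],
) -> GeneModel:
    exons = []
    for ordinal, (exon_id, chrom, start, end) in enumerate(
        _order_by_transcription(records, strand), 1
    ):
        if exon_id not in role_map:
            raise KeyError(f"exon {exon_id!r} missing from role map")
        exons.append(
            ExonRecord(exon_id, chrom, start, end, ExonRole(role_map[exon_id]), ordinal)
        )
    return GeneModel(gene_id=gene_id, strand=strand, exons=exons)


def _load_gff3(path: Path, gene_id: str) -> tuple[str, list[tuple[str, str, int, int]]]:
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    try:
        gene = db[gene_id]
    except Exception as exc:  # gffutils raises its own FeatureNotFoundError
        raise KeyError(f"gene {gene_id!r} not found in {path}") from exc
    strand = gene.strand
    records = []
    for ex in db.children(gene, featuretype="exon", order_by="start"):
        name = (
            ex.attributes.get("Name", [None])[0]
            or ex.attributes.get("exon_id", [None])[0]
            or ex.id
        )
        # GFF3 is 1-based inclusive; convert to 0-based half-open
        records.append((name, ex.seqid, ex.start - 1, ex.end))
    if not records:
        raise KeyError(f"gene {gene_id!r} has no exon children in {path}")
    return strand, records


def _load_bed(
    path: Path, gene_id: str, role_map: Mapping[str, ExonRole | str]
) -> tuple[str, list[tuple[str, str, int, int]]]:
    lines = [
        ln for ln in Path(path).read_text().splitlines()
        if ln.strip() and not ln.startswith(("track", "browser", "#"))
    ]
    records: list[tuple[str, str, int, int]] = []
    strand = "+"
    bed12 = lines and len(lines[0].split("\t")) >= 12
    if bed12:
        for ln in lines:
            f = ln.split("\t")
            if f[3] != gene_id:
                continue
            chrom, chrom_start, strand = f[0], int(f[1]), f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            ids = list(role_map.keys())
            if len(ids) != len(sizes):
                raise ValueError(
                    f"role map has {len(ids)} exons but BED12 record has {len(sizes)} blocks"
                )
            genomic = [
                (chrom, chrom_start + off, chrom_start + off + size)
                for off, size in zip(starts, sizes)
            ]
            if strand == "-":
                genomic = genomic[::-1]  # role-map ids are in transcription order
            for exon_id, (c, s, e) in zip(ids, genomic):
                records.append((exon_id, c, s, e))
        if not records:
            raise KeyError(f"gene {gene_id!r} not found in {path}")
    else:
        # BED6: one exon per line, name = "<gene_id>:<exon_id>" or exon_id
        for ln in lines:
            f = ln.split("\t")
            name = f[3]
            if ":" in name:
                gid, exon_id = name.split(":", 1)
                if gid != gene_id:
                    continue
            else:
                exon_id = name
            if len(f) >= 6:
                strand = f[5]
            records.append((exon_id, f[0], int(f[1]), int(f[2])))
        if not records:
            raise KeyError(f"gene {gene_id!r} not found in {path}")
    return strand, records


def load_gene_model(
    path: str | Path,
    gene_id: str,
    role_map: Mapping[str, ExonRole | str] | str | Path,
) -> GeneModel:
    """Load one gene's exon model from GFF3 or BED (BED6 / BED12).

    ``role_map`` maps every exon id to ``constant``/``variant``; it may be a
    mapping or a path to a two-column TSV / YAML file.  For BED12 input the
    role map's key order defines the exon ids in transcription order.
    Coordinates are normalized to 0-based half-open.
    """
    path = Path(path)
    if not isinstance(role_map, Mapping):
        role_map = load_role_map(role_map)
    suffix = path.suffix.lower()
    if suffix in (".gff3", ".gff"):
        strand, records = _load_gff3(path, gene_id)
    elif suffix == ".bed":
        strand, records = _load_bed(path, gene_id, role_map)
    else:
        raise ValueError(f"unrecognized annotation format: {path.name}")
    return _build_model(gene_id, strand, records, role_map)


def write_bed(model: GeneModel, path: str | Path) -> None:
    """Write one BED6 line per exon (name = gene_id:exon_id, score = ordinal)."""
    with open(path, "w") as fh:
        for e in sorted(model.exons, key=lambda e: e.start):
            fh.write(
                f"{e.chrom}\t{e.start}\t{e.end}\t{model.gene_id}:{e.exon_id}"
                f"\t{e.ordinal}\t{model.strand}\n"
            )


def read_bed_model(
    path: str | Path, gene_id: str, role_map: Mapping[str, ExonRole | str]
) -> GeneModel:
    return load_gene_model(path, gene_id, role_map)


# ---------------------------------------------------------------------------
# built-in CD44-like fixture

CD44_EXON_IDS: tuple[str, ...] = (
    "C1", "C2", "C3", "C4", "C5",
    "v2", "v3", "v4", "v5", "v6", "v7", "v8", "v9", "v10",
    "C16", "C17",
)

CD44_ROLE_MAP: dict[str, ExonRole] = {
    eid: (ExonRole.VARIANT if eid.startswith("v") else ExonRole.CONSTANT)
    for eid in CD44_EXON_IDS
}


def cd44_like_model(
    exon_length: int = 100,
    intron_length: int = 300,
    chrom: str = "chrSim",
    offset: int = 1000,
) -> GeneModel:
    """Topological CD44-like fixture: constant C1-C5, variant v2-v10,
    constant C16-C17 on the '+' strand with compressed coordinates
    (100 bp exons, 300 bp introns by default).  Only the topology matters
    downstream; genomic positions are synthetic.
    """
    exons = []
    pos = offset
    for ordinal, eid in enumerate(CD44_EXON_IDS, 1):
        exons.append(
            ExonRecord(eid, chrom, pos, pos + exon_length, CD44_ROLE_MAP[eid], ordinal)
        )
        pos += exon_length + intron_length
    return GeneModel(gene_id="CD44like", strand="+", exons=exons)
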