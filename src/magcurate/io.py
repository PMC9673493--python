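"""Readers and writers for the formats the curation pipeline touches.

Sequences travel as :class:`SequenceRecord` (FASTA/FASTQ via Bio.SeqIO),
assembly graphs as :class:`AssemblyGraph` (GFA 1.0, S/L lines only), feature
annotations as :class:`FeatureAnnotation` (a GFF3 dialect carrying
``full_length``, ``isotype`` and ``partial`` attributes), and per-genome
quality metadata as :class:`GenomeMetadata` (TSV).  Coordinates are 1-based
inclusive throughout, per GFF convention.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("magcurate")

RRNA_TYPES = ("rRNA_5S", "rRNA_16S", "rRNA_23S")
FEATURE_TYPES = RRNA_TYPES + ("tRNA", "CDS")

METADATA_COLUMNS = [
    "genome_id",
    "is_circular",
    "assembly_size",
    "n_contigs",
    "completeness",
    "contamination",
    "compartment",
]


@dataclass
class SequenceRecord:
    """A named DNA sequence, optionally with per-base Phred qualities."""

    id: str
    sequence: str
    description: str = ""
    qualities: list[int] | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"record {self.id!r}: {len(self.qualities)} qualities for "
                f"{len(self.sequence)} bases"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Segment:
    """A GFA segment: a contig with a coverage depth."""

    id: str
    length: int
    sequence: str | None = None
    depth: float = 0.0

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError(f"segment {self.id!r}: negative depth")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"segment {self.id!r}: length {self.length} != sequence "
                f"length {len(self.sequence)}"
            )


@dataclass(frozen=True)
class Link:
    """An oriented join between two segments (GFA L line)."""

    from_id: str
    from_orient: str
    to_id: str
    to_orient: str
    overlap: str = "0M"

    def __post_init__(self) -> None:
        for o in (self.from_orient, self.to_orient):
            if o not in ("+", "-"):
                raise ValueError(f"malformed orientation {o!r}")

    def canonical(self) -> tuple:
        """Orientation-flipped duplicates of the same join collapse to one key."""
        flip = {"+": "-", "-": "+"}
        a = (self.from_id, self.from_orient, self.to_id, self.to_orient)
        b = (self.to_id, flip[self.to_orient], self.from_id, flip[self.from_orient])
        return min(a, b)


@dataclass
class AssemblyGraph:
    segments: dict[str, Segment] = field(default_factory=dict)
    links: list[Link] = field(default_factory=list)

    def validate(self) -> "AssemblyGraph":
        for ln in self.links:
            for sid in (ln.from_id, ln.to_id):
                if sid not in self.segments:
                    raise ValueError(f"link references unknown segment {sid!r}")
        return self


@dataclass(frozen=True)
class FeatureAnnotation:
    """One rRNA/tRNA/CDS feature on a contig (1-based inclusive coordinates)."""

    contig_id: str
    start: int
    end: int
    strand: str
    feature_type: str
    full_length: bool = True
    isotype: str | None = None
    partial_flags: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"feature on {self.contig_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        if self.feature_type not in FEATURE_TYPES:
            raise ValueError(f"unknown feature type {self.feature_type!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class GenomeMetadata:
    """Assembly-level quality metadata, as produced by binning + CheckM."""

    genome_id: str
    is_circular: bool
    assembly_size: int
    n_contigs: int
    completeness: float
    contamination: float
    compartment: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.completeness <= 100:
            raise ValueError(f"{self.genome_id}: completeness out of [0,100]")
        if self.contamination < 0:
            raise ValueError(f"{self.genome_id}: negative contamination")
        if self.n_contigs < 1:
            raise ValueError(f"{self.genome_id}: n_contigs < 1")
        if self.is_circular and self.n_contigs != 1:
            raise ValueError(f"{self.genome_id}: circular genome with >1 contig")


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def _clean_sequence(rec_id: str, seq: str) -> str:
    seq = seq.upper().replace("U", "T")
    if len(seq) == 0:
        raise ValueError(f"record {rec_id!r} has an empty sequence")
    return seq


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file; uppercases and maps U->T; rejects duplicate ids."""
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(SequenceRecord(rec.id, _clean_sequence(rec.id, str(rec.seq)), desc))
    return records


def write_fasta(records: Sequence[SequenceRecord], path: str | Path, line_width: int = 60) -> None:
    if not records:
        raise ValueError("refusing to write an empty FASTA file")
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), line_width):
                fh.write(rec.sequence[i : i + line_width] + "\n")


def read_fastq(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTQ (Phred+33) file into records carrying qualities."""
    records = []
    for rec in SeqIO.parse(str(path), "fastq"):
        records.append(
            SequenceRecord(
                rec.id,
                _clean_sequence(rec.id, str(rec.seq)),
                qualities=list(rec.letter_annotations["phred_quality"]),
            )
        )
    return records


def write_fastq(records: Sequence[SequenceRecord], path: str | Path) -> None:
    out = []
    for rec in records:
        if rec.qualities is None:
            raise ValueError(f"read {rec.id!r} has no qualities")
        sr = SeqRecord(Seq(rec.sequence), id=rec.id, description=rec.description)
        sr.letter_annotations["phred_quality"] = rec.qualities
        out.append(sr)
    SeqIO.write(out, str(path), "fastq")


# ---------------------------------------------------------------------------
# GFA 1.0


def _parse_tags(fields: Iterable[str]) -> dict[str, str]:
    tags = {}
    for f in fields:
        parts = f.split(":", 2)
        if len(parts) == 3:
            tags[parts[0] + ":" + parts[1]] = parts[2]
    return tags


def read_gfa(path: str | Path) -> AssemblyGraph:
    """Parse GFA 1.0 S and L lines.

    Depth comes from the ``rd:i:`` integer tag (hifiasm-meta), falling back to
    ``dp:f:`` then 0.  Other line types are ignored with a logged count.
    """
    graph = AssemblyGraph()
    ignored: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            kind = fields[0]
            if kind == "S":
                if len(fields) < 3:
                    raise ValueError(f"{path}:{lineno}: malformed S line")
                name, seq = fields[1], fields[2]
                tags = _parse_tags(fields[3:])
                if seq == "*":
                    if "LN:i" not in tags:
                        raise ValueError(
                            f"{path}:{lineno}: segment {name!r} has neither "
                            "sequence nor LN tag"
                        )
                    length, sequence = int(tags["LN:i"]), None
                else:
                    sequence = seq.upper()
                    length = len(sequence)
                if "rd:i" in tags:
                    depth = float(int(tags["rd:i"]))
                elif "dp:f" in tags:
                    depth = float(tags["dp:f"])
                else:
                    depth = 0.0
                if name in graph.segments:
                    raise ValueError(f"{path}:{lineno}: duplicate segment {name!r}")
                graph.segments[name] = Segment(name, length, sequence, depth)
            elif kind == "L":
                if len(fields) < 6:
                    raise ValueError(f"{path}:{lineno}: malformed L line")
                graph.links.append(Link(fields[1], fields[2], fields[3], fields[4], fields[5]))
            else:
                ignored[kind] = ignored.get(kind, 0) + 1
    if ignored:
        logger.info("read_gfa(%s): ignored line types %s", path, ignored)
    return graph.validate()


def write_gfa(graph: AssemblyGraph, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("H\tVN:Z:1.0\n")
        for seg in graph.segments.values():
            seq = seg.sequence if seg.sequence is not None else "*"
            fields = ["S", seg.id, seq, f"LN:i:{seg.length}", f"rd:i:{round(seg.depth)}"]
            fh.write("\t".join(fields) + "\n")
        for ln in graph.links:
            fh.write(
                "\t".join(["L", ln.from_id, ln.from_orient, ln.to_id, ln.to_orient, ln.overlap])
                + "\n"
            )


# ---------------------------------------------------------------------------
# GFF3 dialect


def read_annotations(path: str | Path) -> list[FeatureAnnotation]:
    """Parse the GFF3 dialect with full_length / isotype / partial attributes.

    Rows of unknown feature type are skipped with a warning (predictors emit
    more types than the pipeline consumes).
    """
    feats: list[FeatureAnnotation] = []
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF columns")
            contig, _src, ftype, start, end, _score, strand, _frame, attrs = fields
            if ftype not in FEATURE_TYPES:
                skipped += 1
                continue
            attr_map = {}
            for item in attrs.split(";"):
                item = item.strip()
                if item and "=" in item:
                    k, v = item.split("=", 1)
                    attr_map[k] = v
            feats.append(
                FeatureAnnotation(
                    contig_id=contig,
                    start=int(start),
                    end=int(end),
                    strand=strand,
                    feature_type=ftype,
                    full_length=attr_map.get("full_length", "true").lower() == "true",
                    isotype=attr_map.get("isotype"),
                    partial_flags=attr_map.get("partial"),
                )
            )
    if skipped:
        logger.warning("read_annotations(%s): skipped %d rows of unknown type", path, skipped)
    return feats


def write_annotations(features: Sequence[FeatureAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = [f"full_length={'true' if f.full_length else 'false'}"]
            if f.isotype is not None:
                attrs.append(f"isotype={f.isotype}")
            if f.partial_flags is not None:
                attrs.append(f"partial={f.partial_flags}")
            fh.write(
                "\t".join(
                    [
                        f.contig_id,
                        "magcurate",
                        f.feature_type,
                        str(f.start),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


def annotations_by_contig(
    features: Iterable[FeatureAnnotation],
) -> dict[str, list[FeatureAnnotation]]:
    grouped: dict[str, list[FeatureAnnotation]] = {}
    for f in features:
        grouped.setdefault(f.contig_id, []).append(f)
    return grouped


# ---------------------------------------------------------------------------
# Metadata TSV


def read_metadata(path: str | Path) -> dict[str, GenomeMetadata]:
    df = pd.read_csv(path, sep="\t", dtype={"genome_id": str, "compartment": str})
    missing = [c for c in METADATA_COLUMNS[:-1] if c not in df.columns]
    if missing:
        raise ValueError(f"metadata table {path} lacks columns {missing}")
    out: dict[str, GenomeMetadata] = {}
    for row in df.itertuples(index=False):
        compartment = getattr(row, "compartment", None)
        if compartment is not None and (pd.isna(compartment) or compartment == ""):
            compartment = None
        md = GenomeMetadata(
            genome_id=row.genome_id,
            is_circular=bool(row.is_circular) if not isinstance(row.is_circular, str)
            else row.is_circular.strip().lower() in ("true", "1", "yes"),
            assembly_size=int(row.assembly_size),
            n_contigs=int(row.n_contigs),
            completeness=float(row.completeness),
            contamination=float(row.contamination),
            compartment=compartment,
        )
        if md.genome_id in out:
            raise ValueError(f"duplicate genome_id {md.genome_id!r} in {path}")
        out[md.genome_id] = md
    return out


def write_metadata(metadata: Mapping[str, GenomeMetadata], path: str | Path) -> None:
    rows = [
        {
            "genome_id": m.genome_id,
            "is_circular": m.is_circular,
            "assembly_size": m.assembly_size,
            "n_contigs": m.n_contigs,
            "completeness": m.completeness,
            "contamination": m.contamination,
            "compartment": m.compartment if m.compartment is not None else "",
        }
        for m in metadata.values()
    ]
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Read filtering


def read_accuracy(qualities: Sequence[int]) -> float:
    """Accuracy = 1 - mean per-base error probability, errors from Phred scores."""
    err = sum(10.0 ** (-q / 10.0) for q in qualities) / len(qualities)
    return 1.0 - err


def filter_reads(
    reads: Sequence[SequenceRecord],
    min_length_bp: int = 2000,
    min_accuracy: float = 0.99,
) -> tuple[list[SequenceRecord], dict[str, int]]:
    """Keep reads strictly longer than ``min_length_bp`` with accuracy strictly
    above ``min_accuracy``; both thresholds are exclusive ("over 2 kb", "over
    99%")."""
    kept: list[SequenceRecord] = []
    summary = {
        "kept_reads": 0,
        "removed_reads": 0,
        "kept_bases": 0,
        "removed_bases": 0,
        "removed_short": 0,
        "removed_inaccurate": 0,
    }
    for read in reads:
        if read.qualities is None:
            raise ValueError(f"read {read.id!r} has no quality scores")
        ok_len = len(read) > min_length_bp
        ok_acc = read_accuracy(read.qualities) > min_accuracy
        if ok_len and ok_acc:
            kept.append(read)
            summary["kept_reads"] += 1
            summary["kept_bases"] += len(read)
        else:
            summary["removed_reads"] += 1
            summary["removed_bases"] += len(read)
            if not ok_len:
                summary["removed_short"] += 1
            elif not ok_acc:
                summary["removed_inaccurate"] += 1
    return kept, summary
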