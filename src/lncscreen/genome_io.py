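"""Genomic interval algebra and readers/writers for FASTA, GFF3, BED and count tables.

All internal coordinates are 0-based half-open on a named sequence
(``seqid``).  The only place 1-based inclusive coordinates appear is at the
GFF3 boundary, where they are converted on read and write.  Strand is one of
``+``, ``-`` or ``.``; an unstranded interval (``.``) matches both strands in
stranded overlap queries, so unstranded predictions remain comparable to
stranded annotations.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "SequenceRecord",
    "CountMatrix",
    "FormatError",
    "AnnotationError",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_bed",
    "write_bed",
    "interval_subtract",
    "interval_merge",
    "interval_overlap",
    "interval_distance",
]

_VALID_STRANDS = {"+", "-", "."}
_SEQ_RE = re.compile(r"^[ACGTUNacgtun]*$")


class FormatError(ValueError):
    """Raised for malformed input files (duplicate ids, bad alphabet, ...)."""


class AnnotationError(ValueError):
    """Raised when annotation features violate parent/child containment."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Strand-aware half-open span ``[start, end)`` on chromosome ``seqid``."""

    seqid: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.seqid:
            raise ValueError("seqid must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.seqid}: "
                "need 0 <= start < end"
            )
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def strands_compatible(self, other: "GenomicInterval") -> bool:
        """True unless both intervals are stranded and on opposite strands."""
        if self.strand == "." or other.strand == ".":
            return True
        return self.strand == other.strand

    def overlaps(self, other: "GenomicInterval", stranded: bool = False) -> bool:
        if self.seqid != other.seqid:
            return False
        if stranded and not self.strands_compatible(other):
            return False
        return self.start < other.end and other.start < self.end

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.seqid != other.seqid:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.seqid == other.seqid
            and self.start <= other.start
            and other.end <= self.end
        )

    def distance(self, other: "GenomicInterval") -> int:
        """Gap length between nearest ends; 0 if the intervals overlap or touch."""
        if self.seqid != other.seqid:
            raise ValueError("distance undefined across different seqids")
        if self.start < other.end and other.start < self.end:
            return 0
        if self.end <= other.start:
            return other.start - self.end
        return self.start - other.end

    def extract(self, sequence: str) -> str:
        """Slice this interval out of the full chromosome sequence.

        Minus-strand intervals return the reverse complement.
        """
        sub = sequence[self.start : self.end]
        if self.strand == "-":
            sub = str(Seq(sub).reverse_complement())
        return sub


@dataclass
class GeneModel:
    """Protein-coding gene: gene span, exon/CDS/UTR structure, derived introns."""

    gene_id: str
    interval: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)
    cds: list[GenomicInterval] = field(default_factory=list)
    utr5: list[GenomicInterval] = field(default_factory=list)
    utr3: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        for kind, ivs in (("exon", self.exons), ("CDS", self.cds),
                          ("five_prime_UTR", self.utr5), ("three_prime_UTR", self.utr3)):
            for iv in ivs:
                if not self.interval.contains(iv):
                    raise AnnotationError(
                        f"{kind} {iv.start}-{iv.end} outside gene {self.gene_id} "
                        f"span {self.interval.start}-{self.interval.end}"
                    )

    @property
    def introns(self) -> list[GenomicInterval]:
        """Gene span minus exonic spans (computed, strand inherited)."""
        exonic = self.exons if self.exons else (self.cds + self.utr5 + self.utr3)
        remainder = interval_subtract([self.interval], exonic)
        return [
            GenomicInterval(iv.seqid, iv.start, iv.end, self.interval.strand)
            for iv in remainder
        ]

    @property
    def strand(self) -> str:
        return self.interval.strand

    def spliced_sequence(self, chromosome: str) -> str:
        """mRNA sequence: exons concatenated 5'->3' (reverse-complemented on '-')."""
        exons = sorted(self.exons, key=lambda iv: iv.start)
        parts = [chromosome[iv.start : iv.end] for iv in exons]
        mrna = "".join(parts)
        if self.strand == "-":
            mrna = str(Seq(mrna).reverse_complement())
        return mrna


@dataclass
class SequenceRecord:
    """A named nucleotide sequence (IUPAC subset A/C/G/T/U/N, case kept)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not _SEQ_RE.match(self.sequence):
            bad = sorted({c for c in self.sequence if not _SEQ_RE.match(c)})
            raise FormatError(
                f"record {self.id!r} contains non-nucleotide symbols {bad}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Raises :class:`FormatError` on duplicate ids or non-nucleotide symbols.
    An empty file yields an empty list.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, str(rec.seq)))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                width: int = 70) -> None:
    bio = [_BioSeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# GFF3

_GFF_COLS = ("seqid", "source", "type", "start", "end", "score", "strand",
             "phase", "attributes")


def _gff_attrs(field9: str) -> dict[str, str]:
    out = {}
    for part in field9.strip().split(";"):
        if not part:
            continue
        key, _, val = part.partition("=")
        out[key] = val
    return out


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse gene models from GFF3 (gene / mRNA / exon / CDS / UTR features).

    GFF3 1-based inclusive coordinates are converted to internal 0-based
    half-open.  A child feature outside its parent gene raises
    :class:`AnnotationError` naming the feature.
    """
    genes: dict[str, GeneModel] = {}
    mrna_to_gene: dict[str, str] = {}
    children: list[tuple[str, str, GenomicInterval]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns")
            seqid, _src, ftype, start, end, _score, strand, _phase, attrs = fields
            iv = GenomicInterval(seqid, int(start) - 1, int(end), strand)
            a = _gff_attrs(attrs)
            if ftype == "gene":
                gid = a.get("ID", f"gene:{lineno}")
                genes[gid] = GeneModel(gid, iv)
            elif ftype == "mRNA":
                mrna_to_gene[a.get("ID", f"mRNA:{lineno}")] = a.get("Parent", "")
            elif ftype in ("exon", "CDS", "five_prime_UTR", "three_prime_UTR"):
                parent = a.get("Parent", "")
                children.append((ftype, parent, iv))
    for ftype, parent, iv in children:
        gid = mrna_to_gene.get(parent, parent)
        gene = genes.get(gid)
        if gene is None:
            raise AnnotationError(f"feature {ftype} has unknown parent {parent!r}")
        if not gene.interval.contains(iv):
            raise AnnotationError(
                f"{ftype} [{iv.start},{iv.end}) outside parent gene {gid}"
            )
        attr = {"exon": "exons", "CDS": "cds", "five_prime_UTR": "utr5",
                "three_prime_UTR": "utr3"}[ftype]
        getattr(gene, attr).append(iv)
    for gene in genes.values():
        for lst in (gene.exons, gene.cds, gene.utr5, gene.utr3):
            lst.sort(key=lambda iv: iv.start)
    return sorted(genes.values(), key=lambda g: (g.interval.seqid, g.interval.start))


def write_gff3(genes: Sequence[GeneModel], path: str | Path,
               source: str = "lncscreen") -> None:
    """Write gene models as GFF3 (one mRNA per gene), deterministic order."""
    lines = ["##gff-version 3"]

    def row(iv: GenomicInterval, ftype: str, attrs: str) -> str:
        return "\t".join([iv.seqid, source, ftype, str(iv.start + 1), str(iv.end),
                          ".", iv.strand, ".", attrs])

    for gene in sorted(genes, key=lambda g: (g.interval.seqid, g.interval.start)):
        gid = gene.gene_id
        mid = f"{gid}.1"
        lines.append(row(gene.interval, "gene", f"ID={gid}"))
        lines.append(row(gene.interval, "mRNA", f"ID={mid};Parent={gid}"))
        for ftype, ivs in (("exon", gene.exons), ("five_prime_UTR", gene.utr5),
                           ("CDS", gene.cds), ("three_prime_UTR", gene.utr3)):
            for iv in sorted(ivs, key=lambda x: x.start):
                lines.append(row(iv, ftype, f"Parent={mid}"))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# BED

def read_bed(path: str | Path) -> list[tuple[GenomicInterval, str]]:
    """Read BED3/BED6 into (interval, name) pairs; BED is already 0-based half-open."""
    out: list[tuple[GenomicInterval, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: BED needs >=3 columns")
            seqid, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else f"feature_{lineno}"
            strand = fields[5] if len(fields) > 5 else "."
            out.append((GenomicInterval(seqid, start, end, strand), name))
    return out


def write_bed(entries: Iterable[tuple[GenomicInterval, str]] | Iterable[GenomicInterval],
              path: str | Path) -> None:
    rows = []
    for entry in entries:
        if isinstance(entry, GenomicInterval):
            iv, name = entry, "."
        else:
            iv, name = entry
        rows.append((iv.seqid, iv.start, iv.end, name, 0, iv.strand))
    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    with open(path, "w") as fh:
        for r in rows:
            fh.write("\t".join(map(str, r)) + "\n")


# ---------------------------------------------------------------------------
# Count matrix

@dataclass
class CountMatrix:
    """Features x samples raw counts with feature lengths; normalized is optional."""

    feature_ids: list[str]
    feature_lengths: np.ndarray
    sample_ids: list[str]
    counts: np.ndarray
    normalized: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.feature_lengths = np.asarray(self.feature_lengths, dtype=float)
        self.counts = np.asarray(self.counts)
        n, m = self.counts.shape
        if len(self.feature_ids) != n or len(self.sample_ids) != m:
            raise ValueError("count matrix dimensions inconsistent with ids")
        if len(self.feature_lengths) != n:
            raise ValueError("feature_lengths length mismatch")
        if np.any(self.feature_lengths <= 0):
            raise ValueError("feature lengths must be > 0")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    def to_frame(self, normalized: bool = False) -> pd.DataFrame:
        data = self.normalized if normalized else self.counts
        if data is None:
            raise ValueError("no normalized values present")
        return pd.DataFrame(data, index=self.feature_ids, columns=self.sample_ids)

    def to_tsv(self, path: str | Path, normalized: bool = False) -> None:
        df = self.to_frame(normalized=normalized).copy()
        df.insert(0, "length", self.feature_lengths.astype(int))
        df.index.name = "feature_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        lengths = df.pop("length").to_numpy(float)
        return cls(list(df.index), lengths, list(df.columns),
                   df.to_numpy(), None)

    def subset(self, feature_ids: Sequence[str]) -> "CountMatrix":
        idx = [self.feature_ids.index(f) for f in feature_ids]
        return CountMatrix(
            [self.feature_ids[i] for i in idx],
            self.feature_lengths[idx],
            list(self.sample_ids),
            self.counts[idx],
            None if self.normalized is None else self.normalized[idx],
        )


# ---------------------------------------------------------------------------
# Interval algebra
#
# All operations group by seqid, sort, and emit sorted disjoint results.
# Strand is preserved where unambiguous and dropped ('.') on merge of
# mixed-strand inputs.

def _by_seqid(ivs: Iterable[GenomicInterval]) -> dict[str, list[GenomicInterval]]:
    out: dict[str, list[GenomicInterval]] = {}
    for iv in ivs:
        out.setdefault(iv.seqid, []).append(iv)
    for lst in out.values():
        lst.sort(key=lambda iv: (iv.start, iv.end))
    return out


def interval_merge(intervals: Iterable[GenomicInterval],
                   max_gap: int = 0) -> list[GenomicInterval]:
    """Union intervals whose gap is <= ``max_gap``.

    With ``max_gap=0`` adjacent half-open intervals ([0,50),[50,80)) merge, the
    bedtools convention.  Output is sorted and disjoint; merging is idempotent.
    """
    result: list[GenomicInterval] = []
    for seqid in sorted(_by_seqid(intervals)):
        group = _by_seqid(intervals)[seqid]
        cur_start, cur_end = group[0].start, group[0].end
        strands = {group[0].strand}
        for iv in group[1:]:
            if iv.start - cur_end <= max_gap:
                cur_end = max(cur_end, iv.end)
                strands.add(iv.strand)
            else:
                result.append(GenomicInterval(
                    seqid, cur_start, cur_end,
                    strands.pop() if len(strands) == 1 else "."))
                cur_start, cur_end, strands = iv.start, iv.end, {iv.strand}
        result.append(GenomicInterval(
            seqid, cur_start, cur_end,
            strands.pop() if len(strands) == 1 else "."))
    return result


def interval_subtract(a: Iterable[GenomicInterval],
                      b: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Maximal disjoint remainder of ``a`` after removing every base in ``b``.

    Ignores strand (positional subtraction).  Result strand is inherited from
    the contributing ``a`` interval.
    """
    b = list(b)
    b_merged = _by_seqid(interval_merge(b, 0)) if b else {}
    out: list[GenomicInterval] = []
    for iv in sorted(a, key=lambda x: (x.seqid, x.start, x.end)):
        cuts = b_merged.get(iv.seqid, [])
        pos = iv.start
        for cut in cuts:
            if cut.end <= pos or cut.start >= iv.end:
                continue
            if cut.start > pos:
                out.append(GenomicInterval(iv.seqid, pos, cut.start, iv.strand))
            pos = max(pos, cut.end)
            if pos >= iv.end:
                break
        if pos < iv.end:
            out.append(GenomicInterval(iv.seqid, pos, iv.end, iv.strand))
    return out


def interval_overlap(a: Sequence[GenomicInterval], b: Sequence[GenomicInterval],
                     stranded: bool = False
                     ) -> list[tuple[GenomicInterval, GenomicInterval]]:
    """All overlapping (a_i, b_j) pairs; '.' matches both strands when stranded."""
    b_by = _by_seqid(b)
    pairs: list[tuple[GenomicInterval, GenomicInterval]] = []
    for iv in a:
        for other in b_by.get(iv.seqid, []):
            if other.start >= iv.end:
                break
            if iv.overlaps(other, stranded=stranded):
                pairs.append((iv, other))
    return pairs


def interval_distance(a: GenomicInterval, b: GenomicInterval) -> int:
    """Gap between nearest ends of ``a`` and ``b``; 0 when overlapping/touching."""
    return a.distance(b)
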