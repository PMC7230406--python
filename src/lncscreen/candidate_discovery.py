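"""Non-coding sequence extraction and conserved alignment-block construction.

The search space is the genome minus coding sequence: intergenic spans plus
genic non-coding space (introns and UTRs).  Conservation is established by a
seed-and-extend local aligner (word seeding, ungapped X-drop extension,
banded gapped refinement) with Karlin-Altschul E-values; the best hit per
(region, species) is kept and hit subsequences are combined into one gapped
alignment block per reference region by progressive star alignment around
the reference row.  Blocks shorter than 50 nt on the reference, or conserved
in fewer than three species including the reference, are discarded.

Externally produced BLAST outfmt-6 tables and multi-FASTA alignments can be
imported in place of the internal aligner.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from ._kernels import nw_align
from .genome_io import (
    FormatError,
    GeneModel,
    GenomicInterval,
    SequenceRecord,
    interval_merge,
    interval_subtract,
)

__all__ = [
    "NoncodingRegion",
    "PairwiseHit",
    "AlignmentBlock",
    "extract_noncoding",
    "pairwise_hits",
    "read_blast_table",
    "best_hit_per_pair",
    "build_blocks",
    "filter_blocks",
    "karlin_lambda",
]

logger = logging.getLogger(__name__)

REFERENCE_SPECIES = "reference"

_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class NoncodingRegion:
    """One extracted non-coding span with its category and + strand sequence."""

    interval: GenomicInterval
    category: str          # intron | utr5 | utr3 | intergenic
    sequence: str

    @property
    def region_id(self) -> str:
        iv = self.interval
        return f"{self.category}:{iv.seqid}:{iv.start}-{iv.end}"


@dataclass
class PairwiseHit:
    """A local alignment hit of a query region against one species' sequences.

    ``query_interval`` is in local coordinates of the query region sequence;
    ``subject_interval`` in forward-strand coordinates of the subject record
    (``strand`` '-' means the match is to the subject's reverse complement).
    """

    query_id: str
    subject_id: str
    species: str
    query_interval: tuple[int, int]
    subject_interval: tuple[int, int]
    strand: str
    score: float
    evalue: float
    identity: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")
        if not (0.0 <= self.identity <= 1.0):
            raise ValueError("identity must be within [0, 1]")


@dataclass
class AlignmentBlock:
    """Gapped multi-species alignment anchored on one reference region."""

    block_id: str
    reference_interval: GenomicInterval
    category: str
    rows: list[tuple[str, str]] = field(default_factory=list)  # (species, gapped)
    mean_pairwise_identity: float = 0.0

    @property
    def n_species(self) -> int:
        return len({sp for sp, _ in self.rows})

    @property
    def reference_row(self) -> str:
        for sp, seq in self.rows:
            if sp == REFERENCE_SPECIES:
                return seq
        raise KeyError("block lacks a reference row")

    @property
    def reference_span(self) -> int:
        return self.reference_interval.length


# ---------------------------------------------------------------------------
# extraction

def extract_noncoding(genome: list[SequenceRecord], genes: list[GeneModel]
                      ) -> list[NoncodingRegion]:
    """Partition the genome minus CDS into labelled non-coding regions.

    Intergenic space is the genome minus the union of gene spans (uncapped);
    genic non-coding space is each gene span minus its CDS, labelled intron /
    utr5 / utr3 from the gene model (positionally relative to the CDS when
    the model carries no explicit UTR features).  Overlapping genes are
    resolved by the union of gene spans with a logged warning.
    """
    regions: list[NoncodingRegion] = []
    all_cds = [iv for g in genes for iv in g.cds]
    gene_spans = [g.interval for g in genes]
    merged_genes = interval_merge(gene_spans, 0) if gene_spans else []
    if len(merged_genes) < len(gene_spans):
        logger.warning("overlapping genes resolved by union of gene spans")

    for rec in genome:
        chrom_iv = GenomicInterval(rec.id, 0, len(rec.sequence))
        inter = interval_subtract([chrom_iv],
                                  [g for g in merged_genes if g.seqid == rec.id])
        for iv in inter:
            regions.append(NoncodingRegion(
                GenomicInterval(iv.seqid, iv.start, iv.end),
                "intergenic", rec.sequence[iv.start:iv.end]))

    seq_by_id = {rec.id: rec.sequence for rec in genome}
    for gene in genes:
        pieces = interval_subtract([gene.interval], all_cds)
        cds_sorted = sorted(gene.cds, key=lambda iv: iv.start)
        if not cds_sorted:
            continue
        first_cds, last_cds = cds_sorted[0].start, cds_sorted[-1].end
        for iv in pieces:
            category = None
            for utr in gene.utr5:
                if iv.overlaps(utr):
                    category = "utr5"
                    break
            if category is None:
                for utr in gene.utr3:
                    if iv.overlaps(utr):
                        category = "utr3"
                        break
            if category is None:
                if iv.end <= first_cds:
                    category = "utr5" if gene.strand != "-" else "utr3"
                elif iv.start >= last_cds:
                    category = "utr3" if gene.strand != "-" else "utr5"
                else:
                    category = "intron"
            seq = seq_by_id[iv.seqid][iv.start:iv.end]
            regions.append(NoncodingRegion(
                GenomicInterval(iv.seqid, iv.start, iv.end), category, seq))
    regions.sort(key=lambda r: (r.interval.seqid, r.interval.start, r.interval.end))
    return regions


# ---------------------------------------------------------------------------
# seed-and-extend search with Karlin-Altschul E-values

def karlin_lambda(match: float, mismatch: float, p: float = 0.25) -> float:
    """Solve sum_ij p_i p_j exp(lambda * s_ij) = 1 for uniform base frequencies."""

    # 16 base pairs: 4 matches, 12 mismatches, each with probability p^2
    def g(lam: float) -> float:
        return (4 * math.exp(lam * match)
                + 12 * math.exp(lam * mismatch)) * p * p - 1

    return float(brentq(g, 1e-6, 10.0))


_KA_K = 0.3   # conservative Karlin-Altschul K for the default scheme


def _xdrop_extend(q: str, s: str, qi: int, si: int, word: int,
                  match: int, mismatch: int, xdrop: int
                  ) -> tuple[int, int, int, float]:
    """Ungapped X-drop extension around a seeded word match.

    Returns (qstart, qend, score, identity) with qend exclusive; the subject
    coordinates follow from the shared diagonal.
    """
    score = word * match
    best = score
    # right extension
    qe, se = qi + word, si + word
    best_qe = qe
    while qe < len(q) and se < len(s):
        score += match if q[qe] == s[se] else mismatch
        qe += 1
        se += 1
        if score > best:
            best, best_qe = score, qe
        elif best - score > xdrop:
            break
    score = best
    qs, ss = qi, si
    best_qs = qs
    while qs > 0 and ss > 0:
        score += match if q[qs - 1] == s[ss - 1] else mismatch
        qs -= 1
        ss -= 1
        if score > best:
            best, best_qs = score, qs
        elif best - score > xdrop:
            break
    qs, qe = best_qs, best_qe
    n_match = sum(1 for a, b in zip(q[qs:qe], s[si - (qi - qs): si - (qi - qs) + (qe - qs)])
                  if a == b)
    identity = n_match / (qe - qs) if qe > qs else 0.0
    return qs, qe, best, identity


def pairwise_hits(query_regions: list[NoncodingRegion],
                  subjects: list[SequenceRecord],
                  species: str,
                  max_evalue: float = 0.01,
                  word_size: int = 11,
                  match: int = 1,
                  mismatch: int = -2,
                  xdrop: int = 20,
                  both_strands: bool = True) -> list[PairwiseHit]:
    """Seed-and-extend local search of every query region against one species.

    Hits with Karlin-Altschul E-value E = K*m*n*exp(-lambda*S) below
    ``max_evalue`` are returned.  The aligner seeds on exact ``word_size``
    words, extends ungapped with an X-drop, and deduplicates per diagonal.
    """
    lam = karlin_lambda(match, mismatch)
    total_subject = sum(len(s.sequence) for s in subjects)
    hits: list[PairwiseHit] = []
    for subj in subjects:
        variants = [("+", subj.sequence)]
        if both_strands:
            variants.append(("-", _revcomp(subj.sequence)))
        for strand, sseq in variants:
            index: dict[str, list[int]] = {}
            for i in range(0, len(sseq) - word_size + 1):
                index.setdefault(sseq[i:i + word_size], []).append(i)
            for region in query_regions:
                qseq = region.sequence.upper()
                diag_done: dict[int, int] = {}
                for qi in range(0, len(qseq) - word_size + 1):
                    positions = index.get(qseq[qi:qi + word_size])
                    if not positions:
                        continue
                    for si in positions:
                        diag = qi - si
                        if diag_done.get(diag, -1) >= qi:
                            continue
                        qs, qe, score, ident = _xdrop_extend(
                            qseq, sseq, qi, si, word_size, match, mismatch, xdrop)
                        diag_done[diag] = qe
                        evalue = _KA_K * len(qseq) * total_subject * math.exp(
                            -lam * score)
                        if evalue >= max_evalue:
                            continue
                        ss = qs - diag
                        se = qe - diag
                        if strand == "-":
                            s0 = len(sseq) - se
                            s1 = len(sseq) - ss
                        else:
                            s0, s1 = ss, se
                        hits.append(PairwiseHit(
                            query_id=region.region_id, subject_id=subj.id,
                            species=species, query_interval=(qs, qe),
                            subject_interval=(s0, s1), strand=strand,
                            score=float(score), evalue=float(evalue),
                            identity=float(ident)))
    return hits


def read_blast_table(path: str | Path, species: str,
                     max_evalue: float = 0.01) -> list[PairwiseHit]:
    """Import a BLAST tabular (outfmt 6, 12 columns) hit table.

    Columns: qseqid sseqid pident length mismatch gapopen qstart qend sstart
    send evalue bitscore; coordinates are converted from 1-based inclusive to
    0-based half-open, and sstart > send marks a minus-strand hit.
    """
    hits: list[PairwiseHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise FormatError(f"{path}:{lineno}: expected 12 columns")
            try:
                qid, sid = fields[0], fields[1]
                pident = float(fields[2])
                qstart, qend = int(fields[6]), int(fields[7])
                sstart, send = int(fields[8]), int(fields[9])
                evalue, bitscore = float(fields[10]), float(fields[11])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: malformed field ({exc})") from exc
            strand = "+" if send >= sstart else "-"
            if strand == "-":
                sstart, send = send, sstart
            if evalue < max_evalue:
                hits.append(PairwiseHit(
                    query_id=qid, subject_id=sid, species=species,
                    query_interval=(qstart - 1, qend),
                    subject_interval=(sstart - 1, send), strand=strand,
                    score=bitscore, evalue=evalue, identity=pident / 100.0))
    return hits


def best_hit_per_pair(hits: list[PairwiseHit]) -> list[PairwiseHit]:
    """Keep the single best hit per (query region, species).

    Best = lowest E-value; ties broken by highest score, then leftmost
    subject start.  Idempotent.
    """
    best: dict[tuple[str, str], PairwiseHit] = {}
    for hit in hits:
        key = (hit.query_id, hit.species)
        cur = best.get(key)
        if cur is None:
            best[key] = hit
            continue
        a = (hit.evalue, -hit.score, hit.subject_interval[0])
        b = (cur.evalue, -cur.score, cur.subject_interval[0])
        if a < b:
            best[key] = hit
    return sorted(best.values(),
                  key=lambda h: (h.query_id, h.species, h.subject_interval[0]))


# ---------------------------------------------------------------------------
# progressive star alignment

_ENC = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3, "N": 4}


def _encode_dna(seq: str) -> np.ndarray:
    return np.array([_ENC.get(c, 4) for c in seq.upper()], dtype=np.int8)


def _pairwise_global(x: str, y: str, match: float = 1.0, mismatch: float = -2.0,
                     gap: float = -3.0) -> tuple[str, str]:
    """Global alignment of two sequences (linear gap cost), numba DP."""
    _score, P = nw_align(_encode_dna(x), _encode_dna(y), match, mismatch, gap)
    i, j = len(x), len(y)
    ax, ay = [], []
    while i > 0 or j > 0:
        p = P[i, j]
        if p == 0 and i > 0 and j > 0:
            ax.append(x[i - 1])
            ay.append(y[j - 1])
            i -= 1
            j -= 1
        elif p == 1 and i > 0:
            ax.append(x[i - 1])
            ay.append("-")
            i -= 1
        else:
            ax.append("-")
            ay.append(y[j - 1])
            j -= 1
    return "".join(reversed(ax)), "".join(reversed(ay))


def _star_align(ref: str, others: list[tuple[str, str]]
                ) -> list[tuple[str, str]]:
    """Star MSA anchored on the reference sequence.

    ``others`` are (label, sequence); rows are added in decreasing ungapped
    identity to the reference (the guide order) and merged through the
    reference gap map.  Returns [(REFERENCE_SPECIES, row), (label, row), ...].
    """
    if not others:
        return [(REFERENCE_SPECIES, ref)]

    def quick_identity(seq: str) -> float:
        n = min(len(seq), len(ref))
        if n == 0:
            return 0.0
        return sum(1 for a, b in zip(ref, seq) if a == b) / n

    ordered = sorted(others, key=lambda t: -quick_identity(t[1]))
    n = len(ref)
    # per-row: (label, list over slots 0..n of inserted strings, aligned char per ref pos)
    aligned_rows = []
    master_ins = [0] * (n + 1)
    for label, seq in ordered:
        aref, arow = _pairwise_global(ref, seq)
        ins: list[str] = [""] * (n + 1)
        chars: list[str] = []
        rpos = 0
        for cref, crow in zip(aref, arow):
            if cref == "-":
                ins[rpos] += crow
            else:
                chars.append(crow)
                rpos += 1
        for k in range(n + 1):
            master_ins[k] = max(master_ins[k], len(ins[k]))
        aligned_rows.append((label, ins, chars))

    def build(ins: list[str], chars: list[str]) -> str:
        out = []
        for k in range(n):
            out.append(ins[k] + "-" * (master_ins[k] - len(ins[k])))
            out.append(chars[k])
        out.append(ins[n] + "-" * (master_ins[n] - len(ins[n])))
        return "".join(out)

    ref_row = build([""] * (n + 1), list(ref))
    rows = [(REFERENCE_SPECIES, ref_row)]
    for label, ins, chars in aligned_rows:
        rows.append((label, build(ins, chars)))
    return rows


def mean_pairwise_identity(rows: list[str]) -> float:
    """Mean identity over all row pairs, excluding gap-gap columns.

    A gap aligned to a base counts as a mismatch.
    """
    if len(rows) < 2:
        return 1.0
    total, count = 0.0, 0
    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            cols = [(a, b) for a, b in zip(rows[i], rows[j])
                    if not (a == "-" and b == "-")]
            if not cols:
                continue
            ident = sum(1 for a, b in cols if a == b and a != "-") / len(cols)
            total += ident
            count += 1
    return total / count if count else 1.0


def build_blocks(best_hits: list[PairwiseHit],
                 query_regions: list[NoncodingRegion],
                 subjects_by_species: dict[str, list[SequenceRecord]]
                 ) -> list[AlignmentBlock]:
    """One alignment block per reference region with at least one hit.

    The reference row is the region subsequence spanned by the union of that
    region's best-hit query intervals; each species row is its best-hit
    subject subsequence (reverse-complemented for minus-strand hits); rows
    are combined by progressive star alignment.  Single-species blocks are
    emitted (later flagged ineligible by :func:`filter_blocks`).
    """
    regions_by_id = {r.region_id: r for r in query_regions}
    seq_lookup = {
        (species, rec.id): rec.sequence
        for species, recs in subjects_by_species.items()
        for rec in recs
    }
    grouped: dict[str, list[PairwiseHit]] = {}
    for hit in best_hits:
        grouped.setdefault(hit.query_id, []).append(hit)
    blocks: list[AlignmentBlock] = []
    for qid in sorted(grouped):
        region = regions_by_id[qid]
        hits = grouped[qid]
        qstart = min(h.query_interval[0] for h in hits)
        qend = max(h.query_interval[1] for h in hits)
        ref_seq = region.sequence[qstart:qend]
        rows_in: list[tuple[str, str]] = []
        for hit in sorted(hits, key=lambda h: h.species):
            subj = seq_lookup[(hit.species, hit.subject_id)]
            s0, s1 = hit.subject_interval
            sub = subj[s0:s1]
            if hit.strand == "-":
                sub = _revcomp(sub)
            rows_in.append((hit.species, sub))
        rows = _star_align(ref_seq, rows_in)
        iv = region.interval
        ref_iv = GenomicInterval(iv.seqid, iv.start + qstart, iv.start + qend)
        blocks.append(AlignmentBlock(
            block_id=f"block:{qid}:{qstart}-{qend}",
            reference_interval=ref_iv,
            category=region.category,
            rows=rows,
            mean_pairwise_identity=mean_pairwise_identity([r for _s, r in rows]),
        ))
    return blocks


def filter_blocks(blocks: list[AlignmentBlock], min_length: int = 50,
                  min_species: int = 3) -> list[AlignmentBlock]:
    """Keep blocks with reference span >= min_length conserved in
    >= min_species distinct species including the reference."""
    out = []
    for block in blocks:
        species = {sp for sp, _ in block.rows}
        if REFERENCE_SPECIES not in species:
            continue
        if block.reference_span < min_length:
            continue
        if len(species) < min_species:
            continue
        out.append(block)
    return out
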