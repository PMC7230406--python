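"""Selection of novel lncRNAs from predicted loci and biotype assignment.

A locus becomes a lncRNA candidate when it is longer than 200 nt (strict),
expression supported, unmatched against known ncRNA catalogs, and shows no
coding potential (score < 0, no imported protein hit with E < 0.01).
Retained loci are assigned exactly one biotype:

1. lncNAT -- overlaps a gene on the opposite strand with strand-specific
   expression support (takes precedence);
2. sense-intronic -- genic locus with zero CDS overlap;
3. lincRNA -- intergenic locus more than 500 nt (strict) from both flanking
   genes;
4. otherwise excluded (e.g. intergenic within 500 nt, or CDS overlap).

The internal coding-potential scorer combines ORF fraction with a hexamer
log-likelihood ratio; external CPC/UniProt/Pfam tables can be imported and
take precedence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome_io import GeneModel, GenomicInterval
from .structure_screen import NcrnaLocus
from .verification import VerificationFlags

__all__ = [
    "CodingPotential",
    "LncrnaRecord",
    "HexamerModel",
    "coding_potential",
    "classify_biotype",
    "select_novel_lncrnas",
    "read_protein_hits",
]

# internal coding score: a*log(orf_fraction) + b*hexamer_bias + c.
# Calibrated on the synthetic generator's coding vs dinucleotide-shuffled
# noncoding panels (>=95% separation each way); frozen here.  The hexamer
# bias is frame-aware (best reading frame), which is what separates coding
# sequence from its shuffles: shuffling preserves stop-codon scarcity, so
# ORF length alone cannot.
CODING_A = 1.0
CODING_B = 4.0
CODING_C = 0.0

_STOPS = {"TAA", "TAG", "TGA"}
_COMP = str.maketrans("ACGTN", "TGCAN")


@dataclass
class CodingPotential:
    """Coding-potential evidence for one sequence (negative => non-coding)."""

    score: float
    longest_orf: int
    hexamer_bias: float
    external_score: float | None = None
    low_confidence: bool = False

    @property
    def effective_score(self) -> float:
        return self.external_score if self.external_score is not None else self.score


@dataclass
class LncrnaRecord:
    """One retained lncRNA locus with its biotype and supporting evidence."""

    locus_id: str
    biotype: str                   # lincRNA | lncNAT | sense-intronic | excluded
    length: int
    supported: bool
    unmatched: bool
    coding_score: float
    distance_to_nearest_gene: int | None = None
    antisense_overlap_gene: str | None = None
    strand_specific_support: bool = False
    exclusion_reason: str | None = None


class HexamerModel:
    """Frame-aware hexamer log-likelihood model (coding vs non-coding).

    Coding sequence is counted in-frame (step 3, the codon-pair statistic);
    non-coding background in every frame.  A query is scored as the best
    reading frame's mean log2 likelihood ratio.
    """

    K = 6

    def __init__(self, llr: dict[str, float]):
        self.llr = llr

    @classmethod
    def train(cls, coding: list[str], noncoding: list[str],
              pseudocount: float = 1.0) -> "HexamerModel":
        def counts(seqs: list[str], step: int) -> dict[str, float]:
            c: dict[str, float] = {}
            for seq in seqs:
                seq = seq.upper().replace("U", "T")
                for i in range(0, len(seq) - cls.K + 1, step):
                    word = seq[i:i + cls.K]
                    if "N" in word:
                        continue
                    c[word] = c.get(word, 0.0) + 1.0
            return c

        cod = counts(coding, 3)
        non = counts(noncoding, 1)
        words = set(cod) | set(non)
        total_c = sum(cod.values()) + pseudocount * len(words)
        total_n = sum(non.values()) + pseudocount * len(words)
        llr = {
            w: np.log2((cod.get(w, 0.0) + pseudocount) / total_c)
            - np.log2((non.get(w, 0.0) + pseudocount) / total_n)
            for w in words
        }
        return cls(llr)

    @classmethod
    def from_annotation(cls, genome: list, genes: list[GeneModel]
                        ) -> "HexamerModel":
        """Train from an annotated genome: CDS vs intergenic/intron sequence."""
        seq_by_id = {r.id: r.sequence for r in genome}
        coding, noncoding = [], []
        for gene in genes:
            chrom = seq_by_id[gene.interval.seqid]
            cds = "".join(chrom[iv.start:iv.end]
                          for iv in sorted(gene.cds, key=lambda i: i.start))
            if gene.strand == "-":
                cds = cds.translate(_COMP)[::-1]
            coding.append(cds)
            for intron in gene.introns:
                noncoding.append(chrom[intron.start:intron.end])
        # add intergenic sample between genes
        for rec in genome:
            spans = sorted((g.interval.start, g.interval.end) for g in genes
                           if g.interval.seqid == rec.id)
            pos = 0
            for s, e in spans:
                if s > pos:
                    noncoding.append(rec.sequence[pos:s])
                pos = max(pos, e)
            if pos < len(rec.sequence):
                noncoding.append(rec.sequence[pos:])
        return cls.train(coding, noncoding)

    def score(self, sequence: str) -> float:
        """Best-frame mean log2 likelihood ratio (positive => coding-like)."""
        seq = sequence.upper().replace("U", "T")
        best = None
        for frame in range(3):
            vals = [self.llr.get(seq[i:i + self.K], 0.0)
                    for i in range(frame, len(seq) - self.K + 1, 3)]
            if vals:
                m = float(np.mean(vals))
                best = m if best is None else max(best, m)
        return best if best is not None else 0.0


def _longest_orf(sequence: str) -> int:
    """Longest ATG..stop open reading frame, both strands, in nucleotides."""
    seq = sequence.upper().replace("U", "T")
    best = 0
    for s in (seq, seq.translate(_COMP)[::-1]):
        for frame in range(3):
            start = None
            for i in range(frame, len(s) - 2, 3):
                codon = s[i:i + 3]
                if start is None:
                    if codon == "ATG":
                        start = i
                elif codon in _STOPS:
                    best = max(best, i + 3 - start)
                    start = None
            if start is not None:
                best = max(best, len(s) - (len(s) - start) % 3 - start)
    return best


def coding_potential(sequence: str, hexamer_model: HexamerModel,
                     external_score: float | None = None,
                     protein_hit_evalue: float | None = None,
                     max_hit_evalue: float = 0.01) -> CodingPotential:
    """Score coding potential of a sequence (negative => non-coding).

    ``score = a*log(longest_orf/length) + b*hexamer_bias + c`` with frozen
    calibrated constants.  An imported CPC-style score takes precedence when
    present, and any imported protein hit with E < 0.01 forces a coding
    verdict regardless of the internal score.  Sequences shorter than 60 nt
    are scored but flagged low-confidence.
    """
    length = len(sequence)
    orf = _longest_orf(sequence)
    hexamer = hexamer_model.score(sequence)
    orf_frac = max(orf, 1) / max(length, 1)
    score = CODING_A * float(np.log(orf_frac)) + CODING_B * hexamer + CODING_C
    cp = CodingPotential(score=score, longest_orf=orf, hexamer_bias=hexamer,
                         external_score=external_score,
                         low_confidence=length < 60)
    if protein_hit_evalue is not None and protein_hit_evalue < max_hit_evalue:
        forced = abs(cp.effective_score) if cp.effective_score != 0 else 1.0
        cp.score = forced
        cp.external_score = forced
    return cp


def read_protein_hits(path: str | Path, max_evalue: float = 0.01
                      ) -> dict[str, float]:
    """Import UniProt/Pfam hit TSV (id, evalue); best E-value per locus."""
    df = pd.read_csv(path, sep="\t", header=None, names=["locus_id", "evalue"],
                     comment="#")
    out: dict[str, float] = {}
    for _, row in df.iterrows():
        e = float(row["evalue"])
        lid = str(row["locus_id"])
        if lid not in out or e < out[lid]:
            out[lid] = e
    return {k: v for k, v in out.items() if v < max_evalue}


# ---------------------------------------------------------------------------
# biotype

def classify_biotype(locus: NcrnaLocus, genes: list[GeneModel],
                     flags: VerificationFlags,
                     min_gene_distance: int = 500
                     ) -> tuple[str, dict]:
    """Assign lncNAT / sense-intronic / lincRNA / excluded to one locus.

    Decision order: antisense gene overlap with strand-specific support wins;
    then genic with zero CDS overlap; then intergenic farther than
    ``min_gene_distance`` (strict) from both flanking genes.  Distances are
    measured to gene spans, not CDS.
    """
    iv = locus.interval
    evidence: dict = {}
    same_chrom = [g for g in genes if g.interval.seqid == iv.seqid]
    overlapping = [g for g in same_chrom if g.interval.overlaps(iv)]
    cds_overlap = any(iv.overlaps(c) for g in overlapping for c in g.cds)
    evidence["cds_overlap"] = cds_overlap

    # (1) lncNAT: antisense overlap + stranded support on the antisense strand
    for gene in overlapping:
        anti = "-" if gene.strand == "+" else "+"
        if gene.strand in ("+", "-") and flags.stranded_support.get(anti, False):
            evidence["antisense_overlap_gene"] = gene.gene_id
            evidence["strand_specific_support"] = True
            return "lncNAT", evidence

    # (2) sense-intronic: genic, zero CDS overlap
    if overlapping:
        if not cds_overlap:
            return "sense-intronic", evidence
        return "excluded", {**evidence, "reason": "cds_overlap"}

    # (3) lincRNA: intergenic, strictly >500 nt from both flanking genes
    distances = [iv.distance(g.interval) for g in same_chrom]
    nearest = min(distances) if distances else None
    evidence["distance_to_nearest_gene"] = nearest
    if nearest is None or nearest > min_gene_distance:
        return "lincRNA", evidence
    return "excluded", {**evidence, "reason": "gene_within_500nt"}


def select_novel_lncrnas(loci: list[NcrnaLocus],
                         flags_by_id: dict[str, VerificationFlags],
                         genes: list[GeneModel],
                         coding_by_id: dict[str, CodingPotential],
                         min_length: int = 200,
                         min_gene_distance: int = 500
                         ) -> tuple[list[LncrnaRecord], list[LncrnaRecord]]:
    """Apply the novel-lncRNA filter cascade and classify biotypes.

    Filter order (first failure recorded per excluded locus): length strictly
    greater than ``min_length``; expression supported; unmatched against
    known ncRNAs; coding potential < 0; then biotype assignment.  Returns
    (retained records, exclusion log).
    """
    kept: list[LncrnaRecord] = []
    excluded: list[LncrnaRecord] = []
    for locus in loci:
        flags = flags_by_id[locus.locus_id]
        cp = coding_by_id[locus.locus_id]
        rec = LncrnaRecord(
            locus_id=locus.locus_id,
            biotype="excluded",
            length=locus.interval.length,
            supported=flags.supported,
            unmatched=not flags.known,
            coding_score=cp.effective_score,
        )
        if locus.interval.length <= min_length:
            rec.exclusion_reason = "length_not_over_200nt"
        elif not flags.supported:
            rec.exclusion_reason = "no_expression_support"
        elif flags.known:
            rec.exclusion_reason = "matches_known_ncrna"
        elif cp.effective_score >= 0:
            rec.exclusion_reason = "coding_potential"
        else:
            biotype, evidence = classify_biotype(
                locus, genes, flags, min_gene_distance=min_gene_distance)
            rec.distance_to_nearest_gene = evidence.get("distance_to_nearest_gene")
            rec.antisense_overlap_gene = evidence.get("antisense_overlap_gene")
            rec.strand_specific_support = evidence.get("strand_specific_support",
                                                       False)
            if biotype == "excluded":
                rec.exclusion_reason = evidence.get("reason", "biotype")
            else:
                rec.biotype = biotype
        if rec.biotype == "excluded":
            excluded.append(rec)
        else:
            kept.append(rec)
    return kept, excluded


def records_to_frame(records: list[LncrnaRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "locus_id": r.locus_id, "biotype": r.biotype, "length": r.length,
            "supported": int(r.supported), "unmatched": int(r.unmatched),
            "coding_score": r.coding_score,
            "distance_to_nearest_gene": (
                "" if r.distance_to_nearest_gene is None
                else r.distance_to_nearest_gene),
            "antisense_overlap_gene": r.antisense_overlap_gene or "",
            "strand_specific_support": int(r.strand_specific_support),
            "exclusion_reason": r.exclusion_reason or "",
        })
    return pd.DataFrame(rows)


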