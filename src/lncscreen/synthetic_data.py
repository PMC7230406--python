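"""Synthetic genomes with planted truth for end-to-end pipeline validation.

The generator emulates the data regime the discovery pipeline assumes without
any download: a multi-gene genome with introns/UTRs/intergenic spacers,
orthologous sequences at controlled divergence in which planted structured
elements accumulate compensatory (covariation-preserving) substitutions,
negative-binomial count matrices with planted log2 fold changes, per-base
read-span coverage tracks, planted miRNA binding sites and lncRNA--mRNA
binding cassettes, and a truth table recording everything that was planted.

Planted structured ncRNAs are stem-loops (>=60% of bases paired) flanked by
unstructured sequence; decoys are dinucleotide-shuffled versions of such
constructs (same composition, no structure).  Orthologous copies of planted
and decoy regions are emitted per comparator species; the rest of the genome
is species-specific, so only the planted/decoy neighbourhoods are
discoverable as conserved blocks -- the regime in which a comparative screen
operates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_io import (
    CountMatrix,
    GeneModel,
    GenomicInterval,
    SequenceRecord,
    write_bed,
    write_fasta,
    write_gff3,
)
from .thermo import dinucleotide_shuffle

__all__ = [
    "SynthConfig",
    "TruthRecord",
    "TruthTable",
    "SizingError",
    "SyntheticDataset",
    "generate_genome",
    "generate_orthologs",
    "ortholog_regions",
    "simulate_counts",
    "simulate_coverage",
    "generate_mirnas",
    "plant_binding_cassettes",
    "generate_gene2go",
    "generate_all",
]

_BASES = np.array(list("ACGT"))
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
_WC_PAIRS = [("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")]
CONDITIONS = ("cold", "drought")


class SizingError(ValueError):
    """Requested elements do not fit the genome / host sequence."""


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic genome.

    Lengths are nucleotides; ``ortholog_divergence`` is the per-site
    substitution rate per comparator species; ``nb_dispersion`` is the
    negative-binomial dispersion alpha in Var = mu + alpha mu^2.
    """

    genome_length: int = 100_000
    n_genes: int = 20
    exons_per_gene: tuple[int, int] = (2, 4)
    utr_lengths: tuple[int, int] = (100, 300)
    intron_lengths: tuple[int, int] = (200, 800)
    intergenic_lengths: tuple[int, int] = (500, 3000)
    n_planted_ncrnas: int = 20
    n_decoys: int = 10
    planted_lengths: tuple[int, int] = (220, 300)
    species: tuple[str, ...] = ("ortho_a", "ortho_b", "ortho_c")
    ortholog_divergence: float | Mapping[str, float] = 0.1
    covariation_fraction: float = 1.0
    n_datasets: int = 8
    n_stranded_datasets: int = 2
    depth_mean: float = 100.0
    nb_dispersion: float = 0.1
    planted_log2fc: float = 4.0
    n_replicates: int = 3
    n_mirnas: int = 5
    n_chromosomes: int = 1
    seed: int = 7

    def __post_init__(self) -> None:
        for name in ("genome_length", "n_genes", "n_datasets", "n_replicates"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("exons_per_gene", "utr_lengths", "intron_lengths",
                     "intergenic_lengths", "planted_lengths"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name} must be a positive (lo, hi) range")
        divs = (self.ortholog_divergence.values()
                if isinstance(self.ortholog_divergence, Mapping)
                else [self.ortholog_divergence])
        if any(not (0.0 <= d <= 1.0) for d in divs):
            raise ValueError("ortholog_divergence must be within [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if not (0.0 <= self.covariation_fraction <= 1.0):
            raise ValueError("covariation_fraction must be within [0, 1]")
        if len(self.species) < 2:
            raise ValueError("need >= 2 comparator species")

    def divergence_for(self, species: str) -> float:
        if isinstance(self.ortholog_divergence, Mapping):
            return float(self.ortholog_divergence[species])
        return float(self.ortholog_divergence)


@dataclass
class TruthRecord:
    """One planted feature: structured ncRNA, decoy span, or coding gene."""

    planted_id: str
    interval: GenomicInterval
    cls: str                        # structured-ncRNA | decoy | coding-gene
    intended_biotype: str | None = None   # lincRNA | lncNAT | sense-intronic
    de_condition: str = "none"            # none | cold | drought | both
    planted_log2fc: float = 0.0
    expressed: bool = False
    # stem arms of the planted hairpin (left, right), genomic coordinates
    stem: tuple[GenomicInterval, GenomicInterval] | None = None
    # (mirna_id, site interval, n_mismatches)
    mirna_sites: list[tuple[str, GenomicInterval, int]] = field(default_factory=list)
    # (partner feature id, cassette interval on this feature)
    binding_cassette: tuple[str, GenomicInterval] | None = None

    def is_de_in(self, condition: str) -> bool:
        return self.de_condition == "both" or self.de_condition == condition


class TruthTable:
    """Container for planted truth records with TSV round-trip."""

    def __init__(self, records: Sequence[TruthRecord]):
        self.records = list(records)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def by_id(self, planted_id: str) -> TruthRecord:
        for rec in self.records:
            if rec.planted_id == planted_id:
                return rec
        raise KeyError(planted_id)

    def of_class(self, cls: str) -> list[TruthRecord]:
        return [r for r in self.records if r.cls == cls]

    @property
    def structured(self) -> list[TruthRecord]:
        return self.of_class("structured-ncRNA")

    @property
    def decoys(self) -> list[TruthRecord]:
        return self.of_class("decoy")

    @property
    def genes(self) -> list[TruthRecord]:
        return self.of_class("coding-gene")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            sites = ";".join(
                f"{mid}:{iv.start}-{iv.end}:{k}" for mid, iv, k in r.mirna_sites)
            cassette = ""
            if r.binding_cassette is not None:
                pid, iv = r.binding_cassette
                cassette = f"{pid}:{iv.start}-{iv.end}"
            stem = ""
            if r.stem is not None:
                left, right = r.stem
                stem = f"{left.start}-{left.end}|{right.start}-{right.end}"
            rows.append({
                "planted_id": r.planted_id,
                "seqid": r.interval.seqid,
                "start": r.interval.start,
                "end": r.interval.end,
                "strand": r.interval.strand,
                "class": r.cls,
                "intended_biotype": r.intended_biotype or "",
                "de_condition": r.de_condition,
                "planted_log2fc": r.planted_log2fc,
                "expressed": int(r.expressed),
                "stem": stem,
                "mirna_sites": sites,
                "binding_cassette": cassette,
            })
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TruthTable":
        df = pd.read_csv(path, sep="\t", keep_default_na=False)
        records = []
        for _, row in df.iterrows():
            seqid = str(row["seqid"])
            sites = []
            if row["mirna_sites"]:
                for token in str(row["mirna_sites"]).split(";"):
                    mid, span, k = token.rsplit(":", 2)
                    s, e = span.split("-")
                    sites.append((mid, GenomicInterval(seqid, int(s), int(e)), int(k)))
            cassette = None
            if row["binding_cassette"]:
                pid, span = str(row["binding_cassette"]).rsplit(":", 1)
                s, e = span.split("-")
                cassette = (pid, GenomicInterval(seqid, int(s), int(e)))
            stem = None
            if row["stem"]:
                left, right = str(row["stem"]).split("|")
                ls, le = left.split("-")
                rs, re_ = right.split("-")
                stem = (GenomicInterval(seqid, int(ls), int(le)),
                        GenomicInterval(seqid, int(rs), int(re_)))
            records.append(TruthRecord(
                planted_id=str(row["planted_id"]),
                interval=GenomicInterval(seqid, int(row["start"]), int(row["end"]),
                                         str(row["strand"])),
                cls=str(row["class"]),
                intended_biotype=str(row["intended_biotype"]) or None,
                de_condition=str(row["de_condition"]),
                planted_log2fc=float(row["planted_log2fc"]),
                expressed=bool(int(row["expressed"])),
                stem=stem,
                mirna_sites=sites,
                binding_cassette=cassette,
            ))
        return cls(records)


# ---------------------------------------------------------------------------
# genome construction helpers

_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = sorted(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOPS
)
# mild GC3/codon-usage bias so coding hexamer statistics differ from noncoding
_CODON_WEIGHTS = np.array(
    [1.0 + (0.8 if c[2] in "GC" else 0.0) + (0.4 if c[0] in "AG" else 0.0)
     for c in _SENSE_CODONS])
_CODON_WEIGHTS = _CODON_WEIGHTS / _CODON_WEIGHTS.sum()


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, length)])


def _coding_seq(rng: np.random.Generator, n_codons: int) -> str:
    idx = rng.choice(len(_SENSE_CODONS), size=n_codons, p=_CODON_WEIGHTS)
    return "".join(_SENSE_CODONS[i] for i in idx)


def _revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def _stemloop(rng: np.random.Generator, length: int
              ) -> tuple[str, int, int, int]:
    """Random hairpin construct: returns (seq, stem_len, left_arm_off, right_arm_off).

    Layout: [left flank][left arm][loop=4][right arm][right flank] with
    2*stem >= 0.6*length, flanks split 1:3 so the right flank can host
    planted interaction sites.
    """
    stem = int(np.ceil(0.3 * length))
    loop = 4
    flank_total = length - 2 * stem - loop
    if flank_total < 0:
        raise SizingError(f"planted length {length} too short for a 60%-paired stem")
    left_flank = flank_total // 4
    right_flank = flank_total - left_flank
    arm = _random_seq(rng, stem)
    seq = (_random_seq(rng, left_flank) + arm + _random_seq(rng, loop)
           + _revcomp(arm) + _random_seq(rng, right_flank))
    left_off = left_flank
    right_off = left_flank + stem + loop
    return seq, stem, left_off, right_off


def _assign_conditions(rng: np.random.Generator, n: int,
                       fractions=(0.3, 0.3, 0.15)) -> list[str]:
    """Deterministically assign none/cold/drought/both labels."""
    n_cold = int(round(fractions[0] * n))
    n_drought = int(round(fractions[1] * n))
    n_both = int(round(fractions[2] * n))
    labels = (["cold"] * n_cold + ["drought"] * n_drought + ["both"] * n_both
              + ["none"] * (n - n_cold - n_drought - n_both))
    rng.shuffle(labels)
    return labels


def generate_genome(config: SynthConfig
                    ) -> tuple[list[SequenceRecord], list[GeneModel], TruthTable]:
    """Build the reference genome, gene annotation and planted truth.

    Genes carry CDS / 5' and 3' UTRs / introns; structured ncRNAs (stem-loops
    with >=60% paired bases) are planted in introns and intergenic space
    according to their intended biotype; decoys are shuffled-composition
    spans.  Fixed seed gives byte-identical outputs.

    Raises :class:`SizingError` when the requested elements exceed the genome
    length or no placement slot is available.
    """
    rng = np.random.default_rng([config.seed, 1])
    n_chrom = config.n_chromosomes
    chrom_names = [f"chr{i + 1}" for i in range(n_chrom)]
    per_chrom = [config.genome_length // n_chrom] * n_chrom
    per_chrom[-1] += config.genome_length - sum(per_chrom)

    genes: list[GeneModel] = []
    chrom_seqs: dict[str, bytearray] = {}
    gene_counter = 0
    for ci, (chrom, clen) in enumerate(zip(chrom_names, per_chrom)):
        parts: list[str] = []
        pos = 0
        n_genes_here = config.n_genes // n_chrom + (
            1 if ci < config.n_genes % n_chrom else 0)
        for _g in range(n_genes_here):
            spacer = int(rng.integers(*config.intergenic_lengths))
            strand = "+" if rng.random() < 0.5 else "-"
            n_ex = int(rng.integers(config.exons_per_gene[0],
                                    config.exons_per_gene[1] + 1))
            utr5 = int(rng.integers(*config.utr_lengths))
            utr3 = int(rng.integers(*config.utr_lengths))
            cds_lens = [int(rng.integers(40, 120)) * 3 for _ in range(n_ex)]
            intron_lens = [int(rng.integers(*config.intron_lengths))
                           for _ in range(n_ex - 1)]
            total_codons = sum(cds_lens) // 3
            cds_seq = "ATG" + _coding_seq(rng, total_codons - 2) + "TAA"
            # transcript-orientation blocks
            blocks: list[tuple[str, str]] = [("utr5", _random_seq(rng, utr5))]
            off = 0
            for k, cl in enumerate(cds_lens):
                blocks.append(("cds", cds_seq[off:off + cl]))
                off += cl
                if k < n_ex - 1:
                    blocks.append(("intron", _random_seq(rng, intron_lens[k])))
            blocks.append(("utr3", _random_seq(rng, utr3)))
            if strand == "-":
                blocks = [(label, _revcomp(seq)) for label, seq in reversed(blocks)]
            gene_len = sum(len(s) for _l, s in blocks)
            gene_start = pos + spacer
            if gene_start + gene_len > clen:
                raise SizingError(
                    f"requested gene/intergenic elements exceed chromosome "
                    f"{chrom} length {clen}")
            parts.append(_random_seq(rng, spacer))
            gid = f"gene_{gene_counter:04d}"
            gene_counter += 1
            cds_iv, utr5_iv, utr3_iv = [], [], []
            bpos = gene_start
            for label, seq in blocks:
                iv = GenomicInterval(chrom, bpos, bpos + len(seq), strand)
                if label == "cds":
                    cds_iv.append(iv)
                elif label == "utr5":
                    utr5_iv.append(iv)
                elif label == "utr3":
                    utr3_iv.append(iv)
                parts.append(seq)
                bpos += len(seq)
            # exons = maximal non-intron runs
            exonic = sorted(cds_iv + utr5_iv + utr3_iv, key=lambda iv: iv.start)
            exons: list[GenomicInterval] = []
            for iv in exonic:
                if exons and exons[-1].end == iv.start:
                    exons[-1] = GenomicInterval(chrom, exons[-1].start, iv.end, strand)
                else:
                    exons.append(iv)
            genes.append(GeneModel(
                gid, GenomicInterval(chrom, gene_start, bpos, strand),
                exons=exons, cds=cds_iv, utr5=utr5_iv, utr3=utr3_iv))
            pos = bpos
        if pos > clen:
            raise SizingError(f"elements exceed chromosome {chrom} length")
        parts.append(_random_seq(rng, clen - pos))
        chrom_seqs[chrom] = bytearray("".join(parts), "ascii")

    truth_records = _plant_ncrnas(config, rng, chrom_seqs, genes)
    # coding-gene truth records (DE assignment for downstream stages)
    gene_conditions = _assign_conditions(rng, len(genes))
    for gene, cond in zip(genes, gene_conditions):
        lfc = 0.0
        if cond != "none":
            lfc = config.planted_log2fc * (1 if rng.random() < 0.5 else -1)
        truth_records.append(TruthRecord(
            planted_id=gene.gene_id, interval=gene.interval, cls="coding-gene",
            de_condition=cond, planted_log2fc=lfc, expressed=True))

    records = [SequenceRecord(chrom, chrom_seqs[chrom].decode("ascii"))
               for chrom in chrom_names]
    return records, genes, TruthTable(truth_records)


def _plant_ncrnas(config: SynthConfig, rng: np.random.Generator,
                  chrom_seqs: dict[str, bytearray],
                  genes: list[GeneModel]) -> list[TruthRecord]:
    """Place structured ncRNAs and decoys into introns/intergenic space."""
    margin = 40
    lincrna_clearance = 550   # > the 500 nt rule with room for locus-edge slack
    # candidate slots
    intron_slots: list[tuple[GenomicInterval, GeneModel]] = []
    for gene in genes:
        for intron in gene.introns:
            intron_slots.append((intron, gene))
    intergenic_slots: list[GenomicInterval] = []
    by_chrom: dict[str, list[GeneModel]] = {}
    for gene in genes:
        by_chrom.setdefault(gene.interval.seqid, []).append(gene)
    for chrom, seq in chrom_seqs.items():
        gs = sorted(by_chrom.get(chrom, []), key=lambda g: g.interval.start)
        bounds = [0] + [g.interval.end for g in gs]
        ends = [g.interval.start for g in gs] + [len(seq)]
        for s, e in zip(bounds, ends):
            if e - s > 0:
                intergenic_slots.append(GenomicInterval(chrom, s, e))

    n_linc = int(round(config.n_planted_ncrnas * 0.4))
    n_nat = int(round(config.n_planted_ncrnas * 0.25))
    n_si = config.n_planted_ncrnas - n_linc - n_nat
    biotypes = ["lincRNA"] * n_linc + ["sense-intronic"] * n_si + ["lncNAT"] * n_nat
    conditions = _assign_conditions(rng, config.n_planted_ncrnas)

    records: list[TruthRecord] = []
    # one planted element per non-coding slot: keeps one conserved island per
    # searchable region, so the best-hit-per-region rule is unambiguous
    used_intergenic: set[int] = set()
    used_introns: set[int] = set()

    def place_in(slot: GenomicInterval, length: int, clearance: int
                 ) -> GenomicInterval | None:
        lo = slot.start + clearance
        hi = slot.end - clearance - length
        if hi < lo:
            return None
        start = int(rng.integers(lo, hi + 1))
        return GenomicInterval(slot.seqid, start, start + length)

    def place_intergenic(length: int, clearance: int) -> GenomicInterval | None:
        order = rng.permutation(len(intergenic_slots))
        for si in order:
            si = int(si)
            if si in used_intergenic:
                continue
            iv = place_in(intergenic_slots[si], length, clearance)
            if iv is not None:
                used_intergenic.add(si)
                return iv
        return None

    def place_intronic(length: int, clearance: int) -> GenomicInterval | None:
        order = rng.permutation(len(intron_slots))
        for si in order:
            si = int(si)
            if si in used_introns:
                continue
            iv = place_in(intron_slots[si][0], length, clearance)
            if iv is not None:
                used_introns.add(si)
                return iv
        return None

    for idx in range(config.n_planted_ncrnas):
        biotype = biotypes[idx]
        length = int(rng.integers(*config.planted_lengths))
        seq, stem, left_off, right_off = _stemloop(rng, length)
        if biotype == "lincRNA":
            iv = place_intergenic(length, lincrna_clearance)
        else:
            iv = place_intronic(length, margin)
        if iv is None:
            raise SizingError(
                f"no placement slot for planted ncRNA #{idx} (biotype {biotype}, "
                f"length {length}): enlarge intergenic/intron ranges or genome")
        chrom_seqs[iv.seqid][iv.start:iv.end] = seq.encode("ascii")
        cond = conditions[idx]
        lfc = 0.0
        if cond != "none":
            lfc = config.planted_log2fc * (1 if rng.random() < 0.5 else -1)
        stem_ivs = (
            GenomicInterval(iv.seqid, iv.start + left_off, iv.start + left_off + stem),
            GenomicInterval(iv.seqid, iv.start + right_off, iv.start + right_off + stem),
        )
        records.append(TruthRecord(
            planted_id=f"nc{idx:04d}", interval=iv, cls="structured-ncRNA",
            intended_biotype=biotype, de_condition=cond, planted_log2fc=lfc,
            expressed=True, stem=stem_ivs))

    for d in range(config.n_decoys):
        length = int(rng.integers(*config.planted_lengths))
        seq, _stem, _lo, _ro = _stemloop(rng, length)
        seq = dinucleotide_shuffle(seq, rng)
        iv = place_intergenic(length, margin)
        if iv is None:
            iv = place_intronic(length, margin)
        if iv is None:
            raise SizingError(f"no placement slot for decoy #{d}")
        chrom_seqs[iv.seqid][iv.start:iv.end] = seq.encode("ascii")
        records.append(TruthRecord(
            planted_id=f"decoy{d:04d}", interval=iv, cls="decoy",
            expressed=False))
    return records


# ---------------------------------------------------------------------------
# interaction planting

def plant_binding_cassettes(records: list[SequenceRecord],
                            genes: list[GeneModel], truth: TruthTable,
                            config: SynthConfig, n_cassettes: int = 3,
                            cassette_length: int = 40
                            ) -> list[SequenceRecord]:
    """Plant perfect-complement cassettes between DE lncRNAs and DE gene mRNAs.

    The cassette goes into the right flank of a planted structured ncRNA; its
    reverse complement (in transcript orientation) into the 3' UTR of a gene
    differentially expressed in the same condition.  Truth records on both
    sides are annotated with the cassette interval and partner id.
    """
    rng = np.random.default_rng([config.seed, 2])
    seqs = {r.id: bytearray(r.sequence, "ascii") for r in records}
    gene_by_id = {g.gene_id: g for g in genes}
    candidates = _interaction_pairs(truth, rng)
    planted = 0
    for lnc_rec, gene_rec in candidates:
        if planted >= n_cassettes:
            break
        if lnc_rec.binding_cassette is not None or lnc_rec.mirna_sites:
            continue
        if gene_rec.binding_cassette is not None or gene_rec.mirna_sites:
            continue
        gene = gene_by_id[gene_rec.planted_id]
        host_iv = _flank_slot(lnc_rec, cassette_length)
        utr_iv = _utr3_slot(gene, cassette_length, rng)
        if host_iv is None or utr_iv is None:
            continue
        cassette = _random_seq(rng, cassette_length)
        seqs[host_iv.seqid][host_iv.start:host_iv.end] = cassette.encode("ascii")
        mrna_insert = _revcomp(cassette)
        genomic_insert = (mrna_insert if gene.strand == "+"
                          else _revcomp(mrna_insert))
        seqs[utr_iv.seqid][utr_iv.start:utr_iv.end] = genomic_insert.encode("ascii")
        lnc_rec.binding_cassette = (gene_rec.planted_id, host_iv)
        gene_rec.binding_cassette = (lnc_rec.planted_id, utr_iv)
        planted += 1
    return [SequenceRecord(r.id, seqs[r.id].decode("ascii")) for r in records]


def generate_mirnas(records: list[SequenceRecord], genes: list[GeneModel],
                    truth: TruthTable, config: SynthConfig,
                    mirna_length: int = 21, n_triples: int = 3,
                    plant_negative_control: bool = True
                    ) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Generate miRNAs and plant target-mimicry sites into the genome.

    Each mimicry triple places the reverse complement of one miRNA, with
    exactly 0--2 substitutions, into the flank of a DE structured ncRNA and
    into the 3' UTR of a DE gene in the same condition; site coordinates and
    mismatch counts are recorded in the truth table.  A 3-mismatch negative
    control site is planted when requested.  Returns (miRNA records, updated
    genome records).

    Raises :class:`SizingError` if a miRNA cannot fit its host flank.
    """
    rng = np.random.default_rng([config.seed, 3])
    mirnas = [SequenceRecord(f"mir{m:03d}", _random_seq(rng, mirna_length))
              for m in range(config.n_mirnas)]
    seqs = {r.id: bytearray(r.sequence, "ascii") for r in records}
    gene_by_id = {g.gene_id: g for g in genes}
    if mirna_length > min(config.planted_lengths):
        raise SizingError("miRNA longer than host planted sequences")

    def plant_site(host_iv: GenomicInterval, mirna: SequenceRecord,
                   n_mismatches: int, transcript_strand: str) -> None:
        site = _revcomp(mirna.sequence.replace("U", "T"))
        site = _mismatch_site(site, mirna.sequence, n_mismatches, rng)
        genomic = site if transcript_strand == "+" else _revcomp(site)
        seqs[host_iv.seqid][host_iv.start:host_iv.end] = genomic.encode("ascii")

    candidates = _interaction_pairs(truth, rng)
    planted = 0
    mirna_idx = 0
    for lnc_rec, gene_rec in candidates:
        if planted >= n_triples or mirna_idx >= len(mirnas):
            break
        if lnc_rec.binding_cassette is not None or lnc_rec.mirna_sites:
            continue
        if gene_rec.binding_cassette is not None or gene_rec.mirna_sites:
            continue
        gene = gene_by_id[gene_rec.planted_id]
        host_iv = _flank_slot(lnc_rec, mirna_length)
        utr_iv = _utr3_slot(gene, mirna_length, rng)
        if host_iv is None or utr_iv is None:
            continue
        mir = mirnas[mirna_idx]
        k_lnc = planted % 3          # 0, 1, 2 mismatches across triples
        k_gene = (planted + 2) % 3
        plant_site(host_iv, mir, k_lnc, "+")
        plant_site(utr_iv, mir, k_gene, gene.strand)
        lnc_rec.mirna_sites.append((mir.id, host_iv, k_lnc))
        gene_rec.mirna_sites.append((mir.id, utr_iv, k_gene))
        planted += 1
        mirna_idx += 1
    if plant_negative_control and mirna_idx < len(mirnas):
        for lnc_rec, gene_rec in candidates:
            if lnc_rec.binding_cassette is not None or lnc_rec.mirna_sites:
                continue
            host_iv = _flank_slot(lnc_rec, mirna_length)
            if host_iv is None:
                continue
            mir = mirnas[mirna_idx]
            plant_site(host_iv, mir, 3, "+")
            lnc_rec.mirna_sites.append((mir.id, host_iv, 3))
            break
    new_records = [SequenceRecord(r.id, seqs[r.id].decode("ascii"))
                   for r in records]
    return mirnas, new_records


def _interaction_pairs(truth: TruthTable, rng: np.random.Generator
                       ) -> list[tuple[TruthRecord, TruthRecord]]:
    """DE structured-ncRNA x DE gene pairs sharing a condition, shuffled."""
    pairs = []
    for lnc in truth.structured:
        if lnc.de_condition == "none":
            continue
        for gene in truth.genes:
            if gene.de_condition == "none":
                continue
            shared = ({"cold", "drought"} if lnc.de_condition == "both"
                      else {lnc.de_condition})
            gshared = ({"cold", "drought"} if gene.de_condition == "both"
                       else {gene.de_condition})
            if shared & gshared:
                pairs.append((lnc, gene))
    idx = rng.permutation(len(pairs))
    return [pairs[i] for i in idx]


def _flank_slot(rec: TruthRecord, length: int) -> GenomicInterval | None:
    """A slot in the right flank of a planted stem-loop, clear of the stem."""
    if rec.stem is None:
        return None
    right_arm = rec.stem[1]
    lo = right_arm.end + 2
    hi = rec.interval.end - 2 - length
    if hi < lo:
        return None
    start = (lo + hi) // 2
    return GenomicInterval(rec.interval.seqid, start, start + length)


def _utr3_slot(gene: GeneModel, length: int, rng: np.random.Generator
               ) -> GenomicInterval | None:
    for utr in gene.utr3:
        if utr.length >= length + 4:
            start = utr.start + 2
            return GenomicInterval(utr.seqid, start, start + length)
    return None


def _mismatch_site(site: str, mirna: str, n_mismatches: int,
                   rng: np.random.Generator) -> str:
    """Introduce exactly n substitutions that break pairing (no G:U rescue).

    ``site`` is the reverse complement of the miRNA in DNA letters; position t
    of the site pairs with miRNA position len-1-t.
    """
    site_l = list(site)
    if n_mismatches == 0:
        return site
    positions = rng.choice(len(site_l), size=n_mismatches, replace=False)
    for t in positions:
        mir_base = mirna.replace("U", "T")[len(site_l) - 1 - t]
        # bases that neither WC-pair nor GU-pair with mir_base
        forbidden = {_COMP[mir_base]}
        if mir_base == "T":
            forbidden.add("G")
        if mir_base == "G":
            forbidden.add("T")
        choices = [b for b in "ACGT" if b not in forbidden and b != site_l[t]]
        site_l[t] = choices[int(rng.integers(len(choices)))]
    return "".join(site_l)


# ---------------------------------------------------------------------------
# orthologs

def ortholog_regions(truth: TruthTable, pad: int = 25,
                     genome_lengths: Mapping[str, int] | None = None
                     ) -> list[tuple[str, GenomicInterval]]:
    """Conserved-region set for ortholog simulation: planted + decoy spans, padded."""
    regions = []
    for rec in truth:
        if rec.cls == "coding-gene":
            continue
        iv = rec.interval
        start = max(0, iv.start - pad)
        end = iv.end + pad
        if genome_lengths is not None:
            end = min(end, genome_lengths[iv.seqid])
        regions.append((rec.planted_id, GenomicInterval(iv.seqid, start, end)))
    return regions


def generate_orthologs(reference: list[SequenceRecord],
                       regions: Sequence[tuple[str, GenomicInterval]],
                       config: SynthConfig,
                       truth: TruthTable | None = None
                       ) -> dict[str, list[SequenceRecord]]:
    """Per-species mutated copies of the given reference regions.

    Point substitutions occur at the species' divergence rate.  Within
    planted stems (when ``truth`` is given), a ``covariation_fraction`` of
    substitutions are compensatory: the pairing partner is co-mutated to a
    different Watson-Crick pair, preserving complementarity.  Decoys and
    non-stem positions mutate without compensation.

    Raises ``ValueError`` for regions outside the reference coordinates.
    """
    ref_by_id = {r.id: r.sequence for r in reference}
    stem_partner: dict[tuple[str, int], int] = {}
    if truth is not None:
        for rec in truth.structured:
            if rec.stem is None:
                continue
            left, right = rec.stem
            s = left.length
            for t in range(s):
                a = left.start + t
                b = right.start + s - 1 - t
                stem_partner[(left.seqid, a)] = b
                stem_partner[(left.seqid, b)] = a
    out: dict[str, list[SequenceRecord]] = {}
    for sp_i, species in enumerate(config.species):
        d = config.divergence_for(species)
        rng = np.random.default_rng([config.seed, 10 + sp_i])
        recs: list[SequenceRecord] = []
        for region_id, iv in regions:
            if iv.seqid not in ref_by_id:
                raise ValueError(f"region {region_id} on unknown seqid {iv.seqid}")
            full = ref_by_id[iv.seqid]
            if iv.end > len(full):
                raise ValueError(
                    f"region {region_id} [{iv.start},{iv.end}) outside reference "
                    f"{iv.seqid} of length {len(full)}")
            seq = list(full[iv.start:iv.end])
            flagged = np.flatnonzero(rng.random(len(seq)) < d)
            handled: set[int] = set()
            for p in flagged:
                p = int(p)
                if p in handled:
                    continue
                gpos = iv.start + p
                partner = stem_partner.get((iv.seqid, gpos))
                if partner is not None and iv.start <= partner < iv.end and (
                        rng.random() < config.covariation_fraction):
                    q = partner - iv.start
                    current = (seq[p], seq[q])
                    options = [pr for pr in _WC_PAIRS if pr != current]
                    new = options[int(rng.integers(len(options)))]
                    seq[p], seq[q] = new
                    handled.add(p)
                    handled.add(q)
                else:
                    alts = [b for b in "ACGT" if b != seq[p]]
                    seq[p] = alts[int(rng.integers(3))]
                    handled.add(p)
            recs.append(SequenceRecord(f"{species}|{region_id}", "".join(seq)))
        out[species] = recs
    return out


# ---------------------------------------------------------------------------
# expression

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float
             ) -> np.ndarray:
    """Gamma-Poisson NB sampler, stable down to the Poisson limit alpha->0."""
    mean = np.asarray(mean, dtype=float)
    shape = 1.0 / alpha
    lam = rng.gamma(shape, scale=np.maximum(mean, 0.0) * alpha)
    return rng.poisson(lam)


def simulate_counts(truth: TruthTable, genes: list[GeneModel],
                    config: SynthConfig,
                    features: Sequence[tuple[str, GenomicInterval]] | None = None
                    ) -> dict[str, CountMatrix]:
    """Negative-binomial count matrices for control / cold / drought.

    Per-feature baseline mean is ``depth_mean * length/1000``; features whose
    truth entry is differentially expressed in a condition have the mean
    multiplied by ``2**planted_log2fc`` there.  When ``features`` is given
    (e.g. predicted loci), each feature inherits the expression state of the
    truth record it overlaps most.
    """
    if features is None:
        features = ([(r.planted_id, r.interval) for r in truth
                     if r.cls != "coding-gene"]
                    + [(g.gene_id, g.interval) for g in genes])
    truth_recs = list(truth)

    by_id = {rec.planted_id: rec for rec in truth_recs}

    def state_for(fid: str, iv: GenomicInterval) -> TruthRecord | None:
        # exact id match first (truth features and genes); otherwise planted
        # elements take precedence over the host gene span, because an
        # intronic locus expresses the planted transcript, not the gene
        if fid in by_id:
            return by_id[fid]
        best, best_ov = None, 0
        for rec in truth_recs:
            if rec.cls == "coding-gene":
                continue
            ov = iv.overlap_length(rec.interval)
            if ov > best_ov:
                best, best_ov = rec, ov
        if best is not None:
            return best
        for rec in truth_recs:
            if rec.cls != "coding-gene":
                continue
            ov = iv.overlap_length(rec.interval)
            if ov > best_ov:
                best, best_ov = rec, ov
        return best

    ids = [fid for fid, _ in features]
    lengths = np.array([iv.length for _f, iv in features], dtype=float)
    base = config.depth_mean * lengths / 1000.0
    mult = {c: np.ones(len(features)) for c in CONDITIONS}
    expressed = np.ones(len(features), dtype=bool)
    for i, (fid, iv) in enumerate(features):
        rec = state_for(fid, iv)
        if rec is None:
            continue
        if not rec.expressed:
            expressed[i] = False
        for cond in CONDITIONS:
            if rec.is_de_in(cond) and rec.planted_log2fc != 0.0:
                mult[cond][i] = 2.0 ** rec.planted_log2fc
    base = np.where(expressed, base, base * 0.02)

    rng = np.random.default_rng([config.seed, 20])
    out: dict[str, CountMatrix] = {}
    for cond in ("control",) + CONDITIONS:
        cond_mult = np.ones(len(features)) if cond == "control" else mult[cond]
        cols = []
        for rep in range(config.n_replicates):
            cols.append(_nb_draw(rng, base * cond_mult, config.nb_dispersion))
        counts = np.stack(cols, axis=1)
        samples = [f"{cond}_{r + 1}" for r in range(config.n_replicates)]
        out[cond] = CountMatrix(list(ids), lengths.copy(), samples, counts)
    return out


def simulate_coverage(truth: TruthTable, genes: list[GeneModel],
                      config: SynthConfig):
    """Read-span coverage tracks per dataset (import deferred to avoid cycle)."""
    from .verification import CoverageTrack

    gene_by_id = {g.gene_id: g for g in genes}
    rng = np.random.default_rng([config.seed, 30])
    tracks = []
    for d in range(config.n_datasets):
        stranded = d < config.n_stranded_datasets
        spans: dict[str, list[tuple[int, int, str]]] = {}
        for rec in truth:
            if rec.cls == "coding-gene":
                continue
            # the emitted transcript spans the planted element plus margin, so
            # predicted loci (conserved cassette + alignment overshoot) are
            # fully covered by reads of a genuinely expressed locus
            iv = GenomicInterval(
                rec.interval.seqid,
                max(0, rec.interval.start - 50),
                rec.interval.end + 50,
            )
            if rec.expressed and (d == 0 or rng.random() < 0.7):
                strand = "."
                if stranded:
                    strand = "+"
                    if rec.intended_biotype == "lncNAT":
                        # antisense of the host gene
                        host = next((g for g in genes
                                     if g.interval.overlaps(iv)), None)
                        if host is not None:
                            strand = "-" if host.strand == "+" else "+"
                    elif rec.intended_biotype == "sense-intronic":
                        host = next((g for g in genes
                                     if g.interval.overlaps(iv)), None)
                        if host is not None:
                            strand = host.strand
                for s, e in _covering_spans(iv, 12, rng):
                    spans.setdefault(iv.seqid, []).append((s, e, strand))
            elif not rec.expressed and rng.random() < 0.3:
                # sparse partial spans over the left half only
                half = iv.start + max(20, iv.length // 2)
                for _k in range(3):
                    s = int(rng.integers(iv.start, max(iv.start + 1, half - 30)))
                    e = min(half, s + 60)
                    if e > s:
                        spans.setdefault(iv.seqid, []).append((s, e, "."))
        for chrom_spans in spans.values():
            chrom_spans.sort()
        tracks.append(CoverageTrack(
            dataset_id=f"dataset_{d:02d}",
            stranded=stranded,
            spans=spans,
        ))
    _ = gene_by_id
    return tracks


def _covering_spans(iv: GenomicInterval, n: int, rng: np.random.Generator
                    ) -> list[tuple[int, int]]:
    """n overlapping spans whose union covers [start, end) completely."""
    L = iv.length
    sl = max(50, int(0.6 * L))
    out = []
    for i in range(n):
        if n > 1:
            s = iv.start + int(round(i * (L - sl) / (n - 1)))
        else:
            s = iv.start
        ext_l = int(rng.integers(0, 20))
        ext_r = int(rng.integers(0, 20))
        start = max(0, min(s, iv.end - sl) - ext_l)
        end = max(s + sl, iv.start + sl) + ext_r
        out.append((start, max(end, start + 1)))
    # guarantee exact breadth
    out[0] = (min(out[0][0], iv.start), out[0][1])
    out[-1] = (out[-1][0], max(out[-1][1], iv.end))
    return out


# ---------------------------------------------------------------------------
# GO annotation

GO_STRESS_COLD = "GO:0009409"      # response to cold
GO_STRESS_DROUGHT = "GO:0009414"   # response to water deprivation
_GENERIC_GO = [f"GO:{7000000 + i:07d}" for i in range(15)]


def generate_gene2go(genes: list[GeneModel], truth: TruthTable,
                     config: SynthConfig) -> pd.DataFrame:
    """Gene -> GO map: DE genes are enriched for matching stress terms."""
    rng = np.random.default_rng([config.seed, 40])
    de_by_id = {r.planted_id: r.de_condition for r in truth.genes}
    rows = []
    for gene in genes:
        cond = de_by_id.get(gene.gene_id, "none")
        terms = set()
        if cond in ("cold", "both") and rng.random() < 0.9:
            terms.add(GO_STRESS_COLD)
        if cond in ("drought", "both") and rng.random() < 0.9:
            terms.add(GO_STRESS_DROUGHT)
        if cond == "none":
            if rng.random() < 0.08:
                terms.add(GO_STRESS_COLD)
            if rng.random() < 0.08:
                terms.add(GO_STRESS_DROUGHT)
        n_generic = int(rng.integers(2, 5))
        for gi in rng.choice(len(_GENERIC_GO), size=n_generic, replace=False):
            terms.add(_GENERIC_GO[gi])
        for term in sorted(terms):
            rows.append({"gene_id": gene.gene_id, "go_id": term,
                         "namespace": "biological_process"})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# one-call bundle

@dataclass
class SyntheticDataset:
    """Everything the pipeline consumes, generated from one config."""

    config: SynthConfig
    genome: list[SequenceRecord]
    genes: list[GeneModel]
    truth: TruthTable
    mirnas: list[SequenceRecord]
    orthologs: dict[str, list[SequenceRecord]]
    counts: dict[str, CountMatrix]
    coverage: list
    gene2go: pd.DataFrame

    def chromosome(self, seqid: str) -> str:
        for r in self.genome:
            if r.id == seqid:
                return r.sequence
        raise KeyError(seqid)

    def write(self, outdir: str | Path) -> None:
        """Emit the full file tree (FASTA/GFF3/BED/TSV), deterministic bytes."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.genome, outdir / "genome.fasta")
        write_gff3(self.genes, outdir / "annotation.gff3")
        write_bed([(r.interval, r.planted_id) for r in self.truth
                   if r.cls != "coding-gene"], outdir / "truth.bed")
        self.truth.to_tsv(outdir / "truth.tsv")
        write_fasta(self.mirnas, outdir / "mirnas.fasta")
        for species, recs in sorted(self.orthologs.items()):
            write_fasta(recs, outdir / f"ortholog_{species}.fasta")
        for cond, cm in sorted(self.counts.items()):
            cm.to_tsv(outdir / f"counts_{cond}.tsv")
        for track in self.coverage:
            track.to_tsv(outdir / f"coverage_{track.dataset_id}.tsv")
        self.gene2go.to_csv(outdir / "gene2go.tsv", sep="\t", index=False)


def generate_all(config: SynthConfig) -> SyntheticDataset:
    """Run the full generator: genome, interactions, orthologs, expression."""
    genome, genes, truth = generate_genome(config)
    genome = plant_binding_cassettes(genome, genes, truth, config)
    mirnas, genome = generate_mirnas(genome, genes, truth, config)
    lengths = {r.id: len(r.sequence) for r in genome}
    regions = ortholog_regions(truth, genome_lengths=lengths)
    orthologs = generate_orthologs(genome, regions, config, truth)
    counts = simulate_counts(truth, genes, config)
    coverage = simulate_coverage(truth, genes, config)
    gene2go = generate_gene2go(genes, truth, config)
    return SyntheticDataset(config, genome, genes, truth, mirnas, orthologs,
                            counts, coverage, gene2go)


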