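"""Non-coding extraction, seed-and-extend search, block building/filtering."""

from __future__ import annotations

import numpy as np
import pytest

from lncscreen.candidate_discovery import (
    AlignmentBlock,
    NoncodingRegion,
    PairwiseHit,
    REFERENCE_SPECIES,
    best_hit_per_pair,
    build_blocks,
    extract_noncoding,
    filter_blocks,
    karlin_lambda,
    mean_pairwise_identity,
    pairwise_hits,
    read_blast_table,
)
from lncscreen.genome_io import GeneModel, GenomicInterval, SequenceRecord

from _oracles import bitmap


def _toy_genome():
    rng = np.random.default_rng(0)
    seq = "".join(rng.choice(list("ACGT"), 1000))
    genome = [SequenceRecord("chr1", seq)]
    gene = GeneModel(
        "g1", GenomicInterval("chr1", 100, 400, "+"),
        exons=[GenomicInterval("chr1", 100, 400, "+")],
        cds=[GenomicInterval("chr1", 150, 350, "+")],
    )
    return genome, [gene]


class TestExtraction:
    def test_toy_partition(self):
        genome, genes = _toy_genome()
        regions = extract_noncoding(genome, genes)
        by_cat = {}
        for r in regions:
            by_cat.setdefault(r.category, []).append((r.interval.start,
                                                      r.interval.end))
        assert sorted(by_cat["intergenic"]) == [(0, 100), (400, 1000)]
        genic = sorted(x for c in ("utr5", "utr3", "intron")
                       for x in by_cat.get(c, []))
        assert genic == [(100, 150), (350, 400)]

    def test_zero_genes_single_region(self):
        genome, _ = _toy_genome()
        regions = extract_noncoding(genome, [])
        assert len(regions) == 1
        assert (regions[0].interval.start, regions[0].interval.end) == (0, 1000)
        assert regions[0].category == "intergenic"

    def test_no_cds_overlap(self, dataset):
        regions = extract_noncoding(dataset.genome, dataset.genes)
        cds = [c for g in dataset.genes for c in g.cds]
        for r in regions:
            assert not any(r.interval.overlaps(c) for c in cds)

    def test_noncoding_plus_cds_covers_genome_once(self, dataset):
        regions = extract_noncoding(dataset.genome, dataset.genes)
        L = len(dataset.genome[0].sequence)
        cover = np.zeros(L, dtype=int)
        for r in regions:
            cover[r.interval.start:r.interval.end] += 1
        for g in dataset.genes:
            for c in g.cds:
                cover[c.start:c.end] += 1
        assert (cover == 1).all()

    def test_sequences_match_intervals(self, dataset):
        chrom = dataset.genome[0].sequence
        for r in extract_noncoding(dataset.genome, dataset.genes)[:10]:
            assert r.sequence == chrom[r.interval.start:r.interval.end]


class TestSearch:
    def test_self_hit(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), 500))
        region = NoncodingRegion(GenomicInterval("chr1", 0, 500), "intergenic",
                                 seq)
        hits = pairwise_hits([region], [SequenceRecord("s", seq)], "sp")
        assert hits
        best = min(hits, key=lambda h: h.evalue)
        assert best.identity == 1.0
        assert best.evalue < 1e-50
        assert best.query_interval == (0, 500)

    def test_evalue_calibration_on_random_sequences(self):
        # random 60-nt query vs random 10 kb subject: hits at E < 0.01 are
        # rare (the E-value is calibrated, if conservatively)
        rng = np.random.default_rng(2)
        subject = SequenceRecord("s", "".join(rng.choice(list("ACGT"), 10_000)))
        n_hit = 0
        for t in range(100):
            q = "".join(rng.choice(list("ACGT"), 60))
            region = NoncodingRegion(GenomicInterval("chr1", 0, 60),
                                     "intergenic", q)
            if pairwise_hits([region], [subject], "sp"):
                n_hit += 1
        assert n_hit <= 5

    def test_planted_region_recovered(self):
        rng = np.random.default_rng(3)
        planted = "".join(rng.choice(list("ACGT"), 100))
        qseq = ("".join(rng.choice(list("ACGT"), 300)) + planted
                + "".join(rng.choice(list("ACGT"), 300)))
        # subject at divergence 0.1
        mutated = list(planted)
        for i in range(len(mutated)):
            if rng.random() < 0.1:
                mutated[i] = rng.choice([b for b in "ACGT" if b != mutated[i]])
        subject = SequenceRecord("s", "".join(mutated))
        region = NoncodingRegion(GenomicInterval("chr1", 0, len(qseq)),
                                 "intergenic", qseq)
        hits = pairwise_hits([region], [subject], "sp")
        assert hits
        best = min(hits, key=lambda h: h.evalue)
        qs, qe = best.query_interval
        overlap = min(qe, 400) - max(qs, 300)
        assert overlap >= 80   # >= 80% of the planted 100 nt

    def test_minus_strand_hit(self):
        rng = np.random.default_rng(4)
        seq = "".join(rng.choice(list("ACGT"), 300))
        comp = str.maketrans("ACGT", "TGCA")
        region = NoncodingRegion(GenomicInterval("chr1", 0, 300), "intergenic",
                                 seq)
        hits = pairwise_hits([region],
                             [SequenceRecord("s", seq.translate(comp)[::-1])],
                             "sp")
        assert hits and min(hits, key=lambda h: h.evalue).strand == "-"

    def test_karlin_lambda_solves_identity(self):
        lam = karlin_lambda(1, -2)
        total = (4 * np.exp(lam * 1) + 12 * np.exp(lam * -2)) / 16
        assert total == pytest.approx(1.0, abs=1e-9)


class TestBestHit:
    def _hit(self, qid, species, evalue, score=10.0, sstart=0):
        return PairwiseHit(qid, "s", species, (0, 50), (sstart, sstart + 50),
                           "+", score, evalue, 0.9)

    def test_lowest_evalue_kept(self):
        hits = [self._hit("q", "a", 1e-3), self._hit("q", "a", 1e-5)]
        [best] = best_hit_per_pair(hits)
        assert best.evalue == 1e-5

    def test_tie_break_leftmost_subject(self):
        hits = [self._hit("q", "a", 1e-4, score=20, sstart=100),
                self._hit("q", "a", 1e-4, score=20, sstart=10)]
        [best] = best_hit_per_pair(hits)
        assert best.subject_interval[0] == 10

    def test_idempotent_and_empty(self):
        hits = [self._hit("q", "a", 1e-4), self._hit("q", "b", 1e-3)]
        once = best_hit_per_pair(hits)
        assert best_hit_per_pair(once) == once
        assert best_hit_per_pair([]) == []


class TestBlocks:
    def test_identical_triplet_gapless(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), 120))
        region = NoncodingRegion(GenomicInterval("chr1", 0, 120), "intron", seq)
        subjects = {sp: [SequenceRecord(f"{sp}|r", seq)] for sp in ("a", "b")}
        hits = []
        for sp in subjects:
            hits += pairwise_hits([region], subjects[sp], sp)
        blocks = build_blocks(best_hit_per_pair(hits), [region], subjects)
        assert len(blocks) == 1
        block = blocks[0]
        assert block.mean_pairwise_identity == pytest.approx(1.0)
        assert all("-" not in row for _sp, row in block.rows)

    def test_mean_pairwise_identity_hand_example(self):
        # rows {ACGT, ACGT, AGGT}: pairs (1.0, 0.75, 0.75) -> 5/6
        assert mean_pairwise_identity(["ACGT", "ACGT", "AGGT"]) == \
            pytest.approx(5 / 6)

    def test_single_species_block_flagged_ineligible(self):
        block = AlignmentBlock(
            "b", GenomicInterval("chr1", 0, 100), "intron",
            rows=[(REFERENCE_SPECIES, "A" * 100)])
        assert filter_blocks([block], min_species=3) == []

    def test_filter_thresholds(self):
        def mk(span, species):
            rows = [(sp, "A" * span) for sp in species]
            return AlignmentBlock("b", GenomicInterval("c", 0, span), "intron",
                                  rows=rows)
        ok = mk(50, [REFERENCE_SPECIES, "a", "b"])
        too_short = mk(49, [REFERENCE_SPECIES, "a", "b"])
        no_ref = mk(80, ["a", "b", "c"])
        two_species = mk(80, [REFERENCE_SPECIES, "a"])
        kept = filter_blocks([ok, too_short, no_ref, two_species])
        assert kept == [ok]

    def test_filter_monotone(self, dataset):
        from lncscreen.candidate_discovery import extract_noncoding

        regions = extract_noncoding(dataset.genome, dataset.genes)
        hits = []
        for sp, recs in dataset.orthologs.items():
            hits += pairwise_hits(regions, recs, sp)
        blocks = build_blocks(best_hit_per_pair(hits), regions,
                              dataset.orthologs)
        loose = filter_blocks(blocks, min_length=50, min_species=3)
        tight = filter_blocks(blocks, min_length=100, min_species=4)
        assert {b.block_id for b in tight} <= {b.block_id for b in loose}


class TestBlastImport:
    def test_outfmt6_round(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(
            "q1\ts1\t95.0\t100\t5\t0\t1\t100\t201\t300\t1e-30\t180\n"
            "q1\ts1\t90.0\t100\t10\t0\t1\t100\t400\t301\t1e-20\t150\n"
            "q2\ts1\t88.0\t50\t6\t0\t1\t50\t10\t59\t0.5\t40\n"
        )
        hits = read_blast_table(p, "sp")
        assert len(hits) == 2          # E = 0.5 filtered out
        assert hits[0].query_interval == (0, 100)
        assert hits[0].subject_interval == (200, 300)
        assert hits[1].strand == "-"

    def test_malformed_row_names_line(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("q1\ts1\tnot_a_number\n")
        from lncscreen.genome_io import FormatError

        with pytest.raises(FormatError, match="1"):
            read_blast_table(p, "sp")


def test_planted_blocks_survive_filtering(dataset):
    """>=90% of planted structured regions survive discovery at divergence 0.1."""
    regions = extract_noncoding(dataset.genome, dataset.genes)
    hits = []
    for sp, recs in dataset.orthologs.items():
        hits += pairwise_hits(regions, recs, sp)
    blocks = filter_blocks(build_blocks(best_hit_per_pair(hits), regions,
                                        dataset.orthologs))
    n_ok = sum(
        1 for rec in dataset.truth.structured
        if any(b.reference_interval.overlaps(rec.interval) for b in blocks))
    assert n_ok >= 0.9 * len(dataset.truth.structured)
    _ = bitmap  # oracle shared with genome_io tests
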