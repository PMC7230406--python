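"""cis/trans/mimicry target inference and GO enrichment."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from lncscreen.genome_io import GeneModel, GenomicInterval, SequenceRecord
from lncscreen.target_function import (
    cis_targets,
    duplex_mfe,
    go_enrich,
    mimicry_targets,
    scan_mirna_sites,
    trans_binding_targets,
)

from _oracles import brute_force_sites, exact_hypergeom_upper

_COMP = str.maketrans("ACGU", "UGCA")


def _gene(gene_id, start, end, strand="+"):
    return GeneModel(gene_id, GenomicInterval("chr1", start, end, strand),
                     exons=[GenomicInterval("chr1", start, end, strand)],
                     cds=[GenomicInterval("chr1", start + 10, end - 10, strand)])


class TestCis:
    def test_proximal_pair(self):
        genes = [_gene("g1", 10_000, 12_000)]
        lnc_iv = {"l1": GenomicInterval("chr1", 5_000, 7_300)}
        edges = cis_targets({"cold": {"l1"}}, {"cold": {"g1"}}, lnc_iv, genes)
        assert len(edges) == 1 and edges[0].distance == 2700

    def test_distance_bound(self):
        genes = [_gene("g1", 20_001, 22_000)]
        lnc_iv = {"l1": GenomicInterval("chr1", 5_000, 10_000)}
        edges = cis_targets({"cold": {"l1"}}, {"cold": {"g1"}}, lnc_iv, genes)
        assert edges == []     # distance 10,001
        genes2 = [_gene("g1", 20_000, 22_000)]
        edges2 = cis_targets({"cold": {"l1"}}, {"cold": {"g1"}}, lnc_iv, genes2)
        assert len(edges2) == 1 and edges2[0].distance == 10_000

    def test_condition_mismatch(self):
        genes = [_gene("g1", 10_000, 12_000)]
        lnc_iv = {"l1": GenomicInterval("chr1", 9_000, 9_500)}
        edges = cis_targets({"cold": {"l1"}}, {"drought": {"g1"}}, lnc_iv, genes)
        assert edges == []

    def test_monotone_in_max_distance(self):
        rng = np.random.default_rng(0)
        genes = [_gene(f"g{i}", int(s), int(s) + 1000)
                 for i, s in enumerate(rng.integers(0, 80_000, 15) * 1)]
        lnc_iv = {"l1": GenomicInterval("chr1", 40_000, 40_300)}
        de_l = {"cold": {"l1"}}
        de_g = {"cold": {g.gene_id for g in genes}}
        sizes = [len(cis_targets(de_l, de_g, lnc_iv, genes, max_distance=d))
                 for d in (1000, 5000, 10_000, 50_000)]
        assert sizes == sorted(sizes)


class TestDuplex:
    def test_result_fields(self):
        a = "ACGUACGUACGUACGUACGU"
        b = a.translate(_COMP)[::-1]
        res = duplex_mfe(a, b)
        assert res.energy < -40
        assert res.interval_a == (0, 20) and res.interval_b == (0, 20)
        assert len(res.pairs) == 20

    def test_no_complementarity_empty(self):
        res = duplex_mfe("AAAA", "AAAA")
        assert res.energy == 0.0 and res.pairs == []
        assert res.interval_a is None

    def test_minimum_length(self):
        with pytest.raises(ValueError, match="4 nt"):
            duplex_mfe("ACG", "ACGU")


class TestTransBinding:
    def _setup(self, seed=0):
        rng = np.random.default_rng(seed)

        def rand(n):
            return "".join(rng.choice(list("ACGU"), n))

        cassette = rand(40)
        lnc = rand(100) + cassette + rand(110)
        mrna = rand(400) + cassette.translate(_COMP)[::-1] + rand(400)
        return lnc, mrna, rand(250), rand(840)

    def test_planted_cassette_recovered_with_interval(self):
        lnc, mrna, _rl, _rm = self._setup()
        edges = trans_binding_targets(
            {"cold": {"l1"}}, {"cold": {"g1"}}, {"l1": lnc}, {"g1": mrna})
        assert len(edges) == 1
        a0, a1 = edges[0].duplex.interval_a
        # the reported interval covers the planted cassette; it may extend a
        # little where flanking complementarity continues the chain
        assert a0 <= 102 and a1 >= 138
        assert a1 - a0 <= 80

    def test_shuffled_controls_rejected(self):
        n_edges = 0
        for seed in range(25):
            _l, _m, rl, rm = self._setup(seed)
            n_edges += len(trans_binding_targets(
                {"cold": {"l"}}, {"cold": {"g"}}, {"l": rl}, {"g": rm}))
        assert n_edges <= 1    # >= 95% specificity on random pairs

    def test_threshold_monotonicity(self):
        _l, _m, rl, rm = self._setup(3)
        strict = trans_binding_targets(
            {"c": {"l"}}, {"c": {"g"}}, {"l": rl}, {"g": rm})
        loose = trans_binding_targets(
            {"c": {"l"}}, {"c": {"g"}}, {"l": rl}, {"g": rm},
            absolute_threshold=0.0)
        assert len(loose) >= len(strict)
        assert len(loose) == 1    # any complementarity at threshold 0


class TestMimicry:
    MIRNA = SequenceRecord("mir1", "UGACCUAGCUAGCUUGGACUA")

    def _site(self, mismatches=0):
        site = self.MIRNA.sequence.translate(_COMP)[::-1]
        site = list(site)
        # break pairing without G:U rescue
        for t in range(mismatches):
            mir_base = self.MIRNA.sequence[len(site) - 1 - t]
            bad = {"A": "C", "C": "A", "G": "A", "U": "C"}[mir_base]
            site[t] = bad
        return "".join(site)

    def test_scan_matches_brute_force(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            host = "".join(rng.choice(list("ACGU"), 80))
            mir = SequenceRecord("m", "".join(rng.choice(list("ACGU"), 21)))
            got = [s.offset for s in scan_mirna_sites(
                "h", host, mir, both_orientations=False)]
            assert got == brute_force_sites(host, mir.sequence, 2.0)

    @pytest.mark.parametrize("k,found", [(0, True), (1, True), (2, True),
                                         (3, False)])
    def test_mismatch_threshold(self, k, found):
        rng = np.random.default_rng(2)
        host = ("".join(rng.choice(list("AC"), 30)) + self._site(k)
                + "".join(rng.choice(list("AC"), 30)))
        sites = scan_mirna_sites("h", host, self.MIRNA,
                                 both_orientations=False)
        assert bool(sites) == found
        if found:
            assert any(s.offset == 30 for s in sites)

    def test_gu_counts_half(self):
        # a G:U wobble site: 4 wobbles = 2.0 rounded mismatches -> accepted
        # when counted half, rejected when counted full
        site = list(self.MIRNA.sequence.translate(_COMP)[::-1])
        m = len(site)
        changed = 0
        for t in range(m):
            if changed == 4:
                break
            mir_base = self.MIRNA.sequence[m - 1 - t]
            if mir_base == "U" and site[t] == "A":
                site[t] = "G"     # G:U instead of A:U
                changed += 1
        assert changed == 4
        host = "CCCC" + "".join(site) + "CCCC"
        half = scan_mirna_sites("h", host, self.MIRNA, gu_half=True,
                                both_orientations=False)
        full = scan_mirna_sites("h", host, self.MIRNA, gu_half=False,
                                both_orientations=False)
        assert any(s.offset == 4 for s in half)
        assert not any(s.offset == 4 for s in full)

    def test_edge_requires_both_hosts(self):
        rng = np.random.default_rng(3)
        bg = "".join(rng.choice(list("AC"), 120))
        lnc = bg[:40] + self._site(0) + bg[40:]
        mrna_without = "".join(rng.choice(list("AC"), 300))
        mrna_with = mrna_without[:100] + self._site(2) + mrna_without[100:]
        de_l, de_g = {"c": {"l"}}, {"c": {"g"}}
        no_edge = mimicry_targets(de_l, de_g, {"l": lnc},
                                  {"g": mrna_without}, [self.MIRNA])
        edge = mimicry_targets(de_l, de_g, {"l": lnc}, {"g": mrna_with},
                               [self.MIRNA])
        assert no_edge == []
        assert len(edge) == 1
        assert edge[0].mirna_id == "mir1"
        assert len(edge[0].lncrna_sites) >= 1 and len(edge[0].gene_sites) >= 1

    def test_two_sites_reported_on_one_edge(self):
        rng = np.random.default_rng(4)
        bg = "".join(rng.choice(list("AC"), 200))
        lnc = bg[:30] + self._site(0) + bg[30:90] + self._site(1) + bg[90:]
        mrna = "".join(rng.choice(list("AC"), 200)) + self._site(0)
        edges = mimicry_targets({"c": {"l"}}, {"c": {"g"}}, {"l": lnc},
                                {"g": mrna}, [self.MIRNA])
        assert len(edges) == 1
        plus_sites = [s for s in edges[0].lncrna_sites if s.orientation == "+"]
        assert len(plus_sites) == 2

    def test_mirna_longer_than_host_warns(self):
        with pytest.warns(UserWarning, match="longer"):
            assert scan_mirna_sites("h", "ACGU", self.MIRNA) == []


class TestEnrichment:
    def _gene2go(self, mapping):
        rows = [{"gene_id": g, "go_id": t, "namespace": "bp"}
                for g, terms in mapping.items() for t in terms]
        return pd.DataFrame(rows)

    def test_closed_form_extreme(self):
        # N=20, K=5, n=5, k=5: p = 1/C(20,5) = 1/15504
        background = {f"g{i}" for i in range(20)}
        targets = {f"g{i}" for i in range(5)}
        gene2go = self._gene2go({f"g{i}": ["GO:1"] for i in range(5)})
        [res] = go_enrich(targets, background, gene2go)
        assert res.p == pytest.approx(1 / 15504, rel=1e-9)
        assert res.fdr == pytest.approx(res.p)   # single term: fdr = p

    def test_expected_overlap_not_enriched(self):
        # k = n*K/N exactly: at/below expectation, p > 0.5
        background = {f"g{i}" for i in range(20)}
        targets = {"g0", "g1", "g2", "g3"}       # n=4
        gene2go = self._gene2go(
            {g: ["GO:1"] for g in ["g0", "g4", "g5", "g6", "g7"]})  # K=5, k=1
        [res] = go_enrich(targets, background, gene2go)
        assert res.p > 0.5

    def test_matches_exact_enumeration(self):
        rng = np.random.default_rng(5)
        background = {f"g{i}" for i in range(18)}
        for _ in range(20):
            K = int(rng.integers(1, 10))
            n = int(rng.integers(1, 10))
            term_genes = set(rng.choice(sorted(background), K, replace=False))
            targets = set(rng.choice(sorted(background), n, replace=False))
            k = len(term_genes & targets)
            if k == 0:
                continue
            gene2go = self._gene2go({g: ["GO:x"] for g in term_genes})
            [res] = go_enrich(targets, background, gene2go)
            assert res.p == pytest.approx(
                exact_hypergeom_upper(k, 18, K, n), rel=1e-9)

    def test_target_outside_background_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            go_enrich({"gX"}, {"g1"}, self._gene2go({"g1": ["GO:1"]}))

    def test_fdr_at_least_p(self):
        rng = np.random.default_rng(6)
        background = {f"g{i}" for i in range(40)}
        mapping = {}
        for t in range(8):
            for g in rng.choice(sorted(background), 10, replace=False):
                mapping.setdefault(g, []).append(f"GO:{t}")
        targets = set(rng.choice(sorted(background), 10, replace=False))
        results = go_enrich(targets, background, self._gene2go(mapping))
        for r in results:
            assert r.fdr >= r.p - 1e-12
            assert r.k <= min(r.K, r.n)
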