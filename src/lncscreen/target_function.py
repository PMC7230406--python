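"""Target inference for differentially expressed lncRNAs and GO enrichment.

Three typed lncRNA->gene relations are produced, all conditioned on both
endpoints being significantly differentially expressed in the same stress
condition:

* cis -- the gene lies within 10 kb (closest edges; 0 when overlapping) of
  the lncRNA locus, either side, either strand;
* trans_binding -- the optimal lncRNA:mRNA hybridization duplex (same
  energy model as the folding screen, intermolecular pairing only) is more
  stable than a length-normalized threshold;
* mimicry -- one miRNA has a binding site (reverse complement within <=2
  mismatches, G:U wobble counted half) on both the lncRNA and the mRNA, the
  sponge/decoy configuration.

Gene-set function is summarized by hypergeometric GO enrichment of the
target genes against the annotated background with BH FDR control.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import benjamini_hochberg
from .genome_io import GeneModel, GenomicInterval, SequenceRecord
from .thermo import EnergyParams, duplex_mfe_pairs, load_params

__all__ = [
    "TargetEdge",
    "DuplexResult",
    "EnrichmentResult",
    "MimicrySite",
    "cis_targets",
    "duplex_mfe",
    "trans_binding_targets",
    "scan_mirna_sites",
    "mimicry_targets",
    "go_enrich",
    "read_gene2go",
]

CIS_MAX_DISTANCE = 10_000
# Binding-site interactions permit only short bulges/internal loops (<= 2 nt
# per loop): long loops describe intramolecular folding, not hybridization.
# The per-nt threshold is calibrated under this model so shuffled control
# pairs essentially never pass while planted 40-nt cassettes always do.
TRANS_INTERACTION_MAX_LOOP = 2
TRANS_ENERGY_PER_NT = -0.25       # kcal/mol per nt of the shorter molecule
MIMICRY_MAX_MISMATCH = 2.0


@dataclass
class DuplexResult:
    """Optimal intermolecular duplex between two RNAs."""

    energy: float
    interval_a: tuple[int, int] | None
    interval_b: tuple[int, int] | None
    pairs: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.pairs and self.energy > 0:
            raise ValueError("reported duplex must have energy <= 0")


@dataclass
class MimicrySite:
    """One miRNA binding site on a host transcript."""

    mirna_id: str
    host_id: str
    offset: int                 # window start on the host (+ orientation)
    orientation: str            # '+' or '-': strand of the host scanned
    mismatches: float           # G:U counted as 0.5 when enabled


@dataclass
class TargetEdge:
    """Typed lncRNA -> gene relation with its supporting score."""

    lncrna_id: str
    gene_id: str
    mode: str                   # cis | trans_binding | mimicry
    condition: str
    distance: int | None = None
    energy: float | None = None
    duplex: DuplexResult | None = None
    mirna_id: str | None = None
    lncrna_sites: list[MimicrySite] | None = None
    gene_sites: list[MimicrySite] | None = None


@dataclass
class EnrichmentResult:
    """Hypergeometric GO term enrichment of a target set."""

    go_id: str
    name: str
    k: int      # targets in term
    K: int      # background in term
    n: int      # target-set size
    N: int      # background size
    p: float
    fdr: float

    @property
    def enriched(self) -> bool:
        return self.fdr <= 0.05


# ---------------------------------------------------------------------------
# cis

def cis_targets(de_lncrnas: dict[str, set[str]],
                de_genes: dict[str, set[str]],
                lncrna_intervals: dict[str, GenomicInterval],
                genes: list[GeneModel],
                max_distance: int = CIS_MAX_DISTANCE) -> list[TargetEdge]:
    """Proximity edges: DE lncRNA and DE gene in the same condition within
    ``max_distance`` nt (closest edges, 0 when overlapping), either strand.

    ``de_lncrnas`` / ``de_genes`` map condition -> set of significant ids.
    """
    gene_by_id = {g.gene_id: g for g in genes}
    edges: list[TargetEdge] = []
    for condition in sorted(de_lncrnas):
        lnc_ids = de_lncrnas[condition]
        gene_ids = de_genes.get(condition, set())
        for lnc_id in sorted(lnc_ids):
            iv = lncrna_intervals.get(lnc_id)
            if iv is None:
                continue
            for gene_id in sorted(gene_ids):
                gene = gene_by_id.get(gene_id)
                if gene is None or gene.interval.seqid != iv.seqid:
                    continue
                d = iv.distance(gene.interval)
                if d <= max_distance:
                    edges.append(TargetEdge(
                        lncrna_id=lnc_id, gene_id=gene_id, mode="cis",
                        condition=condition, distance=d))
    return edges


# ---------------------------------------------------------------------------
# trans direct binding

def duplex_mfe(seq_a: str, seq_b: str,
               params: EnergyParams | None = None) -> DuplexResult:
    """Optimal hybridization duplex between two RNA sequences.

    Pairing is intermolecular only and non-crossing (antiparallel); energies
    come from the shared stacking parameter table.  Sequences without any
    complementarity give energy 0 and empty intervals.
    """
    if len(seq_a) < 4 or len(seq_b) < 4:
        raise ValueError("duplex prediction needs sequences of >= 4 nt")
    energy, pairs = duplex_mfe_pairs(seq_a, seq_b, params)
    if not pairs:
        return DuplexResult(0.0, None, None, [])
    ia = (min(i for i, _ in pairs), max(i for i, _ in pairs) + 1)
    ib = (min(j for _, j in pairs), max(j for _, j in pairs) + 1)
    return DuplexResult(energy, ia, ib, pairs)


def trans_binding_targets(de_lncrnas: dict[str, set[str]],
                          de_genes: dict[str, set[str]],
                          lncrna_seqs: dict[str, str],
                          mrna_seqs: dict[str, str],
                          energy_per_nt: float = TRANS_ENERGY_PER_NT,
                          absolute_threshold: float | None = None,
                          params: EnergyParams | None = None
                          ) -> list[TargetEdge]:
    """Direct-binding edges from optimal hybridization energy.

    Default threshold is length-normalized: duplex energy must be at most
    ``energy_per_nt`` times the length of the shorter molecule.  Passing
    ``absolute_threshold`` switches to a fixed kcal/mol cutoff.  Duplexes
    are computed with the interaction loop cap
    (:data:`TRANS_INTERACTION_MAX_LOOP`) so energies reflect one binding
    interface rather than arbitrarily chained helices.
    """
    from dataclasses import replace as _replace

    params = _replace(params or load_params(),
                      max_interior_unpaired=TRANS_INTERACTION_MAX_LOOP)
    edges: list[TargetEdge] = []
    for condition in sorted(de_lncrnas):
        for lnc_id in sorted(de_lncrnas[condition]):
            seq_l = lncrna_seqs.get(lnc_id)
            if seq_l is None:
                continue
            for gene_id in sorted(de_genes.get(condition, set())):
                seq_m = mrna_seqs.get(gene_id)
                if seq_m is None:
                    continue
                result = duplex_mfe(seq_l, seq_m, params)
                if absolute_threshold is not None:
                    threshold = absolute_threshold
                else:
                    threshold = energy_per_nt * min(len(seq_l), len(seq_m))
                if result.energy <= threshold:
                    edges.append(TargetEdge(
                        lncrna_id=lnc_id, gene_id=gene_id,
                        mode="trans_binding", condition=condition,
                        energy=result.energy, duplex=result))
    return edges


# ---------------------------------------------------------------------------
# miRNA target mimicry

_COMP = str.maketrans("ACGUT", "UGCAA")
_DNA = str.maketrans("U", "T")


def _mismatch_weight(host_base: str, mir_base: str, gu_half: bool) -> float:
    """0 for a WC pair, 0.5 for G:U wobble (when enabled), else 1."""
    h, m = host_base.replace("T", "U"), mir_base.replace("T", "U")
    if (h, m) in {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}:
        return 0.0
    if (h, m) in {("G", "U"), ("U", "G")}:
        return 0.5 if gu_half else 1.0
    return 1.0


def scan_mirna_sites(host_id: str, host_seq: str, mirna: SequenceRecord,
                     max_mismatch: float = MIMICRY_MAX_MISMATCH,
                     gu_half: bool = True,
                     both_orientations: bool = True) -> list[MimicrySite]:
    """All windows where the miRNA could bind the host within the mismatch cap.

    Position t of a window pairs with miRNA position m-1-t (antiparallel).
    The mismatch sum counts G:U as half (rounded half-up before comparison);
    unstranded hosts are scanned in both orientations.  Hosts shorter than
    the miRNA are skipped with a warning.
    """
    m = len(mirna.sequence)
    if len(host_seq) < m:
        import warnings

        warnings.warn(f"miRNA {mirna.id} longer than host {host_id}; skipped")
        return []
    mir = mirna.sequence.upper().replace("T", "U")
    sites: list[MimicrySite] = []
    orientations = [("+", host_seq.upper())]
    if both_orientations:
        rc = host_seq.upper().translate(_DNA).translate(
            str.maketrans("ACGT", "TGCA"))[::-1]
        orientations.append(("-", rc))
    for orient, seq in orientations:
        for off in range(len(seq) - m + 1):
            window = seq[off:off + m]
            total = 0.0
            for t in range(m):
                total += _mismatch_weight(window[t], mir[m - 1 - t], gu_half)
                if total > max_mismatch + 0.5:
                    break
            rounded = np.floor(total + 0.5)
            if rounded <= max_mismatch:
                if orient == "-":
                    off_fwd = len(seq) - m - off
                else:
                    off_fwd = off
                sites.append(MimicrySite(mirna.id, host_id, off_fwd, orient,
                                         float(total)))
    return sites


def mimicry_targets(de_lncrnas: dict[str, set[str]],
                    de_genes: dict[str, set[str]],
                    lncrna_seqs: dict[str, str],
                    mrna_seqs: dict[str, str],
                    mirnas: list[SequenceRecord],
                    max_mismatch: float = MIMICRY_MAX_MISMATCH,
                    gu_half: bool = True) -> list[TargetEdge]:
    """Sponge edges: one miRNA with sites on both a DE lncRNA and a DE mRNA.

    All sites are reported on the edge (a host may carry several sites for
    the same miRNA).  mRNAs are scanned in transcript orientation only;
    unstranded lncRNA loci in both orientations.
    """
    edges: list[TargetEdge] = []
    site_cache: dict[tuple[str, str], list[MimicrySite]] = {}

    def sites_for(host_id: str, seq: str, mir: SequenceRecord,
                  both: bool) -> list[MimicrySite]:
        key = (host_id, mir.id)
        if key not in site_cache:
            site_cache[key] = scan_mirna_sites(
                host_id, seq, mir, max_mismatch=max_mismatch, gu_half=gu_half,
                both_orientations=both)
        return site_cache[key]

    for condition in sorted(de_lncrnas):
        for lnc_id in sorted(de_lncrnas[condition]):
            seq_l = lncrna_seqs.get(lnc_id)
            if seq_l is None:
                continue
            for gene_id in sorted(de_genes.get(condition, set())):
                seq_m = mrna_seqs.get(gene_id)
                if seq_m is None:
                    continue
                for mir in mirnas:
                    ls = sites_for(lnc_id, seq_l, mir, both=True)
                    if not ls:
                        continue
                    gs = sites_for(gene_id, seq_m, mir, both=False)
                    if not gs:
                        continue
                    edges.append(TargetEdge(
                        lncrna_id=lnc_id, gene_id=gene_id, mode="mimicry",
                        condition=condition, mirna_id=mir.id,
                        lncrna_sites=ls, gene_sites=gs))
    return edges


# ---------------------------------------------------------------------------
# GO enrichment

def read_gene2go(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "go_id"}
    if not required.issubset(df.columns):
        raise ValueError("gene2go table needs gene_id and go_id columns")
    return df


def go_enrich(target_genes: set[str], background_genes: set[str],
              gene2go: pd.DataFrame, max_fdr: float = 0.05,
              term_names: dict[str, str] | None = None
              ) -> list[EnrichmentResult]:
    """Hypergeometric upper-tail GO enrichment with BH FDR control.

    ``target_genes`` must be a subset of ``background_genes``; violating ids
    raise ``ValueError``.  Terms are tested when at least one target gene is
    annotated to them; results are sorted by p-value.
    """
    missing = target_genes - background_genes
    if missing:
        raise ValueError(
            f"target genes absent from background: {sorted(missing)[:10]}")
    term_names = term_names or {}
    anno = gene2go[gene2go["gene_id"].isin(background_genes)]
    by_term = anno.groupby("go_id")["gene_id"].apply(set)
    N = len(background_genes)
    n = len(target_genes)
    results: list[EnrichmentResult] = []
    for go_id, genes_in_term in sorted(by_term.items()):
        K = len(genes_in_term)
        k = len(genes_in_term & target_genes)
        if k == 0:
            continue
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        results.append(EnrichmentResult(
            go_id=go_id, name=term_names.get(go_id, ""), k=k, K=K, n=n, N=N,
            p=p, fdr=1.0))
    if results:
        fdr = benjamini_hochberg(np.array([r.p for r in results]))
        for r, q in zip(results, fdr):
            r.fdr = float(q)
    results.sort(key=lambda r: (r.p, r.go_id))
    return [r for r in results]


def edges_to_frame(edges: list[TargetEdge]) -> pd.DataFrame:
    rows = []
    for e in edges:
        rows.append({
            "lncrna_id": e.lncrna_id, "gene_id": e.gene_id, "mode": e.mode,
            "condition": e.condition,
            "distance": "" if e.distance is None else e.distance,
            "energy": "" if e.energy is None else round(e.energy, 3),
            "mirna_id": e.mirna_id or "",
            "n_lncrna_sites": len(e.lncrna_sites) if e.lncrna_sites else "",
            "n_gene_sites": len(e.gene_sites) if e.gene_sites else "",
        })
    return pd.DataFrame(rows)
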