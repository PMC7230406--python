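"""Scoring a pipeline run against the synthetic generator's planted truth.

These helpers compare a completed run directory with the truth table the
generator wrote alongside the inputs: recovery of planted structured loci,
decoy false-positive rate, biotype agreement, and recall/precision of the
planted differential-expression calls, cis pairs, binding cassettes and
mimicry triples.  Both the test suite and the reproduction script are built
on this module.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .genome_io import GenomicInterval
from .synthetic_data import CONDITIONS, TruthRecord, TruthTable

__all__ = ["RunEvaluation", "evaluate_run"]


@dataclass
class RunEvaluation:
    """Headline truth-recovery metrics of one synthetic pipeline run."""

    n_planted: int
    n_planted_recovered: int
    n_decoys: int
    n_decoys_called: int
    n_lncrnas: int
    n_biotype_correct: int
    n_biotype_assigned: int
    de_recall: float
    de_precision: float
    cis_recall: float
    cis_precision: float
    trans_recall: float
    trans_precision: float
    mimicry_recall: float
    mimicry_precision: float

    @property
    def planted_recovery(self) -> float:
        return self.n_planted_recovered / self.n_planted if self.n_planted else 0.0

    @property
    def decoy_fp_rate(self) -> float:
        return self.n_decoys_called / self.n_decoys if self.n_decoys else 0.0

    @property
    def biotype_agreement(self) -> float:
        if self.n_biotype_assigned == 0:
            return 0.0
        return self.n_biotype_correct / self.n_biotype_assigned


def _interval(row) -> GenomicInterval:
    return GenomicInterval(str(row["seqid"]), int(row["start"]), int(row["end"]))


def _overlapping_truth(iv: GenomicInterval, records: list[TruthRecord]
                       ) -> TruthRecord | None:
    best, best_ov = None, 0
    for rec in records:
        ov = iv.overlap_length(rec.interval)
        if ov > best_ov:
            best, best_ov = rec, ov
    return best


def _truth_de_ids(truth: TruthTable, cls: str) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {c: set() for c in CONDITIONS}
    for rec in truth.of_class(cls):
        for cond in CONDITIONS:
            if rec.is_de_in(cond) and rec.planted_log2fc != 0.0:
                out[cond].add(rec.planted_id)
    return out


def _prf(true_set: set, pred_set: set) -> tuple[float, float]:
    """(recall, precision); empty sets give 1.0 by convention."""
    recall = (len(true_set & pred_set) / len(true_set)) if true_set else 1.0
    precision = (len(true_set & pred_set) / len(pred_set)) if pred_set else 1.0
    return recall, precision


def evaluate_run(run_dir: str | Path) -> RunEvaluation:
    """Compute all truth-recovery metrics for a finished run directory."""
    run = Path(run_dir)
    truth = TruthTable.from_tsv(run / "inputs" / "truth.tsv")
    loci = pd.read_csv(run / "03_loci" / "loci.tsv", sep="\t")
    loci_iv = {row["locus_id"]: _interval(row) for _, row in loci.iterrows()}

    planted = truth.structured
    decoys = truth.decoys
    n_planted_rec = sum(
        1 for rec in planted
        if any(iv.overlaps(rec.interval) for iv in loci_iv.values()))
    n_decoys_called = sum(
        1 for rec in decoys
        if any(iv.overlaps(rec.interval) for iv in loci_iv.values()))

    # locus -> planted id mapping (largest overlap)
    locus_to_planted: dict[str, str] = {}
    for lid, iv in loci_iv.items():
        rec = _overlapping_truth(iv, planted)
        if rec is not None and iv.overlap_length(rec.interval) > 0:
            locus_to_planted[lid] = rec.planted_id

    # biotype agreement
    try:
        lnc = pd.read_csv(run / "05_lncrnas" / "lncrnas.tsv", sep="\t",
                          keep_default_na=False)
    except pd.errors.EmptyDataError:
        lnc = pd.DataFrame(columns=["locus_id", "biotype"])
    truth_by_id = {r.planted_id: r for r in planted}
    n_assigned = n_correct = 0
    for _, row in lnc.iterrows():
        pid = locus_to_planted.get(row["locus_id"])
        if pid is None:
            continue
        n_assigned += 1
        if truth_by_id[pid].intended_biotype == row["biotype"]:
            n_correct += 1

    # DE recall/precision on lncRNA loci (planted-id space, per condition)
    truth_de = _truth_de_ids(truth, "structured-ncRNA")
    pred_de: dict[str, set[str]] = {c: set() for c in CONDITIONS}
    lnc_ids = set(lnc["locus_id"]) if len(lnc) else set()
    for cond in CONDITIONS:
        de = pd.read_csv(run / "06_de" / f"de_{cond}.tsv", sep="\t")
        sig = de[(de["significant"] == 1) & de["feature_id"].isin(lnc_ids)]
        for fid in sig["feature_id"]:
            pid = locus_to_planted.get(fid)
            if pid is not None:
                pred_de[cond].add(pid)
    de_true = {(c, p) for c in CONDITIONS for p in truth_de[c]}
    de_pred = {(c, p) for c in CONDITIONS for p in pred_de[c]}
    de_recall, de_precision = _prf(de_true, de_pred)

    # target truth sets
    gene_de = _truth_de_ids(truth, "coding-gene")
    truth_genes = {r.planted_id: r for r in truth.genes}
    cis_true: set[tuple[str, str, str]] = set()
    for cond in CONDITIONS:
        for pid in truth_de[cond]:
            rec = truth_by_id[pid]
            for gid in gene_de[cond]:
                giv = truth_genes[gid].interval
                if giv.seqid != rec.interval.seqid:
                    continue
                if rec.interval.distance(giv) <= 10_000:
                    cis_true.add((cond, pid, gid))

    trans_true: set[tuple[str, str, str]] = set()
    mimicry_true: set[tuple[str, str, str]] = set()
    for rec in planted:
        if rec.binding_cassette is not None:
            gid = rec.binding_cassette[0]
            for cond in CONDITIONS:
                if rec.is_de_in(cond) and gid in gene_de[cond]:
                    trans_true.add((cond, rec.planted_id, gid))
        for mid, _iv, k in rec.mirna_sites:
            if k > 2:
                continue
            for grec in truth.genes:
                for gmid, _giv, gk in grec.mirna_sites:
                    if gmid != mid or gk > 2:
                        continue
                    for cond in CONDITIONS:
                        if rec.is_de_in(cond) and grec.is_de_in(cond):
                            mimicry_true.add((cond, rec.planted_id,
                                              grec.planted_id))

    edges = pd.read_csv(run / "07_targets" / "edges.tsv", sep="\t",
                        keep_default_na=False)
    cis_pred, trans_pred, mim_pred = set(), set(), set()
    for _, row in (edges.iterrows() if len(edges) else []):
        pid = locus_to_planted.get(row["lncrna_id"])
        if pid is None:
            continue
        key = (row["condition"], pid, row["gene_id"])
        if row["mode"] == "cis":
            cis_pred.add(key)
        elif row["mode"] == "trans_binding":
            trans_pred.add(key)
        elif row["mode"] == "mimicry":
            mim_pred.add(key)

    cis_r, cis_p = _prf(cis_true, cis_pred)
    trans_r, trans_p = _prf(trans_true, trans_pred)
    mim_r, mim_p = _prf(mimicry_true, mim_pred)

    return RunEvaluation(
        n_planted=len(planted),
        n_planted_recovered=n_planted_rec,
        n_decoys=len(decoys),
        n_decoys_called=n_decoys_called,
        n_lncrnas=len(lnc),
        n_biotype_correct=n_correct,
        n_biotype_assigned=n_assigned,
        de_recall=de_recall, de_precision=de_precision,
        cis_recall=cis_r, cis_precision=cis_p,
        trans_recall=trans_r, trans_precision=trans_p,
        mimicry_recall=mim_r, mimicry_precision=mim_p,
    )
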