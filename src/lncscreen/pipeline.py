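"""End-to-end orchestration of the discovery pipeline with a run manifest.

Stages (in order): simulate -> extract -> conserve -> structure -> verify ->
classify -> de -> targets -> enrich -> summarize.  Each stage writes its
outputs under a numbered subdirectory of the run directory and appends its
record counts to the manifest; later stages load what they need from disk,
so any stage can be re-run individually once its dependencies exist.  All
outputs are deterministically ordered and carry no timestamps: re-running a
config+seed reproduces the output tree byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .candidate_discovery import (
    AlignmentBlock,
    best_hit_per_pair,
    build_blocks,
    extract_noncoding,
    filter_blocks,
    pairwise_hits,
)
from .diffexpr import call_de, nb_test, results_to_frame, venn_partition
from .genome_io import (
    GenomicInterval,
    SequenceRecord,
    read_bed,
    read_fasta,
    read_gff3,
    write_bed,
)
from .lncrna_classification import (
    HexamerModel,
    coding_potential,
    records_to_frame,
    select_novel_lncrnas,
)
from .structure_screen import (
    NcrnaLocus,
    merge_positive_windows,
    score_block,
)
from .synthetic_data import SynthConfig, TruthTable, generate_all, simulate_counts
from .target_function import (
    cis_targets,
    edges_to_frame,
    go_enrich,
    mimicry_targets,
    trans_binding_targets,
)
from .thermo import load_params
from .verification import (
    CoverageTrack,
    getmm_normalize,
    import_structure_matches,
    verify_loci,
)

__all__ = ["PipelineConfig", "PipelineRun", "run_all", "StageError"]

STAGE_ORDER = ("simulate", "extract", "conserve", "structure", "verify",
               "classify", "de", "targets", "enrich", "summarize")


class StageError(RuntimeError):
    """A stage's dependencies are missing or its configuration is invalid."""


@dataclass(frozen=True)
class PipelineConfig:
    """All thresholds of the pipeline; defaults are the published values."""

    run_dir: str = "run"
    seed: int = 7
    # discovery
    evalue: float = 0.01
    min_block_len: int = 50
    min_species: int = 3
    # structure screen
    window: int = 120
    overlap: int = 80
    p_positive: float = 0.5
    p_high: float = 0.9
    n_shuffles: int = 100
    # verification
    min_reads: int = 10
    # classification
    min_lncrna_len: int = 200
    lincrna_distance: int = 500
    # differential expression
    de_log2fc: float = 2.0
    de_q: float = 0.05
    # targets
    cis_distance: int = 10_000
    trans_energy_per_nt: float = -0.25
    mimicry_mismatch: float = 2.0
    enrich_fdr: float = 0.05
    # synthetic generation (used by the simulate stage)
    synth: SynthConfig = field(default_factory=SynthConfig)
    # import-mode file paths (None => compute internally)
    import_structure_tblout: str | None = None

    def __post_init__(self) -> None:
        positive = ("evalue", "min_block_len", "min_species", "window",
                    "p_positive", "p_high", "min_reads", "min_lncrna_len",
                    "lincrna_distance", "de_log2fc", "de_q", "cis_distance",
                    "mimicry_mismatch", "enrich_fdr", "n_shuffles")
        for name in positive:
            if getattr(self, name) <= 0:
                raise StageError(f"config threshold {name} must be positive")
        if not (0 < self.de_q <= 1) or not (0 < self.enrich_fdr <= 1):
            raise StageError("q-value / FDR thresholds must lie in (0, 1]")
        if self.overlap < 0 or self.overlap >= self.window:
            raise StageError("overlap must satisfy 0 <= overlap < window")

    @property
    def window_step(self) -> int:
        return self.window - self.overlap

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        synth_raw = raw.pop("synth", {})
        for key in ("exons_per_gene", "utr_lengths", "intron_lengths",
                    "intergenic_lengths", "planted_lengths", "species"):
            if key in synth_raw and isinstance(synth_raw[key], list):
                synth_raw[key] = tuple(synth_raw[key])
        synth = SynthConfig(**synth_raw)
        return cls(synth=synth, **raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class PipelineRun:
    """One run directory; stages read/write files beneath it."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.root = Path(config.run_dir)
        self.root.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.root / "manifest.json"
        self.manifest: dict = {
            "package_version": __version__,
            "energy_table_version": load_params().version,
            "seed": config.seed,
            "config": _config_dict(config),
            "stage_counts": {},
            "input_checksums": {},
        }
        if self.manifest_path.exists():
            try:
                self.manifest = json.loads(self.manifest_path.read_text())
            except json.JSONDecodeError:
                pass

    # -- helpers ----------------------------------------------------------

    def _dir(self, name: str) -> Path:
        d = self.root / name
        d.mkdir(parents=True, exist_ok=True)
        return d

    def _require(self, path: Path, stage: str) -> Path:
        if not path.exists():
            raise StageError(
                f"missing {path.name}: run the {stage!r} stage first")
        return path

    def _record(self, stage: str, **counts: int) -> None:
        self.manifest["stage_counts"][stage] = counts
        self._write_manifest()

    def _write_manifest(self) -> None:
        self.manifest_path.write_text(
            json.dumps(self.manifest, indent=2, sort_keys=True) + "\n")
        rows = []
        for stage, counts in sorted(self.manifest["stage_counts"].items()):
            for key, val in sorted(counts.items()):
                rows.append((stage, key, val))
        with open(self.root / "manifest.tsv", "w") as fh:
            fh.write("stage\tcounter\tvalue\n")
            for stage, key, val in rows:
                fh.write(f"{stage}\t{key}\t{val}\n")

    # -- stage: simulate ---------------------------------------------------

    def simulate(self):
        inputs = self._dir("inputs")
        dataset = generate_all(self.config.synth)
        dataset.write(inputs)
        for p in sorted(inputs.iterdir()):
            self.manifest["input_checksums"][p.name] = _sha256(p)
        self._record(
            "simulate",
            genes=len(dataset.genes),
            planted_ncrnas=len(dataset.truth.structured),
            decoys=len(dataset.truth.decoys),
            mirnas=len(dataset.mirnas),
            datasets=len(dataset.coverage),
        )
        return dataset

    # -- input loading -----------------------------------------------------

    def _load_genome(self):
        inputs = self.root / "inputs"
        genome = read_fasta(self._require(inputs / "genome.fasta", "simulate"))
        genes = read_gff3(self._require(inputs / "annotation.gff3", "simulate"))
        return genome, genes

    def _load_truth(self) -> TruthTable:
        return TruthTable.from_tsv(
            self._require(self.root / "inputs" / "truth.tsv", "simulate"))

    def _load_orthologs(self) -> dict[str, list[SequenceRecord]]:
        inputs = self.root / "inputs"
        out = {}
        for p in sorted(inputs.glob("ortholog_*.fasta")):
            species = p.stem.removeprefix("ortholog_")
            out[species] = read_fasta(p)
        if not out:
            raise StageError("missing ortholog FASTAs: run the 'simulate' "
                             "stage first or provide comparator sequences")
        return out

    def _load_coverage(self) -> list[CoverageTrack]:
        inputs = self.root / "inputs"
        tracks = [CoverageTrack.from_tsv(p)
                  for p in sorted(inputs.glob("coverage_*.tsv"))]
        if not tracks:
            raise StageError("missing coverage tracks: run the 'simulate' "
                             "stage first or provide read-span TSVs")
        return tracks

    # -- stage: extract ----------------------------------------------------

    def extract(self):
        genome, genes = self._load_genome()
        regions = extract_noncoding(genome, genes)
        out = self._dir("01_noncoding")
        df = pd.DataFrame([{
            "region_id": r.region_id, "seqid": r.interval.seqid,
            "start": r.interval.start, "end": r.interval.end,
            "category": r.category,
        } for r in regions])
        df.to_csv(out / "regions.tsv", sep="\t", index=False)
        write_bed([(r.interval, r.region_id) for r in regions],
                  out / "regions.bed")
        self._record("extract", regions=len(regions))
        return regions

    # -- stage: conserve ---------------------------------------------------

    def conserve(self):
        genome, genes = self._load_genome()
        self._require(self.root / "01_noncoding" / "regions.tsv", "extract")
        regions = extract_noncoding(genome, genes)
        orthologs = self._load_orthologs()
        hits = []
        for species in sorted(orthologs):
            hits.extend(pairwise_hits(
                regions, orthologs[species], species,
                max_evalue=self.config.evalue))
        best = best_hit_per_pair(hits)
        blocks = build_blocks(best, regions, orthologs)
        kept = filter_blocks(blocks, min_length=self.config.min_block_len,
                             min_species=self.config.min_species)
        out = self._dir("02_blocks")
        rows = []
        with open(out / "blocks.fasta", "w") as fh:
            for block in kept:
                for species, row in block.rows:
                    fh.write(f">{block.block_id}|{species}\n{row}\n")
        for block in kept:
            rows.append({
                "block_id": block.block_id,
                "seqid": block.reference_interval.seqid,
                "start": block.reference_interval.start,
                "end": block.reference_interval.end,
                "category": block.category,
                "n_species": block.n_species,
                "mean_pairwise_identity": round(block.mean_pairwise_identity, 4),
            })
        pd.DataFrame(rows).to_csv(out / "blocks.tsv", sep="\t", index=False)
        self._record("conserve", hits=len(hits), best_hits=len(best),
                     blocks=len(blocks), blocks_kept=len(kept))
        return kept

    def _load_blocks(self) -> list[AlignmentBlock]:
        out = self.root / "02_blocks"
        idx = pd.read_csv(self._require(out / "blocks.tsv", "conserve"), sep="\t")
        rows_by_block: dict[str, list[tuple[str, str]]] = {}
        from Bio import SeqIO  # aligned FASTA: rows contain gap characters

        for rec in SeqIO.parse(str(out / "blocks.fasta"), "fasta"):
            block_id, species = rec.id.rsplit("|", 1)
            rows_by_block.setdefault(block_id, []).append((species, str(rec.seq)))
        blocks = []
        for _, row in idx.iterrows():
            blocks.append(AlignmentBlock(
                block_id=row["block_id"],
                reference_interval=GenomicInterval(
                    row["seqid"], int(row["start"]), int(row["end"])),
                category=row["category"],
                rows=rows_by_block[row["block_id"]],
                mean_pairwise_identity=float(row["mean_pairwise_identity"]),
            ))
        return blocks

    # -- stage: structure --------------------------------------------------

    def structure(self):
        blocks = self._load_blocks()
        rng = np.random.default_rng([self.config.seed, 100])
        scores = []
        for block in blocks:
            scores.extend(score_block(block, n_shuffles=self.config.n_shuffles,
                                      rng=rng))
        loci = merge_positive_windows(scores, min_p=self.config.p_positive)
        out = self._dir("03_loci")
        pd.DataFrame([{
            "block_id": s.window.block_id,
            "seqid": s.window.reference_interval.seqid,
            "start": s.window.reference_interval.start,
            "end": s.window.reference_interval.end,
            "zscore": round(s.zscore, 4),
            "sci": round(s.sci, 4),
            "identity": round(s.mean_pairwise_identity, 4),
            "probability": round(s.probability, 6),
        } for s in scores]).to_csv(out / "windows.tsv", sep="\t", index=False)
        self._write_loci(loci, out)
        self._record("structure", windows=len(scores),
                     positive_windows=sum(
                         1 for s in scores
                         if s.probability > self.config.p_positive),
                     loci=len(loci),
                     high_confidence=sum(1 for l in loci if l.high_confidence))
        return loci

    def _write_loci(self, loci: list[NcrnaLocus], out: Path) -> None:
        pd.DataFrame([{
            "locus_id": l.locus_id, "seqid": l.interval.seqid,
            "start": l.interval.start, "end": l.interval.end,
            "probability": round(l.probability, 6),
            "n_windows": l.n_windows, "category": l.category,
            "sci": round(l.sci, 4), "zscore": round(l.zscore, 4),
            "high_confidence": int(l.high_confidence),
        } for l in loci]).to_csv(out / "loci.tsv", sep="\t", index=False)
        write_bed([(l.interval, l.locus_id) for l in loci], out / "loci.bed")

    def _load_loci(self) -> list[NcrnaLocus]:
        path = self._require(self.root / "03_loci" / "loci.tsv", "structure")
        df = pd.read_csv(path, sep="\t")
        return [NcrnaLocus(
            locus_id=row["locus_id"],
            interval=GenomicInterval(row["seqid"], int(row["start"]),
                                     int(row["end"])),
            probability=float(row["probability"]),
            n_windows=int(row["n_windows"]),
            category=row["category"],
            sci=float(row["sci"]),
            zscore=float(row["zscore"]),
        ) for _, row in df.iterrows()]

    # -- stage: verify -----------------------------------------------------

    def verify(self):
        loci = self._load_loci()
        tracks = self._load_coverage()
        catalog = None
        known_bed = self.root / "inputs" / "known_ncrnas.bed"
        if known_bed.exists():
            catalog = read_bed(known_bed)
        structure_matches = None
        if self.config.import_structure_tblout:
            structure_matches = import_structure_matches(
                self.config.import_structure_tblout, max_evalue=self.config.evalue)
        flags = verify_loci({l.locus_id: l.interval for l in loci}, tracks,
                            catalog=catalog,
                            structure_matches=structure_matches,
                            min_reads=self.config.min_reads)
        out = self._dir("04_verification")
        pd.DataFrame([{
            "locus_id": lid,
            "known_sequence_match": int(f.known_sequence_match),
            "matched_catalog_ids": ";".join(f.matched_catalog_ids),
            "known_structure_match": int(f.known_structure_match),
            "rfam_ids": ";".join(f.rfam_ids),
            "n_datasets_supporting": f.n_datasets_supporting,
            "supported": int(f.supported),
            "stranded_support_plus": int(f.stranded_support["+"]),
            "stranded_support_minus": int(f.stranded_support["-"]),
        } for lid, f in sorted(flags.items())]).to_csv(
            out / "verification.tsv", sep="\t", index=False)
        self._record("verify", loci=len(loci),
                     known=sum(1 for f in flags.values() if f.known),
                     supported=sum(1 for f in flags.values() if f.supported))
        return flags

    def _load_flags(self):
        from .verification import VerificationFlags

        path = self._require(self.root / "04_verification" / "verification.tsv",
                             "verify")
        df = pd.read_csv(path, sep="\t", keep_default_na=False)
        flags = {}
        for _, row in df.iterrows():
            f = VerificationFlags(
                known_sequence_match=bool(row["known_sequence_match"]),
                matched_catalog_ids=[x for x in str(
                    row["matched_catalog_ids"]).split(";") if x],
                known_structure_match=bool(row["known_structure_match"]),
                rfam_ids=[x for x in str(row["rfam_ids"]).split(";") if x],
                n_datasets_supporting=int(row["n_datasets_supporting"]),
            )
            f.stranded_support["+"] = bool(row["stranded_support_plus"])
            f.stranded_support["-"] = bool(row["stranded_support_minus"])
            flags[row["locus_id"]] = f
        return flags

    # -- stage: classify ---------------------------------------------------

    def classify(self):
        loci = self._load_loci()
        flags = self._load_flags()
        genome, genes = self._load_genome()
        seq_by_id = {r.id: r.sequence for r in genome}
        hexamer = HexamerModel.from_annotation(genome, genes)
        coding = {}
        for locus in loci:
            seq = seq_by_id[locus.interval.seqid][
                locus.interval.start:locus.interval.end]
            coding[locus.locus_id] = coding_potential(seq, hexamer)
        kept, excluded = select_novel_lncrnas(
            loci, flags, genes, coding,
            min_length=self.config.min_lncrna_len,
            min_gene_distance=self.config.lincrna_distance)
        out = self._dir("05_lncrnas")
        records_to_frame(kept).to_csv(out / "lncrnas.tsv", sep="\t", index=False)
        records_to_frame(excluded).to_csv(out / "excluded.tsv", sep="\t",
                                          index=False)
        loci_by_id = {l.locus_id: l for l in loci}
        write_bed([(loci_by_id[r.locus_id].interval, r.biotype)
                   for r in kept], out / "lncrnas.bed")
        counts = {}
        for biotype in ("lincRNA", "lncNAT", "sense-intronic"):
            counts[biotype.replace("-", "_")] = sum(
                1 for r in kept if r.biotype == biotype)
        self._record("classify", retained=len(kept), excluded=len(excluded),
                     **counts)
        return kept, excluded

    def _load_lncrnas(self):
        path = self._require(self.root / "05_lncrnas" / "lncrnas.tsv",
                             "classify")
        return pd.read_csv(path, sep="\t", keep_default_na=False)

    # -- stage: de ---------------------------------------------------------

    def de(self):
        lnc = self._load_lncrnas()
        loci_by_id = {l.locus_id: l for l in self._load_loci()}
        genome, genes = self._load_genome()
        truth = self._load_truth()
        lnc_features = [(row["locus_id"], loci_by_id[row["locus_id"]].interval)
                        for _, row in lnc.iterrows()]
        gene_features = [(g.gene_id, g.interval) for g in genes]
        counts = simulate_counts(truth, genes, self.config.synth,
                                 features=lnc_features + gene_features)
        out = self._dir("06_de")
        all_results = {}
        for cond in ("cold", "drought"):
            merged = counts["control"]
            stress = counts[cond]
            joint = np.hstack([merged.counts, stress.counts])
            from .genome_io import CountMatrix

            cm = CountMatrix(
                list(merged.feature_ids), merged.feature_lengths,
                merged.sample_ids + stress.sample_ids, joint)
            getmm_normalize(cm).to_tsv(out / f"counts_{cond}.tsv",
                                       normalized=True)
            lnc_ids = {fid for fid, _iv in lnc_features}
            results = []
            for cls_name, members in (
                    ("lncRNA", lnc_ids),
                    ("gene", {fid for fid, _iv in gene_features})):
                sub = cm.subset([f for f in cm.feature_ids if f in members])
                res = nb_test(sub, merged.sample_ids, stress.sample_ids, cond)
                call_de(res, min_abs_log2fc=self.config.de_log2fc,
                        max_q=self.config.de_q)
                results.extend(res)
                _ = cls_name
            results_to_frame(results).to_csv(out / f"de_{cond}.tsv", sep="\t",
                                             index=False)
            all_results[cond] = results
        sig_lnc = {c: {r.feature_id for r in rs
                       if r.significant and r.feature_id in set(lnc["locus_id"])}
                   for c, rs in all_results.items()}
        venn = venn_partition(sig_lnc)
        with open(out / "venn.tsv", "w") as fh:
            fh.write("partition\tn\tids\n")
            for key in sorted(venn):
                fh.write(f"{key}\t{len(venn[key])}\t{';'.join(sorted(venn[key]))}\n")
        counts_rec = {}
        for cond, rs in all_results.items():
            sig = [r for r in rs if r.significant]
            counts_rec[f"{cond}_significant"] = len(sig)
            counts_rec[f"{cond}_up"] = sum(1 for r in sig if r.log2fc > 0)
            counts_rec[f"{cond}_down"] = sum(1 for r in sig if r.log2fc < 0)
        counts_rec["shared_lncrnas"] = len(venn["shared"])
        self._record("de", **counts_rec)
        return all_results

    def _load_de(self):
        out = self.root / "06_de"
        results = {}
        for cond in ("cold", "drought"):
            path = self._require(out / f"de_{cond}.tsv", "de")
            results[cond] = pd.read_csv(path, sep="\t")
        return results

    # -- stage: targets ----------------------------------------------------

    def targets(self):
        de_results = self._load_de()
        lnc = self._load_lncrnas()
        loci_by_id = {l.locus_id: l.interval for l in self._load_loci()}
        genome, genes = self._load_genome()
        seq_by_id = {r.id: r.sequence for r in genome}
        mirnas = read_fasta(
            self._require(self.root / "inputs" / "mirnas.fasta", "simulate"))
        lnc_ids = set(lnc["locus_id"])
        de_lnc: dict[str, set[str]] = {}
        de_gene: dict[str, set[str]] = {}
        for cond, df in de_results.items():
            sig = df[df["significant"] == 1]
            de_lnc[cond] = set(sig["feature_id"]) & lnc_ids
            de_gene[cond] = set(sig["feature_id"]) - lnc_ids
        lnc_seqs = {
            lid: seq_by_id[iv.seqid][iv.start:iv.end]
            for lid, iv in loci_by_id.items() if lid in lnc_ids
        }
        mrna_seqs = {g.gene_id: g.spliced_sequence(seq_by_id[g.interval.seqid])
                     for g in genes}
        edges = []
        edges += cis_targets(de_lnc, de_gene, loci_by_id, genes,
                             max_distance=self.config.cis_distance)
        edges += trans_binding_targets(
            de_lnc, de_gene, lnc_seqs, mrna_seqs,
            energy_per_nt=self.config.trans_energy_per_nt)
        edges += mimicry_targets(de_lnc, de_gene, lnc_seqs, mrna_seqs, mirnas,
                                 max_mismatch=self.config.mimicry_mismatch)
        out = self._dir("07_targets")
        edges_to_frame(edges).to_csv(out / "edges.tsv", sep="\t", index=False)
        site_rows = []
        for e in edges:
            if e.mode != "mimicry":
                continue
            for side, sites in (("lncrna", e.lncrna_sites),
                                ("gene", e.gene_sites)):
                for s in sites or []:
                    site_rows.append({
                        "edge": f"{e.lncrna_id}->{e.gene_id}", "side": side,
                        "host_id": s.host_id, "mirna_id": s.mirna_id,
                        "offset": s.offset, "orientation": s.orientation,
                        "mismatches": s.mismatches,
                    })
        pd.DataFrame(site_rows).to_csv(out / "mimicry_sites.tsv", sep="\t",
                                       index=False)
        self._record(
            "targets",
            cis=sum(1 for e in edges if e.mode == "cis"),
            trans_binding=sum(1 for e in edges if e.mode == "trans_binding"),
            mimicry=sum(1 for e in edges if e.mode == "mimicry"),
        )
        return edges

    # -- stage: enrich -----------------------------------------------------

    def enrich(self):
        edges_path = self._require(self.root / "07_targets" / "edges.tsv",
                                   "targets")
        edges = pd.read_csv(edges_path, sep="\t")
        gene2go = pd.read_csv(
            self._require(self.root / "inputs" / "gene2go.tsv", "simulate"),
            sep="\t")
        _genome, genes = self._load_genome()
        background = {g.gene_id for g in genes}
        out = self._dir("08_enrichment")
        n_enriched = {}
        for cond in ("cold", "drought"):
            sub = edges[edges["condition"] == cond] if len(edges) else edges
            targets = set(sub["gene_id"]) & background if len(sub) else set()
            results = go_enrich(targets, background, gene2go,
                                max_fdr=self.config.enrich_fdr)
            pd.DataFrame([{
                "go_id": r.go_id, "k": r.k, "K": r.K, "n": r.n, "N": r.N,
                "p": r.p, "fdr": r.fdr,
                "enriched": int(r.fdr <= self.config.enrich_fdr),
            } for r in results]).to_csv(out / f"enrichment_{cond}.tsv",
                                        sep="\t", index=False)
            n_enriched[cond] = sum(
                1 for r in results if r.fdr <= self.config.enrich_fdr)
        self._record("enrich", cold_enriched=n_enriched.get("cold", 0),
                     drought_enriched=n_enriched.get("drought", 0))
        return n_enriched

    # -- stage: summarize --------------------------------------------------

    def summarize(self) -> pd.DataFrame:
        counts = self.manifest.get("stage_counts", {})
        rows = []
        missing = [s for s in STAGE_ORDER[:-1] if s not in counts]
        for stage in STAGE_ORDER[:-1]:
            for key, val in sorted(counts.get(stage, {}).items()):
                rows.append({"stage": stage, "counter": key, "value": val})
        df = pd.DataFrame(rows)
        df.to_csv(self.root / "summary.tsv", sep="\t", index=False)
        lines = ["lncscreen run summary", "====================="]
        for stage in STAGE_ORDER[:-1]:
            if stage in counts:
                body = ", ".join(f"{k}={v}" for k, v in
                                 sorted(counts[stage].items()))
                lines.append(f"{stage}: {body}")
            else:
                lines.append(f"{stage}: (not run)")
        if missing:
            lines.append(f"incomplete run; missing stages: {', '.join(missing)}")
        (self.root / "summary.txt").write_text("\n".join(lines) + "\n")
        return df

    # -- orchestration -----------------------------------------------------

    def run_stage(self, name: str):
        if name not in STAGE_ORDER:
            raise StageError(f"unknown stage {name!r}")
        return getattr(self, name)()

    def run_all(self):
        for stage in STAGE_ORDER:
            self.run_stage(stage)
        return self


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    synth = d.pop("synth")
    if isinstance(synth.get("ortholog_divergence"), dict):
        synth["ortholog_divergence"] = dict(synth["ortholog_divergence"])
    d["synth"] = synth
    return d


def run_all(config: PipelineConfig) -> PipelineRun:
    """Execute every stage under ``config.run_dir`` and return the run."""
    run = PipelineRun(config)
    return run.run_all()


_ = replace  # re-exported convenience for building variant configs
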