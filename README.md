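# lncscreen

Comparative, structure-based discovery of plant long non-coding RNAs
(lncRNAs) and inference of their stress-response functions — built as a
reusable pipeline and validated end-to-end on synthetic genomes with
planted truth.

## The problem

Plant genomes encode thousands of lncRNAs (>200 nt, no protein-coding
capacity) that regulate development and stress response, but they are
poorly conserved in primary sequence and expressed at low levels, which
makes them hard to find by expression alone. A complementary signal is
*structural* conservation: a functional RNA element folds into an unusually
stable secondary structure whose base pairs are maintained across species
through compensatory (covarying) substitutions. `lncscreen` implements the
full screen built on that signal:

1. extract the non-coding search space (introns, UTRs, intergenic spans);
2. find regions conserved in ≥3 species (local alignment, E < 0.01; ≥50 bp);
3. score 120-nt windows (80-nt overlap) for conserved structure — minimum
   free energy *E*, thermodynamic z-score
   `z = (E − ⟨E_shuffled⟩)/σ(E_shuffled)` over dinucleotide-preserving
   shuffles, structure conservation index `SCI = E_consensus/⟨E_single⟩` —
   and convert them to a probability *P*; merge positive windows (P > 0.5)
   into predicted loci (high confidence at P > 0.9);
4. verify loci against known-ncRNA catalogs and expression evidence
   (≥10 reads covering 100% of the locus in ≥1 dataset; GeTMM-normalized
   counts);
5. keep novel supported loci >200 nt with negative coding-potential score
   and classify them as lincRNA (>500 nt from flanking genes), lncNAT
   (antisense gene overlap with strand-specific support) or sense-intronic
   (genic, no CDS overlap);
6. call differential expression per stress condition (negative-binomial
   Wald test; |log2FC| ≥ 2, BH q ≤ 0.05);
7. infer targets of DE lncRNAs — *cis* (DE gene within 10 kb), *trans*
   direct binding (optimal RNA:RNA hybridization energy), and miRNA target
   mimicry (shared miRNA site, ≤2 mismatches) — and summarize target-gene
   function by hypergeometric GO enrichment (BH FDR ≤ 0.05).

Because the original inputs (a reference genome, six comparator genomes,
74 RNA-seq libraries) are far beyond desk scale, the package ships a
first-class synthetic-data generator that emulates the statistical
structure every stage assumes — orthologs at controlled divergence with
covariation-preserving structured elements, negative-binomial counts with
planted fold changes, coverage tracks, planted miRNA sites and binding
cassettes — so the whole pipeline runs and is scored against known truth
in minutes. See `docs/methods.md` for models, calibrations and
limitations.

## Worked example

```python
from lncscreen.pipeline import PipelineConfig, run_all
from lncscreen.evaluation import evaluate_run

config = PipelineConfig(run_dir="run", seed=7)
run_all(config)                      # ~2 minutes on one core
print(open("run/summary.txt").read())
ev = evaluate_run("run")
print(f"planted recovery {100*ev.planted_recovery:.0f}%, "
      f"decoy false positives {100*ev.decoy_fp_rate:.0f}%")
```

prints (seed 7):

```
lncscreen run summary
=====================
simulate: datasets=8, decoys=10, genes=20, mirnas=5, planted_ncrnas=20
extract: regions=96
conserve: best_hits=104, blocks=37, blocks_kept=30, hits=159
structure: high_confidence=20, loci=20, positive_windows=20, windows=30
verify: known=0, loci=20, supported=20
classify: excluded=0, lincRNA=8, lncNAT=5, retained=20, sense_intronic=7
de: cold_down=6, cold_significant=18, cold_up=12, drought_down=5,
    drought_significant=18, drought_up=13, shared_lncrnas=3
targets: cis=42, mimicry=3, trans_binding=3
enrich: cold_enriched=0, drought_enriched=1

planted recovery 100%, decoy false positives 0%
```

Reading this: the generator planted 20 structured ncRNAs and 10
unstructured decoys in a 100-kb genome with 3 diverged ortholog sets; 30
conserved blocks survived the ≥50 bp / ≥3-species filter; the structure
screen called exactly the 20 planted loci (all at P > 0.9) and no decoys;
all 20 passed expression support and were classified into their intended
biotypes; the DE stage recovered the planted |log2FC| = 4 effects, and the
target stage recovered the planted cis pairs, the three binding cassettes
and the three mimicry triples. Counters obey the pipeline's bookkeeping
(up + down = significant per condition; biotypes sum to retained loci).

The same pipeline runs from the shell:

```bash
lncscreen all --run-dir run --seed 7      # or stage by stage:
lncscreen simulate --run-dir run --seed 7
lncscreen extract  --run-dir run
...
lncscreen summarize --run-dir run
```

Each stage reads its dependencies from the run directory, so externally
produced inputs (BLAST outfmt-6 hit tables, multi-FASTA alignments, screen
window output, DESeq2-style result tables, CPC/Pfam hit tables, Infernal
tblout matches) can replace any internal computation.

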