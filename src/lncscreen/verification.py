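"""Verification of predicted loci: known-ncRNA matches, expression support,
GeTMM count normalization.

A predicted locus is *known* if it overlaps a catalog entry (sequence match)
or carries an imported structural-family match below the E-value cutoff, and
*expression supported* in a dataset when at least ``min_reads`` read spans
overlap it and their union covers 100% of its length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genome_io import CountMatrix, FormatError, GenomicInterval, interval_merge

__all__ = [
    "CoverageTrack",
    "VerificationFlags",
    "match_known_sequence",
    "import_structure_matches",
    "expression_support",
    "verify_loci",
    "getmm_normalize",
    "tmm_factors",
]


@dataclass
class CoverageTrack:
    """Read spans of one RNA-seq dataset (the contract read alignment fulfils).

    ``spans`` maps seqid to sorted (start, end, strand) tuples; strand is '.'
    for unstranded libraries.
    """

    dataset_id: str
    stranded: bool
    spans: dict[str, list[tuple[int, int, str]]] = field(default_factory=dict)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#dataset_id={self.dataset_id}\tstranded={int(self.stranded)}\n")
            fh.write("seqid\tstart\tend\tstrand\n")
            for seqid in sorted(self.spans):
                for s, e, st in self.spans[seqid]:
                    fh.write(f"{seqid}\t{s}\t{e}\t{st}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CoverageTrack":
        spans: dict[str, list[tuple[int, int, str]]] = {}
        dataset_id = Path(path).stem
        stranded = False
        with open(path) as fh:
            first = fh.readline().strip()
            if first.startswith("#"):
                for token in first[1:].split("\t"):
                    key, _, val = token.partition("=")
                    if key == "dataset_id":
                        dataset_id = val
                    elif key == "stranded":
                        stranded = bool(int(val))
                header = fh.readline()
            else:
                header = first
            if not header.startswith("seqid"):
                raise FormatError(f"{path}: missing coverage header")
            for line in fh:
                seqid, s, e, st = line.rstrip("\n").split("\t")
                spans.setdefault(seqid, []).append((int(s), int(e), st))
        for lst in spans.values():
            lst.sort()
        return cls(dataset_id, stranded, spans)


@dataclass
class VerificationFlags:
    """Per-locus verification outcome."""

    known_sequence_match: bool = False
    matched_catalog_ids: list[str] = field(default_factory=list)
    known_structure_match: bool = False
    rfam_ids: list[str] = field(default_factory=list)
    n_datasets_supporting: int = 0
    # support restricted to stranded libraries, per strand of the locus
    stranded_support: dict[str, bool] = field(
        default_factory=lambda: {"+": False, "-": False})

    @property
    def supported(self) -> bool:
        return self.n_datasets_supporting >= 1

    @property
    def known(self) -> bool:
        return self.known_sequence_match or self.known_structure_match


def match_known_sequence(loci: dict[str, GenomicInterval],
                         catalog: list[tuple[GenomicInterval, str]],
                         known_seqids: set[str] | None = None,
                         min_overlap_fraction: float = 0.0
                         ) -> dict[str, list[str]]:
    """Overlap loci against a known-ncRNA catalog (either strand).

    A locus matches an entry when it overlaps by at least 1 nt and, when
    ``min_overlap_fraction`` > 0, by at least that fraction of the locus
    length.  Catalog entries on seqids absent from ``known_seqids`` are
    skipped with a warning.
    """
    if known_seqids is None:
        known_seqids = {iv.seqid for iv in loci.values()}
    usable = []
    for iv, name in catalog:
        if iv.seqid not in known_seqids:
            warnings.warn(f"catalog entry {name} on unknown seqid {iv.seqid}; skipped")
            continue
        usable.append((iv, name))
    out: dict[str, list[str]] = {}
    for locus_id, locus in loci.items():
        matches = []
        for iv, name in usable:
            ov = locus.overlap_length(iv)
            if ov >= 1 and ov >= min_overlap_fraction * locus.length:
                matches.append(name)
        if matches:
            out[locus_id] = sorted(set(matches))
    return out


def import_structure_matches(path: str | Path, max_evalue: float = 0.01
                             ) -> dict[str, list[str]]:
    """Read an Infernal tblout-style (or 3-column TSV) structural-match table.

    Rows with E-value < ``max_evalue`` flag the named locus with the matching
    family.  tblout dialect: whitespace columns with target name first, query
    name third and E-value in column 16; TSV dialect: locus_id, family_id,
    evalue.  Malformed rows raise :class:`FormatError` with the line number.
    """
    out: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            try:
                if len(fields) >= 16:          # Infernal tblout
                    family, locus_id, evalue = fields[0], fields[2], float(fields[15])
                elif len(fields) == 3:         # TSV: locus, family, E
                    locus_id, family, evalue = fields[0], fields[1], float(fields[2])
                else:
                    raise ValueError("unrecognized column count")
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: malformed row ({exc})") from exc
            if evalue < max_evalue:
                out.setdefault(locus_id, []).append(family)
    return {k: sorted(set(v)) for k, v in out.items()}


def expression_support(locus: GenomicInterval, track: CoverageTrack,
                       min_reads: int = 10, strand: str | None = None
                       ) -> tuple[bool, int, float]:
    """(supported, n_reads, breadth) for one locus against one dataset.

    ``n_reads`` counts read spans overlapping the locus by >=1 nt; ``breadth``
    is the covered fraction of the locus by the union of those spans.
    Support requires ``n_reads >= min_reads`` and breadth exactly 1.0.  When
    ``strand`` is given, only spans on that strand are counted (for stranded
    libraries feeding the antisense-transcript call).
    """
    spans = track.spans.get(locus.seqid, [])
    hit = []
    for s, e, st in spans:
        if e <= locus.start or s >= locus.end:
            continue
        if strand is not None and st != strand:
            continue
        hit.append((s, e))
    n_reads = len(hit)
    if not hit:
        return False, 0, 0.0
    ivs = [GenomicInterval(locus.seqid, s, e) for s, e in hit]
    covered = 0
    for m in interval_merge(ivs, 0):
        covered += m.overlap_length(locus)
    breadth = covered / locus.length
    return (n_reads >= min_reads and breadth == 1.0), n_reads, breadth


def verify_loci(loci: dict[str, GenomicInterval],
                tracks: list[CoverageTrack],
                catalog: list[tuple[GenomicInterval, str]] | None = None,
                structure_matches: dict[str, list[str]] | None = None,
                min_reads: int = 10) -> dict[str, VerificationFlags]:
    """Combine sequence/structure matches and expression support per locus."""
    seq_matches = (match_known_sequence(loci, catalog) if catalog else {})
    structure_matches = structure_matches or {}
    out: dict[str, VerificationFlags] = {}
    for locus_id, locus in loci.items():
        flags = VerificationFlags()
        if locus_id in seq_matches:
            flags.known_sequence_match = True
            flags.matched_catalog_ids = seq_matches[locus_id]
        if locus_id in structure_matches:
            flags.known_structure_match = True
            flags.rfam_ids = structure_matches[locus_id]
        n_support = 0
        for track in tracks:
            ok, _n, _b = expression_support(locus, track, min_reads)
            if ok:
                n_support += 1
            if track.stranded:
                for strand in ("+", "-"):
                    sok, _sn, _sb = expression_support(
                        locus, track, min_reads, strand=strand)
                    if sok:
                        flags.stranded_support[strand] = True
        flags.n_datasets_supporting = n_support
        out[locus_id] = flags
    return out


# ---------------------------------------------------------------------------
# GeTMM

def tmm_factors(rpk: np.ndarray, trim_m: float = 0.30, trim_a: float = 0.05
                ) -> np.ndarray:
    """Trimmed-mean-of-M-values scale factors on an RPK matrix.

    The reference sample is the one whose upper-quartile (of library-scaled
    values) is closest to the mean upper-quartile.  Per-feature log2 ratios
    (M) are trimmed 30% on M and 5% on A with precision weights, following
    the edgeR conventions; factors are rescaled to geometric mean 1.
    """
    rpk = np.asarray(rpk, dtype=float)
    nfeat, nsamp = rpk.shape
    lib = rpk.sum(axis=0)
    if np.any(lib == 0):
        warnings.warn("all-zero sample; its scale factor is set to 1")
    safe_lib = np.where(lib > 0, lib, 1.0)
    frac = rpk / safe_lib
    uq = np.array([
        np.quantile(frac[:, j][rpk[:, j] > 0], 0.75) if (rpk[:, j] > 0).any() else 0.0
        for j in range(nsamp)
    ])
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    factors = np.ones(nsamp)
    for j in range(nsamp):
        if j == ref or lib[j] == 0:
            continue
        mask = (rpk[:, j] > 0) & (rpk[:, ref] > 0)
        if mask.sum() < 2:
            continue
        fj, fr = frac[mask, j], frac[mask, ref]
        m = np.log2(fj / fr)
        a = 0.5 * np.log2(fj * fr)
        # asymptotic binomial precision weights
        w = 1.0 / ((lib[j] - rpk[mask, j]) / (lib[j] * rpk[mask, j])
                   + (lib[ref] - rpk[mask, ref]) / (lib[ref] * rpk[mask, ref]))
        n = len(m)
        m_rank = m.argsort().argsort()
        a_rank = a.argsort().argsort()
        keep = ((m_rank >= trim_m * n) & (m_rank < (1 - trim_m) * n)
                & (a_rank >= trim_a * n) & (a_rank < (1 - trim_a) * n))
        if not keep.any():
            continue
        factors[j] = 2.0 ** (np.sum(w[keep] * m[keep]) / np.sum(w[keep]))
    log_f = np.log(factors)
    factors = factors / np.exp(log_f.mean())
    return factors


def getmm_normalize(matrix: CountMatrix, trim_m: float = 0.30,
                    trim_a: float = 0.05) -> CountMatrix:
    """Gene-length-corrected TMM normalization.

    Counts are converted to reads-per-kilobase, TMM scale factors computed on
    the RPK matrix, and normalized values are RPK scaled to per-million by
    the factor-adjusted RPK library size.  Identical libraries give all
    factors 1; doubling a library leaves its normalized values unchanged.
    """
    rpk = matrix.counts / (matrix.feature_lengths[:, None] / 1000.0)
    factors = tmm_factors(rpk, trim_m=trim_m, trim_a=trim_a)
    lib = rpk.sum(axis=0)
    eff = np.where(lib > 0, lib * factors, 1.0)
    normalized = rpk / eff[None, :] * 1e6
    return CountMatrix(
        list(matrix.feature_ids), matrix.feature_lengths.copy(),
        list(matrix.sample_ids), matrix.counts.copy(), normalized)
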