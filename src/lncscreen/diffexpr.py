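"""Negative-binomial differential expression for stress vs control contrasts.

A self-contained median-of-ratios + moderated-dispersion Wald test stands in
for a full GLM framework: size factors are median-of-ratios, per-feature NB
dispersions are moment estimates moderated 50/50 toward the trimmed-mean
common dispersion (with a floor), fold changes come from normalized group
means with a 0.5 pseudo-count, and two-sided Wald p-values are BH-adjusted
per feature class and condition.  Externally computed result tables
(log2FoldChange / padj columns) can be imported to run in faithful mode.

Significance uses the stress-transcriptomics convention: |log2FC| >= 2 and
q <= 0.05, both inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome_io import CountMatrix

__all__ = [
    "DEResult",
    "size_factors",
    "nb_test",
    "call_de",
    "benjamini_hochberg",
    "read_deseq2_results",
    "venn_partition",
]

DISPERSION_FLOOR = 0.01
MODERATION_PRIOR_DF = 6


@dataclass
class DEResult:
    """Per-feature differential-expression outcome for one condition."""

    feature_id: str
    condition: str
    base_mean: float
    log2fc: float
    se_log2fc: float
    p_value: float
    q_value: float
    significant: bool


def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors (features x samples).

    Features with a zero count in any sample are excluded from the median;
    when none remain, library-size ratios are used with a warning.
    """
    counts = np.asarray(counts, dtype=float)
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        import warnings

        warnings.warn("no feature free of zeros; falling back to library sizes")
        lib = counts.sum(axis=0)
        lib = np.where(lib > 0, lib, 1.0)
        return lib / np.exp(np.mean(np.log(lib)))
    sub = counts[positive]
    log_geo = np.mean(np.log(sub), axis=1, keepdims=True)
    ratios = np.log(sub) - log_geo
    return np.exp(np.median(ratios, axis=0))


def _trimmed_mean(x: np.ndarray, trim: float = 0.2) -> float:
    if len(x) == 0:
        return 0.0
    return float(stats.trim_mean(x, trim)) if len(x) > 4 else float(np.mean(x))


def nb_test(matrix: CountMatrix, group_a: list[str], group_b: list[str],
            condition: str = "", alpha_floor: float = DISPERSION_FLOOR
            ) -> list[DEResult]:
    """Wald test of group_b (stress) vs group_a (control) per feature.

    Dispersion per feature is max(moment estimate, floor) blended 50/50 with
    the trimmed-mean common dispersion; log2FC is computed from normalized
    group means with a 0.5 pseudo-count; the NB-based standard error feeds a
    two-sided normal Wald p-value, BH-adjusted across the tested features.

    Raises ``ValueError`` when either group has fewer than 2 replicates.
    """
    for name, grp in (("control", group_a), (condition or "stress", group_b)):
        if len(grp) < 2:
            raise ValueError(f"group {name!r} needs >= 2 replicates")
    ia = [matrix.sample_ids.index(s) for s in group_a]
    ib = [matrix.sample_ids.index(s) for s in group_b]
    counts = np.asarray(matrix.counts, dtype=float)
    sf = size_factors(counts[:, ia + ib])
    sf_a, sf_b = sf[: len(ia)], sf[len(ia):]
    norm_a = counts[:, ia] / sf_a
    norm_b = counts[:, ib] / sf_b
    norm_all = np.hstack([norm_a, norm_b])

    # moment dispersion on the normalized scale, per group, pooled
    def moment_alpha(x: np.ndarray) -> np.ndarray:
        m = x.mean(axis=1)
        v = x.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (v - m) / np.where(m > 0, m * m, 1.0)
        return np.where(m > 0, np.maximum(a, 0.0), 0.0)

    alpha_feat = 0.5 * (moment_alpha(norm_a) + moment_alpha(norm_b))
    common = max(_trimmed_mean(alpha_feat[np.isfinite(alpha_feat)]), alpha_floor)
    alpha = 0.5 * np.maximum(alpha_feat, alpha_floor) + 0.5 * common

    mean_a = norm_a.mean(axis=1)
    mean_b = norm_b.mean(axis=1)
    log2fc = np.log2(mean_b + 0.5) - np.log2(mean_a + 0.5)
    base_mean = norm_all.mean(axis=1)

    ln2_sq = np.log(2.0) ** 2

    def var_log2_mean(mean: np.ndarray, n: int) -> np.ndarray:
        mu = mean + 0.5
        return (mu + alpha * mu * mu) / (n * mu * mu * ln2_sq)

    se = np.sqrt(var_log2_mean(mean_a, len(ia)) + var_log2_mean(mean_b, len(ib)))
    wald = log2fc / np.maximum(se, 1e-12)
    # t reference: residual df plus prior df contributed by the 50/50
    # moderation of dispersions toward the common value
    df = len(ia) + len(ib) - 2 + MODERATION_PRIOR_DF
    p = 2.0 * stats.t.sf(np.abs(wald), df)
    q = benjamini_hochberg(p)
    out = []
    for i, fid in enumerate(matrix.feature_ids):
        out.append(DEResult(
            feature_id=fid, condition=condition,
            base_mean=float(base_mean[i]), log2fc=float(log2fc[i]),
            se_log2fc=float(se[i]), p_value=float(p[i]), q_value=float(q[i]),
            significant=False))
    return out


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """BH-adjusted q-values (monotone in p-rank, q >= p)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def call_de(results: list[DEResult], min_abs_log2fc: float = 2.0,
            max_q: float = 0.05) -> list[DEResult]:
    """Flag significance in place: |log2FC| >= threshold and q <= threshold,
    both inclusive as printed; returns the significant subset."""
    sig = []
    for r in results:
        r.significant = (abs(r.log2fc) >= min_abs_log2fc and r.q_value <= max_q)
        if r.significant:
            sig.append(r)
    return sig


def venn_partition(sig_by_condition: dict[str, set[str]]
                   ) -> dict[str, set[str]]:
    """Shared / condition-specific partition of significant feature sets."""
    conditions = sorted(sig_by_condition)
    if len(conditions) != 2:
        raise ValueError("venn partition expects exactly two conditions")
    a, b = conditions
    shared = sig_by_condition[a] & sig_by_condition[b]
    return {
        "shared": shared,
        f"{a}_specific": sig_by_condition[a] - shared,
        f"{b}_specific": sig_by_condition[b] - shared,
    }


def read_deseq2_results(path: str | Path, condition: str,
                        min_abs_log2fc: float = 2.0, max_q: float = 0.05
                        ) -> list[DEResult]:
    """Import an externally produced result TSV (faithful mode).

    Requires columns log2FoldChange and padj; optional baseMean, pvalue,
    lfcSE.  Rows with missing padj are treated as q = 1.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if not {"log2FoldChange", "padj"}.issubset(df.columns):
        raise ValueError("result table needs log2FoldChange and padj columns")
    out = []
    for fid, row in df.iterrows():
        q = row["padj"]
        q = 1.0 if pd.isna(q) else float(q)
        lfc = float(row["log2FoldChange"])
        out.append(DEResult(
            feature_id=str(fid), condition=condition,
            base_mean=float(row.get("baseMean", np.nan)),
            log2fc=lfc,
            se_log2fc=float(row.get("lfcSE", np.nan)),
            p_value=float(row.get("pvalue", q)),
            q_value=q,
            significant=abs(lfc) >= min_abs_log2fc and q <= max_q))
    return out


def results_to_frame(results: list[DEResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "feature_id": r.feature_id, "condition": r.condition,
        "base_mean": r.base_mean, "log2fc": r.log2fc,
        "se_log2fc": r.se_log2fc, "p_value": r.p_value,
        "q_value": r.q_value, "significant": int(r.significant),
    } for r in results])
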