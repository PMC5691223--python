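"""Expression profiling, venom-gland specificity calling and qPCR folds.

FPKM matrices (genes x samples) are profiled on a log2 scale; genes
never exceeding 1 FPKM anywhere are flagged as putative pseudogenes.
Venom-gland-specific genes are called with a three-part threshold —
BH-adjusted p < 0.001, log2(FPKM_VG / FPKM_carcass) > 1 and
FPKM_VG > 10.  The per-gene p-value comes from a declared stand-in
test: an exact one-sided binomial test on FPKM-scaled pseudo-counts
(venom-gland counts out of venom-gland + carcass, null p = 0.5); the
engine is deliberately simple, deterministic and swappable.  Relative
qPCR expression uses the 2^-ddCt method with replicate Ct values
averaged per (gene, sample) before delta-Ct.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: pseudo-count multiplier converting FPKM to binomial counts
DEFAULT_LIBRARY_SCALE = 10.0

#: three-part venom-specificity threshold
P_ADJ_THRESHOLD = 0.001
LOG2_RATIO_THRESHOLD = 1.0
FPKM_VG_THRESHOLD = 10.0

#: FPKM above which a gene counts as expressed somewhere
PSEUDOGENE_MAX_FPKM = 1.0


class ExpressionError(ValueError):
    pass


@dataclass(frozen=True)
class VenomCall:
    """Venom-gland specificity call for one gene."""

    gene_id: str
    fpkm_vg: float
    fpkm_carcass: float
    log2_ratio: float
    p_raw: float
    p_adj: float

    @property
    def passed(self) -> bool:
        return (
            self.p_adj < P_ADJ_THRESHOLD
            and self.log2_ratio > LOG2_RATIO_THRESHOLD
            and self.fpkm_vg > FPKM_VG_THRESHOLD
        )


def _check_matrix(mat: pd.DataFrame) -> None:
    if mat.columns.duplicated().any():
        raise ExpressionError("duplicate sample ids")
    if (mat.to_numpy() < 0).any():
        raise ExpressionError("negative FPKM values")


def log2_profile(mat: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Elementwise log2(FPKM + pseudocount); ordering preserved."""
    if pseudocount <= 0:
        raise ExpressionError("pseudocount must be positive")
    _check_matrix(mat)
    return np.log2(mat + pseudocount)


def flag_pseudogene(mat: pd.DataFrame, gene: str) -> bool:
    """True iff the gene never exceeds 1 FPKM in any sample."""
    _check_matrix(mat)
    if gene not in mat.index:
        raise ExpressionError(f"gene {gene!r} not in matrix")
    return bool(mat.loc[gene].max() <= PSEUDOGENE_MAX_FPKM)


def venom_specificity_test(
    fpkm_vg: float, fpkm_carcass: float, library_scale: float = DEFAULT_LIBRARY_SCALE
) -> float:
    """One-sided exact binomial p-value for venom-gland enrichment.

    k = round(FPKM_VG * scale) successes out of
    n = round((FPKM_VG + FPKM_carcass) * scale) trials against p0=0.5;
    n = 0 returns 1.0 (no evidence).
    """
    if library_scale <= 0:
        raise ExpressionError("library_scale must be positive")
    if fpkm_vg < 0 or fpkm_carcass < 0:
        raise ExpressionError("FPKM values must be non-negative")
    k = int(round(fpkm_vg * library_scale))
    n = int(round((fpkm_vg + fpkm_carcass) * library_scale))
    if n == 0:
        return 1.0
    k = min(k, n)
    return float(stats.binomtest(k, n, 0.5, alternative="greater").pvalue)


def bh_adjust(pvals) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, clipped to 1.

    The output preserves the input order and is monotone in ranks.
    """
    arr = np.asarray(list(pvals), dtype=float)
    if arr.size == 0:
        return []
    if np.any((arr < 0) | (arr > 1)) or np.any(np.isnan(arr)):
        raise ExpressionError("p-values must lie in [0, 1]")
    adjusted = multipletests(arr, method="fdr_bh")[1]
    return [float(p) for p in adjusted]


def call_venom_specific(
    mat: pd.DataFrame,
    vg_sample: str,
    carcass_sample: str,
    library_scale: float = DEFAULT_LIBRARY_SCALE,
) -> list[VenomCall]:
    """Apply the three-part venom-specificity threshold to every gene.

    log2 ratios use a pseudocount of 1 in numerator and denominator; BH
    adjustment runs across all genes of the matrix.
    """
    _check_matrix(mat)
    for sample in (vg_sample, carcass_sample):
        if sample not in mat.columns:
            raise ExpressionError(f"sample {sample!r} not in matrix")
    genes = list(mat.index)
    vg = mat[vg_sample].to_numpy(dtype=float)
    car = mat[carcass_sample].to_numpy(dtype=float)
    p_raw = [venom_specificity_test(v, c, library_scale) for v, c in zip(vg, car)]
    p_adj = bh_adjust(p_raw)
    log2_ratio = np.log2((vg + 1.0) / (car + 1.0))
    return [
        VenomCall(
            gene_id=g,
            fpkm_vg=float(v),
            fpkm_carcass=float(c),
            log2_ratio=float(r),
            p_raw=float(pr),
            p_adj=float(pa),
        )
        for g, v, c, r, pr, pa in zip(genes, vg, car, log2_ratio, p_raw, p_adj)
    ]


def ddct(
    ct: pd.DataFrame,
    target_gene: str,
    ref_gene: str,
    calibrator_sample: str,
) -> pd.Series:
    """Relative expression by the 2^-ddCt method, per sample.

    ``ct`` has columns gene, sample, replicate, ct.  Replicate Ct values
    are averaged per (gene, sample) first; then
    dCt_s = Ct_target,s - Ct_ref,s, ddCt_s = dCt_s - dCt_calibrator and
    fold_s = 2^-ddCt_s, so the calibrator fold is 1 by construction.
    """
    required = {"gene", "sample", "replicate", "ct"}
    if not required <= set(ct.columns):
        raise ExpressionError(f"Ct table needs columns {sorted(required)}")
    if (ct["ct"] <= 0).any():
        raise ExpressionError("Ct values must be positive")
    means = ct.groupby(["gene", "sample"])["ct"].mean()
    if target_gene not in means.index.get_level_values("gene"):
        raise ExpressionError(f"target gene {target_gene!r} missing from Ct table")
    if ref_gene not in means.index.get_level_values("gene"):
        raise ExpressionError(f"reference gene {ref_gene!r} missing from Ct table")
    target = means.loc[target_gene]
    ref = means.loc[ref_gene]
    missing_ref = set(target.index) - set(ref.index)
    if missing_ref:
        raise ExpressionError(f"missing reference Ct for samples {sorted(missing_ref)}")
    dct = target - ref.loc[target.index]
    if calibrator_sample not in dct.index:
        raise ExpressionError(f"calibrator sample {calibrator_sample!r} missing")
    dddct = dct - dct.loc[calibrator_sample]
    folds = 2.0 ** (-dddct)
    folds.name = target_gene
    return folds
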