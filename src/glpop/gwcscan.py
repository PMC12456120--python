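"""Genome-wide contrast: per-SNP likelihood-ratio test of allele-frequency
differences between two morph groups, with Bonferroni thresholds.

The null model fits one EM allele frequency to the pooled groups; the
alternative fits one frequency per group.  The statistic
``2 (ll_1 + ll_2 - ll_0)`` is referred to chi-square with 1 df.  The
genome-wide significance threshold is -log10(alpha / N) for N tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from . import glcore

NEGLOG10_CAP = 320.0  # below ~1e-320 the p-value underflows


@dataclass
class ThresholdSpec:
    alpha: float
    n_tests: int
    p_cut: float
    neglog10_threshold: float


def bonferroni_threshold(alpha: float, n_tests: int) -> ThresholdSpec:
    """Bonferroni cut for n_tests tests: p < alpha/N, i.e. -log10(alpha/N)."""
    if not 0.0 < alpha < 1.0:
        raise glcore.ParameterError("alpha must be in (0, 1)")
    if n_tests < 1:
        raise glcore.ParameterError("n_tests must be >= 1")
    return ThresholdSpec(
        alpha=alpha,
        n_tests=int(n_tests),
        p_cut=alpha / n_tests,
        neglog10_threshold=np.log10(n_tests) - np.log10(alpha),
    )


def assoc_lrt(gl: np.ndarray, group1_idx, group2_idx, tol: float = glcore.DEFAULT_EM_TOL,
              max_iter: int = glcore.DEFAULT_EM_MAX_ITER):
    """Allele-frequency-difference LRT per site between two groups.

    Parameters
    ----------
    gl
        (S, N, 3) scaled likelihoods over all individuals.
    group1_idx, group2_idx
        Disjoint integer index arrays into the individual axis.

    Returns a dict of per-site arrays: f_pooled, f_g1, f_g2, lrt, pval,
    tested (False where a group has no non-missing individual; such
    sites carry NaN statistics).
    """
    g1 = np.asarray(group1_idx)
    g2 = np.asarray(group2_idx)
    if np.intersect1d(g1, g2).size:
        raise glcore.ParameterError("contrast groups overlap")
    gl = np.asarray(gl, dtype=np.float64)
    squeeze = gl.ndim == 2
    if squeeze:
        gl = gl[None]
    miss = glcore.missing_mask(gl)
    tested = (~miss[:, g1]).any(axis=1) & (~miss[:, g2]).any(axis=1)

    S = gl.shape[0]
    f0 = np.full(S, np.nan)
    f1 = np.full(S, np.nan)
    f2 = np.full(S, np.nan)
    lrt = np.full(S, np.nan)
    if tested.any():
        pooled = gl[np.ix_(tested, np.concatenate([g1, g2]))]
        f0_t, ll0, _ = glcore.estimate_maf_em(pooled, tol=tol, max_iter=max_iter)
        f1_t, ll1, _ = glcore.estimate_maf_em(gl[np.ix_(tested, g1)], tol=tol, max_iter=max_iter)
        f2_t, ll2, _ = glcore.estimate_maf_em(gl[np.ix_(tested, g2)], tol=tol, max_iter=max_iter)
        f0[tested], f1[tested], f2[tested] = f0_t, f1_t, f2_t
        lrt[tested] = np.maximum(2.0 * (ll1 + ll2 - ll0), 0.0)
    pval = np.where(np.isnan(lrt), np.nan, chi2.sf(lrt, df=1))
    out = {"f_pooled": f0, "f_g1": f1, "f_g2": f2, "lrt": lrt, "pval": pval, "tested": tested}
    if squeeze:
        out = {k: v[0] for k, v in out.items()}
    return out


def neglog10(pval: np.ndarray) -> np.ndarray:
    """-log10(p) capped at 320 where the p-value underflows."""
    p = np.asarray(pval, dtype=np.float64)
    with np.errstate(divide="ignore"):
        nl = -np.log10(p)
    return np.where(np.isfinite(nl), np.minimum(nl, NEGLOG10_CAP), NEGLOG10_CAP)


def genome_scan(
    gl: np.ndarray,
    sites: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    group_a,
    group_b,
    lake=None,
    thresholds=(1e-3, 1e-8),
    n_tests=None,
    site_mask=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the contrast for every SNP and summarise threshold exceedances.

    ``group_a``/``group_b`` are morph labels or iterables of labels
    (pooling, e.g. benthic = SB + LB); ``lake`` optionally restricts the
    contrast to one lake.  ``n_tests`` defaults to the number of tested
    SNPs but can be fixed (e.g. 1e7) to mirror an external convention.

    Returns (scan table, threshold summary table).
    """
    def _members(spec):
        labels = [spec] if isinstance(spec, str) else list(spec)
        sel = sample_sheet["morph"].isin(labels)
        if lake is not None:
            sel &= sample_sheet["lake"] == lake
        return np.flatnonzero(sel.to_numpy()), labels

    idx_a, labels_a = _members(group_a)
    idx_b, labels_b = _members(group_b)
    if set(labels_a) & set(labels_b):
        raise glcore.ParameterError("contrast groups share morph labels")
    if len(idx_a) == 0 or len(idx_b) == 0:
        raise glcore.ParameterError("empty contrast group")

    if site_mask is not None:
        sites = sites.loc[np.asarray(site_mask)].reset_index(drop=True)
        gl = gl[np.asarray(site_mask)]
    if len(sites) == 0:
        empty = pd.DataFrame(
            columns=["scaffold", "pos", "f_pooled", "f_g1", "f_g2", "lrt", "pval", "neglog10p"]
        )
        return empty, pd.DataFrame(columns=["alpha", "n_tests", "neglog10_threshold", "n_snps", "n_scaffolds"])

    res = assoc_lrt(gl, idx_a, idx_b)
    scan = pd.DataFrame(
        {
            "scaffold": sites["scaffold"].to_numpy(),
            "pos": sites["pos"].to_numpy(),
            "f_pooled": res["f_pooled"],
            "f_g1": res["f_g1"],
            "f_g2": res["f_g2"],
            "lrt": res["lrt"],
            "pval": res["pval"],
            "neglog10p": neglog10(res["pval"]),
            "tested": res["tested"],
        }
    ).sort_values(["scaffold", "pos"], kind="mergesort").reset_index(drop=True)

    n_eff = int(res["tested"].sum()) if n_tests is None else int(n_tests)
    summaries = []
    for alpha in thresholds:
        spec = bonferroni_threshold(alpha, max(n_eff, 1))
        sig = scan["tested"] & (scan["neglog10p"] >= spec.neglog10_threshold)
        summaries.append(
            {
                "alpha": alpha,
                "n_tests": spec.n_tests,
                "neglog10_threshold": spec.neglog10_threshold,
                "n_snps": int(sig.sum()),
                "n_scaffolds": scan.loc[sig, "scaffold"].nunique(),
            }
        )
    return scan, pd.DataFrame(summaries)
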