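"""Site-allele-frequency likelihoods, folded SFS via EM, windowed
nucleotide diversity and windowed Hudson-Bhatia Fst.

The SAF vector at a site is the likelihood of each possible total
minor-allele count j in {0..2n} across n diploids, obtained by dynamic
programming over individuals with allele-pairing weights (1, 2, 1)/4 per
genotype.  An EM over SAF vectors yields the sample SFS; used as a
prior it gives the per-site posterior expectation of heterozygosity

    pi_s = E[ 2 j (2n - j) / (2n (2n - 1)) ]

whose window mean (divided by the number of covered sites) estimates
nucleotide diversity.  Diversity uses the no-MAF-cutoff site list; Fst
uses the MAF-filtered SNP list with the Hudson estimator in Bhatia's
ratio-of-sums form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import glcore

PAIR_WEIGHTS = np.array([1.0, 2.0, 1.0]) / 4.0

DEFAULT_THETA_WINDOW = 20_000
DEFAULT_FST_WINDOW = 20_000
DEFAULT_FST_STEP = 10_000


def saf_site(gl: np.ndarray) -> np.ndarray:
    """Site-allele-frequency likelihood vectors by DP over individuals.

    Parameters
    ----------
    gl
        Scaled genotype likelihoods, (S, N, 3) or (N, 3).

    Returns
    -------
    (S, 2N+1) array (or (2N+1,) for a single site), scaled to max 1:
    the likelihood of each total minor-allele count.  The recursion is
    ``h_i(j) = sum_g h_{i-1}(j-g) GL_i(g) w(g)`` with w = (1, 2, 1)/4,
    renormalised per site after each individual to avoid underflow.
    """
    gl = np.asarray(gl, dtype=np.float64)
    squeeze = gl.ndim == 2
    if squeeze:
        gl = gl[None]
    S, N, _ = gl.shape
    h = np.zeros((S, 2 * N + 1))
    h[:, 0] = 1.0
    weighted = gl * PAIR_WEIGHTS  # (S, N, 3)
    for i in range(N):
        w = weighted[:, i, :]
        new = np.zeros_like(h)
        for g in range(3):
            new[:, g : g + 2 * i + 1] += h[:, : 2 * i + 1] * w[:, g : g + 1]
        h = new
        h /= np.maximum(h.max(axis=1, keepdims=True), 1e-300)
    return h[0] if squeeze else h


def fold_sfs(sfs: np.ndarray) -> np.ndarray:
    """Fold a length-(2n+1) spectrum onto minor-allele counts {0..n}."""
    K = len(sfs)
    n = (K - 1) // 2
    return np.array(
        [sfs[j] + (sfs[K - 1 - j] if j != K - 1 - j else 0.0) for j in range(n + 1)]
    )


def sfs_em(
    saf: np.ndarray,
    fold: bool = False,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> np.ndarray:
    """Maximum-likelihood SFS from SAF vectors by EM (uniform start).

    Update: ``p(j) <- (1/S) sum_s SAF_s(j) p(j) / sum_k SAF_s(k) p(k)``.
    Sites with an all-zero SAF are skipped with a warning.  The log
    likelihood is non-decreasing across iterations.  When ``fold`` is
    set, minor-allele counts j and 2n-j are merged before reporting.
    """
    saf = np.asarray(saf, dtype=np.float64)
    keep = saf.sum(axis=1) > 0
    if not keep.all():
        warnings.warn(f"skipping {np.sum(~keep)} all-zero SAF sites")
        saf = saf[keep]
    if len(saf) == 0:
        raise glcore.EstimationError("no usable sites for SFS estimation")
    K = saf.shape[1]
    p = np.full(K, 1.0 / K)
    for _ in range(max_iter):
        num = saf * p
        denom = num.sum(axis=1, keepdims=True)
        p_new = (num / denom).mean(axis=0)
        if np.abs(p_new - p).max() < tol:
            p = p_new
            break
        p = p_new
    return fold_sfs(p) if fold else p


def sfs2d_em(
    saf1: np.ndarray,
    saf2: np.ndarray,
    fold: bool = False,
    tol: float = 1e-8,
    max_iter: int = 300,
) -> np.ndarray:
    """Joint 2D SFS of two groups by EM over outer-product SAF likelihoods."""
    saf1 = np.asarray(saf1, dtype=np.float64)
    saf2 = np.asarray(saf2, dtype=np.float64)
    S, K1 = saf1.shape
    K2 = saf2.shape[1]
    p = np.full((K1, K2), 1.0 / (K1 * K2))
    for _ in range(max_iter):
        acc = np.zeros_like(p)
        # site likelihood factorises as outer(saf1_s, saf2_s)
        for s in range(S):
            lik = p * np.outer(saf1[s], saf2[s])
            tot = lik.sum()
            if tot > 0:
                acc += lik / tot
        p_new = acc / S
        if np.abs(p_new - p).max() < tol:
            p = p_new
            break
        p = p_new
    if fold:
        p = _fold_2d(p)
    return p


def _fold_2d(p: np.ndarray) -> np.ndarray:
    flipped = p[::-1, ::-1]
    folded = p + flipped
    K1, K2 = p.shape
    # keep the half where the pooled count is the minor one; diagonal halved
    tot = np.add.outer(np.arange(K1), np.arange(K2))
    half = tot < (K1 + K2 - 2) / 2.0
    mid = tot == (K1 + K2 - 2) / 2.0
    out = np.where(half, folded, 0.0)
    out[mid] = folded[mid] / 2.0  # boundary cells pair with each other; halve to conserve mass
    return out


def site_pi_posterior(saf: np.ndarray, sfs_prior: np.ndarray) -> np.ndarray:
    """Posterior expected per-site heterozygosity given an SFS prior."""
    saf = np.asarray(saf, dtype=np.float64)
    K = saf.shape[1]
    two_n = K - 1
    j = np.arange(K, dtype=np.float64)
    if two_n < 2:
        raise glcore.ParameterError("need at least one diploid pair of alleles")
    pi_j = 2.0 * j * (two_n - j) / (two_n * (two_n - 1))
    w = saf * sfs_prior
    tot = w.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = (w @ pi_j) / tot
    pi[tot == 0] = np.nan
    return pi


@dataclass
class WindowStat:
    scaffold: str
    start: int  # 1-based inclusive
    end: int
    n_sites: int
    value: float
    numerator: float = np.nan
    denominator: float = np.nan


def theta_windows(
    saf: np.ndarray,
    sfs_prior: np.ndarray,
    scaffolds: np.ndarray,
    positions: np.ndarray,
    window: int = DEFAULT_THETA_WINDOW,
) -> pd.DataFrame:
    """Windowed nucleotide diversity: mean posterior pi over covered sites.

    Non-overlapping windows anchored at position 1 per scaffold; empty
    windows are reported with value NaN, never zero.
    """
    pi = site_pi_posterior(saf, sfs_prior)
    rows = []
    scaffolds = np.asarray(scaffolds)
    positions = np.asarray(positions)
    for scaf in pd.unique(scaffolds):
        sel = scaffolds == scaf
        pos = positions[sel]
        vals = pi[sel]
        if len(pos) == 0:
            continue
        last = pos.max()
        n_win = int((last - 1) // window) + 1
        idx = (pos - 1) // window
        for w in range(n_win):
            in_w = idx == w
            n = int(np.sum(in_w & np.isfinite(vals)))
            value = float(np.nanmean(vals[in_w])) if n else np.nan
            start = w * window + 1
            rows.append(
                WindowStat(scaf, start, min(start + window - 1, max(int(last), start)), n, value)
            )
    return pd.DataFrame([vars(r) for r in rows])


def hudson_components(p1, p2, n1_alleles: int, n2_alleles: int):
    """Per-site Hudson-Bhatia Fst numerator and denominator.

    N = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1);
    D = p1(1-p2) + p2(1-p1), with n in sampled alleles.
    """
    p1 = np.asarray(p1, dtype=np.float64)
    p2 = np.asarray(p2, dtype=np.float64)
    if n1_alleles < 4 or n2_alleles < 4:
        raise glcore.ParameterError("each group needs >= 2 diploid individuals")
    num = (
        (p1 - p2) ** 2
        - p1 * (1 - p1) / (n1_alleles - 1)
        - p2 * (1 - p2) / (n2_alleles - 1)
    )
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def fst_windows(
    p1,
    p2,
    n1_alleles: int,
    n2_alleles: int,
    scaffolds,
    positions,
    window: int = DEFAULT_FST_WINDOW,
    step: int = DEFAULT_FST_STEP,
):
    """Sliding-window Hudson Fst as a ratio of sums, plus a global summary.

    Windows of ``window`` bp advance by ``step`` bp from position 1 on
    each scaffold.  A window with zero denominator is reported missing.
    Returns (window DataFrame, global mean of window values, sd).
    """
    num, den = hudson_components(p1, p2, n1_alleles, n2_alleles)
    scaffolds = np.asarray(scaffolds)
    positions = np.asarray(positions)
    rows = []
    for scaf in pd.unique(scaffolds):
        sel = scaffolds == scaf
        pos = positions[sel]
        ns, ds = num[sel], den[sel]
        order = np.argsort(pos)
        pos, ns, ds = pos[order], ns[order], ds[order]
        last = int(pos.max())
        start = 1
        while start <= last:
            end = start + window - 1
            lo = np.searchsorted(pos, start, side="left")
            hi = np.searchsorted(pos, end, side="right")
            n_sites = hi - lo
            if n_sites > 0:
                dsum = ds[lo:hi].sum()
                value = ns[lo:hi].sum() / dsum if dsum > 0 else np.nan
                rows.append(
                    WindowStat(scaf, start, end, int(n_sites), value, ns[lo:hi].sum(), dsum)
                )
            start += step
    df = pd.DataFrame([vars(r) for r in rows])
    vals = df["value"].to_numpy(dtype=float) if len(df) else np.array([])
    finite = vals[np.isfinite(vals)]
    mean = float(finite.mean()) if len(finite) else np.nan
    sd = float(finite.std(ddof=1)) if len(finite) > 1 else np.nan
    return df, mean, sd


def global_fst(p1, p2, n1_alleles: int, n2_alleles: int) -> float:
    """Genome-wide Hudson Fst over all supplied sites (ratio of sums)."""
    num, den = hudson_components(p1, p2, n1_alleles, n2_alleles)
    d = den.sum()
    if d <= 0:
        raise glcore.EstimationError("Fst denominator is zero over the site set")
    return float(num.sum() / d)
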