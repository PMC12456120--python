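"""Putative-inversion detection and haplotype genotyping.

Candidate blocks are contiguous clusters of highly differentiated SNPs
(from a genome-wide contrast) with a sharp drop in significant-SNP
density at the edges.  Support comes from dosage LD against the block's
top SNP.  Individuals are genotyped into three classes (homozygous for
the tracked haplotype, heterozygous, homozygous other) from their mean
posterior dosage at diagnostic sites, and nucleotide diversity is
compared between the two homozygote classes with a Wilcoxon rank-sum
test — inversion haplotypes often carry asymmetric diversity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import glcore, popstructure, sfsdiversity
from .stats import rank_sum_test

DEFAULT_SIG_NEGLOG10 = 10.0  # block definition cut (alpha 1e-3 over 1e7 tests)
DEFAULT_DIAG_NEGLOG10 = 15.0  # diagnostic-marker cut (alpha 1e-8 over 1e7 tests)
DEFAULT_MAX_GAP = 100_000
DEFAULT_MIN_SNPS = 20
DEFAULT_FLANK = 250_000
DEFAULT_MIN_DENSITY_RATIO = 5.0


@dataclass
class CandidateBlock:
    scaffold: str
    start: int
    end: int
    n_sig: int
    density_ratio: float
    top_snp: int
    ld_mean: float = np.nan
    ld_sd: float = np.nan
    ld_ok: bool = True


@dataclass
class HaplotypeDiversity:
    theta_block: dict  # class -> window theta DataFrame within the block
    theta_genome: dict  # class -> window theta DataFrame genome-wide
    between_class_p: float  # Wilcoxon on block windows, hom vs hom
    between_class_stat: float
    block_vs_genome_p: dict  # class -> p
    mean_theta_block: dict = field(default_factory=dict)


def find_candidate_blocks(
    scan: pd.DataFrame,
    sig_threshold: float = DEFAULT_SIG_NEGLOG10,
    max_gap: int = DEFAULT_MAX_GAP,
    min_snps: int = DEFAULT_MIN_SNPS,
    flank: int = DEFAULT_FLANK,
    min_density_ratio: float = DEFAULT_MIN_DENSITY_RATIO,
) -> list[CandidateBlock]:
    """Cluster significant SNPs into candidate blocks.

    Significant SNPs (neglog10p >= sig_threshold) on a scaffold are
    merged while consecutive gaps are <= max_gap; clusters need at
    least ``min_snps`` members and a significant-SNP density at least
    ``min_density_ratio`` times the density in ``flank``-bp windows on
    either side.  Blocks are trimmed to their outermost significant
    SNPs.  The scan must be position-sorted within scaffolds.
    """
    blocks: list[CandidateBlock] = []
    for scaf, sub in scan.groupby("scaffold", sort=False):
        pos = sub["pos"].to_numpy()
        if np.any(np.diff(pos) < 0):
            raise glcore.ParameterError("scan must be sorted by position")
        nl = sub["neglog10p"].to_numpy()
        sig = np.flatnonzero(nl >= sig_threshold)
        if len(sig) == 0:
            continue
        sig_pos = pos[sig]
        breaks = np.flatnonzero(np.diff(sig_pos) > max_gap)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [len(sig_pos) - 1]])
        for a, b in zip(starts, ends):
            n_sig = b - a + 1
            if n_sig < min_snps:
                continue
            lo, hi = int(sig_pos[a]), int(sig_pos[b])
            span = max(hi - lo + 1, 1)
            inside_density = n_sig / span
            flank_sel = ((sig_pos >= lo - flank) & (sig_pos < lo)) | (
                (sig_pos > hi) & (sig_pos <= hi + flank)
            )
            flank_density = flank_sel.sum() / (2.0 * flank)
            ratio = np.inf if flank_density == 0 else inside_density / flank_density
            if ratio < min_density_ratio:
                continue
            in_block = sig[a : b + 1]
            top = in_block[int(np.argmax(nl[in_block]))]  # argmax: leftmost on ties
            blocks.append(
                CandidateBlock(
                    scaffold=str(scaf),
                    start=lo,
                    end=hi,
                    n_sig=int(n_sig),
                    density_ratio=float(ratio),
                    top_snp=int(pos[top]),
                )
            )
    return blocks


def ld_support(dosages: np.ndarray, sig_positions: np.ndarray, top_pos: int):
    """r^2 of each significant SNP's dosage against the top SNP.

    ``dosages`` is (n_sig_sites, N) aligned with ``sig_positions``.
    Returns (mean, sd, per-SNP r^2 array excluding the top SNP, ok).
    A constant top-SNP dosage makes LD undefined; flagged with ok=False.
    """
    sig_positions = np.asarray(sig_positions)
    if len(sig_positions) < 2:
        raise glcore.ParameterError("need >= 2 significant SNPs for LD support")
    top_idx = int(np.flatnonzero(sig_positions == top_pos)[0])
    top = dosages[top_idx]
    if np.std(top) == 0:
        return np.nan, np.nan, np.full(len(sig_positions) - 1, np.nan), False
    others = np.delete(np.arange(len(sig_positions)), top_idx)
    r2 = np.empty(len(others))
    for k, i in enumerate(others):
        sd = np.std(dosages[i])
        r2[k] = 0.0 if sd == 0 else np.corrcoef(dosages[i], top)[0, 1] ** 2
    return float(r2.mean()), float(r2.std(ddof=1)) if len(r2) > 1 else 0.0, r2, True


def assign_genotype_classes(
    gl: np.ndarray,
    f_pooled: np.ndarray,
    ref_group_idx,
    hom_hi: float = 1.5,
    hom_lo: float = 0.5,
) -> pd.DataFrame:
    """Three-class haplotype genotypes from diagnostic-site dosages.

    Parameters
    ----------
    gl
        (D, N, 3) likelihoods at the D diagnostic sites.
    f_pooled
        Pooled EM frequency per diagnostic site (Hardy-Weinberg prior
        for the posterior dosage).
    ref_group_idx
        Individuals of the reference group; the tracked allele at each
        site is the allele most common there (posterior-frequency
        argmax).

    Returns a DataFrame (one row per individual) with the mean tracked
    dosage, the number of informative sites and the class: hom_major
    (mean >= 1.5 tracked copies), hom_minor (<= 0.5), het, or
    unassigned when no site is informative.
    """
    gl = np.asarray(gl, dtype=np.float64)
    ref_group_idx = np.asarray(ref_group_idx)
    if gl.shape[0] == 0:
        raise glcore.ParameterError("need >= 1 diagnostic site")
    if len(ref_group_idx) == 0:
        raise glcore.ParameterError("reference group is empty")
    f_ref, _, _ = glcore.estimate_maf_em(gl[:, ref_group_idx, :])
    track_minor = f_ref >= 0.5  # tracked allele per site
    dos_minor = glcore.posterior_dosage(gl, np.asarray(f_pooled, dtype=np.float64))
    dos_tracked = np.where(track_minor[:, None], dos_minor, 2.0 - dos_minor)
    informative = ~glcore.missing_mask(gl)
    n_inf = informative.sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean_dos = np.where(
            n_inf > 0, (dos_tracked * informative).sum(axis=0) / np.maximum(n_inf, 1), np.nan
        )
    cls = np.where(
        n_inf == 0,
        "unassigned",
        np.where(mean_dos >= hom_hi, "hom_major", np.where(mean_dos <= hom_lo, "hom_minor", "het")),
    )
    return pd.DataFrame(
        {"class": cls, "mean_dosage": mean_dos, "n_informative_sites": n_inf}
    )


def local_pca_classes(gl: np.ndarray, f_hat: np.ndarray) -> tuple[np.ndarray, bool]:
    """Three-cluster genotype classification from local PCA.

    PC1 scores of the block's SNPs are split by 1-D k-means with
    deterministic initial centres at the 10th/50th/90th percentiles.
    The middle cluster is labelled het; if it does not lie between the
    two homozygote clusters the block is flagged unresolved.
    Returns (labels in {0,1,2} ordered along PC1, resolved flag).
    """
    _, _, vecs = popstructure.pca_covariance(gl, f_hat)
    pc1 = vecs[:, 0]
    centres = np.percentile(pc1, [10, 50, 90])
    for _ in range(100):
        assign = np.argmin(np.abs(pc1[:, None] - centres[None, :]), axis=1)
        new = np.array(
            [pc1[assign == k].mean() if np.any(assign == k) else centres[k] for k in range(3)]
        )
        if np.allclose(new, centres):
            break
        centres = new
    order = np.argsort(centres)
    labels = np.argsort(order)[assign]
    resolved = bool(centres[order][0] < centres[order][1] < centres[order][2])
    return labels, resolved


def per_class_theta(
    gl: np.ndarray,
    scaffolds: np.ndarray,
    positions: np.ndarray,
    block: CandidateBlock,
    classes: pd.DataFrame,
    window: int = sfsdiversity.DEFAULT_THETA_WINDOW,
) -> HaplotypeDiversity:
    """Per-haplotype diversity inside a block, with Wilcoxon comparisons.

    For each homozygote class, theta is computed over the block's
    windows (no MAF cut) and genome-wide for the same individuals.  The
    Wilcoxon rank-sum test compares (a) block windows between the two
    homozygote classes and (b) block vs genome windows within a class.
    Classes with fewer than 2 individuals get diversity but no test.
    """
    scaffolds = np.asarray(scaffolds)
    positions = np.asarray(positions)
    in_block = (scaffolds == block.scaffold) & (positions >= block.start) & (positions <= block.end)
    theta_block: dict = {}
    theta_genome: dict = {}
    mean_theta: dict = {}
    window_values: dict = {}
    for cls in ("hom_major", "hom_minor"):
        idx = np.flatnonzero((classes["class"] == cls).to_numpy())
        if len(idx) < 2:
            continue
        sub = np.asarray(gl)[:, idx, :]
        saf_b = sfsdiversity.saf_site(sub[in_block])
        sfs_b = sfsdiversity.sfs_em(saf_b)
        tw_b = sfsdiversity.theta_windows(
            saf_b, sfs_b, scaffolds[in_block], positions[in_block], window=window
        )
        saf_g = sfsdiversity.saf_site(sub[~in_block])
        sfs_g = sfsdiversity.sfs_em(saf_g)
        tw_g = sfsdiversity.theta_windows(
            saf_g, sfs_g, scaffolds[~in_block], positions[~in_block], window=window
        )
        theta_block[cls] = tw_b
        theta_genome[cls] = tw_g
        vals = tw_b.loc[tw_b["n_sites"] > 0, "value"].to_numpy()
        window_values[cls] = vals
        mean_theta[cls] = float(np.nanmean(vals)) if len(vals) else np.nan

    between_p, between_stat = np.nan, np.nan
    if len(window_values) == 2:
        a = window_values["hom_major"]
        b = window_values["hom_minor"]
        if len(a) and len(b):
            res = rank_sum_test(a, b)
            between_p, between_stat = res.pvalue, res.statistic
    bvg = {}
    for cls in theta_block:
        bw = theta_block[cls].loc[theta_block[cls]["n_sites"] > 0, "value"].to_numpy()
        gw = theta_genome[cls].loc[theta_genome[cls]["n_sites"] > 0, "value"].to_numpy()
        if len(bw) and len(gw):
            bvg[cls] = rank_sum_test(bw, gw).pvalue
    return HaplotypeDiversity(
        theta_block=theta_block,
        theta_genome=theta_genome,
        between_class_p=between_p,
        between_class_stat=between_stat,
        block_vs_genome_p=bvg,
        mean_theta_block=mean_theta,
    )
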