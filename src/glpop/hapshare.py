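"""Cross-lake haplotype-sharing detection.

Diagnostic SNPs (those exceeding the stricter Bonferroni cut in the
reference lake's morph contrast, outside excluded candidate blocks) are
clustered along scaffolds.  For each cluster, tracked-allele frequencies
are tabulated for every (lake, morph) group — the tracked allele at a
column is the allele most common in the designated reference morph —
and a cluster is called *shared* with a partner lake when the morph
contrast there is sign-concordant with the reference contrast and both
mean frequency differences clear their thresholds.  Validation uses
homozygote-only PCA, in-/out-of-region NJ trees, and pairwise Hudson
Fst between (lake x haplotype) groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import glcore, popstructure, sfsdiversity

DEFAULT_DIAG_CUT = 15.0
DEFAULT_MAX_GAP = 50_000
DEFAULT_MIN_SNPS = 5  # "more than four" diagnostic SNPs
DEFAULT_DELTA_REF = 0.5
DEFAULT_DELTA_PARTNER = 0.3


@dataclass
class DiagnosticCluster:
    scaffold: str
    start: int
    end: int
    positions: np.ndarray

    @property
    def n_snps(self) -> int:
        return len(self.positions)


@dataclass
class ShareCall:
    cluster: DiagnosticCluster
    partner_lake: str
    delta_ref: float
    delta_partner: float
    sign_concordant: bool
    call: str  # shared | not_shared | untestable


@dataclass
class ValidationReport:
    pc_scores: np.ndarray | None
    tree_in: str | None  # Newick
    tree_out: str | None
    fst_groups: list
    fst_matrix: np.ndarray | None
    complete: bool
    notes: list = field(default_factory=list)


def select_diagnostic_snps(
    scan: pd.DataFrame,
    neglog10_cut: float = DEFAULT_DIAG_CUT,
    exclude_regions=(),
) -> pd.DataFrame:
    """Rows of the scan above the diagnostic cut and outside excluded regions."""
    sel = scan["neglog10p"].to_numpy() >= neglog10_cut
    scaf = scan["scaffold"].to_numpy()
    pos = scan["pos"].to_numpy()
    for scaffold, start, end in exclude_regions:
        sel &= ~((scaf == scaffold) & (pos >= start) & (pos <= end))
    return scan.loc[sel].reset_index(drop=True)


def cluster_diagnostics(
    sites: pd.DataFrame,
    max_gap: int = DEFAULT_MAX_GAP,
    min_snps: int = DEFAULT_MIN_SNPS,
) -> list[DiagnosticCluster]:
    """Single-linkage clustering of diagnostic SNPs along each scaffold.

    Adjacent SNPs with gaps <= max_gap (boundary inclusive) merge;
    clusters with fewer than ``min_snps`` SNPs are dropped.
    """
    clusters = []
    for scaf, sub in sites.groupby("scaffold", sort=False):
        pos = sub["pos"].to_numpy()
        if np.any(np.diff(pos) < 0):
            raise glcore.ParameterError("diagnostic sites must be position-sorted")
        if len(pos) == 0:
            continue
        breaks = np.flatnonzero(np.diff(pos) > max_gap)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [len(pos) - 1]])
        for a, b in zip(starts, ends):
            if b - a + 1 >= min_snps:
                clusters.append(
                    DiagnosticCluster(
                        scaffold=str(scaf),
                        start=int(pos[a]),
                        end=int(pos[b]),
                        positions=pos[a : b + 1].copy(),
                    )
                )
    return clusters


def freq_matrix(
    gl: np.ndarray,
    scaffolds,
    positions,
    cluster: DiagnosticCluster,
    sample_sheet: pd.DataFrame,
    reference: tuple[str, str],
) -> pd.DataFrame:
    """Tracked-allele frequencies per (lake, morph) at a cluster's sites.

    The tracked allele per column is the most common allele in the
    reference (lake, morph) group.  Columns where the reference group
    has no data are dropped with a warning; other groups' missing
    entries are NaN.
    """
    import warnings

    scaffolds = np.asarray(scaffolds)
    positions = np.asarray(positions)
    col_idx = np.flatnonzero(
        (scaffolds == cluster.scaffold) & np.isin(positions, cluster.positions)
    )
    sub = np.asarray(gl)[col_idx]
    ref_idx = np.flatnonzero(
        ((sample_sheet["lake"] == reference[0]) & (sample_sheet["morph"] == reference[1])).to_numpy()
    )
    if len(ref_idx) == 0:
        raise glcore.ParameterError(f"reference morph {reference} absent from sample sheet")
    ref_has_data = (~glcore.missing_mask(sub[:, ref_idx, :])).any(axis=1)
    if not ref_has_data.all():
        warnings.warn(
            f"dropping {int(np.sum(~ref_has_data))} columns without reference-morph data"
        )
        sub = sub[ref_has_data]
        col_idx = col_idx[ref_has_data]
    f_ref, _, _ = glcore.estimate_maf_em(sub[:, ref_idx, :])
    track_minor = f_ref >= 0.5
    rows = {}
    for (lake, morph), grp in sample_sheet.groupby(["lake", "morph"], sort=True):
        idx = grp.index.to_numpy()
        g = sub[:, idx, :]
        has_data = (~glcore.missing_mask(g)).any(axis=1)
        f = np.full(len(sub), np.nan)
        if has_data.any():
            f_est, _, _ = glcore.estimate_maf_em(g[has_data])
            f[has_data] = f_est
        rows[f"{lake}_{morph}"] = np.where(track_minor, f, 1.0 - f)
    cols = [f"{cluster.scaffold}_{positions[i]}" for i in col_idx]
    return pd.DataFrame(rows, index=cols).T


def call_shared_blocks(
    fm: pd.DataFrame,
    cluster: DiagnosticCluster,
    ref_contrast: tuple[str, str, str],  # (lake, morph_A, morph_B)
    partner_contrasts: list,  # [(lake, morph_A, morph_B), ...]
    delta_ref: float = DEFAULT_DELTA_REF,
    delta_partner: float = DEFAULT_DELTA_PARTNER,
) -> list[ShareCall]:
    """Shared / not-shared / untestable calls for each partner contrast.

    Delta-f is the column mean of (f_morphA - f_morphB).  A cluster is
    shared with a partner lake when |delta_ref| >= delta_ref threshold,
    |delta_partner| >= its threshold, and the signs agree; untestable
    when the partner rows are absent or more than half their columns
    are missing.
    """
    def _row(lake, morph):
        key = f"{lake}_{morph}"
        return fm.loc[key].to_numpy() if key in fm.index else None

    ra = _row(ref_contrast[0], ref_contrast[1])
    rb = _row(ref_contrast[0], ref_contrast[2])
    if ra is None or rb is None:
        raise glcore.ParameterError("reference contrast morphs absent from matrix")
    d_ref = float(np.nanmean(ra - rb))
    calls = []
    for lake, ma, mb in partner_contrasts:
        pa, pb = _row(lake, ma), _row(lake, mb)
        if pa is None or pb is None:
            calls.append(ShareCall(cluster, lake, d_ref, np.nan, False, "untestable"))
            continue
        diff = pa - pb
        frac_missing = np.mean(~np.isfinite(diff))
        if frac_missing > 0.5:
            calls.append(ShareCall(cluster, lake, d_ref, np.nan, False, "untestable"))
            continue
        d_par = float(np.nanmean(diff))
        concordant = np.sign(d_par) == np.sign(d_ref) and d_ref != 0
        shared = (
            abs(d_ref) >= delta_ref and abs(d_par) >= delta_partner and concordant
        )
        calls.append(
            ShareCall(cluster, lake, d_ref, d_par, bool(concordant),
                      "shared" if shared else "not_shared")
        )
    return calls


def validate_region(
    gl: np.ndarray,
    scaffolds,
    positions,
    region: tuple[str, int, int],
    classes: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    min_homozygotes: int = 2,
) -> ValidationReport:
    """Homozygote-only validation of a shared region.

    Restricted to individuals genotyped hom_major or hom_minor at the
    region: PCA on in-region SNPs, NJ trees from covariance distances
    in-region and on the rest of the scaffold's sites, and pairwise
    Hudson Fst between every (lake, haplotype) group in-region.
    """
    scaffolds = np.asarray(scaffolds)
    positions = np.asarray(positions)
    scaf, start, end = region
    in_reg = (scaffolds == scaf) & (positions >= start) & (positions <= end)
    out_reg = ~in_reg
    cls = classes["class"].to_numpy()
    hom = np.isin(cls, ["hom_major", "hom_minor"])
    notes = []
    groups = []
    for (lake,), grp in sample_sheet.groupby(["lake"], sort=True):
        for hap in ("hom_major", "hom_minor"):
            idx = np.array([i for i in grp.index if cls[i] == hap])
            if len(idx) >= min_homozygotes:
                groups.append((f"{lake}:{hap}", idx))
            else:
                notes.append(f"{lake}:{hap} has <{min_homozygotes} homozygotes")
    complete = len(notes) == 0
    hom_idx = np.flatnonzero(hom)
    if len(hom_idx) < 3 or in_reg.sum() < 2:
        return ValidationReport(None, None, None, [g for g, _ in groups], None, False,
                                notes + ["insufficient data for validation"])

    gl = np.asarray(gl)
    sub_in = gl[np.ix_(in_reg, hom_idx)]
    f_in, _, _ = glcore.estimate_maf_em(sub_in)
    try:
        C_in, _, scores = popstructure.pca_covariance(sub_in, f_in)
    except glcore.EstimationError:
        return ValidationReport(None, None, None, [g for g, _ in groups], None, False,
                                notes + ["region monomorphic among homozygotes"])
    labels = [sample_sheet["sample"].iloc[i] for i in hom_idx]
    D_in = popstructure.distance_matrix(C_in, "covariance_individuals")
    tree_in = popstructure.nj_tree(D_in, labels).to_newick()
    tree_out = None
    if out_reg.sum() >= 2:
        sub_out = gl[np.ix_(out_reg, hom_idx)]
        f_out, _, _ = glcore.estimate_maf_em(sub_out)
        try:
            C_out, _, _ = popstructure.pca_covariance(sub_out, f_out)
            D_out = popstructure.distance_matrix(C_out, "covariance_individuals")
            tree_out = popstructure.nj_tree(D_out, labels).to_newick()
        except glcore.EstimationError:
            notes.append("out-of-region sites monomorphic")

    fst = None
    if len(groups) >= 2:
        fst = np.full((len(groups), len(groups)), np.nan)
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                gi, gj = groups[i][1], groups[j][1]
                fi, _, _ = glcore.estimate_maf_em(gl[np.ix_(in_reg, gi)])
                fj, _, _ = glcore.estimate_maf_em(gl[np.ix_(in_reg, gj)])
                try:
                    fst[i, j] = fst[j, i] = sfsdiversity.global_fst(
                        fi, fj, 2 * len(gi), 2 * len(gj)
                    )
                except glcore.EstimationError:
                    notes.append(f"Fst undefined for {groups[i][0]} vs {groups[j][0]}")
        np.fill_diagonal(fst, 0.0)
    return ValidationReport(
        pc_scores=scores,
        tree_in=tree_in,
        tree_out=tree_out,
        fst_groups=[g for g, _ in groups],
        fst_matrix=fst,
        complete=complete,
        notes=notes,
    )
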