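"""Synthetic multi-lake, multi-morph low-coverage datasets with ground truth.

The generator emulates the sampling design of lake-dwelling salmonid
morph studies: a shared ancestral gene pool drifts into lakes, and each
lake's gene pool drifts further into morphs (Balding-Nichols at both
levels, so between-lake and within-lake differentiation are tuned
independently; the drift coefficient F equals the expected Hudson Fst
between two groups drifted by F from a common pool).  Genotypes are
Hardy-Weinberg draws from the morph frequencies; reads are Poisson at a
per-individual mean depth drawn from a Gamma; each read carries the true
base with probability 1 - eps, otherwise one of the three other bases
uniformly.

Two kinds of region can be planted on top of the neutral background:

* inversion-like blocks — each individual carries two non-recombining
  haplotype labels (A/B) drawn from its morph's B-haplotype frequency;
  sites inside the block are fixed A/B differences with probability
  ``fixed_diff_prob`` and otherwise polymorphic within the A (or B)
  background at per-site heterozygosity ``theta_A`` (``theta_B``),
  implemented as a 50:50 polymorphism present with probability 2*theta;
* shared haplotype blocks — the same machinery keyed by (lake, morph),
  emulating an ancestral polymorphism segregating in several lakes.

Everything is driven by one ``numpy.random.default_rng`` seed; identical
seeds give byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import glcore
from .beagle import write_beagle

INVERSION_CLASSES = np.array(["AA", "AB", "BB"])


class ConfigurationError(ValueError):
    """Inconsistent simulation configuration."""


@dataclass
class MorphSpec:
    name: str
    n_individuals: int
    f_morph: float = 0.05  # within-lake drift coefficient


@dataclass
class LakeSpec:
    name: str
    f_lake: float
    morphs: list[MorphSpec] = field(default_factory=list)


@dataclass
class InversionSpec:
    """Inversion-like non-recombining block with morph-specific haplotype frequencies."""

    scaffold: str
    start: int  # 1-based inclusive
    end: int
    hap_freq_per_morph: dict  # morph name or (lake, morph) -> freq of haplotype B
    fixed_diff_prob: float = 0.8
    theta_A: float = 0.05
    theta_B: float = 0.05

    def __post_init__(self):
        if not self.start < self.end:
            raise ConfigurationError("region start must be < end")
        if self.theta_A < 0 or self.theta_B < 0:
            raise ConfigurationError("theta must be >= 0")
        for v in self.hap_freq_per_morph.values():
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError("haplotype frequency outside [0, 1]")


@dataclass
class SharedBlockSpec:
    """Ancestral haplotype block segregating in two or more lakes."""

    scaffold: str
    start: int
    end: int
    tracked_freq_per_morph: dict  # (lake, morph) -> tracked-allele frequency
    fixed_diff_prob: float = 1.0
    theta_A: float = 0.02
    theta_B: float = 0.02

    def __post_init__(self):
        if not self.start < self.end:
            raise ConfigurationError("region start must be < end")
        lakes = {k[0] for k in self.tracked_freq_per_morph if isinstance(k, tuple)}
        if len(lakes) < 2:
            raise ConfigurationError("shared block must span >= 2 lakes")


@dataclass
class SimConfig:
    lakes: list[LakeSpec]
    n_scaffolds: int = 1
    scaffold_length: int = 1_000_000
    n_sites: int = 10_000  # per scaffold
    depth_mean: float = 2.1
    depth_sd: float = 0.9
    error_rate: float = 0.01
    anc_low: float = 0.05
    anc_high: float = 0.95
    poly_fraction: float = 1.0  # fraction of sites with a segregating ancestral allele
    planted_regions: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        if self.n_sites < 0:
            raise ConfigurationError("n_sites must be >= 0")
        if self.depth_mean <= 0:
            raise ConfigurationError("depth_mean must be > 0")
        if not 0.0 < self.error_rate < 0.5:
            raise ConfigurationError("error_rate must be in (0, 0.5)")
        for lake in self.lakes:
            if not 0.0 <= lake.f_lake < 1.0:
                raise ConfigurationError("f_lake must be in [0, 1)")
            for m in lake.morphs:
                if not 0.0 <= m.f_morph < 1.0:
                    raise ConfigurationError("f_morph must be in [0, 1)")
        by_scaffold: dict[str, list] = {}
        for r in self.planted_regions:
            by_scaffold.setdefault(r.scaffold, []).append((r.start, r.end))
        for scaf, ivals in by_scaffold.items():
            ivals.sort()
            for (s1, e1), (s2, _) in zip(ivals, ivals[1:]):
                if s2 <= e1:
                    raise ConfigurationError(f"overlapping planted regions on {scaf}")


@dataclass
class TruthBundle:
    """Hidden state of a simulation, used as the oracle in tests."""

    true_genotypes: np.ndarray  # (S, N) minor-allele counts in {0,1,2}
    true_freqs: np.ndarray  # (S, n_morph_groups)
    inversion_genotypes: dict  # region_id -> length-N array of 'AA'/'AB'/'BB'
    region_coordinates: list  # (region_id, scaffold, start, end, kind)


@dataclass
class SimResult:
    config: SimConfig
    sites: pd.DataFrame  # scaffold, pos, major, minor (allele codes)
    samples: pd.DataFrame  # sample, lake, morph, mean_depth
    morph_cols: list  # ordered (lake, morph) keys for freq columns
    truth: TruthBundle
    counts: np.ndarray  # (S, N, 3): major, minor, other reads
    gl: np.ndarray  # (S, N, 3) scaled likelihoods

    def group_indices(self, lake=None, morph=None) -> np.ndarray:
        sel = np.ones(len(self.samples), dtype=bool)
        if lake is not None:
            sel &= (self.samples["lake"] == lake).to_numpy()
        if morph is not None:
            sel &= (self.samples["morph"] == morph).to_numpy()
        return np.flatnonzero(sel)


def drift_frequencies(p_anc, F: float, rng) -> np.ndarray:
    """Balding-Nichols drift of allele frequencies.

    Each output is Beta-distributed with mean ``p_anc`` and variance
    ``F * p_anc * (1 - p_anc)``; F = 0 returns the input exactly, and
    fixed alleles (0 or 1) stay fixed.
    """
    if not 0.0 <= F < 1.0:
        raise glcore.ParameterError(f"drift coefficient must be in [0, 1), got {F}")
    p = np.asarray(p_anc, dtype=np.float64)
    if np.any((p < 0) | (p > 1)):
        raise glcore.ParameterError("ancestral frequencies must be in [0, 1]")
    if F == 0.0:
        return p.copy()
    out = p.copy()
    seg = (p > 0) & (p < 1)
    scale = (1.0 - F) / F
    out[seg] = rng.beta(p[seg] * scale, (1.0 - p[seg]) * scale)
    return out


def build_sample_sheet(config: SimConfig, rng) -> pd.DataFrame:
    """Sample metadata with per-individual mean depths (Gamma, floored at 0.05X)."""
    rows = []
    for lake in config.lakes:
        for morph in lake.morphs:
            for i in range(morph.n_individuals):
                rows.append((f"{lake.name}_{morph.name}_{i}", lake.name, morph.name))
    df = pd.DataFrame(rows, columns=["sample", "lake", "morph"])
    shape = (config.depth_mean / config.depth_sd) ** 2
    scale = config.depth_sd**2 / config.depth_mean
    depths = np.maximum(rng.gamma(shape, scale, size=len(df)), 0.05)
    df["mean_depth"] = depths
    return df


def simulate_frequencies(config: SimConfig, rng):
    """Ancestral -> lake -> morph frequency hierarchy for every site."""
    S = config.n_scaffolds * config.n_sites
    p_anc = np.zeros(S)
    seg = rng.random(S) < config.poly_fraction
    p_anc[seg] = rng.uniform(config.anc_low, config.anc_high, size=seg.sum())
    cols, freqs = [], []
    for lake in config.lakes:
        p_lake = drift_frequencies(p_anc, lake.f_lake, rng)
        for morph in lake.morphs:
            cols.append((lake.name, morph.name))
            freqs.append(drift_frequencies(p_lake, morph.f_morph, rng))
    return np.column_stack(freqs) if freqs else np.empty((S, 0)), cols


def _region_hap_freq(region, lake: str, morph: str) -> float:
    mapping = (
        region.hap_freq_per_morph
        if isinstance(region, InversionSpec)
        else region.tracked_freq_per_morph
    )
    if (lake, morph) in mapping:
        return mapping[(lake, morph)]
    return mapping.get(morph, 0.0)


def simulate_genotypes(
    freqs: np.ndarray,
    morph_cols: list,
    sample_sheet: pd.DataFrame,
    sites: pd.DataFrame,
    planted_regions: list,
    rng,
) -> TruthBundle:
    """Draw genotypes: binomial(2, f_morph) outside planted regions,
    haplotype-structured inside them (see module docstring)."""
    col_of = {key: j for j, key in enumerate(morph_cols)}
    ind_col = np.array(
        [col_of[(l, m)] for l, m in zip(sample_sheet["lake"], sample_sheet["morph"])]
    )
    S, N = len(sites), len(sample_sheet)
    true_freqs = freqs.copy()
    geno = rng.binomial(2, freqs[:, ind_col]).astype(np.int8) if S else np.zeros((0, N), np.int8)

    inversion_genotypes: dict = {}
    region_coordinates = []
    scaf = sites["scaffold"].to_numpy()
    pos = sites["pos"].to_numpy()
    for k, region in enumerate(planted_regions):
        kind = "inversion" if isinstance(region, InversionSpec) else "shared_block"
        region_id = f"{kind}_{k}_{region.scaffold}"
        region_coordinates.append((region_id, region.scaffold, region.start, region.end, kind))
        in_region = np.flatnonzero(
            (scaf == region.scaffold) & (pos >= region.start) & (pos <= region.end)
        )
        pB = np.array(
            [_region_hap_freq(region, l, m) for l, m in zip(sample_sheet["lake"], sample_sheet["morph"])]
        )
        haps = rng.random((N, 2)) < pB[:, None]  # True = haplotype B
        inversion_genotypes[region_id] = INVERSION_CLASSES[haps.sum(axis=1)]
        if len(in_region) == 0:
            continue
        nr = len(in_region)
        fixed = rng.random(nr) < region.fixed_diff_prob
        qA = np.where(fixed, 0.0, 0.5 * (rng.random(nr) < min(1.0, 2 * region.theta_A)))
        qB = np.where(fixed, 1.0, 0.5 * (rng.random(nr) < min(1.0, 2 * region.theta_B)))
        q_h = np.where(haps[None, :, :], qB[:, None, None], qA[:, None, None])
        geno[in_region] = (rng.random((nr, N, 2)) < q_h).sum(axis=2).astype(np.int8)
        pB_cols = np.array([_region_hap_freq(region, l, m) for l, m in morph_cols])
        true_freqs[in_region] = (
            (1 - pB_cols)[None, :] * qA[:, None] + pB_cols[None, :] * qB[:, None]
        )
    return TruthBundle(geno, true_freqs, inversion_genotypes, region_coordinates)


def simulate_reads(genotypes: np.ndarray, mean_depths: np.ndarray, eps: float, rng) -> np.ndarray:
    """Poisson read counts of (major, minor, other) per site x individual.

    Sequencing error sends a read to one of the three non-true bases
    uniformly, so "other" (neither major nor minor) reads appear at rate
    2*eps/3 regardless of genotype; downstream filters drop them.
    """
    if not 0.0 < eps < 0.5:
        raise glcore.ParameterError("error rate must be in (0, 0.5)")
    S, N = genotypes.shape
    n_reads = rng.poisson(np.broadcast_to(mean_depths, (S, N)))
    n_other = rng.binomial(n_reads, 2 * eps / 3)
    rest = n_reads - n_other
    # P(minor | read is major-or-minor) by genotype
    p_cond = np.array(
        [
            (eps / 3) / (1 - 2 * eps / 3),
            0.5,
            (1 - eps) / (1 - 2 * eps / 3),
        ]
    )
    n_minor = rng.binomial(rest, p_cond[genotypes])
    counts = np.stack([rest - n_minor, n_minor, n_other], axis=2)
    return counts.astype(np.int32)


def _site_table(config: SimConfig, rng) -> pd.DataFrame:
    """Sorted unique positions per scaffold with random major/minor bases."""
    frames = []
    for k in range(config.n_scaffolds):
        n = min(config.n_sites, config.scaffold_length)
        pos = np.sort(rng.choice(config.scaffold_length, size=n, replace=False)) + 1
        major = rng.integers(0, 4, size=n)
        minor = (major + rng.integers(1, 4, size=n)) % 4
        frames.append(
            pd.DataFrame(
                {"scaffold": f"scaffold{k + 1}", "pos": pos, "major": major, "minor": minor}
            )
        )
    if not frames:
        return pd.DataFrame(columns=["scaffold", "pos", "major", "minor"])
    return pd.concat(frames, ignore_index=True)


def simulate_dataset(config: SimConfig) -> SimResult:
    """Run the full generator: frequencies, genotypes, reads, likelihoods."""
    rng = np.random.default_rng(config.seed)
    samples = build_sample_sheet(config, rng)
    sites = _site_table(config, rng)
    freqs, morph_cols = simulate_frequencies(config, rng)
    truth = simulate_genotypes(
        freqs, morph_cols, samples, sites, config.planted_regions, rng
    )
    counts = simulate_reads(
        truth.true_genotypes, samples["mean_depth"].to_numpy(), config.error_rate, rng
    )
    gl = glcore.gl_from_counts(counts[:, :, 0], counts[:, :, 1], config.error_rate)
    return SimResult(config, sites, samples, morph_cols, truth, counts, gl)


def write_dataset(result: SimResult, out_dir) -> dict:
    """Write Beagle GLs, truth VCF, planted-region BED, sample TSV, config echo."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "beagle": out / "dataset.beagle.gz",
        "vcf": out / "truth.vcf",
        "bed": out / "planted_regions.bed",
        "samples": out / "samples.tsv",
        "config": out / "config.txt",
    }
    write_beagle(paths["beagle"], result.sites, result.gl, list(result.samples["sample"]))
    _write_truth_vcf(paths["vcf"], result)
    with open(paths["bed"], "w") as fh:
        for rid, scaffold, start, end, kind in result.truth.region_coordinates:
            fh.write(f"{scaffold}\t{start - 1}\t{end}\t{rid}\t0\t.\n")
    result.samples.to_csv(paths["samples"], sep="\t", index=False, float_format="%.6g")
    cfg = result.config
    with open(paths["config"], "w") as fh:
        for key in (
            "seed", "n_scaffolds", "scaffold_length", "n_sites", "depth_mean",
            "depth_sd", "error_rate", "anc_low", "anc_high", "poly_fraction",
        ):
            fh.write(f"{key}={getattr(cfg, key)}\n")
        fh.write(
            "lakes=" + json.dumps(
                [
                    {
                        "name": lk.name,
                        "f_lake": lk.f_lake,
                        "morphs": [[m.name, m.n_individuals, m.f_morph] for m in lk.morphs],
                    }
                    for lk in cfg.lakes
                ]
            )
            + "\n"
        )
    return paths


def _write_truth_vcf(path, result: SimResult) -> None:
    sites, geno = result.sites, result.truth.true_genotypes
    names = list(result.samples["sample"])
    gt_str = np.array(["0/0", "0/1", "1/1"])
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for k in range(result.config.n_scaffolds):
            fh.write(
                f"##contig=<ID=scaffold{k + 1},length={result.config.scaffold_length}>\n"
            )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(names) + "\n")
        maj = glcore.ALLELES[sites["major"].to_numpy()] if len(sites) else []
        mnr = glcore.ALLELES[sites["minor"].to_numpy()] if len(sites) else []
        for s in range(len(sites)):
            row = "\t".join(gt_str[geno[s]])
            fh.write(
                f"{sites['scaffold'].iloc[s]}\t{sites['pos'].iloc[s]}\t.\t{maj[s]}\t{mnr[s]}\t.\tPASS\t.\tGT\t{row}\n"
            )


def read_truth_vcf(path):
    """Round-trip reader for the truth VCF: (sites df, genotype matrix)."""
    import pysam

    vcf = pysam.VariantFile(str(path))
    rows, genos = [], []
    for rec in vcf.fetch():
        rows.append((rec.chrom, rec.pos, rec.ref, rec.alts[0] if rec.alts else None))
        genos.append([sum(rec.samples[s]["GT"]) for s in rec.samples])
    sites = pd.DataFrame(rows, columns=["scaffold", "pos", "ref", "alt"])
    geno = np.array(genos, dtype=np.int8) if genos else np.zeros((0, 0), np.int8)
    return sites, geno


def study_like_config(seed: int = 0, n_sites: int = 10_000, **overrides) -> SimConfig:
    """Configuration emulating the four-lake Arctic charr study design.

    Four lakes with 2-4 morphs each (286 individuals), between-lake
    drift 0.35 (Hudson Fst between lakes ~0.30-0.41), within-lake morph
    drift spanning the observed 0.01-0.19 morph-Fst range, and the
    2.1 +/- 0.9X depth distribution.
    """
    lakes = [
        LakeSpec("thingvallavatn", 0.35, [
            MorphSpec("SB", 40, 0.05), MorphSpec("LB", 30, 0.05),
            MorphSpec("PL", 30, 0.05), MorphSpec("Pi", 22, 0.05),
        ]),
        LakeSpec("myvatn", 0.35, [MorphSpec("SB", 26, 0.01), MorphSpec("LG", 26, 0.01)]),
        LakeSpec("sirdalsvatnet", 0.35, [MorphSpec("DB", 30, 0.19), MorphSpec("LP", 30, 0.19)]),
        LakeSpec("vangsvatnet", 0.35, [MorphSpec("N", 26, 0.01), MorphSpec("D", 26, 0.01)]),
    ]
    cfg = dict(
        lakes=lakes,
        n_scaffolds=2,
        scaffold_length=5_000_000,
        n_sites=n_sites,
        depth_mean=2.1,
        depth_sd=0.9,
        error_rate=0.01,
        seed=seed,
    )
    cfg.update(overrides)
    return SimConfig(**cfg)
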