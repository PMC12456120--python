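import numpy as np
import pytest

from glpop import simdata


def one_hot_gl(genotypes):
    """Certain-genotype GL triples from an (S, N) or (N,) genotype array."""
    g = np.asarray(genotypes)
    gl = np.zeros(g.shape + (3,))
    np.put_along_axis(gl, g[..., None], 1.0, axis=-1)
    return gl


@pytest.fixture(scope="session")
def two_morph_highdepth():
    """Two well-differentiated morphs at 20X: structure easily recoverable."""
    cfg = simdata.SimConfig(
        lakes=[
            simdata.LakeSpec(
                "lake1",
                0.0,
                [simdata.MorphSpec("m1", 20, 0.19), simdata.MorphSpec("m2", 20, 0.19)],
            )
        ],
        n_sites=800,
        scaffold_length=400_000,
        depth_mean=20.0,
        depth_sd=2.0,
        seed=11,
    )
    return simdata.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def inversion_sim():
    """Two morphs at 2X with a planted 1-Mb inversion-like block: haplotype B
    at frequency 0.9 in morph m1 vs 0.1 in m2, asymmetric within-haplotype
    diversity (theta_A = 2 theta_B)."""
    from glpop import gwcscan

    cfg = simdata.SimConfig(
        lakes=[
            simdata.LakeSpec(
                "lake1",
                0.0,
                [simdata.MorphSpec("m1", 40, 0.0), simdata.MorphSpec("m2", 40, 0.0)],
            )
        ],
        n_scaffolds=1,
        scaffold_length=10_000_000,
        n_sites=2000,
        depth_mean=2.1,
        depth_sd=0.9,
        planted_regions=[
            simdata.InversionSpec(
                "scaffold1",
                4_500_000,
                5_500_000,
                {"m1": 0.9, "m2": 0.1},
                fixed_diff_prob=0.6,
                theta_A=0.3,
                theta_B=0.15,
            )
        ],
        seed=101,
    )
    sim = simdata.simulate_dataset(cfg)
    scan, _ = gwcscan.genome_scan(
        sim.gl, sim.sites, sim.samples, "m1", "m2", thresholds=(1e-3, 1e-8), n_tests=10**7
    )
    return sim, scan


@pytest.fixture(scope="session")
def shared_block_sim():
    """Two lakes, two morphs each, with a planted 100-kb ancestral haplotype
    block showing the same morph contrast in both lakes."""
    from glpop import gwcscan

    cfg = simdata.SimConfig(
        lakes=[
            simdata.LakeSpec("L1", 0.2, [simdata.MorphSpec("m1", 30, 0.02),
                                         simdata.MorphSpec("m2", 30, 0.02)]),
            simdata.LakeSpec("L2", 0.2, [simdata.MorphSpec("m1", 30, 0.02),
                                         simdata.MorphSpec("m2", 30, 0.02)]),
        ],
        n_scaffolds=1,
        scaffold_length=2_000_000,
        n_sites=2000,
        depth_mean=2.1,
        depth_sd=0.9,
        planted_regions=[
            simdata.SharedBlockSpec(
                "scaffold1", 900_000, 1_000_000,
                {("L1", "m1"): 0.95, ("L1", "m2"): 0.05,
                 ("L2", "m1"): 0.85, ("L2", "m2"): 0.15},
            )
        ],
        seed=202,
    )
    sim = simdata.simulate_dataset(cfg)
    scan, _ = gwcscan.genome_scan(
        sim.gl, sim.sites, sim.samples, "m1", "m2", lake="L1",
        thresholds=(1e-8,), n_tests=10**7,
    )
    return sim, scan


@pytest.fixture(scope="session")
def single_pop_lowdepth():
    """One panmictic group of 50 at the study's 2.1X depth."""
    cfg = simdata.SimConfig(
        lakes=[simdata.LakeSpec("lake1", 0.0, [simdata.MorphSpec("m1", 50, 0.0)])],
        n_sites=600,
        scaffold_length=300_000,
        depth_mean=2.1,
        depth_sd=0.9,
        seed=7,
    )
    return simdata.simulate_dataset(cfg)
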