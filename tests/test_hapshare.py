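"""Diagnostic-SNP clustering, tracked-allele frequency matrices, shared-block
calls and homozygote-based validation."""

import numpy as np
import pandas as pd
import pytest

from glpop import glcore, hapshare, invscan


def _scan(positions, neglog10, scaffold="s1"):
    return pd.DataFrame(
        {"scaffold": scaffold, "pos": np.asarray(positions), "neglog10p": np.asarray(neglog10)}
    )


class TestSelectDiagnostics:
    def test_infinite_cut_empty(self):
        scan = _scan([100, 200], [50.0, 60.0])
        assert len(hapshare.select_diagnostic_snps(scan, np.inf)) == 0

    def test_excluded_region_removes_all(self):
        scan = _scan([100, 200], [20.0, 20.0])
        out = hapshare.select_diagnostic_snps(scan, 15.0, [("s1", 1, 300)])
        assert len(out) == 0

    def test_planted_diagnostics_outside_blocks_returned(self, shared_block_sim):
        sim, scan = shared_block_sim
        out = hapshare.select_diagnostic_snps(scan, 15.0, [("scaffold1", 900_000, 1_000_000)])
        # the planted block is excluded; the neutral background offers no
        # diagnostic-grade SNPs between morphs drifted at F=0.02
        assert len(out) == 0
        kept = hapshare.select_diagnostic_snps(scan, 15.0)
        assert (kept["pos"].between(900_000, 1_000_000)).all()
        assert len(kept) >= 5  # enough to form a diagnostic cluster


class TestClusterDiagnostics:
    def test_gap_rule_by_inspection(self):
        pos = np.array([10, 20, 55, 90, 130, 500]) * 1000
        sites = pd.DataFrame({"scaffold": "s1", "pos": pos})
        clusters = hapshare.cluster_diagnostics(sites)
        assert len(clusters) == 1
        c = clusters[0]
        assert (c.start, c.end, c.n_snps) == (10_000, 130_000, 5)

    def test_more_than_four_rule(self):
        sites = pd.DataFrame({"scaffold": "s1", "pos": [1, 2, 3, 4]})
        assert hapshare.cluster_diagnostics(sites, max_gap=10) == []

    def test_boundary_gap_inclusive(self):
        pos = np.arange(5) * 50_000 + 1  # gaps exactly 50 kb
        sites = pd.DataFrame({"scaffold": "s1", "pos": pos})
        clusters = hapshare.cluster_diagnostics(sites)
        assert len(clusters) == 1 and clusters[0].n_snps == 5

    def test_unsorted_rejected(self):
        sites = pd.DataFrame({"scaffold": "s1", "pos": [100, 50, 200, 300, 400]})
        with pytest.raises(glcore.ParameterError):
            hapshare.cluster_diagnostics(sites)


@pytest.fixture(scope="module")
def planted_cluster(shared_block_sim):
    sim, scan = shared_block_sim
    diag = hapshare.select_diagnostic_snps(scan, 15.0)
    clusters = hapshare.cluster_diagnostics(diag)
    assert len(clusters) >= 1
    # the widest cluster corresponds to the planted block
    return max(clusters, key=lambda c: c.n_snps)


class TestFreqMatrix:
    def test_reference_row_at_least_half(self, shared_block_sim, planted_cluster):
        sim, _ = shared_block_sim
        fm = hapshare.freq_matrix(
            sim.gl, sim.sites["scaffold"].to_numpy(), sim.sites["pos"].to_numpy(),
            planted_cluster, sim.samples, ("L1", "m1"),
        )
        ref = fm.loc["L1_m1"].to_numpy()
        assert np.all(ref[np.isfinite(ref)] >= 0.5)

    def test_recovers_planted_frequencies(self, shared_block_sim, planted_cluster):
        sim, _ = shared_block_sim
        fm = hapshare.freq_matrix(
            sim.gl, sim.sites["scaffold"].to_numpy(), sim.sites["pos"].to_numpy(),
            planted_cluster, sim.samples, ("L1", "m1"),
        )
        want = {"L1_m1": 0.95, "L1_m2": 0.05, "L2_m1": 0.85, "L2_m2": 0.15}
        for row, f in want.items():
            assert np.nanmean(fm.loc[row]) == pytest.approx(f, abs=0.07)


class TestShareCalls:
    def test_planted_block_called_shared(self, shared_block_sim, planted_cluster):
        sim, _ = shared_block_sim
        fm = hapshare.freq_matrix(
            sim.gl, sim.sites["scaffold"].to_numpy(), sim.sites["pos"].to_numpy(),
            planted_cluster, sim.samples, ("L1", "m1"),
        )
        calls = hapshare.call_shared_blocks(
            fm, planted_cluster, ("L1", "m1", "m2"), [("L2", "m1", "m2")]
        )
        assert calls[0].call == "shared"

    def test_flat_partner_not_shared(self, planted_cluster):
        fm = pd.DataFrame(
            {
                "c1": [0.9, 0.1, 0.5, 0.5],
                "c2": [0.95, 0.05, 0.5, 0.5],
            },
            index=["L1_m1", "L1_m2", "L2_m1", "L2_m2"],
        )
        calls = hapshare.call_shared_blocks(
            fm, planted_cluster, ("L1", "m1", "m2"), [("L2", "m1", "m2")]
        )
        assert calls[0].call == "not_shared"

    def test_opposite_sign_not_shared_despite_magnitude(self, planted_cluster):
        fm = pd.DataFrame(
            {"c1": [0.9, 0.1, 0.1, 0.9], "c2": [0.95, 0.05, 0.05, 0.95]},
            index=["L1_m1", "L1_m2", "L2_m1", "L2_m2"],
        )
        calls = hapshare.call_shared_blocks(
            fm, planted_cluster, ("L1", "m1", "m2"), [("L2", "m1", "m2")]
        )
        assert calls[0].call == "not_shared"
        assert not calls[0].sign_concordant

    def test_morph_swap_flips_sign_not_call(self, planted_cluster):
        fm = pd.DataFrame(
            {"c1": [0.9, 0.1, 0.8, 0.2], "c2": [0.95, 0.05, 0.85, 0.15]},
            index=["L1_m1", "L1_m2", "L2_m1", "L2_m2"],
        )
        fwd = hapshare.call_shared_blocks(
            fm, planted_cluster, ("L1", "m1", "m2"), [("L2", "m1", "m2")]
        )[0]
        rev = hapshare.call_shared_blocks(
            fm, planted_cluster, ("L1", "m2", "m1"), [("L2", "m2", "m1")]
        )[0]
        assert fwd.call == rev.call == "shared"
        assert fwd.delta_ref == pytest.approx(-rev.delta_ref)

    def test_absent_partner_untestable(self, planted_cluster):
        fm = pd.DataFrame({"c1": [0.9, 0.1]}, index=["L1_m1", "L1_m2"])
        calls = hapshare.call_shared_blocks(
            fm, planted_cluster, ("L1", "m1", "m2"), [("L2", "m1", "m2")]
        )
        assert calls[0].call == "untestable"


class TestValidation:
    def test_trees_and_fst_reflect_planted_structure(self, shared_block_sim, planted_cluster):
        """In-region the homozygote NJ tree groups by haplotype across lakes
        (within-haplotype cross-lake Fst << cross-haplotype Fst); out-of-region
        it groups by lake."""
        import dendropy

        sim, scan = shared_block_sim
        diag_idx = np.flatnonzero(
            (scan["neglog10p"].to_numpy() >= 15)
            & np.isin(scan["pos"].to_numpy(), planted_cluster.positions)
        )
        classes = invscan.assign_genotype_classes(
            sim.gl[diag_idx],
            scan.loc[diag_idx, "f_pooled"].to_numpy(),
            sim.group_indices(lake="L1", morph="m1"),
        )
        report = hapshare.validate_region(
            sim.gl, sim.sites["scaffold"].to_numpy(), sim.sites["pos"].to_numpy(),
            ("scaffold1", planted_cluster.start, planted_cluster.end),
            classes, sim.samples,
        )
        assert report.tree_in and report.tree_out
        # Fst: same haplotype across lakes is far less differentiated than
        # different haplotypes, inside the region
        g = report.fst_groups
        fst = report.fst_matrix
        def _pair(a, b):
            return fst[g.index(a), g.index(b)]
        within = [_pair("L1:hom_major", "L2:hom_major"), _pair("L1:hom_minor", "L2:hom_minor")]
        across = [_pair("L1:hom_major", "L1:hom_minor"), _pair("L2:hom_major", "L2:hom_minor")]
        assert max(within) < min(across)

        def grouping_score(newick, key):
            t = dendropy.Tree.get(data=newick, schema="newick")
            pdm = t.phylogenetic_distance_matrix()
            taxa = {x.label.replace(" ", "_"): x for x in t.taxon_namespace}
            cls = classes["class"].to_numpy()
            names = sim.samples["sample"].to_numpy()
            hom = np.flatnonzero(np.isin(cls, ["hom_major", "hom_minor"]))
            same, diff = [], []
            for ii, i in enumerate(hom):
                for j in hom[ii + 1:]:
                    d = pdm.distance(taxa[names[i]], taxa[names[j]])
                    (same if key(i) == key(j) else diff).append(d)
            return np.median(same), np.median(diff)

        lake = sim.samples["lake"].to_numpy()
        cls = classes["class"].to_numpy()
        s_in, d_in = grouping_score(report.tree_in, key=lambda i: cls[i])
        assert s_in < d_in  # in-region: haplotype groups
        s_out, d_out = grouping_score(report.tree_out, key=lambda i: lake[i])
        assert s_out < d_out  # out-of-region: lake groups

    def test_insufficient_homozygotes_incomplete(self, shared_block_sim):
        sim, _ = shared_block_sim
        classes = pd.DataFrame({"class": ["het"] * len(sim.samples)})
        report = hapshare.validate_region(
            sim.gl, sim.sites["scaffold"].to_numpy(), sim.sites["pos"].to_numpy(),
            ("scaffold1", 900_000, 1_000_000), classes, sim.samples,
        )
        assert not report.complete
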