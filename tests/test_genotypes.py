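"""SNP QC filters, imputation, LD pruning, hybrids, GRM and marker PCs."""

import numpy as np
import pandas as pd
import pytest

from gxemet import genotypes as gt
from gxemet.synthetic import SimulationConfig, simulate_inbred_genotypes


def _matrix(dosage, **kw):
    dosage = np.asarray(dosage, float)
    n, p = dosage.shape
    defaults = dict(
        sample_ids=[f"S{i}" for i in range(n)],
        marker_ids=[f"M{j}" for j in range(p)],
        dosage=dosage,
    )
    defaults.update(kw)
    return gt.MarkerMatrix(**defaults)


class TestFilters:
    def test_multiallelic_markers_dropped(self):
        m = _matrix(np.zeros((3, 4)), allele_counts=np.array([2, 3, 2, 4]))
        out = gt.filter_biallelic(m)
        assert out.marker_ids == ["M0", "M2"]

    def test_biallelic_panel_unchanged(self):
        m = _matrix(np.zeros((3, 4)))
        assert gt.filter_biallelic(m).n_markers == 4

    def test_synthetic_multiallelic_fraction(self):
        cfg = SimulationConfig(n_inbreds=20, n_markers=1000, multiallelic_rate=0.1, seed=5)
        m = simulate_inbred_genotypes(cfg)
        out = gt.filter_biallelic(m)
        assert out.n_markers / m.n_markers == pytest.approx(0.9, abs=0.03)

    def test_coverage_boundary(self):
        # 100 markers: 69% coverage removed, 70% retained
        dosage = np.zeros((2, 100))
        dosage[0, :31] = np.nan  # 69% coverage
        dosage[1, :30] = np.nan  # 70% coverage
        out = gt.filter_taxa(_matrix(dosage))
        assert out.sample_ids == ["S1"]

    def test_heterozygosity_boundary(self):
        # exactly 8% heterozygous retained ("more than 8%" discarded)
        dosage = np.zeros((2, 100))
        dosage[0, :8] = 1.0
        dosage[1, :9] = 1.0
        out = gt.filter_taxa(_matrix(dosage))
        assert out.sample_ids == ["S0"]

    def test_all_taxa_removed_errors(self):
        dosage = np.full((2, 10), np.nan)
        with pytest.raises(ValueError):
            gt.filter_taxa(_matrix(dosage))

    def test_parent_marker_rules(self):
        n = 100
        rng = np.random.default_rng(0)
        poly = rng.choice([0.0, 2.0], size=(n, 1), p=[0.6, 0.4])
        mono = np.zeros((n, 1))
        missing6 = poly.copy()
        missing6[:6] = np.nan  # 6% missing > 5%
        het6 = poly.copy()
        het6[:6] = 1.0
        maf1 = np.zeros((n, 1))
        maf1[:2] = 2.0  # MAF 2% exactly -> retained
        maf_low = np.zeros((n, 1))
        maf_low[:1] = 2.0  # MAF 1% -> removed
        dosage = np.hstack([poly, mono, missing6, het6, maf1, maf_low])
        out = gt.filter_parent_markers(_matrix(dosage))
        assert out.marker_ids == ["M0", "M4"]


class TestImputation:
    def test_no_missing_is_identity(self):
        m = _matrix([[0, 2], [2, 0]])
        out = gt.impute_missing(m)
        np.testing.assert_array_equal(out.dosage, m.dosage)

    def test_mode_rule(self):
        col = np.array([0.0] * 9 + [2.0] + [np.nan])
        m = _matrix(col[:, None])
        out = gt.impute_missing(m)
        assert out.dosage[-1, 0] == 0.0

    def test_observed_calls_preserved(self):
        cfg = SimulationConfig(n_inbreds=50, n_markers=200, missing_rate=0.1, seed=2)
        m = simulate_inbred_genotypes(cfg)
        out = gt.impute_missing(m)
        obs = ~np.isnan(m.dosage)
        np.testing.assert_array_equal(out.dosage[obs], m.dosage[obs])
        assert not np.isnan(out.dosage).any()

    def test_mask_and_restore_beats_random_guessing(self):
        cfg = SimulationConfig(n_inbreds=80, n_markers=400, seed=3)
        m = simulate_inbred_genotypes(cfg)
        rng = np.random.default_rng(1)
        mask = rng.uniform(size=m.dosage.shape) < 0.05
        hidden = m.dosage.copy()
        hidden[mask] = np.nan
        restored = gt.impute_missing(_matrix(hidden, marker_ids=m.marker_ids))
        concordance = (restored.dosage[mask] == m.dosage[mask]).mean()
        assert concordance > 0.55  # random guess over {0, 2} is 0.5

    def test_fully_missing_marker_errors(self):
        dosage = np.full((3, 1), np.nan)
        with pytest.raises(ValueError):
            gt.impute_missing(_matrix(dosage))


def _brute_force_prune(dosage, maf, r2_max):
    """All-pairs pruning oracle with the same removal rule, no windows."""
    removed = set()
    p = dosage.shape[1]
    while True:
        live = [j for j in range(p) if j not in removed]
        r = np.corrcoef(dosage[:, live], rowvar=False)
        r2 = np.nan_to_num(r) ** 2
        np.fill_diagonal(r2, 0)
        if r2.max() <= r2_max:
            break
        a, b = np.unravel_index(np.argmax(r2), r2.shape)
        ga, gb = live[a], live[b]
        if maf[ga] < maf[gb]:
            removed.add(ga)
        elif maf[gb] < maf[ga]:
            removed.add(gb)
        else:
            removed.add(max(ga, gb))
    return {j for j in range(p) if j not in removed}


class TestLDPrune:
    def test_duplicated_marker_one_survives(self):
        rng = np.random.default_rng(0)
        base = rng.choice([0.0, 2.0], size=(30, 3))
        dosage = np.hstack([base, base[:, :1]])  # M3 duplicates M0
        out = gt.ld_prune(_matrix(dosage))
        assert out.n_markers == 3
        survivors = set(out.marker_ids)
        assert ("M0" in survivors) != ("M3" in survivors)

    def test_independent_markers_untouched(self):
        rng = np.random.default_rng(1)
        dosage = rng.choice([0.0, 2.0], size=(200, 20))
        out = gt.ld_prune(_matrix(dosage))
        assert out.n_markers == 20

    def test_matches_bruteforce_oracle(self):
        cfg = SimulationConfig(n_inbreds=60, n_markers=200, seed=9)
        m = simulate_inbred_genotypes(cfg)
        m = gt.impute_missing(m)
        m.chrom = np.ones(m.n_markers, dtype=int)  # single window pass
        pruned = gt.ld_prune(m, window=200, step=200, r2_max=0.99)
        oracle = _brute_force_prune(m.dosage, m.maf(), 0.99)
        got = {m.marker_ids.index(mid) for mid in pruned.marker_ids}
        assert got == oracle

    def test_requires_imputed_input(self):
        dosage = np.array([[0.0, np.nan], [2.0, 0.0]])
        with pytest.raises(ValueError):
            gt.ld_prune(_matrix(dosage))


class TestHybrids:
    def test_dosage_arithmetic(self):
        parents = _matrix([[0.0, 2.0, 2.0], [2.0, 2.0, 0.0]])
        ped = pd.DataFrame({"hybrid": ["X"], "parent1": ["S0"], "parent2": ["S1"]})
        out = gt.build_hybrid_genotypes(parents, ped, maf_min=0.0)
        np.testing.assert_array_equal(out.dosage, [[1.0, 2.0, 1.0]])

    def test_final_maf_filter(self):
        rng = np.random.default_rng(4)
        n = 100
        dosage = rng.choice([0.0, 2.0], size=(n, 2), p=[0.5, 0.5])
        dosage[:, 1] = 0.0
        dosage[0, 1] = 2.0  # near-fixed among hybrids
        ped = pd.DataFrame(
            {"hybrid": [f"X{i}" for i in range(50)],
             "parent1": [f"S{2 * i}" for i in range(50)],
             "parent2": [f"S{2 * i + 1}" for i in range(50)]}
        )
        out = gt.build_hybrid_genotypes(_matrix(dosage), ped, maf_min=0.02)
        assert "M1" not in out.marker_ids

    def test_unknown_parent_rejected(self):
        parents = _matrix([[0.0], [2.0]])
        ped = pd.DataFrame({"hybrid": ["X"], "parent1": ["S0"], "parent2": ["NOPE"]})
        with pytest.raises(KeyError):
            gt.build_hybrid_genotypes(parents, ped)


class TestGRM:
    def _panel(self, n=40, p=100, seed=0):
        cfg = SimulationConfig(n_inbreds=n, n_markers=p, seed=seed)
        return gt.impute_missing(simulate_inbred_genotypes(cfg))

    def test_identical_samples_share_entries(self):
        m = self._panel()
        m.dosage[1] = m.dosage[0]
        g = gt.compute_grm(m).matrix
        assert g[0, 0] == pytest.approx(g[0, 1])
        assert g[1, 1] == pytest.approx(g[0, 1])

    def test_entries_sum_to_zero(self):
        g = gt.compute_grm(self._panel()).matrix
        n = g.shape[0]
        assert abs(g.sum()) < 1e-6 * n * n

    def test_mean_diagonal_under_sample_sd_scaling(self):
        g = gt.compute_grm(self._panel(n=50)).matrix
        assert np.diag(g).mean() == pytest.approx(49 / 50, abs=1e-10)

    def test_positive_semidefinite(self):
        grm = gt.compute_grm(self._panel())
        assert grm.min_eigenvalue() >= -1e-8

    def test_missing_input_rejected(self):
        dosage = np.array([[0.0, np.nan], [2.0, 0.0]])
        with pytest.raises(ValueError):
            gt.compute_grm(_matrix(dosage))


class TestMarkerPCs:
    def test_rank_one_panel_single_component(self):
        v = np.array([0.0, 1.0, 2.0, 1.0])
        dosage = np.outer(v, np.ones(6)) * np.array([1, 1, 1, 1, 1, 1])
        pcs = gt.marker_pcs(_matrix(np.clip(dosage, 0, 2)), 1)
        x, _ = gt._center_scale(np.clip(dosage, 0, 2))
        total = (x**2).sum()
        explained = (pcs.to_numpy() ** 2).sum()
        assert explained == pytest.approx(total, rel=1e-10)

    def test_scores_orthogonal_and_ordered(self):
        cfg = SimulationConfig(n_inbreds=40, n_markers=120, seed=8)
        m = gt.impute_missing(simulate_inbred_genotypes(cfg))
        pcs = gt.marker_pcs(m, 5).to_numpy()
        cross = pcs.T @ pcs
        off = cross - np.diag(np.diag(cross))
        assert np.abs(off).max() < 1e-8
        vars_ = np.diag(cross)
        assert all(b <= a + 1e-9 for a, b in zip(vars_, vars_[1:]))

    def test_deterministic_sign_convention(self):
        cfg = SimulationConfig(n_inbreds=30, n_markers=80, seed=8)
        m = gt.impute_missing(simulate_inbred_genotypes(cfg))
        a = gt.marker_pcs(m, 3)
        b = gt.marker_pcs(m, 3)
        pd.testing.assert_frame_equal(a, b)

    def test_k_too_large_rejected(self):
        m = _matrix(np.array([[0.0, 2.0], [2.0, 0.0]]))
        with pytest.raises(ValueError):
            gt.marker_pcs(m, 5)


class TestIO:
    def test_dosage_csv_roundtrip(self, tmp_path):
        cfg = SimulationConfig(n_inbreds=10, n_markers=20, seed=1)
        m = simulate_inbred_genotypes(cfg)
        path = tmp_path / "dosage.csv"
        gt.write_dosage_csv(m, path)
        back = gt.read_dosage_csv(path)
        np.testing.assert_array_equal(back.dosage, m.dosage)
        assert back.sample_ids == m.sample_ids

    def test_vcf_parsing(self, tmp_path):
        vcf = tmp_path / "toy.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB\tC\n"
            "1\t100\tm1\tA\tT\t.\t.\t.\tGT\t0/0\t0/1\t1/1\n"
            "1\t200\tm2\tG\tC\t.\t.\t.\tGT\t1/1\t1/1\t0/1\n"
        )
        m = gt.read_vcf(vcf)
        assert m.sample_ids == ["A", "B", "C"]
        # m2's alt is the major allele; dosage is flipped to minor-allele counts
        np.testing.assert_array_equal(m.dosage[:, 0], [0, 1, 2])
        np.testing.assert_array_equal(m.dosage[:, 1], [0, 0, 1])
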