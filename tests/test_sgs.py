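"""Loiselle coancestry, distance classes, correlogram nulls, bk and Sp."""

import numpy as np
import pytest

from palmflow.genotype_io import GenotypeDataset, allele_frequencies, pairwise_distances
from palmflow.sgs import (
    build_distance_classes,
    loiselle_coancestry,
    sgs_correlogram,
    sp_from_components,
    sp_statistic,
)
from palmflow.synthetic import SimulationConfig, simulate_population


def _panel(geno, coords=None, stages=None):
    n = geno.shape[0]
    return GenotypeDataset(
        ids=[str(i) for i in range(n)],
        stages=stages or ["s"] * n,
        coords=coords if coords is not None else np.arange(2 * n).reshape(n, 2),
        loci=[f"L{j}" for j in range(geno.shape[1])],
        genotypes=geno,
    )


def brute_force_loiselle(geno, freqs_by_locus):
    """Literal pairwise implementation of the published kinship estimator.

    Independent of the vectorised path: explicit loops over pairs, loci and
    alleles, multilocus value as the polymorphism-weighted ratio of sums.
    """
    n, L, _ = geno.shape
    theta = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            num_sum, den_sum = 0.0, 0.0
            for l in range(L):
                freqs = freqs_by_locus[l]
                gi, gj = geno[i, l], geno[j, l]
                if 0 in gi or 0 in gj:
                    continue
                w = sum(p * (1 - p) for p in freqs.values())
                if w <= 0:
                    continue
                n_l = sum(
                    1 for k in range(n) if geno[k, l, 0] != 0
                )
                num = 0.0
                for a, p in freqs.items():
                    p_i = (list(gi).count(a)) / 2
                    p_j = (list(gj).count(a)) / 2
                    num += (p_i - p) * (p_j - p)
                num_sum += num + w / (n_l - 1)
                den_sum += w
            theta[i, j] = num_sum / den_sum if den_sum > 0 else np.nan
    return theta


class TestLoiselleCoancestry:
    def test_matches_exhaustive_oracle_small_instance(self, rng):
        geno = rng.integers(1, 4, size=(5, 2, 2))
        geno[0, 1] = [0, 0]  # one missing call exercised too
        data = _panel(geno)
        freqs = allele_frequencies(data)
        cm = loiselle_coancestry(data)
        by_locus = [freqs.freqs[f"L{l}"] for l in range(2)]
        expect = brute_force_loiselle(geno, by_locus)
        iu = np.triu_indices(5, k=1)
        assert np.allclose(cm.theta[iu], expect[iu], atol=1e-12, equal_nan=True)

    def test_sample_mean_near_zero(self, rng):
        # the estimator is centred on the sample frequencies
        geno = rng.integers(1, 8, size=(40, 6, 2))
        cm = loiselle_coancestry(_panel(geno))
        assert abs(np.nanmean(cm.pair_values)) < 0.05

    def test_parent_offspring_pairs_quarter(self, rng):
        # kinship of parent-offspring pairs in an unrelated background ~ 1/4
        n_bg, n_fam, L, A = 150, 40, 12, 8
        p = np.full(A, 1 / A)
        bg = rng.integers(1, A + 1, size=(n_bg, L, 2))
        parents = rng.integers(1, A + 1, size=(n_fam, L, 2))
        gam_p = parents[np.arange(n_fam)[:, None], np.arange(L), rng.integers(0, 2, (n_fam, L))]
        other = rng.integers(1, A + 1, size=(n_fam, L))
        kids = np.stack([gam_p, other], axis=2)
        geno = np.concatenate([bg, parents, kids])
        cm = loiselle_coancestry(_panel(geno))
        vals = [
            cm.theta[n_bg + i, n_bg + n_fam + i] for i in range(n_fam)
        ]
        assert np.mean(vals) == pytest.approx(0.25, abs=0.03)

    def test_invariant_to_individual_order(self, rng):
        geno = rng.integers(1, 5, size=(10, 3, 2))
        data = _panel(geno)
        cm = loiselle_coancestry(data)
        perm = rng.permutation(10)
        data2 = GenotypeDataset(
            ids=[data.ids[i] for i in perm],
            stages=["s"] * 10,
            coords=data.coords[perm],
            loci=data.loci,
            genotypes=geno[perm],
        )
        cm2 = loiselle_coancestry(data2)
        assert np.allclose(
            cm.theta[np.ix_(perm, perm)], cm2.theta, equal_nan=True
        )

    def test_monomorphic_locus_excluded(self, rng):
        poly = rng.integers(1, 4, size=(8, 1, 2))
        mono = np.full((8, 1, 2), 9)
        both = np.concatenate([poly, mono], axis=1)
        cm_both = loiselle_coancestry(_panel(both))
        cm_poly = loiselle_coancestry(_panel(poly))
        assert np.allclose(cm_both.theta, cm_poly.theta, equal_nan=True)


class TestDistanceClasses:
    def test_equal_frequency(self, rng):
        coords = rng.uniform(0, 100, size=(20, 2))
        data = _panel(rng.integers(1, 3, size=(20, 1, 2)), coords=coords)
        d = pairwise_distances(data)
        bounds = build_distance_classes(d, n_classes=10)
        iu = np.triu_indices(20, k=1)
        labels = np.searchsorted(bounds, d[iu], side="left")
        counts = np.bincount(labels, minlength=10)
        assert counts.sum() == 190
        assert counts.max() - counts.min() <= 2

    def test_degenerate_all_equidistant(self):
        coords = np.array([[0, 0], [1, 0], [0.5, np.sqrt(3) / 2]])
        data = _panel(np.ones((3, 1, 2), dtype=int), coords=coords)
        with pytest.raises(ValueError, match="distinct"):
            build_distance_classes(pairwise_distances(data), n_classes=3)


class TestCorrelogram:
    def test_null_coordinates_mostly_inside_envelope(self, rng):
        # coordinates independent of genotypes: ~5% of classes significant
        n_sig = n_tot = 0
        for rep in range(20):
            geno = rng.integers(1, 6, size=(40, 5, 2))
            coords = rng.uniform(0, 300, size=(40, 2))
            data = _panel(geno, coords=coords)
            cm = loiselle_coancestry(data)
            d = pairwise_distances(data)
            corr = sgs_correlogram(cm, d, n_perm=199, seed=rep)
            n_sig += int(corr.significant.sum())
            n_tot += len(corr.bounds)
        assert n_sig / n_tot < 0.15

    def test_restricted_seed_dispersal_first_class_positive(self):
        cfg = SimulationConfig(
            plot_width=300.0, plot_height=300.0, seed=42,
            offspring_per_stage={"seedling": 150},
            selfing_rate=0.0, pollen_immigration=0.2,
        )
        data, _ = simulate_population(cfg)
        sub = data.subset("seedling")
        cm = loiselle_coancestry(sub)
        d = pairwise_distances(sub)
        corr = sgs_correlogram(cm, d, n_perm=499, seed=7)
        assert corr.theta_mean[0] > corr.ci_high[0]

    def test_pair_counts_partition(self, study_like):
        data, _ = study_like
        sub = data.subset("seedling")
        cm = loiselle_coancestry(sub)
        d = pairwise_distances(sub)
        corr = sgs_correlogram(cm, d, n_perm=49, seed=0)
        assert corr.n_pairs.sum() == sub.n * (sub.n - 1) // 2
        assert np.all(np.diff(corr.bounds) > 0)


class TestSpStatistic:
    def test_identity_holds_exactly(self, study_like):
        data, _ = study_like
        sub = data.subset("young")
        cm = loiselle_coancestry(sub)
        d = pairwise_distances(sub)
        summ = sp_statistic(cm, d, n_perm=99, seed=0)
        assert summ.sp == -summ.bk / (1.0 - summ.theta1)

    def test_zero_slope_gives_zero_sp(self):
        assert sp_from_components(0.0, 0.3) == 0.0

    def test_restricted_dispersal_negative_slope(self):
        cfg = SimulationConfig(
            plot_width=300.0, plot_height=300.0, seed=11,
            offspring_per_stage={"seedling": 120},
            selfing_rate=0.0, pollen_immigration=0.2,
        )
        data, _ = simulate_population(cfg)
        sub = data.subset("seedling")
        cm = loiselle_coancestry(sub)
        summ = sp_statistic(cm, pairwise_distances(sub), n_perm=199, seed=3)
        assert summ.bk < 0
        assert summ.bk_p_value < 0.05
        assert summ.sp > 0
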