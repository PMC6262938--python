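"""Exclusion probability, LOD scores, Delta criterion, assignment, dispersal."""

from itertools import combinations_with_replacement, product

import numpy as np
import pytest

from palmflow.genotype_io import GenotypeDataset, allele_frequencies
from palmflow.parentage import (
    GeneFlowSummary,
    ParentageModel,
    assign_parentage,
    dispersal_summaries,
    effective_pollination_area,
    exclusion_probability_pairs,
    lod_scores,
    simulate_delta_criterion,
)
from palmflow.synthetic import SimulationConfig, simulate_population


def _freq_table(per_locus):
    from palmflow.genotype_io import AlleleFrequencyTable

    loci = list(per_locus)
    return AlleleFrequencyTable(
        loci=loci,
        freqs={l: dict(per_locus[l]) for l in loci},
        gene_counts={l: 1000 for l in loci},
    )


def brute_force_pair_exclusion(p):
    """Literal enumeration over (offspring, candidate pair) genotype triples."""
    alleles = list(range(len(p)))
    genos = list(combinations_with_replacement(alleles, 2))

    def gprob(g):
        a, b = g
        return p[a] ** 2 if a == b else 2 * p[a] * p[b]

    def compatible(o, u, v):
        x, y = o
        return (x in u and y in v) or (y in u and x in v)

    q = 0.0
    for o, u, v in product(genos, repeat=3):
        if not compatible(o, u, v):
            q += gprob(o) * gprob(u) * gprob(v)
    return q


class TestExclusionProbability:
    def test_monomorphic_only_gives_zero(self):
        freqs = _freq_table({"L1": {1: 1.0}})
        assert exclusion_probability_pairs(freqs) == 0.0

    @pytest.mark.parametrize(
        "p", [[0.5, 0.5], [0.25, 0.25, 0.25, 0.25], [0.6, 0.3, 0.1]]
    )
    def test_matches_enumeration_oracle(self, p):
        freqs = _freq_table({"L1": {i + 1: pi for i, pi in enumerate(p)}})
        expect = brute_force_pair_exclusion(np.array(p))
        assert exclusion_probability_pairs(freqs) == pytest.approx(
            expect, abs=1e-12
        )

    def test_loci_combine_multiplicatively(self):
        one = _freq_table({"L1": {1: 0.5, 2: 0.5}})
        two = _freq_table(
            {"L1": {1: 0.5, 2: 0.5}, "L2": {1: 0.5, 2: 0.5}}
        )
        q = exclusion_probability_pairs(one)
        assert exclusion_probability_pairs(two) == pytest.approx(
            1 - (1 - q) ** 2
        )

    def test_many_loci_approach_one(self, study_like):
        data, _ = study_like
        pp = exclusion_probability_pairs(allele_frequencies(data))
        assert pp > 0.9999


class TestLodScores:
    def _setup(self, off, cand, p):
        freqs = _freq_table({"L1": p})
        return lod_scores(
            np.array([[off]]), np.array([[c] for c in cand]), ["L1"], freqs,
            error_rate=0.0,
        )

    def test_mendelian_exclusion_minus_inf(self):
        res = self._setup([1, 2], [[3, 3]], {1: 0.25, 2: 0.25, 3: 0.5})
        assert res["single"][0, 0] == -np.inf
        assert res["single_mismatches"][0, 0] == 1

    def test_homozygote_single_parent_hand_value(self):
        # offspring A/A, candidate A/A, p(A) = 0.5 -> LOD = ln 2
        res = self._setup([1, 1], [[1, 1]], {1: 0.5, 2: 0.5})
        assert res["single"][0, 0] == pytest.approx(np.log(2))

    def test_pair_lod_brute_force_gametes(self):
        # offspring A/B from pair (A/B, B/B): T = P(mother->A)P(father->B)
        #   + P(mother->B)P(father->A) = .5*1 + .5*0 = .5; P(O) = 2pq
        p = {1: 0.3, 2: 0.7}
        freqs = _freq_table({"L1": p})
        res = lod_scores(
            np.array([[[1, 2]]]), np.array([[[1, 2]], [[2, 2]]]), ["L1"],
            freqs, error_rate=0.0,
        )
        expect = np.log(0.5 / (2 * 0.3 * 0.7))
        assert res["pair"][0, 0, 1] == pytest.approx(expect)
        assert res["pair"][0, 1, 0] == pytest.approx(expect)  # symmetric

    def test_true_father_tops_ranking(self, rng):
        cfg = SimulationConfig(
            seed=5, offspring_per_stage={"young": 60}, n_adults=50,
            selfing_rate=0.0, pollen_immigration=0.0, missing_rate=0.0,
        )
        data, truth = simulate_population(cfg)
        freqs = allele_frequencies(data)
        cand = data.subset("reproductive")
        off = data.subset("young")
        res = lod_scores(
            off.genotypes, cand.genotypes, data.loci, freqs, error_rate=0.01
        )
        hits = 0
        lut = {c: i for i, c in enumerate(cand.ids)}
        tt = truth.table.set_index("offspring")
        for i, oid in enumerate(off.ids):
            top2 = set(np.argsort(res["single"][i])[-2:])
            parents = {lut[tt.loc[oid, "mother"]], lut[tt.loc[oid, "father"]]}
            hits += bool(top2 & parents)
        assert hits / len(off.ids) >= 0.95


class TestDeltaCriterion:
    def test_deterministic_under_seed(self, study_like):
        data, _ = study_like
        freqs = allele_frequencies(data)
        cand = data.subset("reproductive")
        model = ParentageModel(n_sim=300)
        d1 = simulate_delta_criterion(model, freqs, cand.genotypes, data.loci, seed=9)
        d2 = simulate_delta_criterion(model, freqs, cand.genotypes, data.loci, seed=9)
        assert d1["pair"] == d2["pair"] and d1["single"] == d2["single"]

    def test_all_sampled_polymorphic_threshold_near_zero(self, study_like):
        data, _ = study_like
        freqs = allele_frequencies(data)
        cand = data.subset("reproductive")
        model = ParentageModel(n_sim=400, prop_sampled=1.0, error_rate=0.0)
        crit = simulate_delta_criterion(
            model, freqs, cand.genotypes, data.loci, seed=2
        )
        assert crit["pair"] == pytest.approx(0.0, abs=1e-9)

    def test_calibration_on_held_out_set(self, study_like):
        # fraction correct among accepted assignments >= stated confidence
        data, truth = study_like
        freqs = allele_frequencies(data)
        model = ParentageModel(n_sim=1500)
        assignments, _ = assign_parentage(data, model, freqs=freqs, seed=77)
        tt = truth.table.set_index("offspring")
        ok = tot = 0
        for a in assignments:
            if a.classification in ("outcross-within", "selfed"):
                tot += 1
                row = tt.loc[a.offspring_id]
                ok += {a.mother_id, a.father_id} == {row["mother"], row["father"]}
        assert tot > 50
        assert ok / tot >= model.confidence


class TestAssignment:
    def test_gene_flow_counts_partition_and_rates(self, study_like):
        data, _ = study_like
        model = ParentageModel(n_sim=800)
        assignments, summ = assign_parentage(data, model, seed=13)
        assert (
            summ.both_parents_within + summ.selfed + summ.no_father
            == summ.total
        )
        assert summ.selfing_rate == summ.selfed / summ.total
        assert summ.pollen_immigration == summ.no_father / summ.total
        assert summ.seed_immigration == summ.no_parent / summ.total
        by_class = {"selfed": 0, "outcross-within": 0}
        for a in assignments:
            if a.classification in by_class:
                by_class[a.classification] += 1
        assert by_class["selfed"] == summ.selfed
        assert by_class["outcross-within"] == summ.both_parents_within

    def test_error_free_accepted_assignments_have_no_mismatch(self):
        cfg = SimulationConfig(seed=8, error_rate=0.0, missing_rate=0.0)
        data, _ = simulate_population(cfg)
        model = ParentageModel(error_rate=0.0, n_sim=500)
        assignments, _ = assign_parentage(data, model, seed=21)
        for a in assignments:
            if a.confidence_category == "relaxed":
                assert a.mismatches == 0

    def test_no_immigration_low_cryptic_flow(self):
        cfg = SimulationConfig(
            seed=17, selfing_rate=0.0, pollen_immigration=0.0,
            error_rate=0.0, missing_rate=0.0,
        )
        data, _ = simulate_population(cfg)
        model = ParentageModel(error_rate=0.0, n_sim=800, prop_sampled=1.0)
        _, summ = assign_parentage(data, model, seed=3)
        assert summ.pollen_immigration <= 0.05

    def test_selfed_assignment_has_identical_parents(self, study_like):
        data, _ = study_like
        model = ParentageModel(n_sim=800)
        assignments, _ = assign_parentage(data, model, seed=13)
        for a in assignments:
            if a.classification == "selfed":
                assert a.mother_id == a.father_id
                assert a.pollen_distance == 0.0


class TestGeneFlowSummary:
    def test_from_counts_validates_partition(self):
        with pytest.raises(ValueError):
            GeneFlowSummary.from_counts(10, 5, 1, 3, 0)

    def test_rates_are_exact_ratios(self):
        s = GeneFlowSummary.from_counts(189, 107, 8, 74, 7)
        assert s.selfing_rate == 8 / 189
        assert s.pollen_immigration == 74 / 189
        assert s.seed_immigration == 7 / 189
        assert s.fraction_both_parents == 107 / 189
        assert s.fraction_any_parent == 182 / 189


class TestDispersal:
    def test_effective_area_identities(self):
        aep, aep_ha, radius = effective_pollination_area(100.0)
        assert aep == pytest.approx(2 * np.pi * 1e4)
        assert radius == pytest.approx(np.sqrt(aep / np.pi))
        assert radius == pytest.approx(100.0 * np.sqrt(2))

    def test_summaries_on_synthetic(self, study_like):
        data, truth = study_like
        model = ParentageModel(n_sim=800)
        assignments, _ = assign_parentage(data, model, seed=13)
        disp = dispersal_summaries(assignments, data)
        assert np.all(disp.pollen_distances > 0)  # selfing excluded
        assert disp.aep_m2 == pytest.approx(2 * np.pi * disp.sigma_p2)
        assert disp.radius_m == pytest.approx(np.sqrt(disp.aep_m2 / np.pi))
        assert 0 <= disp.ks_d <= 1
        # assigned pollen distances track the true ones reasonably
        assert abs(disp.pollen_mean - np.nanmean(truth.table.pollen_distance[
            truth.table.pollen_distance > 0])) < 60
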