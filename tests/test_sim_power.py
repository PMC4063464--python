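"""Segregation simulator, error processes, stand generation and panel power."""

import itertools
from collections import Counter

import numpy as np
import pytest

from hybstand import (
    CrossSpec,
    GenotypeClass,
    GenotypeRecord,
    LocusState,
    SimConfig,
    Stage,
    apply_error,
    classify_individual,
    default_interspecific_panel,
    generate_stand,
    infer_crosses,
    make_call,
    misclassification_power,
    prob_backcross_scored_pure,
    prob_f1_scored_pure,
    reference_stand_config,
    simulate_cross,
    write_genotypes_csv,
)
from hybstand.classify import locus_state
from hybstand.sim import _pattern_calls, make_individual

G = GenotypeClass
S = LocusState


class TestSimulateCross:
    def test_pure_by_pure_is_fixed(self, panel, rng):
        seed_bb = simulate_cross(G.B, G.B, panel, rng).seed
        assert all(call == ("b", "b") for call in seed_bb.calls.values())
        seed_f1 = simulate_cross(G.B, G.D, panel, rng).seed
        assert all(call == ("b", "d") for call in seed_f1.calls.values())

    def test_f1_by_f1_segregates_1_2_1(self, panel, rng):
        """Per-locus state frequencies over many F1 x F1 seeds approach
        1/4 : 1/2 : 1/4 (HOM_B : HET : HOM_D), within 3 SE."""
        counts = Counter()
        n_seeds = 2000
        for i in range(n_seeds):
            seed = simulate_cross(G.F1, G.F1, panel, rng, f"S{i}").seed
            for locus in panel:
                counts[locus_state(seed.calls[locus.locus_id], locus)] += 1
        total = n_seeds * len(panel)
        for state, expected in ((S.HOM_B, 0.25), (S.HET, 0.5), (S.HOM_D, 0.25)):
            p = counts[state] / total
            se = np.sqrt(expected * (1 - expected) / total)
            assert abs(p - expected) < 3 * se

    def test_seed_inherits_mother_cp_and_id(self, panel, rng):
        mother = make_individual(G.D, panel, rng, "MOM")
        result = simulate_cross(mother, G.B, panel, rng, "KID")
        assert result.seed.mother_id == "MOM"
        assert result.seed.cp_haplotype == mother.cp_haplotype

    def test_transmitted_haplotypes_compose_the_seed(self, panel, rng):
        result = simulate_cross(G.F1, G.BC_B, panel, rng)
        for locus_id, m, p in zip(panel.locus_ids, result.maternal_gamete,
                                  result.paternal_gamete):
            assert result.seed.calls[locus_id] == make_call(m, p)

    def test_exotic_parent_rejected(self, panel, rng):
        with pytest.raises(ValueError):
            simulate_cross(G.EXOTIC, G.B, panel, rng)


class TestApplyError:
    def _het_record(self, panel):
        return GenotypeRecord(
            individual_id="X", stage=Stage.SEED,
            calls=_pattern_calls(panel, [S.HET] * len(panel)),
        )

    def test_zero_rates_identity(self, panel, rng):
        record = self._het_record(panel)
        assert apply_error(record, 0.0, 0.0, rng).calls == record.calls

    def test_full_missingness(self, panel, rng):
        noisy = apply_error(self._het_record(panel), 1.0, 0.0, rng)
        assert all(call is None for call in noisy.calls.values())

    def test_dropout_rate_binomial(self, panel, rng):
        """Dropout 0.02 over 10,000 het calls converts ~200 +- 3 SE, to a
        homozygote of a uniformly chosen constituent allele."""
        e, n_records = 0.02, 10_000 // len(panel) + 1
        converted = Counter()
        total = 0
        for _ in range(n_records):
            noisy = apply_error(self._het_record(panel), 0.0, e, rng)
            for call in noisy.calls.values():
                total += 1
                if call[0] == call[1]:
                    converted[call[0]] += 1
        n_converted = sum(converted.values())
        se = np.sqrt(e * (1 - e) * total)
        assert abs(n_converted - e * total) < 3 * se
        # both homozygote directions occur
        assert set(converted) == {"b", "d"}

    def test_input_record_untouched(self, panel, rng):
        record = self._het_record(panel)
        before = dict(record.calls)
        apply_error(record, 0.5, 0.5, rng)
        assert record.calls == before


class TestGenerateStand:
    def test_determinism_identical_seed(self):
        config = reference_stand_config(rng_seed=42)
        a, b = generate_stand(config), generate_stand(config)
        assert a.truth.equals(b.truth)
        for ra, rb in zip(a.all_records(), b.all_records()):
            assert ra == rb

    def test_different_seed_differs(self):
        a = generate_stand(reference_stand_config(rng_seed=1))
        b = generate_stand(reference_stand_config(rng_seed=2))
        assert not a.truth.equals(b.truth)

    def test_single_f1_adult_is_all_het(self, panel):
        config = SimConfig(
            n_adults=1, class_frequencies={G.F1: 1.0}, crosses=[],
            n_seedlings=0, missing_rate=0.0, rng_seed=0,
        )
        stand = generate_stand(config)
        (adult,) = stand.adults
        assert all(call == ("b", "d") for call in adult.calls.values())

    def test_truth_table_covers_every_individual(self):
        stand = generate_stand(reference_stand_config(rng_seed=3))
        assert set(stand.truth["individual_id"]) == {
            r.individual_id for r in stand.all_records()
        }
        seed_truth = stand.truth[stand.truth["stage"] == "seed"]
        assert (seed_truth["mother_id"] != "").all()
        assert (seed_truth["paternal_gamete"].str.len() == 35).all()

    def test_adult_marginals_match_config(self):
        """Chi-square goodness of fit of generated adult classes against the
        configured frequencies (p > 0.001)."""
        from scipy import stats

        config = reference_stand_config(rng_seed=5)
        config.n_adults = 1000
        config.crosses = []
        config.n_seedlings = 0
        stand = generate_stand(config)
        observed = Counter(stand.truth["true_class"])
        classes = list(config.class_frequencies)
        obs = [observed[c.value] for c in classes]
        exp = [config.class_frequencies[c] * config.n_adults for c in classes]
        assert stats.chisquare(obs, exp).pvalue > 0.001

    def test_invalid_config_lists_fields(self):
        config = SimConfig(missing_rate=1.5, n_loci=0)
        with pytest.raises(ValueError, match="missing_rate") as excinfo:
            generate_stand(config)
        assert "n_loci" in str(excinfo.value)

    def test_config_yaml_round_trip(self, tmp_path):
        config = reference_stand_config(rng_seed=9, dropout_rate=0.01)
        path = tmp_path / "sim.yaml"
        config.to_yaml(path)
        assert SimConfig.from_yaml(path) == config

    def test_zero_error_full_pipeline_recovery(self):
        """Classification, gamete subtraction and cross typing reproduce the
        truth table exactly on an error-free stand."""
        from hybstand.pedigree import AMBIGUOUS, MISSING

        config = reference_stand_config(rng_seed=11, seed_scale=0.2,
                                        missing_rate=0.0, dropout_rate=0.0)
        stand = generate_stand(config)
        truth = stand.truth.set_index("individual_id")
        for record in stand.all_records():
            assigned = classify_individual(record, stand.panel).genotype_class
            assert assigned.value == truth.loc[record.individual_id, "true_class"]
        crosses = infer_crosses(stand.seeds, stand.adults, stand.panel)
        from hybstand import subtract_gamete

        mothers = {m.individual_id: m for m in stand.adults}
        for cross in crosses:
            row = truth.loc[cross.seed_id]
            assert cross.cross_type.value == row["true_cross_type"]
            inference = subtract_gamete(
                next(s for s in stand.seeds if s.individual_id == cross.seed_id),
                mothers[cross.mother_id], stand.panel,
            )
            for locus_id, true_allele in zip(stand.panel.locus_ids,
                                             row["paternal_gamete"]):
                inferred = inference.paternal[locus_id]
                if inferred not in (AMBIGUOUS, MISSING):
                    assert inferred == true_allele


def _enumerated_assignment_prob(per_locus_dist, k, target_class, min_informative, panel):
    """Independent oracle: exact enumeration of all state vectors over k iid
    loci, running the record classifier on each."""
    total = 0.0
    items = list(per_locus_dist.items())
    for combo in itertools.product(items, repeat=k):
        prob = 1.0
        for _, p in combo:
            prob *= p
        if prob == 0.0:
            continue
        states = [s for s, _ in combo]
        record = GenotypeRecord(
            individual_id="X", stage=Stage.SEED, calls=_pattern_calls(panel, states)
        )
        if classify_individual(record, panel, min_informative).genotype_class is target_class:
            total += prob
    return total


class TestPowerClosedForms:
    @pytest.mark.parametrize("e,m", [(0.0, 0.0), (0.3, 0.0), (0.2, 0.1)])
    def test_f1_scored_pure_matches_enumeration(self, small_panel, e, m):
        k, t = 5, 3
        dist = {
            S.MISSING: m,
            S.HET: (1 - m) * (1 - e),
            S.HOM_B: (1 - m) * e / 2,
            S.HOM_D: (1 - m) * e / 2,
        }
        oracle = sum(
            _enumerated_assignment_prob(dist, k, cls, t, small_panel)
            for cls in (G.B, G.D)
        )
        assert prob_f1_scored_pure(k, e, m, t) == pytest.approx(oracle, abs=1e-12)

    @pytest.mark.parametrize("e,m", [(0.0, 0.0), (0.3, 0.0), (0.2, 0.1)])
    def test_backcross_scored_pure_matches_enumeration(self, small_panel, e, m):
        # BC-B seed from an F1 mother x pure-B father, dropout e, missing m
        k, t = 5, 3
        p_hom_b = 0.5 * (1 + e / 2)
        dist = {
            S.MISSING: m,
            S.HOM_B: (1 - m) * p_hom_b,
            S.HET: (1 - m) * 0.5 * (1 - e),
            S.HOM_D: (1 - m) * e / 4,
        }
        oracle = _enumerated_assignment_prob(dist, k, G.B, t, small_panel)
        assert prob_backcross_scored_pure(k, e, m, t) == pytest.approx(oracle, abs=1e-12)

    def test_error_free_f1_never_misclassified(self):
        assert prob_f1_scored_pure(1, 0.0) == 0.0
        assert prob_f1_scored_pure(35, 0.0) == 0.0

    def test_anomaly_positive_and_vanishing_with_dropout(self):
        """Hybrid-mother seeds can be scored pure once dropout is nonzero, and
        the probability decreases to the pure segregation floor as dropout -> 0."""
        k = 35
        floor = prob_backcross_scored_pure(k, 0.0)
        assert floor == pytest.approx(0.5**35)
        probs = [prob_backcross_scored_pure(k, e) for e in (0.05, 0.02, 0.01, 0.0)]
        assert all(p > 0 for p in probs)
        assert probs == sorted(probs, reverse=True)
        assert prob_f1_scored_pure(k, 0.05) > 0 == prob_f1_scored_pure(k, 0.0)


class TestMisclassificationPower:
    def test_monte_carlo_matches_closed_form(self):
        """Error-free BC-B seeds from F1 mothers at k in {5, 12}: the MC
        fraction scored pure B matches (1/2)^k within 3 SE at 1e5 reps."""
        for k in (5, 12):
            config = SimConfig(
                n_loci=k, crosses=[CrossSpec(G.F1, G.B, 1)],
                missing_rate=0.0, dropout_rate=0.0, rng_seed=101,
            )
            matrix = misclassification_power(config, n_reps=100_000)
            label = "F1 x B"
            analytic = prob_backcross_scored_pure(k)
            assert matrix.analytic[(label, "B")] == pytest.approx(analytic)
            se = np.sqrt(analytic * (1 - analytic) / matrix.n_reps)
            assert abs(matrix.probability(label, G.B) - analytic) < 3 * se

    def test_dropout_f1_mc_matches_closed_form(self):
        """F1 seeds with heavy dropout at small k: MC within 3 SE of the
        closed form (the regime where the pure-scored anomaly is visible)."""
        k, e = 5, 0.3
        config = SimConfig(
            n_loci=k, crosses=[CrossSpec(G.B, G.D, 1)],
            missing_rate=0.0, dropout_rate=e, rng_seed=202,
        )
        matrix = misclassification_power(config, n_reps=100_000, min_informative=3)
        analytic = prob_f1_scored_pure(k, e, min_informative=3)
        mc = matrix.probability("B x D", G.B) + matrix.probability("B x D", G.D)
        se = np.sqrt(analytic * (1 - analytic) / matrix.n_reps)
        assert abs(mc - analytic) < 3 * se

    def test_rows_sum_to_rep_count(self):
        config = SimConfig(
            n_loci=8,
            crosses=[CrossSpec(G.F1, G.B, 1), CrossSpec(G.F1, G.F1, 1)],
            missing_rate=0.01, dropout_rate=0.02, rng_seed=5,
        )
        matrix = misclassification_power(config, n_reps=500)
        assert (matrix.counts.sum(axis=1) == 500).all()
        assert (matrix.counts.values >= 0).all()

    def test_rng_determinism(self):
        config = reference_stand_config(rng_seed=17)
        a = misclassification_power(config, n_reps=2000)
        b = misclassification_power(config, n_reps=2000)
        assert a.counts.equals(b.counts)
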