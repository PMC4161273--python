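import numpy as np
import pytest

from kgi import (
    ConfusionCounts,
    EvolutionConfig,
    FitnessEvaluator,
    KnowledgeMatrix,
    PhenotypeVector,
    balanced_accuracy,
    confusion_from_predictions,
    default_grammar,
    evolve_deme,
    initialize_population,
    map_genome,
    migrate,
    model_from_text,
    random_valid_genome,
    run_evolution,
)
from kgi.evolution import FitnessRecord
from kgi.grammar import Genome


class TestBalancedAccuracy:
    def test_perfect_classifier(self):
        assert balanced_accuracy(ConfusionCounts(39, 0, 454, 0)) == 1.0

    def test_majority_class_predictor_scores_half(self):
        # predicting every sample negative on a 39/454 imbalance
        assert balanced_accuracy(ConfusionCounts(0, 0, 454, 39)) == 0.5

    def test_hand_computed_mixture(self):
        c = ConfusionCounts(tp=30, fp=154, tn=300, fn=9)
        assert balanced_accuracy(c) == pytest.approx(
            (30 / 39 + 300 / 454) / 2, abs=1e-12
        )

    def test_absent_class_is_an_error(self):
        with pytest.raises(ValueError):
            balanced_accuracy(ConfusionCounts(0, 0, 10, 0))

    def test_invariant_to_duplicating_negatives(self):
        c1 = ConfusionCounts(30, 154, 300, 9)
        c5 = ConfusionCounts(30, 154 * 5, 300 * 5, 9)
        assert balanced_accuracy(c1) == pytest.approx(balanced_accuracy(c5))

    def test_matches_sklearn_on_random_predictions(self, rng):
        from sklearn.metrics import balanced_accuracy_score

        for _ in range(50):
            y = rng.integers(0, 2, size=40)
            if len(set(y.tolist())) < 2:
                continue
            p = rng.integers(0, 2, size=40)
            c = confusion_from_predictions(y, p)
            assert balanced_accuracy(c) == pytest.approx(
                balanced_accuracy_score(y, p)
            )


class TestInitialization:
    def test_population_size_and_all_functional(self):
        g = default_grammar([f"F{i}" for i in range(6)])
        cfg = EvolutionConfig(pop_per_deme=50, n_demes=2, generations=5,
                              migration_interval=5, seed=1)
        pop = initialize_population(cfg, g)
        assert len(pop) == 100
        assert all(map_genome(genome, g).success for genome in pop)
        assert all(20 <= len(genome) <= 400 for genome in pop)

    def test_same_seed_reproduces_population(self):
        g = default_grammar(["F1", "F2"])
        cfg = EvolutionConfig(pop_per_deme=20, n_demes=1, generations=5,
                              migration_interval=5, seed=9)
        a = initialize_population(cfg, g)
        b = initialize_population(cfg, g)
        assert all(
            np.array_equal(x.codons, y.codons) for x, y in zip(a, b)
        )

    def test_grown_genomes_beat_uniform_random_validity(self, rng):
        g = default_grammar([f"F{i}" for i in range(6)])
        grown_ok = sum(
            map_genome(random_valid_genome(g, rng), g).success
            for _ in range(300)
        )
        uniform_ok = sum(
            map_genome(
                Genome(rng.integers(0, 65536, size=int(rng.integers(20, 401)))),
                g,
            ).success
            for _ in range(300)
        )
        assert grown_ok == 300
        assert uniform_ok < 300


def _records(genomes, fitnesses):
    return [
        FitnessRecord(g, model_from_text("PADD(1.0*F1, 1.0*F1)"), f)
        for g, f in zip(genomes, fitnesses)
    ]


def _genomes(rng, n):
    return [Genome(rng.integers(0, 65536, size=25)) for _ in range(n)]


class TestEvolveDeme:
    def test_elitism_preserves_best_genome(self, rng):
        genomes = _genomes(rng, 10)
        fits = [0.1, 0.9, 0.3, 0.2, 0.5, 0.4, 0.6, 0.0, 0.7, 0.8]
        cfg = EvolutionConfig(pop_per_deme=10, n_demes=1, generations=5,
                              migration_interval=5, elitism=1)
        nxt = evolve_deme(_records(genomes, fits), cfg, rng)
        assert len(nxt) == 10
        assert np.array_equal(nxt[0].codons, genomes[1].codons)

    def test_no_variation_means_parent_copies(self, rng):
        genomes = _genomes(rng, 8)
        fits = list(np.linspace(0, 1, 8))
        cfg = EvolutionConfig(pop_per_deme=8, n_demes=1, generations=5,
                              migration_interval=5, crossover_prob=0.0,
                              mutation_prob_per_codon=0.0)
        nxt = evolve_deme(_records(genomes, fits), cfg, rng)
        originals = {g.codons.tobytes() for g in genomes}
        assert all(child.codons.tobytes() in originals for child in nxt)


class TestMigrate:
    def _deme(self, rng, fits):
        return _records(_genomes(rng, len(fits)), fits)

    def test_ring_exchange_between_two_demes(self, rng):
        cfg = EvolutionConfig(pop_per_deme=3, n_demes=2, generations=5,
                              migration_interval=5)
        d0 = self._deme(rng, [0.9, 0.1, 0.2])
        d1 = self._deme(rng, [0.3, 0.8, 0.4])
        out = migrate([d0, d1], cfg)
        bytes0 = {r.genome.codons.tobytes() for r in out[0]}
        bytes1 = {r.genome.codons.tobytes() for r in out[1]}
        assert d1[1].genome.codons.tobytes() in bytes0  # best of 1 -> deme 0
        assert d0[0].genome.codons.tobytes() in bytes1  # best of 0 -> deme 1
        # the worst were the ones replaced
        assert d0[1].genome.codons.tobytes() not in bytes0
        assert d1[0].genome.codons.tobytes() not in bytes1

    def test_single_deme_is_noop(self, rng):
        cfg = EvolutionConfig(pop_per_deme=3, n_demes=1, generations=5,
                              migration_interval=5)
        d0 = self._deme(rng, [0.5, 0.6, 0.7])
        out = migrate([d0], cfg)
        assert [r.genome for r in out[0]] == [r.genome for r in d0]

    def test_global_best_never_decreases(self, rng):
        cfg = EvolutionConfig(pop_per_deme=4, n_demes=3, generations=5,
                              migration_interval=5)
        demes = [
            self._deme(rng, list(rng.random(4))) for _ in range(3)
        ]
        before = max(r.fitness for d in demes for r in d)
        after = max(r.fitness for d in migrate(demes, cfg) for r in d)
        assert after >= before


class TestFitnessEvaluation:
    def test_constant_model_predicts_all_positive(self, separable_matrix):
        km, labels = separable_matrix
        ev = FitnessEvaluator(km, labels)
        # zero weights -> score exactly 0.5 -> classified positive (tie rule)
        m = model_from_text("PADD(0.0*FA, 0.0*FB)")
        assert ev.fitness_of_model(m) == pytest.approx(0.5)

    def test_failed_mapping_scores_zero(self, separable_matrix):
        km, labels = separable_matrix
        ev = FitnessEvaluator(km, labels)
        rec = ev.evaluate(Genome(np.array([1])))  # forces endless recursion
        assert not rec.success
        assert rec.fitness == 0.0

    def test_separating_model_scores_one(self, rng):
        n = 30
        y = np.r_[np.ones(10, int), np.zeros(20, int)]
        vals = np.where(y == 1, 5.0, -5.0).reshape(-1, 1)
        km = KnowledgeMatrix([f"s{i}" for i in range(n)], ["F"], vals)
        ev = FitnessEvaluator(km, PhenotypeVector(km.sample_ids, y))
        assert ev.fitness_of_model(model_from_text("PADD(1.0*F, 1.0*F)")) == 1.0

    def test_alignment_mismatch_rejected(self, separable_matrix):
        km, labels = separable_matrix
        shuffled = PhenotypeVector(
            list(reversed(labels.sample_ids)), labels.labels[::-1].copy()
        )
        with pytest.raises(ValueError):
            FitnessEvaluator(km, shuffled)


class TestRunEvolution:
    def test_recovers_separable_signal(self, separable_matrix):
        """3-sigma-shifted feature: the evolved model should reach the
        empirical single-threshold optimum (~0.93 on this frozen draw)."""
        km, labels = separable_matrix
        cfg = EvolutionConfig(pop_per_deme=200, n_demes=2, generations=30,
                              migration_interval=10, seed=3)
        best = run_evolution(km, labels, cfg)
        assert best.fitness >= 0.93
        assert "FA" in best.model.features_used

    def test_seed_reproducibility_across_worker_counts(self, separable_matrix):
        km, labels = separable_matrix
        base = EvolutionConfig(pop_per_deme=40, n_demes=3, generations=8,
                               migration_interval=4, seed=11)
        serial = run_evolution(km, labels, base)
        threaded = run_evolution(
            km, labels, EvolutionConfig(**{**base.__dict__, "n_jobs": 3})
        )
        assert serial.fitness == threaded.fitness
        assert np.array_equal(serial.genome.codons, threaded.genome.codons)
        assert serial.model == threaded.model

    def test_best_fitness_monotone_with_elitism(self, separable_matrix):
        km, labels = separable_matrix
        log: list[dict] = []
        cfg = EvolutionConfig(pop_per_deme=40, n_demes=2, generations=12,
                              migration_interval=4, seed=2, elitism=1)
        run_evolution(km, labels, cfg, log=log)
        for deme in range(2):
            series = [r["best_fitness"] for r in log if r["deme"] == deme]
            assert len(series) == 12
            assert all(b >= a for a, b in zip(series, series[1:]))

    def test_degenerate_labels_rejected(self, separable_matrix):
        km, _ = separable_matrix
        ones = PhenotypeVector(km.sample_ids, np.ones(len(km.sample_ids), int))
        with pytest.raises(ValueError):
            run_evolution(km, ones, EvolutionConfig())
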