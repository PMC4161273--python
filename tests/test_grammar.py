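import numpy as np
import pytest

from kgi import (
    Genome,
    GrammarError,
    classify,
    default_grammar,
    evaluate_network,
    genome_from_bits,
    map_genome,
    model_from_text,
)
from oracles import oracle_map


def _random_genome(rng, min_len=1, max_len=60, wrap_limit=2):
    length = int(rng.integers(min_len, max_len + 1))
    return Genome(rng.integers(0, 65536, size=length), wrap_limit)


class TestDefaultGrammar:
    @pytest.mark.parametrize("n_features", [2, 356])
    def test_var_alternatives_enumerate_features(self, n_features):
        g = default_grammar([f"F{i}" for i in range(n_features)])
        assert len(g.alternatives("<var>")) == n_features

    def test_four_activation_alternatives(self):
        g = default_grammar(["F1"])
        assert [a[0] for a in g.alternatives("<func>")] == [
            "PADD",
            "PSUB",
            "PMULT",
            "PDIV",
        ]

    def test_empty_feature_list_rejected(self):
        with pytest.raises(GrammarError):
            default_grammar([])

    def test_bnf_rendering_mentions_every_rule(self):
        text = default_grammar(["F1", "F2"]).to_bnf()
        for nt in ("<net>", "<node>", "<func>", "<in>", "<w>", "<var>"):
            assert nt in text


class TestMapGenome:
    def test_hand_traced_genome(self):
        """Frozen leftmost-derivation trace: arity 0 -> 2 inputs, func 1 ->
        PSUB, then (in 0, w 0, var 0) and (in 0, w 0, var 1)."""
        g = default_grammar(["F1", "F2"])
        out = map_genome(Genome(np.array([0, 1, 0, 0, 0, 0, 0, 1])), g)
        assert out.success
        assert out.model.to_text() == "PSUB(1.0*F1, 1.0*F2)"
        assert out.codons_consumed == 8
        assert out.wrapped == 0

    def test_all_zero_codons_terminate_on_first_alternatives(self):
        g = default_grammar(["F1", "F2"])
        out = map_genome(Genome(np.zeros(8, dtype=int)), g)
        assert out.success
        assert out.model.to_text() == "PADD(1.0*F1, 1.0*F1)"

    def test_forced_recursion_exhausts_wraps(self):
        # codon 1 always selects the recursive <in> alternative
        g = default_grammar(["F1", "F2"])
        out = map_genome(Genome(np.array([1]), wrap_limit=2), g)
        assert not out.success
        assert out.wrapped == 2
        assert out.model is None

    def test_single_alternative_rules_consume_no_codons(self):
        g = default_grammar(["ONLY"])  # <var> has one alternative
        out = map_genome(Genome(np.array([0, 0, 0, 0, 0, 0])), g)
        assert out.success
        # node arity, func, and per input: <in>, <w> -> 4 codons... but
        # <var> consumed nothing: 2 + 2*2 = 6 total
        assert out.codons_consumed == 6

    def test_determinism(self, rng):
        g = default_grammar([f"F{i}" for i in range(7)])
        for _ in range(200):
            genome = _random_genome(rng)
            a = map_genome(genome, g)
            b = map_genome(genome, g)
            assert a.success == b.success
            if a.success:
                assert a.model == b.model

    def test_agrees_with_recursive_descent_oracle(self, rng):
        feats = [f"F{i}" for i in range(5)]
        g = default_grammar(feats)
        n_success = 0
        for _ in range(1000):
            genome = _random_genome(rng)
            got = map_genome(genome, g)
            expected = oracle_map(genome.codons, feats, genome.wrap_limit)
            assert got.success == (expected is not None)
            if expected is not None:
                assert got.model == expected
                n_success += 1
        assert 0 < n_success < 1000  # both outcomes exercised

    def test_appending_unread_codons_is_neutral(self, rng):
        g = default_grammar([f"F{i}" for i in range(5)])
        for _ in range(100):
            genome = _random_genome(rng, min_len=30, max_len=60)
            out = map_genome(genome, g)
            if not out.success or out.wrapped > 0:
                continue
            extended = Genome(
                np.concatenate(
                    [genome.codons, rng.integers(0, 65536, size=10)]
                ),
                genome.wrap_limit,
            )
            assert map_genome(extended, g).model == out.model


class TestEvaluateNetwork:
    def test_sequential_subtraction_and_logistic(self):
        m = model_from_text("PSUB(1.0*F1, 1.0*F2)")
        score = evaluate_network(m, {"F1": 2.0, "F2": 0.5})
        assert score == pytest.approx(1 / (1 + np.exp(-1.5)), abs=1e-6)
        assert score == pytest.approx(0.8176, abs=1e-4)

    def test_protected_division_by_zero(self):
        m = model_from_text("PDIV(1.0*F1, 1.0*F2)")
        assert evaluate_network(m, {"F1": 5.0, "F2": 0.0}) == pytest.approx(
            1 / (1 + np.exp(-1.0)), abs=1e-6
        )

    def test_zero_weights_give_exact_half(self):
        m = model_from_text("PADD(0.0*F1, 0.0*F2)")
        assert evaluate_network(m, {"F1": 9.9, "F2": -3.0}) == 0.5

    def test_missing_feature_named(self):
        from kgi.model import MissingFeatureError

        m = model_from_text("PADD(1.0*F1, 1.0*FX)")
        with pytest.raises(MissingFeatureError, match="FX"):
            evaluate_network(m, {"F1": 1.0})

    def test_total_and_bounded_on_extreme_inputs(self, rng):
        feats = [f"F{i}" for i in range(4)]
        g = default_grammar(feats)
        extremes = [0.0, 1e-12, -1e300, 1e300, 5.0]
        for _ in range(300):
            out = map_genome(_random_genome(rng), g)
            if not out.success:
                continue
            row = {f: float(rng.choice(extremes)) for f in feats}
            s = evaluate_network(out.model, row)
            assert 0.0 < s < 1.0


class TestClassify:
    @pytest.mark.parametrize(
        "score,expected", [(0.5, 1), (0.49, 0), (0.8176, 1), (0.999, 1)]
    )
    def test_threshold_convention(self, score, expected):
        assert classify(score) == expected


class TestBitstringGenomes:
    def test_eight_bit_chunks(self):
        g = genome_from_bits("0000000100000000", codon_bits=8)
        assert g.codons.tolist() == [1, 0]

    def test_bad_input_rejected(self):
        with pytest.raises(GrammarError):
            genome_from_bits("0101", codon_bits=8)
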