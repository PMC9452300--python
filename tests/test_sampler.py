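"""Sampler: inside algorithm, stochastic traceback, constraints."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from strandscape import (
    BitVector,
    Grammar,
    constraints_from_codes,
    in_silico_ensemble,
    inside_fill,
    sample_per_molecule,
    sample_structures,
)
from strandscape.bitvector import MASK
from strandscape.sampler import molecule_seed

from oracles import exact_distribution


class TestInsideFill:
    def test_no_canonical_pairs_leaves_open_chain_only(self, grammar):
        # AAAA cannot pair at all: total weight is the open chain's u^4
        tables = inside_fill("AAAA", grammar)
        assert tables.total == pytest.approx(grammar.unpaired_weight ** 4)

    def test_all_forced_unpaired_collapses_to_open_chain(self, grammar):
        seq = "GGGGAAAACCCC"
        cons = np.ones(len(seq), dtype=bool)
        tables = inside_fill(seq, grammar, cons)
        assert tables.total == pytest.approx(grammar.unpaired_weight ** len(seq))

    @pytest.mark.parametrize("seq", ["GCGAAACGC", "GGGGAAAACCCC", "GCAUCGAAAGCUAG"])
    def test_total_matches_enumeration(self, grammar, seq):
        dist = exact_distribution(seq, grammar)
        # oracle returns probabilities; rebuild Z from unnormalised weights
        from oracles import enumerate_pair_sets, structure_weight

        def can_pair(i, j):
            return grammar.pair_weights.get(seq[i] + seq[j], 0.0) > 0

        Z = sum(
            structure_weight(seq, ps, grammar)
            for ps in enumerate_pair_sets(seq, grammar.min_hairpin, can_pair)
        )
        assert inside_fill(seq, grammar).total == pytest.approx(Z, rel=1e-12)
        assert len(dist) > 1

    def test_constrained_total_matches_enumeration(self, grammar):
        seq = "GGGGAAAACCCC"
        cons = np.zeros(len(seq), dtype=bool)
        cons[[0, 5]] = True
        from oracles import enumerate_pair_sets, structure_weight

        def can_pair(i, j):
            if cons[i] or cons[j]:
                return False
            return grammar.pair_weights.get(seq[i] + seq[j], 0.0) > 0

        Z = sum(
            structure_weight(seq, ps, grammar)
            for ps in enumerate_pair_sets(seq, grammar.min_hairpin, can_pair)
        )
        assert inside_fill(seq, grammar, cons).total == pytest.approx(Z, rel=1e-12)


class TestSampling:
    def test_unpairable_sequence_yields_open_chains(self, grammar):
        out = sample_structures("AAAA", grammar, n_samples=10, seed=3)
        assert all(s.dot_bracket == "...." for s in out)

    def test_forced_position_never_paired(self, grammar):
        seq = "GGGGAAAACCCC"
        cons = np.zeros(len(seq), dtype=bool)
        cons[2] = True  # 1-based position 3
        out = sample_structures(seq, grammar, cons, n_samples=200, seed=5)
        assert all(s.partner()[3] == 0 for s in out)

    def test_same_seed_reproduces_samples(self, grammar):
        a = sample_structures("GGGGAAAACCCC", grammar, n_samples=25, seed=11)
        b = sample_structures("GGGGAAAACCCC", grammar, n_samples=25, seed=11)
        assert [s.dot_bracket for s in a] == [s.dot_bracket for s in b]

    def test_empirical_frequencies_match_exact_distribution(self, grammar):
        seq = "GGGGAAAACCCC"
        dist = exact_distribution(seq, grammar)
        n = 20_000
        out = sample_structures(seq, grammar, n_samples=n, seed=17)
        from collections import Counter

        freq = Counter(s.pairs for s in out)
        tvd = 0.5 * sum(
            abs(freq.get(k, 0) / n - p) for k, p in dist.items()
        ) + 0.5 * sum(freq[k] / n for k in freq if k not in dist)
        assert tvd < 0.03

    def test_mutation_that_destroys_helix_removes_its_pairs(self, grammar):
        # GGGG...CCCC can form the 4-pair stem; AAAA...CCCC cannot
        good = sample_structures("GGGGAAAACCCC", grammar, n_samples=300, seed=7)
        assert any(s.n_pairs > 0 for s in good)
        bad = sample_structures("AAAAAAAACCCC", grammar, n_samples=300, seed=7)
        assert all(s.n_pairs == 0 for s in bad)


class TestPerMolecule:
    def _bv(self, codes, read_id="r0"):
        return BitVector(
            read_id=read_id, reference_id="ref", codes=np.array(codes, dtype=np.int8)
        )

    def test_constraint_derivation_from_codes(self):
        codes = np.array([0, 1, MASK, 0, 1], dtype=np.int8)
        np.testing.assert_array_equal(
            constraints_from_codes(codes), [False, True, False, False, True]
        )

    def test_one_structure_per_bitvector(self, grammar):
        seq = "GGGGAAAACCCC"
        bvs = [self._bv([0] * 12, f"r{k}") for k in range(3)]
        out = sample_per_molecule(bvs, seq, grammar, samples_per_bitvector=1, seed=0)
        assert [rid for rid, _ in out] == ["r0", "r1", "r2"]

    def test_fully_mutated_molecule_gives_open_chain(self, grammar):
        seq = "GGGGAAAACCCC"
        bvs = [self._bv([1] * 12)]
        out = sample_per_molecule(bvs, seq, grammar, samples_per_bitvector=4, seed=0)
        assert all(s.n_pairs == 0 for _, s in out)

    def test_results_independent_of_processing_order(self, grammar):
        seq = "GGGGAAAACCCC"
        rng = np.random.default_rng(0)
        bvs = [
            self._bv(rng.integers(0, 2, size=12).astype(np.int8), f"r{k}")
            for k in range(6)
        ]
        full = {}
        for rid, s in sample_per_molecule(bvs, seq, grammar, seed=9):
            full[rid] = s.dot_bracket
        subset = {}
        for rid, s in sample_per_molecule(bvs[::-1], seq, grammar, seed=9):
            subset[rid] = s.dot_bracket
        assert full == subset

    def test_molecule_seed_depends_on_read_id_only(self):
        a = molecule_seed(5, "molA").generate_state(4)
        b = molecule_seed(5, "molA").generate_state(4)
        c = molecule_seed(5, "molB").generate_state(4)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_simulated_loop_modifications_stay_unpaired(self, grammar):
        # hairpin ground truth, loop positions modified, p_paired_mod = 0
        from strandscape import SimulationConfig, simulate

        seq = "GGGGAAAACCCC"
        conf = "((((....))))"
        cfg = SimulationConfig(
            sequence=seq,
            conformations=(conf,),
            weights=(1.0,),
            n_molecules=30,
            p_unpaired_mod=0.5,
            p_paired_mod=0.0,
            p_background=0.0,
            seed=4,
        )
        sim = simulate(cfg)
        tagged = sample_per_molecule(sim.plus, seq, grammar, seed=8)
        for bv, (rid, s) in zip(sim.plus, tagged):
            assert rid == bv.read_id
            part = s.partner()[1:]
            mutated = bv.codes == 1
            assert not np.any((part > 0) & mutated)


class TestEnsembleMode:
    def test_ensemble_of_unpairable_sequence(self, grammar):
        out = in_silico_ensemble("AAAA", grammar, n_samples=50, seed=2)
        assert len(out) == 50
        assert all(s.n_pairs == 0 for s in out)

    def test_seeded_ensemble_is_byte_identical(self, grammar):
        a = in_silico_ensemble("GGGGAAAACCCC", grammar, n_samples=40, seed=21)
        b = in_silico_ensemble("GGGGAAAACCCC", grammar, n_samples=40, seed=21)
        assert "".join(s.dot_bracket for s in a) == "".join(s.dot_bracket for s in b)


class TestGrammar:
    def test_rejects_invalid_parameters(self):
        with pytest.raises(ValueError):
            Grammar(unpaired_weight=0.0)
        with pytest.raises(ValueError):
            Grammar(helix_init=0.0)
        with pytest.raises(ValueError):
            Grammar(pair_weights={"AA": 1.0})

    def test_round_trips_through_dict(self, grammar):
        assert Grammar.from_dict(grammar.to_dict()) == grammar

    def test_log_weight_matches_oracle(self, grammar):
        from strandscape import SecondaryStructure
        from oracles import structure_weight

        seq = "GGGGAAAACCCC"
        s = SecondaryStructure.from_dot_bracket("((((....))))")
        oracle = structure_weight(seq, frozenset((i - 1, j - 1) for i, j in s.pairs), grammar)
        assert np.exp(grammar.log_weight(seq, s)) == pytest.approx(oracle, rel=1e-12)


@settings(derandomize=True, max_examples=30, deadline=None)
@given(
    st.integers(min_value=0, max_value=2 ** 31 - 1),
    st.lists(st.integers(0, 11), min_size=0, max_size=6),
)
def test_constraint_soundness_property(seed, forced_positions):
    """No sampled structure ever pairs a force-unpaired position."""
    seq = "GGCGAAAACGCC"
    cons = np.zeros(len(seq), dtype=bool)
    for p in forced_positions:
        cons[p] = True
    for s in sample_structures(seq, constraints=cons, n_samples=20, seed=seed):
        part = s.partner()[1:] > 0
        assert not np.any(part & cons)
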