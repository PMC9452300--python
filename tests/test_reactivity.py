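"""Mutation rates, the reactivity equation, normalization, correlation."""

import numpy as np
import pytest

from strandscape import (
    BitVector,
    MASK,
    compute_profile,
    mutation_rate,
    mutation_rates,
    normalize,
    raw_reactivity,
    replicate_correlation,
)


def _bvs(columns, channel="plus"):
    """Build bit vectors from a list of per-read code lists."""
    return [
        BitVector(f"r{k}", "ref", np.array(codes, dtype=np.int8), channel)
        for k, codes in enumerate(columns)
    ]


class TestMutationRate:
    def test_no_mutations(self):
        bvs = _bvs([[0], [0], [0], [0]])
        assert mutation_rate(bvs, 1) == 0.0

    def test_mask_excluded_from_denominator(self):
        bvs = _bvs([[1], [0], [MASK], [1]])
        assert mutation_rate(bvs, 1) == pytest.approx(2 / 3)

    def test_all_mask_is_undefined(self):
        bvs = _bvs([[MASK], [MASK]])
        assert np.isnan(mutation_rate(bvs, 1))

    def test_specificity_identity(self):
        """1 − MR(−) equals the fraction of 0 codes among informative codes."""
        rng = np.random.default_rng(3)
        cols = rng.choice([0, 1, MASK], size=(50, 7), p=[0.8, 0.1, 0.1])
        bvs = _bvs(cols.tolist(), channel="minus")
        rates, _ = mutation_rates(bvs)
        for pos in range(7):
            col = cols[:, pos]
            informative = col[col != MASK]
            if informative.size == 0:
                assert np.isnan(rates[pos])
            else:
                zeros = np.sum(informative == 0)
                assert 1 - rates[pos] == pytest.approx(zeros / informative.size)


class TestRawReactivity:
    def test_equal_rates_give_zero(self):
        assert raw_reactivity(0.3, 0.3) == 0.0

    def test_zero_background(self):
        assert raw_reactivity(0.08, 0.0) == pytest.approx(0.08)

    def test_printed_formula_example(self):
        assert raw_reactivity(0.08, 0.02) == pytest.approx(0.06 / 0.98)

    def test_saturated_control_is_undefined(self):
        assert np.isnan(raw_reactivity(0.5, 1.0))

    def test_negative_reactivities_clamped_to_zero(self):
        assert raw_reactivity(0.01, 0.05) == 0.0

    def test_matches_direct_evaluation_on_grid(self):
        mp, mm = np.meshgrid(np.linspace(0, 1, 100), np.linspace(0, 0.99, 100))
        got = raw_reactivity(mp.ravel(), mm.ravel())
        expected = np.maximum((mp.ravel() - mm.ravel()) / (1 - mm.ravel()), 0.0)
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_pure_function_of_rates(self):
        # invariant to coverage: only the rates matter
        assert raw_reactivity(0.08, 0.02) == raw_reactivity(0.08, 0.02)


class TestNormalize:
    def test_constant_profile_scales_to_one(self):
        raw = np.full(50, 0.37)
        np.testing.assert_allclose(normalize(raw), 1.0)

    def test_two_eight_rule_on_1_to_100(self):
        raw = np.arange(1.0, 101.0)
        normed = normalize(raw)
        divisor = np.mean(np.arange(91.0, 99.0))  # values 91..98
        assert divisor == 94.5
        np.testing.assert_allclose(normed, raw / divisor)

    def test_undefined_entries_pass_through(self):
        raw = np.arange(1.0, 31.0)
        raw[[3, 17]] = np.nan
        normed = normalize(raw)
        assert np.isnan(normed[3]) and np.isnan(normed[17])
        assert np.isfinite(normed[0])

    def test_too_few_defined_positions_is_an_error(self):
        with pytest.raises(ValueError, match="skip normalization"):
            normalize(np.arange(5.0))

    def test_boxplot_variant_runs(self):
        raw = np.concatenate([np.linspace(0, 1, 50), [30.0]])  # one outlier
        normed = normalize(raw, method="boxplot")
        assert np.nanmax(normed[:-1]) <= 1.5


class TestReplicateCorrelation:
    def test_self_correlation_is_one(self):
        from strandscape.reactivity import ReactivityProfile

        raw = np.linspace(0, 1, 30)
        prof = ReactivityProfile(
            "ref", raw, raw, raw, raw, np.ones(30), np.ones(30), np.zeros(30, bool)
        )
        r, n = replicate_correlation(prof, prof)
        assert r == pytest.approx(1.0)
        assert n == 30

    def test_negated_profile_anticorrelates(self):
        from strandscape.reactivity import ReactivityProfile

        raw = np.linspace(0, 1, 30)
        flipped = raw.mean() - (raw - raw.mean())
        a = ReactivityProfile(
            "ref", raw, raw, raw, raw, np.ones(30), np.ones(30), np.zeros(30, bool)
        )
        b = ReactivityProfile(
            "ref", raw, raw, flipped, flipped, np.ones(30), np.ones(30), np.zeros(30, bool)
        )
        r, _ = replicate_correlation(a, b)
        assert r == pytest.approx(-1.0)

    def test_too_few_joint_positions(self):
        from strandscape.reactivity import ReactivityProfile

        raw = np.full(30, np.nan)
        raw[:2] = 1.0
        prof = ReactivityProfile(
            "ref", raw, raw, raw, raw, np.ones(30), np.ones(30), np.zeros(30, bool)
        )
        with pytest.raises(ValueError, match="jointly defined"):
            replicate_correlation(prof, prof)

    def test_simulator_replicates_correlate(self):
        """Two replicates from identical ground truth agree (r > 0.9)."""
        from strandscape import simulate, three_state_fixture

        profiles = []
        for seed in (11, 12):
            cfg = three_state_fixture(n_molecules=2000, seed=seed)
            sim = simulate(cfg)
            profiles.append(
                compute_profile(sim.plus, sim.minus, reference=cfg.reference)
            )
        r, n = replicate_correlation(*profiles)
        assert n > 50
        # piloted margin for this fixture's 122 positions at 2,000 reads
        assert r > 0.85


class TestComputeProfile:
    def test_simulated_unpaired_positions_more_reactive(self):
        from strandscape import simulate, three_state_fixture

        cfg = three_state_fixture(weights=(1.0, 0.0, 0.0), n_molecules=1500, seed=5)
        sim = simulate(cfg)
        prof = compute_profile(sim.plus, sim.minus, reference=cfg.reference)
        unpaired = cfg.conformations[0].partner()[1:] == 0
        mean_unpaired = np.nanmean(prof.normalized[unpaired])
        mean_paired = np.nanmean(np.where(
            np.isfinite(prof.normalized[~unpaired]), prof.normalized[~unpaired], 0.0
        ))
        assert mean_unpaired > mean_paired

    def test_low_coverage_positions_flagged(self):
        plus = _bvs([[0, 1], [1, 0]])
        minus = _bvs([[0, 0], [0, 0]], channel="minus")
        prof = compute_profile(plus, minus, coverage_floor=50, min_defined=1)
        assert prof.low_confidence.all()

    def test_export_encodes_undefined_as_minus999(self, tmp_path):
        plus = _bvs([[0, MASK], [1, MASK]])
        minus = _bvs([[0, MASK], [0, MASK]], channel="minus")
        prof = compute_profile(plus, minus, min_defined=1)
        path = tmp_path / "react.tsv"
        prof.to_tsv(path)
        content = path.read_text()
        assert "-999" in content
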