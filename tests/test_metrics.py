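import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dualpf.dual_pf import ModelOptions
from dualpf.metrics import (BasePairProbabilityMatrix, EnumerationBackend,
                            base_pair_distance, d1, energy_of_structure,
                            ensemble_distance, ensemble_diversity,
                            expected_cross_distance, measure_battery,
                            mutational_robustness, neutrality, plasticity,
                            point_mutants, zscore_report)
from dualpf.structure import parse_target


def pm_from(n, probs):
    return BasePairProbabilityMatrix.from_pairs(n, probs)


def toy_ensemble(n, structures, probs):
    """Explicit ensemble -> probability matrix plus the raw (s, p) list."""
    mats = []
    for db in structures:
        mats.append(set(parse_target(db)[0].pairs))
    p = np.zeros((n + 1, n + 1))
    for pairs, pr in zip(mats, probs):
        for (i, j) in pairs:
            p[i, j] += pr
    return BasePairProbabilityMatrix(n, p), list(zip(mats, probs))


class TestEnergyEvaluator:
    def test_open_chain_and_zero_table(self, params, zero_params):
        assert energy_of_structure("ACGUA", ".....", params) == 0.0
        assert energy_of_structure("GGGAAACCC", "(((...)))", zero_params) == 0.0

    def test_incompatible_is_infinite(self, params):
        assert energy_of_structure("AAAAAA", "(....)", params) == math.inf

    def test_worked_example_energy_recovers_boltzmann_factor(self, params,
                                                             worked_example):
        # a fully specified sequence for the 28-nt worked target
        ts, _ = worked_example
        seq = "GGGAGGAAACC" + "ACCA" + "GGG" + "UUUU" + "CCAC" + "CC"
        assert len(seq) == 28
        e = energy_of_structure(seq, ts, params, ModelOptions(mode="d0"))
        assert math.isfinite(e)

    def test_d2_adds_dangle_terms(self, params):
        seq = "GGAAAACCA"
        db = "((....))."
        e0 = energy_of_structure(seq, db, params, ModelOptions(mode="d0"))
        e2 = energy_of_structure(seq, db, params, ModelOptions(mode="d2"))
        # the 3' dangle A on a GC-ended helix is favorable
        assert e2 == pytest.approx(e0 + params.dangle3[2, 0])


class TestDistances:
    def test_base_pair_distance(self):
        assert base_pair_distance("((...))", "((...))") == 0
        assert base_pair_distance({(1, 7), (2, 6), (3, 5)} - {(3, 5)},
                                  {(8, 12), (9, 11)}) == 4
        s = {(1, 8), (2, 7)}
        t = {(1, 8), (3, 7)}
        assert base_pair_distance(s, t) == len(s ^ t) == 2

    def test_diversity_deterministic_and_half(self):
        assert ensemble_diversity(pm_from(6, {(1, 6): 1.0})) == 0.0
        pm = pm_from(6, {(1, 6): 0.5})
        assert ensemble_diversity(pm) == pytest.approx(0.5)
        assert plasticity(pm, 2) == pytest.approx(0.5)

    def test_diversity_matches_double_sum_on_toy_ensemble(self):
        structs = ["((...))..", "(.....)..", "........."]
        probs = [0.5, 0.3, 0.2]
        pm, ens = toy_ensemble(9, structs, probs)
        direct = sum(pa * pb * len(sa ^ sb)
                     for sa, pa in ens for sb, pb in ens)
        assert ensemble_diversity(pm) == pytest.approx(direct, rel=1e-12)

    def test_ensemble_distance_two_forms_agree(self):
        a_structs = ["((...))..", "(.....).."]
        b_structs = ["..(...)..", ".........", "((...)).."]
        pm_a, ens_a = toy_ensemble(9, a_structs, [0.6, 0.4])
        pm_b, ens_b = toy_ensemble(9, b_structs, [0.3, 0.5, 0.2])
        cross = sum(pa * pb * len(sa ^ sb)
                    for sa, pa in ens_a for sb, pb in ens_b)
        first_form = math.sqrt(cross - (ensemble_diversity(pm_a)
                                        + ensemble_diversity(pm_b)) / 2)
        assert ensemble_distance(pm_a, pm_b) == pytest.approx(first_form, rel=1e-9)
        # d1: cross distance minus the diversity of the first argument
        assert d1(pm_a, pm_b) == pytest.approx(cross - ensemble_diversity(pm_a))
        assert d1(pm_a, pm_b) != pytest.approx(d1(pm_b, pm_a))

    def test_d1_self_is_zero_and_deterministic_case(self):
        pm = pm_from(8, {(1, 8): 0.7, (2, 6): 0.2})
        assert d1(pm, pm) == pytest.approx(0.0, abs=1e-12)
        da = pm_from(8, {(1, 8): 1.0})
        db = pm_from(8, {(2, 7): 1.0})
        assert d1(da, db) == pytest.approx(2.0)  # plain bp distance
        assert ensemble_distance(da, db) == pytest.approx(math.sqrt(2))

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_dv_is_a_metric(self, seed):
        rng = np.random.default_rng(seed)
        n = 7
        mats = []
        for _ in range(3):
            p = np.zeros((n + 1, n + 1))
            for (i, j) in [(1, 7), (2, 6), (3, 7), (1, 5)]:
                p[i, j] = rng.random() * 0.4
            mats.append(BasePairProbabilityMatrix(n, p))
        a, b, c = mats
        assert ensemble_distance(a, b) == pytest.approx(ensemble_distance(b, a))
        assert ensemble_distance(a, a) == 0.0
        assert ensemble_distance(a, c) <= \
            ensemble_distance(a, b) + ensemble_distance(b, c) + 1e-12


class _MatrixStub:
    """Backend with prescribed matrices/structures per sequence."""

    def __init__(self, n, default_pairs, special=None, structures=None):
        self.n = n
        self.default_pairs = default_pairs
        self.special = special or {}
        self.structures = structures or {}

    def basepair_probs(self, seq):
        probs = self.special.get(seq, self.default_pairs)
        return BasePairProbabilityMatrix.from_pairs(self.n, probs)

    def mfe_fold(self, seq):
        return self.structures.get(seq, self._db(self.default_pairs)), 0.0

    def _db(self, probs):
        out = ["."] * self.n
        for (i, j), v in probs.items():
            if v >= 0.5:
                out[i - 1], out[j - 1] = "(", ")"
        return "".join(out)


class TestRobustnessAndNeutrality:
    def test_identical_mutant_ensembles_give_R_one(self):
        stub = _MatrixStub(6, {(1, 6): 1.0})
        assert mutational_robustness("GAAAAC", stub) == pytest.approx(1.0)
        assert mutational_robustness("GAAAAC", stub, "d1") == pytest.approx(1.0)

    def test_hand_computed_dv_average(self):
        # wild type pairs (1,6) with p=1; every mutant loses the pair
        wt = {(1, 6): 1.0}
        seq = "GAAAAC"
        special = {m: {} for m in point_mutants(seq)}
        stub = _MatrixStub(6, wt, special=special)
        # D_V = 1 for each of the 18 mutants => R = 1 - 1/6
        assert mutational_robustness(seq, stub) == pytest.approx(1 - 1 / 6)

    def test_neutrality_wild_type_everywhere(self):
        stub = _MatrixStub(6, {(1, 6): 1.0})
        assert neutrality("GAAAAC", stub) == pytest.approx(1.0)

    def test_neutrality_hand_value(self):
        seq = "GAAAAC"
        wt_db = "(....)"
        structures = {m: "......" for m in point_mutants(seq)}
        stub = _MatrixStub(6, {(1, 6): 1.0}, structures=structures)
        # every mutant loses the single pair: <d> = 1, eta = 1 - 1/6
        assert neutrality(seq, stub) == pytest.approx(1 - 1 / 6)

    def test_invalid_alphabet_rejected(self):
        stub = _MatrixStub(3, {})
        with pytest.raises(ValueError):
            neutrality("GAX", stub)


class TestBattery:
    def test_target_equals_deterministic_ensemble(self):
        db = "((...))."
        stub = _MatrixStub(8, {(1, 7): 1.0, (2, 6): 1.0},
                           structures={})
        m = measure_battery("GGAAACCA", db, stub)
        assert m["ensemble_defect"] == pytest.approx(0.0, abs=1e-12)
        assert m["expected_bp_distance"] == pytest.approx(0.0, abs=1e-12)
        assert m["prop_native_contacts"] == pytest.approx(1.0)
        assert m["positional_entropy"] == pytest.approx(0.0, abs=1e-12)
        assert m["ensemble_diversity"] == pytest.approx(0.0, abs=1e-12)

    def test_toy_matrix_hand_check(self):
        db = "(....)."
        stub = _MatrixStub(7, {(1, 6): 0.5})
        m = measure_battery("GAAAACA", db, stub)
        # positions 1 and 6: 1 - p = 0.5 each; positions 2..5,7: q = 1
        assert m["ensemble_defect"] == pytest.approx((0.5 + 0.5) / 7)
        assert m["expected_bp_distance"] == pytest.approx(0.5 / 7)
        # entropy: two positions with {0.5, 0.5}
        assert m["positional_entropy"] == pytest.approx(2 * math.log(2) / 7)


class TestZScore:
    def test_examples(self):
        assert zscore_report(1.0, [1.0, 1.0, 1.0, 2.0, 0.0]) == pytest.approx(0.0)
        assert zscore_report(2.0, [0.0, 2.0]) == pytest.approx(1 / math.sqrt(2))
        with pytest.raises(ValueError):
            zscore_report(1.0, [0.5])
        with pytest.raises(ValueError):
            zscore_report(1.0, [0.5, 0.5])


class TestEnumerationBackend:
    @pytest.fixture(scope="class")
    def backend(self, params):
        return EnumerationBackend(params)

    def test_mfe_matches_exhaustive_minimum(self, backend, params):
        seq = "GGGAAAACCC"
        db, e = backend.mfe_fold(seq)
        opts = backend.options
        best = min(energy_of_structure(seq, _db(10, s), params, opts)
                   for s in backend.structures(seq))
        assert e == pytest.approx(best)
        assert energy_of_structure(seq, db, params, opts) == pytest.approx(e)

    def test_bpp_sums_match_boltzmann_weights(self, backend, params):
        seq = "GGCAAAGCC"
        pm = backend.basepair_probs(seq)
        pm.validate()
        RT = params.RT
        ws, ps = [], []
        for s in backend.structures(seq):
            e = energy_of_structure(seq, _db(9, s), params, backend.options)
            ws.append(math.exp(-e / RT))
            ps.append(s)
        Z = sum(ws)
        for bp in {(1, 9), (2, 8), (3, 7)}:
            exact = sum(w for w, s in zip(ws, ps) if bp in s) / Z
            assert pm.p[bp] == pytest.approx(exact, rel=1e-12)

    def test_unfoldable_sequence_is_open_chain(self, backend):
        db, e = backend.mfe_fold("AAAAAA")
        assert db == "......" and e == 0.0


def _db(n, pairs):
    out = ["."] * n
    for i, j in pairs:
        out[i - 1], out[j - 1] = "(", ")"
    return "".join(out)
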