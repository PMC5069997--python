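import collections
import math

import numpy as np
import pytest
from scipy import stats

from dualpf.dual_pf import ModelOptions, compute, enumerate_compatible
from dualpf.gc_resolved import compute_gc
from dualpf.metrics import energy_of_structure
from dualpf.sampler import (SamplerConfig, SamplingError, filter_mfe,
                            sample_sequences)
from dualpf.structure import parse_target


def exact_distribution(ts, cons, params, mode):
    opts = ModelOptions(mode=mode)
    RT = params.RT
    w = {s: math.exp(-energy_of_structure(s, ts, params, opts) / RT)
         for s in enumerate_compatible(ts, cons)}
    Z = sum(w.values())
    return {s: v / Z for s, v in w.items()}


def chi2_pvalue(counts, exact, n):
    seqs = list(exact)
    obs = np.array([counts.get(s, 0) for s in seqs], dtype=float)
    exp = np.array([exact[s] * n for s in seqs])
    keep = exp > 5  # standard validity rule; tiny-expectation cells pooled
    pooled_obs, pooled_exp = obs[keep], exp[keep]
    if (~keep).any():
        pooled_obs = np.append(pooled_obs, obs[~keep].sum())
        pooled_exp = np.append(pooled_exp, exp[~keep].sum())
    chi2 = ((pooled_obs - pooled_exp) ** 2 / pooled_exp).sum()
    return 1 - stats.chi2.cdf(chi2, len(pooled_obs) - 1)


class TestDistribution:
    @pytest.mark.parametrize("db,iu,mode", [
        ("(...).", None, "d0"),
        ("(...).", None, "d2"),
        ("(....)", "NNSNNN", "d2"),
    ])
    def test_chi_square_goodness_of_fit(self, params, db, iu, mode):
        ts, cons = parse_target(db, iu)
        st = compute(ts, cons, params, mode=mode)
        exact = exact_distribution(ts, cons, params, mode)
        n = 60_000
        recs = sample_sequences(st, SamplerConfig(n_samples=n, seed=17))
        counts = collections.Counter(r.sequence for r in recs)
        assert set(counts) <= set(exact)
        assert chi2_pvalue(counts, exact, n) > 0.001

    def test_gc_conditioned_matches_filtered_distribution(self, params):
        ts, cons = parse_target("(....)")
        st = compute_gc(ts, cons, params, mode="d2")
        full = exact_distribution(ts, cons, params, "d2")
        k = 3
        exact = {s: p for s, p in full.items()
                 if s.count("G") + s.count("C") == k}
        tot = sum(exact.values())
        exact = {s: p / tot for s, p in exact.items()}
        n = 40_000
        recs = sample_sequences(st, SamplerConfig(n_samples=n, seed=23, gc_target=k))
        assert all(r.gc_count == k for r in recs)
        counts = collections.Counter(r.sequence for r in recs)
        assert set(counts) <= set(exact)
        assert chi2_pvalue(counts, exact, n) > 0.001

    def test_mean_energy_converges(self, params):
        ts, cons = parse_target("((...))")
        st = compute(ts, cons, params, mode="d0")
        exact = exact_distribution(ts, cons, params, "d0")
        opts = ModelOptions(mode="d0")
        mu = sum(p * energy_of_structure(s, ts, params, opts)
                 for s, p in exact.items())
        var = sum(p * (energy_of_structure(s, ts, params, opts) - mu) ** 2
                  for s, p in exact.items())
        n = 20_000
        recs = sample_sequences(st, SamplerConfig(n_samples=n, seed=3))
        got = np.mean([r.energy for r in recs])
        assert abs(got - mu) < 3 * math.sqrt(var / n)


class TestContracts:
    def test_fully_constrained_single_sequence(self, params):
        ts, cons = parse_target("(....).", "GAAAACU")
        st = compute(ts, cons, params, mode="d2", scale_C=1.0)
        recs = sample_sequences(st, SamplerConfig(n_samples=5, seed=1))
        assert {r.sequence for r in recs} == {"GAAAACU"}
        for r in recs:
            assert r.ln_p == pytest.approx(0.0, abs=1e-12)

    def test_determinism_and_scale_invariance(self, params):
        ts, cons = parse_target("((...)).(....)")
        streams = []
        for C in (1.0, 2.5, 5.0):
            st = compute(ts, cons, params, mode="d2", scale_C=C)
            recs = sample_sequences(st, SamplerConfig(n_samples=200, seed=77))
            streams.append([r.sequence for r in recs])
        assert streams[0] == streams[1] == streams[2]
        st = compute(ts, cons, params, mode="d2", scale_C=2.5)
        again = [r.sequence for r in
                 sample_sequences(st, SamplerConfig(n_samples=200, seed=77))]
        assert again == streams[0]

    def test_gc_target_requires_gc_state_and_feasibility(self, params):
        ts, cons = parse_target("(....)")
        st = compute(ts, cons, params)
        with pytest.raises(SamplingError, match="GC-resolved"):
            sample_sequences(st, SamplerConfig(n_samples=1, gc_target=3))
        stg = compute_gc(ts, cons, params)
        with pytest.raises(SamplingError, match="infeasible"):
            sample_sequences(stg, SamplerConfig(n_samples=1, gc_target=7))

    def test_records_respect_constraints(self, params):
        ts, cons = parse_target("((....)).", "NNRYNNNNS")
        st = compute(ts, cons, params, mode="d2")
        for r in sample_sequences(st, SamplerConfig(n_samples=300, seed=8)):
            assert cons.compatible(r.sequence)
            e = energy_of_structure(r.sequence, ts, params, st.options)
            assert r.energy == pytest.approx(e)

    def test_infeasible_state_refuses(self, params):
        ts, cons = parse_target("(....)", "ANNNNC")
        st = compute(ts, cons, params)
        with pytest.raises(SamplingError, match="zero"):
            sample_sequences(st, SamplerConfig(n_samples=1))


class _StubBackend:
    """Declares a fixed set of sequences to fold into the target."""

    def __init__(self, target_db, winners):
        self.target = target_db
        self.winners = set(winners)

    def mfe_fold(self, seq):
        return (self.target if seq in self.winners else "." * len(seq)), 0.0


class TestMfeFiltering:
    def test_filter_mfe_subset_preserves_order(self, params):
        ts, cons = parse_target("(....)")
        st = compute(ts, cons, params)
        recs = sample_sequences(st, SamplerConfig(n_samples=50, seed=4))
        winners = {r.sequence for r in recs[::3]}
        backend = _StubBackend(ts.to_dotbracket(), winners)
        passed, undetermined = filter_mfe(recs, ts, backend)
        assert [r.sequence for r in passed] == \
            [r.sequence for r in recs if r.sequence in winners]
        assert undetermined == []

    def test_filter_mfe_during_sampling_records_attempts(self, params):
        ts, cons = parse_target("(....)")
        st = compute(ts, cons, params)
        probe = sample_sequences(st, SamplerConfig(n_samples=200, seed=5))
        common = collections.Counter(r.sequence for r in probe).most_common(3)
        backend = _StubBackend(ts.to_dotbracket(), [s for s, _ in common])
        recs = sample_sequences(
            st, SamplerConfig(n_samples=20, seed=6, filter_mfe=True,
                              max_attempts=500), backend=backend)
        assert recs and all(r.sequence in backend.winners for r in recs)
        assert all(r.attempts >= 1 for r in recs)

    def test_backend_failure_goes_to_undetermined_bucket(self, params):
        class Flaky:
            def mfe_fold(self, seq):
                raise RuntimeError("engine crash")
        ts, cons = parse_target("(....)")
        st = compute(ts, cons, params)
        recs = sample_sequences(st, SamplerConfig(n_samples=3, seed=9))
        passed, undetermined = filter_mfe(recs, ts, Flaky())
        assert passed == [] and len(undetermined) == 3
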