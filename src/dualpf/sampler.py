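"""Exact Boltzmann sampling of sequences for a fixed target structure.

Sequences are drawn from p*(a) proportional to exp(-E(a, s0)/RT) by
stochastic backtracking over the stored loop plans: the external loop is
instantiated first (adjacency groups jointly), then loops from the outermost
base pairs inward, each decision a roulette wheel over the conditional
partition-function masses.  Scaling constants cancel from every ratio, so
the sampled stream is invariant to the choice of C.

With a GC target, loop-level GC budgets are drawn first (roulette over the
GC-resolved masses, split across factors by suffix convolutions) and
nucleotides are instantiated inside the chosen budgets; every returned
sequence then has exactly the requested number of G/C nucleotides.

Roulette wheels scan outcomes in a fixed canonical order (pairs AU, CG, GC,
UA, GU, UG; nucleotides A, C, G, U; GC budgets ascending), so runs are
reproducible from the seed across platforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .dual_pf import DualPFState
from .gc_resolved import GcResolvedState
from .metrics import energy_of_structure
from .params import NT, NT_GC, PAIR_GC, PAIR_NTS


@dataclass
class SamplerConfig:
    n_samples: int
    seed: int = 0
    gc_target: int | None = None
    filter_mfe: bool = False
    max_attempts: int = 100

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


@dataclass
class SampleRecord:
    sequence: str
    energy: float       # E(a, s0), kcal/mol
    gc_count: int
    ln_p: float         # ln p*(a) = -E/RT - ln Z*(s0)
    attempts: int = 1


class SamplingError(RuntimeError):
    pass


def _roulette(rng, weights) -> int:
    cum = np.cumsum(weights)
    total = cum[-1] if len(cum) else 0.0
    if total <= 0.0:
        raise SamplingError("no admissible outcome at a sampling decision")
    return int(np.searchsorted(cum, rng.random() * total, side="right"))


class _Sampler:
    def __init__(self, state: DualPFState, rng):
        self.state = state
        self.rng = rng
        self.allowed = state.constraints.allowed
        self._wheel = {}     # cached cumulative weights for plain decisions
        self._suffix = {}    # cached suffix convolutions for plan factors
        self._coupled_total = {}

    # -- plain (unconditioned) backtracking --------------------------------

    def _config_weights(self, key, tag, cfgs, pair_bps):
        ck = (key, tag)
        if ck not in self._wheel:
            Z = self.state.Z
            ws = np.empty(len(cfgs))
            for t, c in enumerate(cfgs):
                w = c.weight
                for bp, code in zip(pair_bps, c.pair_codes):
                    w *= Z[bp][code]
                ws[t] = w
            self._wheel[ck] = ws
        return self._wheel[ck]

    def _fill_free(self, seq, positions):
        for p in positions:
            opts = self.allowed[p]
            seq[p] = opts[int(self.rng.integers(len(opts)))]

    def _apply_config(self, seq, stack, cset, cfg, budgeted=None):
        for p, c in zip(cset.positions, cfg.nts):
            seq[p] = c
        if budgeted is None:
            for bp, code in zip(cset.pair_bps, cfg.pair_codes):
                stack.append((bp, code, None))
        else:
            arrays = [self.state.Zgc[bp][code]
                      for bp, code in zip(cset.pair_bps, cfg.pair_codes)]
            budgets = self._split(arrays, budgeted)
            for (bp, code), b in zip(zip(cset.pair_bps, cfg.pair_codes), budgets):
                stack.append((bp, code, b))

    def _instantiate_plain(self, seq, stack, key, closing_code):
        plan = self.state.plans[key]
        if plan.coupled is not None:
            cfgs = plan.coupled.by_closing[closing_code]
            ws = self._config_weights(key, closing_code, cfgs, plan.coupled.pair_bps)
            cfg = cfgs[_roulette(self.rng, ws)]
            self._apply_config(seq, stack, plan.coupled, cfg)
        for gi, gset in enumerate(plan.indep_groups):
            cfgs = gset.by_closing[None]
            ws = self._config_weights(key, ("g", gi), cfgs, gset.pair_bps)
            cfg = cfgs[_roulette(self.rng, ws)]
            self._apply_config(seq, stack, gset, cfg)
        for bp in plan.indep_pairs:
            code = _roulette(self.rng, self.state.Z[bp])
            stack.append((bp, code, None))
        self._fill_free(seq, plan.free_positions)

    # -- GC-conditioned backtracking ---------------------------------------

    def _split(self, arrays, total):
        """Sample budgets for the factors in ``arrays`` summing to ``total``."""
        suffix = [np.ones(1)]
        for arr in reversed(arrays[1:]):
            suffix.append(np.convolve(arr, suffix[-1]))
        suffix.reverse()
        budgets = []
        rem = total
        for arr, nxt in zip(arrays, suffix):
            hi = min(rem, arr.size - 1)
            ws = [arr[b] * nxt[rem - b] if 0 <= rem - b < nxt.size else 0.0
                  for b in range(hi + 1)]
            b = _roulette(self.rng, ws)
            budgets.append(b)
            rem -= b
        return budgets

    def _plan_factors(self, key, closing_code):
        """(descriptors, arrays) for the factor-level GC budget split."""
        ck = (key, closing_code)
        if ck in self._suffix:
            return self._suffix[ck]
        st = self.state
        plan = st.plans[key]
        desc, arrays = [], []
        if plan.coupled is not None:
            arrs = st.config_arrays[(key, closing_code)]
            size = max((a.size for a in arrs), default=1)
            tot = np.zeros(size)
            for a in arrs:
                tot[:a.size] += a
            desc.append(("coupled", closing_code))
            arrays.append(tot)
        for gi in range(len(plan.indep_groups)):
            desc.append(("group", gi))
            arrays.append(st.group_arrays[(key, gi)])
        for bp in plan.indep_pairs:
            desc.append(("pair", bp))
            arrays.append(st.Zgc[bp].sum(axis=0))
        desc.append(("free", None))
        arrays.append(st.free_arrays[key])
        self._suffix[ck] = (plan, desc, arrays)
        return self._suffix[ck]

    def _fill_free_gc(self, seq, positions, beta):
        """Place G/C uniformly over the count-weighted arrangements."""
        from .gc_resolved import count_array
        rem = beta
        tail = [count_array([self.allowed[p] for p in positions[t + 1:]])
                for t in range(len(positions))]
        for t, p in enumerate(positions):
            opts = self.allowed[p]
            gc_opts = [c for c in opts if NT_GC[c]]
            au_opts = [c for c in opts if not NT_GC[c]]
            nxt = tail[t]
            w_gc = len(gc_opts) * (nxt[rem - 1] if 0 <= rem - 1 < nxt.size else 0.0)
            w_au = len(au_opts) * (nxt[rem] if rem < nxt.size else 0.0)
            if _roulette(self.rng, [w_au, w_gc]) == 1:
                seq[p] = gc_opts[int(self.rng.integers(len(gc_opts)))]
                rem -= 1
            else:
                seq[p] = au_opts[int(self.rng.integers(len(au_opts)))]

    def _instantiate_gc(self, seq, stack, key, closing_code, budget):
        st = self.state
        plan, desc, arrays = self._plan_factors(key, closing_code)
        budgets = self._split(arrays, budget)
        for (what, who), b in zip(desc, budgets):
            if what == "coupled":
                arrs = st.config_arrays[(key, closing_code)]
                ws = [a[b] if b < a.size else 0.0 for a in arrs]
                ci = _roulette(self.rng, ws)
                cfg = plan.coupled.by_closing[closing_code][ci]
                inner_budget = b - sum(NT_GC[c] for c in cfg.nts)
                self._apply_config(seq, stack, plan.coupled, cfg, budgeted=inner_budget)
            elif what == "group":
                arrs = st.config_arrays[(key, "g", who)]
                ws = [a[b] if b < a.size else 0.0 for a in arrs]
                gset = plan.indep_groups[who]
                cfg = gset.by_closing[None][_roulette(self.rng, ws)]
                inner_budget = b - sum(NT_GC[c] for c in cfg.nts)
                self._apply_config(seq, stack, gset, cfg, budgeted=inner_budget)
            elif what == "pair":
                code = _roulette(self.rng, st.Zgc[who][:, b] if b < st.Zgc[who].shape[1]
                                 else np.zeros(6))
                stack.append((who, code, b))
            else:
                self._fill_free_gc(seq, plan.free_positions, b)

    # -- one full draw ------------------------------------------------------

    def draw(self, gc_target=None) -> str:
        st = self.state
        n = st.structure.n
        seq = [None] * (n + 1)
        stack = []
        if gc_target is None:
            self._instantiate_plain(seq, stack, None, None)
        else:
            self._instantiate_gc(seq, stack, None, None, gc_target)
        while stack:
            bp, code, budget = stack.pop()
            i, j = bp
            seq[i], seq[j] = PAIR_NTS[code]
            if gc_target is None:
                self._instantiate_plain(seq, stack, bp, code)
            else:
                self._instantiate_gc(seq, stack, bp, code,
                                     budget - PAIR_GC[code])
        return "".join(NT[c] for c in seq[1:])


def sample_sequences(state: DualPFState, config: SamplerConfig,
                     backend=None) -> list:
    """Draw i.i.d. sequences from the dual Boltzmann ensemble of the state.

    GC-conditioned sampling requires a state produced by the GC-resolved
    computation.  With ``config.filter_mfe`` each record is resampled until
    its MFE structure (per ``backend``) equals the target, up to
    ``max_attempts`` draws; records that never pass are dropped and counted.
    """
    if state.Z_total <= 0.0:
        raise SamplingError("dual partition function is zero; nothing to sample")
    gc = config.gc_target
    if gc is not None:
        if not isinstance(state, GcResolvedState):
            raise SamplingError(
                "GC-conditioned sampling needs a GC-resolved state (compute_gc)")
        if not 0 <= gc < state.Zk.size or state.Zk[gc] <= 0.0:
            raise SamplingError(
                f"GC target {gc} is infeasible for this target/constraints")
    if config.filter_mfe and backend is None:
        raise SamplingError("filter_mfe requires a folding backend")

    rng = np.random.default_rng(config.seed)
    sampler = _Sampler(state, rng)
    target_db = state.structure.to_dotbracket()
    ln_Z = state.log_Z()
    RT = state.RT_formal

    records = []
    dropped = 0
    for _ in range(config.n_samples):
        attempts = 0
        accepted = None
        while attempts < (config.max_attempts if config.filter_mfe else 1):
            seq = sampler.draw(gc)
            attempts += 1
            if not config.filter_mfe or backend.mfe_fold(seq)[0] == target_db:
                accepted = seq
                break
        if accepted is None:
            dropped += 1
            continue
        e = energy_of_structure(accepted, state.structure, state.params,
                                state.options)
        records.append(SampleRecord(
            sequence=accepted, energy=e,
            gc_count=accepted.count("G") + accepted.count("C"),
            ln_p=-e / RT - ln_Z, attempts=attempts))
    if dropped:
        import warnings
        warnings.warn(f"{dropped} of {config.n_samples} samples exhausted "
                      f"max_attempts={config.max_attempts} without matching "
                      f"the target MFE structure")
    return records


def filter_mfe(records, structure, backend):
    """Split records into those whose MFE structure equals the target and an
    'undetermined' bucket of records the backend failed on.  Order is
    preserved."""
    target_db = structure.to_dotbracket() if hasattr(structure, "to_dotbracket") \
        else str(structure)
    passed, undetermined = [], []
    for rec in records:
        try:
            db, _ = backend.mfe_fold(rec.sequence)
        except Exception:
            undetermined.append(rec)
            continue
        if db == target_db:
            passed.append(rec)
    return passed, undetermined
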