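"""GC-content-resolved dual partition function.

Z*(s0, k) restricts the dual partition function to sequences with exactly
``k`` G/C nucleotides, for all k simultaneously.  Every recursion case gains
a GC index: a pair instantiation contributes gamma(XY) in {0, 1, 2}; fixed
mismatch/dangle nucleotides contribute their own GC counts; blocks of
energetically free positions contribute the number of constrained
assignments with a given GC count (a position-by-position convolution that
collapses to binom(m, k) * 2^m when unconstrained); and the inner-pair
values are combined by convolution over their GC budgets.  The GC index of
Z*(i, j; X, Y; alpha) includes the closing nucleotides X and Y.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .dual_pf import (DualPFState, ModelOptions, _build_plan, _free_count,
                      compute)
from .params import NT, NT_GC, NT_INDEX, PAIR_GC, default_scale
from .structure import SequenceConstraints, TargetStructure


def gc_count(fragment) -> int:
    """Number of G and C symbols in a nucleotide string or code sequence."""
    if isinstance(fragment, str):
        return sum(1 for c in fragment.upper() if c in "GC")
    return sum(NT_GC[c] for c in fragment)


def _as_code_set(s):
    return tuple(NT_INDEX[c] if isinstance(c, str) else int(c) for c in s)


def count_array(position_sets) -> np.ndarray:
    """counts[k] = number of joint assignments with exactly k G/C symbols."""
    arr = np.ones(1)
    for s in position_sets:
        codes = _as_code_set(s)
        gc = sum(1 for c in codes if NT_GC[c])
        au = len(codes) - gc
        arr = np.convolve(arr, np.array([au, gc], dtype=float))
    return arr


def count_constrained_assignments(position_sets, k: int) -> int:
    """Assignments of the positions with exactly ``k`` of them G or C.

    ``position_sets`` is a list of allowed-nucleotide sets (letters or
    codes).  Returns 0 when infeasible; equals binom(m, k) * 2^m when all m
    positions are unconstrained.
    """
    if k < 0:
        return 0
    arr = count_array(position_sets)
    return int(round(arr[k])) if k < arr.size else 0


# ---------------------------------------------------------------------------


def _conv(a, b):
    return np.convolve(a, b)


def _shift(arr, by):
    if by == 0:
        return arr
    return np.concatenate((np.zeros(by), arr))


def _pad(arr, size):
    if arr.size >= size:
        return arr[:size]
    return np.concatenate((arr, np.zeros(size - arr.size)))


@dataclass
class GcResolvedState(DualPFState):
    """DualPFState plus per-base-pair GC-resolved tables.

    ``Zgc[bp]`` has shape (6, span + 1): scaled Z*(i, j; X, Y; alpha) with
    alpha counting all positions i..j including the pair itself.  ``Zk`` is
    the scaled top-level array over k = 0..n.  ``config_arrays`` and
    ``group_arrays`` retain the conditional GC-resolved masses the sampler's
    roulette wheels need.
    """

    Zgc: dict = field(default_factory=dict)
    Zk: np.ndarray | None = None
    config_arrays: dict = field(default_factory=dict)  # (key, X or (key,'g',gi)) -> list per config
    group_arrays: dict = field(default_factory=dict)   # (key, gi) -> ndarray
    free_arrays: dict = field(default_factory=dict)    # key -> ndarray over beta

    def gc_profile(self) -> np.ndarray:
        """Z*(s0, k) on the scaled ladder; normalize by Zk.sum() for weights."""
        return self.Zk


def compute_gc(structure: TargetStructure, constraints: SequenceConstraints,
               params, mode: str = "d2", scale_C: float | None = None,
               options: ModelOptions | None = None,
               formal_temperature: float | None = None) -> GcResolvedState:
    """Compute the GC-resolved tables Z*(i, j; X, Y; alpha) and Z*(s0, k)."""
    if options is None:
        options = ModelOptions(mode=mode)
    elif options.mode != mode:
        options = ModelOptions(mode=mode, literal_size1_bulge=options.literal_size1_bulge,
                               special_internal=options.special_internal)
    if scale_C is None:
        scale_C = default_scale(params)
    T = params.temperature if formal_temperature is None else formal_temperature
    RTf = params.gas_constant * T

    state = GcResolvedState(structure, constraints, params, options, scale_C, RTf)
    state.infeasible = constraints.infeasible_pairs()
    if state.infeasible:
        state.Z_total = 0.0
        state.Zk = np.zeros(structure.n + 1)
        return state

    def config_array(cfg, pair_bps):
        arr = np.array([cfg.weight])
        for bp2, code in zip(pair_bps, cfg.pair_codes):
            arr = _conv(arr, state.Zgc[bp2][code])
        return _shift(arr, sum(NT_GC[c] for c in cfg.nts))

    def shared_factors(key, plan):
        arr = np.ones(1)
        for gi, gset in enumerate(plan.indep_groups):
            cfgs = gset.by_closing[None]
            arrs = [config_array(c, gset.pair_bps) for c in cfgs]
            size = max(a.size for a in arrs) if arrs else 1
            total = np.zeros(size)
            for a in arrs:
                total[:a.size] += a
            state.config_arrays[(key, "g", gi)] = arrs
            state.group_arrays[(key, gi)] = total
            state.group_values[(key, gi)] = float(total.sum())
            arr = _conv(arr, total)
        for inner in plan.indep_pairs:
            arr = _conv(arr, state.Zgc[inner].sum(axis=0))
        fa = count_array([constraints.allowed[p] for p in plan.free_positions])
        state.free_arrays[key] = fa
        arr = _conv(arr, fa)
        return arr * scale_C ** (-plan.owned)

    for bp in structure.bp_order:
        loop = structure.loop_of[bp]
        plan = _build_plan(loop, structure, constraints, params, options, RTf)
        state.plans[bp] = plan
        span = bp[1] - bp[0] + 1
        shared = shared_factors(bp, plan)
        Zg = np.zeros((6, span + 1))
        for X, cfgs in plan.coupled.by_closing.items():
            arrs = [config_array(c, plan.coupled.pair_bps) for c in cfgs]
            state.config_arrays[(bp, X)] = arrs
            size = max((a.size for a in arrs), default=1)
            tot = np.zeros(size)
            for a in arrs:
                tot[:a.size] += a
            Zg[X] = _pad(_shift(_conv(tot, shared), PAIR_GC[X]), span + 1)
        state.Zgc[bp] = Zg
        state.Z[bp] = Zg.sum(axis=1)

    ext = structure.external_loop
    plan = _build_plan(ext, structure, constraints, params, options, RTf)
    state.plans[None] = plan
    state.Zk = _pad(shared_factors(None, plan), structure.n + 1)
    state.Z_total = float(state.Zk.sum())
    if not math.isfinite(state.Z_total):
        raise OverflowError(
            "GC-resolved dual partition function overflowed; increase C")
    return state


def feasible_gc_range(structure: TargetStructure,
                      constraints: SequenceConstraints) -> tuple:
    """Smallest and largest GC count any compatible sequence can reach.

    Interval arithmetic over the allowed-pair sets of the base pairs and the
    allowed-nucleotide sets of the unpaired positions.
    """
    lo = hi = 0
    for bp in structure.pairs:
        opts = [PAIR_GC[c] for c in constraints.allowed_pairs[bp]]
        if not opts:
            raise ValueError(f"no allowed pair at {bp}")
        lo += min(opts)
        hi += max(opts)
    for i in range(1, constraints.n + 1):
        if structure.pair_table[i] == 0:
            opts = [NT_GC[c] for c in constraints.allowed[i]]
            lo += min(opts)
            hi += max(opts)
    return lo, hi
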