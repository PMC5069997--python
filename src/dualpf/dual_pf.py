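"""Dual partition function over sequence space.

Z*(s0) sums the Boltzmann factors exp(-E(a, s0)/RT) of every sequence ``a``
compatible with the fixed target structure ``s0``.  Because the structure is
fixed, Z* factors over the loops of ``s0``: for every base pair (i, j), taken
in the enclosed-before-enclosing order, the six values Z*(i, j; X, Y) are
assembled from the values of the directly enclosed pairs, and the external
loop assembles Z*(s0) at the top.

Every loop is compiled into a *plan*: an enumeration of the joint nucleotide
configurations whose identity affects the loop energy (inner pair
instantiations, mismatch/flank nucleotides, dangle nucleotides grouped by
adjacency), plus a block of energetically free positions that only contribute
a counting factor.  The same plans drive the plain computation, the
GC-resolved computation and exact stochastic backtracking, which keeps the
three views of the model consistent by construction.

Scaling: values are stored as Z-dagger = Z* / C^(span); the per-loop factor
C^-(owned positions) makes the recursion exact, and C cancels from every
sampling ratio.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .params import (EnergyParameters, NT_GC, PAIR_GC, PAIR_NTS, PAIR_REVERSE,
                     WOBBLE_OR_AU, asymmetry_energy, bulge_energy,
                     default_scale, hairpin_energy, internal_energy)
from .structure import (Loop, SequenceConstraints, TargetStructure,
                        build_groups)

NT_STR = "ACGU"


@dataclass(frozen=True)
class ModelOptions:
    """Model switches shared by the recursions and the energy evaluator.

    ``mode``: 'd0' ignores dangling ends, 'd2' adds both flanking dangle
    terms to every helix of a multiloop or of the external loop.
    ``literal_size1_bulge``: apply the bulge rule (initiation + terminal
    penalty, no cross-bulge stack) to size-1 bulges too; the default follows
    the standard convention (initiation + stacking across the bulge, no
    terminal penalty), which reproduces the published worked example.
    ``special_internal``: use the dedicated 1x1/1x2/2x2 lookup tables where
    available (default); otherwise the generic size/asymmetry/mismatch rule
    is applied to every interior loop.
    """

    mode: str = "d2"
    literal_size1_bulge: bool = False
    special_internal: bool = True

    def __post_init__(self):
        if self.mode not in ("d0", "d2"):
            raise ValueError(f"dangle mode must be 'd0' or 'd2', got {self.mode!r}")


@dataclass
class Config:
    """One joint instantiation of a loop's energy-relevant positions."""

    pair_codes: tuple        # aligned with ConfigSet.pair_bps
    nts: tuple               # aligned with ConfigSet.positions
    weight: float            # exp(-local energy / RT)


@dataclass
class ConfigSet:
    pair_bps: tuple          # coupled inner pairs whose codes are part of each config
    positions: tuple         # loop-local fixed unpaired positions
    by_closing: dict         # closing pair code (or None) -> list[Config]

    @property
    def gc_fixed(self):
        return None


@dataclass
class LoopPlan:
    loop: Loop
    coupled: ConfigSet | None        # keyed by closing code; None for the external loop
    indep_groups: list               # ConfigSets keyed by None
    indep_pairs: list                # inner pairs summed/sampled independently
    free_positions: tuple            # positions contributing a pure counting factor
    owned: int                       # positions this loop contributes to the scale exponent


class InfeasibleConstraints(Exception):
    pass


class GroupTooLarge(Exception):
    pass


GROUP_CONFIG_LIMIT = 10_000_000


def _boltz(energy: float, RT: float) -> float:
    return 0.0 if energy == math.inf else math.exp(-energy / RT)


# ---------------------------------------------------------------------------
# plan construction


def _pair_span(bp):
    return bp[1] - bp[0] + 1


def _hairpin_configs(loop, X, structure, constraints, params, RTf, eI):
    i, j = loop.closing_pair
    m = j - i - 1
    x0, x1 = PAIR_NTS[X]
    allowed = constraints.allowed
    special = {3: params.triloop, 4: params.tetraloop, 6: params.hexaloop}.get(m)
    configs = []
    if m in (3, 4, 6) and (special or m == 3):
        positions = tuple(range(i + 1, j))
        for nts in itertools.product(*(allowed[p] for p in positions)):
            loop_seq = NT_STR[x0] + "".join(NT_STR[c] for c in nts) + NT_STR[x1]
            if loop_seq in special:
                e = special[loop_seq]
            elif m == 3:
                e = hairpin_energy(params, 3) + (params.au_penalty if X in WOBBLE_OR_AU else 0.0)
            else:
                e = hairpin_energy(params, m) + params.mismatch_hairpin[X, nts[0], nts[-1]]
            configs.append(Config((), nts, _boltz(e + eI, RTf)))
        return positions, configs, ()
    # generic hairpin: only the two flanking mismatch nucleotides matter
    positions = (i + 1, j - 1)
    h = hairpin_energy(params, m)
    for n1 in allowed[i + 1]:
        for n2 in allowed[j - 1]:
            e = h + params.mismatch_hairpin[X, n1, n2]
            configs.append(Config((), (n1, n2), _boltz(e + eI, RTf)))
    free = tuple(range(i + 2, j - 1))
    return positions, configs, free


def _internal_configs(loop, X, structure, constraints, params, options, RTf, eI):
    i, j = loop.closing_pair
    k, l = loop.inner_pairs[0]
    r1, r2 = loop.r1, loop.r2
    allowed = constraints.allowed
    inner_codes = constraints.allowed_pairs[(k, l)]
    configs = []
    special = options.special_internal and (
        (r1, r2) == (1, 1) and params.int11 is not None
        or {r1, r2} == {1, 2} and params.int21 is not None
        or (r1, r2) == (2, 2) and params.int22 is not None)
    if special:
        if (r1, r2) == (1, 1):
            positions = (i + 1, j - 1)
            energy = lambda U, a: params.int11_energy(X, U, a[0], a[1])
        elif (r1, r2) == (1, 2):
            positions = (i + 1, l + 1, j - 1)
            energy = lambda U, a: params.int21_energy(X, U, 1, a[0], a[1], a[2])
        elif (r1, r2) == (2, 1):
            positions = (i + 1, k - 1, j - 1)
            energy = lambda U, a: params.int21_energy(X, U, 2, a[0], a[1], a[2])
        else:
            positions = (i + 1, k - 1, l + 1, j - 1)
            energy = lambda U, a: params.int22_energy(X, U, a[0], a[1], a[2], a[3])
        for U in inner_codes:
            for nts in itertools.product(*(allowed[p] for p in positions)):
                configs.append(Config((U,), nts, _boltz(energy(U, nts) + eI, RTf)))
        return positions, configs, ()

    # generic rule: size initiation + asymmetry + two terminal mismatches,
    # with flank positions shared when one side has a single nucleotide
    flanks = []
    for p in (i + 1, j - 1, k - 1, l + 1):
        if p not in flanks:
            flanks.append(p)
    positions = tuple(sorted(flanks))
    base = (internal_energy(params, r1 + r2) + asymmetry_energy(params, r1, r2)
            + (params.au_penalty if X in WOBBLE_OR_AU else 0.0))
    idx = {p: t for t, p in enumerate(positions)}
    for U in inner_codes:
        for nts in itertools.product(*(allowed[p] for p in positions)):
            A, B = nts[idx[i + 1]], nts[idx[j - 1]]
            C, D = nts[idx[k - 1]], nts[idx[l + 1]]
            e = (base + params.mismatch_internal[X, A, B]
                 + params.mismatch_internal[PAIR_REVERSE[U], D, C])
            configs.append(Config((U,), nts, _boltz(e + eI, RTf)))
    free = tuple(p for p in loop.unpaired_positions if p not in positions)
    return positions, configs, free


def _group_config_set(group, constraints, params, RTf, extra_energy=None,
                      closing_code=None) -> list:
    """Enumerate joint instantiations of one adjacency group.

    Returns a list of Config.  ``closing_code`` is the multiloop closing pair
    instantiation for closing groups; ``extra_energy`` is added to every
    configuration (terminal penalties, multiloop affine term).
    """
    allowed = constraints.allowed
    members = group.members
    code_choices = [constraints.allowed_pairs[bp] for bp in members]
    nt_choices = [allowed[p] for p in group.dangle_positions]
    total = math.prod(len(c) for c in code_choices) * math.prod(len(c) for c in nt_choices)
    if total > GROUP_CONFIG_LIMIT:
        raise GroupTooLarge(
            f"adjacency group over pairs {members} has {total} joint instantiations "
            f"(limit {GROUP_CONFIG_LIMIT}); use dangle mode d0 for this target")
    configs = []
    extra = extra_energy or 0.0
    for codes in itertools.product(*code_choices):
        for nts in itertools.product(*nt_choices):
            e = extra
            for slot in group.slots:
                if slot.member >= 0:
                    pc = codes[slot.member]
                else:
                    pc = PAIR_REVERSE[closing_code]
                t = slot.target
                if t[0] == "free":
                    w = nts[t[1]]
                elif t[0] == "member":
                    w = PAIR_NTS[codes[t[1]]][t[2]]
                else:  # closing pair position
                    w = PAIR_NTS[closing_code][t[1]]
                table = params.dangle5 if slot.side == "5" else params.dangle3
                e += table[pc, w]
            configs.append(Config(tuple(codes), tuple(nts), _boltz(e, RTf)))
    return configs


def _build_plan(loop: Loop, structure, constraints, params, options, RTf) -> LoopPlan:
    allowed = constraints.allowed
    if loop.closing_pair is None:
        # external loop
        owned = structure.n - sum(_pair_span(bp) for bp in loop.inner_pairs)
        if options.mode == "d0" or not loop.inner_pairs:
            return LoopPlan(loop, None, [], list(loop.inner_pairs),
                            tuple(loop.unpaired_positions), owned)
        groups = build_groups(loop, "d2", structure)
        gsets = []
        used = set()
        for g in groups:
            gsets.append(ConfigSet(tuple(g.members), g.dangle_positions,
                                   {None: _group_config_set(g, constraints, params, RTf)}))
            used.update(g.dangle_positions)
        free = tuple(p for p in loop.unpaired_positions if p not in used)
        return LoopPlan(loop, None, gsets, [], free, owned)

    i, j = loop.closing_pair
    owned = _pair_span((i, j)) - sum(_pair_span(bp) for bp in loop.inner_pairs)
    closing_codes = constraints.allowed_pairs[(i, j)]
    in_elml = (i, j) in structure.bp_close_el_or_ml

    def eI(X):
        return params.au_penalty if in_elml and X in WOBBLE_OR_AU else 0.0

    def eAU(X):
        return params.au_penalty if X in WOBBLE_OR_AU else 0.0

    by_closing = {}
    if loop.kind == "hairpin":
        positions = free = None
        for X in closing_codes:
            positions, cfgs, free = _hairpin_configs(
                loop, X, structure, constraints, params, RTf, eI(X))
            by_closing[X] = cfgs
        coupled = ConfigSet((), positions or (), by_closing)
        return LoopPlan(loop, coupled, [], [], free or (), owned)

    if loop.kind == "stack":
        inner = loop.inner_pairs[0]
        codes = constraints.allowed_pairs[inner]
        for X in closing_codes:
            by_closing[X] = [Config((U,), (), _boltz(params.stack[X, U] + eI(X), RTf))
                             for U in codes]
        return LoopPlan(loop, ConfigSet((inner,), (), by_closing), [], [], (), owned)

    if loop.kind in ("bulge_left", "bulge_right"):
        inner = loop.inner_pairs[0]
        r = max(loop.r1, loop.r2)
        positions = tuple(loop.unpaired_positions)
        if r == 1 and not options.literal_size1_bulge:
            codes = constraints.allowed_pairs[inner]
            b1 = bulge_energy(params, 1)
            for X in closing_codes:
                by_closing[X] = [Config((U,), (), _boltz(b1 + params.stack[X, U] + eI(X), RTf))
                                 for U in codes]
            return LoopPlan(loop, ConfigSet((inner,), (), by_closing), [], [],
                            positions, owned)
        br = bulge_energy(params, r)
        for X in closing_codes:
            by_closing[X] = [Config((), (), _boltz(br + eAU(X) + eI(X), RTf))]
        return LoopPlan(loop, ConfigSet((), (), by_closing), [], [inner],
                        positions, owned)

    if loop.kind == "internal":
        positions = free = None
        for X in closing_codes:
            positions, cfgs, free = _internal_configs(
                loop, X, structure, constraints, params, options, RTf, eI(X))
            by_closing[X] = cfgs
        return LoopPlan(loop, ConfigSet((loop.inner_pairs[0],), positions or (), by_closing),
                        [], [], free or (), owned)

    # multiloop
    k = len(loop.inner_pairs)
    penalty = params.multiloop_a + params.multiloop_b * (k + 1) + params.multiloop_c * loop.ell
    if options.mode == "d0":
        for X in closing_codes:
            by_closing[X] = [Config((), (), _boltz(penalty + eAU(X) + eI(X), RTf))]
        return LoopPlan(loop, ConfigSet((), (), by_closing), [],
                        list(loop.inner_pairs), tuple(loop.unpaired_positions), owned)

    groups = build_groups(loop, "d2", structure)
    closing_group = next(g for g in groups if g.has_closing)
    gsets = []
    used = set()
    for g in groups:
        if g.has_closing:
            continue
        gsets.append(ConfigSet(tuple(g.members), g.dangle_positions,
                               {None: _group_config_set(g, constraints, params, RTf)}))
        used.update(g.dangle_positions)
    used.update(closing_group.dangle_positions)
    for X in closing_codes:
        by_closing[X] = _group_config_set(
            closing_group, constraints, params, RTf,
            extra_energy=penalty + eAU(X) + eI(X), closing_code=X)
    coupled = ConfigSet(tuple(closing_group.members),
                        closing_group.dangle_positions, by_closing)
    free = tuple(p for p in loop.unpaired_positions if p not in used)
    return LoopPlan(loop, coupled, gsets, [], free, owned)


# ---------------------------------------------------------------------------
# forward computation


@dataclass
class DualPFState:
    structure: TargetStructure
    constraints: SequenceConstraints
    params: EnergyParameters
    options: ModelOptions
    scale_C: float
    RT_formal: float
    plans: dict = field(default_factory=dict)        # bp or None -> LoopPlan
    Z: dict = field(default_factory=dict)            # bp -> ndarray(6), scaled
    group_values: dict = field(default_factory=dict) # (plan key, group idx) -> float
    Z_total: float = 0.0                             # scaled Z-dagger(s0)
    infeasible: list = field(default_factory=list)

    @property
    def mode(self):
        return self.options.mode

    def pair_total(self, bp):
        return float(self.Z[bp].sum())

    def log_Z(self) -> float:
        """ln Z*(s0); -inf when the constraints are infeasible."""
        if self.Z_total <= 0.0:
            return -math.inf
        return math.log(self.Z_total) + self.structure.n * math.log(self.scale_C)

    def unscaled_pair_values(self, bp) -> np.ndarray:
        """Z*(i, j; X, Y) on the natural scale (may overflow for long spans)."""
        return self.Z[bp] * self.scale_C ** _pair_span(bp)


def log_dual_partition(state: DualPFState) -> float:
    return state.log_Z()


def _free_count(constraints, positions) -> float:
    out = 1.0
    for p in positions:
        out *= len(constraints.allowed[p])
    return out


def _config_sum(cfgs, Z, pair_bps) -> float:
    s = 0.0
    for c in cfgs:
        w = c.weight
        for bp, code in zip(pair_bps, c.pair_codes):
            w *= Z[bp][code]
        s += w
    return s


def compute(structure: TargetStructure, constraints: SequenceConstraints,
            params: EnergyParameters, mode: str = "d2",
            scale_C: float | None = None, options: ModelOptions | None = None,
            formal_temperature: float | None = None) -> DualPFState:
    """Compute Z*(i, j; X, Y) for every base pair and assemble Z*(s0).

    ``formal_temperature`` replaces the temperature in the Boltzmann
    exponents only (table energies stay at the table temperature); it is the
    handle the dual-thermodynamics finite differences use.
    """
    if options is None:
        options = ModelOptions(mode=mode)
    elif options.mode != mode:
        options = ModelOptions(mode=mode, literal_size1_bulge=options.literal_size1_bulge,
                               special_internal=options.special_internal)
    if scale_C is None:
        scale_C = default_scale(params)
    if scale_C <= 0:
        raise ValueError("scale constant must be positive")
    T = params.temperature if formal_temperature is None else formal_temperature
    RTf = params.gas_constant * T

    state = DualPFState(structure, constraints, params, options, scale_C, RTf)
    state.infeasible = constraints.infeasible_pairs()
    if state.infeasible:
        state.Z_total = 0.0
        return state

    for bp in structure.bp_order:
        loop = structure.loop_of[bp]
        plan = _build_plan(loop, structure, constraints, params, options, RTf)
        state.plans[bp] = plan
        vals = np.zeros(6)
        shared = 1.0
        for gi, gset in enumerate(plan.indep_groups):
            gv = _config_sum(gset.by_closing[None], state.Z, gset.pair_bps)
            state.group_values[(bp, gi)] = gv
            shared *= gv
        for inner in plan.indep_pairs:
            shared *= state.Z[inner].sum()
        shared *= _free_count(constraints, plan.free_positions)
        shared *= scale_C ** (-plan.owned)
        for X, cfgs in plan.coupled.by_closing.items():
            vals[X] = shared * _config_sum(cfgs, state.Z, plan.coupled.pair_bps)
        state.Z[bp] = vals

    ext = structure.external_loop
    plan = _build_plan(ext, structure, constraints, params, options, RTf)
    state.plans[None] = plan
    total = 1.0
    for gi, gset in enumerate(plan.indep_groups):
        gv = _config_sum(gset.by_closing[None], state.Z, gset.pair_bps)
        state.group_values[(None, gi)] = gv
        total *= gv
    for inner in plan.indep_pairs:
        total *= state.Z[inner].sum()
    total *= _free_count(constraints, plan.free_positions)
    total *= scale_C ** (-plan.owned)
    state.Z_total = total
    if not math.isfinite(total):
        raise OverflowError(
            "dual partition function overflowed despite scaling; "
            "increase the scale constant C")
    return state


# ---------------------------------------------------------------------------
# brute-force oracle


def brute_force_dual_pf(structure: TargetStructure,
                        constraints: SequenceConstraints,
                        params: EnergyParameters, mode: str = "d2",
                        options: ModelOptions | None = None,
                        formal_temperature: float | None = None,
                        by_gc: bool = False, limit: int = 2_000_000):
    """Exact Z*(s0) by full enumeration of compatible sequences.

    Intended as an independent test oracle: sums exp(-E(a, s0)/RT) with the
    standalone per-loop energy evaluator over every sequence compatible with
    the structure and constraints.  Refuses enumerations above ``limit``
    sequences.  With ``by_gc`` the result is an array over GC counts 0..n.
    """
    from .metrics import energy_of_structure

    if options is None:
        options = ModelOptions(mode=mode)
    T = params.temperature if formal_temperature is None else formal_temperature
    RTf = params.gas_constant * T

    n = structure.n
    pair_codes = [constraints.allowed_pairs[bp] for bp in structure.pairs]
    unpaired = [p for p in range(1, n + 1) if structure.pair_table[p] == 0]
    count = math.prod(len(c) for c in pair_codes) * \
        math.prod(len(constraints.allowed[p]) for p in unpaired)
    if count > limit:
        raise ValueError(f"enumeration of {count} sequences exceeds the limit {limit}")

    out = np.zeros(n + 1) if by_gc else 0.0
    seq = [""] * (n + 1)
    for codes in itertools.product(*pair_codes):
        for (i, j), code in zip(structure.pairs, codes):
            seq[i] = NT_STR[PAIR_NTS[code][0]]
            seq[j] = NT_STR[PAIR_NTS[code][1]]
        for nts in itertools.product(*(constraints.allowed[p] for p in unpaired)):
            for p, c in zip(unpaired, nts):
                seq[p] = NT_STR[c]
            s = "".join(seq[1:])
            e = energy_of_structure(s, structure, params, options)
            w = _boltz(e, RTf)
            if by_gc:
                out[s.count("G") + s.count("C")] += w
            else:
                out += w
    return out


def enumerate_compatible(structure, constraints, limit: int = 2_000_000):
    """Yield every sequence compatible with the structure and constraints."""
    n = structure.n
    pair_codes = [constraints.allowed_pairs[bp] for bp in structure.pairs]
    unpaired = [p for p in range(1, n + 1) if structure.pair_table[p] == 0]
    count = math.prod(len(c) for c in pair_codes) * \
        math.prod(len(constraints.allowed[p]) for p in unpaired)
    if count > limit:
        raise ValueError(f"enumeration of {count} sequences exceeds the limit {limit}")
    seq = [""] * (n + 1)
    for codes in itertools.product(*pair_codes):
        for (i, j), code in zip(structure.pairs, codes):
            seq[i] = NT_STR[PAIR_NTS[code][0]]
            seq[j] = NT_STR[PAIR_NTS[code][1]]
        for nts in itertools.product(*(constraints.allowed[p] for p in unpaired)):
            for p, c in zip(unpaired, nts):
                seq[p] = NT_STR[c]
            yield "".join(seq[1:])
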