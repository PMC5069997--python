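"""Per-sequence energies, ensemble metrics and folding backends.

``energy_of_structure`` evaluates E(a, s0) loop by loop under exactly the
conventions the dual recursions exponentiate, so that
``sum_a exp(-E(a, s0)/RT) == Z*(s0)`` holds identically; the test suite
exercises that equivalence by full enumeration.

The ensemble metrics operate on base-pair probability matrices supplied by a
pluggable folding backend: ensemble diversity (the expected base-pair
distance between two structures drawn from one sequence's Boltzmann
ensemble), plasticity (diversity normalized by n/2), the ensemble distance
D_V (Euclidean distance between probability matrices, a true metric), the
asymmetric divergence d1, mutational robustness and neutrality over all 3n
single-point mutants, and a battery of design measures (ensemble defect,
expected base-pair distance to target, proportion of native contacts,
positional entropy).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import (EnergyParameters, NT, NT_INDEX, PAIR_INDEX, PAIR_NTS,
                     PAIR_REVERSE, WOBBLE_OR_AU, asymmetry_energy,
                     bulge_energy, hairpin_energy, internal_energy)
from .structure import THETA, TargetStructure, parse_target


# ---------------------------------------------------------------------------
# standalone Turner-model energy evaluator


def _pair_code(seq, i, j):
    return PAIR_INDEX.get(seq[i - 1] + seq[j - 1])


def energy_of_structure(sequence: str, structure, params: EnergyParameters,
                        options=None) -> float:
    """Free energy E(a, s0) of ``sequence`` folded into ``structure``.

    Returns +inf when the sequence is incompatible with the structure (a
    non-canonical nucleotide combination at some base pair).  ``structure``
    may be a TargetStructure or a dot-bracket string; ``options`` carries the
    dangle mode and the bulge/interior-loop convention switches and defaults
    to the same defaults as the dual recursions.
    """
    from .dual_pf import ModelOptions

    if options is None:
        options = ModelOptions()
    if isinstance(structure, str):
        structure, _ = parse_target(structure)
    seq = sequence.upper().replace("T", "U")
    if len(seq) != structure.n:
        raise ValueError(
            f"sequence length {len(seq)} != structure length {structure.n}")
    if any(c not in NT for c in seq):
        raise ValueError("sequence must be over A, C, G, U")

    code = {}
    for (i, j) in structure.pairs:
        c = _pair_code(seq, i, j)
        if c is None:
            return math.inf
        code[(i, j)] = c
    nt = [None] + [NT_INDEX[c] for c in seq]

    E = 0.0
    # terminal penalty for every helix-end pair bordering the external loop
    # or a multiloop (the indicator-gated factor of the recursions)
    for bp in structure.bp_close_el_or_ml:
        if code[bp] in WOBBLE_OR_AU:
            E += params.au_penalty

    def eAU(X):
        return params.au_penalty if X in WOBBLE_OR_AU else 0.0

    for loop in structure.loops:
        kind = loop.kind
        if kind == "external":
            if options.mode == "d2":
                for (x, y) in loop.inner_pairs:
                    U = code[(x, y)]
                    if x > 1:
                        E += params.dangle5[U, nt[x - 1]]
                    if y < structure.n:
                        E += params.dangle3[U, nt[y + 1]]
            continue

        i, j = loop.closing_pair
        X = code[(i, j)]
        if kind == "hairpin":
            m = j - i - 1
            loop_seq = seq[i - 1:j]
            special = {3: params.triloop, 4: params.tetraloop,
                       6: params.hexaloop}.get(m, {})
            if loop_seq in special:
                E += special[loop_seq]
            elif m == 3:
                E += hairpin_energy(params, 3) + eAU(X)
            else:
                E += hairpin_energy(params, m) + \
                    params.mismatch_hairpin[X, nt[i + 1], nt[j - 1]]
        elif kind == "stack":
            U = code[loop.inner_pairs[0]]
            E += params.stack[X, U]
        elif kind in ("bulge_left", "bulge_right"):
            r = max(loop.r1, loop.r2)
            U = code[loop.inner_pairs[0]]
            if r == 1 and not options.literal_size1_bulge:
                E += bulge_energy(params, 1) + params.stack[X, U]
            else:
                E += bulge_energy(params, r) + eAU(X)
        elif kind == "internal":
            k, l = loop.inner_pairs[0]
            U = code[(k, l)]
            r1, r2 = loop.r1, loop.r2
            if options.special_internal and (r1, r2) == (1, 1) and params.int11 is not None:
                E += params.int11_energy(X, U, nt[i + 1], nt[j - 1])
            elif options.special_internal and (r1, r2) == (1, 2) and params.int21 is not None:
                E += params.int21_energy(X, U, 1, nt[i + 1], nt[l + 1], nt[j - 1])
            elif options.special_internal and (r1, r2) == (2, 1) and params.int21 is not None:
                E += params.int21_energy(X, U, 2, nt[i + 1], nt[k - 1], nt[j - 1])
            elif options.special_internal and (r1, r2) == (2, 2) and params.int22 is not None:
                E += params.int22_energy(X, U, nt[i + 1], nt[k - 1], nt[l + 1], nt[j - 1])
            else:
                E += (internal_energy(params, r1 + r2)
                      + asymmetry_energy(params, r1, r2) + eAU(X)
                      + params.mismatch_internal[X, nt[i + 1], nt[j - 1]]
                      + params.mismatch_internal[PAIR_REVERSE[U], nt[l + 1], nt[k - 1]])
        else:  # multiloop
            k = len(loop.inner_pairs)
            E += (params.multiloop_a + params.multiloop_b * (k + 1)
                  + params.multiloop_c * loop.ell + eAU(X))
            if options.mode == "d2":
                for (x, y) in loop.inner_pairs:
                    U = code[(x, y)]
                    E += params.dangle5[U, nt[x - 1]] + params.dangle3[U, nt[y + 1]]
                R = PAIR_REVERSE[X]
                E += params.dangle3[R, nt[i + 1]] + params.dangle5[R, nt[j - 1]]
    return E


# ---------------------------------------------------------------------------
# base-pair probability matrices and distances


@dataclass
class BasePairProbabilityMatrix:
    """Upper-triangular pairing probabilities p_ij, 1-based."""

    n: int
    p: np.ndarray                   # (n+1, n+1), p[i, j] for i < j

    @classmethod
    def from_pairs(cls, n: int, probs: dict) -> "BasePairProbabilityMatrix":
        m = np.zeros((n + 1, n + 1))
        for (i, j), v in probs.items():
            if not 1 <= i < j <= n:
                raise ValueError(f"bad pair ({i},{j})")
            m[i, j] = v
        return cls(n, m)

    @classmethod
    def from_structure(cls, dotbracket: str) -> "BasePairProbabilityMatrix":
        ts, _ = parse_target(dotbracket)
        return cls.from_pairs(ts.n, {bp: 1.0 for bp in ts.pairs})

    def validate(self, tol: float = 1e-9) -> None:
        if (self.p < -tol).any() or (self.p > 1 + tol).any():
            raise ValueError("probabilities outside [0, 1]")
        if (self.row_sums() > 1 + 1e-9).any():
            raise ValueError("per-position pairing probabilities exceed 1")

    def row_sums(self) -> np.ndarray:
        return (self.p + self.p.T)[1:, 1:].sum(axis=1)

    @property
    def unpaired(self) -> np.ndarray:
        """q_i = 1 - sum_j p_ij, indexed 1..n (entry 0 unused)."""
        q = np.ones(self.n + 1)
        q[1:] -= self.row_sums()
        return q


def base_pair_distance(s, t) -> int:
    """Size of the symmetric difference of two structures' pair sets."""
    def pairs_of(x):
        if isinstance(x, str):
            return set(parse_target(x)[0].pairs)
        if isinstance(x, TargetStructure):
            return set(x.pairs)
        return set(x)
    return len(pairs_of(s) ^ pairs_of(t))


def ensemble_diversity(pm: BasePairProbabilityMatrix) -> float:
    """Expected base-pair distance between two ensemble draws: 2 sum p(1-p)."""
    p = pm.p
    return float(2.0 * (p * (1.0 - p)).sum())


def plasticity(pm: BasePairProbabilityMatrix, n: int | None = None) -> float:
    """Ensemble diversity normalized by n/2; lies in [0, 1]."""
    n = pm.n if n is None else n
    return ensemble_diversity(pm) / (n / 2.0)


def ensemble_distance(pm_a: BasePairProbabilityMatrix,
                      pm_b: BasePairProbabilityMatrix) -> float:
    """D_V: Euclidean distance between base-pair probability matrices."""
    if pm_a.n != pm_b.n:
        raise ValueError("matrices must have equal length")
    return float(np.sqrt(((pm_a.p - pm_b.p) ** 2).sum()))


def expected_cross_distance(pm_a, pm_b) -> float:
    """Expected base-pair distance between draws from two ensembles."""
    pa, pb = pm_a.p, pm_b.p
    return float((pa * (1 - pb) + pb * (1 - pa)).sum())


def d1(pm_a: BasePairProbabilityMatrix, pm_b: BasePairProbabilityMatrix) -> float:
    """Expected cross distance minus the diversity of the first ensemble."""
    return expected_cross_distance(pm_a, pm_b) - ensemble_diversity(pm_a)


# ---------------------------------------------------------------------------
# folding backends


class BackendError(RuntimeError):
    pass


class ViennaRNABackend:
    """Adapter to the ViennaRNA Python bindings, when importable."""

    def __init__(self, dangles: int = 2, temperature: float = 37.0):
        try:
            import RNA
        except ImportError as exc:  # pragma: no cover
            raise BackendError("ViennaRNA Python bindings are not available") from exc
        self._RNA = RNA
        self.md = RNA.md()
        self.md.dangles = dangles
        self.md.temperature = temperature

    def mfe_fold(self, sequence: str):
        fc = self._RNA.fold_compound(sequence, self.md)
        ss, mfe = fc.mfe()
        return ss, float(mfe)

    def basepair_probs(self, sequence: str) -> BasePairProbabilityMatrix:
        fc = self._RNA.fold_compound(sequence, self.md)
        _, mfe = fc.mfe()
        fc.exp_params_rescale(mfe)
        fc.pf()
        bpp = np.array(fc.bpp())
        n = len(sequence)
        m = np.zeros((n + 1, n + 1))
        m[:bpp.shape[0], :bpp.shape[1]] = bpp
        return BasePairProbabilityMatrix(n, m)


class EnumerationBackend:
    """Exact folding by exhaustive structure enumeration (small sequences).

    Enumerates every well-nested secondary structure (canonical pairs,
    minimum hairpin size theta = 3) of the sequence, scores each with
    ``energy_of_structure`` under this package's own energy model, and
    derives the minimum free energy structure and the exact Boltzmann
    base-pair probabilities.  Exact by construction, which makes it the
    independent oracle for the metric pipeline; practical up to roughly 20
    nucleotides.
    """

    def __init__(self, params: EnergyParameters | None = None, options=None,
                 max_structures: int = 200_000):
        from .dual_pf import ModelOptions
        from .params import load_parameters
        self.params = params if params is not None else load_parameters()
        self.options = options if options is not None else ModelOptions(mode="d0")
        self.max_structures = max_structures
        self._cache = {}

    def structures(self, sequence: str):
        seq = sequence.upper().replace("T", "U")
        n = len(seq)
        canon = set(PAIR_INDEX)

        memo = {}

        def enum(i, j):
            # list of pair-tuples for the interval [i, j]
            if (i, j) in memo:
                return memo[(i, j)]
            if j - i <= THETA:
                return [()]
            out = list(enum(i + 1, j))       # i unpaired
            for k in range(i + THETA + 1, j + 1):
                if seq[i - 1] + seq[k - 1] in canon:
                    left = enum(i + 1, k - 1)
                    right = enum(k + 1, j)
                    for a in left:
                        for b in right:
                            out.append(((i, k),) + a + b)
            memo[(i, j)] = out
            return out

        structs = enum(1, n)
        if len(structs) > self.max_structures:
            raise BackendError(
                f"{len(structs)} structures exceed the enumeration limit")
        return structs

    def _ensemble(self, sequence: str):
        seq = sequence.upper().replace("T", "U")
        if seq in self._cache:
            return self._cache[seq]
        n = len(seq)
        RT = self.params.RT
        best = (math.inf, ())
        weights = []
        structs = self.structures(seq)
        for pairs in structs:
            ts = _structure_from_pairs(n, pairs)
            e = energy_of_structure(seq, ts, self.params, self.options)
            weights.append(math.exp(-e / RT))
            if (e, _db(n, pairs)) < (best[0], _db(n, best[1])):
                best = (e, pairs)
        Z = sum(weights)
        p = np.zeros((n + 1, n + 1))
        for pairs, w in zip(structs, weights):
            for (i, j) in pairs:
                p[i, j] += w / Z
        out = (_db(n, best[1]), best[0], BasePairProbabilityMatrix(n, p))
        self._cache[seq] = out
        return out

    def mfe_fold(self, sequence: str):
        db, e, _ = self._ensemble(sequence)
        return db, e

    def basepair_probs(self, sequence: str) -> BasePairProbabilityMatrix:
        return self._ensemble(sequence)[2]


def _db(n, pairs):
    out = ["."] * n
    for i, j in pairs:
        out[i - 1], out[j - 1] = "(", ")"
    return "".join(out)


def _structure_from_pairs(n, pairs):
    return parse_target(_db(n, pairs))[0]


def default_backend(**kwargs):
    """The established folding engine when importable, else the enumerator."""
    try:
        return ViennaRNABackend(**kwargs)
    except BackendError:
        return EnumerationBackend()


# ---------------------------------------------------------------------------
# robustness, neutrality, design measures


def point_mutants(sequence: str):
    """All 3n single-point mutants, positions left to right, ACGU order."""
    seq = sequence.upper().replace("T", "U")
    for i, c in enumerate(seq):
        if c not in NT:
            raise ValueError(f"invalid nucleotide {c!r} at position {i + 1}")
        for x in NT:
            if x != c:
                yield seq[:i] + x + seq[i + 1:]


def mutational_robustness(sequence: str, backend, variant: str = "dv") -> float:
    """1 minus the length-normalized mean distance to all 3n point mutants.

    ``dv`` (default): ensemble distance D_V, normalized by n.
    ``d1``: the asymmetric divergence d1, normalized by n/2.
    """
    if variant not in ("dv", "d1"):
        raise ValueError("variant must be 'dv' or 'd1'")
    n = len(sequence)
    pm = backend.basepair_probs(sequence)
    dists = []
    for mut in point_mutants(sequence):
        pm_b = backend.basepair_probs(mut)
        dists.append(ensemble_distance(pm, pm_b) if variant == "dv" else d1(pm, pm_b))
    mean = float(np.mean(dists))
    return 1.0 - mean / (n if variant == "dv" else n / 2.0)


def neutrality(sequence: str, backend) -> float:
    """1 - <d_BP(mfe(a), mfe(a'))>/n over all 3n single-point mutants."""
    n = len(sequence)
    wt, _ = backend.mfe_fold(sequence)
    dists = [base_pair_distance(wt, backend.mfe_fold(m)[0])
             for m in point_mutants(sequence)]
    return 1.0 - float(np.mean(dists)) / n


def measure_battery(sequence: str, target, backend) -> dict:
    """Ensemble design measures of ``sequence`` against a target structure.

    Returns length-normalized ensemble defect, expected base-pair distance to
    target, proportion of native contacts in the MFE structure, average
    positional entropy (natural log), length-normalized ensemble diversity,
    and the MFE structure/energy.
    """
    if isinstance(target, str):
        target, _ = parse_target(target)
    n = target.n
    pm = backend.basepair_probs(sequence)
    p, q = pm.p, pm.unpaired
    tgt = set(target.pairs)

    defect = 0.0
    for i in range(1, n + 1):
        j = int(target.pair_table[i])
        if j:
            defect += 1.0 - (p[i, j] if i < j else p[j, i])
        else:
            defect += 1.0 - q[i]
    exp_bp = sum(1.0 - p[i, j] for (i, j) in tgt)
    exp_bp += sum(p[i, j] for i in range(1, n + 1) for j in range(i + 1, n + 1)
                  if (i, j) not in tgt)

    entropy = 0.0
    for i in range(1, n + 1):
        probs = np.concatenate((p[i, i + 1:], p[1:i, i], [q[i]]))
        probs = probs[probs > 1e-300]
        entropy -= float((probs * np.log(probs)).sum())

    mfe_db, mfe_e = backend.mfe_fold(sequence)
    mfe_pairs = set(parse_target(mfe_db)[0].pairs)
    native = len(mfe_pairs & tgt) / len(tgt) if tgt else 1.0

    return {
        "ensemble_defect": defect / n,
        "expected_bp_distance": exp_bp / n,
        "prop_native_contacts": native,
        "positional_entropy": entropy / n,
        "ensemble_diversity": ensemble_diversity(pm) / n,
        "mfe_structure": mfe_db,
        "mfe_energy": mfe_e,
        "bp_distance_mfe_target": base_pair_distance(mfe_db, target),
    }


def zscore_report(wild_type_value: float, control_values) -> float:
    """(wt - mean(controls)) / sd(controls), sample sd with n-1."""
    vals = np.asarray(list(control_values), dtype=float)
    if vals.size < 2:
        raise ValueError("need at least two control values")
    sd = float(vals.std(ddof=1))
    if sd == 0.0:
        raise ValueError("control values have zero standard deviation")
    return (wild_type_value - float(vals.mean())) / sd
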