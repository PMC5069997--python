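"""Turner nearest-neighbor energy model: tables, accessors, temperature handling.

All energies are free energies in kcal/mol, evaluated at the table temperature
(310.15 K for the packaged Turner-2004 set).  The canonical pair order used
throughout the package is AU, CG, GC, UA, GU, UG and the nucleotide order is
A, C, G, U; every pair-indexed table follows it.

The packaged parameter files use a simple block grammar: a block name on its
own line (STACK, HAIRPIN, ...), whitespace-separated kcal/mol values below it,
``INF`` for forbidden entries, and ``#`` comments.  See
``data/turner2004.txt`` for the documented layout of each block.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

NT = "ACGU"
NT_INDEX = {c: i for i, c in enumerate(NT)}
PAIRS = ("AU", "CG", "GC", "UA", "GU", "UG")
PAIR_INDEX = {p: i for i, p in enumerate(PAIRS)}
#: pair code -> (5' nucleotide code, 3' nucleotide code)
PAIR_NTS = tuple((NT_INDEX[p[0]], NT_INDEX[p[1]]) for p in PAIRS)
#: pair code of the reversed pair (AU <-> UA etc.)
PAIR_REVERSE = tuple(PAIR_INDEX[p[1] + p[0]] for p in PAIRS)
#: pair codes carrying the terminal AU/GU penalty (everything but CG/GC)
WOBBLE_OR_AU = tuple(i for i, p in enumerate(PAIRS) if p not in ("CG", "GC"))

#: number of G/C nucleotides contributed by a pair code
PAIR_GC = tuple(int(p[0] in "GC") + int(p[1] in "GC") for p in PAIRS)
NT_GC = (0, 1, 1, 0)

JACOBSON_STOCKMAYER = 1.75  # prefactor of the RT ln(size/30) loop extrapolation

DATA_PACKAGE = "dualpf.data"
DEFAULT_PARAMETER_FILE = "turner2004.txt"
DEFAULT_INT22_FILE = "turner2004_int22.txt"


class ParameterError(ValueError):
    """Malformed or incomplete parameter table."""


@dataclass
class EnergyParameters:
    """All thermodynamic constants consumed by the dual recursions.

    Pair-indexed axes use the canonical pair order; nucleotide axes use ACGU.
    ``stack[x, u]`` is the energy of outer pair ``x`` stacked on inner pair
    ``u`` (5'-XU-3' / 3'-YV-5').  ``int11/int21/int22`` are the dedicated
    small-interior-loop tables; ``int21`` is stored for 1x2 loops (one
    unpaired nucleotide 5' of the inner pair) and queried through
    :meth:`int21_energy` which handles the 2x1 mirror case.
    """

    stack: np.ndarray                  # (6, 6)
    hairpin_init: np.ndarray           # (31,), sizes 0..30
    bulge_init: np.ndarray             # (31,)
    internal_init: np.ndarray          # (31,)
    mismatch_hairpin: np.ndarray       # (6, 4, 4): closing pair, nt(i+1), nt(j-1)
    mismatch_internal: np.ndarray      # (6, 4, 4)
    dangle5: np.ndarray                # (6, 4): pair, dangling nt at 5' side
    dangle3: np.ndarray                # (6, 4)
    triloop: dict = field(default_factory=dict)    # full 5-mer -> energy
    tetraloop: dict = field(default_factory=dict)  # full 6-mer -> energy
    hexaloop: dict = field(default_factory=dict)   # full 8-mer -> energy
    int11: np.ndarray | None = None    # (6, 6, 4, 4)
    int21: np.ndarray | None = None    # (6, 6, 4, 4, 4)
    int22: np.ndarray | None = None    # (6, 6, 4, 4, 4, 4)
    multiloop_a: float = 0.0           # closure penalty
    multiloop_b: float = 0.0           # per-branch penalty
    multiloop_c: float = 0.0           # per-unpaired penalty
    au_penalty: float = 0.0            # terminal non-GC/CG penalty
    asym: float = 0.0                  # interior-loop asymmetry coefficient
    max_asym: float = 0.0              # asymmetry cap
    temperature: float = 310.15        # table temperature T0, Kelvin
    gas_constant: float = 1.98717e-3   # kcal/(mol K)

    @property
    def RT(self) -> float:
        return self.gas_constant * self.temperature

    def __post_init__(self) -> None:
        if self.au_penalty < 0:
            raise ParameterError("au_penalty must be >= 0")
        if self.temperature <= 0:
            raise ParameterError("temperature must be positive")

    @classmethod
    def zeros(cls, temperature: float = 310.15) -> "EnergyParameters":
        """An all-zero table: every Boltzmann factor is 1 (pure counting)."""
        return cls(
            stack=np.zeros((6, 6)),
            hairpin_init=np.zeros(31),
            bulge_init=np.zeros(31),
            internal_init=np.zeros(31),
            mismatch_hairpin=np.zeros((6, 4, 4)),
            mismatch_internal=np.zeros((6, 4, 4)),
            dangle5=np.zeros((6, 4)),
            dangle3=np.zeros((6, 4)),
            int11=np.zeros((6, 6, 4, 4)),
            int21=np.zeros((6, 6, 4, 4, 4)),
            int22=np.zeros((6, 6, 4, 4, 4, 4)),
            temperature=temperature,
        )

    # -- interior-loop table accessors (nucleotide arguments are codes) -----

    def int11_energy(self, outer: int, inner: int, a: int, b: int) -> float:
        """1x1 loop: ``a`` at position i+1 (= k-1), ``b`` at j-1 (= l+1)."""
        return float(self.int11[outer, inner, a, b])

    def int21_energy(self, outer: int, inner: int, r1: int,
                     n5: int, n3a: int, n3b: int) -> float:
        """1x2 (r1 == 1) or 2x1 (r1 == 2) loop.

        For 1x2: ``n5`` at i+1, ``n3a`` at l+1, ``n3b`` at j-1.
        For 2x1: ``n5`` at i+1, ``n3a`` at k-1, ``n3b`` at j-1; by the usual
        loop symmetry this is the 1x2 table read on the reversed pairs.
        """
        if r1 == 1:
            return float(self.int21[outer, inner, n5, n3a, n3b])
        return float(self.int21[PAIR_REVERSE[inner], PAIR_REVERSE[outer],
                                n3b, n5, n3a])

    def int22_energy(self, outer: int, inner: int,
                     a: int, b: int, c: int, d: int) -> float:
        """2x2 loop: nts at i+1, k-1, l+1, j-1."""
        return float(self.int22[outer, inner, a, b, c, d])


def _loop_size_energy(table: np.ndarray, size: int, RT: float) -> float:
    if size <= 30:
        return float(table[size])
    return float(table[30]) + JACOBSON_STOCKMAYER * RT * math.log(size / 30.0)


def hairpin_energy(params: EnergyParameters, size: int) -> float:
    """Hairpin initiation for ``size`` unpaired nucleotides (size >= 3)."""
    if size < 3:
        raise ValueError(f"hairpin loops need >= 3 unpaired nucleotides, got {size}")
    return _loop_size_energy(params.hairpin_init, size, params.RT)


def bulge_energy(params: EnergyParameters, size: int) -> float:
    if size < 1:
        raise ValueError(f"bulge size must be >= 1, got {size}")
    return _loop_size_energy(params.bulge_init, size, params.RT)


def internal_energy(params: EnergyParameters, size: int) -> float:
    if size < 2:
        raise ValueError(f"interior-loop size must be >= 2, got {size}")
    return _loop_size_energy(params.internal_init, size, params.RT)


def asymmetry_energy(params: EnergyParameters, r1: int, r2: int) -> float:
    return min(params.asym * abs(r1 - r2), params.max_asym)


def au_penalty_of(params: EnergyParameters, pair) -> float:
    """Terminal penalty: ``au_penalty`` for AU/UA/GU/UG, 0 for GC/CG."""
    code = PAIR_INDEX.get(pair) if isinstance(pair, str) else pair
    if code is None or not 0 <= code < 6:
        raise ValueError(f"not a canonical base pair: {pair!r}")
    return params.au_penalty if code in WOBBLE_OR_AU else 0.0


# ---------------------------------------------------------------------------
# parameter file parsing


def _tokenize(text: str):
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.split("#", 1)[0]
        for tok in line.split():
            yield lineno, tok


_BLOCK_NAMES = {
    "STACK", "HAIRPIN", "BULGE", "INTERNAL", "MISMATCH_HAIRPIN",
    "MISMATCH_INTERNAL", "DANGLE5", "DANGLE3", "TRILOOPS", "TETRALOOPS",
    "HEXALOOPS", "ML_PARAMS", "NINIO", "MISC", "INT11", "INT21", "INT22",
}


def _parse_blocks(text: str) -> dict[str, list[str]]:
    blocks: dict[str, list[str]] = {}
    current = None
    for lineno, tok in _tokenize(text):
        if tok in _BLOCK_NAMES:
            current = blocks.setdefault(tok, [])
        elif current is None:
            raise ParameterError(f"line {lineno}: value {tok!r} before any block header")
        else:
            current.append(tok)
    return blocks


def _floats(blocks, name, count=None) -> np.ndarray:
    if name not in blocks:
        raise ParameterError(f"missing mandatory table {name}")
    try:
        vals = np.array([math.inf if t == "INF" else float(t) for t in blocks[name]])
    except ValueError as exc:
        raise ParameterError(f"block {name}: {exc}") from None
    if count is not None and vals.size != count:
        raise ParameterError(f"block {name}: expected {count} values, got {vals.size}")
    return vals


def _special_loops(blocks, name, length) -> dict:
    toks = blocks.get(name, [])
    if len(toks) % 2:
        raise ParameterError(f"block {name}: expected sequence/energy pairs")
    out = {}
    for seq, val in zip(toks[::2], toks[1::2]):
        seq = seq.upper().replace("T", "U")
        if len(seq) != length or any(c not in NT for c in seq):
            raise ParameterError(f"block {name}: bad loop sequence {seq!r}")
        out[seq] = float(val)
    return out


def load_parameters(source=None, temperature: float | None = None) -> EnergyParameters:
    """Load an energy-parameter table.

    ``source`` may be a path, a string of table text, or None for the
    packaged Turner-2004 set (which also pulls in the companion 2x2
    interior-loop file).  ``temperature`` overrides the MISC block's table
    temperature; the free energies themselves are not rescaled.
    """
    int22_text = None
    if source is None:
        root = resources.files(DATA_PACKAGE)
        text = (root / DEFAULT_PARAMETER_FILE).read_text()
        int22_text = (root / DEFAULT_INT22_FILE).read_text()
    elif isinstance(source, Path) or (isinstance(source, str) and "\n" not in source):
        text = Path(source).read_text()
    else:
        text = source

    blocks = _parse_blocks(text)
    if int22_text is not None:
        blocks.update(_parse_blocks(int22_text))

    misc = _floats(blocks, "MISC")
    if misc.size not in (2, 3):
        raise ParameterError("MISC must hold: au_penalty, temperature[, gas constant]")
    ml = _floats(blocks, "ML_PARAMS", 3)
    ninio = _floats(blocks, "NINIO", 2)

    def opt(name, shape):
        if name not in blocks:
            return None
        return _floats(blocks, name, int(np.prod(shape))).reshape(shape)

    params = EnergyParameters(
        stack=_floats(blocks, "STACK", 36).reshape(6, 6),
        hairpin_init=_floats(blocks, "HAIRPIN", 31),
        bulge_init=_floats(blocks, "BULGE", 31),
        internal_init=_floats(blocks, "INTERNAL", 31),
        mismatch_hairpin=_floats(blocks, "MISMATCH_HAIRPIN", 96).reshape(6, 4, 4),
        mismatch_internal=_floats(blocks, "MISMATCH_INTERNAL", 96).reshape(6, 4, 4),
        dangle5=_floats(blocks, "DANGLE5", 24).reshape(6, 4),
        dangle3=_floats(blocks, "DANGLE3", 24).reshape(6, 4),
        triloop=_special_loops(blocks, "TRILOOPS", 5),
        tetraloop=_special_loops(blocks, "TETRALOOPS", 6),
        hexaloop=_special_loops(blocks, "HEXALOOPS", 8),
        int11=opt("INT11", (6, 6, 4, 4)),
        int21=opt("INT21", (6, 6, 4, 4, 4)),
        int22=opt("INT22", (6, 6, 4, 4, 4, 4)),
        multiloop_a=float(ml[0]),
        multiloop_b=float(ml[1]),
        multiloop_c=float(ml[2]),
        au_penalty=float(misc[0]),
        asym=float(ninio[0]),
        max_asym=float(ninio[1]),
        temperature=float(temperature if temperature is not None else misc[1]),
        gas_constant=float(misc[2]) if misc.size == 3 else 1.98717e-3,
    )
    if not np.isfinite(params.hairpin_init[3:31]).all():
        raise ParameterError("HAIRPIN must be finite for sizes 3..30")
    return params


def default_scale(params: EnergyParameters) -> float:
    """Default per-nucleotide scaling constant.

    The geometric-mean stacking Boltzmann weight per nucleotide,
    exp(-<stack>/(2 RT)); keeps scaled per-pair values near unity.
    """
    mean_stack = float(np.mean(params.stack[np.isfinite(params.stack)]))
    return math.exp(-mean_stack / (2.0 * params.RT))
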