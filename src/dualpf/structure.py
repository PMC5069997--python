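"""Target-structure parsing and decomposition.

Positions are numbered 1..n throughout the public data model.  A target
secondary structure is a well-nested set of base pairs (i, j), i < j, with
j - i > theta = 3 (steric minimum hairpin size).  Each structure decomposes
uniquely into loops: one loop per closing base pair (hairpin, stack, bulge,
interior loop or multiloop) plus the external loop.

For the dangle-aware mode (d2) the helices of a multiloop or of the external
loop are partitioned into maximal *adjacency groups*: helices whose dangling
positions overlap with one another (gap of at most two unpaired positions)
must be instantiated jointly.  The multiloop closing pair counts as adjacent
to a component starting within two positions of either of its ends, which
makes its group the *closing group*.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import NT, NT_INDEX, PAIRS, PAIR_NTS

THETA = 3

IUPAC = {
    "A": "A", "C": "C", "G": "G", "U": "U", "T": "U",
    "R": "AG", "Y": "CU", "S": "CG", "W": "AU", "K": "GU", "M": "AC",
    "B": "CGU", "D": "AGU", "H": "ACU", "V": "ACG", "N": "ACGU",
}


class StructureError(ValueError):
    """Invalid dot-bracket string or constraint string."""


@dataclass
class Loop:
    kind: str                       # hairpin | stack | bulge_left | bulge_right | internal | multiloop | external
    closing_pair: tuple | None      # (i, j) or None for the external loop
    inner_pairs: list               # directly enclosed pairs, left to right
    unpaired_runs: list             # [(start, end)] inclusive intervals, may be empty
    ell: int = 0                    # total unpaired positions in the loop
    r1: int = 0                     # left size (interior loops / left bulges)
    r2: int = 0                     # right size

    @property
    def unpaired_positions(self) -> list:
        return [p for a, b in self.unpaired_runs for p in range(a, b + 1)]


@dataclass
class TargetStructure:
    n: int
    pairs: tuple                    # ((i, j), ...) sorted by i
    pair_table: np.ndarray          # 1-based; partner or 0
    loops: list                     # Loop records; external loop last
    bp_order: list                  # pairs sorted by the inner-before-outer total order
    bp_index: dict                  # pair -> 1-based rank
    bp_close_el_or_ml: frozenset    # pairs whose outside neighbor is the external loop or a multiloop
    loop_of: dict = field(default_factory=dict)   # closing pair -> Loop

    @property
    def external_loop(self) -> Loop:
        return self.loops[-1]

    def to_dotbracket(self) -> str:
        out = ["."] * self.n
        for i, j in self.pairs:
            out[i - 1] = "("
            out[j - 1] = ")"
        return "".join(out)


@dataclass
class SequenceConstraints:
    """Per-position IUPAC-derived allowed nucleotide sets (codes into ACGU)."""

    n: int
    allowed: tuple                  # allowed[i] for position i (1-based; index 0 unused)
    allowed_pairs: dict             # (i, j) -> tuple of allowed pair codes
    iupac: str

    def is_unconstrained(self) -> bool:
        return all(len(self.allowed[i]) == 4 for i in range(1, self.n + 1))

    def infeasible_pairs(self) -> list:
        return [bp for bp, codes in self.allowed_pairs.items() if not codes]

    def compatible(self, sequence: str) -> bool:
        seq = sequence.upper().replace("T", "U")
        if len(seq) != self.n:
            return False
        return all(seq[i - 1] in NT and NT_INDEX[seq[i - 1]] in self.allowed[i]
                   for i in range(1, self.n + 1))


def _expand_constraints(structure: TargetStructure, iupac: str | None) -> SequenceConstraints:
    n = structure.n
    if iupac is None:
        iupac = "N" * n
    iupac = iupac.upper().replace("T", "U")
    if len(iupac) != n:
        raise StructureError(
            f"constraint string length {len(iupac)} != structure length {n}")
    allowed = [()]
    for pos, c in enumerate(iupac, 1):
        if c not in IUPAC:
            raise StructureError(f"position {pos}: invalid IUPAC code {c!r}")
        allowed.append(tuple(NT_INDEX[x] for x in IUPAC[c]))
    allowed_pairs = {}
    for i, j in structure.pairs:
        codes = tuple(p for p in range(6)
                      if PAIR_NTS[p][0] in allowed[i] and PAIR_NTS[p][1] in allowed[j])
        allowed_pairs[(i, j)] = codes
    return SequenceConstraints(n=n, allowed=tuple(allowed),
                               allowed_pairs=allowed_pairs, iupac=iupac)


def _decompose(n: int, pairs, pair_table) -> list:
    children_of = {None: []}
    stack = [None]
    for pos in range(1, n + 1):
        partner = pair_table[pos]
        if partner > pos:
            bp = (pos, partner)
            children_of.setdefault(bp, [])
            children_of[stack[-1]].append(bp)
            stack.append(bp)
        elif 0 < partner < pos:
            stack.pop()

    loops = []
    loop_of = {}

    def runs_between(lo, hi, children):
        """Unpaired runs strictly inside (lo, hi) around the children."""
        runs = []
        cur = lo + 1
        for (a, b) in children:
            if a > cur:
                runs.append((cur, a - 1))
            cur = b + 1
        if hi - 1 >= cur:
            runs.append((cur, hi - 1))
        return runs

    for i, j in pairs:
        children = children_of[(i, j)]
        runs = runs_between(i, j, children)
        ell = sum(b - a + 1 for a, b in runs)
        if not children:
            if ell < THETA:
                raise StructureError(
                    f"hairpin closed by ({i},{j}) has {ell} unpaired positions; "
                    f"the steric minimum is {THETA}")
            loop = Loop("hairpin", (i, j), [], runs, ell=ell)
        elif len(children) == 1:
            k, l = children[0]
            r1, r2 = k - i - 1, j - l - 1
            if r1 == 0 and r2 == 0:
                kind = "stack"
            elif r2 == 0:
                kind = "bulge_left"
            elif r1 == 0:
                kind = "bulge_right"
            else:
                kind = "internal"
            loop = Loop(kind, (i, j), children, runs, ell=ell, r1=r1, r2=r2)
        else:
            loop = Loop("multiloop", (i, j), children, runs, ell=ell)
        loops.append(loop)
        loop_of[(i, j)] = loop

    top = children_of[None]
    runs = runs_between(0, n + 1, top)
    ext = Loop("external", None, top, runs, ell=sum(b - a + 1 for a, b in runs))
    loops.append(ext)
    loop_of[None] = ext
    return loops, loop_of


def order_base_pairs(pairs) -> list:
    """Total order: enclosed pairs first, ties left to right.

    (i, j) precedes (x, y) exactly when x < i < j < y or i < j < x < y;
    equivalently, sort by closing position ascending and opening position
    descending.  Every inner pair of a loop ranks strictly below its closing
    pair, so evaluating pairs in this order is a valid dynamic-programming
    schedule.
    """
    return sorted(pairs, key=lambda bp: (bp[1], -bp[0]))


def parse_target(dotbracket: str, iupac: str | None = None):
    """Parse a dot-bracket target and optional IUPAC constraint string.

    Returns ``(TargetStructure, SequenceConstraints)``.
    """
    db = dotbracket.strip()
    n = len(db)
    if n == 0:
        raise StructureError("empty structure")
    bad = sorted(set(db) - set("().•"))
    if bad:
        raise StructureError(f"invalid characters in dot-bracket string: {bad}")

    pair_table = np.zeros(n + 1, dtype=int)
    opens = []
    pairs = []
    for pos, c in enumerate(db, 1):
        if c == "(":
            opens.append(pos)
        elif c == ")":
            if not opens:
                raise StructureError(f"unbalanced ')' at position {pos}")
            i = opens.pop()
            if pos - i <= THETA:
                raise StructureError(
                    f"pair ({i},{pos}) violates the minimum hairpin size (j-i must exceed {THETA})")
            pairs.append((i, pos))
            pair_table[i], pair_table[pos] = pos, i
    if opens:
        raise StructureError(f"unbalanced '(' at position {opens[-1]}")
    pairs.sort()

    loops, loop_of = _decompose(n, pairs, pair_table)

    bp_order = order_base_pairs(pairs)
    bp_index = {bp: r for r, bp in enumerate(bp_order, 1)}
    closers = set(loops[-1].inner_pairs)
    for loop in loops:
        if loop.kind == "multiloop":
            closers.update(loop.inner_pairs)

    structure = TargetStructure(
        n=n, pairs=tuple(pairs), pair_table=pair_table, loops=loops,
        bp_order=bp_order, bp_index=bp_index,
        bp_close_el_or_ml=frozenset(closers), loop_of=loop_of)
    constraints = _expand_constraints(structure, iupac)
    return structure, constraints


# ---------------------------------------------------------------------------
# dangle-adjacency groups


@dataclass
class DangleSlot:
    """One dangle energy term of a group member.

    ``member`` indexes the group's component helices, or -1 for the multiloop
    closing pair.  ``side`` is '5' or '3' from the loop's point of view.
    ``target`` says where the dangling nucleotide lives:
    ('free', k): k-th entry of the group's dangle_positions;
    ('member', m, end) / ('closing', end): a paired position, end in {0, 1}.
    """

    member: int
    side: str
    position: int
    target: tuple


@dataclass
class Group:
    members: list                   # component pairs, ascending
    has_closing: bool               # multiloop closing pair belongs to this group
    dangle_positions: tuple         # distinct unpaired dangle positions, ascending
    slots: list                     # DangleSlot records


def build_groups(loop: Loop, dangle_mode: str, structure: TargetStructure) -> list:
    """Partition a multiloop/external loop's helices into adjacency groups.

    Under d0 every helix is its own degenerate group with no dangles.  Under
    d2, maximal runs of mutually adjacent helices (and, for multiloops, the
    closing pair when a component starts or ends within two positions of it)
    form joint groups whose dangle positions are recorded with their overlap
    resolution.
    """
    if loop.kind not in ("multiloop", "external"):
        raise ValueError("groups are defined for multiloop and external loops only")
    comps = list(loop.inner_pairs)
    if dangle_mode == "d0":
        return [Group([bp], False, (), []) for bp in comps]
    if dangle_mode != "d2":
        raise ValueError(f"unknown dangle mode {dangle_mode!r}")

    closing = loop.closing_pair
    k = len(comps)
    parent = list(range(k + (1 if closing else 0)))   # union-find; last = closing

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        parent[find(a)] = find(b)

    for r in range(k - 1):
        if comps[r + 1][0] - comps[r][1] <= 2:
            union(r, r + 1)
    if closing:
        i, j = closing
        for r, (x, y) in enumerate(comps):
            if x <= i + 2 or y >= j - 2:
                union(r, k)

    clusters: dict[int, list] = {}
    for r in range(k):
        clusters.setdefault(find(r), []).append(r)
    closing_root = find(k) if closing else None

    n = structure.n
    pt = structure.pair_table
    lo = closing[0] if closing else 0          # loop boundary positions
    hi = closing[1] if closing else n + 1

    groups = []
    roots = sorted(clusters, key=lambda root: clusters[root][0])
    if closing and closing_root not in clusters:
        clusters[closing_root] = []
        roots.append(closing_root)
    for root in roots:
        members = [comps[r] for r in clusters[root]]
        has_closing = closing is not None and root == closing_root
        member_pos = {}
        for m, (x, y) in enumerate(members):
            member_pos[x] = (m, 0)
            member_pos[y] = (m, 1)
        if has_closing:
            member_pos[lo] = (-1, 0)
            member_pos[hi] = (-1, 1)

        slots = []
        free: list[int] = []

        def add_slot(member, side, pos):
            if pos < max(1, lo) or pos > (hi if closing else n):
                return
            if pt[pos]:
                if pos in member_pos:
                    slots.append(DangleSlot(member, side, pos, ("member",) + member_pos[pos]
                                            if member_pos[pos][0] >= 0 else
                                            ("closing", member_pos[pos][1])))
                return
            if pos not in free:
                free.append(pos)
            slots.append(DangleSlot(member, side, pos, ("free", free.index(pos))))

        for m, (x, y) in enumerate(members):
            add_slot(m, "5", x - 1)
            add_slot(m, "3", y + 1)
        if has_closing:
            # inner flanks of the closing pair: 3' dangle at lo+1, 5' at hi-1
            add_slot(-1, "3", lo + 1)
            add_slot(-1, "5", hi - 1)

        order = sorted(range(len(free)), key=lambda t: free[t])
        remap = {old: new for new, old in enumerate(order)}
        for s in slots:
            if s.target[0] == "free":
                s.target = ("free", remap[s.target[1]])
        groups.append(Group(members, has_closing,
                            tuple(sorted(free)), slots))
    return groups


def read_target_record(text: str):
    """Parse a FASTA-like record: '>name', structure line, optional constraints.

    A bare structure string (no header) is also accepted.  Returns
    (name, dotbracket, constraints-or-None).
    """
    lines = [ln.strip() for ln in text.strip().splitlines() if ln.strip()]
    if not lines:
        raise StructureError("empty input")
    name = None
    if lines[0].startswith(">"):
        name = lines[0][1:].strip() or None
        lines = lines[1:]
    if not lines:
        raise StructureError("missing structure line")
    db = lines[0]
    iupac = lines[1] if len(lines) > 1 else None
    return name, db, iupac


def generate_random_structure(n: int, pair_density: float = 0.5,
                              seed: int = 0) -> str:
    """A reproducible random well-nested structure with theta = 3 respected.

    ``pair_density`` is the target fraction of positions that are paired;
    attempts that would cross an existing pair or create a too-small hairpin
    are discarded, so sparse structures are returned when n is small.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    pair_table = np.zeros(n + 1, dtype=int)
    target = int(pair_density * n / 2)
    placed = 0
    for _ in range(20 * n + 40):
        if placed >= target:
            break
        i = int(rng.integers(1, n + 1))
        j = int(rng.integers(1, n + 1))
        i, j = min(i, j), max(i, j)
        if j - i <= THETA or pair_table[i] or pair_table[j]:
            continue
        depth = 0
        ok = True
        for p in range(i + 1, j):
            if pair_table[p] > p:
                depth += 1
            elif pair_table[p] and pair_table[p] < p:
                if depth == 0:
                    ok = False
                    break
                depth -= 1
        if not ok or depth != 0:
            continue
        pair_table[i], pair_table[j] = j, i
        placed += 1
    out = ["."] * n
    for i in range(1, n + 1):
        if pair_table[i] > i:
            out[i - 1] = "("
        elif pair_table[i]:
            out[i - 1] = ")"
    return "".join(out)
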