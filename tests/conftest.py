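import math
import random

import pytest

from dualpf.params import EnergyParameters, load_parameters
from dualpf.structure import StructureError, generate_random_structure, parse_target

# The published per-pair table of the worked 28-nt example: columns AU, CG,
# GC, UA, GU, UG and the row sum, for each base pair (d0, unscaled, 37 C,
# constraints 18=G and 23=C).
WORKED_DB = "(((.((...)).)).(((....)).))."
WORKED_IUPAC = "N" * 17 + "G" + "N" * 4 + "C" + "N" * 5
WORKED_TABLE = {
    (18, 23): ([0.000, 0.000, 0.364, 0.000, 0.000, 0.000], 0.364),
    (17, 24): ([10.977, 17.859, 76.923, 10.977, 10.977, 3.525], 131.238),
    (16, 26): ([11.690, 70.834, 184.603, 12.771, 13.347, 3.915], 297.160),
    (6, 10): ([0.004, 0.010, 0.010, 0.004, 0.004, 0.004], 0.038),
    (5, 11): ([0.750, 3.022, 5.234, 0.899, 0.960, 0.256], 11.120),
    (3, 13): ([109.842, 256.875, 424.976, 108.653, 117.851, 108.132], 1126.330),
    (2, 14): ([10853.104, 86208.448, 170643.321, 12575.544, 13285.398, 3647.077],
              297212.891),
    (1, 27): ([1558.575, 7895.583, 7895.583, 1558.575, 1558.575, 1558.575],
              22025.464),
}
WORKED_TOTAL = 88101.856


@pytest.fixture(scope="session")
def params():
    return load_parameters()


@pytest.fixture(scope="session")
def zero_params():
    return EnergyParameters.zeros()


@pytest.fixture(scope="session")
def worked_example():
    return parse_target(WORKED_DB, WORKED_IUPAC)


def enumeration_size(ts, cons):
    size = 1
    for bp in ts.pairs:
        size *= len(cons.allowed_pairs[bp])
    for p in range(1, ts.n + 1):
        if ts.pair_table[p] == 0:
            size *= len(cons.allowed[p])
    return size


# hand-picked shapes that random draws at small n rarely produce: multiloops
# (with and without dangle-position overlaps), bulges, interior loops
EXTRA_SHAPES = [
    "((....)(....))",
    "((....).(....))",
    "((....)..(....).)",
    "(.(....)(....))",
    "(..(....)...)",
    "((.(...)))",
    "((...)..)",
    "(.(...).)",
    ".(....)(....).",
]


def random_instances(count, seed, max_enum=20000, nmax=13, letters="NNRYSWKM",
                     include_extra=True):
    """Reproducible constrained instances small enough to enumerate."""
    rng = random.Random(seed)
    out = []
    shapes = list(EXTRA_SHAPES) if include_extra else []
    while len(out) < count:
        if shapes:
            db = shapes.pop(0)
            n = len(db)
        else:
            n = rng.randint(5, nmax)
            db = generate_random_structure(n, rng.uniform(0.3, 0.8),
                                           seed=rng.randrange(2 ** 31))
        iu = "".join(rng.choice(letters) for _ in range(n))
        try:
            ts, cons = parse_target(db, iu)
        except StructureError:
            continue
        if cons.infeasible_pairs():
            continue
        if enumeration_size(ts, cons) > max_enum:
            continue
        out.append((db, iu, ts, cons))
    return out
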