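"""Dual thermodynamics: free energy, expected energy, entropy, heat capacity.

The free energy of a structure depends on the *table* temperature T0 at
which the nearest-neighbor parameters are tabulated; the Boltzmann exponent
carries its own *formal* temperature T.  Keeping the two apart lets the dual
expected energy be obtained as a derivative in T alone,

    <E*> = R T^2 d/dT ln Z*(s0, T0, T)  at T = T0,

evaluated here by a central finite difference with the table energies held
fixed.  The dual ensemble free energy is G* = -RT ln Z*, the dual entropy
follows from the definitional identity T S* = <E*> - G*, and the dual heat
capacity is exposed as the finite-difference derivative of <E*> in the
formal temperature (a documented extension; the quantity has no published
reference formula).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .dual_pf import DualPFState, ModelOptions, compute
from .gc_resolved import compute_gc
from .metrics import energy_of_structure


@dataclass
class DualThermo:
    ln_Z: float
    G_star: float                  # kcal/mol
    E_expected: float              # kcal/mol
    S_star: float                  # kcal/(mol K)
    Cp_star: float | None = None   # kcal/(mol K)
    per_gc: dict | None = None     # k -> (ln_Z_k, G_k, E_k, S_k) arrays when requested


class StepSizeError(ValueError):
    pass


def dual_probability(sequence: str, structure, state: DualPFState) -> float:
    """ln p*(a) = -E(a, s0)/RT - ln Z*(s0); -inf for incompatible sequences."""
    e = energy_of_structure(sequence, structure, state.params, state.options)
    if e == math.inf:
        return -math.inf
    return -e / state.RT_formal - state.log_Z()


def _check_h(h):
    if h <= 0:
        raise StepSizeError("finite-difference step h must be positive")
    if h < 1e-7:
        raise StepSizeError(
            f"step h={h} is below the resolution of the log partition "
            "function; use a larger step (default 0.01 K)")


def _lnZ(structure, constraints, params, mode, options, scale_C, T):
    return compute(structure, constraints, params, mode=mode, options=options,
                   scale_C=scale_C, formal_temperature=T).log_Z()


def dual_expected_energy(structure, constraints, params, mode: str = "d2",
                         h: float = 0.01, options: ModelOptions | None = None,
                         scale_C: float | None = None,
                         side: str = "central") -> float:
    """<E*> by finite differencing ln Z* in the formal temperature.

    ``side`` selects 'central' (default), 'forward' or 'backward'
    differences; the one-sided variants are diagnostics.
    """
    _check_h(h)
    T0 = params.temperature
    R = params.gas_constant
    f = lambda T: _lnZ(structure, constraints, params, mode, options, scale_C, T)
    if side == "central":
        d = (f(T0 + h) - f(T0 - h)) / (2 * h)
    elif side == "forward":
        d = (f(T0 + h) - f(T0)) / h
    elif side == "backward":
        d = (f(T0) - f(T0 - h)) / h
    else:
        raise ValueError("side must be 'central', 'forward' or 'backward'")
    return R * T0 * T0 * d


def dual_expected_energy_by_gc(structure, constraints, params, mode: str = "d2",
                               h: float = 0.01, options=None,
                               scale_C: float | None = None) -> np.ndarray:
    """<E*(s0, k)> for every GC count k; NaN where Z*(s0, k) = 0."""
    _check_h(h)
    T0 = params.temperature
    R = params.gas_constant

    def lnZk(T):
        st = compute_gc(structure, constraints, params, mode=mode,
                        options=options, scale_C=scale_C, formal_temperature=T)
        with np.errstate(divide="ignore"):
            return np.log(st.Zk) + structure.n * math.log(st.scale_C)

    d = (lnZk(T0 + h) - lnZk(T0 - h)) / (2 * h)
    out = R * T0 * T0 * d
    out[~np.isfinite(out)] = np.nan
    return out


def dual_free_energy(state: DualPFState) -> float:
    """G* = -RT ln Z* at the state's formal temperature."""
    return -state.RT_formal * state.log_Z()


def dual_entropy(structure, constraints, params, mode: str = "d2",
                 h: float = 0.01, options=None, scale_C=None) -> float:
    """S* = (<E*> - G*)/T0."""
    T0 = params.temperature
    e = dual_expected_energy(structure, constraints, params, mode, h, options, scale_C)
    g = -params.gas_constant * T0 * _lnZ(structure, constraints, params, mode,
                                         options, scale_C, T0)
    return (e - g) / T0


def dual_heat_capacity(structure, constraints, params, mode: str = "d2",
                       h: float = 0.01, options=None, scale_C=None) -> float:
    """C*_p = d<E*>/dT by a central difference of central differences.

    Uses ln Z* at the five formal temperatures T0, T0 +/- h, T0 +/- 2h.
    """
    _check_h(h)
    T0 = params.temperature
    R = params.gas_constant
    f = lambda T: _lnZ(structure, constraints, params, mode, options, scale_C, T)
    f0 = f(T0)

    def e_at(T, lo, hi):
        return R * T * T * (hi - lo) / (2 * h)

    e_plus = e_at(T0 + h, f0, f(T0 + 2 * h))
    e_minus = e_at(T0 - h, f(T0 - 2 * h), f0)
    return (e_plus - e_minus) / (2 * h)


def dual_thermo(structure, constraints, params, mode: str = "d2",
                h: float = 0.01, options=None, scale_C=None,
                heat_capacity: bool = False, gc_profile: bool = False) -> DualThermo:
    """All dual thermodynamic quantities in one pass."""
    T0 = params.temperature
    R = params.gas_constant
    ln_Z = _lnZ(structure, constraints, params, mode, options, scale_C, T0)
    G = -R * T0 * ln_Z
    E = dual_expected_energy(structure, constraints, params, mode, h, options, scale_C)
    S = (E - G) / T0
    Cp = dual_heat_capacity(structure, constraints, params, mode, h,
                            options, scale_C) if heat_capacity else None
    per_gc = None
    if gc_profile:
        st = compute_gc(structure, constraints, params, mode=mode,
                        options=options, scale_C=scale_C)
        with np.errstate(divide="ignore"):
            ln_Zk = np.log(st.Zk) + structure.n * math.log(st.scale_C)
        Ek = dual_expected_energy_by_gc(structure, constraints, params, mode,
                                        h, options, scale_C)
        Gk = -R * T0 * ln_Zk
        per_gc = {"ln_Z_k": ln_Zk, "G_k": Gk, "E_k": Ek,
                  "S_k": (Ek - Gk) / T0}
    return DualThermo(ln_Z=ln_Z, G_star=G, E_expected=E, S_star=S,
                      Cp_star=Cp, per_gc=per_gc)


def fold_change(expected_energy: float, reference_energy: float) -> float:
    """<E(s)> / E(a0, s); undefined for a zero reference energy."""
    if reference_energy == 0:
        raise ZeroDivisionError("reference energy is zero; fold change undefined")
    return expected_energy / reference_energy
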