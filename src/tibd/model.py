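"""Core ODE system for the tumor-bone vicious cycle.

Six dynamical species: responding osteoblasts ``R``, active osteoblasts
``B``, active osteoclasts ``C`` (all pM), bone ``N`` (generic bone units),
tumor cells ``T`` (pM) and the bisphosphonate zoledronic acid ``Z``
(dimensionless ratio of the reference 0.1 mg/mouse dose).

The osteoblast/osteoclast regulatory core follows the classical Lemaire
bone-homeostasis model: receptor-occupancy fractions ``pi_C`` (TGF-beta),
``pi_P`` (PTH/PTHrP) and the RANK/RANKL/OPG function ``pi_L`` drive
differentiation and death of the bone-resident cell pools.  On top of that
core sit: an explicit bone variable with Hill-compensated formation and
resorption fluxes, logistic tumor growth enhanced by TGF-beta, tumor-derived
PTHrP secretion feeding back into ``pi_P``, tumor-induced loss of active
osteoblasts, and ZA-induced killing of active osteoclasts.

State is kept in pM internally; the data interface converts to fM
(1 pM = 1000 fM).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import warnings

import numpy as np
from numba import njit
from scipy.integrate import odeint

from .params import PARAM_NAMES, ModelParameters

__all__ = [
    "SPECIES",
    "SimulationError",
    "compute_pi_C",
    "compute_pi_P",
    "compute_pi_L",
    "effective_pthrp_injection",
    "per_cell_hill_rate",
    "bone_formation_flux",
    "bone_resorption_flux",
    "ode_rhs",
    "simulate",
]

#: state-vector ordering
SPECIES = ("R", "B", "C", "N", "T", "Z")

_EPS = 1e-12  # pM floor guarding X**(n-1) denominators for n > 1

# parameter-vector indices (compile-time constants for the numba kernel)
_iCs = PARAM_NAMES.index("Cs")
_iDA = PARAM_NAMES.index("DA")
_idB = PARAM_NAMES.index("dB")
_iDC = PARAM_NAMES.index("DC")
_iDR = PARAM_NAMES.index("DR")
_ifO = PARAM_NAMES.index("fO")
_iIL = PARAM_NAMES.index("IL")
_iIO = PARAM_NAMES.index("IO")
_iIP = PARAM_NAMES.index("IP")
_iK = PARAM_NAMES.index("K")
_ik1 = PARAM_NAMES.index("k1")
_ik2 = PARAM_NAMES.index("k2")
_ik3 = PARAM_NAMES.index("k3")
_ik4 = PARAM_NAMES.index("k4")
_ik5 = PARAM_NAMES.index("k5")
_ik6 = PARAM_NAMES.index("k6")
_ikB = PARAM_NAMES.index("kB")
_iKLP = PARAM_NAMES.index("KLP")
_ikO = PARAM_NAMES.index("kO")
_iKOP = PARAM_NAMES.index("KOP")
_ikP = PARAM_NAMES.index("kP")
_irL = PARAM_NAMES.index("rL")
_iSP = PARAM_NAMES.index("SP")
_ik1B = PARAM_NAMES.index("k1B")
_ik2B = PARAM_NAMES.index("k2B")
_inB = PARAM_NAMES.index("nB")
_ik1C = PARAM_NAMES.index("k1C")
_iK2C = PARAM_NAMES.index("K2C")
_inC = PARAM_NAMES.index("nC")
_ikTdiv = PARAM_NAMES.index("kTdiv")
_ikTtgfb = PARAM_NAMES.index("kTtgfb")
_ikTdth = PARAM_NAMES.index("kTdth")
_iM = PARAM_NAMES.index("M")
_ikTpthrp = PARAM_NAMES.index("kTpthrp")
_ikTB = PARAM_NAMES.index("kTB")
_ikZC = PARAM_NAMES.index("kZC")


@njit(cache=False)
def _rhs(t, y, p):  # pragma: no cover - exercised through ode_rhs/simulate
    # clip transient solver undershoots; tolerance-level negatives only
    R = y[0] if y[0] > 0.0 else 0.0
    B = y[1] if y[1] > 0.0 else 0.0
    C = y[2] if y[2] > 0.0 else 0.0
    N = y[3] if y[3] > 0.0 else 0.0
    T = y[4] if y[4] > 0.0 else 0.0
    Z = y[5] if y[5] > 0.0 else 0.0

    pi_C = (C + p[_ifO] * p[_iCs]) / (C + p[_iCs])
    if pi_C < 1e-12:
        pi_C = 1e-12
    I_P_eff = p[_iIP] + p[_ikTpthrp] * T * pi_C
    P = (I_P_eff + p[_iSP]) / p[_ikP]
    pi_P = P / (P + p[_ik6] / p[_ik5])
    if pi_P < 1e-12:  # guard underflow at extreme sampled rate ratios
        pi_P = 1e-12
    denom = 1.0 + p[_ik3] * p[_iK] / p[_ik4] + (
        p[_ik1] / (p[_ik2] * p[_ikO])
    ) * (p[_iKOP] * R / pi_P + p[_iIO])
    pi_L = (
        (p[_ik3] / p[_ik4]) * p[_iKLP] * pi_P * B * (1.0 + p[_iIL] / p[_irL]) / denom
    )

    # Hill-compensated total bone fluxes, algebraically regular at X = 0
    nB = p[_inB]
    if nB == 1.0:
        FB = p[_ik1B] * (B + p[_ik2B])
    else:
        Bf = B if B > _EPS else _EPS
        FB = p[_ik1B] * (B**nB + p[_ik2B] ** nB) / Bf ** (nB - 1.0)
    nC = p[_inC]
    if nC == 1.0:
        FC = p[_ik1C] * (C + p[_iK2C])
    else:
        Cf = C if C > _EPS else _EPS
        FC = p[_ik1C] * (C**nC + p[_iK2C] ** nC) / Cf ** (nC - 1.0)

    dy = np.empty(6)
    dy[0] = p[_iDR] * pi_C - p[_idB] * R / pi_C
    dy[1] = p[_idB] * R / pi_C - p[_ikB] * B - p[_ikTB] * T * B
    dy[2] = p[_iDC] * pi_L - p[_iDA] * pi_C * C - p[_ikZC] * Z * C
    dy[3] = FB - FC * N
    dy[4] = (p[_ikTdiv] + p[_ikTtgfb] * pi_C) * T * (1.0 - T / p[_iM]) - p[_ikTdth] * T
    dy[5] = 0.0
    return dy


class SimulationError(RuntimeError):
    """Integration failure; carries the last successfully reached time."""

    def __init__(self, message: str, last_time: float | None = None):
        super().__init__(message)
        self.last_time = last_time


# ---------------------------------------------------------------------------
# regulatory functions
# ---------------------------------------------------------------------------

def compute_pi_C(C, params: ModelParameters):
    """Fraction of TGF-beta receptors on OB progenitors bound to ligand.

    ``pi_C = (C + fO*Cs) / (C + Cs)``: rises from the basal occupancy
    ``fO`` at C = 0 to 1 at saturating osteoclast levels.  Because TGF-beta
    is not an explicit species, ``pi_C`` serves as the proxy for bone-derived
    TGF-beta throughout the model.
    """
    C = np.asarray(C, dtype=float)
    if np.any(C < 0):
        raise ValueError("osteoclast concentration C must be non-negative")
    out = (C + params.fO * params.Cs) / (C + params.Cs)
    return out.item() if out.ndim == 0 else out


def compute_pi_P(I_P_eff, params: ModelParameters):
    """PTH/PTHrP receptor occupancy ``pi_P = P / (P + k6/k5)``.

    ``P = (I_P_eff + SP) / kP`` is the quasi-steady hormone level set by
    systemic synthesis plus any (baseline or tumor-derived) injection rate.
    """
    I_P_eff = np.asarray(I_P_eff, dtype=float)
    if np.any(I_P_eff < 0):
        raise ValueError("effective PTH/PTHrP injection rate must be non-negative")
    P = (I_P_eff + params.SP) / params.kP
    out = P / (P + params.k6 / params.k5)
    return out.item() if out.ndim == 0 else out


def compute_pi_L(state, pi_P, params: ModelParameters):
    """RANK-RANKL occupancy function regulating osteoclast production.

    Proportional to the active-OB pool ``B`` (RANKL carrier) and damped by
    OPG production from the responding-OB pool ``R``.
    """
    R, B = float(state[0]), float(state[1])
    pi_P = float(pi_P)
    if pi_P == 0.0 and R > 0.0:
        raise ZeroDivisionError("pi_P = 0 with R > 0: OPG production term diverges")
    denom = 1.0 + params.k3 * params.K / params.k4
    if R > 0.0 or params.IO > 0.0:
        denom += (params.k1 / (params.k2 * params.kO)) * (
            (params.KOP * R / pi_P if R > 0.0 else 0.0) + params.IO
        )
    return (
        (params.k3 / params.k4)
        * params.KLP
        * pi_P
        * B
        * (1.0 + params.IL / params.rL)
        / denom
    )


def effective_pthrp_injection(T, pi_C, params: ModelParameters):
    """Effective PTH/PTHrP input: baseline plus tumor-derived PTHrP.

    ``I_P_eff = IP + kTpthrp * T * pi_C`` -- tumor cells secrete PTHrP at a
    rate enhanced by local TGF-beta (via ``pi_C``), closing the vicious
    cycle: resorption releases TGF-beta, which boosts PTHrP output, which
    drives further resorption.
    """
    T = np.asarray(T, dtype=float)
    pi_C = np.asarray(pi_C, dtype=float)
    if np.any(T < 0):
        raise ValueError("tumor burden T must be non-negative")
    if np.any((pi_C < 0) | (pi_C > 1)):
        raise ValueError("pi_C must lie in [0, 1]")
    out = params.IP + params.kTpthrp * T * pi_C
    return out.item() if out.ndim == 0 else out


def per_cell_hill_rate(X, k1, k2, n):
    """Per-cell Hill-compensated rate ``r = k1 * (k2**n + X**n) / X**n``.

    Encodes homeostatic compensation at the tissue scale: the per-cell
    bone-formation (or resorption) rate is bounded below by ``k1``, doubles
    when the population drops to ``k2``, and grows as the population
    shrinks further, so that changes in cell number do not translate
    linearly into changes of total flux.
    """
    X = np.asarray(X, dtype=float)
    if np.any(X <= 0):
        raise ValueError(
            "per-cell rate undefined at X = 0; use the total-flux form instead"
        )
    if k1 <= 0 or k2 <= 0:
        raise ValueError("k1 and k2 must be positive")
    if n < 1:
        raise ValueError("Hill coefficient n must be >= 1")
    out = k1 * (k2**n + X**n) / X**n
    return out.item() if out.ndim == 0 else out


def bone_formation_flux(B, params: ModelParameters):
    """Total bone-formation flux ``F_B(B) = k1B * (B**nB + k2B**nB) / B**(nB-1)``.

    Algebraically simplified so it stays finite at B = 0 (exactly, for the
    default nB = 1; a 1e-12 pM floor guards the nB > 1 case).
    """
    B = float(B)
    if B < 0:
        raise ValueError("B must be non-negative")
    if params.nB == 1.0:
        return params.k1B * (B + params.k2B)
    return params.k1B * (B**params.nB + params.k2B**params.nB) / max(B, _EPS) ** (
        params.nB - 1.0
    )


def bone_resorption_flux(C, params: ModelParameters):
    """Total per-bone-unit resorption flux ``F_C(C)``; resorption is F_C(C)*N."""
    C = float(C)
    if C < 0:
        raise ValueError("C must be non-negative")
    if params.nC == 1.0:
        return params.k1C * (C + params.K2C)
    return params.k1C * (C**params.nC + params.K2C**params.nC) / max(C, _EPS) ** (
        params.nC - 1.0
    )


# ---------------------------------------------------------------------------
# right-hand side and integration
# ---------------------------------------------------------------------------

def ode_rhs(t: float, state, params: ModelParameters) -> np.ndarray:
    """Time derivative of (R, B, C, N, T, Z) at ``state``.

    With T = Z = 0 and the bone equation ignored, the (R, B, C) subsystem
    reduces exactly to the Lemaire osteoblast/osteoclast model.
    """
    y = np.asarray(state, dtype=float)
    if y.shape != (6,):
        raise ValueError("state must have six components (R, B, C, N, T, Z)")
    if np.any(y < 0):
        raise ValueError("state components must be non-negative")
    dy = _rhs(float(t), y, params.as_array())
    if not np.all(np.isfinite(dy)):
        bad = [SPECIES[i] for i in np.where(~np.isfinite(dy))[0]]
        raise SimulationError(
            f"non-finite derivative for species {bad} at t={t} (state={y.tolist()})"
        )
    return dy


@dataclass(frozen=True)
class _EventTuple:
    time: float
    index: int
    amount: float


def _normalize_events(events, t0: float, t1: float):
    out = []
    for ev in events or ():
        if hasattr(ev, "time"):
            time, species, amount = float(ev.time), ev.species, float(ev.amount)
        else:
            time, species, amount = float(ev[0]), ev[1], float(ev[2])
        if species not in SPECIES:
            raise ValueError(f"unknown species {species!r}")
        if amount < 0:
            raise ValueError("event amounts must be non-negative")
        if not (t0 <= time <= t1):
            raise ValueError(f"event at t={time} outside simulation window [{t0}, {t1}]")
        out.append(_EventTuple(time, SPECIES.index(species), amount))
    if any(out[i].time > out[i + 1].time for i in range(len(out) - 1)):
        raise ValueError("events must be sorted by time")
    return out


def simulate(
    params: ModelParameters,
    initial,
    t_grid,
    events: Iterable = (),
    rtol: float = 1e-8,
    atol: float = 1e-10,
    max_steps: int = 100_000,
) -> np.ndarray:
    """Integrate the model over ``t_grid``, applying instantaneous injections.

    Uses the stiff-capable LSODA integrator with configurable tolerances;
    ``max_steps`` bounds the internal step count per segment so pathological
    parameter sets fail fast instead of stalling.  Events are additive state
    jumps applied in listed order (stop-inject-restart; the right-hand side
    itself is smooth).  At a grid time that coincides with an event, the
    recorded state is the post-injection one.  Returns an array of shape
    ``(len(t_grid), 6)``.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or t.size < 1:
        raise ValueError("t_grid must be a non-empty 1-D array")
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise ValueError("t_grid must be strictly increasing")
    y = np.asarray(initial, dtype=float).copy()
    if y.shape != (6,):
        raise ValueError("initial state must have six components")

    evs = _normalize_events(events, t[0], t[-1])
    pvec = params.as_array()
    out = np.empty((t.size, 6))
    out.fill(np.nan)

    # breakpoints where integration stops to inject
    ev_times = sorted({e.time for e in evs})

    cur_t = t[0]
    # fire events scheduled at the very start
    for e in evs:
        if e.time == cur_t:
            y[e.index] += e.amount
    if t[0] == cur_t:
        out[0] = y

    boundaries = [bt for bt in ev_times if bt > cur_t] + [t[-1]]
    seg_start = cur_t
    for seg_end in boundaries:
        if seg_end > seg_start:
            mask = (t > seg_start) & (t <= seg_end)
            t_eval = np.unique(np.concatenate([[seg_start], t[mask], [seg_end]]))
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")  # lsoda prints its own excess-work note
                    ys, info = odeint(
                        _rhs,
                        y,
                        t_eval,
                        args=(pvec,),
                        rtol=rtol,
                        atol=atol,
                        mxstep=max_steps,
                        tfirst=True,
                        full_output=True,
                    )
            except (ZeroDivisionError, OverflowError, FloatingPointError) as exc:
                raise SimulationError(
                    f"right-hand side overflowed: {exc}", last_time=seg_start
                ) from exc
            if info["message"] != "Integration successful.":
                reached = float(info["tcur"][-1]) if len(info.get("tcur", [])) else seg_start
                raise SimulationError(
                    f"solver failed: {info['message']}", last_time=reached
                )
            if not np.all(np.isfinite(ys)):
                raise SimulationError(
                    "solver produced non-finite values", last_time=seg_start
                )
            for i, tt in enumerate(t_eval):
                idx = np.searchsorted(t, tt)
                if idx < t.size and np.isclose(t[idx], tt, rtol=0, atol=1e-12):
                    out[idx] = ys[i]
            y = ys[-1].copy()
        # inject at this boundary (if it is an event time)
        for e in evs:
            if e.time == seg_end:
                y[e.index] += e.amount
        idx = np.searchsorted(t, seg_end)
        if idx < t.size and np.isclose(t[idx], seg_end, rtol=0, atol=1e-12):
            out[idx] = y
        seg_start = seg_end

    if np.any(np.isnan(out)):
        raise SimulationError("internal error: some grid times were not filled")
    return out


def lemaire_rhs(t: float, rbc, params: ModelParameters) -> np.ndarray:
    """Right-hand side of the tumor-free (R, B, C) subsystem.

    Convenience for steady-state analysis; equivalent to ``ode_rhs`` with
    T = Z = 0 and the bone equation dropped.
    """
    R, B, C = (float(v) for v in rbc)
    p = ModelParameters.as_dict(params)
    pi_C = compute_pi_C(max(C, 0.0), params)
    pi_P = compute_pi_P(params.IP, params)
    pi_L = compute_pi_L((max(R, 0.0), max(B, 0.0)), pi_P, params)
    dR = p["DR"] * pi_C - p["dB"] * R / pi_C
    dB = p["dB"] * R / pi_C - p["kB"] * B
    dC = p["DC"] * pi_L - p["DA"] * pi_C * C
    return np.array([dR, dB, dC])
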