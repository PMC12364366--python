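"""Hill-function machinery, activation updates and cytokine secretion.

Most rates in the model — recruitment, activation, secretion — are
built on the Hill form

    h(x) = (a*x)^n / ((a*x)^n + k),

with cooperative parameter ``a``, order ``n`` and scale factor ``k``.
Activation variables integrate a Hill drive damped by SOCS-like
inhibition ``1/(1 + socs/socs_infinity)`` minus a linear decay, floored
at zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cells import M1, M2, MINT, F0, F1

__all__ = [
    "HillSpec",
    "hill",
    "update_fibro_activation",
    "update_macrophage_activation",
    "secrete",
    "fibro_rates",
]


@dataclass
class HillSpec:
    """Hill-function parameters: cooperative a, order n, scale k."""

    a: float = 1.0
    n: float = 2.0
    k: float = 1.0

    def __post_init__(self):
        if self.a < 0:
            raise ValueError("Hill a must be >= 0")
        if self.n < 1:
            raise ValueError("Hill n must be >= 1")
        if self.k <= 0:
            raise ValueError("Hill k must be > 0")


def hill(x, spec: HillSpec | None = None, *, a: float = None,
         n: float = None, k: float = None):
    """Evaluate (a*x)^n / ((a*x)^n + k); accepts scalars or arrays."""
    if spec is None:
        spec = HillSpec(a if a is not None else 1.0,
                        n if n is not None else 2.0,
                        k if k is not None else 1.0)
    x = np.asarray(x, dtype=np.float64)
    if np.any(x < 0):
        raise ValueError("hill input must be >= 0")
    ax_n = (spec.a * x) ** spec.n
    out = ax_n / (ax_n + spec.k)
    return float(out) if out.ndim == 0 else out


def update_fibro_activation(f1_act, socs, local_aim, params):
    """One activation-variable update for fibro cells.

    F1act grows with a second-order Hill function of the local AIM
    (gain ``f1_act_scalar``, scale ``f1_act_hill_parameter``), is
    inhibited by SOCS via ``1/(1 + socs/f1_socs_infinity)`` and decays
    at ``f_negative_feedback_rate``.  Scalars or arrays.
    """
    drive = hill(local_aim, a=1.0, n=2.0, k=params.f1_act_hill_parameter)
    inhib = 1.0 / (1.0 + np.asarray(socs) / params.f1_socs_infinity)
    new = (np.asarray(f1_act)
           + params.f1_act_scalar * drive * inhib
           - params.f_negative_feedback_rate * np.asarray(f1_act))
    new = np.maximum(new, 0.0)
    return float(new) if new.ndim == 0 else new


def update_macrophage_activation(m1_act, m2_act, socs,
                                 local_pim, local_aim,
                                 mean_pim, mean_aim, params,
                                 fixed_pim_input=0.0):
    """One activation/SOCS update for macrophages.

    Mirrors the fibro template: M1act is driven by a second-order Hill
    function of the PIM input (local concentration plus the
    lattice-mean, weighted by ``global_mediator_weight``), M2act by the
    AIM input; both decay linearly.  SOCS — the lumped suppressor of
    the pro-inflammatory JAK/STAT arm — accrues with total activation,
    decays, and inhibits the M1 increment only; this asymmetry is what
    lets the response resolve from the M1-dominated acute phase to the
    M2/fibrotic chronic phase.  Returns the updated
    ``(m1_act, m2_act, socs)``.  Scalars or arrays.
    """
    mk = params.mac
    x1 = np.asarray(local_pim) + mk.global_pim_weight * mean_pim
    x2 = (np.asarray(local_aim) + mk.global_aim_weight * mean_aim
          + mk.fix_pim_m2_weight * np.asarray(fixed_pim_input))
    inhib = 1.0 / (1.0 + np.asarray(socs) / mk.m_socs_infinity)
    m1 = (np.asarray(m1_act)
          + mk.m1_act_scalar * hill(x1, a=1.0, n=2.0, k=mk.m1_hill_k) * inhib
          - mk.m_negative_feedback_rate * np.asarray(m1_act))
    m2 = (np.asarray(m2_act)
          + mk.m2_act_scalar * hill(x2, a=1.0, n=2.0, k=mk.m2_hill_k)
          - mk.m_negative_feedback_rate * np.asarray(m2_act))
    m1 = np.maximum(m1, 0.0)
    m2 = np.maximum(m2, 0.0)
    new_socs = np.maximum(
        np.asarray(socs) + mk.socs_scalar * (m1 + m2)
        - mk.socs_decay * np.asarray(socs), 0.0)
    if m1.ndim == 0:
        return float(m1), float(m2), float(new_socs)
    return m1, m2, new_socs


def fibro_rates(params, stimulus_mode: str = "default") -> tuple:
    """(PIM, AIM) per-step secretion rates for fibro cells."""
    if stimulus_mode == "pathological":
        return params.fibro_pim_rate_patho, params.fibro_aim_rate_patho
    if stimulus_mode != "default":
        raise ValueError(f"unknown stimulus mode {stimulus_mode!r}")
    return params.fibro_pim_rate, params.fibro_aim_rate


def secretion_arrays(phen: np.ndarray, m1_act: np.ndarray,
                     m2_act: np.ndarray, params,
                     stimulus_mode: str = "default"):
    """Vectorized per-cell (delta_pim, delta_aim) for one step.

    Fibro cells (F0 and F1 alike) emit at the fixed fibro rates; M1
    emits PIM and M2 emits AIM at a rate proportional to the
    corresponding activation; intermediate cells emit both at
    ``mint_rate_factor`` times those rates.  Naive M0 emits nothing.
    """
    f_pim, f_aim = fibro_rates(params, stimulus_mode)
    mk = params.mac
    d_pim = np.zeros(phen.shape, dtype=np.float64)
    d_aim = np.zeros(phen.shape, dtype=np.float64)
    is_f = (phen == F0) | (phen == F1)
    d_pim[is_f] = f_pim
    d_aim[is_f] = f_aim
    sel = phen == M1
    d_pim[sel] = mk.m1_pim_rate * m1_act[sel]
    d_aim[sel] = mk.m1_aim_rate * m1_act[sel]
    sel = phen == M2
    d_aim[sel] = mk.m2_aim_rate * m2_act[sel]
    sel = phen == MINT
    d_pim[sel] = mk.mint_rate_factor * mk.m1_pim_rate * m1_act[sel]
    d_aim[sel] = mk.mint_rate_factor * (mk.m2_aim_rate * m2_act[sel]
                                        + mk.m1_aim_rate * m1_act[sel])
    return d_pim, d_aim


def secrete(cell, params, stimulus_mode: str = "default") -> tuple:
    """(delta_pim, delta_aim) deposited at one cell's pixel this step."""
    phen_code = {"M0": 0, "M1": M1, "M2": M2, "Mint": MINT,
                 "F0": F0, "F1": F1}[cell.phenotype]
    d_pim, d_aim = secretion_arrays(
        np.array([phen_code], dtype=np.int8),
        np.array([cell.m1_act]), np.array([cell.m2_act]),
        params, stimulus_mode)
    return float(d_pim[0]), float(d_aim[0])
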