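"""Cell state: phenotypes, lifespans, aging and death.

Macrophages carry two activation variables (M1act, M2act) and a SOCS
inhibition variable; the phenotype is a threshold classification of the
activation pair.  Fibro cells carry a single activation variable F1act
that drives the fibrocyte (F0) to fibroblast (F1) transition.  Each
cell samples a lifespan at creation and again whenever its phenotype
class changes; it dies when its age reaches the sampled lifespan.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CellAgent",
    "PhenotypeCounts",
    "PHENOTYPES",
    "classify_macrophage",
    "classify_macrophage_array",
    "sample_lifespan",
    "sample_lifespans",
    "is_dead",
    "apply_phenotype_transitions",
    "lifespan_class",
]

#: phenotype codes used throughout the engine
M0, M1, M2, MINT, F0, F1 = 0, 1, 2, 3, 4, 5
PHENOTYPES = ("M0", "M1", "M2", "Mint", "F0", "F1")
MACROPHAGE, FIBRO = 0, 1


@dataclass
class CellAgent:
    """One cell (scalar API mirror of the engine's array storage)."""

    id: int
    species: str  # "macrophage" | "fibro"
    phenotype: str
    position: tuple
    age: float = 0.0  # hours
    lifespan: float = 24.0  # hours
    m1_act: float = 0.0
    m2_act: float = 0.0
    socs: float = 0.0
    f1_act: float = 0.0

    def __post_init__(self):
        if self.species == "fibro" and self.phenotype not in ("F0", "F1"):
            raise ValueError("fibro cells must be F0 or F1")
        if self.species == "macrophage" and self.phenotype not in (
                "M0", "M1", "M2", "Mint"):
            raise ValueError("macrophages must be M0/M1/M2/Mint")


@dataclass
class PhenotypeCounts:
    """Per-phenotype live-cell counts."""

    m0: int = 0
    m1: int = 0
    m2: int = 0
    mint: int = 0
    f0: int = 0
    f1: int = 0

    def total(self) -> int:
        return self.m0 + self.m1 + self.m2 + self.mint + self.f0 + self.f1

    def as_dict(self) -> dict:
        return {"M0": self.m0, "M1": self.m1, "M2": self.m2,
                "Mint": self.mint, "F0": self.f0, "F1": self.f1}


def classify_macrophage(m1_act: float, m2_act: float) -> str:
    """Threshold classification of a macrophage activation pair.

    M1 if M1act > 0.5 and M1act >= M2act; M2 if M2act > 0.5 and
    M2act > M1act; otherwise intermediate if M1act + M2act > 0.25,
    else naive M0.  When both exceed 0.5 the larger variable wins and
    an exact tie is intermediate.
    """
    if m1_act < 0 or m2_act < 0:
        raise ValueError("activation variables must be >= 0")
    if m1_act > 0.5 and m1_act > m2_act:
        return "M1"
    if m2_act > 0.5 and m2_act > m1_act:
        return "M2"
    if m1_act + m2_act > 0.25:
        return "Mint"
    return "M0"


def classify_macrophage_array(m1: np.ndarray, m2: np.ndarray) -> np.ndarray:
    """Vectorized phenotype codes for macrophage activation arrays."""
    if np.any(m1 < 0) or np.any(m2 < 0):
        raise ValueError("activation variables must be >= 0")
    out = np.full(m1.shape, M0, dtype=np.int8)
    out[(m1 + m2) > 0.25] = MINT
    out[(m1 > 0.5) & (m1 > m2)] = M1
    out[(m2 > 0.5) & (m2 > m1)] = M2
    return out


def lifespan_class(phenotype: str) -> str:
    """Lifespan class of a phenotype: naive, activated_mac or fibroblast."""
    if phenotype in ("M0", "F0"):
        return "naive"
    if phenotype in ("M1", "M2", "Mint"):
        return "activated_mac"
    if phenotype == "F1":
        return "fibroblast"
    raise ValueError(f"unknown phenotype {phenotype!r}")


def sample_lifespans(phenotype_class: str, n: int,
                     rng: np.random.Generator,
                     lifespans: dict | None = None,
                     law: str = "truncnorm") -> np.ndarray:
    """Sample ``n`` lifespans (hours) for one class.

    Default law is a normal(mean, sd) truncated at > 0 (negative draws
    are redrawn; with SD = mean/4 these are ~4 sigma events).  The
    ``"exponential"`` law with the same mean is available for parity
    with the earlier macrophage-only model.
    """
    from .params import LIFESPANS

    mean, sd = (lifespans or LIFESPANS)[phenotype_class]
    if law == "exponential":
        return rng.exponential(mean, size=n)
    if law != "truncnorm":
        raise ValueError(f"unknown lifespan law {law!r}")
    draws = rng.normal(mean, sd, size=n)
    while True:
        bad = draws <= 0
        if not bad.any():
            return draws
        draws[bad] = rng.normal(mean, sd, size=int(bad.sum()))


def sample_lifespan(phenotype_class: str, rng: np.random.Generator,
                    lifespans: dict | None = None,
                    law: str = "truncnorm") -> float:
    """Sample one lifespan in hours (see :func:`sample_lifespans`)."""
    return float(sample_lifespans(phenotype_class, 1, rng, lifespans, law)[0])


def is_dead(cell: CellAgent) -> bool:
    """True iff the cell's age has reached its sampled lifespan."""
    return cell.age >= cell.lifespan


def apply_phenotype_transitions(cell: CellAgent, params,
                                rng: np.random.Generator) -> CellAgent:
    """Re-classify one cell and re-sample its lifespan on a change.

    Macrophages follow the activation-threshold rule; a fibrocyte
    becomes a fibroblast when F1act exceeds the activation threshold
    (0.5 by default).  Differentiation to F1 is latched unless
    ``params.f1_reversible`` is set.  Age keeps accumulating across a
    phenotype change; only the lifespan is re-drawn for the new class.
    """
    if cell.species == "macrophage":
        new = classify_macrophage(cell.m1_act, cell.m2_act)
    else:
        if cell.phenotype == "F1":
            new = ("F0" if params.f1_reversible
                   and cell.f1_act <= params.f1_act_threshold else "F1")
        else:
            new = "F1" if cell.f1_act > params.f1_act_threshold else "F0"
    if new != cell.phenotype:
        old_class = lifespan_class(cell.phenotype)
        new_class = lifespan_class(new)
        cell.phenotype = new
        if new_class != old_class:
            cell.lifespan = sample_lifespan(
                new_class, rng, params.lifespan_mean_sd, params.lifespan_law)
    return cell
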