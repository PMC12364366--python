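"""Simulation engine: one tick, full runs and seeded ensembles.

A step executes the pinned sub-step order: (1) death sweep,
(2) movement of every live cell in randomized order, (3) activation
updates from the current local/global mediator levels, (4) phenotype
transitions with lifespan re-sampling, (5) secretion into the fields
and the cumulative counters, (6) mediator diffusion and decay,
(7) recruitment, (8) aging and trace recording.

Cells are stored struct-of-arrays for speed; the movement loop runs in
a compiled kernel fed with pre-generated uniforms so that a run is a
pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np
import pandas as pd

from . import cells as C
from ._kernels import move_all
from .fields import (DiffusionKernel, MediatorField, diffusion_kernel,
                     diffuse_array, make_stimulus, _blocked_counts)
from .kinetics import secretion_arrays, update_fibro_activation, \
    update_macrophage_activation
from .motility import (border_mask, crown_annulus,
                       recruit_probability_fibro,
                       recruit_probability_macrophage)
from .params import ScenarioConfig, validate

__all__ = ["SimulationState", "SimulationTrace", "step", "run",
           "run_ensemble", "EnsembleResult"]

TRACE_COLUMNS = ("step", "hours", "M0", "M1", "M2", "Mint", "F0", "F1",
                 "total_cells", "pim_total", "aim_total",
                 "cum_pim", "cum_aim", "n_c")

#: uniform 3x3 spreading kernel for secretion deposits
_FOOTPRINT_KERNEL = DiffusionKernel(neighbor_p=1.0 / 9.0,
                                    center_p=1.0 / 9.0, D=0.0,
                                    tau=0.0, dx=0.0)

#: lifespan-class code per phenotype code (naive / activated / fibroblast)
_CLASS_OF_PHEN = np.array([0, 1, 1, 1, 0, 2], dtype=np.int8)
_CLASS_NAMES = ("naive", "activated_mac", "fibroblast")


@dataclass
class SimulationState:
    """Full mutable state of one run."""

    config: ScenarioConfig
    step_index: int = 0
    clock_h: float = 0.0
    pim: np.ndarray = None  # diffusible PIM (stimulus + secreted)
    aim: np.ndarray = None
    fixed_pim: np.ndarray = None  # frozen biomaterial PIM
    bio_mask: Optional[np.ndarray] = None
    # cell arrays (struct-of-arrays)
    species: np.ndarray = None
    phen: np.ndarray = None
    xs: np.ndarray = None
    ys: np.ndarray = None
    age: np.ndarray = None
    lifespan: np.ndarray = None
    m1: np.ndarray = None
    m2: np.ndarray = None
    socs: np.ndarray = None
    f1: np.ndarray = None
    occ: np.ndarray = None
    cum_pim: float = 0.0
    cum_aim: float = 0.0
    n_c: int = 0

    @property
    def n_cells(self) -> int:
        return int(self.xs.shape[0])

    def counts(self) -> C.PhenotypeCounts:
        b = np.bincount(self.phen, minlength=6)
        return C.PhenotypeCounts(*map(int, b[:6]))

    def rebuild_occupancy(self) -> None:
        self.occ.fill(-1)
        self.occ[self.xs, self.ys] = np.arange(self.n_cells)

    def check_invariants(self) -> None:
        n_occ = int((self.occ >= 0).sum())
        if n_occ != self.n_cells:
            raise AssertionError(
                f"step {self.step_index}: occupancy holds {n_occ} cells, "
                f"registry holds {self.n_cells}")
        if self.n_cells and not np.array_equal(
                self.occ[self.xs, self.ys], np.arange(self.n_cells)):
            raise AssertionError(
                f"step {self.step_index}: occupancy/registry mismatch")


@dataclass
class SimulationTrace:
    """Per-step record of one run (one row per executed step)."""

    data: pd.DataFrame
    final_state: Optional[SimulationState] = None
    frames: list = dc_field(default_factory=list)

    @property
    def n_steps(self) -> int:
        return len(self.data)


class _Rngs:
    """Named child streams derived from one run seed."""

    def __init__(self, seed):
        ss = np.random.SeedSequence(seed)
        (self.init, self.movement, self.lifespans,
         self.recruitment, self.activation) = (
            np.random.default_rng(s) for s in ss.spawn(5))


def _subtract(arrays, keep):
    return [a[keep] for a in arrays]


def init_state(config: ScenarioConfig, rngs: _Rngs) -> SimulationState:
    p = config.params
    n = p.grid_n
    st = SimulationState(config=config)
    st.pim = np.zeros((n, n))
    st.aim = np.zeros((n, n))
    st.fixed_pim = np.zeros((n, n))
    if config.pim_stimulus is not None:
        f, mask = make_stimulus(config.pim_stimulus, n, "PIM")
        if mask is not None:
            st.fixed_pim = f.grid
            st.bio_mask = mask
        else:
            st.pim = f.grid
    if config.aim_stimulus is not None:
        f, mask = make_stimulus(config.aim_stimulus, n, "AIM")
        if mask is not None:
            raise ValueError("AIM stimulus cannot be mechanical")
        st.aim = f.grid
    m = config.n_resident_m0
    flat = rngs.init.choice(n * n, size=m, replace=False)
    st.xs = (flat // n).astype(np.int64)
    st.ys = (flat % n).astype(np.int64)
    st.species = np.zeros(m, dtype=np.int8)
    st.phen = np.full(m, C.M0, dtype=np.int8)
    st.age = np.zeros(m)
    st.lifespan = C.sample_lifespans("naive", m, rngs.lifespans,
                                     p.lifespan_mean_sd, p.lifespan_law)
    st.m1 = np.zeros(m)
    st.m2 = np.zeros(m)
    st.socs = np.zeros(m)
    st.f1 = np.zeros(m)
    st.occ = np.full((n, n), -1, dtype=np.int64)
    st.rebuild_occupancy()
    return st


def _add_cells(st: SimulationState, pixels, species, phen, lifespans,
               f1_act=0.0):
    k = len(pixels)
    if k == 0:
        return
    xs = np.array([px[0] for px in pixels], dtype=np.int64)
    ys = np.array([px[1] for px in pixels], dtype=np.int64)
    base = st.n_cells
    st.xs = np.concatenate([st.xs, xs])
    st.ys = np.concatenate([st.ys, ys])
    st.species = np.concatenate(
        [st.species, np.full(k, species, dtype=np.int8)])
    st.phen = np.concatenate([st.phen, np.full(k, phen, dtype=np.int8)])
    st.age = np.concatenate([st.age, np.zeros(k)])
    st.lifespan = np.concatenate([st.lifespan, lifespans])
    st.m1 = np.concatenate([st.m1, np.zeros(k)])
    st.m2 = np.concatenate([st.m2, np.zeros(k)])
    st.socs = np.concatenate([st.socs, np.zeros(k)])
    st.f1 = np.concatenate([st.f1, np.full(k, float(f1_act))])
    st.occ[xs, ys] = base + np.arange(k)


class _StepContext:
    """Per-run cached quantities (kernels, masks, placement regions)."""

    def __init__(self, config: ScenarioConfig):
        p = config.params
        self.kernel_pim = diffusion_kernel(p.D_pim, p.tau, p.dx)
        self.kernel_aim = diffusion_kernel(p.D_aim, p.tau, p.dx)
        self.decay_pim = p.pim_decay_fraction()
        self.decay_aim = p.aim_decay_fraction()
        self.blocked = _blocked_counts(p.grid_n, None)
        extent = 13
        for stim in (config.pim_stimulus, config.aim_stimulus):
            if stim is not None:
                extent = stim.extent
                break
        if config.recruitment_placement == "crown":
            self.placement_region = crown_annulus(
                p.grid_n, extent, p.crown_margin, p.crown_width)
        elif config.recruitment_placement == "border":
            self.placement_region = border_mask(p.grid_n)
        else:
            self.placement_region = np.ones((p.grid_n, p.grid_n),
                                            dtype=bool)
        self.recruit_mode = ("biomaterial" if config.biomaterial_mode
                             else "pathological")


def _recruit(st: SimulationState, ctx: _StepContext, rngs: _Rngs) -> None:
    p = st.config.params
    region_flat = np.flatnonzero(ctx.placement_region.ravel())
    n = p.grid_n
    total_pim = float(st.pim.sum())
    total_fixed_pim = float(st.fixed_pim.sum())
    new_m0, new_f0, new_f1 = [], [], []
    # no species has priority for scarce placement pixels: the three
    # per-step attempts draw in a random order
    fibro_att = (p.recruit_attempts if p.recruit_attempts_fibro is None
                 else p.recruit_attempts_fibro)

    def n_attempts(rate: float) -> int:
        # fractional rates are expected attempts per step
        base = int(rate)
        if rngs.recruitment.random() < rate - base:
            base += 1
        return base

    attempts = ([("M0", new_m0)] * n_attempts(p.recruit_attempts)
                + [("F0", new_f0)] * n_attempts(fibro_att)
                + [("F1", new_f1)] * n_attempts(fibro_att))
    for ai in rngs.recruitment.permutation(len(attempts)):
        kind, species_bucket = attempts[ai]
        for _ in range(1):
            empty = region_flat[st.occ.ravel()[region_flat] == -1]
            if empty.size == 0:
                continue
            flat = int(empty[int(rngs.recruitment.random() * empty.size)])
            px = (flat // n, flat % n)
            local_aim = float(st.aim[px])
            if kind == "M0":
                prob = recruit_probability_macrophage(
                    total_pim, local_aim, p, ctx.recruit_mode,
                    total_fixed_pim)
            else:
                prob = recruit_probability_fibro(
                    float(st.pim[px]), local_aim, p, ctx.recruit_mode,
                    float(st.fixed_pim[px]))
            if rngs.recruitment.random() < prob:
                species_bucket.append(px)
                st.occ[px] = -2  # reserve until the batch insert below
    for px_list in (new_m0, new_f0, new_f1):
        for px in px_list:
            st.occ[px] = -1
    if new_m0:
        ls = C.sample_lifespans("naive", len(new_m0), rngs.lifespans,
                                p.lifespan_mean_sd, p.lifespan_law)
        _add_cells(st, new_m0, C.MACROPHAGE, C.M0, ls)
    if new_f0:
        ls = C.sample_lifespans("naive", len(new_f0), rngs.lifespans,
                                p.lifespan_mean_sd, p.lifespan_law)
        _add_cells(st, new_f0, C.FIBRO, C.F0, ls)
    if new_f1:
        ls = C.sample_lifespans("fibroblast", len(new_f1), rngs.lifespans,
                                p.lifespan_mean_sd, p.lifespan_law)
        _add_cells(st, new_f1, C.FIBRO, C.F1, ls, f1_act=p.recruited_f1_act)


def step(st: SimulationState, rngs: _Rngs, ctx: Optional[_StepContext] = None,
         debug: bool = False) -> SimulationState:
    """Advance the state by one tick of duration tau (in place)."""
    config = st.config
    p = config.params
    if ctx is None:
        ctx = _StepContext(config)

    # (1) death sweep: age >= lifespan; pixels free immediately
    keep = st.age < st.lifespan
    if not keep.all():
        (st.species, st.phen, st.xs, st.ys, st.age, st.lifespan,
         st.m1, st.m2, st.socs, st.f1) = _subtract(
            [st.species, st.phen, st.xs, st.ys, st.age, st.lifespan,
             st.m1, st.m2, st.socs, st.f1], keep)
        st.rebuild_occupancy()
    nc = st.n_cells

    # (2) movement in randomized order
    if nc:
        order = rngs.movement.permutation(nc)
        u_chemo = rngs.movement.random(nc)
        u_dir = rngs.movement.random(nc)
        moved_c, _ = move_all(order, st.xs, st.ys, st.occ, st.pim,
                              p.k_chemo, u_chemo, u_dir)
        st.n_c += int(moved_c)

    # (3) activation updates from current mediator levels
    if nc:
        local_pim = st.pim[st.xs, st.ys] + st.fixed_pim[st.xs, st.ys]
        local_aim = st.aim[st.xs, st.ys]
        # the frozen implant PIM is part of the lattice-global input:
        # the biomaterial triggers secretion everywhere, not only in
        # cells sitting on it
        mean_pim = float(st.pim.mean() + st.fixed_pim.mean())
        mean_aim = float(st.aim.mean())
        mac = st.species == C.MACROPHAGE
        if mac.any():
            fixed_in = (st.fixed_pim[st.xs, st.ys]
                        + st.fixed_pim.mean())
            m1n, m2n, socsn = update_macrophage_activation(
                st.m1[mac], st.m2[mac], st.socs[mac],
                local_pim[mac], local_aim[mac], mean_pim, mean_aim, p,
                fixed_pim_input=fixed_in[mac])
            kick = (rngs.activation.random(int(mac.sum()))
                    < p.mac.spont_act_prob)
            m1n = m1n + p.mac.spont_kick_m1 * kick
            m2n = m2n + p.mac.spont_kick_m2 * kick
            st.m1[mac], st.m2[mac], st.socs[mac] = m1n, m2n, socsn
        fib = ~mac
        if fib.any():
            st.f1[fib] = update_fibro_activation(
                st.f1[fib], st.socs[fib], local_aim[fib], p)
            st.socs[fib] = np.maximum(
                st.socs[fib] + p.mac.socs_scalar * st.f1[fib]
                - p.mac.socs_decay * st.socs[fib], 0.0)

    # (4) phenotype transitions + lifespan re-sampling
    if nc:
        old_phen = st.phen
        new_phen = old_phen.copy()
        mac = st.species == C.MACROPHAGE
        new_phen[mac] = C.classify_macrophage_array(st.m1[mac], st.m2[mac])
        fib = ~mac
        to_f1 = fib & (st.f1 > p.f1_act_threshold)
        new_phen[to_f1] = C.F1
        if p.f1_reversible:
            back = fib & (old_phen == C.F1) & (st.f1 <= p.f1_act_threshold)
            new_phen[back] = C.F0
        changed = _CLASS_OF_PHEN[new_phen] != _CLASS_OF_PHEN[old_phen]
        if changed.any():
            for code, cname in enumerate(_CLASS_NAMES):
                sel = changed & (_CLASS_OF_PHEN[new_phen] == code)
                ns = int(sel.sum())
                if ns:
                    st.lifespan[sel] = C.sample_lifespans(
                        cname, ns, rngs.lifespans, p.lifespan_mean_sd,
                        p.lifespan_law)
        st.phen = new_phen

    # (5) secretion into the fields and cumulative counters; a cell is
    # one pixel wide and secretes around its whole membrane, so each
    # deposit is spread over the cell's 3x3 footprint (reflecting at
    # the grid edge)
    if nc:
        d_pim, d_aim = secretion_arrays(st.phen, st.m1, st.m2, p,
                                        config.secretion_mode)
        dep_pim = np.zeros_like(st.pim)
        dep_aim = np.zeros_like(st.aim)
        np.add.at(dep_pim, (st.xs, st.ys), d_pim)
        np.add.at(dep_aim, (st.xs, st.ys), d_aim)
        st.pim += diffuse_array(dep_pim, _FOOTPRINT_KERNEL, 0.0,
                                blocked=ctx.blocked, boundary=p.boundary)
        st.aim += diffuse_array(dep_aim, _FOOTPRINT_KERNEL, 0.0,
                                blocked=ctx.blocked, boundary=p.boundary)
        st.cum_pim += float(d_pim.sum())
        st.cum_aim += float(d_aim.sum())

    # (6) mediator diffusion + decay (the frozen biomaterial field is
    # separate and is never stepped)
    st.pim = diffuse_array(st.pim, ctx.kernel_pim, ctx.decay_pim,
                           blocked=ctx.blocked, boundary=p.boundary)
    st.aim = diffuse_array(st.aim, ctx.kernel_aim, ctx.decay_aim,
                           blocked=ctx.blocked, boundary=p.boundary)

    # (7) recruitment
    if config.recruitment_enabled:
        _recruit(st, ctx, rngs)

    # (8) aging, clock, bookkeeping
    st.age = st.age + p.tau / 60.0
    st.step_index += 1
    st.clock_h = st.step_index * p.tau / 60.0
    if debug:
        st.check_invariants()
    return st


def _trace_row(st: SimulationState) -> tuple:
    c = st.counts()
    return (st.step_index, st.clock_h, c.m0, c.m1, c.m2, c.mint, c.f0,
            c.f1, c.total(), float(st.pim.sum()), float(st.aim.sum()),
            st.cum_pim, st.cum_aim, st.n_c)


def run(config: ScenarioConfig, seed: int, debug: bool = False,
        keep_final_state: bool = True) -> SimulationTrace:
    """Run one simulation; returns the per-step trace.

    The duration is ``ceil(duration_h * 60 / tau)`` steps.  Identical
    (config, seed) pairs produce bit-identical traces.
    """
    problems = validate(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    rngs = _Rngs(seed)
    st = init_state(config, rngs)
    ctx = _StepContext(config)
    n_steps = config.params.steps_for_hours(config.duration_h)
    rows = []
    frames = []
    for _ in range(n_steps):
        step(st, rngs, ctx, debug=debug)
        rows.append(_trace_row(st))
        if config.frame_stride and st.step_index % config.frame_stride == 0:
            frames.append(_snapshot(st))
    if not config.frame_stride:
        frames.append(_snapshot(st))
    data = pd.DataFrame(rows, columns=TRACE_COLUMNS)
    return SimulationTrace(data=data,
                           final_state=st if keep_final_state else None,
                           frames=frames)


def _snapshot(st: SimulationState) -> dict:
    phen_grid = np.full(st.occ.shape, -1, dtype=np.int8)
    if st.n_cells:
        phen_grid[st.xs, st.ys] = st.phen
    return {"step": st.step_index, "pim": st.pim.copy(),
            "aim": st.aim.copy(), "phenotypes": phen_grid}


@dataclass
class EnsembleResult:
    traces: list
    mean: pd.DataFrame
    sd: pd.DataFrame


def ensemble_seeds(base_seed: int, n_runs: int) -> list:
    """Deterministic, independent per-run seeds from one base seed."""
    return [np.random.SeedSequence([int(base_seed), i]).generate_state(1)[0]
            % (2 ** 31) for i in range(n_runs)]


def run_ensemble(config: ScenarioConfig, n_runs: Optional[int] = None,
                 base_seed: int = 0,
                 keep_final_state: bool = False) -> EnsembleResult:
    """Run an ensemble; aggregate mean/SD per step per trace column."""
    if n_runs is None:
        n_runs = config.n_runs
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    traces = [run(config, s, keep_final_state=keep_final_state)
              for s in ensemble_seeds(base_seed, n_runs)]
    stack = np.stack([t.data.to_numpy(dtype=np.float64) for t in traces])
    mean = pd.DataFrame(stack.mean(axis=0), columns=TRACE_COLUMNS)
    sd = pd.DataFrame(stack.std(axis=0, ddof=1) if n_runs > 1
                      else np.zeros_like(stack[0]), columns=TRACE_COLUMNS)
    return EnsembleResult(traces=traces, mean=mean, sd=sd)
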