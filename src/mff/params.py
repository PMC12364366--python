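"""Model parameters and scenario definitions.

The model describes two interacting cell populations on a 2-D lattice —
macrophages (naive M0, pro-inflammatory M1, pro-healing M2 and an
intermediate state) and fibro cells (fibrocytes F0 and activated
fibroblasts F1) — coupled through two dimensionless mediator fields, a
pro-inflammatory mediator (PIM, a TNF-alpha-like lump) and an
anti-inflammatory mediator (AIM, a TGF-beta/IL-10-like lump).

``ModelParams`` collects every rate and physical constant.  The
fibro-side parameters have published defaults; the macrophage-side
activation/secretion/SOCS constants are inherited from an earlier
macrophage-only lattice model whose values are not reproduced here, so
they live in the :class:`MacKinetics` sub-registry with calibrated,
fully overridable defaults (see docs/methods.md for the calibration
rationale).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Optional

import yaml

from .fields import StimulusSpec

__all__ = [
    "MacKinetics",
    "ModelParams",
    "ScenarioConfig",
    "builtin_scenario",
    "validate",
    "BUILTIN_SCENARIOS",
    "config_to_yaml",
    "config_from_yaml",
]


@dataclass
class MacKinetics:
    """Macrophage-side activation, secretion and SOCS constants.

    These mirror the fibro-side template: activation variables are
    driven by a second-order Hill function of the mediator input
    (local + lattice-mean), damped by a SOCS-like inhibition variable
    ``1/(1 + socs/socs_infinity)`` and by linear decay.  Defaults are
    calibrated so that the simulator reproduces the published secretion
    magnitudes; every field can be overridden from a scenario config.
    """

    #: per-step gain on M1 activation from the PIM Hill term
    m1_act_scalar: float = 0.065
    #: per-step gain on M2 activation from the AIM Hill term
    m2_act_scalar: float = 0.065
    #: Hill scale factor k for the M1 (PIM) input
    m1_hill_k: float = 0.85
    #: Hill scale factor k for the M2 (AIM) input
    m2_hill_k: float = 0.85
    #: linear decay rate of M1/M2 activation per step
    m_negative_feedback_rate: float = 0.01
    #: SOCS level at which inhibition halves the activation increment
    m_socs_infinity: float = 7.0
    #: per-step SOCS accrual per unit of summed activation
    socs_scalar: float = 0.05
    #: per-step linear SOCS decay
    socs_decay: float = 0.01
    #: weights of the lattice-mean mediator terms added to the local
    #: ones; the TNF-like PIM acts mostly at short range, the
    #: TGF-beta/IL-10-like AIM is more systemic
    global_pim_weight: float = 0.2
    global_aim_weight: float = 1.0
    #: PIM secreted per step by an M1 cell, per unit M1 activation
    m1_pim_rate: float = 0.05
    #: AIM secreted per step by an M2 cell, per unit M2 activation
    m2_aim_rate: float = 0.022
    #: AIM secreted per step by an M1 cell, per unit M1 activation
    #: (the IL-10-like self-limiting brake of the pro-inflammatory arm;
    #: the cross-talk that raises AIM secretion under a PIM stimulus)
    m1_aim_rate: float = 0.006
    #: intermediate cells secrete both mediators at this fraction of
    #: the M1/M2 rates (scaled by the respective activation)
    mint_rate_factor: float = 0.5
    #: per-cell per-step probability of a spontaneous activation kick
    #: (background, stimulus-independent low-level activation)
    spont_act_prob: float = 0.007
    #: size of the spontaneous kick on M1 activation
    spont_kick_m1: float = 0.24
    #: size of the spontaneous kick on M2 activation
    spont_kick_m2: float = 0.37
    #: intrinsic mediator lifetimes, minutes; per-step decay fraction
    #: is 1 - exp(-tau/lifetime)
    pim_lifetime: float = 570.0
    aim_lifetime: float = 600.0
    #: Hill cooperative parameter a for macrophage recruitment driven
    #: by the total pathological PIM over the lattice
    patho_pim_recruit_scale_m: float = 0.01
    #: weight with which the frozen implant PIM also drives the M2 arm
    #: (a foreign body triggers secretion of both mediator classes)
    fix_pim_m2_weight: float = 0.5


#: lifespan classes: mean and SD in hours
LIFESPANS = {
    "naive": (24.0, 6.0),
    "activated_mac": (48.0, 12.0),
    "fibroblast": (336.0, 84.0),
}


@dataclass
class ModelParams:
    """Full parameter registry (published table + physical constants)."""

    #: time-step duration, minutes
    tau: float = 20.0
    #: pixel size, micrometres
    dx: float = 10.0
    #: lattice side, pixels
    grid_n: int = 40
    #: mediator diffusion coefficients, um^2/min
    D_pim: float = 900.0
    D_aim: float = 780.0
    #: chemotaxis proportionality constant (dimensionless)
    k_chemo: float = 0.5
    #: PIM units per ug/mL of LPS
    pim_per_lps: float = 30.0
    #: fibro secretion rates per step (default configuration)
    fibro_aim_rate: float = 0.85
    fibro_pim_rate: float = 0.35
    #: fibro secretion rates under pathological stimulus
    fibro_aim_rate_patho: float = 0.60
    fibro_pim_rate_patho: float = 0.55
    #: linear decay of the fibro activation variable F1act
    f_negative_feedback_rate: float = 0.003
    #: Hill scale factors k for fibro / macrophage recruitment
    recruitment_ff_term: float = 30.0
    recruitment_mm_term: float = 30.0
    #: fibro activation gain, Hill k and SOCS half-inhibition level
    f1_act_scalar: float = 0.065
    f1_act_hill_parameter: float = 0.85
    f1_socs_infinity: float = 7.0
    #: Hill cooperative parameters a for recruitment
    patho_pim_recruit_scale_f: float = 0.5
    fix_pim_recruit_scale_f: float = 0.2
    fix_pim_recruit_scale_m: float = 0.7
    aim_recruit_scale_f: float = 1.0
    aim_recruit_scale_m: float = 1.0
    #: lifespan (mean, sd) hours per class
    lifespan_mean_sd: dict = field(default_factory=lambda: dict(LIFESPANS))
    #: lifespan law: truncated normal (default) or exponential(mean)
    lifespan_law: str = "truncnorm"
    #: field boundary: reflecting (mass-conserving) or absorbing
    boundary: str = "reflecting"
    #: f1_act threshold for the F0 -> F1 transition
    f1_act_threshold: float = 0.5
    #: whether an F1 cell may revert to F0 when f1_act decays below
    #: threshold (default: differentiation is latched)
    f1_reversible: bool = False
    #: initial f1_act given to a recruited F1 cell
    recruited_f1_act: float = 0.6
    #: recruitment attempts per step for naive macrophages (M0);
    #: fractional values are expected attempts (drawn per step)
    recruit_attempts: float = 1.0
    #: recruitment attempts per step for each fibro class (F0, F1);
    #: None = same as recruit_attempts
    recruit_attempts_fibro: Optional[float] = None
    #: crown placement annulus: inner margin (pixels beyond the
    #: stimulus half-width) and width
    crown_margin: float = 1.0
    crown_width: float = 2.0
    #: whether cells may occupy biomaterial pixels (no excluded volume
    #: between cells and the implant)
    cells_on_biomaterial: bool = True
    #: macrophage-side sub-registry
    mac: MacKinetics = field(default_factory=MacKinetics)

    # ---- derived quantities -------------------------------------
    def pim_decay_fraction(self) -> float:
        """Per-step PIM decay fraction, 1 - exp(-tau/lifetime)."""
        return 1.0 - math.exp(-self.tau / self.mac.pim_lifetime)

    def aim_decay_fraction(self) -> float:
        """Per-step AIM decay fraction."""
        return 1.0 - math.exp(-self.tau / self.mac.aim_lifetime)

    def steps_for_hours(self, hours: float) -> int:
        return int(math.ceil(hours * 60.0 / self.tau))


@dataclass
class ScenarioConfig:
    """A complete, runnable scenario definition."""

    name: str = "custom"
    #: PIM stimulus (chemical block / chemical Gaussian peak /
    #: mechanical square / none)
    pim_stimulus: Optional[StimulusSpec] = None
    #: initial AIM field specification
    aim_stimulus: Optional[StimulusSpec] = None
    #: number of resident naive macrophages at t=0
    n_resident_m0: int = 0
    #: simulated duration, hours
    duration_h: float = 120.0
    #: ensemble size
    n_runs: int = 1
    #: where recruited cells appear: any empty grid pixel (uniform),
    #: the grid border, or a circular crown just outside the stimulus
    recruitment_placement: str = "uniform"
    #: master switch for recruitment (off for in-vitro emulation)
    recruitment_enabled: bool = True
    #: fibro secretion mode: "default" or "pathological"
    secretion_mode: str = "default"
    #: recruitment Hill terms include the fixed (biomaterial) PIM
    biomaterial_mode: bool = False
    #: save per-step field/cell frames every `frame_stride` steps
    #: (0 = last frame only)
    frame_stride: int = 0
    params: ModelParams = field(default_factory=ModelParams)


def _patho_params(**over) -> ModelParams:
    p = ModelParams(**over)
    p.fibro_pim_rate = p.fibro_pim_rate_patho
    p.fibro_aim_rate = p.fibro_aim_rate_patho
    return p


def _gauss(peak: float, sigma: float = 2.0, extent: int = 13) -> StimulusSpec:
    return StimulusSpec(mode="chemical", amplitude=peak, extent=extent,
                        shape="peak", sigma=sigma)


def _block(amp: float, extent: int = 13, smooth: float = 2.0) -> StimulusSpec:
    return StimulusSpec(mode="chemical", amplitude=amp, extent=extent,
                        shape="block", smooth_sigma=smooth)


def _mech(amp: float, extent: int, smooth: float = 2.0) -> StimulusSpec:
    return StimulusSpec(mode="mechanical", amplitude=amp, extent=extent,
                        smooth_sigma=smooth)


def _scenario_params(**over) -> ModelParams:
    # the four exploration scenarios emulate an in-vivo tissue with a
    # full vascular supply: more recruitment attempts per step than the
    # in-vitro-like validation protocols
    p = ModelParams(**over)
    p.recruit_attempts_fibro = 3
    return p


def _make_builtin(name: str) -> ScenarioConfig:
    if name == "1A":
        return ScenarioConfig(name=name, pim_stimulus=_block(30.0),
                              n_resident_m0=0, duration_h=120.0,
                              params=_scenario_params())
    if name == "1B":
        return ScenarioConfig(name=name, pim_stimulus=_block(30.0),
                              n_resident_m0=400, duration_h=120.0,
                              params=_scenario_params())
    if name == "2A":
        return ScenarioConfig(name=name, pim_stimulus=_mech(2.0, 13),
                              n_resident_m0=0, duration_h=120.0,
                              biomaterial_mode=True,
                              params=_scenario_params(
                                  recruitment_ff_term=3.0,
                                  recruitment_mm_term=3.0))
    if name == "2B":
        return ScenarioConfig(name=name, pim_stimulus=_mech(2.0, 13),
                              n_resident_m0=400, duration_h=120.0,
                              biomaterial_mode=True,
                              params=_scenario_params(
                                  recruitment_ff_term=3.0,
                                  recruitment_mm_term=3.0))
    if name == "validation_patho":
        return ScenarioConfig(name=name, pim_stimulus=_gauss(1500.0),
                              aim_stimulus=_gauss(58.9),
                              n_resident_m0=1280, duration_h=144.0,
                              n_runs=25, recruitment_placement="crown",
                              secretion_mode="pathological",
                              params=_patho_params())
    if name == "validation_patho_pim":
        return ScenarioConfig(name=name, pim_stimulus=_gauss(1500.0),
                              n_resident_m0=1280, duration_h=144.0,
                              n_runs=25, recruitment_placement="crown",
                              secretion_mode="pathological",
                              params=_patho_params())
    if name == "validation_patho_aim":
        return ScenarioConfig(name=name, aim_stimulus=_gauss(58.9),
                              n_resident_m0=1280, duration_h=144.0,
                              n_runs=25, recruitment_placement="crown",
                              secretion_mode="pathological",
                              params=_patho_params())
    if name == "validation_patho_control":
        return ScenarioConfig(name=name, n_resident_m0=1280,
                              duration_h=144.0, n_runs=25,
                              recruitment_placement="crown",
                              secretion_mode="pathological",
                              params=_patho_params())
    if name == "validation_biomat":
        p = _patho_params()
        p.recruitment_ff_term = 3.0
        p.recruitment_mm_term = 3.0
        # recruits enter from the outer tissue margin (the vascular
        # supply side) and migrate in; the implant vicinity is swept by
        # chemotaxis, reproducing the observed near-implant depletion
        p.crown_margin = 10.0
        p.crown_width = 1.5
        p.recruit_attempts = 2.5
        p.recruit_attempts_fibro = 1.5
        return ScenarioConfig(name=name, pim_stimulus=_mech(20.0, 14),
                              n_resident_m0=0, duration_h=7 * 24.0,
                              n_runs=5, recruitment_placement="crown",
                              secretion_mode="pathological",
                              biomaterial_mode=True, params=p)
    if name == "chemotaxis_sweep":
        # scenario 1B with the steep center-peaked Gaussian stimulus:
        # the configuration used to quantify chemotaxis (N_c vs k)
        return ScenarioConfig(name=name, pim_stimulus=_gauss(1500.0),
                              n_resident_m0=400, duration_h=120.0,
                              params=_scenario_params())
    if name == "invitro_polarization":
        return ScenarioConfig(name=name,
                              pim_stimulus=_block(30.0, smooth=0.0),
                              n_resident_m0=1280, duration_h=12.0,
                              n_runs=30, recruitment_enabled=False)
    raise KeyError(name)


BUILTIN_SCENARIOS = (
    "1A", "1B", "2A", "2B",
    "validation_patho", "validation_patho_pim", "validation_patho_aim",
    "validation_patho_control", "validation_biomat",
    "chemotaxis_sweep", "invitro_polarization",
)


def builtin_scenario(name: str) -> ScenarioConfig:
    """Return a fully populated built-in scenario configuration.

    The four exploration scenarios differ by stimulus type and resident
    macrophages: 1A/1B use a diffusing ("chemical"/pathological) PIM=30
    block smoothed with sigma=2 and 0/400 resident M0; 2A/2B use a
    frozen ("mechanical") PIM=2 implant and 0/400 resident M0.  The
    validation scenarios reproduce the published protocols (Gaussian
    PIM peak 1500 / AIM peak 58.9 with 1280 resident M0 and crown
    placement; mechanical PIM=20 on a 14x14 square with recruitment
    terms 3; in-vitro polarization with recruitment disabled).
    """
    try:
        return _make_builtin(name)
    except KeyError:
        raise ValueError(
            f"unknown scenario {name!r}; valid ids: "
            + ", ".join(BUILTIN_SCENARIOS)
        ) from None


def validate(config: ScenarioConfig) -> list[str]:
    """Return a list of invariant-violation messages (empty iff valid)."""
    out: list[str] = []
    p = config.params
    for name in ("tau", "dx"):
        if getattr(p, name) <= 0:
            out.append(f"params.{name} must be > 0")
    if p.grid_n <= 0:
        out.append("params.grid_n must be > 0")
    for name in ("D_pim", "D_aim", "k_chemo", "pim_per_lps",
                 "fibro_aim_rate", "fibro_pim_rate",
                 "f_negative_feedback_rate", "recruitment_ff_term",
                 "recruitment_mm_term", "f1_act_scalar",
                 "f1_act_hill_parameter", "f1_socs_infinity",
                 "patho_pim_recruit_scale_f", "fix_pim_recruit_scale_f",
                 "fix_pim_recruit_scale_m", "aim_recruit_scale_f",
                 "aim_recruit_scale_m"):
        if getattr(p, name) < 0:
            out.append(f"params.{name} must be >= 0")
    for fld in dataclasses.fields(MacKinetics):
        if getattr(p.mac, fld.name) < 0:
            out.append(f"params.mac.{fld.name} must be >= 0")
    for cls, (mean, sd) in p.lifespan_mean_sd.items():
        if mean <= 0 or sd < 0:
            out.append(f"lifespan_mean_sd[{cls}] must have mean>0, sd>=0")
        elif sd >= mean:
            out.append(f"lifespan_mean_sd[{cls}]: SD must be < mean")
    if config.n_resident_m0 < 0:
        out.append("n_resident_m0 must be >= 0")
    elif config.n_resident_m0 > p.grid_n ** 2:
        out.append(
            f"n_resident_m0 = {config.n_resident_m0} exceeds the "
            f"{p.grid_n}x{p.grid_n} pixel count"
        )
    if config.duration_h <= 0:
        out.append("duration_h must be > 0")
    if config.n_runs < 1:
        out.append("n_runs must be >= 1")
    if config.recruitment_placement not in ("uniform", "border", "crown"):
        out.append(
            "recruitment_placement must be 'uniform', 'border' or 'crown'")
    if config.secretion_mode not in ("default", "pathological"):
        out.append("secretion_mode must be 'default' or 'pathological'")
    for stim in (config.pim_stimulus, config.aim_stimulus):
        if stim is None:
            continue
        if stim.amplitude < 0:
            out.append(f"stimulus amplitude must be >= 0 ({stim.mode})")
        if stim.extent > p.grid_n:
            out.append(
                f"stimulus extent {stim.extent} exceeds grid side {p.grid_n}"
            )
    return out


# ---------------------------------------------------------------------
# serialization (plain YAML; round-trips every builtin scenario)

def config_to_yaml(config: ScenarioConfig) -> str:
    d = dataclasses.asdict(config)
    return yaml.safe_dump(d, sort_keys=True)


def config_from_yaml(text: str) -> ScenarioConfig:
    d = yaml.safe_load(text)
    for key in ("pim_stimulus", "aim_stimulus"):
        if d.get(key) is not None:
            d[key] = StimulusSpec(**d[key])
    pd = d.get("params")
    if pd is not None:
        mac = pd.pop("mac", None)
        if pd.get("lifespan_mean_sd"):
            pd["lifespan_mean_sd"] = {k: tuple(v) for k, v
                                      in pd["lifespan_mean_sd"].items()}
        params = ModelParams(**pd)
        if mac is not None:
            params.mac = MacKinetics(**mac)
        d["params"] = params
    for key in ("pim_stimulus", "aim_stimulus"):
        if d.get(key) is not None and d[key].center is not None:
            d[key].center = tuple(d[key].center)
    return ScenarioConfig(**d)


def apply_overrides(config: ScenarioConfig, pairs: list[str]) -> ScenarioConfig:
    """Apply ``key=value`` point overrides (dotted paths into params)."""
    for pair in pairs:
        key, _, raw = pair.partition("=")
        if not _:
            raise ValueError(f"override {pair!r} is not key=value")
        target = config
        parts = key.split(".")
        for part in parts[:-1]:
            target = getattr(target, part)
        current = getattr(target, parts[-1])
        value: object
        if isinstance(current, bool):
            value = raw.lower() in ("1", "true", "yes")
        elif isinstance(current, int):
            value = int(raw)
        elif isinstance(current, float):
            value = float(raw)
        else:
            value = raw
        setattr(target, parts[-1], value)
    return config
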