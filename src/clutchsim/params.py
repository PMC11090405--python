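"""Physical parameters, unit conversions and condition presets.

Internal unit system: piconewton (pN), nanometre (nm), second (s).
Consequently spring constants are pN/nm, forces pN, and stresses/moduli
pN/nm**2, which equals exactly 1 MPa.  Public converters accept and return
SI pascals; stiffness sweeps are specified in kPa (the units gel stiffness
is quoted in).

The slip-bond and talin rate laws are parameterised with force coefficients
in 1/N, the units their published constants carry; they are rescaled to
1/pN at evaluation time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Any

# Boltzmann constant in pN nm / K  (1.380649e-23 J/K * 1e21 pN nm / J)
KB_PN_NM = 1.380649e-2

#: 1 pN/nm**2 expressed in Pa
PA_PER_PN_NM2 = 1.0e6

#: gel stiffness set used throughout (kPa)
DEFAULT_STIFFNESS_KPA = (0.6, 1.3, 2.6, 6.0, 12.7)

PRESET_NAMES = ("WT", "BBS", "CK666-BBS", "SMIFH2-BBS", "LatA-BBS")


class ParameterError(ValueError):
    """Raised when a parameter set violates its physical invariants."""


# ---------------------------------------------------------------------------
# unit conversions
# ---------------------------------------------------------------------------

def stiffness_to_spring(E_pa: float, ra_nm: float) -> float:
    """Convert substrate Young's modulus to the equivalent adhesion spring.

    ksub = 4*pi*ra*E/9 for an adhesion of radius ``ra`` on an elastic
    half-space of modulus ``E``.

    Parameters
    ----------
    E_pa : substrate Young's modulus in Pa (>= 0).
    ra_nm : adhesion radius in nm (> 0).

    Returns
    -------
    Spring constant in pN/nm.
    """
    if ra_nm <= 0:
        raise ParameterError(f"adhesion radius must be positive, got {ra_nm}")
    if E_pa < 0:
        raise ParameterError(f"Young's modulus must be non-negative, got {E_pa}")
    return 4.0 * math.pi * ra_nm * (E_pa / PA_PER_PN_NM2) / 9.0


def modulus_from_spring(ksub: float, ra_nm: float) -> float:
    """Inverse of :func:`stiffness_to_spring`; returns E in Pa."""
    if ra_nm <= 0:
        raise ParameterError(f"adhesion radius must be positive, got {ra_nm}")
    return 9.0 * ksub / (4.0 * math.pi * ra_nm) * PA_PER_PN_NM2


def force_to_stress(F_pn: float, ra_nm: float) -> float:
    """Convert adhesion force to traction stress, Psub = F/(pi*ra**2), in Pa."""
    if ra_nm <= 0:
        raise ParameterError(f"adhesion radius must be positive, got {ra_nm}")
    return F_pn / (math.pi * ra_nm * ra_nm) * PA_PER_PN_NM2


# ---------------------------------------------------------------------------
# parameter blocks
# ---------------------------------------------------------------------------

@dataclass
class PhysicalConstants:
    """Thermodynamic constants for the polymerization ratchet.

    delta is the elongation added per actin subunit (2.7 nm).  T defaults to
    310 K (37 C culture).
    """

    kB: float = KB_PN_NM   # pN nm / K
    T: float = 310.0       # K
    delta: float = 2.7     # nm

    def validate(self) -> None:
        if self.kB <= 0 or self.T <= 0 or self.delta <= 0:
            raise ParameterError("kB, T and delta must all be strictly positive")


@dataclass
class SubstrateSpec:
    """Elastic substrate: Young's modulus E (Pa) and adhesion radius ra (nm).

    The spring constant ksub is derived, never stored, so E and ksub cannot
    drift apart.
    """

    E: float = 2600.0      # Pa
    ra: float = 1000.0     # nm

    @property
    def ksub(self) -> float:
        return stiffness_to_spring(self.E, self.ra)

    def validate(self) -> None:
        if self.ra <= 0:
            raise ParameterError("adhesion radius must be positive")
        if self.E < 0:
            raise ParameterError("Young's modulus must be non-negative")


@dataclass
class MotorParams:
    """Myosin motor ensemble: nm motors of stall force Fm, unloaded speed Va."""

    nm: int = 75           # motors
    Fm: float = 2.0        # pN
    Va: float = 9.0        # nm/s

    @property
    def stall_force(self) -> float:
        """Isometric stall tension nm*Fm (pN)."""
        return self.nm * self.Fm

    def validate(self) -> None:
        if self.nm < 0:
            raise ParameterError("motor count must be non-negative")
        if self.Fm <= 0 or self.Va <= 0:
            raise ParameterError("Fm and Va must be strictly positive")


@dataclass
class ClutchKinetics:
    """Integrin-fibronectin clutch binding/unbinding kinetics.

    Unbinding follows a two-branch exponential slip bond,
    koff = a*exp(b*Fc), with (a1, b1) below 13.2 pN and (a2, b2) from
    13.2 pN up (the second branch is extrapolated beyond its stated 30 pN
    upper bound).  b coefficients are stored in 1/N.  koff_scale multiplies
    the whole law and encodes condition-level unclutching-rate changes.
    """

    nf: int = 10               # clutches
    kc: float = 1.0            # pN/nm
    kont: float = 0.0045       # 1/s per integrin density unit
    dint: float = 100.0        # integrin density units
    koff_a1: float = 0.1905    # 1/s
    koff_b1: float = 2.333e11  # 1/N
    koff_a2: float = 0.04527   # 1/s
    koff_b2: float = 7.251e10  # 1/N
    koff_branch_force: float = 13.2   # pN
    koff_scale: float = 1.0

    @property
    def kon(self) -> float:
        """Effective binding rate kont*dint (1/s)."""
        return self.kont * self.dint

    def validate(self) -> None:
        if self.nf < 0:
            raise ParameterError("clutch count must be non-negative")
        if self.kc <= 0:
            raise ParameterError("clutch spring constant must be positive")
        if self.kont < 0 or self.dint < 0:
            raise ParameterError("kon factors must be non-negative")
        if self.koff_scale < 0:
            raise ParameterError("koff_scale must be non-negative")


@dataclass
class TalinReinforcement:
    """Talin unfolding/refolding and vinculin-mediated adhesion reinforcement.

    kuf(Fc) = exp(kuf_pref)*exp(kuf_exp*Fc*pt) and
    kf(Fc)  = exp(kf_pref)*exp(kf_exp*Fc*pt), with Fc in N inside the
    exponent (exp coefficients in 1/N) and pt the fraction of clutch force
    carried by talin.  Each vinculin binding event raises the effective
    integrin density by dint_increment, raising kon; vinculin occupancy per
    clutch saturates at vinculin_max and is reset when the clutch unbinds.
    """

    kuf_pref: float = -7.573      # ln(1/s)
    kuf_exp: float = 1.786e12     # 1/N
    kf_pref: float = 13.07        # ln(1/s)
    kf_exp: float = -2.288e12     # 1/N
    pt: float = 0.073
    konv: float = 1.0e8           # 1/s (probability-capped)
    dint_increment: float = 10.0  # integrin density units per event
    vinculin_max: int = 1

    def validate(self) -> None:
        if not 0.0 <= self.pt <= 1.0:
            raise ParameterError("pt must lie in [0, 1]")
        if self.konv < 0 or self.dint_increment < 0 or self.vinculin_max < 0:
            raise ParameterError("reinforcement rates must be non-negative")


@dataclass
class ActinPolymerParams:
    """Polymerization-driven flow and its Brownian-ratchet stall force.

    The single-filament stall force is Fmax = kB*T/delta * ln(C/Ccrit); the
    ensemble stall is Fs_actin = naf*Fmax*stall_scale.  When stall_scale is
    None it is derived so that Fs_actin equals myosin_stall_ratio times the
    myosin stall tension (the ~1/3 in-vitro ratio).
    """

    vactin_max: float = 6.5        # nm/s
    naf: int = 5                   # filaments
    C: float = 100.0               # uM
    Ccrit: float = 0.12            # uM
    stall_scale: float | None = None
    myosin_stall_ratio: float = 1.0 / 3.0

    def validate(self) -> None:
        if self.vactin_max < 0 or self.naf < 0:
            raise ParameterError("vactin_max and naf must be non-negative")
        if not self.C > self.Ccrit > 0:
            raise ParameterError("need C > Ccrit > 0 for net polymerization")
        if self.stall_scale is not None and self.stall_scale <= 0:
            raise ParameterError("stall_scale must be positive")
        if self.myosin_stall_ratio <= 0:
            raise ParameterError("myosin_stall_ratio must be positive")


@dataclass
class ViscoelasticParams:
    """Mesoscale viscoelastic actin network (unit springs + damper).

    kactin is the per-unit spring constant (pN/nm, model units), eta the
    damping coefficient (pN s/nm).  Units of rest length L are appended at
    the polymerizing tip, at most Nn_max (real-valued) per step, stalling
    linearly as the largest single-clutch force approaches Fs_actin.
    """

    kactin: float = 11000.0   # pN/nm per unit
    eta: float = 0.175        # pN s/nm
    L: float = 10.0           # nm
    N0: float = 5000.0        # units
    Nn_max: float = 2.5e-4    # units per step
    Fs_actin: float = 40.0    # pN

    def validate(self) -> None:
        for name in ("kactin", "eta", "L", "N0", "Nn_max", "Fs_actin"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"viscoelastic parameter {name} must be positive")


@dataclass
class ParameterSet:
    """All parameters for one simulation condition."""

    constants: PhysicalConstants = field(default_factory=PhysicalConstants)
    substrate: SubstrateSpec = field(default_factory=SubstrateSpec)
    motors: MotorParams = field(default_factory=MotorParams)
    clutches: ClutchKinetics = field(default_factory=ClutchKinetics)
    talin: TalinReinforcement = field(default_factory=TalinReinforcement)
    polymer: ActinPolymerParams = field(default_factory=ActinPolymerParams)
    visco: ViscoelasticParams = field(default_factory=ViscoelasticParams)
    dt: float = 5.0e-4        # s
    duration: float = 60.0    # s
    seed: int = 0
    condition: str = "WT"
    myosin_enabled: bool = True
    allow_reversal: bool = False
    burn_in_fraction: float = 0.2
    sample_stride: int = 20
    koff_mode: str = "force_dependent"   # or "constant"
    release_mode: str = "relax"          # or "reset"

    def validate(self) -> None:
        for block in (self.constants, self.substrate, self.motors,
                      self.clutches, self.talin, self.polymer, self.visco):
            block.validate()
        if self.dt <= 0:
            raise ParameterError("dt must be positive")
        if self.duration < 0:
            raise ParameterError("duration must be non-negative")
        if self.duration and self.duration < 10 * self.dt:
            raise ParameterError("duration must be at least 10*dt (or zero)")
        if not 0.0 <= self.burn_in_fraction < 1.0:
            raise ParameterError("burn_in_fraction must lie in [0, 1)")
        if self.sample_stride < 1:
            raise ParameterError("sample_stride must be >= 1")
        if self.koff_mode not in ("force_dependent", "constant"):
            raise ParameterError(f"unknown koff_mode {self.koff_mode!r}")
        if self.release_mode not in ("relax", "reset"):
            raise ParameterError(f"unknown release_mode {self.release_mode!r}")

    # -- derived quantities -------------------------------------------------

    def brownian_ratchet_stall(self) -> float:
        """Single-filament polymerization stall force (pN)."""
        return brownian_ratchet_stall(self.constants, self.polymer)

    def actin_stall_force(self) -> float:
        """Ensemble polymerization stall force Fs_actin = naf*Fmax*stall_scale (pN)."""
        fmax = self.brownian_ratchet_stall()
        scale = self.polymer.stall_scale
        if scale is None:
            scale = (self.polymer.myosin_stall_ratio * self.motors.stall_force
                     / (self.polymer.naf * fmax))
        return self.polymer.naf * fmax * scale

    # -- dict round trip ----------------------------------------------------

    _BLOCKS = ("constants", "substrate", "motors", "clutches", "talin",
               "polymer", "visco")

    def to_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {"schema_version": 1}
        for name in self._BLOCKS:
            block = getattr(self, name)
            out[name] = {f.name: getattr(block, f.name) for f in fields(block)}
        for f in fields(self):
            if f.name not in self._BLOCKS:
                out[f.name] = getattr(self, f.name)
        return out

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "ParameterSet":
        import warnings

        data = dict(data)
        data.pop("schema_version", None)
        kwargs: dict[str, Any] = {}
        block_types = {f.name: f.default_factory for f in fields(cls)
                       if f.name in cls._BLOCKS}
        for name, factory in block_types.items():
            section = data.pop(name, None)
            if section is None:
                continue
            block = factory()  # type: ignore[misc]
            for key, value in section.items():
                if not hasattr(block, key):
                    warnings.warn(f"ignoring unknown key {name}.{key}",
                                  stacklevel=2)
                    continue
                setattr(block, key, value)
            kwargs[name] = block
        scalar_names = {f.name for f in fields(cls)} - set(cls._BLOCKS)
        for key, value in data.items():
            if key in scalar_names:
                kwargs[key] = value
            else:
                warnings.warn(f"ignoring unknown key {key}", stacklevel=2)
        ps = cls(**kwargs)
        ps.validate()
        return ps


def brownian_ratchet_stall(constants: PhysicalConstants,
                           polymer: ActinPolymerParams) -> float:
    """Brownian-ratchet stall force of one filament, kB*T/delta * ln(C/Ccrit), pN."""
    if polymer.C <= polymer.Ccrit:
        raise ParameterError(
            f"no net polymerization: C={polymer.C} <= Ccrit={polymer.Ccrit}")
    return (constants.kB * constants.T / constants.delta
            * math.log(polymer.C / polymer.Ccrit))


# ---------------------------------------------------------------------------
# condition presets
# ---------------------------------------------------------------------------

def default_params(**overrides: Any) -> ParameterSet:
    """Base (WT) parameter set; keyword overrides replace top-level fields."""
    ps = ParameterSet(**overrides)
    ps.validate()
    return ps


def make_preset(name: str, base: ParameterSet | None = None,
                model: str = "rigid") -> ParameterSet:
    """Apply a named pharmacological condition to a base parameter set.

    WT keeps myosin active and is returned unchanged apart from its label.
    Every inhibited condition zeroes the myosin velocity term.

    The CK666-BBS overrides depend on which engine the set is destined for:
    in the rigid engine CK666-BBS lowers the actin stall force and raises
    the unclutching-rate magnitude to 6 (vs 0.5 for the other inhibited
    conditions), while in the viscoelastic engine CK666-BBS is identical to
    BBS except for kactin (11000 vs 1500).  SMIFH2-BBS and LatA-BBS lower
    kactin further and change the network viscosity.
    """
    if base is None:
        base = default_params()
    if name not in PRESET_NAMES:
        raise KeyError(f"unknown condition {name!r}; choose from {PRESET_NAMES}")
    if model not in ("rigid", "visco"):
        raise KeyError(f"unknown model {model!r}; choose 'rigid' or 'visco'")
    if model == "visco":
        # viscoelastic-engine clutch operating point, identical for every
        # condition: a sparse, stiff clutch ensemble whose load-and-fail
        # cycling matches the network-compression dynamics
        base = replace(base, clutches=replace(base.clutches, kc=5.0,
                                              kont=5.0e-4))

    ps = replace(
        base,
        constants=replace(base.constants),
        substrate=replace(base.substrate),
        motors=replace(base.motors),
        clutches=replace(base.clutches),
        talin=replace(base.talin),
        polymer=replace(base.polymer),
        visco=replace(base.visco),
        condition=name,
    )
    if name == "WT":
        ps.myosin_enabled = True
        ps.validate()
        return ps

    ps.myosin_enabled = False
    if name == "BBS":
        ps.clutches.koff_scale = 0.5
        ps.visco.kactin = 11000.0
        ps.visco.eta = 0.175
    elif name == "CK666-BBS":
        ps.visco.kactin = 1500.0
        ps.visco.eta = 0.175
        if model == "rigid":
            ps.clutches.koff_scale = 6.0
            ps.polymer.stall_scale = _halved_stall_scale(ps)
        else:
            ps.clutches.koff_scale = 0.5
    elif name == "SMIFH2-BBS":
        ps.clutches.koff_scale = 0.5
        ps.visco.kactin = 1150.0
        ps.visco.eta = 1.08
    elif name == "LatA-BBS":
        ps.clutches.koff_scale = 0.5
        ps.visco.kactin = 1000.0
        ps.visco.eta = 0.8
    ps.validate()
    return ps


def _halved_stall_scale(ps: ParameterSet) -> float:
    """Stall-force scale for the Arp2/3-inhibited rigid model (half the base)."""
    fmax = ps.brownian_ratchet_stall()
    base_scale = ps.polymer.stall_scale
    if base_scale is None:
        base_scale = (ps.polymer.myosin_stall_ratio * ps.motors.stall_force
                      / (ps.polymer.naf * fmax))
    return 0.5 * base_scale
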