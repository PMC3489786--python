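"""Physical constants, units, and the internal nondimensionalization.

Every mechanical, kinetic and thermodynamic constant of the model lives in
:class:`ParameterSet`, expressed in laboratory (SI-flavoured) units.  All
force-field and kinetics code consumes parameters through
:func:`ParameterSet.internal`, which converts once into the simulation unit
system (length nm, force pN, time s, energy pN*nm); no literal physical
constant appears outside this module.

A second, fully reduced unit system (length = r_c, energy = k_B*T,
time = zeta*r_c^2/(k_B*T)) is available through :func:`nondimensionalize` /
:func:`redimensionalize` and is exact under round-trip.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from types import SimpleNamespace

import yaml

BOLTZMANN_J_PER_K = 1.380649e-23
AVOGADRO_PER_MOL = 6.02214076e23

# 1 uM expressed as a number density in nm^-3
_UM_TO_PER_NM3 = 1e-6 * AVOGADRO_PER_MOL / 1e24

# unit conversions from the field's laboratory unit to internal (nm, pN, s)
_N_PER_M_TO_PN_PER_NM = 1e3          # stiffness
_J_TO_PN_NM = 1e21                   # bending stiffness per rad^2, energies
_NS_PER_M_TO_PN_S_PER_NM = 1e3       # drag coefficient
_PA_TO_PN_PER_NM2 = 1e-6             # moduli, stresses
_UM_TO_NM = 1e3


@dataclass(frozen=True)
class ParameterSet:
    """Full model configuration.

    Units are fixed per field and documented inline.  ``units`` is ``"lab"``
    for the constructor units below or ``"reduced"`` after
    :func:`nondimensionalize`.

    Default values marked [reconstruction] are implementer defaults chosen on
    documented physical grounds (see docs/methods.md); values without a tag
    are the reference control configuration.
    """

    # --- geometry -----------------------------------------------------------
    r0_A: float = 140.0        # nm, actin segment rest length
    r0_ACP: float = 35.0       # nm, ACP arm rest length (2*r0_ACP = 70 nm span)
    r0_M: float = 70.0         # nm, motor arm rest length (2*r0_M = 140 nm span)
    r_c: float = 7.0           # nm, cylindrical segment diameter [reconstruction]

    # --- extensional stiffnesses, N/m --------------------------------------
    kappa_s_A: float = 2.5e-3      # [reconstruction: softened as in the source
                                   #  framework to enlarge dt; filament strain
                                   #  at motor forces stays ~1% of a segment]
    kappa_s_ACP: float = 2.0e-3    # [reconstruction]
    kappa_s_M: float = 1.0e-4      # [reconstruction: arm compliance sets the
                                   #  tension gained per 140-nm step (~7 pN
                                   #  against a stiff anchor), so an anchored
                                   #  motor reaches stall within 1-2 steps]
    kappa_r: float = 2.0e-3        # N/m, segment-overlap repulsion [reconstruction]

    # --- bending stiffnesses, N*m/rad^2 -------------------------------------
    kappa_b_A: float = 2.66e-19    # persistence length ~9 um at 300 K
    kappa_b_ACP1: float = 1.0e-19  # keeps the two ACP arms parallel [reconstruction]
    kappa_b_ACP2: float = 4.14e-20 # arm-filament right angle, ~10 kBT [reconstruction]
    kappa_b_M1: float = 1.0e-19    # [reconstruction]
    kappa_b_M2: float = 4.14e-20   # [reconstruction]

    # --- motor walking (two-exponential dwell law) ---------------------------
    d_w1: float = 0.04         # s   [reconstruction, calibrated: k_w(0) ~ 22 1/s]
    d_w2: float = 0.005        # s   [reconstruction]
    lambda_w1: float = 0.1     # 1/pN [reconstruction]
    lambda_w2: float = 1.7     # 1/pN [reconstruction: 1% stall load ~4 pN]

    # --- unbinding (Bell law), binding --------------------------------------
    # the bind/unbind pairs set the binding-site occupancy (~50-60% of the
    # one-site-per-node capacity at reference composition): linkers heavily
    # outnumber sites, so a moderate equilibrium is what leaves motors room
    # to walk while keeping the ACP cross-link scaffold percolated
    k0_u_ACP: float = 0.06     # 1/s  [reconstruction, slow cross-linker]
    k0_u_M: float = 0.25       # 1/s  [reconstruction]
    lambda_u_ACP: float = 0.17 # nm, Bell length [reconstruction]
    lambda_u_M: float = 0.4    # nm  [reconstruction]
    k_bind_ACP: float = 2.0    # 1/(uM*s) [reconstruction]
    k_bind_M: float = 2.0      # 1/(uM*s) [reconstruction]

    # --- thermodynamics / integration ---------------------------------------
    T: float = 300.0           # K
    mu: float = 3.44           # Pa*s, effective medium viscosity [reconstruction:
                               #  sized so dt below is stable; rescales time only]
    zeta_per_segment: float = 4.5389e-6   # N*s/m, = 3*pi*mu*r0_A
    dt: float = 1.5e-4         # s, Euler time step (safety factor ~0.08)
    n_kinetic: int = 10        # integration steps per kinetics/boundary window

    # --- composition & domain ------------------------------------------------
    C_A: float = 12.0          # uM actin
    R_ACP: float = 0.01        # C_ACP / C_A
    R_M: float = 0.02          # C_M / C_A
    L_f_mean: float = 2.0      # um, mean filament length
    W0: float = 5.0            # um, initial domain width
    E: float = 1000.0          # Pa, substrate Young's modulus

    # --- auxiliary model constants -------------------------------------------
    actin_monomers_per_nm: float = 0.37   # G-actin per nm of filament
    sticky_capture_nm: float = 30.0       # boundary capture distance
    bind_capture_tol: float = 0.50        # +/- fraction on the 2*r0 span for
                                          # second-arm capture (nodes straddle
                                          # a filament crossing by up to ~r0_A)

    units: str = "lab"

    # ------------------------------------------------------------------ misc
    def replace(self, **kw) -> "ParameterSet":
        return dataclasses.replace(self, **kw)

    @property
    def kBT_pNnm(self) -> float:
        return BOLTZMANN_J_PER_K * self.T * _J_TO_PN_NM

    def validate(self) -> None:
        """Raise ``ValueError`` on an unphysical or unstable configuration."""
        if self.units != "lab":
            raise ValueError("validate() expects lab units")
        positive = [
            "r0_A", "r0_ACP", "r0_M", "r_c", "kappa_s_A", "kappa_s_ACP",
            "kappa_s_M", "kappa_r", "kappa_b_A", "kappa_b_ACP1",
            "kappa_b_ACP2", "kappa_b_M1", "kappa_b_M2", "d_w1", "d_w2",
            "T", "mu", "zeta_per_segment", "dt", "C_A", "L_f_mean", "W0", "E",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("R_ACP", "R_M", "k0_u_ACP", "k0_u_M", "lambda_u_ACP",
                     "lambda_u_M", "k_bind_ACP", "k_bind_M",
                     "lambda_w1", "lambda_w2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.r_c > self.r0_A:
            raise ValueError("r_c must not exceed r0_A")
        bound = stability_bound_s(self)
        if self.dt >= bound:
            raise ValueError(
                f"dt={self.dt:g} s violates the overdamped stability bound "
                f"{bound:g} s (zeta/kappa_max with safety factor 0.1)"
            )

    def internal(self) -> SimpleNamespace:
        """Convert to the simulation unit system: nm, pN, s, pN*nm."""
        if self.units != "lab":
            raise ValueError("internal() expects lab units")
        return SimpleNamespace(
            r0_A=self.r0_A, r0_ACP=self.r0_ACP, r0_M=self.r0_M, rc=self.r_c,
            ks_A=self.kappa_s_A * _N_PER_M_TO_PN_PER_NM,
            ks_ACP=self.kappa_s_ACP * _N_PER_M_TO_PN_PER_NM,
            ks_M=self.kappa_s_M * _N_PER_M_TO_PN_PER_NM,
            kr=self.kappa_r * _N_PER_M_TO_PN_PER_NM,
            kb_A=self.kappa_b_A * _J_TO_PN_NM,
            kb_ACP1=self.kappa_b_ACP1 * _J_TO_PN_NM,
            kb_ACP2=self.kappa_b_ACP2 * _J_TO_PN_NM,
            kb_M1=self.kappa_b_M1 * _J_TO_PN_NM,
            kb_M2=self.kappa_b_M2 * _J_TO_PN_NM,
            d_w1=self.d_w1, d_w2=self.d_w2,
            lambda_w1=self.lambda_w1, lambda_w2=self.lambda_w2,
            k0_u_ACP=self.k0_u_ACP, k0_u_M=self.k0_u_M,
            lambda_u_ACP=self.lambda_u_ACP, lambda_u_M=self.lambda_u_M,
            # second-order rate as nm^3/s per (site, molecule) pair
            kbind_ACP=self.k_bind_ACP / _UM_TO_PER_NM3,
            kbind_M=self.k_bind_M / _UM_TO_PER_NM3,
            kBT=self.kBT_pNnm,
            zeta=self.zeta_per_segment * _NS_PER_M_TO_PN_S_PER_NM,
            dt=self.dt,
            n_kinetic=self.n_kinetic,
            C_A_per_nm3=self.C_A * _UM_TO_PER_NM3,
            R_ACP=self.R_ACP, R_M=self.R_M,
            Lf=self.L_f_mean * _UM_TO_NM,
            W0=self.W0 * _UM_TO_NM,
            E=self.E * _PA_TO_PN_PER_NM2,
            monomers_per_nm=self.actin_monomers_per_nm,
            sticky=self.sticky_capture_nm,
            bind_tol=self.bind_capture_tol,
        )

    # ------------------------------------------------------------------ io
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ParameterSet":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def reference_parameters() -> ParameterSet:
    """Control configuration: C_A = 12 uM, R_ACP = 0.01, R_M = 0.02,
    W0 = 5 um, <L_f> ~ 2 um, 140-nm actin segments, stall force ~4 pN."""
    p = ParameterSet()
    p.validate()
    return p


def stability_bound_s(p: ParameterSet, safety: float = 0.1) -> float:
    """Largest admissible Euler step: safety * zeta / kappa_max."""
    kappa_max = max(p.kappa_s_A, p.kappa_s_ACP, p.kappa_s_M, p.kappa_r)
    return safety * p.zeta_per_segment / kappa_max


def drag_coefficient(mu_Pa_s: float, r0_A_nm: float) -> float:
    """Per-node cylinder drag 3*pi*mu*r0_A in N*s/m."""
    return 3.0 * math.pi * mu_Pa_s * r0_A_nm * 1e-9


# --------------------------------------------------------------------------
# reduced units: length r_c, energy kBT, time zeta*r_c^2/kBT
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class UnitScales:
    """Scales of the reduced unit system, all in internal (nm, pN, s) units."""
    length_nm: float        # r_c
    energy_pNnm: float      # kBT
    time_s: float           # zeta * r_c^2 / kBT

    @property
    def force_pN(self) -> float:
        return self.energy_pNnm / self.length_nm

    @classmethod
    def from_parameters(cls, p: ParameterSet) -> "UnitScales":
        if p.r_c <= 0 or p.T <= 0 or p.zeta_per_segment <= 0:
            raise ValueError("scale constants must be strictly positive")
        zeta = p.zeta_per_segment * _NS_PER_M_TO_PN_S_PER_NM
        kBT = p.kBT_pNnm
        return cls(length_nm=p.r_c, energy_pNnm=kBT,
                   time_s=zeta * p.r_c ** 2 / kBT)


# field -> (factor to internal units, (L, E, T) exponents of its dimension)
_FIELD_DIMS: dict[str, tuple[float, tuple[int, int, int]]] = {
    "r0_A": (1.0, (1, 0, 0)), "r0_ACP": (1.0, (1, 0, 0)),
    "r0_M": (1.0, (1, 0, 0)), "r_c": (1.0, (1, 0, 0)),
    "kappa_s_A": (_N_PER_M_TO_PN_PER_NM, (-2, 1, 0)),
    "kappa_s_ACP": (_N_PER_M_TO_PN_PER_NM, (-2, 1, 0)),
    "kappa_s_M": (_N_PER_M_TO_PN_PER_NM, (-2, 1, 0)),
    "kappa_r": (_N_PER_M_TO_PN_PER_NM, (-2, 1, 0)),
    "kappa_b_A": (_J_TO_PN_NM, (0, 1, 0)),
    "kappa_b_ACP1": (_J_TO_PN_NM, (0, 1, 0)),
    "kappa_b_ACP2": (_J_TO_PN_NM, (0, 1, 0)),
    "kappa_b_M1": (_J_TO_PN_NM, (0, 1, 0)),
    "kappa_b_M2": (_J_TO_PN_NM, (0, 1, 0)),
    "d_w1": (1.0, (0, 0, 1)), "d_w2": (1.0, (0, 0, 1)),
    "lambda_w1": (1.0, (1, -1, 0)), "lambda_w2": (1.0, (1, -1, 0)),
    "k0_u_ACP": (1.0, (0, 0, -1)), "k0_u_M": (1.0, (0, 0, -1)),
    "lambda_u_ACP": (1.0, (1, 0, 0)), "lambda_u_M": (1.0, (1, 0, 0)),
    "k_bind_ACP": (1.0 / _UM_TO_PER_NM3, (3, 0, -1)),
    "k_bind_M": (1.0 / _UM_TO_PER_NM3, (3, 0, -1)),
    "mu": (_NS_PER_M_TO_PN_S_PER_NM * 1e-9, (-3, 1, 1)),  # Pa*s -> pN*s/nm^2
    "zeta_per_segment": (_NS_PER_M_TO_PN_S_PER_NM, (-2, 1, 1)),
    "dt": (1.0, (0, 0, 1)),
    "C_A": (_UM_TO_PER_NM3, (-3, 0, 0)),
    "L_f_mean": (_UM_TO_NM, (1, 0, 0)), "W0": (_UM_TO_NM, (1, 0, 0)),
    "E": (_PA_TO_PN_PER_NM2, (-3, 1, 0)),
    "actin_monomers_per_nm": (1.0, (-1, 0, 0)),
    "sticky_capture_nm": (1.0, (1, 0, 0)),
}
# temperature is handled specially (kBT -> 1 energy unit); pure numbers as-is
_DIMENSIONLESS = {"R_ACP", "R_M", "bind_capture_tol", "n_kinetic"}


def _scale_factor(scales: UnitScales, exps: tuple[int, int, int]) -> float:
    return (scales.length_nm ** exps[0]
            * scales.energy_pNnm ** exps[1]
            * scales.time_s ** exps[2])


def nondimensionalize(p: ParameterSet) -> ParameterSet:
    """Express ``p`` in reduced units (length r_c, energy kBT,
    time zeta*r_c^2/kBT).  ``T`` becomes the thermal energy kBT = 1."""
    if p.units != "lab":
        raise ValueError("parameter set is already reduced")
    scales = UnitScales.from_parameters(p)
    out: dict[str, float] = {}
    for name, (factor, exps) in _FIELD_DIMS.items():
        out[name] = getattr(p, name) * factor / _scale_factor(scales, exps)
    for name in _DIMENSIONLESS:
        out[name] = getattr(p, name)
    out["T"] = 1.0  # thermal energy in units of kBT
    return p.replace(units="reduced", **out)


def redimensionalize(p_red: ParameterSet, scales: UnitScales) -> ParameterSet:
    """Inverse of :func:`nondimensionalize`; exact round trip."""
    if p_red.units != "reduced":
        raise ValueError("parameter set is not in reduced units")
    out: dict[str, float] = {}
    for name, (factor, exps) in _FIELD_DIMS.items():
        out[name] = getattr(p_red, name) * _scale_factor(scales, exps) / factor
    for name in _DIMENSIONLESS:
        out[name] = getattr(p_red, name)
    out["T"] = scales.energy_pNnm / (BOLTZMANN_J_PER_K * _J_TO_PN_NM)
    return p_red.replace(units="lab", **out)
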