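"""State vector, parameter set, quotas and tendency containers.

The model describes a coastal pelagic ecosystem with five compartments:
phytoplankton (carbon, nitrogen, chlorophyll-a and, in the P version,
phosphorus), heterotrophic bacteria, detrital particulate organic matter,
labile dissolved organic matter and dissolved inorganic matter (nitrate,
ammonium, phosphate, oxygen).  Two versions exist: a carbon/nitrogen
version with 12 state variables (``noP``) and a carbon/nitrogen/phosphorus
version with 17 (``P``).

Concentrations are in µmol L⁻¹ except chlorophyll-a, which is in µg L⁻¹;
rates are in d⁻¹.  Forcing readers convert their inputs to these units.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, fields as dc_fields, replace

import numpy as np
import yaml

__all__ = [
    "ModelVersion",
    "StateVector",
    "ParameterSet",
    "TendencyVector",
    "Quotas",
    "DegenerateStateError",
    "VARIABLES_NOP",
    "VARIABLES_P",
    "variables_for",
    "make_initial_state",
    "compute_quotas",
    "validate_state",
    "PRESETS",
]


class ModelVersion(enum.Enum):
    """Which element cycles are resolved: C/N only, or C/N/P."""

    noP = "noP"
    P = "P"


#: Variable order of the C/N version (indices 0–11).
VARIABLES_NOP = (
    "Cb", "Nb", "Chla", "Cba", "Nba",
    "DPOC", "DPON", "LDOC", "LDON",
    "NO3", "NH4", "O",
)

#: The P version appends the five phosphorus pools (indices 12–16).
VARIABLES_P = VARIABLES_NOP + ("Pb", "Pba", "DPOP", "LDOP", "PO4")

#: Long names and units for file metadata.
VARIABLE_METADATA = {
    "Cb": ("phytoplankton carbon", "umol L-1"),
    "Nb": ("phytoplankton nitrogen", "umol L-1"),
    "Chla": ("phytoplankton chlorophyll-a", "ug L-1"),
    "Cba": ("bacterial carbon", "umol L-1"),
    "Nba": ("bacterial nitrogen", "umol L-1"),
    "DPOC": ("detrital particulate organic carbon", "umol L-1"),
    "DPON": ("detrital particulate organic nitrogen", "umol L-1"),
    "LDOC": ("labile dissolved organic carbon", "umol L-1"),
    "LDON": ("labile dissolved organic nitrogen", "umol L-1"),
    "NO3": ("nitrate", "umol L-1"),
    "NH4": ("ammonium", "umol L-1"),
    "O": ("dissolved oxygen", "umol L-1"),
    "Pb": ("phytoplankton phosphorus", "umol L-1"),
    "Pba": ("bacterial phosphorus", "umol L-1"),
    "DPOP": ("detrital particulate organic phosphorus", "umol L-1"),
    "LDOP": ("labile dissolved organic phosphorus", "umol L-1"),
    "PO4": ("phosphate", "umol L-1"),
}

#: Pools belonging to each conserved element (oxygen and chlorophyll are
#: tracked but not element-conserved: there is no DIC pool and chlorophyll
#: is a pigment, not an element reservoir).
ELEMENT_POOLS = {
    "N": ("Nb", "Nba", "DPON", "LDON", "NO3", "NH4"),
    "P": ("Pb", "Pba", "DPOP", "LDOP", "PO4"),
    "C": ("Cb", "Cba", "DPOC", "LDOC"),
}


def variables_for(version: ModelVersion) -> tuple[str, ...]:
    return VARIABLES_P if version is ModelVersion.P else VARIABLES_NOP


class DegenerateStateError(ValueError):
    """Raised when a quota denominator is below the biomass floor."""


class VersionError(KeyError):
    """Raised when a P-only variable is requested from a noP state."""


@dataclass
class StateVector:
    """Concentrations of the active state variables for one box/level.

    Values are stored in a flat float array following :data:`VARIABLES_NOP`
    / :data:`VARIABLES_P` order; named access goes through item syntax
    (``state["NO3"]``) or attributes (``state.NO3``).
    """

    version: ModelVersion
    values: np.ndarray

    def __post_init__(self) -> None:
        want = len(variables_for(self.version))
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (want,):
            raise ValueError(
                f"version {self.version.value} expects {want} variables, "
                f"got shape {self.values.shape}"
            )

    @property
    def variables(self) -> tuple[str, ...]:
        return variables_for(self.version)

    def index(self, name: str) -> int:
        try:
            return self.variables.index(name)
        except ValueError:
            if name in VARIABLES_P:
                raise VersionError(
                    f"variable {name!r} not present in version "
                    f"{self.version.value}"
                ) from None
            raise KeyError(name) from None

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.index(name)])

    def __setitem__(self, name: str, value: float) -> None:
        self.values[self.index(name)] = value

    def __getattr__(self, name: str):
        if name in VARIABLES_P:
            return self[name]
        raise AttributeError(name)

    def copy(self) -> "StateVector":
        return StateVector(self.version, self.values.copy())

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.variables, map(float, self.values)))

    def element_total(self, element: str) -> float:
        """Summed concentration of every pool carrying ``element``."""
        pools = [p for p in ELEMENT_POOLS[element] if p in self.variables]
        if not pools:
            raise VersionError(f"element {element!r} not tracked in "
                               f"version {self.version.value}")
        return float(sum(self[p] for p in pools))


@dataclass
class TendencyVector:
    """Source-minus-sink rates, same variable set as the originating state."""

    version: ModelVersion
    values: np.ndarray

    def __post_init__(self) -> None:
        want = len(variables_for(self.version))
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (want,):
            raise ValueError("tendency/state variable sets differ")

    @property
    def variables(self) -> tuple[str, ...]:
        return variables_for(self.version)

    def __getitem__(self, name: str) -> float:
        try:
            return float(self.values[self.variables.index(name)])
        except ValueError:
            raise VersionError(
                f"variable {name!r} not present in version "
                f"{self.version.value}") from None

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.variables, map(float, self.values)))


# --------------------------------------------------------------------------
# Parameters


@dataclass
class PhytoParams:
    """Phytoplankton growth, quota and uptake constants (diatom-like)."""

    PCm: float = 2.0                # maximum C-specific growth rate, d-1
    alpha_chl: float = 0.6          # P-E initial slope, umolC ugChl-1 (W m-2)-1 d-1
    theta_min: float = 0.012        # Chl:C lower bound, ugChl umolC-1
    theta_max: float = 0.7          # Chl:C upper bound
    theta_N_max: float = 2.5        # Chl synthesised per N assimilated, ug umolN-1
    QN_min: float = 0.05            # N:C quota bounds, mol:mol
    QN_max: float = 0.20
    QP_min: float = 0.002           # P:C quota bounds, mol:mol
    QP_max: float = 0.0125
    Vmax_NO3: float = 0.5           # molN molC-1 d-1
    K_NO3: float = 0.5              # umol L-1
    Vmax_NH4: float = 0.5
    K_NH4: float = 0.3
    Vmax_PO4: float = 0.15          # molP molC-1 d-1 (surge uptake,
                                    # several-fold the maximal P demand)
    K_PO4: float = 0.05
    nh4_inhibition: float = 0.0     # optional NO3-uptake inhibition by NH4, L umol-1
    resp: float = 0.05              # linear respiration, d-1
    exud: float = 0.05              # linear exudation to LDOC, d-1
    mort: float = 0.05              # linear mortality to detritus, d-1


@dataclass
class BacteriaParams:
    """Heterotrophic bacteria quota bounds, uptake kinetics and yields.

    The carbon quota is the cell C:N ratio (low when carbon-starved); the
    N and P quotas are per carbon, as for phytoplankton.
    """

    mu_max: float = 2.0             # maximum growth rate, d-1
    GE: float = 0.3                 # growth efficiency (C yield)
    QC_min: float = 4.0             # C:N quota bounds, mol:mol
    QC_max: float = 8.0
    QN_min: float = 0.125           # N:C quota bounds
    QN_max: float = 0.25
    QP_min: float = 0.005           # P:C quota bounds
    QP_max: float = 0.02
    Vmax_LDOC: float = 4.0          # molC molC-1 d-1
    K_LDOC: float = 10.0
    Vmax_DPOC: float = 0.5
    K_DPOC: float = 5.0
    Vmax_LDON: float = 0.6          # molN molC-1 d-1
    K_LDON: float = 1.0
    Vmax_DPON: float = 0.1
    K_DPON: float = 1.0
    Vmax_NH4: float = 0.3
    K_NH4: float = 0.5
    Vmax_LDOP: float = 0.05         # molP molC-1 d-1
    K_LDOP: float = 0.1
    Vmax_DPOP: float = 0.01
    K_DPOP: float = 0.1
    Vmax_PO4: float = 0.02
    K_PO4: float = 0.05
    adj_rate: float = 1.0           # quota-overflow release rate, d-1
    resp_basal: float = 0.05        # d-1
    mort: float = 0.05              # linear mortality to detritus, d-1


@dataclass
class ClosureParams:
    """Implicit zooplankton closure: grazing and redistribution."""

    g_phy: float = 0.8              # max specific grazing on phytoplankton, d-1
    g_bac: float = 0.5              # max specific grazing on bacteria, d-1
    Q10: float = 2.0                # temperature sensitivity of grazing
    T_ref: float = 24.0             # degC at which f(T)=1
    holling_K: float = 0.0          # half-saturation prey C (0 = linear response)
    # redistribution of grazed matter, per element; must each sum to 1
    frac_pom: float = 1.0 / 3.0
    frac_dom: float = 1.0 / 3.0
    frac_dim: float = 1.0 / 3.0


@dataclass
class ReminParams:
    """First-order hydrolysis / remineralization and nitrification."""

    hydrolysis_C: float = 0.05      # DPOC -> LDOC, d-1
    hydrolysis_N: float = 0.05
    hydrolysis_P: float = 0.05
    remin_DOC: float = 0.01         # LDOC -> (CO2, not tracked), d-1
    remin_DON: float = 0.05         # LDON -> NH4
    remin_DOP: float = 0.05         # LDOP -> PO4
    nitrif: float = 0.05            # NH4 -> NO3, d-1
    Q10: float = 1.0                # 1.0 = temperature-independent
    T_ref: float = 20.0


@dataclass
class OpticsParams:
    """Light attenuation: background water plus chlorophyll self-shading."""

    k_w: float = 0.04               # m-1
    k_chl: float = 0.03             # m-1 (ug Chl L-1)-1


@dataclass
class OxygenParams:
    """Stoichiometry of oxygen production/consumption."""

    gamma_OC: float = 138.0 / 106.0  # mol O2 per mol C fixed/respired
    gamma_ON: float = 2.0            # mol O2 per mol N nitrified


@dataclass
class ParameterSet:
    """All model constants, grouped by process; version-agnostic.

    The flat key-value serialization (``to_flat``/``from_flat``/``to_yaml``)
    uses dotted keys such as ``phyto.PCm`` — one key per constant.
    """

    phyto: PhytoParams = field(default_factory=PhytoParams)
    bacteria: BacteriaParams = field(default_factory=BacteriaParams)
    closure: ClosureParams = field(default_factory=ClosureParams)
    remin: ReminParams = field(default_factory=ReminParams)
    optics: OpticsParams = field(default_factory=OpticsParams)
    oxygen: OxygenParams = field(default_factory=OxygenParams)
    biomass_floor: float = 1e-8     # umol C L-1, below which quotas degenerate

    def validate(self) -> list[str]:
        """Return a list of violated parameter invariants (empty if valid)."""
        bad: list[str] = []
        for group_name in ("phyto", "bacteria", "closure", "remin",
                           "optics", "oxygen"):
            group = getattr(self, group_name)
            for f in dc_fields(group):
                v = getattr(group, f.name)
                if v < 0:
                    bad.append(f"{group_name}.{f.name} negative ({v})")
        for el, lo, hi in (
            ("phyto N", self.phyto.QN_min, self.phyto.QN_max),
            ("phyto P", self.phyto.QP_min, self.phyto.QP_max),
            ("phyto theta", self.phyto.theta_min, self.phyto.theta_max),
            ("bacteria C", self.bacteria.QC_min, self.bacteria.QC_max),
            ("bacteria N", self.bacteria.QN_min, self.bacteria.QN_max),
            ("bacteria P", self.bacteria.QP_min, self.bacteria.QP_max),
        ):
            if not lo < hi:
                bad.append(f"{el} quota bounds not ordered ({lo} >= {hi})")
        fsum = (self.closure.frac_pom + self.closure.frac_dom
                + self.closure.frac_dim)
        if abs(fsum - 1.0) > 1e-12:
            bad.append(f"closure redistribution fractions sum to {fsum}, not 1")
        return bad

    # -- flat serialization -------------------------------------------------

    def to_flat(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for group_name in ("phyto", "bacteria", "closure", "remin",
                           "optics", "oxygen"):
            group = getattr(self, group_name)
            for f in dc_fields(group):
                out[f"{group_name}.{f.name}"] = float(getattr(group, f.name))
        out["biomass_floor"] = self.biomass_floor
        return out

    @classmethod
    def from_flat(cls, flat: dict[str, float]) -> "ParameterSet":
        ps = cls()
        for key, value in flat.items():
            if key == "biomass_floor":
                ps.biomass_floor = float(value)
                continue
            try:
                group_name, field_name = key.split(".", 1)
                group = getattr(ps, group_name)
                if not hasattr(group, field_name):
                    raise AttributeError
            except (ValueError, AttributeError):
                raise KeyError(f"unknown parameter key {key!r}") from None
            setattr(group, field_name, float(value))
        return ps

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_flat(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ParameterSet":
        with open(path) as fh:
            return cls.from_flat(yaml.safe_load(fh) or {})

    def replace(self, **groups) -> "ParameterSet":
        return replace(self, **groups)


# --------------------------------------------------------------------------
# Quotas


@dataclass(frozen=True)
class Quotas:
    """Intracellular element ratios of phytoplankton and bacteria.

    ``QP`` and ``QP_BA`` are NaN under the noP version (never read there).
    """

    QN: float            # phyto N:C, mol:mol
    QP: float            # phyto P:C
    theta: float         # Chl:C, ug umol-1
    QC_BA: float         # bacterial C:N
    QN_BA: float         # bacterial N:C
    QP_BA: float         # bacterial P:C


def neutral_quotas(params: ParameterSet) -> Quotas:
    """Mid-range quota set, used by the integrator when no biomass has
    ever been present (e.g. an abiotic box); with zero biomass every
    quota-scaled flux is zero, so the choice is inert."""
    p, b = params.phyto, params.bacteria
    return Quotas(
        QN=0.5 * (p.QN_min + p.QN_max),
        QP=0.5 * (p.QP_min + p.QP_max),
        theta=0.5 * (p.theta_min + p.theta_max),
        QC_BA=0.5 * (b.QC_min + b.QC_max),
        QN_BA=0.5 * (b.QN_min + b.QN_max),
        QP_BA=0.5 * (b.QP_min + b.QP_max),
    )


def compute_quotas(state: StateVector, params: ParameterSet) -> Quotas:
    """Intracellular ratios; errors if a biomass is below the floor.

    Quotas are ratios of like-units concentrations, hence invariant to a
    common rescaling of the biomass pools.
    """
    floor = params.biomass_floor
    if state.Cb < floor:
        raise DegenerateStateError(
            f"phytoplankton carbon Cb={state.Cb:g} below biomass floor {floor:g}")
    if state.Cba < floor:
        raise DegenerateStateError(
            f"bacterial carbon Cba={state.Cba:g} below biomass floor {floor:g}")
    is_p = state.version is ModelVersion.P
    if state.Nba < floor * params.bacteria.QN_min:
        raise DegenerateStateError(
            f"bacterial nitrogen Nba={state.Nba:g} below biomass floor")
    return Quotas(
        QN=state.Nb / state.Cb,
        QP=(state.Pb / state.Cb) if is_p else float("nan"),
        theta=state.Chla / state.Cb,
        QC_BA=state.Cba / state.Nba,
        QN_BA=state.Nba / state.Cba,
        QP_BA=(state.Pba / state.Cba) if is_p else float("nan"),
    )


# --------------------------------------------------------------------------
# Presets

# Named initial conditions.  "oligotrophic-summer" matches the observed
# summer means of the study area (Chla 0.4 ug L-1, PO4 0.03 umol L-1,
# DIN 1 umol L-1); "winter-mixed" represents the nutrient-replete,
# mixed winter water column.
PRESETS: dict[str, dict[str, float]] = {
    "oligotrophic-summer": {
        "Cb": 1.0, "Nb": 0.15, "Chla": 0.4,
        "Cba": 0.5, "Nba": 0.10,
        "DPOC": 1.0, "DPON": 0.12, "LDOC": 2.0, "LDON": 0.2,
        "NO3": 0.8, "NH4": 0.2, "O": 240.0,
        "Pb": 0.008, "Pba": 0.008, "DPOP": 0.008, "LDOP": 0.01,
        "PO4": 0.03,
    },
    "winter-mixed": {
        "Cb": 0.8, "Nb": 0.14, "Chla": 0.3,
        "Cba": 0.4, "Nba": 0.08,
        "DPOC": 0.8, "DPON": 0.1, "LDOC": 1.5, "LDON": 0.15,
        "NO3": 2.5, "NH4": 0.3, "O": 255.0,
        "Pb": 0.008, "Pba": 0.007, "DPOP": 0.006, "LDOP": 0.008,
        "PO4": 0.12,
    },
}


def make_initial_state(version: ModelVersion, preset: str) -> StateVector:
    """Build a complete, valid state from a registered named scenario."""
    if not isinstance(version, ModelVersion):
        raise KeyError(f"unknown model version {version!r}")
    try:
        table = PRESETS[preset]
    except KeyError:
        raise KeyError(
            f"unknown preset {preset!r}; registered: {sorted(PRESETS)}"
        ) from None
    names = variables_for(version)
    return StateVector(version, np.array([table[v] for v in names]))


# --------------------------------------------------------------------------
# Validation


def validate_state(state: StateVector, params: ParameterSet,
                   theta_tol: float = 1e-9) -> list[str]:
    """Report every violated state invariant; empty list means valid."""
    violations: list[str] = []
    for name, value in state.as_dict().items():
        if not np.isfinite(value):
            violations.append(f"{name} non-finite ({value})")
        elif value < 0:
            violations.append(f"{name} negative ({value})")
    if state.Cb > params.biomass_floor:
        theta = state.Chla / state.Cb
        if theta < params.phyto.theta_min - theta_tol:
            violations.append(
                f"Chla:Cb ratio {theta:g} below theta_min "
                f"{params.phyto.theta_min:g}")
        if theta > params.phyto.theta_max + theta_tol:
            violations.append(
                f"Chla:Cb ratio {theta:g} above theta_max "
                f"{params.phyto.theta_max:g}")
    return violations
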