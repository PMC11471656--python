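"""Material properties, pressure regimes, inlet waveform, protocol constants.

Internally everything is SI (Pa, m, s); interfaces accept the clinical units
(mmHg, mm, cm/s) and convert at the boundary.  Blood is Newtonian with density
1062 kg/m3 and dynamic viscosity 0.0037 Pa*s (high-shear values).  The vessel
wall is isotropic linear elastic: E = 1.5 MPa (normal) or 4 MPa
(atherosclerotic), Poisson ratio 0.49 to emulate near-incompressibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import numpy as np

from .geometry import GeometryParams

__all__ = [
    "MMHG_TO_PA",
    "FluidProperties",
    "WallProperties",
    "PressureRegime",
    "PressureWaveform",
    "SimulationConfig",
    "mmhg_to_pa",
    "pa_to_mmhg",
    "make_pressure_regime",
    "make_wall_properties",
    "make_fluid",
    "build_waveform",
    "heart_rate_bpm",
    "REGIMES",
    "WALL_REGIMES",
]

MMHG_TO_PA = 133.322

#: systolic/diastolic pressures (mmHg) of the three simulated regimes
REGIMES: dict[str, tuple[float, float]] = {
    "hypotension": (100.0, 60.0),
    "normotension": (120.0, 80.0),
    "hypertension": (160.0, 100.0),
}

#: Young's moduli (Pa) of the two wall regimes
WALL_REGIMES: dict[str, float] = {
    "normal": 1.5e6,
    "atherosclerotic": 4.0e6,
}


def mmhg_to_pa(p: float) -> float:
    """Convert pressure from mmHg to Pa (1 mmHg = 133.322 Pa)."""
    return p * MMHG_TO_PA


def pa_to_mmhg(p: float) -> float:
    return p / MMHG_TO_PA


def heart_rate_bpm(period_s: float) -> int:
    """Heart rate (integer bpm) for a cardiac cycle of `period_s` seconds."""
    if period_s <= 0:
        raise ValueError("period must be positive")
    return int(round(60.0 / period_s))


@dataclass(frozen=True)
class FluidProperties:
    density: float = 1062.0  # kg/m^3
    viscosity: float = 0.0037  # Pa*s

    def __post_init__(self) -> None:
        if self.density <= 0 or self.viscosity <= 0:
            raise ValueError("fluid properties must be positive")

    @property
    def kinematic_viscosity(self) -> float:
        return self.viscosity / self.density


@dataclass(frozen=True)
class WallProperties:
    youngs_modulus: float  # Pa
    poisson_ratio: float = 0.49
    regime: str = "normal"

    def __post_init__(self) -> None:
        if not 0.0 < self.poisson_ratio < 0.5:
            raise ValueError("Poisson ratio must lie in (0, 0.5)")
        if self.youngs_modulus <= 0:
            raise ValueError("Young's modulus must be positive")

    @property
    def plane_strain_modulus(self) -> float:
        """E / (1 - nu^2), the effective modulus for plane-strain bending."""
        return self.youngs_modulus / (1.0 - self.poisson_ratio**2)


def make_fluid() -> FluidProperties:
    return FluidProperties()


def make_wall_properties(tag: str) -> WallProperties:
    if tag not in WALL_REGIMES:
        raise KeyError(f"unknown wall regime {tag!r}; expected one of {sorted(WALL_REGIMES)}")
    return WallProperties(youngs_modulus=WALL_REGIMES[tag], regime=tag)


@dataclass(frozen=True)
class PressureRegime:
    name: str
    systolic: float  # mmHg
    diastolic: float  # mmHg
    outlet_offset: float = 10.0  # mmHg below diastolic

    def __post_init__(self) -> None:
        if not self.systolic > self.diastolic > self.outlet_pressure:
            raise ValueError("require systolic > diastolic > outlet pressure")

    @property
    def outlet_pressure(self) -> float:
        """Static outlet pressure (mmHg): diastolic minus the offset."""
        return self.diastolic - self.outlet_offset


def make_pressure_regime(name: str) -> PressureRegime:
    if name not in REGIMES:
        raise KeyError(f"unknown pressure regime {name!r}; expected one of {sorted(REGIMES)}")
    sys_p, dia_p = REGIMES[name]
    return PressureRegime(name=name, systolic=sys_p, diastolic=dia_p)


@dataclass(frozen=True)
class PressureWaveform:
    """Periodic inlet pressure p(t) in Pa.

    The default template is a quarter-sine systolic upstroke over
    ``systolic_fraction * T`` followed by a normalized exponential diastolic
    decay returning exactly to the diastolic pressure, so the stated extrema
    are hit exactly and p(0) == p(T).
    """

    regime: PressureRegime
    period: float = 0.86  # s
    systolic_fraction: float = 0.35
    decay_tau: float = 0.3  # diastolic decay constant, fraction of diastole
    template: str = "sine-exp"

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError("period must be positive")
        if not 0.0 < self.systolic_fraction < 1.0:
            raise ValueError("systolic_fraction must lie in (0,1)")
        if self.decay_tau <= 0:
            raise ValueError("decay_tau must be positive")
        if self.template != "sine-exp":
            raise ValueError(f"unknown waveform template {self.template!r}")

    # normalized template phi(t'): 0 at cycle start, 1 at end of systole,
    # back to 0 at cycle end
    def _phi(self, tp: np.ndarray) -> np.ndarray:
        sT = self.systolic_fraction * self.period
        dT = self.period - sT
        tau = self.decay_tau
        up = np.sin(0.5 * np.pi * tp / sT)
        u = (tp - sT) / dT
        e = (np.exp(-u / tau) - np.exp(-1.0 / tau)) / (1.0 - np.exp(-1.0 / tau))
        return np.where(tp <= sT, up, e)

    def __call__(self, t: np.ndarray | float) -> np.ndarray | float:
        tp = np.mod(np.asarray(t, dtype=float), self.period)
        p_dia = mmhg_to_pa(self.regime.diastolic)
        p_sys = mmhg_to_pa(self.regime.systolic)
        out = p_dia + (p_sys - p_dia) * self._phi(tp)
        return float(out) if np.isscalar(t) else out

    def mean(self) -> float:
        """Analytic cycle mean of p(t) in Pa."""
        s = self.systolic_fraction
        tau = self.decay_tau
        # quarter-sine mean over systole: (2/pi)
        m_sys = 2.0 / np.pi
        # normalized exponential mean over diastole
        em1 = np.exp(-1.0 / tau)
        m_dia = (tau * (1.0 - em1) - em1) / (1.0 - em1)
        phi_mean = s * m_sys + (1.0 - s) * m_dia
        p_dia = mmhg_to_pa(self.regime.diastolic)
        p_sys = mmhg_to_pa(self.regime.systolic)
        return p_dia + (p_sys - p_dia) * phi_mean

    @property
    def systole_end(self) -> float:
        return self.systolic_fraction * self.period


def build_waveform(regime: PressureRegime, period: float = 0.86,
                   systolic_fraction: float = 0.35,
                   decay_tau: float = 0.3) -> PressureWaveform:
    return PressureWaveform(regime=regime, period=period,
                            systolic_fraction=systolic_fraction,
                            decay_tau=decay_tau)


@dataclass
class TimeStepPolicy:
    cfl: float = 0.4
    dt_max: float = 2.0e-4  # s
    min_samples_per_cycle: int = 200

    def __post_init__(self) -> None:
        if not 0.0 < self.cfl < 1.0:
            raise ValueError("CFL must lie in (0,1)")


@dataclass
class CouplingSettings:
    """Partitioned FSI sub-iteration control."""

    max_subiterations: int = 8
    # interface residual tolerance as a fraction of the parent lumen width
    tolerance_fraction: float = 1e-4
    relaxation: str = "aitken"
    initial_relaxation: float = 0.5

    def __post_init__(self) -> None:
        if self.max_subiterations < 1:
            raise ValueError("need at least one sub-iteration")
        if self.tolerance_fraction <= 0:
            raise ValueError("tolerance must be positive")


@dataclass
class SimulationConfig:
    """Everything needed to reproduce one pulsatile FSI run."""

    geometry: GeometryParams | None = None
    regime_name: str = "normotension"
    wall_tag: str = "normal"
    fluid: FluidProperties = field(default_factory=make_fluid)
    period: float = 0.86
    systolic_fraction: float = 0.35
    n_cycles: int = 3
    analysis_cycle: int = 3
    grid_dx: float = 0.5  # mm
    timestep: TimeStepPolicy = field(default_factory=TimeStepPolicy)
    coupling: CouplingSettings = field(default_factory=CouplingSettings)
    output_stride_per_cycle: int = 256
    probe_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.geometry is None:
            self.geometry = GeometryParams()
        if self.n_cycles < 1:
            raise ValueError("need at least one cycle")
        if not 1 <= self.analysis_cycle <= self.n_cycles:
            raise ValueError("analysis_cycle must lie within the simulated cycles")
        _ = make_pressure_regime(self.regime_name)
        _ = make_wall_properties(self.wall_tag)

    @property
    def regime(self) -> PressureRegime:
        return make_pressure_regime(self.regime_name)

    @property
    def wall(self) -> WallProperties:
        return make_wall_properties(self.wall_tag)

    def waveform(self) -> PressureWaveform:
        return build_waveform(self.regime, self.period, self.systolic_fraction)

    # -- config file round trip -------------------------------------------
    def to_dict(self) -> dict:
        from dataclasses import is_dataclass

        def conv(obj):
            if is_dataclass(obj) and not isinstance(obj, type):
                return {k: conv(v) for k, v in asdict(obj).items()}
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        d = {
            "geometry": conv(self.geometry),
            "regime_name": self.regime_name,
            "wall_tag": self.wall_tag,
            "fluid": conv(self.fluid),
            "period": self.period,
            "systolic_fraction": self.systolic_fraction,
            "n_cycles": self.n_cycles,
            "analysis_cycle": self.analysis_cycle,
            "grid_dx": self.grid_dx,
            "timestep": conv(self.timestep),
            "coupling": conv(self.coupling),
            "output_stride_per_cycle": self.output_stride_per_cycle,
            "probe_names": list(self.probe_names),
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "geometry" in d and isinstance(d["geometry"], dict):
            d["geometry"] = GeometryParams(**d["geometry"])
        if "fluid" in d and isinstance(d["fluid"], dict):
            d["fluid"] = FluidProperties(**d["fluid"])
        if "timestep" in d and isinstance(d["timestep"], dict):
            d["timestep"] = TimeStepPolicy(**d["timestep"])
        if "coupling" in d and isinstance(d["coupling"], dict):
            d["coupling"] = CouplingSettings(**d["coupling"])
        if "probe_names" in d:
            d["probe_names"] = tuple(d["probe_names"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
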