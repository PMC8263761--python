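"""Parameter and geometry containers for the multi-scale Ulva cultivation model.

Units follow the governing mass balances: biomass density m in gDW l⁻¹,
internal nitrogen quota N_int in % gN gDW⁻¹, dissolved nitrogen (N_ext,
N_env) in μmol-N l⁻¹ (μM-N), rates in h⁻¹, irradiance in
μmol photons m⁻² s⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

__all__ = [
    "GrowthParameters",
    "ReactorGeometry",
    "PumpSetting",
    "EnvironmentSample",
    "CALIBRATED",
    "QUOTA_PER_UMOL",
    "DW_PER_FW",
]

# Unit bridge: 1 μmol-N gDW⁻¹ of uptake adds 14e-6 gN gDW⁻¹ = 14e-4 % gN gDW⁻¹
# to the internal quota (atomic mass of N = 14 g mol⁻¹).
QUOTA_PER_UMOL: float = 14.0e-4

# Dry-weight fraction of fresh weight used to convert stocking densities
# quoted in kg FW m⁻³ into gDW l⁻¹. Typical for Ulva sp. (80-90 % water).
DW_PER_FW: float = 0.15


@dataclass(frozen=True)
class GrowthParameters:
    """Kinetic and limitation constants of the thallus-scale metabolic model.

    Defaults are the calibrated reactor-scale values (T_opt = 18 °C,
    T_max = 31.5 °C, K_I = 20 μmol photons m⁻² s⁻¹, λ20 = 0.16 % per light
    hour, K_a = 0.15 m² gDW⁻¹) completed with literature-typical values for
    the constants the calibration does not pin down.
    """

    mu_max: float = 0.025          # maximum specific growth rate, h⁻¹
    K_I: float = 20.0              # light half-saturation, μmol photons m⁻² s⁻¹
    T_opt: float = 18.0            # optimal temperature, °C
    T_max: float = 31.5            # lethal/maximal temperature, °C
    n: float = 2.0                 # temperature-response shape exponent
    lambda_20: float = 0.0016      # specific loss rate at 20 °C, h⁻¹ (light hours)
    theta: float = 1.05            # empiric loss temperature factor
    N_int_min: float = 1.0         # subsistence quota, % gN gDW⁻¹
    N_int_max: float = 5.5         # storage quota, % gN gDW⁻¹
    N_int_crit: float = 2.0        # critical quota below which growth slows
    V_max: float = 80.0            # maximum N uptake rate, μmol-N gDW⁻¹ h⁻¹
    K_S: float = 5.0               # uptake half-saturation, μmol-N l⁻¹
    par_fraction: float = 0.43     # photosynthetically active fraction of sunlight
    K_0: float = 0.4               # water light-extinction coefficient, m⁻¹
    K_a: float = 0.15              # biomass light-extinction coefficient, m² gDW⁻¹
    S_opt: float = 25.0            # optimal salinity, PSU
    S_sigma: float = 20.0          # salinity tolerance width, PSU

    def __post_init__(self) -> None:
        if not 0.0 < self.N_int_min < self.N_int_crit < self.N_int_max:
            raise ValueError(
                "quota bounds must satisfy 0 < N_int_min < N_int_crit < N_int_max"
            )
        if not self.T_opt < self.T_max:
            raise ValueError("T_opt must be below T_max")
        for name in ("mu_max", "K_I", "lambda_20", "V_max", "K_S", "K_0", "K_a",
                     "n", "theta", "S_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 < self.par_fraction <= 1.0:
            raise ValueError("par_fraction must lie in (0, 1]")

    def replace(self, **changes: float) -> "GrowthParameters":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **changes)

    @classmethod
    def field_names(cls) -> list[str]:
        return [f.name for f in fields(cls)]


@dataclass(frozen=True)
class ReactorGeometry:
    """Geometry of one well-mixed cage reactor.

    Defaults describe the 1.785 m³ U-shape bottom-aerated sea cage with a
    2 m² illuminated surface; the effective optical depth Z defaults to
    V_cage / illuminated_area.
    """

    V_cage: float = 1.785          # water volume, m³
    illuminated_area: float = 2.0  # illuminated surface area, m²
    Z: float | None = None         # maximum water depth, m

    def __post_init__(self) -> None:
        if self.V_cage <= 0 or self.illuminated_area <= 0:
            raise ValueError("V_cage and illuminated_area must be positive")
        if self.Z is None:
            object.__setattr__(self, "Z", self.V_cage / self.illuminated_area)
        if self.Z <= 0:
            raise ValueError("Z must be positive")

    @property
    def volume_l(self) -> float:
        """Cage volume in litres."""
        return self.V_cage * 1000.0


@dataclass(frozen=True)
class PumpSetting:
    """Airlift pump operating point: water-exchange flow Q_p in l h⁻¹."""

    Q_p: float = 460.0

    def __post_init__(self) -> None:
        if self.Q_p < 0:
            raise ValueError("Q_p must be non-negative")


@dataclass(frozen=True)
class EnvironmentSample:
    """One hourly sample of the constraining environmental conditions."""

    T: float                       # water temperature, °C
    S: float                       # salinity, PSU
    I0: float                      # surface irradiance, μmol photons m⁻² s⁻¹
    is_light_hour: bool = field(default=True)

    def __post_init__(self) -> None:
        if self.I0 < 0:
            raise ValueError("I0 must be non-negative")
        if not self.is_light_hour and self.I0 != 0:
            raise ValueError("I0 must be zero outside light hours")


#: The calibrated reactor-scale parameter set (module-wide default).
CALIBRATED = GrowthParameters()
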