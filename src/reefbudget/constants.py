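"""Model constants for the carbonate-budget equations.

All rate constants used by :mod:`reefbudget.budget` live in one immutable
object so that a run's parameterization can be audited and overridden only
explicitly (via :func:`BudgetConstants.replace` or the YAML ``constants:``
block read by the pipeline).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field


@dataclass(frozen=True)
class BudgetConstants:
    """Empirical constants of the budget model.

    Units are embedded in the field docs; every value is positive unless the
    underlying regression has a negative coefficient (logistic intercept of
    the scar model, length slope of the bite-rate model, etc.).
    """

    # Coralline algae: gross production per unit planar cover, g cm^-2 y^-1,
    # times 10 converts (g cm^-2) x (% cover) to kg m^-2 y^-1.
    cca_rate: float = 0.018

    # Sediment contribution cap, kg CaCO3 m^-2 y^-1, and its sign (+1 for
    # low-sedimentation reefs, -1 where sedimentation smothers accretion).
    sediment_max: float = 0.4
    sediment_sign: int = 1

    # Macroboring erosion constant, kg CaCO3 m^-2 y^-1 at 100% borer cover.
    mec: float = 10.0

    # Parrotfish bite volume: vol = exp(a + b * length) / mm3_per_cm3, cm^3.
    bite_vol_intercept: float = 1.32
    bite_vol_slope: float = 0.06
    mm3_per_cm3: float = 1000.0

    # Scar proportion logistic: 1 / (1 + exp(-(a + b * length))).
    scar_intercept: float = -2.46
    scar_slope: float = 0.089

    # Bite rate, bites day^-1: 60 * ((4.31 + brc - 0.36) - 0.045*reeftime*L).
    bite_rate_scale: float = 60.0
    bite_rate_base: float = 4.31
    bite_rate_offset: float = 0.36
    bite_rate_length_coef: float = 0.045
    reeftime_h: float = 9.0

    # Echinoid erosion allometries: coef * diameter^exponent * 0.365 * 0.57,
    # kg CaCO3 individual^-1 y^-1.
    urchin_coefs: dict = field(
        default_factory=lambda: {
            "Diadema": (1e-6, 3.42),
            "Echinometra": (4e-4, 1.98),
            "Other": (1e-4, 2.32),
        }
    )
    urchin_day_to_year: float = 0.365  # 365 d y^-1 * 0.001 g->kg
    urchin_substrate_frac: float = 0.57

    # Parrotfish unit conversions: days per year and g -> kg.
    days_per_year: float = 365.0
    g_to_kg: float = 0.001

    # Eq 2 / Eq 3 unit adjustment: (g cm^-3)(cm y^-1) cover -> kg m^-2 y^-1.
    unit_factor: float = 10.0

    # Fallback mean coral skeletal density when a site has no live coral.
    default_coral_density: float = 1.5

    # Survey geometry (per transect).
    tape_length_cm: float = 1000.0
    fish_area_m2: float = 120.0  # 30 m x 4 m video transect
    urchin_area_m2: float = 6.0  # 10 m x 0.6 m belt

    def __post_init__(self) -> None:
        # Unit sanity: 365 d/y * 0.001 kg/g must equal the echinoid 0.365.
        if abs(self.days_per_year * self.g_to_kg - self.urchin_day_to_year) > 1e-12:
            raise ValueError(
                "inconsistent unit factors: days_per_year * g_to_kg "
                f"= {self.days_per_year * self.g_to_kg} != {self.urchin_day_to_year}"
            )
        for name in ("cca_rate", "sediment_max", "mec", "reeftime_h",
                     "unit_factor", "tape_length_cm", "fish_area_m2",
                     "urchin_area_m2", "default_coral_density"):
            if getattr(self, name) <= 0:
                raise ValueError(f"constant {name} must be positive")
        if self.sediment_sign not in (-1, 1):
            raise ValueError("sediment_sign must be +1 or -1")

    def replace(self, **overrides) -> "BudgetConstants":
        """Return a copy with ``overrides`` applied (the only mutation path)."""
        return dataclasses.replace(self, **overrides)


#: Projected sea-level-rise rates (mm y^-1) used as keep-up benchmarks.
RCP_SLR_MM_Y = {
    "RCP2.6": 5.0,
    "RCP4.5": 6.5,
    "RCP6": 6.7,
    "RCP8.5": 9.0,
}

DEFAULT_CONSTANTS = BudgetConstants()
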