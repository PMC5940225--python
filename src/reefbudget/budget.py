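"""Census-based carbonate budget: gross calcification by corals and
coralline algae, bioerosion by parrotfish, echinoids and macroborers, the
sediment term, net production, and the conversion of carbonate production to
potential vertical reef growth.

The budget for a reef site is

    net = Cal + sgn * Sed - (parrotfish + urchin + macroboring)

with every component in kg CaCO3 m^-2 y^-1.  Gross calcification scales
planar cover up to true accreting surface with the rugosity index r and a
morphology coefficient m, and multiplies by skeletal density d (g cm^-3) and
vertical extension g (cm y^-1):

    Cal = r * ( sum_j m_j * (x_j / 100) * d_j * g_j * 10  +  ca )

where x_j is percent planar cover of coral taxon j and ca = 0.018 * pca * 10
is the coralline-algae contribution at pca percent cover.  Erosion
sub-models are allometric in fish fork length or urchin test diameter.
Budgets are evaluated per transect and averaged to the site.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import DEFAULT_CONSTANTS, RCP_SLR_MM_Y, BudgetConstants
from .survey import (SiteSurvey, SurveyDataset, TraitTable, Transect,
                     live_coral_cover, planar_cover, rugosity)

__all__ = [
    "SiteBudget", "cca_calcification", "coral_calcification",
    "bite_volume", "scar_proportion", "bite_rate", "fish_erosion_individual",
    "mean_coral_density", "parrotfish_erosion", "urchin_erosion_individual",
    "urchin_erosion", "macroborer_cover", "macroboring_erosion",
    "transect_budgets", "net_production", "dataset_budgets",
    "calibrate_alpha", "vertical_growth", "keep_up_assessment",
]


@dataclass
class SiteBudget:
    """Budget components for one site (or one transect), kg CaCO3 m^-2 y^-1."""

    site_id: str
    gross_calcification: float
    cca_component: float
    parrotfish_erosion: float
    urchin_erosion: float
    macroboring_erosion: float
    sediment: float
    mean_coral_density: float  # g cm^-3
    net_production: float = field(init=False)
    live_coral_cover: float = 0.0  # percent, carried for downstream models
    transect_id: str | None = None

    def __post_init__(self) -> None:
        for name in ("parrotfish_erosion", "urchin_erosion", "macroboring_erosion"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        self.net_production = (
            self.gross_calcification + self.sediment - self.total_erosion
        )

    @property
    def total_erosion(self) -> float:
        return (self.parrotfish_erosion + self.urchin_erosion
                + self.macroboring_erosion)

    @property
    def net_erosion(self) -> bool:
        """True when the site is losing carbonate (negative net production)."""
        return self.net_production < 0


# ---------------------------------------------------------------------------
# Calcification
# ---------------------------------------------------------------------------

def cca_calcification(pca_percent: float,
                      constants: BudgetConstants = DEFAULT_CONSTANTS) -> float:
    """Coralline-algae carbonate production from percent planar cover."""
    if not 0.0 <= pca_percent <= 100.0:
        raise ValueError(f"pca must be in [0, 100] percent, got {pca_percent}")
    return constants.cca_rate * pca_percent * constants.unit_factor


def coral_calcification(transect: Transect, traits: TraitTable,
                        r: float | None = None,
                        constants: BudgetConstants = DEFAULT_CONSTANTS) -> tuple[float, float]:
    """Gross calcification on one transect.

    Returns ``(Cal, ca)``: the rugosity-corrected total including the
    coralline-algae term, and the CCA term itself (pre-rugosity).
    """
    if r is None:
        r = rugosity(transect)
    total = 0.0
    for itc in transect.intercepts:
        if itc.category != "coral":
            continue
        t = traits.lookup(itc.taxon_code)
        x = 100.0 * itc.chord_cm / transect.contour_length_cm
        total += t.m * (x / 100.0) * t.d * t.g * constants.unit_factor
    ca = cca_calcification(planar_cover(transect, "coralline_algae"), constants)
    return r * (total + ca), ca


# ---------------------------------------------------------------------------
# Parrotfish erosion (allometric sub-models in fork length, cm)
# ---------------------------------------------------------------------------

def bite_volume(length_cm: float,
                constants: BudgetConstants = DEFAULT_CONSTANTS) -> float:
    """Volume of carbonate removed per bite (cm^3), exponential in length."""
    if length_cm <= 0:
        raise ValueError("fish length must be positive")
    return math.exp(constants.bite_vol_intercept
                    + constants.bite_vol_slope * length_cm) / constants.mm3_per_cm3


def scar_proportion(length_cm: float,
                    constants: BudgetConstants = DEFAULT_CONSTANTS) -> float:
    """Proportion of bites that leave a grazing scar; logistic in length."""
    if length_cm <= 0:
        raise ValueError("fish length must be positive")
    z = constants.scar_intercept + constants.scar_slope * length_cm
    return 1.0 / (1.0 + math.exp(-z))


def bite_rate(length_cm: float, brc: float,
              constants: BudgetConstants = DEFAULT_CONSTANTS) -> float:
    """Bites per day for a fish of given length and species bite-rate
    constant; the fitted line goes negative for large fish with small brc,
    which we clamp at zero (a fish cannot erode negatively)."""
    if length_cm <= 0:
        raise ValueError("fish length must be positive")
    raw = constants.bite_rate_scale * (
        (constants.bite_rate_base + brc - constants.bite_rate_offset)
        - constants.bite_rate_length_coef * constants.reeftime_h * length_cm
    )
    return max(0.0, raw)


def fish_erosion_individual(length_cm: float, brc: float, coral_density: float,
                            constants: BudgetConstants = DEFAULT_CONSTANTS) -> float:
    """Annual erosion by one parrotfish (kg CaCO3 y^-1):
    bite volume x scar proportion x bite rate x substrate density,
    days -> year and g -> kg."""
    return (bite_volume(length_cm, constants)
            * scar_proportion(length_cm, constants)
            * bite_rate(length_cm, brc, constants)
            * coral_density * constants.days_per_year * constants.g_to_kg)


def mean_coral_density(site: SiteSurvey, traits: TraitTable,
                       constants: BudgetConstants = DEFAULT_CONSTANTS) -> float:
    """Cover-weighted mean skeletal density of live coral at a site
    (g cm^-3); falls back to a configurable default on coral-free sites."""
    wsum = 0.0
    dsum = 0.0
    for t in site.transects:
        for itc in t.intercepts:
            if itc.category == "coral":
                tr = traits.lookup(itc.taxon_code)
                wsum += itc.chord_cm
                dsum += itc.chord_cm * tr.d
    if wsum == 0.0:
        return constants.default_coral_density
    return dsum / wsum


def parrotfish_erosion(site: SiteSurvey, traits: TraitTable,
                       constants: BudgetConstants = DEFAULT_CONSTANTS,
                       coral_density: float | None = None) -> float:
    """Site parrotfish erosion (kg CaCO3 m^-2 y^-1): summed individual
    erosion normalized by the surveyed video area (transects x 120 m^2)."""
    if not site.transects:
        warnings.warn(f"site {site.site_id}: no fish transects, erosion = 0")
        return 0.0
    if coral_density is None:
        coral_density = mean_coral_density(site, traits, constants)
    area = sum(t.fish_area_m2 for t in site.transects)
    total = sum(
        fish_erosion_individual(f.length_cm, traits.brc(f.species_code),
                                coral_density, constants)
        for f in site.fish
    )
    return total / area


# ---------------------------------------------------------------------------
# Echinoid erosion (allometric in test diameter, cm)
# ---------------------------------------------------------------------------

def urchin_erosion_individual(genus_class: str, diameter_cm: float,
                              constants: BudgetConstants = DEFAULT_CONSTANTS) -> float:
    """Annual erosion by one echinoid (kg CaCO3 y^-1), power law in test
    diameter with a genus-specific coefficient and exponent; the 0.57 factor
    restricts erosion to the carbonate fraction of grazed substrate."""
    if diameter_cm <= 0:
        raise ValueError("test diameter must be positive")
    try:
        coef, expo = constants.urchin_coefs[genus_class]
    except KeyError:
        raise ValueError(
            f"unknown urchin genus_class {genus_class!r}; "
            f"expected one of {sorted(constants.urchin_coefs)}"
        ) from None
    return (coef * diameter_cm ** expo
            * constants.urchin_day_to_year * constants.urchin_substrate_frac)


def urchin_erosion(site: SiteSurvey,
                   constants: BudgetConstants = DEFAULT_CONSTANTS) -> float:
    """Site echinoid erosion (kg CaCO3 m^-2 y^-1): summed individual erosion
    over the surveyed belt area (transects x 6 m^2)."""
    if not site.transects:
        return 0.0
    area = sum(t.urchin_area_m2 for t in site.transects)
    total = sum(
        urchin_erosion_individual(u.genus_class, u.test_diameter_cm, constants)
        for u in site.urchins
    )
    return total / area


# ---------------------------------------------------------------------------
# Macroboring and net production
# ---------------------------------------------------------------------------

def macroborer_cover(transect: Transect) -> float:
    """Planar cover of macroboring organisms as a proportion in [0, 1]."""
    return planar_cover(transect, "macroborer") / 100.0


def macroboring_erosion(plamc: float,
                        constants: BudgetConstants = DEFAULT_CONSTANTS) -> float:
    """Macroborer (clionaid sponge) erosion: proportional cover times a
    conservative erosion constant of 10 kg CaCO3 m^-2 y^-1."""
    if plamc < 0:
        raise ValueError("macroborer cover must be >= 0")
    if plamc > 1:
        raise ValueError(
            f"macroborer cover {plamc} > 1: plamc is a proportion in [0, 1]; "
            "a value above 1 suggests percent/proportion confusion"
        )
    return plamc * constants.mec


def transect_budgets(site: SiteSurvey, traits: TraitTable,
                     constants: BudgetConstants = DEFAULT_CONSTANTS) -> list[SiteBudget]:
    """Solve the budget for each transect of a site.

    Fish and urchin observations are attributed to their transect and
    normalized by that transect's surveyed area, so the mean over transects
    equals the site-level per-area rate.  The sediment term enters with the
    configured sign (positive on these low-sedimentation reefs).
    """
    density = mean_coral_density(site, traits, constants)
    sed = constants.sediment_sign * constants.sediment_max
    fish_by_t: dict[str, list] = {}
    for f in site.fish:
        fish_by_t.setdefault(f.transect_id, []).append(f)
    urch_by_t: dict[str, list] = {}
    for u in site.urchins:
        urch_by_t.setdefault(u.transect_id, []).append(u)

    out = []
    for t in site.transects:
        cal, ca = coral_calcification(t, traits, constants=constants)
        fish_tot = sum(
            fish_erosion_individual(f.length_cm, traits.brc(f.species_code),
                                    density, constants)
            for f in fish_by_t.get(t.transect_id, ())
        )
        urch_tot = sum(
            urchin_erosion_individual(u.genus_class, u.test_diameter_cm, constants)
            for u in urch_by_t.get(t.transect_id, ())
        )
        out.append(SiteBudget(
            site_id=site.site_id,
            transect_id=t.transect_id,
            gross_calcification=cal,
            cca_component=ca,
            parrotfish_erosion=fish_tot / t.fish_area_m2,
            urchin_erosion=urch_tot / t.urchin_area_m2,
            macroboring_erosion=macroboring_erosion(macroborer_cover(t), constants),
            sediment=sed,
            mean_coral_density=density,
            live_coral_cover=planar_cover(t, "coral"),
        ))
    return out


def net_production(site: SiteSurvey, traits: TraitTable,
                   constants: BudgetConstants = DEFAULT_CONSTANTS) -> SiteBudget:
    """Site budget: per-transect budgets averaged over the site's transects."""
    per_t = transect_budgets(site, traits, constants)
    n = len(per_t)
    mean = lambda attr: sum(getattr(b, attr) for b in per_t) / n  # noqa: E731
    return SiteBudget(
        site_id=site.site_id,
        gross_calcification=mean("gross_calcification"),
        cca_component=mean("cca_component"),
        parrotfish_erosion=mean("parrotfish_erosion"),
        urchin_erosion=mean("urchin_erosion"),
        macroboring_erosion=mean("macroboring_erosion"),
        sediment=mean("sediment"),
        mean_coral_density=per_t[0].mean_coral_density,
        live_coral_cover=live_coral_cover(site),
    )


def dataset_budgets(ds: SurveyDataset, traits: TraitTable,
                    constants: BudgetConstants = DEFAULT_CONSTANTS,
                    per_transect: bool = False) -> list[SiteBudget]:
    """Budgets for every site (or every transect) in a dataset."""
    if per_transect:
        return [b for s in ds.sites for b in transect_budgets(s, traits, constants)]
    return [net_production(s, traits, constants) for s in ds.sites]


# ---------------------------------------------------------------------------
# Vertical growth and keep-up assessment
# ---------------------------------------------------------------------------

def calibrate_alpha(pairs) -> float:
    """Least-squares estimate of the vertical-growth coefficient alpha from
    (carbonate production kg m^-2 y^-1, vertical growth mm y^-1) pairs.

    The conversion is v = Cp + Cp * (Cp * alpha) = Cp + alpha * Cp^2, linear
    in alpha, so the estimate is closed form:
    alpha = sum Cp^2 (v - Cp) / sum Cp^4.
    """
    cp = np.asarray([p[0] for p in pairs], dtype=float)
    v = np.asarray([p[1] for p in pairs], dtype=float)
    if cp.size == 0 or np.all(cp == 0):
        raise ValueError("alpha is unidentifiable: need at least one pair with Cp > 0")
    denom = np.sum(cp ** 4)
    return float(np.sum(cp ** 2 * (v - cp)) / denom)


def vertical_growth(cp: float, alpha: float) -> float:
    """Potential vertical reef growth (mm y^-1) from carbonate production
    Cp (kg CaCO3 m^-2 y^-1): v = Cp + Cp*(Cp*alpha).

    For alpha < 0 the parabola peaks at Cp = -1/(2*alpha); beyond the apex
    the fitted curve would (unphysically) decrease, so the value is clamped
    at the apex with a warning.
    """
    if cp < 0:
        raise ValueError("carbonate production must be >= 0")
    if alpha < 0:
        apex = -1.0 / (2.0 * alpha)
        if cp > apex:
            warnings.warn(
                f"Cp = {cp:.3g} beyond the calibrated apex {apex:.3g}; "
                "vertical growth clamped at the apex value"
            )
            cp = apex
    return cp + cp * (cp * alpha)


def keep_up_assessment(vertical_mm: float, scenario: str) -> tuple[bool, float]:
    """Can a reef accreting ``vertical_mm`` per year keep up with the
    sea-level-rise rate of an RCP scenario?  Returns (verdict, margin);
    equality counts as keeping up."""
    try:
        rate = RCP_SLR_MM_Y[scenario]
    except KeyError:
        raise ValueError(
            f"unknown scenario {scenario!r}; expected one of {sorted(RCP_SLR_MM_Y)}"
        ) from None
    margin = vertical_mm - rate
    return margin >= 0.0, margin
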