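"""Survey domain model: line-intercept benthos, rugosity lines, parrotfish
video transects and echinoid belts, with validated CSV input/output.

The survey design mirrors a stratified random reef census: sites stratified
by habitat within each island, six 10 m contour-following line-intercept
transects per site (with a paired straight horizontal line for rugosity),
six 30 m x 4 m fish video transects and six 10 m x 0.6 m urchin belts.

CSV schemas (UTF-8, comma separated, header mandatory, WGS84 decimal
degrees):

- ``benthic.csv``  site_id,transect_id,taxon_code,category,morphology_code,chord_cm
- ``fish.csv``     site_id,transect_id,species_code,length_cm
- ``urchins.csv``  site_id,transect_id,genus_class,test_diameter_cm
- ``sites.csv``    site_id,island,habitat,lat,lon
- ``rugosity.csv`` site_id,transect_id,contour_length_cm,horizontal_length_cm
- ``traits.csv``   taxon_code,m,d,g,brc
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

__all__ = [
    "CATEGORIES", "ISLANDS", "HABITATS",
    "SchemaError", "ReferentialError", "SurveyValidationError",
    "BenthicIntercept", "Transect", "ParrotfishObs", "UrchinObs",
    "SiteSurvey", "SurveyDataset", "TaxonTraits", "TraitTable",
    "rugosity", "planar_cover", "live_coral_cover",
    "read_survey_dataset", "write_survey_dataset", "read_trait_table",
]

CATEGORIES = ("coral", "coralline_algae", "macroborer", "other")
ISLANDS = ("Palau", "Yap")
HABITATS = ("outer_west", "outer_east", "patch", "inner")

#: Yap's lagoon is narrow and supports only rare patch reefs; the design has
#: no Yap patch stratum.
LEGAL_HABITATS = {
    "Palau": frozenset(HABITATS),
    "Yap": frozenset(("outer_west", "outer_east", "inner")),
}

TAPE_LENGTH_CM = 1000.0
TAPE_TOLERANCE_CM = 1.0
RUGOSITY_CLAMP_EPS = 1e-6


class SchemaError(ValueError):
    """A CSV is missing a required column."""


class ReferentialError(ValueError):
    """A foreign key (e.g. transect -> site) does not resolve."""


class SurveyValidationError(ValueError):
    """A record violates a domain invariant."""


@dataclass
class BenthicIntercept:
    transect_id: str
    taxon_code: str
    category: str
    morphology_code: str
    chord_cm: float

    def validate(self) -> None:
        if self.category not in CATEGORIES:
            raise SurveyValidationError(
                f"benthic category {self.category!r} not one of {CATEGORIES}"
            )
        if not self.chord_cm > 0:
            raise SurveyValidationError(
                f"chord_cm must be > 0, got {self.chord_cm} "
                f"(taxon {self.taxon_code}, transect {self.transect_id})"
            )


@dataclass
class ParrotfishObs:
    transect_id: str
    species_code: str
    length_cm: float

    def validate(self) -> None:
        if not (1.0 < self.length_cm < 150.0):
            raise SurveyValidationError(
                f"parrotfish length_cm must be in (1, 150), got {self.length_cm}"
            )


@dataclass
class UrchinObs:
    transect_id: str
    genus_class: str
    test_diameter_cm: float

    def validate(self) -> None:
        if self.genus_class not in ("Diadema", "Echinometra", "Other"):
            raise SurveyValidationError(
                f"genus_class {self.genus_class!r} not Diadema/Echinometra/Other"
            )
        if not (0.1 < self.test_diameter_cm < 25.0):
            raise SurveyValidationError(
                f"test_diameter_cm must be in (0.1, 25), got {self.test_diameter_cm}"
            )


@dataclass
class Transect:
    transect_id: str
    site_id: str
    contour_length_cm: float = TAPE_LENGTH_CM
    horizontal_length_cm: float = TAPE_LENGTH_CM
    intercepts: list[BenthicIntercept] = field(default_factory=list)
    fish_area_m2: float = 120.0
    urchin_area_m2: float = 6.0

    def validate(self) -> None:
        if self.contour_length_cm <= 0 or self.horizontal_length_cm <= 0:
            raise SurveyValidationError(
                f"transect {self.transect_id}: tape lengths must be positive"
            )
        if self.fish_area_m2 <= 0 or self.urchin_area_m2 <= 0:
            raise SurveyValidationError(
                f"transect {self.transect_id}: survey areas must be positive"
            )
        for itc in self.intercepts:
            itc.validate()
        total = sum(i.chord_cm for i in self.intercepts)
        if total > self.contour_length_cm + TAPE_TOLERANCE_CM:
            raise SurveyValidationError(
                f"transect {self.transect_id}: intercepted chords sum to "
                f"{total:.1f} cm, exceeding the {self.contour_length_cm:.0f} cm tape"
            )


@dataclass
class SiteSurvey:
    site_id: str
    island: str
    habitat: str
    lat: float
    lon: float
    transects: list[Transect] = field(default_factory=list)
    fish: list[ParrotfishObs] = field(default_factory=list)
    urchins: list[UrchinObs] = field(default_factory=list)

    def validate(self) -> None:
        if self.island not in ISLANDS:
            raise SurveyValidationError(f"unknown island {self.island!r}")
        if self.habitat not in LEGAL_HABITATS[self.island]:
            raise SurveyValidationError(
                f"habitat {self.habitat!r} is not surveyed on {self.island} "
                f"(site {self.site_id})"
            )
        if not 1 <= len(self.transects) <= 6:
            raise SurveyValidationError(
                f"site {self.site_id}: expected 1-6 transects, got {len(self.transects)}"
            )
        tids = {t.transect_id for t in self.transects}
        if len(tids) != len(self.transects):
            raise SurveyValidationError(f"site {self.site_id}: duplicate transect ids")
        for t in self.transects:
            t.validate()
        for obs in (*self.fish, *self.urchins):
            obs.validate()
            if obs.transect_id not in tids:
                raise ReferentialError(
                    f"observation references unknown transect {obs.transect_id!r} "
                    f"at site {self.site_id}"
                )

    @property
    def habitat_label(self) -> str:
        """Five-level island x habitat label (outer strata pooled), e.g. 'P-outer'."""
        prefix = "P" if self.island == "Palau" else "Y"
        hab = "outer" if self.habitat.startswith("outer") else self.habitat
        return f"{prefix}-{hab}"


@dataclass
class SurveyDataset:
    sites: list[SiteSurvey]

    def validate(self) -> None:
        ids = [s.site_id for s in self.sites]
        if len(set(ids)) != len(ids):
            raise SurveyValidationError("duplicate site_id in dataset")
        for s in self.sites:
            s.validate()

    def site(self, site_id: str) -> SiteSurvey:
        for s in self.sites:
            if s.site_id == site_id:
                return s
        raise KeyError(site_id)

    def stratum_counts(self) -> dict[tuple[str, str], int]:
        out: dict[tuple[str, str], int] = {}
        for s in self.sites:
            key = (s.island, s.habitat)
            out[key] = out.get(key, 0) + 1
        return out


@dataclass(frozen=True)
class TaxonTraits:
    """Per-taxon calcification traits.

    m: morphological adjustment coefficient (dimensionless, >0) converting
       planar cover of a growth form to accreting surface;
    d: skeletal bulk density, g cm^-3;
    g: vertical extension rate, cm y^-1;
    brc: bite-rate constant (parrotfish species only).
    """

    taxon_code: str
    m: float
    d: float
    g: float
    brc: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.m > 0:
            raise SurveyValidationError(f"{self.taxon_code}: m must be > 0")
        if not (0.5 < self.d < 3.0):
            raise SurveyValidationError(
                f"{self.taxon_code}: density {self.d} outside plausible (0.5, 3.0) g cm^-3"
            )
        if self.g < 0:
            raise SurveyValidationError(f"{self.taxon_code}: growth g must be >= 0")


class TraitTable:
    """Lookup of :class:`TaxonTraits` by taxon code.

    ``permissive=True`` substitutes a genus-level default (the mean trait of
    taxa sharing the code's genus prefix before ``_``) with a warning instead
    of raising on an unknown taxon.
    """

    def __init__(self, traits: Iterable[TaxonTraits], permissive: bool = False):
        self._traits = {t.taxon_code: t for t in traits}
        self.permissive = permissive

    def __contains__(self, taxon_code: str) -> bool:
        return taxon_code in self._traits

    def __iter__(self):
        return iter(self._traits.values())

    def lookup(self, taxon_code: str) -> TaxonTraits:
        if taxon_code in self._traits:
            return self._traits[taxon_code]
        if self.permissive:
            genus = taxon_code.split("_")[0]
            kin = [t for c, t in self._traits.items() if c.split("_")[0] == genus]
            if kin:
                warnings.warn(
                    f"taxon {taxon_code!r} missing from trait table; "
                    f"substituting genus-level mean of {len(kin)} {genus!r} taxa"
                )
                return TaxonTraits(
                    taxon_code,
                    m=sum(t.m for t in kin) / len(kin),
                    d=sum(t.d for t in kin) / len(kin),
                    g=sum(t.g for t in kin) / len(kin),
                )
        raise LookupError(f"no traits for taxon {taxon_code!r}")

    def brc(self, species_code: str) -> float:
        t = self.lookup(species_code)
        if t.brc is None:
            raise LookupError(f"no bite-rate constant (brc) for {species_code!r}")
        return t.brc


# ---------------------------------------------------------------------------
# Derived per-transect quantities
# ---------------------------------------------------------------------------

def rugosity(transect: Transect) -> float:
    """Topographic-complexity index: contour tape length over horizontal
    chord length (dimensionless, >= 1 for a tape draped over relief).

    Measurement noise can leave the ratio a hair below 1; values in
    ``[1 - eps, 1)`` are clamped to 1, anything lower is an error.
    """
    if transect.horizontal_length_cm <= 0:
        raise SurveyValidationError(
            f"transect {transect.transect_id}: horizontal length must be > 0"
        )
    r = transect.contour_length_cm / transect.horizontal_length_cm
    if r < 1.0 - RUGOSITY_CLAMP_EPS:
        raise SurveyValidationError(
            f"transect {transect.transect_id}: rugosity {r:.4f} < 1 "
            "(contour tape shorter than horizontal chord)"
        )
    return max(r, 1.0)


def planar_cover(transect: Transect, selector: str) -> float:
    """Percent planar cover of a taxon code or category on one transect.

    100 x (sum of matching chord lengths) / tape length; empty selection is 0.
    """
    if selector in CATEGORIES:
        match = [i.chord_cm for i in transect.intercepts if i.category == selector]
    else:
        match = [i.chord_cm for i in transect.intercepts if i.taxon_code == selector]
    return 100.0 * sum(match) / transect.contour_length_cm


def live_coral_cover(site: SiteSurvey) -> float:
    """Site live coral cover (%): mean of per-transect coral planar cover."""
    if not site.transects:
        raise SurveyValidationError(f"site {site.site_id}: no transects")
    covers = [planar_cover(t, "coral") for t in site.transects]
    return sum(covers) / len(covers)


# ---------------------------------------------------------------------------
# CSV input / output
# ---------------------------------------------------------------------------

_SCHEMAS = {
    "benthic": ["site_id", "transect_id", "taxon_code", "category",
                "morphology_code", "chord_cm"],
    "fish": ["site_id", "transect_id", "species_code", "length_cm"],
    "urchins": ["site_id", "transect_id", "genus_class", "test_diameter_cm"],
    "sites": ["site_id", "island", "habitat", "lat", "lon"],
    "rugosity": ["site_id", "transect_id", "contour_length_cm",
                 "horizontal_length_cm"],
    "traits": ["taxon_code", "m", "d", "g", "brc"],
}


def _read_csv(path, kind: str) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"site_id": str, "transect_id": str},
                     float_precision="round_trip")
    missing = [c for c in _SCHEMAS[kind] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing} for {kind}.csv")
    return df


def read_trait_table(path, permissive: bool = False) -> TraitTable:
    df = _read_csv(path, "traits")
    traits = []
    for row in df.itertuples(index=False):
        brc = None if pd.isna(row.brc) else float(row.brc)
        traits.append(TaxonTraits(str(row.taxon_code), float(row.m),
                                  float(row.d), float(row.g), brc))
    return TraitTable(traits, permissive=permissive)


def read_survey_dataset(benthic_path, fish_path, urchin_path, sites_path,
                        rugosity_path=None) -> SurveyDataset:
    """Assemble and validate a :class:`SurveyDataset` from the CSV schemas.

    ``rugosity_path`` defaults to ``rugosity.csv`` next to ``benthic_path``;
    transects absent from it get flat-tape defaults (r = 1).
    """
    benthic = _read_csv(benthic_path, "benthic")
    fish = _read_csv(fish_path, "fish")
    urchins = _read_csv(urchin_path, "urchins")
    sites = _read_csv(sites_path, "sites")
    if rugosity_path is None:
        cand = Path(benthic_path).with_name("rugosity.csv")
        rugosity_path = cand if cand.exists() else None
    rug = _read_csv(rugosity_path, "rugosity") if rugosity_path is not None else None

    site_ids = set(sites["site_id"])
    for name, df in (("benthic", benthic), ("fish", fish), ("urchins", urchins)):
        unknown = set(df["site_id"]) - site_ids
        if unknown:
            raise ReferentialError(
                f"{name}.csv references unknown site_id(s) {sorted(unknown)}"
            )

    rug_map: dict[tuple[str, str], tuple[float, float]] = {}
    if rug is not None:
        for row in rug.itertuples(index=False):
            rug_map[(row.site_id, row.transect_id)] = (
                float(row.contour_length_cm), float(row.horizontal_length_cm))

    out: list[SiteSurvey] = []
    for srow in sites.itertuples(index=False):
        sid = srow.site_id
        tids = sorted(
            set(benthic.loc[benthic.site_id == sid, "transect_id"])
            | set(fish.loc[fish.site_id == sid, "transect_id"])
            | set(urchins.loc[urchins.site_id == sid, "transect_id"])
            | {t for (s, t) in rug_map if s == sid}
        )
        transects = []
        for tid in tids:
            contour, horiz = rug_map.get((sid, tid), (TAPE_LENGTH_CM, TAPE_LENGTH_CM))
            rows = benthic[(benthic.site_id == sid) & (benthic.transect_id == tid)]
            intercepts = [
                BenthicIntercept(tid, str(r.taxon_code), str(r.category),
                                 str(r.morphology_code), float(r.chord_cm))
                for r in rows.itertuples(index=False)
            ]
            transects.append(Transect(tid, sid, contour, horiz, intercepts))
        site = SiteSurvey(
            site_id=sid, island=str(srow.island), habitat=str(srow.habitat),
            lat=float(srow.lat), lon=float(srow.lon), transects=transects,
            fish=[ParrotfishObs(str(r.transect_id), str(r.species_code),
                                float(r.length_cm))
                  for r in fish[fish.site_id == sid].itertuples(index=False)],
            urchins=[UrchinObs(str(r.transect_id), str(r.genus_class),
                               float(r.test_diameter_cm))
                     for r in urchins[urchins.site_id == sid].itertuples(index=False)],
        )
        out.append(site)

    ds = SurveyDataset(out)
    ds.validate()
    return ds


def write_survey_dataset(ds: SurveyDataset, outdir) -> dict[str, Path]:
    """Write the dataset back to the five CSV schemas; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    benthic, fish, urchins, sites, rug = [], [], [], [], []
    for s in ds.sites:
        sites.append((s.site_id, s.island, s.habitat, s.lat, s.lon))
        for t in s.transects:
            rug.append((s.site_id, t.transect_id,
                        t.contour_length_cm, t.horizontal_length_cm))
            for i in t.intercepts:
                benthic.append((s.site_id, t.transect_id, i.taxon_code,
                                i.category, i.morphology_code, i.chord_cm))
        for f in s.fish:
            fish.append((s.site_id, f.transect_id, f.species_code, f.length_cm))
        for u in s.urchins:
            urchins.append((s.site_id, u.transect_id, u.genus_class,
                            u.test_diameter_cm))
    frames = {
        "benthic": pd.DataFrame(benthic, columns=_SCHEMAS["benthic"]),
        "fish": pd.DataFrame(fish, columns=_SCHEMAS["fish"]),
        "urchins": pd.DataFrame(urchins, columns=_SCHEMAS["urchins"]),
        "sites": pd.DataFrame(sites, columns=_SCHEMAS["sites"]),
        "rugosity": pd.DataFrame(rug, columns=_SCHEMAS["rugosity"]),
    }
    paths = {}
    for name, df in frames.items():
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False, float_format="%.17g")
        paths[name] = p
    return paths


def write_trait_table(table: TraitTable, path) -> Path:
    rows = [(t.taxon_code, t.m, t.d, t.g,
             "" if t.brc is None else t.brc) for t in table]
    pd.DataFrame(rows, columns=_SCHEMAS["traits"]).to_csv(path, index=False, float_format="%.17g")
    return Path(path)
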