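"""Survey data model: tables, CSV I/O, design tallies, incidence frequencies.

The dataset is five related tables (all plain CSV, UTF-8, ISO-8601 dates):

``sites``            one row per survey location (region, mountain, habitat,
                     elevation, vegetation covers, whether a recorder was
                     installed).
``surveys``          one row per *site-survey*: a single 6-minute observation
                     unit, either a point count (``PC``) or one analyzed
                     recording window (``ARU``).
``detections``       one row per (survey, species); duplicates collapse.
``families``         species -> family lookup.
``known_community``  (habitat, species) inventory of species known to occur.

Downstream modules consume :class:`SurveyDataset` and
:class:`IncidenceFrequencies` built here.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

REGIONS = ("BC", "Chile")
HABITATS = ("montane", "subalpine", "alpine")
METHODS = ("PC", "ARU")

#: canopy-cover bounds (%) per habitat used when validation is enabled
HABITAT_CANOPY_RULE = {"montane": (50.0, 100.0), "subalpine": (5.0, 50.0), "alpine": (0.0, 5.0)}

SITE_COLUMNS = [
    "site_id", "region", "mountain", "habitat", "elevation", "canopy_cover",
    "understory_cover", "shrub_cover", "ground_cover", "has_aru",
]
SURVEY_COLUMNS = [
    "survey_id", "site_id", "method", "date", "hours_after_sunrise",
    "wind_score", "day_index", "hour_index", "round_index", "canopy_at_survey",
]
DETECTION_COLUMNS = ["survey_id", "species"]
FAMILY_COLUMNS = ["species", "family"]
KNOWN_COLUMNS = ["habitat", "species"]

_TABLE_COLUMNS = {
    "sites": SITE_COLUMNS,
    "surveys": SURVEY_COLUMNS,
    "detections": DETECTION_COLUMNS,
    "families": FAMILY_COLUMNS,
    "known_community": KNOWN_COLUMNS,
}


class SchemaError(ValueError):
    """A table is missing required columns or has malformed values."""


class IntegrityError(ValueError):
    """Cross-table referential integrity is violated."""


@dataclass
class SurveyDataset:
    """Validated container for the five survey tables."""

    sites: pd.DataFrame
    surveys: pd.DataFrame
    detections: pd.DataFrame
    families: pd.DataFrame
    known_community: pd.DataFrame

    def validate(self, check_canopy_rule: bool = False) -> "SurveyDataset":
        for name, cols in _TABLE_COLUMNS.items():
            df = getattr(self, name)
            missing = [c for c in cols if c not in df.columns]
            if missing:
                raise SchemaError(f"table {name!r} is missing column(s): {', '.join(missing)}")

        sites, surveys, dets = self.sites, self.surveys, self.detections
        if sites["site_id"].duplicated().any():
            dup = sites.loc[sites["site_id"].duplicated(), "site_id"].iloc[0]
            raise IntegrityError(f"duplicate site_id {dup!r}")
        if surveys["survey_id"].duplicated().any():
            dup = surveys.loc[surveys["survey_id"].duplicated(), "survey_id"].iloc[0]
            raise IntegrityError(f"duplicate survey_id {dup!r}")

        bad_region = set(sites["region"]) - set(REGIONS)
        if bad_region:
            raise SchemaError(f"unknown region value(s): {sorted(bad_region)}")
        bad_hab = set(sites["habitat"]) - set(HABITATS)
        if bad_hab:
            raise SchemaError(f"unknown habitat value(s): {sorted(bad_hab)}")
        bad_method = set(surveys["method"]) - set(METHODS)
        if bad_method:
            raise SchemaError(f"unknown method value(s): {sorted(bad_method)}")

        if (sites["elevation"] <= 0).any():
            raise SchemaError("elevation must be > 0 for all sites")
        for col in ("canopy_cover", "understory_cover", "shrub_cover", "ground_cover"):
            vals = sites[col]
            if ((vals < 0) | (vals > 100)).any():
                raise SchemaError(f"{col} must lie within [0, 100]")

        unknown_sites = set(surveys["site_id"]) - set(sites["site_id"])
        if unknown_sites:
            raise IntegrityError(f"surveys reference unknown site_id(s): {sorted(unknown_sites)[:5]}")
        unknown_surveys = set(dets["survey_id"]) - set(surveys["survey_id"])
        if unknown_surveys:
            raise IntegrityError(
                f"detections reference unknown survey_id(s): {sorted(unknown_surveys)[:5]}"
            )
        if (dets["species"].astype(str).str.len() == 0).any():
            raise SchemaError("detections contain empty species names")

        aru = surveys[surveys["method"] == "ARU"]
        if len(aru) and not aru["hour_index"].isin([0, 1, 2, 3, 4]).all():
            raise SchemaError("ARU surveys must have hour_index in 0..4")
        pc = surveys[surveys["method"] == "PC"]
        if len(pc) and not pc["round_index"].isin([1, 2, 3]).all():
            raise SchemaError("PC surveys must have round_index in 1..3")
        ws = surveys["wind_score"]
        if ((ws < 0) | (ws > 3)).any():
            raise SchemaError("wind_score must lie within 0..3")
        if (surveys["hours_after_sunrise"] < 0).any():
            raise SchemaError("hours_after_sunrise must be >= 0")

        if check_canopy_rule:
            for hab, (lo, hi) in HABITAT_CANOPY_RULE.items():
                sub = sites.loc[sites["habitat"] == hab, "canopy_cover"]
                if ((sub < lo) | (sub > hi)).any():
                    raise SchemaError(
                        f"canopy_cover outside [{lo}, {hi}] for habitat {hab!r}"
                    )
        return self

    # -- convenience accessors -------------------------------------------------
    def species_to_family(self) -> pd.Series:
        return self.families.set_index("species")["family"]

    def surveys_with_sites(self) -> pd.DataFrame:
        return self.surveys.merge(self.sites, on="site_id", how="left", validate="m:1")

    def paired_sites(self) -> pd.DataFrame:
        """Sites surveyed by both methods (recorder installed)."""
        return self.sites[self.sites["has_aru"].astype(bool)]

    def restrict_to_paired(self) -> "SurveyDataset":
        keep = set(self.paired_sites()["site_id"])
        surveys = self.surveys[self.surveys["site_id"].isin(keep)].reset_index(drop=True)
        dets = self.detections[self.detections["survey_id"].isin(set(surveys["survey_id"]))]
        return replace(
            self,
            sites=self.sites[self.sites["site_id"].isin(keep)].reset_index(drop=True),
            surveys=surveys,
            detections=dets.reset_index(drop=True),
        )


def _read_csv(path: str, name: str) -> pd.DataFrame:
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in _TABLE_COLUMNS[name] if c not in df.columns]
    if missing:
        raise SchemaError(f"{os.path.basename(path)}: missing column(s): {', '.join(missing)}")
    return df


def read_dataset(directory: str, validate: bool = True) -> SurveyDataset:
    """Read the five-table CSV bundle from ``directory``.

    Duplicate (survey_id, species) detection rows are collapsed to a single
    incidence; an optional ``count`` column is ignored.
    """
    tables = {}
    for name in _TABLE_COLUMNS:
        path = os.path.join(directory, f"{name}.csv")
        if not os.path.exists(path):
            raise FileNotFoundError(f"expected {name}.csv in {directory}")
        tables[name] = _read_csv(path, name)
    tables["detections"] = (
        tables["detections"].drop_duplicates(subset=["survey_id", "species"]).reset_index(drop=True)
    )
    # nullable integers (hour_index absent for PC, round_index for ARU) so
    # read -> write round-trips bit-exactly
    for col in ("day_index", "hour_index", "round_index", "wind_score"):
        tables["surveys"][col] = tables["surveys"][col].astype("Int64")
    ds = SurveyDataset(**tables)
    if validate:
        ds.validate()
    return ds


def write_dataset(ds: SurveyDataset, directory: str) -> None:
    """Write all five tables as CSV; round-trips bit-exactly with read_dataset."""
    os.makedirs(directory, exist_ok=True)
    for name, cols in _TABLE_COLUMNS.items():
        df = getattr(ds, name)
        df.to_csv(os.path.join(directory, f"{name}.csv"), index=False, columns=list(df.columns))


# ---------------------------------------------------------------------------
# design tallies
# ---------------------------------------------------------------------------

def tally_site_surveys(ds: SurveyDataset, region: str | None = None,
                       method: str | None = None) -> int:
    """Count survey events (one 6-min PC or ARU sample = one site-survey)."""
    sv = ds.surveys_with_sites() if region is not None else ds.surveys
    if region is not None:
        sv = sv[sv["region"] == region]
    if method is not None:
        sv = sv[sv["method"] == method]
    return int(len(sv))


# ---------------------------------------------------------------------------
# incidence frequencies
# ---------------------------------------------------------------------------

@dataclass
class IncidenceFrequencies:
    """Incidence summary of one assemblage: T sampling units, Y_i counts.

    ``matrix`` (units x species, boolean) is retained when the assemblage is
    built from raw survey data; it enables the sampling-unit bootstrap.
    """

    label: str
    T: int
    counts: "pd.Series"  # species -> Y_i, 1 <= Y_i <= T
    matrix: np.ndarray | None = field(default=None, repr=False)
    species: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.counts = pd.Series(self.counts, dtype=int).sort_index()
        if not self.species:
            self.species = list(self.counts.index)
        if (self.counts < 1).any():
            raise ValueError("incidence counts must be >= 1 (drop undetected species)")
        if (self.counts > self.T).any():
            raise ValueError("incidence count exceeds number of sampling units")
        if self.matrix is not None:
            self.matrix = np.asarray(self.matrix, dtype=bool)
            if self.matrix.shape != (self.T, len(self.counts)):
                raise ValueError("matrix shape must be (T, n_species)")

    @property
    def Y(self) -> np.ndarray:
        return self.counts.to_numpy()

    @property
    def U(self) -> int:
        return int(self.counts.sum())

    @property
    def Q1(self) -> int:
        return int((self.counts == 1).sum())

    @property
    def Q2(self) -> int:
        return int((self.counts == 2).sum())

    @property
    def S_obs(self) -> int:
        return int(len(self.counts))

    @classmethod
    def from_matrix(cls, label: str, matrix: np.ndarray,
                    species: list[str] | None = None) -> "IncidenceFrequencies":
        matrix = np.asarray(matrix, dtype=bool)
        T, S = matrix.shape
        if species is None:
            species = [f"sp{i + 1}" for i in range(S)]
        y = matrix.sum(axis=0)
        keep = y > 0
        counts = pd.Series(y[keep], index=[s for s, k in zip(species, keep) if k])
        order = np.argsort(counts.index)
        return cls(label=label, T=T, counts=counts,
                   matrix=matrix[:, np.flatnonzero(keep)[order]],
                   species=list(counts.index[order]))

    @classmethod
    def from_counts(cls, label: str, T: int, counts) -> "IncidenceFrequencies":
        return cls(label=label, T=T, counts=pd.Series(counts))


POOLINGS = ("per_hour", "pooled_morning", "pc")


def build_incidence(ds: SurveyDataset, habitat: str, method: str | None = None,
                    pooling: str = "pooled_morning", hour: int | None = None,
                    region: str | None = None,
                    paired_only: bool = True) -> IncidenceFrequencies:
    """Incidence frequencies for one assemblage (habitat x method/pooling).

    ``pooling``:

    * ``"pc"`` -- point-count units only,
    * ``"pooled_morning"`` -- all ARU windows pooled over the morning,
    * ``"per_hour"`` -- ARU windows for a single ``hour`` index (0..4).

    Sampling units are individual site-surveys; Y_i counts the units with at
    least one detection of species i.  By default the assemblage is restricted
    to paired PC/ARU sites so the two methods sample identical locations.
    """
    if pooling not in POOLINGS:
        raise ValueError(f"unknown pooling {pooling!r}; expected one of {POOLINGS}")
    base = ds.restrict_to_paired() if paired_only else ds
    sv = base.surveys_with_sites()
    sv = sv[sv["habitat"] == habitat]
    if region is not None:
        sv = sv[sv["region"] == region]
    if pooling == "pc":
        sv = sv[sv["method"] == "PC"]
        label = f"{habitat}/PC"
    elif pooling == "pooled_morning":
        sv = sv[sv["method"] == "ARU"]
        label = f"{habitat}/ARU-pooled"
    else:
        if hour is None:
            raise ValueError("per_hour pooling requires an hour index (0..4)")
        sv = sv[(sv["method"] == "ARU") & (sv["hour_index"] == hour)]
        label = f"{habitat}/ARU-h{hour}"
    if len(sv) == 0:
        raise ValueError(f"no sampling units for assemblage {label!r}")

    unit_ids = list(sv["survey_id"])
    unit_pos = {u: i for i, u in enumerate(unit_ids)}
    dets = ds.detections[ds.detections["survey_id"].isin(unit_pos)]
    species = sorted(dets["species"].unique())
    sp_pos = {s: j for j, s in enumerate(species)}
    matrix = np.zeros((len(unit_ids), len(species)), dtype=bool)
    if len(dets):
        rows = dets["survey_id"].map(unit_pos).to_numpy()
        cols = dets["species"].map(sp_pos).to_numpy()
        matrix[rows, cols] = True
    return IncidenceFrequencies.from_matrix(label, matrix, species)


# ---------------------------------------------------------------------------
# family filters for occupancy modeling
# ---------------------------------------------------------------------------

def filter_families(ds: SurveyDataset, min_occupancy: float = 0.15,
                    habitat_share: float = 0.90) -> list[tuple[str, tuple[str, ...]]]:
    """Select families (and their habitats) eligible for detection modeling.

    A family is retained iff the fraction of sites with at least one detection
    (either method) reaches ``min_occupancy`` within at least one habitat.
    For retained families, habitats are ranked by their share of the family's
    occupied sites and accumulated (greedily, descending) until the cumulative
    share reaches ``habitat_share``.

    Output is sorted by family name and independent of input row order.
    """
    fam_map = ds.species_to_family()
    dets = ds.detections.copy()
    unmapped = sorted(set(dets["species"]) - set(fam_map.index))
    if unmapped:
        raise IntegrityError(f"species without family mapping: {unmapped}")
    dets["family"] = dets["species"].map(fam_map)
    dets = dets.merge(ds.surveys[["survey_id", "site_id"]], on="survey_id")
    dets = dets.merge(ds.sites[["site_id", "habitat"]], on="site_id")

    sites_per_hab = ds.sites.groupby("habitat")["site_id"].nunique()
    occ = dets.drop_duplicates(["family", "site_id"])[["family", "site_id", "habitat"]]

    out: list[tuple[str, tuple[str, ...]]] = []
    for family, grp in occ.groupby("family"):
        occ_by_hab = grp.groupby("habitat")["site_id"].nunique()
        frac = occ_by_hab / sites_per_hab.reindex(occ_by_hab.index)
        if not (frac >= min_occupancy).any():
            continue
        total = occ_by_hab.sum()
        shares = (occ_by_hab / total).reindex(HABITATS).dropna()
        # greedy accumulation in descending share order; habitat order breaks ties
        ranked = sorted(shares.items(), key=lambda kv: (-kv[1], HABITATS.index(kv[0])))
        kept, cum = [], 0.0
        for hab, share in ranked:
            kept.append(hab)
            cum += share
            if cum >= habitat_share - 1e-12:
                break
        out.append((family, tuple(kept)))
    return sorted(out)


# ---------------------------------------------------------------------------
# canopy residuals (site-level occupancy covariate)
# ---------------------------------------------------------------------------

def canopy_residuals(sites: pd.DataFrame) -> pd.Series:
    """OLS residuals of canopy cover regressed on elevation, per site.

    Removes the canopy/elevation co-linearity so both can enter the occupancy
    model.  Residuals sum to zero.  Requires >= 3 sites and non-constant
    elevation.
    """
    elev = sites["elevation"].to_numpy(dtype=float)
    canopy = sites["canopy_cover"].to_numpy(dtype=float)
    ok = np.isfinite(elev) & np.isfinite(canopy)
    if ok.sum() < 3:
        raise ValueError("need at least 3 sites with finite elevation and canopy")
    if np.ptp(elev[ok]) == 0:
        raise ValueError("elevation is constant; regression slope undefined")
    X = np.column_stack([np.ones(ok.sum()), elev[ok]])
    beta, *_ = np.linalg.lstsq(X, canopy[ok], rcond=None)
    resid = np.full(len(sites), np.nan)
    resid[ok] = canopy[ok] - X @ beta
    return pd.Series(resid, index=sites["site_id"].to_numpy(), name="canopy_resid")
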