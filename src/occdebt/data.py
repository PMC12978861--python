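"""Study data containers, validation, CSV readers/writers and design summaries.

A *study* is a multi-season detection/non-detection survey: ``n`` stream sites
visited up to ``J`` times per season over ``T`` seasons, with many site-seasons
never surveyed (unbalanced revisit design). Detection data are stored as a
dense ``(n, T, J)`` float array with ``NaN`` marking missing visits; covariates
live in pandas DataFrames (site level) and dense arrays (season and visit
level) aligned to the same site ordering.

Seasons and visits are numbered 1..T / 1..J in the CSV files and 0-based
internally; the readers and writers convert at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import StudyValidationError

#: Columns required in sites.csv (besides ``site``).
SITE_COLUMNS = [
    "subpopulation",
    "huc10",
    "drainage_area_km2",
    "habitat_score",
    "substrate_score",
    "cover_score",
    "lulc_developed",
    "lulc_herbpasture",
    "lulc_crop",
    "lulc_wetland",
    "tqmean",
]

_UNIT_INTERVAL_COLUMNS = [
    "lulc_developed",
    "lulc_herbpasture",
    "lulc_crop",
    "lulc_wetland",
    "tqmean",
]


@dataclass
class DetectionHistory:
    """Binary detection records ``y[i, t, j]`` with explicit missingness.

    ``y`` holds 0.0, 1.0 or ``NaN`` (visit not performed). A season with all
    visits missing counts as not surveyed for that site.
    """

    site_ids: list
    y: np.ndarray  # (n_sites, n_seasons, n_visits), float, NaN = missing

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if self.y.ndim != 3:
            raise StudyValidationError("detection array must be 3-d (site, season, visit)")
        if len(self.site_ids) != self.y.shape[0]:
            raise StudyValidationError(
                f"{len(self.site_ids)} site ids but {self.y.shape[0]} detection rows"
            )
        self.validate()

    @property
    def n_sites(self) -> int:
        return self.y.shape[0]

    @property
    def n_seasons(self) -> int:
        return self.y.shape[1]

    @property
    def n_visits(self) -> int:
        return self.y.shape[2]

    @property
    def observed(self) -> np.ndarray:
        """Boolean mask of performed visits, shape (n, T, J)."""
        return ~np.isnan(self.y)

    @property
    def surveyed(self) -> np.ndarray:
        """Boolean (n, T): True iff at least one visit that season."""
        return self.observed.any(axis=2)

    def validate(self) -> None:
        vals = self.y[~np.isnan(self.y)]
        bad = vals[(vals != 0.0) & (vals != 1.0)]
        if bad.size:
            i, t, j = [int(v) for v in np.argwhere(~np.isnan(self.y) & (self.y != 0) & (self.y != 1))[0]]
            raise StudyValidationError(
                f"non-binary detection value {self.y[i, t, j]!r} at site "
                f"{self.site_ids[i]!r}, season {t + 1}, visit {j + 1}"
            )
        never = ~self.surveyed.any(axis=1)
        if never.any():
            i = int(np.argmax(never))
            raise StudyValidationError(
                f"site {self.site_ids[i]!r} has no surveyed season and cannot contribute"
            )


@dataclass
class StudyDataset:
    """Consistency-checked bundle of detections and covariates.

    Attributes
    ----------
    detections : DetectionHistory
    sites : pandas.DataFrame
        Indexed by site id, columns :data:`SITE_COLUMNS`; row order defines
        the site ordering of every array in the bundle.
    drought : ndarray (n, T) of int
        Maximum annual drought index per site and season, values in {0,1,2,3}.
    discharge : ndarray (n, T, J)
        Daily mean discharge (m^3/s) per visit; NaN where not available.
    bait_age : ndarray (n, T, J)
        Days since baiting (1..J); NaN where not available.
    """

    detections: DetectionHistory
    sites: pd.DataFrame
    drought: np.ndarray
    discharge: np.ndarray
    bait_age: np.ndarray

    def __post_init__(self) -> None:
        self.drought = np.asarray(self.drought)
        self.discharge = np.asarray(self.discharge, dtype=float)
        self.bait_age = np.asarray(self.bait_age, dtype=float)
        self.validate()

    # -- convenience -------------------------------------------------------
    @property
    def site_ids(self) -> list:
        return self.detections.site_ids

    @property
    def n_sites(self) -> int:
        return self.detections.n_sites

    @property
    def n_seasons(self) -> int:
        return self.detections.n_seasons

    @property
    def n_visits(self) -> int:
        return self.detections.n_visits

    def validate(self) -> None:
        det = self.detections
        n, T, J = det.y.shape
        if list(self.sites.index) != list(det.site_ids):
            missing = set(det.site_ids) - set(self.sites.index)
            if missing:
                raise StudyValidationError(f"sites table missing site ids: {sorted(missing)[:5]}")
            # same set, different order: realign rather than fail
            self.sites = self.sites.loc[det.site_ids]
        for col in SITE_COLUMNS:
            if col not in self.sites.columns:
                raise StudyValidationError(f"sites table missing column {col!r}")
        if self.drought.shape != (n, T):
            raise StudyValidationError(
                f"drought array shape {self.drought.shape} != (n_sites, n_seasons) = {(n, T)}"
            )
        if self.discharge.shape != (n, T, J) or self.bait_age.shape != (n, T, J):
            raise StudyValidationError("visit covariate arrays must have shape (n, T, J)")

        hs = self.sites["habitat_score"].to_numpy(dtype=float)
        if np.any((hs < 0) | (hs > 100) | ~np.isfinite(hs)):
            i = int(np.argmax((hs < 0) | (hs > 100) | ~np.isfinite(hs)))
            raise StudyValidationError(
                f"habitat_score out of [0, 100] for site {self.sites.index[i]!r}: {hs[i]}"
            )
        for col in _UNIT_INTERVAL_COLUMNS:
            v = self.sites[col].to_numpy(dtype=float)
            if np.any((v < 0) | (v > 1) | ~np.isfinite(v)):
                i = int(np.argmax((v < 0) | (v > 1) | ~np.isfinite(v)))
                raise StudyValidationError(
                    f"{col} out of [0, 1] for site {self.sites.index[i]!r}: {v[i]}"
                )
        sub = self.sites["subpopulation"]
        if sub.isna().any() or (sub.astype(str).str.len() == 0).any():
            bad = self.sites.index[sub.isna() | (sub.astype(str).str.len() == 0)][0]
            raise StudyValidationError(f"empty subpopulation label for site {bad!r}")
        if not np.isin(self.drought, [0, 1, 2, 3]).all():
            i, t = [int(v) for v in np.argwhere(~np.isin(self.drought, [0, 1, 2, 3]))[0]]
            raise StudyValidationError(
                f"drought index {self.drought[i, t]!r} outside {{0,1,2,3}} at site "
                f"{self.site_ids[i]!r}, season {t + 1}"
            )
        obs = det.observed
        no_q = obs & ~np.isfinite(self.discharge)
        if no_q.any():
            i, t, j = [int(v) for v in np.argwhere(no_q)[0]]
            raise StudyValidationError(
                f"missing discharge for observed visit: site {self.site_ids[i]!r}, "
                f"season {t + 1}, visit {j + 1}"
            )
        if np.any(self.discharge[np.isfinite(self.discharge)] <= 0):
            raise StudyValidationError("discharge must be > 0 where observed")
        ba = self.bait_age[obs]
        if np.any(~np.isfinite(ba)) or np.any((ba < 1) | (ba > max(4, J)) | (ba != np.round(ba))):
            i, t, j = [int(v) for v in np.argwhere(obs)[0]]
            raise StudyValidationError(
                "bait_age must be an integer in [1, 4] at every observed visit"
            )

    def replace_detections(self, y: np.ndarray) -> "StudyDataset":
        """Return a copy of the bundle with a new detection array (same sites
        and missingness support); used by parametric bootstrap refits."""
        det = DetectionHistory(list(self.site_ids), np.asarray(y, dtype=float))
        return StudyDataset(det, self.sites.copy(), self.drought.copy(),
                            self.discharge.copy(), self.bait_age.copy())


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def _read_csv(path, str_cols=("site",)) -> pd.DataFrame:
    head = pd.read_csv(path, nrows=0)
    dtypes = {c: str for c in str_cols if c in head.columns}
    df = pd.read_csv(path, na_values=["NA", ""], keep_default_na=True,
                     float_precision="round_trip", dtype=dtypes)
    df.columns = [c.strip() for c in df.columns]
    return df


def read_study(detections_path, sites_path, seasons_path, visits_path) -> StudyDataset:
    """Read and validate the four study CSVs into a :class:`StudyDataset`.

    Missing visits may be encoded as empty cells or ``NA``. Seasons/visits are
    1-based in the files. Raises :class:`StudyValidationError` naming the
    offending cell for any schema or domain violation.
    """
    det_df = _read_csv(detections_path)
    sites_df = _read_csv(sites_path, str_cols=("site", "huc10", "subpopulation"))
    seas_df = _read_csv(seasons_path)
    vis_df = _read_csv(visits_path)

    for needed, df, name in [
        (["site", "season", "visit", "y"], det_df, "detections"),
        (["site"] + SITE_COLUMNS, sites_df, "sites"),
        (["site", "season", "drought_index"], seas_df, "seasons"),
        (["site", "season", "visit", "discharge_m3s", "bait_age_days"], vis_df, "visits"),
    ]:
        missing = [c for c in needed if c not in df.columns]
        if missing:
            raise StudyValidationError(f"{name}.csv missing columns {missing}")

    site_ids = list(sites_df["site"].astype(str))
    if len(set(site_ids)) != len(site_ids):
        raise StudyValidationError("duplicate site ids in sites.csv")
    site_pos = {s: i for i, s in enumerate(site_ids)}

    T = int(det_df["season"].max())
    J = int(det_df["visit"].max())
    n = len(site_ids)

    y = np.full((n, T, J), np.nan)
    for row in det_df.itertuples(index=False):
        s = str(row.site)
        if s not in site_pos:
            raise StudyValidationError(f"detections.csv references unknown site {s!r}")
        t, j = int(row.season) - 1, int(row.visit) - 1
        if not (0 <= t < T) or not (0 <= j < J):
            raise StudyValidationError(f"detections.csv season/visit out of range for site {s!r}")
        if pd.isna(row.y):
            continue
        try:
            val = float(row.y)
        except (TypeError, ValueError):
            val = -1.0
        if val not in (0.0, 1.0):
            raise StudyValidationError(
                f"detections.csv non-binary value {row.y!r} at site {s!r}, "
                f"season {t + 1}, visit {j + 1}"
            )
        y[site_pos[s], t, j] = val

    sites = sites_df.set_index(sites_df["site"].astype(str))[SITE_COLUMNS]

    drought = np.zeros((n, T), dtype=int)
    seen = np.zeros((n, T), dtype=bool)
    for row in seas_df.itertuples(index=False):
        s = str(row.site)
        if s not in site_pos:
            raise StudyValidationError(f"seasons.csv references unknown site {s!r}")
        t = int(row.season) - 1
        if pd.isna(row.drought_index):
            raise StudyValidationError(f"seasons.csv missing drought_index for site {s!r}, season {t + 1}")
        drought[site_pos[s], t] = int(row.drought_index)
        seen[site_pos[s], t] = True
    if not seen.all():
        i, t = [int(v) for v in np.argwhere(~seen)[0]]
        raise StudyValidationError(
            f"seasons.csv missing row for site {site_ids[i]!r}, season {t + 1}"
        )

    discharge = np.full((n, T, J), np.nan)
    bait_age = np.full((n, T, J), np.nan)
    for row in vis_df.itertuples(index=False):
        s = str(row.site)
        if s not in site_pos:
            raise StudyValidationError(f"visits.csv references unknown site {s!r}")
        t, j = int(row.season) - 1, int(row.visit) - 1
        if not pd.isna(row.discharge_m3s):
            discharge[site_pos[s], t, j] = float(row.discharge_m3s)
        if not pd.isna(row.bait_age_days):
            bait_age[site_pos[s], t, j] = float(row.bait_age_days)

    det = DetectionHistory(site_ids, y)
    return StudyDataset(det, sites, drought, discharge, bait_age)


def write_study(dataset: StudyDataset, out_dir) -> dict:
    """Write the four study CSVs (detections, sites, seasons, visits) to
    ``out_dir``; missing values are written as ``NA``. Returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n, T, J = dataset.detections.y.shape
    ids = dataset.site_ids

    det_rows = []
    vis_rows = []
    for i in range(n):
        for t in range(T):
            for j in range(J):
                v = dataset.detections.y[i, t, j]
                det_rows.append((ids[i], t + 1, j + 1, "NA" if np.isnan(v) else int(v)))
                q = dataset.discharge[i, t, j]
                b = dataset.bait_age[i, t, j]
                if np.isfinite(q) or np.isfinite(b):
                    vis_rows.append((
                        ids[i], t + 1, j + 1,
                        "NA" if not np.isfinite(q) else repr(float(q)),
                        "NA" if not np.isfinite(b) else int(b),
                    ))
    det_df = pd.DataFrame(det_rows, columns=["site", "season", "visit", "y"])
    vis_df = pd.DataFrame(vis_rows, columns=["site", "season", "visit", "discharge_m3s", "bait_age_days"])
    seas_rows = [(ids[i], t + 1, int(dataset.drought[i, t])) for i in range(n) for t in range(T)]
    seas_df = pd.DataFrame(seas_rows, columns=["site", "season", "drought_index"])
    sites_df = dataset.sites.reset_index(names="site")

    paths = {
        "detections": out / "detections.csv",
        "sites": out / "sites.csv",
        "seasons": out / "seasons.csv",
        "visits": out / "visits.csv",
    }
    det_df.to_csv(paths["detections"], index=False)
    sites_df.to_csv(paths["sites"], index=False, float_format="%.17g")
    seas_df.to_csv(paths["seasons"], index=False)
    vis_df.to_csv(paths["visits"], index=False)
    return paths


# ---------------------------------------------------------------------------
# Design summaries
# ---------------------------------------------------------------------------

def summarize_design(dataset: StudyDataset, traps_per_site: int = 10,
                     nights_per_season: int = 4,
                     habitat_threshold: float = 60.0) -> dict:
    """Summaries of the survey design and raw detections.

    Returns a dict with

    - ``naive_occupancy``: share of sites with at least one detection ever,
      rounded to 2 decimals;
    - ``n_presence_sites``: number of sites with >= 1 detection;
    - ``revisit_counts``: {k: number of sites surveyed in exactly k seasons};
    - ``trap_nights_per_survey``: traps x nights for one surveyed site-season;
    - ``presence_highscore_fraction``: among presence sites, share with
      habitat_score >= ``habitat_threshold`` (NaN when no presence sites).

    All counts are invariant to site ordering.
    """
    det = dataset.detections
    detected_ever = np.nansum(det.y, axis=(1, 2)) > 0
    n = det.n_sites
    n_presence = int(detected_ever.sum())
    naive = round(n_presence / n, 2) if n else float("nan")

    k_seasons = det.surveyed.sum(axis=1)
    revisit = {int(k): int((k_seasons == k).sum()) for k in np.unique(k_seasons)}

    hs = dataset.sites["habitat_score"].to_numpy(dtype=float)
    if n_presence:
        frac_high = float((hs[detected_ever] >= habitat_threshold).sum() / n_presence)
    else:
        frac_high = float("nan")

    return {
        "n_sites": n,
        "n_seasons": det.n_seasons,
        "naive_occupancy": naive,
        "n_presence_sites": n_presence,
        "revisit_counts": revisit,
        "trap_nights_per_survey": traps_per_site * nights_per_season,
        "presence_highscore_fraction": frac_high,
    }
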