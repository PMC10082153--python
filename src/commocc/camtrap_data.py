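"""Camera-trap event ingestion and detection-history construction.

Raw camera triggers arrive as timestamped rows (site, species, timestamp,
image count).  A passing animal — or a livestock herd filing past the
camera — fires the trigger repeatedly at short intervals, so sequential
triggers within a configurable gap are collapsed into a single independent
detection.  Collapsed detections are then binned into fixed-length sampling
occasions (14 days by default) to form the binary species × site × occasion
detection histories that the occupancy likelihood consumes, together with a
per-(site, occasion) effort table in camera-days.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

#: Reserved species label for domestic livestock.  Livestock detections are
#: collapsed with the same rule as wild species but feed the livestock-count
#: site covariate rather than the occupancy model.
LIVESTOCK_LABEL = "livestock"

EVENT_COLUMNS = ["site_id", "species_id", "timestamp", "n_images"]
COVARIATE_COLUMNS = ["canopy_pct", "dist_settlement_m", "livestock_n"]


# ---------------------------------------------------------------------------
# Event tables
# ---------------------------------------------------------------------------

def validate_events(events: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalise an event table.

    Returns a copy with ``timestamp`` coerced to datetime64 and ``n_images``
    to integers.  Raises ``ValueError`` naming the offending row for
    unparseable timestamps or non-positive image counts.
    """
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"event table is missing columns: {missing}")
    out = events.loc[:, EVENT_COLUMNS].copy()
    ts = pd.to_datetime(out["timestamp"], errors="coerce", format="ISO8601")
    bad = ts.isna() & out["timestamp"].notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"unparseable timestamp {out['timestamp'].iloc[row]!r} in event row {row}"
        )
    if ts.isna().any():
        row = int(np.flatnonzero(ts.isna().to_numpy())[0])
        raise ValueError(f"missing timestamp in event row {row}")
    out["timestamp"] = ts
    n_img = pd.to_numeric(out["n_images"], errors="coerce")
    if (n_img.isna() | (n_img < 1)).any():
        row = int(np.flatnonzero((n_img.isna() | (n_img < 1)).to_numpy())[0])
        raise ValueError(f"n_images must be a positive integer (event row {row})")
    out["n_images"] = n_img.astype(int)
    return out


def read_events_csv(path) -> pd.DataFrame:
    """Read an events CSV (header: site_id,species_id,timestamp,n_images)."""
    return validate_events(pd.read_csv(path))


def collapse_events(events: pd.DataFrame, max_gap_seconds: float = 60.0) -> pd.DataFrame:
    """Collapse sequential triggers into independent detections.

    Within each (site, species) group, maximal runs of events whose
    consecutive time gaps are all ≤ ``max_gap_seconds`` merge into a single
    detection carrying the run's first timestamp and the summed image count.
    Events at different sites or of different species never merge.  The rule
    chains transitively, so a herd firing the trigger every 30 s for minutes
    on end still counts once.

    Idempotent: collapsing an already-collapsed table changes nothing
    (surviving gaps all exceed ``max_gap_seconds``).
    """
    if max_gap_seconds <= 0:
        raise ValueError(f"max_gap_seconds must be positive, got {max_gap_seconds}")
    events = validate_events(events)
    if events.empty:
        return events.reset_index(drop=True)
    events = events.sort_values(
        ["site_id", "species_id", "timestamp"], kind="mergesort"
    ).reset_index(drop=True)
    same_group = (
        (events["site_id"] == events["site_id"].shift())
        & (events["species_id"] == events["species_id"].shift())
    ).to_numpy()
    gap_s = events["timestamp"].diff().dt.total_seconds().to_numpy()
    new_run = ~(same_group & (gap_s <= max_gap_seconds))
    run_id = np.cumsum(new_run)
    collapsed = (
        events.groupby(run_id, sort=True)
        .agg(
            site_id=("site_id", "first"),
            species_id=("species_id", "first"),
            timestamp=("timestamp", "first"),
            n_images=("n_images", "sum"),
        )
        .reset_index(drop=True)
    )
    return collapsed


# ---------------------------------------------------------------------------
# Occasion grids and detection matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OccasionGrid:
    """Fixed-length sampling-occasion calendar.

    Occasions are half-open day windows [start + j*L, start + (j+1)*L); a
    trailing partial occasion is retained with its reduced effort rather than
    discarded.
    """

    survey_start: datetime
    survey_end: datetime
    occasion_length_days: int = 14

    def __post_init__(self):
        start = _as_datetime(self.survey_start)
        end = _as_datetime(self.survey_end)
        object.__setattr__(self, "survey_start", start)
        object.__setattr__(self, "survey_end", end)
        if end <= start:
            raise ValueError("survey_end must be after survey_start")
        if self.occasion_length_days < 1:
            raise ValueError("occasion_length_days must be a positive integer")

    @property
    def span_days(self) -> float:
        return (self.survey_end - self.survey_start) / timedelta(days=1)

    @property
    def n_occasions(self) -> int:
        return math.ceil(self.span_days / self.occasion_length_days)

    def occasion_lengths(self) -> np.ndarray:
        """Length in days of each occasion; the last may be partial."""
        L = float(self.occasion_length_days)
        full = [L] * (self.n_occasions - 1)
        last = self.span_days - L * (self.n_occasions - 1)
        return np.asarray(full + [last], dtype=float)

    def occasion_of(self, timestamp) -> int:
        """0-based occasion index of a timestamp; half-open [start, end)."""
        t = _as_datetime(timestamp)
        if not (self.survey_start <= t < self.survey_end):
            raise ValueError(
                f"timestamp {t} outside survey window "
                f"[{self.survey_start}, {self.survey_end})"
            )
        days = (t - self.survey_start) / timedelta(days=1)
        return int(days // self.occasion_length_days)


def _as_datetime(value) -> datetime:
    """Coerce ISO-8601 strings/dates to datetime; bare dates become midnight."""
    if isinstance(value, datetime):
        return value
    return pd.Timestamp(value).to_pydatetime()


@dataclass
class DetectionMatrix:
    """Binary detection histories plus survey effort.

    ``y[k, i, j]`` indicates ≥1 independent detection of species ``k`` at
    site ``i`` during occasion ``j``; ``effort_days[i, j]`` is the number of
    active camera-days behind that cell (0 ⇒ the cell is structurally empty).
    """

    y: np.ndarray
    species_ids: list[str]
    site_ids: list[str]
    effort_days: np.ndarray

    def __post_init__(self):
        self.y = np.asarray(self.y)
        self.effort_days = np.asarray(self.effort_days, dtype=float)
        K, I, J = self.y.shape
        if len(self.species_ids) != K or len(self.site_ids) != I:
            raise ValueError("species/site label lengths do not match y")
        if self.effort_days.shape != (I, J):
            raise ValueError("effort_days shape does not match y")
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("y entries must be binary")
        if (self.effort_days < 0).any():
            raise ValueError("effort_days must be nonnegative")
        if (self.y[:, self.effort_days == 0] != 0).any():
            raise ValueError("detection recorded in a zero-effort (site, occasion) cell")
        self.y = self.y.astype(np.int8)

    @property
    def n_species(self) -> int:
        return self.y.shape[0]

    @property
    def n_sites(self) -> int:
        return self.y.shape[1]

    @property
    def n_occasions(self) -> int:
        return self.y.shape[2]

    @property
    def effort_mask(self) -> np.ndarray:
        """Boolean (site, occasion) mask of surveyed cells."""
        return self.effort_days > 0

    def drop_undetected_species(self) -> "DetectionMatrix":
        """Drop species with all-zero histories (the model covers detected species)."""
        keep = self.y.sum(axis=(1, 2)) > 0
        return DetectionMatrix(
            y=self.y[keep],
            species_ids=[s for s, k in zip(self.species_ids, keep) if k],
            site_ids=list(self.site_ids),
            effort_days=self.effort_days,
        )

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format export: species_id, site_id, occasion (1-based), detected."""
        K, I, J = self.y.shape
        k, i, j = np.meshgrid(range(K), range(I), range(J), indexing="ij")
        return pd.DataFrame(
            {
                "species_id": np.asarray(self.species_ids)[k.ravel()],
                "site_id": np.asarray(self.site_ids)[i.ravel()],
                "occasion": j.ravel() + 1,
                "detected": self.y.ravel(),
            }
        )

    def effort_frame(self) -> pd.DataFrame:
        I, J = self.effort_days.shape
        i, j = np.meshgrid(range(I), range(J), indexing="ij")
        return pd.DataFrame(
            {
                "site_id": np.asarray(self.site_ids)[i.ravel()],
                "occasion": j.ravel() + 1,
                "effort_days": self.effort_days.ravel(),
            }
        )


def bin_occasions(
    events: pd.DataFrame,
    grid: OccasionGrid,
    sites: list[str],
    species: list[str],
    effort_days: np.ndarray | None = None,
) -> DetectionMatrix:
    """Bin collapsed detections into a binary DetectionMatrix.

    ``effort_days`` overrides the default full-grid effort (every site active
    the whole survey window); pass zeros for camera-failure periods.  Species
    in ``events`` but not in ``species`` (e.g. livestock when building the
    wild-mammal matrix) are ignored.
    """
    events = validate_events(events)
    site_index = {s: i for i, s in enumerate(sites)}
    sp_index = {s: k for k, s in enumerate(species)}
    unknown = set(events["site_id"]) - set(sites)
    if unknown:
        raise ValueError(f"events reference sites not in the site list: {sorted(unknown)}")
    J = grid.n_occasions
    y = np.zeros((len(species), len(sites), J), dtype=np.int8)
    for row in events.itertuples(index=False):
        if row.species_id not in sp_index:
            continue
        j = grid.occasion_of(row.timestamp)  # raises if outside the window
        y[sp_index[row.species_id], site_index[row.site_id], j] = 1
    if effort_days is None:
        effort_days = np.tile(grid.occasion_lengths(), (len(sites), 1))
    effort_days = np.asarray(effort_days, dtype=float)
    y[:, effort_days == 0] = 0
    return DetectionMatrix(y=y, species_ids=list(species), site_ids=list(sites),
                           effort_days=effort_days)


# ---------------------------------------------------------------------------
# Site covariates
# ---------------------------------------------------------------------------

@dataclass
class SiteCovariates:
    """Per-site covariates: canopy cover (%), settlement distance (m),
    livestock detections (count); optionally z-scored."""

    table: pd.DataFrame
    standardized: bool = False
    means: pd.Series | None = None
    sds: pd.Series | None = None

    def __post_init__(self):
        t = self.table
        missing = [c for c in ["site_id", *COVARIATE_COLUMNS] if c not in t.columns]
        if missing:
            raise ValueError(f"covariate table is missing columns: {missing}")
        if t[COVARIATE_COLUMNS].isna().any().any():
            raise ValueError("covariate table contains missing values")
        if not self.standardized:
            if ((t["canopy_pct"] < 0) | (t["canopy_pct"] > 100)).any():
                raise ValueError("canopy_pct must lie in [0, 100]")
            if (t["dist_settlement_m"] < 0).any():
                raise ValueError("dist_settlement_m must be nonnegative")
            if (t["livestock_n"] < 0).any():
                raise ValueError("livestock_n must be nonnegative")
        self.table = t.reset_index(drop=True)

    @property
    def site_ids(self) -> list[str]:
        return list(self.table["site_id"])

    @property
    def names(self) -> list[str]:
        return list(COVARIATE_COLUMNS)

    def values(self) -> np.ndarray:
        """(n_sites, n_covariates) float matrix, column order as ``names``."""
        return self.table[COVARIATE_COLUMNS].to_numpy(dtype=float)

    def aligned_to(self, site_ids: list[str]) -> "SiteCovariates":
        """Reorder rows to match a DetectionMatrix's site order."""
        t = self.table.set_index("site_id")
        missing = [s for s in site_ids if s not in t.index]
        if missing:
            raise ValueError(f"covariates missing for sites: {missing}")
        out = t.loc[site_ids].reset_index()
        return SiteCovariates(out, self.standardized, self.means, self.sds)


def read_covariates_csv(path) -> SiteCovariates:
    """Read a covariates CSV (header: site_id,canopy_pct,dist_settlement_m,livestock_n)."""
    return SiteCovariates(pd.read_csv(path))


# ---------------------------------------------------------------------------
# Survey summaries
# ---------------------------------------------------------------------------

def naive_site_occupancy(matrix: DetectionMatrix) -> pd.Series:
    """Observed occupancy: fraction of surveyed sites with ≥1 detection.

    A site counts as surveyed if it has any effort.  This is the raw
    detection-based proportion, a lower bound on model occupancy ψ under
    imperfect detection.
    """
    surveyed = matrix.effort_mask.any(axis=1)
    n_surveyed = int(surveyed.sum())
    if n_surveyed == 0:
        raise ValueError("no site has any survey effort; naive occupancy undefined")
    detected = matrix.y[:, surveyed].any(axis=2).sum(axis=1)
    return pd.Series(detected / n_surveyed, index=matrix.species_ids, name="naive_occupancy")


@dataclass(frozen=True)
class SurveySummary:
    camera_days: float
    n_species_detected: int
    total_detections: int


def summarize_effort(matrix: DetectionMatrix, events: pd.DataFrame) -> SurveySummary:
    """Headline survey numbers: camera-days of effort, wild species detected,
    and total independent wild detections (``events`` must be collapsed)."""
    events = validate_events(events)
    wild = events[events["species_id"] != LIVESTOCK_LABEL]
    return SurveySummary(
        camera_days=float(matrix.effort_days.sum()),
        n_species_detected=int(wild["species_id"].nunique()),
        total_detections=int(len(wild)),
    )
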