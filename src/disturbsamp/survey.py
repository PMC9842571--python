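"""Survey data model: validated containers, readers/writers and per-passage summaries.

A multi-passage line-transect survey is held as three tables:

* **transects** — one row per (transect, passage) walk with its effort in km,
  time of day, and days elapsed since the transect was cut open;
* **observations** — one row per species per sighted group, with the
  perpendicular distance of the group centre to the line (recorded in
  centimetres in the field protocol) and the observed / estimated group
  sizes.  Mixed-species ("poly-specific") groups appear as several rows
  sharing one ``group_event_id`` and the same distance;
* **heard** — groups that were heard vocalising but never seen, binned into
  three coarse distance categories (no measured perpendicular distance).

Passages are repeated walks of the same transect: P1 is the cutting walk,
P2 the same-day afternoon walk, P3 the next morning, P4 at least three days
later.  Encounter rates count observed group events plus heard-only records;
heard-only records never enter detection-function fitting.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("disturbsamp")

#: perpendicular distances are stored in centimetres (field protocol) and
#: converted to metres exactly once, at the detection-model boundary.
CM_PER_M = 100.0

PASSAGES = (1, 2, 3, 4)
HEARD_CATEGORIES = ("close", "far", "very_far")
TIMES_OF_DAY = ("morning", "afternoon")

TRANSECT_COLUMNS = ["transect_id", "passage", "effort_km", "time_of_day", "days_since_cut"]
OBSERVATION_COLUMNS = [
    "transect_id", "passage", "group_event_id", "species",
    "perp_distance_cm", "observed_size", "estimated_size",
]
HEARD_COLUMNS = ["transect_id", "passage", "species", "category"]


class SurveyValidationError(ValueError):
    """A survey table violates the data model; the message names the row."""


@dataclasses.dataclass(frozen=True)
class TransectRecord:
    transect_id: str
    passage: int
    effort_km: float
    time_of_day: str
    days_since_cut: float = 0.0


@dataclasses.dataclass(frozen=True)
class GroupObservation:
    transect_id: str
    passage: int
    group_event_id: str
    species: str
    perp_distance_cm: float
    observed_size: int
    estimated_size: float


@dataclasses.dataclass(frozen=True)
class HeardDetection:
    transect_id: str
    passage: int
    species: str
    category: str


def _require_columns(df: pd.DataFrame, cols: Sequence[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SurveyValidationError(f"{name} table is missing column(s) {missing}")


def _numeric(df: pd.DataFrame, col: str, name: str) -> pd.Series:
    out = pd.to_numeric(df[col], errors="coerce")
    bad = out.isna() & df[col].notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise SurveyValidationError(f"{name} row {row}: non-numeric value {df[col].iloc[row]!r} in '{col}'")
    return out


@dataclasses.dataclass
class SurveyDataset:
    """Validated container for one survey: transects, observations, heard-only.

    The three tables are plain :class:`pandas.DataFrame` objects with the
    column layouts of :data:`TRANSECT_COLUMNS`, :data:`OBSERVATION_COLUMNS`
    and :data:`HEARD_COLUMNS`.  Construction validates referential integrity
    (every observation and heard record points at an existing
    (transect_id, passage) walk) and the per-row invariants.
    """

    transects: pd.DataFrame
    observations: pd.DataFrame
    heard: pd.DataFrame

    def __post_init__(self) -> None:
        self.transects = self.transects.reset_index(drop=True).copy()
        self.observations = self.observations.reset_index(drop=True).copy()
        self.heard = self.heard.reset_index(drop=True).copy()
        self.validate()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        t, o, h = self.transects, self.observations, self.heard
        _require_columns(t, TRANSECT_COLUMNS, "transects")
        _require_columns(o, OBSERVATION_COLUMNS, "observations")
        _require_columns(h, HEARD_COLUMNS, "heard")

        t["passage"] = _numeric(t, "passage", "transects").astype(int)
        t["effort_km"] = _numeric(t, "effort_km", "transects")
        t["days_since_cut"] = _numeric(t, "days_since_cut", "transects")
        for i, row in t.iterrows():
            if row.passage not in PASSAGES:
                raise SurveyValidationError(f"transects row {i}: unknown passage {row.passage}")
            if not row.effort_km > 0:
                raise SurveyValidationError(f"transects row {i}: effort_km must be > 0, got {row.effort_km}")
            if row.time_of_day not in TIMES_OF_DAY:
                raise SurveyValidationError(f"transects row {i}: time_of_day {row.time_of_day!r} not in {TIMES_OF_DAY}")
            if row.days_since_cut < 0:
                raise SurveyValidationError(f"transects row {i}: days_since_cut < 0")
            if row.passage == 2 and row.days_since_cut != 0:
                raise SurveyValidationError(f"transects row {i}: passage 2 must have days_since_cut = 0")
            if row.passage == 4 and row.days_since_cut < 3:
                raise SurveyValidationError(f"transects row {i}: passage 4 requires days_since_cut >= 3")
        dup = t.duplicated(subset=["transect_id", "passage"])
        if dup.any():
            i = int(np.flatnonzero(dup.to_numpy())[0])
            raise SurveyValidationError(f"transects row {i}: duplicate (transect_id, passage) "
                                        f"({t.transect_id.iloc[i]}, {t.passage.iloc[i]})")

        walks = set(zip(t.transect_id, t.passage))

        o["passage"] = _numeric(o, "passage", "observations").astype(int)
        o["perp_distance_cm"] = _numeric(o, "perp_distance_cm", "observations")
        o["observed_size"] = _numeric(o, "observed_size", "observations")
        o["estimated_size"] = _numeric(o, "estimated_size", "observations")
        for i, row in o.iterrows():
            if (row.transect_id, row.passage) not in walks:
                raise SurveyValidationError(
                    f"observations row {i}: orphan reference ({row.transect_id}, passage {row.passage})")
            # distance may be missing (P1 protocol records no distances)
            if not np.isnan(row.perp_distance_cm) and row.perp_distance_cm < 0:
                raise SurveyValidationError(f"observations row {i}: negative perpendicular distance")
            if row.observed_size < 1 or row.observed_size != int(row.observed_size):
                raise SurveyValidationError(f"observations row {i}: observed_size must be an integer >= 1")
            if row.estimated_size < row.observed_size:
                raise SurveyValidationError(
                    f"observations row {i}: estimated_size {row.estimated_size} < observed_size {row.observed_size}")

        for i, row in h.iterrows():
            if (row.transect_id, row.passage) not in walks:
                raise SurveyValidationError(
                    f"heard row {i}: orphan reference ({row.transect_id}, passage {row.passage})")
            if row.category not in HEARD_CATEGORIES:
                raise SurveyValidationError(f"heard row {i}: unknown category {row.category!r}")

    # -- accessors -------------------------------------------------------
    def group_events(self, passages: Iterable[int] | None = None,
                     species: str | None = None) -> pd.DataFrame:
        """One row per sighted group event (poly-specific groups count once).

        When ``species`` is given, events are species rows for that species
        (a poly-specific event contributes one event per member species).
        """
        o = self.observations
        if passages is not None:
            o = o[o.passage.isin(list(passages))]
        if species is not None:
            o = o[o.species == species]
            return o.copy()
        return o.drop_duplicates(subset=["transect_id", "passage", "group_event_id"]).copy()

    def poly_events(self, passages: Iterable[int] | None = None) -> pd.DataFrame:
        """Group events involving more than one species."""
        o = self.observations
        if passages is not None:
            o = o[o.passage.isin(list(passages))]
        nsp = o.groupby(["transect_id", "passage", "group_event_id"])["species"].nunique()
        keys = nsp[nsp > 1].index
        idx = pd.MultiIndex.from_frame(o[["transect_id", "passage", "group_event_id"]])
        return o[idx.isin(keys)].drop_duplicates(subset=["transect_id", "passage", "group_event_id"]).copy()

    def distances_m(self, passages: Iterable[int], species: str | None = None) -> np.ndarray:
        """Perpendicular distances in metres for detection-function fitting.

        Poly-specific events contribute one distance per event (all member
        species share the measured group centre) unless a species filter is
        applied.  Missing distances are dropped.
        """
        ev = self.group_events(passages, species)
        x = ev.perp_distance_cm.to_numpy(dtype=float) / CM_PER_M
        return x[~np.isnan(x)]

    def n_walks(self) -> int:
        return len(self.transects)


def read_survey(transects_path, observations_path, heard_path) -> SurveyDataset:
    """Read the three survey CSVs and return a validated :class:`SurveyDataset`."""
    for p in (transects_path, observations_path, heard_path):
        if not Path(p).exists():
            raise FileNotFoundError(p)
    t = pd.read_csv(transects_path, dtype={"transect_id": str})
    o = pd.read_csv(observations_path, dtype={"transect_id": str, "group_event_id": str})
    h = pd.read_csv(heard_path, dtype={"transect_id": str})
    if len(o) == 0:
        o = pd.DataFrame(columns=OBSERVATION_COLUMNS)
    if len(h) == 0:
        h = pd.DataFrame(columns=HEARD_COLUMNS)
    return SurveyDataset(t, o, h)


def write_survey(ds: SurveyDataset, out_dir) -> dict:
    """Write the dataset back to ``transects.csv``/``observations.csv``/``heard.csv``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "transects": out / "transects.csv",
        "observations": out / "observations.csv",
        "heard": out / "heard.csv",
    }
    ds.transects[TRANSECT_COLUMNS].to_csv(paths["transects"], index=False)
    ds.observations[OBSERVATION_COLUMNS].to_csv(paths["observations"], index=False)
    ds.heard[HEARD_COLUMNS].to_csv(paths["heard"], index=False)
    return paths


def aggregate_observer_counts(observed_counts: Sequence[float],
                              estimated_counts: Sequence[float]) -> tuple[int, float]:
    """Combine independent per-observer group-size counts into one record.

    Observed size is the highest individual count among observers (each
    observer can only undercount directly seen animals); estimated size is
    the mean of the per-observer estimates, which guards against single
    extreme acoustic extrapolations.  If the mean estimate falls below the
    best direct count it is floored there, since the estimate includes every
    animal that was seen.
    """
    if len(observed_counts) == 0 or len(estimated_counts) == 0:
        raise ValueError("need at least one observer count")
    if min(observed_counts) < 0 or min(estimated_counts) < 0:
        raise ValueError("counts must be non-negative")
    observed = int(max(observed_counts))
    estimated = float(np.mean(estimated_counts))
    if estimated < observed:
        logger.warning("mean estimated size %.2f below max observed %d; floored", estimated, observed)
        estimated = float(observed)
    return observed, estimated


def summarize_by_passage(ds: SurveyDataset) -> pd.DataFrame:
    """Per-passage descriptive summary plus a totals row.

    Columns mirror the standard survey summary: number of walks, fraction
    walked in the morning, summed effort, encounter rate of groups
    (observed events + heard-only records, per km), encounter rate of
    poly-specific group events, mean perpendicular distance (cm), and the
    heard-only counts per distance category.

    The ``Total`` row sums walks, efforts and counts.  Its encounter-rate
    entry is the effort-weighted rate (total groups / total effort); the
    unweighted mean of the per-passage rates is provided in
    ``df.attrs["encounter_rate_passage_mean"]`` since either convention is
    defensible for a grand "average" rate.
    """
    rows = []
    t = ds.transects
    present = [p for p in PASSAGES if (t.passage == p).any()]
    for p in present:
        tp = t[t.passage == p]
        ev = ds.group_events([p])
        poly = ds.poly_events([p])
        hp = ds.heard[ds.heard.passage == p]
        effort = float(tp.effort_km.sum())
        n_groups = len(ev) + len(hp)
        dist = ev.perp_distance_cm.dropna()
        rows.append({
            "passage": f"P{p}",
            "n_transects": len(tp),
            "morning_fraction": float((tp.time_of_day == "morning").mean()) if len(tp) else 0.0,
            "effort_km": effort,
            "encounter_rate": n_groups / effort if effort > 0 else 0.0,
            "poly_encounter_rate": len(poly) / effort if effort > 0 else 0.0,
            "mean_perp_distance_cm": float(dist.mean()) if len(dist) else np.nan,
            "heard_close": int((hp.category == "close").sum()),
            "heard_far": int((hp.category == "far").sum()),
            "heard_very_far": int((hp.category == "very_far").sum()),
        })
    if not rows:
        rows = []
    df = pd.DataFrame(rows, columns=[
        "passage", "n_transects", "morning_fraction", "effort_km", "encounter_rate",
        "poly_encounter_rate", "mean_perp_distance_cm", "heard_close", "heard_far", "heard_very_far",
    ])
    total_effort = float(df.effort_km.sum()) if len(df) else 0.0
    total_groups = len(ds.group_events()) + len(ds.heard)
    total = {
        "passage": "Total",
        "n_transects": int(df.n_transects.sum()) if len(df) else 0,
        "morning_fraction": float((t.time_of_day == "morning").mean()) if len(t) else 0.0,
        "effort_km": total_effort,
        "encounter_rate": total_groups / total_effort if total_effort > 0 else 0.0,
        "poly_encounter_rate": len(ds.poly_events()) / total_effort if total_effort > 0 else 0.0,
        "mean_perp_distance_cm": float(ds.observations.perp_distance_cm.dropna().mean())
        if len(ds.observations) and ds.observations.perp_distance_cm.notna().any() else np.nan,
        "heard_close": int(df.heard_close.sum()) if len(df) else 0,
        "heard_far": int(df.heard_far.sum()) if len(df) else 0,
        "heard_very_far": int(df.heard_very_far.sum()) if len(df) else 0,
    }
    if len(df):
        df = pd.concat([df, pd.DataFrame([total])], ignore_index=True)
    else:
        df = pd.DataFrame([total])
    df.attrs["encounter_rate_effort_weighted"] = total["encounter_rate"]
    df.attrs["encounter_rate_passage_mean"] = (
        float(df.encounter_rate.iloc[:-1].mean()) if len(df) > 1 else 0.0)
    return df
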