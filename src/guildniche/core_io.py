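"""Shared domain types and CSV readers/writers.

The pipeline consumes four plain CSV inputs — timestamped detection records,
camera deployment intervals, per-station covariates, and scat food-item
counts — and ships one packaged fixture: the published relative-frequency
(RF%) scat-composition table for three predators across the three study
areas (Chandratal, Kibber, Pin).
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from datetime import date, datetime
from importlib import resources
from pathlib import Path

import pandas as pd

#: Predators surveyed by the camera grid.
DEFAULT_PREDATORS = ("dog", "red_fox", "snow_leopard", "wolf")
#: Prey recorded by the same cameras; their trap success feeds the prey covariate.
DEFAULT_PREY = ("blue_sheep", "ibex", "livestock", "pika", "woolly_hare", "marmot")
DEFAULT_SPECIES = DEFAULT_PREDATORS + DEFAULT_PREY

_FIXTURE_NAME = "table4_scat_rf.csv"
_FIXTURE_SHA256 = "0b9aec1162eea8398e97f75238ee35f12e18fa9c795b345e2d9fc4c23df3eb69"

#: Itemized food categories, in published row order.
SCAT_ITEMS = (
    "blue_sheep", "ibex", "marmot", "stone_marten", "mountain_weasel",
    "lagomorph", "rodent", "bird", "insect",
    "goat", "sheep", "yak_cattle", "horse_donkey",
    "plant_material", "plastic_paper", "unidentified",
)
#: Aggregate row -> itemized rows it summarizes (fixture validation only).
SCAT_AGGREGATE_GROUPS = {
    "wild_animals": SCAT_ITEMS[:9],
    "domestic_animals": SCAT_ITEMS[9:13],
    "others": SCAT_ITEMS[13:],
}


class ValidationError(ValueError):
    """Input fails a structural contract (unknown label, out-of-window record...)."""


class FixtureIntegrityError(RuntimeError):
    """Packaged fixture content does not match its recorded checksum."""


@dataclass(frozen=True)
class DetectionRecord:
    """One camera photograph of one species: the atomic observation."""

    site_id: str
    species: str
    timestamp: datetime


@dataclass(frozen=True)
class Deployment:
    """Continuous active interval of one camera station."""

    site_id: str
    start: date
    end: date
    site_group: str = ""

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValidationError(f"deployment {self.site_id}: end {self.end} before start {self.start}")

    @property
    def effort_days(self) -> int:
        """Camera-days, counting both the mounting and retrieval day."""
        return (self.end - self.start).days + 1


@dataclass
class ScatTable:
    """Scat food-item composition, either raw occurrence counts or RF%.

    ``mode`` is ``"counts"`` for field data and ``"rf"`` when loaded from the
    packaged published table.  Aggregate rows (wild/domestic/others) are kept
    apart from itemized rows and are used only to validate the fixture —
    never as resource categories.
    """

    data: pd.DataFrame  # columns: site_group, predator, item, value
    mode: str = "counts"
    sample_sizes: dict[tuple[str, str], int] = field(default_factory=dict)
    aggregates: pd.DataFrame | None = None

    def profile(self, site_group: str, predator: str) -> pd.Series:
        """Itemized value vector (indexed by item) for one predator at one site group."""
        sel = self.data[(self.data["site_group"] == site_group) & (self.data["predator"] == predator)]
        if sel.empty:
            raise KeyError(f"no scat data for ({site_group}, {predator})")
        return sel.set_index("item")["value"]


def _parse_timestamp(raw: str, row: int):
    try:
        return datetime.fromisoformat(raw.strip())
    except ValueError as exc:
        raise ValidationError(f"row {row}: malformed timestamp {raw!r}") from exc


def read_records(
    path: str | Path,
    species: tuple[str, ...] = DEFAULT_SPECIES,
    deployments: list[Deployment] | None = None,
) -> list[DetectionRecord]:
    """Read detection records from CSV (``site_id,species,timestamp``, ISO-8601).

    Returns records sorted by (site_id, species, timestamp).  Species outside
    the configured vocabulary raise, as do records at sites absent from
    ``deployments`` (when given) or outside their deployment window.
    """
    df = pd.read_csv(path, dtype=str)
    required = {"site_id", "species", "timestamp"}
    if not required.issubset(df.columns):
        raise ValidationError(f"records CSV needs columns {sorted(required)}, got {list(df.columns)}")
    allowed = set(species)
    dep_by_site = {d.site_id: d for d in deployments} if deployments is not None else None
    out: list[DetectionRecord] = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        sp = str(row.species).strip()
        if sp not in allowed:
            raise ValidationError(
                f"row {idx}: unknown species {sp!r}; allowed: {sorted(allowed)}"
            )
        ts = _parse_timestamp(str(row.timestamp), idx)
        sid = str(row.site_id).strip()
        if dep_by_site is not None:
            dep = dep_by_site.get(sid)
            if dep is None:
                raise ValidationError(f"row {idx}: site {sid!r} absent from deployments")
            if not (dep.start <= ts.date() <= dep.end):
                raise ValidationError(
                    f"row {idx}: timestamp {ts} outside deployment [{dep.start}, {dep.end}] of {sid}"
                )
        out.append(DetectionRecord(sid, sp, ts))
    out.sort(key=lambda r: (r.site_id, r.species, r.timestamp))
    return out


def write_records(records: list[DetectionRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "site_id": [r.site_id for r in records],
            "species": [r.species for r in records],
            "timestamp": [r.timestamp.isoformat(sep=" ") for r in records],
        }
    ).to_csv(path, index=False)


def read_deployments(path: str | Path) -> list[Deployment]:
    """Read ``site_id,start,end[,site_group]`` CSV; one row per station."""
    df = pd.read_csv(path, dtype=str)
    if not {"site_id", "start", "end"}.issubset(df.columns):
        raise ValidationError("deployments CSV needs columns site_id,start,end")
    deps = []
    seen: set[str] = set()
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        sid = str(row.site_id).strip()
        if sid in seen:
            raise ValidationError(f"row {idx}: duplicate deployment for site {sid!r}")
        seen.add(sid)
        deps.append(
            Deployment(
                site_id=sid,
                start=date.fromisoformat(str(row.start).strip()),
                end=date.fromisoformat(str(row.end).strip()),
                site_group=str(getattr(row, "site_group", "")).strip(),
            )
        )
    return deps


def write_deployments(deployments: list[Deployment], path: str | Path) -> None:
    pd.DataFrame(
        {
            "site_id": [d.site_id for d in deployments],
            "start": [d.start.isoformat() for d in deployments],
            "end": [d.end.isoformat() for d in deployments],
            "site_group": [d.site_group for d in deployments],
        }
    ).to_csv(path, index=False)


def read_covariates(path: str | Path) -> pd.DataFrame:
    """Site covariate table: ``site_id`` plus numeric columns, indexed by site."""
    df = pd.read_csv(path)
    if "site_id" not in df.columns:
        raise ValidationError("covariates CSV needs a site_id column")
    df["site_id"] = df["site_id"].astype(str)
    df = df.set_index("site_id")
    if df.isna().any().any():
        bad = df.columns[df.isna().any()].tolist()
        raise ValidationError(f"missing covariate values in columns {bad}")
    return df


def write_covariates(cov: pd.DataFrame, path: str | Path) -> None:
    cov.to_csv(path, index_label="site_id")


def read_scats(path: str | Path) -> ScatTable:
    """Field scat CSV: ``site_group,predator,item,count`` occurrence counts."""
    df = pd.read_csv(path)
    need = {"site_group", "predator", "item", "count"}
    if not need.issubset(df.columns):
        raise ValidationError(f"scat CSV needs columns {sorted(need)}")
    if (df["count"] < 0).any():
        raise ValidationError("negative scat occurrence count")
    out = df.rename(columns={"count": "value"})[["site_group", "predator", "item", "value"]]
    return ScatTable(data=out.reset_index(drop=True), mode="counts")


def write_scats(table: ScatTable, path: str | Path) -> None:
    df = table.data.rename(columns={"value": "count" if table.mode == "counts" else "rf"})
    df.to_csv(path, index=False)


def load_table4_fixture() -> ScatTable:
    """Load the packaged published RF% scat table (checksum-verified).

    Itemized rows become the table body; the printed wild/domestic/others
    aggregates and per-column sample sizes are kept for validation only.
    """
    ref = resources.files("guildniche.data").joinpath(_FIXTURE_NAME)
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _FIXTURE_SHA256:
        raise FixtureIntegrityError(
            f"fixture {_FIXTURE_NAME} checksum {digest} != expected {_FIXTURE_SHA256}"
        )
    df = pd.read_csv(ref)
    items = df[df["kind"] == "item"][["site_group", "predator", "item", "value"]]
    aggregates = df[df["kind"] == "aggregate"][["site_group", "predator", "item", "value"]]
    sizes = {
        (r.site_group, r.predator): int(r.value)
        for r in df[df["kind"] == "sample_size"].itertuples(index=False)
    }
    return ScatTable(
        data=items.reset_index(drop=True),
        mode="rf",
        sample_sizes=sizes,
        aggregates=aggregates.reset_index(drop=True),
    )


def validate_fixture_aggregates(table: ScatTable, tol: float = 0.3) -> None:
    """Check every itemized group sums to its printed aggregate within ``tol``."""
    if table.aggregates is None:
        raise ValidationError("table carries no aggregate rows")
    for (sg, pred), sub in table.data.groupby(["site_group", "predator"]):
        vals = sub.set_index("item")["value"]
        aggs = table.aggregates[
            (table.aggregates["site_group"] == sg) & (table.aggregates["predator"] == pred)
        ].set_index("item")["value"]
        for agg_name, members in SCAT_AGGREGATE_GROUPS.items():
            s = float(vals.reindex(members).fillna(0.0).sum())
            printed = float(aggs[agg_name])
            if abs(s - printed) > tol:
                raise ValidationError(
                    f"({sg}, {pred}) {agg_name}: itemized sum {s:.1f} vs printed {printed:.1f}"
                )
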