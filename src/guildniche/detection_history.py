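"""From raw records to detection histories, effort, trap success and naïve occupancy.

Detection histories discretize each station's deployment into weekly sampling
occasions; the relative abundance index (RAI, "trap success") is independent
detections per 100 camera-days.
"""
from __future__ import annotations

from dataclasses import dataclass
from datetime import timedelta

import numpy as np
import pandas as pd

from .core_io import Deployment, DetectionRecord, ValidationError


@dataclass
class DetectionHistory:
    """Site × occasion binary detection matrix for one species.

    ``matrix`` holds 0/1 with NaN marking occasions outside a site's
    deployment.  Rows follow ``site_ids`` order (shared across species so
    histories align for the joint occupancy likelihood).
    """

    species: str
    site_ids: list[str]
    matrix: np.ndarray  # float array, values {0.0, 1.0, nan}
    occasion_days: int
    effort_days: dict[str, int]

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.matrix.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix,
            index=pd.Index(self.site_ids, name="site_id"),
            columns=[f"occ_{k + 1}" for k in range(self.n_occasions)],
        )


def filter_independent(
    records: list[DetectionRecord], window_minutes: float = 30
) -> list[DetectionRecord]:
    """Thin each (site, species) stream to independent detections.

    A record is kept iff at least ``window_minutes`` elapsed since the last
    *kept* record of the same species at the same station (sliding window);
    the first record of every stream is always kept.  Idempotent.
    """
    if window_minutes < 0:
        raise ValueError(f"window_minutes must be non-negative, got {window_minutes}")
    window = timedelta(minutes=window_minutes)
    ordered = sorted(records, key=lambda r: (r.site_id, r.species, r.timestamp))
    kept: list[DetectionRecord] = []
    last: dict[tuple[str, str], DetectionRecord] = {}
    for rec in ordered:
        key = (rec.site_id, rec.species)
        prev = last.get(key)
        if prev is None or rec.timestamp - prev.timestamp >= window:
            kept.append(rec)
            last[key] = rec
    return kept


def n_occasions_for(effort_days: int, occasion_days: int = 7) -> int:
    """Occasions spanned by a deployment; a trailing partial week still counts."""
    return -(-effort_days // occasion_days)  # ceil division


def build_history(
    records: list[DetectionRecord],
    deployments: list[Deployment],
    species: str,
    occasion_days: int = 7,
) -> DetectionHistory:
    """Weekly detection history for one species over all deployed stations.

    Occasion k at a site covers deployment days ``[7(k-1), 7k)`` relative to
    its start; a trailing partial occasion with at least one active day is
    valid (0/1), occasions beyond the deployment are missing (NaN).  The
    matrix width is the maximum occasion count over sites.  Records are
    expected to be independence-filtered already.
    """
    dep_by_site = {d.site_id: d for d in deployments}
    site_ids = [d.site_id for d in deployments]
    n_occ = max(n_occasions_for(d.effort_days, occasion_days) for d in deployments)
    mat = np.full((len(site_ids), n_occ), np.nan)
    idx = {sid: i for i, sid in enumerate(site_ids)}
    for i, d in enumerate(deployments):
        mat[i, : n_occasions_for(d.effort_days, occasion_days)] = 0.0
    for rec in records:
        if rec.species != species:
            continue
        dep = dep_by_site.get(rec.site_id)
        if dep is None:
            raise ValidationError(f"record at unknown site {rec.site_id!r}")
        day = (rec.timestamp.date() - dep.start).days
        if day < 0 or rec.timestamp.date() > dep.end:
            raise ValidationError(
                f"record {rec.species}@{rec.site_id} {rec.timestamp} outside deployment"
            )
        mat[idx[rec.site_id], day // occasion_days] = 1.0
    return DetectionHistory(
        species=species,
        site_ids=site_ids,
        matrix=mat,
        occasion_days=occasion_days,
        effort_days={d.site_id: d.effort_days for d in deployments},
    )


def total_effort(deployments: list[Deployment]) -> pd.Series:
    """Camera-days per site group, with an ``overall`` total row."""
    groups: dict[str, int] = {}
    for d in deployments:
        groups[d.site_group] = groups.get(d.site_group, 0) + d.effort_days
    out = pd.Series(groups, dtype=int).sort_index()
    out.loc["overall"] = int(out.sum())
    return out


def compute_rai(
    records: list[DetectionRecord],
    deployments: list[Deployment],
    species: list[str],
    by: str = "site",
) -> pd.DataFrame:
    """Trap success: 100 × independent detections / camera-days.

    ``by`` is ``"site"`` (per station — the unit for spatial overlap) or
    ``"site_group"``.  Returns long format with detection and effort counts
    retained so downstream gates (≥10 captures) can be applied.
    """
    if by not in ("site", "site_group"):
        raise ValueError("by must be 'site' or 'site_group'")
    key = (lambda d: d.site_id) if by == "site" else (lambda d: d.site_group)
    effort: dict[str, int] = {}
    group_of: dict[str, str] = {}
    for d in deployments:
        effort[key(d)] = effort.get(key(d), 0) + d.effort_days
        group_of[d.site_id] = d.site_group
    if any(v <= 0 for v in effort.values()):
        raise ValueError("zero effort in an aggregation unit; RAI undefined")
    counts: dict[tuple[str, str], int] = {}
    for rec in records:
        if rec.species not in species:
            continue
        unit = rec.site_id if by == "site" else group_of.get(rec.site_id, "")
        counts[(rec.species, unit)] = counts.get((rec.species, unit), 0) + 1
    rows = []
    for sp in species:
        for unit, eff in effort.items():
            n = counts.get((sp, unit), 0)
            rows.append(
                {
                    "species": sp,
                    "unit": unit,
                    "site_group": group_of.get(unit, unit) if by == "site" else unit,
                    "n_detections": n,
                    "effort_days": eff,
                    "rai": 100.0 * n / eff,
                }
            )
    return pd.DataFrame(rows)


def naive_occupancy(history: DetectionHistory) -> float:
    """Proportion of stations with at least one detection (uncorrected)."""
    if history.n_sites == 0:
        raise ValueError("empty history")
    detected = np.nansum(history.matrix, axis=1) > 0
    return float(detected.mean())
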