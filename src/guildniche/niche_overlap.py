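"""Pianka's niche-overlap index on resource-use vectors.

O_jk = Σ_i p_ij p_ik / sqrt(Σ_i p_ij² · Σ_i p_ik²) for two species j, k using
resource categories i.  The index is the cosine similarity of the two use
vectors: 0 = total separation, 1 = total overlap, and it is invariant to
rescaling either vector (raw counts, RAI or percentages all give the same
value).  For spatial overlap the resource categories are the camera stations
and the use vectors are per-station trap-success (RAI) values; confidence
intervals come from resampling stations with replacement.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class PiankaResult:
    species_a: str
    species_b: str
    value: float | None  # None when gated (too few captures)
    basis: list[str]
    site_group: str = ""
    ci: tuple[float, float] | None = None
    reps: int = 0
    gated: bool = False

    def render(self) -> str:
        """Table cell: "observed (lo–hi)" or the "−" gate convention."""
        if self.gated or self.value is None:
            return "−"
        if self.ci is None:
            return f"{self.value:.1f}"
        return f"{self.value:.1f} ({self.ci[0]:.1f}–{self.ci[1]:.1f})"


def pianka(u, v) -> float:
    """Pianka's index of two non-negative resource-use vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1 or u.size < 1:
        raise ValueError("u and v must be 1-D vectors of equal length >= 1")
    if (u < 0).any() or (v < 0).any():
        raise ValueError("resource-use vectors must be non-negative")
    su, sv = (u * u).sum(), (v * v).sum()
    if su == 0 or sv == 0:
        raise ValueError("all-zero resource-use vector; Pianka index undefined")
    return float((u * v).sum() / np.sqrt(su * sv))


def spatial_overlap(
    rai: pd.DataFrame,
    pair: tuple[str, str],
    site_group: str,
    reps: int = 999,
    seed: int | None = 0,
    min_captures: int = 10,
    ci_level: float = 0.95,
) -> PiankaResult:
    """Spatial Pianka overlap of a species pair over camera stations.

    ``rai`` is the long-format per-station trap-success table from
    :func:`guildniche.detection_history.compute_rai` (``by="site"``).  Each
    station is one resource category.  A species with fewer than
    ``min_captures`` independent detections in the site group gates the
    result (rendered "−").  The CI resamples stations with replacement
    (percentile method).
    """
    a, b = pair
    sub = rai[rai["site_group"] == site_group]
    wide = sub.pivot(index="unit", columns="species", values="rai")
    if a not in wide.columns or b not in wide.columns:
        raise KeyError(f"species {pair} not present in RAI table for {site_group!r}")
    counts = sub.groupby("species")["n_detections"].sum()
    stations = wide.index.tolist()
    if len(stations) < 2:
        raise ValueError(f"need >=2 stations in {site_group!r}")
    if counts.get(a, 0) < min_captures or counts.get(b, 0) < min_captures:
        return PiankaResult(a, b, None, stations, site_group, gated=True)
    u = wide[a].to_numpy()
    v = wide[b].to_numpy()
    value = pianka(u, v)
    ci = None
    if reps > 0:
        rng = np.random.default_rng(seed)
        vals = []
        for _ in range(reps):
            idx = rng.integers(0, len(stations), size=len(stations))
            ub, vb = u[idx], v[idx]
            if (ub * ub).sum() == 0 or (vb * vb).sum() == 0:
                continue  # replicate dropped one species entirely
            vals.append(pianka(ub, vb))
        if vals:
            alpha = (1 - ci_level) / 2
            lo, hi = np.percentile(vals, [100 * alpha, 100 * (1 - alpha)])
            ci = (float(lo), float(hi))
    return PiankaResult(a, b, value, stations, site_group, ci=ci, reps=reps)
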