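"""Scat-based diet profiles and dietary overlap.

The relative frequency of occurrence (RF) of food item i in a predator's
scats is 100 × (occurrences of item i) / (total occurrences of all items).
Dietary overlap between two predators is Pianka's index on their RF vectors
over a shared itemized resource basis (items absent from one diet count as
zero use, not missing).  Aggregate wild/domestic/others rows of the packaged
published table are never used as resource categories.
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .core_io import SCAT_ITEMS, ScatTable
from .niche_overlap import PiankaResult, pianka


@dataclass
class DietProfile:
    """RF% vector over itemized food categories for one predator at one site group."""

    predator: str
    site_group: str
    rf: pd.Series  # indexed by item, sums to ~100
    n_scats: int | None = None


def relative_frequency(
    counts: dict[str, int] | pd.Series,
    predator: str = "",
    site_group: str = "",
    n_scats: int | None = None,
) -> DietProfile:
    """RF_i = 100 · c_i / Σc from food-item occurrence counts."""
    c = pd.Series(counts, dtype=float)
    if (c < 0).any():
        raise ValueError("negative occurrence count")
    total = c.sum()
    if total <= 0:
        raise ValueError("all-zero occurrence counts; RF undefined")
    return DietProfile(
        predator=predator, site_group=site_group, rf=100.0 * c / total, n_scats=n_scats
    )


def profiles_from_table(table: ScatTable) -> dict[tuple[str, str], DietProfile]:
    """One DietProfile per (site_group, predator) column of a scat table.

    Count tables are converted to RF; RF tables (the packaged fixture) pass
    through unchanged.
    """
    out: dict[tuple[str, str], DietProfile] = {}
    for (sg, pred), sub in table.data.groupby(["site_group", "predator"]):
        vals = sub.set_index("item")["value"]
        n = table.sample_sizes.get((sg, pred))
        if table.mode == "counts":
            out[(sg, pred)] = relative_frequency(vals, pred, sg, n)
        else:
            out[(sg, pred)] = DietProfile(pred, sg, vals.astype(float), n)
    return out


def diet_overlap(profile_j: DietProfile, profile_k: DietProfile) -> PiankaResult:
    """Pianka's dietary overlap between two predators' RF vectors.

    The resource basis is the union of itemized categories, ordered as in
    the published table where applicable; items one predator never used are
    imputed as 0.
    """
    basis = [i for i in SCAT_ITEMS if i in profile_j.rf.index or i in profile_k.rf.index]
    extra = sorted((set(profile_j.rf.index) | set(profile_k.rf.index)) - set(basis))
    basis = basis + extra
    u = profile_j.rf.reindex(basis).fillna(0.0).to_numpy()
    v = profile_k.rf.reindex(basis).fillna(0.0).to_numpy()
    sg = profile_j.site_group if profile_j.site_group == profile_k.site_group else ""
    return PiankaResult(
        species_a=profile_j.predator,
        species_b=profile_k.predator,
        value=pianka(u, v),
        basis=basis,
        site_group=sg,
    )


def pairwise_overlaps(table: ScatTable) -> pd.DataFrame:
    """All within-site-group predator-pair overlaps of a scat table."""
    profs = profiles_from_table(table)
    rows = []
    groups = sorted({sg for sg, _ in profs})
    for sg in groups:
        preds = sorted(p for g, p in profs if g == sg)
        for i, a in enumerate(preds):
            for b in preds[i + 1 :]:
                res = diet_overlap(profs[(sg, a)], profs[(sg, b)])
                rows.append(
                    {
                        "site_group": sg,
                        "species_a": a,
                        "species_b": b,
                        "overlap": res.value,
                    }
                )
    return pd.DataFrame(rows)
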