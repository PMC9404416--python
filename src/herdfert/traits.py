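"""Derivation of heifer and cow fertility traits from service-event records.

Nine traits are derived per animal (heifer traits, one row per animal) or per
lactation (cow traits, one row per calving):

=========  ========  ======  =====================================================
trait      category  class   definition
=========  ========  ======  =====================================================
AFS        interval  heifer  age at first insemination, months
AFC        interval  heifer  age at first calving, months
SPCh       count     heifer  services required for a heifer to conceive
CFS        interval  cow     days from calving to the next first service
DO         interval  cow     days from calving to conception (days open)
SPC        count     cow     services required for a cow to conceive
FS80d      success   cow     inseminated within 80 d post-partum (1 = no, 2 = yes)
PD100d     success   cow     pregnant within 100 d post-partum (1 = no, 2 = yes)
PD200d     success   cow     pregnant within 200 d post-partum (1 = no, 2 = yes)
=========  ========  ======  =====================================================

Conception is attributed to the last service of a service episode, confirmed
either by a subsequent pregnant diagnosis (with no later service in that
episode) or by a next calving falling inside the gestation window 260-302
days after the service.  Unconfirmed conceptions leave the conception-based
traits missing (censoring), never zero-filled.

Editing removes biologically implausible values (CFS outside 21-250 d, DO
outside 21-435 d, and descriptive-range bounds for the other traits), drops
rows of animals with unknown parents, and deletes contemporary groups
(herd-year-season of birth for heifer rows, of calving for cow rows) smaller
than a minimum size.  Every removal is recorded once in the edit log.
"""

from __future__ import annotations

from dataclasses import dataclass
import datetime as dt

import numpy as np
import pandas as pd

__all__ = [
    "TraitSpec",
    "TRAITS",
    "TRAIT_ORDER",
    "HEIFER_TRAITS",
    "COW_TRAITS",
    "assign_season",
    "months_between",
    "attribute_conception",
    "derive_heifer_traits",
    "derive_cow_traits",
    "build_rows",
    "apply_edits",
    "build_contemporary_groups",
    "derive_phenotypes",
]

DAYS_PER_MONTH = 30.4375  # mean Gregorian month
GESTATION_MIN = 260
GESTATION_MAX = 302


@dataclass(frozen=True)
class TraitSpec:
    """Definition and edit bounds of one fertility trait."""

    name: str
    category: str  # interval | count | success
    animal_class: str  # heifer | cow
    lower: float
    upper: float
    cg_basis: str  # birth | calving

    def __post_init__(self):
        assert self.lower < self.upper
        if self.category == "success":
            assert (self.lower, self.upper) == (1, 2)
        assert self.cg_basis == ("birth" if self.animal_class == "heifer" else "calving")


# canonical reporting order (heifer traits, success traits, cow intervals);
# edit bounds are descriptive-range limits except the explicit biological
# thresholds CFS 21-250 d and DO 21-435 d.
TRAITS = {
    "AFS": TraitSpec("AFS", "interval", "heifer", 10, 30, "birth"),
    "AFC": TraitSpec("AFC", "interval", "heifer", 20, 48, "birth"),
    "SPCh": TraitSpec("SPCh", "count", "heifer", 1, 8, "birth"),
    "FS80d": TraitSpec("FS80d", "success", "cow", 1, 2, "calving"),
    "PD100d": TraitSpec("PD100d", "success", "cow", 1, 2, "calving"),
    "PD200d": TraitSpec("PD200d", "success", "cow", 1, 2, "calving"),
    "SPC": TraitSpec("SPC", "count", "cow", 1, 8, "calving"),
    "CFS": TraitSpec("CFS", "interval", "cow", 21, 250, "calving"),
    "DO": TraitSpec("DO", "interval", "cow", 21, 435, "calving"),
}
TRAIT_ORDER = ["AFS", "AFC", "SPCh", "FS80d", "PD100d", "PD200d", "SPC", "CFS", "DO"]
HEIFER_TRAITS = ["AFS", "AFC", "SPCh"]
COW_TRAITS = ["FS80d", "PD100d", "PD200d", "SPC", "CFS", "DO"]


def assign_season(d: dt.date) -> str:
    """Season of a date: summer is October-March, winter is April-September."""
    return "winter" if 4 <= d.month <= 9 else "summer"


def months_between(start: dt.date, end: dt.date) -> float:
    """Interval in months (days / mean month length), to one decimal."""
    return round((end.toordinal() - start.toordinal()) / DAYS_PER_MONTH, 1)


def attribute_conception(services, next_calving, diagnoses, episode_end=None):
    """Return the conceiving service date of an episode, or None.

    ``services`` is the episode's list of (date, outcome); the candidate is
    its last service. It is confirmed by a next calving 260-302 days later,
    or by a pregnant diagnosis after it (before the episode end) with no
    later service in the episode.
    """
    if not services:
        return None
    last = services[-1][0]
    if next_calving is not None:
        gest = next_calving.toordinal() - last.toordinal()
        return last if GESTATION_MIN <= gest <= GESTATION_MAX else None
    for ddate, result in diagnoses:
        if result == "pregnant" and ddate > last and (episode_end is None or ddate < episode_end):
            return last
    return None


def derive_heifer_traits(rec) -> dict | None:
    """AFS/AFC/SPCh for one animal, or None if it has no services at all.

    Missing components (no calving, unconfirmed conception) are NaN.
    The age covariate is the age at first insemination in months.
    """
    first_calving = rec.calvings[0][0] if rec.calvings else None
    episode = [s for s in rec.services if first_calving is None or s[0] < first_calving]
    if not episode:
        return None
    afs = months_between(rec.birth_date, episode[0][0])
    afc = months_between(rec.birth_date, first_calving) if first_calving else np.nan
    conceive = attribute_conception(episode, first_calving, rec.diagnoses, first_calving)
    spch = float(len(episode)) if conceive is not None else np.nan
    return {
        "parity": 1,
        "cg_date": rec.birth_date,
        "age_months": afs,
        "AFS": afs,
        "AFC": afc,
        "SPCh": spch,
    }


def derive_cow_traits(rec, lactation: int) -> dict | None:
    """CFS/DO/SPC/FS80d/PD100d/PD200d for the episode after one calving.

    ``lactation`` is the lactation number of the initiating calving; the
    produced row carries parity = lactation + 1 (the parity being created).
    Returns None when the calving is absent; traits whose defining events
    are absent are NaN.
    """
    calv = {l: d for d, l in rec.calvings}
    if lactation not in calv:
        return None
    c0 = calv[lactation]
    nxt = calv.get(lactation + 1)
    episode = [
        s for s in rec.services if s[0] > c0 and (nxt is None or s[0] < nxt)
    ]
    row = {
        "parity": lactation + 1,
        "cg_date": c0,
        "age_months": months_between(rec.birth_date, c0),
        "CFS": np.nan,
        "DO": np.nan,
        "SPC": np.nan,
        "FS80d": np.nan,
        "PD100d": np.nan,
        "PD200d": np.nan,
    }
    if not episode:
        return row
    cfs = episode[0][0].toordinal() - c0.toordinal()
    row["CFS"] = float(cfs)
    row["FS80d"] = 2.0 if cfs <= 80 else 1.0
    conceive = attribute_conception(episode, nxt, rec.diagnoses, nxt)
    if conceive is not None:
        do = conceive.toordinal() - c0.toordinal()
        row["DO"] = float(do)
        row["SPC"] = float(len(episode))
        row["PD100d"] = 2.0 if do <= 100 else 1.0
        row["PD200d"] = 2.0 if do <= 200 else 1.0
    return row


def build_rows(records) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Raw phenotype rows (pre-editing) for a RawHerdData collection.

    One heifer row per animal with >= 1 pre-calving service; one cow row per
    calving.  Returns (table, log) where log lists animals contributing no
    heifer row.
    """
    rows, log = [], []
    for rec in records:
        meta = {
            "animal_id": rec.animal_id,
            "herd": rec.herd_id,
            "sire": rec.sire_id,
            "dam": rec.dam_id,
        }
        h = derive_heifer_traits(rec)
        if h is None:
            log.append(
                {"animal_id": rec.animal_id, "parity": 1, "trait": "", "raw_value": np.nan,
                 "rule_violated": "no services"}
            )
        else:
            rows.append(dict(meta, row_type="heifer", **h))
        for _, lact in rec.calvings:
            c = derive_cow_traits(rec, lact)
            if c is not None:
                rows.append(dict(meta, row_type="cow", **c))
    cols = ["animal_id", "herd", "sire", "dam", "row_type", "parity", "cg_date", "age_months"]
    table = pd.DataFrame(rows, columns=cols + TRAIT_ORDER)
    return table, pd.DataFrame(log, columns=["animal_id", "parity", "trait", "raw_value", "rule_violated"])


def apply_edits(table: pd.DataFrame, specs=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bound edits and unknown-parent exclusion.

    Out-of-bound trait values are set missing and logged; rows whose animal
    has an unknown sire or dam are removed entirely; rows left with no trait
    value at all are dropped.  Returns (table, edit_log).
    """
    specs = specs or TRAITS
    table = table.copy()
    log = []
    no_parent = table["sire"].isna() | table["dam"].isna()
    for _, r in table[no_parent].iterrows():
        log.append(
            {"animal_id": r["animal_id"], "parity": r["parity"], "trait": "",
             "raw_value": np.nan, "rule_violated": "unknown parent"}
        )
    table = table[~no_parent]
    present = [t for t in specs if t in table.columns]
    for t in present:
        spec = specs[t]
        vals = table[t]
        bad = vals.notna() & ((vals < spec.lower) | (vals > spec.upper))
        for _, r in table[bad].iterrows():
            log.append(
                {"animal_id": r["animal_id"], "parity": r["parity"], "trait": t,
                 "raw_value": r[t], "rule_violated": f"outside [{spec.lower}, {spec.upper}]"}
            )
        table.loc[bad, t] = np.nan
    empty = table[present].isna().all(axis=1)
    for _, r in table[empty].iterrows():
        log.append(
            {"animal_id": r["animal_id"], "parity": r["parity"], "trait": "",
             "raw_value": np.nan, "rule_violated": "no trait values"}
        )
    table = table[~empty].reset_index(drop=True)
    return table, pd.DataFrame(log, columns=["animal_id", "parity", "trait", "raw_value", "rule_violated"])


def build_contemporary_groups(table: pd.DataFrame, min_size: int = 3):
    """Fill cg_code = herd-year-season and drop undersized groups.

    The grouping date is the birth date for heifer rows and the calving date
    for cow rows (carried in ``cg_date``).  Groups with fewer than
    ``min_size`` rows are removed and their rows logged.
    """
    table = table.copy()
    table["cg_code"] = [
        f"{h}-{d.year}-{assign_season(d)}" for h, d in zip(table["herd"], table["cg_date"])
    ]
    # heifer and cow rows never share a group even if codes coincide
    full = table["row_type"] + ":" + table["cg_code"]
    sizes = full.value_counts()
    small = full.map(sizes) < min_size
    log = [
        {"animal_id": r["animal_id"], "parity": r["parity"], "trait": "",
         "raw_value": np.nan, "rule_violated": f"contemporary group < {min_size}"}
        for _, r in table[small].iterrows()
    ]
    table = table[~small].reset_index(drop=True)
    return table, pd.DataFrame(log, columns=["animal_id", "parity", "trait", "raw_value", "rule_violated"])


def derive_phenotypes(records, min_cg_size: int = 3, require_parents: bool = True):
    """Full derivation pipeline: rows -> edits -> contemporary groups.

    Returns ``(table, edit_log)``: a phenotype table sorted by (animal,
    row_type, parity) with one column per trait (NaN = missing) plus
    ``cg_code`` and ``age_months``, and the concatenated edit log.
    """
    table, log0 = build_rows(records)
    if not require_parents:
        table = table.copy()
        table[["sire", "dam"]] = table[["sire", "dam"]].fillna("?")
    table, log1 = apply_edits(table)
    table, log2 = build_contemporary_groups(table, min_size=min_cg_size)
    table = table.sort_values(["animal_id", "row_type", "parity"], kind="stable").reset_index(
        drop=True
    )
    logs = [l for l in (log0, log1, log2) if len(l)]
    edit_log = (
        pd.concat(logs, ignore_index=True)
        if logs
        else pd.DataFrame(columns=["animal_id", "parity", "trait", "raw_value", "rule_violated"])
    )
    return table, edit_log
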