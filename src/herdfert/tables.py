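"""Delimited-text input/output with strict schema validation.

All on-disk formats are plain delimited text with named header columns:

* service records: ``animal_id, herd, birth_date, sire, dam, event_type,
  event_date, event_value`` — one row per reproductive event
  (SERVICE / CALVING / DIAGNOSIS);
* pedigree: ``animal, sire, dam, birth_date`` with ``0`` for unknown parents;
* phenotypes: one row per heifer or per cow-lactation record;
* results: a square trait-by-trait matrix (heritabilities on the diagonal,
  genetic correlations above, phenotypic below, each ``mean±sd``) plus a
  long-format table.

Every input row is either parsed or recorded once in the edit log with a
machine-readable reason code; rows are never dropped silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import datetime as dt

import numpy as np
import pandas as pd

from .pedigree import Pedigree

__all__ = [
    "TableDialect",
    "RawHerdData",
    "SchemaError",
    "read_service_records",
    "write_service_records",
    "read_pedigree",
    "write_pedigree",
    "read_phenotypes",
    "write_phenotypes",
    "write_results",
    "read_results_long",
]

SERVICE_COLUMNS = [
    "animal_id",
    "herd",
    "birth_date",
    "sire",
    "dam",
    "event_type",
    "event_date",
    "event_value",
]
PEDIGREE_COLUMNS = ["animal", "sire", "dam", "birth_date"]
UNKNOWN_PARENT = "0"  # on-disk sentinel (animal-breeding file convention)


class SchemaError(ValueError):
    """A required column is missing or an id constraint is violated."""


@dataclass(frozen=True)
class TableDialect:
    """How a delimited file is parsed: separator, date format, missing token."""

    delimiter: str = ","
    date_format: str = "%Y-%m-%d"
    missing_token: str = ""

    def parse_date(self, s):
        if s is None or (isinstance(s, float) and np.isnan(s)):
            return None
        s = str(s).strip()
        if s == self.missing_token or s == "":
            return None
        try:
            return dt.datetime.strptime(s, self.date_format).date()
        except ValueError:
            return None

    def format_date(self, d) -> str:
        if d is None:
            return self.missing_token
        return d.strftime(self.date_format)


@dataclass
class RawHerdData:
    """Per-animal reproductive event history.

    ``services`` are (date, outcome) with outcome in {"success", "failure",
    "unknown"}; ``calvings`` are (date, lactation_number); ``diagnoses`` are
    (date, result) with result in {"pregnant", "open"}.  Event lists are kept
    strictly increasing in date.
    """

    animal_id: str
    herd_id: str
    birth_date: dt.date
    sire_id: str | None = None
    dam_id: str | None = None
    services: list = field(default_factory=list)
    calvings: list = field(default_factory=list)
    diagnoses: list = field(default_factory=list)


def _require_columns(df: pd.DataFrame, required, path):
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column '{col}'")


def read_service_records(path, dialect: TableDialect = TableDialect()):
    """Read a service/event table into per-animal :class:`RawHerdData`.

    Returns ``(records, edit_log)`` where ``records`` is a list with one
    entry per animal and ``edit_log`` is a DataFrame of rejected rows, each
    with a machine-readable ``reason`` code.
    """
    df = pd.read_csv(path, sep=dialect.delimiter, dtype=str, keep_default_na=False)
    _require_columns(df, SERVICE_COLUMNS, path)

    log_rows = []
    animals: dict[str, RawHerdData] = {}

    def reject(i, row, reason):
        log_rows.append({"row": i, "animal_id": row.get("animal_id", ""), "reason": reason})

    for i, row in enumerate(df.to_dict("records")):
        aid = row["animal_id"].strip()
        if not aid:
            reject(i, row, "missing animal_id")
            continue
        etype = row["event_type"].strip().upper()
        edate = dialect.parse_date(row["event_date"])
        if edate is None:
            reject(i, row, "unparseable date")
            continue
        if aid not in animals:
            bdate = dialect.parse_date(row["birth_date"])
            if bdate is None:
                reject(i, row, "unparseable date")
                continue

            def parent(v):
                v = v.strip()
                return None if v in (UNKNOWN_PARENT, "", dialect.missing_token) else v

            animals[aid] = RawHerdData(
                animal_id=aid,
                herd_id=row["herd"].strip(),
                birth_date=bdate,
                sire_id=parent(row["sire"]),
                dam_id=parent(row["dam"]),
            )
        rec = animals[aid]
        val = row["event_value"].strip()
        if etype == "SERVICE":
            outcome = val.lower() if val.lower() in ("success", "failure", "unknown") else "unknown"
            if rec.services and edate <= rec.services[-1][0]:
                reject(i, row, "non-increasing service date")
                continue
            rec.services.append((edate, outcome))
        elif etype == "CALVING":
            try:
                lact = int(val)
            except ValueError:
                reject(i, row, "bad lactation number")
                continue
            if lact < 1:
                reject(i, row, "bad lactation number")
                continue
            if edate <= rec.birth_date:
                reject(i, row, "calving not after birth")
                continue
            if rec.calvings and (edate <= rec.calvings[-1][0] or lact <= rec.calvings[-1][1]):
                reject(i, row, "non-increasing calving")
                continue
            rec.calvings.append((edate, lact))
        elif etype == "DIAGNOSIS":
            result = val.lower()
            if result not in ("pregnant", "open"):
                reject(i, row, "bad diagnosis result")
                continue
            rec.diagnoses.append((edate, result))
        else:
            reject(i, row, "unknown event type")

    edit_log = pd.DataFrame(log_rows, columns=["row", "animal_id", "reason"])
    return list(animals.values()), edit_log


def write_service_records(records, path, dialect: TableDialect = TableDialect()):
    """Write RawHerdData back to the long event CSV (inverse of the reader)."""
    rows = []
    for rec in records:
        meta = {
            "animal_id": rec.animal_id,
            "herd": rec.herd_id,
            "birth_date": dialect.format_date(rec.birth_date),
            "sire": rec.sire_id or UNKNOWN_PARENT,
            "dam": rec.dam_id or UNKNOWN_PARENT,
        }
        events = (
            [("SERVICE", d, o) for d, o in rec.services]
            + [("CALVING", d, str(l)) for d, l in rec.calvings]
            + [("DIAGNOSIS", d, r) for d, r in rec.diagnoses]
        )
        events.sort(key=lambda e: (e[1], e[0]))
        for etype, edate, val in events:
            rows.append(
                dict(meta, event_type=etype, event_date=dialect.format_date(edate), event_value=val)
            )
    pd.DataFrame(rows, columns=SERVICE_COLUMNS).to_csv(path, sep=dialect.delimiter, index=False)


# ----------------------------------------------------------------------
# pedigree
# ----------------------------------------------------------------------
def read_pedigree(path, dialect: TableDialect = TableDialect()) -> Pedigree:
    """Read an animal/sire/dam/birth_date table into a validated Pedigree.

    Parents that have no animal row of their own are added as founders with
    unknown birth date; a duplicated animal id raises :class:`SchemaError`.
    """
    df = pd.read_csv(path, sep=dialect.delimiter, dtype=str, keep_default_na=False)
    _require_columns(df, PEDIGREE_COLUMNS, path)
    dupes = df["animal"][df["animal"].duplicated()]
    if len(dupes):
        raise SchemaError(f"{path}: duplicate animal ids: {sorted(set(dupes))}")
    frame = pd.DataFrame(
        {
            "animal": df["animal"].str.strip(),
            "sire": df["sire"].str.strip().replace({UNKNOWN_PARENT: None, "": None}),
            "dam": df["dam"].str.strip().replace({UNKNOWN_PARENT: None, "": None}),
            "birth_date": [dialect.parse_date(v) for v in df["birth_date"]],
        }
    )
    return Pedigree.from_frame(frame)


def write_pedigree(ped: Pedigree, path, dialect: TableDialect = TableDialect()):
    df = ped.to_frame()
    if dialect.date_format != "%Y-%m-%d":
        df["birth_date"] = [
            dialect.format_date(dt.date.fromisoformat(v)) if v else "" for v in df["birth_date"]
        ]
    df.to_csv(path, sep=dialect.delimiter, index=False)


# ----------------------------------------------------------------------
# phenotypes
# ----------------------------------------------------------------------
def write_phenotypes(table: pd.DataFrame, path, dialect: TableDialect = TableDialect()):
    table.to_csv(path, sep=dialect.delimiter, index=False, na_rep=dialect.missing_token or "NA")


def read_phenotypes(path, dialect: TableDialect = TableDialect()) -> pd.DataFrame:
    na = dialect.missing_token or "NA"
    df = pd.read_csv(
        path, sep=dialect.delimiter, na_values=[na], keep_default_na=False,
        dtype={"animal_id": str, "herd": str, "cg_code": str},
    )
    return df


# ----------------------------------------------------------------------
# results
# ----------------------------------------------------------------------
def write_results(summary, path_matrix, path_long=None, ndec: int = 6):
    """Write a genetic-parameter summary as matrix + long-format CSVs.

    The matrix file is square in the summary's trait order: heritability
    (mean±sd) on the diagonal, genetic correlations above it, phenotypic
    correlations below.  The long file has one row per (trait_a, trait_b,
    statistic) with the posterior mean and SD and round-trips to 6 decimals.
    """
    traits = list(summary.traits)
    t = len(traits)

    def cell(m, s):
        return f"{m:.{ndec}f}±{s:.{ndec}f}"

    mat = pd.DataFrame(index=traits, columns=traits, dtype=object)
    long_rows = []
    for i, a in enumerate(traits):
        mat.loc[a, a] = cell(summary.h2_mean[i], summary.h2_sd[i])
        long_rows.append((a, a, "h2", summary.h2_mean[i], summary.h2_sd[i]))
        for j in range(i + 1, t):
            b = traits[j]
            mat.loc[a, b] = cell(summary.rg_mean[i, j], summary.rg_sd[i, j])
            mat.loc[b, a] = cell(summary.rp_mean[i, j], summary.rp_sd[i, j])
            long_rows.append((a, b, "rg", summary.rg_mean[i, j], summary.rg_sd[i, j]))
            long_rows.append((a, b, "rp", summary.rp_mean[i, j], summary.rp_sd[i, j]))
    mat.index.name = "trait"
    mat.to_csv(path_matrix)
    if path_long is not None:
        pd.DataFrame(
            long_rows, columns=["trait_a", "trait_b", "statistic", "posterior_mean", "posterior_sd"]
        ).to_csv(path_long, index=False, float_format=f"%.{ndec}f")


def read_results_long(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"trait_a": str, "trait_b": str, "statistic": str})
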