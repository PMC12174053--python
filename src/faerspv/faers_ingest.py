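"""Reading, deduplicating and joining FAERS-style report tables.

The ingest contract mirrors how spontaneous-report databases are prepared
for disproportionality analysis:

* reports are deduplicated by CASEID, keeping the version with the latest
  FDA receipt date and, among ties, the largest PRIMARYID;
* the analysis cohort is restricted to reports naming the target drug as
  primary suspect (role code PS), matched by exact normalized drug name
  (upper-cased, whitespace-collapsed) against a synonym list — never by
  substring, which would catch combination products;
* ages are normalized to years from FAERS age-unit codes; partial dates
  (YYYYMM or bare YYYY) are retained for descriptive tables but excluded
  from day-resolution computations such as time-to-onset;
* PTs map to a single primary system organ class (SOC) through a
  user-supplied table; unmapped PTs fall into the sentinel SOC "UNMAPPED".
"""

from __future__ import annotations

import datetime as _dt
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dialect import SchemaError, read_table

UNMAPPED_SOC = "UNMAPPED"

#: FAERS age-unit codes → factor converting to years.  A missing unit code
#: is treated as years (the overwhelmingly dominant unit in practice).
AGE_UNIT_TO_YEARS = {
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.18,
    "DY": 1.0 / 365.25,
    "DEC": 10.0,
    "HR": 1.0 / 8766.0,
    "": 1.0,
}

AGE_GROUP_LABELS = ("<18", "18-64.9", "65-85", ">85")
WEIGHT_BAND_LABELS = ("<50", "50-100", ">100")
MISSING_LABEL = "Missing"

#: Occupation codes collapsed for consumer-vs-professional contrasts.
DEFAULT_HCP_CODES = frozenset({"MD", "PH", "HP", "RN", "OT"})
CONSUMER_CLASS = "Consumer"
HCP_CLASS = "Healthcare professional"

OUTCOME_SEVERITY_ORDER = ("DE", "LT", "HO", "DS", "CA", "RI", "OT")


class IngestError(ValueError):
    """Invalid ingest configuration or inputs."""


def read_faers_table(path, table_kind: str) -> pd.DataFrame:
    """Read one '$'-delimited quarterly table (see :mod:`faerspv.dialect`)."""
    return read_table(path, table_kind)


# --------------------------------------------------------------------------
# dates and units
# --------------------------------------------------------------------------

def parse_faers_date(value) -> tuple[_dt.date | None, str]:
    """Parse a FAERS date string/int into ``(date, precision)``.

    Precision is ``"full"`` for YYYYMMDD, ``"partial"`` for YYYYMM/YYYY and
    ``"missing"`` otherwise.  Only full-precision values yield a date; the
    raw partial string is the caller's to keep.
    """
    s = str(value).strip()
    if not s or s in {"nan", "<NA>"}:
        return None, "missing"
    if not s.isdigit():
        return None, "missing"
    if len(s) == 8:
        try:
            return _dt.date(int(s[:4]), int(s[4:6]), int(s[6:8])), "full"
        except ValueError:
            return None, "partial"
    if len(s) in (4, 6):
        return None, "partial"
    return None, "missing"


def age_to_years(age, age_cod) -> float:
    """Normalize a FAERS (age, unit-code) pair to years; NaN if unusable."""
    s = str(age).strip()
    if not s:
        return float("nan")
    try:
        value = float(s)
    except ValueError:
        return float("nan")
    factor = AGE_UNIT_TO_YEARS.get(str(age_cod).strip().upper())
    if factor is None:
        return float("nan")
    years = value * factor
    return years if years >= 0 else float("nan")


def age_group_of(age_years: float) -> str:
    """Assign an age in years to the analysis bands.

    Half-open [18, 65) and [65, 85] conventions: 18 belongs to 18-64.9,
    65 and 85 to 65-85, anything above 85 to >85.
    """
    if age_years is None or np.isnan(age_years):
        return MISSING_LABEL
    if age_years < 18:
        return "<18"
    if age_years < 65:
        return "18-64.9"
    if age_years <= 85:
        return "65-85"
    return ">85"


def weight_band_of(weight_kg: float) -> str:
    if weight_kg is None or np.isnan(weight_kg):
        return MISSING_LABEL
    if weight_kg < 50:
        return "<50"
    if weight_kg <= 100:
        return "50-100"
    return ">100"


def occupation_class_of(occp_cod: str, hcp_codes: frozenset[str] = DEFAULT_HCP_CODES) -> str:
    code = str(occp_cod).strip().upper()
    if code == "CN":
        return CONSUMER_CLASS
    if code in hcp_codes:
        return HCP_CLASS
    return MISSING_LABEL


def normalize_drug_name(name: str) -> str:
    """Case-insensitive, whitespace-collapsed canonical form."""
    return re.sub(r"\s+", " ", str(name).strip()).upper()


def _normalize_drug_series(series: pd.Series) -> pd.Series:
    return series.astype(str).str.strip().str.replace(r"\s+", " ", regex=True).str.upper()


# --------------------------------------------------------------------------
# MedDRA mapping
# --------------------------------------------------------------------------

@dataclass
class MeddraMap:
    """PT → (display name, primary SOC) mapping.

    Each PT maps to exactly one SOC (the primary-SOC convention).  Lookups
    of unmapped PTs return the sentinel ``UNMAPPED`` SOC and are tallied in
    :attr:`unmapped_count`.
    """

    pt_to_soc: dict[str, str]
    pt_names: dict[str, str] = field(default_factory=dict)
    unmapped_count: int = 0

    @classmethod
    def from_rows(cls, rows: Iterable[tuple[str, str, str]]) -> "MeddraMap":
        pt_to_soc, pt_names = {}, {}
        for pt, pt_name, soc in rows:
            if pt in pt_to_soc and pt_to_soc[pt] != soc:
                raise IngestError(f"PT {pt!r} maps to multiple SOCs")
            pt_to_soc[pt] = soc
            pt_names[pt] = pt_name
        return cls(pt_to_soc=pt_to_soc, pt_names=pt_names)

    @classmethod
    def from_tsv(cls, path) -> "MeddraMap":
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        for col in ("pt", "pt_name", "soc"):
            if col not in frame.columns:
                raise SchemaError(f"MedDRA map {path}: missing column {col!r}")
        return cls.from_rows(frame[["pt", "pt_name", "soc"]].itertuples(index=False, name=None))

    def to_tsv(self, path) -> str:
        pd.DataFrame({
            "pt": list(self.pt_to_soc),
            "pt_name": [self.pt_names.get(pt, pt) for pt in self.pt_to_soc],
            "soc": list(self.pt_to_soc.values()),
        }).to_csv(path, sep="\t", index=False)
        return str(path)

    def soc_of(self, pt: str) -> str:
        soc = self.pt_to_soc.get(pt)
        if soc is None:
            self.unmapped_count += 1
            return UNMAPPED_SOC
        return soc


def map_pt_to_soc(pt: str, meddra_map: MeddraMap) -> str:
    """Total function over PTs: mapped SOC or the ``UNMAPPED`` sentinel."""
    return meddra_map.soc_of(pt)


# --------------------------------------------------------------------------
# deduplication and cohort selection
# --------------------------------------------------------------------------

def deduplicate_reports(demo: pd.DataFrame) -> pd.DataFrame:
    """One DEMO record per CASEID: keep the latest FDA date, ties broken by
    the largest PRIMARYID.  Idempotent and independent of input row order."""
    for col in ("primaryid", "caseid", "fda_dt"):
        if col not in demo.columns:
            raise SchemaError(f"DEMO frame lacks required column {col!r}")
    if demo.empty:
        return demo.copy()
    ordered = demo.sort_values(["caseid", "fda_dt", "primaryid"], kind="mergesort")
    kept = ordered.groupby("caseid", sort=True).tail(1)
    return kept.sort_values("primaryid", kind="mergesort").reset_index(drop=True)


def filter_primary_suspect(drug: pd.DataFrame, name_list: Sequence[str]) -> set[int]:
    """PRIMARYIDs with ≥1 primary-suspect mention of a listed drug name.

    Matching is exact on the normalized drug name or active ingredient.
    """
    if not name_list:
        raise IngestError("name_list must be non-empty")
    names = {normalize_drug_name(n) for n in name_list}
    ps = drug[drug["role_cod"].astype(str).str.strip().str.upper() == "PS"]
    if ps.empty:
        return set()
    by_name = _normalize_drug_series(ps["drugname"]).isin(names)
    by_ai = _normalize_drug_series(ps["prod_ai"]).isin(names)
    return set(ps.loc[by_name | by_ai, "primaryid"].astype(int).tolist())


@dataclass
class CaseData:
    """The joined, per-case analysis dataset.

    ``cases`` has one row per deduplicated PRIMARYID with columns::

        caseid fda_dt event_dt sex age_years age_group weight_kg
        weight_band occp_cod occp_class reporter_country outcomes
        reactions indications concomitants start_dt is_target analyzable

    ``outcomes``/``reactions``/``indications`` hold frozensets,
    ``concomitants`` a sorted tuple of normalized non-PS drug names,
    ``event_dt`` the raw date string and ``start_dt`` the earliest
    full-precision target-drug therapy start as int YYYYMMDD (<NA> if none).
    """

    cases: pd.DataFrame
    flow_counts: dict[str, int] = field(default_factory=dict)

    @property
    def target(self) -> pd.DataFrame:
        return self.cases[self.cases["is_target"]]

    @property
    def background(self) -> pd.DataFrame:
        return self.cases[~self.cases["is_target"]]

    @property
    def analyzable(self) -> pd.DataFrame:
        return self.cases[self.cases["analyzable"]]


def _sets_by_pid(child: pd.DataFrame, col: str, valid_pids: set[int]) -> tuple[dict[int, frozenset], int]:
    """Collect child-table values into per-PRIMARYID frozensets; counts
    orphan rows whose PRIMARYID has no surviving DEMO record."""
    if child.empty:
        return {}, 0
    orphan = ~child["primaryid"].isin(valid_pids)
    sub = child.loc[~orphan, ["primaryid", col]].sort_values("primaryid", kind="mergesort")
    pids = sub["primaryid"].to_numpy()
    vals = sub[col].to_numpy()
    uniq, starts = np.unique(pids, return_index=True)
    ends = np.append(starts[1:], len(vals))
    out = {int(u): frozenset(vals[s:e]) for u, s, e in zip(uniq, starts, ends)}
    return out, int(orphan.sum())


def join_case_data(
    demo: pd.DataFrame,
    drug: pd.DataFrame,
    reac: pd.DataFrame,
    ther: pd.DataFrame,
    indi: pd.DataFrame,
    outc: pd.DataFrame,
    target_names: Sequence[str],
) -> CaseData:
    """Join the six tables into one per-case analysis frame.

    ``demo`` must already be deduplicated.  Cases with no reactions are
    retained but flagged not analyzable (they cannot enter contingency
    tables).  Orphan child rows are counted in ``flow_counts``, not fatal.
    """
    pids = set(demo["primaryid"].astype(int).tolist())
    target_ids = filter_primary_suspect(drug, target_names)

    reactions, orphan_reac = _sets_by_pid(reac, "pt", pids)
    indications, orphan_indi = _sets_by_pid(indi, "indi_pt", pids)
    outcomes, orphan_outc = _sets_by_pid(outc, "outc_cod", pids)

    # concomitants: normalized names of non-PS mentions, one per case-drug
    non_ps = drug[drug["role_cod"].astype(str).str.strip().str.upper() != "PS"].copy()
    orphan_drug = int((~drug["primaryid"].isin(pids)).sum())
    concomitants: dict[int, tuple[str, ...]] = {}
    if not non_ps.empty:
        non_ps = non_ps[non_ps["primaryid"].isin(pids)]
        non_ps["_name"] = _normalize_drug_series(non_ps["drugname"])
        name_sets, _ = _sets_by_pid(non_ps, "_name", pids)
        concomitants = {p: tuple(sorted(s)) for p, s in name_sets.items()}

    # earliest full-precision therapy start among target-drug therapy rows:
    # THER links to DRUG through (primaryid, dsg_drug_seq == drug_seq).
    start_by_pid: dict[int, int] = {}
    orphan_ther = int((~ther["primaryid"].isin(pids)).sum()) if not ther.empty else 0
    if not ther.empty:
        names = {normalize_drug_name(n) for n in target_names}
        target_rows = drug[
            _normalize_drug_series(drug["drugname"]).isin(names)
            | _normalize_drug_series(drug["prod_ai"]).isin(names)
        ][["primaryid", "drug_seq"]]
        linked = ther.merge(
            target_rows, left_on=["primaryid", "dsg_drug_seq"],
            right_on=["primaryid", "drug_seq"], how="inner",
        )
        for pid, raw in zip(linked["primaryid"], linked["start_dt"]):
            date, precision = parse_faers_date(raw)
            if precision != "full":
                continue
            as_int = int(date.strftime("%Y%m%d"))
            pid = int(pid)
            if pid not in start_by_pid or as_int < start_by_pid[pid]:
                start_by_pid[pid] = as_int

    cases = demo.copy().reset_index(drop=True)
    cases["age_years"] = [age_to_years(a, c) for a, c in zip(cases["age"], cases["age_cod"])]
    cases["age_group"] = [age_group_of(a) for a in cases["age_years"]]
    weight = []
    for w, wc in zip(cases["wt"], cases["wt_cod"]):
        s = str(w).strip()
        try:
            kg = float(s) if s else float("nan")
        except ValueError:
            kg = float("nan")
        code = str(wc).strip().upper()
        if code == "LBS":
            kg *= 0.45359237
        weight.append(kg)
    cases["weight_kg"] = weight
    cases["weight_band"] = [weight_band_of(w) for w in cases["weight_kg"]]
    cases["occp_class"] = [occupation_class_of(o) for o in cases["occp_cod"]]
    pid_series = cases["primaryid"].astype(int)
    empty_fs = frozenset()
    cases["outcomes"] = [outcomes.get(p, empty_fs) for p in pid_series]
    cases["reactions"] = [reactions.get(p, empty_fs) for p in pid_series]
    cases["indications"] = [indications.get(p, empty_fs) for p in pid_series]
    cases["concomitants"] = [concomitants.get(p, ()) for p in pid_series]
    cases["start_dt"] = pd.array([start_by_pid.get(p) for p in pid_series], dtype="Int64")
    cases["is_target"] = [p in target_ids for p in pid_series]
    cases["analyzable"] = [len(r) > 0 for r in cases["reactions"]]
    cases = cases.drop(columns=["age", "age_cod", "wt", "wt_cod"])

    flow = {
        "cases": len(cases),
        "target_cases": int(cases["is_target"].sum()),
        "cases_without_reactions": int((~cases["analyzable"]).sum()),
        "orphan_reac_rows": orphan_reac,
        "orphan_indi_rows": orphan_indi,
        "orphan_outc_rows": orphan_outc,
        "orphan_drug_rows": orphan_drug,
        "orphan_ther_rows": orphan_ther,
    }
    return CaseData(cases=cases, flow_counts=flow)


def load_and_join(directory, target_names: Sequence[str]) -> tuple[CaseData, dict[str, int]]:
    """Read the six tables from *directory*, deduplicate, and join.

    Returns the joined dataset and the ingest flow counts (rows read per
    table, duplicates removed).
    """
    import os

    frames = {}
    for kind in ("demo", "drug", "reac", "ther", "indi", "outc"):
        frames[kind] = read_faers_table(os.path.join(os.fspath(directory), f"{kind.upper()}.txt"), kind)
    raw_demo = frames["demo"]
    demo = deduplicate_reports(raw_demo)
    case_data = join_case_data(
        demo, frames["drug"], frames["reac"], frames["ther"],
        frames["indi"], frames["outc"], target_names,
    )
    flow = {f"rows_read_{k}": len(v) for k, v in frames.items()}
    flow["demo_rows_read"] = len(raw_demo)
    flow["duplicates_removed"] = len(raw_demo) - len(demo)
    case_data.flow_counts.update(flow)
    return case_data, flow
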