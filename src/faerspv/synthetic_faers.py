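"""Synthetic FAERS-like cohort generator with planted ground truth.

Emulates the structure of FAERS quarterly ASCII archives — per-report
demographics, one primary-suspect drug plus concomitant mentions, one or
more MedDRA preferred-term (PT) reactions, therapy start and event dates,
outcome codes, and duplicate CASEID versions — while recording everything a
downstream test needs as ground truth: the planted relative reporting rate
(RR) per PT, the per-case reaction sets, which duplicate version must
survive deduplication, and the expected post-deduplication case count.

Reaction model
--------------
Each report includes each vocabulary PT independently with its baseline
probability; for reports whose primary suspect is the target drug, a
planted signal multiplies that PT's inclusion probability by RR (optionally
only within one sex).  Because a signal rescales only its own PT and leaves
every other PT untouched, the population reporting odds ratio of a planted
PT equals its RR exactly, which makes RR directly recoverable by the
disproportionality estimators.  Reports that would have no reaction receive
one PT drawn from the baseline distribution.  The expected number of PTs
per report is the sum of the baseline probabilities (≈2 for the default
vocabulary).

Onset model
-----------
Time-to-onset is log-normal in days (default μ=4.0, σ=1.5, truncated to
[0, 8000]), reproducing the heavy right tail seen in spontaneous-report
onset histograms; the event date is the therapy start date plus the onset,
and the FDA receipt date follows the event by a short reporting delay.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dialect import TABLE_COLUMNS, write_table


class ConfigError(ValueError):
    """A synthetic-cohort configuration violates an invariant."""


# --------------------------------------------------------------------------
# default study conditions
# --------------------------------------------------------------------------

def _norm(counts: Mapping[str, float]) -> dict[str, float]:
    total = float(sum(counts.values()))
    return {k: v / total for k, v in counts.items()}


#: (PT, SOC, baseline inclusion probability).  42 terms over 10 organ
#: classes; baselines sum to ≈2.0 so reports average about two reactions.
DEFAULT_EVENT_VOCABULARY: list[tuple[str, str, float]] = [
    ("Nausea", "Gastrointestinal disorders", 0.14),
    ("Vomiting", "Gastrointestinal disorders", 0.07),
    ("Diarrhoea", "Gastrointestinal disorders", 0.07),
    ("Stomatitis", "Gastrointestinal disorders", 0.03),
    ("Abdominal pain", "Gastrointestinal disorders", 0.05),
    ("Drug intolerance", "General disorders and administration site conditions", 0.08),
    ("Drug ineffective", "General disorders and administration site conditions", 0.10),
    ("Fatigue", "General disorders and administration site conditions", 0.09),
    ("Pain", "General disorders and administration site conditions", 0.07),
    ("Condition aggravated", "General disorders and administration site conditions", 0.04),
    ("Treatment failure", "General disorders and administration site conditions", 0.04),
    ("Death", "General disorders and administration site conditions", 0.02),
    ("Drug hypersensitivity", "Immune system disorders", 0.06),
    ("Anaphylactic reaction", "Immune system disorders", 0.01),
    ("Hypersensitivity", "Immune system disorders", 0.02),
    ("Anaemia", "Blood and lymphatic system disorders", 0.04),
    ("Pancytopenia", "Blood and lymphatic system disorders", 0.02),
    ("Leukopenia", "Blood and lymphatic system disorders", 0.03),
    ("Febrile neutropenia", "Blood and lymphatic system disorders", 0.015),
    ("Thrombocytopenia", "Blood and lymphatic system disorders", 0.02),
    ("Hepatotoxicity", "Hepatobiliary disorders", 0.02),
    ("Alanine aminotransferase increased", "Hepatobiliary disorders", 0.025),
    ("Hepatic function abnormal", "Hepatobiliary disorders", 0.015),
    ("Pneumonia", "Infections and infestations", 0.05),
    ("Sepsis", "Infections and infestations", 0.02),
    ("Septic shock", "Infections and infestations", 0.01),
    ("Urinary tract infection", "Infections and infestations", 0.03),
    ("Nasopharyngitis", "Infections and infestations", 0.04),
    ("Arthralgia", "Musculoskeletal and connective tissue disorders", 0.09),
    ("Joint swelling", "Musculoskeletal and connective tissue disorders", 0.04),
    ("Myalgia", "Musculoskeletal and connective tissue disorders", 0.03),
    ("Back pain", "Musculoskeletal and connective tissue disorders", 0.04),
    ("Muscular weakness", "Musculoskeletal and connective tissue disorders", 0.02),
    ("Headache", "Nervous system disorders", 0.08),
    ("Dizziness", "Nervous system disorders", 0.05),
    ("Neurotoxicity", "Nervous system disorders", 0.01),
    ("Seizure", "Nervous system disorders", 0.01),
    ("Alopecia", "Skin and subcutaneous tissue disorders", 0.04),
    ("Rash", "Skin and subcutaneous tissue disorders", 0.06),
    ("Pruritus", "Skin and subcutaneous tissue disorders", 0.04),
    ("Acute kidney injury", "Renal and urinary disorders", 0.02),
    ("Renal impairment", "Renal and urinary disorders", 0.015),
]

# Demographic mixes follow the marginal composition of a large published
# methotrexate reporting cohort (sex, age band, occupation, country,
# weight band, indication); '' denotes a missing value.
DEFAULT_SEX_PROBS = _norm({"F": 83928, "M": 38348, "": 8542})
DEFAULT_AGE_GROUP_PROBS = _norm(
    {"<18": 9751, "18-64.9": 55577, "65-85": 31324, ">85": 1247, "": 32919}
)
DEFAULT_OCCUPATION_PROBS = _norm(
    {"CN": 20258, "HP": 28905, "LW": 115, "MD": 45326, "OT": 26951, "PH": 5341, "RN": 12, "": 3910}
)
DEFAULT_COUNTRY_PROBS = _norm(
    {
        "UNITED STATES": 46017,
        "CANADA": 33374,
        "GERMANY": 9244,
        "FRANCE": 15000,
        "UNITED KINGDOM": 14000,
        "JAPAN": 13183,
    }
)
DEFAULT_WEIGHT_BAND_PROBS = _norm({"<50": 3270, "50-100": 14940, ">100": 2656, "": 109952})
DEFAULT_INDICATION_PROBS = _norm(
    {"Rheumatoid arthritis": 40615, "Acute lymphocytic leukaemia": 4398, "Psoriasis": 20000, "": 65805}
)
DEFAULT_OUTCOME_PROBS = {
    "OT": 0.403, "HO": 0.20, "DE": 0.05, "LT": 0.02,
    "DS": 0.03, "CA": 0.005, "RI": 0.005, "": 0.287,
}
#: Independent per-case inclusion probabilities for concomitant drugs.
DEFAULT_CONCOMITANT_PROBS = {
    "PREDNISONE": 0.15, "ENBREL": 0.13, "HUMIRA": 0.11,
    "FOLIC ACID": 0.20, "SULFASALAZINE": 0.06, "LEFLUNOMIDE": 0.05,
}
DEFAULT_BACKGROUND_DRUG_PROBS = {
    "ADALIMUMAB": 0.20, "INFLIXIMAB": 0.15, "IBUPROFEN": 0.20,
    "ATORVASTATIN": 0.15, "OMEPRAZOLE": 0.15, "AMOXICILLIN": 0.15,
}
TARGET_DRUG_NAMES = ("METHOTREXATE", "RHEUMATREX")
TARGET_ACTIVE_INGREDIENT = "METHOTREXATE"

_AGE_BOUNDS = {"<18": (1.0, 18.0), "18-64.9": (18.0, 65.0), "65-85": (65.0, 85.0), ">85": (85.0, 100.0)}
_WEIGHT_BOUNDS = {"<50": (30.0, 50.0), "50-100": (50.0, 100.0), ">100": (100.0, 150.0)}


@dataclass(frozen=True)
class PlantedSignal:
    """A PT whose inclusion probability is multiplied by ``rr`` for
    target-drug reports; ``sex`` restricts the signal to one sex."""

    pt: str
    rr: float
    sex: str | None = None


@dataclass(frozen=True)
class TTOModel:
    """Log-normal time-to-onset model in days; ``mu_by_sex`` overrides the
    log-scale location per sex (keys 'F'/'M')."""

    mu: float = 4.0
    sigma: float = 1.5
    max_days: int = 8000
    mu_by_sex: Mapping[str, float] | None = None


@dataclass(frozen=True)
class SyntheticConfig:
    n_reports: int = 10_000
    target_drug_prob: float = 0.2
    event_vocabulary: Sequence[tuple[str, str, float]] = tuple(DEFAULT_EVENT_VOCABULARY)
    planted_signals: Sequence[PlantedSignal] = ()
    sex_probs: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_SEX_PROBS))
    age_group_probs: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_AGE_GROUP_PROBS))
    occupation_probs: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_OCCUPATION_PROBS))
    country_probs: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_COUNTRY_PROBS))
    weight_band_probs: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_WEIGHT_BAND_PROBS))
    indication_probs: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_INDICATION_PROBS))
    outcome_probs: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_OUTCOME_PROBS))
    concomitant_probs: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_CONCOMITANT_PROBS))
    background_drug_probs: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_BACKGROUND_DRUG_PROBS))
    tto_model: TTOModel = TTOModel()
    duplicate_rate: float = 0.0
    partial_date_fraction: float = 0.10
    missing_rate_per_field: Mapping[str, float] = field(
        default_factory=lambda: {"event_dt": 0.25, "start_dt": 0.35}
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_reports <= 0:
            raise ConfigError("n_reports must be positive")
        if not 0.0 <= self.target_drug_prob <= 1.0:
            raise ConfigError("target_drug_prob must lie in [0, 1]")
        if not 0.0 <= self.duplicate_rate < 1.0:
            raise ConfigError("duplicate_rate must lie in [0, 1)")
        for name in ("sex_probs", "age_group_probs", "occupation_probs",
                     "country_probs", "weight_band_probs", "indication_probs",
                     "outcome_probs"):
            probs = getattr(self, name)
            if any(p < 0 for p in probs.values()) or abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ConfigError(f"{name} must be non-negative and sum to 1 (±1e-9)")
        pts = [pt for pt, _, _ in self.event_vocabulary]
        if len(set(pts)) != len(pts):
            raise ConfigError("event_vocabulary contains duplicate PTs")
        for pt, _, p in self.event_vocabulary:
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"event_vocabulary baseline for {pt!r} must lie in [0, 1]")
        for sig in self.planted_signals:
            if sig.rr < 0:
                raise ConfigError(f"planted signal RR for {sig.pt!r} must be ≥ 0")
            if sig.pt not in set(pts):
                raise ConfigError(f"planted signal PT {sig.pt!r} is not in the event vocabulary")
        for fname, rate in self.missing_rate_per_field.items():
            if not 0.0 <= rate <= 1.0:
                raise ConfigError(f"missing rate for {fname!r} must lie in [0, 1]")
        if not 0.0 <= self.partial_date_fraction <= 1.0:
            raise ConfigError("partial_date_fraction must lie in [0, 1]")


@dataclass
class FaersTables:
    """The six quarterly tables as DataFrames in the dialect's schema."""

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    ther: pd.DataFrame
    indi: pd.DataFrame
    outc: pd.DataFrame

    def as_dict(self) -> dict[str, pd.DataFrame]:
        return {"demo": self.demo, "drug": self.drug, "reac": self.reac,
                "ther": self.ther, "indi": self.indi, "outc": self.outc}


@dataclass
class SyntheticTruth:
    """Planted ground truth for a generated cohort."""

    pt_rr: dict[str, float]
    pt_case_counts: dict[str, int]
    pt_case_counts_target: dict[str, int]
    case_reactions: dict[int, frozenset[str]]
    target_ids: set[int]
    duplicate_versions: dict[int, list[tuple[int, int]]]
    survivors: dict[int, int]
    expected_case_count: int

    @property
    def survivor_pids(self) -> set[int]:
        return set(self.survivors.values())


@dataclass
class DuplicateTruth:
    """Which duplicate version of each affected case must survive
    deduplication (latest FDA date, ties to the largest PRIMARYID)."""

    versions: dict[int, list[tuple[int, int]]]
    survivors: dict[int, int]


# --------------------------------------------------------------------------
# date helpers
# --------------------------------------------------------------------------

def _dates_to_int(dates: np.ndarray) -> np.ndarray:
    idx = pd.DatetimeIndex(dates)
    return (idx.year * 10000 + idx.month * 100 + idx.day).to_numpy()


def _format_dates(dates: np.ndarray, missing: np.ndarray, partial: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    """Render datetime64 dates as FAERS strings with missing/partial policy.

    Partial dates are YYYYMM two thirds of the time and bare YYYY otherwise.
    """
    idx = pd.DatetimeIndex(dates)
    year = idx.year.to_numpy()
    full = (year * 10000 + idx.month.to_numpy() * 100 + idx.day.to_numpy()).astype("U8")
    month = (year * 100 + idx.month.to_numpy()).astype("U6")
    out = full.astype(object)
    keep_month = rng.random(len(out)) < 2.0 / 3.0
    out[partial & keep_month] = month[partial & keep_month]
    out[partial & ~keep_month] = year.astype("U4").astype(object)[partial & ~keep_month]
    out[missing] = ""
    return out


def _choice(rng: np.random.Generator, probs: Mapping[str, float], n: int) -> np.ndarray:
    keys = np.array(list(probs.keys()), dtype=object)
    p = np.array(list(probs.values()), dtype=float)
    return rng.choice(keys, size=n, p=p / p.sum())


# --------------------------------------------------------------------------
# generation
# --------------------------------------------------------------------------

def generate_cohort(config: SyntheticConfig) -> tuple[FaersTables, SyntheticTruth]:
    """Generate a cohort of reports plus its ground-truth record.

    Deterministic given ``config.seed``: every random stage draws from its
    own child stream of one root :class:`numpy.random.SeedSequence`, so the
    stages are replayable independently.
    """
    config.validate()
    n = config.n_reports
    root = np.random.SeedSequence(config.seed)
    (demo_ss, reac_ss, drug_ss, date_ss, dup_ss) = root.spawn(5)
    rng_demo = np.random.default_rng(demo_ss)
    rng_reac = np.random.default_rng(reac_ss)
    rng_drug = np.random.default_rng(drug_ss)
    rng_date = np.random.default_rng(date_ss)

    pids = np.arange(1_000_001, 1_000_001 + n, dtype=np.int64)
    caseids = pids.copy()

    # --- demographics -----------------------------------------------------
    sex = _choice(rng_demo, config.sex_probs, n)
    age_group = _choice(rng_demo, config.age_group_probs, n)
    age_years = np.full(n, np.nan)
    for band, (lo, hi) in _AGE_BOUNDS.items():
        mask = age_group == band
        age_years[mask] = rng_demo.uniform(lo, hi, mask.sum())
    # emit age under a mixture of units to exercise normalization
    age_cod = np.where(np.isnan(age_years), "", "YR").astype(object)
    age_str = np.where(np.isnan(age_years), "", np.round(age_years, 1).astype("U8")).astype(object)
    has_age = ~np.isnan(age_years)
    unit_pick = rng_demo.random(n)
    as_months = has_age & (unit_pick < 0.10)
    as_days = has_age & (unit_pick >= 0.10) & (unit_pick < 0.15)
    age_cod[as_months] = "MON"
    age_str[as_months] = np.char.mod("%d", np.round(age_years[as_months] * 12).astype(int))
    age_cod[as_days] = "DY"
    age_str[as_days] = np.char.mod("%d", np.round(age_years[as_days] * 365.25).astype(int))

    weight_band = _choice(rng_demo, config.weight_band_probs, n)
    weight = np.full(n, np.nan)
    for band, (lo, hi) in _WEIGHT_BOUNDS.items():
        mask = weight_band == band
        weight[mask] = rng_demo.uniform(lo, hi, mask.sum())
    wt_str = np.where(np.isnan(weight), "", np.round(weight, 1).astype("U8")).astype(object)
    wt_cod = np.where(np.isnan(weight), "", "KG").astype(object)

    occp = _choice(rng_demo, config.occupation_probs, n)
    country = _choice(rng_demo, config.country_probs, n)
    outcome = _choice(rng_demo, config.outcome_probs, n)
    indication = _choice(rng_demo, config.indication_probs, n)

    # --- drugs ------------------------------------------------------------
    is_target = rng_drug.random(n) < config.target_drug_prob
    target_name = np.where(rng_drug.random(n) < 0.85, TARGET_DRUG_NAMES[0], TARGET_DRUG_NAMES[1])
    background_name = _choice(rng_drug, config.background_drug_probs, n)
    ps_name = np.where(is_target, target_name, background_name).astype(object)
    ps_ai = np.where(is_target, TARGET_ACTIVE_INGREDIENT, background_name).astype(object)

    # --- reactions --------------------------------------------------------
    vocab_pts = np.array([pt for pt, _, _ in config.event_vocabulary], dtype=object)
    base = np.array([p for _, _, p in config.event_vocabulary], dtype=float)
    nvocab = len(vocab_pts)
    probs = np.tile(base, (n, 1))
    pt_index = {pt: i for i, pt in enumerate(vocab_pts)}
    pt_rr = {pt: 1.0 for pt in vocab_pts}
    for sig in config.planted_signals:
        col = pt_index[sig.pt]
        rows = is_target if sig.sex is None else (is_target & (sex == sig.sex))
        probs[rows, col] = np.minimum(base[col] * sig.rr, 1.0)
        pt_rr[sig.pt] = sig.rr
    # Rejection-sample whole rows until every report has ≥1 reaction:
    # conditioning on non-emptiness rescales all of a row's inclusion
    # probabilities by the same factor, so planted odds ratios are
    # preserved exactly (a forced single draw would dilute them).
    included = rng_reac.random((n, nvocab)) < probs
    empty = ~included.any(axis=1)
    while empty.any():
        idx = np.nonzero(empty)[0]
        redraw = rng_reac.random((len(idx), nvocab)) < probs[idx]
        included[idx] = redraw
        empty[idx] = ~redraw.any(axis=1)

    # --- dates ------------------------------------------------------------
    start_pool = np.arange(np.datetime64("2004-01-01"), np.datetime64("2024-07-01"))
    start_date = rng_date.choice(start_pool, size=n)
    mu = np.full(n, config.tto_model.mu)
    if config.tto_model.mu_by_sex:
        for s, m in config.tto_model.mu_by_sex.items():
            mu[sex == s] = m
    tto_days = np.clip(
        np.round(np.exp(rng_date.normal(mu, config.tto_model.sigma, n))),
        0, config.tto_model.max_days,
    ).astype(int)
    event_date = start_date + tto_days.astype("timedelta64[D]")
    fda_date = event_date + rng_date.integers(0, 91, n).astype("timedelta64[D]")
    fda_dt = _dates_to_int(fda_date)

    miss = config.missing_rate_per_field
    event_missing = rng_date.random(n) < float(miss.get("event_dt", 0.0))
    start_missing = rng_date.random(n) < float(miss.get("start_dt", 0.0))
    event_partial = ~event_missing & (rng_date.random(n) < config.partial_date_fraction)
    start_partial = ~start_missing & (rng_date.random(n) < config.partial_date_fraction)
    event_str = _format_dates(event_date, event_missing, event_partial, rng_date)
    start_str = _format_dates(start_date, start_missing, start_partial, rng_date)

    # --- assemble tables --------------------------------------------------
    demo = pd.DataFrame({
        "primaryid": pids, "caseid": caseids, "fda_dt": fda_dt,
        "event_dt": event_str, "sex": sex, "age": age_str, "age_cod": age_cod,
        "wt": wt_str, "wt_cod": wt_cod, "occp_cod": occp,
        "reporter_country": country,
    })

    rows, cols = np.nonzero(included)
    reac = pd.DataFrame({
        "primaryid": pids[rows], "caseid": caseids[rows], "pt": vocab_pts[cols],
    })

    drug_parts = [pd.DataFrame({
        "primaryid": pids, "caseid": caseids,
        "drug_seq": np.ones(n, dtype=np.int64),
        "role_cod": np.repeat("PS", n).astype(object),
        "drugname": ps_name, "prod_ai": ps_ai,
    })]
    seq_counter = np.full(n, 2, dtype=np.int64)
    for cname, cprob in config.concomitant_probs.items():
        hit = rng_drug.random(n) < cprob
        if hit.any():
            drug_parts.append(pd.DataFrame({
                "primaryid": pids[hit], "caseid": caseids[hit],
                "drug_seq": seq_counter[hit],
                "role_cod": np.repeat("C", int(hit.sum())).astype(object),
                "drugname": np.repeat(cname, int(hit.sum())).astype(object),
                "prod_ai": np.repeat(cname, int(hit.sum())).astype(object),
            }))
            seq_counter[hit] += 1
    drug = pd.concat(drug_parts, ignore_index=True).sort_values(
        ["primaryid", "drug_seq"], kind="stable").reset_index(drop=True)

    has_start = start_str != ""
    ther = pd.DataFrame({
        "primaryid": pids[has_start], "caseid": caseids[has_start],
        "dsg_drug_seq": np.ones(int(has_start.sum()), dtype=np.int64),
        "start_dt": start_str[has_start],
        "end_dt": np.repeat("", int(has_start.sum())).astype(object),
    })

    has_indi = indication != ""
    indi = pd.DataFrame({
        "primaryid": pids[has_indi], "caseid": caseids[has_indi],
        "indi_drug_seq": np.ones(int(has_indi.sum()), dtype=np.int64),
        "indi_pt": indication[has_indi],
    })

    has_outc = outcome != ""
    outc = pd.DataFrame({
        "primaryid": pids[has_outc], "caseid": caseids[has_outc],
        "outc_cod": outcome[has_outc],
    })

    tables = FaersTables(demo=demo, drug=drug, reac=reac, ther=ther, indi=indi, outc=outc)

    case_reactions = {
        int(pid): frozenset(vocab_pts[included[i]]) for i, pid in enumerate(pids)
    }
    counts_all = included.sum(axis=0)
    counts_target = included[is_target].sum(axis=0)
    truth = SyntheticTruth(
        pt_rr=pt_rr,
        pt_case_counts={pt: int(counts_all[i]) for i, pt in enumerate(vocab_pts)},
        pt_case_counts_target={pt: int(counts_target[i]) for i, pt in enumerate(vocab_pts)},
        case_reactions=case_reactions,
        target_ids=set(pids[is_target].tolist()),
        duplicate_versions={int(c): [(int(p), int(d))] for c, p, d in zip(caseids, pids, fda_dt)},
        survivors={int(c): int(p) for c, p in zip(caseids, pids)},
        expected_case_count=n,
    )

    if config.duplicate_rate > 0:
        tables, dup = inject_duplicates(tables, config.duplicate_rate, seed=dup_ss)
        truth.duplicate_versions.update(dup.versions)
        truth.survivors.update(dup.survivors)
    return tables, truth


def inject_duplicates(
    tables: FaersTables,
    duplicate_rate: float,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[FaersTables, DuplicateTruth]:
    """Emit extra versions of randomly chosen cases.

    Each selected case gains one or two additional versions sharing its
    CASEID but with strictly larger PRIMARYIDs and equal-or-later FDA
    receipt dates.  The truth table records every version and the one that
    the retention rule (latest FDA date, then largest PRIMARYID) keeps.
    A rate of 0 returns the input unchanged.
    """
    if not 0.0 <= duplicate_rate < 1.0:
        raise ConfigError("duplicate_rate must lie in [0, 1)")
    demo = tables.demo
    if demo["primaryid"].duplicated().any():
        raise ConfigError("input reports must have unique PRIMARYIDs")
    if duplicate_rate == 0.0 or len(demo) == 0:
        return tables, DuplicateTruth(versions={}, survivors={})

    rng = np.random.default_rng(seed)
    n = len(demo)
    chosen = np.nonzero(rng.random(n) < duplicate_rate)[0]
    if len(chosen) == 0:
        return tables, DuplicateTruth(versions={}, survivors={})
    extra_counts = 1 + (rng.random(len(chosen)) < 0.2).astype(int)  # 1 or 2 extras

    next_pid = int(demo["primaryid"].max()) + 1
    dup_rows = []       # (orig_row_index, new_pid, new_fda_dt)
    versions: dict[int, list[tuple[int, int]]] = {}
    for row_idx, k in zip(chosen, extra_counts):
        caseid = int(demo["caseid"].iloc[row_idx])
        orig_pid = int(demo["primaryid"].iloc[row_idx])
        orig_dt = int(demo["fda_dt"].iloc[row_idx])
        versions[caseid] = [(orig_pid, orig_dt)]
        base_date = pd.to_datetime(str(orig_dt), format="%Y%m%d")
        for _ in range(int(k)):
            delta = int(rng.integers(0, 181))
            new_dt = int((base_date + pd.Timedelta(days=delta)).strftime("%Y%m%d"))
            dup_rows.append((row_idx, next_pid, new_dt))
            versions[caseid].append((next_pid, new_dt))
            next_pid += 1
    survivors = {c: max(v, key=lambda t: (t[1], t[0]))[0] for c, v in versions.items()}

    extra_demo = demo.iloc[[r for r, _, _ in dup_rows]].copy()
    extra_demo["primaryid"] = [p for _, p, _ in dup_rows]
    extra_demo["fda_dt"] = [d for _, _, d in dup_rows]
    new_demo = pd.concat([demo, extra_demo], ignore_index=True)

    pid_map = pd.DataFrame({
        "primaryid": [int(demo["primaryid"].iloc[r]) for r, _, _ in dup_rows],
        "_new_pid": [p for _, p, _ in dup_rows],
    })

    def _dup_children(child: pd.DataFrame) -> pd.DataFrame:
        merged = child.merge(pid_map, on="primaryid", how="inner")
        if merged.empty:
            return child
        merged["primaryid"] = merged["_new_pid"]
        merged = merged.drop(columns="_new_pid")
        return pd.concat([child, merged], ignore_index=True)

    out = FaersTables(
        demo=new_demo,
        drug=_dup_children(tables.drug),
        reac=_dup_children(tables.reac),
        ther=_dup_children(tables.ther),
        indi=_dup_children(tables.indi),
        outc=_dup_children(tables.outc),
    )
    return out, DuplicateTruth(versions=versions, survivors=survivors)


# --------------------------------------------------------------------------
# output
# --------------------------------------------------------------------------

def write_faers_files(tables: FaersTables, directory: str | os.PathLike) -> dict[str, str]:
    """Write the six quarterly tables under *directory* as KIND.txt files."""
    os.makedirs(directory, exist_ok=True)
    paths = {}
    for kind, frame in tables.as_dict().items():
        path = os.path.join(os.fspath(directory), f"{kind.upper()}.txt")
        paths[kind] = write_table(frame, path, kind)
    return paths


def write_truth_files(truth: SyntheticTruth, directory: str | os.PathLike) -> dict[str, str]:
    """Emit the ground truth as TSVs: per-PT rates/counts and duplicate
    versions with their designated survivors."""
    os.makedirs(directory, exist_ok=True)
    pt_path = os.path.join(os.fspath(directory), "truth_pt.tsv")
    pd.DataFrame({
        "pt": list(truth.pt_rr),
        "rr": [truth.pt_rr[pt] for pt in truth.pt_rr],
        "case_count": [truth.pt_case_counts.get(pt, 0) for pt in truth.pt_rr],
        "case_count_target": [truth.pt_case_counts_target.get(pt, 0) for pt in truth.pt_rr],
    }).to_csv(pt_path, sep="\t", index=False)
    dup_path = os.path.join(os.fspath(directory), "truth_duplicates.tsv")
    rows = []
    for caseid, vers in sorted(truth.duplicate_versions.items()):
        for pid, dt in vers:
            rows.append({"caseid": caseid, "primaryid": pid, "fda_dt": dt,
                         "survivor": int(pid == truth.survivors[caseid])})
    pd.DataFrame(rows, columns=["caseid", "primaryid", "fda_dt", "survivor"]).to_csv(
        dup_path, sep="\t", index=False)
    return {"pt": pt_path, "duplicates": dup_path}


def default_meddra_rows() -> list[tuple[str, str, str]]:
    """(pt, pt_name, soc) rows for the default vocabulary."""
    return [(pt, pt, soc) for pt, soc, _ in DEFAULT_EVENT_VOCABULARY]


def cohort_case_data(tables: FaersTables, truth: SyntheticTruth,
                     target_names: Sequence[str] = TARGET_DRUG_NAMES):
    """Assemble the joined analysis dataset directly from generated tables.

    Fast path for simulation studies: produces the same :class:`CaseData`
    as writing the archive, re-reading and joining it, but without file
    I/O and re-parsing.  Only valid for cohorts without injected
    duplicates (the tables are already one row per case).
    """
    from .faers_ingest import (
        CaseData, _sets_by_pid, age_group_of, age_to_years,
        occupation_class_of, parse_faers_date, weight_band_of,
    )

    demo = tables.demo
    if demo["caseid"].duplicated().any():
        raise ConfigError("cohort_case_data requires a duplicate-free cohort")
    pids = demo["primaryid"].astype(int)
    pid_set = set(pids.tolist())

    outcomes, _ = _sets_by_pid(tables.outc, "outc_cod", pid_set)
    indications, _ = _sets_by_pid(tables.indi, "indi_pt", pid_set)
    non_ps = tables.drug[tables.drug["role_cod"] != "PS"]
    conc_sets, _ = _sets_by_pid(non_ps, "drugname", pid_set)

    start_by_pid: dict[int, int] = {}
    target_ids = truth.target_ids
    for pid, raw in zip(tables.ther["primaryid"], tables.ther["start_dt"]):
        pid = int(pid)
        if pid not in target_ids:
            continue
        date, precision = parse_faers_date(raw)
        if precision == "full":
            as_int = int(date.strftime("%Y%m%d"))
            if pid not in start_by_pid or as_int < start_by_pid[pid]:
                start_by_pid[pid] = as_int

    cases = demo.copy().reset_index(drop=True)
    cases["age_years"] = [age_to_years(a, c) for a, c in zip(cases["age"], cases["age_cod"])]
    cases["age_group"] = [age_group_of(a) for a in cases["age_years"]]
    cases["weight_kg"] = [float(w) if str(w).strip() else float("nan") for w in cases["wt"]]
    cases["weight_band"] = [weight_band_of(w) for w in cases["weight_kg"]]
    cases["occp_class"] = [occupation_class_of(o) for o in cases["occp_cod"]]
    empty_fs = frozenset()
    reactions = [truth.case_reactions[p] for p in pids]
    cases["outcomes"] = [outcomes.get(p, empty_fs) for p in pids]
    cases["reactions"] = reactions
    cases["indications"] = [indications.get(p, empty_fs) for p in pids]
    cases["concomitants"] = [tuple(sorted(conc_sets.get(p, empty_fs))) for p in pids]
    cases["start_dt"] = pd.array([start_by_pid.get(p) for p in pids], dtype="Int64")
    cases["is_target"] = [p in target_ids for p in pids]
    cases["analyzable"] = [len(r) > 0 for r in reactions]
    cases = cases.drop(columns=["age", "age_cod", "wt", "wt_cod"])
    flow = {
        "cases": len(cases),
        "target_cases": int(cases["is_target"].sum()),
        "cases_without_reactions": int((~cases["analyzable"]).sum()),
    }
    return CaseData(cases=cases, flow_counts=flow)
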