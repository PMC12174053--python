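"""Four-method disproportionality analysis over 2×2 contingency tables.

For a target drug and an event term, the fourfold table counts case–term
pairs (one deduplicated case contributes at most once per distinct PT, and
at SOC level once per distinct SOC)::

                    target event     other events
    target drug          a                b
    other drugs          c                d

The four standard pharmacovigilance statistics are computed per term:

* ROR  = ad/bc with 95% CI exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d));
* PRR  = [a/(a+b)] / [c/(c+d)] with a Yates-corrected Pearson χ²;
* BCPNN information component IC = log2((a+½)/(E+½)) with E = (a+b)(a+c)/N
  and the closed-form lower credible bound
  IC025 = IC − 3.3(a+½)^(−1/2) − 2.0(a+½)^(−3/2); the original
  moment-expansion formulation is available behind ``variant="bate"``;
* MGPS: an empirical-Bayes gamma–Poisson mixture (two gamma components on
  the relative reporting rate λ, fitted by maximizing the marginal
  negative-binomial mixture likelihood), yielding the shrunk geometric
  mean EBGM = exp(E[ln λ | a]) and its 5th posterior percentile EBGM05.

A term is a positive signal only when all four methods agree (each at its
conventional threshold); the conjunction is therefore never more
permissive than its strictest member.

Zero cells are handled by the Haldane–Anscombe correction: when any of
a, b, c, d is 0, 0.5 is added to all four cells for ROR, PRR and χ².
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .faers_ingest import CaseData, MeddraMap


class DisproportionalityError(ValueError):
    pass


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ContingencyTable:
    a: int
    b: int
    c: int
    d: int
    level: str = "PT"
    term: str = ""

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise DisproportionalityError("contingency cells must be non-negative")
        if self.n == 0:
            raise DisproportionalityError("contingency table is empty (N=0)")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected(self) -> float:
        """Expected count of cell a under row/column independence."""
        return (self.a + self.b) * (self.a + self.c) / self.n


@dataclass(frozen=True)
class PriorParameters:
    """Five-parameter gamma-mixture prior on the relative reporting rate:
    λ ~ P·Gamma(α₁, β₁) + (1−P)·Gamma(α₂, β₂) (shape/rate)."""

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    mix_p: float
    converged: bool = True
    loglik: float = float("nan")

    def __post_init__(self):
        if min(self.alpha1, self.beta1, self.alpha2, self.beta2) <= 0:
            raise DisproportionalityError("prior shape/rate parameters must be positive")
        if not 0.0 < self.mix_p < 1.0:
            raise DisproportionalityError("mixture weight must lie in (0, 1)")

    @property
    def mean(self) -> float:
        return self.mix_p * self.alpha1 / self.beta1 + (1 - self.mix_p) * self.alpha2 / self.beta2

    @property
    def variance(self) -> float:
        m1 = self.alpha1 / self.beta1
        m2 = self.alpha2 / self.beta2
        second = (
            self.mix_p * (self.alpha1 * (self.alpha1 + 1) / self.beta1**2)
            + (1 - self.mix_p) * (self.alpha2 * (self.alpha2 + 1) / self.beta2**2)
        )
        return second - self.mean**2


#: DuMouchel's canonical starting point for the mixture prior fit.
CANONICAL_PRIOR = PriorParameters(0.2, 0.1, 2.0, 4.0, 1.0 / 3.0)

#: Documented multi-start grid for the prior optimization.
DEFAULT_PRIOR_STARTS: tuple[tuple[float, float, float, float, float], ...] = (
    (0.2, 0.1, 2.0, 4.0, 1.0 / 3.0),   # DuMouchel's canonical start
    (1.0, 1.0, 1.0, 1.0, 0.5),
    (0.5, 0.5, 2.0, 2.0, 0.2),
    (2.0, 4.0, 0.2, 0.1, 2.0 / 3.0),
    (1.0, 2.0, 4.0, 2.0, 0.5),
)


@dataclass(frozen=True)
class SignalThresholds:
    """The positive-signal conjunction: every method must pass."""

    n_min: int = 3
    ror_low95_min: float = 1.0
    prr_min: float = 2.0
    chi2_min: float = 4.0
    ic025_min: float = 0.0
    ebgm05_min: float = 2.0
    alpha: float = 0.05


@dataclass
class SignalMetrics:
    term: str
    level: str
    a: int
    ror: float
    ror_low95: float
    ror_high95: float
    prr: float
    chi2: float
    chi2_p: float
    ic: float
    ic025: float
    ebgm: float
    ebgm05: float
    positive: bool = False
    method_flags: dict = field(default_factory=dict)
    reason: str = ""

    @property
    def n_reports(self) -> int:
        return self.a


# --------------------------------------------------------------------------
# contingency construction
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BackgroundCounts:
    """Pre-tabulated background (all other drugs) case–term pair counts,
    for analyzing a target-only extract without its own comparator set."""

    term_counts: Mapping[str, int]
    total_pairs: int


def case_term_pairs(cases: pd.DataFrame, level: str, meddra_map: MeddraMap | None) -> pd.DataFrame:
    """Distinct (primaryid, term) pairs at PT or SOC level."""
    if level not in ("PT", "SOC"):
        raise DisproportionalityError(f"level must be 'PT' or 'SOC', got {level!r}")
    if level == "SOC" and meddra_map is None:
        raise DisproportionalityError("SOC-level analysis requires a MedDRA map")
    rows = []
    for pid, reactions in zip(cases["primaryid"], cases["reactions"]):
        if not reactions:
            continue
        terms = reactions if level == "PT" else {meddra_map.soc_of(pt) for pt in reactions}
        for term in terms:
            rows.append((int(pid), term))
    return pd.DataFrame(rows, columns=["primaryid", "term"])


def contingency_frame(
    dataset: CaseData,
    level: str = "PT",
    meddra_map: MeddraMap | None = None,
    background: BackgroundCounts | None = None,
) -> pd.DataFrame:
    """All 2×2 tables for a dataset: one row per term with columns
    term, a, b, c, d.

    The comparator is every non-target case in the dataset; when the
    dataset holds only target cases an explicit :class:`BackgroundCounts`
    must be supplied (the target set is never silently its own background).
    """
    target = dataset.target
    target_pairs = case_term_pairs(target[target["analyzable"]], level, meddra_map)
    a_counts = target_pairs.groupby("term").size() if not target_pairs.empty else pd.Series(dtype=int)
    total_target = int(len(target_pairs))

    if background is None:
        bg_cases = dataset.background
        if bg_cases.empty:
            raise DisproportionalityError(
                "dataset has no non-target cases; supply BackgroundCounts explicitly"
            )
        bg_pairs = case_term_pairs(bg_cases[bg_cases["analyzable"]], level, meddra_map)
        c_counts = bg_pairs.groupby("term").size() if not bg_pairs.empty else pd.Series(dtype=int)
        total_bg = int(len(bg_pairs))
    else:
        c_counts = pd.Series(dict(background.term_counts), dtype=int)
        total_bg = int(background.total_pairs)

    terms = sorted(set(a_counts.index) | set(c_counts.index))
    a = np.array([int(a_counts.get(t, 0)) for t in terms])
    c = np.array([int(c_counts.get(t, 0)) for t in terms])
    return pd.DataFrame({
        "term": terms, "a": a, "b": total_target - a, "c": c, "d": total_bg - c,
    })


def build_contingency(
    dataset: CaseData,
    term: str,
    level: str = "PT",
    meddra_map: MeddraMap | None = None,
    background: BackgroundCounts | None = None,
) -> ContingencyTable:
    """The 2×2 table for one term (a=c=0 is valid; downstream guards apply)."""
    frame = contingency_frame(dataset, level, meddra_map, background)
    row = frame[frame["term"] == term]
    if row.empty:
        totals = frame.iloc[0] if len(frame) else None
        b = int(totals["a"] + totals["b"]) if totals is not None else 0
        d = int(totals["c"] + totals["d"]) if totals is not None else 0
        return ContingencyTable(0, b, 0, d, level=level, term=term)
    r = row.iloc[0]
    return ContingencyTable(int(r["a"]), int(r["b"]), int(r["c"]), int(r["d"]), level=level, term=term)


# --------------------------------------------------------------------------
# frequentist estimators (vectorized cores + single-table wrappers)
# --------------------------------------------------------------------------

def haldane_adjust(a, b, c, d):
    """Add 0.5 to all four cells wherever any cell is zero."""
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    zero = (a == 0) | (b == 0) | (c == 0) | (d == 0)
    h = np.where(zero, 0.5, 0.0)
    return a + h, b + h, c + h, d + h


def ror_components(a, b, c, d, z: float = 1.959963984540054):
    """Vectorized ROR with Wald 95% CI on the log scale (Haldane-adjusted)."""
    a, b, c, d = haldane_adjust(a, b, c, d)
    ror = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_ror = np.log(ror)
    return ror, np.exp(log_ror - z * se), np.exp(log_ror + z * se)


def prr_components(a, b, c, d):
    """Vectorized PRR (Haldane-adjusted when any cell is zero)."""
    a, b, c, d = haldane_adjust(a, b, c, d)
    return (a / (a + b)) / (c / (c + d))


def chi_square_components(a, b, c, d, yates: bool = True):
    """Vectorized Pearson χ² (1 df), Yates-corrected by default.

    Degenerate tables (any zero margin) report statistic 0 and p 1.
    """
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    denom = r1 * r2 * c1 * c2
    degenerate = denom == 0
    safe_denom = np.where(degenerate, 1.0, denom)
    diff = np.abs(a * d - b * c)
    if yates:
        diff = np.maximum(diff - n / 2.0, 0.0)
    stat = np.where(degenerate, 0.0, n * diff**2 / safe_denom)
    p = np.where(degenerate, 1.0, stats.chi2.sf(stat, df=1))
    return stat, p


def bcpnn_components(a, b, c, d):
    """Closed-form shrinkage information component and lower credible bound.

    IC = log2((a+½)/(E+½)) with E=(a+b)(a+c)/N;
    IC025 = IC − 3.3(a+½)^(−1/2) − 2.0(a+½)^(−3/2).
    """
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    n = a + b + c + d
    e = (a + b) * (a + c) / n
    ic = np.log2((a + 0.5) / (e + 0.5))
    ic025 = ic - 3.3 * (a + 0.5) ** -0.5 - 2.0 * (a + 0.5) ** -1.5
    return ic, ic025


def bate_ic_components(a, b, c, d, z: float = 1.959963984540054):
    """Original moment-expansion BCPNN information component.

    Uses the Beta/Dirichlet hyperparameters of the original formulation
    (γ11=1, α1=β1=1, α=β=2) with a normal approximation for the credible
    bound.  Provided for comparison with the closed-form default.
    """
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    n = a + b + c + d
    n_drug, n_event = a + b, a + c
    alpha1 = beta1 = gamma11 = 1.0
    alpha = beta = 2.0
    gamma = gamma11 * (n + alpha) * (n + beta) / ((n_drug + alpha1) * (n_event + beta1))
    ic = np.log2(
        (a + gamma11) * (n + alpha) * (n + beta)
        / ((n + gamma) * (n_drug + alpha1) * (n_event + beta1))
    )
    var = (
        (n - a + gamma - gamma11) / ((a + gamma11) * (1 + n + gamma))
        + (n - n_drug + alpha - alpha1) / ((n_drug + alpha1) * (1 + n + alpha))
        + (n - n_event + beta - beta1) / ((n_event + beta1) * (1 + n + beta))
    ) / np.log(2) ** 2
    return ic, ic - z * np.sqrt(var)


def ror_estimate(table: ContingencyTable) -> tuple[float, float, float]:
    """(ROR, lower 95%, upper 95%) for one table."""
    ror, lo, hi = ror_components(table.a, table.b, table.c, table.d)
    return float(ror), float(lo), float(hi)


def prr_estimate(table: ContingencyTable) -> tuple[float, float]:
    """(PRR, Yates χ²) for one table."""
    prr = prr_components(table.a, table.b, table.c, table.d)
    stat, _ = chi_square_components(table.a, table.b, table.c, table.d)
    return float(prr), float(stat)


def chi_square(table: ContingencyTable, yates: bool = True) -> tuple[float, float]:
    """(statistic, p-value) of the Pearson χ² test for one table."""
    stat, p = chi_square_components(table.a, table.b, table.c, table.d, yates=yates)
    return float(stat), float(p)


def bcpnn_ic(table: ContingencyTable, variant: str = "noren") -> tuple[float, float]:
    """(IC, IC025) for one table; ``variant`` selects the closed-form
    shrinkage IC (default) or the original moment expansion ("bate")."""
    if variant == "noren":
        ic, ic025 = bcpnn_components(table.a, table.b, table.c, table.d)
    elif variant == "bate":
        ic, ic025 = bate_ic_components(table.a, table.b, table.c, table.d)
    else:
        raise DisproportionalityError(f"unknown BCPNN variant {variant!r}")
    return float(ic), float(ic025)


# --------------------------------------------------------------------------
# MGPS: empirical-Bayes gamma-Poisson mixture
# --------------------------------------------------------------------------

def _mixture_loglik(params: np.ndarray, a: np.ndarray, e: np.ndarray) -> float:
    """Summed marginal log-likelihood of counts under the mixture prior.

    With λ ~ Gamma(α, β) and a|λ ~ Poisson(λE), a is negative binomial
    with size α and success probability β/(β+E).
    """
    a1, b1, a2, b2, p = params
    lp1 = stats.nbinom.logpmf(a, a1, b1 / (b1 + e))
    lp2 = stats.nbinom.logpmf(a, a2, b2 / (b2 + e))
    return float(np.logaddexp(np.log(p) + lp1, np.log1p(-p) + lp2).sum())


def mgps_fit_prior(
    a: Sequence[int] | np.ndarray,
    e: Sequence[float] | np.ndarray,
    starts: Iterable[tuple[float, float, float, float, float]] = DEFAULT_PRIOR_STARTS,
) -> PriorParameters:
    """Fit the five-parameter mixture prior by maximum marginal likelihood.

    Numerical maximization (L-BFGS-B on log/logit-transformed parameters,
    box [1e-6, 1e6] for shapes/rates) from each documented start; the best
    converged fit wins.  Deterministic for fixed starts.  Requires at
    least 10 (a, E) pairs with E > 0.
    """
    a = np.asarray(a, dtype=float)
    e = np.asarray(e, dtype=float)
    keep = e > 0
    a, e = a[keep], e[keep]
    if len(a) < 10:
        raise DisproportionalityError("MGPS prior fit requires ≥ 10 (a, E) pairs with E > 0")

    lo, hi = np.log(1e-6), np.log(1e6)

    def neg(theta: np.ndarray) -> float:
        a1, b1, a2, b2 = np.exp(theta[:4])
        p = special.expit(theta[4])
        p = min(max(p, 1e-12), 1 - 1e-12)
        return -_mixture_loglik(np.array([a1, b1, a2, b2, p]), a, e)

    best = None
    any_converged = False
    for start in starts:
        theta0 = np.concatenate([np.log(start[:4]), [special.logit(start[4])]])
        res = optimize.minimize(
            neg, theta0, method="L-BFGS-B",
            bounds=[(lo, hi)] * 4 + [(special.logit(1e-6), special.logit(1 - 1e-6))],
        )
        if best is None or res.fun < best.fun:
            best = res
        any_converged = any_converged or bool(res.success)
    if best is None:
        raise DisproportionalityError("MGPS prior optimization produced no result")
    a1, b1, a2, b2 = np.exp(best.x[:4])
    p = float(np.clip(special.expit(best.x[4]), 1e-9, 1 - 1e-9))
    prior = PriorParameters(
        alpha1=float(a1), beta1=float(b1), alpha2=float(a2), beta2=float(b2),
        mix_p=p, converged=any_converged, loglik=float(-best.fun),
    )
    if not any_converged:
        raise DisproportionalityError(
            f"MGPS prior optimization failed on all starts; best partial fit: {prior}"
        )
    return prior


def _posterior_weights(a, e, prior: PriorParameters):
    lp1 = stats.nbinom.logpmf(a, prior.alpha1, prior.beta1 / (prior.beta1 + e))
    lp2 = stats.nbinom.logpmf(a, prior.alpha2, prior.beta2 / (prior.beta2 + e))
    l1 = np.log(prior.mix_p) + lp1
    l2 = np.log1p(-prior.mix_p) + lp2
    return np.exp(l1 - np.logaddexp(l1, l2))


def ebgm_scores(a, e, prior: PriorParameters) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized (EBGM, EBGM05) under the fitted mixture prior.

    The posterior of λ given a is a two-component gamma mixture
    Q·Gamma(α₁+a, β₁+E) + (1−Q)·Gamma(α₂+a, β₂+E); EBGM is its geometric
    mean exp(E[ln λ]) via the digamma function and EBGM05 the 5th
    percentile by root-finding on the mixture CDF.
    """
    a = np.atleast_1d(np.asarray(a, dtype=float))
    e = np.atleast_1d(np.asarray(e, dtype=float))
    if np.any(e <= 0):
        raise DisproportionalityError("EBGM requires E > 0")
    q = _posterior_weights(a, e, prior)
    s1, r1 = prior.alpha1 + a, prior.beta1 + e
    s2, r2 = prior.alpha2 + a, prior.beta2 + e
    ebgm = np.exp(q * (special.digamma(s1) - np.log(r1)) + (1 - q) * (special.digamma(s2) - np.log(r2)))

    ebgm05 = np.empty_like(ebgm)
    for i in range(len(ebgm)):
        cdf = lambda x: (
            q[i] * stats.gamma.cdf(x, s1[i], scale=1.0 / r1[i])
            + (1 - q[i]) * stats.gamma.cdf(x, s2[i], scale=1.0 / r2[i])
            - 0.05
        )
        hi = max(
            stats.gamma.ppf(0.999, s1[i], scale=1.0 / r1[i]),
            stats.gamma.ppf(0.999, s2[i], scale=1.0 / r2[i]),
        )
        ebgm05[i] = optimize.brentq(cdf, 0.0, hi, xtol=1e-12, rtol=1e-12)
    return ebgm, ebgm05


def ebgm_score(table: ContingencyTable, prior: PriorParameters) -> tuple[float, float]:
    """(EBGM, EBGM05) for one table under *prior*."""
    ebgm, ebgm05 = ebgm_scores([table.a], [table.expected], prior)
    return float(ebgm[0]), float(ebgm05[0])


# --------------------------------------------------------------------------
# classification and the full signal table
# --------------------------------------------------------------------------

def classify_signal(
    metrics: SignalMetrics, thresholds: SignalThresholds = SignalThresholds()
) -> SignalMetrics:
    """Apply the four-criteria conjunction, filling in per-method flags,
    the overall verdict and a reason string for negatives."""
    t = thresholds
    reasons = []
    if metrics.a < t.n_min:
        reasons.append(f"n<{t.n_min}")
    values = [metrics.ror_low95, metrics.prr, metrics.chi2, metrics.ic025,
              metrics.ebgm05]
    if any(not np.isfinite(v) for v in values):
        flags = {"ROR": False, "PRR": False, "BCPNN": False, "MGPS": False}
        metrics.method_flags = flags
        metrics.positive = False
        metrics.reason = ";".join(reasons + ["undefined metrics"])
        return metrics
    flags = {
        "ROR": metrics.a >= t.n_min and metrics.ror_low95 > t.ror_low95_min,
        "PRR": metrics.a >= t.n_min and metrics.prr >= t.prr_min and metrics.chi2 >= t.chi2_min,
        "BCPNN": metrics.ic025 > t.ic025_min,
        "MGPS": metrics.ebgm05 > t.ebgm05_min,
    }
    reasons.extend(name for name, ok in flags.items() if not ok and name not in reasons)
    metrics.method_flags = flags
    metrics.positive = all(flags.values())
    metrics.reason = "" if metrics.positive else ";".join(reasons)
    return metrics


def compute_signal_table(
    dataset: CaseData,
    meddra_map: MeddraMap | None = None,
    level: str = "PT",
    thresholds: SignalThresholds = SignalThresholds(),
    background: BackgroundCounts | None = None,
    prior: PriorParameters | None = None,
    bcpnn_variant: str = "noren",
) -> pd.DataFrame:
    """The full per-term signal table for a dataset at PT or SOC level.

    Columns: term, level, soc, a, ror, ror_low95, ror_high95, prr, chi2,
    chi2_p, ic, ic025, ebgm, ebgm05, positive, reason.  The MGPS prior is
    fitted on all terms of the table unless one is supplied.
    """
    frame = contingency_frame(dataset, level, meddra_map, background)
    if frame.empty:
        return pd.DataFrame(columns=[
            "term", "level", "soc", "a", "ror", "ror_low95", "ror_high95",
            "prr", "chi2", "chi2_p", "ic", "ic025", "ebgm", "ebgm05",
            "positive", "reason",
        ])
    a = frame["a"].to_numpy()
    b = frame["b"].to_numpy()
    c = frame["c"].to_numpy()
    d = frame["d"].to_numpy()
    n = a + b + c + d
    e = (a + b) * (a + c) / n

    ror, lo, hi = ror_components(a, b, c, d)
    prr = prr_components(a, b, c, d)
    chi2_stat, chi2_p = chi_square_components(a, b, c, d)
    if bcpnn_variant == "noren":
        ic, ic025 = bcpnn_components(a, b, c, d)
    elif bcpnn_variant == "bate":
        ic, ic025 = bate_ic_components(a, b, c, d)
    else:
        raise DisproportionalityError(f"unknown BCPNN variant {bcpnn_variant!r}")
    if prior is None:
        prior = mgps_fit_prior(a, e)
    ebgm, ebgm05 = ebgm_scores(a, e, prior)

    out = frame.copy()
    out["level"] = level
    if level == "PT" and meddra_map is not None:
        out["soc"] = [meddra_map.soc_of(t) for t in out["term"]]
    else:
        out["soc"] = out["term"] if level == "SOC" else ""
    out["ror"], out["ror_low95"], out["ror_high95"] = ror, lo, hi
    out["prr"] = prr
    out["chi2"], out["chi2_p"] = chi2_stat, chi2_p
    out["ic"], out["ic025"] = ic, ic025
    out["ebgm"], out["ebgm05"] = ebgm, ebgm05

    positives, reasons = [], []
    for row in out.itertuples(index=False):
        m = SignalMetrics(
            term=row.term, level=level, a=int(row.a),
            ror=row.ror, ror_low95=row.ror_low95, ror_high95=row.ror_high95,
            prr=row.prr, chi2=row.chi2, chi2_p=row.chi2_p,
            ic=row.ic, ic025=row.ic025, ebgm=row.ebgm, ebgm05=row.ebgm05,
        )
        m = classify_signal(m, thresholds)
        positives.append(m.positive)
        reasons.append(m.reason)
    out["positive"] = positives
    out["reason"] = reasons
    cols = ["term", "level", "soc", "a", "b", "c", "d", "ror", "ror_low95",
            "ror_high95", "prr", "chi2", "chi2_p", "ic", "ic025", "ebgm",
            "ebgm05", "positive", "reason"]
    return out[cols].sort_values(["a", "term"], ascending=[False, True], kind="stable").reset_index(drop=True)
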