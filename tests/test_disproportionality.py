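import math

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from faerspv.disproportionality import (
    BackgroundCounts, CANONICAL_PRIOR, ContingencyTable, DisproportionalityError,
    PriorParameters, SignalMetrics, SignalThresholds, bate_ic_components,
    bcpnn_ic, build_contingency, chi_square, classify_signal,
    compute_signal_table, contingency_frame, ebgm_score, ebgm_scores,
    mgps_fit_prior, prr_estimate, ror_estimate,
)
from faerspv.faers_ingest import CaseData
from faerspv.synthetic_faers import SyntheticConfig, cohort_case_data, generate_cohort


def make_case_data(rows):
    """rows: (primaryid, is_target, reactions iterable)."""
    frame = pd.DataFrame({
        "primaryid": [r[0] for r in rows],
        "is_target": [r[1] for r in rows],
        "reactions": [frozenset(r[2]) for r in rows],
    })
    frame["analyzable"] = [len(r) > 0 for r in frame["reactions"]]
    return CaseData(cases=frame)


# --------------------------------------------------------------------------
# independent single-table oracles (direct formula evaluation)
# --------------------------------------------------------------------------

def oracle_ror(a, b, c, d):
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.975)
    return ror, ror * math.exp(-z * se), ror * math.exp(z * se)


def oracle_prr(a, b, c, d):
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a / (a + b)) / (c / (c + d))


def oracle_ic(a, b, c, d):
    n = a + b + c + d
    e = (a + b) * (a + c) / n
    ic = math.log2((a + 0.5) / (e + 0.5))
    return ic, ic - 3.3 * (a + 0.5) ** -0.5 - 2.0 * (a + 0.5) ** -1.5


class TestROR:
    def test_symmetric_table_is_one(self):
        ror, lo, hi = ror_estimate(ContingencyTable(10, 10, 10, 10))
        assert ror == pytest.approx(1.0)
        assert lo < 1.0 < hi

    def test_worked_example(self):
        ror, lo, hi = ror_estimate(ContingencyTable(100, 900, 1000, 99000))
        assert ror == pytest.approx(11.0)
        assert lo == pytest.approx(8.864, abs=5e-3)
        assert hi == pytest.approx(13.648, abs=5e-3)

    def test_zero_cell_is_finite_after_correction(self):
        ror, lo, hi = ror_estimate(ContingencyTable(3, 0, 5, 10))
        assert np.isfinite(ror) and np.isfinite(hi)
        assert lo < ror < hi

    def test_invariant_under_double_swap(self):
        t = ContingencyTable(7, 13, 29, 41)
        swapped = ContingencyTable(41, 29, 13, 7)  # swap rows then columns
        assert ror_estimate(t)[0] == pytest.approx(ror_estimate(swapped)[0])


class TestPRRChi2:
    @pytest.mark.parametrize("cells,expected", [
        ((10, 10, 10, 10), 1.0),
        ((10, 90, 90, 9810), 11.0),
        ((100, 900, 1000, 99000), 10.0),
    ])
    def test_prr_worked_examples(self, cells, expected):
        prr, _ = prr_estimate(ContingencyTable(*cells))
        assert prr == pytest.approx(expected)

    def test_chi2_symmetric_table(self):
        stat, p = chi_square(ContingencyTable(10, 10, 10, 10))
        assert stat == 0.0 and p == 1.0

    def test_chi2_uncorrected_worked_example(self):
        stat, _ = chi_square(ContingencyTable(100, 900, 1000, 99000), yates=False)
        assert stat == pytest.approx(744.48, abs=0.05)

    def test_chi2_matches_scipy_with_yates(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            a, b, c, d = rng.integers(1, 500, 4)
            stat, p = chi_square(ContingencyTable(int(a), int(b), int(c), int(d)))
            ref = stats.chi2_contingency([[a, b], [c, d]], correction=True)
            assert stat == pytest.approx(ref.statistic, rel=1e-10)
            assert p == pytest.approx(ref.pvalue, rel=1e-8, abs=1e-12)

    def test_chi2_monotone_in_a(self):
        stats_seq = [chi_square(ContingencyTable(a, 100, 50, 10000))[0] for a in (5, 20, 80)]
        assert stats_seq == sorted(stats_seq)

    def test_degenerate_margin_flagged(self):
        stat, p = chi_square(ContingencyTable(0, 0, 5, 5))
        assert stat == 0.0 and p == 1.0


class TestBCPNN:
    def test_null_table_ic_zero(self):
        ic, ic025 = bcpnn_ic(ContingencyTable(10, 10, 10, 10))
        assert ic == pytest.approx(0.0)
        assert ic025 < ic

    def test_worked_example(self):
        ic, ic025 = bcpnn_ic(ContingencyTable(100, 900, 1000, 99000))
        assert ic == pytest.approx(3.1412, abs=2e-3)
        assert ic025 == pytest.approx(2.810, abs=2e-3)

    def test_zero_a_shrinks_below_null(self):
        ic, _ = bcpnn_ic(ContingencyTable(0, 100, 50, 10000))
        assert ic < 0

    def test_bate_variant_null_near_zero(self):
        ic, ic025 = bate_ic_components(1000, 1000, 1000, 1000)
        assert abs(float(ic)) < 0.01
        assert float(ic025) < float(ic)


class TestEstimatorOracles:
    def test_brute_force_agreement_on_random_tables(self):
        rng = np.random.default_rng(123)
        from faerspv.disproportionality import (
            bcpnn_components, chi_square_components, prr_components, ror_components,
        )
        for _ in range(2000):
            a, b, c, d = (int(x) for x in rng.integers(0, 1000, 4))
            if a + b == 0 or c + d == 0 or a + b + c + d == 0:
                continue
            ror, lo, hi = (float(x) for x in ror_components(a, b, c, d))
            oror, olo, ohi = oracle_ror(a, b, c, d)
            assert ror == pytest.approx(oror, rel=1e-10)
            assert lo == pytest.approx(olo, rel=1e-10)
            assert hi == pytest.approx(ohi, rel=1e-10)
            assert float(prr_components(a, b, c, d)) == pytest.approx(oracle_prr(a, b, c, d), rel=1e-10)
            ic, ic025 = (float(x) for x in bcpnn_components(a, b, c, d))
            oic, oic025 = oracle_ic(a, b, c, d)
            assert ic == pytest.approx(oic, rel=1e-10)
            assert ic025 == pytest.approx(oic025, rel=1e-10, abs=1e-10)


class TestMGPS:
    def test_fit_is_deterministic(self):
        rng = np.random.default_rng(5)
        e = np.exp(rng.normal(1, 1, 300))
        a = rng.poisson(e)
        f1 = mgps_fit_prior(a, e)
        f2 = mgps_fit_prior(a, e)
        assert (f1.alpha1, f1.beta1, f1.alpha2, f1.beta2, f1.mix_p) == \
               (f2.alpha1, f2.beta1, f2.alpha2, f2.beta2, f2.mix_p)
        assert f1.converged

    def test_requires_ten_pairs(self):
        with pytest.raises(DisproportionalityError, match="10"):
            mgps_fit_prior([1, 2, 3], [1.0, 1.0, 1.0])

    def test_null_simulation_prior_mean_near_one(self):
        rng = np.random.default_rng(11)
        e = np.exp(rng.normal(1, 1, 500))
        a = rng.poisson(1.0 * e)
        fit = mgps_fit_prior(a, e)
        assert 0.8 <= fit.mean <= 1.2

    def test_prior_parameter_validation(self):
        with pytest.raises(DisproportionalityError):
            PriorParameters(1, -1, 1, 1, 0.5)
        with pytest.raises(DisproportionalityError):
            PriorParameters(1, 1, 1, 1, 1.5)


class TestEBGM:
    def test_concentrated_prior_dominates(self):
        prior = PriorParameters(1e6, 1e6, 1e6, 1e6, 0.5)
        ebgm, _ = ebgm_score(ContingencyTable(5, 5, 5, 5), prior)
        assert ebgm == pytest.approx(1.0, abs=0.01)

    def test_single_component_gamma_closed_form(self):
        # prior Gamma(2,2), a=5, E=1 → posterior Gamma(7,3)
        prior = PriorParameters(2.0, 2.0, 2.0, 2.0, 0.5)
        a, e = 5, 1.0
        ebgm, ebgm05 = ebgm_scores([a], [e], prior)
        expected = math.exp(special.digamma(7) - math.log(3))
        assert float(ebgm[0]) == pytest.approx(expected, abs=1e-6)
        assert float(ebgm05[0]) == pytest.approx(stats.gamma.ppf(0.05, 7, scale=1 / 3), abs=1e-6)

    def test_large_sample_limit(self):
        ebgm, _ = ebgm_scores([1000], [100.0], CANONICAL_PRIOR)
        assert abs(float(ebgm[0]) - 10.0) / 10.0 < 0.05

    def test_shrinkage_ordering(self):
        prior = CANONICAL_PRIOR
        e = 2.0
        values = [float(ebgm_scores([a], [e], prior)[0][0]) for a in range(0, 12)]
        assert values == sorted(values)
        # relative shrinkage decreases as counts grow at fixed a/E ratio
        small = float(ebgm_scores([4], [2.0], prior)[0][0])
        large = float(ebgm_scores([400], [200.0], prior)[0][0])
        assert abs(large - 2.0) < abs(small - 2.0)

    def test_ebgm05_below_ebgm(self):
        ebgm, ebgm05 = ebgm_scores([5, 50], [2.0, 10.0], CANONICAL_PRIOR)
        assert (ebgm05 < ebgm).all()


class TestClassification:
    BASE = dict(term="X", level="PT", ror=5.0, ror_high95=9.0, prr=5.0,
                chi2=40.0, chi2_p=1e-9, ic=2.0, ebgm=4.0)

    def _metrics(self, **kw):
        values = dict(self.BASE, a=50, ror_low95=2.1, ic025=1.2, ebgm05=3.0)
        values.update(kw)
        return SignalMetrics(**values)

    def test_all_criteria_met(self):
        m = classify_signal(self._metrics())
        assert m.positive and all(m.method_flags.values())

    def test_count_gate(self):
        m = classify_signal(self._metrics(a=2))
        assert not m.positive and "n<3" in m.reason

    def test_single_method_failure_blocks(self):
        m = classify_signal(self._metrics(ebgm05=1.5))
        assert not m.positive and "MGPS" in m.reason

    def test_conjunction_not_more_permissive_than_members(self):
        m = classify_signal(self._metrics(ic025=-0.5))
        assert not m.positive
        assert m.method_flags["BCPNN"] is False


class TestContingency:
    def test_toy_enumeration(self, meddra_map):
        data = make_case_data([
            (1, True, {"Rash"}), (2, True, {"Rash"}),
            (3, False, {"Nausea"}), (4, False, {"Nausea"}),
        ])
        t = build_contingency(data, "Rash", "PT", meddra_map)
        assert (t.a, t.b, t.c, t.d) == (2, 0, 0, 2)

    def test_duplicate_pt_mention_counts_once(self, meddra_map):
        data = make_case_data([
            (1, True, {"Rash", "Nausea"}), (2, False, {"Nausea"}),
        ])
        t = build_contingency(data, "Rash", "PT", meddra_map)
        assert t.a == 1

    def test_soc_level_counts_once_per_soc(self, meddra_map):
        data = make_case_data([
            (1, True, {"Nausea", "Vomiting", "Rash"}),  # 2 SOCs for the case
            (2, False, {"Diarrhoea"}),
        ])
        frame = contingency_frame(data, "SOC", meddra_map)
        gi = frame[frame["term"] == "Gastrointestinal disorders"].iloc[0]
        assert gi["a"] == 1 and gi["a"] + gi["b"] == 2

    def test_pair_totals_match_truth(self, meddra_map):
        tables, truth = generate_cohort(SyntheticConfig(n_reports=3000, seed=13))
        data = cohort_case_data(tables, truth)
        frame = contingency_frame(data, "PT", meddra_map)
        for row in frame.itertuples(index=False):
            assert row.a + row.c == truth.pt_case_counts[row.term]
            assert row.a == truth.pt_case_counts_target[row.term]

    def test_refuses_self_background(self):
        data = make_case_data([(1, True, {"Rash"}), (2, True, {"Nausea"})])
        with pytest.raises(DisproportionalityError, match="[Bb]ackground"):
            contingency_frame(data, "PT", None)

    def test_explicit_background_counts(self):
        data = make_case_data([(1, True, {"Rash"}), (2, True, {"Nausea"})])
        bg = BackgroundCounts(term_counts={"Rash": 10, "Nausea": 500}, total_pairs=1000)
        frame = contingency_frame(data, "PT", None, background=bg)
        rash = frame[frame["term"] == "Rash"].iloc[0]
        assert (rash["a"], rash["b"], rash["c"], rash["d"]) == (1, 1, 10, 990)

    def test_absent_term_yields_zero_cells(self, meddra_map):
        data = make_case_data([(1, True, {"Rash"}), (2, False, {"Nausea"})])
        t = build_contingency(data, "Pyrexia", "PT", meddra_map)
        assert t.a == 0 and t.c == 0 and t.n > 0


class TestSignalTable:
    def test_planted_signal_is_positive(self, meddra_map):
        from faerspv.synthetic_faers import PlantedSignal
        tables, truth = generate_cohort(SyntheticConfig(
            n_reports=20_000, seed=17, planted_signals=(PlantedSignal("Pancytopenia", 10.0),)))
        data = cohort_case_data(tables, truth)
        table = compute_signal_table(data, meddra_map, level="PT")
        row = table[table["term"] == "Pancytopenia"].iloc[0]
        assert row["positive"]
        assert row["ror_low95"] <= 10.0 <= row["ror_high95"] or row["ror"] > 5
        negatives = table[table["term"] != "Pancytopenia"]
        assert negatives["positive"].sum() == 0

    def test_interval_orderings(self, meddra_map, small_cohort):
        tables, truth = small_cohort
        # use a duplicate-free regeneration of the same conditions
        tables, truth = generate_cohort(SyntheticConfig(n_reports=2000, seed=7))
        data = cohort_case_data(tables, truth)
        table = compute_signal_table(data, meddra_map, level="PT")
        assert (table["ror_low95"] <= table["ror"]).all()
        assert (table["ror"] <= table["ror_high95"]).all()
        assert (table["ic025"] <= table["ic"]).all()
        assert (table["ebgm05"] <= table["ebgm"]).all()
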