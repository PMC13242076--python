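"""Cohen's kappa: oracle equivalence, invariants, p-values, reports."""

import numpy as np
import pytest
from sklearn.metrics import cohen_kappa_score

from toxconcord import (
    Arm,
    ContingencyTable,
    DegenerateTableError,
    DOMAINS,
    MatchedObservation,
    Timepoint,
    WeightScheme,
    binary_concordance_summary,
    build_contingency_table,
    cohen_kappa,
    interpret_kappa,
    kappa_p_value,
)
from toxconcord.agreement import _kappa_value, round_half_up


def brute_force_kappa(counts, scheme):
    """Independent explicit double-loop implementation."""
    counts = np.asarray(counts, dtype=float)
    k = counts.shape[0]
    n = counts.sum()
    num = den = 0.0
    for i in range(k):
        for j in range(k):
            if scheme == WeightScheme.UNWEIGHTED:
                d = 0.0 if i == j else 1.0
            else:
                d = (i - j) ** 2 / (k - 1) ** 2
            o = counts[i, j] / n
            e = counts[i, :].sum() * counts[:, j].sum() / n**2
            num += d * o
            den += d * e
    return 1.0 - num / den


def random_tables(k, n_tables, seed, min_total=20):
    rng = np.random.default_rng(seed)
    tables = []
    while len(tables) < n_tables:
        t = rng.integers(0, 30, size=(k, k))
        if t.sum() >= min_total and brute_is_defined(t):
            tables.append(t)
    return tables


def brute_is_defined(t):
    t = np.asarray(t, float)
    n = t.sum()
    e = np.outer(t.sum(1), t.sum(0)) / n**2
    return (e * (1 - np.eye(t.shape[0]))).sum() > 0


def table_to_ratings(counts):
    a, b = [], []
    k = counts.shape[0]
    for i in range(k):
        for j in range(k):
            a += [i] * counts[i, j]
            b += [j] * counts[i, j]
    return np.array(a), np.array(b)


class TestKappaValues:
    def test_printed_binary_example(self):
        # neither=495, clinician_only=27, patient_only=95, both=49
        t = ContingencyTable(np.array([[495, 95], [27, 49]]))
        res = cohen_kappa(t, WeightScheme.UNWEIGHTED)
        assert round_half_up(res.kappa, 2) == 0.35
        assert res.n == 666

    def test_diagonal_table_is_one(self):
        t = ContingencyTable(np.diag([5, 3, 2, 7]))
        for scheme in WeightScheme:
            assert cohen_kappa(t, scheme).kappa == pytest.approx(1.0)

    def test_independence_table_is_zero(self):
        t = ContingencyTable(np.array([[50, 50], [50, 50]]))
        res = cohen_kappa(t, WeightScheme.UNWEIGHTED)
        assert res.kappa == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_quadratic_regression_value(self):
        counts = np.array(
            [[2, 1, 0, 0], [1, 2, 1, 0], [0, 1, 2, 1], [0, 0, 1, 2]]
        )
        expected = brute_force_kappa(counts, WeightScheme.QUADRATIC)
        t = ContingencyTable(counts)
        assert _kappa_value(t, WeightScheme.QUADRATIC) == pytest.approx(
            expected, abs=1e-14
        )
        # frozen from the double-sum oracle
        assert expected == pytest.approx(0.8064516129032259, abs=1e-12)

    def test_degenerate_margins_raise(self):
        t = ContingencyTable(np.array([[5, 0], [0, 0]]))
        with pytest.raises(DegenerateTableError):
            cohen_kappa(t, WeightScheme.UNWEIGHTED)


class TestOracleEquivalence:
    @pytest.mark.parametrize("scheme", list(WeightScheme))
    def test_brute_force_1000_random_4x4(self, scheme):
        for t in random_tables(4, 1000, seed=123):
            got = _kappa_value(ContingencyTable(t), scheme)
            assert got == pytest.approx(
                brute_force_kappa(t, scheme), abs=1e-12
            )

    @pytest.mark.parametrize("scheme,weights", [
        (WeightScheme.UNWEIGHTED, None),
        (WeightScheme.QUADRATIC, "quadratic"),
    ])
    def test_against_sklearn(self, scheme, weights):
        for t in random_tables(4, 50, seed=7):
            a, b = table_to_ratings(t)
            expected = cohen_kappa_score(a, b, labels=[0, 1, 2, 3], weights=weights)
            got = _kappa_value(ContingencyTable(t), scheme)
            assert got == pytest.approx(expected, abs=1e-10)


class TestKappaInvariants:
    def test_quadratic_equals_unweighted_on_2x2(self):
        for t in random_tables(2, 1000, seed=99):
            ct = ContingencyTable(t)
            assert _kappa_value(ct, WeightScheme.QUADRATIC) == pytest.approx(
                _kappa_value(ct, WeightScheme.UNWEIGHTED), abs=1e-12
            )

    def test_scale_invariance(self):
        for t in random_tables(4, 100, seed=3):
            ct = ContingencyTable(t)
            ct5 = ContingencyTable(t * 5)
            for scheme in WeightScheme:
                assert _kappa_value(ct, scheme) == pytest.approx(
                    _kappa_value(ct5, scheme), abs=1e-12
                )

    def test_transpose_invariance_and_upper_bound(self):
        for t in random_tables(4, 100, seed=4):
            for scheme in WeightScheme:
                k1 = _kappa_value(ContingencyTable(t), scheme)
                k2 = _kappa_value(ContingencyTable(t.T), scheme)
                assert k1 == pytest.approx(k2, abs=1e-12)
                assert k1 <= 1.0 + 1e-12

    def test_one_iff_all_diagonal(self):
        for t in random_tables(4, 100, seed=5):
            k = _kappa_value(ContingencyTable(t), WeightScheme.UNWEIGHTED)
            off_diag = t.sum() - np.trace(t)
            assert (k == pytest.approx(1.0)) == (off_diag == 0)


class TestKappaPValue:
    def test_large_n_printed_table_below_0_001(self):
        t = ContingencyTable(np.array([[495, 95], [27, 49]]))
        assert kappa_p_value(t, WeightScheme.UNWEIGHTED) < 0.001

    def test_matches_uncorrected_chi_square_on_2x2(self):
        from scipy import stats

        t = np.array([[40, 30], [35, 45]])
        p = kappa_p_value(ContingencyTable(t), WeightScheme.UNWEIGHTED)
        assert p == pytest.approx(
            stats.chi2_contingency(t, correction=False)[1], abs=1e-10
        )

    def test_asymptotic_close_to_permutation_at_n_200(self):
        """Permutation oracle: shuffle the patient ratings, recompute
        kappa, and compare the tail fraction with the asymptotic p."""
        counts = np.array(
            [[20, 18, 12, 8], [15, 14, 13, 10], [10, 12, 11, 9], [8, 9, 10, 11]]
        )
        scheme = WeightScheme.QUADRATIC
        obs = abs(_kappa_value(ContingencyTable(counts), scheme))
        a, b = table_to_ratings(counts)
        rng = np.random.default_rng(2024)
        hits = 0
        nperm = 10_000
        for _ in range(nperm):
            bp = rng.permutation(b)
            t = np.zeros((4, 4), dtype=int)
            np.add.at(t, (a, bp), 1)
            if abs(_kappa_value(ContingencyTable(t), scheme)) >= obs - 1e-12:
                hits += 1
        perm_p = hits / nperm
        asym_p = kappa_p_value(ContingencyTable(counts), scheme)
        mc_err = 3 * np.sqrt(perm_p * (1 - perm_p) / nperm)
        assert abs(asym_p - perm_p) < mc_err + 0.02


class TestInterpretation:
    @pytest.mark.parametrize(
        "kappa,label",
        [
            (0.35, "minimal"),
            (0.07, "no agreement"),
            (-0.4, "no agreement"),
            (0.204, "no agreement"),   # rounds to 0.20
            (0.205, "minimal"),        # half-up to 0.21
            (0.45, "weak"),
            (0.65, "moderate"),
            (0.85, "strong"),
            (0.90, "strong"),
            (0.95, "almost perfect"),
        ],
    )
    def test_bands_on_rounded_kappa(self, kappa, label):
        assert interpret_kappa(kappa) == label


class TestContingencyAndSummary:
    DOMAIN = DOMAINS["diarrhea"]

    def _pair(self, i, g, s):
        return MatchedObservation(f"P{i}", Arm.A, Timepoint.MID, self.DOMAIN, g, s)

    def test_binary_all_neither(self):
        pairs = [self._pair(i, 0, 1) for i in range(3)]
        t = build_contingency_table(pairs, "binary")
        assert t.counts.tolist() == [[3, 0], [0, 0]]

    def test_ordinal_identity_diagonal(self):
        pairs = [self._pair(i, g, g + 1) for i, g in enumerate(range(4))]
        t = build_contingency_table(pairs, "ordinal4")
        assert np.array_equal(t.counts, np.eye(4, dtype=int))

    def test_grade_4_lands_in_collapsed_row(self):
        t = build_contingency_table([self._pair(0, 4, 4)], "ordinal4")
        assert t.counts[3, 3] == 1

    def test_crosstab_equals_brute_force_tally(self):
        rng = np.random.default_rng(17)
        pairs = [
            self._pair(i, int(g), int(s))
            for i, (g, s) in enumerate(
                zip(rng.integers(0, 5, 200), rng.integers(1, 5, 200))
            )
        ]
        t = build_contingency_table(pairs, "ordinal4")
        tally = np.zeros((4, 4), dtype=int)
        for p in pairs:
            tally[min(p.ctcae_grade, 3), p.eortc_severity - 1] += 1
        assert np.array_equal(t.counts, tally)
        assert t.n == 200

    def test_empty_input_rejected(self):
        with pytest.raises(Exception):
            build_contingency_table([], "binary")

    def test_summary_row_percentages(self):
        # mucositis arm A mid: cells (95, 37, 265, 267), n = 664
        pairs = (
            [self._pair(f"n{i}", 0, 1) for i in range(95)]
            + [self._pair(f"c{i}", 1, 1) for i in range(37)]
            + [self._pair(f"p{i}", 0, 2) for i in range(265)]
            + [self._pair(f"b{i}", 1, 2) for i in range(267)]
        )
        row = binary_concordance_summary(pairs)
        assert row["n"] == 664
        assert row["patient_only_pct"] == 39.9
        assert row["kappa"] == 0.13

    def test_summary_single_cell_is_100_percent(self):
        pairs = [self._pair(i, 2, 3) for i in range(10)]
        row = binary_concordance_summary(pairs)
        assert row["both_pct"] == 100.0
        assert row["neither_pct"] == 0.0
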