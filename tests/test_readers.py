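"""Reading-day schedule constraints, score statistics and the statistical tests
against independently coded textbook-formula oracles."""

import numpy as np
import pandas as pd
import pytest

from pedpet.readers import (
    QUESTIONS,
    dagostino_pearson,
    level_comparison_report,
    make_schedule,
    pearson_r,
    per_reader_correlations,
    score_statistics,
    significance_stars,
    simulate_readers,
)


def _ids(n=29):
    return [f"P{i}" for i in range(1, n + 1)]


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def _oracle_pearson(x, y):
    """Brute-force covariance formula."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / np.sqrt((xm ** 2).sum() * (ym ** 2).sum()))


def _oracle_dagostino_k2(x):
    """Textbook z-transforms of sample skewness and kurtosis, squared and summed."""
    x = np.asarray(x, float)
    n = len(x)
    m = x.mean()
    m2 = ((x - m) ** 2).mean()
    m3 = ((x - m) ** 3).mean()
    m4 = ((x - m) ** 4).mean()
    g1 = m3 / m2 ** 1.5
    b2k = m4 / m2 ** 2  # plain (non-excess) sample kurtosis
    # skewness transform (D'Agostino 1970)
    y = g1 * np.sqrt((n + 1) * (n + 3) / (6.0 * (n - 2)))
    b2 = 3.0 * (n ** 2 + 27 * n - 70) * (n + 1) * (n + 3) / (
        (n - 2) * (n + 5) * (n + 7) * (n + 9))
    w2 = -1 + np.sqrt(2 * (b2 - 1))
    delta = 1 / np.sqrt(0.5 * np.log(w2))
    alpha = np.sqrt(2.0 / (w2 - 1))
    z1 = delta * np.log(y / alpha + np.sqrt((y / alpha) ** 2 + 1))
    # kurtosis transform (Anscombe & Glynn 1983)
    e = 3.0 * (n - 1) / (n + 1)
    var = 24.0 * n * (n - 2) * (n - 3) / ((n + 1) ** 2 * (n + 3) * (n + 5))
    xx = (b2k - e) / np.sqrt(var)
    beta = 6.0 * (n ** 2 - 5 * n + 2) / ((n + 7) * (n + 9)) * np.sqrt(
        6.0 * (n + 3) * (n + 5) / (n * (n - 2) * (n - 3)))
    a = 6.0 + 8.0 / beta * (2.0 / beta + np.sqrt(1 + 4.0 / beta ** 2))
    z2 = ((1 - 2.0 / (9 * a))
          - np.cbrt((1 - 2.0 / a) / (1 + xx * np.sqrt(2 / (a - 4))))
          ) / np.sqrt(2.0 / (9 * a))
    return float(z1 ** 2 + z2 ** 2)


class TestSchedule:
    def test_87_presentations(self):
        entries = make_schedule(_ids(), seed=0)
        assert len(entries) == 87

    def test_constraints_hold_exhaustively(self):
        entries = make_schedule(_ids(), seed=1)
        df = pd.DataFrame([e.__dict__ for e in entries])
        # each patient exactly once per day
        per_day = df.groupby(["day", "patient_id"]).size()
        assert (per_day == 1).all()
        # each patient sees each level exactly once across days
        for _, sub in df.groupby("patient_id"):
            assert sorted(sub["count_level"]) == [0.50, 0.75, 1.00]
        # positions within a day are a permutation of 0..28
        for _, sub in df.groupby("day"):
            assert sorted(sub["position"]) == list(range(29))

    def test_two_seeds_differ_but_both_valid(self):
        a = make_schedule(_ids(), seed=0)
        b = make_schedule(_ids(), seed=99)
        assert [e.patient_id for e in a] != [e.patient_id for e in b]
        for entries in (a, b):
            df = pd.DataFrame([e.__dict__ for e in entries])
            assert (df.groupby(["day", "patient_id"]).size() == 1).all()

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            make_schedule(["P1", "P1", "P2"], seed=0)


def _score_table(rng=None, means=None):
    """Synthetic complete score table for 3 readers x 29 patients x 3 levels."""
    rng = rng or np.random.default_rng(0)
    rows = []
    for reader in ("R1", "R2", "R3"):
        for pid in _ids():
            for lv in (0.5, 0.75, 1.0):
                for q in QUESTIONS:
                    mu = 3.0 if means is None else means[lv]
                    s = int(np.clip(round(rng.normal(mu, 0.8)), 1, 5))
                    rows.append({"reader_id": reader, "patient_id": pid,
                                 "count_level": lv, "question": q, "score": s})
    return pd.DataFrame(rows)


class TestScoreStatistics:
    def test_constant_scores(self):
        df = _score_table()
        df["score"] = 3
        out = score_statistics(df)
        assert (out["mean"] == 3.0).all()
        assert (out["sd"] == 0.0).all()
        assert out.attrs["missing"] == []

    def test_toy_four_scores(self):
        df = pd.DataFrame(
            {
                "reader_id": ["R1"] * 4,
                "patient_id": ["P1", "P2", "P3", "P4"],
                "count_level": [1.0] * 4,
                "question": ["quality"] * 4,
                "score": [2, 3, 4, 5],
            }
        )
        out = score_statistics(df)
        pooled = out[out["reader_id"] == "all"].iloc[0]
        assert pooled["mean"] == pytest.approx(3.5)
        assert pooled["sd"] == pytest.approx(1.29, abs=0.005)

    def test_recovers_known_level_means(self):
        means = {0.5: 2.6, 0.75: 3.2, 1.0: 3.4}
        df = _score_table(np.random.default_rng(5), means)
        out = score_statistics(df)
        pooled = out[out["reader_id"] == "all"]
        for lv, mu in means.items():
            got = pooled[pooled["count_level"] == lv]
            for _, row in got.iterrows():
                se = row["sd"] / np.sqrt(row["n"])
                assert abs(row["mean"] - mu) < 2.5 * se + 0.05  # rounding bias

    def test_missing_cells_listed_not_imputed(self):
        df = _score_table().iloc[:-1]
        out = score_statistics(df)
        assert len(out.attrs["missing"]) == 1


class TestDagostinoPearson:
    def test_matches_textbook_oracle_on_fixed_sample(self):
        rng = np.random.default_rng(42)
        x = np.round(rng.normal(10, 2, 20), 3)
        k2, _ = dagostino_pearson(x)
        assert k2 == pytest.approx(_oracle_dagostino_k2(x), abs=1e-10)

    def test_normal_sample_not_rejected(self):
        x = np.random.default_rng(3).normal(0, 1, 500)
        _, p = dagostino_pearson(x)
        assert p > 0.01

    def test_bimodal_sample_rejected(self):
        rng = np.random.default_rng(4)
        x = np.concatenate([rng.normal(-4, 0.3, 250), rng.normal(4, 0.3, 250)])
        _, p = dagostino_pearson(x)
        assert p < 0.01

    def test_small_or_constant_samples_rejected(self):
        with pytest.raises(ValueError, match="n >= 8"):
            dagostino_pearson([1, 2, 3])
        with pytest.raises(ValueError, match="constant"):
            dagostino_pearson([2.0] * 20)


class TestPearson:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        r, p = pearson_r(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p < 1e-6

    def test_constructed_orthogonality(self):
        r, _ = pearson_r([1, 2, 1, 2], [1, 1, 2, 2])
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_matches_covariance_oracle(self):
        x = [1.2, 5.1, 2.2, 8.8, 4.4, 6.1, 0.3, 7.7, 3.9, 5.5]
        y = [2.0, 4.9, 3.1, 7.6, 4.1, 6.6, 1.9, 6.2, 4.8, 5.0]
        r, _ = pearson_r(x, y)
        assert r == pytest.approx(_oracle_pearson(x, y), abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_r([1, 1, 1, 1], [1, 2, 3, 4])


def test_significance_stars_graphpad_bands():
    assert significance_stars(0.1234) == "ns"
    assert significance_stars(0.0332) == "*"
    assert significance_stars(0.0021) == "**"
    assert significance_stars(0.0002) == "***"
    assert significance_stars(0.00009) == "****"


class TestSimulatedReaders:
    def _fom_table(self):
        rows = []
        for pid in _ids(10):
            for lv, s, n in [(0.5, 3.0, 0.30), (0.75, 4.0, 0.22), (1.0, 5.0, 0.15)]:
                rows.append({"patient_id": pid, "count_level": lv,
                             "snr": s, "noise": n})
        return pd.DataFrame(rows)

    def test_no_noise_equal_bias_identical_scores(self):
        profiles = [{"reader_id": "R1", "bias": 0.0, "sigma": 0.0},
                    {"reader_id": "R2", "bias": 0.0, "sigma": 0.0}]
        scores = simulate_readers(self._fom_table(), profiles, seed=0)
        piv = scores.pivot_table(index=["patient_id", "count_level", "question"],
                                 columns="reader_id", values="score")
        assert (piv["R1"] == piv["R2"]).all()

    def test_mean_score_monotone_in_count_level(self):
        profiles = [{"reader_id": f"R{i}", "bias": 0.1 * i, "sigma": 0.3}
                    for i in range(3)]
        scores = simulate_readers(self._fom_table(), profiles, seed=1)
        for _, sub in scores.groupby("reader_id"):
            means = sub.groupby("count_level")["score"].mean()
            assert means.loc[1.0] >= means.loc[0.75] >= means.loc[0.5]

    def test_inter_reader_correlation_rises_as_noise_vanishes(self):
        table = self._fom_table()
        corrs = []
        for sigma in (1.5, 0.05):
            profiles = [{"reader_id": "R1", "bias": 0.0, "sigma": sigma},
                        {"reader_id": "R2", "bias": 0.0, "sigma": sigma}]
            scores = simulate_readers(table, profiles, seed=2)
            piv = scores.pivot_table(
                index=["patient_id", "count_level", "question"],
                columns="reader_id", values="score")
            corrs.append(_oracle_pearson(piv["R1"], piv["R2"]))
        assert corrs[1] > corrs[0]


class TestReports:
    def test_level_comparison_report_shape(self):
        df = _score_table(np.random.default_rng(8),
                          {0.5: 2.8, 0.75: 3.3, 1.0: 3.5})
        rep = level_comparison_report(df)
        assert set(rep["question"]) == set(QUESTIONS) | {"all"}
        for col in ("mean_50", "sd_50", "mean_75", "mean_100",
                    "r_50v100", "p_50v100", "sig_50v100",
                    "r_75v100", "p_75v100", "sig_75v100"):
            assert col in rep.columns

    def test_per_reader_correlations_shape(self):
        df = _score_table(np.random.default_rng(9),
                          {0.5: 2.8, 0.75: 3.3, 1.0: 3.5})
        rep = per_reader_correlations(df)
        assert len(rep) == 3 * len(QUESTIONS)
        assert {"r_50v100", "r_75v100"}.issubset(rep.columns)
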