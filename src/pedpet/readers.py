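"""Reader-study machinery: randomized presentation schedule, score summaries,
normality/correlation statistics and an optional simulated-reader model.

The clinical stage this mirrors: three reading days, each showing all
patients exactly once in random order, with count levels (50, 75, 100 % of
the original counts) arranged Latin-square style so every patient is seen
once at every level across the three days.  Readers answer four quality
questions (overall quality, noise, smoothness, lesion detectability) on a
5-point scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "QUESTIONS", "READING_LEVELS", "ScheduleEntry",
    "make_schedule", "score_statistics", "dagostino_pearson",
    "pearson_r", "significance_stars", "simulate_readers",
    "level_comparison_report", "per_reader_correlations",
]

QUESTIONS = ("quality", "noise", "smoothness", "detectability")
READING_LEVELS = (0.50, 0.75, 1.00)


@dataclass(frozen=True)
class ScheduleEntry:
    day: int  # 1..3
    position: int  # order index within the day, 0-based
    patient_id: str
    count_level: float


def make_schedule(
    patient_ids: list[str], seed: int = 0,
    levels: tuple[float, ...] = READING_LEVELS,
) -> list[ScheduleEntry]:
    """Randomized 3-day presentation plan.

    Constraints: each patient appears exactly once per day; across the days
    each patient sees each count level exactly once (a per-patient random
    permutation of the levels); presentation order is shuffled per day.
    With 29 patients and 3 levels this yields 87 presentations.
    """
    if len(set(patient_ids)) != len(patient_ids):
        raise ValueError("duplicate patient ids")
    n_days = len(levels)
    rng = np.random.default_rng(seed)
    level_perm = {pid: rng.permutation(levels) for pid in patient_ids}
    entries: list[ScheduleEntry] = []
    for day in range(1, n_days + 1):
        order = rng.permutation(len(patient_ids))
        for pos, idx in enumerate(order):
            pid = patient_ids[idx]
            entries.append(
                ScheduleEntry(day=day, position=pos, patient_id=pid,
                              count_level=float(level_perm[pid][day - 1]))
            )
    return entries


def schedule_dataframe(entries: list[ScheduleEntry]) -> pd.DataFrame:
    return pd.DataFrame([e.__dict__ for e in entries])


def score_statistics(scores: pd.DataFrame) -> pd.DataFrame:
    """Per-question, per-level mean and sample SD, per reader and pooled.

    ``scores`` columns: reader_id, patient_id, count_level, question, score.
    Missing (reader, patient, level, question) cells are listed in the
    attribute ``attrs['missing']`` of the result, never imputed.
    """
    required = {"reader_id", "patient_id", "count_level", "question", "score"}
    if not required.issubset(scores.columns):
        raise ValueError(f"score table must have columns {sorted(required)}")
    per_reader = (
        scores.groupby(["question", "count_level", "reader_id"])["score"]
        .agg(mean="mean", sd=lambda s: s.std(ddof=1), n="count")
        .reset_index()
    )
    pooled = (
        scores.groupby(["question", "count_level"])["score"]
        .agg(mean="mean", sd=lambda s: s.std(ddof=1), n="count")
        .reset_index()
    )
    pooled["reader_id"] = "all"
    out = pd.concat([per_reader, pooled], ignore_index=True)

    full = pd.MultiIndex.from_product(
        [scores["reader_id"].unique(), scores["patient_id"].unique(),
         scores["count_level"].unique(), scores["question"].unique()],
        names=["reader_id", "patient_id", "count_level", "question"],
    )
    have = pd.MultiIndex.from_frame(
        scores[["reader_id", "patient_id", "count_level", "question"]]
    )
    out.attrs["missing"] = list(full.difference(have))
    return out


def dagostino_pearson(sample) -> tuple[float, float]:
    """D'Agostino-Pearson omnibus normality test: (K^2 statistic, p value).

    K^2 combines the z-transformed sample skewness and kurtosis; p comes
    from a chi-square distribution with 2 degrees of freedom.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 8:
        raise ValueError("D'Agostino-Pearson requires n >= 8")
    if np.allclose(x, x[0]):
        raise ValueError("constant sample has no defined skewness/kurtosis")
    k2, p = stats.normaltest(x)
    return float(k2), float(p)


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with two-tailed t-distribution p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need two equal-length samples with n >= 3")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("correlation undefined for a constant sample")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def significance_stars(p: float) -> str:
    """GraphPad-style significance bands."""
    if p < 0.0001:
        return "****"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def simulate_readers(
    fom_table: pd.DataFrame,
    reader_profiles: list[dict],
    seed: int = 0,
    questions: tuple[str, ...] = QUESTIONS,
) -> pd.DataFrame:
    """Ordinal 1-5 scores from a latent-quality model.

    Latent quality per (patient, level) = log(SNR) - noise penalty + reader
    bias + Gaussian reader noise, discretised by fixed cutpoints.  Each
    reader profile is a dict with keys ``reader_id``, ``bias`` (latent
    shift) and ``sigma`` (reader noise SD).  ``fom_table`` needs columns
    patient_id, count_level, snr, noise.
    """
    rng = np.random.default_rng(seed)
    cutpoints = np.array([-1.0, -0.35, 0.35, 1.0])
    base = np.log(fom_table["snr"].to_numpy()) - 2.0 * fom_table["noise"].to_numpy()
    base = (base - base.mean()) / (base.std(ddof=0) or 1.0)
    rows = []
    for prof in reader_profiles:
        for q in questions:
            eps = rng.normal(0.0, prof.get("sigma", 0.3), size=len(fom_table))
            latent = base + prof.get("bias", 0.0) + eps
            score = 1 + np.searchsorted(cutpoints, latent)
            for (_, fr), s in zip(fom_table.iterrows(), score):
                rows.append(
                    {
                        "reader_id": prof["reader_id"],
                        "patient_id": fr["patient_id"],
                        "count_level": fr["count_level"],
                        "question": q,
                        "score": int(np.clip(s, 1, 5)),
                    }
                )
    return pd.DataFrame(rows)


def _matched_scores(scores: pd.DataFrame, question: str, level: float,
                    reference: float, reader: str | None = None):
    sub = scores[scores["question"] == question]
    if reader is not None:
        sub = sub[sub["reader_id"] == reader]
        piv = sub.pivot_table(index="patient_id", columns="count_level",
                              values="score", aggfunc="mean")
    else:
        piv = sub.pivot_table(index="patient_id", columns="count_level",
                              values="score", aggfunc="mean")
    piv = piv.dropna(subset=[level, reference])
    return piv[level].to_numpy(), piv[reference].to_numpy()


def level_comparison_report(
    scores: pd.DataFrame,
    reference_level: float = 1.0,
    comparison_levels: tuple[float, ...] = (0.50, 0.75),
) -> pd.DataFrame:
    """Mean (SD) per level plus patient-matched correlations vs the reference.

    One row per question (and a pooled 'all' row): score means and SDs at
    each level, then Pearson r, p and significance stars for every
    comparison level against the reference, using reader-averaged
    patient-matched scores.
    """
    questions = list(scores["question"].unique()) + ["all"]
    rows = []
    for q in questions:
        sub = scores if q == "all" else scores[scores["question"] == q]
        row: dict = {"question": q}
        for lv in sorted(set(comparison_levels) | {reference_level}):
            vals = sub[sub["count_level"] == lv]["score"]
            row[f"mean_{int(lv * 100)}"] = vals.mean()
            row[f"sd_{int(lv * 100)}"] = vals.std(ddof=1)
        for lv in comparison_levels:
            if q == "all":
                piv = scores.pivot_table(index=["patient_id", "question"],
                                         columns="count_level", values="score",
                                         aggfunc="mean").dropna()
                a, b = piv[lv].to_numpy(), piv[reference_level].to_numpy()
            else:
                a, b = _matched_scores(scores, q, lv, reference_level)
            r, p = pearson_r(a, b)
            row[f"r_{int(lv * 100)}v{int(reference_level * 100)}"] = r
            row[f"p_{int(lv * 100)}v{int(reference_level * 100)}"] = p
            row[f"sig_{int(lv * 100)}v{int(reference_level * 100)}"] = (
                significance_stars(p)
            )
        rows.append(row)
    return pd.DataFrame(rows)


def per_reader_correlations(
    scores: pd.DataFrame,
    reference_level: float = 1.0,
    comparison_levels: tuple[float, ...] = (0.50, 0.75),
) -> pd.DataFrame:
    """Between-level correlations computed per reader and question.

    Despite often being labelled 'inter-reader agreement', what this table
    holds is each reader's own consistency between reduced-count and
    full-count scores.
    """
    rows = []
    for reader in scores["reader_id"].unique():
        for q in scores["question"].unique():
            row = {"reader_id": reader, "question": q}
            for lv in comparison_levels:
                a, b = _matched_scores(scores, q, lv, reference_level, reader=reader)
                key = f"{int(lv * 100)}v{int(reference_level * 100)}"
                try:
                    r, p = pearson_r(a, b)
                    row[f"r_{key}"] = r
                    row[f"p_{key}"] = p
                    row[f"sig_{key}"] = significance_stars(p)
                except ValueError:
                    row[f"r_{key}"] = np.nan
                    row[f"p_{key}"] = np.nan
                    row[f"sig_{key}"] = "undefined"
            rows.append(row)
    return pd.DataFrame(rows)
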