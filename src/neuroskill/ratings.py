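"""Ground-truth skill labels and inter-rater agreement.

Three raters score each segmented subtask on five RACE domains (Likert 1–5):
domains 1–2 (needle positioning, needle entry) assess subtask 1; domains 3–5
(needle driving & tissue trauma, suture placement, tissue approximation)
assess subtask 2.  Per-rater domain means are cut into three ordinal skill
classes (1 inexperienced, 2 competent, 3 experienced) and disagreements
resolved by majority vote.  Agreement is quantified with Fleiss' kappa on the
categorical labels and the single-measure two-way random-effects
absolute-agreement ICC — ICC(2,1) — on the raw Likert scores.

The RACE-score class thresholds are not standardized; they are explicit
configuration with tertile cuts of the 1–5 scale as default and are carried
into every report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synth import SUBTASK_DOMAINS

#: Default RACE-score cuts: tertiles of the 1–5 scale.
DEFAULT_THRESHOLDS = (1 + 4 / 3, 1 + 8 / 3)   # (2.333…, 3.666…)


@dataclass
class AgreementResult:
    statistic: str               # "fleiss_kappa" or "icc"
    value: float
    ci_low: float
    ci_high: float
    n_items: int
    n_raters: int
    degenerate: bool = False     # chance agreement == 1 / zero total variance

    def to_dict(self) -> dict:
        return self.__dict__.copy()


@dataclass
class SkillLabel:
    segment_id: str
    participant_id: str
    subtask: int
    skill_class: int
    per_rater_classes: tuple[int, int, int]
    vote_margin: int             # votes for winner minus runner-up


def aggregate_race(table: pd.DataFrame, subtask: int) -> pd.DataFrame:
    """Mean of the subtask-relevant domain scores, per (segment, rater).

    Returns a frame with columns segment_id, participant_id, rater_id, score.
    Raises if a required domain is missing for any (segment, rater).
    """
    domains = SUBTASK_DOMAINS[subtask]
    sub = table[(table["subtask"] == subtask) & (table["domain"].isin(domains))]
    out = []
    for (seg, pid, rater), grp in sub.groupby(
            ["segment_id", "participant_id", "rater_id"], sort=True):
        present = set(grp["domain"])
        missing = [d for d in domains if d not in present]
        if missing:
            raise ValueError(
                f"segment {seg} rater {rater}: missing domain(s) {missing}")
        out.append((seg, pid, rater, float(grp["score"].mean())))
    return pd.DataFrame(out, columns=["segment_id", "participant_id",
                                      "rater_id", "score"])


def assign_skill_class(score: float,
                       thresholds: tuple[float, float] = DEFAULT_THRESHOLDS) -> int:
    """Cut an ordinal RACE score into class 1/2/3.

    Class 1 below ``t_low``, class 2 in [t_low, t_high), class 3 at or above
    ``t_high``.
    """
    t_low, t_high = thresholds
    if not (1 < t_low < t_high < 5):
        raise ValueError("thresholds must satisfy 1 < t_low < t_high < 5")
    if not (1 <= score <= 5):
        raise ValueError(f"score {score} outside the 1-5 Likert range")
    if score < t_low:
        return 1
    if score < t_high:
        return 2
    return 3


def majority_vote(per_rater_classes: tuple[int, int, int]) -> tuple[int, int]:
    """Modal class of exactly three rater labels; returns (class, margin).

    A three-way tie (all raters disagree) resolves to the ordinal median,
    preserving the ordered scale deterministically.
    """
    labels = tuple(per_rater_classes)
    if len(labels) != 3:
        raise ValueError("majority vote is defined over exactly 3 raters")
    vals, counts = np.unique(labels, return_counts=True)
    if counts.max() >= 2:
        winner = int(vals[np.argmax(counts)])
        margin = int(counts.max() - (sorted(counts)[-2] if len(counts) > 1 else 0))
        return winner, margin
    return int(np.median(labels)), 0


def derive_labels(table: pd.DataFrame, subtask: int,
                  thresholds: tuple[float, float] = DEFAULT_THRESHOLDS,
                  ) -> list[SkillLabel]:
    """RACE table -> per-segment majority-vote skill labels for one subtask."""
    agg = aggregate_race(table, subtask)
    labels = []
    for (seg, pid), grp in agg.groupby(["segment_id", "participant_id"], sort=True):
        grp = grp.sort_values("rater_id")
        per_rater = tuple(assign_skill_class(s, thresholds) for s in grp["score"])
        winner, margin = majority_vote(per_rater)
        labels.append(SkillLabel(seg, pid, subtask, winner, per_rater, margin))
    return labels


def labels_by_participant(table: pd.DataFrame, subtask: int,
                          thresholds: tuple[float, float] = DEFAULT_THRESHOLDS,
                          ) -> dict[str, int]:
    """Participant-level labels: majority vote over rater means pooled per
    participant (the coarser granularity; per-segment is the default)."""
    agg = aggregate_race(table, subtask)
    out: dict[str, int] = {}
    for pid, grp in agg.groupby("participant_id", sort=True):
        per_rater = tuple(
            assign_skill_class(float(s), thresholds)
            for _, s in grp.groupby("rater_id")["score"].mean().sort_index().items())
        out[pid], _ = majority_vote(per_rater)
    return out


def fleiss_kappa(counts: np.ndarray, n_boot: int = 2000,
                 seed: int = 0, ci: float = 0.95) -> AgreementResult:
    """Fleiss' kappa for an items x categories count table.

    kappa = (Pbar - Pbar_e) / (1 - Pbar_e) with Pbar the mean observed
    pairwise agreement per item and Pbar_e the agreement expected from the
    marginal category frequencies.  The CI is a seeded item-level percentile
    bootstrap.  When every rating falls in a single category the statistic is
    0/0; a degenerate flag is returned instead of a value.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2:
        raise ValueError("counts must be items x categories")
    n_raters = counts.sum(axis=1)
    if not np.all(n_raters == n_raters[0]) or n_raters[0] < 2:
        raise ValueError("every item must be rated by the same n >= 2 raters")
    n = int(n_raters[0])
    n_items = counts.shape[0]

    def _kappa(c: np.ndarray) -> float:
        p_cat = c.sum(axis=0) / c.sum()
        p_i = ((c * (c - 1)).sum(axis=1)) / (n * (n - 1))
        p_bar = p_i.mean()
        p_e = (p_cat**2).sum()
        if 1 - p_e < 1e-15:
            return np.nan
        return (p_bar - p_e) / (1 - p_e)

    value = _kappa(counts)
    if np.isnan(value):
        return AgreementResult("fleiss_kappa", np.nan, np.nan, np.nan,
                               n_items, n, degenerate=True)
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, n_items, size=n_items)
        k = _kappa(counts[idx])
        if not np.isnan(k):
            boots.append(k)
    alpha = (1 - ci) / 2
    lo, hi = (np.quantile(boots, [alpha, 1 - alpha]) if boots
              else (np.nan, np.nan))
    return AgreementResult("fleiss_kappa", float(value), float(lo), float(hi),
                           n_items, n)


def icc_absolute(scores: np.ndarray, average: bool = False,
                 ci: float = 0.95) -> AgreementResult:
    """Absolute-agreement ICC from a complete items x raters score matrix.

    Single-measure ICC(2,1) by default (``average=True`` gives ICC(2,k)),
    from the two-way random-effects ANOVA mean squares:

        ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    CI bounds follow the standard F-distribution construction for the
    absolute-agreement form.  Zero total variance returns a degenerate flag.
    """
    x = np.asarray(scores, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need an items x raters matrix with >= 2 of each")
    if np.isnan(x).any():
        raise ValueError("matrix must be complete")
    n, k = x.shape
    grand = x.mean()
    row_m = x.mean(axis=1)
    col_m = x.mean(axis=0)
    ss_total = ((x - grand) ** 2).sum()
    if ss_total < 1e-15:
        return AgreementResult("icc", np.nan, np.nan, np.nan, n, k,
                               degenerate=True)
    ss_rows = k * ((row_m - grand) ** 2).sum()
    ss_cols = n * ((col_m - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    if average:
        denom = msr + (msc - mse) / n
        value = (msr - mse) / denom if abs(denom) > 1e-15 else np.nan
    else:
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
        value = (msr - mse) / denom if abs(denom) > 1e-15 else np.nan

    # F-based CI for the single-measure form (McGraw & Wong construction)
    alpha = 1 - ci
    r = value if not np.isnan(value) else 0.0
    if average:
        # bound the single-measure ICC, then Spearman-Brown to average-measure
        single = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        lo, hi = _icc2_ci(single, msr, msc, mse, n, k, alpha)
        sb = lambda s: np.nan if np.isnan(s) else k * s / (1 + (k - 1) * s)
        lo, hi = sb(lo), sb(hi)
    else:
        lo, hi = _icc2_ci(r, msr, msc, mse, n, k, alpha)
    return AgreementResult("icc", float(value), float(lo), float(hi), n, k)


def _icc2_ci(r: float, msr: float, msc: float, mse: float,
             n: int, k: int, alpha: float) -> tuple[float, float]:
    if mse < 1e-15 and msc < 1e-15:
        return (r, r)  # perfectly consistent raters: interval collapses
    a = k * r / (n * (1 - r)) if r < 1 else np.inf
    b = 1 + k * r * (n - 1) / (n * (1 - r)) if r < 1 else np.inf
    with np.errstate(invalid="ignore", divide="ignore"):
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1)))
    if not np.isfinite(v):
        v = (n - 1) * (k - 1)
    f2u = stats.f.ppf(1 - alpha / 2, v, n - 1)
    f2l = stats.f.ppf(1 - alpha / 2, n - 1, v)
    lower = n * (msr - f2l * mse) / (
        f2l * (k * msc + (k * n - k - n) * mse) + n * msr)
    upper = n * (f2u * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f2u * msr)
    return float(lower), float(upper)


def labels_to_count_table(per_rater: list[tuple[int, ...]],
                          n_categories: int = 3) -> np.ndarray:
    """Per-item rater label tuples -> items x categories count table."""
    out = np.zeros((len(per_rater), n_categories), dtype=int)
    for i, labels in enumerate(per_rater):
        for lab in labels:
            out[i, lab - 1] += 1
    return out
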