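"""Subject-independent model selection, testing and comparison statistics.

Participants — never windows — are the unit of splitting: each repeat holds
out ``n_test`` participants entirely, grid search runs group-based K-fold
cross-validation over the training participants (GroupKFold semantics: no
participant's windows ever cross a fold boundary), the selected
configuration is retrained and evaluated once on the held-out participants,
and the whole procedure repeats with fresh random partitions.  Per-run
metrics feed two-tailed paired t-tests between modality configurations with
Holm-Bonferroni correction over the comparison family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sp_stats
from sklearn.model_selection import GroupKFold
from statsmodels.stats.multitest import multipletests

from .model import ModelConfig, SkillClassifier, compute_class_weights
from .windows import WindowBatch, fit_apply_normalizer

N_CLASSES = 3


# ---------------------------------------------------------------------------
# split plans
# ---------------------------------------------------------------------------

@dataclass
class Repeat:
    train_participants: list[str]
    test_participants: list[str]
    folds: list[tuple[list[str], list[str]]]   # (fold-train, fold-val) ids


@dataclass
class SplitPlan:
    repeats: list[Repeat]
    seed: int


def make_split_plan(participants: list[str], n_train: int = 16,
                    n_test: int = 7, k: int = 4, repeats: int = 10,
                    seed: int = 0,
                    classes: dict[str, int] | None = None) -> SplitPlan:
    """Seeded repeated train/test partitions with inner grouped folds.

    With ``classes`` given, the permutation is stratified: each skill class
    is spread round-robin over train/test and over the inner folds, so small
    cohorts keep every class represented on both sides of every split.  At
    the study's cohort size (23 participants, >= 5 per class) plain random
    partitions suffice and stratification is unnecessary.
    """
    participants = list(participants)
    if len(participants) < n_train + n_test:
        raise ValueError(
            f"need >= {n_train + n_test} participants, got {len(participants)}")
    if k > n_train:
        raise ValueError("more folds than training participants")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(repeats):
        if classes is None:
            perm = [participants[i] for i in rng.permutation(len(participants))]
        else:
            # round-robin interleave shuffled per-class lists
            by_class: dict[int, list[str]] = {}
            for p in participants:
                by_class.setdefault(classes[p], []).append(p)
            pools = []
            for c in sorted(by_class):
                grp = by_class[c]
                pools.append([grp[i] for i in rng.permutation(len(grp))])
            perm = []
            while any(pools):
                for pool in pools:
                    if pool:
                        perm.append(pool.pop())
        train = sorted(perm[:n_train])
        test = sorted(perm[n_train:n_train + n_test])
        if classes is None:
            shuffled = [train[i] for i in rng.permutation(len(train))]
        else:
            # keep the interleaved (class-balanced) order for fold assignment
            shuffled = [p for p in perm[:n_train]]
        groups = np.arange(len(train))
        gkf = GroupKFold(n_splits=k)
        folds = []
        for tr_idx, va_idx in gkf.split(shuffled, groups=groups):
            folds.append((sorted(shuffled[i] for i in tr_idx),
                          sorted(shuffled[i] for i in va_idx)))
        out.append(Repeat(train, test, folds))
    return SplitPlan(out, seed)


def leakage_audit(plan: SplitPlan) -> list[str]:
    """Every (train, eval) participant overlap in the plan; must be empty."""
    issues = []
    for r, rep in enumerate(plan.repeats):
        if set(rep.train_participants) & set(rep.test_participants):
            issues.append(f"repeat {r}: train/test overlap")
        for f, (tr, va) in enumerate(rep.folds):
            if set(tr) & set(va):
                issues.append(f"repeat {r} fold {f}: train/val overlap")
            if not set(tr) <= set(rep.train_participants):
                issues.append(f"repeat {r} fold {f}: fold leaks outside train")
            if set(va) - set(rep.train_participants):
                issues.append(f"repeat {r} fold {f}: val outside train pool")
        covered = set()
        for _, va in rep.folds:
            covered |= set(va)
        if covered != set(rep.train_participants):
            issues.append(f"repeat {r}: folds do not partition training set")
    return issues


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    confusion: np.ndarray            # (3, 3) counts, rows = true
    accuracy: float
    per_class_precision: np.ndarray
    per_class_recall: np.ndarray
    per_class_f1: np.ndarray
    weighted_f1: float
    weighted_precision: float
    weighted_recall: float
    support: np.ndarray

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "per_class_precision": self.per_class_precision.tolist(),
            "per_class_recall": self.per_class_recall.tolist(),
            "per_class_f1": self.per_class_f1.tolist(),
            "weighted_f1": self.weighted_f1,
            "weighted_precision": self.weighted_precision,
            "weighted_recall": self.weighted_recall,
            "support": self.support.tolist(),
        }


def compute_metrics(true_labels: np.ndarray,
                    predicted_labels: np.ndarray) -> MetricsReport:
    """Confusion matrix and derived metrics over classes {1, 2, 3}.

    Per-class F1 is the harmonic mean of precision and recall; the weighted
    F1 averages per-class F1 with true-class support as weights.  A class
    with zero predicted positives gets precision 0 (with a warning) rather
    than NaN.
    """
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape:
        raise ValueError("label vectors must have equal length")
    if not (np.isin(t, [1, 2, 3]).all() and np.isin(p, [1, 2, 3]).all()):
        raise ValueError("labels must be in {1, 2, 3}")
    cm = np.zeros((N_CLASSES, N_CLASSES), dtype=np.int64)
    for ti, pi in zip(t, p):
        cm[ti - 1, pi - 1] += 1
    support = cm.sum(axis=1)
    tp = np.diag(cm).astype(float)
    pred_pos = cm.sum(axis=0).astype(float)
    if ((pred_pos == 0) & (support > 0)).any():
        warnings.warn("class with zero predicted positives; precision set to 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(pred_pos > 0, tp / pred_pos, 0.0)
        recall = np.where(support > 0, tp / support, 0.0)
        f1 = np.where(precision + recall > 0,
                      2 * precision * recall / (precision + recall), 0.0)
    total = cm.sum()
    acc = float(tp.sum() / total) if total else 0.0
    wsum = support.sum()
    w_f1 = float((f1 * support).sum() / wsum) if wsum else 0.0
    w_pr = float((precision * support).sum() / wsum) if wsum else 0.0
    w_rc = float((recall * support).sum() / wsum) if wsum else 0.0
    return MetricsReport(cm, acc, precision, recall, f1, w_f1, w_pr, w_rc,
                         support)


# ---------------------------------------------------------------------------
# grid search / experiment loop
# ---------------------------------------------------------------------------

def _subset_by_participants(batch: WindowBatch,
                            ids: list[str]) -> WindowBatch:
    return batch.select(np.isin(batch.participant_ids, ids))


def _train_and_score(cfg: ModelConfig, train_b: WindowBatch,
                     val_b: WindowBatch, patience: int) -> float:
    (train_n, val_n), _ = fit_apply_normalizer(train_b, val_b)
    weights = compute_class_weights(train_n.labels)
    model = SkillClassifier(cfg, train_n.data.shape[1:])
    model.fit(train_n, val_n, weights, patience=patience)
    _, pred = model.predict(val_n)
    return compute_metrics(val_n.labels, pred).weighted_f1


def grid_search(grid: list[ModelConfig], folds: list[tuple[list[str], list[str]]],
                batch: WindowBatch, patience: int = 10
                ) -> tuple[ModelConfig, dict]:
    """Pick the config maximizing mean cross-fold weighted F1.

    Folds with a missing class in their training windows are skipped with a
    warning.  Ties (including duplicated configs) break deterministically in
    favour of the lexicographically smallest configuration.
    """
    if not grid:
        raise ValueError("empty hyperparameter grid")
    ordered = sorted(grid, key=lambda c: repr(c.key()))
    if len(ordered) == 1:
        return ordered[0], {"scores": {}, "skipped_folds": 0}
    best_cfg, best_score = None, -np.inf
    scores: dict[str, float] = {}
    skipped = 0
    for cfg in ordered:
        fold_scores = []
        for tr_ids, va_ids in folds:
            tr = _subset_by_participants(batch, tr_ids)
            va = _subset_by_participants(batch, va_ids)
            if len(np.unique(tr.labels)) < N_CLASSES or va.n == 0:
                warnings.warn("fold skipped: missing class in fold training set")
                skipped += 1
                continue
            fold_scores.append(_train_and_score(cfg, tr, va, patience))
        mean_score = float(np.mean(fold_scores)) if fold_scores else -np.inf
        scores[repr(cfg.key())] = mean_score
        if mean_score > best_score:
            best_cfg, best_score = cfg, mean_score
    return best_cfg, {"scores": scores, "skipped_folds": skipped}


@dataclass
class RunResult:
    """One repeat's held-out evaluation for one modality."""

    modality: str
    repeat: int
    config: ModelConfig
    report: MetricsReport
    true_labels: np.ndarray
    predicted_labels: np.ndarray


@dataclass
class ExperimentResult:
    runs: dict[str, list[RunResult]] = field(default_factory=dict)

    def per_run_metric(self, modality: str, metric: str = "weighted_f1"
                       ) -> np.ndarray:
        return np.array([getattr(r.report, metric)
                         for r in self.runs[modality]])

    def pooled_report(self, modality: str) -> MetricsReport:
        """Metrics over test predictions pooled across all repeats."""
        t = np.concatenate([r.true_labels for r in self.runs[modality]])
        p = np.concatenate([r.predicted_labels for r in self.runs[modality]])
        return compute_metrics(t, p)

    def summary(self) -> dict:
        out = {}
        for mod, runs in self.runs.items():
            acc = self.per_run_metric(mod, "accuracy")
            f1 = self.per_run_metric(mod, "weighted_f1")
            pooled = self.pooled_report(mod)
            out[mod] = {
                "accuracy_mean": float(acc.mean()),
                "accuracy_sd": float(acc.std(ddof=1)) if len(acc) > 1 else 0.0,
                "weighted_f1_mean": float(f1.mean()),
                "weighted_f1_sd": float(f1.std(ddof=1)) if len(f1) > 1 else 0.0,
                "pooled": pooled.to_dict(),
            }
        return out


def run_experiment(plan: SplitPlan, grid: list[ModelConfig],
                   data: dict[str, WindowBatch], patience: int = 10
                   ) -> ExperimentResult:
    """The full repeated subject-independent evaluation, per modality.

    For every repeat and modality: grid-search on the training participants'
    inner folds, retrain the winning config on all training participants
    (early stopping then monitors the training loss, as no further held-out
    participants remain), then evaluate once on the held-out test
    participants.
    """
    result = ExperimentResult({m: [] for m in data})
    for r, rep in enumerate(plan.repeats):
        for modality, batch in data.items():
            audit = set(rep.train_participants) & set(rep.test_participants)
            if audit:
                raise RuntimeError(f"leakage in repeat {r}: {sorted(audit)}")
            best_cfg, _ = grid_search(grid, rep.folds, batch, patience)
            tr = _subset_by_participants(batch, rep.train_participants)
            te = _subset_by_participants(batch, rep.test_participants)
            if te.n == 0:
                raise ValueError(f"repeat {r}: no test windows")
            (tr_n, te_n), _ = fit_apply_normalizer(tr, te)
            weights = compute_class_weights(tr_n.labels)
            model = SkillClassifier(best_cfg, tr_n.data.shape[1:])
            model.fit(tr_n, None, weights, patience=patience)
            _, pred = model.predict(te_n)
            report = compute_metrics(te_n.labels, pred)
            result.runs[modality].append(RunResult(
                modality, r, best_cfg, report, te_n.labels.copy(), pred))
    return result


# ---------------------------------------------------------------------------
# paired comparisons
# ---------------------------------------------------------------------------

@dataclass
class ComparisonResult:
    name_a: str
    name_b: str
    differences: np.ndarray
    t_statistic: float
    p_value: float
    p_holm: float
    wilcoxon_p: float | None = None   # optional distribution-free companion


def paired_tests(scores: dict[str, np.ndarray],
                 pairs: list[tuple[str, str]] | None = None,
                 wilcoxon: bool = False) -> list[ComparisonResult]:
    """Two-tailed paired t-tests across runs, Holm-adjusted as one family.

    ``scores`` maps configuration name -> per-run metric vector (runs
    matched by index).  With no explicit ``pairs``, all unordered pairs form
    the family.  All-zero differences give t = 0, p = 1.
    """
    names = sorted(scores)
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    raw = []
    rows = []
    for a, b in pairs:
        xa, xb = np.asarray(scores[a], float), np.asarray(scores[b], float)
        if xa.shape != xb.shape:
            raise ValueError(f"unequal run counts for {a} vs {b}")
        d = xa - xb
        if np.allclose(d, 0):
            t, p = 0.0, 1.0
        else:
            t, p = sp_stats.ttest_rel(xa, xb)
        wp = None
        if wilcoxon and not np.allclose(d, 0):
            wp = float(sp_stats.wilcoxon(xa, xb).pvalue)
        rows.append((a, b, d, float(t), float(p), wp))
        raw.append(float(p))
    adj = holm_adjust(np.array(raw))
    return [ComparisonResult(a, b, d, t, p, float(ap), wp)
            for (a, b, d, t, p, wp), ap in zip(rows, adj)]


def holm_adjust(p_values: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    if len(p_values) == 0:
        return p_values
    return multipletests(p_values, method="holm")[1]
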