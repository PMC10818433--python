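"""Confusion-matrix metrics, patient-wise cross-validation and model comparison.

The metric suite is the respiratory-sound-challenge standard: accuracy,
sensitivity, specificity, precision and the Score, defined as the arithmetic
mean of sensitivity and specificity,

    Acc = (TP + TN) / (TP + TN + FP + FN)
    Sen = TP / (TP + FN)
    Spe = TN / (TN + FP)
    Pre = TP / (TP + FP)
    Sco = (Sen + Spe) / 2

with TP counting adventitious cycles correctly recognized as adventitious and
TN normal cycles recognized as normal.  For the 4-class task the full 4x4
matrix is kept and Sen/Spe/Pre are computed on the adventitious-vs-normal
reduction, while Acc is the exact-match multiclass accuracy.

Cross-validation is *patient-wise*: folds partition patients, never cycles,
so no patient contributes to both sides of a split.  Classifier pairs are
compared with the Mann-Whitney U test and the Wilcoxon signed-rank test on
per-fold scores.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import confusion_matrix as _sk_confusion

from .audio_io import LABELS4
from .errors import ConfigurationError, ParameterError

TASKS = ("wheeze_binary", "crackle_binary", "four_class")


@dataclass
class ConfusionCounts:
    """Binary confusion counts, optionally backed by a full 4x4 matrix.

    For the 4-class task ``matrix[i, j]`` counts true class i predicted as
    class j in the canonical order (normal, crackle, wheeze, both), and the
    tp/tn/fp/fn fields hold the adventitious-vs-normal reduction.
    """

    tp: int
    tn: int
    fp: int
    fn: int
    matrix: np.ndarray | None = None

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricSet:
    """The five challenge metrics as proportions in [0, 1]; NaN = undefined."""

    acc: float
    sen: float
    spe: float
    pre: float
    sco: float

    def as_percent(self) -> dict:
        return {k: round(100.0 * v, 2) for k, v in asdict(self).items()}


@dataclass
class FoldSplit:
    """Patient-to-fold assignments, one dict per repetition."""

    k: int
    repeats: int
    assignments: list[dict]

    def test_patients(self, repeat: int, fold: int) -> list:
        return [p for p, f in self.assignments[repeat].items() if f == fold]

    def train_patients(self, repeat: int, fold: int) -> list:
        return [p for p, f in self.assignments[repeat].items() if f != fold]


@dataclass
class ComparisonReport:
    """Two-sided nonparametric comparison of two per-fold score vectors."""

    u_statistic: float
    u_pvalue: float
    w_statistic: float | None
    w_pvalue: float | None
    alpha: float
    verdict: str            # "a", "b" or "indistinguishable"


@dataclass
class EvaluationReport:
    """Cross-validation outcome: per-fold metrics plus two aggregations.

    ``aggregate`` applies the metric formulas to the summed confusion matrix
    (the headline figure); ``fold_mean`` averages per-fold metric values.
    The two differ in general and both are reported.
    """

    task: str
    per_fold: list[MetricSet]
    fold_confusions: list[ConfusionCounts]
    aggregate: MetricSet
    fold_mean: MetricSet

    def to_json(self, path=None) -> str:
        def ms(m: MetricSet) -> dict:
            return {k: (None if np.isnan(v) else v) for k, v in asdict(m).items()}

        payload = {
            "task": self.task,
            "per_fold": [ms(m) for m in self.per_fold],
            "aggregate": ms(self.aggregate),
            "fold_mean": ms(self.fold_mean),
            "fold_confusions": [
                {"tp": c.tp, "tn": c.tn, "fp": c.fp, "fn": c.fn}
                for c in self.fold_confusions
            ],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


# ---------------------------------------------------------------------------
# confusion and metrics

def _as_binary(y, task: str, name: str) -> np.ndarray:
    out = np.asarray(y)
    if out.dtype == bool:
        out = out.astype(int)
    bad = ~np.isin(out, (0, 1))
    if bad.any():
        i = int(np.argmax(bad))
        raise ParameterError(f"{name}[{i}] = {out[i]!r} outside the {task} alphabet {{0, 1}}")
    return out.astype(int)


def _as_four(y, name: str) -> np.ndarray:
    arr = np.asarray(y)
    if arr.dtype.kind in "UO":
        idx = np.full(arr.shape, -1)
        for j, lab in enumerate(LABELS4):
            idx[arr == lab] = j
        if (idx < 0).any():
            i = int(np.argmax(idx < 0))
            raise ParameterError(
                f"{name}[{i}] = {arr[i]!r} outside the four_class alphabet {LABELS4}"
            )
        return idx.astype(int)
    idx = arr.astype(int)
    bad = ~np.isin(idx, range(4))
    if bad.any():
        i = int(np.argmax(bad))
        raise ParameterError(f"{name}[{i}] = {arr[i]!r} outside the four_class alphabet 0..3")
    return idx


def confusion(y_true, y_pred, task: str) -> ConfusionCounts:
    """Confusion counts for one of the three classification tasks.

    Binary tasks take 0/1 (or boolean) labels with 1 = target sound present.
    The 4-class task takes labels from (normal, crackle, wheeze, both) or
    indices 0..3; the binary reduction treats every adventitious class as
    positive and normal as negative.
    """
    if task not in TASKS:
        raise ParameterError(f"unknown task {task!r}; expected one of {TASKS}")
    if len(y_true) != len(y_pred):
        raise ParameterError(f"label lengths differ: {len(y_true)} vs {len(y_pred)}")
    if task == "four_class":
        yt, yp = _as_four(y_true, "y_true"), _as_four(y_pred, "y_pred")
        M = _sk_confusion(yt, yp, labels=range(4))
        bt, bp = (yt != 0).astype(int), (yp != 0).astype(int)
        B = _sk_confusion(bt, bp, labels=(0, 1))
        return ConfusionCounts(
            tp=int(B[1, 1]), tn=int(B[0, 0]), fp=int(B[0, 1]), fn=int(B[1, 0]), matrix=M
        )
    yt = _as_binary(y_true, task, "y_true")
    yp = _as_binary(y_pred, task, "y_pred")
    B = _sk_confusion(yt, yp, labels=(0, 1))
    return ConfusionCounts(tp=int(B[1, 1]), tn=int(B[0, 0]), fp=int(B[0, 1]), fn=int(B[1, 0]))


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reported as NaN", stacklevel=3)
        return float("nan")
    return num / den


def metrics(c: ConfusionCounts) -> MetricSet:
    """The five challenge metrics from confusion counts.

    Zero-denominator cells are NaN with a warning, never a silent zero.  When
    a full 4x4 matrix is attached, accuracy is the exact-match multiclass
    accuracy (matrix trace over total); Sen/Spe/Pre always come from the
    binary counts and Sco = (Sen + Spe) / 2 exactly.
    """
    if c.total == 0:
        raise ParameterError("empty confusion matrix")
    if c.matrix is not None:
        acc = float(np.trace(c.matrix)) / float(c.matrix.sum())
    else:
        acc = (c.tp + c.tn) / c.total
    sen = _ratio(c.tp, c.tp + c.fn, "sensitivity")
    spe = _ratio(c.tn, c.tn + c.fp, "specificity")
    pre = _ratio(c.tp, c.tp + c.fp, "precision")
    return MetricSet(acc=acc, sen=sen, spe=spe, pre=pre, sco=(sen + spe) / 2.0)


def score_identity(sen_pct: float, spe_pct: float, sco_pct: float, decimals: int = 1):
    """Check a printed (Sen, Spe, Sco) percentage triple for internal consistency.

    Recomputes Sco = (Sen + Spe)/2 and compares with the printed value at the
    printing precision (half a unit in the last printed decimal).  Returns
    (computed_sco, consistent_flag).
    """
    computed = (sen_pct + spe_pct) / 2.0
    tol = 0.5 * 10.0 ** (-decimals) + 1e-12
    return computed, bool(abs(computed - sco_pct) <= tol)


# ---------------------------------------------------------------------------
# folds and cross-validation

def make_folds(patient_ids, k: int = 10, repeats: int = 5, seed: int = 0) -> FoldSplit:
    """Seeded random partition of patients into k near-equal folds, repeated.

    Fold sizes differ by at most one (the first ``n % k`` folds get the extra
    patient).  Each repetition reshuffles with an independent stream spawned
    from the seed, giving k x repeats fold-level evaluation points.
    """
    patients = list(dict.fromkeys(patient_ids))   # unique, order-preserving
    if len(patients) < k:
        raise ParameterError(f"{len(patients)} patients cannot fill {k} folds")
    if k < 2:
        raise ParameterError("need at least 2 folds")
    streams = np.random.SeedSequence(seed).spawn(repeats)
    assignments = []
    for ss in streams:
        rng = np.random.default_rng(ss)
        order = rng.permutation(len(patients))
        sizes = np.full(k, len(patients) // k)
        sizes[: len(patients) % k] += 1
        fold_of = {}
        pos = 0
        for f, size in enumerate(sizes):
            for i in order[pos : pos + size]:
                fold_of[patients[i]] = f
            pos += size
        assignments.append(fold_of)
    return FoldSplit(k=k, repeats=repeats, assignments=assignments)


def carve_validation(train_patients, frac: float = 0.1, seed: int = 0):
    """Split training patients into (train, validation) patient lists.

    The validation side receives ceil(frac * n) patients (at least one,
    never all) for early stopping; deterministic under the seed.
    """
    pats = list(train_patients)
    if len(pats) < 2:
        raise ParameterError("need at least 2 training patients to carve validation")
    n_val = min(max(1, int(np.ceil(frac * len(pats)))), len(pats) - 1)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pats))
    val = [pats[i] for i in order[:n_val]]
    train = [pats[i] for i in order[n_val:]]
    return train, val


def cross_validate(
    dataset,
    model_factory,
    task: str,
    folds: FoldSplit,
    repeat: int = 0,
    val_frac: float = 0.1,
    seed: int = 0,
) -> EvaluationReport:
    """Patient-wise k-fold evaluation of a classifier factory.

    ``dataset`` is a triple (X, y, patient_ids): features/images stacked on
    axis 0, integer labels, and the patient of each cycle.  For every fold the
    factory is called to produce a fresh model exposing
    ``fit(X, y, X_val, y_val)`` and ``predict(X)``; it is trained on the
    non-test patients (with a validation carve-out of ``val_frac`` of the
    training patients for early stopping) and evaluated on the test patients.

    Returns per-fold metrics, the metrics of the summed confusion matrix, and
    the mean of the per-fold metrics.
    """
    X, y, patient_ids = dataset
    y = np.asarray(y)
    pid = np.asarray(patient_ids)
    assignment = folds.assignments[repeat]
    missing = set(np.unique(pid)) - set(assignment)
    if missing:
        raise ConfigurationError(f"patients missing from fold assignment: {sorted(missing)}")
    per_fold: list[MetricSet] = []
    confusions: list[ConfusionCounts] = []
    for f in range(folds.k):
        test_pat = [p for p, fi in assignment.items() if fi == f]
        train_pat_all = [p for p, fi in assignment.items() if fi != f]
        test_mask = np.isin(pid, test_pat)
        if not test_mask.any():
            raise ConfigurationError(f"fold {f} contains no test cycles")
        tr_pat, val_pat = carve_validation(train_pat_all, frac=val_frac, seed=seed + f)
        tr_mask = np.isin(pid, tr_pat)
        val_mask = np.isin(pid, val_pat)
        model = model_factory()
        model.fit(X[tr_mask], y[tr_mask], X[val_mask], y[val_mask])
        pred = model.predict(X[test_mask])
        c = confusion(y[test_mask], pred, task)
        confusions.append(c)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            per_fold.append(metrics(c))
    agg = ConfusionCounts(
        tp=sum(c.tp for c in confusions),
        tn=sum(c.tn for c in confusions),
        fp=sum(c.fp for c in confusions),
        fn=sum(c.fn for c in confusions),
        matrix=(
            sum(c.matrix for c in confusions) if confusions[0].matrix is not None else None
        ),
    )
    fold_mean = MetricSet(
        **{
            kf: float(np.nanmean([getattr(m, kf) for m in per_fold]))
            for kf in ("acc", "sen", "spe", "pre", "sco")
        }
    )
    return EvaluationReport(
        task=task,
        per_fold=per_fold,
        fold_confusions=confusions,
        aggregate=metrics(agg),
        fold_mean=fold_mean,
    )


# ---------------------------------------------------------------------------
# significance testing

def compare_models(scores_a, scores_b, alpha: float = 0.05) -> ComparisonReport:
    """Mann-Whitney U and Wilcoxon signed-rank comparison of per-fold scores.

    Both tests are two-sided; exact p-values are used for n <= 12 without
    ties, the tie-corrected normal approximation otherwise.  The signed-rank
    test requires equal-length (paired) vectors and is skipped otherwise.
    Identical paired vectors are reported as indistinguishable (p = 1).
    """
    a = np.asarray(scores_a, dtype=np.float64)
    b = np.asarray(scores_b, dtype=np.float64)
    if a.size < 3 or b.size < 3:
        raise ParameterError("need at least 3 score points per model")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (max(a.size, b.size) <= 12 and not has_ties) else "asymptotic"
    u = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    w_stat = w_p = None
    if a.size == b.size:
        diffs = a - b
        if np.all(diffs == 0):
            w_stat, w_p = 0.0, 1.0
        else:
            nz = diffs[diffs != 0]
            w_method = (
                "exact"
                if (nz.size <= 12 and np.unique(np.abs(nz)).size == nz.size)
                else "approx"
            )
            w = stats.wilcoxon(a, b, alternative="two-sided", method=w_method)
            w_stat, w_p = float(w.statistic), float(w.pvalue)
    pvals = [u.pvalue] + ([w_p] if w_p is not None else [])
    if all(p < alpha for p in pvals):
        verdict = "a" if np.median(a) > np.median(b) else "b"
    else:
        verdict = "indistinguishable"
    return ComparisonReport(
        u_statistic=float(u.statistic),
        u_pvalue=float(u.pvalue),
        w_statistic=w_stat,
        w_pvalue=w_p,
        alpha=alpha,
        verdict=verdict,
    )
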