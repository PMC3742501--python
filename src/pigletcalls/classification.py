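"""Classifying calls to situations and validating the accuracy.

Calls are assigned to their situation of emission by linear discriminant
analysis (Gaussian classes with a pooled covariance), either from the
eight standardized acoustic variables or from 0/1 call-type indicator
variables. Accuracy is cross-validated with the holdout method (random
half-split: fit on the calibration half, score the validation half) and
judged against a permutation null in two ways:

* naive label permutation across calls (appropriate when calls are
  exchangeable), and
* pDFA, which permutes whole subjects (piglets, or piglet-situation pairs
  for the few piglets recorded twice) between situations, so repeated
  calls from one animal cannot masquerade as situation information.

A leave-sample-out simulation measures how accuracy grows when 1..20 calls
from a situation are available: the sampled calls are averaged (mean
acoustic features, or call-type proportions), the discriminant function is
refit on all remaining calls, and the averaged samples are classified.
A MANOVA (Wilks lambda with Rao's F approximation) tests whether mean
acoustic structure differs among situations at all.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .study import GROSS_CATEGORY


@dataclass
class DiscriminantModel:
    """Equal-covariance Gaussian discriminant with class priors."""

    classes: np.ndarray
    means: np.ndarray  # (C, p)
    covariance: np.ndarray  # pooled within-class, ridge added
    priors: np.ndarray
    _precision: np.ndarray = field(repr=False, default=None)


@dataclass
class ClassificationReport:
    confusion: pd.DataFrame  # true x predicted counts
    percent_correct: float
    per_class_percent: pd.Series
    chance_percent: float | None = None
    p_value: float | None = None
    n_permutations: int | None = None


def lda_fit(
    X: np.ndarray,
    y: np.ndarray,
    priors_policy: str = "frequency",
    ridge: float = 0.0,
) -> DiscriminantModel:
    """Fit the pooled-covariance Gaussian discriminant.

    ``priors_policy`` is "frequency" (proportional to training class
    sizes) or "uniform". ``ridge`` adds a small diagonal to the pooled
    covariance; indicator-variable (call type) predictors need this since
    their covariance is singular by construction.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    small = classes[counts < 2]
    if small.size:
        raise ValueError(f"class(es) with fewer than 2 members: {list(small)}")
    n, p = X.shape
    means = np.stack([X[y == c].mean(axis=0) for c in classes])
    cov = np.zeros((p, p))
    for c, mu in zip(classes, means):
        diff = X[y == c] - mu
        cov += diff.T @ diff
    cov /= n - classes.size
    cov = cov + ridge * np.eye(p)
    if priors_policy == "frequency":
        priors = counts / n
    elif priors_policy == "uniform":
        priors = np.full(classes.size, 1.0 / classes.size)
    else:
        raise ValueError(f"unknown priors_policy {priors_policy!r}")
    try:
        precision = np.linalg.inv(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "pooled covariance is singular; drop collinear variables or pass ridge > 0"
        ) from exc
    return DiscriminantModel(
        classes=classes, means=means, covariance=cov, priors=priors, _precision=precision
    )


def _discriminant_scores(model: DiscriminantModel, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    if X.shape[1] != model.means.shape[1]:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match model ({model.means.shape[1]})"
        )
    A = model._precision @ model.means.T  # (p, C)
    const = -0.5 * np.einsum("cp,pc->c", model.means, A) + np.log(model.priors)
    return X @ A + const


def lda_predict(model: DiscriminantModel, X: np.ndarray) -> np.ndarray:
    """Argmax-score class labels; ties go to the earlier class."""
    return model.classes[np.argmax(_discriminant_scores(model, X), axis=1)]


def lda_posterior(model: DiscriminantModel, X: np.ndarray) -> np.ndarray:
    """Posterior class probabilities under the shared-covariance model."""
    scores = _discriminant_scores(model, X)
    scores -= scores.max(axis=1, keepdims=True)
    w = np.exp(scores)
    return w / w.sum(axis=1, keepdims=True)


def dummy_code_types(type_labels: np.ndarray, categories=None) -> pd.DataFrame:
    """0/1 indicator matrix of call-type membership (one column per type)."""
    labels = pd.Series(np.asarray(type_labels))
    if categories is None:
        categories = sorted(labels.unique())
    if len(categories) < 2:
        raise ValueError("need at least 2 call types to discriminate")
    unseen = set(labels.unique()) - set(categories)
    if unseen:
        raise ValueError(f"unseen call type label(s): {sorted(unseen)}")
    out = pd.DataFrame(0, index=labels.index, columns=list(categories), dtype=float)
    for cat in categories:
        out.loc[labels[labels == cat].index, cat] = 1.0
    return out


# ---------------------------------------------------------------------------
# holdout cross-validation and permutation nulls


def _half_split(
    y: np.ndarray, rng: np.random.Generator, max_attempts: int = 100
) -> tuple[np.ndarray, np.ndarray]:
    """Random half-split re-drawn until every class appears in both halves."""
    n = y.shape[0]
    classes = np.unique(y)
    for _ in range(max_attempts):
        perm = rng.permutation(n)
        calib, valid = perm[: n // 2], perm[n // 2 :]
        # the fit side needs >= 2 calls per class, the scored side >= 1
        calib_counts = pd.Series(y[calib]).value_counts()
        ok_c = calib_counts.reindex(classes).fillna(0).ge(2).all()
        ok_v = np.isin(classes, y[valid]).all()
        if ok_c and ok_v:
            return calib, valid
    sizes = {c: int((y == c).sum()) for c in classes}
    worst = min(sizes, key=sizes.get)
    raise ValueError(
        f"could not split with every class in both halves after {max_attempts} attempts; "
        f"smallest class: {worst!r} with {sizes[worst]} calls"
    )


def _report(y_true: np.ndarray, y_pred: np.ndarray, classes: np.ndarray) -> ClassificationReport:
    confusion = pd.crosstab(pd.Series(y_true), pd.Series(y_pred))
    confusion = confusion.reindex(index=classes, columns=classes, fill_value=0)
    correct = float(np.diag(confusion).sum())
    per_class = 100.0 * pd.Series(np.diag(confusion), index=classes) / confusion.sum(axis=1)
    return ClassificationReport(
        confusion=confusion,
        percent_correct=100.0 * correct / len(y_true),
        per_class_percent=per_class,
    )


def holdout_classification(
    X: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
    ridge: float = 0.0,
    priors_policy: str = "frequency",
) -> ClassificationReport:
    """Half-split holdout: fit on the calibration half, score the rest."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    calib, valid = _half_split(y, rng)
    model = lda_fit(X[calib], y[calib], priors_policy=priors_policy, ridge=ridge)
    return _report(y[valid], lda_predict(model, X[valid]), model.classes)


def permutation_significance(
    X: np.ndarray,
    y: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    ridge: float = 0.0,
    priors_policy: str = "frequency",
) -> ClassificationReport:
    """Holdout accuracy judged against a call-level label-permutation null.

    Labels are permuted across calls before the half-split; the split is
    re-drawn in each permutation. ``chance_percent`` is the null mean and
    p = (1 + #{null >= observed}) / (n_perm + 1).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    seeds = np.random.SeedSequence(seed).spawn(n_perm + 1)
    observed = holdout_classification(
        X, y, seed=int(seeds[0].generate_state(1)[0] % 2**31), ridge=ridge,
        priors_policy=priors_policy,
    )
    null = np.empty(n_perm)
    for b in range(n_perm):
        rng = np.random.default_rng(seeds[b + 1])
        y_perm = rng.permutation(y)
        rep = holdout_classification(
            X, y_perm, seed=int(rng.integers(2**31)), ridge=ridge, priors_policy=priors_policy
        )
        null[b] = rep.percent_correct
    observed.chance_percent = float(null.mean())
    observed.p_value = float((1 + np.sum(null >= observed.percent_correct)) / (n_perm + 1))
    observed.n_permutations = n_perm
    return observed


# ---------------------------------------------------------------------------
# pDFA: permutation at the subject level


def _subject_holdout_accuracy(
    X: np.ndarray,
    y: np.ndarray,
    subjects: np.ndarray,
    subject_class: dict,
    rng: np.random.Generator,
    ridge: float,
    priors_policy: str,
    max_attempts: int = 100,
) -> float:
    """Half-split at the subject level; accuracy on validation calls."""
    ids = np.array(sorted(subject_class))
    classes = np.unique([subject_class[s] for s in ids])
    for _ in range(max_attempts):
        perm = rng.permutation(ids)
        calib_ids = set(perm[: ids.size // 2])
        calib = np.isin(subjects, list(calib_ids))
        y_c = np.array([subject_class[s] for s in subjects[calib]])
        y_v = np.array([subject_class[s] for s in subjects[~calib]])
        if (
            np.isin(classes, y_c).all()
            and np.isin(classes, y_v).all()
            and min(np.unique(y_c, return_counts=True)[1]) >= 2
        ):
            model = lda_fit(X[calib], y_c, priors_policy=priors_policy, ridge=ridge)
            pred = lda_predict(model, X[~calib])
            return float(np.mean(pred == y_v))
    raise ValueError("could not split subjects with every class in both halves")


def pdfa(
    X: np.ndarray,
    y: np.ndarray,
    subject_ids: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    ridge: float = 0.0,
    priors_policy: str = "frequency",
) -> ClassificationReport:
    """Permuted DFA: significance with the subject as the permutation unit.

    Subjects must be nested in classes (piglets recorded in two situations
    should be passed as distinct piglet-situation subjects). The test
    statistic is subject-level holdout accuracy; the null permutes the
    subject-to-class assignment while preserving each class's subject
    count, so within-subject dependence is retained under the null.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    subjects = np.asarray(subject_ids)
    subject_class: dict = {}
    for s, c in zip(subjects, y):
        if s in subject_class and subject_class[s] != c:
            raise ValueError(
                f"subject {s!r} appears in classes {subject_class[s]!r} and {c!r}; "
                "pass piglet-situation pairs as subjects"
            )
        subject_class[s] = c
    class_counts = pd.Series(list(subject_class.values())).value_counts()
    lonely = class_counts[class_counts < 2]
    if len(lonely):
        raise ValueError(
            f"class(es) with a single subject cannot be permuted: {list(lonely.index)}"
        )
    seeds = np.random.SeedSequence(seed).spawn(n_perm + 1)
    rng0 = np.random.default_rng(seeds[0])
    observed = _subject_holdout_accuracy(
        X, y, subjects, subject_class, rng0, ridge, priors_policy
    )
    ids = np.array(sorted(subject_class))
    true_assignment = np.array([subject_class[s] for s in ids])
    null = np.empty(n_perm)
    for b in range(n_perm):
        rng = np.random.default_rng(seeds[b + 1])
        permuted = rng.permutation(true_assignment)
        mapping = dict(zip(ids, permuted))
        null[b] = _subject_holdout_accuracy(X, y, subjects, mapping, rng, ridge, priors_policy)
    report = ClassificationReport(
        confusion=pd.DataFrame(),
        percent_correct=100.0 * observed,
        per_class_percent=pd.Series(dtype=float),
        chance_percent=float(100.0 * null.mean()),
        p_value=float((1 + np.sum(null >= observed)) / (n_perm + 1)),
        n_permutations=n_perm,
    )
    return report


# ---------------------------------------------------------------------------
# MANOVA


def manova_wilks(X: np.ndarray, y: np.ndarray) -> dict:
    """Wilks lambda with Rao's F approximation.

    Returns a dict with ``wilks_lambda``, ``F``, ``df`` (numerator,
    denominator) and ``p``.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    classes = np.unique(y)
    n, p = X.shape
    g = classes.size
    if n <= p + g:
        raise ValueError("too few observations for MANOVA")
    grand = X.mean(axis=0)
    W = np.zeros((p, p))
    for c in classes:
        diff = X[y == c] - X[y == c].mean(axis=0)
        W += diff.T @ diff
    Tdiff = X - grand
    T = Tdiff.T @ Tdiff
    sign_w, logdet_w = np.linalg.slogdet(W)
    sign_t, logdet_t = np.linalg.slogdet(T)
    if sign_w <= 0 or sign_t <= 0:
        raise ValueError("singular scatter matrix; drop collinear variables")
    lam = float(np.exp(logdet_w - logdet_t))
    q = g - 1
    t_stat = np.sqrt((p**2 * q**2 - 4) / (p**2 + q**2 - 5)) if p**2 + q**2 - 5 > 0 else 1.0
    df1 = p * q
    df2 = (n - 1 - (p + g) / 2.0) * t_stat - (p * q - 2) / 2.0
    lam_t = lam ** (1.0 / t_stat)
    F = (1 - lam_t) / lam_t * df2 / df1
    pval = float(stats.f.sf(F, df1, df2))
    return {"wilks_lambda": lam, "F": float(F), "df": (df1, float(df2)), "p": pval}


# ---------------------------------------------------------------------------
# multi-call accuracy simulation


@dataclass
class AccuracyCurve:
    """Mean classification success and 95% CI per number of pooled calls."""

    n_calls: np.ndarray
    mean_percent: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    mode: str
    target: str

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_calls": self.n_calls,
                "mean_percent": self.mean_percent,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )


def gross_category_collapse(y) -> np.ndarray:
    """Collapse the 11 situation codes to the three gross categories."""
    y = np.asarray(y)
    unknown = set(np.unique(y)) - set(GROSS_CATEGORY)
    if unknown:
        raise ValueError(f"unknown situation code(s): {sorted(unknown)}")
    return np.array([GROSS_CATEGORY[c] for c in y])


def multi_call_accuracy(
    X,
    y: np.ndarray,
    n_range=range(1, 21),
    inner_reps: int = 10,
    outer_reps: int = 20,
    seed: int = 0,
    mode: str = "acoustic",
    target: str = "situation",
    ridge: float = 0.0,
    priors_policy: str = "frequency",
) -> AccuracyCurve:
    """Leave-sample-out simulation of classification from n pooled calls.

    For each draw, ``n`` calls are sampled (without replacement) from every
    included situation and averaged — mean acoustic features in "acoustic"
    mode, call-type proportions in "types" mode (where ``X`` holds the type
    labels). The discriminant function is refit on all remaining calls and
    the averaged samples classified; with ``target="gross"`` both training
    labels and scoring use the three gross categories. Situations with
    fewer than ``max(n_range)`` calls are excluded with a warning. Each
    outer repetition averages ``inner_reps`` draws; the mean and a normal
    95% CI over outer repetitions are reported per n.
    """
    y = np.asarray(y)
    n_range = list(n_range)
    n_max = max(n_range)
    counts = pd.Series(y).value_counts()
    excluded = counts[counts < n_max]
    if len(excluded):
        warnings.warn(
            f"situation(s) with fewer than {n_max} calls excluded: "
            f"{sorted(excluded.index)}",
            stacklevel=2,
        )
    included = sorted(counts[counts >= n_max].index)

    if mode == "types":
        types = sorted(pd.Series(np.asarray(X)).unique())
        features = dummy_code_types(np.asarray(X), categories=types).to_numpy()
        if ridge == 0.0:
            ridge = 1e-8  # indicator covariance is singular by construction
    elif mode == "acoustic":
        features = np.asarray(X, dtype=np.float64)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if target == "gross":
        labels = gross_category_collapse(y)
    elif target == "situation":
        labels = y
    else:
        raise ValueError(f"unknown target {target!r}")

    situation_rows = {s: np.flatnonzero(y == s) for s in included}
    target_of = {s: labels[rows[0]] for s, rows in situation_rows.items()}

    seeds = np.random.SeedSequence(seed).spawn(outer_reps)
    outer_means = np.empty((outer_reps, len(n_range)))
    for r in range(outer_reps):
        rng = np.random.default_rng(seeds[r])
        for j, n in enumerate(n_range):
            hits = 0
            total = 0
            for _ in range(inner_reps):
                drawn = {
                    s: rng.choice(rows, size=n, replace=False)
                    for s, rows in situation_rows.items()
                }
                held_out = np.concatenate(list(drawn.values()))
                mask = np.ones(y.shape[0], dtype=bool)
                mask[held_out] = False
                model = lda_fit(
                    features[mask], labels[mask], priors_policy=priors_policy, ridge=ridge
                )
                samples = np.stack([features[drawn[s]].mean(axis=0) for s in included])
                pred = lda_predict(model, samples)
                truth = np.array([target_of[s] for s in included])
                hits += int(np.sum(pred == truth))
                total += len(included)
            outer_means[r, j] = 100.0 * hits / total
    mean = outer_means.mean(axis=0)
    sem = outer_means.std(axis=0, ddof=1) / np.sqrt(outer_reps) if outer_reps > 1 else np.zeros_like(mean)
    return AccuracyCurve(
        n_calls=np.array(n_range),
        mean_percent=mean,
        ci_low=mean - 1.96 * sem,
        ci_high=mean + 1.96 * sem,
        mode=mode,
        target=target,
    )
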