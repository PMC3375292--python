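"""Discriminant function analysis: conventional and permuted.

Conventional linear DFA builds canonical discriminant functions from
the pooled within-class covariance, reports resubstitution and
leave-one-out cross-validated classification rates, Wilks' lambda with
Bartlett's chi-square approximation, and the canonical structure matrix
(pooled within-group correlations of the variables with the
discriminant scores).

The permuted DFA (pDFA) handles a nested design: a *control factor*
(e.g. individual bat) is nested inside the *test factor* (e.g. species
or colony).  A balanced random subset of each subject's notes trains
the discriminant functions, the rest are classified, and the mean rate
over repetitions is compared with a permutation null in which the test
labels are reshuffled across subjects while each subject's notes stay
together.  The one-tailed p is the proportion of permuted datasets
whose rate is at least as large as the observed one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted


# ---------------------------------------------------------------------------
# numpy core (shared by LinearDFA and the pDFA inner loop)


def _class_stats(X: np.ndarray, y_codes: np.ndarray, n_classes: int):
    """Class means and pooled within-class SSCP matrix."""
    p = X.shape[1]
    means = np.empty((n_classes, p))
    W = np.zeros((p, p))
    counts = np.bincount(y_codes, minlength=n_classes)
    for c in range(n_classes):
        xc = X[y_codes == c]
        means[c] = xc.mean(axis=0)
        d = xc - means[c]
        W += d.T @ d
    return means, W, counts


def _mahalanobis_classify(X: np.ndarray, means: np.ndarray,
                          cov_inv: np.ndarray) -> np.ndarray:
    """Assign rows to the class with smallest pooled-covariance
    Mahalanobis distance (equal priors)."""
    d2 = np.empty((X.shape[0], means.shape[0]))
    for c in range(means.shape[0]):
        diff = X - means[c]
        d2[:, c] = np.einsum("ij,jk,ik->i", diff, cov_inv, diff)
    return np.argmin(d2, axis=1)


def _fit_classify(X_train, y_train, X_test, n_classes, ridge=1e-8):
    """One balanced-training LDA fit + held-out classification (pDFA core)."""
    means, W, counts = _class_stats(X_train, y_train, n_classes)
    dof = max(1, X_train.shape[0] - n_classes)
    cov = W / dof
    cov.flat[:: cov.shape[0] + 1] += ridge * np.trace(cov) / cov.shape[0]
    cov_inv = np.linalg.pinv(cov)
    return _mahalanobis_classify(X_test, means, cov_inv)


# ---------------------------------------------------------------------------
# conventional DFA


@dataclass
class DFAResult:
    """Summary of a conventional leave-one-out DFA."""

    classes: np.ndarray
    coefficients: np.ndarray  # variables x functions, canonical scaling
    structure_matrix: pd.DataFrame
    training_rate: float  # resubstitution, percent
    cv_rate: float  # leave-one-out, percent
    per_class_rates: pd.DataFrame
    wilks_lambda: float
    chi2: float
    df: int
    p_value: float
    n: int
    eigenvalues: np.ndarray = field(default_factory=lambda: np.empty(0))


class LinearDFA(BaseEstimator, ClassifierMixin):
    """Linear discriminant classifier with canonical functions.

    Classification is by smallest Mahalanobis distance to class
    centroids under the pooled within-class covariance with equal
    priors.  ``fit`` also computes Wilks' lambda with Bartlett's
    chi-square approximation, resubstitution and leave-one-out
    classification rates, and the canonical structure matrix.

    Attributes (after ``fit``)
    --------------------------
    classes_ : class labels
    scalings_ : (p, m) canonical discriminant coefficients, scaled to
        unit pooled within-class variance of the scores
    wilks_lambda_, chi2_, df_, p_value_ : multivariate test of equal
        class mean vectors
    training_rate_, cv_rate_ : overall percent-correct rates
    structure_matrix_ : pooled within-class correlations of each
        variable with each discriminant function
    """

    def __init__(self, compute_loo: bool = True):
        self.compute_loo = compute_loo

    def fit(self, X, y) -> "LinearDFA":
        X, names = _as_matrix(X)
        y = np.asarray(y)
        if np.isnan(X).any():
            raise ValueError("X contains missing values")
        classes, y_codes = np.unique(y, return_inverse=True)
        g = classes.size
        n, p = X.shape
        if g < 2:
            raise ValueError("need at least 2 classes")
        counts = np.bincount(y_codes)
        if counts.min() < 2:
            small = classes[counts < 2]
            raise ValueError(f"class(es) with fewer than 2 notes: {small}")
        if n <= p + g:
            raise ValueError(
                f"too few notes (n={n}) for p={p} variables and g={g} "
                "classes; reduce dimensionality first")

        means, W, counts = _class_stats(X, y_codes, g)
        grand = X.mean(axis=0)
        T = (X - grand).T @ (X - grand)
        B = T - W

        sign_w, logdet_w = np.linalg.slogdet(W)
        sign_t, logdet_t = np.linalg.slogdet(T)
        if sign_w <= 0:
            var_within = np.diag(W)
            worst = [names[i] for i in np.argsort(var_within)[:4]]
            raise ValueError(
                "singular pooled within-class covariance; offending "
                f"variables likely among {worst}")
        wilks = float(np.exp(logdet_w - logdet_t))
        chi2_stat = -(n - 1 - (p + g) / 2.0) * np.log(wilks)
        df = p * (g - 1)
        p_value = float(stats.chi2.sf(chi2_stat, df))

        cov = W / (n - g)
        cov_inv = np.linalg.inv(cov)
        m = min(p, g - 1)
        eigval, eigvec = _generalized_eig(B, W)
        scalings = eigvec[:, :m]
        # unit pooled within-class variance of each discriminant score
        norms = np.sqrt(np.einsum("ji,jk,ki->i", scalings, cov, scalings))
        scalings = scalings / norms

        self.classes_ = classes
        self.means_ = means
        self.grand_mean_ = grand
        self.pooled_cov_ = cov
        self._cov_inv = cov_inv
        self.scalings_ = scalings
        self.eigenvalues_ = eigval[:m]
        self.wilks_lambda_ = wilks
        self.chi2_ = float(chi2_stat)
        self.df_ = int(df)
        self.p_value_ = p_value
        self.n_features_in_ = p
        self.feature_names_ = names

        pred = _mahalanobis_classify(X, means, cov_inv)
        self.training_rate_ = 100.0 * float(np.mean(pred == y_codes))
        rates = {"training": 100.0 * _per_class_rates(pred, y_codes, g)}
        if self.compute_loo:
            loo_pred = self._loo_predictions(X, y_codes, means, W, counts)
            self.cv_rate_ = 100.0 * float(np.mean(loo_pred == y_codes))
            rates["testing"] = 100.0 * _per_class_rates(loo_pred, y_codes, g)
        else:
            self.cv_rate_ = np.nan
            rates["testing"] = np.full(g, np.nan)
        self.per_class_rates_ = pd.DataFrame(rates, index=classes)
        self.n_ = n
        self.structure_matrix_ = self._structure(X, y_codes, means, names)
        return self

    def _loo_predictions(self, X, y_codes, means, W, counts):
        """Leave-one-out classification via rank-1 downdates of the
        pooled SSCP inverse and the left-out class mean."""
        n, p = X.shape
        g = means.shape[0]
        W_inv = np.linalg.inv(W)
        pred = np.empty(n, dtype=int)
        dof = n - 1 - g
        for i in range(n):
            c = y_codes[i]
            n_c = counts[c]
            d = X[i] - means[c]
            alpha = n_c / (n_c - 1.0)
            Wd = W_inv @ d
            denom = 1.0 - alpha * float(d @ Wd)
            W_inv_i = W_inv + alpha * np.outer(Wd, Wd) / denom
            means_i = means.copy()
            means_i[c] = (n_c * means[c] - X[i]) / (n_c - 1.0)
            cov_inv_i = W_inv_i * dof
            pred[i] = _mahalanobis_classify(X[i:i + 1], means_i, cov_inv_i)[0]
        return pred

    def _structure(self, X, y_codes, means, names):
        centered = X - means[y_codes]
        scores = centered @ self.scalings_
        sx = centered.std(axis=0, ddof=0)
        ss = scores.std(axis=0, ddof=0)
        corr = (centered.T @ scores) / X.shape[0] / np.outer(sx, ss)
        return pd.DataFrame(
            corr, index=names,
            columns=[f"DF{j + 1}" for j in range(scores.shape[1])])

    def predict(self, X):
        check_is_fitted(self, "classes_")
        X, _ = _as_matrix(X)
        codes = _mahalanobis_classify(X, self.means_, self._cov_inv)
        return self.classes_[codes]

    def transform(self, X):
        """Canonical discriminant scores."""
        check_is_fitted(self, "classes_")
        X, _ = _as_matrix(X)
        return (X - self.grand_mean_) @ self.scalings_

    def result(self) -> DFAResult:
        check_is_fitted(self, "classes_")
        return DFAResult(
            classes=self.classes_, coefficients=self.scalings_,
            structure_matrix=self.structure_matrix_,
            training_rate=self.training_rate_, cv_rate=self.cv_rate_,
            per_class_rates=self.per_class_rates_,
            wilks_lambda=self.wilks_lambda_, chi2=self.chi2_, df=self.df_,
            p_value=self.p_value_, n=self.n_,
            eigenvalues=self.eigenvalues_)


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    return X, [f"x{i}" for i in range(X.shape[1])]


def _per_class_rates(pred, y_codes, g):
    return np.array([np.mean(pred[y_codes == c] == c) for c in range(g)])


def _generalized_eig(B, W):
    """Eigen decomposition of W^-1 B via the symmetric whitened form."""
    from scipy.linalg import cholesky, eigh, solve_triangular

    L = cholesky(W, lower=True)
    Bi = solve_triangular(L, B, lower=True)
    M = solve_triangular(L, Bi.T, lower=True)
    eigval, u = eigh((M + M.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    vec = solve_triangular(L, u[:, order], lower=True, trans="T")
    return eigval, vec


def lda_fit(features, class_labels) -> DFAResult:
    """Fit a conventional leave-one-out DFA (thin wrapper)."""
    return LinearDFA().fit(features, class_labels).result()


def structure_matrix(result: DFAResult, top: int = 5) -> pd.DataFrame:
    """Top-|loading| variables per discriminant function, in the layout
    used for reporting (variable, loading) pairs per function."""
    rows = []
    for fn in result.structure_matrix.columns:
        col = result.structure_matrix[fn]
        best = col.reindex(col.abs().sort_values(ascending=False).index)[:top]
        for var, loading in best.items():
            rows.append({"function": fn, "variable": var,
                         "loading": float(loading)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# permuted DFA


@dataclass
class PDFAConfig:
    """Configuration of a permuted DFA run."""

    test_factor: str
    control_factor: str
    n_train_per_subject: int | str = "auto"
    n_dfa_reps: int = 100
    n_permutations: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_dfa_reps < 1 or self.n_permutations < 1:
            raise ValueError("n_dfa_reps and n_permutations must be >= 1")


@dataclass
class PDFAResult:
    """Observed classification rate vs its permutation null."""

    observed_cv_rate: float  # mean held-out rate, percent
    observed_training_rate: float
    null_rates: np.ndarray
    p_value: float
    n_train_per_subject: int
    n_notes: int
    per_rep_rates: np.ndarray = field(default_factory=lambda: np.empty(0))


class PermutedDFA(BaseEstimator):
    """Permutation test of a nested test factor's classification rate.

    ``fit(X, y, groups=...)`` takes the measurement matrix, the test
    factor labels ``y`` and the control factor (subject) labels
    ``groups``; every subject must carry exactly one test label.
    """

    def __init__(self, n_train_per_subject: int | str = "auto",
                 n_dfa_reps: int = 100, n_permutations: int = 1000,
                 add_one: bool = False, random_state: int = 0):
        self.n_train_per_subject = n_train_per_subject
        self.n_dfa_reps = n_dfa_reps
        self.n_permutations = n_permutations
        self.add_one = add_one
        self.random_state = random_state

    def fit(self, X, y, groups=None) -> "PermutedDFA":
        if groups is None:
            raise ValueError("PermutedDFA requires subject labels via groups=")
        X, _ = _as_matrix(X)
        y = np.asarray(y)
        groups = np.asarray(groups)
        subjects, subj_codes = np.unique(groups, return_inverse=True)
        subj_test = []
        for s in range(subjects.size):
            levels = np.unique(y[subj_codes == s])
            if levels.size != 1:
                raise ValueError(
                    f"control factor not nested in test factor: subject "
                    f"{subjects[s]!r} carries test labels {levels}")
            subj_test.append(levels[0])
        test_levels, subj_level_codes = np.unique(subj_test,
                                                  return_inverse=True)
        if test_levels.size < 2:
            raise ValueError("test factor needs at least 2 levels")
        counts = np.bincount(subj_codes)
        if self.n_train_per_subject == "auto":
            n_train = int(counts.min() * 2) // 3
        else:
            n_train = int(self.n_train_per_subject)
        if n_train < 1:
            raise ValueError("n_train_per_subject must be >= 1")
        too_small = subjects[counts <= n_train]
        if too_small.size:
            raise ValueError(
                f"subject(s) with <= {n_train} notes (no test notes left): "
                f"{list(too_small)}")

        rng = np.random.default_rng(self.random_state)
        subj_indices = [np.nonzero(subj_codes == s)[0]
                        for s in range(subjects.size)]
        n_levels = test_levels.size

        def stage(level_of_subject: np.ndarray, stage_rng) -> tuple[float, float, np.ndarray]:
            y_codes = level_of_subject[subj_codes]
            cv_rates = np.empty(self.n_dfa_reps)
            train_rates = np.empty(self.n_dfa_reps)
            for rep in range(self.n_dfa_reps):
                train_idx = np.concatenate([
                    stage_rng.choice(idx, size=n_train, replace=False)
                    for idx in subj_indices])
                mask = np.zeros(X.shape[0], dtype=bool)
                mask[train_idx] = True
                pred_test = _fit_classify(X[mask], y_codes[mask], X[~mask],
                                          n_levels)
                cv_rates[rep] = np.mean(pred_test == y_codes[~mask])
                pred_train = _fit_classify(X[mask], y_codes[mask], X[mask],
                                           n_levels)
                train_rates[rep] = np.mean(pred_train == y_codes[mask])
            return (100.0 * cv_rates.mean(), 100.0 * train_rates.mean(),
                    100.0 * cv_rates)

        observed_levels = subj_level_codes
        obs_cv, obs_train, per_rep = stage(observed_levels, rng)
        null = np.empty(self.n_permutations)
        for perm in range(self.n_permutations):
            shuffled = rng.permutation(observed_levels)
            null[perm], _, _ = stage(shuffled, rng)
        ge = int(np.sum(null >= obs_cv - 1e-9))
        if self.add_one:
            p = (ge + 1) / (self.n_permutations + 1)
        else:
            p = ge / self.n_permutations
        self.observed_cv_rate_ = obs_cv
        self.observed_training_rate_ = obs_train
        self.null_rates_ = null
        self.p_value_ = float(p)
        self.n_train_per_subject_ = n_train
        self.per_rep_rates_ = per_rep
        self.n_notes_ = X.shape[0]
        return self

    def result(self) -> PDFAResult:
        check_is_fitted(self, "p_value_")
        return PDFAResult(
            observed_cv_rate=self.observed_cv_rate_,
            observed_training_rate=self.observed_training_rate_,
            null_rates=self.null_rates_, p_value=self.p_value_,
            n_train_per_subject=self.n_train_per_subject_,
            n_notes=self.n_notes_, per_rep_rates=self.per_rep_rates_)


def pdfa(features, test_labels, control_labels,
         config: PDFAConfig | None = None, **kwargs) -> PDFAResult:
    """Run a permuted DFA (thin wrapper over :class:`PermutedDFA`)."""
    if config is not None:
        kwargs = dict(n_train_per_subject=config.n_train_per_subject,
                      n_dfa_reps=config.n_dfa_reps,
                      n_permutations=config.n_permutations,
                      random_state=config.seed, **kwargs)
    est = PermutedDFA(**kwargs)
    est.fit(features, test_labels, groups=control_labels)
    return est.result()


# ---------------------------------------------------------------------------
# summary statistics


def chance_rate(n_classes: int) -> float:
    """Expected percent-correct rate of random assignment to
    ``n_classes`` equally sampled classes."""
    if n_classes < 1:
        raise ValueError("need at least one class")
    return 100.0 / n_classes


def holm_correction(p_values, alpha: float = 0.05) -> pd.DataFrame:
    """Holm step-down (sequential Bonferroni) familywise correction.

    Sorted ascending, p(i) is compared against alpha/(m - i + 1); the
    ladder stops at the first failure.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    reject = np.zeros(m, dtype=bool)
    thresholds = np.empty(m)
    failed = False
    for rank, idx in enumerate(order):
        thresholds[idx] = alpha / (m - rank)
        if not failed and p[idx] <= thresholds[idx]:
            reject[idx] = True
        else:
            failed = True
    return pd.DataFrame({"p": p, "threshold": thresholds, "reject": reject})


@dataclass
class RateComparison:
    t: float
    df: int
    p_value: float
    mean_a: float
    mean_b: float


def compare_group_rates(rates_a, rates_b) -> RateComparison:
    """Pooled two-sample t test of two groups of classification rates
    (two-tailed, df = n_a + n_b - 2)."""
    a = np.asarray(list(rates_a), dtype=float)
    b = np.asarray(list(rates_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 rates")
    sa2, sb2 = a.var(ddof=1), b.var(ddof=1)
    df = a.size + b.size - 2
    pooled = ((a.size - 1) * sa2 + (b.size - 1) * sb2) / df
    if pooled == 0:
        raise ValueError("zero pooled variance")
    t = (a.mean() - b.mean()) / np.sqrt(pooled * (1 / a.size + 1 / b.size))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return RateComparison(t=float(t), df=int(df), p_value=p,
                          mean_a=float(a.mean()), mean_b=float(b.mean()))


def outlier_chisq(rates, candidate: float) -> tuple[float, float]:
    """Chi-square outlier test of one rate against the others.

    The candidate's squared deviation from the mean of the *other*
    values, scaled by their sample variance, is referred to a
    chi-square distribution with 1 df.  Returns ``(X2, p)``.
    """
    values = list(rates)
    if len(values) < 3:
        raise ValueError("need at least 3 rates")
    if candidate not in values:
        raise ValueError("candidate must be one of the rates")
    others = list(values)
    others.remove(candidate)
    others = np.asarray(others, dtype=float)
    var = others.var(ddof=1)
    if var == 0:
        raise ValueError("zero variance among the other rates")
    x2 = float((candidate - others.mean()) ** 2 / var)
    return x2, float(stats.chi2.sf(x2, 1))


def plot_discriminant_scatter(model: LinearDFA, X, y, ax=None):
    """Scatter of the first two canonical discriminant scores by class."""
    import matplotlib.pyplot as plt

    scores = model.transform(X)
    if scores.shape[1] < 2:
        raise ValueError("need at least two discriminant functions to plot")
    if ax is None:
        _, ax = plt.subplots()
    y = np.asarray(y)
    for cls, marker in zip(model.classes_, "osD^v<>*Ph+x" * 3):
        sel = y == cls
        ax.scatter(scores[sel, 0], scores[sel, 1], label=str(cls),
                   marker=marker, alpha=0.6, s=14)
    ax.set_xlabel("Discriminant function 1")
    ax.set_ylabel("Discriminant function 2")
    ax.legend(fontsize="small")
    return ax
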