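"""Signature information capacity from a feature table.

The chain is: decide how many principal components to retain by
parallel analysis; extract that many components from the correlation
matrix and rotate them by varimax; score every note by the Bartlett
(weighted least squares) method; estimate, per component, the variance
attributable to each random factor (species, colony, individual) by
restricted maximum likelihood; and convert between/within variance
ratios into bits of signature information,

    H_i = log2(S_T / S_w) = 1/2 log2(S_T^2 / S_w^2),    H_s = sum_i H_i,

with per-component repeatability r_i = S_B^2 / (S_B^2 + S_w^2).  S_B^2
sums the variance components of the declared signature factors
(typically colony + individual), S_w^2 is the residual within-individual
variance, and S_T^2 = S_B^2 + S_w^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted


# ---------------------------------------------------------------------------
# component retention


def _clean_matrix(table, *, min_rows: int = 3) -> tuple[np.ndarray, list[str]]:
    if isinstance(table, pd.DataFrame):
        names = [str(c) for c in table.columns]
        x = table.to_numpy(dtype=float)
    else:
        x = np.asarray(table, dtype=float)
        names = [f"x{i}" for i in range(x.shape[1])]
    keep = ~np.isnan(x).any(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} rows with missing values "
                      "(listwise deletion)", stacklevel=3)
    x = x[keep]
    if x.shape[1] < 2 or x.shape[0] < min_rows:
        raise ValueError("need at least 2 variables and 3 complete rows")
    sds = x.std(axis=0, ddof=1)
    constant = [n for n, s in zip(names, sds) if s == 0 or not np.isfinite(s)]
    if constant:
        raise ValueError(f"constant variable(s): {constant}")
    return x, names


def parallel_analysis(
    table,
    n_iterations: int = 1000,
    percentile: float = 95.0,
    seed: int | None = None,
    *,
    null: str = "normal",
) -> int:
    """Number of components whose correlation-matrix eigenvalue exceeds
    the chosen percentile of eigenvalues from random data of identical
    shape.

    ``null='normal'`` draws i.i.d. standard-normal datasets;
    ``null='permute'`` permutes each column of the observed data
    independently, breaking correlations while keeping marginals.
    """
    x, _ = _clean_matrix(table)
    n, p = x.shape
    observed = np.sort(np.linalg.eigvalsh(np.corrcoef(x, rowvar=False)))[::-1]
    rng = np.random.default_rng(seed)
    null_eigs = np.empty((n_iterations, p))
    for it in range(n_iterations):
        if null == "normal":
            r = rng.standard_normal((n, p))
        elif null == "permute":
            r = np.column_stack([rng.permutation(x[:, j]) for j in range(p)])
        else:
            raise ValueError("null must be 'normal' or 'permute'")
        null_eigs[it] = np.sort(
            np.linalg.eigvalsh(np.corrcoef(r, rowvar=False)))[::-1]
    threshold = np.percentile(null_eigs, percentile, axis=0)
    above = observed > threshold
    # retain the leading run of components above threshold
    n_retained = int(np.argmin(above)) if not above.all() else p
    return n_retained


# ---------------------------------------------------------------------------
# varimax PCA with Bartlett scores


def varimax(loadings: np.ndarray, *, normalize: bool = True,
            max_sweeps: int = 100, tol: float = 1e-12) -> tuple[np.ndarray, np.ndarray]:
    """Varimax rotation (orthogonal), optionally Kaiser-normalized.

    Uses Kaiser's pairwise planar-rotation algorithm: for every pair of
    components the rotation angle maximizing the varimax criterion has
    a closed form, and sweeps over all pairs repeat until the criterion
    stops improving.  Returns the rotated loadings and the rotation
    matrix ``R`` such that ``rotated = loadings @ R``.
    """
    lam = np.array(loadings, dtype=float)
    p, k = lam.shape
    if k < 2:
        return lam, np.eye(k)
    comm = np.sqrt((lam ** 2).sum(axis=1))
    comm[comm == 0] = 1.0
    x = lam / comm[:, None] if normalize else lam.copy()
    rot = np.eye(k)

    def criterion(z: np.ndarray) -> float:
        z2 = z ** 2
        return float((z2 ** 2).sum() - (z2.sum(axis=0) ** 2).sum() / p)

    crit_old = criterion(x @ rot)
    for _ in range(max_sweeps):
        for i in range(k - 1):
            for j in range(i + 1, k):
                z = x @ rot
                u = z[:, i] ** 2 - z[:, j] ** 2
                v = 2.0 * z[:, i] * z[:, j]
                num = 2.0 * (p * (u * v).sum() - u.sum() * v.sum())
                den = p * (u ** 2 - v ** 2).sum() - (u.sum() ** 2 - v.sum() ** 2)
                phi = 0.25 * np.arctan2(num, den)
                if abs(phi) < 1e-15:
                    continue
                c, s = np.cos(phi), np.sin(phi)
                g = np.eye(k)
                g[i, i] = g[j, j] = c
                g[i, j] = -s
                g[j, i] = s
                rot = rot @ g
        crit_new = criterion(x @ rot)
        if crit_new - crit_old < tol * max(1.0, abs(crit_old)):
            break
        crit_old = crit_new
    rotated = (x @ rot)
    if normalize:
        rotated = rotated * comm[:, None]
    return rotated, rot


class VarimaxPCA(BaseEstimator, TransformerMixin):
    """Correlation-matrix PCA with varimax rotation and Bartlett scores.

    Parameters
    ----------
    n_components : int
        Number of components to retain (from parallel analysis).
    rotate : bool, default True
        Apply varimax with Kaiser normalization to the retained
        loadings.  With one component the rotation is the identity.

    Attributes
    ----------
    loadings_ : ndarray of shape (n_variables, n_components)
        Rotated component loadings (correlations of variables with
        components).
    variance_proportion_ : ndarray of shape (n_components,)
        Share of total variance carried by each rotated component.
    mean_, scale_ : ndarray
        Standardization applied before scoring.
    """

    def __init__(self, n_components: int = 1, rotate: bool = True):
        self.n_components = n_components
        self.rotate = rotate

    def fit(self, X, y=None) -> "VarimaxPCA":
        x, names = _clean_matrix(X)
        n, p = x.shape
        if not 1 <= self.n_components <= p:
            raise ValueError("n_components must be in [1, n_variables]")
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.mean_ = x.mean(axis=0)
        self.scale_ = x.std(axis=0, ddof=1)
        corr = np.corrcoef(x, rowvar=False)
        eigval, eigvec = np.linalg.eigh(corr)
        if eigval[0] < 1e-10:
            culprit = np.abs(eigvec[:, 0])
            worst = [names[i] for i in np.argsort(culprit)[::-1][:4]]
            raise ValueError(
                f"singular correlation matrix; collinear variables likely "
                f"among {worst}")
        order = np.argsort(eigval)[::-1][:self.n_components]
        lam = eigvec[:, order] * np.sqrt(eigval[order])
        if self.rotate and self.n_components > 1:
            lam, rot = varimax(lam)
            # order rotated components by explained variance, fix signs
            idx = np.argsort((lam ** 2).sum(axis=0))[::-1]
            lam = lam[:, idx]
            rot = rot[:, idx]
            signs = np.sign(lam.sum(axis=0))
            signs[signs == 0] = 1.0
            lam *= signs
            self.rotation_ = rot * signs
        else:
            self.rotation_ = np.eye(self.n_components)
        self.loadings_ = lam
        self.variance_proportion_ = (lam ** 2).sum(axis=0) / p
        communalities = (lam ** 2).sum(axis=1)
        self.communalities_ = communalities
        psi = np.clip(1.0 - communalities, 1e-6, None)
        # Bartlett / weighted-least-squares scoring matrix
        lam_psi = lam / psi[:, None]
        self.scoring_matrix_ = np.linalg.solve(lam.T @ lam_psi, lam_psi.T)
        self.n_features_in_ = p
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "loadings_")
        if isinstance(X, pd.DataFrame):
            X = X.to_numpy(dtype=float)
        x = check_array(X, ensure_min_features=self.n_features_in_)
        z = (x - self.mean_) / self.scale_
        return z @ self.scoring_matrix_.T


def pca_varimax(table, n_retained: int) -> VarimaxPCA:
    """Fit a :class:`VarimaxPCA` on a feature table (thin wrapper)."""
    return VarimaxPCA(n_components=n_retained).fit(table)


# ---------------------------------------------------------------------------
# variance components (REML)


@dataclass
class VarianceComponents:
    """Per-component variance attributed to random factors + residual."""

    factors: list[str]
    between: pd.DataFrame  # rows = components, columns = factors (S_B^2)
    within: np.ndarray  # residual S_w^2 per component
    n_truncated: int = 0

    @property
    def total(self) -> np.ndarray:
        return self.between.to_numpy().sum(axis=1) + self.within


def _oneway_reml(y: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """REML estimates (sigma_b^2, sigma_w^2) for a one-way random model.

    The REML log-likelihood is profiled down to a 1-D optimization over
    the variance ratio gamma = sigma_b^2/sigma_w^2; numerically exact in
    balanced designs (matches the ANOVA moment estimator whenever that
    is nonnegative).
    """
    labels, idx = np.unique(groups, return_inverse=True)
    n_i = np.bincount(idx).astype(float)
    N = y.size
    means = np.bincount(idx, weights=y) / n_i
    ss_within = float(((y - means[idx]) ** 2).sum())

    def neg2_profiled(gamma: float) -> float:
        w = n_i / (1.0 + n_i * gamma)
        mu = (w * means).sum() / w.sum()
        q = ss_within + float((w * (means - mu) ** 2).sum())
        return ((N - 1) * np.log(q / (N - 1))
                + float(np.log1p(n_i * gamma).sum()) + np.log(w.sum()))

    # optimize on a log-ish scale with an explicit boundary check
    res = minimize_scalar(lambda u: neg2_profiled(np.expm1(u) if u > 0 else 0.0),
                          bounds=(0.0, np.log(1e6)), method="bounded",
                          options={"xatol": 1e-12})
    gamma = float(np.expm1(res.x)) if res.x > 0 else 0.0
    if neg2_profiled(0.0) <= neg2_profiled(gamma):
        gamma = 0.0
    w = n_i / (1.0 + n_i * gamma)
    mu = (w * means).sum() / w.sum()
    q = ss_within + float((w * (means - mu) ** 2).sum())
    sw2 = q / (N - 1)
    return gamma * sw2, sw2


def _nested_codes(labels: pd.DataFrame, factors: list[str]) -> pd.DataFrame:
    """Unique level codes for nested factors (outer levels prefixed)."""
    out = pd.DataFrame(index=labels.index)
    prefix = None
    for f in factors:
        col = labels[f].astype(str)
        out[f] = col if prefix is None else prefix + "/" + col
        prefix = out[f]
    return out


def _nested_reml(y: np.ndarray, codes: pd.DataFrame,
                 factors: list[str]) -> tuple[dict[str, float], float]:
    """Multi-factor nested REML via statsmodels MixedLM variance
    components (single all-encompassing group)."""
    import statsmodels.formula.api as smf

    data = codes.copy()
    data["y"] = y
    data["_g"] = 1
    vc = {f: f"0 + C({f})" for f in factors}
    model = smf.mixedlm("y ~ 1", data, groups="_g", vc_formula=vc,
                        re_formula="0")
    fit = None
    errors = []
    for method in ("lbfgs", "bfgs", "cg"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = model.fit(reml=True, method=method, maxiter=500)
            if np.all(np.isfinite(fit.params)):
                break
            fit = None
        except (np.linalg.LinAlgError, ValueError) as exc:
            errors.append(f"{method}: {exc}")
    if fit is None:
        raise RuntimeError(
            f"REML did not converge for factors {factors} "
            f"(optimizers tried: {errors})")
    comps = dict(zip(model.exog_vc.names, fit.vcomp))
    return {f: float(comps[f]) for f in factors}, float(fit.scale)


def estimate_vce(
    scores,
    labels: pd.DataFrame,
    factors: list[str],
) -> VarianceComponents:
    """REML variance components of nested random factors, per component.

    ``factors`` are ordered outermost first (e.g. ``["species",
    "colony", "individual"]``); inner levels are automatically prefixed
    with their outer levels so that nesting holds even if level names
    repeat across branches.  Negative estimates are truncated to zero
    and counted in ``n_truncated``.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if scores.shape[0] == 1 and len(labels) != 1:
        scores = scores.T
    if scores.shape[0] != len(labels):
        raise ValueError("scores and labels disagree on the number of notes")
    for f in factors:
        n_levels = labels[f].nunique()
        if n_levels < 2:
            raise ValueError(f"factor {f!r} has {n_levels} level(s); need >= 2")
    codes = _nested_codes(labels[factors], factors)
    # an inner factor whose partition coincides with its outer factor's
    # (e.g. exactly one colony per species) has no identifiable variance
    # of its own; drop it rather than fit a singular model
    kept: list[str] = []
    for f in factors:
        if kept and codes[f].nunique() == codes[kept[-1]].nunique():
            warnings.warn(
                f"factor {f!r} is confounded with {kept[-1]!r} "
                "(identical grouping); dropping it from the model",
                stacklevel=2)
            continue
        kept.append(f)
    factors = kept
    between = np.zeros((scores.shape[1], len(factors)))
    within = np.zeros(scores.shape[1])
    n_trunc = 0
    for i in range(scores.shape[1]):
        y = scores[:, i]
        if len(factors) == 1:
            sb2, sw2 = _oneway_reml(y, codes[factors[0]].to_numpy())
            comps = {factors[0]: sb2}
        else:
            comps, sw2 = _nested_reml(y, codes, factors)
        for j, f in enumerate(factors):
            val = comps[f]
            if val < 0:
                n_trunc += 1
                val = 0.0
            between[i, j] = val
        within[i] = sw2
    if np.any(within <= 0):
        raise ValueError("residual within variance estimated at zero; "
                         "information would be infinite")
    if n_trunc:
        warnings.warn(f"truncated {n_trunc} negative variance component(s) "
                      "to zero", stacklevel=2)
    return VarianceComponents(
        factors=list(factors),
        between=pd.DataFrame(between, columns=factors),
        within=within, n_truncated=n_trunc)


# ---------------------------------------------------------------------------
# information and attribution


@dataclass
class SignatureInfo:
    """Bits of signature information and repeatability per component."""

    h_bits: np.ndarray  # H_i per component
    repeatability: np.ndarray  # r_i per component
    signature_factors: list[str] = field(default_factory=list)

    @property
    def total_bits(self) -> float:
        return float(self.h_bits.sum())

    @property
    def mean_repeatability(self) -> float:
        return float(self.repeatability.mean())


def signature_information(
    vce: VarianceComponents,
    signature_factors: list[str] | None = None,
) -> SignatureInfo:
    """Convert variance components to bits.

    ``S_B^2`` per component is the summed variance of the signature
    factors (default: all factors except ``"species"`` when present,
    i.e. colony + individual); ``H_i = 1/2 log2((S_B^2 + S_w^2)/S_w^2)``.
    """
    if signature_factors is None:
        signature_factors = [f for f in vce.factors if f != "species"]
    missing = set(signature_factors) - set(vce.factors)
    if missing:
        raise ValueError(f"unknown signature factors {sorted(missing)}")
    sb2 = vce.between[signature_factors].to_numpy().sum(axis=1)
    sw2 = vce.within
    if np.any(sw2 <= 0):
        raise ValueError("S_w^2 must be positive (finite information)")
    st2 = sb2 + sw2
    h = 0.5 * np.log2(st2 / sw2)
    r = sb2 / (sb2 + sw2)
    return SignatureInfo(h_bits=h, repeatability=r,
                         signature_factors=list(signature_factors))


def weighted_variance_attribution(
    vce: VarianceComponents,
    model: VarimaxPCA,
) -> dict[str, float]:
    """Percent of PC-explained variance attributable to each factor.

    Each component's fractional variance shares ``S_B^2(f)/S_T^2`` are
    weighted by the component's explained-variance proportion and
    normalized so factors plus residual sum to 100%.
    """
    varprop = np.asarray(model.variance_proportion_, dtype=float)
    if varprop.size != vce.within.size:
        raise ValueError("vce and model cover different numbers of components")
    st2 = vce.total
    weights = varprop / varprop.sum()
    out: dict[str, float] = {}
    for f in vce.factors:
        shares = vce.between[f].to_numpy() / st2
        out[f] = float((shares * weights).sum() * 100.0)
    out["residual"] = float(((vce.within / st2) * weights).sum() * 100.0)
    return out
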