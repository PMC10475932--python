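"""Modified partial least squares (PLS1) calibration with cross-validated
term selection and Mahalanobis global-H outlier screening.

The regression engine is NIPALS PLS1 with the Shenk–Westerhaus
modification: after each latent factor is extracted and deflated, the
columns of the spectral residual matrix are standardised (divided by
their standard deviations) before the next factor is sought, which keeps
late factors from being dominated by a few high-variance wavelengths.
With ``residual_scaling=False`` the algorithm reduces exactly to
standard PLS1, which is the hook used by the oracle-equivalence tests.

Because every stage is linear, the model collapses to a regression
vector per term count; those vectors are stored so predictions are a
single dot product.

Outlier screening uses the global H (GH) statistic: the squared
Mahalanobis distance of a spectrum's factor scores from the calibration
score centroid, divided by the number of factors and normalised so the
calibration-set mean GH is exactly 1 (n-1 covariance with the (N-1)/N
correction).  GH > 3 is the conventional spectral-outlier cut.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .containers import SpectraSet
from .preprocessing import PreprocessingSettings, apply_pipeline

__all__ = [
    "MPLSModel",
    "CVSettings",
    "OutlierPolicy",
    "fit_mpls",
    "predict",
    "cross_validate",
    "global_h",
    "calibrate_with_outlier_protocol",
]

#: cap on the number of factors used for the GH score space
_GH_MAX_FACTORS = 10


@dataclass
class CVSettings:
    """Cross-validation by cyclically formed groups.

    Sample i is assigned to group ``i mod n_groups`` over the input
    ordering (no shuffling), honouring the cycling group-formation rule.
    The optimal term count is the smallest t whose SECV is within
    ``(1 + term_selection_tolerance)`` of the minimum SECV.
    """

    n_groups: int = 5
    max_terms: int = 12
    term_selection_tolerance: float = 0.0

    def __post_init__(self) -> None:
        if self.n_groups < 2:
            raise ValueError("need at least 2 CV groups")
        if self.max_terms < 1:
            raise ValueError("max_terms must be >= 1")
        if self.term_selection_tolerance < 0:
            raise ValueError("tolerance must be >= 0")


@dataclass
class OutlierPolicy:
    """Two-round GH protocol: remove in round 1, only report in round 2."""

    gh_threshold: float = 3.0

    def __post_init__(self) -> None:
        if self.gh_threshold <= 0:
            raise ValueError("gh_threshold must be positive")


@dataclass
class MPLSModel:
    """Fitted PLS1/MPLS model on the preprocessed spectral scale."""

    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray          # (a, p) factor weight vectors
    x_loadings: np.ndarray       # (a, p)
    y_loadings: np.ndarray       # (a,)
    residual_scales: np.ndarray  # (a, p) scales applied after each factor
    coefficients_by_terms: dict[int, np.ndarray]
    intercepts_by_terms: dict[int, float]
    selected_terms: int
    residual_scaling: bool
    cal_scores: np.ndarray | None = None   # (n, a) calibration factor scores
    settings: PreprocessingSettings | None = None
    training_grid: np.ndarray | None = None
    secv_by_terms: dict[int, float] = field(default_factory=dict)
    removed_samples: dict[str, float] = field(default_factory=dict)
    reported_outliers: dict[str, float] = field(default_factory=dict)

    @property
    def max_terms(self) -> int:
        return self.weights.shape[0]

    # ------------------------------------------------------------------
    def transform(self, X: np.ndarray, n_terms: int | None = None) -> np.ndarray:
        """Factor scores for (already preprocessed) spectra rows."""
        a = self.selected_terms if n_terms is None else n_terms
        X = np.atleast_2d(np.asarray(X, dtype=float))
        E = X - self.x_mean
        T = np.empty((X.shape[0], a))
        for k in range(a):
            t = E @ self.weights[k]
            T[:, k] = t
            E = (E - np.outer(t, self.x_loadings[k])) / self.residual_scales[k]
        return T

    def predict_matrix(self, X: np.ndarray, n_terms: int | None = None) -> np.ndarray:
        a = self.selected_terms if n_terms is None else n_terms
        if a not in self.coefficients_by_terms:
            raise ValueError(f"model was not fitted with {a} terms")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return X @ self.coefficients_by_terms[a] + self.intercepts_by_terms[a]

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "x_mean": self.x_mean.tolist(),
            "y_mean": self.y_mean,
            "weights": self.weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "residual_scales": self.residual_scales.tolist(),
            "coefficients_by_terms": {str(k): v.tolist() for k, v in self.coefficients_by_terms.items()},
            "intercepts_by_terms": {str(k): v for k, v in self.intercepts_by_terms.items()},
            "selected_terms": self.selected_terms,
            "residual_scaling": self.residual_scaling,
            "cal_scores": None if self.cal_scores is None else self.cal_scores.tolist(),
            "settings": None if self.settings is None else self.settings.to_dict(),
            "training_grid": None if self.training_grid is None else self.training_grid.tolist(),
            "secv_by_terms": {str(k): v for k, v in self.secv_by_terms.items()},
            "removed_samples": self.removed_samples,
            "reported_outliers": self.reported_outliers,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MPLSModel":
        return cls(
            x_mean=np.asarray(d["x_mean"], dtype=float),
            y_mean=float(d["y_mean"]),
            weights=np.asarray(d["weights"], dtype=float),
            x_loadings=np.asarray(d["x_loadings"], dtype=float),
            y_loadings=np.asarray(d["y_loadings"], dtype=float),
            residual_scales=np.asarray(d["residual_scales"], dtype=float),
            coefficients_by_terms={int(k): np.asarray(v, dtype=float)
                                   for k, v in d["coefficients_by_terms"].items()},
            intercepts_by_terms={int(k): float(v) for k, v in d["intercepts_by_terms"].items()},
            selected_terms=int(d["selected_terms"]),
            residual_scaling=bool(d["residual_scaling"]),
            cal_scores=None if d.get("cal_scores") is None else np.asarray(d["cal_scores"], dtype=float),
            settings=None if d.get("settings") is None else PreprocessingSettings.from_dict(d["settings"]),
            training_grid=None if d.get("training_grid") is None else np.asarray(d["training_grid"], dtype=float),
            secv_by_terms={int(k): float(v) for k, v in d.get("secv_by_terms", {}).items()},
            removed_samples=dict(d.get("removed_samples", {})),
            reported_outliers=dict(d.get("reported_outliers", {})),
        )


def fit_mpls(X: np.ndarray, y: np.ndarray, max_terms: int,
             residual_scaling: bool = True) -> MPLSModel:
    """Fit PLS1 (or MPLS with residual scaling) for 1..max_terms factors.

    Parameters
    ----------
    X : (n, p) preprocessed spectra; y : (n,) constituent values.
    residual_scaling : standardise X-residual columns after each factor
        (the Shenk–Westerhaus modification); off gives standard PLS1.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if y.shape != (n,):
        raise ValueError("y length must match X rows")
    if n <= max_terms + 1:
        raise ValueError(f"need N > max_terms + 1 (N={n}, max_terms={max_terms})")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    if y.std() == 0:
        raise ValueError("y has zero variance")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    E = X - x_mean
    f = y - y_mean

    W = np.empty((max_terms, p))
    P = np.empty((max_terms, p))
    q = np.empty(max_terms)
    S = np.ones((max_terms, p))
    T = np.empty((n, max_terms))

    for a in range(max_terms):
        w = E.T @ f
        norm = np.linalg.norm(w)
        if norm == 0:
            # y residual orthogonal to X residual: no further signal
            W[a:] = 0.0
            P[a:] = 0.0
            q[a:] = 0.0
            T[:, a:] = 0.0
            max_terms = a
            W, P, q, S, T = W[:a], P[:a], q[:a], S[:a], T[:, :a]
            break
        w /= norm
        t = E @ w
        tt = float(t @ t)
        pvec = E.T @ t / tt
        q[a] = float(f @ t) / tt
        W[a] = w
        P[a] = pvec
        T[:, a] = t
        E -= np.outer(t, pvec)
        f = f - q[a] * t
        if residual_scaling:
            s = E.std(axis=0, ddof=1)
            s[s == 0] = 1.0  # degenerate residual column: leave unscaled
            E /= s
            S[a] = s

    if max_terms == 0:
        raise ValueError("could not extract any PLS factor")

    # collapse the stage-wise linear maps into one regression vector per
    # term count: b_t = sum_{a<=t} q_a * M_{a-1} w_a with
    # M_a = M_{a-1} (I - w_a p_a^T) D_a^{-1}
    coefs: dict[int, np.ndarray] = {}
    intercepts: dict[int, float] = {}
    b = np.zeros(p)
    for a in range(max_terms):
        u = W[a].copy()
        for k in range(a - 1, -1, -1):
            u = u / S[k]
            u -= W[k] * float(P[k] @ u)
        b = b + q[a] * u
        coefs[a + 1] = b.copy()
        intercepts[a + 1] = y_mean - float(x_mean @ b)

    return MPLSModel(
        x_mean=x_mean, y_mean=y_mean, weights=W, x_loadings=P, y_loadings=q,
        residual_scales=S, coefficients_by_terms=coefs,
        intercepts_by_terms=intercepts, selected_terms=max_terms,
        residual_scaling=residual_scaling, cal_scores=T,
    )


def predict(model: MPLSModel, spectra: SpectraSet | np.ndarray,
            n_terms: int | None = None) -> np.ndarray:
    """Predict the constituent for raw spectra (preprocessing applied) or
    for an already-preprocessed matrix."""
    if isinstance(spectra, SpectraSet):
        if model.settings is None or model.training_grid is None:
            raise ValueError("model carries no preprocessing settings/grid; "
                             "pass a preprocessed matrix instead")
        pre = apply_pipeline(spectra, model.settings)
        if pre.wavelengths.size != model.training_grid.size or not np.allclose(
            pre.wavelengths, model.training_grid
        ):
            raise ValueError(
                "wavelength grid mismatch: model trained on "
                f"[{model.training_grid[0]:.1f}..{model.training_grid[-1]:.1f}] nm "
                f"({model.training_grid.size} pts), input preprocesses to "
                f"[{pre.wavelengths[0]:.1f}..{pre.wavelengths[-1]:.1f}] nm "
                f"({pre.wavelengths.size} pts)"
            )
        X = pre.absorbance
    else:
        X = np.atleast_2d(np.asarray(spectra, dtype=float))
    return model.predict_matrix(X, n_terms)


def cross_validate(X: np.ndarray, y: np.ndarray, cv: CVSettings,
                   residual_scaling: bool = True) -> tuple[dict[int, float], int]:
    """Group cross-validation; returns (SECV per term count, optimal terms).

    Groups are formed cyclically (sample i -> group i mod n_groups); each
    group is held out in turn, the model refitted on the remainder, and
    SECV(t) = sqrt(mean over all samples of the held-out residual^2).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if cv.n_groups > n:
        raise ValueError(f"more CV groups ({cv.n_groups}) than samples ({n})")
    groups = np.arange(n) % cv.n_groups
    largest_group = (n + cv.n_groups - 1) // cv.n_groups
    max_terms = min(cv.max_terms, n - largest_group - 2)
    if max_terms < 1:
        raise ValueError("too few samples for cross-validation")

    resid = np.empty((n, max_terms))
    for g in range(cv.n_groups):
        hold = groups == g
        if not hold.any():
            raise ValueError(f"CV group {g} is empty")
        model = fit_mpls(X[~hold], y[~hold], max_terms, residual_scaling)
        for t in range(1, model.max_terms + 1):
            resid[hold, t - 1] = model.predict_matrix(X[hold], t) - y[hold]
        # if factor extraction stopped early, reuse the last available terms
        for t in range(model.max_terms + 1, max_terms + 1):
            resid[hold, t - 1] = resid[hold, model.max_terms - 1]

    secv = {t: float(np.sqrt(np.mean(resid[:, t - 1] ** 2)))
            for t in range(1, max_terms + 1)}
    best = min(secv.values())
    # absolute floor so numerically-zero SECVs (exactly recoverable data)
    # count as ties instead of selecting spurious extra factors
    cutoff = (1.0 + cv.term_selection_tolerance) * best + 1e-9 * float(y.std())
    optimal = min(t for t, v in secv.items() if v <= cutoff)
    return secv, optimal


def global_h(model: MPLSModel, spectra: SpectraSet | np.ndarray) -> np.ndarray:
    """Global H (standardised Mahalanobis distance) per sample.

    Scores are taken in the space of ``min(selected_terms, 10)`` factors;
    the distance uses the calibration-score centroid and the n-1
    covariance, and is divided by ``f * (N-1)/N`` so the calibration-set
    mean GH is exactly 1.
    """
    if model.cal_scores is None:
        raise ValueError("model carries no calibration scores")
    a = min(model.selected_terms, _GH_MAX_FACTORS)
    Tcal = model.cal_scores[:, :a]
    n = Tcal.shape[0]
    centroid = Tcal.mean(axis=0)
    cov = np.cov(Tcal, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    try:
        cov_inv = np.linalg.inv(cov)
    except np.linalg.LinAlgError:
        raise ValueError(
            "singular score covariance; refit with fewer factors"
        ) from None
    if isinstance(spectra, SpectraSet):
        if model.settings is None:
            raise ValueError("model carries no preprocessing settings")
        X = apply_pipeline(spectra, model.settings).absorbance
    else:
        X = np.atleast_2d(np.asarray(spectra, dtype=float))
    T = model.transform(X, a)
    d = T - centroid
    d2 = np.einsum("ij,jk,ik->i", d, cov_inv, d)
    return d2 / (a * (n - 1) / n)


def calibrate_with_outlier_protocol(
    X: np.ndarray, y: np.ndarray, cv: CVSettings,
    policy: OutlierPolicy | None = None,
    sample_ids: Sequence[str] | None = None,
    residual_scaling: bool = True,
) -> tuple[MPLSModel, dict]:
    """Calibrate with the two-round GH outlier protocol.

    Round 1: fit with CV-selected terms, score GH, drop samples with
    GH > threshold, refit (CV re-run on the remainder).  Round 2: any
    remaining GH > threshold are *reported* but kept.  Returns the final
    model and a report with removed/remaining outliers and their GH.
    """
    policy = policy or OutlierPolicy()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    ids = [str(s) for s in (sample_ids if sample_ids is not None else range(n))]
    if len(ids) != n:
        raise ValueError("sample_ids length mismatch")

    secv, terms = cross_validate(X, y, cv, residual_scaling)
    model = fit_mpls(X, y, cv.max_terms, residual_scaling)
    model.selected_terms = min(terms, model.max_terms)
    model.secv_by_terms = secv

    gh = global_h(model, X)
    out_mask = gh > policy.gh_threshold
    removed = {ids[i]: float(gh[i]) for i in np.flatnonzero(out_mask)}

    report = {"removed_round1": removed, "reported_round2": {}}
    if removed:
        keep = ~out_mask
        if keep.sum() <= cv.max_terms + 1:
            # refusing to refit on a degenerate remainder: keep round-1 model
            report["warning"] = ("outlier removal would leave too few samples; "
                                 "round-1 model retained")
            model.removed_samples = {}
            model.reported_outliers = removed
            return model, report
        secv, terms = cross_validate(X[keep], y[keep], cv, residual_scaling)
        model = fit_mpls(X[keep], y[keep], cv.max_terms, residual_scaling)
        model.selected_terms = min(terms, model.max_terms)
        model.secv_by_terms = secv
        kept_ids = [ids[i] for i in np.flatnonzero(keep)]
        gh2 = global_h(model, X[keep])
        report["reported_round2"] = {
            kept_ids[i]: float(gh2[i]) for i in np.flatnonzero(gh2 > policy.gh_threshold)
        }
    model.removed_samples = removed
    model.reported_outliers = dict(report["reported_round2"])
    return model, report
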