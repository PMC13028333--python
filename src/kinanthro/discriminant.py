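"""Stepwise canonical linear discriminant analysis with assumption checks,
classification and territorial-map rasterization.

The canonical problem: with between-group scatter B and pooled within-group
scatter W over p variables and g groups, the discriminant directions are the
eigenvectors of W^-1 B.  Eigenvalues lambda_k give canonical correlations
sqrt(lambda_k / (1 + lambda_k)) and Wilks' Lambda = prod 1/(1 + lambda_k);
the overall chi-square uses Bartlett's transform with the
n - 1 - (p + g)/2 multiplier on -ln(Lambda) and p*(g-1) degrees of freedom.

Stepwise selection greedily minimizes partial Wilks' Lambda with classical
F-to-enter/F-to-remove gates (defaults 3.84 / 2.71).  Classification uses
Fisher linear classification functions with configurable priors (equal by
default: group sizes here are design artifacts, not population frequencies).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import linalg, stats


class RankError(ValueError):
    """Scatter matrix is singular for the requested variable set."""


@dataclass
class AssumptionReport:
    """Box's M homogeneity-of-covariance test and per-variable VIF.

    Flags are advisory, never fatal: the analysis is exploratory.
    """

    box_m: float
    box_chi2: float
    box_df: float
    box_p: float
    vif: dict[str, float]
    flags: list[str] = field(default_factory=list)


@dataclass
class StepwisePath:
    selected: list[str]
    lambda_path: list[float]  # Wilks' Lambda after each entry/removal
    log: list[str] = field(default_factory=list)


@dataclass
class DiscriminantModel:
    selected_variables: list[str]
    groups: list[str]
    priors: dict[str, float]
    eigenvalues: np.ndarray
    canonical_correlations: np.ndarray
    variance_explained_pct: np.ndarray
    wilks_lambda: float
    chi_square: float
    chi_df: int
    p_value: float
    raw_coefficients: pd.DataFrame       # variable x function
    standardized_coefficients: pd.DataFrame
    centroids: pd.DataFrame              # group x function
    group_means: pd.DataFrame            # group x variable (original units)
    grand_mean: pd.Series
    pooled_cov: pd.DataFrame             # W / (n - g)
    dispersion_radius: dict[str, float]  # RMS score distance to own centroid (2 fns)
    n: int

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        """Canonical discriminant scores (centered at the grand mean)."""
        Xc = X[self.selected_variables].to_numpy(float) - self.grand_mean.to_numpy()
        return Xc @ self.raw_coefficients.to_numpy()

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "selected_variables": self.selected_variables,
            "groups": self.groups,
            "priors": self.priors,
            "eigenvalues": self.eigenvalues.tolist(),
            "canonical_correlations": self.canonical_correlations.tolist(),
            "variance_explained_pct": self.variance_explained_pct.tolist(),
            "wilks_lambda": self.wilks_lambda,
            "chi_square": self.chi_square,
            "chi_df": self.chi_df,
            "p_value": self.p_value,
            "standardized_coefficients": self.standardized_coefficients.to_dict(),
            "raw_coefficients": self.raw_coefficients.to_dict(),
            "centroids": self.centroids.to_dict(),
            "group_means": self.group_means.to_dict(),
            "grand_mean": self.grand_mean.to_dict(),
            "pooled_cov": self.pooled_cov.to_dict(),
            "dispersion_radius": self.dispersion_radius,
            "n": self.n,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


@dataclass
class ClassificationReport:
    confusion: pd.DataFrame  # true position x predicted position counts
    accuracy_pct: float
    per_position_pct: dict[str, float]
    predictions: np.ndarray


def _scatter(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Within-group, between-group and total scatter matrices."""
    grand = X.mean(axis=0)
    W = np.zeros((X.shape[1], X.shape[1]))
    B = np.zeros_like(W)
    for g in np.unique(y):
        Xg = X[y == g]
        mu = Xg.mean(axis=0)
        W += (Xg - mu).T @ (Xg - mu)
        d = (mu - grand)[:, None]
        B += Xg.shape[0] * (d @ d.T)
    T = W + B
    return W, B, T


def wilks_lambda(X: np.ndarray, y: np.ndarray) -> float:
    """Wilks' Lambda det(W)/det(T) for the given variable set."""
    W, _, T = _scatter(X, y)
    sign_w, logdet_w = np.linalg.slogdet(W)
    sign_t, logdet_t = np.linalg.slogdet(T)
    if sign_w <= 0 or sign_t <= 0:
        raise RankError("singular scatter matrix")
    return float(np.exp(logdet_w - logdet_t))


def check_assumptions(X: pd.DataFrame, y, vif_threshold: float = 5.0,
                      alpha: float = 0.05) -> AssumptionReport:
    """Box's M test of covariance homogeneity and VIF multicollinearity check."""
    from statsmodels.stats.outliers_influence import variance_inflation_factor
    from statsmodels.tools import add_constant

    Xa = X.to_numpy(float)
    ya = np.asarray(y)
    groups = np.unique(ya)
    n, p = Xa.shape
    g = groups.size

    # Box's M with its chi-square approximation
    pooled = np.zeros((p, p))
    log_dets = []
    dfs = []
    for grp in groups:
        Xg = Xa[ya == grp]
        ni = Xg.shape[0]
        if ni <= p:
            raise RankError(f"group {grp!r} has too few observations for Box's M")
        Sg = np.cov(Xg, rowvar=False, ddof=1)
        sign, ld = np.linalg.slogdet(Sg)
        if sign <= 0:
            raise RankError(f"singular covariance in group {grp!r}")
        log_dets.append(ld)
        dfs.append(ni - 1)
        pooled += (ni - 1) * Sg
    pooled /= (n - g)
    sign, ld_pooled = np.linalg.slogdet(pooled)
    if sign <= 0:
        raise RankError("singular pooled covariance")
    m_stat = (n - g) * ld_pooled - float(np.dot(dfs, log_dets))
    c = (sum(1.0 / d for d in dfs) - 1.0 / (n - g)) * (
        (2 * p**2 + 3 * p - 1) / (6.0 * (p + 1) * (g - 1))
    )
    chi2 = m_stat * (1.0 - c)
    df = p * (p + 1) * (g - 1) / 2.0
    box_p = float(stats.chi2.sf(chi2, df))

    with_const = add_constant(Xa)
    vif = {
        col: float(variance_inflation_factor(with_const, i + 1))
        for i, col in enumerate(X.columns)
    }

    flags = []
    if box_p < alpha:
        flags.append(f"Box's M p = {box_p:.4f} < {alpha}: covariances heterogeneous")
    for col, v in vif.items():
        if v > vif_threshold:
            flags.append(f"VIF({col}) = {v:.1f} exceeds {vif_threshold}")
    return AssumptionReport(box_m=float(m_stat), box_chi2=float(chi2),
                            box_df=df, box_p=box_p, vif=vif, flags=flags)


def stepwise_select(X: pd.DataFrame, y, f_enter: float = 3.84,
                    f_remove: float = 2.71, max_steps: int = 100) -> StepwisePath:
    """Greedy stepwise variable selection minimizing partial Wilks' Lambda.

    At each step the candidate with the largest F-to-enter joins the model if
    that F reaches ``f_enter``; previously entered variables are removed when
    their F-to-remove falls below ``f_remove``.  Returns the entry order and
    the Lambda after each change.
    """
    ya = np.asarray(y)
    groups = np.unique(ya)
    g = groups.size
    if g < 2:
        raise ValueError("need at least 2 groups")
    n = len(ya)
    candidates = list(X.columns)
    selected: list[str] = []
    path = StepwisePath(selected=selected, lambda_path=[], log=[])
    current_lambda = 1.0

    def lam(cols: list[str]) -> float:
        return wilks_lambda(X[cols].to_numpy(float), ya)

    for _ in range(max_steps):
        # --- entry ---
        best = None
        for v in candidates:
            if v in selected:
                continue
            try:
                lam_new = lam(selected + [v])
            except RankError:
                continue  # collinear with the current set
            partial = lam_new / current_lambda
            if partial <= 0 or partial > 1:
                continue
            q = len(selected)
            f = ((n - g - q) / (g - 1)) * (1.0 - partial) / partial
            if best is None or f > best[0]:
                best = (f, v, lam_new)
        changed = False
        if best is not None and best[0] >= f_enter:
            f, v, lam_new = best
            selected.append(v)
            current_lambda = lam_new
            path.lambda_path.append(current_lambda)
            path.log.append(f"enter {v}: F = {f:.3f}, Lambda = {lam_new:.4f}")
            changed = True
        # --- removal ---
        removed = True
        while removed and len(selected) > 1:
            removed = False
            worst = None
            for v in selected:
                rest = [c for c in selected if c != v]
                lam_rest = lam(rest)
                partial = current_lambda / lam_rest
                q = len(rest)
                f = ((n - g - q) / (g - 1)) * (1.0 - partial) / partial
                if worst is None or f < worst[0]:
                    worst = (f, v, lam_rest)
            if worst is not None and worst[0] < f_remove:
                f, v, lam_rest = worst
                selected.remove(v)
                current_lambda = lam_rest
                path.lambda_path.append(current_lambda)
                path.log.append(f"remove {v}: F = {f:.3f}, Lambda = {lam_rest:.4f}")
                removed = changed = True
        if not changed:
            break
    return path


def fit_canonical(X: pd.DataFrame, y, priors: dict[str, float] | str = "equal"
                  ) -> DiscriminantModel:
    """Canonical discriminant functions for the supplied (already selected)
    variables.

    ``priors`` is "equal", "proportional", or an explicit mapping.
    """
    cols = list(X.columns)
    Xa = X.to_numpy(float)
    ya = np.asarray([str(v) for v in y])
    groups = sorted(np.unique(ya))
    g, (n, p) = len(groups), Xa.shape
    if n < p + g:
        raise RankError("fewer observations than variables + groups")

    W, B, _ = _scatter(Xa, ya)
    try:
        evals, evecs = linalg.eigh(B, W)
    except linalg.LinAlgError as exc:  # pragma: no cover - guarded by RankError below
        raise RankError(str(exc)) from exc
    order = np.argsort(evals)[::-1]
    m = min(g - 1, p)
    evals = np.clip(evals[order][:m], 0.0, None)
    A = evecs[:, order][:, :m]

    # normalize so within-group variance of each score is 1; fix sign so the
    # largest-magnitude coefficient is positive
    Sw = W / (n - g)
    for k in range(m):
        a = A[:, k]
        scale = np.sqrt(a @ Sw @ a)
        if scale > 0:
            a = a / scale
        if a[np.argmax(np.abs(a))] < 0:
            a = -a
        A[:, k] = a

    lam = float(np.prod(1.0 / (1.0 + evals)))
    chi_mult = n - 1 - (p + g) / 2.0
    chi2 = float(-chi_mult * np.log(lam))
    chi_df = p * (g - 1)
    p_value = float(stats.chi2.sf(chi2, chi_df))
    canon_r = np.sqrt(evals / (1.0 + evals))
    total = evals.sum()
    var_pct = 100.0 * evals / total if total > 0 else np.zeros(m)

    grand = Xa.mean(axis=0)
    scores = (Xa - grand) @ A
    fn_names = [f"DF{k+1}" for k in range(m)]
    centroids = pd.DataFrame(
        [scores[ya == grp].mean(axis=0) for grp in groups],
        index=groups, columns=fn_names,
    )
    radius = {}
    for grp in groups:
        d = scores[ya == grp][:, : min(2, m)] - centroids.loc[grp].to_numpy()[: min(2, m)]
        radius[grp] = float(np.sqrt(np.mean(np.sum(d**2, axis=1))))

    if priors == "equal":
        prior_map = {grp: 1.0 / g for grp in groups}
    elif priors == "proportional":
        prior_map = {grp: float(np.mean(ya == grp)) for grp in groups}
    else:
        prior_map = {str(k): float(v) for k, v in priors.items()}

    std = A * np.sqrt(np.diag(Sw))[:, None]
    return DiscriminantModel(
        selected_variables=cols,
        groups=groups,
        priors=prior_map,
        eigenvalues=evals,
        canonical_correlations=canon_r,
        variance_explained_pct=var_pct,
        wilks_lambda=lam,
        chi_square=chi2,
        chi_df=chi_df,
        p_value=p_value,
        raw_coefficients=pd.DataFrame(A, index=cols, columns=fn_names),
        standardized_coefficients=pd.DataFrame(std, index=cols, columns=fn_names),
        centroids=centroids,
        group_means=pd.DataFrame(
            [Xa[ya == grp].mean(axis=0) for grp in groups],
            index=groups, columns=cols,
        ),
        grand_mean=pd.Series(grand, index=cols),
        pooled_cov=pd.DataFrame(Sw, index=cols, columns=cols),
        dispersion_radius=radius,
        n=n,
    )


def _fisher_scores(model: DiscriminantModel, X: pd.DataFrame) -> np.ndarray:
    """Fisher linear classification function values, one column per group."""
    Xa = X[model.selected_variables].to_numpy(float)
    Sinv = np.linalg.inv(model.pooled_cov.to_numpy())
    out = np.empty((Xa.shape[0], len(model.groups)))
    for j, grp in enumerate(model.groups):
        mu = model.group_means.loc[grp].to_numpy()
        w = Sinv @ mu
        out[:, j] = Xa @ w - 0.5 * mu @ w + np.log(model.priors[grp])
    return out


def predict(model: DiscriminantModel, X: pd.DataFrame) -> np.ndarray:
    """Predicted group per row (ties go to the lowest-index group)."""
    scores = _fisher_scores(model, X)
    idx = np.argmax(scores, axis=1)  # argmax takes the first (lowest) on ties
    return np.asarray(model.groups, dtype=object)[idx]


def classify(model: DiscriminantModel, X: pd.DataFrame, y) -> ClassificationReport:
    """Confusion matrix and accuracy of the model on labelled data."""
    pred = predict(model, X)
    ya = np.asarray([str(v) for v in y])
    groups = model.groups
    conf = pd.DataFrame(0, index=groups, columns=groups, dtype=int)
    for t, p_ in zip(ya, pred):
        conf.loc[t, p_] += 1
    correct = int(np.trace(conf.to_numpy()))
    per_pos = {}
    for grp in groups:
        row_n = int(conf.loc[grp].sum())
        per_pos[grp] = 100.0 * int(conf.loc[grp, grp]) / row_n if row_n else float("nan")
    return ClassificationReport(
        confusion=conf,
        accuracy_pct=100.0 * correct / len(ya),
        per_position_pct=per_pos,
        predictions=pred,
    )


def territorial_map(model: DiscriminantModel, bounds: tuple[float, float, float, float] | None = None,
                    resolution: int = 61) -> dict[str, object]:
    """Rasterize the DF1-DF2 plane into classification regions.

    Scores are whitened within groups, so each grid point is assigned the
    group maximizing -0.5*||z - centroid||^2 + ln(prior) over the first two
    functions.  Returns the grid (long format), the centroids and per-group
    dispersion radii for plotting.
    """
    cent = model.centroids.iloc[:, :2].to_numpy()
    if bounds is None:
        pad = 2.0 + max(model.dispersion_radius.values())
        bounds = (
            float(cent[:, 0].min() - pad), float(cent[:, 0].max() + pad),
            float(cent[:, 1].min() - pad), float(cent[:, 1].max() + pad),
        )
    x0, x1, y0, y1 = bounds
    xs = np.linspace(x0, x1, resolution)
    ys = np.linspace(y0, y1, resolution)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    log_priors = np.array([np.log(model.priors[g]) for g in model.groups])
    d2 = ((pts[:, None, :] - cent[None, :, :]) ** 2).sum(axis=2)
    labels = np.asarray(model.groups, dtype=object)[
        np.argmax(-0.5 * d2 + log_priors[None, :], axis=1)
    ]
    grid = pd.DataFrame({"df1": pts[:, 0], "df2": pts[:, 1], "position": labels})
    return {
        "grid": grid,
        "centroids": model.centroids.iloc[:, :2].copy(),
        "dispersion_radius": dict(model.dispersion_radius),
        "bounds": bounds,
    }
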