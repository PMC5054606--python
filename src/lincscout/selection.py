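"""Feature selection: motif enrichment and SCAD-penalized sparse k-mers.

Motif enrichment uses a two-tailed Fisher exact test per motif on the
(present/absent x positive/negative) table with Benjamini-Hochberg control
across motifs (selected at FDR < 0.01).

The sparse k-mer selector fits a linear classifier under the squared hinge
loss with the SCAD (smoothly clipped absolute deviation) penalty, a
non-convex penalty whose large coefficients are nearly unbiased.  It is
optimized by local linear approximation (LLA): each outer step replaces the
penalty by a weighted L1 term at the current iterate and solves it with
FISTA proximal gradient.  The penalty scale lambda is chosen by
cross-validated misclassification error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


# ---------------------------------------------------------------------------
# Fisher-exact motif enrichment


def motif_enrichment(
    presence: pd.DataFrame,
    labels: Sequence[bool],
    fdr: float = 0.01,
) -> pd.DataFrame:
    """Two-tailed Fisher exact enrichment of each motif between classes.

    ``presence`` is a boolean regions-x-motifs matrix; ``labels`` marks the
    positive regions.  Returns one row per motif with the 2x2 counts, odds
    ratio, p, BH q and the selected flag (q < fdr).
    """
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("labels are degenerate (one class only)")
    rows = []
    for motif in presence.columns:
        present = presence[motif].to_numpy(dtype=bool)
        a = int((present & labels).sum())      # present, positive
        b = int((~present & labels).sum())     # absent, positive
        c = int((present & ~labels).sum())     # present, negative
        d = int((~present & ~labels).sum())    # absent, negative
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append((motif, a, b, c, d, odds, p))
    frame = pd.DataFrame(
        rows,
        columns=[
            "motif", "present_pos", "absent_pos", "present_neg", "absent_neg",
            "odds_ratio", "pvalue",
        ],
    )
    _, q, _, _ = multipletests(frame["pvalue"], method="fdr_bh")
    frame["qvalue"] = np.maximum(q, frame["pvalue"])
    frame["selected"] = frame["qvalue"] < fdr
    return frame.sort_values("pvalue").reset_index(drop=True)


# ---------------------------------------------------------------------------
# SCAD


def scad_penalty(w: np.ndarray, lam: float, a: float = 3.7) -> np.ndarray:
    """SCAD penalty value per coefficient (piecewise: L1, quadratic, flat)."""
    w = np.abs(np.asarray(w, dtype=float))
    p1 = lam * w
    p2 = -(w**2 - 2 * a * lam * w + lam**2) / (2 * (a - 1))
    p3 = (a + 1) * lam**2 / 2
    return np.where(w <= lam, p1, np.where(w <= a * lam, p2, p3))


def scad_derivative(w: np.ndarray, lam: float, a: float = 3.7) -> np.ndarray:
    """SCAD derivative: lam for |w|<=lam; (a*lam-|w|)+/(a-1) then; 0 beyond."""
    w = np.abs(np.asarray(w, dtype=float))
    mid = np.maximum(a * lam - w, 0.0) / (a - 1)
    return np.where(w <= lam, lam, mid)


def _squared_hinge_grad(
    X: np.ndarray, y: np.ndarray, w: np.ndarray, b: float
) -> tuple[float, np.ndarray, float]:
    """Loss, gradient wrt w, gradient wrt b of mean squared hinge."""
    margin = 1.0 - y * (X @ w + b)
    active = margin > 0
    loss = float(np.mean(np.where(active, margin, 0.0) ** 2))
    coef = np.where(active, margin, 0.0) * y
    gw = -2.0 * (X.T @ coef) / X.shape[0]
    gb = -2.0 * float(coef.sum()) / X.shape[0]
    return loss, gw, gb


def _weighted_l1_fit(
    X: np.ndarray,
    y: np.ndarray,
    penalties: np.ndarray,
    w0: np.ndarray,
    b0: float,
    max_iter: int = 500,
    tol: float = 1e-7,
) -> tuple[np.ndarray, float]:
    """FISTA on squared hinge + sum_j penalties_j * |w_j| (b unpenalized)."""
    n = X.shape[0]
    lipschitz = 2.0 * (np.linalg.norm(X, 2) ** 2 + n) / n  # includes intercept col
    step = 1.0 / lipschitz
    w, b = w0.copy(), b0
    zw, zb, t = w.copy(), b, 1.0
    for _ in range(max_iter):
        _, gw, gb = _squared_hinge_grad(X, y, zw, zb)
        w_new = zw - step * gw
        w_new = np.sign(w_new) * np.maximum(np.abs(w_new) - step * penalties, 0.0)
        b_new = zb - step * gb
        t_new = (1 + np.sqrt(1 + 4 * t * t)) / 2
        zw = w_new + (t - 1) / t_new * (w_new - w)
        zb = b_new + (t - 1) / t_new * (b_new - b)
        delta = np.max(np.abs(w_new - w)) + abs(b_new - b)
        w, b, t = w_new, b_new, t_new
        if delta < tol:
            break
    return w, b


def _fit_scad_path(
    X: np.ndarray,
    y: np.ndarray,
    lambdas: np.ndarray,
    a: float,
    lla_steps: int = 4,
) -> list[tuple[np.ndarray, float]]:
    """Warm-started SCAD fits along a decreasing lambda path."""
    d = X.shape[1]
    w, b = np.zeros(d), 0.0
    out = []
    for lam in lambdas:
        for _ in range(lla_steps):
            penalties = scad_derivative(w, lam, a) if lam > 0 else np.zeros(d)
            w, b = _weighted_l1_fit(X, y, penalties, w, b)
        out.append((w.copy(), b))
    return out


@dataclass
class ScadModel:
    """Sparse linear classifier selected by SCAD-penalized squared hinge."""

    feature_names: list[str]
    weights: np.ndarray
    intercept: float
    lam: float
    a: float
    cv_error: dict[float, float] = field(default_factory=dict)
    scaler_mean: np.ndarray | None = None
    scaler_scale: np.ndarray | None = None

    @property
    def selected(self) -> list[str]:
        return [n for n, w in zip(self.feature_names, self.weights) if w != 0.0]

    def decision(self, X: np.ndarray) -> np.ndarray:
        Z = (X - self.scaler_mean) / self.scaler_scale
        return Z @ self.weights + self.intercept


def scad_select(
    X: pd.DataFrame,
    y: Sequence[bool],
    lambdas: np.ndarray | None = None,
    a: float = 3.7,
    folds: int = 5,
    seed: int = 0,
    one_se: bool = True,
) -> ScadModel:
    """Select a sparse feature support by SCAD with CV-chosen lambda.

    ``X`` is a regions-x-features frame (k-mer frequencies); ``y`` the class
    labels.  Columns are standardized on the training data of each fold;
    lambda minimizes CV misclassification error.  With ``one_se`` (default)
    the largest lambda within one standard error of that minimum is taken —
    the usual rule for penalized paths, favouring the sparsest support whose
    error is statistically indistinguishable from the best.  The returned
    model is refit on all data at the chosen lambda.
    """
    names = list(X.columns)
    Xa = X.to_numpy(dtype=float)
    ya = np.where(np.asarray(y, dtype=bool), 1.0, -1.0)
    n, d = Xa.shape
    if lambdas is None:
        mu, sd = Xa.mean(axis=0), Xa.std(axis=0)
        sd[sd == 0] = 1.0
        Z = (Xa - mu) / sd
        lam_max = float(np.max(np.abs(Z.T @ ya)) * 2.0 / n)
        lambdas = np.geomspace(lam_max, lam_max * 1e-3, 20)
    lambdas = np.sort(np.asarray(lambdas, dtype=float))[::-1]

    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    fold_of = np.empty(n, dtype=int)
    # stratified folds
    for cls in (1.0, -1.0):
        members = order[ya[order] == cls]
        if members.size < folds:
            raise ValueError("need >= folds examples per class")
        fold_of[members] = np.arange(members.size) % folds

    errors = np.zeros((folds, lambdas.size))
    for k in range(folds):
        train, test = fold_of != k, fold_of == k
        mu = Xa[train].mean(axis=0)
        sd = Xa[train].std(axis=0)
        sd[sd == 0] = 1.0
        Ztr, Zte = (Xa[train] - mu) / sd, (Xa[test] - mu) / sd
        path = _fit_scad_path(Ztr, ya[train], lambdas, a)
        for j, (w, b) in enumerate(path):
            pred = np.sign(Zte @ w + b)
            pred[pred == 0] = 1.0
            errors[k, j] = float(np.mean(pred != ya[test]))
    mean_err = errors.mean(axis=0)
    best_j = int(np.argmin(mean_err))  # argmin takes the first = largest lambda
    if one_se:
        se = float(errors[:, best_j].std(ddof=1) / np.sqrt(folds))
        within = np.flatnonzero(mean_err <= mean_err[best_j] + se)
        best_j = int(within[0])  # largest lambda within one SE
    lam = float(lambdas[best_j])

    mu, sd = Xa.mean(axis=0), Xa.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (Xa - mu) / sd
    path = _fit_scad_path(Z, ya, lambdas[: best_j + 1], a)
    w, b = path[-1]
    return ScadModel(
        feature_names=names,
        weights=w,
        intercept=b,
        lam=lam,
        a=a,
        cv_error={float(l): float(e) for l, e in zip(lambdas, mean_err)},
        scaler_mean=mu,
        scaler_scale=sd,
    )
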