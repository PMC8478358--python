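"""Log-log allometric regression: GLS with a phylogenetic covariance, profile
maximum-likelihood estimation of Pagel's lambda, and plain OLS.

The model is the standard phylogenetic regression

    y = b0 + b1 * x + e,     e ~ N(0, sigma^2 * V(lambda))

with x and y species means on the log10 scale and V(lambda) the Brownian
covariance from the tree with off-diagonal entries scaled by lambda.  The
GLS estimate is the closed form b = (X' V^-1 X)^-1 X' V^-1 y; sigma^2 is
profiled analytically inside the lambda search, which is a bounded scalar
maximisation of the profile log-likelihood (grid pre-scan, then local
refinement to 1e-6 on lambda).

All published equations in this domain are written in log10, so every
public fit reports log10-scale slopes and intercepts; natural logs appear
only inside the Gaussian likelihood.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .errors import FitError
from .phylo import PhyloCovariance, PhyloTree, normalize_label

__all__ = [
    "AllometricFit",
    "fit_gls",
    "fit_pgls_ml_lambda",
    "fit_ols_loglog",
    "aggregate_species_means",
]

_LAMBDA_TOL = 1e-6
_BOUNDARY_SNAP = 1e-5


@dataclass(frozen=True)
class AllometricFit:
    """A fitted log10-log10 power law with its uncertainty.

    ``predict`` and ``invert`` evaluate the law on the natural measurement
    scale (e.g. cm^3 in, grams out).
    """

    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    r2: float
    adjusted_r2: float
    n: int
    log_likelihood: float
    method: str  # "PGLS" | "GLS" | "OLS"
    lam: Optional[float] = None
    lambda_at_boundary: bool = False
    response: str = "y"
    predictor: str = "x"
    x_unit: str = ""
    y_unit: str = ""

    def predict(self, x) -> np.ndarray | float:
        """Evaluate 10^(slope*log10(x) + intercept)."""
        x = np.asarray(x, dtype=float)
        if np.any(x <= 0):
            raise ValueError("power-law prediction requires positive input")
        out = 10.0 ** (self.slope * np.log10(x) + self.intercept)
        return float(out) if out.ndim == 0 else out

    def invert(self, y) -> np.ndarray | float:
        """Exact inverse of :meth:`predict` (requires non-zero slope)."""
        if self.slope == 0:
            raise FitError("cannot invert a zero-slope power law")
        y = np.asarray(y, dtype=float)
        if np.any(y <= 0):
            raise ValueError("power-law inversion requires positive input")
        out = 10.0 ** ((np.log10(y) - self.intercept) / self.slope)
        return float(out) if out.ndim == 0 else out

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "AllometricFit":
        return cls(**json.loads(text))


# ---------------------------------------------------------------------------
# core GLS machinery
# ---------------------------------------------------------------------------


def _design(table: pd.DataFrame, log10: bool) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(table["x"], dtype=float)
    y = np.asarray(table["y"], dtype=float)
    if log10:
        if np.any(x <= 0) or np.any(y <= 0):
            raise FitError("x and y must be strictly positive before log transform")
        x, y = np.log10(x), np.log10(y)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise FitError("non-finite values in trait table")
    X = np.column_stack([np.ones_like(x), x])
    return X, y


def _gls_core(X: np.ndarray, y: np.ndarray, V: np.ndarray):
    """Closed-form GLS via Cholesky whitening.

    Returns (beta, se, rss, rss_null, logdetV, n).
    """
    n, p = X.shape
    if n < 3:
        raise FitError(f"need at least 3 taxa, got {n}")
    try:
        L = linalg.cholesky(V, lower=True)
    except linalg.LinAlgError as exc:
        raise FitError(f"covariance matrix not positive definite: {exc}") from exc
    Xw = linalg.solve_triangular(L, X, lower=True)
    yw = linalg.solve_triangular(L, y, lower=True)
    XtX = Xw.T @ Xw
    if np.linalg.matrix_rank(XtX) < p:
        raise FitError("rank-deficient design (constant predictor?)")
    XtX_inv = np.linalg.inv(XtX)
    beta = XtX_inv @ (Xw.T @ yw)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    # intercept-only null model for the GLS R^2
    ones_w = Xw[:, 0]
    mu = float(ones_w @ yw) / float(ones_w @ ones_w)
    rss_null = float(((yw - ones_w * mu) ** 2).sum())
    sigma2_hat = rss / (n - p)
    se = np.sqrt(np.diag(XtX_inv) * sigma2_hat)
    logdetV = 2.0 * float(np.sum(np.log(np.diag(L))))
    return beta, se, rss, rss_null, logdetV, n


def _ml_loglik(rss: float, logdetV: float, n: int) -> float:
    """Gaussian log-likelihood with sigma^2 profiled at its ML value rss/n."""
    sigma2_ml = rss / n
    if sigma2_ml <= 0:
        # perfect fit: likelihood unbounded; report +inf and let callers flag it
        return math.inf
    return -0.5 * (n * math.log(2 * math.pi * sigma2_ml) + logdetV + n)


def _check_alignment(table: pd.DataFrame, V: PhyloCovariance) -> None:
    taxa = [normalize_label(t) for t in table["taxon"]]
    if len(set(taxa)) != len(taxa):
        raise FitError("trait table has duplicate taxa; aggregate to species means first")
    if tuple(taxa) != tuple(V.taxa):
        raise FitError(
            "trait table and covariance matrix must list identical taxa in "
            "identical order; use PhyloCovariance.subset to align them"
        )


def fit_gls(
    table: pd.DataFrame,
    V: PhyloCovariance,
    *,
    log10: bool = True,
    response: str = "y",
    predictor: str = "x",
    method: str = "GLS",
    lam: Optional[float] = None,
) -> AllometricFit:
    """GLS fit of ``y ~ x`` with a fixed covariance matrix.

    ``table`` needs columns ``taxon``, ``x``, ``y`` with rows ordered exactly
    as ``V.taxa``.  With ``log10=True`` (default) both traits are transformed
    before fitting, matching how allometries are calibrated.
    """
    _check_alignment(table, V)
    X, y = _design(table, log10)
    beta, se, rss, rss_null, logdetV, n = _gls_core(X, y, V.matrix)
    r2 = 1.0 - rss / rss_null if rss_null > 0 else 1.0
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return AllometricFit(
        slope=float(beta[1]),
        intercept=float(beta[0]),
        slope_se=float(se[1]),
        intercept_se=float(se[0]),
        r2=r2,
        adjusted_r2=adj,
        n=n,
        log_likelihood=_ml_loglik(rss, logdetV, n),
        method=method,
        lam=lam if lam is not None else V.lam,
        response=response,
        predictor=predictor,
    )


def profile_loglik(table: pd.DataFrame, base_cov: PhyloCovariance, lam: float,
                   *, log10: bool = True) -> float:
    """Profile log-likelihood of lambda (sigma^2 and beta profiled out)."""
    V = _pagel(base_cov, lam)
    X, y = _design(table, log10)
    try:
        _, _, rss, _, logdetV, n = _gls_core(X, y, V.matrix)
    except FitError:
        return -math.inf
    return _ml_loglik(rss, logdetV, n)


def _pagel(base_cov: PhyloCovariance, lam: float) -> PhyloCovariance:
    """Apply Pagel's lambda to a lambda=1 covariance (off-diagonal scaling)."""
    V = base_cov.matrix.copy()
    d = np.diag(V).copy()
    V *= lam
    np.fill_diagonal(V, d)
    return PhyloCovariance(base_cov.taxa, V, lam)


def fit_pgls_ml_lambda(
    table: pd.DataFrame,
    tree: PhyloTree,
    *,
    log10: bool = True,
    response: str = "y",
    predictor: str = "x",
    n_grid: int = 101,
) -> AllometricFit:
    """PGLS with Pagel's lambda estimated by profile maximum likelihood.

    lambda maximises the profile log-likelihood over [0, 1]: a grid pre-scan
    of ``n_grid`` points followed by bounded local refinement (tolerance 1e-6
    on lambda).  Boundary optima at exactly 0 or 1 are legal and flagged via
    ``lambda_at_boundary``.
    """
    taxa = [normalize_label(t) for t in table["taxon"]]
    if len(taxa) < 4:
        raise FitError("lambda estimation needs at least 4 taxa")
    sub = tree.prune(taxa) if set(taxa) != set(tree.tip_labels) else tree
    base = sub.covariance(1.0).subset(taxa)

    grid = np.linspace(0.0, 1.0, n_grid)
    lls = np.array([profile_loglik(table, base, g, log10=log10) for g in grid])
    if not np.any(np.isfinite(lls)):
        raise FitError(
            "profile likelihood non-finite at every grid point; check the "
            "conditioning of the phylogenetic covariance (zero branch "
            "lengths, duplicated tips?)"
        )
    best = int(np.nanargmax(np.where(np.isfinite(lls), lls, -np.inf)))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, n_grid - 1)]
    if hi > lo:
        res = optimize.minimize_scalar(
            lambda g: -profile_loglik(table, base, g, log10=log10),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": _LAMBDA_TOL},
        )
        lam_hat = float(res.x)
        if profile_loglik(table, base, lam_hat, log10=log10) < lls[best]:
            lam_hat = float(grid[best])
    else:
        lam_hat = float(grid[best])

    at_boundary = False
    if lam_hat <= _BOUNDARY_SNAP:
        lam_hat, at_boundary = 0.0, True
    elif lam_hat >= 1.0 - _BOUNDARY_SNAP:
        lam_hat, at_boundary = 1.0, True

    fit = fit_gls(
        table,
        _pagel(base, lam_hat),
        log10=log10,
        response=response,
        predictor=predictor,
        method="PGLS",
        lam=lam_hat,
    )
    return AllometricFit(**{**asdict(fit), "lambda_at_boundary": at_boundary})


# ---------------------------------------------------------------------------
# OLS and aggregation
# ---------------------------------------------------------------------------


def fit_ols_loglog(
    pairs: Sequence[tuple[float, float]] | pd.DataFrame,
    *,
    response: str = "y",
    predictor: str = "x",
) -> AllometricFit:
    """Ordinary least squares on log10-transformed positive pairs.

    Equivalent to :func:`fit_gls` with an identity covariance; used where the
    original analyses fit simple regressions (the genus-level length-to-mass
    laws, for example).
    """
    if isinstance(pairs, pd.DataFrame):
        table = pairs[["x", "y"]].copy()
    else:
        table = pd.DataFrame(pairs, columns=["x", "y"])
    if len(table) < 3:
        raise FitError(f"OLS needs at least 3 pairs, got {len(table)}")
    table.insert(0, "taxon", [f"row{i}" for i in range(len(table))])
    n = len(table)
    V = PhyloCovariance(tuple(table["taxon"]), np.eye(n), 1.0)
    fit = fit_gls(table, V, log10=True, response=response, predictor=predictor,
                  method="OLS", lam=None)
    return AllometricFit(**{**asdict(fit), "lam": None})


def aggregate_species_means(
    records: pd.DataFrame,
    x_trait: str,
    y_trait: str,
    *,
    adults_only: bool = True,
    mean_of_logs: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Collapse specimen records to one (taxon, x, y) row per species.

    Means are taken on the natural measurement scale by default (averages of
    masses, not of log-masses); set ``mean_of_logs=True`` for the geometric
    alternative.  With ``adults_only`` (default, matching how the calibrations
    restrict to adults) records whose maturity is not ``"adult"`` are dropped
    — including ``"unknown"``.  Records missing either trait are dropped and
    counted in the returned report.
    """
    df = records.copy()
    df["taxon"] = df["taxon"].map(normalize_label)
    n_total = len(df)
    if adults_only:
        maturity = df.get("maturity", pd.Series("unknown", index=df.index))
        df = df[maturity.fillna("unknown").str.lower() == "adult"]
    n_adult = len(df)
    df = df.dropna(subset=[x_trait, y_trait])
    n_complete = len(df)
    dropped_species = sorted(
        set(records["taxon"].map(normalize_label)) - set(df["taxon"])
    )
    if mean_of_logs:
        agg = df.groupby("taxon", sort=True)[[x_trait, y_trait]].agg(
            lambda v: 10 ** np.mean(np.log10(v))
        )
    else:
        agg = df.groupby("taxon", sort=True)[[x_trait, y_trait]].mean()
    table = agg.reset_index().rename(columns={x_trait: "x", y_trait: "y"})
    report = {
        "n_records": n_total,
        "n_after_maturity_filter": n_adult,
        "n_complete": n_complete,
        "n_species": len(table),
        "species_without_eligible_records": dropped_species,
    }
    return table, report
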