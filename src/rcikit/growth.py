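"""Cell-means linear mixed models on log growth rates.

One model is fitted per species x soil-country subset: no intercept, one
coefficient per cell (provenance for singly grown plants, "focal(partner)"
for plants in paired pots), a nodulation covariate, and a random intercept
for the soil collection site.

The fit profiles the REML (or ML) criterion over the single variance ratio
lambda = sigma_site^2 / sigma_resid^2, which makes the optimisation
one-dimensional and robust near the sigma_site = 0 boundary.  Given lambda,
the fixed effects are the exact GLS solution

    beta = (X' V^-1 X)^-1 X' V^-1 y,   V = sigma^2 (I + lambda Z Z')

computed group-wise via the Sherman-Morrison identity (Z is the site
indicator matrix).  Variance components are bounded at zero; the optimiser
is restarted from two brackets and the criterion is resolved to ~1e-8.
With a single site the random effect is unidentifiable and the fit
degenerates to ordinary least squares (``fitted_by == "ols_fallback"``)
with a warning.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from rcikit.errors import GrowthModelError

__all__ = [
    "GrowthFit",
    "ProvenanceTest",
    "cell_label",
    "design_matrices",
    "fit_growth_model",
    "test_provenance_effect",
]

NOD_SLOPE_LABEL = "nodulation"


def cell_label(focal: str, partner: str | float | None) -> str:
    """Cell name: bare provenance when grown alone, ``focal(partner)`` when paired."""
    if partner is None or (isinstance(partner, float) and math.isnan(partner)):
        return focal
    return f"{focal}({partner})"


@dataclass(frozen=True)
class GrowthFit:
    """A fitted cell-means mixed model.

    ``coefficients`` holds one log-scale cell mean per entry of
    ``cell_labels`` followed by the nodulation coefficient(s); cell means
    are interpretable as expected log growth rate at nodulation score 0.
    ``vcov_fixed`` is the variance-covariance matrix of the full
    coefficient vector.
    """

    cell_labels: tuple[str, ...]
    coef_labels: tuple[str, ...]
    coefficients: np.ndarray
    vcov_fixed: np.ndarray
    sigma_site_hat: float
    sigma_resid_hat: float
    loglik_reml: float
    loglik_ml: float
    n_obs: int
    fitted_by: str

    def index(self, label: str) -> int:
        try:
            return self.coef_labels.index(label)
        except ValueError:
            raise GrowthModelError(
                f"unknown cell label {label!r}; available: {list(self.coef_labels)}"
            ) from None

    def coef(self, label: str) -> float:
        return float(self.coefficients[self.index(label)])

    def summary_frame(self) -> pd.DataFrame:
        se = np.sqrt(np.diag(self.vcov_fixed))
        return pd.DataFrame(
            {"label": self.coef_labels, "estimate": self.coefficients, "se": se}
        )


@dataclass(frozen=True)
class ProvenanceTest:
    """Test of a provenance effect on singly grown plants."""

    statistic: float
    df_num: int
    df_den: int | None
    p_value: float
    method: str


# ---------------------------------------------------------------------------
# profiled likelihood core


class _Core:
    """Group-wise sufficient statistics for the profiled criterion."""

    def __init__(self, X: np.ndarray, y: np.ndarray, groups: np.ndarray):
        self.X, self.y = X, y
        self.n, self.p = X.shape
        codes, _ = pd.factorize(groups, sort=True)
        self.n_groups = codes.max() + 1
        self.sizes = np.bincount(codes).astype(float)
        # per-group sums of rows of X and of y
        self.Sx = np.zeros((self.n_groups, self.p))
        np.add.at(self.Sx, codes, X)
        self.Sy = np.bincount(codes, weights=y)
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.codes = codes

    def gls(self, lam: float):
        """GLS pieces at variance ratio lam: A=X'WX, b=X'Wy, beta, q=r'Wr, logdet."""
        c = lam / (1.0 + lam * self.sizes)  # per-group shrinkage weight
        A = self.XtX - (self.Sx * c[:, None]).T @ self.Sx
        b = self.Xty - self.Sx.T @ (c * self.Sy)
        try:
            beta = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            raise GrowthModelError("singular design matrix (collinear cells)") from None
        r = self.y - self.X @ beta
        Sr = np.bincount(self.codes, weights=r, minlength=self.n_groups)
        q = float(r @ r - c @ Sr**2)
        logdet = float(np.sum(np.log1p(lam * self.sizes)))
        return A, beta, q, logdet

    def neg2_reml(self, lam: float) -> float:
        A, _, q, logdet = self.gls(lam)
        dof = self.n - self.p
        s2 = max(q / dof, 1e-300)
        sign, logdetA = np.linalg.slogdet(A)
        if sign <= 0:
            return np.inf
        return dof * (math.log(2 * math.pi * s2) + 1.0) + logdet + logdetA

    def neg2_ml(self, lam: float) -> float:
        _, _, q, logdet = self.gls(lam)
        s2 = max(q / self.n, 1e-300)
        return self.n * (math.log(2 * math.pi * s2) + 1.0) + logdet


def _optimize_lambda(core: _Core, criterion: str) -> float:
    fun = core.neg2_reml if criterion == "reml" else core.neg2_ml
    if core.n_groups == 1:
        return 0.0
    best_u, best_val = None, fun(0.0)  # sigma_site = 0 boundary
    # two restart brackets on log(lambda) guard against local minima
    for lo, hi in ((-18.0, -1.0), (-4.0, 8.0)):
        res = optimize.minimize_scalar(
            lambda u: fun(math.exp(u)),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-10},
        )
        if res.fun < best_val - 1e-12:
            best_u, best_val = res.x, res.fun
    return 0.0 if best_u is None else math.exp(best_u)


def _fit_core(X: np.ndarray, y: np.ndarray, groups: np.ndarray):
    """REML point estimates plus ML log-likelihood at its own optimum."""
    core = _Core(X, y, groups)
    if core.p >= core.n:
        raise GrowthModelError(f"{core.p} coefficients for only {core.n} observations")

    lam_reml = _optimize_lambda(core, "reml")
    A, beta, q, _ = core.gls(lam_reml)
    dof = core.n - core.p
    s2 = q / dof
    vcov = s2 * np.linalg.inv(A)
    vcov = 0.5 * (vcov + vcov.T)
    loglik_reml = -0.5 * core.neg2_reml(lam_reml)

    lam_ml = _optimize_lambda(core, "ml")
    loglik_ml = -0.5 * core.neg2_ml(lam_ml)

    sigma_resid = math.sqrt(max(s2, 0.0))
    sigma_site = math.sqrt(lam_reml * max(s2, 0.0))
    return beta, vcov, sigma_site, sigma_resid, loglik_reml, loglik_ml


# ---------------------------------------------------------------------------
# model assembly


def design_matrices(
    records: pd.DataFrame,
    include_paired: bool = True,
    nod_as_factor: bool = False,
    include_nodulation: bool = True,
) -> tuple[np.ndarray, np.ndarray, tuple[str, ...], tuple[str, ...], np.ndarray]:
    """Build (X, y, cell_labels, coef_labels, groups) for the cell-means model.

    Exposed so independent oracles (e.g. a brute-force GLS solve) can reuse
    exactly the same design matrix.
    """
    df = records if include_paired else records[records["treatment"] == "single"]
    if df.empty:
        raise GrowthModelError("no observations")
    labels_series = [
        cell_label(f, p)
        for f, p in zip(df["focal_provenance"], df["partner_provenance"])
    ]
    singles = sorted({l for l in labels_series if "(" not in l})
    paired = sorted({l for l in labels_series if "(" in l})
    cell_labels = tuple(singles + paired)
    cell_idx = {l: i for i, l in enumerate(cell_labels)}
    n = len(df)
    X_cells = np.zeros((n, len(cell_labels)))
    X_cells[np.arange(n), [cell_idx[l] for l in labels_series]] = 1.0
    nod = df["nodulation_score"].to_numpy(dtype=float)
    if not include_nodulation:
        X_nod = np.empty((n, 0))
        nod_labels: tuple[str, ...] = ()
    elif nod_as_factor:
        levels = [1, 2, 3]  # score 0 is the reference level
        X_nod = np.column_stack([(nod == lv).astype(float) for lv in levels])
        nod_labels = tuple(f"{NOD_SLOPE_LABEL}_{lv}" for lv in levels)
        keep = X_nod.any(axis=0)
        X_nod = X_nod[:, keep]
        nod_labels = tuple(l for l, k in zip(nod_labels, keep) if k)
    else:
        X_nod = nod[:, None]
        nod_labels = (NOD_SLOPE_LABEL,)
    X = np.hstack([X_cells, X_nod])
    y = np.log(df["growth_rate"].to_numpy(dtype=float))
    groups = df["soil_site"].to_numpy()
    return X, y, cell_labels, cell_labels + nod_labels, groups


def fit_growth_model(
    records: pd.DataFrame,
    include_paired: bool = True,
    nod_as_factor: bool = False,
    include_nodulation: bool = True,
    expected_cells: tuple[str, ...] | None = None,
) -> GrowthFit:
    """Fit the no-intercept cell-means mixed model for one species x soil.

    Parameters
    ----------
    records
        Plant records, all sharing one species and one soil country.
    include_paired
        If False, only singly grown plants enter the model.
    nod_as_factor
        Code the nodulation score as a 4-level factor instead of a numeric
        covariate.
    expected_cells
        Optional cells that must be present; a missing one raises a
        :class:`GrowthModelError` naming it.
    """
    for col in ("species", "soil_country"):
        if records[col].nunique() != 1:
            raise GrowthModelError(f"records span multiple values of {col}; fit one subset at a time")
    X, y, cell_labels, coef_labels, groups = design_matrices(
        records,
        include_paired=include_paired,
        nod_as_factor=nod_as_factor,
        include_nodulation=include_nodulation,
    )
    if expected_cells is not None:
        missing = [c for c in expected_cells if c not in cell_labels]
        if missing:
            raise GrowthModelError(f"no observations for cell(s) {missing}")

    n_sites = len(np.unique(groups))
    if n_sites == 1:
        warnings.warn(
            "only one soil site present; site random effect is unidentifiable, "
            "falling back to ordinary least squares",
            UserWarning,
            stacklevel=2,
        )
        beta, vcov, s_site, s_resid, ll_reml, ll_ml = _fit_core(X, y, groups)
        fitted_by = "ols_fallback"
    else:
        beta, vcov, s_site, s_resid, ll_reml, ll_ml = _fit_core(X, y, groups)
        fitted_by = "reml_mixed"
    return GrowthFit(
        cell_labels=cell_labels,
        coef_labels=coef_labels,
        coefficients=beta,
        vcov_fixed=vcov,
        sigma_site_hat=s_site,
        sigma_resid_hat=s_resid,
        loglik_reml=ll_reml,
        loglik_ml=ll_ml,
        n_obs=len(y),
        fitted_by=fitted_by,
    )


def _ml_loglik(X: np.ndarray, y: np.ndarray, groups: np.ndarray) -> float:
    core = _Core(X, y, groups)
    return -0.5 * core.neg2_ml(_optimize_lambda(core, "ml"))


def test_provenance_effect(
    records: pd.DataFrame, method: str = "lrt_ml", nod_as_factor: bool = False
) -> ProvenanceTest:
    """Test whether singly grown provenances differ in mean log growth rate.

    The primary test compares maximum-likelihood fits of the model with and
    without the provenance factor (nodulation covariate and site random
    effect retained in both) via a chi-square likelihood ratio.  An
    approximate F (Wald contrast on the REML fit, residual-df denominator)
    is available for comparability with ANOVA-style output.
    """
    singles = records[records["treatment"] == "single"]
    provenances = sorted(singles["focal_provenance"].unique())
    k = len(provenances)
    if k < 2:
        raise GrowthModelError("need at least two provenances to test a provenance effect")

    X_full, y, _, coef_labels, groups = design_matrices(
        singles, include_paired=False, nod_as_factor=nod_as_factor
    )
    df_num = k - 1
    p_full = X_full.shape[1]
    n = len(y)

    if method == "lrt_ml":
        X_red = np.hstack([np.ones((n, 1)), X_full[:, k:]])  # intercept + nodulation
        ll_full = _ml_loglik(X_full, y, groups)
        ll_red = _ml_loglik(X_red, y, groups)
        stat = max(2.0 * (ll_full - ll_red), 0.0)
        p = float(stats.chi2.sf(stat, df_num))
        return ProvenanceTest(stat, df_num, None, p, "lrt_ml")
    if method == "approx_f":
        fit = fit_growth_model(singles, include_paired=False, nod_as_factor=nod_as_factor)
        C = np.zeros((df_num, len(fit.coefficients)))
        for i in range(df_num):  # successive differences between cell means
            C[i, i], C[i, i + 1] = 1.0, -1.0
        d = C @ fit.coefficients
        M = C @ fit.vcov_fixed @ C.T
        wald = float(d @ np.linalg.solve(M, d))
        df_den = n - p_full
        f_stat = wald / df_num
        p = float(stats.f.sf(f_stat, df_num, df_den))
        return ProvenanceTest(f_stat, df_num, df_den, p, "approx_f")
    raise GrowthModelError(f"unknown test method {method!r}")


test_provenance_effect.__test__ = False  # not a pytest test, despite the name
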