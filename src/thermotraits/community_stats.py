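"""Community-level trait statistics.

Statistical analyses run on the per-isolate trait table:

* sorting regression — does the thermal optimum of growth track the
  temperature a community was sorted at, and is the relationship curved
  (isolates from cold treatments sitting above the 1:1 line)?  Nested
  OLS comparison of a quadratic against a straight line via an F-test;
* trait PCA on standardized life-history traits (Topt, niche width,
  peak growth and respiration rates, log ATP content, carrying
  capacity), to expose r- versus K-strategist structure;
* power-law (log-log OLS) scaling of ATP content with respiration rate,
  fitted per phylum;
* Wilcoxon rank-sum contrasts of (optionally Arrhenius temperature-
  corrected) rates between phyla.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from thermotraits.tpc_fitting import arrhenius_correct

logger = logging.getLogger(__name__)

__all__ = [
    "ModelComparison",
    "PCAResult",
    "PowerLawFit",
    "RankSumResult",
    "quadratic_vs_linear",
    "pca_traits",
    "powerlaw_fit",
    "rank_sum_test",
    "phylum_summary",
]


@dataclass
class ModelComparison:
    """Nested OLS comparison: straight line versus quadratic."""

    rss_linear: float
    rss_quadratic: float
    f_statistic: float
    df: tuple[int, int]
    p_value: float
    coef_linear: np.ndarray  # (intercept, slope)
    coef_quadratic: np.ndarray  # (intercept, slope, curvature)
    r_squared_linear: float
    r_squared_quadratic: float
    n: int

    @property
    def prefers_quadratic(self) -> bool:
        return self.p_value < 0.05


@dataclass
class PCAResult:
    variables: list[str]
    loadings: np.ndarray  # variables x components
    explained_variance_fraction: np.ndarray
    scores: pd.DataFrame  # isolates x components
    means: np.ndarray
    sds: np.ndarray


@dataclass
class PowerLawFit:
    exponent: float
    exponent_se: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


@dataclass
class RankSumResult:
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    alternative: str
    method: str  # "exact" or "asymptotic"


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError("collinear design matrix")
    rss = float(np.sum((y - X @ coef) ** 2))
    return coef, rss


def quadratic_vs_linear(x, y) -> ModelComparison:
    """Compare y = a + b x against y = a + b x + c x^2 with a nested F-test.

    F = (RSS_lin - RSS_quad) / (RSS_quad / (n - 3)) on (1, n - 3) df.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("at least 4 points required")
    if np.ptp(x) == 0:
        raise ValueError("x values must not all be equal")
    X1 = np.column_stack([np.ones(n), x])
    X2 = np.column_stack([np.ones(n), x, x**2])
    coef1, rss1 = _ols(X1, y)
    coef2, rss2 = _ols(X2, y)
    tss = float(np.sum((y - y.mean()) ** 2))
    df2 = n - 3
    if rss2 <= 0:
        f = math.inf
        p = 0.0
    else:
        f = (rss1 - rss2) / (rss2 / df2)
        f = max(f, 0.0)
        p = float(stats.f.sf(f, 1, df2))
    return ModelComparison(
        rss_linear=rss1,
        rss_quadratic=rss2,
        f_statistic=f,
        df=(1, df2),
        p_value=p,
        coef_linear=coef1,
        coef_quadratic=coef2,
        r_squared_linear=1 - rss1 / tss if tss > 0 else math.nan,
        r_squared_quadratic=1 - rss2 / tss if tss > 0 else math.nan,
        n=n,
    )


#: default PCA inputs: the six life-history traits
DEFAULT_PCA_VARIABLES = [
    "topt",
    "niche_width",
    "mu_max",
    "r_max",
    "log_atp",
    "carrying_capacity",
]


def pca_traits(
    table: pd.DataFrame, variables: list[str] | None = None
) -> PCAResult:
    """PCA of the trait table with variables scaled to mean 0, SD 1.

    Rows with any missing value in the selected variables are dropped.
    Loadings follow a deterministic sign convention: within each
    component, the entry of largest magnitude is made positive.
    """
    variables = list(variables or DEFAULT_PCA_VARIABLES)
    if len(variables) < 2:
        raise ValueError("at least 2 variables required")
    missing_cols = [v for v in variables if v not in table.columns]
    if missing_cols:
        raise ValueError(f"missing columns: {', '.join(missing_cols)}")
    data = table[variables].dropna()
    if len(data) < 3:
        raise ValueError("at least 3 complete rows required")
    X = data.to_numpy(dtype=float)
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    zero_var = [v for v, s in zip(variables, sds) if s == 0]
    if zero_var:
        raise ValueError(f"zero-variance variable(s): {', '.join(zero_var)}")
    Z = (X - means) / sds
    u, s, vt = np.linalg.svd(Z, full_matrices=False)
    loadings = vt.T  # variables x components, orthonormal columns
    # deterministic signs: largest-|loading| entry of each component positive
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            u[:, j] *= -1
    var = s**2
    frac = var / var.sum()
    scores = pd.DataFrame(
        u * s,
        index=data.index,
        columns=[f"PC{j + 1}" for j in range(len(s))],
    )
    return PCAResult(
        variables=variables,
        loadings=loadings,
        explained_variance_fraction=frac,
        scores=scores,
        means=means,
        sds=sds,
    )


def powerlaw_fit(x, y) -> PowerLawFit:
    """Fit y = c * x^b by OLS of log10(y) on log10(x).

    The slope b is the scaling exponent; its standard error comes from the
    simple-regression closed form.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    bad = np.flatnonzero((x <= 0) | (y <= 0) | ~np.isfinite(x) | ~np.isfinite(y))
    if bad.size:
        raise ValueError(
            f"non-positive or non-finite values at rows: {bad.tolist()[:10]}"
        )
    if len(x) < 3:
        raise ValueError("at least 3 points required")
    lx, ly = np.log10(x), np.log10(y)
    res = stats.linregress(lx, ly)
    return PowerLawFit(
        exponent=float(res.slope),
        exponent_se=float(res.stderr),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=len(x),
    )


#: largest pooled sample for which the exact rank-sum null is enumerated
EXACT_RANKSUM_LIMIT = 12


def rank_sum_test(a, b, alternative: str = "two-sided") -> RankSumResult:
    """Wilcoxon rank-sum (Mann-Whitney) test.

    Small untied samples (pooled n <= 12) use exact enumeration of the
    null; larger or tied samples use the normal approximation with tie
    and continuity corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    if no_ties and len(pooled) <= EXACT_RANKSUM_LIMIT:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative=alternative,
        method="exact" if method == "exact" else "asymptotic",
        use_continuity=True,
    )
    return RankSumResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        n_a=len(a),
        n_b=len(b),
        alternative=alternative,
        method=method,
    )


@dataclass
class PhylumContrast:
    trait: str
    phylum_a: str
    phylum_b: str
    median_a: float
    median_b: float
    test: RankSumResult
    stars: str


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def phylum_summary(
    table: pd.DataFrame,
    traits: list[str] | None = None,
    correct_to: float | None = None,
    activation_energy: float = 0.61,
    rate_traits: tuple[str, ...] = ("mu_max", "r_max"),
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """Pairwise phylum contrasts of traits by rank-sum tests.

    When ``correct_to`` is given, rate traits are Arrhenius-corrected from
    each isolate's Topt to the target temperature (degC) before testing.
    Returns a tidy frame with one row per trait per phylum pair; no
    multiple-testing correction is applied, but the number of tests run is
    recorded on ``DataFrame.attrs["n_tests"]``.
    """
    traits = list(traits or ["mu_max", "r_max", "log_atp", "carrying_capacity"])
    if "phylum" not in table.columns:
        raise ValueError("table must have a 'phylum' column")
    phyla = sorted(table["phylum"].dropna().unique())
    if len(phyla) < 2:
        raise ValueError("at least 2 phyla required for contrasts")

    work = table.copy()
    if correct_to is not None and activation_energy != 0.0:
        for trait in rate_traits:
            if trait in work.columns:
                work[trait] = [
                    arrhenius_correct(r, t_obs, correct_to, activation_energy)
                    if r > 0 and np.isfinite(r)
                    else r
                    for r, t_obs in zip(work[trait], work["topt"])
                ]

    rows = []
    for trait in traits:
        if trait not in work.columns:
            logger.warning("trait %s absent from table; skipped", trait)
            continue
        for pa, pb in itertools.combinations(phyla, 2):
            va = work.loc[work["phylum"] == pa, trait].dropna()
            vb = work.loc[work["phylum"] == pb, trait].dropna()
            if len(va) == 0 or len(vb) == 0:
                continue
            test = rank_sum_test(va, vb, alternative=alternative)
            rows.append({
                "trait": trait,
                "phylum_a": pa,
                "phylum_b": pb,
                "median_a": float(va.median()),
                "median_b": float(vb.median()),
                "n_a": test.n_a,
                "n_b": test.n_b,
                "statistic": test.statistic,
                "p_value": test.p_value,
                "stars": _stars(test.p_value),
            })
    out = pd.DataFrame(rows)
    out.attrs["n_tests"] = len(rows)
    return out
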