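"""Statistical layer: exact and asymptotic tests, regression, ellipses.

Conventions used throughout the imaging analyses:

* Fisher's exact test is two-sided by the point-probability rule (sum of
  hypergeometric probabilities of all tables, at fixed margins, no more
  probable than the observed one).
* Chi-square tests of independence carry no Yates continuity correction, so
  the 2x2 statistic equals the closed form ``n(ad-bc)^2 / (row and column
  margin product)``.
* Group comparisons use the pooled-variance (Student) unpaired t-test;
  Welch is available by flag.
* Simple linear regression reports R^2 with conventional strength tiers:
  >= 0.75 substantial, >= 0.50 moderate, >= 0.25 weak, else below-weak.
* Confidence ellipses are data ellipses: sample mean and covariance with
  semi-axes scaled by the chi-square(2) quantile at the coverage level, so
  they enclose the stated fraction of the generating population.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .proximity import INTERSTITIAL, PERIVASCULAR
from .types import ValidationError

logger = logging.getLogger(__name__)

#: Preset significance level for cluster-frequency comparisons.
CLUSTER_ALPHA = 0.0025

R2_TIERS = ((0.75, "substantial"), (0.50, "moderate"), (0.25, "weak"))


class DegenerateEllipseError(ValueError):
    """Raised for collinear point sets with a singular covariance."""


# ---------------------------------------------------------------------------
# Contingency tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 counts; rows = genotype, columns = outcome."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in cells):
            raise ValidationError("2x2 cells must be non-negative integers")
        if sum(cells) == 0:
            raise ValidationError("table is empty")

    def to_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


def fisher_exact_2x2(table: ContingencyTable2x2 | np.ndarray) -> float:
    """Two-sided Fisher exact p-value (point-probability rule)."""
    arr = table.to_array() if isinstance(table, ContingencyTable2x2) else np.asarray(table)
    if arr.shape != (2, 2) or np.any(arr < 0):
        raise ValidationError("need a 2x2 table of non-negative counts")
    _, p = sps.fisher_exact(arr, alternative="two-sided")
    return float(p)


@dataclass
class ChiSquareResult:
    chi2: float
    df: int
    p_value: float
    expected: np.ndarray
    alpha: float
    row_significant: np.ndarray  # per-row flags at alpha (row vs rest 2x2)


def chi_square_independence(
    counts: np.ndarray, alpha: float = 0.05
) -> ChiSquareResult:
    """Uncorrected chi-square test of independence on a K x 2 (or K x C) table.

    Per-row significance flags come from an uncorrected 2x2 chi-square of
    each row against the pooled remaining rows, evaluated at ``alpha`` —
    the per-cluster comparison pattern used with the 0.0025 preset.

    Raises on zero margins; warns when any expected count is below 5.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValidationError("need a table with >= 2 rows and >= 2 columns")
    if np.any(counts < 0):
        raise ValidationError("counts must be non-negative")
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise ValidationError("table has a zero margin")
    if not 0 < alpha < 1:
        raise ValidationError("alpha must lie in (0, 1)")

    chi2, p, df, expected = sps.chi2_contingency(counts, correction=False)
    if np.any(expected < 5):
        warnings.warn(
            "chi-square expected count < 5; asymptotic p-value may be unreliable",
            stacklevel=2,
        )
    flags = np.zeros(counts.shape[0], dtype=bool)
    for i in range(counts.shape[0]):
        rest = counts.sum(axis=0) - counts[i]
        sub = np.vstack([counts[i], rest])
        if np.any(sub.sum(axis=0) == 0) or np.any(sub.sum(axis=1) == 0):
            continue
        _, p_i, _, _ = sps.chi2_contingency(sub, correction=False)
        flags[i] = p_i < alpha
    return ChiSquareResult(
        chi2=float(chi2), df=int(df), p_value=float(p),
        expected=expected, alpha=alpha, row_significant=flags,
    )


# ---------------------------------------------------------------------------
# t-test
# ---------------------------------------------------------------------------

def t_test_unpaired(
    group_a: np.ndarray, group_b: np.ndarray, welch: bool = False
) -> tuple[float, float, float]:
    """Two-sided unpaired t-test; pooled-variance Student form by default.

    Returns ``(t, df, p)``. Degenerate zero-variance inputs: equal means give
    ``(0, df, 1)``; unequal means give ``(+/-inf, df, 0)`` with a warning.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs n >= 2")
    df = a.size + b.size - 2 if not welch else None
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        dfv = float(a.size + b.size - 2)
        if a.mean() == b.mean():
            return 0.0, dfv, 1.0
        warnings.warn("zero variance with unequal means: p = 0", stacklevel=2)
        return float(np.inf if a.mean() > b.mean() else -np.inf), dfv, 0.0
    res = sps.ttest_ind(a, b, equal_var=not welch)
    dfv = float(res.df) if welch else float(a.size + b.size - 2)
    return float(res.statistic), dfv, float(res.pvalue)


# ---------------------------------------------------------------------------
# Regression
# ---------------------------------------------------------------------------

@dataclass
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float
    n: int
    strength_label: str


def r2_strength_label(r_squared: float) -> str:
    """Conventional correlation-strength tier for an R^2 value."""
    for cut, label in R2_TIERS:
        if r_squared >= cut:
            return label
    return "below-weak"


def linear_regression(x: np.ndarray, y: np.ndarray) -> RegressionFit:
    """Ordinary least squares of y on x with R^2 and a strength tier."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("need >= 3 (x, y) pairs")
    if np.ptp(x) == 0:
        raise ValidationError("x is constant; regression undefined")
    res = sps.linregress(x, y)
    r2 = float(res.rvalue**2)
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        n=int(x.size),
        strength_label=r2_strength_label(r2),
    )


# ---------------------------------------------------------------------------
# Confidence ellipse
# ---------------------------------------------------------------------------

@dataclass
class ConfidenceEllipse:
    """Data ellipse: mean +/- covariance eigen-axes scaled to a coverage."""

    center: np.ndarray
    covariance: np.ndarray
    coverage: float = 0.95
    semi_axes: np.ndarray = field(init=False)
    axes_directions: np.ndarray = field(init=False)  # columns = unit eigenvectors

    def __post_init__(self) -> None:
        if not 0 < self.coverage < 1:
            raise ValidationError("coverage must lie in (0, 1)")
        cov = np.asarray(self.covariance, dtype=float)
        if cov.shape != (2, 2) or not np.allclose(cov, cov.T):
            raise ValidationError("covariance must be symmetric 2x2")
        evals, evecs = np.linalg.eigh(cov)
        if evals[0] <= 1e-12 * max(evals[1], 1.0):
            raise DegenerateEllipseError("points are (nearly) collinear")
        q = sps.chi2.ppf(self.coverage, df=2)
        self.semi_axes = np.sqrt(evals * q)
        self.axes_directions = evecs

    def polygon(self, n: int = 256) -> np.ndarray:
        """(n, 2) boundary polyline for plotting."""
        theta = np.linspace(0.0, 2.0 * np.pi, n)
        unit = np.column_stack([np.cos(theta), np.sin(theta)])
        return self.center + (unit * self.semi_axes) @ self.axes_directions.T

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of points with Mahalanobis^2 <= the coverage quantile."""
        pts = np.atleast_2d(np.asarray(points, dtype=float)) - self.center
        q = sps.chi2.ppf(self.coverage, df=2)
        inv = np.linalg.inv(self.covariance)
        m2 = np.einsum("ij,jk,ik->i", pts, inv, pts)
        return m2 <= q


def confidence_ellipse(points: np.ndarray, coverage: float = 0.95) -> ConfidenceEllipse:
    """Data ellipse of a 2-D point cloud at the given coverage."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValidationError("need >= 3 points of dimension 2")
    center = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False)
    return ConfidenceEllipse(center=center, covariance=cov, coverage=coverage)


# ---------------------------------------------------------------------------
# Cohort-level proximity report
# ---------------------------------------------------------------------------

def proximity_shift_report(
    summaries: pd.DataFrame,
    threshold_px: float,
    *,
    fields: pd.DataFrame | None = None,
    alpha: float = 0.05,
    control_genotype: str = "control",
) -> dict:
    """Machine-readable redistribution report for a two-genotype cohort.

    Joins the per-image proximity summaries into: per-genotype object-count
    and fluorescence-area class proportions, a chi-square test on the
    perivascular/interstitial count table, and image- and specimen-level
    t-tests on mean nearest-neighbor distance (plus normalized-GFP t-test
    when a normalized fields table is supplied).
    """
    genotypes = sorted(summaries["genotype"].unique(),
                       key=lambda g: (g != control_genotype, g))
    if len(genotypes) != 2:
        raise ValidationError("report requires exactly two genotypes")

    per_geno = {}
    count_table = []
    for g in genotypes:
        sub = summaries[summaries["genotype"] == g]
        n_peri = int(sub["n_perivascular"].sum())
        n_inter = int(sub["n_interstitial"].sum())
        a_peri = int(sub["perivascular_area_px"].sum())
        a_inter = int(sub["interstitial_area_px"].sum())
        per_geno[g] = {
            "n_images": int(len(sub)),
            "n_gfp_objects": n_peri + n_inter,
            "n_perivascular": n_peri,
            "n_interstitial": n_inter,
            "perivascular_count_fraction": n_peri / max(n_peri + n_inter, 1),
            "perivascular_area_fraction": a_peri / max(a_peri + a_inter, 1),
            "mean_nn_distance_px_by_image": float(sub["mean_nn_distance_px"].mean()),
        }
        count_table.append([n_peri, n_inter])

    chi = chi_square_independence(np.asarray(count_table).T, alpha=alpha)

    def group_values(level: str) -> tuple[np.ndarray, np.ndarray]:
        if level == "image":
            vals = summaries.set_index("genotype")["mean_nn_distance_px"]
            return (vals.loc[[genotypes[0]]].to_numpy(),
                    vals.loc[[genotypes[1]]].to_numpy())
        by_spec = summaries.groupby(["genotype", "specimen_id"])[
            "mean_nn_distance_px"
        ].mean()
        return (by_spec.loc[genotypes[0]].to_numpy(),
                by_spec.loc[genotypes[1]].to_numpy())

    tests = {}
    for level in ("image", "specimen"):
        a, b = group_values(level)
        if len(a) >= 2 and len(b) >= 2:
            t, df, p = t_test_unpaired(a, b)
            tests[f"nn_distance_t_test_{level}"] = {
                "t": t, "df": df, "p": p,
                "n": [int(len(a)), int(len(b))],
            }
    if fields is not None and "normalized_gfp" in fields:
        fa = fields[(fields["genotype"] == genotypes[0]) & fields["valid"]]
        fb = fields[(fields["genotype"] == genotypes[1]) & fields["valid"]]
        t, df, p = t_test_unpaired(
            fa["normalized_gfp"].to_numpy(), fb["normalized_gfp"].to_numpy()
        )
        tests["normalized_gfp_t_test_image"] = {
            "t": t, "df": df, "p": p, "n": [int(len(fa)), int(len(fb))],
            "group_means": [float(fa["normalized_gfp"].mean()),
                            float(fb["normalized_gfp"].mean())],
        }

    return {
        "threshold_px": float(threshold_px),
        "genotypes": list(genotypes),
        "per_genotype": per_geno,
        "class_count_table": {
            "rows": [PERIVASCULAR, INTERSTITIAL],
            "columns": list(genotypes),
            "counts": np.asarray(count_table).T.tolist(),
        },
        "chi_square": {
            "chi2": chi.chi2, "df": chi.df, "p": chi.p_value,
            "alpha": alpha, "significant": bool(chi.p_value < alpha),
        },
        "t_tests": tests,
    }


def tidy_results(report: dict) -> pd.DataFrame:
    """Flatten a redistribution report into a tidy test-results table."""
    rows = [
        {
            "test": "chi_square_class_counts",
            "statistic": report["chi_square"]["chi2"],
            "df": report["chi_square"]["df"],
            "p": report["chi_square"]["p"],
            "n": sum(sum(r) for r in report["class_count_table"]["counts"]),
            "groups": "|".join(report["genotypes"]),
        }
    ]
    for name, res in report["t_tests"].items():
        rows.append(
            {"test": name, "statistic": res["t"], "df": res["df"],
             "p": res["p"], "n": sum(res["n"]),
             "groups": "|".join(report["genotypes"])}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Plot helpers (optional outputs)
# ---------------------------------------------------------------------------

def plot_scatter_with_ellipses(
    pairs: pd.DataFrame, path: str, coverage: float = 0.95
) -> None:
    """Scatter of (CD109 area, GFP area) per field with per-genotype data
    ellipses."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for genotype, sub in pairs.groupby("genotype"):
        x = sub["cd109_area_px"].to_numpy(float)
        y = sub["gfp_area_px"].to_numpy(float)
        ax.scatter(x, y, s=12, label=str(genotype))
        if len(sub) >= 3:
            try:
                ell = confidence_ellipse(np.column_stack([x, y]), coverage)
                poly = ell.polygon()
                ax.plot(poly[:, 0], poly[:, 1], lw=1)
            except DegenerateEllipseError:
                logger.warning("ellipse skipped for %s: collinear points", genotype)
    ax.set_xlabel("CD109+ area (px)")
    ax.set_ylabel("GFP+ area (px)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_class_proportions(report: dict, path: str) -> None:
    """Stacked perivascular/interstitial count-proportion bars per genotype."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    genotypes = report["genotypes"]
    peri = [report["per_genotype"][g]["perivascular_count_fraction"] for g in genotypes]
    inter = [1.0 - p for p in peri]
    fig, ax = plt.subplots(figsize=(3.5, 4))
    ax.bar(genotypes, peri, color="black", label=PERIVASCULAR)
    ax.bar(genotypes, inter, bottom=peri, color="gray", label=INTERSTITIAL)
    ax.set_ylabel("fraction of GFP+ objects")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
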