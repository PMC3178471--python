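"""Power-law exponent estimation at a bifurcation and over a cohort.

The junction exponent n of a bifurcation with parent radius r_cca and
daughter radii r_ica, r_eca is the solution of

    r_cca^n = r_ica^n + r_eca^n

n = 2 preserves cross-sectional area through the junction; n = 3 is the
minimum-work (Murray) optimum.  Two cohort estimators are provided, since
they weight the data differently and need not agree on noisy cohorts:

* per-bifurcation root finding followed by averaging, and
* nonlinear least squares over a single shared exponent (Gauss-Newton
  with step halving), in two model forms.

Cohort tables are pandas DataFrames with columns ``subject_id``, ``side``,
``r_cca_mm``, ``r_ica_mm``, ``r_eca_mm`` and optionally ``ica_tortuosity``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "solve_exponent",
    "solve_exponent_records",
    "RegressionFit",
    "fit_cohort_exponent",
    "IndividualExponentSummary",
    "mean_individual_exponent",
    "ica_adjustment",
    "RatioSummary",
    "summarize_ratios",
    "PairedSideComparison",
    "compare_sides",
    "filter_low_tortuosity",
]

RADIUS_COLUMNS = ["r_cca_mm", "r_ica_mm", "r_eca_mm"]


# ---------------------------------------------------------------------------
# per-bifurcation root finding
# ---------------------------------------------------------------------------

def solve_exponent(
    r_cca: float,
    r_ica: float,
    r_eca: float,
    bracket: tuple[float, float] = (0.05, 50.0),
    tol: float = 1e-10,
) -> tuple[float, str]:
    """Solve r_cca^n = r_ica^n + r_eca^n for n by bracketing root finding.

    Writing a = r_ica/r_cca and e = r_eca/r_cca, the function
    g(n) = a^n + e^n - 1 is strictly decreasing for a, e in (0, 1) with
    g(0) = 1 and limit -1, so the positive root is unique.  If either
    daughter is at least as large as the parent, g never crosses zero from
    above and there is no positive root.

    Returns ``(n, "ok")``, ``(nan, "no_root")`` when a daughter >= parent,
    or ``(nan, "out_of_bracket")`` when the root lies outside ``bracket``.
    Scale-invariant: only the two radius ratios enter.
    """
    if min(r_cca, r_ica, r_eca) <= 0:
        raise ValueError("all radii must be > 0")
    a = r_ica / r_cca
    e = r_eca / r_cca
    if a >= 1.0 or e >= 1.0:
        return math.nan, "no_root"

    def g(n: float) -> float:
        return a**n + e**n - 1.0

    lo, hi = bracket
    if g(lo) < 0 or g(hi) > 0:
        return math.nan, "out_of_bracket"
    n = optimize.brentq(g, lo, hi, xtol=tol, rtol=8.9e-16)
    return float(n), "ok"


def solve_exponent_records(records: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Return a copy of the cohort table with ``n`` and ``solve_status`` columns."""
    out = records.copy()
    sols = [
        solve_exponent(row.r_cca_mm, row.r_ica_mm, row.r_eca_mm, **kwargs)
        for row in out.itertuples()
    ]
    out["n"] = [s[0] for s in sols]
    out["solve_status"] = [s[1] for s in sols]
    return out


# ---------------------------------------------------------------------------
# cohort nonlinear regression
# ---------------------------------------------------------------------------

@dataclass
class RegressionFit:
    """Result of the shared-exponent nonlinear least-squares fit."""

    n_hat: float
    ci95: tuple[float, float]
    n_obs: int
    model_form: str
    converged: bool
    n_iter: int
    sse: float

    def __post_init__(self) -> None:
        if self.converged and not (self.ci95[0] <= self.n_hat <= self.ci95[1]):
            raise ValueError("confidence interval does not contain the estimate")


def _residual_jacobian(n: float, c: np.ndarray, a: np.ndarray, e: np.ndarray, form: str):
    """Residuals and d(residual)/dn for the two model forms.

    parent_radius: r_cca,i = (r_ica,i^n + r_eca,i^n)^(1/n) + eps
    power_sum:     r_cca,i^n = r_ica,i^n + r_eca,i^n + eps  (the form the
                   fitted-line-through-(sum of daughter powers, parent
                   power) plot represents)
    """
    an, en = a**n, e**n
    la, le, lc = np.log(a), np.log(e), np.log(c)
    s = an + en
    ds = an * la + en * le  # dS/dn
    if form == "parent_radius":
        pred = s ** (1.0 / n)
        res = c - pred
        dpred = pred * (ds / (n * s) - np.log(s) / (n * n))
        return res, -dpred
    if form == "power_sum":
        res = c**n - s
        dres = c**n * lc - ds
        return res, dres
    raise ValueError(f"unknown model_form {form!r}")


def _gauss_newton(c, a, e, form, n0, tol, max_iter):
    n = float(n0)
    res, jac = _residual_jacobian(n, c, a, e, form)
    sse = float(res @ res)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        denom = float(jac @ jac)
        if denom == 0.0:
            break
        step = -float(jac @ res) / denom
        # step halving keeps the iteration inside n > 0 and descending
        lam = 1.0
        while lam > 1e-12:
            n_new = n + lam * step
            if n_new > 0:
                res_new, jac_new = _residual_jacobian(n_new, c, a, e, form)
                sse_new = float(res_new @ res_new)
                if sse_new <= sse * (1 + 1e-14):
                    break
            lam *= 0.5
        else:
            break
        moved = abs(n_new - n)
        n, res, jac, sse = n_new, res_new, jac_new, sse_new
        if moved < tol * max(1.0, abs(n)):
            converged = True
            break
    return n, res, jac, sse, converged, it


def fit_cohort_exponent(
    records: pd.DataFrame,
    model_form: str = "parent_radius",
    n0: float = 2.0,
    tol: float = 1e-8,
    max_iter: int = 50,
    ci_method: str = "linearized",
    n_boot: int = 2000,
    seed: int | None = None,
) -> RegressionFit:
    """Fit one exponent to the whole cohort by Gauss-Newton least squares.

    ``ci_method`` is ``"linearized"`` (standard error from the linearised
    model, Student-t quantile) or ``"bootstrap"`` (seeded case resampling,
    percentile interval, ``n_boot`` resamples).
    """
    df = records.dropna(subset=RADIUS_COLUMNS)
    if len(df) < 3:
        raise ValueError("need at least 3 records with radii to fit")
    c = df["r_cca_mm"].to_numpy(float)
    a = df["r_ica_mm"].to_numpy(float)
    e = df["r_eca_mm"].to_numpy(float)
    if min(c.min(), a.min(), e.min()) <= 0:
        raise ValueError("all radii must be > 0")

    n, res, jac, sse, converged, it = _gauss_newton(c, a, e, model_form, n0, tol, max_iter)

    m = len(c)
    dof = m - 1
    if ci_method == "linearized":
        jtj = float(jac @ jac)
        if converged and jtj > 0 and dof > 0:
            se = math.sqrt(sse / dof / jtj)
            tq = stats.t.ppf(0.975, dof)
            ci = (n - tq * se, n + tq * se)
        else:
            ci = (math.nan, math.nan)
            converged = converged and False
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        boots = np.empty(n_boot)
        for k in range(n_boot):
            idx = rng.integers(0, m, size=m)
            nb, *_ = _gauss_newton(c[idx], a[idx], e[idx], model_form, n, tol, max_iter)
            boots[k] = nb
        lo, hi = np.percentile(boots, [2.5, 97.5])
        ci = (min(lo, n), max(hi, n))
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")

    return RegressionFit(
        n_hat=n, ci95=ci, n_obs=m, model_form=model_form,
        converged=converged, n_iter=it, sse=sse,
    )


# ---------------------------------------------------------------------------
# mean of individual exponents
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IndividualExponentSummary:
    mean: float
    sd: float
    n_ok: int
    n_excluded: int

    def __float__(self) -> float:  # convenience: float(summary)
        return self.mean


def mean_individual_exponent(records: pd.DataFrame) -> IndividualExponentSummary:
    """Arithmetic mean of per-bifurcation exponents over solvable records.

    Records without a positive root (daughter >= parent) are excluded and
    counted, not imputed.  Solves on demand if the ``n`` column is absent.
    """
    if "n" not in records.columns:
        records = solve_exponent_records(records)
    ok = records.loc[records["solve_status"] == "ok", "n"] if "solve_status" in records \
        else records["n"].dropna()
    n_excluded = len(records) - len(ok)
    if len(ok) == 0:
        raise ValueError("no record has a positive root; nothing to average")
    sd = float(ok.std(ddof=1)) if len(ok) > 1 else 0.0
    return IndividualExponentSummary(float(ok.mean()), sd, len(ok), n_excluded)


# ---------------------------------------------------------------------------
# ICA adjustment
# ---------------------------------------------------------------------------

def ica_adjustment(r_cca: float, r_ica: float, r_eca: float, n: float) -> float:
    """Percent change in ICA radius required to satisfy the law at exponent n.

    Holding CCA and ECA fixed, the law demands
    r_ica' = (r_cca^n - r_eca^n)^(1/n); returns 100 (r_ica' - r_ica)/r_ica.
    Requires r_eca < r_cca, otherwise no real ICA radius exists.
    """
    if min(r_cca, r_ica, r_eca) <= 0:
        raise ValueError("all radii must be > 0")
    if n <= 0:
        raise ValueError("n must be > 0")
    if r_eca >= r_cca:
        raise ValueError("r_eca must be smaller than r_cca for a real solution")
    r_ica_req = (r_cca**n - r_eca**n) ** (1.0 / n)
    return 100.0 * (r_ica_req - r_ica) / r_ica


# ---------------------------------------------------------------------------
# ratio summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RatioSummary:
    """Mean/SD of the per-bifurcation radius ratios and junction area ratios.

    ``area_ratio_quadratic`` is (r_ica^2 + r_eca^2)/r_cca^2 (true luminal
    area ratio); ``area_ratio_linear`` is (r_ica + r_eca)/r_cca (radius-sum
    form, the convention matched by published carotid bifurcation tables).
    """

    n_obs: int
    stats: pd.DataFrame = field(repr=False)

    def mean(self, key: str) -> float:
        return float(self.stats.loc[key, "mean"])

    def sd(self, key: str) -> float:
        return float(self.stats.loc[key, "sd"])


def summarize_ratios(records: pd.DataFrame) -> RatioSummary:
    """Per-record ratios, then mean and SD across records (mean of ratios)."""
    if len(records) == 0:
        raise ValueError("empty cohort")
    c = records["r_cca_mm"].to_numpy(float)
    a = records["r_ica_mm"].to_numpy(float)
    e = records["r_eca_mm"].to_numpy(float)
    ratios = pd.DataFrame(
        {
            "ica_cca": a / c,
            "eca_cca": e / c,
            "eca_ica": e / a,
            "area_ratio_quadratic": (a**2 + e**2) / c**2,
            "area_ratio_linear": (a + e) / c,
        }
    )
    tbl = pd.DataFrame({"mean": ratios.mean(), "sd": ratios.std(ddof=1).fillna(0.0)})
    return RatioSummary(n_obs=len(records), stats=tbl)


# ---------------------------------------------------------------------------
# paired left/right comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairedSideComparison:
    ica_radius_t: float
    ica_radius_p: float
    exponent_t: float
    exponent_p: float
    df: int
    n_pairs: int
    n_excluded_subjects: int


def _paired_t(left: np.ndarray, right: np.ndarray) -> tuple[float, float]:
    diff = left - right
    if np.allclose(diff, 0.0):
        return 0.0, 1.0  # identical sides: no evidence of asymmetry
    t, p = stats.ttest_rel(left, right)
    return float(t), float(p)


def compare_sides(records: pd.DataFrame) -> PairedSideComparison:
    """Paired t-tests of left vs right ICA radius and exponent.

    Subjects lacking either side (or a solvable exponent on either side)
    are excluded and counted.
    """
    if "n" not in records.columns:
        records = solve_exponent_records(records)
    wide_r = records.pivot_table(index="subject_id", columns="side", values="r_ica_mm")
    wide_n = records.pivot_table(index="subject_id", columns="side", values="n")
    for w in (wide_r, wide_n):
        for side in ("left", "right"):
            if side not in w.columns:
                w[side] = np.nan
    paired = wide_r.dropna(subset=["left", "right"]).index.intersection(
        wide_n.dropna(subset=["left", "right"]).index
    )
    n_subjects = records["subject_id"].nunique()
    n_pairs = len(paired)
    if n_pairs < 2:
        raise ValueError("need at least 2 subjects with both sides (df >= 1)")
    t_r, p_r = _paired_t(
        wide_r.loc[paired, "left"].to_numpy(), wide_r.loc[paired, "right"].to_numpy()
    )
    t_n, p_n = _paired_t(
        wide_n.loc[paired, "left"].to_numpy(), wide_n.loc[paired, "right"].to_numpy()
    )
    return PairedSideComparison(
        ica_radius_t=t_r, ica_radius_p=p_r, exponent_t=t_n, exponent_p=p_n,
        df=n_pairs - 1, n_pairs=n_pairs, n_excluded_subjects=n_subjects - n_pairs,
    )


def filter_low_tortuosity(records: pd.DataFrame, threshold: float = 0.1) -> pd.DataFrame:
    """Keep records with ICA tortuosity strictly below ``threshold``.

    The straight-vessel assumption of the minimum-work model motivates the
    restriction; the inequality is strict, so a tortuosity exactly at the
    threshold is dropped.
    """
    if "ica_tortuosity" not in records.columns:
        raise ValueError("records lack an 'ica_tortuosity' column")
    return records[records["ica_tortuosity"] < threshold].copy()
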