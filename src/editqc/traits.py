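"""Agronomic-trait statistics from group summaries.

Dunnett's many-to-one comparison is computed directly from (n, mean, SD)
summaries, since published trait tables rarely ship raw data. The adjusted
p-value for treatment i is P(max_j |T_j| >= |t_i|) under the K-variate t
distribution with pooled degrees of freedom and product correlations
rho_ij = lambda_i * lambda_j, lambda_i = sqrt(n_i / (n_i + n_0)) — the exact
joint law of the K treatment-vs-control t statistics sharing one control and
one pooled variance estimate. The K-variate probability is evaluated by
deterministic Gauss-Legendre quadrature over the two shared factors (the
control variate and the pooled scale), accurate to well below 1e-6.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

SIGNIFICANCE_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


@dataclass
class GroupSummary:
    """Summary statistics for one group: replicate count, mean, sample SD."""

    label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"{self.label}: need n >= 2, got {self.n}")
        if self.sd < 0:
            raise ValueError(f"{self.label}: negative SD")


@dataclass
class Comparison:
    label: str
    t_statistic: float
    df: int
    p_adjusted: float
    significance: str


@dataclass
class DunnettResult:
    control_label: str
    comparisons: list[Comparison]


def significance_label(p: float) -> str:
    for thr, label in SIGNIFICANCE_THRESHOLDS:
        if p < thr:
            return label
    return "n.s."


def _log_chi_scale_pdf(s: np.ndarray, df: int) -> np.ndarray:
    """log density of S = sqrt(chi2_df / df), the pooled-SD scale factor."""
    half = df / 2.0
    return (
        np.log(2.0) + half * np.log(half) - math.lgamma(half)
        + (df - 1) * np.log(s) - half * s**2
    )

_GL_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _leggauss(n: int) -> tuple[np.ndarray, np.ndarray]:
    if n not in _GL_CACHE:
        _GL_CACHE[n] = np.polynomial.legendre.leggauss(n)
    return _GL_CACHE[n]


def prob_max_abs_below(q: float, lambdas: np.ndarray, df: int, *, nodes: int = 160) -> float:
    """P(max_j |T_j| < q) for the shared-control multivariate t.

    Conditioning on the control variate Z0 and the pooled scale S, the
    treatment statistics are independent: T_j = (lambda_j Z0 +
    sqrt(1-lambda_j^2) X_j) / S. The double integral over (Z0, S) is
    evaluated with tensorized Gauss-Legendre rules on truncated ranges whose
    excluded tail mass is below 1e-12.
    """
    if q <= 0:
        return 0.0
    lam = np.asarray(lambdas, dtype=float)
    c = np.sqrt(1.0 - lam**2)

    zs, zw = _leggauss(nodes)
    z_lo, z_hi = -8.5, 8.5
    z = 0.5 * (z_hi - z_lo) * zs + 0.5 * (z_hi + z_lo)
    zw = zw * 0.5 * (z_hi - z_lo)

    s_lo = math.sqrt(stats.chi2.ppf(1e-13, df) / df)
    s_hi = math.sqrt(stats.chi2.isf(1e-13, df) / df)
    ss, sw = _leggauss(nodes)
    s = 0.5 * (s_hi - s_lo) * ss + 0.5 * (s_hi + s_lo)
    sw = sw * 0.5 * (s_hi - s_lo)

    # inner product over treatments: shape (n_s, n_z)
    u = q * s[:, None, None]  # (n_s, 1, 1)
    zl = lam[None, None, :] * z[None, :, None]  # (1, n_z, K)
    inner = stats.norm.cdf((u - zl) / c) - stats.norm.cdf((-u - zl) / c)
    prod = np.prod(inner, axis=2)  # (n_s, n_z)
    gz = prod @ (zw * stats.norm.pdf(z))
    dens = np.exp(_log_chi_scale_pdf(s, df))
    return float(np.clip(gz @ (sw * dens), 0.0, 1.0))


def dunnett_from_summary(
    control: GroupSummary, treatments: list[GroupSummary], *, nodes: int = 160
) -> DunnettResult:
    """Two-sided Dunnett many-to-one test from group summaries.

    Pooled variance across all groups (classical equal-variance Dunnett);
    adjusted p-values are familywise-exact under normality and reported to
    quadrature accuracy (< 1e-6).
    """
    if not treatments:
        raise ValueError("need at least one treatment group")
    groups = [control, *treatments]
    df = sum(g.n - 1 for g in groups)
    ss = sum((g.n - 1) * g.sd**2 for g in groups)
    if ss <= 0:
        raise ValueError("all groups have zero variance; test degenerate")
    s2 = ss / df
    s = math.sqrt(s2)

    lambdas = np.array([math.sqrt(g.n / (g.n + control.n)) for g in treatments])
    comparisons = []
    for g in treatments:
        se = s * math.sqrt(1.0 / g.n + 1.0 / control.n)
        t = (g.mean - control.mean) / se
        p = 1.0 - prob_max_abs_below(abs(t), lambdas, df, nodes=nodes)
        p = min(max(p, 0.0), 1.0)
        comparisons.append(
            Comparison(
                label=g.label, t_statistic=t, df=df,
                p_adjusted=round(p, 6), significance=significance_label(p),
            )
        )
    return DunnettResult(control_label=control.label, comparisons=comparisons)


def percent_change(treatment_mean: float, control_mean: float) -> float:
    """Percent change of a treatment mean relative to the control mean."""
    if control_mean <= 0:
        raise ValueError("control mean must be positive")
    return 100.0 * (treatment_mean - control_mean) / control_mean


def germination_rate(germinated: int, total: int) -> tuple[float, float]:
    """Germination proportion and its binomial standard error."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= germinated <= total:
        raise ValueError("germinated must lie in [0, total]")
    p = germinated / total
    return p, math.sqrt(p * (1.0 - p) / total)


def summaries_from_raw(values: pd.DataFrame | dict[str, list[float]]) -> list[GroupSummary]:
    """Per-group (n, mean, sample SD) from raw per-individual values.

    Accepts a mapping label -> values or a DataFrame with ``label`` and
    ``value`` columns; preserves first-appearance group order.
    """
    if isinstance(values, pd.DataFrame):
        grouped = {k: g["value"].to_numpy() for k, g in values.groupby("label", sort=False)}
    else:
        grouped = {k: np.asarray(v, dtype=float) for k, v in values.items()}
    out = []
    for label, v in grouped.items():
        out.append(GroupSummary(label, len(v), float(np.mean(v)), float(np.std(v, ddof=1))))
    return out


def dunnett_table(
    summaries: list[GroupSummary], control_label: str, *, trait: str = ""
) -> pd.DataFrame:
    """Convenience wrapper producing a tidy result table for one trait."""
    control = next(g for g in summaries if g.label == control_label)
    treatments = [g for g in summaries if g.label != control_label]
    res = dunnett_from_summary(control, treatments)
    rows = [
        {
            "trait": trait, "label": c.label, "n": t.n, "mean": t.mean, "sd": t.sd,
            "t": c.t_statistic, "df": c.df, "p_adjusted": c.p_adjusted,
            "significance": c.significance,
        }
        for c, t in zip(res.comparisons, treatments)
    ]
    return pd.DataFrame(rows)
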