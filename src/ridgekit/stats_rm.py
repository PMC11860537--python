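"""Repeated-measures one-way ANOVA with Dunnett and Tukey post hoc tests.

The quality counts form a complete subjects x conditions table (every subject
measured under every condition).  The omnibus test is the classical
repeated-measures one-way ANOVA: a two-way additive decomposition with
subjects as blocks,

    SS_total = SS_subject + SS_condition + SS_error
    F = MS_condition / MS_error,  df = (k-1, (k-1)(n-1))

assuming sphericity (a Greenhouse-Geisser toggle is provided).  Post hoc
comparisons follow the designs they suit:

* :func:`dunnett` — each condition vs a designated control.  The per-contrast
  statistic is the paired t (mean difference over its paired SE,
  ``SD(control - test)/sqrt(n)``, df = n-1); the familywise-adjusted p is the
  tail probability of the maximum absolute statistic over the k-1 contrasts,
  whose null correlation is 0.5 (every contrast shares the control column).
  That tail is evaluated by seeded Monte Carlo on the equicorrelated
  multivariate t; with the default 2·10^5 draws the standard error of the
  adjusted p is below ~1.2e-3.  The adjusted p is floored at the unadjusted
  paired-t p so multiplicity monotonicity holds exactly despite MC noise.
* :func:`tukey` — all pairs, adjusted p from the studentized-range
  distribution with parameters (k, df_error) on the pooled-MS_error scale.
  The reported SE of each difference is the pairwise paired SE (matching how
  per-pair SEs are conventionally tabulated for within-subject designs).

Significance stars follow the GraphPad convention: ns p > 0.05, * p <= 0.05,
** p <= 0.01, *** p <= 0.001, **** p <= 0.0001 (boundaries give more stars).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CountTable",
    "MCComparison",
    "RMAnovaReport",
    "rm_anova",
    "dunnett",
    "tukey",
    "star_notation",
    "comparisons_frame",
]

DEFAULT_MC_DRAWS = 200_000


@dataclass(frozen=True)
class CountTable:
    """Complete subjects x conditions response table."""

    values: np.ndarray = field(repr=False)  # shape (n_subjects, k_conditions)
    conditions: tuple[str, ...] = ()
    subjects: tuple[str, ...] = ()

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", v)
        if v.ndim != 2:
            raise ValueError("values must be 2-D (subjects x conditions)")
        n, k = v.shape
        if not np.isfinite(v).all():
            raise ValueError("table has missing/non-finite cells; RM design requires completeness")
        if n < 2 or k < 2:
            raise ValueError("need at least 2 subjects and 2 conditions")
        if not self.conditions:
            object.__setattr__(self, "conditions", tuple(f"C{i+1}" for i in range(k)))
        if not self.subjects:
            object.__setattr__(self, "subjects", tuple(f"S{i+1}" for i in range(n)))
        if len(self.conditions) != k or len(self.subjects) != n:
            raise ValueError("label lengths do not match table shape")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_long(cls, df: pd.DataFrame, subject="subject", condition="condition", value="value"):
        """Build from a long-format frame with subject/condition/value columns."""
        wide = df.pivot_table(index=subject, columns=condition, values=value, aggfunc="mean")
        if wide.isna().any().any():
            missing = [
                f"{s}/{c}" for s in wide.index for c in wide.columns if pd.isna(wide.loc[s, c])
            ]
            raise ValueError(f"incomplete design; missing cells: {', '.join(missing)}")
        return cls(
            values=wide.to_numpy(dtype=np.float64),
            conditions=tuple(str(c) for c in wide.columns),
            subjects=tuple(str(s) for s in wide.index),
        )


@dataclass(frozen=True)
class MCComparison:
    pair: tuple[str, str]
    mean_1: float
    mean_2: float
    mean_diff: float
    se_diff: float
    t: float
    p_unadjusted: float
    p_adjusted: float
    stars: str


@dataclass(frozen=True)
class RMAnovaReport:
    F: float
    df_condition: int
    df_error: int
    p: float
    ms_condition: float
    ms_error: float
    gg_epsilon: float | None = None
    comparisons: list[MCComparison] = field(default_factory=list)


def star_notation(p: float) -> str:
    """GraphPad-style significance stars (boundaries inclusive toward more)."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p-value outside [0, 1]: {p}")
    if p <= 0.0001:
        return "****"
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def _ss_decomposition(v: np.ndarray):
    n, k = v.shape
    grand = v.mean()
    ss_total = float(((v - grand) ** 2).sum())
    ss_subject = float(k * ((v.mean(axis=1) - grand) ** 2).sum())
    ss_condition = float(n * ((v.mean(axis=0) - grand) ** 2).sum())
    ss_error = ss_total - ss_subject - ss_condition
    return ss_total, ss_subject, ss_condition, ss_error


def _gg_epsilon(v: np.ndarray) -> float:
    """Greenhouse-Geisser sphericity estimate from the covariance matrix."""
    k = v.shape[1]
    S = np.cov(v, rowvar=False)
    mean_diag = np.trace(S) / k
    mean_all = S.mean()
    row_means = S.mean(axis=1)
    num = (k * (mean_diag - mean_all)) ** 2
    den = (k - 1) * ((S ** 2).sum() - 2 * k * (row_means ** 2).sum() + k ** 2 * mean_all ** 2)
    return float(num / den) if den > 0 else 1.0


def rm_anova(table: CountTable, gg_correction: bool = False) -> RMAnovaReport:
    """Repeated-measures one-way ANOVA (subjects as blocks)."""
    v = table.values
    n, k = v.shape
    _, _, ss_condition, ss_error = _ss_decomposition(v)
    df_c = k - 1
    df_e = (k - 1) * (n - 1)
    ms_c = ss_condition / df_c
    ms_e = ss_error / df_e
    if ms_e <= 0:
        # All within-subject differences identical; no evidence against H0
        # unless the condition effect itself is nonzero (then F is infinite).
        F = np.inf if ms_c > 0 else 0.0
        p = 0.0 if ms_c > 0 else 1.0
        return RMAnovaReport(F=F, df_condition=df_c, df_error=df_e, p=p,
                             ms_condition=ms_c, ms_error=ms_e)
    F = ms_c / ms_e
    eps = None
    if gg_correction:
        eps = _gg_epsilon(v)
        p = float(sps.f.sf(F, df_c * eps, df_e * eps))
    else:
        p = float(sps.f.sf(F, df_c, df_e))
    return RMAnovaReport(F=float(F), df_condition=df_c, df_error=df_e, p=p,
                         ms_condition=float(ms_c), ms_error=float(ms_e), gg_epsilon=eps)


def _max_abs_t_null(n_contrasts: int, df: int, n_draws: int, seed) -> np.ndarray:
    """Seeded sample of max_m |T_m| under the equicorrelated (rho = 0.5)
    multivariate-t null shared by Dunnett-type contrasts."""
    rng = np.random.default_rng(seed)
    z0 = rng.standard_normal(n_draws)
    zi = rng.standard_normal((n_draws, n_contrasts))
    Z = np.sqrt(0.5) * z0[:, None] + np.sqrt(0.5) * zi
    s = np.sqrt(rng.chisquare(df, n_draws) / df)
    return np.abs(Z / s[:, None]).max(axis=1)


def dunnett(
    table: CountTable,
    control: str,
    n_draws: int = DEFAULT_MC_DRAWS,
    seed: int = 12345,
) -> list[MCComparison]:
    """Two-sided comparisons of every condition against the control.

    ``mean_diff`` follows the Control - Test sign convention.
    """
    if control not in table.conditions:
        raise ValueError(f"unknown control label {control!r}")
    v = table.values
    n = table.n
    ci = table.conditions.index(control)
    others = [j for j in range(table.k) if j != ci]
    m = len(others)
    max_null = _max_abs_t_null(m, n - 1, n_draws, seed) if m > 0 else np.empty(0)

    out: list[MCComparison] = []
    for j in others:
        d = v[:, ci] - v[:, j]
        md = float(d.mean())
        sd = float(d.std(ddof=1))
        se = sd / np.sqrt(n)
        if se == 0:
            t_obs, p_un = 0.0, 1.0
            p_adj = 1.0
        else:
            t_obs = md / se
            p_un = float(2.0 * sps.t.sf(abs(t_obs), n - 1))
            p_adj = float((max_null >= abs(t_obs)).mean())
            p_adj = min(1.0, max(p_adj, p_un))  # monotone despite MC noise
        out.append(
            MCComparison(
                pair=(control, table.conditions[j]),
                mean_1=float(v[:, ci].mean()),
                mean_2=float(v[:, j].mean()),
                mean_diff=md,
                se_diff=float(se),
                t=float(t_obs),
                p_unadjusted=p_un,
                p_adjusted=p_adj,
                stars=star_notation(p_adj),
            )
        )
    return out


def tukey(table: CountTable) -> list[MCComparison]:
    """All-pairs comparisons via the studentized-range distribution."""
    v = table.values
    n, k = v.shape
    report = rm_anova(table)
    ms_e, df_e = report.ms_error, report.df_error
    out: list[MCComparison] = []
    for a in range(k):
        for b in range(a + 1, k):
            d = v[:, a] - v[:, b]
            md = float(d.mean())
            se_paired = float(d.std(ddof=1) / np.sqrt(n))
            if ms_e <= 0:
                q = np.inf if md != 0 else 0.0
                p_adj = 0.0 if md != 0 else 1.0
                p_un = p_adj
                t_obs = np.inf if md != 0 else 0.0
            else:
                se_pooled = np.sqrt(ms_e / n)
                q = abs(md) / se_pooled
                t_obs = md / se_pooled
                p_adj = float(sps.studentized_range.sf(q, k, df_e))
                p_un = float(2.0 * sps.t.sf(q / np.sqrt(2.0), df_e))
            p_adj = min(1.0, max(p_adj, 0.0))
            out.append(
                MCComparison(
                    pair=(table.conditions[a], table.conditions[b]),
                    mean_1=float(v[:, a].mean()),
                    mean_2=float(v[:, b].mean()),
                    mean_diff=md,
                    se_diff=se_paired,
                    t=float(t_obs),
                    p_unadjusted=p_un,
                    p_adjusted=p_adj,
                    stars=star_notation(p_adj),
                )
            )
    return out


def comparisons_frame(comparisons: list[MCComparison]) -> pd.DataFrame:
    """Post hoc comparisons as a table mirroring the conventional layout:
    group means, mean difference, SE of the difference, adjusted p, stars."""
    return pd.DataFrame(
        {
            "group_1": [c.pair[0] for c in comparisons],
            "group_2": [c.pair[1] for c in comparisons],
            "mean_1": [c.mean_1 for c in comparisons],
            "mean_2": [c.mean_2 for c in comparisons],
            "mean_diff": [c.mean_diff for c in comparisons],
            "se_diff": [c.se_diff for c in comparisons],
            "p_adjusted": [c.p_adjusted for c in comparisons],
            "significance": [c.stars for c in comparisons],
        }
    )
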