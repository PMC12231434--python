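"""Nonparametric and repeated-measures statistics for session summaries.

The battery mirrors common practice for small-cohort behavioral designs:
Kruskal-Wallis for between-strain contrasts, the Wilcoxon matched-pairs
signed-rank test for within-animal contrasts (e.g. near vs distant zone),
Spearman rank correlation for the freezing/call-duration coupling, and a
two-way mixed (split-plot) ANOVA — strain as the between factor, the four
day/night x water/sucrose measurements as the within factor — for the
two-bottle sucrose preference test.

All tests are two-tailed; alpha is conventionally 0.05.  No multiple-testing
correction is applied by default (a Holm helper is provided).  Sphericity is
not corrected by default; a Greenhouse-Geisser option exists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DataError
from .io_formats import SessionSummary, SucroseRecord  # re-exported domain types

__all__ = [
    "TestResult",
    "SessionSummary",
    "kruskal_wallis",
    "wilcoxon_signed_rank",
    "spearman",
    "rm_anova_strain_by_measurement",
    "sucrose_summary",
    "SucroseSummary",
    "holm_bonferroni",
]

logger = logging.getLogger(__name__)

#: Within-subject measurement cells of the sucrose test, in fixed order.
MEASUREMENTS = (("day", "water"), ("night", "water"), ("day", "sucrose"), ("night", "sucrose"))


@dataclass(frozen=True)
class TestResult:
    """One hypothesis-test outcome in the field's reporting notation."""

    name: str
    statistic_name: str  # H, W, Rs or F
    statistic_value: float
    df: tuple[float, ...]
    p_value: float
    n_per_group: tuple[int, ...]
    degenerate: bool = False
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")

    def __str__(self) -> str:  # e.g. "H(1, 21) = 6.42, p = 0.011"
        dfs = ", ".join(f"{d:g}" for d in self.df)
        return f"{self.statistic_name}({dfs}) = {self.statistic_value:.3g}, p = {self.p_value:.3g}"


def kruskal_wallis(groups: Sequence[Sequence[float]], name: str = "kruskal_wallis") -> TestResult:
    """Kruskal-Wallis ANOVA by ranks (midrank tie correction).

    H is referred to a chi-square distribution with k-1 degrees of freedom.
    All values identical across groups is a degenerate case: H = 0, p = 1.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(len(a) == 0 for a in arrays):
        raise DataError("kruskal_wallis needs >= 2 non-empty groups")
    ns = tuple(len(a) for a in arrays)
    pooled = np.concatenate(arrays)
    df = (len(arrays) - 1, len(pooled) - len(arrays))
    if np.all(pooled == pooled[0]):
        return TestResult(name, "H", 0.0, df, 1.0, ns, degenerate=True)
    h, p = sps.kruskal(*arrays)
    return TestResult(name, "H", float(h), df, float(p), ns)


def wilcoxon_signed_rank(
    paired_a: Sequence[float], paired_b: Sequence[float], name: str = "wilcoxon"
) -> TestResult:
    """Wilcoxon matched-pairs signed-rank test, two-sided.

    Zero differences are dropped (Wilcoxon's original convention); tied
    absolute differences get midranks.  The exact null distribution is used
    for n <= 25 when there are no ties; otherwise the normal approximation
    with tie correction.  All-zero differences give a degenerate p = 1.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape or a.size < 1:
        raise DataError("wilcoxon needs two equal-length vectors of length >= 1")
    d = a - b
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        return TestResult(name, "W", 0.0, (0,), 1.0, (len(a),), degenerate=True)
    has_ties = np.unique(np.abs(d)).size < n
    method = "exact" if (n <= 25 and not has_ties) else "approx"
    res = sps.wilcoxon(d, zero_method="wilcox", alternative="two-sided", method=method)
    return TestResult(
        name,
        "W",
        float(res.statistic),
        (n,),
        float(min(res.pvalue, 1.0)),
        (len(a),),
        extra={"method": method, "n_nonzero": n},
    )


def spearman(x: Sequence[float], y: Sequence[float], name: str = "spearman") -> TestResult:
    """Spearman rank-order correlation Rs (Pearson correlation of midranks),
    p-value from the t approximation.  Zero rank variance is degenerate."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise DataError("spearman needs two equal-length vectors of length >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        return TestResult(name, "Rs", float("nan"), (x.size - 2,), 1.0, (x.size,), degenerate=True)
    rs, p = sps.spearmanr(x, y)
    return TestResult(name, "Rs", float(rs), (x.size - 2,), float(p), (x.size,))


# -- sucrose test ------------------------------------------------------------


def _sucrose_wide(records: Sequence[SucroseRecord]) -> pd.DataFrame:
    """Rat x measurement matrix (one row per rat, 4 measurement columns,
    plus strain); rats missing any cell are excluded with a warning."""
    df = pd.DataFrame(
        {
            "rat_id": [r.rat_id for r in records],
            "strain": [r.strain_label for r in records],
            "phase": [r.phase for r in records],
            "fluid": [r.fluid for r in records],
            "volume": [r.volume for r in records],
        }
    )
    if df.empty:
        raise DataError("no sucrose records")
    wide = df.pivot_table(
        index=["rat_id", "strain"], columns=["phase", "fluid"], values="volume", aggfunc="mean"
    )
    complete = wide.notna().all(axis=1)
    if not complete.all():
        for rid in wide.index[~complete]:
            logger.warning("rat %s missing a measurement cell; excluded", rid[0])
        wide = wide[complete]
    cols = [(p, f) for p, f in MEASUREMENTS if (p, f) in wide.columns]
    if len(cols) < 4:
        raise DataError("sucrose data must contain all 4 phase x fluid cells")
    return wide[cols]


def _gg_epsilon(y: np.ndarray, strains: np.ndarray, levels: list) -> float:
    """Greenhouse-Geisser epsilon from the pooled within-group covariance."""
    m = y.shape[1]
    resid = np.vstack([y[strains == g] - y[strains == g].mean(axis=0) for g in levels])
    s = resid.T @ resid / max(len(resid) - len(levels), 1)
    sc = s - s.mean(axis=0) - s.mean(axis=1)[:, None] + s.mean()
    denom = (m - 1) * (sc**2).sum()
    if denom <= 0:
        return 1.0
    eps = np.trace(sc) ** 2 / denom
    return float(min(1.0, max(eps, 1.0 / (m - 1))))


def rm_anova_strain_by_measurement(
    records: Sequence[SucroseRecord], gg: bool = False
) -> list[TestResult]:
    """Two-way mixed ANOVA: strain (between) x measurement (within, 4 cells).

    Explicit sum-of-squares decomposition with subjects nested in strain:
    strain is tested against subjects-within-strain, measurement and the
    strain x measurement interaction against the within-subject residual.
    Unbalanced group sizes are handled with observation-weighted means.
    Degrees of freedom are uncorrected by default (sphericity assumed);
    with ``gg=True`` the within-subject tests carry a Greenhouse-Geisser
    corrected p-value in ``extra["p_gg"]``.
    """
    wide = _sucrose_wide(records)
    y = wide.to_numpy(dtype=float)  # subjects x m
    strains = wide.index.get_level_values("strain").to_numpy()
    levels = sorted(set(strains))
    a, (n_subj, m) = len(levels), y.shape
    if a < 2 or n_subj < a + 1:
        raise DataError("need >= 2 strains and more subjects than strains")
    ns = tuple(int((strains == g).sum()) for g in levels)

    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())
    subj_means = y.mean(axis=1)
    ss_subjects = float(m * ((subj_means - grand) ** 2).sum())
    ss_strain = float(sum(m * n_g * (y[strains == g].mean() - grand) ** 2 for g, n_g in zip(levels, ns)))
    ss_meas = float(n_subj * ((y.mean(axis=0) - grand) ** 2).sum())
    ss_cells_resid = float(
        sum(((y[strains == g] - y[strains == g].mean(axis=0)) ** 2).sum() for g in levels)
    )
    ss_inter = ss_total - ss_cells_resid - ss_meas - ss_strain
    ss_err_between = ss_subjects - ss_strain
    ss_err_within = ss_total - ss_meas - ss_subjects - ss_inter

    df_strain, df_errb = a - 1, n_subj - a
    df_meas, df_inter = m - 1, (a - 1) * (m - 1)
    df_errw = (m - 1) * (n_subj - a)

    def _f(ss_eff, df_eff, ss_err, df_err, label):
        ms_err = ss_err / df_err
        if ms_err <= 0:
            degen = ss_eff <= 1e-12
            fval, p = (0.0, 1.0) if degen else (float("inf"), 0.0)
            return TestResult(label, "F", fval, (df_eff, df_err), p, ns, degenerate=True,
                              extra={"ss_effect": ss_eff, "ss_error": ss_err})
        fval = (ss_eff / df_eff) / ms_err
        fval = max(fval, 0.0)  # guard tiny negative SS from cancellation
        p = float(sps.f.sf(fval, df_eff, df_err))
        return TestResult(label, "F", float(fval), (df_eff, df_err), p, ns,
                          extra={"ss_effect": ss_eff, "ss_error": ss_err})

    out = [
        _f(ss_strain, df_strain, ss_err_between, df_errb, "strain"),
        _f(ss_meas, df_meas, ss_err_within, df_errw, "measurement"),
        _f(max(ss_inter, 0.0), df_inter, ss_err_within, df_errw, "strain_x_measurement"),
    ]
    if gg:
        eps = _gg_epsilon(y, strains, levels)
        for res in out[1:]:
            if not res.degenerate:
                res.extra["eps_gg"] = eps
                res.extra["p_gg"] = float(
                    sps.f.sf(res.statistic_value, eps * res.df[0], eps * res.df[1])
                )
    return out


@dataclass
class SucroseSummary:
    """Per-rat volumes and preferences plus group mean +/- SEM tables."""

    per_rat: pd.DataFrame  # rat_id, strain, phase: sucrose, water, preference
    group: pd.DataFrame  # strain, phase, fluid: mean, sem, n


def sucrose_summary(records: Sequence[SucroseRecord]) -> SucroseSummary:
    """Per-phase fluid volumes and the sucrose preference ratio
    sucrose / (sucrose + water) per rat; preference is NaN (flagged) for a
    rat-phase with zero total intake.  Group table gives mean +/- SEM."""
    df = pd.DataFrame(
        {
            "rat_id": [r.rat_id for r in records],
            "strain": [r.strain_label for r in records],
            "phase": [r.phase for r in records],
            "fluid": [r.fluid for r in records],
            "volume": [r.volume for r in records],
        }
    )
    if df.empty:
        raise DataError("no sucrose records")
    wide = df.pivot_table(
        index=["rat_id", "strain", "phase"], columns="fluid", values="volume", aggfunc="mean"
    ).reset_index()
    for fluid in ("sucrose", "water"):
        if fluid not in wide:
            wide[fluid] = np.nan
    total = wide["sucrose"] + wide["water"]
    with np.errstate(invalid="ignore"):
        wide["preference"] = np.where(total > 0, wide["sucrose"] / total, np.nan)
    n_undef = int((~(total > 0)).sum())
    if n_undef:
        logger.warning("%d rat-phases have zero total intake; preference undefined", n_undef)
    group = (
        df.groupby(["strain", "phase", "fluid"])["volume"]
        .agg(mean="mean", sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)), n="count")
        .reset_index()
    )
    return SucroseSummary(per_rat=wide, group=group)


def holm_bonferroni(p_values: Sequence[float]) -> list[float]:
    """Holm step-down adjusted p-values (monotone, capped at 1). Off by
    default everywhere, provided for users who want family-wise control."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    n = len(p)
    adj = np.empty(n)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (n - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj.tolist()
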