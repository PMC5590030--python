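"""Group-level analysis of per-ROI quantification results.

Per-(ROI, day) contrasts between contrast-agent groups with
Benjamini-Hochberg FDR adjustment, Pearson correlation with Fisher-z
confidence interval, the study-design sample-size calculation via the
noncentral-t power function, and a one-way ANOVA for the treatment
question (change in hemispheric lesion fraction).

The linear mixed model (per-subject random intercept, fixed
ROI x agent x day effects) is a reconstruction of the named factors; a
Welch two-sample fallback is provided so the pipeline is testable without
a mixed-model backend.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GROUP_TABLE_COLUMNS",
    "TestResult",
    "PearsonResult",
    "validate_group_table",
    "apply_exclusions",
    "compare_cells",
    "fdr_adjust",
    "pearson_correlation",
    "required_sample_size",
    "treatment_effect",
]

logger = logging.getLogger(__name__)

GROUP_TABLE_COLUMNS = (
    "subject",
    "agent",
    "day",
    "roi",
    "eq1",
    "eq3",
    "lesion_volume_mm3",
    "hemispheric_lesion_fraction",
)


@dataclass
class TestResult:
    """One statistical contrast with raw and FDR-adjusted p values."""

    __test__ = False  # keep pytest from collecting this dataclass

    contrast: str
    estimate: float
    p_value: float
    p_adjusted: float | None = None
    n_per_group: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p value outside [0, 1]: {self.p_value}")
        if self.p_adjusted is not None and self.p_adjusted < self.p_value - 1e-12:
            raise ValueError("adjusted p must be >= raw p")


@dataclass(frozen=True)
class PearsonResult:
    r: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int


def validate_group_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the tidy group table: required columns, one row per
    subject x roi x day."""
    missing = [c for c in GROUP_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"group table missing columns: {missing}")
    dup = table.duplicated(subset=["subject", "roi", "day"])
    if dup.any():
        raise ValueError(
            f"group table has {int(dup.sum())} duplicate subject x roi x day rows"
        )
    return table


def apply_exclusions(
    table: pd.DataFrame,
    rules: Mapping[str, Callable[[pd.Series], bool]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply declarative row-exclusion rules.

    ``rules`` maps a reason label to a predicate returning True when the
    row must be excluded. Returns (kept, excluded) where the excluded frame
    carries an ``exclusion_reason`` column.
    """
    excluded_rows = []
    keep = np.ones(len(table), dtype=bool)
    for reason, predicate in rules.items():
        hits = table.apply(predicate, axis=1).to_numpy(dtype=bool)
        for idx in np.flatnonzero(hits & keep):
            row = table.iloc[idx].copy()
            row["exclusion_reason"] = reason
            excluded_rows.append(row)
        keep &= ~hits
    excluded = pd.DataFrame(excluded_rows) if excluded_rows else pd.DataFrame(
        columns=list(table.columns) + ["exclusion_reason"]
    )
    return table.loc[keep].reset_index(drop=True), excluded.reset_index(drop=True)


# ---------------------------------------------------------------------------
# multiple comparisons


def fdr_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p values, order-preserving."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest rank downward
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.empty(m)
    adjusted[order] = np.minimum(ranked, 1.0)
    return adjusted.tolist()


# ---------------------------------------------------------------------------
# per-cell contrasts


def _welch_cell(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    estimate = float(np.mean(a) - np.mean(b))
    if np.ptp(a) == 0 and np.ptp(b) == 0 and estimate == 0.0:
        return 0.0, 1.0  # identical degenerate cells
    t = sps.ttest_ind(a, b, equal_var=False)
    p = float(t.pvalue)
    if not np.isfinite(p):
        p = 1.0
    return estimate, p


def _mixed_contrasts(
    table: pd.DataFrame,
    value: str,
    agents: tuple[str, str],
    cells: list[tuple[str, object]],
) -> dict[tuple[str, object], tuple[float, float]]:
    """Per-cell agent contrasts from one linear mixed model.

    Fixed effects roi x agent x day (full interaction), random intercept per
    subject; each cell contrast is the difference of fixed-effect
    predictions at the two agents.
    """
    import statsmodels.formula.api as smf
    from patsy import build_design_matrices

    import warnings

    df = table.copy()
    df["day"] = df["day"].astype(str)
    formula = f"{value} ~ C(roi) * C(agent) * C(day)"
    model = smf.mixedlm(formula, df, groups=df["subject"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # small-sample convergence chatter
        fit = model.fit(reml=True, method="powell")
    design_info = model.data.design_info

    out: dict[tuple[str, object], tuple[float, float]] = {}
    for roi, day in cells:
        rows = pd.DataFrame(
            {"roi": [roi, roi], "agent": list(agents), "day": [str(day), str(day)]}
        )
        (mat,) = build_design_matrices([design_info], rows)
        contrast = np.asarray(mat)[0] - np.asarray(mat)[1]
        tt = fit.t_test(contrast.reshape(1, -1))
        out[(roi, day)] = (float(np.squeeze(tt.effect)), float(np.squeeze(tt.pvalue)))
    return out


def compare_cells(
    table: pd.DataFrame,
    model: str = "mixed",
    value: str = "eq3",
    agents: tuple[str, str] | None = None,
) -> list[TestResult]:
    """Per-(roi, day) contrast between two contrast-agent groups.

    ``mixed`` fits one linear mixed model over the full table and reads
    each cell's agent contrast off the fixed effects; ``welch`` runs an
    independent Welch two-sample t-test per cell. Cells with fewer than two
    subjects per group are skipped with a logged reason. All raw p values
    are Benjamini-Hochberg adjusted across the returned contrasts.
    """
    if model not in ("mixed", "welch"):
        raise ValueError(f"model must be 'mixed' or 'welch', got {model!r}")
    table = validate_group_table(table)
    if agents is None:
        found = sorted(table["agent"].unique())
        if len(found) != 2:
            raise ValueError(
                f"expected exactly 2 agents (or pass agents=), found {found}"
            )
        agents = (found[0], found[1])

    cells: list[tuple[str, object]] = []
    samples: dict[tuple[str, object], tuple[np.ndarray, np.ndarray]] = {}
    for (roi, day), cell in table.groupby(["roi", "day"], sort=True):
        a = cell.loc[cell["agent"] == agents[0], value].to_numpy(dtype=float)
        b = cell.loc[cell["agent"] == agents[1], value].to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2:
            logger.info(
                "compare_cells: skipping roi=%s day=%s (n=%d vs %d; need >= 2 per group)",
                roi, day, len(a), len(b),
            )
            continue
        cells.append((roi, day))
        samples[(roi, day)] = (a, b)

    results: list[TestResult] = []
    if model == "mixed" and cells:
        sub = table[table["agent"].isin(agents)]
        estimates = _mixed_contrasts(sub, value, agents, cells)
        for key in cells:
            est, p = estimates[key]
            a, b = samples[key]
            results.append(
                TestResult(
                    contrast=f"{agents[0]} vs {agents[1]} | roi={key[0]}, day={key[1]}",
                    estimate=est,
                    p_value=min(max(p, 0.0), 1.0),
                    n_per_group={agents[0]: len(a), agents[1]: len(b)},
                )
            )
    else:
        for key in cells:
            a, b = samples[key]
            est, p = _welch_cell(a, b)
            results.append(
                TestResult(
                    contrast=f"{agents[0]} vs {agents[1]} | roi={key[0]}, day={key[1]}",
                    estimate=est,
                    p_value=p,
                    n_per_group={agents[0]: len(a), agents[1]: len(b)},
                )
            )

    adjusted = fdr_adjust([r.p_value for r in results])
    for r, q in zip(results, adjusted):
        r.p_adjusted = q
    return results


# ---------------------------------------------------------------------------
# correlation


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> PearsonResult:
    """Pearson product-moment correlation with two-sided t-test p value and
    95% Fisher-z confidence interval (SE = 1/sqrt(n-3))."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    n = x.size
    if n != y.size:
        raise ValueError("x and y must have equal length")
    if n < 3:
        raise ValueError(f"correlation requires n >= 3, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    r = float(np.corrcoef(x, y)[0, 1])
    r = min(max(r, -1.0), 1.0)
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
        p = float(2.0 * sps.t.sf(abs(t), n - 2))
    if n > 3 and abs(r) < 1.0:
        z = np.arctanh(r)
        half = sps.norm.ppf(0.975) / np.sqrt(n - 3)
        lo, hi = float(np.tanh(z - half)), float(np.tanh(z + half))
    else:
        lo, hi = -1.0, 1.0
    return PearsonResult(r=r, ci_low=lo, ci_high=hi, p_value=p, n=n)


# ---------------------------------------------------------------------------
# power / sample size


def two_sample_t_power(n_per_group: int, d: float, alpha: float) -> float:
    """Power of a two-sided two-sample t-test via the noncentral-t
    distribution (equal group sizes, standardized effect d)."""
    df = 2 * n_per_group - 2
    nc = d * np.sqrt(n_per_group / 2.0)
    t_crit = sps.t.ppf(1.0 - alpha / 2.0, df)
    return float(1.0 - sps.nct.cdf(t_crit, df, nc) + sps.nct.cdf(-t_crit, df, nc))


def required_sample_size(
    reduction_percent: float,
    sd_percent: float,
    alpha: float = 0.05,
    power: float = 0.8,
    n_pairwise: int = 1,
    n_max: int = 10_000,
) -> int:
    """Smallest per-group n for a two-sided two-sample t-test to reach the
    requested power at the Bonferroni-adjusted level alpha/n_pairwise.

    The standardized effect is d = reduction_percent / sd_percent, both in
    the same percent units. The floor is n = 2 (minimum for estimating an
    SD).
    """
    if reduction_percent <= 0 or sd_percent <= 0:
        raise ValueError("reduction and SD must be positive")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if not 0 <= power < 1:
        raise ValueError(f"power must lie in [0, 1), got {power}")
    if n_pairwise < 1:
        raise ValueError("n_pairwise must be >= 1")
    d = reduction_percent / sd_percent
    adj_alpha = alpha / n_pairwise
    for n in range(2, n_max + 1):
        if two_sample_t_power(n, d, adj_alpha) >= power:
            return n
    raise ValueError(f"requested power {power} not reachable within n <= {n_max}")


# ---------------------------------------------------------------------------
# treatment effect


def treatment_effect(
    table: pd.DataFrame,
    value: str = "hemispheric_lesion_fraction",
    day_from: int = 1,
    day_to: int = 3,
) -> TestResult:
    """One-way ANOVA on the day_from -> day_to change in hemispheric lesion
    fraction across treatment groups.

    Expects one row per subject x day (any single ROI); the change score is
    the later value minus the earlier, per subject.
    """
    needed = {"subject", "agent", "day", value}
    missing = needed - set(table.columns)
    if missing:
        raise ValueError(f"treatment_effect table missing columns: {sorted(missing)}")
    wide = table.pivot_table(index=["subject", "agent"], columns="day", values=value)
    if day_from not in wide.columns or day_to not in wide.columns:
        raise ValueError(f"table lacks day {day_from} and/or day {day_to} measurements")
    change = (wide[day_to] - wide[day_from]).dropna().reset_index(name="change")
    groups = [g["change"].to_numpy(dtype=float) for _, g in change.groupby("agent")]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("treatment effect requires >= 2 groups with >= 2 subjects each")
    if all(np.ptp(g) == 0 for g in groups) and np.ptp([g.mean() for g in groups]) == 0:
        f_stat, p = 0.0, 1.0  # zero within- and between-group variance
    else:
        f_stat, p = (float(v) for v in sps.f_oneway(*groups))
        if not np.isfinite(p):
            p = 1.0
    return TestResult(
        contrast=f"one-way ANOVA on day {day_from}->{day_to} change in {value}",
        estimate=f_stat,
        p_value=min(max(p, 0.0), 1.0),
        n_per_group={str(a): int(len(g["change"])) for a, g in change.groupby("agent")},
    )
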