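"""Trial statistics: normality, 2x2 mixed ANOVA, Bonferroni post-hoc, Hedges g.

The trial design is a two-arm randomized comparison measured before (W0) and
after (W3) the intervention: a mixed-design ANOVA with a between-subjects
group factor and a within-subjects time factor.  Classical sums of squares
are computed in closed form; sphericity is guarded by a Greenhouse-Geisser
epsilon which is exactly 1 with two repeated measures (the correction is
implemented generically so designs with k > 2 within-levels reuse it).
When the interaction is significant, the four reported cell contrasts
(within-group W0 vs W3 per arm; between-group at each timepoint) are tested
with a Bonferroni family of 4.  Standardized pre-post differences use the
bias-corrected Hedges g with the small/medium/large labels at 0.20/0.50.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DataError, DomainError
from .types import TrialTable, TIMEPOINTS

log = logging.getLogger(__name__)

__all__ = [
    "EffectTest",
    "PairwiseTest",
    "AnovaResult",
    "EffectSize",
    "check_normality",
    "greenhouse_geisser_epsilon",
    "mixed_anova_2x2",
    "hedges_g",
    "build_table1",
]


@dataclass(frozen=True)
class EffectTest:
    F: float
    df: tuple  # (numerator, denominator) after any epsilon correction
    p: float
    epsilon: float = 1.0


@dataclass(frozen=True)
class PairwiseTest:
    label: str
    t: float
    df: float
    p_raw: float
    p_adj: float  # Bonferroni, family of 4


@dataclass
class AnovaResult:
    effects: dict  # keys "G", "T", "GxT"
    posthoc: list = field(default_factory=list)
    n_per_group: dict = field(default_factory=dict)
    outcome: str = ""


@dataclass(frozen=True)
class EffectSize:
    g: Optional[float]
    label: Optional[str]  # small / medium / large
    defined: bool = True


def check_normality(sample: Sequence[float]) -> tuple:
    """Shapiro-Wilk test; returns (W, p)."""
    x = np.asarray(sample, dtype=float)
    if x.size < 3:
        raise DomainError(f"Shapiro-Wilk needs n >= 3, got {x.size}")
    if np.ptp(x) == 0:
        raise DataError("sample is constant; normality test undefined")
    w, p = sps.shapiro(x)
    return float(w), float(p)


def greenhouse_geisser_epsilon(wide: np.ndarray) -> float:
    """Greenhouse-Geisser sphericity correction from subjects x levels data.

    Equals 1 exactly for two within-levels; bounded in [1/(k-1), 1].
    """
    y = np.asarray(wide, dtype=float)
    n, k = y.shape
    if k < 2:
        raise DomainError("need >= 2 within-subject levels")
    if k == 2:
        return 1.0
    s = np.cov(y, rowvar=False)
    mean_diag = np.trace(s) / k
    mean_all = s.mean()
    num = (k * (mean_diag - mean_all)) ** 2
    den = (k - 1) * (np.sum(s**2) - 2 * k * np.sum(s.mean(axis=1) ** 2) + k**2 * mean_all**2)
    return float(max(min(num / den, 1.0), 1.0 / (k - 1)))


def _pooled_t(a: np.ndarray, b: np.ndarray) -> tuple:
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return float(t), float(len(a) + len(b) - 2), float(p)


def mixed_anova_2x2(
    table: TrialTable,
    outcome: str,
    alpha_posthoc: float = 0.05,
) -> AnovaResult:
    """Group x time mixed ANOVA for one outcome of a two-timepoint trial.

    Subjects missing either timepoint are excluded (warning logged).  The
    Bonferroni post-hoc (family = 4 cell contrasts) is populated when the
    interaction p is below ``alpha_posthoc``.
    """
    wide = table.wide(outcome)
    missing = [tp for tp in TIMEPOINTS if tp not in wide.columns]
    if missing:
        raise DataError(f"outcome {outcome!r} lacks timepoint(s) {missing}")
    complete = wide.dropna(subset=list(TIMEPOINTS))
    dropped = len(wide) - len(complete)
    if dropped:
        log.warning("%s: excluded %d subject(s) with a missing timepoint", outcome, dropped)
    groups = sorted(complete["group"].unique())
    if len(groups) < 2:
        raise DataError(f"need two groups, found {groups}")
    y = complete[list(TIMEPOINTS)].to_numpy(float)  # subjects x k
    glab = complete["group"].to_numpy()
    n_per_group = {g: int((glab == g).sum()) for g in groups}
    if min(n_per_group.values()) < 2:
        raise DataError(f"need >= 2 subjects per group, got {n_per_group}")

    n, k = y.shape
    a = len(groups)
    grand = y.mean()
    subj_means = y.mean(axis=1)
    time_means = y.mean(axis=0)
    group_means = np.array([y[glab == g].mean() for g in groups])
    cell_means = np.array([[y[glab == g, t].mean() for t in range(k)] for g in groups])
    nj = np.array([n_per_group[g] for g in groups], dtype=float)

    ss_g = k * float(nj @ (group_means - grand) ** 2)
    ss_sg = k * sum(
        float(((subj_means[glab == g] - group_means[j]) ** 2).sum())
        for j, g in enumerate(groups)
    )
    ss_t = n * float(((time_means - grand) ** 2).sum())
    ss_gt = float(
        (nj[:, None] * (cell_means - group_means[:, None] - time_means[None, :] + grand) ** 2).sum()
    )
    resid = y.copy()
    for j, g in enumerate(groups):
        idx = glab == g
        resid[idx] -= cell_means[j][None, :]
        resid[idx] -= (subj_means[idx] - group_means[j])[:, None]
    ss_err_w = float((resid**2).sum())

    df_g, df_sg = a - 1, n - a
    df_t, df_gt = k - 1, (a - 1) * (k - 1)
    df_err_w = (n - a) * (k - 1)
    eps = greenhouse_geisser_epsilon(y)

    def eff(ss, df1, ms_err, df2, corrected: bool) -> EffectTest:
        e = eps if corrected else 1.0
        if ms_err == 0:  # degenerate (error-free) data
            f = float("inf") if ss > 0 else float("nan")
            p = 0.0 if ss > 0 else float("nan")
        else:
            f = (ss / df1) / ms_err
            p = float(sps.f.sf(f, df1 * e, df2 * e))
        return EffectTest(F=float(f), df=(df1 * e, df2 * e), p=p, epsilon=e)

    ms_sg = ss_sg / df_sg
    ms_err_w = ss_err_w / df_err_w
    effects = {
        "G": eff(ss_g, df_g, ms_sg, df_sg, corrected=False),
        "T": eff(ss_t, df_t, ms_err_w, df_err_w, corrected=True),
        "GxT": eff(ss_gt, df_gt, ms_err_w, df_err_w, corrected=True),
    }

    posthoc = []
    if effects["GxT"].p < alpha_posthoc:
        family = 4
        for j, g in enumerate(groups):
            yg = y[glab == g]
            t, p = sps.ttest_rel(yg[:, 0], yg[:, 1])
            posthoc.append(
                PairwiseTest(
                    label=f"{g}: {TIMEPOINTS[0]} vs {TIMEPOINTS[1]}",
                    t=float(t), df=float(len(yg) - 1),
                    p_raw=float(p), p_adj=min(float(p) * family, 1.0),
                )
            )
        for tcol, tp_name in enumerate(TIMEPOINTS):
            t, df, p = _pooled_t(y[glab == groups[0], tcol], y[glab == groups[1], tcol])
            posthoc.append(
                PairwiseTest(
                    label=f"{groups[0]} vs {groups[1]} at {tp_name}",
                    t=t, df=df, p_raw=p, p_adj=min(p * family, 1.0),
                )
            )
    return AnovaResult(effects=effects, posthoc=posthoc, n_per_group=n_per_group, outcome=outcome)


def hedges_g(group_a: Sequence[float], group_b: Sequence[float]) -> EffectSize:
    """Bias-corrected standardized mean difference between two samples.

    g = (mean_a - mean_b) / pooled SD x (1 - 3 / (4 df - 1)), df = n_a+n_b-2.
    Labels: small |g| < 0.20, large |g| >= 0.50, medium between.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DomainError("hedges_g needs >= 2 values per group")
    df = a.size + b.size - 2
    pooled = np.sqrt(((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df)
    if pooled == 0:
        if a.mean() == b.mean():
            return EffectSize(g=0.0, label="small", defined=True)
        return EffectSize(g=None, label=None, defined=False)
    d = (a.mean() - b.mean()) / pooled
    g = d * (1.0 - 3.0 / (4.0 * df - 1.0))
    mag = abs(g)
    label = "small" if mag < 0.20 else ("large" if mag >= 0.50 else "medium")
    return EffectSize(g=float(g), label=label, defined=True)


def build_table1(
    table: TrialTable,
    outcomes: Optional[Sequence[str]] = None,
    decimals: int = 2,
) -> pd.DataFrame:
    """Mean +/- SD per group x timepoint plus the three ANOVA p-values.

    One row per outcome; columns ``<group> <timepoint>`` hold formatted
    ``mean +/- SD`` strings at the requested precision, followed by
    ``P(G)``, ``P(T)``, ``P(GxT)``.
    """
    if table.data.empty:
        raise DataError("empty cohort")
    groups = sorted(table.data["group"].unique())
    if len(groups) < 2:
        missing = set(("COMB", "MICT")) - set(groups)
        raise DataError(f"cohort lacks group(s): {sorted(missing)}")
    outcomes = list(outcomes) if outcomes is not None else table.outcomes
    rows = {}
    for outcome in outcomes:
        row = {}
        for g in groups:
            for tp in TIMEPOINTS:
                sel = (table.data["group"] == g) & (table.data["timepoint"] == tp)
                vals = table.data.loc[sel, outcome].dropna()
                if vals.empty:
                    row[f"{g} {tp}"] = "-"
                    continue
                sd = vals.std(ddof=1) if len(vals) > 1 else 0.0
                row[f"{g} {tp}"] = f"{vals.mean():.{decimals}f} ± {sd:.{decimals}f}"
        try:
            res = mixed_anova_2x2(table, outcome)
            row["P(G)"] = round(res.effects["G"].p, 3)
            row["P(T)"] = round(res.effects["T"].p, 3)
            row["P(GxT)"] = round(res.effects["GxT"].p, 3)
        except DataError:
            row["P(G)"] = row["P(T)"] = row["P(GxT)"] = float("nan")
        rows[outcome] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "outcome"
    return out
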