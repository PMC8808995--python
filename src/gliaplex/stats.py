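"""Group comparisons and trend statistics for glial intensity data.

Marker z-scores are compared across diagnoses or states with random-
intercept mixed models (REML; subject as random effect) because cells from
one donor are not independent. State-by-diagnosis composition is tested
with the Cochran–Armitage χ² test for trend over the ordinal axis
homeostatic < intermediate < reactive. ``reconstruct_crosstab`` rebuilds a
2×3 diagnosis-by-state contingency table from a printed grand total,
within-group percentage vectors, and one cross-share percentage — the
identity ``s = p₁C / (p₁C + p₂A)`` with ``C + A = total`` pins down the two
group totals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

__all__ = [
    "MixedModelResult",
    "TrendTable",
    "fit_mixed_model",
    "chi2_trend",
    "reconstruct_crosstab",
    "compare_groups",
]


@dataclass
class MixedModelResult:
    """Fixed-effect contrasts vs the reference level of a random-intercept model."""

    contrasts: pd.DataFrame  # rows: level vs reference; estimate, se, df, t, p
    reference: str
    subject_var: float
    resid_var: float
    df_method: str  # "containment" approximate denominator df

    def __post_init__(self):
        if self.subject_var < 0 or self.resid_var < 0:
            raise ValueError("variances must be >= 0")


@dataclass
class TrendTable:
    counts: np.ndarray  # 2 × k
    scores: np.ndarray
    chi2: float
    df: int
    p: float


def fit_mixed_model(
    y: np.ndarray,
    fixed: np.ndarray,
    subject: np.ndarray,
    reference: str | None = None,
) -> MixedModelResult:
    """Random-intercept model ``y ~ fixed + (1 | subject)`` fit by REML.

    Returns pairwise contrasts of each fixed-factor level against the
    reference. p-values use a t distribution with a containment-style
    approximate denominator df (between-subject factor: n_subjects −
    n_levels; within-subject factor: residual df), flagged in
    ``df_method`` — with hundreds of cells per subject this is numerically
    close to a Satterthwaite approximation.
    """
    y = np.asarray(y, float)
    fixed = pd.Series(fixed).astype(str).reset_index(drop=True)
    subject = pd.Series(subject).astype(str).reset_index(drop=True)
    levels = sorted(fixed.unique())
    if len(levels) < 2:
        raise ValueError("fixed factor needs >= 2 levels")
    reference = reference or levels[0]
    if reference not in levels:
        raise ValueError(f"reference {reference!r} not a factor level")
    per_level = fixed.groupby(fixed).apply(lambda g: subject[g.index].nunique())
    if (per_level < 2).any():
        raise ValueError("need >= 2 subjects per fixed level")

    others = [lv for lv in levels if lv != reference]
    exog = pd.DataFrame({"Intercept": np.ones(len(y))})
    for lv in others:
        exog[lv] = (fixed == lv).astype(float)

    model = sm.MixedLM(y, exog.to_numpy(), groups=subject.to_numpy())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(reml=True)

    subject_var = max(0.0, float(np.asarray(fit.cov_re).ravel()[0]))
    resid_var = max(0.0, float(fit.scale))

    # factor is between-subject if every subject sees a single level
    between = subject.groupby(subject).apply(lambda g: fixed[g.index].nunique()).max() == 1
    n_subj = subject.nunique()
    n_obs = len(y)
    if between:
        ddf = max(1, n_subj - len(levels))
    else:
        ddf = max(1, n_obs - n_subj - (len(levels) - 1))

    rows = []
    for i, lv in enumerate(others, start=1):
        est = float(fit.params[i])
        se = float(fit.bse[i])
        tval = est / se if se > 0 else np.inf
        p = float(2 * sps.t.sf(abs(tval), ddf))
        rows.append(
            {"contrast": f"{lv} vs {reference}", "estimate": est, "se": se, "df": ddf, "t": tval, "p": p}
        )
    return MixedModelResult(
        contrasts=pd.DataFrame(rows),
        reference=reference,
        subject_var=subject_var,
        resid_var=resid_var,
        df_method="containment",
    )


def chi2_trend(table, scores=None) -> TrendTable:
    """Cochran–Armitage χ² test for trend on a 2×k table.

    Column scores default to 1..k (equally spaced over the ordinal state
    axis); df = 1 with the asymptotic χ² p-value.
    """
    counts = np.asarray(table, dtype=float)
    if counts.ndim != 2 or counts.shape[0] != 2 or counts.shape[1] < 2:
        raise ValueError("table must be 2 × k with k >= 2")
    if np.any(counts < 0):
        raise ValueError("counts must be >= 0")
    k = counts.shape[1]
    x = np.arange(1, k + 1, dtype=float) if scores is None else np.asarray(scores, float)
    r = counts[0]  # row-1 counts per column
    n = counts.sum(axis=0)  # column totals
    R = r.sum()
    N = counts.sum()
    if R == 0 or R == N:
        raise ValueError("both rows must have positive totals")
    pbar = R / N
    num = (np.sum(r * x) - R * np.sum(n * x) / N) ** 2
    den = pbar * (1 - pbar) * (np.sum(n * x**2) - np.sum(n * x) ** 2 / N)
    chi2 = float(num / den) if den > 0 else 0.0
    p = float(sps.chi2.sf(chi2, 1))
    return TrendTable(counts=counts, scores=x, chi2=chi2, df=1, p=p)


def reconstruct_crosstab(
    total: float,
    group1_props: tuple[float, float, float],
    group2_props: tuple[float, float, float],
    cross_share: float,
    share_state: int = 0,
) -> np.ndarray:
    """Rebuild a 2×3 count table from a grand total and printed percentages.

    ``group1_props``/``group2_props`` are within-group state percentages
    (summing to ~100), and ``cross_share`` is the printed percentage of
    state ``share_state`` belonging to group 1. Solving
    ``s = p₁C / (p₁C + p₂(T − C))`` for the group-1 total C yields the two
    row totals; each row is then split by its within-group proportions.
    Returns real-valued counts (rounding is the caller's choice).
    """
    p1 = np.asarray(group1_props, float) / 100.0
    p2 = np.asarray(group2_props, float) / 100.0
    s = float(cross_share) / 100.0
    if not (0 < s < 1) or np.any(p1 <= 0) or np.any(p2 <= 0):
        raise ValueError("percentages must be in (0, 100)")
    a, b = p1[share_state], p2[share_state]
    denom = a * (1 - s) + s * b
    c_total = s * b * total / denom
    if not (0 < c_total < total):
        raise ValueError("inconsistent inputs: no positive group-total solution")
    g1 = c_total * p1
    g2 = (total - c_total) * p2
    return np.vstack([g1, g2])


def compare_groups(
    matrix,
    grouping: str = "diagnosis",
    reference: str | None = None,
    subject_col: str = "subject",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One mixed model per marker plus box-plot summary statistics.

    ``matrix`` is an IntensityMatrix; ``grouping`` names a metadata column
    (diagnosis or state). Returns ``(contrast_table, summary)`` where the
    summary carries per-group medians and quartiles per marker.
    """
    meta = matrix.meta.reset_index(drop=True)
    if reference is None:
        reference = "CTRL" if grouping == "diagnosis" else "homeostatic"
    rows = []
    for mk in matrix.markers:
        res = fit_mixed_model(
            matrix.values[mk].to_numpy(),
            meta[grouping].to_numpy(),
            meta[subject_col].to_numpy(),
            reference=reference,
        )
        for _, crow in res.contrasts.iterrows():
            rows.append(
                {
                    "marker": mk,
                    "contrast": crow["contrast"],
                    "estimate": crow["estimate"],
                    "se": crow["se"],
                    "df": crow["df"],
                    "p": crow["p"],
                    "subject_var": res.subject_var,
                    "resid_var": res.resid_var,
                    "df_method": res.df_method,
                }
            )
    contrast_table = pd.DataFrame(rows)

    summ = []
    for mk in matrix.markers:
        grp = matrix.values[mk].groupby(meta[grouping])
        q = grp.quantile([0.25, 0.5, 0.75]).unstack()
        for level in q.index:
            summ.append(
                {
                    "marker": mk,
                    grouping: level,
                    "q1": q.loc[level, 0.25],
                    "median": q.loc[level, 0.5],
                    "q3": q.loc[level, 0.75],
                }
            )
    return contrast_table, pd.DataFrame(summ)
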