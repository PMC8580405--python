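"""Statistical procedures for the cohort analyses.

The harness mirrors the study's statistical toolkit: a two-way mixed-design
ANOVA (between: stimulation group; within: time) with Mauchly's sphericity
test and Greenhouse-Geisser correction, Tukey-Kramer post-hoc comparisons
(studentized-range distribution, unequal-n standard errors), Pearson
correlation between behavioral and network measures, and a Mann-Whitney U
test reported with its normal-approximation z statistic.

No multiple-comparison adjustment is applied across region x band tests by
default (the analysis is exploratory); a Benjamini-Hochberg switch is
provided for auditing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps


@dataclass
class AnovaResult:
    """One effect of a mixed-design ANOVA.

    ``p_gg`` (the Greenhouse-Geisser-corrected p) is populated for effects
    involving the within factor; ``p_report`` is the value the analysis
    uses: GG-corrected when Mauchly's test rejects sphericity (p < 0.05),
    uncorrected otherwise.
    """

    effect: str
    F: float
    df1: float
    df2: float
    p: float
    mauchly_w: float | None = None
    mauchly_p: float | None = None
    gg_epsilon: float | None = None
    p_gg: float | None = None
    sphericity_violated: bool | None = None

    @property
    def p_report(self) -> float:
        if self.sphericity_violated and self.p_gg is not None:
            return self.p_gg
        return self.p


def _check_balanced(data: pd.DataFrame, subject: str, within: str) -> None:
    levels = set(data[within].unique())
    counts = data.groupby(subject)[within].apply(
        lambda s: (set(s) == levels) and (len(s) == len(levels))
    )
    if not counts.all():
        bad = list(counts.index[~counts])
        raise ValueError(
            f"unbalanced within-subject design: subject(s) {bad} do not have "
            f"exactly one observation per {within} level"
        )


def mixed_anova(
    data: pd.DataFrame,
    dv: str,
    within: str,
    subject: str,
    between: str,
) -> list[AnovaResult]:
    """Two-way mixed-design ANOVA (between x within, repeated on within).

    Returns the between, within and interaction effects.  Mauchly's W and
    the GG epsilon are estimated on the within factor; GG-corrected p
    values are reported for the within and interaction effects by scaling
    both degrees of freedom by epsilon.

    Raises
    ------
    ValueError
        For unbalanced within-subject data or groups with < 2 subjects.
    """
    _check_balanced(data, subject, within)
    group_sizes = data.groupby(between)[subject].nunique()
    if (group_sizes < 2).any():
        raise ValueError(
            f"every group needs >= 2 subjects; sizes: {group_sizes.to_dict()}"
        )
    aov = pg.mixed_anova(
        data=data, dv=dv, within=within, subject=subject, between=between,
        correction=True,
    )
    aov = aov.set_index("Source")
    wrow = aov.loc[within]
    eps = float(wrow["eps"])
    # with 2 within levels sphericity holds trivially (W = 1, eps = 1) and
    # pingouin omits the Mauchly columns
    w = float(wrow["W_spher"]) if "W_spher" in aov.columns else 1.0
    w_p = float(wrow["p_spher"]) if "p_spher" in aov.columns else 1.0
    if not np.isfinite(w):
        w, w_p = 1.0, 1.0
    violated = bool(w_p < 0.05)

    def gg_p(F: float, df1: float, df2: float) -> float:
        return float(sps.f.sf(F, eps * df1, eps * df2))

    results = []
    brow = aov.loc[aov.index[0]]  # between effect is the first row
    results.append(AnovaResult(
        effect="group", F=float(brow["F"]), df1=float(brow["DF1"]),
        df2=float(brow["DF2"]), p=float(brow["p_unc"]),
    ))
    for name, row in (("time", wrow), ("interaction", aov.loc["Interaction"])):
        results.append(AnovaResult(
            effect=name, F=float(row["F"]), df1=float(row["DF1"]),
            df2=float(row["DF2"]), p=float(row["p_unc"]),
            mauchly_w=w, mauchly_p=w_p, gg_epsilon=eps,
            p_gg=gg_p(float(row["F"]), float(row["DF1"]), float(row["DF2"])),
            sphericity_violated=violated,
        ))
    return results


def rm_anova(
    data: pd.DataFrame, dv: str, within: str, subject: str
) -> AnovaResult:
    """One-way repeated-measures ANOVA (the within-group analysis).

    Used for per-group time effects; returns the within effect with
    Mauchly/GG diagnostics.
    """
    _check_balanced(data, subject, within)
    aov = pg.rm_anova(data=data, dv=dv, within=within, subject=subject,
                      correction=True).set_index("Source")
    row = aov.loc[within]
    eps = float(row["eps"])
    w = float(row["W_spher"]) if "W_spher" in aov.columns else 1.0
    w_p = float(row["p_spher"]) if "p_spher" in aov.columns else 1.0
    if not np.isfinite(w):
        w, w_p = 1.0, 1.0
    df1, df2 = float(row["ddof1"]), float(row["ddof2"])
    return AnovaResult(
        effect="time", F=float(row["F"]), df1=df1, df2=df2,
        p=float(row["p_unc"]), mauchly_w=w, mauchly_p=w_p, gg_epsilon=eps,
        p_gg=float(sps.f.sf(row["F"], eps * df1, eps * df2)),
        sphericity_violated=bool(w_p < 0.05),
    )


def anova_table(results: list[AnovaResult]) -> pd.DataFrame:
    """Tidy frame (effect, F, df1, df2, p, W, epsilon, p_gg, p_report)."""
    return pd.DataFrame([
        dict(effect=r.effect, F=r.F, df1=r.df1, df2=r.df2, p=r.p,
             mauchly_w=r.mauchly_w, mauchly_p=r.mauchly_p,
             gg_epsilon=r.gg_epsilon, p_gg=r.p_gg, p_report=r.p_report)
        for r in results
    ])


def tukey_kramer(groups: dict[str, np.ndarray] | list[np.ndarray]) -> pd.DataFrame:
    """Pairwise Tukey-Kramer comparisons over >= 2 independent groups.

    Uses the pooled within-group variance (MSE on N - k df) and the
    unequal-n Tukey-Kramer standard error; adjusted p values come from the
    studentized-range distribution with k groups.

    Returns a frame with columns (group_a, group_b, mean_diff, se, q, p_adj).
    """
    if isinstance(groups, dict):
        names = list(groups)
        samples = [np.asarray(groups[n], dtype=float) for n in names]
    else:
        samples = [np.asarray(g, dtype=float) for g in groups]
        names = [str(i) for i in range(len(samples))]
    k = len(samples)
    if k < 2:
        raise ValueError("need at least 2 groups")
    if any(len(s) < 2 for s in samples):
        raise ValueError("every group needs >= 2 observations")
    ns = np.array([len(s) for s in samples])
    means = np.array([s.mean() for s in samples])
    sse = sum(((s - s.mean()) ** 2).sum() for s in samples)
    df = int(ns.sum() - k)
    mse = sse / df
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = means[i] - means[j]
            se = np.sqrt(mse / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
            if se == 0:
                q, p = 0.0, 1.0
            else:
                q = abs(diff) / se
                p = float(np.clip(sps.studentized_range.sf(q, k, df), 0, 1))
            rows.append(dict(group_a=names[i], group_b=names[j],
                             mean_diff=diff, se=se, q=q, p_adj=p))
    return pd.DataFrame(rows)


def pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Sample Pearson correlation with a two-sided t-based p value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input has undefined correlation")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def mann_whitney_z(
    x: np.ndarray,
    y: np.ndarray,
    continuity: bool = False,
) -> tuple[float, float, float]:
    """Mann-Whitney U with tie-corrected normal approximation.

    Returns (U, z, p two-sided).  U counts the pairs where an x observation
    outranks a y observation (plus half-ties), so complete separation with
    x > y gives U = n1 * n2.  The continuity correction is off by default.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0
    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts)).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:  # all observations tied
        return float(u), 0.0, 1.0
    delta = u - mu
    if continuity:
        delta = np.sign(delta) * max(abs(delta) - 0.5, 0.0)
    z = delta / np.sqrt(var)
    p = float(2.0 * sps.norm.sf(abs(z)))
    return float(u), float(z), min(p, 1.0)


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """BH-adjusted p values (off by default in the pipeline; audit switch)."""
    p = np.asarray(pvals, dtype=float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    prev = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        prev = min(prev, p[idx] * m / rank)
        adj[idx] = prev
    return adj
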