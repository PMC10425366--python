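"""Group-level inference: chi-square homogeneity, Welch's t, mixed-design
repeated-measures ANOVA with Greenhouse-Geisser correction, and
Dunnett-style many-to-one post hocs.

The ANOVA machinery wraps pingouin; sphericity of the within factor is
tested with Mauchly's W and, when violated (p < 0.05), both degrees of
freedom of the within and interaction terms are multiplied by the
Greenhouse-Geisser epsilon, yielding the fractional df this field's
reports show.  Dunnett-adjusted p-values are computed from the
equicorrelated multivariate-t reference distribution by seeded Monte
Carlo, which handles unequal group sizes without tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "StatResult",
    "chi_square_homogeneity",
    "welch_t",
    "oneway_anova",
    "mixed_anova",
    "dunnett_posthoc",
    "dunnett_max_t_draws",
]


@dataclass(frozen=True)
class StatResult:
    """One inferential result: statistic, df (possibly fractional), p."""

    test: str
    statistic: float
    df: tuple[float, ...]
    p_value: float
    comparison: str = ""
    correction: str = "none"

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError("p_value must lie in [0, 1]")

    def as_dict(self) -> dict:
        return {
            "test": self.test,
            "statistic": self.statistic,
            "df": list(self.df),
            "p_value": self.p_value,
            "comparison": self.comparison,
            "correction": self.correction,
        }


def chi_square_homogeneity(counts: np.ndarray | Sequence[Sequence[int]]) -> StatResult:
    """Pearson chi-square test of homogeneity on an r x c count table.

    No continuity correction is applied.  Raises ``ValueError`` on zero
    row/column margins (expected counts must be positive).
    """
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2:
        raise ValueError("counts must be a 2-D table")
    if np.any(table.sum(axis=0) <= 0) or np.any(table.sum(axis=1) <= 0):
        raise ValueError("zero row or column margin: expected counts undefined")
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return StatResult(
        test="chi-square homogeneity",
        statistic=float(chi2),
        df=(float(dof),),
        p_value=float(p),
    )


def welch_t(x: Sequence[float], y: Sequence[float], comparison: str = "") -> StatResult:
    """Welch's unequal-variance t-test with Satterthwaite df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs n >= 2")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx + vy == 0:
        raise ValueError("both samples have zero variance")
    res = stats.ttest_ind(x, y, equal_var=False)
    nx, ny = len(x), len(y)
    df = (vx / nx + vy / ny) ** 2 / (
        (vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1)
    )
    return StatResult(
        test="Welch t",
        statistic=float(res.statistic),
        df=(float(df),),
        p_value=float(res.pvalue),
        comparison=comparison,
        correction="Satterthwaite df",
    )


def oneway_anova(
    samples: Mapping[str, Sequence[float]], comparison: str = ""
) -> StatResult:
    """One-way between-subjects ANOVA over labeled samples."""
    groups = [np.asarray(v, dtype=float) for v in samples.values()]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if all(np.ptp(g) == 0 for g in groups) and len({g[0] for g in groups}) == 1:
        f, p = 0.0, 1.0  # constant response everywhere
    else:
        f, p = stats.f_oneway(*groups)
    k = len(groups)
    n = sum(len(g) for g in groups)
    return StatResult(
        test="one-way ANOVA",
        statistic=float(f),
        df=(float(k - 1), float(n - k)),
        p_value=float(p),
        comparison=comparison,
    )


def _listwise_complete(
    data: pd.DataFrame, within: str, subject: str
) -> pd.DataFrame:
    levels = data[within].nunique()
    counts = data.groupby(subject)[within].nunique()
    complete = counts[counts == levels].index
    dropped = counts.index.difference(complete)
    if len(dropped):
        logger.warning(
            "listwise deletion: dropped %d subject(s) with missing cells", len(dropped)
        )
    return data[data[subject].isin(complete)]


def mixed_anova(
    data: pd.DataFrame,
    dv: str,
    between: str,
    within: str,
    subject: str,
    *,
    sphericity_alpha: float = 0.05,
) -> list[StatResult]:
    """Mixed-design (split-plot) repeated-measures ANOVA.

    One between-subjects factor crossed with one within-subjects factor.
    Subjects with missing within-factor cells are dropped listwise (and
    logged).  When Mauchly's test rejects sphericity at
    ``sphericity_alpha``, Greenhouse-Geisser epsilon multiplies the df of
    the within and interaction terms and their p-values are recomputed
    from the corrected F distribution.

    With a single between level the model degenerates to a one-way
    repeated-measures ANOVA and only the within effect is returned.
    """
    data = _listwise_complete(data, within, subject)
    if data.empty:
        raise ValueError("no complete subjects remain after listwise deletion")
    n_between = data[between].nunique()
    per_level = data.groupby(between)[subject].nunique()
    if n_between > 1 and (per_level < 2).any():
        raise ValueError("each between-subjects level needs >= 2 subjects")

    if float(data[dv].var(ddof=0)) == 0.0:
        # constant response: every effect is exactly zero
        k0 = data[within].nunique()
        n0 = data[subject].nunique()
        out = []
        if n_between > 1:
            out.append(
                StatResult(
                    test="mixed ANOVA (between)",
                    statistic=0.0,
                    df=(float(n_between - 1), float(n0 - n_between)),
                    p_value=1.0,
                    comparison=between,
                )
            )
        out.append(
            StatResult(
                test="mixed ANOVA (within)" if n_between > 1 else "RM ANOVA (within)",
                statistic=0.0,
                df=(float(k0 - 1), float((n0 - n_between) * (k0 - 1))),
                p_value=1.0,
                comparison=within,
            )
        )
        if n_between > 1:
            out.append(
                StatResult(
                    test="mixed ANOVA (interaction)",
                    statistic=0.0,
                    df=(
                        float((n_between - 1) * (k0 - 1)),
                        float((n0 - n_between) * (k0 - 1)),
                    ),
                    p_value=1.0,
                    comparison=f"{between} x {within}",
                )
            )
        return out

    # sphericity diagnostics on the within-subject covariance
    k = data[within].nunique()
    if k > 2:
        try:
            spher = pg.sphericity(data, dv=dv, within=within, subject=subject)
            sphericity_ok, p_spher = bool(spher[0]), float(spher[4])
            eps = float(
                pg.epsilon(data, dv=dv, within=within, subject=subject, correction="gg")
            )
        except Exception:  # degenerate covariance (e.g. constant data)
            sphericity_ok, p_spher, eps = True, 1.0, 1.0
    else:
        sphericity_ok, p_spher, eps = True, 1.0, 1.0
    if not np.isfinite(eps) or not np.isfinite(p_spher):
        sphericity_ok, p_spher, eps = True, 1.0, 1.0
    apply_gg = (not sphericity_ok) and p_spher < sphericity_alpha

    def corrected(name: str, F: float, df1: float, df2: float, comparison: str) -> StatResult:
        if not np.isfinite(F):  # constant data: no variance anywhere
            return StatResult(
                test=name, statistic=0.0, df=(df1, df2), p_value=1.0,
                comparison=comparison,
            )
        if apply_gg:
            df1c, df2c = eps * df1, eps * df2
            p = float(stats.f.sf(F, df1c, df2c))
            return StatResult(
                test=name,
                statistic=float(F),
                df=(df1c, df2c),
                p_value=p,
                comparison=comparison,
                correction=f"Greenhouse-Geisser (eps={eps:.3f})",
            )
        p = float(stats.f.sf(F, df1, df2))
        return StatResult(
            test=name, statistic=float(F), df=(df1, df2), p_value=p,
            comparison=comparison,
        )

    results: list[StatResult] = []
    if n_between == 1:
        aov = pg.rm_anova(
            data, dv=dv, within=within, subject=subject, correction=False
        )
        row = aov.iloc[0]
        results.append(
            corrected(
                "RM ANOVA (within)",
                float(row["F"]),
                float(row["ddof1"]),
                float(row["ddof2"]),
                within,
            )
        )
        return results

    aov = pg.mixed_anova(
        data, dv=dv, within=within, subject=subject, between=between,
        correction=False,
    )
    by_source = {row["Source"]: row for _, row in aov.iterrows()}
    brow = by_source[between]
    f_between = float(brow["F"])
    results.append(
        StatResult(
            test="mixed ANOVA (between)",
            statistic=f_between if np.isfinite(f_between) else 0.0,
            df=(float(brow["DF1"]), float(brow["DF2"])),
            p_value=float(stats.f.sf(f_between, brow["DF1"], brow["DF2"]))
            if np.isfinite(f_between)
            else 1.0,
            comparison=between,
        )
    )
    wrow = by_source[within]
    results.append(
        corrected(
            "mixed ANOVA (within)",
            float(wrow["F"]),
            float(wrow["DF1"]),
            float(wrow["DF2"]),
            within,
        )
    )
    irow = by_source["Interaction"]
    results.append(
        corrected(
            "mixed ANOVA (interaction)",
            float(irow["F"]),
            float(irow["DF1"]),
            float(irow["DF2"]),
            f"{between} x {within}",
        )
    )
    return results


def dunnett_max_t_draws(
    ns: Sequence[int],
    n_control: int,
    df: float,
    n_draws: int = 100_000,
    seed: int = 0,
) -> np.ndarray:
    """Monte Carlo draws of max |T_i| under the Dunnett null.

    ``T_i`` are the many-to-one t statistics of ``len(ns)`` treatment
    groups (sizes ``ns``) against a control of size ``n_control``, sharing
    one pooled-variance estimate on ``df`` degrees of freedom.  The shared
    control mean and variance estimate induce the equicorrelated
    multivariate-t dependence analytically, so drawing group means and a
    chi-square variance directly reproduces the reference distribution.
    """
    rng = np.random.default_rng(seed)
    ns = np.asarray(ns, dtype=float)
    m0 = rng.standard_normal(n_draws) / np.sqrt(n_control)
    s = np.sqrt(rng.chisquare(df, n_draws) / df)
    maxt = np.zeros(n_draws)
    for n_i in ns:
        mi = rng.standard_normal(n_draws) / np.sqrt(n_i)
        t_i = (mi - m0) / (s * np.sqrt(1.0 / n_i + 1.0 / n_control))
        np.maximum(maxt, np.abs(t_i), out=maxt)
    return maxt


def dunnett_posthoc(
    samples: Mapping[str, Sequence[float]],
    control: str = "VEH",
    *,
    n_draws: int = 100_000,
    seed: int = 0,
) -> list[StatResult]:
    """Two-sided Dunnett many-to-one comparisons against a control group.

    Each treatment group is compared with the control using pooled-variance
    t statistics; the familywise-adjusted p-value of comparison *i* is
    ``P(max_j |T_j| >= |t_i|)`` under the joint null, estimated from
    ``n_draws`` seeded Monte Carlo draws of the equicorrelated
    multivariate-t maximum.  Adjusted p-values are clamped to be at least
    the unadjusted two-sided t p-value, which holds exactly in the
    reference distribution and removes small Monte Carlo violations.
    """
    if control not in samples:
        raise ValueError(f"control label {control!r} absent from samples")
    groups = {k: np.asarray(v, dtype=float) for k, v in samples.items()}
    if len(groups) < 2:
        raise ValueError("need the control plus at least one treatment group")
    x0 = groups[control]
    others = {k: v for k, v in groups.items() if k != control}
    all_vals = list(groups.values())
    n_total = sum(len(g) for g in all_vals)
    k_groups = len(all_vals)
    df = n_total - k_groups
    if df <= 0:
        raise ValueError("not enough observations for a pooled variance")
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in all_vals)
    s2 = ss_within / df
    maxt = dunnett_max_t_draws(
        [len(v) for v in others.values()], len(x0), df, n_draws=n_draws, seed=seed
    )
    results = []
    for label, xi in others.items():
        denom = np.sqrt(s2 * (1.0 / len(xi) + 1.0 / len(x0)))
        diff = xi.mean() - x0.mean()
        if denom == 0:
            # zero pooled variance: identical data -> no evidence; any
            # mean difference with zero variance -> certain difference
            t_i = 0.0 if diff == 0 else np.inf * np.sign(diff)
        else:
            t_i = diff / denom
        p_unadj = 2.0 * stats.t.sf(abs(t_i), df)
        p_adj = float(np.mean(maxt >= abs(t_i)))
        p_adj = min(1.0, max(p_adj, p_unadj))
        results.append(
            StatResult(
                test="Dunnett",
                statistic=float(t_i),
                df=(float(df),),
                p_value=p_adj,
                comparison=f"{label} vs {control}",
                correction=f"Dunnett MC ({n_draws} draws)",
            )
        )
    return results
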