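"""Within-subject inference: repeated-measures ANOVA with
Greenhouse-Geisser correction and generalized eta-squared, Holm-corrected
paired post-hocs, and participant-level bootstrap confidence intervals.

The ANOVA is the classical fully-within-subjects factorial decomposition
with subject as a random factor: every effect is tested against its own
subject x effect interaction.  Sphericity is assessed per effect;
Greenhouse-Geisser epsilon shrinks both degrees of freedom.  Effect size
is generalized eta-squared in its fully-within form,
SS_effect / (SS_effect + SS_subjects + sum of all error SS).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "rm_anova",
    "rm_anova_array",
    "gg_epsilon",
    "mauchly_test",
    "generalized_eta_squared",
    "holm_adjust",
    "posthoc_pairwise",
    "bootstrap_ci",
    "anova_report",
]


# ---------------------------------------------------------------- helpers

def _effect_estimates(Y: np.ndarray) -> dict[tuple[int, ...], np.ndarray]:
    """Inclusion-exclusion effect estimates for every axis subset of Y.

    ``Y`` is the full subject x levels array (axis 0 = subject).  Each
    effect keeps its own axes and is reduced over the rest; estimates
    satisfy the usual sum-to-zero constraints.
    """
    axes = range(Y.ndim)
    marg: dict[tuple[int, ...], np.ndarray] = {}
    for r in range(Y.ndim + 1):
        for sub in itertools.combinations(axes, r):
            other = tuple(a for a in axes if a not in sub)
            marg[sub] = Y.mean(axis=other) if other else Y.copy()
    eff: dict[tuple[int, ...], np.ndarray] = {}
    for sub in sorted(marg, key=len):
        e = marg[sub].copy()
        for smaller in sorted(eff, key=len):
            if set(smaller) <= set(sub):
                shape = [Y.shape[a] if a in smaller else 1 for a in sub]
                e = e - eff[smaller].reshape(shape)
        eff[sub] = e
    return eff


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal contrast matrix (rows orthogonal to the mean)."""
    helmert = np.zeros((k - 1, k))
    for i in range(1, k):
        helmert[i - 1, :i] = 1.0
        helmert[i - 1, i] = -i
    return helmert / np.linalg.norm(helmert, axis=1, keepdims=True)


def gg_epsilon(scores: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon-hat from subject x level scores.

    ``scores`` holds one value per subject and within-subject level
    (k >= 2 levels).  Epsilon is computed from the eigenvalue spread of
    the covariance of the orthonormally contrasted scores and clipped to
    [1/(k-1), 1]; k = 2 gives exactly 1.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[1] < 2:
        raise ValueError("scores must be subjects x levels with >= 2 levels")
    n, k = scores.shape
    d = k - 1
    C = _orthonormal_contrasts(k)
    return _epsilon_from_cov(_contrast_cov(scores, C, n, k), d)


def _contrast_cov(scores, C, n, k):
    z = scores @ C.T
    if n <= 1:
        warnings.warn("single subject: epsilon undefined, returning 1", stacklevel=2)
        return np.eye(C.shape[0])
    return np.cov(z, rowvar=False).reshape(C.shape[0], C.shape[0])


def _epsilon_from_cov(S: np.ndarray, d: int) -> float:
    tr = np.trace(S)
    tr2 = np.trace(S @ S)
    if tr2 <= 0:
        return 1.0
    return float(np.clip(tr**2 / (d * tr2), 1.0 / d, 1.0))


def mauchly_test(S: np.ndarray, n_subjects: int) -> tuple[float, float]:
    """Mauchly's sphericity test on a contrast covariance matrix.

    Returns (W, p).  With too few subjects for a nonsingular covariance
    (n - 1 <= d) the test is undefined: returns (nan, 0.0), i.e. treated
    as a violation so a correction is applied downstream.
    """
    d = S.shape[0]
    if d == 1:
        return 1.0, 1.0
    n1 = n_subjects - 1
    sign, logdet = np.linalg.slogdet(S)
    if n1 <= d or sign <= 0:
        warnings.warn(
            "covariance singular (few subjects): sphericity test undefined, "
            "assuming violation",
            stacklevel=2,
        )
        return float("nan"), 0.0
    log_w = logdet - d * np.log(np.trace(S) / d)
    f = (2.0 * d**2 + d + 2.0) / (6.0 * d * n1)
    chi2 = -(1.0 - f) * n1 * log_w
    df = d * (d + 1) // 2 - 1
    return float(np.exp(log_w)), float(scipy.stats.chi2.sf(chi2, df))


def generalized_eta_squared(
    ss_effect: float, ss_subject: float, ss_errors: float
) -> float:
    """Generalized eta-squared for a fully within-subjects design:
    SS_effect / (SS_effect + SS_subject + sum of all error SS)."""
    denom = ss_effect + ss_subject + ss_errors
    return float(ss_effect / denom) if denom > 0 else 0.0


# ---------------------------------------------------------------- ANOVA

@dataclass
class _Effect:
    name: str
    ss: float
    df: float
    ss_err: float
    df_err: float
    epsilon: float
    mauchly_w: float
    mauchly_p: float


def rm_anova_array(
    Y: np.ndarray,
    factor_names: list[str],
    *,
    gg_policy: str = "mauchly",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Repeated-measures ANOVA on a subject x levels array.

    ``Y`` has shape (n_subjects, k1, ..., km) with one observation per
    subject per cell, m in {1, 2, 3}.  ``gg_policy`` controls when the
    Greenhouse-Geisser correction is applied: "mauchly" (default) only
    when Mauchly's test rejects at ``alpha``; "always" whenever the
    estimated epsilon is < 1; "never" reports epsilon but never corrects.
    The corrected p is reported either way.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim - 1 != len(factor_names):
        raise ValueError("factor_names must match the non-subject axes of Y")
    if not 1 <= len(factor_names) <= 3:
        raise ValueError("supports 1-3 within factors")
    if Y.shape[0] < 2:
        raise ValueError("need at least two subjects")
    if np.isnan(Y).any():
        raise ValueError("missing cells are not supported (balanced design required)")
    if gg_policy not in ("mauchly", "always", "never"):
        raise ValueError("gg_policy must be 'mauchly', 'always' or 'never'")

    n = Y.shape[0]
    eff = _effect_estimates(Y)
    total_cells = int(np.prod(Y.shape[1:]))

    def ss_of(subset: tuple[int, ...]) -> float:
        e = eff[subset]
        mult = np.prod([Y.shape[a] for a in range(Y.ndim) if a not in subset])
        return float(mult * (e**2).sum())

    ss_subject = ss_of((0,))
    factor_axes = range(1, Y.ndim)

    effects: list[_Effect] = []
    total_err = 0.0
    for r in range(1, len(factor_names) + 1):
        for sub in itertools.combinations(factor_axes, r):
            name = ":".join(factor_names[a - 1] for a in sub)
            df_e = float(np.prod([Y.shape[a] - 1 for a in sub]))
            ss_e = ss_of(sub)
            ss_err = ss_of((0,) + sub)
            df_err = (n - 1) * df_e
            # epsilon from the covariance of orthonormally contrasted
            # subject-level marginal means of this effect's cells
            marg = Y.mean(axis=tuple(a for a in factor_axes if a not in sub))
            D = marg.reshape(n, -1)
            C = _kron_contrasts([Y.shape[a] for a in sub])
            S = _contrast_cov(D, C, n, D.shape[1])
            eps = _epsilon_from_cov(S, int(df_e))
            w, p_m = mauchly_test(S, n)
            effects.append(_Effect(name, ss_e, df_e, ss_err, df_err, eps, w, p_m))
            total_err += ss_err

    # round-off floor: SS this far below the data's scale is structurally zero
    ss_total = float(((Y - Y.mean()) ** 2).sum())
    tiny = 1e-12 * max(ss_total, 1.0)

    rows = []
    for e in effects:
        ms_e = e.ss / e.df
        ms_err = e.ss_err / e.df_err if e.df_err > 0 else np.nan
        if e.ss <= tiny:
            F, p_unc, p_gg = 0.0, 1.0, 1.0
        elif ms_err > tiny:
            F = ms_e / ms_err
            p_unc = float(scipy.stats.f.sf(F, e.df, e.df_err))
            p_gg = float(scipy.stats.f.sf(F, e.df * e.epsilon, e.df_err * e.epsilon))
        else:  # nonzero effect against a zero error term
            F, p_unc, p_gg = float("inf"), 0.0, 0.0
        if gg_policy == "always":
            corrected = e.epsilon < 1.0
        elif gg_policy == "mauchly":
            corrected = e.df > 1 and e.mauchly_p < alpha
        else:
            corrected = False
        rows.append(
            {
                "effect": e.name,
                "df_num": e.df,
                "df_den": e.df_err,
                "F": F,
                "epsilon": e.epsilon,
                "mauchly_W": e.mauchly_w,
                "mauchly_p": e.mauchly_p,
                "p_uncorrected": p_unc,
                "p_GG": p_gg,
                "gg_applied": corrected,
                "p": p_gg if corrected else p_unc,
                "ges": generalized_eta_squared(e.ss, ss_subject, total_err),
                "SS": e.ss,
                "SS_error": e.ss_err,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["ss_subject"] = ss_subject
    out.attrs["n_subjects"] = n
    return out


def _kron_contrasts(ks: list[int]) -> np.ndarray:
    C = np.ones((1, 1))
    for k in ks:
        C = np.kron(C, _orthonormal_contrasts(k))
    return C


def rm_anova(
    table: pd.DataFrame,
    dv: str,
    within: list[str],
    subject: str = "participant",
    **kwargs,
) -> pd.DataFrame:
    """Repeated-measures ANOVA from a long-format table.

    Requires a complete balanced design: exactly one value per subject
    per cell (aggregate beforehand if necessary).  Factor level order
    follows first appearance in the table.  See :func:`rm_anova_array`.
    """
    levels = {f: list(pd.unique(table[f])) for f in within}
    subjects = list(pd.unique(table[subject]))
    shape = (len(subjects),) + tuple(len(levels[f]) for f in within)
    counts = table.groupby([subject] + within, sort=False)[dv].count()
    if len(counts) != int(np.prod(shape)) or (counts != 1).any():
        raise ValueError(
            "design not complete/balanced: need exactly one value per "
            "subject per cell"
        )
    idx = {f: {lv: i for i, lv in enumerate(levels[f])} for f in within}
    sidx = {s: i for i, s in enumerate(subjects)}
    Y = np.full(shape, np.nan)
    for _, row in table.iterrows():
        key = (sidx[row[subject]],) + tuple(idx[f][row[f]] for f in within)
        Y[key] = row[dv]
    out = rm_anova_array(Y, within, **kwargs)
    out.attrs["levels"] = levels
    return out


# ---------------------------------------------------------- post-hoc tests

def holm_adjust(pvals: np.ndarray) -> np.ndarray:
    """Bonferroni-Holm step-down adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(running, 1.0)
    return adj


def posthoc_pairwise(
    table: pd.DataFrame,
    dv: str,
    cell: str | list[str],
    subject: str = "participant",
) -> pd.DataFrame:
    """All pairwise paired t-tests between cells, Holm-adjusted as one family.

    ``cell`` names the column (or columns, combined) defining the
    comparison family; values are matched within subject.
    """
    df = table.copy()
    if isinstance(cell, list):
        df["_cell"] = df[cell].astype(str).agg("/".join, axis=1)
        cell = "_cell"
    wide = df.pivot_table(index=subject, columns=cell, values=dv)
    if wide.isna().any().any():
        raise ValueError("every subject must have a value in every cell")
    if len(wide) < 2:
        raise ValueError("need at least two subjects")
    cells = list(wide.columns)
    rows = []
    for a, b in itertools.combinations(cells, 2):
        x, y = wide[a].to_numpy(), wide[b].to_numpy()
        if np.allclose(x, y):
            t, p = 0.0, 1.0
        else:
            t, p = scipy.stats.ttest_rel(x, y)
        rows.append({"A": a, "B": b, "mean_diff": float(np.mean(x - y)),
                     "t": float(t), "p_raw": float(p)})
    out = pd.DataFrame(rows)
    out["p_holm"] = holm_adjust(out["p_raw"].to_numpy())
    out.attrs["family_size"] = len(rows)
    return out


def bootstrap_ci(
    values: np.ndarray,
    b: int = 10_000,
    level: float = 0.95,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Seeded percentile bootstrap CI of the mean over participants."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least two values")
    if b < 1:
        raise ValueError("need at least one resample")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(b, values.size))
    means = values[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def anova_report(anova: pd.DataFrame, dv_name: str = "") -> str:
    """APA-style text lines, one per effect."""
    lines = []
    head = f"ANOVA on {dv_name}" if dv_name else "ANOVA"
    lines.append(head)
    for _, r in anova.iterrows():
        eps = f", GG eps = {r['epsilon']:.3f}" if r["gg_applied"] else ""
        p = "< .001" if r["p"] < 0.001 else f"= {r['p']:.3f}"
        lines.append(
            f"  {r['effect']}: F({r['df_num']:g}, {r['df_den']:g}) = "
            f"{r['F']:.2f}, p {p}, ges = {r['ges']:.3f}{eps}"
        )
    return "\n".join(lines)
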