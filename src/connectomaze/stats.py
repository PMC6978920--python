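"""Group-level statistical procedures.

Three procedures recur throughout the analysis: (1) z-scoring within age
groups before pooling, so that correlations across pooled subjects are not
driven by between-group mean offsets; (2) a two-way mixed ANOVA (one
between-subject factor, one within-subject factor) via the classical
sums-of-squares decomposition with the subject-within-group error term; and
(3) a per-degree-threshold comparison of rich-club curves that runs the
mixed ANOVA independently at each k and reports contiguous significant-k
bands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as st
from statsmodels.stats.multitest import multipletests

from .connectome import RichClubCurve

__all__ = [
    "within_group_zscore",
    "pooled_correlation",
    "mixed_anova",
    "MixedAnovaResult",
    "permutation_mixed_anova",
    "posthoc_contrasts",
    "richclub_group_comparison",
    "curves_to_long",
]


def within_group_zscore(values, groups) -> np.ndarray:
    """Standardize values to mean 0, sample SD 1 within each group.

    Removes between-group location/scale differences before pooling, so a
    pooled correlation cannot be driven by a group mean offset.  Groups with
    fewer than two members or zero variance are undefined (error).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    out = np.empty_like(values)
    for g in np.unique(groups):
        m = groups == g
        if m.sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 members")
        sd = values[m].std(ddof=1)
        if sd == 0:
            raise ValueError(f"group {g!r} has zero variance")
        out[m] = (values[m] - values[m].mean()) / sd
    return out


def pooled_correlation(x, y) -> tuple[float, float, float]:
    """Pearson R with its F statistic and two-sided p.

    F = R^2 (n-2) / (1 - R^2) on (1, n-2) degrees of freedom; p from the F
    distribution (identical to the two-sided t test on R).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need paired 1-d samples with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("values must be finite")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r = float(np.corrcoef(x, y)[0, 1])
    n = x.size
    if abs(r) >= 1.0:
        return r, np.inf, 0.0
    f = r**2 * (n - 2) / (1 - r**2)
    p = float(st.f.sf(f, 1, n - 2))
    return r, float(f), p


@dataclass
class MixedAnovaResult:
    """F tests for the between factor, within factor and their interaction."""

    f_between: float
    p_between: float
    df_between: tuple[int, int]
    f_within: float
    p_within: float
    df_within: tuple[int, int]
    f_interaction: float
    p_interaction: float
    df_interaction: tuple[int, int]


def _anova_from_cube(Y: np.ndarray, group_sizes: np.ndarray) -> tuple[float, float, float]:
    """F statistics from a subjects x sessions value cube, subjects sorted by
    group.  Returns (F_between, F_within, F_interaction); df derive from the
    shape.  Balanced designs only."""
    n_per = group_sizes[0]
    a = group_sizes.size
    b = Y.shape[1]
    grand = Y.mean()
    subj_means = Y.mean(axis=1)
    G = Y.reshape(a, n_per, b)
    group_means = G.mean(axis=(1, 2))
    sess_means = Y.mean(axis=0)
    cell_means = G.mean(axis=1)  # (a, b)

    ss_between_subj = b * ((subj_means - grand) ** 2).sum()
    ss_a = n_per * b * ((group_means - grand) ** 2).sum()
    ss_subj_within = ss_between_subj - ss_a
    ss_b = a * n_per * ((sess_means - grand) ** 2).sum()
    ss_ab = n_per * ((cell_means - group_means[:, None] - sess_means[None, :] + grand) ** 2).sum()
    ss_total = ((Y - grand) ** 2).sum()
    ss_err = ss_total - ss_between_subj - ss_b - ss_ab

    df_a, df_subj = a - 1, a * (n_per - 1)
    df_b = b - 1
    df_ab = df_a * df_b
    df_err = df_subj * df_b
    tol = 1e-12 * max(float(ss_total), np.finfo(float).tiny)

    def f_ratio(ss_eff, df_eff, ss_e, df_e):
        if ss_e > tol:
            return (ss_eff / df_eff) / (ss_e / df_e)
        # degenerate zero error term: effect either absent or infinitely clear
        return 0.0 if ss_eff <= tol else np.inf

    f_a = f_ratio(ss_a, df_a, ss_subj_within, df_subj)
    f_b = f_ratio(ss_b, df_b, ss_err, df_err)
    f_ab = f_ratio(ss_ab, df_ab, ss_err, df_err)
    return f_a, f_b, f_ab


def _validate_long(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list]:
    required = {"subject", "group", "session", "value"}
    if not required.issubset(table.columns):
        raise ValueError(f"long table needs columns {sorted(required)}")
    g_per_subj = table.groupby("subject")["group"].nunique()
    if (g_per_subj > 1).any():
        raise ValueError("each subject must belong to exactly one group")
    wide = table.pivot_table(index="subject", columns="session", values="value",
                             aggfunc="mean")
    if wide.isna().any().any():
        raise ValueError("unbalanced design: missing subject x session cells")
    groups = table.drop_duplicates("subject").set_index("subject")["group"]
    groups = groups.loc[wide.index]
    order = np.argsort(groups.to_numpy(), kind="stable")
    Y = wide.to_numpy()[order]
    glab = groups.to_numpy()[order]
    sizes = pd.Series(glab).value_counts(sort=False).to_numpy()
    if len(set(sizes.tolist())) != 1:
        raise ValueError("unbalanced design: unequal group sizes")
    return Y, sizes, list(pd.unique(glab))


def _gg_epsilon(Y: np.ndarray, group_sizes: np.ndarray) -> float:
    """Greenhouse-Geisser sphericity epsilon from the pooled within-group
    covariance of the repeated measures."""
    b = Y.shape[1]
    n_per = group_sizes[0]
    G = Y.reshape(group_sizes.size, n_per, b)
    S = np.zeros((b, b))
    for g in G:
        S += np.cov(g, rowvar=False, ddof=1)
    S /= group_sizes.size
    C = np.eye(b) - np.full((b, b), 1.0 / b)
    M = C @ S @ C
    tr = np.trace(M)
    denom = (b - 1) * np.trace(M @ M)
    if denom <= 0:
        return 1.0
    return float(np.clip(tr**2 / denom, 1.0 / (b - 1), 1.0))


def mixed_anova(table: pd.DataFrame, gg_correction: bool = False) -> MixedAnovaResult:
    """Two-way mixed ANOVA on a long table with columns
    ``subject, group, session, value``.

    Between-factor F uses the subject-within-group mean square as error;
    within-factor and interaction F use the residual within-subject mean
    square.  No sphericity correction is applied by default (the reported
    df are the classical uncorrected ones); ``gg_correction=True`` scales
    the within-subject df by the Greenhouse-Geisser epsilon when computing
    p-values.  Balanced designs only — unbalanced input is an explicit
    error.
    """
    Y, sizes, _ = _validate_long(table)
    a, b, n_per = sizes.size, Y.shape[1], sizes[0]
    if a < 2 or b < 2 or n_per < 2:
        raise ValueError("need >= 2 groups, >= 2 sessions, >= 2 subjects per group")
    f_a, f_b, f_ab = _anova_from_cube(Y, sizes)
    df_a, df_subj = a - 1, a * (n_per - 1)
    df_b, df_err = b - 1, a * (n_per - 1) * (b - 1)
    df_ab = df_a * df_b
    eps = _gg_epsilon(Y, sizes) if gg_correction else 1.0
    return MixedAnovaResult(
        f_between=f_a, p_between=float(st.f.sf(f_a, df_a, df_subj)),
        df_between=(df_a, df_subj),
        f_within=f_b, p_within=float(st.f.sf(f_b, eps * df_b, eps * df_err)),
        df_within=(df_b, df_err),
        f_interaction=f_ab,
        p_interaction=float(st.f.sf(f_ab, eps * df_ab, eps * df_err)),
        df_interaction=(df_ab, df_err),
    )


def posthoc_contrasts(table: pd.DataFrame, alpha: float = 0.05,
                      correction: str = "bonferroni") -> pd.DataFrame:
    """Per-session two-sample t contrasts between the two groups.

    The per-comparison threshold is ``alpha / n_sessions`` under Bonferroni
    correction (``correction='none'`` disables it); both the raw p and the
    corrected threshold are reported.
    """
    if correction not in ("bonferroni", "none"):
        raise ValueError("correction must be 'bonferroni' or 'none'")
    Y, sizes, group_names = _validate_long(table)
    if sizes.size != 2:
        raise ValueError("contrasts require exactly two groups")
    n_per = sizes[0]
    sessions = sorted(table["session"].unique())
    thresh = alpha / len(sessions) if correction == "bonferroni" else alpha
    rows = []
    for j, session in enumerate(sessions):
        t, p = st.ttest_ind(Y[:n_per, j], Y[n_per:, j])
        rows.append({"session": session, "t": float(t), "p": float(p),
                     "alpha_corrected": thresh, "significant": bool(p < thresh)})
    return pd.DataFrame(rows)


def permutation_mixed_anova(table: pd.DataFrame, n_perm: int = 10_000,
                            rng_seed: int = 0) -> dict[str, float]:
    """Permutation p-values as a cross-check on the parametric mixed ANOVA.

    Group labels are permuted at the subject level (between factor and
    interaction); session labels are permuted within subjects (within
    factor).  Returns ``{'p_between', 'p_within', 'p_interaction'}``.
    """
    Y, sizes, _ = _validate_long(table)
    rng = np.random.default_rng(rng_seed)
    f_a0, f_b0, f_ab0 = _anova_from_cube(Y, sizes)
    n_subj, b = Y.shape
    ge_a = ge_b = ge_ab = 1  # observed stat counted once (permutation-test convention)
    for _ in range(n_perm):
        perm = rng.permutation(n_subj)
        f_a, _, f_ab = _anova_from_cube(Y[perm], sizes)
        Yw = Y[np.arange(n_subj)[:, None], np.argsort(rng.random((n_subj, b)), axis=1)]
        _, f_b, _ = _anova_from_cube(Yw, sizes)
        ge_a += f_a >= f_a0
        ge_b += f_b >= f_b0
        ge_ab += f_ab >= f_ab0
    return {
        "p_between": ge_a / (n_perm + 1),
        "p_within": ge_b / (n_perm + 1),
        "p_interaction": ge_ab / (n_perm + 1),
    }


def curves_to_long(curves: dict[tuple[str, str, int], RichClubCurve],
                   k_range: np.ndarray) -> pd.DataFrame:
    """Flatten per-(subject, group, session) rich-club curves to a long
    table with one row per subject x session x k (undefined entries NaN)."""
    rows = []
    for (subject, group, session), curve in curves.items():
        lookup = dict(zip(curve.k_values.tolist(), zip(curve.phi, curve.defined)))
        for k in k_range:
            phi, defined = lookup.get(int(k), (np.nan, False))
            rows.append({"subject": subject, "group": group, "session": session,
                         "k": int(k), "value": float(phi) if defined else np.nan})
    return pd.DataFrame(rows)


def richclub_group_comparison(
    long: pd.DataFrame,
    alpha: float = 0.05,
    effect: str = "interaction",
    fdr: bool = False,
) -> pd.DataFrame:
    """Mixed ANOVA independently at each degree threshold k.

    ``long`` needs columns ``subject, group, session, k, value``.  k levels
    with missing or insufficient data are flagged undefined.  The returned
    frame carries per-k F/p for all three effects plus a boolean
    ``significant`` column for the chosen effect at ``alpha`` (uncorrected
    by default, mirroring shaded-band presentation; ``fdr=True`` switches to
    Benjamini-Hochberg across k) and a ``band`` id labelling contiguous
    significant runs.
    """
    if effect not in ("between", "within", "interaction"):
        raise ValueError("effect must be 'between', 'within' or 'interaction'")
    rows = []
    for k, sub in long.groupby("k", sort=True):
        sub = sub.dropna(subset=["value"])
        row = {"k": int(k), "defined": False}
        try:
            res = mixed_anova(sub)
        except ValueError:
            rows.append(row)
            continue
        row.update({
            "defined": True,
            "f_between": res.f_between, "p_between": res.p_between,
            "f_within": res.f_within, "p_within": res.p_within,
            "f_interaction": res.f_interaction, "p_interaction": res.p_interaction,
        })
        rows.append(row)
    out = pd.DataFrame(rows)
    pcol = f"p_{effect}"
    pvals = out.loc[out["defined"], pcol].to_numpy() if out["defined"].any() else np.array([])
    sig = np.zeros(len(out), dtype=bool)
    if pvals.size:
        if fdr:
            rej, *_ = multipletests(pvals, alpha=alpha, method="fdr_bh")
        else:
            rej = pvals < alpha
        sig[out["defined"].to_numpy()] = rej
    out["significant"] = sig
    band = np.zeros(len(out), dtype=int)
    current = 0
    prev = False
    for i, s in enumerate(sig):
        if s and not prev:
            current += 1
        band[i] = current if s else 0
        prev = s
    out["band"] = band
    return out
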