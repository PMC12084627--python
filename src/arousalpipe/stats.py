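"""The study's statistical layer.

Paired/one-sample location tests with Cohen's d, Holm sequential
Bonferroni, fully within-subject ANOVA (1-3 factors) with
Greenhouse-Geisser correction, repeated-measures correlation, ordinary
Pearson/Spearman correlations, and the Meng-Rosenthal-Rubin z test for
dependent correlations.  Everything except the textbook distribution
functions (scipy.stats) and the Wilcoxon normal approximation is computed
from the defining formulas so that tests can check it against independent
oracles.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sstats
from scipy.linalg import helmert


@dataclass
class TestResult:
    name: str
    statistic: float
    df: tuple[float, ...] | float
    p: float
    effect_size: float | None = None      # Cohen's d or partial eta squared
    effect_size_name: str | None = None
    mean_difference: float | None = None
    epsilon: float | None = None          # GG epsilon where applicable

    def summary(self) -> str:
        df = self.df if not isinstance(self.df, tuple) else \
            ",".join(f"{d:g}" for d in self.df)
        es = "" if self.effect_size is None else \
            f", {self.effect_size_name}={self.effect_size:.3f}"
        return (f"{self.name}: stat({df})={self.statistic:.3f}, "
                f"p={self.p:.4g}{es}")


# --------------------------------------------------------------------------
# location tests
# --------------------------------------------------------------------------


def _exact_wilcoxon_p(d: np.ndarray) -> tuple[float, float]:
    """Exact two-sided signed-rank p via the rank-sum polynomial.

    Handles midranks (ties) by doubling ranks to integers; zeros are
    dropped beforehand.
    """
    r = sstats.rankdata(np.abs(d))
    r2 = np.round(2 * r).astype(int)
    w_plus = float(np.sum(r[d > 0]))
    # distribution of doubled W+ as polynomial product of (1 + z^r2_i)
    total = int(r2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for ri in r2:
        shifted = np.zeros_like(dist)
        shifted[ri:] = dist[:total + 1 - ri]
        dist = dist + shifted
    dist /= dist.sum()
    w2 = int(round(2 * w_plus))
    cdf = dist[: w2 + 1].sum()
    sf = dist[w2:].sum()
    return w_plus, float(min(1.0, 2 * min(cdf, sf)))


def paired_location_test(x, y=None, method: str = "t",
                         name: str = "paired") -> TestResult:
    """Two-sided paired t or Wilcoxon signed-rank test.

    With ``y=None`` the test is one-sample against zero.  The t variant
    reports Cohen's d for paired data (mean difference / SD of
    differences).  The Wilcoxon uses the exact signed-rank distribution up
    to n=25 and the normal approximation with continuity correction above.
    """
    x = np.asarray(x, float)
    if y is not None and len(x) != len(np.asarray(y)):
        raise ValueError("paired samples must have equal length")
    d = x if y is None else x - np.asarray(y, float)
    n = d.size
    if method == "t":
        if n < 2:
            raise ValueError("need >= 2 pairs")
        sd = d.std(ddof=1)
        md = d.mean()
        if sd == 0:
            t = 0.0 if md == 0 else np.inf * np.sign(md)
            p = 1.0 if md == 0 else 0.0
            cd = 0.0 if md == 0 else np.inf * np.sign(md)
        else:
            t = md / (sd / np.sqrt(n))
            p = 2 * sstats.t.sf(abs(t), n - 1)
            cd = md / sd
        return TestResult(name, float(t), float(n - 1), float(p), float(cd),
                          "cohen_d", float(md))
    if method == "wilcoxon":
        nz = d[d != 0]
        if nz.size == 0:
            return TestResult(name, 0.0, float(n), 1.0,
                              mean_difference=float(d.mean()))
        if nz.size <= 25:
            w, p = _exact_wilcoxon_p(nz)
        else:
            w, p = sstats.wilcoxon(nz, correction=True, method="approx")
        return TestResult(name, float(w), float(nz.size), float(p),
                          mean_difference=float(d.mean()))
    raise ValueError(f"unknown method {method!r}")


def holm_sequential_bonferroni(p_values) -> np.ndarray:
    """Holm step-down adjusted p values, returned in the input order."""
    p = np.asarray(p_values, float)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, min(1.0, (m - rank) * p[idx]))
        adj[idx] = running
    return adj


# --------------------------------------------------------------------------
# within-subject ANOVA
# --------------------------------------------------------------------------


def _r_term(df: pd.DataFrame, cols: list[str], value: str) -> float:
    if not cols:
        return float(df[value].sum() ** 2 / len(df))
    g = df.groupby(cols, observed=True)[value]
    return float((g.sum() ** 2 / g.size()).sum())


def _gg_epsilon(df: pd.DataFrame, subject: str, factors: list[str],
                value: str) -> float:
    """Greenhouse-Geisser epsilon from orthonormal effect contrasts."""
    wide = df.groupby([subject] + factors, observed=True)[value].mean().unstack(
        factors if len(factors) > 1 else factors[0])
    wide = wide.sort_index(axis=1)
    Y = wide.to_numpy()
    mats = []
    levels = [df[f].nunique() for f in factors]
    for k in levels:
        mats.append(helmert(k, full=False))
    M = mats[0]
    for m in mats[1:]:
        M = np.kron(M, m)
    Z = Y @ M.T
    S = np.cov(Z, rowvar=False, ddof=1)
    S = np.atleast_2d(S)
    d = S.shape[0]
    tr = np.trace(S)
    denom = d * np.sum(S * S)
    if denom <= 0:
        return 1.0
    eps = tr ** 2 / denom
    return float(np.clip(eps, 1.0 / d, 1.0))


def rm_anova(data: pd.DataFrame, dv: str, within: list[str] | str,
             subject: str = "participant",
             gg_policy: str = "when_violated") -> pd.DataFrame:
    """Fully within-subject ANOVA for 1-3 factors on balanced data.

    Sums of squares come from the classical balanced-factorial
    decomposition; each effect is tested against its interaction with
    subjects.  Greenhouse-Geisser epsilon is computed per effect from the
    double-centered covariance of orthonormal contrast scores and applied
    to the dfs whenever epsilon < 1 for effects with more than one df
    (``gg_policy='when_violated'``; 'never' and 'always' are available).

    Returns one row per effect with SS, df, F, p (and GG-corrected p),
    partial eta squared and epsilon.
    """
    within = [within] if isinstance(within, str) else list(within)
    if not 1 <= len(within) <= 3:
        raise ValueError("1-3 within factors supported")
    df = data[[subject] + within + [dv]].copy()
    counts = df.groupby([subject] + within, observed=True).size()
    n_cells = df[subject].nunique() * int(
        np.prod([df[f].nunique() for f in within]))
    if counts.nunique() != 1 or len(counts) != n_cells:
        raise ValueError("design must be complete and balanced "
                         "(aggregate replicates first)")
    if counts.iloc[0] != 1:
        df = df.groupby([subject] + within, observed=True,
                        as_index=False)[dv].mean()

    n_subj = df[subject].nunique()
    levels = {f: df[f].nunique() for f in within}

    def ss(term: list[str]) -> float:
        total = 0.0
        for k in range(len(term) + 1):
            for sub in combinations(term, k):
                total += (-1) ** (len(term) - k) * _r_term(df, list(sub), dv)
        return total

    rows = []
    for k in range(1, len(within) + 1):
        for eff in combinations(within, k):
            eff = list(eff)
            ss_eff = ss(eff)
            ss_err = ss(eff + [subject])
            df_eff = int(np.prod([levels[f] - 1 for f in eff]))
            df_err = df_eff * (n_subj - 1)
            ms_eff = ss_eff / df_eff
            ms_err = ss_err / df_err
            F = ms_eff / ms_err if ms_err > 0 else np.inf
            p = float(sstats.f.sf(F, df_eff, df_err))
            eps = _gg_epsilon(df, subject, eff, dv) if df_eff > 1 else 1.0
            apply_gg = {"never": False, "always": df_eff > 1,
                        "when_violated": df_eff > 1 and eps < 1.0}[gg_policy]
            p_gg = float(sstats.f.sf(F, eps * df_eff, eps * df_err)) \
                if apply_gg else p
            rows.append({
                "effect": "*".join(eff), "ss": ss_eff, "ss_error": ss_err,
                "df": df_eff, "df_error": df_err, "F": float(F), "p": p,
                "epsilon": eps, "p_gg": p_gg, "gg_applied": apply_gg,
                "eta_p2": ss_eff / (ss_eff + ss_err)
                if (ss_eff + ss_err) > 0 else np.nan})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# correlations
# --------------------------------------------------------------------------


@dataclass
class RmCorrResult:
    r_rm: float
    df: int
    p: float
    n_subjects: int
    n_obs: int


def rm_correlation(x, y, subjects, z_score_within: bool = False
                   ) -> RmCorrResult:
    """Repeated-measures correlation (common slope, subject intercepts).

    Equivalent to the analysis-of-covariance decomposition: both variables
    are centered within subject, the shared slope is fitted, and r_rm =
    sign(slope) * sqrt(SS_measure / (SS_measure + SS_error)) with df =
    N_obs - n_subjects - 1.  With ``z_score_within`` each subject's values
    are z-scored first (as done for slope-vs-P300 condition averages).
    Subjects with fewer than 2 observations are dropped with a warning.
    """
    df = pd.DataFrame({"x": np.asarray(x, float), "y": np.asarray(y, float),
                       "s": np.asarray(subjects)}).dropna()
    sizes = df.groupby("s").size()
    small = sizes[sizes < 2].index
    if len(small):
        import warnings
        warnings.warn(f"dropping {len(small)} subject(s) with <2 observations")
        df = df[~df["s"].isin(small)]
    if df.empty or df["s"].nunique() < 2:
        raise ValueError("need >= 2 subjects with >= 2 observations")

    if z_score_within:
        for col in ("x", "y"):
            g = df.groupby("s")[col]
            sd = g.transform(lambda v: v.std(ddof=1))
            if (sd == 0).any():
                bad = df.loc[sd == 0, "s"].unique()
                df = df[~df["s"].isin(bad)]
            g = df.groupby("s")[col]
            df[col] = (df[col] - g.transform("mean")) / \
                g.transform(lambda v: v.std(ddof=1))

    xc = df["x"] - df.groupby("s")["x"].transform("mean")
    yc = df["y"] - df.groupby("s")["y"].transform("mean")
    sxy = float((xc * yc).sum())
    sxx = float((xc ** 2).sum())
    syy = float((yc ** 2).sum())
    if sxx == 0 or syy == 0:
        raise ValueError("a variable is constant within subjects")
    slope = sxy / sxx
    ss_measure = sxy ** 2 / sxx
    ss_error = syy - ss_measure
    r = np.sign(slope) * np.sqrt(ss_measure / (ss_measure + ss_error))
    n_obs = len(df)
    n_subj = df["s"].nunique()
    dof = n_obs - n_subj - 1
    if dof < 1:
        raise ValueError("not enough observations for the rm correlation")
    F = ss_measure / (ss_error / dof) if ss_error > 0 else np.inf
    p = float(sstats.f.sf(F, 1, dof))
    return RmCorrResult(float(r), int(dof), p, n_subj, n_obs)


def correlation(x, y, method: str = "pearson",
                name: str = "correlation") -> TestResult:
    """Pearson or Spearman correlation with a two-sided p value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length inputs of size >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for constant input")
    if method == "pearson":
        r, p = sstats.pearsonr(x, y)
    elif method == "spearman":
        r, p = sstats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return TestResult(name, float(r), float(x.size - 2), float(p))


def meng_dependent_correlation_z(r_jk: float, r_jh: float, r_kh: float,
                                 n: int) -> tuple[float, float]:
    """Meng-Rosenthal-Rubin z for two dependent correlations sharing j.

    z = (z_jk - z_jh) * sqrt((n-3) / (2 (1 - r_kh) h)) with
    f = min(1, (1 - r_kh) / (2 (1 - rbar^2))), h = (1 - f rbar^2)/(1 - rbar^2),
    rbar^2 = (r_jk^2 + r_jh^2)/2; two-sided normal p.
    """
    if n <= 3:
        raise ValueError("need n > 3")
    for r in (r_jk, r_jh, r_kh):
        if not -1 < r < 1:
            raise ValueError("correlations must lie strictly inside (-1, 1)")
    zjk = np.arctanh(r_jk)
    zjh = np.arctanh(r_jh)
    rbar2 = (r_jk ** 2 + r_jh ** 2) / 2
    f = min(1.0, (1 - r_kh) / (2 * (1 - rbar2)))
    h = (1 - f * rbar2) / (1 - rbar2)
    z = (zjk - zjh) * np.sqrt((n - 3) / (2 * (1 - r_kh) * h))
    p = 2 * sstats.norm.sf(abs(z))
    return float(z), float(p)
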