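"""The study's statistical battery.

Clinical scores (one value per participant) are compared across the three
groups with Kruskal-Wallis plus Dunn's rank-based post-hoc z-tests.
Per-cycle gait parameters are analysed with a linear mixed model: every
valid gait cycle is a unit of observation, group is the fixed effect and
each participant gets a random intercept, fitted per speed condition by
REML.  Shapiro-Wilk screens normality (annotation only — it does not
switch tests).  False-discovery-rate control uses the one-stage
Benjamini-Hochberg step-up procedure (Benjamini-Yekutieli selectable).

The mixed-model group test converts the Wald statistic to an F with
denominator degrees of freedom ``n_subjects - n_groups``.  For balanced
designs this equals one-way ANOVA on subject means exactly, so the test is
exactly calibrated there; Kenward-Roger style corrections matter only for
unbalanced smaller designs and are noted as a limitation.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

ALPHA = 0.05
PAIRS = (("HS", "BV"), ("HS", "UV"), ("UV", "BV"))


@dataclass
class GroupStatsResult:
    """Overall and pairwise comparison of one outcome across groups."""

    outcome: str
    test: str
    statistic: float
    p_value: float
    pairwise: dict[tuple[str, str], float] = field(default_factory=dict)
    pairwise_adjusted: dict[tuple[str, str], float] = field(default_factory=dict)
    effect_direction: dict[str, float] = field(default_factory=dict)
    n_per_group: dict[str, int] = field(default_factory=dict)
    adjusted_p: float = float("nan")
    flags: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Kruskal-Wallis + Dunn
# ---------------------------------------------------------------------------

def kw_dunn(values_by_group: dict[str, np.ndarray], *,
            outcome: str = "") -> GroupStatsResult:
    """Kruskal-Wallis H (tie-corrected) with Dunn's pairwise z-tests.

    Groups with fewer than 2 observations are excluded with a flag.  Dunn
    p values are two-sided and reported both raw and BH-adjusted across the
    pairs of this outcome.
    """
    flags = []
    groups = {}
    for g, v in values_by_group.items():
        v = np.asarray(v, dtype=float)
        v = v[np.isfinite(v)]
        if len(v) < 2:
            flags.append(f"group {g} excluded (<2 observations)")
            continue
        groups[g] = v
    if len(groups) < 2:
        raise ValueError("need at least 2 groups with >= 2 observations")

    names = list(groups)
    pooled = np.concatenate([groups[g] for g in names])
    if np.ptp(pooled) == 0:
        H, p = 0.0, 1.0
    else:
        H, p = sps.kruskal(*[groups[g] for g in names])

    # Dunn: z on mean ranks with tie correction
    ranks = sps.rankdata(pooled)
    N = len(pooled)
    bounds = np.cumsum([0] + [len(groups[g]) for g in names])
    mean_rank = {g: ranks[bounds[i]:bounds[i + 1]].mean()
                 for i, g in enumerate(names)}
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12 * (N - 1)) if N > 1 else 0.0
    var_unit = N * (N + 1) / 12.0 - tie_term

    pairwise = {}
    for a, b in itertools.combinations(names, 2):
        key = _canonical_pair(a, b)
        se = np.sqrt(var_unit * (1 / len(groups[a]) + 1 / len(groups[b])))
        if se == 0:
            pairwise[key] = 1.0
            continue
        z = (mean_rank[a] - mean_rank[b]) / se
        pairwise[key] = float(2 * sps.norm.sf(abs(z)))
    adj = dict(zip(pairwise, fdr_adjust(list(pairwise.values()))))

    return GroupStatsResult(
        outcome=outcome, test="kruskal_wallis_dunn", statistic=float(H),
        p_value=float(p), pairwise=pairwise, pairwise_adjusted=adj,
        effect_direction={g: float(np.median(v)) for g, v in groups.items()},
        n_per_group={g: int(len(v)) for g, v in groups.items()}, flags=flags)


def _canonical_pair(a: str, b: str) -> tuple[str, str]:
    for pair in PAIRS:
        if {a, b} == set(pair):
            return pair
    return tuple(sorted((a, b)))


# ---------------------------------------------------------------------------
# Mixed model on per-cycle observations
# ---------------------------------------------------------------------------

def mixed_model(df: pd.DataFrame, value: str, *, group: str = "group",
                subject: str = "subject", outcome: str = "",
                ) -> GroupStatsResult:
    """Group comparison of per-cycle values with a participant random intercept.

    ``df`` holds one row per gait cycle.  The group fixed effect is tested
    with a Wald F (denominator df = subjects − groups); pairwise contrasts
    are t-tests on the fitted coefficients with the same df.  With a single
    cycle per subject the random intercept is unidentifiable and the model
    falls back, flagged, to ordinary one-way ANOVA on the same data.
    """
    data = df[[value, group, subject]].dropna()
    levels = sorted(data[group].unique(),
                    key=lambda g: (["HS", "UV", "BV"].index(g)
                                   if g in ("HS", "UV", "BV") else 99))
    n_groups = len(levels)
    if n_groups < 2:
        raise ValueError("need at least 2 groups")
    counts = data.groupby(group)[subject].nunique()
    if (counts < 2).any():
        raise ValueError("need at least 2 participants per group")
    n_subjects = int(data[subject].nunique())

    if float(np.ptp(data[value].to_numpy())) == 0.0:
        return GroupStatsResult(
            outcome=outcome, test="mixed_model", statistic=float("nan"),
            p_value=float("nan"),
            n_per_group=counts.to_dict(),
            flags=["degenerate: zero variance, no test computed"])

    flags = []
    cycles_per_subject = data.groupby(subject)[value].size()
    X = pd.get_dummies(pd.Categorical(data[group], categories=levels),
                       drop_first=True, dtype=float)
    X.insert(0, "const", 1.0)
    coef_names = list(X.columns)

    if (cycles_per_subject < 2).all():
        beta, cov, dfden, flags = _ols_fallback(data, value, X, n_subjects,
                                                n_groups, flags)
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = MixedLM(data[value].to_numpy(float), X.to_numpy(),
                          groups=data[subject].to_numpy()).fit(reml=True)
        beta = np.asarray(fit.fe_params, dtype=float)
        cov = np.asarray(fit.cov_params(), dtype=float)[:len(beta), :len(beta)]
        dfden = n_subjects - n_groups
        if not fit.converged:
            flags.append("mixed model did not converge; OLS fallback")
            beta, cov, dfden, flags = _ols_fallback(data, value, X, n_subjects,
                                                    n_groups, flags)
        elif float(np.asarray(fit.cov_re).squeeze()) == 0.0:
            flags.append("random-intercept variance estimated at boundary 0")

    q = n_groups - 1
    sub = np.s_[1:1 + q]
    W = float(beta[sub] @ np.linalg.solve(cov[sub, sub], beta[sub]))
    p = float(sps.f.sf(W / q, q, dfden))

    means = data.groupby(group)[value].mean().to_dict()
    pairwise = {}
    for i, a in enumerate(levels):
        for b in levels[i + 1:]:
            key = _canonical_pair(a, b)
            c = np.zeros(len(beta))
            if a != levels[0]:
                c[1 + levels.index(a) - 1] = 1.0
            if b != levels[0]:
                c[1 + levels.index(b) - 1] -= 1.0
            est = float(c @ beta)
            se = float(np.sqrt(c @ cov @ c))
            pairwise[key] = float(2 * sps.t.sf(abs(est) / se, dfden)) \
                if se > 0 else 1.0
    adj = dict(zip(pairwise, fdr_adjust(list(pairwise.values()))))

    return GroupStatsResult(
        outcome=outcome, test="mixed_model", statistic=W / q, p_value=p,
        pairwise=pairwise, pairwise_adjusted=adj,
        effect_direction={g: float(means[g]) for g in levels},
        n_per_group=counts.to_dict(), flags=flags)


def _ols_fallback(data, value, X, n_subjects, n_groups, flags):
    y = data[value].to_numpy(float)
    Xn = X.to_numpy()
    beta, *_ = np.linalg.lstsq(Xn, y, rcond=None)
    resid = y - Xn @ beta
    dfden = len(y) - n_groups
    sigma2 = float(resid @ resid) / dfden
    cov = sigma2 * np.linalg.inv(Xn.T @ Xn)
    flags = flags + ["single observation per subject: ordinary ANOVA"]
    return beta, cov, dfden, flags


def mixed_model_by_speed(cycles: pd.DataFrame, parameters, *,
                         speed: str = "speed") -> pd.DataFrame:
    """Fit :func:`mixed_model` per speed stratum and parameter; tidy output.

    Overall p values are FDR-adjusted across all strata × parameters (the
    full family of gait comparisons).
    """
    rows = []
    results = []
    for sp in cycles[speed].unique():
        stratum = cycles[cycles[speed] == sp]
        for p in parameters:
            res = mixed_model(stratum, p, outcome=f"{sp}:{p}")
            results.append((sp, p, res))
    valid = [r for *_, r in results if np.isfinite(r.p_value)]
    adj = fdr_adjust([r.p_value for r in valid])
    for r, a in zip(valid, adj):
        r.adjusted_p = float(a)
    for sp, p, res in results:
        row = {"speed": sp, "parameter": p, "test": res.test,
               "p_raw": res.p_value, "p_adj": res.adjusted_p}
        for pair in PAIRS:
            if pair in res.pairwise:
                row[f"p_{pair[0]}_vs_{pair[1]}"] = res.pairwise[pair]
        row["flags"] = "; ".join(res.flags)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# FDR and normality screen
# ---------------------------------------------------------------------------

def fdr_adjust(p_values, method: str = "fdr_bh") -> np.ndarray:
    """One-stage step-up FDR-adjusted p values (BH; BY selectable)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method=method)[1]


def shapiro_screen(values) -> dict:
    """Shapiro-Wilk W and p; annotation only, never a test switch.

    Returns ``{"w": nan, "p": nan, "note": ...}`` for n < 3 or constant
    samples, where the statistic is undefined.
    """
    v = np.asarray(list(values), dtype=float)
    v = v[np.isfinite(v)]
    if len(v) < 3:
        return {"w": float("nan"), "p": float("nan"), "n": int(len(v)),
                "note": "n < 3: not computed"}
    if np.ptp(v) == 0:
        return {"w": float("nan"), "p": float("nan"), "n": int(len(v)),
                "note": "constant sample: undefined"}
    w, p = sps.shapiro(v)
    return {"w": float(w), "p": float(p), "n": int(len(v)), "note": ""}
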