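"""Inferential statistics for tip-anchorage analyses.

Covers the statistical layer used to establish tip anchorage: tip
distance summaries with kernel density estimates, extension-rate versus
focus-movement correlations per oriC index (Pearson with Fisher-z
intervals), variance-ratio F-tests between strains, Welch ANOVA with
Games-Howell and classical Tukey HSD post hocs, chi-squared tests on
count tables, a random-intercept versus pooled regression comparison,
colocalization fractions and duplication time-courses with Wilson
binomial intervals.

Sign convention for focus movement: movement is the focus displacement
in the laboratory (hypha-material) frame, ``dL - dd`` where ``dL`` is
the tip extension over the interval and ``dd`` the change of the
tip-to-focus distance.  An anchored focus (``dd = 0``) therefore
co-moves with the tip (movement = extension); a focus stationary in the
material frame has movement 0 while its tip distance grows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .tracking import DuplicationEvent, FocusTrack

__all__ = [
    "StatResult",
    "VelocityPair",
    "tip_distance_summary",
    "compute_velocity_pairs",
    "correlation_by_index",
    "pearson_with_ci",
    "variance_ratio_test",
    "anova_games_howell",
    "tukey_hsd",
    "chi_squared_counts",
    "mixed_vs_pooled",
    "colocalization_fraction",
    "duplication_fraction_timecourse",
]


@dataclass
class StatResult:
    """A generic inferential outcome."""

    method: str
    estimate: Optional[float] = None
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    statistic: Optional[float] = None
    dof: Optional[Tuple[float, ...]] = None
    p_value: Optional[float] = None
    n: Optional[Tuple[int, ...]] = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.p_value is not None and not (0.0 <= self.p_value <= 1.0 + 1e-12):
            raise ValueError("p-value outside [0, 1]")
        if (
            self.estimate is not None
            and self.ci_low is not None
            and self.ci_high is not None
            and not (self.ci_low - 1e-9 <= self.estimate <= self.ci_high + 1e-9)
        ):
            raise ValueError("estimate outside its confidence interval")


@dataclass
class VelocityPair:
    """Tip extension and focus movement over one frame interval."""

    hypha_id: int
    interval_index: int  # index of the starting frame
    extension: float  # dL, µm per interval
    movement: float  # dL - dd, µm per interval
    tip_index: int  # oriC index at the interval start (1 = tip-proximal)


# ---------------------------------------------------------------------------
# distributions and summaries
# ---------------------------------------------------------------------------

def tip_distance_summary(
    tracks: Sequence[FocusTrack],
    tip_index: int = 1,
    kde_grid: Optional[np.ndarray] = None,
):
    """Mean, s.d. and KDE of per-frame tip distances for one oriC index.

    The KDE is Gaussian with Silverman's rule-of-thumb bandwidth and is a
    proper density (integrates to 1).
    """
    distances = np.array(
        [
            t.positions[i]
            for t in tracks
            for i, f in enumerate(t.frames)
            if t.tip_index.get(f) == tip_index
        ]
    )
    if len(distances) < 2:
        raise ValueError("need at least 2 observations")
    mean = float(np.mean(distances))
    sd = float(np.std(distances, ddof=1))
    if sd > 0:
        kde = sps.gaussian_kde(distances, bw_method="silverman")
        if kde_grid is None:
            lo = distances.min() - 4 * sd
            hi = distances.max() + 4 * sd
            kde_grid = np.linspace(lo, hi, 512)
        density = kde(kde_grid)
    else:
        kde_grid = np.asarray([mean]) if kde_grid is None else kde_grid
        density = None
    return {
        "mean": mean,
        "sd": sd,
        "n": int(len(distances)),
        "grid": kde_grid,
        "density": density,
        "distances": distances,
    }


def compute_velocity_pairs(
    tracks: Sequence[FocusTrack],
    tip_lengths: Dict[int, Dict[int, float]],
    *,
    movement_definition: str = "material",
) -> List[VelocityPair]:
    """Per-interval (extension, movement) pairs labelled by oriC index.

    Parameters
    ----------
    tip_lengths
        ``{hypha_id: {frame: length_um}}``.
    movement_definition
        ``'material'`` (default): movement = dL - dd, the focus
        displacement in the material frame.  ``'tip_distance'``: -dd
        alone, for sensitivity checks.
    """
    if movement_definition not in ("material", "tip_distance"):
        raise ValueError("movement_definition must be 'material' or 'tip_distance'")
    pairs: List[VelocityPair] = []
    for t in tracks:
        L = tip_lengths.get(t.hypha_id, {})
        for i in range(len(t.frames) - 1):
            f0, f1 = t.frames[i], t.frames[i + 1]
            if f1 != f0 + 1:
                continue
            if f0 not in L or f1 not in L:
                continue
            dL = L[f1] - L[f0]
            dd = t.positions[i + 1] - t.positions[i]
            movement = (dL - dd) if movement_definition == "material" else -dd
            idx = t.tip_index.get(f0)
            if idx is None:
                continue
            pairs.append(VelocityPair(t.hypha_id, f0, float(dL), float(movement), idx))
    return pairs


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

def pearson_with_ci(x: np.ndarray, y: np.ndarray, alpha: float = 0.05) -> StatResult:
    """Pearson r with a Fisher-z confidence interval (two-sided t p-value)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("degenerate: zero variance")
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(np.sum(xc * yc) / np.sqrt(np.sum(xc**2) * np.sum(yc**2)))
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        p = 0.0
        lo = hi = r
    else:
        tstat = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * sps.t.sf(abs(tstat), n - 2))
        z = np.arctanh(r)
        se = 1.0 / np.sqrt(n - 3) if n > 3 else np.inf
        zc = sps.norm.ppf(1.0 - alpha / 2.0)
        lo, hi = np.tanh(z - zc * se), np.tanh(z + zc * se)
    return StatResult(
        method="pearson", estimate=r, ci_low=float(lo), ci_high=float(hi),
        statistic=r, dof=(float(n - 2),), p_value=p, n=(n,),
    )


def correlation_by_index(
    pairs: Sequence[VelocityPair], max_index: Optional[int] = None
) -> Dict[str, object]:
    """Per-index Pearson correlation of movement vs extension + trend.

    Returns per-index ``StatResult``s with fitted least-squares lines
    (slope, intercept) and the least-squares slope of r against index.
    """
    by_index: Dict[int, List[VelocityPair]] = {}
    for p in pairs:
        if max_index is None or p.tip_index <= max_index:
            by_index.setdefault(p.tip_index, []).append(p)
    results: Dict[int, StatResult] = {}
    lines: Dict[int, Tuple[float, float]] = {}
    for idx in sorted(by_index):
        grp = by_index[idx]
        if len(grp) < 3:
            continue
        x = np.array([p.extension for p in grp])
        y = np.array([p.movement for p in grp])
        res = pearson_with_ci(x, y)
        results[idx] = res
        slope, intercept = np.polyfit(x, y, 1)
        lines[idx] = (float(slope), float(intercept))
    trend_slope = None
    if len(results) >= 2:
        idxs = np.array(sorted(results))
        rs = np.array([results[i].estimate for i in idxs])
        trend_slope = float(np.polyfit(idxs.astype(float), rs, 1)[0])
    return {"per_index": results, "lines": lines, "r_trend_slope": trend_slope}


# ---------------------------------------------------------------------------
# variance & location tests
# ---------------------------------------------------------------------------

def variance_ratio_test(
    sample_a: Sequence[float], sample_b: Sequence[float], alpha: float = 0.05
) -> StatResult:
    """Two-sided F-test on the ratio of variances var(a)/var(b)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    va = np.var(a, ddof=1)
    vb = np.var(b, ddof=1)
    if vb == 0:
        raise ValueError("zero variance in denominator sample")
    F = float(va / vb)
    d1, d2 = len(a) - 1, len(b) - 1
    p = float(2.0 * min(sps.f.cdf(F, d1, d2), sps.f.sf(F, d1, d2)))
    p = min(p, 1.0)
    lo = F / sps.f.ppf(1.0 - alpha / 2.0, d1, d2)
    hi = F / sps.f.ppf(alpha / 2.0, d1, d2)
    return StatResult(
        method="variance_ratio_f",
        estimate=F, ci_low=float(lo), ci_high=float(hi),
        statistic=F, dof=(float(d1), float(d2)), p_value=p,
        n=(len(a), len(b)),
    )


def _group_stats(groups: Sequence[Sequence[float]]):
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least 2 groups")
    for g in gs:
        if len(g) < 2:
            raise ValueError("each group needs n >= 2")
    means = np.array([g.mean() for g in gs])
    variances = np.array([g.var(ddof=1) for g in gs])
    ns = np.array([len(g) for g in gs])
    return gs, means, variances, ns


def anova_games_howell(groups: Sequence[Sequence[float]]) -> Dict[str, object]:
    """One-way ANOVA omnibus plus Games-Howell pairwise comparisons.

    Games-Howell uses the Welch statistic per pair with the
    Welch-Satterthwaite degrees of freedom, referring ``q = |t|*sqrt(2)``
    to the studentized-range distribution with ``k`` groups.  It does not
    assume equal variances or sample sizes.
    """
    gs, means, variances, ns = _group_stats(groups)
    if np.all(variances == 0):
        raise ValueError("degenerate: all groups have zero variance")
    k = len(gs)
    F, p = sps.f_oneway(*gs)
    omnibus = StatResult(
        method="anova", statistic=float(F),
        dof=(float(k - 1), float(sum(ns) - k)), p_value=float(p),
        n=tuple(int(x) for x in ns),
    )
    pairwise: Dict[Tuple[int, int], StatResult] = {}
    for i in range(k):
        for j in range(i + 1, k):
            se2_i = variances[i] / ns[i]
            se2_j = variances[j] / ns[j]
            se = np.sqrt(se2_i + se2_j)
            if se == 0:
                raise ValueError(f"groups {i},{j} both have zero variance")
            t = (means[i] - means[j]) / se
            df = (se2_i + se2_j) ** 2 / (
                se2_i**2 / (ns[i] - 1) + se2_j**2 / (ns[j] - 1)
            )
            q = abs(t) * np.sqrt(2.0)
            pval = float(np.clip(sps.studentized_range.sf(q, k, df), 0.0, 1.0))
            pairwise[(i, j)] = StatResult(
                method="games_howell",
                estimate=float(means[i] - means[j]),
                statistic=float(t), dof=(float(df),), p_value=pval,
                n=(int(ns[i]), int(ns[j])),
            )
    return {"omnibus": omnibus, "pairwise": pairwise}


def tukey_hsd(groups: Sequence[Sequence[float]]) -> Dict[Tuple[int, int], StatResult]:
    """Classical Tukey HSD with pooled variance (equal-variance post hoc)."""
    gs, means, variances, ns = _group_stats(groups)
    k = len(gs)
    N = int(ns.sum())
    mse = float(np.sum((ns - 1) * variances) / (N - k))
    if mse == 0:
        raise ValueError("degenerate: pooled variance is zero")
    out: Dict[Tuple[int, int], StatResult] = {}
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(mse / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
            q = abs(means[i] - means[j]) / se
            pval = float(np.clip(sps.studentized_range.sf(q, k, N - k), 0.0, 1.0))
            out[(i, j)] = StatResult(
                method="tukey_hsd",
                estimate=float(means[i] - means[j]),
                statistic=float(q), dof=(float(N - k),), p_value=pval,
                n=(int(ns[i]), int(ns[j])),
            )
    return out


def chi_squared_counts(table: Sequence[Sequence[float]]) -> StatResult:
    """Pearson chi-squared test of independence on a count table."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or np.any(obs < 0):
        raise ValueError("need a 2-D nonnegative count table")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("empty row or column margin")
    total = obs.sum()
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
    stat = float(np.sum((obs - expected) ** 2 / expected))
    dof = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(sps.chi2.sf(stat, dof))
    return StatResult(
        method="chi_squared", statistic=stat, dof=(float(dof),), p_value=p,
        n=(int(total),),
    )


# ---------------------------------------------------------------------------
# mixed vs pooled regression
# ---------------------------------------------------------------------------

def mixed_vs_pooled(
    x: Sequence[float], y: Sequence[float], groups: Sequence[int]
) -> Dict[str, object]:
    """Pooled line vs per-hypha random-intercept line, compared by LRT.

    Both models are fitted by maximum likelihood; the likelihood-ratio
    statistic on the intercept-variance component is referred to a
    chi-squared with 1 d.o.f. (conservative, as the null lies on the
    boundary).  A singular mixed fit is reported as a zero variance
    component with p = 1.
    """
    import warnings

    import pandas as pd
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame({"x": x, "y": y, "g": groups})
    counts = df.groupby("g").size()
    if len(counts) < 3 or counts.min() < 3:
        raise ValueError("need >= 3 hyphae with >= 3 pairs each")
    ols = sm.OLS(df["y"], sm.add_constant(df["x"])).fit()
    ll_pooled = float(ols.llf)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            mixed = smf.mixedlm("y ~ x", df, groups=df["g"]).fit(reml=False)
            ll_mixed = float(mixed.llf)
            var_re = float(np.asarray(mixed.cov_re)[0, 0])
        except Exception:
            ll_mixed = ll_pooled
            var_re = 0.0
    lrt = max(0.0, 2.0 * (ll_mixed - ll_pooled))
    if var_re <= 1e-10:
        p = 1.0
        var_re = 0.0
    else:
        p = float(sps.chi2.sf(lrt, 1))
    result = StatResult(
        method="lrt_random_intercept", statistic=lrt, dof=(1.0,), p_value=p,
        n=(int(len(df)),), extra={"n_groups": int(len(counts))},
    )
    return {
        "loglik_pooled": ll_pooled,
        "loglik_mixed": ll_mixed,
        "intercept_variance": var_re,
        "lrt": result,
    }


# ---------------------------------------------------------------------------
# colocalization & duplication time-course
# ---------------------------------------------------------------------------

def colocalization_fraction(
    foci_a: Sequence, foci_b: Sequence, cutoff: float = 1.0
) -> Dict[str, float]:
    """Fraction of channel-a foci with a channel-b focus closer than ``cutoff``.

    Foci are matched within the same (hypha, frame, region); the distance
    is along the centerline.  The cutoff is strict (< cutoff).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    if len(foci_a) == 0:
        raise ValueError("no foci in channel a")
    b_by_key: Dict[tuple, List[float]] = {}
    for f in foci_b:
        b_by_key.setdefault((f.hypha_id, f.frame, f.region_id), []).append(f.position)
    hits = 0
    for f in foci_a:
        candidates = b_by_key.get((f.hypha_id, f.frame, f.region_id), [])
        if candidates and min(abs(f.position - c) for c in candidates) < cutoff:
            hits += 1
    return {"fraction": hits / len(foci_a), "n": len(foci_a), "hits": hits}


def duplication_fraction_timecourse(
    events: Sequence[DuplicationEvent],
    n_hyphae_observed: int,
    time_bins: Sequence[float],
    alpha: float = 0.05,
    frame_interval: float = 10.0,
) -> List[Dict[str, float]]:
    """Cumulative fraction of hyphae with a detected duplication per time bin.

    For each bin edge ``tau`` (minutes after replisome appearance) the
    fraction of observed hyphae whose duplication lag is <= ``tau`` is
    reported with a Wilson 95% CI, together with the mean daughter
    separation measured ``tau`` minutes after the replisome appeared.
    """
    from statsmodels.stats.proportion import proportion_confint

    if n_hyphae_observed <= 0:
        raise ValueError("empty denominator: no hyphae with replisome appearance")
    lags_by_hypha: Dict[int, float] = {}
    for e in events:
        if e.lag_minutes is None:
            continue
        prev = lags_by_hypha.get(e.hypha_id)
        if prev is None or e.lag_minutes < prev:
            lags_by_hypha[e.hypha_id] = e.lag_minutes
    out = []
    for tau in time_bins:
        k = sum(1 for lag in lags_by_hypha.values() if lag <= tau)
        lo, hi = proportion_confint(k, n_hyphae_observed, alpha=alpha, method="wilson")
        seps = []
        for e in events:
            if e.lag_minutes is None or e.replisome_appear_frame is None:
                continue
            if e.lag_minutes > tau:
                continue
            f_probe = e.replisome_appear_frame + int(round(tau / frame_interval))
            if f_probe in e.separation:
                seps.append(e.separation[f_probe])
        out.append(
            {
                "tau_minutes": float(tau),
                "fraction": k / n_hyphae_observed,
                "ci_low": float(lo),
                "ci_high": float(hi),
                "n": int(n_hyphae_observed),
                "k": int(k),
                "mean_separation": float(np.mean(seps)) if seps else float("nan"),
            }
        )
    return out
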