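"""Inference battery: Spearman/FDR correlation grids, HD-vs-LD t-tests, and
one-way ANOVA with a Levene gate selecting Fisher's LSD or Games-Howell
post hoc comparisons.

The correlation grids mirror the region-by-parameter layout of the source
analyses: for each pial-surface region and each of the five per-FOV
parameters, the section-level regional mean is correlated (Spearman's rho,
two-sided p from the t approximation) with a covariate (ranked burden
sequence, age, or BMI). Missing diameters (fields with no CoA) are removed
pairwise, which is why n varies by cell. Benjamini-Hochberg FDR adjustment
is applied across each grid as one family.

The Levene gate follows the classic SPSS workflow: variances judged equal
(Levene p > alpha, mean-centred) lead to LSD pairwise t-tests on the pooled
within-group mean square; unequal variances lead to Games-Howell, a pairwise
Welch t with Welch-Satterthwaite degrees of freedom referred to the
studentized-range distribution (q = |t|*sqrt(2)) with the full group count.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .regions import PIAL_REGIONS, Region

MISSING = float("nan")

#: The five per-FOV parameters, as columns of the summary tables.
PARAMETERS = (
    "count",
    "area_fraction_pct",
    "mean_diameter_um",
    "min_diameter_um",
    "max_diameter_um",
)


@dataclass
class StatResult:
    """One inferential outcome."""

    comparison_id: str
    method: str  # spearman | t_test | anova | levene | lsd | games_howell
    statistic: float
    p_raw: float
    p_adjusted: float = MISSING
    n: tuple | int = 0
    df: float = MISSING


def _clean_pairs(x, y) -> tuple:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    return x[keep], y[keep]


def spearman(x, y, comparison_id: str = "") -> StatResult:
    """Spearman's rho with pairwise deletion of missing values.

    Ranks use average ranks for ties; the two-sided p-value comes from the
    t approximation t = r*sqrt((n-2)/(1-r^2)). Fewer than 3 complete pairs
    yield a missing result.
    """
    x, y = _clean_pairs(x, y)
    n = len(x)
    if n < 3:
        return StatResult(comparison_id, "spearman", MISSING, MISSING, n=n)
    res = sps.spearmanr(x, y)
    r = float(res.statistic)
    p = float(res.pvalue)
    if not math.isfinite(r):  # a constant margin: correlation undefined
        return StatResult(comparison_id, "spearman", MISSING, MISSING, n=n)
    return StatResult(comparison_id, "spearman", r, p, n=n, df=n - 2)


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; missing entries pass through."""
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = np.isfinite(p)
    if mask.sum() == 0:
        return out
    out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def t_test_unpaired(a, b, comparison_id: str = "") -> StatResult:
    """Unpaired two-tailed Student's t-test (pooled variance)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    n1, n2 = len(a), len(b)
    if n1 < 2 or n2 < 2:
        return StatResult(comparison_id, "t_test", MISSING, MISSING, n=(n1, n2))
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / df
    if sp2 == 0:
        # degenerate: no within-group variability
        if a.mean() == b.mean():
            return StatResult(comparison_id, "t_test", 0.0, 1.0, n=(n1, n2), df=df)
        sign = math.copysign(1.0, a.mean() - b.mean())
        return StatResult(comparison_id, "t_test", sign * math.inf, 0.0, n=(n1, n2), df=df)
    res = sps.ttest_ind(a, b, equal_var=True)
    return StatResult(
        comparison_id, "t_test", float(res.statistic), float(res.pvalue), n=(n1, n2), df=df
    )


def levene(groups, center: str = "mean", comparison_id: str = "") -> StatResult:
    """Levene's test of variance homogeneity (mean-centred by default)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    groups = [g[np.isfinite(g)] for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("levene requires >= 2 groups with >= 2 values each")
    ns = tuple(len(g) for g in groups)
    devs = [np.abs(g - (g.mean() if center == "mean" else np.median(g))) for g in groups]
    if all(d.max() == 0 for d in devs if len(d)):
        # all groups internally constant: no evidence against equal variances
        return StatResult(comparison_id, "levene", 0.0, 1.0, n=ns)
    w, p = sps.levene(*groups, center=center)
    if not math.isfinite(w):
        return StatResult(comparison_id, "levene", 0.0, 1.0, n=ns)
    k, n_tot = len(groups), sum(ns)
    return StatResult(comparison_id, "levene", float(w), float(p), n=ns, df=n_tot - k)


def anova_oneway(groups, comparison_id: str = "") -> StatResult:
    """One-way between-groups ANOVA."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    groups = [g[np.isfinite(g)] for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("anova requires >= 2 groups with >= 2 values each")
    ns = tuple(len(g) for g in groups)
    k, n_tot = len(groups), sum(ns)
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return StatResult(comparison_id, "anova", 0.0, 1.0, n=ns, df=n_tot - k)
    f, p = sps.f_oneway(*groups)
    return StatResult(comparison_id, "anova", float(f), float(p), n=ns, df=n_tot - k)


# ---------------------------------------------------------------------------
# post hoc comparisons


def _lsd_pair(groups, i, j, labels) -> StatResult:
    k = len(groups)
    ns = [len(g) for g in groups]
    n_tot = sum(ns)
    df = n_tot - k
    mse = sum((len(g) - 1) * np.var(g, ddof=1) for g in groups) / df
    a, b = groups[i], groups[j]
    cid = f"{labels[i]} vs {labels[j]}"
    if mse == 0:
        p = 1.0 if a.mean() == b.mean() else 0.0
        t = 0.0 if p == 1.0 else math.copysign(math.inf, a.mean() - b.mean())
        return StatResult(cid, "lsd", t, p, n=(len(a), len(b)), df=df)
    se = math.sqrt(mse * (1 / len(a) + 1 / len(b)))
    t = (a.mean() - b.mean()) / se
    p = 2 * sps.t.sf(abs(t), df)
    return StatResult(cid, "lsd", float(t), float(p), n=(len(a), len(b)), df=df)


def _games_howell_pair(groups, i, j, labels, k: int) -> StatResult:
    a, b = groups[i], groups[j]
    cid = f"{labels[i]} vs {labels[j]}"
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    if se2 == 0:
        p = 1.0 if a.mean() == b.mean() else 0.0
        return StatResult(cid, "games_howell", 0.0, p, n=(na, nb), df=MISSING)
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    q = abs(t) * math.sqrt(2.0)
    try:
        p = float(sps.studentized_range.sf(q, k, df))
    except Exception as exc:  # pragma: no cover - numerical failure path
        raise RuntimeError(
            f"studentized-range evaluation failed for k={k}, df={df:.3f}"
        ) from exc
    return StatResult(cid, "games_howell", float(t), min(max(p, 0.0), 1.0), n=(na, nb), df=df)


def posthoc(groups, levene_result: StatResult | None = None, alpha: float = 0.05, labels=None) -> list:
    """All pairwise comparisons, gated on variance homogeneity.

    Levene p > alpha selects Fisher's LSD (pooled ANOVA error term);
    otherwise Games-Howell (Welch t referred to the studentized range with
    the full group count). At k=2 Games-Howell coincides with the Welch
    two-sample t-test.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    groups = [g[np.isfinite(g)] for g in groups]
    if labels is None:
        labels = [f"group{i}" for i in range(len(groups))]
    if levene_result is None:
        levene_result = levene(groups)
    equal_var = levene_result.p_raw > alpha
    k = len(groups)
    results = []
    for i, j in itertools.combinations(range(k), 2):
        if equal_var:
            results.append(_lsd_pair(groups, i, j, labels))
        else:
            results.append(_games_howell_pair(groups, i, j, labels, k))
    return results


# ---------------------------------------------------------------------------
# correlation grids


def regional_parameter_table(fov_summaries: pd.DataFrame) -> pd.DataFrame:
    """Section x (region, parameter) table of regional means.

    Count and area fraction average over all fields of the region (zeros
    included); diameters average over fields that contained CoA, and are
    missing when no field of the region did.
    """
    frames = {}
    grouped = fov_summaries.groupby(["section_id", "region"], sort=True)
    means = grouped[list(PARAMETERS)].mean()
    for region in PIAL_REGIONS:
        for param in PARAMETERS:
            try:
                col = means.xs(region.value, level="region")[param]
            except KeyError:
                col = pd.Series(dtype=float)
            frames[(region.value, param)] = col
    table = pd.DataFrame(frames)
    table.columns = pd.MultiIndex.from_tuples(table.columns, names=["region", "parameter"])
    return table


@dataclass
class CorrelationGrid:
    """Region x parameter Spearman grid for one covariate, FDR-adjusted."""

    covariate: str
    table: pd.DataFrame  # tidy: region, parameter, r, p_raw, p_adj, n

    def to_wide(self, value: str = "r") -> pd.DataFrame:
        return self.table.pivot(index="parameter", columns="region", values=value).reindex(
            index=list(PARAMETERS), columns=[r.value for r in PIAL_REGIONS]
        )

    def cell(self, region, parameter: str) -> pd.Series:
        region = Region(region).value
        sel = self.table[(self.table.region == region) & (self.table.parameter == parameter)]
        return sel.iloc[0]


def build_grid(param_table: pd.DataFrame, covariate: pd.Series, covariate_name: str) -> CorrelationGrid:
    """Correlate every regional parameter with a covariate, then FDR-adjust.

    The adjustment family is the whole grid; cells without at least 3
    complete pairs stay missing and shrink the family accordingly.
    """
    cov = covariate.reindex(param_table.index)
    rows = []
    for region in PIAL_REGIONS:
        for param in PARAMETERS:
            key = (region.value, param)
            if key in param_table.columns:
                res = spearman(cov.to_numpy(), param_table[key].to_numpy(),
                               comparison_id=f"{covariate_name}:{region.value}:{param}")
            else:
                res = StatResult(f"{covariate_name}:{region.value}:{param}", "spearman",
                                 MISSING, MISSING, n=0)
            rows.append(
                {
                    "region": region.value,
                    "parameter": param,
                    "r": res.statistic,
                    "p_raw": res.p_raw,
                    "n": res.n,
                }
            )
    table = pd.DataFrame(rows)
    table["p_adj"] = fdr_adjust(table["p_raw"].to_numpy())
    return CorrelationGrid(covariate=covariate_name, table=table)


# ---------------------------------------------------------------------------
# HD vs LD comparisons and regional ANOVA


def hd_ld_tests(zone_table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-region unpaired t-tests of HD vs LD zone values across sections.

    ``zone_table`` has one row per (section, region, zone) with the zone
    parameters. Sections contribute their per-section mean over fields.
    Returns one row per region x parameter with the t statistic, raw p,
    HD/LD fold change of means, and significance marks.
    """
    params = ["packing_density_per_mm2", "area_fraction_pct", "mean_diameter_um", "max_diameter_um"]
    per_section = (
        zone_table.groupby(["section_id", "region", "zone"], sort=True)[params].mean().reset_index()
    )
    rows = []
    for region in PIAL_REGIONS:
        sub = per_section[per_section.region == region.value]
        hd = sub[sub.zone == "HD"]
        ld = sub[sub.zone == "LD"]
        for param in params:
            a = hd[param].dropna().to_numpy()
            b = ld[param].dropna().to_numpy()
            res = t_test_unpaired(a, b, comparison_id=f"{region.value}:{param}:HDvsLD")
            fold = (a.mean() / b.mean()) if len(a) and len(b) and b.mean() != 0 else MISSING
            rows.append(
                {
                    "region": region.value,
                    "parameter": param,
                    "t": res.statistic,
                    "p_raw": res.p_raw,
                    "n_hd": len(a),
                    "n_ld": len(b),
                    "fold_change": fold,
                    "significant": bool(np.isfinite(res.p_raw) and res.p_raw < alpha),
                }
            )
    return pd.DataFrame(rows)


def regional_size_comparison(
    param_table: pd.DataFrame, parameter: str = "mean_diameter_um", alpha: float = 0.05
) -> tuple:
    """One-way ANOVA across pial regions with Levene-gated post hoc tests.

    Groups are section-level regional means of ``parameter``. Returns
    (anova, levene, posthoc list). Regions with fewer than 2 values are
    dropped from the comparison.
    """
    groups, labels = [], []
    for region in PIAL_REGIONS:
        key = (region.value, parameter)
        if key not in param_table.columns:
            continue
        vals = param_table[key].dropna().to_numpy()
        if len(vals) >= 2:
            groups.append(vals)
            labels.append(region.value)
    if len(groups) < 2:
        raise ValueError("fewer than two regions with data; no regional comparison")
    an = anova_oneway(groups, comparison_id=f"{parameter}:regions")
    lv = levene(groups, comparison_id=f"{parameter}:regions")
    ph = posthoc(groups, levene_result=lv, alpha=alpha, labels=labels)
    return an, lv, ph


def posthoc_to_frame(results: list, alpha: float = 0.05) -> pd.DataFrame:
    rows = []
    for r in results:
        sig = bool(np.isfinite(r.p_raw) and r.p_raw < alpha)
        rows.append(
            {
                "comparison": r.comparison_id,
                "method": r.method,
                "statistic": r.statistic,
                "p_raw": r.p_raw,
                "df": r.df,
                # '*' marks significance under equal variances (LSD),
                # '#' under unequal variances (Games-Howell)
                "mark": ("*" if r.method == "lsd" else "#") if sig else "",
            }
        )
    return pd.DataFrame(rows)
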