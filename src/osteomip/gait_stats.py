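"""Conventional inference on gait-group ratio data.

Covers the descriptive tables (group and species summaries, specimen-count
weighted pooled means) and the classical test battery: Kolmogorov-Smirnov
normality checks, Levene's homogeneity-of-variance test, one-way ANOVA (from
raw data or from published n/mean/SD summaries), and Tukey HSD post-hoc
comparisons with the Tukey-Kramer adjustment for unequal group sizes.

The ANOVA decomposition is computed directly from sums of squares so that
``anova_oneway`` on raw data and ``anova_from_summary`` on that data's
(n, mean, sd) agree to machine precision — which is also what lets published
summary tables be re-analysed without the raw specimens.

The model-style entry point is :class:`GaitAnova`; ``fit()`` returns a
:class:`GaitAnovaResult` bundling the assumption checks, the ANOVA table and
the post-hoc matrix, with a ``summary()`` in the familiar layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AnovaTable",
    "descriptive_summary",
    "weighted_pooled_mean",
    "species_group_mean",
    "ks_normality",
    "levene_test",
    "anova_oneway",
    "anova_from_summary",
    "tukey_qstats",
    "tukey_hsd",
    "GaitAnova",
    "GaitAnovaResult",
]


@dataclass
class AnovaTable:
    """One-way ANOVA result: degrees of freedom, F, p."""

    df_between: int
    df_within: int
    F: float
    p: float

    def __str__(self) -> str:  # mirrors the usual "df F p" table row
        return f"df = ({self.df_between}, {self.df_within}), F = {self.F:.3f}, p = {self.p:.4g}"


# ---------------------------------------------------------------------------
# descriptive summaries


def descriptive_summary(records: pd.DataFrame, by: str = "gait") -> pd.DataFrame:
    """Per-group n, mean, sample SD and range for both ratio columns.

    ``records`` is the tidy specimen table (columns specimen_id, species,
    gait, max_ratio, second_ratio); ``by`` is "gait" or "species".  The SD is
    the n-1 sample SD and is reported missing (NaN) for single-member groups.
    """
    if records.empty:
        raise ValueError("records must be non-empty")
    out = []
    for label, grp in records.groupby(by, sort=False):
        row = {by: label, "n": len(grp)}
        for col in ("max_ratio", "second_ratio"):
            v = grp[col].to_numpy(dtype=float)
            row[f"{col}_mean"] = v.mean()
            row[f"{col}_sd"] = v.std(ddof=1) if len(v) > 1 else np.nan
            row[f"{col}_min"] = v.min()
            row[f"{col}_max"] = v.max()
        out.append(row)
    return pd.DataFrame(out)


def weighted_pooled_mean(species_rows: pd.DataFrame, value_col: str = "max_mean") -> float:
    """Specimen-count weighted mean over species rows: sum(n_i m_i)/sum(n_i)."""
    n = species_rows["n"].to_numpy(dtype=float)
    m = species_rows[value_col].to_numpy(dtype=float)
    if n.sum() <= 0:
        raise ValueError("total specimen count must be positive")
    return float((n * m).sum() / n.sum())


def species_group_mean(
    species_rows: pd.DataFrame, group: str, value_col: str = "max_mean"
) -> tuple[float, float]:
    """Unweighted mean and sample SD of the species means within one gait group.

    This is the species-level summary used when each species contributes one
    value regardless of how many specimens it has.
    """
    sub = species_rows.loc[species_rows["gait"] == group, value_col].to_numpy(dtype=float)
    if sub.size == 0:
        raise ValueError(f"no species in group {group!r}")
    sd = float(sub.std(ddof=1)) if sub.size > 1 else float("nan")
    return float(sub.mean()), sd


# ---------------------------------------------------------------------------
# assumption checks


def ks_normality(values, lilliefors: bool = False) -> tuple[float, float]:
    """One-sample KS test against a normal with the sample's mean and SD.

    The default p-value uses the asymptotic KS distribution (ignoring that
    the parameters were estimated); ``lilliefors=True`` applies the
    Lilliefors correction instead.  Requires n >= 4 and non-degenerate data.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise ValueError("KS normality needs n >= 4")
    if v.std(ddof=1) == 0:
        raise ValueError("degenerate input: all values equal")
    if lilliefors:
        from statsmodels.stats.diagnostic import lilliefors as _lf

        d, p = _lf(v, dist="norm")
        return float(d), float(p)
    res = stats.kstest(v, "norm", args=(v.mean(), v.std(ddof=1)))
    return float(res.statistic), float(res.pvalue)


def levene_test(groups: list[np.ndarray]) -> tuple[float, float]:
    """Levene's W with group-mean centering; p from F(k-1, N-k)."""
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("Levene needs >= 2 groups with n >= 2 each")
    res = stats.levene(*groups, center="mean")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# ANOVA


def anova_from_summary(n, mean, sd) -> AnovaTable:
    """One-way ANOVA reconstructed from per-group (n, mean, sd).

    SSB = sum n_i (m_i - grand)^2, SSW = sum (n_i - 1) sd_i^2,
    F = (SSB / (k-1)) / (SSW / (N-k)).  Published summary tables rounded to
    a few decimals reproduce the printed F up to that rounding.
    """
    n = np.asarray(n, dtype=float)
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    k = n.size
    if k < 2:
        raise ValueError("need >= 2 groups")
    if np.any(n < 1):
        raise ValueError("all group sizes must be >= 1")
    sd = np.where(n > 1, sd, 0.0)
    N = n.sum()
    if N <= k:
        raise ValueError("need N > k for a within-group df")
    grand = (n * mean).sum() / N
    ssb = (n * (mean - grand) ** 2).sum()
    ssw = ((n - 1) * sd**2).sum()
    dfb, dfw = k - 1, int(N - k)
    if ssw == 0:  # degenerate: zero within-group variance
        F = float("inf") if ssb > 0 else 0.0
        p = 0.0 if ssb > 0 else 1.0
    else:
        F = float((ssb / dfb) / (ssw / dfw))
        p = float(stats.f.sf(F, dfb, dfw))
    return AnovaTable(df_between=dfb, df_within=dfw, F=F, p=p)


def anova_oneway(groups: list[np.ndarray]) -> AnovaTable:
    """One-way ANOVA on raw per-group samples."""
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need >= 2 groups")
    n = np.array([g.size for g in gs], dtype=float)
    mean = np.array([g.mean() for g in gs])
    sd = np.array([g.std(ddof=1) if g.size > 1 else 0.0 for g in gs])
    return anova_from_summary(n, mean, sd)


def tukey_qstats(groups: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray, int, int]:
    """Pairwise Tukey-Kramer statistics: (differences, q values, k, df_within).

    q_ij = |m_i - m_j| / sqrt((MSW/2)(1/n_i + 1/n_j)); pairs are ordered
    (0,1), (0,2), ..., (k-2, k-1).  The familywise test at level alpha
    rejects a pair iff its q exceeds the studentized-range critical value
    for (k, df_within).
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    table = anova_oneway(gs)
    k = len(gs)
    n = np.array([g.size for g in gs], dtype=float)
    mean = np.array([g.mean() for g in gs])
    ssw = sum(((g - g.mean()) ** 2).sum() for g in gs)
    msw = ssw / table.df_within
    diffs, qs = [], []
    for i, j in combinations(range(k), 2):
        diff = mean[i] - mean[j]
        se = np.sqrt(msw / 2.0 * (1.0 / n[i] + 1.0 / n[j]))
        diffs.append(diff)
        qs.append(abs(diff) / se if se > 0 else 0.0)
    return np.array(diffs), np.array(qs), k, table.df_within


def tukey_hsd(groups: list[np.ndarray], labels: list[str] | None = None) -> pd.DataFrame:
    """All-pairs Tukey HSD with Tukey-Kramer handling of unequal n.

    The adjusted p of each pair is the studentized-range tail probability of
    its q with k groups and N-k error df (evaluated by scipy's numerical
    integration of the studentized-range distribution).  Returns a DataFrame
    with columns pair, difference, q, p_adj.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    k = len(gs)
    labels = labels or [str(i) for i in range(k)]
    diffs, qs, k, dfw = tukey_qstats(gs)
    pair_names = [f"{labels[i]} v. {labels[j]}" for i, j in combinations(range(k), 2)]
    p = np.where(qs > 0, stats.studentized_range.sf(qs, k, dfw), 1.0)
    return pd.DataFrame(
        {
            "pair": pair_names,
            "difference": diffs,
            "q": qs,
            "p_adj": np.minimum(1.0, p),
        }
    )


# ---------------------------------------------------------------------------
# model-style wrapper


class GaitAnova:
    """One-way gait-group comparison of a ratio response.

    Parameters
    ----------
    data : tidy DataFrame with one row per specimen
    response : column holding the ratio (e.g. "max_ratio")
    group : column holding the gait label (default "gait")
    """

    def __init__(self, data: pd.DataFrame, response: str, group: str = "gait"):
        if data.empty:
            raise ValueError("data must be non-empty")
        self.data = data
        self.response = response
        self.group = group
        self.labels = list(dict.fromkeys(data[group]))
        self.groups = [
            data.loc[data[group] == lab, response].to_numpy(dtype=float) for lab in self.labels
        ]
        if len(self.labels) < 2:
            raise ValueError("need >= 2 groups")

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, response: str, group: str = "gait"):
        return cls(data, response, group)

    def fit(self, lilliefors: bool = False) -> "GaitAnovaResult":
        anova = anova_oneway(self.groups)
        posthoc = tukey_hsd(self.groups, self.labels)
        # Levene is undefined when every group is internally constant
        levene = (
            levene_test(self.groups)
            if all(len(g) >= 2 for g in self.groups)
            and any(np.std(g) > 0 for g in self.groups)
            else None
        )
        ks = {}
        for lab, g in zip(self.labels, self.groups):
            if len(g) >= 4 and np.std(g, ddof=1) > 0:
                ks[lab] = ks_normality(g, lilliefors=lilliefors)
        return GaitAnovaResult(
            model=self,
            anova=anova,
            posthoc=posthoc,
            levene=levene,
            ks=ks,
        )


@dataclass
class GaitAnovaResult:
    """Fitted gait-group comparison: assumption checks, ANOVA, post hoc."""

    model: GaitAnova
    anova: AnovaTable
    posthoc: pd.DataFrame
    levene: tuple[float, float] | None
    ks: dict[str, tuple[float, float]]

    def summary(self) -> str:
        lines = [
            f"One-way ANOVA of {self.model.response} by {self.model.group}",
            "=" * 58,
        ]
        summ = descriptive_summary(self.model.data, by=self.model.group)
        col = self.model.response
        for _, r in summ.iterrows():
            sd = r[f"{col}_sd"]
            sd_txt = f"{sd:.3f}" if np.isfinite(sd) else "-"
            lines.append(
                f"  {r[self.model.group]:>4}  n={int(r['n']):>3}  "
                f"mean={r[f'{col}_mean']:.3f} ({sd_txt})  "
                f"range={r[f'{col}_min']:.3f}-{r[f'{col}_max']:.3f}"
            )
        for lab, (d, p) in self.ks.items():
            lines.append(f"  KS normality {lab}: D={d:.3f}, p={p:.3f}")
        if self.levene is not None:
            lines.append(f"  Levene: W={self.levene[0]:.3f}, p={self.levene[1]:.3f}")
        lines.append(f"ANOVA: {self.anova}")
        lines.append("Tukey HSD (Tukey-Kramer for unequal n):")
        for _, r in self.posthoc.iterrows():
            lines.append(
                f"  {r['pair']:<12} diff={r['difference']:+.3f}  q={r['q']:.3f}  p={r['p_adj']:.3f}"
            )
        return "\n".join(lines)
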