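"""Statistical analyses of the disorder survey.

The analysis ladder mirrors a proteome-disorder survey: Spearman rank
correlations between percent disorder and genome size (overall and per
group), a nested pair of ordinary-least-squares regressions that
measures the genome-size effect as the difference in adjusted R² between
``D ~ bases`` and ``D ~ bases + size``, Bonferroni correction within
each reported table, variance attribution across predictor sets
(bases, size, genome type, host, family and their combinations), and
grouped summary tables by family, Baltimore type and host category.

Observations are carried in a pandas DataFrame with one row per genome
and columns ``accession, D, S, A, C, G, T, A4, C4, G4, T4, family,
baltimore_type, host_category, overlap_fraction`` (``S`` in kilobases).
Because the four base fractions sum to one, the T fraction is dropped
from every design matrix (T is conventionally the strongest negative
correlate of disorder, making it the natural reference base).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

__all__ = [
    "NestedModelResult",
    "GroupSummary",
    "spearman",
    "nested_size_model",
    "bonferroni",
    "group_summaries",
    "summaries_frame",
    "variance_attribution",
    "composition_disorder_correlations",
    "host_summary",
]

BASE_COVARIATES = ["A", "C", "G"]  # T dropped as the reference base


def spearman(
    x: Sequence[float], y: Sequence[float], p_method: str = "auto"
) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    Ties receive midranks.  The p-value uses the t approximation for
    n > 20; for small samples (``p_method="auto"``) it is a permutation
    p-value — exhaustive for n <= 8, otherwise a fixed-seed Monte Carlo
    permutation test — so that tiny groups do not lean on an asymptotic
    approximation.  ``p_method="t"`` forces the t approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input: rank correlation undefined")

    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])

    if p_method == "t" or n > 20:
        if abs(rho) >= 1.0:
            return rho, 0.0
        t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
        p = 2.0 * sps.t.sf(abs(t), n - 2)
        return rho, float(min(p, 1.0))

    # permutation p-value for small n (deterministic)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = math.sqrt((rxc**2).sum() * (ryc**2).sum())
    if n <= 8:
        perms = np.array(list(itertools.permutations(range(n))))
        vals = ryc[perms] @ rxc / denom
        return rho, float((np.abs(vals) >= abs(rho) - 1e-12).mean())
    rng = np.random.default_rng(0)
    reps = 9999
    perms = np.argsort(rng.random((reps, n)), axis=1)
    vals = ryc[perms] @ rxc / denom
    count = 1 + int((np.abs(vals) >= abs(rho) - 1e-12).sum())
    return rho, count / (reps + 1)


@dataclass
class NestedModelResult:
    """Genome-size effect after correcting for base composition.

    ``delta_r2`` is the difference of the adjusted R² of
    ``D ~ A + C + G + S`` and ``D ~ A + C + G`` fitted on the same rows;
    it can be negative because adjusted R² penalises the extra term.
    """

    r2_bases: float
    r2_bases_size: float
    p_size: float
    n: int
    p_size_corrected: float | None = None

    @property
    def delta_r2(self) -> float:
        return self.r2_bases_size - self.r2_bases


def _fit_adj_r2(y: np.ndarray, X: np.ndarray) -> sm.regression.linear_model.RegressionResultsWrapper:
    return sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()


def nested_size_model(
    obs: pd.DataFrame, response: str = "D", rank_response: bool = False
) -> NestedModelResult:
    """Fit ``response ~ bases`` and ``response ~ bases + size`` by OLS.

    Returns adjusted R² of both models and the two-sided t-test p-value
    for the genome-size coefficient in the larger model.  With
    ``rank_response=True`` the response is rank-transformed first, which
    makes the result invariant to monotone transformations of disorder.
    """
    cols = BASE_COVARIATES + ["S"]
    df = obs.dropna(subset=cols + [response])
    n = len(df)
    if n < 8:
        raise ValueError(f"need at least 8 complete observations, got {n}")
    y = df[response].to_numpy(dtype=float)
    if rank_response:
        y = sps.rankdata(y)
    Xb = df[BASE_COVARIATES].to_numpy(dtype=float)
    Xbs = df[cols].to_numpy(dtype=float)
    if np.linalg.matrix_rank(np.column_stack([np.ones(n), Xbs])) < Xbs.shape[1] + 1:
        raise ValueError(f"rank-deficient design over columns {cols}")
    fit_b = _fit_adj_r2(y, Xb)
    fit_bs = _fit_adj_r2(y, Xbs)
    p_size = float(fit_bs.pvalues[-1])
    return NestedModelResult(float(fit_b.rsquared_adj), float(fit_bs.rsquared_adj), p_size, n)


def bonferroni(p_values: Sequence[float], m: int | None = None) -> list[float]:
    """Bonferroni correction: ``min(1, m * p)`` with ``m`` defaulting to
    the number of tests in the list."""
    ps = [float(p) for p in p_values]
    for p in ps:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value {p} outside [0, 1]")
    m = len(ps) if m is None else m
    return [min(1.0, m * p) for p in ps]


@dataclass
class GroupSummary:
    """One row of a grouped survey table (family / type / host)."""

    group: str
    n: int
    mean_size: float
    sd_size: float | None
    mean_d: float
    sd_d: float | None
    spearman_rho: float | None = None
    spearman_p: float | None = None
    nested: NestedModelResult | None = None
    min_d: float | None = None
    max_d: float | None = None

    @property
    def range_d(self) -> float | None:
        if self.min_d is None or self.max_d is None:
            return None
        return self.max_d - self.min_d


def group_summaries(
    obs: pd.DataFrame,
    group_by: str,
    min_group_n: int = 3,
    with_extremes: bool = False,
) -> list[GroupSummary]:
    """Per-group survey statistics with within-table Bonferroni correction.

    For every group: N, mean/sd of genome size (kb) and percent disorder,
    Spearman correlation of disorder with size, and the nested
    base-composition/size regressions where the group is large enough.
    The Bonferroni family is the number of rows in the table produced.
    Groups with fewer than ``min_group_n`` members get a summary without
    correlation fields; sd fields need N >= 2.
    """
    if group_by not in ("family", "baltimore_type", "host_category"):
        raise ValueError(f"cannot group by {group_by!r}")
    rows: list[GroupSummary] = []
    for name, grp in obs.groupby(group_by, sort=True):
        n = len(grp)
        s = grp["S"].to_numpy(dtype=float)
        d = grp["D"].to_numpy(dtype=float)
        summary = GroupSummary(
            group=str(name),
            n=n,
            mean_size=float(s.mean()),
            sd_size=float(s.std(ddof=1)) if n >= 2 else None,
            mean_d=float(d.mean()),
            sd_d=float(d.std(ddof=1)) if n >= 2 else None,
        )
        if with_extremes:
            summary.min_d = float(d.min())
            summary.max_d = float(d.max())
        if n >= min_group_n:
            try:
                rho, p = spearman(d, s)
                summary.spearman_rho, summary.spearman_p = rho, p
            except ValueError:
                pass
            try:
                summary.nested = nested_size_model(grp)
            except (ValueError, KeyError):
                pass
        rows.append(summary)

    m = len(rows)
    for summary in rows:
        if summary.nested is not None:
            summary.nested.p_size_corrected = bonferroni([summary.nested.p_size], m)[0]
    return rows


def summaries_frame(rows: Sequence[GroupSummary], group_label: str = "group") -> pd.DataFrame:
    """Tabulate :class:`GroupSummary` rows as a DataFrame."""
    out = []
    for r in rows:
        nested = r.nested
        out.append(
            {
                group_label: r.group,
                "N": r.n,
                "mean_S_kb": r.mean_size,
                "sd_S_kb": r.sd_size,
                "mean_D": r.mean_d,
                "sd_D": r.sd_d,
                "rho": r.spearman_rho,
                "p": r.spearman_p,
                "R2_B": nested.r2_bases if nested else None,
                "R2_BS": nested.r2_bases_size if nested else None,
                "p_size_corrected": nested.p_size_corrected if nested else None,
            }
        )
    return pd.DataFrame(out)


def _design_matrix(df: pd.DataFrame, predictors: Sequence[str]) -> np.ndarray:
    """One-hot encode categorical predictors (first level as reference)
    and stack with the continuous ones."""
    blocks: list[np.ndarray] = []
    for col in predictors:
        if col == "bases":
            blocks.append(df[BASE_COVARIATES].to_numpy(dtype=float))
        elif col in ("family", "baltimore_type", "host_category"):
            dummies = pd.get_dummies(df[col], drop_first=True, dtype=float)
            if dummies.shape[1]:
                blocks.append(dummies.to_numpy())
        elif col in df.columns:
            blocks.append(df[[col]].to_numpy(dtype=float))
        else:
            raise KeyError(f"unknown predictor {col!r}")
    if not blocks:
        return np.empty((len(df), 0))
    return np.column_stack(blocks)


def variance_attribution(
    obs: pd.DataFrame,
    model_specs: Mapping[str, Sequence[str]],
    response: str = "D",
    rank_response: bool = False,
) -> list[tuple[str, float]]:
    """Adjusted R² of ``response`` for each predictor set.

    ``model_specs`` maps a label to a list of predictors drawn from
    ``{"bases", "S", "family", "baltimore_type", "host_category",
    "overlap_fraction", ...}``.  All models are fitted on the common
    complete rows so their adjusted R² values are comparable.  An empty
    predictor list gives the intercept-only model (adjusted R² = 0).
    """
    needed = {response}
    for preds in model_specs.values():
        for p in preds:
            if p == "bases":
                needed.update(BASE_COVARIATES)
            elif p not in ("family", "baltimore_type", "host_category"):
                needed.add(p)
    missing = needed - set(obs.columns)
    if missing:
        raise KeyError(f"unknown columns in model specs: {sorted(missing)}")
    df = obs.dropna(subset=sorted(needed))
    y = df[response].to_numpy(dtype=float)
    if rank_response:
        y = sps.rankdata(y)
    results: list[tuple[str, float]] = []
    for label, preds in model_specs.items():
        X = _design_matrix(df, list(preds))
        if X.shape[1] == 0:
            results.append((label, 0.0))
            continue
        fit = _fit_adj_r2(y, X)
        results.append((label, float(fit.rsquared_adj)))
    return results


def composition_disorder_correlations(obs: pd.DataFrame) -> pd.DataFrame:
    """Spearman correlation of disorder with every base at both site
    classes: all sites of the deposited strand and four-fold degenerate
    synonymous third positions (8 rows)."""
    rows = []
    for site_class, suffix in (("all", ""), ("fourfold", "4")):
        for base in "TCAG":
            col = base + suffix
            sub = obs.dropna(subset=[col, "D"])
            rho, p = spearman(sub[col], sub["D"])
            rows.append({"base": base, "site_class": site_class, "rho": rho, "p": p})
    return pd.DataFrame(rows)


def host_summary(
    obs: pd.DataFrame, host_disorder: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Viral disorder per host category, with min/max/range, optionally
    joined against an externally supplied host-proteome disorder table
    (columns ``host_category, host_mean, host_min, host_max``)."""
    rows = group_summaries(obs, "host_category", with_extremes=True)
    df = pd.DataFrame(
        [
            {
                "host_category": r.group,
                "N": r.n,
                "viral_mean_D": r.mean_d,
                "viral_min_D": r.min_d,
                "viral_max_D": r.max_d,
                "viral_range_D": r.range_d,
            }
            for r in rows
        ]
    )
    if host_disorder is not None:
        host = host_disorder.copy()
        if "host_min" in host.columns and "host_max" in host.columns:
            host["host_range"] = host["host_max"] - host["host_min"]
        df = df.merge(host, on="host_category", how="left")
    return df
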