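"""Multi-stage statistical discrimination of texture-parameter tables.

The analysis follows the dietary-discrimination workflow for tooth
microwear textures:

1. advisory Shapiro–Wilk normality check per group;
2. per-parameter one-way ANOVA, switched to Welch's heteroscedastic ANOVA
   (Satterthwaite denominator df) whenever Bartlett's or Levene's test
   finds evidence of unequal variances;
3. Benjamini–Hochberg step-up control of the false discovery rate across
   the 23 parameters;
4. Tukey HSD (Tukey–Kramer for unequal n) pairwise comparisons;
5. correlation-mode PCA on the parameters showing pairwise differences,
   with projection of unknown-diet specimens into the fitted space;
6. Spearman rank correlations of component scores against ordinal diet
   rank and body length;
7. subsampling robustness: repeated ANOVA of one fixed cohort against
   random k-subsets of another.

All gates (which variance test fired, which ANOVA ran) are recorded so a
replication can be diffed decision by decision.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
from statsmodels.stats.multitest import multipletests

from .errors import ParameterError, ValidationError
from .surface_io import ISO_PARAMETER_ORDER, SpecimenTable

__all__ = [
    "AnovaResult",
    "PairwiseResult",
    "PCAModel",
    "StatsConfig",
    "AnalysisReport",
    "normality_check",
    "anova_per_parameter",
    "anova_oneway",
    "bh_adjust",
    "tukey_hsd",
    "fit_pca",
    "project",
    "spearman_rank",
    "subsample_compare",
    "group_summary",
    "select_pca_parameters",
    "full_analysis",
]


# ---------------------------------------------------------------------------
# Result types
# ---------------------------------------------------------------------------

@dataclass
class AnovaResult:
    """One-way ANOVA outcome for a single texture parameter."""

    parameter: str
    F: float
    df1: float
    df2: float
    p: float
    welch: bool
    bartlett_p: float = float("nan")
    levene_p: float = float("nan")
    bh_significant: bool | None = None
    note: str = ""


@dataclass
class PairwiseResult:
    """Tukey HSD pairwise comparisons for one parameter.

    ``pairs`` maps the unordered group pair to a dict with the mean
    difference, the studentized-range statistic ``q``, the adjusted
    p-value and the significance flag.
    """

    parameter: str
    groups: list
    pairs: dict
    excluded_groups: list = field(default_factory=list)

    def significant_pairs(self, alpha: float = 0.05) -> list[frozenset]:
        return [pair for pair, d in self.pairs.items()
                if d["p_adj"] < alpha]


@dataclass
class PCAModel:
    """Correlation-mode principal components model.

    Standardization constants come from the training records only, so new
    records are projected into the training space rather than their own.
    """

    parameters: list
    means: np.ndarray
    sds: np.ndarray
    loadings: np.ndarray        # parameters x components
    explained_pct: np.ndarray
    scores: np.ndarray          # training records x components

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def to_jsonable(self) -> dict:
        return {
            "parameters": list(self.parameters),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "loadings": self.loadings.tolist(),
            "explained_pct": self.explained_pct.tolist(),
        }


def _table_frame(table) -> pd.DataFrame:
    if isinstance(table, SpecimenTable):
        return table.data
    if isinstance(table, pd.DataFrame):
        return table
    raise TypeError("expected SpecimenTable or DataFrame")


def _group_values(df: pd.DataFrame, parameter: str,
                  group_field: str = "group") -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    for g, sub in df.groupby(df[group_field].astype(str), sort=False):
        vals = pd.to_numeric(sub[parameter], errors="coerce").dropna()
        out[str(g)] = vals.to_numpy(dtype=float)
    return out


# ---------------------------------------------------------------------------
# Normality (advisory)
# ---------------------------------------------------------------------------

def normality_check(table, parameter: str,
                    group_field: str = "group") -> dict[str, float]:
    """Per-group Shapiro–Wilk p-values for one parameter.

    Advisory only: the pipeline stays parametric either way.  Groups with
    fewer than three values, or zero variance, are skipped with a warning.
    """
    df = _table_frame(table)
    out: dict[str, float] = {}
    for g, vals in _group_values(df, parameter, group_field).items():
        if len(vals) < 3:
            _warnings.warn(f"group {g!r}: n={len(vals)} < 3, "
                           "Shapiro-Wilk skipped", RuntimeWarning,
                           stacklevel=2)
            out[g] = float("nan")
            continue
        if np.ptp(vals) == 0.0:
            _warnings.warn(f"group {g!r}: constant values, "
                           "Shapiro-Wilk undefined", RuntimeWarning,
                           stacklevel=2)
            out[g] = float("nan")
            continue
        out[g] = float(st.shapiro(vals).pvalue)
    return out


# ---------------------------------------------------------------------------
# Variance-gated ANOVA
# ---------------------------------------------------------------------------

def _welch_anova(groups: Sequence[np.ndarray]) -> tuple[float, float, float, float]:
    """Welch's heteroscedastic one-way ANOVA.

    Returns (F, df1, df2, p) with Satterthwaite-approximated fractional
    denominator degrees of freedom.
    """
    k = len(groups)
    n = np.array([len(g) for g in groups], dtype=float)
    m = np.array([g.mean() for g in groups])
    v = np.array([g.var(ddof=1) for g in groups])
    w = n / v
    W = w.sum()
    mw = (w * m).sum() / W
    A = (w * (m - mw) ** 2).sum() / (k - 1)
    lam = 3.0 * ((1.0 - w / W) ** 2 / (n - 1.0)).sum() / (k ** 2 - 1.0)
    F = A / (1.0 + 2.0 * (k - 2.0) * lam / 3.0)
    df1 = k - 1.0
    df2 = 1.0 / lam
    p = float(st.f.sf(F, df1, df2))
    return float(F), df1, df2, p


def anova_oneway(groups: Sequence[np.ndarray], alpha_var: float = 0.05,
                 levene_center: str = "median") -> AnovaResult:
    """Variance-gated one-way ANOVA over raw group samples.

    Runs Bartlett's test and Levene's test (Brown–Forsythe median
    centering by default); if either rejects homogeneity at ``alpha_var``
    the Welch ANOVA is used, otherwise the classic F-test.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ParameterError("need >= 2 groups with >= 2 values each")
    k = len(groups)
    ntot = sum(len(g) for g in groups)
    if all(np.ptp(g) == 0.0 for g in groups):
        return AnovaResult("", float("nan"), k - 1.0, float(ntot - k),
                           float("nan"), False,
                           note="degenerate: zero within-group variance")
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        try:
            bart_p = float(st.bartlett(*groups).pvalue)
        except ValueError:
            bart_p = float("nan")
        lev_p = float(st.levene(*groups, center=levene_center).pvalue)
    use_welch = (bart_p < alpha_var) or (lev_p < alpha_var)
    if use_welch:
        F, df1, df2, p = _welch_anova(groups)
    else:
        F, p = st.f_oneway(*groups)
        df1, df2 = float(k - 1), float(ntot - k)
        F, p = float(F), float(p)
    return AnovaResult("", F, df1, df2, p, use_welch,
                       bartlett_p=bart_p, levene_p=lev_p)


def anova_per_parameter(table, group_field: str = "group",
                        alpha_var: float = 0.05,
                        parameters: Sequence[str] | None = None,
                        levene_center: str = "median") -> list[AnovaResult]:
    """Run the variance-gated ANOVA for every texture parameter."""
    df = _table_frame(table)
    if parameters is None:
        parameters = [p for p in ISO_PARAMETER_ORDER if p in df.columns]
    results = []
    for param in parameters:
        groups = _group_values(df, param, group_field)
        usable = {g: v for g, v in groups.items() if len(v) >= 2}
        if len(usable) < 2:
            results.append(AnovaResult(param, float("nan"), float("nan"),
                                       float("nan"), float("nan"), False,
                                       note="fewer than two usable groups"))
            continue
        res = anova_oneway(list(usable.values()), alpha_var=alpha_var,
                           levene_center=levene_center)
        res.parameter = param
        results.append(res)
    return results


# ---------------------------------------------------------------------------
# Benjamini–Hochberg
# ---------------------------------------------------------------------------

def bh_adjust(pvalues: Sequence[float], fdr: float = 0.05) -> np.ndarray:
    """Benjamini–Hochberg step-up significance flags.

    Sorts the p-values ascending, finds the largest k with
    ``p(k) <= k * fdr / m`` and flags those k smallest p-values.
    NaN p-values are never flagged.
    """
    p = np.asarray(pvalues, dtype=float)
    finite = np.isfinite(p)
    if ((p[finite] < 0) | (p[finite] > 1)).any():
        raise ParameterError("p-values must lie in [0, 1]")
    flags = np.zeros(len(p), dtype=bool)
    if finite.any():
        rej, *_ = multipletests(p[finite], alpha=fdr, method="fdr_bh")
        flags[finite] = rej
    return flags


def annotate_bh(results: list[AnovaResult], fdr: float = 0.05
                ) -> list[AnovaResult]:
    """Attach B–H significance flags to a list of ANOVA results in place."""
    flags = bh_adjust([r.p for r in results], fdr=fdr)
    for r, f in zip(results, flags):
        r.bh_significant = bool(f)
    return results


# ---------------------------------------------------------------------------
# Tukey HSD
# ---------------------------------------------------------------------------

def tukey_hsd(table, parameter: str, group_field: str = "group"
              ) -> PairwiseResult:
    """Tukey HSD (Tukey–Kramer) pairwise comparisons for one parameter.

    Groups with a single observation are excluded with a warning; the
    pooled within-group variance must be positive.
    """
    df = _table_frame(table)
    groups = _group_values(df, parameter, group_field)
    excluded = [g for g, v in groups.items() if len(v) < 2]
    for g in excluded:
        _warnings.warn(f"group {g!r} has a single observation; excluded "
                       "from Tukey HSD", RuntimeWarning, stacklevel=2)
    usable = {g: v for g, v in groups.items() if len(v) >= 2}
    if len(usable) < 2:
        raise ParameterError("need >= 2 groups with >= 2 values each")
    labels = list(usable)
    vals = [usable[g] for g in labels]
    ssw = sum(((v - v.mean()) ** 2).sum() for v in vals)
    dfw = sum(len(v) for v in vals) - len(vals)
    s2 = ssw / dfw
    if s2 <= 0:
        raise ParameterError("pooled within-group variance is zero")
    res = st.tukey_hsd(*vals)
    pairs: dict = {}
    k = len(labels)
    for i in range(k):
        for j in range(i + 1, k):
            diff = float(vals[i].mean() - vals[j].mean())
            se = np.sqrt(s2 / 2.0 * (1.0 / len(vals[i]) + 1.0 / len(vals[j])))
            q = abs(diff) / se
            p_adj = float(res.pvalue[i, j])
            pairs[frozenset((labels[i], labels[j]))] = {
                "group_a": labels[i], "group_b": labels[j],
                "diff": diff, "q": float(q), "p_adj": p_adj,
                "significant": p_adj < 0.05,
            }
    return PairwiseResult(parameter, labels, pairs, excluded)


# ---------------------------------------------------------------------------
# PCA on correlations
# ---------------------------------------------------------------------------

def fit_pca(table, parameters: Sequence[str]) -> PCAModel:
    """Principal components of the correlation matrix of ``parameters``.

    Each parameter is standardized to zero mean and unit (n-1) standard
    deviation over the training records; the correlation matrix is
    eigendecomposed; components are ordered by decreasing eigenvalue with
    a deterministic sign convention (the largest-magnitude loading of each
    component is positive).
    """
    df = _table_frame(table)
    missing = [p for p in parameters if p not in df.columns]
    if missing:
        raise ParameterError(f"parameters not in table: {missing}")
    X = df[list(parameters)].to_numpy(dtype=float)
    if len(X) < 3:
        raise ParameterError("PCA needs at least 3 records")
    if np.isnan(X).any():
        raise ValidationError("PCA input contains missing values")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    zero = np.asarray(parameters)[sds == 0]
    if len(zero):
        raise ParameterError(f"constant parameter(s): {list(zero)}")
    Z = (X - means) / sds
    corr = (Z.T @ Z) / (len(X) - 1)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    loadings = eigvec[:, order]
    # sign convention: largest-|loading| entry of each component positive
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] = -loadings[:, j]
    explained = eigval / eigval.sum() * 100.0
    scores = Z @ loadings
    return PCAModel(list(parameters), means, sds, loadings, explained, scores)


def project(model: PCAModel, records) -> np.ndarray:
    """Project new records into a fitted PCA space.

    Standardizes with the model's training means and SDs (never the new
    data's own statistics) and multiplies by the loadings.
    """
    df = _table_frame(records) if not isinstance(records, np.ndarray) else None
    if df is not None:
        missing = [p for p in model.parameters if p not in df.columns]
        if missing:
            raise ParameterError(f"records lack model parameters: {missing}")
        X = df[model.parameters].to_numpy(dtype=float)
    else:
        X = np.atleast_2d(records)
        if X.shape[1] != len(model.parameters):
            raise ParameterError("record width does not match model")
    Z = (X - model.means) / model.sds
    return Z @ model.loadings


# ---------------------------------------------------------------------------
# Spearman rank correlation
# ---------------------------------------------------------------------------

def spearman_rank(scores, covariate, method: str = "t",
                  n_permutations: int = 9999, seed: int | None = None
                  ) -> dict:
    """Tie-corrected Spearman correlation of scores against a covariate.

    ``method`` is ``"t"`` (t-approximation, suitable for n in the
    dozens) or ``"permutation"`` (exact-style Monte Carlo with a seed).
    Missing covariate entries are dropped pairwise.
    """
    x = np.asarray(scores, dtype=float)
    y = np.asarray(covariate, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 5:
        raise ParameterError(f"need n >= 5 pairs, got {len(x)}")
    if np.ptp(y) == 0.0:
        _warnings.warn("covariate is all-tied: correlation undefined",
                       RuntimeWarning, stacklevel=2)
        return {"rs": float("nan"), "p": float("nan"),
                "method": method, "n": int(len(x))}
    rho, p_t = st.spearmanr(x, y)
    if method == "t":
        return {"rs": float(rho), "p": float(p_t), "method": "t",
                "n": int(len(x))}
    if method != "permutation":
        raise ParameterError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        r_perm, _ = st.spearmanr(x, rng.permutation(y))
        if abs(r_perm) >= abs(rho) - 1e-15:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return {"rs": float(rho), "p": float(p), "method": "permutation",
            "n": int(len(x))}


# ---------------------------------------------------------------------------
# Subsampling robustness
# ---------------------------------------------------------------------------

@dataclass
class SubsampleResult:
    """Outcome of repeated fixed-vs-random-subset comparisons."""

    per_rep: list           # list of lists of flagged parameter names
    counts: dict            # parameter -> number of repetitions flagged
    reps: int
    k: int

    @property
    def per_rep_counts(self) -> list[int]:
        return [len(s) for s in self.per_rep]


def subsample_compare(table_a, table_b, k: int = 6, reps: int = 10,
                      seed: int = 0, fdr: float = 0.05,
                      alpha_var: float = 0.05,
                      parameters: Sequence[str] | None = None
                      ) -> SubsampleResult:
    """Compare a fixed cohort against random k-subsets of another.

    Per repetition, ``k`` records are drawn from ``table_b`` without
    replacement; the two-group variance-gated ANOVA is run per parameter
    and the B–H-flagged parameter names collected.  Deterministic for a
    given seed.
    """
    dfa = _table_frame(table_a)
    dfb = _table_frame(table_b)
    if k > len(dfb):
        raise ParameterError(f"k={k} exceeds table size {len(dfb)}")
    if parameters is None:
        parameters = [p for p in ISO_PARAMETER_ORDER
                      if p in dfa.columns and p in dfb.columns]
    rng = np.random.default_rng(seed)
    per_rep: list[list[str]] = []
    counts = {p: 0 for p in parameters}
    for _ in range(reps):
        take = rng.choice(len(dfb), size=k, replace=False)
        sub = dfb.iloc[np.sort(take)]
        combined = pd.concat([
            dfa[list(parameters)].assign(group="A"),
            sub[list(parameters)].assign(group="B"),
        ], ignore_index=True)
        results = anova_per_parameter(combined, alpha_var=alpha_var,
                                      parameters=list(parameters))
        annotate_bh(results, fdr=fdr)
        flagged = [r.parameter for r in results if r.bh_significant]
        per_rep.append(flagged)
        for name in flagged:
            counts[name] += 1
    return SubsampleResult(per_rep, counts, reps, k)


# ---------------------------------------------------------------------------
# Group summaries
# ---------------------------------------------------------------------------

def group_summary(scores, groups) -> pd.DataFrame:
    """Per-group mean, standard error and t-based 95% CI, plus grand mean.

    The grand mean over all records is attached as
    ``DataFrame.attrs["grand_mean"]``.  Singleton groups get a mean but
    NaN SE/CI.
    """
    x = np.asarray(scores, dtype=float)
    g = np.asarray([str(v) for v in groups])
    rows = []
    seen: dict[str, None] = {}
    for label in g:
        seen.setdefault(label, None)
    for label in seen:
        vals = x[g == label]
        n = len(vals)
        mean = float(vals.mean())
        if n < 2:
            _warnings.warn(f"group {label!r}: n=1, CI undefined",
                           RuntimeWarning, stacklevel=2)
            rows.append({"group": label, "n": n, "mean": mean,
                         "se": float("nan"), "ci_low": float("nan"),
                         "ci_high": float("nan")})
            continue
        se = float(vals.std(ddof=1) / np.sqrt(n))
        tcrit = float(st.t.ppf(0.975, n - 1))
        rows.append({"group": label, "n": n, "mean": mean, "se": se,
                     "ci_low": mean - tcrit * se,
                     "ci_high": mean + tcrit * se})
    out = pd.DataFrame(rows)
    out.attrs["grand_mean"] = float(x.mean())
    return out


# ---------------------------------------------------------------------------
# PCA parameter selection
# ---------------------------------------------------------------------------

def select_pca_parameters(pairwise: Iterable[PairwiseResult] | Mapping,
                          alpha: float = 0.05,
                          exclude_groups: Sequence[str] = ()) -> list[str]:
    """Union of parameters with significant pairwise differences.

    Accepts either computed :class:`PairwiseResult` objects or an encoded
    published pairwise table mapping ``frozenset({a, b})`` to the tuple of
    differing parameter names.  Pairs involving any label in
    ``exclude_groups`` (e.g. the within-tooth repeats) are ignored.
    Output is in canonical parameter order.
    """
    excluded = {str(g) for g in exclude_groups}
    chosen: set[str] = set()
    if isinstance(pairwise, Mapping):
        for pair, params in pairwise.items():
            if set(map(str, pair)) & excluded:
                continue
            chosen.update(params)
    else:
        for res in pairwise:
            for pair in res.significant_pairs(alpha):
                if set(map(str, pair)) & excluded:
                    continue
                chosen.add(res.parameter)
    return [p for p in ISO_PARAMETER_ORDER if p in chosen]


# ---------------------------------------------------------------------------
# Full analysis
# ---------------------------------------------------------------------------

@dataclass
class StatsConfig:
    """Settings for the end-to-end statistical analysis."""

    group_field: str = "group"
    fdr: float = 0.05
    alpha_var: float = 0.05
    alpha_pairwise: float = 0.05
    unknown_label: str | None = "5"
    within_tooth_label: str | None = "2a"
    include_within_tooth_in_anova: bool = True
    exclude_within_tooth_from_pca_pairs: bool = False
    diet_rank_field: str = "diet_rank"
    length_field: str = "total_length"
    aquarium_label: str = "1"
    subsample_k: int = 6
    subsample_reps: int = 10
    seed: int = 0


@dataclass
class AnalysisReport:
    """Bundle of every stage's outputs from :func:`full_analysis`."""

    anova: list
    pairwise: list
    pca_parameters: list
    pca: PCAModel | None
    training_groups: list
    scores: pd.DataFrame
    projections: pd.DataFrame | None
    spearman: dict
    pc1_anova: AnovaResult | None
    pc1_summary: pd.DataFrame | None
    subsampling: SubsampleResult | None
    config: StatsConfig

    def anova_table(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "parameter": r.parameter, "F": r.F, "df1": r.df1, "df2": r.df2,
            "p": r.p, "welch": r.welch, "bartlett_p": r.bartlett_p,
            "levene_p": r.levene_p, "bh_significant": r.bh_significant,
            "note": r.note,
        } for r in self.anova])

    def pairwise_table(self) -> pd.DataFrame:
        rows = []
        for res in self.pairwise:
            for d in res.pairs.values():
                rows.append({"parameter": res.parameter, **d})
        return pd.DataFrame(rows)


def full_analysis(table, config: StatsConfig | None = None) -> AnalysisReport:
    """Run the whole discrimination workflow on a parameter table.

    The ANOVA/Tukey stage compares all known-diet samples (optionally
    including the within-tooth repeats); the PCA is fitted on the
    individual-specimen samples only, and records with the unknown label
    are projected into it.  PC1 scores are then compared across all
    specimens including the unknown, correlated with diet rank and body
    length, and summarized per group.
    """
    cfg = config or StatsConfig()
    df = _table_frame(table).copy()
    df[cfg.group_field] = df[cfg.group_field].astype(str)
    params = [p for p in ISO_PARAMETER_ORDER if p in df.columns]
    if not params:
        raise ValidationError("table contains no texture parameter columns")

    known = df[df[cfg.group_field] != str(cfg.unknown_label)] \
        if cfg.unknown_label is not None else df
    anova_df = known
    if (not cfg.include_within_tooth_in_anova
            and cfg.within_tooth_label is not None):
        anova_df = known[known[cfg.group_field]
                         != str(cfg.within_tooth_label)]

    anova = anova_per_parameter(anova_df, group_field=cfg.group_field,
                                alpha_var=cfg.alpha_var, parameters=params)
    annotate_bh(anova, fdr=cfg.fdr)
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        pairwise = [tukey_hsd(anova_df, p, group_field=cfg.group_field)
                    for p in params]

    exclude = ([str(cfg.within_tooth_label)]
               if (cfg.exclude_within_tooth_from_pca_pairs
                   and cfg.within_tooth_label is not None) else [])
    pca_params = select_pca_parameters(pairwise, alpha=cfg.alpha_pairwise,
                                       exclude_groups=exclude)

    train_df = known
    if cfg.within_tooth_label is not None:
        train_df = known[known[cfg.group_field]
                         != str(cfg.within_tooth_label)]
    model = None
    scores = pd.DataFrame()
    projections = None
    spearman: dict = {}
    pc1_anova = None
    pc1_summary = None
    if len(pca_params) >= 2 and len(train_df) >= 3:
        model = fit_pca(train_df, pca_params)
        ncomp = model.n_components
        score_cols = [f"PC{i + 1}" for i in range(ncomp)]
        scores = pd.DataFrame(model.scores, columns=score_cols)
        scores.insert(0, "group", train_df[cfg.group_field].to_numpy())
        if "sample_id" in train_df.columns:
            scores.insert(0, "sample_id", train_df["sample_id"].to_numpy())

        unknown_df = (df[df[cfg.group_field] == str(cfg.unknown_label)]
                      if cfg.unknown_label is not None else df.iloc[0:0])
        if len(unknown_df):
            proj = project(model, unknown_df)
            projections = pd.DataFrame(proj, columns=score_cols)
            projections.insert(0, "group",
                               unknown_df[cfg.group_field].to_numpy())
            if "sample_id" in unknown_df.columns:
                projections.insert(0, "sample_id",
                                   unknown_df["sample_id"].to_numpy())

        # correlations against diet rank and length on the training records
        for comp in range(min(2, ncomp)):
            col = score_cols[comp]
            if cfg.diet_rank_field in train_df.columns:
                ranks = pd.to_numeric(train_df[cfg.diet_rank_field],
                                      errors="coerce").to_numpy()
                if np.isfinite(ranks).sum() >= 5:
                    with _warnings.catch_warnings():
                        _warnings.simplefilter("ignore", RuntimeWarning)
                        spearman[f"{col}_vs_diet"] = spearman_rank(
                            model.scores[:, comp], ranks)
            if cfg.length_field in train_df.columns:
                lengths = pd.to_numeric(train_df[cfg.length_field],
                                        errors="coerce").to_numpy()
                if np.isfinite(lengths).sum() >= 5:
                    with _warnings.catch_warnings():
                        _warnings.simplefilter("ignore", RuntimeWarning)
                        spearman[f"{col}_vs_length"] = spearman_rank(
                            model.scores[:, comp], lengths)

        # PC1 across every individual specimen, unknown included
        pc1 = scores[["group", "PC1"]].copy()
        if projections is not None:
            pc1 = pd.concat([pc1, projections[["group", "PC1"]]],
                            ignore_index=True)
        pc1_groups = [grp["PC1"].to_numpy()
                      for _, grp in pc1.groupby("group", sort=False)
                      if len(grp) >= 2]
        if len(pc1_groups) >= 2:
            pc1_anova = anova_oneway(pc1_groups, alpha_var=cfg.alpha_var)
            pc1_anova.parameter = "PC1"
        pc1_summary = group_summary(pc1["PC1"].to_numpy(),
                                    pc1["group"].to_numpy())

    subsampling = None
    wild = known
    for label in (cfg.within_tooth_label, cfg.aquarium_label):
        if label is not None:
            wild = wild[wild[cfg.group_field] != str(label)]
    aquarium = known[known[cfg.group_field] == str(cfg.aquarium_label)]
    if len(aquarium) >= 2 and len(wild) >= cfg.subsample_k:
        subsampling = subsample_compare(
            aquarium, wild, k=cfg.subsample_k, reps=cfg.subsample_reps,
            seed=cfg.seed, fdr=cfg.fdr, alpha_var=cfg.alpha_var,
            parameters=params)

    return AnalysisReport(anova, pairwise, pca_params, model,
                          sorted(set(train_df[cfg.group_field])),
                          scores, projections, spearman, pc1_anova,
                          pc1_summary, subsampling, cfg)
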