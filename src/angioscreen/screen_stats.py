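"""Plate normalization, reproducibility, embedding and group statistics.

Implements the analysis layer of the screen: per-plate vehicle
normalization, replicate reproducibility (Pearson r), PCA/t-SNE phenotypic
embedding of the descriptor table, the gated ANOVA+Tukey / Kruskal-Wallis+
Dunn group comparison with Bonferroni adjustment, rank-sum analyte tests
with Benjamini-Hochberg FDR control, and Welch's t-test.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.preprocessing import StandardScaler
from statsmodels.stats.multitest import multipletests

from .types import ParameterError

STAR_THRESHOLDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    """Convention: ****<0.0001, ***<0.001, **<0.01, *<0.05, else ''."""
    if np.isnan(p):
        return ""
    for thr, stars in STAR_THRESHOLDS:
        if p < thr:
            return stars
    return ""


@dataclass
class GroupComparisonResult:
    readout: str
    group_a: str
    group_b: str
    test: str  # anova_tukey | kw_dunn | wilcoxon | welch
    statistic: float
    p_raw: float
    p_adjusted: float
    adjustment: str  # bonferroni | bh | none
    stars: str = ""

    def __post_init__(self) -> None:
        if not np.isnan(self.p_adjusted):
            self.p_adjusted = float(min(1.0, self.p_adjusted))
            if self.p_adjusted < self.p_raw - 1e-12:
                raise ParameterError("adjusted p cannot be below raw p")
        self.stars = significance_stars(self.p_adjusted)


def results_table(results: Sequence[GroupComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])


# ---------------------------------------------------------------- normalization

def normalize_to_vehicle(
    viability: pd.DataFrame,
    layout: pd.DataFrame,
    control: str = "DMSO",
    value_col: str = "value",
) -> pd.DataFrame:
    """Express each chip as % of its plate's mean vehicle-control value.

    Returns the layout-joined table with an added ``normalized`` column
    (100 = vehicle level). Raises if any plate lacks vehicle chips.
    """
    merged = viability.merge(layout, on="chip", validate="one_to_one")
    ctrl_means = (
        merged[merged["treatment"] == control]
        .groupby("plate")[value_col]
        .mean()
    )
    missing = set(merged["plate"]) - set(ctrl_means.index)
    if missing:
        raise ParameterError(
            f"plate(s) without vehicle ({control}) chips: {sorted(missing)}"
        )
    merged["normalized"] = 100.0 * merged[value_col] / merged["plate"].map(ctrl_means)
    return merged


def replicate_correlation(rep1: Sequence[float], rep2: Sequence[float]) -> float:
    """Pearson r between paired replicate readouts; NaN if degenerate."""
    a = np.asarray(rep1, dtype=float)
    b = np.asarray(rep2, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ParameterError("need >= 3 replicate pairs of equal length")
    if a.std() == 0 or b.std() == 0:
        warnings.warn("zero variance in a replicate vector; r undefined",
                      stacklevel=2)
        return float("nan")
    return float(stats.pearsonr(a, b).statistic)


def replicate_pairs(
    normalized: pd.DataFrame, value_col: str = "normalized"
) -> tuple[np.ndarray, np.ndarray]:
    """First vs second replicate per (plate, treatment) condition."""
    g = normalized.sort_values("replicate").groupby(["plate", "treatment"])
    firsts, seconds = [], []
    for _, grp in g:
        vals = grp[value_col].to_numpy()
        if len(vals) >= 2:
            firsts.append(vals[0])
            seconds.append(vals[1])
    return np.array(firsts), np.array(seconds)


# ------------------------------------------------------------------- embedding

def embed(
    descriptors: pd.DataFrame,
    method: str = "pca",
    n_components: int = 2,
    seed: Optional[int] = None,
    perplexity: Optional[float] = None,
    drop_columns: Sequence[str] = (),
) -> tuple[pd.DataFrame, Optional[np.ndarray]]:
    """2-D PCA or t-SNE embedding of a per-chip descriptor table.

    Columns are standardized to zero mean / unit variance; columns that are
    constant or contain missing (flagged-degenerate) values are dropped.
    PCA uses a fixed sign convention (the loading of largest magnitude on
    each component is positive) so results are reproducible; t-SNE requires
    an explicit seed and a perplexity < n_chips / 3.

    Returns
    -------
    (coords, explained) where coords has columns chip, dim1, dim2 and
    explained is the per-component explained-variance fraction (PCA only).
    """
    chips = descriptors["chip"]
    X = descriptors.drop(columns=["chip", *drop_columns], errors="ignore")
    X = X.loc[:, X.notna().all(axis=0)]
    X = X.loc[:, X.std(axis=0) > 0]
    if len(X) < n_components:
        raise ParameterError("fewer chips than requested components")
    Z = StandardScaler().fit_transform(X.to_numpy(dtype=float))

    if method == "pca":
        pca = PCA(n_components=n_components, svd_solver="full")
        Y = pca.fit_transform(Z)
        # sign convention: largest-|loading| entry of each component positive
        for k in range(n_components):
            comp = pca.components_[k]
            if comp[np.argmax(np.abs(comp))] < 0:
                pca.components_[k] = -comp
                Y[:, k] = -Y[:, k]
        explained = pca.explained_variance_ratio_
    elif method == "tsne":
        if seed is None:
            raise ParameterError("t-SNE requires an explicit seed")
        n = len(Z)
        if perplexity is None:
            perplexity = min(30.0, n / 4.0)
        if not perplexity < n / 3:
            raise ParameterError("perplexity must be < n_chips / 3")
        Y = TSNE(
            n_components=n_components, perplexity=perplexity,
            random_state=seed, init="pca",
        ).fit_transform(Z)
        explained = None
    else:
        raise ParameterError(f"unknown embedding method {method!r}")

    coords = pd.DataFrame(
        {"chip": chips.to_numpy(), **{f"dim{k + 1}": Y[:, k] for k in range(n_components)}}
    )
    return coords, explained


# ------------------------------------------------------------- group comparison

def _dunn_pairwise(groups: Mapping[str, np.ndarray]) -> list[tuple[str, str, float, float]]:
    """Dunn's post-hoc z tests after Kruskal-Wallis, with tie correction.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j))
    where T = sum(t^3 - t) over tie groups of the pooled sample.
    """
    labels = list(groups)
    pooled = np.concatenate([groups[k] for k in labels])
    n = {k: len(groups[k]) for k in labels}
    N = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_rank = {}
    i = 0
    for k in labels:
        mean_rank[k] = ranks[i : i + n[k]].mean()
        i += n[k]
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var_base = N * (N + 1) / 12.0 - tie_term / (12.0 * (N - 1))
    out = []
    for a, b in combinations(labels, 2):
        se = np.sqrt(var_base * (1.0 / n[a] + 1.0 / n[b]))
        if se == 0:
            z, p = 0.0, 1.0
        else:
            z = (mean_rank[a] - mean_rank[b]) / se
            p = 2.0 * stats.norm.sf(abs(z))
        out.append((a, b, float(z), float(p)))
    return out


def _tukey_pairwise(groups: Mapping[str, np.ndarray]) -> list[tuple[str, str, float, float]]:
    """Tukey HSD pairwise p-values via the studentized range distribution."""
    labels = list(groups)
    res = stats.tukey_hsd(*[groups[k] for k in labels])
    out = []
    for i, j in combinations(range(len(labels)), 2):
        out.append((labels[i], labels[j],
                    float(res.statistic[i, j]), float(res.pvalue[i, j])))
    return out


def compare_groups(
    groups: Mapping[str, Sequence[float]],
    design: str = "auto",
    readout: str = "",
    alpha_normality: float = 0.05,
) -> list[GroupComparisonResult]:
    """All-pairs comparison of >= 2 groups with the gated test battery.

    ``auto`` runs Shapiro-Wilk on each group at ``alpha_normality``; if all
    groups look gaussian the parametric path is taken (one-way ANOVA with
    Tukey HSD post-hoc), otherwise the nonparametric path (Kruskal-Wallis
    with Dunn post-hoc). Post-hoc p-values are then Bonferroni-adjusted
    across the pairwise comparisons. A zero-variance group on the parametric
    path triggers a fallback to the nonparametric path with a warning.
    """
    arrs = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(arrs) < 2 or any(len(a) < 2 for a in arrs.values()):
        raise ParameterError("need >= 2 groups with >= 2 values each")

    if design not in ("auto", "parametric", "nonparametric"):
        raise ParameterError(f"unknown design {design!r}")
    path = design
    if path == "auto":
        gaussian = True
        for a in arrs.values():
            if len(a) < 3 or a.std() == 0:
                gaussian = False
                break
            if stats.shapiro(a).pvalue < alpha_normality:
                gaussian = False
                break
        path = "parametric" if gaussian else "nonparametric"
    if path == "parametric" and any(a.std() == 0 for a in arrs.values()):
        warnings.warn("zero-variance group; falling back to nonparametric path",
                      stacklevel=2)
        path = "nonparametric"

    if path == "parametric":
        pairs = _tukey_pairwise(arrs)
        test = "anova_tukey"
    else:
        pairs = _dunn_pairwise(arrs)
        test = "kw_dunn"

    m = len(pairs)
    out = []
    for a, b, stat, p in pairs:
        out.append(
            GroupComparisonResult(
                readout=readout, group_a=a, group_b=b, test=test,
                statistic=stat, p_raw=p,
                p_adjusted=min(1.0, p * m), adjustment="bonferroni",
            )
        )
    return out


# ---------------------------------------------------------------- analyte tests

def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided unpaired Wilcoxon rank-sum (Mann-Whitney U).

    Exact null distribution for small tie-free samples, otherwise the
    normal approximation with mid-ranks, tie correction and continuity
    correction. Identical constant samples give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.std() == 0 and y.std() == 0 and len(x) and len(y) and x[0] == y[0]:
        return 0.0, 1.0
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return float(res.statistic), float(min(1.0, res.pvalue))


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def analyte_tests(
    analytes: pd.DataFrame,
    layout: pd.DataFrame,
    control: str = "DMSO",
    family: str = "global",
) -> list[GroupComparisonResult]:
    """Per analyte x treatment rank-sum tests vs control, BH-adjusted.

    ``family="global"`` adjusts across the full analyte x treatment family
    (the default); ``family="per_analyte"`` adjusts within each analyte.
    """
    merged = analytes.merge(layout[["chip", "treatment"]], on="chip")
    if control not in set(merged["treatment"]):
        raise ParameterError(f"control group {control!r} absent from layout")
    analyte_cols = [c for c in analytes.columns if c != "chip"]
    treatments = [t for t in merged["treatment"].unique() if t != control]

    raw: list[tuple[str, str, float, float]] = []
    for col in analyte_cols:
        ctrl_vals = merged.loc[merged["treatment"] == control, col].to_numpy()
        for trt in treatments:
            vals = merged.loc[merged["treatment"] == trt, col].to_numpy()
            u, p = wilcoxon_rank_sum(vals, ctrl_vals)
            raw.append((col, trt, u, p))

    out: list[GroupComparisonResult] = []
    if not raw:
        return out
    if family == "global":
        q = benjamini_hochberg([r[3] for r in raw])
        q_iter = iter(q)
        for (col, trt, u, p) in raw:
            out.append(GroupComparisonResult(
                readout=col, group_a=trt, group_b=control, test="wilcoxon",
                statistic=u, p_raw=p, p_adjusted=float(next(q_iter)),
                adjustment="bh",
            ))
    elif family == "per_analyte":
        for col in analyte_cols:
            sub = [r for r in raw if r[0] == col]
            q = benjamini_hochberg([r[3] for r in sub])
            for (c, trt, u, p), qv in zip(sub, q):
                out.append(GroupComparisonResult(
                    readout=c, group_a=trt, group_b=control, test="wilcoxon",
                    statistic=u, p_raw=p, p_adjusted=float(qv), adjustment="bh",
                ))
    else:
        raise ParameterError(f"unknown family {family!r}")
    return out


def welch_compare(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Welch's unequal-variance t-test (two-sided, Satterthwaite df)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ParameterError("each group needs n >= 2")
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float("inf") * np.sign(a.mean() - b.mean()), 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


# ------------------------------------------------------------------ heatmapping

def signed_significance_matrix(
    results: Sequence[GroupComparisonResult],
    data: pd.DataFrame,
    layout: pd.DataFrame,
    control: str = "DMSO",
) -> pd.DataFrame:
    """Treatment x readout matrix of signed -log10 adjusted p.

    Sign is the direction of the median treated-vs-control difference;
    magnitude is -log10(q). Heatmap-ready summary of a results list.
    """
    merged = data.merge(layout[["chip", "treatment"]], on="chip")
    med = merged.groupby("treatment").median(numeric_only=True)
    mat: dict[str, dict[str, float]] = {}
    for r in results:
        if r.readout not in med.columns:
            continue
        delta = med.loc[r.group_a, r.readout] - med.loc[control, r.readout]
        sign = 1.0 if delta > 0 else (-1.0 if delta < 0 else 0.0)
        val = sign * (-np.log10(max(r.p_adjusted, 1e-300)))
        mat.setdefault(r.group_a, {})[r.readout] = val
    return pd.DataFrame(mat).T.sort_index()
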