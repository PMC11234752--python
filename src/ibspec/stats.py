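"""Statistical layer: pretest-driven test selection, post hocs, bootstrap.

Group comparisons follow a decision tree: Shapiro-Wilk normality per
group and Bartlett homoscedasticity across groups select between one-way
ANOVA (all pretests pass) and Kruskal-Wallis, followed by a suitable post
hoc (Tukey HSD or Dunnett after ANOVA; Dunn after Kruskal-Wallis).  The
pretest level is controlled family-wise: each pretest p-value is compared
to ``alpha_pretest / (n_groups + 1)`` (Bonferroni over the per-group
Shapiro tests plus Bartlett), so under a Gaussian null the parametric
branch is chosen with probability ~ 1 - alpha_pretest; set
``pretest_correction="none"`` for raw per-test comparisons.

Multiple-comparison adjustment is uncapped Bonferroni by default
(adjusted p-values above 1 are reported as such, e.g. p_adj = 2.2);
confidence intervals are seed-deterministic percentile bootstraps, and
correlation matrices are tested by bootstrapping the per-dataset set of
Pearson correlations against zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA

logger = logging.getLogger("ibspec.stats")

__all__ = [
    "StatTestReport",
    "choose_and_run_test",
    "posthoc",
    "bonferroni",
    "bootstrap_ci",
    "CorrelationMatrixResult",
    "correlation_matrix_bootstrap",
    "PCAResult",
    "pca_spectra",
    "embed_spectra",
    "t_test",
    "wilcoxon_signed_rank",
]


@dataclass
class StatTestReport:
    """Full record of one decision-tree group comparison."""

    group_labels: list[str]
    group_sizes: list[int]
    normality_p: list[float]
    homoscedasticity_p: float
    pretest_alpha: float
    pretest_threshold: float
    chosen_test: str  # "ANOVA" | "Kruskal-Wallis"
    statistic: float
    p: float
    posthoc_method: str | None = None
    posthoc_table: pd.DataFrame | None = None
    m: int = 1  # Bonferroni comparison count applied to `p_adj`
    p_adj: float | None = None
    n_adjustments: int = 0  # guards against silent double-correction

    def to_dict(self) -> dict:
        d = {
            "group_labels": self.group_labels,
            "group_sizes": self.group_sizes,
            "normality_p": self.normality_p,
            "homoscedasticity_p": self.homoscedasticity_p,
            "pretest_alpha": self.pretest_alpha,
            "pretest_threshold": self.pretest_threshold,
            "chosen_test": self.chosen_test,
            "statistic": self.statistic,
            "p": self.p,
            "posthoc_method": self.posthoc_method,
            "m": self.m,
            "p_adj": self.p_adj,
            "n_adjustments": self.n_adjustments,
        }
        if self.posthoc_table is not None:
            d["posthoc"] = self.posthoc_table.to_dict(orient="records")
        return d


def _check_groups(groups: Sequence[np.ndarray], min_n: int = 3) -> list[np.ndarray]:
    gs = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least 2 groups")
    for i, g in enumerate(gs):
        if g.size < min_n:
            raise ValueError(f"group {i} has n={g.size} < {min_n}")
    return gs


def choose_and_run_test(
    groups: Sequence[np.ndarray],
    alpha_pretest: float = 0.05,
    *,
    labels: Sequence[str] | None = None,
    pretest_correction: str = "bonferroni",
    posthoc_method: str | None = None,
    control_index: int | None = None,
    m: int | None = None,
) -> StatTestReport:
    """Run the pretest decision tree and the selected omnibus test.

    ANOVA is chosen when every per-group Shapiro p and the Bartlett p
    exceed the (family-wise corrected) pretest threshold, otherwise
    Kruskal-Wallis.  ``posthoc_method`` optionally appends a pairwise
    table ("tukey", "dunnett" — requires ``control_index`` — or "dunn");
    ``m`` applies an uncapped Bonferroni factor to the omnibus p.
    """
    gs = _check_groups(groups)
    labels = list(labels) if labels is not None else [f"group{i}" for i in range(len(gs))]
    if pretest_correction not in ("bonferroni", "none"):
        raise ValueError("pretest_correction must be 'bonferroni' or 'none'")
    n_pretests = len(gs) + 1
    threshold = alpha_pretest / n_pretests if pretest_correction == "bonferroni" else alpha_pretest
    normality_p = [float(sps.shapiro(g).pvalue) for g in gs]
    bartlett_p = float(sps.bartlett(*gs).pvalue)
    parametric = all(p > threshold for p in normality_p) and bartlett_p > threshold
    if parametric:
        stat, p = sps.f_oneway(*gs)
        chosen = "ANOVA"
    else:
        stat, p = sps.kruskal(*gs)
        chosen = "Kruskal-Wallis"
    report = StatTestReport(
        group_labels=labels,
        group_sizes=[g.size for g in gs],
        normality_p=normality_p,
        homoscedasticity_p=bartlett_p,
        pretest_alpha=alpha_pretest,
        pretest_threshold=threshold,
        chosen_test=chosen,
        statistic=float(stat),
        p=float(p),
    )
    if m is not None:
        report.m = int(m)
        report.p_adj = float(bonferroni([report.p], m=m)[0])
        report.n_adjustments = 1
    if posthoc_method is not None:
        if posthoc_method in ("tukey", "dunnett") and chosen != "ANOVA":
            logger.info(
                "posthoc %s requested but %s branch taken; using Dunn", posthoc_method, chosen
            )
            posthoc_method = "dunn"
        report.posthoc_method = posthoc_method
        report.posthoc_table = posthoc(gs, posthoc_method, control_index=control_index)
    return report


def _dunn(gs: list[np.ndarray]) -> pd.DataFrame:
    """Dunn's rank-based pairwise test (z on mean ranks, tie-corrected)."""
    all_vals = np.concatenate(gs)
    ranks = sps.rankdata(all_vals)
    n = all_vals.size
    # tie correction
    _, counts = np.unique(all_vals, return_counts=True)
    tie = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    splits = np.cumsum([g.size for g in gs])[:-1]
    group_ranks = np.split(ranks, splits)
    mean_ranks = [r.mean() for r in group_ranks]
    rows = []
    for i, j in combinations(range(len(gs)), 2):
        se = np.sqrt(tie * n * (n + 1) / 12.0 * (1.0 / gs[i].size + 1.0 / gs[j].size))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append(dict(group_i=i, group_j=j, statistic=float(z), p=float(p)))
    return pd.DataFrame(rows)


def posthoc(
    groups: Sequence[np.ndarray],
    method: str,
    control_index: int | None = None,
) -> pd.DataFrame:
    """Pairwise post hoc p-value table.

    * ``tukey`` — all pairs, studentized-range distribution;
    * ``dunnett`` — every group against ``groups[control_index]``,
      multivariate-t critical values;
    * ``dunn`` — rank-based pairwise z tests (Kruskal-Wallis follow-up).
    """
    gs = _check_groups(groups)
    if method == "tukey":
        res = sps.tukey_hsd(*gs)
        rows = [
            dict(group_i=i, group_j=j, statistic=float(res.statistic[i, j]),
                 p=float(res.pvalue[i, j]))
            for i, j in combinations(range(len(gs)), 2)
        ]
        return pd.DataFrame(rows)
    if method == "dunnett":
        if control_index is None:
            raise ValueError("Dunnett's test requires a control_index")
        control = gs[control_index]
        others = [(i, g) for i, g in enumerate(gs) if i != control_index]
        res = sps.dunnett(*[g for _, g in others], control=control)
        rows = [
            dict(group_i=control_index, group_j=i, statistic=float(res.statistic[k]),
                 p=float(res.pvalue[k]))
            for k, (i, _) in enumerate(others)
        ]
        return pd.DataFrame(rows)
    if method == "dunn":
        return _dunn(gs)
    raise ValueError(f"unknown post hoc method {method!r}")


def bonferroni(p_values, m: int | None = None, cap: bool = False) -> np.ndarray:
    """Bonferroni adjustment ``p_adj = m * p``, uncapped by default.

    Uncapped values (> 1) are reported as computed, matching the
    convention of quoting e.g. p_adj = 2.2; pass ``cap=True`` to clip at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError(f"m={m} is smaller than the number of p values ({p.size})")
    adj = m * p
    return np.minimum(adj, 1.0) if cap else adj


def bootstrap_ci(
    values,
    statistic: Callable = np.mean,
    n_boot: int = 9999,
    level: float = 0.95,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Seed-deterministic percentile bootstrap CI of a statistic."""
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 2:
        raise ValueError("bootstrap CI needs at least 2 values")
    rng = rng if rng is not None else np.random.default_rng(seed)
    idx = rng.integers(0, v.size, size=(int(n_boot), v.size))
    sample = v[idx]
    try:
        reps = statistic(sample, axis=1)
    except TypeError:
        reps = np.apply_along_axis(statistic, 1, sample)
    a = (1.0 - level) / 2.0
    lo, hi = np.quantile(reps, [a, 1.0 - a])
    return float(lo), float(hi)


@dataclass
class CorrelationMatrixResult:
    """Bootstrap-tested mean Pearson correlation matrix across datasets."""

    properties: list[str]
    r_mean: pd.DataFrame
    p: pd.DataFrame
    p_adj: pd.DataFrame
    significant: pd.DataFrame
    n_datasets: pd.DataFrame
    m: int  # number of property pairs (Bonferroni factor)


def correlation_matrix_bootstrap(
    per_dataset_tables: Sequence[pd.DataFrame],
    columns: Sequence[str] | None = None,
    n_boot: int = 9999,
    alpha: float = 0.05,
    seed: int | None = 0,
) -> CorrelationMatrixResult:
    """Test which property-pair correlations differ from zero.

    Pearson r is computed for every property pair within each dataset
    (constant properties give an undefined r for that dataset and are
    excluded from its pair's set).  The resulting per-pair set of r values
    is bootstrap-resampled (``n_boot`` times); the two-sided percentile
    p-value of the mean r against 0 is Bonferroni-corrected over the
    number of pairs, and pairs with corrected p < ``alpha`` are flagged.
    """
    tables = list(per_dataset_tables)
    if len(tables) < 2:
        raise ValueError("need at least 2 datasets")
    if columns is None:
        columns = [
            c
            for c in tables[0].columns
            if all(c in t.columns for t in tables)
            and np.issubdtype(tables[0][c].dtype, np.number)
        ]
    cols = list(columns)
    k = len(cols)
    pairs = list(combinations(range(k), 2))
    m = len(pairs)
    rng = np.random.default_rng(seed)

    r_sets: dict[tuple[int, int], list[float]] = {pr: [] for pr in pairs}
    for t in tables:
        if len(t) < 3:
            raise ValueError("each dataset needs at least 3 records")
        x = t[cols].to_numpy(dtype=float)
        std = x.std(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.corrcoef(x, rowvar=False)
        for i, j in pairs:
            if std[i] == 0 or std[j] == 0 or not np.isfinite(c[i, j]):
                continue
            r_sets[(i, j)].append(float(c[i, j]))

    r_mean = np.full((k, k), np.nan)
    p_mat = np.full((k, k), np.nan)
    n_mat = np.zeros((k, k), dtype=int)
    np.fill_diagonal(r_mean, 1.0)
    for (i, j), rs in r_sets.items():
        n_mat[i, j] = n_mat[j, i] = len(rs)
        if len(rs) < 2:
            logger.warning(
                "correlation pair (%s, %s): <2 defined correlations; skipped",
                cols[i], cols[j],
            )
            continue
        arr = np.asarray(rs)
        idx = rng.integers(0, arr.size, size=(int(n_boot), arr.size))
        means = arr[idx].mean(axis=1)
        frac_le = (np.sum(means <= 0) + 1) / (n_boot + 1)
        frac_ge = (np.sum(means >= 0) + 1) / (n_boot + 1)
        p = min(1.0, 2.0 * min(frac_le, frac_ge))
        r_mean[i, j] = r_mean[j, i] = arr.mean()
        p_mat[i, j] = p_mat[j, i] = p

    p_adj = m * p_mat  # uncapped Bonferroni over property pairs
    sig = p_adj < alpha

    def df(a):
        return pd.DataFrame(a, index=cols, columns=cols)

    return CorrelationMatrixResult(
        properties=cols,
        r_mean=df(r_mean),
        p=df(p_mat),
        p_adj=df(p_adj),
        significant=df(sig),
        n_datasets=df(n_mat),
        m=m,
    )


@dataclass
class PCAResult:
    components: np.ndarray  # (n_components, n_features) loadings
    scores: np.ndarray  # (n_samples, n_components)
    explained_variance_ratio: np.ndarray
    mean: np.ndarray


def _spectra_matrix(spectra_or_matrix) -> np.ndarray:
    from .data_model import Spectrum

    if isinstance(spectra_or_matrix, np.ndarray):
        return np.asarray(spectra_or_matrix, dtype=float)
    spectra = list(spectra_or_matrix)
    if spectra and isinstance(spectra[0], Spectrum):
        g0 = spectra[0].grid
        for s in spectra[1:]:
            if not g0.matches(s.grid):
                raise ValueError("spectra have mixed grids")
        return np.vstack([s.ir_amplitude for s in spectra])
    return np.asarray(spectra_or_matrix, dtype=float)


def pca_spectra(spectra_or_matrix, n_components: int | None = None) -> PCAResult:
    """Mean-centered PCA of processed spectra with a deterministic sign.

    Each component is flipped, if necessary, so that its largest-magnitude
    loading is positive (scores flipped accordingly).
    """
    x = _spectra_matrix(spectra_or_matrix)
    if x.shape[0] < 3:
        raise ValueError("PCA needs at least 3 spectra")
    n_components = n_components or min(x.shape[0] - 1, x.shape[1], 10)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(x)
    comps = pca.components_.copy()
    for i in range(comps.shape[0]):
        jmax = int(np.argmax(np.abs(comps[i])))
        if comps[i, jmax] < 0:
            comps[i] *= -1.0
            scores[:, i] *= -1.0
    return PCAResult(
        components=comps,
        scores=scores,
        explained_variance_ratio=pca.explained_variance_ratio_,
        mean=pca.mean_,
    )


def embed_spectra(spectra_or_matrix, method="umap", seed: int = 0, **kwargs) -> np.ndarray:
    """2D embedding of spectra via a pluggable nonlinear method.

    ``method`` may be a callable ``(matrix) -> (n, 2)``, ``"umap"``
    (requires umap-learn) or ``"pca"`` (first two principal components).
    """
    x = _spectra_matrix(spectra_or_matrix)
    if callable(method):
        out = np.asarray(method(x))
    elif method == "umap":
        import umap

        out = umap.UMAP(n_components=2, random_state=seed, **kwargs).fit_transform(x)
    elif method == "pca":
        out = pca_spectra(x, n_components=2).scores[:, :2]
    else:
        raise ValueError(f"unknown embedding method {method!r}")
    if out.ndim != 2 or out.shape[1] != 2:
        raise ValueError("embedding must return (n, 2) coordinates")
    return out


def t_test(a, b=None, popmean: float = 0.0, paired: bool = False) -> tuple[float, float]:
    """One-sample, two-sample (pooled) or paired t test -> (statistic, p)."""
    a = np.asarray(a, dtype=float)
    if b is None:
        res = sps.ttest_1samp(a, popmean)
    elif paired:
        res = sps.ttest_rel(a, np.asarray(b, dtype=float))
    else:
        res = sps.ttest_ind(a, np.asarray(b, dtype=float), equal_var=True)
    return float(res.statistic), float(res.pvalue)


def wilcoxon_signed_rank(a, b=None) -> tuple[float, float]:
    """Wilcoxon signed-rank test of paired differences -> (statistic, p)."""
    res = sps.wilcoxon(np.asarray(a, dtype=float), None if b is None else np.asarray(b, float))
    return float(res.statistic), float(res.pvalue)
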