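"""Targeted amino-acid / acylcarnitine panel statistics.

The chain mirrors the standard targeted-metabolomics workflow for a
two-group muscle study: concentrations (already normalized to total protein)
are log10-transformed and Pareto-scaled, a PLS-DA model with VIP scores
ranks discriminant metabolites, and a normality-gated univariate pass
(Welch t where both groups look Gaussian by the D'Agostino-Pearson omnibus
test, Mann-Whitney otherwise) feeds a volcano classification and a
Euclidean hierarchical clustering for heatmap display.

Everything here is deterministic: no random number generator is used.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

logger = logging.getLogger(__name__)

__all__ = [
    "MetabolitePanel",
    "preprocess",
    "pareto_scale",
    "PLSDA",
    "PLSDAResults",
    "fit_plsda",
    "vip_scores",
    "discriminant_features",
    "UnivariateResult",
    "univariate_panel",
    "volcano",
    "cluster_heatmap",
]


@dataclass
class MetabolitePanel:
    """Metabolite x sample concentration matrix with two-group labels.

    Parameters
    ----------
    concentrations
        DataFrame indexed by metabolite id, one column per sample; strictly
        positive values (amount per total protein).
    groups
        Mapping sample -> group label; exactly two labels must occur.
    """

    concentrations: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        self.groups = pd.Series(self.groups)
        missing = [s for s in self.concentrations.columns if s not in self.groups.index]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")
        self.groups = self.groups.loc[list(self.concentrations.columns)]
        labels = self.groups.unique()
        if len(labels) != 2:
            raise ValueError(f"need exactly two groups, got {list(labels)}")
        bad = np.argwhere(~(self.concentrations.to_numpy() > 0))
        if bad.size:
            i, j = bad[0]
            raise ValueError(
                "non-positive concentration for metabolite "
                f"{self.concentrations.index[i]!r} in sample {self.concentrations.columns[j]!r}"
            )

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.concentrations.index)

    @property
    def group_labels(self) -> tuple[str, str]:
        """(group A, group B) in order of first appearance among samples."""
        seen = list(dict.fromkeys(self.groups))
        return seen[0], seen[1]

    def samples_of(self, label: str) -> list[str]:
        return [s for s in self.concentrations.columns if self.groups[s] == label]

    def values_of(self, metabolite: str, label: str) -> np.ndarray:
        return self.concentrations.loc[metabolite, self.samples_of(label)].to_numpy(dtype=float)

    @classmethod
    def from_tsv(cls, panel_path: str | Path, groups_path: str | Path) -> "MetabolitePanel":
        """Read a panel TSV (first column metabolite id) and a two-column
        sample-to-group map TSV (columns: sample, group)."""
        conc = pd.read_csv(panel_path, sep="\t", index_col=0)
        gmap = pd.read_csv(groups_path, sep="\t")
        groups = pd.Series(gmap.iloc[:, 1].values, index=gmap.iloc[:, 0].astype(str).values)
        return cls(conc, groups)

    def to_tsv(self, panel_path: str | Path, groups_path: str | Path) -> None:
        self.concentrations.rename_axis("metabolite").to_csv(panel_path, sep="\t")
        pd.DataFrame({"sample": self.groups.index, "group": self.groups.values}).to_csv(
            groups_path, sep="\t", index=False
        )


def pareto_scale(y: np.ndarray, axis: int = 0) -> np.ndarray:
    """Mean-center and divide by sqrt(sd) (sample sd, ddof=1) per variable.

    Variables with zero spread are passed through centered-only (all zeros).
    """
    y = np.asarray(y, dtype=float)
    mean = y.mean(axis=axis, keepdims=True)
    sd = y.std(axis=axis, ddof=1, keepdims=True)
    if np.any(sd == 0):
        warnings.warn("constant variable(s): Pareto scaling centers only", stacklevel=2)
    divisor = np.where(sd > 0, np.sqrt(np.where(sd > 0, sd, 1.0)), 1.0)
    return (y - mean) / divisor


def preprocess(panel: MetabolitePanel) -> pd.DataFrame:
    """log10 transform then Pareto scaling, per metabolite.

    Returns a sample x metabolite matrix (samples as rows), the layout the
    PLS-DA fit expects.
    """
    x = panel.concentrations.to_numpy(dtype=float).T  # samples x metabolites
    scaled = pareto_scale(np.log10(x), axis=0)
    return pd.DataFrame(scaled, index=panel.concentrations.columns, columns=panel.concentrations.index)


# ---------------------------------------------------------------------------
# PLS-DA


class PLSDA:
    """Two-group PLS-DA model (NIPALS PLS1 against a +/-1 coded response).

    Parameters
    ----------
    X
        Preprocessed sample x variable matrix (DataFrame or array).
    groups
        One label per sample; exactly two labels.  The first label in order
        of appearance is coded +1.
    n_components
        Components requested; reduced with a warning if the data rank is
        lower.
    """

    def __init__(self, X, groups: Sequence[str], n_components: int = 2) -> None:
        if isinstance(X, pd.DataFrame):
            self.var_names = list(X.columns)
            self.sample_names = list(X.index)
            self.X = X.to_numpy(dtype=float)
        else:
            self.X = np.asarray(X, dtype=float)
            self.var_names = [f"v{j}" for j in range(self.X.shape[1])]
            self.sample_names = [f"s{i}" for i in range(self.X.shape[0])]
        self.groups = list(groups)
        if len(self.groups) != self.X.shape[0]:
            raise ValueError("one group label per sample required")
        levels = list(dict.fromkeys(self.groups))
        if len(levels) != 2:
            raise ValueError(f"need exactly two groups, got {levels}")
        counts = [self.groups.count(l) for l in levels]
        if min(counts) < 2:
            raise ValueError("need at least 2 samples per group")
        self.positive_class, self.negative_class = levels
        self.n_components = int(n_components)

    @classmethod
    def from_panel(cls, panel: MetabolitePanel, n_components: int = 2) -> "PLSDA":
        return cls(preprocess(panel), list(panel.groups), n_components=n_components)

    def fit(self) -> "PLSDAResults":
        X = self.X.copy()
        y = np.array([1.0 if g == self.positive_class else -1.0 for g in self.groups])
        y = y - y.mean()  # guard against unbalanced groups
        ss_y = float(y @ y)
        ss_x = float((X * X).sum())
        if ss_y == 0:
            raise ValueError("response has no variance")
        n, p = X.shape
        W, T, P, Q = [], [], [], []
        ssy_expl, ssx_expl = [], []
        a = 0
        while a < self.n_components:
            cov = X.T @ y
            norm = np.linalg.norm(cov)
            if norm < 1e-12 * max(1.0, ss_y):
                warnings.warn(
                    f"rank deficiency: only {a} of {self.n_components} components extracted",
                    stacklevel=2,
                )
                break
            w = cov / norm
            t = X @ w
            tt = float(t @ t)
            if tt < 1e-24:
                break
            p_load = X.T @ t / tt
            q = float(y @ t) / tt
            X = X - np.outer(t, p_load)
            y = y - q * t
            W.append(w)
            T.append(t)
            P.append(p_load)
            Q.append(q)
            ssy_expl.append(q * q * tt / ss_y)
            ssx_expl.append(float(tt * (p_load @ p_load)) / ss_x if ss_x > 0 else 0.0)
            a += 1
        if a == 0:
            raise ValueError("no PLS component could be extracted (X orthogonal to response)")
        return PLSDAResults(
            model=self,
            weights=np.column_stack(W),
            scores=np.column_stack(T),
            x_loadings=np.column_stack(P),
            y_loadings=np.asarray(Q),
            explained_y_variance=np.asarray(ssy_expl),
            explained_x_variance=np.asarray(ssx_expl),
        )


@dataclass
class PLSDAResults:
    """Fitted PLS-DA: scores, weights/loadings, explained variance, VIP."""

    model: PLSDA
    weights: np.ndarray  # variable x component, unit-norm columns
    scores: np.ndarray  # sample x component
    x_loadings: np.ndarray  # variable x component
    y_loadings: np.ndarray  # per component
    explained_y_variance: np.ndarray  # fractions per component
    explained_x_variance: np.ndarray

    @property
    def n_components(self) -> int:
        return self.weights.shape[1]

    @property
    def vip(self) -> pd.Series:
        """Variable importance in projection.

        VIP_j = sqrt(p * sum_a(w_ja^2 * SSY_a) / sum_a(SSY_a)) with p the
        number of variables and SSY_a the Y-variance explained by component
        a; by construction mean(VIP^2) = 1.
        """
        ssy = self.explained_y_variance
        total = float(ssy.sum())
        if total <= 0:
            raise ValueError("VIP undefined: model explains no Y variance")
        p = self.weights.shape[0]
        v = np.sqrt(p * (self.weights**2 @ ssy) / total)
        return pd.Series(v, index=self.model.var_names, name="vip")

    def scores_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.scores,
            index=self.model.sample_names,
            columns=[f"component_{a+1}" for a in range(self.n_components)],
        )

    def discriminant_features(self, cutoff: float = 1.5) -> pd.Series:
        """Variables with VIP strictly above ``cutoff``, sorted descending."""
        v = self.vip
        return v[v > cutoff].sort_values(ascending=False)

    def summary_text(self) -> str:
        lines = [
            f"PLS-DA: {self.model.positive_class} (+1) vs {self.model.negative_class} (-1), "
            f"{len(self.model.sample_names)} samples x {len(self.model.var_names)} variables",
        ]
        for a in range(self.n_components):
            lines.append(
                f"  component {a+1}: explained Y variance "
                f"{100 * self.explained_y_variance[a]:.1f}%  "
                f"(X variance {100 * self.explained_x_variance[a]:.1f}%)"
            )
        top = self.vip.sort_values(ascending=False).head(5)
        lines.append("  top VIP: " + ", ".join(f"{k}={v:.2f}" for k, v in top.items()))
        return "\n".join(lines)


def fit_plsda(X, groups: Sequence[str], n_components: int = 2) -> PLSDAResults:
    """Fit a two-group PLS-DA on an already-preprocessed matrix."""
    return PLSDA(X, groups, n_components=n_components).fit()


def vip_scores(results: PLSDAResults) -> pd.Series:
    return results.vip


def discriminant_features(results: PLSDAResults, cutoff: float = 1.5) -> pd.Series:
    return results.discriminant_features(cutoff)


# ---------------------------------------------------------------------------
# Univariate chain


@dataclass(frozen=True)
class UnivariateResult:
    metabolite_id: str
    mean_a: float
    sem_a: float
    mean_b: float
    sem_b: float
    normality_p_a: float
    normality_p_b: float
    test_used: str  # welch_t | mann_whitney
    p_value: float
    log2_fold_change: float  # group A over group B
    direction: str  # increased | decreased | ns


def _mann_whitney(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Mann-Whitney p: exact for small tie-free samples, normal
    approximation with continuity and tie correction otherwise."""
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if min(len(a), len(b)) <= 8 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def univariate_panel(
    panel: MetabolitePanel,
    alpha_normality: float = 0.05,
    alpha: float = 0.05,
) -> list[UnivariateResult]:
    """Normality-gated two-group test per metabolite on raw concentrations.

    Both groups are screened with the D'Agostino-Pearson omnibus test; if
    both pass (p > ``alpha_normality``) an unpaired Welch t-test is used,
    otherwise a two-sided Mann-Whitney.  Groups smaller than 8 fall back to
    Mann-Whitney with a warning because the omnibus statistic needs n >= 8.
    Direction is assigned at p <= ``alpha`` from the sign of the log2 fold
    change (group A over group B, on raw group means).
    """
    label_a, label_b = panel.group_labels
    out: list[UnivariateResult] = []
    for met in panel.metabolite_ids:
        a = panel.values_of(met, label_a)
        b = panel.values_of(met, label_b)
        if min(len(a), len(b)) < 3:
            raise ValueError(f"{met}: fewer than 3 samples in one group")
        if min(len(a), len(b)) < 8:
            warnings.warn(
                f"{met}: group size < 8, normality untestable; using Mann-Whitney",
                stacklevel=2,
            )
            p_na = p_nb = float("nan")
            test_used = "mann_whitney"
            p_val = _mann_whitney(a, b)
        else:
            p_na = float(stats.normaltest(a).pvalue)
            p_nb = float(stats.normaltest(b).pvalue)
            if p_na > alpha_normality and p_nb > alpha_normality:
                test_used = "welch_t"
                p_val = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
            else:
                test_used = "mann_whitney"
                p_val = _mann_whitney(a, b)
        l2fc = float(np.log2(a.mean() / b.mean()))
        if p_val <= alpha and l2fc > 0:
            direction = "increased"
        elif p_val <= alpha and l2fc < 0:
            direction = "decreased"
        else:
            direction = "ns"
        out.append(
            UnivariateResult(
                metabolite_id=met,
                mean_a=float(a.mean()),
                sem_a=float(stats.sem(a)),
                mean_b=float(b.mean()),
                sem_b=float(stats.sem(b)),
                normality_p_a=p_na,
                normality_p_b=p_nb,
                test_used=test_used,
                p_value=p_val,
                log2_fold_change=l2fc,
                direction=direction,
            )
        )
    return out


def univariate_to_frame(results: Sequence[UnivariateResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results]).set_index("metabolite_id")


def volcano(
    univariate: Sequence[UnivariateResult],
    fc_threshold_log2: float = 0.0,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Volcano classification and plotting coordinates per metabolite.

    ``increased`` needs log2FC > ``fc_threshold_log2`` and p <=
    ``p_threshold``; ``decreased`` is symmetric; everything else is ``ns``.
    Returns columns log2_fold_change, neg_log10_p, volcano_class.
    """
    rows = []
    for r in univariate:
        if r.p_value <= p_threshold and r.log2_fold_change > fc_threshold_log2:
            cls = "increased"
        elif r.p_value <= p_threshold and r.log2_fold_change < -fc_threshold_log2:
            cls = "decreased"
        else:
            cls = "ns"
        rows.append(
            {
                "metabolite_id": r.metabolite_id,
                "log2_fold_change": r.log2_fold_change,
                "neg_log10_p": -np.log10(r.p_value) if r.p_value > 0 else np.inf,
                "volcano_class": cls,
            }
        )
    return pd.DataFrame(rows).set_index("metabolite_id")


def cluster_heatmap(
    panel: MetabolitePanel,
    top_k: int = 40,
    linkage: str = "ward",
    univariate: Sequence[UnivariateResult] | None = None,
) -> dict:
    """Euclidean hierarchical clustering of the top metabolites for heatmap display.

    Metabolites are ranked by univariate p ascending and the ``top_k`` best
    kept; both axes are clustered on the preprocessed (log10 + Pareto)
    matrix with Euclidean distances.  Returns a JSON-serializable dict with
    leaf orders and merge heights for each axis plus the ordered matrix.
    """
    if len(panel.metabolite_ids) < 2:
        raise ValueError("need at least 2 metabolites to cluster")
    if univariate is None:
        univariate = univariate_panel(panel)
    ranked = sorted(univariate, key=lambda r: (r.p_value, r.metabolite_id))
    if top_k > len(ranked):
        warnings.warn(f"top_k={top_k} > {len(ranked)} metabolites: using all", stacklevel=2)
        top_k = len(ranked)
    keep = [r.metabolite_id for r in ranked[:top_k]]
    mat = preprocess(panel)[keep]  # samples x kept metabolites
    met_link = hierarchy.linkage(mat.to_numpy().T, method=linkage, metric="euclidean")
    sample_link = hierarchy.linkage(mat.to_numpy(), method=linkage, metric="euclidean")
    met_order = hierarchy.leaves_list(met_link)
    sample_order = hierarchy.leaves_list(sample_link)
    ordered = mat.iloc[sample_order, met_order]
    return {
        "metabolites": [keep[i] for i in met_order],
        "samples": [str(mat.index[i]) for i in sample_order],
        "metabolite_merge_heights": met_link[:, 2].tolist(),
        "sample_merge_heights": sample_link[:, 2].tolist(),
        "linkage": linkage,
        "matrix": ordered.to_numpy().T.tolist(),  # metabolite x sample, display layout
    }
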