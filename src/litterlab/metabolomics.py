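"""Untargeted LC-MS feature-matrix post-processing and multivariate statistics.

The pipeline starts where peak picking ends: a matrix of feature intensities
(rows = molecular ions with m/z and retention time, columns = injections)
whose columns are study samples, extraction blanks, or pooled-QC injections.
Three filters remove technical artifacts in a fixed order:

1. blank signal-to-noise — drop features whose mean sample intensity is less
   than ``sn_threshold`` times the mean blank intensity;
2. pooled-QC coefficient of variation — drop features that are not
   reproducible across repeated injections of the pooled sample;
3. co-elution redundancy — drop all but the most intense member of each group
   of features that co-elute and are near-perfectly correlated across samples
   (in-source fragments, adducts, isotopologues of one compound).

Every filter appends a :class:`FilterReport` to the matrix provenance, so the
feature counts telescope and the chain is auditable.

Downstream statistics operate on log-transformed, autoscaled data:
PCA, a permutation MANOVA (PERMANOVA) on Euclidean distances, and PLS-DA
with VIP (variable importance in projection) ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA

__all__ = [
    "FeatureMatrix", "FilterReport",
    "blank_sn_filter", "qc_cv_filter", "autocorr_filter",
    "log_autoscale", "pca_scores", "permanova", "plsda_vip", "top_vips",
]

ROLES = ("sample", "blank", "pool")


@dataclass(frozen=True)
class FilterReport:
    """Provenance entry for one filtering step."""

    step: str
    params: dict
    n_before: int
    n_after: int
    removed: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.n_before - len(self.removed) != self.n_after:
            raise ValueError(
                f"filter accounting broken: {self.n_before} - "
                f"{len(self.removed)} != {self.n_after}")


@dataclass
class FeatureMatrix:
    """Feature (m/z, RT) x sample intensity table with sample roles.

    Attributes
    ----------
    features : DataFrame indexed by feature_id with columns ``mz``, ``rt_min``.
    intensities : DataFrame, same index, one column per injection.
    roles : Series mapping column name -> role in {sample, blank, pool}.
    groups : Series mapping column name -> biological group label.
    provenance : applied filters, in order.
    """

    features: pd.DataFrame
    intensities: pd.DataFrame
    roles: pd.Series
    groups: pd.Series
    provenance: list[FilterReport] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.features.index.equals(self.intensities.index):
            raise ValueError("features and intensities must share an index")
        if self.features.index.has_duplicates:
            raise ValueError("feature_ids must be unique")
        if (self.intensities.to_numpy() < 0).any():
            raise ValueError("intensities must be non-negative")
        unknown = set(self.roles) - set(ROLES)
        if unknown:
            raise ValueError(f"unknown sample roles: {sorted(unknown)}")

    # -- column helpers ----------------------------------------------------
    def columns_with_role(self, role: str) -> list[str]:
        return [c for c in self.intensities.columns if self.roles[c] == role]

    @property
    def n_features(self) -> int:
        return len(self.features)

    def sample_block(self) -> pd.DataFrame:
        """Intensities restricted to study-sample columns."""
        return self.intensities[self.columns_with_role("sample")]

    def sample_groups(self) -> pd.Series:
        return self.groups[self.columns_with_role("sample")]

    def subset(self, keep_ids: Sequence[str], report: FilterReport) -> "FeatureMatrix":
        keep_ids = list(keep_ids)
        return FeatureMatrix(
            features=self.features.loc[keep_ids],
            intensities=self.intensities.loc[keep_ids],
            roles=self.roles,
            groups=self.groups,
            provenance=[*self.provenance, report],
        )

    # -- CSV round trip ----------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        """Write as ``feature_id,mz,rt_min,<role>_<group>_<idx>,...``."""
        out = self.features.copy()
        out.insert(0, "feature_id", out.index)
        for col in self.intensities.columns:
            out[col] = self.intensities[col]
        out.to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        frame = pd.read_csv(path, float_precision="round_trip")
        for col in ("feature_id", "mz", "rt_min"):
            if col not in frame.columns:
                raise ValueError(f"missing column {col!r}")
        frame = frame.set_index("feature_id")
        sample_cols = [c for c in frame.columns if c not in ("mz", "rt_min")]
        roles, groups = {}, {}
        for c in sample_cols:
            parts = c.split("_")
            if len(parts) < 3 or parts[0] not in ROLES:
                raise ValueError(
                    f"column {c!r} does not follow <role>_<group>_<idx>")
            roles[c] = parts[0]
            groups[c] = "_".join(parts[1:-1])
        return cls(
            features=frame[["mz", "rt_min"]],
            intensities=frame[sample_cols].astype(float),
            roles=pd.Series(roles),
            groups=pd.Series(groups),
        )


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def blank_sn_filter(matrix: FeatureMatrix,
                    sn_threshold: float = 10.0) -> tuple[FeatureMatrix, FilterReport]:
    """Remove features detected in extraction blanks.

    Keeps a feature iff mean(sample intensities) / mean(blank intensities)
    is at least ``sn_threshold``; a zero blank mean counts as infinite S/N.
    """
    blanks = matrix.columns_with_role("blank")
    samples = matrix.columns_with_role("sample")
    if not blanks:
        raise ValueError("no blank columns in matrix")
    if not samples:
        raise ValueError("no sample columns in matrix")
    sample_mean = matrix.intensities[samples].mean(axis=1)
    blank_mean = matrix.intensities[blanks].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = sample_mean / blank_mean
    keep = (blank_mean == 0) | (ratio >= sn_threshold)
    removed = tuple(matrix.features.index[~keep])
    report = FilterReport(
        step="blank_sn", params={"sn_threshold": sn_threshold},
        n_before=matrix.n_features, n_after=int(keep.sum()), removed=removed)
    return matrix.subset(matrix.features.index[keep], report), report


def qc_cv_filter(matrix: FeatureMatrix,
                 cv_threshold: float = 0.3) -> tuple[FeatureMatrix, FilterReport]:
    """Remove features that vary across pooled-QC injections.

    Keeps a feature iff sd(pools)/mean(pools) <= ``cv_threshold`` (sample
    standard deviation, n-1); a zero pool mean removes the feature.
    """
    pools = matrix.columns_with_role("pool")
    if len(pools) < 2:
        raise ValueError("need at least 2 pool columns for a CV")
    block = matrix.intensities[pools]
    mean = block.mean(axis=1)
    sd = block.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = sd / mean
    keep = (mean > 0) & (cv <= cv_threshold)
    removed = tuple(matrix.features.index[~keep])
    report = FilterReport(
        step="qc_cv", params={"cv_threshold": cv_threshold},
        n_before=matrix.n_features, n_after=int(keep.sum()), removed=removed)
    return matrix.subset(matrix.features.index[keep], report), report


def autocorr_filter(matrix: FeatureMatrix, r_threshold: float = 0.9,
                    rt_tol_min: float = 0.05) -> tuple[FeatureMatrix, FilterReport]:
    """Collapse groups of co-eluting, highly correlated features.

    Two features are linked when their retention times differ by at most
    ``rt_tol_min`` minutes and their Pearson correlation across the sample
    columns is at least ``r_threshold``.  Groups are the transitive closure
    of that relation; within each group only the member with the highest mean
    sample intensity is retained (ties broken by lowest feature_id).
    """
    samples = matrix.columns_with_role("sample")
    if len(samples) < 3:
        raise ValueError("need at least 3 sample columns for correlations")
    ids = list(matrix.features.index)
    n = len(ids)
    rt = matrix.features["rt_min"].to_numpy()
    X = matrix.intensities[samples].to_numpy(dtype=float)
    mean_int = X.mean(axis=1)

    # union-find over linked pairs; only RT-neighbouring pairs are examined
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    order = np.argsort(rt, kind="stable")
    centered = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    for pos_a in range(n):
        a = order[pos_a]
        for pos_b in range(pos_a + 1, n):
            b = order[pos_b]
            if rt[b] - rt[a] > rt_tol_min:
                break
            if norms[a] == 0 or norms[b] == 0:
                continue
            r = float(centered[a] @ centered[b] / (norms[a] * norms[b]))
            if r >= r_threshold:
                union(a, b)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    removed_idx: list[int] = []
    for members in groups.values():
        if len(members) == 1:
            continue
        # keep highest mean intensity; ties -> lexicographically lowest id
        best = min(members, key=lambda i: (-mean_int[i], ids[i]))
        removed_idx.extend(i for i in members if i != best)
    removed_mask = np.zeros(n, dtype=bool)
    removed_mask[removed_idx] = True
    removed = tuple(np.array(ids, dtype=object)[removed_mask])
    keep_ids = [ids[i] for i in range(n) if not removed_mask[i]]
    report = FilterReport(
        step="autocorr",
        params={"r_threshold": r_threshold, "rt_tol_min": rt_tol_min},
        n_before=n, n_after=len(keep_ids), removed=removed)
    return matrix.subset(keep_ids, report), report


def apply_filter_chain(matrix: FeatureMatrix, sn_threshold: float = 10.0,
                       cv_threshold: float = 0.3, r_threshold: float = 0.9,
                       rt_tol_min: float = 0.05) -> FeatureMatrix:
    """The documented chain: blank S/N, then QC CV, then co-elution."""
    matrix, _ = blank_sn_filter(matrix, sn_threshold)
    matrix, _ = qc_cv_filter(matrix, cv_threshold)
    matrix, _ = autocorr_filter(matrix, r_threshold, rt_tol_min)
    return matrix


# ---------------------------------------------------------------------------
# transformation and multivariate statistics
# ---------------------------------------------------------------------------

def log_autoscale(matrix: FeatureMatrix) -> pd.DataFrame:
    """ln(x+1)-transform and autoscale sample intensities.

    Returns a samples x features DataFrame in which every feature has mean 0
    and unit sample variance.  Features with zero variance across samples
    carry no information after scaling and are dropped.
    """
    X = np.log1p(matrix.sample_block().to_numpy(dtype=float).T)
    df = pd.DataFrame(X, index=matrix.columns_with_role("sample"),
                      columns=matrix.features.index)
    sd = df.std(axis=0, ddof=1)
    df = df.loc[:, sd > 0]
    return (df - df.mean(axis=0)) / df.std(axis=0, ddof=1)


def pca_scores(transformed: pd.DataFrame,
               n_components: int | None = None
               ) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """PCA of a samples x features table.

    Returns (scores, loadings, explained-variance fractions).  Fractions are
    non-increasing and sum to 1 over all components.
    """
    n_max = min(transformed.shape[0] - 1, transformed.shape[1])
    if n_max < 1:
        raise ValueError("need at least 2 samples")
    k = n_max if n_components is None else min(n_components, n_max)
    pca = PCA(n_components=k)
    scores = pca.fit_transform(transformed.to_numpy(dtype=float))
    comp_names = [f"PC{i + 1}" for i in range(k)]
    return (
        pd.DataFrame(scores, index=transformed.index, columns=comp_names),
        pd.DataFrame(pca.components_.T, index=transformed.columns,
                     columns=comp_names),
        pca.explained_variance_ratio_,
    )


def _is_distance_matrix(x: np.ndarray) -> bool:
    return (x.ndim == 2 and x.shape[0] == x.shape[1]
            and np.allclose(x, x.T) and np.allclose(np.diag(x), 0.0))


def permanova(data, labels: Sequence, n_perm: int = 999,
              seed: int | np.random.Generator | None = None
              ) -> tuple[float, float]:
    """Permutation MANOVA pseudo-F test on a distance matrix.

    ``data`` is either a samples x features coordinate matrix (Euclidean
    distances are computed) or a square symmetric distance matrix.  The
    pseudo-F uses squared inter-point distances:

        SS_total  = sum_{i<j} d_ij^2 / n
        SS_within = sum_g sum_{i<j in g} d_ij^2 / n_g
        F = (SS_between / (g - 1)) / (SS_within / (n - g))

    The p-value is (1 + #{permuted F >= observed F}) / (1 + n_perm) under
    random relabelling of the samples.
    """
    x = np.asarray(data, dtype=float)
    labels = np.asarray(labels)
    if _is_distance_matrix(x):
        d2 = x ** 2
    else:
        sq = (x ** 2).sum(axis=1)
        d2 = sq[:, None] + sq[None, :] - 2 * x @ x.T
        np.fill_diagonal(d2, 0.0)
        d2 = np.clip(d2, 0.0, None)
    n = d2.shape[0]
    if len(labels) != n:
        raise ValueError("labels length must match number of samples")
    uniq, inv = np.unique(labels, return_inverse=True)
    g = len(uniq)
    if g < 2:
        raise ValueError("need at least 2 groups")
    counts = np.bincount(inv)
    if (counts < 2).any():
        raise ValueError("every group needs at least 2 samples")

    ss_total = d2.sum() / (2 * n)

    def pseudo_f(assign: np.ndarray) -> float:
        ss_within = 0.0
        for gi in range(g):
            idx = np.flatnonzero(assign == gi)
            ss_within += d2[np.ix_(idx, idx)].sum() / (2 * len(idx))
        ss_between = ss_total - ss_within
        return (ss_between / (g - 1)) / (ss_within / (n - g))

    f_obs = pseudo_f(inv)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if pseudo_f(rng.permutation(inv)) >= f_obs:
            count += 1
    return float(f_obs), float((1 + count) / (1 + n_perm))


def plsda_vip(transformed: pd.DataFrame, group_labels: Sequence,
              n_components: int = 2) -> pd.Series:
    """VIP scores from a two-group PLS-DA model.

    The group indicator (0/1) is regressed on the feature table by PLS with
    ``n_components`` latent variables; the VIP of feature j is

        VIP_j = sqrt( p * sum_a [ SSY_a * (w_ja / ||w_a||)^2 ] / sum_a SSY_a )

    with p features, weight vectors w_a and SSY_a the response variance
    captured by component a.  The mean squared VIP over features is 1.
    """
    labels = np.asarray(group_labels)
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError(f"PLS-DA needs exactly 2 groups, got {len(uniq)}")
    y = (labels == uniq[1]).astype(float)
    X = transformed.to_numpy(dtype=float)
    n, p = X.shape
    k = min(n_components, n - 1, p)
    pls = PLSRegression(n_components=k, scale=False)
    pls.fit(X, y)
    W = pls.x_weights_          # p x k
    T = pls.x_scores_           # n x k
    q = pls.y_loadings_.ravel()  # k
    ssy = (q ** 2) * np.einsum("ij,ij->j", T, T)
    wnorm2 = (W ** 2).sum(axis=0)
    vip2 = p * (W ** 2 / wnorm2) @ ssy / ssy.sum()
    return pd.Series(np.sqrt(vip2), index=transformed.columns, name="VIP")


def top_vips(vip_scores: pd.Series, k: int = 15) -> pd.Series:
    """Top-k features by VIP, descending; ties broken by feature_id."""
    if k > len(vip_scores):
        raise ValueError(f"k={k} exceeds {len(vip_scores)} features")
    order = sorted(vip_scores.index, key=lambda i: (-vip_scores[i], i))
    return vip_scores.loc[order[:k]]
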