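"""Diversity, ordination, and correlation statistics for group comparison.

Alpha diversity (richness, Shannon H' in nats, Pielou evenness, Chao1),
Bray-Curtis beta diversity with classical-scaling PCoA, PERMANOVA with
sequential (Type I) covariate adjustment, and Spearman correlations with
Benjamini-Hochberg control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr

from .group_comparison import bh_adjust

__all__ = [
    "DiversityResult",
    "OrdinationResult",
    "diversity",
    "diversity_table",
    "bray_curtis",
    "pcoa",
    "permanova",
    "spearman_bh",
]


@dataclass
class DiversityResult:
    sample_id: str
    richness: int
    shannon_H: float  # nats
    pielou_J: Optional[float]  # undefined for richness <= 1
    chao1: float


@dataclass
class OrdinationResult:
    sample_ids: List[str]
    coordinates: np.ndarray  # samples x axes
    eigenvalues: np.ndarray  # positive eigenvalues, descending
    proportion_explained: np.ndarray


def diversity(sample_row: pd.Series, log_base: Optional[float] = None) -> DiversityResult:
    """Alpha diversity of one sample row (counts or relative abundances).

    Shannon H' = -sum p_i log p_i over positive entries (natural log by
    default), Pielou J = H / log(richness) (undefined when richness <= 1),
    Chao1 = S_obs + F1^2 / (2 F2) when doubletons exist, else the
    bias-corrected S_obs + F1 (F1 - 1) / 2.  Chao1's singleton/doubleton
    counts only make sense on integer counts; on non-count input it
    degrades to S_obs.
    """
    values = np.asarray(sample_row, dtype=float)
    if (values < 0).any():
        raise ValueError("abundances must be non-negative")
    positive = values[values > 0]
    richness = int(len(positive))
    log = np.log if log_base is None else (lambda x: np.log(x) / np.log(log_base))
    if richness == 0:
        return DiversityResult(str(sample_row.name), 0, 0.0, None, 0.0)
    p = positive / positive.sum()
    shannon = float(-(p * log(p)).sum())
    pielou = float(shannon / log(richness)) if richness > 1 else None
    f1 = int(np.sum(positive == 1))
    f2 = int(np.sum(positive == 2))
    if f2 > 0:
        chao1 = richness + f1 * f1 / (2.0 * f2)
    else:
        chao1 = richness + f1 * (f1 - 1) / 2.0
    return DiversityResult(str(sample_row.name), richness, shannon, pielou, float(chao1))


def diversity_table(matrix: pd.DataFrame, log_base: Optional[float] = None) -> pd.DataFrame:
    rows = [diversity(matrix.loc[s], log_base) for s in matrix.index]
    return pd.DataFrame(
        {
            "sample": [r.sample_id for r in rows],
            "richness": [r.richness for r in rows],
            "shannon_H": [r.shannon_H for r in rows],
            "pielou_J": [r.pielou_J for r in rows],
            "chao1": [r.chao1 for r in rows],
        }
    ).set_index("sample")


def bray_curtis(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarities: d = sum|a-b| / sum(a+b)."""
    if (matrix.values < 0).any():
        raise ValueError("abundances must be non-negative")
    dist = squareform(pdist(matrix.values, metric="braycurtis"))
    dist = np.nan_to_num(dist, nan=0.0)  # two all-zero samples: define d = 0
    return pd.DataFrame(dist, index=matrix.index, columns=matrix.index)


def pcoa(distance: pd.DataFrame) -> OrdinationResult:
    """Classical scaling (principal coordinates analysis).

    Double-centre -0.5 * J D^2 J, eigendecompose, keep positive
    eigenvalues, coordinates = eigenvectors * sqrt(eigenvalues), axes
    sorted by eigenvalue descending.  Negative eigenvalues (non-Euclidean
    distances) are dropped with a warning; no Cailliez correction.
    """
    D = np.asarray(distance, dtype=float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be square and symmetric")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D * D) @ J
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(1e-12, 1e-10 * abs(eigvals).max() if n else 0.0)
    if (eigvals < -tol).any():
        warnings.warn(
            "negative PCoA eigenvalues dropped (non-Euclidean distance matrix)"
        )
    keep = eigvals > tol
    eigvals = eigvals[keep]
    coords = eigvecs[:, keep] * np.sqrt(eigvals)
    total = eigvals.sum()
    prop = eigvals / total if total > 0 else eigvals
    return OrdinationResult(list(distance.index), coords, eigvals, prop)


def _gower_center(D: np.ndarray) -> np.ndarray:
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * J @ (D * D) @ J


def _design_matrix(df: pd.DataFrame, columns: Sequence[str]) -> np.ndarray:
    """One-hot encode categorical columns, passthrough numeric; no intercept."""
    parts = []
    for col in columns:
        series = df[col]
        if pd.api.types.is_numeric_dtype(series):
            parts.append(series.to_numpy(dtype=float)[:, None])
        else:
            dummies = pd.get_dummies(series, drop_first=True)
            parts.append(dummies.to_numpy(dtype=float))
    if not parts:
        return np.empty((len(df), 0))
    return np.hstack(parts)


def _hat(X: np.ndarray) -> np.ndarray:
    if X.shape[1] == 0:
        return np.zeros((X.shape[0], X.shape[0]))
    Q, _ = np.linalg.qr(X)
    return Q @ Q.T


def permanova(
    distance: pd.DataFrame,
    metadata: pd.DataFrame,
    group_col: str,
    covariates: Sequence[str] = (),
    n_perm: int = 999,
    seed: int = 0,
) -> Dict[str, float]:
    """Distance-based PERMANOVA with sequential (Type I) covariates.

    Covariates enter the model before the group term; the pseudo-F for the
    group is its marginal sum of squares over the residual, computed on the
    Gower-centred distance matrix.  Significance is by permutation of the
    raw group labels only (covariates stay attached to samples):
    p = (1 + #{perm F >= obs F}) / (1 + n_perm).
    """
    meta = metadata.loc[distance.index]
    groups = meta[group_col]
    counts = groups.value_counts()
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValueError(f"groups with fewer than 2 samples: {small}")
    D = np.asarray(distance, dtype=float)
    n = D.shape[0]
    G = _gower_center(D)
    total_ss = np.trace(G)
    ones = np.ones((n, 1))
    X_cov = np.hstack([ones, _design_matrix(meta, list(covariates))])
    H_cov = _hat(X_cov)
    df_group = groups.nunique() - 1

    def group_F(labels: np.ndarray) -> float:
        dummies = pd.get_dummies(pd.Series(labels), drop_first=True).to_numpy(float)
        X_full = np.hstack([X_cov, dummies])
        H_full = _hat(X_full)
        ss_group = np.trace((H_full - H_cov) @ G)
        ss_resid = np.trace((np.eye(n) - H_full) @ G)
        df_resid = n - X_cov.shape[1] - df_group
        # rank-deficiency guard: use actual column ranks
        return (ss_group / df_group) / (ss_resid / df_resid)

    labels = groups.to_numpy()
    observed = group_F(labels)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        if group_F(rng.permutation(labels)) >= observed:
            exceed += 1
    pvalue = (1 + exceed) / (1 + n_perm)
    return {
        "pseudo_F": float(observed),
        "p_value": float(pvalue),
        "n_permutations": n_perm,
        "total_ss": float(total_ss),
    }


def spearman_bh(
    x_table: pd.DataFrame,
    y_table: pd.DataFrame,
    pairs: Sequence[Tuple[str, str]],
) -> pd.DataFrame:
    """Spearman rank correlation for each (x, y) pair with BH q-values.

    Ties are mid-ranked (scipy convention); q-values are monotone
    non-decreasing in p-rank.
    """
    rows = []
    for x_col, y_col in pairs:
        rho, p = spearmanr(x_table[x_col], y_table[y_col])
        rows.append({"x": x_col, "y": y_col, "rho": float(rho), "p": float(p)})
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    return out
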