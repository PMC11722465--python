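"""Polychoric-correlation PCA and the individual deprivation index.

The index is built in three steps: (1) two-step maximum-likelihood
polychoric correlations between every pair of completed ordinal items --
thresholds from inverse-normal cumulative marginals, then the latent
bivariate-normal correlation maximizing the contingency-table likelihood;
(2) eigendecomposition of the 5x5 polychoric matrix, with the first
component's sign fixed so its loadings sum positive; (3) per-participant
PC1 scores as the loading-weighted sum of standardized ordinals, max-min
scaled to [0, 1] and oriented so that a higher value means greater
deprivation (positive rank correlation with the income ordinal).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .survey_coding import ITEMS

logger = logging.getLogger(__name__)

_EPS = 1e-12


class IndexError_(ValueError):
    """Raised for degenerate inputs to the index construction."""


def thresholds_from_marginals(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Standard-normal cutpoints from the empirical cumulative marginals.

    Returns (levels, thresholds) where ``thresholds`` has length
    ``len(levels) - 1`` and is strictly increasing.
    """
    levels, counts = np.unique(np.asarray(x, int), return_counts=True)
    cum = np.cumsum(counts)[:-1] / counts.sum()
    return levels, stats.norm.ppf(cum)


def _bvn_cell_probs(rho: float, tx: np.ndarray, ty: np.ndarray) -> np.ndarray:
    """Bivariate-normal rectangle probabilities over the threshold grid."""
    ax = np.concatenate(([-np.inf], tx, [np.inf]))
    ay = np.concatenate(([-np.inf], ty, [np.inf]))
    nx, ny = len(ax), len(ay)
    F = np.zeros((nx, ny))
    bvn = stats.multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]])
    for i in range(nx):
        for j in range(ny):
            if np.isinf(ax[i]) and ax[i] < 0 or np.isinf(ay[j]) and ay[j] < 0:
                F[i, j] = 0.0
            elif np.isinf(ax[i]) and np.isinf(ay[j]):
                F[i, j] = 1.0
            elif np.isinf(ax[i]):
                F[i, j] = stats.norm.cdf(ay[j])
            elif np.isinf(ay[j]):
                F[i, j] = stats.norm.cdf(ax[i])
            else:
                F[i, j] = bvn.cdf([ax[i], ay[j]])
    return F[1:, 1:] - F[:-1, 1:] - F[1:, :-1] + F[:-1, :-1]


@dataclass
class PolychoricPair:
    rho: float
    thresholds_x: np.ndarray
    thresholds_y: np.ndarray
    converged: bool
    fallback: str | None = None


def polychoric_pair(x, y) -> PolychoricPair:
    """Two-step ML polychoric correlation of two complete ordinal columns.

    A column with a single observed level yields ``rho = nan`` (flagged);
    optimizer failure falls back to tie-corrected Spearman, flagged and
    logged.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if np.isnan(x).any() or np.isnan(y).any():
        raise IndexError_("polychoric_pair requires complete columns")
    lx, tx = thresholds_from_marginals(x)
    ly, ty = thresholds_from_marginals(y)
    if len(lx) < 2 or len(ly) < 2:
        logger.warning("polychoric undefined: a column has < 2 observed levels")
        return PolychoricPair(np.nan, tx, ty, converged=False, fallback="degenerate")
    # contingency table
    ix = np.searchsorted(lx, x.astype(int))
    iy = np.searchsorted(ly, y.astype(int))
    table = np.zeros((len(lx), len(ly)))
    np.add.at(table, (ix, iy), 1.0)

    def nll(rho: float) -> float:
        p = np.clip(_bvn_cell_probs(rho, tx, ty), _EPS, None)
        return -float(np.sum(table * np.log(p)))

    try:
        res = optimize.minimize_scalar(nll, bounds=(-0.999, 0.999), method="bounded", options={"xatol": 1e-6})
        if not res.success or not np.isfinite(res.x):
            raise RuntimeError("optimizer did not converge")
        return PolychoricPair(float(res.x), tx, ty, converged=True)
    except Exception as exc:
        rho_s = float(stats.spearmanr(x, y).statistic)
        logger.warning("polychoric fallback to Spearman (%s)", exc)
        return PolychoricPair(rho_s, tx, ty, converged=False, fallback="spearman")


@dataclass
class PolychoricMatrix:
    matrix: pd.DataFrame
    thresholds: dict[str, np.ndarray]
    converged: pd.DataFrame
    psd_repaired: bool = False
    repair_magnitude: float = 0.0


def _nearest_psd_correlation(m: np.ndarray) -> tuple[np.ndarray, float]:
    """Clip negative eigenvalues at zero and renormalize to unit diagonal."""
    w, v = np.linalg.eigh(m)
    repaired = (v * np.clip(w, 0.0, None)) @ v.T
    d = np.sqrt(np.clip(np.diag(repaired), _EPS, None))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return repaired, float(np.max(np.abs(repaired - m)))


def polychoric_matrix(table: pd.DataFrame, items: list[str] | None = None) -> PolychoricMatrix:
    """All-pairs polychoric matrix of a completed survey table.

    Raises if any pair is undefined; repairs the assembled matrix to the
    nearest positive-semidefinite correlation matrix if needed, logging the
    repair magnitude.
    """
    items = items or [c for c in table.columns if c in ITEMS]
    if table[items].isna().to_numpy().any():
        raise IndexError_("polychoric_matrix requires a completed table")
    mat = pd.DataFrame(np.eye(len(items)), index=items, columns=items)
    conv = pd.DataFrame(True, index=items, columns=items)
    thresholds: dict[str, np.ndarray] = {}
    for c in items:
        _, thresholds[c] = thresholds_from_marginals(table[c].to_numpy(float))
    for a, b in itertools.combinations(items, 2):
        pair = polychoric_pair(table[a].to_numpy(float), table[b].to_numpy(float))
        if np.isnan(pair.rho):
            raise IndexError_(f"polychoric correlation undefined for pair ({a}, {b})")
        mat.loc[a, b] = mat.loc[b, a] = pair.rho
        conv.loc[a, b] = conv.loc[b, a] = pair.converged
    out = PolychoricMatrix(matrix=mat, thresholds=thresholds, converged=conv)
    w = np.linalg.eigvalsh(mat.to_numpy())
    if w.min() < -1e-10:
        repaired, magnitude = _nearest_psd_correlation(mat.to_numpy())
        out.matrix = pd.DataFrame(repaired, index=items, columns=items)
        out.psd_repaired = True
        out.repair_magnitude = magnitude
        logger.warning("polychoric matrix repaired to PSD (max change %.2e)", magnitude)
    return out


@dataclass
class PCADecomposition:
    eigenvalues: np.ndarray  # descending
    eigenvectors: np.ndarray  # columns, matching eigenvalue order
    percent_variance: np.ndarray
    items: list[str] = field(default_factory=list)

    @property
    def pc1_loadings(self) -> np.ndarray:
        return self.eigenvectors[:, 0]


def pca_decompose(matrix: PolychoricMatrix | pd.DataFrame | np.ndarray) -> PCADecomposition:
    """Eigendecomposition of a correlation matrix, eigenvalues descending.

    PC1's sign is fixed so that the sum of its loadings is positive (a
    single deprivation factor should load every item positively).
    """
    if isinstance(matrix, PolychoricMatrix):
        items = list(matrix.matrix.columns)
        m = matrix.matrix.to_numpy()
    elif isinstance(matrix, pd.DataFrame):
        items, m = list(matrix.columns), matrix.to_numpy()
    else:
        m = np.asarray(matrix, float)
        items = [f"item_{i}" for i in range(m.shape[0])]
    if not np.all(np.isfinite(m)):
        raise IndexError_("correlation matrix has non-finite entries")
    w, v = np.linalg.eigh(m)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    if v[:, 0].sum() < 0:
        v[:, 0] = -v[:, 0]
    return PCADecomposition(
        eigenvalues=w,
        eigenvectors=v,
        percent_variance=100.0 * w / np.trace(m),
        items=items,
    )


def compute_isdi(
    table: pd.DataFrame,
    decomposition: PCADecomposition,
    income_item: str = "income",
) -> pd.DataFrame:
    """Per-participant PC1 score and max-min-normalized deprivation index.

    PC1 scores are the PC1-loading-weighted sums of the cohort-standardized
    ordinals.  The index is scaled to [0, 1] and oriented so that it
    correlates positively with the income deprivation ordinal.
    """
    items = decomposition.items
    X = table[items].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise IndexError_("compute_isdi requires a completed table")
    sd = X.std(axis=0)
    if (sd == 0).any():
        bad = [items[i] for i in np.flatnonzero(sd == 0)]
        raise IndexError_(f"constant item column(s): {bad}")
    Xs = (X - X.mean(axis=0)) / sd
    pc1 = Xs @ decomposition.pc1_loadings
    span = pc1.max() - pc1.min()
    if span == 0 or len(np.unique(pc1)) < 2:
        raise IndexError_("all PC1 scores identical; index undefined")
    isdi = (pc1 - pc1.min()) / span
    rho = stats.spearmanr(isdi, X[:, items.index(income_item)]).statistic
    if rho < 0:
        isdi = 1.0 - isdi
    scores = pd.DataFrame(
        {
            "participant_id": table["participant_id"].to_numpy()
            if "participant_id" in table.columns
            else np.arange(len(table)),
            "pc1_score": pc1,
            "isdi": isdi,
        }
    )
    return scores


def derive_isdi(table: pd.DataFrame, items: list[str] | None = None) -> tuple[pd.DataFrame, PCADecomposition, PolychoricMatrix]:
    """Convenience: polychoric matrix -> PCA -> index for a completed table."""
    poly = polychoric_matrix(table, items)
    decomp = pca_decompose(poly)
    scores = compute_isdi(table, decomp)
    return scores, decomp, poly


def compare_with_area_index(scores: pd.DataFrame, area_index: pd.Series | np.ndarray) -> float:
    """Pearson correlation between the individual index and the area index.

    Returns NaN (with a warning) if either side has zero variance.
    """
    isdi = scores["isdi"].to_numpy(float)
    area = np.asarray(area_index, float)
    if isdi.std() == 0 or area.std() == 0:
        logger.warning("correlation undefined: zero variance")
        return float("nan")
    return float(stats.pearsonr(isdi, area).statistic)
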