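"""Global venom-composition analysis.

The question this module answers: does rearing temperature shift the
multivariate venom profile, and in which direction?  The steps are

1. :func:`permanova` — permutational MANOVA on Euclidean distances
   between band-intensity profiles, with temperature and replicate as
   sequential (Type I) fixed factors, to partition the variation.
2. :func:`center_within_replicates` — remove replicate (batch) means per
   band so batch structure cannot drive the discriminant axes.
3. :func:`fit_lda` — linear discriminant analysis of the three
   temperature groups (two axes for three groups).
4. :func:`centroid_trend_arrow` — the least-squares line through the
   20/25/30 degC centroids in the discriminant plane, oriented toward
   increasing temperature: a one-dimensional summary of the venom trend.
5. :func:`band_trend_correlations` — Spearman correlation of every band
   with the individuals' positions along that arrow, Bonferroni
   corrected, yielding the candidate set of temperature-responsive
   bands.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg
from scipy import stats

from .containers import BandMatrix

__all__ = [
    "PermanovaTable",
    "LDAResult",
    "TrendArrow",
    "center_within_replicates",
    "permanova",
    "fit_lda",
    "centroid_trend_arrow",
    "band_trend_correlations",
    "arrow_scores",
]


def center_within_replicates(matrix: BandMatrix) -> BandMatrix:
    """Give every replicate the same (grand) mean for each band.

    Within-replicate deviations are untouched; only replicate means are
    shifted onto the grand mean, so variation between replicates cannot
    contribute to any subsequent between-group analysis.
    """
    vals = matrix.intensities
    rep = matrix.meta["replicate"]
    if rep.isna().any():
        raise ValueError("replicate labels contain missing values")
    grand = vals.mean(axis=0)
    rep_means = vals.groupby(rep).transform("mean")
    centered = vals - rep_means + grand
    return matrix.with_intensities(centered)


@dataclass
class PermanovaTable:
    """Sequential PERMANOVA decomposition.

    ``table`` has one row per term plus ``Residual`` and ``Total``, with
    columns ``df``, ``sum_sq``, ``r2``, ``pseudo_f`` and ``p_value``.
    """

    table: pd.DataFrame
    n_permutations: int

    def r2(self, term: str) -> float:
        return float(self.table.loc[term, "r2"])

    def p_value(self, term: str) -> float:
        return float(self.table.loc[term, "p_value"])


def _term_projectors(meta: pd.DataFrame, terms: Sequence[str]) -> list[np.ndarray]:
    """Orthonormal bases of the sequential factor subspaces.

    The design matrix is [intercept | dummies(term 1) | dummies(term 2) | ...];
    a QR factorization yields orthonormal columns whose leading blocks
    span the leading design columns, which is exactly the sequential
    (Type I) decomposition.
    """
    n = len(meta)
    blocks = [np.ones((n, 1))]
    sizes = []
    for term in terms:
        codes, levels = pd.factorize(meta[term], sort=True)
        if len(levels) < 2:
            raise ValueError(f"factor {term!r} needs at least 2 levels")
        dummies = np.eye(len(levels))[codes][:, 1:]
        blocks.append(dummies)
        sizes.append(dummies.shape[1])
    X = np.hstack(blocks)
    q, r = np.linalg.qr(X)
    if np.any(np.abs(np.diag(r)) < 1e-10):
        raise ValueError("design matrix is rank deficient (aliased factors)")
    out, start = [], 1
    for k in sizes:
        out.append(q[:, start:start + k])
        start += k
    return out


def permanova(
    matrix: BandMatrix,
    terms: Sequence[str] = ("temperature", "replicate"),
    n_permutations: int | str = 5000,
    seed: int | None = None,
) -> PermanovaTable:
    """Permutational MANOVA on Euclidean distances between rows.

    Sums of squares are sequential (terms entered in the order given,
    temperature first by default).  Under the null, rows are permuted
    freely; each term's p-value is
    ``(1 + #permuted F >= observed F) / (1 + n_permutations)``.

    Pass ``n_permutations="exhaustive"`` to enumerate every row
    permutation (tiny n only); the p-value is then the exact fraction of
    permutations, identity included, with F >= observed.
    """
    vals = matrix.values
    n = vals.shape[0]
    centered = vals - vals.mean(axis=0)
    ss_total = float(np.sum(centered**2))
    if ss_total <= 1e-12:
        raise ValueError("constant matrix: total sum of squares is zero")

    projectors = _term_projectors(matrix.meta, terms)
    dfs = [p.shape[1] for p in projectors]
    df_resid = n - 1 - sum(dfs)
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom")

    def term_stats(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        ss = np.array([float(np.sum((p.T @ y) ** 2)) for p in projectors])
        ss_res = ss_total - ss.sum()
        f = (ss / dfs) / (ss_res / df_resid)
        return ss, f

    ss_obs, f_obs = term_stats(centered)

    if n_permutations == "exhaustive":
        from itertools import permutations as iter_permutations

        exceed = np.zeros(len(projectors))
        count = 0
        for perm in iter_permutations(range(n)):
            _, f = term_stats(centered[list(perm)])
            exceed += f >= f_obs - 1e-12
            count += 1
        pvals = exceed / count
        n_perm_out = count
    else:
        n_permutations = int(n_permutations)
        if n_permutations < 99:
            raise ValueError("n_permutations must be at least 99")
        rng = np.random.default_rng(seed)
        exceed = np.zeros(len(projectors))
        chunk = 250
        done = 0
        while done < n_permutations:
            b = min(chunk, n_permutations - done)
            perms = np.argsort(rng.random((b, n)), axis=1)
            yp = centered[perms]  # (b, n, m)
            ss_res_p = np.full(b, ss_total)
            fs = np.empty((b, len(projectors)))
            ss_terms = []
            for p in projectors:
                z = np.einsum("nk,bnm->bkm", p, yp)
                ss_t = np.sum(z**2, axis=(1, 2))
                ss_terms.append(ss_t)
                ss_res_p -= ss_t
            for j, (p, ss_t) in enumerate(zip(projectors, ss_terms)):
                fs[:, j] = (ss_t / dfs[j]) / (ss_res_p / df_resid)
            exceed += np.sum(fs >= f_obs - 1e-12, axis=0)
            done += b
        pvals = (1.0 + exceed) / (1.0 + n_permutations)
        n_perm_out = n_permutations

    rows = []
    for term, df, ss, f, p in zip(terms, dfs, ss_obs, f_obs, pvals):
        rows.append((term, df, ss, ss / ss_total, f, p))
    ss_res = ss_total - ss_obs.sum()
    rows.append(("Residual", df_resid, ss_res, ss_res / ss_total, np.nan, np.nan))
    rows.append(("Total", n - 1, ss_total, 1.0, np.nan, np.nan))
    table = pd.DataFrame(
        rows, columns=["term", "df", "sum_sq", "r2", "pseudo_f", "p_value"]
    ).set_index("term")
    return PermanovaTable(table=table, n_permutations=n_perm_out)


@dataclass
class LDAResult:
    """Discriminant axes, per-individual scores and group centroids."""

    axes: pd.DataFrame        # bands x axes (unit-norm eigenvectors)
    scores: pd.DataFrame      # individuals x axes
    centroids: pd.DataFrame   # groups (sorted) x axes
    eigenvalues: np.ndarray   # Fisher criteria of the axes, descending


def fit_lda(
    matrix: BandMatrix,
    group: str = "temperature",
    ridge: float | None = 1e-8,
) -> LDAResult:
    """Fisher linear discriminant analysis of the temperature groups.

    Axes solve the generalized eigenproblem ``S_b v = lambda S_w v``
    (between- vs within-group scatter); with g groups the g - 1 leading
    eigenvectors are kept, normalized to unit Euclidean length with the
    largest-magnitude loading positive.  Scores are the grand-mean
    centered data projected on the axes; centroids are per-group mean
    scores.

    ``ridge`` (fraction of ``trace(S_w)`` added to its diagonal,
    default 1e-8) regularizes a near-singular within-group scatter; pass
    ``ridge=None`` to disable, in which case a singular scatter raises.
    """
    X = matrix.values
    groups = matrix.meta[group].to_numpy()
    levels = np.sort(pd.unique(groups))
    g = len(levels)
    if g < 2:
        raise ValueError("need at least 2 groups")
    grand = X.mean(axis=0)
    Xc = X - grand
    p = X.shape[1]
    Sw = np.zeros((p, p))
    Sb = np.zeros((p, p))
    for lev in levels:
        sub = X[groups == lev]
        mu = sub.mean(axis=0)
        d = sub - mu
        Sw += d.T @ d
        diff = (mu - grand)[:, None]
        Sb += len(sub) * (diff @ diff.T)
    if ridge is not None:
        Sw = Sw + ridge * np.trace(Sw) * np.eye(p)
    try:
        scipy.linalg.cholesky(Sw)
    except scipy.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "within-group scatter matrix is singular; pass a positive `ridge` "
            "to regularize it"
        ) from err
    w, v = scipy.linalg.eigh(Sb, Sw)
    order = np.argsort(w)[::-1][: g - 1]
    eigvals = w[order]
    axes = v[:, order]
    for j in range(axes.shape[1]):
        axes[:, j] /= np.linalg.norm(axes[:, j])
        if axes[np.argmax(np.abs(axes[:, j])), j] < 0:
            axes[:, j] *= -1
    axis_names = [f"LD{j + 1}" for j in range(axes.shape[1])]
    axes_df = pd.DataFrame(axes, index=matrix.band_ids, columns=axis_names)
    scores = pd.DataFrame(Xc @ axes, index=matrix.intensities.index, columns=axis_names)
    centroids = scores.groupby(pd.Series(groups, index=scores.index)).mean()
    centroids = centroids.loc[levels]
    centroids.index.name = group
    return LDAResult(axes=axes_df, scores=scores, centroids=centroids,
                     eigenvalues=eigvals)


@dataclass
class TrendArrow:
    """Least-squares line through the temperature centroids.

    ``direction`` is the unit vector along the fitted line, oriented so
    that the projection of the warmest centroid exceeds that of the
    coolest; ``slope``/``intercept`` describe the line LD2 = slope * LD1
    + intercept in the discriminant plane.
    """

    direction: np.ndarray
    slope: float
    intercept: float


def centroid_trend_arrow(centroids: pd.DataFrame) -> TrendArrow:
    """Fit the venom-trend arrow from the three ordered centroids.

    Ordinary least squares of the second discriminant coordinate on the
    first, over the centroids ordered by temperature (20 -> 25 -> 30).
    """
    if centroids.shape[0] != 3 or centroids.shape[1] < 2:
        raise ValueError("need exactly 3 centroids with 2 coordinates")
    c = centroids.sort_index().to_numpy()[:, :2]
    if np.linalg.norm(c[-1] - c[0]) < 1e-12 and np.linalg.norm(c[1] - c[0]) < 1e-12:
        raise ValueError("coincident centroids: trend direction undefined")
    x, y = c[:, 0], c[:, 1]
    if np.ptp(x) < 1e-12:
        # vertical trajectory: regression of y on x undefined, use the axis
        direction = np.array([0.0, 1.0])
        slope, intercept = np.inf, np.nan
    else:
        slope, intercept = np.polyfit(x, y, 1)
        direction = np.array([1.0, slope])
        direction /= np.linalg.norm(direction)
    if np.dot(c[-1] - c[0], direction) < 0:
        direction = -direction
    return TrendArrow(direction=direction, slope=float(slope),
                      intercept=float(intercept))


def arrow_scores(scores: pd.DataFrame, arrow: TrendArrow) -> pd.Series:
    """Scalar projection of each individual's LD scores onto the arrow."""
    proj = scores.to_numpy()[:, :2] @ arrow.direction
    return pd.Series(proj, index=scores.index, name="arrow_score")


def band_trend_correlations(
    matrix: BandMatrix,
    arrow: TrendArrow,
    scores: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Spearman correlation of every band with the trend-arrow score.

    Individuals are projected onto the arrow; each band's intensities
    are rank-correlated with those projections.  P-values are Bonferroni
    corrected over the number of bands; bands with adjusted p < ``alpha``
    form the candidate set and carry the sign of their correlation as
    the trend direction.  Constant bands have undefined correlation and
    are flagged (``defined = False``) and excluded from candidacy.

    The returned table also holds correlation-circle coordinates: the
    Spearman correlation of each band with each discriminant axis.
    """
    if len(scores) != matrix.n_individuals:
        raise ValueError("scores and matrix rows are not aligned")
    proj = arrow_scores(scores, arrow).to_numpy()
    vals = matrix.values
    n_bands = matrix.n_bands
    rows = []
    axis_arrays = [scores.iloc[:, j].to_numpy() for j in range(min(2, scores.shape[1]))]
    for j, band in enumerate(matrix.band_ids):
        x = vals[:, j]
        if np.ptp(x) < 1e-300:
            rows.append((band, np.nan, np.nan, np.nan, False, 0, np.nan, np.nan, False))
            continue
        rho, p = stats.spearmanr(x, proj)
        p_bonf = min(1.0, p * n_bands)
        circ = [stats.spearmanr(x, a)[0] for a in axis_arrays]
        circ += [np.nan] * (2 - len(circ))
        rows.append((band, rho, p, p_bonf, p_bonf < alpha,
                     int(np.sign(rho)) if p_bonf < alpha else 0,
                     circ[0], circ[1], True))
    return pd.DataFrame(
        rows,
        columns=["band_id", "rho", "p_value", "p_bonferroni", "candidate",
                 "sign", "axis1_corr", "axis2_corr", "defined"],
    ).set_index("band_id")
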