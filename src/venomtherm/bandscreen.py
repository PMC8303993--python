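"""Disambiguation of directly vs indirectly temperature-affected bands.

A band can correlate with the venom trend either because temperature
drives its intensity (direct) or because it co-varies with another band
that does (indirect: co-migration on the gel, linkage).  The screen

1. clusters all bands by UPGMA on the distance 1 - |Spearman rho|
   (:func:`correlation_distance_tree`),
2. cuts the dendrogram at a correlation threshold (default |rho| = 0.45,
   i.e. height 0.55) into flat clusters (:func:`cut_tree_at_threshold`),
3. within every cluster holding at least two trend-correlated candidate
   bands, computes each candidate's rank-based partial correlation with
   the trend score conditioning on the other candidates of its cluster;
   candidates whose Bonferroni-adjusted partial p stays below 0.05 are
   classified direct, the rest indirect
   (:func:`partial_correlation_screen`),
4. joins the result with the known protein content of the bands,
   flagging abundant proteins (:func:`annotate_abundant_proteins`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .containers import BandMatrix

__all__ = [
    "CorrelationTree",
    "ClusterScreen",
    "correlation_distance_tree",
    "cut_tree_at_threshold",
    "partial_spearman",
    "partial_correlation_screen",
    "annotate_abundant_proteins",
    "load_annotations",
]


@dataclass
class CorrelationTree:
    """UPGMA dendrogram over bands with 1 - |Spearman rho| distances."""

    linkage_matrix: np.ndarray
    band_ids: list[str]
    distances: pd.DataFrame


def correlation_distance_tree(matrix: BandMatrix) -> CorrelationTree:
    """Average-linkage (UPGMA) clustering of bands by correlation.

    The metric distance between two bands is ``1 - |rho|`` with rho their
    Spearman correlation, so perfectly correlated *or* anti-correlated
    bands are at distance zero.  Constant bands, whose correlation is
    undefined, are assigned distance 1 to every other band (with a
    warning) and end up isolated.
    """
    if matrix.n_bands < 2:
        raise ValueError("need at least 2 bands to cluster")
    vals = matrix.values
    constant = np.ptp(vals, axis=0) < 1e-300
    if constant.any():
        names = [b for b, c in zip(matrix.band_ids, constant) if c]
        warnings.warn(
            f"constant bands {names} have undefined correlations; "
            "assigned distance 1 to all other bands",
            stacklevel=2,
        )
    rho = stats.spearmanr(vals).statistic
    rho = np.atleast_2d(rho)
    dist = 1.0 - np.abs(rho)
    dist[constant, :] = 1.0
    dist[:, constant] = 1.0
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, 1.0)
    z = linkage(squareform(dist, checks=False), method="average")
    dist_df = pd.DataFrame(dist, index=matrix.band_ids, columns=matrix.band_ids)
    return CorrelationTree(linkage_matrix=z, band_ids=matrix.band_ids,
                           distances=dist_df)


def cut_tree_at_threshold(tree: CorrelationTree,
                          rho_threshold: float = 0.45) -> pd.Series:
    """Flat clusters from cutting the dendrogram at height 1 - threshold.

    Bands merged at average distance <= 1 - ``rho_threshold`` (i.e.
    average |rho| >= threshold) share a cluster label.
    """
    if not 0 < rho_threshold < 1:
        raise ValueError("rho_threshold must lie in (0, 1)")
    labels = fcluster(tree.linkage_matrix, t=1.0 - rho_threshold,
                      criterion="distance")
    return pd.Series(labels, index=tree.band_ids, name="cluster")


def partial_spearman(x: np.ndarray, y: np.ndarray,
                     conditioners: np.ndarray | None) -> tuple[float, float]:
    """Rank-based partial correlation of x and y given conditioners.

    All variables are rank-transformed, then the partial correlation is
    read off the inverse of their joint correlation matrix
    (``r = -P_xy / sqrt(P_xx P_yy)``); this equals correlating the
    residuals of x and y after regressing each on the conditioners.  The
    p-value uses the t reference with ``n - 2 - k`` degrees of freedom
    for k conditioners.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if conditioners is None or conditioners.size == 0:
        k = 0
        rho = stats.spearmanr(x, y).statistic
    else:
        conditioners = np.atleast_2d(np.asarray(conditioners, dtype=float))
        if conditioners.shape[0] != n:
            conditioners = conditioners.T
        k = conditioners.shape[1]
        if k > n - 3:
            raise ValueError(
                f"conditioning set of size {k} too large for sample size {n} "
                "(needs k <= n - 3)"
            )
        data = np.column_stack([x, y, conditioners])
        ranks = np.apply_along_axis(stats.rankdata, 0, data)
        corr = np.corrcoef(ranks, rowvar=False)
        prec = np.linalg.inv(corr)
        rho = -prec[0, 1] / np.sqrt(prec[0, 0] * prec[1, 1])
    df = n - 2 - k
    rho = float(np.clip(rho, -1.0, 1.0))
    if df <= 0:
        return rho, np.nan
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt(df / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return rho, float(p)


@dataclass
class ClusterScreen:
    """Outcome of the direct/indirect screen.

    ``table`` has one row per band: cluster membership, marginal trend
    statistics, partial-correlation statistics where screened, the final
    classification in {direct, indirect, unaffected} and the trend sign
    (+1 increasing / -1 decreasing with temperature) of direct bands.
    """

    tree: CorrelationTree
    clusters: pd.Series
    table: pd.DataFrame

    @property
    def direct_bands(self) -> list[str]:
        return list(self.table.index[self.table["classification"] == "direct"])

    @property
    def indirect_bands(self) -> list[str]:
        return list(self.table.index[self.table["classification"] == "indirect"])


def partial_correlation_screen(
    matrix: BandMatrix,
    clusters: pd.Series,
    correlations: pd.DataFrame,
    arrow_score: pd.Series | np.ndarray,
    alpha: float = 0.05,
    tree: CorrelationTree | None = None,
) -> ClusterScreen:
    """Classify every band as direct, indirect or unaffected.

    ``correlations`` is the output of
    :func:`~venomtherm.multivariate.band_trend_correlations`; its
    ``candidate`` column defines the bands eligible to be direct or
    indirect.  Candidates alone in their cluster are direct with their
    marginal sign.  In clusters with two or more candidates, each
    candidate's rank-based partial correlation with the trend score,
    conditioning on the other candidates of the cluster, is tested;
    Bonferroni correction uses the number of bands screened in this
    step.  A candidate stays direct iff its adjusted partial p-value is
    below ``alpha``.
    """
    proj = np.asarray(arrow_score, dtype=float)
    if len(proj) != matrix.n_individuals:
        raise ValueError("arrow scores are not aligned to matrix rows")
    missing = [b for b in correlations.index if b not in clusters.index]
    if missing:
        raise ValueError(f"bands missing from clusters: {missing}")

    vals = matrix.intensities
    candidates = [b for b in matrix.band_ids if bool(correlations.loc[b, "candidate"])]

    partial_rho = pd.Series(np.nan, index=matrix.band_ids, dtype=float)
    partial_p = pd.Series(np.nan, index=matrix.band_ids, dtype=float)
    screened: list[str] = []
    for cl in sorted(clusters.unique()):
        members = [b for b in matrix.band_ids if clusters[b] == cl]
        cands = [b for b in members if b in candidates]
        if len(cands) < 2:
            continue
        for b in cands:
            others = [c for c in cands if c != b]
            rho, p = partial_spearman(
                vals[b].to_numpy(), proj, vals[others].to_numpy()
            )
            partial_rho[b] = rho
            partial_p[b] = p
            screened.append(b)

    n_screened = len(screened)
    partial_p_adj = pd.Series(np.nan, index=matrix.band_ids, dtype=float)
    if n_screened:
        partial_p_adj[screened] = np.minimum(1.0, partial_p[screened] * n_screened)

    classification = pd.Series("unaffected", index=matrix.band_ids)
    sign = pd.Series(0, index=matrix.band_ids, dtype=int)
    for b in candidates:
        if b in screened:
            classification[b] = "direct" if partial_p_adj[b] < alpha else "indirect"
        else:
            classification[b] = "direct"
        if classification[b] == "direct":
            sign[b] = int(correlations.loc[b, "sign"])

    table = pd.DataFrame(
        {
            "cluster": clusters.loc[matrix.band_ids].to_numpy(),
            "classification": classification,
            "sign": sign,
            "rho": correlations["rho"],
            "p_bonferroni": correlations["p_bonferroni"],
            "partial_rho": partial_rho,
            "partial_p": partial_p,
            "partial_p_bonferroni": partial_p_adj,
        }
    )
    table.index.name = "band_id"
    return ClusterScreen(tree=tree, clusters=clusters, table=table)


def annotate_abundant_proteins(
    screen: ClusterScreen,
    annotations: pd.DataFrame,
    min_peptide_matches: int = 10,
) -> pd.DataFrame:
    """Join the screen with the known protein content of each band.

    ``annotations`` needs columns ``band_id``, ``protein`` and
    ``peptide_matches`` (one row per protein found in a band; NaN
    matches mean no proteomic data).  A protein is flagged abundant when
    its peptide-match count reaches ``min_peptide_matches``.  The
    returned report lists, per band, its classification and trend sign
    together with its abundant proteins.  Annotation rows whose band_id
    does not occur in the screen are dropped with a warning.
    """
    required = {"band_id", "protein", "peptide_matches"}
    if not required <= set(annotations.columns):
        raise ValueError(f"annotations need columns {sorted(required)}")
    ann = annotations.copy()
    unknown = sorted(set(ann["band_id"]) - set(screen.table.index))
    if unknown:
        warnings.warn(f"annotations refer to unknown bands {unknown}; ignored",
                      stacklevel=2)
        ann = ann[~ann["band_id"].isin(unknown)]
    ann["abundant"] = ann["peptide_matches"] >= min_peptide_matches
    grouped = (
        ann[ann["abundant"]]
        .groupby("band_id")["protein"]
        .apply(lambda s: "; ".join(s))
    )
    report = screen.table.copy()
    report["abundant_proteins"] = grouped.reindex(report.index).fillna("")
    report["n_abundant_proteins"] = (
        ann[ann["abundant"]].groupby("band_id").size().reindex(report.index)
        .fillna(0).astype(int)
    )
    return report


def load_annotations(line: str) -> pd.DataFrame:
    """Published protein content of the temperature-affected bands.

    ``line`` is ``"ISm"`` or ``"ISy"``.  Columns: ``band_id`` (the gel
    band number), ``protein`` (name, with marker proteins in
    parentheses), ``peptide_matches`` (mass-spectrometry peptide match
    count; NaN when the band was not analyzed) and ``trend`` (the
    published direction of intensity change with temperature).
    """
    from importlib import resources

    name = f"{line.lower()}_band_annotations.csv"
    ref = resources.files("venomtherm.data").joinpath(name)
    if not ref.is_file():
        raise ValueError(f"no annotation table for line {line!r}")
    with resources.as_file(ref) as path:
        return pd.read_csv(path)
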