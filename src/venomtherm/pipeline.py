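"""End-to-end global venom-composition analysis.

Chains the individual steps into the published workflow: normalize the
band matrix (quantile for ISm, cyclic loess for ISy), test the total
band intensity with a Gaussian LMM, partition multivariate variation
with a sequential PERMANOVA (temperature then replicate), center within
replicates, fit the LDA, draw the centroid trend arrow, screen bands by
marginal Spearman correlation with the arrow, and disambiguate direct
from indirect bands with UPGMA clustering plus partial correlations.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import bandscreen, densitometry, multivariate, outcomes
from .containers import BandMatrix

__all__ = ["GlobalAnalysisResult", "run_global_analysis"]

#: normalization method the study assigned to each parasitoid line
LINE_NORMALIZATION = {"ISm": "quantile", "ISy": "cyclic-loess"}


@dataclass
class GlobalAnalysisResult:
    """All intermediate and final products of the global analysis."""

    normalized: BandMatrix
    centered: BandMatrix
    total_intensity: pd.DataFrame
    total_intensity_fit: outcomes.MixedModelFit
    permanova: multivariate.PermanovaTable
    lda: multivariate.LDAResult
    arrow: multivariate.TrendArrow
    arrow_score: pd.Series
    correlations: pd.DataFrame
    screen: bandscreen.ClusterScreen
    report: pd.DataFrame | None = None


def run_global_analysis(
    matrix: BandMatrix,
    normalization: str | None = None,
    n_permutations: int = 5000,
    rho_threshold: float = 0.45,
    seed: int | None = None,
    annotations: pd.DataFrame | None = None,
    loess_span: float = 0.7,
    loess_offset: float = 1.0,
) -> GlobalAnalysisResult:
    """Run the full temperature-trend analysis on a raw band matrix.

    ``normalization`` is ``"quantile"`` or ``"cyclic-loess"``; by default
    it is chosen from the matrix's parasitoid line (quantile for ISm,
    cyclic loess for ISy).  ``seed`` drives the PERMANOVA permutations.
    If ``annotations`` is given, the screen is joined with the protein
    content to produce the final report.
    """
    if normalization is None:
        lines = matrix.meta["line"].unique()
        normalization = LINE_NORMALIZATION.get(lines[0], "quantile") \
            if len(lines) == 1 else "quantile"
    if normalization == "quantile":
        normalized = densitometry.quantile_normalize(matrix)
    elif normalization == "cyclic-loess":
        normalized = densitometry.cyclic_loess_normalize(
            matrix, span=loess_span, offset=loess_offset)
    elif normalization == "none":
        # for matrices already on a common scale (e.g. simulations that
        # plant no lane-loading artifacts) normalization only distorts
        normalized = matrix
    else:
        raise ValueError(f"unknown normalization {normalization!r}")

    # totals come from the raw matrix: quantile normalization forces every
    # lane to the same value multiset, making normalized totals constant
    totals = densitometry.total_band_intensity(matrix)
    total_fit = outcomes.fit_gaussian_lmm(
        totals.rename(columns={"total_intensity": "value"}))
    outcomes.tukey_pairwise(total_fit)

    perm = multivariate.permanova(
        normalized, terms=("temperature", "replicate"),
        n_permutations=n_permutations, seed=seed)

    centered = multivariate.center_within_replicates(normalized)
    lda = multivariate.fit_lda(centered)
    arrow = multivariate.centroid_trend_arrow(lda.centroids)
    score = multivariate.arrow_scores(lda.scores, arrow)
    correlations = multivariate.band_trend_correlations(centered, arrow, lda.scores)

    tree = bandscreen.correlation_distance_tree(centered)
    clusters = bandscreen.cut_tree_at_threshold(tree, rho_threshold)
    screen = bandscreen.partial_correlation_screen(
        centered, clusters, correlations, score, tree=tree)

    report = None
    if annotations is not None:
        report = bandscreen.annotate_abundant_proteins(screen, annotations)

    return GlobalAnalysisResult(
        normalized=normalized,
        centered=centered,
        total_intensity=totals,
        total_intensity_fit=total_fit,
        permanova=perm,
        lda=lda,
        arrow=arrow,
        arrow_score=score,
        correlations=correlations,
        screen=screen,
        report=report,
    )
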