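"""Host-parasitoid interaction outcomes and their mixed-model statistics.

Dissection of a mono-parasitized host larva yields one of three
outcomes: a free parasitoid larva alone (L), a free larva plus an open
capsule (LOC, an escaped parasitoid) or a complete closed capsule (CC, a
host win).  Together with the parasitized / non-parasitized split these
define five derived binomial responses per dish
(:func:`derive_interaction_responses`).  The oil-drop assay scores host
melanization on ordinal classes 0-5, binarized into melanized (2-5)
versus not (0-1) per capillary (:func:`binarize_melanization`).

Responses are analyzed with binomial logit mixed models (random
intercept for the replicate or capillary; an observation-level random
effect is added when the Pearson overdispersion ratio of the first fit
exceeds 2), followed by Tukey-adjusted pairwise temperature contrasts.
Class-by-temperature independence is tested with a Monte-Carlo Fisher
exact test, and continuous responses (total venom intensity, relative
marker-protein intensity) with Gaussian linear mixed models, optionally
after a Box-Cox transform.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

import statsmodels.api as sm

from .glmm import BinomialMixedFit, fit_binomial_mixed

__all__ = [
    "OutcomeRecord",
    "MixedModelFit",
    "derive_interaction_responses",
    "collapse_multiple_drops",
    "binarize_melanization",
    "fit_binomial_glmm",
    "fit_gaussian_lmm",
    "tukey_pairwise",
    "fisher_class_independence",
]

logger = logging.getLogger(__name__)

COUNT_COLUMNS = ("non_parasitized", "mono_L", "mono_LOC", "mono_CC",
                 "multi_parasitized")

RESPONSE_DEFINITIONS = {
    # name: (success categories, failure categories); mono-based unless noted
    "parasitic_success": (("mono_L", "mono_LOC"), ("mono_CC",)),
    "encapsulation_capacity": (("mono_LOC", "mono_CC"), ("mono_L",)),
    "inhibition_capacity": (("mono_L",), ("mono_LOC", "mono_CC")),
    "escape_capacity": (("mono_LOC",), ("mono_CC",)),
}


@dataclass
class OutcomeRecord:
    """Per-dish dissection counts."""

    dish_id: str
    replicate: str
    temperature: float
    host: str
    line: str
    non_parasitized: int
    mono_L: int
    mono_LOC: int
    mono_CC: int
    multi_parasitized: int

    def __post_init__(self) -> None:
        for c in COUNT_COLUMNS:
            if getattr(self, c) < 0:
                raise ValueError(f"count {c} must be non-negative")

    @property
    def total(self) -> int:
        return sum(getattr(self, c) for c in COUNT_COLUMNS)


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        frame = records.copy()
    else:
        frame = pd.DataFrame([vars(r) for r in records])
    missing = [c for c in COUNT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"outcome records lack count columns {missing}")
    if (frame[list(COUNT_COLUMNS)] < 0).any().any():
        raise ValueError("outcome counts must be non-negative")
    return frame


def derive_interaction_responses(records) -> dict[str, pd.DataFrame]:
    """Build the five per-dish binomial responses from outcome counts.

    ``parasitism_rate`` opposes parasitized (mono + multi) to
    non-parasitized larvae and uses every dish.  The other four
    responses are computed on mono-parasitized larvae only (the fate of
    a multi-parasitized larva is confounded by competition among
    parasitoid larvae): ``parasitic_success`` = L + LOC vs CC,
    ``encapsulation_capacity`` = LOC + CC vs L, ``inhibition_capacity``
    = L vs LOC + CC, ``escape_capacity`` = LOC vs CC.  Dishes without
    informative larvae for a response are dropped from it (logged).  The
    ``escape_capacity`` table carries a ``sparse`` flag for dishes with
    at most two larvae showing an encapsulation response; such dishes
    are reported but are best excluded from contrasts.
    """
    frame = _as_frame(records)
    meta_cols = [c for c in ("dish_id", "replicate", "temperature", "host", "line")
                 if c in frame.columns]
    mono_total = frame[["mono_L", "mono_LOC", "mono_CC"]].sum(axis=1)

    out: dict[str, pd.DataFrame] = {}
    para = frame[meta_cols].copy()
    para["successes"] = mono_total + frame["multi_parasitized"]
    para["failures"] = frame["non_parasitized"]
    out["parasitism_rate"] = para[para["successes"] + para["failures"] > 0]

    for name, (succ, fail) in RESPONSE_DEFINITIONS.items():
        tab = frame[meta_cols].copy()
        tab["successes"] = frame[list(succ)].sum(axis=1)
        tab["failures"] = frame[list(fail)].sum(axis=1)
        keep = mono_total > 0
        dropped = frame.loc[~keep, "dish_id"].tolist() if "dish_id" in frame else []
        if dropped:
            logger.info("%s: dropped dishes without mono-parasitized larvae: %s",
                        name, dropped)
        tab = tab[keep]
        informative = tab["successes"] + tab["failures"]
        tab = tab[informative > 0]
        if name == "escape_capacity":
            tab = tab.copy()
            tab["sparse"] = (tab["successes"] + tab["failures"]) <= 2
        out[name] = tab.reset_index(drop=True)
    out["parasitism_rate"] = out["parasitism_rate"].reset_index(drop=True)
    return out


def collapse_multiple_drops(frame: pd.DataFrame) -> pd.DataFrame:
    """Keep, per larva, only the highest melanization class observed.

    For larvae that received several oil drops, only the drop in the
    highest encapsulation class counts.
    """
    keys = [c for c in ("larva_id", "capillary", "species", "temperature")
            if c in frame.columns]
    if "larva_id" not in keys:
        raise ValueError("need a larva_id column to collapse drops")
    return (frame.groupby(keys, as_index=False)["melanization_class"].max())


def binarize_melanization(records: pd.DataFrame) -> pd.DataFrame:
    """Pool melanization classes into melanized (2-5) vs not (0-1).

    Accepts either per-larva rows with a ``melanization_class`` column
    or a wide table with ``class_0`` ... ``class_5`` count columns.
    Counts are grouped by capillary and temperature (and species if
    present), matching the capillary random effect of the downstream
    model.
    """
    frame = records.copy()
    keys = [c for c in ("capillary", "temperature", "species") if c in frame.columns]
    if "capillary" not in keys or "temperature" not in keys:
        raise ValueError("melanization records need capillary and temperature columns")
    if "melanization_class" in frame.columns:
        cls = frame["melanization_class"]
        if not cls.isin(range(6)).all():
            bad = sorted(cls[~cls.isin(range(6))].unique())
            raise ValueError(f"melanization classes outside 0-5: {bad}")
        frame["melanized"] = (cls >= 2).astype(int)
        grouped = frame.groupby(keys).agg(
            successes=("melanized", "sum"),
            failures=("melanized", lambda s: int((1 - s).sum())),
        )
        return grouped.reset_index()
    class_cols = [f"class_{k}" for k in range(6)]
    missing = [c for c in class_cols if c not in frame.columns]
    if missing:
        raise ValueError(f"wide melanization table lacks columns {missing}")
    extra = [c for c in frame.columns if c.startswith("class_")
             and c not in class_cols]
    if extra:
        raise ValueError(f"melanization classes outside 0-5: {extra}")
    frame["successes"] = frame[class_cols[2:]].sum(axis=1)
    frame["failures"] = frame[class_cols[:2]].sum(axis=1)
    return frame.groupby(keys, as_index=False)[["successes", "failures"]].sum()


@dataclass
class MixedModelFit:
    """Outcome of a binomial or Gaussian mixed-model analysis."""

    family: str                         # "binomial-logit" or "gaussian"
    coef: pd.Series
    se: pd.Series
    vcov: pd.DataFrame
    random_sd: dict[str, float]
    levels: np.ndarray                  # fixed-factor (temperature) levels
    level_means: pd.Series              # estimated marginal means, link scale
    level_vcov: pd.DataFrame
    overdispersion_ratio: float | None = None
    olre: bool = False
    converged: bool = True
    separation: bool = False
    degenerate: bool = False
    fixed_effect_test: dict = field(default_factory=dict)
    df_denominator: float | None = None  # Gaussian fits: containment df
    boxcox_lambda: float | None = None
    loglik: float | None = None
    contrasts: pd.DataFrame | None = None


def _temperature_design(frame: pd.DataFrame, fixed: str):
    levels = np.sort(frame[fixed].unique())
    if len(levels) < 2:
        raise ValueError(f"fixed factor {fixed!r} needs >= 2 levels with data")
    X = pd.DataFrame({"Intercept": np.ones(len(frame))}, index=frame.index)
    for lev in levels[1:]:
        X[f"{fixed}[{lev}]"] = (frame[fixed] == lev).astype(float)
    return X, levels


def _level_means(levels, coef: pd.Series, vcov: pd.DataFrame, fixed: str):
    A = np.zeros((len(levels), len(coef)))
    A[:, 0] = 1.0
    for i, lev in enumerate(levels[1:], start=1):
        A[i, list(coef.index).index(f"{fixed}[{lev}]")] = 1.0
    means = pd.Series(A @ coef.to_numpy(), index=levels)
    mv = pd.DataFrame(A @ vcov.to_numpy() @ A.T, index=levels, columns=levels)
    return means, mv


def fit_binomial_glmm(
    response: pd.DataFrame,
    fixed: str = "temperature",
    random: str = "replicate",
    olre_threshold: float = 2.0,
    compute_lrt: bool = True,
) -> MixedModelFit:
    """Binomial logit GLMM of a derived response with the OLRE rule.

    Fits successes/failures against the fixed factor (temperature) with
    a random intercept per ``random`` group.  The Pearson
    overdispersion ratio (chi-square over residual df) is computed on
    this first fit; if it exceeds ``olre_threshold`` (the conventional
    ratio of 2), the model is refitted with an additional
    observation-level random intercept and the ``olre`` flag is set.
    Complete separation (a temperature level with only successes or only
    failures) is detected and flagged rather than silently returned.
    ``fixed_effect_test`` holds a likelihood-ratio test of the fixed
    factor (both models refitted with the same random structure).
    """
    frame = response.copy()
    for col in ("successes", "failures", fixed, random):
        if col not in frame.columns:
            raise ValueError(f"response table lacks column {col!r}")
    frame = frame[frame["successes"] + frame["failures"] > 0].reset_index(drop=True)
    X, levels = _temperature_design(frame, fixed)

    separation = False
    for lev in levels:
        sub = frame[frame[fixed] == lev]
        if sub["successes"].sum() == 0 or sub["failures"].sum() == 0:
            separation = True

    factors = {random: frame[random].to_numpy()}
    fit = fit_binomial_mixed(frame["successes"], frame["failures"], X, factors)
    trials = frame["successes"] + frame["failures"]
    ratio = fit.pearson_ratio(frame["successes"], trials)
    olre = ratio > olre_threshold
    if olre:
        factors = {random: frame[random].to_numpy(),
                   "observation": np.arange(len(frame))}
        fit = fit_binomial_mixed(frame["successes"], frame["failures"], X, factors)

    means, mv = _level_means(levels, fit.beta, fit.vcov, fixed)

    test: dict = {}
    if compute_lrt:
        X0 = X[["Intercept"]]
        fit0 = fit_binomial_mixed(frame["successes"], frame["failures"], X0, factors)
        stat = max(0.0, 2.0 * (fit.loglik - fit0.loglik))
        df = len(levels) - 1
        test = {"statistic": stat, "df": df,
                "p_value": float(stats.chi2.sf(stat, df)), "method": "LRT"}

    return MixedModelFit(
        family="binomial-logit",
        coef=fit.beta,
        se=fit.se,
        vcov=fit.vcov,
        random_sd=fit.random_sd,
        levels=levels,
        level_means=means,
        level_vcov=mv,
        overdispersion_ratio=ratio,
        olre=bool(olre),
        converged=fit.converged,
        separation=separation,
        fixed_effect_test=test,
        loglik=fit.loglik,
    )


def fit_gaussian_lmm(
    data: pd.DataFrame,
    value: str = "value",
    fixed: str = "temperature",
    random: str = "replicate",
    transform: str = "none",
) -> MixedModelFit:
    """Gaussian linear mixed model for a continuous venom response.

    Optionally applies a maximum-likelihood Box-Cox transform before
    fitting (``transform="boxcox"``; values must be positive - shift
    them with an offset first if not).  The temperature effect is
    summarized by a Wald F statistic with containment denominator
    degrees of freedom: the number of distinct temperature x replicate
    cells minus the number of fixed-effect parameters (12 in the
    balanced 3 x 5 design).
    """
    frame = data.copy()
    for col in (value, fixed, random):
        if col not in frame.columns:
            raise ValueError(f"data lacks column {col!r}")
    lam = None
    if transform == "boxcox":
        if (frame[value] <= 0).any():
            raise ValueError(
                "Box-Cox requires positive values; add a positive offset to the "
                "response first"
            )
        transformed, lam = stats.boxcox(frame[value].to_numpy())
        frame[value] = transformed
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")

    X, levels = _temperature_design(frame, fixed)
    total_var = float(np.var(frame[value]))
    if total_var < 1e-12:
        # constant response: nothing to estimate beyond the mean
        coef = pd.Series(0.0, index=X.columns)
        coef["Intercept"] = float(frame[value].mean())
        nanmat = pd.DataFrame(np.nan, index=X.columns, columns=X.columns)
        means, mv = _level_means(levels, coef, nanmat, fixed)
        return MixedModelFit(
            family="gaussian", coef=coef,
            se=pd.Series(np.nan, index=X.columns), vcov=nanmat,
            random_sd={random: 0.0}, levels=levels, level_means=means,
            level_vcov=mv, degenerate=True,
            fixed_effect_test={"statistic": np.nan, "df_num": len(levels) - 1,
                               "df_den": np.nan, "p_value": np.nan,
                               "method": "Wald-F"},
            boxcox_lambda=None if lam is None else float(lam),
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(frame[value].to_numpy(), X.to_numpy(),
                           groups=frame[random].to_numpy())
        result = None
        for method in (None, "powell", "cg"):
            try:
                kwargs = {} if method is None else {"method": method}
                result = model.fit(reml=True, **kwargs)
                break
            except np.linalg.LinAlgError:
                # gradient-based optimizer walked into a singular profile
                # (random variance at the boundary); retry derivative-free
                continue
        if result is None:
            raise np.linalg.LinAlgError(
                "mixed-model fit failed with every optimizer")
    coef = pd.Series(result.fe_params, index=X.columns)
    vcov = pd.DataFrame(np.asarray(result.cov_params())[: len(coef), : len(coef)],
                        index=X.columns, columns=X.columns)
    se = pd.Series(np.sqrt(np.diag(vcov)), index=X.columns)
    resid_var = float(result.scale)
    total_var = float(np.var(frame[value]))
    degenerate = resid_var < 1e-10 * max(total_var, 1.0)

    n_cells = frame.groupby([fixed, random]).ngroups
    df_den = n_cells - len(coef)
    contrast_idx = [i for i, c in enumerate(X.columns) if c != "Intercept"]
    b = coef.to_numpy()[contrast_idx]
    V = vcov.to_numpy()[np.ix_(contrast_idx, contrast_idx)]
    df_num = len(contrast_idx)
    f_stat = float(b @ np.linalg.solve(V, b) / df_num)
    p = float(stats.f.sf(f_stat, df_num, df_den)) if df_den > 0 else np.nan

    means, mv = _level_means(levels, coef, vcov, fixed)
    re_sd = {random: float(np.sqrt(max(np.asarray(result.cov_re).item(), 0.0)))}
    return MixedModelFit(
        family="gaussian",
        coef=coef,
        se=se,
        vcov=vcov,
        random_sd=re_sd,
        levels=levels,
        level_means=means,
        level_vcov=mv,
        converged=bool(result.converged),
        degenerate=degenerate,
        fixed_effect_test={"statistic": f_stat, "df_num": df_num,
                           "df_den": df_den, "p_value": p, "method": "Wald-F"},
        df_denominator=float(df_den),
        boxcox_lambda=None if lam is None else float(lam),
        loglik=float(result.llf),
    )


def _mvn_outside(z_abs: float, corr: np.ndarray) -> float:
    """P(max_j |Z_j| >= z) for Z ~ MVN(0, corr): single-step adjustment."""
    k = corr.shape[0]
    if z_abs == 0:
        return 1.0
    mvn = stats.multivariate_normal(mean=np.zeros(k), cov=corr,
                                    allow_singular=True)
    inside = mvn.cdf(np.full(k, z_abs), lower_limit=np.full(k, -z_abs))
    return float(np.clip(1.0 - inside, 0.0, 1.0))


def tukey_pairwise(fit: MixedModelFit) -> pd.DataFrame:
    """All pairwise temperature contrasts with single-step adjustment.

    Contrasts are differences of estimated marginal means on the link
    scale.  For binomial fits the adjusted p-value is the probability
    that the maximum absolute value of the jointly normal contrast
    statistics exceeds the observed one (the multivariate-normal
    generalization of the Tukey test); for Gaussian fits the classical
    studentized-range reference with the containment denominator df is
    used.
    """
    if fit.level_means is None or len(fit.levels) < 2:
        raise ValueError("model must be fitted with >= 2 levels")
    levels = list(fit.levels)
    pairs = [(a, b) for i, a in enumerate(levels) for b in levels[i + 1:]]
    k = len(levels)
    C = np.zeros((len(pairs), k))
    for r, (a, b) in enumerate(pairs):
        C[r, levels.index(b)] = 1.0
        C[r, levels.index(a)] = -1.0
    est = C @ fit.level_means.to_numpy()
    V = C @ fit.level_vcov.to_numpy() @ C.T
    se = np.sqrt(np.diag(V))
    stat = est / se
    denom = np.sqrt(np.outer(np.diag(V), np.diag(V)))
    corr = V / denom

    rows = []
    for r, (a, b) in enumerate(pairs):
        if fit.family == "gaussian":
            df = fit.df_denominator if fit.df_denominator else np.inf
            p_adj = float(stats.studentized_range.sf(
                abs(stat[r]) * np.sqrt(2.0), k, df))
            p_raw = 2.0 * float(stats.t.sf(abs(stat[r]), df))
        else:
            p_adj = _mvn_outside(abs(stat[r]), corr)
            p_raw = 2.0 * float(stats.norm.sf(abs(stat[r])))
        rows.append({
            "contrast": f"{b} - {a}",
            "estimate": est[r],
            "se": se[r],
            "statistic": stat[r],
            "p_value": p_raw,
            "p_adjusted": min(1.0, p_adj),
        })
    table = pd.DataFrame(rows)
    fit.contrasts = table
    return table


def fisher_class_independence(
    table,
    n_sim: int = 2000,
    seed: int | None = None,
) -> float:
    """Monte-Carlo Fisher exact test of class x temperature independence.

    ``n_sim`` tables are drawn with the observed margins fixed
    (Patefield's algorithm); the p-value is
    ``(1 + #simulated tables at most as probable as the observed one)
    / (1 + n_sim)`` under the multivariate hypergeometric null, the
    convention of R's ``fisher.test(simulate.p.value = TRUE)``.
    """
    obs = np.asarray(table, dtype=float)
    if isinstance(table, pd.DataFrame):
        obs = table.to_numpy(dtype=float)
    if obs.ndim != 2 or min(obs.shape) < 2:
        raise ValueError("need a table with at least 2 rows and 2 columns")
    if np.any(obs < 0) or not np.allclose(obs, np.round(obs)):
        raise ValueError("table entries must be non-negative integers")
    rows_zero = obs.sum(axis=1) == 0
    cols_zero = obs.sum(axis=0) == 0
    if rows_zero.any() or cols_zero.any():
        warnings.warn("dropping all-zero rows/columns from the table", stacklevel=2)
        obs = obs[~rows_zero][:, ~cols_zero]
        if min(obs.shape) < 2:
            raise ValueError("table degenerate after dropping zero margins")

    def log_prob(t: np.ndarray) -> np.ndarray:
        r = t.sum(axis=-1)
        c = t.sum(axis=-2)
        n = r.sum(axis=-1)
        return (
            special.gammaln(r + 1).sum(axis=-1)
            + special.gammaln(c + 1).sum(axis=-1)
            - special.gammaln(n + 1)
            - special.gammaln(t + 1).sum(axis=(-2, -1))
        )

    rng = np.random.default_rng(seed)
    dist = stats.random_table(obs.sum(axis=1), obs.sum(axis=0))
    sims = dist.rvs(n_sim, random_state=rng)
    lp_obs = log_prob(obs)
    lp_sim = log_prob(sims)
    n_le = int(np.sum(lp_sim <= lp_obs + 1e-7))
    return (1.0 + n_le) / (1.0 + n_sim)
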