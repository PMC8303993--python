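"""Synthetic data with the statistical structure the analyses assume.

Three generators mirror the study design:

* :func:`simulate_band_matrix` — venom band-intensity matrices for a
  balanced 3 temperatures x 5 replicates x 7 individuals design with a
  handful of "direct" bands whose expected intensity is linear in
  temperature, "indirect" bands that are a noisy copy of a direct parent
  band (so their partial correlation with the trend given the parent is
  zero by construction), and unaffected bands.
* :func:`simulate_lane_profiles` — Gaussian-peak lane traces whose peak
  areas are the planted band volumes, for round-trip tests of the
  densitometry step.
* :func:`simulate_outcomes` / :func:`simulate_melanization` — per-dish
  parasitism category counts (trinomial split of mono-parasitized larvae
  into L / LOC / CC with dish-level logit noise) and ordinal oil-drop
  melanization classes 0-5 with capillary random intercepts.

Every generator is deterministic given its seed, and each returns
ground-truth labels or parameters alongside the data so that recovery
tests can score the analysis modules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .containers import BandMatrix, LaneProfile, ReferenceBand

__all__ = [
    "BandSimSpec",
    "OutcomeSimSpec",
    "MelanizationSimSpec",
    "LaneSimResult",
    "simulate_band_matrix",
    "simulate_lane_profiles",
    "simulate_outcomes",
    "simulate_melanization",
]

TEMPERATURES = (20.0, 25.0, 30.0)


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class BandSimSpec:
    """Design of a synthetic band-intensity matrix.

    Defaults reproduce the study design for one parasitoid line: three
    rearing temperatures (20/25/30 degC), five replicates of seven females
    each (105 individuals) and 35 reference bands, of which three are
    planted as direct (expected intensity linear in temperature, mixed
    signs), three as indirect (parent direct band plus link noise) and
    the rest unaffected.

    ``effect_size`` is the per-degC shift of a direct band in intensity
    units; ``replicate_sd`` the SD of replicate offsets (drawn per band
    and replicate); ``noise_sd`` the residual SD; ``link_noise_sd`` the
    noise added when deriving an indirect band from its parent.
    """

    n_temperatures: int = 3
    n_replicates: int = 5
    n_per_cell: int = 7
    n_bands: int = 35
    direct_bands: frozenset[int] = frozenset({4, 16, 28})
    indirect_bands: Mapping[int, int] = field(
        default_factory=lambda: {5: 4, 17: 16, 29: 28}
    )
    direct_signs: Mapping[int, int] = field(
        default_factory=lambda: {4: 1, 16: -1, 28: 1}
    )
    effect_size: float = 2.0
    replicate_sd: float = 2.5
    noise_sd: float = 10.0
    link_noise_sd: float = 8.0
    baseline_low: float = 50.0
    baseline_high: float = 150.0
    line: str = "ISm"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_temperatures != len(TEMPERATURES):
            raise ValueError("n_temperatures must be 3 (20, 25, 30 degC)")
        direct = set(self.direct_bands)
        indirect = set(self.indirect_bands)
        if direct & indirect:
            raise ValueError(
                f"direct and indirect band sets overlap: {sorted(direct & indirect)}"
            )
        for b in direct | indirect:
            if not 0 <= b < self.n_bands:
                raise ValueError(f"band index {b} out of range [0, {self.n_bands})")
        for child, parent in self.indirect_bands.items():
            if parent not in direct:
                raise ValueError(f"indirect band {child} has non-direct parent {parent}")
        for sd_name in ("replicate_sd", "noise_sd", "link_noise_sd"):
            if getattr(self, sd_name) < 0:
                raise ValueError(f"{sd_name} must be >= 0")
        if not set(self.direct_signs) <= direct:
            raise ValueError("direct_signs keys must be direct bands")

    @property
    def temperatures(self) -> tuple[float, ...]:
        return TEMPERATURES

    def sign_of(self, band: int) -> int:
        return int(self.direct_signs.get(band, 1))


def simulate_band_matrix(spec: BandSimSpec) -> tuple[BandMatrix, pd.DataFrame]:
    """Draw a band matrix and its ground-truth band labels.

    Direct band b:      baseline_b + sign_b * effect_size * (T - 25) +
                        replicate offset + N(0, noise_sd)
    Indirect band c:    realized value of its parent + N(0, link_noise_sd)
    Unaffected band u:  baseline_u + replicate offset + N(0, noise_sd)

    Intensities are clipped at zero (silver-stain volumes are
    non-negative).  The truth table gives each band's label
    (direct / indirect / unaffected) and trend sign (+1 / -1, 0 for
    unaffected; indirect bands inherit their parent's sign).
    """
    rng = np.random.default_rng(spec.seed)
    n_rows = spec.n_temperatures * spec.n_replicates * spec.n_per_cell
    baselines = rng.uniform(spec.baseline_low, spec.baseline_high, size=spec.n_bands)
    # replicate offsets: per band and replicate, shared by the replicate's rows
    rep_offsets = rng.normal(0.0, spec.replicate_sd,
                             size=(spec.n_replicates, spec.n_bands))

    temps = np.repeat(TEMPERATURES, spec.n_replicates * spec.n_per_cell)
    reps = np.tile(np.repeat(np.arange(spec.n_replicates), spec.n_per_cell),
                   spec.n_temperatures)

    values = np.empty((n_rows, spec.n_bands))
    noise = rng.normal(0.0, spec.noise_sd, size=(n_rows, spec.n_bands))
    for b in range(spec.n_bands):
        if b in spec.indirect_bands:
            continue
        slope = 0.0
        if b in spec.direct_bands:
            slope = spec.sign_of(b) * spec.effect_size
        values[:, b] = (
            baselines[b] + slope * (temps - 25.0) + rep_offsets[reps, b] + noise[:, b]
        )
    for child, parent in spec.indirect_bands.items():
        values[:, child] = values[:, parent] + rng.normal(
            0.0, spec.link_noise_sd, size=n_rows
        )
    values = np.clip(values, 0.0, None)

    # individual counter within each (temperature, replicate) cell
    ids = []
    counter: dict[tuple[float, int], int] = {}
    for t, r in zip(temps, reps):
        counter[(t, r)] = counter.get((t, r), 0) + 1
        ids.append(f"{spec.line}_t{int(t)}_r{r + 1}_i{counter[(t, r)]}")
    idx = pd.Index(ids, name="individual_id")
    meta = pd.DataFrame(
        {
            "line": spec.line,
            "temperature": temps,
            "replicate": [f"r{r + 1}" for r in reps],
        },
        index=idx,
    )
    bands = [f"band_{b}" for b in range(spec.n_bands)]
    matrix = BandMatrix(pd.DataFrame(values, index=idx, columns=bands), meta)

    labels, signs = [], []
    for b in range(spec.n_bands):
        if b in spec.direct_bands:
            labels.append("direct")
            signs.append(spec.sign_of(b))
        elif b in spec.indirect_bands:
            labels.append("indirect")
            signs.append(spec.sign_of(spec.indirect_bands[b]))
        else:
            labels.append("unaffected")
            signs.append(0)
    truth = pd.DataFrame({"band_id": bands, "label": labels, "sign": signs})
    return matrix, truth


class LaneSimResult(NamedTuple):
    """Output of :func:`simulate_lane_profiles`."""

    profiles: list[LaneProfile]
    bands: list[ReferenceBand]
    overlapping: bool


def simulate_lane_profiles(
    band_positions: Sequence[float],
    true_volumes: np.ndarray,
    baseline: float | Callable[[np.ndarray], np.ndarray] = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    peak_sigma: float = 1.0,
    window_halfwidth: float | None = None,
    n_grid: int = 2000,
    metadata: Sequence[dict] | None = None,
) -> LaneSimResult:
    """Synthesize lane intensity traces from planted band volumes.

    Each lane is a sum of Gaussian peaks (area = planted volume, width
    ``peak_sigma``) at the band positions, plus a baseline (constant or a
    function of position) and optional Gaussian noise; negative values
    are clipped.  The returned reference bands use windows of
    ``window_halfwidth`` (default ``3 * peak_sigma``, which captures
    99.7% of a peak's area).  Peaks whose positions are closer than twice
    the window halfwidth cannot be resolved by windowed integration; such
    inputs raise a warning and set the ``overlapping`` flag.
    """
    band_positions = np.asarray(band_positions, dtype=float)
    if band_positions.ndim != 1 or len(band_positions) == 0:
        raise ValueError("band_positions must be a non-empty 1-D sequence")
    if np.any(np.diff(band_positions) <= 0):
        raise ValueError("band_positions must be strictly increasing")
    true_volumes = np.atleast_2d(np.asarray(true_volumes, dtype=float))
    if true_volumes.shape[1] != len(band_positions):
        raise ValueError("true_volumes must have one column per band position")
    if np.any(true_volumes < 0):
        raise ValueError("volumes must be non-negative")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if window_halfwidth is None:
        window_halfwidth = 3.0 * peak_sigma

    overlapping = bool(np.any(np.diff(band_positions) < 2.0 * window_halfwidth))
    if overlapping:
        warnings.warn(
            "some band positions are closer than twice the window halfwidth; "
            "windowed integration cannot separate them",
            stacklevel=2,
        )

    lo = band_positions[0] - 2.0 * window_halfwidth
    hi = band_positions[-1] + 2.0 * window_halfwidth
    grid = np.linspace(lo, hi, n_grid)
    base = baseline(grid) if callable(baseline) else np.full_like(grid, float(baseline))

    rng = np.random.default_rng(seed)
    profiles = []
    norm = peak_sigma * np.sqrt(2.0 * np.pi)
    for lane_i, vols in enumerate(true_volumes):
        trace = base.copy()
        for mu, v in zip(band_positions, vols):
            trace = trace + (v / norm) * np.exp(-0.5 * ((grid - mu) / peak_sigma) ** 2)
        if noise_sd > 0:
            trace = trace + rng.normal(0.0, noise_sd, size=grid.shape)
        trace = np.clip(trace, 0.0, None)
        meta = dict(metadata[lane_i]) if metadata is not None else {}
        meta.setdefault("individual_id", f"lane_{lane_i + 1}")
        profiles.append(LaneProfile(grid, trace, **meta))

    bands = [
        ReferenceBand(band_id=f"band_{b}", nominal_position=float(mu),
                      window_halfwidth=float(window_halfwidth))
        for b, mu in enumerate(band_positions)
    ]
    return LaneSimResult(profiles, bands, overlapping)


@dataclass(frozen=True)
class OutcomeSimSpec:
    """Design of a synthetic parasitism-outcome experiment.

    Dishes of ``larvae_per_dish`` host larvae are exposed at one of three
    temperatures.  Per dish, the parasitized count is binomial with a
    temperature-specific logit plus a dish-level normal intercept (SD
    ``replicate_sd``; this dish-level noise is what creates
    extra-binomial variation relative to a replicate-level model).
    Parasitized larvae are multi-parasitized with probability
    ``multi_fraction``; mono-parasitized larvae are split into
    L / LOC / CC by a baseline-CC multinomial logit whose two category
    logits receive a second, independent dish intercept.
    """

    n_dishes_per_temperature: int = 15
    larvae_per_dish: int = 30
    logit_parasitism: Mapping[float, float] = field(
        default_factory=lambda: {20.0: 1.2, 25.0: 1.2, 30.0: -0.5}
    )
    category_logits: Mapping[float, tuple[float, float]] = field(
        default_factory=lambda: {20.0: (2.0, 0.5), 25.0: (1.5, 0.5), 30.0: (0.0, 0.0)}
    )
    multi_fraction: float = 0.15
    replicate_sd: float = 0.5
    n_replicates: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.larvae_per_dish < 1:
            raise ValueError("larvae_per_dish must be >= 1")
        if not 0 <= self.multi_fraction <= 1:
            raise ValueError("multi_fraction must lie in [0, 1]")
        if self.replicate_sd < 0:
            raise ValueError("replicate_sd must be >= 0")
        if set(self.logit_parasitism) != set(TEMPERATURES):
            raise ValueError("logit_parasitism must map exactly the temperatures 20/25/30")
        if set(self.category_logits) != set(TEMPERATURES):
            raise ValueError("category_logits must map exactly the temperatures 20/25/30")


def simulate_outcomes(spec: OutcomeSimSpec) -> pd.DataFrame:
    """Draw per-dish outcome counts.

    Returns a table with one row per dish: ``dish_id``, ``replicate``,
    ``temperature``, ``host``, ``line`` and the counts
    ``non_parasitized``, ``mono_L``, ``mono_LOC``, ``mono_CC``,
    ``multi_parasitized`` (summing to ``larvae_per_dish``).
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    dish = 0
    for t in TEMPERATURES:
        for d in range(spec.n_dishes_per_temperature):
            dish += 1
            u_par = rng.normal(0.0, spec.replicate_sd)
            u_cat = rng.normal(0.0, spec.replicate_sd)
            p_par = _expit(spec.logit_parasitism[t] + u_par)
            n_par = rng.binomial(spec.larvae_per_dish, p_par)
            n_multi = rng.binomial(n_par, spec.multi_fraction)
            n_mono = n_par - n_multi
            l_l, l_loc = spec.category_logits[t]
            logits = np.array([l_l + u_cat, l_loc + u_cat, 0.0])
            probs = np.exp(logits - logits.max())
            probs /= probs.sum()
            mono_l, mono_loc, mono_cc = rng.multinomial(n_mono, probs)
            rows.append(
                {
                    "dish_id": f"dish_{dish}",
                    "replicate": f"r{d % spec.n_replicates + 1}",
                    "temperature": t,
                    "host": "D. melanogaster",
                    "line": "ISm",
                    "non_parasitized": spec.larvae_per_dish - n_par,
                    "mono_L": int(mono_l),
                    "mono_LOC": int(mono_loc),
                    "mono_CC": int(mono_cc),
                    "multi_parasitized": int(n_multi),
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class MelanizationSimSpec:
    """Design of a synthetic oil-drop melanization assay.

    Larvae are scored on the ordinal classes 0-5 drawn from a cumulative
    logit model: P(class <= k) = expit(cutpoint_k - latent), with latent
    = ``temperature_effect`` x temperature index (0, 1, 2 for 20, 25,
    30 degC) + capillary random intercept.  Capillaries are assigned
    round-robin within each temperature, so each capillary serves all
    temperatures (as in the assay, where one capillary injects one dish
    per temperature).
    """

    n_larvae_per_cell: int = 35
    cumulative_logits: tuple[float, ...] = (-2.0, -1.0, 0.0, 1.0, 2.0)
    temperature_effect: float = -1.0
    capillary_sd: float = 0.5
    n_capillaries: int = 5
    species: str = "D. melanogaster"
    seed: int = 0

    def __post_init__(self) -> None:
        cuts = np.asarray(self.cumulative_logits, dtype=float)
        if len(cuts) != 5 or np.any(np.diff(cuts) <= 0):
            raise ValueError(
                "cumulative_logits must be 5 strictly increasing cutpoints over classes 0-5"
            )
        if self.capillary_sd < 0:
            raise ValueError("capillary_sd must be >= 0")
        if self.n_capillaries < 1 or self.n_larvae_per_cell < 1:
            raise ValueError("counts must be >= 1")


def simulate_melanization(spec: MelanizationSimSpec) -> pd.DataFrame:
    """Draw per-larva ordinal melanization classes.

    Returns a table with ``larva_id``, ``capillary``, ``species``,
    ``temperature`` and ``melanization_class`` in {0..5}.
    """
    rng = np.random.default_rng(spec.seed)
    cuts = np.asarray(spec.cumulative_logits, dtype=float)
    cap_effects = rng.normal(0.0, spec.capillary_sd, size=spec.n_capillaries)
    rows = []
    for ti, t in enumerate(TEMPERATURES):
        for j in range(spec.n_larvae_per_cell):
            cap = j % spec.n_capillaries
            latent = spec.temperature_effect * ti + cap_effects[cap]
            p_le = _expit(cuts - latent)  # P(class <= k), k = 0..4
            u = rng.uniform()
            klass = int(np.searchsorted(p_le, u, side="right"))
            rows.append(
                {
                    "larva_id": f"t{int(t)}_l{j + 1}",
                    "capillary": f"cap_{cap + 1}",
                    "species": spec.species,
                    "temperature": t,
                    "melanization_class": klass,
                }
            )
    return pd.DataFrame(rows)
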