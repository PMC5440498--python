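"""Gel-shift (EMSA) quantification: fraction bound, K_D titration fits,
and replicate comparison of competition series.

Band pixel intensities are the inputs -- image segmentation happens upstream
in gel software.  A lane's fraction bound is shifted/(shifted+free)*100; a
protein titration at fixed labeled-DNA concentration is fitted with the
solution binding isotherm including ligand depletion
(:func:`znfbind.binding.fraction_bound_depletion`), which matters because
the labeled DNA (3 nM) is not always negligible against K_D.

Competition series (band intensity relative to a no-competitor reference
lane across cold-DNA excess ratios) are compared with a stratified paired
bootstrap rather than a parametric trend model: resampling makes no
assumption about the variance structure across ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import lmfit
import numpy as np

from .binding import NM, fraction_bound_depletion

__all__ = [
    "LaneQuantification",
    "TitrationSeries",
    "TitrationModel",
    "TitrationFit",
    "CompetitionSeries",
    "CompetitionComparison",
    "fraction_bound_from_bands",
    "fit_titration",
    "relative_intensity",
    "compare_competition_series",
    "parse_condition",
]

#: fractions outside this band are kept in fits but flagged: affinity
#: differences are hard to resolve below 10% or above 90% complex formation
FLAG_BOUNDS = (10.0, 90.0)


@dataclass
class LaneQuantification:
    """Quantified intensities of one gel lane (complex and free-DNA bands)."""

    lane_id: str
    shifted_intensity: float
    free_intensity: float
    condition: str = ""

    def __post_init__(self) -> None:
        if self.shifted_intensity < 0 or self.free_intensity < 0:
            raise ValueError("band intensities must be >= 0")


def parse_condition(condition: str) -> dict[str, str]:
    """Parse 'key=value;key=value' condition metadata into a dict."""
    out: dict[str, str] = {}
    for part in condition.split(";"):
        part = part.strip()
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def fraction_bound_from_bands(lane: LaneQuantification) -> float:
    """Percent bound: shifted / (shifted + free) * 100."""
    total = lane.shifted_intensity + lane.free_intensity
    if total <= 0:
        raise ValueError(f"lane {lane.lane_id!r}: both band intensities are zero")
    return 100.0 * lane.shifted_intensity / total


@dataclass
class TitrationSeries:
    """Equilibrium fraction-bound observations over a protein ladder.

    concentrations are molar; ``fractions[i]`` holds the replicate
    fraction-bound percentages observed at ``concentrations[i]``.
    """

    L_total: float
    concentrations: np.ndarray
    fractions: list[np.ndarray]

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.fractions = [np.atleast_1d(np.asarray(f, float)) for f in self.fractions]
        if not self.L_total > 0:
            raise ValueError("L_total must be > 0")
        if len(self.fractions) != self.concentrations.size:
            raise ValueError("one replicate set per concentration required")
        for f in self.fractions:
            if np.any(f < 0) or np.any(f > 100):
                raise ValueError("fractions must lie in [0, 100]")

    @property
    def mean_fractions(self) -> np.ndarray:
        return np.array([float(np.mean(f)) for f in self.fractions])

    @property
    def sd_fractions(self) -> np.ndarray:
        return np.array(
            [float(np.std(f, ddof=1)) if f.size > 1 else 0.0 for f in self.fractions]
        )


@dataclass
class TitrationFit:
    """Equilibrium K_D estimate from a titration series."""

    K_D: float
    dK_D: float
    fitted_curve: np.ndarray
    residual_rms: float
    converged: bool
    flagged_points: list[int] = field(default_factory=list)

    @property
    def K_D_nM(self) -> float:
        return self.K_D / NM

    def summary(self) -> str:
        return (
            f"Titration isotherm fit\n"
            f"  K_D = {self.K_D_nM:.4g} +/- {self.dK_D / NM:.2g} nM\n"
            f"  residual RMS: {self.residual_rms:.3g} percentage points\n"
            f"  flagged (<{FLAG_BOUNDS[0]}% or >{FLAG_BOUNDS[1]}% bound): "
            f"{len(self.flagged_points)} of {self.fitted_curve.size} points\n"
            f"  converged: {self.converged}"
        )


class TitrationModel:
    """Fit the depletion isotherm to mean replicate fractions.

    The model is fraction_bound_depletion(R_i, L_total, K_D) with K_D the
    single free parameter; the fit is unweighted least squares on the mean
    fraction per concentration (replicate standard deviations are carried
    for reporting).  Pass ``weighted=True`` to weight points by 1/SD^2
    (points with zero SD get the median weight).
    """

    def __init__(self, series: TitrationSeries, weighted: bool = False) -> None:
        if np.unique(series.concentrations).size < 4:
            raise ValueError("titration fit needs >= 4 distinct concentrations")
        c = series.concentrations
        if c.max() / max(c.min(), 1e-30) < 10:
            raise ValueError("concentrations must span at least one decade")
        means = np.array([np.mean(f) for f in series.fractions])
        if np.all(means < 1e-9) or np.all(means > 100 - 1e-9):
            raise ValueError(
                "all-zero or all-saturated fractions: K_D is not identifiable"
            )
        self.series = series
        self.weighted = weighted

    def _predict(self, K_D: float) -> np.ndarray:
        s = self.series
        return np.array(
            [
                fraction_bound_depletion(R, s.L_total, K_D).fraction_bound
                for R in s.concentrations
            ]
        )

    def fit(self) -> TitrationFit:
        s = self.series
        y = s.mean_fractions
        # starting point: concentration at the 50% crossing of the mean curve
        K0 = self._crossing_guess(y)
        weights = None
        if self.weighted:
            sd = s.sd_fractions
            w = np.where(sd > 0, 1.0 / np.maximum(sd, 1e-12) ** 2, np.nan)
            w = np.where(np.isnan(w), np.nanmedian(w) if np.any(~np.isnan(w)) else 1.0, w)
            weights = np.sqrt(w)

        params = lmfit.Parameters()
        params.add("log10_KD", value=np.log10(K0), min=-16, max=-1)

        def residual(p):
            r = self._predict(10.0 ** p["log10_KD"].value) - y
            return r * weights if weights is not None else r

        out = lmfit.minimize(residual, params, method="leastsq", xtol=1e-13, ftol=1e-13)
        log_kd = out.params["log10_KD"]
        K_D = 10.0**log_kd.value
        # delta method on the log10 parameterization
        dK_D = K_D * np.log(10.0) * (log_kd.stderr or 0.0)
        fitted = self._predict(K_D)
        flagged = [
            i
            for i, f in enumerate(y)
            if f < FLAG_BOUNDS[0] or f > FLAG_BOUNDS[1]
        ]
        return TitrationFit(
            K_D=float(K_D),
            dK_D=float(dK_D),
            fitted_curve=fitted,
            residual_rms=float(np.sqrt(np.mean((fitted - y) ** 2))),
            converged=bool(out.success),
            flagged_points=flagged,
        )

    def _crossing_guess(self, y: np.ndarray) -> float:
        c = self.series.concentrations
        order = np.argsort(c)
        cs, ys = c[order], y[order]
        above = np.nonzero(ys >= 50.0)[0]
        if above.size and above[0] > 0:
            i = above[0]
            # log-linear interpolation between the bracketing points
            f = (50.0 - ys[i - 1]) / (ys[i] - ys[i - 1])
            return float(10 ** (np.log10(cs[i - 1]) + f * np.log10(cs[i] / cs[i - 1])))
        return float(np.sqrt(cs[0] * cs[-1]))


def fit_titration(series: TitrationSeries, weighted: bool = False) -> TitrationFit:
    """Least-squares K_D from a titration series (see :class:`TitrationModel`)."""
    return TitrationModel(series, weighted=weighted).fit()


@dataclass
class CompetitionSeries:
    """Shifted-band intensity relative to a no-competitor reference lane.

    ``relative_intensities[i]`` holds replicate percentages at cold:hot
    excess ``ratios[i]``; the reference lane defines 100%.
    """

    competitor_label: str
    ratios: np.ndarray
    relative_intensities: list[np.ndarray]

    def __post_init__(self) -> None:
        self.ratios = np.asarray(self.ratios, dtype=float)
        self.relative_intensities = [
            np.atleast_1d(np.asarray(v, float)) for v in self.relative_intensities
        ]
        if len(self.relative_intensities) != self.ratios.size:
            raise ValueError("one replicate set per ratio required")
        for v in self.relative_intensities:
            if np.any(v < 0):
                raise ValueError("relative intensities must be >= 0")


def relative_intensity(
    lanes: Sequence[LaneQuantification],
    reference_lane_id: str,
    label: str = "",
) -> CompetitionSeries:
    """Express shifted-band intensities as percent of a reference lane.

    Lanes are grouped into the series by the ``ratio=<x>`` key of their
    condition metadata; lanes without a ratio key (e.g. the reference
    itself) are excluded from the grid but still define the 100% level.
    """
    ref = next((l for l in lanes if l.lane_id == reference_lane_id), None)
    if ref is None:
        raise ValueError(f"reference lane {reference_lane_id!r} not found")
    if ref.shifted_intensity <= 0:
        raise ValueError("reference lane has zero shifted intensity")
    by_ratio: dict[float, list[float]] = {}
    for lane in lanes:
        if lane.lane_id == reference_lane_id:
            continue
        meta = parse_condition(lane.condition)
        if "ratio" not in meta:
            continue
        r = float(meta["ratio"])
        by_ratio.setdefault(r, []).append(
            100.0 * lane.shifted_intensity / ref.shifted_intensity
        )
    ratios = sorted(by_ratio)
    return CompetitionSeries(
        competitor_label=label,
        ratios=np.array(ratios),
        relative_intensities=[np.array(by_ratio[r]) for r in ratios],
    )


@dataclass
class CompetitionComparison:
    """Bootstrap comparison of two competition series on a shared ratio grid."""

    ratios: np.ndarray
    mean_difference_per_ratio: np.ndarray
    mean_difference: float
    p_value: float
    n_boot: int
    seed: int | None

    def summary(self) -> str:
        per = ", ".join(
            f"{r:g}x: {d:+.1f}" for r, d in zip(self.ratios, self.mean_difference_per_ratio)
        )
        return (
            f"Competition-series comparison ({self.n_boot} bootstrap draws)\n"
            f"  per-ratio mean difference [pct pts]: {per}\n"
            f"  overall mean difference: {self.mean_difference:+.2f}\n"
            f"  two-sided p-value: {self.p_value:.4g}"
        )


def compare_competition_series(
    a: CompetitionSeries,
    b: CompetitionSeries,
    n_boot: int = 10_000,
    seed: int | None = None,
) -> CompetitionComparison:
    """Stratified bootstrap test for a difference between two series.

    The statistic is the mean over ratios of (mean_a - mean_b).  The null
    distribution is built by pooling replicates within each ratio, then
    resampling two groups of the original sizes with replacement from the
    pool; the two-sided p-value is the fraction of resampled statistics at
    least as extreme as the observed one (with the usual +1 correction).
    Deterministic for a fixed seed.
    """
    if a.ratios.size == 0 or not np.array_equal(a.ratios, b.ratios):
        raise ValueError("series must share an identical, non-empty ratio grid")
    rng = np.random.default_rng(seed)
    diffs = np.array(
        [
            float(np.mean(va) - np.mean(vb))
            for va, vb in zip(a.relative_intensities, b.relative_intensities)
        ]
    )
    observed = float(np.mean(diffs))

    null_stats = np.zeros(n_boot)
    for va, vb in zip(a.relative_intensities, b.relative_intensities):
        pool = np.concatenate([va, vb])
        ra = pool[rng.integers(0, pool.size, size=(n_boot, va.size))]
        rb = pool[rng.integers(0, pool.size, size=(n_boot, vb.size))]
        null_stats += ra.mean(axis=1) - rb.mean(axis=1)
    null_stats /= a.ratios.size
    p = (1.0 + np.count_nonzero(np.abs(null_stats) >= abs(observed))) / (n_boot + 1.0)
    return CompetitionComparison(
        ratios=a.ratios.copy(),
        mean_difference_per_ratio=diffs,
        mean_difference=observed,
        p_value=float(min(p, 1.0)),
        n_boot=n_boot,
        seed=seed,
    )
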