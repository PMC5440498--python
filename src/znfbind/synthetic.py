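"""Seeded generators emulating the experimental designs.

Every analysis stage in the package can be exercised without instrument or
gel data: these generators produce biosensor traces, titration tables,
competition gel lanes and DNA sequences from known ground-truth parameters,
so that generator + analysis form an identity at zero noise and a measurable
recovery problem at realistic noise.

Design defaults mirror the study conditions: a 78-1250 nM protein ladder
with a 2 h association phase, a single ~15 h dissociation phase measured in
triplicate on three sensor spots, titrations of 0.16-4300 nM protein against
3 nM labeled DNA in triplicate, and hot/cold competition at various excess
ratios.  Noise is additive Gaussian on the normalized response or
fraction-bound scale; spot-to-spot amplitude variation is log-normal.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .binding import NM, RateConstants, fraction_bound_depletion
from .competition import CompetitionModel, Ligand
from .emsa import CompetitionSeries, LaneQuantification, TitrationSeries, relative_intensity
from .tracefit import SwitchTrace

__all__ = [
    "TraceDesign",
    "TitrationDesign",
    "GelCompetitionDesign",
    "SimulatedTitration",
    "simulate_switchsense",
    "simulate_titration",
    "simulate_competition_gel",
    "make_sequences",
    "make_target_site",
]


@dataclass
class TraceDesign:
    """Sampling design of a biosensor kinetics run.

    Concentrations in nanomolar, durations and intervals in seconds,
    noise_sd in normalized-response percentage points, amplitude_cv the
    coefficient of variation of the log-normal spot amplitude factor.
    """

    concentrations_nM: tuple[float, ...] = (78.0, 156.0, 312.0, 625.0, 1250.0)
    association_duration: float = 7200.0
    dissociation_duration: float = 54000.0
    association_interval: float = 60.0
    dissociation_interval: float = 60.0
    spots: int = 3
    dissociation_concentration_nM: float = 625.0
    max_drop: float = 40.0
    noise_sd: float = 1.5
    amplitude_cv: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.association_duration <= 0 or self.dissociation_duration <= 0:
            raise ValueError("durations must be > 0")
        if self.noise_sd < 0 or self.amplitude_cv < 0:
            raise ValueError("noise_sd and amplitude_cv must be >= 0")


def _grid(duration: float, interval: float) -> np.ndarray:
    n = int(round(duration / interval))
    return np.linspace(0.0, n * interval, n + 1)


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    if cv == 0:
        return 1.0
    sigma = np.sqrt(np.log(1.0 + cv**2))
    return float(rng.lognormal(mean=-(sigma**2) / 2.0, sigma=sigma))


def simulate_switchsense(
    rates: RateConstants, design: TraceDesign | None = None
) -> list[SwitchTrace]:
    """Generate normalized association/dissociation traces.

    Association at concentration c starts at 100% and decays with rate
    ``c*k_on + k_off`` toward a plateau set by the equilibrium sensor
    occupancy c/(c + K_D) times the saturating response drop; dissociation
    (measured at one concentration on each sensor spot) recovers from that
    plateau toward 100% with rate k_off.  Additive i.i.d. Gaussian noise.
    """
    design = design or TraceDesign()
    rng = np.random.default_rng(design.seed)
    K_D = rates.K_D
    traces: list[SwitchTrace] = []

    t_assoc = _grid(design.association_duration, design.association_interval)
    for c_nM in design.concentrations_nM:
        c = c_nM * NM
        occupancy = 1.0 if (c + K_D) == 0 else c / (c + K_D)
        drop = design.max_drop * occupancy * _lognormal_factor(rng, design.amplitude_cv)
        k_obs = c * rates.k_on + rates.k_off
        y = (100.0 - drop) + drop * np.exp(-t_assoc * k_obs)
        if design.noise_sd > 0:
            y = y + rng.normal(0.0, design.noise_sd, size=y.size)
        traces.append(
            SwitchTrace(
                times=t_assoc,
                responses=y,
                concentration=c,
                spot_id="1",
                phase="association",
                experiment_id="sim",
            )
        )

    t_diss = _grid(design.dissociation_duration, design.dissociation_interval)
    c_diss = design.dissociation_concentration_nM * NM
    occupancy = 1.0 if (c_diss + K_D) == 0 else c_diss / (c_diss + K_D)
    base_drop = design.max_drop * occupancy
    for spot in range(1, design.spots + 1):
        drop = base_drop * _lognormal_factor(rng, design.amplitude_cv)
        if rates.k_off > 0:
            y = 100.0 - drop * np.exp(-t_diss * rates.k_off)
        else:
            y = np.full_like(t_diss, 100.0 - drop)
        if design.noise_sd > 0:
            y = y + rng.normal(0.0, design.noise_sd, size=y.size)
        traces.append(
            SwitchTrace(
                times=t_diss,
                responses=y,
                concentration=c_diss,
                spot_id=str(spot),
                phase="dissociation",
                experiment_id="sim",
            )
        )
    return traces


@dataclass
class TitrationDesign:
    """Protein ladder design of an equilibrium titration."""

    c_min_nM: float = 0.16
    c_max_nM: float = 4300.0
    n_points: int = 14
    L_total_nM: float = 3.0
    replicates: int = 3
    noise_sd: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_points < 2 or self.replicates < 1:
            raise ValueError("need >= 2 points and >= 1 replicate")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def concentrations(self) -> np.ndarray:
        return np.logspace(
            np.log10(self.c_min_nM), np.log10(self.c_max_nM), self.n_points
        ) * NM


@dataclass
class SimulatedTitration:
    """A titration series plus per-replicate clipping flags (replicates whose
    noisy fraction fell outside [0, 100] and was clipped)."""

    series: TitrationSeries
    clipped: list[np.ndarray]


def simulate_titration(
    K_D_true: float, design: TitrationDesign | None = None
) -> SimulatedTitration:
    """Generate replicate fraction-bound observations from the depletion
    isotherm at a known K_D (molar)."""
    design = design or TitrationDesign()
    rng = np.random.default_rng(design.seed)
    L = design.L_total_nM * NM
    concs = design.concentrations
    fractions, clipped = [], []
    for R in concs:
        truth = fraction_bound_depletion(R, L, K_D_true).fraction_bound
        reps = np.full(design.replicates, truth)
        if design.noise_sd > 0:
            reps = reps + rng.normal(0.0, design.noise_sd, size=reps.size)
        clip = (reps < 0) | (reps > 100)
        fractions.append(np.clip(reps, 0.0, 100.0))
        clipped.append(clip)
    return SimulatedTitration(
        series=TitrationSeries(L_total=L, concentrations=concs, fractions=fractions),
        clipped=clipped,
    )


@dataclass
class GelCompetitionDesign:
    """Simultaneous hot/cold competition read out as gel lanes.

    The hot (labeled) DNA is held at ``hot_total_nM`` while the cold
    competitor is dosed at ``ratio x hot_total`` for each ratio; bands are
    synthesized from the simulated visible-complex fraction at the assay
    endpoint.  noise_sd is in percent of the lane's total intensity.
    """

    protein_total_nM: float = 250.0
    hot_total_nM: float = 10.0
    ratios: tuple[float, ...] = (1.0, 10.0, 100.0)
    incubation: float = 3600.0
    replicates: int = 3
    intensity_scale: float = 1000.0
    noise_sd: float = 3.0
    cold_scale: float = 1.0
    competitor_label: str = "cold"
    seed: int = 0


def simulate_competition_gel(
    hot_rates: RateConstants,
    cold_rates: RateConstants,
    design: GelCompetitionDesign | None = None,
) -> tuple[list[LaneQuantification], CompetitionSeries]:
    """Simulate a competition EMSA and quantify it into lanes + series.

    Returns the lane table (including the no-competitor reference lane)
    and the relative-intensity series derived from it.
    """
    design = design or GelCompetitionDesign()
    rng = np.random.default_rng(design.seed)
    P = design.protein_total_nM * NM
    hot_total = design.hot_total_nM * NM

    def endpoint_fraction(cold_total: float) -> float:
        ligands = [Ligand("hot", hot_total, hot_rates, labeled=True)]
        if cold_total > 0:
            ligands.append(Ligand("cold", cold_total, cold_rates, labeled=False))
        traj = CompetitionModel(P, ligands).simulate(
            horizon=design.incubation, n_samples=50
        )
        return float(traj.visible_fraction[-1])

    lanes: list[LaneQuantification] = []
    scale = design.intensity_scale
    sd = design.noise_sd / 100.0 * scale

    def bands(fraction: float) -> tuple[float, float]:
        shifted = scale * fraction / 100.0
        free = scale * (1.0 - fraction / 100.0)
        if sd > 0:
            shifted += rng.normal(0.0, sd)
            free += rng.normal(0.0, sd)
        return max(shifted, 0.0), max(free, 0.0)

    f_ref = endpoint_fraction(0.0)
    shifted, free = bands(f_ref)
    lanes.append(LaneQuantification("ref", shifted, free, condition="reference"))
    for ratio in design.ratios:
        f = endpoint_fraction(ratio * hot_total * design.cold_scale)
        for rep in range(1, design.replicates + 1):
            shifted, free = bands(f)
            lanes.append(
                LaneQuantification(
                    f"r{ratio:g}_rep{rep}",
                    shifted,
                    free,
                    condition=f"ratio={ratio:g};rep={rep}",
                )
            )
    series = relative_intensity(lanes, "ref", label=design.competitor_label)
    return lanes, series


_BASES = np.array(list("ACGT"))


def _random_seq(
    rng: np.random.Generator,
    length: int,
    gc_bounds: tuple[float, float],
    max_attempts: int,
) -> str:
    for _ in range(max_attempts):
        seq = "".join(rng.choice(_BASES, size=length))
        gc = (seq.count("G") + seq.count("C")) / length
        if gc_bounds[0] <= gc <= gc_bounds[1]:
            return seq
    raise RuntimeError(f"could not sample a {length}-nt sequence in GC bounds")


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def make_sequences(
    site_length: int = 31,
    flank_length: int = 22,
    donor_length: int = 75,
    gc_bounds: tuple[float, float] = (0.35, 0.65),
    k: int = 8,
    seed: int = 0,
    max_attempts: int = 2000,
) -> dict[str, str]:
    """Sample a synthetic target site, flanks and an unspecific donor.

    The donor is rejection-sampled until it shares no k-mer of length >= k
    with the site, guaranteeing the "unspecific" donor carries no accidental
    copy of the specific site.  All sequences respect the GC bounds.
    Deterministic for a fixed seed.
    """
    if k < 6:
        raise ValueError("k must be >= 6")
    if site_length < k or donor_length < k:
        raise ValueError("sequences must be at least k long")
    rng = np.random.default_rng(seed)
    site = _random_seq(rng, site_length, gc_bounds, max_attempts)
    flank5 = _random_seq(rng, flank_length, gc_bounds, max_attempts) if flank_length else ""
    flank3 = _random_seq(rng, flank_length, gc_bounds, max_attempts) if flank_length else ""
    site_kmers = _kmers(site, k)
    for _ in range(max_attempts):
        donor = _random_seq(rng, donor_length, gc_bounds, max_attempts)
        if not (_kmers(donor, k) & site_kmers):
            return {"site": site, "flank5": flank5, "flank3": flank3, "donor": donor}
    raise RuntimeError("could not sample a donor sharing no k-mer with the site")


def make_target_site(seed: int = 0, **kwargs):
    """Convenience: a seeded synthetic (TargetSite, donor) pair.

    The sequences are synthetic stand-ins with the study's geometry (31-nt
    site centered in a 75-bp duplex), not the real hotspot sequence.
    """
    from .znf import TargetSite

    recs = make_sequences(seed=seed, **kwargs)
    return (
        TargetSite(recs["site"], flank5=recs["flank5"], flank3=recs["flank3"]),
        recs["donor"],
    )
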