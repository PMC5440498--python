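"""Mechanistic simulation of hot/cold DNA competition for one protein pool.

Models the mass-action network

    P + D_i  <-- k_on,i / k_off,i -->  PD_i      (i = one species per ligand)

where only *labeled* (biotinylated, "hot") ligands are visible on a gel.
Dosing schedules express the two experimental protocols used to probe
complex stability: simultaneous addition of hot and cold DNA, or
pre-incubation of the protein with hot DNA followed by a late cold chase.
With dissociation halftimes of many hours, a pre-formed hot complex barely
exchanges with the cold competitor over an overnight incubation -- the
simulation makes that argument quantitative.

State is parameterized by the complex concentrations only; free protein and
free DNA follow from conservation, so mass balance holds exactly between
dosing events by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .binding import NM, RateConstants, fraction_bound_depletion

__all__ = [
    "Ligand",
    "DoseEvent",
    "DosingSchedule",
    "CompetitionState",
    "CompetitionModel",
    "CompetitionTrajectory",
    "simulate_competition",
    "equilibrium_occupancy",
]


@dataclass
class Ligand:
    """One DNA species competing for the protein: name, total concentration
    (molar), rate constants, and whether it is visible in the readout."""

    name: str
    total: float
    rates: RateConstants
    labeled: bool = False

    def __post_init__(self) -> None:
        if self.total < 0:
            raise ValueError("ligand total must be >= 0")


@dataclass
class DoseEvent:
    """Instantaneous addition at ``time`` (s): extra protein and/or extra
    ligand totals (molar, keyed by ligand name).  No volume change."""

    time: float
    protein: float = 0.0
    ligands: dict[str, float] = field(default_factory=dict)


@dataclass
class DosingSchedule:
    events: list[DoseEvent]
    horizon: float

    def __post_init__(self) -> None:
        if not self.events or self.events[0].time != 0.0:
            raise ValueError("first dosing event must be at t=0")
        times = [e.time for e in self.events]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("event times must be non-decreasing")
        if self.horizon < times[-1]:
            raise ValueError("horizon must reach the last event")


@dataclass
class CompetitionState:
    """Snapshot of the mixture: free protein, free DNA and complexes (molar)."""

    time: float
    P_free: float
    D_free: dict[str, float]
    PD: dict[str, float]


@dataclass
class CompetitionTrajectory:
    """Sampled states plus the gel-visible observable.

    ``visible_fraction`` is the labeled complex summed over labeled ligands,
    as a percentage of the labeled total -- what an EMSA shifted band
    reports.
    """

    times: np.ndarray
    P_free: np.ndarray
    D_free: dict[str, np.ndarray]
    PD: dict[str, np.ndarray]
    labeled_total: float
    solver_ok: bool

    @property
    def visible_fraction(self) -> np.ndarray:
        if self.labeled_total <= 0:
            return np.zeros_like(self.times)
        bound = np.zeros_like(self.times)
        for name in self.PD:
            if self._labeled.get(name, False):
                bound = bound + self.PD[name]
            # note: unlabeled complexes exist but are invisible
        return 100.0 * bound / self.labeled_total

    _labeled: dict[str, bool] = field(default_factory=dict)

    def state_at(self, index: int) -> CompetitionState:
        return CompetitionState(
            time=float(self.times[index]),
            P_free=float(self.P_free[index]),
            D_free={k: float(v[index]) for k, v in self.D_free.items()},
            PD={k: float(v[index]) for k, v in self.PD.items()},
        )

    @property
    def final_state(self) -> CompetitionState:
        return self.state_at(-1)


class CompetitionModel:
    """ODE model of ligands competing for a shared protein pool.

    d[PD_i]/dt = k_on,i * P_free * D_i - k_off,i * PD_i with
    P_free = P_total - sum(PD) and D_i = L_i - PD_i.  Dosing events
    re-initialize the totals with the complex concentrations carried over
    (instantaneous mixing, no dilution).
    """

    def __init__(
        self,
        protein_total: float,
        ligands: Sequence[Ligand],
        schedule: DosingSchedule | None = None,
    ) -> None:
        if protein_total < 0:
            raise ValueError("protein_total must be >= 0")
        if len(ligands) == 0:
            raise ValueError("need at least one ligand")
        names = [l.name for l in ligands]
        if len(set(names)) != len(names):
            raise ValueError("ligand names must be unique")
        self.protein_total = protein_total
        self.ligands = list(ligands)
        self.schedule = schedule

    def simulate(
        self,
        horizon: float | None = None,
        n_samples: int = 400,
        rtol: float = 1e-9,
        atol_scale: float = 1e-15,
        method: str = "LSODA",
    ) -> CompetitionTrajectory:
        """Integrate the network over the schedule (or a plain horizon)."""
        schedule = self.schedule
        if schedule is None:
            if horizon is None:
                raise ValueError("need a schedule or an explicit horizon")
            schedule = DosingSchedule(
                events=[
                    DoseEvent(
                        0.0,
                        protein=self.protein_total,
                        ligands={l.name: l.total for l in self.ligands},
                    )
                ],
                horizon=horizon,
            )
        names = [l.name for l in self.ligands]
        k_on = np.array([l.rates.k_on for l in self.ligands])
        k_off = np.array([l.rates.k_off for l in self.ligands])

        # running totals, updated at each dosing event
        P_tot = 0.0
        L_tot = np.zeros(len(names))
        PD = np.zeros(len(names))

        # segment boundaries: event times + horizon
        boundaries = sorted({e.time for e in schedule.events} | {schedule.horizon})
        sample_times = np.linspace(0.0, schedule.horizon, n_samples)

        all_t: list[np.ndarray] = []
        all_pd: list[np.ndarray] = []
        tot_trace: list[tuple[float, float, np.ndarray]] = []  # (t_start, P_tot, L_tot)
        ok = True
        for seg_i, t0 in enumerate(boundaries):
            for ev in schedule.events:
                if ev.time == t0:
                    P_tot += ev.protein
                    for nm_, amt in ev.ligands.items():
                        if nm_ not in names:
                            raise ValueError(f"unknown ligand in schedule: {nm_!r}")
                        L_tot[names.index(nm_)] += amt
            if seg_i + 1 >= len(boundaries):
                tot_trace.append((t0, P_tot, L_tot.copy()))
                break
            t1 = boundaries[seg_i + 1]
            tot_trace.append((t0, P_tot, L_tot.copy()))

            def rhs(t, y, P_tot=P_tot, L_tot=L_tot.copy()):
                y = np.clip(y, 0.0, None)
                P = max(P_tot - y.sum(), 0.0)
                D = np.maximum(L_tot - y, 0.0)
                return k_on * P * D - k_off * y

            seg_samples = sample_times[(sample_times >= t0) & (sample_times <= t1)]
            t_eval = np.unique(np.concatenate([[t0], seg_samples, [t1]]))
            scale = max(P_tot, L_tot.max(), 1e-12)
            sol = solve_ivp(
                rhs,
                (t0, t1),
                PD,
                method=method,
                t_eval=t_eval,
                rtol=rtol,
                atol=atol_scale * scale,
            )
            ok = ok and sol.success
            if not sol.success:
                break
            tol = 1e-6 * scale
            if np.any(sol.y < -tol):
                raise ArithmeticError("integrator produced negative concentrations")
            all_t.append(sol.t)
            all_pd.append(np.clip(sol.y, 0.0, None))
            PD = np.clip(sol.y[:, -1], 0.0, None)

        t = np.concatenate(all_t) if all_t else np.array([0.0])
        pd = (
            np.concatenate(all_pd, axis=1)
            if all_pd
            else np.zeros((len(names), 1))
        )
        # totals applicable at each sampled time (step function over segments)
        P_tot_arr = np.empty_like(t)
        L_tot_arr = np.empty((len(names), t.size))
        for t_start, p, l in tot_trace:
            mask = t >= t_start
            P_tot_arr[mask] = p
            L_tot_arr[:, mask] = l[:, None]
        P_free = np.maximum(P_tot_arr - pd.sum(axis=0), 0.0)
        D_free = {n: np.maximum(L_tot_arr[i] - pd[i], 0.0) for i, n in enumerate(names)}
        labeled_total = float(
            sum(L_tot[i] for i, l in enumerate(self.ligands) if l.labeled)
        )
        traj = CompetitionTrajectory(
            times=t,
            P_free=P_free,
            D_free=D_free,
            PD={n: pd[i] for i, n in enumerate(names)},
            labeled_total=labeled_total,
            solver_ok=ok,
        )
        traj._labeled = {l.name: l.labeled for l in self.ligands}
        return traj


def simulate_competition(
    protein_total: float,
    ligands: Sequence[Ligand],
    schedule: DosingSchedule,
    **solver_options,
) -> CompetitionTrajectory:
    """Functional entry point over :class:`CompetitionModel`."""
    return CompetitionModel(protein_total, ligands, schedule).simulate(**solver_options)


def equilibrium_occupancy(
    protein_total: float,
    ligands: Sequence[Ligand],
    tol: float = 1e-12,
) -> dict[str, float]:
    """Coupled mass-action equilibrium: bound concentration per ligand.

    Solves P + sum_i P*L_i/(K_i + P) = P_total for the free protein P by
    root bracketing (the left side is strictly increasing in P), then
    PD_i = P*L_i/(K_i + P).  For a single ligand this reproduces the
    depletion isotherm exactly.
    """
    if len(ligands) == 0:
        raise ValueError("need at least one ligand")
    if protein_total < 0:
        raise ValueError("protein_total must be >= 0")
    K = np.array([l.rates.K_D for l in ligands])
    L = np.array([l.total for l in ligands])
    if protein_total == 0:
        return {l.name: 0.0 for l in ligands}
    # infinitely tight binders (K=0) are handled by a vanishing floor that
    # keeps the balance function continuous
    K = np.maximum(K, 1e-30)

    def balance(P: float) -> float:
        return P + float(np.sum(P * L / (K + P))) - protein_total

    if balance(protein_total) < -tol * protein_total:
        raise ArithmeticError("equilibrium balance has no bracket (internal error)")
    P = brentq(balance, 0.0, protein_total, xtol=1e-30, rtol=8.9e-16, maxiter=500)
    PD = P * L / (K + P)
    return {l.name: float(pd) for l, pd in zip(ligands, PD)}
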