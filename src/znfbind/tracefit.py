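"""Biosensor trace normalization and global exponential rate fitting.

A switchable-nanolever biosensor reports protein-DNA complex formation as a
drop in normalized "dynamic response" versus time.  Association traces at a
ladder of protein concentrations decay with the pseudo-first-order rate
``k_obs = c*k_on + k_off``; the long dissociation trace decays with ``k_off``
alone.  Rate constants are therefore estimated by *global* exponential fits:
a single shared rate parameter across traces, with free per-trace offsets and
amplitudes absorbing spot-to-spot variation.

The module follows the model/results idiom: build a
:class:`DissociationModel` or :class:`AssociationModel` from a collection of
:class:`SwitchTrace` objects, call :meth:`fit`, and read rate constants,
standard errors and diagnostics off the returned :class:`GlobalFitResult`.
The ``fit_dissociation`` / ``fit_association_global`` functions are thin
conveniences over those classes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import lmfit
import numpy as np

from .binding import NM, ExponentialCurve, KineticSummary, RateConstants

__all__ = [
    "SwitchTrace",
    "GlobalFitResult",
    "DissociationModel",
    "AssociationModel",
    "normalize_traces",
    "fit_dissociation",
    "fit_association_global",
    "summarize_kinetics",
]

Phase = Literal["association", "dissociation"]

# parameter bounds for the optimizer (rates in s^-1, tau in s)
K_ON_MAX = 1e9
K_OFF_MAX = 1.0
TAU_MAX = 1e9


@dataclass
class SwitchTrace:
    """One phase of a normalized dynamic-response measurement.

    times are in seconds (strictly increasing), responses in percent of the
    association start level, concentration in molar (the protein
    concentration during the association step; dissociation traces keep the
    concentration of the step they followed for bookkeeping).
    """

    times: np.ndarray
    responses: np.ndarray
    concentration: float
    spot_id: str = "1"
    phase: Phase = "association"
    experiment_id: str = "exp"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.times.size == 0:
            raise ValueError("trace has no samples")
        if self.times.shape != self.responses.shape:
            raise ValueError("times and responses must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if self.phase == "association" and not self.concentration > 0:
            raise ValueError("association traces need concentration > 0")

    @property
    def concentration_nM(self) -> float:
        return self.concentration / NM


def normalize_traces(
    traces: Sequence[SwitchTrace], window: int = 3
) -> list[SwitchTrace]:
    """Scale traces so each association trace starts at 100%.

    The scale factor is 100 over the mean of the first ``window`` samples of
    the association trace; the same factor is applied to the paired
    dissociation trace (matched by experiment, spot and, where possible,
    concentration) so both phases stay on one scale.  A dissociation trace
    with no association partner is scaled to its own start window.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    scales: dict[tuple, float] = {}
    for tr in traces:
        if tr.phase != "association":
            continue
        if tr.responses.size < 3:
            raise ValueError("association trace needs >= 3 samples")
        start = float(np.mean(tr.responses[:window]))
        if start == 0:
            raise ValueError(
                f"association start of trace {tr.experiment_id}/{tr.spot_id} is zero"
            )
        scales[(tr.experiment_id, tr.spot_id, tr.concentration)] = 100.0 / start
        scales.setdefault((tr.experiment_id, tr.spot_id), 100.0 / start)

    out = []
    for tr in traces:
        if tr.phase == "association":
            s = scales[(tr.experiment_id, tr.spot_id, tr.concentration)]
        else:
            s = scales.get((tr.experiment_id, tr.spot_id, tr.concentration))
            if s is None:
                s = scales.get((tr.experiment_id, tr.spot_id))
            if s is None:
                start = float(np.mean(tr.responses[:window]))
                if start == 0:
                    raise ValueError("cannot normalize all-zero dissociation trace")
                s = 100.0 / start
        out.append(
            SwitchTrace(
                times=tr.times.copy(),
                responses=tr.responses * s,
                concentration=tr.concentration,
                spot_id=tr.spot_id,
                phase=tr.phase,
                experiment_id=tr.experiment_id,
            )
        )
    return out


@dataclass
class GlobalFitResult:
    """Result of a single- or multi-trace exponential fit.

    Rate fields are None when the corresponding constant was not part of the
    model (a dissociation fit estimates no k_on).  ``rates`` assembles a
    :class:`~znfbind.binding.RateConstants` once both constants are known.
    """

    k_on: float | None
    dk_on: float | None
    k_off: float | None
    dk_off: float | None
    per_trace_curves: list[ExponentialCurve]
    covariance: np.ndarray | None
    residual_rms: float
    converged: bool
    n_iter: int
    mode: str = "global"
    k_off_values: list[float] = field(default_factory=list)

    @property
    def rates(self) -> RateConstants:
        if self.k_on is None or self.k_off is None:
            raise ValueError(
                "both k_on and k_off are needed; combine association and "
                "dissociation fits with summarize_kinetics()"
            )
        return RateConstants(
            k_on=self.k_on,
            k_off=self.k_off,
            dk_on=self.dk_on or 0.0,
            dk_off=self.dk_off or 0.0,
        )

    def summary(self) -> str:
        lines = [f"Global exponential fit ({self.mode} mode)"]
        if self.k_on is not None:
            lines.append(f"  k_on  = {self.k_on:.6g} +/- {self.dk_on or 0:.3g} M^-1 s^-1")
        if self.k_off is not None:
            lines.append(f"  k_off = {self.k_off:.6g} +/- {self.dk_off or 0:.3g} s^-1")
        lines.append(f"  traces: {len(self.per_trace_curves)}")
        lines.append(f"  residual RMS: {self.residual_rms:.4g} %")
        lines.append(f"  converged: {self.converged} ({self.n_iter} evaluations)")
        return "\n".join(lines)


def _exp_guess(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Deterministic (y0, A, rate) starting point for y = y0 + A exp(-rate t').

    Successive differences of a single exponential decay log-linearly in
    time regardless of the offset y0, which gives a derivative-free rate
    estimate; amplitude and offset then follow from the end points.
    """
    span = t[-1] - t[0]
    idx = np.unique(np.linspace(0, t.size - 1, min(t.size, 15)).astype(int))
    ts, ys = t[idx], y[idx]
    d = np.diff(ys)
    rate = None
    keep = np.abs(d) > 0
    if keep.sum() >= 2 and (np.all(d[keep] > 0) or np.all(d[keep] < 0)):
        slope = np.polyfit(ts[:-1][keep], np.log(np.abs(d[keep])), 1)[0]
        if slope < 0:
            rate = -float(slope)
    if rate is None or not np.isfinite(rate) or rate <= 0:
        rate = math.log(2.0) / (span / 2.0)
    decay = 1.0 - math.exp(-rate * span)
    A = (y[0] - y[-1]) / decay if decay > 1e-12 else y[0] - y[-1]
    y0 = y[0] - A
    return float(y0), float(A), float(rate)


def _fallback_guess(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    span = t[-1] - t[0]
    return float(y[-1]), float(y[0] - y[-1]), math.log(2.0) / (span / 2.0)


def _rms(residual: np.ndarray) -> float:
    return float(np.sqrt(np.mean(residual**2)))


class DissociationModel:
    """Exponential model for dissociation traces, ``k_off = 1/tau``.

    mode="global" shares one time constant across all traces (with free
    per-trace offset and amplitude, matching a triplicate spot measurement);
    mode="individual" fits each trace separately and reports the mean and
    across-trace standard deviation of k_off.
    """

    def __init__(
        self,
        traces: Sequence[SwitchTrace],
        mode: Literal["global", "individual"] = "global",
        fit_x0: bool = False,
    ) -> None:
        if len(traces) == 0:
            raise ValueError("need at least one trace")
        for tr in traces:
            if tr.phase != "dissociation":
                raise ValueError("DissociationModel accepts dissociation traces only")
            if tr.times.size < 4:
                raise ValueError("each trace needs at least 4 samples")
        self.traces = list(traces)
        self.mode = mode
        self.fit_x0 = fit_x0

    def fit(self) -> GlobalFitResult:
        if self.mode == "individual":
            return self._fit_individual()
        return self._fit_global()

    # -- internals ---------------------------------------------------------

    def _fit_global(self) -> GlobalFitResult:
        traces = self.traces
        guesses = [_exp_guess(tr.times, tr.responses) for tr in traces]
        tau0_candidates = []
        # design choice: seed tau from the longest trace's rate estimate
        longest = max(range(len(traces)), key=lambda i: traces[i].times[-1])
        tau0_candidates.append(1.0 / guesses[longest][2])
        tau0_candidates.append((traces[longest].times[-1] - traces[longest].times[0]) / 2)

        best = None
        for tau0 in tau0_candidates:
            params = lmfit.Parameters()
            params.add("tau", value=min(max(tau0, 1e-6), TAU_MAX), min=1e-9, max=TAU_MAX)
            for i, (tr, (y0, A, _)) in enumerate(zip(traces, guesses)):
                params.add(f"y0_{i}", value=y0)
                params.add(f"A_{i}", value=A if A != 0 else 1.0)
                params.add(f"x0_{i}", value=float(tr.times[0]), vary=self.fit_x0)

            def residual(p):
                res = []
                tau = p["tau"].value
                for i, tr in enumerate(traces):
                    model = p[f"y0_{i}"].value + p[f"A_{i}"].value * np.exp(
                        -(tr.times - p[f"x0_{i}"].value) / tau
                    )
                    res.append(model - tr.responses)
                return np.concatenate(res)

            out = lmfit.minimize(residual, params, method="leastsq", xtol=1e-12, ftol=1e-12)
            rms = _rms(out.residual)
            if best is None or rms < best[1]:
                best = (out, rms)
        out, rms = best
        tau = out.params["tau"].value
        dtau = out.params["tau"].stderr or 0.0
        k_off = 1.0 / tau
        dk_off = dtau / tau**2
        curves = [
            ExponentialCurve(
                y0=out.params[f"y0_{i}"].value,
                A=out.params[f"A_{i}"].value,
                x0=out.params[f"x0_{i}"].value,
                tau=tau,
            )
            for i in range(len(traces))
        ]
        return GlobalFitResult(
            k_on=None,
            dk_on=None,
            k_off=k_off,
            dk_off=dk_off,
            per_trace_curves=curves,
            covariance=getattr(out, "covar", None),
            residual_rms=rms,
            converged=bool(out.success),
            n_iter=int(out.nfev),
            mode="global",
        )

    def _fit_individual(self) -> GlobalFitResult:
        k_offs, curves, resids, iters, ok = [], [], [], 0, True
        for tr in self.traces:
            sub = DissociationModel([tr], mode="global", fit_x0=self.fit_x0).fit()
            ok = ok and sub.converged
            iters += sub.n_iter
            k_offs.append(sub.k_off)
            curves.append(sub.per_trace_curves[0])
            resids.append(sub.residual_rms**2 * tr.times.size)
        k_off = float(np.mean(k_offs))
        dk_off = float(np.std(k_offs, ddof=1)) if len(k_offs) > 1 else 0.0
        n_total = sum(tr.times.size for tr in self.traces)
        return GlobalFitResult(
            k_on=None,
            dk_on=None,
            k_off=k_off,
            dk_off=dk_off,
            per_trace_curves=curves,
            covariance=None,
            residual_rms=float(np.sqrt(sum(resids) / n_total)),
            converged=ok,
            n_iter=iters,
            mode="individual",
            k_off_values=[float(k) for k in k_offs],
        )


class AssociationModel:
    """Global pseudo-first-order fit over an association concentration series.

    Each trace decays with rate ``c_i*k_on + k_off`` where ``k_on`` is shared
    across all traces; offsets and amplitudes are free per trace because the
    sensor is regenerated between concentration steps.  ``k_off`` is fixed to
    a supplied value by default (it is measured independently from the
    dissociation phase, being concentration independent); pass
    ``k_off=None`` with at least two distinct concentrations to float it.
    """

    def __init__(
        self,
        traces: Sequence[SwitchTrace],
        k_off: float | None = 0.0,
        fit_x0: bool = False,
    ) -> None:
        if len(traces) == 0:
            raise ValueError("need at least one trace")
        for tr in traces:
            if tr.phase != "association":
                raise ValueError("AssociationModel accepts association traces only")
            if tr.times.size < 4:
                raise ValueError("each trace needs at least 4 samples")
        concs = {tr.concentration for tr in traces}
        if k_off is None and len(concs) < 2:
            raise ValueError(
                "k_on and k_off are not jointly identifiable from a single "
                "concentration; fix k_off or add concentrations"
            )
        self.traces = list(traces)
        self.k_off = k_off
        self.fit_x0 = fit_x0

    def fit(self) -> GlobalFitResult:
        traces = self.traces
        guesses = [_exp_guess(tr.times, tr.responses) for tr in traces]
        concs = np.array([tr.concentration for tr in traces])
        rates = np.array([g[2] for g in guesses])
        # per-trace rate estimates regressed on concentration give the
        # (k_on, k_off) starting point
        if np.unique(concs).size >= 2:
            slope, intercept = np.polyfit(concs, rates, 1)
        else:
            slope, intercept = rates[0] / concs[0], 0.0
        k_on0 = float(np.clip(slope, 1e-6, K_ON_MAX))
        k_off0 = float(np.clip(intercept, 0.0, K_OFF_MAX))

        variants = [(k_on0, k_off0), (float(np.median(rates / concs)), 0.0)]
        best = None
        for kon_init, koff_init in variants:
            params = lmfit.Parameters()
            params.add("k_on", value=kon_init, min=1e-12, max=K_ON_MAX)
            if self.k_off is None:
                params.add("k_off", value=max(koff_init, 1e-12), min=0.0, max=K_OFF_MAX)
            else:
                params.add("k_off", value=float(self.k_off), vary=False)
            for i, (tr, (y0, A, _)) in enumerate(zip(traces, guesses)):
                params.add(f"y0_{i}", value=y0)
                params.add(f"A_{i}", value=A if A != 0 else 1.0)
                params.add(f"x0_{i}", value=float(tr.times[0]), vary=self.fit_x0)

            def residual(p):
                res = []
                for i, tr in enumerate(traces):
                    k_obs = tr.concentration * p["k_on"].value + p["k_off"].value
                    model = p[f"y0_{i}"].value + p[f"A_{i}"].value * np.exp(
                        -(tr.times - p[f"x0_{i}"].value) * k_obs
                    )
                    res.append(model - tr.responses)
                return np.concatenate(res)

            out = lmfit.minimize(residual, params, method="leastsq", xtol=1e-12, ftol=1e-12)
            rms = _rms(out.residual)
            if best is None or rms < best[1]:
                best = (out, rms)
        out, rms = best
        k_on = out.params["k_on"].value
        dk_on = out.params["k_on"].stderr or 0.0
        k_off = out.params["k_off"].value
        dk_off = (out.params["k_off"].stderr or 0.0) if self.k_off is None else 0.0
        curves = [
            ExponentialCurve(
                y0=out.params[f"y0_{i}"].value,
                A=out.params[f"A_{i}"].value,
                x0=out.params[f"x0_{i}"].value,
            )
            for i in range(len(traces))
        ]
        return GlobalFitResult(
            k_on=k_on,
            dk_on=dk_on,
            k_off=k_off,
            dk_off=dk_off,
            per_trace_curves=curves,
            covariance=getattr(out, "covar", None),
            residual_rms=rms,
            converged=bool(out.success),
            n_iter=int(out.nfev),
            mode="global" if self.k_off is None else "k_off-fixed",
        )


def fit_dissociation(
    traces: Sequence[SwitchTrace],
    mode: Literal["global", "individual"] = "global",
) -> GlobalFitResult:
    """Estimate k_off from dissociation traces (see :class:`DissociationModel`)."""
    return DissociationModel(traces, mode=mode).fit()


def fit_association_global(
    traces: Sequence[SwitchTrace], k_off: float | None = 0.0
) -> GlobalFitResult:
    """Estimate k_on by a global fit over all protein concentrations."""
    return AssociationModel(traces, k_off=k_off).fit()


def summarize_kinetics(
    assoc: GlobalFitResult, dissoc: GlobalFitResult
) -> KineticSummary:
    """Combine association and dissociation fits into derived quantities.

    k_on (and its error) comes from the association fit, k_off from the
    dissociation fit; K_D, its propagated error and the dissociation
    halftime follow from the closed forms in :mod:`znfbind.binding`.
    """
    if not (assoc.converged and dissoc.converged):
        raise ValueError("both fits must have converged")
    if assoc.k_on is None or dissoc.k_off is None:
        raise ValueError("association fit must supply k_on, dissociation k_off")
    rates = RateConstants(
        k_on=assoc.k_on,
        k_off=dissoc.k_off,
        dk_on=assoc.dk_on or 0.0,
        dk_off=dissoc.dk_off or 0.0,
    )
    return KineticSummary.from_rates(rates)
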