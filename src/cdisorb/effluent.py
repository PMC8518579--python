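"""Effluent time-series analysis: from (conductivity, pH) traces to SAC and Λ.

On-line conductivity and pH probes behind the cell are the only
concentration information available during a CDI run.  Per sample, the
measured conductivity is inverted through the speciation/conductivity
model (with Na+ from electroneutrality) to the total acid concentration.
Integrating the depletion over an adsorption window gives the salt
adsorption capacity

    SAC = ∫ V̇·(c_0 − c_out) dt / m_E        (mol per g of electrode pair)

and the charge efficiency follows from the supplied charge and the mean
charge of the adsorbed species,

    Λ = F·SAC·(α + 2(1−α))·m_E / ∫I dt · 100%

with α the flow-weighted mean monovalent fraction over the window.
Cycles are delimited by the edges of the applied-current program.  A
forward trace synthesizer closes the loop for testing: it generates a
cyclic steady-state trace whose analysis reproduces a given prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import FARADAY
from .donnan import CellSpec
from .operation import OperatingPoint, PredictionResult
from .speciation import AcidDefinition, invert_conductivity, solve_solution_state

__all__ = [
    "EffluentTrace",
    "CycleResult",
    "trace_to_concentrations",
    "integrate_sac",
    "charge_efficiency_exp",
    "detect_cycles",
    "analyze_cycles",
    "synthesize_trace",
]


@dataclass
class EffluentTrace:
    """Sampled effluent record of one CDI run.

    time in s (strictly increasing), conductivity in S/m, flow_rate in
    L/min, current_program in A per sample (0 during desorption).
    """

    time: np.ndarray
    conductivity: np.ndarray
    pH: np.ndarray
    flow_rate: np.ndarray
    current_program: np.ndarray
    feed_c_total: float
    feed_pH: float

    def __post_init__(self) -> None:
        arrays = [np.asarray(a, dtype=float) for a in (
            self.time, self.conductivity, self.pH, self.flow_rate,
            self.current_program)]
        self.time, self.conductivity, self.pH, self.flow_rate, \
            self.current_program = arrays
        n = self.time.size
        if any(a.size != n for a in arrays):
            raise ValueError("all trace channels must have equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(self.conductivity < 0) or np.any(self.flow_rate < 0):
            raise ValueError("conductivity and flow must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_s": self.time,
            "conductivity_S_m": self.conductivity,
            "pH": self.pH,
            "flow_L_min": self.flow_rate,
            "current_A": self.current_program,
        })

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, feed_c_total: float, feed_pH: float
    ) -> "EffluentTrace":
        return cls(
            time=frame["time_s"].to_numpy(),
            conductivity=frame["conductivity_S_m"].to_numpy(),
            pH=frame["pH"].to_numpy(),
            flow_rate=frame["flow_L_min"].to_numpy(),
            current_program=frame["current_A"].to_numpy(),
            feed_c_total=feed_c_total,
            feed_pH=feed_pH,
        )


@dataclass(frozen=True)
class CycleResult:
    """Per-cycle capacity and efficiency figures."""

    sac_mol: float  # mol/g pair
    sac_eq: float  # eq/g pair
    charge_supplied: float  # C
    lambda_exp: float  # %
    alpha_mean: float
    adsorption_window: tuple[int, int]
    desorption_window: tuple[int, int]


def trace_to_concentrations(
    trace: EffluentTrace, acid: AcidDefinition, mode: str = "ideal"
) -> tuple[np.ndarray, np.ndarray]:
    """Invert conductivity+pH per sample to total acid concentration.

    Returns (c_total array in mol/L, boolean convergence flags).
    Non-invertible samples are flagged and carry NaN, never raise.
    """
    n = trace.time.size
    c_out = np.full(n, np.nan)
    ok = np.zeros(n, dtype=bool)
    for i in range(n):
        try:
            c_out[i], _ = invert_conductivity(
                trace.conductivity[i], trace.pH[i], acid, mode
            )
            ok[i] = True
        except (ValueError, RuntimeError):
            pass
    return c_out, ok


def integrate_sac(
    c_series: np.ndarray,
    trace: EffluentTrace,
    electrode_pair_mass: float,
    window: tuple[int, int],
) -> float:
    """Trapezoidal SAC (mol/g of pair) over a sample-index window."""
    lo, hi = window
    if hi <= lo:
        raise ValueError("empty integration window")
    t = trace.time[lo:hi]
    flow = trace.flow_rate[lo:hi] / 60.0  # L/min → L/s
    depletion = trace.feed_c_total - c_series[lo:hi]  # mol/L
    integrand = flow * depletion  # mol/s
    return float(np.trapezoid(integrand, t)) / electrode_pair_mass


def charge_efficiency_exp(
    sac_mol: float, alpha: float, charge: float, electrode_pair_mass: float
) -> float:
    """Experimental charge efficiency in percent.

    Λ = F·SAC·(α + 2(1−α))·m_E / ∫I dt · 100%.
    """
    if charge <= 0:
        raise ValueError("supplied charge must be positive")
    z_mean = alpha + 2.0 * (1.0 - alpha)
    return FARADAY * sac_mol * z_mean * electrode_pair_mass / charge * 100.0


def detect_cycles(trace: EffluentTrace) -> list[tuple[tuple[int, int], tuple[int, int]]]:
    """Adsorption/desorption windows from the current-program edges.

    Samples with I > 0 belong to adsorption, I = 0 to the following
    desorption.  Returns [(adsorption_window, desorption_window), ...] as
    half-open index pairs; incomplete trailing cycles are dropped.
    """
    on = trace.current_program > 0
    if not on.any():
        raise ValueError("current program contains no adsorption phase")
    edges = np.flatnonzero(np.diff(on.astype(int)))
    starts = [i + 1 for i in edges if on[i + 1]]
    stops = [i + 1 for i in edges if not on[i + 1]]
    if on[0]:
        starts.insert(0, 0)
    cycles = []
    for s in starts:
        stop = next((x for x in stops if x > s), None)
        if stop is None:
            break
        next_start = next((x for x in starts if x > stop), trace.time.size)
        cycles.append(((s, stop), (stop, next_start)))
    if not cycles:
        raise ValueError("no complete adsorption/desorption cycle found")
    return cycles


def analyze_cycles(
    trace: EffluentTrace,
    acid: AcidDefinition,
    spec: CellSpec,
    mode: str = "ideal",
    skip_first: int = 2,
    n_average: int | None = 4,
) -> tuple[list[CycleResult], CycleResult]:
    """Per-cycle SAC/Λ plus the steady-state mean.

    Drops the first ``skip_first`` cycles (start-up transient) and
    averages up to ``n_average`` of the rest, mirroring the practice of
    evaluating the third and following cycles.
    """
    cycles = detect_cycles(trace)
    c_series, _ = trace_to_concentrations(trace, acid, mode)
    m_pair = spec.pair_mass
    results = []
    for (ads, des) in cycles:
        # the depletion dip washes out of the cell volume after the current
        # stops; integrate it to its end (first return to the feed level)
        dip_end = des[1]
        for i in range(des[0], des[1]):
            if np.isfinite(c_series[i]) and \
                    c_series[i] >= trace.feed_c_total * (1.0 - 1e-4):
                dip_end = i + 1
                break
        sac = integrate_sac(c_series, trace, m_pair, (ads[0], dip_end))
        lo, hi = ads
        t = trace.time[lo:hi]
        charge = float(np.trapezoid(trace.current_program[lo:hi], t))
        # flow-weighted mean monovalent fraction over the window
        alphas = np.array([
            solve_solution_state(max(c, 0.0), ph, acid, mode).alpha_mono
            if np.isfinite(c) else np.nan
            for c, ph in zip(c_series[lo:hi], trace.pH[lo:hi])
        ])
        w = trace.flow_rate[lo:hi]
        valid = np.isfinite(alphas)
        alpha = float(np.average(alphas[valid], weights=w[valid]))
        z_mean = alpha + 2.0 * (1.0 - alpha)
        lam = charge_efficiency_exp(sac, alpha, charge, m_pair)
        results.append(CycleResult(
            sac_mol=sac, sac_eq=sac * z_mean, charge_supplied=charge,
            lambda_exp=lam, alpha_mean=alpha,
            adsorption_window=ads, desorption_window=des,
        ))
    tail = results[skip_first:]
    if not tail:
        tail = results
    if n_average is not None:
        tail = tail[:n_average]
    mean = CycleResult(
        sac_mol=float(np.mean([r.sac_mol for r in tail])),
        sac_eq=float(np.mean([r.sac_eq for r in tail])),
        charge_supplied=float(np.mean([r.charge_supplied for r in tail])),
        lambda_exp=float(np.mean([r.lambda_exp for r in tail])),
        alpha_mean=float(np.mean([r.alpha_mean for r in tail])),
        adsorption_window=(-1, -1),
        desorption_window=(-1, -1),
    )
    return results, mean


def synthesize_trace(
    op: OperatingPoint,
    prediction: PredictionResult,
    acid: AcidDefinition,
    spec: CellSpec,
    n_cycles: int = 4,
    dt: float = 5.0,
    desorption_time: float = 2400.0,
    noise: float = 0.0,
    seed: int = 0,
    mode: str = "ideal",
) -> EffluentTrace:
    """Forward-generate a cyclic steady-state effluent trace.

    Each cycle: a lag phase of duration t_E at feed level (the supplied
    charge first expels preloaded coions), then a depletion dip rising
    with a fast capture time constant.  After the current stops the dip
    washes out of the cell's inner volume with time constant
    V_cell/flow, so at operating points where the lag consumes most of
    the charging step the dip extends into the desorption phase — the
    cell's internal inventory supplies what the feed stream cannot.  The
    dip is sized so the integrated SAC equals ``prediction.sac_mol``;
    a later desorption overshoot releases the same amount (cyclic steady
    state).  Conductivity comes from the forward speciation model;
    optional Gaussian sensor noise (relative SD) is applied to it.
    """
    m_pair = spec.pair_mass
    flow_l_s = op.flow_rate / 60.0
    # adsorption duration: time to ramp to the threshold at constant current
    if op.current > 0:
        t_ads = prediction.dphi_eff * m_pair * spec.Cg / (4.0 * op.current)
    else:
        t_ads = 1800.0
    t_cycle = t_ads + desorption_time
    n_per = int(round(t_cycle / dt))
    time = np.arange(n_per * n_cycles + 1) * dt

    target_mol = prediction.sac_mol * m_pair  # mol to remove per cycle
    t_lag = min(prediction.t_E, 0.95 * t_ads)
    tau_rise = max(min(60.0, (t_ads - t_lag) / 2.0), dt)
    tau_mix = spec.inner_volume / flow_l_s  # cell washout
    washout = min(5.0 * tau_mix, 0.6 * desorption_time)

    c_out = np.full(time.size, op.c_feed)
    current = np.zeros(time.size)
    for k in range(n_cycles):
        t0 = k * t_cycle
        in_ads = (time >= t0) & (time < t0 + t_ads)
        current[in_ads] = op.current if op.current > 0 else 1e-12
        # depletion dip: zero before the lag, fast exponential approach
        # while current flows, washout decay afterwards
        s = time - t0
        rising = (s > t_lag) & (s < t_ads)
        shape = np.zeros(time.size)
        shape[rising] = 1.0 - np.exp(-(s[rising] - t_lag) / tau_rise)
        peak = 1.0 - np.exp(-(t_ads - t_lag) / tau_rise)
        tail = (s >= t_ads) & (s < t_ads + washout)
        shape[tail] = peak * np.exp(-(s[tail] - t_ads) / tau_mix)
        span = (s >= 0) & (s <= t_cycle)
        shape_int = np.trapezoid(shape[span], time[span])
        amp = target_mol / (flow_l_s * shape_int)  # mol/L depletion amplitude
        if amp * shape.max() > 0.9 * op.c_feed:
            raise ValueError(
                "requested SAC depletes the feed by more than 90%; "
                "increase flow rate or cycle duration"
            )
        c_out -= amp * shape
        # desorption overshoot after the dip has washed out; a short gap at
        # feed level separates the dip's end from the release peak
        t_rel = t_ads + washout + max(6.0 * dt, 60.0)
        des = (s >= t_rel) & (s < t_cycle)
        tau_d = max((t_cycle - t_rel) / 6.0, dt)
        shape_d = np.zeros(time.size)
        shape_d[des] = np.exp(-(s[des] - t_rel) / tau_d)
        rel_int = np.trapezoid(shape_d[span], time[span])
        c_out += target_mol / (flow_l_s * rel_int) * shape_d

    # small physically-motivated pH dip during depletion (re-equilibration
    # of the dissociation equilibria); the inversion handles it per sample
    ph = np.full(time.size, op.pH_feed) - 0.02 * (op.c_feed - c_out) / max(op.c_feed, 1e-12)

    kappa = np.array([
        solve_solution_state(max(c, 0.0), p, acid, mode).conductivity
        for c, p in zip(c_out, ph)
    ])
    if noise > 0:
        rng = np.random.default_rng(seed)
        kappa = kappa * (1.0 + noise * rng.standard_normal(kappa.shape))
    return EffluentTrace(
        time=time,
        conductivity=kappa,
        pH=ph,
        flow_rate=np.full(time.size, op.flow_rate),
        current_program=current,
        feed_c_total=op.c_feed,
        feed_pH=op.pH_feed,
    )
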