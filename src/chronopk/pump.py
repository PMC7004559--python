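"""Pump-to-patient drug transport along the infusion line.

The drug solution is advected along the tube by the pump-imposed flow, with
no diffusion and an incompressible fluid, so the concentration field obeys

    du/dt = -V(t) du/dx,   u(0, t) = S(t) / (sa * V(t))  when V(t) > 0,

where ``V`` is the (space-uniform) fluid velocity, ``sa`` the tube cross
section and ``S`` the drug mass rate at the inlet.  The delivery rate into
the patient is ``d(t) = sa * V(t) * u(t, L)``.  Because the fluid is
incompressible the outlet depends only on the tube's total (dead) volume,
not on its exact geometry.

Two solvers are provided: an exact method-of-characteristics solution
(volume bookkeeping; used for all quantitative outputs) and a first-order
upwind finite-difference scheme used as an independent numerical cross-check.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "TubeSpec",
    "InfusionSegment",
    "PumpProgram",
    "TransportState",
    "DeliveryProfile",
    "build_trial_schedule",
    "solve_transport_characteristics",
    "solve_transport_fd",
    "fill_delay",
    "flush_spike_fraction",
    "peak_rate_from_dose",
    "TRIAL_SCHEDULES",
    "DEFAULT_TUBE",
    "DEFAULT_REFERENCE_BSA",
]

Shape = Literal["constant", "half_sin_squared"]
Solution = Literal["drug", "glucose"]

#: Reference body surface area (m^2) converting per-m^2 pump rates to ml/h.
DEFAULT_REFERENCE_BSA = 1.84


@dataclass(frozen=True)
class TubeSpec:
    """Infusion-line geometry.

    Only the total (dead) volume matters for the delivery profile at the
    patient end; radius and length are retained for the spatial grid of the
    finite-difference solver.  The default mirrors the clinical set-up: a
    two-section line of total volume 1.84 ml, simplified to an equivalent
    single tube of length 2340 mm (radius chosen to preserve the volume).
    """

    volume_ml: float = 1.84
    length_mm: float = 2340.0

    def __post_init__(self) -> None:
        if self.volume_ml <= 0 or self.length_mm <= 0:
            raise ValueError("tube volume and length must be positive")

    @property
    def cross_section_mm2(self) -> float:
        return self.volume_ml * 1e3 / self.length_mm

    @property
    def radius_mm(self) -> float:
        return math.sqrt(self.cross_section_mm2 / math.pi)

    @classmethod
    def from_geometry(cls, radius_mm: float, length_mm: float) -> "TubeSpec":
        return cls(volume_ml=math.pi * radius_mm**2 * length_mm * 1e-3, length_mm=length_mm)


DEFAULT_TUBE = TubeSpec()


@dataclass(frozen=True)
class InfusionSegment:
    """One piecewise element of a pump program on the shared line.

    ``peak_rate_ml_h`` is the absolute volumetric peak rate at the tube
    (per-m^2 clinical rates are scaled by the patient/reference BSA before
    constructing segments).  For ``half_sin_squared`` the instantaneous rate
    is ``peak * sin^2(pi * (t - origin) / period)``; by default the sine arch
    spans exactly the segment (origin = start, period = duration) so the
    segment mean rate is ``peak / 2``.  ``sin2_origin_h`` / ``sin2_period_h``
    allow truncated arches (used by the corrected-profile designer).
    """

    start_h: float
    duration_h: float
    shape: Shape
    peak_rate_ml_h: float
    solution: Solution = "drug"
    stock_mg_ml: float = 0.0
    sin2_origin_h: float | None = None
    sin2_period_h: float | None = None

    def __post_init__(self) -> None:
        if self.duration_h <= 0:
            raise ValueError("segment duration must be positive")
        if self.peak_rate_ml_h < 0:
            raise ValueError("segment peak rate must be nonnegative")
        if self.solution == "glucose" and self.stock_mg_ml != 0.0:
            raise ValueError("glucose segments carry no drug (stock must be 0)")
        if self.shape not in ("constant", "half_sin_squared"):
            raise ValueError(f"unknown segment shape {self.shape!r}")

    @property
    def end_h(self) -> float:
        return self.start_h + self.duration_h

    @property
    def _origin(self) -> float:
        return self.start_h if self.sin2_origin_h is None else self.sin2_origin_h

    @property
    def _period(self) -> float:
        return self.duration_h if self.sin2_period_h is None else self.sin2_period_h

    def rate_ml_h(self, t: np.ndarray | float) -> np.ndarray:
        """Volumetric rate (ml/h) at absolute program time ``t``."""
        t = np.asarray(t, dtype=float)
        inside = (t >= self.start_h) & (t < self.end_h)
        if self.shape == "constant":
            r = np.where(inside, self.peak_rate_ml_h, 0.0)
        else:
            phase = np.pi * (t - self._origin) / self._period
            r = np.where(inside, self.peak_rate_ml_h * np.sin(phase) ** 2, 0.0)
        return r

    def _sin2_antiderivative(self, t: np.ndarray | float) -> np.ndarray:
        """Antiderivative of sin^2(pi (t - o)/P), evaluated at t."""
        o, p = self._origin, self._period
        t = np.asarray(t, dtype=float)
        return (t - o) / 2.0 - p / (4.0 * np.pi) * np.sin(2.0 * np.pi * (t - o) / p)

    def volume_ml(self, t: np.ndarray | float) -> np.ndarray:
        """Cumulative segment volume (ml) pumped up to absolute time ``t``."""
        t = np.asarray(t, dtype=float)
        tc = np.clip(t, self.start_h, self.end_h)
        if self.shape == "constant":
            return self.peak_rate_ml_h * (tc - self.start_h)
        return self.peak_rate_ml_h * (
            self._sin2_antiderivative(tc) - self._sin2_antiderivative(self.start_h)
        )

    @property
    def total_volume_ml(self) -> float:
        return float(self.volume_ml(self.end_h))

    @property
    def total_mass_mg(self) -> float:
        return self.total_volume_ml * self.stock_mg_ml


@dataclass(frozen=True)
class PumpProgram:
    """Ordered, non-overlapping segments on one infusion line.

    Between segments the flow is zero and the tube contents are frozen
    (pure advection, no diffusion).  ``nominal_dose_mg`` is the prescribed
    dose used as the denominator of dose-fraction metrics; when absent, the
    actually pumped drug mass is used instead.
    """

    segments: tuple[InfusionSegment, ...]
    tube: TubeSpec = DEFAULT_TUBE
    drug: str | None = None
    nominal_dose_mg: float | None = None
    reference_bsa: float | None = None

    def __post_init__(self) -> None:
        segs = tuple(sorted(self.segments, key=lambda s: s.start_h))
        object.__setattr__(self, "segments", segs)
        for a, b in zip(segs, segs[1:]):
            if b.start_h < a.end_h - 1e-12:
                raise ValueError(
                    f"segments overlap: [{a.start_h}, {a.end_h}) and [{b.start_h}, {b.end_h})"
                )

    @property
    def start_h(self) -> float:
        return self.segments[0].start_h

    @property
    def end_h(self) -> float:
        return self.segments[-1].end_h

    def rate_ml_h(self, t: np.ndarray | float) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t, dtype=float)
        for seg in self.segments:
            out += seg.rate_ml_h(t)
        return out

    def pumped_volume_ml(self, t: np.ndarray | float) -> np.ndarray:
        """Cumulative pumped volume W(t) from program start (ml)."""
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t, dtype=float)
        for seg in self.segments:
            out += seg.volume_ml(t)
        return out

    def inlet_stock_mg_ml(self, t: np.ndarray | float) -> np.ndarray:
        """Concentration of the fluid entering the tube at time ``t``."""
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t, dtype=float)
        for seg in self.segments:
            inside = (t >= seg.start_h) & (t < seg.end_h)
            out = np.where(inside, seg.stock_mg_ml, out)
        return out

    # -- concentration indexed by cumulative pumped volume (Lagrangian label) --

    def _volume_breaks(self) -> tuple[np.ndarray, np.ndarray]:
        """Segment boundaries in cumulative-volume coordinates.

        Returns (w_edges, conc) where fluid with Lagrangian volume label in
        [w_edges[i], w_edges[i+1]) has concentration conc[i].
        """
        edges = [0.0]
        conc = []
        for seg in self.segments:
            conc.append(seg.stock_mg_ml)
            edges.append(edges[-1] + seg.total_volume_ml)
        return np.asarray(edges), np.asarray(conc)

    def concentration_at_volume(self, w: np.ndarray | float) -> np.ndarray:
        """Inlet concentration of the fluid parcel with volume label ``w``."""
        edges, conc = self._volume_breaks()
        w = np.asarray(w, dtype=float)
        idx = np.clip(np.searchsorted(edges, w, side="right") - 1, 0, len(conc) - 1)
        out = conc[idx]
        return np.where((w < 0) | (w >= edges[-1]), 0.0, out)

    def mass_up_to_volume(self, w: np.ndarray | float) -> np.ndarray:
        """Drug mass (mg) contained in the first ``w`` ml of pumped fluid."""
        edges, conc = self._volume_breaks()
        w = np.asarray(w, dtype=float)
        wc = np.clip(w, 0.0, edges[-1])
        cum = np.concatenate([[0.0], np.cumsum(conc * np.diff(edges))])
        idx = np.clip(np.searchsorted(edges, wc, side="right") - 1, 0, len(conc) - 1)
        return cum[idx] + conc[idx] * (wc - edges[idx])

    @property
    def total_pumped_mass_mg(self) -> float:
        return float(sum(s.total_mass_mg for s in self.segments))

    @property
    def dose_mg(self) -> float:
        return self.nominal_dose_mg if self.nominal_dose_mg is not None else self.total_pumped_mass_mg

    def with_tube(self, tube: TubeSpec) -> "PumpProgram":
        return replace(self, tube=tube)


@dataclass(frozen=True)
class TransportState:
    """Snapshots of the concentration field u(x, t) along the tube (mg/ml)."""

    grid_x_mm: np.ndarray
    grid_t_h: np.ndarray
    u: np.ndarray  # shape (len(grid_t_h), len(grid_x_mm))


@dataclass(frozen=True)
class DeliveryProfile:
    """Drug mass rate into the patient at the tube outlet.

    ``onset_h`` is the exact tube-fill time (root of W(t) = tube volume) when
    known analytically; ``None`` if the tube is never filled.
    """

    times_h: np.ndarray
    rate_mg_h: np.ndarray
    cumulative_mg: np.ndarray
    onset_h: float | None = None

    @property
    def total_mass_mg(self) -> float:
        return float(self.cumulative_mg[-1])

    def rate_at(self, t: np.ndarray | float) -> np.ndarray:
        return np.interp(np.asarray(t, dtype=float), self.times_h, self.rate_mg_h, left=0.0, right=0.0)

    def cumulative_at(self, t: np.ndarray | float) -> np.ndarray:
        return np.interp(
            np.asarray(t, dtype=float), self.times_h, self.cumulative_mg,
            left=0.0, right=float(self.cumulative_mg[-1]),
        )


# --------------------------------------------------------------------------
# Clinical trial schedules
# --------------------------------------------------------------------------

#: Per-drug chronomodulated schedule: times are clock "HH:MM", rates per m^2.
#: The drug arch is a half-sin^2 whose mean rate is half the printed peak;
#: each infusion is followed by a 30-min glucose rinse on the same line.
TRIAL_SCHEDULES: dict[str, dict] = {
    "CPT11": dict(
        start_clock="02:00", duration_h=6.0, peak_ml_m2_h=18.02,
        stock_mg_ml=3.33, dose_mg_m2=180.0,
        flush_clock="09:45", flush_peak_ml_m2_h=7.38,
    ),
    "LOHP": dict(
        start_clock="10:15", duration_h=11.5, peak_ml_m2_h=1.63,
        stock_mg_ml=3.0, dose_mg_m2=28.0,
        flush_clock="21:45", flush_peak_ml_m2_h=7.28,
    ),
    "FU5": dict(
        start_clock="22:15", duration_h=11.5, peak_ml_m2_h=3.4,
        stock_mg_ml=50.0, dose_mg_m2=933.0,
        flush_clock="09:45", flush_peak_ml_m2_h=6.96,
    ),
}

FLUSH_DURATION_H = 0.5


def clock_to_hours(clock: str) -> float:
    """Parse "HH:MM" into hours since midnight."""
    hh, mm = clock.split(":")
    return int(hh) + int(mm) / 60.0


def peak_rate_from_dose(dose_mg_m2: float, stock_mg_ml: float, duration_h: float) -> float:
    """Peak volumetric rate (ml/m^2/h) of a sin^2 arch delivering ``dose``.

    The arch mean rate is half the peak, so peak = 2 * dose / (stock * T).
    """
    return 2.0 * dose_mg_m2 / (stock_mg_ml * duration_h)


def build_trial_schedule(
    drug: str,
    reference_bsa: float = DEFAULT_REFERENCE_BSA,
    tube: TubeSpec = DEFAULT_TUBE,
) -> PumpProgram:
    """Pump program of the clinical chronomodulated schedule for one drug.

    Times are hours from the drug-infusion pump start; per-m^2 rates are
    scaled to absolute ml/h by ``reference_bsa``.  The program comprises the
    drug sin^2 arch followed by the matching 30-min glucose rinse.
    """
    if drug not in TRIAL_SCHEDULES:
        raise KeyError(f"unknown drug {drug!r}; expected one of {sorted(TRIAL_SCHEDULES)}")
    if reference_bsa <= 0:
        raise ValueError("reference_bsa must be positive")
    sched = TRIAL_SCHEDULES[drug]
    start = clock_to_hours(sched["start_clock"])
    flush = clock_to_hours(sched["flush_clock"])
    flush_offset = (flush - start) % 24.0
    segments = (
        InfusionSegment(
            start_h=0.0, duration_h=sched["duration_h"], shape="half_sin_squared",
            peak_rate_ml_h=sched["peak_ml_m2_h"] * reference_bsa,
            solution="drug", stock_mg_ml=sched["stock_mg_ml"],
        ),
        InfusionSegment(
            start_h=flush_offset, duration_h=FLUSH_DURATION_H, shape="half_sin_squared",
            peak_rate_ml_h=sched["flush_peak_ml_m2_h"] * reference_bsa,
            solution="glucose",
        ),
    )
    return PumpProgram(
        segments=segments, tube=tube, drug=drug,
        nominal_dose_mg=sched["dose_mg_m2"] * reference_bsa,
        reference_bsa=reference_bsa,
    )


# --------------------------------------------------------------------------
# Solvers
# --------------------------------------------------------------------------

def _fill_time(program: PumpProgram) -> float | None:
    """Exact time at which cumulative pumped volume reaches the tube volume."""
    vt = program.tube.volume_ml
    t_end = program.end_h
    if program.pumped_volume_ml(t_end) < vt:
        return None
    lo = program.start_h
    if program.pumped_volume_ml(lo) >= vt:
        return lo
    return float(brentq(lambda t: float(program.pumped_volume_ml(t)) - vt, lo, t_end, xtol=1e-12))


def solve_transport_characteristics(
    program: PumpProgram,
    dt_out_h: float = 1.0 / 240.0,
    t_end_h: float | None = None,
) -> DeliveryProfile:
    """Exact outlet delivery profile by the method of characteristics.

    The fluid parcel exiting at time ``t`` entered when the cumulative pumped
    volume was ``W(t) - V_tube``, so ``d(t) = Q(t) * c(W(t) - V_tube)`` with
    ``c`` the inlet concentration indexed by Lagrangian volume label.  The
    cumulative outlet mass is exactly ``M(W(t) - V_tube)`` where ``M`` is the
    (piecewise-linear) mass-vs-volume relation, so mass conservation holds to
    machine precision once a terminal flush has emptied the tube.
    """
    t_end = program.end_h if t_end_h is None else t_end_h
    # Include segment boundaries in the grid to keep the rate discontinuities sharp.
    times = np.arange(program.start_h, t_end + dt_out_h, dt_out_h)
    breaks = [s.start_h for s in program.segments] + [s.end_h for s in program.segments]
    times = np.unique(np.concatenate([times, [b for b in breaks if b <= t_end]]))
    vt = program.tube.volume_ml
    w = program.pumped_volume_ml(times)
    q = program.rate_ml_h(times)
    rate = np.where(w >= vt, q * program.concentration_at_volume(w - vt), 0.0)
    cumulative = np.asarray(program.mass_up_to_volume(np.maximum(w - vt, 0.0)))
    onset = _fill_time(program)
    return DeliveryProfile(times_h=times, rate_mg_h=rate, cumulative_mg=cumulative, onset_h=onset)


def solve_transport_fd(
    program: PumpProgram,
    dx_mm: float | None = None,
    dt_h: float | None = None,
    cfl: float = 0.9,
    n_snapshots: int = 200,
) -> tuple[TransportState, DeliveryProfile]:
    """First-order upwind finite-difference solution of the transport PDE.

    Explicit in time, backward in space (flow is always pump-to-patient).
    ``dt`` defaults to the largest step satisfying the CFL condition
    ``max(V) dt / dx <= cfl``; an explicitly supplied ``dt`` violating CFL
    raises.  Returns subsampled field snapshots plus the outlet profile.
    """
    tube = program.tube
    L = tube.length_mm
    sa = tube.cross_section_mm2
    if dx_mm is None:
        dx_mm = L / 1000.0
    nx = int(round(L / dx_mm))
    if abs(nx * dx_mm - L) > 1e-9 * L:
        raise ValueError("dx must divide the tube length")
    # Peak velocity in mm/h: ml/h -> mm^3/h over the cross section.
    vmax = max(s.peak_rate_ml_h for s in program.segments) * 1e3 / sa
    if vmax <= 0:
        raise ValueError("program has no flow")
    dt_max = cfl * dx_mm / vmax
    if dt_h is None:
        dt_h = dt_max
    elif dt_h > dx_mm / vmax * (1.0 + 1e-12):
        raise ValueError(f"CFL violation: dt={dt_h} exceeds dx/Vmax={dx_mm / vmax}")
    t0, t_end = program.start_h, program.end_h
    nt = int(np.ceil((t_end - t0) / dt_h)) + 1
    times = t0 + np.arange(nt) * dt_h

    u = np.zeros(nx + 1)
    x = np.linspace(0.0, L, nx + 1)
    out_rate = np.zeros(nt)
    snap_every = max(1, nt // n_snapshots)
    snaps_t, snaps_u = [], []

    q_all = program.rate_ml_h(times)          # ml/h
    c_in_all = program.inlet_stock_mg_ml(times)
    v_all = q_all * 1e3 / sa                  # mm/h
    for k in range(nt):
        v = v_all[k]
        if v > 0:
            u[0] = c_in_all[k]
            lam = v * dt_h / dx_mm
            u[1:] = u[1:] - lam * (u[1:] - u[:-1])
        out_rate[k] = q_all[k] * u[-1]        # ml/h * mg/ml = mg/h
        if k % snap_every == 0:
            snaps_t.append(times[k])
            snaps_u.append(u.copy())
    cumulative = np.concatenate([[0.0], np.cumsum((out_rate[1:] + out_rate[:-1]) / 2.0 * dt_h)])
    state = TransportState(grid_x_mm=x, grid_t_h=np.asarray(snaps_t), u=np.asarray(snaps_u))
    profile = DeliveryProfile(times_h=times, rate_mg_h=out_rate, cumulative_mg=cumulative)
    return state, profile


# --------------------------------------------------------------------------
# Analytics
# --------------------------------------------------------------------------

class TubeNeverFilledError(RuntimeError):
    """Raised when the program pumps less fluid than the tube dead volume."""


def fill_delay(profile: DeliveryProfile, threshold_mg_h: float = 1e-12) -> int:
    """Minutes from pump start to first nonzero drug delivery at the outlet.

    Uses the exact fill time when the profile carries one, otherwise the first
    grid time with rate above ``threshold_mg_h``.  Reported to the nearest
    minute, matching clinical granularity.
    """
    if profile.onset_h is not None:
        onset = profile.onset_h
    else:
        nz = np.nonzero(profile.rate_mg_h > threshold_mg_h)[0]
        if len(nz) == 0:
            raise TubeNeverFilledError("tube never filled: delivery profile is all zero")
        onset = float(profile.times_h[nz[0]])
    start = float(profile.times_h[0])
    return int(round((onset - start) * 60.0))


def flush_spike_fraction(program: PumpProgram) -> float:
    """Percent of the dose expelled during the terminal glucose rinse.

    When the pump stops at the end of the drug arch the tube still holds its
    dead volume of drug solution; the rinse pushes it into the patient as a
    spike.  For a rinse that empties the tube this equals
    ``tube_volume * stock / dose`` in closed form.
    """
    glucose = [s for s in program.segments if s.solution == "glucose"]
    if not glucose:
        raise ValueError("program has no glucose flush segment")
    flush = glucose[-1]
    vt = program.tube.volume_ml
    if flush.total_volume_ml < vt - 1e-12:
        warnings.warn(
            "flush volume is smaller than the tube volume: reporting the partial spike fraction",
            stacklevel=2,
        )
    w0 = float(program.pumped_volume_ml(flush.start_h))
    w1 = float(program.pumped_volume_ml(flush.end_h))
    mass = float(program.mass_up_to_volume(max(w1 - vt, 0.0)) - program.mass_up_to_volume(max(w0 - vt, 0.0)))
    return 100.0 * mass / program.dose_mg
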