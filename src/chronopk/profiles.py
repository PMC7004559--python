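"""Design of corrected pump programs that deliver the intended profile.

An uncorrected program suffers two artefacts at the patient end of the line:
a fill delay (the tube dead volume must be traversed before any drug
arrives) and a terminal spike (the rinse expels the residual tube content at
the rinse rate).  Both are removed by a three-part program:

1. a bolus of drug solution at the channel's maximum rate, sized to exactly
   the tube volume and timed to finish at the intended clinical start, so
   the tube is primed with drug at t0;
2. the intended sin^2 arch itself, truncated at the time ``t_cut`` when the
   drug bag (volume dose/stock) is exhausted;
3. a glucose rinse that continues the arch's volumetric rate from ``t_cut``
   to the intended end, pushing the residual tube drug out at exactly the
   intended rate (the legacy 30-min rinse peak may be appended unchanged).

Drug concentrations are never altered (stability constraint); only the
pumping schedule changes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from chronopk.pump import (
    DeliveryProfile,
    InfusionSegment,
    PumpProgram,
    TubeSpec,
    solve_transport_characteristics,
)

__all__ = [
    "IntendedProfile",
    "CorrectedProgram",
    "MismatchReport",
    "design_corrected_program",
    "compare_profiles",
]

#: Default channel maximum volumetric rate (ml/h) used for the priming bolus.
DEFAULT_MAX_PUMP_RATE = 125.0


@dataclass(frozen=True)
class IntendedProfile:
    """The clinically intended delivery: a sin^2 arch in mass rate.

    ``start_h``/``duration_h`` define the arch on the program clock;
    ``dose_mg`` its integral.  With constant stock concentration the
    volumetric and mass-rate shapes coincide.
    """

    start_h: float
    duration_h: float
    dose_mg: float
    stock_mg_ml: float
    shape: str = "half_sin_squared"

    def __post_init__(self) -> None:
        if self.dose_mg <= 0 or self.stock_mg_ml <= 0 or self.duration_h <= 0:
            raise ValueError("dose, stock concentration and duration must be positive")
        if self.shape != "half_sin_squared":
            raise ValueError("only half_sin_squared intended profiles are supported")

    @property
    def end_h(self) -> float:
        return self.start_h + self.duration_h

    @property
    def bag_volume_ml(self) -> float:
        return self.dose_mg / self.stock_mg_ml

    @property
    def peak_volumetric_ml_h(self) -> float:
        return 2.0 * self.bag_volume_ml / self.duration_h

    @property
    def peak_mass_mg_h(self) -> float:
        return 2.0 * self.dose_mg / self.duration_h

    def mass_rate(self, t: np.ndarray | float) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        inside = (t >= self.start_h) & (t < self.end_h)
        phase = np.pi * (t - self.start_h) / self.duration_h
        return np.where(inside, self.peak_mass_mg_h * np.sin(phase) ** 2, 0.0)

    def cumulative_volume(self, t: np.ndarray | float) -> np.ndarray:
        """Volume (ml) pumped by the intended arch up to ``t``."""
        t = np.asarray(t, dtype=float)
        tc = np.clip(t, self.start_h, self.end_h)
        s = tc - self.start_h
        return self.peak_volumetric_ml_h * (
            s / 2.0 - self.duration_h / (4.0 * np.pi) * np.sin(2.0 * np.pi * s / self.duration_h)
        )


@dataclass(frozen=True)
class CorrectedProgram:
    """Three-part corrected program (bolus + truncated arch + matched rinse)."""

    bolus: InfusionSegment
    main: InfusionSegment
    rinse: InfusionSegment
    legacy_peak: InfusionSegment | None
    tube: TubeSpec
    intended: IntendedProfile

    def to_program(self) -> PumpProgram:
        segments = [self.bolus, self.main, self.rinse]
        if self.legacy_peak is not None:
            segments.append(self.legacy_peak)
        return PumpProgram(
            segments=tuple(segments), tube=self.tube,
            nominal_dose_mg=self.intended.dose_mg,
        )

    @property
    def t_cut_h(self) -> float:
        return self.main.end_h


class InfeasibleProgramError(ValueError):
    """The corrected program cannot be built under the stated constraints."""


def design_corrected_program(
    intended: IntendedProfile,
    tube: TubeSpec,
    max_pump_rate_ml_h: float = DEFAULT_MAX_PUMP_RATE,
    legacy_rinse_peak_ml_h: float | None = None,
    max_lead_time_h: float | None = None,
) -> CorrectedProgram:
    """Construct the corrected three-part program for ``intended``.

    The bolus primes the tube before the clinical start; the drug channel is
    cut at ``t_cut`` when bolus + arch volume equals the bag volume
    (bisection to 1e-9 ml); the rinse continues the arch's volumetric rate to
    the intended end, after which an optional legacy 30-min rinse peak is
    appended unchanged.
    """
    if max_pump_rate_ml_h <= 0:
        raise InfeasibleProgramError("max pump rate must be positive")
    vt = tube.volume_ml
    bag = intended.bag_volume_ml
    if bag <= vt:
        raise InfeasibleProgramError(
            f"drug bag volume ({bag:.3g} ml) does not exceed the tube volume ({vt:.3g} ml)"
        )
    bolus_duration = vt / max_pump_rate_ml_h
    if max_lead_time_h is not None and bolus_duration > max_lead_time_h:
        raise InfeasibleProgramError(
            f"bolus needs {bolus_duration:.3g} h at {max_pump_rate_ml_h} ml/h, "
            f"exceeding the available lead time {max_lead_time_h:.3g} h"
        )
    bolus = InfusionSegment(
        start_h=intended.start_h - bolus_duration, duration_h=bolus_duration,
        shape="constant", peak_rate_ml_h=max_pump_rate_ml_h,
        solution="drug", stock_mg_ml=intended.stock_mg_ml,
    )
    # Truncation: arch volume from start equals bag - tube volume.
    target = bag - vt
    f = lambda t: float(intended.cumulative_volume(t)) - target
    if f(intended.end_h) < -1e-9:
        raise InfeasibleProgramError("dose/volume inconsistency: bag never exhausted before arch end")
    t_cut = float(brentq(f, intended.start_h, intended.end_h, xtol=1e-9 / max(intended.peak_volumetric_ml_h, 1.0)))
    main = InfusionSegment(
        start_h=intended.start_h, duration_h=t_cut - intended.start_h,
        shape="half_sin_squared", peak_rate_ml_h=intended.peak_volumetric_ml_h,
        solution="drug", stock_mg_ml=intended.stock_mg_ml,
        sin2_origin_h=intended.start_h, sin2_period_h=intended.duration_h,
    )
    rinse = InfusionSegment(
        start_h=t_cut, duration_h=intended.end_h - t_cut,
        shape="half_sin_squared", peak_rate_ml_h=intended.peak_volumetric_ml_h,
        solution="glucose",
        sin2_origin_h=intended.start_h, sin2_period_h=intended.duration_h,
    )
    legacy = None
    if legacy_rinse_peak_ml_h is not None:
        legacy = InfusionSegment(
            start_h=intended.end_h, duration_h=0.5, shape="half_sin_squared",
            peak_rate_ml_h=legacy_rinse_peak_ml_h, solution="glucose",
        )
    return CorrectedProgram(bolus=bolus, main=main, rinse=rinse, legacy_peak=legacy,
                            tube=tube, intended=intended)


@dataclass(frozen=True)
class MismatchReport:
    """Normalized mismatch between a delivered and an intended profile."""

    l1_pct_of_dose: float          # integral |delivered - intended| / dose * 100
    linf_mg_h: float
    onset_shift_min: float         # delivered onset minus intended start
    times_h: np.ndarray
    cumulative_delivered_pct: np.ndarray
    cumulative_intended_pct: np.ndarray


def compare_profiles(delivered: DeliveryProfile, intended: IntendedProfile) -> MismatchReport:
    """Quantify how far a delivered profile is from the clinical intent."""
    if intended.dose_mg <= 0:
        raise ValueError("intended profile has zero dose")
    t0 = min(float(delivered.times_h[0]), intended.start_h)
    t1 = max(float(delivered.times_h[-1]), intended.end_h)
    times = np.linspace(t0, t1, 20001)
    d = delivered.rate_at(times)
    i = intended.mass_rate(times)
    l1 = float(np.trapezoid(np.abs(d - i), times)) / intended.dose_mg * 100.0
    linf = float(np.max(np.abs(d - i)))
    if delivered.onset_h is not None:
        onset = delivered.onset_h
    else:
        nz = np.nonzero(delivered.rate_mg_h > 1e-12)[0]
        onset = float(delivered.times_h[nz[0]]) if len(nz) else float("nan")
    onset_shift = round((onset - intended.start_h) * 60.0)
    cum_d = delivered.cumulative_at(times) / intended.dose_mg * 100.0
    cum_i = np.concatenate([[0.0], np.cumsum((i[1:] + i[:-1]) / 2.0 * np.diff(times))])
    cum_i = cum_i / intended.dose_mg * 100.0
    return MismatchReport(
        l1_pct_of_dose=l1, linf_mg_h=linf, onset_shift_min=float(onset_shift),
        times_h=times, cumulative_delivered_pct=cum_d, cumulative_intended_pct=cum_i,
    )
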