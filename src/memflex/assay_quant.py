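"""Wet-assay quantification formulas for liposome/GUV experiments.

Implements the standard readouts used alongside the simulation metrics:

* dithionite-mediated NBD quenching, ``Quench(%) = (F_i − F_0)/(F_T − F_0) × 100``
  with ``F_0`` the pre-dithionite baseline (mean over 0–30 s) and ``F_T`` the
  post-Triton full-quench value — a plateau at 50% means only the externally
  oriented probe half was quenched (an impermeable membrane);
* GUV dye permeability, ``Permeability(%) = I_in/I_ex × 100``;
* GUV shrinkage, ``Shrinking(%) = 100 × A_0/A_i`` as conventionally printed
  (rises above 100% as vesicles shrink), with the consumed-area alternative
  ``100 × (1 − A_i/A_0)`` also available;
* apparent radius of EM profiles, ``R = √(A/π)``;
* GTPase rate from a malachite-green phosphate time series calibrated against
  a 0–200 µM standard curve, in s⁻¹ per enzyme concentration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class QuenchTrace:
    times: np.ndarray          # s
    fluorescence: np.ndarray   # arbitrary units
    f0: float                  # pre-dithionite baseline
    ft: float                  # post-Triton full-quench value

    @classmethod
    def from_arrays(cls, times, fluorescence,
                    baseline_window: tuple[float, float] = (0.0, 30.0),
                    triton_time: float | None = None,
                    ft: float | None = None) -> "QuenchTrace":
        """Build a trace, deriving F_0 from the baseline window and (unless
        given) F_T from the mean fluorescence after ``triton_time``."""
        times = np.asarray(times, dtype=float)
        fl = np.asarray(fluorescence, dtype=float)
        base = (times >= baseline_window[0]) & (times <= baseline_window[1])
        if not base.any():
            raise ValueError("no samples in the baseline window")
        f0 = float(fl[base].mean())
        if ft is None:
            if triton_time is None:
                raise ValueError("supply either ft or triton_time")
            tail = times >= triton_time
            if not tail.any():
                raise ValueError("no samples at or after triton_time")
            ft = float(fl[tail].mean())
        return cls(times=times, fluorescence=fl, f0=f0, ft=float(ft))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "QuenchTrace":
        return cls.from_arrays(df["time_s"].to_numpy(),
                               df["fluorescence"].to_numpy(), **kwargs)


@dataclass
class GuvMeasurement:
    i_in: float    # mean internal intensity
    i_ex: float    # mean external intensity
    a0: float      # area at time 0 (µm²)
    ai: float      # area at time i (µm²)


@dataclass
class PhosphateSeries:
    times: np.ndarray            # s
    absorbance_650: np.ndarray   # a.u.
    standards: pd.DataFrame      # columns conc_uM, abs
    dynamin_conc: float          # µM

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.absorbance_650 = np.asarray(self.absorbance_650, dtype=float)
        if len(self.standards) < 3:
            raise ValueError("standard curve needs at least 3 concentrations")
        if self.dynamin_conc <= 0:
            raise ValueError("dynamin_conc must be > 0")


def nbd_quench_percent(trace: QuenchTrace) -> np.ndarray:
    """Per-timepoint quenching percentage (100% at full quench)."""
    if trace.f0 == trace.ft:
        raise ValueError("no dynamic range: F_0 equals F_T")
    return (trace.fluorescence - trace.f0) / (trace.ft - trace.f0) * 100.0


def quench_plateau(trace: QuenchTrace, at_time: float) -> float:
    """Quench % at the sample nearest to ``at_time`` (s), e.g. the fast-phase
    plateau read just before Triton addition."""
    q = nbd_quench_percent(trace)
    return float(q[np.argmin(np.abs(trace.times - at_time))])


def guv_permeability(m: GuvMeasurement) -> float:
    """Internal/external dye intensity ratio in percent; 100% = fully
    equilibrated (permeable) vesicle."""
    if m.i_ex == 0:
        raise ValueError("external intensity is zero")
    return 100.0 * m.i_in / m.i_ex


def guv_shrinkage(m: GuvMeasurement, ratio: str = "printed") -> float:
    """Vesicle shrinkage in percent.

    ``ratio="printed"`` gives ``100 × A_0/A_i`` (grows past 100% as the
    vesicle shrinks); ``ratio="consumed"`` gives the fraction of the initial
    area lost, ``100 × (1 − A_i/A_0)``.
    """
    if m.ai <= 0 or m.a0 <= 0:
        raise ValueError("areas must be > 0")
    if ratio == "printed":
        return 100.0 * m.a0 / m.ai
    if ratio == "consumed":
        return 100.0 * (1.0 - m.ai / m.a0)
    raise ValueError(f"unknown ratio convention {ratio!r}")


def apparent_radius(area: float) -> float:
    """Apparent radius R = √(A/π) of a (roughly circular) EM profile; any
    consistent squared length unit works (nm² in, nm out)."""
    if area < 0:
        raise ValueError("area must be >= 0")
    return float(np.sqrt(area / np.pi))


@dataclass
class GtpaseFit:
    rate: float                  # s⁻¹
    slope_uM_per_s: float
    calibration_slope: float     # abs per µM
    calibration_intercept: float
    phosphate_uM: np.ndarray = field(repr=False, default=None)


def calibrate_phosphate(series: PhosphateSeries) -> tuple[np.ndarray, float, float]:
    """Convert absorbances to µM phosphate via the least-squares line through
    the standards (intercept free, absorbing background)."""
    conc = series.standards["conc_uM"].to_numpy(dtype=float)
    ab = series.standards["abs"].to_numpy(dtype=float)
    order = np.argsort(conc)
    if np.any(np.diff(ab[order]) <= 0):
        raise ValueError("standard curve absorbances are not monotone in "
                         "concentration")
    res = stats.linregress(conc, ab)
    phosphate = (series.absorbance_650 - res.intercept) / res.slope
    return phosphate, float(res.slope), float(res.intercept)


def gtpase_rate(series: PhosphateSeries,
                fit_window: tuple[float, float] = (15.0, 120.0)) -> GtpaseFit:
    """GTP hydrolysis rate in s⁻¹.

    Absorbances are calibrated to µM phosphate against the standards; the
    least-squares slope of phosphate vs time over ``fit_window`` (s, the
    early linear phase), divided by the enzyme concentration, is the
    turnover rate.
    """
    phosphate, slope_cal, icpt_cal = calibrate_phosphate(series)
    in_win = (series.times >= fit_window[0]) & (series.times <= fit_window[1])
    if in_win.sum() < 3:
        raise ValueError(f"fewer than 3 points in fit window {fit_window}")
    t = series.times[in_win]
    p = phosphate[in_win]
    res = stats.linregress(t, p)
    return GtpaseFit(rate=float(res.slope / series.dynamin_conc),
                     slope_uM_per_s=float(res.slope),
                     calibration_slope=slope_cal,
                     calibration_intercept=icpt_cal,
                     phosphate_uM=phosphate)
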