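"""Closed-system respirometry: pO2 traces to standard metabolic rate.

A chamber's pO2 declines linearly while seeds respire aerobically.  The
processing chain per replicate chamber is

1. moving-window smoothing of the raw pO2 signal (low signal-to-noise
   fluorescence readings),
2. truncation of the trace once pO2 first falls below a fraction (default
   0.8) of its initial value, guarding against hypoxic depression,
3. an OLS slope of pO2 on time (kPa/h, negative for consuming seeds),
4. conversion of the slope to an oxygen consumption rate VO2 in
   ul O2 seed^-1 h^-1 at STP, and per species
5. exclusion of outlier replicates (typically microbial contamination, which
   inflates apparent SMR) by a 2-SD rule on the replicate slopes,
6. averaging of the kept replicates and Q10 standardization of the mean rate
   from the measurement temperature to 20 deg C.

The STP conversion treats the headspace as an ideal gas: the fractional rate
of pO2 decline relative to the dry headspace pressure (total pressure minus
saturation water vapour pressure at chamber temperature, minus measured pCO2
when a CO2 channel is available) gives the fraction of headspace volume
consumed per hour, converted to STP volume by the 273.15/(273.15+T) ratio.
With a respiratory exchange ratio of 1, evolved CO2 replaces consumed O2
mole-for-mole, so total headspace pressure is treated as constant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PO2Trace",
    "RespirometryResult",
    "TraceError",
    "saturation_vapour_pressure",
    "smooth_trace",
    "truncate_hypoxia",
    "fit_slope",
    "slope_to_vo2",
    "filter_outlier_replicates",
    "q10_correct",
    "process_species",
    "process_traces",
]

MIN_TRACE_POINTS = 4


class TraceError(ValueError):
    """Raised when a trace cannot be processed."""


@dataclass
class PO2Trace:
    """One chamber's pO2-versus-time series with chamber metadata.

    times are hours (strictly increasing), po2 and the optional pco2 channel
    are kPa, volume_ul is the gas headspace, t_measure the chamber
    temperature in deg C and pressure_kpa the ambient total pressure.
    """

    chamber_id: str
    species: str
    times: np.ndarray
    po2: np.ndarray
    volume_ul: float
    n_seeds: int
    t_measure: float
    pressure_kpa: float = 101.325
    pco2: np.ndarray | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.po2 = np.asarray(self.po2, dtype=float)
        if self.times.shape != self.po2.shape:
            raise TraceError(f"{self.chamber_id}: times and po2 differ in length")
        if np.any(np.diff(self.times) <= 0):
            raise TraceError(f"{self.chamber_id}: times must be strictly increasing")
        if np.any(self.po2 <= 0):
            raise TraceError(f"{self.chamber_id}: po2 must be positive")
        if self.n_seeds < 1:
            raise TraceError(f"{self.chamber_id}: n_seeds must be >= 1")

    def __len__(self) -> int:
        return len(self.times)

    def replace(self, times: np.ndarray, po2: np.ndarray) -> "PO2Trace":
        pco2 = self.pco2
        if pco2 is not None and len(pco2) != len(po2):
            pco2 = None  # channel alignment lost after resampling; drop it
        return PO2Trace(
            chamber_id=self.chamber_id,
            species=self.species,
            times=times,
            po2=po2,
            volume_ul=self.volume_ul,
            n_seeds=self.n_seeds,
            t_measure=self.t_measure,
            pressure_kpa=self.pressure_kpa,
            pco2=pco2,
        )


@dataclass
class RespirometryResult:
    """Per-species respirometry summary."""

    species: str
    chamber_ids: list  # usable replicates, in processing order
    slopes: np.ndarray  # kPa/h, one per usable replicate
    vo2_per_seed: np.ndarray  # ul O2 seed^-1 h^-1 at STP, per usable replicate
    kept_mask: np.ndarray  # replicate outlier flags (True = kept)
    n_unusable: int  # replicates rejected before slope fitting
    smr_t: float  # mean kept VO2 at measurement temperature
    t_measure: float
    smr20: float  # Q10-standardized to 20 deg C

    @property
    def n_replicates_kept(self) -> int:
        return int(self.kept_mask.sum())


def saturation_vapour_pressure(t_c: float) -> float:
    """Saturation water vapour pressure (kPa) at t_c (deg C), Arden Buck form."""
    t = np.asarray(t_c, dtype=float)
    return 0.61121 * np.exp((18.678 - t / 234.5) * (t / (257.14 + t)))


def smooth_trace(trace: PO2Trace, window: int = 3) -> PO2Trace:
    """Centered moving-window average of the pO2 signal.

    Edge samples without a full window are dropped (output length is
    input length - window + 1); the time stamps are re-centered on the window
    means so a linear signal stays exactly linear.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    if len(trace) < window:
        raise TraceError(
            f"{trace.chamber_id}: trace of length {len(trace)} shorter than "
            f"smoothing window {window}"
        )
    if window == 1:
        return trace
    kernel = np.ones(window) / window
    po2 = np.convolve(trace.po2, kernel, mode="valid")
    times = np.convolve(trace.times, kernel, mode="valid")
    return trace.replace(times=times, po2=po2)


def truncate_hypoxia(
    trace: PO2Trace, frac: float = 0.8, strict: bool = True
) -> PO2Trace:
    """Retain the maximal prefix with po2 >= frac * po2[0].

    Later recoveries above the threshold are not re-admitted: once the
    chamber has gone hypoxic the physiological state is suspect.  With
    ``strict`` (the default in the processing chain), a prefix of fewer than
    4 points raises :class:`TraceError` — the replicate is unusable for
    slope fitting; ``strict=False`` returns the short prefix as-is.
    """
    if not 0 < frac < 1:
        raise ValueError("frac must be in (0, 1)")
    threshold = frac * trace.po2[0]
    below = np.nonzero(trace.po2 < threshold)[0]
    cut = int(below[0]) if len(below) else len(trace)
    if strict and cut < MIN_TRACE_POINTS:
        raise TraceError(
            f"{trace.chamber_id}: only {cut} points above the hypoxia "
            f"threshold ({threshold:.3g} kPa); replicate unusable"
        )
    return trace.replace(times=trace.times[:cut], po2=trace.po2[:cut])


def fit_slope(trace: PO2Trace) -> tuple[float, float]:
    """OLS slope of pO2 on time, in kPa/h, with its standard error.

    Negative for consuming seeds.  The SE is 0 for an exact line.
    """
    if len(trace) < MIN_TRACE_POINTS:
        raise TraceError(f"{trace.chamber_id}: need >= {MIN_TRACE_POINTS} points")
    t = trace.times
    y = trace.po2
    if np.ptp(t) == 0:
        raise TraceError(f"{trace.chamber_id}: zero time variance")
    tc = t - t.mean()
    slope = float(tc @ (y - y.mean()) / (tc @ tc))
    resid = y - y.mean() - slope * tc
    n = len(t)
    se = float(np.sqrt(max(resid @ resid, 0.0) / (n - 2) / (tc @ tc)))
    return slope, se


def slope_to_vo2(
    slope: float,
    volume_ul: float,
    n_seeds: int,
    t_measure: float,
    pressure_kpa: float = 101.325,
    pco2_kpa: float = 0.0,
    correct_vapour: bool = True,
    stp_correction: Callable[[float, float], float] | None = None,
) -> float:
    """Convert a pO2 slope (kPa/h) to VO2 in ul O2 seed^-1 h^-1 at STP.

    VO2 = (-slope / P_dry) * volume * (273.15 / (273.15 + T)) / n_seeds,
    where P_dry = pressure - SVP(T) - pCO2 is the dry headspace pressure.
    Pass ``correct_vapour=False`` for pre-dried readings, or supply
    ``stp_correction(volume_chamber_t, t_measure) -> volume_stp`` to replace
    the ideal-gas temperature correction with an instrument-specific one.
    """
    if volume_ul <= 0 or n_seeds <= 0:
        raise ValueError("volume_ul and n_seeds must be positive")
    if slope > 0:
        warnings.warn(
            f"positive pO2 slope ({slope:.3g} kPa/h): oxygen production?",
            stacklevel=2,
        )
    p_dry = pressure_kpa - pco2_kpa
    if correct_vapour:
        p_dry -= saturation_vapour_pressure(t_measure)
    if p_dry <= 0:
        raise ValueError(f"non-positive dry headspace pressure ({p_dry:.3g} kPa)")
    vol_consumed = (-slope / p_dry) * volume_ul  # ul at chamber T, per hour
    if stp_correction is not None:
        vol_stp = stp_correction(vol_consumed, t_measure)
    else:
        vol_stp = vol_consumed * 273.15 / (273.15 + t_measure)
    return vol_stp / n_seeds


def filter_outlier_replicates(slopes: Sequence[float], k: float = 2.0) -> np.ndarray:
    """Flag replicate slopes more than k SD from the other replicates' mean.

    Single pass (not iterated), leave-one-out: each replicate is compared to
    the mean and SD of the remaining replicates, so one grossly contaminated
    chamber cannot mask itself by inflating the pooled SD.  With all slopes
    identical (SD = 0) everything is kept.  Returns a boolean keep-mask,
    invariant to replicate order.
    """
    slopes = np.asarray(slopes, dtype=float)
    n = len(slopes)
    if n < 3:
        raise ValueError("need at least 3 replicates to filter outliers")
    total = slopes.sum()
    keep = np.ones(n, dtype=bool)
    atol = 1e-12 * max(np.abs(slopes).max(), 1.0)  # guards the SD = 0 branch
    for i in range(n):
        others = np.delete(slopes, i)
        mean = (total - slopes[i]) / (n - 1)
        sd = others.std(ddof=1)
        if abs(slopes[i] - mean) > k * sd + atol:
            keep[i] = False
    return keep


def q10_correct(
    smr_t: float, t_measure: float, t_ref: float = 20.0, q10: float = 2.5
) -> float:
    """Standardize a rate from t_measure to t_ref with a Q10 relationship.

    smr_ref = smr_t * q10 ** ((t_ref - t_measure) / 10).
    """
    if q10 <= 0:
        raise ValueError("q10 must be positive")
    return smr_t * q10 ** ((t_ref - t_measure) / 10.0)


def process_species(
    traces: Sequence[PO2Trace],
    window: int = 3,
    hypoxia_frac: float = 0.8,
    outlier_k: float = 2.0,
    t_ref: float = 20.0,
    q10: float = 2.5,
    correct_vapour: bool = True,
) -> RespirometryResult:
    """Run the full per-species chain over that species' replicate chambers.

    Unusable replicates (too short after truncation) are dropped with a
    count; the outlier filter requires >= 3 usable replicates, otherwise all
    usable replicates are kept.  Per-species SMR is the arithmetic mean of
    the kept replicates' per-seed VO2.
    """
    if not traces:
        raise TraceError("no traces supplied")
    species = traces[0].species
    slopes, vo2s = [], []
    chamber_ids = []
    n_unusable = 0
    for tr in traces:
        try:
            sm = smooth_trace(tr, window=window)
            sm = truncate_hypoxia(sm, frac=hypoxia_frac)
            slope, _ = fit_slope(sm)
        except TraceError:
            n_unusable += 1
            continue
        chamber_ids.append(tr.chamber_id)
        slopes.append(slope)
        vo2s.append(
            slope_to_vo2(
                slope,
                tr.volume_ul,
                tr.n_seeds,
                tr.t_measure,
                tr.pressure_kpa,
                pco2_kpa=float(np.mean(tr.pco2)) if tr.pco2 is not None else 0.0,
                correct_vapour=correct_vapour,
            )
        )
    if not slopes:
        raise TraceError(f"{species}: no usable replicates")
    slopes = np.asarray(slopes)
    vo2s = np.asarray(vo2s)
    if len(slopes) >= 3:
        kept = filter_outlier_replicates(slopes, k=outlier_k)
    else:
        kept = np.ones(len(slopes), dtype=bool)
    t_measure = float(np.mean([tr.t_measure for tr in traces]))
    smr_t = float(vo2s[kept].mean())
    return RespirometryResult(
        species=species,
        chamber_ids=chamber_ids,
        slopes=slopes,
        vo2_per_seed=vo2s,
        kept_mask=kept,
        n_unusable=n_unusable,
        smr_t=smr_t,
        t_measure=t_measure,
        smr20=q10_correct(smr_t, t_measure, t_ref=t_ref, q10=q10),
    )


def process_traces(traces: Sequence[PO2Trace], **kwargs) -> pd.DataFrame:
    """Group traces by species and summarize each into one SMR table row.

    Returns a DataFrame with columns species, smr_t, t_measure, smr20,
    n_replicates_kept (the output SMR table of the respirometry stage).
    """
    by_species: dict[str, list[PO2Trace]] = {}
    for tr in traces:
        by_species.setdefault(tr.species, []).append(tr)
    rows = []
    for species, group in by_species.items():
        res = process_species(group, **kwargs)
        rows.append(
            {
                "species": species,
                "smr_t": res.smr_t,
                "t_measure": res.t_measure,
                "smr20": res.smr20,
                "n_replicates_kept": res.n_replicates_kept,
            }
        )
    return pd.DataFrame(rows)
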