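"""Cycle analysis, QC and inhibition calling for surfactometer traces.

A functional surfactant film reaches very low surface tension on each
compression; the assay therefore (i) segments the trace into
compression-expansion cycles, (ii) extracts the per-cycle minimum surface
tension, (iii) accepts the run only if the baseline minima are below
5 mN/m with per-cycle area compression below 30%, and (iv) calls the film
inhibited when the minima rise to >= 10 mN/m for three or more consecutive
cycles (the threshold above which alveolar collapse is expected in vivo).
Replicate calls are aggregated into a per-chemical binary outcome, and the
inhibitory dose is estimated from the deposition flux and the onset time.

All thresholds live in :class:`AssayCriteria` and default to the assay's
published values; they are configuration, not constants buried in code.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from lungsurf.errors import (
    DoseNotEstimableError,
    InsufficientDataError,
    NoCallError,
    ParameterError,
    SegmentationError,
)


@dataclass(frozen=True)
class AssayCriteria:
    """Acceptance and inhibition thresholds of the bioassay.

    baseline_max_st: baseline minima must be strictly below this (mN/m).
    max_compression: baseline per-cycle compression must be strictly below
    this fraction. inhibition_st: minima at or above this (mN/m) count toward
    an inhibition run. run_length: minimum number of consecutive qualifying
    minima. n_baseline_cycles: cycles that define the baseline.
    replicate_rule: fraction of QC-passing replicates that must be inhibited
    for a positive chemical call.
    """

    baseline_max_st: float = 5.0
    inhibition_st: float = 10.0
    max_compression: float = 0.30
    run_length: int = 3
    n_baseline_cycles: int = 5
    replicate_rule: float = 0.5

    def __post_init__(self) -> None:
        if min(self.baseline_max_st, self.inhibition_st, self.max_compression) <= 0:
            raise ParameterError("thresholds must be positive")
        if self.run_length < 1 or self.n_baseline_cycles < 1:
            raise ParameterError("run_length and n_baseline_cycles must be >= 1")
        if not 0 < self.replicate_rule <= 1:
            raise ParameterError("replicate_rule must be in (0, 1]")


DEFAULT_CRITERIA = AssayCriteria()


@dataclass
class SurfaceTensionTrace:
    """Uniformly sampled surface-tension/area time series of one replicate."""

    time: np.ndarray  # s
    surface_tension: np.ndarray  # mN/m
    surface_area: np.ndarray  # mm^2
    frame_rate: float = 10.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.surface_tension = np.asarray(self.surface_tension, dtype=float)
        self.surface_area = np.asarray(self.surface_area, dtype=float)
        n = len(self.time)
        if not (len(self.surface_tension) == len(self.surface_area) == n):
            raise ParameterError("trace columns must have equal length")
        if n > 1:
            dt = np.diff(self.time)
            if not (dt > 0).all():
                raise ParameterError("time must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ParameterError("time must be uniformly sampled")
        if n and (self.surface_tension <= 0).any():
            raise ParameterError("surface_tension must be > 0")
        if n and (self.surface_area <= 0).any():
            raise ParameterError("surface_area must be > 0")

    def __len__(self) -> int:
        return len(self.time)


@dataclass(frozen=True)
class CycleSummary:
    """Per-cycle extracted quantities (cycle_index is 1-based)."""

    cycle_index: int
    min_surface_tension: float  # mN/m
    time_at_min: float  # s, sample time of the minimum-gamma frame
    area_at_min: float  # mm^2
    max_area: float  # mm^2
    min_area: float  # mm^2

    @property
    def compression_ratio(self) -> float:
        """(A_max - A_min) / A_max within the cycle."""
        return (self.max_area - self.min_area) / self.max_area


@dataclass(frozen=True)
class QCResult:
    """Baseline quality control outcome."""

    baseline_min_st: float  # mN/m
    baseline_compression: float  # fraction
    passed: bool
    reasons: tuple[str, ...] = ()


@dataclass(frozen=True)
class InhibitionCall:
    """Binary inhibition outcome of one replicate trace."""

    inhibited: bool
    onset_cycle: int | None = None  # 1-based
    onset_time: float | None = None  # s

    def __post_init__(self) -> None:
        if self.inhibited != (self.onset_cycle is not None):
            raise ParameterError("inhibited must be set iff onset_cycle is set")


def segment_cycles(trace: SurfaceTensionTrace, min_prominence_frac: float = 0.1) -> list[tuple[int, int]]:
    """Split a trace into compression-expansion cycles.

    Cycles are delimited by successive local maxima of the area signal,
    filtered by prominence (``min_prominence_frac`` of the area peak-to-peak
    range) so sub-sample jitter does not split cycles. Returns half-open
    sample ranges [start, stop); partial leading/trailing cycles are
    discarded.
    """
    area = trace.surface_area
    span = float(np.ptp(area))
    if span <= 0:
        raise SegmentationError("constant-area trace: no cycles to segment")
    # peaks cannot be detected at the array ends, so pad by one sample; this
    # recovers maxima sitting exactly at the trace boundaries
    padded = np.concatenate([[-np.inf], area, [-np.inf]])
    peaks, _ = find_peaks(padded, prominence=min_prominence_frac * span)
    peaks -= 1
    if len(peaks) < 2:
        raise SegmentationError(f"found {len(peaks)} area maxima; need >= 2 for one complete cycle")
    return [(int(peaks[i]), int(peaks[i + 1])) for i in range(len(peaks) - 1)]


def summarize_cycles(trace: SurfaceTensionTrace, ranges: list[tuple[int, int]]) -> list[CycleSummary]:
    """Extract per-cycle minima and compression from segmented ranges."""
    summaries = []
    for k, (start, stop) in enumerate(ranges, start=1):
        if stop - start < 2:
            raise InsufficientDataError(f"cycle {k}: range [{start}, {stop}) has < 2 samples")
        gamma = trace.surface_tension[start:stop]
        area = trace.surface_area[start:stop]
        imin = int(np.argmin(gamma))
        summaries.append(
            CycleSummary(
                cycle_index=k,
                min_surface_tension=float(gamma[imin]),
                time_at_min=float(trace.time[start + imin]),
                area_at_min=float(area[imin]),
                max_area=float(area.max()),
                min_area=float(area.min()),
            )
        )
    return summaries


def qc_baseline(summaries: list[CycleSummary], criteria: AssayCriteria = DEFAULT_CRITERIA) -> QCResult:
    """Check the baseline acceptance criteria on the first cycles.

    The lowest minimum over the first ``criteria.n_baseline_cycles`` cycles
    must be strictly below ``baseline_max_st`` (5 mN/m) and the mean
    per-cycle compression strictly below ``max_compression`` (30%); values
    exactly at either threshold fail.
    """
    n = criteria.n_baseline_cycles
    if len(summaries) < n:
        raise InsufficientDataError(f"need >= {n} baseline cycles, got {len(summaries)}")
    head = summaries[:n]
    min_st = min(c.min_surface_tension for c in head)
    compression = float(np.mean([c.compression_ratio for c in head]))
    reasons = []
    if not min_st < criteria.baseline_max_st:
        reasons.append(f"baseline_min_st={min_st:.3g} not below {criteria.baseline_max_st} mN/m")
    if not compression < criteria.max_compression:
        reasons.append(f"baseline_compression={compression:.3g} not below {criteria.max_compression:.0%}")
    return QCResult(
        baseline_min_st=min_st,
        baseline_compression=compression,
        passed=not reasons,
        reasons=tuple(reasons),
    )


def detect_inhibition(summaries: list[CycleSummary], criteria: AssayCriteria = DEFAULT_CRITERIA) -> InhibitionCall:
    """Call inhibition: minima >= 10 mN/m for >= 3 consecutive cycles.

    The onset is the first cycle of the earliest qualifying run; the
    threshold is inclusive (a run of exactly 10.0 mN/m minima qualifies).
    """
    if len(summaries) < criteria.run_length:
        raise InsufficientDataError(
            f"need >= {criteria.run_length} cycles to call inhibition, got {len(summaries)}"
        )
    run = 0
    for i, cyc in enumerate(summaries):
        if cyc.min_surface_tension >= criteria.inhibition_st:
            run += 1
            if run == criteria.run_length:
                onset = summaries[i - criteria.run_length + 1]
                return InhibitionCall(
                    inhibited=True,
                    onset_cycle=onset.cycle_index,
                    onset_time=onset.time_at_min,
                )
        else:
            run = 0
    return InhibitionCall(inhibited=False)


def analyze_trace(
    trace: SurfaceTensionTrace, criteria: AssayCriteria = DEFAULT_CRITERIA
) -> tuple[list[CycleSummary], QCResult, InhibitionCall | None]:
    """Full single-replicate pipeline: segment, summarize, QC, call.

    The inhibition call is None when baseline QC fails (the replicate is
    discarded, not re-interpreted).
    """
    ranges = segment_cycles(trace)
    summaries = summarize_cycles(trace, ranges)
    qc = qc_baseline(summaries, criteria)
    call = detect_inhibition(summaries, criteria) if qc.passed else None
    return summaries, qc, call


def classify_chemical(
    calls: list[InhibitionCall | None],
    criteria: AssayCriteria = DEFAULT_CRITERIA,
) -> dict:
    """Aggregate replicate calls into the per-chemical binary outcome.

    QC-failed replicates enter as None and are excluded. The chemical is
    labeled inhibitory when the fraction of QC-passing replicates with a
    positive call is >= ``criteria.replicate_rule`` (default: majority).

    Returns a dict with keys ``inhibitory``, ``agreement`` (fraction
    positive), ``n_replicates`` (QC-passing) and ``discordant``.
    """
    passing = [c for c in calls if c is not None]
    if not passing:
        raise NoCallError("no QC-passing replicate: chemical cannot be classified")
    if not 3 <= len(passing) <= 5:
        warnings.warn(
            f"{len(passing)} QC-passing replicates (assay protocol uses 3-5); proceeding",
            stacklevel=2,
        )
    agreement = sum(c.inhibited for c in passing) / len(passing)
    return {
        "inhibitory": agreement >= criteria.replicate_rule,
        "agreement": agreement,
        "n_replicates": len(passing),
        "discordant": 0.0 < agreement < 1.0,
    }


def estimate_inhibitory_dose(
    deposition_flux: float,
    call: InhibitionCall,
    mean_drop_area: float,
    volatile: bool = False,
) -> dict:
    """Estimate the deposited dose at inhibition onset.

    dose_per_area (ng/cm^2) = flux (ng/cm^2/min) * onset time (min);
    total_mass (ng) = dose_per_area * mean cycling drop area (mm^2 -> cm^2).
    Highly volatile chemicals return ``estimable: False`` because deposited
    mass cannot be measured reliably for them.
    """
    if volatile:
        return {
            "estimable": False,
            "reason": "volatile compound: deposited-mass measurement unreliable",
        }
    if not call.inhibited:
        raise DoseNotEstimableError("no inhibition onset: dose undefined for a negative call")
    if deposition_flux <= 0:
        raise ParameterError("deposition_flux must be > 0 to estimate dose")
    dose_per_area = deposition_flux * call.onset_time / 60.0  # ng/cm^2
    total_mass = dose_per_area * (mean_drop_area / 100.0)  # mm^2 -> cm^2
    return {
        "estimable": True,
        "dose_per_area_ng_cm2": dose_per_area,
        "total_mass_ng": total_mass,
        "onset_time_s": call.onset_time,
    }
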