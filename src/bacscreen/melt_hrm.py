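"""Synthetic melt curves, first-derivative peak calling, and primer QC.

High-resolution melt (HRM) analysis monitors the fluorescence of an
intercalating dye as double-stranded PCR product dissociates along a fine
temperature ramp (here 65-90 degC in 0.3 degC steps).  The negative first
derivative -dF/dT peaks at the melting temperature Tm of each amplicon, so
a multiplex reaction with up to three amplicons of well-separated Tm shows
up to three distinguishable peaks.  This module synthesizes idealized
curves (sum of logistic melt transitions plus Gaussian noise) for testing
the screening logic, detects derivative peaks against a no-template
control, assigns peaks to expected markers, and checks primers against
standard design heuristics (length, GC content, Tm window, GC clamps).

The curve synthesis is fixture-grade: it reproduces the qualitative shape
of real melt data, not duplex thermodynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "Amplicon",
    "MeltGrid",
    "MeltCurve",
    "Peak",
    "DerivativePlot",
    "MarkerCall",
    "QCReport",
    "predict_tm",
    "primer_tm",
    "synthesize_melt_curve",
    "derivative_plot",
    "call_markers",
    "check_primer",
]


def predict_tm(
    length: int,
    gc_fraction: float,
    *,
    base: float = 81.5,
    gc_coeff: float = 0.41,
    length_coeff: float = 675.0,
) -> float:
    """Empirical amplicon melting temperature in degC.

    ``Tm = 81.5 + 0.41 * GC% - 675 / length`` — the standard
    product-length/GC approximation (no salt or dye correction).  Constants
    are configurable.
    """
    if length < 1:
        raise ValueError("amplicon length must be >= 1 nt")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError("gc_fraction must be in [0, 1]")
    return base + gc_coeff * (100.0 * gc_fraction) - length_coeff / length


def primer_tm(sequence: str) -> float:
    """Wallace-rule Tm for short oligos: 2(A+T) + 4(G+C) degC."""
    seq = sequence.upper()
    return 2.0 * sum(b in "AT" for b in seq) + 4.0 * sum(b in "GC" for b in seq)


@dataclass(frozen=True)
class Amplicon:
    """A PCR product characterized by length, GC content and melting point."""

    marker_id: str
    length: int
    gc_fraction: float
    predicted_tm: float | None = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must be in [0, 1]")

    @property
    def tm(self) -> float:
        if self.predicted_tm is not None:
            return self.predicted_tm
        return predict_tm(self.length, self.gc_fraction)


@dataclass(frozen=True)
class MeltGrid:
    """Temperature ramp: 65 to 90 degC in 0.3 degC steps by default."""

    t_start: float = 65.0
    t_end: float = 90.0
    step: float = 0.3

    def __post_init__(self) -> None:
        if self.t_start >= self.t_end:
            raise ValueError("t_start must be < t_end")
        if self.step <= 0:
            raise ValueError("step must be positive")

    @property
    def n_points(self) -> int:
        return int(np.floor((self.t_end - self.t_start) / self.step)) + 1

    @property
    def temperatures(self) -> np.ndarray:
        return self.t_start + self.step * np.arange(self.n_points)


@dataclass(frozen=True)
class MeltCurve:
    """Fluorescence series on a melt grid (non-negative, one value/point)."""

    grid: MeltGrid
    fluorescence: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.fluorescence, dtype=float)
        object.__setattr__(self, "fluorescence", f)
        if f.shape != (self.grid.n_points,):
            raise ValueError(
                f"fluorescence length {f.shape} != grid points {self.grid.n_points}"
            )
        if np.any(f < 0):
            raise ValueError("fluorescence must be non-negative")


@dataclass(frozen=True)
class Peak:
    tm: float
    height: float
    width: float


@dataclass(frozen=True)
class DerivativePlot:
    """Negative first derivative of a melt curve with detected peaks."""

    temperatures: np.ndarray
    minus_df_dt: np.ndarray
    peaks: tuple[Peak, ...]


@dataclass(frozen=True)
class MarkerCall:
    marker_id: str
    call: str  # "positive" | "negative"
    matched_peak: Peak | None = None
    reason: str = ""


@dataclass
class QCReport:
    """Per-criterion primer QC; heuristic deviations warn, never reject."""

    sequence: str
    length: int
    gc_fraction: float
    tm: float
    checks: dict[str, bool] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    @property
    def status(self) -> str:
        return "pass" if not self.warnings else "warn"


def synthesize_melt_curve(
    amplicons: list[Amplicon],
    grid: MeltGrid | None = None,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = None,
    amplitude: float = 1.0,
    transition_width: float = 0.5,
    baseline: float = 0.05,
) -> MeltCurve:
    """Idealized melt curve: baseline plus one logistic step per amplicon.

    Each amplicon contributes ``amplitude * logistic((Tm - T)/width)``, a
    sigmoid dropping through its Tm, so -dF/dT peaks there.  Gaussian noise
    of standard deviation ``noise_sd`` is added reproducibly under a fixed
    seed; the result is clipped at zero to keep fluorescence physical.
    """
    grid = grid or MeltGrid()
    if len(amplicons) > 3:
        raise ValueError("multiplexing supports at most 3 amplicons")
    t = grid.temperatures
    f = np.full_like(t, baseline, dtype=float)
    for amp in amplicons:
        f += amplitude / (1.0 + np.exp(-(amp.tm - t) / transition_width))
    if noise_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        f = f + rng.normal(0.0, noise_sd, size=t.shape)
    return MeltCurve(grid=grid, fluorescence=np.clip(f, 0.0, None))


def derivative_plot(
    curve: MeltCurve,
    smoothing_window: int = 1,
    threshold: float = 0.0,
) -> DerivativePlot:
    """Negative first derivative with peak detection.

    Central differences in the interior, one-sided differences at the grid
    ends (so the series keeps the grid length).  ``smoothing_window`` > 1
    applies a moving average of that many grid points before peak finding.
    Peaks are local maxima of -dF/dT strictly above ``threshold``.
    """
    t = curve.grid.temperatures
    f = curve.fluorescence
    if len(f) < 3:
        raise ValueError("curve must have at least 3 points")
    d = -np.gradient(f, t)  # central interior, one-sided ends
    if smoothing_window > 1:
        kernel = np.ones(smoothing_window) / smoothing_window
        d = np.convolve(d, kernel, mode="same")
    # scale-relative prominence floor suppresses float-level ripple on flat
    # regions while leaving genuine melt transitions (and uniform rescaling
    # of the curve) unaffected
    prominence = 1e-6 * float(f.max() - f.min()) / curve.grid.step
    idx, _ = find_peaks(
        d,
        height=threshold if threshold > 0 else None,
        prominence=prominence if prominence > 0 else None,
    )
    step = curve.grid.step
    peaks = []
    for i in idx:
        height = d[i]
        if height <= threshold:
            continue
        above = d >= height / 2
        # crude full-width-at-half-maximum in grid steps around the peak
        left = i
        while left > 0 and above[left - 1]:
            left -= 1
        right = i
        while right < len(d) - 1 and above[right + 1]:
            right += 1
        peaks.append(Peak(tm=float(t[i]), height=float(height),
                          width=float((right - left + 1) * step)))
    peaks.sort(key=lambda p: p.tm)
    return DerivativePlot(temperatures=t, minus_df_dt=d, peaks=tuple(peaks))


def control_threshold(control: DerivativePlot, k: float = 5.0) -> float:
    """Robust peak-height threshold: ``k`` times the median absolute
    deviation of the no-template control derivative."""
    mad = float(np.median(np.abs(control.minus_df_dt
                                 - np.median(control.minus_df_dt))))
    return k * max(mad, np.finfo(float).tiny)


def call_markers(
    dplot: DerivativePlot,
    expected: list[Amplicon],
    tolerance: float = 1.0,
    control: DerivativePlot | None = None,
    threshold_mads: float = 5.0,
) -> tuple[list[MarkerCall], list[Peak]]:
    """Assign detected peaks to expected markers within a Tm tolerance.

    Expected Tms must be pairwise separated by more than twice the
    tolerance (otherwise peaks are not attributable and a multiplex-design
    error is raised).  A marker is positive iff a peak lies within
    +/- tolerance of its expected Tm and exceeds the control-relative
    height threshold.  Peaks matching no marker are returned as
    off-target.
    """
    tms = [a.tm for a in expected]
    for i in range(len(tms)):
        for j in range(i + 1, len(tms)):
            if abs(tms[i] - tms[j]) <= 2 * tolerance:
                raise ValueError(
                    f"expected Tm windows overlap: {expected[i].marker_id} "
                    f"({tms[i]:.1f}) and {expected[j].marker_id} "
                    f"({tms[j]:.1f}) within 2 x tolerance {tolerance}"
                )
    thr = control_threshold(control, threshold_mads) if control is not None else 0.0
    significant = [p for p in dplot.peaks if p.height > thr]
    calls: list[MarkerCall] = []
    matched: set[int] = set()
    for amp in expected:
        best = None
        for k, p in enumerate(significant):
            if abs(p.tm - amp.tm) <= tolerance and (
                best is None or p.height > significant[best].height
            ):
                best = k
        if best is None:
            calls.append(MarkerCall(amp.marker_id, "negative",
                                    reason=f"no peak within {tolerance} degC "
                                           f"of {amp.tm:.1f} degC above threshold"))
        else:
            matched.add(best)
            calls.append(MarkerCall(amp.marker_id, "positive",
                                    matched_peak=significant[best]))
    off_target = [p for k, p in enumerate(significant) if k not in matched]
    return calls, off_target


def check_primer(
    sequence: str,
    length_window: tuple[int, int] = (19, 21),
    gc_target: float = 0.5,
    gc_band: float = 0.10,
    tm_window: tuple[float, float] = (57.0, 60.0),
) -> QCReport:
    """Check a primer against standard design heuristics.

    Criteria (each evaluated separately; deviations warn rather than fail,
    since these are optima, not hard rules): length 19-21 nt, GC content
    within ``gc_band`` of 50%, Wallace-rule Tm of 57-60 degC, the last two
    3' bases both G/C (strong 3' clamp) and the first 5' base G/C.
    """
    seq = sequence.upper().strip()
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"non-ACGT characters in primer: {sorted(bad)}")
    if not seq:
        raise ValueError("empty primer sequence")
    length = len(seq)
    gc = sum(b in "GC" for b in seq) / length
    tm = primer_tm(seq)
    checks = {
        "length": length_window[0] <= length <= length_window[1],
        "gc_content": abs(gc - gc_target) <= gc_band,
        "tm": tm_window[0] <= tm <= tm_window[1],
        "three_prime_clamp": len(seq) >= 2 and all(b in "GC" for b in seq[-2:]),
        "five_prime_gc": seq[0] in "GC",
    }
    messages = {
        "length": f"length {length} outside {length_window[0]}-{length_window[1]} nt",
        "gc_content": f"GC content {100 * gc:.0f}% outside "
                      f"{100 * (gc_target - gc_band):.0f}-"
                      f"{100 * (gc_target + gc_band):.0f}%",
        "tm": f"Tm {tm:.0f} degC outside {tm_window[0]:.0f}-{tm_window[1]:.0f} degC",
        "three_prime_clamp": f"3' end {seq[-2:]!r} is not two G/C bases",
        "five_prime_gc": f"5' base {seq[0]!r} is not G/C",
    }
    warnings = [messages[name] for name, ok in checks.items() if not ok]
    return QCReport(sequence=seq, length=length, gc_fraction=gc, tm=tm,
                    checks=checks, warnings=warnings)
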