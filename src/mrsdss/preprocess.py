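"""Automatic spectral processing pipeline.

The pipeline turns a raw metabolite FID into a canonical 512-point spectrum:

1. residual-water removal — an HLSVD-type fit models the FID as a sum of
   exponentially damped complex sinusoids ("lorentzians", 10 by default) and
   subtracts the components whose frequency falls inside the water band;
2. apodization — 1 Hz exponential line broadening;
3. Fourier transform with the carrier assigned to water at 4.7 ppm, followed
   by automatic zero-order phasing;
4. baseline offset correction using flat regions on both sides of the water
   peak (-2 to -1 ppm and 9 to 11 ppm);
5. linear interpolation onto the canonical grid;
6. automatic alignment: the spectrum is shifted by whole grid points so that
   the first sufficiently tall reference peak found — creatine (3.03 ppm),
   then choline (3.21 ppm), then lipid (1.29 ppm) — sits at its nominal
   position; if no reference qualifies the spectrum is left unchanged.

Chemical-shift convention: the transmitter sits on water, so an offset
frequency f (Hz) maps to ppm = 4.7 - f / f0 with f0 the transmitter
frequency in MHz.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.linalg

from .spectra_io import (
    CanonicalSpectrum,
    N_POINTS,
    PpmAxis,
    RawFID,
    TeClass,
    resample_linear,
)

__all__ = [
    "WATER_PPM",
    "ProcessingParams",
    "DampedSinusoid",
    "AlignmentReport",
    "hlsvd_fit",
    "reconstruct_fid",
    "water_filter",
    "apodize",
    "to_spectrum",
    "zero_order_phase",
    "baseline_offset",
    "find_local_peak",
    "snr_estimate",
    "shift_spectrum",
    "choose_alignment_reference",
    "align",
    "process_pipeline",
]

#: Water resonates at 4.7 ppm; the carrier (0 Hz offset) is placed on it.
WATER_PPM = 4.7


@dataclass(frozen=True)
class ProcessingParams:
    """Tunable constants of the automatic pipeline.

    Defaults follow the processing protocol the pipeline implements:
    10 HLSVD components, 1 Hz line broadening, baseline regions
    (-2, -1) and (9, 11) ppm, alignment references Cr 3.03 / Cho 3.21 /
    Lip 1.29 ppm searched within +/-5 points, tallest-peak search band
    0-4.5 ppm and acceptance factor 5.
    """

    hlsvd_components: int = 10
    water_band: tuple[float, float] = (4.33, 5.07)  # ppm
    lb_hz: float = 1.0
    baseline_regions: tuple[tuple[float, float], ...] = ((-2.0, -1.0), (9.0, 11.0))
    reference_peaks: tuple[tuple[str, float], ...] = (
        ("Cr", 3.03),
        ("Cho", 3.21),
        ("Lip", 1.29),
    )
    search_halfwidth_pts: int = 5
    tp_search_band: tuple[float, float] = (0.0, 4.5)
    tp_ratio: float = 5.0
    noise_region: tuple[float, float] = (9.0, 11.0)
    #: fallback noise region when the working axis ends below 9 ppm
    noise_region_fallback: tuple[float, float] = (-2.7, -1.7)
    phase_band: tuple[float, float] = (0.5, 4.2)  # ppm, zero-order phasing

    def __post_init__(self) -> None:
        if self.hlsvd_components < 1:
            raise ValueError("hlsvd_components must be >= 1")
        if self.search_halfwidth_pts < 1:
            raise ValueError("search_halfwidth_pts must be >= 1")
        if not self.tp_ratio > 0:
            raise ValueError("tp_ratio must be positive")
        for lo, hi in (self.water_band, self.tp_search_band, self.noise_region,
                       self.phase_band, *self.baseline_regions):
            if not hi > lo:
                raise ValueError(f"interval ({lo}, {hi}) is not well-ordered")


@dataclass(frozen=True)
class DampedSinusoid:
    """One exponentially damped complex sinusoid: a*exp(i*phi)*exp((-d + 2*pi*i*f) t)."""

    amplitude: float
    phase: float
    frequency: float  # Hz
    damping: float  # 1/s, >= 0

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        return (
            self.amplitude
            * np.exp(1j * self.phase)
            * np.exp((-self.damping + 2j * np.pi * self.frequency) * t)
        )


@dataclass(frozen=True)
class AlignmentReport:
    reference_used: str  # "Cr", "Cho", "Lip" or "none"
    shift_points: int
    aligned: bool

    def __post_init__(self) -> None:
        if not self.aligned and self.shift_points != 0:
            raise ValueError("unaligned spectrum must report shift 0")


# ---------------------------------------------------------------------------
# HLSVD: subspace fit of damped sinusoids via SVD of the Hankel data matrix
# ---------------------------------------------------------------------------

def hlsvd_fit(fid: RawFID, k: int | None = None) -> list[DampedSinusoid]:
    """Model an FID as at most ``k`` damped complex sinusoids.

    The signal is arranged in a Hankel matrix (rows = half the signal
    length, capped at 256) whose rank-``k`` signal subspace is obtained by a
    full SVD.  Frequencies and dampings come from the shift-invariance of
    the subspace (eigenvalues of the propagator between the subspace with
    its first and last row dropped); amplitudes and phases from a linear
    least-squares fit of the resulting poles to the data.

    Growing poles (|z| > 1) are discarded: only decaying components are
    physical for an FID.
    """
    if k is None:
        k = 10
    x = fid.samples
    if x.size < 4 * k:
        raise ValueError(f"signal too short for {k} components: need >= {4 * k} samples")
    L = min(x.size // 2, 256)
    M = x.size - L + 1
    hankel = scipy.linalg.hankel(x[:L], x[L - 1:])
    assert hankel.shape == (L, M)
    u, s, _ = np.linalg.svd(hankel, full_matrices=False)
    uk = u[:, :k]
    # shift-invariance: Uk_bottom ~= Uk_top @ Z  (Z shares signal poles)
    z_mat = np.linalg.lstsq(uk[:-1], uk[1:], rcond=None)[0]
    poles = np.linalg.eigvals(z_mat)
    dt = fid.dwell_time
    # keep decaying, non-degenerate poles
    keep = (np.abs(poles) <= 1.0 + 1e-9) & (np.abs(poles) > 1e-12)
    poles = poles[keep]
    if poles.size == 0:
        return []
    freqs = np.angle(poles) / (2 * np.pi * dt)
    dampings = np.maximum(-np.log(np.abs(poles)) / dt, 0.0)
    # amplitudes/phases: x[n] ~= sum_j c_j * z_j^n
    n_idx = np.arange(x.size)
    basis = poles[None, :] ** n_idx[:, None]
    coeffs = np.linalg.lstsq(basis, x, rcond=None)[0]
    components = [
        DampedSinusoid(
            amplitude=float(np.abs(c)),
            phase=float(np.angle(c)),
            frequency=float(f),
            damping=float(d),
        )
        for c, f, d in zip(coeffs, freqs, dampings)
    ]
    components.sort(key=lambda c: -c.amplitude)
    return components


def reconstruct_fid(
    components: Sequence[DampedSinusoid], fid: RawFID
) -> np.ndarray:
    """Evaluate a component list on a FID's time grid."""
    t = fid.times
    total = np.zeros(fid.n, dtype=complex)
    for c in components:
        total += c.evaluate(t)
    return total


def ppm_of_frequency(f_hz: float | np.ndarray, transmitter_mhz: float) -> np.ndarray:
    """Offset frequency (Hz) -> chemical shift, water-carrier convention."""
    return WATER_PPM - np.asarray(f_hz) / transmitter_mhz


def frequency_of_ppm(ppm: float | np.ndarray, transmitter_mhz: float) -> np.ndarray:
    return (WATER_PPM - np.asarray(ppm)) * transmitter_mhz


def water_filter(fid: RawFID, params: ProcessingParams | None = None) -> RawFID:
    """Subtract HLSVD components falling inside the water band.

    Components whose ppm-mapped frequency lies in ``params.water_band``
    (default 4.33-5.07 ppm, i.e. +/-0.37 ppm around water) are removed from
    the time-domain signal; everything else is untouched.
    """
    params = params or ProcessingParams()
    components = hlsvd_fit(fid, params.hlsvd_components)
    lo, hi = params.water_band
    in_band = [
        c
        for c in components
        if lo <= float(ppm_of_frequency(c.frequency, fid.transmitter_frequency)) <= hi
    ]
    if not in_band:
        return fid
    water = reconstruct_fid(in_band, fid)
    return fid.with_samples(fid.samples - water)


def apodize(fid: RawFID, lb_hz: float = 1.0) -> RawFID:
    """Exponential line broadening: multiply by exp(-pi*lb*t).

    Adds exactly ``lb_hz`` to the FWHM of every lorentzian line (the
    spectral FWHM of exp(-d t) is d/pi Hz).
    """
    if lb_hz < 0:
        raise ValueError("line broadening must be non-negative")
    if lb_hz == 0:
        return fid
    window = np.exp(-np.pi * lb_hz * fid.times)
    return fid.with_samples(fid.samples * window)


def to_spectrum(fid: RawFID) -> tuple[np.ndarray, np.ndarray]:
    """Discrete Fourier transform with a ppm frequency axis.

    Returns the complex spectrum (use :func:`zero_order_phase` to obtain
    the real absorption part) and its chemical-shift axis, descending in
    ppm to match the canonical orientation.  Zero offset frequency maps to
    water at 4.7 ppm.
    """
    spectrum = np.fft.fftshift(np.fft.fft(fid.samples))
    freqs = np.fft.fftshift(np.fft.fftfreq(fid.n, d=fid.dwell_time))
    ppm = ppm_of_frequency(freqs, fid.transmitter_frequency)
    # freqs ascend, so ppm descends already; keep canonical orientation
    return spectrum, ppm


def zero_order_phase(
    values: np.ndarray,
    ppm: np.ndarray,
    band: tuple[float, float] = (0.5, 4.2),
) -> tuple[np.ndarray, float]:
    """Constant ("zero-order") phase correction.

    The phase phi maximising the integral of Re(e^{i phi} S) over the
    metabolite band is phi = -arg(sum of S over the band), in closed form.
    Falls back to the whole axis when the band holds no points.  Returns
    the real part after rotation and the phase applied (radians).
    """
    values = np.asarray(values, dtype=complex)
    ppm = np.asarray(ppm, dtype=float)
    lo, hi = min(band), max(band)
    mask = (ppm >= lo) & (ppm <= hi)
    if not mask.any():
        mask = np.ones_like(ppm, dtype=bool)
    total = values[mask].sum()
    phi = 0.0 if total == 0 else float(-np.angle(total))
    return (values * np.exp(1j * phi)).real, phi


def _region_mask(ppm: np.ndarray, regions: Sequence[tuple[float, float]]) -> np.ndarray:
    mask = np.zeros(ppm.shape, dtype=bool)
    for lo, hi in regions:
        mask |= (ppm >= min(lo, hi)) & (ppm <= max(lo, hi))
    return mask


def baseline_offset(
    values: np.ndarray,
    ppm: np.ndarray,
    regions: Sequence[tuple[float, float]] = ((-2.0, -1.0), (9.0, 11.0)),
) -> np.ndarray:
    """Subtract the mean intensity over the baseline regions.

    Regions partially (or wholly) off the working axis contribute only
    their in-range points; it is an error for every region to be empty
    (on the canonical axis, which ends at 7.1 ppm, only the (-2, -1) ppm
    region contributes).
    """
    values = np.asarray(values, dtype=float)
    ppm = np.asarray(ppm, dtype=float)
    mask = _region_mask(ppm, regions)
    if not mask.any():
        raise ValueError("no baseline point falls on the working axis")
    return values - values[mask].mean()


def baseline_offset_canonical(
    spectrum: CanonicalSpectrum,
    params: ProcessingParams | None = None,
) -> CanonicalSpectrum:
    """Baseline offset correction of a canonical spectrum."""
    params = params or ProcessingParams()
    out = CanonicalSpectrum(
        baseline_offset(spectrum.intensities, spectrum.ppm, params.baseline_regions),
        spectrum.te_class,
        list(spectrum.provenance),
    )
    out.log(f"baseline_offset regions={params.baseline_regions}")
    return out


# ---------------------------------------------------------------------------
# Peak search, SNR and the alignment algorithm
# ---------------------------------------------------------------------------

def find_local_peak(
    values: np.ndarray,
    center_index: int,
    halfwidth_pts: int = 5,
) -> int | None:
    """Highest *strict* local maximum within +/-halfwidth of a grid index.

    A point counts as a peak only if its intensity strictly exceeds both
    contiguous neighbours; a monotone ramp therefore yields no peak.  Ties
    between equal-height peaks go to the smaller index (higher ppm).
    Returns None when the window holds no strict local maximum.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if not 0 <= center_index < n:
        raise ValueError(f"window centre {center_index} outside axis of length {n}")
    lo = max(center_index - halfwidth_pts, 1)
    hi = min(center_index + halfwidth_pts, n - 2)
    best: int | None = None
    for i in range(lo, hi + 1):
        if values[i] > values[i - 1] and values[i] > values[i + 1]:
            if best is None or values[i] > values[best]:
                best = i
    return best


def snr_estimate(
    values: np.ndarray,
    ppm: np.ndarray,
    peak_index: int,
    noise_region: tuple[float, float] = (9.0, 11.0),
    noise_region_fallback: tuple[float, float] = (-2.7, -1.7),
) -> float:
    """Peak height divided by the noise standard deviation.

    Noise is the sd of the intensities in ``noise_region``; when that region
    misses the working axis entirely (the canonical axis stops at 7.1 ppm),
    the fallback region at the lower end of the axis is used instead.
    """
    values = np.asarray(values, dtype=float)
    ppm = np.asarray(ppm, dtype=float)
    mask = _region_mask(ppm, [noise_region])
    if mask.sum() < 8:
        mask = _region_mask(ppm, [noise_region_fallback])
    if mask.sum() < 8:
        raise ValueError("noise region holds fewer than 8 points on this axis")
    sd = float(values[mask].std())
    if sd == 0:
        return np.inf if values[peak_index] > 0 else 0.0
    return float(values[peak_index]) / sd


def shift_spectrum(values: np.ndarray, k: int) -> np.ndarray:
    """Shift a 512-point spectrum by k whole points, zero-filling the border.

    Positive k prepends k zeros and drops k trailing points, moving spectral
    features toward higher index (lower ppm); negative k does the opposite.
    Length is conserved.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if abs(k) >= n:
        raise ValueError(f"|shift| must be < {n}, got {k}")
    if k == 0:
        return values.copy()
    if k > 0:
        return np.concatenate([np.zeros(k), values[:-k]])
    return np.concatenate([values[-k:], np.zeros(-k)])


def choose_alignment_reference(
    spectrum: CanonicalSpectrum,
    params: ProcessingParams | None = None,
) -> tuple[str, int]:
    """Pick the reference peak and point shift for automatic alignment.

    The tallest peak (TP) in the 0-4.5 ppm band sets the SNR yardstick.
    Candidates are tried in order creatine (3.03), choline (3.21), lipid
    (1.29 ppm): a candidate is accepted when a strict local peak exists
    within +/-5 points of its nominal position and that peak's SNR is at
    least SNR(TP) / 5.  Returns ("none", 0) when every candidate fails.
    """
    params = params or ProcessingParams()
    values = spectrum.intensities
    axis = PpmAxis()
    ppm = axis.values
    band = _region_mask(ppm, [params.tp_search_band])
    if not band.any():
        return "none", 0
    tp_index = int(np.flatnonzero(band)[np.argmax(values[band])])
    try:
        tp_snr = snr_estimate(
            values, ppm, tp_index, params.noise_region, params.noise_region_fallback
        )
    except ValueError:
        return "none", 0
    for name, nominal_ppm in params.reference_peaks:
        nominal_index = axis.index_of(nominal_ppm)
        found = find_local_peak(values, nominal_index, params.search_halfwidth_pts)
        if found is None:
            continue
        cand_snr = snr_estimate(
            values, ppm, found, params.noise_region, params.noise_region_fallback
        )
        if cand_snr >= tp_snr / params.tp_ratio:
            return name, nominal_index - found
    return "none", 0


def align(
    spectrum: CanonicalSpectrum,
    params: ProcessingParams | None = None,
) -> tuple[CanonicalSpectrum, AlignmentReport]:
    """Automatic alignment: shift so the chosen reference sits at its nominal ppm.

    When no reference qualifies the spectrum is returned unchanged with
    ``aligned=False``.
    """
    params = params or ProcessingParams()
    reference, shift = choose_alignment_reference(spectrum, params)
    if reference == "none":
        out = spectrum.copy()
        out.log("align: no reference found, left unchanged")
        return out, AlignmentReport("none", 0, False)
    out = CanonicalSpectrum(
        shift_spectrum(spectrum.intensities, shift),
        spectrum.te_class,
        list(spectrum.provenance),
    )
    out.log(f"align: reference={reference} shift={shift:+d} points")
    return out, AlignmentReport(reference, shift, True)


def process_pipeline(
    metabolite_fid: RawFID,
    water_fid: RawFID | None = None,
    params: ProcessingParams | None = None,
) -> CanonicalSpectrum:
    """Full automatic pipeline: FID in, aligned canonical spectrum out.

    Stage order: water filter -> apodize -> Fourier transform -> zero-order
    phase -> baseline offset -> linear resampling to 512 points -> align.
    The unsuppressed-water FID, when given, is not consumed here (it feeds
    quality control); it is accepted so callers can hand over a whole case.
    Every stage and its parameters are recorded in the provenance log.
    """
    params = params or ProcessingParams()
    log: list[str] = []

    def stage(name: str, fn, *args):
        try:
            return fn(*args)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    fid = stage("water_filter", water_filter, metabolite_fid, params)
    log.append(f"water_filter k={params.hlsvd_components} band={params.water_band} ppm")
    fid = stage("apodize", apodize, fid, params.lb_hz)
    log.append(f"apodize lb={params.lb_hz} Hz")
    complex_spec, ppm = stage("to_spectrum", to_spectrum, fid)
    log.append("to_spectrum (carrier at 4.7 ppm)")
    real_spec, phi = stage("zero_order_phase", zero_order_phase, complex_spec, ppm,
                           params.phase_band)
    log.append(f"zero_order_phase phi={phi:.4f} rad")
    real_spec = stage("baseline_offset", baseline_offset, real_spec, ppm,
                      params.baseline_regions)
    log.append(f"baseline_offset regions={params.baseline_regions}")
    canonical = stage("resample_linear", resample_linear, real_spec, ppm,
                      metabolite_fid.te_class)
    log.append(f"resample_linear -> {N_POINTS} points")
    canonical.provenance = log + canonical.provenance
    aligned, report = stage("align", align, canonical, params)
    return aligned
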