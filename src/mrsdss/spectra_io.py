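"""Canonical spectral format and jMRUI-style text IO.

The exchange currency of the whole toolkit is the *canonical spectrum*: 512
real intensities on a fixed, endpoint-inclusive, uniformly spaced chemical
shift grid running from 7.1 ppm (index 0) down to -2.7 ppm (index 511).
Canonical files (conventionally ``.art``) are plain ASCII: 512 whitespace
separated reals.

Raw time-domain acquisitions (FIDs) enter the system as jMRUI-style text
files: a ``Key: value`` header followed by two columns (real, imaginary)
of signal samples.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "PPM_MAX",
    "PPM_MIN",
    "N_POINTS",
    "TeClass",
    "Sequence_",
    "RawFID",
    "CanonicalSpectrum",
    "PpmAxis",
    "ppm_axis",
    "read_canonical",
    "write_canonical",
    "read_jmrui_text",
    "write_jmrui_text",
    "resample_linear",
    "FormatError",
]

#: Fixed canonical grid endpoints (ppm) and length.
PPM_MAX = 7.1
PPM_MIN = -2.7
N_POINTS = 512

#: Echo-time bands (ms) that define the short / long TE classes.
TE_SHORT_BAND = (20.0, 32.0)
TE_LONG_BAND = (135.0, 144.0)


class FormatError(ValueError):
    """A file does not conform to the documented dialect."""


class TeClass(str, enum.Enum):
    SHORT = "short"
    LONG = "long"
    OTHER = "other"


class Sequence_(str, enum.Enum):
    PRESS = "PRESS"
    STEAM = "STEAM"


def te_class_of(te_ms: float | None) -> TeClass:
    """Map an echo time in ms onto its TE class (short 20-32, long 135-144)."""
    if te_ms is None:
        return TeClass.OTHER
    if TE_SHORT_BAND[0] <= te_ms <= TE_SHORT_BAND[1]:
        return TeClass.SHORT
    if TE_LONG_BAND[0] <= te_ms <= TE_LONG_BAND[1]:
        return TeClass.LONG
    return TeClass.OTHER


@dataclass(frozen=True)
class RawFID:
    """A complex time-domain acquisition plus its sampling metadata.

    Parameters
    ----------
    samples : complex ndarray
        The FID, in arbitrary units.
    dwell_time : float
        Seconds per sample.
    transmitter_frequency : float
        Spectrometer frequency in MHz (~63.87 at 1.5 T for protons).
    te, tr : float, optional
        Echo / repetition time in ms.
    sequence : Sequence_, optional
        Localisation sequence (PRESS or STEAM).
    is_water_reference : bool
        True for the unsuppressed-water acquisition of a case.
    """

    samples: np.ndarray
    dwell_time: float
    transmitter_frequency: float
    te: float | None = None
    tr: float | None = None
    sequence: Sequence_ | None = None
    is_water_reference: bool = False

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=complex)
        if samples.ndim != 1 or samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D sequence")
        if not self.dwell_time > 0:
            raise ValueError("dwell_time must be positive")
        if not self.transmitter_frequency > 0:
            raise ValueError("transmitter_frequency must be positive")
        object.__setattr__(self, "samples", samples)

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def sweep_width(self) -> float:
        """Spectral width in Hz."""
        return 1.0 / self.dwell_time

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds (t = i * dwell_time)."""
        return np.arange(self.n) * self.dwell_time

    @property
    def te_class(self) -> TeClass:
        return te_class_of(self.te)

    def with_samples(self, samples: np.ndarray) -> "RawFID":
        return replace(self, samples=np.asarray(samples, dtype=complex))


@dataclass
class CanonicalSpectrum:
    """512 real intensities on the canonical 7.1 -> -2.7 ppm grid."""

    intensities: np.ndarray
    te_class: TeClass = TeClass.OTHER
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        values = np.asarray(self.intensities, dtype=float)
        if values.shape != (N_POINTS,):
            raise ValueError(
                f"canonical spectrum must have exactly {N_POINTS} points, "
                f"got shape {values.shape}"
            )
        self.intensities = values
        if isinstance(self.te_class, str):
            self.te_class = TeClass(self.te_class)

    @property
    def ppm(self) -> np.ndarray:
        return ppm_axis()

    def log(self, message: str) -> None:
        self.provenance.append(message)

    def copy(self) -> "CanonicalSpectrum":
        return CanonicalSpectrum(
            self.intensities.copy(), self.te_class, list(self.provenance)
        )


@dataclass(frozen=True)
class PpmAxis:
    """The endpoint-inclusive uniform chemical-shift grid convention.

    ``value(0) == ppm_max`` and ``value(n_points - 1) == ppm_min``; the step
    is therefore ``(ppm_max - ppm_min) / (n_points - 1)`` ppm per point
    (9.8/511 for the canonical grid) and ppm decreases strictly with index.
    """

    n_points: int = N_POINTS
    ppm_max: float = PPM_MAX
    ppm_min: float = PPM_MIN

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("a ppm axis needs at least 2 points")
        if not self.ppm_max > self.ppm_min:
            raise ValueError("ppm_max must exceed ppm_min")

    @property
    def step(self) -> float:
        """ppm per point (positive; the axis itself is descending)."""
        return (self.ppm_max - self.ppm_min) / (self.n_points - 1)

    @property
    def values(self) -> np.ndarray:
        return np.linspace(self.ppm_max, self.ppm_min, self.n_points)

    def index_of(self, ppm: float) -> int:
        """Nearest grid index for a chemical shift (clipped to the axis)."""
        i = round((self.ppm_max - ppm) / self.step)
        return int(min(max(i, 0), self.n_points - 1))

    def value_at(self, index: int) -> float:
        return self.ppm_max - index * self.step


def ppm_axis(n_points: int = N_POINTS) -> np.ndarray:
    """Descending endpoint-inclusive grid from 7.1 to -2.7 ppm."""
    return PpmAxis(n_points).values


# ---------------------------------------------------------------------------
# Canonical ".art" files: 512 whitespace-separated reals, one line on write.
# ---------------------------------------------------------------------------

def write_canonical(spectrum: CanonicalSpectrum, path: str | Path) -> None:
    """Write a canonical spectrum as 512 space-separated reals.

    Values are written with 6 significant digits (single precision); readers
    accept any whitespace, including newlines.
    """
    tokens = " ".join(f"{v:.6g}" for v in spectrum.intensities)
    Path(path).write_text(tokens + "\n")


def read_canonical(
    path: str | Path, te_class: TeClass | str = TeClass.OTHER
) -> CanonicalSpectrum:
    """Read a canonical file; exactly 512 numeric tokens are required."""
    text = Path(path).read_text()
    tokens = text.split()
    if len(tokens) != N_POINTS:
        raise FormatError(
            f"{path}: expected {N_POINTS} values, found {len(tokens)}"
        )
    try:
        values = np.array([float(t) for t in tokens])
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric token ({exc})") from None
    spectrum = CanonicalSpectrum(values, TeClass(te_class))
    spectrum.log(f"read_canonical {path}")
    return spectrum


# ---------------------------------------------------------------------------
# jMRUI-style text FIDs. Minimal dialect:
#   header lines  "Key: value"   (unknown keys ignored)
#   mandatory     SamplingInterval (ms), TransmitterFrequency (MHz)
#   data rows     sig(real) sig(imag) [further columns ignored]
# ---------------------------------------------------------------------------

_MANDATORY_KEYS = ("SamplingInterval", "TransmitterFrequency")


def read_jmrui_text(path: str | Path) -> RawFID:
    """Parse a jMRUI-style text FID (key: value header + two-column body)."""
    header: dict[str, str] = {}
    rows: list[tuple[float, float]] = []
    for raw_line in Path(path).read_text().splitlines():
        line = raw_line.strip()
        if not line:
            continue
        parts = line.split()
        try:
            values = [float(p) for p in parts[:2]]
            is_data = len(values) == 2
        except ValueError:
            is_data = False
        if is_data:
            rows.append((values[0], values[1]))
        elif ":" in line:
            key, _, value = line.partition(":")
            header[key.strip()] = value.strip()
        # anything else (banner lines, column captions) is ignored

    for key in _MANDATORY_KEYS:
        if key not in header:
            raise FormatError(f"{path}: missing mandatory header key {key!r}")
    if not rows:
        raise FormatError(f"{path}: no signal rows found")

    n_expected = header.get("PointsInDataset")
    if n_expected is not None and int(float(n_expected)) != len(rows):
        raise FormatError(
            f"{path}: PointsInDataset={n_expected} but {len(rows)} rows read"
        )

    data = np.asarray(rows)
    samples = data[:, 0] + 1j * data[:, 1]
    te = float(header["EchoTime"]) if "EchoTime" in header else None
    tr = float(header["RepetitionTime"]) if "RepetitionTime" in header else None
    seq = header.get("Sequence")
    return RawFID(
        samples=samples,
        dwell_time=float(header["SamplingInterval"]) * 1e-3,  # ms -> s
        transmitter_frequency=float(header["TransmitterFrequency"]),
        te=te,
        tr=tr,
        sequence=Sequence_(seq) if seq in ("PRESS", "STEAM") else None,
        is_water_reference=header.get("IsWaterReference", "0") in ("1", "true", "True"),
    )


def write_jmrui_text(fid: RawFID, path: str | Path) -> None:
    """Write a FID in the same minimal dialect read_jmrui_text accepts."""
    lines = [
        "jMRUI-style data text file",
        "",
        f"PointsInDataset: {fid.n}",
        "DatasetsInFile: 1",
        f"SamplingInterval: {fid.dwell_time * 1e3:.10g}",
        f"TransmitterFrequency: {fid.transmitter_frequency:.10g}",
    ]
    if fid.te is not None:
        lines.append(f"EchoTime: {fid.te:.10g}")
    if fid.tr is not None:
        lines.append(f"RepetitionTime: {fid.tr:.10g}")
    if fid.sequence is not None:
        lines.append(f"Sequence: {fid.sequence.value}")
    if fid.is_water_reference:
        lines.append("IsWaterReference: 1")
    lines.append("")
    lines.append("sig(real) sig(imag)")
    for z in fid.samples:
        lines.append(f"{z.real:.17g} {z.imag:.17g}")
    Path(path).write_text("\n".join(lines) + "\n")


def resample_linear(
    values: Sequence[float],
    source_axis: Sequence[float],
    te_class: TeClass | str = TeClass.OTHER,
) -> CanonicalSpectrum:
    """Piecewise-linear resampling of a spectrum onto the canonical 512-grid.

    The source axis may be ascending or descending in ppm; canonical grid
    points outside the source coverage are set to 0 rather than extrapolated.
    """
    values = np.asarray(values, dtype=float)
    source_axis = np.asarray(source_axis, dtype=float)
    if values.shape != source_axis.shape or values.ndim != 1:
        raise ValueError("values and source_axis must be 1-D of equal length")
    if values.size < 2:
        raise ValueError("at least 2 source points are required")
    diffs = np.diff(source_axis)
    if not (np.all(diffs > 0) or np.all(diffs < 0)):
        raise ValueError("source_axis must be strictly monotone")
    if diffs[0] < 0:  # np.interp wants an ascending abscissa
        source_axis = source_axis[::-1]
        values = values[::-1]
    target = ppm_axis()
    out = np.interp(target, source_axis, values, left=0.0, right=0.0)
    # np.interp clamps at the edges; zero anything strictly outside coverage
    out[(target < source_axis[0]) | (target > source_axis[-1])] = 0.0
    spectrum = CanonicalSpectrum(out, TeClass(te_class))
    spectrum.log(f"resample_linear from {values.size} source points")
    return spectrum
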