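"""Synthetic FIDs, spectra and labelled datasets.

Every other module is testable without clinical data through this module:
it generates class-conditional FIDs as sums of damped complex exponentials
(one per metabolite resonance) plus a residual water component at 4.7 ppm
and complex Gaussian noise.

The default class profiles are *invented*, qualitative caricatures of the
in-vivo MRS literature — meningioma: high choline, low NAA; aggressive
(glioblastoma/metastasis): dominant mobile lipids, low NAA; low-grade glial:
moderate NAA and choline; normal white matter: high NAA; pseudotumoural:
reduced NAA with mild choline — sufficient to exercise the processing and
classification pipeline, with no claim of clinical realism.  At long TE the
lactate doublet appears inverted (phase pi), lipids and myo-inositol are
attenuated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .preprocess import ProcessingParams, frequency_of_ppm, process_pipeline
from .spectra_io import CanonicalSpectrum, RawFID, Sequence_, TeClass, ppm_axis
from .classify import LabeledDataset, restrict_range, normalize

__all__ = [
    "AcquisitionSpec",
    "MetabolitePeak",
    "ClassProfile",
    "DEFAULT_PROFILES",
    "default_profiles",
    "simulate_fid",
    "simulate_water_fid",
    "simulate_dataset",
    "displaced_spectrum",
    "lorentzian_canonical",
]

#: Metabolite resonance positions (ppm) used by the generator.
METABOLITE_PPM = {
    "NAA": 2.01,
    "Cr": 3.03,
    "Cho": 3.21,
    "mI": 3.55,
    "Lac": 1.31,
    "Lip13": 1.29,
    "Lip09": 0.90,
    "Glx": 2.35,
}


@dataclass(frozen=True)
class AcquisitionSpec:
    """Sampling parameters; defaults emulate a 1.5 T proton acquisition."""

    n_points: int = 2048
    sweep_width_hz: float = 2500.0
    transmitter_frequency: float = 63.87  # MHz

    @property
    def dwell_time(self) -> float:
        return 1.0 / self.sweep_width_hz


@dataclass(frozen=True)
class MetabolitePeak:
    name: str
    ppm: float
    amplitude: float
    linewidth_hz: float = 4.0
    phase: float = 0.0

    def __post_init__(self) -> None:
        if not self.linewidth_hz > 0:
            raise ValueError("linewidth must be positive")


@dataclass(frozen=True)
class ClassProfile:
    """Per-superclass recipe: amplitude mean/sd per metabolite and TE class.

    ``amplitudes`` maps metabolite name -> {TeClass: (mean, sd)}; metabolites
    absent from the map are omitted.  ``invert_lactate_long_te`` flips the
    lactate phase by pi at long TE (the J-modulation inversion).
    """

    name: str
    amplitudes: dict[str, dict[TeClass, tuple[float, float]]]
    invert_lactate_long_te: bool = True
    water_amplitude: float = 40.0
    noise_sd: float = 0.05
    linewidth_hz: float = 4.0

    def __post_init__(self) -> None:
        for metabolite, by_te in self.amplitudes.items():
            for te, (mean, sd) in by_te.items():
                if sd < 0:
                    raise ValueError(f"{metabolite}@{te}: sd must be >= 0")


def _amps(short: dict[str, tuple[float, float]],
          long: dict[str, tuple[float, float]]) -> dict:
    out: dict[str, dict[TeClass, tuple[float, float]]] = {}
    for name, ms in short.items():
        out.setdefault(name, {})[TeClass.SHORT] = ms
    for name, ms in long.items():
        out.setdefault(name, {})[TeClass.LONG] = ms
    return out


def default_profiles() -> dict[str, ClassProfile]:
    """The invented default superclass profiles (see module docstring)."""
    return {
        "meningioma": ClassProfile(
            "meningioma",
            _amps(
                short={"Cho": (8.0, 1.0), "NAA": (1.0, 0.3), "Cr": (1.5, 0.4),
                       "mI": (0.8, 0.3), "Glx": (3.0, 0.8), "Lip13": (1.0, 0.5)},
                long={"Cho": (7.0, 1.0), "NAA": (0.8, 0.3), "Cr": (1.2, 0.4),
                      "mI": (0.3, 0.15), "Glx": (1.0, 0.4)},
            ),
        ),
        "aggressive": ClassProfile(
            "aggressive",
            _amps(
                short={"Lip13": (10.0, 2.0), "Lip09": (5.0, 1.2), "Cho": (3.0, 0.8),
                       "NAA": (1.0, 0.4), "Cr": (1.0, 0.4), "Lac": (2.0, 0.8)},
                long={"Lip13": (5.0, 1.5), "Lip09": (2.0, 0.8), "Cho": (3.0, 0.8),
                      "NAA": (0.8, 0.3), "Cr": (0.8, 0.3), "Lac": (2.5, 0.8)},
            ),
        ),
        "low-grade glial": ClassProfile(
            "low-grade glial",
            _amps(
                short={"NAA": (4.0, 0.8), "Cho": (3.0, 0.6), "Cr": (3.0, 0.6),
                       "mI": (3.0, 0.8), "Lac": (0.8, 0.4)},
                long={"NAA": (3.5, 0.8), "Cho": (2.8, 0.6), "Cr": (2.5, 0.6),
                      "mI": (1.2, 0.4), "Lac": (1.0, 0.4)},
            ),
        ),
        "normal": ClassProfile(
            "normal",
            _amps(
                short={"NAA": (8.0, 0.8), "Cr": (4.0, 0.5), "Cho": (2.0, 0.4),
                       "mI": (2.0, 0.5), "Glx": (2.0, 0.5)},
                long={"NAA": (7.0, 0.8), "Cr": (3.5, 0.5), "Cho": (1.8, 0.4),
                      "mI": (0.8, 0.3)},
            ),
        ),
        "pseudotumoural": ClassProfile(
            "pseudotumoural",
            _amps(
                short={"NAA": (3.0, 0.7), "Cho": (2.5, 0.5), "Cr": (3.0, 0.6),
                       "mI": (2.0, 0.6), "Lac": (1.5, 0.6)},
                long={"NAA": (2.8, 0.7), "Cho": (2.3, 0.5), "Cr": (2.6, 0.6),
                      "mI": (0.9, 0.3), "Lac": (1.8, 0.6)},
            ),
        ),
        "tumoural": ClassProfile(
            "tumoural",
            _amps(
                short={"NAA": (2.0, 0.5), "Cho": (5.0, 0.9), "Cr": (2.5, 0.6),
                       "mI": (2.5, 0.7), "Lac": (1.5, 0.6)},
                long={"NAA": (1.8, 0.5), "Cho": (4.5, 0.9), "Cr": (2.2, 0.6),
                      "mI": (1.0, 0.4), "Lac": (2.0, 0.7)},
            ),
        ),
    }


DEFAULT_PROFILES = default_profiles()


def _te_ms(te_class: TeClass) -> float:
    return {TeClass.SHORT: 30.0, TeClass.LONG: 136.0}.get(te_class, 60.0)


def simulate_fid(
    profile: ClassProfile,
    te_class: TeClass | str = TeClass.SHORT,
    acq: AcquisitionSpec | None = None,
    seed: int | np.random.Generator = 0,
) -> RawFID:
    """Draw one synthetic metabolite FID from a class profile.

    Each metabolite contributes a damped complex exponential at its
    ppm-mapped offset frequency with amplitude ~ N(mean, sd) truncated at 0;
    a residual water exponential sits at 4.7 ppm (0 Hz) and complex Gaussian
    noise of the profile's sd is added.  Deterministic per seed.
    """
    te_class = TeClass(te_class)
    acq = acq or AcquisitionSpec()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = np.arange(acq.n_points) * acq.dwell_time
    signal = np.zeros(acq.n_points, dtype=complex)
    damping = np.pi * profile.linewidth_hz  # lorentzian FWHM -> damping
    for name, by_te in profile.amplitudes.items():
        if te_class not in by_te:
            continue
        mean, sd = by_te[te_class]
        amplitude = max(float(rng.normal(mean, sd)), 0.0)
        if amplitude == 0.0:
            continue
        phase = 0.0
        if (
            name == "Lac"
            and te_class is TeClass.LONG
            and profile.invert_lactate_long_te
        ):
            phase = np.pi
        f = float(frequency_of_ppm(METABOLITE_PPM[name], acq.transmitter_frequency))
        signal += amplitude * np.exp(1j * phase) * np.exp((-damping + 2j * np.pi * f) * t)
    # residual water at the carrier, slightly broader than the metabolites
    signal += profile.water_amplitude * np.exp(-np.pi * 6.0 * t)
    noise = rng.normal(0.0, profile.noise_sd, size=(2, acq.n_points))
    signal += noise[0] + 1j * noise[1]
    return RawFID(
        samples=signal,
        dwell_time=acq.dwell_time,
        transmitter_frequency=acq.transmitter_frequency,
        te=_te_ms(te_class),
        tr=2000.0,
        sequence=Sequence_.PRESS,
    )


def simulate_water_fid(
    linewidth_hz: float = 5.0,
    amplitude: float = 1000.0,
    acq: AcquisitionSpec | None = None,
    noise_sd: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> RawFID:
    """Unsuppressed-water acquisition: one lorentzian at 4.7 ppm."""
    acq = acq or AcquisitionSpec()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = np.arange(acq.n_points) * acq.dwell_time
    signal = amplitude * np.exp(-np.pi * linewidth_hz * t).astype(complex)
    noise = rng.normal(0.0, noise_sd, size=(2, acq.n_points))
    signal += noise[0] + 1j * noise[1]
    return RawFID(
        samples=signal,
        dwell_time=acq.dwell_time,
        transmitter_frequency=acq.transmitter_frequency,
        is_water_reference=True,
    )


def simulate_dataset(
    profiles: dict[str, ClassProfile] | list[ClassProfile] | None = None,
    n_per_class: int = 20,
    te_mode: str = "short",
    seed: int = 0,
    acq: AcquisitionSpec | None = None,
    params: ProcessingParams | None = None,
    return_fids: bool = False,
    norm: str = "unit",
):
    """Balanced labelled dataset of processed canonical spectra.

    Each case is simulated as raw FID(s), run through the full automatic
    pipeline, restricted to the 4.05-0.01 ppm analysis window and (by
    default) normalised to unit Euclidean norm.  ``te_mode`` is "short",
    "long" or "concat" (restricted short vector followed by restricted
    long vector).  Reproducible per seed.
    """
    from .classify import concat_te  # local import to avoid cycle at module load

    if profiles is None:
        d = default_profiles()
        profiles = [d["meningioma"], d["aggressive"], d["low-grade glial"]]
    if isinstance(profiles, dict):
        profiles = list(profiles.values())
    if len(profiles) < 1:
        raise ValueError("at least one profile required")
    if te_mode not in ("short", "long", "concat"):
        raise ValueError(f"unknown te_mode {te_mode!r}")
    acq = acq or AcquisitionSpec()
    params = params or ProcessingParams()
    rng = np.random.default_rng(seed)

    vectors: list[np.ndarray] = []
    labels: list[str] = []
    fids: list[dict] = []
    for profile in profiles:
        for _ in range(n_per_class):
            case_fids: dict[str, RawFID] = {}
            spectra: dict[str, CanonicalSpectrum] = {}
            te_classes = (
                [TeClass.SHORT, TeClass.LONG] if te_mode == "concat"
                else [TeClass(te_mode)]
            )
            for tc in te_classes:
                fid = simulate_fid(profile, tc, acq, rng)
                case_fids[tc.value] = fid
                spectra[tc.value] = process_pipeline(fid, None, params)
            if te_mode == "concat":
                vec = concat_te(spectra["short"], spectra["long"], norm=norm)
            else:
                vec = normalize(restrict_range(spectra[te_mode]), norm)
            vectors.append(vec)
            labels.append(profile.name)
            if return_fids:
                fids.append(case_fids)

    dataset = LabeledDataset.from_vectors(
        np.asarray(vectors) if vectors else np.empty((0, 0)),
        labels,
        te_mode=te_mode,
    )
    if return_fids:
        return dataset, fids
    return dataset


def lorentzian_canonical(
    center_ppm: float,
    height: float = 100.0,
    fwhm_ppm: float = 0.06,
    noise_sd: float = 0.0,
    seed: int = 0,
    te_class: TeClass = TeClass.SHORT,
) -> CanonicalSpectrum:
    """A single lorentzian line drawn directly on the canonical grid."""
    ppm = ppm_axis()
    half = fwhm_ppm / 2.0
    values = height * half**2 / ((ppm - center_ppm) ** 2 + half**2)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sd, values.size)
    return CanonicalSpectrum(values, te_class)


def displaced_spectrum(
    base: CanonicalSpectrum,
    k: int,
    seed: int | None = None,
    noise_sd: float = 0.0,
) -> CanonicalSpectrum:
    """Shift a canonical spectrum by k points (optionally adding fresh noise).

    Alignment-test fixture: ``align(displaced_spectrum(s, k))`` should
    restore the reference peak of ``s`` when |k| stays inside the search
    window.
    """
    from .preprocess import shift_spectrum

    values = shift_spectrum(base.intensities, k)
    if noise_sd > 0 and seed is not None:
        values = values + np.random.default_rng(seed).normal(0.0, noise_sd, values.size)
    out = CanonicalSpectrum(values, base.te_class, list(base.provenance))
    out.log(f"displaced by {k:+d} points")
    return out
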