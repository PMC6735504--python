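"""Spectral band analysis of passive cavitation detector (PCD) recordings.

During microbubble-enhanced focused ultrasound at a 230 kHz fundamental,
circulating microbubbles emit acoustic signatures that classify the
cavitation regime: harmonics of the drive frequency (460 and 690 kHz)
indicate stable volumetric oscillation, while subharmonic (115 kHz) and
broadband emissions mark the approach to, or onset of, inertial cavitation
(violent bubble collapse associated with vascular damage).

This module converts sampled hydrophone traces into per-burst band
magnitudes, calibrates noise floors from burst ensembles, and applies the
statistical detection rules that gate the safety logic of the closed-loop
power controller: subharmonic events are flagged above 3.2 standard
deviations over the early-burst noise floor, broadband events above 3.9.

Band powers are reported as ``10*log10`` of the summed one-sided spectral
power inside each bin (Hann window over the full burst, single segment).
The dB scale is arbitrary until referenced to a noise floor; the harmonic
enhancement ``H`` — the controlled variable — is the mean elevation of the
2nd and 3rd harmonic bands above the pre-sonication floor, in dB.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.signal.windows import hann

__all__ = [
    "BAND_NAMES",
    "SILENCE_FLOOR_DB",
    "BandScheme",
    "BurstSpectrum",
    "NoiseFloor",
    "DetectionResult",
    "compute_band_powers",
    "calibrate_noise_floor",
    "detect_events",
]

#: Canonical band labels, in ascending frequency of the narrow bands.
BAND_NAMES: tuple[str, ...] = ("subharmonic", "harmonic2", "harmonic3", "broadband")

#: Finite sentinel substituted for -inf dB when a band carries zero energy.
SILENCE_FLOOR_DB: float = -120.0


@dataclass(frozen=True)
class BandScheme:
    """Frequency-bin layout of the two-detector emission analysis.

    Defaults describe a 230 kHz drive: subharmonic at half the fundamental
    in a 10 kHz bin, 2nd/3rd harmonics at 460/690 kHz in 10 kHz bins, and
    a 40 kHz broadband bin centered on the second hydrophone's 660 kHz
    resonance (chosen to exclude both harmonic bins).
    """

    fundamental_hz: float = 230e3
    subharmonic_center_hz: float = 115e3
    harmonic_centers_hz: tuple[float, float] = (460e3, 690e3)
    broadband_center_hz: float = 660e3
    narrow_bin_width_hz: float = 10e3
    broadband_bin_width_hz: float = 40e3

    def __post_init__(self) -> None:
        f0 = self.fundamental_hz
        if f0 <= 0 or self.narrow_bin_width_hz <= 0 or self.broadband_bin_width_hz <= 0:
            raise ValueError("frequencies and bin widths must be positive")
        if not math.isclose(self.subharmonic_center_hz, f0 / 2, rel_tol=1e-9):
            raise ValueError("subharmonic center must equal fundamental/2")
        h2, h3 = self.harmonic_centers_hz
        if not (math.isclose(h2, 2 * f0, rel_tol=1e-9) and math.isclose(h3, 3 * f0, rel_tol=1e-9)):
            raise ValueError("harmonic centers must equal 2x and 3x the fundamental")
        lo, hi = self.band_edges()["broadband"]
        if lo <= h2 <= hi or lo <= h3 <= hi:
            raise ValueError("broadband bin must exclude both harmonic centers")

    def band_edges(self) -> dict[str, tuple[float, float]]:
        """(low, high) edge in Hz for each named band."""
        nh = self.narrow_bin_width_hz / 2
        bh = self.broadband_bin_width_hz / 2
        h2, h3 = self.harmonic_centers_hz
        return {
            "subharmonic": (self.subharmonic_center_hz - nh, self.subharmonic_center_hz + nh),
            "harmonic2": (h2 - nh, h2 + nh),
            "harmonic3": (h3 - nh, h3 + nh),
            "broadband": (self.broadband_center_hz - bh, self.broadband_center_hz + bh),
        }

    def band_centers(self) -> dict[str, float]:
        h2, h3 = self.harmonic_centers_hz
        return {
            "subharmonic": self.subharmonic_center_hz,
            "harmonic2": h2,
            "harmonic3": h3,
            "broadband": self.broadband_center_hz,
        }

    @property
    def max_edge_hz(self) -> float:
        return max(hi for _, hi in self.band_edges().values())


@dataclass
class BurstSpectrum:
    """Band-resolved emission magnitudes for one 5 ms burst.

    ``detector`` records which hydrophone a band table came from (1 carries
    the subharmonic band, 2 the harmonic and broadband bands); ``None``
    denotes a merged table with all four bands, the usual in-memory form.
    """

    band_power_db: dict[str, float]
    burst_index: int = 0
    target_index: int = 0
    time_s: float = 0.0
    detector: int | None = None
    applied_power_w: float = float("nan")

    def __post_init__(self) -> None:
        if self.time_s < 0:
            raise ValueError("time_s must be >= 0")
        for band, val in self.band_power_db.items():
            if not np.isfinite(val):
                raise ValueError(f"non-finite power in band {band!r}")


@dataclass(frozen=True)
class NoiseFloor:
    """Per-band mean and sample SD of band power across a burst ensemble."""

    mean_db: Mapping[str, float]
    sd_db: Mapping[str, float]
    source: str
    n_samples: int

    def threshold_db(self, band: str, k: float) -> float:
        """Detection threshold: mean + k standard deviations, in dB."""
        return self.mean_db[band] + k * self.sd_db[band]


@dataclass(frozen=True)
class DetectionResult:
    """Outcome of the per-burst safety/control analysis.

    ``harmonic_enhancement_db`` is H, the mean elevation of the 2nd and 3rd
    harmonic bands over the pre-sonication floor; the flags are the strict
    threshold exceedances that trigger the 25% power reduction.
    """

    harmonic_enhancement_db: float
    subharmonic_flag: bool
    broadband_flag: bool


def compute_band_powers(
    waveform: np.ndarray,
    sample_rate: float,
    scheme: BandScheme | None = None,
    *,
    min_duration_s: float = 0.005,
    burst_index: int = 0,
    target_index: int = 0,
    time_s: float = 0.0,
    detector: int | None = None,
    applied_power_w: float = float("nan"),
) -> BurstSpectrum:
    """Integrate a sampled pressure trace into per-band dB powers.

    A Hann window is applied over the full burst (single segment — bursts
    are short and stationary) and the one-sided spectrum is summed over
    each band, normalized so a pure tone of amplitude A at a band center
    contributes A^2/2 to that band. Zero-energy bands are guarded to the
    finite sentinel :data:`SILENCE_FLOOR_DB`.

    Raises ``ValueError`` if the trace is empty or shorter than one burst,
    or if ``sample_rate`` is below Nyquist for the highest band edge.
    """
    scheme = scheme or BandScheme()
    x = np.asarray(waveform, dtype=float)
    if x.size == 0:
        raise ValueError("empty waveform")
    if sample_rate <= 2 * scheme.max_edge_hz:
        raise ValueError(
            f"sample rate {sample_rate:g} Hz is below Nyquist for the highest "
            f"band edge ({scheme.max_edge_hz:g} Hz); need > {2 * scheme.max_edge_hz:g} Hz"
        )
    if x.size / sample_rate < min_duration_s:
        raise ValueError(
            f"waveform of {x.size / sample_rate * 1e3:.3f} ms is shorter than "
            f"one burst ({min_duration_s * 1e3:g} ms)"
        )

    n = x.size
    w = hann(n, sym=False)
    spectrum = np.fft.rfft(x * w)
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate)
    # one-sided power normalized so a unit-amplitude tone integrates to 1/2
    power = np.abs(spectrum) ** 2 / (n * np.sum(w**2))
    power[1:] *= 2.0
    if n % 2 == 0:
        power[-1] /= 2.0

    band_power_db: dict[str, float] = {}
    for band, (lo, hi) in scheme.band_edges().items():
        sel = (freqs >= lo) & (freqs < hi)
        total = float(np.sum(power[sel]))
        band_power_db[band] = 10 * math.log10(total) if total > 0 else SILENCE_FLOOR_DB
    return BurstSpectrum(
        band_power_db=band_power_db,
        burst_index=burst_index,
        target_index=target_index,
        time_s=time_s,
        detector=detector,
        applied_power_w=applied_power_w,
    )


def calibrate_noise_floor(
    spectra: Sequence[BurstSpectrum] | Iterable[BurstSpectrum],
    source: str = "pre_sonication",
) -> NoiseFloor:
    """Per-band mean and sample SD of band power over a burst ensemble.

    Two floors are used in practice: a 3.5 s pre-sonication acquisition
    (reference for the harmonic enhancement H) and the first 8 s of
    low-power bursts before microbubble arrival (reference for the
    subharmonic/broadband event thresholds).
    """
    spectra = list(spectra)
    if len(spectra) < 2:
        raise ValueError("noise-floor calibration requires at least 2 spectra")
    bands = set(spectra[0].band_power_db)
    for s in spectra[1:]:
        bands &= set(s.band_power_db)
    if not bands:
        raise ValueError("spectra share no common bands")
    mean_db, sd_db = {}, {}
    for band in sorted(bands):
        vals = np.array([s.band_power_db[band] for s in spectra])
        mean_db[band] = float(np.mean(vals))
        sd_db[band] = float(np.std(vals, ddof=1))
    return NoiseFloor(mean_db=mean_db, sd_db=sd_db, source=source, n_samples=len(spectra))


def detect_events(
    burst: BurstSpectrum,
    floor_early: NoiseFloor,
    floor_pre: NoiseFloor | None = None,
    k_sub: float = 3.2,
    k_bb: float = 3.9,
) -> DetectionResult:
    """Apply the per-burst detection rules.

    Subharmonic/broadband flags raise when band power strictly exceeds the
    early-burst floor mean plus ``k_sub`` (3.2) / ``k_bb`` (3.9) SDs;
    boundary equality is treated as a non-event. H is the dB-domain mean of
    the 2nd and 3rd harmonic elevations over the pre-sonication floor
    (``floor_pre``; falls back to ``floor_early`` when only one floor was
    measured).
    """
    if floor_pre is None:
        floor_pre = floor_early
    for band in BAND_NAMES:
        if band not in burst.band_power_db:
            raise ValueError(f"burst spectrum is missing band {band!r}")
        if band not in floor_early.mean_db or band not in floor_pre.mean_db:
            raise ValueError(f"noise floor is missing band {band!r}")

    sub_flag = burst.band_power_db["subharmonic"] > floor_early.threshold_db("subharmonic", k_sub)
    bb_flag = burst.band_power_db["broadband"] > floor_early.threshold_db("broadband", k_bb)
    h = 0.5 * (
        (burst.band_power_db["harmonic2"] - floor_pre.mean_db["harmonic2"])
        + (burst.band_power_db["harmonic3"] - floor_pre.mean_db["harmonic3"])
    )
    return DetectionResult(
        harmonic_enhancement_db=float(h),
        subharmonic_flag=bool(sub_flag),
        broadband_flag=bool(bb_flag),
    )
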