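"""Seeded synthetic NIR dataset generator.

The generator emulates the statistical structure the analysis assumes for
powdered plant material scanned in diffuse reflectance: each class has a
characteristic absorbance profile built from Gaussian bands (a backbone of
broad overtone/combination bands shared by every class plus a few
class-specific bands), and each measured sample perturbs its class profile
with

* multiplicative scatter gain  a ~ 1 + N(0, gain_sd),
* an additive offset           b ~ N(0, offset_sd),
* a smooth quadratic baseline drift, and
* white measurement noise      N(0, noise_sd),

i.e. sample = a * profile + b + baseline + noise — exactly the effects SNV,
derivatives and scaling are designed to remove.  With ``separation="low"``
the class-specific bands are small and confined to the weak-difference
windows 4900-5100 and 7200-8000 cm^-1, mimicking nearly identical samples
that differ only in subtle localized features.

All randomness flows from explicit seeds through named generators; output
is bit-identical for a fixed seed.  The default axis matches a typical FT
NIR scan: 10,000 -> 4,000 cm^-1 at 8 cm^-1 resolution (751 points).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import InputError, ParameterError
from .spectra import SpectralDataset, Spectrum, WavenumberAxis

__all__ = [
    "ClassProfile",
    "NoiseModel",
    "WEAK_WINDOWS",
    "DEFAULT_CLASS_SIZES",
    "DEFAULT_SEED",
    "make_axis",
    "generate_profiles",
    "generate_dataset",
    "generate_materials",
]

#: wavenumber windows (cm^-1) carrying the weak localized class differences
WEAK_WINDOWS = ((4900.0, 5100.0), (7200.0, 8000.0))

#: the 51-sample, 10-class study design
DEFAULT_CLASS_SIZES = (4, 3, 6, 5, 10, 3, 8, 4, 4, 4)

DEFAULT_SEED = 20240601


@dataclass(frozen=True)
class ClassProfile:
    """Gaussian-band absorbance profile of one class."""

    peak_centers: np.ndarray  # cm^-1
    peak_widths: np.ndarray  # Gaussian sigma, cm^-1
    peak_amplitudes: np.ndarray  # absorbance units

    def __post_init__(self) -> None:
        c = np.asarray(self.peak_centers, dtype=float)
        w = np.asarray(self.peak_widths, dtype=float)
        a = np.asarray(self.peak_amplitudes, dtype=float)
        if not (c.shape == w.shape == a.shape) or c.ndim != 1:
            raise InputError("peak lists must be equal-length 1-D arrays")
        if np.any(w <= 0):
            raise InputError("peak widths must be > 0")
        for name, arr in (("peak_centers", c), ("peak_widths", w), ("peak_amplitudes", a)):
            arr.flags.writeable = False
            object.__setattr__(self, name, arr)

    def evaluate(self, axis: WavenumberAxis) -> np.ndarray:
        """Noise-free class spectrum: sum of Gaussian bands on the axis."""
        w = axis.points[:, None]
        return np.sum(
            self.peak_amplitudes
            * np.exp(-((w - self.peak_centers) ** 2) / (2.0 * self.peak_widths**2)),
            axis=1,
        )


@dataclass(frozen=True)
class NoiseModel:
    """Per-sample measurement perturbations (all sds >= 0).

    Defaults reflect a well-controlled FT NIR measurement of powdered
    samples: a few percent multiplicative scatter, a small additive offset,
    gentle quadratic baseline drift, and low white noise relative to band
    amplitudes of order 1 absorbance unit."""

    gain_sd: float = 0.05
    offset_sd: float = 0.02
    baseline_coeffs_sd: tuple[float, float, float] = (0.02, 0.01, 0.005)
    noise_sd: float = 0.002
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        sds = (self.gain_sd, self.offset_sd, *self.baseline_coeffs_sd, self.noise_sd)
        if any(s < 0 for s in sds):
            raise InputError("all noise standard deviations must be >= 0")


def make_axis(
    start: float = 10000.0, stop: float = 4000.0, step: float = 8.0
) -> WavenumberAxis:
    """Descending axis from ``start`` down to ``stop`` inclusive.

    ``(start - stop)`` must be an integer multiple of ``step``; defaults
    give 751 points."""
    if not start > stop:
        raise ParameterError(f"start ({start}) must exceed stop ({stop})")
    if not step > 0:
        raise ParameterError(f"step must be > 0, got {step}")
    span = start - stop
    n_steps = span / step
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ParameterError(
            f"range {start}..{stop} is not divisible by step {step}"
        )
    n = int(round(n_steps)) + 1
    return WavenumberAxis(start - step * np.arange(n))


def _random_peaks(
    rng: np.random.Generator,
    n_peaks: int,
    lo: float,
    hi: float,
    width_range: tuple[float, float],
    amp_range: tuple[float, float],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    centers = rng.uniform(lo, hi, n_peaks)
    widths = rng.uniform(*width_range, n_peaks)
    amps = rng.uniform(*amp_range, n_peaks)
    return centers, widths, amps


def generate_profiles(
    n_classes: int,
    axis: WavenumberAxis,
    separation: str = "high",
    seed: int = DEFAULT_SEED,
    n_backbone_peaks: int = 7,
    n_class_peaks: int = 3,
) -> list[ClassProfile]:
    """Class profiles sharing one random backbone, plus class-specific bands.

    ``separation="high"`` places the class-specific bands anywhere on the
    axis with amplitudes 15-35% of the strongest backbone band;
    ``"low"`` confines them to the weak-difference windows with amplitudes
    at most 10% of the strongest backbone band."""
    if n_classes < 2:
        raise ParameterError(f"need at least 2 classes, got {n_classes}")
    if separation not in ("low", "high"):
        raise ParameterError(f"separation must be 'low' or 'high', got {separation!r}")
    rng = np.random.default_rng(seed)
    lo = float(axis.points.min())
    hi = float(axis.points.max())
    bb_c, bb_w, bb_a = _random_peaks(
        rng, n_backbone_peaks, lo, hi, width_range=(120.0, 400.0), amp_range=(0.2, 1.0)
    )
    max_bb = float(bb_a.max())
    profiles = []
    for _ in range(n_classes):
        if separation == "high":
            c, w, a = _random_peaks(
                rng, n_class_peaks, lo, hi,
                width_range=(40.0, 150.0),
                amp_range=(0.15 * max_bb, 0.35 * max_bb),
            )
        else:
            windows = [rng.integers(len(WEAK_WINDOWS)) for _ in range(n_class_peaks)]
            c = np.array([rng.uniform(*WEAK_WINDOWS[k]) for k in windows])
            w = rng.uniform(30.0, 80.0, n_class_peaks)
            a = rng.uniform(0.02 * max_bb, 0.10 * max_bb, n_class_peaks)
        profiles.append(
            ClassProfile(
                np.concatenate([bb_c, c]),
                np.concatenate([bb_w, w]),
                np.concatenate([bb_a, a]),
            )
        )
    return profiles


def _measure(
    clean: np.ndarray, noise: NoiseModel, rng: np.random.Generator, n: int
) -> np.ndarray:
    """One noisy measurement of a clean profile."""
    t = np.linspace(-1.0, 1.0, n)
    a = 1.0 + rng.normal(0.0, noise.gain_sd) if noise.gain_sd else 1.0
    b = rng.normal(0.0, noise.offset_sd) if noise.offset_sd else 0.0
    coeffs = [rng.normal(0.0, sd) if sd else 0.0 for sd in noise.baseline_coeffs_sd]
    baseline = coeffs[0] + coeffs[1] * t + coeffs[2] * t**2
    white = rng.normal(0.0, noise.noise_sd, n) if noise.noise_sd else 0.0
    return a * clean + b + baseline + white


def generate_dataset(
    profiles: Sequence[ClassProfile],
    class_sizes: Sequence[int],
    noise: NoiseModel | None = None,
    axis: WavenumberAxis | None = None,
) -> SpectralDataset:
    """Labeled dataset with ``class_sizes[k]`` noisy measurements of each
    class profile.  Deterministic for a fixed ``noise.seed``.

    Sample ids are ``c<k>_s<i>``; labels are ``class_<k>`` (1-based,
    zero-padded)."""
    if noise is None:
        noise = NoiseModel()
    if axis is None:
        axis = make_axis()
    if len(profiles) != len(class_sizes):
        raise InputError(
            f"{len(profiles)} profiles but {len(class_sizes)} class sizes"
        )
    rng = np.random.default_rng(noise.seed)
    n = len(axis)
    spectra: list[Spectrum] = []
    labels: dict[str, str] = {}
    for k, (profile, size) in enumerate(zip(profiles, class_sizes), start=1):
        clean = profile.evaluate(axis)
        for i in range(1, size + 1):
            sid = f"c{k:02d}_s{i:02d}"
            spectra.append(Spectrum(sid, _measure(clean, noise, rng, n)))
            labels[sid] = f"class_{k:02d}"
    return SpectralDataset(axis, spectra, labels)


def generate_materials(
    n_similar_pairs: int,
    n_dissimilar_pairs: int,
    axis: WavenumberAxis | None = None,
    noise: NoiseModel | None = None,
    seed: int = DEFAULT_SEED,
) -> SpectralDataset:
    """Material fixtures for replacement studies.

    A "similar" pair shares its full band set, with ~2% amplitude jitter on
    the second member (candidate substitutes of near-identical origin); a
    "dissimilar" pair has two independently drawn band sets sharing no
    specific bands.  Each member then receives one noisy measurement.
    Sample ids: ``sim<p>_a/b`` and ``dis<p>_a/b``, labeled
    ``similar_pair_<p>`` / ``dissimilar_pair_<p>``."""
    if n_similar_pairs < 0 or n_dissimilar_pairs < 0:
        raise ParameterError("pair counts must be >= 0")
    if axis is None:
        axis = make_axis()
    if noise is None:
        noise = NoiseModel(seed=seed)
    rng = np.random.default_rng(seed)
    lo = float(axis.points.min())
    hi = float(axis.points.max())
    n = len(axis)
    spectra: list[Spectrum] = []
    labels: dict[str, str] = {}

    def emit(sid: str, label: str, profile: ClassProfile) -> None:
        spectra.append(Spectrum(sid, _measure(profile.evaluate(axis), noise, rng, n)))
        labels[sid] = label

    for p in range(1, n_similar_pairs + 1):
        c, w, a = _random_peaks(rng, 6, lo, hi, (80.0, 300.0), (0.2, 1.0))
        jitter = 1.0 + rng.normal(0.0, 0.02, a.size)
        emit(f"sim{p}_a", f"similar_pair_{p}", ClassProfile(c, w, a))
        emit(f"sim{p}_b", f"similar_pair_{p}", ClassProfile(c, w, a * jitter))
    for p in range(1, n_dissimilar_pairs + 1):
        for member in ("a", "b"):
            c, w, a = _random_peaks(rng, 6, lo, hi, (80.0, 300.0), (0.2, 1.0))
            emit(f"dis{p}_{member}", f"dissimilar_pair_{p}", ClassProfile(c, w, a))
    return SpectralDataset(axis, spectra, labels)
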