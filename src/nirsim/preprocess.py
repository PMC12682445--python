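"""Preprocessing operators and the 32-pipeline grid.

Seven operators arranged in three slots, applied in fixed order
scatter -> enhance -> scale:

* scatter correction: SNV (standard normal variate, per spectrum)
* signal enhancement: Savitzky-Golay smoothing, 1st or 2nd derivative
* scaling: mean centering (MC), min-max scaling (MMS), autoscaling (AS)

Each slot may also be "none", giving 2 x 4 x 4 = 32 pipelines.  SNV and MMS
act per spectrum; MC and AS act per wavenumber across the dataset being
processed (the comparison batch), following standard chemometric
convention — so pairwise similarity after MC/AS depends on the batch.
Standard deviations use the sample (n-1) convention throughout.  SG
derivatives are per index step, not per cm^-1; on the uniform 8 cm^-1 grid
the difference is a global factor that subsequent scaling removes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .errors import InputError, ParameterError
from .spectra import SpectralDataset, Spectrum

__all__ = [
    "PipelineSpec",
    "snv",
    "sg_filter",
    "scale_op",
    "enumerate_grid",
    "apply_pipeline",
    "SCATTER_OPTIONS",
    "ENHANCE_OPTIONS",
    "SCALE_OPTIONS",
]

SCATTER_OPTIONS = ("none", "snv")
ENHANCE_OPTIONS = ("none", "sg_smooth", "d1_sg", "d2_sg")
SCALE_OPTIONS = ("none", "mc", "mms", "as")

DEFAULT_SG_WINDOW = 11
#: default polynomial order per enhancement mode (degree 3 for the second
#: derivative so an exactly linear baseline is annihilated)
DEFAULT_SG_POLYORDER = {"none": 2, "sg_smooth": 2, "d1_sg": 2, "d2_sg": 3}

_SG_DERIV = {"smooth": 0, "d1": 1, "d2": 2}
_ENHANCE_TO_MODE = {"sg_smooth": "smooth", "d1_sg": "d1", "d2_sg": "d2"}


@dataclass(frozen=True)
class PipelineSpec:
    """One ordered preprocessing choice (a cell of the 32-scheme grid).

    The canonical id string is ``"scatter+enhance+scale"``, e.g.
    ``snv+d1_sg+mms``; all three slots are always printed, "none" included.
    """

    scatter: str = "none"
    enhance: str = "none"
    scale: str = "none"
    sg_window: int = DEFAULT_SG_WINDOW
    sg_polyorder: int = 2

    def __post_init__(self) -> None:
        if self.scatter not in SCATTER_OPTIONS:
            raise ParameterError(f"unknown scatter option {self.scatter!r}")
        if self.enhance not in ENHANCE_OPTIONS:
            raise ParameterError(f"unknown enhance option {self.enhance!r}")
        if self.scale not in SCALE_OPTIONS:
            raise ParameterError(f"unknown scale option {self.scale!r}")
        w, p = self.sg_window, self.sg_polyorder
        if w % 2 == 0 or w < 5:
            raise ParameterError(f"sg_window must be odd and >= 5, got {w}")
        if w <= p:
            raise ParameterError(f"sg_window ({w}) must exceed sg_polyorder ({p})")
        if self.enhance == "d2_sg" and p < 2:
            raise ParameterError("second derivative requires sg_polyorder >= 2")

    @property
    def id(self) -> str:
        return f"{self.scatter}+{self.enhance}+{self.scale}"

    @classmethod
    def from_id(
        cls,
        pipeline_id: str,
        sg_window: int = DEFAULT_SG_WINDOW,
        sg_polyorder: int | None = None,
    ) -> "PipelineSpec":
        parts = pipeline_id.split("+")
        if len(parts) != 3:
            raise ParameterError(
                f"pipeline id must have 3 '+'-separated slots, got {pipeline_id!r}"
            )
        scatter, enhance, scale = parts
        poly = sg_polyorder if sg_polyorder is not None else DEFAULT_SG_POLYORDER.get(enhance, 2)
        return cls(scatter, enhance, scale, sg_window, poly)


# ---------------------------------------------------------------------------
# individual operators
# ---------------------------------------------------------------------------

def _snv_rows(matrix: np.ndarray) -> np.ndarray:
    mean = matrix.mean(axis=1, keepdims=True)
    sd = matrix.std(axis=1, ddof=1, keepdims=True)
    out = matrix - mean
    nonzero = sd[:, 0] > 0.0
    out[nonzero] /= sd[nonzero]
    out[~nonzero] = 0.0  # constant spectrum -> all zeros
    return out


def snv(spectrum: Spectrum) -> Spectrum:
    """Standard normal variate: per-spectrum (x - mean)/sd with sample sd.

    Removes multiplicative scatter and additive offset.  A constant
    spectrum maps to all zeros."""
    if len(spectrum) < 2:
        raise InputError("SNV needs at least 2 points")
    out = _snv_rows(spectrum.values[None, :].copy())[0]
    return Spectrum(spectrum.sample_id, out)


def sg_filter(
    dataset: SpectralDataset,
    mode: str,
    window: int = DEFAULT_SG_WINDOW,
    polyorder: int | None = None,
) -> SpectralDataset:
    """Savitzky-Golay smoothing (``mode="smooth"``) or derivative
    (``"d1"``/``"d2"``) along the wavenumber axis.

    Output length equals input length; boundary points come from the
    polynomial fitted on the first/last full window.  Derivatives are per
    index step.  Smoothing reproduces polynomials of degree <= polyorder
    exactly; d1 annihilates constants, d2 (polyorder >= 2) annihilates
    straight lines.
    """
    if mode not in _SG_DERIV:
        raise ParameterError(f"unknown SG mode {mode!r}")
    if polyorder is None:
        polyorder = 3 if mode == "d2" else 2
    if window % 2 == 0:
        raise ParameterError(f"SG window must be odd, got {window}")
    if window <= polyorder:
        raise ParameterError(f"SG window ({window}) must exceed polyorder ({polyorder})")
    if mode == "d2" and polyorder < 2:
        raise ParameterError("second derivative requires polyorder >= 2")
    if len(dataset.axis) < window:
        raise InputError(f"axis length {len(dataset.axis)} < SG window {window}")
    out = savgol_filter(
        dataset.values_matrix(),
        window_length=window,
        polyorder=polyorder,
        deriv=_SG_DERIV[mode],
        delta=1.0,
        axis=1,
        mode="interp",
    )
    return dataset.with_values(out)


def scale_op(dataset: SpectralDataset, mode: str) -> SpectralDataset:
    """Scaling operators.

    * ``mc`` — mean centering: subtract the per-wavenumber mean across
      samples.
    * ``as`` — autoscaling: per-wavenumber (x - mean)/sd across samples,
      sample sd; zero-variance columns map to 0.
    * ``mms`` — min-max scaling: rescale each spectrum independently to
      [0, 1] via (x - min)/(max - min); a constant spectrum maps to zeros.
    """
    if mode not in ("mc", "mms", "as"):
        raise ParameterError(f"unknown scale mode {mode!r}")
    if dataset.n_samples == 0:
        raise InputError("empty dataset")
    M = dataset.values_matrix()
    if mode in ("mc", "as") and dataset.n_samples < 2:
        raise InputError(f"{mode!r} needs at least 2 samples")
    if mode == "mc":
        out = M - M.mean(axis=0, keepdims=True)
    elif mode == "as":
        sd = M.std(axis=0, ddof=1)
        out = M - M.mean(axis=0, keepdims=True)
        nz = sd > 0.0
        out[:, nz] /= sd[nz]
        out[:, ~nz] = 0.0
    else:  # mms
        lo = M.min(axis=1, keepdims=True)
        hi = M.max(axis=1, keepdims=True)
        rng = hi - lo
        out = M - lo
        nz = rng[:, 0] > 0.0
        out[nz] /= rng[nz]
        out[~nz] = 0.0
    return dataset.with_values(out)


# ---------------------------------------------------------------------------
# grid enumeration and pipeline application
# ---------------------------------------------------------------------------

def enumerate_grid(
    sg_window: int = DEFAULT_SG_WINDOW, sg_polyorder: int | None = None
) -> list[PipelineSpec]:
    """All 32 pipelines in deterministic order (scatter slot slowest-varying,
    then enhance, then scale).  The first spec is the identity
    ``none+none+none``.  ``sg_polyorder=None`` uses the per-mode defaults
    (2 for smoothing/d1, 3 for d2)."""
    specs = []
    for scatter in SCATTER_OPTIONS:
        for enhance in ENHANCE_OPTIONS:
            poly = sg_polyorder if sg_polyorder is not None else DEFAULT_SG_POLYORDER[enhance]
            for scale in SCALE_OPTIONS:
                specs.append(PipelineSpec(scatter, enhance, scale, sg_window, poly))
    return specs


def apply_pipeline(dataset: SpectralDataset, spec: PipelineSpec) -> SpectralDataset:
    """Apply one pipeline: scatter -> enhance -> scale, "none" slots are the
    identity.  Sample order and labels are preserved."""
    out = dataset
    if spec.scatter == "snv":
        if len(out.axis) < 2:
            raise InputError("SNV needs at least 2 points")
        out = out.with_values(_snv_rows(out.values_matrix()))
    if spec.enhance != "none":
        out = sg_filter(out, _ENHANCE_TO_MODE[spec.enhance], spec.sg_window, spec.sg_polyorder)
    if spec.scale != "none":
        out = scale_op(out, spec.scale)
    return out
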