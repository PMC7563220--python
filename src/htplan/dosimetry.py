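"""SAR dosimetry: beamforming combination, THQ, |dTHQ| and |dRD|.

The treatment-quality chain is: combine per-channel steady-state fields
under complex drive weights, square into specific absorption rate
SAR = σ|E|²/(2ρ) (peak-phasor convention, |E| the vector norm over
components), then summarize:

* THQ (target-to-hotspot quotient) = mean SAR in the hyperthermia target
  volume ÷ mean SAR of the hottest 1 % of healthy-tissue volume — the
  treatment-planning goal function;
* |dTHQ| (%) — absolute percent relative THQ difference between a reduced
  segmentation and the detailed benchmark; ≤ 5 % is taken as below clinical
  relevance (a simulated median target temperature change of ~0.2 °C);
* per-tissue |dRD| (%) — absolute percent relative difference of the
  maximum average SAR (mean over the hottest 1 % of that tissue's volume),
  evaluated on the *detailed* tissue masks so every scheme is compared on
  identical spatial regions; judged against a 0–20 % band.

No IEEE-style 1 g/10 g mass averaging is applied anywhere: the statistic is
a volume-percentile mean.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .fdtd import ChannelFieldSet, MaterialGrids
from .phantom import CODE_LABELS

__all__ = [
    "DriveSettings",
    "SarMap",
    "DoseReport",
    "combine_fields",
    "compute_sar",
    "hotspot_mean",
    "compute_thq",
    "compute_dthq",
    "compute_drd",
    "summarize_boxplot",
    "build_sar_map",
    "THQ_THRESHOLD_PCT",
    "DRD_BAND_PCT",
]

THQ_THRESHOLD_PCT = 5.0
DRD_BAND_PCT = (0.0, 20.0)
HOTSPOT_FRACTION = 0.01


@dataclass(frozen=True)
class DriveSettings:
    """Per-channel complex drive weights (amplitude scale of the unit
    drive; phase in radians)."""

    weights: tuple[complex, ...]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=complex)
        if w.ndim != 1 or w.size == 0:
            raise ValueError("weights must be a non-empty 1D sequence")
        if not np.all(np.isfinite(w)):
            raise ValueError("weights must be finite")
        if np.all(w == 0):
            raise ValueError("at least one weight must be nonzero")
        object.__setattr__(self, "weights", tuple(complex(x) for x in w))

    @classmethod
    def from_amp_phase(cls, amplitudes, phases) -> "DriveSettings":
        amps = np.asarray(amplitudes, float)
        phs = np.asarray(phases, float)
        return cls(tuple(amps * np.exp(1j * phs)))

    @property
    def n_channels(self) -> int:
        return len(self.weights)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.weights, dtype=complex)


@dataclass
class SarMap:
    """Per-voxel SAR (W/kg) with the masks dosimetry needs.

    ``healthy_mask`` is the labeled body excluding the HTV; ``tissue_masks``
    are cut from the detailed segmentation so they are identical across
    schemes.
    """

    sar: np.ndarray
    htv_mask: np.ndarray
    healthy_mask: np.ndarray
    tissue_masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(self.sar < 0):
            raise ValueError("SAR must be non-negative")


def combine_fields(fields: ChannelFieldSet, drive: DriveSettings) -> np.ndarray:
    """Voxelwise weighted phasor sum of the per-channel fields."""
    if drive.n_channels != fields.n_channels:
        raise ValueError(
            f"{drive.n_channels} weights for {fields.n_channels} channels"
        )
    w = drive.as_array()
    return np.tensordot(w, fields.fields, axes=(0, 0))


def compute_sar(
    total_field: np.ndarray,
    sigma: np.ndarray,
    rho: np.ndarray,
) -> np.ndarray:
    """SAR = σ|E|²/(2ρ) with |E| the peak phasor vector magnitude."""
    if total_field.shape[:-1] != sigma.shape or sigma.shape != rho.shape:
        raise ValueError("field/material grids are not congruent")
    e2 = np.sum(np.abs(total_field) ** 2, axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        sar = sigma * e2 / (2.0 * rho)
    sar[rho <= 0] = 0.0
    return sar


def hotspot_mean(sar: np.ndarray, mask: np.ndarray, fraction: float) -> float:
    """Mean SAR of the hottest ``fraction`` of the masked voxels.

    Selects the ceil(f·|mask|) top voxels.  The top-k values are an exact
    multiset regardless of tie order, so the result equals a full-sort
    oracle bit for bit.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    vals = np.asarray(sar)[np.asarray(mask, bool)]
    nv = vals.size
    if nv == 0:
        raise ValueError("mask is empty")
    k = math.ceil(fraction * nv)
    if k >= nv:
        top = np.sort(vals)
    else:
        top = np.partition(vals, nv - k)[nv - k:]
        top.sort()
    return float(top.mean())


def build_sar_map(
    fields: ChannelFieldSet,
    materials: MaterialGrids,
    drive: DriveSettings,
) -> SarMap:
    """Combine fields, square into SAR, and attach the dosimetry masks."""
    fields.validate_against(materials)
    total = combine_fields(fields, drive)
    sar = compute_sar(total, materials.sigma, materials.rho)
    if materials.htv_mask is None or materials.detailed_labels is None:
        raise ValueError("materials lack target/detailed-label masks")
    body = materials.body_mask
    healthy = body & ~materials.htv_mask
    tissue_masks = {}
    for code in np.unique(materials.detailed_labels):
        if code == 0:
            continue
        tissue_masks[CODE_LABELS[int(code)]] = materials.detailed_labels == code
    return SarMap(
        sar=sar,
        htv_mask=materials.htv_mask,
        healthy_mask=healthy,
        tissue_masks=tissue_masks,
    )


def compute_thq(sar_map: SarMap, fraction: float = HOTSPOT_FRACTION) -> float:
    """Target-to-hotspot quotient: mean target SAR over top-1 % healthy SAR."""
    if not sar_map.htv_mask.any():
        raise ValueError("HTV mask is empty")
    if not sar_map.healthy_mask.any():
        raise ValueError("healthy mask is empty")
    tvals = sar_map.sar[sar_map.htv_mask]
    hvals = sar_map.sar[sar_map.healthy_mask]
    if tvals.min() == tvals.max() == hvals.min() == hvals.max():
        # uniform SAR: numerator and denominator are the same constant, so
        # THQ is exactly 1 (floating-point mean order must not perturb it)
        if tvals[0] == 0.0:
            raise ValueError("zero hotspot SAR: THQ undefined (zero field?)")
        return 1.0
    num = float(tvals.mean())
    den = hotspot_mean(sar_map.sar, sar_map.healthy_mask, fraction)
    if den == 0.0:
        raise ValueError("zero hotspot SAR: THQ undefined (zero field?)")
    return num / den


def compute_dthq(thq_n: float, thq_reference: float) -> float:
    """|dTHQ| in % of the reference (detailed-benchmark) THQ."""
    if not (thq_reference > 0):
        raise ValueError("reference THQ must be positive")
    return abs((thq_n - thq_reference) / thq_reference * 100.0)


def compute_drd(
    sar_n: SarMap,
    sar_ref: SarMap,
    fraction: float = HOTSPOT_FRACTION,
) -> tuple[dict[str, float], list[str]]:
    """Per-tissue |dRD| (%) between a scheme's SAR map and the benchmark.

    Uses the benchmark's (detailed) tissue masks for both maps.  Returns
    (values, undefined): tissues whose reference maximum average SAR is
    zero cannot be normalized and are reported in ``undefined`` with a
    warning instead of a value.
    """
    if sar_n.sar.shape != sar_ref.sar.shape:
        raise ValueError("SAR maps are on different grids")
    values: dict[str, float] = {}
    undefined: list[str] = []
    for tissue, mask in sar_ref.tissue_masks.items():
        m_ref = hotspot_mean(sar_ref.sar, mask, fraction)
        m_n = hotspot_mean(sar_n.sar, mask, fraction)
        if m_ref == 0.0:
            undefined.append(tissue)
            continue
        values[tissue] = abs((m_n - m_ref) / m_ref * 100.0)
    if undefined:
        warnings.warn(
            f"|dRD| undefined (zero reference SAR) for: {', '.join(undefined)}",
            RuntimeWarning,
        )
    return values, undefined


def summarize_boxplot(values) -> dict[str, float]:
    """Median, quartiles and 2.5/97.5 percentiles of a |dRD| collection.

    Percentiles use linear interpolation between closest ranks.
    """
    arr = np.asarray(list(values), float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty collection")
    p = np.percentile(arr, [2.5, 25.0, 50.0, 75.0, 97.5])
    return {
        "p2.5": float(p[0]),
        "q1": float(p[1]),
        "median": float(p[2]),
        "q3": float(p[3]),
        "p97.5": float(p[4]),
    }


@dataclass
class DoseReport:
    """Dosimetry summary of one (phantom, site, size, scheme) cell."""

    scheme: str
    thq: float
    sar_htv_mean: float
    sar_hotspot_mean: float
    dthq_pct: float | None = None
    drd_pct: dict[str, float] = field(default_factory=dict)
    drd_undefined: list[str] = field(default_factory=list)

    @property
    def thq_acceptable(self) -> bool | None:
        """|dTHQ| at or below the 5 % clinical-relevance threshold."""
        if self.dthq_pct is None:
            return None
        return self.dthq_pct <= THQ_THRESHOLD_PCT

    def drd_summary(self) -> dict[str, float]:
        return summarize_boxplot(list(self.drd_pct.values()))
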