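"""Cumulative dose-volume histograms and the monitored dose metrics.

Metrics are computed from the raw per-voxel samples, not from the binned
curve, to avoid binning bias:

* ``V95``  — % of structure volume receiving >= 0.95 x prescription.
* ``Dmean`` — volume-weighted mean dose (Gy).
* ``Dmax`` — maximum voxel dose (Gy).
* ``D1cc`` — minimum dose of the hottest 1 cm^3 (sorted-voxel rule).
* ``hotspot`` — Dmax as % of prescription.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

METRIC_KINDS = ("V95", "Dmean", "Dmax", "D1cc", "hotspot")
SCOPES = ("plan", "day", "sum")


@dataclass
class DVHCurve:
    """Cumulative DVH: % of volume receiving at least each bin dose."""

    dose_bins: np.ndarray        # left edges, Gy, uniform width, starts at 0
    volume_fraction: np.ndarray  # %, non-increasing, starts at 100
    flavor: str = "plan"

    def volume_at(self, dose: float) -> float:
        """% volume receiving >= ``dose`` (nearest bin at or below)."""
        i = int(np.clip(np.searchsorted(self.dose_bins, dose, side="right") - 1,
                        0, len(self.dose_bins) - 1))
        return float(self.volume_fraction[i])

    def mean_dose(self) -> float:
        """Dmean read off the curve (Riemann sum of the survival function)."""
        width = self.dose_bins[1] - self.dose_bins[0] if len(self.dose_bins) > 1 else 0.0
        return float(np.sum(self.volume_fraction / 100.0) * width)


@dataclass
class DoseMetricValue:
    kind: str
    value: float          # % for V95/hotspot, Gy otherwise
    scope: str = "plan"
    reference: float | None = None  # Rx (Gy) for V95/hotspot
    structure: str = ""

    def __post_init__(self) -> None:
        if self.kind not in METRIC_KINDS:
            raise ValueError(f"unknown metric kind {self.kind!r}")
        if self.scope not in SCOPES:
            raise ValueError(f"unknown scope {self.scope!r}")


def cumulative_dvh(
    samples: np.ndarray, voxel_volume: float, bin_width: float = 0.1,
    flavor: str = "plan",
) -> DVHCurve:
    """Cumulative DVH in % of structure volume, uniform ``bin_width`` Gy bins."""
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("cannot build a DVH from zero dose samples")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    n_bins = int(np.floor(samples.max() / bin_width)) + 2
    edges = np.arange(n_bins) * bin_width
    # % of volume with dose >= edge; voxels are equal-volume.  A sample falls
    # in histogram bin i iff edges[i] <= d < edges[i+1], so the survival count
    # at edge i is the reverse cumulative sum from bin i upward.
    hist, _ = np.histogram(samples, bins=np.append(edges, np.inf))
    counts = np.cumsum(hist[::-1])[::-1].astype(float)
    return DVHCurve(
        dose_bins=edges, volume_fraction=100.0 * counts / samples.size, flavor=flavor
    )


def extract_metric(
    samples: np.ndarray,
    kind: str,
    reference: float | None = None,
    voxel_volume: float = 1.0,
    scope: str = "plan",
    structure: str = "",
) -> DoseMetricValue:
    """Compute one dosimetric parameter from raw per-voxel doses."""
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("no dose samples")
    if kind in ("V95", "hotspot") and (reference is None or reference <= 0):
        raise ValueError(f"{kind} requires a positive prescription reference")
    if kind == "V95":
        value = 100.0 * float(np.mean(samples >= 0.95 * reference))
    elif kind == "Dmean":
        value = float(samples.mean())
    elif kind == "Dmax":
        value = float(samples.max())
    elif kind == "hotspot":
        value = 100.0 * float(samples.max()) / float(reference)
    elif kind == "D1cc":
        total_cc = samples.size * voxel_volume
        if total_cc < 1.0:
            warnings.warn(
                f"D1cc on a structure of {total_cc:.2f} cm^3 (<1 cm^3); "
                "reporting the minimum dose"
            )
            value = float(samples.min())
        else:
            hot = np.sort(samples)[::-1]
            n_hot = int(np.ceil(1.0 / voxel_volume))  # voxels spanning the hottest 1 cc
            value = float(hot[n_hot - 1])
    else:  # pragma: no cover - guarded by METRIC_KINDS
        raise ValueError(kind)
    return DoseMetricValue(
        kind=kind, value=value, scope=scope, reference=reference, structure=structure
    )


def export_dvh_csv(curve: DVHCurve, path) -> None:
    """Two-column CSV export: dose (Gy), volume (%)."""
    arr = np.column_stack([curve.dose_bins, curve.volume_fraction])
    np.savetxt(path, arr, fmt="%.4f", delimiter=",", header="dose_gy,volume_pct",
               comments="")
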