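"""Per-subject densitometry from an attenuation histogram.

Statistics follow the subject-specific threshold convention: the low and
high attenuation thresholds are (mean - 1SD) and (mean + 1SD) of the masked
voxels, and the low/high volume fractions count voxels strictly below /
strictly above them. SD uses the population convention (denominator N).
Histograms use width-1 integer-HU bins, so histogram moments equal direct
voxel-wise moments exactly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from pedct.segmentation import LungMask
from pedct.volume import AttenuationVolume


@dataclasses.dataclass
class AttenuationHistogram:
    """Voxel counts per integer HU value, plus the voxel volume in mm^3."""

    bin_values: np.ndarray
    counts: np.ndarray
    voxel_volume_mm3: float

    def __post_init__(self) -> None:
        self.bin_values = np.asarray(self.bin_values, dtype=np.int64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.bin_values.shape != self.counts.shape or self.bin_values.ndim != 1:
            raise ValueError("bin_values and counts must be congruent 1D arrays")
        if np.any(np.diff(self.bin_values) <= 0):
            raise ValueError("bin_values must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("counts must be >= 0")
        if self.counts.sum() <= 0:
            raise ValueError("total count must be > 0")
        if self.voxel_volume_mm3 <= 0:
            raise ValueError("voxel_volume_mm3 must be > 0")

    @property
    def total_count(self) -> int:
        return int(self.counts.sum())

    def to_csv(self, path: str | Path) -> None:
        """Two-column CSV (hu,count) with a voxel-volume header line."""
        with open(path, "w") as fh:
            fh.write(f"# voxel_volume_mm3={self.voxel_volume_mm3!r}\n")
            fh.write("hu,count\n")
            for v, c in zip(self.bin_values, self.counts):
                fh.write(f"{v},{c}\n")

    @classmethod
    def from_csv(cls, path: str | Path) -> "AttenuationHistogram":
        with open(path) as fh:
            header = fh.readline().strip()
            if not header.startswith("# voxel_volume_mm3="):
                raise ValueError("missing voxel_volume_mm3 header line")
            voxel_volume = float(header.split("=", 1)[1])
            data = np.loadtxt(fh, delimiter=",", skiprows=1, ndmin=2, dtype=np.int64)
        return cls(bin_values=data[:, 0], counts=data[:, 1], voxel_volume_mm3=voxel_volume)


@dataclasses.dataclass
class DensitometryResult:
    tlc_ct_mL: float
    mean_hu: float
    sd_hu: float
    lat_hu: float
    hat_hu: float
    pct_low: float
    pct_high: float
    min_hu: int
    max_hu: int

    def rounded(self) -> dict:
        """Presentation form: HU to 0.1, percentages to 0.01."""
        return {
            "tlc_ct_mL": round(self.tlc_ct_mL, 1),
            "mean_hu": round(self.mean_hu, 1),
            "sd_hu": round(self.sd_hu, 1),
            "lat_hu": round(self.lat_hu, 1),
            "hat_hu": round(self.hat_hu, 1),
            "pct_low": round(self.pct_low, 2),
            "pct_high": round(self.pct_high, 2),
            "min_hu": self.min_hu,
            "max_hu": self.max_hu,
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


def build_histogram(volume: AttenuationVolume, mask: LungMask | np.ndarray) -> AttenuationHistogram:
    """Width-1 integer-HU histogram of the masked voxels."""
    voxels = mask.voxels if isinstance(mask, LungMask) else np.asarray(mask, dtype=bool)
    if voxels.shape != volume.shape:
        raise ValueError("mask and volume shapes differ")
    values = volume.voxels[voxels]
    if values.size == 0:
        raise ValueError("mask selects no voxels")
    bins, counts = np.unique(values, return_counts=True)
    return AttenuationHistogram(
        bin_values=bins, counts=counts, voxel_volume_mm3=volume.voxel_volume_mm3
    )


def compute_densitometry(hist: AttenuationHistogram) -> DensitometryResult:
    """Count-weighted moments, thresholds at mean -/+ 1SD, and strict-tail
    volume fractions. Bins whose integer value equals a (real-valued)
    threshold count as neither low nor high."""
    values = hist.bin_values.astype(np.float64)
    counts = hist.counts.astype(np.float64)
    total = counts.sum()

    mean = float(np.dot(counts, values) / total)
    var = float(np.dot(counts, (values - mean) ** 2) / total)  # population SD
    sd = float(np.sqrt(var))
    lat, hat = mean - sd, mean + sd

    pct_low = 100.0 * counts[hist.bin_values < lat].sum() / total
    pct_high = 100.0 * counts[hist.bin_values > hat].sum() / total

    nonzero = hist.bin_values[hist.counts > 0]
    return DensitometryResult(
        tlc_ct_mL=float(total * hist.voxel_volume_mm3 / 1000.0),
        mean_hu=mean,
        sd_hu=sd,
        lat_hu=lat,
        hat_hu=hat,
        pct_low=float(pct_low),
        pct_high=float(pct_high),
        min_hu=int(nonzero.min()),
        max_hu=int(nonzero.max()),
    )


def densitometry_from_volume(
    volume: AttenuationVolume, mask: LungMask | np.ndarray
) -> DensitometryResult:
    """Composition of build_histogram and compute_densitometry."""
    return compute_densitometry(build_histogram(volume, mask))
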