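"""Regional coverage correction, larval preference fractions and densities.

From per-region pixel counts, the chain is:

1. raw coverage per region: larval_px / region_px;
2. corrected coverage: raw coverage × (region_px / image_px) — compensating
   for regions that differ slightly in pixel count after manual cropping
   (algebraically this equals larval_px / image_px; the identity is asserted
   in the tests);
3. preference fraction: corrected coverage normalised by the summed
   corrected coverage, so the three fractions sum to 1;
4. regional density: preference × total larvae / (one third of the water
   volume), in larva/ml — each region is treated as an equal-volume
   vertical prism.

The crowding ratio (preference / (1/3)) expresses how much denser a region
is than the uniform expectation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import REGIONS, Container


class OccupancyError(ValueError):
    """Invalid occupancy input."""


class NoLarvaeDetectedError(OccupancyError):
    """All corrected coverages are zero; preferences are undefined."""


def corrected_coverage(larval_px_r: int, total_px_r: int, total_px_image: int) -> float:
    """Cropping-corrected larval coverage of one region.

    Computed as (larval_px_r / total_px_r) · (total_px_r / total_px_image),
    deliberately as the two-factor product rather than the simplified
    larval_px_r / total_px_image.
    """
    if total_px_r <= 0:
        raise OccupancyError("region has zero pixels")
    if not (0 <= larval_px_r <= total_px_r <= total_px_image):
        raise OccupancyError("pixel counts must satisfy 0 <= larval <= region <= image")
    return (larval_px_r / total_px_r) * (total_px_r / total_px_image)


def preference_fractions(corrected) -> np.ndarray:
    """Normalise corrected coverages into preference fractions summing to 1.

    Raises :class:`NoLarvaeDetectedError` when every corrected coverage is
    zero (an image with no detected larvae has no defined preference).
    """
    corrected = np.asarray(corrected, dtype=float)
    if np.any(corrected < 0):
        raise OccupancyError("corrected coverages must be non-negative")
    total = corrected.sum()
    if total == 0:
        raise NoLarvaeDetectedError("no larval pixels detected in any region")
    return corrected / total


def regional_density(preference: float, n_larvae: int, water_volume_ml: float) -> float:
    """Larvae per ml in a region: preference × N / (V / 3)."""
    if not 0 <= preference <= 1:
        raise OccupancyError("preference must lie in [0, 1]")
    if water_volume_ml <= 0:
        raise OccupancyError("water volume must be positive")
    return preference * n_larvae / (water_volume_ml / 3.0)


def crowding_ratio(preference: float) -> float:
    """Regional density relative to a uniform distribution (preference / (1/3))."""
    if not 0 <= preference <= 1:
        raise OccupancyError("preference must lie in [0, 1]")
    return preference * 3.0


@dataclass(frozen=True)
class OccupancyResult:
    """Per-image occupancy summary (arrays ordered edge, intermediate, central)."""

    coverage: np.ndarray
    corrected: np.ndarray
    preference: np.ndarray
    density: np.ndarray
    total_coverage: float
    no_larvae: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region": list(REGIONS),
                "coverage": self.coverage,
                "corrected_coverage": self.corrected,
                "preference": self.preference,
                "density_larva_per_ml": self.density,
                "crowding_ratio": self.preference * 3.0,
            }
        )


def occupancy_from_counts(counts: pd.DataFrame, container: Container) -> OccupancyResult:
    """Apply the full coverage→preference→density chain to one image's counts.

    ``counts`` is the table from :func:`larvatray.imaging.area_fractions`
    (one row per region plus a ``total`` row).  Images without any detected
    larvae are flagged (``no_larvae=True``) and carry NaN preferences and
    densities rather than silent zeros.
    """
    by_region = counts.set_index("region")
    larval = np.array([by_region.loc[r, "larval_px"] for r in REGIONS], dtype=float)
    totals = np.array([by_region.loc[r, "total_px"] for r in REGIONS], dtype=float)
    image_px = float(totals.sum())
    cov = larval / totals
    corr = np.array(
        [corrected_coverage(int(l), int(t), int(image_px)) for l, t in zip(larval, totals)]
    )
    try:
        pref = preference_fractions(corr)
        no_larvae = False
    except NoLarvaeDetectedError:
        pref = np.full(3, np.nan)
        no_larvae = True
    dens = np.array(
        [
            regional_density(p, container.n_larvae, container.water_volume_ml)
            if np.isfinite(p)
            else np.nan
            for p in pref
        ]
    )
    return OccupancyResult(
        coverage=cov,
        corrected=corr,
        preference=pref,
        density=dens,
        total_coverage=float(larval.sum() / image_px),
        no_larvae=no_larvae,
    )


def analyze_counts(counts: pd.DataFrame, container: Container) -> pd.DataFrame:
    """Tidy per-image, per-region occupancy table.

    ``counts`` has columns ``image_id, region, larval_px, total_px`` covering
    any number of images.  Returns one row per image × region with coverage,
    corrected coverage, preference, density (larva/ml), crowding ratio and a
    ``no_larvae`` flag.
    """
    required = {"image_id", "region", "larval_px", "total_px"}
    missing = required - set(counts.columns)
    if missing:
        raise OccupancyError(f"counts table missing columns: {sorted(missing)}")
    frames = []
    for image_id, sub in counts.groupby("image_id", sort=False):
        res = occupancy_from_counts(sub, container)
        frame = res.to_frame()
        frame.insert(0, "image_id", image_id)
        frame["total_coverage"] = res.total_coverage
        frame["no_larvae"] = res.no_larvae
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)
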