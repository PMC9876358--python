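"""Synthetic container photographs and life-history tables with known truth.

The image generator emulates the photographs the analysis chain was built
for: dark larvae floating on light water, small dark food particles, a mild
illumination gradient and sensor noise.  Each larva's region is drawn from a
configurable edge/intermediate/central placement distribution, its position
is uniform within that region, and it is rendered as a curved stroke
(quadratic Bézier polyline with a circular brush).  The truth table records
the per-region larva counts and the realised per-region larval pixel
fractions from the union ground-truth mask, so every downstream stage can be
scored against exact truth.

The life-history generator draws per-tray development time, survival and
winglength from treatment-cell parameters and builds fecundity per female as
a linear function of winglength (larger females lay more eggs) before
averaging per tray.  Zero dispersions reproduce the configured means
exactly.  All randomness flows through one seeded generator per call.
"""

from __future__ import annotations

from dataclasses import dataclass

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.draw import disk

from .geometry import Container, REGION_LABELS, REGIONS, region_label_mask


class SimulationError(ValueError):
    """Invalid simulation configuration."""


#: Observed mean regional preferences (edge, intermediate, central) used as
#: the default placement distribution; printed means sum to 0.9999 and are
#: normalised internally.
DEFAULT_PLACEMENT = (0.7594, 0.1505, 0.0900)


def study_containers() -> dict[str, Container]:
    """The three rearing containers of the study design (low-density counts).

    Small: 10.00 cm diameter × 4.20 cm, 100 ml; medium: 18.00 × 11.00 ×
    6.00 cm, 500 ml; large: 27.00 × 20.70 × 11.00 cm, 1000 ml.
    """
    return {
        "small": Container("circle", diameter_cm=10.0, depth_cm=4.2,
                           water_volume_ml=100.0, n_larvae=20),
        "medium": Container("rectangle", length_cm=18.0, width_cm=11.0, depth_cm=6.0,
                            water_volume_ml=500.0, n_larvae=100),
        "large": Container("rectangle", length_cm=27.0, width_cm=20.7, depth_cm=11.0,
                           water_volume_ml=1000.0, n_larvae=200),
    }


def design_table(experiment: str = "diet") -> pd.DataFrame:
    """Treatment design tables of the two experiments.

    ``experiment="diet"`` varies diet at constant 0.20 larva/ml;
    ``experiment="density"`` varies stocking density at a constant surplus
    diet concentration of 7.00 mg/ml.
    """
    if experiment == "diet":
        rows = []
        for diet, mg in (("High", 0.50), ("Medium", 0.30), ("Low", 0.10)):
            for size, vol, n in (("Large", 1000, 200), ("Medium", 500, 100), ("Small", 100, 20)):
                rows.append((diet, size, 5, vol, n, mg))
        return pd.DataFrame(
            rows,
            columns=["Diet", "Size", "Replicates", "WaterVolume_ml",
                     "NLarvae", "mg_per_larva_day"],
        )
    if experiment == "density":
        rows = [
            ("High", "Large", 4, 1000, 1400, 5.00),
            ("High", "Medium", 4, 500, 700, 5.00),
            ("High", "Small", 5, 100, 140, 5.00),
            ("Low", "Large", 4, 1000, 200, 3.50),
            ("Low", "Medium", 4, 500, 100, 3.50),
            ("Low", "Small", 5, 100, 20, 3.50),
        ]
        return pd.DataFrame(
            rows,
            columns=["Density", "Size", "Replicates", "WaterVolume_ml",
                     "NLarvae", "mg_per_larva_day"],
        )
    raise SimulationError(f"unknown experiment {experiment!r}")


# ---------------------------------------------------------------------------
# image simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImageSimConfig:
    """Configuration of the container-photograph simulator.

    Larval dimensions default to a day-2–4 instar (0.40 × 0.12 cm);
    intensities are 8-bit grey levels (water bright, larvae dark).
    """

    container: Container
    px_per_cm: float = 25.0
    n_larvae: int | None = None  # default: the container's stocked count
    placement_probs: tuple[float, float, float] = DEFAULT_PLACEMENT
    larva_length_cm: float = 0.40
    larva_width_cm: float = 0.12
    larva_curvature: float = 0.35  # bow height as a fraction of body length
    larva_intensity: float = 40.0
    larva_intensity_sd: float = 10.0
    food_per_cm2: float = 0.4
    food_radius_px: tuple[int, int] = (1, 2)
    food_intensity: float = 95.0
    background: float = 210.0
    background_gradient: float = 12.0
    noise_sd: float = 4.0
    confine_to_region: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        probs = np.asarray(self.placement_probs, dtype=float)
        if probs.shape != (3,) or np.any(probs < 0):
            raise SimulationError("placement_probs must be three non-negative numbers")
        if abs(probs.sum() - 1.0) > 1e-3:
            raise SimulationError("placement_probs must sum to 1")
        if self.px_per_cm <= 0:
            raise SimulationError("px_per_cm must be positive")
        if self.larva_length_cm <= 0 or self.larva_width_cm <= 0:
            raise SimulationError("larva dimensions must be positive")
        min_extent = min(self.container.footprint_cm)
        if self.larva_length_cm >= min_extent:
            raise SimulationError("larvae too large for the container footprint")

    @property
    def effective_n_larvae(self) -> int:
        n = self.container.n_larvae if self.n_larvae is None else self.n_larvae
        if n <= 0:
            raise SimulationError("need a positive larva count to simulate")
        return n

    @property
    def normalized_probs(self) -> np.ndarray:
        p = np.asarray(self.placement_probs, dtype=float)
        return p / p.sum()


def _bezier_points(p0, p1, p2, n: int) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n)[:, None]
    return ((1 - t) ** 2) * p0 + 2 * t * (1 - t) * p1 + (t**2) * p2


def _render_stroke(canvas_shape, center_rc, length_px, width_px, curvature, rng):
    """Pixel coordinates of one curved larva stroke clipped to the canvas."""
    theta = rng.uniform(0.0, 2.0 * np.pi)
    u = np.array([np.sin(theta), np.cos(theta)])  # (row, col) direction
    perp = np.array([-u[1], u[0]])
    half = length_px / 2.0
    c = np.asarray(center_rc, dtype=float)
    bow = curvature * length_px * rng.uniform(-1.0, 1.0)
    p0, p2 = c - half * u, c + half * u
    p1 = c + bow * perp
    pts = _bezier_points(p0, p1, p2, max(int(2 * length_px), 4))
    radius = max(width_px / 2.0, 1.0)
    rr_all, cc_all = [], []
    for r, col in pts:
        rr, cc = disk((r, col), radius)
        rr_all.append(rr)
        cc_all.append(cc)
    rr = np.concatenate(rr_all)
    cc = np.concatenate(cc_all)
    in_canvas = (rr >= 0) & (rr < canvas_shape[0]) & (cc >= 0) & (cc < canvas_shape[1])
    clipped = not bool(in_canvas.all())
    rr, cc = rr[in_canvas], cc[in_canvas]
    flat = np.unique(rr * canvas_shape[1] + cc)
    return flat // canvas_shape[1], flat % canvas_shape[1], clipped


def generate_image(
    config: ImageSimConfig,
    rng: np.random.Generator,
    labels: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Render one photograph.

    Returns ``(image_uint8, larva_truth_mask, truth)`` where ``truth`` maps
    ``count_<region>`` to the number of larvae placed in each region and
    ``truepx_<region>`` to the realised larval pixel count of the union
    truth mask inside each region.
    """
    if labels is None:
        labels = region_label_mask(config.container, px_per_cm=config.px_per_cm)
    shape = labels.shape
    inside = labels > 0
    # background: light water with a lateral illumination gradient and noise
    grad = np.linspace(-1.0, 1.0, shape[1])[None, :] * config.background_gradient
    img = config.background + grad + rng.normal(0.0, config.noise_sd, size=shape)

    region_pixels = {
        r: np.flatnonzero(labels.ravel() == REGION_LABELS[r]) for r in REGIONS
    }
    probs = config.normalized_probs
    larva_mask = np.zeros(shape, dtype=bool)
    counts = dict.fromkeys(REGIONS, 0)
    length_px = config.larva_length_cm * config.px_per_cm
    width_px = config.larva_width_cm * config.px_per_cm
    n = config.effective_n_larvae
    region_draws = rng.choice(3, size=n, p=probs)
    for ridx in region_draws:
        region = REGIONS[ridx]
        label = REGION_LABELS[region]
        counts[region] += 1
        # with confine_to_region (default) the whole body is resampled into
        # the drawn region, so pixel-mass truth matches count truth exactly
        max_tries = 50 if config.confine_to_region else 1
        for _ in range(max_tries):
            flat = region_pixels[region][rng.integers(len(region_pixels[region]))]
            center = (flat // shape[1] + rng.uniform(-0.5, 0.5),
                      flat % shape[1] + rng.uniform(-0.5, 0.5))
            rr, cc, clipped = _render_stroke(shape, center, length_px, width_px,
                                             config.larva_curvature, rng)
            if not config.confine_to_region or (
                not clipped and np.all(labels[rr, cc] == label)
            ):
                break
        keep = inside[rr, cc]
        rr, cc = rr[keep], cc[keep]
        larva_mask[rr, cc] = True
        shade = rng.normal(config.larva_intensity, config.larva_intensity_sd)
        img[rr, cc] = np.minimum(img[rr, cc], shade)
    # food particles: small dark blobs scattered over the water surface
    n_food = rng.poisson(config.food_per_cm2 * config.container.surface_area_cm2)
    surface = np.flatnonzero(inside.ravel())
    for _ in range(n_food):
        flat = surface[rng.integers(len(surface))]
        radius = rng.integers(config.food_radius_px[0], config.food_radius_px[1] + 1)
        rr, cc = disk((flat // shape[1], flat % shape[1]), radius, shape=shape)
        shade = rng.normal(config.food_intensity, 10.0)
        img[rr, cc] = np.minimum(img[rr, cc], shade)
    img = np.clip(img, 0, 255).astype(np.uint8)
    truth = {f"count_{r}": counts[r] for r in REGIONS}
    for r in REGIONS:
        truth[f"truepx_{r}"] = int(np.count_nonzero(
            larva_mask & (labels == REGION_LABELS[r])
        ))
    return img, larva_mask, truth


def generate_images(
    config: ImageSimConfig,
    n_images: int,
    out_dir=None,
) -> tuple[list[np.ndarray], pd.DataFrame]:
    """Render a batch of photographs with one seeded generator.

    Returns the images and a truth table (one row per image with region
    counts and true pixel counts).  With ``out_dir`` given, writes
    ``image_###.png``, ``mask_###.png`` (truth masks) and ``truth.csv``.
    """
    rng = np.random.default_rng(config.seed)
    labels = region_label_mask(config.container, px_per_cm=config.px_per_cm)
    if out_dir is not None:
        from pathlib import Path

        Path(out_dir).mkdir(parents=True, exist_ok=True)
    images, rows = [], []
    for i in range(n_images):
        img, mask, truth = generate_image(config, rng, labels=labels)
        truth["image_id"] = f"image_{i:03d}"
        images.append(img)
        rows.append(truth)
        if out_dir is not None:
            iio.imwrite(f"{out_dir}/image_{i:03d}.png", img)
            iio.imwrite(f"{out_dir}/mask_{i:03d}.png",
                        (mask.astype(np.uint8) * 255))
    truth_df = pd.DataFrame(rows)
    truth_df = truth_df[["image_id"] + [c for c in truth_df.columns if c != "image_id"]]
    if out_dir is not None:
        truth_df.to_csv(f"{out_dir}/truth.csv", index=False)
        iio.imwrite(f"{out_dir}/regions.png", labels)
    return images, truth_df


# ---------------------------------------------------------------------------
# life-history simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellParams:
    """Trait distribution of one size × treatment cell.

    Development time is a tray-level mean in days with Gaussian tray noise
    (``d_sd``); survival is beta-distributed with the given mean and sd
    (exact when ``s_sd`` is 0); winglength is normal per female (mm).
    """

    d_mean: float
    s_mean: float
    wl_mean: float
    d_sd: float = 0.0
    s_sd: float = 0.0
    wl_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.d_mean <= 0 or self.wl_mean <= 0:
            raise SimulationError("trait means must be positive")
        if not 0 < self.s_mean < 1:
            raise SimulationError("survival mean must lie in (0, 1)")
        if min(self.d_sd, self.s_sd, self.wl_sd) < 0:
            raise SimulationError("dispersions must be non-negative")


@dataclass(frozen=True)
class LifeSimConfig:
    """Configuration of the life-history table simulator.

    ``cells`` maps (size, treatment) to :class:`CellParams`.  Fecundity per
    female is ``intercept + slope·winglength + N(0, fecundity_sd)`` clipped
    at 0 and averaged over ``females_per_tray``.
    """

    cells: dict[tuple[str, str], CellParams]
    treatment_name: str = "Density"
    replicates: int | dict[tuple[str, str], int] = 5
    females_per_tray: int = 5
    fecundity_intercept: float = -95.0
    fecundity_slope: float = 55.0  # eggs per mm of winglength
    fecundity_sd: float = 8.0
    seed: int = 0

    def n_replicates(self, cell: tuple[str, str]) -> int:
        if isinstance(self.replicates, dict):
            return self.replicates[cell]
        return self.replicates


def _beta_draw(rng, mean, sd):
    if sd == 0:
        return mean
    var = sd * sd
    max_var = mean * (1 - mean)
    if var >= max_var:
        raise SimulationError("survival sd too large for a beta proportion")
    nu = max_var / var - 1.0
    return float(rng.beta(mean * nu, (1 - mean) * nu))


def generate_lifehistory(
    config: LifeSimConfig, return_females: bool = False
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one tidy per-tray life-history table.

    Columns: Size, <treatment>, Replicate, Development (days), Survival
    (proportion), Winglength (mm, tray mean), Fecundity (eggs/female, tray
    mean).  With all dispersions zero the table equals the configured means
    exactly.  ``return_females=True`` also returns the per-female table
    (Size, <treatment>, Replicate, MM, Fecundity) from which the tray means
    were taken.
    """
    rng = np.random.default_rng(config.seed)
    rows, female_rows = [], []
    for (size, treat), params in config.cells.items():
        for rep in range(1, config.n_replicates((size, treat)) + 1):
            d = params.d_mean + (rng.normal(0.0, params.d_sd) if params.d_sd else 0.0)
            d = max(d, 1.0)
            s = _beta_draw(rng, params.s_mean, params.s_sd)
            if params.wl_sd or config.fecundity_sd:
                wl = rng.normal(params.wl_mean, params.wl_sd, size=config.females_per_tray)
                fec = (config.fecundity_intercept + config.fecundity_slope * wl
                       + rng.normal(0.0, config.fecundity_sd, size=config.females_per_tray))
                fec = np.clip(fec, 0.0, None)
                wl_mean = float(wl.mean())
                f_mean = float(fec.mean())
            else:
                wl = np.full(config.females_per_tray, params.wl_mean)
                fec = np.full(
                    config.females_per_tray,
                    max(config.fecundity_intercept
                        + config.fecundity_slope * params.wl_mean, 0.0),
                )
                wl_mean = params.wl_mean
                f_mean = float(fec[0])
            rows.append((size, treat, rep, d, s, wl_mean, f_mean))
            for w, f in zip(wl, fec):
                female_rows.append((size, treat, rep, float(w), float(f)))
    table = pd.DataFrame(
        rows,
        columns=["Size", config.treatment_name, "Replicate",
                 "Development", "Survival", "Winglength", "Fecundity"],
    )
    if not return_females:
        return table
    females = pd.DataFrame(
        female_rows,
        columns=["Size", config.treatment_name, "Replicate", "MM", "Fecundity"],
    )
    return table, females


def study_density_config(seed: int = 0) -> LifeSimConfig:
    """Density-experiment preset: 2 densities × 3 sizes, 4–5 trays per cell.

    High density slows development, more so in larger containers (~1–3 days
    longer in large vs small), lowers survival and shrinks adults; low
    density traits are near-uniform across sizes.
    """
    cells = {
        ("Small", "Low"): CellParams(8.6, 0.90, 3.25, d_sd=0.35, s_sd=0.04, wl_sd=0.08),
        ("Medium", "Low"): CellParams(8.8, 0.90, 3.25, d_sd=0.35, s_sd=0.04, wl_sd=0.08),
        ("Large", "Low"): CellParams(9.1, 0.89, 3.22, d_sd=0.35, s_sd=0.04, wl_sd=0.08),
        ("Small", "High"): CellParams(11.5, 0.76, 2.92, d_sd=0.45, s_sd=0.06, wl_sd=0.10),
        ("Medium", "High"): CellParams(12.3, 0.74, 2.90, d_sd=0.45, s_sd=0.06, wl_sd=0.10),
        ("Large", "High"): CellParams(13.8, 0.72, 2.88, d_sd=0.45, s_sd=0.06, wl_sd=0.10),
    }
    replicates = {c: (5 if c[0] == "Small" else 4) for c in cells}
    return LifeSimConfig(cells=cells, treatment_name="Density",
                         replicates=replicates, seed=seed)


def study_diet_config(seed: int = 0) -> LifeSimConfig:
    """Diet-experiment preset: 3 diets × 3 sizes, 5 trays per cell.

    Less diet slows development and shrinks adults; on the low diet, large
    containers add ~1.2 days over medium and ~2.7 over small.  Survival is
    diet-independent.
    """
    cells = {}
    d_means = {
        ("High", "Small"): 8.0, ("High", "Medium"): 8.3, ("High", "Large"): 8.6,
        ("Medium", "Small"): 9.0, ("Medium", "Medium"): 9.5, ("Medium", "Large"): 10.0,
        ("Low", "Small"): 9.3, ("Low", "Medium"): 10.8, ("Low", "Large"): 12.0,
    }
    wl_means = {"High": 3.30, "Medium": 3.10, "Low": 2.85}
    for (diet, size), d in d_means.items():
        cells[(size, diet)] = CellParams(
            d, 0.88, wl_means[diet], d_sd=0.4, s_sd=0.05, wl_sd=0.08
        )
    return LifeSimConfig(cells=cells, treatment_name="Diet", replicates=5, seed=seed)


def container_via_development_config(seed: int = 0) -> LifeSimConfig:
    """Fixture where container size affects productivity only through D.

    Survival, winglength and fecundity are dispersion-free constants, so all
    PI variation flows through development time: container offsets of 0,
    1.5 and 3.0 days over a 9-day baseline with 0.3-day tray noise.
    Holding D constant then freezes PI entirely.
    """
    cells = {}
    for size, off in (("Small", 0.0), ("Medium", 1.5), ("Large", 3.0)):
        for treat in ("Low", "High"):
            cells[(size, treat)] = CellParams(9.0 + off, 0.85, 3.10, d_sd=0.3)
    return LifeSimConfig(cells=cells, treatment_name="Density", replicates=5,
                         fecundity_sd=0.0, seed=seed)


def to_s4_schema(table: pd.DataFrame, formula: str = "ln100fs") -> pd.DataFrame:
    """Project a simulated table onto the tray-level productivity CSV schema.

    Adds Hatch (assumed 100%) and the PI column; treatment column is kept
    under its own name (Density or Diet).
    """
    from .lifehistory import productivity_table

    with_pi, errors = productivity_table(table, formula=formula)
    if errors:
        raise SimulationError(f"invalid rows: {errors}")
    treat = table.columns[1]
    out = with_pi[["Size", treat, "Replicate", "Fecundity", "Survival",
                   "Development", "PI"]].copy()
    out.insert(3, "Hatch", 100.0)
    return out
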