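"""Synthetic inputs with the statistical structure the pipeline assumes.

Generates fluorescence z-stacks with known droplet ground truth (rod-shaped
cell interiors on a dark background, droplets as compact Gaussian spots with
optional touching pairs, Poisson photon noise plus Gaussian read noise, a
fraction of dead cells fully covered by an exclusion mask), plate-reader
growth curves (lag / exponential / plateau with multiplicative noise) and
per-cell phenotype tables with a planted association between the 'cut'
phenotype and the absence of detectable lipid droplets. All generators are
pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .image_io import ExclusionMask, ZStack
from .quantification import PHENOTYPE_COLUMNS
from .stats import GrowthCurve

__all__ = [
    "ImageSimParams",
    "GroundTruth",
    "simulate_stack",
    "simulate_growth",
    "simulate_phenotypes",
]


@dataclass
class ImageSimParams:
    """Knobs of the image simulator; defaults emulate the study's acquisitions.

    Geometry follows the imaging setup being emulated: 16-bit stacks of 10
    slices 0.3 um apart, fission-yeast rods a few microns long (tens of
    pixels at ~0.1 um/px), droplets a few hundred nanometres across rendered
    as Gaussian spots 2-5 px in radius. ``amplitude_range`` is set well above
    the cytoplasm level so the top quantization class captures spot cores
    (dim droplets included); ``sigma_z`` is wide, as in widefield imaging
    where out-of-focus droplet light reaches every slice. ``cluster_fraction``
    of droplets are planted as touching pairs to exercise the recursive
    splitting path.
    """

    height: int = 512
    width: int = 512
    n_slices: int = 10
    z_step: float = 0.3
    n_cells: int = 8
    cell_length_range: tuple[int, int] = (40, 70)
    cell_width_range: tuple[int, int] = (12, 18)
    droplets_per_cell: tuple[str, float, float] = ("zip", 3.0, 0.25)
    droplet_radius_range: tuple[float, float] = (3.0, 5.0)
    amplitude_range: tuple[float, float] = (12000.0, 17000.0)
    cluster_fraction: float = 0.0
    background_level: float = 200.0
    cytoplasm_level: float = 1200.0
    read_noise_sigma: float = 60.0
    dead_cell_fraction: float = 0.0
    sigma_z: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.height, self.width, self.n_slices, self.n_cells + 1) <= 0:
            raise ValueError("dimensions must be positive (n_cells >= 0)")
        for frac in (self.cluster_fraction, self.dead_cell_fraction):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if self.amplitude_range[0] <= self.background_level:
            raise ValueError("droplet amplitude must exceed the background level")


@dataclass
class GroundTruth:
    """Planted scene description used to verify pipeline recovery.

    ``droplets`` columns: cell_id, row, col, z, radius, amplitude,
    in_cluster. ``cells`` columns: cell_id, row0, col0, row1, col1 (bounding
    box of the rod footprint), dead.
    """

    droplets: pd.DataFrame
    cells: pd.DataFrame
    params: ImageSimParams

    @property
    def n_droplets(self) -> int:
        return len(self.droplets)


def _place_cells(params: ImageSimParams, rng: np.random.Generator):
    """Axis-aligned non-overlapping rod footprints via rejection sampling."""
    boxes: list[tuple[int, int, int, int]] = []  # r0, c0, r1, c1 (exclusive)
    margin = 8
    for _ in range(params.n_cells):
        placed = False
        for _attempt in range(2000):
            length = int(rng.integers(*params.cell_length_range, endpoint=True))
            width = int(rng.integers(*params.cell_width_range, endpoint=True))
            horizontal = bool(rng.integers(0, 2))
            h, w = (width, length) if horizontal else (length, width)
            if params.height - h - 2 * margin <= 0 or params.width - w - 2 * margin <= 0:
                continue
            r0 = int(rng.integers(margin, params.height - h - margin))
            c0 = int(rng.integers(margin, params.width - w - margin))
            box = (r0, c0, r0 + h, c0 + w)
            pad = 6  # keep neighbouring cells apart
            if all(box[2] + pad <= b[0] or b[2] + pad <= box[0]
                   or box[3] + pad <= b[1] or b[3] + pad <= box[1] for b in boxes):
                boxes.append(box)
                placed = True
                break
        if not placed:
            raise RuntimeError("cannot place cells: image too crowded")
    return boxes


def _rod_mask(box: tuple[int, int, int, int], shape) -> np.ndarray:
    """Rectangle with rounded (quarter-disc) ends — a crude rod footprint."""
    r0, c0, r1, c1 = box
    mask = np.zeros(shape, dtype=bool)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    h, w = r1 - r0, c1 - c0
    if w >= h:  # horizontal rod: rounded left/right caps of radius h/2
        rad = h / 2.0
        cyl = (cc >= c0 + rad) & (cc < c1 - rad)
        left = (rr - (r0 + rad - 0.5)) ** 2 + (cc - (c0 + rad - 0.5)) ** 2 <= rad**2
        right = (rr - (r0 + rad - 0.5)) ** 2 + (cc - (c1 - rad - 0.5)) ** 2 <= rad**2
        mask[r0:r1, c0:c1] = cyl | left | right
    else:
        rad = w / 2.0
        cyl = (rr >= r0 + rad) & (rr < r1 - rad)
        top = (cc - (c0 + rad - 0.5)) ** 2 + (rr - (r0 + rad - 0.5)) ** 2 <= rad**2
        bot = (cc - (c0 + rad - 0.5)) ** 2 + (rr - (r1 - rad - 0.5)) ** 2 <= rad**2
        mask[r0:r1, c0:c1] = cyl | top | bot
    return mask


def _n_droplets_for_cell(spec, rng: np.random.Generator) -> int:
    kind = spec[0]
    if kind == "fixed":
        return int(spec[1])
    if kind == "zip":  # zero-inflated Poisson: (mean of the Poisson part, P(zero class))
        _, mean, zero_frac = spec
        if rng.random() < zero_frac:
            return 0
        return int(rng.poisson(mean))
    raise ValueError(f"unknown droplet-count distribution {spec!r}")


def simulate_stack(params: ImageSimParams | None = None,
                   seed: int | None = None):
    """Render a synthetic z-stack plus its exclusion mask and ground truth.

    Returns ``(stack, exclusion_mask, truth, cell_labels)``. Dead cells are
    rendered dimmer and their footprints (dilated by 2 px) are covered by
    the exclusion mask, so droplets planted inside them must be removed by
    the pipeline's mask-overlap filter. ``seed`` overrides ``params.seed``.
    """
    if params is None:
        params = ImageSimParams()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    shape = (params.height, params.width)
    boxes = _place_cells(params, rng)

    ideal = np.full((params.n_slices,) + shape, params.background_level)
    cell_labels = np.zeros(shape, dtype=np.int32)
    exclusion = np.zeros(shape, dtype=bool)
    cell_rows, droplet_rows = [], []

    n_dead = int(round(params.dead_cell_fraction * len(boxes)))
    dead_ids = set(rng.choice(len(boxes), size=n_dead, replace=False).tolist()) if n_dead else set()

    for i, box in enumerate(boxes):
        cell_id = i + 1
        dead = i in dead_ids
        footprint = _rod_mask(box, shape)
        cell_labels[footprint] = cell_id
        level = params.cytoplasm_level * (0.4 if dead else 1.0)
        ideal[:, footprint] += level - params.background_level
        if dead:
            r0, c0, r1, c1 = box
            exclusion[max(0, r0 - 2):r1 + 2, max(0, c0 - 2):c1 + 2] = True
        cell_rows.append({"cell_id": cell_id, "row0": box[0], "col0": box[1],
                          "row1": box[2], "col1": box[3], "dead": dead})

        n_drop = _n_droplets_for_cell(params.droplets_per_cell, rng)
        centers = _droplet_centers(box, footprint, n_drop, params, rng)
        for (r, c, clustered) in centers:
            # size and peak brightness co-vary (a larger droplet carries
            # more dye): shared latent size u with lognormal scatter on top
            u = float(rng.uniform())
            rlo_, rhi_ = params.droplet_radius_range
            alo_, ahi_ = params.amplitude_range
            radius = rlo_ + u * (rhi_ - rlo_)
            amp = float(alo_ * (ahi_ / alo_) ** u * rng.lognormal(0.0, 0.05))
            z0 = float(rng.uniform(0.38, 0.62) * (params.n_slices - 1))
            _render_spot(ideal, r, c, z0, radius, amp, params.sigma_z)
            droplet_rows.append({"cell_id": cell_id, "row": r, "col": c, "z": z0,
                                 "radius": radius, "amplitude": amp,
                                 "in_cluster": clustered})

    noisy = rng.poisson(np.clip(ideal, 0, None)).astype(np.float64)
    noisy += rng.normal(0.0, params.read_noise_sigma, size=ideal.shape)
    planes = np.clip(np.round(noisy), 0, 2**16 - 1).astype(np.uint16)

    stack = ZStack(planes=planes, pixel_depth=16, z_step=params.z_step,
                   channel="synthetic-green")
    truth = GroundTruth(
        droplets=pd.DataFrame(droplet_rows, columns=["cell_id", "row", "col", "z",
                                                     "radius", "amplitude", "in_cluster"]),
        cells=pd.DataFrame(cell_rows, columns=["cell_id", "row0", "col0",
                                               "row1", "col1", "dead"]),
        params=params,
    )
    return stack, ExclusionMask(exclusion), truth, cell_labels


def _droplet_centers(box, footprint, n_drop, params: ImageSimParams,
                     rng: np.random.Generator):
    """Droplet centres inside the cell, kept mutually separated except for
    planted touching pairs (cluster_fraction)."""
    r0, c0, r1, c1 = box
    rmax = params.droplet_radius_range[1]
    centers: list[tuple[int, int, bool]] = []
    min_sep = 4 * rmax + 4
    placed = 0
    while placed < n_drop:
        as_pair = (n_drop - placed >= 2) and (rng.random() < params.cluster_fraction)
        rlo, rhi = r0 + int(rmax) + 1, r1 - int(rmax) - 1
        clo, chi = c0 + int(rmax) + 1, c1 - int(rmax) - 1
        for _attempt in range(500):
            r = int(rng.integers(rlo, rhi)) if rhi > rlo else (r0 + r1) // 2
            c = int(rng.integers(clo, chi)) if chi > clo else (c0 + c1) // 2
            if not footprint[r, c]:
                continue
            if all((r - pr) ** 2 + (c - pc) ** 2 >= min_sep**2 for pr, pc, _ in centers):
                break
        else:
            return centers  # cell too small for more well-separated droplets
        if as_pair:
            # partner at distance < sum of radii: the rendered pair touches
            angle = rng.uniform(0, 2 * np.pi)
            d = 1.5 * rmax
            pr = int(round(r + d * np.sin(angle)))
            pc = int(round(c + d * np.cos(angle)))
            pr = int(np.clip(pr, r0 + 1, r1 - 2))
            pc = int(np.clip(pc, c0 + 1, c1 - 2))
            centers.append((r, c, True))
            centers.append((pr, pc, True))
            placed += 2
        else:
            centers.append((r, c, False))
            placed += 1
    return centers


def _render_spot(ideal: np.ndarray, r: int, c: int, z0: float,
                 radius: float, amplitude: float, sigma_z: float) -> None:
    """Add a Gaussian spot truncated at 2*radius in-plane, Gaussian along z."""
    n_slices, height, width = ideal.shape
    ext = int(np.ceil(2 * radius))
    rr, cc = np.mgrid[max(0, r - ext):min(height, r + ext + 1),
                      max(0, c - ext):min(width, c + ext + 1)]
    d2 = (rr - r) ** 2 + (cc - c) ** 2
    lateral = np.exp(-d2 / (2 * (radius / 1.5) ** 2))
    lateral[d2 > (2 * radius) ** 2] = 0.0
    for z in range(n_slices):
        axial = np.exp(-((z - z0) ** 2) / (2 * sigma_z**2))
        ideal[z, rr, cc] += amplitude * axial * lateral


def simulate_growth(dt: float = 3.0, lag: float = 2.0, plateau_od: float = 0.6,
                    noise_sigma: float = 0.02, n_points: int = 73,
                    seed: int = 0, od0: float = 0.05,
                    interval_h: float = 1 / 6, label: str = "synthetic") -> GrowthCurve:
    """Simulate a plate-reader growth curve.

    Lag (constant at ``od0``), exponential doubling every ``dt`` hours,
    plateau at ``plateau_od``; multiplied by log-normal noise with the given
    log-sigma. Defaults give a 12 h run sampled every 10 minutes.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    rng = np.random.default_rng(seed)
    times = np.arange(n_points) * interval_h
    od = od0 * np.power(2.0, np.clip(times - lag, 0, None) / dt)
    od = np.minimum(od, plateau_od)
    if noise_sigma > 0:
        od = od * rng.lognormal(mean=0.0, sigma=noise_sigma, size=od.shape)
    return GrowthCurve(times=times, od=od, label=label)


def simulate_phenotypes(n_cells: int = 300,
                        p_cut_given_no_droplets: float = 0.6,
                        p_cut_given_droplets: float = 0.05,
                        droplet_count_distribution: tuple = ("zip", 3.0, 0.3),
                        seed: int = 0,
                        strain: str = "synthetic",
                        medium: str = "YES",
                        mean_droplet_intensity: float = 5e4) -> pd.DataFrame:
    """Simulate per-cell phenotype records with a planted 'cut' association.

    Droplet counts are drawn from a zero-inflated Poisson; 'cut' status is
    Bernoulli conditional on droplet presence. With
    ``p_cut_given_no_droplets > p_cut_given_droplets`` the planted enrichment
    of 'cut' among droplet-free cells is recoverable by a one-sided Fisher
    exact test on :func:`~dropletquant.quantification.cut_by_droplet_contingency`.
    """
    for p in (p_cut_given_no_droplets, p_cut_given_droplets):
        if not 0 <= p <= 1:
            raise ValueError("probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    records = []
    for cell_id in range(1, n_cells + 1):
        count = _n_droplets_for_cell(droplet_count_distribution, rng)
        p_cut = p_cut_given_droplets if count > 0 else p_cut_given_no_droplets
        total = float(rng.gamma(count, mean_droplet_intensity)) if count > 0 else 0.0
        records.append({
            "cell_id": cell_id,
            "strain": strain,
            "medium": medium,
            "cut_status": bool(rng.random() < p_cut),
            "droplet_count": count,
            "total_intensity": total,
        })
    return pd.DataFrame(records, columns=PHENOTYPE_COLUMNS)
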