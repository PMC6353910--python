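"""Ground-truthed synthetic inputs for every analysis stage.

Real tomograms for this kind of experiment are rarely deposited, so the
test bench is synthetic: section images with dark globular particles of
known positions and sizes, NPC annotation scenes with known frames and
particle coordinates, and equilibrium occupancy censuses.  Every generator
is deterministic under its seed and returns the truth table next to the
data, so each pipeline stage can be checked as a parameter-recovery
problem.

Defaults emulate the wild-type yeast measurements: ~19 nm globular
particles at nucleoplasmic densities near 75/um^2, NPCs of 100 nm pore
width in a 31 nm envelope, a three-Gaussian ring mixture along Y (centers
-21.5, 1.2, 25.1 nm), near-axis X in the nuclear/inner rings and a 5.4 nm
off-axis shift at the cytoplasmic ring, and Bernoulli/geometric occupancy
at rate psi = 0.054.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .morphometry import SectionImage
from .npc_mapper import NpcAnnotation
from .queueing import JacksonModel, snapshot_census

__all__ = [
    "SceneConfig",
    "NpcSceneConfig",
    "generate_section",
    "generate_npc_scene",
    "generate_census",
]


@dataclass
class SceneConfig:
    """Configuration of a synthetic tomogram section.

    Particles are rendered as dark discs of Gaussian-blurred edge
    (``blur_sigma_nm``), with diameters drawn Normal(mean, sd), placed
    uniformly without overlap at a Poisson-distributed count matching
    ``density`` (particles/um^2).  Additive Gaussian noise of standard
    deviation ``contrast / snr`` is applied; ``snr`` is therefore the
    particle depth in noise-sigma units.
    """

    pixel_size: float = 1.01  # nm / px
    shape: tuple[int, int] = (1024, 1024)
    particle_diameter: float = 19.0  # nm, mean
    particle_diameter_sd: float = 1.5  # nm
    density: float = 75.0  # particles / um^2
    background: float = 1.0
    contrast: float = 0.5  # depth of a particle below background
    snr: float = 5.0
    blur_sigma_nm: float = 2.0
    margin_nm: float = 8.0  # minimum gap between particle edges (resolved objects)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.pixel_size, self.particle_diameter, self.density, self.contrast) <= 0:
            raise ValueError("pixel_size, particle_diameter, density, contrast must be > 0")
        if self.snr < 0 or self.particle_diameter_sd < 0:
            raise ValueError("snr and particle_diameter_sd must be >= 0")
        if self.particle_diameter / self.pixel_size < 2:
            raise ValueError("particle diameter must span >= 2 px at this pixel size")

    @property
    def area_um2(self) -> float:
        return self.shape[0] * self.shape[1] * self.pixel_size**2 * 1e-6

    @property
    def noise_sd(self) -> float:
        return self.contrast / self.snr if self.snr > 0 else 0.0


def generate_section(config: SceneConfig) -> tuple[SectionImage, pd.DataFrame]:
    """Render a synthetic section image plus its particle truth table.

    Returns ``(image, truth)`` where ``truth`` has columns x_nm, y_nm,
    diameter_nm.  Raises if the requested density is infeasible without
    overlap (reporting the achievable maximum).
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.shape
    px = config.pixel_size
    n_target = rng.poisson(config.density * config.area_um2)

    # rejection-sample non-overlapping centers, keeping particles inside the frame
    max_r_nm = (config.particle_diameter + 4 * config.particle_diameter_sd) / 2
    centers: list[np.ndarray] = []
    radii: list[float] = []
    budget = 200 * max(n_target, 1)
    attempts = 0
    while len(centers) < n_target and attempts < budget:
        attempts += 1
        d = rng.normal(config.particle_diameter, config.particle_diameter_sd)
        d = float(np.clip(d, 2 * px, 2 * max_r_nm))
        r = d / 2
        x = rng.uniform(r + config.margin_nm, w * px - r - config.margin_nm)
        y = rng.uniform(r + config.margin_nm, h * px - r - config.margin_nm)
        c = np.array([x, y])
        ok = all(
            np.linalg.norm(c - c0) >= r + r0 + config.margin_nm
            for c0, r0 in zip(centers, radii)
        )
        if ok:
            centers.append(c)
            radii.append(r)
    if len(centers) < n_target:
        achievable = len(centers) / config.area_um2
        raise ValueError(
            f"density {config.density}/um^2 infeasible without overlap; "
            f"achieved at most ~{achievable:.0f}/um^2"
        )

    img = np.zeros((h, w), dtype=float)
    yy, xx = np.mgrid[:h, :w]
    for c, r in zip(centers, radii):
        cx, cy = c / px
        rp = r / px
        lo_r, hi_r = max(int(cy - rp) - 3, 0), min(int(cy + rp) + 4, h)
        lo_c, hi_c = max(int(cx - rp) - 3, 0), min(int(cx + rp) + 4, w)
        sub = (xx[lo_r:hi_r, lo_c:hi_c] - cx) ** 2 + (yy[lo_r:hi_r, lo_c:hi_c] - cy) ** 2
        img[lo_r:hi_r, lo_c:hi_c] += (sub <= rp**2).astype(float)
    img = gaussian_filter(img, config.blur_sigma_nm / px)
    img = config.background - config.contrast * img
    if config.noise_sd > 0:
        img = img + rng.normal(0.0, config.noise_sd, size=img.shape)

    truth = pd.DataFrame(
        {
            "x_nm": [c[0] for c in centers],
            "y_nm": [c[1] for c in centers],
            "diameter_nm": [2 * r for r in radii],
        }
    )
    image = SectionImage(img, pixel_size=px, provenance=f"synthetic(seed={config.seed})")
    return image, truth


@dataclass
class NpcSceneConfig:
    """Configuration of a synthetic NPC annotation scene.

    Per NPC, the particle count is drawn from the geometric equilibrium law
    at occupancy ``psi``; particle Y positions come from the three-Gaussian
    ring mixture, X from a near-axis Gaussian (nuclear/inner) or a folded
    Gaussian off-axis shift with random sign (cytoplasmic).  Each
    annotation is emitted in a random rigid pose (rotation + translation)
    so the mapper genuinely has to invert the frame.
    """

    n_npcs: int = 818
    psi: float = 0.054
    ring_weights: tuple = (0.18, 0.49, 0.33)
    ring_means: tuple = (-21.5, 1.2, 25.1)  # nm
    ring_sds: tuple = (5.8, 6.1, 6.8)  # nm
    x_sd: float = 0.65  # nm, nuclear + inner rings
    x_cyt_mean: float = 5.4  # nm, cytoplasmic off-axis shift
    x_cyt_sd: float = 3.7
    pore_width: float = 100.0
    pore_width_sd: float = 5.0
    envelope_width: float = 31.0
    envelope_width_sd: float = 3.0
    nucleolar_fraction: float = 0.34
    scene_extent: float = 2000.0  # nm, span of random translations
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.psi < 1:
            raise ValueError("psi must be in [0, 1)")
        if abs(sum(self.ring_weights) - 1.0) > 1e-9:
            raise ValueError("ring_weights must sum to 1")
        if self.n_npcs <= 0:
            raise ValueError("n_npcs must be > 0")


def _sample_position(cfg: NpcSceneConfig, rng: np.random.Generator) -> tuple[float, float, str]:
    ring_idx = rng.choice(3, p=np.asarray(cfg.ring_weights))
    ring = ("nuclear", "inner", "cytoplasmic")[ring_idx]
    Y = rng.normal(cfg.ring_means[ring_idx], cfg.ring_sds[ring_idx])
    if ring == "cytoplasmic":
        shift = abs(rng.normal(cfg.x_cyt_mean, cfg.x_cyt_sd))
        X = shift * (1 if rng.random() < 0.5 else -1)
    else:
        X = rng.normal(0.0, cfg.x_sd)
    return X, Y, ring


def generate_npc_scene(
    config: NpcSceneConfig,
) -> tuple[list[NpcAnnotation], pd.DataFrame]:
    """Generate annotated NPCs in random poses plus the truth positions.

    Returns ``(annotations, truth)``; ``truth`` has one row per particle
    with npc_id, particle_id, the generating X/Y (nm) and ring label.
    """
    rng = np.random.default_rng(config.seed)
    annotations = []
    truth_rows = []
    for i in range(config.n_npcs):
        npc_id = f"npc{i:04d}"
        pore_w = rng.normal(config.pore_width, config.pore_width_sd)
        env_w = rng.normal(config.envelope_width, config.envelope_width_sd)
        # canonical frame: median plane along x, +y cytoplasmic
        local_edges = {
            "edge_outer_left": np.array([-pore_w / 2, env_w / 2]),
            "edge_inner_left": np.array([-pore_w / 2, -env_w / 2]),
            "edge_outer_right": np.array([pore_w / 2, env_w / 2]),
            "edge_inner_right": np.array([pore_w / 2, -env_w / 2]),
        }
        if config.psi == 0:
            n_particles = 0
        else:
            n_particles = int(rng.geometric(1.0 - config.psi) - 1)
        local_particles = []
        ids = []
        for j in range(n_particles):
            X, Y, ring = _sample_position(config, rng)
            pid = f"{npc_id}_p{j}"
            local_particles.append(np.array([X, Y]))
            ids.append(pid)
            truth_rows.append(
                {"npc_id": npc_id, "particle_id": pid, "X_nm": X, "Y_nm": Y, "ring": ring}
            )
        theta = rng.uniform(0, 2 * np.pi)
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        shift = rng.uniform(-config.scene_extent, config.scene_extent, size=2)
        side = "nucleolar" if rng.random() < config.nucleolar_fraction else "nucleoplasmic"
        annotations.append(
            NpcAnnotation(
                npc_id=npc_id,
                edge_points={k: rot @ v + shift for k, v in local_edges.items()},
                particles=[rot @ p + shift for p in local_particles],
                particle_ids=ids,
                compartment_side=side,
            )
        )
    return annotations, pd.DataFrame(
        truth_rows, columns=["npc_id", "particle_id", "X_nm", "Y_nm", "ring"]
    )


def generate_census(
    psi: float,
    n_snapshots: int,
    seed: int = 0,
    n_servers: int = 110,
    flux_per_min: float = 4000.0,
):
    """Equilibrium occupancy census at the given occupancy rate.

    Thin wrapper over :func:`porequeue.queueing.snapshot_census` that
    builds the matching Jackson model first.
    """
    dwell = psi * n_servers / (flux_per_min / 60.0)
    model = JacksonModel(flux_per_min / 60.0, n_servers, dwell)
    return snapshot_census(model, n_snapshots, seed)
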