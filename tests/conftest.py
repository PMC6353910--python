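import numpy as np
import pytest

from porequeue.npc_mapper import NpcAnnotation


def disc_mask(radius: int, size: int | None = None) -> np.ndarray:
    """Binary mask of a rasterized disc (pixel centers within ``radius``)."""
    size = size or int(2 * radius + 12)
    yy, xx = np.mgrid[:size, :size]
    c = size / 2
    return np.hypot(yy - c, xx - c) <= radius


def square_mask(side: int, size: int | None = None) -> np.ndarray:
    size = size or side + 10
    m = np.zeros((size, size), bool)
    m[5 : 5 + side, 5 : 5 + side] = True
    return m


def mask_to_region(mask: np.ndarray, intensity: np.ndarray | None = None):
    """Single regionprops region for a one-component mask."""
    from skimage import measure

    labels = measure.label(mask, connectivity=2)
    regions = measure.regionprops(labels, intensity_image=intensity)
    assert len(regions) == 1
    return regions[0]


def symmetric_annotation(
    npc_id: str = "npc0",
    pore_width: float = 100.0,
    envelope_width: float = 31.0,
    particles=(),
    **kwargs,
) -> NpcAnnotation:
    """Canonical annotation: median plane along x, +y cytoplasmic."""
    hw, he = pore_width / 2, envelope_width / 2
    return NpcAnnotation(
        npc_id=npc_id,
        edge_points={
            "edge_outer_left": np.array([-hw, he]),
            "edge_inner_left": np.array([-hw, -he]),
            "edge_outer_right": np.array([hw, he]),
            "edge_inner_right": np.array([hw, -he]),
        },
        particles=[np.asarray(p, dtype=float) for p in particles],
        **kwargs,
    )


def rigid_transform(annotation: NpcAnnotation, angle_deg: float, shift) -> NpcAnnotation:
    th = np.deg2rad(angle_deg)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    shift = np.asarray(shift, dtype=float)
    return NpcAnnotation(
        npc_id=annotation.npc_id,
        edge_points={k: rot @ v + shift for k, v in annotation.edge_points.items()},
        particles=[rot @ p + shift for p in annotation.particles],
        particle_ids=list(annotation.particle_ids),
        compartment_side=annotation.compartment_side,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
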