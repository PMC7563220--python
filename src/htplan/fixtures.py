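"""Synthetic benchmark fixtures with known symmetry or closed-form behavior.

These are *not* anatomical phantoms: they are deliberately simple material
layouts (homogeneous disks, blocks) whose physics can be predicted
analytically or by symmetry, used to validate the solver, the dosimetry
chain and the optimizer.
"""

from __future__ import annotations

import numpy as np

from .phantom import LABEL_CODES, VoxelPhantom

__all__ = ["disk_phantom", "homogeneous_block_materials"]


def disk_phantom(
    radius_mm: float = 120.0,
    target_radius_mm: float = 20.0,
    spacing_mm: float = 5.0,
    nz: int = 3,
) -> VoxelPhantom:
    """Homogeneous muscle disk with a central target region.

    The target carries the muscle label (the material stays uniform); the
    GTV/HTV masks mark the central disk as the evaluation region.  With a
    symmetric ring applicator the THQ-optimal drive is all channels equal
    in amplitude and phase, which makes this the optimizer's ground-truth
    fixture.
    """
    nh = int(np.ceil(radius_mm / spacing_mm)) + 1
    n = 2 * nh + 1
    coords = (np.arange(n) - nh) * spacing_mm
    xx, yy = np.meshgrid(coords, coords, indexing="ij")
    rr = np.hypot(xx, yy)
    disk = rr <= radius_mm
    target = rr <= target_radius_mm
    labels = np.zeros((n, n, nz), dtype=np.int16)
    labels[disk] = LABEL_CODES["muscle"]
    gtv = np.zeros((n, n, nz), dtype=bool)
    gtv[:, :, nz // 2] = target
    return VoxelPhantom(
        labels=labels,
        spacing_mm=spacing_mm,
        origin_mm=(0.0, 0.0, 0.0),
        gtv_mask=gtv,
        htv_mask=gtv.copy(),
        params={"fixture": "disk", "radius_mm": radius_mm},
    )


def homogeneous_block_materials(
    shape: tuple[int, ...],
    eps_r: float,
    sigma: float,
    rho: float,
    spacing_mm: float,
):
    """Uniform-material grid (no phantom, no masks) for propagation tests."""
    from .fdtd import MaterialGrids

    center = tuple(s // 2 for s in shape)
    return MaterialGrids(
        eps_r=np.full(shape, float(eps_r)),
        sigma=np.full(shape, float(sigma)),
        rho=np.full(shape, float(rho)),
        labels=np.zeros(shape, dtype=np.int16),
        spacing_mm=spacing_mm,
        center=center,
    )
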