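"""Synthetic cardiac CT phantoms with paired 10-class label maps.

The private hospital dataset the framework was designed around cannot
be redistributed, so this module generates seedable stand-ins that
reproduce its *statistical* structure: ten substructures with a fixed
four-chamber in-slice arrangement (LV upper-left, RV upper-right, LA
lower-left, RA lower-right), three medium vessels with circular cross
sections (ascending/descending aorta as axial tubes, a branching
pulmonary artery touching the RV), and three thin veins (PV entering
the LA, IVC below the RA, SVC just right of the AA).  Voxel counts
honour the real dataset's severe size imbalance — the four chambers
dwarf the vessels, the LV is the largest structure and the SVC the
smallest — and the veins get intensity means close to their
neighbouring structure, reproducing the low-contrast regime that makes
them hard to segment.

Geometry is built from parametric primitives (ellipsoids and tubes) on
an anisotropic grid (default 5 mm slices, finer in-plane), which is all
the cascade's size-imbalance mechanics need and keeps every case fully
reproducible from one integer seed.  Inter-patient variation is
emulated with per-structure position jitter and ±10% size jitter.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .imageio import LabelMap, Volume, write_labelmap, write_volume
from .registry import ACRONYMS, get

__all__ = ["PhantomSpec", "generate_phantom", "generate_dataset", "write_dataset"]

# HU-like intensity means on the 0..2048 scale.  Veins (PV/IVC/SVC) sit
# 20 HU from their anatomical neighbour (LA/RA/AA) so the shared border
# is nearly invisible once blur and noise are applied.
DEFAULT_MEANS: dict[str, float] = {
    "LV": 1220.0,
    "RV": 1140.0,
    "LA": 1190.0,
    "RA": 1120.0,
    "AA": 1260.0,
    "DA": 1230.0,
    "PA": 1090.0,
    "PV": 1170.0,
    "IVC": 1100.0,
    "SVC": 1240.0,
}
DEFAULT_BACKGROUND = 950.0


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic case.

    ``shape`` is (n_slices, height, width); ``spacing`` is (dz, dy, dx)
    in mm.  ``contrast_scale`` multiplies every structure's offset from
    the background mean, providing a difficulty axis: 0 makes
    structures invisible, large values make a plain threshold
    sufficient.  ``position_jitter`` (fraction of each dimension) and
    ``size_jitter`` (relative) control inter-case anatomical variation.
    """

    shape: tuple[int, int, int] = (16, 96, 96)
    spacing: tuple[float, float, float] = (5.0, 1.0, 1.0)
    means: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MEANS))
    background: float = DEFAULT_BACKGROUND
    intensity_sd: float = 25.0
    contrast_scale: float = 1.0
    noise_sigma: float = 40.0
    blur_sigma: float = 1.0
    position_jitter: float = 0.0
    size_jitter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 8 for s in self.shape):
            raise ValueError(f"shape components must be >= 8, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if self.noise_sigma < 0:
            raise ValueError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        missing = [a for a in ACRONYMS if a not in self.means]
        if missing:
            raise ValueError(f"means missing structures: {missing}")


# --- parametric geometry -------------------------------------------------
# All coordinates and radii are fractions of the corresponding grid
# dimension (z, y, x); painting order is large -> small so the thin
# vessels overwrite (and hence guarantee contact with) their neighbours.

_ELLIPSOIDS = {
    # acronym: center (z, y, x), semi-axes (z, y, x)
    "LV": ((0.50, 0.36, 0.33), (0.30, 0.17, 0.16)),
    "RV": ((0.50, 0.35, 0.67), (0.28, 0.15, 0.14)),
    "LA": ((0.50, 0.70, 0.34), (0.26, 0.13, 0.13)),
    "RA": ((0.50, 0.70, 0.66), (0.25, 0.125, 0.12)),
}

PAINT_ORDER = ("LV", "RV", "LA", "RA", "AA", "DA", "PA", "PV", "IVC", "SVC")


def _grid(shape):
    z, y, x = np.indices(shape, dtype=np.float32)
    return z, y, x


def _ellipsoid(grid, shape, center, semi):
    z, y, x = grid
    (nz, ny, nx) = shape
    cz, cy, cx = center[0] * nz, center[1] * ny, center[2] * nx
    sz, sy, sx = semi[0] * nz, semi[1] * ny, semi[2] * nx
    if min(sz, sy, sx) < 0.5:
        return None
    return ((z - cz) / sz) ** 2 + ((y - cy) / sy) ** 2 + ((x - cx) / sx) ** 2 <= 1.0


def _axis_index(frac: float, n: int) -> int:
    return int(np.clip(round(frac * n), 0, n - 1))


def _ztube(grid, shape, cy, cx, ry, rx, z0, z1):
    z, y, x = grid
    nz, ny, nx = shape
    ry_v, rx_v = ry * ny, rx * nx
    if min(ry_v, rx_v) < 0.5:
        return None
    zrange = (z >= z0 * nz) & (z <= z1 * nz)
    inplane = ((y - cy * ny) / ry_v) ** 2 + ((x - cx * nx) / rx_v) ** 2 <= 1.0
    # a tube is never thinner than its discrete axis line
    axis = (y == _axis_index(cy, ny)) & (x == _axis_index(cx, nx))
    return (inplane | axis) & zrange


def _xtube(grid, shape, cz, cy, rz, ry, x0, x1):
    z, y, x = grid
    nz, ny, nx = shape
    rz_v, ry_v = rz * nz, ry * ny
    if min(rz_v, ry_v) < 0.5:
        return None
    xrange_ = (x >= x0 * nx) & (x <= x1 * nx)
    cross = ((z - cz * nz) / rz_v) ** 2 + ((y - cy * ny) / ry_v) ** 2 <= 1.0
    axis = (z == _axis_index(cz, nz)) & (y == _axis_index(cy, ny))
    return (cross | axis) & xrange_


def _ytube(grid, shape, cz, cx, rz, rx, y0, y1):
    z, y, x = grid
    nz, ny, nx = shape
    rz_v, rx_v = rz * nz, rx * nx
    if min(rz_v, rx_v) < 0.5:
        return None
    yrange = (y >= y0 * ny) & (y <= y1 * ny)
    cross = ((z - cz * nz) / rz_v) ** 2 + ((x - cx * nx) / rx_v) ** 2 <= 1.0
    axis = (z == _axis_index(cz, nz)) & (x == _axis_index(cx, nx))
    return (cross | axis) & yrange


def _jitters(spec: PhantomSpec, rng: np.random.Generator):
    """Per-structure (dz, dy, dx) position shift (fractions) and size factor."""
    out = {}
    for a in PAINT_ORDER:
        shift = rng.uniform(-spec.position_jitter, spec.position_jitter, size=3)
        size = 1.0 + rng.uniform(-spec.size_jitter, spec.size_jitter)
        out[a] = (shift, size)
    return out


def _paint_structure(acronym, grid, shape, shift, size):
    sz, sy, sx = shift
    if acronym in _ELLIPSOIDS:
        (c, semi) = _ELLIPSOIDS[acronym]
        c = (c[0] + sz, c[1] + sy, c[2] + sx)
        semi = tuple(s * size for s in semi)
        return _ellipsoid(grid, shape, c, semi)
    if acronym == "AA":
        return _ztube(grid, shape, 0.15 + sy, 0.46 + sx, 0.055 * size, 0.055 * size, 0.08, 0.92)
    if acronym == "DA":
        return _ztube(grid, shape, 0.88 + sy, 0.52 + sx, 0.045 * size, 0.045 * size, 0.08, 0.92)
    if acronym == "PA":
        # branch attaches at the RV surface (shallow penetration): the
        # vessels meet the chambers at their walls rather than tunnelling
        # through them
        main = _xtube(grid, shape, 0.50 + sz, 0.13 + sy, 0.12 * size, 0.040 * size, 0.55 + sx, 0.85 + sx)
        branch = _ytube(grid, shape, 0.50 + sz, 0.67 + sx, 0.12 * size, 0.030 * size, 0.11 + sy, 0.26 + sy)
        if main is None or branch is None:
            return None
        return main | branch
    if acronym == "PV":
        return _xtube(grid, shape, 0.50 + sz, 0.70 + sy, 0.10 * size, 0.023 * size, 0.08 + sx, 0.26 + sx)
    if acronym == "IVC":
        return _ztube(grid, shape, 0.82 + sy, 0.68 + sx, 0.026 * size, 0.026 * size, 0.05, 0.55)
    if acronym == "SVC":
        return _ztube(grid, shape, 0.15 + sy, 0.56 + sx, 0.019 * size, 0.019 * size, 0.08, 0.92)
    raise KeyError(acronym)


def generate_phantom(spec: PhantomSpec) -> tuple[Volume, LabelMap]:
    """Generate one paired (CT-like volume, 10-class label map) case.

    Deterministic for a fixed ``spec`` (including its seed).  Raises if
    any structure cannot be represented at the requested resolution.
    """
    shape = tuple(int(s) for s in spec.shape)
    rng = np.random.default_rng(spec.seed)
    jit = _jitters(spec, rng)

    grid = _grid(shape)
    labels = np.zeros(shape, dtype=np.int16)
    for acronym in PAINT_ORDER:
        shift, size = jit[acronym]
        mask = _paint_structure(acronym, grid, shape, shift, size)
        if mask is None or not mask.any():
            raise ValueError(
                f"structure {acronym} cannot fit in shape {shape}; "
                "increase the grid size"
            )
        labels[mask] = get(acronym).code
    # painting order lets small vessels overwrite chambers; re-check
    # that nothing was wiped out entirely
    present = set(np.unique(labels).tolist())
    for acronym in PAINT_ORDER:
        if get(acronym).code not in present:
            raise ValueError(
                f"structure {acronym} cannot fit in shape {shape} "
                "(fully overwritten by later structures)"
            )

    img = np.full(shape, spec.background, dtype=np.float32)
    for acronym in PAINT_ORDER:
        code = get(acronym).code
        mean_eff = spec.background + spec.contrast_scale * (
            spec.means[acronym] - spec.background
        )
        img[labels == code] = mean_eff
    img += rng.normal(0.0, spec.intensity_sd, size=shape).astype(np.float32)
    if spec.blur_sigma > 0:
        dz, dy, dx = spec.spacing
        sigma = (spec.blur_sigma * dx / dz, spec.blur_sigma, spec.blur_sigma)
        img = ndimage.gaussian_filter(img, sigma=sigma)
    if spec.noise_sigma > 0:
        img += rng.normal(0.0, spec.noise_sigma, size=shape).astype(np.float32)
    img = np.clip(img, 0.0, 2048.0)

    return (
        Volume(img.astype(np.float32), spec.spacing, intensity_kind="HU"),
        LabelMap(labels, spec.spacing),
    )


def case_seed(master_seed: int, index: int) -> int:
    """Stable per-case seed derived from a master seed."""
    return int(np.random.SeedSequence([int(master_seed), int(index)]).generate_state(1)[0] % (2**31))


def generate_dataset(
    n_cases: int,
    spec: PhantomSpec | None = None,
    seed: int = 0,
) -> list[tuple[Volume, LabelMap]]:
    """Generate ``n_cases`` phantoms with inter-case anatomical variation.

    Each case gets a seed derived deterministically from ``seed`` and,
    unless the spec overrides them, position jitter of 2% and size
    jitter of 10% to emulate patient-to-patient variability.
    """
    if n_cases < 1:
        raise ValueError(f"n_cases must be >= 1, got {n_cases}")
    base = spec or PhantomSpec()
    if spec is None or (base.position_jitter == 0 and base.size_jitter == 0):
        base = replace(base, position_jitter=0.02, size_jitter=0.10)
    out = []
    for i in range(n_cases):
        out.append(generate_phantom(replace(base, seed=case_seed(seed, i))))
    return out


def write_dataset(
    cases: list[tuple[Volume, LabelMap]],
    outdir: str | os.PathLike,
    seed: int | None = None,
) -> list[str]:
    """Write cases as paired NIfTI files plus a manifest.tsv; returns case ids."""
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    ids = []
    with open(os.path.join(outdir, "manifest.tsv"), "w") as fh:
        fh.write("case_id\tseed\timage\tlabels\n")
        for i, (vol, lab) in enumerate(cases):
            cid = f"case_{i:03d}"
            img_path = os.path.join(outdir, f"{cid}_image.nii.gz")
            lab_path = os.path.join(outdir, f"{cid}_labels.nii.gz")
            write_volume(vol, img_path)
            write_labelmap(lab, lab_path)
            sd = case_seed(seed, i) if seed is not None else ""
            fh.write(f"{cid}\t{sd}\t{os.path.basename(img_path)}\t{os.path.basename(lab_path)}\n")
            ids.append(cid)
    return ids
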