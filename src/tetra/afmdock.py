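"""AFM topograph simulation and rigid envelope docking.

An AFM topograph is a height map h(x, y) in nm of molecules adsorbed on a
flat substrate (the substrate plane is 0). Simulated topographs use
hard-sphere tip dilation: each atom of radius r probed by a spherical tip of
radius R contributes

    z_atom + sqrt((r + R)^2 - d^2) - R

at lateral distance d, wherever the root is real.

Docking places a rigid atomic model at every lateral grid position and
sampled rotation, grounds it on the substrate, and scores the pose by the
number of atoms inside the "favorable layer" - a shell of configurable
thickness just beneath the AFM envelope. The score maps to a pseudo-energy
E = -N_favorable so that the best score is the lowest energy. Atoms poking
above the envelope beyond a clash tolerance invalidate the pose (the
envelope is a physical upper bound on where matter can be); a soft-penalty
mode is available for exploration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .structio import AtomicModel, RigidTransform

ANGSTROM_PER_NM = 10.0


class TopographError(ValueError):
    pass


@dataclass
class Topograph:
    heights: np.ndarray  # (ny, nx), nm
    pixel_size: float  # nm
    origin: tuple[float, float] = (0.0, 0.0)  # (x0, y0) nm of the grid corner

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2 or min(self.heights.shape) < 2:
            raise TopographError("height grid must be 2-D and at least 2x2")
        if not np.all(np.isfinite(self.heights)) or np.any(self.heights < 0):
            raise TopographError("heights must be finite and >= 0")
        if self.pixel_size <= 0:
            raise TopographError("pixel_size must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.heights.shape

    def grid_center(self) -> tuple[float, float]:
        ny, nx = self.heights.shape
        x0, y0 = self.origin
        return (x0 + nx * self.pixel_size / 2.0, y0 + ny * self.pixel_size / 2.0)

    def pixel_center(self, iy: int, ix: int) -> tuple[float, float]:
        x0, y0 = self.origin
        return (x0 + (ix + 0.5) * self.pixel_size, y0 + (iy + 0.5) * self.pixel_size)

    def save(self, matrix_path: str, sidecar_path: str | None = None) -> None:
        """Plain-text matrix plus a JSON sidecar carrying pixel size and units."""
        np.savetxt(matrix_path, self.heights, fmt="%.6f")
        if sidecar_path is None:
            sidecar_path = matrix_path + ".json"
        with open(sidecar_path, "w") as fh:
            json.dump(
                {"pixel_size_nm": self.pixel_size, "origin_nm": list(self.origin),
                 "units": "nm"},
                fh, indent=1,
            )

    @classmethod
    def load(cls, matrix_path: str, sidecar_path: str | None = None) -> "Topograph":
        heights = np.loadtxt(matrix_path)
        if sidecar_path is None:
            sidecar_path = matrix_path + ".json"
        with open(sidecar_path) as fh:
            meta = json.load(fh)
        return cls(heights, float(meta["pixel_size_nm"]), tuple(meta.get("origin_nm", (0.0, 0.0))))


def max_height(topo: Topograph) -> float:
    """Whole-field maximum height in nm."""
    return float(topo.heights.max())


# -- topograph simulation ---------------------------------------------------


def simulate_topograph(
    model: AtomicModel,
    pixel_size: float = 0.5,
    tip_radius: float = 1.0,
    atom_radius: float = 0.15,
    pad: float = 1.0,
    shape: tuple[int, int] | None = None,
) -> Topograph:
    """Hard-sphere tip-dilated height map of a grounded model.

    All length arguments are nm. The model is grounded so the lowest atom
    sphere touches the substrate (min over atoms of z - atom_radius = 0) and
    its centroid is placed on the center pixel's center, so the placement is
    commensurate with the grid (a discrete rigid search can reproduce it
    exactly). The grid covers the model bounding box plus ``pad`` unless an
    explicit ``shape`` is given.
    """
    model._require_nonempty()
    if pixel_size <= 0:
        raise TopographError("pixel_size must be > 0")
    if tip_radius < 0 or atom_radius <= 0:
        raise TopographError("tip_radius must be >= 0 and atom_radius > 0")
    xyz = model.coords / ANGSTROM_PER_NM
    z = xyz[:, 2] - (xyz[:, 2].min() - atom_radius)
    reach = atom_radius + tip_radius
    cx, cy = xyz[:, 0].mean(), xyz[:, 1].mean()
    if shape is None:
        half_x = np.abs(xyz[:, 0] - cx).max() + pad + reach
        half_y = np.abs(xyz[:, 1] - cy).max() + pad + reach
        nx = max(2, 2 * int(np.ceil(half_x / pixel_size)) + 1)
        ny = max(2, 2 * int(np.ceil(half_y / pixel_size)) + 1)
    else:
        ny, nx = shape
    # centroid on the center pixel's center: the placement stays inside the
    # discrete pose space searched by dock()
    x = xyz[:, 0] - cx + (nx // 2 + 0.5) * pixel_size
    y = xyz[:, 1] - cy + (ny // 2 + 0.5) * pixel_size

    heights = np.zeros((ny, nx))
    px = (np.arange(nx) + 0.5) * pixel_size
    py = (np.arange(ny) + 0.5) * pixel_size
    win = int(np.ceil(reach / pixel_size)) + 1
    for xa, ya, za in zip(x, y, z):
        jx = int(xa / pixel_size)
        jy = int(ya / pixel_size)
        j0, j1 = max(0, jx - win), min(nx, jx + win + 1)
        i0, i1 = max(0, jy - win), min(ny, jy + win + 1)
        if j0 >= j1 or i0 >= i1:
            continue
        dx = px[j0:j1] - xa
        dy = py[i0:i1] - ya
        d2 = dx[None, :] ** 2 + dy[:, None] ** 2
        disc = reach * reach - d2
        contrib = np.where(disc >= 0, za + np.sqrt(np.maximum(disc, 0.0)) - tip_radius, 0.0)
        np.maximum(heights[i0:i1, j0:j1], np.maximum(contrib, 0.0), out=heights[i0:i1, j0:j1])
    return Topograph(heights, pixel_size)


# -- docking ----------------------------------------------------------------


@dataclass(frozen=True)
class Pose:
    transform: RigidTransform  # nm frame: model centroid -> grid position
    angles: tuple[float, ...]  # sampled Euler angles, degrees
    grid_ij: tuple[int, int]  # (iy, ix) of centroid pixel
    n_favorable: int
    n_protruding: int
    energy: float  # -n_favorable in hard-clash mode


@dataclass
class DockResult:
    poses: list[Pose]  # ascending energy
    min_energy: float | None
    mean_energy_top10: float | None
    rmsd_top3: float | None  # Angstrom, no superposition
    xy_offset_best: float | None  # nm from grid center
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_poses(self) -> int:
        return len(self.poses)


def _rotation_grid(rotation_step: float, mode: str) -> list[tuple[float, ...]]:
    angles = np.arange(0.0, 360.0, rotation_step)
    if mode == "z":
        return [(float(a),) for a in angles]
    if mode == "euler":
        tilt = np.arange(0.0, 180.0, rotation_step)
        return [
            (float(a), float(b), float(c))
            for a in angles
            for b in tilt
            for c in angles
        ]
    raise TopographError(f"unknown rotation mode {mode!r}")


def _rotated_coords(model_nm: np.ndarray, angles: tuple[float, ...]) -> np.ndarray:
    if len(angles) == 1:
        rt = RigidTransform.about_z(angles[0])
    else:
        rt = RigidTransform.from_euler(angles)
    centered = model_nm - model_nm.mean(axis=0)
    coords = rt.apply(centered)
    coords[:, 2] -= coords[:, 2].min()  # ground: min atom z = 0
    return coords


def place_coords(
    model: AtomicModel, topo: Topograph, angles: tuple[float, ...], grid_ij: tuple[int, int]
) -> np.ndarray:
    """Atom coordinates (nm) of the model placed at a pose."""
    coords = _rotated_coords(model.coords / ANGSTROM_PER_NM, angles)
    cx, cy = topo.pixel_center(*grid_ij)
    out = coords.copy()
    out[:, 0] += cx
    out[:, 1] += cy
    return out


def score_pose(
    model: AtomicModel,
    topo: Topograph,
    angles: tuple[float, ...],
    grid_ij: tuple[int, int],
    layer_thickness: float = 1.0,
    clash_tolerance: float = 0.3,
) -> tuple[int, int, bool]:
    """Independent single-pose score: (n_favorable, n_protruding, valid).

    An atom is favorable iff h - layer_thickness <= z <= h at its pixel;
    protruding iff z > h + clash_tolerance; a pose with any atom off-grid is
    invalid.
    """
    coords = place_coords(model, topo, angles, grid_ij)
    ny, nx = topo.shape
    ix = np.floor((coords[:, 0] - topo.origin[0]) / topo.pixel_size).astype(int)
    iy = np.floor((coords[:, 1] - topo.origin[1]) / topo.pixel_size).astype(int)
    if np.any((ix < 0) | (ix >= nx) | (iy < 0) | (iy >= ny)):
        return 0, 0, False
    h = topo.heights[iy, ix]
    z = coords[:, 2]
    fav = int(np.sum((z >= h - layer_thickness) & (z <= h)))
    prot = int(np.sum(z > h + clash_tolerance))
    return fav, prot, True


def dock(
    model: AtomicModel,
    topo: Topograph,
    rotation_step: float = 30.0,
    layer_thickness: float = 1.0,
    keep: int = 100_000,
    clash_tolerance: float = 0.3,
    rotation_mode: str = "z",
    clash_mode: str = "hard",
    soft_penalty: float = 1.0,
) -> DockResult:
    """Exhaustive rigid search of a model over a topograph.

    The search covers the rotation grid times every integer-pixel lateral
    placement of the model centroid. For each pose the model is grounded
    (lowest atom center at z = 0) and scored by the favorable-layer count;
    the ranked result reports the four pose statistics: minimum energy, mean
    energy of the top 10, mean pairwise C-alpha RMSD of the top 3 (no
    superposition, Angstrom), and the lateral offset of the best pose's
    centroid from the grid center (nm).
    """
    model._require_nonempty()
    ny, nx = topo.shape
    p = topo.pixel_size
    model_nm = model.coords / ANGSTROM_PER_NM
    records: list[tuple[float, tuple[float, ...], int, int, int, int]] = []
    for angles in _rotation_grid(rotation_step, rotation_mode):
        coords = _rotated_coords(model_nm, angles)
        z = coords[:, 2]
        # centroid sits at a pixel center; each atom then falls in a fixed
        # integer-offset pixel, so scoring vectorizes over all placements
        dj = np.floor(coords[:, 0] / p + 0.5).astype(int)
        di = np.floor(coords[:, 1] / p + 0.5).astype(int)
        i_lo, i_hi = -di.min(), ny - 1 - di.max()
        j_lo, j_hi = -dj.min(), nx - 1 - dj.max()
        if i_lo > i_hi or j_lo > j_hi:
            continue  # model does not fit at this rotation
        wi = i_hi - i_lo + 1
        wj = j_hi - j_lo + 1
        fav = np.zeros((wi, wj), dtype=int)
        prot = np.zeros((wi, wj), dtype=int)
        H = topo.heights
        for a in range(len(z)):
            hs = H[i_lo + di[a]: i_lo + di[a] + wi, j_lo + dj[a]: j_lo + dj[a] + wj]
            fav += (z[a] >= hs - layer_thickness) & (z[a] <= hs)
            prot += z[a] > hs + clash_tolerance
        if clash_mode == "hard":
            valid = prot == 0
            energy = -fav.astype(float)
        elif clash_mode == "soft":
            valid = np.ones_like(prot, dtype=bool)
            energy = -fav.astype(float) + soft_penalty * prot
        else:
            raise TopographError(f"unknown clash_mode {clash_mode!r}")
        for ii, jj in zip(*np.nonzero(valid)):
            records.append(
                (float(energy[ii, jj]), angles, i_lo + ii, j_lo + jj,
                 int(fav[ii, jj]), int(prot[ii, jj]))
            )
    if not records:
        return DockResult([], None, None, None, None,
                          diagnostics={"reason": "no valid pose (model may not fit grid)"})
    records.sort(key=lambda r: (r[0], r[1], r[2], r[3]))
    records = records[:keep]
    poses = []
    for energy, angles, iy, ix, nfav, nprot in records:
        cx, cy = topo.pixel_center(iy, ix)
        if len(angles) == 1:
            rt = RigidTransform.about_z(angles[0], (cx, cy, 0.0))
        else:
            rt = RigidTransform.from_euler(angles, (cx, cy, 0.0))
        poses.append(Pose(rt, angles, (iy, ix), nfav, nprot, energy))

    energies = np.array([p_.energy for p_ in poses])
    top10 = energies[: min(10, len(energies))]
    rmsd3 = _pairwise_ca_rmsd(model, topo, poses[: min(3, len(poses))])
    best = poses[0]
    gx, gy = topo.grid_center()
    bx, by = topo.pixel_center(*best.grid_ij)
    offset = float(np.hypot(bx - gx, by - gy))
    return DockResult(
        poses=poses,
        min_energy=float(energies[0]),
        mean_energy_top10=float(top10.mean()),
        rmsd_top3=rmsd3,
        xy_offset_best=offset,
        diagnostics={
            "n_valid_poses": len(records),
            "rotation_step_deg": rotation_step,
            "layer_thickness_nm": layer_thickness,
            "clash_tolerance_nm": clash_tolerance,
            "clash_mode": clash_mode,
        },
    )


def _pairwise_ca_rmsd(model: AtomicModel, topo: Topograph, poses: Sequence[Pose]) -> float | None:
    """Mean pairwise RMSD (Angstrom) of placed C-alpha atoms, no superposition."""
    if len(poses) < 2:
        return 0.0 if poses else None
    mask = model.atom_names == "CA"
    if not mask.any():
        mask = np.ones(model.n_atoms, dtype=bool)  # toy models without CA naming
    placed = []
    for pose in poses:
        coords = place_coords(model, topo, pose.angles, pose.grid_ij)
        placed.append(coords[mask] * ANGSTROM_PER_NM)
    vals = []
    for a in range(len(placed)):
        for b in range(a + 1, len(placed)):
            diff = placed[a] - placed[b]
            vals.append(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))
    return float(np.mean(vals))
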