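"""Seeded generators for every synthetic input the pipeline consumes.

All generators are pure functions of (parameters, seed): the same call
produces byte-identical output. The geometric models are deliberately
abstract stand-ins — a helix or bead chain for a protein chain, a compact
ball with a thin arm for a bi-partite particle (a compact dimer from which
filamentous arms extend) — carrying just enough structure (named C-alpha /
C-beta anchors, two height regimes, plantable cross-link distances) to
exercise the restraint, docking, and titration machinery.
"""

from __future__ import annotations

import numpy as np

from .itc import Isotherm
from .afmdock import Topograph
from .structio import AtomicModel
from .xlinks import CrossLink


class SynthError(ValueError):
    pass


MIN_SEPARATION = 2.0  # Angstrom, self-avoidance floor for generated models


# -- atomic models ----------------------------------------------------------


def _chain_coords(n_res: int, geometry: str, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """(CA coords, CB coords) for one chain, local frame, Angstrom."""
    t = np.arange(n_res)
    if geometry == "helix":
        radius, rise, turn = 2.3, 1.5, np.deg2rad(100.0)
        ca = np.stack(
            [radius * np.cos(turn * t), radius * np.sin(turn * t), rise * t], axis=1
        )
        radial = np.stack([np.cos(turn * t), np.sin(turn * t), np.zeros(n_res)], axis=1)
        cb = ca + 2.2 * radial
    elif geometry == "beads":
        ca = np.stack([3.9 * t, np.zeros(n_res), np.zeros(n_res)], axis=1)
        cb = ca + np.array([0.0, 0.0, 2.2])
    else:
        raise SynthError(f"unknown geometry {geometry!r}")
    jitter = rng.uniform(-0.05, 0.05, size=ca.shape)
    return ca + jitter, cb + jitter


def toy_model(
    n_chains: int = 2,
    residues_per_chain: int = 10,
    geometry: str = "helix",
    seed: int = 0,
    glycine_every: int = 0,
) -> AtomicModel:
    """Self-avoiding multi-chain model with CA and CB atoms per residue.

    ``glycine_every > 0`` plants a glycine (no C-beta) at every k-th residue.
    Retries chain placement a bounded number of times to keep every atom
    pair at least 2 Angstrom apart.
    """
    if n_chains < 1 or residues_per_chain < 1:
        raise SynthError("counts must be >= 1")
    rng = np.random.default_rng(seed)
    chain_ids, res_ids, res_names, atom_names, coords = [], [], [], [], []
    placed: list[np.ndarray] = []
    for k in range(n_chains):
        chain = chr(ord("A") + k)
        for attempt in range(50):
            ca, cb = _chain_coords(residues_per_chain, geometry, rng)
            offset = np.array([0.0, 12.0 * k, 0.0]) + rng.uniform(-1, 1, 3) * (attempt > 0)
            ca_o, cb_o = ca + offset, cb + offset
            new = np.vstack([ca_o, cb_o])
            if placed:
                prev = np.vstack(placed)
                d = np.linalg.norm(prev[:, None, :] - new[None, :, :], axis=2)
                if d.min() < MIN_SEPARATION:
                    continue
            break
        else:
            raise SynthError("could not place chains without clashes")
        for r in range(residues_per_chain):
            res = r + 1
            is_gly = glycine_every > 0 and res % glycine_every == 0
            name = "GLY" if is_gly else "ALA"
            chain_ids.append(chain)
            res_ids.append(res)
            res_names.append(name)
            atom_names.append("CA")
            coords.append(ca_o[r])
            if not is_gly:
                chain_ids.append(chain)
                res_ids.append(res)
                res_names.append(name)
                atom_names.append("CB")
                coords.append(cb_o[r])
        placed.append(np.vstack([ca_o, cb_o]))
    return AtomicModel(
        np.array(chain_ids), np.array(res_ids), np.array(res_names),
        np.array(atom_names), np.array(coords), title=f"toy_model(seed={seed})",
    )


def bipartite_model(
    core_radius: float = 2.0, arm_length: float = 6.0, seed: int = 0
) -> AtomicModel:
    """Compact ball (chain A) plus a thin low-lying arm (chain B); nm arguments.

    Emulates a bi-partite particle: a compact body from which a filamentous
    arm extends, with the arm strictly lower than the body so a simulated
    topograph shows two height regimes.
    """
    if arm_length <= core_radius:
        raise SynthError("arm_length must exceed core_radius")
    rng = np.random.default_rng(seed)
    core_r = core_radius * 10.0  # Angstrom
    arm_l = arm_length * 10.0
    spacing = 3.5
    # core: jittered cubic lattice clipped to a ball, resting on z >= 0
    grid = np.arange(-core_r, core_r + spacing, spacing)
    pts = np.array([(x, y, z) for x in grid for y in grid for z in grid])
    pts = pts[np.linalg.norm(pts, axis=1) <= core_r]
    pts = pts + rng.uniform(-0.3, 0.3, pts.shape)
    pts[:, 2] -= pts[:, 2].min()
    n_core = len(pts)
    # arm: single strand at low z, leaving the core along +x
    n_arm = max(3, int(arm_l / spacing))
    arm_x = core_r + spacing + spacing * np.arange(n_arm)
    arm = np.stack([arm_x, np.zeros(n_arm), np.full(n_arm, 2.0)], axis=1)
    arm += rng.uniform(-0.2, 0.2, arm.shape)
    assert arm[:, 2].max() < pts[:, 2].max()
    coords = np.vstack([pts, arm])
    chain_ids = np.array(["A"] * n_core + ["B"] * n_arm)
    res_ids = np.concatenate([np.arange(1, n_core + 1), np.arange(1, n_arm + 1)])
    res_names = np.array(["ALA"] * (n_core + n_arm))
    atom_names = np.array(["CA"] * (n_core + n_arm))
    return AtomicModel(chain_ids, res_ids, res_names, atom_names, coords,
                       title=f"bipartite_model(seed={seed})")


# -- cross-link planting ----------------------------------------------------


def _anchor_table(model: AtomicModel) -> dict[tuple[str, int], np.ndarray]:
    anchors: dict[tuple[str, int], np.ndarray] = {}
    for i in range(model.n_atoms):
        key = (str(model.chain_ids[i]), int(model.res_ids[i]))
        name = model.atom_names[i]
        if name == "CB" or (name == "CA" and key not in anchors):
            anchors[key] = model.coords[i]
    return anchors


def sample_crosslinks(
    model: AtomicModel,
    n: int = 40,
    satisfied_fraction: float = 0.75,
    seed: int = 0,
    bounds: tuple[float, float] = (3.0, 24.0),
) -> tuple[list[CrossLink], list[bool]]:
    """Cross-links with a planted fraction of in-band anchor distances.

    Exactly round(n * satisfied_fraction) sampled residue pairs have a
    C-beta (C-alpha fallback) distance inside ``bounds``; the rest lie
    outside. Returns the links (protein id = chain id) and the ground-truth
    in-band labels, aligned.
    """
    if not 0 <= satisfied_fraction <= 1:
        raise SynthError("satisfied_fraction must be in [0, 1]")
    anchors = _anchor_table(model)
    keys = sorted(anchors)
    in_band, out_band = [], []
    for a in range(len(keys)):
        for b in range(a + 1, len(keys)):
            d = float(np.linalg.norm(anchors[keys[a]] - anchors[keys[b]]))
            (in_band if bounds[0] <= d <= bounds[1] else out_band).append((keys[a], keys[b]))
    n_in = round(n * satisfied_fraction)
    n_out = n - n_in
    if len(in_band) < n_in or len(out_band) < n_out:
        raise SynthError(
            f"infeasible demand: need {n_in} in-band / {n_out} out-of-band pairs, "
            f"model offers {len(in_band)} / {len(out_band)}"
        )
    rng = np.random.default_rng(seed)
    picks = [(in_band[i], True) for i in rng.choice(len(in_band), n_in, replace=False)]
    picks += [(out_band[i], False) for i in rng.choice(len(out_band), n_out, replace=False)]
    rng.shuffle(picks)
    links, labels = [], []
    for ((c1, r1), (c2, r2)), label in picks:
        links.append(CrossLink(c1, r1, c2, r2, "DSS"))
        labels.append(label)
    return links, labels


# -- noise ------------------------------------------------------------------


def noisy_isotherm(iso: Isotherm, sd: float, seed: int = 0) -> Isotherm:
    """Add iid zero-mean Gaussian noise (kJ/mol) to the normalized heats."""
    if sd < 0:
        raise SynthError("sd must be >= 0")
    rng = np.random.default_rng(seed)
    q = iso.q_norm + (rng.normal(0.0, sd, iso.n_injections) if sd > 0 else 0.0)
    meta = dict(iso.metadata)
    meta.update({"noise_sd": sd, "noise_seed": seed})
    return Isotherm(iso.molar_ratio.copy(), q, iso.injection_volumes_ul, meta)


def noisy_topograph(topo: Topograph, sd: float, seed: int = 0) -> Topograph:
    """Per-pixel Gaussian height noise (nm), clipped at the substrate plane."""
    if sd < 0:
        raise SynthError("sd must be >= 0")
    rng = np.random.default_rng(seed)
    if sd == 0:
        return Topograph(topo.heights.copy(), topo.pixel_size, topo.origin)
    noisy = topo.heights + rng.normal(0.0, sd, topo.heights.shape)
    out = Topograph(np.maximum(noisy, 0.0), topo.pixel_size, topo.origin)
    out.n_clipped = int(np.sum(noisy < 0))  # bookkeeping for diagnostics
    return out
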