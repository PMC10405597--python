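"""Torsion-angle Monte Carlo conformer generation.

Each trial perturbs one backbone dihedral of a residue drawn uniformly from
the user-declared flexible segments by a uniform random angle in
[-max_step, +max_step], rotating every atom downstream (C-terminal) of the
rotated bond about the bond axis.  The trial is accepted iff the perturbed
model is free of steric clashes; accepted conformers accumulate into a pool.
Bond lengths and angles are untouched — only dihedrals move — so all rigid
(non-flexible) internal geometry is preserved exactly.

For all-atom models the rotatable bonds are phi (N-CA) and psi (CA-C); for
coarse-grained single-bead chains (one CA per residue) the pseudo-dihedral
about each CA(k)-CA(k+1) virtual bond is used.

A clash is a heavy-atom pair, excluding bonded (1-2) and angle (1-3)
neighbours, closer than overlap_fraction * (radius_i + radius_j).  The
default overlap_fraction of 0.8 reflects that united-atom group radii are
inflated relative to van der Waals radii.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .model_io import ProteinModel, SegmentSpec
from .scattering import rg_from_model

#: heavy-atom pairs closer than this fraction of summed group radii clash
DEFAULT_OVERLAP_FRACTION = 0.8
#: covalent-bond distance cutoff used to build the exclusion topology, A
BOND_CUTOFF = 2.0
#: virtual CA-CA bonds in coarse-grained chains are ~3.8 A
PSEUDO_BOND_CUTOFF = 4.2


@dataclass
class ClashParams:
    overlap_fraction: float = DEFAULT_OVERLAP_FRACTION


@dataclass
class ConformerPool:
    """Accepted conformers plus run provenance."""

    models: list[ProteinModel]
    rg_values: list[float]
    n_trials: int
    n_accepted: int
    stride: int = 1
    seed: int = 0
    segments: SegmentSpec | None = None

    def __len__(self):
        return len(self.models)

    def manifest(self) -> dict:
        return {
            "n_trials": self.n_trials,
            "n_accepted": self.n_accepted,
            "n_models": len(self.models),
            "stride": self.stride,
            "seed": self.seed,
            "segments": self.segments.ranges if self.segments else [],
            "rg_min": float(min(self.rg_values)) if self.rg_values else None,
            "rg_max": float(max(self.rg_values)) if self.rg_values else None,
        }

    def write_manifest(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.manifest(), fh, indent=2)


# ---------------------------------------------------------------------------
# topology helpers


def _bond_list(model: ProteinModel) -> list[tuple[int, int]]:
    """Covalent bonds (distance-inferred) or virtual CA-CA chain bonds."""
    coords = model.coords
    is_bead = all(n == "CA" for n in model.atom_names)
    if is_bead:
        # beads bond only along the chain; folded-back contacts are not bonds
        ridx = model.residue_index
        return [(i, i + 1) for i in range(len(coords) - 1)
                if ridx[i + 1] == ridx[i] + 1]
    tree = cKDTree(coords)
    pairs = tree.query_pairs(BOND_CUTOFF)
    return sorted((min(i, j), max(i, j)) for i, j in pairs)


def _exclusion_pairs(model: ProteinModel) -> set[tuple[int, int]]:
    """1-2 (bonded) and 1-3 (angle) atom pairs, as sorted index tuples."""
    bonds = _bond_list(model)
    neighbours: dict[int, set[int]] = {}
    for i, j in bonds:
        neighbours.setdefault(i, set()).add(j)
        neighbours.setdefault(j, set()).add(i)
    excl = set(bonds)
    for center, nbrs in neighbours.items():
        nbrs = sorted(nbrs)
        for a in range(len(nbrs)):
            for b in range(a + 1, len(nbrs)):
                excl.add((nbrs[a], nbrs[b]))
    return excl


def clash_check(model: ProteinModel, clash_params: ClashParams | None = None,
                _exclusions: set | None = None) -> tuple[bool, int]:
    """(is_clash_free, n_clashes) under the fractional-overlap criterion."""
    if model.radius is None:
        raise ValueError("group radii not assigned; run assign_scattering_factors")
    cp = clash_params or ClashParams()
    excl = _exclusions if _exclusions is not None else _exclusion_pairs(model)
    radii = model.radius
    cutoff = cp.overlap_fraction * 2.0 * radii.max()
    tree = cKDTree(model.coords)
    n_clashes = 0
    for i, j in tree.query_pairs(cutoff):
        i, j = (i, j) if i < j else (j, i)
        if (i, j) in excl:
            continue
        d = np.linalg.norm(model.coords[i] - model.coords[j])
        if d < cp.overlap_fraction * (radii[i] + radii[j]):
            n_clashes += 1
    return n_clashes == 0, n_clashes


# ---------------------------------------------------------------------------
# rotatable bonds


def _rotatable_bonds(model: ProteinModel, segments: SegmentSpec) -> list[tuple[int, int, int]]:
    """(axis_atom_1, axis_atom_2, first_moved_atom) per rotatable dihedral.

    Atoms strictly after the second axis atom (file order) move; the
    N-terminal part of the chain is the fixed anchor.
    """
    names = model.atom_names
    ridx = model.residue_index
    flex = set(segments.residues())
    is_bead = all(n == "CA" for n in names)
    bonds: list[tuple[int, int, int]] = []
    if is_bead:
        for i in range(len(names) - 1):
            # pseudo-dihedral about the CA(k)-CA(k+1) virtual bond, rotating k+2...
            if int(ridx[i]) in flex and i + 2 < len(names):
                bonds.append((i, i + 1, i + 2))
        return bonds
    # all-atom: phi = N-CA, psi = CA-C of each flexible residue
    by_res: dict[int, dict[str, int]] = {}
    for i, (nm, ri) in enumerate(zip(names, ridx)):
        by_res.setdefault(int(ri), {})[str(nm)] = i
    for ri in sorted(flex):
        atoms = by_res.get(ri)
        if not atoms:
            continue
        if "N" in atoms and "CA" in atoms:
            first_moved = atoms["CA"] + 1
            if first_moved < len(names):
                bonds.append((atoms["N"], atoms["CA"], first_moved))
        if "CA" in atoms and "C" in atoms:
            first_moved = atoms["C"] + 1
            if first_moved < len(names):
                bonds.append((atoms["CA"], atoms["C"], first_moved))
    return bonds


def _rotate_downstream(coords: np.ndarray, axis_a: int, axis_b: int,
                       first_moved: int, angle_rad: float) -> None:
    """Rotate coords[first_moved:] about the axis_a->axis_b axis, in place."""
    origin = coords[axis_b]
    axis = coords[axis_b] - coords[axis_a]
    norm = np.linalg.norm(axis)
    if norm < 1e-9:
        return
    k = axis / norm
    pts = coords[first_moved:] - origin
    cos, sin = np.cos(angle_rad), np.sin(angle_rad)
    # Rodrigues rotation
    rotated = (pts * cos
               + np.cross(k, pts) * sin
               + k[None, :] * (pts @ k)[:, None] * (1.0 - cos))
    coords[first_moved:] = rotated + origin


# ---------------------------------------------------------------------------
# sampling


def sample_pool(model: ProteinModel, segments: SegmentSpec, n_trials: int,
                max_step_deg: float = 30.0, seed: int = 0,
                clash_params: ClashParams | None = None) -> ConformerPool:
    """Monte Carlo pool generation over flexible-segment dihedrals.

    Every trial perturbs one dihedral; clash-free results are appended to the
    pool (the chain continues from the accepted conformer; rejected moves are
    undone).  Bit-reproducible for a given seed.
    """
    if segments is None or len(segments) == 0:
        raise ValueError("no flexible segments to sample")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if not (0 < max_step_deg <= 180):
        raise ValueError("max_step_deg must be in (0, 180]")
    if model.radius is None:
        raise ValueError("assign scattering factors before sampling")
    bonds = _rotatable_bonds(model, segments)
    if not bonds:
        raise ValueError("segments contain no rotatable dihedrals")
    rng = np.random.default_rng(seed)
    excl = _exclusion_pairs(model)
    cp = clash_params or ClashParams()
    current = model.copy()
    accepted: list[ProteinModel] = []
    rgs: list[float] = []
    for _ in range(n_trials):
        b = bonds[rng.integers(len(bonds))]
        angle = np.deg2rad(rng.uniform(-max_step_deg, max_step_deg))
        trial = current.copy()
        _rotate_downstream(trial.coords, b[0], b[1], b[2], angle)
        ok, _n = clash_check(trial, cp, _exclusions=excl)
        if ok:
            current = trial
            snap = trial.copy()
            snap.label = f"{model.label}#mc{len(accepted) + 1}"
            accepted.append(snap)
            rgs.append(rg_from_model(snap))
    if not accepted:
        warnings.warn("no conformers accepted; returning empty pool")
    return ConformerPool(models=accepted, rg_values=rgs, n_trials=n_trials,
                         n_accepted=len(accepted), seed=seed, segments=segments)


def subselect_pool(pool: ConformerPool, stride: int) -> ConformerPool:
    """Keep the last conformer of each complete block of ``stride``.

    floor(n_accepted / stride) models survive, order preserved; e.g. 15661
    accepted at stride 9 -> 1740 representatives.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    n = len(pool.models)
    if stride > n:
        warnings.warn(f"stride {stride} exceeds pool size {n}; empty pool")
    keep = list(range(stride - 1, n, stride))
    return ConformerPool(
        models=[pool.models[i] for i in keep],
        rg_values=[pool.rg_values[i] for i in keep],
        n_trials=pool.n_trials, n_accepted=pool.n_accepted,
        stride=stride, seed=pool.seed, segments=pool.segments)


def subselect_count(n_accepted: int, stride: int) -> int:
    """Size of a stride sub-selection without materializing the pool."""
    if stride < 1:
        raise ValueError("stride must be >= 1")
    return n_accepted // stride


def compare_rg_distributions(pool_a: ConformerPool, pool_b: ConformerPool,
                             n_bins: int = 20):
    """Density histograms of Rg on a shared grid + max per-bin difference.

    Used to verify that a stride sub-selection remains representative of the
    original pool.
    """
    if not pool_a.rg_values or not pool_b.rg_values:
        raise ValueError("empty pool")
    all_rg = np.concatenate([pool_a.rg_values, pool_b.rg_values])
    edges = np.linspace(all_rg.min(), all_rg.max() + 1e-9, n_bins + 1)
    hist_a, _ = np.histogram(pool_a.rg_values, bins=edges, density=True)
    hist_b, _ = np.histogram(pool_b.rg_values, bins=edges, density=True)
    return hist_a, hist_b, float(np.abs(hist_a - hist_b).max())
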