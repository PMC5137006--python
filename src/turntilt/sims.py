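"""Conceptual perturbation simulations of the helix backbone.

Four idealised perturbations probe how the optimal (rho, theta)
conformation responds to its environment:

1. *Near bulkiness* — a single virtual side-chain atom per residue,
   held 1.54 A from its C-alpha, radially outward from the helix axis,
   with its LJ radius sigma inflated from 3.5 to 9.5 A (models beta-
   branched residues such as VAL/ILE/THR).
2. *Far bulkiness* — the same virtual residue held at sigma - 1.96 A
   from the C-alpha (models large aromatic side chains).
3. *Cylindrical electric field* — a potential growing linearly with
   distance from the helix axis acting on the carbonyl oxygens
   (charge -0.5) and amide hydrogens (+0.33, OPLS partial charges).
4. *Radial stretch force* — a uniform outward (or inward) force on the
   C-alpha atoms, dE = -scale * distance-from-axis per residue.

Each simulation reports the energy-optimal helix descriptor as a
function of the perturbation parameter; magnitudes of the field/force
are in arbitrary units per Angstrom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .energy import EnergyModel, backbone_pair_table, optimal_conformation
from .geometry import HelixDescriptor, _unit

__all__ = [
    "VirtualResidue",
    "FieldSpec",
    "SIGMA_SWEEP",
    "NEAR_BULK_DISTANCE",
    "FAR_BULK_OFFSET",
    "sim_near_bulk",
    "sim_far_bulk",
    "sim_electric",
    "sim_stretch",
    "sweep_simulation",
]

SIGMA_SWEEP = tuple(np.arange(3.5, 9.51, 0.5))   # [A]
NEAR_BULK_DISTANCE = 1.54                        # [A] C-alpha to virtual site
FAR_BULK_OFFSET = 1.96                           # far case: d = sigma - offset
Q_O = -0.5     # OPLS partial charge of the carbonyl oxygen
Q_H = 0.33     # OPLS partial charge of the amide hydrogen


@dataclass(frozen=True)
class VirtualResidue:
    """A one-site side chain attached radially outward from the axis."""

    sigma: float                     # [A] LJ radius (swept)
    distance: float                  # [A] attachment distance from C-alpha
    epsilon: float = 0.066           # [kCal/mole]; ALA-like CA well depth

    def __post_init__(self) -> None:
        if self.distance <= 0:
            raise ValueError("attachment distance must be positive")


@dataclass(frozen=True)
class FieldSpec:
    """A cylindrical field acting from the helix axis outwards."""

    kind: str                        # "electric" | "stretch"
    scale: float                     # signed magnitude [arb. units / A]
    q_O: float = Q_O
    q_H: float = Q_H

    def __post_init__(self) -> None:
        if self.kind not in ("electric", "stretch"):
            raise ValueError("kind must be 'electric' or 'stretch'")


def _axis_distance(points, axis, centroid):
    """Perpendicular distance of points (..., n, 3) from the axis line."""
    rel = points - centroid[..., None, :]
    along = np.sum(rel * axis[..., None, :], axis=-1, keepdims=True)
    return np.linalg.norm(rel - along * axis[..., None, :], axis=-1)


def _virtual_sites(atoms, axis, centroid, distance):
    """Virtual side-chain positions: radially outward of each C-alpha."""
    ca = atoms["CA"]
    rel = ca - centroid[..., None, :]
    along = np.sum(rel * axis[..., None, :], axis=-1, keepdims=True)
    radial = rel - along * axis[..., None, :]
    return ca + distance * _unit(radial)


def _virtual_energy(atoms, axis, centroid, vr: VirtualResidue,
                    model: EnergyModel) -> np.ndarray:
    """LJ energy of virtual sites with the backbone and each other.

    A virtual residue ignores its own residue's N, CA, C, O (bonded
    exclusion); all other virtual-backbone and virtual-virtual pairs
    interact with geometric mixing.
    """
    sites = _virtual_sites(atoms, axis, centroid, vr.distance)
    n = sites.shape[-2]
    sig_b = np.array([model.vdw.sigma[t] for t in ("N", "CA", "C", "O")])
    eps_b = np.array([model.vdw.epsilon[t] for t in ("N", "CA", "C", "O")])

    # virtual-backbone: site i vs atoms of residues j != i
    bb = np.stack([atoms["N"], atoms["CA"], atoms["C"], atoms["O"]], axis=-2)
    # bb shape (..., n, 4, 3); distances site_i to atom (j, t)
    d = np.linalg.norm(sites[..., :, None, None, :] - bb[..., None, :, :, :], axis=-1)
    sij = np.sqrt(vr.sigma * sig_b)          # (4,)
    eij = np.sqrt(vr.epsilon * eps_b)        # (4,)
    sr6 = (sij / d) ** 6
    e = 4.0 * eij * (sr6 * sr6 - sr6)
    mask = ~np.eye(n, dtype=bool)            # exclude own residue
    e_vb = np.sum(e * mask[:, :, None], axis=(-1, -2, -3))

    # virtual-virtual
    iu, ju = np.triu_indices(n, k=1)
    dvv = np.linalg.norm(sites[..., iu, :] - sites[..., ju, :], axis=-1)
    sr6 = (vr.sigma / dvv) ** 6
    e_vv = np.sum(4.0 * vr.epsilon * (sr6 * sr6 - sr6), axis=-1)
    return e_vb + e_vv


def _field_energy(atoms, axis, centroid, spec: FieldSpec) -> np.ndarray:
    if spec.kind == "electric":
        d_O = _axis_distance(atoms["O"], axis, centroid).sum(axis=-1)
        H = atoms["H"][..., 1:, :]   # no amide H on the first residue
        d_H = _axis_distance(H, axis, centroid).sum(axis=-1)
        return spec.scale * (spec.q_O * d_O + spec.q_H * d_H)
    d_CA = _axis_distance(atoms["CA"], axis, centroid).sum(axis=-1)
    return spec.scale * (-d_CA)


def sim_near_bulk(sigma: float, model: EnergyModel | None = None,
                  resolution: float = 1.0):
    """Optimal descriptor with a near-backbone virtual residue of radius
    ``sigma`` held ``NEAR_BULK_DISTANCE`` from each C-alpha."""
    vr = VirtualResidue(sigma=sigma, distance=NEAR_BULK_DISTANCE)
    model = model or EnergyModel()
    return optimal_conformation(
        model, resolution=resolution,
        extra_energy=lambda a, ax, c: _virtual_energy(a, ax, c, vr, model))


def sim_far_bulk(sigma: float, model: EnergyModel | None = None,
                 resolution: float = 1.0):
    """As :func:`sim_near_bulk` with the site held at sigma - 1.96 A."""
    vr = VirtualResidue(sigma=sigma, distance=sigma - FAR_BULK_OFFSET)
    model = model or EnergyModel()
    return optimal_conformation(
        model, resolution=resolution,
        extra_energy=lambda a, ax, c: _virtual_energy(a, ax, c, vr, model))


def sim_electric(scale: float, model: EnergyModel | None = None,
                 resolution: float = 1.0):
    """Optimal descriptor under a cylindrical electric field."""
    spec = FieldSpec(kind="electric", scale=scale)
    return optimal_conformation(
        model or EnergyModel(), resolution=resolution,
        extra_energy=lambda a, ax, c: _field_energy(a, ax, c, spec))


def sim_stretch(scale: float, model: EnergyModel | None = None,
                resolution: float = 1.0):
    """Optimal descriptor under a radial stretch (scale > 0) or squeeze
    (scale < 0) force on the C-alpha atoms."""
    spec = FieldSpec(kind="stretch", scale=scale)
    return optimal_conformation(
        model or EnergyModel(), resolution=resolution,
        extra_energy=lambda a, ax, c: _field_energy(a, ax, c, spec))


_SIMS = {"near-bulk": sim_near_bulk, "far-bulk": sim_far_bulk,
         "electric": sim_electric, "stretch": sim_stretch}


def sweep_simulation(kind: str, values, model: EnergyModel | None = None,
                     resolution: float = 1.0) -> pd.DataFrame:
    """Run one conceptual simulation over a parameter sweep.

    Returns a DataFrame (parameter, rho, theta, phi, psi, energy).
    """
    fn = _SIMS[kind]
    rows = []
    for v in values:
        hd, conf, e = fn(float(v), model=model, resolution=resolution)
        rows.append({"parameter": float(v), "rho": hd.rho, "theta": hd.theta,
                     "phi": conf.phi, "psi": conf.psi, "energy": e})
    return pd.DataFrame(rows)
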