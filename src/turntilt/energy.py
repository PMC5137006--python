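"""Conformational energy of the alpha-helix backbone.

The total energy combines a Lennard-Jones 12-6 van der Waals term over
the backbone heavy atoms (OPLS parameters, geometric mixing) with a
hydrogen-bond term: every i -> i+4 bond contributes -e_hb * s_i, so for
a chain with n_b possible bonds and mean alignment score S

    E_total = E_vdW - e_hb * n_b * S     [kCal/mole]

with e_hb the per-bond hydrogen-bond magnitude (default 4 kCal/mole, the
middle of the 2-6 kCal/mole range reported for backbone hydrogen bonds).

LJ pairs separated by up to ``exclusion_bonds`` covalent bonds are
excluded.  The default (4) drops all interactions local to one peptide
unit, including the 1-5 carbonyl-carbonyl O_i-C_{i+1} contact: in real
helices that contact sits near 2.8 A, inside the LJ radius, stabilised
by charge interactions this backbone model does not carry, so pure LJ
would misprice every helical conformation by ~2.5 kCal/mole/residue.
The policy is a parameter; see :func:`exclusion_sensitivity`.

A separate harmonic model approximates the conformational energy on the
(rho, theta) space:

    E = (theta - theta0)^2 + K^2 (rho - rho0)^2   [EU]

where one EU is the energy of a 1 degree shift in theta and K converts
rho displacements into equivalent theta displacements.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .geometry import BackboneChain

__all__ = [
    "VdwParams",
    "EnergyModel",
    "HarmonicModel",
    "K_DEFAULT",
    "backbone_pair_table",
    "vdw_energy",
    "vdw_energy_batch",
    "total_energy",
    "energy_map",
    "optimal_conformation",
    "exclusion_sensitivity",
    "harmonic_energy",
    "log_compress",
]

#: conversion ratio <d_theta>/<d_rho> between confinement half-widths
K_DEFAULT = 10.6 / 0.63  # ~16.8 [deg Turn/Res]

_ATOM_TYPES = ("N", "CA", "C", "O")


@dataclass(frozen=True)
class VdwParams:
    """OPLS Lennard-Jones parameters for backbone atoms, geometric mixing."""

    sigma: dict = field(default_factory=lambda: {
        "N": 3.25, "CA": 3.50, "C": 3.75, "O": 2.96})
    epsilon: dict = field(default_factory=lambda: {
        "N": 0.17, "CA": 0.066, "C": 0.105, "O": 0.21})
    mixing: str = "geometric"


@dataclass(frozen=True)
class EnergyModel:
    """Total backbone energy model: LJ + per-bond hydrogen-bond term."""

    ehb_magnitude: float = 4.0       # [kCal/mole per bond]; E_HB,i = -ehb * s_i
    vdw: VdwParams = field(default_factory=VdwParams)
    exclusion_bonds: int = 4         # exclude pairs <= this many bonds apart

    def __post_init__(self) -> None:
        if self.ehb_magnitude < 0:
            raise ValueError("ehb_magnitude must be >= 0")


@dataclass(frozen=True)
class HarmonicModel:
    """Harmonic (rho, theta) energy about a minimum-energy conformation."""

    theta0: float = 0.0          # [deg]
    rho0: float = 3.6            # [Res/Turn]
    K: float = K_DEFAULT         # [deg Turn/Res]

    def __post_init__(self) -> None:
        if self.K <= 0:
            raise ValueError("K must be positive")


# ---------------------------------------------------------------------------
# Lennard-Jones machinery


def _bond_graph(n_residues: int):
    """Covalent bonds among backbone atoms, atom index = 4*res + type.

    Types: 0=N, 1=CA, 2=C, 3=O.  Bonds: N-CA, CA-C, C-O, C-N(next).
    """
    bonds = []
    for r in range(n_residues):
        b = 4 * r
        bonds += [(b, b + 1), (b + 1, b + 2), (b + 2, b + 3)]
        if r + 1 < n_residues:
            bonds.append((b + 2, b + 4))
    return bonds


def backbone_pair_table(n_residues: int, vdw: VdwParams | None = None,
                        exclusion_bonds: int = 3):
    """Precompute interacting atom pairs and their mixed LJ parameters.

    Pairs separated by ``exclusion_bonds`` covalent bonds or fewer are
    excluded (with fixed internal geometry those terms are conformational
    constants).  Returns (idx_i, idx_j, sigma_ij, epsilon_ij).
    """
    import networkx as nx  # lazy: only needed to build the table once

    vdw = vdw or VdwParams()
    natoms = 4 * n_residues
    g = nx.Graph(_bond_graph(n_residues))
    g.add_nodes_from(range(natoms))
    dist = dict(nx.all_pairs_shortest_path_length(g, cutoff=exclusion_bonds))

    types = np.array([_ATOM_TYPES[k % 4] for k in range(natoms)])
    sig = np.array([vdw.sigma[t] for t in types])
    eps = np.array([vdw.epsilon[t] for t in types])

    ii, jj = np.triu_indices(natoms, k=1)
    keep = np.array([dist.get(a, {}).get(b) is None for a, b in zip(ii, jj)])
    ii, jj = ii[keep], jj[keep]
    if vdw.mixing != "geometric":
        raise ValueError("only geometric mixing is supported")
    return ii, jj, np.sqrt(sig[ii] * sig[jj]), np.sqrt(eps[ii] * eps[jj])


def _stack_atoms(atoms: dict) -> np.ndarray:
    """Interleave N, CA, C, O into an (..., 4n, 3) array."""
    stacked = np.stack([atoms["N"], atoms["CA"], atoms["C"], atoms["O"]], axis=-2)
    shp = stacked.shape
    return stacked.reshape(shp[:-3] + (shp[-3] * 4, 3))


def vdw_energy_batch(atoms: dict, table) -> np.ndarray:
    """LJ 12-6 energy for a batch of chains given a precomputed pair table."""
    ii, jj, sij, eij = table
    xyz = _stack_atoms(atoms)
    d = np.linalg.norm(xyz[..., ii, :] - xyz[..., jj, :], axis=-1)
    if np.any(d < 1e-6):
        raise FloatingPointError("overlapping atoms in LJ evaluation")
    sr6 = (sij / d) ** 6
    return np.sum(4.0 * eij * (sr6 * sr6 - sr6), axis=-1)


def vdw_energy(chain: BackboneChain, params: VdwParams | None = None,
               exclusion_bonds: int = 4) -> float:
    """Total LJ 12-6 energy of a single chain [kCal/mole], no cutoff."""
    n = len(chain)
    table = backbone_pair_table(n, params, exclusion_bonds)
    atoms = {"N": chain.N, "CA": chain.CA, "C": chain.C, "O": chain.O}
    return float(vdw_energy_batch(atoms, table))


def total_energy(chain: BackboneChain, model: EnergyModel | None = None) -> float:
    """E_vdW - ehb * (sum of per-bond scores) for one chain [kCal/mole]."""
    from .hbond import alignment_score

    model = model or EnergyModel()
    e = vdw_energy(chain, model.vdw, model.exclusion_bonds)
    sc = alignment_score(chain)
    if sc.defined:
        e -= model.ehb_magnitude * sc.n_bonds * sc.S
    return e


# ---------------------------------------------------------------------------
# energy maps over the basin and their optima


def energy_map(model: EnergyModel | None = None, resolution: float = 1.0):
    """Total-energy SweepMap over the S > 0 basin in (phi, psi).

    Bins outside the basin are masked; the vdW term is evaluated only on
    basin bins (chunked to bound memory).
    """
    from .geometry import DEFAULT_PARAMS, build_backbone_batch
    from .transform import SweepMap, basin_maps

    model = model or EnergyModel()
    maps = basin_maps(resolution)
    S = maps["S"]
    basin = maps["rho"].valid
    ii, jj = np.where(basin)
    n_bonds = DEFAULT_PARAMS.n_residues - 4
    _, _, Evdw, Sb, _, _ = _basin_vdw(resolution, model.exclusion_bonds)
    E = Evdw - model.ehb_magnitude * n_bonds * Sb
    vals = np.full(S.values.shape, np.nan)
    vals[ii, jj] = E
    return SweepMap(("phi", "psi"), S.axis1, S.axis2, vals, basin)


@lru_cache(maxsize=8)
def _basin_vdw(resolution: float, exclusion_bonds: int):
    """Cached vdW energies on the basin bins (ehb-independent)."""
    from .geometry import DEFAULT_PARAMS, build_backbone_batch
    from .transform import basin_maps

    maps = basin_maps(resolution)
    basin = maps["rho"].valid
    ii, jj = np.where(basin)
    phi = maps["S"].axis1[ii]
    psi = maps["S"].axis2[jj]
    table = backbone_pair_table(DEFAULT_PARAMS.n_residues, None, exclusion_bonds)
    E = np.empty(ii.size)
    for s0 in range(0, ii.size, 512):
        sl = slice(s0, s0 + 512)
        atoms = build_backbone_batch(phi[sl], psi[sl])
        E[sl] = vdw_energy_batch(atoms, table)
    return phi, psi, E, maps["S"].values[ii, jj], \
        maps["rho"].values[ii, jj], maps["theta"].values[ii, jj]


def optimal_conformation(model: EnergyModel | None = None,
                         resolution: float = 1.0,
                         refine_step: float = 0.1,
                         extra_energy=None):
    """Minimum of the total energy over the basin, locally refined.

    A coarse basin sweep locates the argmin bin; a local grid at
    ``refine_step`` (spanning +/- one coarse bin) refines it.  The
    returned descriptor is measured geometrically on the refined chain.

    ``extra_energy`` optionally maps (atoms dict, axis, centroid) batches
    to an additive energy (used by the perturbation simulations).

    Returns (HelixDescriptor, Conformation, energy).
    """
    from .geometry import (DEFAULT_PARAMS, Conformation, HelixDescriptor,
                           build_backbone_batch, fit_axis_batch)
    from .transform import _score_and_descriptors

    model = model or EnergyModel()
    if model.vdw != VdwParams():
        raise NotImplementedError("cached basin sweep assumes default vdW parameters")
    phi, psi, Evdw, Sb, Rb, Tb = _basin_vdw(resolution, model.exclusion_bonds)
    if phi.size == 0:
        raise ValueError("empty basin")
    n = DEFAULT_PARAMS.n_residues
    table = backbone_pair_table(n, model.vdw, model.exclusion_bonds)
    n_bonds = n - 4

    def evaluate(p, q):
        S, rho, theta, atoms = _score_and_descriptors(p, q, DEFAULT_PARAMS)
        E = vdw_energy_batch(atoms, table) - model.ehb_magnitude * n_bonds * S
        if extra_energy is not None:
            axis, centroid = fit_axis_batch(atoms["CA"])
            E = E + extra_energy(atoms, axis, centroid)
        return np.where(S > 0, E, np.nan), rho, theta

    E = Evdw - model.ehb_magnitude * n_bonds * Sb
    if extra_energy is not None:
        for s0 in range(0, phi.size, 512):
            sl = slice(s0, s0 + 512)
            atoms = build_backbone_batch(phi[sl], psi[sl])
            axis, centroid = fit_axis_batch(atoms["CA"])
            E[sl] = E[sl] + extra_energy(atoms, axis, centroid)
    k = np.nanargmin(E)
    p0, q0 = phi[k], psi[k]

    fp = np.arange(p0 - resolution, p0 + resolution + refine_step / 2, refine_step)
    fq = np.arange(q0 - resolution, q0 + resolution + refine_step / 2, refine_step)
    FP, FQ = np.meshgrid(fp, fq, indexing="ij")
    Ef, Rf, Tf = evaluate(FP.ravel(), FQ.ravel())
    kf = np.nanargmin(Ef)
    return (HelixDescriptor(rho=float(Rf[kf]), theta=float(Tf[kf])),
            Conformation(phi=float(FP.ravel()[kf]), psi=float(FQ.ravel()[kf])),
            float(Ef[kf]))


def exclusion_sensitivity(ehb_values=(0.0, 2.0, 3.0, 4.0),
                          exclusion_policies=(2, 3, 4),
                          resolution: float = 1.0):
    """Optimal (rho, theta) under each LJ exclusion policy and HB magnitude.

    Returns a pandas DataFrame (policy, ehb, rho, theta, phi, psi, energy)
    documenting how strongly the energy optima depend on which local LJ
    pairs are excluded.
    """
    import pandas as pd

    rows = []
    for excl in exclusion_policies:
        for ehb in ehb_values:
            model = EnergyModel(ehb_magnitude=ehb, exclusion_bonds=excl)
            hd, conf, e = optimal_conformation(model, resolution=resolution)
            rows.append({"exclusion_bonds": excl, "ehb": ehb,
                         "rho": hd.rho, "theta": hd.theta,
                         "phi": conf.phi, "psi": conf.psi, "energy": e})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# harmonic (rho, theta) model


def harmonic_energy(rho, theta, model: HarmonicModel | None = None):
    """E = (theta - theta0)^2 + K^2 (rho - rho0)^2 in EU; broadcasts."""
    model = model or HarmonicModel()
    e = (np.asarray(theta, float) - model.theta0) ** 2 \
        + model.K ** 2 * (np.asarray(rho, float) - model.rho0) ** 2
    return float(e) if np.ndim(e) == 0 else e


def log_compress(value):
    """Double-log display compression log(1 + log(1 + E)); requires E >= 0."""
    v = np.asarray(value, dtype=float)
    if np.any(v < 0):
        raise ValueError("log_compress requires non-negative energies")
    out = np.log1p(np.log1p(v))
    return float(out) if out.ndim == 0 else out
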