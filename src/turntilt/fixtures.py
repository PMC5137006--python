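"""Synthetic PDB fixtures with known ground truth.

The generator emits standard PDB-format files containing multi-chain
ideal and noise-perturbed alpha-helices with HELIX annotations and
per-residue amino-acid identities, so the whole statistics pipeline can
be exercised without downloading real structures.

Per-transition target conformations are specified in (phi, psi); noise
is drawn as an isotropic Gaussian in the (rho, theta) space — matching
the symmetric scatter real helices show there — and mapped back through
the inverse linear transform before the chain is built.  The default
noise SDs are chosen so that the 50% confinement radius of the generated
scatter matches the level-averaged half-widths observed for real helices
(<d_theta> = 10.6 deg, <d_rho> = 0.63 Res/Turn; the median radius of a
2-D isotropic Gaussian is sigma * sqrt(2 ln 2) ~ 1.18 sigma).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import (
    DEFAULT_PARAMS,
    BackboneChain,
    Conformation,
    HelixDescriptor,
    build_backbone_batch,
    chain_to_pdb,
    make_parametric_helix,
    _THREE,
)
from .transform import (
    LinearTransform,
    default_transform,
    phi_psi_to_rho_theta,
    rho_theta_to_phi_psi,
)

__all__ = ["FixtureSpec", "make_helix_pdb", "make_parametric_helix",
           "iph_exact_targets", "SIGMA_THETA_DEFAULT", "SIGMA_RHO_DEFAULT"]

#: matches the level-averaged 50% confinement observed for real helices
SIGMA_THETA_DEFAULT = 10.6 / np.sqrt(2 * np.log(2))   # [deg]  ~9.0
SIGMA_RHO_DEFAULT = 0.63 / np.sqrt(2 * np.log(2))     # [Res/Turn] ~0.54

_CHAIN_IDS = ("ABCDEFGHIJKLMNOPQRSTUVWXYZ"
              "abcdefghijklmnopqrstuvwxyz0123456789")

_HELIX_FMT = ("HELIX  {ser:3d} {hid:>3s} {res1:>3s} {c1:1s} {s1:4d} "
              "{res2:>3s} {c2:1s} {s2:4d}  1{comment:>30s} {length:5d}\n")


@dataclass
class FixtureSpec:
    """Recipe for a set of synthetic helix PDB files.

    ``targets`` maps ordered transitions (X, Y) to their mean (phi, psi)
    in degrees.  For every unordered pair the generator emits alternating
    X-Y-X-Y... helices (plus X-X-X... helices for homogeneous keys) until
    each requested transition has at least ``samples_per_transition``
    samples.  Noise SDs are in (rho, theta) units; ``decoy_fraction``
    adds extra non-helical chains (built outside the helical dihedral
    window, without HELIX records).  A fixed seed makes the output
    byte-identical across runs.
    """

    targets: dict
    samples_per_transition: int = 200
    sigma_rho: float = SIGMA_RHO_DEFAULT
    sigma_theta: float = SIGMA_THETA_DEFAULT
    helix_length: int = 30
    seed: int = 0
    decoy_fraction: float = 0.0
    decoy_conformation: tuple = (-120.0, 130.0)
    chains_per_file: int = 50

    def __post_init__(self) -> None:
        if self.sigma_rho < 0 or self.sigma_theta < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.helix_length < 5:
            raise ValueError("helix_length must be >= 5")
        if self.samples_per_transition < 1:
            raise ValueError("samples_per_transition must be >= 1")
        for key in self.targets:
            if len(key) != 2:
                raise ValueError(f"bad transition key {key!r}")


def _sequences_for_targets(targets: dict, length: int, per_transition: int):
    """Plan chain sequences so each target transition appears often enough."""
    pairs = set()
    for (x, y) in targets:
        pairs.add((x, y) if x <= y else (y, x))
    plans = []
    for p in sorted(pairs):
        x, y = p
        if x == y:
            seq = x * length
            per_chain = length - 1
        else:
            seq = "".join(x if k % 2 == 0 else y for k in range(length))
            per_chain = (length - 1) // 2   # count of the rarer direction
        plans += [seq] * int(np.ceil(per_transition / per_chain))
    return plans


def _draw_conformations(spec: FixtureSpec, seq: str, transform: LinearTransform,
                        rng: np.random.Generator):
    """Per-transition (phi, psi) draws for one chain.

    Returns the (n, 2) per-residue dihedral array and the ground-truth
    rows (one per transition, with the drawn (rho, theta) and the
    resulting (phi, psi))."""
    n = len(seq)
    phi = np.empty(n)
    psi = np.empty(n)
    truth = []
    first_phi = None
    for i in range(n - 1):
        key = (seq[i], seq[i + 1])
        tphi, tpsi = spec.targets[key]
        hd = phi_psi_to_rho_theta(transform, Conformation(tphi, tpsi))
        rho = hd.rho + rng.normal(0.0, spec.sigma_rho)
        theta = hd.theta + rng.normal(0.0, spec.sigma_theta)
        conf = rho_theta_to_phi_psi(transform, HelixDescriptor(rho, theta))
        truth.append({"src": key[0], "dst": key[1], "position": i,
                      "phi": conf.phi, "psi": conf.psi,
                      "rho": rho, "theta": theta})
        psi[i] = conf.psi
        phi[i + 1] = conf.phi
        if first_phi is None:
            first_phi = conf.phi
    phi[0] = first_phi          # phi of residue 1 is structurally unused
    psi[n - 1] = psi[n - 2]     # only orients the terminal carbonyl
    return np.column_stack([phi, psi]), truth


def _build_chain(dihedrals: np.ndarray, seq: str) -> BackboneChain:
    params = replace(DEFAULT_PARAMS, n_residues=len(seq))
    atoms = build_backbone_batch(dihedrals[None, :, 0], dihedrals[None, :, 1],
                                 params)
    return BackboneChain(N=atoms["N"][0], CA=atoms["CA"][0],
                         C=atoms["C"][0], O=atoms["O"][0], labels=list(seq))


def make_helix_pdb(spec: FixtureSpec, out_dir,
                   transform: LinearTransform | None = None):
    """Write the fixture PDB files; returns (paths, ground-truth frame).

    Output is deterministic for a fixed spec (seeded RNG, fixed-format
    records).  The ground-truth DataFrame carries one row per generated
    transition with the drawn (phi, psi) and (rho, theta).
    """
    from .pdb_analysis import LEVEL0_PHI, LEVEL0_PSI

    for key, (tphi, tpsi) in spec.targets.items():
        if not (LEVEL0_PHI[0] < tphi < LEVEL0_PHI[1]
                and LEVEL0_PSI[0] < tpsi < LEVEL0_PSI[1]):
            raise ValueError(
                f"target {key} at ({tphi}, {tpsi}) lies outside the helical "
                f"window phi in {LEVEL0_PHI}, psi in {LEVEL0_PSI}")

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    transform = transform or default_transform()
    rng = np.random.default_rng(spec.seed)

    plans = _sequences_for_targets(spec.targets, spec.helix_length,
                                   spec.samples_per_transition)
    n_decoys = int(round(len(plans) * spec.decoy_fraction))

    # assemble per-chain records first, then group into files
    chains = []          # (seq, BackboneChain, is_helix)
    truth_rows = []
    for seq in plans:
        dihedrals, truth = _draw_conformations(spec, seq, transform, rng)
        chains.append((seq, _build_chain(dihedrals, seq), True))
        truth_rows += truth
    for k in range(n_decoys):
        seq = plans[k % len(plans)][::-1]
        n = len(seq)
        dihedrals = np.tile(np.asarray(spec.decoy_conformation), (n, 1))
        chains.append((seq, _build_chain(dihedrals, seq), False))

    paths = []
    for start in range(0, len(chains), spec.chains_per_file):
        group = chains[start:start + spec.chains_per_file]
        path = out_dir / f"fixture_{len(paths):03d}.pdb"
        with open(path, "w") as fh:
            ser = 0
            for ci, (seq, chain, is_helix) in enumerate(group):
                if not is_helix:
                    continue
                ser += 1
                fh.write(_HELIX_FMT.format(
                    ser=ser, hid=f"H{ser}",
                    res1=_THREE[seq[0]], c1=_CHAIN_IDS[ci], s1=1,
                    res2=_THREE[seq[-1]], c2=_CHAIN_IDS[ci], s2=len(seq),
                    comment="", length=len(seq)))
            serial = 1
            for ci, (seq, chain, is_helix) in enumerate(group):
                text, serial = chain_to_pdb(chain, chain_id=_CHAIN_IDS[ci],
                                            serial_start=serial)
                fh.write(text)
                fh.write("TER\n")
            fh.write("END\n")
        paths.append(path)

    truth = pd.DataFrame(truth_rows)
    return paths, truth


def iph_exact_targets(amino_acids: str, base: tuple = (-63.0, -43.0),
                      spacing: float = 4.0) -> dict:
    """Targets for which heterogeneous means equal homogeneous averages.

    Homogeneous targets are placed on the histogram-bin-center lattice
    with separations that are even multiples of the bin width, so every
    heterogeneous midpoint is itself a bin center; with zero noise the
    pipeline then recovers an IPH energy table that is exactly zero.
    """
    if spacing % 4.0 != 0.0:
        raise ValueError("spacing must be a multiple of 4 degrees "
                         "(twice the 2-degree bin width)")
    homo = {}
    for k, aa in enumerate(amino_acids):
        homo[aa] = (base[0] + spacing * k, base[1] + spacing * (k % 2))
    targets = {}
    for x in amino_acids:
        for y in amino_acids:
            targets[(x, y)] = (0.5 * (homo[x][0] + homo[y][0]),
                               0.5 * (homo[x][1] + homo[y][1]))
    return targets
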