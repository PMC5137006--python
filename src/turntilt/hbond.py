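"""Hydrogen-bond alignment scoring of the alpha-helix backbone.

An i -> i+4 backbone hydrogen bond (donor amide of residue i+4, acceptor
carbonyl of residue i) is scored by the product of four sub-scores, each
in [0, 1]:

* ``s_HO``   — harmonic score of the H...O distance, optimal at 1.9 A
  with a fluctuation range of +/- 1.2 A;
* ``s_OCNH`` — collinearity of the O->C carbonyl normal with the N->H
  amide normal;
* ``s_OCHO`` — collinearity of the O->C normal with the H->O normal;
* ``s_HAND`` — 1 for right-handed chains, 0 otherwise.

The chain-level alignment score S is the mean of the per-bond scores over
every possible i -> i+4 bond; regions of (phi, psi) with S > 0 delimit
the alpha-helix basin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import (
    DEFAULT_PARAMS,
    BackboneChain,
    BackboneParams,
    Conformation,
    build_backbone,
    build_backbone_batch,
    fit_axis_batch,
    fit_helix_frame,
    _step_rotations,
    _unit,
)

__all__ = [
    "HBondSubscores",
    "AlignmentScore",
    "score_bond",
    "alignment_score",
    "alignment_score_batch",
    "is_basin",
    "HO_OPT",
    "HO_RANGE",
]

HO_OPT = 1.9    # optimal H...O distance [A]
HO_RANGE = 1.2  # harmonic fluctuation range [A]


@dataclass(frozen=True)
class HBondSubscores:
    s_HO: float
    s_OCNH: float
    s_OCHO: float
    s_HAND: float

    @property
    def s(self) -> float:
        """Per-bond score: the product of the four sub-scores."""
        return self.s_HO * self.s_OCNH * self.s_OCHO * self.s_HAND


@dataclass(frozen=True)
class AlignmentScore:
    S: float
    n_bonds: int

    @property
    def defined(self) -> bool:
        return self.n_bonds > 0


def _distance_subscore(d):
    return np.maximum(0.0, 1.0 - ((d - HO_OPT) / HO_RANGE) ** 2)


def _is_right_handed(chain: BackboneChain) -> bool:
    frame = fit_helix_frame(chain)
    return frame.cumulative_rotation > 0


def score_bond(chain: BackboneChain, i: int,
               right_handed: bool | None = None) -> HBondSubscores:
    """Score the i -> i+4 hydrogen bond of a chain (0-based residue i).

    ``right_handed`` may be supplied to avoid re-fitting the axis when
    scoring many bonds of one chain.
    """
    n = len(chain)
    if not 0 <= i <= n - 5:
        raise IndexError(f"bond {i} -> {i + 4} outside chain of {n} residues")
    O = chain.O[i]
    C = chain.C[i]
    if chain.H is None or not np.isfinite(chain.H[i + 4]).all():
        warnings.warn(f"residue {i + 4} has no amide hydrogen; bond skipped")
        return HBondSubscores(0.0, 0.0, 0.0, 0.0)
    if not np.isfinite(O).all():
        warnings.warn(f"residue {i} has no carbonyl oxygen; bond skipped")
        return HBondSubscores(0.0, 0.0, 0.0, 0.0)
    H = chain.H[i + 4]
    Natom = chain.N[i + 4]

    s_ho = float(_distance_subscore(np.linalg.norm(H - O)))
    u_oc = _unit(C - O)
    u_nh = _unit(H - Natom)
    u_ho = _unit(O - H)
    s_ocnh = float(max(0.0, np.dot(u_oc, u_nh)))
    s_ocho = float(max(0.0, np.dot(u_oc, u_ho)))
    if right_handed is None:
        right_handed = _is_right_handed(chain)
    return HBondSubscores(s_HO=s_ho, s_OCNH=s_ocnh, s_OCHO=s_ocho,
                          s_HAND=1.0 if right_handed else 0.0)


def alignment_score(chain: BackboneChain) -> AlignmentScore:
    """Mean per-bond score S over all i -> i+4 bonds of the chain."""
    n = len(chain)
    if n < 5:
        return AlignmentScore(S=float("nan"), n_bonds=0)
    handed = _is_right_handed(chain)
    scores = [score_bond(chain, i, right_handed=handed).s for i in range(n - 4)]
    return AlignmentScore(S=float(np.mean(scores)), n_bonds=len(scores))


def alignment_score_batch(atoms: dict) -> np.ndarray:
    """Vectorised S for a batch of chains built by ``build_backbone_batch``.

    Input arrays have shape (M, n, 3); returns S with shape (M,).
    """
    O = atoms["O"][:, :-4]
    C = atoms["C"][:, :-4]
    H = atoms["H"][:, 4:]
    N = atoms["N"][:, 4:]

    d = np.linalg.norm(H - O, axis=-1)
    s_ho = _distance_subscore(d)
    u_oc = _unit(C - O)
    u_nh = _unit(H - N)
    u_ho = _unit(O - H)
    s_ocnh = np.maximum(0.0, np.sum(u_oc * u_nh, axis=-1))
    s_ocho = np.maximum(0.0, np.sum(u_oc * u_ho, axis=-1))
    s = s_ho * s_ocnh * s_ocho

    ca = atoms["CA"]
    axis, centroid = fit_axis_batch(ca)
    R = _step_rotations(ca, axis, centroid).sum(axis=-1)
    s_hand = (R > 0).astype(float)
    return s.mean(axis=-1) * s_hand


def is_basin(conf: Conformation, threshold: float = 0.0,
             params: BackboneParams = DEFAULT_PARAMS) -> bool:
    """True iff the chain built at ``conf`` scores S > threshold."""
    if not 0.0 <= threshold < 1.0:
        raise ValueError("threshold must lie in [0, 1)")
    chain = build_backbone(params, conf)
    sc = alignment_score(chain)
    return sc.defined and sc.S > threshold
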