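"""Conformational sweeps and the linear (phi,psi) <-> (rho,theta) map.

A conformational sweep evaluates a property P on every bin of a
discretised conformational space.  Sweeping the alignment score S, the
residues-per-turn rho and the carbonyl tilt theta over the (phi, psi)
plane shows that, inside the alpha-helix basin (S > 0), both descriptors
depend almost linearly on the dihedrals.  An unweighted least-squares
affine fit over the basin therefore gives an invertible transformation

    [rho  ]   [a11 a12] [phi]   [b1]
    [theta] = [a21 a22] [psi] + [b2]

whose maximum residuals over the basin quantify its quality.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .geometry import (
    DEFAULT_PARAMS,
    BackboneParams,
    Conformation,
    HelixDescriptor,
    build_backbone_batch,
    fit_axis_batch,
    wrap_angle,
    _step_rotations,
    _unit,
)
from .hbond import _distance_subscore

__all__ = [
    "SweepMap",
    "LinearTransform",
    "sweep",
    "basin_maps",
    "score_optimum",
    "fit_linear_transform",
    "default_transform",
    "phi_psi_to_rho_theta",
    "rho_theta_to_phi_psi",
]


@dataclass
class SweepMap:
    """A property evaluated on a binned 2-D space.

    ``values`` is indexed [i, j] for (axis1[i], axis2[j]); masked bins
    hold NaN and are flagged False in ``valid``.
    """

    axis_names: tuple[str, str]
    axis1: np.ndarray
    axis2: np.ndarray
    values: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        shape = (len(self.axis1), len(self.axis2))
        if self.values.shape != shape or self.valid.shape != shape:
            raise ValueError("grid shape must match axis definitions")

    @property
    def masked_values(self) -> np.ndarray:
        out = np.where(self.valid, self.values, np.nan)
        return out

    def argbest(self, mode: str = "max") -> tuple[float, float]:
        """Grid coordinates of the extremum over valid bins."""
        v = self.masked_values
        if mode == "max":
            k = np.nanargmax(v)
        else:
            k = np.nanargmin(v)
        i, j = np.unravel_index(k, v.shape)
        return float(self.axis1[i]), float(self.axis2[j])

    def to_frame(self):
        """Long-format pandas DataFrame (axis1, axis2, value) of valid bins."""
        import pandas as pd

        ii, jj = np.where(self.valid)
        return pd.DataFrame({
            self.axis_names[0]: self.axis1[ii],
            self.axis_names[1]: self.axis2[jj],
            "value": self.values[ii, jj],
        })


def sweep(evaluator, axis1, axis2,
          axis_names: tuple[str, str] = ("phi", "psi")) -> SweepMap:
    """Evaluate ``evaluator(a1, a2)`` on every bin of a 2-D grid.

    The evaluator receives flat arrays of bin-center coordinates and
    returns one value per point (NaN marks a masked bin).
    """
    axis1 = np.asarray(axis1, dtype=float)
    axis2 = np.asarray(axis2, dtype=float)
    A, B = np.meshgrid(axis1, axis2, indexing="ij")
    vals = np.asarray(evaluator(A.ravel(), B.ravel()), dtype=float).reshape(A.shape)
    return SweepMap(axis_names=axis_names, axis1=axis1, axis2=axis2,
                    values=vals, valid=np.isfinite(vals))


def _score_and_descriptors(phi_flat, psi_flat, params: BackboneParams):
    """Batched S, rho, theta for uniform conformations (rho/theta NaN when
    the winding is not right-handed)."""
    atoms = build_backbone_batch(phi_flat, psi_flat, params)
    O = atoms["O"][:, :-4]
    C = atoms["C"][:, :-4]
    H = atoms["H"][:, 4:]
    N = atoms["N"][:, 4:]
    s_ho = _distance_subscore(np.linalg.norm(H - O, axis=-1))
    u_oc = _unit(C - O)
    u_nh = _unit(H - N)
    u_ho = _unit(O - H)
    s = s_ho * np.maximum(0.0, np.sum(u_oc * u_nh, axis=-1)) \
             * np.maximum(0.0, np.sum(u_oc * u_ho, axis=-1))

    ca = atoms["CA"]
    axis, centroid = fit_axis_batch(ca)
    R = _step_rotations(ca, axis, centroid).sum(axis=-1)
    right = R > 0
    S = s.mean(axis=-1) * right

    n_steps = ca.shape[-2] - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.where(right, 360.0 * n_steps / R, np.nan)
    rel_c = atoms["C"] - centroid[:, None]
    Q = rel_c - np.sum(rel_c * axis[:, None], axis=-1, keepdims=True) * axis[:, None]
    q = _unit(Q)
    n_co = _unit(atoms["C"] - atoms["O"])
    theta = np.degrees(np.arcsin(-np.clip(np.sum(q * n_co, axis=-1), -1, 1))).mean(-1)
    theta = np.where(right, theta, np.nan)
    return S, rho, theta, atoms


@lru_cache(maxsize=4)
def basin_maps(resolution: float = 1.0,
               params: BackboneParams = DEFAULT_PARAMS) -> dict:
    """Sweep S, rho and theta over the full (phi, psi) plane.

    Returns SweepMaps keyed ``"S"``, ``"rho"``, ``"theta"``; rho and theta
    are masked outside the basin (S <= 0 or left-handed winding).
    Results are cached per (resolution, params).
    """
    ax = np.arange(-180.0, 180.0, resolution)
    P, Q = np.meshgrid(ax, ax, indexing="ij")
    S, rho, theta, _ = _score_and_descriptors(P.ravel(), Q.ravel(), params)
    S = S.reshape(P.shape)
    basin = S > 0
    rho = np.where(basin, rho.reshape(P.shape), np.nan)
    theta = np.where(basin, theta.reshape(P.shape), np.nan)
    mk = lambda v, valid: SweepMap(("phi", "psi"), ax, ax, v, valid)
    return {
        "S": mk(S, np.isfinite(S)),
        "rho": mk(rho, basin & np.isfinite(rho)),
        "theta": mk(theta, basin & np.isfinite(theta)),
    }


def score_optimum(resolution: float = 1.0, refine_step: float = 0.1,
                  params: BackboneParams = DEFAULT_PARAMS):
    """Refined maximum of the alignment score S over the (phi, psi) plane.

    A coarse sweep locates the argmax bin; a local grid at ``refine_step``
    spanning +/- one coarse bin refines it.  Returns (Conformation, S,
    HelixDescriptor) with the descriptor measured geometrically at the
    refined optimum.
    """
    maps = basin_maps(resolution, params)
    phi0, psi0 = maps["S"].argbest("max")
    fp = np.arange(phi0 - resolution, phi0 + resolution + refine_step / 2,
                   refine_step)
    fq = np.arange(psi0 - resolution, psi0 + resolution + refine_step / 2,
                   refine_step)
    FP, FQ = np.meshgrid(fp, fq, indexing="ij")
    S, rho, theta, _ = _score_and_descriptors(FP.ravel(), FQ.ravel(), params)
    k = int(np.nanargmax(S))
    conf = Conformation(phi=float(FP.ravel()[k]), psi=float(FQ.ravel()[k]))
    return conf, float(S[k]), HelixDescriptor(rho=float(rho[k]),
                                              theta=float(theta[k]))


@dataclass(frozen=True)
class LinearTransform:
    """Affine map (phi, psi) -> (rho, theta) with its fit diagnostics."""

    matrix: np.ndarray          # 2x2
    offset: np.ndarray          # (2,)
    max_residual_rho: float     # [Res/Turn]
    max_residual_theta: float   # [deg]
    s_threshold: float          # basin mask used for the fit

    def __post_init__(self) -> None:
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise ValueError("transform matrix is singular")


def fit_linear_transform(rho_map: SweepMap, theta_map: SweepMap,
                         mask: np.ndarray | None = None,
                         s_threshold: float = 0.0) -> LinearTransform:
    """Unweighted least-squares affine fit of (rho, theta) on (phi, psi).

    ``mask`` defaults to the joint validity of the two maps (the S > 0
    basin).  rho and theta are fitted independently; for an affine model
    this equals the joint fit.
    """
    if rho_map.values.shape != theta_map.values.shape:
        raise ValueError("maps must share a grid")
    if mask is None:
        mask = rho_map.valid & theta_map.valid
    ii, jj = np.where(mask)
    if ii.size < 3:
        raise ValueError("mask too small for an affine fit")
    X = np.column_stack([rho_map.axis1[ii], rho_map.axis2[jj], np.ones(ii.size)])
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("rank-deficient design (degenerate mask)")
    cr, *_ = np.linalg.lstsq(X, rho_map.values[ii, jj], rcond=None)
    ct, *_ = np.linalg.lstsq(X, theta_map.values[ii, jj], rcond=None)
    res_r = X @ cr - rho_map.values[ii, jj]
    res_t = X @ ct - theta_map.values[ii, jj]
    return LinearTransform(
        matrix=np.array([[cr[0], cr[1]], [ct[0], ct[1]]]),
        offset=np.array([cr[2], ct[2]]),
        max_residual_rho=float(np.abs(res_r).max()),
        max_residual_theta=float(np.abs(res_t).max()),
        s_threshold=s_threshold,
    )


@lru_cache(maxsize=2)
def default_transform(resolution: float = 1.0,
                      params: BackboneParams = DEFAULT_PARAMS) -> LinearTransform:
    """The affine transform fitted over the S > 0 basin at ``resolution``."""
    maps = basin_maps(resolution, params)
    return fit_linear_transform(maps["rho"], maps["theta"])


def phi_psi_to_rho_theta(t: LinearTransform, conf: Conformation) -> HelixDescriptor:
    """Affine image of a (phi, psi) pair."""
    v = t.matrix @ np.array([conf.phi, conf.psi]) + t.offset
    return HelixDescriptor(rho=float(v[0]), theta=float(v[1]))


def rho_theta_to_phi_psi(t: LinearTransform, hd: HelixDescriptor) -> Conformation:
    """Exact inverse of :func:`phi_psi_to_rho_theta`."""
    v = np.linalg.solve(t.matrix, np.array([hd.rho, hd.theta]) - t.offset)
    return Conformation(phi=wrap_angle(v[0]), psi=wrap_angle(v[1]))
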