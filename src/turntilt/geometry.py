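"""Backbone construction and helical descriptors.

Polypeptide backbones are built from internal coordinates (fixed bond
lengths, bend angles and the trans peptide dihedral) plus per-residue
(phi, psi) dihedrals.  From the Cartesian chain we derive the two helical
descriptors used throughout the package:

* ``rho`` — residues per helical turn, from the cumulative rotation of
  consecutive C-alpha radial vectors about the fitted helix axis;
* ``theta`` — the mean tilt of the backbone carbonyls relative to the
  plane normal to the helix axis, positive when the C=O bond points
  outward from the axis.

All heavy routines are vectorised over a leading batch dimension so that
conformational sweeps (hundreds of thousands of conformations) stay cheap;
the single-chain API is a thin wrapper over the batched kernels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "BackboneParams",
    "Conformation",
    "BackboneChain",
    "HelixFrame",
    "HelixDescriptor",
    "DEFAULT_PARAMS",
    "wrap_angle",
    "dihedral",
    "bend_angle",
    "build_backbone",
    "build_backbone_batch",
    "measure_dihedrals",
    "fit_helix_frame",
    "fit_axis_batch",
    "residues_per_turn",
    "carbonyl_tilt",
    "make_parametric_helix",
    "chain_to_pdb",
]


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class BackboneParams:
    """Fixed internal-coordinate geometry of the backbone model.

    Lengths in Angstrom, angles in degrees.  Defaults are mean values
    sampled from experimentally determined protein structures.
    """

    d_NCa: float = 1.46
    d_CaC: float = 1.52
    d_CN: float = 1.33
    d_CO: float = 1.23
    d_NH: float = 0.98
    a_CaCN: float = 117.0
    a_CNCa: float = 121.0
    a_NCaC: float = 111.0
    omega: float = 180.0
    n_residues: int = 30

    def __post_init__(self) -> None:
        for name in ("d_NCa", "d_CaC", "d_CN", "d_CO", "d_NH"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("a_CaCN", "a_CNCa", "a_NCaC"):
            a = getattr(self, name)
            if not 0.0 < a < 180.0:
                raise ValueError(f"{name} must lie in (0, 180) degrees")
        if self.n_residues < 1:
            raise ValueError("n_residues must be >= 1")


DEFAULT_PARAMS = BackboneParams()


def wrap_angle(a):
    """Wrap angle(s) in degrees to the interval (-180, 180]."""
    a = np.asarray(a, dtype=float)
    w = -np.mod(-a + 180.0, 360.0) + 180.0
    return w if w.ndim else float(w)


@dataclass(frozen=True)
class Conformation:
    """A (phi, psi) dihedral pair in degrees, wrapped to (-180, 180]."""

    phi: float
    psi: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.phi) and np.isfinite(self.psi)):
            raise ValueError("phi and psi must be finite")
        object.__setattr__(self, "phi", wrap_angle(self.phi))
        object.__setattr__(self, "psi", wrap_angle(self.psi))


@dataclass
class BackboneChain:
    """Cartesian backbone atoms of an n-residue chain.

    Arrays have shape (n, 3).  ``H`` rows may be NaN where no amide
    hydrogen is defined (the N-terminal residue); ``O`` rows may be NaN
    for chains read from coordinate files that lack the atom.
    """

    N: np.ndarray
    CA: np.ndarray
    C: np.ndarray
    O: np.ndarray
    H: np.ndarray | None = None
    labels: list[str] | None = None  # one-letter amino-acid codes

    def __post_init__(self) -> None:
        n = len(self.CA)
        for name in ("N", "CA", "C", "O"):
            a = np.asarray(getattr(self, name), dtype=float)
            if a.shape != (n, 3):
                raise ValueError(f"{name} must have shape ({n}, 3)")
            setattr(self, name, a)
        if self.H is not None:
            self.H = np.asarray(self.H, dtype=float).reshape(n, 3)

    def __len__(self) -> int:
        return len(self.CA)

    def mirrored(self) -> "BackboneChain":
        """Return the mirror image (all coordinates negated)."""
        return BackboneChain(
            N=-self.N, CA=-self.CA, C=-self.C, O=-self.O,
            H=None if self.H is None else -self.H,
            labels=self.labels,
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "BackboneChain":
        """Apply a rigid motion ``x -> R x + t`` to every atom."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        return BackboneChain(
            N=self.N @ R.T + t, CA=self.CA @ R.T + t,
            C=self.C @ R.T + t, O=self.O @ R.T + t,
            H=None if self.H is None else self.H @ R.T + t,
            labels=self.labels,
        )


@dataclass
class HelixFrame:
    """Axis frame of a helical chain.

    ``axis_direction`` is the unit helix axis oriented from the N toward
    the C terminus; ``rotations`` holds the signed per-step rotation
    angles r_{i,i+1} (degrees, positive for right-handed winding) of
    consecutive C-alpha radial vectors about the axis, and
    ``cumulative_rotation`` their sum R.
    """

    axis_direction: np.ndarray
    axis_point: np.ndarray
    radial_normals: np.ndarray        # q_i, unit vectors axis -> C_i, shape (n, 3)
    carbonyl_normals: np.ndarray      # n_CO,i = (C_i - O_i)/|..|, shape (n, 3)
    rotations: np.ndarray             # r_{i,i+1}, shape (n-1,)
    cumulative_rotation: float        # R = sum of rotations [deg]


@dataclass(frozen=True)
class HelixDescriptor:
    """(rho, theta): residues per turn and mean carbonyl tilt [deg]."""

    rho: float
    theta: float


# ---------------------------------------------------------------------------
# vector helpers (batched over arbitrary leading dimensions)


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


def dihedral(p0, p1, p2, p3):
    """Signed dihedral angle p0-p1-p2-p3 in degrees (IUPAC convention).

    Accepts arrays with arbitrary leading batch dimensions.
    """
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m = np.cross(n1, _unit(b1))
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(m * n2, axis=-1)
    ang = -np.degrees(np.arctan2(y, x))
    return float(ang) if ang.ndim == 0 else ang


def bend_angle(p0, p1, p2):
    """Bend angle p0-p1-p2 in degrees."""
    u = _unit(np.asarray(p0, float) - np.asarray(p1, float))
    v = _unit(np.asarray(p2, float) - np.asarray(p1, float))
    c = np.clip(np.sum(u * v, axis=-1), -1.0, 1.0)
    ang = np.degrees(np.arccos(c))
    return float(ang) if ang.ndim == 0 else ang


def _place(a, b, c, bond: float, theta_deg, chi_deg):
    """Place atom D so that |CD| = bond, angle(B,C,D) = theta and
    dihedral(A,B,C,D) = chi, batched over leading dimensions."""
    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    th = np.radians(theta_deg)
    chi = np.radians(chi_deg)
    if np.ndim(th):
        th = np.asarray(th)[..., None]
    if np.ndim(chi):
        chi = np.asarray(chi)[..., None]
    d = -np.cos(th) * bc + np.sin(th) * (np.cos(chi) * m + np.sin(chi) * n)
    return c + bond * d


def _bisector_place(p_left, center, p_right, bond: float):
    """Place an atom at ``bond`` from ``center``, in the plane of the three
    points, on the bisector opposite p_left/p_right (equal bend angles)."""
    u = _unit(p_left - center)
    v = _unit(p_right - center)
    return center - bond * _unit(u + v)


# ---------------------------------------------------------------------------
# backbone construction


def build_backbone_batch(phi, psi, params: BackboneParams = DEFAULT_PARAMS):
    """Build a batch of backbones from per-conformation dihedrals.

    Parameters
    ----------
    phi, psi : array-like
        Either shape (M,) — one uniform (phi, psi) per chain — or shape
        (M, n_residues) with per-residue values.  ``phi[:, 0]`` is unused
        (the first residue has no preceding carbonyl); ``psi[:, -1]``
        only orients the terminal carbonyl oxygen.

    Returns
    -------
    dict with arrays ``N, CA, C, O, H`` of shape (M, n, 3); ``H[:, 0]``
    is NaN (no amide hydrogen on the first residue).
    """
    n = params.n_residues
    phi = np.atleast_1d(np.asarray(phi, dtype=float))
    psi = np.atleast_1d(np.asarray(psi, dtype=float))
    if not (np.all(np.isfinite(phi)) and np.all(np.isfinite(psi))):
        raise ValueError("dihedrals must be finite")
    if phi.ndim == 1:
        phi = np.repeat(phi[:, None], n, axis=1)
    if psi.ndim == 1:
        psi = np.repeat(psi[:, None], n, axis=1)
    M = phi.shape[0]
    if phi.shape != (M, n) or psi.shape != (M, n):
        raise ValueError("phi/psi must have shape (M,) or (M, n_residues)")

    N = np.empty((M, n, 3))
    CA = np.empty((M, n, 3))
    C = np.empty((M, n, 3))

    # seed residue: N at origin, CA on +x, C in the xy-plane
    N[:, 0] = 0.0
    CA[:, 0] = np.array([params.d_NCa, 0.0, 0.0])
    ang = np.radians(180.0 - params.a_NCaC)
    C[:, 0] = CA[:, 0] + params.d_CaC * np.array([np.cos(ang), np.sin(ang), 0.0])

    for i in range(1, n):
        N[:, i] = _place(N[:, i - 1], CA[:, i - 1], C[:, i - 1],
                         params.d_CN, params.a_CaCN, psi[:, i - 1])
        CA[:, i] = _place(CA[:, i - 1], C[:, i - 1], N[:, i],
                          params.d_NCa, params.a_CNCa, params.omega)
        C[:, i] = _place(C[:, i - 1], N[:, i], CA[:, i],
                         params.d_CaC, params.a_NCaC, phi[:, i])

    # virtual next-residue nitrogen orients the terminal carbonyl
    N_virt = _place(N[:, n - 1], CA[:, n - 1], C[:, n - 1],
                    params.d_CN, params.a_CaCN, psi[:, n - 1])
    N_next = np.concatenate([N[:, 1:], N_virt[:, None]], axis=1)

    # carbonyl O: coplanar with CA, C, N(next), equal bend angles
    O = _bisector_place(CA, C, N_next, params.d_CO)

    # amide H: coplanar with C(prev), N, CA, equal bend angles; none on res 1
    H = np.full((M, n, 3), np.nan)
    H[:, 1:] = _bisector_place(C[:, :-1], N[:, 1:], CA[:, 1:], params.d_NH)

    return {"N": N, "CA": CA, "C": C, "O": O, "H": H}


def build_backbone(params: BackboneParams, conf: Conformation,
                   phi_psi_per_residue: np.ndarray | None = None) -> BackboneChain:
    """Build a single backbone chain at a uniform conformation.

    If ``phi_psi_per_residue`` (shape (n, 2)) is given it overrides the
    uniform conformation with per-residue dihedrals.
    """
    if phi_psi_per_residue is not None:
        pp = np.asarray(phi_psi_per_residue, dtype=float)
        atoms = build_backbone_batch(pp[None, :, 0], pp[None, :, 1], params)
    else:
        atoms = build_backbone_batch([conf.phi], [conf.psi], params)
    return BackboneChain(N=atoms["N"][0], CA=atoms["CA"][0],
                         C=atoms["C"][0], O=atoms["O"][0], H=atoms["H"][0])


def measure_dihedrals(chain: BackboneChain) -> list[Conformation]:
    """Transitional (phi, psi) pairs of consecutive residue pairs.

    For the pair (X, Y) = (i, i+1) the transitional psi is the dihedral
    N_X-CA_X-C_X-N_Y and the transitional phi is C_X-N_Y-CA_Y-C_Y, i.e.
    the conformation of the peptide bond between them.
    """
    n = len(chain)
    if n < 2:
        raise ValueError("need at least 2 residues")
    psi = dihedral(chain.N[:-1], chain.CA[:-1], chain.C[:-1], chain.N[1:])
    phi = dihedral(chain.C[:-1], chain.N[1:], chain.CA[1:], chain.C[1:])
    return [Conformation(phi=float(p), psi=float(s)) for p, s in zip(phi, psi)]


# ---------------------------------------------------------------------------
# helix frame and descriptors


def fit_axis_batch(ca: np.ndarray):
    """Total-least-squares helix axis for batches of C-alpha traces.

    Returns (axis, centroid): the principal direction of the centered
    C-alpha cloud, oriented from the N toward the C terminus.
    ``ca`` has shape (..., n, 3).
    """
    centroid = ca.mean(axis=-2, keepdims=True)
    X = ca - centroid
    cov = np.swapaxes(X, -1, -2) @ X
    _, vecs = np.linalg.eigh(cov)
    axis = vecs[..., :, -1]  # eigenvector of the largest eigenvalue
    sense = np.sum(axis * (ca[..., -1, :] - ca[..., 0, :]), axis=-1)
    axis = axis * np.where(sense < 0, -1.0, 1.0)[..., None]
    return axis, centroid[..., 0, :]


def _step_rotations(ca: np.ndarray, axis: np.ndarray, centroid: np.ndarray):
    """Signed rotation angles (deg) between consecutive C-alpha radial
    vectors about the axis, positive by the right-hand rule."""
    rel = ca - centroid[..., None, :]
    proj = rel - np.sum(rel * axis[..., None, :], axis=-1, keepdims=True) * axis[..., None, :]
    a = proj[..., :-1, :]
    b = proj[..., 1:, :]
    y = np.sum(np.cross(a, b) * axis[..., None, :], axis=-1)
    x = np.sum(a * b, axis=-1)
    return np.degrees(np.arctan2(y, x))


def fit_helix_frame(chain: BackboneChain) -> HelixFrame:
    """Fit the helix axis and per-residue frame of a chain (>= 5 residues)."""
    n = len(chain)
    if n < 5:
        raise ValueError("need at least 5 residues (one full i -> i+4 span)")
    ca = chain.CA
    axis, centroid = fit_axis_batch(ca)
    spread = ca - centroid
    radial = spread - np.sum(spread * axis, axis=-1, keepdims=True) * axis
    if np.max(np.linalg.norm(radial, axis=-1)) < 1e-8:
        raise ValueError("degenerate chain: C-alpha trace is collinear")
    r = _step_rotations(ca, axis, centroid)

    rel_c = chain.C - centroid
    Q = rel_c - np.sum(rel_c * axis, axis=-1, keepdims=True) * axis
    q = _unit(Q)
    co = chain.C - chain.O
    n_co = np.where(np.isfinite(co).all(axis=-1, keepdims=True), co, np.nan)
    with np.errstate(invalid="ignore"):
        n_co = n_co / np.linalg.norm(n_co, axis=-1, keepdims=True)

    return HelixFrame(
        axis_direction=axis, axis_point=centroid,
        radial_normals=q, carbonyl_normals=n_co,
        rotations=r, cumulative_rotation=float(r.sum()),
    )


def residues_per_turn(frame: HelixFrame, n_steps: int | None = None) -> float:
    """rho = 360 N / R with N the number of summed rotation steps.

    Raises for non-positive cumulative rotation (left-handed winding),
    where the right-handed residues-per-turn count is undefined.
    """
    R = frame.cumulative_rotation
    if R <= 0:
        raise ValueError("cumulative rotation <= 0: not a right-handed helix")
    N = len(frame.rotations) if n_steps is None else n_steps
    return 360.0 * N / R


def carbonyl_tilt(frame: HelixFrame) -> float:
    """Mean carbonyl tilt theta = <asin(-q_i . n_CO,i)> in degrees.

    Positive when the C=O bonds point outward from the helix axis.
    """
    d = np.sum(frame.radial_normals * frame.carbonyl_normals, axis=-1)
    d = d[np.isfinite(d)]
    if d.size == 0:
        raise ValueError("no carbonyl vectors defined")
    if np.any(np.abs(d) > 1.0 + 1e-9):
        raise ValueError("non-unit normals: |q . n_CO| > 1")
    return float(np.degrees(np.arcsin(-np.clip(d, -1.0, 1.0))).mean())


def chain_descriptor(chain: BackboneChain) -> HelixDescriptor:
    """Convenience: fit the frame and return (rho, theta)."""
    frame = fit_helix_frame(chain)
    return HelixDescriptor(rho=residues_per_turn(frame), theta=carbonyl_tilt(frame))


# ---------------------------------------------------------------------------
# synthetic parametric helices and PDB output


def make_parametric_helix(points_per_turn: float, rise: float = 1.5,
                          n: int = 12, radius: float = 2.3) -> np.ndarray:
    """Exact circular-helix points (for axis/rho unit tests).

    Positive ``points_per_turn`` yields a right-handed helix about +z;
    negative a left-handed one.  Must satisfy |points_per_turn| > 2.
    """
    if abs(points_per_turn) <= 2:
        raise ValueError("|points_per_turn| must exceed 2")
    # negative points_per_turn reverses the winding sense at positive rise,
    # which flips the handedness (a genuine mirror, not a rotation)
    t = np.arange(n) * (2 * np.pi / points_per_turn)
    return np.column_stack([radius * np.cos(t), radius * np.sin(t),
                            rise * np.arange(n, dtype=float)])


_PDB_ATOM = "ATOM  {serial:5d} {name:^4s}{alt:1s}{res:3s} {chain:1s}{seq:4d}{icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {elem:>2s}\n"

_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


def chain_to_pdb(chain: BackboneChain, chain_id: str = "A",
                 first_seq: int = 1, serial_start: int = 1,
                 include_h: bool = False) -> tuple[str, int]:
    """Render a chain as PDB ATOM records.

    Returns (text, next_serial).  Residue labels default to ALA.
    """
    labels = chain.labels or ["A"] * len(chain)
    lines = []
    serial = serial_start
    for i in range(len(chain)):
        res3 = _THREE.get(labels[i], "ALA")
        atoms = [("N", chain.N[i], "N"), ("CA", chain.CA[i], "C"),
                 ("C", chain.C[i], "C"), ("O", chain.O[i], "O")]
        if include_h and chain.H is not None and np.isfinite(chain.H[i]).all():
            atoms.append(("H", chain.H[i], "H"))
        for name, pos, elem in atoms:
            lines.append(_PDB_ATOM.format(
                serial=serial, name=name, alt=" ", res=res3, chain=chain_id,
                seq=first_seq + i, icode=" ", x=pos[0], y=pos[1], z=pos[2],
                occ=1.00, b=0.00, elem=elem))
            serial += 1
    return "".join(lines), serial
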