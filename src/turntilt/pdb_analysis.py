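"""Helix-transition statistics from PDB coordinate files.

A *transition* is an ordered amino-acid pair X -> Y spanning one peptide
bond; its conformation is the transitional pair (phi into Y, psi of X).
Transitions are harvested from PDB files and passed through four nested
filtering levels of increasing helical order:

* Level 0 — the (phi, psi) pair falls in the helical window
  -100 < phi < -20 and -80 < psi < 0 (degrees);
* Level 1 — additionally inside a HELIX-annotated segment;
* Level 2 — additionally the local i..i+4 segment scores S >= 0.01;
* Level 3 — additionally S >= 0.5.

Per-transition 2-D histograms (2-degree bins over the Level-0 window)
are compressed with log(1 + count) to damp database redundancy and
normalised to unit mass; means are taken in (phi, psi) and mapped to
(rho, theta) through the linear transform.  Confinement half-widths,
the isolated-pair-hypothesis (IPH) energy table and the predictability
fraction are derived from those statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .energy import HarmonicModel, harmonic_energy
from .geometry import dihedral, _unit
from .hbond import _distance_subscore
from .transform import LinearTransform

__all__ = [
    "AMINO_ACIDS",
    "LEVEL0_PHI",
    "LEVEL0_PSI",
    "S_WEAK",
    "S_STRONG",
    "ChainRecord",
    "read_structures",
    "extract_transitions",
    "filter_level",
    "TransitionStats",
    "transition_means",
    "confinement",
    "ConfinementStats",
    "iph_table",
    "predictability_fraction",
]

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"

LEVEL0_PHI = (-100.0, -20.0)
LEVEL0_PSI = (-80.0, 0.0)
S_WEAK = 0.01
S_STRONG = 0.5
CHAIN_BREAK_CN = 2.0   # [A] C-N distance above which the chain is broken
BIN_WIDTH = 2.0        # [deg] histogram bin width over the Level-0 window

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


@dataclass
class ChainRecord:
    """Ordered residues of one chain with helix annotation intervals."""

    structure_id: str
    chain_id: str
    resseq: np.ndarray               # (n,) residue sequence numbers
    aa: list[str]                    # one-letter codes
    atoms: dict                      # name -> (n, 3) array, NaN where absent
    helix_intervals: list[tuple[int, int]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.aa)

    def in_helix(self, seq: int) -> bool:
        return any(a <= seq <= b for a, b in self.helix_intervals)


def _read_helix_records(path) -> dict:
    """HELIX records (fixed-column) -> {chain_id: [(start_seq, end_seq)]}."""
    intervals: dict = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("HELIX"):
                continue
            try:
                init_chain = line[19]
                init_seq = int(line[21:25])
                end_seq = int(line[33:37])
            except (ValueError, IndexError):
                warnings.warn(f"malformed HELIX record in {path!s}: {line.rstrip()!r}")
                continue
            intervals.setdefault(init_chain, []).append((init_seq, end_seq))
    return intervals


def read_structures(paths) -> list[ChainRecord]:
    """Parse PDB files into per-chain residue streams.

    Only the first model of multi-model files is used; HETATM and
    non-standard residues are skipped; disordered atoms resolve to the
    highest-occupancy location (Bio.PDB default).  Malformed files are
    skipped with a warning.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionException

    parser = PDBParser(QUIET=True)
    records: list[ChainRecord] = []
    if isinstance(paths, (str, Path)):
        paths = [paths]
    for path in paths:
        helices = _read_helix_records(path)
        try:
            structure = parser.get_structure(Path(path).stem, str(path))
        except (PDBConstructionException, ValueError) as exc:
            warnings.warn(f"skipping malformed file {path!s}: {exc}")
            continue
        try:
            model = next(structure.get_models())
        except StopIteration:
            warnings.warn(f"no models in {path!s}")
            continue
        for chain in model:
            resseq, aa, coords = [], [], {k: [] for k in ("N", "CA", "C", "O")}
            for res in chain:
                hetflag, seq, _ = res.get_id()
                if hetflag.strip():
                    continue
                one = _THREE_TO_ONE.get(res.get_resname())
                if one is None:
                    continue
                resseq.append(seq)
                aa.append(one)
                for name in coords:
                    if name in res:
                        coords[name].append(res[name].get_coord())
                    else:
                        coords[name].append(np.full(3, np.nan))
            if not aa:
                continue
            records.append(ChainRecord(
                structure_id=structure.id, chain_id=chain.id,
                resseq=np.asarray(resseq), aa=aa,
                atoms={k: np.asarray(v, dtype=float) for k, v in coords.items()},
                helix_intervals=helices.get(chain.id, []),
            ))
    return records


# ---------------------------------------------------------------------------
# transition extraction and filtering


def _contiguous(chain: ChainRecord, i: int, j: int) -> bool:
    """True when residues i..j are consecutive and peptide-bonded."""
    for k in range(i, j):
        c = chain.atoms["C"][k]
        n = chain.atoms["N"][k + 1]
        if not (np.isfinite(c).all() and np.isfinite(n).all()):
            return False
        if np.linalg.norm(n - c) > CHAIN_BREAK_CN:
            return False
    return True


def _segment_bond_score(chain: ChainRecord, i: int) -> float:
    """Alignment score of the single i -> i+4 hydrogen bond of the
    5-residue window starting at the transition's donor residue i.

    The amide hydrogen of residue i+4 is estimated from the backbone
    (N-H 0.98 A on the C-N-CA bisector); handedness comes from the
    winding of the five C-alpha positions.
    """
    if i + 4 >= len(chain) or not _contiguous(chain, i, i + 4):
        return 0.0
    A = chain.atoms
    need = [A["O"][i], A["C"][i]] + [A["CA"][k] for k in range(i, i + 5)] \
        + [A["C"][i + 3], A["N"][i + 4], A["CA"][i + 4]]
    if not np.all([np.isfinite(x).all() for x in need]):
        return 0.0
    O, C = A["O"][i], A["C"][i]
    Nd = A["N"][i + 4]
    u = _unit(A["C"][i + 3] - Nd)
    v = _unit(A["CA"][i + 4] - Nd)
    Hd = Nd - 0.98 * _unit(u + v)

    s_ho = float(_distance_subscore(np.linalg.norm(Hd - O)))
    u_oc = _unit(C - O)
    s_ocnh = max(0.0, float(np.dot(u_oc, _unit(Hd - Nd))))
    s_ocho = max(0.0, float(np.dot(u_oc, _unit(O - Hd))))

    ca = np.stack([A["CA"][k] for k in range(i, i + 5)])
    from .geometry import fit_axis_batch, _step_rotations
    axis, centroid = fit_axis_batch(ca)
    hand = 1.0 if _step_rotations(ca, axis, centroid).sum() > 0 else 0.0
    return s_ho * s_ocnh * s_ocho * hand


def filter_level(phi: float, psi: float, in_helix: bool, segment_score: float) -> int:
    """Highest passing filtering level (0-3), or -1 when Level 0 fails."""
    if not (LEVEL0_PHI[0] < phi < LEVEL0_PHI[1] and LEVEL0_PSI[0] < psi < LEVEL0_PSI[1]):
        return -1
    if not in_helix:
        return 0
    if segment_score < S_WEAK:
        return 1
    if segment_score < S_STRONG:
        return 2
    return 3


def extract_transitions(chains, transform: LinearTransform | None = None) -> pd.DataFrame:
    """Harvest transitional (phi, psi) pairs with their filtering levels.

    Returns a DataFrame with columns structure, chain, position, src, dst,
    phi, psi, level (highest passing, -1 outside the Level-0 window) and,
    when a transform is given, rho and theta.
    """
    rows = []
    for chain in chains:
        A = chain.atoms
        for i in range(len(chain) - 1):
            if not _contiguous(chain, i, i + 1):
                continue
            needed = [A["N"][i], A["CA"][i], A["C"][i],
                      A["N"][i + 1], A["CA"][i + 1], A["C"][i + 1]]
            if not np.all([np.isfinite(x).all() for x in needed]):
                continue
            psi = dihedral(A["N"][i], A["CA"][i], A["C"][i], A["N"][i + 1])
            phi = dihedral(A["C"][i], A["N"][i + 1], A["CA"][i + 1], A["C"][i + 1])
            in_helix = chain.in_helix(int(chain.resseq[i])) and \
                chain.in_helix(int(chain.resseq[i + 1]))
            seg = _segment_bond_score(chain, i) if in_helix else 0.0
            rows.append((chain.structure_id, chain.chain_id, i,
                         chain.aa[i], chain.aa[i + 1], phi, psi,
                         filter_level(phi, psi, in_helix, seg)))
    df = pd.DataFrame(rows, columns=["structure", "chain", "position",
                                     "src", "dst", "phi", "psi", "level"])
    if transform is not None and len(df):
        rt = (transform.matrix @ df[["phi", "psi"]].to_numpy().T).T + transform.offset
        df["rho"] = rt[:, 0]
        df["theta"] = rt[:, 1]
    return df


# ---------------------------------------------------------------------------
# per-transition histograms


def _bin_edges():
    phi_edges = np.arange(LEVEL0_PHI[0], LEVEL0_PHI[1] + BIN_WIDTH / 2, BIN_WIDTH)
    psi_edges = np.arange(LEVEL0_PSI[0], LEVEL0_PSI[1] + BIN_WIDTH / 2, BIN_WIDTH)
    return phi_edges, psi_edges


class TransitionStats:
    """Per-transition 2-D histograms over the Level-0 window, per level.

    Histograms are accumulated as raw counts; ``compress_and_normalize``
    applies log(1 + count) (redundancy damping) and scales each histogram
    to unit mass.  Levels nest: a sample passing level L increments the
    histograms of all levels <= L.
    """

    def __init__(self) -> None:
        self.phi_edges, self.psi_edges = _bin_edges()
        self.counts: dict = {}     # (src, dst, level) -> 2-D array
        self.normalized = False

    def _hist(self, key):
        if key not in self.counts:
            self.counts[key] = np.zeros(
                (len(self.phi_edges) - 1, len(self.psi_edges) - 1))
        return self.counts[key]

    def accumulate(self, src: str, dst: str, phi: float, psi: float, level: int):
        """Add one sample at its highest passing level (and all below)."""
        if self.normalized:
            raise RuntimeError("stats already normalised")
        if level < 0:
            return
        i = int(np.searchsorted(self.phi_edges, phi, side="right")) - 1
        j = int(np.searchsorted(self.psi_edges, psi, side="right")) - 1
        i = min(max(i, 0), len(self.phi_edges) - 2)
        j = min(max(j, 0), len(self.psi_edges) - 2)
        for lvl in range(level + 1):
            self._hist((src, dst, lvl))[i, j] += 1

    @classmethod
    def from_samples(cls, samples: pd.DataFrame) -> "TransitionStats":
        stats = cls()
        for row in samples.itertuples(index=False):
            stats.accumulate(row.src, row.dst, row.phi, row.psi, row.level)
        return stats

    def compress_and_normalize(self) -> "TransitionStats":
        """b -> log(1 + b), then scale each histogram to unit mass."""
        for key, h in self.counts.items():
            h = np.log1p(h)
            total = h.sum()
            if total > 0:
                h = h / total
            else:
                warnings.warn(f"all-zero histogram for {key}")
            self.counts[key] = h
        self.normalized = True
        return self

    def bin_centers(self):
        return (0.5 * (self.phi_edges[:-1] + self.phi_edges[1:]),
                0.5 * (self.psi_edges[:-1] + self.psi_edges[1:]))


def transition_means(stats: TransitionStats,
                     transform: LinearTransform | None = None) -> pd.DataFrame:
    """Histogram-weighted mean conformation per transition and level.

    Means are taken over bin centers in (phi, psi); the (rho, theta)
    mean is the transform image of each bin center, weighted identically.
    Empty histograms are excluded.
    """
    pc, qc = stats.bin_centers()
    P, Q = np.meshgrid(pc, qc, indexing="ij")
    rows = []
    for (src, dst, level), h in sorted(stats.counts.items()):
        w = h.sum()
        if w <= 0:
            continue
        phi_mean = float((h * P).sum() / w)
        psi_mean = float((h * Q).sum() / w)
        row = {"src": src, "dst": dst, "level": level,
               "phi": phi_mean, "psi": psi_mean, "weight": w}
        if transform is not None:
            v = transform.matrix @ np.array([phi_mean, psi_mean]) + transform.offset
            row["rho"], row["theta"] = float(v[0]), float(v[1])
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# confinement and the isolated-pair hypothesis


@dataclass
class ConfinementStats:
    """Per-level 50% confinement half-widths and their averages."""

    per_level: pd.DataFrame          # level, d_theta, d_rho, n
    d_theta_mean: float              # <d_theta> [deg]
    d_rho_mean: float                # <d_rho> [Res/Turn]


def confinement(samples: pd.DataFrame, K: float = HarmonicModel().K,
                shape: str = "ellipse", fraction: float = 0.5) -> ConfinementStats:
    """Smallest harmonic contour holding ``fraction`` of the samples.

    Samples (with rho/theta columns) are pooled per level; the contour is
    centred on the pooled mean with the theta/rho aspect ratio fixed to K.
    ``shape="ellipse"`` uses the harmonic (elliptic) contour
    (theta - m_t)^2 + K^2 (rho - m_r)^2 <= d_theta^2; ``shape="box"`` a
    K-consistent rectangle (Chebyshev contour in scaled coordinates).
    """
    if shape not in ("ellipse", "box"):
        raise ValueError("shape must be 'ellipse' or 'box'")
    rows = []
    for level in range(4):
        sub = samples[samples["level"] >= level]
        if len(sub) < 2:
            continue
        dt = sub["theta"].to_numpy() - sub["theta"].mean()
        dr = (sub["rho"].to_numpy() - sub["rho"].mean()) * K
        if shape == "ellipse":
            radius = np.hypot(dt, dr)
        else:
            radius = np.maximum(np.abs(dt), np.abs(dr))
        d_theta = float(np.quantile(radius, fraction))
        rows.append({"level": level, "d_theta": d_theta,
                     "d_rho": d_theta / K, "n": len(sub)})
    per_level = pd.DataFrame(rows)
    if per_level.empty:
        raise ValueError("no level has >= 2 samples")
    return ConfinementStats(per_level=per_level,
                            d_theta_mean=float(per_level["d_theta"].mean()),
                            d_rho_mean=float(per_level["d_rho"].mean()))


def iph_table(means: pd.DataFrame, model: HarmonicModel | None = None,
              level: int = 1) -> pd.DataFrame:
    """Isolated-pair-hypothesis energy table at one filtering level.

    For each ordered pair (X, Y) the predicted conformation is the
    arithmetic (rho, theta) mean of the homogeneous transitions X->X and
    Y->Y; the cell holds the harmonic energy [EU] of that prediction with
    the measured X->Y mean as the energy minimum.  Cells lacking any of
    the three means are NaN; the diagonal is 0 by construction.
    """
    model = model or HarmonicModel()
    sub = means[means["level"] == level].set_index(["src", "dst"])
    aas = list(AMINO_ACIDS)
    table = pd.DataFrame(np.nan, index=aas, columns=aas)
    for x in aas:
        for y in aas:
            try:
                measured = sub.loc[(x, y)]
                hx = sub.loc[(x, x)]
                hy = sub.loc[(y, y)]
            except KeyError:
                continue
            pred_rho = 0.5 * (hx["rho"] + hy["rho"])
            pred_theta = 0.5 * (hx["theta"] + hy["theta"])
            m = HarmonicModel(theta0=float(measured["theta"]),
                              rho0=float(measured["rho"]), K=model.K)
            table.loc[x, y] = harmonic_energy(pred_rho, pred_theta, m)
    return table


def predictability_fraction(table: pd.DataFrame, tolerance: float) -> float:
    """Fraction of off-diagonal (heterogeneous) cells with dE <= tolerance."""
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    vals = table.to_numpy().copy()
    np.fill_diagonal(vals, np.nan)
    off = vals[np.isfinite(vals)]
    if off.size == 0:
        raise ValueError("no heterogeneous cells available")
    return float((off <= tolerance).mean())
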