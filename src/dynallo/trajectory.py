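"""MD-trajectory statistics: contacts, Cartesian PCA, dihedral mutual information.

Three analyses aimed at locating condition-dependent dynamics in replica
trajectory sets (e.g. phosphorylated vs non-phosphorylated constructs):

* sliding-window contact probability between two atom groups under a
  heavy-atom minimum-distance cutoff;
* principal component analysis of superposed Cartesian coordinates fitted
  on merged trajectories, with per-replica projections, interval-overlap
  convergence checks, and per-residue RMSF of individual eigenvectors;
* histogram mutual information between side-chain dihedral angles with
  Miller–Madow bias correction, and replica-level Welch t-tests on the
  condition difference.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist

log = logging.getLogger(__name__)

__all__ = [
    "Topology",
    "Replica",
    "TrajectoryEnsemble",
    "select",
    "ContactProfile",
    "contact_probability",
    "PCAModel",
    "fit_pca",
    "project",
    "overlap",
    "eigenvector_rmsf",
    "dihedral_angles",
    "MIMatrix",
    "dihedral_mi",
    "mi_difference",
]


# ---------------------------------------------------------------------------
# Containers and IO
# ---------------------------------------------------------------------------

@dataclass
class Topology:
    """Minimal atom table: names, residue ids/names, elements."""

    names: np.ndarray       # str
    resids: np.ndarray      # int
    resnames: np.ndarray    # str
    elements: np.ndarray    # str, e.g. "C", "N", "H"

    def __post_init__(self) -> None:
        n = len(self.names)
        if not (len(self.resids) == len(self.resnames) == len(self.elements) == n):
            raise ValueError("topology arrays must share one length")

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def residues(self) -> np.ndarray:
        return np.unique(self.resids)


@dataclass
class Replica:
    """One trajectory replica: coordinates in Å, frame interval in ns."""

    coords: np.ndarray  # (n_frames, n_atoms, 3)
    dt_ns: float
    label: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (frames, atoms, 3)")
        if self.dt_ns <= 0:
            raise ValueError("frame interval must be > 0")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]


@dataclass
class TrajectoryEnsemble:
    """Replica trajectories sharing one topology, tagged with a condition."""

    topology: Topology
    replicas: list[Replica]
    condition: str = ""

    def __post_init__(self) -> None:
        for r in self.replicas:
            if r.coords.shape[1] != self.topology.n_atoms:
                raise ValueError(
                    f"replica '{r.label}' has {r.coords.shape[1]} atoms, "
                    f"topology has {self.topology.n_atoms}"
                )

    @property
    def n_replicas(self) -> int:
        return len(self.replicas)

    @classmethod
    def from_files(
        cls,
        topology_path: str | Path,
        trajectory_paths: list[str | Path],
        dt_ns: float,
        condition: str = "",
    ) -> "TrajectoryEnsemble":
        """Load replicas via MDAnalysis (PDB/DCD/XTC and multi-model PDB)."""
        import MDAnalysis as mda

        replicas = []
        topo = None
        for path in trajectory_paths:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # mda guesses masses noisily
                u = mda.Universe(str(topology_path), str(path))
                if topo is None:
                    try:
                        elements = np.array([a.element for a in u.atoms])
                    except Exception:
                        elements = np.array(
                            [name[0] for name in u.atoms.names], dtype=object
                        )
                    topo = Topology(
                        names=np.array(u.atoms.names),
                        resids=np.array(u.atoms.resids),
                        resnames=np.array(u.atoms.resnames),
                        elements=np.array([str(e).upper() for e in elements]),
                    )
                coords = np.stack([u.atoms.positions.copy() for _ in u.trajectory])
            replicas.append(Replica(coords=coords, dt_ns=dt_ns, label=Path(path).stem))
        return cls(topology=topo, replicas=replicas, condition=condition)

    def write_pdb_models(self, directory: str | Path, prefix: str = "replica") -> list[Path]:
        """Write each replica as a plain multi-model PDB (text, codec-free)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = []
        for ri, rep in enumerate(self.replicas):
            path = directory / f"{prefix}_{ri:02d}.pdb"
            with path.open("w") as fh:
                for fi in range(rep.n_frames):
                    fh.write(f"MODEL     {fi + 1:4d}\n")
                    for ai in range(self.topology.n_atoms):
                        x, y, z = rep.coords[fi, ai]
                        fh.write(
                            "ATOM  {serial:5d} {name:^4s} {resn:>3s} A{resid:4d}    "
                            "{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {el:>2s}\n".format(
                                serial=ai + 1,
                                name=self.topology.names[ai][:4],
                                resn=str(self.topology.resnames[ai])[:3],
                                resid=int(self.topology.resids[ai]),
                                x=x, y=y, z=z,
                                el=str(self.topology.elements[ai])[:2],
                            )
                        )
                    fh.write("ENDMDL\n")
                fh.write("END\n")
            paths.append(path)
        return paths


# ---------------------------------------------------------------------------
# Selections: a small "resid 757-770 and heavy" grammar
# ---------------------------------------------------------------------------

def select(topology: Topology, expression: str) -> np.ndarray:
    """Boolean atom mask from a mini selection grammar.

    Clauses joined by ``and``:  ``all`` | ``heavy`` | ``name N1 N2 ...`` |
    ``element C N ...`` | ``resid 757-770 545 660``.
    """
    mask = np.ones(topology.n_atoms, dtype=bool)
    tokens = expression.split()
    if not tokens:
        raise ValueError("empty selection expression")
    clauses: list[list[str]] = [[]]
    for tok in tokens:
        if tok.lower() == "and":
            clauses.append([])
        else:
            clauses[-1].append(tok)
    for clause in clauses:
        if not clause:
            raise ValueError(f"dangling 'and' in selection {expression!r}")
        kw, *args = clause
        kw = kw.lower()
        if kw == "all":
            sub = np.ones(topology.n_atoms, dtype=bool)
        elif kw == "heavy":
            sub = np.char.upper(topology.elements.astype(str)) != "H"
        elif kw == "name":
            sub = np.isin(topology.names, args)
        elif kw == "element":
            sub = np.isin(
                np.char.upper(topology.elements.astype(str)),
                [a.upper() for a in args],
            )
        elif kw == "resid":
            wanted: set[int] = set()
            for a in args:
                if "-" in a[1:]:  # allow negative single ids, not ranges
                    lo, hi = a.split("-")
                    wanted.update(range(int(lo), int(hi) + 1))
                else:
                    wanted.add(int(a))
            sub = np.isin(topology.resids, sorted(wanted))
        else:
            raise ValueError(f"unknown selection keyword {kw!r}")
        mask &= sub
    return mask


def _as_mask(topology: Topology, sel) -> np.ndarray:
    if isinstance(sel, str):
        return select(topology, sel)
    arr = np.asarray(sel)
    if arr.dtype == bool:
        return arr
    mask = np.zeros(topology.n_atoms, dtype=bool)
    mask[arr] = True
    return mask


# ---------------------------------------------------------------------------
# Contact probability
# ---------------------------------------------------------------------------

@dataclass
class ContactProfile:
    """Per-frame contact indicator plus its sliding-window probability."""

    pair_label: str
    indicator: np.ndarray        # (n_frames,) 0/1
    window_series: np.ndarray    # (n_frames - window + 1,)
    cutoff: float                # Å
    window_frames: int
    dt_ns: float

    @property
    def mean_probability(self) -> float:
        return float(self.indicator.mean())


def contact_probability(
    ens: TrajectoryEnsemble,
    sel_a,
    sel_b,
    cutoff: float = 2.5,
    window_ns: float = 1.0,
    include_hydrogens: bool = False,
) -> list[ContactProfile]:
    """Sliding-window contact probability between two atom groups.

    A frame counts as a single contact event when the minimum distance over
    all selected atom pairs is below ``cutoff`` (any number of simultaneous
    contacts still counts once).  Heavy atoms only by default.  The window
    slides with stride 1; partial windows are truncated.
    """
    topo = ens.topology
    mask_a = _as_mask(topo, sel_a)
    mask_b = _as_mask(topo, sel_b)
    if not include_hydrogens:
        heavy = np.char.upper(topo.elements.astype(str)) != "H"
        mask_a = mask_a & heavy
        mask_b = mask_b & heavy
    if not mask_a.any() or not mask_b.any():
        raise ValueError("empty atom selection for contact analysis")
    if (mask_a & mask_b).any():
        raise ValueError("contact selections must be disjoint")
    ia, ib = np.where(mask_a)[0], np.where(mask_b)[0]

    profiles = []
    for rep in ens.replicas:
        window = int(round(window_ns / rep.dt_ns))
        if window < 1:
            raise ValueError(
                f"window {window_ns} ns is shorter than one frame ({rep.dt_ns} ns)"
            )
        window = min(window, rep.n_frames)
        indicator = np.empty(rep.n_frames, dtype=float)
        for fi in range(rep.n_frames):
            dmin = cdist(rep.coords[fi, ia], rep.coords[fi, ib]).min()
            indicator[fi] = 1.0 if dmin < cutoff else 0.0
        kernel = np.ones(window) / window
        series = np.convolve(indicator, kernel, mode="valid")
        profiles.append(
            ContactProfile(
                pair_label=f"{ens.condition}:{rep.label}",
                indicator=indicator,
                window_series=series,
                cutoff=cutoff,
                window_frames=window,
                dt_ns=rep.dt_ns,
            )
        )
    return profiles


# ---------------------------------------------------------------------------
# Cartesian PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAModel:
    """Covariance eigendecomposition of superposed Cartesian coordinates."""

    atom_indices: np.ndarray     # atoms in the selection
    resids: np.ndarray           # residue id per selected atom
    mean: np.ndarray             # (n_sel, 3) Å
    eigenvectors: np.ndarray     # (3n_sel, n_modes), columns orthonormal
    eigenvalues: np.ndarray      # Å², descending, >= 0
    provenance: list[str] = field(default_factory=list)
    degenerate: bool = False     # all frames identical

    @property
    def n_modes(self) -> int:
        return self.eigenvectors.shape[1]


def _kabsch(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Least-squares superpose one frame (n,3) onto a reference (n,3)."""
    mc = mobile - mobile.mean(axis=0)
    rc = reference - reference.mean(axis=0)
    h = mc.T @ rc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, 1.0, d]) @ vt
    return mc @ rot + reference.mean(axis=0)


def _superpose_stack(frames: np.ndarray, reference: np.ndarray, n_iter: int = 2) -> np.ndarray:
    """Superpose all frames onto the (iteratively refined) mean structure."""
    out = np.stack([_kabsch(f, reference) for f in frames])
    for _ in range(n_iter):
        ref = out.mean(axis=0)
        out = np.stack([_kabsch(f, ref) for f in out])
    return out


def fit_pca(ens_list: list[TrajectoryEnsemble], selection) -> PCAModel:
    """Fit Cartesian PCA on merged trajectories.

    Frames from every replica of every ensemble are merged, least-squares
    superposed onto the mean of the selection, and the 3N-dimensional
    coordinate covariance is eigendecomposed.  Replica order does not affect
    the result.  All-identical frames yield zero eigenvalues and set the
    ``degenerate`` flag.
    """
    if not ens_list:
        raise ValueError("need at least one ensemble")
    topo = ens_list[0].topology
    mask = _as_mask(topo, selection)
    idx = np.where(mask)[0]
    if idx.size == 0:
        raise ValueError("empty PCA selection")
    frames = []
    provenance = []
    for ens in ens_list:
        for rep in ens.replicas:
            frames.append(rep.coords[:, idx, :])
            provenance.append(f"{ens.condition}:{rep.label}")
    merged = np.concatenate(frames, axis=0)
    if merged.shape[0] < 2:
        raise ValueError("need >= 2 frames for PCA")
    sup = _superpose_stack(merged, merged[0])
    mean = sup.mean(axis=0)
    dev = (sup - mean).reshape(sup.shape[0], -1)
    cov = (dev.T @ dev) / (dev.shape[0] - 1)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals = np.clip(vals[order], 0.0, None)
    vecs = vecs[:, order]
    degenerate = bool(np.all(vals < 1e-12))
    return PCAModel(
        atom_indices=idx,
        resids=topo.resids[idx],
        mean=mean,
        eigenvectors=vecs,
        eigenvalues=vals,
        provenance=provenance,
        degenerate=degenerate,
    )


def project(replica: Replica, model: PCAModel, k: int) -> np.ndarray:
    """Projection time series of one replica on eigenvector ``k`` (0-based)."""
    if not 0 <= k < model.n_modes:
        raise IndexError(f"eigenvector index {k} out of range [0, {model.n_modes})")
    frames = replica.coords[:, model.atom_indices, :]
    sup = np.stack([_kabsch(f, model.mean) for f in frames])
    dev = (sup - model.mean).reshape(sup.shape[0], -1)
    return dev @ model.eigenvectors[:, k]


def overlap(series_a: np.ndarray, series_b: np.ndarray) -> float:
    """Interval Jaccard of two projection ranges: |∩| / |∪| in [0, 1]."""
    lo_a, hi_a = float(np.min(series_a)), float(np.max(series_a))
    lo_b, hi_b = float(np.min(series_b)), float(np.max(series_b))
    inter = min(hi_a, hi_b) - max(lo_a, lo_b)
    union = max(hi_a, hi_b) - min(lo_a, lo_b)
    if union <= 0:  # both ranges are single points
        return 1.0 if lo_a == lo_b else 0.0
    return max(inter, 0.0) / union


def eigenvector_rmsf(model: PCAModel, k: int) -> pd.DataFrame:
    """Per-residue RMSF (Å) carried by one eigenvector.

    RMSF_r = sqrt(λ_k · Σ_{atoms of r} Σ_{xyz} v²); by orthonormality the
    squared values sum to λ_k over all residues.
    """
    if not 0 <= k < model.n_modes:
        raise IndexError(f"eigenvector index {k} out of range")
    v = model.eigenvectors[:, k].reshape(-1, 3)
    per_atom = (v ** 2).sum(axis=1) * model.eigenvalues[k]
    frame = pd.DataFrame({"resid": model.resids, "msf": per_atom})
    out = frame.groupby("resid", as_index=False)["msf"].sum()
    out["rmsf"] = np.sqrt(out["msf"])
    return out[["resid", "rmsf"]]


# ---------------------------------------------------------------------------
# Dihedral mutual information
# ---------------------------------------------------------------------------

def dihedral_angles(coords: np.ndarray, quadruple: np.ndarray) -> np.ndarray:
    """Torsion angle time series in degrees, in (−180, 180].

    ``coords`` is (frames, atoms, 3); ``quadruple`` the four atom indices.
    """
    p0, p1, p2, p3 = (coords[:, i, :] for i in quadruple)
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1, axis=1, keepdims=True)
    v = b0 - (b0 * b1n).sum(axis=1, keepdims=True) * b1n
    w = b2 - (b2 * b1n).sum(axis=1, keepdims=True) * b1n
    x = (v * w).sum(axis=1)
    y = (np.cross(b1n, v) * w).sum(axis=1)
    ang = np.degrees(np.arctan2(y, x))
    ang[ang <= -180.0] += 360.0
    return ang


def _circular_bins(angles: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-width circular bin index over (−180, 180]."""
    shifted = np.mod(angles + 180.0, 360.0)  # [0, 360)
    idx = np.floor(shifted / (360.0 / n_bins)).astype(int)
    return np.clip(idx, 0, n_bins - 1)


def histogram_mi(a: np.ndarray, b: np.ndarray, n_bins: int = 24) -> float:
    """Miller–Madow-corrected histogram MI (nats) between two angle series."""
    n = a.size
    ia = _circular_bins(np.asarray(a, dtype=float), n_bins)
    ib = _circular_bins(np.asarray(b, dtype=float), n_bins)
    joint = np.zeros((n_bins, n_bins))
    np.add.at(joint, (ia, ib), 1.0)
    joint /= n
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    mi = float(
        np.sum(joint[nz] * np.log(joint[nz] / np.outer(px, py)[nz]))
    )
    # Miller-Madow: H_true ≈ H_plugin + (m−1)/2N per entropy term
    mx = int(np.count_nonzero(px))
    my = int(np.count_nonzero(py))
    mxy = int(np.count_nonzero(joint))
    mi += ((mx - 1) + (my - 1) - (mxy - 1)) / (2.0 * n)
    return mi


def mi_bias_bound(n_samples: int, n_bins: int = 24) -> float:
    """First-order plugin MI bias, (Bx−1)(By−1)/(2N) nats."""
    return (n_bins - 1) ** 2 / (2.0 * n_samples)


@dataclass
class MIMatrix:
    """Residue × residue mutual information for one replica (nats)."""

    residues: np.ndarray
    matrix: np.ndarray            # symmetric, diagonal = 0 (excluded)
    n_bins: int
    replica_label: str = ""

    def row_sums(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"residue": self.residues, "mi_sum": self.matrix.sum(axis=1)}
        )


def dihedral_mi(
    ens: TrajectoryEnsemble,
    residue_dihedral_map: dict[int, list],
    n_bins: int = 24,
) -> list[MIMatrix]:
    """Residue-pair MI matrices, one per replica.

    ``residue_dihedral_map`` maps residue id → list of 4-atom index
    quadruples (its side-chain torsions).  Pair MI is the sum over all
    torsion combinations of the two residues; the diagonal (self MI) is
    excluded.  Residues with no torsions are dropped with a log entry.
    """
    usable = {r: q for r, q in residue_dihedral_map.items() if q}
    for r in set(residue_dihedral_map) - set(usable):
        log.info("residue %s has no dihedrals; excluded from MI", r)
    residues = np.array(sorted(usable))
    if residues.size < 2:
        raise ValueError("need >= 2 residues with dihedrals for pair MI")
    out = []
    for rep in ens.replicas:
        if rep.n_frames < n_bins ** 2 / 5:
            warnings.warn(
                f"{rep.n_frames} frames < n_bins^2/5 = {n_bins ** 2 / 5:.0f}: "
                "MI estimates will be noisy", stacklevel=2,
            )
        series = {
            r: [dihedral_angles(rep.coords, np.asarray(q)) for q in usable[r]]
            for r in residues
        }
        m = np.zeros((residues.size, residues.size))
        for i in range(residues.size):
            for j in range(i + 1, residues.size):
                total = 0.0
                for a in series[residues[i]]:
                    for b in series[residues[j]]:
                        total += histogram_mi(a, b, n_bins=n_bins)
                m[i, j] = m[j, i] = total
        out.append(MIMatrix(residues=residues, matrix=m, n_bins=n_bins,
                            replica_label=rep.label))
    return out


@dataclass
class MIDifference:
    """Filtered condition difference of MI matrices."""

    residues: np.ndarray
    difference: np.ndarray       # mean(A) − mean(B), unfiltered
    filtered: np.ndarray         # difference where significant, else 0
    mask: np.ndarray             # bool, p < alpha
    p_values: np.ndarray
    alpha: float
    corrected: bool


def mi_difference(
    mi_a: list[MIMatrix],
    mi_b: list[MIMatrix],
    alpha: float = 0.05,
    benjamini_hochberg: bool = False,
) -> MIDifference:
    """Element-wise Welch t-test between two replica sets of MI matrices.

    Off-diagonal upper-triangle elements are tested two-sided across
    replicas; elements failing ``p < alpha`` are zeroed in the filtered
    difference.  Optional Benjamini–Hochberg control across the tested
    elements.
    """
    if len(mi_a) < 2 or len(mi_b) < 2:
        raise ValueError("need >= 2 replicas per condition for the t-test")
    residues = mi_a[0].residues
    for m in mi_a + mi_b:
        if m.matrix.shape != mi_a[0].matrix.shape or not np.array_equal(
            m.residues, residues
        ):
            raise ValueError("MI matrices must share shape and residue order")
    stack_a = np.stack([m.matrix for m in mi_a])
    stack_b = np.stack([m.matrix for m in mi_b])
    diff = stack_a.mean(axis=0) - stack_b.mean(axis=0)
    n = residues.size
    pvals = np.ones((n, n))
    iu = np.triu_indices(n, k=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = stats.ttest_ind(
            stack_a[:, iu[0], iu[1]], stack_b[:, iu[0], iu[1]],
            axis=0, equal_var=False,
        )
    p_flat = np.where(np.isnan(t.pvalue), 1.0, t.pvalue)
    if benjamini_hochberg:
        order = np.argsort(p_flat)
        m_tests = p_flat.size
        adj = np.empty_like(p_flat)
        prev = 1.0
        for rank_pos in range(m_tests - 1, -1, -1):
            i = order[rank_pos]
            val = p_flat[i] * m_tests / (rank_pos + 1)
            prev = min(prev, val)
            adj[i] = prev
        p_flat = adj
    pvals[iu] = p_flat
    pvals[(iu[1], iu[0])] = p_flat
    mask = pvals < alpha
    np.fill_diagonal(mask, False)
    filtered = np.where(mask, diff, 0.0)
    return MIDifference(
        residues=residues, difference=diff, filtered=filtered,
        mask=mask, p_values=pvals, alpha=alpha, corrected=benjamini_hochberg,
    )
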