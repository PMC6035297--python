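"""Synthetic data with planted ground truth.

Generates the three kinds of inputs the analysis consumes, with every
planted parameter recorded so downstream modules can be checked for
recovery:

* per-construct HSQC peak lists whose crosspeaks lie on residue-specific
  open→closed vectors at known closed fractions, with slow-exchange peak
  multiplicity from manifold populations, an off-vector perturbation near a
  mutation site, and isotropic Gaussian noise in weighted shift space;
* titration series in which a phosphopeptide captures the open state by
  mass action, shifting the slow-exchange populations toward a distinct
  bound-state peak;
* toy replica trajectories with a condition-dependent tail–core contact
  (two-state telegraph switching), a planted collective stretch mode, and
  side-chain torsion pairs drawn from wrapped bivariate Gaussians with
  condition-dependent correlation.

The geometry is schematic (a few spatially separated atom groups), not a
protein force field; residue numbering reuses the tandem-SH2 segment ranges
(nSH2 545–662, junction 658–668, cSH2 663–756, pre-C-terminus 757–770,
linker 771–778, phosphotyrosine peptide 779–790) so selections read
naturally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .peaks import Peak, PeakList
from .trajectory import Replica, Topology, TrajectoryEnsemble

__all__ = [
    "ConstructTruth",
    "SyntheticTruth",
    "default_truth",
    "gen_peak_lists",
    "gen_titration_series",
    "gen_toy_trajectories",
    "random_exchange_scheme",
    "telegraph_stationary",
    "telegraph_mean_sd",
]

OPEN_REF = "open-ref"
CLOSED_REF = "closed-ref"

# toy-trajectory landmarks (residue ids reuse the tandem-SH2 numbering)
CONTACT_PAIRS = {
    "tail-core": (783, 700),   # condition-dependent rates
    "tail2-core2": (790, 667),  # null pair, identical rates in both conditions
}
MODE_RESIDUES = (660, 661)      # symmetric stretch pair (junction)
DIHEDRAL_RESIDUES = (757, 775, 742)  # (correlated pair) + null residue
CONTACT_ON_DISTANCE = 2.0   # Å, below the 2.5 Å cutoff
CONTACT_OFF_DISTANCE = 5.0  # Å
DIHEDRAL_SIGMA_DEG = 45.0   # wrapped-Gaussian width


@dataclass
class ConstructTruth:
    """Planted parameters of one construct.

    ``populations`` are the slow-exchange manifold weights; ``f`` holds one
    residue → closed-fraction map per manifold; ``off_vector`` gives
    perpendicular displacements (weighted ppm) for residues whose
    perturbation is dominated by a local chemical change.
    """

    populations: tuple[float, ...]
    f: list[dict[int, float]]
    off_vector: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if abs(sum(self.populations) - 1.0) > 1e-12:
            raise ValueError("manifold populations must sum to 1")
        if len(self.f) != len(self.populations):
            raise ValueError("need one closed-fraction map per manifold")
        for fm in self.f:
            for res, fi in fm.items():
                if not 0.0 <= fi <= 1.0:
                    raise ValueError(f"f[{res}]={fi} outside [0,1]")

    def effective_f(self, residue: int) -> float:
        """Population-weighted overall closed fraction of one residue."""
        return sum(p * fm[residue] for p, fm in zip(self.populations, self.f))


@dataclass
class SyntheticTruth:
    """Every planted parameter of a synthetic study, keyed by one seed."""

    residues: list[int]
    delta_o: dict[int, tuple[float, float]]   # (¹H, ¹⁵N) ppm
    delta_c: dict[int, tuple[float, float]]
    delta_op: dict[int, tuple[float, float]]  # bound-state shifts (off-vector)
    constructs: dict[str, ConstructTruth]
    pathway_residues: list[int]               # residues carrying the mutant f shift
    mutant_shift: float                       # planted Δf (mutant − wild type)
    noise_sd: float = 0.005                   # ppm, weighted-space isotropic
    intensity_noise: float = 0.02             # lognormal sd on peak intensities
    alpha: float = 0.14
    ligand_kd_um: float = 10.0
    contact_rates: dict[str, dict[str, tuple[float, float]]] = field(default_factory=dict)
    mode_amplitude: dict[str, float] = field(default_factory=dict)
    dihedral_rho: dict[str, float] = field(default_factory=dict)
    jitter_sd: float = 0.02                   # Å, thermal jitter in trajectories
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if self.ligand_kd_um <= 0:
            raise ValueError("ligand Kd must be > 0")
        for label in (OPEN_REF, CLOSED_REF):
            if label not in self.constructs:
                raise ValueError(f"truth must define the '{label}' construct")
        for name, ct in self.constructs.items():
            for fm in ct.f:
                missing = set(self.residues) - set(fm)
                if missing:
                    raise ValueError(f"construct '{name}' lacks f for {sorted(missing)[:3]}...")

    def weighted_separation(self, residue: int) -> float:
        """|δC − δO| in weighted ppm for one residue."""
        o, c = self.delta_o[residue], self.delta_c[residue]
        return math.hypot(c[0] - o[0], self.alpha * (c[1] - o[1]))


def default_truth(seed: int = 0, n_residues: int = 100) -> SyntheticTruth:
    """The standard planted study: references, four query constructs, rates.

    Open/closed weighted separations are drawn from U(0.1, 0.3) ppm — well
    clear of the 0.005 ppm noise floor, as for well-resolved amide
    crosspeaks.  The wild-type tandem construct carries heterogeneous
    per-residue closed fractions; a two-manifold construct has populations
    (0.7, 0.3); a three-manifold construct (0.5, 0.3, 0.2) with ordered,
    well-separated closed fractions; the mutant shifts pre-C-terminal
    residues 0.35 toward open and displaces one residue off-vector.
    """
    rng = np.random.default_rng(seed)
    # pre-C-terminal reporters are always present: they carry the planted
    # mutant effect and anchor the pathway analyses
    reporters = [757, 760, 761, 765, 766, 770]
    if n_residues < len(reporters) + 4:
        raise ValueError(f"n_residues must be >= {len(reporters) + 4}")
    pool = np.array([r for r in range(545, 791) if r not in reporters])
    residues = sorted(
        reporters
        + rng.choice(pool, size=n_residues - len(reporters), replace=False).tolist()
    )
    alpha = 0.14
    delta_o, delta_c, delta_op = {}, {}, {}
    for res in residues:
        h = rng.uniform(7.0, 9.5)
        n = rng.uniform(105.0, 130.0)
        sep = rng.uniform(0.1, 0.3)  # weighted ppm
        theta = rng.uniform(0, 2 * np.pi)
        w = sep * np.array([np.cos(theta), np.sin(theta)])
        delta_o[res] = (h, n)
        delta_c[res] = (h + w[0], n + w[1] / alpha)
        # bound state: off the O-C axis (perpendicular + slight overshoot)
        perp = np.array([-w[1], w[0]]) / sep
        wp = 1.1 * w + 0.12 * perp
        delta_op[res] = (h + wp[0], n + wp[1] / alpha)

    ones = {r: 1.0 for r in residues}
    zeros = {r: 0.0 for r in residues}
    pathway = [r for r in residues if 757 <= r <= 770]
    # pre-C-terminal residues start with substantial closed character, so the
    # planted open-ward mutant shift is never truncated at the floor
    f_wt = {
        r: float(rng.uniform(0.45, 0.95)) if r in pathway
        else float(rng.uniform(0.05, 0.95))
        for r in residues
    }
    f_lo = {r: float(rng.uniform(0.05, 0.45)) for r in residues}
    f_hi = {r: min(f_lo[r] + float(rng.uniform(0.35, 0.5)), 0.98) for r in residues}
    f3_1 = {r: float(rng.uniform(0.05, 0.2)) for r in residues}
    f3_2 = {r: f3_1[r] + float(rng.uniform(0.3, 0.35)) for r in residues}
    f3_3 = {r: f3_2[r] + float(rng.uniform(0.3, 0.35)) for r in residues}

    mutant_shift = -0.35
    f_mut = dict(f_wt)
    for r in pathway:
        f_mut[r] = max(f_wt[r] + mutant_shift, 0.02)
    off_res = min(pathway, key=lambda r: abs(r - 765)) if pathway else residues[0]

    constructs = {
        OPEN_REF: ConstructTruth((1.0,), [zeros]),
        CLOSED_REF: ConstructTruth((1.0,), [ones]),
        "tandem": ConstructTruth((1.0,), [f_wt]),
        "tandem-2state": ConstructTruth((0.7, 0.3), [f_lo, f_hi]),
        "csh2-3state": ConstructTruth((0.5, 0.3, 0.2), [f3_1, f3_2, f3_3]),
        "mutant": ConstructTruth((1.0,), [f_mut], off_vector={off_res: 0.1}),
    }
    return SyntheticTruth(
        residues=residues,
        delta_o=delta_o,
        delta_c=delta_c,
        delta_op=delta_op,
        constructs=constructs,
        pathway_residues=pathway,
        mutant_shift=mutant_shift,
        ligand_kd_um=10.0,
        contact_rates={
            "apo": {"tail-core": (0.3, 0.7), "tail2-core2": (0.5, 0.5)},
            "phospho": {"tail-core": (0.7, 0.3), "tail2-core2": (0.5, 0.5)},
        },
        mode_amplitude={"apo": 1.0, "phospho": 0.0},
        dihedral_rho={"apo": 0.0, "phospho": 0.8},
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Peak lists
# ---------------------------------------------------------------------------

def _perp_unit(truth: SyntheticTruth, residue: int) -> np.ndarray:
    """Unit vector perpendicular to the O->C axis in weighted space."""
    o, c = truth.delta_o[residue], truth.delta_c[residue]
    w = np.array([c[0] - o[0], truth.alpha * (c[1] - o[1])])
    n = np.linalg.norm(w)
    return np.array([-w[1], w[0]]) / n


def gen_peak_lists(
    truth: SyntheticTruth, constructs: list[str]
) -> dict[str, PeakList]:
    """Generate one peak list per requested construct label.

    Residue i of a construct yields one peak per manifold m at
    (1 − f_{m,i})·δO + f_{m,i}·δC (+ any off-vector offset), with intensity
    proportional to p_m, plus isotropic Gaussian noise of sd ``noise_sd`` in
    weighted shift space.  Reference constructs sit at δO and δC.
    """
    unknown = [c for c in constructs if c not in truth.constructs]
    if unknown:
        raise KeyError(
            f"unknown construct label(s) {unknown}; known: "
            f"{sorted(truth.constructs)}"
        )
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 1]))
    out: dict[str, PeakList] = {}
    for label in constructs:
        ct = truth.constructs[label]
        pl = PeakList(construct=label)
        for res in truth.residues:
            o = np.array(truth.delta_o[res])
            c = np.array(truth.delta_c[res])
            off = ct.off_vector.get(res, 0.0)
            for mi, (p, fm) in enumerate(zip(ct.populations, ct.f)):
                pos = (1.0 - fm[res]) * o + fm[res] * c
                if off:
                    perp = _perp_unit(truth, res)
                    pos = pos + np.array([perp[0], perp[1] / truth.alpha]) * off
                nz = rng.normal(size=2) * truth.noise_sd
                h = pos[0] + nz[0]
                n = pos[1] + nz[1] / truth.alpha
                inten = p
                if truth.intensity_noise > 0:
                    inten = p * math.exp(rng.normal(0.0, truth.intensity_noise))
                pl.add(Peak(residue=res, h_ppm=float(h), n_ppm=float(n),
                            intensity=float(inten), index=mi))
        out[label] = pl
    return out


def gen_titration_series(
    truth: SyntheticTruth,
    ligand_concentrations_um: list[float],
    construct: str = "csh2-3state",
    protein_total_um: float = 100.0,
) -> list[PeakList]:
    """Peak lists along a phosphopeptide titration of one construct.

    Manifold populations at each point follow the mass-action equilibrium of
    :func:`dynallo.exchange.titrate`; a distinct bound-state (O:P) peak at
    δ_OP grows monotonically with ligand and dominates at saturating excess.
    """
    from .exchange import ExchangeScheme, Manifold, titrate

    conc = np.asarray(ligand_concentrations_um, dtype=float)
    if np.any(conc < 0):
        raise ValueError("ligand concentrations must be non-negative")
    if np.any(np.diff(conc) < 0):
        raise ValueError("ligand concentrations must be ascending")
    ct = truth.constructs[construct]
    scheme = ExchangeScheme(
        manifolds=[
            Manifold(label=str(mi + 1), population=p, f=dict(fm))
            for mi, (p, fm) in enumerate(zip(ct.populations, ct.f))
        ],
        delta_o=truth.delta_o,
        delta_c=truth.delta_c,
        delta_op=truth.delta_op,
    )
    table = titrate(scheme, truth.ligand_kd_um, protein_total_um, conc)
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 2]))
    out = []
    for _, row in table.iterrows():
        pl = PeakList(construct=f"{construct}@{row['ligand_total']:g}uM")
        for res in truth.residues:
            o = np.array(truth.delta_o[res])
            c = np.array(truth.delta_c[res])
            idx = 0
            for mi, fm in enumerate(ct.f):
                p = row[f"p_{mi + 1}"]
                if p < 1e-6:
                    continue
                pos = (1.0 - fm[res]) * o + fm[res] * c
                nz = rng.normal(size=2) * truth.noise_sd
                pl.add(Peak(residue=res, h_ppm=float(pos[0] + nz[0]),
                            n_ppm=float(pos[1] + nz[1] / truth.alpha),
                            intensity=float(p), index=idx))
                idx += 1
            if row["p_bound"] >= 1e-6:
                pos = np.array(truth.delta_op[res])
                nz = rng.normal(size=2) * truth.noise_sd
                pl.add(Peak(residue=res, h_ppm=float(pos[0] + nz[0]),
                            n_ppm=float(pos[1] + nz[1] / truth.alpha),
                            intensity=float(row["p_bound"]), index=idx))
        out.append(pl)
    return out


def random_exchange_scheme(rng: np.random.Generator, n_manifolds: int | None = None):
    """A random but well-conditioned exchange scheme for oracle comparisons.

    Manifold populations are floored at 0.15 and closed fractions spaced by
    at least ~0.3, and the open/closed shift separations are large relative
    to the linewidth, so every predicted peak is resolvable in the
    asymptotic fast/slow regimes.
    """
    from .exchange import ExchangeScheme, Manifold

    if n_manifolds is None:
        n_manifolds = int(rng.integers(1, 4))
    while True:
        p = rng.dirichlet(np.ones(n_manifolds))
        if p.min() >= 0.15 or n_manifolds == 1:
            break
    p = p / p.sum()
    centers = np.linspace(0.1, 0.9, n_manifolds)
    f_vals = np.clip(centers + rng.uniform(-0.05, 0.05, n_manifolds), 0.02, 0.98)
    dh = rng.uniform(0.3, 0.6) * rng.choice([-1.0, 1.0])
    dn = rng.uniform(2.0, 4.0) * rng.choice([-1.0, 1.0])
    residue = 1
    return ExchangeScheme(
        manifolds=[
            Manifold(str(i + 1), float(pi), {residue: float(fi)})
            for i, (pi, fi) in enumerate(zip(p, f_vals))
        ],
        delta_o={residue: (8.0, 115.0)},
        delta_c={residue: (8.0 + dh, 115.0 + dn)},
        r2=15.0,
    )


# ---------------------------------------------------------------------------
# Toy trajectories
# ---------------------------------------------------------------------------

def telegraph_stationary(k_on: float, k_off: float, dt_ns: float) -> float:
    """Stationary on-probability of the simulated discrete telegraph chain.

    The chain uses per-frame transition probabilities 1 − exp(−k·dt), so its
    stationary distribution is p01/(p01 + p10) — exact for the sampled grid
    (and → k_on/(k_on + k_off) as dt → 0).
    """
    p01 = 1.0 - math.exp(-k_on * dt_ns)
    p10 = 1.0 - math.exp(-k_off * dt_ns)
    return p01 / (p01 + p10)


def telegraph_mean_sd(k_on: float, k_off: float, dt_ns: float, n_frames: int) -> float:
    """Large-T standard deviation of the time-average of the telegraph chain.

    Var(mean) ≈ π(1−π)/T · (1+λ)/(1−λ) with λ = 1 − p01 − p10 the chain's
    autocorrelation eigenvalue.
    """
    p01 = 1.0 - math.exp(-k_on * dt_ns)
    p10 = 1.0 - math.exp(-k_off * dt_ns)
    pi = p01 / (p01 + p10)
    lam = 1.0 - p01 - p10
    return math.sqrt(pi * (1.0 - pi) / n_frames * (1.0 + lam) / (1.0 - lam))


def _simulate_telegraph(
    rng: np.random.Generator, k_on: float, k_off: float, dt_ns: float,
    n_frames: int, initial: int | None = None,
) -> np.ndarray:
    p01 = 1.0 - math.exp(-k_on * dt_ns)
    p10 = 1.0 - math.exp(-k_off * dt_ns)
    pi = p01 / (p01 + p10) if (p01 + p10) > 0 else 0.0
    state = int(rng.random() < pi) if initial is None else int(initial)
    u = rng.random(n_frames)
    out = np.empty(n_frames, dtype=int)
    for t in range(n_frames):
        out[t] = state
        if state == 0:
            state = 1 if u[t] < p01 else 0
        else:
            state = 0 if u[t] < p10 else 1
    return out


def place_fourth_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, angle_deg: float, torsion_deg: np.ndarray,
) -> np.ndarray:
    """Position atom D so that the torsion A-B-C-D equals ``torsion_deg``.

    Vectorized over torsion values; bond = |C−D|, angle = ∠(B,C,D).
    """
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    theta = math.radians(angle_deg)
    phi = np.radians(np.asarray(torsion_deg, dtype=float))
    d_local = np.stack(
        [
            -bond * math.cos(theta) * np.ones_like(phi),
            bond * math.sin(theta) * np.cos(phi),
            bond * math.sin(theta) * np.sin(phi),
        ],
        axis=-1,
    )
    frame = np.stack([bc, m, n], axis=0)  # rows are the local basis
    return c + d_local @ frame


def _wrap_deg(angles: np.ndarray) -> np.ndarray:
    out = np.mod(angles + 180.0, 360.0) - 180.0
    out[out == -180.0] = 180.0
    return out


def _toy_topology() -> tuple[Topology, dict]:
    """Static scaffold of the toy system plus an index map of the landmarks."""
    names, resids, resnames, elements, coords = [], [], [], [], []

    def add(name, resid, resname, element, xyz):
        names.append(name)
        resids.append(resid)
        resnames.append(resname)
        elements.append(element)
        coords.append(xyz)
        return len(names) - 1

    info: dict = {}
    # contact pair 1: core (three heavy atoms + one H) and a single tail atom
    add("C1", 700, "COR", "C", (0.0, 0.0, 0.0))
    add("C2", 700, "COR", "C", (1.5, 0.0, 0.0))
    add("C3", 700, "COR", "C", (0.0, 1.5, 0.0))
    add("H1", 700, "COR", "H", (0.8, 0.8, 0.5))
    info["tail"] = add("CT", 783, "TAL", "C", (CONTACT_OFF_DISTANCE, 0.0, 0.0))
    # contact pair 2 (null): displaced along y
    add("C1", 667, "CO2", "C", (0.0, 30.0, 0.0))
    info["tail2"] = add("CT", 790, "TA2", "C", (CONTACT_OFF_DISTANCE, 30.0, 0.0))
    # collective mode: symmetric stretch pair (zero net translation/torque)
    info["mode"] = (
        add("CM", MODE_RESIDUES[0], "MOD", "C", (20.0, -20.0, 0.0)),
        add("CM", MODE_RESIDUES[1], "MOD", "C", (26.0, -20.0, 0.0)),
    )
    # torsion residues: four atoms each, D placed per sampled angle
    info["dihedral"] = {}
    for k, res in enumerate(DIHEDRAL_RESIDUES):
        x0 = 40.0 + 20.0 * k
        ia = add("CA", res, "DIH", "C", (x0, 0.0, 20.0))
        ib = add("CB", res, "DIH", "C", (x0 + 1.5, 0.0, 20.0))
        ic = add("CG", res, "DIH", "C", (x0 + 2.0, 1.4, 20.0))
        idd = add("CD", res, "DIH", "C", (x0 + 2.0, 2.0, 21.0))
        info["dihedral"][res] = (ia, ib, ic, idd)
    topo = Topology(
        names=np.array(names),
        resids=np.array(resids),
        resnames=np.array(resnames),
        elements=np.array(elements),
    )
    return topo, {"coords": np.array(coords), **info}


def dihedral_map(topology: Topology) -> dict[int, list[np.ndarray]]:
    """Residue → torsion quadruples for the toy topology's DIH residues."""
    out: dict[int, list[np.ndarray]] = {}
    for res in DIHEDRAL_RESIDUES:
        idx = np.where((topology.resids == res) & (topology.resnames == "DIH"))[0]
        if idx.size == 4:
            out[int(res)] = [idx]
    return out


def gen_toy_trajectories(
    truth: SyntheticTruth,
    n_replicas_per_condition: int = 4,
    n_frames: int = 2000,
    dt_ns: float = 0.1,
) -> tuple[TrajectoryEnsemble, TrajectoryEnsemble]:
    """Toy replica trajectories for the two conditions ("apo", "phospho").

    Plants, per condition: telegraph tail–core contacts at the truth's
    switching rates (events/ns), a collective stretch mode on the junction
    residue pair with condition-dependent amplitude, and wrapped-Gaussian
    torsion pairs with the truth's correlation ρ.  All atoms carry small
    isotropic jitter.
    """
    if n_replicas_per_condition < 2:
        raise ValueError("need >= 2 replicas per condition (t-test filtering)")
    if n_frames < 2:
        raise ValueError("need >= 2 frames")
    if dt_ns <= 0:
        raise ValueError("frame interval must be > 0")
    topo, info = _toy_topology()
    base = info["coords"]
    ensembles = []
    for ci, condition in enumerate(("apo", "phospho")):
        rates = truth.contact_rates[condition]
        amp = truth.mode_amplitude[condition]
        rho = truth.dihedral_rho[condition]
        replicas = []
        for ri in range(n_replicas_per_condition):
            rng = np.random.default_rng(
                np.random.SeedSequence([truth.seed, 3, ci, ri])
            )
            coords = np.repeat(base[np.newaxis], n_frames, axis=0).astype(float)
            coords += rng.normal(0.0, truth.jitter_sd, size=coords.shape)

            for pair, tail_key in (("tail-core", "tail"), ("tail2-core2", "tail2")):
                k_on, k_off = rates[pair]
                states = _simulate_telegraph(rng, k_on, k_off, dt_ns, n_frames)
                dist = np.where(states == 1, CONTACT_ON_DISTANCE, CONTACT_OFF_DISTANCE)
                coords[:, info[tail_key], 0] = dist + rng.normal(
                    0.0, truth.jitter_sd, size=n_frames
                )

            if amp > 0:
                s = rng.normal(0.0, amp, size=n_frames)
                i1, i2 = info["mode"]
                coords[:, i1, 0] += s / 2.0
                coords[:, i2, 0] -= s / 2.0

            # torsions: first two residues correlated, third independent
            z = rng.multivariate_normal(
                [0.0, 0.0], [[1.0, rho], [rho, 1.0]], size=n_frames
            )
            z3 = rng.normal(size=n_frames)
            angles = {
                DIHEDRAL_RESIDUES[0]: _wrap_deg(z[:, 0] * DIHEDRAL_SIGMA_DEG),
                DIHEDRAL_RESIDUES[1]: _wrap_deg(z[:, 1] * DIHEDRAL_SIGMA_DEG),
                DIHEDRAL_RESIDUES[2]: _wrap_deg(z3 * DIHEDRAL_SIGMA_DEG),
            }
            for res, (ia, ib, ic, idd) in info["dihedral"].items():
                coords[:, idd, :] = place_fourth_atom(
                    base[ia], base[ib], base[ic], 1.5, 109.5, angles[res]
                )
            replicas.append(
                Replica(coords=coords, dt_ns=dt_ns, label=f"{condition}-{ri}")
            )
        ensembles.append(
            TrajectoryEnsemble(topology=topo, replicas=replicas, condition=condition)
        )
    return ensembles[0], ensembles[1]
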