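"""Chemical-shift projection analysis on an open⇌closed fast-exchange axis.

For a residue whose crosspeak moves between a reference "open" position δO
(C-terminal tail dissociated from the cSH2 surface) and a reference "closed"
position δC (tail bound), fast exchange places the observed peak at the
population-weighted average

    δ_obs = (1 − f)·δO + f·δC,

so the closed-state population f is read off as the scalar projection of the
observed peak onto the O→C vector in weighted shift space.  Work is done in
weighted coordinates (δH, α·δN) with the standard amide weighting α = 0.14,
so that perpendicular displacement d⊥ is directly comparable to the combined
chemical-shift-perturbation scale.

A peak displaced *off* the O–C vector (large d⊥) cannot be explained by the
two-state population shift — e.g. a residue next to a mutation site whose
perturbation is dominated by the local chemical change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .peaks import Peak, PeakList

__all__ = [
    "composite_shift",
    "ReferenceVectors",
    "build_reference",
    "ProjectionResult",
    "project_peak",
    "closed_fraction_profile",
    "pathway_classification",
    "csp_map",
]

DEFAULT_ALPHA = 0.14
DEFAULT_MIN_SEP = 0.02   # weighted ppm: below this the O–C axis is uninformative
DEFAULT_PERP_TOL = 0.015  # weighted ppm: on-vector tolerance (3× default noise sd)
CLAMP_LO, CLAMP_HI = -0.25, 1.25


def composite_shift(dh: float, dn: float, alpha: float = DEFAULT_ALPHA) -> float:
    """Combined ¹H/¹⁵N shift difference: sqrt(ΔδH² + (α·ΔδN)²) in ppm."""
    if not (math.isfinite(dh) and math.isfinite(dn)):
        raise ValueError("non-finite shift difference")
    return math.hypot(dh, alpha * dn)


def _weighted(peak_or_xy, alpha: float) -> np.ndarray:
    if isinstance(peak_or_xy, Peak):
        return np.array([peak_or_xy.h_ppm, alpha * peak_or_xy.n_ppm])
    h, n = peak_or_xy
    return np.array([h, alpha * n])


@dataclass
class ResidueReference:
    residue: int
    open_hn: tuple[float, float]    # (¹H, ¹⁵N) ppm
    closed_hn: tuple[float, float]
    norm: float                      # |C − O| weighted ppm
    informative: bool


@dataclass
class ReferenceVectors:
    """Per-residue open/closed endpoints defining the fast-exchange axis."""

    alpha: float
    min_sep: float
    entries: dict[int, ResidueReference] = field(default_factory=dict)

    def residues(self) -> list[int]:
        return sorted(self.entries)

    def informative_residues(self) -> list[int]:
        return sorted(r for r, e in self.entries.items() if e.informative)

    def __contains__(self, residue: int) -> bool:
        return residue in self.entries

    def __getitem__(self, residue: int) -> ResidueReference:
        return self.entries[residue]


def build_reference(
    open_list: PeakList,
    closed_list: PeakList,
    min_sep: float = DEFAULT_MIN_SEP,
    alpha: float = DEFAULT_ALPHA,
) -> ReferenceVectors:
    """Build per-residue O/C reference vectors from the two endpoint spectra.

    Only residues present in both lists are kept (major peak per residue);
    residues whose weighted O–C separation falls below ``min_sep`` are
    retained but flagged uninformative.
    """
    shared = sorted(set(open_list.residues()) & set(closed_list.residues()))
    if not shared:
        raise ValueError(
            f"no shared residues between '{open_list.construct}' "
            f"and '{closed_list.construct}'"
        )
    refs = ReferenceVectors(alpha=alpha, min_sep=min_sep)
    for res in shared:
        o = open_list.major_peak(res)
        c = closed_list.major_peak(res)
        norm = float(np.linalg.norm(_weighted(c, alpha) - _weighted(o, alpha)))
        refs.entries[res] = ResidueReference(
            residue=res,
            open_hn=(o.h_ppm, o.n_ppm),
            closed_hn=(c.h_ppm, c.n_ppm),
            norm=norm,
            informative=norm >= min_sep,
        )
    return refs


@dataclass
class ProjectionResult:
    """Projection of one crosspeak onto its residue's O–C axis."""

    residue: int
    construct: str
    peak_index: int
    f: float | None           # clamped closed fraction, None if uninformative
    f_raw: float | None       # unclamped projection coefficient
    d_perp: float | None      # perpendicular offset, weighted ppm
    on_vector: bool
    note: str = ""


def project_peak(
    peak: Peak,
    refs: ReferenceVectors,
    construct: str = "",
    perp_tol: float = DEFAULT_PERP_TOL,
) -> ProjectionResult:
    """Project one peak onto its residue's open→closed vector.

    f̂ = ((q − O)·(C − O)) / |C − O|² in weighted coordinates;
    d⊥ = |q − O − f̂·(C − O)|.  f̂ is clamped to [−0.25, 1.25] with the raw
    value retained so pathological fits stay visible.
    """
    res = peak.residue
    if res not in refs:
        return ProjectionResult(res, construct, peak.index, None, None, None,
                                False, note="residue absent from references")
    entry = refs[res]
    if not entry.informative:
        return ProjectionResult(
            res, construct, peak.index, None, None, None, False,
            note=f"O–C separation {entry.norm:.4f} < min_sep {refs.min_sep:.4f}",
        )
    o = _weighted(entry.open_hn, refs.alpha)
    c = _weighted(entry.closed_hn, refs.alpha)
    q = _weighted(peak, refs.alpha)
    axis = c - o
    f_raw = float(np.dot(q - o, axis) / np.dot(axis, axis))
    d_perp = float(np.linalg.norm(q - o - f_raw * axis))
    f = min(max(f_raw, CLAMP_LO), CLAMP_HI)
    on_vector = d_perp <= perp_tol
    note = "" if on_vector else f"off-vector: d_perp {d_perp:.4f} > tol {perp_tol:.4f}"
    return ProjectionResult(res, construct, peak.index, f, f_raw, d_perp,
                            on_vector, note=note)


def closed_fraction_profile(
    construct: PeakList,
    refs: ReferenceVectors,
    perp_tol: float = DEFAULT_PERP_TOL,
) -> pd.DataFrame:
    """Per-residue closed-fraction profile of a construct (major peaks only).

    Returns one row per informative residue with columns
    ``residue, f, f_raw, d_perp, on_vector``; the frame's ``attrs`` carry the
    profile median and interquartile range.  Residue-to-residue heterogeneity
    of f is expected — a single construct-wide two-state constant is not
    assumed.
    """
    rows = []
    for res in construct.residues():
        if res not in refs or not refs[res].informative:
            continue
        peak = construct.major_peak(res)
        pr = project_peak(peak, refs, construct=construct.construct,
                          perp_tol=perp_tol)
        if pr.f is None:
            continue
        rows.append({"residue": res, "f": pr.f, "f_raw": pr.f_raw,
                     "d_perp": pr.d_perp, "on_vector": pr.on_vector})
    out = pd.DataFrame(rows, columns=["residue", "f", "f_raw", "d_perp", "on_vector"])
    if len(out):
        out.attrs["median_f"] = float(out["f"].median())
        out.attrs["iqr_f"] = float(out["f"].quantile(0.75) - out["f"].quantile(0.25))
    else:
        out.attrs["median_f"] = float("nan")
        out.attrs["iqr_f"] = float("nan")
    return out


def pathway_classification(
    peak_query: Peak,
    peak_closed: Peak,
    peak_open: Peak,
    alpha: float = DEFAULT_ALPHA,
    min_sep: float = DEFAULT_MIN_SEP,
    lower: float = 0.25,
    upper: float = 0.75,
) -> tuple[float, str]:
    """Classify allosteric communication as linker-dependent or -independent.

    The query is the peak of the truncated construct saturated with free
    phosphopeptide; the closed/open anchors are the covalently
    phosphorylated and the truncated apo constructs.  The score is the
    scalar projection of (query − open) onto (closed − open), normalized by
    |closed − open|²: near 1 the phosphopeptide alone reproduces the closed
    perturbation (tail-linker-independent pathway); near 0 it does not
    (linker-dependent).  The sign is preserved, so opposite-direction shifts
    along the axis report score < 0.
    """
    o = _weighted(peak_open, alpha)
    c = _weighted(peak_closed, alpha)
    q = _weighted(peak_query, alpha)
    axis = c - o
    sep = float(np.linalg.norm(axis))
    if sep < min_sep:
        return float("nan"), "unclassifiable"
    score = float(np.dot(q - o, axis) / np.dot(axis, axis))
    if score >= upper:
        label = "linker-independent"
    elif score <= lower:
        label = "linker-dependent"
    else:
        label = "mixed"
    return score, label


def csp_map(
    list_a: PeakList,
    list_b: PeakList,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Per-residue combined CSP between two constructs (major peaks).

    Residues missing from either list are reported with status ``no-data``
    rather than dropped, so sparsely assigned regions stay visible.
    """
    residues = sorted(set(list_a.residues()) | set(list_b.residues()))
    rows = []
    for res in residues:
        a = list_a.major_peak(res)
        b = list_b.major_peak(res)
        if a is None or b is None:
            rows.append({"residue": res, "csp": float("nan"), "status": "no-data"})
            continue
        csp = composite_shift(b.h_ppm - a.h_ppm, b.n_ppm - a.n_ppm, alpha=alpha)
        rows.append({"residue": res, "csp": csp, "status": "ok"})
    return pd.DataFrame(rows, columns=["residue", "csp", "status"])
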