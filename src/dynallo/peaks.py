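"""Peak lists for 2D ¹H,¹⁵N correlation spectra.

A :class:`PeakList` holds the crosspeak centroids for one protein construct:
one or more peaks per residue, each with amide ¹H and ¹⁵N chemical shifts
(ppm) and a relative intensity.  Multiple peaks per residue encode slow
exchange between sub-states; the most intense peak of a residue is its
"major" peak.

The on-disk format is the Sparky peak-list dialect: a whitespace-delimited
table with an ``Assignment  w1  w2  Data Height`` header where ``w1`` is the
¹⁵N shift and ``w2`` the ¹H shift, and the assignment string looks like
``G777N-H``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

__all__ = ["Peak", "PeakList", "read_sparky", "write_sparky"]

# e.g. "G777N-H", "T660N-H", "777N-H", "Gly777N-H"
_ASSIGNMENT_RE = re.compile(r"^([A-Za-z]*?)(\d+)(?:N(?:-?HN?)?)?$")


@dataclass(frozen=True)
class Peak:
    """One crosspeak: residue id, shifts in ppm, relative intensity."""

    residue: int
    h_ppm: float
    n_ppm: float
    intensity: float = 1.0
    index: int = 0  # peak index within residue (0 = first listed)
    resname: str = "X"  # one-letter residue type, cosmetic

    def __post_init__(self) -> None:
        import math

        if not (math.isfinite(self.h_ppm) and math.isfinite(self.n_ppm)):
            raise ValueError(f"non-finite shift for residue {self.residue}")
        if self.intensity <= 0:
            raise ValueError(f"intensity must be > 0 (residue {self.residue})")

    @property
    def assignment(self) -> str:
        return f"{self.resname}{self.residue}N-H"


@dataclass
class PeakList:
    """Crosspeaks of one construct; (residue, index) pairs are unique."""

    construct: str
    peaks: list[Peak] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for p in self.peaks:
            key = (p.residue, p.index)
            if key in seen:
                raise ValueError(f"duplicate peak key {key} in '{self.construct}'")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    def residues(self) -> list[int]:
        return sorted({p.residue for p in self.peaks})

    def by_residue(self, residue: int) -> list[Peak]:
        """All peaks of a residue, most intense first (ties: lowest index)."""
        sub = [p for p in self.peaks if p.residue == residue]
        return sorted(sub, key=lambda p: (-p.intensity, p.index))

    def major_peak(self, residue: int) -> Peak | None:
        """The most intense crosspeak of a residue, or None if absent."""
        sub = self.by_residue(residue)
        return sub[0] if sub else None

    def add(self, peak: Peak) -> None:
        if any(p.residue == peak.residue and p.index == peak.index for p in self.peaks):
            raise ValueError(f"duplicate peak key {(peak.residue, peak.index)}")
        self.peaks.append(peak)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "residue": [p.residue for p in self.peaks],
                "index": [p.index for p in self.peaks],
                "h_ppm": [p.h_ppm for p in self.peaks],
                "n_ppm": [p.n_ppm for p in self.peaks],
                "intensity": [p.intensity for p in self.peaks],
            }
        )

    # -- Sparky dialect IO ------------------------------------------------

    def write(self, path: str | Path) -> None:
        write_sparky(self, path)

    @classmethod
    def read(cls, path: str | Path, construct: str | None = None) -> "PeakList":
        return read_sparky(path, construct=construct)


def parse_assignment(text: str) -> tuple[str, int]:
    """Split an assignment like ``G777N-H`` into (resname, residue number)."""
    m = _ASSIGNMENT_RE.match(text.strip())
    if m is None:
        raise ValueError(f"cannot parse assignment {text!r}")
    resname = m.group(1) or "X"
    return resname, int(m.group(2))


def read_sparky(path: str | Path, construct: str | None = None) -> PeakList:
    """Read a Sparky-dialect peak list (w1 = ¹⁵N, w2 = ¹H).

    Peak indices within a residue follow order of appearance in the file.
    """
    path = Path(path)
    peaks: list[Peak] = []
    counts: dict[int, int] = {}
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.lower().startswith("assignment"):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"malformed peak row: {line!r}")
            resname, residue = parse_assignment(parts[0])
            n_ppm = float(parts[1])
            h_ppm = float(parts[2])
            intensity = float(parts[3]) if len(parts) > 3 else 1.0
            idx = counts.get(residue, 0)
            counts[residue] = idx + 1
            peaks.append(
                Peak(residue=residue, h_ppm=h_ppm, n_ppm=n_ppm,
                     intensity=intensity, index=idx, resname=resname)
            )
    return PeakList(construct=construct or path.stem, peaks=peaks)


def write_sparky(peaklist: PeakList, path: str | Path) -> None:
    """Write a peak list; shifts at 1e-4 ppm precision (round-trip safe)."""
    path = Path(path)
    lines = [f"{'Assignment':>12s} {'w1':>10s} {'w2':>10s} {'Data Height':>14s}"]
    ordered = sorted(peaklist.peaks, key=lambda p: (p.residue, p.index))
    for p in ordered:
        lines.append(
            f"{p.assignment:>12s} {p.n_ppm:10.4f} {p.h_ppm:10.4f} {p.intensity:14.6g}"
        )
    path.write_text("\n".join(lines) + "\n")
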