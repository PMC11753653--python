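"""Charge-density and electrostatic-potential profiles of bilayer frames.

A hydrated bilayer configuration is represented as a :class:`ParticleFrame`
(positions in nm, per-particle charges in units of e, species labels, and
an orthorhombic periodic box).  The electrostatic potential along the
membrane normal is obtained from the Poisson equation by integrating the
slice-binned charge density twice,

    φ(z) = −(1/ε₀) ∬₀^z ρ(z″) dz″ dz′,

in reduced units (ε₀ = 1, charge in e, length in nm) with the gauge
φ(0) = 0 at the lower box edge.  The transmembrane potential Δφ is the
difference of the mean potential between two bulk-water regions on either
side of the membrane.  No periodic or dipole correction is applied; for a
frame with a net dipole the potential at the two box edges differs, which
is accepted, not corrected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "ParticleFrame",
    "AxisProfile",
    "read_frame",
    "write_frame",
    "read_pdb",
    "read_gro",
    "charge_density_profile",
    "potential_profile",
    "transmembrane_potential",
    "leaflet_bounds",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Frame container and I/O
# ---------------------------------------------------------------------------


@dataclass
class ParticleFrame:
    """One particle configuration: positions (nm), charges (e), labels, box.

    Coordinates are wrapped into [0, L) per axis on construction.
    """

    positions: np.ndarray  # (N, 3) nm
    charges: np.ndarray  # (N,) e
    labels: np.ndarray  # (N,) str
    box: np.ndarray  # (3,) nm
    time: float | None = None  # ns

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.charges = np.asarray(self.charges, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        self.box = np.asarray(self.box, dtype=float)
        n = self.positions.shape[0]
        if self.positions.shape != (n, 3):
            raise ValueError("positions must be (N, 3)")
        if len(self.charges) != n or len(self.labels) != n:
            raise ValueError("positions, charges and labels must have equal length")
        if self.box.shape != (3,) or (self.box <= 0).any():
            raise ValueError("box must be three positive edge lengths")
        # wrap into [0, L); particles exactly at L go to 0
        self.positions = np.mod(self.positions, self.box)

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]

    def total_charge(self) -> float:
        return float(self.charges.sum())

    def select(self, mask: np.ndarray) -> "ParticleFrame":
        return ParticleFrame(
            self.positions[mask], self.charges[mask], self.labels[mask],
            self.box.copy(), self.time,
        )

    def translated(self, shift) -> "ParticleFrame":
        """Rigidly translate all particles (re-wrapped into the box)."""
        return ParticleFrame(
            self.positions + np.asarray(shift, dtype=float),
            self.charges.copy(), self.labels.copy(), self.box.copy(), self.time,
        )


def write_frame(frame: ParticleFrame, path: str | Path) -> None:
    """Write a frame in the native columnar text format.

    Floats are written with shortest round-trip repr so read/write is
    bit-exact.
    """
    lines = ["# pulsepore frame v1"]
    lines.append(f"time {frame.time!r}" if frame.time is not None else "time none")
    lines.append("box " + " ".join(repr(float(v)) for v in frame.box))
    for pos, q, lab in zip(frame.positions, frame.charges, frame.labels):
        lines.append(
            f"{float(pos[0])!r} {float(pos[1])!r} {float(pos[2])!r} {float(q)!r} {lab}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_frame(path: str | Path) -> ParticleFrame:
    """Read a frame from the native columnar text format."""
    lines = [ln for ln in Path(path).read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    if len(lines) < 2:
        raise ValueError(f"{path}: not a frame file")
    time_tok = lines[0].split(None, 1)
    if time_tok[0] != "time":
        raise ValueError(f"{path}: expected 'time' line, got {lines[0]!r}")
    t = None if time_tok[1].strip() == "none" else float(time_tok[1])
    box_tok = lines[1].split()
    if box_tok[0] != "box":
        raise ValueError(f"{path}: expected 'box' line, got {lines[1]!r}")
    box = np.array([float(v) for v in box_tok[1:4]])
    pos, chg, lab = [], [], []
    for ln in lines[2:]:
        parts = ln.split()
        pos.append([float(parts[0]), float(parts[1]), float(parts[2])])
        chg.append(float(parts[3]))
        lab.append(parts[4])
    return ParticleFrame(np.array(pos), np.array(chg), np.array(lab, dtype=object), box, t)


def _frame_from_universe(u, charge_map: dict[str, float]) -> ParticleFrame:
    labels = np.array([a.name for a in u.atoms], dtype=object)
    unmapped = sorted(set(labels) - set(charge_map))
    if unmapped:
        raise ValueError(f"charge map does not cover labels: {unmapped}")
    charges = np.array([charge_map[l] for l in labels], dtype=float)
    box = np.asarray(u.dimensions[:3], dtype=float) / 10.0  # Å → nm
    positions = np.asarray(u.atoms.positions, dtype=float) / 10.0
    return ParticleFrame(positions, charges, labels, box)


def read_pdb(path: str | Path, charge_map: dict[str, float]) -> ParticleFrame:
    """Read a PDB structure as a frame; charges come from the label map.

    PDB carries no partial charges, so ``charge_map`` must assign one per
    atom-name label (an unmapped label raises, naming it).
    """
    import MDAnalysis as mda

    u = mda.Universe(str(path))
    return _frame_from_universe(u, charge_map)


def read_gro(path: str | Path, charge_map: dict[str, float]) -> ParticleFrame:
    """Read a GRO structure as a frame; charges come from the label map."""
    import MDAnalysis as mda

    u = mda.Universe(str(path))
    return _frame_from_universe(u, charge_map)


# ---------------------------------------------------------------------------
# Axis profiles
# ---------------------------------------------------------------------------


@dataclass
class AxisProfile:
    """A binned quantity along the membrane normal.

    ``kind`` is ``charge_density`` (e·nm⁻³) or ``potential`` (reduced
    units); bins are uniform and half-open [edge_i, edge_{i+1}).
    Potential profiles carry the gauge constant phi0 = 0 (the value at
    the lower box edge) and eps0 = 1 as metadata.
    """

    axis: int
    bin_edges: np.ndarray
    values: np.ndarray
    kind: str
    phi0: float = 0.0
    eps0: float = 1.0

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.bin_edges) - 1:
            raise ValueError("values must have one entry per bin")
        widths = np.diff(self.bin_edges)
        if np.ptp(widths) > 1e-12:
            raise ValueError("bins must be uniform")
        if self.kind not in ("charge_density", "potential"):
            raise ValueError(f"unknown profile kind {self.kind!r}")

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        with open(path, "w") as fh:
            fh.write(f"# kind={self.kind} axis={self.axis} bin_width={self.bin_width!r}\n")
            pd.DataFrame(
                {"bin_center": self.bin_centers, "value": self.values}
            ).to_csv(fh, index=False)


def charge_density_profile(
    frame: ParticleFrame, bin_width: float = 0.1, axis: int = 2
) -> AxisProfile:
    """Charge density ρ(z): summed charge per slice / slice volume.

    If ``bin_width`` does not divide the box edge to one part in 10⁶ the
    grid stops short of the box edge and particles beyond the last edge
    are counted into the last bin (logged warning).  The integral of the
    profile over the box cross-section recovers the total frame charge.
    """
    if frame.n_particles == 0:
        raise ValueError("empty frame")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    L = float(frame.box[axis])
    area = float(np.prod(frame.box)) / L
    nbins = int(np.floor(L / bin_width + 1e-9))
    if nbins < 1:
        raise ValueError("bin_width exceeds the box edge")
    if abs(nbins * bin_width - L) > 1e-6 * L:
        logger.warning(
            "bin_width %g does not divide box edge %g; last bin truncated at %g",
            bin_width, L, nbins * bin_width,
        )
    edges = np.arange(nbins + 1) * bin_width
    z = frame.positions[:, axis]
    idx = np.minimum((z / bin_width).astype(int), nbins - 1)
    values = np.bincount(idx, weights=frame.charges, minlength=nbins)
    values /= area * bin_width
    return AxisProfile(axis=axis, bin_edges=edges, values=values, kind="charge_density")


def potential_profile(density: AxisProfile) -> AxisProfile:
    """Electrostatic potential by double cumulative integration of ρ(z).

    Two successive cumulative sums of bin value × bin width (midpoint
    rule, exact for piecewise-constant densities); φ(0) = 0 by the gauge
    convention, ε₀ = 1.  Values are the potential at the *upper* edge of
    each bin.  The operation is linear: the profile of a sum of densities
    is the sum of the individual profiles.
    """
    if density.kind != "charge_density":
        raise ValueError("potential_profile expects a charge_density profile")
    dz = density.bin_width
    efield = np.cumsum(density.values) * dz  # ∫ρ: field/ε₀ at upper bin edges
    phi = -np.cumsum(efield) * dz  # second integration
    return AxisProfile(
        axis=density.axis, bin_edges=density.bin_edges.copy(), values=phi,
        kind="potential", phi0=0.0, eps0=1.0,
    )


def transmembrane_potential(
    potential: AxisProfile,
    water_region_lower: tuple[float, float],
    water_region_upper: tuple[float, float],
    membrane_bounds: tuple[float, float] | None = None,
) -> float:
    """Δφ = mean potential over the upper water region − over the lower.

    Both regions are z-intervals that must lie in bulk water; when the
    leaflet bounds are supplied, a region overlapping the membrane slab
    raises.
    """
    lo1, hi1 = map(float, water_region_lower)
    lo2, hi2 = map(float, water_region_upper)
    if not (lo1 < hi1 and lo2 < hi2):
        raise ValueError("regions must satisfy lower < upper")
    if hi1 > lo2:
        raise ValueError("lower region must lie below upper region")
    if membrane_bounds is not None:
        mlo, mhi = membrane_bounds
        for (lo, hi) in ((lo1, hi1), (lo2, hi2)):
            if lo < mhi and hi > mlo:
                raise ValueError(
                    f"water region ({lo}, {hi}) overlaps the membrane slab "
                    f"({mlo}, {mhi})"
                )

    def region_mean(lo: float, hi: float) -> float:
        centers = potential.bin_centers
        mask = (centers >= lo) & (centers <= hi)
        if not mask.any():
            raise ValueError(f"no bins inside region ({lo}, {hi})")
        return float(potential.values[mask].mean())

    return region_mean(lo2, hi2) - region_mean(lo1, hi1)


def leaflet_bounds(
    frame: ParticleFrame,
    head_label: str = "HEAD",
    axis: int = 2,
    min_separation: float = 0.5,
) -> tuple[float, float]:
    """Mean z of each leaflet's headgroup layer, by 1-D 2-means on z.

    Head particles are those whose label starts with ``head_label``
    (matching both HEAD+ and HEAD− by default).  The two clusters are
    found by Lloyd iterations initialised at the z extremes; if the
    resulting means are closer than ``min_separation`` nm the frame is
    not a two-leaflet membrane and an error advises supplying bounds
    manually.
    """
    mask = np.array([str(l).startswith(head_label) for l in frame.labels])
    z = frame.positions[mask, axis]
    if len(z) < 2:
        raise ValueError(f"need at least 2 particles labeled {head_label}*")
    c_lo, c_hi = float(z.min()), float(z.max())
    for _ in range(200):
        assign_hi = np.abs(z - c_hi) < np.abs(z - c_lo)
        if assign_hi.all() or (~assign_hi).all():
            raise ValueError(
                "headgroups form a single layer; supply leaflet bounds manually"
            )
        new_lo, new_hi = float(z[~assign_hi].mean()), float(z[assign_hi].mean())
        if new_lo == c_lo and new_hi == c_hi:
            break
        c_lo, c_hi = new_lo, new_hi
    if c_hi - c_lo < min_separation:
        raise ValueError(
            f"leaflet separation {c_hi - c_lo:.3f} nm < {min_separation} nm; "
            "supply leaflet bounds manually"
        )
    return (c_lo, c_hi) if c_lo < c_hi else (c_hi, c_lo)
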