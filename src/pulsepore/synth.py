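"""Synthetic inputs with known ground truth for the analysis pipeline.

Three generators, all fully deterministic under a single integer seed:

* :func:`make_bilayer_frame` — an idealized two-leaflet lipid slab:
  pseudo-lipids (one ± charged head pair per lipid, neutral tail beads)
  on a jittered lattice, bulk water on both sides, and optional planted
  transmembrane cylindrical water pores.  The ground-truth record carries
  the exact leaflet planes and pore geometry so every downstream metric
  can be checked by parameter recovery.
* :func:`make_charged_slab_frame` — two oppositely charged parallel
  sheets of scattered point charges, the closed-form oracle for the
  potential profile (|Δφ| = σ·d for a parallel plate in reduced units).
* :func:`make_pef_response_dataset` — a generative pulse→response model
  emulating the statistical structure of the electro-poration/fusion
  experiment: pulse strength above a threshold sets the number of pores,
  pulse width sets the large-pore fraction, the two dye-positive rates
  saturate on those latents, and the fusion rate is linear in the rates
  with the large-pore (PI) coefficient dominant.

These generators fabricate test geometry and statistics, never physics:
no water structure, lipid dynamics, or field-driven time evolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fields import ParticleFrame
from .pls import SampleTable

__all__ = [
    "BilayerSpec",
    "ResponseSpec",
    "make_bilayer_frame",
    "make_charged_slab_frame",
    "make_pef_response_dataset",
]

_HEAD_OFFSET = 0.05  # nm, half-separation of the ± head charge pair
_TAIL_SPACING = 0.25  # nm, spacing of tail beads toward the midplane
_WATER_MARGIN = 0.4  # nm, gap between leaflet plane and bulk water slabs


@dataclass
class BilayerSpec:
    """Geometry and composition of a synthetic hydrated bilayer."""

    box: tuple[float, float, float] = (8.0, 8.0, 10.0)
    leaflet_z: tuple[float, float] = (4.0, 7.0)
    lipids_per_leaflet: int = 256
    head_charges: tuple[float, float] = (0.5, -0.5)
    tail_beads: int = 3
    water_density: float = 33.3  # nm^-3
    pores: list[tuple[tuple[float, float], float]] = field(default_factory=list)
    jitter_sd: float = 0.03  # nm
    seed: int = 0

    def validate(self) -> None:
        Lx, Ly, Lz = self.box
        zl, zu = self.leaflet_z
        if not (0 < zl < zu < Lz):
            raise ValueError("leaflet planes must lie inside the box, lower first")
        if self.water_density <= 0:
            raise ValueError("water_density must be positive")
        if abs(self.head_charges[0] + self.head_charges[1]) > 1e-12:
            raise ValueError("head charges must be an equal/opposite pair")
        rmax = min(Lx, Ly) / 4
        for (cx, cy), r in self.pores:
            if r >= rmax:
                raise ValueError(f"pore radius {r} must be < min(Lx,Ly)/4 = {rmax}")
        for i, ((c1, r1)) in enumerate(self.pores):
            for (c2, r2) in self.pores[i + 1 :]:
                dx = _min_image(c1[0] - c2[0], Lx)
                dy = _min_image(c1[1] - c2[1], Ly)
                if np.hypot(dx, dy) < r1 + r2:
                    raise ValueError(f"overlapping pores at {c1} and {c2}")


def _min_image(d: float, L: float) -> float:
    return d - L * np.round(d / L)


def _in_any_pore(x, y, pores, Lx, Ly):
    inside = np.zeros(len(x), dtype=bool)
    for (cx, cy), r in pores:
        dx = x - cx - Lx * np.round((x - cx) / Lx)
        dy = y - cy - Ly * np.round((y - cy) / Ly)
        inside |= dx * dx + dy * dy <= r * r
    return inside


def make_bilayer_frame(
    spec: BilayerSpec, time: float | None = None
) -> tuple[ParticleFrame, dict]:
    """Build one bilayer configuration plus its ground-truth record.

    Each pseudo-lipid is a charged head pair at ±0.05 nm about its
    leaflet plane (labels HEAD+/HEAD−) and neutral TAIL beads toward the
    midplane, on a square lattice with Gaussian positional jitter.  Bulk
    WATER fills both sides of the membrane at ``water_density``; for each
    planted pore the lipids inside the cylinder are removed and the
    cylinder is filled with water at the same density.  Net frame charge
    is zero by construction.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    Lx, Ly, Lz = spec.box
    zl, zu = spec.leaflet_z
    q_plus, q_minus = spec.head_charges

    pos_list, chg_list, lab_list = [], [], []

    side = int(np.ceil(np.sqrt(spec.lipids_per_leaflet)))
    sx, sy = Lx / side, Ly / side
    lattice = np.array(
        [((i + 0.5) * sx, (j + 0.5) * sy) for i in range(side) for j in range(side)]
    )[: spec.lipids_per_leaflet]

    n_lipids_kept = 0
    for plane, inward in ((zl, +1.0), (zu, -1.0)):
        keep = ~_in_any_pore(lattice[:, 0], lattice[:, 1], spec.pores, Lx, Ly)
        xy = lattice[keep]
        n_lipids_kept += len(xy)
        for x0, y0 in xy:
            # head pair straddling the leaflet plane, + outward
            for dz, q, lab in (
                (-inward * _HEAD_OFFSET, q_plus, "HEAD+"),
                (+inward * _HEAD_OFFSET, q_minus, "HEAD-"),
            ):
                pos_list.append((x0, y0, plane + dz))
                chg_list.append(q)
                lab_list.append(lab)
            for k in range(1, spec.tail_beads + 1):
                pos_list.append((x0, y0, plane + inward * k * _TAIL_SPACING))
                chg_list.append(0.0)
                lab_list.append("TAIL")

    pos = np.asarray(pos_list, dtype=float)
    if spec.jitter_sd > 0:
        pos += rng.normal(0.0, spec.jitter_sd, pos.shape)

    positions = [pos]
    charges = [np.asarray(chg_list)]
    labels = [np.asarray(lab_list, dtype=object)]

    def add_water(n: int, sampler) -> int:
        n = int(n)
        if n <= 0:
            return 0
        positions.append(sampler(n))
        charges.append(np.zeros(n))
        labels.append(np.full(n, "WATER", dtype=object))
        return n

    water_counts = {}
    # bulk slabs below and above the membrane
    for name, (z0, z1) in (
        ("lower_bulk", (0.0, zl - _WATER_MARGIN)),
        ("upper_bulk", (zu + _WATER_MARGIN, Lz)),
    ):
        vol = Lx * Ly * max(0.0, z1 - z0)
        water_counts[name] = add_water(
            round(spec.water_density * vol),
            lambda n, z0=z0, z1=z1: np.column_stack(
                [rng.uniform(0, Lx, n), rng.uniform(0, Ly, n), rng.uniform(z0, z1, n)]
            ),
        )
    # planted pore cylinders spanning the leaflet gap
    pore_water = []
    for (cx, cy), r in spec.pores:
        n = round(spec.water_density * np.pi * r * r * (zu - zl))

        def cyl(n, cx=cx, cy=cy, r=r):
            rad = r * np.sqrt(rng.uniform(0, 1, n))
            ang = rng.uniform(0, 2 * np.pi, n)
            return np.column_stack(
                [cx + rad * np.cos(ang), cy + rad * np.sin(ang), rng.uniform(zl, zu, n)]
            )

        pore_water.append(add_water(n, cyl))

    frame = ParticleFrame(
        np.vstack(positions), np.concatenate(charges),
        np.concatenate(labels), np.asarray(spec.box), time,
    )
    ground_truth = {
        "leaflet_z": (zl, zu),
        "pores": [{"center": list(c), "radius": r} for c, r in spec.pores],
        "pore_water_counts": pore_water,
        "bulk_water_counts": water_counts,
        "n_lipids": n_lipids_kept,
        "water_density": spec.water_density,
        "seed": spec.seed,
    }
    return frame, ground_truth


def make_charged_slab_frame(
    sigma: float,
    separation: float,
    box: tuple[float, float, float] = (10.0, 10.0, 10.0),
    particles_per_sheet: int = 400,
    seed: int = 0,
) -> ParticleFrame:
    """Two parallel sheets of scattered point charges, ±σ (e·nm⁻²).

    The +σ sheet sits at z = (Lz − separation)/2 and the −σ sheet at
    z = (Lz + separation)/2; per-particle charge is σ·Lx·Ly/n so the
    planted surface density is exact regardless of discretization.
    """
    Lx, Ly, Lz = box
    if not 0 < separation < Lz / 2:
        raise ValueError("separation must be in (0, Lz/2)")
    if particles_per_sheet < 1:
        raise ValueError("particles_per_sheet must be >= 1")
    rng = np.random.default_rng(seed)
    q = sigma * Lx * Ly / particles_per_sheet
    z_lo, z_hi = (Lz - separation) / 2, (Lz + separation) / 2
    pos, chg, lab = [], [], []
    for z_sheet, sign, name in ((z_lo, +1.0, "SHEET+"), (z_hi, -1.0, "SHEET-")):
        x = rng.uniform(0, Lx, particles_per_sheet)
        y = rng.uniform(0, Ly, particles_per_sheet)
        pos.append(np.column_stack([x, y, np.full(particles_per_sheet, z_sheet)]))
        chg.append(np.full(particles_per_sheet, sign * q))
        lab.extend([name] * particles_per_sheet)
    return ParticleFrame(
        np.vstack(pos), np.concatenate(chg), np.asarray(lab, dtype=object), np.asarray(box)
    )


# ---------------------------------------------------------------------------
# Generative PEF → (YP, PI) → fusion dataset
# ---------------------------------------------------------------------------


@dataclass
class ResponseSpec:
    """Parameters of the generative pulse-response model.

    Latents: pore number N = a_N·max(0, E − E_threshold); large-pore
    fraction S = logistic(a_S·(log10 w − width_log10_mid)).  Dye-positive
    rates saturate on the latents through the shifted logistic
    100·(2·logistic(x) − 1), which is 0 at x = 0 and → 100; the fusion
    rate is β₀ + β_small·yp + β_large·pi with β_large > β_small in the
    default preset (the large-pore channel dominates fusion).  Gaussian
    noise is added per response, then yp/pi are clipped to [0, 100] and
    fusion to ≥ 0.
    """

    strength_grid: tuple[float, ...] = (0.0, 0.4, 0.8, 1.2, 1.6, 2.0, 2.4)  # kV/cm
    width_grid: tuple[float, ...] = (200.0, 1000.0, 10000.0, 40000.0)  # ns
    E_threshold: float = 0.2  # kV/cm
    a_N: float = 2.0  # pores per kV/cm above threshold
    a_S: float = 2.0  # logistic steepness on log10(width)
    width_log10_mid: float = 3.5  # log10 ns at which S = 1/2
    k_y: float = 0.6  # YP saturation rate on N
    k_p: float = 0.55  # PI saturation rate on N·S
    beta0: float = 0.3  # baseline fusion %
    beta_small: float = 0.02  # fusion per YP %
    beta_large: float = 0.12  # fusion per PI %
    yp_noise_sd: float = 3.0
    pi_noise_sd: float = 3.0
    fusion_noise_sd: float = 0.5
    replicates: int = 1
    seed: int = 0

    def validate(self) -> None:
        if not self.strength_grid or not self.width_grid:
            raise ValueError("strength_grid and width_grid must be non-empty")
        for name in ("yp_noise_sd", "pi_noise_sd", "fusion_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.beta_large <= self.beta_small:
            raise ValueError("preset requires beta_large > beta_small")


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def _saturating_rate(x):
    """Shifted logistic: 0 at x=0, asymptote 100."""
    return 100.0 * (2.0 * _logistic(x) - 1.0)


def make_pef_response_dataset(spec: ResponseSpec) -> tuple[SampleTable, dict]:
    """Sample a synthetic PEF response table plus its ground truth.

    One row per (width, strength) grid point and replicate, with role
    ``unassigned``.  The ground-truth record stores the per-row latents
    and noiseless responses plus every generative coefficient, so tests
    can check that the fitted PLS recovers the planted β ordering
    (weight for PI above weight for YP) and that the noiseless responses
    are monotone in pulse strength.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rows = []
    latents = []
    for rep in range(spec.replicates):
        for w in spec.width_grid:
            for E in spec.strength_grid:
                N = spec.a_N * max(0.0, E - spec.E_threshold)
                S = float(_logistic(spec.a_S * (np.log10(w) - spec.width_log10_mid)))
                yp0 = float(_saturating_rate(spec.k_y * N))
                pi0 = float(_saturating_rate(spec.k_p * N * S))
                fus0 = spec.beta0 + spec.beta_small * yp0 + spec.beta_large * pi0
                yp = float(np.clip(yp0 + rng.normal(0, spec.yp_noise_sd), 0, 100))
                pi = float(np.clip(pi0 + rng.normal(0, spec.pi_noise_sd), 0, 100))
                fus = float(max(0.0, fus0 + rng.normal(0, spec.fusion_noise_sd)))
                sid = f"synth_W_{w:g}ns_E_{E:g}" + (f"_r{rep}" if spec.replicates > 1 else "")
                rows.append(
                    {
                        "sample_id": sid, "pulse_width_ns": w,
                        "field_strength_kv_cm": E, "yp_rate": yp, "pi_rate": pi,
                        "fusion_rate": fus, "role": "unassigned",
                    }
                )
                latents.append(
                    {"sample_id": sid, "N": N, "S": S, "yp_noiseless": yp0,
                     "pi_noiseless": pi0, "fusion_noiseless": fus0}
                )
    table = SampleTable(pd.DataFrame(rows))
    ground_truth = {
        "coefficients": {
            "E_threshold": spec.E_threshold, "a_N": spec.a_N, "a_S": spec.a_S,
            "width_log10_mid": spec.width_log10_mid, "k_y": spec.k_y,
            "k_p": spec.k_p, "beta0": spec.beta0,
            "beta_small": spec.beta_small, "beta_large": spec.beta_large,
        },
        "latents": latents,
        "seed": spec.seed,
    }
    return table, ground_truth
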