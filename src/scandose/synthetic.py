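"""Synthetic study inputs: time-activity datasets and voxel phantoms.

The generators produce every input the pipeline consumes, with the
statistical structure the analysis assumes, so all stages are testable
without external data:

* organ time-activity curves are two-term exponential sums whose dominant
  *effective* half-life (biological clearance plus the Lu-177 physical
  decay) is drawn from the 50–80 h band typical of parenchymal organs in
  lutetium-177 DOTATATE therapy, sampled at the 4/24/168 h acquisition
  schedule with multiplicative log-normal measurement noise;
* phantoms are water-density bodies containing non-overlapping ellipsoidal
  organs (liver, spleen, left/right kidney, a single-ellipsoid red-marrow
  surrogate) with the rest of the body as remainder.

Everything is deterministic given the spec's seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np

from .decay_data import HALF_LIVES_HOURS
from .phantom_transport import Region, VoxelPhantom
from .tiac_kinetics import LN2, SOURCE_REGIONS, TimeActivityCurve

__all__ = [
    "SyntheticStudySpec",
    "TACDataset",
    "generate_tac_dataset",
    "generate_phantom",
    "bundle_paper_fixtures",
    "DEFAULT_UPTAKE_FRACTIONS",
    "DEFAULT_ORGAN_SPECS",
]

#: Plausible normalised uptake ranges per source region (fraction of the
#: administered activity resident at t=0 under instantaneous uptake).
DEFAULT_UPTAKE_FRACTIONS: dict[str, tuple[float, float]] = {
    "right kidney": (0.01, 0.03),
    "left kidney": (0.01, 0.03),
    "spleen": (0.015, 0.04),
    "liver": (0.08, 0.20),
    "RBM": (0.002, 0.006),
    "remainder": (0.10, 0.25),
}

#: Organ ellipsoids: name → (target mass g, semi-axes mm, density g/cm³).
DEFAULT_ORGAN_SPECS: dict[str, tuple[float, tuple[float, float, float], float]] = {
    "liver": (1800.0, (90.0, 70.0, 40.0), 1.06),
    "spleen": (150.0, (40.0, 25.0, 25.0), 1.06),
    "left kidney": (150.0, (35.0, 25.0, 25.0), 1.05),
    "right kidney": (150.0, (35.0, 25.0, 25.0), 1.05),
    "RBM": (1100.0, (80.0, 50.0, 50.0), 1.03),
}


@dataclass(frozen=True)
class SyntheticStudySpec:
    """Configuration of one synthetic study realisation."""

    seed: int = 0
    regions: tuple[str, ...] = SOURCE_REGIONS
    effective_half_life_range_h: tuple[float, float] = (50.0, 80.0)
    uptake_fractions: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_UPTAKE_FRACTIONS)
    )
    sampling_times_h: tuple[float, ...] = (4.0, 24.0, 168.0)
    noise_rel_sd: float = 0.05
    fast_half_life_range_h: tuple[float, float] = (2.0, 10.0)
    fast_amplitude_share: tuple[float, float] = (0.1, 0.3)
    uptake_phase: bool = False
    body_half_extent_mm: tuple[float, float, float] = (160.0, 120.0, 280.0)
    voxel_size_mm: float = 8.0

    def __post_init__(self) -> None:
        lo, hi = self.effective_half_life_range_h
        if not 0 < lo <= hi:
            raise ValueError("invalid effective half-life range")
        times = self.sampling_times_h
        if any(t <= 0 for t in times) or any(
            t2 <= t1 for t1, t2 in zip(times, times[1:])
        ):
            raise ValueError("sampling times must be positive and increasing")
        if self.noise_rel_sd < 0:
            raise ValueError("noise must be >= 0")
        for r in self.regions:
            if r not in SOURCE_REGIONS:
                raise ValueError(f"unknown region {r!r}")


@dataclass
class TACDataset:
    """Truth curves plus (noisy) sampled measurement points per region."""

    spec: SyntheticStudySpec
    biological_curves: dict[str, TimeActivityCurve]
    samples: dict[str, list[tuple[float, float]]]
    amplitude_sums: dict[str, float]
    true_tiacs_lu177: dict[str, float]


def generate_tac_dataset(spec: SyntheticStudySpec) -> TACDataset:
    """Draw biological curves and their decayed, noise-perturbed samples.

    Each region gets a two-term biological curve: a dominant slow component
    whose effective half-life (biological + Lu-177 physical) falls in the
    configured band, and a faster washout component.  With
    ``spec.uptake_phase`` the fast component instead has a negative
    amplitude and a 1 h half-time, modelling gradual uptake (this is the
    configuration under which ratio rescaling is visibly biased).  Samples
    are the curve times the Lu-177 decay factor at the acquisition times,
    multiplied by log-normal noise of the configured relative sd.
    """
    rng = np.random.default_rng(spec.seed)
    lam_lu = LN2 / HALF_LIVES_HOURS["lutetium-177"]
    times = np.asarray(spec.sampling_times_h)

    curves: dict[str, TimeActivityCurve] = {}
    samples: dict[str, list[tuple[float, float]]] = {}
    amp_sums: dict[str, float] = {}
    tiacs: dict[str, float] = {}
    for region in spec.regions:
        lo, hi = spec.uptake_fractions.get(region, (0.01, 0.05))
        uptake = rng.uniform(lo, hi)
        t_eff = rng.uniform(*spec.effective_half_life_range_h)
        lam_bio_slow = max(LN2 / t_eff - lam_lu, 0.0)
        if spec.uptake_phase:
            a_slow = uptake
            a_fast = -rng.uniform(*spec.fast_amplitude_share) * uptake
            lam_fast = LN2 / 1.0
        else:
            share = rng.uniform(*spec.fast_amplitude_share)
            a_fast = share * uptake
            a_slow = uptake - a_fast
            lam_fast = LN2 / rng.uniform(*spec.fast_half_life_range_h)
        curve = TimeActivityCurve(
            ((a_slow, lam_bio_slow), (a_fast, lam_fast)),
            includes_physical_decay=False,
        )
        curve.check_nonnegative()
        curves[region] = curve
        amp_sums[region] = a_slow + a_fast
        tiacs[region] = sum(
            a / (l + lam_lu) for a, l in curve.terms
        )
        clean = curve(times) * np.exp(-lam_lu * times)
        if spec.noise_rel_sd > 0:
            sigma = math.sqrt(math.log(1.0 + spec.noise_rel_sd**2))
            noise = rng.lognormal(-0.5 * sigma**2, sigma, size=times.shape)
        else:
            noise = np.ones_like(times)
        samples[region] = list(zip(times.tolist(), (clean * noise).tolist()))
    return TACDataset(spec, curves, samples, amp_sums, tiacs)


# ---------------------------------------------------------------------------
# phantom generation

def generate_phantom(
    spec: SyntheticStudySpec,
    organ_specs: Mapping[str, tuple[float, tuple[float, float, float], float]] | None = None,
    max_retries: int = 200,
) -> VoxelPhantom:
    """Water body with non-overlapping ellipsoidal organs.

    Organ semi-axes are scaled so the analytic ellipsoid mass matches the
    requested mass at the organ density; voxelisation error stays within a
    few percent at the default 8 mm voxels.  Placement is rejection-sampled
    inside the body with a deterministic generator; infeasible placement
    after ``max_retries`` attempts raises.
    """
    organ_specs = dict(organ_specs if organ_specs is not None else DEFAULT_ORGAN_SPECS)
    rng = np.random.default_rng(spec.seed + 1)
    hx, hy, hz = spec.body_half_extent_mm
    v = spec.voxel_size_mm
    nx, ny, nz = (int(math.ceil(2 * e / v)) for e in (hx, hy, hz))
    grid = np.zeros((nx, ny, nz), dtype=np.int32)

    # voxel-centre coordinates relative to the body centre
    cx = (np.arange(nx) + 0.5) * v - hx
    cy = (np.arange(ny) + 0.5) * v - hy
    cz = (np.arange(nz) + 0.5) * v - hz
    X, Y, Z = np.meshgrid(cx, cy, cz, indexing="ij")

    body = (X / hx) ** 2 + (Y / hy) ** 2 + (Z / hz) ** 2 <= 1.0
    regions: dict[int, Region] = {}
    next_id = 1

    placed: list[tuple[np.ndarray, np.ndarray]] = []
    for name, (mass_g, axes, density) in organ_specs.items():
        # rescale semi-axes so (4/3)π·a·b·c·ρ = requested mass
        a, b, c = axes
        vol_cm3 = 4.0 / 3.0 * math.pi * a * b * c / 1000.0
        scale = (mass_g / (vol_cm3 * density)) ** (1.0 / 3.0)
        a, b, c = a * scale, b * scale, c * scale
        if a >= hx or b >= hy or c >= hz:
            raise ValueError(f"organ {name!r} does not fit inside the body")
        ok = False
        for _ in range(max_retries):
            centre = rng.uniform(
                [-(hx - a) * 0.8, -(hy - b) * 0.8, -(hz - c) * 0.8],
                [(hx - a) * 0.8, (hy - b) * 0.8, (hz - c) * 0.8],
            )
            mask = (
                ((X - centre[0]) / a) ** 2
                + ((Y - centre[1]) / b) ** 2
                + ((Z - centre[2]) / c) ** 2
                <= 1.0
            )
            if not mask.any():
                continue
            if (grid[mask] != 0).any() or not body[mask].all():
                continue
            grid[mask] = next_id
            regions[next_id] = Region(next_id, name, "water", density)
            next_id += 1
            ok = True
            break
        if not ok:
            raise RuntimeError(
                f"could not place organ {name!r} after {max_retries} attempts"
            )

    remainder_mask = body & (grid == 0)
    grid[remainder_mask] = next_id
    regions[next_id] = Region(next_id, "remainder", "water", 1.0)
    return VoxelPhantom(grid, (v, v, v), regions, tag=f"synthetic-seed{spec.seed}")


# ---------------------------------------------------------------------------
# fixture bundling

def bundle_paper_fixtures(out_dir: str | Path, seed: int = 0) -> dict[str, str]:
    """Copy the curated study fixtures into ``out_dir`` with a manifest.

    Writes the reference Lu-177 TIAC table, the five-nuclide decay table
    and the per-phantom effective-dose coefficient table, and returns a
    manifest mapping artifact names to paths (also written as JSON).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    for artifact, fname in [
        ("decay_table", "decay_table.csv"),
        ("tiac_lu177", "tiac_lu177.csv"),
        ("tiac_reference", "tiac_reference.csv"),
        ("effective_dose_coefficients", "effective_dose_coefficients.csv"),
        ("tissue_weights", "tissue_weights_icrp103.csv"),
    ]:
        ref = resources.files("scandose").joinpath(f"data/{fname}")
        target = out / fname
        target.write_text(ref.read_text())
        manifest[artifact] = str(target)
    (out / "manifest.json").write_text(
        json.dumps({"seed": seed, "artifacts": manifest}, indent=1)
    )
    manifest["manifest"] = str(out / "manifest.json")
    return manifest
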