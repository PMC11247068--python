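"""MIRD-formalism dose assembly.

The chain is S-value construction from emission data and absorbed
fractions,

    S(target ← source) = Σ_i Y_i · E_i · φ_i(target ← source) / m_target,

converted to mGy per MBq·h (1 MBq·h = 3.6×10⁹ decays, 1 MeV =
1.602176634×10⁻¹³ J), followed by the dose sum over source regions,

    AD/IA(target) = Σ_s TIAC(s) · S(target ← s)   [mGy/MBq],

and finally the effective-dose coefficient as the tissue-weighted sum of
organ equivalent doses with radiation weighting factor 1 for all photon
and electron emissions in scope (so equivalent dose equals absorbed dose
numerically).  Tissues without an explicit dose inherit the remainder
region's dose.  Effective doses are reported per phantom, not
sex-averaged.

Uncertainties propagate first-order from the Monte Carlo standard errors
of the absorbed fractions, treated as independent; TIACs are exact.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .decay_data import DECAYS_PER_MBQ_HOUR, MEV_TO_J, RadionuclideDecayData
from .phantom_transport import AbsorbedFractionTable
from .tiac_kinetics import TIACTable

__all__ = [
    "SValueMatrix",
    "DoseResult",
    "TissueWeights",
    "load_icrp103_weights",
    "build_svalue_matrix",
    "compute_absorbed_dose",
    "effective_dose",
    "combine_kidneys",
    "MGY_PER_MEV_G_PER_MBQ_H",
]

#: mGy per (MeV/g) per MBq·h: J/MeV × decays/(MBq·h) × 1000 g/kg × 1000 mGy/Gy.
MGY_PER_MEV_G_PER_MBQ_H = MEV_TO_J * DECAYS_PER_MBQ_HOUR * 1e6


@dataclass
class SValueMatrix:
    """S(target ← source) in mGy/(MBq·h) with MC standard deviations."""

    nuclide_tag: str
    phantom_tag: str
    targets: tuple[str, ...]
    sources: tuple[str, ...]
    values: np.ndarray  # (n_target, n_source)
    sd: np.ndarray      # (n_target, n_source)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        self.sd = np.asarray(self.sd, float)
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("S-values must be finite and non-negative")

    def s(self, target: str, source: str) -> float:
        return float(self.values[self.targets.index(target), self.sources.index(source)])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, t in enumerate(self.targets):
            for j, s in enumerate(self.sources):
                rows.append(
                    {
                        "phantom": self.phantom_tag,
                        "nuclide": self.nuclide_tag,
                        "target": t,
                        "source": s,
                        "S_mGy_per_MBq_h": self.values[i, j],
                        "sd": self.sd[i, j],
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class DoseResult:
    """Organ absorbed doses per injected activity and effective dose."""

    phantom_tag: str
    nuclide_tag: str
    organ_doses_mgy_per_mbq: dict[str, float]
    organ_sd: dict[str, float] = field(default_factory=dict)
    effective_dose_msv_per_mbq: float | None = None
    effective_dose_sd: float | None = None

    def __post_init__(self) -> None:
        for organ, d in self.organ_doses_mgy_per_mbq.items():
            if d < 0:
                raise ValueError(f"negative dose for {organ}")
            if self.organ_sd.get(organ, 0.0) < 0:
                raise ValueError(f"negative uncertainty for {organ}")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "phantom": self.phantom_tag,
                "nuclide": self.nuclide_tag,
                "organ": organ,
                "value": d,
                "sd": self.organ_sd.get(organ, 0.0),
                "unit": "mGy/MBq",
            }
            for organ, d in self.organ_doses_mgy_per_mbq.items()
        ]
        if self.effective_dose_msv_per_mbq is not None:
            rows.append(
                {
                    "phantom": self.phantom_tag,
                    "nuclide": self.nuclide_tag,
                    "organ": "effective dose",
                    "value": self.effective_dose_msv_per_mbq,
                    "sd": self.effective_dose_sd or 0.0,
                    "unit": "mSv/MBq",
                }
            )
        return pd.DataFrame(rows)

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class TissueWeights:
    """Tissue weighting factors w_T; must sum to 1 with the remainder."""

    weights: Mapping[str, float]
    remainder_weight: float

    def __post_init__(self) -> None:
        w = dict(self.weights)
        if any(v < 0 for v in w.values()) or self.remainder_weight < 0:
            raise ValueError("tissue weights must be non-negative")
        total = sum(w.values()) + self.remainder_weight
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"tissue weights sum to {total}, expected 1")
        object.__setattr__(self, "weights", w)


def load_icrp103_weights() -> TissueWeights:
    """The bundled ICRP 103 tissue weighting factors."""
    ref = resources.files("scandose").joinpath("data/tissue_weights_icrp103.csv")
    weights: dict[str, float] = {}
    remainder = 0.0
    with resources.as_file(ref) as path, open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            if row["tissue"] == "remainder":
                remainder = float(row["w_T"])
            else:
                weights[row["tissue"]] = float(row["w_T"])
    return TissueWeights(weights, remainder)


# ---------------------------------------------------------------------------

def build_svalue_matrix(
    nuclide: RadionuclideDecayData,
    af: AbsorbedFractionTable,
    masses_g: Mapping[str, float],
    source_keys: Mapping[str, str] | None = None,
) -> SValueMatrix:
    """Assemble S(target ← source) from per-line absorbed fractions.

    ``masses_g`` lists the target regions and their masses in grams.
    ``source_keys`` maps each logical source region to the source key used
    in the absorbed-fraction table (defaults to identity).  A missing
    (emission, source) entry is an error naming the triple; S is additive
    over emission lines.
    """
    targets = tuple(masses_g)
    for t, m in masses_g.items():
        if m <= 0:
            raise ValueError(f"target {t!r}: mass must be positive")
    by_key = af.by_key()
    source_keys = dict(source_keys) if source_keys else {}
    sources = tuple(sorted({e.source_key for e in af.entries})) if not source_keys else tuple(source_keys)
    values = np.zeros((len(targets), len(sources)))
    var = np.zeros_like(values)
    for j, src in enumerate(sources):
        key = source_keys.get(src, src)
        lines = [e for e in af.entries if e.source_key == key]
        if not lines:
            raise KeyError(f"no absorbed fractions for source region {key!r}")
        seen = set()
        for line in nuclide.emissions:
            ekey = f"{line.radiation_class.value}@{line.mean_energy_mev:.6g}MeV"
            if (key, ekey) in seen:
                continue
            seen.add((key, ekey))
            entry = by_key.get((key, ekey))
            if entry is None:
                raise KeyError(
                    f"missing absorbed-fraction entry for emission {ekey!r}, "
                    f"source {key!r} (targets {targets})"
                )
            for i, tgt in enumerate(targets):
                phi = entry.phi.get(tgt, 0.0)
                contrib = (
                    line.yield_per_decay
                    * line.mean_energy_mev
                    * phi
                    / masses_g[tgt]
                    * MGY_PER_MEV_G_PER_MBQ_H
                )
                values[i, j] += contrib
                rse = entry.rse.get(tgt, 0.0)
                var[i, j] += (contrib * rse) ** 2
    return SValueMatrix(
        nuclide.name, af.phantom_tag, targets, sources, values, np.sqrt(var)
    )


def combine_kidneys(
    doses: Mapping[str, float],
    sd: Mapping[str, float],
    masses_g: Mapping[str, float],
) -> tuple[float, float] | None:
    """Mass-weighted combined kidneys dose from left/right target doses."""
    if "left kidney" not in doses or "right kidney" not in doses:
        return None
    ml, mr = masses_g["left kidney"], masses_g["right kidney"]
    wl, wr = ml / (ml + mr), mr / (ml + mr)
    d = wl * doses["left kidney"] + wr * doses["right kidney"]
    s = math.sqrt((wl * sd.get("left kidney", 0.0)) ** 2 + (wr * sd.get("right kidney", 0.0)) ** 2)
    return d, s


def compute_absorbed_dose(
    tiac: TIACTable,
    s: SValueMatrix,
    masses_g: Mapping[str, float] | None = None,
) -> DoseResult:
    """Organ absorbed dose per injected activity: Σ_s TIAC(s)·S(t←s).

    When both kidney targets are present and masses are supplied, a
    combined mass-weighted ``kidneys`` entry is added.  Uncertainties
    combine the per-source S standard deviations in quadrature (TIACs are
    treated as exact).
    """
    if tiac.nuclide_tag != s.nuclide_tag:
        raise ValueError(
            f"TIAC table is for {tiac.nuclide_tag!r} but S-matrix for {s.nuclide_tag!r}"
        )
    missing = [r for r in tiac.regions() if r not in s.sources]
    if missing:
        raise ValueError(f"TIAC source regions {missing} absent from S-matrix")
    doses: dict[str, float] = {}
    sds: dict[str, float] = {}
    for i, tgt in enumerate(s.targets):
        total = 0.0
        var = 0.0
        for region in tiac.regions():
            j = s.sources.index(region)
            total += tiac[region] * s.values[i, j]
            var += (tiac[region] * s.sd[i, j]) ** 2
        doses[tgt] = total
        sds[tgt] = math.sqrt(var)
    if masses_g is not None:
        combined = combine_kidneys(doses, sds, masses_g)
        if combined is not None:
            doses["kidneys"], sds["kidneys"] = combined
    return DoseResult(s.phantom_tag, s.nuclide_tag, doses, sds)


def effective_dose(
    doses: DoseResult,
    weights: TissueWeights,
    remainder_organ: str = "remainder",
) -> tuple[float, float]:
    """Effective-dose coefficient E = Σ_T w_T·H_T + w_rem·H_rem, mSv/MBq.

    Radiation weighting factor is 1 for every emission class in scope, so
    organ equivalent doses equal the absorbed doses numerically (mGy →
    mSv).  Tissues with a nonzero w_T but no explicit dose fall back to the
    remainder organ's dose; if that is also absent, an error names the
    tissue.  Returns (E, sd).
    """
    organ = doses.organ_doses_mgy_per_mbq
    sd = doses.organ_sd
    rem_dose = organ.get(remainder_organ)
    e = 0.0
    var = 0.0
    for tissue, w in weights.weights.items():
        if tissue in organ:
            d, s_ = organ[tissue], sd.get(tissue, 0.0)
        elif rem_dose is not None:
            d, s_ = rem_dose, sd.get(remainder_organ, 0.0)
        else:
            raise ValueError(
                f"tissue {tissue!r} has no dose and no remainder fallback"
            )
        e += w * d
        var += (w * s_) ** 2
    if weights.remainder_weight > 0:
        if rem_dose is None:
            raise ValueError("remainder dose required but absent")
        e += weights.remainder_weight * rem_dose
        var += (weights.remainder_weight * sd.get(remainder_organ, 0.0)) ** 2
    return e, math.sqrt(var)
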