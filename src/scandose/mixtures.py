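"""Scandium mixture composition scan and dose-comparison arithmetic.

A production batch of scandium-44 carries a scandium-44m impurity quoted
as a percentage p of the scandium-44 activity share; the balance of the
administration is scandium-43.  With f the scandium-44 share of the
administered activity, the activity fractions at administration time are

    f_sc44 = f·(1−p),   f_sc44m = f·p,   f_sc43 = 1 − f,

summing to one exactly.  Effective-dose coefficients mix linearly in the
activity fractions; no decay-chain in-growth of the metastable state is
modelled (coefficients are fixed per-nuclide properties, mixed at
administration time).

The comparison statistic used throughout is the percentage difference
Δ = (1 − δ/ε)·100 between two dose quantities δ and ε.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "MixtureSpec",
    "ComparisonResult",
    "mixture_effective_dose",
    "mixture_scan",
    "total_patient_dose",
    "percent_difference",
    "impurity_increase_percent",
    "load_coefficients",
    "load_bundled_coefficients",
    "SC_NUCLIDES",
]

SC_NUCLIDES = ("scandium-43", "scandium-44", "scandium-44m")


@dataclass(frozen=True)
class MixtureSpec:
    """Scandium composition: Sc-44 share and its Sc-44m impurity level.

    ``fraction_sc44`` ∈ [0, 1] is the scandium-44 share of the administered
    activity before impurity accounting; ``sc44m_percent_of_sc44`` ∈
    [0, 0.15] is the metastable impurity as a fraction of that share.
    """

    fraction_sc44: float
    sc44m_percent_of_sc44: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_sc44 <= 1.0:
            raise ValueError("fraction_sc44 must be in [0, 1]")
        if not 0.0 <= self.sc44m_percent_of_sc44 <= 0.15 + 1e-12:
            raise ValueError("sc44m_percent_of_sc44 must be in [0, 0.15]")

    @property
    def fractions(self) -> dict[str, float]:
        f, p = self.fraction_sc44, self.sc44m_percent_of_sc44
        fr = {
            "scandium-43": 1.0 - f,
            "scandium-44": f * (1.0 - p),
            "scandium-44m": f * p,
        }
        assert abs(sum(fr.values()) - 1.0) < 1e-12
        return fr


@dataclass(frozen=True)
class ComparisonResult:
    """Δ = (1 − δ/ε)·100 with its operand tags."""

    delta_percent: float
    numerator_tag: str
    denominator_tag: str


def percent_difference(
    delta_value: float,
    epsilon_value: float,
    numerator_tag: str = "delta",
    denominator_tag: str = "epsilon",
) -> ComparisonResult:
    """Percentage difference Δ = (1 − δ/ε)·100; ε must be nonzero."""
    if epsilon_value == 0:
        raise ValueError("denominator of the percentage difference must be nonzero")
    return ComparisonResult(
        (1.0 - delta_value / epsilon_value) * 100.0, numerator_tag, denominator_tag
    )


def mixture_effective_dose(spec: MixtureSpec, coefficients: Mapping[str, float]) -> float:
    """Activity-fraction-weighted effective-dose coefficient, mSv/MBq."""
    missing = [n for n in SC_NUCLIDES if n not in coefficients]
    if missing:
        raise KeyError(f"missing effective-dose coefficients for {missing}")
    return sum(frac * coefficients[n] for n, frac in spec.fractions.items())


def mixture_scan(
    coefficients: Mapping[str, float],
    phantom_tag: str = "",
    sc44_step: float = 0.1,
    sc44m_step: float = 0.01,
    sc44m_max: float = 0.15,
) -> pd.DataFrame:
    """Effective dose over the composition grid.

    Defaults scan the scandium-44 share from 0 to 100% in 10% steps and
    the scandium-44m impurity from 0 to 15% of that share in 1% steps:
    11 × 16 = 176 rows.
    """
    f44_grid = np.round(np.arange(0.0, 1.0 + 1e-9, sc44_step), 10) if sc44_step > 0 else np.array([])
    p_grid = np.round(np.arange(0.0, sc44m_max + 1e-9, sc44m_step), 10) if sc44m_step > 0 else np.array([])
    rows = []
    for f44, p in itertools.product(f44_grid, p_grid):
        spec = MixtureSpec(float(f44), float(p))
        fr = spec.fractions
        rows.append(
            {
                "f_sc43": fr["scandium-43"],
                "f_sc44": fr["scandium-44"],
                "f_sc44m": fr["scandium-44m"],
                "phantom": phantom_tag,
                "E_mix_mSv_per_MBq": mixture_effective_dose(spec, coefficients),
            }
        )
    return pd.DataFrame(rows, columns=["f_sc43", "f_sc44", "f_sc44m", "phantom", "E_mix_mSv_per_MBq"])


def total_patient_dose(
    spec: MixtureSpec | str,
    coefficients: Mapping[str, float],
    administered_activity_mbq: float,
) -> float:
    """Total effective dose in mSv for an administered activity in MBq."""
    if administered_activity_mbq < 0:
        raise ValueError("administered activity must be >= 0")
    if isinstance(spec, str):
        if spec not in coefficients:
            raise KeyError(f"no coefficient for nuclide {spec!r}")
        e = coefficients[spec]
    else:
        e = mixture_effective_dose(spec, coefficients)
    return e * administered_activity_mbq


def impurity_increase_percent(
    coefficients: Mapping[str, float], impurity: float = 0.15
) -> float:
    """Relative increase (%) of the effective dose of a pure scandium-44
    sample when it carries a metastable impurity at the given level."""
    pure = coefficients["scandium-44"]
    mixed = mixture_effective_dose(MixtureSpec(1.0, impurity), coefficients)
    return (mixed - pure) / pure * 100.0


# ---------------------------------------------------------------------------
# coefficient files

def load_coefficients(path: str | Path, phantom: str | None = None) -> dict[str, dict[str, float]]:
    """Read a coefficients CSV (phantom, nuclide, effective dose, optional
    organ doses) into {phantom: {nuclide: E (mSv/MBq)}}.

    Restricted to one phantom when ``phantom`` is given (then the outer
    level is still present, with that single key).
    """
    df = pd.read_csv(path)
    required = {"phantom", "nuclide", "effective_dose_mSv_per_MBq"}
    if not required.issubset(df.columns):
        raise ValueError(f"coefficients file must have columns {sorted(required)}")
    if phantom is not None:
        df = df[df["phantom"] == phantom]
        if df.empty:
            raise ValueError(f"no coefficients for phantom {phantom!r}")
    out: dict[str, dict[str, float]] = {}
    for _, row in df.iterrows():
        out.setdefault(row["phantom"], {})[row["nuclide"]] = float(
            row["effective_dose_mSv_per_MBq"]
        )
    return out


def load_bundled_coefficients() -> dict[str, dict[str, float]]:
    """Per-phantom effective-dose coefficients bundled with the package."""
    ref = resources.files("scandose").joinpath("data/effective_dose_coefficients.csv")
    with resources.as_file(ref) as path:
        return load_coefficients(path)
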