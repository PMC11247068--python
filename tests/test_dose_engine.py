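import math

import numpy as np
import pytest

from scandose.decay_data import (
    DECAYS_PER_MBQ_HOUR,
    MEV_TO_J,
    EmissionLine,
    RadiationClass,
    RadionuclideDecayData,
)
from scandose.dose_engine import (
    MGY_PER_MEV_G_PER_MBQ_H,
    DoseResult,
    SValueMatrix,
    TissueWeights,
    build_svalue_matrix,
    compute_absorbed_dose,
    effective_dose,
    load_icrp103_weights,
)
from scandose.phantom_transport import (
    AbsorbedFractionEntry,
    AbsorbedFractionTable,
    simulate_absorbed_fractions,
)
from scandose.tiac_kinetics import TIACTable


def af_entry(source, rclass, y, e_mev, phi, escape=0.0):
    return AbsorbedFractionEntry(
        source_key=source,
        emission_key=f"{rclass.value}@{e_mev:.6g}MeV",
        radiation_class=rclass,
        yield_per_decay=y,
        mean_energy_mev=e_mev,
        phi=dict(phi),
        escape=escape,
        rse={k: 0.0 for k in phi},
        escape_rse=0.0,
        histories=1,
        seed=0,
    )


def single_line_table(phi_self=1.0):
    nuc = RadionuclideDecayData(
        "unit", 1.0, (EmissionLine(RadiationClass.GAMMA, 1.0, 1.0),)
    )
    af = AbsorbedFractionTable(
        "toy", "unit",
        [af_entry("organ", RadiationClass.GAMMA, 1.0, 1.0, {"organ": phi_self},
                  escape=1.0 - phi_self)],
    )
    return nuc, af


# ---------------------------------------------------------------------------
# S-values

def test_unit_conversion_oracle():
    """Y=1, E=1 MeV, φ=1 into a 1 kg target: hand unit conversion."""
    nuc, af = single_line_table()
    s = build_svalue_matrix(nuc, af, {"organ": 1000.0})
    expected = 1.0 * MEV_TO_J * DECAYS_PER_MBQ_HOUR / 1.0 * 1000.0  # Gy->mGy, J/kg
    assert s.s("organ", "organ") == pytest.approx(expected, rel=1e-12)
    assert expected == pytest.approx(5.767836e-4 * 1000.0, rel=1e-4)
    assert MGY_PER_MEV_G_PER_MBQ_H == pytest.approx(MEV_TO_J * DECAYS_PER_MBQ_HOUR * 1e6)


def test_zero_yields_give_zero_matrix():
    nuc = RadionuclideDecayData(
        "z", 1.0, (EmissionLine(RadiationClass.GAMMA, 0.0, 1.0),)
    )
    af = AbsorbedFractionTable(
        "toy", "z", [af_entry("organ", RadiationClass.GAMMA, 0.0, 1.0, {"organ": 1.0})]
    )
    s = build_svalue_matrix(nuc, af, {"organ": 500.0})
    assert np.all(s.values == 0.0)


def test_svalue_additive_over_split_lines():
    one = RadionuclideDecayData(
        "one", 1.0, (EmissionLine(RadiationClass.GAMMA, 0.8, 0.5),)
    )
    two = RadionuclideDecayData(
        "two", 1.0,
        (
            EmissionLine(RadiationClass.GAMMA, 0.4, 0.5),
            EmissionLine(RadiationClass.XRAY, 0.4, 0.5),
        ),
    )
    af1 = AbsorbedFractionTable(
        "toy", "one", [af_entry("o", RadiationClass.GAMMA, 0.8, 0.5, {"o": 0.6}, 0.4)]
    )
    af2 = AbsorbedFractionTable(
        "toy", "two",
        [
            af_entry("o", RadiationClass.GAMMA, 0.4, 0.5, {"o": 0.6}, 0.4),
            af_entry("o", RadiationClass.XRAY, 0.4, 0.5, {"o": 0.6}, 0.4),
        ],
    )
    s1 = build_svalue_matrix(one, af1, {"o": 100.0})
    s2 = build_svalue_matrix(two, af2, {"o": 100.0})
    assert s2.s("o", "o") == pytest.approx(s1.s("o", "o"), rel=1e-12)


def test_missing_phi_entry_names_triple():
    nuc = RadionuclideDecayData(
        "m", 1.0,
        (
            EmissionLine(RadiationClass.GAMMA, 1.0, 1.0),
            EmissionLine(RadiationClass.XRAY, 1.0, 0.05),
        ),
    )
    af = AbsorbedFractionTable(
        "toy", "m", [af_entry("organ", RadiationClass.GAMMA, 1.0, 1.0, {"organ": 1.0})]
    )
    with pytest.raises(KeyError, match="xray@0.05MeV"):
        build_svalue_matrix(nuc, af, {"organ": 100.0})


# ---------------------------------------------------------------------------
# dose assembly

def toy_smatrix():
    return SValueMatrix(
        "toy", "phantom",
        targets=("liver", "spleen"),
        sources=("liver", "spleen"),
        values=np.array([[1.0, 0.5], [0.2, 2.0]]),
        sd=np.zeros((2, 2)),
    )


def test_dose_is_tiac_weighted_sum():
    tiac = TIACTable("toy", {"liver": 2.0, "spleen": 3.0})
    dose = compute_absorbed_dose(tiac, toy_smatrix())
    assert dose.organ_doses_mgy_per_mbq["liver"] == pytest.approx(3.5)
    assert dose.organ_doses_mgy_per_mbq["spleen"] == pytest.approx(6.4)


def test_zero_tiac_zero_dose_and_linearity():
    zero = TIACTable("toy", {"liver": 0.0, "spleen": 0.0})
    assert all(
        v == 0.0
        for v in compute_absorbed_dose(zero, toy_smatrix()).organ_doses_mgy_per_mbq.values()
    )
    t1 = TIACTable("toy", {"liver": 1.0, "spleen": 2.0})
    t2 = TIACTable("toy", {"liver": 2.0, "spleen": 4.0})
    d1 = compute_absorbed_dose(t1, toy_smatrix()).organ_doses_mgy_per_mbq
    d2 = compute_absorbed_dose(t2, toy_smatrix()).organ_doses_mgy_per_mbq
    for organ in d1:
        assert d2[organ] == pytest.approx(2 * d1[organ], rel=1e-12)


def test_nuclide_mismatch_rejected():
    tiac = TIACTable("other", {"liver": 1.0})
    with pytest.raises(ValueError, match="other"):
        compute_absorbed_dose(tiac, toy_smatrix())


def test_combined_kidneys_mass_weighted():
    s = SValueMatrix(
        "toy", "p",
        targets=("left kidney", "right kidney"),
        sources=("left kidney", "right kidney"),
        values=np.array([[1.0, 0.0], [0.0, 2.0]]),
        sd=np.zeros((2, 2)),
    )
    tiac = TIACTable("toy", {"left kidney": 1.0, "right kidney": 1.0})
    masses = {"left kidney": 100.0, "right kidney": 300.0}
    dose = compute_absorbed_dose(tiac, s, masses)
    assert dose.organ_doses_mgy_per_mbq["kidneys"] == pytest.approx(
        (100 * 1.0 + 300 * 2.0) / 400
    )


# ---------------------------------------------------------------------------
# effective dose

def test_effective_dose_toy_weighted_sum():
    weights = TissueWeights({"A": 0.5, "B": 0.3}, 0.2)
    doses = DoseResult("p", "n", {"A": 2.0, "B": 1.0, "remainder": 0.5})
    e, _ = effective_dose(doses, weights)
    assert e == pytest.approx(0.5 * 2 + 0.3 * 1 + 0.2 * 0.5)  # 1.4


def test_uniform_dose_gives_same_effective_dose():
    weights = load_icrp103_weights()
    doses = DoseResult(
        "p", "n", {"liver": 0.7, "RBM": 0.7, "remainder": 0.7}
    )
    e, _ = effective_dose(doses, weights)
    assert e == pytest.approx(0.7, rel=1e-9)


def test_zero_doses_zero_effective_dose():
    weights = load_icrp103_weights()
    doses = DoseResult("p", "n", {"liver": 0.0, "RBM": 0.0, "remainder": 0.0})
    assert effective_dose(doses, weights)[0] == 0.0


def test_missing_tissue_without_remainder_errors():
    weights = TissueWeights({"A": 1.0}, 0.0)
    doses = DoseResult("p", "n", {"B": 1.0})
    with pytest.raises(ValueError, match="no dose"):
        effective_dose(doses, weights)


def test_icrp103_weights_sum_to_one():
    w = load_icrp103_weights()
    assert sum(w.weights.values()) + w.remainder_weight == pytest.approx(1.0)
    assert w.weights["RBM"] == 0.12


def test_tissue_weights_validation():
    with pytest.raises(ValueError, match="sum"):
        TissueWeights({"A": 0.5}, 0.4)


# ---------------------------------------------------------------------------
# MIRD factored path vs direct energy tally

def test_mird_path_matches_direct_energy_tally(toy_phantom, toy_nuclide):
    """Factored S-matrix route equals a direct per-history energy tally
    (independent MC realisation) within combined MC uncertainty."""
    masses = toy_phantom.organ_masses_g()
    tiac = {"A": 2.0, "B": 3.0, "remainder": 5.0}
    n = 20_000

    entries_a, entries_b = [], []
    for src in tiac:
        entries_a.extend(
            simulate_absorbed_fractions(
                toy_phantom, toy_nuclide, src, n, seed=31, source_key=src
            ).entries
        )
        entries_b.extend(
            simulate_absorbed_fractions(
                toy_phantom, toy_nuclide, src, n, seed=77, source_key=src
            ).entries
        )

    s = build_svalue_matrix(
        toy_nuclide, AbsorbedFractionTable("toy", "toy", entries_a), masses
    )
    mird = {
        t: sum(tiac[src] * s.values[i, s.sources.index(src)] for src in tiac)
        for i, t in enumerate(s.targets)
    }
    mird_sd = {
        t: math.sqrt(
            sum((tiac[src] * s.sd[i, s.sources.index(src)]) ** 2 for src in tiac)
        )
        for i, t in enumerate(s.targets)
    }

    direct = {t: 0.0 for t in s.targets}
    direct_var = {t: 0.0 for t in s.targets}
    for e in entries_b:
        decays = tiac[e.source_key] * DECAYS_PER_MBQ_HOUR
        for t in s.targets:
            edep_j = e.yield_per_decay * e.mean_energy_mev * e.phi.get(t, 0.0) * MEV_TO_J
            contrib = decays * edep_j / (masses[t] * 1e-3) * 1e3  # mGy
            direct[t] += contrib
            direct_var[t] += (contrib * e.rse.get(t, 0.0)) ** 2

    for t in s.targets:
        sigma = math.hypot(mird_sd[t], math.sqrt(direct_var[t]))
        assert abs(mird[t] - direct[t]) <= 3.5 * sigma + 1e-9 * mird[t]
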