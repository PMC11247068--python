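import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from scandose.decay_data import HALF_LIVES_HOURS
from scandose.tiac_kinetics import (
    LN2,
    SOURCE_REGIONS,
    TIACTable,
    TimeActivityCurve,
    apply_physical_decay,
    fit_biexponential,
    integrate_tiac,
    read_tiac_csv,
    rescale_diagnostic,
    rescale_tiac_exact,
    rescale_tiac_ratio,
    strip_physical_decay,
    write_tiac_csv,
)

LU = HALF_LIVES_HOURS["lutetium-177"]


def biexp(a1, l1, a2, l2, decayed=True):
    return TimeActivityCurve(((a1, l1), (a2, l2)), includes_physical_decay=decayed)


# ---------------------------------------------------------------------------
# strip / apply

def test_strip_pure_physical_decay_gives_flat_biology():
    tac = TimeActivityCurve(((1.0, LN2 / LU),), includes_physical_decay=True)
    biol = strip_physical_decay(tac, LU)
    assert biol.terms == ((1.0, 0.0),)
    assert not biol.includes_physical_decay


def test_strip_matches_pointwise_exponential_product():
    tac = biexp(0.8, 0.05, 0.2, 0.3)
    biol = strip_physical_decay(tac, LU)
    for t in (0.0, 4.0, 24.0, 168.0):
        assert biol(t) == pytest.approx(tac(t) * math.exp(LN2 * t / LU), rel=1e-12)


def test_apply_matches_pointwise_at_grid():
    biol = biexp(0.7, 0.01, 0.3, 0.2, decayed=False)
    hl = HALF_LIVES_HOURS["scandium-44"]
    decayed = apply_physical_decay(biol, hl)
    for t in np.linspace(0.0, 30.0, 5):
        assert decayed(t) == pytest.approx(biol(t) * math.exp(-LN2 * t / hl), rel=1e-12)


def test_strip_rejects_curve_slower_than_physics():
    tac = TimeActivityCurve(((1.0, 0.001),), includes_physical_decay=True)
    with pytest.raises(ValueError, match="physical decay"):
        strip_physical_decay(tac, 4.0)  # lambda_phys = 0.17/h >> 0.001


@settings(derandomize=True, max_examples=100)
@given(
    a1=st.floats(0.01, 1.0),
    a2=st.floats(0.0, 0.5),
    hl_bio1=st.floats(10.0, 500.0),
    hl_bio2=st.floats(0.5, 10.0),
    hl_phys=st.floats(0.5, 200.0),
)
def test_strip_apply_identity(a1, a2, hl_bio1, hl_bio2, hl_phys):
    biol = biexp(a1, LN2 / hl_bio1, a2, LN2 / hl_bio2, decayed=False)
    round_tripped = strip_physical_decay(apply_physical_decay(biol, hl_phys), hl_phys)
    for (a, l), (b, m) in zip(biol.terms, round_tripped.terms):
        assert b == pytest.approx(a, rel=1e-12)
        assert m == pytest.approx(l, rel=1e-9, abs=1e-12)


# ---------------------------------------------------------------------------
# integration

def test_integrate_single_term_closed_form():
    assert integrate_tiac(
        TimeActivityCurve(((1.0, 0.25),), includes_physical_decay=True)
    ) == pytest.approx(4.0)
    assert integrate_tiac(
        TimeActivityCurve(((0.0, 0.25),), includes_physical_decay=True)
    ) == 0.0


def test_integrate_matches_quadrature():
    curve = biexp(0.7, LN2 / 65.0 + LN2 / LU, 0.3, LN2 / 3.0 + LN2 / LU)
    analytic = integrate_tiac(curve)
    numeric, _ = quad(curve, 0.0, 40.0 * LU / LN2 * LN2, limit=400)
    # tail beyond the truncation point is negligible at 40 half-lives
    assert analytic == pytest.approx(numeric, rel=1e-6)


def test_integrate_rejects_divergent_terms():
    flat = TimeActivityCurve(((1.0, 0.0),), includes_physical_decay=True)
    with pytest.raises(ValueError, match="divergent"):
        integrate_tiac(flat)


@settings(derandomize=True, max_examples=50)
@given(a1=st.floats(0.0, 1.0), a2=st.floats(0.0, 1.0), scale=st.floats(0.1, 10.0))
def test_integrate_linear_in_amplitudes(a1, a2, scale):
    l1, l2 = 0.05, 0.4
    base = integrate_tiac(biexp(a1, l1, a2, l2))
    scaled = integrate_tiac(biexp(scale * a1, l1, scale * a2, l2))
    assert scaled == pytest.approx(scale * base, rel=1e-12, abs=1e-12)


# ---------------------------------------------------------------------------
# rescaling

def test_ratio_rescaling_identity_and_linearity():
    table = TIACTable("lutetium-177", {"liver": 15.2, "spleen": 2.5})
    same = rescale_tiac_ratio(table, LU, LU)
    assert same.entries == table.entries
    halved = rescale_tiac_ratio(table, LU / 2, LU)
    assert halved["liver"] == pytest.approx(15.2 / 2)


def test_ratio_rescaling_preserves_interorgan_ratios():
    table = TIACTable(
        "lutetium-177",
        {"right kidney": 1.6, "left kidney": 1.6, "spleen": 2.5, "liver": 15.2,
         "RBM": 0.3, "remainder": 12.5},
    )
    for name, hl in HALF_LIVES_HOURS.items():
        r = rescale_tiac_ratio(table, hl, LU, nuclide_tag=name)
        assert r["liver"] / r["spleen"] == pytest.approx(15.2 / 2.5, rel=1e-12)


def test_exact_rescaling_equals_ratio_for_flat_biology():
    biol = {"liver": TimeActivityCurve(((0.5, 0.0),), includes_physical_decay=False)}
    exact = rescale_tiac_exact(biol, HALF_LIVES_HOURS["scandium-44"])
    ref = rescale_tiac_exact(biol, LU, "lutetium-177")
    ratio = rescale_tiac_ratio(ref, HALF_LIVES_HOURS["scandium-44"], LU)
    assert exact["liver"] == pytest.approx(ratio["liver"], rel=1e-12)


def test_exact_exceeds_ratio_for_decaying_biology():
    """(λ_b+λ_ref)/(λ_b+λ_tgt) > λ_ref/λ_tgt when T_tgt < T_ref and λ_b > 0."""
    lam_b = LN2 / 65.0
    biol = {"liver": TimeActivityCurve(((0.5, lam_b),), includes_physical_decay=False)}
    for name in ("scandium-43", "scandium-44", "scandium-44m", "gallium-68"):
        hl = HALF_LIVES_HOURS[name]
        exact = rescale_tiac_exact(biol, hl)["liver"]
        ref = rescale_tiac_exact(biol, LU, "lutetium-177")
        ratio = rescale_tiac_ratio(ref, hl, LU)["liver"]
        assert exact > ratio


def test_zero_amplitude_biology_gives_zero_table():
    biol = {"liver": TimeActivityCurve(((0.0, 0.01),), includes_physical_decay=False)}
    assert rescale_tiac_exact(biol, 4.0)["liver"] == 0.0


@settings(derandomize=True, max_examples=100)
@given(
    lam_b=st.floats(0.0, 0.1),
    uptake=st.floats(0.01, 1.0),
    hl_target=st.floats(0.5, 159.0),
)
def test_ratio_never_exceeds_exact_for_shorter_lived_targets(lam_b, uptake, hl_target):
    biol = {"liver": TimeActivityCurve(((uptake, lam_b),), includes_physical_decay=False)}
    exact = rescale_tiac_exact(biol, hl_target)["liver"]
    ref = rescale_tiac_exact(biol, LU, "lutetium-177")
    ratio = rescale_tiac_ratio(ref, hl_target, LU)["liver"]
    assert ratio <= exact * (1 + 1e-12)


def test_rescale_diagnostic_reports_gap():
    biol = {
        "liver": TimeActivityCurve(((0.5, LN2 / 65.0),), includes_physical_decay=False),
        "spleen": TimeActivityCurve(((0.05, 0.0),), includes_physical_decay=False),
    }
    diag = rescale_diagnostic(biol, HALF_LIVES_HOURS["scandium-44"], LU)
    assert diag.loc["liver", "rel_difference"] < 0  # ratio underestimates
    assert diag.loc["spleen", "rel_difference"] == pytest.approx(0.0, abs=1e-12)


# ---------------------------------------------------------------------------
# fitting

def test_fit_recovers_biexponential_from_noise_free_samples():
    truth = biexp(0.12, LN2 / 70.0 - LN2 / LU, 0.04, LN2 / 5.0, decayed=False)
    times = [4.0, 24.0, 168.0]
    samples = [(t, truth(t) * math.exp(-LN2 * t / LU)) for t in times]
    fit = fit_biexponential(samples, LU, amplitude_sum=0.16)
    for (a, l), (b, m) in zip(sorted(truth.terms), sorted(fit.terms)):
        assert b == pytest.approx(a, rel=1e-4)
        assert m == pytest.approx(l, rel=1e-4, abs=1e-9)


def test_fit_monoexponential_data_yields_negligible_second_term():
    truth = TimeActivityCurve(((0.2, LN2 / 60.0),), includes_physical_decay=False)
    samples = [(t, truth(t) * math.exp(-LN2 * t / LU)) for t in (4.0, 24.0, 96.0, 168.0)]
    fit = fit_biexponential(samples, LU, amplitude_sum=0.2)
    slow, fast = sorted(fit.terms, key=lambda t: t[1])
    assert abs(fast[0]) < 1e-5 or fast[1] == pytest.approx(slow[1], rel=1e-3)


def test_fit_requires_three_samples():
    with pytest.raises(ValueError, match="3 samples"):
        fit_biexponential([(4.0, 0.1), (24.0, 0.05)], LU)


# ---------------------------------------------------------------------------
# I/O

def test_tiac_csv_round_trip(tmp_path):
    table = TIACTable(
        "lutetium-177",
        {r: v for r, v in zip(SOURCE_REGIONS, (1.6, 1.6, 2.5, 15.2, 0.3, 12.5))},
    )
    path = tmp_path / "tiac.csv"
    write_tiac_csv([table], path)
    (loaded,) = read_tiac_csv(path)
    assert loaded.nuclide_tag == "lutetium-177"
    for r in SOURCE_REGIONS:
        assert loaded[r] == pytest.approx(table[r], abs=5e-5)  # 4-decimal format


def test_tiac_table_rejects_unknown_region_and_negative_value():
    with pytest.raises(ValueError, match="unknown source region"):
        TIACTable("x", {"pancreas": 1.0})
    with pytest.raises(ValueError, match="negative"):
        TIACTable("x", {"liver": -0.1})
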