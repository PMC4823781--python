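"""Deformation energy: twist phasing, closed forms vs QP oracle, symmetries."""

import numpy as np
import pytest
from scipy.optimize import minimize

from nucdeform import (
    EnergyModelConfig,
    energy_profile,
    twist_phase,
    window_energy,
)
from nucdeform.params import revcomp


def _random_window(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))


TOY_CFG = dict(L=21, alpha=579.0 * 20 / 128, S=41.96 * 20 / 128)


# -- twist phase ------------------------------------------------------------


def test_uniform_window_twists_equal_omega_bar(table, cfg129):
    tp = twist_phase("A" * 129, table, cfg129)
    np.testing.assert_allclose(tp.scaled_twists, cfg129.omega_bar, rtol=1e-12)
    half = cfg129.half
    assert tp.cumulative[half] == pytest.approx(cfg129.omega_bar / 2)
    assert tp.cumulative[half - 1] == pytest.approx(-cfg129.omega_bar / 2)


def test_twist_sum_constraint_exact(table, cfg129, rng):
    for _ in range(25):
        w = _random_window(rng, 129)
        tp = twist_phase(w, table, cfg129)
        target = (cfg129.L - 1) * cfg129.omega_bar
        assert tp.scaled_twists.sum() == pytest.approx(target, rel=1e-9)


def test_phase_mirror_under_reverse_complement(table, cfg129, rng):
    w = _random_window(rng, 129)
    tp = twist_phase(w, table, cfg129)
    tq = twist_phase(revcomp(w), table, cfg129)
    np.testing.assert_allclose(tq.cumulative, -tp.cumulative[::-1], rtol=1e-9)


def test_ambiguous_base_rejected(table, cfg129):
    with pytest.raises(ValueError, match="ambiguous"):
        twist_phase("A" * 64 + "N" + "A" * 64, table, cfg129)


# -- closed form vs constrained quadratic minimizer ------------------------


def _qp_energy(window, table, cfg, block):
    """Constrained quadratic minimum via SLSQP (independent of closed form)."""
    tp = twist_phase(window, table, cfg)
    phases = np.deg2rad(tp.cumulative)
    cos, sin = np.cos(phases), np.sin(phases)
    steps = [window[i:i + 2] for i in range(len(window) - 1)]
    if block == "bend":
        x0 = np.concatenate([[table[s].roll0 for s in steps],
                             [table[s].tilt0 for s in steps]])
        k = np.concatenate([[table[s].k_roll for s in steps],
                            [table[s].k_tilt for s in steps]])
        target = cfg.alpha
    else:
        x0 = np.concatenate([[table[s].slide0 for s in steps],
                             [table[s].shift0 for s in steps]])
        k = np.concatenate([[table[s].k_slide for s in steps],
                            [table[s].k_shift for s in steps]])
        target = cfg.S
    proj = np.concatenate([cos, sin])

    def energy(x):
        return 0.5 * np.sum(k * (x - x0) ** 2)

    res = minimize(energy, x0, jac=lambda x: k * (x - x0), method="SLSQP",
                   constraints={"type": "eq",
                                "fun": lambda x: np.dot(proj, x) - target,
                                "jac": lambda x: proj},
                   options={"ftol": 1e-14, "maxiter": 500})
    assert res.success
    return res.fun / (len(window) - 1)


@pytest.mark.parametrize("block", ["bend", "shear"])
def test_energy_matches_qp_oracle(table, rng, block):
    cfg = EnergyModelConfig(**TOY_CFG)
    for _ in range(30):
        w = _random_window(rng, cfg.L)
        we = window_energy(w, table, cfg)
        closed = we.E_bend if block == "bend" else we.E_shear
        assert closed == pytest.approx(_qp_energy(w, table, cfg, block),
                                       rel=1e-8, abs=1e-10)


def test_presatisfied_constraint_gives_zero_energy(table, rng):
    """alpha equal to the intrinsic projected bend -> F_b = 0, E_bend = 0."""
    probe = EnergyModelConfig(**TOY_CFG)
    # find a window whose intrinsic projected bend is positive
    for _ in range(100):
        w = _random_window(rng, 21)
        tp = twist_phase(w, table, probe)
        phases = np.deg2rad(tp.cumulative)
        steps = [w[i:i + 2] for i in range(len(w) - 1)]
        a0 = sum(table[s].roll0 * np.cos(p) + table[s].tilt0 * np.sin(p)
                 for s, p in zip(steps, phases))
        if a0 > 1.0:
            break
    assert a0 > 1.0
    cfg = EnergyModelConfig(L=21, alpha=float(a0), S=TOY_CFG["S"])
    we = window_energy(w, table, cfg)
    assert we.F_b == pytest.approx(0.0, abs=1e-12)
    assert we.E_bend == pytest.approx(0.0, abs=1e-12)


def test_strand_symmetry_of_energies(table, cfg129, rng):
    for _ in range(200):
        w = _random_window(rng, 129)
        a = window_energy(w, table, cfg129)
        b = window_energy(revcomp(w), table, cfg129)
        assert a.E_bend == pytest.approx(b.E_bend, rel=1e-10)
        assert a.E_shear == pytest.approx(b.E_shear, rel=1e-10)


def test_energy_scales_linearly_with_force_constants(table, cfg129, make_window):
    """Multiplying all k by c multiplies both energies by c (linear constraint)."""
    from nucdeform.params import DinucParams, ParamTable

    w = make_window(129)
    c = 3.7
    scaled_entries = {
        d: DinucParams(d, p.roll0, p.tilt0, p.twist0, p.slide0, p.shift0,
                       c * p.k_roll, c * p.k_tilt, c * p.k_slide,
                       c * p.k_shift, p.n_obs)
        for d, p in table.entries.items()
    }
    scaled = ParamTable(scaled_entries)
    a = window_energy(w, table, cfg129)
    b = window_energy(w, scaled, cfg129)
    assert b.E_bend == pytest.approx(c * a.E_bend, rel=1e-10)
    assert b.E_shear == pytest.approx(c * a.E_shear, rel=1e-10)


def test_total_is_sum_of_parts(table, cfg129, make_window):
    we = window_energy(make_window(129), table, cfg129)
    assert we.E_total == we.E_bend + we.E_shear
    assert we.E_bend >= 0 and we.E_shear >= 0


def test_constraints_satisfied_after_response(table, cfg129, make_window):
    """Realised phase-projected bend equals alpha to 1e-9 relative."""
    w = make_window(129)
    we = window_energy(w, table, cfg129)
    tp = twist_phase(w, table, cfg129)
    phases = np.deg2rad(tp.cumulative)
    cos, sin = np.cos(phases), np.sin(phases)
    steps = [w[i:i + 2] for i in range(len(w) - 1)]
    realized_bend = sum(
        (table[s].roll0 + we.F_b * c / table[s].k_roll) * c
        + (table[s].tilt0 + we.F_b * si / table[s].k_tilt) * si
        for s, c, si in zip(steps, cos, sin))
    realized_shear = sum(
        (table[s].slide0 + we.F_s * c / table[s].k_slide) * c
        + (table[s].shift0 + we.F_s * si / table[s].k_shift) * si
        for s, c, si in zip(steps, cos, sin))
    assert realized_bend == pytest.approx(cfg129.alpha, rel=1e-9)
    assert realized_shear == pytest.approx(cfg129.S, rel=1e-9)


# -- profiles ---------------------------------------------------------------


def test_profile_constant_on_homopolymer(table, cfg129):
    prof = energy_profile("A" * 300, table, cfg129)
    assert len(prof) == 300 - 129 + 1
    np.testing.assert_allclose(prof.bend, prof.bend[0], rtol=1e-12)
    np.testing.assert_allclose(prof.total, prof.bend + prof.shear)


def test_profile_reverse_complement_is_reversed(table, cfg129, rng):
    seq = _random_window(rng, 400)
    a = energy_profile(seq, table, cfg129)
    b = energy_profile(revcomp(seq), table, cfg129)
    np.testing.assert_allclose(b.bend, a.bend[::-1], rtol=1e-9)
    np.testing.assert_allclose(b.shear, a.shear[::-1], rtol=1e-9)


def test_profile_matches_window_energy(table, cfg129, rng):
    seq = _random_window(rng, 200)
    prof = energy_profile(seq, table, cfg129)
    for k in (0, 31, len(prof) - 1):
        c = prof.start_offset + k
        we = window_energy(seq[c - 64:c + 65], table, cfg129)
        assert prof.bend[k] == pytest.approx(we.E_bend, rel=1e-12)
        assert prof.shear[k] == pytest.approx(we.E_shear, rel=1e-12)


def test_ambiguous_windows_flagged_not_zeroed(table, cfg129, rng):
    seq = _random_window(rng, 300)
    seq = seq[:150] + "N" + seq[151:]
    prof = energy_profile(seq, table, cfg129)
    hit = np.abs(prof.centers() - 150) <= 64
    assert not prof.valid[hit].any()
    assert np.isnan(prof.bend[hit]).all()
    assert prof.valid[~hit].all()


def test_short_sequence_gives_empty_profile(table, cfg129):
    with pytest.warns(UserWarning, match="shorter than window"):
        prof = energy_profile("ACGT" * 10, table, cfg129)
    assert len(prof) == 0


def test_129_vs_147_profiles_positively_correlated(table, rng):
    """Window-length robustness on a 10-kb synthetic genome (R > 0.8)."""
    from nucdeform import SynthSpec, pearson, synth_sequence

    spec = SynthSpec(seed=99, length=10_000,
                     periodic_dinucs=(("AA", 10, 0), ("GC", 10, 5)))
    seq = synth_sequence(spec)
    p129 = energy_profile(seq, table, EnergyModelConfig(L=129))
    p147 = energy_profile(seq, table, EnergyModelConfig(L=147))
    # align on shared dyad positions
    lo = p147.start_offset
    hi = lo + len(p147)
    a = p129.bend[lo - p129.start_offset: hi - p129.start_offset]
    assert pearson(a, p147.bend) > 0.8
    a = p129.shear[lo - p129.start_offset: hi - p129.start_offset]
    assert pearson(a, p147.shear) > 0.8


def test_bending_profile_oscillates_near_10bp(table, cfg129):
    """Phased AA planting produces ~10-bp bending-energy oscillation."""
    from nucdeform import SynthSpec, synth_sequence
    from nucdeform.dyads import band_fraction

    spec = SynthSpec(seed=5, length=600,
                     periodic_dinucs=(("AA", 10, 0), ("CG", 10, 5)))
    prof = energy_profile(synth_sequence(spec), table, cfg129)
    frac = band_fraction(prof.bend[:256])
    assert frac > 0.2  # far above the ~0.05 white-noise band fraction
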