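"""Toy Monte Carlo simulator: geometry, sampling, RDFs, oracles."""

import math

import numpy as np
import pytest

from hydralk import forcefield as ff
from hydralk import toy_simulator as toy
from hydralk.fep_estimator import ThermoState, accumulate, make_lambda_schedule


def _spec(**kw):
    base = dict(
        n_solvent=48,
        density=8.0,
        T=300.0,
        seed=13,
        cutoff_ss=ff.CutoffSpec(0.8),
        cutoff_su=ff.CutoffSpec(0.85),
        n_sweeps=30,
        n_burnin=10,
    )
    base.update(kw)
    return toy.SimSpec(**base)


# ---------------------------------------------------------------------------
# chain geometry
# ---------------------------------------------------------------------------

def test_methane_is_single_site_at_origin():
    coords, labels = toy.build_alkane_chain(ff.AlkaneSpec(1))
    assert coords.shape == (1, 3)
    assert np.allclose(coords, 0.0)
    assert labels == ["CH4"]


def test_ethane_bond_length():
    coords, labels = toy.build_alkane_chain(ff.AlkaneSpec(2))
    assert np.linalg.norm(coords[1] - coords[0]) == pytest.approx(toy.CC_BOND)
    assert labels == ["CH3", "CH3"]


def test_backbone_angle_and_bond_lengths_along_chain():
    coords, _ = toy.build_alkane_chain(ff.AlkaneSpec(8))
    bonds = np.diff(coords, axis=0)
    assert np.allclose(np.linalg.norm(bonds, axis=1), toy.CC_BOND)
    for b1, b2 in zip(bonds, bonds[1:]):
        cosang = -np.dot(b1, b2) / (np.linalg.norm(b1) * np.linalg.norm(b2))
        assert math.degrees(math.acos(cosang)) == pytest.approx(toy.CCC_ANGLE_DEG)


def test_eicosane_end_to_end_matches_closed_form():
    n = 20
    coords, _ = toy.build_alkane_chain(ff.AlkaneSpec(n))
    half = math.radians(toy.CCC_ANGLE_DEG) / 2
    dx = (n - 1) * toy.CC_BOND * math.sin(half)
    dz = ((n - 1) % 2) * toy.CC_BOND * math.cos(half)
    expected = math.hypot(dx, dz)
    got = np.linalg.norm(coords[-1] - coords[0])
    assert got == pytest.approx(expected, rel=1e-12)


# ---------------------------------------------------------------------------
# Metropolis sampling contracts
# ---------------------------------------------------------------------------

def test_same_seed_gives_bit_identical_window_samples(toy_solvent_pair, toy_cross_pair):
    sched = make_lambda_schedule(0.25)
    solute = np.zeros((1, 3))
    out = []
    for _ in range(2):
        _, wins = toy.mc_run(_spec(), solute, [toy_cross_pair], sched, toy_solvent_pair)
        out.append(wins)
    for a, b in zip(*out):
        assert np.array_equal(a.dU, b.dU)
        assert np.array_equal(a.V, b.V)


def test_no_solvent_means_zero_gaps_and_zero_total(toy_cross_pair, ts300):
    sched = make_lambda_schedule(0.25)
    _, wins = toy.mc_run(
        _spec(n_solvent=0), np.zeros((1, 3)), [toy_cross_pair], sched,
        ff.PairPar(0.4, 0.34),
    )
    assert all(np.all(w.dU == 0.0) for w in wins)
    assert accumulate(wins, ts300).total == 0.0


def test_energy_bookkeeping_matches_recomputation(toy_solvent_pair, toy_cross_pair):
    traj, _ = toy.mc_run(
        _spec(n_sweeps=20), np.zeros((1, 3)), [toy_cross_pair],
        make_lambda_schedule(0.5), toy_solvent_pair,
    )
    assert traj.energy_drift < 1e-8


def test_reverse_run_starts_coupled_and_samples_descending(toy_solvent_pair, toy_cross_pair):
    sched = make_lambda_schedule(0.25)
    _, wins = toy.mc_run(
        _spec(), np.zeros((1, 3)), [toy_cross_pair], sched, toy_solvent_pair,
        direction="reverse",
    )
    assert [w.lam_i for w in wins] == [1.0, 0.75, 0.5, 0.25]
    assert all(w.lam_j < w.lam_i for w in wins)


def test_npt_mode_produces_fluctuating_volumes(toy_solvent_pair, toy_cross_pair, ts300):
    spec = _spec(npt=True, n_sweeps=60, n_burnin=20, seed=5)
    _, wins = toy.mc_run(
        spec, np.zeros((1, 3)), [toy_cross_pair], make_lambda_schedule(0.5),
        toy_solvent_pair,
    )
    vols = np.concatenate([w.V for w in wins])
    assert vols.std() > 0.0
    res = accumulate(wins, ts300)
    assert np.isfinite(res.total)


# ---------------------------------------------------------------------------
# radial distribution function
# ---------------------------------------------------------------------------

def test_ideal_gas_rdf_is_flat(ts300):
    spec = _spec(n_solvent=100, n_sweeps=150, n_burnin=10, frame_every=1,
                 seed=99, density=8.0)
    traj = toy.run_solvent(spec, ff.PairPar(0.0, 0.34))
    rdf = toy.compute_rdf(traj, "solvent", 0.05, 0.49 * spec.box_edge)
    # every bin within counting noise of 1 (no structure at all)
    assert np.all(np.abs(rdf.g - 1.0) < 0.15)
    assert abs(rdf.g.mean() - 1.0) < 0.02


def test_two_fixed_particles_fill_single_bin():
    d = 0.52
    frame = toy.Frame(np.array([[1.0, 1.0, 1.0], [1.0, 1.0, 1.0 + d]]), 4.0, 0.0)
    traj = toy.Trajectory(frames=[frame], solute_positions=None)
    rdf = toy.compute_rdf(traj, "solvent", 0.05, 1.9)
    nonzero = np.nonzero(rdf.g)[0]
    assert len(nonzero) == 1
    assert abs(rdf.r_centers[nonzero[0]] - d) <= 0.05


def test_rdf_closure_recovers_in_range_neighbor_count():
    rng = np.random.default_rng(21)
    box = 3.0
    frames = [toy.Frame(rng.uniform(0, box, (64, 3)), box, 0.0) for _ in range(40)]
    traj = toy.Trajectory(frames=frames, solute_positions=None)
    r_max = 1.45
    rdf = toy.compute_rdf(traj, "solvent", 0.05, r_max)
    shell = 4 * math.pi * rdf.r_centers**2 * rdf.bin_width
    implied = (rdf.rho_used * rdf.g * shell).sum()
    # direct mean count of neighbors within r_max
    direct = []
    for fr in frames:
        dvec = fr.positions[:, None, :] - fr.positions[None, :, :]
        dvec -= box * np.round(dvec / box)
        r = np.sqrt((dvec**2).sum(-1))
        direct.append(((r > 0) & (r <= r_max)).sum() / 64)
    assert implied == pytest.approx(np.mean(direct), rel=0.02)


def test_rdf_rejects_r_max_beyond_half_box():
    frame = toy.Frame(np.zeros((2, 3)), 2.0, 0.0)
    traj = toy.Trajectory(frames=[frame], solute_positions=None)
    with pytest.raises(ValueError):
        toy.compute_rdf(traj, "solvent", 0.05, 1.5)


def test_toy_solvent_rdf_is_near_unity_beyond_first_shell(toy_solvent_pair):
    spec = _spec(n_solvent=150, n_sweeps=300, n_burnin=30, frame_every=1, seed=31)
    traj = toy.run_solvent(spec, toy_solvent_pair)
    rdf = toy.compute_rdf(traj, "solvent", 0.04, 0.49 * spec.box_edge)
    beyond = rdf.r_centers > 1.5 * toy_solvent_pair.sigma
    assert np.all(np.abs(rdf.g[beyond] - 1.0) < 0.1)


# ---------------------------------------------------------------------------
# Widom insertion and the low-density closed form
# ---------------------------------------------------------------------------

def test_phantom_particle_has_zero_excess_chemical_potential(ts300):
    frame = toy.Frame(np.random.default_rng(0).uniform(0, 2, (20, 3)), 2.0, 0.0)
    traj = toy.Trajectory(frames=[frame], solute_positions=None)
    mu = toy.widom_mu_excess(traj, ff.PairPar(0.0, 0.3), ts300, 100, seed=1)
    assert mu == 0.0
    with pytest.raises(ValueError):
        toy.widom_mu_excess(traj, ff.PairPar(0.1, 0.3), ts300, 0, seed=1)


def test_widom_in_dilute_solvent_matches_low_density_form(ts300, toy_cross_pair):
    spec = _spec(n_solvent=30, density=0.5, n_sweeps=150, n_burnin=10,
                 frame_every=1, seed=17, cutoff_su=ff.CutoffSpec(1.2))
    traj = toy.run_solvent(spec, ff.PairPar(0.0, 0.34))
    mu, se = toy.widom_mu_excess(
        traj, toy_cross_pair, ts300, 2000, seed=18, rc=1.2, return_se=True
    )
    ref = toy.low_density_mu_excess(toy_cross_pair, 0.5, ts300, rc=1.2)
    assert mu == pytest.approx(ref, abs=max(3 * se, 0.01))


def test_low_density_closed_form_against_mc_quadrature(ts300, toy_cross_pair):
    got = toy.low_density_mu_excess(toy_cross_pair, 0.4, ts300)
    # brute-force Monte Carlo estimate of the same Mayer integral
    rng = np.random.default_rng(5)
    upper = 10 * toy_cross_pair.sigma
    r = rng.uniform(0, upper, 400_000)
    u = np.where(
        r > 1e-9,
        4 * toy_cross_pair.epsilon
        * ((toy_cross_pair.sigma / r) ** 12 - (toy_cross_pair.sigma / r) ** 6),
        1e9,
    )
    integrand = (1 - np.exp(-np.clip(u / ts300.kT, -700, 700))) * 4 * math.pi * r**2
    mc = upper * integrand.mean()
    assert got == pytest.approx(ts300.kT * 0.4 * mc, rel=0.02)


def test_low_density_zero_epsilon_is_zero(ts300):
    assert toy.low_density_mu_excess(ff.PairPar(0.0, 0.3), 1.0, ts300) == 0.0


def test_low_density_warns_when_expansion_unreliable(ts300):
    with pytest.warns(UserWarning, match="unreliable"):
        toy.low_density_mu_excess(ff.PairPar(3.0, 0.5), 40.0, ts300)


# ---------------------------------------------------------------------------
# synthetic gap fixture
# ---------------------------------------------------------------------------

def test_gaussian_gap_samples_contract():
    w = toy.gaussian_gap_samples(2.5, 0.0, 10, seed=1)
    assert np.all(w.dU == 2.5)
    a = toy.gaussian_gap_samples(0.0, 1.0, 50, seed=9)
    b = toy.gaussian_gap_samples(0.0, 1.0, 50, seed=9)
    assert np.array_equal(a.dU, b.dU)
    ln = toy.gaussian_gap_samples(0.0, 1.0, 50, seed=9, v_mode="lognormal")
    assert ln.V.std() > 0.0
    with pytest.raises(ValueError):
        toy.gaussian_gap_samples(0.0, -1.0, 5, seed=0)


# ---------------------------------------------------------------------------
# output formats
# ---------------------------------------------------------------------------

def test_xyz_and_rdf_files_roundtrip(tmp_path, toy_solvent_pair):
    spec = _spec(n_sweeps=10, n_burnin=2, frame_every=1)
    traj = toy.run_solvent(spec, toy_solvent_pair)
    xyz = tmp_path / "t.xyz"
    toy.write_xyz(traj, xyz)
    text = xyz.read_text().splitlines()
    assert int(text[0]) == spec.n_solvent
    elog = tmp_path / "e.tsv"
    toy.write_energy_log(traj, elog)
    assert len(elog.read_text().splitlines()) == len(traj.frames) + 1
    rdf = toy.compute_rdf(traj, "solvent", 0.1, 0.45 * spec.box_edge)
    p = tmp_path / "g.tsv"
    toy.write_rdf_tsv(rdf, p)
    back = toy.read_rdf_tsv(p)
    assert np.allclose(back.g, rdf.g)
    assert back.rho_used == pytest.approx(rdf.rho_used)
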