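import numpy as np
import pytest

import nanosyn as ns
from nanosyn.engine import _Batch


def test_no_ligand_means_no_current(numerics):
    p = ns.SimulationParameters(nnt=0)
    res = ns.run_ensemble(p, numerics.replace(duration_ms=0.1), n_reps=2, seed=1)
    assert np.all(res.current == 0.0)
    assert np.all(res.opening_counts == 0)


def test_no_receptors_means_no_current_and_full_clearance():
    p = ns.SimulationParameters(nnt=500, n_c=0, n_r=0, R=200.0)
    num = ns.NumericsConfig(duration_ms=1.0)
    res = ns.run_ensemble(p, num, n_reps=3, seed=2,
                          options=ns.EngineOptions(check_conservation=True))
    assert np.all(res.current == 0.0)
    # with a 200 nm rim every molecule is absorbed well before 1 ms
    assert np.all(res.absorbed[:, -1] >= 0.99 * p.nnt)
    assert np.all(np.diff(res.absorbed.astype(int), axis=1) >= 0)


def test_same_seed_bit_identical():
    p = ns.SimulationParameters(nnt=300, ani=0.5)
    num = ns.NumericsConfig(duration_ms=0.3)
    a = ns.run_ensemble(p, num, n_reps=3, seed=7)
    b = ns.run_ensemble(p, num, n_reps=3, seed=7)
    assert np.array_equal(a.current, b.current)
    assert np.array_equal(a.opening_counts, b.opening_counts)
    assert np.array_equal(a.capture_counts, b.capture_counts)
    c = ns.run_ensemble(p, num, n_reps=3, seed=8)
    assert not np.array_equal(a.current, c.current)


def test_transient_shape(fig3_run):
    """The mean current rises within 0.3 ms and decays towards zero."""
    mean = fig3_run.mean_current
    t = fig3_run.time_ms
    ipk = int(np.argmax(mean))
    assert 0 < t[ipk] < 0.3
    assert mean[ipk] > 5.0
    assert mean[-1] < 0.2 * mean[ipk]


def test_molecule_bookkeeping(fig3_run):
    """free + bound + absorbed = nnt at the final step of every repetition."""
    # absorbed is cumulative; captures and openings are consistent counters
    assert np.all(fig3_run.absorbed[:, -1] <= fig3_run.params.nnt)
    assert np.all(fig3_run.capture_counts >= 0)
    # every opening implies at least one capture happened in that repetition
    opened = fig3_run.opening_counts.sum(axis=1) > 0
    captured = (fig3_run.capture_counts >= 1).sum(axis=1) > 0
    assert np.all(~opened | captured)


def test_field_feedback_reduces_current_in_narrow_cleft():
    """With 80 clustered channels and a 10 nm cleft the potential feedback
    measurably lowers the peak current (field off -> larger current)."""
    p = ns.SimulationParameters(nnt=5000, ani=0.5, n_c=80, n_r=0, H_c=10.0)
    num = ns.NumericsConfig(duration_ms=0.6)
    on = ns.run_ensemble(p, num, n_reps=4, seed=3)
    off = ns.run_ensemble(p, num, n_reps=4, seed=3,
                          options=ns.EngineOptions(field_enabled=False,
                                                   drift_enabled=False))
    peak_on = on.mean_current.max()
    peak_off = off.mean_current.max()
    assert peak_off > peak_on * 1.01
    assert on.max_depolarization_mV.mean() > 1.0


def test_single_event_train_equals_single_release():
    p = ns.SimulationParameters(nnt=400, ani=0.5)
    num = ns.NumericsConfig(duration_ms=2.0)
    single = ns.run_ensemble(p, num, n_reps=2, seed=9)
    train = ns.run_train(p, ns.NumericsConfig(), frequency_hz=500.0, n_events=1,
                         seed=9, n_reps=2)
    assert np.array_equal(single.current, train.current)


def test_train_desensitization_and_lateral_mitigation():
    """Across a high-frequency train the response declines (cumulative desensitization);
    receptor lateral diffusion replenishes the pool and lessens the decline."""
    p = ns.SimulationParameters(nnt=2000, ani=0.0, n_c=0, n_r=80, D_r=1.0)
    num = ns.NumericsConfig(dt_ns=100.0)
    fixed = ns.run_train(p, num, frequency_hz=150.0, n_events=3, seed=4, n_reps=4,
                         options=ns.EngineOptions(lateral_diffusion=False))
    moving = ns.run_train(p, num, frequency_hz=150.0, n_events=3, seed=4, n_reps=4,
                          options=ns.EngineOptions(lateral_diffusion=True))
    pk_fixed = fixed.event_peaks_pA()
    assert pk_fixed[2] < pk_fixed[0]
    # desensitized fraction just before the third release
    i = np.searchsorted(fixed.time_ms, fixed.event_times_ms[2]) - 1
    assert moving.desensitized_fraction[i] < fixed.desensitized_fraction[i]


def test_lateral_walk_diffusion_limit(numerics):
    """Excluded-volume lattice walk of a lone receptor recovers MSD ~ 4 D_r t."""
    p = ns.SimulationParameters(nnt=0, n_c=1, n_r=0, D_r=1.0)
    batch = _Batch(p, ns.NumericsConfig(duration_ms=1.0), n_reps=60, seed=5,
                   options=ns.EngineOptions(lateral_diffusion=True))
    x0, y0 = batch.rec_x.copy(), batch.rec_y.copy()
    batch.run()
    msd = np.mean((batch.rec_x - x0) ** 2 + (batch.rec_y - y0) ** 2)
    t_s = 1.0e-3
    expect = 4 * p.D_r * 1e6 * t_s  # nm^2
    assert msd == pytest.approx(expect, rel=0.25)
    # exclusion invariant: one receptor per occupied cell
    occ = batch.occupancy
    assert np.all(np.sum(occ >= 0, axis=(1, 2)) == 1)


def test_zero_lateral_diffusion_keeps_layout(numerics):
    p = ns.SimulationParameters(nnt=0, n_c=10, n_r=10, D_r=0.0)
    batch = _Batch(p, ns.NumericsConfig(duration_ms=0.05), n_reps=2, seed=6,
                   options=ns.EngineOptions(lateral_diffusion=True))
    x0 = batch.rec_x.copy()
    batch.run()
    assert np.array_equal(batch.rec_x, x0)


def test_random_release_distances_within_psd():
    p = ns.SimulationParameters(nnt=50, ani=0.5)
    res = ns.run_random_release_events(p, ns.NumericsConfig(duration_ms=0.05),
                                       n_events=12, seed=10)
    assert len(res.release_distances_nm) == 12
    assert np.all(res.release_distances_nm <= p.D_dr / 2)


def test_confined_lateral_diffusion_respects_nanocolumn_edge():
    """In confined mode no receptor crosses the nanocolumn boundary."""
    p = ns.SimulationParameters(nnt=0, n_c=20, n_r=20, D_r=1.0)
    batch = _Batch(p, ns.NumericsConfig(duration_ms=0.5), n_reps=5, seed=11,
                   options=ns.EngineOptions(lateral_diffusion=True,
                                            lateral_confined=True))
    inside0 = batch.lat_inside_col.copy()
    batch.run()
    inside1 = batch.rec_x**2 + batch.rec_y**2 < (p.D_ani / 2) ** 2
    assert np.array_equal(inside0, inside1)
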