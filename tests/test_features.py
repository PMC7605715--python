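"""Time-series statistics: medians, RMSF, AUC, distributions."""

import numpy as np
import pytest

from retinotune.exceptions import MissingAtomError, RetinotuneError
from retinotune.features import (
    FeatureSeries,
    angle_time_series,
    auc_rmsf,
    circular_median,
    compare_paralog_distributions,
    frequency_distribution,
    rmsf,
    summarize,
    wrap_degrees,
)
from retinotune.geometry import default_registry, dihedral, bond_angle
from retinotune.io import Trajectory
from retinotune.synthetic import SyntheticSpec, synth_angle_series, synth_trajectory


@pytest.fixture(scope="module")
def traj():
    return synth_trajectory(n_frames=100, seed=9, pigment_id="synthetic")


@pytest.fixture(scope="module")
def series(traj):
    return angle_time_series(traj, default_registry())


def test_series_shape(series):
    assert len(series.values) == 19
    assert series.n_frames == 100


def test_static_trajectory_constant_series():
    traj = synth_trajectory(n_frames=5, jitter_angstrom=0.0, seed=0)
    series = angle_time_series(traj, default_registry())
    for vals in series.values.values():
        assert np.ptp(vals) == 0.0


def test_medians_match_naive_per_frame_oracle(traj, series):
    """Per-parameter medians equal brute-force frame-by-frame evaluation."""
    registry = default_registry()
    summary = summarize(series)
    for d in registry:
        naive = []
        for t in range(traj.n_frames):
            frame = traj.frame_mapping(t)
            pts = [frame[a] for a in d.atoms]
            naive.append(dihedral(*pts) if d.kind == "torsion" else bond_angle(*pts))
        naive = np.asarray(naive)
        # independent seam handling: if the raw values straddle ±180°, move
        # the branch cut to 0° (add 180 mod 360) before the sorted median
        shifted = naive.max() - naive.min() > 180.0
        if shifted:
            naive = np.mod(naive, 360.0)  # contiguous branch with cut at 0°
        naive = np.sort(naive)
        expected = wrap_degrees(0.5 * (naive[49] + naive[50]))
        assert abs(wrap_degrees(summary.medians[d.name] - expected)) < 1e-6


def test_circular_median_straddling_seam():
    """{175°, −175°, 179°} has branch median 179°, not the naive ~60°."""
    values = [175.0, -175.0, 179.0]
    # independent oracle: enumerate branch representations and take the
    # ordinary median on the contiguous branch
    unwrapped = [175.0, 185.0, 179.0]
    expected = wrap_degrees(np.median(unwrapped))
    got = circular_median(values)
    assert got == pytest.approx(expected, abs=1e-9)
    assert got == pytest.approx(179.0, abs=1e-9)
    assert abs(np.median(values)) > 100.0  # the naive median is on the wrong branch


def test_summarize_permutation_invariant(series, rng):
    summary = summarize(series)
    perm = rng.permutation(series.n_frames)
    shuffled = FeatureSeries(
        series.pigment_id,
        {k: v[perm] for k, v in series.values.items()},
        series.kinds,
    )
    other = summarize(shuffled)
    for name in summary.medians:
        assert other.medians[name] == pytest.approx(summary.medians[name], abs=1e-12)


def test_summarize_empty_series_errors():
    empty = FeatureSeries("x", {}, {})
    with pytest.raises(RetinotuneError):
        summarize(empty)


class TestRmsf:
    def test_static_trajectory_zero(self):
        traj = synth_trajectory(n_frames=5, jitter_angstrom=0.0, seed=0)
        profile = rmsf(traj, align=False)
        assert np.allclose(profile.to_numpy(), 0.0)

    def test_one_dimensional_oscillation_closed_form(self):
        coords = np.zeros((4, 2, 3))
        coords[:, 1, 0] = 5.0  # second atom fixed elsewhere
        coords[:, 0, 0] = [-1.0, 1.0, -1.0, 1.0]  # oscillates x = ±1
        traj = Trajectory(("C1", "C2"), coords)
        profile = rmsf(traj, align=False)
        assert profile["C1"] == pytest.approx(1.0, abs=1e-12)
        assert profile["C2"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_two_pass_oracle(self, traj):
        profile = rmsf(traj, align=False)
        x = traj.coords
        mean = x.mean(axis=0)
        oracle = np.sqrt(((x - mean) ** 2).sum(axis=2).mean(axis=0))
        np.testing.assert_allclose(profile.to_numpy(), oracle, atol=1e-9)

    def test_alignment_removes_rigid_motion(self):
        """Frames that are rigid rotations of one structure have zero RMSF."""
        from scipy.spatial.transform import Rotation

        base = synth_trajectory(n_frames=1, jitter_angstrom=0.0, seed=0).coords[0]
        rots = Rotation.random(5, random_state=np.random.RandomState(3))
        coords = np.stack([base @ r.as_matrix().T + i for i, r in enumerate(rots)])
        traj = Trajectory(
            tuple(synth_trajectory(n_frames=1, seed=0).atom_names), coords
        )
        aligned = rmsf(traj, align=True)
        assert aligned.max() < 1e-9
        assert rmsf(traj, align=False).max() > 1.0

    def test_subset_and_errors(self, traj):
        sub = rmsf(traj, atom_subset=["CE", "NZ"], align=False)
        assert list(sub.index) == ["CE", "NZ"]
        with pytest.raises(MissingAtomError):
            rmsf(traj, atom_subset=["QQ"])
        single = Trajectory(("C1",), np.zeros((1, 1, 3)))
        with pytest.raises(RetinotuneError):
            rmsf(single)


class TestAucRmsf:
    def test_constant_profile_rectangle(self):
        assert auc_rmsf([0.7] * 5) == pytest.approx(0.7 * 4)

    def test_triangle(self):
        assert auc_rmsf([0.0, 1.0, 0.0]) == pytest.approx(1.0)

    def test_matches_piecewise_oracle(self, rng):
        for _ in range(20):
            v = rng.uniform(0, 2, size=rng.integers(2, 30))
            oracle = sum(0.5 * (v[i] + v[i + 1]) for i in range(len(v) - 1))
            assert auc_rmsf(v) == pytest.approx(oracle, abs=1e-12)

    def test_linear_in_profile(self, rng):
        a = rng.uniform(0, 1, size=10)
        b = rng.uniform(0, 1, size=10)
        assert auc_rmsf(2 * a + 3 * b) == pytest.approx(
            2 * auc_rmsf(a) + 3 * auc_rmsf(b), abs=1e-10
        )

    def test_needs_two_atoms(self):
        with pytest.raises(RetinotuneError):
            auc_rmsf([1.0])


class TestFrequencyDistribution:
    def test_masses_sum_to_one(self, rng):
        hist = frequency_distribution(rng.normal(120, 5, size=1000))
        assert hist.masses.sum() == pytest.approx(1.0, abs=1e-12)

    def test_single_value_one_bin(self):
        hist = frequency_distribution([42.0, 42.0, 42.0])
        assert (hist.masses > 0).sum() == 1

    def test_invalid_bin_width(self):
        with pytest.raises(RetinotuneError):
            frequency_distribution([1.0, 2.0], bin_width=0.0)


def test_paralog_groups_ordered_by_fluctuation_width():
    """Sws2b pigments generated with wider fluctuations show larger IQR."""
    spec = SyntheticSpec(seed=21, n_frames=500, width_sws2a_deg=2.0, width_sws2b_deg=8.0)
    series, dataset, _ = synth_angle_series(spec, parameters=["Angle 2"])
    paralog_of = {r.pigment_id: r.paralog for r in dataset}
    # keep the two duplicated-gene groups, as in the paralog comparison
    series = {
        pid: s for pid, s in series.items() if paralog_of[pid] in ("Sws2a", "Sws2b")
    }
    cmp = compare_paralog_distributions(series, paralog_of, "Angle 2")
    assert cmp.wider_group() == "Sws2b"
    assert cmp.iqr["Sws2b"] > cmp.iqr["Sws2a"]
    assert cmp.variance["Sws2b"] > cmp.variance["Sws2a"]
    assert cmp.histograms["Sws2b"].masses.sum() == pytest.approx(1.0, abs=1e-12)


def test_paralog_comparison_missing_parameter():
    spec = SyntheticSpec(seed=21, n_frames=10)
    series, dataset, _ = synth_angle_series(spec, parameters=["Angle 2"])
    paralog_of = {r.pigment_id: r.paralog for r in dataset}
    with pytest.raises(RetinotuneError, match="Angle 4"):
        compare_paralog_distributions(series, paralog_of, "Angle 4")
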