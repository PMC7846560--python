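"""Kabsch superposition, TM-score, the iterative aligner, subset rule."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from pvrscan.superposition import (
    AlignmentError,
    PairwiseAlignment,
    RigidTransform,
    align_pair,
    kabsch,
    select_subset,
    seq_identity,
    tm_d0,
    tm_score,
)
from pvrscan.synthetic import PlantedRegion, SyntheticEnsembleSpec, generate_ensemble


def random_points(rng, n):
    return rng.uniform(-10, 10, size=(n, 3))


def random_rotation(rng):
    q = rng.standard_normal(4)
    return Rotation.from_quat(q / np.linalg.norm(q)).as_matrix()


class TestKabsch:
    def test_identity_on_equal_sets(self):
        rng = np.random.default_rng(0)
        P = random_points(rng, 4)
        tr, rmsd = kabsch(P, P)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(tr.rotation, np.eye(3), atol=1e-9)
        assert np.allclose(tr.translation, 0.0, atol=1e-9)

    def test_recovers_known_motion(self):
        rng = np.random.default_rng(1)
        P = random_points(rng, 4)
        R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        Q = (P - np.array([1.0, 2.0, 3.0])) @ R.T  # inverse motion applied to P
        tr, rmsd = kabsch(P, Q)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(tr.apply(Q), P, atol=1e-9)

    def test_reflection_corrected(self):
        rng = np.random.default_rng(2)
        P = random_points(rng, 6)
        Q = P.copy()
        Q[:, 0] *= -1  # mirror image: best proper rotation cannot reach rmsd 0
        tr, rmsd = kabsch(P, Q)
        assert np.linalg.det(tr.rotation) == pytest.approx(1.0, abs=1e-9)
        assert rmsd > 0.1

    def test_errors(self):
        with pytest.raises(AlignmentError):
            kabsch(np.zeros((2, 3)), np.zeros((2, 3)))
        with pytest.raises(AlignmentError):
            kabsch(np.zeros((4, 3)), np.zeros((5, 3)))
        line = np.column_stack([np.arange(4.0), np.zeros(4), np.zeros(4)])
        with pytest.raises(AlignmentError):
            kabsch(line, line)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10_000), n=st.integers(4, 12))
    def test_rmsd_invariant_under_common_rigid_motion(self, seed, n):
        """Moving both point sets by the same rigid motion leaves the
        minimal RMSD unchanged."""
        rng = np.random.default_rng(seed)
        P = random_points(rng, n)
        Q = P + rng.normal(0, 0.5, size=P.shape)
        _, r0 = kabsch(P, Q)
        R = random_rotation(rng)
        t = rng.uniform(-5, 5, 3)
        _, r1 = kabsch(P @ R.T + t, Q @ R.T + t)
        assert r1 == pytest.approx(r0, abs=1e-6)


class TestRigidTransform:
    def test_inverse_round_trip(self):
        rng = np.random.default_rng(3)
        tr = RigidTransform(random_rotation(rng), rng.uniform(-5, 5, 3))
        X = random_points(rng, 7)
        assert np.allclose(tr.inverse().apply(tr.apply(X)), X, atol=1e-9)

    def test_rejects_improper_rotation(self):
        with pytest.raises(AlignmentError):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))


class TestTMScore:
    def test_perfect_self_alignment(self):
        assert tm_score(np.zeros(100), 100) == pytest.approx(1.0)

    def test_all_distances_at_d0(self):
        d0 = tm_d0(80)
        assert tm_score(np.full(80, d0), 80) == pytest.approx(0.5)

    def test_half_coverage(self):
        assert tm_score(np.zeros(50), 100) == pytest.approx(0.5)

    def test_domain_errors(self):
        with pytest.raises(AlignmentError):
            tm_score([1.0], 15)
        with pytest.raises(AlignmentError):
            tm_score([-0.1], 100)
        with pytest.raises(AlignmentError):
            tm_score([], 100)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_monotone_in_distances(self, seed):
        """Increasing any aligned-pair distance never increases the score."""
        rng = np.random.default_rng(seed)
        d = rng.uniform(0, 10, size=40)
        s0 = tm_score(d, 40)
        i = rng.integers(0, 40)
        d2 = d.copy()
        d2[i] += rng.uniform(0.1, 5)
        assert tm_score(d2, 40) <= s0 + 1e-12


def _rigid_pair(seed=5, n=80):
    """Same chain under two rigid frames (no indels, no noise)."""
    spec = SyntheticEnsembleSpec(
        n_structures=2,
        core_blocks=(n // 2, n - n // 2),
        planted_regions=(),
        noise_sigma=0.0,
        seed=seed,
    )
    return generate_ensemble(spec).structures


class TestAlignPair:
    def test_self_alignment(self, small_spec):
        s = generate_ensemble(small_spec).structures[0]
        al = align_pair(s, s)
        assert al.n_aligned == s.n_polymer_residues
        assert al.rmsd == pytest.approx(0.0, abs=1e-6)
        assert al.tm_score == pytest.approx(1.0, abs=1e-9)
        assert al.seq_identity == pytest.approx(100.0)

    def test_rigid_case_recovers_all_pairs(self):
        a, b = _rigid_pair()
        al = align_pair(a, b)
        assert al.n_aligned == a.n_polymer_residues
        assert al.rmsd == pytest.approx(0.0, abs=1e-6)
        # mapping is the identity on residue numbers
        assert all(ra.seq_id == rb.seq_id for ra, rb in al.pairs)

    def test_symmetry_of_mapping(self):
        """Pair mapping of (a,b) equals the transposed mapping of (b,a)."""
        a, b = _rigid_pair(seed=7)
        ab = align_pair(a, b)
        ba = align_pair(b, a)
        assert sorted(ab.pair_indices) == sorted((j, i) for i, j in ba.pair_indices)

    def test_planted_insertion_left_unaligned(self):
        spec = SyntheticEnsembleSpec(
            n_structures=2,
            core_blocks=(40, 40),
            planted_regions=(PlantedRegion(0, (0, 15)),),
            noise_sigma=0.0,
            seed=9,
        )
        ens = generate_ensemble(spec)
        a, b = ens.structures
        al = align_pair(a, b)
        # all 80 core residues of a are paired, the 15 extra of b are not
        assert al.n_aligned == 80
        b_core = {ref.seq_id for _, ref in al.pairs}
        ins = ens.truth_msa.insertions[0]
        loop_seq_ids = {
            ens.truth_msa.traces[b.id][k][0].seq_id for k in ins.trace_indices
        }
        assert b_core.isdisjoint(loop_seq_ids)

    def test_core_recovery_under_noise(self):
        """>= 99% of planted core correspondences recovered at sigma 0.3."""
        spec = SyntheticEnsembleSpec(
            n_structures=2,
            core_blocks=(60, 60),
            planted_regions=(PlantedRegion(0, (0, 20)),),
            noise_sigma=0.3,
            seed=13,
        )
        ens = generate_ensemble(spec)
        a, b = ens.structures
        al = align_pair(a, b)
        truth = {
            (col.cells[a.id], col.cells[b.id]) for col in ens.truth_msa.columns
        }
        got = set(al.pair_indices)
        assert len(truth & got) / len(truth) >= 0.99

    def test_pairs_strictly_increasing(self, small_spec):
        ens = generate_ensemble(small_spec)
        al = align_pair(ens.structures[0], ens.structures[2])
        idx = np.array(al.pair_indices)
        assert np.all(np.diff(idx[:, 0]) > 0)
        assert np.all(np.diff(idx[:, 1]) > 0)

    def test_too_short_traces(self):
        import conftest

        rng = np.random.default_rng(0)
        s = conftest.ca_only_structure("tiny", rng.uniform(0, 10, (10, 3)))
        with pytest.raises(AlignmentError):
            align_pair(s, s)


class TestSeqIdentity:
    def _dummy(self, names):
        return PairwiseAlignment(
            a_id="a",
            b_id="b",
            pairs=[(None, None)] * len(names),
            transform=RigidTransform.identity(),
            rmsd=0.0,
            tm_score=1.0,
            seq_identity=0.0,
            n_aligned=len(names),
            pair_names=names,
        )

    def test_all_identical(self):
        assert seq_identity(self._dummy([("ALA", "ALA")] * 5)) == 100.0

    def test_none_identical(self):
        assert seq_identity(self._dummy([("ALA", "GLY")] * 5)) == 0.0

    def test_three_of_ten(self):
        names = [("ALA", "ALA")] * 3 + [("ALA", "GLY")] * 7
        assert seq_identity(self._dummy(names)) == pytest.approx(30.0)

    def test_empty_alignment_errors(self):
        with pytest.raises(AlignmentError):
            seq_identity(self._dummy([]))


class TestSelectSubset:
    def _al(self, n_aligned, rmsd):
        return PairwiseAlignment(
            a_id="ref",
            b_id=f"t{n_aligned}_{rmsd}",
            pairs=[(None, None)] * n_aligned,
            transform=RigidTransform.identity(),
            rmsd=rmsd,
            tm_score=0.5,
            seq_identity=10.0,
            n_aligned=n_aligned,
        )

    @pytest.mark.parametrize(
        "n_aligned,rmsd,kept",
        [
            (221, 5.0, True),   # length rule alone
            (100, 2.9, True),   # rmsd rule alone
            (220, 3.0, False),  # both at boundary: strict inequalities
            (220, 2.99, True),
            (221, 3.0, True),
            (100, 5.0, False),
        ],
    )
    def test_rule_boundaries(self, n_aligned, rmsd, kept):
        result = select_subset([self._al(n_aligned, rmsd)])
        assert (len(result) == 1) is kept
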