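"""Anchor profiles, anchor calling, PVR delineation, sigma_abs."""

import numpy as np
import pytest
from scipy.special import gammaln
from scipy.spatial.transform import Rotation

from pvrscan.multi_alignment import Column, MultipleAlignment, star_align
from pvrscan.pvr_analysis import (
    AnchorProfile,
    PVRError,
    call_anchors,
    column_profile,
    delineate_pvrs,
    pvr_report,
)
from pvrscan.structure_io import ResidueRef
from pvrscan.superposition import RigidTransform
from pvrscan.synthetic import PlantedRegion, SyntheticEnsembleSpec, generate_ensemble


def toy_msa(coords_by_structure: dict[str, np.ndarray]) -> MultipleAlignment:
    """All structures same length, column k = residue k everywhere."""
    ids = list(coords_by_structure)
    n = len(next(iter(coords_by_structure.values())))
    traces = {
        sid: [(ResidueRef(sid, "A", i + 1), np.asarray(xyz[i], float)) for i in range(n)]
        for sid, xyz in coords_by_structure.items()
    }
    return MultipleAlignment(
        reference_id=ids[0],
        structure_ids=ids,
        columns=[Column(index=k, cells={sid: k for sid in ids}) for k in range(n)],
        insertions=[],
        transforms={sid: RigidTransform.identity() for sid in ids},
        traces=traces,
        names={sid: ["ALA"] * n for sid in ids},
    )


class TestColumnProfile:
    def test_identical_copies_zero_rmsd(self):
        X = np.random.default_rng(0).uniform(0, 10, (5, 3))
        msa = toy_msa({"a": X, "b": X, "c": X})
        prof = column_profile(msa)
        assert np.allclose(prof.column_rmsd, 0.0)
        assert np.all(prof.occupancy == 3)

    def test_two_structures_closed_form(self):
        """CAs 2.0 Å apart -> RMSD about the centroid is 1.0 Å."""
        a = np.zeros((1, 3))
        b = np.array([[2.0, 0.0, 0.0]])
        # pad to 3 columns so the MSA is non-trivial
        A = np.vstack([a, [[5, 0, 0]], [[10, 0, 0]]])
        B = np.vstack([b, [[5, 0, 0]], [[10, 0, 0]]])
        prof = column_profile(toy_msa({"a": A, "b": B}))
        assert prof.column_rmsd[0] == pytest.approx(1.0)
        assert prof.column_rmsd[1] == pytest.approx(0.0)

    def test_partial_columns_never_anchor(self):
        X = np.random.default_rng(1).uniform(0, 10, (4, 3))
        msa = toy_msa({"a": X, "b": X})
        msa.columns[2].cells["b"] = None
        prof = column_profile(msa)
        assert np.isinf(prof.column_rmsd[2])
        assert 2 not in call_anchors(prof, rmsd_cut=100.0)

    def test_gaussian_noise_calibration(self):
        """Isotropic per-axis noise sigma over n structures gives
        RMS(column_rmsd) = sigma * sqrt(3) * sqrt((n-1)/n) and a mean given
        by the chi-distribution moment; checked against simulation."""
        sigma, n_struct, n_cols = 0.4, 4, 400
        rng = np.random.default_rng(7)
        base = rng.uniform(0, 50, (n_cols, 3))
        coords = {
            f"s{i}": base + rng.normal(0, sigma, (n_cols, 3)) for i in range(n_struct)
        }
        prof = column_profile(toy_msa(coords))
        rms = np.sqrt(np.mean(prof.column_rmsd**2))
        expected_rms = sigma * np.sqrt(3.0) * np.sqrt((n_struct - 1) / n_struct)
        assert rms == pytest.approx(expected_rms, rel=0.06)
        # exact mean of sigma/sqrt(n) * chi_{3(n-1)}
        k = 3 * (n_struct - 1)
        chi_mean = np.sqrt(2.0) * np.exp(gammaln((k + 1) / 2) - gammaln(k / 2))
        expected_mean = sigma / np.sqrt(n_struct) * chi_mean
        assert prof.column_rmsd.mean() == pytest.approx(expected_mean, rel=0.06)

    def test_missing_transform_errors(self):
        X = np.zeros((3, 3))
        msa = toy_msa({"a": X, "b": X})
        del msa.transforms["b"]
        with pytest.raises(PVRError):
            column_profile(msa)


class TestCallAnchors:
    def _profile(self, rmsds, n=2):
        arr = np.asarray(rmsds, float)
        return AnchorProfile(
            occupancy=np.full(len(arr), n, dtype=int), column_rmsd=arr, n_structures=n
        )

    def test_all_zero_all_anchor(self):
        prof = self._profile([0.0] * 6)
        assert list(call_anchors(prof)) == list(range(6))

    def test_boundary_is_strict(self):
        prof = self._profile([2.0, 1.999])
        assert list(call_anchors(prof, rmsd_cut=2.0)) == [1]

    def test_pattern(self):
        prof = self._profile([0.5, 3.0, 0.5])
        assert list(call_anchors(prof, rmsd_cut=2.0, min_run=1)) == [0, 2]

    def test_min_run_suppresses_short_runs(self):
        prof = self._profile([0.5, 3.0, 0.5, 0.5, 3.0, 0.5])
        assert list(call_anchors(prof, min_run=2)) == [2, 3]

    def test_invalid_cut(self):
        with pytest.raises(PVRError):
            call_anchors(self._profile([0.1]), rmsd_cut=0.0)


class TestDelineate:
    def test_identical_structures_no_pvrs(self):
        X = np.random.default_rng(3).uniform(0, 30, (30, 3))
        msa = toy_msa({"a": X, "b": X, "c": X})
        table = delineate_pvrs(msa, call_anchors(column_profile(msa)))
        assert table.n_pvrs == 0
        assert set(table.sigma_abs.values()) == {0}

    def test_single_planted_region_by_construction(self):
        spec = SyntheticEnsembleSpec(
            n_structures=3,
            core_blocks=(40, 40),
            planted_regions=(PlantedRegion(0, (0, 0, 15)),),
            noise_sigma=0.0,
            seed=31,
        )
        ens = generate_ensemble(spec)
        msa = star_align(ens.structures, "S0")
        table = delineate_pvrs(msa, call_anchors(column_profile(msa)))
        assert table.n_pvrs == 1
        p = table.pvrs[0]
        assert p.kind == "internal"
        assert p.length_range == 15
        assert p.lengths == {"S0": 0, "S1": 0, "S2": 15}
        assert table.sigma_abs == {"S0": 0, "S1": 0, "S2": 15}

    def test_terminal_regions_called(self):
        """A long extra N-terminal stretch in one structure becomes an
        N-terminal PVR bounded by a single anchor."""
        def helix(idx):
            # generous-radius helix with ~3.8 Å between consecutive CAs
            t = np.asarray(idx, float) * 0.35
            return np.column_stack([9.0 * np.cos(t), 9.0 * np.sin(t), 1.5 * t])

        core = helix(np.arange(40))
        # straight arm off the helix start: clearly distinct geometry, so
        # the register of the alignment is unambiguous
        v = np.array([-0.6, -0.6, -0.52915])
        ext = core[0] + v[None, :] * (3.8 * np.arange(20, 0, -1))[:, None]
        import conftest

        a = conftest.ca_only_structure("a", core)
        b = conftest.ca_only_structure("b", np.vstack([ext, core]))
        msa = star_align([a, b], "a")
        table = delineate_pvrs(msa, call_anchors(column_profile(msa)))
        kinds = [p.kind for p in table.pvrs]
        assert kinds == ["N_terminal"]
        assert table.pvrs[0].lengths == {"a": 0, "b": 20}

    def test_no_anchors_errors(self, small_spec):
        ens = generate_ensemble(small_spec)
        msa = star_align(ens.structures, "S0")
        with pytest.raises(PVRError, match="conserved core"):
            delineate_pvrs(msa, [])

    def test_sigma_abs_invariant_under_rigid_motion(self, small_spec):
        """Moving one input structure rigidly changes nothing."""
        from pvrscan.structure_io import Atom, Chain, Residue, Structure

        ens = generate_ensemble(small_spec)
        msa = star_align(ens.structures, "S0")
        t0 = delineate_pvrs(msa, call_anchors(column_profile(msa)))

        R = Rotation.from_euler("xyz", [10, 111, 222], degrees=True).as_matrix()
        t = np.array([40.0, -3.0, 17.0])
        moved = []
        for s in ens.structures:
            if s.id != "S1":
                moved.append(s)
                continue
            chains = [
                Chain(
                    chain_id=c.chain_id,
                    residues=[
                        Residue(
                            ref=r.ref,
                            name=r.name,
                            atoms=[
                                Atom(a.name, a.element, tuple(R @ a.coord + t))
                                for a in r.atoms
                            ],
                        )
                        for r in c.residues
                    ],
                )
                for c in s.chains
            ]
            moved.append(Structure(id=s.id, chains=chains))
        msa2 = star_align(moved, "S0")
        t1 = delineate_pvrs(msa2, call_anchors(column_profile(msa2)))
        assert t1.sigma_abs == t0.sigma_abs
        assert [p.length_range for p in t1.pvrs] == [p.length_range for p in t0.pvrs]

    def test_reference_sigma_always_zero(self, small_spec):
        ens = generate_ensemble(small_spec)
        msa = star_align(ens.structures, "S0")
        table = delineate_pvrs(msa, call_anchors(column_profile(msa)))
        assert table.sigma_abs["S0"] == 0


class TestReport:
    def _table(self, spec):
        ens = generate_ensemble(spec)
        msa = star_align(ens.structures, "S0")
        return delineate_pvrs(msa, call_anchors(column_profile(msa))), msa

    def test_one_row_per_structure_per_pvr(self, small_spec):
        table, msa = self._table(small_spec)
        df, sigma, selections = pvr_report(table, msa)
        assert len(df) == table.n_pvrs * msa.n_structures
        assert set(df["structure"]) == set(msa.structure_ids)

    def test_zero_length_segment_rows(self, small_spec):
        table, msa = self._table(small_spec)
        df, _, selections = pvr_report(table, msa)
        empty = df[df["length"] == 0]
        assert not empty.empty
        assert (empty["first"] == "").all()
        for sid, sel in selections.items():
            assert len(sel) == table.n_pvrs

    def test_sigma_vector_matches_table(self, small_spec):
        table, msa = self._table(small_spec)
        _, sigma, _ = pvr_report(table, msa)
        assert sigma.to_dict() == table.sigma_abs
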