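"""Per-residue contribution scan, classification, distances, differentials."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from evbcat.constants import COULOMB_CONST
from evbcat.embedding import (
    AtomTable,
    CoulombBackend,
    Snapshot,
    SnapshotEnsemble,
    decompose_barrier,
)
from evbcat.residue_scan import (
    classify_contribution,
    count_scan_jobs,
    differential_profile,
    per_residue_contribution,
    residue_moiety_distance,
    scan_all,
    sequence_domains,
)
from evbcat.synthetic_data import (
    generate_snapshots,
    make_synthetic_enzyme,
    shift_residue,
)


def _snapshot(state, moiety_pos, moiety_q, env_pos, env_q, env_rid):
    n_m, n_e = len(moiety_q), len(env_q)
    moiety = AtomTable(
        positions=np.asarray(moiety_pos, float),
        charges=np.asarray(moiety_q, float),
        residue_ids=np.full(n_m, 9001),
        residue_names=("SRO",) * n_m,
        atom_names=tuple(f"M{i}" for i in range(n_m)),
        elements=("C",) * n_m,
    )
    env = AtomTable(
        positions=np.asarray(env_pos, float),
        charges=np.asarray(env_q, float),
        residue_ids=np.asarray(env_rid, int),
        residue_names=tuple(f"R{r}" for r in env_rid),
        atom_names=tuple(f"E{i}" for i in range(n_e)),
        elements=("C",) * n_e,
    )
    return Snapshot(state, moiety, env)


class TestClassification:
    @pytest.mark.parametrize(
        "value,expected",
        [
            (-0.5, "catalytic"),
            (-0.1, "catalytic"),
            (-0.0999, "negligible"),
            (0.0999, "negligible"),
            (0.1, "anticatalytic"),
            (2.0, "anticatalytic"),
        ],
    )
    def test_threshold_boundaries(self, value, expected):
        assert classify_contribution(value) == expected


class TestPerResidueContribution:
    def test_single_residue_environment_equals_full_effect(self, backend):
        snaps = SnapshotEnsemble(
            [
                _snapshot("R", [[0, 0, 0]], [0.3], [[6, 0, 0]], [1.0], [1]),
                _snapshot("TS", [[0, 0, 0]], [0.9], [[6, 0, 0]], [1.0], [1]),
            ]
        )
        full = decompose_barrier(snaps, backend).catalytic_effect
        single = per_residue_contribution(snaps, 1, backend)
        assert single.contribution == pytest.approx(full, rel=1e-12)

    def test_zero_charge_residue_is_negligible(self, backend):
        snaps = SnapshotEnsemble(
            [
                _snapshot("R", [[0, 0, 0]], [0.3], [[6, 0, 0]], [0.0], [1]),
                _snapshot("TS", [[0, 0, 0]], [0.9], [[6, 0, 0]], [0.0], [1]),
            ]
        )
        rc = per_residue_contribution(snaps, 1, backend)
        assert rc.contribution == 0.0
        assert rc.classification == "negligible"

    def test_three_residue_hand_computed_contributions(self, backend):
        # One moiety atom whose charge grows from 0.2 (R) to 0.5 (TS);
        # three single-atom residues on the x axis.
        env_pos = [[4, 0, 0], [8, 0, 0], [12, 0, 0]]
        env_q = [1.0, -0.5, 0.25]
        snaps = SnapshotEnsemble(
            [
                _snapshot("R", [[0, 0, 0]], [0.2], env_pos, env_q, [1, 2, 3]),
                _snapshot("TS", [[0, 0, 0]], [0.5], env_pos, env_q, [1, 2, 3]),
            ]
        )
        dq = 0.5 - 0.2
        for rid, (r, q) in enumerate(zip([4.0, 8.0, 12.0], env_q), start=1):
            expected = COULOMB_CONST * dq * q / r
            rc = per_residue_contribution(snaps, rid, backend)
            assert rc.contribution == pytest.approx(expected, rel=1e-12)

    def test_unknown_residue_rejected(self, jitterfree_ensemble, backend):
        with pytest.raises(ValueError, match="residue 999"):
            per_residue_contribution(jitterfree_ensemble, 999, backend)


class TestScan:
    @pytest.mark.parametrize(
        "n_res,n_snap,n_var,expected",
        [(512, 200, 4, 409_600), (1, 1, 1, 1), (20, 10, 2, 400)],
    )
    def test_job_counting(self, n_res, n_snap, n_var, expected):
        assert count_scan_jobs(n_res, n_snap, n_var) == expected

    def test_scan_plans_and_tabulates(self, backend):
        enz = make_synthetic_enzyme(n_residues=20, planted_effect=-5.0, seed=3)
        variants = {}
        for i, name in enumerate(("WT", "MUT")):
            variants[name] = generate_snapshots(
                enz, "R", 5, 0.05, seed=10 * i
            ) + generate_snapshots(enz, "TS", 5, 0.05, seed=10 * i + 1)
        result = scan_all(variants, backend)
        assert result.planned_jobs == 400
        assert len(result.table) == 40
        assert set(result.table["classification"]).issubset(
            {"catalytic", "anticatalytic", "negligible"}
        )

    def test_contributions_sum_to_full_catalytic_effect(
        self, jitterfree_ensemble, backend
    ):
        result = scan_all({"WT": jitterfree_ensemble}, backend)
        total = result.table["contribution"].sum()
        full = decompose_barrier(jitterfree_ensemble, backend).catalytic_effect
        assert total == pytest.approx(full, rel=1e-8)

    def test_inconsistent_residue_numbering_rejected(self, backend):
        a = _snapshot("R", [[0, 0, 0]], [0.2], [[4, 0, 0]], [1.0], [1])
        b = _snapshot("TS", [[0, 0, 0]], [0.5], [[4, 0, 0]], [1.0], [2])
        with pytest.raises(ValueError, match="inconsistent residue numbering"):
            scan_all({"WT": SnapshotEnsemble([a, b])}, backend)

    def test_scan_is_deterministic(self, jitterfree_ensemble, backend):
        t1 = scan_all({"WT": jitterfree_ensemble}, backend).table
        t2 = scan_all({"WT": jitterfree_ensemble}, backend).table
        pd.testing.assert_frame_equal(t1, t2, check_exact=True)

    def test_contribution_decays_with_distance_for_uniform_charges(self):
        # Monopole moiety change + single-atom unit-like residues: |dE| ~ 1/r.
        enz = make_synthetic_enzyme(
            n_residues=30,
            atoms_per_residue=1,
            planted_effect=None,
            seed=5,
            moiety_charges_r=[0.1, 0.0, 0.0, 0.0, 0.0, 0.0],
            moiety_charges_ts=[0.6, 0.0, 0.0, 0.0, 0.0, 0.0],
        )
        # Uniform charge magnitude isolates the geometric decay.
        from dataclasses import replace

        residues = tuple(
            replace(r, charges=np.full_like(r.charges, 0.3)) for r in enz.residues
        )
        enz = replace(enz, residues=residues)
        ens = generate_snapshots(enz, "R", 2, 0.0, seed=1) + generate_snapshots(
            enz, "TS", 2, 0.0, seed=2
        )
        backend = CoulombBackend(state_energies={"R": 0.0, "TS": 30.0})
        result = scan_all({"WT": ens}, backend)
        rho = spearmanr(
            result.table["contribution"].abs(), result.table["mean_distance"]
        ).statistic
        assert rho < -0.95


class TestDistances:
    def test_three_four_five_triangle(self, backend):
        snap = _snapshot(
            "R",
            [[0, 0, 0], [0, 0, 0]],
            [0.1, 0.1],
            [[3, 4, 0], [3, 4, 0]],
            [0.2, 0.2],
            [1, 1],
        )
        assert residue_moiety_distance(SnapshotEnsemble([snap]), 1) == pytest.approx(5.0)

    def test_translation_invariance(self):
        base = _snapshot("R", [[0, 0, 0]], [0.1], [[3, 4, 0]], [0.2], [1])
        shifted = _snapshot("R", [[10, 10, 10]], [0.1], [[13, 14, 10]], [0.2], [1])
        ens_a, ens_b = SnapshotEnsemble([base]), SnapshotEnsemble([shifted])
        assert residue_moiety_distance(ens_a, 1) == pytest.approx(
            residue_moiety_distance(ens_b, 1)
        )

    def test_mean_of_per_snapshot_distances(self):
        a = _snapshot("R", [[0, 0, 0]], [0.1], [[4, 0, 0]], [0.2], [1])
        b = _snapshot("TS", [[0, 0, 0]], [0.1], [[6, 0, 0]], [0.2], [1])
        assert residue_moiety_distance(SnapshotEnsemble([a, b]), 1) == pytest.approx(5.0)

    def test_missing_residue_rejected(self):
        snap = _snapshot("R", [[0, 0, 0]], [0.1], [[4, 0, 0]], [0.2], [1])
        with pytest.raises(ValueError, match="residue 2 missing"):
            residue_moiety_distance(SnapshotEnsemble([snap]), 2)


class TestDifferentialProfile:
    def test_identical_variants_give_zero_profile(self, jitterfree_ensemble, backend):
        table = scan_all({"WT": jitterfree_ensemble}, backend).table
        diff = differential_profile(table, table)
        assert np.allclose(diff["d_contribution"], 0.0)
        assert np.allclose(diff["d_distance"], 0.0)

    def test_disjoint_residue_sets_rejected(self):
        a = pd.DataFrame(
            {"residue_id": [1], "residue_name": ["ALA"], "contribution": [0.0],
             "mean_distance": [5.0]}
        )
        b = a.assign(residue_id=[2])
        with pytest.raises(ValueError, match="share no residues"):
            differential_profile(a, b)

    def test_planted_radial_shift_recovered(self, backend):
        enz = make_synthetic_enzyme(n_residues=10, planted_effect=-5.0, seed=9)
        target = 7
        center = np.mean(enz.residue(target).positions, axis=0)
        outward = center / np.linalg.norm(center)
        mutant = shift_residue(enz, target, 0.3 * outward)

        def table(e, seed):
            ens = generate_snapshots(e, "R", 20, 0.02, seed=seed) + generate_snapshots(
                e, "TS", 20, 0.02, seed=seed + 1
            )
            return scan_all({"V": ens}, backend).table

        diff = differential_profile(table(mutant, 50), table(enz, 60))
        d7 = float(diff.loc[diff["residue_id"] == target, "d_distance"].iloc[0])
        others = diff.loc[diff["residue_id"] != target, "d_distance"].abs().max()
        assert d7 == pytest.approx(0.3, abs=0.05)
        assert others < 0.05

    def test_sequence_domains_group_contiguous_runs(self):
        diff = pd.DataFrame(
            {
                "residue_id": [1, 2, 3, 4, 5, 6],
                "d_contribution": [0.3, 0.4, 0.0, 0.0, -0.5, 0.26],
            }
        )
        assert sequence_domains(diff) == [(1, 2), (5, 6)]

    def test_negligible_fraction_matches_generator_design(self, backend):
        enz = make_synthetic_enzyme(
            n_residues=40, planted_effect=-10.0, negligible_fraction=0.6, seed=21
        )
        truth = np.array([enz.ground_truth[r.residue_id] for r in enz.residues])
        design_fraction = np.mean(np.abs(truth) < 0.1)
        ens = generate_snapshots(enz, "R", 15, 0.02, seed=1) + generate_snapshots(
            enz, "TS", 15, 0.02, seed=2
        )
        table = scan_all({"WT": ens}, backend).table
        observed = np.mean(table["classification"] == "negligible")
        n = len(table)
        binom_se = np.sqrt(design_fraction * (1 - design_fraction) / n)
        assert abs(observed - design_fraction) <= max(3 * binom_se, 2 / n)
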