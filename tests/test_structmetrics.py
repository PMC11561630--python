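"""Superposition, ensemble RMSD, restraint tallies and in-silico PCR."""

import numpy as np
import pytest

from conftest import quaternion_rmsd, random_rotation, write_model_pdb
from csabmine.structmetrics import (
    DistanceRestraint,
    StructureEnsemble,
    StructureError,
    ensemble_rmsd,
    insilico_pcr,
    kabsch_superpose,
    load_ensemble,
    read_restraints,
    restraint_category,
    tally_restraints,
)


def _backbone_atoms(n_residues):
    return [
        (ri + 1, "ALA", name)
        for ri in range(n_residues)
        for name in ("N", "CA", "C")
    ]


class TestKabsch:
    def test_self_superposition_zero(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 3))
        _, _, rmsd = kabsch_superpose(X, X)
        assert rmsd <= 1e-12

    def test_rigid_motion_removed(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(12, 3))
        R = random_rotation(rng)
        t = rng.normal(size=3)
        rot, trans, rmsd = kabsch_superpose(X, X @ R.T + t)
        assert rmsd <= 1e-8
        assert np.linalg.det(rot) == pytest.approx(1.0)

    def test_agrees_with_quaternion_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            A = rng.normal(size=(10, 3))
            B = rng.normal(size=(10, 3))
            _, _, rmsd = kabsch_superpose(A, B)
            assert rmsd == pytest.approx(quaternion_rmsd(A, B), abs=1e-8)

    def test_too_few_points_rejected(self):
        with pytest.raises(StructureError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_rejected(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(StructureError):
            kabsch_superpose(line, line)


class TestEnsembleRmsd:
    def test_identical_models_zero(self):
        rng = np.random.default_rng(3)
        base = rng.normal(scale=4, size=(30, 3))
        ensemble = StructureEnsemble(
            atoms=_backbone_atoms(10),
            coords=np.repeat(base[None], 6, axis=0),
        )
        mean, sd = ensemble_rmsd(ensemble)
        assert mean <= 1e-12 and sd <= 1e-12

    def test_rigid_motions_removed(self):
        rng = np.random.default_rng(4)
        base = rng.normal(scale=4, size=(30, 3))
        coords = np.stack(
            [base @ random_rotation(rng).T + rng.normal(size=3) for _ in range(8)]
        )
        ensemble = StructureEnsemble(atoms=_backbone_atoms(10), coords=coords)
        mean, _ = ensemble_rmsd(ensemble)
        assert mean <= 1e-8

    def test_invariant_to_global_rigid_motion(self):
        rng = np.random.default_rng(5)
        base = rng.normal(scale=4, size=(36, 3))
        coords = base[None] + rng.normal(scale=0.4, size=(5, 36, 3))
        ensemble = StructureEnsemble(atoms=_backbone_atoms(12), coords=coords)
        mean1, sd1 = ensemble_rmsd(ensemble)
        R = random_rotation(rng)
        moved = StructureEnsemble(
            atoms=ensemble.atoms, coords=coords @ R.T + rng.normal(size=3)
        )
        mean2, sd2 = ensemble_rmsd(moved)
        assert mean1 == pytest.approx(mean2, abs=1e-8)
        assert sd1 == pytest.approx(sd2, abs=1e-8)

    def test_residue_range_outside_rejected(self):
        rng = np.random.default_rng(6)
        ensemble = StructureEnsemble(
            atoms=_backbone_atoms(10), coords=rng.normal(size=(3, 30, 3))
        )
        with pytest.raises(StructureError):
            ensemble_rmsd(ensemble, residue_range=(50, 60))

    def test_load_multi_model_pdb(self, tmp_path):
        rng = np.random.default_rng(7)
        base = rng.normal(scale=5, size=(36, 3))
        models = [base + rng.normal(scale=0.2, size=base.shape) for _ in range(4)]
        path = tmp_path / "ensemble.pdb"
        write_model_pdb(path, models)
        ensemble = load_ensemble(path)
        assert ensemble.n_models == 4
        assert len(ensemble.atoms) == 36
        mean, sd = ensemble_rmsd(ensemble, residue_range=(2, 11))
        assert 0 < mean < 1.0


class TestRestraints:
    def test_category_definition(self):
        pairs = [(3, 3), (3, 4), (3, 6), (3, 9)]
        tally = tally_restraints([DistanceRestraint(i, j) for i, j in pairs])
        assert (tally.intraresidue, tally.sequential, tally.medium, tally.long) == (
            1, 1, 1, 1,
        )
        assert tally.total == 4

    def test_empty_all_zero(self):
        tally = tally_restraints([])
        assert tally.total == 0

    def test_partition_disjoint_exhaustive(self):
        rng = np.random.default_rng(8)
        for _ in range(2000):
            i, j = rng.integers(1, 60, size=2)
            category = restraint_category(int(i), int(j))
            d = abs(int(i) - int(j))
            expected = (
                "intraresidue" if d == 0
                else "sequential" if d == 1
                else "medium" if d < 5
                else "long"
            )
            assert category == expected

    def test_read_tsv(self, tmp_path):
        path = tmp_path / "r.tsv"
        path.write_text("# i j bound\n3 3 3.1\n3 4\n3 6 4.5\n")
        restraints = read_restraints(path)
        assert [(r.residue_i, r.residue_j) for r in restraints] == [
            (3, 3), (3, 4), (3, 6),
        ]

    def test_read_upl(self, tmp_path):
        path = tmp_path / "r.upl"
        path.write_text(
            "  2 GLU  HA     5 CYS  HB2    4.50\n"
            " 10 ALA  HN    10 ALA  HA     2.80\n"
        )
        restraints = read_restraints(path)
        assert [(r.residue_i, r.residue_j) for r in restraints] == [(2, 5), (10, 10)]

    def test_read_nmrstar_counts_ambiguous_once(self, tmp_path):
        # synthetic NMR-STAR snippet (minimal general-distance-constraint loop)
        text = """
loop_
  _Gen_dist_constraint.ID
  _Gen_dist_constraint.Seq_ID_1
  _Gen_dist_constraint.Seq_ID_2
  1 3 3
  2 3 4
  2 3 5
  3 3 9
stop_
"""
        path = tmp_path / "r.str"
        path.write_text(text)
        restraints = read_restraints(path)
        assert [(r.residue_i, r.residue_j) for r in restraints] == [
            (3, 3), (3, 4), (3, 9),
        ]


class TestInsilicoPcr:
    FWD = "GTCACGCGATGAAGAAGAAT"
    REV = "GAAGTGGTCACAGTCCGAGT"

    def _template(self, insert_len, rng):
        from Bio.Seq import Seq

        middle = "".join(rng.choice(list("ACGT")) for _ in range(insert_len))
        return self.FWD + middle + str(Seq(self.REV).reverse_complement())

    def test_product_spans_whole_constructed_template(self):
        import random

        rng = random.Random(11)
        template = self._template(60, rng)
        result = insilico_pcr(template, self.FWD, self.REV)
        assert result.status == "OK"
        assert result.products[0].length == len(template)

    def test_absent_primers_no_product(self):
        result = insilico_pcr("ACGT" * 50, self.FWD, self.REV)
        assert result.status == "NO_PRODUCT"
        assert result.products == ()

    def test_product_invariant_to_flanking_sequence(self):
        import random

        rng = random.Random(12)
        template = self._template(40, rng)
        flank5 = "".join(rng.choice(list("ACGT")) for _ in range(30))
        flank3 = "".join(rng.choice(list("ACGT")) for _ in range(30))
        inner = insilico_pcr(template, self.FWD, self.REV)
        flanked = insilico_pcr(flank5 + template + flank3, self.FWD, self.REV)
        assert flanked.status == "OK"
        assert flanked.products[0].length == inner.products[0].length

    def test_short_primer_rejected(self):
        with pytest.raises(StructureError):
            insilico_pcr("ACGT" * 30, "ACGTACGT", self.REV)

    def test_multiple_sites_all_reported(self):
        import random

        rng = random.Random(13)
        template = self._template(30, rng)
        double = template + "TTTT" + template
        result = insilico_pcr(double, self.FWD, self.REV)
        # 2 forward sites x 2 reverse sites, minus upstream-reverse combos
        assert len(result.products) == 3
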