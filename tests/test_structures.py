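"""Superposition, PDB I/O, template ranking, threading, interface calls."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from ringscape.sequences import (
    LigandAssignment,
    ProteinSequence,
    pairwise_global_align,
)
from ringscape.structures import (
    Atom,
    DegenerateGeometryError,
    Residue,
    StructureModel,
    StructureError,
    TemplateEntry,
    exposure_score,
    interface_residues,
    kabsch_superpose,
    longest_aligned_block,
    rank_templates,
    read_structure,
    spacing_compatibility,
    thread_model,
    write_structure,
    zinc_geometry_check,
)
from ringscape.simulate import StructureConfig, gen_ring_structure


# ---------------------------------------------------------------------------
# PDB reading
# ---------------------------------------------------------------------------

MINIMAL_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  CA  GLY A   2       3.800   1.000   0.000  1.00  0.00           C
ATOM      4  CA  CYS A   3       7.600   2.000   0.500  1.00  0.00           C
ATOM      5  SG  CYS A   3       8.500   3.500   1.200  1.00  0.00           S
END
"""

ZN_PDB = MINIMAL_PDB.replace(
    "END\n",
    "HETATM    6 ZN    ZN A  90      10.000   4.000   2.000  1.00  0.00          ZN\nEND\n",
)

ALTLOC_PDB = """\
ATOM      1  CA AALA A   1       1.000   0.000   0.000  0.30  0.00           C
ATOM      2  CA BALA A   1       2.000   0.000   0.000  0.70  0.00           C
ATOM      3  CA  GLY A   2       5.000   0.000   0.000  1.00  0.00           C
ATOM      4  CA  GLY A   3       9.000   0.000   0.000  1.00  0.00           C
END
"""

ICODE_PDB = """\
ATOM      1  CA  ALA A   1       1.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  GLY A   1A      5.000   0.000   0.000  1.00  0.00           C
END
"""


class TestReadStructure:
    def test_minimal_single_chain(self, tmp_path):
        p = tmp_path / "m.pdb"
        p.write_text(MINIMAL_PDB)
        st = read_structure(p)
        assert list(st.chains) == ["A"]
        assert len(st.chains["A"]) == 3
        assert st.chains["A"][0].atom("N") is not None

    def test_zinc_hetatm_populates_metals(self, tmp_path):
        p = tmp_path / "z.pdb"
        p.write_text(ZN_PDB)
        st = read_structure(p)
        assert len(st.metals) == 1
        el, xyz = st.metals[0]
        assert el.upper() == "ZN"
        assert xyz == pytest.approx([10.0, 4.0, 2.0])

    def test_altloc_resolved_by_occupancy(self, tmp_path):
        p = tmp_path / "a.pdb"
        p.write_text(ALTLOC_PDB)
        st = read_structure(p)
        res = st.chains["A"][0]
        assert len(res.atoms) == 1
        assert res.ca.xyz == pytest.approx([2.0, 0.0, 0.0])  # occ 0.70 wins

    def test_insertion_codes_rejected(self, tmp_path):
        p = tmp_path / "i.pdb"
        p.write_text(ICODE_PDB)
        with pytest.raises(StructureError):
            read_structure(p)

    def test_roundtrip_coordinates_to_pdb_precision(self, tmp_path, toy_structure):
        model, _, _ = toy_structure
        p = tmp_path / "rt.pdb"
        write_structure(model, p)
        back = read_structure(p)
        for cid, residues in model.chains.items():
            for r_in, r_out in zip(residues, back.chains[cid]):
                assert r_out.number == r_in.number
                assert r_out.name == r_in.name
                for a_in in r_in.atoms:
                    a_out = r_out.atom(a_in.name)
                    assert a_out.xyz == pytest.approx(a_in.xyz, abs=1.5e-3)
        assert len(back.metals) == len(model.metals)


# ---------------------------------------------------------------------------
# Kabsch superposition
# ---------------------------------------------------------------------------


def _random_cloud(rng, n=10):
    return rng.normal(0, 5, (n, 3))


def _random_rigid(rng):
    R = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31)))
    return R.as_matrix(), rng.normal(0, 10, 3)


def _optimizer_oracle_rmsd(P, Q, n_starts=5, seed=0):
    """Numerical minimisation over rotation vectors (translation optimal
    by centering); best of several starts."""
    rng = np.random.default_rng(seed)
    P0 = P - P.mean(axis=0)
    Q0 = Q - Q.mean(axis=0)

    def objective(rv):
        R = Rotation.from_rotvec(rv).as_matrix()
        d = P0 @ R.T - Q0
        return np.sqrt((d**2).sum() / len(P0))

    best = np.inf
    starts = [np.zeros(3)] + [rng.normal(0, 2, 3) for _ in range(n_starts - 1)]
    for x0 in starts:
        res = minimize(objective, x0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
        best = min(best, res.fun)
    return best


class TestKabsch:
    def test_identical_sets_rmsd_zero_identity_rotation(self, rng):
        P = _random_cloud(rng)
        sup = kabsch_superpose(P, P)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-12)
        assert sup.rotation == pytest.approx(np.eye(3), abs=1e-9)

    def test_recovers_constructed_rigid_motion(self, rng):
        P = _random_cloud(rng)
        Rz = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        t = np.array([1.0, -2.0, 3.0])
        Q = P @ Rz.T + t
        sup = kabsch_superpose(P, Q)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)
        assert sup.rotation == pytest.approx(Rz, abs=1e-9)
        assert sup.translation == pytest.approx(t, abs=1e-9)

    def test_rotation_is_proper(self, rng):
        # Mirror-image clouds: the best proper rotation must NOT be a reflection.
        P = _random_cloud(rng)
        Q = P.copy()
        Q[:, 0] *= -1
        sup = kabsch_superpose(P, Q)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_rmsd_below_any_sampled_rigid_transform(self, rng):
        P, Q = _random_cloud(rng), _random_cloud(rng)
        sup = kabsch_superpose(P, Q)
        for _ in range(1000):
            R, t = _random_rigid(rng)
            rmsd = np.sqrt((((P @ R.T + t) - Q) ** 2).sum() / len(P))
            assert sup.rmsd <= rmsd + 1e-12

    def test_agrees_with_svd_reference_on_100_clouds(self, rng):
        """Independent reference: scipy Rotation.align_vectors."""
        for _ in range(100):
            P, Q = _random_cloud(rng), _random_cloud(rng)
            sup = kabsch_superpose(P, Q)
            rot, rssd = Rotation.align_vectors(
                Q - Q.mean(axis=0), P - P.mean(axis=0)
            )
            assert sup.rmsd == pytest.approx(rssd / np.sqrt(len(P)), abs=1e-6)

    def test_agrees_with_numerical_minimizer(self, rng):
        for i in range(10):
            P, Q = _random_cloud(rng), _random_cloud(rng)
            sup = kabsch_superpose(P, Q)
            oracle = _optimizer_oracle_rmsd(P, Q, seed=i)
            assert sup.rmsd <= oracle + 1e-6
            assert sup.rmsd == pytest.approx(oracle, abs=1e-6)

    def test_idempotence(self, rng):
        P, Q = _random_cloud(rng), _random_cloud(rng)
        sup = kabsch_superpose(P, Q)
        again = kabsch_superpose(sup.apply(P), Q)
        assert again.rotation == pytest.approx(np.eye(3), abs=1e-7)
        assert np.linalg.norm(again.translation) == pytest.approx(0.0, abs=1e-7)

    def test_degenerate_inputs_rejected(self, rng):
        with pytest.raises(ValueError):
            kabsch_superpose(_random_cloud(rng, 5), _random_cloud(rng, 6))
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose(line, line)


# ---------------------------------------------------------------------------
# Template ranking
# ---------------------------------------------------------------------------


def _ca_chain(seq: str, spacing=3.8):
    residues = []
    for i, aa in enumerate(seq):
        name = {"C": "CYS", "A": "ALA", "G": "GLY"}.get(aa, "ALA")
        xyz = [i * spacing, 1.5 * (i % 2), 1.0 * ((i % 3) - 1)]  # non-collinear
        residues.append(Residue(i + 1, name, [Atom("CA", xyz, "C")]))
    return StructureModel({"A": residues})


def _template_from_gaps(tid, gaps):
    positions = [1]
    for g in gaps:
        positions.append(positions[-1] + g + 1)
    seq = ["A"] * positions[-1]
    for p in positions:
        seq[p - 1] = "C"
    st = _ca_chain("".join(seq))
    return TemplateEntry(tid, st, "A", tuple(positions))


@pytest.fixture
def query_with_assignment():
    gaps = (2, 11, 2, 3, 2, 5, 2)
    tmpl = _template_from_gaps("Q", gaps)
    seq = tmpl.structure.chain_sequence("A")
    return seq, LigandAssignment(tmpl.ligand_positions)


class TestRankTemplates:
    def test_identical_template_ranks_first_with_compat_1(self, query_with_assignment):
        seq, asg = query_with_assignment
        exact = _template_from_gaps("exact", asg.gaps)
        other = _template_from_gaps("other", (2, 9, 1, 2, 2, 4, 2))
        scores = rank_templates(seq, asg, [other, exact])
        assert scores[0].template_id == "exact"
        assert scores[0].ligand_spacing_compatibility == pytest.approx(1.0)

    def test_exact_spacing_beats_reversed_spacing(self, query_with_assignment):
        seq, asg = query_with_assignment
        exact = _template_from_gaps("exact", asg.gaps)
        rev = _template_from_gaps("rev", tuple(reversed(asg.gaps)))
        scores = {s.template_id: s for s in rank_templates(seq, asg, [exact, rev])}
        assert (
            scores["exact"].ligand_spacing_compatibility
            > scores["rev"].ligand_spacing_compatibility
        )
        assert scores["exact"].combined >= scores["rev"].combined

    def test_ordering_matches_independent_score_recomputation(self, query_with_assignment):
        seq, asg = query_with_assignment
        templates = [
            _template_from_gaps("t1", (2, 11, 2, 3, 2, 5, 2)),
            _template_from_gaps("t2", (2, 9, 1, 2, 2, 4, 2)),
            _template_from_gaps("t3", (2, 20, 3, 4, 2, 10, 2)),
            _template_from_gaps("t4", (2, 11, 2, 3, 2, 48, 2)),
        ]
        scores = rank_templates(seq, asg, templates)
        # independent recomputation of the combined score formula
        raw = {}
        for t in templates:
            aln = pairwise_global_align(seq, t.sequence)
            raw[t.template_id] = (
                aln.report.percent_identity,
                float(longest_aligned_block(aln)),
                spacing_compatibility(asg.gaps, t.gap_vector),
            )
        comps = list(zip(*raw.values()))
        scaled = {}
        for j, comp in enumerate(comps):
            lo, hi = min(comp), max(comp)
            for tid, v in zip(raw, comp):
                scaled.setdefault(tid, []).append(
                    1.0 if hi - lo < 1e-12 else (v - lo) / (hi - lo)
                )
        combined = {tid: sum(v) / 3 for tid, v in scaled.items()}
        expected_order = sorted(combined, key=lambda t: (-combined[t], t))
        assert [s.template_id for s in scores] == expected_order
        for s in scores:
            assert s.combined == pytest.approx(combined[s.template_id])

    def test_input_order_invariance(self, query_with_assignment):
        seq, asg = query_with_assignment
        ts = [
            _template_from_gaps("a", (2, 11, 2, 3, 2, 5, 2)),
            _template_from_gaps("b", (2, 9, 1, 2, 2, 4, 2)),
            _template_from_gaps("c", (2, 39, 3, 4, 2, 8, 2)),
        ]
        s1 = rank_templates(seq, asg, ts)
        s2 = rank_templates(seq, asg, list(reversed(ts)))
        assert s1 == s2

    def test_unannotated_template_excluded_with_warning(self, query_with_assignment):
        seq, asg = query_with_assignment
        good = _template_from_gaps("good", asg.gaps)
        bad = TemplateEntry("bad", good.structure, "A", ())
        with pytest.warns(UserWarning, match="bad"):
            scores = rank_templates(seq, asg, [good, bad])
        assert [s.template_id for s in scores] == ["good"]


# ---------------------------------------------------------------------------
# Threading
# ---------------------------------------------------------------------------


class TestThreadModel:
    def test_identical_sequence_inherits_all_cas(self):
        tmpl = _ca_chain("ACGAAC")
        seq = tmpl.chain_sequence("A")
        aln = pairwise_global_align(seq, seq)
        model = thread_model(seq, tmpl, aln)
        assert model.unmodeled == []
        np.testing.assert_allclose(model.ca_coords("A"), tmpl.ca_coords("A"))

    def test_query_insertion_flagged_unmodeled(self):
        tmpl = _ca_chain("ACDEFGHIKLMNP")
        t_seq = tmpl.chain_sequence("A")
        q = ProteinSequence("q", t_seq.residues[:6] + "WW" + t_seq.residues[6:])
        aln = pairwise_global_align(q, t_seq)
        model = thread_model(q, tmpl, aln)
        assert len(model.unmodeled) == 2

    def test_aligned_rmsd_is_zero_by_construction(self):
        tmpl = _ca_chain("ACDEFGHIKLMNPQRS")
        t_seq = tmpl.chain_sequence("A")
        q = ProteinSequence("q", t_seq.residues[2:])  # N-terminal truncation
        aln = pairwise_global_align(q, t_seq)
        model = thread_model(q, tmpl, aln)
        # threaded CAs == template CAs for aligned residues; verify via Kabsch
        built = model.ca_coords("A")
        sup = kabsch_superpose(built, tmpl.ca_coords("A")[2:])
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)

    def test_metals_copied_through(self, toy_structure):
        struct, asg, _ = toy_structure
        seq = struct.chain_sequence("A")
        aln = pairwise_global_align(seq, seq)
        model = thread_model(seq, struct, aln, template_chain="A")
        assert len(model.metals) == 2


# ---------------------------------------------------------------------------
# Interface residues
# ---------------------------------------------------------------------------


def _two_chain_toy():
    a = [
        Residue(1, "ALA", [Atom("CA", [0.0, 0.0, 0.0], "C")]),
        Residue(2, "ALA", [Atom("CA", [0.0, 0.0, 4.9], "C")]),
        Residue(3, "ALA", [Atom("CA", [0.0, 0.0, 10.1], "C")]),
    ]
    b = [Residue(1, "GLY", [Atom("CA", [0.0, 0.0, 15.2], "C")])]
    return StructureModel({"A": a, "B": b})


class TestInterfaceResidues:
    def test_inclusive_threshold_boundary(self):
        # residue 3 at 5.1 A of partner, residue 2 at 10.3: with the
        # partner at z=15.2 and cutoff 5.0 only nothing is included;
        # cutoff 5.1 includes residue 3 (inclusive boundary).
        toy = _two_chain_toy()
        rep49 = interface_residues(toy, "B", cutoff=5.0)
        assert rep49.positions() == set()
        rep51 = interface_residues(toy, "B", cutoff=5.1)
        assert rep51.positions() == {("A", 3)}
        assert rep51.residues[0].min_distance == pytest.approx(5.1)

    def test_constructed_in_out_pair(self):
        a = [
            Residue(1, "ALA", [Atom("CA", [0, 0, 4.9], "C")]),
            Residue(2, "ALA", [Atom("CA", [0, 0, -5.1], "C")]),
        ]
        b = [Residue(1, "GLY", [Atom("CA", [0, 0, 0], "C")])]
        model = StructureModel({"A": a, "B": b})
        rep = interface_residues(model, "B", 5.0)
        assert rep.positions() == {("A", 1)}

    def test_empty_partner_gives_empty_report(self):
        model = StructureModel(
            {"A": [Residue(1, "ALA", [Atom("CA", [0, 0, 0], "C")])]}
        )
        rep = interface_residues(model, StructureModel(), 5.0)
        assert rep.residues == ()

    def test_matches_bruteforce_all_pairs_scan(self, rng):
        chains = {}
        for cid, n in (("A", 50), ("B", 50)):
            residues = []
            for i in range(n):
                atoms = [
                    Atom(name, rng.normal(0, 12, 3), el)
                    for name, el in (("CA", "C"), ("CB", "C"), ("O", "O"))
                ]
                residues.append(Residue(i + 1, "ALA", atoms))
            chains[cid] = residues
        model = StructureModel(chains)
        rep = interface_residues(model, "B", 5.0)
        # brute force O(n^2)
        expected = set()
        b_atoms = [a.xyz for r in chains["B"] for a in r.atoms]
        for r in chains["A"]:
            dmin = min(
                np.linalg.norm(a.xyz - b) for a in r.atoms for b in b_atoms
            )
            if dmin <= 5.0:
                expected.add(("A", r.number))
        assert rep.positions() == expected

    def test_monotone_in_cutoff(self, toy_structure):
        model, _, _ = toy_structure
        prev = set()
        for cutoff in (2.0, 3.5, 5.0, 8.0, 12.0):
            cur = interface_residues(model, "B", cutoff).positions()
            assert prev <= cur
            prev = cur

    def test_report_sorted_by_residue_number(self, toy_structure):
        model, _, _ = toy_structure
        rep = interface_residues(model, "B", 8.0)
        nums = [(r.chain, r.number) for r in rep.residues]
        assert nums == sorted(nums)


# ---------------------------------------------------------------------------
# Exposure and zinc geometry
# ---------------------------------------------------------------------------


class TestExposureScore:
    def test_isolated_residue_fully_exposed(self):
        model = StructureModel(
            {"A": [Residue(1, "ALA", [Atom("CA", [0, 0, 0], "C")])]}
        )
        assert exposure_score(model, "A", 1) == 1.0

    def test_dense_cluster_saturates_to_zero(self, rng):
        residues = [Residue(1, "ALA", [Atom("CA", [0, 0, 0], "C")])]
        for i in range(30):
            residues.append(
                Residue(i + 2, "ALA", [Atom("CA", rng.normal(0, 3, 3), "C")])
            )
        model = StructureModel({"A": residues})
        assert exposure_score(model, "A", 1) == 0.0

    def test_matches_neighbor_recount(self, toy_structure):
        model, _, _ = toy_structure
        for r in model.chains["A"][:10]:
            got = exposure_score(model, "A", r.number)
            count = 0
            for cid, other in model.all_residues():
                if (cid, other.number) == ("A", r.number) or other.ca is None:
                    continue
                if np.linalg.norm(other.ca.xyz - r.ca.xyz) <= 10.0:
                    count += 1
            assert got == pytest.approx(1.0 - min(count, 20) / 20)

    def test_monotone_adding_neighbors_never_raises_score(self):
        base = [Residue(1, "ALA", [Atom("CA", [0, 0, 0], "C")])]
        prev = 1.0
        for i in range(25):
            base.append(Residue(i + 2, "ALA", [Atom("CA", [1 + 0.2 * i, 0, 0], "C")]))
            score = exposure_score(StructureModel({"A": [r for r in base]}), "A", 1)
            assert score <= prev + 1e-12
            prev = score


class TestZincGeometry:
    def test_ideal_sites_all_pass(self, toy_structure):
        model, asg, _ = toy_structure
        reports = zinc_geometry_check(model, asg)
        assert len(reports) == 2
        assert all(r.passed for r in reports)
        for r in reports:
            for _, d in r.ligand_distances:
                assert d == pytest.approx(2.3, abs=1e-9)

    def test_single_displaced_ligand_flagged(self):
        model, asg, _ = gen_ring_structure(StructureConfig(seed=3))
        bad = asg.positions[0]
        res = model.find_residue("A", bad)
        res.atom("SG").xyz = res.atom("SG").xyz + np.array([0.0, 0.0, 4.0])
        reports = zinc_geometry_check(model, asg)
        flagged = [n for r in reports for n in r.flagged]
        assert flagged == [bad]

    def test_distances_equal_raw_recomputation(self, toy_structure):
        model, asg, _ = toy_structure
        zincs = [xyz for el, xyz in model.metals if el.upper() == "ZN"]
        for rep in zinc_geometry_check(model, asg):
            zn = zincs[rep.zinc_index]
            for num, d in rep.ligand_distances:
                sg = model.find_residue("A", num).atom("SG")
                assert d == pytest.approx(np.linalg.norm(sg.xyz - zn))

    def test_fewer_than_two_zincs_rejected(self, toy_structure):
        model, asg, _ = toy_structure
        single = StructureModel(dict(model.chains), metals=model.metals[:1])
        with pytest.raises(StructureError):
            zinc_geometry_check(single, asg)
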