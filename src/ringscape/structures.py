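"""Structure-level analysis: superposition, template ranking, threading,
interface calling, exposure and zinc-site geometry.

The homology-modelling step is deliberately light-weight: a query sequence
is threaded rigidly onto a template's CA trace through a pairwise
alignment.  That is enough to support the downstream geometric questions —
which residues sit within a distance cutoff of a bound partner chain, how
buried a residue is, and whether putative zinc sites have chemically
sensible ligand–metal distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from .sequences import (
    AlignmentParams,
    LigandAssignment,
    PairwiseAlignment,
    ProteinSequence,
    pairwise_global_align,
)

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}
_ONE_TO_THREE["X"] = "UNK"


class StructureError(ValueError):
    """Malformed or unusable structural input."""


class DegenerateGeometryError(ValueError):
    """Point set too degenerate for a unique rigid superposition."""


@dataclass
class Atom:
    name: str
    xyz: np.ndarray  # shape (3,), Å
    element: str = ""

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (3,) or not np.all(np.isfinite(self.xyz)):
            raise StructureError(f"bad coordinates for atom {self.name}")
        if not self.element:
            self.element = self.name.strip()[:1]

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"


@dataclass
class Residue:
    number: int
    name: str  # 3-letter code
    atoms: list[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> Atom | None:
        return self.atom("CA")

    @property
    def one_letter(self) -> str:
        return _THREE_TO_ONE.get(self.name.upper(), "X")

    def heavy_coords(self) -> np.ndarray:
        xyz = [a.xyz for a in self.atoms if a.is_heavy]
        return np.array(xyz) if xyz else np.empty((0, 3))


@dataclass
class StructureModel:
    """Chains of residues plus free metal ions, all coordinates in Å."""

    chains: dict[str, list[Residue]] = field(default_factory=dict)
    metals: list[tuple[str, np.ndarray]] = field(default_factory=list)
    unmodeled: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for cid, residues in self.chains.items():
            nums = [r.number for r in residues]
            if any(b <= a for a, b in zip(nums, nums[1:])):
                raise StructureError(
                    f"residue numbers not strictly increasing in chain {cid}"
                )
        self.metals = [(el, np.asarray(x, dtype=float)) for el, x in self.metals]

    def chain_sequence(self, chain_id: str, numbering_offset=None) -> ProteinSequence:
        residues = self.chains[chain_id]
        offset = residues[0].number if numbering_offset is None else numbering_offset
        return ProteinSequence(
            chain_id, "".join(r.one_letter for r in residues), offset
        )

    def ca_coords(self, chain_id: str) -> np.ndarray:
        out = []
        for r in self.chains[chain_id]:
            if r.ca is None:
                raise StructureError(
                    f"residue {r.number} in chain {chain_id} lacks a CA atom"
                )
            out.append(r.ca.xyz)
        return np.array(out)

    def all_residues(self) -> Iterable[tuple[str, Residue]]:
        for cid, residues in self.chains.items():
            for r in residues:
                yield cid, r

    def find_residue(self, chain_id: str, number: int) -> Residue:
        for r in self.chains[chain_id]:
            if r.number == number:
                return r
        raise KeyError(f"residue {number} not in chain {chain_id}")

    def transformed(self, rotation: np.ndarray, translation: np.ndarray):
        """A copy with x -> R x + t applied to every atom and metal."""
        R = np.asarray(rotation)
        t = np.asarray(translation)
        chains = {
            cid: [
                Residue(
                    r.number,
                    r.name,
                    [Atom(a.name, R @ a.xyz + t, a.element) for a in r.atoms],
                )
                for r in residues
            ]
            for cid, residues in self.chains.items()
        }
        metals = [(el, R @ xyz + t) for el, xyz in self.metals]
        return StructureModel(chains, metals, list(self.unmodeled))


# ---------------------------------------------------------------------------
# PDB I/O (gemmi-backed)
# ---------------------------------------------------------------------------


def read_structure(path) -> StructureModel:
    """Read a PDB file into a :class:`StructureModel`.

    Altloc duplicates are resolved to the highest-occupancy conformer
    (first wins on ties); insertion codes are rejected outright; zinc and
    other metal HETATMs populate ``metals``.
    """
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise StructureError(f"no models in {path}")
    model = st[0]
    out = StructureModel()
    metal_elements = {"ZN", "FE", "MG", "MN", "CA", "CU", "NI", "CO", "NA", "K"}
    for chain in model:
        residues: list[Residue] = []
        for res in chain:
            if res.seqid.icode not in (" ", "", "\x00"):
                raise StructureError(
                    f"insertion code {res.seqid.icode!r} at residue "
                    f"{res.seqid.num} not supported"
                )
            if res.het_flag == "H" and res.name.upper() in metal_elements and len(res) == 1:
                a = res[0]
                out.metals.append(
                    (a.element.name, np.array([a.pos.x, a.pos.y, a.pos.z]))
                )
                continue
            if res.name == "HOH":
                continue
            best: dict[str, gemmi.Atom] = {}
            for a in res:
                prev = best.get(a.name)
                if prev is None or a.occ > prev.occ:
                    best[a.name] = a
            atoms = [
                Atom(a.name, np.array([a.pos.x, a.pos.y, a.pos.z]), a.element.name)
                for a in best.values()
            ]
            residues.append(Residue(res.seqid.num, res.name, atoms))
        if residues:
            out.chains[chain.name] = residues
    if not out.chains:
        raise StructureError(f"no polymer chains parsed from {path}")
    return StructureModel(out.chains, out.metals)  # re-validate ordering


def write_structure(model: StructureModel, path) -> None:
    """Write a StructureModel as a PDB file (3-decimal coordinates)."""
    st = gemmi.Structure()
    st.name = "model"
    gm = gemmi.Model("1")
    serial = 1
    for cid, residues in model.chains.items():
        chain = gemmi.Chain(cid)
        for r in residues:
            res = gemmi.Residue()
            res.name = r.name
            res.seqid = gemmi.SeqId(r.number, " ")
            for a in r.atoms:
                atom = gemmi.Atom()
                atom.name = a.name
                atom.pos = gemmi.Position(*a.xyz)
                atom.element = gemmi.Element(a.element or a.name[:1])
                atom.occ = 1.0
                atom.serial = serial
                serial += 1
                res.add_atom(atom)
            chain.add_residue(res)
        gm.add_chain(chain)
    if model.metals:
        mchain = gemmi.Chain("Z")
        for i, (el, xyz) in enumerate(model.metals, 1):
            res = gemmi.Residue()
            res.name = el.upper()
            res.seqid = gemmi.SeqId(i, " ")
            res.het_flag = "H"
            atom = gemmi.Atom()
            atom.name = el.upper()
            atom.pos = gemmi.Position(*xyz)
            atom.element = gemmi.Element(el)
            atom.occ = 1.0
            res.add_atom(atom)
            mchain.add_residue(res)
        gm.add_chain(mchain)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Kabsch superposition
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Superposition:
    """Optimal rigid map x -> R x + t of mobile onto target, with RMSD."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    paired_residues: tuple[tuple[int, int], ...] = ()

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch_superpose(
    mobile: np.ndarray,
    target: np.ndarray,
    paired_residues: Sequence[tuple[int, int]] = (),
) -> Superposition:
    """Least-squares optimal proper rigid superposition (Kabsch, via SVD).

    Reflections are excluded by flipping the sign of the smallest singular
    direction when det(V Uᵀ) < 0.  Collinear or near-collinear point sets
    have no unique rotation about the line and are rejected.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(target, dtype=float)
    if P.shape != Q.shape:
        raise ValueError(f"point-set shapes differ: {P.shape} vs {Q.shape}")
    if P.ndim != 2 or P.shape[1] != 3 or P.shape[0] < 3:
        raise ValueError("need at least 3 paired 3-D points")
    if not (np.all(np.isfinite(P)) and np.all(np.isfinite(Q))):
        raise ValueError("non-finite coordinates")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - cp, Q - cq
    scale = max(np.linalg.norm(P0), np.linalg.norm(Q0), 1e-12)
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    # Rank < 2 after centering => points (near-)collinear: rotation about
    # the common axis is unconstrained.
    sv_p = np.linalg.svd(P0, compute_uv=False)
    sv_q = np.linalg.svd(Q0, compute_uv=False)
    if sv_p[1] < 1e-8 * scale or sv_q[1] < 1e-8 * scale:
        raise DegenerateGeometryError("collinear point set: superposition not unique")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d if d != 0 else 1.0])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    diff = P @ R.T + t - Q
    rmsd = float(np.sqrt((diff**2).sum() / P.shape[0]))
    return Superposition(R, t, rmsd, tuple(paired_residues))


# ---------------------------------------------------------------------------
# Template ranking
# ---------------------------------------------------------------------------


@dataclass
class TemplateEntry:
    """A candidate modelling template: structure + sequence + ligand sites."""

    template_id: str
    structure: StructureModel
    chain_id: str
    ligand_positions: tuple[int, ...] = ()

    @property
    def sequence(self) -> ProteinSequence:
        return self.structure.chain_sequence(self.chain_id)

    @property
    def gap_vector(self) -> tuple[int, ...]:
        p = self.ligand_positions
        return tuple(b - a - 1 for a, b in zip(p, p[1:]))


@dataclass(frozen=True)
class TemplateScore:
    template_id: str
    percent_identity: float
    longest_contiguous_block: int
    ligand_spacing_compatibility: float
    combined: float = float("nan")


def spacing_compatibility(gaps_a: Sequence[int], gaps_b: Sequence[int]) -> float:
    """1 − normalised L1 distance between inter-ligand gap vectors.

    Normalisation by the summed gap totals maps the distance into [0, 1],
    so identical spacing scores 1 and fully disjoint spacing scores 0.
    """
    if len(gaps_a) != len(gaps_b):
        raise ValueError("gap vectors differ in length")
    total = sum(gaps_a) + sum(gaps_b)
    if total == 0:
        return 1.0
    l1 = sum(abs(a - b) for a, b in zip(gaps_a, gaps_b))
    return 1.0 - l1 / total


def longest_aligned_block(aln: PairwiseAlignment) -> int:
    """Longest run of alignment columns that are identical or similar
    (positive substitution score), with no gaps."""
    matrix = aln.params.matrix()
    best = run = 0
    for x, y in zip(aln.aligned_a, aln.aligned_b):
        if x != "-" and y != "-" and (x == y or matrix[x, y] > 0):
            run += 1
            best = max(best, run)
        else:
            run = 0
    return best


def _minmax_scale(values: list[float]) -> list[float]:
    lo, hi = min(values), max(values)
    if hi - lo < 1e-12:
        return [1.0] * len(values)
    return [(v - lo) / (hi - lo) for v in values]


def rank_templates(
    query: ProteinSequence,
    query_assignment: LigandAssignment,
    templates: Sequence[TemplateEntry],
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
    params: AlignmentParams | None = None,
) -> list[TemplateScore]:
    """Rank modelling templates by the three classic selection criteria:
    overall sequence identity to the query, longest contiguous block of
    homologous residues, and zinc-ligand spacing compatibility.

    Components are min-max scaled across the template set and combined as
    a weighted sum (equal weights by default).  Templates without ligand
    annotation are excluded with a warning.  Ties break on template_id.
    """
    usable: list[TemplateEntry] = []
    for t in templates:
        if len(t.ligand_positions) != len(query_assignment.positions):
            warnings.warn(
                f"template {t.template_id} lacks a full ligand annotation; excluded"
            )
            continue
        usable.append(t)
    if not usable:
        return []
    idents, blocks, compats = [], [], []
    for t in usable:
        aln = pairwise_global_align(query, t.sequence, params)
        idents.append(aln.report.percent_identity)
        blocks.append(float(longest_aligned_block(aln)))
        compats.append(spacing_compatibility(query_assignment.gaps, t.gap_vector))
    s_id = _minmax_scale(idents)
    s_bl = _minmax_scale(blocks)
    s_cp = _minmax_scale(compats)
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    scores = [
        TemplateScore(
            template_id=t.template_id,
            percent_identity=idents[i],
            longest_contiguous_block=int(blocks[i]),
            ligand_spacing_compatibility=compats[i],
            combined=float(w[0] * s_id[i] + w[1] * s_bl[i] + w[2] * s_cp[i]),
        )
        for i, t in enumerate(usable)
    ]
    return sorted(scores, key=lambda s: (-s.combined, s.template_id))


# ---------------------------------------------------------------------------
# CA-level threading
# ---------------------------------------------------------------------------


def thread_model(
    query: ProteinSequence,
    template: StructureModel,
    alignment: PairwiseAlignment,
    template_chain: str | None = None,
    query_chain_id: str = "A",
) -> StructureModel:
    """Thread a query sequence onto a template CA trace through an alignment.

    Each query residue aligned to a template residue inherits that
    residue's CA coordinate; query residues aligned to gaps are recorded in
    ``unmodeled`` (they get no coordinates).  Template metals are carried
    through unchanged.  The alignment's first row must be the query, the
    second the template chain sequence.
    """
    if template_chain is None:
        template_chain = next(iter(template.chains))
    t_residues = template.chains[template_chain]
    n_q = sum(1 for c in alignment.aligned_a if c != "-")
    n_t = sum(1 for c in alignment.aligned_b if c != "-")
    if n_q != len(query):
        raise ValueError("alignment row 1 does not match the query length")
    if n_t != len(t_residues):
        raise ValueError("alignment row 2 does not match the template chain length")
    out_residues: list[Residue] = []
    unmodeled: list[tuple[str, int]] = []
    iq = it = 0
    for x, y in zip(alignment.aligned_a, alignment.aligned_b):
        if x != "-":
            q_num = query.numbering_offset + iq
            q_name = _ONE_TO_THREE.get(query.residues[iq], "UNK")
            if y != "-":
                t_res = t_residues[it]
                ca = t_res.ca
                if ca is None:
                    raise StructureError(
                        f"template residue {t_res.number} lacks a CA atom"
                    )
                out_residues.append(
                    Residue(q_num, q_name, [Atom("CA", ca.xyz.copy(), "C")])
                )
            else:
                unmodeled.append((query_chain_id, q_num))
            iq += 1
        if y != "-":
            it += 1
    if not out_residues:
        raise ValueError("empty alignment: no query residue received coordinates")
    metals = [(el, xyz.copy()) for el, xyz in template.metals]
    return StructureModel({query_chain_id: out_residues}, metals, unmodeled)


# ---------------------------------------------------------------------------
# Interface residues, exposure, zinc geometry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InterfaceResidue:
    chain: str
    number: int
    name: str
    min_distance: float


@dataclass(frozen=True)
class InterfaceReport:
    cutoff: float
    residues: tuple[InterfaceResidue, ...]

    def positions(self) -> set[tuple[str, int]]:
        return {(r.chain, r.number) for r in self.residues}

    def to_records(self) -> list[dict]:
        return [
            {
                "chain": r.chain,
                "residue": r.number,
                "name": r.name,
                "min_distance": round(r.min_distance, 3),
            }
            for r in self.residues
        ]


def interface_residues(
    model: StructureModel,
    partner: "StructureModel | str",
    cutoff: float = 5.0,
) -> InterfaceReport:
    """Residues of ``model`` with any heavy atom within ``cutoff`` Å of any
    heavy atom of the partner (inclusive boundary).

    ``partner`` may be a separate structure or the id of one of the model's
    own chains (which is then excluded from the reported side).  The
    KD-tree acceleration is exact: results equal the all-pairs scan.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if isinstance(partner, str):
        partner_atoms = [
            a.xyz
            for r in model.chains[partner]
            for a in r.atoms
            if a.is_heavy
        ]
        own = [(c, r) for c, r in model.all_residues() if c != partner]
    else:
        partner_atoms = [
            a.xyz
            for _, r in partner.all_residues()
            for a in r.atoms
            if a.is_heavy
        ]
        own = list(model.all_residues())
    if not partner_atoms:
        return InterfaceReport(cutoff, ())
    tree = cKDTree(np.array(partner_atoms))
    hits = []
    for cid, res in own:
        coords = res.heavy_coords()
        if coords.shape[0] == 0:
            warnings.warn(f"residue {res.number} in chain {cid} has no heavy atoms")
            continue
        d, _ = tree.query(coords)
        dmin = float(np.min(d))
        if dmin <= cutoff:
            hits.append(InterfaceResidue(cid, res.number, res.name, dmin))
    hits.sort(key=lambda r: (r.chain, r.number))
    return InterfaceReport(cutoff, tuple(hits))


def exposure_score(
    model: StructureModel,
    chain_id: str,
    residue_number: int,
    radius: float = 10.0,
    cap: int = 20,
) -> float:
    """Burial-based solvent-exposure proxy in [0, 1].

    Counts CA atoms within ``radius`` Å of the residue's CA (self excluded)
    and maps the count through 1 − min(count, cap)/cap: an isolated residue
    scores 1 (fully exposed), a residue with ``cap`` or more CA neighbours
    scores 0 (buried).  A proxy for solvent accessibility, not an SASA.
    """
    res = model.find_residue(chain_id, residue_number)
    if res.ca is None:
        raise StructureError(f"residue {residue_number} has no CA atom")
    center = res.ca.xyz
    count = 0
    for cid, other in model.all_residues():
        if cid == chain_id and other.number == residue_number:
            continue
        ca = other.ca
        if ca is not None and np.linalg.norm(ca.xyz - center) <= radius:
            count += 1
    return 1.0 - min(count, cap) / cap


@dataclass(frozen=True)
class ZincSiteReport:
    zinc_index: int
    ligand_distances: tuple[tuple[int, float], ...]  # (residue number, Å to Zn)
    flagged: tuple[int, ...]  # residue numbers outside tolerance

    @property
    def passed(self) -> bool:
        return not self.flagged


def zinc_geometry_check(
    model: StructureModel,
    assignment: LigandAssignment,
    chain_id: str | None = None,
    tolerances: tuple[float, float] = (1.8, 3.0),
) -> list[ZincSiteReport]:
    """Validate ligand–zinc distances at each predicted zinc site.

    Each cross-brace ligand quartet is matched to the zinc ion nearest its
    ligand centroid; ligand distance uses the side-chain sulfur (SG) when
    present, otherwise CA.  Distances outside ``tolerances`` Å are flagged.
    """
    zincs = [xyz for el, xyz in model.metals if el.upper() == "ZN"]
    if len(zincs) < 2:
        raise StructureError(f"expected >= 2 zinc ions, found {len(zincs)}")
    if chain_id is None:
        chain_id = next(iter(model.chains))
    lo, hi = tolerances
    reports = []
    for group in assignment.zinc_partition:
        coords = {}
        for num in sorted(group):
            res = model.find_residue(chain_id, num)
            atom = res.atom("SG") or res.atom("S") or res.ca
            if atom is None:
                raise StructureError(f"ligand residue {num} has no SG or CA atom")
            coords[num] = atom.xyz
        centroid = np.mean(list(coords.values()), axis=0)
        zn = min(zincs, key=lambda z: np.linalg.norm(z - centroid))
        zn_index = next(i for i, z in enumerate(zincs) if z is zn)
        dists = tuple(
            (num, float(np.linalg.norm(xyz - zn))) for num, xyz in coords.items()
        )
        flagged = tuple(num for num, d in dists if not lo <= d <= hi)
        reports.append(ZincSiteReport(zn_index, dists, flagged))
    return reports
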