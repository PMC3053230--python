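"""Synthetic benchmark generators with known ground truth.

Three generators mirror the three data modalities of the analysis:

* :func:`gen_ring_sequence` — protein sequences with a planted C4C4
  ligand spacing on a cysteine-free background, so the motif scanner has
  a unique recoverable truth;
* :func:`gen_ring_structure` — toy coordinates with two idealised
  tetrahedral zinc sites, a CA trace through the ligand residues and a
  partner chain placed so a known residue subset lies inside the contact
  cutoff (with a safety margin against the coordinate jitter);
* :func:`gen_broods` — per-worm brood counts with line-level log-normal
  random effects and genotype-level rescue fractions, emulating the
  layout of a transgenic-rescue assay (several independently derived
  lines per construct, a handful of scored worms per line).

Every generator is a pure function of its config's seed: the same config
yields byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .sequences import LigandAssignment, ProteinSequence, SpacingModel
from .structures import Atom, Residue, StructureModel

#: The SPE-42-like inter-ligand spacing used as the default planted motif.
DEFAULT_GAP_VECTOR = (2, 15, 2, 4, 2, 6, 2)

#: Background composition: uniform over the 19 non-cysteine residues, so
#: planted cysteines are the only scanner candidates.
BACKGROUND_ALPHABET = "ADEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SequenceConfig:
    seed: int = 0
    gap_vector: tuple[int, ...] = DEFAULT_GAP_VECTOR
    n_terminal_pad: int = 8
    c_terminal_pad: int = 8
    numbering_offset: int = 670
    ligand_residue: str = "C"


@dataclass(frozen=True)
class StructureConfig:
    seed: int = 0
    zn_s_distance: float = 2.3          # Å, ideal ligand S to zinc
    zn_separation: float = 14.0         # Å between the two zinc ions
    gap_vector: tuple[int, ...] = (2, 2, 2, 2, 2, 2, 2)
    contact_distance: float = 3.5       # Å, planted partner-atom distance
    contact_cutoff: float = 5.0         # Å, cutoff the truth is planted for
    n_contacts: int = 4
    jitter_sigma: float = 0.0           # Å, Gaussian noise applied last
    numbering_offset: int = 1


@dataclass(frozen=True)
class BroodConfig:
    seed: int = 0
    wild_type_mean: float = 110.0       # grand mean brood of reference lines
    dispersion: float = 3.0             # negative-binomial shape (smaller = wider)
    line_sigma: float = 0.2             # SD of log-normal line random effect
    lines_per_genotype: int = 3
    worms_per_line: int = 10
    fractions: Mapping[str, float] = field(
        default_factory=lambda: {"wild type": 1.0, "mutant": 0.5}
    )
    zero_inflation_null: float = 0.0    # extra P(0) for fractions < 0.10
    reference: str = "wild type"


@dataclass(frozen=True)
class SimulationConfig:
    """Umbrella config bundling the three generators' parameters."""

    seed: int = 0
    sequence: SequenceConfig = field(default_factory=SequenceConfig)
    structure: StructureConfig = field(default_factory=StructureConfig)
    brood: BroodConfig = field(default_factory=BroodConfig)


def gen_ring_sequence(
    config: SequenceConfig,
) -> tuple[ProteinSequence, LigandAssignment]:
    """A sequence with one planted ligand spacing and no background cysteines."""
    model = SpacingModel.c4c4()
    gaps = config.gap_vector
    if len(gaps) != model.ligand_count - 1:
        raise ValueError("gap vector must have 7 entries")
    for (lo, hi), g in zip(model.gap_ranges, gaps):
        if not lo <= g <= hi:
            raise ValueError(f"planted gap {g} outside consensus range ({lo},{hi})")
    rng = np.random.default_rng(config.seed)
    span = model.ligand_count + sum(gaps)
    length = config.n_terminal_pad + span + config.c_terminal_pad
    letters = list(rng.choice(list(BACKGROUND_ALPHABET), size=length))
    pos = config.n_terminal_pad
    positions = []
    for i in range(model.ligand_count):
        letters[pos] = config.ligand_residue
        positions.append(config.numbering_offset + pos)
        if i < len(gaps):
            pos += gaps[i] + 1
    seq = ProteinSequence("synthetic-ring", "".join(letters), config.numbering_offset)
    return seq, LigandAssignment(tuple(positions))


_TETRA = np.array(
    [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
) / np.sqrt(3.0)


def gen_ring_structure(
    config: StructureConfig,
) -> tuple[StructureModel, LigandAssignment, set[tuple[str, int]]]:
    """Toy two-zinc structure plus partner chain with planted contacts.

    Returns the structure (chain A: the zinc-finger trace; chain B: the
    partner), the ground-truth ligand assignment and the planted contact
    set {(chain, residue number)}.  Raises if the planted geometry leaves
    any residue inside the cutoff ± 2σ ambiguity band, so jittered output
    always has an unambiguous truth.
    """
    rng = np.random.default_rng(config.seed)
    zn1 = np.zeros(3)
    zn2 = np.array([config.zn_separation, 0.0, 0.0])
    # Cross-brace: slots 1,2,5,6 (0-based 0,1,4,5) on zn1; 3,4,7,8 on zn2.
    slot_zn = {0: zn1, 1: zn1, 4: zn1, 5: zn1, 2: zn2, 3: zn2, 6: zn2, 7: zn2}
    slot_vertex = {0: 0, 1: 1, 4: 2, 5: 3, 2: 0, 3: 1, 6: 2, 7: 3}
    gaps = config.gap_vector
    if len(gaps) != 7:
        raise ValueError("gap vector must have 7 entries")

    lig_ca = {}
    lig_s = {}
    for slot in range(8):
        zn, v = slot_zn[slot], _TETRA[slot_vertex[slot]]
        lig_s[slot] = zn + config.zn_s_distance * v
        lig_ca[slot] = zn + 2.0 * config.zn_s_distance * v

    # Partner contact atoms: one pseudo-atom per chosen contact ligand,
    # pushed radially outward along the ligand's tetrahedral axis.
    contact_atoms = [
        slot_zn[s] + (2.0 * config.zn_s_distance + config.contact_distance)
        * _TETRA[slot_vertex[s]]
        for s in range(config.n_contacts)
    ]
    contact_arr = np.array(contact_atoms)
    # Spacer residues must never stray inside the contact cutoff of a
    # partner atom (the planted truth is the ligand contacts only), so
    # straight-line interpolants are pushed out of a safety sphere.
    safe = config.contact_cutoff + 2.0 * config.jitter_sigma + 1.0

    def _clear_of_partner(p: np.ndarray) -> np.ndarray:
        for _ in range(20):
            d = np.linalg.norm(contact_arr - p, axis=1)
            i = int(np.argmin(d))
            if d[i] >= safe:
                return p
            u = p - contact_arr[i]
            n = np.linalg.norm(u)
            u = u / n if n > 1e-9 else np.array([0.0, 0.0, 1.0])
            p = contact_arr[i] + safe * 1.01 * u
        raise ValueError("could not route spacer trace clear of partner atoms")

    residues: list[Residue] = []
    number = config.numbering_offset
    lig_numbers = []
    for slot in range(8):
        lig_numbers.append(number)
        residues.append(
            Residue(
                number,
                "CYS",
                [Atom("CA", lig_ca[slot].copy(), "C"), Atom("SG", lig_s[slot].copy(), "S")],
            )
        )
        if slot < 7:
            a, b = lig_ca[slot], lig_ca[slot + 1]
            for k in range(1, gaps[slot] + 1):
                number += 1
                frac = k / (gaps[slot] + 1)
                xyz = _clear_of_partner(a + frac * (b - a))
                residues.append(Residue(number, "ALA", [Atom("CA", xyz, "C")]))
            number += 1
    assignment = LigandAssignment(tuple(lig_numbers))

    ca_all = np.array([r.ca.xyz for r in residues])
    centroid = ca_all.mean(axis=0)
    contact_targets = lig_numbers[: config.n_contacts]
    partner_res: list[Residue] = []
    pnum = 1
    for p in contact_atoms:
        partner_res.append(Residue(pnum, "GLY", [Atom("CA", p.copy(), "C")]))
        pnum += 1
    for k in range(4):  # distal filler, far from chain A
        partner_res.append(
            Residue(pnum, "GLY", [Atom("CA", centroid + np.array([0.0, 60.0 + 3.8 * k, 0.0]), "C")])
        )
        pnum += 1

    # Ground truth from planted (pre-jitter) geometry: residues within the
    # cutoff of any partner atom, by a direct distance scan.  Reject
    # configs whose geometry leaves any residue inside the cutoff +/- 2*sigma
    # ambiguity band, so jitter can never flip the truth.
    band = 2.0 * config.jitter_sigma
    p_coords = np.array([a.xyz for r in partner_res for a in r.atoms])
    truth: set[tuple[str, int]] = set()
    for r in residues:
        d = min(
            float(np.min(np.linalg.norm(p_coords - a.xyz, axis=1))) for a in r.atoms
        )
        if abs(d - config.contact_cutoff) <= band or d == config.contact_cutoff:
            raise ValueError(
                f"geometry ambiguous: residue {r.number} at {d:.2f} Å of partner "
                f"(cutoff {config.contact_cutoff} ± {band:.2f}); lower jitter_sigma "
                "or move contact_distance away from the cutoff"
            )
        if d < config.contact_cutoff:
            truth.add(("A", r.number))
    if truth != {("A", n) for n in contact_targets}:
        raise ValueError("planted contact set is not the intended target set")

    model = StructureModel(
        {"A": residues, "B": partner_res},
        metals=[("Zn", zn1), ("Zn", zn2)],
    )
    if config.jitter_sigma > 0:
        for _, r in model.all_residues():
            for a in r.atoms:
                a.xyz = a.xyz + rng.normal(0.0, config.jitter_sigma, 3)
    return model, assignment, truth


def gen_broods(config: BroodConfig) -> tuple[pd.DataFrame, dict[str, float]]:
    """Long-format brood counts with planted genotype rescue fractions.

    Per line: a log-normal random effect (mean 1) scales the genotype's
    expected brood; per worm: a negative-binomial count around the line
    mean.  Genotypes with planted fraction below 0.10 optionally get extra
    zero-inflation, mimicking the near-sterile mutants of such assays.
    """
    if config.wild_type_mean <= 0:
        raise ValueError("wild-type mean brood must be positive")
    rng = np.random.default_rng(config.seed)
    rows = []
    for genotype, fraction in config.fractions.items():
        if fraction < 0:
            raise ValueError(f"negative rescue fraction for {genotype}")
        for li in range(config.lines_per_genotype):
            effect = float(
                np.exp(rng.normal(-0.5 * config.line_sigma**2, config.line_sigma))
            )
            mu = config.wild_type_mean * fraction * effect
            tg = f"sim-{genotype}-{li + 1}"
            for wi in range(config.worms_per_line):
                if mu <= 0:
                    c = 0
                else:
                    k = config.dispersion
                    c = int(rng.negative_binomial(k, k / (k + mu)))
                    if (
                        fraction < 0.10
                        and config.zero_inflation_null > 0
                        and rng.random() < config.zero_inflation_null
                    ):
                        c = 0
                rows.append(
                    {
                        "transgene_id": tg,
                        "genotype": genotype,
                        "worm_id": f"worm-{wi + 1}",
                        "progeny_total": c,
                    }
                )
    return pd.DataFrame(rows), dict(config.fractions)
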