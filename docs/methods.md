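# Methods

This note documents the models and procedures implemented in
`ringscape`, their assumptions and tunable parameters, the synthetic
benchmarks, and the design choices made where the underlying methodology
is genuinely open.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. Zinc-ligand assignment by constraint satisfaction

A RING finger binds two Zn²⁺ ions through eight side chains.  The
`SpacingModel` encodes, per ligand slot, the allowed residues and, per
adjacent slot pair, a window on the number of residues strictly between
them.  Defaults:

| parameter | default | meaning |
|---|---|---|
| `ligand_count` | 8 | slots in the cross-brace |
| `gap_ranges` | (2,2), (9,39), (1,3), (2,4), (2,2), (4,48), (2,2) | inter-ligand spacing windows (residues) |
| slot residues | C ×8 (`c4c4`) | `c3hc4` allows H at slot 4; `permit_aspartate` adds D |
| `forbid_internal_free_cysteines` | on | reject parses leaving an unassigned C inside the span |

The windows follow the classic RING consensus, with the slot-4→5 window
widened to (2,4); family members (including the SPE-42 domain, whose
gaps are 2,15,2,4,2,6,2) sit inside these windows but no published
numeric ranges exist for the C4C4 subfamily, so the ranges are
configurable rather than fixed facts.

`scan_ring_ligands` runs a depth-first search over candidate positions
with gap-window pruning; it is complete (tested against exhaustive
enumeration of all candidate subsets on every fuzzed input ≤ 80 aa).
Assignments partition into the canonical cross-brace: ligands 1,2,5,6 on
one zinc, 3,4,7,8 on the other.  The partition is a structural
convention of the family, not something sequence alone can prove.

**The free-internal-cysteine rule.** Spacing windows alone can be
ambiguous: in the SPE-42 C-terminal domain the nine cysteines admit two
window-consistent parses — one starting at C681 (leaving C678 upstream
of the motif) and one starting at C678 (leaving C684 unassigned *inside*
the motif, because the slot-2→3 window tolerates both a 15- and an
18-residue gap).  The scanner's default resolves this on chemical
grounds: an unassigned free thiol strictly inside the cross-brace core
would compete for Zn²⁺ coordination and is disallowed, while candidates
outside the matched span are merely reported as excluded.  This yields a
unique parse for SPE-42 that excludes C678 — consistent with the
domain-swap genetics, where C678A alone has no phenotype.  The rule is a
scanner default, not a theorem; `forbid_internal_free_cysteines=False`
restores pure spacing semantics (and reports both parses).

## 2. Pairwise alignment and divergence statistics

Global Needleman–Wunsch alignment with affine gaps via Biopython's
`PairwiseAligner`: BLOSUM62, gap open 10, extend 0.5.  Percent identity
counts identical columns over **all** alignment columns (gap columns in
the denominator); percent similarity additionally counts substitutions
with positive BLOSUM62 score.  These conventions are decisions — ortholog
comparisons in the literature rarely state their method, so reported
identity figures can differ by a point or two depending on denominator
convention and gap parameters.  `cterminal_divergence` recomputes both
statistics over the alignment columns touched by the last *k* residues
of either sequence, for questions about divergent C-terminal tails
(e.g. tails encoded by their own exon).

The optimal score is oracle-tested against exhaustive alignment-path
enumeration on short strings; statistics are symmetric in the inputs and
invariant to numbering offsets.

## 3. Structure analysis

**Representation.** `StructureModel` holds chains of residues (typed
atoms with Å coordinates) plus free metal ions.  PDB I/O goes through
gemmi; altloc duplicates resolve to the highest-occupancy conformer,
insertion codes are rejected (renumber upstream), and metal HETATMs
populate `metals`.

**Kabsch superposition.** Centroid-centred SVD with the determinant
correction, so reflections are never returned.  Near-collinear point
sets (second singular value < 1e-8 of the cloud scale) are rejected as
degenerate rather than silently returning one of infinitely many optimal
rotations.  Tested for optimality against 1000 sampled rigid transforms
per cloud, against an independent SVD reference, and against a
Nelder–Mead minimiser over rotation vectors (agreement within 1e-6 Å).

**Template ranking.** Three criteria per template: global percent
identity to the query; the longest gap-free run of identical-or-similar
aligned columns; and ligand-spacing compatibility
1 − Σ|gq−gt| / (Σgq+Σgt) ∈ [0,1].  Components are min–max scaled across
the template set and combined as a weighted sum (equal weights by
default; the weighting is a package decision, as template-selection
criteria are usually stated without weights).  Ties break
lexicographically on template id; templates without ligand annotation
are excluded with a warning.

**Threading.** Deliberately minimal: query residues aligned to template
residues inherit the template CA coordinate; gap-aligned query residues
are flagged `unmodeled`; template metals are carried through.  This is a
stand-in for restraint-based homology modelling — sufficient for
CA-level geometry (superposition, neighbour counts, interface calls on
CA-resolution models), and deliberately not an all-atom model builder.
Interface and exposure analyses accept threaded and user-supplied
all-atom models alike.

**Interface residues.** A residue is at the interface iff the minimum
distance from any of its heavy atoms to any partner heavy atom is ≤ the
cutoff (default 5 Å, boundary inclusive).  Any-heavy-atom contact was
chosen because published interface figures display side chains; the
KD-tree implementation is tested equal to the brute-force all-pairs scan
and is monotone in the cutoff.

**Exposure proxy.** 1 − min(n, cap)/cap where n is the number of CA
atoms within 10 Å of the residue's CA (cap 20).  A burial proxy, not an
SASA: it ranks exposed vs buried positions on CA-level models where no
solvent-accessibility algorithm applies.  Radius and cap are
configurable.

**Zinc-site geometry.** Each cross-brace ligand quartet is matched to
its nearest zinc; ligand–Zn distances use SG when present (CA otherwise)
and must fall in [1.8, 3.0] Å — bracketing the ~2.3 Å Zn–S coordination
bond — else the site is flagged.  Used to validate synthetic structures
and sanity-check models.

## 4. Rescue-assay quantification

Per line: mean brood ± SEM (sample SD, n−1, over √n).  Table entries
printed as "<1" are ingested as the interval (0,1) with numeric value
0.5 and a flag; single-worm lines carry an undefined-SEM flag.  Lines
whose non-transgenic control siblings produced any progeny are excluded
as recombinants (the null background is fully sterile, so control
progeny indicate a recombinant chromosome); lines without controls are
retained with a logged warning.

Genotype level: the grand mean is the **unweighted mean of line means**
— independently derived transgenic arrays differ strongly in expression,
so lines are the replication unit.  On the packaged compensation table
this convention gives C681A = 51/110 ≈ 46.4%; pooling worms instead
(`n-weighted`) gives a slightly different figure (≈45%), which is why
both modes exist and the choice is explicit in every report.
Classification thresholds (null-like < 0.10 ≤ partial ≤ 0.80 < full) are
configurable conventions, not measured quantities.

The compensation verdict is a deterministic function of the three
fractions: *compensatory* iff single A is full, the double is null-like,
and single B is partial or clearly better than the double;
*independent* iff the double matches the product of the singles within
tolerance (multiplicative model of unrelated defects); two null-like
singles are *inconclusive* (no signal).  No hypothesis tests are
attached — the assay tables carry three lines per construct, and the
bootstrap intervals provided are descriptive percentile intervals over
lines (seeded, reproducible).

## 5. Synthetic benchmarks

* **Sequences**: planted gap vector (default 2,15,2,4,2,6,2 — the
  SPE-42 spacing) with uniform non-cysteine background, so the planted
  ligands are the only candidates and recovery is exact.
* **Structures**: two idealised tetrahedral zinc sites (Zn–S 2.3 Å,
  Zn–Zn 14 Å), a pseudo-CA trace through the ligands (spacers
  interpolated between ligand CAs and routed outside a safety sphere
  around partner atoms), and a partner chain with one atom placed
  3.5 Å outside each of the first `n_contacts` ligands.  Ground truth
  is computed from the pre-jitter geometry by a direct distance scan;
  configurations where any residue falls within cutoff ± 2σ of the
  boundary are refused, so Gaussian jitter (σ configurable) can never
  flip the truth.  Pseudo-atoms only (CA + SG): sufficient for every
  geometric operation implemented, with no pretence of a physical fold.
* **Broods**: line effect ~ logNormal(−σ²/2, σ) (mean 1, σ default 0.2
  matching the relative spread of real line means), per-worm counts ~
  NegativeBinomial(mean = wild-type mean × fraction × effect, shape 3 —
  chosen so a mean-92 line has SD ≈ 50, as in the wild-type transgene
  arm), defaults 3 lines × 10 worms as in the assay design.  Optional
  zero-inflation for near-null genotypes.

What these benchmarks do **not** emulate: real structural folds,
evolutionary sequence covariation, day-to-day brood-count correlation,
or germline-silencing effects on transgene expression.  Passing recovery
tests therefore demonstrates the correctness of the computations, not
the biological fidelity of upstream data.

## 6. Numerical and study-design choices

* Problem sizes: the parameter-recovery study uses 200 seeded replicates
  per planted fraction at the default 3×10 design; the bootstrap
  coverage study uses 500 replicates with 20 lines per arm and B = 400,
  since percentile-bootstrap coverage is an asymptotic property and the
  3-line design is far outside its regime (with 3 lines the interval is
  knowingly anti-conservative and documented as descriptive).
* All randomness flows through `numpy.random.default_rng` seeds carried
  in configs; identical configs give byte-identical outputs, and
  pipeline outputs embed a SHA-256 hash of the resolved config.
* Distances are Å throughout; residue numbering is 1-based in the
  input's own coordinate system (`numbering_offset`), so reported
  positions match published residue numbers.
* Known limitations: threading gives no side-chain coordinates, so
  5 Å interface calls on threaded models are CA-level approximations of
  the all-atom definition; the scanner's uniqueness on SPE-42 depends on
  the free-internal-cysteine rule (section 1); identity/similarity
  figures depend on the stated alignment conventions; ortholog
  comparisons require user-supplied sequences (none ship with the
  package).
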