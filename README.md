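# ringscape

Structural and quantitative analysis of C4C4 RING-finger domains, built
around the *C. elegans* sperm protein SPE-42: sequence-level assignment of
the eight zinc-coordinating cysteines, light-weight template threading
with protein–protein interface prediction, and quantification of
transgenic-rescue fertility assays.

## The scientific problem

SPE-42 is a six-pass membrane protein required for sperm–egg fusion.  Its
C-terminal cytoplasmic domain carries a predicted RING finger: two Zn²⁺
ions held in a cross-brace arrangement by eight cysteine side chains (the
C4C4 pattern, in contrast to the C3HC4 arrangement of most E3 ubiquitin
ligases).  Three analyses recur in the study of such domains, and
`ringscape` implements each as a tested, scriptable stage:

1. **Zinc-ligand assignment.** Given a sequence with candidate cysteines,
   which eight are the ligands?  The domain is located by constraint
   satisfaction: an assignment places candidates into the 8 slots so that
   each inter-ligand gap gᵢ (residues strictly between ligands i and i+1)
   falls inside a consensus window.  The default windows are the classic
   RING consensus C-x₂-C-x₍₉₋₃₉₎-C-x₍₁₋₃₎-C-x₍₂₋₄₎-C-x₂-C-x₍₄₋₄₈₎-C-x₂-C.
   The scan is complete (every valid assignment is returned), and by
   default rejects parses that leave a free cysteine inside the matched
   span, since an unpaired thiol in the cross-brace core would compete
   for Zn²⁺.  On the SPE-42 C-terminal domain (cysteines at 678, 681,
   684, 700, 703, 708, 711, 718, 721) this yields a unique assignment
   that excludes C678.
2. **Template ranking, threading and interface calling.** Candidate
   modelling templates are ranked by percent identity, longest contiguous
   homologous block, and ligand-spacing compatibility
   (1 − ‖g_query − g_template‖₁ / (Σg_query + Σg_template)).  The query
   is threaded rigidly onto the best template's CA trace through a global
   alignment, and interface residues are called as all residues with any
   heavy atom within a cutoff (default 5 Å) of a partner chain — the
   standard way to read an E2-binding surface off a co-crystal template.
   Superpositions use the Kabsch algorithm (proper rotations only).
3. **Rescue quantification.** Protein function is measured as brood size
   (live progeny per hermaphrodite) of transgenic lines in a sterile null
   background.  For genotype g with line means m̄₁…m̄ₖ, the rescue
   fraction is f_g = mean(m̄ᵢ) / mean(m̄ⱼ^wt) — independently derived
   lines, not worms, are the replication unit.  Fractions classify as
   null-like (< 0.10), partial, or full (> 0.80), and a single/double
   mutant triple tests compensation: full single A + partial single B +
   null-like double is the signature that A can substitute for the loss
   of B (as C678 does for C681).

Synthetic generators (`ringscape.simulate`) produce sequences with
planted motifs, toy two-zinc structures with planted partner contacts,
and negative-binomial brood counts with line-level random effects, so
every stage has a closed recovery loop without external downloads.

## Worked example

The packaged fixture `load_brood_tables(2)` holds the printed line
summaries of the cysteine-compensation assay:

```python
from ringscape import RescueModel, load_brood_tables

results = RescueModel.from_dataframe(
    load_brood_tables(2), reference="wild type"
).fit(bootstrap=1000, seed=0)
print(results.summary())
print(results.compensation("C678A", "C681A", "C678A; C681A").verdict)
```

```
Transgenic rescue summary (reference: wild type, unweighted)
============================================================
    genotype  lines  grand_mean  rescue_fraction  rescue_percent classification  ci_low  ci_high
       C678A      3     110.333            1.003         100.303           full   0.873    1.185
       C681A      3      51.000            0.464          46.364        partial   0.355    0.592
C678A; C681A      3       2.000            0.018           1.818      null-like   0.010    0.027
   wild type      3     110.000            1.000         100.000           full   0.828    1.207
...
compensatory
```

Read: lines carrying the C678A transgene rescue at wild-type level
(100%), C681A retains ~46% of wild-type activity, and the C678A;C681A
double collapses to ~2% — so C678 is not itself a zinc ligand but can
partially compensate when C681 is lost.  The bracketing columns are
percentile-bootstrap 95% intervals over lines.

The sequence side from the shell:

```sh
ringscape scan-ring --fasta spe42_cterm.fasta --offset 670
# -> 1 assignment: ligands 681,684,700,703,708,711,718,721; excluded: 678
```

`ringscape run-all --config config.yaml` chains scan → template ranking
→ threading → interface calling (or broods → rescue report) and writes
JSON/TSV outputs stamped with the config hash.

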