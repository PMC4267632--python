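# Methods

## Model

`costruct` predicts the common secondary structure of two unaligned RNA
homologs by minimizing a joint free energy over all pseudoknot-free
structure pairs and all alignments consistent with them:

    dG_total = dG1 + dG2 + n_gap * dG_gap
               + sum_i (dG_opening + x_i * dG_elongation)

`dG1`/`dG2` are nearest-neighbor folding energies; `n_gap` counts
unaligned nucleotides outside inserted domains; each inserted domain of
length `x_i` pays an affine opening + per-nucleotide elongation penalty
*instead of* per-gap penalties (the two penalty systems never stack on
the same nucleotide — otherwise insertions would be strictly dominated).
Only nucleotides in conserved base pairs are structurally aligned; loop
nucleotides are placed freely, so gap counts inside a loop region reduce
to the length difference of the corresponding unpaired stretches.

### Energy model

A reduced, self-consistent nearest-neighbor model, shipped as a
plain-text bundle and fully configurable:

* sequence-dependent helix stacks for the six canonical pairs
  (AU, UA, GC, CG, GU, UG), symmetric under strand reversal;
* hairpin / internal-loop / bulge initiations by loop length (tables to
  size 30, logarithmic extrapolation beyond, coefficient 1.1 kcal/mol);
* internal-loop asymmetry 0.6 kcal/mol per unit, capped at 3.0;
  length-1 bulges keep the flanking helix stack and pay no end
  penalties;
* a 0.5 kcal/mol penalty per A-U or G-U helix end, charged once per
  helix terminus in the loop it borders (hairpin and internal loops
  include their closing-pair penalties; multibranch and exterior loops
  charge each branch; stacks charge nothing);
* a linear multibranch model: closure 3.4, per-branch 0.4, per-unpaired
  0.0 kcal/mol (the last deliberately zero, as in later linear fits of
  the Turner model);
* alignment penalties: gap 0.4, domain opening 0.5, domain elongation
  0.1 kcal/mol per nucleotide.

No dangling ends, coaxial stacking, or special hairpin bonuses: the
algorithmic recursions, not the parameter set, are the point, and the
reduced motif set keeps the exhaustive reference oracle exact and
tractable.  All energies live on a fixed decimal grid (integer tenths
of kcal/mol), so DP comparisons and traceback tie-breaks are exact
integer operations and every run is bit-reproducible.

### Recursions

The joint DP fills `V(i,j,k,l)` (minimum energy of fragments [i,j], [k,l]
with i–j and k–l paired and aligned) and `W(i,j,k,l)` (aligned
multibranch-loop content with at least one conserved branch), plus
prefix/suffix arrays `W5(i,k)` / `W3(j,l)`.  `V` composes hairpins
(+ gap for the loop-length difference), aligned two-pair motifs
(internal/bulge/stack in both sequences, + gaps for side-length
differences), multibranch closures, and, per move set:

* **stackII** — a motif in one sequence aligned with 2–5 consecutive
  stacked pairs in the other (lockstep indices, no gaps), and a whole
  motif inserted in one sequence only (every inserted nucleotide pays a
  gap); these realize stem extensions and base-pair openings;
* **domain insertion** — a fragment of one sequence spliced out of the
  alignment at one of four positions flanking the aligned content
  (5'/3' side of either sequence), priced as opening + elongation plus
  a precomputed single-sequence energy.

Inserted-domain content comes from four auxiliary single-sequence
arrays, computed by an ordinary Zuker-style fold of each homolog:
multibranch-context content with >= 1 branch (`wm`) and exterior-context
content with >= 1 branch (`web`).  A domain inserted into a multibranch
loop charges its branches and unpaired nucleotides at multibranch
rates; one inserted into the exterior loop charges unpaired nucleotides
nothing.  A domain must contain at least one hairpin (the arrays are
infinite otherwise); zero-length insertions are excluded by the strict
recursion bounds.

When a domain insertion leaves only one conserved branch in the other
sequence's loop, that loop is still scored as a multibranch loop (the
lone stem-loop is charged as a branch).  This deliberate simplification
keeps the recursion local; the independent rescoring applies the same
convention so the traceback/rescoring identity is exact.

`W5`/`W3` extend with unpaired nucleotides (a gap when only one
sequence extends), add conserved branches, and splice exterior domains.
Prefix indices start at 0 (`W5(0,k) = k` gaps), so branches and domains
may begin at position 1.  The global optimum is `W5(N1,N2) = W3(1,1)`;
the identity is asserted on every run.

### Alignment band and pair filter

Alignment coordinates are restricted to a fixed diagonal band
`|k - i*N2/N1| <= d/2` (default `d = max(10, 0.2*max(N1,N2))`, rounded
even, widened to `2|N1-N2|` when the endpoints would otherwise be
unreachable).  This replaces the HMM-posterior alignment envelope used
by the heavier production implementations: one model fewer, same
`O(N^3 d^3)` complexity.  Candidate pairs are pre-filtered per sequence:
pair i–j is kept if the best single-sequence structure containing it
(inside + outside energy) lies within `window_percent` (default 0.2) of
the MFE; `window_percent = 1` disables the filter.  Helix-extension and
domain pairs are not subject to the filter (they enter through stacks
and the single-sequence arrays, not through V cells).

### Traceback and rescoring

Traceback re-derives, per cell, which term attains the stored value, in
a fixed priority order (hairpin > internal/stack > stackII > multibranch
> domain insertion, smallest index first), so ties resolve
deterministically and conservative, conserved-motif interpretations are
preferred.  The traced structure is rescored from scratch by
`total_energy`, which never consults the DP tables: it rebuilds the
joint tree from the conserved quadruples, classifies each loop (both
sequences' branch counts plus hosted domains), recomputes `dG1`, `dG2`
per sequence, recounts gaps per loop region (inserted-domain
nucleotides excluded), and re-minimizes only the step decomposition of
helix-extension chains (whose per-sequence motif sums are
decomposition-invariant — only the gap count needs the minimization).
`total_energy(traceback(fill(...)))` must equal `W5(N1,N2)` exactly; a
mismatch is a hard assertion failure.

## Validation strategy

The acceptance surface is exhaustive enumeration, sharing no code with
the DP fill: `enumerate_structures` lists every pseudoknot-free
structure of one short sequence; `enumerate_common` crosses two such
lists with every order-isomorphic pair matching and every legal
domain-interval annotation and rescans them with `total_energy`.  On
random pairs of length 6–10 with an unconstrained band, the DP optimum
equals the enumerated optimum exactly (integer tenths).  At these
lengths the enumeration exercises exterior-loop insertions and all
stackII moves; multibranch-loop insertions need ~40 nt and are covered
by targeted construction tests plus the rescoring identity.

## Synthetic fixtures

`make_fixture` emulates homolog pairs with a conserved multi-hairpin
core: GC-only stems (5' to 3': linker, stem-loop, linker, ...), linkers
and loops drawn from {A, C} so they cannot pair with each other,
compensatory mutations applied per conserved pair (default rate 0.3,
drawing any canonical pair), optional single-pair helix jitter (a stem
one pair longer in sequence 2), and an optional planted stem-loop
domain (GC stem, poly-A loop) spliced into a linker of one sequence.
Defaults (3 stems of 4–5 pairs, loops 4–6, linkers 6–8, planted stems
4–6 pairs) give 60–100 nt pairs.  Generation self-checks that each
sequence's reference structure is its single-sequence MFE fold under
the shipped parameters, redrawing deterministically otherwise — the
planted features are study conditions and must be thermodynamically
supported, or recovery would measure fixture artifacts rather than the
algorithm.

What the fixtures do not emulate: sequence-identity signal in loops
(the objective ignores it anyway), non-compensatory mutations that open
pairs asymmetrically, pseudoknots, modified nucleotides, and the length
and compositional heterogeneity of real ncRNA families.  Passing the
fixture suite therefore demonstrates correctness of the optimization
and the insertion machinery under the stated model, not accuracy on
biological benchmarks, which additionally depends on the richness of
the thermodynamic parameters.

## Problem sizes and numerics

Test and acceptance runs use: 200 random pairs (6–10 nt) for oracle
equivalence, 100 random sequences (<= 12 nt) for the single-sequence
oracle, 50 planted-domain fixtures (60–100 nt, band width 20) for
insertion recovery, and three 60–125 nt banded fixtures for the global
identities.  The DP kernels are compiled with numba (single-threaded,
integer arithmetic, cached after first use); a 80 nt pair with band 28
fills in a few seconds.  Band edges are computed in exact integer
arithmetic (`|2*k*N1 - 2*i*N2| <= d*N1`), avoiding floating-point
rounding at the band boundary.

## Known limitations

* Only the optimal common structure is traced; no suboptimal structures
  or pair probabilities.
* Two sequences only; no pseudoknots; no temperature dependence.
* The reduced energy bundle is not the full Turner 2004 model; absolute
  energies and accuracy on real families will differ from
  production-grade implementations, though richer tables can be dropped
  into the bundle format.
* The "original" move set is the conserved-motif core (every pair
  aligned); the historic single-pair-insertion special case of early
  implementations is not reproduced.
* The reference alignment emitted by the fixture generator aligns
  position-to-position outside the planted domain; it does not model
  alignment uncertainty.
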