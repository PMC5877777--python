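# Methods

## Scope and model

`allonet` identifies dynamically coupled residue networks in a single
protein chain and predicts where a site-mutation's structural effect is
likely to land.  Four models are composed; their assumptions are listed
with each.

### Cross-correlation of residue fluctuations

The dynamical cross-correlation map is the normalized covariance of the
3-vector node fluctuations over a frame window,
C(i,j) = ⟨Δr_i·Δr_j⟩/(⟨Δr_i²⟩^½⟨Δr_j²⟩^½), with Δr the deviation from the
window-mean position.  The same normalized covariance serves both the map
itself and the edge weights of the pathway graph — implementing it once
avoids silent divergence between the two stages.  Assumptions: fluctuations
are meaningful only after global rotation/translation is removed, so frames
are rigid-body superposed first (all-node Kabsch fit; the "mean" reference
iterates align → recompute-mean twice).  A node with zero variance in the
window makes C undefined and is reported as an error naming the residue,
never silently patched.

Window: by default the final 10% of frames (the equilibrium tail of a
production trajectory); any absolute half-open frame interval can be given
instead.  The synthetic fixtures set the window to the full frame range
because their frames are stationary by construction.

Region tiers relative to an anchor residue default to red ≥ 0.7,
orange ∈ [0.55, 0.7), yellow ∈ [0.4, 0.55), anticorrelated ≤ −0.4, rest
unclassified.  Published correlation maps are usually colour-coded without
numeric boundaries, so these are configuration, recorded in output
metadata, not inferred quantities.

### Correlation-weighted residue graph and pathways

Nodes are Cβ atoms (Cα for glycine — glycine has no Cβ; where sources
disagree on this convention the Cα fallback is used).  An edge survives iff
the node pair is within 5.7 Å in at least half of the frames; the boundary
is inclusive (frequencies *below* 0.5 are removed).  Edge weight is the
correlation C_ij; the path cost is w = −ln|C| by default (strong coupling →
short edge; standard in correlation-based network analysis), with
w = 1 − |C| available.  |C| is floored at 1 − 1e−12 so costs stay strictly
positive, and C = 0 edges are dropped (infinite cost).  The magnitude is
used because perturbations propagate through strongly coupled neighbours
whether the phase is correlated or anticorrelated.

Dijkstra search breaks cost ties by fewer hops, then by lexicographically
smallest residue sequence, so pathway outputs are reproducible.  Per-site
pathway bundles de-duplicate traversed edges (shared stems appear once).
The correlation→cost transform and the tie-break are design choices the
source material leaves open; both are flagged in output metadata.

### Centrality on the 7.0 Å contact network

Separate from the weighted graph: edges are defined purely by a 7.0 Å Cβ
cutoff, unweighted, distances in hops.  Betweenness uses Brandes
fractional counting over unordered pairs with endpoints excluded (the
verbal "number of shortest paths through a node" is ambiguous under ties;
fractional counting is the standard the field's tooling uses).
Reachability L_i averages hop distances over residues actually reachable
within a frame; unreachable pairs are excluded from the denominator and
tallied, and a residue isolated in every frame gets NaN, never a silent 0.
ΔBC/ΔL is provided both between two states (wild-type vs mutant) and
against the first window of a sliding sequence; peak extraction defaults
to local maxima with z ≥ 2, with top-k as the alternative.

### Ensemble allosteric model

Folding units tile the chain: consecutive windows of 8 residues, terminal
units at least 4 (a short trailing remainder merges into the last unit;
164 residues → 20×8 + 4 = 21 units).  Each unit is folded or unfolded,
2^U states, enumerated exhaustively up to the hard cap U = 24 (no silent
sampling; above the cap the model refuses and suggests a coarser window).
State free energy is the sum of unfolding penalties g_u of unfolded units;
the native state sits at 0 by convention.  Per-residue stability constants
κ_f,j = W_folded/W_unfolded over Boltzmann weights, ΔG_f,j = −RT ln κ_f,j
with R = 1.987×10⁻³ kcal/(mol·K) and T = 298.15 K by default.  A mutation
at residue k shifts g of k's unit by δ_k; the coupling is
ΔΔG_j = ΔG_f,j(mut) − ΔG_f,j(WT).

**Surrogate energetics.**  The COREX-style surface-area parameterization of
unit energetics is not publicly specified, so the unfolding penalties are a
declared surrogate: uniform (g_u = ΔG_total/U, calibrated so the fully
unfolded state sits at the configured overall stability, default
5 kcal/mol), user-supplied, or structure-derived (g_u proportional to the
unit's mean Cβ contact number at 7.0 Å, rescaled to the overall total).
Consequence worth stating plainly: with additive unit energies the
ensemble factorizes, so ΔΔG is exactly zero outside the mutated unit —
the surrogate reproduces the ensemble *machinery* exactly but not the
inter-unit cooperativity a surface-area model would add.  Absolute ΔΔG
values from the surrogate are therefore not comparable to published
COREX numbers; the thresholding, region extraction and consensus logic
downstream are energy-model-agnostic.

δ_k defaults to a per-residue-type table, −0.15 kcal/mol per side-chain
heavy atom removed by the X→Ala substitution (bundled constants, always
overridable); on a poly-Ala chain this is zero, so synthetic demos pass an
explicit δ.  Shifted partitions (COREX-style window sliding) are supported
via the `shift` parameter; the default is a single shift-0 partition.
Susceptibility thresholding is strict (>) on |ΔΔG| by default, with a
signed mode behind a flag because the conventional phrasings differ.

### Consensus

Percent consistency is recall of the reference set
(|query ∩ reference|/|reference| × 100); because head-to-head method
comparisons may intend a symmetric measure, Jaccard overlap is co-reported
in every result.  Empty references yield an explicit missing value with a
warning, not 0 or 100.

## Synthetic data: what it emulates and what it does not

`make_correlated_trajectory` draws per-axis displacements from a
multivariate normal whose correlation matrix is built from latent factors:
a block (A, B, ρ) loads √|ρ| on A and sign(ρ)√|ρ| on B.  This makes the
vector-dot correlation equal the planted scalar in expectation (identical
loadings on x/y/z) and gives tests an analytic oracle; it also implies
|ρ| within A and within B, and cross-pair-only planting would not be
positive semi-definite.  PSD is validated before sampling; per-residue
total factor variance above 1 is rejected with the offending residue
named.

These trajectories are statistical, not dynamical: no force field, no
kinetics, no solvent, no anharmonicity, no time correlation between
frames.  Passing tests therefore demonstrate the estimators and graph
machinery are correct, not that any MD protocol samples equilibrium.
Structures are ideal α-helix bundles (rise 1.5 Å, 100° twist, Cα radius
2.3 Å) with a pseudo-Cβ 1.53 Å from Cα tilted 45° from the outward helix
normal toward the axis — the tilt reproduces the ~5.4 Å Cβ(i)–Cβ(i±1) and
~5.6 Å Cβ(i)–Cβ(i±3) contacts of real helices, so both the 5.7 Å and
7.0 Å networks get realistic intra- and inter-helix edges.  Helix packing
distance is chosen on a fixed grid so the closest inter-helix node pair
falls in [4.0, 5.7] Å.  A 0.02 Å seeded jitter breaks exact symmetry.

Problem sizes in the shipped demo and test fixtures (30 residues,
600-frame demo; 5000-frame estimation checks; graphs to n = 12; ensembles
to U = 16) are the package's choices for desk-scale reproducibility; every
generator scales beyond them.

## Numerical choices

- Superposition via scipy's rotation alignment after centering;
  degenerate (collinear) frames are rejected.
- DCCM is symmetrized, clipped to [−1, 1] and the diagonal pinned to 1
  after the einsum accumulation; agreement with a naive two-pass
  direct-summation oracle is ≤ 1e−12 by test.
- PDB coordinates carry 3 decimals; round-trips through files are exact at
  that precision, and files written by the package re-write byte-
  identically.  First altloc kept, hydrogens and HETATM ignored,
  insertion-code duplicates resolved to the first occurrence.
- Ensemble enumeration is chunked bit-mask arithmetic; results are
  invariant to chunk size (tested), and state tables are stored only for
  U ≤ 16.
- κ with no unfolded weight is reported as +inf with ΔG_f = −inf (flagged,
  never NaN); unreachable path targets return an explicit no-path result.
- Golden-file comparisons print floats at 6 decimals; the stored goldens
  are compared token-wise with a 1e−6 numeric tolerance so that BLAS
  reduction-order differences across machines cannot masquerade as
  regressions, while two runs in one environment must match byte-for-byte.

## Known limitations

- Single-chain analyses; no PDBx/mmCIF, no binary trajectory formats in
  v1 (the multi-model PDB contract is the interchange format).
- The additive ensemble surrogate has no inter-unit cooperativity (see
  above); structure-derived energies are a declared heuristic.
- No suboptimal-path ensembles, community detection, or eigenvector/
  closeness centralities.
- Correlation tiers and the cost transform are configuration; results
  should be reported together with the recorded metadata.
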