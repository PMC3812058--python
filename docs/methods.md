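# Methods

This note documents the models, calibrated constants, and design choices
behind `pocketspace`, and states what the synthetic test conditions do and
do not establish about real structural data.

## Pocket definition and curation

A residue belongs to a pocket when any of its heavy atoms lies closer to a
ligand heavy atom than the sum of the two van der Waals radii plus 2.8 Å
(the diameter of a water probe). Radii are a Bondi-style element table
(C 1.70, N 1.55, O 1.52, S/P 1.80 Å, …) shipped as an editable mapping with
a configurable fallback of 1.70 Å for unlisted elements.

Curation reproduces the survey's published filters in order: ligands must
have at least 10 and fewer than 200 heavy atoms; polymeric HET groups
(peptide- or nucleotide-like linkage atoms, plus standard residue codes)
and common solvents/buffers/ions are excluded; when one entry holds several
copies of the same HET code, the copy with the most contacts is kept (ties:
first occurrence); the primary chain of each pocket (the chain contributing
most contacts) is clustered at 90% sequence identity by greedy incremental
clustering (longest sequence first); within each (cluster, HET code) one
representative survives, preferring better X-ray resolution and then more
contacts; finally pockets with 10 or fewer residues are dropped. Pocket
residues from *all* chains are retained; the primary chain is only a
clustering key. Sequence identity is the identity count of an optimal
global alignment divided by the shorter sequence length — the conventional
denominator for redundancy clustering.

## PS-score

For an alignment of N_a residue pairs between a template (length L_T) and a
query (length L_Q), under a rigid superposition of the query:

    PS = max over superpositions of
         (1/L_Q) * sum_i [ 1/(1 + d_i^2/d0^2) ] * (p_i + c*r_i)/(1 + c)

* `d_i` — Cα–Cα distance of pair i (Å).
* `p_i` — Cα→Cβ directional similarity, (1 + cos θ_i)/2; 1.0 when both
  residues are glycine and 0.77 when exactly one is (the mean directional
  term of random alignments). Residues whose Cβ cannot be placed follow
  the glycine convention; for non-glycine residues with full backbones the
  Cβ is first reconstructed at ideal tetrahedral geometry from N/Cα/C.
* `r_i` — 1 when both amino acids fall in the same of eight chemical
  groups, LVIMC / AG / ST / P / FYW / EDNQ / KR / H, else 0. Nonstandard
  residues match nothing.
* `c = 0.1` — weight of the chemical term relative to the geometric terms;
  small so that geometry dominates while chemistry still breaks ties.
* `d0(L_Q)` — distance scale,
  `d0 = max(0.50, [0.70*(L_Q-5)^(1/3) - 0.20] * (L_Q/50)^(-0.2))` Å.

The cube-root form of d0 belongs to the TM-score family of
length-normalized distance kernels. The leading constants (0.70, −0.20)
are the package's defaults for pocket-sized point sets; the exponent −0.2
of the length-scaling factor was calibrated with the shipped recalibration
routine (`pipeline.fit_length_scaling`): it is the grid value that makes
the mean PS-score of aligned random pocket pairs flat in pocket length
(relative spread across L ∈ {20, 40, 80} under 1%, measured on 30 null
pairs per length; verified under 10% on an independent seed). The
reference length 50 pins the scale so that typical pockets are unaffected.
A companion routine (`pipeline.fit_d0_constants`) refits the d0 constants
to the Cα-distance distribution of random superposed correspondences if a
different synthetic regime is used.

Normalizing by the query length makes the score directional: PS(A→B)
differs from PS(B→A) when lengths differ. Identical pockets score exactly
1.0, the upper bound.

## Alignment search

1. **Seeds.** All gapless relative shifts (enumerated outward from zero
   shift, capped at 60), 6-mer fragment matches whose internal Cα distance
   matrices agree within 0.8 Å on average, a coarse 3-state secondary
   structure alignment (states from the i→i+3 Cα distance: 4.3–6.2 Å helix,
   9.0–11.5 Å strand), and a local contact-pattern alignment (Cα neighbors
   within 8 Å). Seeds are quick-scored by a single superposition.
2. **Sequential phase.** From each of the top 3 seeds, iterate:
   superpose on current pairs → score all residue pairs → global
   Needleman–Wunsch (gap opening −0.6 × mean pair score, free extension —
   small openings, as in TM-score-family aligners) → new pairs; stop on a
   repeated pair set or after 30 iterations.
3. **Non-sequential phase.** From the best sequential superposition *and*
   four permutation-invariant principal-axis superpositions, iterate:
   score → linear sum assignment (in-package shortest-augmenting-path
   solver, O(N³)) → drop pairs contributing less than 10% of the best
   pair's score (suppresses spurious long-distance pairs) → re-superpose;
   up to 30 iterations. The non-sequential result replaces the sequential
   one only when its PS-score is strictly higher; exact ties prefer the
   sequential alignment, then larger N_a, then lower RMSD.

The "max over superpositions" is realized heuristically: each candidate
pair set is evaluated by superposing on all pairs and then repeatedly on
the close subset (Cα distance < max(2·d0, 4.5 Å)), keeping the best score
encountered. The reported RMSD is the least-squares RMSD over the final
aligned pairs. The whole search is deterministic for fixed inputs.

Degenerate inputs: pockets with fewer than 3 residues cannot be aligned
(error); collinear point sets cannot be superposed (error); an empty
alignment scores 0 by convention.

## Significance

Because the PS-score is a maximum over many alignment trials, null scores
are modeled by a Gumbel (type I extreme value) distribution, fitted by
maximum likelihood per pocket-length bin (minimum 200 samples per bin;
underfilled bins widen symmetrically with a warning). P(s) is the fitted
survival function; at the fitted location μ it equals 1 − e⁻¹ ≈ 0.632, and
the P = α crossing is μ + β·(−ln(−ln(1−α))).

Calibrated on 2,000 aligned pairs of unrelated synthetic pockets with
lengths in [45, 55] (seed 1), the P = 0.05 crossing lands at a PS-score of
≈ 0.34, with null scores centered at ≈ 0.29. The empirical null tail is
slightly lighter than the fitted Gumbel, so P-values are conservative: the
empirical false-positive rate at nominal P < 0.05 is ≈ 0.016. Absolute
P-values are therefore not interchangeable with those of other
implementations, although score rankings are stable.

## Ligand chemistry

Fingerprints enumerate all linear heavy-atom paths of up to 7 bonds
(atoms never revisited, so pure ring-closure paths are not distinguished),
canonicalize each path string end-to-end, and set two salted-CRC32 bits per
path on a 1024-bit vector. This is an operational stand-in for
"Daylight-like" fingerprints: deterministic, atom-order invariant, and
suitable for Tanimoto ranking and thresholding, but absolute Tc values are
implementation-specific. Two empty fingerprints have Tc 0 by convention.
Conformer RMSD matches heavy atoms by name (unmatched names are dropped
with a warning; symmetry-equivalent atoms are not canonicalized) and uses
Kabsch superposition.

## Contact classification and conserved fractions

Atoms fall into five classes: hydrophilic (N/O), aliphatic carbon,
aromatic carbon (ring carbons of F/Y/W/H on the protein side; a caller
supplied flag for ligand atoms), sulfur, and other. A symmetric class-pair
matrix assigns each contact a type: hydrophilic–hydrophilic pairs are
hydrogen bonds when within 3.35 Å (else neutral); carbon–carbon pairs are
hydrophobic (aromatic–aromatic: aromatic); hydrophilic–carbon pairs are
unfavorable; sulfur acts hydrophobically toward carbon and neutrally toward
hydrophilic atoms; "other" is always neutral. This taxonomy is a documented
approximation of the upstream contact-typing program, whose internals are
not published; dataset-level composition percentages are therefore treated
as qualitative references only.

The contact surface area of a pair is the spherical cap cut on the
solvent-expanded protein-atom sphere (radius + 1.4 Å) by the radical plane
of the expanded ligand-atom sphere. Since the two probe radii sum to the
2.8 Å contact allowance, the area decays continuously to zero exactly at
the contact cutoff. Caps competing for one protein atom are rescaled so
their sum never exceeds the expanded hemisphere.

Between two complexes sharing a pocket (residue correspondence by key for
same-protein pairs, by alignment otherwise), a contact is conserved when
the corresponding residue makes a contact of the same type in both; its
conserved area is the smaller of the two sides' per-(residue, type) areas.
The per-type fraction is f_i = S_cons,i / mean(S_p1,i, S_p2,i) — symmetric
in complex order, 1 on self-comparison, clipped to [0, 1]. The exact
denominators of the published formula are not recoverable from the source
text; the arithmetic mean is this package's documented choice. Types absent
from both complexes are reported as missing, not zero.

## Graph analyses

An edge A→B exists when the alignment *with B as the query* passes both
thresholds (PS ≥ ps_min, P < p_max); the direction convention fixes which
length normalizes each edge, which the survey leaves open. Two pockets are
matched when connected in both directions. The greedy dominating set
repeatedly selects the node matching the most still-unmatched nodes (a node
matches itself; ties break lexicographically — determinism for tests) until
every node is matched, so isolated pockets self-represent and coverage is
complete by construction. SCCs come from networkx; the LSCC fraction is
|LSCC| / |nodes|. Growth curves recompute the dominating set per cumulative
year (pockets without a deposition year are excluded with a warning).
Ligand subspaces consider HET codes with more than 30 pockets and report
LSCC coverage within each subspace.

## Synthetic data: what it does and does not emulate

Synthetic pockets are compact self-avoiding Cα chains (steps 3.8 ± 0.2 Å,
clipped to [3.2, 4.4]; non-adjacent Cα ≥ 4 Å; confined to a sphere of
radius 3.2·L^(1/3) Å, matching protein-like packing density) with Cβ atoms
at ideal geometry and amino acids sampled uniformly over the eight chemical
groups. Complexes wind the contact residues on a helix of radius 5.5 Å
around an axial ligand so that the contact rule is satisfied with ≥ 0.5 Å
margin for contacting residues and ≥ 1 Å clearance for all others — contact
tables are therefore exact ground truth. Fingerprint pairs hit a requested
Tanimoto within ±0.02 by explicit bit-count construction; synthetic graphs
carry planted cliques and, for n ≤ 12, the exhaustively computed minimum
dominating set.

These generators emulate geometry, not biology: there is no secondary
structure realism, no amino-acid composition bias, no ligand chemistry, and
no evolutionary redundancy structure. That is adequate for validating the
scoring, search, calibration, and graph machinery — the PS-score depends
only on Cα/Cβ geometry and residue identity — but passing tests do not
establish that absolute thresholds (e.g. the significance onset) transfer
unchanged to curated PDB pockets, whose shapes are more regular and more
clustered than random chains. Full-scale survey numbers (20,414 pockets,
1,315 representatives, mean Tc 0.162) depend on a specific PDB snapshot
and on upstream programs and are out of scope.

## Problem sizes and determinism

The shipped test suite and the acceptance script run at desk scale: 2,000
null pairs for significance calibration, 40 pairs per length for the
length-independence check, 50 perturbation seeds per noise level, 100 seeded
point sets / cost matrices for the superposition and assignment oracles,
and 20 seeded 12-node graphs for the domination oracle. These sizes give
stable means (standard errors well inside the asserted tolerances) while
keeping a full run in the low minutes on one CPU. Every stochastic routine
takes an explicit integer seed (default 1); alignments themselves are
deterministic.

## Known limitations

* The alignment search is heuristic; the global maximum over superpositions
  is not certified (mitigated by multi-seed DP, principal-axis starts, and
  the subset-superposition refinement).
* P-values are calibrated to this package's null ensemble and are slightly
  conservative; cross-implementation absolute P-values differ.
* Fingerprints do not perceive aromaticity or stereochemistry; bond orders
  for PDB HET groups default to single bonds unless a component dictionary
  is supplied.
* Contact typing and surface areas approximate an unpublished upstream
  method; per-type percentages should be compared qualitatively.
* mmCIF input, biological assemblies, and symmetry mates are out of scope.
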