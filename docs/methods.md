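# Methods

## Scope and model

`wadjetscan` reconstructs, at desk scale, a comparative-genomics procedure
for discovering Wadjet/Mks (MukBEF-like) SMC operons in annotated genomes
and placing their SMC (MksB) subunits on a phylogeny. The procedure has
four stages:

1. **Profile search.** Per-family position-specific scoring matrices
   (PSSMs) for MksB (SMC ATPase), MksF (kleisin), MksE (KITE) and MksG
   (nuclease) are built from family alignments and scored against every
   protein in a genome set by local alignment.
2. **Operon inference.** Three co-directional genes whose best hits are a
   permutation of {MksF, MksE, MksB}, strictly adjacent in gene order,
   form a candidate operon; a co-directional MksG hit immediately up- or
   downstream is attached (upstream preferred). Candidates then pass a
   filter cascade: MksB longer than 890 residues (strict) and carrying a
   Walker-A motif; MksF within 400–1200 residues and MksE within 150–800
   (inclusive); and at least two genes flanking the operon on both sides
   of the contig, so that only fully sequenced operons survive. Every
   rejection carries a machine-readable reason code
   (`B_LEN`, `B_WALKER`, `F_LEN`, `E_LEN`, `EDGE`).
3. **Iterative refinement.** Search → inference → profile rebuild is run
   a fixed number of rounds (default 6). Rebuilt profiles use the member
   proteins of accepted operons, clustered at 80% identity to dampen
   redundancy and progressively re-aligned. Families that gain no members
   keep their previous profile.
4. **Composite phylogeny.** Members (plus any external reference SMC
   sequences) are globally aligned to a reference; the N-terminal head,
   C-terminal head and hinge regions are extracted, re-aligned separately
   and concatenated. Columns with more than 30% gaps are removed.
   Pairwise Poisson-corrected distances feed neighbor joining with
   column-resampling bootstrap; the trimmed composite is also exported
   (relaxed PHYLIP + partition file) for external maximum-likelihood
   programs.

## Alignment machinery

All aligners share one affine-gap dynamic program over a precomputed
cell-score matrix, with full Gotoh state transitions (a gap may open from
the match state or from the opposite gap state; with BLOSUM62 the worst
mismatch at −4 can lose to two opposing gap extensions at −2, so the
restricted recurrence would be suboptimal). Gap convention everywhere: a
gap of length L costs `open + (L−1)·extend`, defaults 11/1 with BLOSUM62
for residue-level alignment. Unknown residues (X) score 0 against
everything, never count as identities, and never match in distance
calculations.

* **Pairwise identity** = identical aligned pairs / min(sequence
  lengths). The input pair is canonicalized (lexicographic order) before
  aligning so the value is exactly symmetric even when co-optimal
  alignments exist. The min-length denominator makes fragments behave
  predictably under clustering.
* **Clustering** is greedy and longest-first (ties by name): a sequence
  joins the first existing cluster whose representative it matches at or
  above the threshold (default 0.80), else founds a new cluster. This is
  a deterministic stand-in for set-cover clustering heuristics.
* **Progressive alignment** builds a neighbor-joining guide tree on 3-mer
  cosine distances and merges profiles by DP over sum-of-pairs BLOSUM62
  column scores (column frequency vectors; gaps carry no mass). Inputs
  are canonicalized by name, so member order never changes the result.
  Degapping any output row returns its input sequence.

## Profiles

A profile is built from an alignment by dropping columns with more than
50% gaps (a standard profile-HMM heuristic, configurable) and scoring
residue *a* in a match column as

    s_a = log2( ((c_a + α·b_a) / (N + α)) / b_a )   [bits]

with `c_a` the residue count, `N` the column's residue total, `α` the
pseudocount weight (default 1.0) and `b` the background distribution
(uniform 1/20 by default; a custom vector is accepted). Limits behave
analytically: a single-sequence profile at α→0 scores log2(20) ≈ 4.32
bits per observed residue; α→∞ flattens all scores to zero.

Sequences are scored by Smith–Waterman over the profile's match columns
with affine gap penalties in bits (defaults 11/1). Scores are reported in
bits and thresholded directly (default 50 bits) rather than converted to
E-values: on desk-scale databases Karlin–Altschul calibration buys
nothing, and the threshold is per-family configuration. Each gene gets a
single best family (ties break on family name), matching the operon
logic's per-gene assignment.

## Synthetic data

The generator is first-class code, not a fixture: it defines the study
conditions under which the pipeline is tested.

* **Family divergence** follows a Poisson/uniform substitution model:
  along a branch of length *b* (expected substitutions/site) each site
  substitutes with probability 1 − e^(−b), the replacement uniform over
  the other 19 residues. No rate matrix, no indels — enough to test
  profile tolerance and tree recovery with closed-form expectations.
* **Family pools** default to 12 members per family evolved along random
  join trees with branch lengths uniform in [0.05, 0.15]; default target
  lengths are MksB 1450, MksF 500, MksE 230, MksG 350 residues — inside
  the accepted filter ranges with margin, and near natural SMC sizes.
  Twelve members (not fewer) because the full 10-case plan implants nine
  distinct MksB sequences.
* **Forged genomes** place one case per contig (unambiguous truth
  mapping), default 9 genes per contig, background genes i.i.d. random
  proteins of 100–600 residues. Valid operons are three co-directional
  F,E,B genes with at least two background genes on each side. Each
  distractor violates exactly one rule: `B_TOO_SHORT` truncates MksB to
  880 residues but keeps its Walker motif; `B_NO_WALKER` ablates every
  Walker-A occurrence by a K→R substitution; `F_OUT_OF_RANGE` /
  `E_OUT_OF_RANGE` truncate below the length floor; `NOT_CODIRECTIONAL`
  flips the MksE strand; `NOT_CONSECUTIVE` inserts a background gene;
  `NEAR_CONTIG_EDGE` leaves a single flanking gene; `DECOY_BACKGROUND`
  implants nothing. Every implanted MksB (except the no-Walker case) has
  a Walker-A exemplar stitched in at a fixed offset, so motif presence is
  controlled by the case code rather than left to chance.

What the generator does **not** emulate: indel evolution (gaps arise only
from alignment), codon-level structure, compositional bias, paralogy, and
fragmented or mis-annotated gene models. Passing tests therefore
demonstrate that the discovery logic implements its stated rules and that
profile search tolerates substitution-level divergence with a wide
score margin; they do not measure sensitivity on real, messy assemblies.

## Phylogeny

Distances are p-distances over mutually non-gap columns (at least 50
required per pair) with Poisson correction d = −ln(1 − p); p is clamped
at 0.95 so distances stay finite (d ≤ −ln 0.05 ≈ 3.0). Neighbor joining
follows Saitou–Nei with the standard Q criterion; ties break on the
lexicographically smallest pair of cluster labels (a cluster's label is
its smallest leaf name) and negative branch lengths clamp to zero, so
the tree is deterministic and invariant to taxon input order. Bootstrap
resamples columns with replacement (default 100 replicates; more via
configuration) and reports, per internal split of the point-estimate
tree, the percentage of replicates containing it. NJ plus Poisson
correction stands in for external maximum-likelihood inference; the
export path (relaxed PHYLIP, aligned FASTA, partition file) preserves the
route to an external ML program, and topology-recovery tests (exact on
additive matrices, RF = 0 on sequences evolved along a known tree)
validate the in-package stand-in.

Region spans are supplied as reference-sequence coordinates in the
region-spec YAML, not derived from 3D structures; structure-guided span
choice is upstream curation. The shipped defaults for the synthetic
MksB reference (length 1450) are headN [0, 160), hinge [640, 860),
headC [1280, 1450).

## Numerical and design choices

* Filter boundary semantics: "larger than 890" is strictly exclusive at
  890; "between A and B" is inclusive at both ends. Documented so the
  audit trail is unambiguous.
* "Consecutive" means strictly adjacent order indices by default; a
  `window_slack` parameter (default 0) admits intervening genes for
  sensitivity analysis. Any permutation of F/E/B is accepted and the
  order signature recorded, since natural operon orders vary.
* MksG must be immediately adjacent and co-directional to be attached
  (configurable off); the attached MksG counts toward the contig-edge
  span.
* Walker-A only by default (`[AG]xxxxGK[ST]`); Walker-B
  (`[ILVFM]{4}D[ED]`) is available behind a flag.
* The contig-edge filter is applied in every iteration, which is
  strictly monotone versus applying it only in the final round; a toggle
  disables it.
* The iteration count is fixed (no convergence test), with an optional
  `stop_on_fixpoint` flag that halts once profile hashes repeat.
* Trimming compares each column's gap fraction to the cutoff with plain
  `<=`; the operation is idempotent because surviving columns keep their
  gap fractions.
* Each sequence record in a FASTA is treated as one contig; scaffold
  gaps are not modeled.

## Problem sizes

The shipped study conditions are deliberately desk-scale: 10 contigs of
9 genes (one truth case each), 12-member family pools, 6 refinement
iterations, 100 bootstrap replicates, 1000-site simulated alignments for
tree-recovery checks. A full pipeline run on the forge fixture completes
in well under two minutes on one CPU.

## Known limitations

* Bit-score thresholds are not calibrated statistics; on large real
  databases E-values (or per-family score calibration) would be needed.
* The progressive aligner has no iterative refinement and uses flat gap
  penalties for profile columns; it is adequate for the substitution-only
  synthetic families, not a general MAFFT replacement.
* Poisson-corrected NJ ignores rate heterogeneity and saturation beyond
  the clamp; deep SMC relationships should be inferred from the exported
  composite with an external ML program.
* MksG functional verification (e.g., structure-based inspection of
  operons lacking a G hit) is out of scope; the catalog carries the
  attachment column only.
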