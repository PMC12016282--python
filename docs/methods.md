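# Methods

## Problem

K-mer LCA classifiers (Kraken and its relatives) label each read with the
lowest common ancestor of every genome that contains the read's k-mers.
When genomes share sequence — strains of one species, or near-identical
species in one genus — reads from the shared regions are pushed up to
internal nodes of the taxonomy and never reach a species label. A Kraken
report is therefore *not* a species abundance profile: a large share of
the reads is stranded above the species level, and the amount stranded
depends on how much sequence each species shares with its neighbours.

This package re-estimates per-species read counts from a Kraken-style
report by redistributing the stranded reads with Bayes' theorem, using a
precomputed description of how each database genome classifies against
the database itself.

## The model

Fix a read length `r` and a k-mer size `k` (defaults 75 and 31). For each
database genome `S_i`, slide a window of length `r` along the genome and
classify every window with the same k-mer LCA rule used for reads: a
window's k-mers each map to a taxonomy node, all of those nodes lie on the
root-to-leaf path of `S_i`, and the window is assigned to the deepest of
them. Tallying windows per node gives, for every node `G_j` above or at
`S_i`,

    P(G_j | S_i) = (windows of S_i classified to G_j) / (total windows of S_i)

These fractions sum to 1 over each genome's path, exactly (all arithmetic
on them is done with rational numbers). The **unique fraction**

    U_i = P(S_i | S_i)

is the share of the genome's windows that classify to the genome's own
node.

Given a sample, let `K_i` be the reads the classifier assigned directly
to `S_i`. Since only a fraction `U_i` of reads drawn from `S_i` can land
on `S_i` itself, the number of reads *deriving* from the genome is
estimated as

    K̂_i = K_i / U_i

(1,000 direct reads at `U_i = 0.25` imply 4,000 reads of true origin).
Normalising the `K̂_i` over a set of candidate genomes gives the prior
`P(S_i)`. A read classified at an internal node `G_j` then came from
`S_i` with posterior probability

    P(S_i | G_j) ∝ P(G_j | S_i) · P(S_i)

where the proportionality constant renormalises over the candidate
genomes below `G_j` (conditioning on the read having been classified at
`G_j` makes `P(G_j) = 1`). Each internal node's direct reads are split
across its candidates in these proportions; priors are renormalised per
distributing node, over exactly the genomes in that node's subtree.

The final estimate for a species is its rolled-up Kraken count (its own
direct reads plus everything below it, e.g. strain-level reads) plus all
shares it received from nodes above it.

## Guarantees

* **Read conservation, exact.** Internal arithmetic uses
  `fractions.Fraction`; every classified read ends up in exactly one of a
  species estimate or the unallocated pool. Rounding to integers happens
  only when a table is written, half-to-even, and the written `added`
  column is derived from the rounded estimate so the per-row identity
  `kraken + added = estimate` survives rounding.
* **Identity limit.** If every genome is fully unique (`U_i = 1` and no
  windows above the species), no reads strand and the output equals the
  classifier's counts.
* **Nothing moves sideways.** Reads are only ever rolled up to their own
  level ancestor or pushed down within the subtree they were classified
  in. Reads in subtrees with no detected species, and reads at nodes
  where every candidate has zero signal, are reported as *unallocated*
  (with a warning), never silently dropped or reassigned elsewhere.

## Semantics and edge cases

* **Level boundary.** A node's level ancestor is its nearest ancestor-
  or-self with exactly the target rank; `no rank` nodes are transparent.
  Nodes *with* a level ancestor (the level taxon itself, strains,
  unranked subspecies clades) roll up into it. Nodes *without* one
  (genus, family, unranked clades above the level) distribute down.
* **Detection threshold.** A species counts as present only if its
  rolled-up read count reaches the threshold (default 10 reads),
  applied after strain roll-up: 4 species reads plus 7 strain reads pass
  a threshold of 10. Reads belonging to undetected species are
  unallocated, and undetected species receive nothing from above.
* **Reads between the species and its genomes.** Direct reads at
  non-genome nodes inside a species' subtree (the species node when the
  database genomes sit at strains, or unranked intermediates) are split
  across the species' genomes in proportion to their unique window
  counts before computing `K̂`, with an even split as the fallback when
  no genome has unique windows.
* **`U_i = 0`.** A genome with no unique windows cannot be inflated;
  its Kraken count is used as its derived total and a warning is
  emitted. (`K̂` would otherwise divide by zero; such a genome is
  indistinguishable from its neighbours at this `k` and `r`.)
* **Read ties.** A read whose k-mer hits support several root-to-leaf
  paths equally well is assigned the LCA of the tied paths' deepest
  nodes — the same rule brute-force path enumeration gives.
* **Windows of ambiguous bases.** A window in which every k-mer overlaps
  an `N` has no k-mer evidence and is counted at the root, so window
  tallies still sum to the window total.
* **Read-length mismatch.** Using a distribution built for a different
  `r` than the sample's read length warns but proceeds; the fractions
  degrade gracefully rather than invalidating the run.

## Parameter defaults and the mock community

`k = 31` and `r = 75` are the conventional classifier defaults for short
Illumina reads; the threshold of 10 reads suppresses the long tail of
one-off false positives that k-mer classifiers produce.

The bundled nine-species community (`skin_like_spec`) mirrors a
skin-like mock community: four species in one genus, five singleton
genera, equal proportions, with one pair of congeneric species at 99.9%
identity. Near-identity is modelled as i.i.d. point substitutions
(divergence 0.001), matching how real near-identical bacterial genomes
differ — thousands of SNPs scattered along the genome rather than one
verbatim shared block. A generator for the verbatim-block regime
(`shared_fraction`) is also provided; it produces a *different* and much
harsher ambiguity structure (whole regions with zero unique windows).
The default genome length is 100 kb so that the sister pair carries
roughly a hundred SNPs: the unique fraction is then a stable property of
the divergence, as it is for real genome pairs, rather than a
small-sample Poisson draw.

## Limitations

* The prior is estimated from the same sample being corrected
  (empirical Bayes); species with zero direct reads everywhere in a
  subtree cannot receive reads from it.
* The distribution assumes reads are uniform draws along genomes;
  coverage bias (GC, library preparation) is out of scope.
* Windows stand in for reads without sequencing errors; errors in real
  reads make classification more conservative (more reads strand higher
  or go unclassified), which the redistribution partly, but not fully,
  compensates.
* Abundance is reported in reads, not cell counts; no genome-length
  normalisation is applied.
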