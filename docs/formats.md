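# File formats

Every file the tool reads or writes is plain UTF-8 text. Columns are
separated by single tab characters (shown as `<TAB>`-free literal tabs in
the examples below); lines end with `\n`. All readers reject malformed
input rather than repairing it, and every writer/reader pair round-trips
losslessly — the Kraken report and the distribution TSV round-trip
byte-identically.

All examples on this page were produced by the package itself from one
toy setup: a genus `G` (taxid 2) holding species `S1` (taxid 3) and `S2`
(taxid 4) under the root (taxid 1).

## Reference genomes — FASTA

Standard FASTA. The record id is the first whitespace-delimited token of
the header. On reading, sequences are uppercased and `U` is mapped to
`T`; allowed bases afterwards are `ACGTN`. The writer wraps at 70
columns by default (8 in this small example):

```
>chr1
ACGTACGT
ACGT
>plasmid1
TTGGCC
```

An empty file or sequence data before the first header is an error.

## Sequence-to-taxon map — `seqid2taxid.tsv`

Two tab-separated columns, one row per FASTA record: the record id and
the taxid of the genome it belongs to. Several records may map to one
taxid (multi-contig genomes); duplicate record ids are an error.

```
chr1	3
plasmid1	3
```

## Taxonomy — `nodes.dmp` and `names.dmp`

The NCBI taxonomy dump dialect: fields separated by `\t|\t` (the reader
also accepts spaced pipes), each line terminated by `\t|`. `nodes.dmp`
carries taxid, parent taxid, rank; the root is its own parent. Exactly
one root is required; orphan parents and cycles are errors.

```
1	|	1	|	root	|
2	|	1	|	genus	|
3	|	2	|	species	|
4	|	2	|	species	|
```

`names.dmp` carries taxid, name, a unique-name field (unused, may be
empty), and the name class; only `scientific name` rows are used.

```
1	|	root	|		|	scientific name	|
2	|	G	|		|	scientific name	|
3	|	S1	|		|	scientific name	|
4	|	S2	|		|	scientific name	|
```

Recognised ranks are `root`, `domain`, `kingdom`, `phylum`, `class`,
`order`, `family`, `genus`, `species-group`, `species`, `strain`, and
`no rank`; `species group`, `superkingdom` and `leaf` are normalised to
`species-group`, `domain` and `strain`, and unknown ranks to `no rank`.

## Kraken report

Six tab-separated columns: percentage of total reads in the clade
(two decimals), clade read count, direct read count, rank code, taxid,
and the name indented two spaces per tree depth. An `unclassified` row
(taxid 0, code `U`, clade == direct) leads when present. Rows are
emitted depth-first; siblings are ordered by descending clade count,
then taxid. Rank codes are single letters (`R D K P C O F G S`);
intermediate nodes take their nearest lettered ancestor's code plus the
step count, e.g. a species group directly under a genus is `G1` and a
strain under a species is `S1`.

```
6.50	130	130	U	0	unclassified
93.50	1870	0	R	1	root
93.50	1870	420	G	2	  G
50.00	1000	1000	S	3	    S1
22.50	450	450	S	4	    S2
```

The reader rebuilds clade counts from the direct column and rejects the
file if they disagree with the clade column (the clade-sum invariant:
`clade(t) = direct(t) + Σ clade(children)`).

## K-mer distribution TSV

One file per database build. Line 1 is a header comment carrying the
k-mer size and window length; line 2 names the columns; then one row per
(genome, node) pair with a nonzero window count, genomes in ascending
taxid order and nodes root-down:

```
# k=31	r=75
genome_taxid	node_taxid	node_rank	window_count	total_windows	fraction
3	2	genus	5	10	0.5
3	3	species	5	10	0.5
4	2	genus	1	10	0.1
4	4	species	9	10	0.9
```

The integer counts are the source of truth; `fraction` is
`window_count / total_windows` written at full precision for human
inspection and verified on read. Per genome, the window counts must sum
to `total_windows`, `total_windows` must be consistent across rows, and
duplicate nodes are rejected.

## Abundance table

The estimator's output: one row per detected taxon at the target level,
sorted by descending estimate.

```
name	taxonomy_id	taxonomy_lvl	kraken_assigned_reads	added_reads	new_est_reads	fraction_total_reads
S1	3	species	1000	400	1400	0.70000
S2	4	species	450	20	470	0.23500
```

`kraken_assigned_reads` is the taxon's rolled-up classifier count,
`new_est_reads` the estimate rounded half-to-even to an integer, and
`added_reads` is defined as `new_est_reads − kraken_assigned_reads` so
the identity holds exactly in the written file. `fraction_total_reads`
is the estimate over all reads including unclassified, to five decimals.

## Truth table

Known composition of a simulated community, for scoring:

```
name	taxonomy_id	reads
S1	3	1400.0
S2	4	470.0
```

`reads` is the expected read count (proportion × total reads) and may be
fractional.
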