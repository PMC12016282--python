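"""A redistribution you can check by hand.

Two species under one genus. Kraken assigned 1,000 reads to species S1,
450 to species S2, and stranded 420 at the genus because they came from
sequence the two species share. The k-mer distribution says half of S1's
windows are genus-ambiguous (unique fraction 1/2) but only a tenth of
S2's are (unique fraction 9/10).

Following the math through by hand:

  derived totals  K/U:   1000 / (1/2) = 2000      450 / (9/10) = 500
  priors P(S):           2000/2500 = 4/5          500/2500 = 1/5
  Bayes scores P(G|S)P(S):  (1/2)(4/5) = 2/5      (1/10)(1/5) = 1/50
  genus shares:          (2/5)/(21/50) = 20/21    (1/50)/(21/50) = 1/21
  of 420 genus reads:    400                      20

so S1 ends at 1000 + 400 = 1400 reads and S2 at 450 + 20 = 470 — the
420 stranded reads go overwhelmingly to the species that both had more
reads and hides a larger share of its genome in the shared sequence.
"""

from brackenlite import KrakenReport, estimate_abundance
from brackenlite.distribution import GenomeDistribution, KmerDistribution
from brackenlite.taxonomy import TaxonNode, TaxonomyTree

tree = TaxonomyTree(
    [
        TaxonNode(1, 1, "root", "root"),
        TaxonNode(2, 1, "genus", "G"),
        TaxonNode(3, 2, "species", "S1"),
        TaxonNode(4, 2, "species", "S2"),
    ]
)

dist = KmerDistribution(
    read_length=75,
    k=31,
    per_genome={
        3: GenomeDistribution(taxid=3, num_windows=10, node_counts={3: 5, 2: 5}),
        4: GenomeDistribution(taxid=4, num_windows=10, node_counts={4: 9, 2: 1}),
    },
)

report = KrakenReport.from_direct_counts({3: 1000, 4: 450, 2: 420}, tree)

table = estimate_abundance(report, dist, tree)

print(f"{'species':<8}{'kraken':>8}{'added':>8}{'estimate':>10}")
for row in table.rows:
    print(
        f"{row.name:<8}{row.kraken_assigned_reads:>8}"
        f"{float(row.added_reads):>8.0f}{float(row.new_est_reads):>10.0f}"
    )
print(f"\nconserved: {sum(r.new_est_reads for r in table.rows)} "
      f"of {report.classified_reads} classified reads placed")
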