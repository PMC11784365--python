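"""Genome-guided pathway completeness calling with shared-gene decoys.

Several CO2-fixation key enzymes occur in more than one pathway (e.g.
4-hydroxybutyryl-CoA dehydratase in both the DC/4-HB and 3-HP/4-HB cycles),
so a genome carrying only shared genes must never be called complete.  The
caller demands every key gene plus at least one pathway-exclusive gene, and
arbitrates ambiguous key-gene-only calls by looking at completeness among
same-genus relatives.
"""

from darkfix import PathwayRegistry, call_genome, resolve_conflicts
from darkfix.pathways import call_all_genomes
from darkfix.types import GeneRecord, GenomeRecord

registry = PathwayRegistry.default()


def genome(gid, genus="Desulfogenus"):
    tax = (f"d__Bacteria;p__Desulfobacterota;c__c;o__o;f__f;"
           f"g__{genus};s__{genus} sp.")
    return GenomeRecord(genome_id=gid, taxonomy=tax, completeness=90,
                        contamination=1)


def genes(gid, pathway, symbols=None):
    pw = registry.pathways[pathway]
    return [
        GeneRecord(gene_id=f"{gid}_{kg.symbol.replace('/', '_')}",
                   genome_id=gid, length=900, ko=kg.ko, symbol=kg.symbol)
        for kg in pw.key_genes if symbols is None or kg.symbol in symbols
    ]


# a complete WLP genome, a congeneric carrying only CO dehydrogenase, and a
# DC/4-HB "decoy" holding exactly the two shared genes of that cycle
g1, g2, g3 = genome("G1"), genome("G2"), genome("G3", genus="Othertaxon")
pool = (genes("G1", "WLP")
        + genes("G2", "WLP", symbols={"cooS"})
        + genes("G3", "DC/4-HB"))  # mdh + abfD, both shared

calls = resolve_conflicts(
    call_all_genomes([g1, g2, g3], pool, registry), [g1, g2, g3], registry
)
for c in calls:
    if c.status != "absent":
        support = f" lineage_support={c.lineage_support}" if c.lineage_support else ""
        note = f" [{c.conflict_note}]" if c.conflict_note else ""
        print(f"{c.genome_id} {c.pathway:10s} {c.status:14s} "
              f"evidence={c.evidence}{support}{note}")

# G1 is complete (acsC/cdhE + cooS, both exclusive to the WLP); G2 stays
# key_gene_only but gains genus-level lineage support from G1; G3's DC/4-HB
# call can never become complete because its evidence is entirely shared.
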