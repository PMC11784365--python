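import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from darkfix.pathways import PathwayRegistry
from darkfix.synthetic import SyntheticConfig, generate_all
from darkfix.types import GeneRecord, GenomeRecord


@pytest.fixture(scope="session")
def registry():
    return PathwayRegistry.default()


@pytest.fixture(scope="session")
def default_run():
    """One default synthetic run shared by read-only tests."""
    return generate_all(SyntheticConfig(seed=11))


def random_gene(rng: np.random.Generator, gene_id: str, length: int,
                genome_id: str = "G") -> GeneRecord:
    seq = "".join(rng.choice(list("ACGT"), size=length))
    return GeneRecord(gene_id=gene_id, genome_id=genome_id, length=length, sequence=seq)


def make_genome(genome_id: str, genus: str = "Testus", phylum: str = "Testota",
                species: str | None = None, completeness: float = 90.0,
                contamination: float = 1.0) -> GenomeRecord:
    species = species or f"{genus} sp."
    tax = (
        f"d__Bacteria;p__{phylum};c__{phylum}ia;o__{phylum}ales;"
        f"f__{phylum}aceae;g__{genus};s__{species}"
    )
    return GenomeRecord(genome_id=genome_id, taxonomy=tax,
                        completeness=completeness, contamination=contamination)


def genes_for(genome_id: str, registry, pathway: str, symbols=None):
    """GeneRecords carrying the named registry key genes (all when symbols is
    None), with KO set from the registry."""
    pw = registry.pathways[pathway]
    chosen = [
        kg for kg in list(pw.key_genes) + list(pw.companion_genes)
        if symbols is None or kg.symbol in symbols
    ]
    return [
        GeneRecord(
            gene_id=f"{genome_id}_{kg.symbol.replace('/', '_')}",
            genome_id=genome_id, length=900, ko=kg.ko, ec=kg.ec, symbol=kg.symbol,
        )
        for kg in chosen
    ]
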