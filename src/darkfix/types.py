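"""Core domain types shared across the pipeline stages.

The pipeline's unit of pathway calling is a :class:`GenomeRecord` (a MAG with
taxonomy and CheckM-style QC metrics) together with its gene complement
(:class:`GeneRecord`).  Quantification operates on a non-redundant catalog of
representative genes (:class:`GeneCluster`) and produces
:class:`AbundanceMatrix` objects whose ``stage`` tracks the normalization
applied so far: raw mapped-read counts, gene-length-normalized gene copies,
KO-summarized copies, and finally per-cell copies after division by the median
single-copy marker-gene abundance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .errors import ValidationError

TAXONOMIC_RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

#: Stages an abundance matrix moves through, in pipeline order.
STAGES = ("raw_counts", "gene_copies", "ko_copies", "per_cell_copies")


@dataclass(frozen=True)
class GenomeRecord:
    """A metagenome-assembled genome (MAG) with taxonomy and QC metrics."""

    genome_id: str
    taxonomy: str  # 7-rank, semicolon-separated
    completeness: float  # percent, 0-100
    contamination: float  # percent, >= 0
    sample_of_origin: str = ""

    def rank(self, rank: str) -> str:
        """Return the named taxonomic rank (empty string if unpopulated)."""
        idx = TAXONOMIC_RANKS.index(rank)
        parts = [p.strip() for p in self.taxonomy.split(";")]
        if idx >= len(parts):
            return ""
        # strip GTDB-style prefixes like "p__"
        part = parts[idx]
        if len(part) >= 3 and part[1:3] == "__":
            part = part[3:]
        return part


@dataclass(frozen=True)
class GeneRecord:
    """A predicted gene belonging to one genome.

    ``sequence`` is optional: quantification and pathway calling work from
    tables alone; clustering requires sequences.
    """

    gene_id: str
    genome_id: str
    length: int  # bp
    sequence: Optional[str] = None
    ko: Optional[str] = None
    ec: tuple = ()
    symbol: Optional[str] = None

    def __post_init__(self):
        if self.length < 1:
            raise ValidationError(f"gene {self.gene_id}: length must be >= 1")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValidationError(
                f"gene {self.gene_id}: sequence length {len(self.sequence)} "
                f"!= declared length {self.length}"
            )


@dataclass
class GeneCluster:
    """A 95%-identity cluster; the representative is the longest member."""

    representative_gene_id: str
    member_gene_ids: list
    ko: Optional[str] = None


@dataclass(frozen=True)
class AnnotationHit:
    """A filtered-alignment annotation hit of a gene against a KO reference."""

    gene_id: str
    ko: str
    query_coverage: float  # fraction 0-1
    subject_coverage: float  # fraction 0-1
    bitscore: float
    self_bitscore: float  # reference aligned against itself


@dataclass(frozen=True)
class ReadAlignment:
    """One read-to-catalog alignment from the mapping stage."""

    read_id: str
    gene_id: str
    aligned_length: int  # bp
    identity: float  # fraction 0-1
    read_coverage: float  # fraction of the read aligned, 0-1
    sample_id: str
    assay: str = "metaG"  # metaG | metaT


@dataclass
class AbundanceMatrix:
    """A sample x feature abundance table with its normalization stage.

    ``values`` is a DataFrame indexed by sample id with feature (gene or KO)
    columns.  ``marker_kos`` is populated at the per-cell stage and records
    which single-copy marker KOs defined the per-sample denominator;
    ``excluded_samples`` lists samples dropped because their marker median was
    zero (flagged, never silently zeroed).
    """

    values: pd.DataFrame
    stage: str
    feature_kind: str  # gene | KO
    assay: str  # metaG | metaT
    marker_kos: list = field(default_factory=list)
    excluded_samples: list = field(default_factory=list)

    def __post_init__(self):
        if self.stage not in STAGES:
            raise ValidationError(f"unknown stage {self.stage!r}")
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("abundance values must be non-negative")

    @property
    def samples(self):
        return list(self.values.index)

    @property
    def features(self):
        return list(self.values.columns)


@dataclass(frozen=True)
class SampleMetadata:
    """Environmental covariates for one sample of the crossed spatial design."""

    sample_id: str
    site: str  # marine | brackish | fresh
    zone: str  # pioneer | low | high
    depth_layer: str  # surface | deep
    chloride: float
    nitrate: float
    sulfate: float
    acetate: float
    pyruvate: float
    isocitrate: float
    organic_matter: float  # percent
    reduction_index: float  # 0-1

    def __post_init__(self):
        if not (0.0 <= self.reduction_index <= 1.0):
            raise ValidationError(
                f"sample {self.sample_id}: reduction_index outside [0, 1]"
            )
        if not (0.0 <= self.organic_matter <= 100.0):
            raise ValidationError(
                f"sample {self.sample_id}: organic_matter outside [0, 100]"
            )
        for name in ("chloride", "nitrate", "sulfate", "acetate", "pyruvate", "isocitrate"):
            if getattr(self, name) < 0:
                raise ValidationError(f"sample {self.sample_id}: {name} negative")


#: Ordinal encodings of the three spatial gradients.  Distance to sea counts
#: seaward -> landward (marine=1 ... fresh=3) so that the observed negative
#: chloride/sulfate correlations carry the conventional sign; soil depth is
#: surface=0, deep=1.
SITE_ORDINAL = {"marine": 1, "brackish": 2, "fresh": 3}
ZONE_ORDINAL = {"pioneer": 1, "low": 2, "high": 3}
DEPTH_ORDINAL = {"surface": 0, "deep": 1}

#: Covariate column order used in all correlation tables and reports.
COVARIATE_ORDER = (
    "chloride",
    "organic_matter",
    "acetate",
    "pyruvate",
    "isocitrate",
    "nitrate",
    "sulfate",
    "reduction_index",
)


def metadata_frame(samples) -> pd.DataFrame:
    """Tabulate SampleMetadata records, adding the three gradient ordinals."""
    rows = []
    for s in samples:
        rows.append(
            {
                "sample_id": s.sample_id,
                "site": s.site,
                "zone": s.zone,
                "depth_layer": s.depth_layer,
                "distance_to_sea": SITE_ORDINAL[s.site],
                "surface_elevation": ZONE_ORDINAL[s.zone],
                "soil_depth": DEPTH_ORDINAL[s.depth_layer],
                **{c: getattr(s, c) for c in COVARIATE_ORDER},
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")
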