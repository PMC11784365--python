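"""Readers and writers for the pipeline's tabular artifacts.

Everything on disk is plain TSV with a header row (FASTA for sequences,
JSON for the ground truth and report).  Columns follow the domain types in
:mod:`darkfix.types`.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .errors import ValidationError
from .types import (
    AbundanceMatrix,
    AnnotationHit,
    GeneCluster,
    GeneRecord,
    GenomeRecord,
    ReadAlignment,
    SampleMetadata,
    metadata_frame,
)

logger = logging.getLogger(__name__)


# -- genomes -----------------------------------------------------------------

def write_genomes(genomes, path):
    pd.DataFrame(
        [
            {
                "genome_id": g.genome_id,
                "taxonomy": g.taxonomy,
                "completeness": g.completeness,
                "contamination": g.contamination,
                "sample_of_origin": g.sample_of_origin,
            }
            for g in genomes
        ]
    ).to_csv(path, sep="\t", index=False)


def read_genomes(path) -> list:
    df = pd.read_csv(path, sep="\t", dtype={"genome_id": str})
    return [
        GenomeRecord(
            genome_id=r.genome_id,
            taxonomy=r.taxonomy,
            completeness=float(r.completeness),
            contamination=float(r.contamination),
            sample_of_origin=getattr(r, "sample_of_origin", "") or "",
        )
        for r in df.itertuples()
    ]


# -- genes -------------------------------------------------------------------

def write_genes(genes, path, fasta_path=None):
    pd.DataFrame(
        [
            {
                "gene_id": g.gene_id,
                "genome_id": g.genome_id,
                "length": g.length,
                "ko": g.ko or "",
                "ec": ",".join(g.ec),
                "symbol": g.symbol or "",
            }
            for g in genes
        ]
    ).to_csv(path, sep="\t", index=False)
    if fasta_path is not None:
        with open(fasta_path, "w") as fh:
            for g in genes:
                if g.sequence is not None:
                    fh.write(f">{g.gene_id}\n{g.sequence}\n")


def read_genes(path, fasta_path=None) -> list:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    seqs = {}
    if fasta_path is not None and Path(fasta_path).exists():
        from Bio import SeqIO

        seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    out = []
    for r in df.itertuples():
        out.append(
            GeneRecord(
                gene_id=r.gene_id,
                genome_id=r.genome_id,
                length=int(r.length),
                sequence=seqs.get(r.gene_id),
                ko=r.ko or None,
                ec=tuple(x for x in r.ec.split(",") if x),
                symbol=getattr(r, "symbol", "") or None,
            )
        )
    return out


# -- annotations -------------------------------------------------------------

def write_annotations(hits, path):
    pd.DataFrame(
        [
            {
                "gene_id": h.gene_id,
                "ko": h.ko,
                "query_coverage": h.query_coverage,
                "subject_coverage": h.subject_coverage,
                "bitscore": h.bitscore,
                "self_bitscore": h.self_bitscore,
            }
            for h in hits
        ]
    ).to_csv(path, sep="\t", index=False)


def read_annotations(path) -> list:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "ko": str})
    return [
        AnnotationHit(
            gene_id=r.gene_id,
            ko=r.ko,
            query_coverage=float(r.query_coverage),
            subject_coverage=float(r.subject_coverage),
            bitscore=float(r.bitscore),
            self_bitscore=float(r.self_bitscore),
        )
        for r in df.itertuples()
    ]


# -- alignments --------------------------------------------------------------

ALIGNMENT_COLUMNS = [
    "read_id", "gene_id", "aligned_length", "identity", "read_coverage",
    "sample_id", "assay",
]


def write_alignments(alignments, path):
    pd.DataFrame(
        [{c: getattr(a, c) for c in ALIGNMENT_COLUMNS} for a in alignments]
    ).to_csv(path, sep="\t", index=False)


def read_alignments(path) -> list:
    df = pd.read_csv(path, sep="\t", dtype={"read_id": str, "gene_id": str, "sample_id": str})
    return [
        ReadAlignment(
            read_id=r.read_id,
            gene_id=r.gene_id,
            aligned_length=int(r.aligned_length),
            identity=float(r.identity),
            read_coverage=float(r.read_coverage),
            sample_id=r.sample_id,
            assay=r.assay,
        )
        for r in df.itertuples()
    ]


def sam_to_alignments(path, sample_id: str, assay: str = "metaG") -> list:
    """Best-effort converter from a text SAM file to alignment records.

    Identity is derived from the NM tag over the aligned length; read
    coverage from the CIGAR's aligned fraction.  Intended for quick imports,
    not validated against every mapper's conventions.
    """
    import re

    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("@"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 11:
                continue
            qname, flag, rname, cigar = fields[0], int(fields[1]), fields[2], fields[5]
            if rname == "*" or flag & 4:
                continue
            ops = re.findall(r"(\d+)([MIDNSHP=X])", cigar)
            aligned = sum(int(n) for n, op in ops if op in "M=X")
            read_len = sum(int(n) for n, op in ops if op in "MIS=X") or 1
            nm = 0
            for tag in fields[11:]:
                if tag.startswith("NM:i:"):
                    nm = int(tag[5:])
            span = sum(int(n) for n, op in ops if op in "MID=X") or 1
            out.append(
                ReadAlignment(
                    read_id=qname,
                    gene_id=rname,
                    aligned_length=aligned,
                    identity=max(0.0, 1.0 - nm / span),
                    read_coverage=aligned / read_len,
                    sample_id=sample_id,
                    assay=assay,
                )
            )
    return out


# -- counts / abundance matrices ---------------------------------------------

def write_counts(matrix: AbundanceMatrix, path):
    """Features as rows (feature-id column + one column per sample)."""
    out = matrix.values.T
    out.index.name = "gene_id" if matrix.feature_kind == "gene" else "ko"
    out.to_csv(path, sep="\t")


def read_counts(path, assay: str, stage: str = "raw_counts",
                feature_kind: str = "gene") -> AbundanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    mat = df.T.astype(float)
    mat.index.name = "sample_id"
    return AbundanceMatrix(values=mat, stage=stage, feature_kind=feature_kind, assay=assay)


# -- metadata ----------------------------------------------------------------

METADATA_COLUMNS = [
    "sample_id", "site", "zone", "depth_layer", "chloride", "nitrate",
    "sulfate", "acetate", "pyruvate", "isocitrate", "organic_matter",
    "reduction_index",
]


def write_metadata(samples, path):
    pd.DataFrame(
        [{c: getattr(s, c) for c in METADATA_COLUMNS} for s in samples]
    ).to_csv(path, sep="\t", index=False)


def read_metadata(path) -> list:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"metadata file missing columns: {missing}")
    return [
        SampleMetadata(**{c: getattr(r, c) for c in METADATA_COLUMNS})
        for r in df.itertuples()
    ]


# -- catalog -----------------------------------------------------------------

def write_catalog(clusters, path):
    pd.DataFrame(
        [
            {
                "cluster_id": f"C{i + 1:05d}",
                "representative": cl.representative_gene_id,
                "members": ",".join(cl.member_gene_ids),
                "ko": cl.ko or "",
            }
            for i, cl in enumerate(clusters)
        ]
    ).to_csv(path, sep="\t", index=False)


def read_catalog(path) -> list:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return [
        GeneCluster(
            representative_gene_id=r.representative,
            member_gene_ids=r.members.split(","),
            ko=r.ko or None,
        )
        for r in df.itertuples()
    ]


# -- pathway calls -----------------------------------------------------------

def write_calls(calls, path):
    pd.DataFrame(
        [
            {
                "genome_id": c.genome_id,
                "pathway": c.pathway,
                "status": c.status,
                "evidence": ",".join(c.evidence),
                "missing": ",".join(c.missing),
                "conflict_note": c.conflict_note or "",
                "lineage_support": (
                    "{}:{}:{}".format(*c.lineage_support) if c.lineage_support else ""
                ),
            }
            for c in calls
        ]
    ).to_csv(path, sep="\t", index=False)


def write_metadata_frame(samples, path):
    metadata_frame(samples).to_csv(path, sep="\t")
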