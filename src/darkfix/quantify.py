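"""Read-alignment filtering and per-cell copy-number normalization.

The quantification chain turns mapped reads into "mean copies per cell":

1. alignment filter — keep alignments of >= 45 bp, >= 97% identity, covering
   >= 80% of the read; credit each read to at most one gene (best hit);
2. gene-length normalization — reads / gene length in kb ("gene copies");
3. KO summarization — sum gene copies over genes sharing a KEGG ortholog;
4. per-cell normalization — divide each sample by the median copy number of a
   set of universal single-copy marker KOs, so a KO present once per genome in
   every cell reads ~1.0.

Normalizing to single-copy markers rather than library size makes the result
robust to eukaryotic/viral read fractions and comparable between samples; the
same machinery applies to metagenomes (gene copies per cell) and
metatranscriptomes (transcript copies per cell, which may exceed 1).
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import RecordError, ValidationError
from .types import AbundanceMatrix, ReadAlignment

logger = logging.getLogger(__name__)

MIN_ALIGNED_LENGTH = 45  # bp, inclusive
MIN_IDENTITY = 0.97  # inclusive
MIN_READ_COVERAGE = 0.80  # inclusive


def filter_alignments(
    alignments: Iterable[ReadAlignment],
    min_length: int = MIN_ALIGNED_LENGTH,
    min_identity: float = MIN_IDENTITY,
    min_read_coverage: float = MIN_READ_COVERAGE,
    multimap: str = "best",
) -> list:
    """Apply the mapping-quality filter and resolve multi-mapped reads.

    All three thresholds are inclusive.  With ``multimap="best"`` each
    (sample, assay, read) keeps its single best alignment: highest identity,
    then longest aligned length, then lexicographically smallest gene id.
    ``multimap="all"`` keeps every passing alignment (for fractional counting
    schemes downstream).
    """
    if multimap not in ("best", "all"):
        raise ValidationError(f"unknown multimap policy {multimap!r}")
    passing = [
        a
        for a in alignments
        if a.aligned_length >= min_length
        and a.identity >= min_identity
        and a.read_coverage >= min_read_coverage
    ]
    if multimap == "all":
        return passing
    best: dict = {}
    for a in passing:
        key = (a.sample_id, a.assay, a.read_id)
        cur = best.get(key)
        if cur is None or (-a.identity, -a.aligned_length, a.gene_id) < (
            -cur.identity,
            -cur.aligned_length,
            cur.gene_id,
        ):
            best[key] = a
    return [best[k] for k in sorted(best)]


def count_alignments(alignments: Iterable[ReadAlignment], assay: str = "metaG") -> AbundanceMatrix:
    """Count distinct read ids per (sample, gene) into a raw-count matrix."""
    rows = [
        (a.sample_id, a.gene_id, a.read_id)
        for a in alignments
        if a.assay == assay
    ]
    if not rows:
        return AbundanceMatrix(
            values=pd.DataFrame(dtype=float), stage="raw_counts",
            feature_kind="gene", assay=assay,
        )
    df = pd.DataFrame(rows, columns=["sample_id", "gene_id", "read_id"])
    counts = (
        df.groupby(["sample_id", "gene_id"])["read_id"]
        .nunique()
        .unstack(fill_value=0)
        .astype(float)
    )
    counts = counts.sort_index().sort_index(axis=1)
    return AbundanceMatrix(values=counts, stage="raw_counts", feature_kind="gene", assay=assay)


def collapse_to_catalog(counts: AbundanceMatrix, gene_to_rep: Mapping[str, str]) -> AbundanceMatrix:
    """Sum raw gene counts over cluster members onto catalog representatives.

    Genes absent from the catalog map (e.g. from QC-failing MAGs) are dropped
    with a log entry.
    """
    if counts.stage != "raw_counts":
        raise ValidationError("collapse_to_catalog expects raw counts")
    known = [g for g in counts.values.columns if g in gene_to_rep]
    dropped = len(counts.values.columns) - len(known)
    if dropped:
        logger.info("collapse_to_catalog: dropped %d uncataloged genes", dropped)
    collapsed = (
        counts.values[known]
        .T.groupby(lambda g: gene_to_rep[g])
        .sum()
        .T.sort_index(axis=1)
    )
    return AbundanceMatrix(
        values=collapsed, stage="raw_counts", feature_kind="gene", assay=counts.assay
    )


def length_normalize(counts: AbundanceMatrix, gene_lengths: Mapping[str, int]) -> AbundanceMatrix:
    """Divide raw counts by gene length in kb, giving gene copies."""
    if counts.stage != "raw_counts":
        raise ValidationError("length_normalize expects raw counts")
    missing = [g for g in counts.values.columns if g not in gene_lengths]
    if missing:
        raise RecordError(
            f"no length for counted genes: {', '.join(map(str, missing))}", ids=missing
        )
    kb = pd.Series({g: gene_lengths[g] / 1000.0 for g in counts.values.columns})
    vals = counts.values.div(kb, axis=1)
    return AbundanceMatrix(values=vals, stage="gene_copies", feature_kind="gene", assay=counts.assay)


def summarize_ko(gene_copies: AbundanceMatrix, rep_to_ko: Mapping[str, str]) -> AbundanceMatrix:
    """Sum gene copies into KEGG ortholog groups; unannotated genes dropped."""
    if gene_copies.stage != "gene_copies":
        raise ValidationError("summarize_ko expects gene copies")
    annotated = [g for g in gene_copies.values.columns if rep_to_ko.get(g)]
    n_drop = len(gene_copies.values.columns) - len(annotated)
    if n_drop:
        logger.info("summarize_ko: %d genes without KO dropped", n_drop)
    ko_vals = (
        gene_copies.values[annotated]
        .T.groupby(lambda g: rep_to_ko[g])
        .sum()
        .T.sort_index(axis=1)
    )
    return AbundanceMatrix(values=ko_vals, stage="ko_copies", feature_kind="KO", assay=gene_copies.assay)


def per_cell_normalize(ko_copies: AbundanceMatrix, marker_kos) -> AbundanceMatrix:
    """Normalize each sample by the median copy number of single-copy markers.

    The denominator d(s) is the median over the requested marker KOs of their
    KO copies in sample s; markers absent from the matrix enter the median as
    0 (an even marker count uses the mean of the two central values).  Samples
    with d(s) = 0 are excluded and listed in ``excluded_samples``; if every
    sample has d(s) = 0 a hard error is raised.
    """
    if ko_copies.stage != "ko_copies":
        raise ValidationError("per_cell_normalize expects KO copies")
    marker_kos = list(marker_kos)
    if len(marker_kos) < 3:
        raise ValidationError("need at least 3 marker KOs for a stable median")
    marker_tab = pd.DataFrame(
        {m: ko_copies.values.get(m, pd.Series(0.0, index=ko_copies.values.index)) for m in marker_kos}
    )
    d = marker_tab.median(axis=1)
    retained = d[d > 0].index
    excluded = [s for s in ko_copies.values.index if s not in set(retained)]
    if len(retained) == 0:
        raise ValidationError("marker median is zero in every sample; cannot normalize")
    if excluded:
        logger.warning("per_cell_normalize: excluded samples with zero marker median: %s", excluded)
    vals = ko_copies.values.loc[retained].div(d.loc[retained], axis=0)
    # With an even marker count the median is the mean of two central values,
    # which is not exactly division-invariant in floating point; a couple of
    # refinement passes pin the normalized marker median to 1.0 bit-exactly.
    marker_cols = pd.DataFrame(
        {m: vals.get(m, pd.Series(0.0, index=vals.index)) for m in marker_kos}
    )
    for _ in range(5):
        resid = marker_cols.median(axis=1)
        if (resid == 1.0).all():
            break
        vals = vals.div(resid, axis=0)
        marker_cols = marker_cols.div(resid, axis=0)
    return AbundanceMatrix(
        values=vals,
        stage="per_cell_copies",
        feature_kind="KO",
        assay=ko_copies.assay,
        marker_kos=marker_kos,
        excluded_samples=excluded,
    )


def quantify_counts(
    raw: AbundanceMatrix,
    gene_lengths: Mapping[str, int],
    rep_to_ko: Mapping[str, str],
    marker_kos,
    gene_to_rep: Mapping[str, str] | None = None,
) -> AbundanceMatrix:
    """Run the full chain raw counts -> per-cell KO copies."""
    if gene_to_rep is not None:
        raw = collapse_to_catalog(raw, gene_to_rep)
    copies = length_normalize(raw, gene_lengths)
    kos = summarize_ko(copies, rep_to_ko)
    return per_cell_normalize(kos, marker_kos)


def counts_from_frame(df: pd.DataFrame, assay: str) -> AbundanceMatrix:
    """Wrap a pre-counted genes x samples table (gene_id column + sample columns)."""
    mat = df.set_index("gene_id").T.astype(float)
    mat.index.name = "sample_id"
    return AbundanceMatrix(values=mat, stage="raw_counts", feature_kind="gene", assay=assay)
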