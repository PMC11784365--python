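"""Non-redundant gene catalog construction.

Three filters and one clustering step reduce the per-genome gene predictions
to a dereplicated, annotated catalog of representative genes:

* MAG quality control keeps genomes with completeness >= 50% and
  contamination < 10% (strict).
* Greedy incremental clustering at 95% nucleotide identity over >= 90% of the
  shorter sequence, longest sequence as representative.
* Annotation hits are kept when query AND subject coverage are >= 70% and the
  bitscore reaches >= 50% of the reference's self-alignment bitscore; one best
  KO is retained per gene.

Pairwise identity is computed over the best local alignment of the pair
(match +1, mismatch -1, gap -2 by default) with identity defined as
matches / alignment columns; the scoring is configurable via
:class:`AlignmentParams`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

from Bio import Align

from .errors import RecordError, ValidationError
from .types import AnnotationHit, GeneCluster, GeneRecord, GenomeRecord

logger = logging.getLogger(__name__)

MIN_COMPLETENESS = 50.0  # percent, inclusive
MAX_CONTAMINATION = 10.0  # percent, exclusive


def filter_mags(genomes: Iterable[GenomeRecord]) -> list:
    """Keep genomes with completeness >= 50 and contamination < 10, in order.

    Raises :class:`RecordError` naming the genome if either QC metric is
    missing (None/NaN).
    """
    kept = []
    bad = []
    for g in genomes:
        comp, cont = g.completeness, g.contamination
        if comp is None or cont is None or comp != comp or cont != cont:
            bad.append(g.genome_id)
            continue
        if comp >= MIN_COMPLETENESS and cont < MAX_CONTAMINATION:
            kept.append(g)
    if bad:
        raise RecordError(
            f"missing completeness/contamination for genomes: {', '.join(bad)}", ids=bad
        )
    return kept


@dataclass(frozen=True)
class AlignmentParams:
    """Local-alignment scoring used for pairwise identity."""

    match: float = 1.0
    mismatch: float = -1.0
    gap: float = -2.0


def _aligner(params: AlignmentParams) -> Align.PairwiseAligner:
    aln = Align.PairwiseAligner()
    aln.mode = "local"
    aln.match_score = params.match
    aln.mismatch_score = params.mismatch
    aln.open_gap_score = params.gap
    aln.extend_gap_score = params.gap
    return aln


def pairwise_identity(
    seq_a: str, seq_b: str, params: AlignmentParams = AlignmentParams()
):
    """Best-local-alignment identity and coverage of the shorter sequence.

    Returns ``(identity, coverage_short)`` where identity is
    matches / alignment columns (gap columns count) and coverage_short is the
    aligned span on the shorter sequence divided by its length.
    """
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    aln = _aligner(params)
    alignments = aln.align(seq_a, seq_b)
    if len(seq_a) == 0 or len(seq_b) == 0 or alignments.score <= 0:
        return 0.0, 0.0
    best = alignments[0]
    a_aln, b_aln = str(best[0]), str(best[1])
    columns = len(a_aln)
    matches = sum(1 for x, y in zip(a_aln, b_aln) if x == y and x != "-")
    identity = matches / columns if columns else 0.0
    # aligned span on each input sequence
    spans = []
    for row in (0, 1):
        start, end = best.aligned[row][0][0], best.aligned[row][-1][1]
        spans.append(end - start)
    short_len = min(len(seq_a), len(seq_b))
    span_short = spans[0] if len(seq_a) <= len(seq_b) else spans[1]
    return identity, span_short / short_len


def cluster_genes(
    genes: Iterable[GeneRecord],
    identity_threshold: float = 0.95,
    coverage_short: float = 0.9,
    params: AlignmentParams = AlignmentParams(),
) -> list:
    """Greedy incremental clustering, longest sequence as representative.

    Genes are sorted by length descending (ties broken by gene_id); each gene
    joins the first existing cluster whose representative it matches at
    >= ``identity_threshold`` over >= ``coverage_short`` of the shorter
    sequence, else it founds a new cluster.  The founding (longest) member is
    the representative.  Every input gene lands in exactly one cluster.
    """
    genes = list(genes)
    if not genes:
        return []
    missing = [g.gene_id for g in genes if g.sequence is None]
    if missing:
        raise RecordError(
            f"genes without sequence cannot be clustered: {', '.join(missing)}",
            ids=missing,
        )
    order = sorted(genes, key=lambda g: (-g.length, g.gene_id))
    clusters: list = []
    reps: list = []  # parallel list of representative GeneRecords
    for gene in order:
        placed = False
        for cl, rep in zip(clusters, reps):
            ident, cov = pairwise_identity(rep.sequence, gene.sequence, params)
            if ident >= identity_threshold and cov >= coverage_short:
                cl.member_gene_ids.append(gene.gene_id)
                placed = True
                break
        if not placed:
            clusters.append(
                GeneCluster(representative_gene_id=gene.gene_id, member_gene_ids=[gene.gene_id])
            )
            reps.append(gene)
    return clusters


def filter_annotations(
    hits: Iterable[AnnotationHit],
    min_cov: float = 0.7,
    min_bitscore_frac: float = 0.5,
) -> list:
    """Coverage/bitscore filter plus best-KO-per-gene selection.

    Keeps hits with query_coverage >= min_cov AND subject_coverage >= min_cov
    AND bitscore >= min_bitscore_frac * self_bitscore, then retains one best
    KO per gene (highest bitscore, ties broken by lexicographically smallest
    KO id).  Order-independent and idempotent.
    """
    best: dict = {}
    for h in hits:
        if h.self_bitscore <= 0:
            raise ValidationError(
                f"hit {h.gene_id}->{h.ko}: self_bitscore must be positive"
            )
        if h.query_coverage < min_cov or h.subject_coverage < min_cov:
            continue
        if h.bitscore < min_bitscore_frac * h.self_bitscore:
            continue
        cur = best.get(h.gene_id)
        if cur is None or (-h.bitscore, h.ko) < (-cur.bitscore, cur.ko):
            best[h.gene_id] = h
    return [best[g] for g in sorted(best)]


def build_catalog(
    genomes: Iterable[GenomeRecord],
    genes: Iterable[GeneRecord],
    hits: Iterable[AnnotationHit],
    identity_threshold: float = 0.95,
    coverage_short: float = 0.9,
    min_cov: float = 0.7,
    min_bitscore_frac: float = 0.5,
) -> list:
    """Full catalog stage: MAG QC -> clustering -> KO annotation.

    Genes of QC-failing MAGs are excluded before clustering.  When sequences
    are absent (table-only pipelines) every gene forms its own singleton
    cluster; with sequences present, greedy 95%-identity clustering applies.
    The cluster KO is the filtered best KO of its representative gene.
    """
    genes = list(genes)
    kept_genomes = {g.genome_id for g in filter_mags(genomes)}
    pool = [g for g in genes if g.genome_id in kept_genomes]
    n_dropped = len(genes) - len(pool)
    if n_dropped:
        logger.info("catalog: dropped %d genes from QC-failing MAGs", n_dropped)
    if pool and all(g.sequence is not None for g in pool):
        clusters = cluster_genes(pool, identity_threshold, coverage_short)
    else:
        clusters = [
            GeneCluster(representative_gene_id=g.gene_id, member_gene_ids=[g.gene_id])
            for g in sorted(pool, key=lambda g: (-g.length, g.gene_id))
        ]
    ko_of = {h.gene_id: h.ko for h in filter_annotations(hits, min_cov, min_bitscore_frac)}
    for cl in clusters:
        cl.ko = ko_of.get(cl.representative_gene_id)
    return clusters


def catalog_gene_to_rep(clusters: Iterable[GeneCluster]) -> dict:
    """Map every member gene id to its cluster representative id."""
    out = {}
    for cl in clusters:
        for m in cl.member_gene_ids:
            out[m] = cl.representative_gene_id
    return out


def catalog_rep_to_ko(clusters: Iterable[GeneCluster]) -> dict:
    """Map representative gene id to its KO (annotated clusters only)."""
    return {
        cl.representative_gene_id: cl.ko
        for cl in clusters
        if cl.ko is not None
    }
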