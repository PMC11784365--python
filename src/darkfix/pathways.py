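"""Pathway registry and genome-guided completeness calling.

Seven autotrophic CO2-fixation pathways are recognised: the reductive TCA
cycle (rTCA), the Wood-Ljungdahl pathway (WLP), the Calvin cycle, the
dicarboxylate/4-hydroxybutyrate cycle (DC/4-HB), the 3-hydroxypropionate
bicycle, the 3-hydroxypropionate/4-hydroxybutyrate cycle (3-HP/4-HB) and the
reductive glycine pathway (rGlyP).  Several diagnostic enzymes are shared
between pathways (e.g. 4-hydroxybutyryl-CoA dehydratase between DC/4-HB and
3-HP/4-HB), so the caller demands *exclusive* evidence before declaring a
pathway complete in a genome, and shared-gene conflicts are arbitrated by
comparing pathway completeness among close relatives (same genus, falling
back to species).  This deliberately avoids percent-completeness scoring of
the KEGG-module/MetaCyc kind, which overestimates pathways whose genes
overlap other metabolism.

Calling rule per genome and pathway:

* ``absent`` — no key gene of the pathway present;
* ``complete`` — every key gene and every configured companion gene present,
  and at least one present key gene exclusive to the pathway;
* ``key_gene_only`` — anything in between.

A dataset-level absence verdict additionally requires zero abundance of every
registry KO of the pathway across all samples of both assays.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Optional

import pandas as pd
import yaml

from .errors import ValidationError
from .types import AbundanceMatrix, GeneRecord, GenomeRecord

logger = logging.getLogger(__name__)

PATHWAYS = ("rTCA", "WLP", "Calvin", "DC/4-HB", "3-HP bicycle", "3-HP/4-HB", "rGlyP")

#: The four starred key genes used for abundance and correlation analysis.
ABUNDANCE_MARKER_SYMBOLS = ("aclA", "acsC/cdhE", "rbcL", "grdB")


@dataclass(frozen=True)
class KeyGene:
    symbol: str
    enzyme: str
    ec: tuple
    ko: str
    shared_with: tuple = ()
    abundance_marker: bool = False
    accepted_symbols: tuple = ()

    @property
    def exclusive(self) -> bool:
        return not self.shared_with

    def matches(self, gene: GeneRecord) -> bool:
        """KO first, EC fallback, accepted symbols last."""
        if gene.ko:
            return gene.ko == self.ko
        if gene.ec:
            return bool(set(gene.ec) & set(self.ec))
        if gene.symbol:
            return gene.symbol == self.symbol or gene.symbol in self.accepted_symbols
        return False


@dataclass(frozen=True)
class Pathway:
    name: str
    full_name: str
    key_genes: tuple
    companion_genes: tuple = ()

    @property
    def abundance_marker(self) -> Optional[KeyGene]:
        for g in self.key_genes:
            if g.abundance_marker:
                return g
        return None

    @property
    def kos(self) -> tuple:
        return tuple(g.ko for g in self.key_genes)


@dataclass
class PathwayRegistry:
    pathways: dict  # name -> Pathway
    accessory_genes: dict = field(default_factory=dict)  # symbol -> {ko, ec, enzyme}

    def __post_init__(self):
        self.validate()

    def validate(self):
        for name, pw in self.pathways.items():
            marker = pw.abundance_marker
            if marker is not None and marker.symbol not in ABUNDANCE_MARKER_SYMBOLS:
                raise ValidationError(
                    f"{name}: abundance marker {marker.symbol} is not one of "
                    f"{ABUNDANCE_MARKER_SYMBOLS}"
                )
            for g in pw.key_genes:
                for other in g.shared_with:
                    if other not in self.pathways:
                        raise ValidationError(
                            f"{name}/{g.symbol}: shared_with references unknown pathway {other!r}"
                        )
                    # symmetry: when the partner pathway also lists this gene
                    # (same KO), it must point back here
                    partner = self.pathways[other]
                    listed = [kg for kg in partner.key_genes if kg.ko == g.ko]
                    for kg in listed:
                        if name not in kg.shared_with:
                            raise ValidationError(
                                f"shared_with not symmetric for {g.symbol} "
                                f"between {name} and {other}"
                            )

    @classmethod
    def from_dict(cls, data: Mapping) -> "PathwayRegistry":
        pathways = {}
        for name, pw in data["pathways"].items():
            keys = tuple(
                KeyGene(
                    symbol=g["symbol"],
                    enzyme=g.get("enzyme", ""),
                    ec=tuple(g.get("ec", [])),
                    ko=g["ko"],
                    shared_with=tuple(g.get("shared_with", [])),
                    abundance_marker=bool(g.get("abundance_marker", False)),
                    accepted_symbols=tuple(g.get("accepted_symbols", [])),
                )
                for g in pw["key_genes"]
            )
            companions = tuple(
                KeyGene(
                    symbol=g["symbol"],
                    enzyme=g.get("enzyme", ""),
                    ec=tuple(g.get("ec", [])),
                    ko=g["ko"],
                    shared_with=tuple(g.get("shared_with", [])),
                    accepted_symbols=tuple(g.get("accepted_symbols", [])),
                )
                for g in pw.get("companion_genes", [])
            )
            pathways[name] = Pathway(
                name=name,
                full_name=pw.get("full_name", name),
                key_genes=keys,
                companion_genes=companions,
            )
        return cls(pathways=pathways, accessory_genes=dict(data.get("accessory_genes", {})))

    def to_dict(self) -> dict:
        out = {"pathways": {}, "accessory_genes": dict(self.accessory_genes)}
        for name, pw in self.pathways.items():
            def gene_dict(g: KeyGene, marker_field: bool) -> dict:
                d = {
                    "symbol": g.symbol,
                    "enzyme": g.enzyme,
                    "ec": list(g.ec),
                    "ko": g.ko,
                    "shared_with": list(g.shared_with),
                }
                if g.accepted_symbols:
                    d["accepted_symbols"] = list(g.accepted_symbols)
                if marker_field and g.abundance_marker:
                    d["abundance_marker"] = True
                return d

            out["pathways"][name] = {
                "full_name": pw.full_name,
                "key_genes": [gene_dict(g, True) for g in pw.key_genes],
                "companion_genes": [gene_dict(g, False) for g in pw.companion_genes],
            }
        return out

    @classmethod
    def from_yaml(cls, path) -> "PathwayRegistry":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False, allow_unicode=True)

    @classmethod
    def default(cls) -> "PathwayRegistry":
        """The registry shipped with the package."""
        text = resources.files("darkfix").joinpath("registry.yaml").read_text()
        return cls.from_dict(yaml.safe_load(text))

    def marker_ko(self, pathway: str) -> Optional[str]:
        m = self.pathways[pathway].abundance_marker
        return m.ko if m else None


@dataclass
class PathwayCall:
    """Per-genome verdict for one pathway with its evidence trail."""

    genome_id: str
    pathway: str
    status: str  # complete | key_gene_only | absent
    evidence: list = field(default_factory=list)  # found gene symbols
    missing: list = field(default_factory=list)
    conflict_note: Optional[str] = None
    lineage_support: Optional[tuple] = None  # (rank, n_relatives, n_complete)


@dataclass(frozen=True)
class AutotrophyAnnotation:
    genome_id: str
    has_puf: bool
    has_tsd: bool
    has_soxZ: bool
    label: str  # chemoautotrophic-S-oxidizer | photosynthesis-capable | unclassified


def call_genome(
    genome: GenomeRecord,
    genes: Iterable[GeneRecord],
    registry: PathwayRegistry,
) -> list:
    """Call completeness of all registry pathways for one genome."""
    genes = [g for g in genes if g.genome_id == genome.genome_id]
    calls = []
    for name, pw in registry.pathways.items():
        required = list(pw.key_genes) + list(pw.companion_genes)
        found, missing = [], []
        for kg in required:
            if any(kg.matches(g) for g in genes):
                found.append(kg)
            else:
                missing.append(kg)
        key_found = [kg for kg in found if kg in pw.key_genes]
        if not key_found:
            status = "absent"
        elif not missing and any(kg.exclusive for kg in key_found):
            status = "complete"
        else:
            status = "key_gene_only"
        note = None
        if status == "key_gene_only" and key_found and all(not kg.exclusive for kg in key_found):
            competitors = sorted({p for kg in key_found for p in kg.shared_with})
            note = "shared-evidence conflict with: " + ", ".join(competitors)
        calls.append(
            PathwayCall(
                genome_id=genome.genome_id,
                pathway=name,
                status=status,
                evidence=[kg.symbol for kg in found],
                missing=[kg.symbol for kg in missing],
                conflict_note=note,
            )
        )
    return calls


def call_all_genomes(genomes, genes, registry: PathwayRegistry) -> list:
    genes = list(genes)
    by_genome: dict = {}
    for g in genes:
        by_genome.setdefault(g.genome_id, []).append(g)
    calls = []
    for genome in genomes:
        calls.extend(call_genome(genome, by_genome.get(genome.genome_id, []), registry))
    return calls


def resolve_conflicts(calls: Iterable[PathwayCall], genomes: Iterable[GenomeRecord],
                      registry: PathwayRegistry) -> list:
    """Arbitrate key-gene-only calls using completeness among close relatives.

    For each key_gene_only call, relatives are same-genus genomes (same
    species when the genus rank is unpopulated).  If at least one relative
    holds a complete call for the pathway and none for any competing pathway
    (pathways sharing the evidence genes), the call gains
    ``lineage_support = (rank, n_relatives, n_complete)`` and is annotated as
    lineage-supported.  Ties between pathways, or no informative relatives,
    leave the call unresolved (both candidates noted).  A call is never
    promoted to complete by lineage evidence.
    """
    calls = list(calls)
    genome_by_id = {g.genome_id: g for g in genomes}
    complete = {}  # (genome_id, pathway) -> True
    for c in calls:
        if c.status == "complete":
            complete[(c.genome_id, c.pathway)] = True

    def relatives_of(genome: GenomeRecord):
        genus = genome.rank("genus")
        rank = "genus"
        if not genus:
            genus = genome.rank("species")
            rank = "species"
        rel = [
            g for g in genome_by_id.values()
            if g.genome_id != genome.genome_id and g.rank(rank) == genus and genus
        ]
        return rank, rel

    symbol_to_gene = {
        kg.symbol: kg for pw in registry.pathways.values() for kg in pw.key_genes
    }
    out = []
    for c in calls:
        if c.status != "key_gene_only":
            out.append(c)
            continue
        genome = genome_by_id.get(c.genome_id)
        if genome is None:
            out.append(c)
            continue
        evidence_genes = [symbol_to_gene[s] for s in c.evidence if s in symbol_to_gene]
        competitors = sorted({p for kg in evidence_genes for p in kg.shared_with})
        rank, rel = relatives_of(genome)
        if not rel:
            c.conflict_note = ((c.conflict_note + "; ") if c.conflict_note else "") + "unresolved: no relatives"
            out.append(c)
            continue
        n_self = sum(1 for r in rel if complete.get((r.genome_id, c.pathway)))
        n_comp = {p: sum(1 for r in rel if complete.get((r.genome_id, p))) for p in competitors}
        if n_self >= 1 and all(v == 0 for v in n_comp.values()):
            c.lineage_support = (rank, len(rel), n_self)
            c.conflict_note = (
                f"lineage-supported: {n_self}/{len(rel)} {rank}-level relatives "
                f"complete for {c.pathway}"
            )
        elif n_self >= 1:
            tied = [p for p, v in n_comp.items() if v >= 1]
            c.conflict_note = (
                f"unresolved: lineage support tied between {c.pathway} and "
                + ", ".join(tied)
            )
        elif any(v >= 1 for v in n_comp.values()):
            supported = [p for p, v in n_comp.items() if v >= 1]
            c.conflict_note = (
                "unresolved for this pathway; lineage favours " + ", ".join(supported)
            )
        else:
            c.conflict_note = ((c.conflict_note + "; ") if c.conflict_note else "") + "unresolved: no complete relatives"
        out.append(c)
    return out


def apply_overrides(calls: Iterable[PathwayCall], overrides: Iterable[Mapping],
                    genomes: Iterable[GenomeRecord]) -> list:
    """Apply a curated literature-knowledge override table, last and logged.

    Each override is a mapping with keys ``match`` (a genome id or a taxon
    name occurring in the taxonomy string), ``pathway``, ``status`` and
    optional ``note``.
    """
    calls = list(calls)
    genomes = list(genomes)
    tax_of = {g.genome_id: g.taxonomy for g in genomes}
    for ov in overrides:
        target, pathway, status = ov["match"], ov["pathway"], ov["status"]
        if status not in ("complete", "key_gene_only", "absent"):
            raise ValidationError(f"override status {status!r} unknown")
        for c in calls:
            if c.pathway != pathway:
                continue
            tax = tax_of.get(c.genome_id, "")
            if c.genome_id == target or target in tax:
                logger.info(
                    "override: %s/%s %s -> %s (%s)",
                    c.genome_id, pathway, c.status, status, ov.get("note", "curated"),
                )
                c.status = status
                c.conflict_note = (
                    (c.conflict_note + "; " if c.conflict_note else "")
                    + f"curated override: {ov.get('note', 'literature')}"
                )
    return calls


def declare_dataset_absence(
    calls: Iterable[PathwayCall],
    per_cell_metaG: AbundanceMatrix,
    per_cell_metaT: AbundanceMatrix,
    registry: PathwayRegistry,
) -> pd.DataFrame:
    """Dataset-level verdicts: a pathway is absent from the whole dataset iff
    no genome shows any evidence for it AND every one of its registry KOs has
    zero abundance in every sample of both assays."""
    for mat in (per_cell_metaG, per_cell_metaT):
        if mat.stage != "per_cell_copies":
            raise ValidationError("declare_dataset_absence expects per-cell matrices")
    calls = list(calls)
    rows = []
    for name, pw in registry.pathways.items():
        genomes_with_evidence = sorted(
            {c.genome_id for c in calls if c.pathway == name and c.status != "absent"}
        )
        n_samples_abund = 0
        for mat in (per_cell_metaG, per_cell_metaT):
            present = [k for k in pw.kos if k in mat.values.columns]
            if present:
                n_samples_abund += int((mat.values[present].sum(axis=1) > 0).sum())
        rows.append(
            {
                "pathway": name,
                "dataset_absent": not genomes_with_evidence and n_samples_abund == 0,
                "n_genomes_with_evidence": len(genomes_with_evidence),
                "n_samples_with_abundance": n_samples_abund,
            }
        )
    return pd.DataFrame(rows).set_index("pathway")


def _gene_has(genes, ko: str, symbols) -> bool:
    for g in genes:
        if g.ko == ko:
            return True
        if g.ko is None and g.symbol in symbols:
            return True
    return False


def annotate_autotrophy(
    genomes: Iterable[GenomeRecord],
    genes: Iterable[GeneRecord],
    registry: Optional[PathwayRegistry] = None,
) -> list:
    """Classify RuBisCO-positive genomes as chemoautotrophic sulfur oxidizers
    (tsd or soxZ present, puf operon absent) or photosynthesis-capable (puf
    present); genomes without rbcL stay unclassified."""
    registry = registry or PathwayRegistry.default()
    acc = registry.accessory_genes
    puf_kos = {v["ko"] for k, v in acc.items() if k.startswith("puf")}
    tsd_ko = acc.get("tsd", {}).get("ko", "K19713")
    soxz_ko = acc.get("soxZ", {}).get("ko", "K17227")
    rbcl_ko = None
    for pw in registry.pathways.values():
        for kg in pw.key_genes:
            if kg.symbol == "rbcL":
                rbcl_ko = kg.ko
    by_genome: dict = {}
    for g in genes:
        by_genome.setdefault(g.genome_id, []).append(g)
    out = []
    for genome in genomes:
        gg = by_genome.get(genome.genome_id, [])
        has_rbcl = _gene_has(gg, rbcl_ko, {"rbcL"})
        has_puf = any(_gene_has(gg, ko, {"pufM", "pufL"}) for ko in puf_kos)
        has_tsd = _gene_has(gg, tsd_ko, {"tsd"})
        has_soxz = _gene_has(gg, soxz_ko, {"soxZ"})
        if not has_rbcl:
            label = "unclassified"
        elif has_puf:
            label = "photosynthesis-capable"
        elif has_tsd or has_soxz:
            label = "chemoautotrophic-S-oxidizer"
        else:
            label = "unclassified"
        out.append(
            AutotrophyAnnotation(
                genome_id=genome.genome_id,
                has_puf=has_puf,
                has_tsd=has_tsd,
                has_soxZ=has_soxz,
                label=label,
            )
        )
    return out


def aggregate_by_taxon(
    per_cell: AbundanceMatrix,
    gene_copies: AbundanceMatrix,
    clusters,
    genes: Iterable[GeneRecord],
    genomes: Iterable[GenomeRecord],
    rank: str = "phylum",
) -> pd.DataFrame:
    """Split each KO's per-cell abundance across taxa.

    The split is proportional to the member genes' contributing gene copies:
    each catalog cluster's per-sample copies are shared equally among its
    member genes, each member attributed to its source genome's taxon at
    ``rank``.  Row sums over taxa reproduce the unsplit KO abundance.

    Returns a DataFrame with rows = samples and MultiIndex columns
    (KO, taxon).
    """
    if per_cell.stage != "per_cell_copies" or gene_copies.stage != "gene_copies":
        raise ValidationError("aggregate_by_taxon expects per-cell and gene-copy matrices")
    genome_of = {g.gene_id: g.genome_id for g in genes}
    taxon_of_genome = {g.genome_id: (g.rank(rank) or "unassigned") for g in genomes}
    # per (ko, taxon) weight matrix over samples
    weights: dict = {}
    for cl in clusters:
        if cl.ko is None or cl.representative_gene_id not in gene_copies.values.columns:
            continue
        copies = gene_copies.values[cl.representative_gene_id]
        share = copies / len(cl.member_gene_ids)
        for m in cl.member_gene_ids:
            taxon = taxon_of_genome.get(genome_of.get(m, ""), "unassigned")
            key = (cl.ko, taxon)
            weights[key] = weights.get(key, 0) + share
    if not weights:
        return pd.DataFrame(index=per_cell.values.index)
    w = pd.DataFrame(weights).reindex(per_cell.values.index).fillna(0.0)
    w.columns = pd.MultiIndex.from_tuples(w.columns, names=["ko", "taxon"])
    out = {}
    for ko in per_cell.values.columns:
        if ko not in w.columns.get_level_values("ko"):
            out[(ko, "unassigned")] = per_cell.values[ko]
            continue
        wk = w[ko]
        tot = wk.sum(axis=1)
        frac = wk.div(tot.where(tot > 0, 1.0), axis=0)
        # samples with abundance but zero weight: attribute to 'unassigned'
        zero = (tot == 0) & (per_cell.values[ko] > 0)
        for taxon in wk.columns:
            out[(ko, taxon)] = per_cell.values[ko] * frac[taxon]
        if zero.any():
            out[(ko, "unassigned")] = out.get((ko, "unassigned"), 0) + per_cell.values[ko] * zero
    res = pd.DataFrame(out, index=per_cell.values.index)
    res.columns = pd.MultiIndex.from_tuples(res.columns, names=["ko", "taxon"])
    return res.sort_index(axis=1)
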