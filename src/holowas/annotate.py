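"""SNP-to-gene annotation against a GFF3 gene set.

A SNP is linked to a gene by three window criteria (window default
100 kb, boundaries inclusive, strand ignored):

* ``within_gene``     — the SNP position lies inside [start, end];
* ``within_window``   — the gene lies entirely inside the SNP-centered
  interval [pos - window, pos + window];
* ``overlaps_window`` — the gene partially intersects that interval.

``distance`` is the base-pair gap between the SNP and the nearest gene
edge (0 when the SNP is inside the gene).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = ["GeneModel", "SnpGeneHit", "load_gff", "annotate_snps", "nearest_gene"]


@dataclass(frozen=True)
class GeneModel:
    """One gene feature, 1-based inclusive coordinates."""

    gene_id: str
    name: str
    chrom: str
    start: int
    end: int
    strand: str = "."
    biotype: str = ""

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start {self.start} > end {self.end}")
        if not self.chrom:
            raise ValueError(f"gene {self.gene_id}: empty chromosome")


@dataclass(frozen=True)
class SnpGeneHit:
    snp_id: str
    gene_id: str
    name: str
    relation: str  # within_gene | within_window | overlaps_window
    distance: int  # bp to nearest gene edge; 0 if inside


def load_gff(path: str | Path) -> list[GeneModel]:
    """Load gene features from a GFF3 file.

    Only features of type ``gene`` become GeneModels; a file without any
    raises no error but warns.  Uses gffutils for parsing, so attribute
    quirks (quoting, multi-values) follow the GFF3 standard.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        attrs = feat.attributes
        name = attrs.get("Name", attrs.get("gene_name", [feat.id]))[0]
        biotype = attrs.get("biotype", attrs.get("gene_biotype", [""]))[0]
        genes.append(
            GeneModel(feat.id, name, feat.seqid, feat.start, feat.end, feat.strand, biotype)
        )
    if not genes:
        warnings.warn(f"{path}: no gene features found", stacklevel=2)
    return genes


def _distance(pos: int, g: GeneModel) -> int:
    if g.start <= pos <= g.end:
        return 0
    return g.start - pos if pos < g.start else pos - g.end


def annotate_snps(
    snps: pd.DataFrame, genes: list[GeneModel], window: int = 100_000
) -> list[SnpGeneHit]:
    """Report every gene linked to each SNP by the three window criteria.

    ``snps`` needs columns ``id, chrom, pos``.  Chromosome mismatches
    simply produce no hit.  With ``window=0`` only containing genes are
    reported.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
        by_chrom.setdefault(str(g.chrom), []).append(g)
    hits = []
    for _, row in snps.iterrows():
        pos = int(row["pos"])
        lo, hi = pos - window, pos + window
        for g in by_chrom.get(str(row["chrom"]), []):
            if g.end < lo or g.start > hi:
                continue
            d = _distance(pos, g)
            if d == 0:
                relation = "within_gene"
            elif lo <= g.start and g.end <= hi:
                relation = "within_window"
            else:
                relation = "overlaps_window"
            if d > window:
                continue
            hits.append(SnpGeneHit(str(row["id"]), g.gene_id, g.name, relation, d))
    return hits


def nearest_gene(
    snp_id: str, chrom: str, pos: int, genes: list[GeneModel]
) -> SnpGeneHit | None:
    """Single closest gene on the SNP's chromosome.

    Ties break by smaller distance, then smaller start coordinate, then
    lexicographic gene ID; returns None when the chromosome has no gene.
    """
    cands = [g for g in genes if str(g.chrom) == str(chrom)]
    if not cands:
        return None
    best = min(cands, key=lambda g: (_distance(int(pos), g), g.start, g.gene_id))
    d = _distance(int(pos), best)
    relation = "within_gene" if d == 0 else "within_window"
    return SnpGeneHit(str(snp_id), best.gene_id, best.name, relation, d)


def hits_to_frame(hits: list[SnpGeneHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [(h.snp_id, h.gene_id, h.name, h.relation, h.distance) for h in hits],
        columns=["snp_id", "gene_id", "name", "relation", "distance"],
    )
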