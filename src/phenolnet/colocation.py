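"""lncRNA–gene co-location analysis.

Candidate cis-regulatory lncRNA–gene edges combine two filters: genomic
proximity (the gene intersects the lncRNA interval extended by a flanking
window, default 100 kb on each side) and strong co-expression
(|PCC| > 0.8 by default). lncRNAs are additionally classified as antisense
(overlapping a gene on the opposite strand), intergenic (no gene overlap),
or sense_overlapping (same-strand overlap; an explicit extension of the
usual two-way vocabulary).

All intervals are 0-based half-open internally; GFF3 (1-based inclusive)
and BED (0-based half-open) are converted on input. Proximity is
strand-agnostic — strand matters only for the antisense call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)

VALID_STRANDS = {"+", "-", "."}


@dataclass(frozen=True)
class GenomicFeature:
    """A typed, stranded interval (0-based half-open) on a chromosome."""

    id: str
    chrom: str
    start: int
    end: int
    strand: str
    kind: str  # "gene" | "lncRNA"

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"feature {self.id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"feature {self.id}: unknown strand {self.strand!r}")

    def overlaps(self, other: "GenomicFeature") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def gap_to(self, other: "GenomicFeature") -> int | None:
        """Distance between closest interval ends; 0 on overlap, None across chromosomes."""
        if self.chrom != other.chrom:
            return None
        if self.overlaps(other):
            return 0
        return max(self.start, other.start) - min(self.end, other.end)


@dataclass
class ColocationConfig:
    """Flanking window (bp, default 100,000) and co-expression cutoff."""

    window_bp: int = 100_000
    pcc_threshold: float = 0.8

    def __post_init__(self) -> None:
        if self.window_bp < 0:
            raise ValueError("window_bp must be >= 0")


@dataclass(frozen=True)
class ColocationPair:
    lncrna_id: str
    gene_id: str
    distance_bp: int
    relation: str  # "antisense" | "intergenic_neighbor"
    r: float


def _parse_gff3_attributes(field: str) -> dict[str, str]:
    out = {}
    for item in field.strip().split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def parse_features(path) -> list[GenomicFeature]:
    """Parse genes and lncRNAs from GFF3 or BED into internal coordinates.

    The dialect is chosen from the extension (.bed ⇒ BED, else GFF3) and
    logged. GFF3 features of type ``gene`` (or with biotype=lncRNA, or type
    ``lnc_RNA``/``lncRNA``) are kept; BED records use column 4 as the id
    (ids prefixed ``lnc`` are classed lncRNA), column 6 as strand.
    """
    path = str(path)
    dialect = "bed" if path.endswith(".bed") else "gff3"
    logger.info("parse_features: reading %s as %s", path, dialect)
    feats: list[GenomicFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if dialect == "gff3":
                if len(cols) < 9:
                    raise ValueError(f"{path}:{lineno}: malformed GFF3 record")
                chrom, _, ftype, start1, end1, _, strand, _, attrs = cols[:9]
                attr = _parse_gff3_attributes(attrs)
                fid = attr.get("ID", f"{chrom}:{start1}-{end1}")
                start, end = int(start1) - 1, int(end1)
                biotype = attr.get("biotype", "")
                if ftype in ("lnc_RNA", "lncRNA") or biotype == "lncRNA":
                    kind = "lncRNA"
                elif ftype == "gene":
                    kind = "gene"
                else:
                    continue
            else:
                if len(cols) < 4:
                    raise ValueError(f"{path}:{lineno}: BED record needs >= 4 columns")
                chrom, start, end = cols[0], int(cols[1]), int(cols[2])
                fid = cols[3]
                strand = cols[5] if len(cols) >= 6 else "."
                kind = "lncRNA" if fid.lower().startswith("lnc") else "gene"
            if end <= start:
                raise ValueError(
                    f"{path}:{lineno}: record {fid} has end <= start after conversion"
                )
            feats.append(GenomicFeature(fid, chrom, start, end, strand, kind))
    return feats


def features_to_gff3(feats: list[GenomicFeature]) -> str:
    """Serialize features back to GFF3 (1-based inclusive)."""
    lines = ["##gff-version 3"]
    for f in feats:
        ftype = "lnc_RNA" if f.kind == "lncRNA" else "gene"
        attrs = f"ID={f.id}" + (";biotype=lncRNA" if f.kind == "lncRNA" else "")
        lines.append(
            "\t".join(
                [f.chrom, "phenolnet", ftype, str(f.start + 1), str(f.end), ".",
                 f.strand, ".", attrs]
            )
        )
    return "\n".join(lines) + "\n"


def colocated_genes(
    lncrna: GenomicFeature,
    genes: list[GenomicFeature],
    config: ColocationConfig | None = None,
) -> list[tuple[GenomicFeature, int]]:
    """Genes intersecting the lncRNA interval extended by the window.

    The search interval is ``[lncrna.start - window, lncrna.end + window)``
    (half-open), so a gene whose gap to the lncRNA equals the window exactly
    is excluded. Distance is the gap between closest interval ends, 0 on
    overlap. Strand is ignored. Results sorted by (distance, gene id).
    """
    config = config or ColocationConfig()
    w = config.window_bp
    lo, hi = lncrna.start - w, lncrna.end + w
    out: list[tuple[GenomicFeature, int]] = []
    for g in genes:
        if g.chrom != lncrna.chrom or g.id == lncrna.id:
            continue
        if g.start < hi and lo < g.end:
            out.append((g, lncrna.gap_to(g)))
    out.sort(key=lambda t: (t[1], t[0].id))
    return out


def classify_lncrna(
    lncrna: GenomicFeature, genes: list[GenomicFeature]
) -> str:
    """Classify a lncRNA by gene overlap and relative strand.

    antisense: overlaps ≥1 gene on the opposite strand; sense_overlapping:
    overlaps genes only on the same strand; intergenic: overlaps no gene.
    A strand-less lncRNA ('.') overlapping a gene cannot be oriented and is
    flagged ``overlapping_unstranded``.
    """
    overlapping = [g for g in genes if lncrna.overlaps(g)]
    if not overlapping:
        return "intergenic"
    if lncrna.strand == ".":
        logger.warning(
            "lncRNA %s overlaps a gene but has no strand; antisense undeterminable",
            lncrna.id,
        )
        return "overlapping_unstranded"
    if any(g.strand != "." and g.strand != lncrna.strand for g in overlapping):
        return "antisense"
    return "sense_overlapping"


def lncrna_edges(
    lncrnas: list[GenomicFeature],
    genes: list[GenomicFeature],
    corr: pd.DataFrame,
    config: ColocationConfig | None = None,
) -> list[ColocationPair]:
    """Co-located lncRNA–gene pairs that are also strongly co-expressed.

    Keeps pairs with ``|r| >`` the cutoff where both members are present in
    the correlation matrix; lncRNAs absent from the expression data are
    dropped with a warning. Relation is ``antisense`` when the pair itself
    overlaps on opposite strands, else ``intergenic_neighbor``.
    """
    config = config or ColocationConfig()
    pairs: list[ColocationPair] = []
    for lnc in lncrnas:
        if lnc.id not in corr.index:
            logger.warning("lncRNA %s absent from expression matrix; dropped", lnc.id)
            continue
        for gene, dist in colocated_genes(lnc, genes, config):
            if gene.id not in corr.index:
                continue
            r = corr.loc[lnc.id, gene.id]
            if not pd.notna(r) or abs(r) <= config.pcc_threshold:
                continue
            if lnc.overlaps(gene) and lnc.strand != "." and gene.strand != "." \
                    and lnc.strand != gene.strand:
                relation = "antisense"
            else:
                relation = "intergenic_neighbor"
            pairs.append(ColocationPair(lnc.id, gene.id, dist, relation, float(r)))
    return pairs


def pairs_to_frame(pairs: list[ColocationPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.lncrna_id, p.gene_id, p.distance_bp, p.relation, p.r) for p in pairs],
        columns=["lncrna", "gene", "distance_bp", "relation", "r"],
    )
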