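"""Promoter extraction, IUPAC motif scanning, and per-module enrichment.

Promoters default to the 2,000 bp upstream of the annotated gene start
(strand-aware, truncated at chromosome edges). Transcription-factor binding
sites are given as IUPAC-degenerate strings (e.g. the R2R3-MYB site CCWACC,
W = A/T) and scanned on both strands, overlapping hits included. Enrichment
of motif *presence* (≥1 hit per promoter) in a gene module against a
background universe uses the one-sided hypergeometric upper tail with
Benjamini–Hochberg FDR across all (module, motif) tests.

The bundled default motif set pairs the MYB CCWACC site with standard
literature consensi for the other TF families implicated in berry
phenylpropanoid regulation (WRKY W-box, AP2/ERF GCC-box, bHLH E-box,
bZIP G-box); users replace it via a motif TSV (name, iupac, family).
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .colocation import GenomicFeature

logger = logging.getLogger(__name__)

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_IUPAC_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R", "S": "S",
    "W": "W", "K": "M", "M": "K", "B": "V", "V": "B", "D": "H", "H": "D",
    "N": "N",
}


@dataclass(frozen=True)
class Motif:
    """An IUPAC-degenerate TF binding site."""

    name: str
    iupac: str
    tf_family: str = "other"

    def __post_init__(self) -> None:
        if not self.iupac:
            raise ValueError(f"motif {self.name}: empty IUPAC string")
        for ch in self.iupac.upper():
            if ch not in IUPAC:
                raise ValueError(f"motif {self.name}: invalid IUPAC code {ch!r}")

    def __len__(self) -> int:
        return len(self.iupac)

    def reverse_complement(self) -> "Motif":
        rc = "".join(_IUPAC_COMPLEMENT[c] for c in reversed(self.iupac.upper()))
        return Motif(self.name, rc, self.tf_family)

    def matches(self, word: str) -> bool:
        """Exact-length IUPAC match of ``word`` against this motif."""
        if len(word) != len(self.iupac):
            return False
        return all(
            b.upper() in IUPAC[m] for b, m in zip(word, self.iupac.upper())
        )


DEFAULT_MOTIFS = [
    Motif("MYB_CCWACC", "CCWACC", "R2R3-MYB"),
    Motif("WRKY_Wbox", "TTGACY", "WRKY"),
    Motif("ERF_GCCbox", "GCCGCC", "AP2/ERF"),
    Motif("bHLH_Ebox", "CANNTG", "bHLH"),
    Motif("bZIP_Gbox", "CACGTG", "bZIP"),
]


@dataclass(frozen=True)
class MotifHit:
    gene_id: str
    motif_name: str
    position: int  # 0-based offset in the promoter, forward coordinates
    strand: str  # "+" | "-"


@dataclass(frozen=True)
class EnrichmentResult:
    module_id: str
    motif_name: str
    k: int  # genes with the motif in the module
    n: int  # module size
    K: int  # genes with the motif in the background
    N: int  # background size
    p_value: float
    fdr: float


def load_motifs(path) -> list[Motif]:
    """Read a motif TSV with columns name, iupac, family (header optional)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    cols = [c.lower() for c in df.columns]
    if "iupac" not in cols:  # headerless file
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["name", "iupac", "family"])
    else:
        df.columns = cols
        if "family" not in df.columns:
            df["family"] = "other"
    return [Motif(str(r["name"]), str(r["iupac"]), str(r.get("family", "other")))
            for _, r in df.iterrows()]


def _read_fasta_dict(source) -> dict[str, str]:
    if isinstance(source, dict):
        return {k: str(v) for k, v in source.items()}
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(source, "fasta")}


def extract_promoters(
    genes: list[GenomicFeature], genome, length: int = 2000
) -> dict[str, str]:
    """Strand-aware upstream promoter sequences, keyed by gene id.

    For a + strand gene the ``length`` bp ending at its start; for a −
    strand gene the reverse complement of the ``length`` bp following its
    end. Promoters running off a chromosome edge are truncated with a
    warning. ``genome`` is a FASTA path/handle/text or a dict of sequences.
    """
    chroms = _read_fasta_dict(genome)
    out: dict[str, str] = {}
    for g in genes:
        if g.chrom not in chroms:
            raise ValueError(f"gene {g.id}: chromosome {g.chrom!r} absent from FASTA")
        seq = chroms[g.chrom]
        if g.strand == "-":
            lo, hi = g.end, min(g.end + length, len(seq))
            prom = str(Seq(seq[lo:hi]).reverse_complement())
        else:
            lo, hi = max(g.start - length, 0), g.start
            prom = seq[lo:hi]
        if len(prom) < length:
            logger.warning(
                "promoter of %s truncated to %d bp at chromosome edge", g.id, len(prom)
            )
        out[g.id] = prom.upper()
    return out


def _iupac_regex(motif: Motif) -> re.Pattern:
    parts = []
    for ch in motif.iupac.upper():
        opts = IUPAC[ch]
        parts.append(opts if len(opts) == 1 else f"[{opts}]")
    # lookahead so overlapping occurrences are all found
    return re.compile("(?=(" + "".join(parts) + "))")


def scan_motif(promoters: dict[str, str], motif: Motif) -> list[MotifHit]:
    """All occurrences of the motif on both strands of each promoter.

    Reverse-strand hits are matches of the reverse-complement pattern,
    reported at their forward-strand offset with strand '-'. Overlapping
    matches all reported; order is (gene, position, strand).
    """
    fwd = _iupac_regex(motif)
    rev = _iupac_regex(motif.reverse_complement())
    hits: list[MotifHit] = []
    for gid in sorted(promoters):
        seq = promoters[gid].upper()
        found: list[tuple[int, str]] = []
        found.extend((m.start(), "+") for m in fwd.finditer(seq))
        for m in rev.finditer(seq):
            found.append((m.start(), "-"))
        for pos, strand in sorted(found):
            hits.append(MotifHit(gid, motif.name, pos, strand))
    return hits


def scan_motifs(promoters: dict[str, str], motifs: list[Motif]) -> list[MotifHit]:
    out: list[MotifHit] = []
    for m in motifs:
        out.extend(scan_motif(promoters, m))
    return out


def annotate_presence(
    hits: list[MotifHit], universe: list[str], motif_names: list[str] | None = None
) -> pd.DataFrame:
    """Boolean gene × motif presence matrix (≥1 hit ⇒ present)."""
    if motif_names is None:
        motif_names = sorted({h.motif_name for h in hits})
    presence = pd.DataFrame(False, index=list(universe), columns=motif_names)
    for h in hits:
        if h.gene_id in presence.index:
            presence.loc[h.gene_id, h.motif_name] = True
    return presence


def enrich_modules(
    presence: pd.DataFrame,
    modules: dict[str, list[str]],
    background: list[str] | None = None,
) -> list[EnrichmentResult]:
    """Hypergeometric motif-presence enrichment per (module, motif).

    p = P(X ≥ k) for X ~ Hypergeom(N, K, n) where N is the background size,
    K the background genes carrying the motif, n the module size, and k the
    module genes carrying it. BH FDR is applied across all tests jointly.
    Module genes without a promoter in ``presence`` are excluded from n with
    a warning.
    """
    bg = list(background) if background is not None else list(presence.index)
    bg = [g for g in bg if g in presence.index]
    N = len(bg)
    sub = presence.loc[bg]
    tests: list[tuple[str, str, int, int, int, int, float]] = []
    for mod_id in sorted(modules):
        members = [g for g in modules[mod_id] if g in presence.index]
        dropped = set(modules[mod_id]) - set(members)
        if dropped:
            logger.warning(
                "module %s: %d genes lack promoters; excluded", mod_id, len(dropped)
            )
        members = [g for g in members if g in set(bg)]
        n = len(members)
        for motif_name in presence.columns:
            K = int(sub[motif_name].sum())
            k = int(presence.loc[members, motif_name].sum()) if n else 0
            p = float(hypergeom.sf(k - 1, N, K, n))
            tests.append((mod_id, motif_name, k, n, K, N, min(p, 1.0)))
    if not tests:
        return []
    pvals = [t[6] for t in tests]
    fdr = multipletests(pvals, method="fdr_bh")[1]
    return [
        EnrichmentResult(mod, mot, k, n, K, N, p, float(q))
        for (mod, mot, k, n, K, N, p), q in zip(tests, fdr)
    ]


def hits_to_frame(hits: list[MotifHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [(h.gene_id, h.motif_name, h.position, h.strand) for h in hits],
        columns=["gene_id", "motif_name", "position", "strand"],
    )


def enrichment_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.module_id, r.motif_name, r.k, r.n, r.K, r.N, r.p_value, r.fdr)
            for r in results
        ],
        columns=["module_id", "motif_name", "k", "n", "K", "N", "p_value", "fdr"],
    )
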