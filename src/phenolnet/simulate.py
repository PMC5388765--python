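"""Synthetic inputs with the statistical and genomic structure the analysis assumes.

The generator emulates the shape of a berry-development study — five
cultivars sampled at four stages — without mimicking any real genome:

* an expression matrix with *planted modules*: groups of genes sharing a
  piecewise-linear stage profile (ripening-up, early-up, mid-peak), each
  member carrying a sign (+1/−1, so anti-correlated members are allowed)
  and a target within-module correlation, plus uncorrelated background
  genes and i.i.d. Gaussian noise;
* a pseudo-genome whose hallmark features are a tandem cluster of nine
  same-strand paralogs with one adjacent intergenic lncRNA (the
  chromosome-10 stilbene-synthase motif) and one antisense lncRNA
  overlapping a gene on the opposite strand;
* promoter sets with a degenerate IUPAC motif planted at a controlled
  fraction, the remaining sequences guaranteed motif-free;
* miRNA/target pairs built as exact reverse complements with a requested
  number of mismatches and G:U wobbles introduced at recorded positions,
  together with a truth table of the implied expectation scores.

All outputs are reproducible: the same seed yields byte-identical files.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .colocation import GenomicFeature
from .gcn import ExpressionMatrix
from .motifs import IUPAC, Motif

logger = logging.getLogger(__name__)

BASES = np.array(list("ACGT"))

#: Piecewise-linear stage templates (evaluated at n_stages points).
PROFILES = {
    "ripening_up": lambda n: np.linspace(0.0, 1.0, n),
    "early_up": lambda n: np.linspace(1.0, 0.0, n),
    "mid_peak": lambda n: 1.0 - np.abs(np.linspace(-1.0, 1.0, n)),
}


@dataclass
class PlantedModule:
    """A group of genes sharing one stage profile, up to sign and noise."""

    module_id: str
    gene_ids: list[str]
    base_profile: str | np.ndarray = "ripening_up"
    signs: list[int] | None = None  # +1/-1 per gene; default all +1
    within_module_r: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.within_module_r <= 1.0:
            raise ValueError("within_module_r must lie in [0, 1]")
        if self.signs is None:
            self.signs = [1] * len(self.gene_ids)
        if len(self.signs) != len(self.gene_ids):
            raise ValueError("signs must match gene_ids in length")
        if any(s not in (1, -1) for s in self.signs):
            raise ValueError("signs must be +1 or -1")

    def profile(self, n_stages: int) -> np.ndarray:
        if isinstance(self.base_profile, str):
            try:
                return PROFILES[self.base_profile](n_stages)
            except KeyError:
                raise ValueError(f"unknown profile {self.base_profile!r}") from None
        p = np.asarray(self.base_profile, dtype=float)
        if len(p) != n_stages:
            raise ValueError("explicit base_profile length must equal n_stages")
        return p


@dataclass
class SimulationDesign:
    """Factorial expression design: cultivars × stages × replicates."""

    n_cultivars: int = 5
    n_stages: int = 4
    replicates_per_cell: int = 1
    modules: list[PlantedModule] = field(default_factory=list)
    n_background: int = 0
    noise_sd: float = 6.0
    baseline: float = 120.0
    amplitude: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cultivars < 1:
            raise ValueError("n_cultivars must be >= 1")
        if self.n_stages < 2:
            raise ValueError("n_stages must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        seen: dict[str, str] = {}
        for mod in self.modules:
            for g in mod.gene_ids:
                if g in seen:
                    raise ValueError(
                        f"gene {g!r} planted in both {seen[g]!r} and {mod.module_id!r}"
                    )
                seen[g] = mod.module_id

    @property
    def n_samples(self) -> int:
        return self.n_cultivars * self.n_stages * self.replicates_per_cell

    def sample_ids(self) -> list[str]:
        return [
            f"cultivar{c + 1}_stage{s + 1}_rep{r + 1}"
            for c in range(self.n_cultivars)
            for s in range(self.n_stages)
            for r in range(self.replicates_per_cell)
        ]

    def stage_index(self) -> np.ndarray:
        return np.array(
            [
                s
                for _ in range((self.n_cultivars))
                for s in range(self.n_stages)
                for _ in range(self.replicates_per_cell)
            ]
        )


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        raise ValueError("cannot standardize a constant profile")
    return (v - v.mean()) / sd


def simulate_expression(design: SimulationDesign) -> ExpressionMatrix:
    """Generate the planted-module expression matrix.

    Each module gene's abundance is
    ``baseline + sign * amplitude * (w·z + sqrt(1−w²)·u) + noise``
    with ``w = sqrt(within_module_r)``, ``z`` the standardized per-sample
    stage profile, ``u`` a gene-specific standardized vector orthogonalized
    against ``z``, and Gaussian noise of sd ``noise_sd``; background genes
    get only ``baseline + amplitude·u + noise``. Values are floored at 0
    (with a warning when flooring occurs), so at ``noise_sd = 0`` and
    ``within_module_r = 1`` pairwise correlations are exactly ±1.
    """
    rng = np.random.default_rng(design.seed)
    stage = design.stage_index()
    rows: list[np.ndarray] = []
    index: list[str] = []

    def idio() -> np.ndarray:
        u = rng.normal(size=design.n_samples)
        return u

    for mod in design.modules:
        z = _standardize(mod.profile(design.n_stages)[stage])
        w = float(np.sqrt(mod.within_module_r))
        for gid, sign in zip(mod.gene_ids, mod.signs):
            if w < 1.0:
                u = idio()
                u = u - (u @ z) / (z @ z) * z  # orthogonalize against the profile
                u = _standardize(u)
                core = w * z + np.sqrt(1.0 - w**2) * u
            else:
                core = z
            noise = rng.normal(0.0, design.noise_sd, design.n_samples)
            rows.append(design.baseline + sign * design.amplitude * core + noise)
            index.append(gid)
    for b in range(design.n_background):
        u = _standardize(idio())
        noise = rng.normal(0.0, design.noise_sd, design.n_samples)
        rows.append(design.baseline + design.amplitude * u + noise)
        index.append(f"BG{b + 1:03d}")

    values = np.vstack(rows) if rows else np.empty((0, design.n_samples))
    if (values < 0).any():
        logger.warning(
            "simulate_expression: %d values floored at 0", int((values < 0).sum())
        )
        values = np.clip(values, 0.0, None)
    df = pd.DataFrame(values, index=index, columns=design.sample_ids())
    return ExpressionMatrix(df)


# ---------------------------------------------------------------------------
# Genome simulation


@dataclass
class GenomeSpec:
    """Layout of the pseudo-genome: chromosomes, features, and landmarks.

    ``tandem_cluster`` names (chrom, consecutive same-strand paralog ids,
    adjacent lncRNA id); ``antisense_pair`` names (lncRNA id, gene id)
    overlapping on opposite strands.
    """

    chromosomes: list[tuple[str, int]]
    features: list[GenomicFeature]
    tandem_cluster: tuple[str, list[str], str] | None = None
    antisense_pair: tuple[str, str] | None = None
    colocation_window: int = 100_000

    def __post_init__(self) -> None:
        lengths = dict(self.chromosomes)
        by_id = {f.id: f for f in self.features}
        for f in self.features:
            if f.chrom not in lengths:
                raise ValueError(f"feature {f.id}: unknown chromosome {f.chrom!r}")
            if f.end > lengths[f.chrom]:
                raise ValueError(
                    f"feature {f.id} exceeds chromosome {f.chrom} length"
                )
        if self.tandem_cluster is not None:
            chrom, gene_ids, lnc_id = self.tandem_cluster
            genes = [by_id[g] for g in gene_ids]
            if any(g.chrom != chrom for g in genes) or by_id[lnc_id].chrom != chrom:
                raise ValueError("tandem cluster members must share one chromosome")
            if len({g.strand for g in genes}) != 1:
                raise ValueError("tandem cluster genes must share a strand")
            ordered = sorted(genes, key=lambda g: g.start)
            for a, b in zip(ordered, ordered[1:]):
                gap = b.start - a.end
                if gap < 0 or gap >= self.colocation_window:
                    raise ValueError(
                        f"tandem cluster gap {a.id}-{b.id} = {gap} violates layout"
                    )
        if self.antisense_pair is not None:
            lnc, gene = self.antisense_pair
            if not by_id[lnc].overlaps(by_id[gene]):
                raise ValueError("antisense pair must overlap")
            if by_id[lnc].strand == by_id[gene].strand:
                raise ValueError("antisense pair must lie on opposite strands")

    def genes(self) -> list[GenomicFeature]:
        return [f for f in self.features if f.kind == "gene"]

    def lncrnas(self) -> list[GenomicFeature]:
        return [f for f in self.features if f.kind == "lncRNA"]


def default_genome_spec() -> GenomeSpec:
    """The standard fixture genome.

    chr10 carries nine tandem paralogs STS01–STS09 (3 kb bodies, 5 kb gaps,
    + strand) with the intergenic lncRNA ``lnc_STS_cluster`` 20 kb upstream
    of STS01, plus a distant gene FAR1 outside the 100 kb window of the
    lncRNA. chr03 carries gene GGT1 with the antisense lncRNA
    ``lnc_antisense`` overlapping it on the − strand. chr01 carries the
    remaining pathway/TF genes.
    """
    feats: list[GenomicFeature] = []
    # tandem cluster on chr10: gene i body [start, start+3000), 5 kb gaps
    sts_ids = [f"STS{i:02d}" for i in range(1, 10)]
    start = 60_000
    for gid in sts_ids:
        feats.append(GenomicFeature(gid, "chr10", start, start + 3_000, "+", "gene"))
        start += 8_000  # 3 kb body + 5 kb gap
    lnc_start = 60_000 - 20_000 - 1_000  # 20 kb upstream of STS01, 1 kb long
    feats.append(
        GenomicFeature("lnc_STS_cluster", "chr10", lnc_start, lnc_start + 1_000, "+", "lncRNA")
    )
    # distant gene: gap to the lncRNA interval far beyond 100 kb
    feats.append(GenomicFeature("FAR1", "chr10", 290_000, 293_000, "+", "gene"))
    # antisense pair on chr03
    feats.append(GenomicFeature("GGT1", "chr03", 20_000, 24_000, "+", "gene"))
    feats.append(GenomicFeature("lnc_antisense", "chr03", 21_000, 23_000, "-", "lncRNA"))
    # pathway and regulator genes on chr01, well separated
    chr01_ids = ["PAL1", "PAL2", "C4H1", "CHS1", "CHI1", "F3H1", "MYB14", "WRKY03"]
    pos = 10_000
    for gid in chr01_ids:
        feats.append(GenomicFeature(gid, "chr01", pos, pos + 2_000, "+", "gene"))
        pos += 12_000
    return GenomeSpec(
        chromosomes=[("chr01", 120_000), ("chr03", 50_000), ("chr10", 310_000)],
        features=feats,
        tandem_cluster=("chr10", sts_ids, "lnc_STS_cluster"),
        antisense_pair=("lnc_antisense", "GGT1"),
    )


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.choice(BASES, size=n)


def _concrete_motif(rng: np.random.Generator, motif: Motif) -> str:
    return "".join(rng.choice(list(IUPAC[c])) for c in motif.iupac.upper())


def _scrub_region(
    seq: np.ndarray, lo: int, hi: int, motifs: list[Motif], rng: np.random.Generator
) -> None:
    """Mutate bases until [lo, hi) contains no occurrence of any motif, either strand."""
    lo, hi = max(lo, 0), min(hi, len(seq))
    patterns = []
    for m in motifs:
        patterns.append(m)
        patterns.append(m.reverse_complement())
    for _ in range(200):
        dirty = False
        region = "".join(seq[lo:hi])
        for pat in patterns:
            L = len(pat)
            for i in range(len(region) - L + 1):
                if pat.matches(region[i : i + L]):
                    seq[lo + i + L // 2] = rng.choice(BASES)
                    dirty = True
        if not dirty:
            return
    raise RuntimeError("failed to scrub motif occurrences from region")


def simulate_genome(
    spec: GenomeSpec,
    seed: int = 0,
    planted_motif: Motif | None = None,
    motif_gene_ids: list[str] | None = None,
    promoter_length: int = 500,
) -> tuple[str, str]:
    """Emit (GFF3 text, FASTA text) realizing the genome spec.

    Chromosome sequences are uniform random A/C/G/T. When ``planted_motif``
    is given, the upstream ``promoter_length`` bp of every gene are first
    scrubbed of motif occurrences (both strands), then one concrete motif
    instance is planted in the promoters of ``motif_gene_ids``, making
    promoter enrichment ground truth exact.
    """
    from .colocation import features_to_gff3

    rng = np.random.default_rng(seed)
    seqs: dict[str, np.ndarray] = {}
    for name, length in spec.chromosomes:
        seqs[name] = _random_seq(rng, length)
    if planted_motif is not None:
        genes = spec.genes()
        for g in genes:
            if g.strand == "-":
                lo, hi = g.end, g.end + promoter_length
            else:
                lo, hi = g.start - promoter_length, g.start
            _scrub_region(seqs[g.chrom], lo, hi, [planted_motif], rng)
        for g in genes:
            if motif_gene_ids is not None and g.id not in motif_gene_ids:
                continue
            word = _concrete_motif(rng, planted_motif)
            if g.strand == "-":
                # promoter is revcomp of downstream window: plant revcomp word
                word = str(Seq(word).reverse_complement())
                lo = g.end
                offset = int(rng.integers(0, promoter_length - len(word) + 1))
                pos = lo + offset
            else:
                lo = g.start - promoter_length
                offset = int(rng.integers(0, promoter_length - len(word) + 1))
                pos = lo + offset
            seqs[g.chrom][pos : pos + len(word)] = list(word)
    fasta_lines: list[str] = []
    for name, _ in spec.chromosomes:
        fasta_lines.append(f">{name}")
        s = "".join(seqs[name])
        fasta_lines.extend(s[i : i + 80] for i in range(0, len(s), 80))
    gff3 = features_to_gff3(sorted(spec.features, key=lambda f: (f.chrom, f.start)))
    return gff3, "\n".join(fasta_lines) + "\n"


# ---------------------------------------------------------------------------
# Promoter simulation


def round_half_up(x: float) -> int:
    """Fractional planted counts round half up: round_half_up(3.5) == 4."""
    return int(np.floor(x + 0.5))


def simulate_promoters(
    gene_ids: list[str],
    motif: Motif | str,
    planted_fraction: float,
    promoter_length: int = 2000,
    seed: int = 0,
) -> str:
    """FASTA text of synthetic promoters with a motif planted at a set rate.

    Exactly ``round_half_up(planted_fraction * n)`` promoters (the first
    ones in ``gene_ids`` order after seeded shuffling) contain ≥1 planted
    instance of the motif; every other promoter is rejection-sampled to
    contain no match on either strand.
    """
    if isinstance(motif, str):
        motif = Motif(motif, motif)
    if not 0.0 <= planted_fraction <= 1.0:
        raise ValueError("planted_fraction must lie in [0, 1]")
    if len(motif) > promoter_length:
        raise ValueError("motif longer than promoter_length")
    rng = np.random.default_rng(seed)
    n_planted = round_half_up(planted_fraction * len(gene_ids))
    order = list(gene_ids)
    rng.shuffle(order)
    planted = set(order[:n_planted])
    lines: list[str] = []
    for gid in gene_ids:
        seq = _random_seq(rng, promoter_length)
        _scrub_region(seq, 0, promoter_length, [motif], rng)
        if gid in planted:
            word = _concrete_motif(rng, motif)
            pos = int(rng.integers(0, promoter_length - len(word) + 1))
            seq[pos : pos + len(word)] = list(word)
        lines.append(f">{gid}")
        lines.append("".join(seq))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# miRNA/target simulation

_WOBBLEABLE = {"T": "G", "U": "G", "G": "U"}  # target base -> miRNA base giving G:U
_MISMATCH_CHOICES = {  # target base -> miRNA bases that neither pair nor wobble
    "A": ["A", "C", "G"],
    "C": ["A", "C", "U"],
    "G": ["A", "G"],
    "T": ["C", "U"],
    "U": ["C", "U"],
}
_RNA_COMPLEMENT = {"A": "U", "C": "G", "G": "C", "T": "A", "U": "A"}


def _truth_expectation(
    positions_mm: list[int],
    positions_wb: list[int],
    mismatch_penalty: float = 1.0,
    wobble_penalty: float = 0.5,
    core_start: int = 2,
    core_end: int = 13,
    core_multiplier: float = 2.0,
) -> float:
    # independent arithmetic over the recorded 1-based miRNA positions
    total = 0.0
    for p in positions_mm:
        total += mismatch_penalty * (core_multiplier if core_start <= p <= core_end else 1.0)
    for p in positions_wb:
        total += wobble_penalty * (core_multiplier if core_start <= p <= core_end else 1.0)
    return total


def simulate_mirna_pairs(
    transcripts: list[tuple[str, str]],
    n_pairs: int,
    mismatches: int = 0,
    wobbles: int = 0,
    seed: int = 0,
    mirna_length: int = 21,
) -> tuple[str, pd.DataFrame]:
    """Plant miRNA/target pairs with controlled imperfection.

    Each emitted miRNA starts as the exact reverse complement (RNA alphabet)
    of a random window of its target transcript; then exactly ``mismatches``
    mismatching and ``wobbles`` G:U-wobble positions are introduced at
    recorded miRNA positions. Returns (miRNA FASTA text, truth table) with
    columns mirna, transcript, window_start, expectation,
    mismatch_positions, wobble_positions (1-based miRNA coordinates).
    Transcripts shorter than the miRNA are skipped with a warning.
    """
    if mismatches < 0 or wobbles < 0:
        raise ValueError("mismatches and wobbles must be >= 0")
    rng = np.random.default_rng(seed)
    usable = []
    for tid, seq in transcripts:
        if len(seq) < mirna_length:
            warnings.warn(f"transcript {tid} shorter than {mirna_length} nt; skipped")
            continue
        usable.append((tid, seq.upper()))
    if not usable:
        return "", pd.DataFrame(
            columns=["mirna", "transcript", "window_start", "expectation",
                     "mismatch_positions", "wobble_positions"]
        )
    fasta_lines: list[str] = []
    rows = []
    for k in range(n_pairs):
        tid, seq = usable[k % len(usable)]
        n = len(seq)
        for _attempt in range(500):
            start = int(rng.integers(0, n - mirna_length + 1))
            window = seq[start : start + mirna_length]
            # perfect miRNA: reverse complement, RNA alphabet
            mirna = [_RNA_COMPLEMENT[b] for b in reversed(window)]
            # miRNA position i (0-based) pairs with window base L-1-i
            wobble_ok = [
                i for i in range(mirna_length)
                if window[mirna_length - 1 - i] in _WOBBLEABLE
            ]
            if len(wobble_ok) >= wobbles and mirna_length >= mismatches + wobbles:
                break
        else:
            raise RuntimeError("could not place requested wobbles in any window")
        wb = (
            sorted(rng.choice(wobble_ok, size=wobbles, replace=False).tolist())
            if wobbles else []
        )
        remaining = [i for i in range(mirna_length) if i not in set(wb)]
        mm = (
            sorted(rng.choice(remaining, size=mismatches, replace=False).tolist())
            if mismatches else []
        )
        for i in wb:
            mirna[i] = _WOBBLEABLE[window[mirna_length - 1 - i]]
        for i in mm:
            choices = _MISMATCH_CHOICES[window[mirna_length - 1 - i]]
            mirna[i] = str(rng.choice(choices))
        mid = f"mir{k + 1:03d}"
        fasta_lines.append(f">{mid}")
        fasta_lines.append("".join(mirna))
        rows.append(
            (
                mid, tid, start,
                _truth_expectation([p + 1 for p in mm], [p + 1 for p in wb]),
                ",".join(str(p + 1) for p in mm),
                ",".join(str(p + 1) for p in wb),
            )
        )
    truth = pd.DataFrame(
        rows,
        columns=["mirna", "transcript", "window_start", "expectation",
                 "mismatch_positions", "wobble_positions"],
    )
    return "\n".join(fasta_lines) + "\n", truth
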