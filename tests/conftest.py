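"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive results from first principles
(textbook Pearson formula, exhaustive interval checks, position-by-position
IUPAC matching) so the implementation is checked against an independent
route, not against itself.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from phenolnet.colocation import GenomicFeature
from phenolnet.pipeline import PipelineConfig, run_pipeline, write_fixture_suite


@pytest.fixture(scope="session")
def fixture_suite(tmp_path_factory):
    """Synthetic input suite (seed 7) with the pipeline run once into results/."""
    out = tmp_path_factory.mktemp("suite")
    write_fixture_suite(out, seed=7)
    run_pipeline(PipelineConfig.from_yaml(out / "config.yaml"))
    return out


# ---------------------------------------------------------------------------
# Oracles


def pearson_oracle(x, y) -> float:
    """Textbook Pearson correlation, written as the plain double-sum formula."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y))
    dx = math.sqrt(sum((xi - mx) ** 2 for xi in x))
    dy = math.sqrt(sum((yi - my) ** 2 for yi in y))
    if dx == 0 or dy == 0:
        return float("nan")
    return num / (dx * dy)


def edges_oracle(matrix: np.ndarray, gene_ids: list[str], threshold: float) -> set:
    """Brute-force signed edge set: double loop over unordered pairs."""
    out = set()
    for i in range(len(gene_ids)):
        for j in range(i + 1, len(gene_ids)):
            r = pearson_oracle(matrix[i], matrix[j])
            if not math.isnan(r) and abs(r) > threshold:
                a, b = sorted((gene_ids[i], gene_ids[j]))
                out.add((a, b, "positive" if r > 0 else "negative"))
    return out


def colocation_oracle(
    lncrna: GenomicFeature, genes: list[GenomicFeature], window: int
) -> set:
    """Exhaustive all-pairs interval check against the extended lncRNA window."""
    lo, hi = lncrna.start - window, lncrna.end + window
    hits = set()
    for g in genes:
        if g.chrom != lncrna.chrom or g.id == lncrna.id:
            continue
        if max(lo, g.start) < min(hi, g.end):  # nonempty half-open intersection
            hits.add(g.id)
    return hits


IUPAC_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"}, "B": {"C", "G", "T"}, "D": {"A", "G", "T"},
    "H": {"A", "C", "T"}, "V": {"A", "C", "G"}, "N": {"A", "C", "G", "T"},
}


def iupac_match_oracle(word: str, pattern: str) -> bool:
    """Position-by-position IUPAC comparison."""
    return len(word) == len(pattern) and all(
        b in IUPAC_SETS[p] for b, p in zip(word.upper(), pattern.upper())
    )


def scan_oracle(seq: str, pattern: str) -> list[int]:
    """All forward-strand motif starts by sliding the oracle matcher."""
    L = len(pattern)
    return [i for i in range(len(seq) - L + 1) if iupac_match_oracle(seq[i : i + L], pattern)]


def adjusted_rand_index(labels_a: list, labels_b: list) -> float:
    """Independent ARI via the pair-counting formula."""
    from collections import Counter

    n = len(labels_a)
    pairs = Counter(zip(labels_a, labels_b))
    a_counts = Counter(labels_a)
    b_counts = Counter(labels_b)

    def comb2(k: int) -> float:
        return k * (k - 1) / 2

    sum_ij = sum(comb2(v) for v in pairs.values())
    sum_a = sum(comb2(v) for v in a_counts.values())
    sum_b = sum(comb2(v) for v in b_counts.values())
    expected = sum_a * sum_b / comb2(n)
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:
        return 1.0
    return (sum_ij - expected) / (max_index - expected)
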