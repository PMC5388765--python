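"""Plant-style miRNA target prediction by complementarity penalty scoring.

Each candidate duplex aligns the miRNA (5'→3') against a same-length
transcript window in antiparallel orientation: miRNA position i pairs with
the window base at the mirrored position. Per-position penalties accumulate
into an *expectation* score — 0 for a perfect reverse complement, higher as
complementarity degrades:

* Watson–Crick pair (A:U, G:C) → 0
* G:U wobble → 0.5
* anything else → 1.0
* penalties doubled inside the seed/core region, miRNA positions 2–13

Duplexes with expectation ≤ 3.0 are reported by default. All constants live
in :class:`ScoringScheme`. Alignment is ungapped; T and U are equivalent.
The scheme follows the classical plant target-finding rules and is
psRNATarget-like, not a byte-level reproduction of that server.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

_WATSON_CRICK = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}
_VALID = set("ACGU")


@dataclass
class ScoringScheme:
    """Penalty constants of the plant complementarity score.

    Core positions are 1-based on the miRNA, 5'→3', inclusive at both ends.
    """

    mismatch_penalty: float = 1.0
    wobble_penalty: float = 0.5
    core_start: int = 2
    core_end: int = 13
    core_multiplier: float = 2.0
    max_expectation: float = 3.0

    def __post_init__(self) -> None:
        if self.mismatch_penalty < 0 or self.wobble_penalty < 0:
            raise ValueError("penalties must be nonnegative")
        if not 1 <= self.core_start <= self.core_end:
            raise ValueError("require 1 <= core_start <= core_end")


@dataclass(frozen=True)
class TargetDuplex:
    """One miRNA/transcript alignment window with its expectation score."""

    mirna_id: str
    transcript_id: str
    window_start: int  # 0-based on the transcript
    expectation: float
    paired_string: tuple[str, ...]  # per miRNA position: match|wobble|mismatch


def _normalize(seq: str, what: str) -> str:
    s = seq.upper().replace("T", "U")
    bad = set(s) - _VALID
    if bad:
        raise ValueError(f"invalid character(s) {sorted(bad)} in {what}")
    return s


def score_duplex(
    mirna_seq: str, target_window: str, scheme: ScoringScheme | None = None
) -> tuple[float, tuple[str, ...]]:
    """Score one ungapped miRNA/target-window duplex.

    Both sequences are given 5'→3' and must be equal length; miRNA position
    i (1-based) is paired with window position ``L - i`` (0-based), i.e. the
    duplex is antiparallel. Returns (expectation, per-position labels along
    the miRNA).
    """
    scheme = scheme or ScoringScheme()
    mi = _normalize(mirna_seq, "miRNA")
    tg = _normalize(target_window, "target window")
    if len(mi) != len(tg):
        raise ValueError(
            f"ungapped mode needs equal lengths: miRNA {len(mi)} vs window {len(tg)}"
        )
    if scheme.core_end > len(mi):
        raise ValueError("core_end exceeds miRNA length")
    n = len(mi)
    total = 0.0
    labels: list[str] = []
    for i in range(n):  # i: 0-based miRNA position; 1-based is i+1
        pair = (mi[i], tg[n - 1 - i])
        if pair in _WATSON_CRICK:
            penalty, label = 0.0, "match"
        elif pair in _WOBBLE:
            penalty, label = scheme.wobble_penalty, "wobble"
        else:
            penalty, label = scheme.mismatch_penalty, "mismatch"
        if scheme.core_start <= i + 1 <= scheme.core_end:
            penalty *= scheme.core_multiplier
        total += penalty
        labels.append(label)
    return total, tuple(labels)


def _read_fasta(path_or_handle) -> list[tuple[str, str]]:
    if isinstance(path_or_handle, str) and (
        path_or_handle == "" or path_or_handle.startswith(">") or "\n" in path_or_handle
    ):
        handle = io.StringIO(path_or_handle)
    else:
        handle = path_or_handle
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(handle, "fasta")]


def predict_targets(
    mirnas, transcripts, scheme: ScoringScheme | None = None
) -> list[TargetDuplex]:
    """Slide every miRNA over every transcript and keep good duplexes.

    ``mirnas``/``transcripts`` are FASTA paths, handles, or FASTA text.
    Every window with expectation ≤ ``scheme.max_expectation`` is reported,
    ordered by (miRNA id, transcript id, window start). Transcripts shorter
    than the miRNA are skipped with a warning.
    """
    scheme = scheme or ScoringScheme()
    mi_list = _read_fasta(mirnas)
    tx_list = _read_fasta(transcripts)
    if not mi_list or not tx_list:
        logger.warning("predict_targets: empty FASTA input; no duplexes")
        return []
    out: list[TargetDuplex] = []
    for mid, mseq in sorted(mi_list):
        m = _normalize(mseq, f"miRNA {mid}")
        for tid, tseq in sorted(tx_list):
            t = _normalize(tseq, f"transcript {tid}")
            if len(t) < len(m):
                logger.warning(
                    "transcript %s shorter than miRNA %s; skipped", tid, mid
                )
                continue
            for start in range(len(t) - len(m) + 1):
                exp, labels = score_duplex(m, t[start : start + len(m)], scheme)
                if exp <= scheme.max_expectation:
                    out.append(TargetDuplex(mid, tid, start, exp, labels))
    return out


def best_duplexes(duplexes: list[TargetDuplex]) -> dict[tuple[str, str], TargetDuplex]:
    """Per (miRNA, transcript) minimum-expectation duplex; ties → smallest start."""
    best: dict[tuple[str, str], TargetDuplex] = {}
    for d in duplexes:
        key = (d.mirna_id, d.transcript_id)
        cur = best.get(key)
        if cur is None or (d.expectation, d.window_start) < (
            cur.expectation,
            cur.window_start,
        ):
            best[key] = d
    return best


def mirna_edges(
    duplexes: list[TargetDuplex], gene_map: dict[str, str]
) -> pd.DataFrame:
    """Collapse duplexes to one miRNA→gene edge at the per-gene minimum.

    Transcripts without a gene mapping edge to the transcript id itself
    (with a warning). Columns: mirna, gene, expectation.
    """
    rows: dict[tuple[str, str], float] = {}
    for d in duplexes:
        gene = gene_map.get(d.transcript_id)
        if gene is None:
            logger.warning(
                "transcript %s has no gene mapping; edge kept to transcript id",
                d.transcript_id,
            )
            gene = d.transcript_id
        key = (d.mirna_id, gene)
        if key not in rows or d.expectation < rows[key]:
            rows[key] = d.expectation
    return pd.DataFrame(
        [(m, g, e) for (m, g), e in sorted(rows.items())],
        columns=["mirna", "gene", "expectation"],
    )


def duplexes_to_frame(duplexes: list[TargetDuplex]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (d.mirna_id, d.transcript_id, d.window_start, d.expectation,
             ",".join(d.paired_string))
            for d in duplexes
        ],
        columns=["mirna", "transcript", "window_start", "expectation", "paired"],
    )
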