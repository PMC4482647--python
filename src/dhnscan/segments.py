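"""Conserved dehydrin segment mining.

Dehydrins are defined by a ~15-residue lysine-rich K-segment (consensus
EKKGIMDKIKEKLPG), an optional N-terminal Y-segment (T/VDEYGNP) and an
optional S-segment (a run of three or more serines).  K- and Y-segments are
located with a position-frequency-matrix log-odds scan seeded from known
segment sequences; the scan is iterated, each round adding newly found
segment variants to the seed pool and rebuilding the PFM, until the pool
stops growing.  S-segments are located with a maximal-run pattern match.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .pfm import AA_ALPHABET, PositionFrequencyMatrix, build_pfm

K_SEGMENT_CONSENSUS = "EKKGIMDKIKEKLPG"
Y_SEGMENT_CONSENSUS = ("TDEYGNP", "VDEYGNP")

DEFAULT_PSEUDOCOUNT = 0.5
DEFAULT_MIN_RELATIVE_SCORE = 0.7

#: Default scanning background: uniform over the 20 residues.  Scoring
#: against a uniform background keeps the per-column log-odds argmax equal
#: to the count argmax, so the consensus word is the maximum-scoring window
#: and relative scores stay in (-inf, 1].  (Against a skewed composition the
#: "best" window would be a string of rare residues, which distorts the
#: relative-score threshold.)
UNIFORM_AA_BACKGROUND = {aa: 1.0 / len(AA_ALPHABET) for aa in AA_ALPHABET}


@dataclass(frozen=True)
class SegmentHit:
    """A located segment instance: 0-based half-open residue coordinates,
    log-odds score in bits, and the min-max scaled relative score
    (score - min) / (max - min) in [0, 1], the usual relative score of PWM
    scanning toolkits.  The per-column argmax word scores exactly 1."""

    sequence_id: str
    start: int
    end: int
    score: float
    relative_score: float
    kind: str  # K, Y or S

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError("invalid hit coordinates")
        if self.kind not in ("K", "Y", "S"):
            raise ValueError(f"unknown segment kind {self.kind!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


def _encode(protein: str, alphabet: str = AA_ALPHABET) -> np.ndarray:
    """Residues as alphabet indices; unknown residues become -1."""
    table = np.full(128, -1, dtype=np.int64)
    for i, sym in enumerate(alphabet):
        table[ord(sym)] = i
    arr = np.frombuffer(protein.upper().encode("ascii"), dtype=np.uint8)
    return table[arr]


def log_odds_score(
    pfm: PositionFrequencyMatrix,
    window: str,
    background: Mapping[str, float] | None = None,
) -> float:
    """Sum over columns of log2(smoothed column frequency / background)."""
    if len(window) != len(pfm):
        raise ValueError("window length must equal PFM length")
    background = dict(background) if background else dict(UNIFORM_AA_BACKGROUND)
    lo = pfm.log_odds(background)
    idx = _encode(window, pfm.alphabet)
    if np.any(idx < 0):
        raise ValueError("window contains symbols outside the PFM alphabet")
    return float(lo[np.arange(len(pfm)), idx].sum())


def scan_sequence(
    pfm: PositionFrequencyMatrix,
    protein: str,
    min_relative_score: float = DEFAULT_MIN_RELATIVE_SCORE,
    background: Mapping[str, float] | None = None,
    sequence_id: str = "",
    kind: str | None = None,
) -> list[SegmentHit]:
    """All windows whose min-max scaled score reaches
    ``min_relative_score``, sorted by start.  Overlapping hits are all
    reported; non-overlap resolution is the classifier's job."""
    if not (0 < min_relative_score <= 1):
        raise ValueError("min_relative_score must be in (0, 1]")
    background = dict(background) if background else dict(UNIFORM_AA_BACKGROUND)
    L = len(pfm)
    if len(protein) < L:
        return []
    lo = pfm.log_odds(background)
    max_score = float(lo.max(axis=1).sum())
    min_score = float(lo.min(axis=1).sum())
    if max_score <= min_score:
        raise ValueError("degenerate PFM: all windows score identically")
    idx = _encode(protein, pfm.alphabet)
    # accumulate window scores column by column (L is small); windows that
    # contain unknown residues never match
    n_windows = len(protein) - L + 1
    scores = np.zeros(n_windows)
    valid = np.ones(n_windows, dtype=bool)
    for j in range(L):
        col_idx = idx[j : j + n_windows]
        ok = col_idx >= 0
        valid &= ok
        scores[ok] += lo[j, col_idx[ok]]
    scores[~valid] = -np.inf
    rel = (scores - min_score) / (max_score - min_score)
    hits = [
        SegmentHit(
            sequence_id=sequence_id,
            start=int(i),
            end=int(i) + L,
            score=float(scores[i]),
            relative_score=float(rel[i]),
            kind=kind or (pfm.kind_tag or "K"),
        )
        for i in np.nonzero(rel >= min_relative_score - 1e-12)[0]
    ]
    return hits


def find_s_segments(
    protein: str, min_run: int = 3, sequence_id: str = ""
) -> list[SegmentHit]:
    """Maximal runs of at least ``min_run`` consecutive serines.  The score
    is the run length (the natural precedence weight for an S hit)."""
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    hits = []
    for m in re.finditer("S{%d,}" % min_run, protein.upper()):
        hits.append(
            SegmentHit(
                sequence_id=sequence_id,
                start=m.start(),
                end=m.end(),
                score=float(m.end() - m.start()),
                relative_score=1.0,
                kind="S",
            )
        )
    return hits


def iterative_expand(
    seed_set: Iterable[str],
    proteomes: Mapping[str, str],
    min_relative_score: float = DEFAULT_MIN_RELATIVE_SCORE,
    max_rounds: int = 10,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    background: Mapping[str, float] | None = None,
    kind: str = "K",
) -> tuple[PositionFrequencyMatrix, list[SegmentHit], list[int]]:
    """Iterative seed augmentation: rebuild the PFM from the (deduplicated)
    seed pool, scan every protein, add hit substrings not yet in the pool;
    stop when a round adds nothing new or ``max_rounds`` is reached.

    Returns the converged PFM, the final hit set, and the number of new
    seeds added per round (the audit trail).
    """
    if max_rounds < 1:
        raise ValueError("max_rounds must be >= 1")
    if not proteomes:
        raise ValueError("empty proteome collection")
    background = dict(background) if background else dict(UNIFORM_AA_BACKGROUND)
    pool: list[str] = []
    seen: set[str] = set()
    for s in seed_set:
        if s not in seen:
            pool.append(s)
            seen.add(s)
    if not pool:
        raise ValueError("empty seed set")

    new_per_round: list[int] = []
    pfm = build_pfm(pool, pseudocount, kind_tag=kind)
    hits: list[SegmentHit] = []
    for _ in range(max_rounds):
        pfm = build_pfm(pool, pseudocount, kind_tag=kind)
        hits = []
        for seq_id in sorted(proteomes):
            hits.extend(
                scan_sequence(
                    pfm,
                    proteomes[seq_id],
                    min_relative_score,
                    background,
                    sequence_id=seq_id,
                    kind=kind,
                )
            )
        added = 0
        for hit in hits:
            sub = proteomes[hit.sequence_id][hit.start : hit.end].upper()
            if sub not in seen:
                pool.append(sub)
                seen.add(sub)
                added += 1
        new_per_round.append(added)
        if added == 0:
            break
    return pfm, hits, new_per_round


def hits_to_tsv(hits: Iterable[SegmentHit]) -> str:
    lines = ["sequence_id\tstart\tend\tkind\tscore\trelative_score"]
    for h in hits:
        lines.append(
            f"{h.sequence_id}\t{h.start}\t{h.end}\t{h.kind}"
            f"\t{h.score:.4f}\t{h.relative_score:.4f}"
        )
    return "\n".join(lines) + "\n"
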