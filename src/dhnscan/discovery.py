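"""Word-based de novo motif discovery in promoter sets.

For every k-mer (k in a configurable range) present in at least two
foreground promoters, the promoter-presence count in the foreground is
tested against the presence rate in a large background promoter pool with a
binomial upper tail (the background rate is Laplace-smoothed), and the
resulting p-values are Benjamini-Hochberg adjusted jointly across all
tested words.  Words and their reverse complements are canonicalised to one
strand before testing, matching the convention of counting a promoter once
whether the element sits on either strand.  Significant words are extended
into a position frequency matrix from their flanked foreground occurrences
and summarised with an IUPAC consensus and an occurrence fraction n/N.

This module is a self-contained word-enumeration discovery method; its
reports are not MEME/Seeder/Weeder output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .pfm import DNA_ALPHABET, PositionFrequencyMatrix, iupac_consensus
from .simulate import reverse_complement

_BASE_INDEX = np.full(128, -1, dtype=np.int64)
for _i, _b in enumerate(DNA_ALPHABET):
    _BASE_INDEX[ord(_b)] = _i
    _BASE_INDEX[ord(_b.lower())] = _i


@dataclass
class MotifModel:
    """One discovered motif: enriched seed word, occurrence PFM built from
    flanked occurrences, IUPAC consensus, occurrence n/N and q-value."""

    seed_word: str
    n_with: int
    n_total: int
    bg_with: int
    bg_total: int
    p_value: float
    q_value: float = float("nan")
    pfm: PositionFrequencyMatrix | None = None
    consensus_iupac: str = ""
    strand_policy: str = "both"
    enrichment: float = field(default=float("nan"))

    @property
    def occurrence(self) -> str:
        return f"{self.n_with}/{self.n_total}"


def canonical_word(word: str) -> str:
    """Lexicographically smaller of a word and its reverse complement."""
    rc = reverse_complement(word)
    return word if word <= rc else rc


def _encode_seq(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _BASE_INDEX[arr & 0x7F]


def _canonical_kmer_codes(seq: str, k: int) -> np.ndarray:
    """Sorted unique canonical k-mer codes present in one sequence.
    Windows containing non-ACGT symbols are skipped."""
    digits = _encode_seq(seq)
    if len(digits) < k:
        return np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(digits, k)
    valid = (win >= 0).all(axis=1)
    win = win[valid]
    if not len(win):
        return np.empty(0, dtype=np.int64)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    codes = win @ powers
    rc_codes = (3 - win) @ powers[::-1]
    return np.unique(np.minimum(codes, rc_codes))


def _decode(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(DNA_ALPHABET[code & 3])
        code >>= 2
    return "".join(reversed(out))


def _presence_counts(seqs: Sequence[str], k: int) -> dict[int, int]:
    """Canonical k-mer code -> number of sequences containing it."""
    chunks = [_canonical_kmer_codes(s, k) for s in seqs]
    chunks = [c for c in chunks if len(c)]
    if not chunks:
        return {}
    codes, counts = np.unique(np.concatenate(chunks), return_counts=True)
    return dict(zip(codes.tolist(), counts.tolist()))


def promoters_containing(
    word: str, promoters: Sequence[str], both_strands: bool = True
) -> int:
    """Number of promoters with at least one exact occurrence of the word
    (or, if requested, its reverse complement); each promoter counts once."""
    word = word.upper()
    if not word or any(c not in DNA_ALPHABET for c in word):
        raise ValueError("word must be a non-empty A/C/G/T string")
    if not promoters:
        raise ValueError("empty promoter set")
    rc = reverse_complement(word)
    count = 0
    for seq in promoters:
        s = seq.upper()
        if word in s or (both_strands and rc in s):
            count += 1
    return count


def binomial_upper_tail(observed: int, n: int, p0: float) -> float:
    """P(X >= observed) for X ~ Binomial(n, p0)."""
    if not (0 <= observed <= n):
        raise ValueError("observed must be in [0, n]")
    return float(stats.binom.sf(observed - 1, n, p0))


def bh_qvalues(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up, clipped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    if m == 0:
        return np.empty(0)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(ranked, 1.0)
    return q


def _chance_presence(word: str, base_freqs: dict[str, float], mean_length: float) -> float:
    """Probability that a promoter of the given mean length contains the
    word on either strand under a zero-order background model (Poisson
    approximation over window starts)."""
    p_fwd = 1.0
    p_rev = 1.0
    for b in word:
        p_fwd *= base_freqs[b]
        p_rev *= base_freqs[reverse_complement(b)]
    rate = max(0.0, mean_length - len(word) + 1)
    lam = rate * (p_fwd + (p_rev if reverse_complement(word) != word else 0.0))
    return float(1.0 - np.exp(-lam))


def enrich_words(
    foreground: Sequence[str],
    background: Sequence[str],
    k_min: int = 6,
    k_max: int = 10,
    q_max: float = 0.01,
    min_foreground_promoters: int = 2,
) -> list[MotifModel]:
    """Overrepresented canonical k-mers in the foreground promoters.

    The null presence rate is the Laplace-smoothed background rate
    p0 = (b + 1) / (B + 2), floored by the zero-order-composition chance
    presence probability (the analogue of the background sequence model of
    de novo discovery tools; without the floor, a long word absent from the
    background gets an unrealistically small p0, and words selected for
    foreground presence leak through as false discoveries).  The foreground
    presence count is tested with a binomial upper tail; Benjamini-Hochberg
    runs jointly over every tested word of every k; words with
    q <= ``q_max`` are returned ranked by q, then by observed/expected
    ratio (descending), then by word.
    """
    if not foreground or not background:
        raise ValueError("foreground and background must be non-empty")
    if len(foreground) < 2:
        raise ValueError("foreground must contain at least 2 promoters")
    if k_min > k_max or k_min < 1:
        raise ValueError("require 1 <= k_min <= k_max")
    n_fg = len(foreground)
    n_bg = len(background)
    mean_length = float(np.mean([len(s) for s in background]))
    counts = {b: 1.0 for b in DNA_ALPHABET}  # +1 smoothing
    for seq in background:
        s = seq.upper()
        for b in DNA_ALPHABET:
            counts[b] += s.count(b)
    total = sum(counts.values())
    base_freqs = {b: c / total for b, c in counts.items()}

    candidates: list[tuple[str, int, int]] = []  # (word, fg_count, bg_count)
    for k in range(k_min, k_max + 1):
        fg_counts = _presence_counts(foreground, k)
        if not fg_counts:
            continue
        bg_counts = _presence_counts(background, k)
        for code, n_with in fg_counts.items():
            if n_with >= min_foreground_promoters:
                candidates.append(
                    (_decode(code, k), n_with, bg_counts.get(code, 0))
                )

    if not candidates:
        return []

    def null_rate(word: str, b: int) -> float:
        return max(
            (b + 1) / (n_bg + 2), _chance_presence(word, base_freqs, mean_length)
        )

    pvals = np.array(
        [
            binomial_upper_tail(n_with, n_fg, null_rate(word, b))
            for word, n_with, b in candidates
        ]
    )
    qvals = bh_qvalues(pvals)
    motifs = []
    for (word, n_with, b), p, q in zip(candidates, pvals, qvals):
        if q <= q_max:
            p0 = null_rate(word, b)
            motifs.append(
                MotifModel(
                    seed_word=word,
                    n_with=n_with,
                    n_total=n_fg,
                    bg_with=b,
                    bg_total=n_bg,
                    p_value=float(p),
                    q_value=float(q),
                    enrichment=n_with / (n_fg * p0),
                )
            )
    motifs.sort(key=lambda m: (m.q_value, -m.enrichment, m.seed_word))
    return motifs


def extend_to_pfm(
    word: str,
    foreground: Sequence[str],
    flank: int = 2,
    motif: MotifModel | None = None,
) -> MotifModel:
    """Build the occurrence PFM of an enriched word from all its foreground
    occurrences plus ``flank`` bp of context on each side.

    Minus-strand occurrences are reverse-complemented into the word's
    orientation; occurrences at promoter edges contribute N padding that is
    excluded column-wise from the tallies.
    """
    word = word.upper()
    rc = reverse_complement(word)
    k = len(word)
    width = k + 2 * flank
    counts = np.zeros((width, 4))
    n_occ = 0
    contained = 0
    for seq in foreground:
        s = seq.upper()
        found = False
        for target, is_rc in ((word, False), (rc, True)) if rc != word else ((word, False),):
            start = s.find(target)
            while start != -1:
                found = True
                left = start - flank
                right = start + k + flank
                window = (
                    "N" * max(0, -left)
                    + s[max(0, left) : min(len(s), right)]
                    + "N" * max(0, right - len(s))
                )
                if is_rc:
                    window = reverse_complement(window)
                for j, base in enumerate(window):
                    idx = _BASE_INDEX[ord(base) & 0x7F]
                    if idx >= 0:
                        counts[j, idx] += 1.0
                n_occ += 1
                start = s.find(target, start + 1)
        if found:
            contained += 1
    if n_occ == 0:
        raise ValueError(f"word {word!r} has no occurrence in the foreground")
    # drop flank columns with no observation at all (every occurrence sat at
    # a promoter edge there)
    covered = np.nonzero(counts.sum(axis=1) > 0)[0]
    counts = counts[covered[0] : covered[-1] + 1]
    pfm = PositionFrequencyMatrix(
        alphabet=DNA_ALPHABET, counts=counts, n_seeds=n_occ, pseudocount=0.0,
        kind_tag=word,
    )
    out = motif or MotifModel(
        seed_word=word,
        n_with=contained,
        n_total=len(foreground),
        bg_with=0,
        bg_total=0,
        p_value=float("nan"),
    )
    out.n_with = contained
    out.n_total = len(foreground)
    out.pfm = pfm
    out.consensus_iupac = iupac_consensus(pfm)
    return out


def collapse_redundant(motifs: Sequence[MotifModel]) -> list[MotifModel]:
    """Drop motifs whose seed word is a substring, superstring, or
    shift-by-<=2 overlap (>= 5 identical shared bases) of a better-ranked
    motif's seed, on either strand."""

    def related(a: str, b: str) -> bool:
        for bb in {b, reverse_complement(b)}:
            if bb in a or a in bb:
                return True
            for shift in range(-2, 3):
                # positions of bb relative to a
                lo = max(0, shift)
                hi = min(len(a), shift + len(bb))
                if hi - lo >= 5 and a[lo:hi] == bb[lo - shift : hi - shift]:
                    return True
        return False

    kept: list[MotifModel] = []
    for m in motifs:
        if not any(related(k.seed_word, m.seed_word) for k in kept):
            kept.append(m)
    return kept


def discover_motifs(
    foreground: Sequence[str],
    background: Sequence[str],
    k_min: int = 6,
    k_max: int = 10,
    q_max: float = 0.01,
    flank: int = 2,
    max_motifs: int = 10,
) -> list[MotifModel]:
    """Full discovery pass: enrich, collapse redundant words, extend each
    survivor to a PFM with consensus and occurrence counts."""
    enriched = enrich_words(foreground, background, k_min, k_max, q_max)
    collapsed = collapse_redundant(enriched)[:max_motifs]
    return [extend_to_pfm(m.seed_word, foreground, flank, motif=m) for m in collapsed]


def motifs_to_tsv(motifs: Iterable[MotifModel]) -> str:
    lines = ["seed_word\tconsensus\toccurrence\tq_value\tp_value\tenrichment"]
    for m in motifs:
        lines.append(
            f"{m.seed_word}\t{m.consensus_iupac or m.seed_word}\t{m.occurrence}"
            f"\t{m.q_value:.3g}\t{m.p_value:.3g}\t{m.enrichment:.3g}"
        )
    return "\n".join(lines) + "\n"
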