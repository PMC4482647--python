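"""Dehydrin architecture resolution and five-class assignment.

A protein's raw segment hits (possibly overlapping) are resolved greedily by
score into one ordered, disjoint architecture, and the ordered string of
segment kinds is mapped onto the five dehydrin classes: K_n, KS, SK_n,
Y_nK_n and Y_nSK_n.  A dehydrin must contain a K-segment; architectures
whose segment order fits none of the class grammars (for example a Y after
a K, or an S interleaved between K's) are reported as unclassified rather
than forced into a class.

Doubtful candidates (the short KS proteins in particular) can be compared
with a reference dehydrin by Needleman-Wunsch global alignment with affine
gap penalties, reporting percent identity and percent similarity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio.Align import substitution_matrices

from .segments import SegmentHit

CLASS_LABELS = ("K_n", "KS", "SK_n", "Y_nK_n", "Y_nSK_n", "unclassified")

_KIND_RANK = {"K": 0, "Y": 1, "S": 2}  # tie-break precedence K > Y > S


@dataclass(frozen=True)
class SegmentArchitecture:
    """Ordered, pairwise disjoint segment hits of one protein."""

    ordered_segments: tuple[SegmentHit, ...]

    def __post_init__(self) -> None:
        segs = self.ordered_segments
        for a, b in zip(segs, segs[1:]):
            if a.end > b.start:
                raise ValueError("architecture segments must be sorted and disjoint")

    @property
    def kinds(self) -> str:
        return "".join(s.kind for s in self.ordered_segments)

    @property
    def counts(self) -> tuple[int, int, int]:
        """(nY, nS, nK)"""
        k = self.kinds
        return k.count("Y"), k.count("S"), k.count("K")


@dataclass(frozen=True)
class DehydrinRecord:
    sequence_id: str
    architecture: SegmentArchitecture
    class_label: str
    formula: str

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {self.class_label!r}")
        if self.class_label != "unclassified" and self.architecture.counts[2] < 1:
            raise ValueError("a classified dehydrin must contain a K-segment")

    @property
    def is_dehydrin(self) -> bool:
        return self.class_label != "unclassified"


def resolve_overlaps(hits: Sequence[SegmentHit]) -> SegmentArchitecture:
    """Greedy non-overlap selection: descending score, ties broken by
    leftmost start, then by kind precedence K > Y > S."""
    ids = {h.sequence_id for h in hits}
    if len(ids) > 1:
        raise ValueError("hits reference multiple sequences")
    ranked = sorted(hits, key=lambda h: (-h.score, h.start, _KIND_RANK[h.kind]))
    kept: list[SegmentHit] = []
    for hit in ranked:
        if all(hit.end <= k.start or hit.start >= k.end for k in kept):
            kept.append(hit)
    kept.sort(key=lambda h: h.start)
    return SegmentArchitecture(tuple(kept))


def classify_kinds(kinds: str) -> str:
    """Class label for an ordered segment-kind string (e.g. ``"YYSKK"``)."""
    if any(c not in "KYS" for c in kinds):
        raise ValueError(f"illegal kind string {kinds!r}")
    n_y, n_s, n_k = kinds.count("Y"), kinds.count("S"), kinds.count("K")
    if n_k == 0:
        return "unclassified"
    if n_y == 0 and n_s == 0:
        return "K_n"
    if n_y == 0:
        if kinds == "K" * n_k + "S" * n_s:
            return "KS"
        if kinds == "S" * n_s + "K" * n_k:
            return "SK_n"
        return "unclassified"
    if n_s == 0:
        if kinds == "Y" * n_y + "K" * n_k:
            return "Y_nK_n"
        return "unclassified"
    if kinds == "Y" * n_y + "S" * n_s + "K" * n_k:
        return "Y_nSK_n"
    return "unclassified"


def _formula(label: str, n_y: int, n_s: int, n_k: int) -> str:
    # Multiple S runs are not encoded in the class name: print a bare "S".
    if label == "K_n":
        return f"K{n_k}"
    if label == "KS":
        return f"K{n_k}S"
    if label == "SK_n":
        return f"SK{n_k}"
    if label == "Y_nK_n":
        return f"Y{n_y}K{n_k}"
    if label == "Y_nSK_n":
        return f"Y{n_y}SK{n_k}"
    return ""


def classify(architecture: SegmentArchitecture, sequence_id: str = "") -> DehydrinRecord:
    """Assign one of the five dehydrin classes (or unclassified) to a
    resolved architecture.  Pure function of the ordered kind string."""
    label = classify_kinds(architecture.kinds)
    n_y, n_s, n_k = architecture.counts
    seq_id = sequence_id or (
        architecture.ordered_segments[0].sequence_id
        if architecture.ordered_segments
        else ""
    )
    return DehydrinRecord(
        sequence_id=seq_id,
        architecture=architecture,
        class_label=label,
        formula=_formula(label, n_y, n_s, n_k),
    )


def classify_hits(hits: Sequence[SegmentHit], sequence_id: str = "") -> DehydrinRecord:
    return classify(resolve_overlaps(hits), sequence_id=sequence_id)


# ---------------------------------------------------------------------------
# Pairwise alignment validation


def _gotoh_global(a, b, matrix, gap_open, gap_extend):
    """Global affine-gap alignment (Gotoh), end gaps penalised.

    A gap of length L costs gap_open + (L-1) * gap_extend.  Traceback
    tie-break: diagonal, then gap in the second sequence, then gap in the
    first.  Returns (score, aligned_a, aligned_b).
    """
    n, m = len(a), len(b)
    NEG = float("-inf")
    # M: a[i] aligned to b[j]; X: gap in b (consumes a); Y: gap in a
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -gap_open - (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0][j] = -gap_open - (j - 1) * gap_extend
    for i in range(1, n + 1):
        ai = a[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        Mp, Xp, Yp = M[i - 1], X[i - 1], Y[i - 1]
        for j in range(1, m + 1):
            s = matrix[ai, b[j - 1]]
            Mi[j] = max(Mp[j - 1], Xp[j - 1], Yp[j - 1]) + s
            Xi[j] = max(Mp[j] - gap_open, Xp[j] - gap_extend, Yp[j] - gap_open)
            Yi[j] = max(Mi[j - 1] - gap_open, Yi[j - 1] - gap_extend, Xi[j - 1] - gap_open)
    score = max(M[n][m], X[n][m], Y[n][m])

    # traceback
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    if M[n][m] >= X[n][m] and M[n][m] >= Y[n][m]:
        state = "M"
    elif X[n][m] >= Y[n][m]:
        state = "X"
    else:
        state = "Y"
    eps = 1e-9
    while i > 0 or j > 0:
        if state == "M":
            s = matrix[a[i - 1], b[j - 1]]
            prev = M[i][j] - s
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            if abs(M[i][j] - prev) < eps:
                state = "M"
            elif abs(X[i][j] - prev) < eps:
                state = "X"
            else:
                state = "Y"
        elif state == "X":
            out_a.append(a[i - 1])
            out_b.append("-")
            val = X[i][j]
            i -= 1
            if i == 0 and j == 0:
                break
            if abs(M[i][j] - gap_open - val) < eps:
                state = "M"
            elif abs(X[i][j] - gap_extend - val) < eps:
                state = "X"
            else:
                state = "Y"
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            val = Y[i][j]
            j -= 1
            if j == 0 and i == 0:
                break
            if abs(M[i][j] - gap_open - val) < eps:
                state = "M"
            elif abs(Y[i][j] - gap_extend - val) < eps:
                state = "Y"
            else:
                state = "X"
    return score, "".join(reversed(out_a)), "".join(reversed(out_b))


def validate_similarity(
    candidate: str,
    reference: str,
    substitution_matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> tuple[float, float]:
    """Percent identity and percent similarity of the global alignment of two
    proteins (identity: identical aligned pairs / alignment length;
    similarity: aligned pairs with a positive substitution score / alignment
    length)."""
    score, aln_a, aln_b = align_global(
        candidate, reference, substitution_matrix, gap_open, gap_extend
    )
    matrix = substitution_matrices.load(substitution_matrix)
    length = len(aln_a)
    ident = sum(1 for x, y in zip(aln_a, aln_b) if x == y and x != "-")
    similar = sum(
        1
        for x, y in zip(aln_a, aln_b)
        if x != "-" and y != "-" and matrix[x, y] > 0
    )
    return 100.0 * ident / length, 100.0 * similar / length


def align_global(
    candidate: str,
    reference: str,
    substitution_matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> tuple[float, str, str]:
    """Global alignment returning (score, gapped candidate, gapped reference)."""
    if not candidate or not reference:
        raise ValueError("both sequences must be non-empty")
    try:
        matrix = substitution_matrices.load(substitution_matrix)
    except FileNotFoundError:
        raise ValueError(f"unknown substitution matrix {substitution_matrix!r}") from None
    return _gotoh_global(
        candidate.upper(), reference.upper(), matrix, float(gap_open), float(gap_extend)
    )


def records_to_tsv(records: Iterable[DehydrinRecord]) -> str:
    lines = ["sequence_id\tclass\tformula\tsegments"]
    for r in records:
        segs = ";".join(
            f"{s.kind}:{s.start}-{s.end}" for s in r.architecture.ordered_segments
        )
        lines.append(f"{r.sequence_id}\t{r.class_label}\t{r.formula}\t{segs}")
    return "\n".join(lines) + "\n"
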