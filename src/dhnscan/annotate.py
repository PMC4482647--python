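"""Annotation of discovered motifs against a known-element library.

Discovered position frequency matrices are aligned to the bundled library
of named plant cis-regulatory elements (I-box, DRE/CRT, ABREs, ...) by
ungapped PFM-PFM alignment: the score of an offset is the mean per-column
Pearson correlation of the frequency vectors over the overlap, maximised
over offsets and both orientations.  Match significance is empirical: the
query's columns are shuffled many times and the element's p-value is the
fraction of shuffles scoring at least as well, scaled by library size into
an E-value.  Similar motifs are grouped by UPGMA on alignment-score
distances and one representative per cluster is reported.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .discovery import MotifModel
from .pfm import PositionFrequencyMatrix, iupac_to_pfm
from .resources import KnownElement, load_element_library

DEFAULT_MIN_OVERLAP = 5


@dataclass(frozen=True)
class PFMAlignment:
    query_id: str
    target_name: str
    offset: int  # position of query column 0 relative to target column 0
    orientation: str  # 'forward' or 'revcomp' (query orientation)
    column_scores: tuple[float, ...]
    total_score: float  # mean per-column Pearson correlation over the overlap
    p_value: float = float("nan")
    e_value: float = float("nan")


def _standardise(pfm: PositionFrequencyMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-column z-scored frequency vectors (rows), plus a mask of
    zero-variance (uninformative) columns."""
    freq = pfm.frequencies
    mean = freq.mean(axis=1, keepdims=True)
    std = freq.std(axis=1, keepdims=True)
    constant = std[:, 0] < 1e-12
    std = np.where(std < 1e-12, 1.0, std)
    z = (freq - mean) / std
    z[constant] = 0.0
    return z, constant


def _column_correlations(
    query: PositionFrequencyMatrix, target: PositionFrequencyMatrix
) -> np.ndarray:
    """Pearson correlation of every query column against every target column.
    A pair of identical uninformative columns scores 1, otherwise an
    uninformative column scores 0 against everything."""
    zq, cq = _standardise(query)
    zt, ct = _standardise(target)
    corr = (zq @ zt.T) / zq.shape[1]
    if cq.any() and ct.any():
        fq, ft = query.frequencies, target.frequencies
        for i in np.nonzero(cq)[0]:
            for j in np.nonzero(ct)[0]:
                if np.allclose(fq[i], ft[j]):
                    corr[i, j] = 1.0
    return corr


def _permuted_column_correlations(
    query: PositionFrequencyMatrix,
    target: PositionFrequencyMatrix,
    base_perms: np.ndarray,
) -> np.ndarray:
    """Correlations of every query column under every base-identity
    permutation against every target column: shape (Lq, n_perms, Lt)."""
    fq = query.frequencies  # (Lq, 4)
    ft = target.frequencies
    fq_perm = fq[:, base_perms]  # (Lq, P, 4)
    mean = fq_perm.mean(axis=2, keepdims=True)
    std = fq_perm.std(axis=2, keepdims=True)
    const_q = std[..., 0] < 1e-12  # (Lq, P)
    zq = (fq_perm - mean) / np.where(std < 1e-12, 1.0, std)
    zq[const_q] = 0.0
    zt, const_t = _standardise(target)
    corr = np.einsum("ipb,jb->ipj", zq, zt) / 4.0
    if const_q.any() and const_t.any():
        for i, p in zip(*np.nonzero(const_q)):
            for j in np.nonzero(const_t)[0]:
                if np.allclose(fq_perm[i, p], ft[j]):
                    corr[i, p, j] = 1.0
    return corr


def _offset_scores(corr: np.ndarray, min_overlap: int) -> list[tuple[int, np.ndarray]]:
    """(offset, per-column scores) for every offset with enough overlap."""
    lq, lt = corr.shape
    out = []
    for offset in range(-(lq - min_overlap), lt - min_overlap + 1):
        q0 = max(0, -offset)
        t0 = max(0, offset)
        ov = min(lq - q0, lt - t0)
        if ov >= min_overlap:
            cols = corr[np.arange(q0, q0 + ov), np.arange(t0, t0 + ov)]
            out.append((offset, cols))
    return out


def align_pfms(
    query: PositionFrequencyMatrix,
    target: PositionFrequencyMatrix,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    query_id: str = "query",
    target_name: str = "target",
) -> PFMAlignment:
    """Best ungapped alignment of two nucleotide PFMs over all offsets and
    both orientations; ties break to the smaller |offset|, then forward."""
    if len(query) < min_overlap or len(target) < min_overlap:
        raise ValueError("both PFMs must span at least the minimum overlap")
    best: PFMAlignment | None = None
    for orientation, q in (("forward", query), ("revcomp", query.reverse_complement())):
        corr = _column_correlations(q, target)
        for offset, cols in _offset_scores(corr, min_overlap):
            score = float(cols.mean())
            cand = PFMAlignment(
                query_id=query_id,
                target_name=target_name,
                offset=offset,
                orientation=orientation,
                column_scores=tuple(round(c, 6) for c in cols),
                total_score=score,
            )
            if (
                best is None
                or score > best.total_score + 1e-12
                or (
                    abs(score - best.total_score) <= 1e-12
                    and (
                        abs(offset) < abs(best.offset)
                        or (
                            abs(offset) == abs(best.offset)
                            and orientation == "forward"
                            and best.orientation == "revcomp"
                        )
                    )
                )
            ):
                best = cand
    assert best is not None
    return best


def match_library(
    query: PositionFrequencyMatrix,
    library: Sequence[KnownElement] | None = None,
    n_null: int = 1000,
    seed: int = 0,
    e_max: float = 0.05,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    query_id: str = "query",
) -> list[PFMAlignment]:
    """Significant known-element matches of a query PFM.

    Each element's null distribution comes from ``n_null`` randomised
    replicas of the query: the column order is shuffled and, within every
    column, the base identities are permuted.  This preserves each column's
    information content while destroying both the column arrangement and
    the base composition, i.e. the replica is an unrelated motif of the
    same complexity (a plain column-order shuffle keeps the exact columns,
    so any replica containing a perfect few-column run ties the true match
    and the empirical p-value can never reach the significance gate).
    p = (1 + #null >= observed) / (1 + n_null) and E = p * library size.
    Matches with E <= ``e_max`` are returned ranked by E-value.
    """
    library = list(library) if library is not None else list(load_element_library())
    if not library:
        raise ValueError("empty element library")
    rng = np.random.default_rng(seed)
    lq = len(query)
    perms = np.stack([rng.permutation(lq) for _ in range(n_null)])
    # per null column: one of the 24 base-identity permutations
    base_perms = np.array(list(itertools.permutations(range(4))))
    sigma = rng.integers(0, len(base_perms), size=(n_null, lq))
    matches = []
    for element in library:
        target = iupac_to_pfm(element.consensus_iupac, kind_tag=element.name)
        if lq < min_overlap or len(target) < min_overlap:
            continue
        observed = align_pfms(
            query, target, min_overlap, query_id=query_id, target_name=element.name
        )
        null_best = np.full(n_null, -np.inf)
        for q in (query, query.reverse_complement()):
            corr = _permuted_column_correlations(q, target, base_perms)
            lq_, lt = corr.shape[0], corr.shape[2]
            for offset in range(-(lq_ - min_overlap), lt - min_overlap + 1):
                q0 = max(0, -offset)
                t0 = max(0, offset)
                ov = min(lq_ - q0, lt - t0)
                if ov < min_overlap:
                    continue
                rows = perms[:, q0 : q0 + ov]
                sig = sigma[:, q0 : q0 + ov]
                cols = np.arange(t0, t0 + ov)
                scores = corr[rows, sig, cols].mean(axis=1)
                np.maximum(null_best, scores, out=null_best)
        p = (1.0 + np.sum(null_best >= observed.total_score - 1e-12)) / (1.0 + n_null)
        e = p * len(library)
        if e <= e_max:
            matches.append(
                PFMAlignment(
                    query_id=observed.query_id,
                    target_name=observed.target_name,
                    offset=observed.offset,
                    orientation=observed.orientation,
                    column_scores=observed.column_scores,
                    total_score=observed.total_score,
                    p_value=float(p),
                    e_value=float(e),
                )
            )
    matches.sort(key=lambda m: (m.e_value, -m.total_score, m.target_name))
    return matches


def motif_distance(
    a: PositionFrequencyMatrix,
    b: PositionFrequencyMatrix,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> float:
    """1 - best alignment score clipped to [0, 1]; 1.0 when no alignment
    reaches the minimum overlap."""
    try:
        best = align_pfms(a, b, min_overlap)
    except ValueError:
        return 1.0
    if len(a) < min_overlap or len(b) < min_overlap:
        return 1.0
    return float(1.0 - max(0.0, min(1.0, best.total_score)))


def cluster_motifs(
    motifs: Sequence[MotifModel | PositionFrequencyMatrix],
    cut_distance: float = 0.25,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> tuple[np.ndarray | None, np.ndarray, list[int]]:
    """UPGMA clustering of motifs on alignment-score distances.

    Returns (linkage matrix, cluster label per motif, representative index
    per cluster).  The representative minimises the summed within-cluster
    distance, ties broken by the most significant q-value, then input order.
    A single motif passes through as its own cluster.
    """
    pfms = [m.pfm if isinstance(m, MotifModel) else m for m in motifs]
    if any(p is None for p in pfms):
        raise ValueError("every motif needs a PFM")
    n = len(pfms)
    if n == 0:
        raise ValueError("no motifs to cluster")
    if n == 1:
        return None, np.array([1]), [0]
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = motif_distance(pfms[i], pfms[j], min_overlap)
            dist[i, j] = dist[j, i] = d
    linkage = hierarchy.linkage(squareform(dist, checks=False), method="average")
    labels = hierarchy.fcluster(linkage, t=cut_distance, criterion="distance")
    representatives = []
    for cluster in sorted(set(labels)):
        members = np.nonzero(labels == cluster)[0]
        sums = dist[np.ix_(members, members)].sum(axis=1)
        best_order = sorted(
            range(len(members)),
            key=lambda idx: (
                sums[idx],
                motifs[members[idx]].q_value
                if isinstance(motifs[members[idx]], MotifModel)
                else 0.0,
                idx,
            ),
        )
        representatives.append(int(members[best_order[0]]))
    return linkage, labels, representatives


def annotation_report_tsv(
    motifs: Sequence[MotifModel],
    annotations: Sequence[Sequence[PFMAlignment]],
) -> str:
    """Class-table style report: one row per (motif, library match)."""
    lines = ["consensus\toccurrence\tq_value\telement\telement_e_value\tfunction"]
    library = {e.name: e for e in load_element_library()}
    for motif, matches in zip(motifs, annotations):
        if not matches:
            lines.append(
                f"{motif.consensus_iupac or motif.seed_word}\t{motif.occurrence}"
                f"\t{motif.q_value:.3g}\t-\t-\t-"
            )
        for match in matches:
            note = library[match.target_name].function_note if match.target_name in library else ""
            lines.append(
                f"{motif.consensus_iupac or motif.seed_word}\t{motif.occurrence}"
                f"\t{motif.q_value:.3g}\t{match.target_name}"
                f"\t{match.e_value:.3g}\t{note}"
            )
    return "\n".join(lines) + "\n"
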