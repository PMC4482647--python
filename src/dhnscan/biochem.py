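"""Hydropathy and intrinsic-disorder statistics.

Dehydrins are strongly hydrophilic and intrinsically disordered; the study
contrast is the grand average of hydropathy (GRAVY, Kyte-Doolittle) and the
per-protein proportion of residues predicted disordered, compared between a
dehydrin set and a background protein set with Welch's t-test.

The disorder scorer is a windowed charge-hydropathy fold index (Uversky's
boundary line) mapped onto [0, 1] so that a score above 0.5 means predicted
disorder, preserving the usual per-residue decision rule.  It is pluggable:
any callable returning per-residue scores in [0, 1] can be swapped in.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

#: Kyte-Doolittle hydropathy index
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

_CHARGE = {"K": 1.0, "R": 1.0, "D": -1.0, "E": -1.0}


def _standard_residues(protein: str) -> str:
    """Drop ambiguous residues (B, Z, X, U, ...) with a logged count."""
    kept = [aa for aa in protein.upper() if aa in KYTE_DOOLITTLE]
    skipped = len(protein) - len(kept)
    if skipped:
        logger.warning("skipping %d non-standard residue(s)", skipped)
    return "".join(kept)


def gravy(protein: str) -> float:
    """Grand average of hydropathy: mean Kyte-Doolittle value per residue.
    Negative values indicate hydrophilic proteins."""
    seq = _standard_residues(protein)
    if not seq:
        raise ValueError("empty (or fully non-standard) sequence")
    return sum(KYTE_DOOLITTLE[aa] for aa in seq) / len(seq)


def disorder_scores(protein: str, window: int = 21) -> np.ndarray:
    """Per-residue disorder scores in [0, 1].

    Over a centred window (clipped at the sequence ends) the mean hydropathy
    is rescaled to <H> = (mean KD + 4.5) / 9 and combined with the mean net
    charge magnitude |<R>| into the fold index
    I = 2.785 <H> - |<R>| - 1.151; the score is clamp(0.5 - I, 0, 1), so
    score > 0.5 corresponds to a negative fold index, i.e. predicted
    disorder.
    """
    if window < 5 or window % 2 == 0:
        raise ValueError("window must be odd and >= 5")
    seq = _standard_residues(protein)
    if not seq:
        raise ValueError("empty (or fully non-standard) sequence")
    kd = np.array([KYTE_DOOLITTLE[aa] for aa in seq])
    charge = np.array([_CHARGE.get(aa, 0.0) for aa in seq])
    half = window // 2
    n = len(seq)
    # cumulative sums for O(n) clipped-window means
    kd_cum = np.concatenate([[0.0], np.cumsum(kd)])
    ch_cum = np.concatenate([[0.0], np.cumsum(charge)])
    starts = np.maximum(0, np.arange(n) - half)
    ends = np.minimum(n, np.arange(n) + half + 1)
    widths = ends - starts
    mean_kd = (kd_cum[ends] - kd_cum[starts]) / widths
    mean_ch = np.abs((ch_cum[ends] - ch_cum[starts]) / widths)
    scaled_h = (mean_kd + 4.5) / 9.0
    fold_index = 2.785 * scaled_h - mean_ch - 1.151
    return np.clip(0.5 - fold_index, 0.0, 1.0)


def disorder_proportion(
    protein: str,
    window: int = 21,
    scorer: Callable[[str, int], np.ndarray] | None = None,
) -> float:
    """Fraction of residues with disorder score above 0.5."""
    scores = (scorer or disorder_scores)(protein, window)
    return float(np.mean(scores > 0.5))


def welch_t(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test: (t, Welch-Satterthwaite df,
    two-sided p)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    if se2 == 0:
        if np.isclose(a.mean(), b.mean()):
            return 0.0, float(na + nb - 2), 1.0
        raise ValueError("zero variance in both groups with unequal means")
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def student_t(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, float, float]:
    """Pooled-variance Student's t-test (t, df, two-sided p); the Welch test
    is the default throughout the package."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    res = stats.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(len(a) + len(b) - 2), float(res.pvalue)


@dataclass
class BiochemSummary:
    """Group contrast of GRAVY and disorder proportion with Welch tests."""

    ids_a: list[str]
    ids_b: list[str]
    gravy_a: list[float]
    gravy_b: list[float]
    disorder_a: list[float]
    disorder_b: list[float]
    gravy_test: tuple[float, float, float]
    disorder_test: tuple[float, float, float]

    @property
    def gravy_mean_a(self) -> float:
        return float(np.mean(self.gravy_a))

    @property
    def gravy_mean_b(self) -> float:
        return float(np.mean(self.gravy_b))

    @property
    def disorder_mean_a(self) -> float:
        return float(np.mean(self.disorder_a))

    @property
    def disorder_mean_b(self) -> float:
        return float(np.mean(self.disorder_b))

    def to_json(self) -> str:
        payload = {
            "n_dehydrins": len(self.ids_a),
            "n_background": len(self.ids_b),
            "gravy_mean_dehydrins": round(self.gravy_mean_a, 4),
            "gravy_mean_background": round(self.gravy_mean_b, 4),
            "disorder_mean_dehydrins": round(self.disorder_mean_a, 4),
            "disorder_mean_background": round(self.disorder_mean_b, 4),
            "gravy_welch": {
                "t": round(self.gravy_test[0], 4),
                "df": round(self.gravy_test[1], 2),
                "p": self.gravy_test[2],
            },
            "disorder_welch": {
                "t": round(self.disorder_test[0], 4),
                "df": round(self.disorder_test[1], 2),
                "p": self.disorder_test[2],
            },
        }
        return json.dumps(payload, indent=2, sort_keys=True) + "\n"

    def to_tsv(self) -> str:
        lines = ["id\tgroup\tgravy\tdisorder_proportion"]
        for i, sid in enumerate(self.ids_a):
            lines.append(
                f"{sid}\tdehydrin\t{self.gravy_a[i]:.4f}\t{self.disorder_a[i]:.4f}"
            )
        for i, sid in enumerate(self.ids_b):
            lines.append(
                f"{sid}\tbackground\t{self.gravy_b[i]:.4f}\t{self.disorder_b[i]:.4f}"
            )
        return "\n".join(lines) + "\n"


def compare_sets(
    dehydrins: Iterable[tuple[str, str]],
    background: Iterable[tuple[str, str]],
    window: int = 21,
) -> BiochemSummary:
    """Contrast two sets of (id, protein sequence) pairs on GRAVY and
    disorder proportion with Welch's t-test for each metric."""
    dehydrins = list(dehydrins)
    background = list(background)
    if not dehydrins or not background:
        raise ValueError("both sets must be non-empty")
    ids_a = [i for i, _ in dehydrins]
    ids_b = [i for i, _ in background]
    gravy_a = [gravy(s) for _, s in dehydrins]
    gravy_b = [gravy(s) for _, s in background]
    dis_a = [disorder_proportion(s, window) for _, s in dehydrins]
    dis_b = [disorder_proportion(s, window) for _, s in background]
    return BiochemSummary(
        ids_a, ids_b, gravy_a, gravy_b, dis_a, dis_b,
        gravy_test=welch_t(gravy_a, gravy_b),
        disorder_test=welch_t(dis_a, dis_b),
    )
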