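"""Position frequency matrices over protein or nucleotide alphabets.

A :class:`PositionFrequencyMatrix` stores per-column symbol counts built from
a set of equal-length seed strings, optionally smoothed with a pseudocount
added to every symbol of every column.  Its log-odds form (column frequency
over a background composition, in bits) is the scanning score used for
segment mining and the basis of motif reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
DNA_ALPHABET = "ACGT"

IUPAC_TO_BASES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
BASES_TO_IUPAC = {frozenset(v): k for k, v in IUPAC_TO_BASES.items()}


@dataclass
class PositionFrequencyMatrix:
    """Per-column symbol counts with a smoothed frequency/log-odds view.

    ``counts`` has shape ``(length, len(alphabet))`` and already includes the
    pseudocount, so every fully observed column sums to
    ``n_seeds + len(alphabet) * pseudocount``.
    """

    alphabet: str
    counts: np.ndarray
    n_seeds: int
    pseudocount: float = 0.0
    kind_tag: str = ""
    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] != len(self.alphabet):
            raise ValueError("counts must be (length, |alphabet|)")
        if self.counts.shape[0] < 1:
            raise ValueError("PFM must have at least one column")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")
        self._index = {s: i for i, s in enumerate(self.alphabet)}

    def __len__(self) -> int:
        return self.counts.shape[0]

    @property
    def frequencies(self) -> np.ndarray:
        """Column-normalised frequencies (each row sums to 1)."""
        colsums = self.counts.sum(axis=1, keepdims=True)
        if np.any(colsums == 0):
            raise ValueError("PFM column with zero total count")
        return self.counts / colsums

    def log_odds(self, background: dict[str, float]) -> np.ndarray:
        """Per-column log2(frequency / background) score matrix."""
        bg = np.array([background[s] for s in self.alphabet], dtype=float)
        if np.any(bg <= 0):
            raise ValueError("background frequencies must be strictly positive")
        if not np.isclose(bg.sum(), 1.0, atol=1e-6):
            raise ValueError("background frequencies must sum to 1")
        freq = self.frequencies
        with np.errstate(divide="ignore"):
            return np.where(freq > 0, np.log2(np.maximum(freq, 1e-300) / bg), -np.inf)

    def max_score(self, background: dict[str, float]) -> float:
        """Score of the per-column argmax word (the best achievable score)."""
        return float(self.log_odds(background).max(axis=1).sum())

    def min_score(self, background: dict[str, float]) -> float:
        """Score of the per-column worst word (the lowest achievable score)."""
        return float(self.log_odds(background).min(axis=1).sum())

    def argmax_word(self) -> str:
        return "".join(self.alphabet[i] for i in self.counts.argmax(axis=1))

    def reverse_complement(self) -> "PositionFrequencyMatrix":
        if set(self.alphabet) != set(DNA_ALPHABET):
            raise ValueError("reverse complement is defined for nucleotide PFMs")
        order = [self._index[b] for b in "TGCA"]  # complement of A,C,G,T
        return PositionFrequencyMatrix(
            alphabet=self.alphabet,
            counts=self.counts[::-1, order].copy(),
            n_seeds=self.n_seeds,
            pseudocount=self.pseudocount,
            kind_tag=self.kind_tag,
        )

    # ---- serialisation -------------------------------------------------

    def to_jaspar(self, name: str = "") -> str:
        lines = [f">{name or self.kind_tag or 'motif'}"]
        for j, sym in enumerate(self.alphabet):
            vals = " ".join(f"{v:g}" for v in self.counts[:, j])
            lines.append(f"{sym} [ {vals} ]")
        return "\n".join(lines) + "\n"

    def to_meme_minimal(self, name: str = "", background: dict | None = None) -> str:
        if set(self.alphabet) != set(DNA_ALPHABET):
            raise ValueError("MEME minimal output is defined for nucleotide PFMs")
        freq = self.frequencies
        head = (
            "MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n"
            "Background letter frequencies\n"
        )
        bg = background or {b: 0.25 for b in DNA_ALPHABET}
        head += " ".join(f"{b} {bg[b]:.5f}" for b in DNA_ALPHABET) + "\n\n"
        body = f"MOTIF {name or self.kind_tag or 'motif'}\n"
        body += f"letter-probability matrix: alength= 4 w= {len(self)} nsites= {self.n_seeds}\n"
        for row in freq:
            body += " ".join(f"{v:.6f}" for v in row) + "\n"
        return head + body

    def to_tsv(self) -> str:
        lines = ["pos\t" + "\t".join(self.alphabet)]
        for i, row in enumerate(self.counts):
            lines.append(f"{i}\t" + "\t".join(f"{v:g}" for v in row))
        return "\n".join(lines) + "\n"


def build_pfm(
    seeds: list[str],
    pseudocount: float = 0.0,
    alphabet: str = AA_ALPHABET,
    kind_tag: str = "",
) -> PositionFrequencyMatrix:
    """Tally equal-length seed strings into a PFM, adding ``pseudocount``
    to every symbol of every column."""
    if not seeds:
        raise ValueError("empty seed list")
    length = len(seeds[0])
    if length == 0:
        raise ValueError("seeds must be non-empty strings")
    if any(len(s) != length for s in seeds):
        raise ValueError("ragged seed lengths")
    index = {s: i for i, s in enumerate(alphabet)}
    counts = np.full((length, len(alphabet)), float(pseudocount))
    for seed in seeds:
        for j, sym in enumerate(seed):
            if sym not in index:
                raise ValueError(f"illegal symbol {sym!r} for alphabet")
            counts[j, index[sym]] += 1.0
    return PositionFrequencyMatrix(
        alphabet=alphabet,
        counts=counts,
        n_seeds=len(seeds),
        pseudocount=pseudocount,
        kind_tag=kind_tag,
    )


def iupac_consensus(pfm: PositionFrequencyMatrix, threshold: float = 0.25) -> str:
    """IUPAC consensus: per column, every base at frequency >= ``threshold``
    joins the degenerate symbol."""
    if set(pfm.alphabet) != set(DNA_ALPHABET):
        raise ValueError("IUPAC consensus is defined for nucleotide PFMs")
    out = []
    freq = pfm.frequencies
    for row in freq:
        included = frozenset(
            pfm.alphabet[i] for i in range(4) if row[i] >= threshold - 1e-12
        )
        if not included:  # every base below threshold: fall back to argmax
            included = frozenset(pfm.alphabet[int(np.argmax(row))])
        out.append(BASES_TO_IUPAC[included])
    return "".join(out)


def iupac_to_pfm(consensus: str, kind_tag: str = "") -> PositionFrequencyMatrix:
    """Inverse of :func:`iupac_consensus`: each column splits frequency
    equally among its allowed bases."""
    if not consensus:
        raise ValueError("empty consensus")
    counts = np.zeros((len(consensus), 4))
    index = {b: i for i, b in enumerate(DNA_ALPHABET)}
    for j, sym in enumerate(consensus.upper()):
        try:
            bases = IUPAC_TO_BASES[sym]
        except KeyError:
            raise ValueError(f"illegal IUPAC symbol {sym!r}") from None
        for b in bases:
            counts[j, index[b]] = 1.0 / len(bases)
    return PositionFrequencyMatrix(
        alphabet=DNA_ALPHABET, counts=counts, n_seeds=1, pseudocount=0.0,
        kind_tag=kind_tag,
    )
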