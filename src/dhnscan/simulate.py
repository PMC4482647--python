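"""Synthetic inputs with known ground truth.

Three generators emulate the study's inputs at desk scale:

* proteomes: dehydrins assembled from mutated K/Y/S segment instances joined
  by disorder-biased linkers, mixed with background proteins drawn from a
  globular-average composition;
* gene-bearing contigs with GFF3 annotation, including genes with less than
  a full promoter length of upstream sequence;
* foreground/background promoter pools with a motif word planted at
  controlled per-promoter probabilities on either strand.

Every generator is driven by a single integer seed through a named
numpy Generator and returns a truth object listing everything it planted.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from io import StringIO

import numpy as np
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .classify import classify_kinds
from .resources import disorder_biased_composition, globular_composition
from .segments import K_SEGMENT_CONSENSUS, Y_SEGMENT_CONSENSUS
from .pfm import AA_ALPHABET

DNA = "ACGT"
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: The five dehydrin classes; classes with an ``_n`` draw segment
#: multiplicities in 1..3 per instance.
DEHYDRIN_CLASSES = ("K_n", "KS", "SK_n", "Y_nK_n", "Y_nSK_n")


@dataclass(frozen=True)
class SegmentSpec:
    """One conserved-segment template and its per-position substitution rate."""

    kind: str  # K, Y or S
    template: str
    substitution_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("K", "Y", "S"):
            raise ValueError(f"unknown segment kind {self.kind!r}")
        if not self.template or any(c not in AA_ALPHABET for c in self.template):
            raise ValueError("template must be non-empty over the 20-letter alphabet")
        if not (0.0 <= self.substitution_rate <= 0.3):
            raise ValueError("substitution_rate must be in [0, 0.3]")
        if self.kind == "S" and (len(self.template) < 3 or set(self.template) != {"S"}):
            raise ValueError("S-segment template must be a serine run of length >= 3")


@dataclass(frozen=True)
class PlantedDehydrin:
    sequence_id: str
    kinds: tuple[str, ...]
    intervals: tuple[tuple[int, int], ...]  # 0-based half-open, ordered, disjoint
    class_label: str


@dataclass(frozen=True)
class PlantedMotif:
    promoter_id: str
    word: str
    start: int
    strand: str  # '+' or '-'


@dataclass(frozen=True)
class PlantedGene:
    gene_id: str
    contig_id: str
    strand: str
    tss: int  # 0-based position of the transcription start
    upstream_available: int


@dataclass
class PlantTruth:
    """Everything a generator planted, for downstream truth comparison."""

    planted_dehydrins: list[PlantedDehydrin] = field(default_factory=list)
    planted_motifs: list[PlantedMotif] = field(default_factory=list)
    planted_genes: list[PlantedGene] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n"

    def dehydrins_tsv(self) -> str:
        lines = ["sequence_id\tclass\tkinds\tintervals"]
        for d in self.planted_dehydrins:
            ivals = ";".join(f"{s}-{e}" for s, e in d.intervals)
            lines.append(
                f"{d.sequence_id}\t{d.class_label}\t{''.join(d.kinds)}\t{ivals}"
            )
        return "\n".join(lines) + "\n"

    def motifs_tsv(self) -> str:
        lines = ["promoter_id\tword\tstart\tstrand"]
        for m in self.planted_motifs:
            lines.append(f"{m.promoter_id}\t{m.word}\t{m.start}\t{m.strand}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# helpers


def records_to_fasta(records: list[SeqRecord]) -> str:
    """FASTA text wrapped at 60 columns (deterministic for identical input)."""
    buf = StringIO()
    SeqIO.write(records, buf, "fasta")
    return buf.getvalue()


def reverse_complement(dna: str) -> str:
    bad = set(dna.upper()) - set("ACGTN")
    if bad:
        raise ValueError(f"illegal DNA symbols: {sorted(bad)}")
    return dna.translate(_COMPLEMENT)[::-1]


def _draw_residues(rng, composition: dict[str, float], n: int) -> str:
    letters = sorted(composition)
    probs = np.array([composition[a] for a in letters])
    probs = probs / probs.sum()
    return "".join(rng.choice(letters, size=n, p=probs)) if n else ""


def _draw_linker(rng, composition, length: int, no_s_start: bool, no_s_end: bool) -> str:
    """A linker with no serine run of 3+ (which would fake an S-segment) and,
    where it touches an S-segment, no serine at the junction."""
    non_s = {a: f for a, f in composition.items() if a != "S"}
    while True:
        linker = _draw_residues(rng, composition, length)
        if "SSS" in linker:
            continue
        if length:
            if no_s_start and linker[0] == "S":
                linker = _draw_residues(rng, non_s, 1) + linker[1:]
            if no_s_end and linker[-1] == "S":
                linker = linker[:-1] + _draw_residues(rng, non_s, 1)
            if "SSS" in linker:
                continue
        return linker


def _mutate(rng, template: str, rate: float, keep_s_run: int = 0) -> str:
    """i.i.d. substitutions (no indels, so truth coordinates stay exact).

    With ``keep_s_run`` > 0 the outcome must retain a serine run of that
    length: an S-segment that lost its defining run would no longer be an
    S-segment and the planted truth label would be false.
    """
    if rate == 0:
        return template
    while True:
        out = list(template)
        for i, aa in enumerate(out):
            if rng.random() < rate:
                others = [c for c in AA_ALPHABET if c != aa]
                out[i] = others[int(rng.integers(len(others)))]
        mutated = "".join(out)
        if not keep_s_run or "S" * keep_s_run in mutated:
            return mutated


def _class_kinds(rng, class_label: str) -> list[str]:
    n = lambda: int(rng.integers(1, 4))  # noqa: E731 - multiplicity 1..3
    if class_label == "K_n":
        return ["K"] * n()
    if class_label == "KS":
        return ["K", "S"]
    if class_label == "SK_n":
        return ["S"] + ["K"] * n()
    if class_label == "Y_nK_n":
        return ["Y"] * n() + ["K"] * n()
    if class_label == "Y_nSK_n":
        return ["Y"] * n() + ["S"] + ["K"] * n()
    raise ValueError(f"unknown dehydrin class {class_label!r}")


# ---------------------------------------------------------------------------
# generators


def make_proteome(
    n_background: int,
    class_mix: dict[str, int],
    substitution_rate: float = 0.1,
    linker_length_range: tuple[int, int] = (15, 40),
    seed: int = 0,
    s_run_range: tuple[int, int] = (5, 8),
    background_length_range: tuple[int, int] = (80, 300),
) -> tuple[list[SeqRecord], PlantTruth]:
    """Planted dehydrins plus background proteins.

    Dehydrin sequences interleave mutated segment instances (in the class's
    canonical order) with linkers drawn from a disorder-biased composition;
    background proteins are drawn from the globular average composition.
    """
    if n_background < 0 or any(v < 0 for v in class_mix.values()):
        raise ValueError("counts must be >= 0")
    unknown = set(class_mix) - set(DEHYDRIN_CLASSES)
    if unknown:
        raise ValueError(f"unknown class name(s): {sorted(unknown)}")
    n_dehydrins = sum(class_mix.values())
    if n_background + n_dehydrins == 0:
        raise ValueError("at least one sequence must be requested")
    if not (0.0 <= substitution_rate <= 0.3):
        raise ValueError("substitution_rate must be in [0, 0.3]")

    rng = np.random.default_rng(seed)
    linker_comp = disorder_biased_composition()
    bg_comp = globular_composition()
    lo, hi = linker_length_range

    records: list[SeqRecord] = []
    truth = PlantTruth()
    idx = 0
    for class_label in sorted(class_mix):
        for _ in range(class_mix[class_label]):
            idx += 1
            seq_id = f"dhn_{idx:04d}"
            kinds = _class_kinds(rng, class_label)
            parts: list[str] = []
            intervals: list[tuple[int, int]] = []
            pos = 0
            for i, kind in enumerate(kinds):
                linker = _draw_linker(
                    rng,
                    linker_comp,
                    int(rng.integers(lo, hi + 1)),
                    # serines at a junction with an S-segment would silently
                    # extend the planted run and shift the truth coordinates
                    no_s_start=(i > 0 and kinds[i - 1] == "S"),
                    no_s_end=(kind == "S"),
                )
                parts.append(linker)
                pos += len(linker)
                if kind == "K":
                    template = K_SEGMENT_CONSENSUS
                elif kind == "Y":
                    template = Y_SEGMENT_CONSENSUS[int(rng.integers(2))]
                else:
                    template = "S" * int(rng.integers(s_run_range[0], s_run_range[1] + 1))
                realised = _mutate(
                    rng, template, substitution_rate, keep_s_run=3 if kind == "S" else 0
                )
                parts.append(realised)
                intervals.append((pos, pos + len(realised)))
                pos += len(realised)
            tail = _draw_linker(
                rng,
                linker_comp,
                int(rng.integers(lo, hi + 1)),
                no_s_start=(kinds[-1] == "S"),
                no_s_end=False,
            )
            parts.append(tail)
            sequence = "".join(parts)
            assert classify_kinds("".join(kinds)) == class_label
            truth.planted_dehydrins.append(
                PlantedDehydrin(seq_id, tuple(kinds), tuple(intervals), class_label)
            )
            records.append(SeqRecord(Seq(sequence), id=seq_id, description=""))

    for i in range(n_background):
        length = int(rng.integers(*background_length_range))
        seq = _draw_residues(rng, bg_comp, length)
        records.append(SeqRecord(Seq(seq), id=f"bg_{i + 1:04d}", description=""))
    return records, truth


def make_genome_with_genes(
    n_genes: int,
    contig_length: int = 6000,
    near_edge_fraction: float = 0.0,
    seed: int = 0,
    promoter_length: int = 1000,
    gene_length_range: tuple[int, int] = (300, 1500),
) -> tuple[list[SeqRecord], str, PlantTruth]:
    """Random contigs, one gene each, on both strands, with a chosen fraction
    of genes given less than ``promoter_length`` bp of upstream sequence.
    Returns (genome records, GFF3 text, truth)."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if contig_length < 2000:
        raise ValueError("contig_length must be >= 2000")
    if not (0.0 <= near_edge_fraction <= 1.0):
        raise ValueError("near_edge_fraction must be a probability")

    rng = np.random.default_rng(seed)
    n_near = int(round(near_edge_fraction * n_genes))
    records: list[SeqRecord] = []
    truth = PlantTruth()
    gff_lines = ["##gff-version 3"]
    bases = np.array(list(DNA))
    for i in range(n_genes):
        contig_id = f"contig_{i + 1:04d}"
        gene_id = f"gene_{i + 1:04d}"
        seq = "".join(rng.choice(bases, size=contig_length))
        strand = "+" if rng.random() < 0.5 else "-"
        gene_len = int(rng.integers(*gene_length_range))
        near = i < n_near
        if near:
            upstream = int(rng.integers(50, promoter_length))
        else:
            upstream = int(rng.integers(promoter_length, contig_length - gene_len + 1))
        if strand == "+":
            start0 = upstream  # tss at gene 5' end
            end0 = start0 + gene_len
            tss = start0
        else:
            tss = contig_length - 1 - upstream
            start0 = tss - gene_len + 1
            end0 = tss + 1
        gff_lines.append(
            f"{contig_id}\tdhnscan\tgene\t{start0 + 1}\t{end0}\t.\t{strand}\t."
            f"\tID={gene_id}"
        )
        gff_lines.append(
            f"{contig_id}\tdhnscan\tmRNA\t{start0 + 1}\t{end0}\t.\t{strand}\t."
            f"\tID={gene_id}.1;Parent={gene_id}"
        )
        truth.planted_genes.append(
            PlantedGene(gene_id, contig_id, strand, tss, upstream)
        )
        records.append(SeqRecord(Seq(seq), id=contig_id, description=""))
    return records, "\n".join(gff_lines) + "\n", truth


def make_promoter_sets(
    n_fg: int,
    n_bg: int,
    word: str,
    p_fg: float,
    p_bg: float,
    length: int = 1000,
    seed: int = 0,
) -> tuple[list[SeqRecord], list[SeqRecord], PlantTruth]:
    """Foreground and background promoter pools with at most one planted copy
    of ``word`` per promoter, at a uniform position on a uniform strand."""
    word = word.upper()
    if not word or any(c not in DNA for c in word):
        raise ValueError("word must be a non-empty A/C/G/T string")
    if len(word) > length:
        raise ValueError("word longer than promoter length")
    if not (0.0 <= p_bg <= p_fg <= 1.0):
        raise ValueError("require 0 <= p_bg <= p_fg <= 1")

    rng = np.random.default_rng(seed)
    bases = np.array(list(DNA))
    truth = PlantTruth()

    def build(prefix: str, n: int, p: float) -> list[SeqRecord]:
        out = []
        for i in range(n):
            pid = f"{prefix}_{i + 1:04d}"
            seq = "".join(rng.choice(bases, size=length))
            if rng.random() < p:
                pos = int(rng.integers(0, length - len(word) + 1))
                strand = "+" if rng.random() < 0.5 else "-"
                planted = word if strand == "+" else reverse_complement(word)
                seq = seq[:pos] + planted + seq[pos + len(word):]
                truth.planted_motifs.append(PlantedMotif(pid, word, pos, strand))
            out.append(SeqRecord(Seq(seq), id=pid, description=""))
        return out

    fg = build("fg", n_fg, p_fg)
    bg = build("bg", n_bg, p_bg)
    return fg, bg, truth
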