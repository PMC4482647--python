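"""End-to-end orchestration: mine -> classify -> extract -> biochem ->
per-class discover -> annotate, writing class-wise report tables.

A run is driven by a :class:`PipelineConfig` (YAML round-trip, CLI flags
override) and a single seed; identical config + seed reproduces every
output file byte for byte.  In synthetic mode the pipeline first generates
its own inputs (proteome, gene-bearing genome, per-class promoter pools
with class-specific planted words) so the whole study can be replayed at
desk scale with known ground truth.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import annotate as annotate_mod
from . import biochem, discovery, promoters, segments, simulate
from .classify import DehydrinRecord, classify_hits, records_to_tsv

logger = logging.getLogger(__name__)

#: class-specific words planted in synthetic per-class promoter pools;
#: each echoes an element family the class's promoters are known to carry
#: (LTRE, I-box/GATA, CRT/DRE, ABRE/G-box cores).  Degenerate IUPAC
#: positions are realised per promoter, like the real elements.
SYNTHETIC_CLASS_WORDS = {
    "K_n": "ACCGACA",
    "KS": "GATAAGR",
    "SK_n": "RCCGACC",
    "Y_nK_n": "ACGTGGCA",
    "Y_nSK_n": "GACACGTG",
}


def _iupac_realisations(word: str) -> list[str]:
    from .pfm import IUPAC_TO_BASES

    words = [""]
    for sym in word:
        words = [w + b for w in words for b in IUPAC_TO_BASES[sym]]
    return words


@dataclass
class PipelineConfig:
    """Inputs, thresholds and the seed for one pipeline run."""

    output_dir: str = "dhnscan_run"
    seed: int = 0
    # real-data inputs (ignored in synthetic mode)
    proteome_fasta: str | None = None
    genome_fasta: str | None = None
    gff3: str | None = None
    class_promoters: dict[str, str] = field(default_factory=dict)
    background_promoters: str | None = None
    # synthetic mode
    synthetic: bool = True
    n_background_proteins: int = 200
    class_counts: dict[str, int] = field(
        default_factory=lambda: {"K_n": 10, "KS": 10, "SK_n": 10, "Y_nK_n": 10, "Y_nSK_n": 10}
    )
    substitution_rate: float = 0.1
    #: promoters per class pool; the study's class sets hold 21-123 promoters
    n_promoters_per_class: int = 40
    n_background_promoters: int = 1000
    p_fg: float = 0.9
    p_bg: float = 0.1
    near_edge_fraction: float = 0.05
    # thresholds
    min_relative_score: float = 0.7
    s_min_run: int = 3
    promoter_length: int = 1000
    q_max: float = 0.01
    e_max: float = 0.05
    k_min: int = 6
    k_max: int = 10
    pseudocount: float = 0.5
    max_rounds: int = 10
    n_null: int = 1000

    def __post_init__(self) -> None:
        if not (0 < self.min_relative_score <= 1):
            raise ValueError("min_relative_score must be in (0, 1]")
        if self.s_min_run < 1 or self.promoter_length < 1:
            raise ValueError("invalid threshold")
        if not (0 <= self.q_max <= 1 and 0 <= self.e_max):
            raise ValueError("invalid significance gate")
        if self.k_min > self.k_max or self.k_min < 1:
            raise ValueError("invalid k range")

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        return cls(**(yaml.safe_load(text) or {}))


def mine_proteome(
    proteome: dict[str, str], config: PipelineConfig
) -> tuple[list[DehydrinRecord], dict]:
    """Iterative K/Y PFM mining plus S-run detection, resolved and
    classified per protein.  Returns (records, audit dict)."""
    k_pfm, k_hits, k_rounds = segments.iterative_expand(
        [segments.K_SEGMENT_CONSENSUS],
        proteome,
        min_relative_score=config.min_relative_score,
        max_rounds=config.max_rounds,
        pseudocount=config.pseudocount,
        kind="K",
    )
    y_pfm, y_hits, y_rounds = segments.iterative_expand(
        list(segments.Y_SEGMENT_CONSENSUS),
        proteome,
        min_relative_score=config.min_relative_score,
        max_rounds=config.max_rounds,
        pseudocount=config.pseudocount,
        kind="Y",
    )
    by_seq: dict[str, list[segments.SegmentHit]] = {sid: [] for sid in proteome}
    for hit in k_hits + y_hits:
        by_seq[hit.sequence_id].append(hit)
    for sid, seq in proteome.items():
        by_seq[sid].extend(segments.find_s_segments(seq, config.s_min_run, sid))
    records = [
        classify_hits(hits, sequence_id=sid) for sid, hits in sorted(by_seq.items())
    ]
    audit = {
        "k_seed_rounds": k_rounds,
        "y_seed_rounds": y_rounds,
        "k_pfm_seeds": k_pfm.n_seeds,
        "y_pfm_seeds": y_pfm.n_seeds,
    }
    return records, audit


def census_table(records: list[DehydrinRecord], species: str = "synthetic") -> str:
    """Species x class counts (one row per species plus a total row)."""
    classes = ("K_n", "KS", "SK_n", "Y_nK_n", "Y_nSK_n")
    counts = {c: 0 for c in classes}
    for r in records:
        if r.class_label in counts:
            counts[r.class_label] += 1
    header = "species\t" + "\t".join(classes) + "\ttotal"
    row = species + "\t" + "\t".join(str(counts[c]) for c in classes)
    row += f"\t{sum(counts.values())}"
    total = "total\t" + "\t".join(str(counts[c]) for c in classes)
    total += f"\t{sum(counts.values())}"
    return "\n".join([header, row, total]) + "\n"


def report_class_table(
    class_name: str,
    motifs: list[discovery.MotifModel],
    annotations: list[list[annotate_mod.PFMAlignment]],
) -> str:
    """Per-class motif table: consensus, occurrence n/N, q-value, matched
    element, match E-value and function note; one row per (motif, match)."""
    del class_name  # present for the report API; content is per-class by file
    return annotate_mod.annotation_report_tsv(motifs, annotations)


def _read_fasta_pairs(path: str | Path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def run_full(config: PipelineConfig) -> Path:
    """Execute every stage in order and write the run directory.  Any stage
    failure aborts with a stage-labelled message and leaves a FAILED marker
    next to the partial outputs."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("dhnscan")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    timings: dict[str, float] = {}
    stage = "setup"
    try:
        (out / "config.yaml").write_text(config.to_yaml())
        root.info("run seed=%d output=%s", config.seed, out)

        # ---- stage: inputs ------------------------------------------------
        stage = "inputs"
        t0 = time.perf_counter()
        if config.synthetic:
            prot_records, prot_truth = simulate.make_proteome(
                config.n_background_proteins,
                config.class_counts,
                config.substitution_rate,
                seed=config.seed,
            )
            proteome = {r.id: str(r.seq) for r in prot_records}
            (out / "proteome.fasta").write_text(simulate.records_to_fasta(prot_records))
            (out / "proteome_truth.tsv").write_text(prot_truth.dehydrins_tsv())
            n_genes = max(1, sum(config.class_counts.values()))
            genome_records, gff_text, gene_truth = simulate.make_genome_with_genes(
                n_genes,
                near_edge_fraction=config.near_edge_fraction,
                seed=config.seed + 1,
                promoter_length=config.promoter_length,
            )
            genome = {r.id: str(r.seq) for r in genome_records}
            (out / "genome.fasta").write_text(simulate.records_to_fasta(genome_records))
            (out / "genes.gff3").write_text(gff_text)
            class_pools: dict[str, list[tuple[str, str]]] = {}
            offset = 2
            for class_name in sorted(config.class_counts):
                if config.class_counts[class_name] == 0:
                    continue
                n_fg = config.n_promoters_per_class
                if n_fg < 2:
                    continue
                pool: list[tuple[str, str]] = []
                words = _iupac_realisations(SYNTHETIC_CLASS_WORDS[class_name])
                share = [n_fg // len(words)] * len(words)
                share[0] += n_fg - sum(share)
                for word, n_part in zip(words, share):
                    if n_part == 0:
                        continue
                    fg, _, _ = simulate.make_promoter_sets(
                        n_part,
                        0,
                        word,
                        config.p_fg,
                        0.0,
                        length=config.promoter_length,
                        seed=config.seed + offset,
                    )
                    pool.extend(
                        (f"{class_name}_{word}_{r.id}", str(r.seq)) for r in fg
                    )
                    offset += 1
                class_pools[class_name] = pool
            _, bg_recs, _ = simulate.make_promoter_sets(
                0,
                config.n_background_promoters,
                "ACGTACGT",
                0.0,
                0.0,
                length=config.promoter_length,
                seed=config.seed + offset,
            )
            background_pool = [(r.id, str(r.seq)) for r in bg_recs]
        else:
            if not config.proteome_fasta:
                raise ValueError("proteome_fasta required when synthetic=false")
            proteome = dict(_read_fasta_pairs(config.proteome_fasta))
            genome = (
                promoters.load_genome(config.genome_fasta)
                if config.genome_fasta
                else {}
            )
            gff_text = Path(config.gff3).read_text() if config.gff3 else ""
            class_pools = {
                cls: _read_fasta_pairs(path)
                for cls, path in sorted(config.class_promoters.items())
            }
            if not config.background_promoters:
                raise ValueError("background_promoters required when synthetic=false")
            background_pool = _read_fasta_pairs(config.background_promoters)
        timings[stage] = time.perf_counter() - t0

        # ---- stage: mine + classify --------------------------------------
        stage = "mine"
        t0 = time.perf_counter()
        records, audit = mine_proteome(proteome, config)
        dehydrins = [r for r in records if r.is_dehydrin]
        (out / "dehydrins.tsv").write_text(records_to_tsv(dehydrins))
        (out / "census.tsv").write_text(census_table(dehydrins))
        (out / "mining_audit.json").write_text(
            json.dumps(audit, indent=2, sort_keys=True) + "\n"
        )
        root.info("classified %d dehydrins", len(dehydrins))
        timings[stage] = time.perf_counter() - t0

        # ---- stage: extract promoters ------------------------------------
        stage = "extract"
        t0 = time.perf_counter()
        if genome and gff_text:
            genes = promoters.parse_gene_models(gff_text)
            proms = promoters.extract_promoters(
                genome, genes, length=config.promoter_length
            )
            (out / "promoters.fasta").write_text(promoters.promoters_to_fasta(proms))
            (out / "promoters.bed").write_text(promoters.promoters_to_bed(proms))
            root.info(
                "extracted %d promoters (%d truncated)",
                len(proms),
                sum(p.truncated for p in proms),
            )
        timings[stage] = time.perf_counter() - t0

        # ---- stage: biochem ----------------------------------------------
        stage = "biochem"
        t0 = time.perf_counter()
        dhn_ids = {r.sequence_id for r in dehydrins}
        dhn_set = [(sid, proteome[sid]) for sid in sorted(dhn_ids)]
        bg_set = [
            (sid, seq) for sid, seq in sorted(proteome.items()) if sid not in dhn_ids
        ]
        if len(dhn_set) >= 2 and len(bg_set) >= 2:
            summary = biochem.compare_sets(dhn_set, bg_set)
            (out / "biochem.tsv").write_text(summary.to_tsv())
            (out / "biochem.json").write_text(summary.to_json())
        timings[stage] = time.perf_counter() - t0

        # ---- stage: discover + annotate per class ------------------------
        stage = "discover"
        t0 = time.perf_counter()
        bg_seqs = [s for _, s in background_pool]
        for class_name in sorted(class_pools):
            fg_seqs = [s for _, s in class_pools[class_name]]
            if len(fg_seqs) < 2:
                continue
            motifs = discovery.discover_motifs(
                fg_seqs,
                bg_seqs,
                k_min=config.k_min,
                k_max=config.k_max,
                q_max=config.q_max,
            )
            annotations = [
                annotate_mod.match_library(
                    m.pfm,
                    n_null=config.n_null,
                    seed=config.seed,
                    e_max=config.e_max,
                    query_id=m.seed_word,
                )
                for m in motifs
            ]
            (out / f"motifs_{class_name}.tsv").write_text(
                report_class_table(class_name, motifs, annotations)
            )
            root.info("class %s: %d motifs", class_name, len(motifs))
        timings[stage] = time.perf_counter() - t0

        (out / "timings.json").write_text(
            json.dumps({k: round(v, 3) for k, v in timings.items()}, indent=2, sort_keys=True)
            + "\n"
        )
    except Exception as exc:
        (out / "FAILED").write_text(f"stage {stage}: {exc}\n")
        root.error("stage %s failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()
    return out
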