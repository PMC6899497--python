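"""Synthetic transcriptome, footprint and total-mRNA library generator.

Emulates the footprint geometry of a mammalian ribosome-profiling library:

* footprints 28-30 nt long (default length distribution 0.3/0.4/0.3);
* 5' ends sitting 12 nt upstream of the ribosomal P-site codon, exactly so
  with probability ``periodicity_fidelity`` and otherwise jittered by
  +-1 nt, which produces the 3-nt periodicity and frame-1 preference of
  real footprint libraries;
* P-sites uniform over sense codons (start codon included, stop codon
  excluded), so 5'-end density vanishes 15 nt upstream of the stop codon;
* a total-mRNA control fragmented uniformly at random over the transcript
  with fragment sizes similar to footprints, hence flat frame usage;
* per-gene mRNA abundance and true translational efficiency both
  log-normal, so footprint sampling weight is abundance x TE x sense-codon
  count and mRNA sampling weight is abundance x transcript length.

Everything is emitted as plain-text standards (FASTA, annotation TSV, SAM,
gene->term TSV, ground-truth TSV) so the downstream readers exercise the
same code paths as real data. A single integer seed makes every output
byte-identical across runs; each stage draws from its own child stream of
that seed so stages may be rerun independently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Mapping, Set, Tuple

import numpy as np
import pandas as pd

from .annotation_io import AnnotationSet, TranscriptAnnotation, write_annotation_tsv

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_transcriptome",
    "simulate_footprints",
    "simulate_total_mrna",
    "simulate_term_annotation",
    "simulate_all",
    "write_fasta",
    "write_ground_truth_tsv",
]

_STOP_CODONS = ("TAA", "TAG", "TGA")
# stable child-stream keys, one per stage
_STREAM_TRANSCRIPTOME = 0
_STREAM_FOOTPRINTS = 1
_STREAM_MRNA = 2
_STREAM_TERMS = 3


class SimulationError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults are the documented mammalian geometry: 12 nt P-site offset,
    28-30 nt footprints, periodicity fidelity 0.9, 200 genes and 50,000
    reads per library.
    """

    n_genes: int = 200
    utr5_range: Tuple[int, int] = (30, 200)
    cds_codons_range: Tuple[int, int] = (100, 500)  # incl. start + stop codons
    utr3_range: Tuple[int, int] = (50, 300)
    abundance_sigma: float = 1.0
    te_sigma: float = 0.5
    psite_offset: int = 12
    periodicity_fidelity: float = 0.9
    footprint_length_pmf: Dict[int, float] = field(
        default_factory=lambda: {28: 0.3, 29: 0.4, 30: 0.3}
    )
    mrna_fragment_length_range: Tuple[int, int] = (25, 34)
    n_footprint_reads: int = 50_000
    n_mrna_reads: int = 50_000
    n_terms: int = 20
    enriched_term_fraction: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise SimulationError("n_genes must be positive")
        for name in ("utr5_range", "cds_codons_range", "utr3_range",
                     "mrna_fragment_length_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise SimulationError(f"{name} must satisfy 0 < lo <= hi")
        if self.psite_offset < 0:
            raise SimulationError("psite_offset must be non-negative")
        if not (0.0 <= self.periodicity_fidelity <= 1.0):
            raise SimulationError("periodicity_fidelity must be in [0, 1]")
        if abs(sum(self.footprint_length_pmf.values()) - 1.0) > 1e-9:
            raise SimulationError("footprint_length_pmf must sum to 1")
        if any(l <= 0 for l in self.footprint_length_pmf):
            raise SimulationError("footprint lengths must be positive")
        if self.utr5_range[0] <= self.psite_offset + 1:
            raise SimulationError(
                "min(utr5_range) must exceed psite_offset + 1 so no "
                "footprint 5' end falls off the transcript"
            )
        for name in ("abundance_sigma", "te_sigma"):
            if getattr(self, name) <= 0:
                raise SimulationError(f"{name} must be positive")
        if self.n_footprint_reads <= 0 or self.n_mrna_reads <= 0:
            raise SimulationError("read counts must be positive")
        if self.n_terms <= 0:
            raise SimulationError("n_terms must be positive")
        if not (0.0 <= self.enriched_term_fraction <= 1.0):
            raise SimulationError("enriched_term_fraction must be in [0, 1]")

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        cfg = cls()
        for key, value in d.items():
            if not hasattr(cfg, key):
                raise SimulationError(f"unknown simulation parameter {key!r}")
            if key.endswith("_range"):
                value = (int(value[0]), int(value[1]))
            elif key == "footprint_length_pmf":
                value = {int(k): float(v) for k, v in value.items()}
            cfg = replace(cfg, **{key: value})
        return cfg


@dataclass
class GroundTruth:
    """Per-gene generative parameters, for parameter-recovery testing."""

    gene_ids: List[str]
    abundance: np.ndarray  # positive, arbitrary units
    true_te: np.ndarray  # positive
    terms: Dict[str, Set[str]] = field(default_factory=dict)
    designated_term: str | None = None

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene_id": self.gene_ids, "abundance": self.abundance, "true_te": self.true_te}
        )


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


def simulate_transcriptome(
    config: SimulationConfig,
) -> Tuple[AnnotationSet, Dict[str, str], GroundTruth]:
    """Draw gene models, sequences and per-gene abundance/TE.

    One transcript per gene. UTR and CDS lengths are uniform on the
    configured ranges (CDS length a multiple of 3); sequences are uniform
    random ACGT except that the CDS begins with ATG and ends with a stop
    codon. Abundance ~ LogNormal(0, abundance_sigma); true TE ~
    LogNormal(0, te_sigma).
    """
    config.validate()
    rng = _rng(config.seed, _STREAM_TRANSCRIPTOME)
    n = config.n_genes
    width = max(4, len(str(n - 1)))

    utr5 = rng.integers(config.utr5_range[0], config.utr5_range[1] + 1, size=n)
    codons = rng.integers(config.cds_codons_range[0], config.cds_codons_range[1] + 1, size=n)
    utr3 = rng.integers(config.utr3_range[0], config.utr3_range[1] + 1, size=n)
    abundance = rng.lognormal(0.0, config.abundance_sigma, size=n)
    true_te = rng.lognormal(0.0, config.te_sigma, size=n)

    bases = np.array(list("ACGT"))
    transcripts: Dict[str, TranscriptAnnotation] = {}
    seqs: Dict[str, str] = {}
    gene_ids: List[str] = []
    for i in range(n):
        gene = f"g{i:0{width}d}"
        tid = f"tx{i:0{width}d}"
        length = int(utr5[i] + 3 * codons[i] + utr3[i])
        cds_start = int(utr5[i])
        cds_end = cds_start + 3 * int(codons[i])
        seq = rng.choice(bases, size=length)
        seq[cds_start : cds_start + 3] = list("ATG")
        stop = _STOP_CODONS[rng.integers(0, 3)]
        seq[cds_end - 3 : cds_end] = list(stop)
        transcripts[tid] = TranscriptAnnotation(tid, gene, length, cds_start, cds_end)
        seqs[tid] = "".join(seq)
        gene_ids.append(gene)

    ann = AnnotationSet(transcripts)
    truth = GroundTruth(gene_ids=gene_ids, abundance=abundance, true_te=true_te)
    return ann, seqs, truth


def _sam_header(ann: AnnotationSet) -> List[str]:
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for tid in sorted(ann.transcripts):
        lines.append(f"@SQ\tSN:{tid}\tLN:{ann[tid].length}")
    return lines


def _write_sam(
    path: str | Path,
    ann: AnnotationSet,
    seqs: Mapping[str, str],
    prefix: str,
    tids: List[str],
    gene_idx: np.ndarray,
    five_prime: np.ndarray,
    lengths: np.ndarray,
) -> None:
    lines = _sam_header(ann)
    for j in range(len(gene_idx)):
        tid = tids[gene_idx[j]]
        start = int(five_prime[j])
        ln = int(lengths[j])
        seq = seqs[tid][start : start + ln]
        lines.append(
            f"{prefix}{j}\t0\t{tid}\t{start + 1}\t255\t{ln}M\t*\t0\t0\t{seq}\t*"
        )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def simulate_footprints(
    ann: AnnotationSet,
    seqs: Mapping[str, str],
    truth: GroundTruth,
    config: SimulationConfig,
    path: str | Path,
) -> None:
    """Emit a footprint SAM library against the transcript references.

    A read's gene is drawn with probability proportional to
    abundance x true TE x number of sense codons; its P-site is uniform on
    the sense codons {cds_start, cds_start+3, ..., cds_end-6}; its 5' end
    is P-site - psite_offset, jittered by +-1 nt (equiprobable) with
    probability 1 - periodicity_fidelity; its length is drawn from
    ``footprint_length_pmf`` and truncated at the transcript end.
    """
    config.validate()
    rng = _rng(config.seed, _STREAM_FOOTPRINTS)
    tids = [ann.gene_to_transcript[g] for g in truth.gene_ids]
    cds_start = np.array([ann[t].cds_start for t in tids])
    cds_end = np.array([ann[t].cds_end for t in tids])
    tlen = np.array([ann[t].length for t in tids])
    n_sense = (cds_end - cds_start) // 3 - 1  # stop codon never a P-site

    weights = truth.abundance * truth.true_te * n_sense
    p = weights / weights.sum()
    n = config.n_footprint_reads
    gene_idx = rng.choice(len(tids), size=n, p=p)

    slot = np.floor(rng.random(n) * n_sense[gene_idx]).astype(np.int64)
    psite = cds_start[gene_idx] + 3 * slot

    u = rng.random(n)
    fid = config.periodicity_fidelity
    jitter = np.zeros(n, dtype=np.int64)
    jitter[u >= fid] = 1
    jitter[u >= fid + (1.0 - fid) / 2.0] = -1
    five = psite - config.psite_offset + jitter

    pmf_lengths = np.array(sorted(config.footprint_length_pmf))
    pmf_probs = np.array([config.footprint_length_pmf[l] for l in pmf_lengths])
    lengths = rng.choice(pmf_lengths, size=n, p=pmf_probs / pmf_probs.sum())
    lengths = np.minimum(lengths, tlen[gene_idx] - five)  # truncate at transcript end

    _write_sam(path, ann, seqs, "fp", tids, gene_idx, five, lengths)


def simulate_total_mrna(
    ann: AnnotationSet,
    seqs: Mapping[str, str],
    truth: GroundTruth,
    config: SimulationConfig,
    path: str | Path,
) -> None:
    """Emit a randomly fragmented total-mRNA SAM library.

    Gene drawn with probability proportional to abundance x transcript
    length; fragment length uniform on ``mrna_fragment_length_range``;
    fragment start uniform over all valid positions. Transcripts shorter
    than the minimum fragment length are excluded with a warning.
    """
    config.validate()
    rng = _rng(config.seed, _STREAM_MRNA)
    tids = [ann.gene_to_transcript[g] for g in truth.gene_ids]
    tlen = np.array([ann[t].length for t in tids])

    frag_lo, frag_hi = config.mrna_fragment_length_range
    usable = tlen >= frag_lo
    if not usable.all():
        excluded = [tids[i] for i in np.flatnonzero(~usable)]
        logger.warning(
            "%d transcript(s) shorter than min fragment length excluded: %s",
            len(excluded), ", ".join(excluded[:5]),
        )
    weights = truth.abundance * tlen * usable
    p = weights / weights.sum()
    n = config.n_mrna_reads
    gene_idx = rng.choice(len(tids), size=n, p=p)

    lengths = rng.integers(frag_lo, frag_hi + 1, size=n)
    lengths = np.minimum(lengths, tlen[gene_idx])
    starts = np.floor(rng.random(n) * (tlen[gene_idx] - lengths + 1)).astype(np.int64)

    _write_sam(path, ann, seqs, "mr", tids, gene_idx, starts, lengths)


def simulate_term_annotation(
    truth: GroundTruth, config: SimulationConfig
) -> pd.DataFrame:
    """Build a gene->term table with one term enriched among high-TE genes.

    The designated term (``term_high_te``) is assigned to each gene in the
    top ``enriched_term_fraction`` of genes by true TE with probability
    0.8 and to other genes with probability 0.05, so enrichment of high-TE
    selections is detectable by construction. The remaining
    ``n_terms - 1`` background terms are assigned to uniformly random gene
    subsets. Membership is also recorded on ``truth.terms``.
    """
    config.validate()
    rng = _rng(config.seed, _STREAM_TERMS)
    genes = truth.gene_ids
    n = len(genes)

    rows: List[Tuple[str, str, str]] = []
    truth.terms = {g: set() for g in genes}

    order = np.argsort(-truth.true_te, kind="stable")
    n_top = int(round(config.enriched_term_fraction * n))
    top = set(np.asarray(genes)[order[:n_top]])
    designated = "term_high_te"
    truth.designated_term = designated
    for g in genes:
        p_in = 0.8 if g in top else 0.05
        if rng.random() < p_in:
            rows.append((g, designated, "high-TE module"))
            truth.terms[g].add(designated)

    for t in range(config.n_terms - 1):
        term_id = f"term_{t:03d}"
        size = int(rng.integers(max(2, n // 20), max(3, n // 2)))
        members = rng.choice(n, size=min(size, n), replace=False)
        for i in members:
            g = genes[int(i)]
            rows.append((g, term_id, f"background set {t}"))
            truth.terms[g].add(term_id)

    df = pd.DataFrame(rows, columns=["gene_id", "term_id", "term_name"])
    return df.sort_values(["term_id", "gene_id"], kind="stable").reset_index(drop=True)


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for tid in sorted(seqs):
            fh.write(f">{tid}\n")
            seq = seqs[tid]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_ground_truth_tsv(truth: GroundTruth, path: str | Path) -> None:
    truth.as_frame().to_csv(path, sep="\t", index=False)


def simulate_all(config: SimulationConfig, outdir: str | Path) -> Dict[str, Path]:
    """Run every simulation stage, writing the full fixture set to ``outdir``.

    Returns the paths of the emitted files: ``annotation`` (TSV),
    ``fasta``, ``footprints`` (SAM), ``total_mrna`` (SAM), ``terms`` (TSV)
    and ``ground_truth`` (TSV).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ann, seqs, truth = simulate_transcriptome(config)
    paths = {
        "annotation": outdir / "annotation.tsv",
        "fasta": outdir / "transcripts.fa",
        "footprints": outdir / "footprints.sam",
        "total_mrna": outdir / "total_mrna.sam",
        "terms": outdir / "terms.tsv",
        "ground_truth": outdir / "ground_truth.tsv",
    }
    write_annotation_tsv(ann, paths["annotation"])
    write_fasta(seqs, paths["fasta"])
    simulate_footprints(ann, seqs, truth, config, paths["footprints"])
    simulate_total_mrna(ann, seqs, truth, config, paths["total_mrna"])
    terms = simulate_term_annotation(truth, config)
    terms.to_csv(paths["terms"], sep="\t", index=False)
    write_ground_truth_tsv(truth, paths["ground_truth"])
    return paths
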