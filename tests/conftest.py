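"""Shared fixtures: a tiny hand-built annotation and a small simulated study.

All fixture data is generated programmatically; the simulated study is
session-scoped so the SAM round-trip (simulator -> text SAM -> pysam
ingestion) is paid once.
"""

import pandas as pd
import pytest

from riboprof.annotation_io import (
    AnnotationSet,
    TranscriptAnnotation,
    read_annotation_tsv,
)
from riboprof.read_ingest import read_alignments
from riboprof.synthetic_data import SimulationConfig, simulate_all


@pytest.fixture
def tiny_annotation() -> AnnotationSet:
    """Three genes; g2 has two isoforms to exercise representative choice."""
    txs = [
        TranscriptAnnotation("tx1", "g1", 600, 100, 403),
        TranscriptAnnotation("tx2", "g2", 500, 50, 350),
        TranscriptAnnotation("tx2b", "g2", 400, 20, 320),  # same CDS length as tx2
        TranscriptAnnotation("tx3", "g3", 200, 30, 90),
    ]
    return AnnotationSet({t.transcript_id: t for t in txs})


def write_sam(path, ann, records):
    """Write a minimal SAM: records are (qname, flag, tid, pos1, cigar, seq)."""
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for tid in sorted(ann.transcripts):
        lines.append(f"@SQ\tSN:{tid}\tLN:{ann[tid].length}")
    for qname, flag, tid, pos, cigar, seq in records:
        lines.append(f"{qname}\t{flag}\t{tid}\t{pos}\t255\t{cigar}\t*\t0\t0\t{seq}\t*")
    path.write_text("\n".join(lines) + "\n")
    return path


SMALL_CONFIG = SimulationConfig(
    n_genes=30, n_footprint_reads=8000, n_mrna_reads=8000, seed=11
)


@pytest.fixture(scope="session")
def small_study(tmp_path_factory):
    """A complete simulated study (files + loaded objects) at reduced scale."""
    outdir = tmp_path_factory.mktemp("small_study")
    paths = simulate_all(SMALL_CONFIG, outdir)
    ann = read_annotation_tsv(paths["annotation"])
    fp = read_alignments(paths["footprints"], ann, library_label="footprint")
    mrna = read_alignments(paths["total_mrna"], ann, library_label="total_mrna")
    truth = pd.read_csv(paths["ground_truth"], sep="\t").set_index("gene_id")
    return {
        "config": SMALL_CONFIG,
        "paths": paths,
        "ann": ann,
        "fp": fp,
        "mrna": mrna,
        "truth": truth,
    }
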