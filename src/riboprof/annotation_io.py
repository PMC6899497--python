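"""Transcript-coordinate annotation input/output.

All coordinates in this package are 0-based, half-open, in sense-strand
transcript space. ``cds_start`` is the first nucleotide of the start codon
and ``cds_end`` is one past the last nucleotide of the stop codon, so the
CDS *includes* the stop codon and its length is a multiple of 3. SAM's
1-based POS is converted at the ingestion boundary only (see
:mod:`riboprof.read_ingest`).

Two annotation formats are read:

* a simple TSV dialect with columns ``transcript_id``, ``gene_id``,
  ``length``, ``cds_start``, ``cds_end`` (header row mandatory, ``#``
  comment lines allowed, unknown extra columns ignored);
* a GTF dialect in which the seqname column holds the transcript id and
  ``exon`` / ``CDS`` features carry 1-based inclusive transcript-space
  coordinates. GTF CDS features exclude the stop codon and are extended by
  3 nt on read.

Each gene is assigned one representative transcript: the one with the
longest CDS, ties broken lexicographically by transcript id.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, Iterator, Mapping

from Bio import SeqIO

logger = logging.getLogger(__name__)

__all__ = [
    "TranscriptAnnotation",
    "AnnotationSet",
    "AnnotationError",
    "AnnotationFormatError",
    "AnnotationValidationError",
    "read_annotation_tsv",
    "write_annotation_tsv",
    "read_annotation_gtf",
    "read_transcript_fasta",
]

TSV_COLUMNS = ("transcript_id", "gene_id", "length", "cds_start", "cds_end")


class AnnotationError(ValueError):
    """Base class for annotation I/O failures."""


class AnnotationFormatError(AnnotationError):
    """File does not conform to the declared dialect (e.g. missing column)."""


class AnnotationValidationError(AnnotationError):
    """One or more records violate the annotation invariants.

    Attributes
    ----------
    rejected : list of (transcript_id, rule)
        Per-record report of every invariant violation found.
    """

    def __init__(self, message: str, rejected: list[tuple[str, str]] | None = None):
        super().__init__(message)
        self.rejected = rejected or []


@dataclass(frozen=True)
class TranscriptAnnotation:
    """CDS geometry of one transcript, 0-based half-open transcript coords."""

    transcript_id: str
    gene_id: str
    length: int
    cds_start: int
    cds_end: int

    @property
    def cds_length(self) -> int:
        return self.cds_end - self.cds_start

    def violations(self) -> list[str]:
        """Return the list of invariant rules this record violates (empty if valid)."""
        rules = []
        if not (0 <= self.cds_start < self.cds_end <= self.length):
            rules.append("0 <= cds_start < cds_end <= length")
        if (self.cds_end - self.cds_start) % 3 != 0:
            rules.append("CDS length multiple of 3")
        if self.cds_end - self.cds_start < 6:
            rules.append("CDS length >= 6 (start + stop codon)")
        return rules


class AnnotationSet:
    """A validated collection of transcripts with one representative per gene."""

    def __init__(
        self,
        transcripts: Mapping[str, TranscriptAnnotation],
        gene_to_transcript: Mapping[str, str] | None = None,
    ):
        self.transcripts: Dict[str, TranscriptAnnotation] = dict(transcripts)
        if gene_to_transcript is None:
            gene_to_transcript = self._pick_representatives(self.transcripts.values())
        for gene, tid in gene_to_transcript.items():
            if tid not in self.transcripts:
                raise AnnotationValidationError(
                    f"representative transcript {tid!r} for gene {gene!r} "
                    "is not in the transcript set"
                )
        self.gene_to_transcript: Dict[str, str] = dict(gene_to_transcript)

    @staticmethod
    def _pick_representatives(
        transcripts: Iterable[TranscriptAnnotation],
    ) -> Dict[str, str]:
        # longest CDS wins; ties broken lexicographically by transcript_id
        best: Dict[str, TranscriptAnnotation] = {}
        for tx in transcripts:
            cur = best.get(tx.gene_id)
            if (
                cur is None
                or tx.cds_length > cur.cds_length
                or (tx.cds_length == cur.cds_length and tx.transcript_id < cur.transcript_id)
            ):
                best[tx.gene_id] = tx
        return {gene: tx.transcript_id for gene, tx in sorted(best.items())}

    def representative(self, gene_id: str) -> TranscriptAnnotation:
        return self.transcripts[self.gene_to_transcript[gene_id]]

    @property
    def genes(self) -> list[str]:
        return sorted(self.gene_to_transcript)

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self) -> Iterator[TranscriptAnnotation]:
        return iter(self.transcripts.values())

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self.transcripts

    def __getitem__(self, transcript_id: str) -> TranscriptAnnotation:
        return self.transcripts[transcript_id]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationSet):
            return NotImplemented
        return (
            self.transcripts == other.transcripts
            and self.gene_to_transcript == other.gene_to_transcript
        )


def _build_set(records: list[TranscriptAnnotation]) -> AnnotationSet:
    rejected: list[tuple[str, str]] = []
    seen: set[str] = set()
    valid: Dict[str, TranscriptAnnotation] = {}
    for tx in records:
        rules = tx.violations()
        if tx.transcript_id in seen:
            rules.append("transcript_id unique")
        seen.add(tx.transcript_id)
        if rules:
            rejected.extend((tx.transcript_id, rule) for rule in rules)
        else:
            valid[tx.transcript_id] = tx
    if rejected:
        detail = "; ".join(f"{tid}: {rule}" for tid, rule in rejected)
        raise AnnotationValidationError(
            f"{len({t for t, _ in rejected})} transcript(s) rejected ({detail})",
            rejected=rejected,
        )
    return AnnotationSet(valid)


def read_annotation_tsv(path: str | Path) -> AnnotationSet:
    """Read the annotation TSV dialect into an :class:`AnnotationSet`.

    Raises
    ------
    AnnotationFormatError
        If the header is missing a required column.
    AnnotationValidationError
        If any row violates a transcript invariant; the exception lists
        every rejected transcript and the rule it broke.
    """
    path = Path(path)
    records: list[TranscriptAnnotation] = []
    header: list[str] | None = None
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                missing = [c for c in TSV_COLUMNS if c not in header]
                if missing:
                    raise AnnotationFormatError(
                        f"{path}: missing required column(s): {', '.join(missing)}"
                    )
                idx = {c: header.index(c) for c in TSV_COLUMNS}
                continue
            try:
                records.append(
                    TranscriptAnnotation(
                        transcript_id=fields[idx["transcript_id"]],
                        gene_id=fields[idx["gene_id"]],
                        length=int(fields[idx["length"]]),
                        cds_start=int(fields[idx["cds_start"]]),
                        cds_end=int(fields[idx["cds_end"]]),
                    )
                )
            except (IndexError, ValueError) as exc:
                raise AnnotationFormatError(f"{path}: malformed row {line!r}") from exc
    if header is None:
        raise AnnotationFormatError(f"{path}: empty file (header row required)")
    return _build_set(records)


def write_annotation_tsv(ann: AnnotationSet, path: str | Path) -> None:
    """Write an :class:`AnnotationSet` in the TSV dialect (sorted by transcript id)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(TSV_COLUMNS) + "\n")
        for tid in sorted(ann.transcripts):
            tx = ann.transcripts[tid]
            fh.write(
                f"{tx.transcript_id}\t{tx.gene_id}\t{tx.length}"
                f"\t{tx.cds_start}\t{tx.cds_end}\n"
            )


_GENE_ID_RE = re.compile(r'gene_id\s+"([^"]+)"')


def read_annotation_gtf(path: str | Path) -> AnnotationSet:
    """Read the transcript-space GTF dialect.

    seqname = transcript id; ``exon`` features define the transcript length
    (max exon end); the CDS span is min CDS start .. max CDS end + 3 nt for
    the stop codon. 1-based inclusive [s, e] maps to 0-based half-open
    [s-1, e). Transcripts with no CDS feature are skipped with a warning;
    overlapping CDS records for one transcript are a validation error.
    """
    path = Path(path)
    exon_end: Dict[str, int] = {}
    cds_spans: Dict[str, list[tuple[int, int]]] = {}
    gene_of: Dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise AnnotationFormatError(f"{path}:{lineno}: expected 9 GTF columns")
            tid, _, feature, start, end = fields[0], fields[1], fields[2], fields[3], fields[4]
            attrs = fields[8]
            m = _GENE_ID_RE.search(attrs)
            if m:
                gene_of.setdefault(tid, m.group(1))
            s, e = int(start) - 1, int(end)  # to 0-based half-open
            if feature == "exon":
                exon_end[tid] = max(exon_end.get(tid, 0), e)
            elif feature == "CDS":
                cds_spans.setdefault(tid, []).append((s, e))

    records: list[TranscriptAnnotation] = []
    for tid in sorted(set(exon_end) | set(cds_spans)):
        spans = cds_spans.get(tid)
        if not spans:
            logger.warning("transcript %s has no CDS feature; skipped", tid)
            continue
        spans = sorted(spans)
        for (s1, e1), (s2, _) in zip(spans, spans[1:]):
            if s2 < e1:
                raise AnnotationValidationError(
                    f"{tid}: overlapping CDS records [{s1},{e1}) and starting at {s2}"
                )
        if tid not in gene_of:
            raise AnnotationFormatError(f"{path}: transcript {tid} has no gene_id attribute")
        cds_start = spans[0][0]
        cds_end = spans[-1][1] + 3  # append the stop codon
        length = max(exon_end.get(tid, 0), cds_end)
        records.append(
            TranscriptAnnotation(
                transcript_id=tid,
                gene_id=gene_of[tid],
                length=length,
                cds_start=cds_start,
                cds_end=cds_end,
            )
        )
    return _build_set(records)


def read_transcript_fasta(path: str | Path, ann: AnnotationSet) -> Dict[str, str]:
    """Read transcript sequences, validating lengths against the annotation.

    Returns a mapping transcript_id -> uppercase sequence. Records in the
    FASTA but not in the annotation are ignored with a warning; an annotated
    transcript that is absent, or whose sequence length disagrees with the
    annotated length, is a validation error.
    """
    seqs: Dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id not in ann:
            logger.warning("FASTA record %s not in annotation; ignored", record.id)
            continue
        seq = str(record.seq).upper()
        expected = ann[record.id].length
        if len(seq) != expected:
            raise AnnotationValidationError(
                f"{record.id}: FASTA sequence length {len(seq)} != annotated {expected}"
            )
        seqs[record.id] = seq
    missing = sorted(set(ann.transcripts) - set(seqs))
    if missing:
        raise AnnotationValidationError(
            f"annotated transcript(s) missing from FASTA: {', '.join(missing[:10])}"
        )
    return seqs
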