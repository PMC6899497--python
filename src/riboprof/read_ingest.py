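"""SAM/BAM ingestion: alignments -> validated 5'-end records.

Reads aligned against transcript references are reduced to weighted
(transcript, 5' position, length) records in 0-based transcript
coordinates. Only primary, mapped, forward-strand alignments are retained;
everything else is dropped (not errored) with a per-reason counter, since
footprints align sense to their transcript and silently discarding reads
would hide library problems. Reads with more than 2 nt soft-clipped on the
5' side are dropped as well: 5'-end precision is what the downstream
metagene analysis rests on. An alignment to a reference absent from the
annotation is a hard error — it means the wrong annotation was paired with
the alignments.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pysam

from .annotation_io import AnnotationSet

logger = logging.getLogger(__name__)

__all__ = ["FootprintRecord", "FootprintSet", "IngestError", "read_alignments", "filter_by_length"]


class IngestError(ValueError):
    """Unrecoverable problem with an alignment file."""


@dataclass(frozen=True)
class FootprintRecord:
    """One retained alignment: transcript, 0-based 5' end, length, weight."""

    transcript_id: str
    five_prime: int
    length: int
    weight: float = 1.0


@dataclass
class FootprintSet:
    """Column-oriented collection of retained alignments for one library.

    ``transcript_ids``/``five_prime``/``length``/``weight`` are parallel
    arrays; ``mapped_total`` is the number of retained alignments and
    serves as the million-mapped-reads denominator in RPKM.
    """

    transcript_ids: np.ndarray  # dtype object/str
    five_prime: np.ndarray  # int
    length: np.ndarray  # int
    weight: np.ndarray  # float
    library_label: str = "footprint"  # "footprint" | "total_mrna"
    drop_counts: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.five_prime)
        if not (len(self.transcript_ids) == len(self.length) == len(self.weight) == n):
            raise ValueError("FootprintSet columns must have equal length")

    @property
    def mapped_total(self) -> int:
        return len(self.five_prime)

    def __len__(self) -> int:
        return self.mapped_total

    def records(self):
        """Iterate as :class:`FootprintRecord` (for small sets / tests)."""
        for tid, fp, ln, w in zip(
            self.transcript_ids, self.five_prime, self.length, self.weight
        ):
            yield FootprintRecord(str(tid), int(fp), int(ln), float(w))

    def drop_report_json(self) -> str:
        return json.dumps(dict(sorted(self.drop_counts.items())), indent=2)


def read_alignments(
    path: str | Path,
    ann: AnnotationSet,
    length_bounds: Optional[Tuple[int, int]] = None,
    library_label: str = "footprint",
    max_5p_softclip: int = 2,
) -> FootprintSet:
    """Load a SAM/BAM file of transcript-space alignments.

    Parameters
    ----------
    path
        SAM or BAM file whose reference names are transcript ids of ``ann``.
    length_bounds
        Optional (lo, hi) inclusive bounds on aligned read length; reads
        outside are dropped and counted under ``length_out_of_bounds``.
    library_label
        "footprint" or "total_mrna"; carried on the returned set.
    max_5p_softclip
        Reads with more than this many nt soft-clipped on the 5' side are
        dropped (counter ``softclip_5p``).

    The 5' end is SAM POS - 1 (pysam's ``reference_start``). Drop reasons
    are tallied on the returned set's ``drop_counts``.
    """
    if library_label not in ("footprint", "total_mrna"):
        raise ValueError(f"unknown library_label {library_label!r}")
    path = Path(path)
    tids: list = []
    fives: list = []
    lengths: list = []
    drops: Dict[str, int] = {}

    def drop(reason: str) -> None:
        drops[reason] = drops.get(reason, 0) + 1

    mode = "rb" if path.suffix == ".bam" else "r"
    try:
        handle = pysam.AlignmentFile(str(path), mode, check_sq=False)
    except (OSError, ValueError) as exc:
        raise IngestError(f"{path}: cannot open alignments: {exc}") from exc
    with handle:
        for i, aln in enumerate(handle.fetch(until_eof=True)):
            if aln.is_unmapped:
                drop("unmapped")
                continue
            if aln.is_secondary:
                drop("secondary")
                continue
            if aln.is_supplementary:
                drop("supplementary")
                continue
            if aln.is_reverse:
                drop("reverse_strand")
                continue
            tid = aln.reference_name
            if tid not in ann:
                raise IngestError(
                    f"{path}: alignment record {i + 1} maps to reference "
                    f"{tid!r} absent from the annotation (wrong annotation "
                    "paired with these alignments?)"
                )
            cigar = aln.cigartuples
            if cigar and cigar[0][0] == 4 and cigar[0][1] > max_5p_softclip:
                drop("softclip_5p")
                continue
            five = aln.reference_start
            length = aln.query_alignment_length
            if length <= 0:
                raise IngestError(f"{path}: record {i + 1} has no aligned bases")
            if five + length > ann[tid].length:
                drop("exceeds_transcript")
                continue
            if length_bounds is not None and not (
                length_bounds[0] <= length <= length_bounds[1]
            ):
                drop("length_out_of_bounds")
                continue
            tids.append(tid)
            fives.append(five)
            lengths.append(length)

    n = len(fives)
    if drops:
        logger.info("%s: dropped %s", path.name, dict(sorted(drops.items())))
    return FootprintSet(
        transcript_ids=np.asarray(tids, dtype=object),
        five_prime=np.asarray(fives, dtype=np.int64),
        length=np.asarray(lengths, dtype=np.int64),
        weight=np.ones(n),
        library_label=library_label,
        drop_counts=drops,
    )


def filter_by_length(fs: FootprintSet, lo: int, hi: int) -> FootprintSet:
    """Retain records with lo <= length <= hi (in-silico gel size selection)."""
    if lo > hi:
        raise ValueError(f"invalid length bounds: lo={lo} > hi={hi}")
    mask = (fs.length >= lo) & (fs.length <= hi)
    return FootprintSet(
        transcript_ids=fs.transcript_ids[mask],
        five_prime=fs.five_prime[mask],
        length=fs.length[mask],
        weight=fs.weight[mask],
        library_label=fs.library_label,
        drop_counts=dict(fs.drop_counts),
    )
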