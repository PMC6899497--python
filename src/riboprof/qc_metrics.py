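"""Footprint quality-control statistics.

The four canonical Ribo-seq QC views of a library:

* read-length distribution (footprints peak sharply at 28-30 nt; a
  randomly fragmented total-mRNA control does not);
* reading-frame usage of 5' ends relative to the annotated start codon
  (elongating ribosomes step in codons, so genuine footprints concentrate
  in frame 1);
* metagene profiles — 5'-end counts aggregated over transcripts against
  displacement from the start or stop codon, where the initiating
  ribosome's 5' peak sits ~12 nt upstream of the start codon and density
  dies ~15 nt upstream of the stop codon;
* a periodicity score and a P-site offset estimate derived from those
  profiles.

Frame labels are 1-based (frame 1 = 5' end in phase with the start codon)
to match the field's plotting convention; internally frames are
non-negative remainders mod 3. Frame counting admits 5' ends up to 12 nt
upstream of the start codon, since an initiating ribosome's footprint
legitimately begins there; reads outside [cds_start - 12, cds_end) are
excluded from frame counts and tallied separately.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Tuple

import numpy as np
import pandas as pd

from .annotation_io import AnnotationSet
from .read_ingest import FootprintSet

__all__ = [
    "LengthHistogram",
    "FrameUsage",
    "MetageneProfile",
    "QCError",
    "length_distribution",
    "frame_usage",
    "metagene",
    "periodicity_score",
    "estimate_psite_offset",
    "qc_report",
]

FRAME_UPSTREAM_MARGIN = 12  # admit initiating-ribosome 5' ends upstream of the start
OFFSET_SEARCH_WINDOW = (-18, -6)  # inclusive; brackets plausible eukaryotic offsets


class QCError(ValueError):
    """A QC statistic is undefined for the given input."""


@dataclass
class LengthHistogram:
    counts: Dict[int, int]
    total: int

    @property
    def mode(self) -> int:
        """Modal read length; ties broken toward the shorter length."""
        return max(self.counts, key=lambda l: (self.counts[l], -l))

    def to_frame(self) -> pd.DataFrame:
        lengths = sorted(self.counts)
        return pd.DataFrame({"length": lengths, "count": [self.counts[l] for l in lengths]})


@dataclass
class FrameUsage:
    counts: Tuple[int, int, int]  # frames 1..3
    fractions: Tuple[float, float, float]
    n_excluded: int = 0  # 5' ends outside [cds_start - 12, cds_end)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"frame": [1, 2, 3], "count": self.counts, "fraction": self.fractions}
        )


@dataclass
class MetageneProfile:
    """5'-end counts by signed displacement from an anchor codon.

    Displacement 0 is the first nucleotide of the anchor codon (start
    codon, or stop codon for ``anchor="stop_codon"``).
    """

    anchor: str  # "start_codon" | "stop_codon"
    displacements: np.ndarray  # strictly increasing, contiguous
    counts: np.ndarray  # float (may be normalized)

    def __post_init__(self) -> None:
        d = np.asarray(self.displacements)
        if len(d) == 0 or not np.all(np.diff(d) == 1):
            raise QCError("displacements must be contiguous and non-empty")

    def count_at(self, d: int) -> float:
        i = int(d) - int(self.displacements[0])
        if not 0 <= i < len(self.counts):
            raise KeyError(f"displacement {d} outside profile window")
        return float(self.counts[i])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"displacement": self.displacements, "count": self.counts})


def length_distribution(fs: FootprintSet) -> LengthHistogram:
    """Exact per-length read counts."""
    if fs.mapped_total == 0:
        raise QCError("cannot compute a length distribution of an empty library")
    lengths, counts = np.unique(fs.length, return_counts=True)
    return LengthHistogram(
        counts={int(l): int(c) for l, c in zip(lengths, counts)},
        total=int(counts.sum()),
    )


def _annot_arrays(fs: FootprintSet, ann: AnnotationSet, fields: Tuple[str, ...]) -> list:
    """Per-record annotation columns aligned to the FootprintSet arrays."""
    missing = set(map(str, np.unique(fs.transcript_ids))) - set(ann.transcripts)
    if missing:
        raise QCError(f"transcript(s) not in annotation: {sorted(missing)[:5]}")
    tid_series = pd.Series(fs.transcript_ids)
    out = []
    for name in fields:
        lut = {tid: getattr(tx, name) for tid, tx in ann.transcripts.items()}
        out.append(tid_series.map(lut).to_numpy(dtype=np.int64))
    return out


def frame_usage(fs: FootprintSet, ann: AnnotationSet) -> FrameUsage:
    """Reading-frame usage of 5' ends relative to the start codon.

    Frame label = ((five_prime - cds_start) mod 3) + 1 for reads whose 5'
    end lies in [cds_start - 12, cds_end); the mod is non-negative, so a
    5' end 12 nt upstream of the start codon is frame 1.
    """
    if fs.mapped_total == 0:
        raise QCError("empty library")
    cds_start, cds_end = _annot_arrays(fs, ann, ("cds_start", "cds_end"))
    in_span = (fs.five_prime >= cds_start - FRAME_UPSTREAM_MARGIN) & (
        fs.five_prime < cds_end
    )
    frames = np.mod(fs.five_prime[in_span] - cds_start[in_span], 3)
    counts = np.bincount(frames, minlength=3)
    total = counts.sum()
    fractions = counts / total if total > 0 else np.zeros(3)
    return FrameUsage(
        counts=tuple(int(c) for c in counts),
        fractions=tuple(float(f) for f in fractions),
        n_excluded=int(fs.mapped_total - in_span.sum()),
    )


def metagene(
    fs: FootprintSet,
    ann: AnnotationSet,
    anchor: str = "start_codon",
    window: Tuple[int, int] = (-40, 20),
    normalize: str = "raw",
) -> MetageneProfile:
    """Aggregate 5'-end counts by displacement from the start or stop codon.

    ``window`` is half-open [lo, hi) in nt. The anchor position is
    ``cds_start`` for ``start_codon`` and ``cds_end - 3`` (first nt of the
    stop codon) for ``stop_codon``. With ``normalize="per_transcript_mean"``
    each transcript's contribution is divided by its mean CDS 5'-end
    density, so a handful of highly expressed genes cannot dominate the
    aggregate; transcripts with no CDS reads then contribute nothing.
    Positions of the window that fall outside a transcript contribute
    nothing for that transcript.
    """
    lo, hi = window
    if lo >= hi:
        raise QCError(f"empty metagene window ({lo}, {hi})")
    if anchor not in ("start_codon", "stop_codon"):
        raise QCError(f"unknown anchor {anchor!r}")
    if normalize not in ("raw", "per_transcript_mean"):
        raise QCError(f"unknown normalization {normalize!r}")

    cds_start, cds_end, tlen = _annot_arrays(fs, ann, ("cds_start", "cds_end", "length"))
    anchor_pos = cds_start if anchor == "start_codon" else cds_end - 3
    disp = fs.five_prime - anchor_pos
    in_window = (disp >= lo) & (disp < hi)

    weights = fs.weight.astype(float)
    if normalize == "per_transcript_mean":
        in_cds = (fs.five_prime >= cds_start) & (fs.five_prime < cds_end)
        df = pd.DataFrame(
            {
                "tid": fs.transcript_ids,
                "w": np.where(in_cds, fs.weight, 0.0),
                "cds_len": cds_end - cds_start,
            }
        )
        per_tx = df.groupby("tid", sort=False).agg(w=("w", "sum"), cds_len=("cds_len", "first"))
        density = (per_tx["w"] / per_tx["cds_len"]).to_dict()
        scale = pd.Series(fs.transcript_ids).map(density).to_numpy(dtype=float)
        with np.errstate(divide="ignore"):
            weights = np.where(scale > 0, fs.weight / scale, 0.0)

    displacements = np.arange(lo, hi)
    counts = np.zeros(hi - lo, dtype=float)
    np.add.at(counts, disp[in_window] - lo, weights[in_window])
    return MetageneProfile(anchor=anchor, displacements=displacements, counts=counts)


def periodicity_score(profile: MetageneProfile, span: Tuple[int, int]) -> float:
    """Fraction of metagene signal in the dominant frame over ``span``.

    ``span`` is half-open [lo, hi) in displacement units and must lie
    within the profile. The score is max over r in {0,1,2} of the mass at
    displacements congruent to r mod 3, divided by the total mass in the
    span: 1/3 for a frame-uniform signal, 1.0 for a perfectly periodic one.
    Invariant under uniform scaling and under cyclic 3-nt shifts of the span.
    """
    lo, hi = span
    if lo >= hi:
        raise QCError("empty span")
    if lo < profile.displacements[0] or hi > profile.displacements[-1] + 1:
        raise QCError("span outside profile window")
    sel = (profile.displacements >= lo) & (profile.displacements < hi)
    d = profile.displacements[sel]
    c = profile.counts[sel]
    total = c.sum()
    if total <= 0:
        raise QCError("zero total counts in span: periodicity undefined")
    by_frame = [c[np.mod(d, 3) == r].sum() for r in (0, 1, 2)]
    return float(max(by_frame) / total)


def estimate_psite_offset(
    profile: MetageneProfile,
    search: Tuple[int, int] = OFFSET_SEARCH_WINDOW,
    rise_fraction: float = 0.5,
) -> int:
    """Estimate the 5'-end -> P-site offset from a start-anchored metagene.

    Footprint 5' ends begin exactly one offset upstream of the first
    occupied P-site codon (the start codon), so the offset is identified
    by the onset of 5'-end density: the most upstream displacement d in
    the inclusive search window (default [-18, -6], bracketing plausible
    eukaryotic offsets) whose count reaches ``rise_fraction`` of the
    window maximum. Returns -d; the expected value for a mammalian
    library is +12. The half-maximum criterion makes the onset robust to
    the +-1 nt jitter counts just upstream of the true edge, and on
    libraries with a dominant initiation peak the onset coincides with
    that peak.
    """
    if profile.anchor != "start_codon":
        raise QCError("P-site offset estimation requires a start-anchored profile")
    if not (0.0 < rise_fraction <= 1.0):
        raise QCError("rise_fraction must be in (0, 1]")
    lo, hi = search
    if profile.displacements[0] > lo or profile.displacements[-1] < hi:
        raise QCError(
            f"profile window must cover displacements [{lo}, {hi}] for offset estimation"
        )
    candidates = np.arange(lo, hi + 1)
    counts = np.array([profile.count_at(d) for d in candidates])
    if counts.max() <= 0:
        raise QCError("all-zero offset search window")
    onset = candidates[counts >= rise_fraction * counts.max()][0]
    return int(-onset)


def qc_report(
    fs: FootprintSet,
    ann: AnnotationSet,
    window: Tuple[int, int] = (-40, 20),
    outdir: str | Path | None = None,
) -> dict:
    """Compute all QC metrics; optionally write TSVs + a JSON report.

    Returns a dict with the length histogram, frame usage, start/stop
    metagenes, periodicity score over the in-CDS portion of the window,
    and the estimated P-site offset.
    """
    hist = length_distribution(fs)
    frames = frame_usage(fs, ann)
    start_prof = metagene(fs, ann, "start_codon", window)
    stop_prof = metagene(fs, ann, "stop_codon", window)
    span = (max(0, window[0]), window[1] - (window[1] - max(0, window[0])) % 3)
    period = periodicity_score(start_prof, span) if span[0] < span[1] else None
    offset = estimate_psite_offset(start_prof)
    report = {
        "library_label": fs.library_label,
        "mapped_total": fs.mapped_total,
        "drop_counts": fs.drop_counts,
        "modal_length": hist.mode,
        "frame_counts": list(frames.counts),
        "frame_fractions": list(frames.fractions),
        "frame_excluded": frames.n_excluded,
        "periodicity_score": period,
        "estimated_offset": offset,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        hist.to_frame().to_csv(outdir / "length_histogram.tsv", sep="\t", index=False)
        frames.to_frame().to_csv(outdir / "frame_usage.tsv", sep="\t", index=False)
        start_prof.to_frame().to_csv(outdir / "metagene_start.tsv", sep="\t", index=False)
        stop_prof.to_frame().to_csv(outdir / "metagene_stop.tsv", sep="\t", index=False)
        with open(outdir / "qc_report.json", "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2)
    return report
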