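"""Gene-level quantification: counts, RPKM, translational efficiency.

Footprint reads are assigned to a gene when their inferred P-site
(5' end + offset) lies in a sense codon of the gene's representative
transcript, i.e. in [cds_start, cds_end - 3); the stop codon is never a
P-site of an elongating ribosome. Total-mRNA reads are assigned anywhere
on the representative transcript. RPKM = count * 1e9 / (mapped_total *
length), with the CDS length normalizing footprints and the full
transcript length normalizing total mRNA. Translational efficiency (TE)
is the per-gene ratio footprint RPKM / total-mRNA RPKM, left undefined
for genes below a minimum mRNA count (default 10) because an RPKM ratio
is unstable at small denominators.
"""

from __future__ import annotations

import logging
import warnings
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .annotation_io import AnnotationSet
from .read_ingest import FootprintSet

logger = logging.getLogger(__name__)

__all__ = [
    "count_per_gene",
    "rpkm",
    "build_gene_quant_table",
    "translational_efficiency",
    "top_n",
    "overlap",
    "QuantError",
]

DEFAULT_MIN_MRNA_COUNT = 10


class QuantError(ValueError):
    """Invalid quantification input."""


def count_per_gene(
    fs: FootprintSet, ann: AnnotationSet, offset: Optional[int] = None
) -> pd.Series:
    """Per-gene read counts on representative transcripts.

    For a footprint library, ``offset`` (nt, non-negative) is required and
    a read counts toward a gene iff its inferred P-site ``five_prime +
    offset`` falls in [cds_start, cds_end - 3). For a total-mRNA library
    the offset is ignored and every read on the representative transcript
    counts. Reads aligned to non-representative transcripts are not
    counted. Returns an integer Series over all annotated genes (zeros
    included), sorted by gene id.
    """
    genes = ann.genes
    rep_tid = {ann.gene_to_transcript[g]: g for g in genes}

    is_fp = fs.library_label == "footprint"
    if is_fp:
        if offset is None:
            raise QuantError("footprint counting requires a P-site offset")
        if offset < 0:
            raise QuantError(f"negative P-site offset: {offset}")

    counts: Dict[str, int] = {g: 0 for g in genes}
    tid_series = pd.Series(fs.transcript_ids)
    on_rep = tid_series.isin(rep_tid).to_numpy()
    if on_rep.any():
        tids = tid_series[on_rep]
        fives = fs.five_prime[on_rep]
        if is_fp:
            cs = tids.map({t: ann[t].cds_start for t in rep_tid}).to_numpy(np.int64)
            ce = tids.map({t: ann[t].cds_end for t in rep_tid}).to_numpy(np.int64)
            psite = fives + offset
            keep = (psite >= cs) & (psite < ce - 3)
        else:
            keep = np.ones(len(fives), dtype=bool)  # 0 <= five_prime < length by invariant
        gene_counts = tids[keep].map(rep_tid).value_counts()
        for g, c in gene_counts.items():
            counts[g] = int(c)
    return pd.Series(counts, name=f"{fs.library_label}_count").sort_index()


def rpkm(count, length_nt, mapped_total):
    """Reads per kilobase of feature per million mapped reads.

    ``count * 1e9 / (mapped_total * length_nt)``; accepts scalars or
    aligned arrays. Zero/negative length or mapped total is an error.
    """
    length_nt = np.asarray(length_nt)
    if np.any(length_nt <= 0):
        raise QuantError("length_nt must be positive")
    if np.any(np.asarray(mapped_total) <= 0):
        raise QuantError("mapped_total must be positive")
    out = np.asarray(count) * 1e9 / (np.asarray(mapped_total) * length_nt)
    return float(out) if np.ndim(out) == 0 else out


def build_gene_quant_table(
    fp_fs: FootprintSet,
    mrna_fs: FootprintSet,
    ann: AnnotationSet,
    offset: int,
    min_mrna_count: int = DEFAULT_MIN_MRNA_COUNT,
) -> pd.DataFrame:
    """Assemble the per-gene quantification table with RPKM and TE.

    Columns: ``fp_count``, ``mrna_count``, ``fp_rpkm`` (CDS-length
    normalized), ``mrna_rpkm`` (transcript-length normalized), ``te``
    (NaN where undefined), ``fp_length_used``, ``mrna_length_used``.
    Indexed by gene id.
    """
    fp_counts = count_per_gene(fp_fs, ann, offset=offset)
    mrna_counts = count_per_gene(mrna_fs, ann)
    genes = fp_counts.index
    cds_len = pd.Series({g: ann.representative(g).cds_length for g in genes})
    tx_len = pd.Series({g: ann.representative(g).length for g in genes})
    df = pd.DataFrame(
        {
            "fp_count": fp_counts,
            "mrna_count": mrna_counts,
            "fp_length_used": cds_len,
            "mrna_length_used": tx_len,
        }
    )
    df["fp_rpkm"] = rpkm(df["fp_count"], df["fp_length_used"], fp_fs.mapped_total)
    df["mrna_rpkm"] = rpkm(df["mrna_count"], df["mrna_length_used"], mrna_fs.mapped_total)
    return translational_efficiency(df, min_mrna_count=min_mrna_count)


def translational_efficiency(
    q: pd.DataFrame, min_mrna_count: int = DEFAULT_MIN_MRNA_COUNT
) -> pd.DataFrame:
    """Fill the ``te`` column: fp_rpkm / mrna_rpkm where mRNA support suffices.

    Genes with ``mrna_count < min_mrna_count`` get ``te = NaN`` and are
    thereby excluded from TE rankings; the exclusion count is logged.
    """
    q = q.copy()
    defined = q["mrna_count"] >= min_mrna_count
    with np.errstate(divide="ignore", invalid="ignore"):
        te = q["fp_rpkm"] / q["mrna_rpkm"]
    q["te"] = te.where(defined & (q["mrna_rpkm"] > 0))
    n_excluded = int((~defined).sum())
    if n_excluded:
        logger.info(
            "TE undefined for %d gene(s) with mrna_count < %d", n_excluded, min_mrna_count
        )
    return q


def top_n(values: Mapping[str, float] | pd.Series, n: int) -> List[str]:
    """The n genes with the largest defined values, descending.

    Ties are broken lexicographically by gene id (stable). NaN values are
    treated as undefined and never selected. If fewer than n genes have
    defined values, all of them are returned with a warning.
    """
    if n <= 0:
        raise QuantError(f"n must be >= 1, got {n}")
    series = pd.Series(values).dropna()
    ranked = sorted(series.items(), key=lambda kv: (-kv[1], kv[0]))
    if len(ranked) < n:
        warnings.warn(
            f"requested top {n} but only {len(ranked)} genes have defined values",
            stacklevel=2,
        )
    return [g for g, _ in ranked[:n]]


def _normalize_ids(ids: Iterable[str]) -> set:
    return {str(g).strip().upper() for g in ids}


def overlap(list_a: Sequence[str], list_b: Sequence[str]) -> Tuple[int, float]:
    """Size and fraction of A's members also in B.

    Identifiers are compared after uppercasing and whitespace stripping;
    the fraction is relative to the first list (the caller's own list).
    """
    if not list_a or not list_b:
        raise QuantError("overlap requires two non-empty gene lists")
    a = _normalize_ids(list_a)
    b = _normalize_ids(list_b)
    count = len(a & b)
    return count, count / len(a)
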