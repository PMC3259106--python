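"""Recursive partitioning of CNV probes into correlated chromosomal segments.

Adjacent CGH probes tend to co-vary because amplifications and deletions span
contiguous chromosomal regions.  Each chromosome's ordered probe matrix is
split recursively at the weakest adjacent-probe correlation until every
emitted segment is internally coherent; the segment CNV profile is the mean
over its member probes and is then quantized like any continuous feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dataio import FeatureTrack


@dataclass
class Segment:
    """A contiguous run of CNV probes with a per-sample mean profile."""

    segment_id: str
    chromosome: str
    probe_range: tuple[int, int]           # half-open index range, genomic order
    probe_ids: tuple[str, ...]
    profile: np.ndarray                    # per-sample mean CNV
    span: tuple[int, int] | None = None    # genomic span (min start, max end)
    member_genes: tuple[str, ...] = ()

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)


def _pairwise_min_corr(x: np.ndarray) -> float:
    """Minimum pairwise Pearson correlation over the rows of ``x``.

    The minimum (rather than the mean) is used as the coherence statistic:
    a segment is emitted only when every probe pair co-varies, which keeps a
    block containing two independent latent signals from slipping through
    when their chance correlation drifts positive.
    """
    if x.shape[0] < 2:
        return 1.0
    with np.errstate(invalid="ignore"):
        c = np.corrcoef(x)
    iu = np.triu_indices(x.shape[0], k=1)
    vals = c[iu]
    vals = np.where(np.isfinite(vals), vals, 0.0)
    return float(vals.min())


def _adjacent_corr(x: np.ndarray) -> np.ndarray:
    """Pearson correlation between each adjacent probe pair (length k-1)."""
    out = np.empty(x.shape[0] - 1)
    for i in range(x.shape[0] - 1):
        a, b = x[i], x[i + 1]
        ok = np.isfinite(a) & np.isfinite(b)
        if ok.sum() < 3 or np.std(a[ok]) == 0 or np.std(b[ok]) == 0:
            out[i] = 0.0
        else:
            out[i] = np.corrcoef(a[ok], b[ok])[0, 1]
    return out


def partition_chromosome(probes: np.ndarray, min_corr: float = 0.5,
                         min_probes: int = 1) -> list[tuple[int, int]]:
    """Partition ordered probes into half-open index ranges.

    A block is emitted when it has at most ``min_probes`` probes or its
    minimum pairwise correlation reaches ``min_corr``; otherwise it is split between
    the adjacent pair with the weakest correlation (leftmost on ties) and
    both halves are partitioned recursively.
    """
    probes = np.asarray(probes, dtype=float)
    if probes.ndim != 2:
        raise ValueError("expected a probe-by-sample matrix")
    k = probes.shape[0]
    if k == 0:
        return []
    if probes.shape[1] < 2:
        raise ValueError("need at least 2 samples")

    ranges: list[tuple[int, int]] = []

    def recurse(lo: int, hi: int) -> None:
        block = probes[lo:hi]
        if hi - lo <= min_probes or _pairwise_min_corr(block) >= min_corr:
            ranges.append((lo, hi))
            return
        adj = _adjacent_corr(block)
        cut = int(np.argmin(adj)) + 1      # leftmost minimal pair
        recurse(lo, lo + cut)
        recurse(lo + cut, hi)

    recurse(0, k)
    return ranges


def segment_profile(probes: np.ndarray) -> np.ndarray:
    """Per-sample mean over member probes, skipping missing probe values."""
    probes = np.asarray(probes, dtype=float)
    if probes.size == 0:
        raise ValueError("empty segment")
    present = np.isfinite(probes).sum(axis=0)
    out = np.full(probes.shape[1], np.nan)
    cols = present > 0      # a sample missing in all probes stays missing
    if cols.any():
        out[cols] = np.nansum(probes[:, cols], axis=0) / present[cols]
    return out


def build_segments(cnv: pd.DataFrame,
                   annotations: Mapping[str, FeatureTrack],
                   min_corr: float = 0.5, min_probes: int = 1) -> list[Segment]:
    """Segment every chromosome of a probe-by-sample CNV matrix.

    Probes are grouped by chromosome from ``annotations`` and ordered by
    genomic start before partitioning.
    """
    by_chrom: dict[str, list[str]] = {}
    for fid in cnv.index:
        tr = annotations.get(fid)
        if tr is None or tr.chrom is None:
            continue
        by_chrom.setdefault(tr.chrom, []).append(fid)

    segments: list[Segment] = []
    for chrom in sorted(by_chrom):
        ids = sorted(by_chrom[chrom], key=lambda f: (annotations[f].start, f))
        mat = cnv.loc[ids].to_numpy(dtype=float)
        for lo, hi in partition_chromosome(mat, min_corr=min_corr,
                                           min_probes=min_probes):
            member = ids[lo:hi]
            span = (min(annotations[f].start for f in member),
                    max(annotations[f].end for f in member))
            segments.append(Segment(
                segment_id=f"seg_{len(segments) + 1}", chromosome=chrom,
                probe_range=(lo, hi), probe_ids=tuple(member),
                profile=segment_profile(mat[lo:hi]), span=span))
    return segments


def assign_genes_to_segments(annotations: Mapping[str, FeatureTrack],
                             segments: Sequence[Segment],
                             feature_ids: Sequence[str] | None = None,
                             margin: int = 0) -> dict[str, str]:
    """Map each gene to the segment whose genomic span contains its midpoint.

    Genes on chromosomes without probes, or falling outside all spans beyond
    ``margin``, remain unmapped.  The mapping is recorded back onto
    ``Segment.member_genes``.
    """
    by_chrom: dict[str, list[Segment]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.chromosome, []).append(seg)

    mapping: dict[str, str] = {}
    members: dict[str, list[str]] = {s.segment_id: [] for s in segments}
    ids = feature_ids if feature_ids is not None else list(annotations)
    for fid in ids:
        tr = annotations.get(fid)
        if tr is None or tr.chrom is None or tr.start is None:
            continue
        segs = by_chrom.get(tr.chrom)
        if not segs:
            continue
        mid = tr.midpoint
        best, best_dist = None, np.inf
        for seg in segs:
            lo, hi = seg.span
            if lo <= mid < hi:
                best, best_dist = seg, 0.0
                break
            dist = lo - mid if mid < lo else mid - hi
            if dist < best_dist:
                best, best_dist = seg, dist
        if best is not None and best_dist <= margin:
            mapping[fid] = best.segment_id
            members[best.segment_id].append(fid)

    for seg in segments:
        seg.member_genes = tuple(members[seg.segment_id])
    return mapping


def density_entropy(positions: Sequence[float] | np.ndarray,
                    span: tuple[float, float], bins: int = 10) -> float:
    """Entropy (nats) of feature positions binned over a chromosome span.

    Uniform occupancy over all bins gives ln(bins); concentration in a single
    bin gives 0.  Returns NaN for an empty position list.
    """
    if bins < 2:
        raise ValueError("need at least 2 bins")
    pos = np.asarray(positions, dtype=float)
    pos = pos[np.isfinite(pos)]
    if pos.size == 0:
        return float("nan")
    counts, _ = np.histogram(pos, bins=bins, range=span)
    p = counts[counts > 0] / pos.size
    return float(-(p * np.log(p)).sum())


def segment_table(segments: Sequence[Segment]) -> pd.DataFrame:
    """Summary table (segment_id, chrom, start, end, n_probes, member_gene_count)."""
    return pd.DataFrame([{
        "segment_id": s.segment_id, "chrom": s.chromosome,
        "start": s.span[0] if s.span else -1, "end": s.span[1] if s.span else -1,
        "n_probes": s.n_probes, "member_gene_count": len(s.member_genes),
    } for s in segments])
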