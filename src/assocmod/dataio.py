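"""Loading, validation and trinary quantization of multi-omic matrices.

All continuous data types (mRNA, microRNA, CNV probes, promoter methylation)
are rank-transformed into CDF values per feature and then converted into
probability triples over the ordered states {low, mid, high}.  This puts
heterogeneous platforms on one scale while retaining information from values
near the tertile cut-points.  Binary mutation calls bypass quantization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

CONTINUOUS_TYPES = ("mrna", "mirna", "cnv_probe", "methylation")
DATA_TYPES = CONTINUOUS_TYPES + ("mutation",)

#: default tertile boundaries on the CDF scale
TERTILES = (1.0 / 3.0, 2.0 / 3.0)


class ConfigurationError(ValueError):
    """Raised when quantization or pipeline settings are out of range."""


@dataclass(frozen=True)
class SamplePanel:
    """An ordered cell-line panel with one tissue label per sample."""

    sample_ids: tuple[str, ...]
    tissue_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(set(self.sample_ids)):
            raise ValueError("duplicate sample ids")
        if len(self.sample_ids) != len(self.tissue_labels):
            raise ValueError("one tissue label per sample required")
        if len(self.sample_ids) < 2:
            raise ValueError("need at least 2 samples")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def tissues(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for t in self.tissue_labels:
            seen.setdefault(t)
        return tuple(seen)

    def tissue_members(self, tissue: str) -> np.ndarray:
        """Boolean mask of the samples belonging to ``tissue``."""
        return np.asarray([t == tissue for t in self.tissue_labels])


@dataclass(frozen=True)
class FeatureTrack:
    """Genomic annotation of one feature (location optional for expression)."""

    feature_id: str
    data_type: str
    chrom: str | None = None
    start: int | None = None
    end: int | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if self.data_type not in DATA_TYPES:
            raise ValueError(f"unknown data_type {self.data_type!r}")
        if self.start is not None and self.end is not None and self.end < self.start:
            raise ValueError("interval end before start")

    @property
    def midpoint(self) -> float:
        if self.start is None or self.end is None:
            raise ValueError(f"feature {self.feature_id} has no location")
        return 0.5 * (self.start + self.end)


class TrinaryMatrix:
    """Per-feature, per-sample probability triples over {low, mid, high}.

    ``probs`` has shape (features, samples, 3); missing samples hold NaN in
    all three slots.  ``cdf`` retains the rank/CDF provenance values.
    """

    def __init__(self, feature_ids: Sequence[str], sample_ids: Sequence[str],
                 probs: np.ndarray, cdf: np.ndarray) -> None:
        probs = np.asarray(probs, dtype=float)
        cdf = np.asarray(cdf, dtype=float)
        if probs.shape != (len(feature_ids), len(sample_ids), 3):
            raise ValueError("probs shape mismatch")
        if cdf.shape != probs.shape[:2]:
            raise ValueError("cdf shape mismatch")
        sums = np.nansum(probs, axis=-1)
        present = ~np.isnan(probs).any(axis=-1)
        if not np.allclose(sums[present], 1.0, atol=1e-9):
            raise ValueError("probability triples must sum to 1")
        self.feature_ids = list(feature_ids)
        self.sample_ids = list(sample_ids)
        self.probs = probs
        self.cdf = cdf
        self._index = {f: i for i, f in enumerate(self.feature_ids)}

    def row(self, feature_id: str) -> np.ndarray:
        return self.probs[self._index[feature_id]]

    def expectation(self, feature_id: str | None = None) -> np.ndarray:
        """Scalar driver value(s) ``p_high - p_low`` in [-1, 1]."""
        p = self.probs if feature_id is None else self.row(feature_id)
        return p[..., 2] - p[..., 0]


def rank_to_cdf(values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Rank-transform one feature profile into CDF values in (0, 1].

    Ties receive the mean of their rank range; missing entries (NaN) are
    excluded from ranking and returned as NaN in place.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise ValueError("expected a per-sample vector")
    mask = np.isfinite(v)
    if not mask.any():
        raise ValueError("empty feature: all values missing")
    n = int(mask.sum())
    if n < 2:
        raise ValueError("need at least 2 present values to rank")
    out = np.full(v.shape, np.nan)
    out[mask] = rankdata(v[mask], method="average") / n
    return out


def quantize_trinary(cdf: Sequence[float] | np.ndarray,
                     boundaries: tuple[float, float] = TERTILES,
                     w: float = 0.1) -> np.ndarray:
    """Soft-assign CDF values to the three ordered states.

    Within a half-width ``w`` window around a boundary the assignment is
    piecewise linear: a value at distance d from boundary b puts mass
    0.5 + d/(2w) on the state on its own side of b and the remainder on the
    adjacent state.  Outside all windows the assignment is hard one-hot;
    ``w = 0`` reduces to hard tertiles.
    """
    b1, b2 = boundaries
    if not (0.0 < b1 < b2 <= 1.0):
        raise ConfigurationError("boundaries must satisfy 0 < b1 < b2 <= 1")
    gap = min(b1, b2 - b1, 1.0 - b2 + 1e-12)
    if w < 0 or (w > 0 and w >= gap / 2 + 1e-12) or w >= 1 / 6:
        raise ConfigurationError(f"softness w={w} overlaps quantization windows")
    c = np.asarray(cdf, dtype=float)
    scalar = c.ndim == 0
    c = np.atleast_1d(c)
    present = np.isfinite(c)
    if ((c[present] <= 0) | (c[present] > 1)).any():
        raise ValueError("CDF values must lie in (0, 1]")

    # hard state: (0, b1] -> 0, (b1, b2] -> 1, (b2, 1] -> 2
    state = np.digitize(c, [b1, b2], right=True)
    probs = np.zeros(c.shape + (3,))
    idx = np.arange(c.size)
    probs.reshape(-1, 3)[idx, state.ravel()] = 1.0

    if w > 0:
        for k, b in enumerate((b1, b2)):
            d = c - b
            win = present & (np.abs(d) <= w)
            if not win.any():
                continue
            own = 0.5 + np.abs(d[win]) / (2 * w)
            # side of b containing the value: lower state k if d <= 0
            lower = d[win] <= 0
            p = np.zeros((int(win.sum()), 3))
            p[lower, k] = own[lower]
            p[lower, k + 1] = 1 - own[lower]
            p[~lower, k + 1] = own[~lower]
            p[~lower, k] = 1 - own[~lower]
            probs[win] = p

    probs[~present] = np.nan
    return probs[0] if scalar else probs


def quantize_matrix(matrix: pd.DataFrame, w: float = 0.1,
                    boundaries: tuple[float, float] = TERTILES) -> TrinaryMatrix:
    """Quantize a feature-by-sample continuous matrix row by row."""
    cdf = np.vstack([rank_to_cdf(matrix.iloc[i].to_numpy())
                     for i in range(matrix.shape[0])])
    probs = quantize_trinary(cdf, boundaries=boundaries, w=w)
    return TrinaryMatrix(list(matrix.index), list(matrix.columns), probs, cdf)


@dataclass
class Dataset:
    """A loaded, quantized multi-omic panel ready for association analysis."""

    panel: SamplePanel
    tracks: dict[str, pd.DataFrame]
    annotations: dict[str, FeatureTrack] = field(default_factory=dict)
    trinary: dict[str, TrinaryMatrix] = field(default_factory=dict)
    tf_ids: frozenset[str] = frozenset()

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return self.panel.sample_ids

    def quantize(self, w: float = 0.1) -> None:
        """(Re)build trinary matrices for every continuous data type."""
        for dtype, mat in self.tracks.items():
            if dtype in CONTINUOUS_TYPES and len(mat):
                self.trinary[dtype] = quantize_matrix(mat, w=w)

    def driver_values(self, dtype: str, feature_id: str) -> np.ndarray:
        """Per-sample scalar driver profile for any feature."""
        if dtype == "mutation":
            return self.tracks["mutation"].loc[feature_id].to_numpy(dtype=float)
        return self.trinary[dtype].expectation(feature_id)

    def passenger_probs(self, dtype: str, feature_ids: Sequence[str]) -> np.ndarray:
        tm = self.trinary[dtype]
        return np.stack([tm.row(f) for f in feature_ids])


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a TSV matrix: first column feature id, header of sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicated feature ids: {dups}")
    return df.astype(float)


def read_bed(path: str | Path, data_types: Mapping[str, str]) -> dict[str, FeatureTrack]:
    """Read BED6 annotations; ``data_types`` maps feature id -> data type."""
    tracks: dict[str, FeatureTrack] = {}
    bed = pd.read_csv(path, sep="\t", header=None,
                      names=["chrom", "start", "end", "name", "score", "strand"])
    for rec in bed.itertuples(index=False):
        fid = str(rec.name)
        if fid in tracks:
            raise ValueError(f"duplicated feature id in annotations: {fid}")
        tracks[fid] = FeatureTrack(
            feature_id=fid, data_type=data_types.get(fid, "mrna"),
            chrom=str(rec.chrom), start=int(rec.start), end=int(rec.end),
            strand=str(rec.strand) if rec.strand in ("+", "-") else None)
    return tracks


def read_labels(path: str | Path) -> SamplePanel:
    lab = pd.read_csv(path, sep="\t", header=None, names=["sample_id", "tissue"])
    return SamplePanel(tuple(lab["sample_id"].astype(str)),
                       tuple(lab["tissue"].astype(str)))


def load_dataset(matrix_files: Mapping[str, str | Path],
                 annotation_file: str | Path | None,
                 labels_file: str | Path,
                 tf_file: str | Path | None = None,
                 w: float = 0.1) -> Dataset:
    """Assemble a :class:`Dataset` from on-disk TSV/BED inputs.

    Sample columns are intersected across files (a warning is logged when any
    file carries extra samples); continuous types are quantized and mutation
    matrices validated as {0, 1, NA}.
    """
    panel = read_labels(labels_file)
    tracks: dict[str, pd.DataFrame] = {}
    common = list(panel.sample_ids)
    for dtype, path in matrix_files.items():
        if dtype not in DATA_TYPES:
            raise ValueError(f"unknown data_type {dtype!r}")
        mat = read_matrix(path)
        missing = [s for s in common if s not in mat.columns]
        if missing:
            logger.warning("%s matrix lacks %d sample(s); taking intersection",
                           dtype, len(missing))
            common = [s for s in common if s in mat.columns]
        tracks[dtype] = mat

    keep = [i for i, s in enumerate(panel.sample_ids) if s in common]
    if len(keep) < panel.n_samples:
        panel = SamplePanel(tuple(panel.sample_ids[i] for i in keep),
                            tuple(panel.tissue_labels[i] for i in keep))
    tracks = {d: m[list(panel.sample_ids)] for d, m in tracks.items()}

    if "mutation" in tracks:
        mvals = tracks["mutation"].to_numpy(dtype=float)
        ok = np.isnan(mvals) | (mvals == 0) | (mvals == 1)
        if not ok.all():
            raise ValueError("mutation matrix must contain only 0, 1 or NA")

    seen: set[str] = set()
    for dtype, mat in tracks.items():
        clash = seen & set(mat.index)
        if clash:
            raise ValueError(f"duplicated feature ids across matrices: {sorted(clash)[:5]}")
        seen |= set(mat.index)

    data_types = {f: d for d, m in tracks.items() for f in m.index}
    annotations = read_bed(annotation_file, data_types) if annotation_file else {}
    tf_ids: frozenset[str] = frozenset()
    if tf_file is not None:
        lines = Path(tf_file).read_text().split()
        tf_ids = frozenset(lines)

    ds = Dataset(panel=panel, tracks=tracks, annotations=annotations, tf_ids=tf_ids)
    ds.quantize(w=w)
    return ds


def coherence_filter(replicates: Sequence[pd.DataFrame],
                     min_corr: float = 0.5) -> list[str]:
    """Keep features coherent across replicate expression matrices.

    A feature is retained when its mean pairwise Pearson correlation across
    all replicate matrices (over shared samples) reaches ``min_corr``.
    """
    if len(replicates) < 2:
        logger.warning("coherence_filter: single matrix, passing all features")
        return list(replicates[0].index) if replicates else []
    features = set(replicates[0].index)
    samples = set(replicates[0].columns)
    for m in replicates[1:]:
        features &= set(m.index)
        samples &= set(m.columns)
    cols = [s for s in replicates[0].columns if s in samples]
    kept = []
    for f in replicates[0].index:
        if f not in features:
            continue
        rows = [m.loc[f, cols].to_numpy(dtype=float) for m in replicates]
        cors = []
        for i in range(len(rows)):
            for j in range(i + 1, len(rows)):
                ok = np.isfinite(rows[i]) & np.isfinite(rows[j])
                if ok.sum() < 3 or np.std(rows[i][ok]) == 0 or np.std(rows[j][ok]) == 0:
                    cors.append(0.0)
                else:
                    cors.append(float(np.corrcoef(rows[i][ok], rows[j][ok])[0, 1]))
        if np.mean(cors) >= min_corr:
            kept.append(f)
    return kept
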