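"""Synthetic multi-omic cell-line panels with planted association modules.

The generator emulates a 60-sample, 9-tissue cell-line panel: correlated CNV
probe blocks with tissue-specific amplifications, sparse binary mutations,
promoter methylation, microRNA and transcription-factor expression drivers,
and passenger expressions sampled from the three-state log-linear
conditional model at a planted effect size.  Continuous observables are the
state code {-1, 0, +1} plus Gaussian noise and are re-quantized by the
pipeline, so the full analysis path is exercised.  Every dataset carries a
machine-readable ground truth (planted segment boundaries, module
memberships, per-link effect sizes and signs).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .dataio import Dataset, FeatureTrack, SamplePanel

#: NCI-60-shaped panel: 9 tissues over 60 cell lines
DEFAULT_TISSUES = (("BR", 5), ("CNS", 6), ("CO", 7), ("LE", 6), ("ME", 10),
                   ("LC", 9), ("OV", 7), ("PR", 2), ("RE", 8))

OBS_SD = 0.4       # observable = state code + N(0, OBS_SD^2)
PROBE_SD = 0.1     # probe = block latent + N(0, PROBE_SD^2)
TISSUE_SHIFT = 2.5  # latent elevation of a tissue-specific driver


@dataclass
class ModuleSpec:
    """One planted module: driver type, sign, size and effect strength."""

    driver_type: str                  # cis_cnv/trans_cnv/mutation/methylation/mirna/tf
    name: str
    sign: int
    n_passengers: int
    lam: float
    tissue: str | None = None         # tissue-specific driver elevation, or None
    lam_tf: float = 2.0               # segment->mediator link (trans_cnv only)
    mut_rate_in: float = 0.9
    mut_rate_out: float = 0.3
    mut_rate: float = 0.3             # tissue-independent carrier rate


@dataclass
class SimulationConfig:
    seed: int
    tissue_sizes: tuple = DEFAULT_TISSUES
    modules: list[ModuleSpec] = field(default_factory=list)
    n_decoy_mrna: int = 40
    n_decoy_mirna: int = 5
    n_decoy_methylation: int = 3
    n_decoy_mutation: int = 2
    decoy_cnv_blocks: tuple[int, ...] = (4, 4)   # probe counts on a decoy chrom
    probes_per_block: int = 6
    noise_sd: float = PROBE_SD
    obs_sd: float = OBS_SD

    @property
    def n_samples(self) -> int:
        return sum(n for _, n in self.tissue_sizes)


@dataclass
class GroundTruth:
    """Planted structure emitted alongside every simulated dataset."""

    segment_blocks: dict[str, list[int]]          # chrom -> probe counts
    modules: list[dict]                           # type/sign/passengers/...
    seed: int

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(segment_blocks=d["segment_blocks"], modules=d["modules"],
                   seed=d["seed"])


def conditional_probs(x: float, lam: float, sign: int) -> np.ndarray:
    """P(y | x) over y in {-1, 0, +1} under the log-linear model."""
    eta = lam * sign * x
    w = np.array([np.exp(-eta), 1.0, np.exp(eta)])
    return w / w.sum()


def _sample_states(x: np.ndarray, lam: float, sign: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Draw one passenger state per sample from the conditional model."""
    y = np.empty(x.size)
    for s in range(x.size):
        p = conditional_probs(float(x[s]), lam, sign)
        y[s] = rng.choice((-1.0, 0.0, 1.0), p=p)
    return y


def _tertile_code(v: np.ndarray) -> np.ndarray:
    """Hard tertile state {-1, 0, +1} of a continuous profile by ranks."""
    order = np.argsort(np.argsort(v, kind="stable"), kind="stable")
    n = v.size
    code = np.zeros(n)
    code[order < n // 3] = -1.0
    code[order >= n - n // 3] = 1.0
    return code


class _Builder:
    """Accumulates features, positions and truth while simulating."""

    def __init__(self, cfg: SimulationConfig) -> None:
        self.cfg = cfg
        self.rng = np.random.default_rng(cfg.seed)
        labels = [t for t, n in cfg.tissue_sizes for _ in range(n)]
        ids = [f"S{i + 1:02d}" for i in range(len(labels))]
        self.panel = SamplePanel(tuple(ids), tuple(labels))
        self.n = len(ids)
        self.rows: dict[str, dict[str, np.ndarray]] = {
            t: {} for t in ("mrna", "mirna", "cnv_probe", "methylation", "mutation")}
        self.ann: dict[str, FeatureTrack] = {}
        self.tf_ids: set[str] = set()
        self.truth_modules: list[dict] = []
        self.segment_blocks: dict[str, list[int]] = {}
        self._gene_cursor: dict[str, int] = {}

    def tissue_mask(self, tissue: str | None) -> np.ndarray:
        if tissue is None:
            return np.zeros(self.n, dtype=bool)
        return self.panel.tissue_members(tissue)

    def latent(self, tissue: str | None) -> np.ndarray:
        z = self.rng.normal(size=self.n)
        z[self.tissue_mask(tissue)] += TISSUE_SHIFT
        return z

    def add_block(self, chrom: str, n_probes: int, latent: np.ndarray) -> None:
        blocks = self.segment_blocks.setdefault(chrom, [])
        start_idx = sum(blocks)
        blocks.append(n_probes)
        for j in range(n_probes):
            pid = f"probe_{chrom}_{start_idx + j + 1}"
            self.rows["cnv_probe"][pid] = latent + self.rng.normal(
                0, self.cfg.noise_sd, self.n)
            pos = (start_idx + j) * 1_000_000
            self.ann[pid] = FeatureTrack(pid, "cnv_probe", chrom, pos, pos + 1000, "+")

    def block_span(self, chrom: str, block_idx: int) -> tuple[int, int]:
        blocks = self.segment_blocks[chrom]
        lo = sum(blocks[:block_idx]) * 1_000_000
        hi = (sum(blocks[:block_idx + 1]) - 1) * 1_000_000 + 1000
        return lo, hi

    def place_gene(self, fid: str, chrom: str, span: tuple[int, int] | None) -> None:
        cur = self._gene_cursor.get(chrom, 0)
        self._gene_cursor[chrom] = cur + 1
        if span is None:
            start = cur * 100_000
        else:   # spread gene midpoints inside the block span
            lo, hi = span
            start = lo + 10_000 + (cur % 50) * max((hi - lo - 20_000) // 50, 1)
        self.ann[fid] = FeatureTrack(fid, self.ann_type(fid), chrom,
                                     int(start), int(start) + 2000, "+")

    def ann_type(self, fid: str) -> str:
        for t, rows in self.rows.items():
            if fid in rows:
                return t
        raise KeyError(fid)

    def add_expression(self, fid: str, dtype: str, states: np.ndarray,
                       chrom: str = "chrZ",
                       span: tuple[int, int] | None = None) -> None:
        self.rows[dtype][fid] = states + self.rng.normal(0, self.cfg.obs_sd, self.n)
        self.place_gene(fid, chrom, span)

    def decoy_states(self) -> np.ndarray:
        return self.rng.choice((-1.0, 0.0, 1.0), size=self.n)


def simulate(config: SimulationConfig) -> tuple[Dataset, GroundTruth]:
    """Generate a dataset with the configured planted modules plus decoys."""
    b = _Builder(config)
    rng = b.rng
    cfg = config
    for spec in cfg.modules:
        if spec.n_passengers < 1 or spec.lam < 0:
            raise ValueError("module spec requires >=1 passengers and lam >= 0")

    chrom_counter = 0
    for spec in cfg.modules:
        passengers: list[str] = []
        regulators: list[str] = []
        if spec.driver_type == "cis_cnv":
            chrom_counter += 1
            chrom = f"chr{chrom_counter}"
            z = b.latent(spec.tissue)
            b.add_block(chrom, cfg.probes_per_block, z)
            x = _tertile_code(z)
            span = b.block_span(chrom, len(b.segment_blocks[chrom]) - 1)
            for i in range(spec.n_passengers):
                fid = f"{spec.name}_p{i + 1}"
                y = _sample_states(x, spec.lam, spec.sign, rng)
                b.add_expression(fid, "mrna", y, chrom=chrom, span=span)
                passengers.append(fid)
            driver_desc = f"{chrom}:block1"
        elif spec.driver_type == "trans_cnv":
            chrom_counter += 1
            chrom = f"chr{chrom_counter}"
            z = b.latent(spec.tissue)
            b.add_block(chrom, cfg.probes_per_block, z)
            x_seg = _tertile_code(z)
            span = b.block_span(chrom, len(b.segment_blocks[chrom]) - 1)
            tf = f"{spec.name}_TF"
            y_tf = _sample_states(x_seg, spec.lam_tf, 1, rng)
            b.add_expression(tf, "mrna", y_tf, chrom=chrom, span=span)
            b.tf_ids.add(tf)
            regulators.append(tf)
            for i in range(spec.n_passengers):
                fid = f"{spec.name}_p{i + 1}"
                y = _sample_states(y_tf, spec.lam, spec.sign, rng)
                b.add_expression(fid, "mrna", y)
                passengers.append(fid)
            driver_desc = f"{chrom}:block1"
        elif spec.driver_type == "mutation":
            mut = f"{spec.name}"
            if spec.tissue is None:
                rate = np.full(b.n, spec.mut_rate)
            else:
                rate = np.where(b.tissue_mask(spec.tissue), spec.mut_rate_in,
                                spec.mut_rate_out)
            x = (rng.random(b.n) < rate).astype(float)
            b.rows["mutation"][mut] = x
            for i in range(spec.n_passengers):
                fid = f"{spec.name}_p{i + 1}"
                y = _sample_states(x, spec.lam, spec.sign, rng)
                b.add_expression(fid, "mrna", y)
                passengers.append(fid)
            driver_desc = mut
        elif spec.driver_type in ("methylation", "mirna", "tf"):
            z = b.latent(spec.tissue)
            x = _tertile_code(z)
            if spec.driver_type == "methylation":
                drv = spec.name
                b.rows["methylation"][drv] = z + rng.normal(0, cfg.obs_sd, b.n)
            elif spec.driver_type == "mirna":
                drv = spec.name
                b.rows["mirna"][drv] = z + rng.normal(0, cfg.obs_sd, b.n)
                b.place_gene(drv, "chrZ", None)
            else:
                drv = f"{spec.name}_TF"
                b.add_expression(drv, "mrna", x + rng.normal(0, 0.1, b.n))
                b.tf_ids.add(drv)
            for i in range(spec.n_passengers):
                fid = f"{spec.name}_p{i + 1}"
                y = _sample_states(x, spec.lam, spec.sign, rng)
                b.add_expression(fid, "mrna", y)
                passengers.append(fid)
            driver_desc = drv
        else:
            raise ValueError(f"unknown driver type {spec.driver_type!r}")
        b.truth_modules.append({
            "driver_type": spec.driver_type, "driver": driver_desc,
            "sign": spec.sign, "lam": spec.lam, "tissue": spec.tissue,
            "regulators": regulators, "passengers": passengers})

    # decoy CNV blocks on one extra chromosome (independent latents)
    if cfg.decoy_cnv_blocks:
        chrom_counter += 1
        chrom = f"chr{chrom_counter}"
        for k, n_probes in enumerate(cfg.decoy_cnv_blocks):
            b.add_block(chrom, n_probes, b.latent(None))
            span = b.block_span(chrom, k)
            for j in range(3):     # unassociated local genes
                fid = f"decoy_{chrom}_b{k + 1}_g{j + 1}"
                b.add_expression(fid, "mrna", b.decoy_states(), chrom=chrom,
                                 span=span)

    for i in range(cfg.n_decoy_mrna):
        b.add_expression(f"decoy_mrna_{i + 1}", "mrna", b.decoy_states())
    for i in range(cfg.n_decoy_mirna):
        fid = f"decoy_mir_{i + 1}"
        b.rows["mirna"][fid] = b.decoy_states() + rng.normal(0, cfg.obs_sd, b.n)
        b.place_gene(fid, "chrZ", None)
    for i in range(cfg.n_decoy_methylation):
        b.rows["methylation"][f"decoy_meth_{i + 1}"] = \
            b.decoy_states() + rng.normal(0, cfg.obs_sd, b.n)
    for i in range(cfg.n_decoy_mutation):
        b.rows["mutation"][f"decoy_mut_{i + 1}"] = \
            (rng.random(b.n) < 0.3).astype(float)

    n_feats = sum(len(r) for r in b.rows.values())
    if any(len(m["passengers"]) > n_feats for m in b.truth_modules):
        raise ValueError("infeasible config: more passengers than features")

    tracks = {}
    for dtype, rows in b.rows.items():
        if rows:
            tracks[dtype] = pd.DataFrame.from_dict(
                rows, orient="index", columns=list(b.panel.sample_ids))
    ds = Dataset(panel=b.panel, tracks=tracks, annotations=b.ann,
                 tf_ids=frozenset(b.tf_ids))
    ds.quantize()
    truth = GroundTruth(segment_blocks=b.segment_blocks,
                        modules=b.truth_modules, seed=cfg.seed)
    return ds, truth


def default_module_specs() -> list[ModuleSpec]:
    """One planted instance of each of the six module types.

    Effect sizes sit in the 1-2 range; tissue assignments mix tissue-specific
    drivers (melanoma-style CNV amplification, colon-style mutations) with a
    tissue-independent TF driver.
    """
    return [
        ModuleSpec("cis_cnv", "cis1", 1, 20, 1.8, tissue="ME"),
        ModuleSpec("trans_cnv", "trans1", 1, 16, 1.8, tissue="LE", lam_tf=2.0),
        ModuleSpec("mutation", "mut1", 1, 18, 2.0, tissue=None),
        ModuleSpec("methylation", "meth1", -1, 15, 1.8, tissue="CNS"),
        ModuleSpec("mirna", "mir1", -1, 16, 1.8, tissue="RE"),
        ModuleSpec("tf", "tfexo1", 1, 20, 1.8, tissue=None),
    ]


def benchmark_suite(seed: int) -> list[tuple[Dataset, GroundTruth]]:
    """Datasets spanning all six module types, with full ground truth."""
    cfg = SimulationConfig(seed=seed, modules=default_module_specs())
    return [simulate(cfg)]


def noise_only_config(seed: int, n_decoy_mrna: int = 50) -> SimulationConfig:
    """A decoy-only panel for specificity and FDR calibration runs."""
    return SimulationConfig(seed=seed, modules=[], n_decoy_mrna=n_decoy_mrna)


def write_dataset(ds: Dataset, truth: GroundTruth, outdir: str | Path) -> dict[str, Path]:
    """Emit the dataio input files (matrices TSV, BED6, labels, TF list) + truth."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for dtype, mat in ds.tracks.items():
        p = out / f"{dtype}.tsv"
        formatted = mat.round(6)
        formatted.to_csv(p, sep="\t", na_rep="NA",
                         index_label="feature_id",
                         float_format="%.6g" if dtype != "mutation" else "%g")
        paths[dtype] = p
    bed = out / "annotations.bed"
    with open(bed, "w") as fh:
        for fid, tr in sorted(ds.annotations.items()):
            if tr.chrom is None:
                continue
            fh.write(f"{tr.chrom}\t{tr.start}\t{tr.end}\t{fid}\t0\t{tr.strand or '+'}\n")
    paths["annotations"] = bed
    lab = out / "labels.tsv"
    with open(lab, "w") as fh:
        for s, t in zip(ds.panel.sample_ids, ds.panel.tissue_labels):
            fh.write(f"{s}\t{t}\n")
    paths["labels"] = lab
    tfp = out / "tf_list.tsv"
    with open(tfp, "w") as fh:
        for tf in sorted(ds.tf_ids):
            fh.write(tf + "\n")
    paths["tf_list"] = tfp
    tj = out / "truth.json"
    tj.write_text(truth.to_json())
    paths["truth"] = tj
    return paths
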