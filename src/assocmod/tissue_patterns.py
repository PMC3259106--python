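"""Tissue-specific expression patterns of modules.

An expression profile is decomposed as a linear combination of ideal tissue
profiles (indicator vectors that are 1 on one tissue's samples and 0
elsewhere).  After grand-mean centering the least-squares coefficient on a
tissue's indicator is simply the within-tissue mean of the centered profile,
which determines the tissue's up/down call.  A module is called coherently
up (down) in a tissue when its passengers are enriched in genes called up
(down) there AND the driver profile concentrates in that tissue's samples by
a GSEA-style running-sum test with the matching sign; otherwise the module
is incoherent in that tissue.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dataio import SamplePanel
from .enrichment import EnrichmentCounts, hypergeom_tail


@dataclass
class TissueDecomposition:
    """Per-tissue mixture coefficients and up/down/none calls for one profile."""

    coefficients: dict[str, float]
    calls: dict[str, str]


@dataclass
class ModuleTissuePattern:
    """Per-tissue module call in {up, down, incoherent}."""

    module_id: int
    calls: dict[str, str]


def tissue_decompose(profile: np.ndarray, panel: SamplePanel,
                     z_threshold: float = 1.0) -> TissueDecomposition:
    """Decompose one expression profile onto ideal tissue profiles.

    The profile is grand-mean centered; coefficient_t is the mean of the
    centered profile over tissue t.  Calls are up/down when the coefficient
    exceeds ``z_threshold`` standard deviations of the centered profile.
    """
    v = np.asarray(profile, dtype=float)
    if v.size != panel.n_samples:
        raise ValueError("profile length must match the panel")
    ok = np.isfinite(v)
    center = v - np.nanmean(v)
    sd = float(np.nanstd(center))
    coef: dict[str, float] = {}
    calls: dict[str, str] = {}
    for t in panel.tissues:
        mask = panel.tissue_members(t) & ok
        c = float(center[mask].mean()) if mask.any() else 0.0
        coef[t] = c
        if sd > 0 and c > z_threshold * sd:
            calls[t] = "up"
        elif sd > 0 and c < -z_threshold * sd:
            calls[t] = "down"
        else:
            calls[t] = "none"
    return TissueDecomposition(coef, calls)


def gsea_score(values: np.ndarray, in_set: np.ndarray,
               n_perm: int = 1000, seed: int = 0) -> tuple[float, float]:
    """Unweighted running-sum enrichment of a sample set along a ranking.

    Samples are ranked by ``values`` (descending); hits add 1/|set| and
    misses subtract 1/(n - |set|).  ES is the signed maximum deviation of
    the running sum, and the p-value comes from set-label permutations.
    """
    v = np.asarray(values, dtype=float)
    members = np.asarray(in_set, dtype=bool)
    if v.size != members.size:
        raise ValueError("set mask must match the profile length")
    m = int(members.sum())
    if m == 0 or m == v.size:
        raise ValueError("set must be nonempty and a strict subset of samples")

    order = np.argsort(-v, kind="stable")

    def es(mask: np.ndarray) -> float:
        steps = np.where(mask[order], 1.0 / m, -1.0 / (v.size - m))
        run = np.cumsum(steps)
        i = int(np.argmax(np.abs(run)))
        return float(run[i])

    obs = es(members)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for t in range(n_perm):
        perm = np.zeros(v.size, dtype=bool)
        perm[rng.choice(v.size, size=m, replace=False)] = True
        null[t] = es(perm)
    p = (1 + np.sum(np.abs(null) >= abs(obs))) / (n_perm + 1)
    return obs, float(p)


def module_tissue_pattern(module_id: int,
                          passenger_decomps: Mapping[str, TissueDecomposition],
                          universe_decomps: Mapping[str, TissueDecomposition],
                          driver_profile: np.ndarray,
                          panel: SamplePanel,
                          alpha: float = 0.05,
                          n_perm: int = 1000,
                          seed: int = 0) -> ModuleTissuePattern:
    """Intersect passenger and driver tissue-specific patterns for one module.

    Tissue t is called up (down) iff the module's passengers are enriched
    (hypergeometric tail at ``alpha``) among universe genes called up (down)
    in t AND the driver profile is significantly concentrated (depleted) in
    t's samples by :func:`gsea_score` with matching sign.
    """
    calls: dict[str, str] = {}
    pas = set(passenger_decomps)
    uni = set(universe_decomps)
    driver = np.asarray(driver_profile, dtype=float)
    for t in panel.tissues:
        call = "incoherent"
        if pas:
            members = panel.tissue_members(t)
            try:
                es, p_drv = gsea_score(np.nan_to_num(driver), members,
                                       n_perm=n_perm, seed=seed)
            except ValueError:
                es, p_drv = 0.0, 1.0
            for direction, es_sign in (("up", 1), ("down", -1)):
                marked = {g for g in uni
                          if universe_decomps[g].calls.get(t) == direction}
                k = len({g for g in pas
                         if passenger_decomps[g].calls.get(t) == direction})
                counts = EnrichmentCounts(N=len(uni), K=len(marked),
                                          n=len(pas & uni), k=min(k, len(marked)))
                p_enr = hypergeom_tail(counts)
                if p_enr <= alpha and p_drv <= alpha and np.sign(es) == es_sign:
                    call = direction
                    break
        calls[t] = call
    return ModuleTissuePattern(module_id, calls)


def pattern_matrix(patterns: Sequence[ModuleTissuePattern],
                   panel: SamplePanel) -> pd.DataFrame:
    """Modules-by-tissues matrix of {up, down, incoherent} calls."""
    return pd.DataFrame(
        [[p.calls[t] for t in panel.tissues] for p in patterns],
        index=[p.module_id for p in patterns], columns=list(panel.tissues))
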