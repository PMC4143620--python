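"""Marker filtering, IBD sharing rates by pair group, and region calling.

The scan contrasts per-marker IBD sharing between case-case (CaCa) and
case-control (CaCo) pairs. Sharing rates use *called* ANY_IBD states, with
NO_CALL markers kept in the denominator; each group's rate curve is centered
by its own genomic mean, and a marker is flagged when the centered CaCa rate
exceeds the genome-wide maximum of the centered CaCo rate by at least the
threshold ``tau``. Regions are maximal runs of at least ``min_markers``
consecutive flagged markers.

Marker preparation mirrors common practice for IBD panels: drop markers with
MAF below 5% (a falsely shared "rare" allele is otherwise taken as strong IBD
evidence), and optionally LD-prune with a 1 cM sliding window, removing the
lower-MAF member of any pair in high LD.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ibdassoc.hmm import CLASS_ANY, IBDTrack

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PruneConfig:
    """LD-pruning configuration: 1 cM sliding window, r² ceiling, MAF floor."""

    window_cm: float = 1.0
    maf_min: float = 0.05
    r2_max: float = 0.5

    def __post_init__(self):
        if not self.window_cm > 0:
            raise ValueError("window_cm must be > 0")
        if not 0 <= self.maf_min < 0.5:
            raise ValueError("maf_min must be in [0, 0.5)")
        if not 0 < self.r2_max <= 1:
            raise ValueError("r2_max must be in (0, 1]")


@dataclass(frozen=True)
class RegionSelectionConfig:
    """Excess-sharing threshold tau (rate units) and minimum run length."""

    tau: float = 0.0
    min_markers: int = 2
    compare: str = "max"   # "max": against genome-wide max CaCo; "pointwise": per marker

    def __post_init__(self):
        if self.min_markers < 2:
            raise ValueError("min_markers must be >= 2")
        if self.compare not in ("max", "pointwise"):
            raise ValueError("compare must be 'max' or 'pointwise'")


@dataclass
class Region:
    """Contiguous interval of excess CaCa sharing (1-based inclusive bp)."""

    chrom: str
    start_bp: int
    end_bp: int
    start_cm: float
    end_cm: float
    n_markers_flagged: int
    n_snps: int | None = None
    n_rare: int | None = None


def sample_freq(genotypes: np.ndarray) -> np.ndarray:
    """Per-marker alt-allele frequency from non-missing hard calls (<0 = missing)."""
    g = np.asarray(genotypes, dtype=float)
    g = np.where(g < 0, np.nan, g)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-missing columns
        return np.nanmean(g, axis=0) / 2.0


def maf_filter(genotypes: np.ndarray, panel: pd.DataFrame,
               maf_min: float = 0.05) -> np.ndarray:
    """Indices of markers with MAF >= ``maf_min`` (boundary inclusive).

    MAF is min(p̂, 1-p̂) with p̂ the sample alt frequency; monomorphic and
    all-missing markers are removed.
    """
    p = sample_freq(genotypes)
    maf = np.minimum(p, 1.0 - p)
    keep = np.flatnonzero((maf >= maf_min) & (maf > 0))
    if keep.size == 0:
        warnings.warn("MAF filter removed every marker", stacklevel=2)
    return keep


def ld_prune(genotypes: np.ndarray, panel: pd.DataFrame,
             cfg: PruneConfig) -> np.ndarray:
    """Deterministic greedy sliding-window LD pruning; returns kept indices.

    Windows of ``window_cm`` advance by half a window. Within a window, while
    any kept marker pair has genotype r² > ``r2_max``, the pair with the
    largest r² is resolved by dropping its lower-MAF member (tie: the higher
    panel index). The surviving set has all within-window pairwise r² at or
    below the ceiling.
    """
    cm = panel["cm"].to_numpy(dtype=float)
    p = sample_freq(genotypes)
    maf = np.minimum(p, 1.0 - p)
    kept = np.ones(len(panel), dtype=bool)

    g = np.asarray(genotypes, dtype=float)
    g = np.where(g < 0, np.nan, g)

    start = cm.min() if len(cm) else 0.0
    stop = cm.max() if len(cm) else 0.0
    step = cfg.window_cm / 2.0
    w = start
    while w <= stop:
        idx = np.flatnonzero(kept & (cm >= w) & (cm < w + cfg.window_cm))
        if idx.size > 1:
            sub = g[:, idx]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                r = pd.DataFrame(sub).corr().to_numpy()
            r2 = np.nan_to_num(r ** 2)
            np.fill_diagonal(r2, 0.0)
            active = np.ones(idx.size, dtype=bool)
            while True:
                masked = np.where(np.outer(active, active), r2, 0.0)
                if masked.max() <= cfg.r2_max:
                    break
                i, j = np.unravel_index(np.argmax(masked), masked.shape)
                a, b = idx[i], idx[j]
                if maf[a] < maf[b] or (maf[a] == maf[b] and a > b):
                    drop_local, drop = i, a
                else:
                    drop_local, drop = j, b
                active[drop_local] = False
                kept[drop] = False
        w += step
    return np.flatnonzero(kept)


def ibd_rates(tracks_by_group: Mapping[str, Sequence[IBDTrack]],
              panel: pd.DataFrame) -> pd.DataFrame:
    """Per-marker called-ANY_IBD rate for each pair group.

    rate_g(m) = (# pairs in g called ANY_IBD at marker m) / (# pairs in g);
    NO_CALL pairs count only in the denominator.
    """
    M = len(panel)
    out = {}
    for group, tracks in tracks_by_group.items():
        if not tracks:
            raise ValueError(f"group {group!r} has no tracks")
        any_ibd = np.zeros(M)
        for t in tracks:
            any_ibd += (t.call_classes == CLASS_ANY)
        out[group] = any_ibd / len(tracks)
    return pd.DataFrame(out)


def centered_excess(rates: pd.DataFrame) -> pd.DataFrame:
    """Subtract each group's genomic mean rate; centered curves average to 0."""
    return rates - rates.mean(axis=0)


def call_regions(centered: pd.DataFrame, panel: pd.DataFrame,
                 cfg: RegionSelectionConfig,
                 caca: str = "caca", caco: str = "caco") -> list[Region]:
    """Regions where centered CaCa sharing exceeds the CaCo reference + tau.

    In the default ``compare="max"`` mode the reference is the genome-wide
    maximum of the centered CaCo curve; ``"pointwise"`` compares marker by
    marker. Regions are maximal runs of >= ``min_markers`` consecutive
    flagged markers; boundaries are the bp/cM of the first and last flagged
    marker.
    """
    ca = centered[caca].to_numpy()
    co = centered[caco].to_numpy()
    if cfg.compare == "max":
        flagged = ca > co.max() + cfg.tau
    else:
        flagged = ca > co + cfg.tau

    bp = panel["bp"].to_numpy()
    cm = panel["cm"].to_numpy(dtype=float)
    chrom = str(panel["chrom"].iloc[0]) if "chrom" in panel.columns and len(panel) else "1"

    regions: list[Region] = []
    run_start = None
    for m in range(len(flagged) + 1):
        if m < len(flagged) and flagged[m]:
            if run_start is None:
                run_start = m
            continue
        if run_start is not None:
            n = m - run_start
            if n >= cfg.min_markers:
                regions.append(Region(
                    chrom=chrom,
                    start_bp=int(bp[run_start]), end_bp=int(bp[m - 1]),
                    start_cm=float(cm[run_start]), end_cm=float(cm[m - 1]),
                    n_markers_flagged=n,
                ))
            run_start = None
    return regions


def annotate_regions(regions: Sequence[Region], assoc_panel: pd.DataFrame,
                     assoc_genotypes: np.ndarray,
                     rare_maf_max: float = 0.01) -> list[Region]:
    """Fill n_snps / n_rare counts from an association panel (bp-inclusive).

    ``n_snps`` counts association-panel markers with bp inside the region;
    ``n_rare`` counts those whose sample MAF is below ``rare_maf_max`` (and
    positive, i.e. the rare allele is observed).
    """
    bp = assoc_panel["bp"].to_numpy()
    p = sample_freq(assoc_genotypes)
    maf = np.minimum(p, 1.0 - p)
    rare = (maf < rare_maf_max) & (maf > 0)
    out = []
    for r in regions:
        inside = (bp >= r.start_bp) & (bp <= r.end_bp)
        out.append(Region(
            chrom=r.chrom, start_bp=r.start_bp, end_bp=r.end_bp,
            start_cm=r.start_cm, end_cm=r.end_cm,
            n_markers_flagged=r.n_markers_flagged,
            n_snps=int(inside.sum()), n_rare=int((inside & rare).sum()),
        ))
    return out


def regions_table(regions: Sequence[Region]) -> pd.DataFrame:
    """Regions as a table with 1-based inclusive physical positions."""
    return pd.DataFrame([{
        "chrom": r.chrom, "start_bp": r.start_bp, "end_bp": r.end_bp,
        "start_cm": r.start_cm, "end_cm": r.end_cm,
        "n_markers_flagged": r.n_markers_flagged,
        "n_snps": r.n_snps, "n_rare": r.n_rare,
    } for r in regions])


def regions_bed(regions: Sequence[Region]) -> pd.DataFrame:
    """BED-style view: 0-based half-open coordinates."""
    return pd.DataFrame([{
        "chrom": r.chrom, "start": r.start_bp - 1, "end": r.end_bp,
    } for r in regions])
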