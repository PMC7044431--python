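"""Locally normalised nucleosome occupancy on a 10-bp grid.

Fragment midpoint counts in 10-bp bins are normalised by the total count in
the surrounding 1-kb interval (making occupancy invariant to sequencing
depth and to broad enrichment differences), then averaged in overlapping
50-bp windows centred every 10 bp.  Promoter-anchored matrices cover
TSS +/- 1 kb with minus-strand profiles flipped so that positive relative
positions are downstream of the TSS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fragments import FragmentSet

logger = logging.getLogger(__name__)

GRID = 10  # bp; the analysis grid everywhere downstream
NORM_WINDOW = 1_000  # bp; local normalisation window
OCC_WINDOW = 50  # bp; occupancy smoothing window
PROMOTER_FLANK = 1_000  # bp; promoter matrices cover TSS +/- this


@dataclass(frozen=True)
class Region:
    chrom: str
    start: int
    end: int
    anchor: int | None = None  # e.g. the TSS
    strand: str = "+"

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("region end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class OccupancyProfile:
    """Normalised occupancy values over a region on the 10-bp grid."""

    region: Region
    values: np.ndarray
    raw_counts: np.ndarray
    normalized_counts: np.ndarray
    grid_step: int = GRID

    def positions(self) -> np.ndarray:
        """Genomic coordinates of the grid (bin left edges)."""
        n = len(self.values)
        return self.region.start + self.grid_step * np.arange(n)


@dataclass
class PromoterMatrix:
    """Per-promoter occupancy over TSS +/- 1 kb, TSS-oriented.

    ``relative_positions`` run -1000..+1000 in 10-bp steps; +x is downstream
    of the TSS on the promoter's own strand.
    """

    promoter_ids: list
    relative_positions: np.ndarray
    values: np.ndarray  # (n_promoters, n_positions)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.promoter_ids, columns=self.relative_positions
        )

    def row(self, promoter_id) -> np.ndarray:
        return self.values[self.promoter_ids.index(promoter_id)]

    def mean_profile(self, ids=None) -> np.ndarray:
        if ids is None:
            return self.values.mean(axis=0)
        idx = [self.promoter_ids.index(i) for i in ids]
        return self.values[idx].mean(axis=0)


def _sorted_mids_by_chrom(frags: FragmentSet) -> dict[str, np.ndarray]:
    return {
        chrom: np.sort(((g["start"] + g["end"]) // 2).to_numpy())
        for chrom, g in frags.df.groupby("chrom")
    }


def _bin_counts_sorted(mids: np.ndarray, region: Region, bin: int) -> np.ndarray:
    n_bins = region.length // bin
    lo = np.searchsorted(mids, region.start)
    hi = np.searchsorted(mids, region.start + n_bins * bin)
    window = mids[lo:hi]
    return np.bincount((window - region.start) // bin, minlength=n_bins).astype(float)


def _bin_counts(frags: FragmentSet, region: Region, bin: int) -> np.ndarray:
    sel = (frags.df["chrom"] == region.chrom).to_numpy()
    mids = np.sort(frags.midpoints[sel])
    return _bin_counts_sorted(mids, region, bin)


def bin_and_normalize(
    frags: FragmentSet, region: Region, bin: int = GRID, window: int = NORM_WINDOW
) -> OccupancyProfile:
    """Count fragment midpoints per bin and normalise by the local window sum.

    ``normalized[i] = raw[i] / S_i`` where ``S_i`` is the raw-count total over
    the ``window``-bp interval centred on bin i.  At region edges the window
    is truncated and the truncated sum scaled up to its full-window
    equivalent; bins whose window sum is zero normalise to 0.
    """
    if region.length < window:
        raise ValueError("region shorter than the normalisation window")
    if isinstance(frags, np.ndarray):  # pre-sorted midpoints (internal fast path)
        raw = _bin_counts_sorted(frags, region, bin)
    else:
        raw = _bin_counts(frags, region, bin)
    w_bins = window // bin
    half = w_bins // 2
    n = len(raw)
    csum = np.concatenate([[0.0], np.cumsum(raw)])
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + (w_bins - half), n)
    wsum = csum[hi] - csum[lo]
    avail = hi - lo
    denom = wsum * (w_bins / avail)  # truncation-length correction
    with np.errstate(divide="ignore", invalid="ignore"):
        normalized = np.where(denom > 0, raw / denom, 0.0)
    occ = occupancy_from_normalized(normalized)
    return OccupancyProfile(
        region=region, values=occ, raw_counts=raw, normalized_counts=normalized,
        grid_step=bin,
    )


def occupancy_from_normalized(
    normalized: np.ndarray, win: int = OCC_WINDOW, step: int = GRID
) -> np.ndarray:
    """Mean of normalised counts in overlapping ``win``-bp windows per grid bin.

    With the defaults this is the 5-bin centred running mean; edges average
    over the available bins only.
    """
    k = win // step
    half = k // 2
    n = len(normalized)
    csum = np.concatenate([[0.0], np.cumsum(normalized)])
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + (k - half), n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def tss_of(promoters: pd.DataFrame) -> pd.Series:
    """TSS column, deriving it from txStart/txEnd when absent.

    refGene convention: txStart for '+' transcripts, txEnd - 1 for '-'.
    """
    if "tss" in promoters.columns:
        return promoters["tss"]
    minus = promoters["strand"] == "-"
    return promoters["txStart"].where(~minus, promoters["txEnd"] - 1)


def promoter_matrix(
    frags: FragmentSet,
    promoters: pd.DataFrame,
    flank: int = PROMOTER_FLANK,
    contig_sizes: dict[str, int] | None = None,
) -> PromoterMatrix:
    """Occupancy over TSS +/- ``flank`` for every promoter, TSS-oriented.

    Profiles are computed over a padded region so the 1-kb normalisation
    window is fully informed inside the reported span, then sliced to
    TSS +/- flank.  Minus-strand rows are reversed so +x means downstream.
    Promoters whose padded region leaves the contig are dropped with a
    warning.
    """
    pad = NORM_WINDOW // 2 + OCC_WINDOW  # normalisation + smoothing reach
    tss = tss_of(promoters)
    n_pos = 2 * flank // GRID + 1
    rel = np.arange(-flank, flank + GRID, GRID)
    mids_by_chrom = _sorted_mids_by_chrom(frags)
    ids, rows = [], []
    for (_, prom), t in zip(promoters.iterrows(), tss):
        t = int(t)
        start = t - flank - pad
        end = t + flank + pad + GRID
        if start < 0 or (
            contig_sizes is not None and end > contig_sizes.get(prom["chrom"], np.inf)
        ):
            logger.warning("promoter %s too close to contig end; dropped",
                           prom.get("promoter_id", prom.get("gene", "?")))
            continue
        region = Region(prom["chrom"], start, end, anchor=t, strand=prom["strand"])
        mids = mids_by_chrom.get(prom["chrom"], np.empty(0, dtype=np.int64))
        profile = bin_and_normalize(mids, region)
        first = (t - flank - start) // GRID
        vals = profile.values[first : first + n_pos]
        if prom["strand"] == "-":
            vals = vals[::-1]
        ids.append(prom.get("promoter_id", prom.get("gene")))
        rows.append(vals)
    values = np.vstack(rows) if rows else np.empty((0, n_pos))
    return PromoterMatrix(promoter_ids=ids, relative_positions=rel, values=values)


def subnucleosomal_profile(
    frags: FragmentSet,
    promoters: pd.DataFrame,
    min_len: int = 50,
    max_len: int = 100,
    **kwargs,
) -> PromoterMatrix:
    """Promoter matrix restricted to sub-nucleosomal (50-100 bp) fragments.

    Expects the unfiltered fragment set (before the mononucleosome gate).
    """
    from .fragments import select_size

    return promoter_matrix(select_size(frags, min_len, max_len), promoters, **kwargs)


def fold_enrichment(
    frags: FragmentSet, regions: list[Region], mappable_genome_size: int
) -> np.ndarray:
    """Fragment density per region divided by the genome-wide mean density."""
    if mappable_genome_size <= 0:
        raise ValueError("mappable_genome_size must be positive")
    genome_density = len(frags) / mappable_genome_size
    out = np.empty(len(regions))
    mids_by_chrom = {
        chrom: np.sort(((g["start"] + g["end"]) // 2).to_numpy())
        for chrom, g in frags.df.groupby("chrom")
    }
    for i, r in enumerate(regions):
        mids = mids_by_chrom.get(r.chrom, np.empty(0))
        n = np.searchsorted(mids, r.end) - np.searchsorted(mids, r.start)
        out[i] = (n / r.length) / genome_density if genome_density > 0 else np.nan
    return out


def promoter_coverage(
    frags: FragmentSet, promoters: pd.DataFrame, flank: int = PROMOTER_FLANK
) -> np.ndarray:
    """Mean fragments per bp over TSS +/- flank for each promoter."""
    tss = tss_of(promoters).to_numpy()
    mids_by_chrom = {
        chrom: np.sort(((g["start"] + g["end"]) // 2).to_numpy())
        for chrom, g in frags.df.groupby("chrom")
    }
    cov = np.empty(len(promoters))
    for i, (chrom, t) in enumerate(zip(promoters["chrom"], tss)):
        mids = mids_by_chrom.get(chrom, np.empty(0))
        n = np.searchsorted(mids, t + flank) - np.searchsorted(mids, t - flank)
        cov[i] = n / (2 * flank)
    return cov


def select_high_coverage(
    frags_by_sample: dict[str, FragmentSet],
    promoters: pd.DataFrame,
    threshold: float = 0.05,
    flank: int = PROMOTER_FLANK,
) -> pd.DataFrame:
    """Promoters with >= ``threshold`` fragments/bp over TSS +/- 1 kb in every sample.

    The default 0.05/bp equals 100 fragments within the 2-kb span.
    """
    if not frags_by_sample:
        raise ValueError("at least one sample required")
    keep = np.ones(len(promoters), dtype=bool)
    for name, frags in frags_by_sample.items():
        cov = promoter_coverage(frags, promoters, flank)
        keep &= cov >= threshold
    return promoters[keep].reset_index(drop=True)


def write_matrix_tsv(matrix: PromoterMatrix, path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="promoter_id")


def write_bedgraph(profile: OccupancyProfile, path) -> None:
    pos = profile.positions()
    with open(path, "w") as fh:
        for p, v in zip(pos, profile.values):
            fh.write(f"{profile.region.chrom}\t{p}\t{p + profile.grid_step}\t{v:.6g}\n")
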