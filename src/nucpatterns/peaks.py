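"""Nucleosome position calling by topographic prominence, and resolution.

A preferred nucleosome position is a local maximum of the occupancy profile.
Its topographic prominence — the height of the peak above the lowest valley
separating it from an adjacent higher peak — separates discrete positions
from measurement noise: a sample-wide prominence cutoff excluding roughly
the lowest 20% of peaks is applied before positions are reported.

Positional resolution is quantified from replicates as the symmetrised mean
distance between each called position and the closest position called
independently in the other replicate; mock replicates (pooled and randomly
reassorted fragments) bound the contribution of biological differences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fragments import FragmentSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Peak:
    position: int  # grid coordinate (bp) of the local maximum
    height: float
    prominence: float


@dataclass
class PositionSet:
    """Called nucleosome positions for one region, sorted by coordinate."""

    region_id: object
    peaks: list[Peak]
    cutoff_used: float

    @property
    def positions(self) -> np.ndarray:
        return np.array([p.position for p in self.peaks], dtype=float)

    def __len__(self) -> int:
        return len(self.peaks)


def _plateau_maxima(values: np.ndarray) -> list[tuple[int, float]]:
    """Indices of local maxima; plateaus yield one peak at their centre.

    Even-length plateaus are assigned the left-of-centre index.  Boundary
    plateaus (touching either end of the profile) are not maxima.
    """
    n = len(values)
    out = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and values[j + 1] == values[i]:
            j += 1
        left_lower = i > 0 and values[i - 1] < values[i]
        right_lower = j < n - 1 and values[j + 1] < values[i]
        if left_lower and right_lower:
            out.append(((i + j) // 2, float(values[i])))
        i = j + 1
    return out


def prominences(values: np.ndarray, grid_step: int = 10, origin: int = 0) -> list[Peak]:
    """Topographic prominence of every interior local maximum.

    For each peak, walk outwards in both directions until a strictly higher
    value is met, tracking the minimum along the way.  The key col is the
    higher of the two path minima among directions that reach higher ground;
    prominence = height - key col.  A peak with no higher ground on either
    side (the global maximum) gets height - global minimum.  A constant
    profile has no peaks.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 3:
        return []
    maxima = _plateau_maxima(values)
    if not maxima:
        return []
    gmin = float(values.min())
    peaks = []
    for idx, h in maxima:
        cols = []
        # leftwards
        m = h
        for k in range(idx - 1, -1, -1):
            if values[k] > h:
                cols.append(m)
                break
            m = min(m, values[k])
        # rightwards
        m = h
        for k in range(idx + 1, len(values)):
            if values[k] > h:
                cols.append(m)
                break
            m = min(m, values[k])
        key = max(cols) if cols else gmin
        peaks.append(Peak(position=origin + idx * grid_step, height=h,
                          prominence=h - key))
    return peaks


def call_positions(
    profiles: dict,
    exclusion_fraction: float = 0.20,
    cutoff: float | None = None,
    grid_step: int = 10,
    origins: dict | None = None,
) -> dict:
    """Call positions in every profile using a sample-wide prominence cutoff.

    ``profiles`` maps region id -> occupancy value array.  The cutoff is the
    ``exclusion_fraction`` quantile of all prominences pooled over the whole
    sample (peaks with prominence >= cutoff are retained, so ties at the
    cutoff survive); pass ``cutoff`` explicitly to override.  With fewer
    than 10 peaks sample-wide a quantile is refused and an explicit cutoff
    is required.
    """
    all_peaks = {
        rid: prominences(vals, grid_step=grid_step,
                         origin=(origins or {}).get(rid, 0))
        for rid, vals in profiles.items()
    }
    proms = np.array([p.prominence for ps in all_peaks.values() for p in ps])
    if cutoff is None:
        if len(proms) < 10:
            raise ValueError(
                "fewer than 10 peaks sample-wide; supply an explicit cutoff"
            )
        cutoff = float(np.quantile(proms, exclusion_fraction))
    out = {}
    for rid, ps in all_peaks.items():
        kept = sorted((p for p in ps if p.prominence >= cutoff),
                      key=lambda p: p.position)
        out[rid] = PositionSet(region_id=rid, peaks=kept, cutoff_used=cutoff)
    return out


def prominence_cutoff_by_gap(
    all_prominences: np.ndarray, qrange: tuple[float, float] = (0.05, 0.8)
) -> float:
    """Alternative cutoff: the visible break in the prominence distribution.

    Prominence distributions are typically a low-level noise mode plus the
    true-position mode.  The cutoff is placed at the largest multiplicative
    jump between consecutive sorted prominences, searched between the
    ``qrange`` quantiles (so extreme order statistics cannot set it);
    returns the geometric mean across the break.  Falls back to 0 when all
    prominences are equal or non-positive.
    """
    p = np.sort(np.asarray(all_prominences, dtype=float))
    p = p[p > 0]
    if p.size < 3 or p[0] == p[-1]:
        return 0.0
    lo = max(int(qrange[0] * p.size), 0)
    hi = min(int(qrange[1] * p.size), p.size - 1)
    if hi <= lo:
        return 0.0
    ratios = p[lo + 1 : hi + 1] / p[lo:hi]
    i = lo + int(np.argmax(ratios))
    return float(np.sqrt(p[i] * p[i + 1]))


@dataclass
class ResolutionResult:
    """Symmetrised mean nearest-position discrepancy between replicates."""

    mean: float
    n_discrepancies: int
    n_excluded_positions: int  # positions in regions with no counterpart
    discrepancies: np.ndarray = field(repr=False, default=None)

    def __float__(self) -> float:
        return self.mean


def _directed_discrepancies(
    a: PositionSet, b: PositionSet, edge_exclusion: int, bounds
) -> np.ndarray:
    pa, pb = a.positions, b.positions
    if bounds is not None and edge_exclusion > 0:
        lo, hi = bounds
        pa = pa[(pa >= lo + edge_exclusion) & (pa <= hi - edge_exclusion)]
    if len(pa) == 0 or len(pb) == 0:
        return np.empty(0)
    idx = np.searchsorted(pb, pa)
    left = np.abs(pa - pb[np.clip(idx - 1, 0, len(pb) - 1)])
    right = np.abs(pb[np.clip(idx, 0, len(pb) - 1)] - pa)
    return np.minimum(left, right)


def resolution(
    a: dict,
    b: dict,
    edge_exclusion: int = 50,
    region_bounds: dict | None = None,
) -> ResolutionResult:
    """Mean distance from each called position to its replicate counterpart.

    ``a`` and ``b`` map region id -> :class:`PositionSet` over a shared
    region universe.  Discrepancies are collected in both directions (a->b
    and b->a) and averaged together.  Positions within ``edge_exclusion`` bp
    of a region boundary (when ``region_bounds`` maps region id ->
    (lo, hi)) are excluded, as are regions whose counterpart called nothing
    (their positions are counted and reported).
    """
    discrepancies = []
    excluded = 0
    shared = set(a) & set(b)
    for rid in shared:
        bounds = (region_bounds or {}).get(rid)
        for x, y in ((a[rid], b[rid]), (b[rid], a[rid])):
            if len(y) == 0:
                excluded += len(x)
                continue
            discrepancies.append(
                _directed_discrepancies(x, y, edge_exclusion, bounds)
            )
    d = np.concatenate(discrepancies) if discrepancies else np.empty(0)
    if excluded:
        logger.info("resolution: %d positions in regions without counterpart", excluded)
    mean = float(d.mean()) if d.size else float("nan")
    return ResolutionResult(mean=mean, n_discrepancies=int(d.size),
                            n_excluded_positions=excluded, discrepancies=d)


def mock_replicates(
    fragsA: FragmentSet, fragsB: FragmentSet, seed: int
) -> tuple[FragmentSet, FragmentSet]:
    """Pool two replicates and randomly reassort into two mock replicates.

    The mock sets preserve the original sizes, eliminating any underlying
    biological difference between the samples while keeping sampling depth.
    Deterministic given ``seed``.
    """
    pooled = pd.concat([fragsA.df, fragsB.df], ignore_index=True)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(pooled))
    nA = len(fragsA)
    mockA = pooled.iloc[perm[:nA]].reset_index(drop=True)
    mockB = pooled.iloc[perm[nA:]].reset_index(drop=True)
    return (
        FragmentSet(mockA, provenance="mock replicate A"),
        FragmentSet(mockB, provenance="mock replicate B"),
    )


def resolution_by_coverage(
    fragsA: FragmentSet,
    fragsB: FragmentSet,
    genome_length: int,
    interval: int = 4_000,
    exclusion_fraction: float = 0.20,
    chrom: str | None = None,
) -> pd.DataFrame:
    """Resolution stratified by coverage over genomic ``interval``-bp windows.

    Windows are grouped into twofold coverage bands anchored at the lowest
    non-zero window coverage (band k spans [min*2^k, min*2^(k+1))); per band
    the mean coverage and the replicate resolution are reported.  Empty
    bands are skipped.
    """
    from .occupancy import Region, bin_and_normalize, _sorted_mids_by_chrom

    if chrom is None:
        chrom = fragsA.df["chrom"].iloc[0]
    midsA = _sorted_mids_by_chrom(fragsA).get(chrom, np.empty(0, dtype=np.int64))
    midsB = _sorted_mids_by_chrom(fragsB).get(chrom, np.empty(0, dtype=np.int64))
    n_windows = genome_length // interval
    rows = []
    profsA, profsB, bounds, covs = {}, {}, {}, {}
    for w in range(n_windows):
        region = Region(chrom, w * interval, (w + 1) * interval)
        pA = bin_and_normalize(midsA, region)
        pB = bin_and_normalize(midsB, region)
        cov = (pA.raw_counts.sum() + pB.raw_counts.sum()) / (2 * interval)
        if cov == 0:
            continue
        profsA[w], profsB[w] = pA.values, pB.values
        bounds[w] = (region.start, region.end)
        covs[w] = cov
    if not covs:
        return pd.DataFrame(columns=["band", "mean_coverage", "resolution", "n_windows"])
    posA = call_positions(profsA, exclusion_fraction,
                          origins={w: b[0] for w, b in bounds.items()})
    posB = call_positions(profsB, exclusion_fraction,
                          origins={w: b[0] for w, b in bounds.items()})
    cmin = min(covs.values())
    bands: dict[int, list[int]] = {}
    for w, c in covs.items():
        bands.setdefault(int(np.floor(np.log2(c / cmin))), []).append(w)
    rows = []
    for band in sorted(bands):
        ws = bands[band]
        res = resolution({w: posA[w] for w in ws}, {w: posB[w] for w in ws},
                         region_bounds=bounds)
        rows.append({
            "band": band,
            "mean_coverage": float(np.mean([covs[w] for w in ws])),
            "resolution": res.mean,
            "n_windows": len(ws),
        })
    return pd.DataFrame(rows)


def positions_to_bed(positions: dict, chrom_of, path) -> None:
    """Write called positions as BED with prominence in the score column."""
    with open(path, "w") as fh:
        for rid, ps in positions.items():
            chrom = chrom_of(rid) if callable(chrom_of) else chrom_of
            for p in ps.peaks:
                fh.write(
                    f"{chrom}\t{int(p.position)}\t{int(p.position) + 1}"
                    f"\t{rid}\t{p.prominence:.6g}\t+\n"
                )
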