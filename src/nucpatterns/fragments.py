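"""Mapped-fragment container and pre-analysis filters.

MNase-protected fragments are the raw material of every downstream stage.
This module reads them from BED/BEDPE/BAM, removes PCR-duplicate excess by a
local Poisson test, applies mononucleosome size selection, and estimates the
mean fragment size of single-end libraries from opposite-strand read
distances.

Coordinates are 0-based half-open (BED convention) throughout.  The 5' end of
a plus-strand fragment is its ``start``; for a minus-strand fragment it is
its ``end`` (the exclusive coordinate), so that the plus-to-minus 5' span of
a fully protected particle equals its length.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

_COLUMNS = ["chrom", "start", "end", "strand"]


class FragmentFormatError(ValueError):
    """Raised for unknown dialects or malformed records."""


@dataclass
class FragmentSet:
    """A set of strand-aware genomic fragments.

    Parameters
    ----------
    df : pandas.DataFrame
        Columns ``chrom`` (str), ``start`` (int), ``end`` (int),
        ``strand`` ('+'/'-'); an optional ``name`` column is preserved.
    provenance : str
        Free-text record of sample identity and filters applied.
    """

    df: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"FragmentSet missing columns: {missing}")
        if len(self.df) and (self.df["end"] <= self.df["start"]).any():
            raise ValueError("fragment end must exceed start")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def lengths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()

    @property
    def midpoints(self) -> np.ndarray:
        """Integer fragment midpoints, the standard dyad proxy."""
        return ((self.df["start"] + self.df["end"]) // 2).to_numpy()

    def five_prime(self) -> np.ndarray:
        """Strand-dependent 5' coordinate (start for '+', end for '-')."""
        minus = (self.df["strand"] == "-").to_numpy()
        return np.where(minus, self.df["end"].to_numpy(), self.df["start"].to_numpy())

    def sort(self) -> "FragmentSet":
        """Return a copy sorted by (chrom, start, end, strand); idempotent."""
        out = self.df.sort_values(
            ["chrom", "start", "end", "strand"], kind="mergesort"
        ).reset_index(drop=True)
        return replace(self, df=out)

    def with_provenance(self, note: str) -> "FragmentSet":
        prov = f"{self.provenance}; {note}" if self.provenance else note
        return replace(self, provenance=prov)

    def to_bed(self, path) -> None:
        """Write as 6-column BED (name/score filled if absent)."""
        out = self.df.copy()
        if "name" not in out.columns:
            out["name"] = [f"f{i}" for i in range(len(out))]
        out["score"] = 0
        out[["chrom", "start", "end", "name", "score", "strand"]].to_csv(
            path, sep="\t", header=False, index=False
        )


def _read_bed(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FragmentFormatError(f"line {lineno}: fewer than 3 BED fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FragmentFormatError(f"line {lineno}: non-integer coordinate") from exc
            if start < 0:
                raise FragmentFormatError(f"line {lineno}: negative coordinate")
            strand = parts[5] if len(parts) >= 6 else "+"
            name = parts[3] if len(parts) >= 4 else f"f{lineno}"
            rows.append((parts[0], start, end, strand, name))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "name"])


def _read_bedpe(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise FragmentFormatError(f"line {lineno}: fewer than 6 BEDPE fields")
            if parts[0] != parts[3]:
                logger.warning("line %d: interchromosomal pair skipped", lineno)
                continue
            s1, e1, s2, e2 = (int(parts[i]) for i in (1, 2, 4, 5))
            if min(s1, s2) < 0:
                raise FragmentFormatError(f"line {lineno}: negative coordinate")
            strand = parts[8] if len(parts) >= 9 else "+"
            name = parts[6] if len(parts) >= 7 else f"f{lineno}"
            rows.append((parts[0], min(s1, s2), max(e1, e2), strand, name))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "name"])


def _read_bam(path, paired: bool) -> pd.DataFrame:
    import pysam

    rows = []
    with pysam.AlignmentFile(str(path), "rb") as bam:
        for aln in bam.fetch(until_eof=True):
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if paired:
                # template interval from the leftmost mate only, once per pair
                if not aln.is_proper_pair or aln.is_read2 or aln.template_length <= 0:
                    continue
                start = aln.reference_start
                end = start + aln.template_length
                strand = "-" if aln.is_reverse else "+"
            else:
                start, end = aln.reference_start, aln.reference_end
                strand = "-" if aln.is_reverse else "+"
            rows.append((aln.reference_name, start, end, strand, aln.query_name))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "name"])


def read_fragments(path, format: str = "bed") -> FragmentSet:
    """Read mapped fragments from ``path`` in the named dialect.

    ``format`` is one of ``bed``, ``bedpe``, ``bam-paired``, ``bam-single``.
    For paired formats one fragment is emitted per template.  Malformed lines
    raise :class:`FragmentFormatError` with the line number.
    """
    readers = {
        "bed": _read_bed,
        "bedpe": _read_bedpe,
        "bam-paired": lambda p: _read_bam(p, paired=True),
        "bam-single": lambda p: _read_bam(p, paired=False),
    }
    if format not in readers:
        raise FragmentFormatError(f"unknown fragment format: {format!r}")
    df = readers[format](path)
    if df.empty:
        warnings.warn(f"no fragments read from {path}", stacklevel=2)
        df = pd.DataFrame(columns=["chrom", "start", "end", "strand", "name"])
    df = df.astype({"start": np.int64, "end": np.int64})
    return FragmentSet(df, provenance=f"read {path} ({format})")


def select_size(frags: FragmentSet, min_len: int, max_len: int) -> FragmentSet:
    """Keep fragments with min_len <= length <= max_len (bounds inclusive).

    The mononucleosome gate is 140-180 bp; the subnucleosomal gate 50-100 bp.
    """
    if min_len > max_len:
        raise ValueError("min_len must not exceed max_len")
    lengths = frags.df["end"] - frags.df["start"]
    keep = (lengths >= min_len) & (lengths <= max_len)
    out = FragmentSet(frags.df[keep].reset_index(drop=True), frags.provenance)
    return out.with_provenance(f"size [{min_len},{max_len}]")


def _poisson_retain_count(m: int, lam: float, alpha: float) -> int:
    """Largest count k not rejected by the one-sided Poisson upper-tail test.

    k is retained while P(X >= k | lam) >= alpha; the returned value is the
    largest such k (at least 1: a singleton is never a duplicate).
    """
    if m <= 1:
        return m
    # P(X >= k) = sf(k - 1); decreasing in k.  Bracket with ppf then adjust.
    k = int(stats.poisson.ppf(1.0 - alpha, lam)) + 1
    while k > 1 and stats.poisson.sf(k - 1, lam) < alpha:
        k -= 1
    while stats.poisson.sf(k, lam) >= alpha:
        k += 1
    return max(k, 1)


def filter_duplicates(
    frags: FragmentSet, alpha: float = 0.05, flank: int = 2
) -> FragmentSet:
    """Remove excess exact duplicates judged against the local read density.

    Fragments sharing the exact (chrom, start, end, strand) are candidate PCR
    duplicates.  For each such position with multiplicity ``m`` the expected
    per-position count ``lam`` is the mean fragment count over positions
    within +/-``flank`` bp on the same chromosome and strand (the focal
    position excluded).  ``min(m, k*)`` copies are retained, where ``k*`` is
    the largest count not rejected by a one-sided Poisson upper-tail test at
    level ``alpha``.  Positions whose multiplicity is not a significant
    excess are untouched.
    """
    df = frags.df
    if df.empty:
        return frags
    key_cols = ["chrom", "start", "end", "strand"]
    grouped = df.groupby(key_cols, sort=False).size()
    if (grouped <= 1).all():
        return frags

    # per (chrom, strand): fragment counts indexed by start, for the local mean
    start_counts: dict[tuple, pd.Series] = {
        cs: g.groupby("start").size()
        for cs, g in df.groupby(["chrom", "strand"], sort=False)
    }

    keep_mask = np.ones(len(df), dtype=bool)
    order = df.groupby(key_cols, sort=False).cumcount().to_numpy()
    # map each row to its group's multiplicity
    mult = df.merge(
        grouped.rename("m").reset_index(), on=key_cols, how="left"
    )["m"].to_numpy()

    # evaluate k* per distinct position with m > 1
    excess = grouped[grouped > 1]
    kstar: dict[tuple, int] = {}
    for (chrom, start, end, strand), m in excess.items():
        counts = start_counts[(chrom, strand)]
        lo, hi = start - flank, start + flank
        window = counts.loc[(counts.index >= lo) & (counts.index <= hi)]
        neighbour_total = int(window.sum()) - int(counts.get(start, 0))
        lam = neighbour_total / (2 * flank)
        if lam <= 0:
            lam = 1e-9  # empty neighbourhood: any excess is significant
        kstar[(chrom, start, end, strand)] = _poisson_retain_count(int(m), lam, alpha)

    if kstar:
        keys = list(zip(df["chrom"], df["start"], df["end"], df["strand"]))
        limits = np.array([kstar.get(k, np.iinfo(np.int64).max) for k in keys])
        keep_mask = order < np.minimum(mult, limits)

    removed = int((~keep_mask).sum())
    logger.info("duplicate filter removed %d of %d fragments", removed, len(df))
    out = FragmentSet(df[keep_mask].reset_index(drop=True), frags.provenance)
    return out.with_provenance(f"dedup alpha={alpha} flank={flank} removed={removed}")


def filter_promoter_unique(
    frags: FragmentSet, promoters: pd.DataFrame, flank: int = 10_000
) -> FragmentSet:
    """Keep fragments with exactly one alignment inside the promoter universe.

    The promoter universe is TSS +/- ``flank``.  Alignments of the same
    physical fragment must share a ``name``; a fragment is retained (at its
    promoter-overlapping alignment) when exactly one of its alignments
    overlaps any promoter region, regardless of additional non-promoter
    alignments.  Input without a ``name`` column is assumed pre-resolved and
    returned unchanged.
    """
    df = frags.df
    if "name" not in df.columns or df.empty:
        return frags
    hits = np.zeros(len(df), dtype=bool)
    for chrom, grp in promoters.groupby("chrom"):
        tss = grp["tss"].to_numpy()
        lo, hi = np.sort(tss - flank), np.sort(tss + flank)
        sel = df["chrom"] == chrom
        mids = ((df.loc[sel, "start"] + df.loc[sel, "end"]) // 2).to_numpy()
        # a midpoint is inside some interval if the latest interval start at or
        # before it has an end beyond it; intervals may overlap, so count them
        inside = np.zeros(len(mids), dtype=bool)
        for l, h in zip(tss - flank, tss + flank):
            inside |= (mids >= l) & (mids < h)
        hits[np.where(sel)[0]] = inside
    n_promoter_alns = pd.Series(hits).groupby(df["name"].to_numpy()).transform("sum")
    keep = hits & (n_promoter_alns.to_numpy() == 1)
    out = FragmentSet(df[keep].reset_index(drop=True), frags.provenance)
    return out.with_provenance("promoter-unique")


def estimate_fragment_size(
    reads: FragmentSet,
    max_dist: int = 500,
    smooth_sd: float = 5.0,
    min_peak_ratio: float = 2.0,
) -> tuple[int, bool]:
    """Estimate the mean fragment size of a single-end library.

    Builds the distribution of distances between nearby reads mapped in
    opposite orientations (minus-strand 5' minus plus-strand 5', within
    ``max_dist`` bp), smooths it with a Gaussian kernel (``smooth_sd`` bp) and
    returns the argmax together with a confidence flag.  The flag is False
    when the smoothed peak exceeds the median histogram level by less than
    ``min_peak_ratio``.
    """
    df = reads.df
    plus = df[df["strand"] == "+"]
    minus = df[df["strand"] == "-"]
    if plus.empty or minus.empty:
        raise ValueError("fragment-size estimation requires reads on both strands")
    hist = np.zeros(max_dist + 1)
    for chrom in df["chrom"].unique():
        p5 = np.sort(plus.loc[plus["chrom"] == chrom, "start"].to_numpy())
        m5 = np.sort(minus.loc[minus["chrom"] == chrom, "end"].to_numpy())
        if len(p5) == 0 or len(m5) == 0:
            continue
        # all opposite-strand distances in (0, max_dist] via lagged sweep
        idx = np.searchsorted(m5, p5, side="right")
        k = 0
        while True:
            j = idx + k
            valid = j < len(m5)
            if not valid.any():
                break
            d = m5[j[valid]] - p5[valid]
            d = d[(d > 0) & (d <= max_dist)]
            if d.size == 0 and k > 0:
                break
            hist += np.bincount(d, minlength=max_dist + 1)
            k += 1
    if hist.sum() == 0:
        raise ValueError("no opposite-strand read pairs within max_dist")
    from scipy.ndimage import gaussian_filter1d

    smoothed = gaussian_filter1d(hist, smooth_sd) if smooth_sd > 0 else hist
    size = int(np.argmax(smoothed[1:])) + 1
    background = float(np.median(smoothed[1:]))
    confident = background == 0 or smoothed[size] / background >= min_peak_ratio
    if not confident:
        warnings.warn("fragment-size estimate is low-confidence", stacklevel=2)
    return size, confident


def extend_reads(reads: FragmentSet, fragment_size: int) -> FragmentSet:
    """Extend single-end reads to ``fragment_size`` from their 5' ends."""
    df = reads.df.copy()
    minus = df["strand"] == "-"
    df.loc[~minus, "end"] = df.loc[~minus, "start"] + fragment_size
    df.loc[minus, "start"] = df.loc[minus, "end"] - fragment_size
    df.loc[df["start"] < 0, "start"] = 0
    out = FragmentSet(df, reads.provenance)
    return out.with_provenance(f"extended to {fragment_size} bp")
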