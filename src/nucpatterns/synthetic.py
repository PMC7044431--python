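"""Ground-truthed synthetic inputs for the whole analysis chain.

Every downstream stage (filtering, occupancy, position calling, period
estimation, patterning, gap/DHS analysis, pause indices, classification) is
testable without external sequencing data: this module plants promoter
nucleosome architectures — phased arrays with an upstream NDR at patterned
promoters, irregular arrays without an NDR at unpatterned ones — and samples
fragments, DNase cuts, pol-II coverage, expression tables and genome
sequence whose statistical structure matches what the analysis assumes.

The planted quantities (spacing, footprint, NDR presence, pause ratio,
class label, CGI status) are all recorded, so each estimator can be checked
against its own ground truth.

What is emulated: mononucleosome-sized protected fragments centred on
jittered dyads, replicates sharing architecture with independent sampling
noise, allele subpopulations mixing patterned/unpatterned dyad sets,
DNase cut pile-ups inside NDRs, pol-II tracks with per-gene promoter:body
ratios, and expression tables with inducible/active/inactive/BAF structure.
Not emulated: sequencing error, mappability, GC bias, MNase sequence
preference (out of scope by design).

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fragments import FragmentSet

CLASSES = (
    "active_patterned",
    "inactive",
    "inducible_patterned",
    "inducible_nonpatterned",
)
PATTERNED_CLASSES = {"active_patterned", "inducible_patterned"}

CHROM = "chrS"
PROMOTER_FLANK = 10_000  # bp; promoter region is TSS +/- this
NDR_REL = (-150, 0)  # default NDR, bp relative to TSS
DEFAULT_PLUS_ONE = 100  # bp downstream of TSS; +1 nucleosome dyad
ARRAY_SPAN = 5_000  # bp; planted arrays extend this far from the TSS


class SizingError(ValueError):
    """Requested promoters do not fit in the genome without overlap."""


@dataclass
class PromoterArchitecture:
    """Planted nucleosome architecture of one promoter.

    ``dyads_patterned`` is the phased array (NDR-respecting); where an
    allele mixture is simulated, ``dyads_unpatterned`` provides the
    alternative allele's irregular dyads and ``allele_fraction_patterned``
    the mixing weight.
    """

    promoter_id: str
    tss: int
    strand: str
    class_label: str
    ndr_present: bool
    ndr_interval: tuple[int, int] | None  # bp relative to TSS
    plus_one_dyad: int  # bp relative to TSS
    spacing: float
    jitter_sd: float
    footprint: int
    allele_fraction_patterned: float
    occupancy_scale: float
    dyads_patterned: np.ndarray = field(repr=False, default=None)
    dyads_unpatterned: np.ndarray = field(repr=False, default=None)
    pause_ratio: float = 0.0
    baf_dependent: bool = False
    cgi: bool = False

    def __post_init__(self):
        if not (self.spacing > self.footprint > 0):
            raise ValueError("need spacing > footprint > 0")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        if not 0 <= self.allele_fraction_patterned <= 1:
            raise ValueError("allele_fraction_patterned must be in [0, 1]")
        if not self.ndr_present and self.ndr_interval is not None:
            raise ValueError("ndr_interval must be empty when ndr_present is false")

    @property
    def region(self) -> tuple[int, int]:
        return (self.tss - PROMOTER_FLANK, self.tss + PROMOTER_FLANK)

    def active_dyads(self) -> np.ndarray:
        """Dyad set of the majority allele (for ground-truth comparisons)."""
        if self.allele_fraction_patterned >= 0.5:
            return self.dyads_patterned
        return self.dyads_unpatterned


@dataclass
class ArchitectureSet:
    architectures: list[PromoterArchitecture]
    genome_length: int
    background_rate: float  # uniform background, fragments per bp, whole contig
    seed: int

    def __iter__(self):
        return iter(self.architectures)

    def __len__(self):
        return len(self.architectures)

    def by_class(self, label: str) -> list[PromoterArchitecture]:
        return [a for a in self.architectures if a.class_label == label]

    def promoter_table(self) -> pd.DataFrame:
        """Promoter annotation as a DataFrame (promoter_id, gene, chrom, tss, strand)."""
        return pd.DataFrame(
            {
                "promoter_id": [a.promoter_id for a in self.architectures],
                "gene": [a.promoter_id for a in self.architectures],
                "chrom": CHROM,
                "tss": [a.tss for a in self.architectures],
                "strand": [a.strand for a in self.architectures],
                "class_label": [a.class_label for a in self.architectures],
            }
        )


def _patterned_dyads(
    tss: int, strand: str, spacing: float, footprint: int,
    plus_one: int, ndr: tuple[int, int], span: int,
) -> np.ndarray:
    """Phased array: regular dyads downstream of +1 and upstream of the NDR."""
    sgn = 1 if strand == "+" else -1
    rel = []
    # downstream array anchored at the +1 dyad
    k = 0
    while plus_one + k * spacing <= span:
        rel.append(plus_one + k * spacing)
        k += 1
    # upstream array beyond the NDR (-1 nucleosome and outwards)
    up0 = ndr[0] - footprint // 2 - 5
    k = 0
    while up0 - k * spacing >= -span:
        rel.append(up0 - k * spacing)
        k += 1
    rel = np.round(np.array(sorted(rel))).astype(int)
    return np.sort(tss + sgn * rel)


def _irregular_dyads(
    rng: np.random.Generator, tss: int, spacing: float, footprint: int, span: int
) -> np.ndarray:
    """Irregular dyads: successive gaps uniform with mean = spacing."""
    lo, hi = footprint + 5, 2 * spacing - footprint - 5
    pos = [tss - span + rng.uniform(0, spacing)]
    while pos[-1] < tss + span:
        pos.append(pos[-1] + rng.uniform(lo, hi))
    return np.round(np.array(pos[:-1])).astype(int)


def build_architectures(
    n_per_class: int,
    spacing: float = 192.0,
    jitter_sd: float = 15.0,
    footprint: int = 147,
    seed: int = 0,
    genome_length: int | None = None,
    background_rate: float = 0.0125,
    ndr_interval: tuple[int, int] = NDR_REL,
    plus_one_dyad: int = DEFAULT_PLUS_ONE,
    scale_sigma: float = 0.3,
    classes: tuple[str, ...] = CLASSES,
) -> ArchitectureSet:
    """Plant ``n_per_class`` promoters of each class on one synthetic contig.

    Patterned classes get phased dyads downstream of the TSS and an NDR
    covering ``ndr_interval`` (default [-150, 0) bp); unpatterned classes get
    irregularly spaced dyads and no NDR.  Strands are assigned randomly and
    promoter regions (TSS +/- 10 kb) never overlap.  ``occupancy_scale`` is
    lognormal with unit mean (sigma ``scale_sigma``), modelling promoter-to-
    promoter yield differences shared between replicates.  Deterministic
    given ``seed``.

    ``background_rate`` defaults to 0.0125 fragments/bp: the genome-wide
    mean density implied by a 0.05 fragments/bp promoter-coverage threshold
    corresponding to roughly 4-fold enrichment.  This background is what
    gives occupancy profiles their population of very-low-prominence noise
    peaks, the feature the downstream 20% prominence exclusion is calibrated
    to remove.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if spacing <= footprint:
        raise ValueError("need spacing > footprint")
    rng = np.random.default_rng(seed)
    n_total = n_per_class * len(classes)
    slot = 2 * PROMOTER_FLANK
    needed = n_total * slot
    if genome_length is None:
        genome_length = needed
    if genome_length < needed:
        raise SizingError(
            f"{n_total} promoters need {needed} bp; genome_length={genome_length}"
        )
    labels = np.repeat(np.array(classes, dtype=object), n_per_class)
    rng.shuffle(labels)
    archs = []
    half = footprint // 2
    for i, label in enumerate(labels):
        tss = i * slot + PROMOTER_FLANK
        strand = "+" if rng.random() < 0.5 else "-"
        patterned = label in PATTERNED_CLASSES
        dy_pat = _patterned_dyads(
            tss, strand, spacing, footprint, plus_one_dyad, ndr_interval, ARRAY_SPAN
        )
        dy_irr = _irregular_dyads(rng, tss, spacing, footprint, ARRAY_SPAN)
        scale = float(rng.lognormal(mean=-scale_sigma**2 / 2, sigma=scale_sigma))
        archs.append(
            PromoterArchitecture(
                promoter_id=f"p{i:05d}",
                tss=tss,
                strand=strand,
                class_label=str(label),
                ndr_present=patterned,
                ndr_interval=ndr_interval if patterned else None,
                plus_one_dyad=plus_one_dyad,
                spacing=float(spacing),
                jitter_sd=float(jitter_sd),
                footprint=int(footprint),
                allele_fraction_patterned=1.0 if patterned else 0.0,
                occupancy_scale=scale,
                dyads_patterned=dy_pat,
                dyads_unpatterned=dy_irr,
            )
        )
    return ArchitectureSet(
        architectures=archs,
        genome_length=int(genome_length),
        background_rate=background_rate,
        seed=seed,
    )


def planted_gaps(arch: ArchitectureSet, max_gap: float | None = None) -> np.ndarray:
    """Adjacent-dyad distances of every promoter's active allele.

    ``max_gap`` (default 2*spacing - footprint) drops NDR-crossing gaps so
    the remainder reflects the planted internucleosomal spacing.
    """
    gaps = []
    for a in arch:
        d = np.diff(np.sort(a.active_dyads()))
        cut = max_gap if max_gap is not None else 2 * a.spacing - a.footprint
        gaps.append(d[d <= cut])
    return np.concatenate(gaps)


def sample_fragments(
    arch: ArchitectureSet,
    coverage: float,
    frag_len_range: tuple[int, int] = (140, 180),
    seed: int = 0,
    return_counts: bool = False,
):
    """Sample mononucleosome-like fragments from the planted architectures.

    Each promoter emits ``Poisson(coverage * 20 kb * occupancy_scale)``
    fragments.  A fragment picks its source allele Bernoulli
    (``allele_fraction_patterned``), a dyad uniformly from that allele's
    set, adds truncated Gaussian jitter (sd = ``jitter_sd``, confined to the
    promoter window), draws a length uniformly from ``frag_len_range``
    (inclusive) and a strand with equal probability; the fragment is the
    length-bp interval centred on the jittered dyad.  NDR intervals contain
    no planted dyads and therefore yield no dyad-derived fragments.
    Background fragments are uniform Poisson at ``background_rate`` per bp
    over the whole contig.  Deterministic given ``seed``.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    lo, hi = frag_len_range
    if not (50 < lo <= hi < 400):
        raise ValueError("frag_len_range must lie within (50, 400)")
    rng = np.random.default_rng(seed)
    span = 2 * PROMOTER_FLANK
    centers, counts = [], {}
    for a in arch:
        n = int(rng.poisson(coverage * span * a.occupancy_scale))
        counts[a.promoter_id] = n
        if n == 0:
            continue
        use_pat = rng.random(n) < a.allele_fraction_patterned
        dy = np.empty(n)
        for mask, dyads in ((use_pat, a.dyads_patterned), (~use_pat, a.dyads_unpatterned)):
            m = int(mask.sum())
            if m:
                dy[mask] = rng.choice(dyads, size=m)
        c = dy + rng.normal(0, a.jitter_sd, size=n) if a.jitter_sd > 0 else dy
        w0, w1 = a.region
        c = np.clip(c, w0 + hi // 2 + 1, w1 - hi // 2 - 1)  # jitter truncation
        centers.append(np.round(c).astype(np.int64))
    n_bg = int(rng.poisson(arch.background_rate * arch.genome_length))
    counts["__background__"] = n_bg
    if n_bg:
        centers.append(rng.integers(hi, arch.genome_length - hi, size=n_bg))
    centers = np.concatenate(centers) if centers else np.empty(0, dtype=np.int64)
    n_tot = len(centers)
    lengths = rng.integers(lo, hi + 1, size=n_tot)
    strands = np.where(rng.random(n_tot) < 0.5, "+", "-")
    starts = centers - lengths // 2
    df = pd.DataFrame(
        {
            "chrom": CHROM,
            "start": starts,
            "end": starts + lengths,
            "strand": strands,
        }
    )
    frags = FragmentSet(df, provenance=f"synthetic coverage={coverage} seed={seed}").sort()
    if return_counts:
        return frags, pd.Series(counts, name="n_fragments")
    return frags


def sample_replicates(
    arch: ArchitectureSet,
    coverage: float,
    frag_len_range: tuple[int, int] = (140, 180),
    seeds: tuple[int, int] = (1, 2),
) -> tuple[FragmentSet, FragmentSet]:
    """Two fragment samples from identical architectures, independent noise."""
    a = sample_fragments(arch, coverage, frag_len_range, seed=seeds[0])
    b = sample_fragments(arch, coverage, frag_len_range, seed=seeds[1])
    return a, b


@dataclass
class AuxTracks:
    """DNase cuts, pol-II coverage, gene table and expression table."""

    dnase_cuts: pd.DataFrame  # chrom, pos (0-based cut sites)
    polii_coverage: np.ndarray  # per-bp, whole contig
    genes: pd.DataFrame  # gene, chrom, tss, strand, pause_ratio
    expression: pd.DataFrame


def sample_aux_tracks(
    arch: ArchitectureSet,
    seed: int = 0,
    dnase_background: float = 0.002,  # cuts per bp genome-wide
    ndr_cut_rate: float = 0.25,  # extra cuts per bp inside NDRs
    body_level: float = 2.0,  # mean pol-II coverage in gene bodies
    pause_ratios: dict[str, float] | None = None,
    induction_diff: float = 1.6,  # RMA units, planted for inducible classes
    rep_sd: float = 0.15,
    n_reps: int = 3,
    baf_fraction: float = 0.5,
) -> AuxTracks:
    """Auxiliary ground-truthed tracks consistent with the class labels.

    DNase cuts are uniform background plus pile-ups inside planted NDRs.
    Pol-II coverage is Poisson around a piecewise-constant profile whose
    promoter (TSS +/- 500) to body (+1..+6 kb) ratio is ``pause_ratios``
    per class (default: 4.0 at active, 2.0 at inducible, 0 at inactive).
    The expression table carries non-stimulated FPKM-like levels, replicate
    RMA-like values pre/post stimulation, their difference, and a BAF
    knockdown difference; planted so classification recovers the labels.
    """
    rng = np.random.default_rng(seed)
    if pause_ratios is None:
        pause_ratios = {
            "active_patterned": 4.0,
            "inducible_patterned": 2.0,
            "inducible_nonpatterned": 2.0,
            "inactive": 0.0,
        }
    # --- DNase cuts
    n_bg = int(rng.poisson(dnase_background * arch.genome_length))
    cuts = [rng.integers(0, arch.genome_length, size=n_bg)]
    for a in arch:
        if not a.ndr_present:
            continue
        sgn = 1 if a.strand == "+" else -1
        r0, r1 = sorted((a.tss + sgn * a.ndr_interval[0], a.tss + sgn * a.ndr_interval[1]))
        n = int(rng.poisson(ndr_cut_rate * (r1 - r0)))
        cuts.append(rng.integers(r0, r1, size=n))
    dnase = pd.DataFrame({"chrom": CHROM, "pos": np.sort(np.concatenate(cuts))})

    # --- pol-II coverage
    level = np.zeros(arch.genome_length)
    gene_rows = []
    for a in arch:
        r = pause_ratios.get(a.class_label, 0.0)
        sgn = 1 if a.strand == "+" else -1
        if r > 0:
            p0, p1 = sorted((a.tss - 500, a.tss + 500))
            b0, b1 = sorted((a.tss + sgn * 1000, a.tss + sgn * 6000))
            level[max(b0, 0) : b1] = body_level
            level[max(p0, 0) : p1] = r * body_level
        gene_rows.append(
            {"gene": a.promoter_id, "chrom": CHROM, "tss": a.tss,
             "strand": a.strand, "pause_ratio": r}
        )
    polii = rng.poisson(level).astype(float)

    # --- expression table
    mean_active_fpkm = 6.0
    rows = []
    for a in arch:
        label = a.class_label
        inducible = label.startswith("inducible")
        if label == "inactive":
            nonstim_fpkm = 0.0
        elif label == "active_patterned":
            nonstim_fpkm = float(rng.uniform(2.0, 2 * mean_active_fpkm - 2.0))
        else:
            nonstim_fpkm = float(rng.uniform(0.05, 0.5))
        base_rma = float(rng.uniform(4.0, 8.0))
        diff = induction_diff if inducible else 0.0
        nonstim_reps = base_rma + rng.normal(0, rep_sd, n_reps)
        stim_reps = base_rma + diff + rng.normal(0, rep_sd, n_reps)
        a.baf_dependent = bool(inducible and rng.random() < baf_fraction)
        baf = float(-0.6 + rng.normal(0, 0.05)) if a.baf_dependent else float(
            rng.normal(0, 0.05)
        )
        row = {
            "gene": a.promoter_id,
            "nonstim_level": nonstim_fpkm,
            "induction_diff": float(stim_reps.mean() - nonstim_reps.mean()),
            "baf_diff": baf,
        }
        for j in range(n_reps):
            row[f"nonstim_rep{j + 1}"] = float(nonstim_reps[j])
            row[f"stim_rep{j + 1}"] = float(stim_reps[j])
        rows.append(row)
    expr = pd.DataFrame(rows)
    genes = pd.DataFrame(gene_rows)
    return AuxTracks(dnase_cuts=dnase, polii_coverage=polii, genes=genes,
                     expression=expr)


def generate_sequence(
    arch: ArchitectureSet,
    seed: int = 0,
    background_gc: float = 0.42,
    cgi_classes: tuple[str, ...] = ("active_patterned", "inducible_patterned"),
    cgi_halfwidth: int = 200,
) -> str:
    """Synthetic contig sequence with CpG islands at selected promoters.

    Background is i.i.d. with GC fraction ``background_gc`` (fails the CGI
    GC criterion); promoters of ``cgi_classes`` get a GC-rich, CpG-retaining
    stretch over TSS +/- ``cgi_halfwidth`` and are flagged ``cgi=True`` in
    the ground truth.
    """
    rng = np.random.default_rng(seed)
    p_gc = background_gc / 2
    p_at = (1 - background_gc) / 2
    seq = rng.choice(
        np.array(list("ACGT")), size=arch.genome_length,
        p=[p_at, p_gc, p_gc, p_at],
    )
    for a in arch:
        if a.class_label in cgi_classes:
            island = rng.choice(
                np.array(list("ACGT")), size=2 * cgi_halfwidth,
                p=[0.17, 0.33, 0.33, 0.17],
            )
            seq[a.tss - cgi_halfwidth : a.tss + cgi_halfwidth] = island
            a.cgi = True
    return "".join(seq)


# ---------------------------------------------------------------------------
# writers

def write_dnase_bed(dnase: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for i, (chrom, pos) in enumerate(zip(dnase["chrom"], dnase["pos"])):
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\tcut{i}\t0\t+\n")


def write_expression_tsv(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", index=False)


def write_promoters_tsv(arch: ArchitectureSet, path, gene_span: int = 8_000) -> None:
    """refGene-like annotation: gene, chrom, strand, txStart, txEnd."""
    rows = []
    for a in arch:
        if a.strand == "+":
            tx_start, tx_end = a.tss, a.tss + gene_span
        else:
            tx_start, tx_end = a.tss - gene_span + 1, a.tss + 1
        rows.append((a.promoter_id, CHROM, a.strand, tx_start, tx_end))
    pd.DataFrame(rows, columns=["gene", "chrom", "strand", "txStart", "txEnd"]).to_csv(
        path, sep="\t", index=False
    )


def write_ground_truth(arch: ArchitectureSet, tsv_path, json_path) -> None:
    """Planted architecture as TSV (per promoter) + JSON sidecar (run params)."""
    rows = []
    for a in arch:
        rows.append(
            {
                "promoter_id": a.promoter_id,
                "tss": a.tss,
                "strand": a.strand,
                "class_label": a.class_label,
                "ndr_present": a.ndr_present,
                "ndr_start": a.ndr_interval[0] if a.ndr_interval else "",
                "ndr_end": a.ndr_interval[1] if a.ndr_interval else "",
                "plus_one_dyad": a.plus_one_dyad,
                "spacing": a.spacing,
                "jitter_sd": a.jitter_sd,
                "footprint": a.footprint,
                "allele_fraction_patterned": a.allele_fraction_patterned,
                "occupancy_scale": a.occupancy_scale,
                "pause_ratio": a.pause_ratio,
                "baf_dependent": a.baf_dependent,
                "cgi": a.cgi,
                "n_dyads_patterned": len(a.dyads_patterned),
                "n_dyads_unpatterned": len(a.dyads_unpatterned),
            }
        )
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)
    with open(json_path, "w") as fh:
        json.dump(
            {
                "genome_length": arch.genome_length,
                "background_rate": arch.background_rate,
                "seed": arch.seed,
                "n_promoters": len(arch),
                "chrom": CHROM,
            },
            fh,
            indent=2,
        )


def write_fasta(sequence: str, path, name: str = CHROM, width: int = 80) -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(sequence), width):
            fh.write(sequence[i : i + width] + "\n")
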