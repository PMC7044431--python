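# nucpatterns

Nucleosome patterning analysis for ChIP-MNase data: locally normalised
occupancy, prominence-based nucleosome position calling, Fourier estimation
of the nucleosome repeat length, promoter patterning quantification and
classification, nucleosome-gap/DHS analysis, and RNA pol-II pause indices —
with a ground-truthed synthetic data generator that makes the whole chain
testable end to end.

## The problem

ChIP-MNase maps nucleosome positions at antibody-selected chromatin by
digesting immunoprecipitated fragments to mononucleosomes.  Downstream of
the sequencer, the analytical questions are: where are the preferred
nucleosome positions and how reproducible are they; what is the
internucleosomal repeat length and the protected footprint; which promoters
carry the canonical architecture of a nucleosome-depleted region (NDR) with
a phased downstream array; and how do accessibility (DNase) and
transcription (pol-II pausing) relate to local gaps in the nucleosome
landscape.  This package implements that analysis chain for anyone working
with mononucleosome fragment data (BED/BEDPE/BAM), and ships a simulator
that plants known architectures so every estimator can be validated against
ground truth.

## The core quantities

- **Occupancy** — fragment-midpoint counts in 10-bp bins, normalised by the
  total count in the surrounding 1-kb window (depth- and
  enrichment-invariant), averaged in overlapping 50-bp windows:
  `occ_i = mean_{|j-i|<=2} ( n_j / sum_{|k-j|<=50} n_k )`.
- **Positions** — local maxima of occupancy ranked by topographic
  prominence (height above the lowest valley separating a peak from an
  adjacent higher peak); a sample-wide cutoff excludes the low-prominence
  noise mode (default: the 20% quantile; alternatively the visible break in
  the prominence distribution).
- **Resolution** — symmetrised mean distance between each called position
  and the closest position called independently in a replicate.
- **Period, offset, footprint** — the same-strand and opposite-strand
  distributions of pairwise 5′-end distances within 1 kb are Fourier
  transformed; the repeat length `s` is the interpolated magnitude argmax
  (120–350 bp band), the offset is the same/opposite phase difference at
  `1/s` scaled to bp, and the footprint is `s − offset`.
- **Patterning score** — per promoter, the mean-centred cross product
  between its occupancy profile (TSS ± 1 kb) and the mean profile of all
  active promoters: `score = Σ_i (p_i − p̄)(t_i − t̄)`.
- **Pause index** — mean pol-II coverage over TSS ± 500 bp divided by the
  mean over +1 to +6 kb.

## Worked example

One command generates synthetic data (100 promoters, 25 per class:
active-patterned, inactive, inducible-patterned, inducible-nonpatterned;
192-bp planted spacing; two replicates at 0.1 fragments/bp) and runs every
stage:

```sh
nucpatterns demo --seed 7 --out demo/ --n-per-class 25
```

Abridged output (full report in `demo/report.json`):

```json
{
  "fragments":   {"repA": {"fragments_in": 216941, "fragments_kept": 216479,
                           "fragments_removed_duplicates": 462}},
  "peaks":       {"n_positions_repA": 1057, "resolution_bp": 10.37},
  "periodicity": {"period_bp": 192.16, "offset_bp": 32.07,
                  "footprint_bp": 160.09, "n_pairs_same": 21899083},
  "patterning":  {"mean_score_by_class": {"active": 0.0328,
                  "inducible": 0.0168, "inactive": 0.00004},
                  "n_high_patterned_inducible": 25},
  "features":    {"n_pause_defined": 75, "mean_pause_index": 2.67}
}
```

Reading this: the duplicate filter removed ~0.2% of fragments (the
synthetic data has little PCR-like excess); positions called independently
in the two replicates agree to 10.4 bp on average; the Fourier estimator
recovers the planted 192-bp repeat to 0.2 bp and measures a 160-bp
protected span — the mean of the 140–180-bp fragment lengths, as it should,
since the footprint estimate is the mean 5′-to-5′ span of protected
fragments; active and patterned-inducible promoters score high on
patterning while inactive promoters score near zero, and exactly the 25
planted patterned inducible promoters fall in the high-patterned half; the
mean pause index over genes with pol-II signal reflects the planted 4:1 and
2:1 promoter:body ratios.

Each stage is also exposed as a library module
(`nucpatterns.fragments`, `.occupancy`, `.peaks`, `.periodicity`,
`.patterning`, `.features`, `.synthetic`) and as CLI subcommands
(`fragments`, `occupancy`, `peaks`, `resolution`, `period`, `run`, `demo`).

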