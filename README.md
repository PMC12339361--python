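# nisseq

Image analysis for **nuclear in situ barcode-sequencing screens** (optical
pooled CRISPR screening): from raw multi-cycle in situ sequencing image
stacks and live-cell phenotype images to per-nucleus barcode calls,
per-cell phenotype metrics, and per-gene screen statistics.

In this screening modality, each cell carries one lentivirally delivered
sgRNA whose spacer is amplified *in the nucleus* (T7 transcription →
padlock ligation → rolling-circle amplification) and read out by
sequencing-by-synthesis imaging: one dominant sub-nuclear spot per
transduced cell whose per-cycle three-channel color encodes, base by base,
the **reverse complement of the spacer**. A separate live-imaging session
records a phenotype (e.g. NF-κB p65 nuclear translocation, or ASC/C1C
inflammasome specking) for the same cells, and per-gene statistics link
the two.

The package is written for screen analysts: it implements the full
computational pipeline plus a ground-truthed synthetic-scene simulator
that stands in for raw screening data (which runs to terabytes per
screen), so every stage is testable against planted truth.

## The method

Given registered cycle images, the genotyping chain is:

1. **Registration** — each cycle's nuclear-stain image is aligned to
   cycle 1 by FFT-accelerated cross-correlation; the integer shift is
   applied to that cycle's three sequencing channels.
2. **Spot detection** — all sequencing channels are summed over the first
   three cycles, high-pass filtered, and strict local maxima above a
   robust threshold become spot candidates.
3. **Profile extraction** — per cycle and channel, images are high-pass
   filtered, negatives removed, and intensities summed over a 5×5-pixel
   window per spot, giving a cycles×3 matrix per spot.
4. **Crosstalk unmixing** — the 3×3 matrix *M* of base-wise average
   channel intensities is estimated from the data itself
   (column-normalized), and each cycle's channel vector **v** is replaced
   by *M*⁻¹**v**.
5. **Base calling** — the chemistry is three-color with a dark G: non-G
   bases are the argmax unmixed channel; G is called at cycles where all
   unmixed intensities fall below 20% of the spot's maximum unmixed
   intensity across cycles.
6. **Dictionary matching** — called sequences are assigned to the
   reverse-complemented library dictionary allowing zero or one mismatch
   and no ambiguities.
7. **Nucleus assignment** — a nucleus is genotyped when the dominant
   sequence exceeds two-thirds of the total intensity of library spots in
   that nucleus and the maximum spot intensity passes a numeric gate
   (7×10⁵ counts by default; a 2×10⁵ preset exists for low-signal cells).

Phenotype and sequencing fields of view are paired by stage position,
mapped coarsely at 8×8- and finely at 2×2-downsampled resolution, and
nuclei are matched one-to-one by centers of gravity (≤ 11.1 µm movement,
two-fold area margin, ambiguous mappings excluded). Phenotypes are the
pixelwise Pearson correlation between nuclear stain and reporter
(translocation) or the ratio of high-pass-filtered to overall reporter
signal per cell after local background subtraction (specking). Per-gene
statistics pool cells by targeted gene, compare against non-targeting
controls with a two-sided Wilcoxon–Mann–Whitney test, and control FDR by
Benjamini–Hochberg; genes need at least 10 cells to be tested.

## Worked example

Simulate a 100-nucleus, 6-cycle scene with stage drift and camera noise,
then run the full genotyping chain:

```python
import numpy as np
import nisseq as nq

lib = nq.simulate_library(n_genes=8, guides_per_gene=2, n_nt=4, seed=7)
cfg = nq.SimConfig(n_nuclei=100, n_cycles=6, noise_sd=1e4,
                   drift_per_cycle=(2, -1), frac_unbarcoded=0.2, seed=7)
stack, truth = nq.render_nis_scene(lib, cfg)

aligned = nq.align_cycles(stack)
print([(s.dy, s.dx) for s in aligned.shifts])
# [(0, 0), (2, -1), (4, -2), (5, -3), (8, -3), (10, -5)]

profiles, M = nq.call_stack(aligned)
print(np.round(M.M, 3))
# [[1.    0.036 0.038]
#  [0.039 1.    0.037]
#  [0.036 0.037 1.   ]]

index = nq.build_index(lib, read_length=6)
matches = nq.match_profiles(profiles, index)
labels = nq.segment_objects(aligned.nuclear[0], mode="nuclei")
calls = nq.assign_spots_to_nuclei(profiles, matches, labels)
summary = nq.mapping_summary(calls, lib)
print(summary["n_nuclei"], summary["mapped_fraction"])
# 100 0.79
```

The recovered shifts track the planted cumulative drift (2, −1) per cycle
to within one pixel at this noise level — a wiggle absorbed by the
5×5-pixel aggregation window. The estimated crosstalk matrix is close to
the identity used to render the scene (the ~0.04 off-diagonal terms come
from spot/background overlap at this noise). 79% of nuclei map to the
library: 20% were rendered unbarcoded, and a spot whose first three bases
are all dark G is invisible to the detection image.

Per-gene statistics on a simulated screen (one gene with a 2× reduced
mean metric):

```python
cells = nq.simulate_screen_metrics(n_genes=50, cells_per_gene=100,
                                   n_nt_cells=1000,
                                   effects={"G0001": 0.5}, seed=7)
res = nq.screen_test(cells, "metric")
print(res.head(3)[["gene", "n_cells", "log2_fc", "p_value", "fdr"]])
#  gene  n_cells  log2_fc  p_value    fdr
# G0001      100  -1.1202   0.0000 0.0000
# G0003      100  -0.3025   0.0001 0.0037
# G0006      100  -0.1828   0.0022 0.0374
```

The planted hit ranks first at log2 fold change ≈ −1. (The two trailing
genes illustrate that all genes share one finite non-targeting control
sample, so occasional small null p-values are correlated across genes —
a property of shared-control screen designs, not of the test.)

The same stages are available from a shell:

```bash
nisseq simulate --n-nuclei 100 --n-cycles 6 --seed 2 --out-dir scene/
nisseq align    --cycles-dir scene/ --out-dir aligned/
nisseq call     --stack-dir aligned/ --library scene/library.csv --out spots.csv
nisseq screen   --cells cells.csv --metric metric --nt-label NT --out genes.csv
nisseq run      --config run.yaml        # full pipeline with manifest
```

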