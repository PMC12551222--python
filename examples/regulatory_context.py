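"""Super-enhancer stitching and TAD co-membership around a candidate locus.

Stitches H3K27ac-like peaks (12.5 kb gap rule), calls super-enhancers with
the hockey-stick slope rule, and checks whether the called element shares a
TAD with a gene.
"""

import numpy as np

import hapintro as hi
from hapintro.intervals import GenomicInterval
from hapintro.regulatory import SignalPeak

rng = np.random.default_rng(8)
peaks = []
x = 30_000_000
for i in range(60):
    width = int(rng.integers(500, 3000))
    gap = int(rng.integers(2000, 40_000))
    signal = float(rng.exponential(1.5))
    peaks.append(SignalPeak("7", x, x + width, signal))
    x += width + gap
# a dense strong cluster mimicking a super-enhancer
for j in range(6):
    peaks.append(SignalPeak("7", 30_297_170 + j * 11_000,
                            30_297_170 + j * 11_000 + 8_000, 40.0))
peaks.sort(key=lambda p: p.start)

stitched, ses, report = hi.stitch_super_enhancers(peaks)
print(f"{len(peaks)} peaks -> {len(stitched)} stitched regions -> "
      f"{len(ses)} super-enhancer(s)")
for se in ses:
    kb = hi.span_kb_inclusive(se.start + 1, se.end)
    print(f"  super-enhancer 7:{se.start + 1:,}-{se.end:,} "
          f"({kb} kb, signal {se.signal:.1f})")
print(f"printed-coordinate span check 7:30,297,170-30,364,571 -> "
      f"{hi.span_kb_inclusive(30_297_170, 30_364_571)} kb")

tads = [GenomicInterval("7", 29_800_000, 30_900_000),
        GenomicInterval("7", 30_900_000, 32_000_000)]
gene = GenomicInterval("7", 30_650_000, 30_700_000, "gene")
if ses:
    se_iv = GenomicInterval("7", ses[-1].start, ses[-1].end)
    same = hi.tad_comembership(se_iv, gene, tads)
    print(f"super-enhancer and gene share a TAD: {same}")

# a shared TAD makes an enhancer-promoter contact between the called
# super-enhancer and the gene physically plausible.
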