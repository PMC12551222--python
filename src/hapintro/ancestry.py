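"""Local-ancestry assignment and 5-SNP haplotype-block recoding.

An admixed haplotype is recoded, block by non-overlapping block of
``block_size_snps`` consecutive SNPs, to one of {EUR, DONOR1, DONOR2}: the
ancestry codes of the recipient and the two donor reference panels.  The
classifier is a deliberately simple window classifier standing in for a full
conditional-random-field painter: per block, each panel receives the mean of
``exp(-Hamming distance)`` over its reference haplotypes; per-block scores
are combined in log space over a centered context window of neighbouring
blocks (ancestry tracts span many blocks, so context sharpens calls
considerably), renormalized, and a block is assigned to the argmax panel
only if its combined score exceeds 0.5, falling back to EUR otherwise
(conservative: under-calls introgression).  ``context_blocks=1`` gives the
bare single-block score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .intervals import GenomicInterval
from .simulate import ANCESTRY_NAMES, EUR
from .vcfio import HaplotypeMatrix


@dataclass
class AncestryPaint:
    """Per-haplotype, per-block ancestry codes.

    ``codes`` is (n_haplotypes x n_blocks) with values indexing
    ``panel_names`` (0 is always the recipient/EUR code); ``posterior``
    holds the winning panel's combined score per call.
    """

    blocks: list[GenomicInterval]
    codes: np.ndarray
    panel_names: tuple[str, ...]
    sample_ids: list[str]
    posterior: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.codes.shape[1] != len(self.blocks):
            raise ValueError("codes column count != number of blocks")
        if self.codes.shape[0] != 2 * len(self.sample_ids):
            raise ValueError("codes row count != 2 x sample count")

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def to_frame(self) -> pd.DataFrame:
        d = {
            "chrom": [b.chrom for b in self.blocks],
            "start": [b.start for b in self.blocks],
            "end": [b.end for b in self.blocks],
        }
        for i, s in enumerate(self.sample_ids):
            d[f"{s}.0"] = self.codes[2 * i]
            d[f"{s}.1"] = self.codes[2 * i + 1]
        return pd.DataFrame(d)


def snp_blocks(hm: HaplotypeMatrix, block_size_snps: int = 5) -> list[GenomicInterval]:
    """Non-overlapping blocks of consecutive SNPs, anchored per chromosome.

    Blocks are anchored at each chromosome's first retained SNP; the last
    block of a chromosome may hold fewer SNPs.  The interval spans the
    0-based positions of the first through last SNP of the block.
    """
    blocks = []
    frame = hm.variants.frame
    for chrom, sub in frame.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        for s in range(0, len(pos), block_size_snps):
            chunk = pos[s : s + block_size_snps]
            blocks.append(GenomicInterval(str(chrom), int(chunk[0]) - 1, int(chunk[-1])))
    return blocks


def _block_site_slices(hm: HaplotypeMatrix, block_size_snps: int) -> list[np.ndarray]:
    out = []
    frame = hm.variants.frame
    offset = 0
    for chrom, sub in frame.groupby("chrom", sort=False):
        n = len(sub)
        for s in range(0, n, block_size_snps):
            out.append(np.arange(offset + s, offset + min(s + block_size_snps, n)))
        offset += n
    return out


def classify_local_ancestry(
    target: HaplotypeMatrix,
    refs: dict[str, HaplotypeMatrix],
    block_size_snps: int = 5,
    context_blocks: int = 11,
    prob_threshold: float = 0.5,
) -> AncestryPaint:
    """Paint target haplotypes with reference-panel ancestry per block.

    ``refs`` must contain at least two panels sharing the target's variant
    set; the recipient (EUR-like) panel must be first.  See the module
    docstring for the scoring rule.
    """
    if len(refs) < 2:
        raise ValueError("need at least two reference panels")
    panel_names = tuple(refs)
    for name, r in refs.items():
        if r.n_variants != target.n_variants:
            raise ValueError(f"panel {name} does not share the target variant set")
        if r.n_haplotypes == 0:
            raise ValueError(f"panel {name} has zero reference haplotypes")
    slices = _block_site_slices(target, block_size_snps)
    blocks = snp_blocks(target, block_size_snps)
    n_hap = target.n_haplotypes
    n_blocks = len(blocks)
    k = len(panel_names)
    scores = np.empty((k, n_hap, n_blocks))
    for b, idx in enumerate(slices):
        tb = target.alleles[:, idx]
        for ki, name in enumerate(panel_names):
            rb = refs[name].alleles[:, idx]
            d = (tb[:, None, :] != rb[None, :, :]).sum(-1)
            scores[ki, :, b] = np.exp(-d).mean(1)
    log_s = np.log(np.maximum(scores, 1e-300))
    if context_blocks > 1:
        from scipy.ndimage import uniform_filter1d

        # sum (not mean) of log-scores over the centered context window
        log_s = uniform_filter1d(log_s, context_blocks, axis=2, mode="nearest")
        log_s = log_s * context_blocks
    log_s = log_s - log_s.max(0)
    post = np.exp(log_s)
    post /= post.sum(0)
    best = post.argmax(0)
    best_p = post.max(0)
    codes = np.where(best_p > prob_threshold, best, EUR).astype(np.int8)
    return AncestryPaint(blocks, codes, panel_names, list(target.sample_ids), best_p)


def read_ancestry_paint(
    path: str,
    hm: HaplotypeMatrix,
    block_size_snps: int = 5,
    panel_names: tuple[str, ...] = ANCESTRY_NAMES,
) -> AncestryPaint:
    """Ingest an externally produced MSP-like TSV of ancestry segments.

    Expected columns: chrom, start, end (0-based half-open), then one
    integer ancestry-code column per haplotype, named ``<sample>.0`` /
    ``<sample>.1`` in the sample-major order of ``hm``.  Segments are
    re-segmented onto the pipeline's SNP blocks by majority bp overlap.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.empty:
        raise ValueError(f"empty ancestry file: {path}")
    hap_cols = [c for c in df.columns if c not in ("chrom", "start", "end")]
    if len(hap_cols) != hm.n_haplotypes:
        raise ValueError(
            f"haplotype count mismatch: file has {len(hap_cols)}, "
            f"VCF has {hm.n_haplotypes}"
        )
    blocks = snp_blocks(hm, block_size_snps)
    codes = np.zeros((hm.n_haplotypes, len(blocks)), dtype=np.int8)
    seg_codes = df[hap_cols].to_numpy(dtype=np.int8)
    for b, blk in enumerate(blocks):
        sub = df[
            (df["chrom"].astype(str) == blk.chrom)
            & (df["end"] > blk.start)
            & (df["start"] < blk.end)
        ]
        if sub.empty:
            continue
        overlap = (
            np.minimum(sub["end"].to_numpy(), blk.end)
            - np.maximum(sub["start"].to_numpy(), blk.start)
        ).astype(float)
        for h in range(hm.n_haplotypes):
            votes = {}
            for oi, code in zip(overlap, seg_codes[sub.index, h]):
                votes[code] = votes.get(code, 0.0) + oi
            # majority-bp rule; ties go to the lower code (EUR-conservative)
            codes[h, b] = min(
                (c for c, v in votes.items() if v == max(votes.values()))
            )
    return AncestryPaint(blocks, codes, panel_names, list(hm.sample_ids))


@dataclass
class DonorFrequencyTrack:
    """Per-block ancestry-code frequencies across a named cohort."""

    blocks: list[GenomicInterval]
    freqs: pd.DataFrame  # columns: one per panel name + 'DONOR_ALL'
    cohort: str = "cohort"

    def frequency(self, code_name: str) -> np.ndarray:
        return self.freqs[code_name].to_numpy()


def donor_frequency(
    paint: AncestryPaint, cohort: Optional[list[str]] = None, name: str = "cohort"
) -> DonorFrequencyTrack:
    """Fraction of cohort haplotypes carrying each ancestry code per block.

    Code frequencies sum to 1 at every block; the combined donor channel
    ``DONOR_ALL`` pools all non-recipient codes.
    """
    if cohort is None:
        rows = np.arange(paint.codes.shape[0])
    else:
        if not cohort:
            raise ValueError("cohort must be non-empty")
        index = {s: i for i, s in enumerate(paint.sample_ids)}
        rows = []
        for s in cohort:
            if s not in index:
                raise KeyError(f"unknown sample id: {s}")
            rows.extend([2 * index[s], 2 * index[s] + 1])
        rows = np.array(rows)
    sub = paint.codes[rows]
    n = len(rows)
    data = {
        pname: (sub == ki).sum(0) / n for ki, pname in enumerate(paint.panel_names)
    }
    donor_all = np.zeros(paint.n_blocks)
    for ki, pname in enumerate(paint.panel_names):
        if ki != EUR:
            donor_all += data[pname]
    data["DONOR_ALL"] = donor_all
    return DonorFrequencyTrack(paint.blocks, pd.DataFrame(data), name)


def call_introgressed_regions(
    track: DonorFrequencyTrack, channel: str = "DONOR_ALL", threshold: float = 0.5
) -> list[GenomicInterval]:
    """Maximal runs of consecutive blocks with frequency > threshold.

    Adjacent qualifying blocks on the same chromosome are merged into one
    interval labeled by the frequency channel.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    freq = track.frequency(channel)
    out = []
    run_start = None
    prev = None
    for i, blk in enumerate(track.blocks):
        hit = freq[i] > threshold
        contiguous = prev is not None and blk.chrom == prev.chrom
        if hit and (run_start is None or not contiguous):
            if run_start is not None:
                out.append(
                    GenomicInterval(prev.chrom, run_start.start, prev.end, channel)
                )
            run_start = blk
        elif not hit and run_start is not None:
            out.append(GenomicInterval(prev.chrom, run_start.start, prev.end, channel))
            run_start = None
        prev = blk
    if run_start is not None:
        out.append(GenomicInterval(prev.chrom, run_start.start, prev.end, channel))
    return out


def compare_frequency_profiles(
    a: DonorFrequencyTrack,
    b: DonorFrequencyTrack,
    channel: str = "DONOR_ALL",
    eps: float = 1e-9,
) -> tuple[float, float]:
    """(Pearson r, KLD) between two per-block frequency profiles.

    KLD(P||Q) is computed after adding a pseudo-count ``eps`` to each block
    frequency and normalizing both vectors to sum 1.  Pearson r is NaN for a
    zero-variance track.
    """
    fa = a.frequency(channel)
    fb = b.frequency(channel)
    if len(fa) != len(fb):
        raise ValueError("tracks are not on the same block grid")
    if np.std(fa) == 0 or np.std(fb) == 0:
        r = float("nan")
    else:
        from scipy.stats import pearsonr

        r = float(pearsonr(fa, fb)[0])
    p = fa + eps
    q = fb + eps
    p = p / p.sum()
    q = q / q.sum()
    kld = float(np.sum(p * np.log(p / q)))
    return r, kld
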