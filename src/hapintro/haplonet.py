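"""Top-LSBL marker haplotypes, minimum spanning networks, and GEBV bins.

The k SNPs with the highest locus-specific branch lengths inside a QTL
region form representative marker haplotypes; their per-population
frequencies feed a minimum spanning network (an MST over Hamming distances
plus every non-tree edge tied with the maximum weight on the tree path
between its endpoints — the epsilon = 0 MSN).  Ranking individuals by GEBV
and binning them relates introgressed-haplotype frequency to breeding
value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomicInterval
from .vcfio import HaplotypeMatrix


@dataclass
class MarkerHaplotypeSet:
    """Distinct k-SNP haplotypes with per-population counts and labels."""

    snp_ids: list[str]
    snp_pos: list[int]
    table: pd.DataFrame = field(default=None)
    # table columns: label, allele_string, <pop>_count, <pop>_freq, pooled_freq

    def hamming(self, lab_a: str, lab_b: str) -> int:
        t = self.table.set_index("label")
        a, b = t.loc[lab_a, "allele_string"], t.loc[lab_b, "allele_string"]
        return sum(x != y for x, y in zip(a, b))


def top_lsbl_haplotypes(
    lsbl_frame: pd.DataFrame,
    region: GenomicInterval,
    populations: dict[str, HaplotypeMatrix],
    k: int = 10,
) -> MarkerHaplotypeSet:
    """Build k-SNP haplotypes from the highest-LSBL sites in a region.

    ``lsbl_frame`` needs chrom/pos/lsbl.  Ties at the k-th value go to the
    lower position; selected SNPs are read off the phased data of each
    population in position order.  Labels H1, H2, ... are assigned by
    descending pooled frequency, ties by allele-string lexicographic order.
    """
    sub = lsbl_frame[
        (lsbl_frame["chrom"].astype(str) == region.chrom)
        & (lsbl_frame["pos"] - 1 >= region.start)
        & (lsbl_frame["pos"] - 1 < region.end)
    ]
    if len(sub) < k:
        raise ValueError(f"region holds {len(sub)} scored SNPs, need >= {k}")
    picked = sub.sort_values(["lsbl", "pos"], ascending=[False, True]).head(k)
    picked = picked.sort_values("pos")
    sel_pos = picked["pos"].tolist()
    counts: dict[str, dict[str, int]] = {}
    pops = list(populations)
    snp_ids = None
    for pop, hm in populations.items():
        frame = hm.variants.frame
        idx = frame.index[frame["pos"].isin(sel_pos)].to_numpy()
        if len(idx) != k:
            raise ValueError(f"population {pop} lacks some selected SNPs")
        if snp_ids is None:
            snp_ids = frame.loc[idx, "id"].tolist()
        ref = frame.loc[idx, "ref"].to_numpy()
        alt = frame.loc[idx, "alt"].to_numpy()
        sub_h = hm.alleles[:, idx]
        for row in sub_h:
            s = "".join(alt[i] if row[i] else ref[i] for i in range(k))
            counts.setdefault(s, {})[pop] = counts.setdefault(s, {}).get(pop, 0) + 1
    strings = sorted(counts)
    totals = {p: sum(counts[s].get(p, 0) for s in strings) for p in pops}
    pooled_n = sum(totals.values())
    rows = []
    for s in strings:
        row = {"allele_string": s}
        for p in pops:
            c = counts[s].get(p, 0)
            row[f"{p}_count"] = c
            row[f"{p}_freq"] = c / totals[p] if totals[p] else np.nan
        row["pooled_freq"] = sum(counts[s].get(p, 0) for p in pops) / pooled_n
        rows.append(row)
    tab = pd.DataFrame(rows).sort_values(
        ["pooled_freq", "allele_string"], ascending=[False, True]
    )
    tab.insert(0, "label", [f"H{i+1}" for i in range(len(tab))])
    return MarkerHaplotypeSet(snp_ids, sel_pos, tab.reset_index(drop=True))


def msn(haps: MarkerHaplotypeSet) -> nx.Graph:
    """Minimum spanning network over Hamming distances (epsilon = 0).

    Kruskal MST plus every non-tree edge whose weight equals the maximum
    edge weight on the tree path between its endpoints.  Node attributes
    carry the pooled frequency; edge attribute ``in_mst`` marks tree edges.
    """
    tab = haps.table
    labels = tab["label"].tolist()
    if len(labels) < 2:
        raise ValueError("need >= 2 distinct haplotypes")
    strings = dict(zip(labels, tab["allele_string"]))
    G = nx.Graph()
    for _, r in tab.iterrows():
        G.add_node(r["label"], frequency=r["pooled_freq"], allele_string=r["allele_string"])
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            d = sum(x != y for x, y in zip(strings[a], strings[b]))
            G.add_edge(a, b, weight=d)
    T = nx.minimum_spanning_tree(G, algorithm="kruskal")
    out = nx.Graph()
    out.add_nodes_from(G.nodes(data=True))
    for u, v, d in T.edges(data=True):
        out.add_edge(u, v, weight=d["weight"], in_mst=True)
    for u, v, d in G.edges(data=True):
        if out.has_edge(u, v):
            continue
        path = nx.shortest_path(T, u, v)
        path_max = max(
            T[path[i]][path[i + 1]]["weight"] for i in range(len(path) - 1)
        )
        if d["weight"] == path_max:
            out.add_edge(u, v, weight=d["weight"], in_mst=False)
    return out


def gebv_frequency_bins(
    gebv: pd.DataFrame,
    carrier_counts: dict[str, int],
    bin_size: int = 325,
) -> pd.DataFrame:
    """Haplotype frequency across GEBV-ranked bins, with the trend.

    ``carrier_counts`` maps sample_id to the number of that individual's
    two haplotypes carrying the target haplotype (0/1/2).  Individuals are
    sorted by GEBV ascending; consecutive bins of ``bin_size`` are formed
    (a smaller remainder bin is kept and flagged); per bin the target
    frequency among the bin's haplotypes and the mean GEBV are reported.
    The result carries the least-squares slope and Pearson r of frequency
    on mean GEBV as frame attrs (NaN when frequency is constant).
    """
    n = len(gebv)
    if n < 2 * bin_size:
        raise ValueError("need n >= 2 x bin_size individuals")
    ranked = gebv.sort_values(["gebv", "sample_id"]).reset_index(drop=True)
    rows = []
    for s in range(0, n, bin_size):
        chunk = ranked.iloc[s : s + bin_size]
        carriers = sum(carrier_counts.get(sid, 0) for sid in chunk["sample_id"])
        rows.append(
            {
                "bin": len(rows),
                "n": len(chunk),
                "mean_gebv": chunk["gebv"].mean(),
                "hap_frequency": carriers / (2 * len(chunk)),
                "is_remainder": len(chunk) < bin_size,
            }
        )
    out = pd.DataFrame(rows)
    f = out["hap_frequency"].to_numpy()
    g = out["mean_gebv"].to_numpy()
    if np.std(f) == 0 or np.std(g) == 0:
        slope, r = (0.0 if np.std(f) == 0 else np.nan), np.nan
    else:
        slope = float(np.polyfit(g, f, 1)[0])
        r = float(stats.pearsonr(f, g)[0])
    out.attrs["slope"] = slope
    out.attrs["pearson_r"] = r
    return out


def carrier_counts_from_haplotypes(
    hm: HaplotypeMatrix, snp_pos: list[int], allele_string: str
) -> dict[str, int]:
    """Per-sample count (0/1/2) of haplotypes matching a target string."""
    frame = hm.variants.frame
    idx = frame.index[frame["pos"].isin(snp_pos)].to_numpy()
    if len(idx) != len(snp_pos):
        raise ValueError("cohort lacks some of the selected SNPs")
    ref = frame.loc[idx, "ref"].to_numpy()
    alt = frame.loc[idx, "alt"].to_numpy()
    target = np.array(
        [0 if allele_string[i] == ref[i] else 1 for i in range(len(idx))], dtype=np.int8
    )
    match = (hm.alleles[:, idx] == target).all(axis=1)
    per_sample = match.reshape(-1, 2).sum(1)
    return dict(zip(hm.sample_ids, per_sample.astype(int)))
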