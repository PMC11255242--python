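"""Sequence features on the non-template (sense) strand.

GC skew, base percentages, maximal T-run inventory, summit head/tail
partition, T-run association, distance to the nearest 3' splice site,
G%-by-T-run-length binning, k-mer enrichment, and matched random regions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .expr_assoc import bh_adjust
from .genome import GenomeBundle, revcomp
from .peakcall import Peak


def extract_sense_sequence(peak: Peak, bundle: GenomeBundle) -> str:
    """Sense-strand (non-template) sequence of a peak, 5'->3', uppercase."""
    return bundle.fetch(peak.chrom, peak.start, peak.end, peak.strand)


def gc_skew(seq: str) -> float:
    """(G - C) / (G + C); 0.0 when the sequence has no G or C."""
    g = seq.count("G") + seq.count("g")
    c = seq.count("C") + seq.count("c")
    if g + c == 0:
        return 0.0
    return (g - c) / (g + c)


def base_pct(seq: str, base: str) -> float:
    """Percentage of ``base`` in ``seq`` (length includes ambiguous bases)."""
    if not seq:
        raise ValueError("base_pct requires a non-empty sequence")
    return 100.0 * (seq.upper().count(base.upper())) / len(seq)


@dataclass(frozen=True)
class TRun:
    """Maximal run of T at ``start`` (offset within the sense sequence)."""

    start: int
    length: int


def find_t_runs(seq: str, min_len: int = 5) -> list[TRun]:
    """All maximal T-runs of length >= min_len, sorted by start offset."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    runs = []
    s = seq.upper()
    i, n = 0, len(s)
    while i < n:
        if s[i] == "T":
            j = i
            while j < n and s[j] == "T":
                j += 1
            if j - i >= min_len:
                runs.append(TRun(start=i, length=j - i))
            i = j
        else:
            i += 1
    return runs


@dataclass
class RegionFeatures:
    peak: Peak
    sequence: str
    gc_skew: float
    g_pct: float
    t_pct: float
    t_runs: list[TRun]
    summit_offset: int  # head = [0, summit_offset), tail = [summit_offset, width)
    dist_3ss: float = math.inf
    context: str = ""

    @property
    def max_trun(self) -> int:
        return max((r.length for r in self.t_runs), default=0)

    @property
    def head(self) -> str:
        return self.sequence[: self.summit_offset]

    @property
    def tail(self) -> str:
        return self.sequence[self.summit_offset :]


def _summit_offset(peak: Peak) -> int:
    """Summit position expressed as an offset into the sense sequence."""
    if peak.strand == "+":
        return peak.summit - peak.start
    return peak.end - 1 - peak.summit


def region_features(
    peak: Peak,
    bundle: GenomeBundle,
    min_trun: int = 5,
) -> RegionFeatures:
    seq = extract_sense_sequence(peak, bundle)
    return RegionFeatures(
        peak=peak,
        sequence=seq,
        gc_skew=gc_skew(seq),
        g_pct=base_pct(seq, "G"),
        t_pct=base_pct(seq, "T"),
        t_runs=find_t_runs(seq, min_trun),
        summit_offset=_summit_offset(peak),
    )


def associate_t_runs(
    peaks: list[Peak],
    bundle: GenomeBundle,
    min_len: int = 5,
) -> tuple[list[Peak], list[Peak]]:
    """Partition peaks into (t_run_associated, other).

    A peak is T-run associated iff the tail half of its sense sequence
    (downstream of the summit) contains a maximal T-run of length >= min_len.
    """
    associated, other = [], []
    for peak in peaks:
        feats = region_features(peak, bundle, min_trun=min_len)
        if find_t_runs(feats.tail, min_len):
            associated.append(peak)
        else:
            other.append(peak)
    return associated, other


def distance_to_3ss(peak: Peak, bundle: GenomeBundle) -> float:
    """Distance from the summit to the nearest intron acceptor on the peak's
    strand; inf when that strand has no introns."""
    acceptors = [
        a
        for g in bundle.genes
        if g.chrom == peak.chrom and g.strand == peak.strand
        for a in g.acceptor_sites()
    ]
    if not acceptors:
        return math.inf
    return float(min(abs(peak.summit - a) for a in acceptors))


DEFAULT_TRUN_BINS = (5, 10, 15, 20, 25)


def gpct_by_trun_bins(
    features: list[RegionFeatures],
    bin_edges: tuple[int, ...] = DEFAULT_TRUN_BINS,
) -> pd.DataFrame:
    """Mean G% (+/- SEM) binned by each region's longest T-run.

    The last bin is open-ended. Also reports the Spearman correlation of
    per-region (max T-run length, G%) as a monotone-trend statistic.
    """
    rows = []
    lengths = np.array([f.max_trun for f in features])
    gpcts = np.array([f.g_pct for f in features])
    if np.any(lengths < 1):
        raise ValueError("every region must contain at least one T-run")
    edges = list(bin_edges) + [np.inf]
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (lengths >= lo) & (lengths < hi)
        n = int(mask.sum())
        vals = gpcts[mask]
        rows.append(
            {
                "bin_lo": lo,
                "bin_hi": hi,
                "n": n,
                "mean_g_pct": float(vals.mean()) if n else np.nan,
                "sem_g_pct": float(vals.std(ddof=1) / math.sqrt(n)) if n > 1 else np.nan,
            }
        )
    table = pd.DataFrame(rows)
    if len(features) > 2 and len(set(lengths)) > 1:
        rho = float(stats.spearmanr(lengths, gpcts).statistic)
    else:
        rho = np.nan
    table.attrs["spearman_rho"] = rho
    return table


# --------------------------------------------------------------------------
# k-mer enrichment


def _kmer_counts(seqs: list[str], k: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for s in seqs:
        s = s.upper()
        for i in range(len(s) - k + 1):
            kmer = s[i : i + k]
            if set(kmer) <= set("ACGT"):
                counts[kmer] = counts.get(kmer, 0) + 1
    return counts


def kmer_enrichment(
    target: list[str],
    background: list[str],
    k: int = 6,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Rank k-mers by one-sided binomial enrichment of target vs background.

    Expected frequency of each k-mer comes from its (pseudocounted)
    background frequency; p-values are BH-adjusted across all 4^k tests.
    """
    if not target or not background:
        raise ValueError("kmer_enrichment requires non-empty target and background")
    if any(len(s) < k for s in target):
        raise ValueError(f"all target sequences must be at least {k} long")
    tgt = _kmer_counts(target, k)
    bkg = _kmer_counts(background, k)
    n_tgt = sum(tgt.values())
    n_bkg = sum(bkg.values())
    if n_tgt == 0 or n_bkg == 0:
        raise ValueError("no countable k-mers in target or background")

    from itertools import product

    all_kmers = ["".join(p) for p in product("ACGT", repeat=k)]
    n_kinds = len(all_kmers)
    # conditional binomial: target count among pooled target+background
    # occurrences, so background sampling noise is absorbed
    p0 = n_tgt / (n_tgt + n_bkg)
    rows = []
    for kmer in all_kmers:
        x = tgt.get(kmer, 0)
        y = bkg.get(kmer, 0)
        pval = float(stats.binom.sf(x - 1, x + y, p0)) if x > 0 else 1.0
        p_bkg = (y + pseudocount) / (n_bkg + pseudocount * n_kinds)
        expected = n_tgt * p_bkg
        rows.append(
            {
                "kmer": kmer,
                "observed": x,
                "expected": expected,
                "enrichment": x / expected if expected > 0 else np.nan,
                "p_value": min(1.0, pval),
            }
        )
    table = pd.DataFrame(rows)
    table["q_value"] = bh_adjust(table["p_value"].to_numpy())
    table = table.sort_values(
        ["p_value", "enrichment"], ascending=[True, False], kind="mergesort"
    ).reset_index(drop=True)
    return table


# --------------------------------------------------------------------------
# random region sampling


def sample_random_regions(
    bundle: GenomeBundle,
    n: int,
    lengths: list[int],
    seed: int,
    max_resample: int = 1000,
) -> list[Peak]:
    """n regions inside gene spans with lengths resampled from ``lengths``.

    Strand follows the host gene. Deterministic given the seed.
    """
    if not bundle.genes:
        raise ValueError("no genes to sample from")
    rng = np.random.default_rng(seed)
    lengths_arr = np.asarray(lengths, dtype=int)
    regions: list[Peak] = []
    genes = bundle.genes
    for i in range(n):
        length = int(lengths_arr[rng.integers(0, lengths_arr.size)])
        for attempt in range(max_resample):
            g = genes[int(rng.integers(0, len(genes)))]
            if g.length > length:
                start = g.start + int(rng.integers(0, g.length - length))
                regions.append(
                    Peak(
                        chrom=g.chrom,
                        strand=g.strand,
                        start=start,
                        end=start + length,
                        summit=start + length // 2,
                        intensity=0.0,
                        p_value=1.0,
                        name=f"rand_{i + 1}",
                    )
                )
                break
        else:
            raise ValueError(
                f"could not place a {length} bp region after {max_resample} tries"
            )
    return regions


def features_table(
    peaks: list[Peak],
    bundle: GenomeBundle,
    min_trun: int = 5,
    contexts: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Feature TSV contract: one row per peak."""
    rows = []
    for i, p in enumerate(peaks):
        f = region_features(p, bundle, min_trun=min_trun)
        f.dist_3ss = distance_to_3ss(p, bundle)
        rows.append(
            {
                "peak_id": p.name or f"peak_{i + 1}",
                "chrom": p.chrom,
                "start": p.start,
                "end": p.end,
                "strand": p.strand,
                "gc_skew": f.gc_skew,
                "g_pct": f.g_pct,
                "t_pct": f.t_pct,
                "max_trun": f.max_trun,
                "n_truns": len(f.t_runs),
                "dist_3ss": f.dist_3ss,
                "context": (contexts or {}).get(p.name, ""),
            }
        )
    return pd.DataFrame(rows)
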