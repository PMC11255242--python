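"""Synthetic dataset generator.

Produces a genome with gene models, plants G-cluster/spacer/T-run motifs
inside introns, and simulates stranded coverage for two conditions plus
negative-binomial count matrices, with a complete ground-truth table.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import Gene, GenomeBundle, file_digest, revcomp

logger = logging.getLogger(__name__)

BASES = "ACGT"


# --------------------------------------------------------------------------
# configuration types


@dataclass
class SpeciesProfile:
    """Statistical laws for one synthetic species."""

    name: str
    n_genes: int
    chrom_length: int
    intron_length_law: tuple[float, float]  # log-normal (mu, sigma) in log-bp
    exon_length_law: tuple[float, float]
    exons_per_gene_law: tuple[int, int]  # inclusive discrete uniform
    background_base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    chrom_name: str = "chr1"

    def validate(self) -> list[str]:
        problems = []
        if self.n_genes <= 0:
            problems.append("n_genes must be positive")
        if self.chrom_length <= 0:
            problems.append("chrom_length must be positive")
        if abs(sum(self.background_base_freqs) - 1.0) > 1e-9:
            problems.append("background_base_freqs must sum to 1")
        if any(f < 0 for f in self.background_base_freqs):
            problems.append("background_base_freqs must be non-negative")
        if self.exons_per_gene_law[0] < 1:
            problems.append("exons_per_gene_law minimum must be >= 1")
        for law_name in ("intron_length_law", "exon_length_law"):
            mu, sigma = getattr(self, law_name)
            if sigma <= 0:
                problems.append(f"{law_name} sigma must be positive")
        return problems


HUMAN_LIKE = SpeciesProfile(
    name="human_like",
    n_genes=250,
    chrom_length=12_000_000,
    intron_length_law=(8.0, 0.8),
    exon_length_law=(5.3, 0.4),
    exons_per_gene_law=(4, 8),
)

MOUSE_LIKE = SpeciesProfile(
    name="mouse_like",
    n_genes=250,
    chrom_length=6_000_000,
    intron_length_law=(7.0, 0.25),
    exon_length_law=(5.3, 0.4),
    exons_per_gene_law=(4, 8),
)

PROFILES = {"human_like": HUMAN_LIKE, "mouse_like": MOUSE_LIKE}


@dataclass
class MotifLaw:
    """Sampling law for planted G-cluster + spacer + T-run motifs.

    G-cluster length is coupled negatively to T-run length so that longer
    T-runs come with less G-rich upstream clusters.
    """

    density_per_intron_bp: float = 1.0 / 28_000
    t_run_range: tuple[int, int] = (5, 24)
    gap_range: tuple[int, int] = (5, 15)
    g_base: float = 30.0
    g_slope: float = 0.8
    g_noise_sd: float = 2.0
    g_min: int = 10
    g_max: int = 40
    amplitude_high: float = 300.0
    amplitude_low: float = 5.0
    frac_subthreshold: float = 0.45
    kd_gain_high: float = 2.0
    kd_gain_low: float = 24.0
    n_motifs: int | None = None  # overrides density when set
    spacer_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)


@dataclass
class SimulationConfig:
    seed: int = 0
    depth: float = 2.0
    peak_kernel_sd: float = 25.0
    n_replicates: int = 3
    nb_dispersion: float = 0.1
    kd_effect: float = 0.8  # log2FC magnitude per planted motif
    cap_m: int = 4
    frac_compensatory_up: float = 0.05
    up_effect: float = 1.6  # log2FC of compensatory upregulated genes
    tss_amplitude: float = 300.0
    count_mean_law: tuple[float, float] = (5.3, 1.0)  # log-normal baseline means
    read_length_equiv: int = 50

    def validate(self) -> list[str]:
        problems = []
        if self.depth < 0:
            problems.append("depth must be non-negative")
        if self.peak_kernel_sd <= 0:
            problems.append("peak_kernel_sd must be positive")
        if self.n_replicates < 1:
            problems.append("n_replicates must be >= 1")
        if self.nb_dispersion <= 0:
            problems.append("nb_dispersion must be positive")
        if self.kd_effect < 0:
            problems.append("kd_effect must be non-negative")
        if self.cap_m < 1:
            problems.append("cap_m must be >= 1")
        if not 0 <= self.frac_compensatory_up <= 1:
            problems.append("frac_compensatory_up must be in [0, 1]")
        return problems


# --------------------------------------------------------------------------
# truth records


@dataclass
class PlantedMotif:
    gene_id: str
    chrom: str
    strand: str
    g_cluster_start: int  # genomic start of the G-cluster footprint
    g_cluster_len: int
    gap_len: int
    t_run_len: int
    base_amplitude: float
    kd_gain: float
    start: int = 0  # leftmost genomic coordinate of the whole motif
    end: int = 0

    @property
    def total_len(self) -> int:
        return self.g_cluster_len + self.gap_len + self.t_run_len

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class TruthTable:
    motifs: list[PlantedMotif]
    genes: pd.DataFrame  # gene_id, chrom, strand, start, end, length, motif_count, true_log2fc

    def motif_count(self, gene_id: str) -> int:
        row = self.genes.loc[self.genes.gene_id == gene_id]
        return int(row.motif_count.iloc[0]) if len(row) else 0


# --------------------------------------------------------------------------
# genome simulation


def _sample_gene_structures(profile: SpeciesProfile, rng: np.random.Generator):
    """Sample exon/intron lengths per gene; returns list of block-length lists."""
    structures = []
    lo, hi = profile.exons_per_gene_law
    imu, isd = profile.intron_length_law
    emu, esd = profile.exon_length_law
    for _ in range(profile.n_genes):
        n_exons = int(rng.integers(lo, hi + 1))
        exon_lens = np.maximum(
            1, np.round(rng.lognormal(emu, esd, n_exons))
        ).astype(int)
        intron_lens = np.maximum(
            1, np.round(rng.lognormal(imu, isd, n_exons - 1))
        ).astype(int)
        structures.append((exon_lens, intron_lens))
    return structures


def simulate_genome(profile: SpeciesProfile, seed: int) -> GenomeBundle:
    """Sample a background genome and place non-overlapping gene models.

    Raises ``ValueError`` when the chromosome cannot hold the requested
    gene complement.
    """
    problems = profile.validate()
    if problems:
        raise ValueError("invalid profile: " + "; ".join(problems))
    rng = np.random.default_rng(seed)

    structures = _sample_gene_structures(profile, rng)
    gene_lengths = [int(e.sum() + i.sum()) for e, i in structures]
    total = sum(gene_lengths)
    spare = profile.chrom_length - total
    if spare < profile.n_genes + 1:
        raise ValueError(
            f"chrom_length {profile.chrom_length} too small for {profile.n_genes} "
            f"genes totalling {total} bp"
        )

    # intergenic gaps: n_genes+1 slots sharing the spare length
    cuts = np.sort(rng.integers(0, spare + 1, profile.n_genes))
    gaps = np.diff(np.concatenate([[0], cuts, [spare]]))

    seq = rng.choice(
        np.frombuffer(BASES.encode(), dtype=np.uint8),
        size=profile.chrom_length,
        p=np.asarray(profile.background_base_freqs),
    )

    genes = []
    pos = 0
    for i, (exon_lens, intron_lens) in enumerate(structures):
        pos += int(gaps[i])
        start = pos
        exons = []
        for j, el in enumerate(exon_lens):
            exons.append((pos, pos + int(el)))
            pos += int(el)
            if j < len(intron_lens):
                pos += int(intron_lens[j])
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            Gene(
                gene_id=f"{profile.name}_g{i:05d}",
                chrom=profile.chrom_name,
                strand=strand,
                start=start,
                end=pos,
                exons=exons,
            )
        )
    return GenomeBundle(
        chroms={profile.chrom_name: seq.tobytes().decode()}, genes=genes
    )


# --------------------------------------------------------------------------
# motif planting


def _sample_motif(law: MotifLaw, rng: np.random.Generator):
    t_len = int(rng.integers(law.t_run_range[0], law.t_run_range[1] + 1))
    g_len = int(
        np.clip(
            round(
                law.g_base
                - law.g_slope * (t_len - law.t_run_range[0])
                + rng.normal(0.0, law.g_noise_sd)
            ),
            law.g_min,
            law.g_max,
        )
    )
    gap = int(rng.integers(law.gap_range[0], law.gap_range[1] + 1))
    if rng.random() < law.frac_subthreshold:
        amp, gain = law.amplitude_low, law.kd_gain_low
    else:
        amp, gain = law.amplitude_high, law.kd_gain_high
    return g_len, gap, t_len, amp, gain


def plant_motifs(
    bundle: GenomeBundle,
    config: SimulationConfig,
    motif_law: MotifLaw | None = None,
) -> tuple[GenomeBundle, TruthTable]:
    """Plant motifs into introns, placement probability proportional to length.

    The sense-strand sequence at each planted locus is literally
    G-cluster, spacer drawn from background, then T-run. Introns too short
    for a sampled motif are skipped with a warning.
    """
    law = motif_law or MotifLaw()
    rng = np.random.default_rng(config.seed + 104729)

    introns = []  # (gene, intron_start, intron_end)
    for gene in bundle.genes:
        for iv in gene.introns:
            introns.append((gene, iv[0], iv[1]))
    if not introns:
        raise ValueError("no introns available for motif planting")

    intron_lens = np.array([e - s for _, s, e in introns], dtype=float)
    total_intron_bp = intron_lens.sum()
    n_motifs = (
        law.n_motifs
        if law.n_motifs is not None
        else max(1, int(round(law.density_per_intron_bp * total_intron_bp)))
    )
    weights = intron_lens / intron_lens.sum()

    seqs = {name: bytearray(s, "ascii") for name, s in bundle.chroms.items()}
    occupied: dict[int, list[tuple[int, int]]] = {}
    motifs: list[PlantedMotif] = []
    freqs = np.asarray(law.spacer_freqs)

    for _ in range(n_motifs):
        idx = int(rng.choice(len(introns), p=weights))
        gene, istart, iend = introns[idx]
        g_len, gap, t_len, amp, gain = _sample_motif(law, rng)
        total = g_len + gap + t_len
        if iend - istart < total + 2:
            logger.warning(
                "intron [%d,%d) of %s shorter than motif (%d bp); skipped",
                istart,
                iend,
                gene.gene_id,
                total,
            )
            continue
        placed = False
        for _attempt in range(20):
            start = int(rng.integers(istart + 1, iend - total))
            span = (start, start + total)
            if any(s < span[1] and span[0] < e for s, e in occupied.get(idx, [])):
                continue
            placed = True
            break
        if not placed:
            continue
        occupied.setdefault(idx, []).append(span)

        spacer = list(rng.choice(list(BASES), size=gap, p=freqs))
        if spacer[0] == "G":  # must not extend the G-cluster
            spacer[0] = "A"
        if spacer[-1] == "T":  # must not extend the T-run
            spacer[-1] = "A"
        sense = "G" * g_len + "".join(spacer) + "T" * t_len
        plus = sense if gene.strand == "+" else revcomp(sense)
        seqs[gene.chrom][span[0] : span[1]] = plus.encode()
        # keep the planted runs maximal: flanking bases must not extend them
        left_bad, right_bad = ("G", "T") if gene.strand == "+" else ("A", "C")
        if chr(seqs[gene.chrom][span[0] - 1]) == left_bad:
            seqs[gene.chrom][span[0] - 1] = ord("C" if left_bad != "C" else "A")
        if chr(seqs[gene.chrom][span[1]]) == right_bad:
            seqs[gene.chrom][span[1]] = ord("C" if right_bad != "C" else "A")

        if gene.strand == "+":
            g_start = span[0]
        else:
            g_start = span[1] - g_len
        motifs.append(
            PlantedMotif(
                gene_id=gene.gene_id,
                chrom=gene.chrom,
                strand=gene.strand,
                g_cluster_start=g_start,
                g_cluster_len=g_len,
                gap_len=gap,
                t_run_len=t_len,
                base_amplitude=amp,
                kd_gain=gain,
                start=span[0],
                end=span[1],
            )
        )

    new_bundle = GenomeBundle(
        chroms={name: bytes(b).decode() for name, b in seqs.items()},
        genes=bundle.genes,
    )
    truth = _build_truth(new_bundle, motifs, config, rng)
    return new_bundle, truth


def _build_truth(
    bundle: GenomeBundle,
    motifs: list[PlantedMotif],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> TruthTable:
    counts = {g.gene_id: 0 for g in bundle.genes}
    for m in motifs:
        counts[m.gene_id] += 1
    records = []
    motif_free = [g for g in bundle.genes if counts[g.gene_id] == 0]
    n_up = int(round(config.frac_compensatory_up * len(motif_free)))
    up_ids = set(
        rng.choice([g.gene_id for g in motif_free], size=n_up, replace=False)
    ) if n_up else set()
    for g in bundle.genes:
        m = counts[g.gene_id]
        if m > 0:
            lfc = -config.kd_effect * min(m, config.cap_m)
        elif g.gene_id in up_ids:
            lfc = config.up_effect
        else:
            lfc = 0.0
        records.append(
            {
                "gene_id": g.gene_id,
                "chrom": g.chrom,
                "strand": g.strand,
                "start": g.start,
                "end": g.end,
                "length": g.length,
                "motif_count": m,
                "true_log2fc": lfc,
            }
        )
    return TruthTable(motifs=motifs, genes=pd.DataFrame.from_records(records))


# --------------------------------------------------------------------------
# coverage simulation


@dataclass
class StrandedCoverage:
    """Per-chromosome, per-strand integer coverage vectors."""

    tracks: dict[str, dict[str, np.ndarray]]  # chrom -> strand -> counts
    read_length_equiv: int = 50

    def library_size(self, strand: str) -> float:
        """Read-equivalent library size for one strand track."""
        total = sum(
            float(self.tracks[c][strand].sum())
            for c in self.tracks
            if strand in self.tracks[c]
        )
        return total / self.read_length_equiv

    def get(self, chrom: str, strand: str) -> np.ndarray:
        return self.tracks[chrom][strand]


def simulate_coverage(
    bundle: GenomeBundle,
    truth: TruthTable,
    condition: str,
    config: SimulationConfig,
) -> StrandedCoverage:
    """Poisson coverage: background depth + Gaussian peaks at planted motifs.

    TSS peaks of fixed amplitude are added on every gene's strand in both
    conditions; motif amplitudes are multiplied by their knockdown gain
    under ``condition == 'kd'``.
    """
    if condition not in ("control", "kd"):
        raise ValueError(f"condition must be 'control' or 'kd', got {condition!r}")
    problems = config.validate()
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    cond_offset = 0 if condition == "control" else 1
    rng = np.random.default_rng(config.seed + 7919 * (1 + cond_offset))

    sd = config.peak_kernel_sd
    half = int(math.ceil(4 * sd))
    offsets = np.arange(-half, half + 1)
    kernel = np.exp(-(offsets**2) / (2 * sd * sd))

    tracks: dict[str, dict[str, np.ndarray]] = {}
    for chrom, seq in bundle.chroms.items():
        n = len(seq)
        lam = {
            "+": np.full(n, float(config.depth)),
            "-": np.full(n, float(config.depth)),
        }

        def add_peak(center: int, strand: str, amplitude: float) -> None:
            lo = max(0, center - half)
            hi = min(n, center + half + 1)
            lam[strand][lo:hi] += amplitude * kernel[
                lo - (center - half) : hi - (center - half)
            ]

        for gene in bundle.genes:
            if gene.chrom != chrom:
                continue
            if config.tss_amplitude > 0:
                add_peak(gene.tss, gene.strand, config.tss_amplitude)
        for m in truth.motifs:
            if m.chrom != chrom:
                continue
            amp = m.base_amplitude * (m.kd_gain if condition == "kd" else 1.0)
            add_peak(m.center, m.strand, amp)

        tracks[chrom] = {s: rng.poisson(lam[s]) for s in "+-"}
    return StrandedCoverage(tracks=tracks, read_length_equiv=config.read_length_equiv)


# --------------------------------------------------------------------------
# count simulation


def simulate_counts(
    truth: TruthTable, config: SimulationConfig, condition: str
) -> pd.DataFrame:
    """Negative-binomial counts per gene for one condition.

    Counts ~ NB(mean mu_g * 2^(log2FC_g [kd]), dispersion phi) drawn as a
    gamma-Poisson mixture; baseline means are log-normal and fixed by the
    config seed so both conditions share them.
    """
    if condition not in ("control", "kd"):
        raise ValueError(f"condition must be 'control' or 'kd', got {condition!r}")
    base_rng = np.random.default_rng(config.seed + 15485863)
    mu0 = base_rng.lognormal(*config.count_mean_law, size=len(truth.genes))

    cond_offset = 0 if condition == "control" else 1
    rng = np.random.default_rng(config.seed + 32452843 * (1 + cond_offset))
    lfc = truth.genes.true_log2fc.to_numpy()
    mu = mu0 * np.power(2.0, lfc * cond_offset)
    phi = config.nb_dispersion

    data = {}
    for rep in range(config.n_replicates):
        shape = 1.0 / phi
        lam = rng.gamma(shape, mu * phi)
        data[f"{condition}_{rep + 1}"] = rng.poisson(lam)
    return pd.DataFrame(data, index=truth.genes.gene_id.to_numpy())


def nb_draws(
    mu: float, phi: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Plain NB(mu, phi) sampler (gamma-Poisson); variance mu + phi*mu^2."""
    lam = rng.gamma(1.0 / phi, mu * phi, size=size)
    return rng.poisson(lam)


# --------------------------------------------------------------------------
# dataset writer


@dataclass
class Dataset:
    bundle: GenomeBundle
    truth: TruthTable
    coverage: dict[str, StrandedCoverage]  # condition -> coverage
    counts: pd.DataFrame  # genes x samples, both conditions


def simulate_dataset(
    profile: SpeciesProfile,
    config: SimulationConfig,
    motif_law: MotifLaw | None = None,
) -> Dataset:
    """Full simulation for one species profile."""
    bundle = simulate_genome(profile, config.seed)
    bundle, truth = plant_motifs(bundle, config, motif_law)
    coverage = {
        cond: simulate_coverage(bundle, truth, cond, config)
        for cond in ("control", "kd")
    }
    counts = pd.concat(
        [simulate_counts(truth, config, c) for c in ("control", "kd")], axis=1
    )
    return Dataset(bundle=bundle, truth=truth, coverage=coverage, counts=counts)


def _write_bedgraph(path: Path, chrom: str, counts: np.ndarray) -> None:
    """Run-length encoded bedGraph tiling the chromosome (0-based half-open)."""
    change = np.flatnonzero(np.diff(counts)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(counts)]])
    vals = counts[starts]
    with open(path, "w") as fh:
        for s, e, v in zip(starts, ends, vals):
            fh.write(f"{chrom}\t{s}\t{e}\t{int(v)}\n")


def read_bedgraph(path: str | Path, chrom_lengths: dict[str, int]) -> dict[str, np.ndarray]:
    """Read a bedGraph into dense per-chromosome vectors."""
    out = {c: np.zeros(n, dtype=np.int64) for c, n in chrom_lengths.items()}
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "value"],
        comment="#",
    )
    for chrom, sub in df.groupby("chrom"):
        if chrom not in out:
            continue
        for s, e, v in zip(sub.start, sub.end, sub.value):
            out[chrom][s:e] = v
    return out


def write_dataset(dataset: Dataset, out_dir: str | Path) -> pd.DataFrame:
    """Write FASTA/GFF/bedGraph/TSV files; returns a manifest with digests."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out}: {exc}") from exc

    files = []
    dataset.bundle.write_fasta(out / "genome.fa")
    files.append("genome.fa")
    dataset.bundle.write_gff(out / "genes.gff")
    files.append("genes.gff")

    strand_tag = {"+": "plus", "-": "minus"}
    cond_tag = {"control": "ctrl", "kd": "kd"}
    for cond, cov in dataset.coverage.items():
        for chrom in sorted(cov.tracks):
            for strand in "+-":
                name = f"cov.{strand_tag[strand]}.{cond_tag[cond]}.bedGraph"
                _write_bedgraph(out / name, chrom, cov.tracks[chrom][strand])
                files.append(name)

    dataset.counts.rename_axis("gene_id").to_csv(out / "counts.tsv", sep="\t")
    files.append("counts.tsv")

    truth_genes = dataset.truth.genes
    truth_genes.to_csv(out / "truth.tsv", sep="\t", index=False)
    files.append("truth.tsv")
    motif_df = pd.DataFrame(
        [
            {
                "gene_id": m.gene_id,
                "chrom": m.chrom,
                "strand": m.strand,
                "start": m.start,
                "end": m.end,
                "g_cluster_start": m.g_cluster_start,
                "g_cluster_len": m.g_cluster_len,
                "gap_len": m.gap_len,
                "t_run_len": m.t_run_len,
                "base_amplitude": m.base_amplitude,
                "kd_gain": m.kd_gain,
            }
            for m in dataset.truth.motifs
        ]
    )
    motif_df.to_csv(out / "motifs.tsv", sep="\t", index=False)
    files.append("motifs.tsv")

    manifest = pd.DataFrame(
        {"file": files, "sha256": [file_digest(out / f) for f in files]}
    )
    manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    return manifest
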