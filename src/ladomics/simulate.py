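"""Seeded generator of synthetic inputs with the study's data structure.

The generator emulates a two-group fibroblast methylation study with a
LAD-centric effect architecture:

* a genome of alternating LAD / inter-LAD blocks (lamin A and lamin B
  tracks drawn independently), genes, histone-mark tracks and CpG probes
  whose density and region class (CpG island / PMD / HMD, solo-WCGW)
  depend on LAD membership;
* a beta-value matrix in which case samples carry planted
  hypermethylation on a subset of lamin A LAD probes, and one case
  subgroup additionally drifts globally toward partial methylation
  (beta ~ 0.6), creating a three-group sample structure;
* differential ATAC-like peaks placed inside lamin A LADs with a
  configurable enrichment factor over a uniform background peak set;
* differentially expressed genes drawn preferentially from
  LAD-proximal positions;
* a sparse synthetic clock whose beta columns are constructed by
  inverting the age transform at planted DNAm ages, including an
  age-accelerated case subgroup;
* ChIP/input signal over LAD and inter-LAD segments with a planted
  log2 enrichment.

Every output is a pure function of ``(config, seed)``; the planted
parameters are recorded in a truth dictionary so each downstream stage
can be checked for parameter recovery.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .clock import ClockModel, inverse_transform_age
from .diffmeth import BetaMatrix
from .intervals import AnnotationTrack, GenomicInterval, write_bed

__all__ = [
    "SimulationConfig",
    "SyntheticGenome",
    "make_genome",
    "make_methylation",
    "make_diff_peaks",
    "make_expression",
    "make_clock",
    "make_chip_signal",
    "simulate_all",
]

# stable per-stage stream keys so stages stay independent of each other
_STAGE_GENOME, _STAGE_METH, _STAGE_PEAKS, _STAGE_EXPR, _STAGE_CLOCK, _STAGE_CHIP = range(6)

HISTONE_MARKS: dict[str, float] = {
    # probability that a mark interval falls inside a lamin A LAD
    "H3K4me1": 0.6,
    "H3K4me2": 0.1,
    "H3K4me3": 0.05,
    "H3K27ac": 0.1,
    "H3K36me3": 0.1,
    "H3K9me3": 0.8,
    "H3K27me3": 0.5,
}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults are the study conditions."""

    # genome geometry
    n_chromosomes: int = 4
    chrom_length: int = 25_000_000
    lad_fraction: float = 0.20
    lad_mean_length: int = 500_000
    lamin_b_fraction: float = 0.30

    # probes
    n_probes: int = 20_000
    probe_in_lad_fraction: float = 0.12
    island_fraction: float = 0.10         # among non-LAD probes
    pmd_prob_in_lad: float = 0.80
    pmd_prob_outside: float = 0.05
    solo_wcgw_fraction: float = 0.15
    flag_fraction: float = 0.01           # sex / SNP / cross-reactive each
    det_fail_probe_fraction: float = 0.005

    # beta noise: per-region-class mean and per-probe sd
    class_means: Mapping[str, float] = field(
        default_factory=lambda: {"island": 0.10, "pmd": 0.60, "hmd": 0.85}
    )
    class_sds: Mapping[str, float] = field(
        default_factory=lambda: {"island": 0.03, "pmd": 0.05, "hmd": 0.03}
    )
    probe_mean_jitter: float = 0.05

    # samples and planted methylation effects
    n_control: int = 6
    n_case_sub1: int = 5
    n_case_sub2: int = 4
    lad_delta_beta: float = 0.10
    n_affected_probes: int = 2000
    subgroup_shift: float = 0.30          # weight toward beta = 0.6 in subgroup 2
    clip_tolerance: float = 0.02

    # differential peaks
    n_diff_peaks: int = 545
    n_gained: int = 397
    n_lost: int = 148
    n_background_peaks: int = 5000
    peak_width: int = 500
    peak_lad_enrichment: float = 2.6

    # expression
    n_genes: int = 2000
    gene_min_length: int = 5_000
    gene_max_length: int = 50_000
    n_de_genes: int = 343
    n_de_up: int = 160
    n_de_down: int = 183
    de_lad_proximal_frac: float = 0.5
    proximal_max_distance: int = 10_000

    # clock and ages
    clock_n_probes: int = 200
    clock_beta_noise_sd: float = 0.0
    age_min: float = 2.0
    age_max: float = 9.0
    accel_shift: float = 9.73             # planted DNAm age shift, subgroup 2
    decel_shift: float = -1.51            # planted shift, subgroup 1
    control_shift: float = 0.0
    passage_min: int = 8
    passage_max: int = 12
    seeded_cells: int = 100_000

    # ChIP signal
    chip_log2_enrichment: float = 1.0
    chip_noise_sd: float = 0.15

    def validate(self) -> "SimulationConfig":
        if not 0 <= self.lad_fraction < 1:
            raise ValueError("lad_fraction must lie in [0, 1)")
        if self.lad_mean_length > self.chrom_length:
            raise ValueError("mean LAD length exceeds the chromosome")
        if min(self.n_control, self.n_case_sub1, self.n_case_sub2) < 2:
            raise ValueError("every group needs >= 2 samples")
        if self.n_gained + self.n_lost != self.n_diff_peaks:
            raise ValueError("n_gained + n_lost must equal n_diff_peaks")
        if self.n_de_up + self.n_de_down != self.n_de_genes:
            raise ValueError("n_de_up + n_de_down must equal n_de_genes")
        return self

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["class_means"] = dict(d["class_means"])
        d["class_sds"] = dict(d["class_sds"])
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d).validate()


@dataclass
class SyntheticGenome:
    """Genome-level outputs shared by the downstream generators."""

    lamin_a: AnnotationTrack
    lamin_b: AnnotationTrack
    inter_lad: AnnotationTrack            # lamin A complement
    genes: pd.DataFrame
    probe_annot: pd.DataFrame
    probe_class: pd.Series                # island / pmd / hmd per probe
    histone_tracks: dict[str, AnnotationTrack]
    enhancers: AnnotationTrack
    chrom_lengths: dict[str, int]


def _alternating_blocks(rng, length: int, frac: float, mean_len: int):
    """Alternating kept/skipped blocks with exponential lengths; returns
    the kept ([start, end)) list covering ~frac of the chromosome."""
    if frac == 0:
        return []
    gap_mean = mean_len * (1 - frac) / frac
    blocks = []
    pos = int(rng.exponential(gap_mean / 2))  # random phase
    while pos < length:
        lad_len = max(int(rng.exponential(mean_len)), 10_000)
        end = min(pos + lad_len, length)
        if end - pos >= 10_000:
            blocks.append((pos, end))
        pos = end + max(int(rng.exponential(gap_mean)), 10_000)
    return blocks


def _complement(blocks, length: int):
    out, pos = [], 0
    for s, e in blocks:
        if s > pos:
            out.append((pos, s))
        pos = e
    if pos < length:
        out.append((pos, length))
    return out


def _uniform_in_blocks(rng, blocks, width: int = 1):
    """Uniform position for an interval of `width` fully inside a block."""
    usable = [(s, e) for s, e in blocks if e - s > width]
    lens = np.array([e - s - width for s, e in usable], dtype=float)
    i = rng.choice(len(usable), p=lens / lens.sum())
    s, e = usable[i]
    start = int(rng.integers(s, e - width))
    return start, start + width


def make_genome(config: SimulationConfig, seed: int) -> SyntheticGenome:
    """Deterministic synthetic genome: LAD tracks, genes, probes, marks."""
    config.validate()
    rng = np.random.default_rng([int(seed), _STAGE_GENOME])
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    chrom_lengths = {c: config.chrom_length for c in chroms}

    lad_a, lad_b, inter = [], [], []
    blocks_a: dict[str, list] = {}
    inter_a: dict[str, list] = {}
    for c in chroms:
        blocks = _alternating_blocks(
            rng, config.chrom_length, config.lad_fraction, config.lad_mean_length
        )
        blocks_a[c] = blocks
        inter_a[c] = _complement(blocks, config.chrom_length)
        lad_a += [GenomicInterval(c, s, e) for s, e in blocks]
        inter += [GenomicInterval(c, s, e) for s, e in inter_a[c]]
        lad_b += [
            GenomicInterval(c, s, e)
            for s, e in _alternating_blocks(
                rng, config.chrom_length, config.lamin_b_fraction,
                config.lad_mean_length,
            )
        ]

    lamin_a = AnnotationTrack(lad_a, name="laminA_LAD")
    lamin_b = AnnotationTrack(lad_b, name="laminB_LAD")
    inter_lad = AnnotationTrack(inter, name="inter_LAD")

    # genes: uniform placement, TSS at the strand-dependent body end
    g_chrom = rng.choice(chroms, size=config.n_genes)
    g_len = rng.integers(config.gene_min_length, config.gene_max_length,
                         size=config.n_genes)
    g_start = np.array(
        [rng.integers(0, chrom_lengths[c] - l) for c, l in zip(g_chrom, g_len)]
    )
    g_strand = rng.choice(["+", "-"], size=config.n_genes)
    genes = pd.DataFrame(
        {
            "chrom": g_chrom,
            "start": g_start,
            "end": g_start + g_len,
            "strand": g_strand,
        },
        index=pd.Index([f"gene{i:05d}" for i in range(config.n_genes)], name="gene_id"),
    )
    genes["tss"] = np.where(genes["strand"] == "+", genes["start"], genes["end"])

    # probes: LAD membership first, then unique positions
    n_in = int(round(config.n_probes * config.probe_in_lad_fraction))
    if not any(blocks_a.values()):
        n_in = 0  # no LADs anywhere to place probes in
    positions: set[tuple[str, int]] = set()
    rows = []
    for i in range(config.n_probes):
        in_lad = i < n_in
        while True:
            c = chroms[int(rng.integers(len(chroms)))]
            blocks = blocks_a[c] if in_lad else inter_a[c]
            if not blocks:
                continue  # chromosome lacks this block type; redraw
            s, _ = _uniform_in_blocks(rng, blocks)
            pos = s + 1  # 1-based CpG coordinate
            if (c, pos) not in positions:
                positions.add((c, pos))
                break
        rows.append((c, pos, in_lad))
    chrom_col = [r[0] for r in rows]
    pos_col = [r[1] for r in rows]
    in_lad_col = np.array([r[2] for r in rows])

    island = np.zeros(config.n_probes, dtype=bool)
    island[~in_lad_col] = rng.random((~in_lad_col).sum()) < config.island_fraction
    pmd = np.where(
        in_lad_col,
        rng.random(config.n_probes) < config.pmd_prob_in_lad,
        rng.random(config.n_probes) < config.pmd_prob_outside,
    )
    pmd &= ~island
    hmd = ~pmd & ~island
    solo = (pmd | hmd) & (rng.random(config.n_probes) < config.solo_wcgw_fraction)

    annot = pd.DataFrame(
        {
            "chrom": chrom_col,
            "pos": pos_col,
            "sex_chromosome": rng.random(config.n_probes) < config.flag_fraction,
            "snp_affected": rng.random(config.n_probes) < config.flag_fraction,
            "cross_reactive": rng.random(config.n_probes) < config.flag_fraction,
            "solo_wcgw": solo,
            "in_pmd": pmd,
            "in_hmd": hmd,
        },
        index=pd.Index(
            [f"cg{i:07d}" for i in range(config.n_probes)], name="probe_id"
        ),
    )
    probe_class = pd.Series(
        np.select([island, pmd], ["island", "pmd"], default="hmd"),
        index=annot.index, name="region_class",
    )

    histone_tracks = {}
    for mark, lad_prob in HISTONE_MARKS.items():
        ivs = []
        for j in range(300):
            width = int(rng.integers(500, 2500))
            c = chroms[int(rng.integers(len(chroms)))]
            blocks = blocks_a[c] if rng.random() < lad_prob else inter_a[c]
            if not blocks:
                blocks = inter_a[c] or blocks_a[c]
            s, e = _uniform_in_blocks(rng, blocks, width)
            ivs.append(GenomicInterval(c, s, e, name=f"{mark}_{j:04d}"))
        histone_tracks[mark] = AnnotationTrack(ivs, name=mark)

    enh = []
    for j in range(200):
        c = chroms[int(rng.integers(len(chroms)))]
        s, e = _uniform_in_blocks(rng, inter_a[c] or blocks_a[c], 1000)
        enh.append(GenomicInterval(c, s, e, name=f"enh{j:04d}"))
    enhancers = AnnotationTrack(enh, name="active_enhancers")

    return SyntheticGenome(
        lamin_a=lamin_a,
        lamin_b=lamin_b,
        inter_lad=inter_lad,
        genes=genes,
        probe_annot=annot,
        probe_class=probe_class,
        histone_tracks=histone_tracks,
        enhancers=enhancers,
        chrom_lengths=chrom_lengths,
    )


def _sample_sheet(config: SimulationConfig, rng) -> pd.DataFrame:
    labels, groups, subgroups = [], [], []
    for i in range(config.n_control):
        labels.append(f"CTRL{i + 1:02d}")
        groups.append("control")
        subgroups.append("control")
    for i in range(config.n_case_sub1):
        labels.append(f"CASE{i + 1:02d}")
        groups.append("case")
        subgroups.append("sub1")
    for i in range(config.n_case_sub2):
        labels.append(f"CASE{config.n_case_sub1 + i + 1:02d}")
        groups.append("case")
        subgroups.append("sub2")
    n = len(labels)
    ages = np.round(rng.uniform(config.age_min, config.age_max, size=n), 1)
    passages = rng.integers(config.passage_min, config.passage_max + 1, size=n)
    doublings = rng.uniform(1.5, 2.5, size=n)
    harvested = (config.seeded_cells * 2.0**doublings).astype(int)
    return pd.DataFrame(
        {
            "group": groups,
            "subgroup": subgroups,
            "age_years": ages,
            "passage": passages,
            "harvested": harvested,
            "seeded": config.seeded_cells,
        },
        index=pd.Index(labels, name="sample_id"),
    )


def make_methylation(
    config: SimulationConfig, genome: SyntheticGenome, seed: int
) -> tuple[BetaMatrix, pd.DataFrame, pd.DataFrame, dict]:
    """Beta matrix, detection-p matrix, sample sheet and planted truth."""
    config.validate()
    rng = np.random.default_rng([int(seed), _STAGE_METH])
    annot = genome.probe_annot
    n_probes = len(annot)
    sheet = _sample_sheet(config, rng)
    n_samples = len(sheet)
    case = (sheet["group"] == "case").to_numpy()
    sub2 = (sheet["subgroup"] == "sub2").to_numpy()

    cls = genome.probe_class.to_numpy()
    base_mean = np.array([config.class_means[c] for c in cls])
    base_mean = np.clip(
        base_mean + rng.normal(0, config.probe_mean_jitter, size=n_probes),
        0.05, 0.95,
    )
    sds = np.array([config.class_sds[c] for c in cls])

    # planted hypermethylation on clean lamin A LAD probes
    clean = ~(
        annot["sex_chromosome"] | annot["snp_affected"] | annot["cross_reactive"]
    ).to_numpy()
    in_lad = np.array(
        [
            genome.lamin_a.overlaps(c, p - 1, p)
            for c, p in zip(annot["chrom"], annot["pos"])
        ]
    )
    # hypermethylation needs headroom: only probes whose shifted mean stays
    # inside (0, 1) within the clipping tolerance are eligible
    shifted = base_mean + config.lad_delta_beta
    headroom = (shifted <= 1 - 0.01 + config.clip_tolerance) & (
        shifted >= 0.01 - config.clip_tolerance
    )
    eligible = np.flatnonzero(clean & in_lad & headroom)
    if len(eligible) < config.n_affected_probes:
        raise ValueError(
            f"only {len(eligible)} clean LAD probes can carry a "
            f"{config.lad_delta_beta:+.2f} shift without leaving (0, 1); "
            f"{config.n_affected_probes} requested"
        )
    affected = rng.choice(eligible, size=config.n_affected_probes, replace=False)
    affected_mask = np.zeros(n_probes, dtype=bool)
    affected_mask[affected] = True

    true_delta = np.where(affected_mask, config.lad_delta_beta, 0.0)
    case_mean = np.clip(base_mean + true_delta, 0.01, 0.99)

    # per-sample probe means: group effect plus subgroup-2 drift toward 0.6
    means = np.empty((n_probes, n_samples))
    for j in range(n_samples):
        m = case_mean if case[j] else base_mean
        if sub2[j]:
            m = m + config.subgroup_shift * (0.6 - m)
        means[:, j] = m

    conc = base_mean * (1 - base_mean) / sds**2 - 1
    conc = np.maximum(conc, 2.0)
    a = means * conc[:, None]
    b = (1 - means) * conc[:, None]
    values = rng.beta(a, b)

    detection = rng.uniform(0.0, 0.005, size=(n_probes, n_samples))
    n_fail = int(round(config.det_fail_probe_fraction * n_probes))
    fail_probes = rng.choice(n_probes, size=n_fail, replace=False)
    fail_samples = rng.integers(0, n_samples, size=n_fail)
    detection[fail_probes, fail_samples] = rng.uniform(0.02, 0.5, size=n_fail)

    beta = BetaMatrix(
        pd.DataFrame(values, index=annot.index, columns=sheet.index)
    )
    det = pd.DataFrame(detection, index=annot.index, columns=sheet.index)
    truth = {
        "affected_probes": list(annot.index[affected_mask]),
        "true_delta_beta": config.lad_delta_beta,
        "subgroup_labels": sheet["subgroup"].to_dict(),
        "subgroup_shift": config.subgroup_shift,
        "detection_failed_probes": sorted(annot.index[fail_probes]),
    }
    return beta, det, sheet, truth


def make_diff_peaks(
    config: SimulationConfig, genome: SyntheticGenome, seed: int
) -> tuple[pd.DataFrame, dict]:
    """Differential + background peak table with planted LAD enrichment.

    The placement probability for differential peaks is solved so that
    the signed fold enrichment of the significant peaks in lamin A LADs,
    measured against the pooled peak universe, targets
    ``peak_lad_enrichment`` in expectation.
    """
    config.validate()
    rng = np.random.default_rng([int(seed), _STAGE_PEAKS])
    lad_blocks = {
        c: [(iv.start, iv.end) for iv in genome.lamin_a if iv.chrom == c]
        for c in genome.chrom_lengths
    }
    inter_blocks = {
        c: [(iv.start, iv.end) for iv in genome.inter_lad if iv.chrom == c]
        for c in genome.chrom_lengths
    }
    genome_len = sum(genome.chrom_lengths.values())
    p0 = genome.lamin_a.total_bases() / genome_len
    f = config.peak_lad_enrichment
    n_s, n_b = config.n_diff_peaks, config.n_background_peaks
    q = f * n_b * p0 / (n_s + n_b - f * n_s)
    if not 0 < q <= 1:
        raise ValueError(
            f"target enrichment {f} is unreachable with LAD fraction {p0:.2f}"
        )

    chrom_names = list(genome.chrom_lengths)

    def place(in_lad: bool):
        while True:
            c = chrom_names[int(rng.integers(len(chrom_names)))]
            blocks = lad_blocks[c] if in_lad else inter_blocks[c]
            if any(e - s > config.peak_width for s, e in blocks):
                s, e = _uniform_in_blocks(rng, blocks, config.peak_width)
                return c, s, e

    records = []
    directions = np.array(
        ["gained"] * config.n_gained + ["lost"] * config.n_lost
    )
    rng.shuffle(directions)
    for i in range(n_s):
        in_lad = bool(rng.random() < q)
        c, s, e = place(in_lad)
        records.append(
            (c, s, e, f"diffpeak{i:05d}", directions[i],
             float(rng.uniform(1e-6, 0.049)), True, in_lad)
        )
    for i in range(n_b):
        in_lad = bool(rng.random() < p0)
        c, s, e = place(in_lad)
        records.append(
            (c, s, e, f"bgpeak{i:05d}", ".",
             float(rng.uniform(0.051, 1.0)), False, in_lad)
        )
    peaks = pd.DataFrame.from_records(
        records,
        columns=["chrom", "start", "end", "name", "direction", "q_value",
                 "significant", "in_lamin_a"],
    )
    truth = {
        "peak_lad_enrichment": f,
        "placement_prob_diff": q,
        "placement_prob_background": p0,
        "n_gained": config.n_gained,
        "n_lost": config.n_lost,
    }
    return peaks, truth


def make_expression(
    config: SimulationConfig, genome: SyntheticGenome, seed: int
) -> tuple[pd.DataFrame, dict]:
    """Differential expression table with LAD-proximal DE genes."""
    config.validate()
    rng = np.random.default_rng([int(seed), _STAGE_EXPR])
    genes = genome.genes
    from .intervals import nearest_distance

    ivs = [
        GenomicInterval(c, int(s), int(e))
        for c, s, e in zip(genes["chrom"], genes["start"], genes["end"])
    ]
    dist = nearest_distance(ivs, genome.lamin_a)
    proximal_pool = np.flatnonzero(dist <= config.proximal_max_distance)
    distal_pool = np.flatnonzero(dist > config.proximal_max_distance)

    n_prox = int(round(config.de_lad_proximal_frac * config.n_de_genes))
    n_prox = min(n_prox, len(proximal_pool))
    n_rest = config.n_de_genes - n_prox
    if n_rest > len(distal_pool):
        raise ValueError("not enough LAD-distal genes for the requested DE set")
    de_idx = np.concatenate(
        [
            rng.choice(proximal_pool, size=n_prox, replace=False),
            rng.choice(distal_pool, size=n_rest, replace=False),
        ]
    )
    de_mask = np.zeros(len(genes), dtype=bool)
    de_mask[de_idx] = True

    base = rng.lognormal(mean=2.0, sigma=1.0, size=len(genes))
    lfc = np.zeros(len(genes))
    de_positions = np.flatnonzero(de_mask)
    signs = np.array([1.0] * config.n_de_up + [-1.0] * config.n_de_down)
    rng.shuffle(signs)
    lfc[de_positions] = signs[: len(de_positions)] * rng.normal(
        1.5, 0.4, size=len(de_positions)
    ).clip(0.5, None)
    q = np.where(
        de_mask,
        rng.uniform(1e-6, 0.049, size=len(genes)),
        rng.uniform(0.051, 1.0, size=len(genes)),
    )
    mean_control = base
    mean_case = base * 2.0**lfc
    table = pd.DataFrame(
        {
            "mean_fpkm_case": mean_case,
            "mean_fpkm_control": mean_control,
            "log2_fold_change": lfc,
            "q_value": q,
            "significant": de_mask,
        },
        index=genes.index,
    )
    truth = {
        "de_genes": sorted(genes.index[de_mask]),
        "n_de_lad_proximal": int(n_prox),
        "de_gene_lad_distances": {
            g: float(d) for g, d in zip(genes.index[de_mask], dist[de_mask])
        },
    }
    return table, truth


def make_clock(
    config: SimulationConfig,
    genome: SyntheticGenome,
    sheet: pd.DataFrame,
    seed: int,
) -> tuple[ClockModel, pd.DataFrame, dict]:
    """Synthetic sparse clock plus beta rows realising planted DNAm ages.

    The clock's beta columns are constructed by inverting the age
    transform at the planted DNAm age of each sample (chronological age
    plus the subgroup shift), so with zero noise the clock recovers the
    planted ages exactly.
    """
    config.validate()
    rng = np.random.default_rng([int(seed), _STAGE_CLOCK])
    n_p = config.clock_n_probes
    probe_ids = [f"clk{i:05d}" for i in range(n_p)]
    weights = rng.normal(0, 1.0, size=n_p)

    shift = sheet["subgroup"].map(
        {"control": config.control_shift, "sub1": config.decel_shift,
         "sub2": config.accel_shift}
    ).to_numpy()
    dnam_age = np.maximum(sheet["age_years"].to_numpy() + shift, 0.1)
    scores = inverse_transform_age(dnam_age)
    intercept = float(np.mean(scores) - weights.sum() * 0.5)
    resid = scores - intercept - weights.sum() * 0.5
    wnorm2 = float(weights @ weights)
    cols = {}
    for j, sample in enumerate(sheet.index):
        beta = 0.5 + resid[j] * weights / wnorm2
        if config.clock_beta_noise_sd > 0:
            # noise orthogonalised against w keeps the score exact in
            # expectation; plain iid noise perturbs the score mildly
            beta = beta + rng.normal(0, config.clock_beta_noise_sd, size=n_p)
        if beta.min() < 0 or beta.max() > 1:
            raise ValueError("clock beta construction left [0, 1]; lower noise")
        cols[sample] = beta
    clock_beta = pd.DataFrame(cols, index=pd.Index(probe_ids, name="probe_id"))
    model = ClockModel(
        intercept=intercept,
        weights=dict(zip(probe_ids, weights.tolist())),
        adult_age=20.0,
    )
    truth = {
        "planted_dnam_age": dict(zip(sheet.index, dnam_age.tolist())),
        "accel_shift": config.accel_shift,
        "decel_shift": config.decel_shift,
    }
    return model, clock_beta, truth


def make_chip_signal(
    config: SimulationConfig, genome: SyntheticGenome, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """ChIP/input mean signal per LAD and inter-LAD segment.

    The ChIP track carries a planted ``chip_log2_enrichment`` over input
    inside lamin A LADs and none outside.
    """
    rng = np.random.default_rng([int(seed), _STAGE_CHIP])
    rows_chip, rows_input = [], []
    for iv, region_class in [(iv, "LAD") for iv in genome.lamin_a] + [
        (iv, "inter_LAD") for iv in genome.inter_lad
    ]:
        # coverage-scale signal keeps the downstream pseudocount negligible
        base = float(rng.lognormal(np.log(100.0), 0.3))
        enrich = 2.0**config.chip_log2_enrichment if region_class == "LAD" else 1.0
        chip_val = base * enrich * 2.0 ** rng.normal(0, config.chip_noise_sd)
        rows_chip.append((iv.chrom, iv.start, iv.end, region_class, chip_val))
        rows_input.append((iv.chrom, iv.start, iv.end, region_class, base))
    cols = ["chrom", "start", "end", "region_class", "value"]
    chip = pd.DataFrame(rows_chip, columns=cols)
    inp = pd.DataFrame(rows_input, columns=cols)
    truth = {"chip_log2_enrichment": config.chip_log2_enrichment}
    return chip, inp, truth


def simulate_all(
    config: SimulationConfig, outdir: str | Path, seed: int
) -> dict:
    """Generate the full self-contained input directory.

    Writes BED tracks, the beta / detection-p matrices (clock probes
    appended), sample sheet, differential peak and expression tables,
    the clock files, a truth JSON and a copy of the config.  Returns the
    truth dictionary.
    """
    config.validate()
    outdir = Path(outdir)
    (outdir / "tracks").mkdir(parents=True, exist_ok=True)
    genome = make_genome(config, seed)
    beta, det, sheet, truth_meth = make_methylation(config, genome, seed)
    peaks, truth_peaks = make_diff_peaks(config, genome, seed)
    expr, truth_expr = make_expression(config, genome, seed)
    model, clock_beta, truth_clock = make_clock(config, genome, sheet, seed)
    chip, inp, truth_chip = make_chip_signal(config, genome, seed)

    write_bed(genome.lamin_a, outdir / "tracks" / "laminA_LAD.bed")
    write_bed(genome.lamin_b, outdir / "tracks" / "laminB_LAD.bed")
    write_bed(genome.inter_lad, outdir / "tracks" / "inter_LAD.bed")
    write_bed(genome.enhancers, outdir / "tracks" / "active_enhancers.bed")
    for mark, track in genome.histone_tracks.items():
        write_bed(track, outdir / "tracks" / f"{mark}.bed")

    # clock probes join the matrix with clean annotation rows
    clock_annot = pd.DataFrame(
        {
            "chrom": "chrC",  # dedicated contig keeps clock probes out of LAD strata
            "pos": np.arange(len(clock_beta)) * 2000 + 1000,
            "sex_chromosome": False,
            "snp_affected": False,
            "cross_reactive": False,
            "solo_wcgw": False,
            "in_pmd": False,
            "in_hmd": True,
        },
        index=clock_beta.index,
    )
    full_annot = pd.concat([genome.probe_annot, clock_annot])
    full_beta = pd.concat([beta.values, clock_beta])
    full_det = pd.concat(
        [det, pd.DataFrame(0.0, index=clock_beta.index, columns=det.columns)]
    )

    full_beta.to_csv(outdir / "beta.tsv", sep="\t", index_label="probe_id",
                     float_format="%.6g")
    full_det.to_csv(outdir / "detection_p.tsv", sep="\t",
                    index_label="probe_id", float_format="%.6g")
    full_annot.to_csv(outdir / "probe_annotation.tsv", sep="\t")
    sheet.to_csv(outdir / "sample_sheet.tsv", sep="\t")
    genome.genes.to_csv(outdir / "genes.tsv", sep="\t")
    peaks.to_csv(outdir / "diff_peaks.tsv", sep="\t", index=False,
                 float_format="%.6g")
    expr.to_csv(outdir / "expression.tsv", sep="\t", index_label="gene_id",
                float_format="%.6g")
    chip.to_csv(outdir / "chip_signal.tsv", sep="\t", index=False,
                float_format="%.6g")
    inp.to_csv(outdir / "input_signal.tsv", sep="\t", index=False,
               float_format="%.6g")
    model.to_files(outdir / "clock.tsv", outdir / "clock.yaml")

    truth = {
        "seed": int(seed),
        "methylation": truth_meth,
        "peaks": truth_peaks,
        "expression": truth_expr,
        "clock": truth_clock,
        "chip": truth_chip,
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    (outdir / "config.yaml").write_text(yaml.safe_dump(config.to_dict()))
    return truth
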