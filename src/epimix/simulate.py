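"""Synthetic data with the statistical structure the models assume.

The generator plants non-overlapping functional segments (geometric lengths)
until a target fraction of the genome is functional, draws the eight binary
marks block-wise from the two-component Bernoulli model (rates p1 inside
functional segments, p0 outside), and simulates GWAS p-values from the
three-case mixture: SNPs on functional basepairs are trait-associated with
probability w_cond (p ~ Beta(alpha, 1)) and null otherwise; SNPs on
non-functional basepairs are always null (p ~ Uniform).

Mark draws are constant within a segment block per mark, so emitted peak
files contain realistic contiguous intervals while the per-bp marginal
P(A_i = 1 | Z) is unchanged.  Everything is keyed by a single seed with
deterministically derived per-stage substreams, so runs are byte-identical.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .annotation_io import (
    DEFAULT_MARKS,
    N_MARKS,
    GenomicInterval,
    MarkTrackSet,
    write_bed,
    write_genome_file,
)
from .mixture import MixtureParams

_STAGE_TRACKS = 0
_STAGE_GWAS = 1
_STAGE_LOCI = 2


def _default_params() -> MixtureParams:
    return MixtureParams(0.1, np.full(N_MARKS, 0.7), np.full(N_MARKS, 0.05))


@dataclass
class SimConfig:
    """Study conditions for the synthetic workspace.

    Defaults: a 1 Mb single-chromosome genome, two tissues, 10% functional
    basepairs in segments of mean length 1 kb, well-separated mark rates
    (p1 = 0.7, p0 = 0.05), 10,000 SNPs, signal Beta(0.3, 1), and a 30%
    chance that a tissue-functional SNP is trait-associated.
    """

    genome: dict[str, int] = field(default_factory=lambda: {"chr1": 1_000_000})
    n_tissues: int = 2
    true_params: list[MixtureParams] | None = None
    region_length_mean: int = 1000
    functional_bp_fraction: float = 0.1
    n_snps: int = 10_000
    true_alpha: float = 0.3
    true_w_cond: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_params is None:
            self.true_params = [_default_params() for _ in range(self.n_tissues)]
        if len(self.true_params) != self.n_tissues:
            raise ValueError("need one MixtureParams per tissue")
        if not 0.0 <= self.functional_bp_fraction < 1.0:
            raise ValueError("functional_bp_fraction must lie in [0, 1)")
        if not 0.0 < self.true_alpha < 1.0:
            raise ValueError("true_alpha must lie in (0, 1)")
        if not 0.0 <= self.true_w_cond <= 1.0:
            raise ValueError("true_w_cond must lie in [0, 1]")

    def tissue_names(self) -> list[str]:
        return [f"tissue{i + 1}" for i in range(self.n_tissues)]


def _stage_rng(cfg: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, stage]))


def _plant_segments(
    rng: np.random.Generator, length: int, target_bp: int, mean_len: int
) -> np.ndarray:
    """Boolean functional mask with non-overlapping geometric-length segments."""
    mask = np.zeros(length, dtype=bool)
    planted = 0
    failures = 0
    while planted < target_bp:
        seg = int(rng.geometric(1.0 / mean_len))
        seg = min(seg, target_bp - planted)
        start = int(rng.integers(0, max(length - seg, 1)))
        if mask[start : start + seg].any():
            failures += 1
            if failures > 100_000:
                raise ValueError(
                    "cannot place the requested functional fraction on this genome"
                )
            continue
        mask[start : start + seg] = True
        planted += seg
    return mask


def _block_bounds(rng: np.random.Generator, length: int, mean_len: int) -> np.ndarray:
    """Random breakpoints cutting [0, length) into geometric-length blocks."""
    cuts = [0]
    while cuts[-1] < length:
        cuts.append(cuts[-1] + int(rng.geometric(1.0 / mean_len)))
    cuts[-1] = length
    return np.asarray(cuts, dtype=np.int64)


def _mask_to_intervals(chrom: str, mask: np.ndarray) -> list[GenomicInterval]:
    diff = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(diff == 1) + 1
    ends = np.flatnonzero(diff == -1) + 1
    if mask[0]:
        starts = np.concatenate([[0], starts])
    if mask[-1]:
        ends = np.concatenate([ends, [mask.size]])
    return [GenomicInterval(chrom, int(a), int(b)) for a, b in zip(starts, ends)]


def simulate_tracks(
    cfg: SimConfig,
) -> tuple[dict[str, MarkTrackSet], dict[str, dict[str, np.ndarray]]]:
    """Simulate per-tissue mark track sets and the planted truth labels.

    Returns ``(tracksets, truth)`` where ``truth[tissue][chrom]`` is the
    per-bp boolean functionality mask the marks were generated from.
    """
    rng = _stage_rng(cfg, _STAGE_TRACKS)
    tracksets: dict[str, MarkTrackSet] = {}
    truth: dict[str, dict[str, np.ndarray]] = {}
    for tissue, params in zip(cfg.tissue_names(), cfg.true_params):
        masks: dict[str, np.ndarray] = {}
        coverage: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {
            m: {} for m in DEFAULT_MARKS
        }
        for chrom, length in cfg.genome.items():
            target = int(round(cfg.functional_bp_fraction * length))
            z = (
                _plant_segments(rng, length, target, cfg.region_length_mean)
                if target > 0
                else np.zeros(length, dtype=bool)
            )
            masks[chrom] = z
            # block partition: functional segments are blocks; background is
            # cut into geometric blocks of the same mean length
            func_ivs = _mask_to_intervals(chrom, z) if z.any() else []
            bg_cuts = _block_bounds(rng, length, cfg.region_length_mean)
            bounds = np.unique(
                np.concatenate(
                    [bg_cuts]
                    + [np.array([iv.start, iv.end]) for iv in func_ivs]
                    or [bg_cuts]
                )
            )
            seg_s, seg_e = bounds[:-1], bounds[1:]
            seg_z = z[seg_s]
            # z is constant within blocks only for functional segments; split
            # background blocks crossing a functional boundary were handled by
            # adding the functional bounds above, so constancy holds for all
            rates1 = params.p1
            rates0 = params.p0
            for i, mark in enumerate(DEFAULT_MARKS):
                u = rng.random(seg_s.size)
                present = np.where(seg_z, u < rates1[i], u < rates0[i])
                if present.any():
                    dense = np.zeros(length, dtype=bool)
                    for a, b in zip(seg_s[present], seg_e[present]):
                        dense[a:b] = True
                    ivs = _mask_to_intervals(chrom, dense)
                    coverage[mark][chrom] = (
                        np.array([iv.start for iv in ivs], dtype=np.int64),
                        np.array([iv.end for iv in ivs], dtype=np.int64),
                    )
        tracksets[tissue] = MarkTrackSet(
            tissue, DEFAULT_MARKS, coverage, dict(cfg.genome)
        )
        truth[tissue] = masks
    return tracksets, truth


def simulate_gwas(
    cfg: SimConfig, gs_truth: Mapping[str, np.ndarray]
) -> pd.DataFrame:
    """Simulate a GWAS summary table conditioned on planted functionality.

    ``gs_truth`` is the per-chromosome truth mask of one tissue (the trait's
    relevant tissue).  Returns columns CHR, BP, SNP, P and the planted CASE
    (1 = trait- and tissue-functional, 2 = tissue-functional only,
    3 = not tissue-functional).
    """
    rng = _stage_rng(cfg, _STAGE_GWAS)
    chroms = list(cfg.genome)
    lengths = np.array([cfg.genome[c] for c in chroms], dtype=np.int64)
    total = int(lengths.sum())
    if cfg.n_snps > total:
        raise ValueError("more SNPs requested than basepairs available")
    flat = np.sort(rng.choice(total, size=cfg.n_snps, replace=False))
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    chrom_idx = np.searchsorted(offsets, flat, side="right") - 1
    pos = flat - offsets[chrom_idx]
    functional = np.zeros(cfg.n_snps, dtype=bool)
    for i, chrom in enumerate(chroms):
        sel = chrom_idx == i
        if sel.any():
            functional[sel] = gs_truth[chrom][pos[sel]]
    case = np.full(cfg.n_snps, 3, dtype=np.int64)
    assoc = rng.random(cfg.n_snps) < cfg.true_w_cond
    case[functional & assoc] = 1
    case[functional & ~assoc] = 2
    u = rng.random(cfg.n_snps)
    p = np.where(case == 1, u ** (1.0 / cfg.true_alpha), u)
    return pd.DataFrame(
        {
            "CHR": np.asarray(chroms, dtype=object)[chrom_idx],
            "BP": pos.astype(np.int64),
            "SNP": [f"snp{i + 1}" for i in range(cfg.n_snps)],
            "P": p,
            "CASE": case,
        }
    )


def _demo_loci(
    cfg: SimConfig, gwas: pd.DataFrame, n_loci: int = 5, width: int = 50_000
) -> pd.DataFrame:
    """Risk loci centered on the strongest planted associations."""
    hits = gwas[gwas["CASE"] == 1].nsmallest(n_loci * 3, "P")
    rows: list[dict] = []
    for _, row in hits.iterrows():
        length = cfg.genome[row["CHR"]]
        start = max(int(row["BP"]) - width // 2, 0)
        end = min(int(row["BP"]) + width // 2, length)
        if any(
            r["CHR"] == row["CHR"] and not (end <= r["START"] or start >= r["END"])
            for r in rows
        ):
            continue
        rows.append(
            {
                "CHR": row["CHR"],
                "START": start,
                "END": end,
                "LABEL": f"locus{len(rows) + 1}",
            }
        )
        if len(rows) == n_loci:
            break
    return pd.DataFrame(rows)


def make_demo_workspace(cfg: SimConfig, out_dir: str | Path) -> pd.DataFrame:
    """Write a complete demo workspace and return its file manifest.

    Files: per-tissue narrowPeak files for the eight marks, the genome size
    file, the GWAS summary table, risk loci BED, and per-tissue truth
    tables.  The manifest lists every file with its sha256 checksum;
    regeneration with the same config is byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tracksets, truth = simulate_tracks(cfg)
    files: list[Path] = []

    genome_path = out / "genome.txt"
    write_genome_file(cfg.genome, genome_path)
    files.append(genome_path)

    for tissue, ts in tracksets.items():
        tdir = out / tissue
        tdir.mkdir(exist_ok=True)
        for mark in ts.marks:
            path = tdir / f"{mark}.narrowPeak"
            with open(path, "w") as fh:
                for chrom in sorted(ts.coverage[mark]):
                    s, e = ts.coverage[mark][chrom]
                    for a, b in zip(s, e):
                        fh.write(
                            f"{chrom}\t{a}\t{b}\t.\t0\t.\t0\t-1\t-1\t-1\n"
                        )
            files.append(path)
        truth_path = out / f"{tissue}.truth.bed"
        ivs = [
            iv
            for chrom in sorted(truth[tissue])
            for iv in _mask_to_intervals(chrom, truth[tissue][chrom])
        ] if any(m.any() for m in truth[tissue].values()) else []
        write_bed(ivs, truth_path)
        files.append(truth_path)

    first_tissue = cfg.tissue_names()[0]
    gwas = simulate_gwas(cfg, truth[first_tissue])
    gwas_path = out / "gwas.tsv"
    gwas[["CHR", "BP", "SNP", "P"]].to_csv(gwas_path, sep="\t", index=False)
    files.append(gwas_path)
    truth_snp_path = out / "gwas.truth.tsv"
    gwas.to_csv(truth_snp_path, sep="\t", index=False)
    files.append(truth_snp_path)

    loci = _demo_loci(cfg, gwas)
    loci_path = out / "loci.bed"
    with open(loci_path, "w") as fh:
        for _, row in loci.iterrows():
            fh.write(f"{row['CHR']}\t{row['START']}\t{row['END']}\t{row['LABEL']}\n")
    files.append(loci_path)

    manifest = pd.DataFrame(
        {
            "file": [str(f.relative_to(out)) for f in files],
            "sha256": [
                hashlib.sha256(f.read_bytes()).hexdigest() for f in files
            ],
        }
    )
    manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    return manifest
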