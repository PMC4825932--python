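"""Locus-level analytics on prioritized SNPs.

Given per-tissue posterior scores for the SNPs in a GWAS, these tools answer
locus-scale questions: which tissue shows the strongest posterior inside a
risk locus (the locus's predicted relevant tissue), how the best rank at each
locus changes between two scoring schemes (with an exact one-sided binomial
sign test), and how enriched a target SNP set is among the top-ranked SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binomtest, rankdata


class RiskLocus(NamedTuple):
    """A 0-based half-open genomic interval hosting a GWAS risk signal."""

    chrom: str
    start: int
    end: int
    label: str = ""


def read_loci_bed(path: str | Path) -> list[RiskLocus]:
    """Read risk loci from a BED3+label file."""
    loci = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 columns")
            label = fields[3] if len(fields) > 3 else f"locus{lineno}"
            loci.append(RiskLocus(fields[0], int(fields[1]), int(fields[2]), label))
    return loci


@dataclass
class LocusTissueReport:
    """Per-tissue maximal posterior within a locus and the winning tissue."""

    locus: RiskLocus
    per_tissue_max: dict[str, float]
    relevant_tissue: str
    tie: bool
    tied_tissues: tuple[str, ...]
    tie_tolerance: float


def local_max_gsp(
    scored_snps: Mapping[str, pd.DataFrame],
    locus: RiskLocus,
    tie_tol: float = 1e-4,
) -> LocusTissueReport:
    """Maximal posterior score per tissue within a risk locus.

    ``scored_snps`` maps tissue name to a SNP table with CHR, BP and GSP
    columns.  The tissue attaining the largest local maximum is the
    predicted relevant tissue; if the top two maxima differ by less than
    ``tie_tol`` the call is flagged as a tie and all tied tissues listed.
    """
    per_tissue: dict[str, float] = {}
    for tissue, df in scored_snps.items():
        sel = (
            (df["CHR"].astype(str) == locus.chrom)
            & (df["BP"] >= locus.start)
            & (df["BP"] < locus.end)
        )
        if not sel.any():
            raise ValueError(
                f"locus {locus.label or locus} contains no scored SNPs "
                f"for tissue {tissue!r}"
            )
        per_tissue[tissue] = float(df.loc[sel, "GSP"].max())
    ordered = sorted(per_tissue.items(), key=lambda kv: kv[1], reverse=True)
    top_name, top_val = ordered[0]
    tied = tuple(name for name, val in ordered if top_val - val < tie_tol)
    tie = len(tied) > 1
    return LocusTissueReport(
        locus=locus,
        per_tissue_max=per_tissue,
        relevant_tissue="NA" if tie else top_name,
        tie=tie,
        tied_tissues=tied,
        tie_tolerance=tie_tol,
    )


def locus_report_table(reports: Sequence[LocusTissueReport]) -> pd.DataFrame:
    """Tabular report: locus coordinates, relevant tissue, posterior score."""
    rows = []
    for r in reports:
        rows.append(
            {
                "LOCUS": r.locus.label,
                "CHR": r.locus.chrom,
                "START": r.locus.start,
                "END": r.locus.end,
                "TISSUE": r.relevant_tissue,
                "POSTERIOR": (
                    np.nan if r.tie else r.per_tissue_max[r.relevant_tissue]
                ),
                "TIE": r.tie,
            }
        )
    return pd.DataFrame(rows)


def best_rank_at_loci(
    scores: pd.DataFrame,
    loci: Sequence[RiskLocus],
    score_col: str,
    direction: str = "higher_better",
) -> tuple[dict[str, int], list[str]]:
    """Best genome-wide rank among the SNPs inside each locus.

    SNPs are ranked over the whole table (rank 1 = best: largest score for
    ``higher_better``, smallest for ``lower_better``; ties share the minimum
    rank).  Loci containing no SNPs are excluded and their labels returned
    separately.
    """
    if direction not in ("higher_better", "lower_better"):
        raise ValueError("direction must be 'higher_better' or 'lower_better'")
    vals = scores[score_col].to_numpy(dtype=np.float64)
    key = -vals if direction == "higher_better" else vals
    ranks = rankdata(key, method="min").astype(np.int64)
    chroms = scores["CHR"].astype(str).to_numpy()
    pos = scores["BP"].to_numpy()
    out: dict[str, int] = {}
    missing: list[str] = []
    for locus in loci:
        sel = (chroms == locus.chrom) & (pos >= locus.start) & (pos < locus.end)
        if not sel.any():
            missing.append(locus.label)
            continue
        out[locus.label] = int(ranks[sel].min())
    return out, missing


def rank_improvement_test(
    ranks_a: Mapping[str, int], ranks_b: Mapping[str, int]
) -> tuple[int, int, float]:
    """Exact one-sided binomial sign test for rank improvement.

    Counts loci where scheme b ranks strictly better (numerically smaller)
    than scheme a; loci with identical ranks are dropped.  Returns
    ``(n_improved, n_total, p)`` with p the exact one-sided tail
    P(X >= n_improved | n_total, 1/2).
    """
    if set(ranks_a) != set(ranks_b):
        raise ValueError("rank maps must cover the same loci")
    n_improved = sum(1 for k in ranks_a if ranks_b[k] < ranks_a[k])
    n_total = sum(1 for k in ranks_a if ranks_b[k] != ranks_a[k])
    if n_total == 0:
        raise ValueError("no loci with differing ranks; test undefined")
    p = binomtest(n_improved, n_total, 0.5, alternative="greater").pvalue
    return n_improved, n_total, float(p)


def enrichment_curve(
    ranked_snps: Sequence[str],
    target_set: set[str],
    top_ns: Sequence[int],
) -> list[tuple[int, float]]:
    """Fold enrichment of a target SNP set among the top-N ranked SNPs.

    fold(N) = [(# targets in top N) / N] / [(# targets) / (total SNPs)].
    """
    total = len(ranked_snps)
    n_targets = sum(1 for s in ranked_snps if s in target_set)
    if n_targets == 0:
        raise ValueError("target set does not intersect the ranked SNPs")
    background = n_targets / total
    is_target = np.fromiter(
        (s in target_set for s in ranked_snps), dtype=np.int64, count=total
    )
    cum = np.cumsum(is_target)
    out = []
    for n in top_ns:
        if not 1 <= n <= total:
            raise ValueError(f"top-N value {n} outside [1, {total}]")
        out.append((int(n), float(cum[n - 1] / n / background)))
    return out
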