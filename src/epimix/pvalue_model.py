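"""GWAS SNP prioritization from summary statistics and functional score tracks.

Each SNP falls into one of three disjoint cases: (I) functional for both the
trait and the tissue (Z_D = 1, Z_T = 1), (II) tissue-functional but trait-
irrelevant (Z_D = 0, Z_T = 1), (III) not tissue-functional (Z_T = 0).  The
per-SNP prior P(Z_T = 1) is the mean tissue score over the surrounding
10 kb window.  P-value densities: trait-functional SNPs follow Beta(alpha, 1)
with 0 < alpha < 1; the two null densities are histogram estimates (bin count
chosen by cross-validation) on the low-prior SNP partitions, using the
identity f(p | Z_D=0, Z_T=1) = f(p | Z=0).  The global weight
w = P(Z_D=1 | Z_T=1) and alpha are fitted by EM with closed-form updates on
the high-prior partition.  The joint posterior of case I given the p-value is
the tissue-specific prioritization score (GSP); the analogous two-case model
on a general (non-tissue) functionality track gives the NSFP score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .annotation_io import ScoreTrack
from .mixture import EmTrace

P_FLOOR = 1e-300  # p-values clipped to [P_FLOOR, 1] so log p stays finite
ALPHA_CLIP = (1e-4, 1.0 - 1e-4)
DEFAULT_CANDIDATE_BINS: tuple[int, ...] = (5,) + tuple(range(10, 201, 10))


def clip_pvalues(p: np.ndarray) -> np.ndarray:
    return np.clip(np.asarray(p, dtype=np.float64), P_FLOOR, 1.0)


# ---------------------------------------------------------------------------
# densities
# ---------------------------------------------------------------------------

@dataclass
class HistogramDensity:
    """Equal-width histogram density on [0, 1]."""

    bin_edges: np.ndarray
    heights: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=np.float64)
        self.heights = np.asarray(self.heights, dtype=np.float64)
        if self.heights.size != self.bin_edges.size - 1:
            raise ValueError("heights must have one entry per bin")
        if (self.heights < 0).any():
            raise ValueError("negative histogram height")
        widths = np.diff(self.bin_edges)
        if abs(float(self.heights @ widths) - 1.0) > 1e-9:
            raise ValueError("histogram density must integrate to 1")

    @property
    def n_bins(self) -> int:
        return self.heights.size

    def pdf(self, p: np.ndarray) -> np.ndarray:
        p = clip_pvalues(p)
        idx = np.searchsorted(self.bin_edges, p, side="right") - 1
        idx = np.clip(idx, 0, self.n_bins - 1)
        return self.heights[idx]

    @classmethod
    def uniform(cls) -> "HistogramDensity":
        return cls(np.array([0.0, 1.0]), np.array([1.0]))


@dataclass
class BetaSignal:
    """Beta(alpha, 1) p-value density for trait-functional SNPs: alpha p^(alpha-1)."""

    alpha: float

    def __post_init__(self) -> None:
        if not ALPHA_CLIP[0] <= self.alpha <= ALPHA_CLIP[1]:
            raise ValueError("alpha must lie in (0, 1) after clipping")

    def pdf(self, p: np.ndarray) -> np.ndarray:
        p = clip_pvalues(p)
        return self.alpha * p ** (self.alpha - 1.0)


def _heights_from_counts(counts: np.ndarray, edges: np.ndarray,
                         pseudocount: float = 0.5) -> np.ndarray:
    counts = counts + pseudocount
    widths = np.diff(edges)
    mass = counts / counts.sum()
    return mass / widths


def fit_histogram_density(
    pvalues: Sequence[float],
    candidate_bins: Sequence[int] = DEFAULT_CANDIDATE_BINS,
    folds: int = 10,
    seed: int = 0,
) -> HistogramDensity:
    """Histogram density with the bin count chosen by K-fold cross-validation.

    For each candidate bin count the held-out log-likelihood of the
    train-fold histogram (+0.5 pseudocount per bin, renormalized) is
    averaged over folds; the maximizer wins, ties going to fewer bins.
    """
    p = clip_pvalues(pvalues)
    if p.size < 50:
        raise ValueError(f"need >= 50 p-values to fit a density, got {p.size}")
    rng = np.random.default_rng(seed)
    # folds are assigned per distinct value (grouped assignment) so tied or
    # duplicated observations never leak between train and held-out folds
    uniq, inverse = np.unique(p, return_inverse=True)
    uniq_folds = rng.permutation(uniq.size) % folds
    assignments = uniq_folds[inverse]
    best_bins = None
    best_ll = -np.inf
    for n_bins in candidate_bins:
        edges = np.linspace(0.0, 1.0, n_bins + 1)
        total_ll = 0.0
        for k in range(folds):
            train = p[assignments != k]
            test = p[assignments == k]
            if train.size == 0 or test.size == 0:
                continue
            counts, _ = np.histogram(train, bins=edges)
            heights = _heights_from_counts(counts, edges)
            idx = np.clip(np.searchsorted(edges, test, side="right") - 1,
                          0, n_bins - 1)
            total_ll += float(np.log(heights[idx]).sum())
        mean_ll = total_ll / folds
        if mean_ll > best_ll + 1e-12:
            best_ll = mean_ll
            best_bins = n_bins
    edges = np.linspace(0.0, 1.0, best_bins + 1)
    counts, _ = np.histogram(p, bins=edges)
    return HistogramDensity(edges, _heights_from_counts(counts, edges))


# ---------------------------------------------------------------------------
# beta-null EM
# ---------------------------------------------------------------------------

def _signal_m_step(p: np.ndarray, resp: np.ndarray) -> tuple[float, float]:
    """Closed-form M-step: w = mean responsibility, alpha = -sum r / sum r log p."""
    w = float(resp.mean())
    denom = float(resp @ np.log(p))
    alpha = -float(resp.sum()) / denom if denom < 0 else ALPHA_CLIP[1]
    alpha = float(np.clip(alpha, *ALPHA_CLIP))
    return alpha, w


def fit_signal_mixture(
    pvalues: Sequence[float],
    f_null: HistogramDensity,
    tol: float = 1e-8,
    max_iter: int = 1000,
    alpha_init: float = 0.5,
    w_init: float = 0.5,
) -> tuple[BetaSignal, float, EmTrace]:
    """EM fit of f(p | Z_T=1) = w Beta(alpha, 1) + (1 - w) f_null(p).

    Applied to the SNPs in tissue-functional regions; returns the signal
    density, the conditional weight w = P(Z_D=1 | Z_T=1), and the EM trace.
    """
    p = clip_pvalues(pvalues)
    if p.size < 50:
        raise ValueError(f"need >= 50 p-values to fit the mixture, got {p.size}")
    null_pdf = f_null.pdf(p)
    logp = np.log(p)
    alpha, w = float(alpha_init), float(w_init)
    logliks: list[float] = []
    converged = False
    for _ in range(max_iter):
        sig = alpha * np.exp((alpha - 1.0) * logp)
        num = w * sig
        den = num + (1.0 - w) * null_pdf
        logliks.append(float(np.log(den).sum()))
        resp = num / den
        alpha, w = _signal_m_step(p, resp)
        if len(logliks) >= 2:
            prev, cur = logliks[-2], logliks[-1]
            if abs(cur - prev) < tol * (abs(prev) + 1e-12):
                converged = True
                break
    return (
        BetaSignal(alpha),
        w,
        EmTrace(np.asarray(logliks), len(logliks), converged),
    )


# ---------------------------------------------------------------------------
# fitted models
# ---------------------------------------------------------------------------

@dataclass
class PValueModel:
    """Everything needed to score a SNP: the two null histogram densities,
    the Beta(alpha, 1) signal, and the conditional weight P(Z_D=1 | Z_T=1)."""

    f_tissue_null: HistogramDensity
    f_general_null: HistogramDensity
    signal: BetaSignal
    w_cond: float
    em_trace: EmTrace | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.w_cond <= 1.0:
            raise ValueError("w_cond must lie in [0, 1]")


@dataclass
class GeneralPValueModel:
    """Two-case model on a general functionality track (for the NSFP score)."""

    f_null: HistogramDensity
    signal: BetaSignal
    w: float
    em_trace: EmTrace | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.w <= 1.0:
            raise ValueError("w must lie in [0, 1]")


# ---------------------------------------------------------------------------
# SNP table handling
# ---------------------------------------------------------------------------

REQUIRED_COLUMNS = ("CHR", "BP", "P")


def read_gwas_table(path: str | Path) -> pd.DataFrame:
    """Read a whitespace/tab-delimited GWAS summary table.

    Requires columns CHR, BP, P (case-insensitive); SNP is optional and
    synthesized from position when absent.
    """
    df = pd.read_csv(path, sep=r"\s+")
    rename = {}
    for col in df.columns:
        if col.upper() in REQUIRED_COLUMNS + ("SNP",):
            rename[col] = col.upper()
    df = df.rename(columns=rename)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"GWAS table missing required columns: {missing}")
    if "SNP" not in df.columns:
        df["SNP"] = df["CHR"].astype(str) + ":" + df["BP"].astype(str)
    df["CHR"] = df["CHR"].astype(str)
    df["BP"] = df["BP"].astype(np.int64)
    df["P"] = clip_pvalues(df["P"].to_numpy())
    return df


def assign_priors(
    snps: pd.DataFrame,
    tissue_track: ScoreTrack,
    general_track: ScoreTrack,
    window_bp: int = 10_000,
) -> pd.DataFrame:
    """Window-mean functional priors per SNP.

    PRIOR_T is the mean tissue score over the surrounding ``window_bp``
    basepairs (the 10 kb default), PRIOR_G the analogue on the general
    track; windows are clipped at chromosome bounds and unannotated bp
    count as 0.  SNPs on chromosomes absent from the genome are dropped
    with a warning.
    """
    if window_bp <= 0 or window_bp % 2:
        raise ValueError("window_bp must be a positive even integer")
    half = window_bp // 2
    known = snps["CHR"].isin(tissue_track.genome.keys())
    if (~known).any():
        warnings.warn(
            f"dropping {int((~known).sum())} SNPs on chromosomes absent "
            "from the score track", stacklevel=2,
        )
    out = snps.loc[known].reset_index(drop=True).copy()
    prior_t = np.zeros(len(out))
    prior_g = np.zeros(len(out))
    for chrom, grp in out.groupby("CHR", sort=False):
        pos = grp["BP"].to_numpy()
        idx = grp.index.to_numpy()
        prior_t[idx] = tissue_track.window_means(chrom, pos - half, pos + half)
        prior_g[idx] = general_track.window_means(chrom, pos - half, pos + half)
    out["PRIOR_T"] = np.clip(prior_t, 0.0, 1.0)
    out["PRIOR_G"] = np.clip(prior_g, 0.0, 1.0)
    return out


def partition_snps(
    snps: pd.DataFrame, which_prior: str = "tissue", threshold: float = 0.1
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split SNPs into low/high subsets at a mean-score prior threshold.

    The priors are strongly bimodal in practice, so the split is insensitive
    to the exact threshold (0.1 by default).
    """
    col = {"tissue": "PRIOR_T", "general": "PRIOR_G"}.get(which_prior)
    if col is None:
        raise ValueError("which_prior must be 'tissue' or 'general'")
    if col not in snps.columns:
        raise ValueError(f"priors not assigned: column {col} missing")
    low = snps[snps[col] < threshold]
    high = snps[snps[col] >= threshold]
    if low.empty or high.empty:
        raise ValueError(
            f"prior partition at threshold {threshold} left an empty subset "
            f"(low={len(low)}, high={len(high)}); threshold/data mismatch"
        )
    return low, high


# ---------------------------------------------------------------------------
# posterior scores
# ---------------------------------------------------------------------------

def case_posteriors(
    pvalues: np.ndarray, prior_tissue: np.ndarray, model: PValueModel
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Posterior probabilities of the three SNP cases given the p-value.

    Case I: trait- and tissue-functional (the GSP score); case II:
    tissue-functional only; case III: not tissue-functional.  The three sum
    to one by construction.
    """
    p = clip_pvalues(pvalues)
    t = np.clip(np.asarray(prior_tissue, dtype=np.float64), 0.0, 1.0)
    f_sig = model.signal.pdf(p)
    f_gnull = model.f_general_null.pdf(p)
    f_tnull = model.f_tissue_null.pdf(p)
    a1 = f_sig * model.w_cond * t
    a2 = f_gnull * (1.0 - model.w_cond) * t
    a3 = f_tnull * (1.0 - t)
    den = a1 + a2 + a3
    den = np.where(den > 0, den, 1.0)
    return a1 / den, a2 / den, a3 / den


def gsp_score(
    pvalues: np.ndarray, prior_tissue: np.ndarray, model: PValueModel
) -> np.ndarray:
    """Tissue-specific joint posterior P(Z_D=1, Z_T=1 | p) per SNP."""
    return case_posteriors(pvalues, prior_tissue, model)[0]


def nsfp_score(
    pvalues: np.ndarray, prior_general: np.ndarray, model: GeneralPValueModel
) -> np.ndarray:
    """Non-tissue-specific posterior P(Z_D=1 | p) from a general score track."""
    p = clip_pvalues(pvalues)
    g = np.clip(np.asarray(prior_general, dtype=np.float64), 0.0, 1.0) * model.w
    f_sig = model.signal.pdf(p)
    f_null = model.f_null.pdf(p)
    num = f_sig * g
    den = num + f_null * (1.0 - g)
    den = np.where(den > 0, den, 1.0)
    return num / den


# ---------------------------------------------------------------------------
# model serialization
# ---------------------------------------------------------------------------

def _write_density(fh, prefix: str, d: HistogramDensity) -> None:
    fh.write(f"{prefix}.edges\t{','.join(repr(float(x)) for x in d.bin_edges)}\n")
    fh.write(f"{prefix}.heights\t{','.join(repr(float(x)) for x in d.heights)}\n")


def _read_density(kv: dict[str, str], prefix: str) -> HistogramDensity:
    edges = np.array([float(x) for x in kv[f"{prefix}.edges"].split(",")])
    heights = np.array([float(x) for x in kv[f"{prefix}.heights"].split(",")])
    return HistogramDensity(edges, heights)


def save_pvalue_models(
    path: str | Path,
    model: PValueModel,
    general_model: GeneralPValueModel,
    window_bp: int,
    threshold: float,
    seed: int,
) -> None:
    """Key-value text serialization sufficient for exact re-scoring."""
    with open(path, "w") as fh:
        fh.write(f"window_bp\t{window_bp}\n")
        fh.write(f"threshold\t{threshold!r}\n")
        fh.write(f"seed\t{seed}\n")
        fh.write(f"alpha\t{model.signal.alpha!r}\n")
        fh.write(f"w_cond\t{model.w_cond!r}\n")
        _write_density(fh, "tissue_null", model.f_tissue_null)
        _write_density(fh, "general_null", model.f_general_null)
        fh.write(f"general.alpha\t{general_model.signal.alpha!r}\n")
        fh.write(f"general.w\t{general_model.w!r}\n")
        _write_density(fh, "general.null", general_model.f_null)


def load_pvalue_models(
    path: str | Path,
) -> tuple[PValueModel, GeneralPValueModel, dict[str, float]]:
    kv: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                key, _, val = line.rstrip("\n").partition("\t")
                kv[key] = val
    model = PValueModel(
        f_tissue_null=_read_density(kv, "tissue_null"),
        f_general_null=_read_density(kv, "general_null"),
        signal=BetaSignal(float(kv["alpha"])),
        w_cond=float(kv["w_cond"]),
    )
    general = GeneralPValueModel(
        f_null=_read_density(kv, "general.null"),
        signal=BetaSignal(float(kv["general.alpha"])),
        w=float(kv["general.w"]),
    )
    meta = {
        "window_bp": int(kv["window_bp"]),
        "threshold": float(kv["threshold"]),
        "seed": int(kv["seed"]),
    }
    return model, general, meta


# ---------------------------------------------------------------------------
# estimator + end-to-end pipeline
# ---------------------------------------------------------------------------

class PvaluePrioritizer(TransformerMixin, BaseEstimator):
    """Fit the p-value mixture models and score SNP tables.

    ``fit(X, tissue_track=..., general_track=...)`` takes a GWAS summary
    DataFrame (columns CHR, BP, P, optional SNP), assigns window-mean
    priors from the two score tracks, fits both null histogram densities
    (bin count by cross-validation), and runs the closed-form EM for
    (alpha, w).  ``transform`` then adds PRIOR_T, PRIOR_G, GSP and NSFP
    columns to any SNP table on the same genome.

    Parameters
    ----------
    window_bp : int
        Width of the window whose mean score is the per-SNP prior.
    prior_threshold : float
        Mean-score threshold splitting SNPs into low/high partitions.
    candidate_bins : sequence of int
        Histogram bin counts tried during cross-validation.
    cv_folds : int
    tol, max_iter : EM stopping rule.
    random_state : int
        Seed for CV fold shuffling.
    """

    def __init__(
        self,
        window_bp: int = 10_000,
        prior_threshold: float = 0.1,
        candidate_bins: Sequence[int] = DEFAULT_CANDIDATE_BINS,
        cv_folds: int = 10,
        tol: float = 1e-8,
        max_iter: int = 1000,
        random_state: int = 0,
    ):
        self.window_bp = window_bp
        self.prior_threshold = prior_threshold
        self.candidate_bins = candidate_bins
        self.cv_folds = cv_folds
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y=None, *,
            tissue_track: ScoreTrack, general_track: ScoreTrack | None = None):
        if general_track is None:
            warnings.warn(
                "no general functionality track given; using the tissue track "
                "as a same-track baseline for the NSFP score", stacklevel=2,
            )
            general_track = tissue_track
        self.tissue_track_ = tissue_track
        self.general_track_ = general_track
        snps = assign_priors(X, tissue_track, general_track, self.window_bp)

        low_t, high_t = partition_snps(snps, "tissue", self.prior_threshold)
        low_g, high_g = partition_snps(snps, "general", self.prior_threshold)

        f_tissue_null = fit_histogram_density(
            low_t["P"].to_numpy(), self.candidate_bins, self.cv_folds,
            self.random_state,
        )
        f_general_null = fit_histogram_density(
            low_g["P"].to_numpy(), self.candidate_bins, self.cv_folds,
            self.random_state,
        )
        signal, w_cond, trace = fit_signal_mixture(
            high_t["P"].to_numpy(), f_general_null, self.tol, self.max_iter,
        )
        self.model_ = PValueModel(
            f_tissue_null, f_general_null, signal, w_cond, trace
        )
        sig_g, w_g, trace_g = fit_signal_mixture(
            high_g["P"].to_numpy(), f_general_null, self.tol, self.max_iter,
        )
        self.general_model_ = GeneralPValueModel(f_general_null, sig_g, w_g, trace_g)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "model_"):
            raise ValueError("PvaluePrioritizer is not fitted")
        snps = assign_priors(
            X, self.tissue_track_, self.general_track_, self.window_bp
        )
        p = snps["P"].to_numpy()
        snps["GSP"] = gsp_score(p, snps["PRIOR_T"].to_numpy(), self.model_)
        snps["NSFP"] = nsfp_score(
            p, snps["PRIOR_G"].to_numpy(), self.general_model_
        )
        return snps


def prioritize(
    snps: pd.DataFrame,
    tissue_track: ScoreTrack,
    general_track: ScoreTrack | None = None,
    window_bp: int = 10_000,
    prior_threshold: float = 0.1,
    candidate_bins: Sequence[int] = DEFAULT_CANDIDATE_BINS,
    cv_folds: int = 10,
    tol: float = 1e-8,
    max_iter: int = 1000,
    seed: int = 0,
) -> tuple[pd.DataFrame, PvaluePrioritizer]:
    """End-to-end SNP prioritization: priors, density fits, GSP/NSFP scores.

    Deterministic given ``seed``.  Returns the scored table and the fitted
    prioritizer (whose ``model_`` / ``general_model_`` can be serialized).
    """
    est = PvaluePrioritizer(
        window_bp=window_bp,
        prior_threshold=prior_threshold,
        candidate_bins=candidate_bins,
        cv_folds=cv_folds,
        tol=tol,
        max_iter=max_iter,
        random_state=seed,
    )
    est.fit(snps, tissue_track=tissue_track, general_track=general_track)
    return est.transform(snps), est
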