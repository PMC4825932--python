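"""Two-component Bernoulli mixture over binarized epigenetic marks.

The model: at each basepair a latent indicator Z says whether the position is
functional in the tissue (Z = 1, prior pi) or not (Z = 0).  Given Z, the
eight binary mark indicators A_1..A_8 are independent Bernoulli variables
with rates p_{i1} (functional) or p_{i0} (background) — 17 free parameters.
Fitting is by EM over the 256 distinct mark patterns with bp multiplicities,
which is exactly equivalent to per-bp EM but runs in constant time per
iteration.  The per-position posterior P(Z=1 | A) is the tissue functional
score used everywhere downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, DensityMixin

from .annotation_io import (
    DEFAULT_MARKS,
    N_MARKS,
    N_PATTERNS,
    PATTERNS,
    MarkTrackSet,
    ScoreTrack,
    TrainingSample,
)

RATE_CLIP = 1e-6  # Bernoulli rates and pi kept in [RATE_CLIP, 1 - RATE_CLIP]


@dataclass(frozen=True)
class MixtureParams:
    """Parameters Theta = (pi, P1, P0) of the two-component mark mixture."""

    pi: float
    p1: np.ndarray
    p0: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "p1", np.asarray(self.p1, dtype=np.float64))
        object.__setattr__(self, "p0", np.asarray(self.p0, dtype=np.float64))
        for name, arr in (("p1", self.p1), ("p0", self.p0)):
            if arr.shape != (N_MARKS,):
                raise ValueError(f"{name} must have length {N_MARKS}")
            if (arr <= 0).any() or (arr >= 1).any():
                raise ValueError(f"{name} entries must lie strictly in (0, 1)")
        if not 0.0 < self.pi < 1.0:
            raise ValueError("pi must lie strictly in (0, 1)")

    @property
    def n_parameters(self) -> int:
        return 1 + 2 * N_MARKS  # 17

    def as_vector(self) -> np.ndarray:
        return np.concatenate([[self.pi], self.p1, self.p0])


@dataclass
class EmTrace:
    """Per-iteration log-likelihood record of an EM run."""

    loglik_per_iter: np.ndarray
    n_iter: int
    converged: bool


# ---------------------------------------------------------------------------
# core computations on 256-pattern counts
# ---------------------------------------------------------------------------

def _as_counts(data: TrainingSample | np.ndarray) -> np.ndarray:
    if isinstance(data, TrainingSample):
        counts = data.pattern_counts
    else:
        counts = np.asarray(data, dtype=np.int64)
        if counts.shape != (N_PATTERNS,):
            raise ValueError("expected a TrainingSample or a length-256 count vector")
    if counts.sum() == 0:
        raise ValueError("empty training data")
    return counts


def _pattern_log_density(rates: np.ndarray) -> np.ndarray:
    """log f(A | rates) for each of the 256 patterns under mark independence."""
    return PATTERNS @ np.log(rates) + (1.0 - PATTERNS) @ np.log1p(-rates)


def log_likelihood(params: MixtureParams, data: TrainingSample | np.ndarray) -> float:
    """Mixture log-likelihood of the data (bp multiplicities included)."""
    counts = _as_counts(data)
    l1 = _pattern_log_density(params.p1)
    l0 = _pattern_log_density(params.p0)
    m = np.maximum(l1, l0)
    mix = m + np.log(
        params.pi * np.exp(l1 - m) + (1.0 - params.pi) * np.exp(l0 - m)
    )
    return float(counts @ mix)


def _e_step(params: MixtureParams, counts: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-pattern responsibilities P(Z=1 | A) and the current log-likelihood."""
    l1 = _pattern_log_density(params.p1) + np.log(params.pi)
    l0 = _pattern_log_density(params.p0) + np.log1p(-params.pi)
    m = np.maximum(l1, l0)
    w1 = np.exp(l1 - m)
    w0 = np.exp(l0 - m)
    resp = w1 / (w1 + w0)
    ll = float(counts @ (m + np.log(w1 + w0)))
    return resp, ll


def _m_step(counts: np.ndarray, resp: np.ndarray) -> MixtureParams:
    """Weighted-mean updates: pi, p1 from responsibilities, p0 from complements."""
    n = counts.sum()
    w1 = counts * resp
    w0 = counts * (1.0 - resp)
    pi = w1.sum() / n
    s1 = w1.sum()
    s0 = w0.sum()
    p1 = (w1 @ PATTERNS) / s1 if s1 > 0 else np.full(N_MARKS, 0.5)
    p0 = (w0 @ PATTERNS) / s0 if s0 > 0 else np.full(N_MARKS, 0.5)
    clip = lambda x: np.clip(x, RATE_CLIP, 1.0 - RATE_CLIP)
    return MixtureParams(float(np.clip(pi, RATE_CLIP, 1.0 - RATE_CLIP)),
                         clip(p1), clip(p0))


def _run_em(counts: np.ndarray, init: MixtureParams, tol: float,
            max_iter: int) -> tuple[MixtureParams, EmTrace]:
    params = init
    logliks: list[float] = []
    converged = False
    for _ in range(max_iter):
        resp, ll = _e_step(params, counts)
        logliks.append(ll)
        params = _m_step(counts, resp)
        if len(logliks) >= 2:
            prev, cur = logliks[-2], logliks[-1]
            if abs(cur - prev) < tol * (abs(prev) + 1e-12):
                converged = True
                break
    return params, EmTrace(np.asarray(logliks), len(logliks), converged)


def _random_init(rng: np.random.Generator) -> MixtureParams:
    return MixtureParams(
        0.5,
        rng.uniform(0.5, 0.9, size=N_MARKS),
        rng.uniform(0.05, 0.3, size=N_MARKS),
    )


def em_fit(
    data: TrainingSample | np.ndarray,
    init: MixtureParams | int | None = None,
    tol: float = 1e-8,
    max_iter: int = 1000,
    n_restarts: int = 5,
    seed: int = 0,
) -> tuple[MixtureParams, EmTrace]:
    """Fit the 17-parameter mixture by EM.

    ``init`` may be explicit ``MixtureParams`` (single run from that start) or
    an integer seed; otherwise ``n_restarts`` random initializations are run
    (p1 ~ U(0.5, 0.9), p0 ~ U(0.05, 0.3), pi = 0.5) and the best final
    log-likelihood is kept.  After fitting, components are labeled so the
    functional component is the annotation-rich one (mean p1 >= mean p0).
    """
    counts = _as_counts(data)
    if (counts > 0).sum() < 2:
        raise ValueError(
            "training data contains a single mark pattern and cannot "
            "inform a two-component mixture"
        )
    if isinstance(init, MixtureParams):
        starts = [init]
    else:
        if isinstance(init, (int, np.integer)):
            seed = int(init)
        rng = np.random.default_rng(seed)
        starts = [_random_init(rng) for _ in range(n_restarts)]
    best: tuple[MixtureParams, EmTrace] | None = None
    for start in starts:
        params, trace = _run_em(counts, start, tol, max_iter)
        if best is None or trace.loglik_per_iter[-1] > best[1].loglik_per_iter[-1]:
            best = (params, trace)
    params, trace = best
    if params.p1.mean() < params.p0.mean():
        params = MixtureParams(1.0 - params.pi, params.p0, params.p1)
    return params, trace


# ---------------------------------------------------------------------------
# posterior scoring
# ---------------------------------------------------------------------------

def gs_posterior(params: MixtureParams, a: np.ndarray) -> float | np.ndarray:
    """Posterior P(Z=1 | A): the per-position tissue functional score.

    ``a`` is a length-8 binary vector or an (n, 8) matrix.
    """
    a = np.asarray(a, dtype=np.float64)
    single = a.ndim == 1
    a = np.atleast_2d(a)
    if a.shape[1] != N_MARKS:
        raise ValueError("mark vectors must have 8 entries")
    l1 = a @ np.log(params.p1) + (1 - a) @ np.log1p(-params.p1) + np.log(params.pi)
    l0 = a @ np.log(params.p0) + (1 - a) @ np.log1p(-params.p0) + np.log1p(-params.pi)
    m = np.maximum(l1, l0)
    w1 = np.exp(l1 - m)
    post = w1 / (w1 + np.exp(l0 - m))
    return float(post[0]) if single else post


def pattern_posteriors(params: MixtureParams) -> np.ndarray:
    """P(Z=1 | A) for all 256 mark patterns (lookup table for genome scoring)."""
    return np.asarray(gs_posterior(params, PATTERNS))


def score_genome(params: MixtureParams, ts: MarkTrackSet) -> ScoreTrack:
    """Per-bp functional posterior over the whole genome as an RLE track.

    Runs on the <=256 distinct mark patterns via the pattern-run overlay of
    the eight mark tracks; identical to naive per-bp evaluation.
    """
    lookup = pattern_posteriors(params)
    runs = {}
    for chrom in ts.genome:
        s, e, codes = ts.pattern_runs(chrom)
        runs[chrom] = (s, e, lookup[codes])
    return ScoreTrack.from_runs(ts.genome, runs)


# ---------------------------------------------------------------------------
# genome-level summaries
# ---------------------------------------------------------------------------

def functional_fraction(track: ScoreTrack, cutoff: float = 0.5) -> float:
    """Fraction of genome bp whose score >= cutoff (uncovered bp score 0)."""
    total = track.total_bp
    covered = sum(iv.length for iv in track.threshold_intervals(cutoff))
    return covered / total if total else 0.0


def tissue_count_profile(
    tracks: Mapping[str, ScoreTrack], cutoff: float = 0.5
) -> dict[int, int]:
    """bp counts by the number of tissues in which a position is functional.

    Returns {k: bp functional (score >= cutoff) in exactly k tissues} for
    k = 0..n_tissues.  All tracks must share the same genome.
    """
    names = list(tracks)
    genomes = [tracks[n].genome for n in names]
    if any(g != genomes[0] for g in genomes[1:]):
        raise ValueError("tracks must share the same genome")
    genome = genomes[0]
    n = len(names)
    out = {k: 0 for k in range(n + 1)}
    from .annotation_io import _coverage_at, _merge_arrays, _segment_bounds

    per_track_iv = {
        name: _group_by_chrom(tracks[name].threshold_intervals(cutoff))
        for name in names
    }
    for chrom, length in genome.items():
        sets = []
        for name in names:
            ivs = per_track_iv[name].get(chrom, [])
            if ivs:
                arr = np.asarray(ivs, dtype=np.int64)
                sets.append(_merge_arrays(arr[:, 0], arr[:, 1]))
            else:
                sets.append((np.empty(0, np.int64), np.empty(0, np.int64)))
        bounds = _segment_bounds(sets, length)
        seg_s, seg_e = bounds[:-1], bounds[1:]
        k = np.zeros(seg_s.size, dtype=np.int64)
        for s, e in sets:
            if s.size:
                k += _coverage_at(s, e, seg_s)
        for kk in range(n + 1):
            sel = k == kk
            if sel.any():
                out[kk] += int((seg_e[sel] - seg_s[sel]).sum())
    return out


def _group_by_chrom(intervals) -> dict[str, list[tuple[int, int]]]:
    grouped: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        grouped.setdefault(iv.chrom, []).append((iv.start, iv.end))
    return grouped


def overlap_log_odds(
    track_a: ScoreTrack, track_b: ScoreTrack, cutoff: float = 0.5
) -> float:
    """Log odds ratio of functional-bp overlap between two tissue tracks.

    Builds the 2x2 bp-count table of (>=cutoff vs <cutoff) for the two tracks
    and returns log[(n11 n00) / (n10 n01)] with the Haldane-Anscombe +0.5
    correction on every cell.
    """
    if track_a.genome != track_b.genome:
        raise ValueError("tracks must share the same genome")
    from .annotation_io import _coverage_at, _merge_arrays, _segment_bounds

    n11 = n10 = n01 = n00 = 0
    iv_a = _group_by_chrom(track_a.threshold_intervals(cutoff))
    iv_b = _group_by_chrom(track_b.threshold_intervals(cutoff))
    for chrom, length in track_a.genome.items():
        sets = []
        for grouped in (iv_a, iv_b):
            ivs = grouped.get(chrom, [])
            if ivs:
                arr = np.asarray(ivs, dtype=np.int64)
                sets.append(_merge_arrays(arr[:, 0], arr[:, 1]))
            else:
                sets.append((np.empty(0, np.int64), np.empty(0, np.int64)))
        bounds = _segment_bounds(sets, length)
        seg_s, seg_e = bounds[:-1], bounds[1:]
        seg_len = seg_e - seg_s
        in_a = (
            _coverage_at(*sets[0], seg_s) if sets[0][0].size
            else np.zeros(seg_s.size, bool)
        )
        in_b = (
            _coverage_at(*sets[1], seg_s) if sets[1][0].size
            else np.zeros(seg_s.size, bool)
        )
        n11 += int(seg_len[in_a & in_b].sum())
        n10 += int(seg_len[in_a & ~in_b].sum())
        n01 += int(seg_len[~in_a & in_b].sum())
        n00 += int(seg_len[~in_a & ~in_b].sum())
    return float(
        np.log((n11 + 0.5) * (n00 + 0.5) / ((n10 + 0.5) * (n01 + 0.5)))
    )


# ---------------------------------------------------------------------------
# parameter serialization
# ---------------------------------------------------------------------------

def save_mixture_params(
    path: str | Path,
    params: MixtureParams,
    marks: Sequence[str] = DEFAULT_MARKS,
    trace: EmTrace | None = None,
) -> None:
    """Key-value text serialization; floats printed with repr for exact read-back."""
    with open(path, "w") as fh:
        fh.write(f"marks\t{','.join(marks)}\n")
        fh.write(f"pi\t{float(params.pi)!r}\n")
        for name, arr in (("p1", params.p1), ("p0", params.p0)):
            for mark, val in zip(marks, arr):
                fh.write(f"{name}.{mark}\t{float(val)!r}\n")
        if trace is not None:
            fh.write(f"loglik\t{float(trace.loglik_per_iter[-1])!r}\n")
            fh.write(f"n_iter\t{trace.n_iter}\n")
            fh.write(f"converged\t{int(trace.converged)}\n")


def load_mixture_params(path: str | Path) -> tuple[MixtureParams, tuple[str, ...]]:
    kv: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                key, _, val = line.rstrip("\n").partition("\t")
                kv[key] = val
    marks = tuple(kv["marks"].split(","))
    p1 = np.array([float(kv[f"p1.{m}"]) for m in marks])
    p0 = np.array([float(kv[f"p0.{m}"]) for m in marks])
    return MixtureParams(float(kv["pi"]), p1, p0), marks


# ---------------------------------------------------------------------------
# sklearn estimator
# ---------------------------------------------------------------------------

class BernoulliMarkMixture(DensityMixin, BaseEstimator):
    """Two-component Bernoulli mixture estimator over binary mark vectors.

    scikit-learn-style interface: ``fit(X)`` with X an (n, 8) binary matrix
    (optionally ``sample_weight`` for bp multiplicities), ``predict_proba``
    returning the (background, functional) responsibilities, and
    ``posterior(X)`` returning the functional posterior directly.

    Parameters
    ----------
    tol : float
        Relative log-likelihood change below which EM stops.
    max_iter : int
        Maximum EM iterations per restart.
    n_restarts : int
        Number of random initializations; the best log-likelihood wins.
    random_state : int
        Seed for the initializations.

    Attributes
    ----------
    pi_ : float
        Prior probability of the functional component.
    p1_, p0_ : ndarray of shape (8,)
        Per-mark Bernoulli rates of the functional / background component.
    loglik_ : float
        Final log-likelihood of the training data.
    n_iter_ : int
        EM iterations used by the winning restart.
    converged_ : bool
    """

    def __init__(self, tol: float = 1e-8, max_iter: int = 1000,
                 n_restarts: int = 5, random_state: int = 0):
        self.tol = tol
        self.max_iter = max_iter
        self.n_restarts = n_restarts
        self.random_state = random_state

    def fit(self, X, y=None, sample_weight=None):
        X = np.asarray(X)
        if X.ndim != 2 or X.shape[1] != N_MARKS:
            raise ValueError("X must be an (n, 8) binary matrix")
        if not np.isin(X, (0, 1)).all():
            raise ValueError("X entries must be 0/1")
        codes = (X.astype(np.int64) << np.arange(N_MARKS)).sum(axis=1)
        if sample_weight is None:
            counts = np.bincount(codes, minlength=N_PATTERNS)
        else:
            sample_weight = np.asarray(sample_weight, dtype=np.int64)
            counts = np.bincount(codes, weights=sample_weight,
                                 minlength=N_PATTERNS).astype(np.int64)
        params, trace = em_fit(
            counts, tol=self.tol, max_iter=self.max_iter,
            n_restarts=self.n_restarts, seed=self.random_state,
        )
        self.pi_ = params.pi
        self.p1_ = params.p1
        self.p0_ = params.p0
        self.loglik_ = float(trace.loglik_per_iter[-1])
        self.loglik_path_ = trace.loglik_per_iter
        self.n_iter_ = trace.n_iter
        self.converged_ = trace.converged
        return self

    @property
    def params_(self) -> MixtureParams:
        return MixtureParams(self.pi_, self.p1_, self.p0_)

    def posterior(self, X) -> np.ndarray:
        """P(Z=1 | A) for each row of X — the functional score."""
        return np.asarray(gs_posterior(self.params_, np.atleast_2d(X)))

    def predict_proba(self, X) -> np.ndarray:
        post = self.posterior(X)
        return np.column_stack([1.0 - post, post])

    def predict(self, X) -> np.ndarray:
        return (self.posterior(X) >= 0.5).astype(np.int64)

    def score_samples(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        p = self.params_
        l1 = X @ np.log(p.p1) + (1 - X) @ np.log1p(-p.p1) + np.log(p.pi)
        l0 = X @ np.log(p.p0) + (1 - X) @ np.log1p(-p.p0) + np.log1p(-p.pi)
        m = np.maximum(l1, l0)
        return m + np.log(np.exp(l1 - m) + np.exp(l0 - m))

    def score(self, X, y=None) -> float:
        return float(np.mean(self.score_samples(X)))
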