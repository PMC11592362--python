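"""Distance-correlation functional connectivity with subsampling bias control.

Distance correlation (Szekely, Rizzo & Bakirov) measures statistical
dependence between two time series on a [0, 1] scale and, unlike Pearson
correlation, is sensitive to nonlinear coupling.  Its sample estimate is
biased upward at small n and the bias depends on n, so conditions with
different durations are not directly comparable.  The estimator here
removes that duration confound: within each run and condition it draws
``reps`` random subsamples of exactly ``m`` paired time points
(defaults m=30, reps=100), computes the distance correlation of each,
pools the estimates across runs, and takes the pooled median as the
connectivity value for that (subject, condition, ROI pair).

The V-statistic (biased, non-negative) form of distance correlation is
used throughout; a constant series has zero distance variance and the
correlation is defined as 0 in that case.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .atlas import ParcellationMap
from .timeseries import CONDITIONS, SubjectRecord, segment_conditions

logger = logging.getLogger(__name__)

__all__ = [
    "SubsampleConfig",
    "ConnectivityTensor",
    "distance_correlation",
    "pairwise_distance_correlation",
    "subsample_estimates",
    "median_connectivity",
    "compute_connectivity_tensor",
    "substream",
]


@dataclass(frozen=True)
class SubsampleConfig:
    """Subsampling policy for the duration-bias-corrected estimator.

    Parameters
    ----------
    m
        Subsample size in volumes; every estimate uses exactly ``m`` paired
        time points regardless of condition duration.
    reps
        Number of random subsamples per run x condition.
    share_indices
        If True (default), one index set per (subject, run, condition,
        repetition) is shared across all ROI pairs; if False, every ROI
        pair draws its own indices.  The per-edge marginal distribution of
        the estimator is identical either way.
    seed
        Master seed; per-(subject, run, condition) substreams are derived
        from it so results do not depend on iteration order.
    """

    m: int = 30
    reps: int = 100
    share_indices: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 4:
            raise ValueError("subsample size m must be >= 4")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")


def substream(seed: int, *keys: object) -> np.random.Generator:
    """Deterministic RNG substream keyed by stable string identifiers."""
    digest = zlib.crc32("/".join(str(k) for k in keys).encode())
    return np.random.default_rng(np.random.SeedSequence([int(seed), digest]))


def _centered_distance_matrix(x: np.ndarray) -> np.ndarray:
    d = np.abs(x[:, None] - x[None, :])
    return d - d.mean(axis=0, keepdims=True) - d.mean(axis=1, keepdims=True) + d.mean()


def distance_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample (V-statistic) distance correlation of two 1-D series, in [0, 1].

    Pairwise absolute-difference matrices of x and y are double-centred
    (row means, column means and grand mean removed); dCov^2 is the mean
    elementwise product and dCor = sqrt(dCov^2 / sqrt(dVar2_x * dVar2_y)).
    Returns 0.0 when either series is constant (zero distance variance).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    A = _centered_distance_matrix(x)
    B = _centered_distance_matrix(y)
    dvar_x = (A * A).mean()
    dvar_y = (B * B).mean()
    if dvar_x <= 0.0 or dvar_y <= 0.0:
        logger.warning("constant series encountered; distance correlation set to 0")
        return 0.0
    dcov2 = (A * B).mean()
    return float(np.sqrt(max(dcov2, 0.0) / np.sqrt(dvar_x * dvar_y)))


def pairwise_distance_correlation(X: np.ndarray) -> np.ndarray:
    """All-pairs distance correlation of the columns of X (n x R).

    Vectorised over ROIs: each column's centred distance matrix is formed
    once and dCov^2 for every pair is a single Gram product.  Equivalent
    to calling :func:`distance_correlation` on every column pair.
    """
    X = np.asarray(X, dtype=float)
    n, r = X.shape
    D = np.abs(X[:, None, :] - X[None, :, :])  # n x n x R
    D -= D.mean(axis=0, keepdims=True)
    D -= D.mean(axis=1, keepdims=True)
    D += D.mean(axis=(0, 1), keepdims=True)
    F = D.reshape(n * n, r)
    G = (F.T @ F) / (n * n)  # dCov^2 for every pair
    dvar = np.clip(np.diag(G), 0.0, None)
    denom = np.sqrt(np.outer(dvar, dvar))  # sqrt(dVar2_i * dVar2_j)
    out = np.zeros((r, r))
    ok = denom > 0
    out[ok] = np.sqrt(np.clip(G[ok], 0.0, None) / denom[ok])
    np.fill_diagonal(out, np.where(dvar > 0, 1.0, 0.0))
    return out


def subsample_estimates(
    x: np.ndarray,
    y: np.ndarray,
    cfg: SubsampleConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Repeated m-point subsample distance-correlation estimates for one pair.

    Each of ``cfg.reps`` estimates is the distance correlation of a uniform
    without-replacement subsample of ``cfg.m`` time points; the same indices
    are applied to both series so the pairing is preserved.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = x.size
    if n < cfg.m:
        raise ValueError(f"condition length {n} < subsample size m={cfg.m}")
    out = np.empty(cfg.reps)
    for k in range(cfg.reps):
        # a subsample is a set of time points; sorting keeps temporal order
        # and makes the m == n case reproduce the full-sample estimate exactly
        idx = np.sort(rng.choice(n, size=cfg.m, replace=False))
        out[k] = distance_correlation(x[idx], y[idx])
    return out


def median_connectivity(per_run_estimates: Iterable[np.ndarray]) -> float:
    """Median of subsample estimates pooled across runs (the connectivity value)."""
    chunks = [np.asarray(e, dtype=float).ravel() for e in per_run_estimates]
    pooled = np.concatenate(chunks) if chunks else np.array([])
    if pooled.size == 0:
        raise ValueError("no estimates to pool")
    return float(np.median(pooled))


@dataclass
class ConnectivityTensor:
    """(subject, condition, edge) array of pooled-median connectivity estimates."""

    values: np.ndarray  # S x C x E
    subjects: list[str]
    groups: list[str]  # group label per subject
    conditions: list[str]
    edge_index: np.ndarray  # E x 2, 0-based ROI positions, i < j

    def __post_init__(self) -> None:
        s, c, e = self.values.shape
        if len(self.subjects) != s or len(self.groups) != s:
            raise ValueError("subject axis mismatch")
        if len(self.conditions) != c:
            raise ValueError("condition axis mismatch")
        if self.edge_index.shape != (e, 2):
            raise ValueError("edge axis mismatch")

    @property
    def n_edges(self) -> int:
        return self.values.shape[2]

    def condition_slice(self, condition: str) -> np.ndarray:
        """(subjects x edges) slice for one condition."""
        try:
            c = self.conditions.index(condition)
        except ValueError:
            raise KeyError(f"condition {condition!r} not in tensor") from None
        return self.values[:, c, :]

    def save(self, outdir: str | Path, pmap: ParcellationMap | None = None) -> None:
        """Persist as a directory of TSV tables (edges.tsv + values.tsv)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        i, j = self.edge_index.T
        edges = pd.DataFrame({"edge_id": np.arange(self.n_edges), "roi_i": i, "roi_j": j})
        if pmap is not None:
            nets = np.asarray(pmap.network_of)
            edges["net_i"] = nets[i]
            edges["net_j"] = nets[j]
        edges.to_csv(outdir / "edges.tsv", sep="\t", index=False)
        s, c, e = self.values.shape
        long = pd.DataFrame(
            {
                "subject": np.repeat(self.subjects, c * e),
                "group": np.repeat(self.groups, c * e),
                "condition": np.tile(np.repeat(self.conditions, e), s),
                "edge_id": np.tile(np.arange(e), s * c),
                "estimate": self.values.ravel(),
            }
        )
        long.to_csv(outdir / "values.tsv", sep="\t", index=False, float_format="%.10g")

    @classmethod
    def load(cls, indir: str | Path) -> "ConnectivityTensor":
        indir = Path(indir)
        edges = pd.read_csv(indir / "edges.tsv", sep="\t")
        long = pd.read_csv(indir / "values.tsv", sep="\t")
        subjects = list(long["subject"].astype(str).drop_duplicates())
        groups = [
            str(long.loc[long["subject"].astype(str) == s, "group"].iloc[0]) for s in subjects
        ]
        conditions = list(long["condition"].drop_duplicates())
        e = len(edges)
        values = np.full((len(subjects), len(conditions), e), np.nan)
        s_idx = {s: k for k, s in enumerate(subjects)}
        c_idx = {c: k for k, c in enumerate(conditions)}
        values[
            long["subject"].astype(str).map(s_idx),
            long["condition"].map(c_idx),
            long["edge_id"],
        ] = long["estimate"]
        if np.isnan(values).any():
            raise ValueError(f"{indir}: incomplete tensor (missing cells)")
        return cls(
            values,
            subjects,
            groups,
            conditions,
            edges[["roi_i", "roi_j"]].to_numpy(),
        )


def _edge_values(dcor_matrix: np.ndarray, edge_index: np.ndarray) -> np.ndarray:
    return dcor_matrix[edge_index[:, 0], edge_index[:, 1]]


def compute_connectivity_tensor(
    cohort: Sequence[SubjectRecord],
    pmap: ParcellationMap,
    cfg: SubsampleConfig,
) -> ConnectivityTensor:
    """Pooled-median subsampled distance-correlation tensor for a cohort.

    For every subject, run and condition, ``cfg.reps`` subsamples of
    ``cfg.m`` volumes are drawn and all-pairs distance correlations
    computed; estimates are pooled over runs and the per-edge median taken.
    Deterministic given ``cfg.seed`` regardless of subject order.
    """
    edge_index = pmap.edge_index()
    n_edges = len(edge_index)
    conditions = list(CONDITIONS)
    values = np.empty((len(cohort), len(conditions), n_edges))
    for s, subj in enumerate(cohort):
        if subj.runs and subj.runs[0].n_rois != pmap.n_rois:
            raise ValueError(
                f"subject {subj.subject_id}: {subj.runs[0].n_rois} ROIs vs "
                f"parcellation {pmap.n_rois}"
            )
        for c, cond in enumerate(conditions):
            per_run: list[np.ndarray] = []
            for r, run in enumerate(subj.runs):
                seg = segment_conditions(run)[cond]
                n = seg.shape[0]
                if n < cfg.m:
                    raise ValueError(
                        f"subject {subj.subject_id} run {r} condition {cond!r}: "
                        f"{n} volumes < subsample size m={cfg.m}"
                    )
                rng = substream(cfg.seed, "conn", subj.subject_id, r, cond)
                per_run.append(_run_condition_estimates(seg, edge_index, cfg, rng))
            values[s, c] = np.median(np.concatenate(per_run, axis=0), axis=0)
    return ConnectivityTensor(
        values,
        [s.subject_id for s in cohort],
        [s.group for s in cohort],
        conditions,
        edge_index,
    )


def _run_condition_estimates(
    seg: np.ndarray, edge_index: np.ndarray, cfg: SubsampleConfig, rng: np.random.Generator
) -> np.ndarray:
    """(reps x edges) subsample estimates for one run x condition segment."""
    n = seg.shape[0]
    out = np.empty((cfg.reps, len(edge_index)))
    if cfg.share_indices:
        for k in range(cfg.reps):
            idx = np.sort(rng.choice(n, size=cfg.m, replace=False))
            out[k] = _edge_values(pairwise_distance_correlation(seg[idx]), edge_index)
    else:
        # literal per-pair draws; only sensible at small ROI counts
        for e, (i, j) in enumerate(edge_index):
            out[:, e] = subsample_estimates(seg[:, i], seg[:, j], cfg, rng)
    return out
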