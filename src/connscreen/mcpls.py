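"""Mean-centered partial least squares with permutation and bootstrap inference.

Mean-centered PLS, in the form standard in task neuroimaging, decomposes
the matrix of design-cell mean feature vectors (after removing the grand
mean across cells) with a singular value decomposition.  Each latent
variable (LV) pairs a data-driven *contrast* across cells (left singular
vector) with a *salience* pattern over features (right singular vector);
the squared singular values apportion the explained cross-cell
covariance.  Inference follows the usual two-resampling recipe:

* a permutation test on the dominant singular value — rows are reassigned
  to cells (cell sizes preserved), the decomposition repeated, and the
  p-value is the add-one tail proportion of permuted s1 >= observed s1;
* bootstrap ratios ("z-scores") per feature — subjects are resampled with
  replacement within group, saliences re-estimated, Procrustes-aligned to
  the observed solution, and each reference salience divided by its
  bootstrap standard deviation.

Only LV1 (highest explained variance) is inferenced; the full
decomposition is kept on the results object.  If the median bootstrap
ratio is negative the whole LV (contrast, saliences, z-scores) is
negated, so z-score distributions are always skewed positive and
contrasts are comparable across analyses.

The model object follows the statsmodels convention: construct
:class:`MeanCenteredPLS` from data, call :meth:`~MeanCenteredPLS.fit`,
get a :class:`PLSResults` with estimates, diagnostics and ``summary()``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .features import FeatureMatrix

logger = logging.getLogger(__name__)

__all__ = ["MeanCenteredPLS", "PLSResults", "cell_mean_center", "pls_svd"]

_RANK_TOL = 1e-12


def cell_mean_center(
    X: np.ndarray, row_cells: np.ndarray, n_cells: int
) -> tuple[np.ndarray, np.ndarray]:
    """Cell means minus their unweighted grand mean.

    The grand mean is the unweighted average of the cell means (not the
    pooled row mean), so unbalanced cells do not tilt the centering.
    Returns (M_c of shape cells x features, grand_mean); columns of M_c
    sum to zero.
    """
    X = np.asarray(X, dtype=float)
    means = np.empty((n_cells, X.shape[1]))
    for c in range(n_cells):
        rows = X[row_cells == c]
        if rows.shape[0] == 0:
            raise ValueError(f"design cell {c} is empty")
        means[c] = rows.mean(axis=0)
    grand = means.mean(axis=0)
    return means - grand, grand


def pls_svd(M_c: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Thin SVD of the centered cell-mean matrix, singular values descending.

    Returns (U, S, V, explained_variance) with columns of U the cell
    saliences (contrasts), columns of V the feature saliences, and
    explained_variance_l = s_l^2 / sum(s^2) (all zeros for a zero matrix).
    """
    U, S, Vt = np.linalg.svd(np.asarray(M_c, dtype=float), full_matrices=False)
    total = float(np.sum(S**2))
    ev = S**2 / total if total > 0 else np.zeros_like(S)
    return U, S, Vt.T, ev


def _resolve_rows(fm_or_X, row_cells, cells, subjects):
    if isinstance(fm_or_X, FeatureMatrix):
        fm = fm_or_X
        return fm.X, fm.row_cells, list(fm.cells), list(fm.row_subjects)
    X = np.asarray(fm_or_X, dtype=float)
    row_cells = np.asarray(row_cells)
    if cells is None:
        cells = [str(c) for c in range(int(row_cells.max()) + 1)]
    if subjects is None:
        subjects = [str(i) for i in range(X.shape[0])]
    return X, row_cells, list(cells), list(subjects)


class MeanCenteredPLS:
    """Mean-centered PLS model for a (observations x features) data matrix.

    Parameters
    ----------
    data
        A :class:`~connscreen.features.FeatureMatrix` or a plain array;
        in the latter case ``row_cells`` (cell index per row) is required
        and ``cells``/``subjects`` are optional labels.
    permute_scheme
        ``"rows"`` (default) reassigns rows to cells freely, preserving
        cell sizes; ``"subjects"`` permutes group labels of whole subjects,
        keeping each subject's condition rows together.
    """

    def __init__(
        self,
        data,
        row_cells: Sequence[int] | None = None,
        cells: Sequence[str] | None = None,
        subjects: Sequence[str] | None = None,
        permute_scheme: str = "rows",
    ) -> None:
        self.X, self.row_cells, self.cells, self.subjects = _resolve_rows(
            data, row_cells, cells, subjects
        )
        if self.X.ndim != 2:
            raise ValueError("data must be 2-D (observations x features)")
        if len(self.cells) < 2:
            raise ValueError("need at least 2 design cells")
        if permute_scheme not in ("rows", "subjects"):
            raise ValueError(f"unknown permute_scheme {permute_scheme!r}")
        self.permute_scheme = permute_scheme
        # subjects sharing a cell-membership pattern form one resampling
        # stratum (a group, in the two-group designs used here)
        self._subject_ids = list(dict.fromkeys(self.subjects))
        subj_arr = np.asarray(self.subjects)
        self._subject_rows = {s: np.flatnonzero(subj_arr == s) for s in self._subject_ids}
        self._subject_stratum = {
            s: tuple(sorted(set(self.row_cells[self._subject_rows[s]])))
            for s in self._subject_ids
        }
        strata: dict[tuple, list[str]] = {}
        for s in self._subject_ids:
            strata.setdefault(self._subject_stratum[s], []).append(s)
        self._strata = strata

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def _decompose(self, X: np.ndarray, row_cells: np.ndarray):
        M_c, _ = cell_mean_center(X, row_cells, self.n_cells)
        return pls_svd(M_c)

    def fit(
        self,
        n_permutations: int | str = 1000,
        n_bootstraps: int = 1000,
        rng: np.random.Generator | int | None = None,
    ) -> "PLSResults":
        """Decompose, run permutation and bootstrap inference, align signs.

        ``n_permutations="exact"`` enumerates every distinct cell assignment
        (small designs only) and reports the exact tail proportion instead
        of the add-one Monte-Carlo estimate.
        """
        rng = np.random.default_rng(rng)
        U, S, V, ev = self._decompose(self.X, self.row_cells)
        s1 = float(S[0]) if S.size else 0.0
        if n_permutations == "exact":
            p = self._exact_permutation_pvalue(s1)
            n_permutations = -1
        else:
            p = self._permutation_pvalue(s1, n_permutations, rng)
        z = self._bootstrap_ratios(U, S, V, n_bootstraps, rng)
        res = PLSResults(
            model=self,
            contrast=U[:, 0].copy(),
            cell_saliences=U,
            singular_values=S,
            feature_saliences=V,
            explained_variance=ev,
            p_value=p,
            z_scores=z,
            n_permutations=n_permutations,
            n_bootstraps=n_bootstraps,
        )
        return res._align_sign()

    # -- permutation ---------------------------------------------------------

    def _permuted_cells(self, rng: np.random.Generator) -> np.ndarray:
        if self.permute_scheme == "rows":
            return rng.permutation(self.row_cells)
        # subjects: shuffle stratum membership of whole subjects across
        # strata of equal cell-pattern cardinality (two-group designs:
        # permute group labels, conditions kept)
        perm_cells = self.row_cells.copy()
        patterns = list(self._strata)
        pooled = [s for pat in patterns for s in self._strata[pat]]
        shuffled = list(rng.permutation(pooled))
        k = 0
        for pat in patterns:
            for _ in self._strata[pat]:
                s = shuffled[k]
                k += 1
                src = self._subject_stratum[s]
                mapping = dict(zip(src, pat))
                rows = self._subject_rows[s]
                perm_cells[rows] = [mapping[c] for c in self.row_cells[rows]]
        return perm_cells

    def _permutation_pvalue(
        self, s1_obs: float, n_perm: int, rng: np.random.Generator
    ) -> float:
        if n_perm < 1:
            raise ValueError("n_permutations must be >= 1")
        if s1_obs <= 0.0:
            logger.warning("degenerate zero first singular value; p set to 1.0")
            return 1.0
        exceed = 0
        for _ in range(n_perm):
            perm = self._permuted_cells(rng)
            _, S, _, _ = self._decompose(self.X, perm)
            if S.size and S[0] >= s1_obs:
                exceed += 1
        return (1 + exceed) / (1 + n_perm)

    def _exact_permutation_pvalue(self, s1_obs: float, limit: int = 20000) -> float:
        """Exact p over all distinct cell assignments (the observed one included)."""
        from itertools import permutations

        if s1_obs <= 0.0:
            return 1.0
        if self.permute_scheme != "rows":
            raise ValueError("exact enumeration is implemented for the rows scheme")
        seen = set()
        exceed = total = 0
        for assignment in permutations(self.row_cells):
            if assignment in seen:
                continue
            seen.add(assignment)
            total += 1
            if total > limit:
                raise ValueError(f"more than {limit} distinct assignments; use Monte Carlo")
            _, S, _, _ = self._decompose(self.X, np.asarray(assignment))
            if S.size and S[0] >= s1_obs - 1e-12:
                exceed += 1
        return exceed / total

    # -- bootstrap -----------------------------------------------------------

    def _bootstrap_ratios(
        self,
        U_ref: np.ndarray,
        S_ref: np.ndarray,
        V_ref: np.ndarray,
        n_boot: int,
        rng: np.random.Generator,
    ) -> np.ndarray:
        if n_boot < 2:
            raise ValueError("n_bootstraps must be >= 2")
        counts = np.bincount(self.row_cells, minlength=self.n_cells)
        subj_per_cell = {
            c: len({self.subjects[i] for i in np.flatnonzero(self.row_cells == c)})
            for c in range(self.n_cells)
        }
        if min(subj_per_cell.values()) < 2:
            raise ValueError("every design cell needs >= 2 subjects for the bootstrap")
        smax = float(S_ref[0]) if S_ref.size else 0.0
        keep = int(np.sum(S_ref > _RANK_TOL * max(smax, 1.0)))
        keep = max(keep, 1)
        v1_boot = np.empty((n_boot, V_ref.shape[0]))
        for b in range(n_boot):
            rows, cells = self._bootstrap_rows(rng)
            v1_boot[b] = _procrustes_first(self.X[rows], cells, U_ref, keep, self)
        sd = v1_boot.std(axis=0, ddof=1)
        sd = np.maximum(sd, 1e-12)
        return V_ref[:, 0] / sd

    def _bootstrap_rows(self, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        """Resample subjects with replacement within stratum; rows move together."""
        rows: list[np.ndarray] = []
        cells: list[np.ndarray] = []
        for pat, members in self._strata.items():
            picks = rng.choice(len(members), size=len(members), replace=True)
            for k in picks:
                r = self._subject_rows[members[k]]
                rows.append(r)
                cells.append(self.row_cells[r])
        return np.concatenate(rows), np.concatenate(cells)


def _procrustes_first(Xb, cellsb, U_ref, keep, model) -> np.ndarray:
    """First feature salience of the resample, Procrustes-aligned to the reference.

    Alignment uses the orthogonal rotation of the resampled cell saliences
    onto the observed ones, restricted to the retained (non-null) LVs; for
    a single retained LV this is exactly a sign flip.
    """
    M_c, _ = cell_mean_center(Xb, cellsb, model.n_cells)
    U_b, S_b, Vt_b = np.linalg.svd(M_c, full_matrices=False)
    V_b = Vt_b.T
    k = min(keep, U_b.shape[1], U_ref.shape[1])
    W, _, Zt = np.linalg.svd(U_b[:, :k].T @ U_ref[:, :k])
    Q = W @ Zt  # rotation minimising ||U_b Q - U_ref||_F
    return (V_b[:, :k] @ Q)[:, 0]


@dataclass
class PLSResults:
    """Fitted mean-centered PLS for one feature space.

    Attributes
    ----------
    contrast
        LV1 cell saliences (unit norm): the data-driven contrast over
        design cells.
    singular_values, explained_variance
        Full spectrum; ``explained_variance`` sums to 1 unless the matrix
        is zero.
    p_value
        Add-one permutation p for s1.
    z_scores
        Bootstrap ratio per feature (salience / bootstrap SD), aligned so
        the median is non-negative.
    sign_flipped
        True if the LV was negated to satisfy the median-z convention.
    """

    model: MeanCenteredPLS
    contrast: np.ndarray
    cell_saliences: np.ndarray
    singular_values: np.ndarray
    feature_saliences: np.ndarray
    explained_variance: np.ndarray
    p_value: float
    z_scores: np.ndarray
    n_permutations: int
    n_bootstraps: int
    sign_flipped: bool = False
    feature_edges: np.ndarray | None = None  # edge ids when fitted to a pairing

    def _align_sign(self) -> "PLSResults":
        """Negate the LV if the median z-score is negative (idempotent)."""
        if np.median(self.z_scores) < 0:
            self.contrast = -self.contrast
            self.z_scores = -self.z_scores
            self.feature_saliences = self.feature_saliences.copy()
            self.feature_saliences[:, 0] *= -1
            self.cell_saliences = self.cell_saliences.copy()
            self.cell_saliences[:, 0] *= -1
            self.sign_flipped = not self.sign_flipped
        return self

    def to_dict(self) -> dict:
        return {
            "cells": self.model.cells,
            "contrast": self.contrast.tolist(),
            "singular_values": self.singular_values.tolist(),
            "explained_variance": self.explained_variance.tolist(),
            "p_value": self.p_value,
            "z_scores": self.z_scores.tolist(),
            "n_permutations": self.n_permutations,
            "n_bootstraps": self.n_bootstraps,
            "sign_flipped": self.sign_flipped,
        }

    def summary(self) -> str:
        lines = [
            "Mean-Centered PLS Results",
            "=" * 56,
            f"Observations: {self.model.X.shape[0]:>6}    Features: {self.model.X.shape[1]}",
            f"Permutations: {self.n_permutations:>6}    Bootstraps: {self.n_bootstraps}",
            f"LV1 singular value: {self.singular_values[0]:.6g}",
            f"LV1 explained variance: {self.explained_variance[0]:.4f}",
            f"LV1 permutation p: {self.p_value:.4g}",
            f"Sign flipped: {self.sign_flipped}",
            "-" * 56,
            f"{'cell':<24}{'contrast':>12}",
        ]
        for cell, c in zip(self.model.cells, self.contrast):
            lines.append(f"{cell:<24}{c:>12.4f}")
        z = self.z_scores
        lines += [
            "-" * 56,
            f"z-scores: median {np.median(z):.3f}, max {z.max():.3f}, "
            f"{int((z > 2.5).sum())} feature(s) above 2.5",
        ]
        return "\n".join(lines)
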