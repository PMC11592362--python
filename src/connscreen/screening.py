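"""Pairing-wise PLS screening with FDR control and edge-level reporting.

One mean-centered PLS runs per network pairing (595 at the 34-network
scale: 34 intra + 561 inter).  All pairing p-values of one analysis
series form a single family corrected with Benjamini-Hochberg FDR; the
two analysis series (group-by-condition, idiosyncrasy) are corrected
separately.  For pairings surviving FDR, the edges whose bootstrap
z-score exceeds a display threshold (default 2.5, strict inequality) are
reported as a connection graph, and edges can be classified by the
hemispheres of their ROIs (left-intra / right-intra / inter-hemispheric).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .atlas import NetworkPairing, ParcellationMap, enumerate_pairings
from .connectivity import ConnectivityTensor, substream
from .features import assemble_feature_matrix
from .mcpls import MeanCenteredPLS, PLSResults

logger = logging.getLogger(__name__)

ANALYSES = ("group_by_condition", "idiosyncrasy")

__all__ = [
    "ANALYSES",
    "ScreeningConfig",
    "PairingRecord",
    "ScreeningReport",
    "fdr_bh",
    "threshold_edges",
    "classify_edges_by_hemisphere",
    "run_screening",
]


def fdr_bh(p_values: Sequence[float], q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up procedure.

    Returns (reject flags at level ``q``, q-values).  The q-value of a test
    is the smallest FDR level at which it would be rejected (monotone
    step-up adjusted p, capped at 1).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, bool), np.zeros(0)
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    reject, qvals, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, qvals


def threshold_edges(z_scores: np.ndarray, threshold: float = 2.5) -> np.ndarray:
    """Indices of features with z strictly above threshold, descending z."""
    if not np.isfinite(threshold) and threshold > 0:
        raise ValueError("threshold must be finite or -inf")
    z = np.asarray(z_scores, dtype=float)
    passing = np.flatnonzero(z > threshold)
    return passing[np.argsort(-z[passing], kind="stable")]


@dataclass(frozen=True)
class ScreeningConfig:
    """Inference settings for one screening series."""

    n_permutations: int = 1000
    n_bootstraps: int = 1000
    z_threshold: float = 2.5
    q_levels: tuple[float, float] = (0.05, 0.10)
    permute_scheme: str = "rows"
    seed: int = 0


@dataclass
class PairingRecord:
    """One pairing's PLS outcome within the screening family."""

    pairing: NetworkPairing
    result: PLSResults | None
    p_value: float
    q_value: float = float("nan")
    failed: bool = False


@dataclass
class ScreeningReport:
    """All pairing records of one analysis series, FDR-corrected."""

    analysis_id: str
    records: list[PairingRecord]
    q_levels: tuple[float, float]
    z_threshold: float
    significant: dict[float, list[str]] = field(default_factory=dict)
    edge_graphs: dict[str, pd.DataFrame] = field(default_factory=dict)

    @property
    def pairing_labels(self) -> list[str]:
        return [r.pairing.label for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            res = r.result
            rows.append(
                {
                    "pairing": r.pairing.label,
                    "kind": r.pairing.kind,
                    "s1": float(res.singular_values[0]) if res else np.nan,
                    "explained_variance": float(res.explained_variance[0]) if res else np.nan,
                    "p": r.p_value,
                    "q": r.q_value,
                    **{
                        f"significant_{int(q * 100):02d}": r.pairing.label
                        in self.significant[q]
                        for q in self.q_levels
                    },
                    "failed": r.failed,
                }
            )
        return pd.DataFrame(rows)

    def save(self, outdir: str | Path, pmap: ParcellationMap | None = None) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(
            outdir / f"pairings_{self.analysis_id}.tsv", sep="\t", index=False
        )
        payload = {
            "analysis_id": self.analysis_id,
            "q_levels": list(self.q_levels),
            "z_threshold": self.z_threshold,
            "significant": {str(q): self.significant[q] for q in self.q_levels},
            "pairings": [
                {
                    "pairing": r.pairing.label,
                    "kind": r.pairing.kind,
                    "p": r.p_value,
                    "q": r.q_value,
                    "failed": r.failed,
                    **(r.result.to_dict() if r.result else {}),
                }
                for r in self.records
            ],
        }
        with open(outdir / f"report_{self.analysis_id}.json", "w") as fh:
            json.dump(payload, fh, indent=1, allow_nan=False)
        for label, graph in self.edge_graphs.items():
            safe = label.replace("--", "__")
            graph.to_csv(outdir / f"edges_{self.analysis_id}_{safe}.tsv", sep="\t", index=False)


def classify_edges_by_hemisphere(
    edges: pd.DataFrame, pmap: ParcellationMap
) -> pd.Series:
    """Assign each reported edge to left-intra / right-intra / inter-hemispheric."""
    hemi = np.asarray(pmap.hemisphere_of)
    hi, hj = hemi[edges["roi_i"]], hemi[edges["roi_j"]]
    out = np.where(
        hi != hj,
        "inter-hemispheric",
        np.where(hi == "L", "left-intra", "right-intra"),
    )
    return pd.Series(out, index=edges.index, name="hemisphere_class")


def _edge_graph(
    record: PairingRecord, pmap: ParcellationMap, z_threshold: float
) -> pd.DataFrame:
    res = record.result
    fe = res.feature_edges
    order = threshold_edges(res.z_scores, z_threshold)
    i = pmap.edge_index()[fe[order]]
    nets = np.asarray(pmap.network_of)
    ids = np.asarray(pmap.roi_ids)
    return pd.DataFrame(
        {
            "roi_i": i[:, 0],
            "roi_j": i[:, 1],
            "roi_id_i": ids[i[:, 0]],
            "roi_id_j": ids[i[:, 1]],
            "net_i": nets[i[:, 0]],
            "net_j": nets[i[:, 1]],
            "z": res.z_scores[order],
        }
    )


def run_screening(
    tensor: ConnectivityTensor,
    pmap: ParcellationMap,
    analysis_id: str,
    config: ScreeningConfig = ScreeningConfig(),
) -> ScreeningReport:
    """One PLS per network pairing; joint BH-FDR; thresholded edge graphs.

    A pairing whose feature matrix is degenerate (e.g. a single-ROI
    network's empty intra edge set) is recorded with p = 1 and flagged
    rather than dropped, keeping the FDR family size stable.  Each pairing
    uses an independent RNG substream keyed by the analysis and pairing
    labels, so results do not depend on execution order.
    """
    if analysis_id not in ANALYSES:
        raise ValueError(f"unknown analysis {analysis_id!r}; expected one of {ANALYSES}")
    records: list[PairingRecord] = []
    for pairing in enumerate_pairings(pmap):
        try:
            fm = assemble_feature_matrix(tensor, pairing, pmap, analysis_id)
            model = MeanCenteredPLS(fm, permute_scheme=config.permute_scheme)
            res = model.fit(
                n_permutations=config.n_permutations,
                n_bootstraps=config.n_bootstraps,
                rng=substream(config.seed, "pls", analysis_id, pairing.label),
            )
            res.feature_edges = fm.feature_edges  # edge ids for reporting
            records.append(PairingRecord(pairing, res, res.p_value))
        except ValueError as exc:
            logger.warning("pairing %s failed: %s", pairing.label, exc)
            records.append(PairingRecord(pairing, None, 1.0, failed=True))
    p = np.array([r.p_value for r in records])
    report = ScreeningReport(
        analysis_id, records, tuple(config.q_levels), config.z_threshold
    )
    for q in config.q_levels:
        reject, qvals = fdr_bh(p, q)
        for r, qv in zip(records, qvals):
            r.q_value = float(qv)
        report.significant[q] = [
            r.pairing.label for r, rej in zip(records, reject) if rej and not r.failed
        ]
    widest = max(config.q_levels)
    for r in records:
        if r.pairing.label in report.significant[widest] and r.result is not None:
            report.edge_graphs[r.pairing.label] = _edge_graph(r, pmap, config.z_threshold)
    for r in records:
        logger.info(
            "pairing=%s kind=%s p=%.4g q=%.4g", r.pairing.label, r.pairing.kind,
            r.p_value, r.q_value,
        )
    return report
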