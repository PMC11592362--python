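"""Synthetic cohort generator emulating the two-group speech-act fMRI design.

Cohorts mirror the study layout the pipeline targets: two groups (ASD,
TD; 16 and 19 subjects at full scale), two runs per subject, and three
conditions per run with fixed per-condition volume counts (66/55/55 in
run 1, 54/44/44 in run 2 at a 2 s repetition time).  Each subject's
per-condition data are multivariate normal draws from a block-structured
correlation matrix: ``base_within`` inside networks, ``base_between``
across networks, plus

* *mean effects* — a correlation offset on one pairing's edges for a
  chosen (group, condition), producing group-by-condition connectivity
  differences; and
* *idiosyncratic perturbations* — per-subject, per-condition random edge
  offsets (stable across runs) whose SD may differ by group and be
  elevated on chosen pairings, producing group differences in the
  |semantic - pragmatic| idiosyncrasy statistic without any mean shift.

Signals are temporally white by default (distance correlation pairs time
points, so serial structure is not needed for functional tests); an
optional AR(1) coefficient probes the subsampling estimator under serial
dependence.  Perturbed matrices are repaired to positive definiteness by
eigenvalue clipping and re-normalised to unit diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .atlas import NetworkPairing, ParcellationMap
from .connectivity import substream
from .timeseries import CONDITIONS, RunData, SubjectRecord

__all__ = [
    "MeanEffect",
    "IdioEffect",
    "CohortSpec",
    "make_covariance",
    "generate_subject",
    "generate_cohort",
    "build_parcellation",
    "study_spec",
    "scaled_spec",
]

#: per-run condition volume counts of the emulated acquisition
STUDY_RUN_LENGTHS = (
    {"baseline": 66, "semantic": 55, "pragmatic": 55},
    {"baseline": 54, "semantic": 44, "pragmatic": 44},
)


@dataclass(frozen=True)
class MeanEffect:
    """Correlation offset on one pairing's edges for one (group, condition)."""

    pairing: str  # pairing label, e.g. "LH_NetA" or "LH_NetA--RH_NetB"
    group: str
    condition: str
    delta: float


@dataclass(frozen=True)
class IdioEffect:
    """Elevated idiosyncratic-perturbation SD on one pairing's edges for one group."""

    pairing: str
    group: str
    sd: float


@dataclass
class CohortSpec:
    """Design of a synthetic cohort (defaults follow the emulated study)."""

    n_asd: int = 16
    n_td: int = 19
    networks: Sequence[str] = ()
    rois_per_network: int = 5
    run_condition_lengths: Sequence[dict] = STUDY_RUN_LENGTHS
    base_within: float = 0.20
    base_between: float = 0.05
    effects: Sequence[MeanEffect] = ()
    idio_sd_asd: float = 0.05
    idio_sd_td: float = 0.05
    idio_effects: Sequence[IdioEffect] = ()
    ar_coefficient: float = 0.0
    tr_seconds: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.networks:
            self.networks = _default_networks(8)
        self.networks = list(self.networks)
        self.run_condition_lengths = [dict(r) for r in self.run_condition_lengths]
        self.effects = list(self.effects)
        self.idio_effects = list(self.idio_effects)
        if min(self.n_asd, self.n_td) < 1 or self.rois_per_network < 1:
            raise ValueError("counts must be >= 1")
        for v in (self.base_within, self.base_between):
            if abs(v) >= 1:
                raise ValueError("baseline correlations must satisfy |r| < 1")
        if not 0 <= self.ar_coefficient < 1:
            raise ValueError("AR(1) coefficient must be in [0, 1)")

    @property
    def n_rois(self) -> int:
        return len(self.networks) * self.rois_per_network

    def parcellation(self) -> ParcellationMap:
        return build_parcellation(self.networks, self.rois_per_network)

    def group_of(self, index: int) -> str:
        return "ASD" if index < self.n_asd else "TD"

    def subject_ids(self) -> list[str]:
        return [
            f"sub-{'asd' if i < self.n_asd else 'td'}{i if i < self.n_asd else i - self.n_asd:02d}"
            for i in range(self.n_asd + self.n_td)
        ]

    def to_yaml(self, path: str | Path) -> None:
        d = {
            **{
                k: getattr(self, k)
                for k in (
                    "n_asd", "n_td", "rois_per_network", "base_within", "base_between",
                    "idio_sd_asd", "idio_sd_td", "ar_coefficient", "tr_seconds", "seed",
                )
            },
            "networks": list(self.networks),
            "run_condition_lengths": [dict(r) for r in self.run_condition_lengths],
            "effects": [vars(e) for e in self.effects],
            "idio_effects": [vars(e) for e in self.idio_effects],
        }
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortSpec":
        d = yaml.safe_load(Path(path).read_text())
        d["effects"] = [MeanEffect(**e) for e in d.get("effects", [])]
        d["idio_effects"] = [IdioEffect(**e) for e in d.get("idio_effects", [])]
        return cls(**d)


def _default_networks(n: int) -> list[str]:
    half = (n + 1) // 2
    names = [f"LH_Net{chr(65 + i)}" for i in range(half)]
    names += [f"RH_Net{chr(65 + i)}" for i in range(n - half)]
    return names


def build_parcellation(networks: Sequence[str], rois_per_network: int) -> ParcellationMap:
    """Parcellation with ``rois_per_network`` consecutive ROIs per network.

    Hemisphere is taken from the label prefix (``LH_``/``RH_``); unprefixed
    labels default to left.
    """
    roi_ids, nets, hemis = [], [], []
    k = 0
    for net in networks:
        hemi = "R" if str(net).upper().startswith(("RH", "R_")) else "L"
        for _ in range(rois_per_network):
            roi_ids.append(k + 1)  # atlas-native ids are 1-based
            nets.append(str(net))
            hemis.append(hemi)
            k += 1
    return ParcellationMap(roi_ids, nets, hemis)


def _pairing_mask(pmap: ParcellationMap, label: str) -> np.ndarray:
    """Boolean R x R mask of the off-diagonal cells of a pairing's edge set."""
    if "--" in label:
        a, b = sorted(label.split("--"))
        pairing = NetworkPairing(a, b)
    else:
        pairing = NetworkPairing(label, label)
    r = pmap.n_rois
    mask = np.zeros((r, r), dtype=bool)
    ei = pmap.edge_index()[pmap.edge_positions(pairing)]
    mask[ei[:, 0], ei[:, 1]] = True
    return mask | mask.T


def make_covariance(
    spec: CohortSpec,
    subject_index: int,
    group: str,
    condition: str,
    pmap: ParcellationMap | None = None,
) -> np.ndarray:
    """Subject/condition correlation matrix: blocks + effects + idiosyncrasy.

    Deterministic given ``spec.seed`` and the subject index; the
    idiosyncratic perturbation is drawn once per (subject, condition) so it
    is stable across runs — a subject trait that differs between the two
    speech-act conditions, which is what the idiosyncrasy statistic
    measures.  The result is repaired to positive definiteness (eigenvalue
    clip at 1e-6) and re-normalised to unit diagonal.
    """
    pmap = pmap or spec.parcellation()
    r = pmap.n_rois
    nets = np.asarray(pmap.network_of)
    same_net = nets[:, None] == nets[None, :]
    cov = np.where(same_net, spec.base_within, spec.base_between).astype(float)
    np.fill_diagonal(cov, 1.0)

    for eff in spec.effects:
        if eff.group == group and eff.condition == condition:
            cov[_pairing_mask(pmap, eff.pairing)] += eff.delta
    off = cov[~np.eye(r, dtype=bool)]
    if (np.abs(off) >= 1).any():
        raise ValueError(
            "spec implies |correlation| >= 1 before PD repair; reduce effect sizes"
        )

    base_sd = spec.idio_sd_asd if group == "ASD" else spec.idio_sd_td
    sd_matrix = np.full((r, r), base_sd)
    for eff in spec.idio_effects:
        if eff.group == group:
            sd_matrix[_pairing_mask(pmap, eff.pairing)] = eff.sd
    if sd_matrix.max() > 0:
        rng = substream(spec.seed, "idio", subject_index, condition)
        noise = rng.standard_normal((r, r))
        noise = np.triu(noise, 1)
        noise = noise + noise.T
        # random tails are truncated so the perturbed matrix stays a valid
        # correlation matrix; the hard |r| < 1 check above applies only to
        # the deterministic structure
        cov = np.clip(cov + sd_matrix * noise, -0.97, 0.97)
    np.fill_diagonal(cov, 1.0)
    return _repair_pd(cov)


def _repair_pd(cov: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    # re-normalising the diagonal can push the smallest eigenvalue back
    # below the floor, so clip-and-renormalise is iterated to convergence
    fixed = cov
    for _ in range(50):
        w, v = np.linalg.eigh(fixed)
        if w.min() >= floor:
            return fixed
        w = np.clip(w, floor * 1.01, None)
        fixed = (v * w) @ v.T
        d = np.sqrt(np.diag(fixed))
        fixed = fixed / np.outer(d, d)
        np.fill_diagonal(fixed, 1.0)
    raise ValueError("positive-definite repair failed to converge")


def _draw_series(
    n: int, cov: np.ndarray, rng: np.random.Generator, ar: float
) -> np.ndarray:
    L = np.linalg.cholesky(cov)
    z = rng.standard_normal((n, cov.shape[0]))
    if ar > 0:
        for t in range(1, n):
            z[t] = ar * z[t - 1] + np.sqrt(1 - ar**2) * z[t]
    return z @ L.T


def generate_subject(
    spec: CohortSpec,
    subject_index: int,
    pmap: ParcellationMap | None = None,
) -> SubjectRecord:
    """One subject's runs: per-condition Gaussian draws interleaved per run.

    Within a run the conditions appear as contiguous blocks in the fixed
    order baseline, semantic, pragmatic; block lengths come from
    ``spec.run_condition_lengths``.  Fully deterministic given the spec.
    """
    pmap = pmap or spec.parcellation()
    group = spec.group_of(subject_index)
    sid = spec.subject_ids()[subject_index]
    covs = {
        c: make_covariance(spec, subject_index, group, c, pmap) for c in CONDITIONS
    }
    runs = []
    for r, lengths in enumerate(spec.run_condition_lengths):
        blocks, labels = [], []
        for cond in CONDITIONS:
            n = int(lengths[cond])
            rng = substream(spec.seed, "ts", subject_index, r, cond)
            blocks.append(_draw_series(n, covs[cond], rng, spec.ar_coefficient))
            labels += [cond] * n
        runs.append(RunData(np.vstack(blocks), labels, spec.tr_seconds))
    return SubjectRecord(sid, group, runs)


def generate_cohort(
    spec: CohortSpec,
    outdir: str | Path | None = None,
    overwrite: bool = False,
) -> tuple[list[SubjectRecord], ParcellationMap]:
    """All subjects of the cohort; optionally written to disk with a manifest.

    When ``outdir`` is given, each run matrix and label vector is written in
    the canonical tab-separated formats together with ``atlas.tsv`` and
    ``manifest.tsv``, ready for the file-based pipeline.
    """
    pmap = spec.parcellation()
    cohort = [
        generate_subject(spec, i, pmap) for i in range(spec.n_asd + spec.n_td)
    ]
    if outdir is not None:
        outdir = Path(outdir)
        if outdir.exists() and any(outdir.iterdir()) and not overwrite:
            raise FileExistsError(f"{outdir} exists and is not empty")
        outdir.mkdir(parents=True, exist_ok=True)
        pmap.save(outdir / "atlas.tsv")
        rows = []
        for subj in cohort:
            for r, run in enumerate(subj.runs):
                ts = f"{subj.subject_id}_run-{r + 1}_timeseries.tsv"
                lb = f"{subj.subject_id}_run-{r + 1}_labels.txt"
                np.savetxt(outdir / ts, run.data, delimiter="\t", fmt="%.8g")
                (outdir / lb).write_text("\n".join(run.labels) + "\n")
                rows.append(
                    {
                        "subject_id": subj.subject_id,
                        "group": subj.group,
                        "run": r,
                        "timeseries": ts,
                        "labels": lb,
                    }
                )
        pd.DataFrame(rows).to_csv(outdir / "manifest.tsv", sep="\t", index=False)
        spec.to_yaml(outdir / "cohort_spec.yaml")
    return cohort, pmap


def study_spec(**overrides) -> CohortSpec:
    """Full-scale study design: 16 + 19 subjects, study run lengths."""
    return CohortSpec(**{"n_asd": 16, "n_td": 19, **overrides})


def scaled_spec(**overrides) -> CohortSpec:
    """Desk-scale test design: 8 networks x 5 ROIs, 6 + 6 subjects."""
    return CohortSpec(
        **{
            "n_asd": 6,
            "n_td": 6,
            "networks": _default_networks(8),
            "rois_per_network": 5,
            **overrides,
        }
    )
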