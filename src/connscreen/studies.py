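"""Simulation studies validating calibration and parameter recovery.

These are the package's standard self-checks, each a complete
generate -> estimate -> screen experiment on synthetic cohorts:

* ``null_pvalue_study`` — permutation p-values of a designated pairing
  over many independent null cohorts; should be uniform when the
  permutation scheme's exchangeability assumption matches the design
  (rows for the one-row-per-subject idiosyncrasy design, whole-subject
  permutation for the paired group-by-condition design).
* ``fdr_calibration_study`` — proportion of 5%-FDR-significant pairings
  under a fully null cohort; Benjamini-Hochberg should keep its mean at
  or below the nominal level.
* ``gbc_recovery_study`` — a planted condition-specific connectivity
  increase in one group on one network pairing; the screen should rank
  that pairing at the family's minimum p.
* ``idio_recovery_study`` — one group gets 3x the idiosyncratic
  perturbation SD on one pairing, with no mean effect; the idiosyncrasy
  screen should flag that pairing at 10% FDR with an ASD > TD contrast.
* ``determinism_study`` — the file-based pipeline rerun with the same
  seed must produce byte-identical reports.

Problem sizes are desk-scale: recovery studies use the full study group
sizes (16 + 19) on an 8-network x 5-ROI atlas; calibration studies use
smaller cohorts so many independent replicates stay cheap.  All seeds
derive from a single ``base_seed``.
"""

from __future__ import annotations

import filecmp
from pathlib import Path

import numpy as np

from .cli import PipelineConfig, run_pipeline
from .connectivity import SubsampleConfig, compute_connectivity_tensor
from .screening import ScreeningConfig, run_screening
from .synthgen import CohortSpec, IdioEffect, MeanEffect, generate_cohort, scaled_spec

__all__ = [
    "PLANTED_PAIRING",
    "null_pvalue_study",
    "fdr_calibration_study",
    "gbc_recovery_study",
    "idio_recovery_study",
    "determinism_study",
]

PLANTED_PAIRING = "LH_NetA--LH_NetB"


def _tiny_null_spec(seed: int) -> CohortSpec:
    return CohortSpec(
        n_asd=5,
        n_td=5,
        networks=["LH_NetA", "RH_NetB"],
        rois_per_network=3,
        seed=seed,
    )


def null_pvalue_study(
    n_datasets: int = 200,
    base_seed: int = 0,
    analysis: str = "idiosyncrasy",
    permute_scheme: str = "rows",
    n_permutations: int = 200,
    reps: int = 20,
) -> np.ndarray:
    """Inter-network-pairing p-values over independent null cohorts."""
    ps = np.empty(n_datasets)
    for k in range(n_datasets):
        seed = base_seed + 100_000 + k
        cohort, pmap = generate_cohort(_tiny_null_spec(seed))
        tensor = compute_connectivity_tensor(
            cohort, pmap, SubsampleConfig(m=30, reps=reps, seed=seed)
        )
        rep = run_screening(
            tensor,
            pmap,
            analysis,
            ScreeningConfig(
                n_permutations=n_permutations,
                n_bootstraps=2,
                permute_scheme=permute_scheme,
                seed=seed,
            ),
        )
        ps[k] = next(r.p_value for r in rep.records if r.pairing.kind == "inter")
    return ps


def fdr_calibration_study(
    n_seeds: int = 20,
    base_seed: int = 0,
    q: float = 0.05,
    n_permutations: int = 200,
    reps: int = 25,
) -> dict[str, np.ndarray]:
    """Per-seed proportion of q-level-FDR-significant pairings, fully null cohorts."""
    out = {"group_by_condition": np.empty(n_seeds), "idiosyncrasy": np.empty(n_seeds)}
    for k in range(n_seeds):
        seed = base_seed + 200_000 + k
        spec = scaled_spec(seed=seed)
        cohort, pmap = generate_cohort(spec)
        tensor = compute_connectivity_tensor(
            cohort, pmap, SubsampleConfig(m=30, reps=reps, seed=seed)
        )
        for analysis in out:
            rep = run_screening(
                tensor,
                pmap,
                analysis,
                ScreeningConfig(n_permutations=n_permutations, n_bootstraps=2, seed=seed),
            )
            out[analysis][k] = len(rep.significant[q]) / len(rep.records)
    return out


def gbc_recovery_study(
    n_seeds: int = 20,
    base_seed: int = 0,
    delta: float = 0.3,
    n_permutations: int = 200,
    reps: int = 50,
) -> dict:
    """Planted group-by-condition effect: is the pairing the family's minimum p?"""
    effect = MeanEffect(
        pairing=PLANTED_PAIRING, group="ASD", condition="semantic", delta=delta
    )
    hits, pvals = [], []
    for k in range(n_seeds):
        seed = base_seed + 300_000 + k
        spec = scaled_spec(n_asd=16, n_td=19, effects=[effect], seed=seed)
        cohort, pmap = generate_cohort(spec)
        tensor = compute_connectivity_tensor(
            cohort, pmap, SubsampleConfig(m=30, reps=reps, seed=seed)
        )
        rep = run_screening(
            tensor,
            pmap,
            "group_by_condition",
            ScreeningConfig(n_permutations=n_permutations, n_bootstraps=50, seed=seed),
        )
        p = {r.pairing.label: r.p_value for r in rep.records}
        hits.append(p[PLANTED_PAIRING] == min(p.values()))
        pvals.append(p[PLANTED_PAIRING])
    return {"hits": np.array(hits), "p_values": np.array(pvals)}


def idio_recovery_study(
    n_seeds: int = 20,
    base_seed: int = 0,
    sd_hi: float = 0.30,
    sd_lo: float = 0.10,
    n_permutations: int = 1000,
    reps: int = 100,
) -> dict:
    """Planted 3x idiosyncrasy SD: pairing significant at 10% FDR, ASD > TD."""
    idio = IdioEffect(pairing=PLANTED_PAIRING, group="ASD", sd=sd_hi)
    hits, pvals, asd_gt = [], [], []
    for k in range(n_seeds):
        seed = base_seed + 400_000 + k
        spec = scaled_spec(
            n_asd=16, n_td=19, idio_sd_asd=sd_lo, idio_sd_td=sd_lo,
            idio_effects=[idio], seed=seed,
        )
        cohort, pmap = generate_cohort(spec)
        tensor = compute_connectivity_tensor(
            cohort, pmap, SubsampleConfig(m=30, reps=reps, seed=seed)
        )
        rep = run_screening(
            tensor,
            pmap,
            "idiosyncrasy",
            ScreeningConfig(n_permutations=n_permutations, n_bootstraps=200, seed=seed),
        )
        rec = next(r for r in rep.records if r.pairing.label == PLANTED_PAIRING)
        contrast_ok = rec.result.contrast[0] > rec.result.contrast[1]  # cells (ASD, TD)
        hits.append(PLANTED_PAIRING in rep.significant[0.10] and contrast_ok)
        pvals.append(rec.p_value)
        asd_gt.append(contrast_ok)
    return {"hits": np.array(hits), "p_values": np.array(pvals), "asd_gt": np.array(asd_gt)}


def determinism_study(workdir: str | Path, base_seed: int = 0) -> bool:
    """Run the full file-based pipeline twice; True iff reports are byte-identical."""
    workdir = Path(workdir)
    data = workdir / "cohort"
    spec = scaled_spec(seed=base_seed + 500_000)
    generate_cohort(spec, data, overwrite=True)
    reports = [
        "report_group_by_condition.json",
        "report_idiosyncrasy.json",
        "pairings_group_by_condition.tsv",
        "pairings_idiosyncrasy.tsv",
    ]
    for rundir in ("run_a", "run_b"):
        config = PipelineConfig(
            manifest=str(data / "manifest.tsv"),
            atlas=str(data / "atlas.tsv"),
            out=str(workdir / rundir),
            reps=10,
            n_permutations=50,
            n_bootstraps=50,
            seed=base_seed + 500_000,
        )
        if run_pipeline(config) != 0:
            return False
    return all(
        filecmp.cmp(workdir / "run_a" / n, workdir / "run_b" / n, shallow=False)
        for n in reports
    )
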