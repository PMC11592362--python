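"""Cortical parcellation model: ROI -> (hemisphere, network) lookup and network pairings.

A parcellation assigns each region of interest (ROI) to one functional
network within one hemisphere.  Homologous left/right networks are kept
distinct, so a 17-networks-per-hemisphere atlas yields 34 network labels.
Every unordered pair of ROIs (an "edge") then belongs to exactly one
*network pairing*: either the intra-pairing of a single network or the
inter-pairing of two distinct networks.  Pairings are the unit over which
PLS screening analyses run: n networks give n intra + n(n-1)/2 inter
pairings (34 -> 34 + 561 = 595).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "ParcellationMap",
    "NetworkPairing",
    "load_parcellation",
    "enumerate_pairings",
    "convert_schaefer_order",
]

_HEMI_TOKENS = {"L": "L", "LH": "L", "LEFT": "L", "R": "R", "RH": "R", "RIGHT": "R"}


@dataclass(frozen=True)
class NetworkPairing:
    """One intra- or inter-network pairing; inter pairings are canonically ordered."""

    net_a: str
    net_b: str

    @property
    def kind(self) -> str:
        return "intra" if self.net_a == self.net_b else "inter"

    @property
    def label(self) -> str:
        return self.net_a if self.kind == "intra" else f"{self.net_a}--{self.net_b}"

    def __post_init__(self) -> None:
        if self.net_a > self.net_b:
            raise ValueError(
                f"inter pairing must be in canonical order: {self.net_a!r} > {self.net_b!r}"
            )


class ParcellationMap:
    """ROI -> network/hemisphere lookup defining the pairing space.

    Parameters
    ----------
    roi_ids
        Atlas-native integer ROI identifiers, in file order.  Internally
        ROIs are addressed 0-based by position; ``roi_ids`` is kept for
        labelling outputs.
    networks
        Hemisphere-qualified network label per ROI (e.g. ``"LH_SomMotB"``).
    hemispheres
        ``"L"`` or ``"R"`` per ROI.
    """

    def __init__(
        self,
        roi_ids: Iterable[int],
        networks: Iterable[str],
        hemispheres: Iterable[str],
    ) -> None:
        self.roi_ids = [int(r) for r in roi_ids]
        self.network_of = list(networks)
        self.hemisphere_of = [str(h) for h in hemispheres]
        if not self.roi_ids:
            raise ValueError("parcellation is empty")
        if len(set(self.roi_ids)) != len(self.roi_ids):
            dupes = sorted({r for r in self.roi_ids if self.roi_ids.count(r) > 1})
            raise ValueError(f"duplicate roi_id values: {dupes}")
        if not (len(self.roi_ids) == len(self.network_of) == len(self.hemisphere_of)):
            raise ValueError("roi_ids, networks and hemispheres must have equal length")
        bad = sorted({h for h in self.hemisphere_of if h not in ("L", "R")})
        if bad:
            raise ValueError(f"unknown hemisphere token(s): {bad}")
        # distinct labels in first-appearance order; stable across calls
        seen: dict[str, None] = {}
        for n in self.network_of:
            seen.setdefault(n, None)
        self.networks: list[str] = list(seen)

    @property
    def n_rois(self) -> int:
        return len(self.roi_ids)

    @property
    def n_networks(self) -> int:
        return len(self.networks)

    def rois_in(self, network: str) -> np.ndarray:
        """0-based ROI positions belonging to ``network``."""
        return np.flatnonzero(np.asarray(self.network_of) == network)

    def edge_index(self) -> np.ndarray:
        """All unordered ROI position pairs (i < j), row-major canonical order.

        Row k of the returned ``(n_edges, 2)`` array is edge k everywhere in
        the pipeline: connectivity tensors, feature matrices and reports all
        share this ordering.
        """
        r = self.n_rois
        iu = np.triu_indices(r, k=1)
        return np.column_stack(iu)

    def edge_positions(self, pairing: NetworkPairing) -> np.ndarray:
        """Indices (into the canonical edge list) of the pairing's edge set."""
        nets = np.asarray(self.network_of)
        i, j = self.edge_index().T
        if pairing.kind == "intra":
            mask = (nets[i] == pairing.net_a) & (nets[j] == pairing.net_a)
        else:
            mask = ((nets[i] == pairing.net_a) & (nets[j] == pairing.net_b)) | (
                (nets[i] == pairing.net_b) & (nets[j] == pairing.net_a)
            )
        return np.flatnonzero(mask)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "roi_id": self.roi_ids,
                "network": self.network_of,
                "hemisphere": self.hemisphere_of,
            }
        )

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def load_parcellation(path: str | Path) -> ParcellationMap:
    """Read a tab-separated atlas lookup table (roi_id, network, hemisphere).

    ROI order in the file defines the column order expected of every
    time-series matrix downstream.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"roi_id", "network", "hemisphere"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    if df.empty:
        raise ValueError(f"{path}: empty lookup table")
    hemis = []
    for h in df["hemisphere"].astype(str):
        token = h.strip().upper()
        if token not in _HEMI_TOKENS:
            raise ValueError(f"{path}: unknown hemisphere token {h!r}")
        hemis.append(_HEMI_TOKENS[token])
    return ParcellationMap(df["roi_id"].tolist(), df["network"].astype(str).tolist(), hemis)


def enumerate_pairings(pmap: ParcellationMap) -> list[NetworkPairing]:
    """All network pairings in deterministic canonical order.

    Intra pairings first (atlas network order), then inter pairings sorted
    lexicographically on (net_a, net_b).  Total is n + n(n-1)/2.
    """
    nets = pmap.networks
    intra = [NetworkPairing(n, n) for n in nets]
    inter = sorted(
        (NetworkPairing(*sorted((a, b))) for k, a in enumerate(nets) for b in nets[k + 1 :]),
        key=lambda p: (p.net_a, p.net_b),
    )
    return intra + inter


_SCHAEFER_LABEL = re.compile(r"^17Networks_(LH|RH)_([A-Za-z0-9]+)_")


def convert_schaefer_order(path: str | Path, out: str | Path) -> ParcellationMap:
    """Convert a Schaefer "order" lookup file to the canonical atlas format.

    The published dialect has an integer index and a label string such as
    ``17Networks_LH_SomMotB_Cent_1`` encoding hemisphere and network.  The
    converted table keeps hemisphere-qualified labels (``LH_SomMotB``) so
    left/right homologues stay distinct.
    """
    df = pd.read_csv(path, sep="\t", header=None)
    roi_ids, networks, hemis = [], [], []
    for _, row in df.iterrows():
        label = str(row[1])
        m = _SCHAEFER_LABEL.match(label)
        if not m:
            raise ValueError(f"unrecognised Schaefer label: {label!r}")
        hemi = "L" if m.group(1) == "LH" else "R"
        roi_ids.append(int(row[0]))
        networks.append(f"{m.group(1)}_{m.group(2)}")
        hemis.append(hemi)
    pmap = ParcellationMap(roi_ids, networks, hemis)
    pmap.save(out)
    return pmap
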