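"""Percentage of conserved proteins (POCP) and taxonomic rank delineation.

For genomes i and j with T_i, T_j total proteins and C_i, C_j proteins of
each genome assigned to orthogroups containing both,

    POCP(i, j) = 100 * (C_i + C_j) / (T_i + T_j).

Rank thresholds follow the fungal-symbiont calibration: pairs sharing fewer
than 91% of their proteins sit in different genera; 91-95% delineates
distinct species within a genus; 95% and above marks strains of one species.
The 87-91% genus band is carried along for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from .io import OrthologySummary

__all__ = ["PocpThresholds", "PocpTable", "compute_pocp", "classify_pairs", "pocp_heatmap_order"]

RANKS = ("inter_genus", "intra_genus_inter_species", "intra_species")


@dataclass
class PocpThresholds:
    genus_cut: float = 91.0
    species_cut: float = 95.0
    genus_band: tuple[float, float] = (87.0, 91.0)  # reporting only

    def __post_init__(self) -> None:
        if not self.genus_cut < self.species_cut:
            raise ValueError("genus_cut must be below species_cut")

    def call(self, p: float) -> str:
        """Half-open boundary convention: P < genus_cut strictly inter-genus."""
        if p < self.genus_cut:
            return "inter_genus"
        if p < self.species_cut:
            return "intra_genus_inter_species"
        return "intra_species"


@dataclass
class PocpTable:
    matrix: pd.DataFrame  # symmetric, diagonal 100
    orthogroup_units: bool = False

    def __post_init__(self) -> None:
        m = self.matrix.to_numpy(dtype=float)
        if not np.allclose(m, m.T):
            raise ValueError("POCP matrix must be symmetric")
        if not np.allclose(np.diag(m), 100.0):
            raise ValueError("POCP diagonal must be 100")


def compute_pocp(orthology: OrthologySummary, orthogroup_units: bool = False) -> PocpTable:
    """Pairwise conserved-protein percentages from an orthology summary.

    ``orthogroup_units=True`` switches the shared counts to be interpreted as
    counts of shared orthogroups on both sides (same formula, different
    units); the default per-protein units match the formula's C/T dimensions.
    """
    ids = orthology.genome_ids
    m = pd.DataFrame(100.0, index=ids, columns=ids, dtype=float)
    for a_i, a in enumerate(ids):
        for b in ids[a_i + 1:]:
            ca, cb = orthology.shared[(a, b)], orthology.shared[(b, a)]
            if orthogroup_units:
                ca = cb = min(ca, cb)
            p = 100.0 * (ca + cb) / (orthology.totals[a] + orthology.totals[b])
            m.loc[a, b] = m.loc[b, a] = p
    return PocpTable(matrix=m, orthogroup_units=orthogroup_units)


def classify_pairs(table: PocpTable, thresholds: PocpThresholds | None = None) -> pd.DataFrame:
    """Rank call per unordered genome pair."""
    thresholds = thresholds or PocpThresholds()
    ids = list(table.matrix.index)
    rows = []
    for a_i, a in enumerate(ids):
        for b in ids[a_i + 1:]:
            p = float(table.matrix.loc[a, b])
            rows.append(
                {
                    "genome_i": a,
                    "genome_j": b,
                    "pocp": p,
                    "rank_call": thresholds.call(p),
                    "in_genus_band": thresholds.genus_band[0] <= p < thresholds.genus_band[1],
                }
            )
    return pd.DataFrame(rows)


def pocp_heatmap_order(table: PocpTable) -> tuple[list[str], np.ndarray]:
    """Average-linkage clustering on distance 100 - P; deterministic leaf order.

    Returns (ordered labels, scipy linkage matrix).
    """
    ids = list(table.matrix.index)
    dist = 100.0 - table.matrix.to_numpy(dtype=float)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, None)
    z = linkage(squareform(dist, checks=False), method="average")
    order = [ids[i] for i in leaves_list(z)]
    return order, z
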