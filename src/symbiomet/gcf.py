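"""Gene cluster families: fragment curation, clustering, and the
presence/absence matrix with its ecological summaries.

The pairwise BGC distance is a documented surrogate for full architectural
similarity scoring:

    d(a, b) = 1 - [w_j * J(labels) + w_a * J(adjacent label pairs)]

where both J terms are Jaccard indices (of gene function-label sets, and of
orientation-insensitive adjacent-label pairs).  Families are the connected
components of the graph with edges d <= cutoff (single linkage), so the
result is deterministic and invariant to input order; singleton BGCs form
singleton families.  An externally computed distance matrix can be supplied
instead.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import DisjointSet
from scipy.special import gammaln

from .io import Assembly, BgcRecord

__all__ = [
    "CurationDirectives",
    "curate_fragments",
    "GcfConfig",
    "GeneClusterFamily",
    "bgc_distance",
    "cluster_gcfs",
    "build_presence_absence",
    "rank_abundance",
    "rarefaction",
]


# ---------------------------------------------------------------------------
# fragment curation
# ---------------------------------------------------------------------------

@dataclass
class CurationDirectives:
    merges: list[tuple[str, str]] = field(default_factory=list)
    splits: list[tuple[str, int]] = field(default_factory=list)  # (bgc_id, breakpoint gene index)
    auto_suggest: bool = False
    apply_suggestions: bool = False
    edge_distance: int = 1000
    suggest_coverage: float = 0.8
    max_label_overlap: int = 0  # merging fragments whose label sets overlap more is an error


def _near_contig_edge(bgc: BgcRecord, assemblies: dict[str, Assembly], edge_distance: int) -> bool:
    asm = assemblies.get(bgc.genome_id)
    if asm is None or bgc.contig_id not in asm.contigs:
        return False
    contig_len = len(asm.contigs[bgc.contig_id])
    return bgc.start < edge_distance or bgc.end > contig_len - edge_distance


def _merge_records(a: BgcRecord, b: BgcRecord) -> BgcRecord:
    cls = a.bgc_class if a.bgc_class == b.bgc_class else "hybrid"
    return BgcRecord(
        bgc_id=f"{a.bgc_id}+{b.bgc_id}",
        genome_id=a.genome_id,
        contig_id=a.contig_id,
        start=a.start,
        end=a.end,
        bgc_class=cls,
        genes=list(a.genes) + list(b.genes),
    )


def curate_fragments(
    bgcs: list[BgcRecord],
    assemblies: dict[str, Assembly] | None = None,
    directives: CurationDirectives | None = None,
) -> tuple[list[BgcRecord], list[dict]]:
    """Apply explicit merge/split directives; optionally suggest merges.

    Auto-suggestion proposes merging two same-genome contig-edge fragments
    whose disjoint gene-label sets jointly cover at least
    ``suggest_coverage`` of some other genome's single BGC.  Suggestions are
    only applied when ``apply_suggestions`` is set; otherwise they appear in
    the log as proposals.
    """
    directives = directives or CurationDirectives()
    assemblies = assemblies or {}
    by_id = {b.bgc_id: b for b in bgcs}
    if len(by_id) != len(bgcs):
        raise ValueError("duplicate bgc_ids in input")
    log: list[dict] = []
    consumed: set[str] = set()

    def take(bgc_id: str) -> BgcRecord:
        if bgc_id in consumed:
            raise ValueError(f"directive references already-consumed BGC {bgc_id!r}")
        if bgc_id not in by_id:
            raise ValueError(f"directive references unknown BGC {bgc_id!r}")
        return by_id[bgc_id]

    for id_a, id_b in directives.merges:
        a, b = take(id_a), take(id_b)
        overlap = a.function_labels & b.function_labels
        if len(overlap) > directives.max_label_overlap:
            raise ValueError(
                f"merge {id_a}+{id_b}: label sets overlap ({sorted(overlap)})"
            )
        merged = _merge_records(a, b)
        consumed.update((id_a, id_b))
        by_id[merged.bgc_id] = merged
        log.append({"action": "merge", "inputs": [id_a, id_b], "output": merged.bgc_id})

    for bgc_id, breakpoint in directives.splits:
        bgc = take(bgc_id)
        if not 0 < breakpoint < len(bgc.genes):
            raise ValueError(
                f"split {bgc_id}: breakpoint {breakpoint} outside (0, {len(bgc.genes)})"
            )
        parts = []
        for k, genes in enumerate((bgc.genes[:breakpoint], bgc.genes[breakpoint:]), 1):
            part = BgcRecord(
                bgc_id=f"{bgc_id}.{k}",
                genome_id=bgc.genome_id,
                contig_id=bgc.contig_id,
                start=bgc.start,
                end=bgc.end,
                bgc_class=bgc.bgc_class,
                genes=list(genes),
            )
            by_id[part.bgc_id] = part
            parts.append(part.bgc_id)
        consumed.add(bgc_id)
        log.append({"action": "split", "inputs": [bgc_id], "output": parts, "breakpoint": breakpoint})

    if directives.auto_suggest:
        current = [b for bid, b in by_id.items() if bid not in consumed]
        edge = [b for b in current if _near_contig_edge(b, assemblies, directives.edge_distance)]
        suggested: list[tuple[str, str]] = []
        for a, b in itertools.combinations(edge, 2):
            if a.genome_id != b.genome_id or a.contig_id == b.contig_id:
                continue
            if a.function_labels & b.function_labels:
                continue
            union = a.function_labels | b.function_labels
            for ref in current:
                if ref.genome_id == a.genome_id:
                    continue
                ref_labels = ref.function_labels
                if not ref_labels:
                    continue
                coverage = len(union & ref_labels) / len(ref_labels)
                if coverage >= directives.suggest_coverage:
                    suggested.append((a.bgc_id, b.bgc_id))
                    log.append(
                        {
                            "action": "suggest_merge",
                            "inputs": [a.bgc_id, b.bgc_id],
                            "reference": ref.bgc_id,
                            "coverage": coverage,
                            "applied": directives.apply_suggestions,
                        }
                    )
                    break
        if directives.apply_suggestions:
            for id_a, id_b in suggested:
                if id_a in consumed or id_b in consumed:
                    continue
                merged = _merge_records(by_id[id_a], by_id[id_b])
                consumed.update((id_a, id_b))
                by_id[merged.bgc_id] = merged
                log.append({"action": "merge", "inputs": [id_a, id_b], "output": merged.bgc_id})

    curated = [b for bid, b in by_id.items() if bid not in consumed]
    return curated, log


# ---------------------------------------------------------------------------
# distance + clustering
# ---------------------------------------------------------------------------

@dataclass
class GcfConfig:
    distance_cutoff: float = 0.5
    w_jaccard: float = 0.5
    w_adjacency: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.distance_cutoff <= 1.0:
            raise ValueError("cutoff must lie in [0, 1]")
        if abs(self.w_jaccard + self.w_adjacency - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")


@dataclass
class GeneClusterFamily:
    gcf_id: str
    member_bgc_ids: list[str]
    modal_class: str
    representative_bgc_id: str


def _jaccard(a: frozenset, b: frozenset) -> float:
    if not a and not b:
        return 1.0  # two empty sets are identical
    union = len(a | b)
    return len(a & b) / union if union else 1.0


def bgc_distance(a: BgcRecord, b: BgcRecord, config: GcfConfig | None = None) -> float:
    """Surrogate architectural distance in [0, 1]; 0 for identical clusters."""
    config = config or GcfConfig()
    j = _jaccard(a.function_labels, b.function_labels)
    adj = _jaccard(a.adjacency_pairs, b.adjacency_pairs)
    return 1.0 - (config.w_jaccard * j + config.w_adjacency * adj)


def cluster_gcfs(
    bgcs: list[BgcRecord],
    config: GcfConfig | None = None,
    distances: pd.DataFrame | None = None,
) -> list[GeneClusterFamily]:
    """Connected components of the BGC graph at the distance cutoff.

    ``distances`` may carry an externally computed symmetric distance matrix
    indexed by bgc_id; otherwise the surrogate metric is used.  Family ids
    are assigned by sorting components on their smallest member bgc_id, so
    output is invariant to input order.
    """
    config = config or GcfConfig()
    ids = [b.bgc_id for b in bgcs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate bgc_ids")
    by_id = {b.bgc_id: b for b in bgcs}
    ds = DisjointSet(ids)
    for a, b in itertools.combinations(bgcs, 2):
        if distances is not None:
            d = float(distances.loc[a.bgc_id, b.bgc_id])
        else:
            d = bgc_distance(a, b, config)
        if d <= config.distance_cutoff:
            ds.merge(a.bgc_id, b.bgc_id)
    components = sorted((sorted(sub) for sub in ds.subsets()), key=lambda s: s[0])
    families = []
    width = max(4, len(str(len(components))))
    for k, members in enumerate(components, 1):
        classes = sorted(by_id[m].bgc_class for m in members)
        modal = max(set(classes), key=lambda c: (classes.count(c), c))
        rep = max(members, key=lambda m: (by_id[m].length, m))
        families.append(
            GeneClusterFamily(
                gcf_id=f"GCF{k:0{width}d}",
                member_bgc_ids=members,
                modal_class=modal,
                representative_bgc_id=rep,
            )
        )
    return families


# ---------------------------------------------------------------------------
# presence/absence and summaries
# ---------------------------------------------------------------------------

def build_presence_absence(
    families: list[GeneClusterFamily],
    bgcs: list[BgcRecord],
    strains: list[str] | None = None,
) -> pd.DataFrame:
    """strains x families binary matrix; 1 iff the strain contributes a BGC."""
    genome_of = {b.bgc_id: b.genome_id for b in bgcs}
    all_strains = strains if strains is not None else sorted({b.genome_id for b in bgcs})
    unknown = {genome_of[m] for f in families for m in f.member_bgc_ids} - set(all_strains)
    if unknown:
        raise ValueError(f"BGCs from strains not in the strain list: {sorted(unknown)}")
    mat = pd.DataFrame(
        0, index=all_strains, columns=[f.gcf_id for f in families], dtype="int8"
    )
    for fam in families:
        for m in fam.member_bgc_ids:
            mat.loc[genome_of[m], fam.gcf_id] = 1
    return mat


def rank_abundance(matrix: pd.DataFrame) -> pd.DataFrame:
    """Family occurrence spectrum: for each family, in how many strains it
    occurs; sorted descending (rank-abundance plot data)."""
    occ = matrix.sum(axis=0).astype(int)
    out = (
        occ.sort_values(ascending=False, kind="stable")
        .rename("occurrence")
        .rename_axis("family")
        .reset_index()
    )
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def occurrence_spectrum(matrix: pd.DataFrame) -> dict[int, int]:
    """k -> number of families present in exactly k strains (k >= 1)."""
    occ = matrix.sum(axis=0).astype(int)
    out: dict[int, int] = {}
    for k in occ[occ > 0]:
        out[int(k)] = out.get(int(k), 0) + 1
    return dict(sorted(out.items()))


def _log_comb(n: np.ndarray, k: int) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def rarefaction(
    matrix: pd.DataFrame,
    groups: dict[str, list[str]] | None = None,
    with_variance: bool = True,
) -> pd.DataFrame:
    """Exact sample-based rarefaction per group of strains.

    With N strains in the group and family f present in N_f of them, the
    expected richness of a uniform random subset of n strains is

        E[S(n)] = sum_f 1 - C(N - N_f, n) / C(N, n),

    with the exact variance from the pairwise joint absence probabilities
    C(N - |supp_f u supp_g|, n) / C(N, n).  The curve is concave,
    non-decreasing, and ends at the observed richness.
    """
    import math

    if groups is None:
        groups = {"all": list(matrix.index)}
    rows = []
    for gname, strains in groups.items():
        if not strains:
            raise ValueError(f"group {gname!r} is empty")
        sub = matrix.loc[strains]
        supports = [frozenset(sub.index[sub[c] == 1]) for c in sub.columns]
        supports = [s for s in supports if s]
        n_total = len(strains)
        for n in range(1, n_total + 1):
            denom = math.comb(n_total, n)
            q = np.array([math.comb(n_total - len(s), n) / denom for s in supports])
            expected = float(np.sum(1.0 - q))
            var = float("nan")
            if with_variance:
                var = float(np.sum(q * (1.0 - q)))
                for (i, si), (j, sj) in itertools.combinations(enumerate(supports), 2):
                    q_ij = math.comb(n_total - len(si | sj), n) / denom
                    var += 2.0 * (q_ij - q[i] * q[j])
            rows.append(
                {
                    "group": gname,
                    "n_strains": n,
                    "expected_richness": expected,
                    "variance": var,
                }
            )
    return pd.DataFrame(rows)
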