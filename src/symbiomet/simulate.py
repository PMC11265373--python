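"""Synthetic data with the statistical structure the downstream analyses assume.

Every generator is driven by a single integer seed through numpy's
``SeedSequence`` spawning, so identical configurations give byte-identical
outputs.  Each fixture carries a machine-readable ground truth (``SimTruth``)
sufficient to score the module that consumes it: true node states and
gain/loss events for the ancestral-state reconstruction, planted telomere
copies and RIP-mutated spans for the genome screens, and target conserved-
protein percentages for the POCP formula.

The binary-trait generator evolves each pathway independently down the tree
as a two-state continuous-time Markov chain with gain rate g (0->1) and loss
rate l (1->0); over a branch of length t,

    P(0->1) = g/(g+l) * (1 - exp(-(g+l) t)),
    P(1->0) = l/(g+l) * (1 - exp(-(g+l) t)),

the exact matrix-exponential transition probabilities, so no event-time
discretisation error enters.  Gain/loss events are defined as parent->child
state changes.
"""

from __future__ import annotations

import random as _random
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .io import Assembly, GeneAnnotation, GeneRecord, OrthologySummary
from .tree import Node, Phylogeny

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_tree",
    "evolve_binary_traits",
    "synth_assembly",
    "synth_orthology",
    "emit_bgcs_from_traits",
]

TELOMERE_MOTIF = "TTAGGG"
TELOMERE_MOTIF_RC = "CCCTAA"

#: Default BGC class mix, the observed secondary-metabolite class frequencies
#: in attine-ant fungal symbionts (NRPS, PKS, terpene, hybrid, betalactone,
#: other), renormalised to sum to one.
DEFAULT_CLASS_MIX = {
    "NRPS": 0.287,
    "PKS": 0.256,
    "terpene": 0.213,
    "hybrid": 0.163,
    "betalactone": 0.024,
    "other": 0.036,
}
_mix_total = sum(DEFAULT_CLASS_MIX.values())
DEFAULT_CLASS_MIX = {k: v / _mix_total for k, v in DEFAULT_CLASS_MIX.items()}

#: Observed range of per-genome protein-coding gene counts in the symbionts.
GENE_COUNT_RANGE = (6477, 7693)


@dataclass
class SimConfig:
    seed: int = 0
    n_strains: int = 12
    birth_rate: float = 1.0
    death_rate: float = 0.2
    n_pathways: int = 40
    gain_rate: float = 0.02
    loss_rate: float = 0.05
    root_presence_prob: float | None = None  # None -> stationary g/(g+l)
    class_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    total_range: tuple[int, int] = GENE_COUNT_RANGE
    max_tree_attempts: int = 100

    def __post_init__(self) -> None:
        if self.birth_rate <= self.death_rate or self.death_rate < 0:
            raise ValueError("require birth_rate > death_rate >= 0")
        if self.gain_rate < 0 or self.loss_rate < 0:
            raise ValueError("transition rates must be non-negative")
        if abs(sum(self.class_mix.values()) - 1.0) > 1e-9:
            raise ValueError("class_mix must sum to 1")

    @property
    def effective_root_presence(self) -> float:
        if self.root_presence_prob is not None:
            return self.root_presence_prob
        denom = self.gain_rate + self.loss_rate
        return self.gain_rate / denom if denom > 0 else 0.0


@dataclass
class SimTruth:
    """Ground truth planted by the generators."""

    tree: Phylogeny | None = None
    node_states: dict[str, dict[str, int]] = field(default_factory=dict)  # pathway -> node_id -> state
    gain_nodes: dict[str, list[str]] = field(default_factory=dict)
    loss_nodes: dict[str, list[str]] = field(default_factory=dict)
    telomere_copies: dict[str, tuple[int, int]] = field(default_factory=dict)  # contig -> (left, right)
    rip_spans: dict[str, list[tuple[int, int]]] = field(default_factory=dict)  # contig -> 0-based spans
    gene_coords: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    pocp_targets: dict[tuple[str, str], float] = field(default_factory=dict)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


# ---------------------------------------------------------------------------
# species tree
# ---------------------------------------------------------------------------

def simulate_tree(config: SimConfig) -> Phylogeny:
    """Birth-death species tree conditioned on exactly ``n_strains`` extant tips.

    Simulation is delegated to dendropy's forward birth-death sampler
    (simulate-and-reject on extinction), then converted and relabelled with
    deterministic strain ids S01..Sn in leaf order.
    """
    py_rng = _random.Random(int(_rng(config.seed, 0).integers(0, 2**31 - 1)))
    dtree = None
    for _ in range(config.max_tree_attempts):
        try:
            dtree = treesim.birth_death_tree(
                birth_rate=config.birth_rate,
                death_rate=config.death_rate,
                num_extant_tips=config.n_strains,
                rng=py_rng,
                repeat_until_success=True,
            )
            break
        except Exception:
            continue
    if dtree is None:
        raise RuntimeError(
            f"could not reach {config.n_strains} tips in {config.max_tree_attempts} attempts"
        )

    def convert(dnode) -> Node:
        node = Node(length=dnode.edge.length if dnode.parent_node is not None else None)
        for child in dnode.child_nodes():
            node.add_child(convert(child))
        return node

    root = convert(dtree.seed_node)
    # collapse unifurcations dendropy sometimes leaves at the root
    while len(root.children) == 1:
        root = root.children[0]
        root.parent = None
        root.length = None

    # the sampler stops exactly at the n-th speciation, leaving the newest
    # tip branches at zero length; extend every tip branch by one exponential
    # waiting time so all terminal branches are positive and the tree stays
    # ultrametric
    rng = _rng(config.seed, 5)
    extra = float(rng.exponential(1.0 / (config.n_strains * (config.birth_rate + config.death_rate))))

    width = max(2, len(str(config.n_strains)))
    counter = 0

    def relabel(node: Node) -> None:
        nonlocal counter
        if node.is_leaf:
            counter += 1
            node.label = f"S{counter:0{width}d}"
            node.length = (node.length or 0.0) + extra
        for c in node.children:
            relabel(c)

    relabel(root)
    return Phylogeny(root)


# ---------------------------------------------------------------------------
# binary traits
# ---------------------------------------------------------------------------

def _transition_probs(state: int, g: float, l: float, t: float) -> float:
    """P(child = 1 | parent = state) over branch length t."""
    denom = g + l
    if denom == 0:
        return float(state)
    decay = np.exp(-denom * t)
    pi1 = g / denom
    if state == 0:
        return pi1 * (1.0 - decay)
    return pi1 + (1.0 - pi1) * decay


def evolve_binary_traits(
    tree: Phylogeny, config: SimConfig
) -> tuple[pd.DataFrame, SimTruth]:
    """Evolve ``n_pathways`` independent binary presence traits down the tree.

    Returns a strains x pathways tip matrix (cells in {0,1}) and the full
    ground truth (node states, gain and loss nodes per pathway).
    """
    if config.gain_rate == 0 and config.loss_rate == 0 and 0 < config.effective_root_presence < 1:
        import warnings

        warnings.warn("both rates zero: traits are root states frozen in place", stacklevel=2)
    rng = _rng(config.seed, 1)
    nodes = list(tree.preorder())
    truth = SimTruth(tree=tree)
    tips = tree.tip_labels
    mat = np.zeros((len(tips), config.n_pathways), dtype=np.int8)
    tip_index = {lab: k for k, lab in enumerate(tips)}
    pi_root = config.effective_root_presence
    for p in range(config.n_pathways):
        pid = f"PW{p + 1:03d}"
        states: dict[str, int] = {}
        gains: list[str] = []
        losses: list[str] = []
        for node in nodes:
            if node.parent is None:
                state = int(rng.random() < pi_root)
            else:
                p1 = _transition_probs(
                    states[node.parent.node_id], config.gain_rate, config.loss_rate, node.length or 0.0
                )
                state = int(rng.random() < p1)
                parent_state = states[node.parent.node_id]
                if parent_state == 0 and state == 1:
                    gains.append(node.node_id)
                elif parent_state == 1 and state == 0:
                    losses.append(node.node_id)
            states[node.node_id] = state
            if node.is_leaf:
                mat[tip_index[node.label], p] = state
        truth.node_states[pid] = states
        truth.gain_nodes[pid] = gains
        truth.loss_nodes[pid] = losses
    matrix = pd.DataFrame(mat, index=tips, columns=[f"PW{p + 1:03d}" for p in range(config.n_pathways)])
    return matrix, truth


# ---------------------------------------------------------------------------
# assemblies with planted telomeres, genes, RIP windows
# ---------------------------------------------------------------------------

def _random_dna(rng: np.random.Generator, length: int) -> np.ndarray:
    """i.i.d. uniform A/C/G/T as a byte array (50% GC, indices ~ 1 under null)."""
    return rng.integers(0, 4, size=length).astype(np.uint8)


_IDX2BASE = np.frombuffer(b"ACGT", dtype=np.uint8)


def _rip_mutate(idx: np.ndarray, start: int, end: int) -> None:
    """Apply the canonical RIP signature within [start, end): C->T at CpA
    dinucleotides and, strand-symmetrically, G->A at TpG."""
    # indices: A=0 C=1 G=2 T=3
    seg = idx[start:end]
    is_cpa = (seg[:-1] == 1) & (seg[1:] == 0)
    is_tpg = (seg[:-1] == 3) & (seg[1:] == 2)
    seg[:-1][is_cpa] = 3  # C -> T
    seg[1:][is_tpg] = 0   # G -> A


def synth_assembly(
    config: SimConfig,
    genome_id: str = "SYN1",
    telomere_plan: list[tuple[str, int, int, int]] | None = None,
    telomere_copies: int = 5,
    rip_fraction: float = 0.0,
    rip_block: int = 5000,
    gene_length: int = 1500,
    gene_spacing: int = 3500,
) -> tuple[Assembly, GeneAnnotation, SimTruth]:
    """Build a synthetic assembly with planted features.

    ``telomere_plan`` rows are (contig_id, length_bp, left_copies,
    right_copies); left copies of (TTAGGG)n are planted at the very start of
    the contig and right copies of the reverse complement (CCCTAA)n at the
    very end.  ``rip_fraction`` of each contig (in contiguous ``rip_block``
    sized spans aligned to the block grid) is RIP-mutated.  Genes of
    ``gene_length`` bp are planted every ``gene_spacing`` bp.
    """
    if telomere_plan is None:
        telomere_plan = [
            ("ctg1", 120_000, telomere_copies, telomere_copies),
            ("ctg2", 100_000, telomere_copies, 0),
            ("ctg3", 80_000, 0, 0),
        ]
    rng = _rng(config.seed, 2)
    truth = SimTruth()
    contigs: dict[str, str] = {}
    gene_records: list[GeneRecord] = []
    motif_idx = np.frombuffer(TELOMERE_MOTIF.encode(), dtype=np.uint8)
    motif_map = np.zeros(256, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        motif_map[b] = i
    motif_idx = motif_map[motif_idx]
    motif_rc_idx = motif_map[np.frombuffer(TELOMERE_MOTIF_RC.encode(), dtype=np.uint8)]

    for contig_id, length, left, right, in telomere_plan:
        need = (left + right) * len(TELOMERE_MOTIF)
        if need > length:
            raise ValueError(
                f"contig {contig_id}: length {length} too short for {left}+{right} telomere copies"
            )
        idx = _random_dna(rng, length)
        if left:
            planted = np.tile(motif_idx, left)
            idx[: len(planted)] = planted
        if right:
            planted = np.tile(motif_rc_idx, right)
            idx[len(idx) - len(planted):] = planted
        truth.telomere_copies[contig_id] = (left, right)

        # RIP spans: contiguous run of blocks in the interior of the contig
        spans: list[tuple[int, int]] = []
        if rip_fraction > 0:
            n_blocks = length // rip_block
            n_rip = int(round(rip_fraction * n_blocks))
            if n_rip > 0:
                start_block = int(rng.integers(1, max(2, n_blocks - n_rip)))
                span = (start_block * rip_block, (start_block + n_rip) * rip_block)
                _rip_mutate(idx, span[0], span[1])
                spans.append(span)
        truth.rip_spans[contig_id] = spans

        # planted genes (skipping telomeric termini)
        coords: list[tuple[int, int]] = []
        pos = max(left * len(TELOMERE_MOTIF), 200)
        gnum = 0
        while pos + gene_length < length - right * len(TELOMERE_MOTIF):
            gnum += 1
            coords.append((pos, pos + gene_length))
            gene_records.append(
                GeneRecord(
                    contig_id=contig_id,
                    start=pos,
                    end=pos + gene_length,
                    strand="+" if gnum % 2 else "-",
                    gene_id=f"{genome_id}_{contig_id}_g{gnum:04d}",
                )
            )
            pos += gene_spacing
        truth.gene_coords[contig_id] = coords

        contigs[contig_id] = _IDX2BASE[idx].tobytes().decode()

    assembly = Assembly(genome_id=genome_id, contigs=contigs)
    annotation = GeneAnnotation(genome_id=genome_id, records=gene_records)
    return assembly, annotation, truth


# ---------------------------------------------------------------------------
# orthology tables with controlled POCP
# ---------------------------------------------------------------------------

def synth_orthology(
    config: SimConfig,
    pocp_targets: dict[tuple[str, str], float] | None = None,
    tree: Phylogeny | None = None,
    distance_scale: float = 5.0,
) -> tuple[OrthologySummary, SimTruth]:
    """Orthology summary whose realized conserved-protein percentages hit targets.

    Targets may be given per unordered pair (percent, 0..100).  When absent
    and a tree is supplied, targets decay with patristic distance,
    ``100 * exp(-d / distance_scale)``, mimicking the loss of shared
    orthogroup content with divergence.  Per-genome totals are drawn
    uniformly from the observed symbiont gene-count range.
    """
    rng = _rng(config.seed, 3)
    if pocp_targets is None:
        if tree is None:
            raise ValueError("need pocp_targets or a tree to derive them from")
        dists = tree.patristic_distances()
        labels = tree.tip_labels
        pocp_targets = {}
        for a_i, a in enumerate(labels):
            for b in labels[a_i + 1:]:
                pocp_targets[(a, b)] = 100.0 * float(np.exp(-dists[(a, b)] / distance_scale))
    genomes = sorted({g for pair in pocp_targets for g in pair})
    lo, hi = config.total_range
    totals = {g: int(rng.integers(lo, hi + 1)) for g in genomes}
    shared: dict[tuple[str, str], int] = {}
    truth = SimTruth(pocp_targets=dict(pocp_targets))
    for (a, b), target in pocp_targets.items():
        if not 0.0 <= target <= 100.0:
            raise ValueError(f"target for ({a}, {b}) outside [0, 100]: {target}")
        ca = int(round(target / 100.0 * totals[a]))
        cb = int(round(target / 100.0 * totals[b]))
        shared[(a, b)] = min(ca, totals[a])
        shared[(b, a)] = min(cb, totals[b])
    return OrthologySummary(genome_ids=genomes, totals=totals, shared=shared), truth


# ---------------------------------------------------------------------------
# BGC emission from a trait matrix
# ---------------------------------------------------------------------------

_FUNCTION_POOL = [
    "transporter", "oxidoreductase", "methyltransferase", "p450",
    "regulator", "dehydrogenase", "acyltransferase", "glycosyltransferase",
    "halogenase", "esterase", "aminotransferase", "hydrolase",
]

_AA = np.frombuffer(b"ACDEFGHIKLMNPQRSTVWY", dtype=np.uint8)


def emit_bgcs_from_traits(
    matrix: pd.DataFrame,
    config: SimConfig,
    genes_per_bgc: tuple[int, int] = (4, 9),
    protein_length: tuple[int, int] = (120, 320),
):
    """Emit one BGC per (strain, present pathway) so that clustering the
    emitted BGCs into families and binarising recovers ``matrix`` exactly.

    Every pathway gets its own gene-label architecture and per-gene protein
    sequences; all strains carrying the pathway share them, so the
    family-clustering distance between same-pathway BGCs is 0 and between
    different-pathway BGCs is (with probability ~1) far above any sensible
    cutoff.
    """
    from .io import BgcGene, BgcRecord

    rng = _rng(config.seed, 4)
    classes = list(config.class_mix)
    probs = np.array([config.class_mix[c] for c in classes])
    pathway_arch: dict[str, tuple[str, list[str], list[str]]] = {}
    for pid in matrix.columns:
        n_genes = int(rng.integers(genes_per_bgc[0], genes_per_bgc[1] + 1))
        labels = [f"{pid}_backbone"] + [
            f"{pid}_{_FUNCTION_POOL[int(rng.integers(0, len(_FUNCTION_POOL)))]}_{k}"
            for k in range(1, n_genes)
        ]
        prots = []
        for _ in range(n_genes):
            ln = int(rng.integers(protein_length[0], protein_length[1] + 1))
            prots.append(_AA[rng.integers(0, 20, size=ln)].tobytes().decode())
        bgc_class = classes[int(rng.choice(len(classes), p=probs))]
        pathway_arch[pid] = (bgc_class, labels, prots)

    bgcs = []
    for strain in matrix.index:
        pos = 1000
        for pid in matrix.columns:
            if matrix.loc[strain, pid] != 1:
                continue
            bgc_class, labels, prots = pathway_arch[pid]
            genes = [
                BgcGene(
                    gene_id=f"{strain}_{pid}_g{k}",
                    function_label=lab,
                    is_backbone=(k == 0),
                    protein_sequence=prot,
                )
                for k, (lab, prot) in enumerate(zip(labels, prots))
            ]
            span = sum(len(p) * 3 for p in prots) + 200 * len(genes)
            bgcs.append(
                BgcRecord(
                    bgc_id=f"{strain}|{pid}",
                    genome_id=strain,
                    contig_id="ctg1",
                    start=pos,
                    end=pos + span,
                    bgc_class=bgc_class,
                    genes=genes,
                )
            )
            pos += span + 5000
    return bgcs
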