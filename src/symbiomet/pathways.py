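"""Pathway grouping of gene-cluster families and Mk ancestral-state
reconstruction of pathway gains, losses, and candidate horizontal transfers.

Grouping rules
--------------
Two families belong to one pathway when their representative clusters
(i)  share architecture: same backbone class (optional) and adjacency-pair
     Jaccard above a floor,
(ii) more than half of the genes of the smaller cluster share a function
     label with the other (strict majority), and
(iii) more than half of the genes of the smaller cluster have a local
     protein alignment with identity above ``identity_min`` covering at
     least ``coverage_min`` of the shorter protein (strict majority).
Pathways are the connected components of the qualifying-pair graph.

Mk1 model
---------
A single symmetric rate mu; over a branch of length t the 2-state transition
matrix is

    P(t) = [[(1 + e^{-2 mu t})/2, (1 - e^{-2 mu t})/2],
            [(1 - e^{-2 mu t})/2, (1 + e^{-2 mu t})/2]].

The likelihood is computed by Felsenstein pruning; mu is maximised by a
bounded 1-D search on log mu.  Marginal posteriors per node come from the
standard two-pass (pruning up, conditioning down) algorithm; a node is
called present when its marginal presence probability strictly exceeds 0.5.
An acquisition is a present node with an absent parent (or a present root);
a loss is the converse; two or more acquisitions for one pathway flag
candidate horizontal transfer.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import DisjointSet
from scipy.optimize import minimize_scalar

from .gcf import GeneClusterFamily
from .io import BgcRecord
from .tree import Phylogeny

__all__ = [
    "PathwayRules",
    "Pathway",
    "group_pathways",
    "MkModel",
    "fit_mk1",
    "mk_loglik",
    "MarginalStates",
    "reconstruct_marginals",
    "EventMap",
    "call_events",
    "event_recovery_report",
]

MU_BOUNDS = (1e-6, 1e3)


# ---------------------------------------------------------------------------
# pathway grouping
# ---------------------------------------------------------------------------

@dataclass
class PathwayRules:
    identity_min: float = 0.50       # strict >
    coverage_min: float = 0.80       # >=
    majority: float = 0.50           # strict >
    require_same_backbone_class: bool = True
    architecture_min: float = 0.30   # adjacency-pair Jaccard floor for rule (i)

    def __post_init__(self) -> None:
        for name in ("identity_min", "coverage_min", "majority"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1]")


@dataclass
class Pathway:
    pathway_id: str
    member_gcf_ids: list[str]
    presence: pd.Series  # index strains, values {0,1}


def _make_aligner():
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner(mode="local")
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def _best_local_match(query: str, targets: list[str], aligner) -> tuple[float, float]:
    """Best (identity, coverage-of-shorter) of a local alignment of ``query``
    against any of ``targets``.  Identity = identities / alignment columns."""
    best = (0.0, 0.0)
    for target in targets:
        if not target:
            continue
        try:
            aln = aligner.align(query, target)[0]
        except (IndexError, ValueError):
            continue
        counts = aln.counts()
        columns = counts.aligned + counts.gaps
        identity = counts.identities / columns if columns else 0.0
        shorter = min(len(query), len(target))
        # span of the shorter sequence inside the local alignment
        tgt_is_shorter = len(target) < len(query)
        coords = aln.aligned[1] if tgt_is_shorter else aln.aligned[0]
        covered = sum(e - s for s, e in coords)
        coverage = covered / shorter if shorter else 0.0
        if identity > best[0] or (identity == best[0] and coverage > best[1]):
            best = (identity, coverage)
    return best


def _genes_qualify(a: BgcRecord, b: BgcRecord, rules: PathwayRules, aligner) -> bool:
    small, large = (a, b) if len(a.genes) <= len(b.genes) else (b, a)
    n = len(small.genes)

    # rule (ii): shared function labels for a strict majority of the smaller
    large_labels = large.function_labels
    shared = sum(1 for g in small.genes if g.function_label in large_labels)
    if not shared / n > rules.majority:
        return False

    # rule (iii): local protein similarity for a strict majority
    if not (small.has_proteins and large.has_proteins):
        raise ValueError(
            f"protein sequences required for similarity rule: {small.bgc_id} / {large.bgc_id}"
        )
    targets = [g.protein_sequence for g in large.genes]
    hits = 0
    for k, gene in enumerate(small.genes):
        identity, coverage = _best_local_match(gene.protein_sequence, targets, aligner)
        if identity > rules.identity_min and coverage >= rules.coverage_min:
            hits += 1
        # early exit: remaining genes cannot change the verdict
        if hits / n > rules.majority:
            return True
        if (hits + (n - 1 - k)) / n <= rules.majority:
            return False
    return hits / n > rules.majority


def group_pathways(
    families: list[GeneClusterFamily],
    bgcs: list[BgcRecord],
    presence: pd.DataFrame,
    rules: PathwayRules | None = None,
) -> list[Pathway]:
    """Partition families into pathways; presence = union of member columns."""
    rules = rules or PathwayRules()
    by_id = {b.bgc_id: b for b in bgcs}
    reps = {f.gcf_id: by_id[f.representative_bgc_id] for f in families}
    lacking = sorted(r.bgc_id for r in reps.values() if not r.has_proteins)
    if lacking:
        raise ValueError(
            f"protein sequences required for the similarity rule; missing in: {lacking}"
        )
    aligner = _make_aligner()
    ds = DisjointSet([f.gcf_id for f in families])
    backbone = {f.gcf_id: reps[f.gcf_id].bgc_class for f in families}
    for fa, fb in itertools.combinations(families, 2):
        a, b = reps[fa.gcf_id], reps[fb.gcf_id]
        if rules.require_same_backbone_class and backbone[fa.gcf_id] != backbone[fb.gcf_id]:
            continue
        adj = a.adjacency_pairs, b.adjacency_pairs
        union = adj[0] | adj[1]
        arch = (len(adj[0] & adj[1]) / len(union)) if union else 1.0
        if arch < rules.architecture_min:
            continue
        if _genes_qualify(a, b, rules, aligner):
            ds.merge(fa.gcf_id, fb.gcf_id)
    components = sorted((sorted(sub) for sub in ds.subsets()), key=lambda s: s[0])
    pathways = []
    for k, members in enumerate(components, 1):
        vec = (presence[members].sum(axis=1) > 0).astype("int8")
        pathways.append(Pathway(pathway_id=f"P{k}", member_gcf_ids=members, presence=vec))
    return pathways


# ---------------------------------------------------------------------------
# Mk1 likelihood
# ---------------------------------------------------------------------------

@dataclass
class MkModel:
    mu: float
    log_likelihood: float
    root_prior: tuple[float, float] = (0.5, 0.5)
    boundary: bool = False

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError("mu must be non-negative")
        if abs(sum(self.root_prior) - 1.0) > 1e-9:
            raise ValueError("root prior must sum to 1")


def _p_matrix(mu: float, t: float) -> np.ndarray:
    e = np.exp(-2.0 * mu * t)
    same, diff = (1.0 + e) / 2.0, (1.0 - e) / 2.0
    return np.array([[same, diff], [diff, same]])


def _tip_partials(tree: Phylogeny, states: dict[str, int]) -> dict[str, np.ndarray]:
    partials = {}
    for tip in tree.tips():
        if tip.label not in states:
            raise ValueError(f"no observation for tip {tip.label!r}")
        s = int(states[tip.label])
        vec = np.zeros(2)
        vec[s] = 1.0
        partials[tip.node_id] = vec
    return partials


def _prune(tree: Phylogeny, states: dict[str, int], mu: float) -> dict[str, np.ndarray]:
    """Post-order conditional likelihoods L_v(s) = P(tip data below v | state s)."""
    partials = _tip_partials(tree, states)
    for node in tree.postorder():
        if node.is_leaf:
            continue
        vec = np.ones(2)
        for child in node.children:
            p = _p_matrix(mu, child.length or 0.0)
            vec = vec * (p @ partials[child.node_id])
        partials[node.node_id] = vec
    return partials


def mk_loglik(
    tree: Phylogeny,
    states: dict[str, int],
    mu: float,
    root_prior: tuple[float, float] = (0.5, 0.5),
) -> float:
    partials = _prune(tree, states, mu)
    like = float(np.dot(root_prior, partials[tree.root.node_id]))
    return float(np.log(like)) if like > 0 else -np.inf


def fit_mk1(
    tree: Phylogeny,
    states: dict[str, int] | pd.Series,
    root_prior: tuple[float, float] = (0.5, 0.5),
) -> MkModel:
    """Maximum-likelihood symmetric rate by bounded search on log mu."""
    if isinstance(states, pd.Series):
        states = {str(k): int(v) for k, v in states.items()}
    observed = {states[t] for t in tree.tip_labels}
    constant = len(observed) == 1
    if constant:
        warnings.warn(
            "constant character: mu is not identifiable, returning lower-boundary fit",
            stacklevel=2,
        )
        mu = MU_BOUNDS[0]
        return MkModel(
            mu=mu,
            log_likelihood=mk_loglik(tree, states, mu, root_prior),
            root_prior=root_prior,
            boundary=True,
        )
    log_bounds = (np.log(MU_BOUNDS[0]), np.log(MU_BOUNDS[1]))
    res = minimize_scalar(
        lambda lm: -mk_loglik(tree, states, float(np.exp(lm)), root_prior),
        bounds=log_bounds,
        method="bounded",
        options={"xatol": 1e-8},
    )
    mu = float(np.exp(res.x))
    boundary = (
        abs(res.x - log_bounds[0]) < 1e-6 or abs(res.x - log_bounds[1]) < 1e-6
    )
    return MkModel(mu=mu, log_likelihood=-float(res.fun), root_prior=root_prior, boundary=boundary)


# ---------------------------------------------------------------------------
# marginal reconstruction
# ---------------------------------------------------------------------------

@dataclass
class MarginalStates:
    probabilities: pd.DataFrame  # index node_id, columns ["absent", "present"]
    calls: pd.Series             # node_id -> bool (present iff P(present) > 0.5)


def reconstruct_marginals(
    tree: Phylogeny,
    states: dict[str, int] | pd.Series,
    model: MkModel,
) -> MarginalStates:
    """Marginal posterior state probabilities per node, conditioning on all tips."""
    if isinstance(states, pd.Series):
        states = {str(k): int(v) for k, v in states.items()}
    mu = model.mu
    down = _prune(tree, states, mu)  # L_v(s): data below v
    prior = np.array(model.root_prior)

    # up-pass: U_v(s) = P(data outside subtree of v, state of v = s) / P-ish terms;
    # marginal(v) propto U_v * L_v
    up: dict[str, np.ndarray] = {tree.root.node_id: prior.copy()}
    for node in tree.preorder():
        if node.is_leaf:
            continue
        u_parent = up[node.node_id]
        # contribution of each child's siblings, seen from the parent state
        sib_msgs = {}
        for child in node.children:
            p = _p_matrix(mu, child.length or 0.0)
            sib_msgs[child.node_id] = p @ down[child.node_id]
        for child in node.children:
            prod = u_parent.copy()
            for other in node.children:
                if other is child:
                    continue
                prod = prod * sib_msgs[other.node_id]
            p = _p_matrix(mu, child.length or 0.0)
            up[child.node_id] = p.T @ prod

    rows, calls = [], {}
    for node in tree.postorder():
        post = up[node.node_id] * down[node.node_id]
        total = post.sum()
        post = post / total if total > 0 else np.array([0.5, 0.5])
        rows.append({"node_id": node.node_id, "absent": post[0], "present": post[1]})
        calls[node.node_id] = bool(post[1] > 0.5)
    probs = pd.DataFrame(rows).set_index("node_id")
    return MarginalStates(probabilities=probs, calls=pd.Series(calls))


# ---------------------------------------------------------------------------
# event calling
# ---------------------------------------------------------------------------

@dataclass
class EventMap:
    pathway_id: str
    acquisition_nodes: list[str]
    loss_nodes: list[str]
    hgt_flag: bool


def call_events(marginals: MarginalStates, tree: Phylogeny, pathway_id: str = "P1") -> EventMap:
    calls = marginals.calls
    acquisitions, losses = [], []
    for node in tree.preorder():
        present = bool(calls[node.node_id])
        if node.parent is None:
            if present:
                acquisitions.append(node.node_id)
            continue
        parent_present = bool(calls[node.parent.node_id])
        if present and not parent_present:
            acquisitions.append(node.node_id)
        elif not present and parent_present:
            losses.append(node.node_id)
    return EventMap(
        pathway_id=pathway_id,
        acquisition_nodes=acquisitions,
        loss_nodes=losses,
        hgt_flag=len(acquisitions) >= 2,
    )


def tally_events(event_maps: list[EventMap], tree: Phylogeny) -> pd.DataFrame:
    """Per-node counts of pathway acquisitions and losses (tree-figure data)."""
    rows = []
    acq: dict[str, int] = {}
    loss: dict[str, int] = {}
    for em in event_maps:
        for n in em.acquisition_nodes:
            acq[n] = acq.get(n, 0) + 1
        for n in em.loss_nodes:
            loss[n] = loss.get(n, 0) + 1
    for node in tree.preorder():
        rows.append(
            {
                "node_id": node.node_id,
                "is_tip": node.is_leaf,
                "acquisitions": acq.get(node.node_id, 0),
                "losses": loss.get(node.node_id, 0),
            }
        )
    return pd.DataFrame(rows).set_index("node_id")


def event_recovery_report(
    event_maps: dict[str, EventMap],
    truth_gains: dict[str, list[str]],
    truth_losses: dict[str, list[str]],
    root_id: str | None = None,
) -> pd.DataFrame:
    """Precision/recall of inferred vs true gain and loss nodes.

    Events are matched by node identity on the shared tree.  A root
    "acquisition" encodes inferred ancestral presence rather than a gain
    event on a branch (the simulated truth records gains only as
    parent-to-child changes), so when ``root_id`` is given, root
    acquisitions are excluded from the comparison.  Recall denominators are
    the true event counts; pathways without true events contribute only to
    precision.
    """
    rows = []
    for kind, truth in (("gain", truth_gains), ("loss", truth_losses)):
        tp = fp = fn = 0
        for pid, em in event_maps.items():
            inferred = set(em.acquisition_nodes if kind == "gain" else em.loss_nodes)
            if kind == "gain" and root_id is not None:
                inferred.discard(root_id)
            true = set(truth.get(pid, []))
            tp += len(inferred & true)
            fp += len(inferred - true)
            fn += len(true - inferred)
        precision = tp / (tp + fp) if tp + fp else float("nan")
        recall = tp / (tp + fn) if tp + fn else float("nan")
        rows.append(
            {"event": kind, "tp": tp, "fp": fp, "fn": fn, "precision": precision, "recall": recall}
        )
    return pd.DataFrame(rows).set_index("event")
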