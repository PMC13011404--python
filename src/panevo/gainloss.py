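"""Gene gain/loss inference on a rooted phylogeny by asymmetric-cost
Wagner parsimony.

Transition costs are c(0->1) = gain_cost (default 2) and c(1->0) =
loss_cost (default 1); presence at the root is charged one additional gain
(a virtual origin from an absent ancestor), so that with loss cheaper than
gain the reconstruction does not spuriously push presence to the root.
Ties among minimum-cost reconstructions are resolved deterministically by
preferring fewer gains, then absence.

Event significance is assessed with a label-permutation null (tip states
shuffled across tips) plus a tip-subsampling stability score; the
procedure and its reported statistics are this package's own definition
and are recorded as such in output metadata.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

from panevo.io import PresenceAbsenceMatrix
from panevo.cooccur import bh_adjust
from panevo.pangenome import PangenomePartition
from panevo.simulate import label_tree_nodes

logger = logging.getLogger("panevo")

__all__ = [
    "GainLossEvents",
    "EventSignificance",
    "wagner_events",
    "pangenome_events",
    "event_significance",
    "classify_lineage_events",
]

DUAL_P_THRESHOLD = 1e-5
DUAL_FDR_THRESHOLD = 0.05
ROOT_BRANCH = "root"
_TOL = 1e-9


@dataclass(eq=True)
class GainLossEvents:
    """Minimum-cost reconstruction for one COG.

    ``gains`` includes the root-origin gain when the root is resolved
    present; ``per_branch`` maps the child-node label of each branch with
    an event (or "root" for the origin) to "gain" or "loss".
    """

    cog_id: str
    min_cost: float
    gains: int
    losses: int
    per_branch: dict[str, str] = field(default_factory=dict)
    root_state: str = "absent"


@dataclass
class EventSignificance:
    cog_id: str
    z_gain: float
    z_loss: float
    p_gain: float
    p_loss: float
    fdr_gain: float = math.nan
    fdr_loss: float = math.nan
    stability: float = math.nan
    event_class: str = "none"  # {GoF, LoF, both, none}


class _TreeIndex:
    """Array view of a rooted dendropy tree for vectorised Sankoff DP."""

    def __init__(self, tree: dendropy.Tree):
        if not tree.is_rooted:
            raise ValueError("tree is unrooted; root it before parsimony "
                             "reconstruction")
        label_tree_nodes(tree)
        nodes = list(tree.postorder_node_iter())
        self.index = {id(nd): i for i, nd in enumerate(nodes)}
        self.labels = [nd.label for nd in nodes]
        self.children = [[self.index[id(ch)] for ch in nd.child_nodes()]
                         for nd in nodes]
        self.parent = [self.index[id(nd.parent_node)]
                       if nd.parent_node is not None else -1 for nd in nodes]
        self.is_leaf = [nd.is_leaf() for nd in nodes]
        self.root = self.index[id(tree.seed_node)]
        self.tip_order = [i for i in range(len(nodes)) if self.is_leaf[i]]
        self.tip_labels = [self.labels[i] for i in self.tip_order]


def _lex_better(c_new, g_new, c_cur, g_cur):
    """Elementwise: is (c_new, g_new) strictly better than (c_cur, g_cur)
    under (cost, then gains) lexicographic order?"""
    return (c_new < c_cur - _TOL) | (np.abs(c_new - c_cur) <= _TOL) & (g_new < g_cur)


def _sankoff_batch(idx: _TreeIndex, tips: np.ndarray,
                   gain_cost: float, loss_cost: float,
                   root_origin: bool = True):
    """Vectorised Sankoff over a batch of presence patterns.

    ``tips``: (P, n_tips) binary states ordered as ``idx.tip_labels``.
    Returns (min_cost, gains, losses, node_states) with node_states of
    shape (P, n_nodes).  Ties prefer fewer gains, then absence (state 0);
    presence at the root is charged one origin gain.
    """
    tips = np.asarray(tips)
    P = tips.shape[0]
    n_nodes = len(idx.labels)
    INF = np.inf
    cost = np.zeros((n_nodes, P, 2))
    gains = np.zeros((n_nodes, P, 2))
    # choice[v][p, s] = best state of v given its parent chose state s
    choice = np.zeros((n_nodes, P, 2), dtype=np.int8)

    tc = np.array([[0.0, gain_cost], [loss_cost, 0.0]])
    gc = np.array([[0.0, 1.0], [0.0, 0.0]])

    tip_col = {v: j for j, v in enumerate(idx.tip_order)}
    for v in range(n_nodes):
        if idx.is_leaf[v]:
            s = tips[:, tip_col[v]]
            cost[v][np.arange(P), 1 - s] = INF
            continue
        for ch in idx.children[v]:
            c0, c1 = cost[ch][:, 0], cost[ch][:, 1]
            g0, g1 = gains[ch][:, 0], gains[ch][:, 1]
            for s in (0, 1):
                cand0 = c0 + tc[s, 0]
                cand1 = c1 + tc[s, 1]
                gg0 = g0 + gc[s, 0]
                gg1 = g1 + gc[s, 1]
                take1 = _lex_better(cand1, gg1, cand0, gg0)
                choice[ch][:, s] = take1
                cost[v][:, s] += np.where(take1, cand1, cand0)
                gains[v][:, s] += np.where(take1, gg1, gg0)

    r = idx.root
    origin_c = gain_cost if root_origin else 0.0
    origin_g = 1.0 if root_origin else 0.0
    tot0, tot1 = cost[r][:, 0], cost[r][:, 1] + origin_c
    g0, g1 = gains[r][:, 0], gains[r][:, 1] + origin_g
    root1 = _lex_better(tot1, g1, tot0, g0)
    min_cost = np.where(root1, tot1, tot0)
    tot_gains = np.where(root1, g1, g0)

    states = np.zeros((P, n_nodes), dtype=np.int8)
    states[:, r] = root1
    for v in reversed(range(n_nodes)):  # postorder reversed = preorder
        if v == r:
            continue
        ps = states[:, idx.parent[v]]
        states[:, v] = choice[v][np.arange(P), ps]
    # losses from cost identity: cost = gain_cost * gains + loss_cost * losses
    losses = (min_cost - gain_cost * tot_gains) / loss_cost
    return min_cost, tot_gains.astype(int), np.rint(losses).astype(int), states


def wagner_events(tree: dendropy.Tree,
                  presence: Mapping[str, int],
                  gain_cost: float = 2.0,
                  loss_cost: float = 1.0,
                  root_origin: bool = True) -> GainLossEvents:
    """Minimum-cost gain/loss reconstruction of one binary character.

    With ``root_origin=False`` presence at the root is not charged, and
    the reported gains exclude a root origin.
    """
    if gain_cost <= 0 or loss_cost <= 0:
        raise ValueError("costs must be > 0")
    idx = _TreeIndex(tree)
    missing = [t for t in idx.tip_labels if t not in presence]
    if missing:
        raise ValueError(f"tip(s) without a state: {missing[:5]}")
    tips = np.array([[int(presence[t]) for t in idx.tip_labels]])
    cost, gains, losses, states = _sankoff_batch(idx, tips, gain_cost,
                                                 loss_cost, root_origin)
    return _events_from_states(idx, "character", float(cost[0]),
                               int(gains[0]), int(losses[0]), states[0],
                               root_origin)


def _events_from_states(idx: _TreeIndex, cog_id: str, cost: float,
                        gains: int, losses: int,
                        states: np.ndarray,
                        root_origin: bool = True) -> GainLossEvents:
    per_branch: dict[str, str] = {}
    if root_origin and states[idx.root] == 1:
        per_branch[ROOT_BRANCH] = "gain"
    for v in range(len(states)):
        if v == idx.root:
            continue
        ps, s = states[idx.parent[v]], states[v]
        if ps == 0 and s == 1:
            per_branch[idx.labels[v]] = "gain"
        elif ps == 1 and s == 0:
            per_branch[idx.labels[v]] = "loss"
    return GainLossEvents(
        cog_id=cog_id, min_cost=cost, gains=gains, losses=losses,
        per_branch=per_branch,
        root_state="present" if states[idx.root] == 1 else "absent")


def pangenome_events(tree: dendropy.Tree,
                     matrix: PresenceAbsenceMatrix,
                     gain_cost: float = 2.0,
                     loss_cost: float = 1.0,
                     root_origin: bool = True) -> list[GainLossEvents]:
    """Wagner reconstruction for every COG of a presence/absence matrix.

    Identical presence patterns are reconstructed once and shared.
    """
    idx = _TreeIndex(tree)
    tips = set(idx.tip_labels)
    genomes = set(matrix.genome_ids)
    if tips != genomes:
        raise ValueError(
            f"tree tips and matrix genomes differ: only in tree "
            f"{sorted(tips - genomes)[:5]}, only in matrix "
            f"{sorted(genomes - tips)[:5]}")
    row = {g: i for i, g in enumerate(matrix.genome_ids)}
    ordered = matrix.values[[row[t] for t in idx.tip_labels], :].T  # (C, T)
    patterns, inverse = np.unique(ordered, axis=0, return_inverse=True)
    cost, gains, losses, states = _sankoff_batch(idx, patterns, gain_cost,
                                                 loss_cost, root_origin)
    out = []
    for j, cog in enumerate(matrix.cog_ids):
        p = inverse[j]
        out.append(_events_from_states(idx, cog, float(cost[p]),
                                       int(gains[p]), int(losses[p]),
                                       states[p], root_origin))
    return out


def _null_distributions(idx: _TreeIndex, ks: Sequence[int], n_perms: int,
                        gain_cost: float, loss_cost: float,
                        rng: np.random.Generator
                        ) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Null (gains, losses) distributions for random placements of k
    presences across the tips, per distinct carrier count k.

    Shuffling a COG's tip states preserves its carrier count, so the
    label-permutation null depends on k only and is shared across COGs.
    """
    T = len(idx.tip_labels)
    out = {}
    for k in sorted(set(ks)):
        if k == 0 or k == T:
            const = np.array([1 if k else 0] * n_perms)
            out[k] = (const.copy(), np.zeros(n_perms, int))
            continue
        u = rng.random((n_perms, T))
        sel = np.argpartition(u, k - 1, axis=1)[:, :k]
        tips = np.zeros((n_perms, T), dtype=np.int8)
        np.put_along_axis(tips, sel, 1, axis=1)
        _, g, l, _ = _sankoff_batch(idx, tips, gain_cost, loss_cost)
        out[k] = (g, l)
    return out


def _classify(p_gain, p_loss, fdr_gain, fdr_loss, p_thresh):
    gof = p_gain <= p_thresh and fdr_gain < DUAL_FDR_THRESHOLD
    lof = p_loss <= p_thresh and fdr_loss < DUAL_FDR_THRESHOLD
    if gof and lof:
        return "both"
    if gof:
        return "GoF"
    if lof:
        return "LoF"
    return "none"


def _significance_pass(idx: _TreeIndex, ordered: np.ndarray,
                       cog_ids: Sequence[str], n_perms: int,
                       gain_cost: float, loss_cost: float,
                       rng: np.random.Generator, p_thresh: float
                       ) -> pd.DataFrame:
    """One full significance evaluation: observed events, per-k permutation
    nulls, upper-tail smoothed p per tail, BH per tail, class."""
    patterns, inverse = np.unique(ordered, axis=0, return_inverse=True)
    _, g_obs_p, l_obs_p, _ = _sankoff_batch(idx, patterns, gain_cost,
                                            loss_cost)
    ks = patterns.sum(axis=1).astype(int)
    nulls = _null_distributions(idx, ks, n_perms, gain_cost, loss_cost, rng)
    rows = []
    for j, cog in enumerate(cog_ids):
        p = inverse[j]
        g_obs, l_obs = int(g_obs_p[p]), int(l_obs_p[p])
        ng, nl = nulls[int(ks[p])]
        sd_g, sd_l = ng.std(), nl.std()
        z_g = (g_obs - ng.mean()) / sd_g if sd_g > 0 else 0.0
        z_l = (l_obs - nl.mean()) / sd_l if sd_l > 0 else 0.0
        p_g = (1 + int((ng >= g_obs).sum())) / (1 + n_perms)
        p_l = (1 + int((nl >= l_obs).sum())) / (1 + n_perms)
        rows.append((cog, float(z_g), float(z_l), p_g, p_l))
    frame = pd.DataFrame(rows, columns=["cog_id", "z_gain", "z_loss",
                                        "p_gain", "p_loss"])
    frame["fdr_gain"] = bh_adjust(frame["p_gain"].to_numpy())
    frame["fdr_loss"] = bh_adjust(frame["p_loss"].to_numpy())
    frame["event_class"] = [
        _classify(pg, pl, fg, fl, p_thresh)
        for pg, pl, fg, fl in zip(frame["p_gain"], frame["p_loss"],
                                  frame["fdr_gain"], frame["fdr_loss"])]
    return frame


def event_significance(tree: dendropy.Tree,
                       matrix: PresenceAbsenceMatrix,
                       n_label_perms: int = 1000,
                       n_subsample_rounds: int = 100,
                       subsample_frac: float = 0.8,
                       seed: Optional[int] = None,
                       gain_cost: float = 2.0,
                       loss_cost: float = 1.0) -> list[EventSignificance]:
    """Permutation significance and subsample stability of gain/loss
    events.

    Per COG the null shuffles tip states across tips ``n_label_perms``
    times; the upper-tail smoothed p per tail is
    (1 + #{null >= observed}) / (1 + n).  BH runs across COGs per tail.
    The nominal dual threshold is p < 1e-5 AND FDR < 0.05; with fewer than
    1e5 permutations the p cutoff falls back to the smallest attainable
    value, 1/(1+n), with a logged warning.  Stability is the fraction of
    tip-subsample rounds (``subsample_frac`` of tips, induced subtree)
    reproducing the full-data class.
    """
    if n_label_perms < 100:
        raise ValueError("n_label_perms must be >= 100")
    rng = np.random.default_rng(seed)
    idx = _TreeIndex(tree)
    tips = set(idx.tip_labels)
    if tips != set(matrix.genome_ids):
        raise ValueError("tree tips and matrix genomes differ")
    if n_label_perms >= 1e5:
        p_thresh = DUAL_P_THRESHOLD
    else:
        p_thresh = 1.0 / (1 + n_label_perms)
        logger.warning(
            "n_label_perms=%d cannot resolve p < %.0e; falling back to the "
            "smallest attainable p-value %.2e as the per-tail cutoff",
            n_label_perms, DUAL_P_THRESHOLD, p_thresh)

    row = {g: i for i, g in enumerate(matrix.genome_ids)}
    ordered = matrix.values[[row[t] for t in idx.tip_labels], :].T
    full = _significance_pass(idx, ordered, matrix.cog_ids, n_label_perms,
                              gain_cost, loss_cost, rng, p_thresh)
    full_class = dict(zip(full["cog_id"], full["event_class"]))

    agree = {c: 0 for c in matrix.cog_ids}
    rounds_done = 0
    T = len(idx.tip_labels)
    n_sub = int(round(subsample_frac * T))
    taxon_ns = {t.label: t for t in tree.taxon_namespace}
    for _ in range(n_subsample_rounds):
        keep = [idx.tip_labels[i]
                for i in rng.choice(T, size=n_sub, replace=False)]
        if len(keep) < 4:
            logger.warning("subsample round leaves %d tips (< 4); skipped",
                           len(keep))
            continue
        sub = tree.extract_tree_with_taxa([taxon_ns[t] for t in keep])
        sub.is_rooted = True
        sub_idx = _TreeIndex(sub)
        cols = [row[t] for t in sub_idx.tip_labels]
        sub_ordered = matrix.values[cols, :].T
        res = _significance_pass(sub_idx, sub_ordered, matrix.cog_ids,
                                 n_label_perms, gain_cost, loss_cost, rng,
                                 p_thresh)
        rounds_done += 1
        for cog, cls in zip(res["cog_id"], res["event_class"]):
            if cls == full_class[cog]:
                agree[cog] += 1

    out = []
    for _, r in full.iterrows():
        stability = (agree[r["cog_id"]] / rounds_done
                     if rounds_done else math.nan)
        out.append(EventSignificance(
            cog_id=r["cog_id"], z_gain=r["z_gain"], z_loss=r["z_loss"],
            p_gain=r["p_gain"], p_loss=r["p_loss"],
            fdr_gain=r["fdr_gain"], fdr_loss=r["fdr_loss"],
            stability=stability, event_class=r["event_class"]))
    return out


def classify_lineage_events(focal_partition: PangenomePartition,
                            sibling_prevalence: pd.DataFrame,
                            soft_min: float = 0.95,
                            cloud_max: float = 0.15,
                            conserved_min: float = 0.90,
                            significance: Optional[Mapping[str, str]] = None
                            ) -> pd.DataFrame:
    """Lineage-specific gain/loss candidates against sibling species.

    ``sibling_prevalence``: species x COG prevalence fractions (focal
    species excluded).  A lineage-GoF candidate sits in the focal
    soft-core (prevalence >= soft_min, i.e. soft-core or core) while below
    ``cloud_max`` in every sibling; a lineage-LoF candidate sits in the
    focal cloud while >= ``conserved_min`` in at least one sibling.  When
    per-COG significance classes are supplied, candidates additionally
    require a matching GoF/LoF (or both) class.
    """
    if sibling_prevalence.empty:
        raise ValueError("no sibling species given")
    if sibling_prevalence.isna().any().any():
        raise ValueError("sibling prevalence contains missing values "
                         "(species with no genomes?)")
    prev = focal_partition.prevalence
    eps = 1e-9
    rows = []
    for cog in prev.index:
        sib = (sibling_prevalence[cog]
               if cog in sibling_prevalence.columns else None)
        cls = "none"
        if prev[cog] >= soft_min - eps:
            if sib is None or bool((sib <= cloud_max - eps).all()):
                cls = "lineage_GoF"
        elif prev[cog] < cloud_max - eps:
            if sib is not None and bool((sib >= conserved_min - eps).any()):
                cls = "lineage_LoF"
        if significance is not None and cls != "none":
            sig = significance.get(cog, "none")
            want = "GoF" if cls == "lineage_GoF" else "LoF"
            if sig not in {want, "both"}:
                cls = "none"
        rows.append((cog, cls))
    return pd.DataFrame(rows, columns=["cog_id", "lineage_class"])
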