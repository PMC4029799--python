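"""Classifier networks, output-bin tallies and prevalence-rescaled confidence.

Single hard classifiers give a yes/no answer; chaining them gives a
confidence.  Two topologies are provided:

* **Sequential chain** — each classifier removes the images it calls
  normal into its own terminal bin and passes the suspicious remainder
  to the next classifier (a different wavelet basis at every stage).
  The further an image travels, the more classifiers agree it is
  suspicious.
* **Branched (tuned-tap) networks** — classifiers tuned to one lesion
  type (calcifications or masses) are arranged in two legs; terminal
  bins ("taps") separate calcification-suspicious, mass-suspicious and
  normal verdicts.  Four-tap and six-tap layouts are supported.

Every routed image lands in exactly one terminal bin.  Counting the
actually-normal and actually-suspicious images per bin gives the bin
tallies eta(bin, N) and eta(bin, S), from which a confidence that a
bin's verdict is correct is computed.  Because the development datasets
are far richer in abnormalities than a screening clinic, tallies are
rescaled to a target prevalence through the constant

    alpha = P_real(N) * T_exp(S) / (P_real(S) * T_exp(N)),

where T_exp are the experimental class totals.  For a normal bin

    C_real(N) = 1 / (1 + (1/alpha) * eta(S)/eta(N)),

and symmetrically (with alpha in place of 1/alpha) for a suspicious
bin.  ``C_even`` uses alpha at 50% prevalence; the alpha-rescaling is
monotone, so bins rank identically under either measure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .classify import ConfusionCounts, loo_predict, search_basis
from .labels import TARGETS, target_vector

__all__ = [
    "PriorSpec",
    "BinTally",
    "ClassifierNode",
    "Network",
    "compute_alpha",
    "bin_confidence",
    "network_metrics",
    "build_sequential",
    "build_branched",
    "run_network",
    "WaveletFilterNetwork",
]


def compute_alpha(p_real_s: float, t_exp_n: int, t_exp_s: int) -> float:
    """Prevalence-rescaling constant alpha.

    ``p_real_s`` is the clinic prevalence of suspicious images;
    ``t_exp_n``/``t_exp_s`` are the experimental class totals.
    """
    if not (0.0 < p_real_s < 1.0):
        raise ValueError("prevalence must be strictly between 0 and 1")
    if t_exp_n <= 0 or t_exp_s <= 0:
        raise ValueError("experimental class totals must be positive")
    return (1.0 - p_real_s) * t_exp_s / (p_real_s * t_exp_n)


@dataclass
class PriorSpec:
    """Clinic prevalence plus experimental class totals."""

    p_real_s: float
    t_exp_n: int
    t_exp_s: int

    @property
    def alpha(self) -> float:
        return compute_alpha(self.p_real_s, self.t_exp_n, self.t_exp_s)

    @property
    def alpha_even(self) -> float:
        """Alpha under equal prior chance of normal and suspicious."""
        return compute_alpha(0.5, self.t_exp_n, self.t_exp_s)


@dataclass
class BinTally:
    """Counts of actually-normal / actually-suspicious images in one bin."""

    bin_id: str
    kind: str  # 'normal' or 'suspicious'
    eta_n: int = 0
    eta_s: int = 0

    def __post_init__(self):
        if self.kind not in ("normal", "suspicious"):
            raise ValueError("bin kind must be 'normal' or 'suspicious'")
        if self.eta_n < 0 or self.eta_s < 0:
            raise ValueError("tallies must be non-negative")

    @property
    def total(self) -> int:
        return self.eta_n + self.eta_s


def bin_confidence(tally: BinTally, alpha: float) -> float:
    """Confidence that an image in this bin truly has the bin's class.

    For a normal bin, ``1 / (1 + (1/alpha) * eta_S/eta_N)``; for a
    suspicious bin, ``1 / (1 + alpha * eta_N/eta_S)``.  A pure bin gives
    1; an empty on-class count with off-class occupants gives 0 by
    continuity; an entirely empty bin is undefined.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    on, off = (tally.eta_n, tally.eta_s) if tally.kind == "normal" else (tally.eta_s, tally.eta_n)
    ratio = (1.0 / alpha) if tally.kind == "normal" else alpha
    if on == 0:
        if off == 0:
            raise ValueError(f"bin {tally.bin_id!r} is empty: confidence undefined")
        return 0.0
    return 1.0 / (1.0 + ratio * off / on)


def network_metrics(bins: Sequence[BinTally]):
    """Sensitivity, specificity and classification rate from bin tallies.

    Suspicious images in suspicious bins are true positives; normal
    images in normal bins are true negatives.  Returns
    ``(sensitivity, specificity, classification_rate, ConfusionCounts)``.
    """
    if not bins or all(b.total == 0 for b in bins):
        raise ValueError("empty tallies")
    tp = sum(b.eta_s for b in bins if b.kind == "suspicious")
    tn = sum(b.eta_n for b in bins if b.kind == "normal")
    fp = sum(b.eta_n for b in bins if b.kind == "suspicious")
    fn = sum(b.eta_s for b in bins if b.kind == "normal")
    counts = ConfusionCounts(ntp=tp, ntn=tn, nfp=fp, nfn=fn)
    return counts.sensitivity, counts.specificity, counts.classification_rate, counts


# ---------------------------------------------------------------------------
# topology


@dataclass
class ClassifierNode:
    """One classifier in a network and where its two verdicts route to.

    Routes name either another node id or a terminal bin id (declared in
    the owning :class:`Network`).  ``feature_set`` is filled in by the
    subset search at training time unless given explicitly.
    """

    node_id: str
    basis: str
    moments: object = "auto"  # pair of moment codes, or 'auto'
    tuned_target: str = "any"
    route_normal: str = ""
    route_suspicious: str = ""
    feature_set: Optional[Tuple] = None

    def __post_init__(self):
        if self.tuned_target not in TARGETS:
            raise ValueError(f"tuned_target must be one of {TARGETS}")


@dataclass
class Network:
    """A DAG of classifier nodes with terminal bins."""

    nodes: Dict[str, ClassifierNode]
    bins: Dict[str, str]  # bin_id -> 'normal' | 'suspicious'
    root: str

    def __post_init__(self):
        self.validate()

    def validate(self):
        if self.root not in self.nodes:
            raise ValueError(f"root {self.root!r} is not a node")
        for node in self.nodes.values():
            for route in (node.route_normal, node.route_suspicious):
                if route not in self.nodes and route not in self.bins:
                    raise ValueError(f"route {route!r} of node {node.node_id!r} resolves to nothing")
        # cycle check: DFS from every node
        state: Dict[str, int] = {}

        def visit(nid: str):
            if nid in self.bins:
                return
            if state.get(nid) == 1:
                raise ValueError(f"cycle detected through node {nid!r}")
            if state.get(nid) == 2:
                return
            state[nid] = 1
            node = self.nodes[nid]
            visit(node.route_normal)
            visit(node.route_suspicious)
            state[nid] = 2

        for nid in self.nodes:
            visit(nid)

    @property
    def n_taps(self) -> int:
        return len(self.bins)


def build_sequential(nodes: Sequence[ClassifierNode], depth: Optional[int] = None) -> Network:
    """Chain classifiers: normal verdicts terminate, suspicious pass on.

    Each node's normal route is its own terminal bin; the last node's
    suspicious route is the final suspicious bin.  ``depth`` truncates
    the chain (the high-sensitivity operating point stops early, before
    the late stages where the normal-bin confidence collapses).  No
    wavelet basis may appear twice.
    """
    nodes = list(nodes)[: depth if depth is not None else None]
    if not nodes:
        raise ValueError("need at least one classifier")
    bases = [n.basis for n in nodes]
    if len(set(bases)) != len(bases):
        raise ValueError("no wavelet basis may be used more than once in a series")
    bins = {}
    node_map = {}
    for i, node in enumerate(nodes):
        nb = f"{node.node_id}.n"
        bins[nb] = "normal"
        node.route_normal = nb
        node.route_suspicious = nodes[i + 1].node_id if i + 1 < len(nodes) else "suspicious"
        node_map[node.node_id] = node
    bins["suspicious"] = "suspicious"
    return Network(nodes=node_map, bins=bins, root=nodes[0].node_id)


def build_branched(leg1: Sequence[ClassifierNode], leg2: Sequence[ClassifierNode]) -> Network:
    """Branched tuned network with four (2+2 nodes) or six (3+2) taps.

    Four-tap: the two leg-1 classifiers screen for their lesion type;
    both normal verdicts fall through to leg 2 and the confirmed
    suspicious verdict is a terminal tap.  Leg 2 screens for the other
    lesion: its first node's normal verdict terminates, its suspicious
    verdict is re-examined by the second node, whose two verdicts both
    terminate.

    Six-tap: leg 1's first node is a router (suspicious to the rest of
    leg 1, normal to leg 2); within each 2-node leg every normal verdict
    is its own terminal bin and the confirmed suspicious verdict is the
    leg's tap.
    """
    leg1, leg2 = list(leg1), list(leg2)
    if len(leg2) != 2 or len(leg1) not in (2, 3):
        raise ValueError("leg sizes must be 2+2 (four-tap) or 3+2 (six-tap)")
    for leg in (leg1[-2:], leg2):
        if len({n.tuned_target for n in leg}) != 1:
            raise ValueError("tuned targets must be consistent within a leg")

    bins: Dict[str, str] = {}
    m1, m2 = leg2

    if len(leg1) == 2:  # four-tap
        c1, c2 = leg1
        c1.route_suspicious = c2.node_id
        c1.route_normal = m1.node_id
        c2.route_suspicious = f"{c2.node_id}.s"
        c2.route_normal = m1.node_id
        bins[c2.route_suspicious] = "suspicious"
        m1.route_normal = f"{m1.node_id}.n"
        m1.route_suspicious = m2.node_id
        bins[m1.route_normal] = "normal"
        m2.route_normal = f"{m2.node_id}.n"
        m2.route_suspicious = f"{m2.node_id}.s"
        bins[m2.route_normal] = "normal"
        bins[m2.route_suspicious] = "suspicious"
        root = c1
        nodes = [c1, c2, m1, m2]
    else:  # six-tap
        r, c1, c2 = leg1
        r.route_suspicious = c1.node_id
        r.route_normal = m1.node_id
        c1.route_normal = f"{c1.node_id}.n"
        c1.route_suspicious = c2.node_id
        bins[c1.route_normal] = "normal"
        c2.route_normal = f"{c2.node_id}.n"
        c2.route_suspicious = f"{c2.node_id}.s"
        bins[c2.route_normal] = "normal"
        bins[c2.route_suspicious] = "suspicious"
        m1.route_normal = f"{m1.node_id}.n"
        m1.route_suspicious = m2.node_id
        bins[m1.route_normal] = "normal"
        m2.route_normal = f"{m2.node_id}.n"
        m2.route_suspicious = f"{m2.node_id}.s"
        bins[m2.route_normal] = "normal"
        bins[m2.route_suspicious] = "suspicious"
        root = r
        nodes = [r, c1, c2, m1, m2]

    return Network(nodes={n.node_id: n for n in nodes}, bins=bins, root=root.node_id)


def run_network(
    network: Network,
    node_predictions: Dict[str, np.ndarray],
    y_suspicious: np.ndarray,
):
    """Route each image through the network and tally the terminal bins.

    ``node_predictions[node_id]`` is the boolean suspicious-verdict
    vector of that node for every image (each node's verdict is
    precomputed; routing only decides which verdicts matter).  Returns
    ``(bins, assignment)`` where ``assignment[i]`` is the bin id image i
    landed in.
    """
    y_suspicious = np.asarray(y_suspicious, dtype=bool)
    n = y_suspicious.shape[0]
    for nid in network.nodes:
        if nid not in node_predictions:
            raise ValueError(f"missing predictions for node {nid!r}")
        if np.asarray(node_predictions[nid]).shape[0] != n:
            raise ValueError(f"prediction length mismatch for node {nid!r}")
    tallies = {bid: BinTally(bid, kind) for bid, kind in network.bins.items()}
    assignment = []
    for i in range(n):
        nid = network.root
        while nid in network.nodes:
            node = network.nodes[nid]
            nid = node.route_suspicious if node_predictions[node.node_id][i] else node.route_normal
        t = tallies[nid]
        if y_suspicious[i]:
            t.eta_s += 1
        else:
            t.eta_n += 1
        assignment.append(nid)
    return list(tallies.values()), assignment


class WaveletFilterNetwork:
    """A classifier network trained by per-node exhaustive subset search.

    ``fit`` selects each node's feature subset by the weighted LOOCV
    search restricted to the node's basis/moment pool and tuned target.
    ``evaluate_loocv`` routes every training image using leave-one-out
    node verdicts (each node refit without the image under evaluation),
    yielding unbiased-by-fold bin tallies and metrics.

    Parameters
    ----------
    network : Network
        Topology; node ``feature_set`` entries may be pre-assigned to
        skip the search for that node.
    w : float, default 0.995
        Sensitivity weighting of the subset-selection score.
    max_k : int, default 3
        Largest feature-subset size searched.
    """

    def __init__(self, network: Network, w: float = 0.995, max_k: int = 3):
        self.network = network
        self.w = w
        self.max_k = max_k

    def fit(self, table: pd.DataFrame):
        """Run the subset search for every node lacking an explicit feature set."""
        self.search_results_ = {}
        for node in self.network.nodes.values():
            if node.feature_set is None:
                res = search_basis(
                    table, node.basis, node.moments, node.tuned_target, self.max_k, self.w
                )
                node.feature_set = res.feature_set
                self.search_results_[node.node_id] = res
        self.table_ = table
        return self

    def _node_loo_predictions(self, table: pd.DataFrame) -> Dict[str, np.ndarray]:
        preds = {}
        for node in self.network.nodes.values():
            y = target_vector(table["label"], node.tuned_target)
            X = table[[f.encode() for f in node.feature_set]].to_numpy()
            preds[node.node_id] = loo_predict(X, y)
        return preds

    def evaluate_loocv(self, table: Optional[pd.DataFrame] = None):
        """Leave-one-out network evaluation on the (training) table.

        Returns ``(bins, assignment, metrics)`` where ``metrics`` is the
        ``network_metrics`` tuple over the any-abnormality partition.
        """
        table = self.table_ if table is None else table
        preds = self._node_loo_predictions(table)
        y = target_vector(table["label"], "any")
        bins, assignment = run_network(self.network, preds, y)
        return bins, assignment, network_metrics(bins)

    def report(self, prior: PriorSpec, table: Optional[pd.DataFrame] = None) -> dict:
        """Bin tallies with realistic and even-prior confidences plus metrics."""
        bins, assignment, (sens, spec, rate, counts) = self.evaluate_loocv(table)
        out_bins = []
        for b in bins:
            entry = {"bin": b.bin_id, "kind": b.kind, "eta_n": b.eta_n, "eta_s": b.eta_s}
            if b.total > 0:
                entry["c_real"] = bin_confidence(b, prior.alpha)
                entry["c_even"] = bin_confidence(b, prior.alpha_even)
            out_bins.append(entry)
        return {
            "bins": out_bins,
            "sensitivity": sens,
            "specificity": spec,
            "classification_rate": rate,
            "counts": {"ntp": counts.ntp, "ntn": counts.ntn, "nfp": counts.nfp, "nfn": counts.nfn},
            "alpha": prior.alpha,
            "alpha_even": prior.alpha_even,
            "nodes": {
                nid: [f.encode() for f in node.feature_set]
                for nid, node in self.network.nodes.items()
            },
        }
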