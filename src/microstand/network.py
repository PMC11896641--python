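"""Spearman co-occurrence networks, modules, and Zi/Pi node roles.

Edges connect taxa whose rank correlation across samples is strong
(|rho| >= rho_min) and significant after Benjamini-Hochberg correction
(q <= q_max), restricted to taxa above a mean relative-abundance floor.
Node roles follow the within-module degree z-score (Zi) / participation
coefficient (Pi) scheme: module hubs (Zi > 2.5, Pi < 0.62), network hubs
(Zi > 2.5, Pi > 0.62), connectors (Zi < 2.5, Pi > 0.62) and peripherals
(everything else; threshold equality falls to the peripheral side).
"""

from __future__ import annotations

import logging
import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("microstand")

ZI_THRESHOLD = 2.5
PI_THRESHOLD = 0.62


def spearman_matrix(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs Spearman rho and two-sided p across samples.

    Features (rows of ``table``) are the variables; rho is Pearson on
    mid-ranks with average ranks for ties, p from the t approximation.
    Constant features yield NaN against every partner and are excluded
    from edges downstream.
    """
    if table.shape[1] < 4:
        raise ValueError("need at least 4 samples for a correlation network")
    if table.shape[0] < 2:
        raise ValueError("need at least 2 features")
    X = table.to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        if X.shape[0] == 2:  # scipy returns a scalar for two variables
            r, pv = stats.spearmanr(X[0], X[1])
            rho = np.array([[1.0, r], [r, 1.0]])
            p = np.array([[0.0, pv], [pv, 0.0]])
        else:
            rho, p = stats.spearmanr(X.T)
    np.fill_diagonal(rho, 1.0)
    ids = table.index
    return (pd.DataFrame(rho, index=ids, columns=ids),
            pd.DataFrame(p, index=ids, columns=ids))


def build_cooccurrence(rel: pd.DataFrame, min_abund: float = 0.001,
                       rho_min: float = 0.6, q_max: float = 0.05,
                       correction: str = "bh",
                       abundance_mode: str = "mean") -> nx.Graph:
    """Build the co-occurrence graph from a relative-abundance table.

    Taxa whose mean (or, with ``abundance_mode="max"``, per-sample
    maximum) relative abundance exceeds ``min_abund`` become nodes; an
    edge requires |rho| >= rho_min and corrected p <= q_max. Isolated
    nodes are retained and flagged. Thresholds are recorded as graph
    attributes so every export carries its own provenance.
    """
    if abundance_mode == "mean":
        abund = rel.mean(axis=1)
    elif abundance_mode == "max":
        abund = rel.max(axis=1)
    else:
        raise ValueError(f"unknown abundance_mode: {abundance_mode!r}")
    nodes = rel.index[abund > min_abund]
    if len(nodes) < 2:
        raise ValueError(
            f"fewer than 2 features exceed min_abund={min_abund}; no network")
    sub = rel.loc[nodes]
    rho, p = spearman_matrix(sub)

    iu = np.triu_indices(len(nodes), k=1)
    pvals = p.to_numpy()[iu]
    rhos = rho.to_numpy()[iu]
    valid = ~np.isnan(pvals) & ~np.isnan(rhos)
    q = np.full_like(pvals, np.nan)
    if correction == "bh":
        if valid.any():
            q[valid] = multipletests(pvals[valid], method="fdr_bh")[1]
    elif correction == "none":
        q[valid] = pvals[valid]
    else:
        raise ValueError(f"unknown correction: {correction!r}")

    g = nx.Graph(min_abund=float(min_abund), rho_min=float(rho_min),
                 q_max=float(q_max), correction=correction,
                 abundance_mode=abundance_mode)
    for node in nodes:
        g.add_node(str(node), mean_abundance=float(abund[node]))
    for (i, j), r, qv, ok in zip(zip(*iu), rhos, q, valid):
        if not ok:
            continue
        if abs(r) >= rho_min and qv <= q_max:
            g.add_edge(str(nodes[i]), str(nodes[j]), rho=float(r),
                       q_value=float(qv),
                       sign="positive" if r > 0 else "negative")
    for node in g.nodes:
        g.nodes[node]["isolated"] = g.degree(node) == 0
    return g


def assign_modules(net: nx.Graph, seed: int = 0, method: str = "greedy") -> dict[str, str]:
    """Modularity-based module partition; returns node -> module label.

    ``greedy`` (default) is the deterministic Clauset-Newman-Moore
    agglomeration; ``louvain`` is available behind the flag and uses the
    seed for its tie-breaking. Labels are ``M1, M2, ...`` ordered by
    decreasing module size; isolated nodes end up in singleton modules.
    The partition is also stored on the nodes as the ``module`` attribute.
    """
    if net.number_of_edges() == 0:
        communities = [{n} for n in net.nodes]
    elif method == "greedy":
        communities = [set(c) for c in
                       nx.community.greedy_modularity_communities(net)]
    elif method == "louvain":
        communities = [set(c) for c in
                       nx.community.louvain_communities(net, seed=seed)]
    else:
        raise ValueError(f"unknown module detection method: {method!r}")
    communities.sort(key=lambda c: (-len(c), sorted(c)[0]))
    modules = {}
    for mi, comm in enumerate(communities, start=1):
        for node in comm:
            modules[node] = f"M{mi}"
    nx.set_node_attributes(net, modules, "module")
    return modules


def topology_summary(net: nx.Graph, modules: dict[str, str] | None = None) -> dict:
    """Node/edge counts, edge signs, mean degree, density, modularity."""
    n = net.number_of_nodes()
    e = net.number_of_edges()
    if n == 0:
        logger.warning("topology_summary: empty network")
        return {"n_nodes": 0, "n_edges": 0, "n_positive": 0, "n_negative": 0,
                "mean_degree": 0.0, "density": 0.0, "modularity": np.nan,
                "n_modules": 0}
    signs = [d.get("sign") for _, _, d in net.edges(data=True)]
    if modules is None:
        modules = nx.get_node_attributes(net, "module")
    if modules and e > 0:
        comms = {}
        for node, mod in modules.items():
            comms.setdefault(mod, set()).add(node)
        modularity = nx.community.modularity(net, comms.values())
        n_modules = len(comms)
    else:
        modularity, n_modules = np.nan, 0
    return {
        "n_nodes": n,
        "n_edges": e,
        "n_positive": sum(s == "positive" for s in signs),
        "n_negative": sum(s == "negative" for s in signs),
        "mean_degree": 2.0 * e / n,
        "density": 2.0 * e / (n * (n - 1)) if n > 1 else 0.0,
        "modularity": modularity,
        "n_modules": n_modules,
    }


def zi_pi(net: nx.Graph, modules: dict[str, str] | None = None) -> pd.DataFrame:
    """Within-module degree z-score and participation coefficient per node.

    Zi standardizes a node's edge count into its own module against the
    nodes of that module (population SD; a module of uniform internal
    degree gets Zi = 0 by convention). Pi = 1 - sum_m (k_im / k_i)^2 over
    the modules the node's edges reach; a degree-zero node gets Pi = 0.
    """
    if modules is None:
        modules = nx.get_node_attributes(net, "module")
    missing = [n for n in net.nodes if n not in modules]
    if missing:
        raise ValueError(f"nodes without a module label: {missing}")

    own_degree = {}
    for node in net.nodes:
        own = modules[node]
        own_degree[node] = sum(1 for nb in net[node] if modules[nb] == own)
    stats_by_module = {}
    for mod in set(modules.values()):
        ks = np.array([own_degree[n] for n in net.nodes if modules[n] == mod], dtype=float)
        stats_by_module[mod] = (ks.mean(), ks.std())

    rows = []
    for node in net.nodes:
        k = net.degree(node)
        mean_own, sd_own = stats_by_module[modules[node]]
        zi = 0.0 if sd_own == 0 else (own_degree[node] - mean_own) / sd_own
        if k == 0:
            pi = 0.0
        else:
            per_module: dict[str, int] = {}
            for nb in net[node]:
                per_module[modules[nb]] = per_module.get(modules[nb], 0) + 1
            pi = 1.0 - sum((km / k) ** 2 for km in per_module.values())
        rows.append({"node": node, "module": modules[node], "degree": k,
                     "zi": zi, "pi": pi})
    return pd.DataFrame(rows).set_index("node")


def classify_roles(zipi: pd.DataFrame, zi_thresh: float = ZI_THRESHOLD,
                   pi_thresh: float = PI_THRESHOLD) -> pd.DataFrame:
    """Assign each node one of the four (Zi, Pi) roles.

    Strict inequalities, matching the published rules; equality at a
    threshold falls to the non-hub / non-connector side.
    """
    out = zipi.copy()
    is_hub = out["zi"] > zi_thresh
    is_conn = out["pi"] > pi_thresh
    role = np.where(is_hub & is_conn, "network_hub",
           np.where(is_hub, "module_hub",
           np.where(is_conn, "connector", "peripheral")))
    out["role"] = role
    return out
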