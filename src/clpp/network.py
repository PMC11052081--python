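"""Co-occurrence network construction over abundant ASVs.

The construction follows the rank-correlation route common in microbial
ecology: restrict to the most abundant ASVs, compute all pairwise Spearman
correlations on relative abundances, keep the pairs that are both strong
(|rho| above a threshold) and significant after Benjamini-Hochberg FDR
control, and summarize the resulting signed graph by its Louvain modularity
and the proportion of positive edges overall and per taxonomic stratum.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr
from statsmodels.stats.multitest import multipletests

from .community import relative_abundance, validate_asv_table
from .errors import ClppError, NetworkError, TableError

DEFAULT_TOP_K = 200
DEFAULT_R_THRESHOLD = 0.6
DEFAULT_ALPHA = 0.05


def select_top_asvs(table: pd.DataFrame, k: int = DEFAULT_TOP_K) -> pd.DataFrame:
    """Keep the k ASVs with the highest total relative abundance across samples.

    Ties are broken lexicographically by ASV id.  If the table has fewer than
    k ASVs, all are retained with a warning.
    """
    validate_asv_table(table)
    if table.shape[1] == 0:
        raise TableError("empty ASV table")
    if k > table.shape[1]:
        warnings.warn(
            f"requested top {k} ASVs but table has only {table.shape[1]}; keeping all",
            stacklevel=2,
        )
        k = table.shape[1]
    totals = relative_abundance(table).sum(axis=0)
    order = sorted(table.columns, key=lambda a: (-totals[a], str(a)))
    keep = order[:k]
    return table[keep]


def spearman_matrix(
    table: pd.DataFrame, exact_p: bool = False, basis: str = "counts"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs Spearman rho and two-sided p over ASVs.

    Ties get midranks; p-values come from the t-distribution approximation
    with n-2 degrees of freedom, or from exhaustive rank permutations when
    ``exact_p=True`` (only sensible for very small sample counts).
    Zero-variance ASVs are excluded with a warning.

    ``basis="counts"`` (default) correlates the abundances as given;
    ``basis="relative"`` row-normalizes first.  Per-sample normalization puts
    a shared total in every denominator and thereby *injects* cross-taxon
    rank correlations whenever sample totals vary (the classic
    compositionality artifact), so it is not the default.
    """
    n = table.shape[0]
    if n < 4:
        raise ClppError("need at least 4 samples for correlation screening")
    if basis == "counts":
        data = validate_asv_table(table)
    elif basis == "relative":
        data = relative_abundance(table)
    else:
        raise ClppError(f"unknown basis {basis!r}")
    variances = data.var(axis=0)
    constant = list(data.columns[variances == 0])
    if constant:
        warnings.warn(f"excluding {len(constant)} constant ASV(s): {constant[:5]}...", stacklevel=2)
        data = data.drop(columns=constant)
    if data.shape[1] < 2:
        raise ClppError("fewer than 2 non-constant ASVs")
    rho, p = spearmanr(data.to_numpy(), axis=0)
    if np.ndim(rho) == 0:  # scipy returns scalars for exactly 2 variables
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
        p = np.array([[0.0, float(p)], [float(p), 0.0]])
    np.fill_diagonal(rho, 1.0)
    np.fill_diagonal(p, 0.0)
    if exact_p:
        if n > 8:
            raise ClppError("exact permutation p only supported for n <= 8 samples")
        p = _exact_spearman_p(data.to_numpy(), rho)
    cols = data.columns
    return (
        pd.DataFrame(rho, index=cols, columns=cols),
        pd.DataFrame(p, index=cols, columns=cols),
    )


def _exact_spearman_p(data: np.ndarray, rho: np.ndarray) -> np.ndarray:
    """Two-sided p by enumerating all rank permutations of one variable."""
    n, m = data.shape
    ranks = np.apply_along_axis(rankdata, 0, data)
    perms = np.array(list(itertools.permutations(range(n))))
    p = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            ri = ranks[:, i]
            null = np.array([np.corrcoef(ri[perm], ranks[:, j])[0, 1] for perm in perms])
            p[i, j] = p[j, i] = np.mean(np.abs(null) >= abs(rho[i, j]) - 1e-12)
    return p


def bh_fdr(p_values: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any() or not np.isfinite(p).all():
        raise ClppError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def adjust_p_matrix(p: pd.DataFrame) -> pd.DataFrame:
    """BH-adjust the strict upper triangle of a symmetric p-value matrix."""
    arr = p.to_numpy(dtype=float)
    iu = np.triu_indices(arr.shape[0], k=1)
    adj = np.zeros_like(arr)
    adj[iu] = bh_fdr(arr[iu])
    adj = adj + adj.T
    return pd.DataFrame(adj, index=p.index, columns=p.columns)


@dataclass
class CoocNetwork:
    """Signed, weighted co-occurrence graph with taxonomy on the nodes."""

    graph: nx.Graph  # nodes carry domain/phylum/class; edges carry rho/sign/p_adj
    r_threshold: float
    alpha: float
    partition: dict = field(default_factory=dict)  # node -> module id
    modularity_q: float | None = None

    @property
    def nodes(self) -> list:
        return list(self.graph.nodes)

    @property
    def edges(self) -> pd.DataFrame:
        rows = [
            {
                "source": u,
                "target": v,
                "rho": d["rho"],
                "sign": d["sign"],
                "p_adj": d["p_adj"],
            }
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["source", "target", "rho", "sign", "p_adj"])

    @property
    def isolated_nodes(self) -> list:
        return [n for n in self.graph.nodes if self.graph.degree(n) == 0]

    def node_table(self) -> pd.DataFrame:
        rows = [
            {
                "id": n,
                "domain": d.get("domain"),
                "phylum": d.get("phylum"),
                "class": d.get("class"),
                "module": self.partition.get(n),
            }
            for n, d in self.graph.nodes(data=True)
        ]
        return pd.DataFrame(rows)


def build_network(
    rho: pd.DataFrame,
    p_adj: pd.DataFrame,
    taxonomy: pd.DataFrame,
    r_threshold: float = DEFAULT_R_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
) -> CoocNetwork:
    """Keep undirected edges with |rho| > r_threshold AND adjusted p < alpha.

    Nodes without any qualifying edge are retained (flagged via
    :attr:`CoocNetwork.isolated_nodes`).  Edge sign is the sign of rho.
    """
    if rho.shape != p_adj.shape or not rho.index.equals(p_adj.index):
        raise NetworkError("rho and p_adj matrices are not conformable")
    missing = set(rho.index) - set(taxonomy.index)
    if missing:
        raise NetworkError(f"taxonomy missing for ASV(s): {sorted(missing)[:5]}")
    g = nx.Graph()
    for asv in rho.index:
        tax = taxonomy.loc[asv]
        g.add_node(asv, domain=tax["domain"], phylum=tax["phylum"], **{"class": tax["class"]})
    ids = list(rho.index)
    r = rho.to_numpy()
    q = p_adj.to_numpy()
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if abs(r[i, j]) > r_threshold and q[i, j] < alpha:
                g.add_edge(
                    ids[i],
                    ids[j],
                    rho=float(r[i, j]),
                    sign=int(math.copysign(1, r[i, j])),
                    p_adj=float(q[i, j]),
                )
    return CoocNetwork(g, r_threshold, alpha)


def modularity(
    network: CoocNetwork | nx.Graph,
    seed: int = 0,
    resolution: float = 1.0,
    signed: bool = False,
) -> tuple[dict, float | None]:
    """Louvain partition and Newman-Girvan modularity Q.

    By default Q is computed on the unweighted, sign-agnostic edge set;
    ``signed=True`` uses |rho| edge weights instead (non-default).  Returns
    ``({}, None)`` for an edgeless graph.  The partition is stored on the
    network when one is passed.
    """
    g = network.graph if isinstance(network, CoocNetwork) else network
    if g.number_of_edges() == 0:
        if isinstance(network, CoocNetwork):
            network.partition, network.modularity_q = {}, None
        return {}, None
    weight = None
    h = g
    if signed:
        h = g.copy()
        for _, _, d in h.edges(data=True):
            d["abs_rho"] = abs(d.get("rho", 1.0))
        weight = "abs_rho"
    communities = nx.community.louvain_communities(
        h, weight=weight, resolution=resolution, seed=seed
    )
    q = nx.community.modularity(h, communities, weight=weight, resolution=resolution)
    partition = {n: i for i, com in enumerate(communities) for n in com}
    if isinstance(network, CoocNetwork):
        network.partition, network.modularity_q = partition, float(q)
    return partition, float(q)


def edge_sign_summary(network: CoocNetwork) -> pd.DataFrame:
    """Proportion of positive edges overall and per taxonomy stratum.

    Strata: overall, archaea-archaea, bacteria-bacteria, archaea-bacteria,
    and each unordered phylum pair.  Strata without edges are omitted.
    """
    rows = []

    def stratum(name: str, signs: list[int]) -> None:
        if signs:
            pos = sum(1 for s in signs if s > 0)
            rows.append(
                {
                    "stratum": name,
                    "n_edges": len(signs),
                    "positive_fraction": pos / len(signs),
                    "negative_fraction": 1 - pos / len(signs),
                }
            )

    g = network.graph
    all_signs = [d["sign"] for _, _, d in g.edges(data=True)]
    stratum("overall", all_signs)

    domain_pairs: dict[str, list[int]] = {
        "archaea-archaea": [],
        "bacteria-bacteria": [],
        "archaea-bacteria": [],
    }
    phylum_pairs: dict[str, list[int]] = {}
    for u, v, d in g.edges(data=True):
        du, dv = g.nodes[u]["domain"].lower(), g.nodes[v]["domain"].lower()
        key = f"{min(du, dv)}-{max(du, dv)}"
        domain_pairs.setdefault(key, []).append(d["sign"])
        pu, pv = sorted([g.nodes[u]["phylum"], g.nodes[v]["phylum"]])
        phylum_pairs.setdefault(f"{pu}|{pv}", []).append(d["sign"])
    for name in ("archaea-archaea", "bacteria-bacteria", "archaea-bacteria"):
        stratum(name, domain_pairs.get(name, []))
    for name in sorted(phylum_pairs):
        stratum(name, phylum_pairs[name])
    return pd.DataFrame(rows, columns=["stratum", "n_edges", "positive_fraction", "negative_fraction"])


def cooccurrence_network(
    table: pd.DataFrame,
    taxonomy: pd.DataFrame,
    top_k: int = DEFAULT_TOP_K,
    r_threshold: float = DEFAULT_R_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
    seed: int = 0,
    exact_p: bool = False,
    basis: str = "counts",
) -> CoocNetwork:
    """Full construction: top-k selection, Spearman screen, BH-FDR, Louvain."""
    top = select_top_asvs(table, k=top_k)
    rho, p = spearman_matrix(top, exact_p=exact_p, basis=basis)
    p_adj = adjust_p_matrix(p)
    net = build_network(rho, p_adj, taxonomy, r_threshold=r_threshold, alpha=alpha)
    modularity(net, seed=seed)
    return net
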