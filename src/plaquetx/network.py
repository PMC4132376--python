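"""Signed Spearman co-abundance networks ("complexes").

Whether taxa rise and fall together across subjects is assessed with rank
correlation of their scaled-log2 abundances. Edges passing an absolute-rho
threshold (optionally with Benjamini-Hochberg FDR control on the
two-sided rank-correlation p-values) form a signed graph; its connected
components — connectivity through edges of either sign — are the
co-abundance complexes, and each node's balance of positive versus
negative edges identifies predominantly anti-correlated taxa.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .datatypes import NetworkError, TaxonProfile


def rank_correlation(rows: np.ndarray) -> np.ndarray:
    """Spearman rho between rows: average ranks (ties averaged), then
    Pearson correlation of the rank vectors. Constant rows give NaN."""
    ranks = rankdata(rows, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.corrcoef(ranks)


def spearman_matrix(profile: TaxonProfile | pd.DataFrame, layer: str = "scaled_log2") -> pd.DataFrame:
    """Taxa x taxa Spearman rho across subjects (average ranks for ties).

    Constant taxa have undefined rank correlation: their off-diagonal
    entries are NaN (and they can never form edges). The diagonal is 1.
    """
    mat = profile.layer(layer) if isinstance(profile, TaxonProfile) else profile
    if mat.shape[1] < 3:
        raise NetworkError("Spearman matrix needs at least 3 subjects")
    if mat.shape[0] < 2:
        raise NetworkError("Spearman matrix needs at least 2 taxa")
    rho = rank_correlation(mat.to_numpy())
    constant = mat.nunique(axis=1).to_numpy() <= 1
    rho[constant, :] = np.nan
    rho[:, constant] = np.nan
    np.fill_diagonal(rho, 1.0)
    rho = np.clip((rho + rho.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=mat.index, columns=mat.index)


def _rho_pvalues(rho: pd.DataFrame, n_subjects: int) -> pd.DataFrame:
    """Two-sided p-values for rank correlations via the t approximation."""
    from scipy.stats import t as t_dist

    r = rho.to_numpy().astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = r * np.sqrt((n_subjects - 2) / (1.0 - r**2))
        p = 2.0 * t_dist.sf(np.abs(tstat), df=n_subjects - 2)
    p[np.abs(r) >= 1.0] = 0.0
    p[np.isnan(r)] = np.nan
    np.fill_diagonal(p, 0.0)
    return pd.DataFrame(p, index=rho.index, columns=rho.columns)


@dataclass
class CorrelationNetwork:
    """Signed, thresholded co-abundance graph over taxa."""

    nodes: list[str]
    rho: pd.DataFrame
    edges: pd.DataFrame  # source, target, rho, sign, weight, p, q
    min_abs_rho: float
    fdr_q: float | None
    n_subjects: int
    complexes: list[dict] = field(default_factory=list)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for _, e in self.edges.iterrows():
            g.add_edge(
                e["source"], e["target"],
                rho=float(e["rho"]), sign=int(e["sign"]), weight=float(e["weight"]),
            )
        return g

    def write_edges(self, path: str | Path) -> None:
        self.edges.to_csv(path, sep="\t", index=False)

    def write_rho(self, path: str | Path) -> None:
        df = self.rho.copy()
        df.index.name = "taxon"
        df.to_csv(path, sep="\t")

    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.graph(), path)

    def write_complexes(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.complexes, indent=2))


def extract_network(
    rho: pd.DataFrame,
    min_abs_rho: float = 0.5,
    fdr_q: float | None = 0.05,
    n_subjects: int | None = None,
) -> CorrelationNetwork:
    """Threshold a rho matrix into a signed edge list.

    An edge (a, b) is retained iff |rho| >= ``min_abs_rho`` and, when
    ``fdr_q`` is set, its two-sided rank-correlation p-value passes
    Benjamini-Hochberg at that q over all candidate pairs. Edge sign is
    sign(rho), weight is |rho|. NaN correlations (constant taxa) never
    form edges.
    """
    if not 0.0 <= min_abs_rho <= 1.0:
        raise NetworkError(f"min_abs_rho must lie in [0, 1], got {min_abs_rho}")
    if fdr_q is not None and not 0.0 < fdr_q <= 1.0:
        raise NetworkError(f"fdr_q must lie in (0, 1], got {fdr_q}")
    taxa = list(rho.index)
    r = rho.to_numpy()
    iu = np.triu_indices(len(taxa), k=1)
    pairs = pd.DataFrame(
        {
            "source": np.array(taxa)[iu[0]],
            "target": np.array(taxa)[iu[1]],
            "rho": r[iu],
        }
    ).dropna(subset=["rho"])

    if fdr_q is not None:
        if n_subjects is None:
            raise NetworkError("FDR control requires n_subjects")
        pmat = _rho_pvalues(rho, n_subjects).to_numpy()
        pairs["p"] = pmat[iu][pairs.index]
        reject, qvals, _, _ = multipletests(pairs["p"].to_numpy(), alpha=fdr_q, method="fdr_bh")
        pairs["q"] = qvals
        keep = reject & (pairs["rho"].abs().to_numpy() >= min_abs_rho)
    else:
        pairs["p"] = np.nan
        pairs["q"] = np.nan
        keep = pairs["rho"].abs().to_numpy() >= min_abs_rho

    edges = pairs[keep].copy()
    edges["sign"] = np.sign(edges["rho"]).astype(int)
    edges["weight"] = edges["rho"].abs()
    edges = edges[["source", "target", "rho", "sign", "weight", "p", "q"]].reset_index(drop=True)
    return CorrelationNetwork(
        nodes=taxa,
        rho=rho,
        edges=edges,
        min_abs_rho=min_abs_rho,
        fdr_q=fdr_q,
        n_subjects=n_subjects if n_subjects is not None else -1,
    )


def find_complexes(network: CorrelationNetwork) -> list[dict]:
    """Connected components of the retained-edge graph.

    Connectivity runs through edges of either sign; each complex is
    reported with its members and positive/negative edge counts (mixed-sign
    complexes are expected and kept whole). Isolated nodes belong to no
    complex. Complexes are numbered by decreasing size, ties by member name.
    """
    g = network.graph()
    comps = []
    for members in nx.connected_components(g):
        if len(members) < 2:
            continue
        sub = g.subgraph(members)
        signs = [d["sign"] for _, _, d in sub.edges(data=True)]
        comps.append(
            {
                "members": sorted(members),
                "n_members": len(members),
                "n_edges": sub.number_of_edges(),
                "n_positive": int(sum(s > 0 for s in signs)),
                "n_negative": int(sum(s < 0 for s in signs)),
            }
        )
    comps.sort(key=lambda c: (-c["n_members"], c["members"]))
    for i, c in enumerate(comps):
        c["complex_id"] = f"complex_{i + 1}"
    network.complexes = comps
    return comps


def node_sign_profile(network: CorrelationNetwork, flag_threshold: float = 0.8) -> pd.DataFrame:
    """Per-node retained degree and negative-edge fraction.

    Nodes whose retained edges are >= ``flag_threshold`` negative are
    flagged ``predominantly_anticorrelated`` — the signature of an
    antagonist taxon whose activity runs against the rest of its complex.
    Isolated nodes have degree 0, NaN fraction, and are never flagged.
    """
    g = network.graph()
    rows = []
    for node in network.nodes:
        signs = [d["sign"] for _, _, d in g.edges(node, data=True)]
        degree = len(signs)
        neg_frac = (sum(s < 0 for s in signs) / degree) if degree else float("nan")
        rows.append(
            {
                "taxon": node,
                "degree": degree,
                "negative_fraction": neg_frac,
                "predominantly_anticorrelated": bool(degree and neg_frac >= flag_threshold),
            }
        )
    return pd.DataFrame(rows).set_index("taxon")
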