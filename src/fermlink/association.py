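"""Genus-flavour correlation networks.

Pairwise Pearson (optionally Spearman) correlations between every genus
profile and every flavour profile across the fermentation samples,
thresholded into an edge set (moderate |rho| > 0.7, high |rho| > 0.8 in
the standard workflow).  Thresholds are strict inequalities.  Constant
profiles have undefined correlation; they are stored as zero, flagged,
and never produce edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from fermlink.tables import AbundanceTable, FlavourTable

FLAVOUR_SETS = {"organic_acid": "OA", "amino_acid": "AA", "volatile": "VF"}


class AssociationError(ValueError):
    pass


def correlation_matrix(abundance: AbundanceTable, flavours: FlavourTable,
                       method: str = "pearson") -> pd.DataFrame:
    """Genus x flavour correlation matrix across aligned samples.

    Correlations involving a constant genus or flavour profile are set to
    zero (flagged via ``attrs['undefined']``) and are excluded from any
    thresholded edge set downstream.
    """
    if list(abundance.samples) != list(flavours.samples):
        raise AssociationError("abundance and flavour samples are not aligned")
    n = len(abundance.samples)
    if n < 3:
        raise AssociationError(f"need at least 3 samples, got {n}")
    A = abundance.values.to_numpy(dtype=float)
    F = flavours.values.to_numpy(dtype=float)
    if method == "spearman":
        A = np.apply_along_axis(stats.rankdata, 1, A)
        F = np.apply_along_axis(stats.rankdata, 1, F)
    elif method != "pearson":
        raise AssociationError(f"unknown method {method!r}")
    Ac = A - A.mean(axis=1, keepdims=True)
    Fc = F - F.mean(axis=1, keepdims=True)
    a_sd = np.sqrt((Ac ** 2).sum(axis=1))
    f_sd = np.sqrt((Fc ** 2).sum(axis=1))
    const_a = a_sd == 0
    const_f = f_sd == 0
    a_sd[const_a] = 1.0
    f_sd[const_f] = 1.0
    R = (Ac @ Fc.T) / np.outer(a_sd, f_sd)
    R[const_a, :] = 0.0
    R[:, const_f] = 0.0
    out = pd.DataFrame(R, index=abundance.taxa, columns=flavours.flavours)
    out.attrs["undefined"] = {
        "taxa": abundance.taxa[const_a].tolist(),
        "flavours": flavours.flavours[const_f].tolist(),
    }
    out.attrs["method"] = method
    return out


@dataclass
class AssociationNetwork:
    """Thresholded genus-flavour edge set with per-genus tallies."""

    threshold: float
    edges: pd.DataFrame            # columns: genus, kingdom, flavour, category, subcategory, rho, sign
    genus_counts: pd.DataFrame     # per-genus: total, OA, AA, VF, sugar edge counts

    def n_edges(self) -> int:
        return len(self.edges)

    def recompute_counts(self) -> pd.DataFrame:
        """Re-tally per-genus counts from the edge list (consistency check)."""
        return _tally(self.edges, self.genus_counts.index)


def _tally(edges: pd.DataFrame, genera) -> pd.DataFrame:
    counts = pd.DataFrame(
        0, index=pd.Index(genera, name="genus"),
        columns=["total", "OA", "AA", "VF", "sugar"],
    )
    if len(edges):
        counts["total"] = edges.groupby("genus").size().reindex(genera, fill_value=0)
        for cat, col in (("organic_acid", "OA"), ("amino_acid", "AA"),
                         ("volatile", "VF"), ("sugar", "sugar")):
            sub = edges[edges["category"] == cat]
            counts[col] = sub.groupby("genus").size().reindex(genera, fill_value=0)
    return counts


def threshold_edges(corr: pd.DataFrame, abundance: AbundanceTable,
                    flavours: FlavourTable, threshold: float = 0.7) -> AssociationNetwork:
    """Edges where |rho| strictly exceeds the threshold.

    Undefined (constant-profile) entries never become edges even if a
    numerical artefact placed them above the threshold.
    """
    if not (0.0 < threshold < 1.0):
        raise AssociationError("threshold must lie in (0, 1)")
    R = corr.to_numpy()
    mask = np.abs(R) > threshold
    undef = corr.attrs.get("undefined", {})
    for t in undef.get("taxa", []):
        mask[corr.index.get_loc(t), :] = False
    for f in undef.get("flavours", []):
        mask[:, corr.columns.get_loc(f)] = False
    gi, fi = np.where(mask)
    edges = pd.DataFrame({
        "genus": corr.index[gi],
        "kingdom": abundance.kingdom.loc[corr.index[gi]].to_numpy(),
        "flavour": corr.columns[fi],
        "category": flavours.category.loc[corr.columns[fi]].to_numpy(),
        "subcategory": flavours.subcategory.loc[corr.columns[fi]].to_numpy(),
        "rho": R[gi, fi],
    })
    edges["sign"] = np.where(edges["rho"] > 0, "positive", "negative")
    return AssociationNetwork(
        threshold=threshold,
        edges=edges,
        genus_counts=_tally(edges, corr.index),
    )


def flavour_set_membership(network: AssociationNetwork) -> pd.DataFrame:
    """Per-genus membership in the OA / AA / VF flavour sets.

    A genus belongs to a set when it has at least one edge to a flavour of
    that category at the network's threshold.  Sugars are tracked in a
    separate column and excluded from the three-set logic.
    """
    counts = network.genus_counts
    out = pd.DataFrame({
        "OA": counts["OA"] > 0,
        "AA": counts["AA"] > 0,
        "VF": counts["VF"] > 0,
        "sugar": counts["sugar"] > 0,
    }, index=counts.index)
    out["sets"] = out.apply(
        lambda r: frozenset(s for s in ("OA", "AA", "VF") if r[s]), axis=1,
    )
    return out


def export_graph(network: AssociationNetwork, edge_path: str | Path,
                 graphml_path: str | Path | None = None) -> None:
    """Write the network as an edge-list TSV and (optionally) GraphML.

    Node attributes carry kingdom (genera) and category/subcategory
    (flavours); edge attributes carry rho and its sign.
    """
    cols = ["genus", "kingdom", "flavour", "category", "subcategory", "rho", "sign"]
    network.edges[cols].to_csv(edge_path, sep="\t", index=False)
    if graphml_path is None:
        return
    import networkx as nx

    G = nx.Graph()
    for row in network.edges.itertuples(index=False):
        G.add_node(row.genus, node_type="genus", kingdom=row.kingdom)
        G.add_node(row.flavour, node_type="flavour", category=row.category,
                   subcategory=row.subcategory or "")
        G.add_edge(row.genus, row.flavour, rho=float(row.rho), sign=row.sign)
    nx.write_graphml(G, graphml_path)


def import_graph(graphml_path: str | Path):
    """Round-trip helper: read a GraphML network back as a networkx graph."""
    import networkx as nx

    return nx.read_graphml(graphml_path)
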