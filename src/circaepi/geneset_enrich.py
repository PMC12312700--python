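"""Gene-set over-representation analysis and kappa-score term networks.

ORA: per term, the upper-tail hypergeometric probability of drawing at least
the observed overlap between a gene list and the term's universe members,
with Benjamini-Hochberg FDR across terms and the gene ratio k/n (term hits
over list size).

Term similarity: each term is treated as a binary rater over the gene
universe; Cohen's kappa = (Pr(a) - Pr(e)) / (1 - Pr(e)) where Pr(a) is the
observed co-membership agreement and Pr(e) the chance agreement from the
marginals. Significant terms are linked when kappa >= a threshold (default
0.4) and functional groups are the connected components of that graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneSetCollection

__all__ = [
    "ora",
    "KappaEdge",
    "kappa",
    "kappa_network",
    "DEFAULT_KAPPA_THRESHOLD",
]

DEFAULT_KAPPA_THRESHOLD = 0.4


def ora(
    list_genes: Iterable[str],
    universe: Iterable[str],
    collection: GeneSetCollection,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a gene list in each term.

    Per term: k = list genes in the term, K = universe genes in the term,
    n = list size, N = universe size; p = P(overlap >= k) upper tail;
    gene_ratio = k/n; BH FDR across the tested terms. Terms with no universe
    members are skipped with a warning.
    """
    lst = set(list_genes)
    uni = set(universe)
    if not lst <= uni:
        raise ValueError("gene list is not a subset of the universe")
    if not lst:
        raise ValueError("empty gene list")
    N, n = len(uni), len(lst)
    rows = []
    for term, (desc, members) in collection.sets.items():
        K = len(set(members) & uni)
        if K == 0:
            warnings.warn(f"term {term!r} has no universe members; skipped")
            continue
        k = len(set(members) & lst)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "term_id": term,
                "description": desc,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "gene_ratio": k / n,
                "p": min(p, 1.0),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


@dataclass(frozen=True)
class KappaEdge:
    """Cohen's kappa between two terms rated over a common gene universe."""

    term_a: str
    term_b: str
    kappa: float
    pr_a: float
    pr_e: float


def kappa(
    term_a_members: Iterable[str],
    term_b_members: Iterable[str],
    universe: Iterable[str],
    term_a: str = "A",
    term_b: str = "B",
) -> KappaEdge:
    """Cohen's kappa of two gene sets as binary raters over the universe.

    kappa = (Pr(a) - Pr(e)) / (1 - Pr(e)). Identical sets give kappa = 1
    (including both-constant-and-equal raters, where Pr(e) = 1); constant but
    different raters give kappa = 0 with a warning.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    a = set(term_a_members) & uni
    b = set(term_b_members) & uni
    N = len(uni)
    n11 = len(a & b)
    n10 = len(a - b)
    n01 = len(b - a)
    n00 = N - n11 - n10 - n01
    pr_a = (n11 + n00) / N
    pa, pb = len(a) / N, len(b) / N
    pr_e = pa * pb + (1 - pa) * (1 - pb)
    constant_a = pa in (0.0, 1.0)
    constant_b = pb in (0.0, 1.0)
    if constant_a and constant_b:
        # degenerate raters: equal -> perfect agreement by convention
        if a == b:
            return KappaEdge(term_a, term_b, 1.0, pr_a, pr_e)
        warnings.warn("kappa: constant but different raters; kappa set to 0")
        return KappaEdge(term_a, term_b, 0.0, pr_a, pr_e)
    if pr_e >= 1.0:
        return KappaEdge(term_a, term_b, 1.0 if a == b else 0.0, pr_a, pr_e)
    k = (pr_a - pr_e) / (1.0 - pr_e)
    if a == b:
        k = 1.0
    return KappaEdge(term_a, term_b, float(k), pr_a, pr_e)


def kappa_network(
    significant_terms: Sequence[str] | pd.DataFrame,
    collection: GeneSetCollection,
    universe: Iterable[str],
    kappa_threshold: float = DEFAULT_KAPPA_THRESHOLD,
    significance_column: str = "fdr",
    significance_level: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Kappa-similarity network over significant terms.

    ``significant_terms`` is either an explicit term list or an ORA result
    table, in which case terms with ``significance_column`` <= level are
    admitted. Undirected edges link term pairs with kappa >= threshold;
    functional groups are the numbered connected components (singletons
    included). Returns (edge table, node table); the node table carries the
    component label and the term's mapped-gene count.
    """
    if isinstance(significant_terms, pd.DataFrame):
        mask = significant_terms[significance_column] <= significance_level
        terms = list(significant_terms.loc[mask, "term_id"])
    else:
        terms = list(significant_terms)
    uni = set(universe)
    members = {t: collection.members(t) & uni for t in terms}
    edges = []
    g = nx.Graph()
    g.add_nodes_from(terms)
    for i, ta in enumerate(terms):
        for tb in terms[i + 1 :]:
            e = kappa(members[ta], members[tb], uni, ta, tb)
            if e.kappa >= kappa_threshold:
                edges.append(
                    {
                        "term_a": ta,
                        "term_b": tb,
                        "kappa": e.kappa,
                        "pr_a": e.pr_a,
                        "pr_e": e.pr_e,
                    }
                )
                g.add_edge(ta, tb)
    edge_df = pd.DataFrame(edges, columns=["term_a", "term_b", "kappa", "pr_a", "pr_e"])
    comp_label = {}
    for i, comp in enumerate(
        sorted(nx.connected_components(g), key=lambda c: sorted(c)[0]), start=1
    ):
        for t in comp:
            comp_label[t] = i
    node_df = pd.DataFrame(
        {
            "term_id": terms,
            "component": [comp_label[t] for t in terms],
            "n_mapped_genes": [len(members[t]) for t in terms],
        }
    )
    return edge_df, node_df
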