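"""Co-abundance networks and cooperatives.

Neighborhood-selection (Meinshausen-Buhlmann style) sparse regression on
clr-transformed abundances with stability subsampling, a StARS-style
penalty choice, Louvain clustering of the resulting graph, and
cluster-vs-rest cooperative balances with their factor associations.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.linear_model import lasso_path

from ._lm import encode_factor, ols_many
from .balances import Balance, balance_values
from .coda import DEFAULT_PSEUDOCOUNT, clr, zero_replace
from .design import AssociationDesign
from .io import CountTable
from .stats import bh_adjust

logger = logging.getLogger(__name__)


def prevalence_filter(
    table: CountTable, min_count: int = 10, min_samples: int = 10
) -> CountTable:
    """Keep taxa with count > ``min_count`` in > ``min_samples`` samples.

    Both inequalities are strict. Raises if nothing survives.
    """
    hits = (table.counts > min_count).sum(axis=1)
    kept = table.counts.index[hits > min_samples].tolist()
    if not kept:
        raise ValueError(
            f"no taxa with >{min_count} reads in >{min_samples} samples; "
            "relax the thresholds"
        )
    return table.subset_taxa(kept)


@dataclass
class CoabundanceNetwork:
    """Undirected stability-selected co-abundance graph."""

    nodes: tuple[str, ...]
    edges: dict[frozenset, float]  # pair -> selection frequency
    lambda_path: np.ndarray
    chosen_lambda: float
    instability: np.ndarray
    params: dict = field(default_factory=dict)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def density(self) -> float:
        d = len(self.nodes)
        possible = d * (d - 1) / 2
        return self.n_edges / possible if possible else 0.0

    def to_graph(self) -> nx.Graph:
        """Graph over edge endpoints only (isolated taxa are excluded)."""
        g = nx.Graph()
        for pair, freq in sorted(
            self.edges.items(), key=lambda kv: tuple(sorted(kv[0]))
        ):
            a, b = sorted(pair)
            g.add_edge(a, b, weight=float(freq))
        return g

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"taxon_a": min(pair), "taxon_b": max(pair), "frequency": freq}
            for pair, freq in self.edges.items()
        ]
        rows.sort(key=lambda r: (r["taxon_a"], r["taxon_b"]))
        return pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "frequency"])

    def to_tsv(self, path) -> None:
        self.edge_table().to_csv(path, sep="\t", index=False)

    def to_gml(self, path) -> None:
        nx.write_gml(self.to_graph(), path)


def mb_network(
    table: CountTable,
    n_subsamples: int = 10,
    n_lambda: int = 10,
    lambda_min_ratio: float = 0.2,
    selection_threshold: float = 0.8,
    instability_target: float = 0.05,
    subsample_ratio: float = 0.8,
    seed: int = 0,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    lambda_min_absolute: float | None = None,
) -> CoabundanceNetwork:
    """Stability-selected neighborhood-selection network on clr abundances.

    Each taxon's clr profile is lasso-regressed on all others over a
    log-spaced path of ``n_lambda`` penalties from the smallest
    empty-model penalty down to ``lambda_min_ratio`` times it (or down to
    ``lambda_min_absolute`` if given). Selection frequencies are collected
    over ``n_subsamples`` random subsamples of ``subsample_ratio`` of the
    samples; the penalty is chosen as the densest one whose monotonized
    edge instability stays at or below ``instability_target``. An
    undirected edge is kept when either direction's selection frequency
    reaches ``selection_threshold``.
    """
    n = len(table.samples)
    min_needed = max(10, int(np.ceil(1 / (1 - subsample_ratio))))
    if n < min_needed:
        raise ValueError(f"need at least {min_needed} samples, got {n}")
    comp = zero_replace(table, pseudocount)
    X_full = clr(comp).to_numpy(dtype=float)
    taxa = list(comp.columns)
    D = len(taxa)

    Xc = X_full - X_full.mean(axis=0)
    lambda_max = max(
        float(np.abs(np.delete(Xc, j, axis=1).T @ Xc[:, j]).max()) / n
        for j in range(D)
    )
    lo = lambda_min_absolute if lambda_min_absolute is not None else (
        lambda_min_ratio * lambda_max
    )
    alphas = np.logspace(np.log10(lambda_max), np.log10(lo), n_lambda)

    rng = np.random.default_rng(seed)
    m = int(np.floor(subsample_ratio * n))
    # presence[s, l] boolean adjacency per subsample and lambda (or-rule)
    directed = np.zeros((n_subsamples, n_lambda, D, D), dtype=bool)
    for s in range(n_subsamples):
        idx = rng.choice(n, size=m, replace=False)
        Xs = X_full[idx]
        Xs = Xs - Xs.mean(axis=0)
        for j in range(D):
            others = np.delete(np.arange(D), j)
            _, coefs, _ = lasso_path(Xs[:, others], Xs[:, j], alphas=alphas)
            nz = coefs != 0  # (D-1, n_lambda)
            for li in range(n_lambda):
                directed[s, li, j, others] = nz[:, li]

    sym = directed | directed.transpose(0, 1, 3, 2)  # or-rule
    iu = np.triu_indices(D, k=1)
    theta = sym.mean(axis=0)[:, iu[0], iu[1]]  # (n_lambda, n_pairs)
    instability = (2 * theta * (1 - theta)).mean(axis=1)
    # alphas run dense->... actually from lambda_max (sparsest) downward
    monotone = np.maximum.accumulate(instability)
    ok = np.nonzero(monotone <= instability_target)[0]
    chosen_idx = int(ok.max()) if ok.size else 0
    chosen_lambda = float(alphas[chosen_idx])

    freq_dir = directed[:, chosen_idx].mean(axis=0)  # (D, D)
    freq_sym = np.maximum(freq_dir, freq_dir.T)
    edges: dict[frozenset, float] = {}
    for a, b in zip(*np.nonzero(np.triu(freq_sym >= selection_threshold, k=1))):
        edges[frozenset((taxa[a], taxa[b]))] = float(freq_sym[a, b])

    return CoabundanceNetwork(
        nodes=tuple(taxa),
        edges=edges,
        lambda_path=alphas,
        chosen_lambda=chosen_lambda,
        instability=instability,
        params={
            "n_subsamples": n_subsamples,
            "n_lambda": n_lambda,
            "lambda_min_ratio": lambda_min_ratio,
            "lambda_min_absolute": lambda_min_absolute,
            "selection_threshold": selection_threshold,
            "instability_target": instability_target,
            "subsample_ratio": subsample_ratio,
            "seed": seed,
        },
    )


def louvain_clusters(
    net: CoabundanceNetwork, seed: int = 0
) -> list[frozenset]:
    """Louvain modularity communities of the network's non-isolated nodes.

    Returns an empty list for an edgeless network. Deterministic given the
    seed; clusters are sorted by their smallest member for stable output.
    """
    graph = net.to_graph()
    if graph.number_of_edges() == 0:
        return []
    communities = nx.community.louvain_communities(graph, seed=seed)
    return sorted((frozenset(c) for c in communities), key=lambda c: min(c))


@dataclass
class Cooperative:
    """A co-abundance cluster summarized as a cluster-vs-rest balance."""

    members: tuple[str, ...]
    balance: Balance
    factor: str
    slope: float
    p: float
    q: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "members": list(self.members),
            "balance": self.balance.to_dict(),
            "factor": self.factor,
            "slope": self.slope,
            "p": self.p,
            "q": self.q,
        }


def cooperative_balance(members, all_taxa) -> Balance:
    """Balance with the cluster as numerator and every other analyzed taxon
    as denominator."""
    members = tuple(sorted(members))
    rest = tuple(sorted(set(all_taxa) - set(members)))
    if not rest:
        raise ValueError("cluster spans all taxa; denominator would be empty")
    return Balance(members, rest)


def cooperative_association(
    table: CountTable,
    clusters: list[frozenset],
    metadata: pd.DataFrame,
    factors: list[str],
    covariates: tuple[str, ...] = (),
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> list[Cooperative]:
    """Linear models of cooperative-balance values on each factor.

    Intended to be run within one (sample type, batch) stratum; BH
    adjustment is applied across all cluster x factor tests performed in
    this call.
    """
    comp = zero_replace(table, pseudocount)
    meta = metadata.set_index("sample_id").loc[comp.index]
    results: list[Cooperative] = []
    for members in clusters:
        balance = cooperative_balance(members, table.taxa)
        values = balance_values(balance, comp).to_numpy()
        for factor in factors:
            sub = meta[factor].dropna()
            y = values[[list(comp.index).index(s) for s in sub.index]]
            try:
                coded, _ = encode_factor(sub)
            except ValueError:
                logger.info("cooperative_association: skipping constant factor %r", factor)
                continue
            covs = [meta.loc[sub.index, c].to_numpy(dtype=float) for c in covariates]
            X = np.column_stack([np.ones(len(y)), coded, *covs])
            fit = ols_many(y[:, None], X, test_col=1)
            results.append(
                Cooperative(
                    members=tuple(sorted(members)),
                    balance=balance,
                    factor=factor,
                    slope=float(fit.coef[0]),
                    p=float(fit.p[0]),
                )
            )
    if results:
        qs = bh_adjust([c.p for c in results])
        for coop, q in zip(results, qs):
            coop.q = float(q)
    return results


def cooperatives_to_json(cooperatives: list[Cooperative], path) -> None:
    with open(path, "w") as fh:
        json.dump([c.to_dict() for c in cooperatives], fh, indent=2, sort_keys=True)
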