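"""Compositional machinery on the simplex.

Zero replacement, closure, clr/ilr transforms, Aitchison distance,
perturbation, taxonomic aggregation, and the ilr-shift correction that
moves luminal (stool) samples toward the paired mucosal (biopsy)
composition. Natural logarithms throughout.

Compositions are stored row-per-sample: a pandas DataFrame with sample
ids as the index and taxon ids ("parts") as columns, strictly positive,
each row summing to 1.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .io import RANKS, UNCLASSIFIED, CountTable, parse_lineage

DEFAULT_PSEUDOCOUNT = 0.5


def closure(values: np.ndarray) -> np.ndarray:
    """Rescale each row of a positive matrix to sum to 1."""
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        return values / values.sum()
    return values / values.sum(axis=1, keepdims=True)


def zero_replace(
    table: CountTable, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> pd.DataFrame:
    """Substitute zero counts with a pseudocount, then close to proportions.

    Zeros are replaced on the count scale (nonzero counts are untouched)
    and each sample is closed to sum 1. Returns a samples x parts
    composition table.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    counts = table.counts.T.astype(float)  # samples x taxa
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        empty = totals.index[totals == 0].tolist()
        raise ValueError(f"samples with all-zero counts: {empty}")
    filled = counts.where(counts > 0, pseudocount)
    comp = filled.div(filled.sum(axis=1), axis=0)
    comp.index.name = "sample_id"
    return comp


def _validate_composition(comp: pd.DataFrame | np.ndarray) -> np.ndarray:
    values = np.asarray(comp, dtype=float)
    if values.ndim == 1:
        values = values[None, :]
    if (values <= 0).any():
        raise ValueError(
            "composition has non-positive entries; apply zero_replace first"
        )
    return values


def clr(comp: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Centered log-ratio transform: ln(x) minus the row mean of ln(x)."""
    values = _validate_composition(comp)
    logs = np.log(values)
    out = logs - logs.mean(axis=1, keepdims=True)
    if isinstance(comp, pd.DataFrame):
        return pd.DataFrame(out, index=comp.index, columns=comp.columns)
    return out if np.asarray(comp).ndim > 1 else out[0]


def clr_inverse(y: np.ndarray | pd.DataFrame) -> np.ndarray | pd.DataFrame:
    """Map clr coordinates back to the simplex (softmax closure)."""
    values = np.asarray(y, dtype=float)
    single = values.ndim == 1
    if single:
        values = values[None, :]
    values = values - values.max(axis=1, keepdims=True)  # overflow guard
    comp = closure(np.exp(values))
    if isinstance(y, pd.DataFrame):
        return pd.DataFrame(comp, index=y.index, columns=y.columns)
    return comp[0] if single else comp


def ilr_basis(n_parts: int) -> np.ndarray:
    """Orthonormal pivot (Gram-Schmidt) contrast basis, shape (D-1, D).

    Row i contrasts part i against the geometric mean of parts i+1..D.
    Rows sum to zero, are pairwise orthogonal, and have unit norm.
    """
    if n_parts < 2:
        raise ValueError("need at least 2 parts")
    basis = np.zeros((n_parts - 1, n_parts))
    for i in range(n_parts - 1):
        r = n_parts - i - 1  # parts to the right
        basis[i, i] = np.sqrt(r / (r + 1))
        basis[i, i + 1 :] = -1.0 / np.sqrt(r * (r + 1))
    return basis


def random_ilr_basis(n_parts: int, seed: int) -> np.ndarray:
    """A random orthonormal contrast basis (for basis-invariance checks)."""
    rng = np.random.default_rng(seed)
    rotation = np.linalg.qr(rng.normal(size=(n_parts - 1, n_parts - 1)))[0]
    return rotation @ ilr_basis(n_parts)


def _check_basis(basis: np.ndarray, n_parts: int) -> np.ndarray:
    basis = np.asarray(basis, dtype=float)
    if basis.shape != (n_parts - 1, n_parts):
        raise ValueError(
            f"basis shape {basis.shape} does not match {n_parts} parts"
        )
    return basis


def ilr(
    comp: pd.DataFrame | np.ndarray, basis: np.ndarray | None = None
) -> np.ndarray:
    """Isometric log-ratio coordinates: clr rows projected on the basis."""
    values = _validate_composition(comp)
    n_parts = values.shape[1]
    basis = ilr_basis(n_parts) if basis is None else _check_basis(basis, n_parts)
    coords = clr(values) @ basis.T
    return coords if np.asarray(comp).ndim > 1 else coords[0]


def ilr_inverse(
    coords: np.ndarray,
    basis: np.ndarray | None = None,
    parts: Sequence[str] | None = None,
    index: Sequence[str] | None = None,
) -> pd.DataFrame | np.ndarray:
    """Invert :func:`ilr`; exact round trip up to floating point."""
    coords = np.asarray(coords, dtype=float)
    single = coords.ndim == 1
    if single:
        coords = coords[None, :]
    n_parts = coords.shape[1] + 1
    basis = ilr_basis(n_parts) if basis is None else _check_basis(basis, n_parts)
    comp = clr_inverse(coords @ basis)
    if parts is not None:
        return pd.DataFrame(comp, columns=list(parts), index=index)
    return comp[0] if single else comp


def perturb(
    x: pd.DataFrame | np.ndarray, p: np.ndarray | pd.Series
) -> pd.DataFrame | np.ndarray:
    """Simplex group operation: componentwise product followed by closure."""
    xv = np.asarray(x, dtype=float)
    pv = np.asarray(p, dtype=float)
    out = closure(xv * pv)
    if isinstance(x, pd.DataFrame):
        return pd.DataFrame(out, index=x.index, columns=x.columns)
    return out


def aitchison_distance(comp: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Euclidean distance between clr-transformed samples."""
    transformed = clr(_validate_composition(comp))
    dist = squareform(pdist(transformed, metric="euclidean"))
    index = comp.index if isinstance(comp, pd.DataFrame) else None
    return pd.DataFrame(dist, index=index, columns=index)


def write_distance_matrix(dist: pd.DataFrame, path) -> None:
    dist.to_csv(path, sep="\t")


def read_distance_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def sample_type_correction(
    stool: pd.DataFrame,
    biopsy: pd.DataFrame,
    basis: np.ndarray | None = None,
) -> pd.DataFrame:
    """Shift stool samples so their ilr mean coincides with the biopsy mean.

    Each stool sample's ilr coordinates are translated by
    (mean biopsy ilr - mean stool ilr) and mapped back to the simplex.
    The result does not depend on the orthonormal basis chosen; it equals
    perturbing each stool sample by the difference of the closed per-taxon
    geometric-mean compositions of the two groups.
    """
    if list(stool.columns) != list(biopsy.columns):
        raise ValueError("stool and biopsy tables must share the same parts")
    if len(stool) == 0 or len(biopsy) == 0:
        raise ValueError("both tables need at least one sample")
    n_parts = stool.shape[1]
    basis = ilr_basis(n_parts) if basis is None else _check_basis(basis, n_parts)
    stool_coords = ilr(stool, basis)
    shift = ilr(biopsy, basis).mean(axis=0) - stool_coords.mean(axis=0)
    corrected = ilr_inverse(stool_coords + shift, basis)
    return pd.DataFrame(corrected, index=stool.index, columns=stool.columns)


# ---------------------------------------------------------------------------
# Taxonomic aggregation
# ---------------------------------------------------------------------------

def aggregate_to_rank(table: CountTable, rank: str) -> CountTable:
    """Sum counts over taxa sharing the same lineage prefix up to ``rank``.

    Taxa unclassified at the target rank are grouped under an explicit
    placeholder keyed by their deepest classified prefix, so per-sample
    totals are conserved exactly.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    depth = RANKS.index(rank) + 1
    groups: dict[tuple[str, ...], list[str]] = {}
    for taxon in table.taxa:
        prefix = parse_lineage(table.lineages.loc[taxon])[:depth]
        # normalize: once a rank is unclassified, deeper ranks are too
        norm = []
        seen_unclassified = False
        for part in prefix:
            if part == UNCLASSIFIED:
                seen_unclassified = True
            norm.append(UNCLASSIFIED if seen_unclassified else part)
        groups.setdefault(tuple(norm), []).append(taxon)

    ids = {}
    for key in groups:
        if key[-1] != UNCLASSIFIED:
            ids[key] = key[-1]
        else:
            classified = [p for p in key if p != UNCLASSIFIED]
            anchor = classified[-1] if classified else "root"
            ids[key] = f"{UNCLASSIFIED}_{anchor}"
    # disambiguate colliding display names with the full prefix
    from collections import Counter

    counts_by_id = Counter(ids.values())
    for key, name in ids.items():
        if counts_by_id[name] > 1:
            ids[key] = ";".join(key)

    rows = []
    lineages = []
    index = []
    for key in sorted(groups):
        members = groups[key]
        rows.append(table.counts.loc[members].sum(axis=0))
        lineages.append(";".join(key))
        index.append(ids[key])
    counts = pd.DataFrame(rows, index=pd.Index(index, name=table.counts.index.name))
    return CountTable(counts, pd.Series(lineages, index=counts.index))
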