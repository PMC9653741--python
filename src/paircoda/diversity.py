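"""Rarefaction and alpha-diversity indices (Shannon in nats, chao1)."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import CountTable

logger = logging.getLogger(__name__)


def rarefy(table: CountTable, depth: int | None = None, seed: int = 0) -> CountTable:
    """Subsample each sample to exactly ``depth`` reads without replacement.

    Draws are multivariate hypergeometric, reproducible given ``seed``.
    ``depth=None`` uses the minimum per-sample total. Samples whose total
    is below ``depth`` are dropped with a logged warning.
    """
    totals = table.sample_totals()
    if depth is None:
        depth = int(totals.min())
    if depth <= 0:
        raise ValueError("depth must be positive")
    keep = totals.index[totals >= depth].tolist()
    dropped = sorted(set(table.samples) - set(keep))
    if dropped:
        logger.warning(
            "rarefy: dropping %d samples below depth %d: %s",
            len(dropped), depth, dropped,
        )
    rng = np.random.default_rng(seed)
    out = {}
    for sample in keep:
        counts = table.counts[sample].to_numpy()
        if counts.sum() == depth:
            out[sample] = counts
        else:
            out[sample] = rng.multivariate_hypergeometric(counts, depth)
    rarefied = pd.DataFrame(out, index=table.counts.index)
    return CountTable(rarefied, table.lineages)


def shannon(counts: np.ndarray | pd.Series) -> float:
    """Shannon index in nats: -sum p_i ln p_i over nonzero proportions."""
    values = np.asarray(counts, dtype=float)
    total = values.sum()
    if total <= 0:
        raise ValueError("sample has no reads")
    p = values[values > 0] / total
    return float(-(p * np.log(p)).sum())


def chao1(counts: np.ndarray | pd.Series) -> float:
    """chao1 richness: S_obs + F1^2/(2 F2), with the bias-corrected
    fallback S_obs + F1(F1-1)/2 when there are no doubletons."""
    values = np.asarray(counts)
    if values.sum() <= 0:
        raise ValueError("sample has no reads")
    s_obs = int((values > 0).sum())
    f1 = int((values == 1).sum())
    f2 = int((values == 2).sum())
    if f2 > 0:
        return s_obs + f1 * f1 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1) / 2.0


def alpha_diversity(table: CountTable) -> pd.DataFrame:
    """Per-sample Shannon and chao1 as a tidy table."""
    records = []
    for sample in table.samples:
        counts = table.counts[sample].to_numpy()
        records.append(
            {"sample_id": sample, "shannon": shannon(counts), "chao1": chao1(counts)}
        )
    return pd.DataFrame(records)


def write_alpha_diversity(alpha: pd.DataFrame, path) -> None:
    alpha.to_csv(path, sep="\t", index=False)
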