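"""Distance-based and per-feature association statistics.

PERMANOVA on a fixed distance matrix with sequential covariate adjustment
and strata-restricted permutations; alpha-diversity association models;
component-wise per-taxon analysis on arcsine-square-root-transformed
rarefied proportions; Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._lm import dummy_columns, encode_factor, mixedlm_single, ols_many
from .design import AssociationDesign
from .diversity import rarefy, shannon
from .io import CountTable

logger = logging.getLogger(__name__)


def bh_adjust(p: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest rank down
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class PermanovaResult:
    factor: str
    r2: float
    pseudo_f: float
    p_value: float
    n_permutations: int
    df_factor: int
    df_resid: int
    level: str | None = None

    def to_dict(self) -> dict:
        return {
            "factor": self.factor,
            "r2": self.r2,
            "pseudo_f": self.pseudo_f,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
            "df_factor": self.df_factor,
            "df_resid": self.df_resid,
            "level": self.level,
        }


def _design_columns(meta: pd.DataFrame, columns: tuple[str, ...]) -> np.ndarray:
    """Numeric columns pass through; categoricals become drop-first dummies."""
    blocks = []
    for col in columns:
        series = meta[col]
        if pd.api.types.is_numeric_dtype(series):
            blocks.append(series.to_numpy(dtype=float)[:, None])
        else:
            blocks.append(dummy_columns(series))
    if not blocks:
        return np.empty((len(meta), 0))
    return np.hstack(blocks)


def _hat(X: np.ndarray) -> np.ndarray:
    return X @ np.linalg.pinv(X.T @ X) @ X.T


def permanova(
    dist: pd.DataFrame,
    metadata: pd.DataFrame,
    design: AssociationDesign,
    n_perm: int = 999,
    seed: int = 0,
    level: str | None = None,
) -> PermanovaResult:
    """Covariate-adjusted PERMANOVA with strata-restricted permutations.

    The Gower-centered inner-product matrix ``G`` is computed from the
    squared distances; covariates (and the intercept) enter first, the
    factor is tested conditionally: partial R2 = tr((H1-H0)G)/tr(G) and
    pseudo-F uses the residual trace of the full model. The null
    distribution permutes sample identities (factor and covariate rows
    together) within strata only; p uses the add-one estimator.
    """
    samples = list(dist.index)
    if list(dist.columns) != samples:
        raise ValueError("distance matrix rows and columns must match")
    meta = metadata.set_index("sample_id").loc[samples]
    n = len(samples)

    d2 = dist.to_numpy(dtype=float) ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ d2 @ J

    factor_block = _design_columns(meta, (design.factor,))
    if factor_block.shape[1] == 0 or np.allclose(factor_block.std(axis=0), 0):
        raise ValueError("factor is constant across samples")
    cov_block = _design_columns(meta, design.covariates)
    intercept = np.ones((n, 1))

    if design.strata is not None:
        strata = meta[design.strata].to_numpy()
        varies = (
            pd.DataFrame({"s": strata, "f": meta[design.factor].astype(str).to_numpy()})
            .groupby("s")["f"]
            .nunique()
        )
        if (varies <= 1).all():
            raise ValueError(
                "factor is constant within every stratum and cannot be permuted"
            )
        groups = [np.nonzero(strata == s)[0] for s in pd.unique(strata)]
    else:
        groups = [np.arange(n)]

    df_factor = int(np.linalg.matrix_rank(np.hstack([intercept, cov_block, factor_block]))
                    - np.linalg.matrix_rank(np.hstack([intercept, cov_block])))
    if df_factor == 0:
        raise ValueError("factor is collinear with the covariates")

    def statistic(perm: np.ndarray) -> tuple[float, float]:
        X0 = np.hstack([intercept, cov_block[perm]])
        X1 = np.hstack([X0, factor_block[perm]])
        H0, H1 = _hat(X0), _hat(X1)
        tr_g = np.trace(G)
        ss_factor = np.trace((H1 - H0) @ G)
        ss_resid = np.trace((np.eye(n) - H1) @ G)
        df_resid = n - int(np.linalg.matrix_rank(X1))
        # saturated designs: residual trace is 0 up to round-off
        floor = 1e-12 * max(tr_g, 1.0)
        f = (ss_factor / df_factor) / max(ss_resid / df_resid, floor)
        return f, ss_factor / tr_g

    identity = np.arange(n)
    f_obs, r2 = statistic(identity)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = identity.copy()
        for g in groups:
            perm[g] = g[rng.permutation(len(g))]
        f_perm, _ = statistic(perm)
        if f_perm >= f_obs:
            count += 1
    p = (1 + count) / (n_perm + 1)

    X1_full = np.hstack([intercept, cov_block, factor_block])
    df_resid = n - int(np.linalg.matrix_rank(X1_full))
    return PermanovaResult(
        factor=design.factor,
        r2=float(r2),
        pseudo_f=float(f_obs),
        p_value=float(p),
        n_permutations=n_perm,
        df_factor=df_factor,
        df_resid=df_resid,
        level=level,
    )


# ---------------------------------------------------------------------------
# Alpha-diversity association
# ---------------------------------------------------------------------------

def alpha_association(
    alpha: pd.DataFrame,
    metadata: pd.DataFrame,
    factor: str,
    index: str = "shannon",
    batch: str | None = "batch",
    covariates: tuple[str, ...] = (),
) -> dict:
    """Linear model of an alpha-diversity index on a factor.

    The batch enters as a random grouping; with fewer than three batches a
    fixed-effect dummy fallback is used (logged). Returns slope and p.
    """
    merged = alpha.merge(metadata, on="sample_id", how="inner")
    y = merged[index].to_numpy(dtype=float)
    if np.allclose(y.std(), 0):
        raise ValueError(f"{index} is constant; nothing to model")
    factor_vals, level = encode_factor(merged[factor])
    counts = pd.Series(factor_vals).value_counts()
    if (counts < 3).any() and merged[factor].dtype == object:
        logger.warning("alpha_association: fewer than 3 samples in a factor level")
    covs = [merged[c].to_numpy(dtype=float) for c in covariates]

    if batch is not None and batch in merged.columns:
        n_batches = merged[batch].nunique()
        if n_batches >= 3:
            X = np.column_stack([np.ones(len(y)), factor_vals, *covs])
            slope, p = mixedlm_single(y, X, merged[batch].to_numpy(), test_col=1)
            return {"factor": factor, "index": index, "slope": slope, "p": p, "level": level}
        if n_batches == 2:
            logger.info(
                "alpha_association: 2 batch levels; using fixed-effect fallback"
            )
            covs = covs + [dummy_columns(merged[batch]).ravel()]
    X = np.column_stack([np.ones(len(y)), factor_vals, *covs])
    fit = ols_many(y[:, None], X, test_col=1)
    return {
        "factor": factor,
        "index": index,
        "slope": float(fit.coef[0]),
        "p": float(fit.p[0]),
        "level": level,
    }


def alpha_associations(
    alpha: pd.DataFrame,
    metadata: pd.DataFrame,
    factors: list[str],
    index: str = "shannon",
    batch: str | None = "batch",
) -> pd.DataFrame:
    """Test several factors and BH-adjust across them."""
    rows = [
        alpha_association(alpha, metadata, factor, index=index, batch=batch)
        for factor in factors
    ]
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# Component-wise per-taxon analysis
# ---------------------------------------------------------------------------

def arcsine_sqrt(p: np.ndarray | float) -> np.ndarray | float:
    """Variance-stabilizing transform for proportions: arcsin(sqrt(p))."""
    return np.arcsin(np.sqrt(p))


def componentwise(
    table: CountTable,
    metadata: pd.DataFrame,
    design: AssociationDesign,
    depth: int | None = 2442,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-taxon association on arcsine-sqrt proportions after rarefaction.

    Rarefies to ``depth`` (capped at the minimum sample total), converts
    to proportions, applies arcsin(sqrt(.)), then fits each taxon against
    the design factor with the Shannon index of the rarefied sample as a
    fixed covariate and the batch as grouping (fixed-effect dummies for
    two batches). Returns a table with slope, p and BH-adjusted q.
    """
    min_total = int(table.sample_totals().min())
    if depth is None or depth > min_total:
        if depth is not None:
            logger.info("componentwise: capping depth %d at minimum total %d", depth, min_total)
        depth = min_total
    rarefied = rarefy(table, depth=depth, seed=seed)
    props = rarefied.counts.T / depth  # samples x taxa
    Y = arcsine_sqrt(props.to_numpy(dtype=float))

    meta = metadata.set_index("sample_id").loc[props.index]
    factor_vals, level = encode_factor(meta[design.factor])
    shannon_vals = np.array(
        [shannon(rarefied.counts[s].to_numpy()) for s in props.index]
    )
    covs = [shannon_vals] + [meta[c].to_numpy(dtype=float) for c in design.covariates]

    group_col = design.random_group
    if group_col and group_col in meta.columns:
        n_groups = meta[group_col].nunique()
        if n_groups >= 3:
            slopes = np.empty(Y.shape[1])
            ps = np.empty(Y.shape[1])
            X = np.column_stack([np.ones(len(Y)), factor_vals, *covs])
            groups = meta[group_col].to_numpy()
            for j in range(Y.shape[1]):
                slopes[j], ps[j] = mixedlm_single(Y[:, j], X, groups, test_col=1)
        else:
            if n_groups == 2:
                logger.info("componentwise: 2 %s levels; fixed-effect fallback", group_col)
                covs = covs + [dummy_columns(meta[group_col]).ravel()]
            X = np.column_stack([np.ones(len(Y)), factor_vals, *covs])
            fit = ols_many(Y, X, test_col=1)
            slopes, ps = fit.coef, fit.p
    else:
        X = np.column_stack([np.ones(len(Y)), factor_vals, *covs])
        fit = ols_many(Y, X, test_col=1)
        slopes, ps = fit.coef, fit.p

    out = pd.DataFrame(
        {
            "taxon": props.columns,
            "factor": design.factor,
            "level": level,
            "slope": slopes,
            "p": ps,
        }
    )
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out
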