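"""Nearest-balance association analysis.

The central objects and routines: per-taxon clr regression against a
factor, the nearest balance of the resulting coefficient vector, bootstrap
reproducibility refinement, balance evaluation on arbitrary samples
(including external relative-abundance tables with clade fallback), and
the stool-vs-biopsy AUC cross-validation analysis.

A *balance* is a normalized log-contrast between two disjoint taxon sets:
for numerator size k+ and denominator size k-, its clr contrast vector
carries +sqrt(k-/(k+(k+ + k-))) on numerator taxa and
-sqrt(k+/(k-(k+ + k-))) on denominator taxa, zero elsewhere — a unit-norm,
zero-sum vector. The *nearest balance* of a clr coefficient vector b is
the balance whose contrast maximizes cosine similarity with b.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from ._lm import encode_factor, mixedlm_single, ols_many
from .coda import DEFAULT_PSEUDOCOUNT, clr, zero_replace
from .design import AssociationDesign
from .io import RANKS, UNCLASSIFIED, CountTable, parse_lineage

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Balance:
    """Disjoint numerator/denominator taxon sets with their unit contrast."""

    numerator: tuple[str, ...]
    denominator: tuple[str, ...]

    def __post_init__(self) -> None:
        num, den = set(self.numerator), set(self.denominator)
        if num & den:
            raise ValueError(f"numerator and denominator overlap: {num & den}")
        object.__setattr__(self, "numerator", tuple(sorted(num)))
        object.__setattr__(self, "denominator", tuple(sorted(den)))

    @property
    def is_empty(self) -> bool:
        return not self.numerator or not self.denominator

    @property
    def size(self) -> int:
        return len(self.numerator) + len(self.denominator)

    def contrast(self, taxa: Sequence[str]) -> np.ndarray:
        """Unit-norm zero-sum contrast over the given taxon ordering."""
        if self.is_empty:
            raise ValueError("empty balance has no contrast")
        index = {t: i for i, t in enumerate(taxa)}
        missing = [t for t in self.numerator + self.denominator if t not in index]
        if missing:
            raise ValueError(f"balance taxa missing from universe: {missing}")
        kp, km = len(self.numerator), len(self.denominator)
        vec = np.zeros(len(taxa))
        vec[[index[t] for t in self.numerator]] = np.sqrt(km / (kp * (kp + km)))
        vec[[index[t] for t in self.denominator]] = -np.sqrt(kp / (km * (kp + km)))
        return vec

    def flip(self) -> "Balance":
        return Balance(self.denominator, self.numerator)

    def to_dict(self) -> dict:
        return {"numerator": list(self.numerator), "denominator": list(self.denominator)}


def nearest_balance(
    b: np.ndarray | pd.Series, taxa: Sequence[str] | None = None
) -> Balance:
    """Balance whose contrast maximizes the inner product with ``b``.

    Candidates are generated by sorting taxa by coefficient (descending)
    and taking the top k+ as numerator against the bottom k- as
    denominator, for all k+ >= 1, k- >= 1, k+ + k- <= D; a rearrangement
    argument shows the optimum lies in this family (verified against
    exhaustive search in the test suite). Ties are broken toward fewer
    taxa, then lexicographically smaller taxon-id sets.
    """
    if isinstance(b, pd.Series):
        taxa = list(b.index) if taxa is None else list(taxa)
        values = b.to_numpy(dtype=float)
    else:
        values = np.asarray(b, dtype=float)
        taxa = [f"t{i}" for i in range(len(values))] if taxa is None else list(taxa)
    D = len(values)
    if D < 2:
        raise ValueError("need at least 2 taxa")
    if np.allclose(values, values[0]):
        raise ValueError("coefficient vector is constant; no direction to fit")

    # stable order: coefficient descending, taxon id ascending on ties
    order = np.lexsort((np.asarray(taxa, dtype=object), -values))
    sorted_vals = values[order]
    prefix = np.concatenate([[0.0], np.cumsum(sorted_vals)])
    total = prefix[-1]

    best = (-np.inf, np.inf)  # (score, size) for tie-breaking
    best_pair: tuple[int, int] | None = None
    kp_range = np.arange(1, D)
    top_means = prefix[1:D] / kp_range  # mean of top k+ values
    for km in range(1, D):
        bottom_mean = (total - prefix[D - km]) / km
        max_kp = D - km
        kp = kp_range[:max_kp]
        scale = np.sqrt(kp * km / (kp + km))
        scores = scale * (top_means[:max_kp] - bottom_mean)
        idx = int(np.argmax(scores))
        # scan near-ties in this row for the smallest balance
        row_best = scores[idx]
        for j in np.nonzero(scores >= row_best - 1e-12)[0]:
            cand = (float(scores[j]), int(j + 1 + km))
            if cand[0] > best[0] + 1e-12 or (
                abs(cand[0] - best[0]) <= 1e-12 and cand[1] < best[1]
            ):
                best = cand
                best_pair = (int(j + 1), km)
    assert best_pair is not None
    kp, km = best_pair
    num = [taxa[i] for i in order[:kp]]
    den = [taxa[i] for i in order[D - km :]]
    return Balance(tuple(num), tuple(den))


def balance_value(
    balance: Balance, sample: pd.Series | Mapping[str, float]
) -> float:
    """Normalized log-contrast value of one sample (counts or proportions).

    Equals sqrt(k+ k-/(k+ + k-)) times the difference between the mean
    natural log over numerator taxa and over denominator taxa; identical
    to ``contrast . clr(sample)`` and invariant to overall scaling.
    """
    sample = pd.Series(sample, dtype=float)
    missing = [
        t for t in balance.numerator + balance.denominator if t not in sample.index
    ]
    if missing:
        raise ValueError(f"sample lacks balance taxa: {missing}")
    num = sample.loc[list(balance.numerator)].to_numpy()
    den = sample.loc[list(balance.denominator)].to_numpy()
    if (num <= 0).any() or (den <= 0).any():
        raise ValueError("balance taxa must have positive values (zero_replace first)")
    kp, km = len(balance.numerator), len(balance.denominator)
    scale = np.sqrt(kp * km / (kp + km))
    return float(scale * (np.log(num).mean() - np.log(den).mean()))


def balance_values(balance: Balance, comp: pd.DataFrame) -> pd.Series:
    """Vectorized :func:`balance_value` over a samples x parts table."""
    missing = [
        t for t in balance.numerator + balance.denominator if t not in comp.columns
    ]
    if missing:
        raise ValueError(f"table lacks balance taxa: {missing}")
    num = np.log(comp.loc[:, list(balance.numerator)].to_numpy())
    den = np.log(comp.loc[:, list(balance.denominator)].to_numpy())
    kp, km = len(balance.numerator), len(balance.denominator)
    scale = np.sqrt(kp * km / (kp + km))
    return pd.Series(scale * (num.mean(axis=1) - den.mean(axis=1)), index=comp.index)


# ---------------------------------------------------------------------------
# clr association
# ---------------------------------------------------------------------------

def clr_association(
    clr_table: pd.DataFrame,
    metadata: pd.DataFrame,
    design: AssociationDesign,
) -> tuple[pd.Series, pd.Series]:
    """Per-taxon slope of clr abundance on the design's factor.

    Returns (coefficients, p-values) indexed by taxon. The random grouping
    is honored exactly for the structures used here: a paired design with
    two samples per group and the factor flipping within every group is
    fit on within-group differences; a factor constant within groups is
    fit on group means (exact for balanced random-intercept models);
    otherwise a per-taxon mixed model is used. Without a random grouping,
    plain OLS with the covariates applies.
    """
    meta = metadata.set_index("sample_id").loc[clr_table.index]
    factor_vals, _ = encode_factor(meta[design.factor])
    Y = clr_table.to_numpy(dtype=float)
    covs = []
    for c in design.covariates:
        series = meta[c]
        if pd.api.types.is_numeric_dtype(series):
            covs.append(series.to_numpy(dtype=float))
        else:
            from ._lm import dummy_columns

            covs.extend(dummy_columns(series).T)

    if design.random_group:
        groups = meta[design.random_group].to_numpy()
        route = _grouping_route(groups, factor_vals)
        if route == "paired":
            coef, p = _paired_fit(Y, factor_vals, covs, groups)
        elif route == "group_means":
            coef, p = _group_mean_fit(Y, factor_vals, covs, groups)
        else:
            coef, p = _mixed_fit(Y, factor_vals, covs, groups)
    else:
        X = np.column_stack([np.ones(len(Y)), factor_vals, *covs])
        fit = ols_many(Y, X, test_col=1)
        coef, p = fit.coef, fit.p

    taxa = clr_table.columns
    return pd.Series(coef, index=taxa, name="coef"), pd.Series(p, index=taxa, name="p")


def _grouping_route(groups: np.ndarray, factor: np.ndarray) -> str:
    frame = pd.DataFrame({"g": groups, "f": factor})
    sizes = frame.groupby("g").size()
    nun = frame.groupby("g")["f"].nunique()
    if (sizes == 2).all() and (nun == 2).all():
        return "paired"
    if (nun == 1).all():
        return "group_means"
    return "mixed"


def _paired_fit(Y, factor, covs, groups):
    """Within-group differences: eliminates group intercepts exactly."""
    frame = pd.DataFrame({"g": groups, "f": factor})
    diffs, cov_diffs = [], []
    for g, idx in frame.groupby("g").groups.items():
        idx = list(idx)
        hi, lo = (idx[0], idx[1]) if factor[idx[0]] > factor[idx[1]] else (idx[1], idx[0])
        scale = factor[hi] - factor[lo]
        diffs.append((Y[hi] - Y[lo]) / scale)
        cov_diffs.append([(c[hi] - c[lo]) / scale for c in covs])
    Yd = np.asarray(diffs)
    X = np.column_stack([np.ones(len(Yd)), *np.asarray(cov_diffs).T]) if covs else np.ones(
        (len(Yd), 1)
    )
    fit = ols_many(Yd, X, test_col=0)
    return fit.coef, fit.p


def _group_mean_fit(Y, factor, covs, groups):
    """Collapse to group means; exact GLS for balanced random intercepts."""
    frame = pd.DataFrame({"g": groups})
    means, fvals, cvals = [], [], []
    for g, idx in frame.groupby("g").groups.items():
        idx = list(idx)
        means.append(Y[idx].mean(axis=0))
        fvals.append(factor[idx].mean())
        cvals.append([np.asarray(c)[idx].mean() for c in covs])
    Ym = np.asarray(means)
    fm = np.asarray(fvals)
    if np.all(fm == fm[0]):
        raise ValueError("factor is constant across groups")
    X = np.column_stack([np.ones(len(Ym)), fm, *np.asarray(cvals).T]) if covs else (
        np.column_stack([np.ones(len(Ym)), fm])
    )
    fit = ols_many(Ym, X, test_col=1)
    return fit.coef, fit.p


def _mixed_fit(Y, factor, covs, groups):
    X = np.column_stack([np.ones(len(Y)), factor, *covs])
    coef = np.empty(Y.shape[1])
    p = np.empty(Y.shape[1])
    for j in range(Y.shape[1]):
        coef[j], p[j] = mixedlm_single(Y[:, j], X, groups, test_col=1)
    return coef, p


# ---------------------------------------------------------------------------
# Bootstrap reproducibility
# ---------------------------------------------------------------------------

@dataclass
class BalanceFit:
    """Result of the reproducibility-refined nearest-balance search."""

    balance: Balance
    full_balance: Balance
    coefficients: pd.Series
    numerator_freq: pd.Series
    denominator_freq: pd.Series
    n_iter: int
    cosine: float = field(default=float("nan"))

    def to_dict(self) -> dict:
        return {
            "balance": self.balance.to_dict(),
            "full_balance": self.full_balance.to_dict(),
            "coefficients": {t: float(v) for t, v in self.coefficients.items()},
            "numerator_freq": {t: float(v) for t, v in self.numerator_freq.items()},
            "denominator_freq": {t: float(v) for t, v in self.denominator_freq.items()},
            "n_iter": self.n_iter,
            "cosine": None if np.isnan(self.cosine) else float(self.cosine),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    def to_table(self) -> pd.DataFrame:
        """Export in the shape of a reproducibility bar chart: taxon, side,
        coefficient, reproducibility frequency."""
        rows = []
        for taxon in self.coefficients.index:
            nf = float(self.numerator_freq.get(taxon, 0.0))
            df_ = float(self.denominator_freq.get(taxon, 0.0))
            side = ""
            if taxon in self.balance.numerator:
                side = "numerator"
            elif taxon in self.balance.denominator:
                side = "denominator"
            rows.append(
                {
                    "taxon": taxon,
                    "side": side,
                    "coefficient": float(self.coefficients[taxon]),
                    "numerator_freq": nf,
                    "denominator_freq": df_,
                }
            )
        return pd.DataFrame(rows)


def reproducible_balance(
    data: CountTable,
    metadata: pd.DataFrame,
    design: AssociationDesign,
    n_iter: int = 500,
    subsample_fraction: float = 0.5,
    threshold: float = 0.80,
    seed: int = 0,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> BalanceFit:
    """Refine the nearest balance by subsample reproducibility.

    The association + nearest-balance step runs ``n_iter`` times on random
    subsamples of ``subsample_fraction`` of the sampling units (patients
    for designs with a random grouping, samples otherwise). Taxa landing
    in the numerator (resp. denominator) in more than ``threshold`` of the
    iterations form the final balance. If either side ends up empty, an
    empty-balance marker is returned along with the frequencies.
    """
    if not 0 < subsample_fraction < 1:
        raise ValueError("subsample_fraction must be in (0, 1)")
    comp = zero_replace(data, pseudocount)
    clr_table = clr(comp)
    meta = metadata.set_index("sample_id").loc[clr_table.index].reset_index()

    b_full, _ = clr_association(clr_table, meta, design)
    full_balance = nearest_balance(b_full)

    if design.random_group:
        units = meta[design.random_group].unique()
        unit_col = design.random_group
    else:
        units = meta["sample_id"].unique()
        unit_col = "sample_id"
    n_sub = max(2, int(round(subsample_fraction * len(units))))

    rng = np.random.default_rng(seed)
    taxa = clr_table.columns
    num_hits = pd.Series(0, index=taxa, dtype=float)
    den_hits = pd.Series(0, index=taxa, dtype=float)
    max_redraws = 100
    for _ in range(n_iter):
        for _attempt in range(max_redraws):
            chosen = rng.choice(units, size=n_sub, replace=False)
            mask = meta[unit_col].isin(chosen).to_numpy()
            sub_meta = meta.loc[mask]
            if sub_meta[design.factor].nunique() > 1:
                break
        else:
            raise RuntimeError("could not draw a subsample with factor variation")
        sub_clr = clr_table.loc[sub_meta["sample_id"]]
        try:
            b_sub, _ = clr_association(sub_clr, sub_meta, design)
            bal = nearest_balance(b_sub)
        except ValueError:
            continue
        num_hits[list(bal.numerator)] += 1
        den_hits[list(bal.denominator)] += 1

    num_freq = num_hits / n_iter
    den_freq = den_hits / n_iter
    numerator = tuple(taxa[num_freq > threshold])
    denominator = tuple(taxa[den_freq > threshold])
    balance = Balance(numerator, denominator)
    cosine = float("nan")
    if not balance.is_empty:
        contrast = balance.contrast(list(taxa))
        bv = b_full.to_numpy()
        cosine = float(contrast @ bv / np.linalg.norm(bv))
    else:
        logger.info("reproducible_balance: empty consensus balance")
    return BalanceFit(
        balance=balance,
        full_balance=full_balance,
        coefficients=b_full,
        numerator_freq=num_freq,
        denominator_freq=den_freq,
        n_iter=n_iter,
        cosine=cosine,
    )


# ---------------------------------------------------------------------------
# External evaluation with clade fallback
# ---------------------------------------------------------------------------

def evaluate_balance_external(
    balance: Balance,
    relabund: pd.DataFrame,
    lineages: Mapping[str, str],
    member_lineages: Mapping[str, str] | None = None,
    group: pd.Series | None = None,
) -> tuple[pd.Series, dict | None]:
    """Evaluate a balance on an external samples x species table.

    Members are matched by exact species name first. A member that is
    unclassified at species level is replaced by the summed abundance of
    all species from its deepest classified clade (genus or family), using
    the external table's lineages. Zeros in the assembled member matrix
    are replaced by half the smallest positive entry before taking logs.

    With ``group`` (a binary per-sample label), a linear-model comparison
    of the balance values between the two groups is returned as
    ``{"slope", "p", "level"}``.
    """
    member_lineages = member_lineages or {}
    external_lineages = {s: parse_lineage(lineages[s]) for s in relabund.columns if s in lineages}

    columns: dict[str, np.ndarray] = {}
    unmatched: list[str] = []
    for member in balance.numerator + balance.denominator:
        if member in relabund.columns:
            columns[member] = relabund[member].to_numpy(dtype=float)
            continue
        series = _clade_sum(member, member_lineages.get(member), relabund, external_lineages)
        if series is None:
            unmatched.append(member)
        else:
            columns[member] = series
    if unmatched:
        raise ValueError(f"no external match (exact or clade) for: {unmatched}")

    matrix = pd.DataFrame(columns, index=relabund.index)
    positive = matrix.to_numpy()
    nonzero = positive[positive > 0]
    if nonzero.size == 0:
        raise ValueError("all matched abundances are zero")
    floor = nonzero.min() / 2.0
    matrix = matrix.where(matrix > 0, floor)
    values = balance_values(balance, matrix)

    comparison = None
    if group is not None:
        group = pd.Series(group).loc[values.index]
        coded, level = encode_factor(group)
        X = np.column_stack([np.ones(len(values)), coded])
        fit = ols_many(values.to_numpy()[:, None], X, test_col=1)
        comparison = {"slope": float(fit.coef[0]), "p": float(fit.p[0]), "level": level}
    return values, comparison


def _clade_sum(member, lineage_str, relabund, external_lineages):
    if lineage_str is None:
        return None
    lineage = parse_lineage(lineage_str)
    classified = [
        (i, part) for i, part in enumerate(lineage) if part != UNCLASSIFIED
    ]
    if not classified:
        return None
    depth, _ = classified[-1]
    prefix = lineage[: depth + 1]
    members = [
        species
        for species, lin in external_lineages.items()
        if lin[: depth + 1] == prefix
    ]
    if not members:
        return None
    return relabund.loc[:, members].sum(axis=1).to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# Sample-type AUC cross-validation
# ---------------------------------------------------------------------------

def sample_type_auc(
    data: CountTable,
    metadata: pd.DataFrame,
    n_iter: int = 500,
    seed: int = 0,
    test_fraction: float = 0.5,
    inner_iter: int = 50,
    inner_threshold: float = 0.80,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> tuple[float, float, np.ndarray]:
    """Repeated cross-validated AUC of the stool-vs-biopsy balance score.

    Each iteration splits *patients* (keeping pairs intact) into train and
    test; the reproducibility-refined sample-type balance is fit on the
    training samples (``inner_iter`` subsample iterations) and test
    samples are scored by their balance value; the AUC of scores against
    the true sample type is recorded. Returns (mean, sd, per-iteration
    AUCs).
    """
    design = AssociationDesign(
        factor="sample_type", random_group="patient_id", strata="patient_id"
    )
    meta = metadata.set_index("sample_id").loc[data.samples].reset_index()
    if meta["sample_type"].nunique() < 2:
        raise ValueError("both sample types must be present")
    comp = zero_replace(data, pseudocount)
    patients = meta["patient_id"].unique()
    n_test = max(1, int(round(test_fraction * len(patients))))
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_iter)
    for it in range(n_iter):
        while True:
            test_patients = rng.choice(patients, size=n_test, replace=False)
            test_mask = meta["patient_id"].isin(test_patients)
            test_meta = meta.loc[test_mask]
            train_meta = meta.loc[~test_mask]
            if (
                test_meta["sample_type"].nunique() == 2
                and train_meta["sample_type"].nunique() == 2
            ):
                break
        train_table = data.subset_samples(train_meta["sample_id"].tolist())
        fit = reproducible_balance(
            train_table,
            train_meta,
            design,
            n_iter=inner_iter,
            threshold=inner_threshold,
            seed=int(rng.integers(2**31)),
            pseudocount=pseudocount,
        )
        balance = fit.balance if not fit.balance.is_empty else fit.full_balance
        scores = balance_values(balance, comp.loc[test_meta["sample_id"]])
        labels = (test_meta.set_index("sample_id")["sample_type"] == "stool").astype(int)
        aucs[it] = roc_auc_score(labels.loc[scores.index], scores)
    return float(aucs.mean()), float(aucs.std(ddof=0)), aucs
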