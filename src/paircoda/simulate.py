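"""Synthetic paired stool/biopsy cohorts with known ground truth.

The generative family is logistic-normal/multinomial: each patient has a
latent clr profile drawn around a baseline mean with low-rank-plus-
diagonal covariance, shifted along a planted balance contrast by the
patient's factor value; the biopsy sample additionally receives a fixed
sample-type perturbation, both samples receive their batch's perturbation
and independent residual noise, and reads are drawn multinomially at a
log-normal depth. Because the clr-space structure is exactly what the
analysis stages assume, parameter recovery is a fair end-to-end test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .balances import Balance, BalanceFit
from .coda import clr_inverse
from .io import CountTable

_LINEAGE_TEMPLATE = (
    "d__Bacteria;p__Phylum{g};c__Class{g};o__Order{g};f__Family{g};"
    "g__Genus{i:03d};s__Species{i:03d}"
)


@dataclass
class SyntheticTruth:
    """Planted structure of a synthetic cohort."""

    taxa: tuple[str, ...]
    mu: np.ndarray                      # baseline clr mean, sums to 0
    cov_loadings: np.ndarray            # D x r low-rank loadings
    cov_diag: float                     # diagonal variance
    delta_type: np.ndarray              # biopsy-minus-stool clr shift, sums to 0
    batch_effect: np.ndarray            # clr shift of batch "B2", sums to 0
    type_balance: Balance | None        # balance carrying delta_type (if aligned)
    planted_balance: Balance            # factor-linked balance B*
    beta: float                         # clr shift per unit factor along B*
    factor_name: str                    # metadata column carrying the effect
    sigma_patient: float
    sigma_eps: float
    log_depth_mean: float               # natural-log scale
    log_depth_sigma: float
    blocks: tuple[tuple[str, ...], ...] = field(default=())
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mu", "delta_type", "batch_effect"):
            vec = np.asarray(getattr(self, name), dtype=float)
            if vec.shape != (len(self.taxa),):
                raise ValueError(f"{name} must have one entry per taxon")
            setattr(self, name, vec - vec.mean())  # enforce clr zero-sum
        self.cov_loadings = np.asarray(self.cov_loadings, dtype=float)
        if self.cov_loadings.shape[0] != len(self.taxa):
            raise ValueError("cov_loadings rows must match taxa")
        if min(self.sigma_patient, self.sigma_eps, self.cov_diag) < 0:
            raise ValueError("variance parameters must be non-negative")

    def contrast(self) -> np.ndarray:
        return self.planted_balance.contrast(list(self.taxa))

    def to_json(self, path) -> None:
        doc = asdict(self)
        for key in ("mu", "delta_type", "batch_effect", "cov_loadings"):
            doc[key] = np.asarray(doc[key]).tolist()
        doc["type_balance"] = self.type_balance.to_dict() if self.type_balance else None
        doc["planted_balance"] = self.planted_balance.to_dict()
        doc["blocks"] = [list(b) for b in self.blocks]
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2, sort_keys=True)


def default_truth(
    n_taxa: int = 150,
    seed: int = 0,
    beta: float = 1.0,
    type_effect: float = 4.0,
    batch_scale: float = 0.2,
    balance_size: tuple[int, int] | None = None,
    type_balance_size: tuple[int, int] | None = None,
    sigma_patient: float = 0.06,
    sigma_eps: float = 0.08,
    cov_rank: int = 3,
    cov_scale: float = 0.03,
    cov_diag: float = 0.005,
    median_depth: float = 3e4,
    log_depth_sigma: float = 0.4,
    factor_name: str = "n_lesions",
    blocks: tuple[tuple[str, ...], ...] = (),
) -> SyntheticTruth:
    """Construct a default planted truth.

    The factor-linked balance is planted on taxa of above-median baseline
    abundance so its members are reliably observed at the simulated
    sequencing depths; the sample-type shift is carried by a disjoint
    balance plus nothing else, so both are recoverable targets.
    """
    if n_taxa < 10:
        raise ValueError("need at least 10 taxa")
    # default planted-set sizes shrink with the taxon universe
    if balance_size is None:
        k = max(2, min(5, n_taxa // 8))
        balance_size = (k, k)
    if type_balance_size is None:
        k = max(2, min(8, n_taxa // 8))
        type_balance_size = (k, k)
    rng = np.random.default_rng(seed)
    taxa = tuple(f"sp{i:03d}" for i in range(n_taxa))
    mu = rng.normal(0.0, 1.5, size=n_taxa)
    mu -= mu.mean()
    loadings = rng.normal(0.0, cov_scale, size=(n_taxa, cov_rank))

    needed = sum(balance_size) + sum(type_balance_size)
    if needed > n_taxa:
        raise ValueError(
            f"balance sizes need {needed} distinct taxa but only {n_taxa} exist"
        )
    abundant = np.argsort(mu)[::-1][: max(n_taxa // 3, needed)]
    picks = rng.choice(abundant, size=sum(balance_size) + sum(type_balance_size), replace=False)
    kp, km = balance_size
    tp, tm = type_balance_size
    planted = Balance(
        tuple(taxa[i] for i in picks[:kp]),
        tuple(taxa[i] for i in picks[kp : kp + km]),
    )
    type_members = picks[kp + km :]
    type_balance = Balance(
        tuple(taxa[i] for i in type_members[:tp]),
        tuple(taxa[i] for i in type_members[tp : tp + tm]),
    )
    delta_type = type_effect * type_balance.contrast(list(taxa))

    batch_effect = rng.normal(0.0, 1.0, size=n_taxa)
    batch_effect -= batch_effect.mean()
    batch_effect *= batch_scale / max(np.linalg.norm(batch_effect), 1e-12)
    batch_effect *= np.sqrt(n_taxa)  # keep per-taxon scale depth-independent

    return SyntheticTruth(
        taxa=taxa,
        mu=mu,
        cov_loadings=loadings,
        cov_diag=cov_diag,
        delta_type=delta_type,
        batch_effect=batch_effect,
        type_balance=type_balance,
        planted_balance=planted,
        beta=beta,
        factor_name=factor_name,
        sigma_patient=sigma_patient,
        sigma_eps=sigma_eps,
        log_depth_mean=float(np.log(median_depth)),
        log_depth_sigma=log_depth_sigma,
        blocks=blocks,
        seed=seed,
    )


def block_truth(
    n_taxa: int = 30,
    block_sizes: tuple[int, int] = (5, 5),
    partial_corr: float = 0.24,
    background_var: float = 0.4,
    seed: int = 0,
    **kwargs,
) -> SyntheticTruth:
    """Truth with two planted co-abundance blocks (for network recovery).

    Blocks are planted directly in the latent precision matrix — each
    block's members share uniform negative precision off-diagonals (i.e.
    uniform positive partial correlation ``partial_corr``) on an otherwise
    diagonal background — which is exactly the conditional-dependence
    structure neighborhood selection estimates. Positive-definiteness
    caps ``partial_corr`` below 1/(block size - 1). Sample-type, batch
    and factor shifts default to zero so the co-abundance signal is pure.
    """
    kwargs.setdefault("type_effect", 0.0)
    kwargs.setdefault("batch_scale", 0.0)
    kwargs.setdefault("beta", 0.0)
    kwargs.setdefault("sigma_patient", 0.05)
    kwargs.setdefault("sigma_eps", 0.05)
    kwargs.setdefault("balance_size", (2, 2))
    kwargs.setdefault("type_balance_size", (2, 2))
    truth = default_truth(n_taxa=n_taxa, seed=seed, cov_scale=0.0, cov_diag=0.0, **kwargs)
    if any(partial_corr >= 1.0 / (k - 1) for k in block_sizes):
        raise ValueError("partial_corr too large for the block sizes (not PD)")
    rng = np.random.default_rng(seed + 1)
    D = n_taxa
    order = rng.permutation(D)
    precision = np.eye(D) / background_var
    start = 0
    blocks = []
    for size in block_sizes:
        members = np.sort(order[start : start + size])
        start += size
        omega = (np.eye(size) - partial_corr * (np.ones((size, size)) - np.eye(size)))
        precision[np.ix_(members, members)] = omega / background_var
        blocks.append(tuple(sorted(truth.taxa[i] for i in members)))
    cov = np.linalg.inv(precision)
    # express the full covariance through the loadings (cov_diag = 0)
    truth.cov_loadings = np.linalg.cholesky(cov)
    truth.blocks = tuple(blocks)
    # give block taxa a visible baseline so counts are informative
    members = order[: sum(block_sizes)]
    truth.mu[members] = np.abs(truth.mu[members])
    truth.mu -= truth.mu.mean()
    return truth


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

#: Cohort-level marginals used for lesion metadata (fractions of patients).
_MARGINALS = {
    "location_right": 17 / 50,
    "multiple_lesions": 16 / 50,
    "size_large": 23 / 50,
    "nice_gt1": 40 / 50,
}


def generate_cohort(
    n_patients: int = 50,
    truth: SyntheticTruth | None = None,
    n_taxa: int = 150,
    seed: int | None = None,
) -> tuple[CountTable, pd.DataFrame, SyntheticTruth]:
    """Simulate a paired stool/biopsy cohort from a planted truth.

    Returns the count table (taxa x samples), the per-sample metadata and
    the truth object. Fully deterministic given the truth and seed.
    """
    if n_patients < 4:
        raise ValueError("need at least 4 patients")
    if truth is None:
        truth = default_truth(n_taxa=n_taxa)
    if seed is None:
        seed = truth.seed
    rng = np.random.default_rng(seed)
    D = len(truth.taxa)
    contrast = truth.contrast()

    metadata = _draw_metadata(n_patients, rng)
    factor01 = _factor_codes(metadata, truth.factor_name)

    counts: dict[str, np.ndarray] = {}
    records = []
    for i, row in metadata.iterrows():
        z_common = (
            truth.mu
            + truth.beta * factor01[i] * contrast
            + rng.normal(0.0, truth.sigma_patient, size=D)
            + truth.cov_loadings @ rng.normal(size=truth.cov_loadings.shape[1])
        )
        batch_shift = truth.batch_effect if row["batch"] == "B2" else 0.0
        for sample_type in ("stool", "biopsy"):
            z = z_common + batch_shift + rng.normal(0.0, truth.sigma_eps, size=D)
            if sample_type == "biopsy":
                z = z + truth.delta_type
            composition = clr_inverse(z - z.mean())
            depth = int(np.round(np.exp(
                rng.normal(truth.log_depth_mean, truth.log_depth_sigma)
            )))
            depth = max(depth, 100)
            sample_id = f"{row['patient_id']}_{sample_type}"
            counts[sample_id] = rng.multinomial(depth, composition)
            records.append({**row.to_dict(), "sample_id": sample_id, "sample_type": sample_type})

    table = CountTable(
        pd.DataFrame(counts, index=pd.Index(truth.taxa, name="taxon_id")),
        pd.Series(
            [_LINEAGE_TEMPLATE.format(g=i % 7, i=i) for i in range(D)],
            index=list(truth.taxa),
        ),
    )
    meta = pd.DataFrame(records)
    cols = ["sample_id", "patient_id", "sample_type", "batch"]
    meta = meta[cols + [c for c in meta.columns if c not in cols]]
    return table, meta, truth


def _draw_metadata(n_patients: int, rng: np.random.Generator) -> pd.DataFrame:
    def split(fraction: float) -> np.ndarray:
        k = int(round(fraction * n_patients))
        flags = np.zeros(n_patients, dtype=bool)
        flags[rng.choice(n_patients, size=k, replace=False)] = True
        return flags

    right = split(_MARGINALS["location_right"])
    multiple = split(_MARGINALS["multiple_lesions"])
    large = split(_MARGINALS["size_large"])
    nice_hi = split(_MARGINALS["nice_gt1"])
    batch = np.where(split(0.5), "B2", "B1")
    pathway = np.where(split(32 / 50), "adenoma-carcinoma", "serrated")
    return pd.DataFrame(
        {
            "patient_id": [f"P{i:03d}" for i in range(n_patients)],
            "batch": batch,
            "location": np.where(right, "Right", "Left"),
            "n_lesions": np.where(multiple, ">1", "1"),
            "size": np.where(large, ">=10 mm", "<10 mm"),
            "nice": np.where(nice_hi, ">1", "1"),
            "pathway": pathway,
        }
    )


def _factor_codes(metadata: pd.DataFrame, factor_name: str) -> np.ndarray:
    values = metadata[factor_name]
    if pd.api.types.is_numeric_dtype(values):
        return values.to_numpy(dtype=float)
    levels = sorted(values.unique())
    if len(levels) != 2:
        raise ValueError(f"planted factor {factor_name!r} must be binary")
    return (values == levels[1]).to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# Recovery metrics
# ---------------------------------------------------------------------------

def jaccard(a, b) -> float:
    a, b = set(a), set(b)
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def signed_jaccard(recovered: Balance, planted: Balance) -> float:
    """Side-respecting Jaccard: matched members over the union, summed
    across numerator and denominator."""
    num_r, den_r = set(recovered.numerator), set(recovered.denominator)
    num_p, den_p = set(planted.numerator), set(planted.denominator)
    inter = len(num_r & num_p) + len(den_r & den_p)
    union = len(num_r | num_p) + len(den_r | den_p)
    return inter / union if union else 1.0


def balance_recovery(
    recovered: BalanceFit | Balance, truth: SyntheticTruth
) -> dict:
    """Jaccard/cosine recovery report for a recovered balance."""
    planted = truth.planted_balance
    if isinstance(recovered, BalanceFit):
        balance = recovered.balance if not recovered.balance.is_empty else recovered.full_balance
        b = recovered.coefficients.reindex(list(truth.taxa)).to_numpy()
        cosine = float(
            truth.contrast() @ b / max(np.linalg.norm(b), 1e-300)
        )
    else:
        balance = recovered
        cosine = float("nan")
        if not balance.is_empty:
            rec_contrast = balance.contrast(list(truth.taxa))
            cosine = float(truth.contrast() @ rec_contrast)
    oriented = balance
    if not balance.is_empty and signed_jaccard(balance.flip(), planted) > signed_jaccard(
        balance, planted
    ):
        oriented = balance.flip()
    return {
        "jaccard_numerator": jaccard(oriented.numerator, planted.numerator),
        "jaccard_denominator": jaccard(oriented.denominator, planted.denominator),
        "jaccard_signed": signed_jaccard(oriented, planted),
        "jaccard_union": jaccard(
            set(oriented.numerator) | set(oriented.denominator),
            set(planted.numerator) | set(planted.denominator),
        ),
        "cosine_coefficients": cosine,
    }


def correction_error(estimated_delta_clr: np.ndarray, truth: SyntheticTruth) -> float:
    """clr-space L2 error of an estimated sample-type shift vs the truth."""
    est = np.asarray(estimated_delta_clr, dtype=float)
    est = est - est.mean()
    return float(np.linalg.norm(est - truth.delta_type))


def block_ari(clusters: list[frozenset], truth: SyntheticTruth) -> float:
    """Adjusted Rand index of recovered clusters vs planted blocks,
    computed over the planted-block taxa (unclustered taxa get singleton
    labels)."""
    from sklearn.metrics import adjusted_rand_score

    if not truth.blocks:
        raise ValueError("truth has no planted blocks")
    block_taxa = [t for block in truth.blocks for t in block]
    true_labels = {t: b for b, block in enumerate(truth.blocks) for t in block}
    pred_labels = {}
    for c, members in enumerate(clusters):
        for t in members:
            pred_labels[t] = c
    next_label = len(clusters)
    y_true, y_pred = [], []
    for t in block_taxa:
        y_true.append(true_labels[t])
        if t in pred_labels:
            y_pred.append(pred_labels[t])
        else:
            y_pred.append(next_label)
            next_label += 1
    return float(adjusted_rand_score(y_true, y_pred))


def network_edge_metrics(net, truth: SyntheticTruth) -> dict:
    """Precision/recall of network edges against within-block pairs."""
    if not truth.blocks:
        raise ValueError("truth has no planted blocks")
    true_edges = set()
    for block in truth.blocks:
        members = sorted(block)
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                true_edges.add(frozenset((a, b)))
    found = set(net.edges)
    tp = len(found & true_edges)
    precision = tp / len(found) if found else 0.0
    recall = tp / len(true_edges) if true_edges else 1.0
    return {"precision": precision, "recall": recall, "n_edges": len(found)}


def truth_metrics(recovered, truth: SyntheticTruth) -> dict:
    """Dispatch recovery metrics by the type of ``recovered``."""
    from .networks import CoabundanceNetwork

    if isinstance(recovered, (Balance, BalanceFit)):
        return balance_recovery(recovered, truth)
    if isinstance(recovered, CoabundanceNetwork):
        return network_edge_metrics(recovered, truth)
    if isinstance(recovered, np.ndarray):
        return {"delta_type_error": correction_error(recovered, truth)}
    if isinstance(recovered, list):
        return {"block_ari": block_ari(recovered, truth)}
    raise TypeError(f"cannot score object of type {type(recovered)!r}")
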