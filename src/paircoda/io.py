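"""Count-table and metadata I/O, contaminant removal, metadata aggregation.

Count tables are tab-separated: one row per taxon, a ``taxon_id`` column,
a ``lineage`` column holding a semicolon-delimited rank string
(domain;phylum;class;order;family;genus;species, missing ranks may be
empty or the literal ``unclassified``), and one integer column per sample.
A read-only BIOM-style JSON reader (format 1.0, dense or sparse) is also
provided.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Taxonomic ranks, shallowest to deepest.
RANKS: tuple[str, ...] = (
    "domain",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

UNCLASSIFIED = "unclassified"

TAXON_COL = "taxon_id"
LINEAGE_COL = "lineage"


def parse_lineage(lineage: str) -> tuple[str, ...]:
    """Split a semicolon-delimited lineage into a 7-tuple of rank names.

    Missing trailing ranks and empty fields become ``"unclassified"``.
    """
    if lineage is None or (isinstance(lineage, float) and np.isnan(lineage)):
        parts: list[str] = []
    else:
        parts = [p.strip() for p in str(lineage).split(";")]
    out = []
    for i in range(len(RANKS)):
        value = parts[i] if i < len(parts) else ""
        out.append(value if value else UNCLASSIFIED)
    return tuple(out)


@dataclass
class CountTable:
    """Non-negative integer taxon-by-sample matrix with lineages.

    ``counts`` is taxa (rows) by samples (columns); ``lineages`` maps each
    taxon id to its semicolon-delimited rank string.
    """

    counts: pd.DataFrame
    lineages: pd.Series

    def __post_init__(self) -> None:
        counts = self.counts
        if counts.index.has_duplicates:
            dupes = counts.index[counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate taxon ids: {dupes}")
        if counts.columns.has_duplicates:
            dupes = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dupes}")
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts must be integers")
            counts = counts.round().astype(np.int64)
        if (counts.to_numpy() < 0).any():
            taxon, sample = self._first_negative(counts)
            raise ValueError(
                f"negative count at taxon {taxon!r}, sample {sample!r}"
            )
        self.counts = counts.astype(np.int64)
        lineages = pd.Series(self.lineages, dtype=object)
        self.lineages = lineages.reindex(counts.index).fillna(UNCLASSIFIED)

    @staticmethod
    def _first_negative(counts: pd.DataFrame) -> tuple[str, str]:
        rows, cols = np.nonzero(counts.to_numpy() < 0)
        return counts.index[rows[0]], counts.columns[cols[0]]

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def lineage_table(self) -> pd.DataFrame:
        """Lineages parsed into one column per rank."""
        parsed = [parse_lineage(self.lineages.loc[t]) for t in self.taxa]
        return pd.DataFrame(parsed, index=self.counts.index, columns=RANKS)

    def subset_taxa(self, taxa: Sequence[str]) -> "CountTable":
        return CountTable(self.counts.loc[list(taxa)], self.lineages.loc[list(taxa)])

    def subset_samples(self, samples: Sequence[str]) -> "CountTable":
        return CountTable(self.counts.loc[:, list(samples)], self.lineages)

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)


def read_count_table(path: str | Path, format: str = "tsv") -> CountTable:
    """Read a count table from TSV or BIOM-style JSON.

    TSV dialect: header row of sample ids, first column ``taxon_id``,
    second column semicolon-delimited ``lineage``, remaining columns
    integer counts.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        return _read_tsv(path)
    if format == "biom":
        return _read_biom_json(path)
    raise ValueError(f"unknown format {format!r}; expected 'tsv' or 'biom'")


def _read_tsv(path: Path) -> CountTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if TAXON_COL not in df.columns or LINEAGE_COL not in df.columns:
        raise ValueError(
            f"{path}: expected columns {TAXON_COL!r} and {LINEAGE_COL!r}, "
            f"got {list(df.columns)[:4]}"
        )
    sample_cols = [c for c in df.columns if c not in (TAXON_COL, LINEAGE_COL)]
    counts = {}
    for col in sample_cols:
        try:
            counts[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            bad = df.loc[pd.to_numeric(df[col], errors="coerce").isna(), TAXON_COL]
            raise ValueError(
                f"{path}: non-numeric count in sample {col!r}, "
                f"taxon {bad.iloc[0]!r}"
            ) from exc
    matrix = pd.DataFrame(counts)
    matrix.index = df[TAXON_COL]
    matrix.index.name = TAXON_COL
    neg = matrix.lt(0)
    if neg.to_numpy().any():
        rows, cols = np.nonzero(neg.to_numpy())
        raise ValueError(
            f"{path}: negative count at taxon {matrix.index[rows[0]]!r}, "
            f"sample {matrix.columns[cols[0]]!r}"
        )
    lineages = pd.Series(df[LINEAGE_COL].to_numpy(), index=matrix.index)
    return CountTable(matrix, lineages)


def _read_biom_json(path: Path) -> CountTable:
    with open(path) as fh:
        doc = json.load(fh)
    taxa = [r["id"] for r in doc["rows"]]
    samples = [c["id"] for c in doc["columns"]]
    matrix = np.zeros((len(taxa), len(samples)))
    if doc.get("matrix_type") == "sparse":
        for i, j, v in doc["data"]:
            matrix[int(i), int(j)] = v
    else:
        matrix[:] = np.asarray(doc["data"], dtype=float)
    lineages = []
    for row in doc["rows"]:
        meta = row.get("metadata") or {}
        tax = meta.get("taxonomy")
        lineages.append(";".join(tax) if tax else UNCLASSIFIED)
    counts = pd.DataFrame(matrix, index=pd.Index(taxa, name=TAXON_COL), columns=samples)
    return CountTable(counts, pd.Series(lineages, index=counts.index))


def write_count_table(table: CountTable, path: str | Path) -> None:
    """Write a count table in the TSV dialect ``read_count_table`` accepts."""
    out = table.counts.copy()
    out.insert(0, LINEAGE_COL, table.lineages)
    out.index.name = TAXON_COL
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Contaminant removal
# ---------------------------------------------------------------------------

def remove_contaminants(
    table: CountTable,
    control: pd.Series | Mapping[str, int],
    tau: float = 1.0,
    samples: Sequence[str] | None = None,
) -> tuple[CountTable, list[str]]:
    """Drop taxa over-represented in a batch's negative-control library.

    A taxon is removed (as a whole row, from all the given samples' batch)
    iff its relative abundance in the control is at least ``tau`` times its
    mean relative abundance across the batch's biological samples. Taxa
    absent from the control are always retained; an all-zero control leaves
    the table unchanged.

    Returns the filtered table and the list of removed taxon ids.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    control = pd.Series(control, dtype=float)
    unknown = control.index.difference(table.counts.index)
    if len(unknown):
        raise ValueError(f"control taxa not in table: {list(unknown)}")
    control = control.reindex(table.counts.index, fill_value=0.0)
    total = float(control.sum())
    if total == 0:
        return table, []
    control_ra = control / total
    sub = table.counts if samples is None else table.counts.loc[:, list(samples)]
    sample_ra = sub / sub.sum(axis=0)
    mean_ra = sample_ra.mean(axis=1)
    removed_mask = (control_ra > 0) & (control_ra >= tau * mean_ra)
    removed = sorted(table.counts.index[removed_mask])
    kept = [t for t in table.taxa if t not in set(removed)]
    if removed:
        logger.info("remove_contaminants: dropping %d taxa: %s", len(removed), removed)
    return table.subset_taxa(kept), removed


def remove_contaminants_batched(
    table: CountTable,
    metadata: pd.DataFrame,
    controls: Mapping[str, pd.Series | Mapping[str, int]],
    tau: float = 1.0,
) -> tuple[CountTable, dict[str, list[str]]]:
    """Apply :func:`remove_contaminants` per batch and take the union.

    ``controls`` maps batch id to that batch's negative-control counts.
    A taxon flagged in any batch is removed from the whole table (keeping
    the taxon set consistent across batches for downstream compositional
    work).
    """
    removed_by_batch: dict[str, list[str]] = {}
    all_removed: set[str] = set()
    for batch, control in controls.items():
        batch_samples = metadata.loc[metadata["batch"] == batch, "sample_id"]
        batch_samples = [s for s in batch_samples if s in table.counts.columns]
        if not batch_samples:
            continue
        _, removed = remove_contaminants(table, control, tau=tau, samples=batch_samples)
        removed_by_batch[batch] = removed
        all_removed.update(removed)
    kept = [t for t in table.taxa if t not in all_removed]
    return table.subset_taxa(kept), removed_by_batch


# ---------------------------------------------------------------------------
# Metadata
# ---------------------------------------------------------------------------

SAMPLE_TYPES = ("stool", "biopsy")

#: Aggregation vocabularies: raw category -> aggregated category.
LOCATION_MAP = {
    "cecum": "Right",
    "ascending colon": "Right",
    "transverse colon": "Right",
    "descending colon": "Left",
    "sigmoid colon": "Left",
    "rectum": "Left",
    # idempotence
    "right": "Right",
    "left": "Left",
}

NICE_MAP = {"1": "1", "2": ">1", "3": ">1", ">1": ">1"}

SIZE_MAP = {
    "<5 mm": "<10 mm",
    "6-9 mm": "<10 mm",
    "10-14 mm": ">=10 mm",
    "15-19 mm": ">=10 mm",
    ">20 mm": ">=10 mm",
    # idempotence
    "<10 mm": "<10 mm",
    ">=10 mm": ">=10 mm",
}

AGGREGATED_COLUMNS = ("location", "nice", "n_lesions", "size")


def _normalize(value: object) -> str:
    s = str(value).strip().lower()
    s = s.replace("–", "-").replace("—", "-")  # en/em dash
    s = s.replace("≥", ">=")
    return " ".join(s.split())


def _map_column(values: pd.Series, mapping: Mapping[str, str], name: str) -> pd.Series:
    out = []
    bad = set()
    for v in values:
        if pd.isna(v):
            out.append(v)
            continue
        key = _normalize(v)
        if key in mapping:
            out.append(mapping[key])
        else:
            bad.add(str(v))
            out.append(v)
    if bad:
        raise ValueError(f"unknown {name} categories: {sorted(bad)}")
    return pd.Series(out, index=values.index, dtype=object)


def _aggregate_lesion_count(values: pd.Series) -> pd.Series:
    out = []
    bad = set()
    for v in values:
        if pd.isna(v):
            out.append(v)
            continue
        s = _normalize(v)
        if s == ">1":
            out.append(">1")
            continue
        try:
            n = int(float(s))
        except ValueError:
            bad.add(str(v))
            out.append(v)
            continue
        if n < 1:
            bad.add(str(v))
            out.append(v)
        else:
            out.append("1" if n == 1 else ">1")
    if bad:
        raise ValueError(f"unknown n_lesions values: {sorted(bad)}")
    return pd.Series(out, index=values.index, dtype=object)


def aggregate_metadata(raw: pd.DataFrame) -> pd.DataFrame:
    """Collapse lesion-characteristic categories into coarse two-level groups.

    Location: cecum / ascending colon / transverse colon -> ``Right``;
    descending colon / sigmoid colon / rectum -> ``Left``. NICE category:
    1 -> ``1``, 2 or 3 -> ``>1``. Number of lesions: 1 -> ``1``, two or
    more -> ``>1``. Size: bands under 10 mm -> ``<10 mm``, bands at or
    above -> ``>=10 mm``. Missing values pass through; columns not present
    are ignored; the operation is idempotent.
    """
    out = raw.copy()
    if "location" in out.columns:
        out["location"] = _map_column(out["location"], LOCATION_MAP, "location")
    if "nice" in out.columns:
        out["nice"] = _map_column(out["nice"].astype(object), NICE_MAP, "nice")
    if "n_lesions" in out.columns:
        out["n_lesions"] = _aggregate_lesion_count(out["n_lesions"])
    if "size" in out.columns:
        out["size"] = _map_column(out["size"], SIZE_MAP, "size")
    return out


def validate_metadata(
    metadata: pd.DataFrame, table: CountTable | None = None
) -> pd.DataFrame:
    """Check structural invariants of a per-sample metadata table.

    Requires ``sample_id``, ``patient_id`` and ``sample_type`` columns;
    sample ids must be unique, sample types drawn from stool/biopsy, and
    each patient may contribute at most one sample of each type. When a
    count table is given, every one of its samples must have a record.
    """
    for col in ("sample_id", "patient_id", "sample_type"):
        if col not in metadata.columns:
            raise ValueError(f"metadata missing required column {col!r}")
    if metadata["sample_id"].duplicated().any():
        dupes = metadata.loc[metadata["sample_id"].duplicated(), "sample_id"]
        raise ValueError(f"duplicate sample ids in metadata: {list(dupes)}")
    bad_types = set(metadata["sample_type"]) - set(SAMPLE_TYPES)
    if bad_types:
        raise ValueError(f"invalid sample types: {sorted(bad_types)}")
    per_patient = metadata.groupby(["patient_id", "sample_type"]).size()
    if (per_patient > 1).any():
        offenders = per_patient[per_patient > 1].index.tolist()
        raise ValueError(f"patients with duplicated sample types: {offenders}")
    if table is not None:
        missing = set(table.samples) - set(metadata["sample_id"])
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
    return metadata


def read_metadata(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sample_id": str, "patient_id": str})


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.to_csv(path, sep="\t", index=False)
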