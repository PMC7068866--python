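"""Expression-matrix and label I/O plus the validated in-memory dataset.

The on-disk contract is deliberately plain: a delimited text matrix with
genes in rows (first column ``probe_id``, header row of sample ids) and a
two-column labels file mapping each sample id to class 1 or 2.  Values are
assumed to be already normalised (typically log scale); the loader performs
no normalisation beyond an optional log2(x + 1) transform.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import FrequencyTable, GeneticSignature

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionDataset",
    "load_dataset",
    "write_dataset",
    "write_frequency_table",
    "write_signatures",
    "read_signatures",
]


def _sep_for(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


@dataclass
class ExpressionDataset:
    """A genes x samples expression matrix with binary sample labels.

    ``values`` has shape (s, n) with s genes and n samples; ``labels`` holds
    class codes in {1, 2}.  The constructor validates shape, uniqueness of
    identifiers, absence of missing values and presence of both classes.
    """

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        s, n = self.values.shape
        if s < 1 or n < 2:
            raise ValueError("need at least 1 gene and 2 samples")
        if len(self.probe_ids) != s:
            raise ValueError("probe_ids length does not match the matrix")
        if len(self.sample_ids) != n or len(self.labels) != n:
            raise ValueError("sample_ids/labels length does not match the matrix")
        dup = _first_duplicate(self.probe_ids)
        if dup is not None:
            raise ValueError(f"duplicate probe id: {dup!r}")
        dup = _first_duplicate(self.sample_ids)
        if dup is not None:
            raise ValueError(f"duplicate sample id: {dup!r}")
        if not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value at probe {self.probe_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )
        present = set(np.unique(self.labels))
        if not present <= {1, 2}:
            raise ValueError(f"labels must be 1 or 2, got {sorted(present)}")
        if present != {1, 2}:
            raise ValueError("both classes required (labels must include 1 and 2)")

    # -- basic geometry -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def class_indices(self, label: int) -> np.ndarray:
        return np.flatnonzero(self.labels == label)

    def subset_samples(self, indices: np.ndarray | list[int]) -> "ExpressionDataset":
        """A new dataset restricted to the given sample columns (gene space unchanged)."""
        idx = np.asarray(indices, dtype=np.int64)
        return ExpressionDataset(
            probe_ids=self.probe_ids,
            sample_ids=[self.sample_ids[i] for i in idx],
            values=self.values[:, idx],
            labels=self.labels[idx],
        )


def _first_duplicate(items: list[str]) -> str | None:
    seen: set[str] = set()
    for it in items:
        if it in seen:
            return it
        seen.add(it)
    return None


def load_dataset(
    matrix_path: str | Path,
    labels_path: str | Path,
    *,
    log2_transform: bool = False,
    impute: bool = False,
) -> ExpressionDataset:
    """Load and validate an expression matrix and its class labels.

    Samples present in the matrix but absent from the labels file are dropped
    with a warning; label entries without a matrix column are an error.
    Missing values are rejected unless ``impute`` is set, in which case each
    missing cell is replaced by its gene's within-class mean.
    """
    matrix_path, labels_path = Path(matrix_path), Path(labels_path)
    mat = pd.read_csv(
        matrix_path, sep=_sep_for(matrix_path), index_col=0, dtype={0: str},
        float_precision="round_trip",
    )
    if mat.index.has_duplicates:
        dup = mat.index[mat.index.duplicated()][0]
        raise ValueError(f"duplicate probe id: {dup!r}")

    lab = pd.read_csv(
        labels_path, sep=_sep_for(labels_path), header=None, names=["sample_id", "class"],
        dtype={"sample_id": str},
        comment="#",
    )
    # tolerate an optional header row
    if str(lab.iloc[0, 1]).strip().lower() in {"class", "label"}:
        lab = lab.iloc[1:]
    labels_map = dict(zip(lab["sample_id"].astype(str), lab["class"].astype(int)))

    missing_cols = [s for s in labels_map if s not in mat.columns]
    if missing_cols:
        raise ValueError(f"label entries without matrix columns: {missing_cols[:5]}")
    dropped = [c for c in mat.columns if c not in labels_map]
    if dropped:
        logger.warning("dropping %d unlabelled sample column(s): %s", len(dropped), dropped[:5])
        mat = mat.drop(columns=dropped)

    # locate non-numeric cells before coercion so the error names them
    values = mat.apply(pd.to_numeric, errors="coerce")
    bad = values.isna() & mat.notna()
    if bad.any().any():
        r, c = next(zip(*np.where(bad.values)))
        raise ValueError(
            f"non-numeric value at probe {mat.index[r]!r}, sample {mat.columns[c]!r}"
        )
    if values.isna().any().any():
        if not impute:
            r, c = next(zip(*np.where(values.isna().values)))
            raise ValueError(
                f"missing value at probe {values.index[r]!r}, sample {values.columns[c]!r} "
                "(pass impute=True to fill with class means)"
            )
        labels_arr = np.array([labels_map[s] for s in values.columns])
        arr = values.values
        for cls in (1, 2):
            cols = labels_arr == cls
            block = arr[:, cols]
            means = np.nanmean(block, axis=1, keepdims=True)
            inds = np.where(np.isnan(block))
            block[inds] = np.take(means[:, 0], inds[0])
            arr[:, cols] = block
        values = pd.DataFrame(arr, index=values.index, columns=values.columns)

    arr = values.values.astype(float)
    if log2_transform:
        arr = np.log2(arr + 1.0)
    return ExpressionDataset(
        probe_ids=[str(p) for p in values.index],
        sample_ids=[str(c) for c in values.columns],
        values=arr,
        labels=np.array([labels_map[str(c)] for c in values.columns]),
    )


def write_dataset(
    dataset: ExpressionDataset, matrix_path: str | Path, labels_path: str | Path
) -> None:
    """Write matrix + labels files that :func:`load_dataset` round-trips bit-exactly.

    Values are serialised with 17 significant digits (repr round-trip for
    float64).
    """
    matrix_path, labels_path = Path(matrix_path), Path(labels_path)
    df = pd.DataFrame(dataset.values, index=dataset.probe_ids, columns=dataset.sample_ids)
    df.index.name = "probe_id"
    df.to_csv(matrix_path, sep=_sep_for(matrix_path), float_format="%.17g")
    with open(labels_path, "w") as fh:
        for sid, lab in zip(dataset.sample_ids, dataset.labels):
            fh.write(f"{sid}{_sep_for(labels_path)}{lab}\n")


def write_frequency_table(table: FrequencyTable, path: str | Path) -> None:
    """Serialise a frequency table as TSV (probe_id, frequency, rank).

    Rows come out sorted by descending frequency with ties broken by probe id
    — the table's own rank order.
    """
    if len(table) == 0:
        raise ValueError("cannot write an empty frequency table")
    with open(path, "w") as fh:
        fh.write("probe_id\tfrequency\trank\n")
        for rank, (pid, freq) in enumerate(zip(table.probe_ids, table.frequencies), start=1):
            fh.write(f"{pid}\t{freq:.12g}\t{rank}\n")


def write_signatures(
    signatures: list[GeneticSignature], sampler: str, probe_ids: list[str], path: str | Path
) -> None:
    """Dump retained signatures as JSON lines, one object per network."""
    with open(path, "w") as fh:
        for sig in signatures:
            fh.write(
                json.dumps(
                    {
                        "genes": [probe_ids[g] for g in sig.genes],
                        "accuracy": sig.accuracy,
                        "sampler": sampler,
                        "iteration": sig.iteration,
                    }
                )
                + "\n"
            )


def read_signatures(path: str | Path) -> list[dict]:
    """Read a JSON-lines signature dump back into a list of dicts."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(json.loads(line))
    return out
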