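"""Expression-matrix I/O, preprocessing and train/test splitting.

The central container is :class:`ExpressionDataset`: an ``n x p`` matrix of
log2-scale expression values together with a continuous per-sample response
(a clinical dose or chemical concentration).  Datasets arrive either from a
GEO Series Matrix export (probes as rows, samples as columns, ``!``-prefixed
metadata) or from the package's own TSV dialect
(``sample_id<TAB>dose<TAB><gene>...``, missing values written ``NA``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "ExpressionDataset",
    "SplitPair",
    "SeriesMatrixError",
    "NoResponseError",
    "EmptyDatasetError",
    "read_series_matrix",
    "read_tsv",
    "write_tsv",
    "preprocess",
    "split_train_test",
]

_MISSING_TOKENS = {"", "null", "NULL", "NA", "na", "NaN", "nan"}


class SeriesMatrixError(ValueError):
    """Raised when a Series Matrix file is structurally malformed."""


class NoResponseError(ValueError):
    """Raised when no dose/response mapping can be resolved for a dataset."""


class EmptyDatasetError(ValueError):
    """Raised when an operation would leave a dataset with no genes or samples."""


@dataclass
class ExpressionDataset:
    """Samples-by-genes expression matrix with a continuous response.

    Attributes
    ----------
    sample_ids : list of str
    gene_ids : list of str
    X : ndarray, shape (n_samples, n_genes)
        Expression values; NaN marks missing cells prior to preprocessing.
    y : ndarray, shape (n_samples,)
        Dose / concentration response, dataset-specific units.
    meta : dict
        Free-form annotations (organism, response name, true support, ...).
    """

    sample_ids: list[str]
    gene_ids: list[str]
    X: np.ndarray
    y: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n, p = self.X.shape
        if len(self.sample_ids) != n or len(self.y) != n:
            raise ValueError(
                f"inconsistent sample dimension: X has {n} rows, "
                f"{len(self.sample_ids)} sample_ids, {len(self.y)} responses"
            )
        if len(self.gene_ids) != p:
            raise ValueError(
                f"inconsistent gene dimension: X has {p} columns, "
                f"{len(self.gene_ids)} gene_ids"
            )
        if not np.all(np.isfinite(self.y)):
            raise ValueError("response vector must be finite")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_genes(self) -> int:
        return self.X.shape[1]

    def subset_samples(self, idx: np.ndarray) -> "ExpressionDataset":
        idx = np.asarray(idx)
        return ExpressionDataset(
            sample_ids=[self.sample_ids[i] for i in idx],
            gene_ids=list(self.gene_ids),
            X=self.X[idx].copy(),
            y=self.y[idx].copy(),
            meta=dict(self.meta),
        )


@dataclass
class SplitPair:
    """A reproducible train/test partition of one dataset."""

    train: ExpressionDataset
    test: ExpressionDataset
    seed: int
    train_fraction: float

    def __post_init__(self) -> None:
        tr = set(self.train.sample_ids)
        te = set(self.test.sample_ids)
        if tr & te:
            raise ValueError("train and test sample_ids overlap")


def _parse_cell(token: str) -> float:
    token = token.strip().strip('"')
    if token in _MISSING_TOKENS:
        return math.nan
    return float(token)


def read_series_matrix(
    path: str | Path,
    dose: np.ndarray | list[float] | None = None,
    dose_key: str | None = None,
) -> ExpressionDataset:
    """Read a GEO Series Matrix TXT export.

    The file layout is ``!``-prefixed metadata lines followed by a
    tab-delimited table between ``!series_matrix_table_begin`` and
    ``!series_matrix_table_end`` whose first column is the probe ID and whose
    remaining columns are samples.  The table is transposed so that genes
    become columns.

    The response must be supplied either directly (``dose``) or by naming a
    ``!Sample_characteristics_ch1`` key of the form ``key: value`` whose
    values parse as numbers (``dose_key``).
    """
    path = Path(path)
    meta: dict[str, list[str]] = {}
    header: list[str] | None = None
    rows: list[tuple[str, list[float]]] = []
    in_table = False
    saw_begin = saw_end = False

    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("!series_matrix_table_begin"):
                if saw_begin:
                    raise SeriesMatrixError(
                        f"line {lineno}: duplicate table begin marker"
                    )
                saw_begin, in_table = True, True
                continue
            if line.startswith("!series_matrix_table_end"):
                if not in_table:
                    raise SeriesMatrixError(
                        f"line {lineno}: table end marker before begin"
                    )
                saw_end, in_table = True, False
                continue
            if line.startswith("!"):
                if in_table:
                    raise SeriesMatrixError(
                        f"line {lineno}: metadata line inside table"
                    )
                key, _, value = line[1:].partition("\t")
                meta.setdefault(key, []).append(value.strip().strip('"'))
                continue
            if not in_table:
                continue
            fields = line.split("\t")
            if header is None:
                header = [f.strip().strip('"') for f in fields]
                continue
            probe = fields[0].strip().strip('"')
            values = [_parse_cell(tok) for tok in fields[1:]]
            if len(values) != len(header) - 1:
                raise SeriesMatrixError(
                    f"line {lineno}: row '{probe}' has {len(values)} values "
                    f"but header names {len(header) - 1} samples"
                )
            rows.append((probe, values))

    if not saw_begin or not saw_end:
        raise SeriesMatrixError(
            f"{path.name}: missing table begin/end markers"
        )
    if header is None or not rows:
        raise SeriesMatrixError(f"{path.name}: table contains no data rows")

    sample_ids = header[1:]
    gene_ids = [probe for probe, _ in rows]
    X = np.array([vals for _, vals in rows], dtype=float).T  # samples x genes

    if dose is not None:
        y = np.asarray(dose, dtype=float)
        if len(y) != len(sample_ids):
            raise NoResponseError(
                f"dose vector length {len(y)} != sample count {len(sample_ids)}"
            )
    elif dose_key is not None:
        y = _dose_from_characteristics(meta, dose_key, len(sample_ids))
    else:
        raise NoResponseError(
            "no response: supply `dose` or a `dose_key` naming a sample "
            "characteristic"
        )

    return ExpressionDataset(
        sample_ids=sample_ids,
        gene_ids=gene_ids,
        X=X,
        y=y,
        meta={k: v for k, v in meta.items()},
    )


def _dose_from_characteristics(
    meta: dict[str, list[str]], dose_key: str, n: int
) -> np.ndarray:
    for key, lines in meta.items():
        if not key.startswith("Sample_characteristics"):
            continue
        for entry in lines:
            fields = [f.strip().strip('"') for f in entry.split("\t")]
            parsed = []
            for f in fields:
                name, _, val = f.partition(":")
                if name.strip().lower() != dose_key.lower():
                    parsed = []
                    break
                parsed.append(float(val))
            if parsed and len(parsed) == n:
                return np.asarray(parsed, dtype=float)
    raise NoResponseError(
        f"no sample characteristic matching dose key '{dose_key}'"
    )


def read_tsv(path: str | Path) -> ExpressionDataset:
    """Read the package TSV dialect (``sample_id\\tdose\\t<gene>...``)."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 3 or header[0] != "sample_id" or header[1] != "dose":
            raise ValueError(
                f"{path.name}: expected header 'sample_id\\tdose\\t<gene>...'"
            )
        gene_ids = header[2:]
        sample_ids, ys, rows = [], [], []
        for raw in fh:
            if not raw.strip():
                continue
            fields = raw.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise ValueError(
                    f"{path.name}: row '{fields[0]}' has {len(fields)} fields, "
                    f"expected {len(header)}"
                )
            sample_ids.append(fields[0])
            ys.append(float(fields[1]))
            rows.append([_parse_cell(tok) for tok in fields[2:]])
    return ExpressionDataset(
        sample_ids=sample_ids,
        gene_ids=gene_ids,
        X=np.asarray(rows, dtype=float),
        y=np.asarray(ys, dtype=float),
    )


def write_tsv(ds: ExpressionDataset, path: str | Path) -> None:
    """Write a dataset in the package TSV dialect; round-trips bit-exactly."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\tdose\t" + "\t".join(ds.gene_ids) + "\n")
        for i, sid in enumerate(ds.sample_ids):
            cells = [
                "NA" if math.isnan(v) else repr(float(v)) for v in ds.X[i]
            ]
            fh.write(f"{sid}\t{float(ds.y[i])!r}\t" + "\t".join(cells) + "\n")


def preprocess(
    ds: ExpressionDataset,
    already_log2: bool = False,
    max_missing_fraction: float = 0.2,
) -> ExpressionDataset:
    """Log2-transform, drop high-missingness genes, impute the rest.

    Raw intensities are mapped through ``log2(max(v, 0) + 1)`` — the
    pseudo-count keeps the transform total on background-corrected values
    that can be zero or slightly negative.  A gene whose missing fraction
    exceeds ``max_missing_fraction`` is dropped; surviving missing cells are
    imputed with that gene's median over observed samples.  The result
    contains no missing values, and the operation is idempotent when
    ``already_log2=True`` and nothing is missing.
    """
    if not 0.0 <= max_missing_fraction <= 1.0:
        raise ValueError("max_missing_fraction must lie in [0, 1]")
    X = ds.X.copy()
    if not already_log2:
        with np.errstate(invalid="ignore"):
            X = np.log2(np.maximum(X, 0.0) + 1.0)

    missing = np.isnan(X)
    frac = missing.mean(axis=0)
    # a fully-missing gene is always dropped, even at threshold 1.0
    keep = (frac <= max_missing_fraction) & (frac < 1.0)
    if not keep.any():
        raise EmptyDatasetError("all genes dropped by the missingness filter")
    X = X[:, keep]
    gene_ids = [g for g, k in zip(ds.gene_ids, keep) if k]

    missing = np.isnan(X)
    if missing.any():
        med = np.nanmedian(X, axis=0)
        idx = np.where(missing)
        X[idx] = med[idx[1]]

    return ExpressionDataset(
        sample_ids=list(ds.sample_ids),
        gene_ids=gene_ids,
        X=X,
        y=ds.y.copy(),
        meta=dict(ds.meta),
    )


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def split_train_test(
    ds: ExpressionDataset,
    train_fraction: float = 0.7,
    seed: int = 0,
) -> SplitPair:
    """Uniform random 70/30-style partition, fully determined by ``seed``.

    The training size is ``round(train_fraction * n)`` with half-away-from-
    zero rounding (ties cannot occur for integer n and fraction 0.7).
    """
    n = ds.n_samples
    if n < 4:
        raise ValueError("need at least 4 samples to split")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    n_train = _round_half_away(train_fraction * n)
    if n_train == 0 or n_train == n:
        raise ValueError(
            f"split with fraction {train_fraction} leaves an empty part"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return SplitPair(
        train=ds.subset_samples(np.sort(perm[:n_train])),
        test=ds.subset_samples(np.sort(perm[n_train:])),
        seed=seed,
        train_fraction=train_fraction,
    )
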