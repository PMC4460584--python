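"""Data containers, readers/writers and run configuration.

Expression matrices are stored genes x samples (the orientation of the
standard tabular formats); estimators consume the transposed samples x genes
view via :meth:`ExpressionDataset.to_xy`, following the scikit-learn
convention.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

NOT_ASSIGNED = "NOT_ASSIGNED"

MIN_SAMPLES_PER_CLASS = 3


class MarkernetError(Exception):
    """Base class for user-facing errors."""


class ParseError(MarkernetError):
    """Malformed input file."""


class ValidationError(MarkernetError):
    """Input violates a data-model invariant."""


@dataclasses.dataclass
class RunConfig:
    """Tunable parameters of the full pipeline.

    Attributes
    ----------
    significance_threshold : float
        Posterior probability above which a ranked gene is flagged
        significant (default 0.95).
    cv_folds, cv_repeats : int
        Folds and repeats of the cross-validation wrapping the forward
        gene selection (defaults 8 and 6).
    max_genes_train : int
        Cap on the per-class gene count explored during selection.
    continue_zero_error : bool
        Keep adding genes after reaching zero cross-validation error.
    lp_factor, diff_factor : float
        Assignment-rule multipliers of the random probability 1/K: the top
        class probability must reach ``lp_factor/K`` and exceed the runner-up
        by more than ``diff_factor/K``; otherwise the sample is left
        Not-Assigned.
    correlations_threshold, interactions_threshold : float
        Absolute Pearson correlation and normalized mutual-information
        cutoffs for network edges.
    network_top_n : int
        Number of top-ranked genes per class included in its network.
    seed : int
        Master seed; every random stage derives its own stream from it.
    """

    significance_threshold: float = 0.95
    cv_folds: int = 8
    cv_repeats: int = 6
    max_genes_train: int = 100
    continue_zero_error: bool = False
    lp_factor: float = 2.0
    diff_factor: float = 0.8
    correlations_threshold: float = 0.8
    interactions_threshold: float = 0.5
    network_top_n: int = 30
    svm_c: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.significance_threshold <= 1.0:
            raise ValidationError("significance_threshold must be in [0, 1]")
        if self.cv_folds < 2:
            raise ValidationError("cv_folds must be >= 2")
        if self.cv_repeats < 1:
            raise ValidationError("cv_repeats must be >= 1")
        if self.max_genes_train < 1:
            raise ValidationError("max_genes_train must be >= 1")
        if not 0.0 <= self.correlations_threshold <= 1.0:
            raise ValidationError("correlations_threshold must be in [0, 1]")
        if not 0.0 <= self.interactions_threshold <= 1.0:
            raise ValidationError("interactions_threshold must be in [0, 1]")
        if self.lp_factor < 0 or self.diff_factor < 0:
            raise ValidationError("lp_factor and diff_factor must be >= 0")
        if self.network_top_n < 1:
            raise ValidationError("network_top_n must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})


def derive_seed(seed: int, *tags) -> int:
    """Derive a reproducible sub-seed (< 2**31) from the master seed.

    Tags identify the pipeline stage (strings or ints), so re-ordering
    stages cannot silently reuse a stream.
    """
    key = tuple(
        int.from_bytes(str(t).encode(), "little") % (2**32) for t in tags
    )
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=key)
    return int(ss.generate_state(1)[0] % (2**31))


def derive_rng(seed: int, *tags) -> np.random.Generator:
    return np.random.default_rng(derive_seed(seed, *tags))


@dataclasses.dataclass
class ExpressionDataset:
    """A genes x samples log-scale expression matrix with class labels.

    ``matrix`` is a DataFrame indexed by gene id with sample ids as columns.
    ``labels`` maps each sample id to a class name; ``classes`` keeps the
    class order of first appearance.
    """

    matrix: pd.DataFrame
    labels: dict[str, str] | None = None
    classes: list[str] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        if self.matrix.index.duplicated().any():
            dup = self.matrix.index[self.matrix.index.duplicated()][0]
            raise ValidationError(f"duplicate gene id: {dup!r}")
        if self.matrix.columns.duplicated().any():
            dup = self.matrix.columns[self.matrix.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample id: {dup!r}")
        values = self.matrix.to_numpy()
        if not np.isfinite(values).all():
            gi, si = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                "non-finite value at gene "
                f"{self.matrix.index[gi]!r}, sample {self.matrix.columns[si]!r}"
            )
        if self.labels is not None and not self.classes:
            seen: list[str] = []
            for s in self.matrix.columns:
                c = self.labels.get(s)
                if c is not None and c not in seen:
                    seen.append(c)
            self.classes = seen

    # ------------------------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.matrix.columns)

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    def attach_labels(self, labels: dict[str, str]) -> "ExpressionDataset":
        """Return a copy with labels attached; matrix order is unchanged."""
        missing = [s for s in labels if s not in set(self.sample_ids)]
        if missing:
            raise ValidationError(
                f"labelled samples absent from matrix: {missing[:5]}"
            )
        unlabelled = [s for s in self.sample_ids if s not in labels]
        if unlabelled:
            raise ValidationError(
                f"samples without a label: {unlabelled[:5]}"
            )
        ds = ExpressionDataset(self.matrix, dict(labels))
        counts = ds.class_counts()
        small = {c: n for c, n in counts.items() if n < MIN_SAMPLES_PER_CLASS}
        if small:
            warnings.warn(
                f"classes with fewer than {MIN_SAMPLES_PER_CLASS} samples: "
                f"{small}; analysis will refuse to start",
                stacklevel=2,
            )
        return ds

    def class_counts(self) -> dict[str, int]:
        if self.labels is None:
            return {}
        counts = {c: 0 for c in self.classes}
        for s in self.sample_ids:
            counts[self.labels[s]] += 1
        return counts

    def validate_for_analysis(self) -> None:
        """Raise unless the dataset satisfies the analysis preconditions."""
        if self.labels is None:
            raise ValidationError("dataset has no labels attached")
        if len(self.classes) < 2:
            raise ValidationError("at least 2 classes are required")
        for c, n in self.class_counts().items():
            if n < MIN_SAMPLES_PER_CLASS:
                raise ValidationError(
                    f"class {c!r} has {n} samples; "
                    f"at least {MIN_SAMPLES_PER_CLASS} are required"
                )

    def to_xy(self) -> tuple[pd.DataFrame, np.ndarray]:
        """Samples x genes matrix and label vector (scikit-learn layout)."""
        if self.labels is None:
            raise ValidationError("dataset has no labels attached")
        X = self.matrix.T
        y = np.array([self.labels[s] for s in X.index])
        return X, y

    def subset_samples(self, sample_ids) -> "ExpressionDataset":
        labels = (
            {s: self.labels[s] for s in sample_ids}
            if self.labels is not None
            else None
        )
        return ExpressionDataset(self.matrix.loc[:, list(sample_ids)], labels)


# ----------------------------------------------------------------------
# readers / writers


def _read_table(path, sep: str, skiprows: int = 0) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, skiprows=skiprows)
    except pd.errors.ParserError as exc:  # pragma: no cover - message passthrough
        raise ParseError(f"{path}: {exc}") from exc
    return df


def read_expression(
    path, fmt: str | None = None, log2_rpkm: bool = False
) -> ExpressionDataset:
    """Read a genes x samples expression table (TSV, CSV or GCT 1.2).

    The first column holds gene ids and the header row sample ids. With
    ``log2_rpkm`` the values are taken as raw RPKM and log2(x+1)-transformed,
    the usual RNA-Seq preprocessing for this analysis.
    """
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower() or "tsv"
    fmt = fmt.lower()
    if fmt == "gct":
        with open(path) as fh:
            first = fh.readline().strip()
            if not first.startswith("#1.2"):
                raise ParseError(f"{path}: line 1: expected '#1.2' GCT header")
            dims = fh.readline().split()
            if len(dims) < 2:
                raise ParseError(f"{path}: line 2: expected dimension line")
            n_genes, n_samples = int(dims[0]), int(dims[1])
        df = _read_table(path, sep="\t", skiprows=2)
        # GCT carries a Description column between ids and data
        if df.columns[0].lower() == "description":
            df = df.drop(columns=df.columns[0])
        if df.shape != (n_genes, n_samples):
            raise ParseError(
                f"{path}: dimension line says {n_genes}x{n_samples}, "
                f"found {df.shape[0]}x{df.shape[1]}"
            )
    elif fmt in ("tsv", "txt"):
        df = _read_table(path, sep="\t")
    elif fmt == "csv":
        df = _read_table(path, sep=",")
    else:
        raise ParseError(f"unknown expression format: {fmt!r}")

    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            gene = bad.index[0] if len(bad) else "?"
            raise ParseError(
                f"{path}: non-numeric value for gene {gene!r}, sample {col!r}"
            )
    if log2_rpkm:
        if (df.to_numpy() < 0).any():
            raise ValidationError("negative RPKM value under --log2-rpkm")
        df = np.log2(df + 1.0)
    return ExpressionDataset(df.astype(float))


def read_labels(path) -> dict[str, str]:
    """Read a two-column sample_id -> class table (TSV, optional header)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty labels file") from exc
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected two tab-separated columns")
    df = df.iloc[:, :2]
    # tolerate a header line
    if df.iloc[0, 0].lower() in ("sample", "sample_id", "id"):
        df = df.iloc[1:]
    if df.empty:
        raise ParseError(f"{path}: no label rows")
    labels: dict[str, str] = {}
    for _, (sample, cls) in df.iterrows():
        if sample in labels and labels[sample] != cls:
            raise ParseError(
                f"{path}: sample {sample!r} has two labels "
                f"({labels[sample]!r}, {cls!r})"
            )
        labels[str(sample)] = str(cls)
    return labels


FLOAT_FORMAT = "%.12g"


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    """Write a tabular result as TSV (12 significant digits)."""
    pd.DataFrame(df).to_csv(
        path, sep="\t", index=index, float_format=FLOAT_FORMAT
    )


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
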