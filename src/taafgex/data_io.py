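"""Expression-matrix containers, I/O, standardization and splitting.

The central container is :class:`ExpressionDataset`: a samples x genes matrix
of (log-scale) expression with per-gene roles marking each gene as a
*landmark* (measured, used as network input) or a *target* (reconstructed).
Optional per-sample series labels (GEO-series-style experiment groups) drive
the heterogeneity-aware split, and optional per-sample phenotype labels feed
the differential-expression evaluation.

Standardization is deliberately *global* — one mean and one standard
deviation for the whole matrix, never per gene — so that highly expressed
genes keep proportionally larger magnitudes and therefore more weight in
absolute-error metrics, while genes near the noise floor contribute less.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "Scaler",
    "global_standardize",
    "random_split",
    "group_aware_split",
    "read_expression",
    "write_expression",
    "FormatError",
]


class FormatError(ValueError):
    """Raised when an expression file violates its declared dialect."""


@dataclass
class ExpressionDataset:
    """Samples x genes expression matrix with gene roles and sample metadata."""

    values: np.ndarray
    sample_ids: List[str]
    gene_ids: List[str]
    gene_role: List[str]  # "landmark" or "target", aligned with gene_ids
    series_label: Optional[List[str]] = None
    phenotype: Optional[List[str]] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D samples x genes matrix")
        n_s, n_g = self.values.shape
        if len(self.sample_ids) != n_s:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n_s} rows")
        if len(self.gene_ids) != n_g:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {n_g} columns")
        if len(set(self.sample_ids)) != n_s:
            raise ValueError("sample ids must be unique")
        if len(set(self.gene_ids)) != n_g:
            raise ValueError("gene ids must be unique")
        if len(self.gene_role) != n_g:
            raise ValueError("gene_role length must match gene_ids")
        bad = set(self.gene_role) - {"landmark", "target"}
        if bad:
            raise ValueError(f"unknown gene roles: {sorted(bad)}")
        if self.series_label is not None and len(self.series_label) != n_s:
            raise ValueError("series_label length must match sample count")
        if self.phenotype is not None and len(self.phenotype) != n_s:
            raise ValueError("phenotype length must match sample count")

    # -- derived views ----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def landmark_ids(self) -> List[str]:
        return [g for g, r in zip(self.gene_ids, self.gene_role) if r == "landmark"]

    @property
    def target_ids(self) -> List[str]:
        return [g for g, r in zip(self.gene_ids, self.gene_role) if r == "target"]

    def landmarks(self) -> np.ndarray:
        """The samples x landmarks block, in gene_ids order."""
        idx = [i for i, r in enumerate(self.gene_role) if r == "landmark"]
        return self.values[:, idx]

    def targets(self) -> np.ndarray:
        """The samples x targets block, in gene_ids order."""
        idx = [i for i, r in enumerate(self.gene_role) if r == "target"]
        return self.values[:, idx]

    def target_columns(self, gene_ids: Sequence[str]) -> np.ndarray:
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        return self.values[:, [pos[g] for g in gene_ids]]

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionDataset":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return ExpressionDataset(
            values=self.values[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
            gene_ids=list(self.gene_ids),
            gene_role=list(self.gene_role),
            series_label=None
            if self.series_label is None
            else [self.series_label[i] for i in idx],
            phenotype=None
            if self.phenotype is None
            else [self.phenotype[i] for i in idx],
        )


@dataclass(frozen=True)
class Scaler:
    """Global affine transform: x -> (x - global_mean) / global_sd."""

    global_mean: float
    global_sd: float

    def transform(self, values: np.ndarray) -> np.ndarray:
        return (np.asarray(values, dtype=float) - self.global_mean) / self.global_sd

    def inverse(self, values: np.ndarray) -> np.ndarray:
        return np.asarray(values, dtype=float) * self.global_sd + self.global_mean


def global_standardize(dataset: ExpressionDataset) -> Tuple[ExpressionDataset, Scaler]:
    """Standardize the whole matrix to zero mean and unit (population) sd.

    No per-gene centering or scaling happens: gene columns retain unequal
    variances, which is the point of the method.
    """
    vals = dataset.values
    if vals.size < 2:
        raise ValueError("need at least 2 values to standardize")
    mean = float(np.mean(vals))
    sd = float(np.std(vals))  # population sd
    if sd <= 0 or not np.isfinite(sd):
        raise ValueError("matrix is constant or non-finite; cannot standardize")
    scaler = Scaler(global_mean=mean, global_sd=sd)
    return replace(dataset, values=scaler.transform(vals)), scaler


def _largest_remainder_sizes(n: int, fractions: Sequence[float]) -> List[int]:
    """Integer split sizes summing to n: floors plus leftovers to the largest
    remainders, earlier splits winning ties."""
    exact = [n * f for f in fractions]
    sizes = [int(np.floor(e)) for e in exact]
    leftover = n - sum(sizes)
    remainders = sorted(
        range(len(fractions)), key=lambda i: (-(exact[i] - sizes[i]), i)
    )
    for i in remainders[:leftover]:
        sizes[i] += 1
    return sizes


def _check_fractions(fractions: Sequence[float]) -> Tuple[float, float, float]:
    if len(fractions) != 3:
        raise ValueError("fractions must be (train, validation, test)")
    if any(f <= 0 for f in fractions):
        raise ValueError("all three fractions must be strictly positive")
    if abs(sum(fractions) - 1.0) > 1e-8:
        raise ValueError("fractions must sum to 1")
    return tuple(fractions)  # type: ignore[return-value]


def random_split(
    dataset: ExpressionDataset,
    fractions: Sequence[float] = (0.7, 0.15, 0.15),
    seed: int = 0,
) -> Tuple[ExpressionDataset, ExpressionDataset, ExpressionDataset]:
    """Random train/validation/test split of samples.

    Sizes follow largest-remainder rounding of the fractions.  Sample ids are
    sorted lexicographically before the seeded shuffle, so the split is a
    function of the ids, not of row order.
    """
    fractions = _check_fractions(fractions)
    if dataset.n_samples < 3:
        raise ValueError("need at least 3 samples to split three ways")
    ids = sorted(dataset.sample_ids)
    rng = np.random.default_rng(seed)
    rng.shuffle(ids)
    sizes = _largest_remainder_sizes(len(ids), fractions)
    bounds = np.cumsum([0] + sizes)
    parts = [ids[bounds[i] : bounds[i + 1]] for i in range(3)]
    return tuple(dataset.subset_samples(p) for p in parts)  # type: ignore[return-value]


def group_aware_split(
    dataset: ExpressionDataset,
    fractions: Sequence[float] = (0.6, 0.2, 0.2),
    seed: int = 0,
    deviation_warn: float = 0.05,
) -> Tuple[ExpressionDataset, ExpressionDataset, ExpressionDataset]:
    """Series-grouped split: no series contributes samples to two splits.

    Removes the series-level information leakage a random split allows.
    Samples without a series label are dropped first.  Series are assigned
    greedily, largest first, each to the split with the largest remaining
    sample deficit; ties break toward train, then validation, then test.
    If realized fractions end up more than ``deviation_warn`` from the
    targets (e.g. one giant series), a warning is emitted rather than failing
    silently.
    """
    fractions = _check_fractions(fractions)
    if dataset.series_label is None:
        raise ValueError("group_aware_split requires series labels")
    labelled = [
        (s, lab)
        for s, lab in zip(dataset.sample_ids, dataset.series_label)
        if lab is not None and str(lab) != ""
    ]
    series: dict[str, List[str]] = {}
    for s, lab in labelled:
        series.setdefault(str(lab), []).append(s)
    if len(series) < 3:
        raise ValueError(f"need at least 3 series, got {len(series)}")
    n_total = len(labelled)
    targets = [f * n_total for f in fractions]

    # seeded shuffle of series ids (sorted first for order independence),
    # then stable sort by descending size
    sids = sorted(series)
    rng = np.random.default_rng(seed)
    rng.shuffle(sids)
    sids.sort(key=lambda s: -len(series[s]))

    assigned: List[List[str]] = [[], [], []]
    counts = [0, 0, 0]
    for sid in sids:
        size = len(series[sid])
        # place the series where it least distorts the target fractions;
        # ties go to train, then validation, then test
        costs = [
            sum(
                abs((counts[j] + (size if j == k else 0)) - targets[j])
                for j in range(3)
            )
            for k in range(3)
        ]
        k = int(np.argmin(costs))
        assigned[k].extend(series[sid])
        counts[k] += size

    realized = [c / n_total for c in counts]
    worst = max(abs(r - f) for r, f in zip(realized, fractions))
    if worst > deviation_warn:
        warnings.warn(
            f"group-aware split fractions {tuple(round(r, 3) for r in realized)} "
            f"deviate from targets {tuple(fractions)} by up to {worst:.3f} "
            "(dominant series prevent a closer assignment)",
            stacklevel=2,
        )
    return tuple(
        dataset.subset_samples(sorted(part)) for part in assigned
    )  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# File formats: GCT v1.2 (genes x samples) and TSV (samples x genes)
# ---------------------------------------------------------------------------


def _read_landmark_list(path: Path) -> List[str]:
    return [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]


def write_expression(
    dataset: ExpressionDataset,
    path: str | Path,
    format: str = "tsv",
    landmark_file: str | Path | None = None,
) -> None:
    """Write the matrix as GCT v1.2 or TSV; gene roles go to a sidecar
    landmark-id list (one id per line) when ``landmark_file`` is given."""
    path = Path(path)
    if format == "gct-1.2":
        n_genes, n_samples = len(dataset.gene_ids), dataset.n_samples
        with path.open("w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{n_genes}\t{n_samples}\n")
            fh.write("NAME\tDescription\t" + "\t".join(dataset.sample_ids) + "\n")
            for j, gid in enumerate(dataset.gene_ids):
                row = "\t".join(f"{v:.17g}" for v in dataset.values[:, j])
                fh.write(f"{gid}\tna\t{row}\n")
    elif format == "tsv":
        df = pd.DataFrame(
            dataset.values, index=dataset.sample_ids, columns=dataset.gene_ids
        )
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t", float_format="%.17g")
    else:
        raise ValueError(f"unknown format {format!r}; expected 'gct-1.2' or 'tsv'")
    if landmark_file is not None:
        Path(landmark_file).write_text("\n".join(dataset.landmark_ids) + "\n")


def read_expression(
    path: str | Path,
    format: str = "tsv",
    landmark_file: str | Path | None = None,
) -> ExpressionDataset:
    """Read a GCT v1.2 or TSV expression matrix.

    Gene roles come from the companion landmark-id list when provided;
    otherwise every gene is marked a target.
    """
    path = Path(path)
    if format == "gct-1.2":
        values, sample_ids, gene_ids = _read_gct(path)
    elif format == "tsv":
        values, sample_ids, gene_ids = _read_tsv(path)
    else:
        raise ValueError(f"unknown format {format!r}; expected 'gct-1.2' or 'tsv'")
    landmarks = (
        set(_read_landmark_list(Path(landmark_file))) if landmark_file else set()
    )
    unknown = landmarks - set(gene_ids)
    if unknown:
        raise FormatError(
            f"landmark ids not present in matrix: {sorted(unknown)[:5]} ..."
        )
    roles = ["landmark" if g in landmarks else "target" for g in gene_ids]
    return ExpressionDataset(values, sample_ids, gene_ids, roles)


def _read_gct(path: Path) -> Tuple[np.ndarray, List[str], List[str]]:
    lines = path.read_text().splitlines()
    if not lines or lines[0].strip() != "#1.2":
        raise FormatError(f"{path}:1: expected GCT version line '#1.2'")
    try:
        n_genes, n_samples = (int(tok) for tok in lines[1].split("\t"))
    except (IndexError, ValueError):
        raise FormatError(f"{path}:2: expected '<n_rows>\\t<n_cols>'") from None
    header = lines[2].split("\t")
    if len(header) != n_samples + 2:
        raise FormatError(
            f"{path}:3: header declares {len(header) - 2} samples, "
            f"dimension line declares {n_samples}"
        )
    sample_ids = header[2:]
    if len(set(sample_ids)) != len(sample_ids):
        raise FormatError(f"{path}:3: duplicate sample ids")
    body = lines[3:]
    if len(body) != n_genes:
        raise FormatError(
            f"{path}: {len(body)} data rows but dimension line declares {n_genes}"
        )
    gene_ids: List[str] = []
    rows = np.empty((n_genes, n_samples))
    for i, line in enumerate(body):
        toks = line.split("\t")
        if len(toks) != n_samples + 2:
            raise FormatError(f"{path}:{i + 4}: ragged row ({len(toks)} fields)")
        gene_ids.append(toks[0])
        try:
            rows[i] = [float(t) for t in toks[2:]]
        except ValueError:
            raise FormatError(f"{path}:{i + 4}: non-numeric value") from None
    dupes = pd.Index(gene_ids)[pd.Index(gene_ids).duplicated()]
    if len(dupes):
        raise FormatError(f"{path}: duplicate gene ids: {sorted(set(dupes))}")
    return rows.T, sample_ids, gene_ids


def _read_tsv(path: Path) -> Tuple[np.ndarray, List[str], List[str]]:
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    dupes = sorted({g for g in header if header.count(g) > 1})
    if dupes:
        raise FormatError(f"{path}: duplicate gene columns: {dupes}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas error variety
        raise FormatError(f"{path}: {exc}") from exc
    gene_ids = [str(c) for c in df.columns]
    sample_ids = [str(s) for s in df.index]
    if len(set(sample_ids)) != len(sample_ids):
        raise FormatError(f"{path}: duplicate sample ids")
    values = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(values) | np.isnan(values)):
        raise FormatError(f"{path}: non-numeric values present")
    return values, sample_ids, gene_ids


def write_split_manifest(
    splits: Sequence[ExpressionDataset], paths: Sequence[str | Path]
) -> None:
    """Write one id-list file per split (train/validation/test)."""
    for ds, p in zip(splits, paths):
        Path(p).write_text("\n".join(ds.sample_ids) + "\n")
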