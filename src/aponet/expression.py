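"""Expression-matrix data model, FPKM normalization and phenotypic-class specificity.

The central container is :class:`ExpressionMatrix`, a validated wrapper around a
transcripts x samples :class:`pandas.DataFrame` of non-negative abundances
(raw fragment counts or FPKM).  Sample annotations (genotype, clone, tissue,
phenotypic class) travel in a plain metadata DataFrame validated by
:func:`validate_metadata`.

FPKM follows the standard definition

    FPKM(g, i) = 1e9 * C(g, i) / (N(i) * L(g))

where ``C`` is the fragment count of transcript ``g`` in sample ``i``, ``N``
the total mapped fragments of sample ``i`` (column sum), and ``L`` the
transcript length in base pairs.

"Specific" transcripts are those detected in every genotype of exactly one
phenotypic class and in no other class; :func:`classify_specific` produces the
full Venn partition over classes from which the specific sets are read off.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

METADATA_COLUMNS = ("sample_id", "genotype", "clone", "tissue", "phenotypic_class")


class ExpressionMatrix:
    """Transcripts x samples matrix of non-negative values.

    Parameters
    ----------
    data:
        DataFrame with transcript ids as index and sample ids as columns.
    unit:
        ``"count"`` or ``"fpkm"``.
    """

    VALID_UNITS = ("count", "fpkm")

    def __init__(self, data: pd.DataFrame, unit: str = "count"):
        if unit not in self.VALID_UNITS:
            raise ValueError(f"unit must be one of {self.VALID_UNITS}, got {unit!r}")
        if not data.index.is_unique:
            dupes = data.index[data.index.duplicated()].unique().tolist()[:5]
            raise ValueError(f"duplicate transcript ids: {dupes}")
        if not data.columns.is_unique:
            dupes = data.columns[data.columns.duplicated()].unique().tolist()[:5]
            raise ValueError(f"duplicate sample ids: {dupes}")
        values = data.to_numpy(dtype=float)
        if values.size and (np.isnan(values).any() or (values < 0).any()):
            raise ValueError("expression values must be non-negative and finite")
        self.data = data.astype(float)
        self.data.index.name = None
        self.data.columns.name = None
        self.unit = unit

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)], unit=self.unit)

    def subset_transcripts(self, transcript_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(transcript_ids)], unit=self.unit)

    def to_tsv(self, path) -> None:
        out = self.data.copy()
        out.index.name = "transcript_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, unit: str = "count") -> "ExpressionMatrix":
        data = pd.read_csv(path, sep="\t", index_col=0)
        data.index = data.index.astype(str)
        return cls(data, unit=unit)

    def __repr__(self) -> str:  # pragma: no cover
        g, s = self.shape
        return f"ExpressionMatrix({g} transcripts x {s} samples, unit={self.unit})"


def validate_metadata(meta: pd.DataFrame, matrix: ExpressionMatrix | None = None) -> pd.DataFrame:
    """Check the sample-metadata contract.

    Every matrix sample must have exactly one record and every genotype must
    map to a single phenotypic class.
    """
    missing_cols = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise ValueError(f"metadata missing columns: {missing_cols}")
    if meta["sample_id"].duplicated().any():
        dupes = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample records: {dupes}")
    geno_classes = meta.groupby("genotype")["phenotypic_class"].nunique()
    bad = geno_classes[geno_classes > 1].index.tolist()
    if bad:
        raise ValueError(f"genotypes mapped to more than one class: {bad}")
    if matrix is not None:
        absent = set(matrix.sample_ids) - set(meta["sample_id"])
        if absent:
            raise ValueError(f"matrix samples without metadata: {sorted(absent)}")
    return meta


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str)
    return validate_metadata(meta)


def read_lengths(path) -> pd.Series:
    """Read a two-column (transcript_id, length) TSV into a Series."""
    df = pd.read_csv(path, sep="\t")
    lengths = pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0].astype(str))
    return lengths.astype(int)


def fpkm_from_counts(counts: ExpressionMatrix, lengths: pd.Series) -> ExpressionMatrix:
    """Convert a count matrix to FPKM: 1e9 * C / (N * L).

    Raises
    ------
    KeyError
        if any transcript lacks a length.
    ValueError
        naming the sample, if a column sum is zero, or a length is < 1.
    """
    if counts.unit != "count":
        raise ValueError(f"expected a count matrix, got unit={counts.unit!r}")
    missing = [t for t in counts.transcript_ids if t not in lengths.index]
    if missing:
        raise KeyError(f"transcripts without length: {missing[:10]}"
                       + ("..." if len(missing) > 10 else ""))
    L = lengths.loc[counts.transcript_ids].to_numpy(dtype=float)
    if (L < 1).any():
        raise ValueError("transcript lengths must be >= 1 bp")
    N = counts.data.to_numpy().sum(axis=0)
    zero_cols = [s for s, n in zip(counts.sample_ids, N) if n == 0]
    if zero_cols:
        raise ValueError(f"zero total fragments in sample(s): {zero_cols}")
    fpkm = 1e9 * counts.data.to_numpy() / (N[None, :] * L[:, None])
    return ExpressionMatrix(
        pd.DataFrame(fpkm, index=counts.data.index, columns=counts.data.columns),
        unit="fpkm",
    )


def filter_low_expression(matrix: ExpressionMatrix, theta: float = 0.5) -> ExpressionMatrix:
    """Drop transcripts whose fraction of zero-valued samples exceeds ``theta``.

    The inequality is strict: a transcript with zero fraction exactly equal to
    ``theta`` is retained.  Survivor order is preserved.
    """
    if not 0 <= theta <= 1:
        raise ValueError("theta must be in [0, 1]")
    zero_frac = (matrix.data.to_numpy() == 0).mean(axis=1)
    keep = zero_frac <= theta
    return ExpressionMatrix(matrix.data.loc[keep], unit=matrix.unit)


@dataclass
class VennPartition:
    """Partition of expressed transcripts by the exact subset of groups detecting them.

    ``cells`` maps a frozenset of group labels to the transcripts expressed in
    exactly those groups; cells are pairwise disjoint by construction.
    """

    groups: tuple[str, ...]
    cells: dict[frozenset, set] = field(default_factory=dict)

    @property
    def specific_sets(self) -> dict[str, set]:
        """Transcripts expressed in exactly one group, keyed by group label."""
        return {g: set(self.cells.get(frozenset({g}), set())) for g in self.groups}

    @property
    def expressed(self) -> set:
        out: set = set()
        for members in self.cells.values():
            out |= members
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for subset, members in self.cells.items():
            label = "&".join(sorted(subset))
            for t in sorted(members):
                rows.append((t, label))
        return pd.DataFrame(rows, columns=["transcript_id", "subset"])


def _group_samples(meta: pd.DataFrame, group_by) -> dict[str, pd.DataFrame]:
    if isinstance(group_by, str):
        keys = meta[group_by].astype(str)
    else:  # class x tissue style composite grouping
        keys = meta[list(group_by)].astype(str).agg("|".join, axis=1)
    groups: dict[str, pd.DataFrame] = {}
    for label in keys.unique():
        groups[label] = meta.loc[keys == label]
    return groups


def classify_specific(
    matrix: ExpressionMatrix,
    meta: pd.DataFrame,
    epsilon: float = 0.0,
    group_by="phenotypic_class",
    require_all_genotypes: bool = True,
) -> VennPartition:
    """Assign each expressed transcript to its Venn cell over phenotypic groups.

    A transcript is "expressed in group G" iff its value exceeds ``epsilon``
    in at least one sample of **every** genotype of G (the default,
    within-class-consistent rule), or of any sample of G when
    ``require_all_genotypes`` is False.  Single-group cells are the groups'
    specific sets.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    validate_metadata(meta, matrix)
    groups = _group_samples(meta, group_by)
    for label, records in groups.items():
        present = [s for s in records["sample_id"] if s in matrix.data.columns]
        if not present:
            raise ValueError(f"group {label!r} has no samples in the matrix")

    values = matrix.data
    col_idx = {s: j for j, s in enumerate(values.columns)}
    expressed_in = {}
    arr = values.to_numpy()
    for label, records in groups.items():
        if require_all_genotypes:
            flags = None
            for _, geno_records in records.groupby("genotype"):
                cols = [col_idx[s] for s in geno_records["sample_id"] if s in col_idx]
                if not cols:
                    raise ValueError(
                        f"genotype of group {label!r} has no samples in the matrix")
                detected = (arr[:, cols] > epsilon).any(axis=1)
                flags = detected if flags is None else (flags & detected)
            expressed_in[label] = flags
        else:
            cols = [col_idx[s] for s in records["sample_id"] if s in col_idx]
            expressed_in[label] = (arr[:, cols] > epsilon).any(axis=1)

    labels = tuple(groups.keys())
    membership = np.column_stack([expressed_in[g] for g in labels])
    cells: dict[frozenset, set] = {}
    transcript_ids = np.asarray(values.index)
    for row_flags in {tuple(r) for r in map(tuple, membership)}:
        if not any(row_flags):
            continue
        subset = frozenset(g for g, f in zip(labels, row_flags) if f)
        mask = (membership == np.asarray(row_flags)).all(axis=1)
        cells[subset] = set(transcript_ids[mask])
    return VennPartition(groups=labels, cells=cells)


def venn_counts(partition: VennPartition) -> pd.DataFrame:
    """Tabulate non-empty Venn cells; counts sum to the expressed-set size."""
    rows = []
    for r in range(1, len(partition.groups) + 1):
        for combo in itertools.combinations(partition.groups, r):
            members = partition.cells.get(frozenset(combo))
            if members:
                rows.append(("&".join(combo), len(members)))
    return pd.DataFrame(rows, columns=["subset", "count"])
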