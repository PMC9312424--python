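"""Expression-matrix container and readers/writers for the package's file formats.

The in-memory convention everywhere in this package is genes x samples:
rows are genes, columns are samples. Dense matrices travel as tab-separated
text with a mandatory header row of sample IDs and a first column of gene
IDs; sparse matrices travel as Matrix Market triples plus two plain-text
sidecar files of gene and sample names. Gene lists are one identifier per
line with ``#`` comments. Identifier maps and ortholog maps are TSV with a
header naming the namespaces/organisms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.io import mmread


class Unit(str, Enum):
    """Abundance unit carried by an :class:`ExpressionMatrix`."""

    TPM = "TPM"
    READS_PER_BASE = "READS_PER_BASE"
    RAW = "RAW"


class ExpressionError(ValueError):
    """Base class for malformed expression input."""


class DuplicateIdentifierError(ExpressionError):
    """A gene or sample identifier occurs more than once."""


class AmbiguousMappingError(ExpressionError):
    """Two or more source genes map onto the same target identifier."""


@dataclass(frozen=True)
class GeneList:
    """An unordered, duplicate-free set of gene identifiers with a label."""

    genes: frozenset
    label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "genes", frozenset(self.genes))

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene) -> bool:
        return gene in self.genes

    def __iter__(self):
        return iter(sorted(self.genes))


@dataclass
class ExpressionMatrix:
    """Nonnegative gene x sample abundance matrix with identifiers and a unit tag.

    Parameters
    ----------
    gene_ids, sample_ids
        Ordered, unique identifiers for rows and columns.
    values
        Nonnegative, finite float matrix of shape ``(len(gene_ids), len(sample_ids))``.
    unit
        Abundance unit. TPM matrices produced by :func:`reads_per_base_to_tpm`
        carry ``tpm_verified=True`` (each column sums to 1e6); imported TPM
        matrices are accepted as-is with ``tpm_verified=False``.
    degenerate_samples
        Sample IDs whose column was all-zero at conversion time.
    """

    gene_ids: list
    sample_ids: list
    values: np.ndarray
    unit: Unit = Unit.RAW
    tpm_verified: bool = False
    degenerate_samples: tuple = ()

    def __post_init__(self):
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        self.unit = Unit(self.unit)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ExpressionError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = _duplicates(self.gene_ids)
            raise DuplicateIdentifierError(f"duplicate gene IDs: {dupes}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = _duplicates(self.sample_ids)
            raise DuplicateIdentifierError(f"duplicate sample IDs: {dupes}")
        if not np.all(np.isfinite(self.values)):
            raise ExpressionError("expression values must be finite")
        if np.any(self.values < 0):
            raise ExpressionError("expression values must be nonnegative")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, unit: Unit = Unit.RAW, **kw) -> "ExpressionMatrix":
        return cls(
            gene_ids=list(frame.index),
            sample_ids=list(frame.columns),
            values=frame.to_numpy(dtype=float),
            unit=unit,
            **kw,
        )

    def subset_genes(self, genes: Iterable) -> "ExpressionMatrix":
        keep = [str(g) for g in genes]
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [idx[g] for g in keep]
        return ExpressionMatrix(
            gene_ids=keep,
            sample_ids=list(self.sample_ids),
            values=self.values[rows, :],
            unit=self.unit,
            tpm_verified=self.tpm_verified,
            degenerate_samples=self.degenerate_samples,
        )


def _duplicates(ids: Sequence) -> list:
    seen, dupes = set(), []
    for x in ids:
        if x in seen and x not in dupes:
            dupes.append(x)
        seen.add(x)
    return dupes


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_expression_matrix(
    path,
    format: str = "tsv",
    unit: Unit = Unit.RAW,
    genes_path=None,
    samples_path=None,
    samples_by_genes: bool = False,
) -> ExpressionMatrix:
    """Read a dense TSV or sparse Matrix Market expression matrix.

    ``format="tsv"`` expects a header row of sample IDs and a first column of
    gene IDs. ``format="mtx"`` expects a Matrix Market file plus gene-name and
    sample-name sidecars (defaulting to ``<path>.genes.txt`` and
    ``<path>.samples.txt``). Set ``samples_by_genes=True`` when the file is
    oriented samples x genes; it is transposed on read.

    Duplicate gene rows are an error, never merged: merging would silently
    change downstream Gini coefficients.
    """
    path = Path(path)
    fmt = format.lower()
    if fmt == "tsv":
        frame = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype={0: str})
        if frame.shape[1] == 0:
            raise ExpressionError(f"{path}: no sample columns found (malformed header?)")
        try:
            frame = frame.astype(float)
        except (ValueError, TypeError) as exc:
            raise ExpressionError(f"{path}: non-numeric expression value ({exc})") from exc
    elif fmt in {"mtx", "mtx_triple"}:
        genes_path = Path(genes_path) if genes_path else path.with_suffix(path.suffix + ".genes.txt")
        samples_path = Path(samples_path) if samples_path else path.with_suffix(path.suffix + ".samples.txt")
        mat = mmread(str(path))
        if hasattr(mat, "toarray"):
            mat = mat.toarray()
        mat = np.asarray(mat, dtype=float)
        genes = _read_lines(genes_path)
        samples = _read_lines(samples_path)
        frame = pd.DataFrame(mat, index=genes, columns=samples)
    else:
        raise ValueError(f"unknown expression format: {format!r}")
    if samples_by_genes:
        frame = frame.T
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    return ExpressionMatrix.from_frame(frame, unit=unit)


def write_expression_matrix(m: ExpressionMatrix, path) -> None:
    """Write a dense TSV (genes x samples) with full float precision."""
    frame = m.to_frame()
    frame.index.name = "gene_id"
    frame.to_csv(path, sep="\t", float_format="%.17g")


def _read_lines(path) -> list:
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def read_gene_list(path, label: str = "") -> GeneList:
    """Read a gene list: one identifier per line, ``#`` comments allowed."""
    ids = _read_lines(path)
    if len(set(ids)) != len(ids):
        raise DuplicateIdentifierError(f"{path}: duplicate gene IDs in list")
    return GeneList(frozenset(ids), label=label or Path(path).stem)


def write_gene_list(genes: Iterable, path) -> None:
    Path(path).write_text("\n".join(str(g) for g in sorted(set(map(str, genes)))) + "\n")


def read_id_map(path) -> dict:
    """Read a two-column TSV (header required) mapping source IDs to targets.

    Empty, ``NA`` or ``-`` targets are recorded as missing (``None``) rather
    than dropped, so the mapping step can report what it discarded.
    """
    frame = pd.read_csv(path, sep="\t", header=0, dtype=str, keep_default_na=False)
    if frame.shape[1] < 2:
        raise ExpressionError(f"{path}: ID map needs two columns")
    mapping: dict = {}
    for src, tgt in zip(frame.iloc[:, 0], frame.iloc[:, 1]):
        if src in mapping:
            raise DuplicateIdentifierError(f"{path}: source ID {src!r} appears twice")
        mapping[src] = None if tgt in {"", "NA", "-", "None"} else tgt
    return mapping


# ---------------------------------------------------------------------------
# Transformations
# ---------------------------------------------------------------------------

def reads_per_base_to_tpm(m: ExpressionMatrix, exon_lengths: Mapping) -> ExpressionMatrix:
    """Convert read-per-exon-base (or raw read) abundances to TPM.

    For gene *i* in sample *s* with reads ``r_is`` and exon length ``L_ie``::

        TPM_is = (r_is / L_ie) / sum_i (r_is / L_ie) * 1e6

    Every non-degenerate output column sums to 1e6. A column whose rate sum
    is zero stays all-zero and its sample ID is recorded in
    ``degenerate_samples``.
    """
    if isinstance(exon_lengths, pd.Series):
        exon_lengths = exon_lengths.to_dict()
    missing = [g for g in m.gene_ids if g not in exon_lengths]
    if missing:
        raise KeyError(f"exon length missing for genes: {missing[:5]}{'...' if len(missing) > 5 else ''}")
    lengths = np.array([float(exon_lengths[g]) for g in m.gene_ids])
    if np.any(lengths <= 0):
        raise ExpressionError("exon lengths must be positive")
    rates = m.values / lengths[:, None]
    col_sums = rates.sum(axis=0)
    degenerate = tuple(s for s, c in zip(m.sample_ids, col_sums) if c == 0)
    safe = np.where(col_sums == 0, 1.0, col_sums)
    tpm = rates / safe[None, :] * 1e6
    return ExpressionMatrix(
        gene_ids=list(m.gene_ids),
        sample_ids=list(m.sample_ids),
        values=tpm,
        unit=Unit.TPM,
        tpm_verified=True,
        degenerate_samples=degenerate,
    )


def map_gene_ids(m: ExpressionMatrix, mapping: Mapping) -> tuple:
    """Rename genes through an identifier map; discard unmapped genes.

    Genes absent from the map or mapping to a missing target are removed and
    returned as the ``discarded`` :class:`GeneList` (never silently dropped).
    Two source genes mapping to one target raise
    :class:`AmbiguousMappingError` — there is no defensible merge rule for
    expression rows.
    """
    kept_rows, new_ids, discarded = [], [], []
    target_sources: dict = {}
    for i, g in enumerate(m.gene_ids):
        tgt = mapping.get(g)
        if tgt is None:
            discarded.append(g)
            continue
        target_sources.setdefault(tgt, []).append(g)
        kept_rows.append(i)
        new_ids.append(str(tgt))
    collisions = {t: s for t, s in target_sources.items() if len(s) > 1}
    if collisions:
        raise AmbiguousMappingError(f"many-to-one gene ID mappings: {collisions}")
    mapped = ExpressionMatrix(
        gene_ids=new_ids,
        sample_ids=list(m.sample_ids),
        values=m.values[kept_rows, :],
        unit=m.unit,
        tpm_verified=m.tpm_verified,
        degenerate_samples=m.degenerate_samples,
    )
    return mapped, GeneList(frozenset(discarded), label="discarded")


def intersect_gene_universe(matrices: Sequence[ExpressionMatrix]) -> GeneList:
    """Genes present in every matrix — the shared universe for comparisons."""
    if len(matrices) < 2:
        raise ValueError("need at least two matrices to intersect")
    common = set(matrices[0].gene_ids)
    for m in matrices[1:]:
        common &= set(m.gene_ids)
    if not common:
        warnings.warn("gene universes are disjoint: empty intersection", stacklevel=2)
    return GeneList(frozenset(common), label="intersection")


# ---------------------------------------------------------------------------
# Ortholog maps
# ---------------------------------------------------------------------------

@dataclass
class OrthologMap:
    """Rows of per-organism gene IDs; ``one_to_one`` flags the 1:1 subset.

    Within the 1:1 subset each gene ID appears in exactly one row per
    organism; this is validated on construction.
    """

    table: pd.DataFrame = field(repr=False)
    one_to_one: pd.Series = field(repr=False)

    def __post_init__(self):
        self.one_to_one = self.one_to_one.astype(bool)
        sub = self.table.loc[self.one_to_one]
        for org in self.table.columns:
            col = sub[org]
            if col.duplicated().any():
                dupes = sorted(col[col.duplicated()].unique().tolist())[:5]
                raise DuplicateIdentifierError(
                    f"1:1 ortholog subset has repeated {org} gene IDs: {dupes}"
                )

    @property
    def organisms(self) -> list:
        return list(self.table.columns)

    def one_to_one_rows(self) -> pd.DataFrame:
        return self.table.loc[self.one_to_one]


def read_ortholog_map(path, one_to_one_column: str = "one_to_one") -> OrthologMap:
    """Read an ortholog-map TSV: one column per organism plus a 1:1 flag.

    Without a flag column every row is taken as 1:1.
    """
    frame = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if one_to_one_column in frame.columns:
        flag = frame[one_to_one_column].str.lower().isin({"1", "true", "yes"})
        table = frame.drop(columns=[one_to_one_column])
    else:
        table = frame
        flag = pd.Series(True, index=frame.index)
    return OrthologMap(table=table, one_to_one=flag)


def write_ortholog_map(om: OrthologMap, path) -> None:
    out = om.table.copy()
    out["one_to_one"] = om.one_to_one.map({True: "1", False: "0"})
    out.to_csv(path, sep="\t", index=False)
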