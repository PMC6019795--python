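"""Data containers and readers for the formats the tool touches.

Expression data are expected on the log2 scale (the output of RMA-style
normalisation); every "fold change >= c" rule elsewhere in the package is
applied as ``|difference in log2 space| >= log2(c)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GeneSetCollection",
    "TissueDesign",
    "PromoterSet",
    "PWM",
    "read_expression",
    "read_gmt",
    "write_gmt",
    "read_jaspar",
    "write_jaspar",
    "read_fasta",
    "write_fasta",
]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class TissueDesign:
    """Ordered tissue labels and the replicate samples belonging to each.

    The per-tissue sample lists partition the full sample list; every tissue
    must carry at least two replicates for the pooled-variance t-statistic to
    be defined.
    """

    tissues: list[str]
    replicates: dict[str, list[str]]

    def __post_init__(self) -> None:
        if len(self.tissues) < 2:
            raise ValueError("a design needs at least 2 tissues")
        seen: set[str] = set()
        for t in self.tissues:
            reps = self.replicates.get(t, [])
            if len(reps) < 2:
                raise ValueError(f"tissue {t!r} has {len(reps)} replicate(s); need >= 2")
            dup = seen.intersection(reps)
            if dup:
                raise ValueError(f"samples assigned to more than one tissue: {sorted(dup)}")
            seen.update(reps)

    @property
    def sample_ids(self) -> list[str]:
        return [s for t in self.tissues for s in self.replicates[t]]

    @property
    def tissue_of(self) -> dict[str, str]:
        return {s: t for t in self.tissues for s in self.replicates[t]}


@dataclass
class ExpressionMatrix:
    """A genes x samples matrix of log2-scale normalised intensities.

    ``data`` is indexed by gene id (rows) and sample id (columns);
    ``tissue_of`` maps every sample to exactly one tissue label.
    """

    data: pd.DataFrame
    tissue_of: dict[str, str]

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        missing = [s for s in self.data.columns if s not in self.tissue_of]
        if missing:
            raise ValueError(f"samples without a tissue label: {missing}")
        if self.data.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        labels = {self.tissue_of[s] for s in self.data.columns}
        if len(labels) < 2:
            raise ValueError("fewer than 2 distinct tissues")

    @property
    def gene_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def design(self) -> TissueDesign:
        """Derive the tissue design from the sample labels (column order)."""
        tissues: list[str] = []
        replicates: dict[str, list[str]] = {}
        for s in self.data.columns:
            t = self.tissue_of[s]
            if t not in replicates:
                tissues.append(t)
                replicates[t] = []
            replicates[t].append(s)
        return TissueDesign(tissues=tissues, replicates=replicates)


@dataclass
class GeneSetCollection:
    """Named gene sets: set name -> (description, unique member gene ids)."""

    sets: dict[str, tuple[str, list[str]]]

    def __post_init__(self) -> None:
        for name, (_, genes) in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def genes(self, name: str) -> list[str]:
        return self.sets[name][1]

    @property
    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class PromoterSet:
    """Upstream promoter sequences keyed by gene id (uppercase A/C/G/T/N)."""

    records: dict[str, str]

    def __post_init__(self) -> None:
        allowed = set("ACGTN")
        for gid, seq in self.records.items():
            bad = set(seq) - allowed
            if bad:
                raise ValueError(f"promoter {gid!r} has invalid characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.records)


BASES = "ACGT"


@dataclass
class PWM:
    """A position weight matrix of per-position base frequencies.

    ``matrix`` has shape (L, 4) with columns ordered A, C, G, T; each row
    sums to one after pseudocount normalisation.  ``pseudocount`` is the
    per-cell count added before normalisation when building from counts.
    """

    motif_id: str
    matrix: np.ndarray
    pseudocount: float = 0.01

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must have shape (L, 4)")
        if len(self) < 4:
            raise ValueError("PWM must have length >= 4")
        if np.any(self.matrix < 0):
            raise ValueError("PWM frequencies must be non-negative")
        sums = self.matrix.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("PWM rows must each sum to 1")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @classmethod
    def from_counts(cls, motif_id: str, counts: np.ndarray, pseudocount: float = 0.01) -> "PWM":
        counts = np.asarray(counts, dtype=float)
        if np.any(counts < 0):
            raise ValueError(f"negative counts in motif {motif_id!r}")
        freq = counts + pseudocount
        freq = freq / freq.sum(axis=1, keepdims=True)
        return cls(motif_id=motif_id, matrix=freq, pseudocount=pseudocount)

    @property
    def consensus(self) -> str:
        return "".join(BASES[b] for b in np.argmax(self.matrix, axis=1))


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _collapse_duplicates(df: pd.DataFrame, how: str) -> pd.DataFrame:
    if not df.index.has_duplicates:
        return df
    if how == "max":
        return df.groupby(level=0, sort=False).max()
    if how == "mean":
        return df.groupby(level=0, sort=False).mean()
    if how == "first":
        return df[~df.index.duplicated(keep="first")]
    raise ValueError(f"unknown duplicate-collapse rule {how!r}")


def read_expression(path, labels_path, collapse: str = "max") -> ExpressionMatrix:
    """Read a genes x samples TSV plus a two-column sample->tissue table.

    The expression file carries gene ids in the first column and sample ids
    in the header row.  Duplicate gene rows are collapsed (default: per-cell
    maximum).  Every sample must appear in the label table; missing labels,
    non-numeric cells and designs with fewer than two tissues are fatal.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().argmax()]
            raise FormatError(f"non-numeric expression value at gene {row!r}, sample {col!r}")
        df[col] = coerced
    if df.isna().any().any():
        raise FormatError("missing expression values are not allowed")
    df = _collapse_duplicates(df, collapse)

    labels = pd.read_csv(labels_path, sep="\t", header=None, comment="#", dtype=str)
    if labels.shape[1] < 2:
        raise FormatError("label table needs two columns: sample, tissue")
    tissue_of = dict(zip(labels.iloc[:, 0], labels.iloc[:, 1]))
    unlabeled = [s for s in df.columns if s not in tissue_of]
    if unlabeled:
        raise FormatError(f"no tissue label for sample(s): {unlabeled}")
    tissue_of = {s: tissue_of[s] for s in df.columns}
    return ExpressionMatrix(data=df, tissue_of=tissue_of)


def read_gmt(path) -> GeneSetCollection:
    """Read gene sets in GMT format (name TAB description TAB gene ...).

    Member genes are deduplicated preserving order.  Empty sets and duplicate
    set names are fatal.  Genes absent from any expression matrix are kept;
    intersection with the measured universe happens at scoring time.
    """
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"line {lineno}: GMT set with no genes")
            name, desc = parts[0], parts[1]
            genes = list(dict.fromkeys(g for g in parts[2:] if g))
            if not genes:
                raise FormatError(f"line {lineno}: GMT set {name!r} with no genes")
            if name in sets:
                raise FormatError(f"line {lineno}: duplicate set name {name!r}")
            sets[name] = (desc, genes)
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, (desc, genes) in collection.sets.items():
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_jaspar(path, pseudocount: float = 0.01) -> list[PWM]:
    """Read one or more PFM records in JASPAR text format.

    Each record is a ``>motif_id`` header followed by four base rows of
    counts, either bracketed (``A [ 3 5 ... ]``) or bare numbers.  Counts are
    converted to column-normalised frequencies after adding ``pseudocount``
    to every cell.
    """
    pwms: list[PWM] = []
    motif_id: str | None = None
    rows: dict[str, list[float]] = {}

    def flush() -> None:
        nonlocal rows, motif_id
        if motif_id is None:
            return
        if sorted(rows) != list("ACGT"):
            raise FormatError(f"motif {motif_id!r}: need exactly rows A, C, G, T")
        lengths = {len(v) for v in rows.values()}
        if len(lengths) != 1:
            raise FormatError(f"motif {motif_id!r}: base rows of unequal length")
        counts = np.array([rows[b] for b in BASES]).T
        pwms.append(PWM.from_counts(motif_id, counts, pseudocount))
        rows, motif_id = {}, None

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                motif_id = line[1:].split()[0]
                continue
            base = line[0].upper()
            body = line[1:].replace("[", " ").replace("]", " ")
            if base not in BASES:
                # headerless 4-row blocks are not supported; be explicit
                raise FormatError(f"unexpected PFM row: {line[:40]!r}")
            try:
                rows[base] = [float(x) for x in body.split()]
            except ValueError as exc:
                raise FormatError(f"non-numeric count in row {line[:40]!r}") from exc
    flush()
    return pwms


def write_jaspar(pwms: list[PWM], path, counts_scale: float = 100.0) -> None:
    """Write PWMs back as JASPAR-style PFM records (frequencies x scale)."""
    with open(path, "w") as fh:
        for p in pwms:
            fh.write(f">{p.motif_id}\n")
            for bi, b in enumerate(BASES):
                vals = " ".join(f"{v * counts_scale:.4f}" for v in p.matrix[:, bi])
                fh.write(f"{b} [ {vals} ]\n")


def read_fasta(path) -> PromoterSet:
    """Read promoter sequences from FASTA; duplicate ids are rejected."""
    records: dict[str, str] = {}
    name: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        nonlocal name, chunks
        if name is None:
            return
        if name in records:
            raise FormatError(f"duplicate FASTA id {name!r}")
        records[name] = "".join(chunks).upper()
        name, chunks = None, []

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                name = line[1:].split()[0]
            else:
                chunks.append(line)
    flush()
    return PromoterSet(records=records)


def write_fasta(promoters: PromoterSet, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for gid, seq in promoters.records.items():
            fh.write(f">{gid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_expression(expr: ExpressionMatrix, path, labels_path=None) -> None:
    expr.data.to_csv(path, sep="\t", index_label="gene_id")
    if labels_path is not None:
        with open(labels_path, "w") as fh:
            for s in expr.sample_ids:
                fh.write(f"{s}\t{expr.tissue_of[s]}\n")
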