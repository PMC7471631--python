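"""Readers and writers for the on-disk formats the pipeline touches.

All tabular formats are tab-separated UTF-8 text with LF line endings.
Genomic coordinates are 1-based inclusive throughout (SEG convention).
Every reader validates its input strictly and reports dropped or
collapsed records through a :class:`LoadReport` rather than silently
discarding rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The six genomic region classes used for methylation probe annotation.
REGION_CLASSES = ("TSS1500", "TSS200", "5UTR", "1stExon", "Body", "3UTR")

#: Recognized expression units.
UNITS = ("FPKM", "TPM", "LOG2TPM")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class LoadReport:
    """Accounting of what a reader did: nothing is dropped silently."""

    n_read: int = 0
    n_kept: int = 0
    n_collapsed: int = 0
    n_dropped: int = 0
    messages: list[str] = field(default_factory=list)


@dataclass
class ExpressionMatrix:
    """Genes x samples abundance matrix with a unit tag.

    ``values`` is a DataFrame indexed by gene id with sample-id columns.
    The unit is one of ``FPKM`` (arbitrary linear abundance), ``TPM``
    (columns sum to 1e6) or ``LOG2TPM`` (log2(TPM + 1)).
    """

    values: pd.DataFrame
    unit: str = "TPM"

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {UNITS}")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene ids: {dups[:5]}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups[:5]}")
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise FormatError("expression values must be finite (no NA/inf)")
        if self.unit != "LOG2TPM" and (arr < 0).any():
            raise FormatError("abundance values must be non-negative")
        if self.unit == "TPM" and arr.size:
            sums = arr.sum(axis=0)
            if not np.allclose(sums, 1e6, rtol=1e-6):
                bad = self.values.columns[~np.isclose(sums, 1e6, rtol=1e-6)][:5].tolist()
                raise FormatError(f"TPM columns must sum to 1e6; offending samples: {bad}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class Segment:
    """One copy-number segment; positions are 1-based inclusive."""

    sample_id: str
    chromosome: str
    start: int
    end: int
    n_probes: int
    segment_mean: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(
                f"segment start > end ({self.start} > {self.end}) for {self.sample_id}"
            )
        if self.n_probes < 1:
            raise FormatError(f"segment n_probes must be >= 1, got {self.n_probes}")


@dataclass(frozen=True)
class ProbeAnnotation:
    """Methylation probe annotation: location, gene and region class."""

    probe_id: str
    chromosome: str
    position: int
    gene_symbol: str
    region_class: str
    cpg_class: str = ""

    def __post_init__(self) -> None:
        if self.region_class not in REGION_CLASSES:
            raise FormatError(
                f"region_class {self.region_class!r} not one of {REGION_CLASSES}"
            )


@dataclass
class InteractionTable:
    """A set of (regulator, target) pairs from one interaction database."""

    kind: str  # "lnc_mi" or "mi_gene"
    source_db: str
    pairs: set[tuple[str, str]]

    def __post_init__(self) -> None:
        if self.kind not in ("lnc_mi", "mi_gene"):
            raise ValueError(f"kind must be 'lnc_mi' or 'mi_gene', got {self.kind!r}")


# ---------------------------------------------------------------------------
# expression / methylation matrices
# ---------------------------------------------------------------------------


def read_expression(path, unit: str = "TPM") -> tuple[ExpressionMatrix, LoadReport]:
    """Read a genes x samples TSV (first column gene ids, header sample ids).

    Duplicate gene rows are collapsed by arithmetic mean; the collapse is
    counted in the returned :class:`LoadReport`. Non-numeric cells raise
    :class:`FormatError` naming the offending row and column.
    """
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(header) != len(set(header)):  # pandas would mangle duplicates
        raise FormatError(f"duplicate sample ids in header of {path}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    report = LoadReport(n_read=df.shape[0])
    num = df.apply(pd.to_numeric, errors="coerce")
    bad = num.isna() & df.notna()
    if bad.any().any() or df.isna().any().any():
        mask = num.isna()
        r = mask.any(axis=1).idxmax()
        c = mask.loc[r].idxmax()
        raise FormatError(f"non-numeric cell at gene {r!r}, sample {c!r} in {path}")
    if num.index.duplicated().any():
        n_dup_rows = int(num.index.duplicated().sum())
        num = num.groupby(level=0, sort=False).mean()
        report.n_collapsed = n_dup_rows
        report.messages.append(f"collapsed {n_dup_rows} duplicate gene rows by mean")
        logger.info("collapsed %d duplicate gene rows by mean", n_dup_rows)
    report.n_kept = num.shape[0]
    return ExpressionMatrix(values=num, unit=unit), report


def write_expression(matrix: ExpressionMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", lineterminator="\n")


def read_methylation(path) -> tuple[pd.DataFrame, LoadReport]:
    """Read a probes x samples beta matrix.

    Rows that are NA in every sample are dropped (and counted); a row
    with partial NA is an error, since downstream tests assume complete
    per-probe observations. Betas must lie in [0, 1].
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    report = LoadReport(n_read=df.shape[0])
    all_na = df.isna().all(axis=1)
    if all_na.any():
        report.n_dropped = int(all_na.sum())
        report.messages.append(f"dropped {report.n_dropped} all-NA probes")
        df = df.loc[~all_na]
    if df.isna().any().any():
        r = df.index[df.isna().any(axis=1)][0]
        raise FormatError(f"probe {r!r} has partial NA values in {path}")
    arr = df.to_numpy(dtype=float)
    if arr.size and ((arr < 0) | (arr > 1)).any():
        raise FormatError(f"beta values outside [0, 1] in {path}")
    report.n_kept = df.shape[0]
    return df, report


def write_methylation(betas: pd.DataFrame, path) -> None:
    betas.to_csv(path, sep="\t", lineterminator="\n")


# ---------------------------------------------------------------------------
# SEG segments
# ---------------------------------------------------------------------------

SEG_COLUMNS = ["sample", "chromosome", "start", "end", "num_probes", "segment_mean"]


def read_segments(path) -> list[Segment]:
    """Read a SEG-style TSV into a validated, file-ordered Segment list."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SEG_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"SEG file {path} missing columns {missing}")
    return [
        Segment(
            sample_id=str(row.sample),
            chromosome=str(row.chromosome),
            start=int(row.start),
            end=int(row.end),
            n_probes=int(row.num_probes),
            segment_mean=float(row.segment_mean),
        )
        for row in df.itertuples(index=False)
    ]


def write_segments(segments: list[Segment], path) -> None:
    df = pd.DataFrame(
        [
            (s.sample_id, s.chromosome, s.start, s.end, s.n_probes, s.segment_mean)
            for s in segments
        ],
        columns=SEG_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# GMT gene sets and signed edges
# ---------------------------------------------------------------------------


def read_gmt(path) -> dict[str, set[str]]:
    """Read GMT pathway definitions: name, description, members.

    Members are deduplicated; a pathway with fewer than two genes is
    retained with a warning (it cannot carry topology but may still be
    tested for over-representation).
    """
    sets: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"GMT line with < 3 fields in {path}: {line!r}")
            name, members = parts[0], set(parts[2:]) - {""}
            if len(members) < 2:
                logger.warning("pathway %s has < 2 genes; retained", name)
            sets[name] = members
    return sets


def write_gmt(sets: dict[str, set[str]], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, "na", *sorted(members)]) + "\n")


def read_edges(path) -> dict[str, list[tuple[str, str, int]]]:
    """Read a signed gene-gene edge list: pathway, src, dst, sign (+1/-1)."""
    df = pd.read_csv(path, sep="\t", dtype={"pathway": str, "src": str, "dst": str})
    missing = [c for c in ("pathway", "src", "dst", "sign") if c not in df.columns]
    if missing:
        raise FormatError(f"edge file {path} missing columns {missing}")
    edges: dict[str, list[tuple[str, str, int]]] = {}
    for row in df.itertuples(index=False):
        sign = int(row.sign)
        if sign not in (1, -1):
            raise FormatError(f"unknown edge sign {row.sign!r} in {path}")
        edges.setdefault(row.pathway, []).append((row.src, row.dst, sign))
    return edges


def write_edges(edges: dict[str, list[tuple[str, str, int]]], path) -> None:
    rows = [
        (p, src, dst, sign) for p, lst in edges.items() for (src, dst, sign) in lst
    ]
    pd.DataFrame(rows, columns=["pathway", "src", "dst", "sign"]).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


# ---------------------------------------------------------------------------
# interaction tables, survival, probe annotation
# ---------------------------------------------------------------------------


def read_interactions(path, kind: str, source_db: str) -> InteractionTable:
    """Read a two-column (regulator, target) interaction TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"interaction file {path} needs >= 2 columns")
    pairs = set(zip(df.iloc[:, 0], df.iloc[:, 1]))
    return InteractionTable(kind=kind, source_db=source_db, pairs=pairs)


def write_interactions(table: InteractionTable, path) -> None:
    cols = ("lncrna", "mirna") if table.kind == "lnc_mi" else ("mirna", "gene")
    pd.DataFrame(sorted(table.pairs), columns=list(cols)).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


def read_survival(path) -> pd.DataFrame:
    """Read a survival table: sample, time (days), event (0/1), optional group."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    missing = [c for c in ("sample", "time", "event") if c not in df.columns]
    if missing:
        raise FormatError(f"survival table {path} missing columns {missing}")
    if (df["time"] < 0).any():
        raise FormatError("survival times must be >= 0")
    if not df["event"].isin([0, 1]).all():
        raise FormatError("event must be 0 (censored) or 1 (death)")
    return df


def write_survival(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_probe_annotation(path) -> list[ProbeAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [
        c
        for c in ("probe", "chromosome", "position", "gene", "region_class")
        if c not in df.columns
    ]
    if missing:
        raise FormatError(f"probe annotation {path} missing columns {missing}")
    return [
        ProbeAnnotation(
            probe_id=row.probe,
            chromosome=row.chromosome,
            position=int(row.position),
            gene_symbol=row.gene,
            region_class=row.region_class,
            cpg_class=getattr(row, "cpg_class", "") or "",
        )
        for row in df.itertuples(index=False)
    ]


def write_probe_annotation(annotation: list[ProbeAnnotation], path) -> None:
    pd.DataFrame(
        [
            (a.probe_id, a.chromosome, a.position, a.gene_symbol, a.region_class, a.cpg_class)
            for a in annotation
        ],
        columns=["probe", "chromosome", "position", "gene", "region_class", "cpg_class"],
    ).to_csv(path, sep="\t", index=False, lineterminator="\n")
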