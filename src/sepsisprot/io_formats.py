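"""On-disk formats and in-memory containers for the pipeline.

Everything the pipeline touches on disk is plain text: tab-separated
tables for abundances, metadata and result tables, GMT for gene sets,
GraphML for the pathway-clinical association network, and JSON for
configuration echoes and simulation ground truth.  All writers are
deterministic (same object, same bytes) and all readers validate
structure rather than silently repairing it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "AbundanceMatrix",
    "SampleRecord",
    "GeneSetCollection",
    "read_abundance",
    "write_abundance",
    "read_metadata",
    "write_metadata",
    "read_gmt",
    "write_gmt",
    "write_graphml",
]

# Text precision for floats on write: 17 significant digits round-trips
# IEEE doubles exactly through decimal text.
_FLOAT_FMT = "%.17g"

GROUPS = ("HC", "SEPSIS")
TIMEPOINTS = ("D1", "D3", "NA")


class FormatError(ValueError):
    """A structural violation in an on-disk file or in-memory container."""


@dataclass
class AbundanceMatrix:
    """Samples x proteins matrix of log2 protein abundances.

    Rows are samples, columns are proteins.  Protein identifiers are
    opaque strings (multiplexed panels mix gene symbols with assay names
    such as ``pTau-217``).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        idx = pd.Index(self.data.index.astype(str))
        cols = pd.Index(self.data.columns.astype(str))
        if idx.has_duplicates:
            dup = idx[idx.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dup}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()].unique().tolist()
            raise FormatError(f"duplicate protein ids: {dup}")
        self.data = self.data.astype(float)
        self.data.index = idx
        self.data.columns = cols
        self.data.index.name = "sample_id"
        vals = self.data.to_numpy()
        if np.isinf(vals).any():
            raise FormatError("abundance values must be finite or missing (NA)")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def protein_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def values_for(self, sample_ids: list[str]) -> pd.DataFrame:
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        return self.data.loc[sample_ids]


@dataclass
class SampleRecord:
    """Identity and clinical annotation of one plasma sample."""

    sample_id: str
    subject_id: str
    group: str  # HC | SEPSIS
    timepoint: str  # D1 | D3 | NA
    clinical: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise FormatError(f"{self.sample_id}: group must be one of {GROUPS}, got {self.group!r}")
        if self.timepoint not in TIMEPOINTS:
            raise FormatError(
                f"{self.sample_id}: timepoint must be one of {TIMEPOINTS}, got {self.timepoint!r}"
            )
        if self.group == "HC" and self.timepoint != "NA":
            raise FormatError(f"{self.sample_id}: healthy controls carry timepoint NA")
        mort = self.clinical.get("mortality")
        if mort is not None and not _is_na(mort) and float(mort) not in (0.0, 1.0):
            raise FormatError(f"{self.sample_id}: mortality must be 0/1, got {mort!r}")


def _is_na(x) -> bool:
    return x is None or (isinstance(x, float) and np.isnan(x)) or x == "NA"


def validate_records(records: list[SampleRecord]) -> None:
    seen: set[tuple[str, str]] = set()
    for r in records:
        key = (r.subject_id, r.timepoint)
        if key in seen:
            raise FormatError(f"duplicate (subject_id, timepoint): {key}")
        seen.add(key)


@dataclass
class GeneSetCollection:
    """Ordered gene-set annotation (GMT semantics).

    ``terms`` is an ordered list of (term_id, description, member ids).
    Member lists are non-empty and duplicate-free; duplicated members
    found on read are dropped with a warning.
    """

    terms: list[tuple[str, str, list[str]]]

    def __post_init__(self) -> None:
        ids = [t[0] for t in self.terms]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate term ids: {dup}")
        for term_id, _desc, members in self.terms:
            if not members:
                raise FormatError(f"term {term_id!r} has no members")
            if len(members) != len(set(members)):
                raise FormatError(f"term {term_id!r} has duplicate members")

    @property
    def term_ids(self) -> list[str]:
        return [t[0] for t in self.terms]

    def members(self, term_id: str) -> list[str]:
        for tid, _d, m in self.terms:
            if tid == term_id:
                return m
        raise KeyError(term_id)

    def __len__(self) -> int:
        return len(self.terms)


# ---------------------------------------------------------------------------
# Abundance TSV
# ---------------------------------------------------------------------------

def read_abundance(path) -> AbundanceMatrix:
    """Read a samples x proteins abundance TSV (first column = sample_id)."""
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip("\n\r\t ") != ""]
    if not lines:
        raise FormatError(f"{path}: empty abundance file")
    header = lines[0].split("\t")
    if len(header) < 2:
        raise FormatError(f"{path}: header must contain sample_id plus >=1 protein column")
    proteins = header[1:]
    width = len(header)
    sample_ids: list[str] = []
    rows: list[list[float]] = []
    for i, ln in enumerate(lines[1:], start=2):
        fields = ln.split("\t")
        if len(fields) != width:
            raise FormatError(f"{path}: line {i} has {len(fields)} fields, expected {width}")
        sample_ids.append(fields[0])
        rows.append([np.nan if f in ("", "NA") else float(f) for f in fields[1:]])
    df = pd.DataFrame(rows, index=sample_ids, columns=proteins)
    return AbundanceMatrix(df)


def write_abundance(matrix: AbundanceMatrix, path) -> None:
    df = matrix.data
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\t" + "\t".join(df.columns) + "\n")
        for sid, row in zip(df.index, df.to_numpy()):
            cells = ["NA" if np.isnan(v) else _FLOAT_FMT % v for v in row]
            fh.write(sid + "\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# Sample metadata TSV
# ---------------------------------------------------------------------------

_CORE_COLS = ["sample_id", "subject_id", "group", "timepoint"]


def write_metadata(records: list[SampleRecord], path) -> None:
    """Write sample records to TSV, one row per sample, clinical fields as columns."""
    clin_cols: list[str] = []
    for r in records:
        for k in r.clinical:
            if k not in clin_cols:
                clin_cols.append(k)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_CORE_COLS + clin_cols) + "\n")
        for r in records:
            cells = [r.sample_id, r.subject_id, r.group, r.timepoint]
            for c in clin_cols:
                v = r.clinical.get(c)
                if _is_na(v):
                    cells.append("NA")
                elif isinstance(v, float):
                    cells.append(_FLOAT_FMT % v)
                else:
                    cells.append(str(v))
            fh.write("\t".join(cells) + "\n")


def read_metadata(path) -> list[SampleRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _CORE_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing metadata columns {missing}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise FormatError(f"{path}: duplicate sample ids {dup}")
    clin_cols = [c for c in df.columns if c not in _CORE_COLS]
    records = []
    for _, row in df.iterrows():
        clinical = {}
        for c in clin_cols:
            v = row[c]
            if v == "NA" or v == "":
                clinical[c] = np.nan
            else:
                try:
                    clinical[c] = float(v)
                except ValueError:
                    clinical[c] = v
        records.append(
            SampleRecord(
                sample_id=row["sample_id"],
                subject_id=row["subject_id"],
                group=row["group"],
                timepoint=row["timepoint"],
                clinical=clinical,
            )
        )
    validate_records(records)
    return records


def records_to_frame(records: list[SampleRecord]) -> pd.DataFrame:
    """Flatten records into a DataFrame indexed by sample_id."""
    rows = []
    for r in records:
        row = {"subject_id": r.subject_id, "group": r.group, "timepoint": r.timepoint}
        row.update(r.clinical)
        rows.append(row)
    return pd.DataFrame(rows, index=pd.Index([r.sample_id for r in records], name="sample_id"))


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------

def read_gmt(path) -> GeneSetCollection:
    terms = []
    with open(path, encoding="utf-8") as fh:
        for i, ln in enumerate(fh, start=1):
            ln = ln.rstrip("\n")
            if not ln.strip():
                continue
            fields = ln.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {i}: GMT line needs >=3 tab-separated fields")
            term_id, desc = fields[0], fields[1]
            members, seen = [], set()
            dups = []
            for m in fields[2:]:
                if m == "":
                    continue
                if m in seen:
                    dups.append(m)
                    continue
                seen.add(m)
                members.append(m)
            if dups:
                warnings.warn(
                    f"{path}: line {i}: term {term_id!r} has duplicated members {sorted(set(dups))}; deduplicated"
                )
            terms.append((term_id, desc, members))
    return GeneSetCollection(terms)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term_id, desc, members in collection.terms:
            fh.write("\t".join([term_id, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# GraphML
# ---------------------------------------------------------------------------

def write_graphml(graph: nx.Graph, path) -> None:
    """Serialize a pathway-clinical bipartite graph to GraphML.

    Nodes carry ``node_type`` in {pathway, clinical}; edges carry a signed
    ``weight`` and the count ``n_proteins`` of proteins backing the edge.
    """
    for node, attrs in graph.nodes(data=True):
        if attrs.get("node_type") not in ("pathway", "clinical"):
            raise FormatError(f"node {node!r} lacks node_type in {{pathway, clinical}}")
    out = nx.Graph()
    for node in sorted(graph.nodes):
        out.add_node(node, node_type=graph.nodes[node]["node_type"])
    for u, v, attrs in sorted(graph.edges(data=True)):
        out.add_edge(u, v, weight=float(attrs["weight"]), n_proteins=int(attrs["n_proteins"]))
    nx.write_graphml(out, path, named_key_ids=True)
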