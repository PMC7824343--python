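"""Reading and validation of OTU count / taxonomy / metadata / qPCR tables, and network I/O.

All tabular inputs are plain tab-separated text.  Counts files carry OTUs as
rows and samples as columns (a transposed file is accepted only when its row
index unambiguously matches the sample metadata, otherwise it is an error —
silent transposition is a classic corruption source).  Taxonomy lineages are
semicolon-separated, ``domain;...;genus``; SILVA-style rank prefixes such as
``d__`` are stripped on read.  All identifiers are opaque, case-sensitive
strings.

Networks are written to GraphML, GML, or a flat edge list (``edge_tsv``) with
Gephi-compatible attribute names: ``weight`` on edges, ``taxonomy`` and
``module`` on nodes.  The edge list carries node attributes in leading ``#``
comment lines so that every format round-trips exactly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

__all__ = [
    "OtuTable",
    "QpcrRun",
    "TableParseError",
    "TableValidationError",
    "read_otu_table",
    "read_qpcr_table",
    "write_network",
    "read_network",
]

_RANK_PREFIX = re.compile(r"\b[a-z]__")

NETWORK_FORMATS = ("graphml", "gml", "edge_tsv")


class TableParseError(ValueError):
    """A cell could not be parsed (e.g. a non-integer count)."""


class TableValidationError(ValueError):
    """Structurally parseable input that violates an OtuTable invariant."""


@dataclass
class OtuTable:
    """An integer OTU count matrix with taxonomy and sample metadata.

    Parameters
    ----------
    counts : pandas.DataFrame
        Non-negative integers, indexed by OTU id (rows) and sample id
        (columns).
    taxonomy : pandas.Series
        OTU id -> semicolon-separated lineage string (domain ... genus).
    samples : pandas.DataFrame
        Indexed by sample id; carries at least a ``group`` column and an
        optional ``timepoint`` column.
    """

    counts: pd.DataFrame
    taxonomy: pd.Series
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        c = self.counts
        if c.shape[0] < 2 or c.shape[1] < 2:
            raise TableValidationError(
                f"need at least 2 OTUs and 2 samples, got {c.shape[0]}x{c.shape[1]}"
            )
        if (c.values < 0).any():
            bad = c.index[(c.values < 0).any(axis=1)][0]
            raise TableValidationError(f"negative count in OTU {bad!r}")
        missing_tax = c.index.difference(self.taxonomy.index)
        if len(missing_tax):
            raise TableValidationError(
                f"taxonomy missing for OTU(s): {', '.join(map(repr, missing_tax[:5]))}"
            )
        missing_meta = c.columns.difference(self.samples.index)
        if len(missing_meta):
            raise TableValidationError(
                f"sample metadata missing for sample(s): "
                f"{', '.join(map(repr, missing_meta[:5]))}"
            )

    # -- conveniences ---------------------------------------------------
    @property
    def otu_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_otus(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def subset_otus(self, otu_ids) -> "OtuTable":
        """A new table restricted to ``otu_ids`` (order preserved)."""
        return OtuTable(
            counts=self.counts.loc[otu_ids],
            taxonomy=self.taxonomy.loc[otu_ids],
            samples=self.samples,
        )


@dataclass
class QpcrRun:
    """One qPCR run: a dilution-series standard table plus unknowns.

    ``standards`` columns: known_log10_copies, ct, replicate.
    ``unknowns`` columns: sample_id, timepoint, ct, replicate,
    dilution_factor, mass_or_volume, units ("g" or "mL").
    """

    standards: pd.DataFrame
    unknowns: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        std = self.standards
        if std["known_log10_copies"].nunique() < 3:
            raise TableValidationError(
                "standard curve needs >= 3 distinct concentrations"
            )
        for frame, name in ((std, "standards"), (self.unknowns, "unknowns")):
            if len(frame) and (~pd.to_numeric(frame["ct"], errors="coerce").gt(0)).any():
                raise TableValidationError(f"non-positive or non-finite Ct in {name}")


def _strip_rank_prefixes(lineage: str) -> str:
    return _RANK_PREFIX.sub("", lineage)


def read_otu_table(counts_path, taxonomy_path, metadata_path) -> OtuTable:
    """Read a tab-separated OTU table with its taxonomy and sample metadata.

    The counts file must have a header row of sample ids and a first column
    of OTU ids.  If instead the *row* index matches the metadata's sample ids
    (and the header does not), the matrix is transposed with a warning-free
    auto-detection; any other mismatch is an error.
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    counts.index = counts.index.astype(str)
    counts.columns = counts.columns.astype(str)

    meta = pd.read_csv(metadata_path, sep="\t", index_col=0)
    meta.index = meta.index.astype(str)

    sample_ids = set(meta.index)
    cols_match = set(counts.columns) <= sample_ids
    rows_match = set(counts.index) <= sample_ids
    if not cols_match and rows_match:
        counts = counts.T
    elif not cols_match and not rows_match:
        unknown = [c for c in counts.columns if c not in sample_ids][:5]
        raise TableValidationError(
            f"count columns do not match metadata sample ids (e.g. "
            f"{', '.join(map(repr, unknown))}); refusing to guess orientation"
        )

    # integer check with a line number for the offender
    for i, (otu, row) in enumerate(counts.iterrows(), start=2):
        for val in row:
            f = float(val)
            if f != int(f):
                raise TableParseError(
                    f"non-integer count {val!r} for OTU {otu!r} (line {i})"
                )
            if f < 0:
                raise TableParseError(
                    f"negative count {val!r} for OTU {otu!r} (line {i})"
                )
    counts = counts.astype(int)

    tax_raw = pd.read_csv(taxonomy_path, sep="\t", index_col=0)
    taxonomy = tax_raw.iloc[:, 0].astype(str).map(_strip_rank_prefixes)
    taxonomy.index = taxonomy.index.astype(str)

    return OtuTable(counts=counts, taxonomy=taxonomy, samples=meta)


_QPCR_COLUMNS = {
    "role", "sample_id", "timepoint", "ct", "replicate",
    "known_log10_copies", "dilution_factor", "mass_or_volume", "units",
}


def read_qpcr_table(path) -> QpcrRun:
    """Read a combined standards+unknowns qPCR table (TSV, ``role`` column)."""
    frame = pd.read_csv(path, sep="\t")
    missing = {"role", "ct"} - set(frame.columns)
    if missing:
        raise TableParseError(f"qPCR table missing column(s): {sorted(missing)}")
    std = frame[frame["role"] == "standard"].copy()
    unk = frame[frame["role"] == "unknown"].copy()
    return QpcrRun(standards=std.reset_index(drop=True),
                   unknowns=unk.reset_index(drop=True))


# ---------------------------------------------------------------------------
# network I/O
# ---------------------------------------------------------------------------

def write_network(network: nx.Graph, path, format: str = "graphml") -> None:
    """Write a co-occurrence network with node ``taxonomy``/``module`` and edge
    ``weight`` attributes.

    ``edge_tsv`` writes node attributes in ``#node`` comment lines followed by
    a three-column ``source  target  weight`` section (weights at 6 decimal
    places).
    """
    if format not in NETWORK_FORMATS:
        raise ValueError(f"unknown network format {format!r}; expected one of {NETWORK_FORMATS}")
    if network.number_of_nodes() == 0:
        raise ValueError("refusing to write an empty network")

    g = network.copy()
    for _, data in g.nodes(data=True):
        data.setdefault("taxonomy", "")
        data.setdefault("module", -1)

    if format == "graphml":
        nx.write_graphml(g, path)
    elif format == "gml":
        nx.write_gml(g, path)
    else:
        with open(path, "w") as fh:
            for node, data in g.nodes(data=True):
                fh.write(f"#node\t{node}\t{data['taxonomy']}\t{data['module']}\n")
            fh.write("source\ttarget\tweight\n")
            for u, v, data in g.edges(data=True):
                fh.write(f"{u}\t{v}\t{data['weight']:.6f}\n")


def read_network(path, format: str = "graphml") -> nx.Graph:
    """Inverse of :func:`write_network`."""
    if format not in NETWORK_FORMATS:
        raise ValueError(f"unknown network format {format!r}; expected one of {NETWORK_FORMATS}")
    if format == "graphml":
        g = nx.read_graphml(path)
    elif format == "gml":
        g = nx.read_gml(path)
    else:
        g = nx.Graph()
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#node\t"):
                    _, node, taxonomy, module = line.split("\t")
                    g.add_node(node, taxonomy=taxonomy, module=int(module))
                elif line and not line.startswith("source\t"):
                    u, v, w = line.split("\t")
                    g.add_edge(u, v, weight=float(w))
    # normalise module attribute type (GraphML preserves ints, GML may not)
    for _, data in g.nodes(data=True):
        if "module" in data:
            data["module"] = int(data["module"])
    return g
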