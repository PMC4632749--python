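"""Typed containers and readers/writers shared by every pipeline stage.

The central container is :class:`AbundanceTable`: a wide samples x metabolites
matrix of positive relative abundances (GC-MS responses normalized to an
internal standard, hence unitless) together with the factorial sample metadata
(cultivar, growth temperature, sampling day, replicate/vine id). Temperatures
are kept as categorical string labels ("25", "35") so no arithmetic is ever
done on them.

Networks are written in three interchange formats: GraphML (attributes
preserved), SIF for Cytoscape, and a plain sorted TSV edge list. All writers
are deterministic: rows, nodes and edges are emitted in lexicographic order so
repeated runs are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

#: metadata columns every abundance table must carry, in canonical order
METADATA_COLUMNS = ("cultivar", "temperature", "day", "replicate")

#: the six biochemical classes used to annotate the metabolite panel
BIOCHEMICAL_CLASSES = (
    "amino acid",
    "glycolysis",
    "TCA cycle",
    "non-glycolytic sugar",
    "flavonoid",
    "carboxylic acid",
)


class AbundanceTableError(ValueError):
    """Raised when an abundance table violates its invariants."""


@dataclass(frozen=True)
class AbundanceTable:
    """Wide table of positive relative abundances with sample metadata.

    Parameters
    ----------
    samples:
        DataFrame with exactly the columns ``cultivar``, ``temperature``,
        ``day``, ``replicate`` (strings), one row per sample.
    data:
        DataFrame of abundances aligned row-wise with ``samples``; one column
        per metabolite, strictly positive values.
    """

    samples: pd.DataFrame
    data: pd.DataFrame

    def __post_init__(self) -> None:
        validate_abundance_table(self.samples, self.data)

    @property
    def metabolites(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def subset(self, **criteria: str) -> "AbundanceTable":
        """Rows whose metadata match every ``column=value`` criterion."""
        mask = pd.Series(True, index=self.samples.index)
        for column, value in criteria.items():
            if column not in self.samples.columns:
                raise KeyError(f"unknown metadata column {column!r}")
            mask &= self.samples[column] == value
        return AbundanceTable(
            self.samples.loc[mask].reset_index(drop=True),
            self.data.loc[mask].reset_index(drop=True),
        )

    def group_values(self, metabolite: str, **criteria: str) -> pd.Series:
        """Abundances of one metabolite over the samples matching ``criteria``."""
        return self.subset(**criteria).data[metabolite]

    def to_wide_frame(self) -> pd.DataFrame:
        return pd.concat([self.samples, self.data], axis=1)

    def equals(self, other: "AbundanceTable") -> bool:
        return self.samples.equals(other.samples) and self.data.equals(other.data)


def validate_abundance_table(samples: pd.DataFrame, data: pd.DataFrame) -> None:
    missing = [c for c in METADATA_COLUMNS if c not in samples.columns]
    if missing:
        raise AbundanceTableError(f"missing metadata columns: {missing}")
    if list(samples.columns) != list(METADATA_COLUMNS):
        extra = [c for c in samples.columns if c not in METADATA_COLUMNS]
        if extra:
            raise AbundanceTableError(f"unexpected metadata columns: {extra}")
    if len(samples) != len(data):
        raise AbundanceTableError(
            f"metadata has {len(samples)} rows but data has {len(data)}"
        )
    keys = samples[list(METADATA_COLUMNS)].astype(str)
    duplicated = keys.duplicated()
    if duplicated.any():
        first = keys.loc[duplicated].iloc[0].tolist()
        raise AbundanceTableError(f"duplicated sample key {tuple(first)}")
    if data.columns.duplicated().any():
        dupes = data.columns[data.columns.duplicated()].tolist()
        raise AbundanceTableError(f"duplicated metabolite columns: {dupes}")
    numeric = data.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        col = numeric.columns[numeric.isna().any()][0]
        row = int(numeric.index[numeric[col].isna()][0])
        raise AbundanceTableError(f"non-numeric abundance at row {row}, column {col!r}")
    nonpos = numeric <= 0
    if nonpos.any().any():
        col = nonpos.columns[nonpos.any()][0]
        row = int(nonpos.index[nonpos[col]][0])
        raise AbundanceTableError(
            f"non-positive abundance at row {row}, column {col!r} "
            f"(value {numeric.at[row, col]!r}); log10 undefined"
        )


def read_abundance_table(path: str | Path) -> AbundanceTable:
    """Read a wide TSV/CSV abundance table (separator inferred from suffix)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    frame = pd.read_csv(path, sep=sep, dtype={c: str for c in METADATA_COLUMNS})
    missing = [c for c in METADATA_COLUMNS if c not in frame.columns]
    if missing:
        raise AbundanceTableError(f"{path}: missing metadata columns {missing}")
    samples = frame[list(METADATA_COLUMNS)].reset_index(drop=True)
    data = frame.drop(columns=list(METADATA_COLUMNS)).astype(float)
    return AbundanceTable(samples, data.reset_index(drop=True))


def write_abundance_table(table: AbundanceTable, path: str | Path) -> Path:
    """Write the wide TSV dialect; deterministic row and column order."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    table.to_wide_frame().to_csv(path, sep=sep, index=False)
    return path


def read_class_annotation(path: str | Path) -> dict[str, str]:
    """Read the two-column metabolite -> biochemical class TSV."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if list(frame.columns[:2]) != ["metabolite", "class"]:
        raise ValueError(f"{path}: expected columns 'metabolite' and 'class'")
    annotation = dict(zip(frame["metabolite"], frame["class"]))
    unknown = sorted(set(annotation.values()) - set(BIOCHEMICAL_CLASSES))
    if unknown:
        raise ValueError(f"{path}: unknown biochemical classes {unknown}")
    return annotation


def write_class_annotation(annotation: Mapping[str, str], path: str | Path) -> Path:
    frame = pd.DataFrame(
        sorted(annotation.items()), columns=["metabolite", "class"]
    )
    frame.to_csv(path, sep="\t", index=False)
    return Path(path)


def sorted_pair(a: str, b: str) -> tuple[str, str]:
    """Unordered node pair serialized with the lexicographically smaller first."""
    return (a, b) if a <= b else (b, a)


def network_to_graph(net) -> nx.Graph:
    """Convert a CorrelationNetwork to a networkx Graph (sorted insertion order)."""
    graph = nx.Graph()
    for node in sorted(net.nodes):
        graph.add_node(node, biochemical_class=net.nodes[node])
    for (a, b) in sorted(net.edges):
        rho, p = net.edges[(a, b)]
        graph.add_edge(a, b, rho=float(rho), p=float(p))
    return graph


def write_network(net, path: str | Path, fmt: str | None = None) -> Path:
    """Write a correlation network as GraphML, SIF or a TSV edge list.

    ``fmt`` is one of ``"graphml"``, ``"sif"``, ``"tsv"``; when omitted it is
    inferred from the path suffix. SIF uses the interaction label ``corr``.
    """
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    fmt = fmt.lower()
    if fmt == "graphml":
        nx.write_graphml(network_to_graph(net), path, infer_numeric_types=False)
    elif fmt == "sif":
        lines = [f"{a}\tcorr\t{b}" for (a, b) in sorted(net.edges)]
        connected = {n for pair in net.edges for n in pair}
        lines += [name for name in sorted(net.nodes) if name not in connected]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    elif fmt == "tsv":
        rows = [
            {"source": a, "target": b, "rho": rho, "p": p}
            for (a, b), (rho, p) in sorted(net.edges.items())
        ]
        frame = pd.DataFrame(rows, columns=["source", "target", "rho", "p"])
        frame.to_csv(path, sep="\t", index=False, float_format="%.12g")
    else:
        raise ValueError(f"unknown network format {fmt!r}")
    return path


def read_network_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(Path(path))
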