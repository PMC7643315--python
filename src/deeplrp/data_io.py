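"""Readers and writers for expression matrices, probe maps, GMT gene sets and
model checkpoints.

Formats
-------
Expression matrix
    Tab-separated text. Samples are rows, probes are columns. The first
    column holds the sample id and one column (default ``label``) holds the
    class label. Values are written with 17 significant digits so a
    write/read round trip is value-exact for float64.
Probe map
    Two-column TSV ``probe_id<TAB>gene_id`` with a header line. Probes with
    no gene mapping are simply absent from the file.
Gene sets
    Standard GMT: one term per line, ``term_id<TAB>description<TAB>gene...``.
Checkpoint
    A zip archive of ``.npy`` arrays (one weight matrix and one bias vector
    per layer) plus a ``meta.json`` record. Member timestamps are fixed so
    that identical networks serialize to identical bytes.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "ProbeAnnotation",
    "GeneSetTerm",
    "AnnotationDatabase",
    "read_expression",
    "write_expression",
    "read_probe_map",
    "write_probe_map",
    "read_gmt",
    "write_gmt",
    "gene_universe",
    "save_checkpoint",
    "load_checkpoint",
]

_CHECKPOINT_DATE = (1980, 1, 1, 0, 0, 0)  # fixed so identical nets give identical bytes


def _check_unique(ids: Sequence[str], kind: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {kind} id: {x!r}")
        seen.add(x)


@dataclass
class ExpressionDataset:
    """A labelled samples x probes expression matrix.

    ``matrix`` holds normalized, unitless expression values, one row per
    sample and one column per probe. ``class_set`` fixes the class order
    used everywhere downstream (output-neuron k corresponds to
    ``class_set[k]``).
    """

    matrix: np.ndarray
    sample_ids: list[str]
    probe_ids: list[str]
    labels: list[str]
    class_set: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("expression matrix must be 2-dimensional")
        n, p = self.matrix.shape
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(self.probe_ids) != p:
            raise ValueError(f"{len(self.probe_ids)} probe ids for {p} columns")
        if len(self.labels) != n:
            raise ValueError(f"{len(self.labels)} labels for {n} samples")
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.probe_ids, "probe")
        _check_unique(self.class_set, "class")
        bad = ~np.isfinite(self.matrix)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"non-finite expression value at sample {self.sample_ids[i]!r}, "
                f"probe {self.probe_ids[j]!r}"
            )
        classes = set(self.class_set)
        for sid, lab in zip(self.sample_ids, self.labels):
            if lab not in classes:
                raise ValueError(f"sample {sid!r} has unknown label {lab!r}")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_probes(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_classes(self) -> int:
        return len(self.class_set)

    @property
    def X(self) -> np.ndarray:
        return self.matrix

    @property
    def y(self) -> np.ndarray:
        """Labels encoded as indices into ``class_set``."""
        index = {c: k for k, c in enumerate(self.class_set)}
        return np.array([index[lab] for lab in self.labels], dtype=int)

    def class_index(self, name: str) -> int:
        try:
            return self.class_set.index(name)
        except ValueError:
            raise KeyError(f"unknown class {name!r}; classes are {self.class_set}") from None

    def subset(self, rows: np.ndarray) -> "ExpressionDataset":
        rows = np.asarray(rows)
        if rows.dtype == bool:
            rows = np.flatnonzero(rows)
        return ExpressionDataset(
            matrix=self.matrix[rows],
            sample_ids=[self.sample_ids[i] for i in rows],
            probe_ids=list(self.probe_ids),
            labels=[self.labels[i] for i in rows],
            class_set=list(self.class_set),
        )

    def equals(self, other: "ExpressionDataset") -> bool:
        return (
            self.sample_ids == other.sample_ids
            and self.probe_ids == other.probe_ids
            and self.labels == other.labels
            and self.class_set == other.class_set
            and np.array_equal(self.matrix, other.matrix)
        )


@dataclass
class ProbeAnnotation:
    """Mapping from probe id to gene identifier (many probes may share a gene)."""

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        for probe, gene in self.mapping.items():
            if not isinstance(gene, str) or not gene:
                raise ValueError(f"probe {probe!r} maps to an empty gene identifier")

    def get(self, probe_id: str) -> str | None:
        return self.mapping.get(probe_id)

    @property
    def genes(self) -> set[str]:
        return set(self.mapping.values())

    def genes_for(self, probe_ids: Iterable[str]) -> list[str]:
        """Mapped genes for the given probes, deduplicated, first occurrence wins."""
        out: list[str] = []
        seen: set[str] = set()
        for p in probe_ids:
            g = self.mapping.get(p)
            if g is not None and g not in seen:
                seen.add(g)
                out.append(g)
        return out


@dataclass(frozen=True)
class GeneSetTerm:
    term_id: str
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"term {self.term_id!r} has an empty gene set")


@dataclass
class AnnotationDatabase:
    """A collection of annotation terms plus the gene universe of the assay.

    The universe (size ``N_G``) is the set of distinct genes the dataset can
    measure, i.e. the image of its probe ids under the probe annotation. It
    is deliberately *not* derived from the GMT file: terms are intersected
    with the universe at test time so the hypergeometric model stays
    coherent when the database mentions genes absent from the chip.
    """

    terms: list[GeneSetTerm]
    universe: frozenset[str] | None = None

    @property
    def n_G(self) -> int:
        if self.universe is None:
            raise ValueError("gene universe not set; call with_universe() first")
        return len(self.universe)

    def with_universe(self, genes: Iterable[str]) -> "AnnotationDatabase":
        return AnnotationDatabase(terms=list(self.terms), universe=frozenset(genes))

    def term(self, term_id: str) -> GeneSetTerm:
        for t in self.terms:
            if t.term_id == term_id:
                return t
        raise KeyError(f"term {term_id!r} not in database")


def gene_universe(dataset: ExpressionDataset, annotation: ProbeAnnotation) -> frozenset[str]:
    """Distinct genes obtained by mapping the dataset's probes; unmapped probes excluded."""
    return frozenset(
        g for g in (annotation.get(p) for p in dataset.probe_ids) if g is not None
    )


# ---------------------------------------------------------------------------
# expression matrices


def read_expression(path: str | Path, label_column: str = "label",
                    class_order: Sequence[str] | None = None) -> ExpressionDataset:
    """Read a TSV expression matrix (samples x probes) with a label column.

    The first column is the sample id; every remaining column except
    ``label_column`` is a probe. The class set (which fixes the output-
    neuron order downstream) is taken from ``class_order`` when given,
    otherwise it is the list of distinct labels in order of first
    appearance.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    columns = header[1:]
    if label_column not in columns:
        raise ValueError(f"label column {label_column!r} not found in {path}")
    _check_unique(columns, "column")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={label_column: str},
                     float_precision="round_trip")
    labels = df[label_column].tolist()
    probes = [c for c in columns if c != label_column]
    values = df[probes]
    non_numeric = values.dtypes.apply(lambda d: not np.issubdtype(d, np.number))
    if non_numeric.any():
        col = values.columns[non_numeric.to_numpy()][0]
        raise ValueError(f"non-numeric expression values in column {col!r}")
    class_set = list(class_order) if class_order is not None \
        else list(dict.fromkeys(labels))
    return ExpressionDataset(
        matrix=values.to_numpy(dtype=float),
        sample_ids=[str(s) for s in df.index],
        probe_ids=probes,
        labels=labels,
        class_set=class_set,
    )


def write_expression(dataset: ExpressionDataset, path: str | Path,
                     label_column: str = "label") -> None:
    df = pd.DataFrame(dataset.matrix, index=dataset.sample_ids, columns=dataset.probe_ids)
    df.insert(0, label_column, dataset.labels)
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", float_format="%.17g")


# ---------------------------------------------------------------------------
# probe maps and GMT gene sets


def read_probe_map(path: str | Path) -> ProbeAnnotation:
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or (lineno == 1 and line == "probe_id\tgene_id"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 fields, got {len(fields)}")
            probe, gene = fields
            if probe in mapping:
                raise ValueError(f"{path}:{lineno}: duplicate probe id {probe!r}")
            mapping[probe] = gene
    return ProbeAnnotation(mapping)


def write_probe_map(annotation: ProbeAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("probe_id\tgene_id\n")
        for probe, gene in annotation.mapping.items():
            fh.write(f"{probe}\t{gene}\n")


def read_gmt(path: str | Path) -> AnnotationDatabase:
    """Read a GMT gene-set file. Duplicate genes within a term are collapsed."""
    terms: list[GeneSetTerm] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            term_id, name = fields[0], fields[1]
            if term_id in seen:
                raise ValueError(f"{path}:{lineno}: duplicate term id {term_id!r}")
            seen.add(term_id)
            genes = frozenset(g for g in fields[2:] if g)
            terms.append(GeneSetTerm(term_id=term_id, name=name, genes=genes))
    return AnnotationDatabase(terms=terms)


def write_gmt(database: AnnotationDatabase, path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in database.terms:
            fh.write("\t".join([t.term_id, t.name, *sorted(t.genes)]) + "\n")


# ---------------------------------------------------------------------------
# model checkpoints


def _npy_bytes(arr: np.ndarray) -> bytes:
    buf = io.BytesIO()
    np.lib.format.write_array(buf, np.ascontiguousarray(arr))
    return buf.getvalue()


def save_checkpoint(network, path: str | Path, metadata: Mapping | None = None) -> None:
    """Serialize a network to a deterministic zip archive of named arrays.

    ``load_checkpoint(save_checkpoint(net))`` reproduces the weights
    bit-exactly, and two saves of the same network produce identical bytes.
    """
    meta = {
        "format": "deeplrp-checkpoint-1",
        "layer_sizes": [int(s) for s in network.layer_sizes],
        "hidden_activation": "relu",
        "output_activation": "softmax",
        "classes": list(network.classes) if network.classes is not None else None,
        "metadata": dict(metadata or {}),
    }
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_STORED) as zf:
        info = zipfile.ZipInfo("meta.json", date_time=_CHECKPOINT_DATE)
        zf.writestr(info, json.dumps(meta, sort_keys=True, indent=1))
        for l, (w, b) in enumerate(zip(network.weights, network.biases)):
            zf.writestr(zipfile.ZipInfo(f"w_{l:03d}.npy", date_time=_CHECKPOINT_DATE),
                        _npy_bytes(np.asarray(w, dtype=np.float64)))
            zf.writestr(zipfile.ZipInfo(f"b_{l:03d}.npy", date_time=_CHECKPOINT_DATE),
                        _npy_bytes(np.asarray(b, dtype=np.float64)))


def load_checkpoint(path: str | Path):
    """Load a checkpoint written by :func:`save_checkpoint`."""
    from .mlp import MLPNetwork  # local import to avoid a cycle

    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("meta.json"))
        sizes = meta["layer_sizes"]
        weights, biases = [], []
        for l in range(len(sizes) - 1):
            w = np.lib.format.read_array(io.BytesIO(zf.read(f"w_{l:03d}.npy")))
            b = np.lib.format.read_array(io.BytesIO(zf.read(f"b_{l:03d}.npy")))
            expect_w = (sizes[l], sizes[l + 1])
            if w.shape != expect_w:
                raise ValueError(
                    f"checkpoint layer {l + 1}: weight shape {w.shape} does not match "
                    f"declared layer sizes {expect_w}"
                )
            if b.shape != (sizes[l + 1],):
                raise ValueError(
                    f"checkpoint layer {l + 1}: bias length {b.shape[0]} != {sizes[l + 1]}"
                )
            weights.append(w)
            biases.append(b)
    return MLPNetwork(
        weights=weights,
        biases=biases,
        classes=meta.get("classes"),
        metadata=meta.get("metadata") or {},
    )
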