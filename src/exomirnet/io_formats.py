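"""Readers and writers for every external artifact the pipeline touches.

Tabular formats are plain TSV (UTF-8, ``.`` decimal, header row); gene sets
use the GMT dialect; sequences use FASTA. All parsers validate their schema
eagerly and never silently drop rows: a malformed line raises with its line
number rather than being skipped.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ExpressionMatrix",
    "DifferentialRecord",
    "GeneSetCollection",
    "read_counts",
    "read_expression",
    "read_differential_table",
    "read_gmt",
    "read_edge_list",
    "read_fasta",
    "write_matrix",
    "write_differential_table",
    "write_gmt",
    "write_edge_list",
    "write_fasta",
    "read_yaml_config",
    "write_json_report",
    "harmonize_gene",
    "harmonize_mirna",
    "normalize_rna",
]

LAYERS = ("exosome_mirna", "tissue_mirna", "mrna", "protein")

#: species prefixes stripped when matching miRNA ids across organisms
_MIRNA_PREFIXES = ("hsa-", "mmu-", "rno-")

_RNA_ALPHABET = set("ACGU")


def harmonize_gene(symbol: str) -> str:
    """Case-insensitive gene-symbol key (upper-cased, stripped)."""
    return symbol.strip().upper()


def harmonize_mirna(mirna_id: str) -> str:
    """miRNA id key: species prefix stripped, lower-cased.

    Exosomal (mouse) and tissue (human) layers use different prefixes for
    the same mature miRNA name; matching is done on the prefix-free name.
    """
    key = mirna_id.strip()
    low = key.lower()
    for pre in _MIRNA_PREFIXES:
        if low.startswith(pre):
            key = key[len(pre):]
            break
    return key.lower()


def normalize_rna(seq: str, *, context: str = "sequence") -> str:
    """Upper-case and convert T->U; reject non-ACGTU characters."""
    s = seq.strip().upper().replace("T", "U")
    bad = set(s) - _RNA_ALPHABET
    if bad:
        raise ValueError(
            f"{context}: non-ACGTU character(s) {sorted(bad)} in sequence"
        )
    return s


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Features x samples numeric matrix with per-sample group labels.

    ``unit`` tracks what the values mean: raw small-RNA counts, reads per
    million (RPM), per-feature Z-scores, or arbitrary expression units from
    a microarray. ``flags`` marks degenerate features (e.g. constant rows
    that could not be Z-scored).
    """

    values: pd.DataFrame
    unit: str = "raw_count"
    group_of: dict[str, str] = field(default_factory=dict)
    flags: dict[str, str] = field(default_factory=dict)

    VALID_UNITS = ("raw_count", "rpm", "zscore", "arbitrary_expression")

    def __post_init__(self) -> None:
        if self.unit not in self.VALID_UNITS:
            raise ValueError(f"unknown unit {self.unit!r}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate feature id(s): {', '.join(map(str, dups))}")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        if self.unit == "raw_count":
            arr = self.values.to_numpy()
            if (arr < 0).any():
                raise ValueError("raw counts must be non-negative")
        if self.group_of:
            missing = [s for s in self.values.columns if s not in self.group_of]
            if missing:
                raise ValueError(f"samples without group label: {missing}")
            unknown = [s for s in self.group_of if s not in set(self.values.columns)]
            if unknown:
                raise ValueError(f"group map names unknown sample(s): {unknown}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.sample_ids if self.group_of.get(s) == group]


@dataclass(frozen=True)
class DifferentialRecord:
    """One feature's differential call in one dataset and omics layer."""

    feature_id: str
    layer: str
    dataset_id: str
    log2fc: float
    p: float | None = None
    q: float | None = None

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}")
        for name, v in (("p", self.p), ("q", self.q)):
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1] for {self.feature_id}")

    @property
    def direction(self) -> str:
        """'up' iff log2fc > 0; exact zeros classify as 'down' (see read_differential_table)."""
        return "up" if self.log2fc > 0 else "down"


@dataclass
class GeneSetCollection:
    """Named gene sets plus the gene universe they live in."""

    sets: dict[str, tuple[str, frozenset[str]]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        for set_id, (_, members) in self.sets.items():
            if not members:
                raise ValueError(f"gene set {set_id!r} is empty")
            stray = members - self.universe
            if stray:
                raise ValueError(
                    f"gene set {set_id!r} has members outside the universe: {sorted(stray)[:5]}"
                )

    @classmethod
    def from_sets(
        cls,
        sets: Mapping[str, tuple[str, Iterable[str]]],
        universe: Iterable[str] | None = None,
    ) -> "GeneSetCollection":
        harmonized = {
            sid: (desc, frozenset(harmonize_gene(g) for g in members))
            for sid, (desc, members) in sets.items()
        }
        if universe is None:
            uni: frozenset[str] = frozenset().union(*(m for _, m in harmonized.values()))
        else:
            uni = frozenset(harmonize_gene(g) for g in universe)
        return cls(sets=harmonized, universe=uni)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=0, dtype=str, keep_default_na=False)


def read_counts(
    path: str | Path,
    group_map: Mapping[str, str] | str | Path,
) -> ExpressionMatrix:
    """Read a raw-count TSV (first column feature ids, header = sample ids).

    ``group_map`` is either a mapping sample_id -> group or a path to a
    two-column TSV (sample_id, group).
    """
    if not isinstance(group_map, Mapping):
        gdf = _read_tsv(group_map)
        if gdf.shape[1] < 2:
            raise ValueError("group sidecar needs two columns: sample_id, group")
        group_map = dict(zip(gdf.iloc[:, 0], gdf.iloc[:, 1]))
    raw = _read_tsv(path)
    feat_col = raw.columns[0]
    features = raw[feat_col].tolist()
    dup = pd.Index(features)[pd.Index(features).duplicated()].unique()
    if len(dup):
        raise ValueError(f"duplicate feature id(s): {', '.join(dup)}")
    samples = list(raw.columns[1:])
    mat = np.empty((len(features), len(samples)), dtype=float)
    for j, col in enumerate(samples):
        for i, cell in enumerate(raw[col]):
            try:
                v = float(cell)
            except ValueError as exc:
                raise ValueError(
                    f"malformed numeric cell at feature {features[i]!r}, sample {col!r}: {cell!r}"
                ) from exc
            if v < 0 or v != int(v):
                raise ValueError(
                    f"raw count must be a non-negative integer at {features[i]!r}/{col!r}: {cell!r}"
                )
            mat[i, j] = v
    values = pd.DataFrame(mat, index=features, columns=samples)
    return ExpressionMatrix(values=values, unit="raw_count", group_of=dict(group_map))


def read_expression(path: str | Path, unit: str = "arbitrary_expression") -> ExpressionMatrix:
    """Read a generic numeric expression TSV (no group labels required)."""
    df = pd.read_csv(path, sep="\t", header=0, index_col=0)
    return ExpressionMatrix(values=df.astype(float), unit=unit)


def read_differential_table(
    path: str | Path, layer: str, dataset_id: str
) -> list[DifferentialRecord]:
    """Read a differential table TSV with columns id, log2fc, p[, q].

    Rows with log2fc exactly 0 classify as 'down' (with a warning): they are
    removed by any |logFC| threshold downstream, so the tie rule only needs
    to be deterministic.
    """
    df = _read_tsv(path)
    cols = {c.lower(): c for c in df.columns}
    for required in ("id", "log2fc"):
        if required not in cols:
            raise ValueError(f"{path}: missing column {required!r}")
    records: list[DifferentialRecord] = []
    n_zero = 0
    for i, row in df.iterrows():
        lfc = float(row[cols["log2fc"]])
        if lfc == 0.0:
            n_zero += 1

        def _opt(name: str) -> float | None:
            if name not in cols:
                return None
            cell = str(row[cols[name]]).strip()
            if cell in ("", "NA", "NaN", "nan"):
                return None
            v = float(cell)
            if not (0.0 <= v <= 1.0):
                raise ValueError(
                    f"{path} line {i + 2}: {name}={v} outside [0, 1]"
                )
            return v

        records.append(
            DifferentialRecord(
                feature_id=str(row[cols["id"]]),
                layer=layer,
                dataset_id=dataset_id,
                log2fc=lfc,
                p=_opt("p"),
                q=_opt("q"),
            )
        )
    if n_zero:
        warnings.warn(
            f"{path}: {n_zero} feature(s) with log2fc == 0 classified as 'down'",
            stacklevel=2,
        )
    return records


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: set_id TAB description TAB member..."""
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path} line {lineno}: gene set has no members")
            sid, desc, members = parts[0], parts[1], [m for m in parts[2:] if m]
            if not members:
                raise ValueError(f"{path} line {lineno}: gene set {sid!r} is empty")
            if sid in sets:
                raise ValueError(f"{path} line {lineno}: duplicate set id {sid!r}")
            sets[sid] = (desc, members)
    return GeneSetCollection.from_sets(sets)


def read_edge_list(path: str | Path) -> list[tuple[str, str, float]]:
    """Read a 2-3 column TSV edge list; a missing weight defaults to 1.0."""
    edges: list[tuple[str, str, float]] = []
    header_names = {"node_a", "node1", "source", "from", "protein1", "gene_a"}
    with open(path, encoding="utf-8") as fh:
        lines = fh.readlines()
    start = 1 if lines and lines[0].split("\t")[0].strip().lower() in header_names else 0
    for lineno, line in enumerate(lines[start:], start=start + 1):
        line = line.rstrip("\n")
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path} line {lineno}: expected 2-3 columns")
        a, b = parts[0], parts[1]
        if a == b:
            raise ValueError(f"{path} line {lineno}: self-loop edge {a!r}")
        w = float(parts[2]) if len(parts) > 2 and parts[2] != "" else 1.0
        if w <= 0:
            raise ValueError(f"{path} line {lineno}: non-positive weight {w}")
        edges.append((a, b, w))
    return edges


def read_fasta(path: str | Path, *, rna: bool = True) -> dict[str, str]:
    """Read FASTA into id -> sequence; uppercased, T->U when ``rna``."""
    seqs: dict[str, str] = {}
    current: str | None = None
    chunks: list[str] = []

    def _flush(lineno: int) -> None:
        if current is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise ValueError(f"{path}: empty record {current!r} before line {lineno}")
        seqs[current] = normalize_rna(seq, context=f"{path} record {current!r}") if rna else seq.upper()

    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush(lineno)
                current = line[1:].split()[0]
                if current in seqs:
                    raise ValueError(f"{path} line {lineno}: duplicate id {current!r}")
                chunks = []
            else:
                if current is None:
                    raise ValueError(f"{path} line {lineno}: sequence before header")
                chunks.append(line)
        _flush(lineno=-1)
    return seqs


def read_yaml_config(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


# ---------------------------------------------------------------------------
# writers (byte-stable given fixed inputs)
# ---------------------------------------------------------------------------

def write_matrix(m: ExpressionMatrix, path: str | Path) -> None:
    df = m.values.copy()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t", float_format="%.10g")


def write_differential_table(records: Sequence[DifferentialRecord], path: str | Path) -> None:
    rows = [
        {
            "id": r.feature_id,
            "log2fc": f"{r.log2fc:.10g}",
            "p": "" if r.p is None else f"{r.p:.10g}",
            "q": "" if r.q is None else f"{r.q:.10g}",
            "direction": r.direction,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=["id", "log2fc", "p", "q", "direction"]).to_csv(
        path, sep="\t", index=False
    )


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sid in sorted(collection.sets):
            desc, members = collection.sets[sid]
            fh.write("\t".join([sid, desc, *sorted(members)]) + "\n")


def write_edge_list(edges: Iterable[tuple[str, str, float]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("node_a\tnode_b\tweight\n")
        for a, b, w in edges:
            fh.write(f"{a}\t{b}\t{w:.10g}\n")


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sid, seq in seqs.items():
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_json_report(report: Mapping, path: str | Path) -> None:
    """JSON with sorted keys and fixed formatting for diffability."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
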