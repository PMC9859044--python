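"""Readers, writers and domain containers for every on-disk format the
pipeline touches: GTF transcript models, FASTA sequences, TSV count
matrices with a sample design, GMT gene sets, undirected edge lists and
generic validated tables.

Coordinates are 1-based inclusive throughout (GTF convention); conversions
happen only at the boundary of whatever library produced them.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

log = logging.getLogger(__name__)

DNA_ALPHABET = frozenset("ACGTN")
MIRNA_LEN_RANGE = (18, 26)

__all__ = [
    "TranscriptModel",
    "ExpressionMatrix",
    "SequenceRecord",
    "GeneSetCollection",
    "read_gtf",
    "write_gtf",
    "read_counts",
    "write_counts",
    "write_design",
    "read_fasta",
    "write_fasta",
    "read_gmt",
    "write_gmt",
    "read_edge_list",
    "write_edge_list",
    "read_table",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class TranscriptModel:
    """Genomic structure of one assembled transcript."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: List[Tuple[int, int]]
    class_code: Optional[str] = None
    biotype_hint: str = "unknown"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.transcript_id}: strand must be + or -, got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript must have >=1 exon")
        self.exons = sorted(tuple(e) for e in self.exons)
        prev_end = 0
        for start, end in self.exons:
            if start > end:
                raise ValueError(f"{self.transcript_id}: exon start {start} > end {end}")
            if start <= prev_end:
                raise ValueError(f"{self.transcript_id}: exons overlap or are unsorted")
            prev_end = end
        if self.biotype_hint not in ("coding", "noncoding", "unknown"):
            raise ValueError(f"bad biotype_hint {self.biotype_hint!r}")

    @property
    def spliced_length(self) -> int:
        return sum(end - start + 1 for start, end in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def span(self) -> Tuple[int, int]:
        """Genomic span (min exon start, max exon end), 1-based inclusive."""
        return self.exons[0][0], self.exons[-1][1]


@dataclass
class SequenceRecord:
    """A DNA-alphabet sequence; RNA input is normalized U->T at ingest."""

    id: str
    seq: str
    moltype: str = "transcript"

    def __post_init__(self) -> None:
        self.seq = self.seq.upper().replace("U", "T")
        if len(self.seq) < 1:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(self.seq) - DNA_ALPHABET
        if bad:
            raise ValueError(f"{self.id}: illegal characters {sorted(bad)!r}")
        if self.moltype not in ("transcript", "utr3", "mirna_mature"):
            raise ValueError(f"bad moltype {self.moltype!r}")
        if self.moltype == "mirna_mature":
            lo, hi = MIRNA_LEN_RANGE
            if not lo <= len(self.seq) <= hi:
                raise ValueError(
                    f"{self.id}: mature miRNA length {len(self.seq)} outside [{lo}, {hi}]"
                )

    def __len__(self) -> int:
        return len(self.seq)


class ExpressionMatrix:
    """Features x samples expression values plus a two-column design.

    ``values`` is a float array even for counts; ``unit`` records whether
    entries are raw counts or FPKM.
    """

    def __init__(
        self,
        feature_ids: Sequence[str],
        sample_ids: Sequence[str],
        values: np.ndarray,
        unit: str = "count",
        design: Optional[Mapping[str, str]] = None,
    ) -> None:
        feature_ids = list(feature_ids)
        sample_ids = list(sample_ids)
        values = np.asarray(values, dtype=float)
        if unit not in ("count", "fpkm"):
            raise ValueError(f"unit must be count or fpkm, got {unit!r}")
        if len(set(feature_ids)) != len(feature_ids):
            dupes = sorted({f for f in feature_ids if feature_ids.count(f) > 1})
            raise ValueError(f"duplicate feature ids: {dupes[:5]}")
        if len(set(sample_ids)) != len(sample_ids):
            raise ValueError("duplicate sample ids")
        if values.shape != (len(feature_ids), len(sample_ids)):
            raise ValueError(
                f"values shape {values.shape} != ({len(feature_ids)}, {len(sample_ids)})"
            )
        if np.any(values < 0) or not np.all(np.isfinite(values)):
            raise ValueError("expression values must be finite and >= 0")
        design = dict(design) if design is not None else {}
        missing = [s for s in sample_ids if s not in design]
        if design and missing:
            raise ValueError(f"samples missing from design: {missing}")
        self.feature_ids = feature_ids
        self.sample_ids = sample_ids
        self.values = values
        self.unit = unit
        self.design = design
        self._findex = {f: i for i, f in enumerate(feature_ids)}

    # -- accessors ---------------------------------------------------------
    @property
    def shape(self) -> Tuple[int, int]:
        return self.values.shape

    def row(self, feature_id: str) -> np.ndarray:
        return self.values[self._findex[feature_id]]

    def groups(self) -> Dict[str, List[str]]:
        out: Dict[str, List[str]] = {}
        for s in self.sample_ids:
            out.setdefault(self.design[s], []).append(s)
        return out

    def group_columns(self, label: str) -> np.ndarray:
        idx = [i for i, s in enumerate(self.sample_ids) if self.design[s] == label]
        if not idx:
            raise KeyError(f"no samples with group label {label!r}")
        return np.asarray(idx)

    def subset(self, feature_ids: Iterable[str]) -> "ExpressionMatrix":
        wanted = [f for f in feature_ids if f in self._findex]
        rows = [self._findex[f] for f in wanted]
        return ExpressionMatrix(
            wanted, self.sample_ids, self.values[rows], unit=self.unit, design=self.design
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self.feature_ids == other.feature_ids
            and self.sample_ids == other.sample_ids
            and self.unit == other.unit
            and self.design == other.design
            and np.array_equal(self.values, other.values)
        )


@dataclass
class GeneSetCollection:
    """set_id -> (display name, member gene ids)."""

    sets: Dict[str, Tuple[str, List[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for set_id, (name, members) in self.sets.items():
            if not members:
                raise ValueError(f"gene set {set_id} is empty")
            if len(set(members)) != len(members):
                raise ValueError(f"gene set {set_id} has duplicate members")

    def __len__(self) -> int:
        return len(self.sets)

    def members(self, set_id: str) -> List[str]:
        return self.sets[set_id][1]

    def items(self):
        return self.sets.items()


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(attr_field: str) -> Dict[str, str]:
    return dict(_ATTR_RE.findall(attr_field))


def read_gtf(path: str | Path) -> List[TranscriptModel]:
    """Parse a GTF2.2-style file into transcript models.

    Exon features are aggregated per ``transcript_id``; a ``class_code``
    attribute (StringTie-merge dialect) is captured when present on any of
    the transcript's lines. Unknown attributes are ignored.
    """
    per_tx: Dict[str, dict] = {}
    order: List[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 tab-separated fields, got {len(fields)}")
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs_s = fields
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            attrs = _parse_attributes(attrs_s)
            tx_id = attrs.get("transcript_id")
            if feature not in ("exon", "transcript"):
                continue
            if tx_id is None:
                raise ValueError(f"{path}:{lineno}: {feature} line without transcript_id")
            gene_id = attrs.get("gene_id", tx_id)
            rec = per_tx.get(tx_id)
            if rec is None:
                rec = {"gene_id": gene_id, "chrom": chrom, "strand": strand,
                       "exons": [], "class_code": None}
                per_tx[tx_id] = rec
                order.append(tx_id)
            if "class_code" in attrs:
                rec["class_code"] = attrs["class_code"]
            if feature == "exon":
                rec["exons"].append((start, end))
            if rec["chrom"] != chrom:
                raise ValueError(f"{path}:{lineno}: transcript {tx_id} spans chromosomes")
    models = []
    for tx_id in order:
        rec = per_tx[tx_id]
        if not rec["exons"]:
            raise ValueError(f"{path}: transcript {tx_id} has no exon lines")
        models.append(
            TranscriptModel(
                transcript_id=tx_id,
                gene_id=rec["gene_id"],
                chrom=rec["chrom"],
                strand=rec["strand"],
                exons=rec["exons"],
                class_code=rec["class_code"],
            )
        )
    return models


def write_gtf(models: Iterable[TranscriptModel], path: str | Path, source: str = "cernanet") -> None:
    with open(path, "w") as fh:
        for m in models:
            attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
            if m.class_code is not None:
                attrs += f' class_code "{m.class_code}";'
            span = m.span
            fh.write("\t".join([m.chrom, source, "transcript", str(span[0]), str(span[1]),
                                ".", m.strand, ".", attrs]) + "\n")
            for start, end in m.exons:
                fh.write("\t".join([m.chrom, source, "exon", str(start), str(end),
                                    ".", m.strand, ".", attrs]) + "\n")


# ---------------------------------------------------------------------------
# counts + design
# ---------------------------------------------------------------------------

def read_counts(path: str | Path, design_path: str | Path) -> ExpressionMatrix:
    """Read a TSV count matrix (first column feature ids, header sample ids)
    plus a two-column sample->group design table."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate feature ids {dupes[:5]}")
    values = df.to_numpy(dtype=float)
    if np.any(values < 0):
        raise ValueError(f"{path}: negative count values")
    if not np.allclose(values, np.round(values)):
        raise ValueError(f"{path}: non-integer count values")
    design_df = pd.read_csv(design_path, sep="\t", dtype=str)
    if design_df.shape[1] < 2:
        raise ValueError(f"{design_path}: design needs sample and group columns")
    design = dict(zip(design_df.iloc[:, 0], design_df.iloc[:, 1]))
    missing = [s for s in df.columns if s not in design]
    if missing:
        raise ValueError(f"samples missing from design: {missing}")
    return ExpressionMatrix(
        list(df.index.astype(str)),
        list(df.columns.astype(str)),
        np.round(values),
        unit="count",
        design={s: design[s] for s in df.columns},
    )


def write_counts(matrix: ExpressionMatrix, path: str | Path) -> None:
    df = matrix.to_frame()
    if matrix.unit == "count":
        df = df.astype(int)
    df.to_csv(path, sep="\t", index_label="feature_id")


def write_design(design: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tgroup\n")
        for sample, group in design.items():
            fh.write(f"{sample}\t{group}\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, moltype: str = "transcript") -> List[SequenceRecord]:
    records: List[SequenceRecord] = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        records.append(SequenceRecord(id=rec.id, seq=str(rec.seq), moltype=moltype))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = [_BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    SeqIO.write(bio, str(path), "fasta")


# ---------------------------------------------------------------------------
# GMT / edge list / generic tables
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> GeneSetCollection:
    sets: Dict[str, Tuple[str, List[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs id, name and >=1 member")
            set_id, name, *members = parts
            members = [m for m in members if m]
            if not members:
                raise ValueError(f"{path}:{lineno}: gene set {set_id} is empty")
            if set_id in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set id {set_id}")
            sets[set_id] = (name, members)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for set_id, (name, members) in collection.items():
            fh.write("\t".join([set_id, name, *members]) + "\n")


def read_edge_list(path: str | Path) -> List[Tuple[str, str]]:
    """Read an undirected 2+-column TSV edge list, dropping self-loops."""
    edges: List[Tuple[str, str]] = []
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: edge line needs >=2 columns")
            a, b = parts[0], parts[1]
            if a == b:
                dropped += 1
                continue
            edges.append((a, b))
    if dropped:
        log.info("dropped %d self-loop edges from %s", dropped, path)
    return edges


def write_edge_list(edges: Iterable[Tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b in edges:
            fh.write(f"{a}\t{b}\n")


def read_table(path: str | Path, schema: Sequence[Tuple[str, type]]) -> List[tuple]:
    """Read a headered TSV, validating the named columns against ``schema``
    (list of ``(column_name, python_type)``). Returns rows as tuples in
    schema order; extra columns are ignored."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    rows: List[tuple] = []
    for name, _typ in schema:
        if name not in df.columns:
            raise ValueError(f"{path}: missing required column {name!r}")
    for i, rec in df.iterrows():
        row = []
        for name, typ in schema:
            raw = rec[name]
            try:
                row.append(typ(raw))
            except (TypeError, ValueError) as exc:
                raise ValueError(
                    f"{path}: row {i + 1}: column {name!r} value {raw!r} is not {typ.__name__}"
                ) from exc
        rows.append(tuple(row))
    return rows
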