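"""Domain types and file I/O for the DE-motif context pipeline.

The pipeline consumes three kinds of files, all plain text:

* a TSV table with columns ``id``, ``label``, ``group`` describing each
  protein;
* a FASTA file with the amino-acid sequences (ids must match the table);
* an optional FASTA-formatted companion file mapping each id to a
  per-residue 3-state secondary-structure string over ``{H, E, C}``.

Coordinates are 0-based half-open internally; every emitted table uses
1-based inclusive positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: residues accepted in protein sequences (X = unknown, neutral imputation)
SEQUENCE_ALPHABET = frozenset(AMINO_ACIDS + "X")
SS_ALPHABET = frozenset("HEC")
LABELS = ("secretory", "non_secretory", "unknown")
GAP_CHARS = frozenset("-.")


class DatasetError(ValueError):
    """Raised when an input file violates the dataset schema."""


@dataclass
class ProteinRecord:
    """One protein: sequence, optional 3-state structure string, label, group."""

    id: str
    sequence: str
    ss_string: str | None = None
    label: str = "unknown"
    group: str = ""

    def validate(self) -> None:
        if not self.id:
            raise DatasetError("empty protein id")
        bad = set(self.sequence) - SEQUENCE_ALPHABET
        if bad:
            raise DatasetError(
                f"record {self.id!r}: invalid residues {sorted(bad)}"
            )
        if self.label not in LABELS:
            raise DatasetError(
                f"record {self.id!r}: label {self.label!r} not in {LABELS}"
            )
        if self.ss_string is not None:
            if len(self.ss_string) != len(self.sequence):
                raise DatasetError(
                    f"record {self.id!r}: ss/sequence length mismatch "
                    f"({len(self.ss_string)} vs {len(self.sequence)})"
                )
            bad_ss = set(self.ss_string) - SS_ALPHABET
            if bad_ss:
                raise DatasetError(
                    f"record {self.id!r}: invalid structure states {sorted(bad_ss)}"
                )

    @property
    def has_de(self) -> bool:
        return "DE" in self.sequence


@dataclass
class Dataset:
    """Ordered collection of validated protein records."""

    records: list[ProteinRecord] = field(default_factory=list)
    provenance: str = ""
    #: count of records dropped by the DE-containing inclusion rule
    n_excluded_no_de: int = 0
    #: planted ground truth when produced by the synthetic generator
    truth: dict | None = None

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            seen, dups = set(), []
            for i in ids:
                if i in seen:
                    dups.append(i)
                seen.add(i)
            raise DatasetError(f"duplicate protein ids: {sorted(set(dups))}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, protein_id: str) -> ProteinRecord:
        for r in self.records:
            if r.id == protein_id:
                return r
        raise KeyError(protein_id)

    def label_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in self.records:
            counts[r.label] = counts.get(r.label, 0) + 1
        return counts

    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.group)
        return list(seen)

    def subset(self, protein_ids: Iterable[str] | None = None,
               group: str | None = None) -> "Dataset":
        keep = list(self.records)
        if protein_ids is not None:
            wanted = set(protein_ids)
            keep = [r for r in keep if r.id in wanted]
        if group is not None:
            keep = [r for r in keep if r.group == group]
        return Dataset(records=keep, provenance=self.provenance)


@dataclass
class MSA:
    """A multiple sequence alignment with uniform row width."""

    ids: list[str]
    rows: list[str]
    truth: dict | None = None

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise DatasetError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise DatasetError("duplicate sequence ids in MSA")
        if self.rows:
            width = len(self.rows[0])
            for sid, row in zip(self.ids, self.rows):
                if len(row) != width:
                    raise DatasetError(
                        f"ragged alignment: sequence {sid!r} has length "
                        f"{len(row)}, expected {width}"
                    )

    @property
    def ncols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def nseq(self) -> int:
        return len(self.rows)


def read_dataset(table_path: str | Path, fasta_path: str | Path,
                 ss_path: str | Path | None = None) -> Dataset:
    """Read the protein table, sequences and optional structure strings.

    Records whose sequence contains no ``DE`` dipeptide are excluded (the
    analysis-set inclusion rule); the exclusion count is logged and stored
    on the returned :class:`Dataset`.
    """
    table = pd.read_csv(table_path, sep="\t", dtype=str).fillna("")
    required = {"id", "label", "group"}
    missing = required - set(table.columns)
    if missing:
        raise DatasetError(f"table missing columns: {sorted(missing)}")
    if table["id"].duplicated().any():
        dups = table.loc[table["id"].duplicated(), "id"].tolist()
        raise DatasetError(f"duplicate protein ids: {sorted(set(dups))}")

    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    ss_map: dict[str, str] = {}
    if ss_path is not None:
        ss_map = {rec.id: str(rec.seq).upper()
                  for rec in SeqIO.parse(str(ss_path), "fasta")}

    records: list[ProteinRecord] = []
    n_no_de = 0
    for row in table.itertuples(index=False):
        pid = row.id
        if pid not in seqs:
            raise DatasetError(f"id {pid!r} in table but not in FASTA")
        rec = ProteinRecord(
            id=pid,
            sequence=seqs[pid],
            ss_string=ss_map.get(pid),
            label=row.label,
            group=row.group,
        )
        rec.validate()
        if not rec.has_de:
            n_no_de += 1
            logger.info("excluding %s: no DE motif", pid)
            continue
        records.append(rec)
    if n_no_de:
        logger.info("excluded %d record(s) without a DE motif", n_no_de)
    return Dataset(records=records,
                   provenance=f"table={table_path} fasta={fasta_path}",
                   n_excluded_no_de=n_no_de)


def read_msa(path: str | Path, format: str = "afa") -> MSA:
    """Read an alignment in aligned-FASTA (``afa``) or ``stockholm`` format.

    Residues are uppercased and ``.`` gaps are normalized to ``-``.
    """
    if format not in ("afa", "stockholm"):
        raise ValueError(f"unsupported MSA format {format!r}")
    bio_format = "fasta" if format == "afa" else "stockholm"
    ids: list[str] = []
    rows: list[str] = []
    for rec in SeqIO.parse(str(path), bio_format):
        ids.append(rec.id)
        rows.append(str(rec.seq).upper().replace(".", "-"))
    return MSA(ids=ids, rows=rows)


def write_msa(msa: MSA, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, row in zip(msa.ids, msa.rows):
            fh.write(f">{sid}\n{row}\n")


MOTIF_TABLE_COLUMNS = ["id", "start_1based", "H", "C", "order_class",
                       "flank_left", "flank_right"]


def write_motif_table(motifs: Sequence, path: str | Path) -> None:
    """Write DE-motif context records as a TSV (1-based inclusive starts).

    Rows are emitted sorted by (id, position) for deterministic output.
    """
    rows = []
    for m in motifs:
        rows.append({
            "id": m.protein_id,
            "start_1based": m.start + 1,
            "H": m.H,
            "C": m.C,
            "order_class": m.order_class if m.order_class is not None else "NA",
            "flank_left": m.n_flank_left,
            "flank_right": m.n_flank_right,
        })
    frame = pd.DataFrame(rows, columns=MOTIF_TABLE_COLUMNS)
    frame = frame.sort_values(["id", "start_1based"], kind="mergesort")
    frame.to_csv(path, sep="\t", index=False)


def read_motif_table(path: str | Path) -> list:
    """Read a motif TSV back into context records (inverse of the writer)."""
    from .context_features import DEMotifContext  # local import: avoid cycle

    frame = pd.read_csv(path, sep="\t")
    out = []
    for row in frame.itertuples(index=False):
        order = None if pd.isna(row.order_class) or row.order_class == "NA" \
            else str(row.order_class)
        out.append(DEMotifContext(
            protein_id=str(row.id),
            start=int(row.start_1based) - 1,
            H=float(row.H),
            C=float(row.C),
            order_class=order,
            n_flank_left=int(row.flank_left),
            n_flank_right=int(row.flank_right),
        ))
    return out
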