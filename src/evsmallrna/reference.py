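"""Compilation of a deduplicated, class-annotated ncRNA reference.

Source databases (miRBase/Ensembl/RFAM/piRNA-cluster style extracts supplied
as FASTA) overlap: the same mature sequence can appear under several
accessions, alphabets (RNA vs DNA, case) and even classes. Exact-match read
counting needs one entry per distinct sequence, so sources are normalized
(uppercase, U→T) and collapsed; the canonical identity/class of a collapsed
entry comes from the highest-priority source, with class conflicts reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from ._io import write_fasta, write_tsv

logger = logging.getLogger(__name__)

RNA_CLASSES = ("miRNA", "snoRNA", "tRNA", "rRNA", "piRNA", "snRNA", "Mt_tRNA", "other")

# Analytic focus is miRNA cargo; ties between conflicting class annotations
# resolve in this order. Fully overridable by the caller.
DEFAULT_CLASS_PRIORITY = ("miRNA", "piRNA", "tRNA", "Mt_tRNA", "snoRNA", "snRNA", "rRNA", "other")

_VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class SourceRecord:
    record_id: str
    sequence: str
    rna_class: str
    source: str
    source_priority: int


@dataclass
class RefEntry:
    canonical_id: str
    sequence: str
    rna_class: str
    source_ids: list[str] = field(default_factory=list)


class ReferenceDB:
    """Unique-sequence ncRNA reference: the exact-match mapping target."""

    def __init__(self, entries: list[RefEntry]):
        self.entries = entries
        self.by_sequence = {e.sequence: e for e in entries}
        self.by_id = {e.canonical_id: e for e in entries}
        if len(self.by_sequence) != len(entries):
            raise ValueError("reference entries must have unique sequences")

    def __len__(self) -> int:
        return len(self.entries)

    def class_of(self, canonical_id: str) -> str:
        return self.by_id[canonical_id].rna_class

    def classmap_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "canonical_id": [e.canonical_id for e in self.entries],
            "rna_class": [e.rna_class for e in self.entries],
            "length": [len(e.sequence) for e in self.entries],
            "source_ids": [";".join(e.source_ids) for e in self.entries],
        })


def normalize_sequence(seq: str) -> str:
    """Uppercase and convert the RNA alphabet to DNA (U→T)."""
    return seq.upper().replace("U", "T")


def load_source_fasta(path: str | Path, rna_class: str, source: str,
                      priority: int) -> tuple[list[SourceRecord], list[str]]:
    """Load one source FASTA; returns (records, rejected record ids).

    Sequences are normalized; records containing ambiguity codes (N, R, ...)
    are rejected because exact 0-mismatch matching is undefined on them.
    """
    if rna_class not in RNA_CLASSES:
        raise ValueError(f"unknown ncRNA class {rna_class!r}; expected one of {RNA_CLASSES}")
    records: list[SourceRecord] = []
    rejected: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = normalize_sequence(str(rec.seq))
        if not seq or set(seq) - _VALID_BASES:
            rejected.append(rec.id)
            logger.warning("rejected record %s from %s (non-ACGT characters)", rec.id, path)
            continue
        records.append(SourceRecord(rec.id, seq, rna_class, source, priority))
    if not records and not rejected:
        logger.warning("source FASTA %s is empty", path)
    return records, rejected


def compile_unique(records: list[SourceRecord],
                   class_priority: tuple[str, ...] = DEFAULT_CLASS_PRIORITY,
                   ) -> tuple[ReferenceDB, pd.DataFrame]:
    """Collapse identical normalized sequences into unique reference entries.

    The canonical id and class of a collapsed entry come from the member
    record with the lowest ``source_priority``; ties break by class priority
    order, then lexicographic record id — so the result is independent of
    input record order. All merged source ids are retained. The second
    return value reports sequences whose member records disagree on class.
    """
    if not records:
        raise ValueError("compile_unique requires at least one source record")
    rank = {c: i for i, c in enumerate(class_priority)}
    groups: dict[str, list[SourceRecord]] = {}
    for rec in records:
        groups.setdefault(rec.sequence, []).append(rec)

    entries: list[RefEntry] = []
    collisions: list[dict] = []
    for seq, members in groups.items():
        best = min(members, key=lambda r: (r.source_priority,
                                           rank.get(r.rna_class, len(rank)),
                                           r.record_id))
        source_ids = sorted({f"{r.source}:{r.record_id}" for r in members})
        entries.append(RefEntry(best.record_id, seq, best.rna_class, source_ids))
        classes = sorted({r.rna_class for r in members})
        if len(classes) > 1:
            collisions.append({"sequence": seq, "classes": ";".join(classes),
                               "chosen_class": best.rna_class,
                               "canonical_id": best.record_id})
    entries.sort(key=lambda e: e.canonical_id)
    report = pd.DataFrame(collisions, columns=["sequence", "classes", "chosen_class",
                                               "canonical_id"])
    return ReferenceDB(entries), report


def write_reference(db: ReferenceDB, fasta_path: str | Path,
                    classmap_path: str | Path, meta: dict | None = None) -> None:
    """Write the canonical FASTA and the TSV class map."""
    write_fasta(((e.canonical_id, e.sequence) for e in db.entries), fasta_path)
    write_tsv(db.classmap_frame(), classmap_path, meta=meta)


def load_reference(fasta_path: str | Path, classmap_path: str | Path) -> ReferenceDB:
    """Round-trip loader for a compiled reference written by :func:`write_reference`."""
    classmap = pd.read_csv(classmap_path, sep="\t", comment="#",
                           dtype={"source_ids": str})
    class_of = dict(zip(classmap.canonical_id, classmap.rna_class))
    srcs = dict(zip(classmap.canonical_id, classmap.source_ids.fillna("")))
    entries = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id not in class_of:
            raise ValueError(f"reference entry {rec.id} missing from class map")
        ids = [s for s in srcs[rec.id].split(";") if s]
        entries.append(RefEntry(rec.id, normalize_sequence(str(rec.seq)),
                                class_of[rec.id], ids))
    return ReferenceDB(entries)
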