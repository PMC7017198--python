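"""Exact-match mapping of curated reads to the unique ncRNA reference.

Matching is 0-mismatch and realized as two containment modes:

* ``read_in_target`` — the whole read is a substring of the reference
  sequence, and the read covers at least half of it;
* ``target_in_read`` — the whole reference sequence is a substring of the
  read, and the read is at most 1.5 times the reference length.

Both boundaries are inclusive and evaluated in integer arithmetic
(``2*len(read) >= len(target)`` and ``2*len(read) <= 3*len(target)``), so
coverage exactly 0.5 and ratio exactly 1.5 are accepted without floating
error. A k-mer postings index provides the candidates; every candidate is
verified base-for-base.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from ._io import write_tsv
from .curation import iter_fastq
from .reference import DEFAULT_CLASS_PRIORITY, ReferenceDB

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class MappingParams:
    min_target_coverage: float = 0.5
    max_read_target_ratio: float = 1.5
    mismatches_allowed: int = 0
    multimap_policy: str = "unique_priority"   # or "fractional"
    strand: str = "sense_only"                 # or "both"
    kmer_size: int = 12
    containment: str = "both"                  # or "read_in_target"

    def __post_init__(self) -> None:
        if self.mismatches_allowed != 0:
            raise ValueError("mapping is exact: mismatches_allowed must be 0")
        if not (0 < self.min_target_coverage <= 1):
            raise ValueError("min_target_coverage must lie in (0, 1]")
        if self.max_read_target_ratio < 1:
            raise ValueError("max_read_target_ratio must be >= 1")
        if self.multimap_policy not in ("unique_priority", "fractional"):
            raise ValueError(f"unknown multimap_policy {self.multimap_policy!r}")
        if self.strand not in ("sense_only", "both"):
            raise ValueError(f"unknown strand mode {self.strand!r}")
        if self.containment not in ("both", "read_in_target"):
            raise ValueError(f"unknown containment mode {self.containment!r}")


@dataclass(frozen=True)
class AlignmentHit:
    read_id: str
    target_id: str
    mode: str            # "read_in_target" | "target_in_read"
    match_start: int     # on the target, 0-based half-open
    match_length: int
    target_coverage: float
    length_ratio: float
    strand: str = "+"


class KmerIndex:
    """k-mer -> (target, offset) postings over the reference sequences."""

    def __init__(self, db: ReferenceDB, params: MappingParams):
        if len(db) == 0:
            raise ValueError("cannot index an empty reference database")
        self.db = db
        self.k = params.kmer_size
        self.params = params
        self.postings: dict[str, list[tuple[str, int]]] = {}
        #: targets shorter than k cannot contribute k-mers; scanned directly
        self.short_targets: list[tuple[str, str]] = []
        self.seq_of: dict[str, str] = {}
        for entry in db.entries:
            seq = entry.sequence
            self.seq_of[entry.canonical_id] = seq
            if len(seq) < self.k:
                self.short_targets.append((entry.canonical_id, seq))
                continue
            for off in range(len(seq) - self.k + 1):
                self.postings.setdefault(seq[off:off + self.k], []).append(
                    (entry.canonical_id, off))

    def n_postings(self) -> int:
        return sum(len(v) for v in self.postings.values())


def build_index(db: ReferenceDB, params: MappingParams | None = None) -> KmerIndex:
    return KmerIndex(db, params or MappingParams())


def _accepts(params: MappingParams, read_len: int, target_len: int, match_len: int) -> bool:
    """The acceptance predicate shared by both containment modes."""
    cov_num = 2 if params.min_target_coverage == 0.5 else None
    if cov_num is not None:
        cov_ok = cov_num * match_len >= target_len
    else:
        cov_ok = match_len / target_len >= params.min_target_coverage - 1e-12
    if params.max_read_target_ratio == 1.5:
        ratio_ok = 2 * read_len <= 3 * target_len
    else:
        ratio_ok = read_len / target_len <= params.max_read_target_ratio + 1e-12
    return cov_ok and ratio_ok


def _map_oriented(seq: str, read_id: str, index: KmerIndex, params: MappingParams,
                  strand: str) -> dict[str, AlignmentHit]:
    k = index.k
    n = len(seq)
    hits: dict[str, AlignmentHit] = {}

    def add(target_id: str, mode: str, start: int, match_len: int, target_len: int) -> None:
        if target_id in hits:
            return
        hits[target_id] = AlignmentHit(
            read_id, target_id, mode, start, match_len,
            target_coverage=match_len / target_len,
            length_ratio=n / target_len, strand=strand)

    if n >= k:
        # read contained in target: anchor with the read's first k-mer
        for target_id, off in index.postings.get(seq[:k], ()):
            tseq = index.seq_of[target_id]
            if tseq[off:off + n] == seq and _accepts(params, n, len(tseq), n):
                add(target_id, "read_in_target", off, n, len(tseq))
        if params.containment == "both":
            # target contained in read: a target starts wherever one of the
            # read's k-mers is that target's first k-mer
            for i in range(n - k + 1):
                for target_id, off in index.postings.get(seq[i:i + k], ()):
                    if off != 0 or target_id in hits:
                        continue
                    tseq = index.seq_of[target_id]
                    tl = len(tseq)
                    if tl <= n and seq[i:i + tl] == tseq and _accepts(params, n, tl, tl):
                        add(target_id, "target_in_read", 0, tl, tl)
            for target_id, tseq in index.short_targets:
                if len(tseq) <= n and tseq in seq and _accepts(params, n, len(tseq), len(tseq)):
                    add(target_id, "target_in_read", 0, len(tseq), len(tseq))
    else:
        # read shorter than k: fall back to a direct scan (rare; curation's
        # min_length normally exceeds the k-mer size)
        for entry in index.db.entries:
            tseq = entry.sequence
            if n <= len(tseq) and seq in tseq and _accepts(params, n, len(tseq), n):
                add(entry.canonical_id, "read_in_target", tseq.index(seq), n, len(tseq))
            elif (params.containment == "both" and len(tseq) < n and tseq in seq
                  and _accepts(params, n, len(tseq), len(tseq))):
                add(entry.canonical_id, "target_in_read", 0, len(tseq), len(tseq))
    return hits


def map_read(seq: str, index: KmerIndex, params: MappingParams,
             read_id: str = "read") -> list[AlignmentHit]:
    """All accepted alignment hits of one curated read (empty list = unmapped)."""
    hits = _map_oriented(seq, read_id, index, params, "+")
    if params.strand == "both":
        for tid, hit in _map_oriented(reverse_complement(seq), read_id, index,
                                      params, "-").items():
            hits.setdefault(tid, hit)
    return sorted(hits.values(), key=lambda h: h.target_id)


def resolve_multimap(hits: list[AlignmentHit], params: MappingParams,
                     class_priority: tuple[str, ...] = DEFAULT_CLASS_PRIORITY,
                     class_of: Mapping[str, str] | None = None):
    """Resolve a read's hits to an assignment.

    ``unique_priority`` picks one target by (longest match, highest target
    coverage, class priority, lexicographically smallest id) and returns the
    winning hit; ``fractional`` returns ``[(hit, 1/n_hits), ...]``.
    """
    if not hits:
        raise ValueError("resolve_multimap requires at least one hit")
    if params.multimap_policy == "fractional":
        w = 1.0 / len(hits)
        return [(h, w) for h in hits]
    rank = {c: i for i, c in enumerate(class_priority)}
    class_of = class_of or {}

    def key(h: AlignmentHit):
        return (-h.match_length, -h.target_coverage,
                rank.get(class_of.get(h.target_id, "other"), len(rank)), h.target_id)

    return min(hits, key=key)


def count_samples(sample_fastqs: Mapping[str, str | Path], db: ReferenceDB,
                  params: MappingParams | None = None,
                  class_priority: tuple[str, ...] = DEFAULT_CLASS_PRIORITY,
                  assignments_path: str | Path | None = None,
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Map each sample's curated FASTQ and build the feature x sample counts.

    Returns ``(counts, report)``: integer counts under ``unique_priority``
    (real-valued under ``fractional``) and a per-sample mapping report with
    total / mapped / unmapped / ambiguous read counts plus per-class
    ambiguity tallies.
    """
    params = params or MappingParams()
    if len(set(sample_fastqs)) != len(list(sample_fastqs)):
        raise ValueError("sample name collision in input FASTQ mapping")
    index = build_index(db, params)
    class_of = {e.canonical_id: e.rna_class for e in db.entries}
    feature_ids = [e.canonical_id for e in db.entries]
    counts = pd.DataFrame(0.0, index=pd.Index(feature_ids, name="feature_id"),
                          columns=list(sample_fastqs))
    report_rows = []
    assign_fh = open(assignments_path, "w") if assignments_path else None
    if assign_fh:
        assign_fh.write("sample\tread_id\ttarget_id\tmode\tmatch_start\tmatch_length\n")
    try:
        for sample, path in sample_fastqs.items():
            n_total = n_mapped = n_ambig = 0
            ambig_by_class: dict[str, int] = {}
            col = counts[sample].to_dict()
            for read_id, seq, _qual in iter_fastq(path):
                n_total += 1
                hits = map_read(seq, index, params, read_id)
                if not hits:
                    continue
                n_mapped += 1
                if len(hits) > 1:
                    n_ambig += 1
                    for h in hits:
                        cls = class_of[h.target_id]
                        ambig_by_class[cls] = ambig_by_class.get(cls, 0) + 1
                if params.multimap_policy == "fractional":
                    for h, w in resolve_multimap(hits, params, class_priority, class_of):
                        col[h.target_id] += w
                else:
                    best = resolve_multimap(hits, params, class_priority, class_of)
                    col[best.target_id] += 1
                    if assign_fh:
                        assign_fh.write(f"{sample}\t{read_id}\t{best.target_id}\t"
                                        f"{best.mode}\t{best.match_start}\t"
                                        f"{best.match_length}\n")
            counts[sample] = pd.Series(col)
            report_rows.append({
                "sample": sample, "n_reads": n_total, "mapped": n_mapped,
                "unmapped": n_total - n_mapped, "ambiguous": n_ambig,
                "ambiguous_by_class": ";".join(
                    f"{c}={n}" for c, n in sorted(ambig_by_class.items()))})
    finally:
        if assign_fh:
            assign_fh.close()
    if params.multimap_policy == "unique_priority":
        counts = counts.astype(int)
    report = pd.DataFrame(report_rows)
    return counts, report


def write_counts(counts: pd.DataFrame, path: str | Path, meta: dict | None = None) -> None:
    write_tsv(counts.reset_index(), path, meta=meta)
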