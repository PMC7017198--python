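"""Read curation: 3' adapter clipping, poly-A trimming, artifact and quality
filtering, and length gating, with per-step accounting.

Trimming (adapter clip and poly-A trim) is iterated to a fixpoint before any
filter runs: removing a poly-A tail can expose a fresh adapter-prefix suffix
and vice versa, and evaluating filters on the final retained bases makes the
whole step idempotent — re-curating curated output is a no-op. All matching
is exact; reads carrying sequencing errors would not survive the 0-mismatch
mapping stage anyway.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ._io import write_tsv

DROP_REASONS = ("quality", "artifact", "too_short")


class FastqParseError(ValueError):
    """Malformed or truncated FASTQ input."""


@dataclass
class CurationParams:
    adapter: str = ""
    min_adapter_overlap: int = 3
    quality_threshold: int = 20
    quality_min_fraction: float = 0.8
    artifact_max_mono_fraction: float = 0.8
    polya_min_run: int = 5
    min_length: int = 15
    max_length: int | None = None  # raw reads never exceed their cycle count

    def __post_init__(self) -> None:
        if not (0 < self.quality_min_fraction <= 1 and 0 < self.artifact_max_mono_fraction <= 1):
            raise ValueError("fractions must lie in (0, 1]")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if set(self.adapter) - set("ACGT"):
            raise ValueError(f"adapter contains non-ACGT characters: {self.adapter!r}")


@dataclass
class CuratedRead:
    read_id: str
    sequence: str
    quality: str
    adapter_clipped: bool = False
    polya_trimmed: bool = False
    dropped_reason: str = "none"

    @property
    def retained(self) -> bool:
        return self.dropped_reason == "none"


def adapter_clip_index(seq: str, adapter: str, min_overlap: int) -> int | None:
    """Leftmost position where an adapter prefix of length >= min_overlap
    matches through the read's 3' end (or a full adapter occurs internally).

    Returns the cut index, or None when no match exists. A full internal
    occurrence is the special case where the remaining read is longer than
    the adapter; everything 3' of the match start is discarded either way.
    """
    if not adapter:
        return None
    n, alen = len(seq), len(adapter)
    need = min(min_overlap, alen)
    for i in range(n - need + 1):
        span = min(alen, n - i)
        if seq[i:i + span] == adapter[:span]:
            return i
    return None


def clip_adapter(seq: str, params: CurationParams) -> str:
    """Single-pass 3' adapter clip (exact matching only)."""
    cut = adapter_clip_index(seq, params.adapter, params.min_adapter_overlap)
    return seq if cut is None else seq[:cut]


def polya_trim_index(seq: str, min_run: int) -> int | None:
    """Start of a terminal poly-A run of length >= min_run, else None."""
    n = len(seq)
    i = n
    while i > 0 and seq[i - 1] == "A":
        i -= 1
    return i if n - i >= min_run else None


def trim_polya(seq: str, params: CurationParams) -> str:
    cut = polya_trim_index(seq, params.polya_min_run)
    return seq if cut is None else seq[:cut]


def passes_quality(qual: str, params: CurationParams) -> bool:
    """Keep iff the fraction of bases at or above the Phred threshold is at
    least ``quality_min_fraction`` (inclusive boundary). Vacuously true for
    empty reads (they drop as too_short instead)."""
    if not qual:
        return True
    good = sum(1 for c in qual if ord(c) - 33 >= params.quality_threshold)
    return good / len(qual) >= params.quality_min_fraction


def passes_artifact(seq: str, params: CurationParams) -> bool:
    """Drop iff a single base makes up more than ``artifact_max_mono_fraction``."""
    if not seq:
        return True
    top = max(seq.count(b) for b in "ACGT")
    return top / len(seq) <= params.artifact_max_mono_fraction


def curate_read(read_id: str, seq: str, qual: str, params: CurationParams) -> CuratedRead:
    """Apply fixpoint trimming then the filters to one read."""
    if len(seq) != len(qual):
        raise FastqParseError(
            f"read {read_id}: sequence length {len(seq)} != quality length {len(qual)}")
    adapter_clipped = polya_trimmed = False
    while True:
        cut = adapter_clip_index(seq, params.adapter, params.min_adapter_overlap)
        if cut is not None:
            seq, qual = seq[:cut], qual[:cut]
            adapter_clipped = True
            continue
        cut = polya_trim_index(seq, params.polya_min_run)
        if cut is not None:
            seq, qual = seq[:cut], qual[:cut]
            polya_trimmed = True
            continue
        break
    read = CuratedRead(read_id, seq, qual, adapter_clipped, polya_trimmed)
    if not passes_quality(qual, params):
        read.dropped_reason = "quality"
    elif not passes_artifact(seq, params):
        read.dropped_reason = "artifact"
    elif len(seq) < params.min_length or (params.max_length is not None
                                          and len(seq) > params.max_length):
        read.dropped_reason = "too_short"
    return read


@dataclass
class CurationReport:
    n_input: int = 0
    n_output: int = 0
    n_adapter_clipped: int = 0
    n_polya_trimmed: int = 0
    drops: dict[str, int] = field(default_factory=lambda: {r: 0 for r in DROP_REASONS})

    def conserves(self) -> bool:
        return self.n_input == self.n_output + sum(self.drops.values())

    def to_frame(self) -> pd.DataFrame:
        row = {"n_input": self.n_input, "n_output": self.n_output,
               "n_adapter_clipped": self.n_adapter_clipped,
               "n_polya_trimmed": self.n_polya_trimmed}
        row.update({f"dropped_{k}": v for k, v in self.drops.items()})
        return pd.DataFrame([row])


def iter_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (read_id, sequence, quality) from a Phred+33 FASTQ file."""
    try:
        with open(path) as fh:
            record = 0
            for title, seq, qual in FastqGeneralIterator(fh):
                record += 1
                yield title.split()[0], seq, qual
    except ValueError as exc:
        raise FastqParseError(
            f"{path}: malformed FASTQ near record {record + 1} "
            f"(approx. line {record * 4 + 1}): {exc}") from exc


def curate_reads(reads: Iterable[tuple[str, str, str]],
                 params: CurationParams) -> tuple[list[CuratedRead], CurationReport]:
    report = CurationReport()
    kept: list[CuratedRead] = []
    for read_id, seq, qual in reads:
        report.n_input += 1
        cur = curate_read(read_id, seq, qual, params)
        report.n_adapter_clipped += cur.adapter_clipped
        report.n_polya_trimmed += cur.polya_trimmed
        if cur.retained:
            report.n_output += 1
            kept.append(cur)
        else:
            report.drops[cur.dropped_reason] += 1
    return kept, report


def curate(fastq_in: str | Path, fastq_out: str | Path, params: CurationParams,
           report_path: str | Path | None = None,
           meta: dict | None = None) -> CurationReport:
    """Curate a FASTQ file; write retained reads and the accounting report.

    Counts conserve exactly: n_input == n_output + sum of per-reason drops.
    """
    fastq_out = Path(fastq_out)
    fastq_out.parent.mkdir(parents=True, exist_ok=True)
    report = CurationReport()
    with open(fastq_out, "w") as out:
        for read_id, seq, qual in iter_fastq(fastq_in):
            report.n_input += 1
            cur = curate_read(read_id, seq, qual, params)
            report.n_adapter_clipped += cur.adapter_clipped
            report.n_polya_trimmed += cur.polya_trimmed
            if cur.retained:
                report.n_output += 1
                out.write(f"@{cur.read_id}\n{cur.sequence}\n+\n{cur.quality}\n")
            else:
                report.drops[cur.dropped_reason] += 1
    if report_path is not None:
        header = {"quality_threshold": params.quality_threshold,
                  "quality_min_fraction": params.quality_min_fraction,
                  "artifact_max_mono_fraction": params.artifact_max_mono_fraction,
                  "polya_min_run": params.polya_min_run,
                  "min_length": params.min_length,
                  "adapter": params.adapter or "(none)"}
        header.update(meta or {})
        write_tsv(report.to_frame(), report_path, meta=header)
    return report
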