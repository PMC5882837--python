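"""Raw small-RNA read processing: demultiplex -> trim -> filter -> collapse
-> quantify.

Multiplexed libraries are told apart by the first 11 nucleotides of the 3'
adapter (a per-library barcode); reads are trimmed at the leftmost exact
occurrence of the adapter prefix, short inserts are discarded, duplicates
are collapsed into unique sequences with multiplicities, and unique
sequences are assigned to mature miRNAs by exact match with a +/-2-nt
3'-end isomiR tolerance. Every stage conserves reads: assigned plus
undetermined plus discarded equals the input count.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .simulate import ConfigurationError, MiRNAReference, ReferenceError, _check_barcodes

__all__ = [
    "ReadBatch",
    "CollapsedSet",
    "UNDETERMINED",
    "demultiplex",
    "trim_adapter",
    "filter_and_collapse",
    "quantify",
    "process_library",
    "read_fastq",
]

UNDETERMINED = "undetermined"

#: adapter prefix length used for matching (first k nt, k = min(10, len))
_ADAPTER_K = 10


@dataclass
class ReadBatch:
    """FASTQ records, optionally labelled with their source library."""

    records: list[tuple[str, str, str]]
    library: str | None = None

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class CollapsedSet:
    """Unique surviving sequences with multiplicities."""

    multiplicity: dict[str, int]
    n_reads: int = 0
    n_discarded_short: int = 0

    def __post_init__(self):
        assert sum(self.multiplicity.values()) + self.n_discarded_short == self.n_reads


def read_fastq(path) -> ReadBatch:
    """Plain or gzipped 4-line FASTQ."""
    opener = gzip.open if str(path).endswith(".gz") else open
    records = []
    with opener(path, "rt") as fh:
        while True:
            head = fh.readline()
            if not head:
                break
            seq = fh.readline().strip()
            fh.readline()
            qual = fh.readline().strip()
            records.append((head.strip().lstrip("@"), seq, qual))
    return ReadBatch(records)


def demultiplex(
    reads: ReadBatch, barcodes: Mapping[str, str], adapter3: str
) -> dict[str, ReadBatch]:
    """Assign each read to the library whose 11-nt barcode occurs in it.

    The barcode is the start of the read's 3'-adapter region, so the
    leftmost barcode occurrence marks the insert/adapter boundary; when
    several libraries' barcodes occur, the earliest occurrence wins
    (distinct same-length barcodes cannot tie). Reads matching no barcode
    go to the ``"undetermined"`` bin; the output is a partition of the
    input.
    """
    _check_barcodes(barcodes)
    if UNDETERMINED in barcodes:
        raise ConfigurationError(f"{UNDETERMINED!r} is a reserved library name")
    out: dict[str, ReadBatch] = {lib: ReadBatch([], library=lib) for lib in barcodes}
    out[UNDETERMINED] = ReadBatch([], library=UNDETERMINED)
    for rec in reads.records:
        seq = rec[1]
        best_lib, best_pos = None, None
        for lib, bc in barcodes.items():
            pos = seq.find(bc)
            if pos != -1 and (best_pos is None or pos < best_pos):
                best_lib, best_pos = lib, pos
        out[best_lib if best_lib is not None else UNDETERMINED].records.append(rec)
    return out


def trim_adapter(sequence: str, adapter3: str) -> tuple[str, bool]:
    """Return (insert, trimmed_flag).

    The insert is the prefix preceding the leftmost exact occurrence of the
    first ``min(10, len(adapter3))`` nt of the adapter; a read without a
    match is returned unchanged and flagged untrimmed. Trimming an
    already-trimmed insert is a no-op (the adapter prefix is gone).
    """
    if len(adapter3) < 8:
        raise ConfigurationError("adapter must be at least 8 nt")
    key = adapter3[: min(_ADAPTER_K, len(adapter3))]
    pos = sequence.find(key)
    if pos == -1:
        return sequence, False
    return sequence[:pos], True


def filter_and_collapse(inserts: Iterable[str], min_len: int = 16) -> CollapsedSet:
    """Discard inserts shorter than ``min_len`` and collapse duplicates."""
    counts: Counter[str] = Counter()
    n = 0
    short = 0
    for ins in inserts:
        n += 1
        if len(ins) < min_len:
            short += 1
        else:
            counts[ins] += 1
    return CollapsedSet(dict(counts), n_reads=n, n_discarded_short=short)


def _assignment_index(reference: MiRNAReference) -> dict[str, set[str]]:
    """sequence-form -> mature names; forms are the mature sequence and its
    1- and 2-nt 3'-truncations (the isomiR tolerance)."""
    index: dict[str, set[str]] = {}
    for name, seq in reference.sequences.items():
        for form in (seq, seq[:-1], seq[:-2]):
            index.setdefault(form, set()).add(name)
    return index


def quantify(
    collapsed: CollapsedSet, reference: MiRNAReference
) -> tuple[pd.Series, int]:
    """Per-mature raw counts from a collapsed set.

    A unique sequence contributes its multiplicity to a mature miRNA iff it
    equals the mature sequence or is a 3'-end variant shifted by at most
    2 nt (either end trimmed or extended). Sequences matching no mature are
    tallied as unassigned; a sequence matching several matures indicates a
    malformed reference and raises.
    Returns ``(profile, n_unassigned)``.
    """
    index = _assignment_index(reference)
    profile = pd.Series(0, index=pd.Index(reference.matures, name="miRNA"), dtype="int64")
    unassigned = 0
    for seq, mult in collapsed.multiplicity.items():
        candidates: set[str] = set()
        # read equal to, or 3'-extended version of, a mature (query trimmed)
        for form in (seq, seq[:-1], seq[:-2]):
            candidates |= index.get(form, set())
        if len(candidates) > 1:
            raise ReferenceError(
                f"sequence assigns ambiguously to {sorted(candidates)}"
            )
        if candidates:
            profile[candidates.pop()] += mult
        else:
            unassigned += mult
    return profile, unassigned


@dataclass
class LibraryAccounting:
    """Stage-by-stage read accounting for one library."""

    library: str
    n_input: int = 0
    n_untrimmed: int = 0
    n_discarded_short: int = 0
    n_unique: int = 0
    n_assigned: int = 0
    n_unassigned: int = 0
    notes: list[str] = field(default_factory=list)


def process_library(
    batch: ReadBatch,
    reference: MiRNAReference,
    adapter3: str,
    min_len: int = 16,
) -> tuple[pd.Series, LibraryAccounting]:
    """Trim, filter, collapse and quantify one demultiplexed library.

    ``adapter3`` must be the library's full 3' adapter, i.e. its barcode
    followed by the common adapter tail, so that trimming removes both.
    """
    acc = LibraryAccounting(library=batch.library or "?", n_input=len(batch))
    inserts = []
    for _, seq, _ in batch.records:
        ins, trimmed = trim_adapter(seq, adapter3)
        if not trimmed:
            acc.n_untrimmed += 1
        inserts.append(ins)
    collapsed = filter_and_collapse(inserts, min_len=min_len)
    acc.n_discarded_short = collapsed.n_discarded_short
    acc.n_unique = len(collapsed.multiplicity)
    profile, unassigned = quantify(collapsed, reference)
    acc.n_assigned = int(profile.sum())
    acc.n_unassigned = unassigned
    assert acc.n_assigned + acc.n_unassigned + acc.n_discarded_short == acc.n_input
    return profile, acc
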