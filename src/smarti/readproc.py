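"""FASTQ read processing: adapter/UMI trimming, anchored alignment, and
cleaved/full-length classification by 3' terminus.

The library contains only point substitutions, so alignment is an anchored,
ungapped, substitution-only comparison of the trimmed insert against the
equal-length reference prefix — exact and deterministic for this read
structure. Reads requiring gaps (length beyond the reference) are discarded.
A read is *cleaved* when its insert ends exactly at the cleavage position
and *full-length* when it ends at the following position or later; shorter
termini (e.g. degradation products) are discarded. Quality scores are
ignored; no quality filtering is part of the protocol.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .reference import RNA_ALPHABET, ReferenceConstruct, VariantKey, variant_label
from .simulate import AdapterSpec

DISCARD_REASONS = ("no_adapter", "unalignable", "too_many_mutations", "short_terminus")

_DNA2RNA = str.maketrans("Tt", "Uu")


@dataclass(frozen=True)
class ReadRecord:
    """One processed read: trimmed insert identity plus classification."""

    read_id: str
    insert: str
    umi: str
    terminus: int | None
    substitutions: tuple[tuple[int, str, str], ...]
    status: str  # cleaved | full_length | discarded
    discard_reason: str | None = None


def trim_read(raw_sequence: str, adapter: AdapterSpec) -> tuple[str, str] | None:
    """Split a raw read into (insert, UMI) at the suffix-anchored adapter.

    The adapter constant must terminate the read; the ``umi_length`` bases
    immediately 5' of it form the UMI and everything upstream is the insert.
    Returns ``None`` when the adapter (or a complete UMI) is absent. Because
    the match is anchored at the 3' end, an extra occurrence of the constant
    inside the insert never truncates it — the rightmost occurrence wins.
    """
    raw = raw_sequence.upper().translate(_DNA2RNA)
    constant = adapter.constant.upper().translate(_DNA2RNA)
    if not raw.endswith(constant):
        return None
    stem = raw[: len(raw) - len(constant)]
    if len(stem) < adapter.umi_length:
        return None
    return stem[: len(stem) - adapter.umi_length], stem[len(stem) - adapter.umi_length :]


def align_insert(
    insert: str, reference: ReferenceConstruct
) -> tuple[int, tuple[tuple[int, str, str], ...]] | None:
    """Anchored ungapped alignment of an insert to the reference prefix.

    The insert is compared base-by-base against the reference prefix of
    equal length starting at the construct's first base; the terminus is the
    genomic coordinate of the insert's last base and every mismatch is a
    substitution. Returns ``None`` (unalignable) for empty inserts, inserts
    longer than the reference, or inserts with non-ACGU characters.
    """
    insert = insert.upper().translate(_DNA2RNA)
    n = len(insert)
    if n == 0 or n > len(reference.sequence):
        return None
    if not set(insert) <= RNA_ALPHABET:
        return None
    terminus = reference.genomic_offset + n - 1
    prefix = reference.sequence[:n]
    if insert == prefix:
        return terminus, ()
    a = np.frombuffer(insert.encode(), dtype=np.uint8)
    b = np.frombuffer(prefix.encode(), dtype=np.uint8)
    subs = tuple(
        (reference.genomic_offset + int(i), prefix[int(i)], insert[int(i)])
        for i in np.flatnonzero(a != b)
    )
    return terminus, subs


def classify_read(terminus: int, cleavage_position: int) -> str | None:
    """``cleaved`` iff the read ends exactly at the cleavage position,
    ``full_length`` iff it ends at the next position or later, otherwise
    ``None`` (discard as short_terminus)."""
    if terminus == cleavage_position:
        return "cleaved"
    if terminus >= cleavage_position + 1:
        return "full_length"
    return None


def call_variant(
    substitutions: tuple[tuple[int, str, str], ...], max_mutations: int = 2
) -> VariantKey | None:
    """Map a read's substitution set to a variant; ``None`` when it carries
    more than ``max_mutations`` substitutions. Substitutions outside the
    mutagenized intervals still count toward the limit."""
    if len(substitutions) > max_mutations:
        return None
    return VariantKey(substitutions)


@dataclass
class ProcessResult:
    """Aggregate result of processing one FASTQ sample."""

    counts: pd.DataFrame  # columns: variant, status, n (non-discarded reads)
    discards: dict[str, int]
    n_reads: int
    n_collapsed: int = 0  # UMI duplicates removed (dedup mode only)
    records: pd.DataFrame | None = None

    @property
    def n_kept(self) -> int:
        return int(self.counts["n"].sum()) if len(self.counts) else 0


def process_fastq(
    fastq_path,
    reference: ReferenceConstruct,
    adapter: AdapterSpec | None = None,
    max_mutations: int = 2,
    keep_records: bool = False,
    dedup_umi: bool = False,
    records_tsv=None,
) -> ProcessResult:
    """Process one demultiplexed FASTQ file end to end.

    Every read lands in exactly one of cleaved / full_length / discarded and
    the three counts sum to the input count. With ``dedup_umi`` (off by
    default), reads identical in (UMI, terminus, variant) within the sample
    are collapsed to one.
    """
    adapter = adapter or AdapterSpec()
    cache: dict[str, tuple] = {}
    counts: dict[tuple[str, str], int] = {}
    discards = {reason: 0 for reason in DISCARD_REASONS}
    seen: set[tuple] = set()
    records: list[tuple] = []
    n_reads = 0
    n_collapsed = 0

    rec_fh = open(records_tsv, "w") if records_tsv is not None else None
    if rec_fh:
        rec_fh.write("read_id\tvariant\tstatus\tterminus\tumi\tdiscard_reason\n")

    with open(fastq_path) as fh:
        for read_id, seq, _qual in FastqGeneralIterator(fh):
            n_reads += 1
            trimmed = trim_read(seq, adapter)
            if trimmed is None:
                insert, umi = "", ""
                outcome = ("discarded", "", None, "no_adapter")
            else:
                insert, umi = trimmed
                outcome = cache.get(insert)
                if outcome is None:
                    outcome = _classify_insert(insert, reference, max_mutations)
                    cache[insert] = outcome
            status, label, terminus, reason = outcome
            if status != "discarded" and dedup_umi:
                key = (umi, terminus, label)
                if key in seen:
                    n_collapsed += 1
                    continue
                seen.add(key)
            if status == "discarded":
                discards[reason] += 1
            else:
                counts[(label, status)] = counts.get((label, status), 0) + 1
            if keep_records or rec_fh:
                row = (read_id, label, status, terminus, umi, reason)
                if keep_records:
                    records.append(row)
                if rec_fh:
                    rec_fh.write(
                        "\t".join("" if v is None else str(v) for v in row) + "\n"
                    )
    if rec_fh:
        rec_fh.close()

    counts_df = pd.DataFrame(
        [{"variant": v, "status": s, "n": n} for (v, s), n in sorted(counts.items())],
        columns=["variant", "status", "n"],
    )
    records_df = None
    if keep_records:
        records_df = pd.DataFrame(
            records,
            columns=["read_id", "variant", "status", "terminus", "umi", "discard_reason"],
        )
    return ProcessResult(
        counts=counts_df,
        discards=discards,
        n_reads=n_reads,
        n_collapsed=n_collapsed,
        records=records_df,
    )


def _classify_insert(
    insert: str, reference: ReferenceConstruct, max_mutations: int
) -> tuple[str, str, int | None, str | None]:
    """(status, variant label, terminus, discard_reason) for one insert."""
    aligned = align_insert(insert, reference)
    if aligned is None:
        return ("discarded", "", None, "unalignable")
    terminus, subs = aligned
    status = classify_read(terminus, reference.cleavage_position)
    if status is None:
        return ("discarded", "", terminus, "short_terminus")
    variant = call_variant(subs, max_mutations)
    if variant is None:
        return ("discarded", "", terminus, "too_many_mutations")
    return (status, variant_label(variant, reference), terminus, None)
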