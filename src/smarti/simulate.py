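"""Synthetic SMARTI data generator.

Emulates the forward process of the RelE-cleavage ribosome-loading assay:
doped-oligonucleotide mutagenesis over the library intervals, per-variant
one-phase association loading kinetics, endonucleolytic cleavage that
truncates the RNA exactly at the cleavage position, and ligation of a 3'
adapter carrying a 5-nt random UMI. Output is demultiplexed per-timepoint
FASTQ (DNA alphabet, Phred+33) plus aggregate truth tables.

Reads are emitted as single full-insert sense-strand sequences; paired-end
merging of the real protocol is out of scope because the analysis depends
only on insert identity and the 3' terminus. Sequencing errors default to
zero and can be switched on to exercise the downstream mutation-count
filter.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reference import (
    _ALTERNATIVES,
    LibraryDesign,
    ReferenceConstruct,
    VariantKey,
    positions_of,
    variant_label,
)

DEFAULT_ADAPTER_CONSTANT = "CTGTAGGCACCATCAAT"
DEFAULT_TIMEPOINTS = (0.0, 2.0, 5.0, 10.0, 20.0, 30.0, 60.0)

_DNA = b"ACGT"
_RNA2DNA = bytes.maketrans(b"U", b"T")


@dataclass(frozen=True)
class KineticTruth:
    """Ground-truth one-phase association parameters for one variant.

    Y0 is the percent cleaved at time zero, amplitude the plateau increase
    (percent), and k the combined rate constant (1/min).
    """

    variant: VariantKey
    Y0: float
    amplitude: float
    k: float

    def __post_init__(self) -> None:
        if self.Y0 < 0 or self.amplitude < 0 or self.k < 0:
            raise ValueError("Y0, amplitude, and k must be non-negative")
        if self.Y0 + self.amplitude > 100:
            raise ValueError("Y0 + amplitude may not exceed 100%")


@dataclass(frozen=True)
class TimepointSample:
    """One demultiplexed sample: a replicate at one incubation time."""

    replicate_id: str
    time: float  # minutes
    n_reads: int
    seed: int

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("time must be >= 0")
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")


@dataclass(frozen=True)
class AdapterSpec:
    """Ligated 3' adapter: ``umi_length`` random bases then a constant."""

    umi_length: int = 5
    constant: str = DEFAULT_ADAPTER_CONSTANT

    def __post_init__(self) -> None:
        if not self.constant:
            raise ValueError("adapter constant must be non-empty")


@dataclass
class TruthSet:
    """Per-variant kinetic truths with an optional default.

    Templates carrying more than two substitutions have no tracked variant
    identity; they always use the default truth.
    """

    truths: dict[VariantKey, KineticTruth] = field(default_factory=dict)
    default: KineticTruth | None = None

    def truth_for(self, variant: VariantKey | None) -> KineticTruth:
        if variant is not None and variant in self.truths:
            return self.truths[variant]
        if self.default is None:
            raise KeyError(f"no truth for {variant} and no default truth set")
        return self.default


def derive_seed(master_seed: int, *keys) -> int:
    """Deterministic per-sample seed (< 2^31) from a master seed and keys."""
    entropy = [int(master_seed)]
    for key in keys:
        entropy.append(zlib.crc32(str(key).encode()))
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] % (2**31))


def cleavage_fraction(truth: KineticTruth, t: float) -> float:
    """Percent cleaved predicted by the one-phase association model at time t
    (minutes): ``Y0 + amplitude * (1 - exp(-k t))``."""
    if t < 0:
        raise ValueError("time must be >= 0")
    return truth.Y0 + truth.amplitude * (1.0 - np.exp(-truth.k * t))


def sample_doped_template(
    reference: ReferenceConstruct,
    design: LibraryDesign,
    rng: np.random.Generator,
) -> list[tuple[int, str, str]]:
    """Draw one doped template: each design position is independently
    substituted with probability ``3 * doping_rate_per_alternative``, the
    alternative chosen uniformly. May exceed two substitutions."""
    positions = positions_of(design)
    hit = np.flatnonzero(rng.random(len(positions)) < design.substitution_rate)
    subs = []
    for i in hit:
        pos = positions[i]
        ref = reference.base_at(pos)
        alt = _ALTERNATIVES[ref][rng.integers(0, 3)]
        subs.append((pos, ref, alt))
    return subs


def synthetic_reference(seed: int = 0) -> ReferenceConstruct:
    """A study-shaped construct: 229 nt spanning genomic 6006-6234.

    The real viral sequence is not distributed with the package; the method
    is sequence-generic, so tests and simulations use a seeded random
    construct that carries the study's fixed landmarks (5' G at 6006, UAG
    first codon at 6217-6219, UU at 6232-6233) plus the wild-type base
    identities at positions named in the literature, so published variant
    labels parse against it.
    """
    rng = np.random.default_rng(seed)
    offset = 6006
    length = 229
    bases = list(rng.choice(list("ACGU"), size=length))
    pinned = {
        6006: "G",
        6038: "G", 6041: "C", 6087: "G",                     # loop 1.1
        6066: "G", 6069: "U", 6165: "C", 6166: "C",          # PKII
        6101: "U", 6102: "A", 6103: "G", 6104: "G",          # PKIII
        6134: "C", 6135: "C", 6136: "U", 6137: "A",
        6148: "C", 6149: "A", 6150: "C",
        6176: "U", 6177: "U", 6178: "U", 6179: "U", 6180: "U",  # P3.1
        6182: "A", 6183: "G", 6187: "A", 6190: "U", 6191: "A",
        6194: "C", 6214: "C", 6215: "C", 6216: "U",          # PKI
        6217: "U", 6218: "A", 6219: "G",                     # first codon UAG
        6232: "U", 6233: "U",
    }
    for pos, base in pinned.items():
        bases[pos - offset] = base
    return ReferenceConstruct(
        sequence="".join(bases),
        genomic_offset=offset,
        cleavage_position=6218,
        first_codon_span=(6217, 6219),
    )


class _ConstructTemplates:
    """Precomputed DNA byte templates and cached truth lookups."""

    def __init__(self, reference: ReferenceConstruct, adapter: AdapterSpec):
        self.reference = reference
        self.ref_dna = reference.sequence.encode().translate(_RNA2DNA)
        self.cut_index = reference.index(reference.cleavage_position) + 1
        self.adapter_dna = adapter.constant.encode().translate(_RNA2DNA)
        self.umi_length = adapter.umi_length

    def read_pair(self, subs) -> tuple[bytes, bytes]:
        """(cleaved insert, full-length insert) for a substitution set."""
        tpl = bytearray(self.ref_dna)
        for pos, _, alt in subs:
            tpl[self.reference.index(pos)] = ord(alt.translate(_RNA2DNA))
        return bytes(tpl[: self.cut_index]), bytes(tpl)


def _umi_bytes(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    codes = np.frombuffer(_DNA, dtype=np.uint8)
    return codes[rng.integers(0, 4, size=(n, length))]


def _write_read(fh, read_id: str, insert: bytes, umi: bytes, adapter_dna: bytes) -> None:
    seq = insert + umi + adapter_dna
    fh.write(b"@" + read_id.encode() + b"\n" + seq + b"\n+\n" + b"I" * len(seq) + b"\n")


def _apply_sequencing_errors(tpl: bytearray, rng, error_rate: float) -> None:
    n_err = rng.binomial(len(tpl), error_rate)
    for i in rng.choice(len(tpl), size=n_err, replace=False):
        cur = tpl[i]
        choices = [b for b in _DNA if b != cur]
        tpl[i] = choices[rng.integers(0, 3)]


def simulate_timepoint_fastq(
    reference: ReferenceConstruct,
    design: LibraryDesign | None,
    truths: TruthSet,
    sample: TimepointSample,
    adapter: AdapterSpec,
    out_fastq,
    truth_tsv=None,
    variant_mix: list[tuple[VariantKey, int]] | None = None,
    error_rate: float = 0.0,
) -> pd.DataFrame:
    """Simulate one demultiplexed FASTQ sample.

    Each read draws a doped template from ``design`` (or, in mix mode, uses a
    fixed variant from ``variant_mix`` with explicit per-variant read counts),
    is emitted cleaved with probability ``cleavage_fraction(truth, t)/100``
    or full-length otherwise, and receives a random UMI plus the adapter
    constant at its 3' end. Returns an aggregate truth table with one row per
    (variant label, status); templates with >2 substitutions are pooled under
    the label ``multi``. If ``truth_tsv`` is given, per-read truth records
    (read id, variant, status, UMI) are written there.
    """
    rng = np.random.default_rng(sample.seed)
    tmpl = _ConstructTemplates(reference, adapter)
    counts: dict[tuple[str, str], int] = {}
    truth_fh = open(truth_tsv, "w") if truth_tsv is not None else None
    if truth_fh:
        truth_fh.write("read_id\tvariant\tstatus\tumi\n")

    def emit(fh, i, subs, label, p_cleave, umi_row):
        cleaved = rng.random() < p_cleave
        status = "cleaved" if cleaved else "full_length"
        if error_rate > 0.0:
            tpl = bytearray(tmpl.ref_dna)
            for pos, _, alt in subs:
                tpl[tmpl.reference.index(pos)] = ord(alt.translate(_RNA2DNA))
            _apply_sequencing_errors(tpl, rng, error_rate)
            insert = bytes(tpl[: tmpl.cut_index]) if cleaved else bytes(tpl)
        else:
            cut, full = tmpl.read_pair(subs)
            insert = cut if cleaved else full
        umi = umi_row.tobytes()
        read_id = f"{sample.replicate_id}:t{sample.time:g}:{i}"
        _write_read(fh, read_id, insert, umi, tmpl.adapter_dna)
        counts[(label, status)] = counts.get((label, status), 0) + 1
        if truth_fh:
            truth_fh.write(f"{read_id}\t{label}\t{status}\t{umi.decode()}\n")

    with open(out_fastq, "wb") as fh:
        if variant_mix is not None:
            i = 0
            for variant, n_reads in variant_mix:
                if n_reads < 0:
                    raise ValueError("n_reads must be >= 0")
                label = variant_label(variant, reference)
                p = cleavage_fraction(truths.truth_for(variant), sample.time) / 100.0
                umis = _umi_bytes(rng, n_reads, adapter.umi_length)
                for j in range(n_reads):
                    emit(fh, i, variant.substitutions, label, p, umis[j])
                    i += 1
        else:
            if design is None:
                raise ValueError("either a design or a variant_mix is required")
            positions = positions_of(design)
            pos_arr = np.asarray(positions)
            alts = [_ALTERNATIVES[reference.base_at(p)] for p in positions]
            p_cache: dict[tuple, tuple[str, float]] = {}
            p_multi: float | None = None
            chunk = 20000
            i = 0
            remaining = sample.n_reads
            while remaining > 0:
                m = min(chunk, remaining)
                remaining -= m
                mask = rng.random((m, len(positions))) < design.substitution_rate
                alt_idx = rng.integers(0, 3, size=(m, len(positions)))
                umis = _umi_bytes(rng, m, adapter.umi_length)
                for r in range(m):
                    hit = np.flatnonzero(mask[r])
                    subs = tuple(
                        (int(pos_arr[h]), reference.base_at(int(pos_arr[h])), alts[h][alt_idx[r, h]])
                        for h in hit
                    )
                    if len(subs) <= 2:
                        cached = p_cache.get(subs)
                        if cached is None:
                            variant = VariantKey(subs)
                            label = variant_label(variant, reference)
                            p = cleavage_fraction(truths.truth_for(variant), sample.time) / 100.0
                            cached = (label, p)
                            p_cache[subs] = cached
                        label, p = cached
                    else:
                        if p_multi is None:
                            p_multi = cleavage_fraction(truths.truth_for(None), sample.time) / 100.0
                        label, p = "multi", p_multi
                    emit(fh, i, subs, label, p, umis[r])
                    i += 1
    if truth_fh:
        truth_fh.close()

    rows = [
        {"variant": label, "status": status, "n": n}
        for (label, status), n in sorted(counts.items())
    ]
    summary = pd.DataFrame(rows, columns=["variant", "status", "n"])
    total = int(summary["n"].sum()) if len(summary) else 0
    expected = sum(n for _, n in variant_mix) if variant_mix is not None else sample.n_reads
    assert total == expected, "read-count conservation violated"
    return summary


def exact_mode_simulate(
    reference: ReferenceConstruct,
    truths: TruthSet,
    sample: TimepointSample,
    adapter: AdapterSpec,
    variant_counts: dict[VariantKey, int],
    out_fastq,
    truth_tsv=None,
) -> pd.DataFrame:
    """Deterministic simulator: per variant, emit exactly
    ``round(n * cleavage_fraction/100)`` cleaved reads (round-half-even) and
    the remainder full-length, with deterministic UMIs, enabling bit-exact
    pipeline round trips."""
    tmpl = _ConstructTemplates(reference, adapter)
    rows = []
    truth_fh = open(truth_tsv, "w") if truth_tsv is not None else None
    if truth_fh:
        truth_fh.write("read_id\tvariant\tstatus\tumi\n")
    with open(out_fastq, "wb") as fh:
        i = 0
        for variant, n_reads in variant_counts.items():
            frac = cleavage_fraction(truths.truth_for(variant), sample.time)
            n_cleaved = round(n_reads * frac / 100.0)
            label = variant_label(variant, reference)
            cut, full = tmpl.read_pair(variant.substitutions)
            for j in range(n_reads):
                status = "cleaved" if j < n_cleaved else "full_length"
                insert = cut if j < n_cleaved else full
                umi = _int_umi(i, adapter.umi_length)
                read_id = f"{sample.replicate_id}:t{sample.time:g}:{i}"
                _write_read(fh, read_id, insert, umi, tmpl.adapter_dna)
                if truth_fh:
                    truth_fh.write(f"{read_id}\t{label}\t{status}\t{umi.decode()}\n")
                i += 1
            rows.append(
                {
                    "variant": label,
                    "n_cleaved": n_cleaved,
                    "n_full": n_reads - n_cleaved,
                    "pct_cleaved_config": frac,
                }
            )
    if truth_fh:
        truth_fh.close()
    return pd.DataFrame(rows, columns=["variant", "n_cleaved", "n_full", "pct_cleaved_config"])


def _int_umi(i: int, length: int) -> bytes:
    out = bytearray()
    for _ in range(length):
        out.append(_DNA[i % 4])
        i //= 4
    return bytes(out)


def simulate_gel_timecourse(
    truth: KineticTruth,
    timepoints,
    n_molecules: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Gel-mode time course: at each timepoint the observed percent cleaved
    is a Binomial(n_molecules, fraction/100) draw scaled back to percent."""
    if n_molecules <= 0:
        raise ValueError("n_molecules must be > 0")
    rows = []
    for t in timepoints:
        p = cleavage_fraction(truth, t) / 100.0
        n_cleaved = rng.binomial(n_molecules, p)
        rows.append(
            {
                "time_min": float(t),
                "pct_cleaved": 100.0 * n_cleaved / n_molecules,
                "n_total": n_molecules,
            }
        )
    return pd.DataFrame(rows, columns=["time_min", "pct_cleaved", "n_total"])
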