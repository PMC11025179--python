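"""FASTA/FASTQ reading and writing (plain or gzip) and Phred-quality masking.

Phred scores encode base-call confidence as Q = -10·log10(P), where P is the
estimated error probability: Q10 means a 10% error chance, Q20 means 1%.
Bases whose score falls at or below a threshold (conventionally 10 or 20)
are masked to the ambiguous symbol 'N' before deduplication, so that the
wildcard equivalence can absorb likely sequencing errors.

Parsing goes through Biopython's SeqIO; records come back as this package's
:class:`~wildtrie.alphabet.SeqRecord` with ``input_rank`` set to the stream
position.  Gzip is detected by the ``.gz`` extension, the format by
extension and, failing that, the first byte ('>' FASTA, '@' FASTQ).
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .alphabet import DNA, Alphabet, SeqRecord, normalize
from .errors import FormatError, ParseError


@dataclass(frozen=True)
class QualityPolicy:
    """How to turn per-base quality into wildcard masking.

    ``mask_threshold`` is inclusive by default: a base with Q <= threshold is
    masked.  ``phred_offset`` is 33 for modern (Sanger/Illumina 1.8+) FASTQ;
    64 covers legacy Illumina encodings.
    """

    phred_offset: int = 33
    mask_threshold: int = 10
    inclusive: bool = True

    def __post_init__(self) -> None:
        if self.phred_offset not in (33, 64):
            raise ValueError("phred_offset must be 33 or 64")
        if not 0 <= self.mask_threshold <= 93:
            raise ValueError("mask_threshold must be in [0, 93]")

    def masks(self, q: int) -> bool:
        return q <= self.mask_threshold if self.inclusive else q < self.mask_threshold


def phred_to_error_prob(q: float) -> float:
    """Estimated base-call error probability for Phred score ``q``: 10^(-q/10)."""
    if q < 0:
        raise ValueError(f"Phred score must be non-negative, got {q}")
    return 10.0 ** (-q / 10.0)


def error_prob_to_phred(p: float) -> float:
    """Inverse of :func:`phred_to_error_prob` (for round-trip checks)."""
    if not 0 < p <= 1:
        raise ValueError(f"error probability must be in (0, 1], got {p}")
    return -10.0 * math.log10(p)


def mask_low_quality(
    record: SeqRecord,
    policy: QualityPolicy = QualityPolicy(),
    alphabet: Alphabet = DNA,
) -> SeqRecord:
    """Return a copy with low-quality bases replaced by the wildcard.

    Qualities are preserved so the masked read can still be written as FASTQ.
    """
    if record.quals is None:
        raise FormatError(f"record {record.read_id!r} has no quality values to mask on")
    if len(record.quals) != len(record.seq):
        raise FormatError(
            f"record {record.read_id!r}: quality/sequence length mismatch"
        )
    wc = alphabet.wildcard
    seq = "".join(
        wc if policy.masks(q) else c for c, q in zip(record.seq, record.quals)
    )
    return SeqRecord(
        read_id=record.read_id,
        seq=seq,
        quals=list(record.quals),
        n_ambiguous=seq.count(wc),
        input_rank=record.input_rank,
    )


# -- file I/O ------------------------------------------------------------


def _open_text(path: Path, mode: str = "rt") -> IO[str]:
    if path.suffix == ".gz":
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


def detect_format(path: Path) -> str:
    """'fasta' or 'fastq', by extension then by first character."""
    suffixes = [s.lower() for s in path.suffixes]
    if suffixes and suffixes[-1] == ".gz":
        suffixes = suffixes[:-1]
    if suffixes:
        ext = suffixes[-1]
        if ext in (".fa", ".fasta", ".fna"):
            return "fasta"
        if ext in (".fq", ".fastq"):
            return "fastq"
    with _open_text(path) as fh:
        first = fh.read(1)
    if first == ">":
        return "fasta"
    if first == "@":
        return "fastq"
    raise ParseError(f"{path}: cannot detect format (first character {first!r})")


def read_records(
    path: str | Path,
    fmt: str = "auto",
    alphabet: Alphabet = DNA,
    coerce_unknown: bool = False,
) -> Iterator[SeqRecord]:
    """Stream records from a FASTA/FASTQ file, assigning ``input_rank``.

    Sequences are uppercased on ingest; symbol validation is left to the
    consumer (the dedup entry points validate) unless ``coerce_unknown``
    converts out-of-alphabet characters to the wildcard here.
    """
    path = Path(path)
    if fmt == "auto":
        fmt = detect_format(path)
    if fmt not in ("fasta", "fastq"):
        raise ValueError(f"unknown format {fmt!r}")
    rank = 0
    with _open_text(path) as fh:
        try:
            for bio in SeqIO.parse(fh, fmt):
                seq = normalize(str(bio.seq), alphabet, coerce_unknown)
                quals = bio.letter_annotations.get("phred_quality")
                yield SeqRecord(
                    read_id=bio.id,
                    seq=seq,
                    quals=list(quals) if quals is not None else None,
                    n_ambiguous=seq.count(alphabet.wildcard),
                    input_rank=rank,
                )
                rank += 1
        except ValueError as err:
            # Biopython reports malformed FASTQ as ValueError; re-raise with
            # the file and the record where parsing stopped.
            line = rank * 4 + 1 if fmt == "fastq" else None
            at = f" near line {line}" if line is not None else ""
            raise ParseError(f"{path}{at} (record {rank + 1}): {err}") from err


def write_records(
    records: Iterable[SeqRecord],
    path: str | Path,
    fmt: str = "auto",
) -> int:
    """Write records as FASTA or FASTQ (gzip if the path ends in .gz).

    FASTQ output requires every record to carry qualities.  Returns the
    number of records written; an empty input yields a valid empty file.
    """
    path = Path(path)
    if fmt == "auto":
        try:
            fmt = detect_format(path)
        except (FileNotFoundError, ParseError):
            fmt = "fastq" if path.name.rstrip(".gz").endswith(("fq", "fastq")) else "fasta"
    bio_records = []
    for rec in records:
        bio = BioSeqRecord(Seq(rec.seq), id=rec.read_id, description="")
        if fmt == "fastq":
            if rec.quals is None:
                raise FormatError(
                    f"record {rec.read_id!r} has no qualities; cannot write FASTQ"
                )
            bio.letter_annotations["phred_quality"] = list(rec.quals)
        bio_records.append(bio)
    with _open_text(path, "wt") as fh:
        return SeqIO.write(bio_records, fh, fmt)


def masked_fraction(records: Iterable[SeqRecord], alphabet: Alphabet = DNA) -> float:
    """Fraction of all bases that are the wildcard (a read set's N%)."""
    total = 0
    masked = 0
    wc = alphabet.wildcard
    for rec in records:
        total += len(rec.seq)
        masked += rec.seq.count(wc)
    return masked / total if total else 0.0
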