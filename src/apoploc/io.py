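"""Sequence, label, PSSM and feature-table I/O.

The on-disk formats are deliberately plain: FASTA for sequences, a
two-column TSV manifest for class labels (``id<TAB>class``), the PSI-BLAST
ASCII PSSM layout (the ``-Q`` output dialect) for evolutionary profiles,
and TSV for feature tables.  Everything is UTF-8 text; both Unix and CRLF
newlines are accepted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

#: The 20 standard amino acids, alphabetical by one-letter code.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Column order used by PSI-BLAST PSSM output.
PSSM_COLUMN_ORDER = "ARNDCQEGHILKMFPSTWYV"

#: Substitutions for ambiguous residue codes; anything else is dropped.
AMBIGUOUS_RESIDUE_MAP = {"B": "D", "Z": "E", "U": "C", "O": "K"}


class FastaParseError(ValueError):
    """Raised when a FASTA file is malformed."""


class PssmParseError(ValueError):
    """Raised when a PSI-BLAST ASCII PSSM file cannot be parsed."""


class InvalidSequenceError(ValueError):
    """Raised when a sequence is empty after sanitization."""


class DatasetConsistencyError(ValueError):
    """Raised when records, labels and profiles disagree."""


@dataclass
class ProteinRecord:
    """A protein sequence with an identifier and optional class label."""

    id: str
    sequence: str
    label: str | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise InvalidSequenceError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - set(AMINO_ACIDS)
        if bad:
            raise InvalidSequenceError(
                f"record {self.id!r}: non-standard residues {sorted(bad)}; "
                "run sanitize_sequence first"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PssmProfile:
    """An L x 20 position-specific scoring matrix (raw log-odds scores).

    Columns follow PSI-BLAST order (``A R N D C Q E G H I L K M F P S T W Y V``).
    """

    id: str
    scores: np.ndarray
    column_order: str = PSSM_COLUMN_ORDER

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ValueError(
                f"profile {self.id!r}: expected L x 20 scores, got {self.scores.shape}"
            )

    @property
    def length(self) -> int:
        return self.scores.shape[0]


@dataclass
class LabeledDataset:
    """Protein records with class labels and (optionally) PSSM profiles."""

    records: list[ProteinRecord]
    class_names: list[str] = field(default_factory=list)
    profiles: dict[str, PssmProfile] | None = None

    def __post_init__(self) -> None:
        if not self.class_names:
            seen: list[str] = []
            for rec in self.records:
                if rec.label is not None and rec.label not in seen:
                    seen.append(rec.label)
            self.class_names = seen
        self.validate()

    def validate(self) -> None:
        for rec in self.records:
            if rec.label is not None and rec.label not in self.class_names:
                raise DatasetConsistencyError(
                    f"record {rec.id!r} has label {rec.label!r} not in class_names"
                )
        if self.profiles is not None:
            rec_ids = {r.id for r in self.records}
            prof_ids = set(self.profiles)
            if rec_ids != prof_ids:
                raise DatasetConsistencyError(
                    f"profile ids do not match record ids "
                    f"(missing: {sorted(rec_ids - prof_ids)[:5]}, "
                    f"extra: {sorted(prof_ids - rec_ids)[:5]})"
                )
            for rec in self.records:
                prof = self.profiles[rec.id]
                if prof.length != len(rec):
                    raise DatasetConsistencyError(
                        f"profile {rec.id!r} has {prof.length} rows but the "
                        f"sequence has {len(rec)} residues"
                    )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.records]

    def min_length(self) -> int:
        return min(len(r) for r in self.records)


def sanitize_sequence(raw: str) -> str:
    """Uppercase a residue string and resolve non-standard codes.

    B, Z, U and O are mapped to their closest standard residues (D, E, C, K);
    X and any other character are removed.  Raises
    :class:`InvalidSequenceError` if nothing remains.
    """
    if not raw:
        raise InvalidSequenceError("empty input sequence")
    out = []
    for ch in raw.upper():
        if ch in AMINO_ACIDS:
            out.append(ch)
        elif ch in AMBIGUOUS_RESIDUE_MAP:
            out.append(AMBIGUOUS_RESIDUE_MAP[ch])
        # anything else (X, gaps, whitespace, digits) is dropped
    if not out:
        raise InvalidSequenceError(
            f"sequence {raw[:20]!r} contains no standard residues after sanitization"
        )
    return "".join(out)


def read_fasta(path, sanitize: bool = True) -> list[ProteinRecord]:
    """Read a FASTA file into a list of :class:`ProteinRecord`.

    The record id is the first whitespace-delimited token of the header.
    Sequences are upper-cased; with ``sanitize=True`` (default) ambiguous
    residues are resolved via :func:`sanitize_sequence`.
    """
    records: list[ProteinRecord] = []
    header: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        seq = "".join(chunks)
        seq = sanitize_sequence(seq) if sanitize else seq.upper()
        records.append(ProteinRecord(id=header, sequence=seq))

    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].split()[0] if line[1:].split() else ""
                if not header:
                    raise FastaParseError(f"{path}:{lineno}: empty FASTA header")
                chunks = []
            else:
                if header is None:
                    raise FastaParseError(
                        f"{path}:{lineno}: sequence data before any '>' header"
                    )
                chunks.append(line.strip())
    flush()
    if not records:
        warnings.warn(f"{path}: no FASTA records found", stacklevel=2)
    return records


def write_fasta(records, path, width: int = 60) -> None:
    """Write records as FASTA, wrapping sequences at ``width`` columns."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_labels(path) -> dict[str, str]:
    """Read a two-column TSV label manifest (``id<TAB>class``)."""
    labels: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 'id<TAB>class', got {line!r}"
                )
            labels[parts[0]] = parts[1]
    return labels


def write_labels(labels: dict[str, str], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rid, cls in labels.items():
            fh.write(f"{rid}\t{cls}\n")


def read_pssm(path, id: str | None = None) -> PssmProfile:
    """Parse a PSI-BLAST ASCII PSSM file (the ``-Q`` output dialect).

    The layout is: two or three header lines, then one row per sequence
    position carrying the position index, the residue, 20 integer log-odds
    columns, 20 weighted-percentage columns and two trailing floats.  Only
    the 20 log-odds columns are kept.
    """
    rows: list[list[float]] = []
    saw_header = False
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            stripped = line.strip()
            if not stripped:
                continue
            parts = stripped.split()
            # header line: starts with the column letters, i.e. first token
            # is a single letter 'A' and there are >= 20 single-letter tokens
            if not parts[0].lstrip("-").isdigit():
                if all(len(p) == 1 and p.isalpha() for p in parts[:20]) and len(parts) >= 20:
                    saw_header = True
                continue
            if not saw_header:
                raise PssmParseError(
                    f"{path}:{lineno}: data row before the amino-acid header line"
                )
            pos = int(parts[0])
            if len(parts) < 22:
                raise PssmParseError(
                    f"{path}:{lineno}: position {pos}: too few columns for 20 log-odds"
                )
            try:
                scores = [float(v) for v in parts[2:22]]
            except ValueError as exc:
                raise PssmParseError(
                    f"{path}:{lineno}: position {pos}: non-numeric log-odds value"
                ) from exc
            rows.append(scores)
    if not saw_header:
        raise PssmParseError(f"{path}: missing PSSM header line")
    if not rows:
        raise PssmParseError(f"{path}: no PSSM rows found")
    pid = id if id is not None else str(path)
    return PssmProfile(id=pid, scores=np.array(rows, dtype=float))


def write_pssm(profile: PssmProfile, path, sequence: str | None = None) -> None:
    """Write a profile in PSI-BLAST ASCII layout (for fixtures and round-trips)."""
    seq = sequence if sequence is not None else "A" * profile.length
    letters = " ".join(profile.column_order)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n")
        fh.write("Last position-specific scoring matrix computed\n")
        fh.write(f"            {letters}   {letters}\n")
        for i, row in enumerate(profile.scores, start=1):
            logodds = " ".join(f"{int(round(v)):3d}" for v in row)
            pct = " ".join(f"{0:3d}" for _ in row)
            fh.write(f"{i:5d} {seq[i - 1]}  {logodds}  {pct}  0.00 0.00\n")
        fh.write("\n")


def load_dataset(fasta_path, labels_path=None, pssm_dir=None) -> LabeledDataset:
    """Assemble a :class:`LabeledDataset` from FASTA + label manifest (+ PSSM dir).

    When ``pssm_dir`` is given, a file ``<id>.pssm`` is expected per record.
    """
    from pathlib import Path

    records = read_fasta(fasta_path)
    if labels_path is not None:
        labels = read_labels(labels_path)
        for rec in records:
            if rec.id not in labels:
                raise DatasetConsistencyError(f"no label for record {rec.id!r}")
            rec.label = labels[rec.id]
    profiles = None
    if pssm_dir is not None:
        profiles = {}
        for rec in records:
            ppath = Path(pssm_dir) / f"{rec.id}.pssm"
            if not ppath.exists():
                raise DatasetConsistencyError(f"no PSSM file for record {rec.id!r}")
            profiles[rec.id] = read_pssm(ppath, id=rec.id)
    return LabeledDataset(records=records, profiles=profiles)
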