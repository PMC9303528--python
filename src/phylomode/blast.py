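"""Parsing of all-vs-all BLAST tabular (outfmt 6) hit tables.

Only the columns the downstream graph construction and reciprocal-best-hit
logic need are retained: query id, subject id, alignment length, e-value and
bit score. Files may be plain or gzip-compressed.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

logger = logging.getLogger(__name__)

__all__ = ["HitRecord", "BlastParseError", "parse_blast_tab", "species_of"]

#: outfmt 6 default column order
_QSEQID, _SSEQID, _LENGTH, _EVALUE, _BITSCORE = 0, 1, 3, 10, 11
_MIN_COLUMNS = 12
#: fraction of malformed rows tolerated before the parse is aborted
_MAX_BAD_FRACTION = 0.01


class BlastParseError(ValueError):
    """Raised when a hit table is unreadable or too corrupted to trust."""


@dataclass(frozen=True)
class HitRecord:
    """One pairwise similarity hit.

    ``length`` is the alignment length (outfmt-6 column 4); it participates
    in the reciprocal-best-hit tie-break chain.
    """

    query_id: str
    subject_id: str
    evalue: float
    bitscore: float
    length: int = 0

    def __post_init__(self):
        if not self.query_id or not self.subject_id:
            raise ValueError("hit with empty sequence id")
        if self.evalue < 0:
            raise ValueError(f"negative evalue: {self.evalue}")
        if self.bitscore <= 0:
            raise ValueError(f"non-positive bitscore: {self.bitscore}")


def species_of(protein_id: str, delim: str = "|") -> str:
    """Species code encoded in a protein id (prefix before ``delim``)."""
    return protein_id.split(delim, 1)[0]


def _open(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def parse_blast_tab(
    path: str | Path,
    evalue_cutoff: float = 1e-5,
) -> list[HitRecord]:
    """Read an outfmt-6 hit table, keeping hits with evalue <= cutoff.

    Self-hits are retained (they become self-loops in the similarity graph
    and are overwritten during graph finalization). Malformed rows are
    collected with their line numbers and logged; if more than 1% of rows
    are malformed the parse fails.

    Parameters
    ----------
    path:
        Tab-separated file with >= 12 outfmt-6 columns per row, optionally
        gzipped.
    evalue_cutoff:
        Inclusive e-value threshold; must be >= 0.

    Returns
    -------
    list of HitRecord
    """
    if evalue_cutoff < 0:
        raise ValueError("evalue_cutoff must be >= 0")
    path = Path(path)
    records: list[HitRecord] = []
    bad: list[tuple[int, str]] = []
    n_rows = 0
    try:
        fh = _open(path)
    except OSError as exc:
        raise BlastParseError(f"cannot read hit table {path}: {exc}") from exc
    with fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            n_rows += 1
            fields = line.split("\t")
            if len(fields) < _MIN_COLUMNS:
                bad.append((lineno, "fewer than 12 columns"))
                continue
            try:
                evalue = float(fields[_EVALUE])
                bitscore = float(fields[_BITSCORE])
                length = int(fields[_LENGTH])
            except ValueError:
                bad.append((lineno, "non-numeric evalue/bitscore/length"))
                continue
            if evalue < 0 or bitscore <= 0:
                bad.append((lineno, "out-of-range evalue/bitscore"))
                continue
            if evalue > evalue_cutoff:
                continue
            records.append(
                HitRecord(
                    query_id=fields[_QSEQID],
                    subject_id=fields[_SSEQID],
                    evalue=evalue,
                    bitscore=bitscore,
                    length=length,
                )
            )
    if bad:
        for lineno, why in bad[:10]:
            logger.error("%s line %d: %s", path, lineno, why)
        if n_rows and len(bad) / n_rows >= _MAX_BAD_FRACTION:
            raise BlastParseError(
                f"{len(bad)} of {n_rows} rows malformed in {path} "
                f"(first: line {bad[0][0]}: {bad[0][1]})"
            )
    if n_rows == 0:
        logger.warning("empty hit table: %s", path)
    return records
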