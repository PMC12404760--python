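"""Reading, validating and species-pairing of orthologous protein alignments.

Each protein of a complex is represented by one multiple sequence alignment
(MSA) with exactly one row per species.  Two proteins are made comparable by
restricting both MSAs to the species they share ("row matching"), after which
per-column statistics across species are meaningful.  Columns dominated by
gaps carry little signal and are removed by an occupancy filter before any
coevolution scoring.

Coordinates: alignment columns are 1-based throughout.  Mapping a column to a
residue number of a named reference species (for labels such as "SSPN Leu145")
is done by skipping that species' gaps; see :func:`reference_position_map`.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("coevmi")

#: The 20 canonical amino acids, in the fixed order used for integer encoding.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
UNKNOWN = "X"
ALPHABET = set(AMINO_ACIDS) | {GAP, UNKNOWN}

#: Default species extractor: trailing "_SPECIES" mnemonic in the header.
DEFAULT_SPECIES_REGEX = r"_([A-Za-z0-9]+)\s*$"


class AlignmentError(ValueError):
    """Base class for alignment input problems."""


class AlignmentShapeError(AlignmentError):
    """Rows of an alignment do not all have the same length."""


class HeaderParseError(AlignmentError):
    """A sequence header does not match the species-extraction pattern."""


class EmptyInputError(AlignmentError):
    """The input file contains no sequence records."""


class InsufficientOverlapError(AlignmentError):
    """Fewer than two species are shared between two alignments."""


def _clean_seq(seq: str) -> str:
    """Uppercase and map any letter outside the alphabet to 'X' ('.' to '-')."""
    out = []
    for ch in seq.upper():
        if ch == ".":
            ch = GAP
        out.append(ch if ch in ALPHABET else UNKNOWN)
    return "".join(out)


@dataclass
class OrthologAlignment:
    """One protein's species-tagged MSA.

    ``rows`` is an ordered list of ``(species_tag, aligned_seq)`` pairs; all
    aligned sequences have identical length and are drawn from the 20
    amino-acid letters plus ``-`` (gap) and ``X`` (unknown, treated as
    missing data downstream).
    """

    protein_id: str
    rows: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.rows:
            raise EmptyInputError(f"{self.protein_id}: alignment has no rows")
        lengths = {len(s) for _, s in self.rows}
        if len(lengths) != 1:
            raise AlignmentShapeError(
                f"{self.protein_id}: unequal row lengths {sorted(lengths)}"
            )
        if next(iter(lengths)) < 1:
            raise AlignmentShapeError(f"{self.protein_id}: zero-length alignment")
        tags = [t for t, _ in self.rows]
        if len(set(tags)) != len(tags):
            raise AlignmentError(f"{self.protein_id}: duplicate species tags {tags}")
        for tag, seq in self.rows:
            bad = set(seq) - ALPHABET
            if bad:
                raise AlignmentError(
                    f"{self.protein_id}/{tag}: letters outside alphabet: {sorted(bad)}"
                )

    @property
    def length(self) -> int:
        return len(self.rows[0][1])

    @property
    def species(self) -> list[str]:
        return [t for t, _ in self.rows]

    def row(self, species: str) -> str:
        for tag, seq in self.rows:
            if tag == species:
                return seq
        raise KeyError(f"species {species!r} not in alignment {self.protein_id}")

    def to_matrix(self) -> np.ndarray:
        """Residues as a (n_species, length) array of single characters."""
        return np.array([list(s) for _, s in self.rows], dtype="<U1")


@dataclass
class PairedAlignment:
    """Two alignments row-matched on shared species and column-filtered.

    ``cols_a``/``cols_b`` hold the retained 1-based alignment-column indices
    of each protein; ``matrix_a``/``matrix_b`` are (n_species, n_cols)
    character matrices in the same (lexicographic) species order.
    """

    protein_a: str
    protein_b: str
    species: list[str]
    cols_a: list[int]
    cols_b: list[int]
    matrix_a: np.ndarray
    matrix_b: np.ndarray

    def __post_init__(self) -> None:
        if len(self.species) < 2:
            raise InsufficientOverlapError(
                f"{self.protein_a}/{self.protein_b}: "
                f"only {len(self.species)} shared species"
            )
        for m, cols in ((self.matrix_a, self.cols_a), (self.matrix_b, self.cols_b)):
            if m.shape != (len(self.species), len(cols)):
                raise AlignmentShapeError("matrix shape inconsistent with species/cols")

    @property
    def n_species(self) -> int:
        return len(self.species)


def read_alignment(
    path: str | Path,
    format: str = "fasta",
    species_regex: str = DEFAULT_SPECIES_REGEX,
    protein_id: str | None = None,
) -> OrthologAlignment:
    """Read a FASTA or Stockholm MSA and tag each row with its species.

    The species tag is the first capture group of ``species_regex`` applied to
    each record header (description, falling back to id).  Duplicate species
    keep the first occurrence and log a warning.  Letters outside the 20
    amino acids map to ``X``.
    """
    path = Path(path)
    if format not in ("fasta", "stockholm"):
        raise ValueError(f"unsupported alignment format: {format}")
    pattern = re.compile(species_regex)
    try:
        aln = AlignIO.read(str(path), format)
    except ValueError as exc:
        msg = str(exc).lower()
        if "no records" in msg or "empty" in msg or "none" in msg:
            raise EmptyInputError(f"{path}: no alignment records") from exc
        raise AlignmentShapeError(f"{path}: {exc}") from exc
    if len(aln) == 0:
        raise EmptyInputError(f"{path}: no alignment records")

    rows: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in aln:
        header = rec.description if rec.description else rec.id
        m = pattern.search(header) or pattern.search(rec.id)
        if m is None:
            raise HeaderParseError(
                f"{path}: header {header!r} does not match species pattern "
                f"{species_regex!r}"
            )
        tag = m.group(1)
        if tag in seen:
            logger.warning(
                "%s: duplicate species %r; keeping first occurrence", path, tag
            )
            continue
        seen.add(tag)
        rows.append((tag, _clean_seq(str(rec.seq))))
    return OrthologAlignment(protein_id or path.stem, rows)


def write_alignment(
    aln: OrthologAlignment, path: str | Path, format: str = "fasta"
) -> None:
    """Write an alignment with ``{protein_id}_{species}`` headers.

    Headers are chosen so that :func:`read_alignment` with the default
    species pattern round-trips to the identical alignment.
    """
    records = [
        SeqRecord(Seq(seq), id=f"{aln.protein_id}_{tag}", description="")
        for tag, seq in aln.rows
    ]
    AlignIO.write(MultipleSeqAlignment(records), str(path), format)


def column_gap_fractions(matrix: np.ndarray) -> np.ndarray:
    """Fraction of gap ('-') characters per column of a character matrix."""
    return (matrix == GAP).mean(axis=0)


def pair_by_species(
    a: OrthologAlignment,
    b: OrthologAlignment,
    max_gap_frac: float = 0.5,
) -> PairedAlignment:
    """Row-match two alignments on shared species and drop gappy columns.

    Rows are restricted to species present in both alignments (sorted
    lexicographically); columns whose gap fraction over the shared rows
    exceeds ``max_gap_frac`` are dropped, independently per protein.
    Retained columns keep their original 1-based indices.
    """
    if not 0 <= max_gap_frac < 1:
        raise ValueError(f"max_gap_frac must be in [0, 1): {max_gap_frac}")
    shared = sorted(set(a.species) & set(b.species))
    if len(shared) < 2:
        raise InsufficientOverlapError(
            f"{a.protein_id}/{b.protein_id}: only {len(shared)} shared species"
        )

    def _restrict(aln: OrthologAlignment) -> tuple[list[int], np.ndarray]:
        mat = np.array([list(aln.row(sp)) for sp in shared], dtype="<U1")
        keep = column_gap_fractions(mat) <= max_gap_frac
        cols = [i + 1 for i in np.flatnonzero(keep)]
        return cols, mat[:, keep]

    cols_a, mat_a = _restrict(a)
    cols_b, mat_b = _restrict(b)
    return PairedAlignment(
        protein_a=a.protein_id,
        protein_b=b.protein_id,
        species=shared,
        cols_a=cols_a,
        cols_b=cols_b,
        matrix_a=mat_a,
        matrix_b=mat_b,
    )


def reference_position_map(
    aln: OrthologAlignment, reference_species: str
) -> dict[int, int]:
    """Map 1-based residue numbers of the reference row to alignment columns.

    Gap columns of the reference row have no residue number and are absent
    from the mapping.
    """
    seq = aln.row(reference_species)
    mapping: dict[int, int] = {}
    resnum = 0
    for col, ch in enumerate(seq, start=1):
        if ch != GAP:
            resnum += 1
            mapping[resnum] = col
    return mapping


def column_reference_labels(
    aln: OrthologAlignment, reference_species: str
) -> dict[int, str]:
    """Label each alignment column with ``<Res><number>`` of the reference row.

    Columns gapped in the reference row are labelled ``-``.
    """
    seq = aln.row(reference_species)
    labels: dict[int, str] = {}
    resnum = 0
    for col, ch in enumerate(seq, start=1):
        if ch != GAP:
            resnum += 1
            labels[col] = f"{ch}{resnum}"
        else:
            labels[col] = GAP
    return labels
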