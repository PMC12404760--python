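"""Pairwise percent identity/similarity and per-position conservation.

Two conservation views are provided.  ``global_align_identity`` aligns two
full-length protein sequences with Needleman–Wunsch (BLOSUM62, gap open 10 /
extend 0.5 by default) and reports percent identity and percent similarity
over the full alignment length, gap columns included in the denominator —
the convention under which two paralogous sarcoglycans come out near 50%
identity.  ``position_conservation`` scores named residues of a reference
sequence (e.g. SSPN Leu145) across the species rows of an orthologous MSA.

"Similarity" groups residues by conservative-substitution classes; the
default classes are the conventional strong groups and can be overridden.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

from .alignment_io import GAP, UNKNOWN, OrthologAlignment, reference_position_map

#: Conservative-substitution classes used for percent similarity.
DEFAULT_SIMILARITY_GROUPS: tuple[frozenset[str], ...] = tuple(
    frozenset(g) for g in ("ILMV", "FWY", "KRH", "DE", "NQ", "ST", "AG", "C", "P")
)


def _group_of(residue: str, groups) -> frozenset[str] | None:
    for g in groups:
        if residue in g:
            return g
    return None


def residues_similar(a: str, b: str, groups=DEFAULT_SIMILARITY_GROUPS) -> bool:
    """True if the residues are identical or share a similarity group."""
    if a == b and a not in (GAP, UNKNOWN):
        return True
    ga = _group_of(a, groups)
    return ga is not None and b in ga


@dataclass
class IdentityResult:
    """Identity/similarity of one global pairwise alignment.

    Percentages use the full alignment length (gap columns included) as the
    denominator.
    """

    percent_identity: float
    percent_similarity: float
    aligned_length: int
    n_matches: int
    n_similar: int


@dataclass
class PositionConservation:
    """Cross-species conservation of one reference residue position."""

    protein_id: str
    reference_species: str
    reference_position: int
    reference_residue: str
    alignment_column: int
    identity_pct: float
    similarity_pct: float
    n_species_scored: int


def global_align_identity(
    seq_a: str,
    seq_b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    similarity_groups=DEFAULT_SIMILARITY_GROUPS,
) -> IdentityResult:
    """Needleman–Wunsch global alignment with identity/similarity percentages.

    The first optimal traceback reported by the aligner is used; identity and
    similarity counts are tallied column-by-column over that alignment.
    """
    for name, s in (("seq_a", seq_a), ("seq_b", seq_b)):
        if not s:
            raise ValueError(f"{name} is empty")
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    aligner.mode = "global"
    aln = aligner.align(seq_a.upper(), seq_b.upper())[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    length = len(row_a)
    n_match = sum(1 for x, y in zip(row_a, row_b) if x == y and x != GAP)
    n_sim = sum(
        1
        for x, y in zip(row_a, row_b)
        if x != GAP and y != GAP and residues_similar(x, y, similarity_groups)
    )
    return IdentityResult(
        percent_identity=100.0 * n_match / length,
        percent_similarity=100.0 * n_sim / length,
        aligned_length=length,
        n_matches=n_match,
        n_similar=n_sim,
    )


def position_conservation(
    aln: OrthologAlignment,
    reference_species: str,
    positions: list[int],
    similarity_groups=DEFAULT_SIMILARITY_GROUPS,
) -> list[PositionConservation]:
    """Conservation of named reference residues across the species panel.

    Each 1-based residue number of the reference row is mapped to its
    alignment column by skipping reference gaps; identity is the fraction of
    scored rows carrying the reference residue, similarity the fraction in
    the same similarity class.  Rows gapped (or 'X') at the column are
    excluded from the denominator; ``n_species_scored`` reports the rows
    actually scored (the reference row included).
    """
    pos_map = reference_position_map(aln, reference_species)
    ref_len = len(pos_map)
    out: list[PositionConservation] = []
    for pos in positions:
        if pos not in pos_map:
            raise IndexError(
                f"position {pos} beyond reference length {ref_len} "
                f"({aln.protein_id}/{reference_species})"
            )
        col = pos_map[pos]
        ref_res = aln.row(reference_species)[col - 1]
        column = [seq[col - 1] for _, seq in aln.rows]
        scored = [c for c in column if c not in (GAP, UNKNOWN)]
        n = len(scored)
        n_id = sum(1 for c in scored if c == ref_res)
        n_sim = sum(1 for c in scored if residues_similar(ref_res, c, similarity_groups))
        out.append(
            PositionConservation(
                protein_id=aln.protein_id,
                reference_species=reference_species,
                reference_position=pos,
                reference_residue=ref_res,
                alignment_column=col,
                identity_pct=100.0 * n_id / n,
                similarity_pct=100.0 * n_sim / n,
                n_species_scored=n,
            )
        )
    return out
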