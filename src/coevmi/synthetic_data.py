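"""Synthetic species-matched alignments with planted interprotein covariation.

The generator emulates the statistical structure a coevolution scan assumes:
a panel of species, one orthologous sequence per species per protein, and a
small number of "planted" column pairs between chosen proteins whose
substitutions are coupled.  Evolution follows a star phylogeny — every
species descends independently from a single ancestral sequence — so species
rows are exchangeable under the null and a row-permutation test is exactly
calibrated on unplanted columns.

Model, per column: an ancestral residue is drawn uniformly from the 20 amino
acids; each species substitutes it with probability ``m`` to a residue drawn
uniformly from the other 19.  For a planted pair (i, j, rho): whenever column
i substitutes in a species, column j substitutes in that same species with
probability ``rho``, and j's substituted residue is a deterministic bijective
map of i's residue (the bijection fixes ancestral_i -> ancestral_j, so a
coupled substitution of i always changes j).  Covariation is therefore
informative — which residue appears at j depends on which appears at i — and
not merely co-occurrence of change.  Gaps are injected i.i.d. with
probability ``g`` after substitution.

Randomness is expanded from the single seed via per-column
``numpy.random.SeedSequence`` keys, so output is byte-identical for a given
spec regardless of iteration order.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alignment_io import AMINO_ACIDS, GAP, OrthologAlignment, write_alignment


class SpecValidationError(ValueError):
    """A SimulationSpec violates one of its invariants."""


@dataclass(frozen=True)
class PlantedPair:
    """One coupled interprotein column pair (1-based columns)."""

    protein_a: str
    col_a: int
    protein_b: str
    col_b: int
    rho: float


@dataclass
class SimulationSpec:
    """Parameters of one synthetic complex.

    ``proteins`` is an ordered list of ``(protein_id, n_columns)``;
    ``substitution_prob`` is the per-column per-species substitution
    probability m; ``gap_prob`` the i.i.d. gap injection probability g.
    """

    n_species: int
    proteins: list[tuple[str, int]]
    planted_pairs: list[PlantedPair] = field(default_factory=list)
    substitution_prob: float = 0.3
    gap_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise SpecValidationError("n_species must be >= 1")
        if not self.proteins:
            raise SpecValidationError("at least one protein required")
        ids = [p for p, _ in self.proteins]
        if len(set(ids)) != len(ids):
            raise SpecValidationError(f"duplicate protein ids: {ids}")
        if not 0 <= self.substitution_prob <= 1:
            raise SpecValidationError("substitution_prob must be in [0, 1]")
        if not 0 <= self.gap_prob < 1:
            raise SpecValidationError("gap_prob must be in [0, 1)")
        ncols = dict(self.proteins)
        used: set[tuple[str, int]] = set()
        for pp in self.planted_pairs:
            if not 0 <= pp.rho <= 1:
                raise SpecValidationError(f"rho out of [0, 1]: {pp}")
            for prot, col in ((pp.protein_a, pp.col_a), (pp.protein_b, pp.col_b)):
                if prot not in ncols:
                    raise SpecValidationError(f"unknown protein in planted pair: {pp}")
                if not 1 <= col <= ncols[prot]:
                    raise SpecValidationError(f"planted column out of range: {pp}")
                if (prot, col) in used:
                    raise SpecValidationError(
                        f"column {prot}:{col} appears in more than one planted pair"
                    )
                used.add((prot, col))


@dataclass
class SyntheticComplex:
    """Generated alignments (shared species panel) plus the planted truth."""

    alignments: dict[str, OrthologAlignment]
    truth: list[PlantedPair]
    spec: SimulationSpec


def _species_tags(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"SP{i:0{width}d}" for i in range(1, n + 1)]


def _column_rng(seed: int, stream: int, p_idx: int, c_idx: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, stream, p_idx, c_idx]))


def simulate_complex(spec: SimulationSpec) -> SyntheticComplex:
    """Generate one synthetic complex under the star-phylogeny model."""
    n = spec.n_species
    m = spec.substitution_prob
    species = _species_tags(n)
    p_index = {p: i for i, (p, _) in enumerate(spec.proteins)}

    # Independent evolution of every column; keep ancestral residue and the
    # substitution mask so planted couplings can condition on them.
    codes: dict[str, np.ndarray] = {}
    anc: dict[str, np.ndarray] = {}
    subst: dict[str, np.ndarray] = {}
    for prot, ncol in spec.proteins:
        pi = p_index[prot]
        col_codes = np.empty((n, ncol), dtype=np.int8)
        col_anc = np.empty(ncol, dtype=np.int8)
        col_sub = np.empty((n, ncol), dtype=bool)
        for c in range(ncol):
            rng = _column_rng(spec.seed, 1, pi, c)
            a = rng.integers(20)
            sub = rng.random(n) < m
            col = np.full(n, a, dtype=np.int8)
            # uniform over the 19 non-ancestral residues
            col[sub] = (a + 1 + rng.integers(19, size=int(sub.sum()))) % 20
            col_anc[c] = a
            col_sub[:, c] = sub
            col_codes[:, c] = col
        codes[prot] = col_codes
        anc[prot] = col_anc
        subst[prot] = col_sub

    # Planted couplings: overwrite the target column where the source
    # column substituted, using a bijection that fixes anc_i -> anc_j.
    for k, pp in enumerate(spec.planted_pairs):
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2, k]))
        ai = int(anc[pp.protein_a][pp.col_a - 1])
        aj = int(anc[pp.protein_b][pp.col_b - 1])
        bij = rng.permutation(20)
        # force bij[ai] == aj by swapping
        pos = int(np.flatnonzero(bij == aj)[0])
        bij[pos], bij[ai] = bij[ai], aj
        src_sub = subst[pp.protein_a][:, pp.col_a - 1]
        coupled = src_sub & (rng.random(n) < pp.rho)
        src = codes[pp.protein_a][:, pp.col_a - 1]
        tgt = codes[pp.protein_b]
        tgt[coupled, pp.col_b - 1] = bij[src[coupled]]
        subst[pp.protein_b][coupled, pp.col_b - 1] = True

    # Gap injection, then render to character alignments.
    aa = np.array(list(AMINO_ACIDS), dtype="<U1")
    alignments: dict[str, OrthologAlignment] = {}
    for prot, ncol in spec.proteins:
        pi = p_index[prot]
        chars = aa[codes[prot]]
        if spec.gap_prob > 0:
            for c in range(ncol):
                rng = _column_rng(spec.seed, 3, pi, c)
                gaps = rng.random(n) < spec.gap_prob
                chars[gaps, c] = GAP
        rows = [(sp, "".join(chars[i])) for i, sp in enumerate(species)]
        alignments[prot] = OrthologAlignment(prot, rows)

    return SyntheticComplex(alignments=alignments, truth=list(spec.planted_pairs), spec=spec)


TRUTH_COLUMNS = ("protein_a", "col_a", "protein_b", "col_b", "rho")


def write_fixture(complex_: SyntheticComplex, dir: str | Path) -> list[Path]:
    """Write one FASTA per protein plus a TSV truth table of planted pairs.

    ``read_alignment`` on the written FASTAs (default species pattern)
    reproduces the in-memory alignments.
    """
    out_dir = Path(dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for prot, aln in complex_.alignments.items():
        p = out_dir / f"{prot}.fasta"
        write_alignment(aln, p, "fasta")
        written.append(p)
    truth_path = out_dir / "truth.tsv"
    with open(truth_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(TRUTH_COLUMNS)
        for pp in complex_.truth:
            w.writerow([pp.protein_a, pp.col_a, pp.protein_b, pp.col_b, pp.rho])
    written.append(truth_path)
    return written


def read_truth(path: str | Path) -> list[PlantedPair]:
    """Read a truth table written by :func:`write_fixture`."""
    pairs: list[PlantedPair] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            pairs.append(
                PlantedPair(
                    row["protein_a"],
                    int(row["col_a"]),
                    row["protein_b"],
                    int(row["col_b"]),
                    float(row["rho"]),
                )
            )
    return pairs
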