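"""Mutual-information coevolution scores with permutation significance.

For a pair of row-matched alignment columns the dependence between residue
distributions across species is measured by plug-in mutual information

    MI(a, b) = H(a) + H(b) - H(a, b)        (bits, log base 2),

with all three entropies estimated from the empirical residue frequencies on
the species rows where *both* columns carry a residue (pairwise-complete gap
policy: '-' and 'X' are missing data, never a 21st informative state).

Significance is assessed with a block row-permutation null: protein B's
species rows are shuffled as a whole (one shared permutation per replicate
across all of B's columns), which breaks any interprotein covariation while
preserving B's intraprotein column structure, and the add-one permutation
p-value p = (1 + #{MI_perm >= MI_obs}) / (1 + n_perm) is assigned per column
pair.  Benjamini–Hochberg q-values are computed within each protein pair by
default.  Two per-protein-pair summary fractions are reported: the
proportion of significant pairs (q below a threshold) and the fraction of
pairs with nonzero MI.

Implementation note: all-vs-all grids are computed by a single one-hot
matrix product per replicate (contingency counts for every column pair at
once) followed by an integer c·log2(c) table lookup, so permutation nulls
over thousands of column pairs run in seconds.  ``mutual_information`` is an
independent straight per-pair implementation kept as the readable reference.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .alignment_io import AMINO_ACIDS, GAP, UNKNOWN, PairedAlignment

_CODE = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_MISSING = -1


class InsufficientDataError(ValueError):
    """Fewer than two jointly observed rows for a column pair."""


class UndefinedEntropyError(ValueError):
    """Entropy requested for a column with no observed residues."""


def encode_columns(matrix: np.ndarray | Sequence[str]) -> np.ndarray:
    """Encode residue characters to int8 codes (0–19; -1 for '-'/'X')."""
    arr = np.asarray(matrix, dtype="<U1")
    codes = np.full(arr.shape, _MISSING, dtype=np.int8)
    for aa, i in _CODE.items():
        codes[arr == aa] = i
    return codes


def _encode_vector(column: Sequence[str] | str | np.ndarray) -> np.ndarray:
    if isinstance(column, str):
        column = list(column)
    return encode_columns(np.asarray(column, dtype="<U1"))


# ---------------------------------------------------------------------------
# Reference per-pair estimators
# ---------------------------------------------------------------------------

def column_entropy(column: Sequence[str] | str | np.ndarray) -> float:
    """Plug-in Shannon entropy (bits) of one column, gap rows excluded."""
    codes = _encode_vector(column)
    obs = codes[codes != _MISSING]
    if obs.size == 0:
        raise UndefinedEntropyError("all-gap column has no defined entropy")
    _, counts = np.unique(obs, return_counts=True)
    f = counts / counts.sum()
    return float(-(f * np.log2(f)).sum())


def mutual_information(
    col_a: Sequence[str] | str | np.ndarray,
    col_b: Sequence[str] | str | np.ndarray,
) -> tuple[float, int]:
    """Plug-in MI (bits) and row count on the jointly non-gap rows.

    Straightforward contingency-table implementation; the grid route in
    :func:`mi_grid` must agree with it exactly.
    """
    a = _encode_vector(col_a)
    b = _encode_vector(col_b)
    if a.shape != b.shape:
        raise ValueError("columns have different lengths")
    keep = (a != _MISSING) & (b != _MISSING)
    n_eff = int(keep.sum())
    if n_eff < 2:
        raise InsufficientDataError(f"only {n_eff} jointly observed rows")
    a, b = a[keep], b[keep]
    joint = np.zeros((20, 20))
    np.add.at(joint, (a, b), 1.0)
    p = joint / n_eff
    pa = p.sum(axis=1)
    pb = p.sum(axis=0)

    def h(q: np.ndarray) -> float:
        q = q[q > 0]
        return float(-(q * np.log2(q)).sum())

    mi = h(pa) + h(pb) - h(p.ravel())
    return max(mi, 0.0), n_eff


# ---------------------------------------------------------------------------
# Vectorised all-vs-all grid
# ---------------------------------------------------------------------------

def _onehot(codes: np.ndarray) -> np.ndarray:
    """(n, L) int codes -> (L*20, n) float32 indicator matrix."""
    n, L = codes.shape
    x = np.zeros((L, 20, n), dtype=np.float32)
    rows, cols = np.nonzero(codes.T != _MISSING)  # rows over L, cols over n
    x[rows, codes.T[rows, cols], cols] = 1.0
    return x.reshape(L * 20, n)


def _xlog2x_table(n_max: int) -> np.ndarray:
    t = np.zeros(n_max + 1)
    c = np.arange(1, n_max + 1)
    t[1:] = c * np.log2(c)
    return t


def _grid_from_onehot(
    xa: np.ndarray, xb: np.ndarray, la: int, lb: int, table: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """MI (bits) and n_eff for every column pair from one matrix product."""
    counts = np.rint(xa @ xb.T).astype(np.int64).reshape(la, 20, lb, 20)
    n_eff = counts.sum(axis=(1, 3))
    tj = table[counts].sum(axis=(1, 3))
    ta = table[counts.sum(axis=3)].sum(axis=1)
    tb = table[counts.sum(axis=1)].sum(axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        tn = np.where(n_eff > 0, n_eff * np.log2(np.maximum(n_eff, 1)), 0.0)
        mi = (tj - ta - tb + tn) / np.maximum(n_eff, 1)
    mi = np.maximum(mi, 0.0)
    mi[n_eff < 2] = np.nan
    return mi, n_eff


@dataclass
class MIGrid:
    """All-vs-all MI for one paired alignment.

    ``mi[i, j]`` is the MI of (cols_a[i], cols_b[j]) in bits; entries with
    fewer than two jointly observed rows are NaN (flagged missing).
    """

    cols_a: list[int]
    cols_b: list[int]
    mi: np.ndarray
    n_eff: np.ndarray


def mi_grid(paired: PairedAlignment) -> MIGrid:
    """Compute the full MI grid of a paired alignment."""
    ca = encode_columns(paired.matrix_a)
    cb = encode_columns(paired.matrix_b)
    la, lb = ca.shape[1], cb.shape[1]
    table = _xlog2x_table(paired.n_species)
    mi, n_eff = _grid_from_onehot(_onehot(ca), _onehot(cb), la, lb, table)
    return MIGrid(list(paired.cols_a), list(paired.cols_b), mi, n_eff)


def apc_correct(mi: np.ndarray) -> np.ndarray:
    """Average-product correction: mi - row_mean*col_mean/grand_mean.

    Optional background subtraction; off by default throughout the package
    so the headline scores are plain plug-in MI.
    """
    with np.errstate(invalid="ignore"):
        row = np.nanmean(mi, axis=1, keepdims=True)
        col = np.nanmean(mi, axis=0, keepdims=True)
        grand = np.nanmean(mi)
    if not np.isfinite(grand) or grand == 0:
        return mi.copy()
    return mi - row * col / grand


# ---------------------------------------------------------------------------
# Permutation null
# ---------------------------------------------------------------------------

_TIE_TOL = 1e-12


def permutation_pvalues(
    paired: PairedAlignment,
    grid: MIGrid | None = None,
    n_perm: int = 999,
    seed: int | None = None,
    exhaustive: bool = False,
) -> np.ndarray:
    """Permutation p-values for every column pair of the grid.

    Protein B's species rows are shuffled as a block: one shared random row
    permutation per replicate applied to all of B's columns, preserving B's
    intraprotein structure while breaking interprotein covariation.  With
    ``exhaustive=True`` all n! row permutations are enumerated (n <= 8) and
    the exact p-value #{MI_perm >= MI_obs}/n! is returned; otherwise the
    add-one estimate (1 + #{MI_perm >= MI_obs}) / (1 + n_perm).
    """
    if grid is None:
        grid = mi_grid(paired)
    ca = encode_columns(paired.matrix_a)
    cb = encode_columns(paired.matrix_b)
    la, lb = ca.shape[1], cb.shape[1]
    table = _xlog2x_table(paired.n_species)
    xa = _onehot(ca)
    xb = _onehot(cb).reshape(lb, 20, paired.n_species)
    obs = grid.mi

    count = np.zeros((la, lb), dtype=np.int64)
    if exhaustive:
        n = paired.n_species
        if n > 8:
            raise ValueError("exhaustive enumeration limited to <= 8 species")
        total = math.factorial(n)
        for perm in itertools.permutations(range(n)):
            xbp = xb[:, :, perm].reshape(lb * 20, n)
            mi_p, _ = _grid_from_onehot(xa, xbp, la, lb, table)
            count += (mi_p >= obs - _TIE_TOL) & np.isfinite(obs)
        p = count / total
    else:
        if n_perm < 1:
            raise ValueError(f"n_perm must be >= 1: {n_perm}")
        rng = np.random.default_rng(seed)
        for _ in range(n_perm):
            perm = rng.permutation(paired.n_species)
            xbp = xb[:, :, perm].reshape(lb * 20, paired.n_species)
            mi_p, _ = _grid_from_onehot(xa, xbp, la, lb, table)
            count += (mi_p >= obs - _TIE_TOL) & np.isfinite(obs)
        p = (1 + count) / (1 + n_perm)
    p = p.astype(float)
    p[~np.isfinite(obs)] = np.nan
    return p


# ---------------------------------------------------------------------------
# Multiple testing and summaries
# ---------------------------------------------------------------------------

def bh_qvalues(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values (monotone, capped at 1).

    NaN entries (flagged-missing pairs) are passed through as NaN and do not
    enter the correction.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    mask = np.isfinite(p)
    if mask.any():
        pv = p[mask]
        if (pv <= 0).any() or (pv > 1).any():
            raise ValueError("p-values must lie in (0, 1]")
    q = np.full(p.shape, np.nan)
    if mask.any():
        q[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return np.minimum(q, 1.0, where=np.isfinite(q), out=q)


@dataclass
class ResiduePairScore:
    """MI, significance and labels for one (column_a, column_b) pair."""

    col_a: int
    col_b: int
    mi: float
    n_eff: int
    p_value: float
    q_value: float = float("nan")
    label_a: str = ""
    label_b: str = ""


@dataclass
class ProteinPairSummary:
    """The per-protein-pair dot-plot metrics.

    ``frac_significant`` — proportion of tested column pairs with q below
    the threshold; ``frac_nonzero_mi`` — fraction with MI > 0.  Flagged
    missing pairs count in the denominator and are never significant, so
    frac_significant <= frac_nonzero_mi always holds.
    """

    protein_a: str
    protein_b: str
    n_pairs_tested: int
    frac_significant: float
    frac_nonzero_mi: float
    q_threshold: float
    top_pairs: list[ResiduePairScore]


def score_pair(
    paired: PairedAlignment,
    n_perm: int = 999,
    seed: int | None = None,
    apc: bool = False,
    labels_a: dict[int, str] | None = None,
    labels_b: dict[int, str] | None = None,
) -> list[ResiduePairScore]:
    """Full scoring of one protein pair: MI grid, permutation p, BH q.

    Returns one score per non-missing column pair (missing pairs — fewer
    than two jointly observed rows — are dropped from the list but remain in
    the tested-pair count used by :func:`summarize_pair`).
    """
    grid = mi_grid(paired)
    p = permutation_pvalues(paired, grid, n_perm=n_perm, seed=seed)
    mi = apc_correct(grid.mi) if apc else grid.mi
    q = bh_qvalues(p.ravel()).reshape(p.shape)
    scores: list[ResiduePairScore] = []
    for i, col_a in enumerate(grid.cols_a):
        for j, col_b in enumerate(grid.cols_b):
            if not np.isfinite(grid.mi[i, j]):
                continue
            scores.append(
                ResiduePairScore(
                    col_a=col_a,
                    col_b=col_b,
                    mi=float(mi[i, j]),
                    n_eff=int(grid.n_eff[i, j]),
                    p_value=float(p[i, j]),
                    q_value=float(q[i, j]),
                    label_a=(labels_a or {}).get(col_a, ""),
                    label_b=(labels_b or {}).get(col_b, ""),
                )
            )
    return scores


def summarize_pair(
    scores: Iterable[ResiduePairScore],
    q_threshold: float = 0.05,
    n_pairs_tested: int | None = None,
    protein_a: str = "",
    protein_b: str = "",
    k_top: int = 20,
) -> ProteinPairSummary:
    """Aggregate scores of one protein pair into the dot-plot metrics."""
    scores = list(scores)
    n = n_pairs_tested if n_pairs_tested is not None else len(scores)
    if n == 0:
        raise ValueError("no pairs tested")
    n_sig = sum(1 for s in scores if np.isfinite(s.q_value) and s.q_value < q_threshold)
    n_nonzero = sum(1 for s in scores if s.mi > 0)
    top = sorted(scores, key=_rank_key)[:k_top]
    return ProteinPairSummary(
        protein_a=protein_a,
        protein_b=protein_b,
        n_pairs_tested=n,
        frac_significant=n_sig / n,
        frac_nonzero_mi=n_nonzero / n,
        q_threshold=q_threshold,
        top_pairs=top,
    )


def _rank_key(item) -> tuple:
    """Descending MI; ties by smaller p, then lexicographic labels/columns."""
    if isinstance(item, tuple):
        pa, pb, s = item
    else:
        pa, pb, s = "", "", item
    p = s.p_value if np.isfinite(s.p_value) else 2.0
    return (-s.mi, p, pa, pb, s.col_a, s.col_b)


def rank_top_pairs(
    scores: Iterable[tuple[str, str, ResiduePairScore]], k: int = 20
) -> list[tuple[str, str, ResiduePairScore]]:
    """Global top-k residue pairs across all protein pairs, by MI."""
    if k < 1:
        raise ValueError(f"k must be >= 1: {k}")
    return sorted(scores, key=_rank_key)[:k]
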