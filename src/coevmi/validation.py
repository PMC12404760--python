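"""Self-contained validation studies of the coevolution pipeline.

Every study here generates its own inputs with the package's synthetic
simulator (or the synthetic coordinate fixtures), runs the ordinary public
API on them, and returns measured numbers.  They back the test suite and the
reproducibility script and double as usage examples:

* analytic MI identities and the entropy bound on random columns;
* exact agreement of sampled/enumerated permutation p-values on tiny panels;
* type-I calibration of the permutation test on null complexes;
* power and headline-pattern recovery on a 10-protein complex with couplings
  planted only between the SSPN and SGCG blocks — the synthetic mirror of a
  scan over the sarcoglycan–sarcospan complex plus control proteins;
* BH q-values against an independent step-up implementation;
* the interface-contact inventory of the synthetic canonical/compensatory
  structure pair;
* percent identity of a synthetic paralog pair built at sarcoglycan-like
  divergence.

All randomness is derived from a single integer seed.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import stats

from .alignment_io import AMINO_ACIDS, OrthologAlignment, pair_by_species
from .coevolution import (
    bh_qvalues,
    column_entropy,
    mi_grid,
    mutual_information,
    permutation_pvalues,
    rank_top_pairs,
)
from .conservation import global_align_identity
from .pipeline import analyze_complex
from .structure_contacts import (
    HYDROPHOBIC_CARBONS,
    SALT_ACIDIC,
    SALT_BASIC,
    SYNTHETIC_CHAIN_CORRESPONDENCE,
    SYNTHETIC_RESIDUE_CORRESPONDENCE,
)
from .synthetic_data import PlantedPair, SimulationSpec, simulate_complex


def _sub_seed(seed: int, label: str) -> int:
    import zlib

    return (seed * 1000003 + zlib.crc32(label.encode())) % (2**31)


# ---------------------------------------------------------------------------
# MI identities
# ---------------------------------------------------------------------------

def mi_identity_checks(seed: int, n_random: int = 10_000) -> dict:
    """Analytic MI identities plus the entropy bound on random column pairs.

    Returns the worst absolute deviation from each identity and the largest
    violation of MI <= min(H_a, H_b) over ``n_random`` random small columns.
    """
    rng = np.random.default_rng(_sub_seed(seed, "identities"))
    dev_self = 0.0
    dev_const = 0.0
    bound_violation = 0.0
    alphabet = np.array(list(AMINO_ACIDS))
    for _ in range(n_random):
        n = int(rng.integers(4, 16))
        k = int(rng.integers(2, 6))
        letters = rng.choice(alphabet, size=k, replace=False)
        a = rng.choice(letters, size=n)
        b = rng.choice(rng.choice(alphabet, size=k, replace=False), size=n)
        mi_aa, _ = mutual_information(a, a)
        dev_self = max(dev_self, abs(mi_aa - column_entropy(a)))
        mi_const, _ = mutual_information(np.full(n, "A"), b)
        dev_const = max(dev_const, abs(mi_const))
        mi_ab, _ = mutual_information(a, b)
        bound_violation = max(
            bound_violation, mi_ab - min(column_entropy(a), column_entropy(b))
        )
    mi_coupled, _ = mutual_information("AACC", "DDEE")
    return {
        "n_random_pairs": n_random,
        "max_dev_mi_self_vs_entropy": dev_self,
        "max_dev_mi_constant": dev_const,
        "coupled_binary_mi_bits": mi_coupled,
        "max_entropy_bound_violation": max(bound_violation, 0.0),
    }


# ---------------------------------------------------------------------------
# Exhaustive permutation agreement
# ---------------------------------------------------------------------------

def exhaustive_agreement(seed: int, n_panels: int = 20) -> dict:
    """Exact enumeration vs the production path on <=5-species panels."""
    rng = np.random.default_rng(_sub_seed(seed, "exhaustive"))
    worst = 0.0
    n_checked = 0
    for _ in range(n_panels):
        n = int(rng.integers(3, 6))
        la, lb = int(rng.integers(1, 4)), int(rng.integers(1, 4))
        rows_a = [
            (f"S{i}", "".join(rng.choice(list("ACDEF"), la))) for i in range(n)
        ]
        rows_b = [
            (f"S{i}", "".join(rng.choice(list("KLMNP"), lb))) for i in range(n)
        ]
        paired = pair_by_species(
            OrthologAlignment("A", rows_a), OrthologAlignment("B", rows_b), 0.99
        )
        grid = mi_grid(paired)
        p = permutation_pvalues(paired, grid, exhaustive=True)
        n_fact = math.factorial(n)
        for i in range(la):
            for j in range(lb):
                obs, _ = mutual_information(
                    paired.matrix_a[:, i], paired.matrix_b[:, j]
                )
                count = sum(
                    mutual_information(
                        paired.matrix_a[:, i], paired.matrix_b[list(perm), j]
                    )[0]
                    >= obs - 1e-12
                    for perm in itertools.permutations(range(n))
                )
                worst = max(worst, abs(p[i, j] - count / n_fact))
                n_checked += 1
    return {"n_pairs_checked": n_checked, "max_abs_p_difference": worst}


# ---------------------------------------------------------------------------
# Type-I calibration
# ---------------------------------------------------------------------------

def type_one_calibration(
    seed: int,
    n_pairs: int = 500,
    n_species: int = 100,
    m: float = 0.3,
    n_perm: int = 199,
    alpha: float = 0.05,
) -> dict:
    """Rejection rate of the permutation test on independent null pairs.

    Each pair is a fresh two-protein, one-column-each complex with no planted
    coupling, so the ``n_pairs`` p-values are independent and the rejection
    count is binomial(n_pairs, ~alpha).  Ties between permuted and observed
    MI are counted against rejection, making the test slightly conservative.
    """
    base = _sub_seed(seed, "type1")
    rejections = 0
    for k in range(n_pairs):
        spec = SimulationSpec(
            n_species=n_species,
            proteins=[("A", 1), ("B", 1)],
            substitution_prob=m,
            seed=(base + k) % (2**31),
        )
        cx = simulate_complex(spec)
        paired = pair_by_species(cx.alignments["A"], cx.alignments["B"])
        p = permutation_pvalues(
            paired, n_perm=n_perm, seed=(base + 7919 + k) % (2**31)
        )
        rejections += bool(p[0, 0] <= alpha)
    lo, hi = stats.binom.interval(0.95, n_pairs, alpha)
    return {
        "n_null_pairs": n_pairs,
        "alpha": alpha,
        "rejection_rate": rejections / n_pairs,
        "interval_low": lo / n_pairs,
        "interval_high": hi / n_pairs,
    }


# ---------------------------------------------------------------------------
# Headline-pattern study
# ---------------------------------------------------------------------------

COMPLEX_PROTEINS = (
    "SSPN", "SGCA", "SGCB", "SGCD", "SGCG", "SGCE", "SGCZ", "DAG1",
    "GAPDH", "ATP1A1",
)


def headline_study(
    seed: int,
    n_species: int = 200,
    n_columns: int = 20,
    n_planted: int = 12,
    m: float = 0.3,
    gap_prob: float = 0.02,
    n_perm: int = 999,
    q_threshold: float = 0.05,
) -> dict:
    """Power and pattern recovery on a 10-protein complex.

    Perfectly coupled (rho=1) column pairs are planted only between the SSPN
    and SGCG blocks; every other protein (the remaining complex members plus
    the two control blocks) evolves independently.  Measures the fraction of
    planted pairs called significant, whether SSPN–SGCG attains the maximal
    per-protein-pair significant fraction among all 45 pairs, and how many
    of the global top-20 MI-ranked pairs are planted SSPN–SGCG pairs.
    """
    planted = [
        PlantedPair("SSPN", i + 1, "SGCG", i + 1, 1.0) for i in range(n_planted)
    ]
    spec = SimulationSpec(
        n_species=n_species,
        proteins=[(p, n_columns) for p in COMPLEX_PROTEINS],
        planted_pairs=planted,
        substitution_prob=m,
        gap_prob=gap_prob,
        seed=_sub_seed(seed, "headline"),
    )
    cx = simulate_complex(spec)
    scores, summaries = analyze_complex(
        cx.alignments,
        n_perm=n_perm,
        q_threshold=q_threshold,
        seed=_sub_seed(seed, "headline-perm"),
    )
    truth = {(p.protein_a, p.col_a, p.protein_b, p.col_b) for p in planted}

    def _is_planted(a: str, b: str, s) -> bool:
        return ((a, s.col_a, b, s.col_b) in truth) or ((b, s.col_b, a, s.col_a) in truth)

    target = tuple(sorted(("SSPN", "SGCG")))
    planted_scores = [
        s for s in scores[target] if _is_planted(target[0], target[1], s)
    ]
    n_sig_planted = sum(1 for s in planted_scores if s.q_value < q_threshold)
    best = max(summaries, key=lambda s: s.frac_significant)
    flat = [(a, b, s) for (a, b), ss in scores.items() for s in ss]
    top20 = rank_top_pairs(flat, 20)
    n_top20_planted = sum(1 for a, b, s in top20 if _is_planted(a, b, s))
    by_pair = {(s.protein_a, s.protein_b): s for s in summaries}
    return {
        "n_protein_pairs": len(summaries),
        "n_planted": n_planted,
        "planted_power_pct": 100.0 * n_sig_planted / n_planted,
        "best_pair": (best.protein_a, best.protein_b),
        "best_pair_is_sspn_sgcg": float((best.protein_a, best.protein_b) == target),
        "sspn_sgcg_frac_significant": by_pair[target].frac_significant,
        "sspn_sgcg_frac_nonzero_mi": by_pair[target].frac_nonzero_mi,
        "top20_planted_count": n_top20_planted,
        "n_perm": n_perm,
    }


# ---------------------------------------------------------------------------
# BH agreement
# ---------------------------------------------------------------------------

def bh_step_up_reference(p: np.ndarray) -> np.ndarray:
    """Independent BH step-up implementation (oracle only)."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def bh_agreement(seed: int, n_vectors: int = 1000) -> dict:
    """Max |q - q_ref| over random p-vectors of varying length."""
    rng = np.random.default_rng(_sub_seed(seed, "bh"))
    worst = 0.0
    for _ in range(n_vectors):
        n = int(rng.integers(1, 60))
        p = rng.uniform(1e-9, 1.0, size=n)
        worst = max(worst, float(np.abs(bh_qvalues(p) - bh_step_up_reference(p)).max()))
    return {"n_vectors": n_vectors, "max_abs_q_difference": worst}


# ---------------------------------------------------------------------------
# Interface fixture
# ---------------------------------------------------------------------------

def interface_fixture_report(tmp_dir) -> dict:
    """Contact inventory and diff of the synthetic interface structure pair."""
    from pathlib import Path

    from .structure_contacts import (
        SYNTHETIC_CHAIN_MAP_CANONICAL,
        SYNTHETIC_CHAIN_MAP_COMPENSATORY,
        build_synthetic_interface_pair,
        detect_all_contacts,
        diff_interfaces,
        load_structure,
    )

    d = Path(tmp_dir)
    can_text, comp_text = build_synthetic_interface_pair()
    (d / "canonical.pdb").write_text(can_text)
    (d / "compensatory.pdb").write_text(comp_text)
    m1 = load_structure(d / "canonical.pdb", chain_map=SYNTHETIC_CHAIN_MAP_CANONICAL)
    m2 = load_structure(
        d / "compensatory.pdb", chain_map=SYNTHETIC_CHAIN_MAP_COMPENSATORY
    )
    contacts = detect_all_contacts(m1)
    salt = [c for c in contacts if c.type == "salt_bridge"]
    hydro = [c for c in contacts if c.type == "hydrophobic"]

    # brute-force distance recomputation over the qualifying atom sets
    worst = 0.0
    for c in contacts:
        sets = (
            HYDROPHOBIC_CARBONS if c.type == "hydrophobic"
            else {**SALT_BASIC, **SALT_ACIDIC}
        )
        _, pa = m1.atom_coords(c.res_a[0], c.res_a[1], sets[c.res_a[2]])
        _, pb = m1.atom_coords(c.res_b[0], c.res_b[1], sets[c.res_b[2]])
        brute = min(
            float(np.linalg.norm(x - y)) for x, y in itertools.product(pa, pb)
        )
        worst = max(worst, abs(brute - c.min_distance))

    # rigid-body invariance
    theta = 1.1
    rot = np.array(
        [
            [np.cos(theta), -np.sin(theta), 0.0],
            [np.sin(theta), np.cos(theta), 0.0],
            [0.0, 0.0, 1.0],
        ]
    )
    moved = m1.transformed(rot, np.array([7.0, -4.0, 12.0]))
    moved_contacts = detect_all_contacts(moved)
    rigid_dev = max(
        abs(a.min_distance - b.min_distance)
        for a, b in zip(contacts, moved_contacts)
    )

    diff = diff_interfaces(
        m1, m2, SYNTHETIC_CHAIN_CORRESPONDENCE, SYNTHETIC_RESIDUE_CORRESPONDENCE
    )
    return {
        "n_salt_bridges": len(salt),
        "salt_bridge_distance_angstrom": salt[0].min_distance,
        "n_pocket_contacts": len(hydro),
        "max_brute_force_distance_dev": worst,
        "max_rigid_body_distance_dev": rigid_dev,
        "n_conserved": len(diff.conserved),
        "n_substituted_partner": len(diff.substituted_partner),
        "n_lost": len(diff.lost),
        "n_gained": len(diff.gained),
    }


# ---------------------------------------------------------------------------
# Synthetic paralog identity
# ---------------------------------------------------------------------------

def synthetic_paralog_identity(
    seed: int, length: int = 291, divergence: float = 0.47
) -> dict:
    """Percent identity of a synthetic paralog pair at set divergence.

    A stand-in for a real paralog comparison: a random ancestor of
    sarcoglycan-like length is copied, an exact ``divergence`` fraction of
    sites is substituted to different residues and a 5-residue block is
    deleted, and the pair is scored with the standard global-alignment
    identity operation.  Expected identity is close to
    100·(1 - divergence)·(length - 5)/length.
    """
    rng = np.random.default_rng(_sub_seed(seed, "paralog"))
    aa = list(AMINO_ACIDS)
    ancestor = "".join(rng.choice(aa, length))
    mutated = list(ancestor)
    n_sub = round(divergence * length)
    for i in rng.choice(length, size=n_sub, replace=False):
        mutated[i] = rng.choice([c for c in aa if c != mutated[i]])
    # one 5-residue deletion in the middle of the paralog
    del mutated[length // 2 : length // 2 + 5]
    result = global_align_identity(ancestor, "".join(mutated))
    return {
        "length": length,
        "divergence": divergence,
        "percent_identity": result.percent_identity,
        "percent_similarity": result.percent_similarity,
        "expected_identity_pct": 100.0 * (1 - divergence) * (length - 5) / length,
    }
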