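"""End-to-end coevolution runs, plotting-ready tables and the run manifest.

``run_pipeline`` drives the whole analysis: read every protein's MSA from a
directory, pair proteins on shared species, score all residue pairs (MI,
permutation p, BH q), and write

* one TSV of residue-pair scores per protein pair,
* a dot-plot summary table (one row per protein pair with the tested-pair
  count, the fraction significant at the q threshold, and the fraction with
  nonzero MI),
* the global top-K residue pairs ranked by MI,
* a long-format heatmap table of the per-protein-pair significant fractions,
* a JSON manifest echoing every tunable parameter and the seed,

and, when a structure and chain map are supplied, a cross-reference table
stating for each top-K coevolving pair whether the two residues are in 3D
contact.  Given identical inputs and seed the outputs are byte-identical;
per-protein-pair permutation seeds are derived from the pair's sorted names
so results do not depend on iteration order.
"""

from __future__ import annotations

import itertools
import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import __version__
from .alignment_io import (
    DEFAULT_SPECIES_REGEX,
    OrthologAlignment,
    column_reference_labels,
    pair_by_species,
    read_alignment,
)
from .coevolution import (
    ProteinPairSummary,
    ResiduePairScore,
    bh_qvalues,
    rank_top_pairs,
    score_pair,
    summarize_pair,
)
from .structure_contacts import detect_all_contacts, load_structure

MSA_SUFFIXES = {".fa": "fasta", ".fasta": "fasta", ".sto": "stockholm", ".stk": "stockholm"}


@dataclass
class RunConfig:
    """All tunables of one pipeline run (echoed into the manifest)."""

    msa_dir: str
    out_dir: str
    seed: int
    format: str = "auto"
    species_regex: str = DEFAULT_SPECIES_REGEX
    max_gap_frac: float = 0.5
    pairs: list[tuple[str, str]] | None = None
    n_perm: int = 999
    q_threshold: float = 0.05
    top_k: int = 20
    apc: bool = False
    global_fdr: bool = False
    reference_species: str | None = None
    structure_path: str | None = None
    chain_map: dict[str, str] | None = None
    salt_cutoff: float = 4.0
    hydro_cutoff: float = 4.5


def _pair_seed(base_seed: int, protein_a: str, protein_b: str) -> int:
    """Pair-order-independent permutation seed (stable across runs)."""
    tag = "|".join(sorted((protein_a, protein_b)))
    return (base_seed * 2654435761 + zlib.crc32(tag.encode())) % (2**31)


def load_msa_dir(
    msa_dir: str | Path,
    format: str = "auto",
    species_regex: str = DEFAULT_SPECIES_REGEX,
) -> dict[str, OrthologAlignment]:
    """Read every alignment file of a directory, protein id = file stem."""
    alignments: dict[str, OrthologAlignment] = {}
    for path in sorted(Path(msa_dir).iterdir()):
        fmt = MSA_SUFFIXES.get(path.suffix.lower())
        if fmt is None:
            continue
        if format != "auto":
            fmt = format
        alignments[path.stem] = read_alignment(path, fmt, species_regex)
    if len(alignments) < 2:
        raise ValueError(f"{msa_dir}: need at least two protein alignments")
    return alignments


def analyze_complex(
    alignments: dict[str, OrthologAlignment],
    pairs: list[tuple[str, str]] | None = None,
    max_gap_frac: float = 0.5,
    n_perm: int = 999,
    q_threshold: float = 0.05,
    seed: int = 0,
    apc: bool = False,
    global_fdr: bool = False,
    reference_species: str | None = None,
    top_k: int = 20,
) -> tuple[dict[tuple[str, str], list[ResiduePairScore]], list[ProteinPairSummary]]:
    """Score every requested protein pair of a complex.

    Returns the per-pair score lists and the per-pair summaries, both in
    stable sorted pair order.  With ``global_fdr`` the BH correction is
    re-applied jointly across all protein pairs.
    """
    if pairs is None:
        pairs = list(itertools.combinations(sorted(alignments), 2))
    pairs = [tuple(sorted(p)) for p in pairs]
    all_scores: dict[tuple[str, str], list[ResiduePairScore]] = {}
    n_tested: dict[tuple[str, str], int] = {}
    for a, b in pairs:
        paired = pair_by_species(alignments[a], alignments[b], max_gap_frac)
        labels_a = labels_b = None
        if reference_species is not None:
            labels_a = column_reference_labels(alignments[a], reference_species)
            labels_b = column_reference_labels(alignments[b], reference_species)
        scores = score_pair(
            paired,
            n_perm=n_perm,
            seed=_pair_seed(seed, a, b),
            apc=apc,
            labels_a=labels_a,
            labels_b=labels_b,
        )
        all_scores[(a, b)] = scores
        n_tested[(a, b)] = len(paired.cols_a) * len(paired.cols_b)
    if global_fdr:
        flat = [s for ss in all_scores.values() for s in ss]
        qs = bh_qvalues([s.p_value for s in flat])
        for s, q in zip(flat, qs):
            s.q_value = float(q)
    summaries = [
        summarize_pair(
            all_scores[p],
            q_threshold=q_threshold,
            n_pairs_tested=n_tested[p],
            protein_a=p[0],
            protein_b=p[1],
            k_top=top_k,
        )
        for p in pairs
    ]
    return all_scores, summaries


def _score_rows(scores: list[ResiduePairScore]) -> list[str]:
    rows = []
    for s in sorted(scores, key=lambda s: (s.col_a, s.col_b)):
        rows.append(
            f"{s.col_a}\t{s.col_b}\t{s.label_a}\t{s.label_b}\t"
            f"{s.mi:.6f}\t{s.n_eff}\t{s.p_value:.6f}\t{s.q_value:.6f}"
        )
    return rows


SCORE_HEADER = "col_a\tcol_b\tlabel_a\tlabel_b\tmi_bits\tn_eff\tp_value\tq_value"
SUMMARY_HEADER = "protein_a\tprotein_b\tn_pairs_tested\tfrac_significant\tfrac_nonzero_mi"


def export_dotplot_table(
    summaries: list[ProteinPairSummary], path: str | Path, metadata: dict | None = None
) -> None:
    """Write the long-format dot-plot table (one row per protein pair)."""
    if not summaries:
        raise ValueError("no summaries to export")
    lines = [f"# {k} = {v}" for k, v in (metadata or {}).items()]
    lines.append(SUMMARY_HEADER)
    for s in sorted(summaries, key=lambda s: (s.protein_a, s.protein_b)):
        lines.append(
            f"{s.protein_a}\t{s.protein_b}\t{s.n_pairs_tested}\t"
            f"{s.frac_significant:.6f}\t{s.frac_nonzero_mi:.6f}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the full analysis and write every output file.

    Returns a name -> path mapping of the written outputs.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    try:
        alignments = load_msa_dir(config.msa_dir, config.format, config.species_regex)
    except Exception as exc:
        raise RuntimeError(f"[alignment_io] {exc}") from exc

    try:
        all_scores, summaries = analyze_complex(
            alignments,
            pairs=config.pairs,
            max_gap_frac=config.max_gap_frac,
            n_perm=config.n_perm,
            q_threshold=config.q_threshold,
            seed=config.seed,
            apc=config.apc,
            global_fdr=config.global_fdr,
            reference_species=config.reference_species,
            top_k=config.top_k,
        )
    except Exception as exc:
        raise RuntimeError(f"[coevolution] {exc}") from exc

    meta = {
        "tool": f"coevmi {__version__}",
        "mi_units": "bits",
        "seed": config.seed,
        "n_perm": config.n_perm,
        "q_threshold": config.q_threshold,
        "max_gap_frac": config.max_gap_frac,
        "apc": config.apc,
        "global_fdr": config.global_fdr,
    }

    pair_dir = out_dir / "pair_scores"
    pair_dir.mkdir(exist_ok=True)
    for (a, b), scores in sorted(all_scores.items()):
        p = pair_dir / f"{a}__{b}.tsv"
        lines = [f"# {k} = {v}" for k, v in meta.items()]
        lines.append(SCORE_HEADER)
        lines.extend(_score_rows(scores))
        p.write_text("\n".join(lines) + "\n")
        outputs[f"scores:{a}__{b}"] = p

    summary_path = out_dir / "summary.tsv"
    export_dotplot_table(summaries, summary_path, meta)
    outputs["summary"] = summary_path

    flat = [(a, b, s) for (a, b), ss in sorted(all_scores.items()) for s in ss]
    top = rank_top_pairs(flat, k=config.top_k)
    top_path = out_dir / f"top{config.top_k}.tsv"
    lines = [f"# {k} = {v}" for k, v in meta.items()]
    lines.append("rank\tprotein_a\tprotein_b\t" + SCORE_HEADER)
    for rank, (a, b, s) in enumerate(top, 1):
        lines.append(
            f"{rank}\t{a}\t{b}\t{s.col_a}\t{s.col_b}\t{s.label_a}\t{s.label_b}\t"
            f"{s.mi:.6f}\t{s.n_eff}\t{s.p_value:.6f}\t{s.q_value:.6f}"
        )
    top_path.write_text("\n".join(lines) + "\n")
    outputs["top_pairs"] = top_path

    heat_path = out_dir / "heatmap_long.tsv"
    lines = [f"# {k} = {v}" for k, v in meta.items()]
    lines.append(SUMMARY_HEADER)
    for s in sorted(summaries, key=lambda s: (s.protein_a, s.protein_b)):
        for pa, pb in ((s.protein_a, s.protein_b), (s.protein_b, s.protein_a)):
            lines.append(
                f"{pa}\t{pb}\t{s.n_pairs_tested}\t"
                f"{s.frac_significant:.6f}\t{s.frac_nonzero_mi:.6f}"
            )
    heat_path.write_text("\n".join(lines) + "\n")
    outputs["heatmap"] = heat_path

    if config.structure_path:
        try:
            outputs["contact_xref"] = _contact_xref(
                config, alignments, top, out_dir, meta
            )
        except Exception as exc:
            raise RuntimeError(f"[structure_contacts] {exc}") from exc

    manifest = {
        "tool": "coevmi",
        "version": __version__,
        "config": asdict(config),
        "proteins": sorted(alignments),
        "n_species": {p: len(a.species) for p, a in sorted(alignments.items())},
        "outputs": {k: str(v) for k, v in sorted(outputs.items())},
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    outputs["manifest"] = manifest_path
    return outputs


def _contact_xref(config, alignments, top, out_dir: Path, meta: dict) -> Path:
    """Cross-reference top coevolving pairs with 3D interchain contacts.

    Requires a reference species (to translate alignment columns to residue
    numbers) and a chain map naming which chain carries which protein.
    """
    if config.reference_species is None:
        raise ValueError("contact cross-reference requires reference_species")
    if not config.chain_map:
        raise ValueError("contact cross-reference requires a chain map")
    model = load_structure(config.structure_path, chain_map=config.chain_map)
    contacts = detect_all_contacts(model, config.salt_cutoff, config.hydro_cutoff)
    protein_chain = {prot: ch for ch, prot in model.chains}
    from .alignment_io import reference_position_map

    col_to_res = {
        prot: {c: r for r, c in reference_position_map(aln, config.reference_species).items()}
        for prot, aln in alignments.items()
    }
    contact_index: dict[frozenset, str] = {}
    for c in contacts:
        key = frozenset(((c.res_a[0], c.res_a[1]), (c.res_b[0], c.res_b[1])))
        contact_index.setdefault(key, c.type)

    path = out_dir / "top_pairs_contacts.tsv"
    lines = [f"# {k} = {v}" for k, v in meta.items()]
    lines.append(
        "rank\tprotein_a\tprotein_b\tcol_a\tcol_b\tres_a\tres_b\tmi_bits\t"
        "q_value\tin_contact\tcontact_type"
    )
    for rank, (a, b, s) in enumerate(top, 1):
        ra = col_to_res.get(a, {}).get(s.col_a)
        rb = col_to_res.get(b, {}).get(s.col_b)
        ctype = ""
        in_contact = 0
        if ra is not None and rb is not None and a in protein_chain and b in protein_chain:
            key = frozenset(((protein_chain[a], ra), (protein_chain[b], rb)))
            if key in contact_index:
                in_contact, ctype = 1, contact_index[key]
        lines.append(
            f"{rank}\t{a}\t{b}\t{s.col_a}\t{s.col_b}\t{ra or ''}\t{rb or ''}\t"
            f"{s.mi:.6f}\t{s.q_value:.6f}\t{in_contact}\t{ctype}"
        )
    path.write_text("\n".join(lines) + "\n")
    return path
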