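"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator is a pure function of its arguments (including the seed,
consumed through a dedicated ``numpy`` PCG64 generator — no global RNG
state) and returns the latent truth it embeds alongside the data: class
labels for bimodal proteomes, realized identity for diverged pairs, true
internal states for Brownian-motion simulations, and the constructed
overlap structure for gene-coordinate tables.  This makes every downstream
estimator testable as a recovery problem.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import numpy as np

from .ancestral import Tree
from .markers import MarkerHitTable, MarkerSet
from .proteome import CANONICAL_AA, Proteome

__all__ = [
    "gen_proteome", "gen_bimodal_proteome", "gen_diverged_pair",
    "gen_marker_table", "gen_tree", "simulate_bm",
    "gen_annotations", "AnnotationTable",
    "ACIDIC_WEIGHTS", "BASIC_WEIGHTS",
]

_AA = np.array(list(CANONICAL_AA))

# Default class compositions for bimodal proteomes: a flat background with
# the charged residues of one polarity strongly enriched, which puts the
# two pI modes near ~4 and ~10 as in real archaeal proteomes.
ACIDIC_WEIGHTS = {aa: 1.0 for aa in CANONICAL_AA} | {"D": 8.0, "E": 8.0}
BASIC_WEIGHTS = {aa: 1.0 for aa in CANONICAL_AA} | {"K": 8.0, "R": 8.0}


def _weight_vector(weights: dict[str, float]) -> np.ndarray:
    vec = np.zeros(len(_AA))
    for aa, w in weights.items():
        if aa not in CANONICAL_AA:
            raise ValueError(f"non-canonical residue in weights: {aa!r}")
        if w < 0:
            raise ValueError(f"negative weight for {aa!r}")
        vec[CANONICAL_AA.index(aa)] = w
    if vec.sum() == 0:
        raise ValueError("all residue weights are zero")
    return vec / vec.sum()


def _draw_proteins(rng: np.random.Generator, n: int,
                   length_range: tuple[int, int], probs: np.ndarray,
                   prefix: str) -> list[tuple[str, str]]:
    lo, hi = length_range
    if lo < 1 or hi < lo:
        raise ValueError(f"invalid length range: {length_range}")
    records = []
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(_AA, size=length, p=probs))
        records.append((f"{prefix}{i:05d}", seq))
    return records


def gen_proteome(n_proteins: int, length_range: tuple[int, int],
                 residue_weights: dict[str, float], seed: int,
                 genome_id: str = "synthetic") -> Proteome:
    """Random proteome with residues drawn i.i.d. from normalized weights."""
    rng = np.random.default_rng(seed)
    probs = _weight_vector(residue_weights)
    records = _draw_proteins(rng, n_proteins, length_range, probs, "p")
    return Proteome(genome_id=genome_id, records=records)


def gen_bimodal_proteome(n: int, frac_acidic: float, seed: int,
                         acidic_weights: dict[str, float] | None = None,
                         basic_weights: dict[str, float] | None = None,
                         length_range: tuple[int, int] = (80, 200),
                         genome_id: str = "bimodal",
                         ) -> tuple[Proteome, list[str]]:
    """Two-class proteome: D/E-enriched acidic and K/R-enriched basic proteins.

    Returns the proteome and the true class label (``"acidic"``/``"basic"``)
    of each protein, in record order.  ``round(n · frac_acidic)`` proteins
    are acidic.
    """
    if not 0.0 <= frac_acidic <= 1.0:
        raise ValueError(f"frac_acidic out of [0, 1]: {frac_acidic}")
    if n == 0:
        import warnings
        warnings.warn("empty bimodal proteome requested")
        return Proteome(genome_id=genome_id, records=[]), []
    rng = np.random.default_rng(seed)
    p_acid = _weight_vector(acidic_weights or ACIDIC_WEIGHTS)
    p_base = _weight_vector(basic_weights or BASIC_WEIGHTS)
    n_acidic = round(n * frac_acidic)
    records = _draw_proteins(rng, n_acidic, length_range, p_acid, "acid_")
    records += _draw_proteins(rng, n - n_acidic, length_range, p_base, "base_")
    labels = ["acidic"] * n_acidic + ["basic"] * (n - n_acidic)
    return Proteome(genome_id=genome_id, records=records), labels


def gen_diverged_pair(base: Proteome, sub_rate: float, seed: int
                      ) -> tuple[Proteome, Proteome, float]:
    """Point-substituted copy of a proteome with its realized identity.

    Each residue is independently replaced (probability ``sub_rate``) by a
    uniformly random *different* canonical residue.  The returned
    ``true_identity`` is the exact realized fraction of unchanged residues,
    not the nominal rate.
    """
    if not 0.0 <= sub_rate < 1.0:
        raise ValueError(f"sub_rate out of [0, 1): {sub_rate}")
    if len(base) == 0:
        raise ValueError("empty base proteome")
    rng = np.random.default_rng(seed)
    mutated_records = []
    n_same = 0
    n_total = 0
    for pid, seq in base:
        chars = np.array(list(seq))
        hit = rng.random(len(chars)) < sub_rate
        for idx in np.flatnonzero(hit):
            alternatives = [aa for aa in CANONICAL_AA if aa != chars[idx]]
            chars[idx] = alternatives[int(rng.integers(len(alternatives)))]
        n_same += int(len(chars) - hit.sum())
        n_total += len(chars)
        mutated_records.append((pid, "".join(chars)))
    derived = Proteome(genome_id=f"{base.genome_id}_derived", records=mutated_records)
    return base, derived, n_same / n_total


def gen_marker_table(genome_ids: list[str], marker_set: MarkerSet,
                     completeness: float, contamination: float, seed: int,
                     genus_map: dict[str, str] | None = None) -> MarkerHitTable:
    """Marker copy counts hitting exact completeness/contamination targets.

    Per genome, ``round(completeness·|set|)`` randomly chosen markers are
    present once and ``round(contamination·|set|)`` of those are duplicated
    (count 2), so the QC formulas recover the targets exactly up to
    rounding.
    """
    if not 0.0 <= completeness <= 1.0:
        raise ValueError(f"completeness out of [0, 1]: {completeness}")
    if contamination < 0:
        raise ValueError(f"negative contamination: {contamination}")
    rng = np.random.default_rng(seed)
    size = len(marker_set)
    n_present = round(completeness * size)
    n_dup = min(round(contamination * size), n_present)
    counts: dict[str, dict[str, int]] = {}
    for genome in genome_ids:
        chosen = rng.choice(size, size=n_present, replace=False)
        row = {marker_set.marker_ids[i]: 1 for i in chosen}
        for i in chosen[:n_dup]:
            row[marker_set.marker_ids[i]] = 2
        counts[genome] = row
    return MarkerHitTable(counts, genus_map)


# ---------------------------------------------------------------------------
# Trees and Brownian motion
# ---------------------------------------------------------------------------

def gen_tree(n_tips: int, mode: str = "random-split", seed: int = 0,
             branch_range: tuple[float, float] = (0.1, 1.0)) -> Tree:
    """Rooted binary tree with uniform random branch lengths.

    ``balanced`` splits tip sets in half recursively; ``random-split``
    draws the split point uniformly, giving variable (pectinate-to-bushy)
    shapes.
    """
    if n_tips < 2:
        raise ValueError(f"need at least 2 tips, got {n_tips}")
    if mode not in ("balanced", "random-split"):
        raise ValueError(f"unknown mode: {mode!r}")
    rng = np.random.default_rng(seed)
    labels = [f"t{i}" for i in range(n_tips)]

    def build(names: list[str]) -> str:
        if len(names) == 1:
            return names[0]
        if mode == "balanced":
            k = len(names) // 2
        else:
            k = int(rng.integers(1, len(names)))
        bl_left = rng.uniform(*branch_range)
        bl_right = rng.uniform(*branch_range)
        return (f"({build(names[:k])}:{bl_left:.6f},"
                f"{build(names[k:])}:{bl_right:.6f})")

    return Tree.from_newick(build(labels) + ";")


def simulate_bm(tree: Tree, sigma2: float, root_state: float, seed: int
                ) -> tuple[dict[str, float], dict[str, float]]:
    """Brownian-motion trait simulation with exact Gaussian increments.

    Child value = parent value + Normal(0, sigma2·branch_length).  Returns
    ``(tip_traits, true_internal_states)`` keyed by tip and internal node
    labels; the root's true state is ``root_state``.
    """
    if sigma2 < 0:
        raise ValueError(f"negative sigma2: {sigma2}")
    tree.require_branch_lengths()
    rng = np.random.default_rng(seed)
    values: dict[int, float] = {}
    tips: dict[str, float] = {}
    internals: dict[str, float] = {}
    for node in tree.dendropy_tree.preorder_node_iter():
        if node.parent_node is None:
            values[id(node)] = float(root_state)
        else:
            bl = float(node.edge.length)
            step = rng.normal(0.0, math.sqrt(sigma2 * bl)) if sigma2 > 0 else 0.0
            values[id(node)] = values[id(node.parent_node)] + step
        if node.is_leaf():
            tips[node.taxon.label] = values[id(node)]
        else:
            internals[node.label] = values[id(node)]
    return tips, internals


# ---------------------------------------------------------------------------
# Gene-coordinate tables
# ---------------------------------------------------------------------------

@dataclass
class AnnotationTable:
    """CDS intervals (1-based inclusive) on one or more contigs."""

    rows: list[tuple[str, int, int, str]]  # (seq_id, start, end, strand)

    def __post_init__(self) -> None:
        for seq_id, start, end, strand in self.rows:
            if start < 1 or end < start:
                raise ValueError(f"bad interval {start}-{end} on {seq_id}")
            if strand not in "+-":
                raise ValueError(f"bad strand {strand!r}")

    def __len__(self) -> int:
        return len(self.rows)


def gen_annotations(genome_length: int, n_genes: int, overlap_fraction: float,
                    seed: int, gene_length_range: tuple[int, int] = (90, 300),
                    seq_id: str = "contig1") -> AnnotationTable:
    """Gene-coordinate table with an exact constructed overlap fraction.

    ``round(n_genes·overlap_fraction)`` genes are laid out in overlapping
    runs (each sharing ≥1 bp with a neighbour); the rest are separated by
    ≥1 bp gaps.  Raises if the genes cannot be packed into
    ``genome_length`` or if exactly one overlapping gene is requested
    (an overlap needs a partner).
    """
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError(f"overlap_fraction out of [0, 1]: {overlap_fraction}")
    if n_genes < 1:
        raise ValueError("need at least one gene")
    n_overlap = round(n_genes * overlap_fraction)
    if n_overlap == 1:
        raise ValueError("cannot construct exactly one overlapping gene")
    rng = np.random.default_rng(seed)
    lo, hi = gene_length_range

    lengths = rng.integers(lo, hi + 1, size=n_genes)
    # overlapping genes come first, chained with small overlaps
    overlaps = rng.integers(1, max(2, lo // 3), size=max(n_overlap - 1, 0))
    rows: list[tuple[str, int, int, str]] = []
    pos = 1
    for i in range(n_overlap):
        if i > 0:
            pos = rows[-1][2] - int(overlaps[i - 1]) + 1  # step back to overlap
            pos = max(pos, rows[-1][1] + 1)  # never fully contain the previous gene
        start = pos
        end = start + int(lengths[i]) - 1
        rows.append((seq_id, start, end, "+" if rng.random() < 0.5 else "-"))
        pos = end + 2  # default next position (overridden by chain step-back)
    if n_overlap:
        pos = rows[-1][2] + 2  # gap after the overlapping block
    for i in range(n_overlap, n_genes):
        start = pos
        end = start + int(lengths[i]) - 1
        rows.append((seq_id, start, end, "+" if rng.random() < 0.5 else "-"))
        pos = end + 2
    max_end = max(end for _, _, end, _ in rows)
    if max_end > genome_length:
        raise ValueError(
            f"cannot pack {n_genes} genes into {genome_length} bp "
            f"(need ≥{max_end})"
        )
    return AnnotationTable(rows=rows)
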