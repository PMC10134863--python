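"""Single-copy-marker genome quality control with lineage-aware exclusions.

Completeness and contamination of a MAG are estimated from the occurrence
of single-copy marker genes (SCGs): completeness is the percentage of
expected markers present at least once, contamination the percentage of
excess copies.  Deep-branching DPANN-like lineages genuinely lack some of
the universal archaeal markers, which deflates completeness estimates; the
remedy implemented here is to derive, per genus, the set of markers missing
from *every* member genome and drop those from the expected set before
scoring (``derive_exclusion`` → ``adjusted_set``).

The module ships curated absence lists for five Parvarchaeales-related
genera (Jingweiarchaeum, Haiyanarchaeum, Rehaiarchaeum,
Acidifodinimicrobium, Parvarchaeum) against the 149-marker archaeal
CheckM-style set, plus the nine markers absent across all of them.

Contamination uses the simple per-marker excess-copy formula
``100·Σ max(count−1, 0)/|set|``; collocated-marker-set weighting (as in the
full CheckM machinery) is deliberately out of scope.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "MarkerSet", "MarkerHitTable", "QualityReport",
    "SHARED_MISSING", "GENUS_EXCLUSIONS",
    "checkm149_set", "scg48_set",
    "scg_occurrence", "derive_exclusion", "adjusted_set",
    "completeness", "contamination", "quality_report", "quality_tier",
    "read_hits_tsv", "write_reports_tsv",
    "read_exclusion_config", "write_exclusion_config",
]


@dataclass(frozen=True)
class MarkerSet:
    """An ordered, duplicate-free collection of marker accessions."""

    name: str
    marker_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.marker_ids:
            raise ValueError(f"marker set {self.name!r} is empty")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValueError(f"duplicate marker ids in set {self.name!r}")

    def __len__(self) -> int:
        return len(self.marker_ids)

    def __contains__(self, marker_id: str) -> bool:
        return marker_id in set(self.marker_ids)


# Markers absent from every genome of all five genera (vs the 149-marker
# archaeal set); also the full per-genus absence lists.
SHARED_MISSING: tuple[str, ...] = (
    "PF01849.13", "PF01912.13", "PF01922.12", "PF04127.10", "PF05221.12",
    "PF06026.9", "TIGR00336", "TIGR00670", "TIGR01213",
)

GENUS_EXCLUSIONS: dict[str, tuple[str, ...]] = {
    "Jingweiarchaeum": (
        "PF01849.13", "PF01912.13", "PF01922.12", "PF04127.10", "PF05221.12",
        "PF06026.9", "TIGR00336", "TIGR00670", "TIGR01213",
    ),
    "Haiyanarchaeum": (
        "PF00398.15", "TIGR02076", "PF06418.9", "PF01725.11", "PF04019.7",
        "TIGR00270", "TIGR00057", "PF00832.15", "TIGR00549", "PF01982.11",
        "PF00958.17", "PF01864.12", "PF01849.13", "PF01912.13", "TIGR00670",
        "PF06026.9", "PF01922.12", "PF04127.10", "PF05221.12", "TIGR00336",
        "TIGR01213",
    ),
    "Rehaiarchaeum": (
        "PF00900.15", "PF00466.15", "TIGR02338", "PF04010.8", "TIGR00422",
        "TIGR00344", "PF06418.9", "PF01282.14", "PF01725.11", "PF04019.7",
        "PF00831.18", "TIGR00057", "TIGR03677", "TIGR00432", "PF13685.1",
        "PF00832.15", "TIGR00549", "PF01982.11", "PF00958.17", "PF01864.12",
        "PF01849.13", "PF01912.13", "TIGR00670", "PF06026.9", "PF01922.12",
        "PF04127.10", "PF05221.12", "TIGR00336", "TIGR01213",
    ),
    "Acidifodinimicrobium": (
        "PF02005.11", "PF08071.7", "TIGR02076", "PF01725.11", "PF04019.7",
        "PF00831.18", "TIGR00057", "TIGR03677", "TIGR00432", "PF13685.1",
        "PF00832.15", "TIGR00549", "PF01982.11", "PF00958.17", "PF01864.12",
        "PF01849.13", "PF01912.13", "TIGR00670", "PF06026.9", "PF01922.12",
        "PF04127.10", "PF05221.12", "TIGR00336", "TIGR01213",
    ),
    "Parvarchaeum": (
        "TIGR03677", "TIGR00432", "PF13685.1", "PF00832.15", "TIGR00549",
        "PF01982.11", "PF00958.17", "PF01864.12", "PF01849.13", "PF01912.13",
        "TIGR00670", "PF06026.9", "PF01922.12", "PF04127.10", "PF05221.12",
        "TIGR00336", "TIGR01213",
    ),
}


def _padded_set(name: str, known: Iterable[str], size: int, prefix: str) -> MarkerSet:
    known = list(dict.fromkeys(known))
    if len(known) > size:
        raise ValueError(f"more known ids than set size for {name}")
    fillers = [f"{prefix}{i:03d}" for i in range(size - len(known))]
    return MarkerSet(name=name, marker_ids=tuple(known + fillers))


def checkm149_set() -> MarkerSet:
    """The 149-marker archaeal set.

    Only the accessions appearing in the shipped exclusion lists are known
    by name; the remainder are editable ``ARC_MARKER_*`` placeholders users
    should replace with their own accession list when scoring real HMM
    output.  All set arithmetic (exclusion, completeness denominators) is
    exact regardless of naming.
    """
    known: list[str] = []
    for ids in GENUS_EXCLUSIONS.values():
        known.extend(ids)
    return _padded_set("checkm149", known, 149, "ARC_MARKER_")


def scg48_set() -> MarkerSet:
    """The 48-SCG DPANN screening set (placeholder accessions, editable)."""
    return _padded_set("scg48", [], 48, "SCG_")


class MarkerHitTable:
    """Copy counts of markers per genome, with optional genus labels.

    Backed by a nested dict ``{genome_id: {marker_id: count}}``; absent
    pairs count zero.
    """

    def __init__(self,
                 counts: Mapping[str, Mapping[str, int]],
                 genus: Mapping[str, str] | None = None) -> None:
        self._counts: dict[str, dict[str, int]] = {}
        for genome, row in counts.items():
            clean: dict[str, int] = {}
            for marker, c in row.items():
                c = int(c)
                if c < 0:
                    raise ValueError(
                        f"negative count for ({genome}, {marker}): {c}")
                if c > 0:
                    clean[marker] = c
            self._counts[genome] = clean
        self.genus: dict[str, str] = dict(genus) if genus else {}

    @property
    def genomes(self) -> list[str]:
        return sorted(self._counts)

    def count(self, genome_id: str, marker_id: str) -> int:
        self._require(genome_id)
        return self._counts[genome_id].get(marker_id, 0)

    def row(self, genome_id: str) -> dict[str, int]:
        self._require(genome_id)
        return dict(self._counts[genome_id])

    def _require(self, genome_id: str) -> None:
        if genome_id not in self._counts:
            raise KeyError(f"genome {genome_id!r} absent from marker hit table")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"genome_id": g, "marker_id": m, "count": c}
            for g in self.genomes
            for m, c in sorted(self._counts[g].items())
        ]
        return pd.DataFrame(rows, columns=["genome_id", "marker_id", "count"])


def read_hits_tsv(path: str | os.PathLike,
                  genus_map_path: str | os.PathLike | None = None) -> MarkerHitTable:
    """Read a long-form hits TSV (genome_id, marker_id, count)."""
    df = pd.read_csv(path, sep="\t")
    counts: dict[str, dict[str, int]] = {}
    for rec in df.itertuples(index=False):
        counts.setdefault(str(rec.genome_id), {})[str(rec.marker_id)] = int(rec.count)
    genus = None
    if genus_map_path is not None:
        gdf = pd.read_csv(genus_map_path, sep="\t")
        genus = dict(zip(gdf["genome_id"].astype(str), gdf["genus"].astype(str)))
    return MarkerHitTable(counts, genus)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def scg_occurrence(hits: MarkerHitTable, marker_set: MarkerSet) -> dict[str, tuple[int, int]]:
    """Per genome: (number of set markers present ≥1×, total copies)."""
    out = {}
    for genome in hits.genomes:
        row = hits.row(genome)
        present = sum(1 for m in marker_set.marker_ids if row.get(m, 0) >= 1)
        copies = sum(row.get(m, 0) for m in marker_set.marker_ids)
        out[genome] = (present, copies)
    return out


def derive_exclusion(hits: MarkerHitTable, marker_set: MarkerSet,
                     genus_map: Mapping[str, str] | None = None) -> dict[str, tuple[str, ...]]:
    """Per genus, the set markers missing from every member genome.

    These are the markers a lineage plausibly never had, and hence the ones
    to drop from its expected set before estimating completeness.
    """
    genus_map = dict(genus_map) if genus_map is not None else hits.genus
    missing_label = [g for g in hits.genomes if g not in genus_map]
    if missing_label:
        raise ValueError(f"genomes without genus assignment: {missing_label}")
    members: dict[str, list[str]] = {}
    for genome, genus in genus_map.items():
        if genome in set(hits.genomes):
            members.setdefault(genus, []).append(genome)
    out: dict[str, tuple[str, ...]] = {}
    for genus, genomes in sorted(members.items()):
        if not genomes:
            raise ValueError(f"genus {genus!r} has no genomes")
        absent = tuple(
            m for m in marker_set.marker_ids
            if all(hits.count(g, m) == 0 for g in genomes)
        )
        out[genus] = absent
    return out


def adjusted_set(marker_set: MarkerSet, exclusion: Iterable[str]) -> MarkerSet:
    """Remove an exclusion list from a marker set, preserving order."""
    exclusion = set(exclusion)
    stray = exclusion - set(marker_set.marker_ids)
    if stray:
        raise ValueError(f"exclusion ids not in set {marker_set.name!r}: {sorted(stray)}")
    kept = tuple(m for m in marker_set.marker_ids if m not in exclusion)
    if not kept:
        raise ValueError("exclusion would empty the marker set")
    return MarkerSet(name=f"{marker_set.name}-adjusted", marker_ids=kept)


def completeness(hits: MarkerHitTable, genome_id: str, marker_set: MarkerSet) -> float:
    """Percentage of expected markers present at least once."""
    row = hits.row(genome_id)
    present = sum(1 for m in marker_set.marker_ids if row.get(m, 0) >= 1)
    return 100.0 * present / len(marker_set)


def contamination(hits: MarkerHitTable, genome_id: str, marker_set: MarkerSet) -> float:
    """Percentage of excess marker copies: 100·Σ max(count−1, 0)/|set|."""
    row = hits.row(genome_id)
    excess = sum(max(row.get(m, 0) - 1, 0) for m in marker_set.marker_ids)
    return 100.0 * excess / len(marker_set)


@dataclass
class QualityReport:
    genome_id: str
    completeness: float
    contamination: float
    marker_set_used: str
    n_expected: int
    n_present: int
    n_multicopy: int
    tier: str | None = None


def quality_report(hits: MarkerHitTable, genome_id: str,
                   marker_set: MarkerSet) -> QualityReport:
    row = hits.row(genome_id)
    present = [m for m in marker_set.marker_ids if row.get(m, 0) >= 1]
    multi = [m for m in marker_set.marker_ids if row.get(m, 0) >= 2]
    return QualityReport(
        genome_id=genome_id,
        completeness=completeness(hits, genome_id, marker_set),
        contamination=contamination(hits, genome_id, marker_set),
        marker_set_used=marker_set.name,
        n_expected=len(marker_set),
        n_present=len(present),
        n_multicopy=len(multi),
    )


def quality_tier(report: QualityReport, has_rrna: bool, n_trna: int) -> str:
    """MIMAG-style tier: high / medium / low.

    High needs completeness ≥90%, contamination <5%, both rRNAs and >18
    tRNAs; medium needs completeness >50% and contamination <5%.
    """
    if (report.completeness >= 90.0 and report.contamination < 5.0
            and has_rrna and n_trna > 18):
        return "high"
    if report.completeness > 50.0 and report.contamination < 5.0:
        return "medium"
    return "low"


def write_reports_tsv(reports: Iterable[QualityReport], path: str | os.PathLike) -> None:
    df = pd.DataFrame([{
        "genome_id": r.genome_id,
        "completeness_pct": r.completeness,
        "contamination_pct": r.contamination,
        "marker_set": r.marker_set_used,
        "n_expected": r.n_expected,
        "n_present": r.n_present,
        "n_multicopy": r.n_multicopy,
        "tier": r.tier if r.tier is not None else "",
    } for r in reports])
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Exclusion-list config (plain text, one genus per block)
# ---------------------------------------------------------------------------

def write_exclusion_config(exclusions: Mapping[str, Iterable[str]],
                           path: str | os.PathLike) -> None:
    """Write exclusion lists as ``[genus]`` blocks of one accession per line."""
    with open(path, "w") as fh:
        for genus in sorted(exclusions):
            fh.write(f"[{genus}]\n")
            for marker in exclusions[genus]:
                fh.write(f"{marker}\n")
            fh.write("\n")


def read_exclusion_config(path: str | os.PathLike) -> dict[str, tuple[str, ...]]:
    out: dict[str, list[str]] = {}
    current: str | None = None
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("[") and line.endswith("]"):
                current = line[1:-1]
                out[current] = []
            else:
                if current is None:
                    raise ValueError(f"marker id before any [genus] header: {line}")
                out[current].append(line)
    return {g: tuple(ids) for g, ids in out.items()}
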