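"""Lineage-aware marker QC: deriving per-genus exclusions and scoring genomes.

Single-copy-marker completeness penalises lineages that genuinely lack
some universal markers.  This example builds a hit table for a genus that
is missing a fixed block of markers in every genome, derives the exclusion
list from the table itself, and shows how completeness changes when the
expected set is adjusted.
"""

from revecol import (MarkerHitTable, adjusted_set, checkm149_set,
                     completeness, contamination, derive_exclusion)
from revecol.markers import GENUS_EXCLUSIONS

markers = checkm149_set()

# three genomes of one genus, all missing the same curated 17-marker block
absent = set(GENUS_EXCLUSIONS["Parvarchaeum"])
counts = {
    f"parv_{i}": {m: 1 for m in markers.marker_ids if m not in absent}
    for i in range(3)
}
hits = MarkerHitTable(counts, genus={g: "Parvarchaeum" for g in counts})

excl = derive_exclusion(hits, markers)["Parvarchaeum"]
adj = adjusted_set(markers, excl)

print(f"marker set: {len(markers)} markers")
print(f"derived exclusion list: {len(excl)} markers absent in every genome")
print(f"adjusted set: {len(adj)} markers")
for g in hits.genomes:
    before = completeness(hits, g, markers)
    after = completeness(hits, g, adj)
    print(f"{g}: completeness {before:.1f}% -> {after:.1f}% "
          f"(contamination {contamination(hits, g, adj):.1f}%)")
print()
print("Markers the whole genus lacks are treated as lineage absences, not")
print("assembly gaps, so excluding them restores completeness to 100%.")
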