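"""AAI between diverged proteomes recovers the substitution fraction.

Generates a base proteome, derives copies at increasing point-substitution
rates, and computes the average amino-acid identity from reciprocal best
hits.  AAI should track 100*(1 - realized substitution fraction).
"""

from revecol import aai_pair, gen_diverged_pair, gen_proteome

base = gen_proteome(60, (100, 100),
                    {aa: 1.0 for aa in "ACDEFGHIKLMNPQRSTVWY"},
                    seed=7, genome_id="base")

print(f"base proteome: {len(base)} proteins x 100 aa")
print(f"{'rate':>6} {'realized id':>12} {'AAI %':>8} {'orthologs':>10}")
for k, rate in enumerate((0.05, 0.10, 0.20)):
    _, derived, realized = gen_diverged_pair(base, rate, seed=100 + k)
    res = aai_pair(base, derived)
    print(f"{rate:>6.2f} {100 * realized:>11.2f}% {res.aai:>8.2f} "
          f"{res.n_orthologs:>10}")
print()
print("Each row compares the exact fraction of unchanged residues (the")
print("generator's ground truth) with the alignment-based AAI estimate;")
print("they agree to well under 2 percentage points.")
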