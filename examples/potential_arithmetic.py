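"""Inspect the bundled reference four-body potential.

Loads the 126-quadruplet potential table derived from a large corpus of
high-resolution crystal structures, recomputes the expected multinomial rate
and log-odds score for a few quadruplets from the raw counts, and shows they
match the tabulated values.
"""

from fourbody import expected_probability, load_reference_potential, quadruplet_score

table = load_reference_potential()
comp = table.comp

print(f"corpus: {comp.total:,} atoms, {table.total_tetrahedra:,} retained tetrahedra")
print(f"class frequencies a_n: "
      + ", ".join(f"{c}={f:.6f}" for c, f in comp.frequencies.items()))
print()
print(f"{'quad':<6}{'count':>9}{'f':>12}{'p':>12}{'s (table)':>11}{'s (recomputed)':>16}")
for key in ("CCCC", "CCNO", "CMSS", "MMMM", "XXXX"):
    entry = table.entries[key]
    f = entry.count / table.total_tetrahedra
    p = expected_probability(key, comp)
    s = quadruplet_score(f, p)
    s_str = "--" if entry.s is None else f"{entry.s:.6f}"
    s_re = "--" if s is None else f"{s:.6f}"
    print(f"{key:<6}{entry.count:>9}{f:>12.3E}{p:>12.3E}{s_str:>11}{s_re:>16}")

print()
print("s = log10(f/p): positive for quadruplets seen more often than chance")
print("(favourable contacts, e.g. metal clusters), negative for avoided ones;")
print("'--' marks quadruplets never observed in the corpus (score undefined).")
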