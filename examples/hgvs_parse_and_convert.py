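"""Parse HGVS expressions and convert a variant between coordinate systems.

First parses the four canonical forms (genomic, coding, non-coding, protein)
to show the grammar, then builds a record and walks one substitution through
g. -> c. -> p.: the same variant reported on the genomic sequence, on the
transcript, and as its predicted protein consequence.
"""

from lrgkit import (
    CdnaCoord,
    FixtureSpec,
    build_record,
    c_to_g,
    convert_variant,
    format_hgvs,
    make_fixture,
    parse_hgvs,
)

for expr in ("LRG_1:g.8463G>C", "LRG_1t1:c.572G>C",
             "LRG_163t1:n.5C>T", "LRG_1p1:p.Gly191Ala"):
    v = parse_hgvs(expr)
    print(f"{expr:24s} -> system={v.system} selector={v.selector} "
          f"position={v.position}")

genome, model = make_fixture(FixtureSpec(seed=7))
record = build_record(genome, model, lrg_number=1)
t1 = record.fixed.transcript("t1")

# pick the middle base of codon 4 and mutate it
g_pos = c_to_g(t1, CdnaCoord("cds", 11))
ref = record.fixed.genomic_sequence[g_pos - 1]
alt = "C" if ref != "C" else "T"
v_g = parse_hgvs(f"LRG_1:g.{g_pos}{ref}>{alt}")
v_c = convert_variant(record, v_g, "c")
v_p = convert_variant(record, v_g, "p")

print()
print(f"genomic    : {format_hgvs(v_g)}")
print(f"coding     : {format_hgvs(v_c)}   (same base, transcript coordinates)")
print(f"protein    : {format_hgvs(v_p)}   (codon 4, middle position)")
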