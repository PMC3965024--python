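"""Remap positions between the record and a genome assembly through an
alignment with sequence differences.

The mapping has one minus-strand span and two indel differences; positions
3' of an indel shift by its length, and positions inside an insertion have no
counterpart on the other side and are reported as such.
"""

from lrgkit import (
    AssemblyMapping,
    MappingSpan,
    SequenceDiff,
    assembly_to_lrg,
    lrg_to_assembly,
)
from lrgkit.coords import UnmappableDiffError

# LRG 1..100 aligns to chr5:2001..2102 on the minus strand; the LRG carries a
# 2 bp insertion at 40-41 and the assembly a 4 bp insertion after LRG base 70.
mapping = AssemblyMapping(
    assembly="GRCh38",
    other_name="chr5",
    spans=(MappingSpan(1, 100, 2001, 2102, -1),),
    diffs=(
        SequenceDiff("lrg_insertion", 40, 41, 2063, 2063, "AT", ""),
        SequenceDiff("assembly_insertion", 70, 70, 2030, 2033, "", "GGCC"),
    ),
)

for g in (1, 39, 42, 70, 71, 100):
    pos, strand = lrg_to_assembly(mapping, g)
    back = assembly_to_lrg(mapping, pos)
    print(f"LRG {g:>3} -> {mapping.other_name}:{pos} (strand {strand:+d}); "
          f"back -> {back}")

try:
    lrg_to_assembly(mapping, 40)
except UnmappableDiffError as exc:
    print(f"LRG  40 -> {exc}")
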