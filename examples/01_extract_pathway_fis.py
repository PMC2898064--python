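"""Extract functional interactions from pathway content.

Builds a toy reaction (two inputs, a catalyst, an inhibitor, an output)
and a small complex, and prints the FIs each implies.  Every pair of
proteins acting in the same reaction — as input, catalyst, activator or
inhibitor — or sitting in the same complex is a functional interaction;
the reaction output takes no part.
"""

from finet import (
    ComplexRecord,
    ProteinRef,
    ReactionRecord,
    extract_fis_from_complex,
    extract_fis_from_reaction,
)

reaction = ReactionRecord(
    id="kinase_step",
    inputs=frozenset({ProteinRef("SUBSTRATE1"), ProteinRef("SUBSTRATE2")}),
    catalysts=frozenset({ProteinRef("KINASE")}),
    inhibitors=frozenset({ProteinRef("REPRESSOR")}),
    outputs=frozenset({ProteinRef("PRODUCT")}),
)

print("Reaction FIs (note PRODUCT appears in none):")
for fi in sorted(extract_fis_from_reaction(reaction), key=lambda f: f.pair):
    arrow = f"  [{fi.direction}"
    if fi.direction_source:
        arrow += f" from {fi.direction_source}"
    arrow += "]"
    print(f"  {fi.pair[0]} -- {fi.pair[1]}{arrow}")

complex_ = ComplexRecord(
    id="trimer",
    components=frozenset(
        {ProteinRef("SUBUNIT_A"), ProteinRef("SUBUNIT_B"),
         ProteinRef("SUBUNIT_C")}
    ),
)
print("\nComplex FIs (all undirected member pairs):")
for fi in sorted(extract_fis_from_complex(complex_), key=lambda f: f.pair):
    print(f"  {fi.pair[0]} -- {fi.pair[1]}")

# A catalyst or activator points an "activates" edge at each input and an
# inhibitor an "inhibits" edge; co-inputs and complex members are
# undirected.  These tags matter downstream: a mutation in a regulator
# supports a hypothesis about its targets, but not the other way round.
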