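# Monosaccharide template: D-glucopyranose (pyranose chair, GLYCAM/Amber atom names)
# Schema:
#   sugar <ID>
#   atom <name> <element> <heavy|h>
#   bond <name1> <name2>
#   ring <six ring atom names in cycle order C1..C5,O5>
#   hydroxyl <position> <oxygen name>
#   stereo <atom> <descriptor>      # metadata only; not used by graph code
sugar GLC
atom C1 C heavy
atom H1 H h
atom O1 O heavy
atom HO1 H h
atom C2 C heavy
atom H2 H h
atom O2 O heavy
atom HO2 H h
atom C3 C heavy
atom H3 H h
atom O3 O heavy
atom HO3 H h
atom C4 C heavy
atom H4 H h
atom O4 O heavy
atom HO4 H h
atom C5 C heavy
atom H5 H h
atom O5 O heavy
atom C6 C heavy
atom H61 H h
atom H62 H h
atom O6 O heavy
atom HO6 H h
bond C1 C2
bond C2 C3
bond C3 C4
bond C4 C5
bond C5 O5
bond O5 C1
bond C5 C6
bond C1 O1
bond C2 O2
bond C3 O3
bond C4 O4
bond C6 O6
bond C1 H1
bond C2 H2
bond C3 H3
bond C4 H4
bond C5 H5
bond C6 H61
bond C6 H62
bond O1 HO1
bond O2 HO2
bond O3 HO3
bond O4 HO4
bond O6 HO6
ring C1 C2 C3 C4 C5 O5
hydroxyl 1 O1
hydroxyl 2 O2
hydroxyl 3 O3
hydroxyl 4 O4
hydroxyl 6 O6
stereo C2 equatorial
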