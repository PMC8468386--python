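# Fragment-disconnection cut rules (RECAP-like subset).
#
# Each SMARTS names the bond to break via map atoms :1 and :2.
- "[R:1]-!@[R:2]"            # acyclic single bond joining two ring systems
- "[CX3:1](=O)-!@[NX3:2]"    # amide C-N
- "[CX3:1](=O)-!@[OX2:2][#6]"  # ester C-O
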