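"""Decompose the canonical logic gates with both redundancy functions.

The gates are the standard test battery for information decomposition:
XOR is pure synergy (the target is readable only from both inputs
jointly), the redundant copy is pure redundancy (either input alone tells
you everything), COPY is pure unique information, and AND mixes
redundancy with synergy even though its inputs are independent.
"""

from synpid import gate_distribution, node_label, pid_broja, pid_imin

SOURCES = [("X1",), ("X2",)]

for name in ("xor", "and", "copy_x1", "redundant_copy"):
    dist = gate_distribution(name)
    print(f"\n{name.upper()}")
    for method, fn in (("Imin", pid_imin), ("optimization", pid_broja)):
        r = fn(dist, SOURCES, "Y")
        atoms = {node_label(k): round(float(v), 4) for k, v in sorted(
            r.atoms.items(), key=lambda kv: node_label(kv[0]))}
        print(f"  {method:>12}: joint MI {r.joint_mi:.4f} bits, atoms {atoms}")

print(
    "\nEach line splits the joint mutual information into redundant {1}{2},"
    "\nunique {1}/{2}, and synergistic {12} bits; the two redundancy"
    "\nfunctions agree on every gate."
)
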