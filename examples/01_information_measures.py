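"""Compare MI, CMI and CMI2 on the three canonical gene-triple scenarios.

Each scenario is an exact population Gaussian over genes (X, Y, Z), so
the printed numbers are analytic, not estimates.  The interesting case is
the last one: Z is a near-copy of Y, conditioning on it drives plain CMI
of a genuinely direct X-Y edge to ~0 (a false negative at any reasonable
threshold), while CMI2 keeps the edge clearly above threshold.
"""

from cmi2ni import TripleQuery, cmi, cmi2, fixture_triples, mi

q = TripleQuery("X", "Y", ("Z",))

for scenario in ("independent-pair", "mediated-chain", "redundant-conditioner"):
    model, dag = fixture_triples(scenario)
    direct = frozenset(("X", "Y")) in dag.skeleton
    print(f"{scenario}  (X-Y edge truly present: {direct})")
    print(f"  MI(X;Y)      = {mi(model, 'X', 'Y'):.4f} nats")
    print(f"  CMI(X;Y|Z)   = {cmi(model, q):.4f} nats")
    print(f"  CMI2(X;Y|Z)  = {cmi2(model, q):.4f} nats")
    print()

print("MI overestimates in the mediated chain (the X-Y dependence is all")
print("via Z); CMI fixes that but collapses under the redundant")
print("conditioner; CMI2 is correct in all three cases.")
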