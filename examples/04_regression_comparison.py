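"""Why an interaction-term regression cannot tell redundancy from synergy.

Two columns are constructed from the same synthetic cohort: a cyclically
shifted copy of the income bracket (all of its health information is
redundant with income) and the income-health parity (informative about
health only jointly with income).  The information decompositions are
categorically different; the interaction-term regressions are not.
"""

from synpid import GeneratorConfig, dummy_experiment, generate_population, node_label

table = generate_population(GeneratorConfig(n=59_858, seed=1))
res = dummy_experiment(table)

print("Information view:")
for label, r in [
    ("income + shifted copy", res.pid_red_construct),
    ("income + parity      ", res.pid_syn_construct),
]:
    top = node_label(max(r.atoms, key=r.atoms.get))
    share = r.fractions[max(r.atoms, key=r.atoms.get)]
    print(f"  {label}: dominant atom {top} carrying {100*share:.1f}% of the MI")

print("\nRegression view (health ~ income * construct):")
for label, fit in [("shifted copy", res.fit_red), ("parity      ", res.fit_syn)]:
    print(
        f"  {label}: betas "
        + ", ".join(f"{b:+.3f}" for b in fit.coefficients)
        + f"; interaction t = {fit.t_statistics[3]:+.1f}"
    )

print(
    "\nBoth regressions report significant interactions with the same sign"
    "\npattern — from the coefficients alone you cannot tell which construct"
    "\nwas pure redundancy and which was almost pure synergy."
)
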