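"""Stress-testing the pipeline: shrinking samples and injected noise.

Small samples inflate plug-in information estimates, so the
whole-minus-sum heuristic is over-estimated at a few hundred records and
converges by a thousand or so.  Scrambling a fraction of rows (column
shuffles that keep every marginal) erodes the measured association but
leaves the redundant/synergistic shares nearly unchanged.
"""

from synpid import CohortConfig, GeneratorConfig, generate_population
from synpid.robustness import noise_sweep, subsample_sweep

table = generate_population(GeneratorConfig(n=6_000, seed=21))
config = CohortConfig(n_resamples=10, seed=0)

sub = subsample_sweep(
    table, sizes=(250, 500, 1_000, 2_000, 4_000, 6_000),
    reps=25, seed=3, config=config,
)
print("Whole-minus-sum vs subset size (mean over 25 replicates):")
print(
    sub.data.groupby("axis")["whole_minus_sum"].mean()
    .to_string(float_format=lambda v: f"{v:+.4f}")
)

noi = noise_sweep(
    table, fractions=(1e-4, 1e-3, 1e-2, 0.05, 0.10),
    reps=25, seed=4, config=config,
)
print("\nAtom shares vs scrambled-row fraction:")
print(
    noi.data.groupby("axis")[["redundant_fraction", "synergistic_fraction"]]
    .mean().to_string(float_format=lambda v: f"{v:.3f}")
)

print(
    "\nThe first table shows the small-sample over-estimation shrinking"
    "\ntoward the full-sample value; the second shows the decomposition's"
    "\nshares staying within a narrow band as noise rises to 10%."
)
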