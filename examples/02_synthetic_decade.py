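"""A ten-year synthetic cohort through the full effective-information pipeline.

Generates ten census-like survey years, applies the cohort filters
(working-age, native-born, full-time employed, single-race categories),
coarse-grains income into four brackets, forces the joint identity-cell
distribution to uniform by balanced resampling, and decomposes the
effective information of the three standard source/target combinations.
"""

from synpid import CohortConfig, GeneratorConfig, decade_analysis, generate_population

tables = []
for i in range(10):
    t = generate_population(GeneratorConfig(n=12_000, filter_fail_fraction=0.05, seed=i))
    t.year = 2011 + i
    tables.append(t)

config = CohortConfig(n_resamples=100, seed=0)
result = decade_analysis(tables, config=config)

print("Across-year mean and sd of each atom's share of the joint MI:\n")
print(result.summary.to_string(index=False, float_format=lambda v: f"{v:.3f}"))

wms = result.wms.groupby("triad")["whole_minus_sum"].mean()
print("\nMean whole-minus-sum (bits) per triad:")
print(wms.to_string(float_format=lambda v: f"{v:+.4f}"))

print(
    "\nA positive whole-minus-sum says the identities jointly disclose more"
    "\nabout the outcome than the sum of their separate contributions; the"
    "\nsmall sd columns show the decomposition is stable across years."
)
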