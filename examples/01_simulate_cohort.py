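"""Generate a synthetic reference cohort and inspect its structure.

The cohort stands in for the large population reference datasets an
imputation model would normally be fitted on: correlated mixed-type risk
factors drawn through a Gaussian copula, with family history generated
conditionally on the genetic factors.
"""
import riskuq as rq

schema = rq.default_schema()
pop = rq.default_population()
cohort = rq.simulate_cohort(schema, pop, n=10_000, seed=42)

rec = cohort.records
print(f"cohort: {len(rec)} records, {len(schema.names)} risk factors\n")
print(rec[schema.names].head(5).to_string(), "\n")
print("polygenic score: mean %.3f, SD %.3f (standard normal by construction)"
      % (rec.pgs.mean(), rec.pgs.std()))
print("pathogenic-variant carriers:", (rec.pv != "none").sum(),
      "(rare: each gene frequency <= 1%)")
print("zero alcohol intake: %.1f%% (structural zeros of the two-part model)"
      % (100 * (rec.alcohol == 0).mean()))
print("family history 1 / 2+ affected relatives: %.1f%% / %.1f%%"
      % (100 * (rec.family_history == "1").mean(),
         100 * (rec.family_history == "2+").mean()))
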