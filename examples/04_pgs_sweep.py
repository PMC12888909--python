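"""How uncertainty varies with the polygenic score.

Same family-history background, variant status known to be negative, PGS
fixed at each decile of its standard-normal distribution, all remaining
factors unmeasured. Point estimates rise with the PGS percentile and the
95% UIs widen — individuals at higher predicted risk carry more absolute
uncertainty from their unmeasured factors.
"""
import riskuq as rq

schema = rq.default_schema()
pop = rq.default_population()
cohort = rq.simulate_cohort(schema, pop, n=20_000, seed=1)
models = rq.fit_conditional_models(cohort, schema)
pop = rq.calibrate_baseline(pop, schema, cohort)

profile = rq.IndividualProfile(
    age=40,
    values={v.name: None for v in schema} | {"family_history": "2+", "pv": "none"},
)
sweep = rq.pgs_sweep(profile, models, pop, schema, M=2000, seed=5)

print("PGS pct   point est.   95% UI           width")
for p, dist in sweep.items():
    lo, hi = dist.ui
    print("  %2d      %5.1f%%      %4.1f%% - %5.1f%%   %5.1f%%"
          % (p, 100 * dist.point_estimate, 100 * lo, 100 * hi, 100 * (hi - lo)))
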