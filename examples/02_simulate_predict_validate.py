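"""Full pipeline on synthetic data: simulate -> predict -> validate.

Generates a year of synthetic exposures with a planted lag-1 PM10 effect on
admissions, predicts daily admissions with the fuzzy model, and scores the
predictions against the simulated counts at lags 0-2.
"""

from fuzzyair import (
    GeneratorSpec,
    build_default_system,
    generate_admissions,
    generate_exposures,
    predict_series,
    validate,
)

spec = GeneratorSpec(n_days=365, seed=7, betas={"pm10": {1: 0.3}})
series = generate_admissions(generate_exposures(spec), spec)
print(f"simulated {len(series)} days; "
      f"mean admissions {series['admissions'].mean():.2f}/day")

system = build_default_system()
pred = predict_series(system, series)
print(f"predictions span {pred['predicted'].min():.2f} to "
      f"{pred['predicted'].max():.2f} admissions/day")

report = validate(pred["predicted"].to_numpy(),
                  series["admissions"].to_numpy(),
                  lags=(0, 1, 2), threshold=2)
print()
print(report.render())

best = max(report.results, key=lambda r: r.auc)
print(
    f"\nThe planted effect acts at lag 1 and the AUC ranking recovers it "
    f"(best lag = {best.lag}).\n"
    "AUC ~0.5 would be chance; the Hanley-McNeil intervals quantify the\n"
    "uncertainty of each AUC at this series length."
)
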