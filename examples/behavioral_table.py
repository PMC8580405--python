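"""Behavioral table: summary means and responder classification.

Loads the packaged 24-patient table (three stimulation groups, three time
points), reproduces its summary means, and classifies responders by the
sign of the visual-field (FOV) percentage change from baseline.
"""

from hemianet import (
    classify_responders,
    load_cohort,
    percentage_change,
    responder_counts,
    summarize,
)

records = load_cohort()
summary = summarize(records)
print("cohort of", len(records), "patients; selected summary means:")
for col in ("lesion_age_months", "hrp_black_pre", "fov_pre", "fov_post",
            "age_years"):
    print(f"  {col:<18} {summary.loc[col, 'mean']:>8.2f} "
          f"(SD {summary.loc[col, 'sd']:.2f})")

labels = classify_responders(records, later="post")
n_resp, n_non = responder_counts(labels)
print(f"\nresponders (FOV % change post vs pre > 0): {n_resp}")
print(f"non-responders:                            {n_non}")

pct = percentage_change(records, "fov", later="post", baseline="pre")
print(f"largest improvement: patient {pct.idxmax()} ({pct.max():+.1f}%)")
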