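"""Test functional redundancy as a barrier to FMT donor engraftment.

Generates a synthetic FMT cohort in which the fraction of donor-specific
strains observed post-FMT declines with the recipient's pre-FMT functional
redundancy (known negative effect), then fits the multiple linear regression
of f_ds on FR_pre and days post-FMT and reports the F test.
"""

from gcnfr import (
    SynthSpec,
    donor_specific_fraction,
    engraftment_regression,
    synth_fmt_dataset,
    synth_gcn,
)

g = synth_gcn(SynthSpec("identical_genomes", 5, 20))
records, truth = synth_fmt_dataset(
    25, fr_effect=-0.5, noise_sd=0.05, g=g, seed=7
)

print("first records (recipient, t_post, f_ds):")
for rec in records[:5]:
    print(f"  {rec.recipient_id}  day {rec.t_post:>2d}  "
          f"f_ds = {donor_specific_fraction(rec):.2f}")

report = engraftment_regression(records, "FR", g)
print(f"\nground truth: intercept {truth['beta0']}, FR effect "
      f"{truth['fr_effect']}, day effect {truth['beta2']}")
print(report.summary_frame().round(4).to_string())
print(f"F = {report.f_statistic:.2f}, p = {report.f_pvalue:.2e}, "
      f"R^2 = {report.r_squared:.3f} (n = {report.n_obs})")

print(
    "\nThe fitted FR coefficient is negative and the F test significant:"
    "\nrecipients with more redundant pre-FMT communities engraft fewer"
    "\ndonor-specific strains."
)
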