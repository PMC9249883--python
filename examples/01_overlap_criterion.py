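"""The overlap criterion: how far must a reference gene sit from a target?

A reference gene R is safe for normalizing a target T only when their
expression distributions are separated: |muT - muR| >= 3*sdT + 2*sdR.
This script evaluates the worked scenarios for a unit-SD target and
then applies the criterion to lab-scale Cq statistics.
"""

from refselect import criterion_passes, required_gap

print("Minimum mean separation for a target with SD = 1 Cq cycle:")
for sd_r in (0.0, 0.25, 0.5, 1.0):
    print(f"  reference SD {sd_r:4.2f} -> gap >= {required_gap(1.0, sd_r):.1f} cycles")
# Doubling the reference SD adds two cycles to the requirement: the
# reference's own spread contributes 2*sdR on top of the target's 3*sdT.

print()
print("Applying the criterion to tumor-tissue Cq statistics:")
cases = [
    # (target mean, ref mean, target sd, ref sd, label)
    (28.44, 25.69, 2.65, 3.85, "high-variance reference (GAPDH-like)"),
    (28.44, 29.59, 2.65, 1.62, "low-variance overlapping reference (SYMPK-like)"),
    (28.44, 15.00, 2.65, 0.80, "well-separated low-variance reference"),
]
for mu_t, mu_r, sd_t, sd_r, label in cases:
    rec = criterion_passes(mu_t, mu_r, sd_t, sd_r)
    verdict = "PASS" if rec.passes else "FAIL"
    print(
        f"  {label}: gap {rec.gap:.2f} vs required {rec.required_gap:.2f} "
        f"(margin {rec.margin:+.2f}) -> {verdict}"
    )
# A negative margin means the two Cq distributions overlap enough that
# individual samples can flip the sign of their ddCq, so expression
# calls would depend on which reference gene was chosen.
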