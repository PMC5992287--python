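"""The complete gated workflow on one simulated patient.

VT2 screening -> 70% gate (with a mechanical-artifact ceiling) -> VT3
attended-wrist paradigm -> six yes/no communication questions decoded with
a permutation test that abstains when the evidence is weak.
"""

from vibrotap import (RunConfig, SubjectProfile, run_pipeline)

config = RunConfig(
    out_dir="scratch/example_assessment",
    profile=SubjectProfile(p3_amplitude_uv=8.0, noise_sd_uv=1.0,
                           artifact_rate_per_min=0.0),
    n_questions=6,
    intended_answers=("yes", "no", "yes", "no", "yes", "no"),
)
report = run_pipeline(config)

asmt = report["stages"]["assessment"]
print(f"VT2 performance : {asmt['vt2']['performance_pct']:.1f}% "
      f"({asmt['vt2']['n_rejected']} trials rejected)")
print(f"escalated to VT3: {asmt['escalated']} "
      f"(artifact flag: {asmt['artifact_flag']})")
if asmt["vt3"]:
    print(f"VT3 performance : {asmt['vt3']['performance_pct']:.1f}%")
print(f"covert command following concluded: {asmt['covert_cf']}")
print("decoded answers :", [a["answer"] for a in asmt["answers"] or []],
      "(intended:", list(config.intended_answers), ")")
print("full report in  :", config.out_dir + "/report.json")
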