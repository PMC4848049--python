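"""Full pipeline on a simulated lesion survey with a planted conduction gap.

A 4x4 site grid carries a lesion line on rows B and C; site B3 is left
unablated (the planted gap). Every site is probed pre- and post-ablation,
the recordings are calibrated, filtered and run through MAP detection, the
pre-ablation detection forces become the site-matched references, and the
classifier labels each site.
"""

from mapgap import LesionPattern, SimulationConfig, analyze_survey, classify_survey, generate_survey

pattern = LesionPattern.grid(
    4, 4,
    pattern_sites=["B1", "B2", "B3", "B4", "C1", "C2", "C3", "C4"],
    gap_sites=["B3"],
)
survey = generate_survey(pattern, SimulationConfig(seed=7))
pre, post = analyze_survey(survey)
report = classify_survey(post, pre_assessments=pre)

print(report.to_table())
print(f"\nplanted gap: B3; recovered gap set: {report.gap_sites}")
print("-> the ablated line reads non-conductive, tissue off the line stays"
      " conductive, and the planted gap is recovered exactly.")
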