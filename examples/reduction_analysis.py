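"""Estimate the DC-mediated reduction of windowed evoked activity.

Generates a neuropathic-group tactile cohort whose true during-DC reduction
is the generator default for that condition (57.6%), runs windowed counting
and evoked classification, fits the linear mixed model (animal and unit as
random effects) and reports estimated marginal means (EMMs) and the percent
reduction 100 x (1 - EMM_during / EMM_pre).
"""

from dcblock.orchestrate import PipelineConfig, run_pipeline

cfg = PipelineConfig(modality="tactile", group="neuropathic",
                     n_animals=6, units_per_animal=10, seed=42,
                     generator={"n_pre_sets": 2, "n_post_sets": 0})
report = run_pipeline(cfg)
red = report.reduction

print(f"units analysed (evoked pre-DC): {red['n_units']}")
print(f"EMM pre-DC windowed count:    {red['emm_pre']:.3f} +- {red['se_pre']:.3f}")
print(f"EMM during-DC windowed count: {red['emm_dc']:.3f} +- {red['se_dc']:.3f}")
print(f"percent reduction: {red['pct_reduction']:.1f}%  (phase contrast "
      f"p = {red['p']:.2e})")
print("generator truth for this condition is 57.6%; the estimate should land")
print("within a few points of it, since the during/pre expectation ratio is")
print("1 - r by construction and the EMM ratio is an unbiased estimate of it.")
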