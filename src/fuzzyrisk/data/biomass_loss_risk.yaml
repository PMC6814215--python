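# Default biomass-loss-risk logic tree.
#
# Six fuzzified inputs feed a fire branch (burned biomass / fire frequency
# joined by Union, gated by modeled total biomass) and a mortality branch
# (vegetation-departure stress gated by modeled live biomass); the two
# branches combine with Or into the model-only risk node, which is finally
# And-ed with the observed-biomass input so risk (and its uncertainty) is 0
# wherever observed biomass is 0.
#
# Input thresholds here are the frozen "paper" profile (false = 10th
# percentile, true = 90th percentile of the original baseline-period
# distributions); the pipeline can re-derive them from any baseline bundle.
name: biomass_loss_risk
nodes:
  - name: biomass_burned_high
    statement: "Simulated biomass burned is high"
    kind: input
    variable: mc2_biomass_burned
    thresholds: {"false": 0.0, "true": 110.0}
  - name: fire_frequency_high
    statement: "Simulated fire frequency is high"
    kind: input
    variable: mc2_fire_frequency
    thresholds: {"false": 0.0, "true": 1.0}
  - name: biomass_high
    statement: "Simulated biomass is high"
    kind: input
    variable: mc2_biomass
    thresholds: {"false": 31572.0, "true": 73148.0}
  - name: live_biomass_high
    statement: "Simulated live biomass is high"
    kind: input
    variable: mc2_live_biomass
    thresholds: {"false": 5839.0, "true": 29387.0}
  - name: vegetation_stress_high
    statement: "Vegetation-type departure from baseline is high"
    kind: input
    variable: mc2_vegetation_stress
    thresholds: {"false": 0.0, "true": 3.0}
  - name: observed_biomass_high
    statement: "Observed biomass is high"
    kind: input
    variable: observed_biomass
    thresholds: {"false": 4053.0, "true": 21844.0}
  - name: fire_threat
    statement: "Fire threat is high"
    kind: union
    children: [biomass_burned_high, fire_frequency_high]
  - name: fire_loss_risk
    statement: "Risk of losing biomass to fire is high"
    kind: and
    children: [fire_threat, biomass_high]
  - name: mortality_risk
    statement: "Risk of losing biomass to climate-maladaptation mortality is high"
    kind: and
    children: [vegetation_stress_high, live_biomass_high]
  - name: mc2_biomass_loss_risk
    statement: "Simulated risk of biomass loss is high"
    kind: or
    children: [fire_loss_risk, mortality_risk]
  - name: biomass_loss_risk
    statement: "Risk of biomass loss is high"
    kind: and
    children: [mc2_biomass_loss_risk, observed_biomass_high]
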