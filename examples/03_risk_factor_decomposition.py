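"""Risk-factor routes: odds-ratio decomposition of stunting.

Preventive zinc supplementation does not avert deaths directly; it
lowers the odds of stunting (odds ratio 1.18 for unsupplemented vs
supplemented children).  With 25% supplemented and 35% of children
stunted at baseline, the two-status solve splits the population into
status-specific stunting probabilities; scaling supplementation to 50%
projects a lower prevalence.  A drop in diarrhoea incidence from 3 to 2
episodes/year enters the same machinery through a per-episode odds
ratio raised to the mean episode count.
"""

import childimpact as ci

p_risky, p_nonrisky = ci.solve_two_state(
    ci.TwoStateRiskModel(odds_ratio=1.18, risky_fraction=0.75, prevalence=0.35)
)
print(f"stunting among unsupplemented children: {100 * p_risky:.1f}%")
print(f"stunting among supplemented children:   {100 * p_nonrisky:.1f}%")

projected = ci.project_prevalence(p_risky, p_nonrisky, new_risky_fraction=0.50)
decline = ci.prevalence_reduction(0.35, projected)
print(f"scale-up to 50% supplementation: prevalence {100 * projected:.1f}%, "
      f"a {100 * decline:.1f}% proportional decline")

model = ci.diarrhoea_or_to_two_state(
    baseline_episodes=3.0, target_episodes=2.0, per_episode_or=1.05
)
print(f"3 -> 2 episodes/year: {100 * model.risky_fraction:.1f}% of children keep "
      f"3 episodes, {100 * (1 - model.risky_fraction):.1f}% move to none "
      f"(population stunting OR {model.odds_ratio:.3f})")
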