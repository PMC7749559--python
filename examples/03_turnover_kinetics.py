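"""Why the non-steady-state correction matters during atrophy.

Plants a degradation constant in an atrophying pool (r < 1 over the label
window), then estimates kdeg with and without the pool-ratio correction.
"""

from heavywater import kdeg_nonsteady, kdeg_steady, ksyn_nonsteady, simulate_pool

true_kdeg, true_ksyn, t = 0.0490, 0.02, 5.0
pool = simulate_pool(true_ksyn, true_kdeg, p0=1.0, t=t)
f, r = pool.fraction_new, pool.r
print(f"planted kdeg = {true_kdeg}/day, ksyn = {true_ksyn}/day over {t} days")
print(f"observables: fraction new f = {f:.4f}, pool ratio r = {r:.4f} (atrophy)")

naive = kdeg_steady(f, t)
corrected = kdeg_nonsteady(f, r, t)
ksyn = ksyn_nonsteady(corrected, f, r, 1.0, t)
print(f"steady-state estimate   : kdeg = {naive:.4f}/day  (biased low: pool shrank)")
print(f"non-steady-state inverse: kdeg = {corrected:.4f}/day, ksyn = {ksyn:.4f}/day")
# Ignoring the pool loss attributes too little of the labelling deficit to
# degradation; the closed form kdeg = -ln(r(1-f))/t recovers the plant exactly.
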