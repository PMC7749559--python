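"""From a measured isotopomer distribution to fraction-new protein.

Forward-simulates one sample at a known excess enrichment, then runs the
analysis direction: natural-abundance correction -> precursor enrichment ->
f = E/p.
"""

from heavywater import (
    correct_natural_abundance,
    fraction_new,
    isotopomerize,
    natural_isotopomer_distribution,
    precursor_enrichment,
)

nat = natural_isotopomer_distribution()
print("natural M0..M3 baseline:", [f"{x:.5f}" for x in nat])

true_excess = 0.0222
sample = isotopomerize(true_excess, natural_dist=nat)
print("labelled sample M0..M3:", [f"{x:.5f}" for x in sample.fractions])

excess = correct_natural_abundance(sample, nat)
p = precursor_enrichment(body_water=0.03, n_sites=3.7)
f = fraction_new(excess, p)
print(f"recovered excess enrichment E = {excess:.4f} (planted {true_excess})")
print(f"precursor enrichment p = {p.p:.4f} (0.03 body water x 3.7 sites)")
print(f"fraction-new protein f = {f.f:.4f}")
# f = E/p is the fraction of the protein pool synthesized during labelling;
# it is the sole kinetic observable besides the pool-size ratio.
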