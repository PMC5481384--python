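"""Design calculator: how likely is a sample to contain enough short-lookers?

If only short-looking infants show a same-race preference at 3 months, a
study needs enough of them per cohort for an unconditional test to stand a
chance.  Sampling infants is a Bernoulli process with per-infant SL
probability p.
"""

from lookmix import sampling_probability

p_sl = 21 / 58  # weak-SL share among 3-month infants
need = 5        # SL infants needed in a cohort of 12

for k in (1, 2, 3):
    q = sampling_probability(12, p_sl, need, n_samples=k)
    print(f"P(all of {k} independent cohorts of 12 have >= {need} SL infants)"
          f" = {q:.2f}")
print("\nwith a third of infants short-looking, even one adequately "
      "composed cohort is a coin flip - and three in a row are rare; "
      "null preference findings in small samples may reflect looking-style "
      "composition rather than absent preference")
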