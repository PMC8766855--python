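"""Quantify the center-periphery bias before and after correction.

Builds a two-day phantom pair, reads per-neuron activities at fixed centre
pixels, and prints the normalised bias statistics DeltaC and DeltaSTD for
center-angle (C-A) versus edge-edge (E-E) region pairs.  Values near 1 mean
no bias; DeltaC(C-A) << 1 and DeltaSTD(C-A) >> 1 are the vignetting
signature.
"""

from vigncorr import pipeline
from vigncorr.phantom import PhantomSpec, generate_phantom

spec = PhantomSpec(n_slices=2, neurons_per_slice=250, seed=3)
ph = generate_phantom(spec)

f0 = pipeline.estimate_stack_fields(ph.stack_day0)
f1 = pipeline.estimate_stack_fields(ph.stack_day1)
consts = pipeline.stack_constants(f0 + f1)
c0 = pipeline.correct_stack(ph.stack_day0, f0, consts)
c1 = pipeline.correct_stack(ph.stack_day1, f1, consts)

for label, s0, s1 in [("raw", ph.stack_day0, ph.stack_day1),
                      ("corrected", c0, c1)]:
    _, summ = pipeline.evaluate_stack_pair(s0, s1, ph.neuron_table,
                                           layers=[None], measures=("X",))
    s = summ[(None, "X")]
    print(f"{label:9s}: DeltaC(C-A)={s.loc['C-A', 'delta_c']:5.2f}  "
          f"DeltaC(E-E)={s.loc['E-E', 'delta_c']:5.2f}  "
          f"DeltaSTD(C-A)={s.loc['C-A', 'delta_stdev']:5.2f}  "
          f"DeltaSTD(E-E)={s.loc['E-E', 'delta_stdev']:5.2f}")
print("After full correction all four statistics should sit near 1: the "
      "center-periphery bias in neural activity is gone.")
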