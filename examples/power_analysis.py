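"""Power of a 1-df chi-square association test as a function of the
noncentrality parameter, at alpha = 0.05.

The noncentrality parameter summarizes effect size and sample size together;
ncp ~ 7.85 is the classic 80%-power reference point.
"""

from poolgwas import power_chisq

for ncp in (0.0, 2.0, 4.0, 7.849, 12.0, 20.0):
    print(f"ncp = {ncp:6.3f}  ->  power = {power_chisq(0.05, 1, ncp):.3f}")
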