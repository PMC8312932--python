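"""Apply the two maturity-offset prediction equations to one measurement.

A 13-year-old boy, 160 cm tall, sitting height 83 cm, 50 kg.  Negative
offsets mean the spurt peak is still ahead; predicted APHV is age minus
offset.
"""

from phvalid import mirwald_offset, moore_offset

ca, height, sitting, weight = 13.0, 160.0, 83.0, 50.0
mir = mirwald_offset(ca, height, sitting, weight)
moo = moore_offset(ca, height)

print(f"Mirwald offset: {mir:+.3f} yr  ->  predicted APHV {ca - mir:.2f} yr")
print(f"Moore offset:   {moo:+.3f} yr  ->  predicted APHV {ca - moo:.2f} yr")
# Both equations place this boy about half a year before his spurt peak;
# the Mirwald equation (using trunk/leg proportions and weight) predicts a
# slightly later peak than the age-by-height Moore equation.
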