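"""Hypergeometric overlap of two DEG signatures.

The overlap p-value is computed in log space, so the astronomically small
values produced by concordant signatures (1e-200 and beyond) remain exact
rather than underflowing to zero.
"""

from sigforge import overlap_signatures
from sigforge.diffexpr import hypergeom_upper_logp

# toy: two 5-gene lists that coincide completely within a 10-gene universe
res = overlap_signatures(list("abcde"), list("abcde"), background_n=10)
print(f"toy overlap: k={res.k}, p={res.p:.6g}  (exactly 1/C(10,5) = 1/252)")

# at published-signature scale the upper-tail mass is far below underflow
logp = hypergeom_upper_logp(264, 488, 960, 20000)
print(f"264-gene overlap of 488- and 960-gene lists in a 20000-gene universe:")
print(f"  log10(p) = {logp:.1f}  (p ~ 1e{logp:.0f}, representable only in log space)")
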