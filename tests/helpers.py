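"""A straight-line, unvectorized re-implementation of the decision tree.

Deliberately independent of the package internals: plain floats, no
shared helpers, every branch written out.  Used as the oracle when
checking that the pipeline's classification agrees exactly.
"""

from __future__ import annotations


def naive_classify(aina, ainb, binb, bina, theta):
    """Return (category, block_subtype, subtype_a, subtype_b) as strings."""
    if aina == 0 or binb == 0:
        return "unclassified", "none", "none", "none"

    e1a = abs(aina - ainb) / abs(aina)
    e1b = abs(binb - bina) / abs(binb)
    plastic_a = e1a > theta
    plastic_b = e1b > theta

    if not (plastic_a and plastic_b):
        den = abs((aina + binb) / 2.0)
        if den == 0:
            return "unclassified", "none", "none", "none"
        e2 = abs(aina - binb) / den
        if e2 <= theta:
            return "canalized_no_diff", "none", "none", "none"
        return "canalized_diff", "none", "none", "none"

    if aina == binb:
        return "unclassified", "none", "none", "none"
    e3a = abs(ainb - binb) / abs(aina - binb)
    e3b = abs(bina - aina) / abs(binb - aina)
    score = max(e3a, e3b)

    if score <= theta:
        return "perfect_adaptive", "none", "none", "none"
    if score < 1.0:
        return "adaptive", "none", "none", "none"

    sub_a = "none"
    if e3a >= 1.0:
        if (aina > binb and ainb < binb) or (aina < binb and ainb > binb):
            sub_a = "steep"
        elif (aina > binb and ainb > aina) or (aina < binb and ainb < aina):
            sub_a = "wrong_sign"
    sub_b = "none"
    if e3b >= 1.0:
        if (binb > aina and bina < aina) or (binb < aina and bina > aina):
            sub_b = "steep"
        elif (binb > aina and bina > binb) or (binb < aina and bina < binb):
            sub_b = "wrong_sign"
    block_sub = "wrong_sign" if "wrong_sign" in (sub_a, sub_b) else "steep"
    return "nonadaptive", block_sub, sub_a, sub_b
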