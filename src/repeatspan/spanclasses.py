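"""Span-class labels for reads relative to the repeat tract.

The labels follow the field's convention for spanning-read sorting:
forward-strand full span, reverse-strand full span, 5'-partial, 3'-partial,
and non-spanning.  Classes are read-orientation dependent: reverse
complementing a read swaps full_dGGCCTGn with full_dGGCCTGr and the two
partial classes with each other.
"""

FULL_FWD = "full_dGGCCTGn"
FULL_REV = "full_dGGCCTGr"
PARTIAL_5P = "5p_GGCCTGn"
PARTIAL_3P = "3p_GGCCTGn"
NON_SPANNING = "non_spanning"

#: All classes, in reporting order.
SPAN_CLASSES = (FULL_FWD, PARTIAL_5P, PARTIAL_3P, FULL_REV, NON_SPANNING)

#: Classes that overlap the repeat tract at all.
SPANNING_CLASSES = (FULL_FWD, PARTIAL_5P, PARTIAL_3P, FULL_REV)

#: Full-length classes (both flank anchors present).
FULL_CLASSES = (FULL_FWD, FULL_REV)

#: Effect of reverse complementing a read on its class.
RC_SWAP = {
    FULL_FWD: FULL_REV,
    FULL_REV: FULL_FWD,
    PARTIAL_5P: PARTIAL_3P,
    PARTIAL_3P: PARTIAL_5P,
    NON_SPANNING: NON_SPANNING,
}
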