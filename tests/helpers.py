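"""Shared test utilities."""

import dataclasses


def modify(p, **kw):
    """Replace parameter fields, dropping DSA ranges.

    Experimental parameter sets in tests often move a value outside its
    published sensitivity range; the range-bracketing invariant would
    (correctly) reject that, so the ranges are cleared unless supplied.
    """
    kw.setdefault("dsa_ranges", {})
    return dataclasses.replace(p, **kw)
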