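import numpy as np
import pytest

from qmapseq import build_tlr_construct
from qmapseq.constructs import LibraryDesign


@pytest.fixture(scope="session")
def wt_construct():
    return build_tlr_construct("WT")


@pytest.fixture(scope="session")
def three_construct_library():
    """Three scaffold variants distinguished by their 7-bp helix barcodes.

    Barcodes are mutually at hamming distance >= 5 so that single-error
    reads remain unambiguous at max_hamming 1.
    """
    recs = [
        build_tlr_construct("WT", barcode="GGCACUC"),
        build_tlr_construct("MUT1", barcode="CAUGGAG"),
        build_tlr_construct("MUT2", barcode="UCCUUGU"),
    ]
    return LibraryDesign(recs)


def random_balanced_structure(rng: np.random.Generator, length: int) -> str:
    """Random balanced dot-bracket string (may contain nested/serial helices)."""
    out = []
    open_count = 0
    remaining = length
    while remaining > 0:
        can_close = open_count > 0
        must_close = remaining == open_count
        if must_close:
            out.append(")")
            open_count -= 1
        else:
            r = rng.random()
            if r < 0.35 and remaining > open_count + 1:
                out.append("(")
                open_count += 1
            elif r < 0.65 and can_close:
                out.append(")")
                open_count -= 1
            else:
                out.append(".")
        remaining -= 1
    return "".join(out)
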